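"""Class-balanced train/test table assembly.

Feature tables are drawn per class without replacement from the pooled
feature rows, giving exactly balanced training and testing tables
(equal HC and PD counts).  The default draw is at the sample level —
rows of one speaker may land in both tables — because that is the
simplest reading of a random balanced draw; the audit therefore ALWAYS
reports subject overlap between tables so the resulting optimism risk is
visible.  Setting ``subject_disjoint`` draws over speakers first,
guaranteeing no speaker spans both tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FEATURE_COLUMNS, MFCC_COLUMNS, GTCC_COLUMNS

CLASSES = ("HC", "PD")


@dataclass
class FeatureTable:
    """A labelled feature table with column-access and evaluation tracking.

    ``matrix`` is the only sanctioned route to the numeric features; it
    records which columns were touched so experiments can prove that a
    single-feature-set run never read the other set's columns.
    """

    df: pd.DataFrame
    role: str  # train | test
    seed: int | None = None
    accessed_columns: set = field(default_factory=set)
    eval_count: int = 0

    def __len__(self) -> int:
        return len(self.df)

    @property
    def balance(self) -> dict[str, int]:
        return self.df["label"].value_counts().to_dict()

    def matrix(self, columns: list[str]) -> np.ndarray:
        self.accessed_columns.update(columns)
        return self.df[list(columns)].to_numpy(dtype=np.float64)

    @property
    def labels(self) -> np.ndarray:
        return self.df["label"].to_numpy()


@dataclass(frozen=True)
class SplitSpec:
    n_train: int
    n_test: int
    seed: int
    balanced: bool = True
    subject_disjoint: bool = False

    def __post_init__(self) -> None:
        if self.balanced and (self.n_train % 2 or self.n_test % 2):
            raise ValueError("balanced tables need even n_train and n_test")
        if self.n_train < 2 or self.n_test < 1:
            raise ValueError("table sizes too small")


def build_tables(features_df: pd.DataFrame, spec: SplitSpec) -> tuple[FeatureTable, FeatureTable]:
    """Draw disjoint balanced train/test tables from a pooled feature table.

    Per class, ``n_train/2`` rows are drawn first and ``n_test/2`` next,
    without replacement, using the spec's seed.  With
    ``subject_disjoint``, whole speakers are assigned to the training
    side until its quota is coverable, and test rows come only from the
    remaining speakers.
    """
    rng = np.random.default_rng(spec.seed)
    train_parts, test_parts = [], []
    if spec.balanced:
        quota = {c: (spec.n_train // 2, spec.n_test // 2) for c in CLASSES}
    else:
        # unbalanced mode: proportional split of requested totals
        counts = features_df["label"].value_counts()
        total = counts.sum()
        quota = {
            c: (round(spec.n_train * counts.get(c, 0) / total),
                round(spec.n_test * counts.get(c, 0) / total))
            for c in CLASSES
        }
    for cls in CLASSES:
        pool = features_df[features_df["label"] == cls]
        n_tr, n_te = quota[cls]
        if spec.subject_disjoint:
            subjects = pool["source_id"].str.split("#").str[0].to_numpy()
            uniq = np.array(sorted(set(subjects)))
            rng.shuffle(uniq)
            train_subjects, acc = [], 0
            for s in uniq:
                if acc >= n_tr:
                    break
                train_subjects.append(s)
                acc += int((subjects == s).sum())
            train_pool = pool[np.isin(subjects, train_subjects)]
            test_pool = pool[~np.isin(subjects, train_subjects)]
            if len(train_pool) < n_tr or len(test_pool) < n_te:
                raise ValueError(
                    f"class {cls}: subject-disjoint pools too small "
                    f"(train {len(train_pool)}/{n_tr}, test {len(test_pool)}/{n_te})"
                )
            tr_idx = rng.choice(train_pool.index.to_numpy(), n_tr, replace=False)
            te_idx = rng.choice(test_pool.index.to_numpy(), n_te, replace=False)
        else:
            if len(pool) < n_tr + n_te:
                raise ValueError(
                    f"class {cls}: need {n_tr + n_te} rows, have {len(pool)} "
                    f"(shortfall {n_tr + n_te - len(pool)})"
                )
            order = rng.permutation(pool.index.to_numpy())
            tr_idx, te_idx = order[:n_tr], order[n_tr:n_tr + n_te]
        train_parts.append(features_df.loc[tr_idx])
        test_parts.append(features_df.loc[te_idx])
    train_df = pd.concat(train_parts).reset_index(drop=True)
    test_df = pd.concat(test_parts).reset_index(drop=True)
    return (
        FeatureTable(train_df, role="train", seed=spec.seed),
        FeatureTable(test_df, role="test", seed=spec.seed),
    )


def _subjects(t: FeatureTable) -> set[str]:
    return set(t.df["source_id"].str.split("#").str[0])


def audit_table(t: FeatureTable, other: FeatureTable | None = None) -> dict:
    """Class counts, subject counts, duplicates, and cross-table overlap."""
    dup = t.df.duplicated(subset=["source_id", "chunk_index"])
    report = {
        "role": t.role,
        "n_rows": len(t),
        "class_counts": t.balance,
        "n_subjects": len(_subjects(t)),
        "duplicate_keys": int(dup.sum()),
    }
    if other is not None:
        overlap = _subjects(t) & _subjects(other)
        row_keys = set(map(tuple, t.df[["source_id", "chunk_index"]].to_numpy()))
        other_keys = set(map(tuple, other.df[["source_id", "chunk_index"]].to_numpy()))
        report["subject_overlap"] = sorted(overlap)
        report["row_overlap"] = len(row_keys & other_keys)
    return report


def feature_subset_columns(subset: str) -> list[str]:
    """Column names for a feature subset: 'mfcc', 'gtcc' or 'both'."""
    return {
        "mfcc": MFCC_COLUMNS,
        "gtcc": GTCC_COLUMNS,
        "both": FEATURE_COLUMNS,
    }[subset]
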