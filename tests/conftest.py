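import numpy as np
import pandas as pd
import pytest

from pdvoice import synth
from pdvoice.datasets import FeatureTable
from pdvoice.features import FEATURE_COLUMNS


@pytest.fixture(scope="session")
def clean_voice():
    """A perturbation-free voice: exactly periodic source, no noise."""
    spec = synth.hc_spec(jitter_pct=0.0, shimmer_pct=0.0, hnr_db=None, f0_sd=0.0)
    return synth.synth_voice(spec, 1.0, 16000, seed=11)


@pytest.fixture(scope="session")
def two_speaker_conversation():
    """One default synthetic conversation with its ground-truth timeline."""
    a = synth.hc_spec(f0_mean=100.0, hnr_db=None)
    b = synth.hc_spec(f0_mean=220.0, hnr_db=None,
                      formants=((600.0, 80.0), (1800.0, 120.0), (3000.0, 160.0)))
    script = synth.ConversationScript(tuple((k % 2, 2.0) for k in range(6)))
    conv, timeline = synth.synth_conversation(a, b, script, 16000, seed=5)
    return conv, timeline


def gaussian_features(n_per_class: int, separation: float, seed: int) -> pd.DataFrame:
    """Two Gaussian classes in 26-d feature space; unit within-class sd.

    The class centroids differ by ``separation`` standard deviations
    along the diagonal direction (split evenly over all coordinates).
    """
    rng = np.random.default_rng(seed)
    shift = separation / np.sqrt(len(FEATURE_COLUMNS))
    rows = []
    for cls, offset in (("HC", 0.0), ("PD", shift)):
        X = rng.standard_normal((n_per_class, len(FEATURE_COLUMNS))) + offset
        for i, x in enumerate(X):
            row = dict(zip(FEATURE_COLUMNS, x))
            row.update(label=cls, source_id=f"{cls.lower()}_subj{i % 10}",
                       chunk_index=i)
            rows.append(row)
    return pd.DataFrame(rows)


def as_table(df: pd.DataFrame, role: str = "train", seed: int = 0) -> FeatureTable:
    return FeatureTable(df.reset_index(drop=True), role=role, seed=seed)


@pytest.fixture()
def separable_tables():
    """Linearly separable train/test tables (centroid distance 6 sd)."""
    train = as_table(gaussian_features(50, 6.0, seed=1), "train")
    test = as_table(gaussian_features(20, 6.0, seed=2), "test")
    return train, test
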