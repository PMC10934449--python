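"""Per-coefficient group inference: unpaired two-sample t-tests.

For each of the 26 cepstral coefficients, the HC and PD feature
distributions are compared with an unpaired t-test (pooled-variance
Student by default; Welch available for unequal variances).  Results
carry the conventional star annotation:

    *    p < 0.05
    **   p < 0.01
    ***  p < 0.001
    **** p < 0.0001

A Holm step-down correction across the 26 tests is available; the panel
reports raw and corrected p side by side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .features import FEATURE_COLUMNS

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class TTestResult:
    coefficient_id: str
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    stars: str
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int


def stars_for_p(p: float) -> str:
    for threshold, mark in STAR_THRESHOLDS:
        if p < threshold:
            return mark
    return "ns"


def unpaired_ttest(a, b, variant: str = "student", coefficient_id: str = "") -> TTestResult:
    """Two-sided unpaired t-test between samples ``a`` and ``b``.

    ``student`` uses the pooled-variance statistic with
    ``df = n_a + n_b - 2``; ``welch`` uses the Welch-Satterthwaite df.
    Two degenerate identical-constant groups give t = 0, p = 1.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("groups must be finite")
    na, nb = a.size, b.size
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if variant == "student":
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se = np.sqrt(sp2 * (1 / na + 1 / nb))
    elif variant == "welch":
        se = np.sqrt(va / na + vb / nb)
        if se > 0:
            df = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
        else:
            df = na + nb - 2
    else:
        raise ValueError("variant must be 'student' or 'welch'")
    if se == 0:
        # zero variance in both groups
        t = 0.0 if ma == mb else np.inf * np.sign(ma - mb)
        p = 1.0 if ma == mb else 0.0
    else:
        t = (ma - mb) / se
        p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(
        coefficient_id=coefficient_id,
        t_statistic=float(t),
        degrees_of_freedom=float(df),
        p_value=float(p),
        stars=stars_for_p(float(p)),
        mean_a=float(ma), mean_b=float(mb),
        sd_a=float(np.sqrt(va)), sd_b=float(np.sqrt(vb)),
        n_a=int(na), n_b=int(nb),
    )


def coefficient_panel(
    hc_table: pd.DataFrame,
    pd_table: pd.DataFrame,
    variant: str = "student",
    correction: str = "none",
) -> pd.DataFrame:
    """One t-test per cepstral coefficient, ordered mfcc_0..12, gtcc_0..12.

    Stars come from the corrected p when a correction is requested,
    otherwise from the raw p; both p columns are always present.
    """
    if correction not in ("none", "holm"):
        raise ValueError("correction must be 'none' or 'holm'")
    results = [
        unpaired_ttest(hc_table[c], pd_table[c], variant=variant, coefficient_id=c)
        for c in FEATURE_COLUMNS
    ]
    raw_p = np.array([r.p_value for r in results])
    if correction == "holm":
        corrected = multipletests(raw_p, method="holm")[1]
    else:
        corrected = raw_p
    rows = []
    for r, pc in zip(results, corrected):
        rows.append({
            "coefficient": r.coefficient_id,
            "n_hc": r.n_a, "n_pd": r.n_b,
            "mean_hc": r.mean_a, "mean_pd": r.mean_b,
            "sd_hc": r.sd_a, "sd_pd": r.sd_b,
            "t": r.t_statistic, "df": r.degrees_of_freedom,
            "p": r.p_value, "p_corrected": float(pc),
            "stars": stars_for_p(float(pc)),
        })
    return pd.DataFrame(rows)


def plot_panel(hc_table: pd.DataFrame, pd_table: pd.DataFrame,
               panel: pd.DataFrame, path) -> None:
    """Cumulative-distribution grid per coefficient with star annotations."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(4, 7, figsize=(22, 12), sharey=True)
    for ax, (_, row) in zip(axes.ravel(), panel.iterrows()):
        c = row["coefficient"]
        for table, name in ((hc_table, "HC"), (pd_table, "PD")):
            x = np.sort(table[c].to_numpy())
            ax.step(x, np.arange(1, x.size + 1) / x.size, label=name)
        ax.set_title(f"{c}  {row['stars']}", fontsize=9)
    for ax in axes.ravel()[len(panel):]:
        ax.axis("off")
    axes[0, 0].legend(fontsize=8)
    fig.suptitle("Cumulative distributions of cepstral coefficients, HC vs PD")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
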