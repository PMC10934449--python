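"""Mel- and gammatone-frequency cepstral coefficients (MFCC / GTCC).

Both front-ends share one pipeline shape: per-frame power spectrum ->
filterbank energies -> log -> orthonormal type-II DCT -> first
``n_coeffs`` coefficients.  The only difference is the filterbank: mel
triangles on the mel scale for MFCCs, fourth-order gammatone magnitude
responses on the ERB-rate scale for GTCCs.  Gammatone filters are
realised as frequency-domain magnitude responses sampled on the FFT grid
(not time-domain IIR filtering) so that the two feature sets share one
code path.

A fixed-length audio sample is summarised as one 26-value feature vector
(13 MFCCs then 13 GTCCs, coefficient-wise mean over frames), the row
format every downstream stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.fft import dct, rfft

from . import audio
from .audio import FrameMatrix, Waveform

MFCC_COLUMNS = [f"mfcc_{i}" for i in range(13)]
GTCC_COLUMNS = [f"gtcc_{i}" for i in range(13)]
FEATURE_COLUMNS = MFCC_COLUMNS + GTCC_COLUMNS
META_COLUMNS = ["label", "source_id", "chunk_index"]


@dataclass(frozen=True)
class CepstralConfig:
    n_coeffs: int = 13
    n_mel_filters: int = 40
    n_gammatone_filters: int = 40
    fmin: float = 50.0
    fmax: float | None = None  # None -> rate/2
    include_c0: bool = True
    log_floor: float = 1e-10
    mel_variant: str = "htk"
    frame_len_s: float = audio.DEFAULT_FRAME_S
    hop_s: float = audio.DEFAULT_HOP_S
    window: str = audio.DEFAULT_WINDOW
    preemphasis: float = audio.DEFAULT_PREEMPHASIS
    aggregation: str = "mean"  # or "median"

    def __post_init__(self) -> None:
        if self.n_coeffs > min(self.n_mel_filters, self.n_gammatone_filters):
            raise ValueError("n_coeffs must not exceed the filter count")
        if self.log_floor <= 0:
            raise ValueError("log_floor must be positive")
        if self.mel_variant not in ("htk", "slaney"):
            raise ValueError("mel_variant must be 'htk' or 'slaney'")
        if self.aggregation not in ("mean", "median"):
            raise ValueError("aggregation must be 'mean' or 'median'")

    def resolved_fmax(self, rate: int) -> float:
        fmax = rate / 2 if self.fmax is None else self.fmax
        if not self.fmin < fmax <= rate / 2:
            raise ValueError("need fmin < fmax <= rate/2")
        return fmax


@dataclass(frozen=True)
class FilterBank:
    weights: np.ndarray  # (n_filters, n_fft_bins)
    center_freqs: np.ndarray
    kind: str  # mel_triangular | gammatone

    def __post_init__(self) -> None:
        if np.any(self.weights < 0):
            raise ValueError("filterbank weights must be non-negative")
        if np.any(np.diff(self.center_freqs) <= 0):
            raise ValueError("center frequencies must be strictly increasing")


@dataclass(frozen=True)
class FeatureVector:
    """26-dimensional cepstral descriptor of one audio sample."""

    mfcc: np.ndarray
    gtcc: np.ndarray
    label: str | None = None
    source_id: str = ""
    chunk_index: int = 0

    def concat(self) -> np.ndarray:
        return np.concatenate([self.mfcc, self.gtcc])


@dataclass(frozen=True)
class NormalizationStats:
    mean: np.ndarray
    sd: np.ndarray
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        if np.any(self.sd <= 0):
            raise ValueError("all column standard deviations must be positive")


# ---------------------------------------------------------------------------
# frequency scales

def mel_scale(f, variant: str = "htk"):
    """Hz -> mel.  HTK variant: 2595 * log10(1 + f/700)."""
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    if variant == "htk":
        return 2595.0 * np.log10(1.0 + f / 700.0)
    if variant == "slaney":
        # linear below 1 kHz, logarithmic above
        lin = f / (200.0 / 3.0)
        brk = 1000.0 / (200.0 / 3.0)
        step = np.log(6.4) / 27.0
        return np.where(f < 1000.0, lin, brk + np.log(f / 1000.0) / step)
    raise ValueError(f"unknown mel variant {variant!r}")


def mel_inverse(m, variant: str = "htk"):
    """mel -> Hz, exact inverse of :func:`mel_scale`."""
    m = np.asarray(m, dtype=np.float64)
    if variant == "htk":
        return 700.0 * (10.0 ** (m / 2595.0) - 1.0)
    if variant == "slaney":
        brk = 1000.0 / (200.0 / 3.0)
        step = np.log(6.4) / 27.0
        return np.where(m < brk, m * (200.0 / 3.0), 1000.0 * np.exp(step * (m - brk)))
    raise ValueError(f"unknown mel variant {variant!r}")


def erb_bandwidth(f):
    """Equivalent rectangular bandwidth at frequency f: 24.7*(4.37 f/1000 + 1)."""
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    return 24.7 * (4.37 * f / 1000.0 + 1.0)


def erb_rate(f):
    """Hz -> ERB-rate (number of ERBs below f): 21.4 * log10(1 + 0.00437 f)."""
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    return 21.4 * np.log10(1.0 + 0.00437 * f)


def erb_rate_inverse(e):
    e = np.asarray(e, dtype=np.float64)
    return (10.0 ** (e / 21.4) - 1.0) / 0.00437


# ---------------------------------------------------------------------------
# filterbanks

def fft_bin_freqs(n_fft: int, rate: int) -> np.ndarray:
    return np.arange(n_fft // 2 + 1) * (rate / n_fft)


def build_mel_filterbank(cfg: CepstralConfig, n_fft: int, rate: int) -> FilterBank:
    """Triangular filters with apexes equally spaced on the mel scale."""
    fmax = cfg.resolved_fmax(rate)
    n_bins = n_fft // 2 + 1
    if n_bins < cfg.n_mel_filters + 2:
        raise ValueError("fewer FFT bins than mel filters")
    mels = np.linspace(mel_scale(cfg.fmin, cfg.mel_variant),
                       mel_scale(fmax, cfg.mel_variant),
                       cfg.n_mel_filters + 2)
    edges = mel_inverse(mels, cfg.mel_variant)
    freqs = fft_bin_freqs(n_fft, rate)
    weights = np.zeros((cfg.n_mel_filters, n_bins))
    for k in range(cfg.n_mel_filters):
        lo, ctr, hi = edges[k], edges[k + 1], edges[k + 2]
        rising = (freqs - lo) / (ctr - lo)
        falling = (hi - freqs) / (hi - ctr)
        weights[k] = np.clip(np.minimum(rising, falling), 0.0, None)
    return FilterBank(weights, edges[1:-1].copy(), "mel_triangular")


def build_gammatone_filterbank(cfg: CepstralConfig, n_fft: int, rate: int) -> FilterBank:
    """Fourth-order gammatone magnitude responses on the ERB-rate scale.

    Centers are equally spaced in ERB-rate between fmin and fmax.  Each
    filter's squared magnitude is ``(1 + ((f - fc)/b)^2)^-4`` with
    ``b = 1.019 * ERB(fc)``, giving the classical 3-dB bandwidth of
    ``0.887 * ERB(fc)`` for a fourth-order gammatone.
    """
    fmax = cfg.resolved_fmax(rate)
    n_bins = n_fft // 2 + 1
    if n_bins < cfg.n_gammatone_filters:
        raise ValueError("fewer FFT bins than gammatone filters")
    centers = erb_rate_inverse(
        np.linspace(erb_rate(cfg.fmin), erb_rate(fmax), cfg.n_gammatone_filters)
    )
    freqs = fft_bin_freqs(n_fft, rate)
    b = 1.019 * erb_bandwidth(centers)
    x = (freqs[None, :] - centers[:, None]) / b[:, None]
    weights = (1.0 + x**2) ** -4  # squared-magnitude response, order 4
    return FilterBank(weights, centers, "gammatone")


# ---------------------------------------------------------------------------
# cepstra

def _next_pow2(n: int) -> int:
    return 1 << (n - 1).bit_length()


def _cepstra(frames: FrameMatrix, bank: FilterBank, cfg: CepstralConfig) -> np.ndarray:
    n_fft = 2 * (bank.weights.shape[1] - 1)
    spectrum = rfft(frames.frames, n=n_fft, axis=1)
    power = np.abs(spectrum) ** 2
    energies = power @ bank.weights.T
    logE = np.log(np.maximum(energies, cfg.log_floor))
    cep = dct(logE, type=2, norm="ortho", axis=1)
    start = 0 if cfg.include_c0 else 1
    return cep[:, start:start + cfg.n_coeffs]


def mfcc(frames: FrameMatrix, cfg: CepstralConfig = CepstralConfig()) -> np.ndarray:
    """Per-frame MFCCs, shape (n_frames, n_coeffs)."""
    n_fft = _next_pow2(frames.frame_len)
    bank = build_mel_filterbank(cfg, n_fft, frames.rate)
    return _cepstra(frames, bank, cfg)


def gtcc(frames: FrameMatrix, cfg: CepstralConfig = CepstralConfig()) -> np.ndarray:
    """Per-frame GTCCs, shape (n_frames, n_coeffs)."""
    n_fft = _next_pow2(frames.frame_len)
    bank = build_gammatone_filterbank(cfg, n_fft, frames.rate)
    return _cepstra(frames, bank, cfg)


def featurize_sample(
    sample: Waveform,
    cfg: CepstralConfig = CepstralConfig(),
    label: str | None = None,
    chunk_index: int = 0,
) -> FeatureVector:
    """Pre-emphasis -> framing -> per-frame MFCC+GTCC -> mean over frames."""
    emph = audio.pre_emphasis(sample, cfg.preemphasis)
    frames = audio.frame_signal(emph, cfg.frame_len_s, cfg.hop_s, cfg.window)
    agg = np.mean if cfg.aggregation == "mean" else np.median
    m = agg(mfcc(frames, cfg), axis=0)
    g = agg(gtcc(frames, cfg), axis=0)
    return FeatureVector(m, g, label=label, source_id=sample.source_id,
                         chunk_index=chunk_index)


def features_to_frame(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into the canonical 26-column table."""
    rows = []
    for v in vectors:
        row = dict(zip(MFCC_COLUMNS, v.mfcc))
        row.update(zip(GTCC_COLUMNS, v.gtcc))
        row["label"] = v.label
        row["source_id"] = v.source_id
        row["chunk_index"] = v.chunk_index
        rows.append(row)
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS + META_COLUMNS)


def write_feature_csv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def read_feature_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# z-score normalisation

def zscore_fit(df: pd.DataFrame, columns: list[str] | None = None) -> NormalizationStats:
    """Column means and sample standard deviations of the fit set."""
    columns = list(columns or FEATURE_COLUMNS)
    sub = df[columns]
    if len(sub) < 2:
        raise ValueError("need at least two rows to fit normalisation")
    mean = sub.mean(axis=0).to_numpy()
    sd = sub.std(axis=0, ddof=1).to_numpy()
    bad = [c for c, s in zip(columns, sd) if not s > 0]
    if bad:
        raise ValueError(f"zero-variance columns: {bad}")
    return NormalizationStats(mean, sd, tuple(columns))


def zscore_apply(df: pd.DataFrame, stats: NormalizationStats) -> pd.DataFrame:
    """Return a copy with the stats' columns transformed to z-scores."""
    out = df.copy()
    cols = list(stats.columns)
    out[cols] = (df[cols].to_numpy() - stats.mean) / stats.sd
    return out
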