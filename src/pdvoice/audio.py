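"""WAV input/output and shared signal conditioning.

Every stage of the pipeline consumes and produces :class:`Waveform` objects:
mono float signals in [-1, 1] with an explicit sample rate and a free-text
provenance tag.  The module also provides the conditioning steps shared by
both cepstral front-ends (pre-emphasis, framing/windowing) and the
non-overlapping partitioning used to cut long recordings into fixed-length
audio samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly, get_window

log = logging.getLogger(__name__)

#: default pre-emphasis coefficient (common practice for speech analysis)
DEFAULT_PREEMPHASIS = 0.97
#: default short-time analysis frame length / hop, seconds
DEFAULT_FRAME_S = 0.025
DEFAULT_HOP_S = 0.010
DEFAULT_WINDOW = "hamming"
#: default fixed sample length for non-overlapping partitioning, seconds
DEFAULT_SAMPLE_LEN_S = 1.0

_WINDOWS = ("hamming", "hann", "rectangular")


@dataclass(frozen=True)
class Waveform:
    """A mono audio signal with sample rate and provenance."""

    samples: np.ndarray
    rate: int
    source_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.rate <= 0:
            raise ValueError(f"sample rate must be positive, got {self.rate}")
        if samples.ndim != 1:
            raise ValueError(f"waveform must be mono (1-D), got shape {samples.shape}")
        if not np.all(np.isfinite(samples)):
            raise ValueError("waveform contains non-finite samples")
        if samples.size and np.max(np.abs(samples)) > 1.0 + 1e-6:
            raise ValueError("waveform exceeds full scale [-1, 1]")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    def __len__(self) -> int:
        return self.samples.size

    @classmethod
    def _unchecked(cls, samples: np.ndarray, rate: int, source_id: str = "") -> "Waveform":
        # pre-emphasis output may exceed [-1, 1]; skip the full-scale check
        obj = object.__new__(cls)
        object.__setattr__(obj, "samples", np.asarray(samples, dtype=np.float64))
        object.__setattr__(obj, "rate", rate)
        object.__setattr__(obj, "source_id", source_id)
        return obj


@dataclass(frozen=True)
class FrameMatrix:
    """Short-time frames of a waveform, one row per (windowed) frame."""

    frames: np.ndarray  # (n_frames, frame_len)
    frame_len: int
    hop: int
    window: str
    rate: int

    def __post_init__(self) -> None:
        if self.hop < 1:
            raise ValueError("hop must be >= 1 sample")
        if self.window not in _WINDOWS:
            raise ValueError(f"unknown window {self.window!r}; choose from {_WINDOWS}")
        if self.frames.ndim != 2 or self.frames.shape[1] != self.frame_len:
            raise ValueError("frames must be (n_frames, frame_len)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def read_wav(path: str | Path) -> Waveform:
    """Read a PCM WAV file, scaling integer samples to [-1, 1].

    Integer PCM is divided by the full-scale constant of its bit depth
    (e.g. 32768 for 16-bit, so the most negative code maps to -1.0).
    Multi-channel input is averaged down to mono with a logged notice.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rate, data = wavfile.read(str(path))
    if data.dtype == np.int16:
        x = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        x = data.astype(np.float64) / 2147483648.0
    elif data.dtype == np.uint8:
        x = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        x = data.astype(np.float64)
    else:
        raise ValueError(f"unsupported WAV encoding {data.dtype} in {path}")
    if x.ndim == 2:
        log.info("averaging %d channels of %s to mono", x.shape[1], path.name)
        x = x.mean(axis=1)
    return Waveform(x, int(rate), source_id=path.stem)


def write_wav(path: str | Path, w: Waveform) -> None:
    """Write a waveform as 16-bit PCM WAV (round-trips bit-exactly)."""
    x = np.clip(w.samples, -1.0, 1.0)
    ints = np.clip(np.round(x * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(str(path), w.rate, ints)


def pre_emphasis(w: Waveform, alpha: float = DEFAULT_PREEMPHASIS) -> Waveform:
    """First-order high-pass: y[n] = x[n] - alpha * x[n-1], y[0] = x[0]."""
    if not 0.0 <= alpha < 1.0:
        raise ValueError(f"pre-emphasis coefficient must be in [0, 1), got {alpha}")
    x = w.samples
    y = np.empty_like(x)
    if x.size:
        y[0] = x[0]
        y[1:] = x[1:] - alpha * x[:-1]
    return Waveform._unchecked(y, w.rate, w.source_id)


def frame_count(n: int, frame_len: int, hop: int) -> int:
    """Number of full frames from a length-n signal: 1 + floor((n-L)/hop)."""
    if n < frame_len:
        return 0
    return 1 + (n - frame_len) // hop


def frame_signal(
    w: Waveform,
    frame_len_s: float = DEFAULT_FRAME_S,
    hop_s: float = DEFAULT_HOP_S,
    window: str = DEFAULT_WINDOW,
) -> FrameMatrix:
    """Slice a waveform into overlapping windowed frames.

    The trailing remainder shorter than one frame is discarded.
    """
    frame_len = int(round(frame_len_s * w.rate))
    hop = int(round(hop_s * w.rate))
    if hop < 1:
        raise ValueError("hop must be at least one sample")
    n = w.samples.size
    if n < frame_len:
        raise ValueError(
            f"signal ({n} samples) shorter than one frame ({frame_len} samples)"
        )
    count = frame_count(n, frame_len, hop)
    idx = np.arange(frame_len)[None, :] + hop * np.arange(count)[:, None]
    frames = w.samples[idx]
    if window == "rectangular":
        win = np.ones(frame_len)
    else:
        win = get_window(window, frame_len, fftbins=True)
    return FrameMatrix(frames * win, frame_len, hop, window, w.rate)


def partition_samples(w: Waveform, sample_len_s: float = DEFAULT_SAMPLE_LEN_S) -> list[Waveform]:
    """Cut a recording into consecutive non-overlapping fixed-length samples.

    The final remainder shorter than ``sample_len_s`` is discarded; each
    chunk's provenance records the source id and its chunk index.  A
    recording shorter than one sample length yields an empty list with a
    logged warning.
    """
    if sample_len_s <= 0:
        raise ValueError("sample length must be positive")
    step = int(round(sample_len_s * w.rate))
    n_chunks = w.samples.size // step
    if n_chunks == 0:
        log.warning(
            "recording %s (%.3f s) shorter than one sample (%.3f s); no samples",
            w.source_id, w.duration, sample_len_s,
        )
        return []
    return [
        Waveform(w.samples[i * step:(i + 1) * step], w.rate,
                 source_id=f"{w.source_id}#chunk{i}")
        for i in range(n_chunks)
    ]


def resample(w: Waveform, rate: int) -> Waveform:
    """Polyphase rational resampling to a new rate (logged when it fires)."""
    if rate == w.rate:
        return w
    frac = Fraction(rate, w.rate).limit_denominator(1000)
    log.info("resampling %s: %d Hz -> %d Hz (x%s)", w.source_id, w.rate, rate, frac)
    y = resample_poly(w.samples, frac.numerator, frac.denominator)
    peak = np.max(np.abs(y)) if y.size else 0.0
    if peak > 1.0:
        y = y / peak
    return Waveform(y, rate, source_id=w.source_id)
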