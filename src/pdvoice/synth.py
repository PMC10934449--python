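"""Synthetic dysarthric voice generator.

Produces single-speaker sustained-speech-like recordings and two-speaker
turn-taking conversations with known ground truth, so every downstream
stage (features, diarization, classification, inference) is testable
without any external recordings.

The voice model is a deliberately simple source-filter scheme whose
perturbation parameters are exactly controllable and re-measurable:

* glottal source: an impulse train whose per-cycle period and amplitude
  are perturbed according to the requested jitter and shimmer, plus white
  aspiration noise mixed at the requested harmonics-to-noise ratio (HNR);
* vocal tract: a cascade of second-order resonators at the configured
  formant frequencies/bandwidths.

Hypokinetic dysarthria (the Parkinsonian speech disorder) is emulated by
its classical acoustic correlates: reduced utterance-level pitch
variability (monopitch), elevated cycle-to-cycle jitter and shimmer, and
reduced HNR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .audio import Waveform

#: seconds of voicing driven by one pitch-target draw; utterance-level pitch
#: variability (f0_sd) acts at this time scale, jitter acts per cycle
F0_SEGMENT_S = 0.5

#: default formants: neutral-ish vowel, (center Hz, bandwidth Hz)
DEFAULT_FORMANTS = ((500.0, 80.0), (1500.0, 120.0), (2500.0, 160.0))

#: class-level generative defaults. These are package constants chosen from
#: typical dysarthria-literature ranges; they are configuration, not
#: measurements of any particular cohort.
HC_DEFAULTS = dict(f0_mean=120.0, f0_sd=15.0, jitter_pct=0.5,
                   shimmer_pct=3.0, hnr_db=20.0)
PD_DEFAULTS = dict(f0_mean=120.0, f0_sd=4.0, jitter_pct=2.0,
                   shimmer_pct=8.0, hnr_db=10.0)

#: silence between conversation turns, seconds
DEFAULT_TURN_GAP_S = 0.25


@dataclass(frozen=True)
class SyntheticVoiceSpec:
    """Generative parameters defining one synthetic speaker/class.

    Parameters
    ----------
    f0_mean, f0_sd
        Mean fundamental frequency and its utterance-level standard
        deviation (Hz).  Low ``f0_sd`` emulates monopitch.
    jitter_pct
        Cycle-to-cycle period perturbation, percent of the local period.
    shimmer_pct
        Cycle-to-cycle amplitude perturbation, percent.
    hnr_db
        Harmonics-to-noise ratio of the glottal source in dB;
        ``None`` disables aspiration noise entirely.
    formants
        ``(center Hz, bandwidth Hz)`` pairs for the vocal-tract resonators,
        at least two, centers strictly increasing.
    label
        Class label, ``"HC"`` or ``"PD"``.
    """

    f0_mean: float
    f0_sd: float
    jitter_pct: float
    shimmer_pct: float
    hnr_db: float | None
    formants: tuple[tuple[float, float], ...] = DEFAULT_FORMANTS
    label: str = "HC"

    def __post_init__(self) -> None:
        if self.f0_mean <= 0:
            raise ValueError("f0_mean must be positive")
        if self.f0_sd < 0:
            raise ValueError("f0_sd must be non-negative")
        if not 0 <= self.jitter_pct < 50:
            raise ValueError("jitter_pct must be in [0, 50)")
        if not 0 <= self.shimmer_pct < 100:
            raise ValueError("shimmer_pct must be in [0, 100)")
        if len(self.formants) < 2:
            raise ValueError("at least two formants required")
        centers = [f for f, _ in self.formants]
        if any(b <= a for a, b in zip(centers, centers[1:])) or len(set(centers)) != len(centers):
            raise ValueError("formant centers must be strictly increasing")
        if any(bw <= 0 for _, bw in self.formants):
            raise ValueError("formant bandwidths must be positive")
        if self.label not in ("HC", "PD"):
            raise ValueError(f"label must be HC or PD, got {self.label!r}")


@dataclass(frozen=True)
class ConversationScript:
    """Ordered speaker turns for a two-party conversation."""

    turns: tuple[tuple[int, float], ...]  # (speaker_index 0|1, duration s)
    gap: float = DEFAULT_TURN_GAP_S

    def __post_init__(self) -> None:
        if not self.turns:
            raise ValueError("script needs at least one turn")
        speakers = {s for s, _ in self.turns}
        if not speakers <= {0, 1}:
            raise ValueError("speaker indices must be 0 or 1")
        if speakers != {0, 1}:
            raise ValueError("each speaker needs at least one turn")
        if any(d <= 0 for _, d in self.turns):
            raise ValueError("turn durations must be positive")
        if self.gap < 0:
            raise ValueError("gap must be non-negative")


@dataclass(frozen=True)
class GroundTruthTimeline:
    """Non-overlapping (start, end, speaker) segments, sorted by start."""

    segments: tuple[tuple[float, float, int], ...]

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for start, end, _ in self.segments:
            if end <= start:
                raise ValueError("segment end must exceed start")
            if start < prev_end - 1e-12:
                raise ValueError("segments must be sorted and non-overlapping")
            prev_end = end

    def total_speech(self) -> float:
        return sum(end - start for start, end, _ in self.segments)


def glottal_pulse_train(
    spec: SyntheticVoiceSpec, duration: float, rate: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Jittered/shimmered impulse train; returns (signal, pulse sample indices).

    One pitch target per ~0.5 s voicing segment is drawn from
    Normal(f0_mean, f0_sd); each cycle's period is then perturbed by
    Normal(0, jitter_pct/100 * period) and its amplitude by
    Normal(0, shimmer_pct/100).  Pulse positions are rounded to samples.
    """
    n = int(round(duration * rate))
    seg_len = int(round(F0_SEGMENT_S * rate))
    out = np.zeros(n)
    positions: list[int] = []
    pos = 0
    # pitch target for the segment containing `pos`
    f0_seg = None
    seg_idx = -1
    min_period = int(round(rate / spec.f0_mean))
    if n < min_period:
        raise ValueError("duration shorter than one pitch period")
    while pos < n:
        cur_seg = pos // seg_len
        if cur_seg != seg_idx:
            seg_idx = cur_seg
            f0_seg = spec.f0_mean + spec.f0_sd * rng.standard_normal()
            f0_seg = max(f0_seg, spec.f0_mean * 0.3)  # keep voiced
        period = rate / f0_seg
        period *= 1.0 + (spec.jitter_pct / 100.0) * rng.standard_normal()
        period_n = max(2, int(round(period)))
        amp = 1.0 + (spec.shimmer_pct / 100.0) * rng.standard_normal()
        out[pos] = amp
        positions.append(pos)
        pos += period_n
    return out, np.asarray(positions, dtype=np.intp)


def _formant_filter(x: np.ndarray, formants, rate: int) -> np.ndarray:
    """Cascade of unit-peak-gain second-order resonators."""
    y = x
    for fc, bw in formants:
        r = np.exp(-np.pi * bw / rate)
        theta = 2 * np.pi * fc / rate
        a = [1.0, -2.0 * r * np.cos(theta), r * r]
        b = [1.0 - r]  # rough gain normalisation; peak normalisation follows
        y = lfilter(b, a, y)
    return y


def synth_voice(
    spec: SyntheticVoiceSpec, duration: float, rate: int, seed: int
) -> Waveform:
    """Synthesise one sustained-phonation-like recording.

    Deterministic given ``seed``; peak-normalised to 0.9.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if rate < 8000:
        raise ValueError("rate must be at least 8000 Hz")
    rng = np.random.default_rng(seed)
    source, _ = glottal_pulse_train(spec, duration, rate, rng)
    if spec.hnr_db is not None:
        noise = rng.standard_normal(source.size)
        p_harm = np.mean(source**2)
        p_noise = np.mean(noise**2)
        target = p_harm / (10.0 ** (spec.hnr_db / 10.0))
        noise *= np.sqrt(target / p_noise)
        source = source + noise
    y = _formant_filter(source, spec.formants, rate)
    peak = np.max(np.abs(y))
    if peak > 0:
        y = 0.9 * y / peak
    return Waveform(y, rate, source_id=f"synth_{spec.label}_seed{seed}")


def hc_spec(**overrides) -> SyntheticVoiceSpec:
    """Default healthy-control voice spec (override any field)."""
    kw = dict(HC_DEFAULTS, label="HC")
    kw.update(overrides)
    return SyntheticVoiceSpec(**kw)


def pd_spec(**overrides) -> SyntheticVoiceSpec:
    """Default Parkinsonian (hypokinetic-dysarthric) voice spec."""
    kw = dict(PD_DEFAULTS, label="PD")
    kw.update(overrides)
    return SyntheticVoiceSpec(**kw)


def _draw_spec(cls_defaults: dict, label: str, rng: np.random.Generator) -> SyntheticVoiceSpec:
    """Per-speaker spec: mild between-speaker scatter around class defaults."""
    f0 = cls_defaults["f0_mean"] * (1.0 + 0.1 * rng.standard_normal())
    jitter = max(0.05, cls_defaults["jitter_pct"] * (1.0 + 0.15 * rng.standard_normal()))
    shimmer = max(0.2, cls_defaults["shimmer_pct"] * (1.0 + 0.15 * rng.standard_normal()))
    hnr = cls_defaults["hnr_db"] + 1.5 * rng.standard_normal()
    # between-speaker formant scatter (vocal-tract length differences)
    scale = 1.0 + 0.06 * rng.standard_normal()
    formants = tuple((fc * scale, bw) for fc, bw in DEFAULT_FORMANTS)
    return SyntheticVoiceSpec(
        f0_mean=max(60.0, f0), f0_sd=cls_defaults["f0_sd"],
        jitter_pct=jitter, shimmer_pct=shimmer, hnr_db=hnr,
        formants=formants, label=label,
    )


def synth_cohort(
    n_hc: int, n_pd: int, duration: float, rate: int, seed: int
) -> list[tuple[Waveform, str, SyntheticVoiceSpec]]:
    """Generate a labelled cohort of single-speaker recordings.

    Per-recording specs are drawn from the two documented class
    distributions (:data:`HC_DEFAULTS`, :data:`PD_DEFAULTS`); each item
    carries its spec so generation parameters can be re-estimated later.
    Deterministic given ``seed``.
    """
    if n_hc < 1 or n_pd < 1:
        raise ValueError("cohort needs at least one recording per class")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_hc + n_pd):
        label = "HC" if i < n_hc else "PD"
        defaults = HC_DEFAULTS if label == "HC" else PD_DEFAULTS
        spec = _draw_spec(defaults, label, rng)
        voice_seed = int(rng.integers(0, 2**31 - 1))
        w = synth_voice(spec, duration, rate, voice_seed)
        w = Waveform(w.samples, w.rate, source_id=f"{label.lower()}{i:03d}")
        out.append((w, label, spec))
    return out


def synth_conversation(
    spec_a: SyntheticVoiceSpec,
    spec_b: SyntheticVoiceSpec,
    script: ConversationScript,
    rate: int,
    seed: int,
) -> tuple[Waveform, GroundTruthTimeline]:
    """Render a two-speaker conversation with an exact speaker timeline.

    Turns are concatenated in script order separated by silent gaps; no
    background noise is added, matching a direct-line recording.
    """
    rng = np.random.default_rng(seed)
    specs = (spec_a, spec_b)
    pieces: list[np.ndarray] = []
    segments: list[tuple[float, float, int]] = []
    t = 0.0
    gap_n = int(round(script.gap * rate))
    for k, (speaker, dur) in enumerate(script.turns):
        turn_seed = int(rng.integers(0, 2**31 - 1))
        w = synth_voice(specs[speaker], dur, rate, turn_seed)
        pieces.append(w.samples)
        segments.append((t, t + w.duration, speaker))
        t += w.duration
        if k < len(script.turns) - 1 and gap_n:
            pieces.append(np.zeros(gap_n))
            t += gap_n / rate
    samples = np.concatenate(pieces)
    w = Waveform(samples, rate, source_id=f"conv_seed{seed}")
    return w, GroundTruthTimeline(tuple(segments))


def write_timeline_rttm(path, timeline: GroundTruthTimeline, file_id: str = "conv") -> None:
    """Write a ground-truth timeline in RTTM (SPEAKER lines)."""
    with open(path, "w") as fh:
        for start, end, speaker in timeline.segments:
            fh.write(
                f"SPEAKER {file_id} 1 {start:.3f} {end - start:.3f} "
                f"<NA> <NA> spk{speaker} <NA> <NA>\n"
            )
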