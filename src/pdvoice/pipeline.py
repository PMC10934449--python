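"""End-to-end experiment orchestration.

Two experiment shapes, mirroring a reading task and a phone-conversation
task:

* reading: partition each single-speaker recording into fixed-length
  samples -> cepstral features -> balanced train/test tables -> nested-CV
  model suite;
* conversation: diarize each two-speaker call -> extract the subject's
  audio (by default the cluster with the greater total speaking time) ->
  one feature row per merged subject segment -> tables -> suite ->
  per-coefficient t-test panel.

Both pipelines share every stage implementation and write a
machine-readable provenance file (config, seeds, per-stage counts)
sufficient to reproduce a run exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib.metadata import version as pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

from . import audio, classify, diarize, features, stats, synth
from .audio import Waveform
from .classify import CVConfig, run_model_suite, suite_to_frame
from .datasets import SplitSpec, audit_table, build_tables
from .diarize import DiarizationConfig
from .features import CepstralConfig, features_to_frame, featurize_sample
from .synth import ConversationScript


@dataclass
class PipelineConfig:
    task: str  # reading | conversation | synth-demo
    out_dir: Path
    sample_len_s: float = audio.DEFAULT_SAMPLE_LEN_S
    cepstral: CepstralConfig = field(default_factory=CepstralConfig)
    diarization: DiarizationConfig = field(default_factory=DiarizationConfig)
    split: SplitSpec | None = None
    cv: CVConfig = field(default_factory=CVConfig)


def _provenance(cfg: PipelineConfig, counts: dict) -> dict:
    try:
        ver = pkg_version("pdvoice")
    except Exception:
        ver = "unknown"
    return {
        "package_version": ver,
        "task": cfg.task,
        "sample_len_s": cfg.sample_len_s,
        "cepstral": asdict(cfg.cepstral),
        "diarization": {k: v for k, v in asdict(cfg.diarization).items()
                        if k != "cepstral"},
        "split": asdict(cfg.split) if cfg.split else None,
        "cv": asdict(cfg.cv),
        "stage_counts": counts,
    }


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def _write_config_yaml(path: Path, cfg: PipelineConfig) -> None:
    import yaml

    doc = {
        "task": cfg.task,
        "sample_len_s": cfg.sample_len_s,
        "cepstral": asdict(cfg.cepstral),
        "diarization": {k: v for k, v in asdict(cfg.diarization).items()
                        if k != "cepstral"},
        "split": asdict(cfg.split) if cfg.split else None,
        "cv": asdict(cfg.cv),
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=True))


def _write_tables(out: Path, train, test) -> None:
    features.write_feature_csv(out / "train_table.csv", train.df)
    features.write_feature_csv(out / "test_table.csv", test.df)


def featurize_recordings(
    recordings: list[tuple[Waveform, str]],
    cfg: CepstralConfig,
    sample_len_s: float,
) -> pd.DataFrame:
    """Partition recordings into fixed-length samples and featurize each."""
    vectors = []
    for w, label in recordings:
        for i, chunk in enumerate(audio.partition_samples(w, sample_len_s)):
            vectors.append(featurize_sample(chunk, cfg, label=label, chunk_index=i))
    return features_to_frame(vectors)


def run_reading(
    recordings: list[tuple[Waveform, str]],
    cfg: PipelineConfig,
) -> tuple[pd.DataFrame, list[classify.CVReport]]:
    """Reading-task experiment: partition -> features -> tables -> suite."""
    if not recordings:
        raise ValueError("empty recording manifest")
    bad = [lab for _, lab in recordings if lab not in ("HC", "PD")]
    if bad:
        raise ValueError(f"labels must be HC or PD, got {bad}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    feats = featurize_recordings(recordings, cfg.cepstral, cfg.sample_len_s)
    features.write_feature_csv(out / "features.csv", feats)
    _write_config_yaml(out / "config.yaml", cfg)
    train, test = build_tables(feats, cfg.split)
    _write_tables(out, train, test)
    suite = run_model_suite(train, test, cfg.cv)
    summary = suite_to_frame(suite)
    summary.to_csv(out / "suite.csv", index=False, float_format="%.6g")
    _write_json(out / "reports.json", [r.to_dict() for r in suite])
    counts = {
        "recordings": len(recordings),
        "feature_rows": len(feats),
        "train_rows": len(train),
        "test_rows": len(test),
    }
    prov = _provenance(cfg, counts)
    prov["audit"] = {"train": audit_table(train, test), "test": audit_table(test, train)}
    _write_json(out / "provenance.json", prov)
    return summary, suite


def subject_segments(
    conv: Waveform, cfg: DiarizationConfig, subject_cluster: int | None = None,
) -> tuple[diarize.Diarization, int, list[Waveform]]:
    """Diarize a call and return the subject's merged segments as samples.

    The subject is, by default, the non-noise cluster with the greater
    total speaking time (the patient speaks most on their own call);
    pass ``subject_cluster`` to override.
    """
    d = diarize.diarize(conv, cfg)
    candidates = [c for c in d.cluster_ids() if c != d.noise_cluster]
    if len(candidates) < 2 and subject_cluster is None and cfg.n_speakers > 1:
        raise RuntimeError("diarization produced a singleton cluster")
    if subject_cluster is None:
        subject_cluster = max(candidates, key=d.speaking_time)
    segs = []
    for idx, (s, e, c) in enumerate(d.segments):
        if c != subject_cluster:
            continue
        piece = conv.samples[int(round(s * conv.rate)):int(round(e * conv.rate))]
        segs.append(Waveform(piece, conv.rate,
                             source_id=f"{conv.source_id}#seg{idx}"))
    return d, subject_cluster, segs


def run_conversation(
    conversations: list[tuple[Waveform, str]],
    cfg: PipelineConfig,
) -> tuple[pd.DataFrame, list[classify.CVReport], pd.DataFrame]:
    """Conversation-task experiment: diarize -> subject features -> suite -> panel."""
    if not conversations:
        raise ValueError("empty conversation manifest")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vectors = []
    n_ok = 0
    for conv, label in conversations:
        try:
            d, subject, segs = subject_segments(conv, cfg.diarization)
        except RuntimeError as exc:
            import logging
            logging.getLogger(__name__).warning("skipping %s: %s", conv.source_id, exc)
            continue
        n_ok += 1
        diarize.write_rttm(out / f"{conv.source_id}.rttm", d, conv.source_id)
        for i, seg in enumerate(segs):
            min_len = cfg.cepstral.frame_len_s
            if seg.duration < min_len:
                continue
            vectors.append(featurize_sample(seg, cfg.cepstral, label=label, chunk_index=i))
    feats = features_to_frame(vectors)
    features.write_feature_csv(out / "features.csv", feats)
    _write_config_yaml(out / "config.yaml", cfg)
    train, test = build_tables(feats, cfg.split)
    _write_tables(out, train, test)
    suite = run_model_suite(train, test, cfg.cv)
    summary = suite_to_frame(suite)
    summary.to_csv(out / "suite.csv", index=False, float_format="%.6g")
    _write_json(out / "reports.json", [r.to_dict() for r in suite])
    panel = stats.coefficient_panel(
        feats[feats["label"] == "HC"], feats[feats["label"] == "PD"]
    )
    panel.to_csv(out / "ttest_panel.csv", index=False, float_format="%.6g")
    counts = {
        "conversations": len(conversations),
        "diarized": n_ok,
        "feature_rows": len(feats),
        "train_rows": len(train),
        "test_rows": len(test),
    }
    prov = _provenance(cfg, counts)
    prov["audit"] = {"train": audit_table(train, test), "test": audit_table(test, train)}
    _write_json(out / "provenance.json", prov)
    return summary, suite, panel


# ---------------------------------------------------------------------------
# synthetic demo

def default_conversation_script(n_turns: int = 6, turn_s: float = 2.5,
                                gap_s: float = synth.DEFAULT_TURN_GAP_S) -> ConversationScript:
    turns = tuple((k % 2, turn_s) for k in range(n_turns))
    return ConversationScript(turns, gap=gap_s)


def synth_demo_reading(
    out_dir: Path,
    n_hc: int = 21,
    n_pd: int = 16,
    duration: float = 12.0,
    rate: int = 16000,
    seed: int = 0,
    n_train: int = 400,
    n_test: int = 40,
) -> tuple[pd.DataFrame, list[classify.CVReport]]:
    """Reading-task experiment on a generated cohort (no external data)."""
    cohort = synth.synth_cohort(n_hc, n_pd, duration, rate, seed)
    recordings = [(w, label) for w, label, _ in cohort]
    cfg = PipelineConfig(
        task="synth-demo",
        out_dir=Path(out_dir),
        split=SplitSpec(n_train=n_train, n_test=n_test, seed=seed + 1),
        cv=CVConfig(seed=seed + 2),
    )
    return run_reading(recordings, cfg)


def synth_demo_conversation(
    out_dir: Path,
    n_hc: int = 10,
    n_pd: int = 10,
    rate: int = 16000,
    seed: int = 0,
    n_train: int = 60,
    n_test: int = 20,
    n_turns: int = 12,
    turn_s: float = 2.5,
) -> tuple[pd.DataFrame, list[classify.CVReport], pd.DataFrame]:
    """Conversation-task experiment on generated calls.

    Each call pairs a subject (HC or PD voice) with a healthy
    interviewer; the subject takes the longer share of turns so the
    speaking-time rule identifies them.
    """
    rng = np.random.default_rng(seed)
    conversations = []
    # subject is speaker 0 with longer turns; interviewer (speaker 1) turns
    # stay > 2 windows long so smoothing cannot erase them
    script = ConversationScript(
        tuple((0, turn_s) if k % 2 == 0 else (1, 0.8 * turn_s)
              for k in range(n_turns)),
        gap=synth.DEFAULT_TURN_GAP_S,
    )
    for i in range(n_hc + n_pd):
        label = "HC" if i < n_hc else "PD"
        defaults = synth.HC_DEFAULTS if label == "HC" else synth.PD_DEFAULTS
        subject = synth._draw_spec(defaults, label, rng)
        # the interviewer keeps a fixed, clearly distinct register (higher
        # pitch and a shorter vocal tract) so the two voices are separable
        # the way two people on a phone line are
        interviewer = synth.hc_spec(
            f0_mean=synth.HC_DEFAULTS["f0_mean"] * 1.8,
            formants=tuple((fc * 1.25, bw) for fc, bw in synth.DEFAULT_FORMANTS),
        )
        conv_seed = int(rng.integers(0, 2**31 - 1))
        w, _ = synth.synth_conversation(subject, interviewer, script, rate, conv_seed)
        w = Waveform(w.samples, rate, source_id=f"call_{label.lower()}{i:03d}")
        conversations.append((w, label))
    cfg = PipelineConfig(
        task="synth-demo",
        out_dir=Path(out_dir),
        split=SplitSpec(n_train=n_train, n_test=n_test, seed=seed + 1),
        cv=CVConfig(seed=seed + 2),
        diarization=DiarizationConfig(n_speakers=2, seed=seed + 3),
    )
    return run_conversation(conversations, cfg)
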