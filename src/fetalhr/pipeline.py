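"""End-to-end pipeline driver.

Stage order per one-minute buffer:

    reset reconstruction -> filtering -> amplitude demodulation
    -> bipolar leads -> ICA -> maternal QRS detection (a posteriori)
    -> SVD maternal cancellation -> block-wise fetal HR estimation

Longer recordings are processed in non-overlapping one-minute buffers
(a trailing remainder shorter than 30 s is appended to the previous
buffer) and the per-buffer estimates are concatenated.  Every stage's key
decisions are collected in a structured log dict; failures degrade the
result (flags, empty estimates) rather than raising.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .bss import fast_ica, make_bipolar
from .fetal import FhrEstimate, estimate_fhr
from .io import PipelineConfig
from .maternal import QrsAnnotation, cancel_mecg, detect_mqrs, hr_series
from .metrics import MetricsReport, score
from .preprocess import UnipolarRecording, preprocess_recording

log = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    estimate: FhrEstimate
    mqrs: QrsAnnotation
    report: MetricsReport | None
    config_hash: str
    stage_log: dict = field(default_factory=dict)


def _buffer_spans(n: int, fs: float, buffer_s: float, min_tail_s: float) -> list[tuple[int, int]]:
    buf = int(buffer_s * fs)
    tail_min = int(min_tail_s * fs)
    if n <= buf:
        return [(0, n)]
    starts = list(range(0, n, buf))
    spans = [(s, min(s + buf, n)) for s in starts]
    if len(spans) > 1 and spans[-1][1] - spans[-1][0] < tail_min:
        last = spans.pop()
        prev = spans.pop()
        spans.append((prev[0], last[1]))
    return spans


def _run_buffer(
    rec: UnipolarRecording, config: PipelineConfig, seed: int, stage_log: dict
) -> tuple[FhrEstimate, QrsAnnotation]:
    pre, envs = preprocess_recording(
        rec, config.filter_spec(), window_ms=config.reset_window_ms
    )
    stage_log["demodulated_channels"] = [e.applied for e in envs]
    Y = make_bipolar(pre.x).Y
    cm = fast_ica(Y, seed=seed)
    mqrs, qscores = detect_mqrs(
        cm,
        rec.fs,
        lo=config.maternal_rate_range[0],
        hi=config.maternal_rate_range[1],
        ref=config.maternal_ref_bpm,
        band=config.mqrs_band,
    )
    stage_log["mqrs_component"] = mqrs.component_index
    stage_log["mqrs_n_beats"] = len(mqrs)
    stage_log["mqrs_quality"] = [None if q is None else q.q for q in qscores]
    est_m = cancel_mecg(
        cm,
        mqrs,
        rec.fs,
        n_keep=config.svd_rank,
        reject=config.reject_artifact_cycles,
        multiplier=config.artifact_multiplier,
    )
    stage_log["mecg_cancelled"] = not est_m.skipped
    stage_log["rejected_cycles"] = est_m.n_rejected
    est = estimate_fhr(
        est_m.W,
        mqrs,
        rec.fs,
        seed=seed,
        segment_s=config.segment_s,
        step_s=config.step_s,
    )
    stage_log["fetal_flags"] = list(est.flags)
    stage_log["n_blocks"] = len(est.blocks)
    if est.s_opt is not None:
        stage_log["s_opt"] = (est.s_opt.start, est.s_opt.end, est.s_opt.component_index)
    return est, mqrs


def run_pipeline(
    recording: UnipolarRecording,
    config: PipelineConfig | None = None,
    reference: QrsAnnotation | None = None,
) -> PipelineResult:
    """Run the full estimation chain on a recording.

    When ``reference`` fetal annotations are supplied the result includes
    a metrics report (sensitivity, F1, fHR RMSE at the configured
    tolerance).
    """
    config = config or PipelineConfig()
    spans = _buffer_spans(
        recording.n_samples, recording.fs, config.buffer_s, config.min_tail_s
    )
    stage_log: dict = {"n_buffers": len(spans), "buffers": []}
    all_beats: list[np.ndarray] = []
    all_mbeats: list[np.ndarray] = []
    blocks = []
    flags: list[str] = []
    s_opt = None
    for bi, (lo, hi) in enumerate(spans):
        sub = UnipolarRecording(
            x=recording.x[:, lo:hi].copy(),
            fs=recording.fs,
            adc_bits=recording.adc_bits,
            reset_events=[
                type(e)(e.channel, e.sample - lo)
                for e in recording.reset_events
                if lo < e.sample < hi
            ],
            full_scale_v=recording.full_scale_v,
        )
        blog: dict = {"span": (lo, hi)}
        est, mqrs = _run_buffer(sub, config, seed=config.seed + bi, stage_log=blog)
        stage_log["buffers"].append(blog)
        if len(est.fqrs):
            all_beats.append(est.fqrs.samples + lo)
        if len(mqrs):
            all_mbeats.append(mqrs.samples + lo)
        blocks.extend(est.blocks)
        flags.extend(f"buffer{bi}:{f}" for f in est.flags)
        if s_opt is None:
            s_opt = est.s_opt

    fs = recording.fs
    beats = np.concatenate(all_beats) if all_beats else np.array([], dtype=int)
    beats = np.unique(beats)
    fqrs = QrsAnnotation(beats, fs, source="fetal")
    mbeats = np.concatenate(all_mbeats) if all_mbeats else np.array([], dtype=int)
    mqrs_all = QrsAnnotation(np.unique(mbeats), fs, source="maternal")
    fhr = hr_series(fqrs) if len(fqrs) >= 2 else None
    estimate = FhrEstimate(fqrs, fhr, blocks=blocks, s_opt=s_opt, flags=flags)
    report = None
    if reference is not None and len(reference):
        report = score(fqrs, reference, tol_ms=config.match_tolerance_ms)
    return PipelineResult(
        estimate=estimate,
        mqrs=mqrs_all,
        report=report,
        config_hash=config.hash,
        stage_log=stage_log,
    )
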