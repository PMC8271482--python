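"""Beat-detection and heart-rate scoring.

A detected QRS counts as correct when it lies strictly within 50 ms of a
reference annotation (the standard matching rule for fetal QRS scoring).
Matching is one-to-one greedy nearest-first; for physiological beat trains
(reference spacing > 100 ms, i.e. more than twice the tolerance) every
estimate can match at most one reference, so greedy matching is provably
optimal there — the test suite cross-checks it against an assignment-based
optimal matcher anyway.

Se  = 100 * TP / (TP + FN)
F1  = 100 * 2*TP / (2*TP + FN + FP)
RMSE is computed over the P reference rate values, sampling the estimated
beat-to-beat rate series at the reference beat times by linear
interpolation (so missed beats contribute the interpolated estimate).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .maternal import QrsAnnotation, hr_series

__all__ = ["MetricsReport", "match_beats", "score"]


@dataclass
class MetricsReport:
    tp: int
    fp: int
    fn: int
    sensitivity: float
    f1: float
    rmse: float
    n_beats: int
    match_tolerance_ms: float = 50.0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_tsv_line(self, record_id: str = "-") -> str:
        return (
            f"{record_id}\t{self.sensitivity:.1f}\t{self.f1:.1f}\t{self.rmse:.2f}"
            f"\t{self.tp}\t{self.fp}\t{self.fn}"
        )


def match_beats(
    est: QrsAnnotation, ref: QrsAnnotation, tol_ms: float = 50.0
) -> tuple[int, int, int, list[tuple[int, int]]]:
    """One-to-one greedy nearest matching within a strict tolerance.

    Candidate (ref, est) pairs closer than ``tol_ms`` are accepted in
    order of increasing distance (ties broken toward the earlier
    reference, then the earlier estimate); each beat matches at most once.
    Returns (TP, FP, FN, matched index pairs).
    """
    rt = ref.times * 1000.0
    et = est.times * 1000.0
    pairs: list[tuple[float, int, int]] = []
    j0 = 0
    for i, r in enumerate(rt):
        for j in range(np.searchsorted(et, r - tol_ms), len(et)):
            d = et[j] - r
            if d >= tol_ms:
                break
            if abs(d) < tol_ms:
                pairs.append((abs(d), i, j))
    pairs.sort()
    used_r: set[int] = set()
    used_e: set[int] = set()
    matched: list[tuple[int, int]] = []
    for _, i, j in pairs:
        if i in used_r or j in used_e:
            continue
        used_r.add(i)
        used_e.add(j)
        matched.append((i, j))
    tp = len(matched)
    fn = len(ref) - tp
    fp = len(est) - tp
    return tp, fp, fn, sorted(matched)


def score(
    est: QrsAnnotation,
    ref: QrsAnnotation,
    tol_ms: float = 50.0,
) -> MetricsReport:
    """Sensitivity, F1 and fHR RMSE of an estimated annotation vs truth."""
    if len(ref) == 0:
        raise ValueError("empty reference annotation")
    tp, fp, fn, _ = match_beats(est, ref, tol_ms=tol_ms)
    se = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    f1 = 100.0 * 2 * tp / (2 * tp + fn + fp) if 2 * tp + fn + fp else 0.0

    if len(ref) >= 2:
        ref_hr = hr_series(ref)
        if len(est) >= 2:
            est_hr = hr_series(est)
            est_at_ref = np.interp(ref_hr.beat_times, est_hr.beat_times, est_hr.bpm)
        else:
            est_at_ref = np.zeros_like(ref_hr.bpm)
        rmse = float(np.sqrt(np.mean((est_at_ref - ref_hr.bpm) ** 2)))
        p = ref_hr.bpm.size
    else:
        rmse = float("nan")
        p = 0
    return MetricsReport(
        tp=tp, fp=fp, fn=fn, sensitivity=se, f1=f1, rmse=rmse,
        n_beats=p, match_tolerance_ms=tol_ms,
    )
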