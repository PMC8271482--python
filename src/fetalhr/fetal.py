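"""Fetal ECG enhancement and block-wise fetal heart-rate estimation.

After maternal cancellation the residual channels W still mix fetal ECG,
noise and motion transients.  A second full-trace ICA is applied and a
derivative-based detector (det. 1) finds candidate fetal beats on every
component.  Each component contributes a "good" interval — the longest
beat run whose rate stays near the modal rate of that component — and the
best of the four (long, fetal-rate, not maternal-synchronous) seeds the
predictive stage.

The rest of the trace is processed in 5 s blocks.  Each block is covered
by up to two 10 s segments (consecutive segments overlap by 5 s); ICA on a
short segment sees fewer artifact sources, so the fetal component separates
even when the full-trace ICA cannot isolate it.  An AR(2) predictive
detector (det. 2), adapted by normalized LMS on the RR sequence and
anchored on the beats accepted so far, scans every candidate component;
the candidate minimizing a score that combines rate smoothness, maternal
synchrony and a physiological-range penalty wins the block.  Forward and
backward chains extend from the optimal interval to both record edges.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .bss import fast_ica
from .maternal import HrSeries, QrsAnnotation, hr_series

log = logging.getLogger(__name__)

__all__ = [
    "IntervalCandidate",
    "BlockPlan",
    "BlockEstimate",
    "FhrEstimate",
    "detect_fqrs_derivative",
    "good_interval",
    "select_optimal_interval",
    "plan_blocks",
    "ar_predictive_detect",
    "score_block_candidate",
    "estimate_fhr",
]

REFRACTORY_MS = 200.0  # 300 bpm hard cap
MATCH_TOL_MS = 50.0


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def derivative_enhance(x: np.ndarray, fs: float) -> np.ndarray:
    """Rectified, smoothed derivative: large only at sharp QRS slopes."""
    d = np.gradient(np.asarray(x, dtype=float))
    return _moving_average(np.abs(d), max(1, int(0.025 * fs)))


def _refine_peak(x: np.ndarray, idx: int, fs: float, half_ms: float = 25.0) -> int:
    """Snap a detection to the local extremum of |x| (better R timing)."""
    h = int(half_ms * 1e-3 * fs)
    lo, hi = max(0, idx - h), min(x.size, idx + h + 1)
    if hi <= lo:
        return idx
    return lo + int(np.argmax(np.abs(x[lo:hi])))


def detect_fqrs_derivative(
    w: np.ndarray, fs: float, floor_k: float = 3.0
) -> QrsAnnotation:
    """Fetal beat detector det. 1: derivative filter + adaptive threshold.

    Candidates must also exceed ``floor_k`` times the median of the
    enhanced trace, which rejects smooth drift (whose derivative never
    stands out of its own baseline).  Detections are refined to the local
    extremum of the raw component.
    """
    from .preprocess import detect_peaks_adaptive

    w = np.asarray(w, dtype=float)
    if w.size == 0 or np.ptp(w) == 0:
        return QrsAnnotation(np.array([], dtype=int), fs, source="fetal")
    e = derivative_enhance(w, fs)
    gate = floor_k * float(np.median(e))
    peaks = detect_peaks_adaptive(
        e, fs, polarity=+1, refractory_ms=REFRACTORY_MS, min_height=gate
    )
    if peaks.size == 0:
        return QrsAnnotation(np.array([], dtype=int), fs, source="fetal")
    refined = np.array(sorted({_refine_peak(w, p, fs) for p in peaks}), dtype=int)
    keep = np.concatenate(([True], np.diff(refined) > REFRACTORY_MS * 1e-3 * fs))
    return QrsAnnotation(refined[keep], fs, source="fetal")


@dataclass
class IntervalCandidate:
    component_index: int
    start: int
    end: int
    fqrs: QrsAnnotation
    fhr: np.ndarray
    mqrs_correlation: float = 0.0

    @property
    def length(self) -> int:
        return max(0, self.end - self.start)


def good_interval(
    ann: QrsAnnotation,
    trace_len: int,
    bin_bpm: float = 5.0,
    tol_bpm: float = 10.0,
    component_index: int = 0,
) -> IntervalCandidate:
    """Longest run of beats whose rate stays near the modal rate.

    The mode is taken on a ``bin_bpm``-wide histogram of the beat-to-beat
    rates; beats whose rate lies within ``tol_bpm`` of the mode form runs,
    and the longest run becomes the candidate interval.  Fewer than 3
    beats give a degenerate zero-length candidate.
    """
    empty = IntervalCandidate(
        component_index, 0, 0, QrsAnnotation(np.array([], dtype=int), ann.fs, source="fetal"),
        np.array([]),
    )
    if len(ann) < 3:
        return empty
    bpm = hr_series(ann).bpm
    lo = np.floor(bpm.min() / bin_bpm) * bin_bpm
    edges = np.arange(lo, bpm.max() + bin_bpm, bin_bpm)
    if edges.size < 2:
        edges = np.array([lo, lo + bin_bpm])
    counts, _ = np.histogram(bpm, bins=edges)
    mode = float(edges[int(np.argmax(counts))] + bin_bpm / 2)
    ok = np.abs(bpm - mode) <= tol_bpm
    # longest run of consecutive True rate values
    best_len, best_i = 0, 0
    i = 0
    while i < ok.size:
        if ok[i]:
            j = i
            while j < ok.size and ok[j]:
                j += 1
            if j - i > best_len:
                best_len, best_i = j - i, i
            i = j
        else:
            i += 1
    if best_len == 0:
        return empty
    beats = ann.samples[best_i : best_i + best_len + 1]
    return IntervalCandidate(
        component_index,
        int(beats[0]),
        int(beats[-1]),
        QrsAnnotation(beats, ann.fs, source="fetal", component_index=component_index),
        bpm[best_i : best_i + best_len],
    )


def overlap_fraction(
    fqrs: np.ndarray, mqrs: QrsAnnotation, fs: float, tol_ms: float = MATCH_TOL_MS
) -> float:
    """Fraction of candidate beats falling within tol of any maternal beat."""
    fqrs = np.asarray(fqrs)
    if fqrs.size == 0 or len(mqrs) == 0:
        return 0.0
    tol = tol_ms * 1e-3 * fs
    m = mqrs.samples
    idx = np.clip(np.searchsorted(m, fqrs), 1, m.size - 1)
    d = np.minimum(np.abs(fqrs - m[idx - 1]), np.abs(fqrs - m[np.minimum(idx, m.size - 1)]))
    return float(np.mean(d < tol))


def select_optimal_interval(
    candidates: list[IntervalCandidate],
    mqrs: QrsAnnotation,
    fs: float,
    corr_max: float = 0.70,
    lo_bpm: float = 100.0,
    hi_bpm: float = 180.0,
) -> IntervalCandidate | None:
    """Pick the longest interval that is neither maternal nor implausible.

    A candidate is discarded when its beats are synchronous with the
    maternal annotation (overlap fraction > ``corr_max``) or its mean rate
    leaves [lo_bpm, hi_bpm].  Ties on length go to the lowest component
    index.  Returns None when everything is discarded.
    """
    best: IntervalCandidate | None = None
    for c in candidates:
        if c.length <= 0 or c.fhr.size == 0:
            continue
        c.mqrs_correlation = overlap_fraction(c.fqrs.samples, mqrs, fs)
        if c.mqrs_correlation > corr_max:
            continue
        if not (lo_bpm <= float(c.fhr.mean()) <= hi_bpm):
            continue
        if best is None or c.length > best.length:
            best = c
    return best


@dataclass(frozen=True)
class Block:
    index: int
    start: int
    end: int
    direction: str  # "forward" | "backward"
    segments: tuple[tuple[int, int], ...]  # covering 10 s segment spans


@dataclass
class BlockPlan:
    s_opt: tuple[int, int]
    forward_segments: list[tuple[int, int]]
    backward_segments: list[tuple[int, int]]
    blocks: list[Block]


def _grid_segments(
    origin: int, seg: int, step: int, trace_len: int
) -> list[tuple[int, int]]:
    """10 s spans on a 5 s grid anchored at ``origin``, clipped to the trace.

    The grid stays anchored even when ``origin`` is negative (optimal
    interval near a record edge): only the span *edges* are clipped, so
    every interior block keeps two fully-containing segments.
    """
    spans: list[tuple[int, int]] = []
    s = origin
    while s < trace_len:
        a, b = max(0, s), min(s + seg, trace_len)
        if b - a >= step // 2 and (not spans or (a, b) != spans[-1]):
            spans.append((a, b))
        if s + seg >= trace_len:
            break
        s += step
    return spans


def plan_blocks(
    s_opt: tuple[int, int],
    trace_len: int,
    fs: float,
    segment_s: float = 10.0,
    step_s: float = 5.0,
) -> BlockPlan:
    """Segment the trace outside the optimal interval into 5 s blocks.

    Forward segments start half a step inside the optimal interval (so the
    first one overlaps it) and advance by the 5 s step; each block is the
    5 s span shared by two consecutive segments (the terminal block is
    covered by a single segment).  The backward side mirrors this toward
    the start of the record.  The union of all blocks with the optimal
    interval covers the whole trace.
    """
    start, end = int(s_opt[0]), int(s_opt[1])
    seg = int(segment_s * fs)
    step = int(step_s * fs)
    fwd: list[tuple[int, int]] = []
    bwd: list[tuple[int, int]] = []
    blocks: list[Block] = []

    if end < trace_len:
        fwd = _grid_segments(end - step, seg, step, trace_len)
        b0 = end
        k = 0
        while b0 < trace_len:
            b1 = min(b0 + step, trace_len)
            # only segments containing the whole block can track across it
            covering = tuple(s for s in fwd if s[0] <= b0 and s[1] >= b1)
            if not covering:
                covering = tuple(s for s in fwd if s[0] <= b0 < s[1])
            blocks.append(Block(k, b0, b1, "forward", covering))
            k += 1
            b0 = b1

    if start > 0:
        # mirror of the forward grid: anchored at start + step, marching down
        origin = start + step
        bwd = []
        s = origin
        while s > 0:
            a, b = max(0, s - seg), min(s, trace_len)
            if b - a >= step // 2 and (not bwd or (a, b) != bwd[-1]):
                bwd.append((a, b))
            if s - seg <= 0:
                break
            s -= step
        b1 = start
        k = 0
        while b1 > 0:
            b0 = max(b1 - step, 0)
            covering = tuple(s for s in bwd if s[0] <= b0 and s[1] >= b1)
            if not covering:
                covering = tuple(s for s in bwd if s[0] < b1 <= s[1])
            blocks.append(Block(k, b0, b1, "backward", covering))
            k += 1
            b1 = b0

    return BlockPlan(s_opt=(start, end), forward_segments=fwd, backward_segments=bwd, blocks=blocks)


def _fit_ar2(rr: np.ndarray) -> np.ndarray:
    """Least-squares AR(2) on RR intervals; persistence fallback."""
    if rr.size >= 5:
        y = rr[2:]
        X = np.column_stack([rr[1:-1], rr[:-2]])
        try:
            a, *_ = np.linalg.lstsq(X, y, rcond=None)
            if np.all(np.isfinite(a)) and 0 < a.sum() < 2:
                return a
        except np.linalg.LinAlgError:
            pass
    return np.array([1.0, 0.0])


def ar_predictive_detect(
    env: np.ndarray,
    fs: float,
    anchor: float,
    rr_init: np.ndarray,
    stop: int,
    mu: float = 0.1,
    rr_bounds_s: tuple[float, float] = (0.28, 0.80),
) -> list[int]:
    """Predictive beat tracking (det. 2) on an enhanced trace.

    Starting from the last accepted beat (``anchor``, local coordinates,
    may be negative), the next R position is predicted with an AR(2) model
    of the recent RR intervals; the beat is taken as the argmax of the
    enhanced trace under a trapezoidal window centered on the prediction
    (full width 50% of the predicted RR, flat central 20%).  Coefficients
    update after every accepted beat by normalized LMS.  Scanning stops
    when the prediction passes ``stop``.
    """
    env = np.asarray(env, dtype=float)
    n = env.size
    rr_hist = [float(r) / fs for r in rr_init][-8:]
    if not rr_hist:
        raise ValueError("rr_init must be non-empty")
    while len(rr_hist) < 2:
        rr_hist.insert(0, rr_hist[0])
    a = _fit_ar2(np.asarray(rr_hist))
    beats: list[int] = []
    last = float(anchor)
    lo_rr, hi_rr = rr_bounds_s
    while True:
        u = np.array([rr_hist[-1], rr_hist[-2]])
        rr_pred = float(np.clip(a @ u, lo_rr, hi_rr))
        center = last + rr_pred * fs
        if center > stop:
            break
        if center < 0:
            last = center
            continue
        half = 0.25 * rr_pred * fs  # full width 50% of predicted RR
        w_lo, w_hi = int(max(0, center - half)), int(min(n, center + half + 1))
        if w_hi - w_lo < 2:
            break
        xp = [w_lo, center - 0.2 * half, center + 0.2 * half, w_hi - 1]
        trap = np.interp(np.arange(w_lo, w_hi, dtype=float), xp, [0.0, 1.0, 1.0, 0.0])
        windowed = env[w_lo:w_hi] * trap
        idx = w_lo + int(np.argmax(windowed)) if windowed.max() > 0 else int(round(center))
        if beats and idx - beats[-1] < REFRACTORY_MS * 1e-3 * fs:
            idx = int(round(center))
        beats.append(idx)
        rr_obs = (idx - last) / fs
        err = rr_obs - rr_pred
        a = a + mu * err * u / (u @ u + 1e-12)
        if not np.all(np.isfinite(a)) or not (0 < a.sum() < 2):
            a = np.array([1.0, 0.0])
        rr_hist.append(rr_obs)
        if len(rr_hist) > 8:
            rr_hist.pop(0)
        last = float(idx)
    return beats


def score_block_candidate(
    fhr_all: np.ndarray,
    cand_bpm: np.ndarray,
    cand_beats: np.ndarray,
    mqrs: QrsAnnotation,
    fs: float,
    ref_bpm: float = 85.0,
    lo_bpm: float = 100.0,
    hi_bpm: float = 180.0,
    salience: float | None = None,
    salience_target: float = 3.0,
    expected_n: int | None = None,
    weights: tuple[float, float, float, float, float] = (1.0, 1.0, 1.0, 1.0, 1.0),
) -> tuple[float, tuple[float, float, float, float, float]]:
    """Score a block candidate appended to the accepted series (lower wins).

    Terms: rate smoothness of the whole series (mean |first| + |second|
    derivative, normalized by ``ref_bpm``), maternal synchrony of the
    candidate beats, a penalty growing with the candidate's mean-rate
    excursion outside [lo_bpm, hi_bpm], a salience deficit, and a coverage
    deficit.  Salience is the typical enhanced-trace amplitude at the
    tracked beats relative to the segment's enhanced baseline: a
    predictive tracker free-running on a noise component produces a
    smooth, physiologically plausible series with *no* peak evidence
    under it — the salience term rejects those.  The coverage deficit
    penalizes candidates with far fewer beats than the block duration
    implies (an under-covering candidate adds little to the series'
    variability and would otherwise win by default).
    """
    if cand_beats.size == 0 or cand_bpm.size == 0 or fhr_all.size < 2:
        return float("inf"), (float("inf"), 0.0, 0.0, 0.0, 0.0)
    d1 = float(np.mean(np.abs(np.diff(fhr_all)))) if fhr_all.size > 1 else 0.0
    d2 = float(np.mean(np.abs(np.diff(fhr_all, 2)))) if fhr_all.size > 2 else 0.0
    variability = (d1 + d2) / ref_bpm
    corr = overlap_fraction(cand_beats, mqrs, fs)
    mean = float(cand_bpm.mean())
    penalty = max(0.0, lo_bpm - mean, mean - hi_bpm) / ref_bpm
    if salience is None:
        deficit = 0.0
    else:
        deficit = max(0.0, 1.0 - salience / salience_target)
    if expected_n is None or expected_n <= 0:
        cov = 0.0
    else:
        cov = max(0.0, (expected_n - cand_beats.size) / expected_n)
    w1, w2, w3, w4, w5 = weights
    total = w1 * variability + w2 * corr + w3 * penalty + w4 * deficit + w5 * cov
    return total, (variability, corr, penalty, deficit, cov)


def repair_annotation(
    beats: np.ndarray, env: np.ndarray, fs: float
) -> tuple[np.ndarray, int, int]:
    """Seam repair of an assembled beat sequence (evidence-driven).

    Block seams occasionally produce a double-fire (two beats sharing one
    true complex) or a dropped beat (QRS truncated at a segment edge).
    Both poison the rate series with half/double-rate spikes.  A spurious
    beat is removed when an interval is far below the local median and
    merging it with its neighbor restores a normal interval; a gap close
    to a multiple of the local median interval is filled at the maximum of
    the enhanced evidence trace near the expected position (falling back
    to the expected position itself when no evidence stands out).

    Returns (repaired beats, n_removed, n_inserted).
    """
    b = [int(x) for x in np.sort(beats)]
    if len(b) < 4:
        return np.asarray(b, dtype=int), 0, 0
    n_removed = 0
    n_inserted = 0

    def local_med(k: int) -> float:
        rr = np.diff(b)
        lo, hi = max(0, k - 4), min(len(rr), k + 4)
        return float(np.median(rr[lo:hi]))

    # pass 1: drop double-fires
    k = 1
    while k < len(b) - 1:
        med = local_med(k)
        rr_prev = b[k] - b[k - 1]
        rr_next = b[k + 1] - b[k]
        if (rr_prev < 0.6 * med or rr_next < 0.6 * med) and abs(
            (b[k + 1] - b[k - 1]) - med
        ) < 0.3 * med:
            e_mid = env[min(b[k], env.size - 1)]
            e_nb = max(env[min(b[k - 1], env.size - 1)], env[min(b[k + 1], env.size - 1)])
            if e_mid <= e_nb:
                del b[k]
                n_removed += 1
                continue
        k += 1

    # pass 2: fill gaps at evidence maxima
    base = float(np.median(env))
    k = 0
    while k < len(b) - 1:
        med = local_med(k)
        gap = b[k + 1] - b[k]
        if 1.6 * med < gap < 3.2 * med and med > 0:
            expect = b[k] + gap / round(gap / med)
            half = int(0.25 * med)
            lo, hi = int(expect - half), int(expect + half)
            lo, hi = max(0, lo), min(env.size, hi)
            if hi - lo > 2:
                idx = lo + int(np.argmax(env[lo:hi]))
                if env[idx] < 2.0 * base:
                    idx = int(round(expect))
                b.insert(k + 1, idx)
                n_inserted += 1
                continue
        k += 1
    return np.asarray(sorted(set(b)), dtype=int), n_removed, n_inserted


@dataclass
class BlockEstimate:
    block: Block
    chosen: int  # winning candidate index (component within the block)
    score: float
    score_terms: tuple[float, ...]
    n_candidates: int
    beats: np.ndarray


@dataclass
class FhrEstimate:
    fqrs: QrsAnnotation
    fhr: HrSeries | None
    blocks: list[BlockEstimate] = field(default_factory=list)
    s_opt: IntervalCandidate | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return len(self.fqrs) < 2


def _segment_components(W: np.ndarray, span: tuple[int, int], seed: int, cache: dict):
    key = span
    if key not in cache:
        seg = W[:, span[0] : span[1]]
        cm = fast_ica(seg, seed=seed + (span[0] % 7919))
        cache[key] = cm.Z
    return cache[key]


def _assemble_rates(beats: np.ndarray, fs: float) -> np.ndarray:
    if beats.size < 2:
        return np.array([])
    return 60.0 * fs / np.diff(beats)


def _drop_near(beats: np.ndarray, existing: np.ndarray, refr: float) -> np.ndarray:
    """Remove beats closer than ``refr`` samples to any existing beat."""
    if beats.size == 0 or existing.size == 0:
        return beats
    idx = np.searchsorted(existing, beats)
    d_lo = beats - existing[np.clip(idx - 1, 0, existing.size - 1)]
    d_hi = existing[np.clip(idx, 0, existing.size - 1)] - beats
    d = np.minimum(np.abs(d_lo), np.abs(d_hi))
    return beats[d > refr]


def estimate_fhr(
    W: np.ndarray,
    mqrs: QrsAnnotation,
    fs: float,
    seed: int = 0,
    segment_s: float = 10.0,
    step_s: float = 5.0,
    evidence_skip_deficit: float = 0.75,
    retry_threshold: float = 0.5,
) -> FhrEstimate:
    """Full fetal stage: second ICA, optimal interval, block-wise tracking.

    ``W`` is the residual lead matrix after maternal cancellation.  The
    returned estimate carries per-block provenance and degradation flags;
    an unusable record yields a flagged empty estimate, never an exception.
    """
    n = W.shape[1]
    empty_ann = QrsAnnotation(np.array([], dtype=int), fs, source="fetal")
    cm = fast_ica(W, seed=seed)
    if cm.n_components == 0:
        return FhrEstimate(empty_ann, None, flags=["no-components"])

    flags: list[str] = []
    cache: dict = {}
    candidates = []
    for i in range(cm.n_components):
        ann = detect_fqrs_derivative(cm.Z[i], fs)
        candidates.append(good_interval(ann, n, component_index=i))
    s_opt = select_optimal_interval(candidates, mqrs, fs)
    if s_opt is None or len(s_opt.fqrs) < 3:
        # Full-trace ICA failed to expose a usable fetal run (too many
        # artifact sources competing for the available components).  Short
        # windows contain few artifact sources, so retry the search on
        # segment-wise ICAs and keep the best interval found anywhere.
        seg = int(segment_s * fs)
        stp = int(step_s * fs)
        seg_cands: list[IntervalCandidate] = []
        s0 = 0
        while s0 < n:
            span = (s0, min(s0 + seg, n))
            if span[1] - span[0] >= seg // 2:
                comps = _segment_components(W, span, seed, cache)
                for i in range(comps.shape[0]):
                    ann = detect_fqrs_derivative(comps[i], fs)
                    loc = good_interval(ann, span[1] - span[0], component_index=i)
                    if loc.length > 0 and len(loc.fqrs) >= 3:
                        gann = QrsAnnotation(
                            loc.fqrs.samples + span[0], fs,
                            source="fetal", component_index=i,
                        )
                        seg_cands.append(
                            IntervalCandidate(
                                i, loc.start + span[0], loc.end + span[0], gann, loc.fhr
                            )
                        )
            s0 += stp
        s_opt = select_optimal_interval(seg_cands, mqrs, fs)
        if s_opt is not None:
            flags.append("s-opt-from-segment-ica")
    if s_opt is None or len(s_opt.fqrs) < 3:
        return FhrEstimate(empty_ann, None, flags=flags + ["no-optimal-interval"])

    assembled = list(int(b) for b in s_opt.fqrs.samples)
    owner_score: dict[int, float] = {b: -1.0 for b in assembled}  # Sopt beats win ties
    # physiological rate band around the trusted interval's median RR
    g_rr = float(np.median(np.diff(s_opt.fqrs.samples)))
    rr_lo = max(0.28, 0.7 * g_rr / fs)
    rr_hi = min(0.80, 1.4 * g_rr / fs)
    plan = plan_blocks((s_opt.start, s_opt.end), n, fs, segment_s, step_s)
    block_estimates: list[BlockEstimate] = []
    refr = REFRACTORY_MS * 1e-3 * fs

    forward_blocks = sorted(
        (b for b in plan.blocks if b.direction == "forward"), key=lambda b: b.start
    )
    backward_blocks = sorted(
        (b for b in plan.blocks if b.direction == "backward"), key=lambda b: -b.start
    )

    def _snap(env_local: np.ndarray, pos: float, half_ms: float = 120.0) -> float:
        # the anchor beat came from a different ICA mixture whose peak
        # phase can differ; re-center it on this component's evidence
        h = int(half_ms * 1e-3 * fs)
        lo = int(max(0, pos - h))
        hi = int(min(env_local.size, pos + h + 1))
        if hi - lo < 3:
            return pos
        w = env_local[lo:hi]
        if w.max() > 2.0 * np.median(env_local):
            return float(lo + int(np.argmax(w)))
        return pos

    def _evaluate(block: Block, fwd: bool, exclude: np.ndarray | None = None):
        """Best candidate for a block given the current assembled beats.

        Returns (score, terms, beats, candidate_index, n_candidates) or
        None when no anchor is available.  ``exclude`` removes beats from
        the anchoring context (used when re-estimating a block).
        """
        ctx = sorted(set(assembled) - set(exclude.tolist() if exclude is not None else []))
        arr = np.array(ctx)
        if fwd:
            prior = arr[arr < block.start]
            if prior.size < 2:
                return None
            anchor_g = float(prior[-1])
            rr_init = np.diff(prior[-9:]).astype(float)
        else:
            nxt = arr[arr >= block.end]
            if nxt.size < 2:
                return None
            anchor_g = float(nxt[0])
            rr_init = np.diff(nxt[:9]).astype(float)[::-1]
        # robust anchor rates: an outlier RR (seam artifact) would derail
        # the AR predictor, so replace deviants with the median interval,
        # and keep everything inside the rate band established by the
        # trusted optimal interval (a block that went wrong must not be
        # allowed to re-anchor the whole chain at a sub-harmonic rate)
        med_rr = float(np.median(rr_init))
        rr_init = np.where(np.abs(rr_init - med_rr) > 0.15 * fs, med_rr, rr_init)
        rr_init = np.clip(rr_init, rr_lo * fs, rr_hi * fs)
        med_rr = float(np.clip(med_rr, rr_lo * fs, rr_hi * fs))

        assembled_arr = arr
        best: tuple[float, tuple, np.ndarray, int] | None = None
        cand_idx = 0
        # track every candidate: component x covering segment x anchor variant
        runs: list[tuple[int, np.ndarray, float | None]] = []
        for span in block.segments:
            comps = _segment_components(W, span, seed, cache)
            for ci in range(comps.shape[0]):
                env = derivative_enhance(comps[ci], fs)
                comp = comps[ci]
                if fwd:
                    anchor0 = anchor_g - span[0]
                    stop_l = block.end - span[0]
                    trace = env
                else:
                    m = span[1] - span[0]
                    trace = env[::-1]
                    anchor0 = (m - 1) - (anchor_g - span[0])
                    stop_l = (m - 1) - (block.start - span[0])
                # try the anchor as-is and re-centered on this component's
                # evidence, and let the score pick the better lock
                anchors = {float(anchor0), _snap(trace, anchor0)}
                for anchor_l in anchors:
                    beats_l = ar_predictive_detect(
                        trace, fs, anchor_l, rr_init, stop_l, rr_bounds_s=(rr_lo, rr_hi)
                    )
                    if fwd:
                        beats_g = np.array([b + span[0] for b in beats_l], dtype=int)
                    else:
                        m = span[1] - span[0]
                        beats_g = np.array(
                            sorted(span[0] + (m - 1) - np.array(beats_l, dtype=int)),
                            dtype=int,
                        )
                    beats_g = beats_g[(beats_g >= block.start) & (beats_g < block.end)]
                    # refine on the raw component for timing accuracy
                    beats_g = np.array(
                        sorted({_refine_peak(comp, b - span[0], fs) + span[0] for b in beats_g}),
                        dtype=int,
                    )
                    if beats_g.size:
                        keep = np.concatenate(([True], np.diff(beats_g) > refr))
                        beats_g = beats_g[keep]
                    # a candidate beat duplicating a seam beat would inject a
                    # fictitious near-zero RR into the scored series
                    beats_g = _drop_near(beats_g, assembled_arr, refr)
                    salience = None
                    if beats_g.size:
                        base = float(np.median(env))
                        if base > 0:
                            at_beats = env[np.clip(beats_g - span[0], 0, env.size - 1)]
                            salience = float(np.median(at_beats)) / base
                    runs.append((cand_idx, beats_g, salience))
                cand_idx += 1

        for idx, beats_g, salience in runs:
            all_beats = np.array(sorted(set(ctx) | set(beats_g.tolist())))
            # smoothness judged in a local window around the block: a rate
            # jump at the seam must not be diluted by a long accepted series
            lo_w, hi_w = block.start - int(4 * fs), block.end + int(4 * fs)
            local = all_beats[(all_beats >= lo_w) & (all_beats < hi_w)]
            fhr_all = _assemble_rates(local if local.size >= 3 else all_beats, fs)
            ext = (
                np.sort(np.concatenate(([anchor_g], beats_g))) if beats_g.size else beats_g
            )
            cand_bpm = _assemble_rates(ext.astype(float), fs)
            exp_n = int(round((block.end - block.start) / max(med_rr, 1.0)))
            sc, terms = score_block_candidate(
                fhr_all, cand_bpm, beats_g, mqrs, fs,
                salience=salience, expected_n=exp_n,
            )
            if best is None or sc < best[0]:
                best = (sc, terms, beats_g, idx)
        if best is None:
            return None
        return best + (cand_idx,)

    def _commit(block: Block, best, replace: np.ndarray | None = None) -> BlockEstimate:
        sc, terms, beats_g, chosen, n_cand = best
        if replace is not None:
            for b in replace.tolist():
                if b in owner_score:
                    assembled.remove(b)
                    owner_score.pop(b)
        for b in beats_g:
            near = [x for x in assembled if abs(x - b) <= refr]
            if near:
                # seam duplicate: keep the beat owned by the lower score
                if all(owner_score[x] > sc for x in near):
                    for x in near:
                        assembled.remove(x)
                        owner_score.pop(x)
                else:
                    continue
            assembled.append(int(b))
            owner_score[int(b)] = sc
        return BlockEstimate(block, chosen, sc, terms, n_cand, beats_g)

    for block in forward_blocks + backward_blocks:
        fwd = block.direction == "forward"
        best = _evaluate(block, fwd)
        if best is None:
            flags.append(f"block-{block.direction}-{block.index}: no anchor")
            continue
        if not np.isfinite(best[0]):
            flags.append(f"block-{block.direction}-{block.index}: no candidate")
            block_estimates.append(
                BlockEstimate(
                    block, -1, float("inf"), (0.0, 0.0, 0.0, 0.0, 0.0), best[4],
                    np.array([], dtype=int),
                )
            )
            continue
        if best[1][3] >= evidence_skip_deficit:
            # even the best candidate has no peak evidence under its beats:
            # contribute nothing rather than poison downstream anchors
            flags.append(f"block-{block.direction}-{block.index}: no evidence")
            block_estimates.append(
                BlockEstimate(block, best[3], best[0], best[1], best[4], np.array([], dtype=int))
            )
            continue
        block_estimates.append(_commit(block, best))

    # second chance: a block that scored poorly in chain order can now be
    # re-estimated with anchors available on BOTH sides (its neighbors may
    # have succeeded from cleaner data); adopt whichever direction scores
    # best, including the original choice.  Iterate — every repaired block
    # provides a clean anchor for the next one.
    for _round in range(3):
        retry = [be for be in block_estimates if be.score > retry_threshold or be.beats.size == 0]
        improved = False
        for be in sorted(retry, key=lambda b: -b.score):
            block = be.block
            options: list[tuple[float, object]] = [(be.score, None)]
            for fwd in (True, False):
                cand = _evaluate(block, fwd, exclude=be.beats)
                if (
                    cand is not None
                    and np.isfinite(cand[0])
                    and cand[1][3] < evidence_skip_deficit
                ):
                    options.append((cand[0], cand))
            options.sort(key=lambda t: t[0])
            sc, cand = options[0]
            if cand is not None and sc < be.score - 0.05:
                new_be = _commit(block, cand, replace=be.beats)
                block_estimates[block_estimates.index(be)] = new_be
                flags.append(
                    f"block-{block.direction}-{block.index}: re-estimated "
                    f"({be.score:.2f} -> {sc:.2f})"
                )
                improved = True
        if not improved:
            break

    final = np.array(sorted(set(assembled)), dtype=int)
    if final.size:
        keep = np.concatenate(([True], np.diff(final) > refr))
        final = final[keep]
    env_sum = np.sum([derivative_enhance(W[i], fs) for i in range(W.shape[0])], axis=0)
    final, n_rm, n_ins = repair_annotation(final, env_sum, fs)
    if n_rm or n_ins:
        flags.append(f"seam-repair: removed {n_rm}, inserted {n_ins}")
    ann = QrsAnnotation(final, fs, source="fetal")
    fhr = hr_series(ann) if len(ann) >= 2 else None
    return FhrEstimate(ann, fhr, blocks=block_estimates, s_opt=s_opt, flags=flags)
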