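"""Maternal QRS detection and maternal-ECG cancellation.

The maternal ECG dominates every abdominal lead and must be removed before
the fetal complexes become detectable.  The stages here are:

* :func:`detect_mqrs` — band-pass each independent component in the QRS
  band (6.3-16 Hz), run the adaptive peak detector on both polarities
  (ICA sign is arbitrary), and select the best component *a posteriori*
  by a heart-rate quality index Q combining outlier count, beat-to-beat
  variability and discrepancy from a nominal 85 bpm maternal rate.
  Lower Q is better; components whose mean rate falls outside
  [50, 180] bpm are discarded outright.
* :func:`cancel_mecg` — segment every component into cardiac cycles at
  the selected maternal R times, window with a trapezoid, discard cycles
  whose peak exceeds 5x the median peak (motion artifacts would otherwise
  leak into the template), approximate the rest with a rank-Ne SVD
  truncation, and subtract the rebuilt maternal signal: W = Z - M.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .bss import ComponentMatrix
from .preprocess import detect_peaks_adaptive

log = logging.getLogger(__name__)

__all__ = [
    "QrsAnnotation",
    "HrSeries",
    "QualityScore",
    "CycleMatrix",
    "EstimatedMecg",
    "hr_series",
    "quality_index",
    "detect_mqrs",
    "build_cycle_matrix",
    "reject_artifact_cycles",
    "cancel_mecg",
]


@dataclass
class QrsAnnotation:
    """Ordered R-peak sample indices for one beat source."""

    samples: np.ndarray
    fs: float
    source: str = "maternal"
    component_index: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=int)
        if self.samples.size > 1 and np.any(np.diff(self.samples) <= 0):
            raise ValueError("annotation samples must be strictly increasing")

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def times(self) -> np.ndarray:
        return self.samples / self.fs

    def shifted(self, offset: int) -> "QrsAnnotation":
        return replace(self, samples=self.samples + offset)


@dataclass
class HrSeries:
    """Beat-to-beat rate: ``bpm[j] = 60 / RR_j``, one value per interval."""

    bpm: np.ndarray
    beat_times: np.ndarray  # midpoint of each RR interval, seconds
    n_beats: int


def hr_series(ann: QrsAnnotation) -> HrSeries:
    if len(ann) < 2:
        raise ValueError("need at least 2 peaks for a rate series")
    t = ann.times
    rr = np.diff(t)
    return HrSeries(bpm=60.0 / rr, beat_times=(t[:-1] + t[1:]) / 2, n_beats=len(ann))


@dataclass
class QualityScore:
    q: float
    n_outliers: int
    outlier_term: float
    variability_term: float
    discrepancy_term: float
    reference_rate: float = 85.0


def quality_index(
    hr: HrSeries, lo: float = 50.0, hi: float = 180.0, ref: float = 85.0
) -> QualityScore:
    """Heart-rate series quality index (lower is better).

    Q = N_outliers/N + sum|dHR| / sum HR + |mean(HR) - ref| / ref,
    summing over the available rate values.  The discrepancy term uses the
    absolute deviation so rates below the nominal value are penalized the
    same as rates above it.
    """
    bpm = np.asarray(hr.bpm, dtype=float)
    if bpm.size == 0:
        raise ValueError("empty rate series")
    n = bpm.size
    n_out = int(np.count_nonzero((bpm < lo) | (bpm > hi)))
    t_out = n_out / n
    t_var = float(np.abs(np.diff(bpm)).sum() / bpm.sum()) if n > 1 else 0.0
    t_disc = abs(float(bpm.mean()) - ref) / ref
    return QualityScore(
        q=t_out + t_var + t_disc,
        n_outliers=n_out,
        outlier_term=t_out,
        variability_term=t_var,
        discrepancy_term=t_disc,
        reference_rate=ref,
    )


def detect_mqrs(
    cm: ComponentMatrix,
    fs: float,
    lo: float = 50.0,
    hi: float = 180.0,
    ref: float = 85.0,
    band: tuple[float, float] = (6.3, 16.0),
) -> tuple[QrsAnnotation, list[QualityScore | None]]:
    """A-posteriori maternal component selection.

    Every component is searched with both polarities; a component is kept
    only if its mean detected rate lies in [lo, hi] bpm.  Among the kept
    components the one minimizing the quality index wins.  If all are
    discarded an empty annotation is returned (maternal cancellation is
    then skipped upstream).
    """
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    best: tuple[float, QrsAnnotation] | None = None
    scores: list[QualityScore | None] = []
    for i in range(cm.n_components):
        z = sps.sosfiltfilt(sos, cm.Z[i])
        comp_best: tuple[float, QrsAnnotation, QualityScore] | None = None
        for pol in (+1, -1):
            peaks = detect_peaks_adaptive(z, fs, polarity=pol)
            if peaks.size < 2:
                continue
            ann = QrsAnnotation(peaks, fs, source="maternal", component_index=i)
            hr = hr_series(ann)
            if not (lo <= float(hr.bpm.mean()) <= hi):
                continue
            qs = quality_index(hr, lo=lo, hi=hi, ref=ref)
            if comp_best is None or qs.q < comp_best[0]:
                comp_best = (qs.q, ann, qs)
        if comp_best is None:
            scores.append(None)
            continue
        scores.append(comp_best[2])
        if best is None or comp_best[0] < best[0]:
            best = (comp_best[0], comp_best[1])
    if best is None:
        return QrsAnnotation(np.array([], dtype=int), fs, source="maternal"), scores
    return best[1], scores


def _trapezoid_window(n: int, taper_frac: float = 0.2) -> np.ndarray:
    """Trapezoid with linear tapers reaching exactly zero at both ends."""
    taper = max(1, int(round(taper_frac * n)))
    xp = [0.0, float(taper), float(n - 1 - taper), float(n - 1)]
    return np.interp(np.arange(n, dtype=float), xp, [0.0, 1.0, 1.0, 0.0])


@dataclass
class CycleMatrix:
    """Windowed cardiac cycles as columns (Nd x Nq), centered on mQRS."""

    K: np.ndarray
    centers: np.ndarray
    window: np.ndarray
    kept_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.kept_mask is None:
            self.kept_mask = np.ones(self.K.shape[1], dtype=bool)

    @property
    def n_d(self) -> int:
        return self.K.shape[0]

    @property
    def n_q(self) -> int:
        return self.K.shape[1]

    @property
    def n_rejected(self) -> int:
        return int(np.count_nonzero(~self.kept_mask))

    @property
    def Ks(self) -> np.ndarray:
        return self.K[:, self.kept_mask]


def build_cycle_matrix(
    z: np.ndarray, mqrs: QrsAnnotation, fs: float, taper_frac: float = 0.2
) -> CycleMatrix:
    """Segment a trace into trapezoid-windowed cycles centered on mQRS.

    The segment length Nd is the median RR interval forced odd so each
    column is centered on its R sample; cycles running past the record
    edges are zero-padded.
    """
    z = np.asarray(z, dtype=float)
    if len(mqrs) < 4:
        raise ValueError("need at least 4 maternal beats for cycle segmentation")
    rr = np.diff(mqrs.samples)
    nd = int(round(float(np.median(rr))))
    if nd % 2 == 0:
        nd += 1
    half = nd // 2
    win = _trapezoid_window(nd, taper_frac)
    n = z.size
    K = np.zeros((nd, len(mqrs)))
    for j, c in enumerate(mqrs.samples):
        lo, hi = c - half, c + half + 1
        src_lo, src_hi = max(0, lo), min(n, hi)
        col = np.zeros(nd)
        col[src_lo - lo : src_lo - lo + (src_hi - src_lo)] = z[src_lo:src_hi]
        K[:, j] = col * win
    return CycleMatrix(K=K, centers=mqrs.samples.copy(), window=win)


def reject_artifact_cycles(cm: CycleMatrix, multiplier: float = 5.0) -> CycleMatrix:
    """Discard cycles whose peak exceeds ``multiplier`` x the median peak.

    Motion artifacts have amplitudes far above any cardiac cycle; if they
    stay in the matrix they capture the leading singular vectors and the
    maternal template is underestimated.  If rejection would leave fewer
    than two cycles, everything is kept (degenerate medians).
    """
    maxima = np.abs(cm.K).max(axis=0)
    thr = multiplier * float(np.median(maxima))
    kept = maxima <= thr
    if kept.sum() < 2:
        log.warning("artifact rejection would discard all cycles; keeping all")
        kept = np.ones_like(kept)
    return CycleMatrix(K=cm.K, centers=cm.centers, window=cm.window, kept_mask=kept)


@dataclass
class EstimatedMecg:
    """Per-component maternal estimate M and residual W = Z - M."""

    M: np.ndarray
    W: np.ndarray
    n_rejected: list[int]
    skipped: bool = False


def cancel_mecg(
    cm: ComponentMatrix,
    mqrs: QrsAnnotation,
    fs: float,
    n_keep: int = 2,
    reject: bool = True,
    multiplier: float = 5.0,
    blank_rejected: bool = False,
) -> EstimatedMecg:
    """SVD template cancellation of the maternal ECG on every component.

    The *same* maternal R times segment all components.  For each one the
    artifact-free cycle matrix is truncated to its first ``n_keep``
    singular values; the rebuilt cycles (which taper to zero at their
    edges) are placed back at their beat positions, and inter-cycle gaps
    stay at zero — the straight-line fill.  Spans whose cycle was rejected
    as an artifact carry no usable cardiac information and (with
    ``blank_rejected``) are replaced by a straight line in the residual as
    well, so high-amplitude transients cannot dominate the later source
    separations.  With an empty annotation the input passes through
    unchanged.
    """
    Z = cm.Z
    if len(mqrs) < 4:
        if len(mqrs) > 0:
            log.warning("too few maternal beats (%d); cancellation skipped", len(mqrs))
        return EstimatedMecg(
            M=np.zeros_like(Z), W=Z.copy(), n_rejected=[0] * Z.shape[0], skipped=True
        )
    M = np.zeros_like(Z)
    W = Z.copy()
    n_rej: list[int] = []
    n = Z.shape[1]
    for i in range(Z.shape[0]):
        kmat = build_cycle_matrix(Z[i], mqrs, fs)
        if reject:
            kmat = reject_artifact_cycles(kmat, multiplier=multiplier)
        ks = kmat.Ks
        try:
            U, s, Vt = np.linalg.svd(ks, full_matrices=False)
        except np.linalg.LinAlgError:
            log.warning("SVD failed on component %d; cancellation skipped", i)
            n_rej.append(kmat.n_rejected)
            continue
        r = min(n_keep, s.size)
        recon = (U[:, :r] * s[:r]) @ Vt[:r]
        half = kmat.n_d // 2
        kept_idx = np.flatnonzero(kmat.kept_mask)
        for col, j in enumerate(kept_idx):
            c = int(kmat.centers[j])
            lo, hi = c - half, c + half + 1
            src_lo, src_hi = max(0, lo), min(n, hi)
            M[i, src_lo:src_hi] += recon[src_lo - lo : src_lo - lo + (src_hi - src_lo), col]
        W[i] = Z[i] - M[i]
        if blank_rejected:
            for j in np.flatnonzero(~kmat.kept_mask):
                c = int(kmat.centers[j])
                W[i, max(0, c - half) : min(n, c + half + 1)] = 0.0
        n_rej.append(kmat.n_rejected)
    return EstimatedMecg(M=M, W=W, n_rejected=n_rej, skipped=False)
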