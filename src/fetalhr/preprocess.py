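"""Pre-processing for dry-electrode abdominal ECG recordings.

Dry/textile electrodes produce artifact classes that gelled electrodes do
not: volt-scale triboelectric charge steps (handled in hardware by a reset
circuit that snaps the channel back to mid-scale, leaving a logged step
discontinuity), slow multiplicative amplitude modulation from motion-induced
impedance changes, and broadband motion transients.  This module implements
the digital half of that hybrid strategy:

1. :func:`reconstruct_resets` — remove the logged step discontinuities so
   the DC level is constant over the full trace.
2. :func:`apply_filters` — zero-phase notch + band-limiting to the QRS band.
3. :func:`demodulate` — spline-envelope amplitude demodulation driven by an
   adaptive-threshold peak detector.

All operations are pure: they return new arrays/recordings and never mutate
their inputs.
"""
from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

log = logging.getLogger(__name__)

__all__ = [
    "ResetEvent",
    "UnipolarRecording",
    "FilterSpec",
    "EnvelopePair",
    "reconstruct_resets",
    "apply_filters",
    "detect_peaks_adaptive",
    "demodulate",
    "preprocess_recording",
]


@dataclass(frozen=True)
class ResetEvent:
    """A hardware reset: ``sample`` is the first post-reset sample index."""

    channel: int
    sample: int


@dataclass
class UnipolarRecording:
    """Multi-channel unipolar abdominal recording.

    Parameters
    ----------
    x : ndarray, shape (n_channels, n_samples)
        Samples in volts.
    fs : float
        Sampling rate in Hz.
    adc_bits : int
        ADC resolution; together with ``full_scale_v`` defines the LSB.
    reset_events : list of ResetEvent
        Logged reset instants (sidecar of the acquisition hardware).
    full_scale_v : float
        Rail-to-rail input range in volts (symmetric around zero).
    """

    x: np.ndarray
    fs: float
    adc_bits: int = 14
    reset_events: list[ResetEvent] = field(default_factory=list)
    full_scale_v: float = 0.016
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 2:
            raise ValueError("x must be a 2-D (n_channels, n_samples) array")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.reset_events = sorted(
            self.reset_events, key=lambda e: (e.channel, e.sample)
        )

    @property
    def n_channels(self) -> int:
        return self.x.shape[0]

    @property
    def n_samples(self) -> int:
        return self.x.shape[1]

    @property
    def lsb(self) -> float:
        return self.full_scale_v / 2**self.adc_bits

    def copy(self) -> "UnipolarRecording":
        return replace(self, x=self.x.copy(), reset_events=list(self.reset_events))


@dataclass(frozen=True)
class FilterSpec:
    """Band-limiting chain: notch -> FIR low-pass -> Butterworth high-pass."""

    notch_freq: float = 50.0
    notch_bw: float = 1.0
    lp_cutoff: float = 75.0
    lp_order: int = 200
    hp_cutoff: float = 10.0
    hp_order: int = 6

    def __post_init__(self) -> None:
        if not (0.0 < self.hp_cutoff < self.lp_cutoff):
            raise ValueError("need 0 < hp_cutoff < lp_cutoff")


@dataclass
class EnvelopePair:
    """Positive/negative spline envelopes and the demodulation scale.

    ``gamma = (gamma_plus - gamma_minus) / 2`` and ``sigma = median(gamma)``;
    the demodulated trace is ``x * sigma / gamma``.  ``applied`` is False
    when too few peaks were available and the trace was passed through.
    """

    gamma_plus: np.ndarray | None
    gamma_minus: np.ndarray | None
    gamma: np.ndarray | None
    sigma: float
    applied: bool


def reconstruct_resets(
    recording: UnipolarRecording, window_ms: float = 50.0
) -> UnipolarRecording:
    """Remove logged reset step discontinuities channel by channel.

    For each event the difference between the post-reset and pre-reset
    window means is subtracted from every sample at or after the reset,
    processing events in increasing sample order so stacked steps cancel
    sequentially.  Events at the very edges of the record are skipped with
    a warning.
    """
    out = recording.copy()
    w = max(1, int(round(window_ms * 1e-3 * recording.fs)))
    n = recording.n_samples
    for ev in out.reset_events:
        s = ev.sample
        if s <= 0 or s >= n:
            log.warning("reset event at sample %d outside (0, %d); skipped", s, n)
            continue
        pre = out.x[ev.channel, max(0, s - w) : s]
        post = out.x[ev.channel, s : min(n, s + w)]
        step = post.mean() - pre.mean()
        out.x[ev.channel, s:] -= step
    return out


def _notch_sos(freq: float, bw: float, fs: float) -> np.ndarray:
    b, a = sps.iirnotch(freq, freq / bw, fs=fs)
    return sps.tf2sos(b, a)


def apply_filters(
    recording: UnipolarRecording, spec: FilterSpec | None = None
) -> UnipolarRecording:
    """Zero-phase notch, FIR low-pass and Butterworth high-pass, in order.

    All stages are applied forward-backward so the QRS shape is not skewed
    by phase distortion.  Resets must have been reconstructed first: a
    residual step smears over the full impulse-response length.
    """
    spec = spec or FilterSpec()
    fs = recording.fs
    if spec.lp_cutoff >= fs / 2:
        raise ValueError("lp_cutoff must be below Nyquist")
    min_len = 3 * max(spec.lp_order + 1, int(fs))
    if recording.n_samples < min_len:
        raise ValueError(
            f"record too short for filtering: {recording.n_samples} < {min_len}"
        )
    out = recording.copy()
    sos_notch = _notch_sos(spec.notch_freq, spec.notch_bw, fs)
    fir = sps.firwin(spec.lp_order + 1, spec.lp_cutoff, fs=fs)
    sos_hp = sps.butter(spec.hp_order, spec.hp_cutoff, btype="highpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos_notch, out.x, axis=1)
    y = sps.filtfilt(fir, [1.0], y, axis=1)
    y = sps.sosfiltfilt(sos_hp, y, axis=1)
    out.x = y
    return out


def detect_peaks_adaptive(
    x: np.ndarray,
    fs: float,
    polarity: int = 1,
    threshold_fraction: float = 0.4,
    n_recent: int = 8,
    half_life_beats: float = 5.0,
    refractory_ms: float = 200.0,
    min_height: float = 0.0,
) -> np.ndarray:
    """Adaptive-threshold peak detector (two-state search/refractory FSM).

    The acceptance threshold is ``threshold_fraction`` times an
    exponentially weighted mean (half-life ``half_life_beats``) of the last
    ``n_recent`` accepted peak amplitudes, so it tracks slow amplitude
    modulation.  A refractory period suppresses double fires; after a long
    silence the threshold decays so the detector re-locks onto an
    attenuated signal.

    Returns strictly increasing sample indices of accepted peaks of the
    requested polarity (+1 for maxima, -1 for minima).
    """
    s = np.asarray(x, dtype=float) * (1 if polarity >= 0 else -1)
    if s.size == 0 or np.ptp(s) == 0:
        return np.array([], dtype=int)
    dist = max(1, int(round(refractory_ms * 1e-3 * fs)))
    cand, _ = sps.find_peaks(s, distance=dist)
    if min_height > 0:
        cand = cand[s[cand] >= min_height]
    if cand.size == 0:
        return np.array([], dtype=int)
    heights = s[cand]

    early = heights[cand < 3 * fs]
    est0 = float(np.quantile(early if early.size else heights, 0.9))
    decay = 0.5 ** (1.0 / half_life_beats)
    recent: deque[float] = deque([est0], maxlen=n_recent)

    def threshold() -> float:
        w = decay ** np.arange(len(recent))
        amps = np.fromiter(recent, dtype=float)  # most recent first
        return threshold_fraction * float(np.dot(w, amps) / w.sum())

    accepted: list[int] = []
    thr = threshold()
    silence_limit = 1.5 * fs  # seconds before the threshold starts decaying
    for idx, h in zip(cand, heights):
        last = accepted[-1] if accepted else cand[0]
        if accepted:
            rr = np.diff(accepted)
            expected = float(np.median(rr)) if rr.size else fs
            silence_limit = max(1.5 * expected, 2 * dist)
        if idx - last > silence_limit and h < thr:
            # lost lock: decay threshold until this candidate is testable
            thr *= 0.5
        if h >= thr:
            accepted.append(int(idx))
            # cap the influence of aberrant (artifact) peaks on the threshold
            cap = 3.0 * thr / threshold_fraction
            recent.appendleft(min(float(h), cap))
            thr = threshold()
    return np.asarray(accepted, dtype=int)


def _clamped_spline(knots: np.ndarray, values: np.ndarray, n: int) -> np.ndarray:
    """Cubic spline through (knots, values), constant beyond the end knots."""
    t = np.arange(n, dtype=float)
    spl = CubicSpline(knots.astype(float), values)
    y = spl(np.clip(t, knots[0], knots[-1]))
    return y


def demodulate(
    x: np.ndarray,
    fs: float,
    gamma_floor: float = 0.05,
    detector_kwargs: dict | None = None,
) -> tuple[np.ndarray, EnvelopePair]:
    """Amplitude demodulation by cubic-spline peak envelopes.

    Positive and negative QRS peaks are located with the adaptive detector,
    cubic splines through them give the envelopes ``gamma_plus`` and
    ``gamma_minus``; their half-difference ``gamma`` is the instantaneous
    modulation and ``sigma = median(gamma)`` restores the amplitude scale:
    output is ``x * sigma / gamma``.  ``gamma`` is floored at
    ``gamma_floor * sigma`` to keep the division bounded where envelopes
    cross.  With fewer than 3 peaks of either polarity the trace is
    returned unchanged (``applied=False``).
    """
    x = np.asarray(x, dtype=float)
    # the envelope must follow QRS peaks only: a 250 ms refractory rejects
    # the T wave (~200 ms after R) while maternal RR stays >= 333 ms
    kw = {"refractory_ms": 250.0, **(detector_kwargs or {})}
    pos = detect_peaks_adaptive(x, fs, polarity=+1, **kw)
    neg = detect_peaks_adaptive(x, fs, polarity=-1, **kw)
    if len(pos) < 3 or len(neg) < 3:
        return x.copy(), EnvelopePair(None, None, None, float("nan"), False)
    n = x.size
    gp = _clamped_spline(pos, x[pos], n)
    gm = _clamped_spline(neg, x[neg], n)
    gamma = (gp - gm) / 2.0
    sigma = float(np.median(gamma))
    if sigma <= 0:
        log.warning("non-positive demodulation scale; trace passed through")
        return x.copy(), EnvelopePair(gp, gm, gamma, sigma, False)
    gamma = np.maximum(gamma, gamma_floor * sigma)
    xhat = x * sigma / gamma
    return xhat, EnvelopePair(gp, gm, gamma, sigma, True)


def preprocess_recording(
    recording: UnipolarRecording,
    spec: FilterSpec | None = None,
    window_ms: float = 50.0,
) -> tuple[UnipolarRecording, list[EnvelopePair]]:
    """Full pre-processing chain: reconstruct -> filter -> demodulate."""
    rec = reconstruct_resets(recording, window_ms=window_ms)
    rec = apply_filters(rec, spec)
    envs: list[EnvelopePair] = []
    for c in range(rec.n_channels):
        xhat, env = demodulate(rec.x[c], rec.fs)
        rec.x[c] = xhat
        envs.append(env)
    return rec, envs
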