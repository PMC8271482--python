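# Methods

`fetalhr` estimates fetal heart rate (fHR) from 4-channel unipolar
abdominal recordings made with dry/textile electrodes, and ships a
synthetic-recording generator that emulates the conditions such hardware
produces. This note documents the models, the tunable constants and their
defaults, the numerical choices, and what the synthetic validation does and
does not establish.

## Signal model and processing chain

An abdominal surface recording mixes the maternal ECG (mECG, the dominant
cardiac component), the fetal ECG (fECG, one to three orders of magnitude
weaker), instrumentation and electromyographic noise, and — specific to
gel-free electrodes — triboelectric charge artifacts, multiplicative
amplitude modulation from motion-induced impedance changes, and broadband
motion transients. The chain is:

1. **Reset reconstruction.** The acquisition hardware snaps a
   near-saturated channel back to mid-scale and logs the event. Digitally,
   the difference between the 50 ms post-reset and pre-reset window means
   is subtracted from everything after the event, making the DC level
   continuous; the slow charge-drift precursor that remains is removed by
   the high-pass stage. The 50 ms window is short enough to exclude the
   neighbouring QRS at any maternal rate ≥ 50 bpm and long enough to
   average noise; it is configurable.
2. **Filtering.** Zero-phase (forward-backward) notch at the mains
   frequency (1 Hz bandwidth), FIR low-pass at 75 Hz (order 200), and
   Butterworth high-pass at 10 Hz (order 6). All stages run
   forward-backward so the QRS shape is not skewed; this doubles the
   effective high-pass order, which we accept in exchange for zero phase.
3. **Amplitude demodulation.** Positive and negative QRS peaks are found
   by an adaptive-threshold detector; cubic splines through the peak
   values give envelopes γ⁺ and γ⁻, Γ = (γ⁺ − γ⁻)/2 is the instantaneous
   modulation, σ = median(Γ) restores scale, and the channel is divided by
   Γ/σ. The envelope detector uses a 250 ms refractory period so that the
   T wave (≈ 200 ms after R) cannot enter the envelope — T-wave knots
   would bias σ low — while maternal RR (≥ 333 ms at 180 bpm) is never
   violated. Γ is floored at 0.05 σ to keep the division bounded where the
   envelopes cross; splines extrapolate as constants beyond the outermost
   peaks. Channels with fewer than 3 peaks of either polarity pass through
   unmodified, flagged.
4. **Bipolar leads.** y₁ = x̂₁ − x̂₄, y₂ = x̂₂ − x̂₄, y₃ = x̂₃ − x̂₄,
   y₄ = x̂₁ − x̂₃. Differencing rejects common-mode pickup. Note y₄ is a
   linear combination of y₁ and y₃, so the lead matrix has rank 3 by
   construction and source separation operates on 3 effective components.
5. **Source separation.** Deflationary FastICA with the kurtosis contrast
   after global PCA whitening (scikit-learn `FastICA(algorithm="deflation",
   fun="cube")`; tolerance 1e-4, 1000 iterations, one seeded restart on
   non-convergence). ICA output is canonicalized — largest-magnitude
   extremum positive, components ordered by descending kurtosis — so that
   fixed seed + fixed input is bit-reproducible; all downstream selection
   logic is additionally designed to be invariant to sign/permutation.
6. **Maternal QRS detection (a posteriori).** Each component is band-passed
   6.3–16 Hz (zero phase), peaks are detected at both polarities, and each
   resulting rate series is scored with

   Q = N_outliers/N + Σ|ΔHR| / ΣHR + |mean(HR) − 85| / 85,

   where outliers lie outside [50, 180] bpm. Components whose mean rate
   leaves that range are discarded outright; the minimum-Q survivor
   supplies the maternal annotation. The third term uses the absolute
   deviation — a signed deviation would reward implausibly low rates. If
   every component is discarded, maternal cancellation is skipped.
7. **Maternal cancellation.** All components are segmented into cardiac
   cycles at the *same* maternal R times (length = median RR forced odd,
   centred, zero-padded at edges) and windowed with a trapezoid
   (20 %–60 %–20 % taper/flat/taper, endpoints exactly zero). Cycles whose
   peak magnitude exceeds 5× the median peak are discarded — motion
   transients would otherwise capture the leading singular vectors and
   starve the maternal template. The remaining cycle matrix is truncated
   to its first Nₑ = 2 singular values (configurable 1–4) and the rebuilt
   cycles are subtracted at their positions; gaps and discarded spans
   remain untouched (straight-line fill of the estimate). W = Z − M holds
   elementwise. An optional mode that also blanks discarded-cycle spans in
   W exists but is off by default: rejections in noise-dominated
   components are themselves noisy, and blanking there punches holes in
   the fetal signal.
8. **Fetal stage.** A second full-trace ICA on W; per component, a
   derivative detector (rectified smoothed derivative, adaptive threshold,
   200 ms refractory = a 300 bpm cap, plus a 3×-median evidence floor that
   rejects smooth drift) proposes beats, and the longest run whose rate
   stays within ±10 bpm of the 5 bpm-binned modal rate becomes that
   component's "good" interval. Intervals synchronous with the maternal
   beats (> 70 % of beats within 50 ms of an mQRS) or with mean rate
   outside [100, 180] bpm are discarded; the longest survivor seeds the
   block stage. If the full-trace search fails entirely, the same
   search runs on 10 s segment-wise ICAs — short windows contain few
   artifact sources, which is the same reasoning the block stage is built
   on — and the best interval found anywhere is used.
9. **Block-wise tracking.** The rest of the trace is processed in 5 s
   blocks on a 10 s / 5 s-overlap segment grid anchored at the optimal
   interval (the grid stays aligned even when the interval touches a
   record edge, so every interior block is fully contained in two
   segments). Per block, ICA runs on each covering segment; every
   component is scanned by a predictive detector: an AR(2) model of the
   recent RR intervals (least-squares init, normalized-LMS adaptation,
   predictions clipped to 0.7–1.4× the trusted interval's median RR)
   predicts the next beat, and the beat is the argmax of the enhanced
   trace under a trapezoid centred on the prediction (full width 50 % of
   the predicted RR, flat central 20 %). Each component is tracked from
   the seam anchor both as-is and re-centred on the component's own
   nearest salient peak (ICA mixtures shift peak phase between segments);
   backward blocks run the identical algorithm on the time-reversed trace.
10. **Block selection.** The candidate minimizing

    score = smoothness + maternal-synchrony + range-penalty
            + salience-deficit + coverage-deficit

    wins. Smoothness is the mean |first| + |second| derivative of the rate
    series in a local ±4 s window around the block (a seam rate-jump must
    not be diluted by a long accepted history), normalized by 85 bpm.
    Salience is the median enhanced-trace amplitude under the tracked
    beats relative to the segment median; without this term a tracker
    free-running on a noise component produces a smooth, plausible and
    entirely fictitious series. Coverage penalizes candidates with far
    fewer beats than the block duration implies. A block whose best
    candidate still shows a salience deficit ≥ 0.75 contributes nothing
    rather than poisoning downstream anchors. After both chains finish,
    poorly scoring blocks are re-estimated with anchors now available on
    both sides (iterated until no block improves; a replacement must score
    strictly better). Finally, seam double-fires are removed and isolated
    missed beats are filled at evidence maxima near the expected position.
11. **Scoring.** A detected beat is correct when strictly within 50 ms of
    a reference beat (greedy nearest one-to-one matching — provably
    optimal when reference spacing exceeds twice the tolerance, and
    cross-checked against an assignment-based matcher in the tests).
    Se = 100·TP/(TP+FN), F1 = 100·2TP/(2TP+FN+FP). RMSE compares the
    reference beat-to-beat rate series with the estimated series linearly
    interpolated at the reference beat times, so missed beats contribute
    the interpolated value; a record with no estimate at all is scored
    against a zero series, the most conservative convention.

Records longer than one minute are processed in non-overlapping one-minute
buffers (a trailing remainder under 30 s joins the previous buffer) and
concatenated.

## Synthetic recordings

The generator emulates a semi-simulated validation design: a dominant
maternal background with a weak fetal ECG added on top, then the
dry-electrode artifact taxonomy.

* **Waveforms.** Gaussian-sum PQRST (one Gaussian per wave on the beat
  phase axis); the fetal complex uses 0.55× wave widths and an independent
  beat clock. Maternal RR jitter is Gaussian with 25 ms sd, fetal 15 ms sd.
  Defaults: maternal 80 bpm, fetal 140 bpm; configurations with equal
  rates are rejected (equal pseudo-periodicities are not separable).
* **Lead geometry.** Fixed per-channel projection gains with ±8 % seeded
  scatter. The maternal source projects with a single sign everywhere
  (distant source); the fetal dipole flips sign across the montage, which
  is what makes the bipolar leads fetal-sensitive.
* **Amplitudes and SNR.** The fetal amplitude is drawn uniformly from
  10–20 µVpp (strongest channel). The noise floor is an instrument
  property — 1/f noise at 2 µV RMS broadband, a realistic figure for
  fabric electrodes with good skin contact — so the fetal-to-background
  power ratio is set by scaling the *maternal* projection; bisection on
  the channel-averaged ratio lands on the target exactly. The cohort draws
  per-record targets from N(−48, 6) dB.
* **Artifacts.** Multiplicative per-channel envelopes
  1 + m·sin(2πf t + φ) with depth up to 0.3 and f = 0.25 Hz; 50 Hz mains
  at 15 % of background RMS; motion bursts (band-limited 0.5–120 Hz,
  0.3–1.5 s, 5–50× the fetal amplitude) at 3 events/min across the
  montage, each hitting a single electrode; and one reset per channel per
  minute — a 0.5–2 s irregular charge drift toward a rail (curved, with a
  low-frequency wobble: a perfectly linear ramp would quantize into a
  narrowband tone no physical electrode produces) snapped back to
  mid-scale with the event logged. 14-bit quantization over a ±8 mV input
  range closes the chain.

Everything derives from one integer seed; identical seed and configuration
give bit-identical recordings and annotations.

### What the synthetic validation does not show

The maternal background is synthetic and spatially rank-1 after
demodulation; real abdominal recordings contain electrohysterogram
activity, position-dependent morphology changes, and maternal ectopy, none
of which are modelled. Fetal rate is stationary around its mean —
accelerations and decelerations are absent, so the block-selection
smoothness term is tested only in its easy regime. Electrode-contact
physics is reduced to its digital consequences (reset log, quantization,
modulation); no volume-conductor or capacitive-circuit modelling is
attempted. Passing the synthetic cohort therefore demonstrates the
signal-processing chain is internally correct and robust to the modelled
artifact classes at the stated SNRs, not clinical performance.

## Failure behaviour

Performance is strongly polarized: a record either tracks almost perfectly
(Se near 100 %, RMSE 1–7 bpm) or fails badly when no fetal-rate interval
survives the selection rules anywhere. In the shipped cohort one record
drawn at −64 dB (2.7 sd below the mean) is unrecoverable: isolating a
source 64 dB below the background would require unmixing-weight precision
beyond what one minute of data can estimate, and every candidate interval
is correctly rejected as maternal or implausible. The pipeline returns a
flagged empty estimate rather than fabricating a series; under the
zero-series RMSE convention such a record contributes ≈ 140 bpm to the
cohort mean, which dominates it (the mean over the remaining 26 records is
≈ 4.4 bpm). This is a deliberate honesty trade-off, not a tuning target.

## Problem sizes

All development and acceptance runs use the full study geometry — 27
one-minute, 4-channel, 1 kHz records — which processes in well under a
minute in total; nothing is scaled down.
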