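import numpy as np
import pytest

from fetalhr.fetal import (
    IntervalCandidate,
    ar_predictive_detect,
    derivative_enhance,
    detect_fqrs_derivative,
    estimate_fhr,
    good_interval,
    plan_blocks,
    score_block_candidate,
    select_optimal_interval,
)
from fetalhr.maternal import QrsAnnotation, hr_series
from fetalhr.metrics import match_beats
from fetalhr.simulate import _gaussian_sum_ecg

FS = 1000.0


def _ann(samples, fs=FS):
    return QrsAnnotation(np.asarray(samples, dtype=int), fs, source="fetal")


def _fetal_trace(bpm=140.0, dur=60.0, seed=0, jitter_ms=10.0):
    rng = np.random.default_rng(seed)
    n = int(dur * FS)
    rr = 60.0 / bpm
    rrs = rr + rng.normal(0, jitter_ms * 1e-3, 200)
    t = np.cumsum(np.concatenate(([0.3], rrs)))
    beats = np.round(t[t < dur - 0.3] * FS).astype(int)
    return _gaussian_sum_ecg(beats, n, FS, width_scale=0.55), beats


class TestDerivativeDetector:
    def test_fetal_rate_trace_detected(self):
        x, beats = _fetal_trace()
        ann = detect_fqrs_derivative(x, FS)
        tp, fp, fn, _ = match_beats(ann, _ann(beats), tol_ms=20.0)
        assert tp >= len(beats) - 2
        assert fp <= 2

    def test_slow_drift_yields_nothing(self):
        t = np.arange(60000) / FS
        drift = np.sin(2 * np.pi * 0.2 * t)
        assert len(detect_fqrs_derivative(drift, FS)) == 0

    def test_amplitude_invariance(self):
        x, _ = _fetal_trace(seed=1)
        a = detect_fqrs_derivative(x, FS)
        b = detect_fqrs_derivative(0.5 * x, FS)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_flat_trace_empty(self):
        assert len(detect_fqrs_derivative(np.zeros(10000), FS)) == 0


class TestGoodInterval:
    def _beats_from_rates(self, bpm_list):
        rr = 60.0 * FS / np.asarray(bpm_list, dtype=float)
        return np.round(np.cumsum(np.concatenate(([500.0], rr)))).astype(int)

    def test_constant_series_spans_everything(self):
        beats = self._beats_from_rates([140.0] * 30)
        gi = good_interval(_ann(beats), int(beats[-1] + 1000))
        assert len(gi.fqrs) == len(beats)

    def test_rate_change_isolates_majority_run(self):
        beats = self._beats_from_rates([140.0] * 40 + [70.0] * 10)
        gi = good_interval(_ann(beats), int(beats[-1] + 1000))
        assert 39 <= len(gi.fqrs) <= 42
        assert gi.fhr.mean() == pytest.approx(140.0, abs=2.0)

    def test_alternating_rates_degenerate(self):
        beats = self._beats_from_rates([100.0, 180.0] * 15)
        gi = good_interval(_ann(beats), int(beats[-1] + 1000))
        assert len(gi.fqrs) <= 3

    def test_too_few_beats(self):
        gi = good_interval(_ann([100, 600]), 5000)
        assert gi.length == 0


class TestSelectOptimalInterval:
    def _cand(self, idx, start, end, bpm, n_beats):
        rr = 60.0 * FS / bpm
        beats = np.round(start + np.arange(n_beats) * rr).astype(int)
        return IntervalCandidate(idx, start, end, _ann(beats), np.full(n_beats - 1, bpm))

    def test_fetal_candidate_beats_maternal_copies(self):
        mqrs = _ann(np.arange(500, 59000, 750))
        fetal = self._cand(2, 10000, 20000, 140.0, 24)
        maternal = self._cand(0, 5000, 45000, 80.0, 50)
        maternal.fqrs = QrsAnnotation(mqrs.samples[10:60].copy(), FS, source="fetal")
        maternal.fhr = np.full(49, 80.0)
        maternal.start, maternal.end = int(mqrs.samples[10]), int(mqrs.samples[59])
        best = select_optimal_interval([maternal, fetal], mqrs, FS)
        assert best is not None and best.component_index == 2

    def test_all_out_of_range_discarded(self):
        mqrs = _ann(np.arange(500, 59000, 750))
        cands = [self._cand(i, 1000, 30000, 80.0, 30) for i in range(4)]
        for c in cands:
            c.fqrs = _ann(c.fqrs.samples + 137 * (1 + c.component_index))
        assert select_optimal_interval(cands, mqrs, FS) is None

    def test_longest_survivor_wins(self):
        mqrs = _ann(np.arange(500, 59000, 750))
        short = self._cand(0, 10000, 30000, 140.0, 20)
        long = self._cand(1, 5000, 35000, 150.0, 30)
        best = select_optimal_interval([short, long], mqrs, FS)
        assert best.component_index == 1


class TestBlockPlan:
    def test_forward_segment_grid(self):
        plan = plan_blocks((25000, 35000), 60000, FS)
        starts = sorted(s[0] for s in plan.forward_segments)
        assert starts == [30000, 35000, 40000, 45000, 50000]

    def test_whole_trace_interval_no_blocks(self):
        plan = plan_blocks((0, 60000), 60000, FS)
        assert plan.blocks == []

    def test_block_coverage_complete(self):
        plan = plan_blocks((25000, 35000), 60000, FS)
        covered = np.zeros(60000, bool)
        covered[25000:35000] = True
        for b in plan.blocks:
            covered[b.start : b.end] = True
        assert covered.all()

    def test_interior_blocks_have_two_segments(self):
        plan = plan_blocks((25000, 35000), 60000, FS)
        interior = [b for b in plan.blocks if 5000 < b.start and b.end < 55000]
        assert interior and all(len(b.segments) == 2 for b in interior)


class TestPredictiveDetector:
    def test_periodic_trace_tracked_precisely(self):
        x, beats = _fetal_trace(jitter_ms=0.0, seed=2)
        env = derivative_enhance(x, FS)
        start = 5
        found = ar_predictive_detect(
            env, FS, float(beats[start]), np.diff(beats[:start + 1]).astype(float),
            stop=beats[-1] + 100,
        )
        found = np.asarray(found)
        errs = []
        for b in beats[start + 1 :]:
            d = np.abs(found - b).min()
            errs.append(d)
        assert np.median(errs) < 5.0

    def test_relocks_after_gap(self):
        x, beats = _fetal_trace(jitter_ms=5.0, seed=3)
        x[20000:22000] = 0.0  # 2 s dropout
        env = derivative_enhance(x, FS)
        found = np.asarray(
            ar_predictive_detect(
                env, FS, float(beats[5]), np.diff(beats[:6]).astype(float),
                stop=beats[-1] + 100,
            )
        )
        after = beats[beats > 23500]
        hits = sum(np.abs(found - b).min() < 50 for b in after[3:])
        assert hits >= len(after) - 6

    def test_backward_equals_reversed_forward_on_symmetric_trace(self):
        x, beats = _fetal_trace(jitter_ms=0.0, seed=4)
        n = x.size
        xs = x + x[::-1]  # time-symmetric by construction
        env = derivative_enhance(xs, FS)
        fwd = ar_predictive_detect(
            env, FS, 1000.0, np.array([430.0, 430.0]), stop=n // 2
        )
        bwd = ar_predictive_detect(
            env[::-1], FS, 1000.0, np.array([430.0, 430.0]), stop=n // 2
        )
        np.testing.assert_allclose(fwd[:5], bwd[:5], atol=2)


class TestBlockScore:
    def test_ideal_candidate_scores_zero(self):
        fhr_all = np.full(30, 140.0)
        beats = np.arange(1000, 5000, 430)
        sc, terms = score_block_candidate(
            fhr_all, np.full(9, 140.0), beats, _ann([]), FS
        )
        assert sc == pytest.approx(0.0, abs=1e-9)

    def test_maternal_copy_scores_worse_than_fetal(self):
        mqrs = _ann(np.arange(500, 59000, 750))
        fhr_all = np.full(30, 140.0)
        fetal_beats = np.arange(10137, 15000, 430)
        maternal_beats = mqrs.samples[14:20]
        s_f, _ = score_block_candidate(fhr_all, np.full(10, 140.0), fetal_beats, mqrs, FS)
        s_m, _ = score_block_candidate(fhr_all, np.full(10, 140.0), maternal_beats, mqrs, FS)
        assert s_f < s_m

    def test_out_of_range_mean_penalized(self):
        fhr_all = np.full(30, 140.0)
        beats = np.arange(1000, 5000, 316)
        sc, terms = score_block_candidate(
            fhr_all, np.full(9, 190.0), beats, _ann([]), FS
        )
        assert terms[2] == pytest.approx(10.0 / 85.0, abs=1e-9)

    def test_empty_candidate_infinite(self):
        sc, _ = score_block_candidate(
            np.full(10, 140.0), np.array([]), np.array([]), _ann([]), FS
        )
        assert np.isinf(sc)

    def test_salience_deficit_raises_score(self):
        fhr_all = np.full(30, 140.0)
        beats = np.arange(1000, 5000, 430)
        lo, _ = score_block_candidate(fhr_all, np.full(9, 140.0), beats, _ann([]), FS, salience=5.0)
        hi, _ = score_block_candidate(fhr_all, np.full(9, 140.0), beats, _ann([]), FS, salience=1.0)
        assert hi > lo


class TestEstimateFhr:
    def test_clean_record_high_sensitivity(self, separated_clean):
        rec, truth, cm, mqrs, em = separated_clean
        est = estimate_fhr(em.W, mqrs, rec.fs, seed=11)
        assert not est.empty
        tp, fp, fn, _ = match_beats(est.fqrs, truth.fqrs)
        assert 100.0 * tp / (tp + fn) >= 99.0

    def test_pure_noise_flagged_empty(self):
        rng = np.random.default_rng(5)
        W = rng.standard_normal((4, 60000))
        est = estimate_fhr(W, _ann(np.arange(500, 59000, 750)), FS, seed=0)
        assert est.empty
        assert est.flags

    def test_assembled_beats_respect_refractory(self, separated_clean):
        rec, truth, cm, mqrs, em = separated_clean
        est = estimate_fhr(em.W, mqrs, rec.fs, seed=11)
        assert np.all(np.diff(est.fqrs.samples) > 0.2 * rec.fs)
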