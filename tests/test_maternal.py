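import numpy as np
import pytest

from fetalhr.bss import ComponentMatrix, fast_ica
from fetalhr.maternal import (
    QrsAnnotation,
    build_cycle_matrix,
    cancel_mecg,
    detect_mqrs,
    hr_series,
    quality_index,
    reject_artifact_cycles,
)
from fetalhr.metrics import match_beats
from fetalhr.simulate import _gaussian_sum_ecg

FS = 1000.0


def _ann(samples, fs=FS):
    return QrsAnnotation(np.asarray(samples, dtype=int), fs)


def _hr(bpm_values):
    """HrSeries with exactly the given rate values (Eq-level arithmetic)."""
    from fetalhr.maternal import HrSeries

    bpm = np.asarray(bpm_values, dtype=float)
    times = np.cumsum(np.concatenate(([0.0], 60.0 / bpm)))
    return HrSeries(bpm=bpm, beat_times=(times[:-1] + times[1:]) / 2,
                    n_beats=bpm.size + 1)


class TestHrSeries:
    @pytest.mark.parametrize(
        "samples,expected",
        [
            ([0, 1000, 2000], [60.0, 60.0]),
            ([0, 500, 1500], [120.0, 60.0]),
            ([0, 400, 800, 1200], [150.0, 150.0, 150.0]),
        ],
    )
    def test_rate_arithmetic(self, samples, expected):
        np.testing.assert_allclose(_ann(samples=samples) and hr_series(_ann(samples)).bpm, expected)

    def test_too_few_peaks(self):
        with pytest.raises(ValueError):
            hr_series(_ann([100]))

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            _ann([100, 50])


class TestQualityIndex:
    def test_ideal_series_scores_zero(self):
        q = quality_index(_hr([85.0] * 10))
        assert q.q == pytest.approx(0.0, abs=1e-9)

    def test_constant_170(self):
        q = quality_index(_hr([170.0] * 10))
        assert q.q == pytest.approx(1.0, abs=1e-3)
        assert q.n_outliers == 0

    def test_hand_computed_mixed_series(self):
        q = quality_index(_hr([85.0, 85.0, 170.0]))
        assert q.variability_term == pytest.approx(0.25, abs=1e-3)
        assert q.discrepancy_term == pytest.approx(1 / 3, abs=1e-3)
        assert q.q == pytest.approx(0.5833, abs=2e-3)

    def test_outliers_counted(self):
        q = quality_index(_hr([85.0, 40.0, 85.0, 190.0]))
        assert q.n_outliers == 2

    def test_added_variability_never_decreases_q(self):
        base = quality_index(_hr([120.0] * 12)).q
        for noisy in ([120.0] * 6 + [150.0] + [120.0] * 5, [120.0, 140.0] * 6):
            assert quality_index(_hr(noisy)).q >= base


def _component_matrix(rows):
    Z = np.vstack(rows)
    Z = (Z - Z.mean(axis=1, keepdims=True)) / Z.std(axis=1, keepdims=True)
    return ComponentMatrix(Z=Z, mixing=np.eye(len(rows)), converged=np.ones(len(rows), bool))


class TestDetectMqrs:
    def test_selects_clean_ecg_component(self):
        rng = np.random.default_rng(0)
        n = 60000
        beats = np.arange(400, n - 400, 750)  # 80 bpm
        ecg = _gaussian_sum_ecg(beats, n, FS)
        rows = [rng.standard_normal(n) * 0.05, 5 * ecg + 0.05 * rng.standard_normal(n),
                rng.standard_normal(n) * 0.05]
        cm = _component_matrix(rows)
        ann, scores = detect_mqrs(cm, FS)
        assert ann.component_index == 1
        hr = hr_series(ann)
        assert hr.bpm.mean() == pytest.approx(80.0, abs=1.0)
        tp, fp, fn, _ = match_beats(ann, _ann(beats))
        assert tp >= len(beats) - 2 and fp <= 2

    def test_all_noise_components_discarded(self):
        rng = np.random.default_rng(7)
        cm = _component_matrix([rng.standard_normal(60000) for _ in range(4)])
        ann, scores = detect_mqrs(cm, FS)
        assert len(ann) == 0

    def test_steadier_component_wins(self):
        n = 60000
        steady = np.arange(400, n - 400, int(60 / 85 * FS))  # 85 bpm, zero jitter
        rng = np.random.default_rng(1)
        jittered = np.cumsum(
            np.concatenate(([500], 420 + rng.integers(-60, 60, 100)))
        )
        jittered = jittered[jittered < n - 400]
        rows = [_gaussian_sum_ecg(jittered, n, FS), _gaussian_sum_ecg(steady, n, FS)]
        ann, scores = detect_mqrs(_component_matrix(rows), FS)
        assert ann.component_index == 1
        assert scores[1].q < scores[0].q


class TestCycleMatrix:
    def test_odd_segment_length_from_median_rr(self):
        beats = np.arange(1000, 50000, 800)
        cm = build_cycle_matrix(np.random.default_rng(0).standard_normal(50000), _ann(beats), FS)
        assert cm.n_d == 801
        assert cm.n_q == len(beats)

    def test_edge_cycle_zero_padded(self):
        z = np.ones(5000)
        beats = [10, 1000, 2000, 3000]
        cm = build_cycle_matrix(z, _ann(beats), FS)
        half = cm.n_d // 2
        col = cm.K[:, 0]
        assert np.all(col[: half - 10] == 0.0)

    def test_window_tapers_to_zero(self):
        beats = np.arange(500, 20000, 700)
        cm = build_cycle_matrix(np.ones(20000), _ann(beats), FS)
        assert cm.window[0] == 0.0 and cm.window[-1] == 0.0
        assert cm.window.max() == 1.0

    def test_too_few_beats_rejected(self):
        with pytest.raises(ValueError):
            build_cycle_matrix(np.ones(5000), _ann([100, 900, 1700]), FS)


class TestArtifactRejection:
    def _matrix_with_maxima(self, maxima):
        nd = 11
        K = np.zeros((nd, len(maxima)))
        K[5] = maxima
        beats = np.arange(len(maxima)) * 800 + 500
        from fetalhr.maternal import CycleMatrix

        return CycleMatrix(K=K, centers=beats, window=np.ones(nd))

    def test_five_times_median_rule(self):
        cm = reject_artifact_cycles(self._matrix_with_maxima([10, 10, 10, 10, 100.0]))
        assert cm.n_rejected == 1
        assert not cm.kept_mask[-1]

    def test_equal_maxima_all_kept(self):
        cm = reject_artifact_cycles(self._matrix_with_maxima([7.0] * 6))
        assert cm.n_rejected == 0

    def test_boundary_value_kept(self):
        cm = reject_artifact_cycles(self._matrix_with_maxima([1, 1, 1, 1, 4.9]))
        assert cm.n_rejected == 0


class TestCancelMecg:
    def test_periodic_template_removed(self):
        n = 60000
        beats = np.arange(400, n - 400, 750)
        ecg = _gaussian_sum_ecg(beats, n, FS)
        cm = ComponentMatrix(
            Z=ecg[None, :].copy(), mixing=np.eye(1), converged=np.ones(1, bool)
        )
        est = cancel_mecg(cm, _ann(beats), FS, n_keep=1)
        # straight-line gaps keep a little inter-beat energy; compare in
        # the beat neighbourhoods where the template lives
        sel = np.zeros(n, bool)
        for b in beats:
            sel[b - 100 : b + 100] = True
        assert np.sqrt((est.W[0][sel] ** 2).mean()) < 0.05 * np.sqrt((ecg[sel] ** 2).mean())

    def test_empty_annotation_passthrough(self):
        Z = np.random.default_rng(0).standard_normal((2, 5000))
        cm = ComponentMatrix(Z=Z.copy(), mixing=np.eye(2), converged=np.ones(2, bool))
        est = cancel_mecg(cm, _ann([]), FS)
        assert est.skipped
        np.testing.assert_array_equal(est.W, Z)

    def test_conservation(self, separated_clean):
        _, _, cm, mqrs, em = separated_clean
        np.testing.assert_allclose(cm.Z, em.M + em.W, atol=1e-9)

    def test_robust_to_injected_artifact_cycle(self):
        n = 60000
        beats = np.arange(400, n - 400, 750)
        ecg = _gaussian_sum_ecg(beats, n, FS)
        dirty = ecg.copy()
        dirty[30000:30400] += 30.0  # one huge artifact
        def template(z, reject):
            cm = ComponentMatrix(
                Z=z[None, :].copy(), mixing=np.eye(1), converged=np.ones(1, bool)
            )
            est = cancel_mecg(cm, _ann(beats), FS, n_keep=1, reject=reject)
            return est.M[0]

        clean_t = template(ecg, True)
        dirty_t = template(dirty, True)
        sel = np.abs(clean_t) > 1e-6
        sel[29000:31500] = False
        rel = np.abs(dirty_t[sel] - clean_t[sel]).mean() / np.abs(clean_t[sel]).mean()
        assert rel < 0.02
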