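"""DTW/DBA oracles and the six detectors' decision rules."""

import numpy as np
import pytest

from mrcpbench.detect import (
    DETECTORS,
    DetectorModel,
    _dtw_cost,
    best_threshold,
    dba_template,
    dtw_distance,
    fit_detector,
    medoid_index,
    predict,
    predict_batch,
)
from mrcpbench.preprocess import MRCP, NON_MRCP, Epoch
from tests.conftest import make_single_channel_epochs


def brute_force_dtw(a, b, w):
    """Exhaustive enumeration of all monotone warping paths inside the band."""
    n, m = len(a), len(b)
    best = [np.inf]

    def walk(i, j, cost):
        cost += (a[i] - b[j]) ** 2
        if cost >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cost
            return
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            ii, jj = i + di, j + dj
            if ii < n and jj < m and abs(ii - jj) <= w:
                walk(ii, jj, cost)

    walk(0, 0, 0.0)
    return np.sqrt(best[0])


class TestDtwDistance:
    def test_identity_is_zero(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.standard_normal(20)
            assert dtw_distance(x, x, 0.1) == 0.0

    def test_perfect_warp_hand_example(self):
        a = np.array([0.0, 0.0, 1.0, 0.0])
        b = np.array([0.0, 1.0, 0.0, 0.0])
        assert dtw_distance(a, b, r=1.0) == 0.0

    def test_matches_exhaustive_path_enumeration(self):
        rng = np.random.default_rng(1)
        cases = [(n, r) for n in (4, 6, 8) for r in (0.2, 0.5, 1.0)]
        cases += [(12, 0.2), (12, 0.5)]  # narrow bands keep enumeration tractable
        for n, r in cases:
            a = rng.standard_normal(n)
            b = rng.standard_normal(n)
            w = int(np.ceil(r * n))
            assert dtw_distance(a, b, r) == pytest.approx(
                brute_force_dtw(a, b, w), abs=1e-8
            )

    def test_never_exceeds_euclidean_with_full_band(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            a = rng.standard_normal(16)
            b = rng.standard_normal(16)
            assert dtw_distance(a, b, r=1.0) <= np.linalg.norm(a - b) + 1e-12

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.standard_normal(15)
            b = rng.standard_normal(15)
            assert dtw_distance(a, b, 0.1) == pytest.approx(
                dtw_distance(b, a, 0.1), abs=1e-12
            )

    def test_zero_band_equals_euclidean(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal(10)
        b = rng.standard_normal(10)
        assert np.sqrt(_dtw_cost(a, b, 0)) == pytest.approx(
            np.linalg.norm(a - b), abs=1e-12
        )

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal-length"):
            dtw_distance(np.zeros(5), np.zeros(6))


class TestDba:
    def test_identical_inputs_fixed_point(self):
        s = np.sin(np.linspace(0, 5, 40))
        template = dba_template(np.tile(s, (4, 1)))
        assert np.allclose(template, s, atol=1e-12)

    def test_objective_is_nonincreasing(self):
        rng = np.random.default_rng(0)
        base = np.exp(-((np.arange(50) - 25.0) ** 2) / 20)
        series = np.stack([np.roll(base, k) + 0.1 * rng.standard_normal(50)
                           for k in (-3, -1, 0, 2, 4)])
        _, history = dba_template(series, return_history=True)
        assert all(b <= a + 1e-10 for a, b in zip(history, history[1:]))

    def test_medoid_matches_exhaustive_pairwise_matrix(self):
        rng = np.random.default_rng(1)
        series = rng.standard_normal((6, 30))
        idx = medoid_index(series)
        w = int(np.ceil(0.1 * 30))
        sums = [
            sum(np.sqrt(_dtw_cost(series[i], series[j], w)) for j in range(6))
            for i in range(6)
        ]
        assert idx == int(np.argmin(sums))

    def test_beats_arithmetic_mean_on_shifted_pulses(self):
        base = np.zeros(60)
        base[25:30] = 1.0
        series = np.stack([np.roll(base, 2), np.roll(base, -2)])
        w = int(np.ceil(0.1 * 60))
        dba = dba_template(series)
        mean = series.mean(axis=0)
        cost = lambda t: sum(np.sqrt(_dtw_cost(t, s, w)) for s in series)
        assert cost(dba) <= cost(mean) + 1e-12


class TestThreshold:
    def test_three_point_sweep(self):
        thr, f1 = best_threshold(np.array([1.0, 2.0, 3.0]), np.array([0, 1, 1]))
        assert 1.0 < thr <= 2.0
        assert f1 == 1.0

    def test_matches_exhaustive_sweep(self):
        from sklearn.metrics import f1_score as sk_f1

        rng = np.random.default_rng(2)
        for _ in range(20):
            stats = rng.standard_normal(30).round(1)  # force ties
            y = rng.integers(0, 2, 30)
            if y.sum() in (0, 30):
                continue
            _, f1 = best_threshold(stats, y)
            candidates = np.concatenate([stats - 1e-9, stats + 1e-9])
            oracle = max(
                sk_f1(y, (stats >= c).astype(int), zero_division=0)
                for c in candidates
            )
            assert f1 == pytest.approx(oracle, abs=1e-8)


def _epoch(vec, label):
    return Epoch(data=np.asarray(vec, float)[None, :], label=label, fs=32.0,
                 channel_names=["X"])


class TestDetectors:
    @pytest.mark.parametrize("kind", DETECTORS)
    def test_separable_toy_reaches_perfect_test_f1(self, kind):
        train = make_single_channel_epochs(n_per_class=8, sep=4.0, noise=0.2, seed=3)
        test = make_single_channel_epochs(n_per_class=6, sep=4.0, noise=0.2, seed=4)
        model = fit_detector(kind, train, seed=0)
        pred = predict_batch(model, test)
        truth = np.array([1 if e.label == MRCP else 0 for e in test])
        assert np.array_equal(pred, truth)

    def test_lda_zero_training_error_on_separable_data(self):
        train = make_single_channel_epochs(n_per_class=10, sep=5.0, noise=0.2, seed=5)
        model = fit_detector("LDA", train, seed=0)
        pred = predict_batch(model, train)
        truth = np.array([1 if e.label == MRCP else 0 for e in train])
        assert np.array_equal(pred, truth)

    def test_nn_single_class_training_rejected(self):
        eps = [_epoch(np.arange(8.0), MRCP) for _ in range(4)]
        with pytest.raises(ValueError, match="per class"):
            fit_detector("NN_ED", eps)

    def test_nn_tie_goes_to_lowest_training_index(self):
        x = np.linspace(0, 1, 8)
        train = [_epoch(x + 1, MRCP), _epoch(x - 1, NON_MRCP),
                 _epoch(x + 1, MRCP), _epoch(x - 1, NON_MRCP)]
        for kind in ("NN_ED", "NN_DTW"):
            model = fit_detector(kind, train)
            # probe equidistant from the MRCP (index 0) and non-MRCP (index 1) epochs
            assert predict(model, _epoch(x, MRCP)) == MRCP

    def test_mf_statistic_at_threshold_is_mrcp(self):
        template = np.ones(8)
        model = DetectorModel(kind="MF", n_features=8, template=template)
        x = np.linspace(-1, 1, 8)
        stat = float(np.convolve(x, template[::-1], mode="same").max())
        model.threshold = stat
        assert predict(model, _epoch(x, NON_MRCP)) == MRCP
        model.threshold = stat + 1e-9
        assert predict(model, _epoch(x, NON_MRCP)) == NON_MRCP

    def test_length_mismatch_rejected(self):
        train = make_single_channel_epochs(n_per_class=4, seed=6)
        model = fit_detector("NN_ED", train)
        with pytest.raises(ValueError, match="length"):
            predict(model, _epoch(np.zeros(10), MRCP))

    def test_mf_threshold_calibration_on_training_set(self):
        train = make_single_channel_epochs(n_per_class=8, sep=4.0, noise=0.2, seed=7)
        model = fit_detector("MF", train)
        assert model.fit_metadata["train_f1"] == 1.0
        assert model.template.shape == (64,)

    def test_tm_template_length_matches_epochs(self):
        train = make_single_channel_epochs(n_per_class=5, sep=3.0, noise=0.3, seed=8)
        model = fit_detector("TM", train)
        assert model.template.shape == (64,)
        assert model.dtw_band_r == 0.10
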