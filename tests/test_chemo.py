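"""PLS core, splits, screening, discriminant rule and metrics."""

import json

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

import shikispec
from shikispec import chemo


@pytest.fixture(scope="module")
def printed_model():
    return shikispec.printed_equation_model()


class TestFitPLSR:
    def test_constant_response_gives_flat_model(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 5))
        y = np.full(20, 7.5)
        with pytest.warns(UserWarning):
            m = chemo.fit_plsr(X, y, 2)
        np.testing.assert_allclose(m.coefficients, 0.0, atol=1e-12)
        assert m.intercept == pytest.approx(7.5)

    def test_full_rank_equals_least_squares(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            X = rng.normal(size=(20, 5))
            y = rng.normal(size=20)
            m = chemo.fit_plsr(X, y, 5)
            A = np.column_stack([np.ones(20), X])
            beta = np.linalg.lstsq(A, y, rcond=None)[0]
            np.testing.assert_allclose(m.coefficients, beta[1:], atol=1e-8)
            assert m.intercept == pytest.approx(beta[0], abs=1e-8)

    def test_single_predictor_slope_is_cov_over_var(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        y = 2.0 * x + rng.normal(0, 0.1, 30)
        m = chemo.fit_plsr(x[:, None], y, 1)
        expected = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert m.coefficients[0] == pytest.approx(expected, rel=1e-10)

    def test_matches_sklearn_nipals(self):
        """Independent cross-check against scikit-learn's PLS implementation."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 12))
        y = rng.normal(size=40)
        for n_lv in (1, 3, 6):
            mine = chemo.fit_plsr(X, y, n_lv)
            ref = PLSRegression(n_components=n_lv, scale=False).fit(X, y)
            np.testing.assert_allclose(mine.coefficients, ref.coef_.ravel(), atol=1e-8)

    def test_scores_route_equals_coefficient_route(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 8))
        y = rng.normal(size=30)
        for scale in (False, True):
            m = chemo.fit_plsr(X, y, 4, scale=scale)
            Xnew = rng.normal(size=(10, 8))
            np.testing.assert_allclose(
                chemo.predict(m, Xnew), chemo.predict_by_scores(m, Xnew), atol=1e-10
            )


class TestPredictPrintedEquation:
    def test_zero_reflectance_returns_printed_intercept(self, printed_model):
        out = chemo.predict(printed_model, np.zeros(11))
        assert out[0] == -1126.19

    def test_unit_reflectance_matches_manual_summation(self, printed_model):
        expected = sum(printed_model.coefficients) + printed_model.intercept
        out = chemo.predict(printed_model, np.ones(11))
        assert out[0] == pytest.approx(expected, abs=1e-12)

    def test_feature_count_mismatch_names_features(self, printed_model):
        with pytest.raises(ValueError, match="704"):
            chemo.predict(printed_model, np.zeros(5))

    def test_prediction_at_calibration_mean_is_mean_response(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(25, 6))
        y = rng.normal(size=25)
        m = chemo.fit_plsr(X, y, 3)
        out = chemo.predict(m, X.mean(axis=0))
        assert out[0] == pytest.approx(y.mean(), abs=1e-10)


class TestSelectLV:
    def test_exact_rank_two_structure_found(self):
        rng = np.random.default_rng(6)
        T = rng.normal(size=(40, 2))
        P = rng.normal(size=(2, 10))
        X = T @ P
        y = T @ np.array([1.5, -2.0])
        n_lv, rmsecv = chemo.select_lv_loocv(X, y, 6)
        assert n_lv == 2
        assert rmsecv[1] < 1e-8

    def test_pure_noise_prefers_few_lvs(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(30, 15))
            y = rng.normal(size=30)
            n_lv, _ = chemo.select_lv_loocv(X, y, 8)
            wins += n_lv <= 3
        assert wins >= 18

    def test_three_samples_single_lv(self):
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array([0.0, 1.0, 2.1])
        n_lv, _ = chemo.select_lv_loocv(X, y, 1)
        assert n_lv == 1


class TestDetectOutliers:
    def test_clean_data_rarely_flagged(self):
        flags = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(60, 8))
            y = X @ rng.normal(size=8) + rng.normal(0, 0.5, 60)
            flags += chemo.detect_outliers(X, y, 4).size > 0
        assert flags <= 2

    def test_injected_shift_is_flagged(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 8))
        y = X @ rng.normal(size=8) + rng.normal(0, 0.5, 60)
        y2 = y.copy()
        y2[13] += 10 * y.std()
        assert 13 in chemo.detect_outliers(X, y2, 4)

    def test_infinite_cutoff_flags_nothing(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(20, 4))
        y = rng.normal(size=20)
        assert chemo.detect_outliers(X, y, 2, k_sd=np.inf).size == 0


class TestSPXY:
    def test_study_scale_counts(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(216, 20))
        y = rng.normal(size=216)
        split = chemo.spxy_split(X, y, 2.0 / 3.0)
        assert split.calibration_indices.size == 144
        assert split.prediction_indices.size == 72

    def test_per_day_scale_counts(self):
        rng = np.random.default_rng(10)
        split = chemo.spxy_split(rng.normal(size=(60, 8)), rng.normal(size=60), 0.75)
        assert split.calibration_indices.size == 45
        assert split.prediction_indices.size == 15

    def test_collinear_extremes_enter_calibration(self):
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array([0.0, 1.0, 2.0])
        split = chemo.spxy_split(X, y, 2.0 / 3.0)
        assert split.calibration_indices.tolist() == [0, 2]
        assert split.prediction_indices.tolist() == [1]

    def test_matches_bruteforce_maxmin_oracle(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(12, 3))
        y = rng.normal(size=12)
        split = chemo.spxy_split(X, y, 0.5)
        # independent greedy max-min on the joint distance
        from scipy.spatial.distance import cdist

        dx = cdist(X, X)
        dy = np.abs(y[:, None] - y[None, :])
        d = dx / dx.max() + dy / dy.max()
        i, j = np.unravel_index(np.argmax(d), d.shape)
        chosen = [min(i, j), max(i, j)]
        while len(chosen) < 6:
            rest = [k for k in range(12) if k not in chosen]
            k_best = max(rest, key=lambda k: (min(d[k][c] for c in chosen), -k))
            chosen.append(k_best)
        assert sorted(chosen) == split.calibration_indices.tolist()

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        split = chemo.spxy_split(X, y, 0.6)
        perm = rng.permutation(30)
        split_p = chemo.spxy_split(X[perm], y[perm], 0.6)
        orig_from_perm = np.sort(perm[split_p.calibration_indices])
        np.testing.assert_array_equal(orig_from_perm, split.calibration_indices)

    def test_near_unity_fraction_leaves_one_out(self):
        rng = np.random.default_rng(13)
        split = chemo.spxy_split(rng.normal(size=(10, 2)), rng.normal(size=10), 0.95)
        assert split.prediction_indices.size == 1

    def test_identical_samples_warn_but_split(self):
        X = np.ones((6, 3))
        y = np.ones(6)
        with pytest.warns(UserWarning):
            split = chemo.spxy_split(X, y, 0.5)
        assert split.calibration_indices.size == 3


class TestPLSDA:
    @staticmethod
    def clusters(seed, n=60, sep=6.0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 5))
        labels = np.where(np.arange(n) < n // 2, 1, 2)
        X[labels == 2, 0] += sep
        return X, labels

    def test_separated_clusters_classified_perfectly(self):
        X, labels = self.clusters(0)
        m = chemo.fit_plsda(X, labels, 2)
        pred, valid = chemo.classify_plsda(m, X)
        assert chemo.accuracy(labels, pred) == 1.0
        assert valid.all()

    def test_permuted_labels_near_chance(self):
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            X = rng.normal(size=(60, 5))
            labels = rng.permutation(np.repeat([1, 2], 30))
            train, test = np.arange(40), np.arange(40, 60)
            m = chemo.fit_plsda(X[train], labels[train], 2)
            pred, _ = chemo.classify_plsda(m, X[test])
            accs.append(chemo.accuracy(labels[test], pred))
        assert 0.35 <= np.mean(accs) <= 0.65

    def test_duplicate_row_same_value(self):
        X, labels = self.clusters(3)
        m = chemo.fit_plsda(X, labels, 2)
        twice = np.vstack([X[4], X[4]])
        out = chemo.predict(m, twice)
        assert out[0] == out[1]

    def test_single_class_rejected(self):
        X = np.random.default_rng(4).normal(size=(10, 3))
        with pytest.raises(ValueError):
            chemo.fit_plsda(X, np.ones(10, dtype=int), 1)

    def test_decision_rule_boundaries(self):
        # a discriminant model with unit coefficient: prediction equals input
        m = chemo.PLSModel(
            n_lv=1,
            x_mean=np.zeros(1),
            y_mean=0.0,
            x_scale=None,
            weights=np.ones((1, 1)),
            x_loadings=np.ones((1, 1)),
            y_loadings=np.ones(1),
            coefficients=np.ones(1),
            intercept=0.0,
            mode="discriminant",
        )
        pred, valid = chemo.classify_plsda(m, np.array([[1.4], [1.5], [2.6], [0.4]]))
        assert pred.tolist() == [1, 1, 0, 0]
        assert valid.tolist() == [True, True, False, False]


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        r2, rmse = chemo.regression_metrics(y, y)
        assert (r2, rmse) == (1.0, 0.0)
        assert chemo.accuracy(np.array([1, 2]), np.array([1, 2])) == 1.0

    def test_mean_prediction_scores_zero(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        r2, _ = chemo.regression_metrics(y, np.full(4, y.mean()))
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_four_point_hand_example(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        yhat = np.array([1.1, 1.9, 3.2, 3.7])
        ss_res = 0.01 + 0.01 + 0.04 + 0.09
        ss_tot = (1.5**2 + 0.5**2) * 2
        r2, rmse = chemo.regression_metrics(y, yhat)
        assert r2 == pytest.approx(1 - ss_res / ss_tot, abs=1e-12)
        assert rmse == pytest.approx(np.sqrt(ss_res / 4), abs=1e-12)


class TestSerialization:
    def test_model_json_roundtrip(self, tmp_path):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(25, 6))
        y = rng.normal(size=25)
        m = chemo.fit_plsr(X, y, 3, feature_names=[f"b{i}" for i in range(6)])
        path = tmp_path / "model.json"
        chemo.save_model(m, path)
        back = chemo.load_model(path)
        np.testing.assert_allclose(back.coefficients, m.coefficients)
        np.testing.assert_allclose(
            chemo.predict(back, X), chemo.predict(m, X), atol=1e-12
        )
        assert back.feature_names == m.feature_names

    def test_printed_fixture_metadata_records_band_assumption(self, printed_model):
        assert "534" in json.dumps(printed_model.metadata)
        assert printed_model.feature_names.index("534") == 1
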