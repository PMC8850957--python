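import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pymbms as pm
from pymbms.errors import (
    DegenerateResponseError,
    InconsistentNormalizationError,
    InvalidFoldsError,
    RankDeficientError,
)


def _exact_linear_toy(n=12, slope=3.0, channel=100, seed=0):
    """y depends on exactly one channel, no noise."""
    rng = np.random.default_rng(seed)
    X = np.zeros((n, pm.N_CHANNELS))
    X[:, pm.mz_index(channel)] = rng.random(n)
    y = slope * X[:, pm.mz_index(channel)]
    return X, y


class TestFitPLS1:
    def test_exact_linear_single_factor(self):
        X, y = _exact_linear_toy(slope=3.0)
        model = pm.fit_pls1(X, y, 1)
        assert model.coef[pm.mz_index(100)] == pytest.approx(3.0)
        np.testing.assert_allclose(model.predict(X), y, atol=1e-10)

    def test_full_rank_equals_least_squares(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(8, 5))
        y = rng.normal(size=8)
        model = pm.fit_pls1(X, y, 5)
        Xc = X - X.mean(axis=0)
        b_ols = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
        np.testing.assert_allclose(model.coef, b_ols, atol=1e-8)

    def test_constant_y_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 4))
        with pytest.raises(DegenerateResponseError):
            pm.fit_pls1(X, np.full(6, 2.0), 1)

    def test_rank_exhaustion_reports_achieved(self):
        # rank-1 X cannot support 3 factors
        rng = np.random.default_rng(1)
        u = rng.normal(size=10)
        v = rng.normal(size=6)
        X = np.outer(u, v)
        y = u.copy()
        with pytest.raises(RankDeficientError) as exc:
            pm.fit_pls1(X, y, 3)
        assert exc.value.achieved == 1

    def test_nipals_invariants(self):
        """Unit-norm weights and mutually orthogonal score vectors."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 12))
        y = rng.normal(size=20)
        model = pm.fit_pls1(X, y, 4)
        norms = np.linalg.norm(model.weights, axis=0)
        np.testing.assert_allclose(norms, 1.0, atol=1e-10)
        # rebuild scores by replaying the deflation
        Xc = X - X.mean(axis=0)
        T = []
        for a in range(4):
            t = Xc @ model.weights[:, a]
            Xc = Xc - np.outer(t, model.x_loadings[:, a])
            T.append(t)
        T = np.array(T)
        G = T @ T.T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() <= 1e-8 * np.abs(np.diag(G)).max()

    def test_calibration_rmse_non_increasing_in_factors(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 10))
        y = X @ rng.normal(size=10) + rng.normal(size=30)
        rmses = []
        for a in range(1, 8):
            model = pm.fit_pls1(X, y, a)
            rmses.append(float(np.sqrt(np.mean((model.predict(X) - y) ** 2))))
        assert all(b <= a + 1e-10 for a, b in zip(rmses, rmses[1:]))

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_shift_invariance_and_scale_equivariance_of_y(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(15, 6))
        y = rng.normal(size=15)
        base = pm.fit_pls1(X, y, 3)
        shifted = pm.fit_pls1(X, y + 11.0, 3)
        scaled = pm.fit_pls1(X, y * 2.5, 3)
        Xnew = rng.normal(size=(4, 6))
        np.testing.assert_allclose(shifted.predict(Xnew), base.predict(Xnew) + 11.0,
                                   rtol=1e-8, atol=1e-8)
        np.testing.assert_allclose(scaled.predict(Xnew), base.predict(Xnew) * 2.5,
                                   rtol=1e-8, atol=1e-8)

    def test_sklearn_cross_check(self):
        """Independent oracle: scikit-learn's PLSRegression coefficients."""
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(5)
        X = rng.normal(size=(25, 10))
        y = X @ rng.normal(size=10) + 0.1 * rng.normal(size=25)
        ours = pm.fit_pls1(X, y, 3)
        ref = PLSRegression(n_components=3, scale=False).fit(X, y.reshape(-1, 1))
        np.testing.assert_allclose(ours.coef, ref.coef_.ravel(), rtol=1e-6, atol=1e-9)


class TestPredict:
    def test_training_mean_maps_to_y_mean(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(12, 5))
        y = rng.normal(size=12)
        model = pm.fit_pls1(X, y, 2)
        assert model.predict(X.mean(axis=0)[None, :])[0] == pytest.approx(y.mean())

    def test_exact_linear_training_recovered(self):
        X, y = _exact_linear_toy()
        model = pm.fit_pls1(X, y, 1)
        np.testing.assert_allclose(pm.predict_pls(model, X), y, atol=1e-10)

    def test_normalization_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        mat = pm.SpectrumMatrix(["a", "b", "c"], rng.random((3, pm.N_CHANNELS)),
                                normalization_state="tic")
        model = pm.fit_pls1(mat, [1.0, 2.0, 3.0], 1)
        other = pm.SpectrumMatrix(["a", "b", "c"], rng.random((3, pm.N_CHANNELS)),
                                  normalization_state="mean")
        with pytest.raises(InconsistentNormalizationError):
            pm.predict_pls(model, other)

    def test_heldout_recovery_within_noise_floor(self, natural_set):
        """Held-out prediction RMSE stays within 2x the reference noise."""
        ns = natural_set
        ref = ns["reference"]["glucose_dw_pct"].to_numpy()
        cal = pm.select_calibration_ids(range(500), ref, 93)
        mask = np.zeros(500, bool)
        mask[cal] = True
        model = pm.fit_pls1(ns["matrix"].matrix[mask], ref[mask], 4)
        pred = model.predict(ns["matrix"].matrix[~mask])
        rmse = np.sqrt(np.mean((pred - ns["glucose_true"][~mask]) ** 2))
        assert rmse <= 2.0 * ns["config"].reference_sd["glucose_dw_pct"]


class TestCrossValidate:
    def test_noiseless_linear_toy_near_zero(self):
        X, y = _exact_linear_toy(n=10)
        rmsecv = pm.cross_validate(X, y, 2, scheme="loo")
        assert rmsecv[0] == pytest.approx(0.0, abs=1e-8)

    def test_pure_noise_rmsecv_at_least_sd(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 30))
        y = rng.normal(size=40)
        rmsecv = pm.cross_validate(X, y, 5, scheme="loo")
        assert np.all(rmsecv >= y.std() * 0.9)

    def test_loo_refit_count(self):
        X, y = _exact_linear_toy(n=9)
        counter = []
        pm.cross_validate(X, y, 1, scheme="loo", _fit_counter=counter)
        assert len(counter) == 9

    def test_kfold_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 8))
        y = rng.normal(size=30)
        a = pm.cross_validate(X, y, 3, scheme="kfold", k=5, seed=7)
        b = pm.cross_validate(X, y, 3, scheme="kfold", k=5, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_too_many_folds_rejected(self):
        X, y = _exact_linear_toy(n=5)
        with pytest.raises(InvalidFoldsError):
            pm.cross_validate(X, y, 1, scheme="kfold", k=10)

    def test_default_scheme_switchover(self):
        assert pm.default_cv_scheme(150)[0] == "loo"
        assert pm.default_cv_scheme(151) == ("kfold", 10)


class TestValidationMetrics:
    def test_perfect_prediction(self):
        r = pm.validation_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.r2 == pytest.approx(1.0)
        assert r.pcc == pytest.approx(1.0)
        assert r.rmse == 0.0
        assert r.err_mean_abs_pct == 0.0

    def test_constant_predictor_degenerate(self):
        measured = np.array([1.0, 2.0, 3.0, 4.0])
        r = pm.validation_metrics(measured, np.full(4, measured.mean()))
        assert r.degenerate
        assert r.pcc == 0.0
        assert r.rmse == pytest.approx(measured.std())

    def test_hand_computed_example(self):
        r = pm.validation_metrics([10.0, 20.0, 10.0, 20.0], [11.0, 18.0, 11.0, 18.0])
        assert r.rmse == pytest.approx(np.sqrt((1 + 4 + 1 + 4) / 4))
        assert r.err_min_pct == pytest.approx(-10.0)
        assert r.err_max_pct == pytest.approx(10.0)
        assert r.err_mean_abs_pct == pytest.approx(10.0)

    def test_r2_is_squared_pcc(self):
        rng = np.random.default_rng(0)
        m = rng.random(20) + 1
        p = m + rng.normal(0, 0.2, 20)
        r = pm.validation_metrics(m, p)
        assert r.r2 == pytest.approx(r.pcc**2)

    def test_zero_measured_excluded_from_relative_errors(self):
        r = pm.validation_metrics([0.0, 10.0, 20.0], [1.0, 11.0, 22.0])
        assert r.err_max_pct == pytest.approx(10.0)
        assert r.n == 3


class TestFactorLoadings:
    def test_exact_linear_concentrates_on_informative_channel(self):
        X, y = _exact_linear_toy(channel=126)
        model = pm.fit_pls1(X, y, 1)
        p1 = pm.factor1_loadings(model)
        assert len(p1) == pm.N_CHANNELS
        assert np.argmax(np.abs(p1)) == pm.mz_index(126)
        assert p1[pm.mz_index(126)] > 0  # sign fixed so q_1 > 0

    def test_synthetic_glucose_model_sign_structure(self, natural_set):
        """C6 sugar channels load positive, syringyl-lignin channels negative."""
        ns = natural_set
        model = pm.fit_pls1(ns["matrix"].matrix, ns["glucose_true"], 4)
        p1 = pm.factor1_loadings(model)
        for mz in (126, 98, 69):
            assert p1[pm.mz_index(mz)] > 0
        for mz in (154, 194, 210):
            assert p1[pm.mz_index(mz)] < 0


class TestPCA:
    def test_collinear_data_single_component(self):
        t = np.linspace(0, 1, 10)
        X = np.column_stack([t, 2 * t])
        r = pm.fit_pca(X)
        assert r.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_fractions_match_eigendecomposition(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 4))
        r = pm.fit_pca(X)
        ev = np.linalg.eigvalsh(np.cov(X.T))[::-1]
        np.testing.assert_allclose(r.explained_variance_ratio, ev / ev.sum(), atol=1e-8)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(9, 5))
        r = pm.fit_pca(X)
        assert r.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-8)
        assert np.all(np.diff(r.explained_variance_ratio) <= 1e-12)

    def test_sklearn_cross_check(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(12)
        X = rng.normal(size=(15, 7))
        ours = pm.fit_pca(X)
        ref = PCA().fit(X)
        np.testing.assert_allclose(
            ours.explained_variance_ratio, ref.explained_variance_ratio_, atol=1e-10
        )

    def test_loading_sign_convention(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 6))
        r = pm.fit_pca(X)
        for j in range(r.loadings.shape[1]):
            i = np.argmax(np.abs(r.loadings[:, j]))
            assert r.loadings[i, j] > 0


class TestCorrelationProfile:
    def test_trait_equal_to_channel(self):
        rng = np.random.default_rng(0)
        X = rng.random((30, pm.N_CHANNELS))
        prof = pm.correlation_profile(X, X[:, pm.mz_index(126)])
        assert prof.at(126) == pytest.approx(1.0)

    def test_independent_noise_small_correlations(self):
        rng = np.random.default_rng(3)
        X = rng.random((200, pm.N_CHANNELS))
        prof = pm.correlation_profile(X, rng.normal(size=200))
        assert np.abs(prof.r).max() < 0.3

    def test_constant_channel_flagged_zero(self):
        rng = np.random.default_rng(1)
        X = rng.random((20, pm.N_CHANNELS))
        X[:, 5] = 2.0
        prof = pm.correlation_profile(X, rng.normal(size=20))
        assert prof.r[5] == 0.0
        assert prof.constant_channel[5]

    def test_constant_trait_rejected(self):
        X = np.random.default_rng(0).random((10, pm.N_CHANNELS))
        with pytest.raises(DegenerateResponseError):
            pm.correlation_profile(X, np.ones(10))

    def test_synthetic_sign_structure(self, natural_set):
        """C6 ions correlate positively with glucose; syringyl-lignin ion sum
        correlates positively with xylose (the carbon-allocation signature)."""
        ns = natural_set
        prof = pm.correlation_profile(ns["matrix"], ns["glucose_true"])
        assert prof.at(126) > 0.5
        s_idx = [pm.mz_index(m) for m in pm.LIGNIN_IONS.sublabel_members("S")]
        s_sum = ns["matrix"].matrix[:, s_idx].sum(axis=1)
        assert np.corrcoef(s_sum, ns["xylose_true"])[0, 1] > 0.3
        assert prof.at(154) < 0  # S-lignin ion negative with glucose


class TestModelSerialization:
    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(12, 8))
        y = rng.normal(size=12)
        model = pm.fit_pls1(X, y, 2, sample_ids=[f"s{i}" for i in range(12)],
                            trait="glucose_dw_pct")
        path = tmp_path / "model.json"
        model.to_json(path, seed=0)
        back = pm.PLSModel.from_json(path)
        np.testing.assert_allclose(back.coef, model.coef)
        np.testing.assert_allclose(back.x_mean, model.x_mean)
        assert back.trait == "glucose_dw_pct"
        assert back.training_sample_ids == model.training_sample_ids
        Xnew = rng.normal(size=(3, 8))
        np.testing.assert_allclose(back.predict(Xnew), model.predict(Xnew))


def test_select_calibration_ids_spans_range():
    rng = np.random.default_rng(0)
    vals = rng.random(100)
    ids = [f"s{i}" for i in range(100)]
    cal = pm.select_calibration_ids(ids, vals, 10)
    assert len(cal) == 10
    picked = [vals[ids.index(c)] for c in cal]
    assert min(picked) == vals.min()
    assert max(picked) == vals.max()
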