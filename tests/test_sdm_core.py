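import numpy as np
import pytest

from esdm.sdm_core import (
    ALGORITHM_IDS,
    ensemble_predict,
    fit_member,
    fit_nppen,
    predict_nppen,
)


def counting_oracle(ref, x, ridge_model):
    """Brute-force NPPEN oracle: direct proportion of reference distances
    at least as large as the candidate's, using the model's metric."""
    d2_ref = ridge_model.mahalanobis_sq(ref)
    d2_x = ridge_model.mahalanobis_sq(np.atleast_2d(x))
    return np.array([(d2_ref >= d).mean() for d in d2_x])


class TestFitNppen:
    def test_moments_recovered_on_standard_normal_cloud(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((2000, 2))
        m = fit_nppen(X)
        np.testing.assert_allclose(m.mean, [0, 0], atol=0.08)
        np.testing.assert_allclose(m.cov, np.eye(2), atol=0.08)

    def test_duplicate_column_ridged_not_failed(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=50)
        X = np.column_stack([a, a])  # singular covariance
        m = fit_nppen(X)
        assert np.isfinite(m.cov_inv).all()
        assert predict_nppen(m, m.mean[None, :])[0] == 1.0

    def test_refit_identical(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 3))
        a, b = fit_nppen(X), fit_nppen(X)
        np.testing.assert_array_equal(a.ref_d2, b.ref_d2)
        np.testing.assert_array_equal(a.cov, b.cov)

    def test_n_must_exceed_d(self):
        with pytest.raises(ValueError, match="more points"):
            fit_nppen(np.zeros((2, 2)) + np.arange(2))

    def test_zero_variance_factor_rejected(self):
        X = np.column_stack([np.arange(10.0), np.ones(10)])
        with pytest.raises(ValueError, match="zero-variance"):
            fit_nppen(X)

    def test_leave_one_out_variant_runs(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 2))
        m = fit_nppen(X, leave_one_out=True)
        assert m.ref_d2.shape == (30,)
        assert (m.ref_d2 > 0).all()


class TestPredictNppen:
    def test_centroid_scores_one(self):
        rng = np.random.default_rng(4)
        m = fit_nppen(rng.normal(size=(50, 2)))
        assert predict_nppen(m, m.mean[None, :])[0] == 1.0

    def test_far_point_scores_zero(self):
        rng = np.random.default_rng(5)
        m = fit_nppen(rng.normal(size=(50, 2)))
        assert predict_nppen(m, np.array([[100.0, 100.0]]))[0] == 0.0

    def test_matches_counting_oracle_on_random_instances(self):
        # exact agreement with the brute-force proportion, incl. ties
        rng = np.random.default_rng(6)
        for _ in range(100):
            n = rng.integers(5, 51)
            d = rng.integers(1, 4)
            if n <= d:
                n = d + 2
            ref = rng.normal(size=(n, d)) * rng.uniform(0.5, 3)
            m = fit_nppen(ref)
            x = rng.normal(size=(10, d)) * rng.uniform(0.5, 4)
            np.testing.assert_array_equal(predict_nppen(m, x), counting_oracle(ref, x, m))

    def test_tied_distances_counted_inclusively(self):
        ref = np.array([[0.0, 0.0], [1.0, 0.0], [-1.0, 0.0], [0.0, 2.0], [0.0, -2.0]])
        m = fit_nppen(ref)
        # a reference point's own distance ties with itself: >= is inclusive
        esi_ref = predict_nppen(m, ref)
        oracle = counting_oracle(ref, ref, m)
        np.testing.assert_array_equal(esi_ref, oracle)

    def test_monotone_along_ray_from_centroid(self):
        rng = np.random.default_rng(7)
        m = fit_nppen(rng.normal(size=(60, 2)))
        direction = np.array([1.0, 0.5])
        ts = np.linspace(0, 6, 40)
        esi = predict_nppen(m, m.mean + ts[:, None] * direction)
        assert np.all(np.diff(esi) <= 1e-12)

    def test_dimension_mismatch_rejected(self):
        m = fit_nppen(np.random.default_rng(8).normal(size=(20, 2)))
        with pytest.raises(ValueError, match="dim"):
            predict_nppen(m, np.zeros((1, 3)))


@pytest.fixture(scope="module")
def toy_design():
    # linearly separable 1-factor problem
    rng = np.random.default_rng(9)
    x_pres = rng.normal(2.0, 0.5, size=60)
    x_abs = rng.normal(-2.0, 0.5, size=60)
    X = np.concatenate([x_pres, x_abs])[:, None]
    y = np.concatenate([np.ones(60), np.zeros(60)])
    return X, y


class TestClassifierMembers:
    def test_glm_monotone_on_separable_toy(self, toy_design):
        X, y = toy_design
        m = fit_member("GLM", X, y, seed=0, hyperparams={"degree": 1})
        xs = np.linspace(-4, 4, 50)[:, None]
        pred = m.predict(xs)
        assert np.all(np.diff(pred) >= -1e-9)
        assert (pred >= 0).all() and (pred <= 1).all()

    @pytest.mark.parametrize("alg", ["GLM", "GAM", "GBM", "ANN", "FDA", "MARS", "RF"])
    def test_training_presences_score_above_absences(self, alg, toy_design):
        X, y = toy_design
        m = fit_member(alg, X, y, seed=0)
        pred = m.predict(X)
        assert pred[y == 1].mean() > pred[y == 0].mean()

    def test_unknown_algorithm_rejected(self, toy_design):
        X, y = toy_design
        with pytest.raises(ValueError, match="unknown algorithm"):
            fit_member("MaxEnt", X, y)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            fit_member("GLM", np.zeros((5, 1)), np.ones(5))

    def test_determinism_of_fitted_member(self, toy_design):
        X, y = toy_design
        a = fit_member("RF", X, y, seed=3)
        b = fit_member("RF", X, y, seed=3)
        xs = np.linspace(-3, 3, 20)[:, None]
        np.testing.assert_array_equal(a.predict(xs), b.predict(xs))

    def test_algorithm_vocabulary(self):
        assert set(ALGORITHM_IDS) == {"NPPEN", "GLM", "GAM", "GBM", "ANN", "FDA", "MARS", "RF"}


class _Const:
    def __init__(self, v):
        self.v = v

    def predict(self, X):
        return np.full(len(X), self.v)


class TestEnsemblePredict:
    def test_single_member_sd_zero(self, stack):
        smap = ensemble_predict([_Const(0.4)], stack, ("SBT",))
        ocean = stack.ocean_mask
        np.testing.assert_allclose(smap.sd[ocean], 0.0)
        np.testing.assert_allclose(smap.esi[ocean], 0.4)

    def test_mean_of_two_members(self, stack):
        smap = ensemble_predict([_Const(0.2), _Const(0.6)], stack, ("SBT",))
        ocean = stack.ocean_mask
        np.testing.assert_allclose(smap.esi[ocean], 0.4)
        np.testing.assert_allclose(smap.sd[ocean], 0.2)

    def test_mean_within_member_envelope(self, stack, dataset):
        from esdm.sdm_core import fit_nppen

        nppen = fit_nppen(dataset.presences[["SBT", "SBTrange"]].to_numpy())
        X, y = dataset.design()
        glm = fit_member("GLM", X, y, seed=0)
        smap = ensemble_predict([nppen, glm], stack, ("SBT", "SBTrange"))
        cells, Xbg = stack.background_env(("SBT", "SBTrange"))
        lo = np.minimum(nppen.predict(Xbg), glm.predict(Xbg))
        hi = np.maximum(nppen.predict(Xbg), glm.predict(Xbg))
        esi = smap.esi.ravel()[cells]
        assert (esi >= lo - 1e-12).all() and (esi <= hi + 1e-12).all()

    def test_permutation_invariance_of_members(self, stack):
        members = [_Const(0.1), _Const(0.5), _Const(0.9)]
        a = ensemble_predict(members, stack, ("SBT",))
        b = ensemble_predict(members[::-1], stack, ("SBT",))
        np.testing.assert_array_equal(
            np.nan_to_num(a.esi), np.nan_to_num(b.esi)
        )
        np.testing.assert_array_equal(np.nan_to_num(a.sd), np.nan_to_num(b.sd))

    def test_missing_factor_rejected(self, stack):
        with pytest.raises(ValueError, match="lacks"):
            ensemble_predict([_Const(0.5)], stack, ("SBT", "NOPE"))

    def test_masked_cells_are_nan_not_zero(self, stack):
        smap = ensemble_predict([_Const(0.4)], stack, ("SBT",))
        land = ~stack.ocean_mask
        if land.any():
            assert np.isnan(smap.esi[land]).all()
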