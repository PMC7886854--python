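import numpy as np
import pytest

from esdm import synthetic_world as sw
from esdm.projection import (
    ScenarioSpec,
    anomaly,
    apply_hierarchical_filter,
    delta_correct,
    delta_correct_stack,
    hierarchical_filter,
    project_future,
    taylor_stats,
)
from esdm.sdm_core import SuitabilityMap, ensemble_predict, fit_nppen


class TestScenarioSpec:
    def test_vocabulary_enforced(self):
        ScenarioSpec("GCM-A", "RCP8.5", "2090-2099")
        with pytest.raises(ValueError, match="RCP"):
            ScenarioSpec("GCM-A", "RCP6.0", "2090-2099")
        with pytest.raises(ValueError, match="decade"):
            ScenarioSpec("GCM-A", "RCP8.5", "2000-2009")


class TestTaylorStats:
    def test_identical_fields(self):
        f = np.random.default_rng(0).normal(size=(10, 10))
        ts = taylor_stats(f, f)
        assert ts.pearson_r == pytest.approx(1.0)
        assert ts.sd_ratio == pytest.approx(1.0)
        assert ts.centered_rmsd == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_removed_by_centering(self):
        f = np.random.default_rng(1).normal(size=(8, 8))
        ts = taylor_stats(f, f + 5.0)
        assert ts.pearson_r == pytest.approx(1.0)
        assert ts.centered_rmsd == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_fields(self):
        f = np.random.default_rng(2).normal(size=(6, 6))
        ts = taylor_stats(f, -f)
        assert ts.pearson_r == pytest.approx(-1.0)

    def test_nan_cells_ignored(self):
        f = np.random.default_rng(3).normal(size=(5, 5))
        g = f.copy()
        g[0, 0] = np.nan
        ts = taylor_stats(f, g)
        assert ts.pearson_r == pytest.approx(1.0)

    def test_too_few_cells(self):
        with pytest.raises(ValueError, match="2"):
            taylor_stats(np.array([[1.0]]), np.array([[1.0]]))


class TestDeltaCorrect:
    def test_formula(self):
        out = delta_correct(np.array([[15.0]]), np.array([[10.0]]), np.array([[12.0]]))
        assert out[0, 0] == pytest.approx(13.0)

    def test_zero_bias_is_identity(self):
        f = np.random.default_rng(4).normal(size=(4, 4))
        base = np.random.default_rng(5).normal(size=(4, 4))
        np.testing.assert_allclose(delta_correct(f, base, base), f)

    def test_corrected_baseline_reproduces_observations(self, stack):
        forcing = sw.make_forcing(stack.grid, "GCM-A", "RCP8.5", bias_scale=2.0, seed=9)
        gcm_base = sw.generate_gcm_stack(stack, forcing, "baseline")
        corrected = delta_correct(
            gcm_base.factors["SBT"], stack.factors["SBT"], gcm_base.factors["SBT"]
        )
        ocean = stack.ocean_mask
        np.testing.assert_allclose(corrected[ocean], stack.factors["SBT"][ocean])
        ts = taylor_stats(stack.factors["SBT"], corrected)
        assert ts.pearson_r == pytest.approx(1.0)
        assert ts.sd_ratio == pytest.approx(1.0)
        assert ts.centered_rmsd == pytest.approx(0.0, abs=1e-9)

    def test_missing_baseline_cell_rejected(self):
        obs = np.array([[np.nan]])
        with pytest.raises(ValueError, match="baseline"):
            delta_correct(np.array([[1.0]]), obs, np.array([[1.0]]))

    def test_stack_correction_keeps_sss_constant(self, stack):
        forcing = sw.make_forcing(stack.grid, "GCM-B", "RCP4.5", seed=8)
        base = sw.generate_gcm_stack(stack, forcing, "baseline")
        fut = sw.generate_gcm_stack(stack, forcing, "2090-2099")
        corrected = delta_correct_stack(fut, stack, base)
        ocean = stack.ocean_mask
        np.testing.assert_array_equal(
            corrected.factors["SSS"][ocean], stack.factors["SSS"][ocean]
        )
        # corrected future = contemporary + pure warming trend
        warming = fut.meta["warming"]
        np.testing.assert_allclose(
            corrected.factors["SBT"][ocean],
            stack.factors["SBT"][ocean] + warming,
            atol=1e-9,
        )


class _Warmth:
    """Toy member: suitability decays as SBT exceeds an optimum of 15."""

    def predict(self, X):
        return np.exp(-((X[:, 0] - 15.0) ** 2) / 18.0)


class TestProjectFuture:
    def _corrected(self, stack, rcp, decade, n_gcms=3):
        out = {}
        for k in range(n_gcms):
            forcing = sw.make_forcing(stack.grid, f"G{k}", rcp, seed=100 + k)
            base = sw.generate_gcm_stack(stack, forcing, "baseline")
            fut = sw.generate_gcm_stack(stack, forcing, decade)
            out[f"G{k}"] = delta_correct_stack(fut, stack, base)
        return out

    def test_identical_gcms_mean_equals_single(self, stack):
        corrected = self._corrected(stack, "RCP4.5", "2050-2059", n_gcms=1)
        single = ensemble_predict([_Warmth()], corrected["G0"], ("SBT",))
        multi = project_future(
            [_Warmth()], {"A": corrected["G0"], "B": corrected["G0"]},
            ("SBT",), "RCP4.5", "2050-2059",
        )
        np.testing.assert_allclose(
            np.nan_to_num(multi.esi), np.nan_to_num(single.esi), atol=1e-12
        )

    def test_multi_gcm_mean_within_envelope(self, stack):
        corrected = self._corrected(stack, "RCP8.5", "2090-2099")
        maps = {
            g: ensemble_predict([_Warmth()], s, ("SBT",)).esi for g, s in corrected.items()
        }
        multi = project_future([_Warmth()], corrected, ("SBT",), "RCP8.5", "2090-2099")
        ocean = stack.ocean_mask
        stackd = np.stack(list(maps.values()))
        assert (multi.esi[ocean] >= stackd.min(axis=0)[ocean] - 1e-12).all()
        assert (multi.esi[ocean] <= stackd.max(axis=0)[ocean] + 1e-12).all()

    def test_correction_beats_raw_biased_gcm(self, stack, niche):
        # a warm-biased GCM: ESI from corrected fields is closer to the
        # truth-driven ESI than ESI from uncorrected fields
        member = _Warmth()
        ref = ensemble_predict([member], stack, ("SBT",)).esi
        forcing = sw.make_forcing(stack.grid, "HOT", "RCP2.6", bias_scale=3.0, seed=77)
        base = sw.generate_gcm_stack(stack, forcing, "baseline")
        fut = sw.generate_gcm_stack(stack, forcing, "2030-2039")
        raw_esi = ensemble_predict([member], fut, ("SBT",)).esi
        cor_esi = ensemble_predict(
            [member], delta_correct_stack(fut, stack, base), ("SBT",)
        ).esi
        ocean = stack.ocean_mask
        err_raw = np.abs(raw_esi - ref)[ocean].mean()
        err_cor = np.abs(cor_esi - ref)[ocean].mean()
        assert err_cor < err_raw

    def test_rcp_ordering_where_optimum_exceeded(self, stack):
        member = _Warmth()
        esi = {}
        for rcp in ("RCP2.6", "RCP4.5", "RCP8.5"):
            corrected = self._corrected(stack, rcp, "2090-2099")
            esi[rcp] = project_future([member], corrected, ("SBT",), rcp, "2090-2099").esi
        warm = stack.factors["SBT"] > 15.0  # already past the optimum
        ocean = stack.ocean_mask & warm
        assert np.all(esi["RCP4.5"][ocean] <= esi["RCP2.6"][ocean] + 1e-9)
        assert np.all(esi["RCP8.5"][ocean] <= esi["RCP4.5"][ocean] + 1e-9)


class TestHierarchicalFilter:
    def test_truth_table(self):
        field = np.full((1, 3), 0.7)
        depth = np.array([[200.0, 400.0, 400.0]])
        dist = np.array([[200.0, 30.0, 200.0]])
        # coast filter on: shallow kept, deep-but-coastal kept, deep offshore masked
        out = hierarchical_filter(field, depth, dist, coast_enabled=True)
        assert out[0, 0] == pytest.approx(0.7)
        assert out[0, 1] == pytest.approx(0.7)
        assert np.isnan(out[0, 2])

    def test_coast_filter_disabled(self):
        field = np.full((1, 2), 0.5)
        depth = np.array([[400.0, 200.0]])
        dist = np.array([[10.0, 10.0]])
        out = hierarchical_filter(field, depth, dist, coast_enabled=False)
        assert np.isnan(out[0, 0]) and out[0, 1] == pytest.approx(0.5)

    def test_masked_cells_nan_not_zero(self, stack):
        smap = SuitabilityMap(
            grid=stack.grid,
            esi=np.where(stack.ocean_mask, 0.5, np.nan),
            sd=np.zeros(stack.grid.shape),
        )
        out = apply_hierarchical_filter(smap, stack, depth_max=300.0)
        deep = stack.ocean_mask & (stack.factors["bathymetry"] > 300.0)
        assert np.isnan(out.esi[deep]).all()
        assert out.mask_applied

    def test_misaligned_bathymetry_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            hierarchical_filter(np.zeros((2, 2)), np.zeros((3, 3)), np.zeros((2, 2)))


class TestAnomaly:
    def _map(self, stack, value):
        esi = np.where(stack.ocean_mask, value, np.nan)
        return SuitabilityMap(grid=stack.grid, esi=esi, sd=np.zeros(stack.grid.shape))

    def test_identical_maps_zero(self, stack):
        a = self._map(stack, 0.5)
        out = anomaly(a, a)
        assert np.nanmax(np.abs(out)) == 0.0

    def test_difference_value(self, stack):
        out = anomaly(self._map(stack, 0.9), self._map(stack, 0.3))
        ocean = stack.ocean_mask
        np.testing.assert_allclose(out[ocean], 0.6)

    def test_antisymmetry(self, stack):
        a, b = self._map(stack, 0.8), self._map(stack, 0.25)
        np.testing.assert_allclose(anomaly(a, b), -anomaly(b, a))

    def test_mask_mismatch_rejected(self, stack):
        a = self._map(stack, 0.5)
        esi = a.esi.copy()
        esi[np.argwhere(stack.ocean_mask)[0][0], np.argwhere(stack.ocean_mask)[0][1]] = np.nan
        b = SuitabilityMap(grid=stack.grid, esi=esi, sd=np.zeros(stack.grid.shape))
        with pytest.raises(ValueError, match="mask"):
            anomaly(a, b)
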