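"""Virtual-species generator: determinism, field statistics, niche
arithmetic, contamination bounds, and scenario-shift truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from deepsdm import (ContaminationSpec, GridSpec, ScenarioShift,
                     VirtualSpeciesSpec, apply_scenario_shift, cell_areas,
                     generate_effort_bias, generate_env_stack,
                     sample_occurrences, true_suitability,
                     true_suitable_area_km2)
from deepsdm.grids import RasterGrid


class TestGenerateEnvStack:
    def test_seeded_determinism(self, small_grid):
        a, ba = generate_env_stack(small_grid, 3, smoothness=4, seed=7)
        b, bb = generate_env_stack(small_grid, 3, smoothness=4, seed=7)
        for c in a.names:
            np.testing.assert_array_equal(a[c].values, b[c].values)
        np.testing.assert_array_equal(ba.values, bb.values)

    def test_independent_fields_nearly_uncorrelated(self):
        grid = GridSpec(100, 100, 50.0, 70.0, -20.0, 20.0)
        stack, _ = generate_env_stack(grid, 4, smoothness=3, seed=3)
        X = np.stack([stack[c].values.ravel() for c in stack.names])
        corr = np.corrcoef(X)
        off = corr[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.15

    def test_requested_correlation_is_approached(self):
        grid = GridSpec(100, 100, 50.0, 70.0, -20.0, 20.0)
        target = np.array([[1.0, 0.7], [0.7, 1.0]])
        stack, _ = generate_env_stack(grid, 2, target_correlation=target,
                                      smoothness=3, seed=5)
        X = np.stack([stack[c].values.ravel() for c in stack.names])
        assert np.corrcoef(X)[0, 1] == pytest.approx(0.7, abs=0.1)

    def test_smoothness_gives_spatial_autocorrelation(self):
        grid = GridSpec(100, 100, 50.0, 70.0, -20.0, 20.0)
        stack, _ = generate_env_stack(grid, 2, smoothness=10, seed=9)
        for c in stack.names:
            v = stack[c].values
            lag1 = np.corrcoef(v[:, :-1].ravel(), v[:, 1:].ravel())[0, 1]
            assert lag1 > 0.8

    def test_non_positive_definite_rejected(self, small_grid):
        bad = np.array([[1.0, 1.2], [1.2, 1.0]])
        with pytest.raises(ValueError, match="positive definite"):
            generate_env_stack(small_grid, 2, target_correlation=bad, seed=1)

    def test_bathymetry_positive(self, small_world):
        _, bathy, _, _ = small_world
        assert (bathy.values > 0).all()


class TestTrueSuitability:
    def test_equals_one_at_optimum(self, small_world):
        stack, _, _, sp = small_world
        flat = {c: stack[c].copy_with(np.full(stack.grid.shape, sp.optima[c]))
                for c in stack.names}
        from deepsdm import EnvStack
        s = true_suitability(sp, EnvStack(flat))
        np.testing.assert_allclose(s.values, 1.0)

    def test_one_sigma_displacement_closed_form(self, small_grid):
        stack, _ = generate_env_stack(small_grid, 1, smoothness=4, seed=2)
        c = stack.names[0]
        sp = VirtualSpeciesSpec("sp", {c: 0.0}, {c: 2.0})
        from deepsdm import EnvStack
        shifted = EnvStack({c: stack[c].copy_with(
            np.full(small_grid.shape, 2.0))})
        s = true_suitability(sp, shifted)
        np.testing.assert_allclose(s.values, np.exp(-0.5), rtol=1e-12)

    def test_wider_tolerance_never_decreases_suitability(self, small_world):
        stack, _, _, sp = small_world
        wide = VirtualSpeciesSpec(sp.species_id, sp.optima,
                                  {c: 2 * v for c, v in sp.tolerances.items()})
        s1 = true_suitability(sp, stack).values
        s2 = true_suitability(wide, stack).values
        assert (s2 >= s1).all()

    def test_missing_covariate_rejected(self, small_world):
        stack, _, _, _ = small_world
        sp = VirtualSpeciesSpec("x", {"nope": 0.0}, {"nope": 1.0})
        with pytest.raises(KeyError, match="nope"):
            true_suitability(sp, stack)


class TestSampleOccurrences:
    def test_uniform_world_gof(self, small_grid):
        # flat suitability and flat bias -> uniform multinomial over cells
        from deepsdm import EnvStack
        const = RasterGrid(small_grid, np.zeros(small_grid.shape))
        stack = EnvStack({"cov1": const})
        sp = VirtualSpeciesSpec("sp", {"cov1": 0.0}, {"cov1": 1.0})
        bathy = RasterGrid(small_grid, np.full(small_grid.shape, 1000.0))
        bias = RasterGrid(small_grid, np.ones(small_grid.shape))
        occ, truth = sample_occurrences(sp, stack, bathy, bias, n=10_000, seed=5)
        rows, cols, inside = small_grid.rowcol(
            occ["decimalLatitude"], occ["decimalLongitude"])
        assert inside.all()
        counts = np.bincount(rows * small_grid.n_cols + cols,
                             minlength=small_grid.n_rows * small_grid.n_cols)
        p = stats.chisquare(counts).pvalue
        assert p > 0.001
        assert truth["clean_flag"].all()

    def test_zero_suitability_region_gets_no_presences(self, small_grid):
        from deepsdm import EnvStack
        vals = np.zeros(small_grid.shape)
        vals[:, : small_grid.n_cols // 2] = 5.0  # west half far from optimum
        stack = EnvStack({"cov1": RasterGrid(small_grid, vals)})
        sp = VirtualSpeciesSpec("sp", {"cov1": 5.0}, {"cov1": 0.5})
        bathy = RasterGrid(small_grid, np.full(small_grid.shape, 1000.0))
        bias = RasterGrid(small_grid, np.ones(small_grid.shape))
        occ, _ = sample_occurrences(sp, stack, bathy, bias, n=500, seed=1)
        # suitability in the east half is exp(-50) ~ 0; all points west
        assert (occ["decimalLongitude"] < small_grid.lon_min
                + (small_grid.lon_max - small_grid.lon_min) / 2).all()

    def test_pelagic_contamination_binomial_bounds(self, small_world):
        stack, bathy, bias, sp = small_world
        occ, truth = sample_occurrences(
            sp, stack, bathy, bias, n=1000,
            contamination=ContaminationSpec(pelagic_rate=0.1), seed=3)
        bvals, _ = bathy.sample(occ["decimalLatitude"], occ["decimalLongitude"])
        mism = np.abs(occ["depth"] - bvals) / bvals > 0.05
        lo, hi = stats.binom.ppf([0.0005, 0.9995], 1000, 0.1)
        assert lo <= mism.sum() <= hi
        assert mism.sum() == (~truth["clean_flag"]).sum()

    def test_zero_weight_rejected(self, small_grid):
        from deepsdm import EnvStack
        stack = EnvStack({"cov1": RasterGrid(small_grid, np.zeros(small_grid.shape))})
        sp = VirtualSpeciesSpec("sp", {"cov1": 0.0}, {"cov1": 1.0})
        bathy = RasterGrid(small_grid, np.full(small_grid.shape, 1000.0))
        zero = RasterGrid(small_grid, np.zeros(small_grid.shape))
        with pytest.raises(ValueError, match="zero"):
            sample_occurrences(sp, stack, bathy, zero, n=10, seed=0)


class TestScenarioShift:
    def test_identity_shift_is_exact(self, small_world):
        stack, _, _, sp = small_world
        shifted, truth = apply_scenario_shift(stack, ScenarioShift(),
                                              species=[sp])
        for c in stack.names:
            np.testing.assert_array_equal(shifted[c].values, stack[c].values)
        assert truth["delta_km2"].iloc[0] == 0.0

    def test_shift_toward_optimum_grows_habitat(self, small_grid):
        stack, _ = generate_env_stack(small_grid, 2, smoothness=4, seed=4)
        sp = VirtualSpeciesSpec("sp", {c: 0.0 for c in stack.names},
                                {c: 0.8 for c in stack.names})
        # moving every cell halfway toward the optimum (scale 0.5 about 0)
        shift = ScenarioShift(scales={c: 0.5 for c in stack.names})
        _, truth = apply_scenario_shift(stack, shift, species=[sp],
                                        threshold=0.5)
        assert truth["delta_km2"].iloc[0] >= 0.0

    def test_truth_area_matches_brute_force(self, small_world):
        stack, _, _, sp = small_world
        shift = ScenarioShift(offsets={stack.names[0]: 0.7})
        shifted, truth = apply_scenario_shift(stack, shift, species=[sp],
                                              threshold=0.6)
        # independent brute force: evaluate the Gaussian cell by cell
        areas = cell_areas(stack.grid)
        expect = 0.0
        for i in range(stack.grid.n_rows):
            for j in range(stack.grid.n_cols):
                log_s = 0.0
                for c in stack.names:
                    x = shifted[c].values[i, j]
                    log_s -= (x - sp.optima[c]) ** 2 / (2 * sp.tolerances[c] ** 2)
                if np.exp(log_s) >= 0.6:
                    expect += areas[i]
        assert truth["area_after_km2"].iloc[0] == pytest.approx(expect, rel=1e-12)

    def test_unknown_covariate_rejected(self, small_world):
        stack, _, _, _ = small_world
        with pytest.raises(KeyError):
            apply_scenario_shift(stack, ScenarioShift(offsets={"ghost": 1.0}))


def test_contamination_spec_validation():
    with pytest.raises(ValueError):
        ContaminationSpec(pelagic_rate=-0.1)
    with pytest.raises(ValueError):
        ContaminationSpec(0.4, 0.4, 0.2, 0.1)
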