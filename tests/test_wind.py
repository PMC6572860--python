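import math

import numpy as np
import pytest

from dunewalk.types import InvariantError, ShootMap
from dunewalk.walk import WalkConfig, simulate_walk
from dunewalk.wind import (WindConfig, analytic_kernel, brute_force_field,
                           deposition, experiment_layouts, mean_rhizome_length,
                           sweep, sweep_summary, argmax_mu, wind_field)


@pytest.fixture(scope="module")
def cfg():
    return WindConfig()


@pytest.fixture(scope="module")
def kern(cfg):
    return analytic_kernel(cfg)


class TestKernel:
    def test_peak_deficit_at_shoot_cell(self, cfg, kern):
        r0, c0 = kern.origin
        assert kern.values[r0, c0] == pytest.approx(cfg.a0)

    def test_on_axis_decay_at_lx(self, cfg, kern):
        r0, c0 = kern.origin
        col = c0 + int(round(cfg.Lx / cfg.cell))
        assert kern.values[r0, col] == pytest.approx(cfg.a0 / math.e)

    def test_single_shoot_wake_area_nonzero(self, cfg, kern):
        # peak deficit 0.65 exceeds the 0.39 deficit the 0.61 threshold
        # needs, so one shoot already deposits immediately downwind
        smap = ShootMap(plant_id="one", xy=[[0.0, 0.0]])
        fld = wind_field(smap, cfg, kern)
        assert fld.deposition_area(cfg.deposition_fraction) > 0

    def test_boundary_and_range(self, kern):
        v = kern.values
        assert v.min() >= 0.0 and v.max() <= 1.0
        assert v[0, :].max() == 0.0 and v[-1, :].max() == 0.0
        assert v[:, -1].max() == 0.0

    def test_zero_upwind_beyond_diameter(self, cfg, kern):
        r0, c0 = kern.origin
        assert np.all(kern.values[:, :max(c0 - 1, 0)] == 0.0)

    def test_parameter_validation(self):
        with pytest.raises(InvariantError):
            WindConfig(a0=1.5)
        with pytest.raises(InvariantError):
            WindConfig(deposition_fraction=0.0)


class TestWindField:
    def test_single_shoot_equals_one_minus_kernel(self, cfg, kern):
        smap = ShootMap(plant_id="one", xy=[[0.0, 0.0]])
        fld = wind_field(smap, cfg, kern)
        np.testing.assert_allclose(fld.u, 1.0 - kern.values, atol=1e-9)

    def test_matches_brute_force_summation(self, cfg, kern):
        rng = np.random.default_rng(0)
        smap = ShootMap(plant_id="m", xy=rng.uniform(0, 30, (20, 2)))
        a = wind_field(smap, cfg, kern)
        b = brute_force_field(smap, cfg, kern)
        np.testing.assert_allclose(a.u, b.u, atol=1e-9)

    def test_two_far_shoots_superpose(self, cfg, kern):
        single = wind_field(ShootMap(plant_id="s", xy=[[0.0, 0.0]]), cfg, kern)
        pair = wind_field(ShootMap(plant_id="p", xy=[[0.0, 0.0], [0.0, 500.0]]),
                          cfg, kern)
        a1 = single.deposition_area(cfg.deposition_fraction)
        a2 = pair.deposition_area(cfg.deposition_fraction)
        assert abs(a2 - 2 * a1) <= cfg.cell ** 2  # within one cell

    def test_translation_invariance(self, cfg, kern):
        smap = simulate_walk(WalkConfig(mu=2.0, n_shoots=100, seed=1))
        moved = ShootMap(plant_id="t", xy=smap.xy + [17.3, -4.9],
                         parent_index=smap.parent_index)
        a = wind_field(smap, cfg, kern).deposition_area(0.61)
        b = wind_field(moved, cfg, kern).deposition_area(0.61)
        assert abs(a - b) <= cfg.cell ** 2

    def test_area_monotone_in_threshold(self, cfg, kern):
        smap = simulate_walk(WalkConfig(mu=2.0, n_shoots=200, seed=2))
        fld = wind_field(smap, cfg, kern)
        areas = [fld.deposition_area(t) for t in (0.25, 0.45, 0.61, 0.85)]
        assert np.all(np.diff(areas) >= 0)


class TestDeposition:
    def test_single_shoot_efficiency_undefined(self, cfg):
        summ = deposition(ShootMap(plant_id="one", xy=[[0.0, 0.0]]), cfg)
        assert math.isnan(summ.mean_step) and math.isnan(summ.efficiency)
        assert summ.deposition_area > 0

    def test_mean_step_counts_subcutoff_links(self):
        smap = ShootMap(plant_id="p", xy=[[0, 0], [0.5, 0], [2.5, 0]],
                        parent_index=[-1, 0, 1])
        assert mean_rhizome_length(smap) == pytest.approx(1.25)

    def test_clump_saturation(self, cfg, kern):
        # doubling shoots inside one saturated patch grows area sublinearly
        rng = np.random.default_rng(3)
        patch = rng.uniform(0, 10, (400, 2))
        a1 = wind_field(ShootMap(plant_id="a", xy=patch[:200]), cfg,
                        kern).deposition_area(0.61)
        a2 = wind_field(ShootMap(plant_id="b", xy=patch), cfg,
                        kern).deposition_area(0.61)
        assert a2 < 2 * a1

    def test_area_ordering_dispersed_levy_brownian(self, cfg, kern):
        areas = {}
        for mu in (1.5, 2.0, 3.0):
            areas[mu] = np.mean([
                deposition(simulate_walk(WalkConfig(mu=mu, n_shoots=400, seed=s)),
                           cfg, kernel=kern).deposition_area for s in range(3)])
        assert areas[1.5] > areas[2.0] > areas[3.0]


class TestSweep:
    def test_single_point_grid(self):
        df = sweep([2.0], [100], thresholds=[0.61], n_reps=1, seed=0)
        assert len(df) == 1

    def test_determinism(self):
        a = sweep([1.5, 2.0], [100], n_reps=2, seed=5)
        b = sweep([1.5, 2.0], [100], n_reps=2, seed=5)
        assert a.equals(b)

    def test_summary_and_argmax_shapes(self):
        df = sweep([1.5, 2.0], [100], thresholds=[0.45, 0.61], n_reps=2, seed=1)
        summ = sweep_summary(df)
        assert len(summ) == 4
        best = argmax_mu(summ, "eff_mean")
        assert set(best.columns) >= {"n_shoots", "threshold", "best_mu"}


class TestExperimentLayouts:
    def test_single_patch_much_smaller_than_domain(self):
        smap = experiment_layouts("single_patch", n_shoots=500, seed=0)
        span = smap.xy.max(axis=0) - smap.xy.min(axis=0)
        assert span.prod() < 0.25 * 200 * 200

    def test_layouts_confined_to_domain(self):
        for pat in ("dispersed", "patchy"):
            smap = experiment_layouts(pat, n_shoots=500, seed=1)
            assert smap.xy.min() >= 0.0 and smap.xy.max() <= 200.0

    def test_infeasible_density_rejected(self):
        with pytest.raises(InvariantError):
            experiment_layouts("dispersed", n_shoots=100_000)

    def test_unknown_pattern_rejected(self):
        with pytest.raises(InvariantError):
            experiment_layouts("spiral")
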