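"""Cost distances, the logistic dispersal kernel, rank-sum scoring and the
threshold sweep."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from streamvuln import (
    CostSurface,
    DistanceField,
    KernelParams,
    apply_kernel,
    build_cost_surface,
    cost_distance,
    dispersal_pressure,
    generate_landscape,
    habitat_shift_score,
    kernel_value,
    rank_sum_z,
    sweep_score_from_series,
    threshold_sweep,
)
from streamvuln.landscape import OccurrenceSet
from conftest import surface


def brute_force_distance(costs, cell_size, source, target):
    """Exhaustive least-cost path search (DFS with cost-bound pruning)."""
    n_rows, n_cols = costs.shape
    best = [math.inf]

    def step_cost(a, b):
        mult = math.sqrt(2) if (a[0] != b[0] and a[1] != b[1]) else 1.0
        return cell_size * mult * 0.5 * (costs[a] + costs[b])

    def dfs(cell, acc, visited):
        if acc >= best[0]:
            return
        if cell == target:
            best[0] = acc
            return
        r, c = cell
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                nr, nc = r + dr, c + dc
                if 0 <= nr < n_rows and 0 <= nc < n_cols and (nr, nc) not in visited:
                    dfs((nr, nc), acc + step_cost((r, c), (nr, nc)), visited | {(nr, nc)})

    dfs(source, 0.0, {source})
    return best[0]


def _uniform_landscape(n):
    return generate_landscape(n, n, 1.0, n, 0.0, seed=0)


class TestCostSurface:
    def test_all_land_uniform_one(self, landscape):
        flat = generate_landscape(5, 5, 1.0, 3, 0.0, seed=1)
        cs = build_cost_surface(flat, 2.0)
        assert np.all(cs.costs == 1.0)

    @pytest.mark.parametrize("mult", [2.0, 100.0])
    def test_water_multiplier(self, landscape, mult):
        cs = build_cost_surface(landscape, mult)
        assert np.all(cs.costs[landscape.is_water] == mult)
        assert np.all(cs.costs[~landscape.is_water] == 1.0)

    def test_multiplier_below_one_rejected(self, landscape):
        with pytest.raises(ValueError):
            build_cost_surface(landscape, 0.5)


class TestCostDistance:
    def test_zero_at_source_and_stated_metric(self):
        ls = _uniform_landscape(6)
        cs = build_cost_surface(ls, 2.0)
        d = cost_distance(cs, [(0, 0)], ls)
        cells = d.cell_distances
        assert cells[0, 0] == 0.0
        assert cells[0, 5] == pytest.approx(5.0)
        assert cells[3, 3] == pytest.approx(3 * math.sqrt(2))

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(14)
        for n in (3, 4, 5):
            costs = np.ones((n, n))
            # water strip with doubled cost down the middle column
            costs[:, n // 2] = 2.0
            cs = CostSurface(costs=costs, cell_size=1.0)
            ls = _uniform_landscape(n)
            d = cost_distance(cs, [(0, 0)], ls).cell_distances
            for r in range(n):
                for c in range(n):
                    assert d[r, c] == pytest.approx(
                        brute_force_distance(costs, 1.0, (0, 0), (r, c))
                    )
        # and a random-cost 4x4 grid
        costs = rng.uniform(1.0, 3.0, (4, 4))
        cs = CostSurface(costs=costs, cell_size=2.0)
        ls = _uniform_landscape(4)
        d = cost_distance(cs, [(1, 2)], ls).cell_distances
        for r in range(4):
            for c in range(4):
                assert d[r, c] == pytest.approx(
                    brute_force_distance(costs, 2.0, (1, 2), (r, c))
                )

    def test_triangle_consistency(self, landscape):
        cs = build_cost_surface(landscape, 2.0)
        d = cost_distance(cs, [(0, 0)], landscape).cell_distances
        n_rows, n_cols = d.shape
        for r in range(n_rows):
            for c in range(n_cols):
                for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
                    nr, nc = r + dr, c + dc
                    if 0 <= nr < n_rows and 0 <= nc < n_cols:
                        mult = math.sqrt(2) if dr and dc else 1.0
                        w = landscape.cell_size * mult * 0.5 * (
                            cs.costs[r, c] + cs.costs[nr, nc]
                        )
                        assert d[nr, nc] <= d[r, c] + w + 1e-9

    def test_multi_source_is_min(self):
        ls = _uniform_landscape(6)
        cs = build_cost_surface(ls, 2.0)
        d_both = cost_distance(cs, [(0, 0), (5, 5)], ls).cell_distances
        d_a = cost_distance(cs, [(0, 0)], ls).cell_distances
        d_b = cost_distance(cs, [(5, 5)], ls).cell_distances
        assert np.allclose(d_both, np.minimum(d_a, d_b))

    def test_empty_sources_rejected(self, landscape):
        cs = build_cost_surface(landscape, 2.0)
        with pytest.raises(ValueError):
            cost_distance(cs, [], landscape)


class TestKernel:
    def test_asymptote_and_midpoint(self):
        p = KernelParams(d0=300.0, b=4.0)
        assert kernel_value(0.0, p) == pytest.approx(1.0, abs=1e-12)
        assert kernel_value(300.0, p) == pytest.approx(0.5)

    def test_horizon_curves_ordered(self):
        ds = np.linspace(0, 3000, 301)
        k300 = kernel_value(ds, KernelParams(d0=300.0))
        k630 = kernel_value(ds, KernelParams(d0=630.0))
        k1080 = kernel_value(ds, KernelParams(d0=1080.0))
        assert np.all(k300 <= k630 + 1e-12) and np.all(k630 <= k1080 + 1e-12)

    def test_monotone_and_bounded_random_params(self):
        rng = np.random.default_rng(77)
        ds = np.sort(rng.uniform(0, 5000, 200))
        for _ in range(1000):
            c = rng.uniform(0, 0.5)
            a = c + rng.uniform(0.01, 1.0)
            p = KernelParams(
                d0=rng.uniform(1, 2000), b=rng.uniform(0.1, 10), a=a, c=c
            )
            k = kernel_value(ds, p)
            assert np.all(np.diff(k) <= 1e-12)
            assert np.all((k >= c - 1e-12) & (k <= a + 1e-12))
            assert kernel_value(p.d0, p) == pytest.approx((a + c) / 2)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            KernelParams(d0=-1.0)
        with pytest.raises(ValueError):
            KernelParams(d0=10.0, b=0.0)
        with pytest.raises(ValueError):
            KernelParams(d0=10.0, a=0.2, c=0.5)


class TestApplyKernel:
    def _dist(self, values):
        return DistanceField("sp", pd.Series(values))

    def test_zero_distance_identity(self):
        surf = surface({"a": 0.3, "b": 0.9})
        out = apply_kernel(surf, self._dist({"a": 0.0, "b": 0.0}),
                           KernelParams(d0=300.0))
        assert np.allclose(out.values, surf.values, atol=1e-12)
        assert out.tss_threshold == surf.tss_threshold

    def test_midpoint_halves(self):
        surf = surface({"a": 0.8})
        out = apply_kernel(surf, self._dist({"a": 300.0}), KernelParams(d0=300.0))
        assert out.values["a"] == pytest.approx(0.4)

    def test_far_distance_collapses(self):
        surf = surface({"a": 1.0})
        out = apply_kernel(
            surf, self._dist({"a": 3000.0}), KernelParams(d0=300.0, b=4.0)
        )
        assert out.values["a"] < 1e-3

    def test_infinite_distance_zeroes(self):
        surf = surface({"a": 0.9})
        out = apply_kernel(
            surf, self._dist({"a": float("inf")}), KernelParams(d0=300.0, c=0.2)
        )
        assert out.values["a"] == 0.0

    def test_never_increases(self):
        rng = np.random.default_rng(3)
        vals = pd.Series(rng.uniform(size=20), index=[f"s{i}" for i in range(20)])
        surf = surface(vals)
        dist = DistanceField(
            "sp", pd.Series(rng.uniform(0, 2000, 20), index=vals.index)
        )
        out = apply_kernel(surf, dist, KernelParams(d0=500.0))
        assert (out.values <= surf.values + 1e-12).all()


class TestRankSum:
    def test_exact_small_sample(self):
        res = rank_sum_z([1.0, 2.0], [3.0, 4.0], exact=True)
        assert res.p_one_sided == pytest.approx(1 / 6)

    def test_identical_samples_null(self):
        res = rank_sum_z([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.z == pytest.approx(0.0)
        res2 = rank_sum_z([5.0] * 4, [5.0] * 4)
        assert res2.z == 0.0 and res2.p_one_sided == 0.5

    def test_normal_approx_close_to_permutation(self):
        rng = np.random.default_rng(55)
        for _ in range(50):
            na, nb = rng.integers(3, 9, size=2)
            a = np.round(rng.normal(0, 1, na), 1)
            b = np.round(rng.normal(rng.uniform(-1, 2), 1, nb), 1)
            approx = rank_sum_z(a, b).p_one_sided
            exact = rank_sum_z(a, b, exact=True).p_one_sided
            assert abs(approx - exact) < 0.05

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 20)
        b = rng.normal(1, 1, 25)
        ours = rank_sum_z(a, b)
        ref = stats.mannwhitneyu(b, a, alternative="greater", method="asymptotic",
                                 use_continuity=True)
        assert ours.p_one_sided == pytest.approx(ref.pvalue, abs=1e-9)


class TestHabitatShift:
    def _dist(self, n=80, seed=0):
        rng = np.random.default_rng(seed)
        vals = pd.Series(
            np.sort(rng.uniform(0, 1000, n)), index=[f"s{i}" for i in range(n)]
        )
        return DistanceField("sp", vals)

    def _occ(self):
        return OccurrenceSet("sp", pd.DataFrame({"subcatchment": ["s0"]}))

    def test_identical_sets_score_zero(self):
        d = self._dist()
        cur = {f"s{i}" for i in range(30)}
        res = habitat_shift_score(self._occ(), cur, cur, d)
        assert res.score == 0

    def test_large_uniform_shift_scores_two(self):
        vals = pd.concat([
            pd.Series(np.arange(30.0), index=[f"c{i}" for i in range(30)]),
            pd.Series(np.arange(30.0) + 500.0, index=[f"f{i}" for i in range(30)]),
        ])
        d = DistanceField("sp", vals)
        res = habitat_shift_score(
            self._occ(), {f"c{i}" for i in range(30)},
            {f"f{i}" for i in range(30)}, d,
        )
        assert res.score == 2 and res.z >= 3

    def test_moderate_shift_scores_one(self):
        # offset 6 on 0..29 gives z ~ 2.40 (verified against the rank-sum
        # statistic directly): significant but below three SDs
        vals = pd.concat([
            pd.Series(np.arange(30.0), index=[f"c{i}" for i in range(30)]),
            pd.Series(np.arange(30.0) + 6.0, index=[f"f{i}" for i in range(30)]),
        ])
        d = DistanceField("sp", vals)
        res = habitat_shift_score(
            self._occ(), {f"c{i}" for i in range(30)},
            {f"f{i}" for i in range(30)}, d,
        )
        assert 1.96 <= res.z < 3
        assert res.score == 1

    def test_empty_future_sentinel(self):
        res = habitat_shift_score(self._occ(), {"s0", "s1"}, set(), self._dist())
        assert res.score == 2 and math.isinf(res.z) and res.degenerate

    def test_empty_current_rejected(self):
        with pytest.raises(ValueError):
            habitat_shift_score(self._occ(), set(), {"s0"}, self._dist())


class TestThresholdSweep:
    def test_constant_series_scores_zero(self):
        # distances all zero: kernel is 1 at every level, S never moves
        idx = [f"s{i}" for i in range(10)]
        cur = surface(pd.Series(0.8, index=idx), tau=0.2)
        fut = surface(pd.Series(0.6, index=idx), tau=0.2, scenario="f")
        d = DistanceField("sp", pd.Series(0.0, index=idx))
        res = threshold_sweep(fut, cur, d, 300.0, 1080.0)
        assert res.score == 0
        assert all(abs(s) < 1e-9 for s in res.slopes.values())

    def test_closed_form_log_series_scores_three(self):
        levels = np.linspace(300.0, 1080.0, 30)
        S = -2.0 * np.log(levels) + 5.0
        score, slopes = sweep_score_from_series(levels, S)
        for s in slopes.values():
            assert s == pytest.approx(-2.0)
        assert score == 3

    def test_piecewise_steep_low_tercile_scores_one(self):
        levels = np.linspace(300.0, 1080.0, 30)
        S = np.full(30, 1.0)
        S[:10] = -3.0 * np.log(levels[:10]) + 20.0
        score, slopes = sweep_score_from_series(levels, S)
        assert slopes["low"] == pytest.approx(-3.0)
        assert abs(slopes["medium"]) < 1e-9 and abs(slopes["high"]) < 1e-9
        assert score == 1

    def test_all_degenerate_flags_and_scores_three(self):
        idx = [f"s{i}" for i in range(6)]
        cur = surface(pd.Series(0.9, index=idx), tau=0.5)
        fut = surface(pd.Series(0.1, index=idx), tau=0.5, scenario="f")
        d = DistanceField("sp", pd.Series(100.0, index=idx))
        res = threshold_sweep(fut, cur, d, 300.0, 630.0)
        assert res.score == 3 and res.degenerate

    def test_sweep_monotone_nonincreasing_S(self):
        rng = np.random.default_rng(12)
        idx = [f"s{i}" for i in range(40)]
        cur = surface(pd.Series(rng.uniform(0.4, 1.0, 40), index=idx), tau=0.3)
        fut = surface(pd.Series(rng.uniform(0.2, 1.0, 40), index=idx),
                      tau=0.3, scenario="f")
        d = DistanceField("sp", pd.Series(rng.uniform(0, 1500, 40), index=idx))
        res = threshold_sweep(fut, cur, d, 300.0, 1080.0)
        finite = res.S_values[np.isfinite(res.S_values)]
        assert np.all(np.diff(finite) <= 1e-9)
        assert all(s <= 1e-9 for s in res.slopes.values())

    def test_parameter_validation(self):
        idx = ["a"]
        cur = surface(pd.Series(0.9, index=idx))
        fut = surface(pd.Series(0.9, index=idx), scenario="f")
        d = DistanceField("sp", pd.Series(0.0, index=idx))
        with pytest.raises(ValueError):
            threshold_sweep(fut, cur, d, 630.0, 300.0)
        with pytest.raises(ValueError):
            threshold_sweep(fut, cur, d, 300.0, 630.0, n_levels=31)


class TestDispersalPressure:
    @pytest.mark.parametrize(
        "shift,sweep,total,pressured",
        [(2, 3, 5, True), (0, 0, 0, False), (1, 2, 3, True), (2, 0, 2, False)],
    )
    def test_combination(self, shift, sweep, total, pressured):
        res = dispersal_pressure(shift, sweep)
        assert res.total == total and res.pressured is pressured

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dispersal_pressure(3, 0)
        with pytest.raises(ValueError):
            dispersal_pressure(0, 4)
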