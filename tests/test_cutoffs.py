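"""Cutoff discovery: KDE, density difference, minor-group filter."""

import numpy as np
import pytest

from siristrat import SurvivalForest, discover_cutoffs, kde
from siristrat.cutoffs import (
    DensityEstimate,
    density_difference_maxima,
    filter_minor_groups,
    silverman_bandwidth,
)


class TestKde:
    def test_normal_density_at_zero(self):
        rng = np.random.default_rng(0)
        est = kde(rng.normal(size=10000))
        d0 = np.interp(0.0, est.grid, est.density)
        assert 0.36 <= d0 <= 0.44  # 1/sqrt(2*pi) within KDE bias

    def test_uniform_weights_equal_no_weights(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=500)
        a = kde(x)
        b = kde(x, weights=np.ones(500))
        assert np.allclose(a.density, b.density)
        assert a.bandwidth == b.bandwidth

    def test_two_point_sample_is_bimodal(self):
        est = kde(np.array([0.0, 10.0]))
        m0 = np.interp(0.0, est.grid, est.density)
        m10 = np.interp(10.0, est.grid, est.density)
        mid = np.interp(5.0, est.grid, est.density)
        assert m0 > mid and m10 > mid

    def test_unit_integral_by_trapezoid(self):
        rng = np.random.default_rng(2)
        est = kde(rng.lognormal(0, 0.8, 2000))
        assert np.trapezoid(est.density, est.grid) == pytest.approx(1.0, abs=1e-6)
        assert (est.density >= 0).all()

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError):
            kde(np.full(50, 3.0))

    def test_weighted_bandwidth_downweights_ignored_points(self):
        # points with zero weight must not influence the bandwidth
        x = np.concatenate([np.random.default_rng(3).normal(size=200), [1e3]])
        w = np.concatenate([np.ones(200), [0.0]])
        assert silverman_bandwidth(x, w) == pytest.approx(
            silverman_bandwidth(x[:-1], w[:-1])
        )


class TestDensityDifferenceMaxima:
    def test_identical_densities_yield_nothing(self):
        rng = np.random.default_rng(4)
        est = kde(rng.normal(size=1000))
        c, s = density_difference_maxima(est, est)
        assert len(c) == 0

    def test_concentrated_splits_over_broad_data(self):
        rng = np.random.default_rng(5)
        data = rng.lognormal(0.3, 0.8, 2000)
        bw = silverman_bandwidth(data, np.ones_like(data))
        splits = rng.normal(3.5, 0.1, 3000)
        c, s = density_difference_maxima(
            kde(splits, bandwidth=bw), kde(data, bandwidth=bw)
        )
        assert len(c) == 1
        grid_step = (data.max() - data.min() + 2 * bw) / 511
        assert abs(c[0] - 3.5) <= max(grid_step, 0.15)

    def test_two_separated_bumps_give_two_candidates(self):
        rng = np.random.default_rng(6)
        data = rng.uniform(0, 10, 4000)
        bw = 0.5
        splits = np.concatenate([rng.normal(2.5, 0.1, 2000), rng.normal(7.5, 0.1, 2000)])
        c, s = density_difference_maxima(
            kde(splits, bandwidth=bw), kde(data, bandwidth=bw)
        )
        assert len(c) == 2
        assert abs(c[0] - 2.5) < 0.3 and abs(c[1] - 7.5) < 0.3
        assert (s > 0).all()

    def test_plateau_resolves_to_leftmost_point(self):
        grid = np.linspace(0.0, 1.0, 11)
        d = np.array([0.0, 1.0, 2.0, 2.0, 2.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        base = np.zeros(11)
        a = DensityEstimate(grid=grid, density=d, bandwidth=0.1)
        b = DensityEstimate(grid=grid, density=base, bandwidth=0.1)
        c, s = density_difference_maxima(a, b, grid_size=11, min_ratio=0.0)
        assert len(c) == 1
        assert c[0] == pytest.approx(0.2)


class TestFilterMinorGroups:
    def test_tail_candidate_excluded(self):
        values = np.arange(1000.0)
        q95 = np.quantile(values, 0.95)
        out = filter_minor_groups([q95], [1.0], values)
        assert out.cutoffs == []
        assert len(out.excluded) == 1
        assert "minor group" in out.excluded[0]["reason"]

    def test_median_candidate_retained(self):
        values = np.arange(1000.0)
        out = filter_minor_groups([500.0], [1.0], values)
        assert out.cutoffs == [500.0]

    def test_interacting_candidates_greedy_rule(self):
        # 25th and 30th percentile, equal scores: interval between them
        # holds 5% < 10%, so only one survives (the lower by tie-break)
        values = np.arange(1000.0)
        q25, q30 = np.quantile(values, [0.25, 0.30])
        out = filter_minor_groups([q25, q30], [1.0, 1.0], values)
        assert len(out.cutoffs) == 1
        assert out.cutoffs[0] == pytest.approx(q25)

    def test_occupancy_invariant_holds_structurally(self):
        rng = np.random.default_rng(7)
        values = rng.lognormal(0.3, 0.8, 5000)
        cand = np.quantile(values, [0.05, 0.2, 0.5, 0.8, 0.97])
        out = filter_minor_groups(cand, [5, 4, 3, 2, 1], values)
        edges = [-np.inf] + out.cutoffs + [np.inf]
        for lo, hi in zip(edges[:-1], edges[1:]):
            assert np.mean((values >= lo) & (values < hi)) >= 0.10


def brute_force_discover(model, train, variable, min_prop=0.10, min_ratio=2.0):
    """Independent oracle: recompute the full composition with plain loops
    over the grid, checking local-maximum, positivity, concentration and
    occupancy conditions directly."""
    rules = model.split_rules(variable)
    thr = np.array([r.threshold for r in rules])
    w = np.array([r.node_size for r in rules], dtype=float)
    data = train[variable].to_numpy(dtype=float)
    bw = silverman_bandwidth(data, np.ones_like(data))

    def dens_at(points, x, wts):
        out = np.zeros(len(points))
        for i, p in enumerate(points):
            out[i] = np.sum(wts * np.exp(-0.5 * ((p - x) / bw) ** 2))
        return out / (wts.sum() * bw * np.sqrt(2 * np.pi))

    lo = min(thr.min(), data.min()) - bw
    hi = max(thr.max(), data.max()) + bw
    # evaluate each normalised density on its own grid, then resample
    gs = np.linspace(thr.min() - bw, thr.max() + bw, 512)
    gd = np.linspace(data.min() - bw, data.max() + bw, 512)
    ds_own = dens_at(gs, thr, w)
    ds_own /= np.trapezoid(ds_own, gs)
    dd_own = dens_at(gd, data, np.ones_like(data))
    dd_own /= np.trapezoid(dd_own, gd)
    grid = np.linspace(lo, hi, 512)
    ds = np.interp(grid, gs, ds_own, left=0, right=0)
    dd = np.interp(grid, gd, dd_own, left=0, right=0)
    diff = ds - dd
    cand = []
    for i in range(1, 511):
        if diff[i] > diff[i - 1] and diff[i] > diff[i + 1]:
            if diff[i] > 0 and ds[i] >= min_ratio * dd[i]:
                cand.append((diff[i], grid[i]))
    cand.sort(key=lambda t: (-t[0], t[1]))
    accepted = []
    for score, c in cand:
        trial = sorted(accepted + [c])
        edges = [-np.inf] + trial + [np.inf]
        ok = all(
            np.mean((data >= a) & (data < b)) >= min_prop
            for a, b in zip(edges[:-1], edges[1:])
        )
        if ok:
            accepted = trial
    return accepted


class TestDiscoverCutoffs:
    def test_agrees_with_brute_force_oracle_on_fixture_forest(self):
        rng = np.random.default_rng(8)
        data = rng.lognormal(0.3, 0.85, 400)
        train = __import__("pandas").DataFrame({"siri": data})
        trees = []
        for k in range(50):
            t = 3.5 + rng.normal(0, 0.15)
            trees.append([
                {"variable": "siri", "threshold": float(t), "node_size": 300,
                 "left": 1, "right": 2},
                {"variable": None, "threshold": None, "node_size": 150, "left": -1, "right": -1},
                {"variable": "siri", "threshold": float(rng.uniform(0.5, 3.0)),
                 "node_size": 50, "left": 4, "right": 5},
            ])
        model = SurvivalForest.from_node_lists(trees, ["siri"])
        cs = discover_cutoffs(model, train, "siri")
        oracle = brute_force_discover(model, train, "siri")
        assert cs.cutoffs == pytest.approx(oracle, abs=1e-9)
        assert len(cs.cutoffs) == 1 and 3.0 <= cs.cutoffs[0] <= 4.0

    def test_never_split_variable_flagged(self):
        model = SurvivalForest.from_node_lists(
            [[{"variable": None, "threshold": None, "node_size": 10, "left": -1, "right": -1}]],
            ["siri"],
        )
        train = __import__("pandas").DataFrame({"siri": np.arange(100.0)})
        cs = discover_cutoffs(model, train, "siri")
        assert cs.cutoffs == [] and cs.never_split

    def test_deterministic_for_fixed_model(self, small_forest, default_split):
        train, _ = default_split
        a = discover_cutoffs(small_forest, train, "siri")
        b = discover_cutoffs(small_forest, train, "siri")
        assert a.cutoffs == b.cutoffs and a.scores == b.scores

    @staticmethod
    def _recovering_train():
        import pandas as pd

        from siristrat import generate_cohort, split_cohort
        coh = generate_cohort(n=600, seed=5)
        part = split_cohort(coh, seed=5)
        return coh[part == "train_validation"].reset_index(drop=True)

    def test_scale_equivariance(self):
        train = self._recovering_train()
        c = 10.0
        scaled = train.copy()
        scaled["siri"] = scaled["siri"] * c
        f1 = SurvivalForest(n_trees=200, random_state=3).fit(train)
        f2 = SurvivalForest(n_trees=200, random_state=3).fit(scaled)
        cs1 = discover_cutoffs(f1, train, "siri")
        cs2 = discover_cutoffs(f2, scaled, "siri")
        assert len(cs1.cutoffs) == len(cs2.cutoffs)
        bw = silverman_bandwidth(scaled["siri"].to_numpy(), np.ones(len(scaled)))
        grid_step = (scaled["siri"].max() - scaled["siri"].min() + 2 * bw) / 511
        for a, b in zip(cs1.cutoffs, cs2.cutoffs):
            assert abs(a * c - b) <= grid_step + 1e-9

    def test_planted_threshold_recovered(self):
        train = self._recovering_train()
        forest = SurvivalForest(n_trees=200, random_state=5).fit(train)
        cs = discover_cutoffs(forest, train, "siri")
        assert len(cs.cutoffs) == 1
        assert 3.0 <= cs.cutoffs[0] <= 4.0

    def test_json_roundtrip(self, small_forest, default_split, tmp_path):
        train, _ = default_split
        cs = discover_cutoffs(small_forest, train, "siri")
        path = tmp_path / "cs.json"
        cs.save(path)
        import json

        from siristrat.cutoffs import CutoffSet
        back = CutoffSet.from_json(json.loads(path.read_text()))
        assert back.cutoffs == cs.cutoffs and back.variable == "siri"
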