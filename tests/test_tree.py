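"""Robust risk tree: discretization, growth constraints, merging, reference."""

import itertools

import numpy as np
import pandas as pd
import pytest

from siristrat import (
    RobustRiskTree,
    assign_groups,
    discretize,
    grow_tree,
    merge_leaves,
    parsimonious_reference_tree,
    true_risk_group,
)
from siristrat.cutoffs import CutoffSet
from siristrat.evaluate import km_survival_at, logrank_test


def _surv_df(groups_spec, seed=0):
    """Build a survival table from {label: (n, hazard)} with exponential
    event times and light uniform censoring."""
    rng = np.random.default_rng(seed)
    rows = []
    for label, (n, hz) in groups_spec.items():
        t = rng.exponential(1.0 / hz, n)
        c = rng.uniform(20, 60, n)
        rows.append(pd.DataFrame({
            "leaf": label,
            "time": np.minimum(t, c),
            "event": (t <= c).astype(int),
        }))
    return pd.concat(rows, ignore_index=True)


class TestDiscretize:
    def test_value_at_cutoff_goes_high(self):
        df = pd.DataFrame({"siri": [3.5, 3.49, 0.2]})
        out = discretize(df, [CutoffSet(variable="siri", cutoffs=[3.5])])
        assert out["siri"].tolist() == [">=3.5", "<3.5", "<3.5"]

    def test_kps_70_dichotomy(self):
        df = pd.DataFrame({"kps": [100.0, 90.0, 70.0, 60.0]})
        out = discretize(df, [CutoffSet(variable="kps", cutoffs=[75.0])])
        assert out["kps"].tolist() == [">=75", ">=75", "<75", "<75"]

    def test_multiple_cutoffs_interval_labels(self):
        df = pd.DataFrame({"bmi": [17.0, 27.0, 31.0]})
        out = discretize(df, [CutoffSet(variable="bmi", cutoffs=[25.0, 30.0])])
        assert out["bmi"].tolist() == ["<25", "[25,30)", ">=30"]

    def test_no_cutoffs_categorical_passthrough(self):
        df = pd.DataFrame({"smoking": ["never", "former"]})
        out = discretize(df, [CutoffSet(variable="smoking")])
        assert out["smoking"].tolist() == ["never", "former"]

    def test_no_cutoffs_few_level_numeric_becomes_categorical(self):
        df = pd.DataFrame({"kps": [100.0, 90.0, 60.0]})
        out = discretize(df, [CutoffSet(variable="kps")])
        assert out["kps"].tolist() == ["100", "90", "60"]

    def test_missing_stays_missing(self):
        df = pd.DataFrame({"siri": [np.nan, 4.0]})
        out = discretize(df, [CutoffSet(variable="siri", cutoffs=[3.5])])
        assert pd.isna(out["siri"].iloc[0]) and out["siri"].iloc[1] == ">=3.5"


class TestGrowTree:
    def test_single_strong_binary_covariate_gives_depth_one(self):
        df = _surv_df({"A": (150, 0.01), "B": (150, 0.06)}, seed=1)
        df = df.rename(columns={"leaf": "exposure"})
        tree = grow_tree(df, covariates=["exposure"])
        assert tree.depth() == 1
        assert tree.n_leaves_ == 2

    def test_structural_constraints_on_planted_cohorts(self, default_split):
        train, _ = default_split
        sets = {
            "siri": CutoffSet(variable="siri", cutoffs=[3.5]),
            "kps": CutoffSet(variable="kps"),
            "bmi": CutoffSet(variable="bmi", cutoffs=[27.0]),
        }
        d = discretize(train, sets)
        tree = grow_tree(d, covariates=["siri", "kps", "bmi", "smoking"])
        assert tree.depth() <= 3
        assert all(leaf.n >= 40 for leaf in tree.leaves_)

    def test_numeric_covariate_rejected(self, default_split):
        train, _ = default_split
        with pytest.raises(ValueError, match="numeric"):
            grow_tree(train, covariates=["siri", "smoking"])

    def test_tiny_cohort_yields_single_leaf(self):
        df = _surv_df({"A": (30, 0.02), "B": (30, 0.1)}, seed=2)
        df = df.rename(columns={"leaf": "exposure"})
        tree = grow_tree(df, covariates=["exposure"])  # 60 < 2*40
        assert tree.n_leaves_ == 1

    def test_three_level_smoking_grouping_discovered(self):
        """Given a strong never-vs-ever contrast, the grower receiving the
        raw 3-level smoking variable finds the {never} | {former, current}
        bipartition on its own."""
        rng = np.random.default_rng(21)
        n = 600
        smoking = rng.choice(["never", "former", "current"], n, p=[0.31, 0.54, 0.15])
        hz = np.where(smoking == "never", 0.006, 0.03)
        t = rng.exponential(1.0 / hz)
        c = rng.uniform(30, 80, n)
        df = pd.DataFrame({"smoking": smoking, "time": np.minimum(t, c),
                           "event": (t <= c).astype(int)})
        tree = grow_tree(df, covariates=["smoking"])
        root = tree.tree_
        assert not root.is_leaf
        assert root.left_levels in (frozenset({"never"}), frozenset({"current", "former"}))

    def test_path_never_tests_a_variable_twice(self, default_split):
        train, _ = default_split
        sets = {"siri": CutoffSet(variable="siri", cutoffs=[1.0, 3.5])}
        d = discretize(train, sets)
        tree = grow_tree(d, covariates=["siri", "smoking"])

        def walk(node, seen):
            if node.is_leaf:
                return True
            if node.variable in seen:
                return False
            return walk(node.left, seen | {node.variable}) and walk(
                node.right, seen | {node.variable}
            )

        assert walk(tree.tree_, set())


def exhaustive_contiguous_merge(leaf_data, n_groups):
    """Oracle: best contiguous partition of ranked leaves into n_groups,
    maximising the overall k-group log-rank statistic."""
    k = len(leaf_data)
    best_stat, best_part = -np.inf, None
    for edges in itertools.combinations(range(1, k), n_groups - 1):
        bounds = (0,) + edges + (k,)
        labels, times, events = [], [], []
        for g, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
            for i in range(a, b):
                t, e = leaf_data[i]
                labels += [g] * len(t)
                times.append(t)
                events.append(e)
        stat, _ = logrank_test(
            np.array(labels), np.concatenate(times), np.concatenate(events)
        )
        if stat > best_stat:
            best_stat, best_part = stat, bounds
    return best_part


class TestMergeLeaves:
    @staticmethod
    def _four_leaf_tree():
        """Hand-built depth-2 tree over two binary covariates u, v."""
        from siristrat.tree import _Node

        def leaf():
            return _Node(depth=2, n=0)

        left = _Node(depth=1, n=0, variable="v", left_levels=frozenset({"x"}),
                     left=leaf(), right=leaf())
        right = _Node(depth=1, n=0, variable="v", left_levels=frozenset({"x"}),
                      left=leaf(), right=leaf())
        root = _Node(depth=0, n=0, variable="u", left_levels=frozenset({"p"}),
                     left=left, right=right)
        tree = RobustRiskTree(covariates=["u", "v"])
        tree.feature_names_ = ["u", "v"]
        tree.tree_ = root
        return tree

    @staticmethod
    def _four_cell_df(hazards, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for (u, v), hz in hazards.items():
            n = 120
            t = rng.exponential(1.0 / hz, n)
            c = rng.uniform(30, 70, n)
            rows.append(pd.DataFrame({
                "u": u, "v": v, "leaf": u + v,
                "time": np.minimum(t, c), "event": (t <= c).astype(int),
            }))
        return pd.concat(rows, ignore_index=True)

    @pytest.mark.parametrize("seed", [3, 4, 5, 6])
    def test_greedy_agrees_with_exhaustive_on_separated_leaves(self, seed):
        hazards = {("p", "x"): 0.004, ("p", "y"): 0.006,
                   ("q", "x"): 0.030, ("q", "y"): 0.045}
        df = self._four_cell_df(hazards, seed)
        tree = merge_leaves(self._four_leaf_tree(), df, n_groups=3)
        order = sorted(
            df["leaf"].unique(),
            key=lambda g: -km_survival_at(
                df.loc[df["leaf"] == g, "time"], df.loc[df["leaf"] == g, "event"], 24.0
            ),
        )
        leaf_data = [
            (df.loc[df["leaf"] == g, "time"].to_numpy(),
             df.loc[df["leaf"] == g, "event"].to_numpy())
            for g in order
        ]
        part = exhaustive_contiguous_merge(leaf_data, 3)
        pred = tree.predict(df.assign(id=np.arange(len(df)).astype(str)))
        groups_by_leaf = {g: int(np.unique(pred[df["leaf"] == g])[0])
                          for g in df["leaf"].unique()}
        greedy_sizes = [
            sum(1 for g in order if groups_by_leaf[g] == grp)
            for grp in sorted(set(groups_by_leaf.values()))
        ]
        oracle_sizes = [b - a for a, b in zip(part[:-1], part[1:])]
        assert greedy_sizes == oracle_sizes

    def test_identical_leaves_merge_first(self):
        # two leaves share a hazard among four: they must end up together
        hazards = {("p", "x"): 0.005, ("p", "y"): 0.020,
                   ("q", "x"): 0.020, ("q", "y"): 0.080}
        df = self._four_cell_df(hazards, seed=7)
        tree = merge_leaves(self._four_leaf_tree(), df, n_groups=3)
        pred = tree.predict(df.assign(id=np.arange(len(df)).astype(str)))
        g_py = int(np.unique(pred[df["leaf"] == "py"])[0])
        g_qx = int(np.unique(pred[df["leaf"] == "qx"])[0])
        assert g_py == g_qx

    def test_identity_when_groups_equal_leaves(self):
        hazards = {("p", "x"): 0.004, ("p", "y"): 0.012,
                   ("q", "x"): 0.030, ("q", "y"): 0.080}
        df = self._four_cell_df(hazards, seed=8)
        tree = merge_leaves(self._four_leaf_tree(), df, n_groups=4)
        assert sorted({leaf.group for leaf in tree.leaves_}) == [1, 2, 3, 4]
        merge_leaves(tree, df, n_groups=2)
        assert len({leaf.group for leaf in tree.leaves_}) == 2

    def test_group_ordering_by_training_km(self, default_split):
        train, _ = default_split
        sets = {"siri": CutoffSet(variable="siri", cutoffs=[3.5]),
                "kps": CutoffSet(variable="kps")}
        d = discretize(train, sets)
        tree = grow_tree(d, covariates=["siri", "kps", "smoking"])
        g = tree.predict(d)
        surv = [
            km_survival_at(train["time"][g == k], train["event"][g == k], 24.0)
            for k in sorted(np.unique(g))
        ]
        assert all(a >= b - 1e-12 for a, b in zip(surv, surv[1:]))


class TestReferenceTreeAndAssignment:
    @pytest.mark.parametrize(
        "siri,kps,smoking,expected",
        [
            (5.0, 100, "never", 3),
            (1.0, 60, "never", 3),
            (1.0, 90, "former", 2),
            (1.0, 90, "current", 2),
            (1.0, 90, "never", 1),
        ],
    )
    def test_published_rule(self, siri, kps, smoking, expected):
        df = pd.DataFrame({"id": ["x"], "siri": [siri], "kps": [kps],
                           "bmi": [25.0], "smoking": [smoking]})
        assert parsimonious_reference_tree().predict(df)[0] == expected

    def test_agrees_with_generator_truth_everywhere(self, default_cohort):
        ref = parsimonious_reference_tree()
        assert np.array_equal(ref.predict(default_cohort), true_risk_group(default_cohort))

    def test_empty_cohort_empty_assignment(self):
        df = pd.DataFrame(columns=["id", "siri", "kps", "bmi", "smoking"])
        assert len(assign_groups(parsimonious_reference_tree(), df)) == 0

    def test_missing_covariate_error_names_patient(self):
        df = pd.DataFrame({"id": ["p7"], "siri": [1.0], "kps": [np.nan],
                           "bmi": [25.0], "smoking": ["never"]})
        with pytest.raises(ValueError, match="p7"):
            parsimonious_reference_tree().predict(df)

    def test_grown_tree_missing_path_covariate_names_patient(self):
        df = _surv_df({"A": (100, 0.01), "B": (100, 0.08)}, seed=9)
        df = df.rename(columns={"leaf": "exposure"})
        tree = grow_tree(df, covariates=["exposure"])
        probe = pd.DataFrame({"id": ["q1"], "exposure": [np.nan]})
        with pytest.raises(ValueError, match="q1"):
            tree.predict(probe)

    def test_json_and_rules_rendering(self, default_split, tmp_path):
        train, _ = default_split
        sets = {"siri": CutoffSet(variable="siri", cutoffs=[3.5])}
        d = discretize(train, sets)
        tree = grow_tree(d, covariates=["siri", "smoking"])
        tree.save(tmp_path / "tree.json")
        assert (tmp_path / "tree.json").stat().st_size > 0
        assert any("group" in r for r in tree.rules())
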