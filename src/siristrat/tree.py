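"""The robust risk tree: discretize, grow, merge into three risk groups.

Continuous predictors are first converted to interval labels at the
forest-derived cutoffs (value >= cutoff goes to the upper interval, so
SIRI 3.5 with cutoff 3.5 is "high").  A survival decision tree is then
grown on the all-categorical table by recursive binary partitioning of
category levels, maximising the two-group log-rank statistic at each
node, under hard interpretability constraints: maximum depth 3, minimum
leaf size 40, no variable tested twice on a path, and a significance
stop — a node is split only when its best log-rank statistic clears the
chi-square(1) critical value 3.84.  Ordinal variables (interval labels
from discretization, numeric band codes) admit only threshold splits,
which keeps the per-node search small enough for the 3.84 stop to hold
its nominal error under prognostically inert covariates; an optional
Bonferroni mode divides the level by the number of candidate splits
examined at the node for stricter control.  Finally the
leaves are merged into a small number of ordered risk groups: leaves are
ranked by training KM survival at 24 months and the least-separated
adjacent leaves (smallest pairwise log-rank statistic) are merged until
three groups remain, labelled 1 (best prognosis) to 3 (worst).

The published three-group rule (SIRI >= 3.5 -> worst group regardless of
anything else; low SIRI with KPS <= 70 -> worst group; otherwise
ever-smokers intermediate, never-smokers best) is available as a fixed
reference tree for external validation.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.base import BaseEstimator

from .cutoffs import CutoffSet
from .evaluate import km_survival_at, logrank_test

__all__ = [
    "discretize",
    "RobustRiskTree",
    "grow_tree",
    "merge_leaves",
    "assign_groups",
    "ParsimoniousReferenceTree",
    "parsimonious_reference_tree",
]

SPLIT_STAT_THRESHOLD = 3.84  # chi-square(1) at alpha = 0.05


def _interval_labels(cutoffs: list[float]) -> list[str]:
    edges = [-np.inf] + list(cutoffs) + [np.inf]
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if lo == -np.inf:
            labels.append(f"<{hi:g}")
        elif hi == np.inf:
            labels.append(f">={lo:g}")
        else:
            labels.append(f"[{lo:g},{hi:g})")
    return labels


def discretize(
    cohort: pd.DataFrame,
    cutoff_sets: list[CutoffSet] | dict[str, CutoffSet],
    max_passthrough_levels: int = 6,
) -> pd.DataFrame:
    """Replace continuous covariates by interval labels at their cutoffs.

    Convention: ``value >= cutoff`` goes to the upper interval.  A variable
    with no retained cutoffs passes through untouched when it is already
    categorical (or takes at most ``max_passthrough_levels`` distinct
    values, in which case its values become string categories).  Missing
    values stay missing.
    """
    if isinstance(cutoff_sets, dict):
        cutoff_sets = list(cutoff_sets.values())
    out = cohort.copy()
    for cs in cutoff_sets:
        var = cs.variable
        if var not in out.columns:
            raise ValueError(f"cutoff variable {var!r} not in table")
        col = out[var]
        if not cs.cutoffs:
            if pd.api.types.is_numeric_dtype(col):
                distinct = col.dropna().unique()
                if len(distinct) <= max_passthrough_levels:
                    out[var] = col.map(lambda v: f"{v:g}" if pd.notna(v) else np.nan)
                # else: left numeric; the tree grower will reject it
            continue
        labels = _interval_labels(cs.cutoffs)
        edges = [-np.inf] + list(cs.cutoffs) + [np.inf]
        idx = pd.cut(col, bins=edges, labels=False, right=False)
        out[var] = pd.Series(idx, index=out.index).map(
            lambda i: labels[int(i)] if pd.notna(i) else np.nan
        )
    return out


@dataclass
class _Node:
    depth: int
    n: int
    variable: str | None = None
    left_levels: frozenset = frozenset()
    left: "_Node | None" = None
    right: "_Node | None" = None
    leaf_id: int | None = None
    group: int | None = None
    km24: float | None = None

    @property
    def is_leaf(self) -> bool:
        return self.variable is None

    def to_json(self) -> dict:
        if self.is_leaf:
            return {"leaf": self.leaf_id, "group": self.group, "n": self.n,
                    "km24": self.km24}
        return {
            "variable": self.variable,
            "left_levels": sorted(self.left_levels),
            "n": self.n,
            "left": self.left.to_json(),
            "right": self.right.to_json(),
        }


def _bipartitions(levels: list[str]):
    """Non-trivial splits of a nominal level set into two branches, each once."""
    levels = sorted(levels)
    first, rest = levels[0], levels[1:]
    for r in range(len(rest) + 1):
        for combo in itertools.combinations(rest, r):
            left = frozenset((first,) + combo)
            if len(left) < len(levels):
                yield left


def _level_sort_key(label: str):
    """Numeric position of an interval/numeric level label, else None."""
    try:
        return float(label)
    except (TypeError, ValueError):
        pass
    s = str(label)
    try:
        if s.startswith("<"):
            return float(s[1:]) - 1e-9
        if s.startswith(">="):
            return float(s[2:])
        if s.startswith("[") and "," in s:
            return float(s[1:].split(",")[0])
    except ValueError:
        return None
    return None


def _ordered_prefix_splits(levels: list[str]):
    """Threshold splits of an ordered level set: each proper prefix."""
    for k in range(1, len(levels)):
        yield frozenset(levels[:k])


class RobustRiskTree(BaseEstimator):
    """Constrained survival decision tree over categorical covariates.

    Parameters
    ----------
    covariates : list of str or None
        Columns to grow on (all non-outcome, non-id columns by default).
    max_depth : int, default 3
    min_node_size : int, default 40
        Every leaf must retain at least this many training subjects.
    split_alpha : float, default 0.05
        A node becomes a leaf when its best log-rank statistic fails the
        chi-square(1) test at this level (0.05 -> the 3.84 threshold).
        With ``bonferroni=True`` the level is divided by the number of
        candidate splits evaluated at the node, giving family-wise
        control of the per-node search.
    n_groups : int, default 3
        Ordered risk groups after leaf merging.
    km_horizon : float, default 24 months
        Horizon at which leaves are ranked for merging and group ordering.
    ordered_levels : dict or None
        Explicit level order per variable.  By default a variable whose
        levels all parse as numbers or interval labels ("<3.5",
        "[3.5,5)", ">=5") is treated as ordinal and only threshold
        (prefix) splits are considered, as is standard for ordered
        factors; other variables are nominal and every bipartition of
        their levels is a candidate.

    Attributes
    ----------
    tree_ : root node; ``leaves_`` in ranked order; ``n_leaves_``.
    """

    def __init__(self, covariates=None, max_depth: int = 3, min_node_size: int = 40,
                 split_alpha: float = 0.05, bonferroni: bool = False,
                 n_groups: int = 3, km_horizon: float = 24.0, ordered_levels=None):
        self.covariates = covariates
        self.max_depth = max_depth
        self.min_node_size = min_node_size
        self.split_alpha = split_alpha
        self.bonferroni = bonferroni
        self.n_groups = n_groups
        self.km_horizon = km_horizon
        self.ordered_levels = ordered_levels

    # -- growing -------------------------------------------------------------

    def fit(self, cohort: pd.DataFrame, y=None):
        covs = self.covariates
        if covs is None:
            covs = [c for c in cohort.columns if c not in ("id", "time", "event")]
        for c in covs:
            if pd.api.types.is_numeric_dtype(cohort[c]):
                raise ValueError(f"covariate {c!r} is numeric; discretize first")
        time = cohort["time"].to_numpy(dtype=float)
        event = cohort["event"].to_numpy(dtype=int)
        X = cohort[covs].astype(object)
        self.feature_names_ = list(covs)
        self.ordered_levels_ = {}
        for c in covs:
            if self.ordered_levels is not None and c in self.ordered_levels:
                self.ordered_levels_[c] = list(self.ordered_levels[c])
            else:
                lv = [v for v in pd.unique(X[c]) if pd.notna(v)]
                keys = [_level_sort_key(v) for v in lv]
                if all(k is not None for k in keys):
                    self.ordered_levels_[c] = [v for _, v in sorted(zip(keys, lv))]
        self.tree_ = self._grow(X, time, event, depth=0, used=frozenset())
        self._collect_and_merge(X, time, event)
        return self

    def _grow(self, X, time, event, depth, used) -> _Node:
        n = len(time)
        node = _Node(depth=depth, n=n)
        if depth >= self.max_depth or n < 2 * self.min_node_size:
            return node
        best = None  # (stat, variable, left_levels)
        n_candidates = 0
        for var in self.feature_names_:
            if var in used:
                continue
            col = X[var].to_numpy()
            levels = sorted({v for v in col if pd.notna(v)})
            if len(levels) < 2:
                continue
            if var in self.ordered_levels_:
                order = [v for v in self.ordered_levels_[var] if v in levels]
                splits = _ordered_prefix_splits(order)
            else:
                splits = _bipartitions(levels)
            for left in splits:
                mask = np.isin(col, list(left))
                n_l, n_r = int(mask.sum()), int((~mask).sum())
                if n_l < self.min_node_size or n_r < self.min_node_size:
                    continue
                stat, _ = logrank_test(mask.astype(int), time, event)
                n_candidates += 1
                # maximise the statistic; ties break to the lexicographically
                # smallest (variable, levels) for determinism
                if best is None or stat > best[0] + 1e-12 or (
                    abs(stat - best[0]) <= 1e-12
                    and (var, tuple(sorted(left))) < (best[1], tuple(sorted(best[2])))
                ):
                    best = (stat, var, left)
        if best is None:
            return node
        alpha = self.split_alpha / n_candidates if self.bonferroni else self.split_alpha
        if best[0] < chi2.isf(alpha, df=1):
            return node
        stat, var, left = best
        col = X[var].to_numpy()
        mask = np.isin(col, list(left))
        node.variable = var
        node.left_levels = left
        node.left = self._grow(X[mask], time[mask], event[mask], depth + 1, used | {var})
        node.right = self._grow(X[~mask], time[~mask], event[~mask], depth + 1, used | {var})
        return node

    # -- merging leaves into ordered groups ----------------------------------

    def _leaf_masks(self, X) -> list[tuple[_Node, np.ndarray]]:
        out = []

        def walk(node, mask):
            if node.is_leaf:
                out.append((node, mask))
                return
            col = X[node.variable].to_numpy()
            left = np.isin(col, list(node.left_levels))
            walk(node.left, mask & left)
            walk(node.right, mask & ~left)

        walk(self.tree_, np.ones(len(X), dtype=bool))
        return out

    def _collect_and_merge(self, X, time, event):
        leaf_masks = self._leaf_masks(X)
        # rank leaves from best to worst training KM survival at the horizon
        ranked = sorted(
            leaf_masks,
            key=lambda lm: -km_survival_at(time[lm[1]], event[lm[1]], self.km_horizon),
        )
        for i, (leaf, mask) in enumerate(ranked):
            leaf.leaf_id = i
            leaf.km24 = km_survival_at(time[mask], event[mask], self.km_horizon)
        clusters = [[i] for i in range(len(ranked))]
        masks = [m for _, m in ranked]
        while len(clusters) > self.n_groups:
            stats = []
            for k in range(len(clusters) - 1):
                m_a = np.logical_or.reduce([masks[i] for i in clusters[k]])
                m_b = np.logical_or.reduce([masks[i] for i in clusters[k + 1]])
                both = m_a | m_b
                lab = m_b[both].astype(int)
                if event[both].sum() == 0 or len(np.unique(lab)) < 2:
                    stats.append(0.0)
                else:
                    stats.append(logrank_test(lab, time[both], event[both])[0])
            k = int(np.argmin(stats))
            clusters[k] = clusters[k] + clusters[k + 1]
            del clusters[k + 1]
        for g, cluster in enumerate(clusters, start=1):
            for i in cluster:
                ranked[i][0].group = g
        self.leaves_ = [leaf for leaf, _ in ranked]
        self.n_leaves_ = len(ranked)

    # -- prediction ----------------------------------------------------------

    def predict(self, cohort: pd.DataFrame) -> np.ndarray:
        """Route every patient to a leaf and return its risk group."""
        if len(cohort) == 0:
            return np.empty(0, dtype=int)
        ids = cohort["id"].to_numpy() if "id" in cohort.columns else np.arange(len(cohort))
        groups = np.empty(len(cohort), dtype=int)
        X = cohort.reset_index(drop=True)
        for i in range(len(X)):
            node = self.tree_
            while not node.is_leaf:
                v = X.at[i, node.variable]
                if pd.isna(v):
                    raise ValueError(
                        f"missing covariate {node.variable!r} on the path of patient {ids[i]!r}"
                    )
                node = node.left if v in node.left_levels else node.right
            groups[i] = node.group
        return groups

    # -- serialization -------------------------------------------------------

    def to_json(self) -> dict:
        return {
            "format": "siristrat-risktree-v1",
            "max_depth": self.max_depth,
            "min_node_size": self.min_node_size,
            "n_groups": self.n_groups,
            "tree": self.tree_.to_json(),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=2))

    def rules(self) -> list[str]:
        """Plain-text rule list, one line per leaf."""
        lines = []

        def walk(node, conds):
            if node.is_leaf:
                cond = " AND ".join(conds) if conds else "TRUE"
                lines.append(f"IF {cond} THEN group {node.group} (n={node.n})")
                return
            lv = "{" + ",".join(sorted(node.left_levels)) + "}"
            walk(node.left, conds + [f"{node.variable} in {lv}"])
            walk(node.right, conds + [f"{node.variable} not in {lv}"])

        walk(self.tree_, [])
        return lines

    def depth(self) -> int:
        def d(node):
            return 0 if node.is_leaf else 1 + max(d(node.left), d(node.right))

        return d(self.tree_)


def grow_tree(
    train: pd.DataFrame,
    covariates=None,
    max_depth: int = 3,
    min_node: int = 40,
    n_groups: int = 3,
) -> RobustRiskTree:
    """Grow and merge the constrained risk tree on a discretized cohort."""
    return RobustRiskTree(
        covariates=covariates, max_depth=max_depth, min_node_size=min_node, n_groups=n_groups
    ).fit(train)


def merge_leaves(tree: RobustRiskTree, train: pd.DataFrame, n_groups: int = 3) -> RobustRiskTree:
    """Re-merge an already-grown tree's leaves into ``n_groups`` groups."""
    tree.n_groups = n_groups
    covs = tree.feature_names_
    time = train["time"].to_numpy(dtype=float)
    event = train["event"].to_numpy(dtype=int)
    tree._collect_and_merge(train[covs].astype(object), time, event)
    return tree


def assign_groups(tree, cohort: pd.DataFrame) -> np.ndarray:
    return tree.predict(cohort)


class ParsimoniousReferenceTree:
    """The fixed published three-group rule on raw covariates.

    Group 3: SIRI >= 3.5 (regardless of other variables) or KPS <= 70;
    group 2: remaining ever-smokers; group 1: remaining never-smokers.
    """

    threshold_siri = 3.5
    threshold_kps = 70.0

    def predict(self, cohort: pd.DataFrame) -> np.ndarray:
        if len(cohort) == 0:
            return np.empty(0, dtype=int)
        for col in ("siri", "kps", "smoking"):
            if cohort[col].isna().any():
                bad = cohort.loc[cohort[col].isna(), "id"].tolist() if "id" in cohort else []
                raise ValueError(f"missing {col} for patients {bad}")
        siri = cohort["siri"].to_numpy(dtype=float)
        kps = cohort["kps"].to_numpy(dtype=float)
        ever = cohort["smoking"].isin(["former", "current"]).to_numpy()
        return np.where(
            (siri >= self.threshold_siri) | (kps <= self.threshold_kps),
            3,
            np.where(ever, 2, 1),
        ).astype(int)

    def rules(self) -> list[str]:
        return [
            "IF siri >= 3.5 THEN group 3",
            "IF siri < 3.5 AND kps <= 70 THEN group 3",
            "IF siri < 3.5 AND kps > 70 AND smoking in {former,current} THEN group 2",
            "IF siri < 3.5 AND kps > 70 AND smoking = never THEN group 1",
        ]


def parsimonious_reference_tree() -> ParsimoniousReferenceTree:
    return ParsimoniousReferenceTree()
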