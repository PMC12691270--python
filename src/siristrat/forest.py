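"""Random survival forest wrapper, risk scores, C-index, VIMP and AUC.

The forest itself is scikit-survival's ``RandomSurvivalForest`` (log-rank
splitting, 1000 trees, mtry = sqrt(p), minimum terminal node size 15, no
depth limit).  What this module adds around it:

* a cohort-table interface (categorical smoking encoded ordinally),
* a scalar risk score — the ensemble cumulative hazard summed over the
  training event-time grid (higher = worse prognosis),
* extraction of every internal-node split rule ``(variable, threshold,
  node_size)`` into a backend-agnostic node-list representation, which is
  what the cutoff-discovery algorithm consumes and what is persisted to
  JSON,
* Harrell's concordance index with explicit pair-evaluability rules,
  out-of-sample permutation variable importance, and IPCW time-dependent
  cumulative/dynamic AUC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sksurv.ensemble import RandomSurvivalForest
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

from .cohort import SMOKING_LEVELS

__all__ = [
    "SplitRule",
    "SurvivalForest",
    "fit_rsf",
    "harrell_cindex",
    "permutation_vimp",
    "time_dependent_auc",
    "extract_split_rules",
]

DEFAULT_COVARIATES = ["siri", "kps", "bmi", "smoking"]

_SMOKING_CODE = {lvl: i for i, lvl in enumerate(SMOKING_LEVELS)}


@dataclass(frozen=True)
class SplitRule:
    """One internal-node splitting rule harvested from one forest tree."""

    variable: str
    threshold: float
    node_size: int


def _encode_features(cohort: pd.DataFrame, covariates) -> np.ndarray:
    cols = []
    for c in covariates:
        if c == "smoking":
            s = cohort["smoking"].map(_SMOKING_CODE)
            if s.isna().any() and cohort["smoking"].notna().any():
                bad = cohort.loc[s.isna() & cohort["smoking"].notna(), "smoking"].unique()
                raise ValueError(f"unknown smoking levels {bad!r}")
            cols.append(s.to_numpy(dtype=float))
        else:
            cols.append(cohort[c].to_numpy(dtype=float))
    X = np.column_stack(cols)
    if np.isnan(X).any():
        raise ValueError("covariates must be complete (impute first)")
    return X


class SurvivalForest(BaseEstimator):
    """Random survival forest over a cohort table.

    Parameters
    ----------
    covariates : list of str, default ``["siri", "kps", "bmi", "smoking"]``
    n_trees : int, default 1000
    min_node : int, default 15
        Minimum terminal node size for the forest (the depth-3 / size-40
        constraints apply only to the robust risk tree, not here).
    random_state : int, default 0

    Attributes
    ----------
    rsf_ : fitted ``sksurv.ensemble.RandomSurvivalForest``
    feature_names_ : covariate roster
    nodes_ : per-tree node lists ``{variable, threshold, node_size,
        left, right}`` (``variable is None`` for leaves); the
        backend-agnostic representation used for split extraction and
        persistence.
    event_times_ : training event-time grid of the ensemble hazard.
    """

    def __init__(self, covariates=None, n_trees: int = 1000, min_node: int = 15,
                 random_state: int = 0):
        self.covariates = covariates
        self.n_trees = n_trees
        self.min_node = min_node
        self.random_state = random_state

    def fit(self, cohort: pd.DataFrame, y=None):
        covs = list(self.covariates) if self.covariates is not None else list(DEFAULT_COVARIATES)
        unknown = [c for c in covs if c not in cohort.columns]
        if unknown:
            raise ValueError(f"unknown covariates {unknown}")
        event = cohort["event"].to_numpy(dtype=int)
        if event.sum() < 2:
            raise ValueError("training data must contain at least 2 events")
        X = _encode_features(cohort, covs)
        yy = Surv.from_arrays(event=event.astype(bool), time=cohort["time"].to_numpy(dtype=float))
        self.rsf_ = RandomSurvivalForest(
            n_estimators=self.n_trees,
            min_samples_leaf=self.min_node,
            max_features="sqrt",
            random_state=self.random_state,
            n_jobs=1,
        )
        self.rsf_.fit(X, yy)
        self.feature_names_ = covs
        self.event_times_ = np.asarray(self.rsf_.unique_times_, dtype=float)
        self.nodes_ = [_sklearn_tree_to_nodes(est.tree_, covs) for est in self.rsf_.estimators_]
        return self

    def predict_risk(self, cohort: pd.DataFrame) -> np.ndarray:
        """Ensemble cumulative hazard summed over the event-time grid."""
        X = _encode_features(cohort, self.feature_names_)
        return np.asarray(self.rsf_.predict(X), dtype=float)

    def split_rules(self, variable: str) -> list[SplitRule]:
        """Every internal-node split on ``variable`` across all trees."""
        if variable not in self.feature_names_:
            raise ValueError(f"variable {variable!r} not in model roster {self.feature_names_}")
        rules = []
        for tree_nodes in self.nodes_:
            for node in tree_nodes:
                if node["variable"] == variable:
                    rules.append(
                        SplitRule(variable, float(node["threshold"]), int(node["node_size"]))
                    )
        return rules

    # -- persistence (documented JSON schema) --------------------------------

    def to_json(self) -> dict:
        return {
            "format": "siristrat-forest-v1",
            "feature_names": self.feature_names_,
            "n_trees": len(self.nodes_),
            "trees": self.nodes_,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json()))

    @classmethod
    def from_node_lists(cls, trees: list[list[dict]], feature_names: list[str]) -> "SurvivalForest":
        """Build a split-extraction-only model from explicit node lists.

        Used for hand-written fixture forests and for reloading persisted
        models; such a model supports ``split_rules`` but not prediction.
        """
        model = cls(covariates=feature_names)
        model.feature_names_ = list(feature_names)
        model.nodes_ = trees
        return model

    @classmethod
    def load(cls, path: str | Path) -> "SurvivalForest":
        payload = json.loads(Path(path).read_text())
        return cls.from_node_lists(payload["trees"], payload["feature_names"])


def _sklearn_tree_to_nodes(tree, feature_names) -> list[dict]:
    nodes = []
    for i in range(tree.node_count):
        f = tree.feature[i]
        if f >= 0:
            nodes.append(
                {
                    "variable": feature_names[f],
                    "threshold": float(tree.threshold[i]),
                    "node_size": int(tree.n_node_samples[i]),
                    "left": int(tree.children_left[i]),
                    "right": int(tree.children_right[i]),
                }
            )
        else:
            nodes.append(
                {
                    "variable": None,
                    "threshold": None,
                    "node_size": int(tree.n_node_samples[i]),
                    "left": -1,
                    "right": -1,
                }
            )
    return nodes


def fit_rsf(train: pd.DataFrame, covariates=None, seed: int = 0, n_trees: int = 1000) -> SurvivalForest:
    """Fit the default random survival forest on a training cohort."""
    return SurvivalForest(covariates=covariates, n_trees=n_trees, random_state=seed).fit(train)


def extract_split_rules(model: SurvivalForest, variable: str) -> list[SplitRule]:
    return model.split_rules(variable)


def harrell_cindex(risk, time, event) -> float:
    """Harrell's concordance index: concordant / evaluable pairs.

    A pair is evaluable iff the subject with the shorter observed time had
    the event, or the times are tied with exactly one event (the event
    subject counts as the shorter).  Tied-time pairs with two events, or
    pairs whose shorter time is censored, are not evaluable.  The pair is
    concordant when the shorter-lived subject has the higher risk; risk
    ties count 1/2.
    """
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if not (len(risk) == len(time) == len(event)):
        raise ValueError("risk, time and event must have equal lengths")
    # vectorised over all ordered pairs (i = candidate shorter subject)
    ti, tj = time[:, None], time[None, :]
    ri, rj = risk[:, None], risk[None, :]
    ei, ej = event[:, None].astype(bool), event[None, :].astype(bool)
    evaluable = (ei & (ti < tj)) | (ei & ~ej & (ti == tj))
    n_pairs = int(evaluable.sum())
    if n_pairs == 0:
        raise ValueError("no evaluable pairs (need at least one event before another time)")
    concordant = float((evaluable & (ri > rj)).sum())
    tied = float((evaluable & (ri == rj)).sum())
    return (concordant + 0.5 * tied) / n_pairs


def permutation_vimp(
    model: SurvivalForest,
    data: pd.DataFrame,
    variable: str,
    n_repeats: int = 10,
    seed: int = 0,
    shuffle: bool = True,
) -> float:
    """Permutation variable importance: mean drop in C-index on ``data``
    when ``variable``'s column is shuffled.

    Computed out-of-sample on the supplied (held-out) data rather than
    out-of-bag, which is equivalent in meaning and backend-independent.
    ``shuffle=False`` applies the identity permutation (importance is then
    exactly 0), which pins down the sign convention.
    """
    if variable not in model.feature_names_:
        raise ValueError(f"variable {variable!r} not in model roster")
    time = data["time"].to_numpy(dtype=float)
    event = data["event"].to_numpy(dtype=int)
    baseline = harrell_cindex(model.predict_risk(data), time, event)
    rng = np.random.default_rng(seed)
    drops = []
    for _ in range(n_repeats):
        shuffled = data.copy()
        col = shuffled[variable].to_numpy()
        perm = rng.permutation(len(col)) if shuffle else np.arange(len(col))
        shuffled[variable] = col[perm]
        drops.append(baseline - harrell_cindex(model.predict_risk(shuffled), time, event))
    return float(np.mean(drops))


def time_dependent_auc(risk, time, event, horizons, train_time=None, train_event=None):
    """Cumulative/dynamic AUC with IPCW at each horizon (months).

    Cases at horizon ``h`` are subjects with an event by ``h``; controls
    are those still at risk beyond ``h``; weights come from the censoring
    distribution of the training data (the evaluation data itself when no
    training outcomes are supplied).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int).astype(bool)
    horizons = np.atleast_1d(np.asarray(horizons, dtype=float))
    if horizons.max() >= time.max():
        raise ValueError("horizons must lie strictly within the observed follow-up range")
    y_test = Surv.from_arrays(event=event, time=time)
    if train_time is None:
        y_train = y_test
    else:
        y_train = Surv.from_arrays(
            event=np.asarray(train_event, dtype=int).astype(bool),
            time=np.asarray(train_time, dtype=float),
        )
    auc, _ = cumulative_dynamic_auc(y_train, y_test, np.asarray(risk, dtype=float), horizons)
    return np.asarray(auc, dtype=float)
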