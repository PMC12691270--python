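"""Covariate derivation, coding, imputation and the 70/30 cohort split.

SIRI is derived from the pre-treatment complete blood count as
``neutrophils * monocytes / lymphocytes`` (all in 10^9 cells/L, so the
index is dimensionless).  BMI is coded into the four standard WHO classes
and ECOG performance status is mapped onto the Karnofsky scale.  Missing
covariates are filled by iterative random-forest imputation (300 trees,
5 iterations by default) that never sees the outcome columns, and the
cohort is split 70/30 into training/validation and test sets before any
model fitting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .cohort import COVARIATE_COLUMNS, SMOKING_LEVELS

__all__ = [
    "compute_siri",
    "categorize_bmi",
    "map_ecog_to_kps",
    "recode_smoking_binary",
    "RandomForestImputer",
    "rf_impute",
    "split_cohort",
    "ECOG_TO_KPS",
    "BMI_CLASSES",
]

#: Fixed ECOG -> KPS mapping; only the KPS <= 70 dichotomy matters downstream.
ECOG_TO_KPS = {0: 100, 1: 90, 2: 60, 3: 40, 4: 20}

BMI_CLASSES = ["underweight", "normal", "overweight", "obese"]


def compute_siri(neutrophils, monocytes, lymphocytes):
    """SIRI = neutrophils * monocytes / lymphocytes (counts in 10^9 cells/L).

    Scale-consistent: multiplying all three counts by ``c`` multiplies the
    index by ``c``.  Raises on nonpositive lymphocytes or negative counts.
    """
    neutrophils = np.asarray(neutrophils, dtype=float)
    monocytes = np.asarray(monocytes, dtype=float)
    lymphocytes = np.asarray(lymphocytes, dtype=float)
    if np.any(lymphocytes <= 0):
        raise ValueError("lymphocyte count must be > 0")
    if np.any(neutrophils < 0) or np.any(monocytes < 0):
        raise ValueError("blood counts must be nonnegative")
    out = neutrophils * monocytes / lymphocytes
    return float(out) if out.ndim == 0 else out


def categorize_bmi(bmi):
    """WHO BMI classes with half-open boundaries.

    ``(0, 18.5)`` underweight, ``[18.5, 25)`` normal, ``[25, 30)``
    overweight, ``[30, inf)`` obese — every positive value maps to exactly
    one class.
    """
    arr = np.asarray(bmi, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("BMI must be > 0")
    idx = np.digitize(arr, [18.5, 25.0, 30.0])
    classes = np.asarray(BMI_CLASSES, dtype=object)[idx]
    return str(classes) if arr.ndim == 0 else classes


def map_ecog_to_kps(ecog):
    """ECOG 0-4 -> KPS via the standard correspondence (0->100 ... 4->20)."""
    arr = np.asarray(ecog)
    if not np.isin(arr, list(ECOG_TO_KPS)).all():
        raise ValueError(f"ECOG must be in {sorted(ECOG_TO_KPS)}")
    out = np.vectorize(ECOG_TO_KPS.get)(arr)
    return int(out) if arr.ndim == 0 else out


def recode_smoking_binary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Collapse smoking to {never, ever} (former and current grouped).

    Used for the risk tree, which groups current with former smokers; the
    raw three-level variable is preserved in the cohort table itself.
    """
    out = cohort.copy()
    obs = out["smoking"].notna()
    out.loc[obs, "smoking"] = np.where(
        out.loc[obs, "smoking"].isin(["former", "current"]), "ever", "never"
    )
    return out


class RandomForestImputer(BaseEstimator, TransformerMixin):
    """Iterative (missForest-style) random-forest imputation of covariates.

    ``fit`` learns on one partition only: columns are initialised with the
    training mean (numeric) or mode (categorical), then visited in order of
    increasing missingness for ``iterations`` full passes; each visit fits
    a random forest of ``n_trees`` on the rows where the column is observed,
    using the other covariates as predictors, and fills the missing cells
    with its predictions.  ``transform`` replays the stored initialisation
    and the per-pass fitted forests on new data in the same order, so the
    test partition never influences the fit.  Outcome columns are never
    read; observed cells are never altered.

    Parameters
    ----------
    columns : list of str, default covariate roster
        Columns eligible for imputation and used as predictors.
    n_trees : int, default 300
    iterations : int, default 5
        Full passes over the incomplete columns (fixed count, no
        convergence check).
    random_state : int, default 0
    """

    def __init__(self, columns=None, n_trees=300, iterations=5, random_state=0):
        self.columns = columns
        self.n_trees = n_trees
        self.iterations = iterations
        self.random_state = random_state

    def _cols(self, X):
        cols = self.columns if self.columns is not None else COVARIATE_COLUMNS
        missing = [c for c in cols if c not in X.columns]
        if missing:
            raise ValueError(f"columns {missing} not in table")
        return list(cols)

    @staticmethod
    def _is_categorical(s: pd.Series) -> bool:
        return not pd.api.types.is_numeric_dtype(s)

    def fit(self, X: pd.DataFrame, y=None):
        cols = self._cols(X)
        work = X[cols].copy()
        self.categorical_ = {c: self._is_categorical(work[c]) for c in cols}
        self.levels_ = {
            c: sorted(work[c].dropna().unique().tolist())
            for c in cols
            if self.categorical_[c]
        }
        for c in cols:
            if work[c].isna().all():
                raise ValueError(f"covariate {c!r} is entirely missing; nothing to learn")
        # initialisation statistics from the fitting partition
        self.init_fill_ = {}
        for c in cols:
            obs = work[c].dropna()
            self.init_fill_[c] = obs.mode().iloc[0] if self.categorical_[c] else float(obs.mean())
        incomplete = [c for c in cols if work[c].isna().any()]
        incomplete.sort(key=lambda c: (work[c].isna().mean(), c))
        self.visit_order_ = incomplete

        masks = {c: work[c].isna().to_numpy() for c in incomplete}
        filled = work.copy()
        for c in cols:
            filled[c] = filled[c].fillna(self.init_fill_[c])

        self.models_ = []  # [(column, fitted forest)] in replay order
        rs = np.random.RandomState(self.random_state)
        for _ in range(self.iterations):
            for c in incomplete:
                predictors = [p for p in cols if p != c]
                Xmat = self._encode(filled, predictors)
                obs = ~masks[c]
                if self.categorical_[c]:
                    model = RandomForestClassifier(
                        n_estimators=self.n_trees, random_state=rs.randint(2**31 - 1)
                    )
                    target = work.loc[obs, c].astype(str)
                else:
                    model = RandomForestRegressor(
                        n_estimators=self.n_trees, random_state=rs.randint(2**31 - 1)
                    )
                    target = work.loc[obs, c].astype(float)
                model.fit(Xmat[obs], target)
                if masks[c].any():
                    filled.loc[masks[c], c] = model.predict(Xmat[masks[c]])
                self.models_.append((c, predictors, model))
        self.columns_ = cols
        return self

    def _encode(self, df: pd.DataFrame, predictors) -> np.ndarray:
        mats = []
        for p in predictors:
            if self.categorical_[p]:
                codes = pd.Categorical(df[p].astype(str), categories=[str(v) for v in self.levels_[p]]).codes
                mats.append(codes.astype(float))
            else:
                mats.append(df[p].to_numpy(dtype=float))
        return np.column_stack(mats)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        cols = self.columns_
        masks = {c: out[c].isna().to_numpy() for c in cols}
        filled = out[cols].copy()
        for c in cols:
            filled[c] = filled[c].fillna(self.init_fill_[c])
        for c, predictors, model in self.models_:
            if masks[c].any():
                Xmat = self._encode(filled, predictors)
                filled.loc[masks[c], c] = model.predict(Xmat[masks[c]])
        for c in cols:
            if masks[c].any():
                out.loc[masks[c], c] = filled.loc[masks[c], c]
        return out


def rf_impute(
    cohort: pd.DataFrame,
    trees: int = 300,
    iterations: int = 5,
    seed: int = 0,
    columns=None,
    fit_mask=None,
) -> pd.DataFrame:
    """Impute missing covariates; outcome columns are neither read nor touched.

    ``fit_mask`` restricts the rows the imputer learns from (e.g. the
    training partition); the fitted imputer is then applied to all rows.
    """
    if "time" in cohort.columns and cohort["time"].notna().any():
        if cohort["time"].isna().any() or cohort["event"].isna().any():
            raise ValueError("(time, event) must be fully observed before imputation")
    imp = RandomForestImputer(
        columns=columns, n_trees=trees, iterations=iterations, random_state=seed
    )
    fit_data = cohort if fit_mask is None else cohort.loc[np.asarray(fit_mask)]
    imp.fit(fit_data)
    return imp.transform(cohort)


def split_cohort(cohort: pd.DataFrame, seed: int, train_frac: float = 0.7) -> pd.Series:
    """Random 70/30 partition into ``train_validation`` / ``test``.

    Exactly ``round(train_frac * n)`` subjects go to training/validation;
    deterministic under ``seed``.  Performed before any model fitting.
    """
    n = len(cohort)
    if n < 10:
        raise ValueError("cohort must have at least 10 subjects to split")
    n_train = int(round(train_frac * n))
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(10,)))
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=object)
    labels[perm[:n_train]] = "train_validation"
    labels[perm[n_train:]] = "test"
    return pd.Series(labels, index=cohort.index, name="partition")
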