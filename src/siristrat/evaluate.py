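"""Survival statistics for internal and external validation.

Kaplan–Meier curves with Greenwood standard errors, k-group log-rank
tests, pairwise Cox hazard ratios with Wald confidence intervals and
Holm–Bonferroni adjustment, percentile-based risk stratification,
calibration tables at a fixed horizon, and an intercept-only
recalibration on the complementary-log-log scale.  KM/log-rank/Cox are
delegated to lifelines (Breslow tie handling for Cox).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.optimize import brentq
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SurvivalCurve",
    "PairwiseHR",
    "km_estimate",
    "km_survival_at",
    "logrank_test",
    "cox_pairwise_hr",
    "holm_bonferroni",
    "percentile_risk_split",
    "calibration",
    "recalibrate",
    "RecalibrationResult",
    "stratification_report",
]


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate at the distinct event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    greenwood_se: np.ndarray

    def at(self, horizon: float) -> float:
        """Step-function value S(horizon)."""
        idx = np.searchsorted(self.times, horizon, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class PairwiseHR:
    comparison: str
    hr: float
    ci_low: float
    ci_high: float
    p_raw: float
    p_adjusted: float = np.nan
    flag: str | None = None


def _check_times(time) -> np.ndarray:
    time = np.asarray(time, dtype=float)
    if (time < 0).any():
        raise ValueError("survival times must be nonnegative")
    return time


def km_estimate(time, event) -> SurvivalCurve:
    """Kaplan–Meier product-limit estimate with Greenwood variance.

    Returned at the distinct event times (a fully censored sample gives an
    empty curve, i.e. survival identically 1).
    """
    time = _check_times(time)
    event = np.asarray(event, dtype=int)
    if len(time) == 0:
        raise ValueError("need at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    tab = kmf.event_table
    is_event = tab["observed"] > 0
    d = tab.loc[is_event, "observed"].to_numpy(dtype=float)
    n = tab.loc[is_event, "at_risk"].to_numpy(dtype=float)
    times = tab.index[is_event].to_numpy(dtype=float)
    surv = np.cumprod(1.0 - d / n)
    # Greenwood: var(S) = S^2 * cumsum(d / (n (n - d)))
    with np.errstate(divide="ignore", invalid="ignore"):
        gw = np.cumsum(np.where(n > d, d / (n * (n - d)), np.inf))
    se = np.where(np.isfinite(gw), surv * np.sqrt(gw), 0.0)
    return SurvivalCurve(times=times, survival=surv, at_risk=n, greenwood_se=se)


def km_survival_at(time, event, horizon: float) -> float:
    return km_estimate(time, event).at(horizon)


def logrank_test(groups, time, event):
    """k-group log-rank test; returns ``(chi2 statistic, two-sided p)``."""
    groups = np.asarray(groups)
    time = _check_times(time)
    event = np.asarray(event, dtype=int)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("log-rank test needs at least 2 non-empty groups")
    res = multivariate_logrank_test(time, groups, event)
    return float(res.test_statistic), float(res.p_value)


def cox_pairwise_hr(groups, time, event, reference=None) -> list[PairwiseHR]:
    """Two-group Cox models for every pair of groups (Breslow ties).

    For the pair ``(a, b)`` (labels sorted; ``reference`` first when
    given) the HR is the hazard of ``b`` relative to ``a`` with Wald 95%
    CI.  A pair in which one group has no events is flagged rather than
    dropped.  Holm-adjusted p-values are filled across the computed pairs.
    """
    groups = np.asarray(groups)
    time = _check_times(time)
    event = np.asarray(event, dtype=int)
    labels = sorted(pd.unique(groups).tolist())
    if reference is not None and reference in labels:
        labels = [reference] + [g for g in labels if g != reference]
    results: list[PairwiseHR] = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            mask = (groups == a) | (groups == b)
            name = f"{b} vs {a}"
            ev_a = event[(groups == a)].sum()
            ev_b = event[(groups == b)].sum()
            if ev_a == 0 or ev_b == 0:
                results.append(
                    PairwiseHR(name, np.nan, np.nan, np.nan, np.nan,
                               flag="no events in one group")
                )
                continue
            df = pd.DataFrame(
                {
                    "time": time[mask],
                    "event": event[mask],
                    "exposed": (groups[mask] == b).astype(int),
                }
            )
            cph = CoxPHFitter()
            cph.fit(df, duration_col="time", event_col="event")
            s = cph.summary.loc["exposed"]
            results.append(
                PairwiseHR(
                    comparison=name,
                    hr=float(s["exp(coef)"]),
                    ci_low=float(s["exp(coef) lower 95%"]),
                    ci_high=float(s["exp(coef) upper 95%"]),
                    p_raw=float(s["p"]),
                )
            )
    ok = [r for r in results if r.flag is None]
    if ok:
        adj = holm_bonferroni([r.p_raw for r in ok])
        adj_iter = iter(adj)
        results = [
            PairwiseHR(r.comparison, r.hr, r.ci_low, r.ci_high, r.p_raw,
                       next(adj_iter), r.flag)
            if r.flag is None
            else r
            for r in results
        ]
    return results


def holm_bonferroni(p_values) -> np.ndarray:
    """Step-down Holm adjustment, order-preserving relative to the input."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="holm")[1]


def percentile_risk_split(risk, q: float = 0.75) -> np.ndarray:
    """Label patients ``high`` when risk strictly exceeds the q-quantile
    (linear-interpolation definition); ties at the threshold are ``low``."""
    risk = np.asarray(risk, dtype=float)
    if len(risk) < 4:
        raise ValueError("need at least 4 subjects to stratify by percentile")
    thr = np.quantile(risk, q, method="linear")
    return np.where(risk > thr, "high", "low")


def calibration(predicted_survival, time, event, horizon: float, n_bins: int = 5) -> pd.DataFrame:
    """Predicted vs observed survival at ``horizon`` by quantile bin.

    Bins are quantile bins of the predicted survival; heavy ties can make
    fewer than ``n_bins`` distinct bins, in which case the coincident bins
    are merged (``pandas.qcut`` with duplicate edges dropped).  Observed
    survival is the KM estimate at the horizon within each bin.
    """
    pred = np.asarray(predicted_survival, dtype=float)
    time = _check_times(time)
    event = np.asarray(event, dtype=int)
    if horizon > time.max():
        raise ValueError("horizon lies beyond the observed follow-up")
    bins = pd.qcut(pred, q=n_bins, labels=False, duplicates="drop")
    if np.all(pd.isna(bins)):  # all predictions identical -> single bin
        bins = np.zeros(len(pred), dtype=int)
    rows = []
    for b in sorted(pd.unique(bins)):
        m = bins == b
        rows.append(
            {
                "bin": int(b),
                "n": int(m.sum()),
                "predicted": float(pred[m].mean()),
                "observed": km_survival_at(time[m], event[m], horizon),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RecalibrationResult:
    adjusted: np.ndarray
    shift: float


def recalibrate(predicted_survival, time, event, horizon: float) -> RecalibrationResult:
    """Intercept-only recalibration on the complementary-log-log scale.

    Shifts ``cloglog(S) = log(-log S)`` by a constant ``delta`` — i.e.
    ``S' = S ** exp(delta)`` — chosen so the mean adjusted prediction
    matches the observed marginal KM survival at the horizon.  Predictions
    are clipped to ``[1e-6, 1 - 1e-6]`` before transforming.
    """
    pred = np.clip(np.asarray(predicted_survival, dtype=float), 1e-6, 1 - 1e-6)
    target = km_survival_at(_check_times(time), np.asarray(event, dtype=int), horizon)
    target = float(np.clip(target, 1e-6, 1 - 1e-6))

    def gap(delta):
        return np.mean(pred ** np.exp(delta)) - target

    delta = float(brentq(gap, -20.0, 20.0))
    return RecalibrationResult(adjusted=pred ** np.exp(delta), shift=delta)


def stratification_report(
    groups,
    time,
    event,
    horizons=(12.0, 24.0, 36.0, 48.0, 60.0),
) -> dict:
    """KM summaries per group, overall log-rank, and Holm-adjusted pairwise
    Cox HRs — the standard validation readout for a grouped cohort."""
    groups = np.asarray(groups)
    time = _check_times(time)
    event = np.asarray(event, dtype=int)
    stat, p = logrank_test(groups, time, event)
    labels = sorted(pd.unique(groups).tolist())
    curves = {}
    for g in labels:
        m = groups == g
        curve = km_estimate(time[m], event[m])
        curves[str(g)] = {
            "n": int(m.sum()),
            "events": int(event[m].sum()),
            "survival_at": {str(h): curve.at(h) for h in horizons},
        }
    hrs = cox_pairwise_hr(groups, time, event)
    return {
        "logrank": {"statistic": stat, "p": p},
        "groups": curves,
        "pairwise_hr": [
            {
                "comparison": r.comparison,
                "hr": None if np.isnan(r.hr) else r.hr,
                "ci_low": None if np.isnan(r.ci_low) else r.ci_low,
                "ci_high": None if np.isnan(r.ci_high) else r.ci_high,
                "p_raw": None if np.isnan(r.p_raw) else r.p_raw,
                "p_adjusted": None if np.isnan(r.p_adjusted) else r.p_adjusted,
                "flag": r.flag,
            }
            for r in hrs
        ],
    }


def save_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))


def save_km_curves(groups, time, event, outdir: str | Path) -> list[Path]:
    """Write each group's KM curve as two-column text (time, survival)."""
    groups = np.asarray(groups)
    time = _check_times(time)
    event = np.asarray(event, dtype=int)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for g in sorted(pd.unique(groups).tolist()):
        m = groups == g
        curve = km_estimate(time[m], event[m])
        path = outdir / f"km_group_{g}.tsv"
        np.savetxt(
            path,
            np.column_stack([np.r_[0.0, curve.times], np.r_[1.0, curve.survival]]),
            delimiter="\t", header="time\tsurvival", comments="",
        )
        paths.append(path)
    return paths
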