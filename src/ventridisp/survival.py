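"""Prognostic analyses: median split, Kaplan-Meier, log-rank, Cox.

The cohort table carries per-subject imaging metrics (LVd, LVx, CEV, FHV),
clinical covariates (age, KPS) and right-censored outcomes (overall and
progression-free survival).  Missing covariates are handled by
complete-case analysis per model, with the n actually used reported on
the fit.

Kaplan-Meier estimation, the log-rank test and Cox proportional-hazards
fitting are delegated to lifelines; ties in the Cox partial likelihood use
the Efron correction, and per-covariate p-values are Wald, matching how
such models are conventionally tabulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .errors import ConvergenceError, DataError

__all__ = [
    "COVARIATE_COLUMNS",
    "CoxFit",
    "KMEstimate",
    "dichotomize_median",
    "km_estimate",
    "logrank_test",
    "cox_fit",
]

#: covariate menu -> cohort-table column (``*_high`` are derived splits)
COVARIATE_COLUMNS = {
    "lvd": "lvd_mm",
    "lvx": "lvx_mm",
    "cev": "cev_mm3",
    "fhv": "fhv_mm3",
    "age": "age_years",
    "kps": "kps",
}

OUTCOME_COLUMNS = {"os": ("os_days", "os_event"), "pfs": ("pfs_days", "pfs_event")}


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit survival curve plus the median survival time.

    ``median_days`` is the earliest time at which the estimated survival
    drops to 0.5 or below; ``None`` when the curve never reaches 0.5
    (e.g. heavy censoring or no events).
    """

    times: np.ndarray
    survival: np.ndarray
    median_days: float | None
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class CoxFit:
    """Cox proportional-hazards fit: one row per covariate.

    ``summary`` columns: coef, se, hazard_ratio, ci95_low, ci95_high,
    p_value (Wald).
    """

    summary: pd.DataFrame
    n_used: int
    n_events: int
    log_partial_likelihood: float
    converged: bool


def dichotomize_median(values) -> tuple[np.ndarray, float]:
    """Binary high/low labels at the sample median (high iff value > median).

    Values equal to the cutoff go to the low group.  Raises on a
    degenerate split (all values identical).
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise DataError("median split needs at least 2 values")
    cutoff = float(np.median(vals))
    labels = (vals > cutoff).astype(int)
    if labels.all() or not labels.any():
        if np.all(vals == vals[0]):
            raise DataError("degenerate split: all values identical")
    return labels, cutoff


def km_estimate(times, events) -> KMEstimate:
    """Product-limit (Kaplan-Meier) estimator under right censoring."""
    t = np.asarray(list(times), dtype=float)
    e = np.asarray(list(events), dtype=int)
    if t.size == 0 or t.size != e.size:
        raise DataError("times and events must be equal-length and nonempty")
    if np.any(t <= 0):
        raise DataError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    times_out = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    med = kmf.median_survival_time_
    median = None if np.isinf(med) else float(med)
    return KMEstimate(times=times_out, survival=surv, median_days=median,
                      n=int(t.size), n_events=int(e.sum()))


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p) with 1 df."""
    ta, tb = np.asarray(list(times_a), float), np.asarray(list(times_b), float)
    ea, eb = np.asarray(list(events_a), int), np.asarray(list(events_b), int)
    if ta.size == 0 or tb.size == 0:
        raise DataError("both groups must be non-empty")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def _build_design(table: pd.DataFrame, outcome: str,
                  covariates: list[str]) -> tuple[pd.DataFrame, str, str]:
    if outcome not in OUTCOME_COLUMNS:
        raise DataError(f"unknown outcome {outcome!r}; use 'os' or 'pfs'")
    tcol, ecol = OUTCOME_COLUMNS[outcome]
    cols = {}
    for cov in covariates:
        base = cov[:-5] if cov.endswith("_high") else cov
        if base not in COVARIATE_COLUMNS:
            raise DataError(f"unknown covariate {cov!r}")
        col = COVARIATE_COLUMNS[base]
        if col not in table.columns:
            raise DataError(f"cohort table lacks column {col!r} for {cov!r}")
        cols[cov] = col
    df = table[[tcol, ecol, *dict.fromkeys(cols.values())]].dropna()
    design = pd.DataFrame(index=df.index)
    design["_time"] = df[tcol].astype(float)
    design["_event"] = df[ecol].astype(int)
    for cov, col in cols.items():
        if cov.endswith("_high"):
            labels, _ = dichotomize_median(df[col])
            design[cov] = labels
        else:
            design[cov] = df[col].astype(float)
    return design, "_time", "_event"


def cox_fit(
    table: pd.DataFrame,
    outcome: str,
    covariates: list[str],
    ties: str = "efron",
) -> CoxFit:
    """Cox proportional-hazards regression on a cohort table.

    ``covariates`` draw from the menu ``lvd, lvx, cev, fhv, age, kps``,
    each optionally with a ``_high`` suffix for its median split (computed
    on the complete cases of this model).  Rows missing any required
    column are dropped (complete-case analysis); the returned fit reports
    the n actually used.
    """
    if ties != "efron":
        raise DataError("only the Efron ties correction is supported")
    design, tcol, ecol = _build_design(table, outcome, covariates)
    n = len(design)
    if n < 10 * len(covariates):
        warnings.warn(
            f"only {n} complete cases for {len(covariates)} covariates",
            stacklevel=2,
        )
    if n < 2 or design[ecol].sum() == 0:
        raise DataError("too few subjects or no events for a Cox fit")
    cph = CoxPHFitter()
    try:
        cph.fit(design, duration_col=tcol, event_col=ecol)
    except Exception as exc:  # lifelines raises its own convergence errors
        raise ConvergenceError(f"Cox fit failed: {exc}") from exc

    s = cph.summary
    summary = pd.DataFrame({
        "coef": s["coef"],
        "se": s["se(coef)"],
        "hazard_ratio": s["exp(coef)"],
        "ci95_low": np.exp(s["coef lower 95%"]),
        "ci95_high": np.exp(s["coef upper 95%"]),
        "p_value": s["p"],
    })
    summary.index.name = "covariate"
    return CoxFit(
        summary=summary,
        n_used=n,
        n_events=int(design[ecol].sum()),
        log_partial_likelihood=float(cph.log_likelihood_),
        converged=True,
    )
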