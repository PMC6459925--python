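"""Survival analysis: Kaplan-Meier, log-rank, and Cox models.

Thin, validated wrappers around lifelines with the conventions this
pipeline needs: an RFS/OS endpoint extracted from the cohort table, a
p = 1 convention for degenerate log-rank inputs, Efron tie handling in Cox
fits (event times are day-resolution, so ties happen), and the entry rule
that covariates with univariate hazard ratio >= 2 feed the multivariate
model.  A from-scratch partial-likelihood score test at beta = 0 (Breslow
ties) is provided because for a binary covariate it coincides with the
log-rank chi-square, a useful internal consistency check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from .types import ValidationError

__all__ = [
    "SurvivalCurve",
    "LogrankResult",
    "CoxResult",
    "km_fit",
    "logrank",
    "cox_fit",
    "cox_score_test",
    "multivariate_select",
]


@dataclass
class SurvivalCurve:
    """Product-limit estimate: step function defined at event times."""

    event_times: np.ndarray
    survival_prob: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): survival just after time t (1 before the first event)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival_prob[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival_prob,
                "at_risk": self.at_risk,
                "events": self.events,
            }
        )


@dataclass
class LogrankResult:
    chi2: float
    p: float
    degenerate: bool = False


@dataclass
class CoxResult:
    """Per-covariate hazard ratios with Wald 95% CIs and p-values."""

    model_type: str  # "univariate" | "multivariate"
    table: pd.DataFrame  # index covariate; columns hr, ci_low, ci_high, p
    flags: dict[str, str] = field(default_factory=dict)

    def hr(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "hr"])


def km_fit(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    All-censored input yields a flat curve at 1 (no event times).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValidationError("km_fit needs at least one observation")
    if (times <= 0).any():
        raise ValidationError("survival times must be strictly positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    ev = kmf.event_table
    ev = ev[ev["observed"] > 0]
    if ev.empty:
        return SurvivalCurve(
            event_times=np.array([]),
            survival_prob=np.array([]),
            at_risk=np.array([]),
            events=np.array([]),
        )
    surv = kmf.survival_function_at_times(ev.index.to_numpy()).to_numpy()
    return SurvivalCurve(
        event_times=ev.index.to_numpy(dtype=float),
        survival_prob=surv,
        at_risk=ev["at_risk"].to_numpy(dtype=float),
        events=ev["observed"].to_numpy(dtype=float),
    )


def logrank(times_a, events_a, times_b, events_b) -> LogrankResult:
    """Two-group log-rank test (observed minus expected, 1 df).

    Identical groups give statistic 0; with no events anywhere the test is
    undefined and p = 1 is returned with a degenerate flag.
    """
    ta = np.asarray(times_a, float)
    tb = np.asarray(times_b, float)
    ea = np.asarray(events_a, bool)
    eb = np.asarray(events_b, bool)
    if ta.size == 0 or tb.size == 0:
        raise ValidationError("both groups must be non-empty")
    if not ea.any() and not eb.any():
        return LogrankResult(chi2=0.0, p=1.0, degenerate=True)
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    chi2 = float(res.test_statistic)
    p = float(res.p_value)
    if not np.isfinite(chi2):  # identical groups can yield 0/0
        chi2, p = 0.0, 1.0
    return LogrankResult(chi2=chi2, p=p)


def cox_fit(
    covariates: pd.DataFrame,
    times,
    events,
    mode: str = "univariate",
) -> CoxResult | list[CoxResult]:
    """Cox proportional-hazards fit(s) with Efron tie handling.

    ``mode="univariate"`` fits one model per column and returns a single
    :class:`CoxResult` whose table has one row per covariate;
    ``mode="multivariate"`` fits all columns jointly.  Non-convergence or
    monotone likelihood (perfect separation) is flagged and the affected
    CI reported as unbounded.
    """
    if covariates.isna().any().any():
        raise ValidationError("missing covariate values are not allowed")
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    flags: dict[str, str] = {}

    def _fit_one(frame: pd.DataFrame) -> pd.DataFrame:
        df = frame.copy()
        df["_time"] = times
        df["_event"] = events
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="_time", event_col="_event")
        s = cph.summary
        return pd.DataFrame(
            {
                "hr": s["exp(coef)"],
                "ci_low": s["exp(coef) lower 95%"],
                "ci_high": s["exp(coef) upper 95%"],
                "p": s["p"],
            }
        )

    if mode == "univariate":
        rows = []
        for col in covariates.columns:
            try:
                rows.append(_fit_one(covariates[[col]]))
            except Exception as exc:  # monotone likelihood / separation
                flags[col] = f"fit failed: {exc}"
                rows.append(
                    pd.DataFrame(
                        {"hr": [np.nan], "ci_low": [0.0],
                         "ci_high": [np.inf], "p": [np.nan]},
                        index=[col],
                    )
                )
        return CoxResult("univariate", pd.concat(rows), flags)
    if mode == "multivariate":
        try:
            table = _fit_one(covariates)
        except Exception as exc:
            flags["__model__"] = f"fit failed: {exc}"
            table = pd.DataFrame(
                {"hr": np.nan, "ci_low": 0.0, "ci_high": np.inf, "p": np.nan},
                index=covariates.columns,
            )
        return CoxResult("multivariate", table, flags)
    raise ValidationError(f"unknown mode {mode!r}")


def cox_score_test(x, times, events) -> tuple[float, float]:
    """Partial-likelihood score test at beta = 0, Breslow ties.

    Returns (chi2, p) with 1 df.  For a binary covariate on tie-free data
    this equals the log-rank chi-square exactly.
    """
    x = np.asarray(x, float)
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    order = np.argsort(times, kind="stable")
    x, times, events = x[order], times[order], events[order]
    u = 0.0
    info = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        d = int((events & (times == t)).sum())
        xbar = x[at_risk].mean()
        var = x[at_risk].var()
        u += x[events & (times == t)].sum() - d * xbar
        info += d * var
    if info <= 0:
        return 0.0, 1.0
    chi2 = u * u / info
    from scipy.stats import chi2 as chi2_dist

    return float(chi2), float(chi2_dist.sf(chi2, df=1))


def multivariate_select(
    univariate: CoxResult, hr_threshold: float = 2.0
) -> list[str]:
    """Covariates whose univariate HR meets the entry threshold.

    Input order is preserved; an empty selection means the multivariate
    model is skipped.
    """
    picked = [
        c for c in univariate.table.index
        if np.isfinite(univariate.table.loc[c, "hr"])
        and univariate.table.loc[c, "hr"] >= hr_threshold
    ]
    return picked
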