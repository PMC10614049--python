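"""Statistical models for the difference series.

The interrupted time series (ITS) is the segmented regression

    D(t) = b0 + b1*time + b2*establishment + b3*time_since_establishment + e

where ``time`` runs over the pooled event window (e.g. -8..9),
``establishment`` indicates the post-establishment period and
``time_since_establishment`` counts elapsed post years. The establishment
year itself (t = 0) is coded as pre-intervention — management efforts are
assumed to start after establishment, so both intervention terms are 0 at
t = 0 and switch on at t = 1. b2 is the level change at establishment and
b3 the trend change per year thereafter.

A second, cohort-level regression tests whether effectiveness depends on
the establishment year by regressing per-cohort differences on years
since establishment, establishment year, and their interaction.

Mann-Kendall trend screens (with Bonferroni correction across screens)
guard the design: covariate imbalance must not trend with establishment
year, and the outcome trajectories themselves are tested for monotone
decline.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DesignError, InsufficientDataError
from .event_panel import EventSeries

ITS_TERMS = ("intercept", "pre_trend", "level_change", "trend_change")
COHORT_TERMS = ("intercept", "time_since_establishment", "establishment_year",
                "interaction")


def build_its_design(window: tuple[int, int] | np.ndarray) -> pd.DataFrame:
    """Design rows for the ITS coding.

    t <= 0 maps to (establishment, time_since) = (0, 0); t >= 1 to (1, t).
    ``time`` enters on its native scale (no recentring).
    """
    t = (np.arange(window[0], window[1] + 1)
         if isinstance(window, tuple) else np.asarray(window, dtype=int))
    if t.size < 4:
        raise DesignError(f"ITS needs at least 4 time points, got {t.size}")
    post = (t >= 1).astype(float)
    return pd.DataFrame(
        {"time": t.astype(float), "cf_establishment": post,
         "time_since_establishment": post * t}
    )


def _check_rank(exog: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        # name the offending columns via near-zero R diagonal of a QR
        diag = np.abs(np.diag(np.linalg.qr(exog, mode="r")))
        bad = [n for n, d in zip(names, diag) if d < 1e-10 * max(diag.max(), 1.0)]
        raise DesignError(f"rank-deficient design; collinear columns: {bad or names}")


class _OLSResultsBase:
    """Thin named wrapper around a statsmodels RegressionResults."""

    terms: tuple[str, ...] = ()

    def __init__(self, sm_results):
        self.sm_results = sm_results

    @property
    def params(self) -> pd.Series:
        return pd.Series(np.asarray(self.sm_results.params), index=self.terms)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.asarray(self.sm_results.bse), index=self.terms)

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(np.asarray(self.sm_results.pvalues), index=self.terms)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = np.asarray(self.sm_results.conf_int(alpha))
        return pd.DataFrame(ci, index=self.terms, columns=["lower", "upper"])

    @property
    def resid(self) -> np.ndarray:
        return np.asarray(self.sm_results.resid)

    @property
    def fittedvalues(self) -> np.ndarray:
        return np.asarray(self.sm_results.fittedvalues)

    @property
    def rsquared(self) -> float:
        return float(self.sm_results.rsquared)

    @property
    def nobs(self) -> int:
        return int(self.sm_results.nobs)

    def summary(self):
        return self.sm_results.summary(xname=list(self.terms))

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.params, "se": self.bse, "p": self.pvalues}
        ).rename_axis("term").reset_index()


class ITSResults(_OLSResultsBase):
    terms = ITS_TERMS

    @property
    def level_change(self) -> float:
        return float(self.params["level_change"])

    @property
    def trend_change(self) -> float:
        return float(self.params["trend_change"])


class InterruptedTimeSeries:
    """Segmented-regression model of an event-time difference series.

    Parameters
    ----------
    series
        An :class:`~cfimpact.event_panel.EventSeries`, or any object with
        ``t`` and ``diff`` arrays, or a (t, diff) pair of arrays.
    """

    def __init__(self, series: EventSeries | tuple):
        if isinstance(series, tuple):
            t, d = series
        else:
            t, d = series.t, series.diff
        self.t = np.asarray(t, dtype=int)
        self.endog = np.asarray(d, dtype=float)
        design = build_its_design(self.t)
        self.exog = sm.add_constant(design.to_numpy(), has_constant="add")
        self.exog_names = list(ITS_TERMS)
        _check_rank(self.exog, self.exog_names)

    @classmethod
    def from_series(cls, series: EventSeries) -> "InterruptedTimeSeries":
        return cls(series)

    def fit(self, cov_type: str = "nonrobust",
            hac_maxlags: int | None = None) -> ITSResults:
        """OLS fit; ``cov_type='HAC'`` gives Newey-West standard errors
        (off by default: the canonical analysis uses homoskedastic SEs)."""
        model = sm.OLS(self.endog, self.exog)
        if cov_type == "HAC":
            res = model.fit(cov_type="HAC",
                            cov_kwds={"maxlags": hac_maxlags or 1})
        else:
            res = model.fit()
        return ITSResults(res)


def fit_its(series: EventSeries | tuple, **kwargs) -> ITSResults:
    """Convenience: fit the ITS model in one call."""
    return InterruptedTimeSeries(series).fit(**kwargs)


class PostTrendResults(_OLSResultsBase):
    terms = ("intercept", "slope")


def fit_post_trend(series: EventSeries | tuple) -> PostTrendResults:
    """Simple OLS of D(t) on t over the post-establishment window (t >= 0).

    The intercept is the level difference at establishment, the slope the
    yearly change thereafter; run per outcome and stratum."""
    if isinstance(series, tuple):
        t, d = np.asarray(series[0]), np.asarray(series[1])
    else:
        t, d = series.t, series.diff
    keep = t >= 0
    t, d = t[keep], d[keep]
    if t.size < 3:
        raise DesignError(f"post-trend fit needs >= 3 points, got {t.size}")
    exog = sm.add_constant(t.astype(float), has_constant="add")
    return PostTrendResults(sm.OLS(d.astype(float), exog).fit())


class CohortRegressionResults(_OLSResultsBase):
    terms = COHORT_TERMS

    @property
    def interaction(self) -> float:
        return float(self.params["interaction"])


class CohortTrendModel:
    """OLS of per-cohort differences on time since establishment,
    establishment year (raw calendar year, matching the published
    coefficient scale) and their interaction.

    A negative interaction means recently established zones gain less per
    post-establishment year than older ones.
    """

    def __init__(self, panel: pd.DataFrame):
        required = {"est_year", "t", "diff"}
        if not required <= set(panel.columns):
            raise DesignError(f"cohort panel needs columns {sorted(required)}")
        if panel["est_year"].nunique() < 2:
            raise DesignError(
                "interaction unidentifiable with a single cohort"
            )
        t = panel["t"].to_numpy(float)
        y = panel["est_year"].to_numpy(float)
        X = np.column_stack([t, y, t * y])
        self.exog = sm.add_constant(X, has_constant="add")
        self.endog = panel["diff"].to_numpy(float)
        _check_rank(self.exog, list(COHORT_TERMS))

    def fit(self) -> CohortRegressionResults:
        return CohortRegressionResults(sm.OLS(self.endog, self.exog).fit())


def fit_cohort_regression(panel: pd.DataFrame) -> CohortRegressionResults:
    """Convenience: fit the establishment-year interaction model."""
    return CohortTrendModel(panel).fit()


@dataclass
class TrendTestResult:
    """Mann-Kendall trend test: S statistic, tau, tie-corrected variance,
    continuity-corrected z, and the two-sided normal p-value."""

    s: int
    tau: float
    var_s: float
    z: float
    p: float


def mann_kendall(values) -> TrendTestResult:
    """Mann-Kendall test for a monotone trend in a series.

    S sums the signs of all pairwise differences; its variance uses the
    tie correction sum t_k (t_k - 1)(2 t_k + 5)/18 over tied groups; z
    applies the +-1 continuity correction, and p is two-sided normal.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"Mann-Kendall needs n >= 3, got {n}")
    diff_sign = np.sign(x[None, :] - x[:, None])
    s = int(np.triu(diff_sign, k=1).sum())
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var_s = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    tau = s / (0.5 * n * (n - 1))
    if var_s <= 0:
        z = 0.0
    elif s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    p = float(2 * stats.norm.sf(abs(z)))
    return TrendTestResult(s=s, tau=float(tau), var_s=float(var_s), z=float(z), p=min(p, 1.0))


def bonferroni(pvalues, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, m * p)."""
    p = np.atleast_1d(np.asarray(pvalues, dtype=float))
    if m is None:
        m = p.size
    if m < 1:
        raise InsufficientDataError(f"number of tests must be >= 1, got {m}")
    return np.minimum(1.0, m * p)
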