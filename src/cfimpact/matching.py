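"""Phased exact + propensity-score matching with balance diagnostics.

Treated samples are matched cohort by cohort, from the oldest CF
establishment year to the newest. Within a phase, matching is exact on
the binary forest state in the establishment year and nearest-neighbour
on the propensity score (logistic regression of treatment on the eight
continuous confounders) for everything else, 1:1 and without replacement:
a control used in any phase is unavailable to every later phase. Balance
is assessed by the standardized mean difference (SMD), standardized by
the treated-group SD, and phases whose post-matching |SMD| exceeds 0.25
for any covariate are excluded wholesale.
"""
from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .covariates import COVARIATE_NAMES, PROPENSITY_COVARIATES, CovariateLayers
from .errors import (
    EmptyResultError,
    InsufficientDataError,
    SeparationWarning,
)

SMD_THRESHOLD = 0.25  # acceptable absolute SMD after matching


def compute_smd(treated: np.ndarray, control: np.ndarray) -> float:
    """Signed standardized mean difference.

    (mean_treated - mean_control) / sd_treated with the n-1 treated-group
    SD; the same formula is applied to binary covariates. A zero treated
    SD makes the SMD undefined: NaN is returned with a warning so callers
    report a flag rather than a silent 0.
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if treated.size < 2:
        raise InsufficientDataError("SMD needs at least 2 treated values")
    sd = treated.std(ddof=1)
    if sd == 0:
        warnings.warn("treated-group SD is 0; SMD undefined", stacklevel=2)
        return float("nan")
    return float((treated.mean() - control.mean()) / sd)


def _safe_smd(treated, control) -> float:
    """SMD for balance tables: NaN (flagged downstream) instead of an error
    when a cohort is too small or constant."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return compute_smd(treated, control)
        except InsufficientDataError:
            return float("nan")


def fit_propensity(
    treated_cov: pd.DataFrame,
    control_cov: pd.DataFrame,
    covariates: tuple[str, ...] = PROPENSITY_COVARIATES,
) -> tuple[np.ndarray, np.ndarray]:
    """Propensity scores from logistic regression of the treatment
    indicator on the continuous confounders.

    Covariates are standardized (pooled mean/SD) for numeric stability;
    zero-variance columns are dropped. On (quasi-)separation or a failed
    fit, a ridge-penalized logistic fit is used instead and a
    ``SeparationWarning`` is raised. Deterministic given the data.

    Returns (scores_treated, scores_control), each in (0, 1).
    """
    X = np.vstack(
        [treated_cov[list(covariates)].to_numpy(float),
         control_cov[list(covariates)].to_numpy(float)]
    )
    y = np.concatenate([np.ones(len(treated_cov)), np.zeros(len(control_cov))])
    if y.size == 0 or y.min() == y.max():
        raise InsufficientDataError("need at least one treated and one control sample")
    mu, sd = X.mean(axis=0), X.std(axis=0)
    keep = sd > 0
    Z = (X[:, keep] - mu[keep]) / sd[keep]
    exog = sm.add_constant(Z, has_constant="add")

    scores = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, exog).fit(disp=0, maxiter=200)
        p = np.asarray(res.predict(exog))
        converged = bool(getattr(res.mle_retvals, "get", lambda *a: True)("converged", True))
        eps = 1e-10
        separated = (p[y == 1].min() > p[y == 0].max()) and (
            p.min() < eps or p.max() > 1 - eps
        )
        if converged and not separated and np.isfinite(res.params).all():
            scores = p
    except Exception:  # statsmodels raises PerfectSeparationError and friends
        scores = None
    if scores is None:
        from sklearn.linear_model import LogisticRegression

        warnings.warn(
            "propensity model separation/non-convergence; using ridge-penalized fit",
            SeparationWarning,
            stacklevel=2,
        )
        clf = LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000)
        clf.fit(Z, y)
        scores = clf.predict_proba(Z)[:, 1]
    scores = np.clip(scores, 1e-12, 1 - 1e-12)
    return scores[: len(treated_cov)], scores[len(treated_cov):]


def exact_nn_match(
    treated: pd.DataFrame,
    controls: pd.DataFrame,
) -> pd.DataFrame:
    """Greedy 1:1 nearest-neighbour match on propensity score within exact
    forest-state strata, without replacement.

    Inputs need columns sample_id, score, forest_at_est. Treated units are
    processed in decreasing score order (ties by sample_id); each takes
    the unmatched control in its stratum with the smallest absolute score
    difference (distance ties resolved toward the lower control score,
    then the smaller control id). Treated units whose stratum is exhausted
    are left unmatched. No caliper is applied.
    """
    pairs = []
    pools: dict[float, list[tuple[float, int]]] = {}
    for stratum, grp in controls.groupby("forest_at_est"):
        pool = sorted(zip(grp["score"].tolist(), grp["sample_id"].tolist()))
        pools[float(stratum)] = pool
    order = treated.sort_values(["score", "sample_id"],
                                ascending=[False, True])
    for tid, t_score, t_stratum in zip(
        order["sample_id"].tolist(), order["score"].tolist(),
        order["forest_at_est"].tolist()
    ):
        pool = pools.get(float(t_stratum))
        if not pool:
            continue
        i = bisect.bisect_left(pool, (float(t_score), -1))
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(pool):
                d = abs(pool[j][0] - t_score)
                key = (d, pool[j][0], pool[j][1])
                if best is None or key < best[0]:
                    best = (key, j)
        if best is None:
            continue
        score_c, cid = pool.pop(best[1])
        pairs.append(
            {
                "treated_id": int(tid),
                "control_id": int(cid),
                "score_treated": float(t_score),
                "score_control": float(score_c),
                "forest_at_est": float(t_stratum),
            }
        )
    return pd.DataFrame(
        pairs,
        columns=["treated_id", "control_id", "score_treated", "score_control",
                 "forest_at_est"],
    )


@dataclass
class MatchResult:
    """Matched pairs, per-phase balance, and pooled balance diagnostics."""

    pairs: pd.DataFrame          # treated_id, control_id, est_year, scores, forest_at_est
    balance: pd.DataFrame        # est_year, covariate, smd_pre, smd_post, ns
    excluded_phases: list[int] = field(default_factory=list)
    n_unmatched: dict[int, int] = field(default_factory=dict)
    smd_covariates: tuple[str, ...] = COVARIATE_NAMES
    # per-phase covariate values backing pooled SMDs:
    # {est_year: {"pre": (treated_df, pool_df), "post": (treated_df, control_df)}}
    phase_values: dict = field(default_factory=dict)

    def phases(self) -> list[int]:
        return sorted(self.pairs["est_year"].unique().tolist())

    def _pooled(self, stage: str) -> pd.DataFrame:
        rows = []
        phases = self.phases()
        for cov in self.smd_covariates:
            t = np.concatenate(
                [self.phase_values[p][stage][0][cov].to_numpy(float) for p in phases]
            )
            c = np.concatenate(
                [self.phase_values[p][stage][1][cov].to_numpy(float) for p in phases]
            )
            smd = _safe_smd(t, c)
            rows.append({"covariate": cov, "smd": smd,
                         "n_treated": t.size, "n_control": c.size,
                         "undefined": not np.isfinite(smd)})
        return pd.DataFrame(rows)

    def pooled_balance(self) -> pd.DataFrame:
        """Pooled pre/post SMD per covariate across retained phases."""
        pre = self._pooled("pre").rename(columns={"smd": "smd_pre"})
        post = self._pooled("post").rename(columns={"smd": "smd_post"})
        return pre[["covariate", "smd_pre"]].merge(
            post[["covariate", "smd_post", "n_treated", "undefined"]], on="covariate"
        )

    def max_abs_smd(self, stage: str = "post") -> float:
        """Pooled max |SMD| over covariates with a defined SMD."""
        tab = self._pooled(stage)
        vals = tab.loc[~tab["undefined"], "smd"].abs()
        return float(vals.max()) if len(vals) else float("nan")


def phased_match(
    samples: pd.DataFrame,
    layers: CovariateLayers,
    propensity_covariates: tuple[str, ...] = PROPENSITY_COVARIATES,
    smd_covariates: tuple[str, ...] = COVARIATE_NAMES,
) -> MatchResult:
    """Sequential matching over establishment years, oldest first.

    At each phase the time-varying confounders are re-evaluated at that
    phase's establishment year for the cohort's treated samples and for
    every control not matched in an earlier phase. Establishment years
    with no treated samples are skipped. Matched controls leave the pool.
    """
    treated_all = samples[samples["group"] == "treated"]
    control_pool = samples[samples["group"] == "control"].copy()
    phase_years = sorted(int(y) for y in treated_all["est_year"].unique() if y >= 0)

    all_pairs, balance_rows = [], []
    n_unmatched: dict[int, int] = {}
    phase_values: dict = {}

    for year in phase_years:
        cohort = treated_all[treated_all["est_year"] == year]
        if cohort.empty or control_pool.empty:
            continue
        cov_t = layers.table(cohort, year)
        cov_c = layers.table(control_pool, year)
        s_t, s_c = fit_propensity(cov_t, cov_c, propensity_covariates)
        t_in = cov_t[["sample_id", "forest_at_est"]].copy()
        t_in["score"] = s_t
        c_in = cov_c[["sample_id", "forest_at_est"]].copy()
        c_in["score"] = s_c
        pairs = exact_nn_match(t_in, c_in)
        n_unmatched[year] = len(cohort) - len(pairs)
        if pairs.empty:
            continue
        pairs.insert(2, "est_year", year)
        matched_t = cov_t.set_index("sample_id").loc[pairs["treated_id"]].reset_index()
        matched_c = cov_c.set_index("sample_id").loc[pairs["control_id"]].reset_index()
        phase_values[year] = {"pre": (cov_t, cov_c), "post": (matched_t, matched_c)}
        for cov in smd_covariates:
            smd_pre = _safe_smd(cov_t[cov], cov_c[cov])
            smd_post = _safe_smd(matched_t[cov], matched_c[cov])
            balance_rows.append(
                {"est_year": year, "covariate": cov,
                 "smd_pre": smd_pre, "smd_post": smd_post,
                 "n_treated": len(pairs), "n_control_pool": len(control_pool)}
            )
        all_pairs.append(pairs)
        control_pool = control_pool[
            ~control_pool["sample_id"].isin(pairs["control_id"])
        ]

    pairs_df = (
        pd.concat(all_pairs, ignore_index=True)
        if all_pairs
        else pd.DataFrame(columns=["treated_id", "control_id", "est_year",
                                   "score_treated", "score_control", "forest_at_est"])
    )
    return MatchResult(
        pairs=pairs_df,
        balance=pd.DataFrame(balance_rows),
        n_unmatched=n_unmatched,
        smd_covariates=smd_covariates,
        phase_values=phase_values,
    )


def filter_balanced_phases(
    result: MatchResult, threshold: float = SMD_THRESHOLD
) -> MatchResult:
    """Drop every pair from phases whose post-matching max |SMD| exceeds
    ``threshold``; pooled balance is then recomputed on the survivors."""
    bal = result.balance
    by_phase = bal.groupby("est_year")["smd_post"].agg(
        lambda s: np.nanmax(np.abs(s.to_numpy(float))) if s.notna().any() else 0.0
    )
    bad = [int(y) for y, m in by_phase.items() if m > threshold]
    keep = ~result.pairs["est_year"].isin(bad)
    if not keep.any():
        raise EmptyResultError(
            f"all matching phases exceeded the |SMD| <= {threshold} rule"
        )
    return replace(
        result,
        pairs=result.pairs.loc[keep].reset_index(drop=True),
        balance=bal[~bal["est_year"].isin(bad)].reset_index(drop=True),
        excluded_phases=sorted(set(result.excluded_phases) | set(bad)),
        phase_values={y: v for y, v in result.phase_values.items() if y not in bad},
    )
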