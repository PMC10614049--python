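"""End-to-end orchestration: generate -> sample -> covariates -> match ->
event panel -> inference, with deterministic seeding, artifact output and
replicate aggregation for parameter-recovery experiments.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .covariates import COVARIATE_NAMES, CovariateLayers
from .errors import ConfigurationError, EmptyResultError
from .event_panel import (
    EventSeries,
    cohort_difference_series,
    difference_series,
    pooled_window,
    stratify_by_initial_condition,
)
from .inference import (
    CohortRegressionResults,
    ITSResults,
    PostTrendResults,
    bonferroni,
    fit_cohort_regression,
    fit_its,
    fit_post_trend,
    mann_kendall,
)
from .matching import MatchResult, filter_balanced_phases, phased_match
from .study_design import build_sample_frame
from .synthetic_landscape import GroundTruth, ScenarioConfig, generate_scenario

logger = logging.getLogger("cfimpact")

#: the five post-establishment data sets (outcome, stratum)
FIVE_DATASETS = (
    ("tcc", "forest"),
    ("forest", "forest"),
    ("tcc", "nonforest"),
    ("forest", "nonforest"),
    ("tcc", "forest_throughout"),
)


@dataclass
class RunConfig:
    """One pipeline run: a synthetic scenario (or a directory of saved
    inputs), the sampling design, and the matching/window policy."""

    scenario: ScenarioConfig | None = None
    input_dir: str | None = None
    sampling_fraction: float = 0.5
    buffer_radius: float = 126.0
    smd_threshold: float = 0.25
    post_window: tuple[int, int] = (0, 9)
    outcomes: tuple[str, ...] = ("tcc", "forest")
    include_forest_throughout: bool = True
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.scenario is None) == (self.input_dir is None):
            raise ConfigurationError(
                "exactly one of scenario / input_dir must be given"
            )
        if self.seed is None:
            raise ConfigurationError("a seed is mandatory")

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario.to_dict() if self.scenario else None,
            "input_dir": self.input_dir,
            "sampling_fraction": self.sampling_fraction,
            "buffer_radius": self.buffer_radius,
            "smd_threshold": self.smd_threshold,
            "post_window": list(self.post_window),
            "outcomes": list(self.outcomes),
            "include_forest_throughout": self.include_forest_throughout,
            "seed": self.seed,
            "output_dir": self.output_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("scenario"):
            d["scenario"] = ScenarioConfig.from_dict(d["scenario"])
        if "post_window" in d:
            d["post_window"] = tuple(d["post_window"])
        if "outcomes" in d:
            d["outcomes"] = tuple(d["outcomes"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


@dataclass
class PipelineResult:
    """Everything a run produces, from samples to fitted models."""

    config: RunConfig
    truth: GroundTruth | None
    samples: pd.DataFrame
    match: MatchResult
    match_forest_throughout: MatchResult | None
    window: tuple[int, int]
    series: dict[tuple[str, str], EventSeries]
    its: dict[str, ITSResults]
    post_trends: dict[tuple[str, str], PostTrendResults]
    cohort_fits: dict[tuple[str, str], CohortRegressionResults | None]
    trend_tests: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            "cfimpact pipeline run",
            f"  samples: {len(self.samples)} "
            f"({(self.samples['group'] == 'treated').sum()} treated)",
            f"  matched pairs: {len(self.match.pairs)} over phases "
            f"{self.match.phases()}; excluded phases: {self.match.excluded_phases}",
            f"  pooled max |SMD|: pre {self.match.max_abs_smd('pre'):.3f} -> "
            f"post {self.match.max_abs_smd('post'):.3f}",
            f"  pooled event window: [{self.window[0]}, {self.window[1]}]",
        ]
        for name, res in self.its.items():
            lines.append(
                f"  ITS {name}: level {res.level_change:+.3f} "
                f"(p={res.pvalues['level_change']:.3g}), "
                f"trend {res.trend_change:+.3f}/yr "
                f"(p={res.pvalues['trend_change']:.3g})"
            )
        for (outcome, stratum), res in self.cohort_fits.items():
            if res is not None:
                lines.append(
                    f"  cohort interaction {outcome}/{stratum}: "
                    f"{res.interaction:+.4f} (p={res.pvalues['interaction']:.3g})"
                )
        return "\n".join(lines)


def _trend_screens(match: MatchResult, series: dict) -> pd.DataFrame:
    """Mann-Kendall screens with Bonferroni correction.

    Two families: (a) does pre-matching imbalance trend with establishment
    year (per covariate, across retained phases); (b) do the matched
    trajectories themselves decline over event time."""
    rows = []
    bal = match.balance
    phases = sorted(bal["est_year"].unique())
    if len(phases) >= 3:
        for cov in match.smd_covariates:
            vals = (bal[bal["covariate"] == cov]
                    .set_index("est_year")["smd_pre"].reindex(phases))
            if vals.notna().all():
                mk = mann_kendall(vals.to_numpy())
                rows.append({"family": "smd_pre_by_phase", "name": cov,
                             "s": mk.s, "tau": mk.tau, "p": mk.p})
    for (outcome, stratum), s in series.items():
        if stratum != "all":
            continue
        for grp, vals in (("treated", s.mean_treated), ("control", s.mean_control)):
            mk = mann_kendall(vals)
            rows.append({"family": "trajectory", "name": f"{outcome}_{grp}",
                         "s": mk.s, "tau": mk.tau, "p": mk.p})
            post = vals[s.t >= 0]
            if post.size >= 3:
                mk_post = mann_kendall(post)
                rows.append({"family": "trajectory_post",
                             "name": f"{outcome}_{grp}",
                             "s": mk_post.s, "tau": mk_post.tau, "p": mk_post.p})
    out = pd.DataFrame(rows, columns=["family", "name", "s", "tau", "p"])
    if not out.empty:
        out["p_bonferroni"] = np.nan
        for fam, grp in out.groupby("family"):
            out.loc[grp.index, "p_bonferroni"] = bonferroni(
                grp["p"].to_numpy(), len(grp)
            )
    return out


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage in order on one seeded scenario."""
    if config.input_dir is not None:
        from . import io as _io

        panel = _io.load_panel(config.input_dir)
        zones = _io.load_zones(config.input_dir, panel.shape, panel.cell_size,
                               panel.origin)
        surfaces = _io.load_surfaces(config.input_dir, panel.cell_size)
        truth = None
        scenario_dict = None
    else:
        scen_seed, = _child_seeds(config.seed, 1)
        scenario = replace(config.scenario, seed=scen_seed)
        scenario_dict = scenario.to_dict()
        surfaces, zones, truth, panel = generate_scenario(scenario)

    _, sample_seed = _child_seeds(config.seed, 2)
    samples = build_sample_frame(
        panel, zones, config.sampling_fraction, sample_seed,
        buffer_radius=config.buffer_radius,
    )
    logger.info("sample frame: %d samples (%d treated)", len(samples),
                (samples["group"] == "treated").sum())

    layers = CovariateLayers(panel, surfaces, buffer_radius=config.buffer_radius)
    match = filter_balanced_phases(phased_match(samples, layers),
                                   config.smd_threshold)

    match_ft = None
    if config.include_forest_throughout:
        ft_mask = panel.forest_throughout
        ft_samples = samples[
            ft_mask[samples["row"].to_numpy(), samples["col"].to_numpy()]
        ]
        smd_ft = tuple(c for c in COVARIATE_NAMES if c != "forest_at_est")
        try:
            match_ft = filter_balanced_phases(
                phased_match(ft_samples, layers, smd_covariates=smd_ft),
                config.smd_threshold,
            )
        except (EmptyResultError, ValueError) as exc:
            logger.warning("forest-throughout matching skipped: %s", exc)
            match_ft = None

    window = pooled_window(match.phases(), panel.years)
    strata = stratify_by_initial_condition(
        match.pairs, match_ft.pairs if match_ft is not None else None
    )

    series: dict[tuple[str, str], EventSeries] = {}
    for outcome in config.outcomes:
        series[(outcome, "all")] = difference_series(
            match.pairs, samples, panel, outcome, window, "all"
        )
    if match_ft is not None and not match_ft.pairs.empty:
        wft = pooled_window(match_ft.phases(), panel.years)
        wft = (max(wft[0], window[0]), min(wft[1], window[1]))
        series[("tcc", "forest_throughout")] = difference_series(
            match_ft.pairs, samples, panel, "tcc", wft, "forest_throughout"
        )
    for outcome in config.outcomes:
        for stratum in ("forest", "nonforest"):
            pairs = strata[stratum]
            if pairs.empty:
                continue
            w = pooled_window(sorted(pairs["est_year"].unique()), panel.years)
            w = (max(w[0], window[0]), min(w[1], window[1]))
            series[(outcome, stratum)] = difference_series(
                pairs, samples, panel, outcome, w, stratum
            )

    its = {
        name: fit_its(series[key])
        for name, key in (
            ("tcc", ("tcc", "all")),
            ("forest", ("forest", "all")),
            ("tcc_forest_throughout", ("tcc", "forest_throughout")),
        )
        if key in series
    }

    post_trends = {}
    cohort_fits: dict[tuple[str, str], CohortRegressionResults | None] = {}
    for outcome, stratum in FIVE_DATASETS:
        key = (outcome, stratum)
        if key not in series:
            cohort_fits[key] = None
            continue
        post_trends[key] = fit_post_trend(series[key])
        pairs = (match_ft.pairs if stratum == "forest_throughout" and match_ft
                 else strata.get(stratum))
        try:
            panel_df = cohort_difference_series(
                pairs, samples, panel, outcome, config.post_window
            )
            cohort_fits[key] = fit_cohort_regression(panel_df)
        except Exception as exc:  # single cohort / empty stratum
            logger.warning("cohort regression %s skipped: %s", key, exc)
            cohort_fits[key] = None

    trend_tests = _trend_screens(match, series)

    result = PipelineResult(
        config=config, truth=truth, samples=samples, match=match,
        match_forest_throughout=match_ft, window=window, series=series,
        its=its, post_trends=post_trends, cohort_fits=cohort_fits,
        trend_tests=trend_tests,
    )
    if config.output_dir:
        result.manifest = write_run_artifacts(result, Path(config.output_dir),
                                              scenario_dict)
    return result


def write_run_artifacts(result: PipelineResult, outdir: Path,
                        scenario_dict: dict | None = None) -> dict:
    """Persist every intermediate as CSV plus a manifest with config hash."""
    from . import io as _io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    def _write(df: pd.DataFrame, name: str):
        p = outdir / name
        df.to_csv(p, index=False)
        paths.append(p)

    _write(result.samples, "samples.csv")
    _write(result.match.pairs, "pairs.csv")
    _write(result.match.balance, "balance.csv")
    _write(result.match.pooled_balance(), "balance_pooled.csv")
    if result.match_forest_throughout is not None:
        _write(result.match_forest_throughout.pairs, "pairs_forest_throughout.csv")
        _write(result.match_forest_throughout.balance,
               "balance_forest_throughout.csv")
    _write(
        pd.concat([s.to_frame() for s in result.series.values()],
                  ignore_index=True),
        "event_series.csv",
    )
    fits = []
    for name, res in result.its.items():
        tab = res.coef_table()
        tab.insert(0, "model", f"its_{name}")
        fits.append(tab)
    for (outcome, stratum), res in result.post_trends.items():
        tab = res.coef_table()
        tab.insert(0, "model", f"post_trend_{outcome}_{stratum}")
        fits.append(tab)
    for (outcome, stratum), res in result.cohort_fits.items():
        if res is None:
            continue
        tab = res.coef_table()
        tab.insert(0, "model", f"cohort_{outcome}_{stratum}")
        fits.append(tab)
    _write(pd.concat(fits, ignore_index=True), "fits.csv")
    if not result.trend_tests.empty:
        _write(result.trend_tests, "trend_tests.csv")
    if result.truth is not None:
        _write(result.truth.table, "ground_truth.csv")

    config_dict = result.config.to_dict()
    config_dict.pop("output_dir", None)  # hash the science, not the destination
    if scenario_dict is not None:
        config_dict["scenario"] = scenario_dict
    mp = _io.write_manifest(outdir, config_dict, result.config.seed, paths)
    return yaml.safe_load(mp.read_text())


@dataclass
class ReplicateStudy:
    """Per-replicate estimates and recovery diagnostics."""

    frame: pd.DataFrame
    truth_level: float
    truth_trend: float

    def summary(self) -> dict:
        f = self.frame
        n = len(f)
        out = {
            "n_replicates": n,
            "mean_level_change": float(f["level_change"].mean()),
            "mean_trend_change": float(f["trend_change"].mean()),
            "sd_level_change": float(f["level_change"].std(ddof=1)),
            "sd_trend_change": float(f["trend_change"].std(ddof=1)),
            "mc_se_level": float(f["level_change"].std(ddof=1) / np.sqrt(n)),
            "mc_se_trend": float(f["trend_change"].std(ddof=1) / np.sqrt(n)),
            "bias_level": float(f["level_change"].mean() - self.truth_level),
            "bias_trend": float(f["trend_change"].mean() - self.truth_trend),
            "rmse_level": float(
                np.sqrt(((f["level_change"] - self.truth_level) ** 2).mean())
            ),
            "rmse_trend": float(
                np.sqrt(((f["trend_change"] - self.truth_trend) ** 2).mean())
            ),
            "coverage_level": float(
                ((f["level_lo"] <= self.truth_level)
                 & (self.truth_level <= f["level_hi"])).mean()
            ),
            "coverage_trend": float(
                ((f["trend_lo"] <= self.truth_trend)
                 & (self.truth_trend <= f["trend_hi"])).mean()
            ),
            "rejection_rate_level": float((f["p_level"] < 0.05).mean()),
            "mean_max_smd_pre": float(f["max_smd_pre"].mean()),
            "mean_max_smd_post": float(f["max_smd_post"].mean()),
            "balance_ok_rate": float((f["max_smd_post"] < 0.25).mean()),
            "balance_improved_rate": float(
                (f["max_smd_post"] < f["max_smd_pre"]).mean()
            ),
        }
        if "cohort_interaction" in f and f["cohort_interaction"].notna().any():
            ci = f["cohort_interaction"].dropna()
            out["mean_cohort_interaction"] = float(ci.mean())
            out["negative_interaction_rate"] = float((ci < 0).mean())
        return out


def replicate_study(
    config: RunConfig,
    n_replicates: int,
    include_cohort: bool = False,
) -> ReplicateStudy:
    """Run the pipeline over ``n_replicates`` derived seeds and aggregate
    the TCC ITS estimates against the injected ground truth."""
    if n_replicates < 2:
        raise ConfigurationError("need at least 2 replicates to aggregate")
    seeds = _child_seeds(config.seed, n_replicates + 8)[8:]
    rows = []
    for i, seed in enumerate(seeds):
        rep = replace(config, seed=int(seed), output_dir=None)
        res = run_pipeline(rep)
        its = res.its["tcc"]
        ci = its.conf_int()
        row = {
            "replicate": i,
            "seed": int(seed),
            "level_change": its.level_change,
            "trend_change": its.trend_change,
            "level_lo": ci.loc["level_change", "lower"],
            "level_hi": ci.loc["level_change", "upper"],
            "trend_lo": ci.loc["trend_change", "lower"],
            "trend_hi": ci.loc["trend_change", "upper"],
            "p_level": its.pvalues["level_change"],
            "p_trend": its.pvalues["trend_change"],
            "max_smd_pre": res.match.max_abs_smd("pre"),
            "max_smd_post": res.match.max_abs_smd("post"),
            "n_pairs": len(res.match.pairs),
        }
        if include_cohort:
            fit = res.cohort_fits.get(("tcc", "forest"))
            row["cohort_interaction"] = fit.interaction if fit else np.nan
        rows.append(row)
    scenario = config.scenario
    return ReplicateStudy(
        frame=pd.DataFrame(rows),
        truth_level=scenario.effect_level if scenario else np.nan,
        truth_trend=scenario.effect_trend if scenario else np.nan,
    )
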