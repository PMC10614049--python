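"""Event-time realignment and the treated-minus-control difference series.

Calendar outcomes are re-indexed to event time t = year - establishment
year (controls inherit their matched partner's establishment year; t = 0
is the establishment year itself). Cohorts are pooled over the window all
retained cohorts observe in full, and the ITS dependent variable is the
difference D(t) between the treated and control group means at each t.
Forest cover means are scaled x100 so effects read in percentage points.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CoverageError, DesignError, PairingError
from .panel import LandscapePanel


@dataclass
class EventSeries:
    """D(t) = mean_treated(t) - mean_control(t) over a pooled event window."""

    outcome: str                 # 'tcc' (percent) or 'forest' (percentage points)
    stratum: str
    t: np.ndarray
    mean_treated: np.ndarray
    mean_control: np.ndarray
    diff: np.ndarray
    n: np.ndarray                # contributing pair count at each t

    def __post_init__(self) -> None:
        if not np.allclose(self.diff, self.mean_treated - self.mean_control):
            raise CoverageError("difference series must equal treated - control means")
        if (self.n <= 0).any():
            raise CoverageError("every reported event time needs contributing pairs")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"outcome": self.outcome, "stratum": self.stratum, "t": self.t,
             "mean_treated": self.mean_treated, "mean_control": self.mean_control,
             "diff": self.diff, "n": self.n}
        )

    def plot(self, ax=None):
        """Treated/control trajectories and their difference vs event time."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.t, self.mean_treated, marker="o", label="CF (treated)")
        ax.plot(self.t, self.mean_control, marker="s", label="non-CF (control)")
        ax.axvline(0, color="grey", ls=":")
        ax.set_xlabel("years since CF establishment")
        ax.set_ylabel(self.outcome)
        ax.set_title(f"{self.outcome} / {self.stratum}")
        ax.legend()
        return ax


def to_event_time(years: np.ndarray, est_year: int) -> np.ndarray:
    """t = calendar year - establishment year (invertible: t + est = year)."""
    return np.asarray(years, dtype=int) - int(est_year)


def pooled_window(est_years, panel_years) -> tuple[int, int]:
    """Event window observed in full by every cohort.

    t_min is set by the oldest cohort's pre-establishment history, t_max
    by the youngest cohort's post-establishment data.
    """
    est_years = np.asarray(list(est_years), dtype=int)
    panel_years = np.asarray(list(panel_years), dtype=int)
    if est_years.size == 0:
        raise DesignError("no establishment years: cannot form a pooled window")
    t_min = -(int(est_years.min()) - int(panel_years[0]))
    t_max = int(panel_years[-1]) - int(est_years.max())
    if t_min >= t_max:
        raise DesignError(
            f"degenerate pooled window [{t_min}, {t_max}]: cohorts span the panel"
        )
    return t_min, t_max


def stratify_by_initial_condition(
    pairs: pd.DataFrame,
    forest_throughout_pairs: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Split matched pairs by the exact-matched forest state at
    establishment; the forest-throughout stratum comes from the dedicated
    forest-only matching run."""
    strata = {
        "forest": pairs[pairs["forest_at_est"] == 1].reset_index(drop=True),
        "nonforest": pairs[pairs["forest_at_est"] == 0].reset_index(drop=True),
    }
    if forest_throughout_pairs is not None:
        strata["forest_throughout"] = forest_throughout_pairs.reset_index(drop=True)
    return strata


def _positions(samples: pd.DataFrame) -> pd.DataFrame:
    return samples.set_index("sample_id")[["row", "col"]]


def difference_series(
    pairs: pd.DataFrame,
    samples: pd.DataFrame,
    panel: LandscapePanel,
    outcome: str,
    window: tuple[int, int],
    stratum: str = "all",
) -> EventSeries:
    """Build D(t) over ``window`` from matched pairs.

    Means are unweighted over samples (each matched sample counts once);
    controls are evaluated at their treated partner's establishment year.
    Forest cover is scaled to percentage points. Any t in the window with
    zero contributing pairs raises a CoverageError (the window policy
    never extrapolates).
    """
    if pairs.empty:
        raise CoverageError(f"no pairs available for stratum {stratum!r}")
    missing = set(pairs["control_id"]) - set(samples["sample_id"])
    if missing:
        raise PairingError(f"controls without sample records: {sorted(missing)[:5]}")
    pos = _positions(samples)
    t_lo, t_hi = window
    ts = np.arange(t_lo, t_hi + 1)
    scale = 100.0 if outcome == "forest" else 1.0

    sum_t = np.zeros(ts.size)
    sum_c = np.zeros(ts.size)
    count = np.zeros(ts.size, dtype=int)
    for est_year, grp in pairs.groupby("est_year"):
        years = est_year + ts
        if years[0] < panel.years[0] or years[-1] > panel.years[-1]:
            raise CoverageError(
                f"cohort {est_year} not observed over the full window {window}"
            )
        yidx = (years - panel.years[0]).astype(int)
        pt = pos.loc[grp["treated_id"]]
        pc = pos.loc[grp["control_id"]]
        cube = panel.outcome(outcome)
        vt = cube[yidx][:, pt["row"].to_numpy(), pt["col"].to_numpy()]
        vc = cube[yidx][:, pc["row"].to_numpy(), pc["col"].to_numpy()]
        sum_t += vt.sum(axis=1) * scale
        sum_c += vc.sum(axis=1) * scale
        count += len(grp)
    if (count == 0).any():
        raise CoverageError("event times in the window without contributing pairs")
    mean_t = sum_t / count
    mean_c = sum_c / count
    return EventSeries(
        outcome=outcome, stratum=stratum, t=ts,
        mean_treated=mean_t, mean_control=mean_c,
        diff=mean_t - mean_c, n=count,
    )


def cohort_difference_series(
    pairs: pd.DataFrame,
    samples: pd.DataFrame,
    panel: LandscapePanel,
    outcome: str,
    t_range: tuple[int, int] = (0, 9),
) -> pd.DataFrame:
    """Per-cohort difference panel for the establishment-year regressions.

    Returns tidy rows (est_year, t, diff, n) for every cohort observed
    over the full ``t_range``.
    """
    frames = []
    for est_year, grp in pairs.groupby("est_year"):
        try:
            series = difference_series(
                grp, samples, panel, outcome, t_range, stratum=f"cohort_{est_year}"
            )
        except CoverageError:
            continue
        frames.append(pd.DataFrame(
            {"est_year": int(est_year), "t": series.t, "diff": series.diff,
             "n": series.n}
        ))
    if not frames:
        raise CoverageError("no cohort observed over the requested post window")
    return pd.concat(frames, ignore_index=True)
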