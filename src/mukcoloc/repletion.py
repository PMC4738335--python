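"""Focus-formation kinetics during protein repletion.

After switching an inducible allele on, cluster formation is followed over
time by two per-cell metrics measured at each sampled timepoint:

* the intensity of the brightest pixel in each cell (a focus-formation proxy
  that is defined even before discrete foci are resolvable), and
* the fraction of cells with at least one detected focus.

Both rise roughly linearly over an initial window (~20 min for a fast
strain); strains are compared by the ratio of their initial slopes.  Because
strains differ in the steady-state fraction of cells that ever form a focus,
series can be adjusted by dividing by that fraction, expressing signal per
focus-competent cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidSpecError, SchemaError, UndefinedFoldError

_REQUIRED = ("time_min", "replicate", "cell_id", "brightest_intensity", "n_foci")

METRIC_COLUMNS = {
    "brightest_pixel": "mean_brightest_intensity",
    "focus_fraction": "fraction_cells_with_focus",
}


def build_timecourse(cell_table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a per-cell table into a time course.

    ``cell_table`` is tidy with one row per (time, replicate, cell):
    columns ``time_min, replicate, cell_id, brightest_intensity, n_foci``.

    Per timepoint, each replicate contributes its mean brightest-pixel
    intensity and its fraction of cells with ≥1 focus; the point estimate is
    the mean of replicate means and the SEM is sd(replicate means)/sqrt(R).
    """
    missing = [c for c in _REQUIRED if c not in cell_table.columns]
    if missing:
        raise SchemaError(f"repletion cell table lacks column(s): {', '.join(missing)}")
    if cell_table.duplicated(["time_min", "replicate", "cell_id"]).any():
        raise InvalidSpecError("duplicate (time, replicate, cell) rows in repletion table")
    if len(cell_table["time_min"].unique()) < 2:
        raise InvalidSpecError("need >= 2 timepoints to build a time course")

    per_rep = (
        cell_table.groupby(["time_min", "replicate"])
        .agg(
            mean_brightest=("brightest_intensity", "mean"),
            fraction=("n_foci", lambda x: float((x > 0).mean())),
            n_cells=("cell_id", "size"),
        )
        .reset_index()
    )

    def _sem(x: pd.Series) -> float:
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0

    summary = (
        per_rep.groupby("time_min")
        .agg(
            mean_brightest_intensity=("mean_brightest", "mean"),
            sem_brightest=("mean_brightest", _sem),
            fraction_cells_with_focus=("fraction", "mean"),
            sem_fraction=("fraction", _sem),
            n_cells=("n_cells", "sum"),
            n_replicates=("replicate", "nunique"),
        )
        .reset_index()
        .sort_values("time_min", ignore_index=True)
    )
    return summary


def adjust_by_focus_fraction(series: pd.DataFrame, steady_state_fraction: float) -> pd.DataFrame:
    """Express the series per focus-competent cell.

    Intensity and focus-fraction columns (and their SEMs) are divided by the
    strain's steady-state fraction of focus-forming cells.  The factor is
    recorded in ``result.attrs['focus_fraction_adjustment']``.
    """
    if not 0 < steady_state_fraction <= 1:
        raise InvalidSpecError("steady_state_fraction must be in (0, 1]")
    adjusted = series.copy()
    for col in (
        "mean_brightest_intensity",
        "sem_brightest",
        "fraction_cells_with_focus",
        "sem_fraction",
    ):
        if col in adjusted.columns:
            adjusted[col] = adjusted[col] / steady_state_fraction
    adjusted.attrs["focus_fraction_adjustment"] = steady_state_fraction
    return adjusted


@dataclass
class RateFit:
    slope_per_min: float
    stderr: float
    intercept: float
    n_points: int
    window_min: tuple[float, float]
    metric: str


def fit_initial_rate(
    series: pd.DataFrame,
    metric: str = "brightest_pixel",
    window_min: tuple[float, float] = (0.0, 20.0),
) -> RateFit:
    """OLS slope of the chosen metric vs time over the initial linear window."""
    if metric not in METRIC_COLUMNS:
        raise InvalidSpecError(f"unknown metric {metric!r}; use one of {sorted(METRIC_COLUMNS)}")
    col = METRIC_COLUMNS[metric]
    lo, hi = window_min
    sel = series[(series["time_min"] >= lo) & (series["time_min"] <= hi)]
    if len(sel) < 2:
        raise InvalidSpecError(f"fewer than 2 points in fit window [{lo}, {hi}] min")
    fit = stats.linregress(sel["time_min"], sel[col])
    stderr = float(fit.stderr) if np.isfinite(fit.stderr) else 0.0
    return RateFit(float(fit.slope), stderr, float(fit.intercept), len(sel), (lo, hi), metric)


@dataclass
class FoldResult:
    fold: float
    rate_ref: RateFit
    rate_test: RateFit
    metric: str


def rate_fold_difference(
    series_ref: pd.DataFrame,
    series_test: pd.DataFrame,
    metric: str = "brightest_pixel",
    window_ref: tuple[float, float] = (0.0, 20.0),
    window_test: tuple[float, float] | None = None,
) -> FoldResult:
    """slope(reference) / slope(test strain) for the chosen metric.

    The fit window is per-series: a slow strain is typically sampled (and
    fitted) over a longer window than the fast reference.
    """
    window_test = window_test or window_ref
    ref = fit_initial_rate(series_ref, metric, window_ref)
    test = fit_initial_rate(series_test, metric, window_test)
    if test.slope_per_min <= 0:
        raise UndefinedFoldError(
            f"test-series slope {test.slope_per_min:.4g}/min is not positive; fold undefined"
        )
    return FoldResult(ref.slope_per_min / test.slope_per_min, ref, test, metric)
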