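"""Heat-stress exposure statistics on a normalized (noleap) calendar.

Implements the exposure metrics reported per period: threshold exceedance
hours per year (step counts multiplied by the step width), heat days from
the daily maximum, durations of consecutive heat days, and stress-class
frequency distributions stratified by season and working hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .comfort import classify_pet, stress_class_order
from .series import IndoorSeries, MeteoSeries

#: Inclusive (">=") exceedance thresholds, degC.
TI_THRESHOLDS = (26.0, 30.0, 35.0)
PET_THRESHOLDS = (23.0, 29.0, 35.0, 41.0)

#: Working-hours window, UTC, closed interval.
WORKING_HOURS = (9, 18)

SEASON_MONTHS = {
    "DJF": (12, 1, 2),
    "MAM": (3, 4, 5),
    "JJA": (6, 7, 8),
    "SON": (9, 10, 11),
}

STRATIFIERS = ("full-year", "DJF", "MAM", "JJA", "SON", "working-hours")


def to_noleap(obj):
    """Drop every Feb 29 so each year holds exactly 365 days of steps.

    Accepts a pandas Series/DataFrame with a DatetimeIndex or one of the
    series containers (whose calendar flag is switched to ``noleap``).
    """
    if isinstance(obj, (MeteoSeries, IndoorSeries)):
        data = to_noleap(obj.data)
        return type(obj)(data, step_hours=obj.step_hours, calendar="noleap")
    index = obj.index
    keep = ~((index.month == 2) & (index.day == 29))
    return obj[keep]


def _assert_no_leap_day(index: pd.DatetimeIndex) -> None:
    if ((index.month == 2) & (index.day == 29)).any():
        raise ValueError("series contains Feb 29; normalize with to_noleap first")


def exceedance_hours_per_year(
    series: pd.Series,
    threshold: float,
    step_hours: int,
    allow_any_step: bool = False,
) -> tuple[float, pd.Series]:
    """Mean hours per year at or above a threshold, plus the per-year values.

    Each step meeting the threshold contributes ``step_hours`` hours (at
    the 3-hour resolution every exceeding value is multiplied by three).
    """
    if step_hours not in (1, 3) and not allow_any_step:
        raise ValueError("step_hours must be 1 or 3 (override with allow_any_step)")
    _assert_no_leap_day(series.index)
    flags = series >= threshold
    per_year = flags.groupby(series.index.year).sum() * float(step_hours)
    per_year.name = f"hours_ge_{threshold:g}"
    return float(per_year.mean()), per_year


def daily_heat_flags(series: pd.Series, threshold: float, step_hours: int) -> pd.Series:
    """Boolean per-day flags: daily maximum >= threshold.

    Partial days at the series edges (fewer steps than a full day) are
    excluded.
    """
    _assert_no_leap_day(series.index)
    steps_per_day = 24 // step_hours
    by_day = series.groupby(series.index.normalize())
    counts = by_day.count()
    daily_max = by_day.max()
    full = counts == steps_per_day
    flags = (daily_max >= threshold)[full]
    flags.name = f"heat_day_ge_{threshold:g}"
    return flags


def heat_days_per_year(
    series: pd.Series, threshold: float, step_hours: int
) -> tuple[float, pd.Series]:
    """Mean heat days per year (daily-maximum rule) and the per-day flags."""
    flags = daily_heat_flags(series, threshold, step_hours)
    if len(flags) == 0:
        return 0.0, flags
    per_year = flags.groupby(flags.index.year).sum()
    return float(per_year.mean()), flags


def _run_lengths(values: np.ndarray) -> list[int]:
    runs, current = [], 0
    for flag in values:
        if flag:
            current += 1
        elif current:
            runs.append(current)
            current = 0
    if current:
        runs.append(current)
    return runs


def mean_consecutive_run(
    day_flags: pd.Series,
    include_empty_years: bool = True,
    method: str = "within-year",
) -> float:
    """Mean length (days) of consecutive heat-day runs.

    ``within-year`` averages run lengths inside each year and then across
    years; years without any run contribute 0 unless
    ``include_empty_years`` is False. ``pooled`` averages all runs of all
    years together. Runs are not capped (a fully flagged year yields 365).
    """
    if len(day_flags) == 0:
        return 0.0
    if method == "pooled":
        runs = _run_lengths(day_flags.to_numpy())
        return float(np.mean(runs)) if runs else 0.0
    if method != "within-year":
        raise ValueError(f"unknown method {method!r}")
    yearly = []
    for _, flags in day_flags.groupby(day_flags.index.year):
        runs = _run_lengths(flags.to_numpy())
        if runs:
            yearly.append(float(np.mean(runs)))
        elif include_empty_years:
            yearly.append(0.0)
    return float(np.mean(yearly)) if yearly else 0.0


def filter_working_hours(series):
    """Keep steps with hour in the closed interval [09:00, 18:00] UTC."""
    hours = series.index.hour
    return series[(hours >= WORKING_HOURS[0]) & (hours <= WORKING_HOURS[1])]


def _stratum_subset(series: pd.Series, stratifier: str) -> pd.Series:
    if stratifier == "full-year":
        return series
    if stratifier == "working-hours":
        return filter_working_hours(series)
    if stratifier in SEASON_MONTHS:
        return series[series.index.month.isin(SEASON_MONTHS[stratifier])]
    raise ValueError(f"unknown stratifier {stratifier!r}")


def stress_frequency(pet_series: pd.Series, stratifier: str = "full-year"):
    """Stress-class frequency (%) of steps within a stratum.

    Returns a dict class-name -> percentage summing to 100, or None for an
    empty stratum (reported as such, never as zeros).
    """
    subset = _stratum_subset(pet_series, stratifier)
    if len(subset) == 0:
        return None
    order = stress_class_order()
    counts = {cls: 0 for cls in order}
    for value in subset.to_numpy():
        counts[classify_pet(value)] += 1
    n = len(subset)
    return {cls.value: 100.0 * counts[cls] / n for cls in order}


@dataclass
class HeatMetricsReport:
    """Per-period exposure statistics for one indoor variable pair."""

    period: str
    n_years: int
    step_hours: int
    exceedance_hours: dict[str, dict[float, float]] = field(default_factory=dict)
    heat_days: dict[str, dict[float, float]] = field(default_factory=dict)
    mean_run_days: dict[str, dict[float, float]] = field(default_factory=dict)
    stress_frequency: dict[str, dict[str, float] | None] = field(default_factory=dict)
    means: dict[str, float] = field(default_factory=dict)

    def to_flat_dict(self) -> dict[str, float]:
        """Flatten to scalar metrics for ensemble aggregation."""
        flat: dict[str, float] = {}
        for var, per_thr in self.exceedance_hours.items():
            for thr, value in per_thr.items():
                flat[f"{var}_hours_ge{thr:g}"] = value
        for var, per_thr in self.heat_days.items():
            for thr, value in per_thr.items():
                flat[f"{var}_days_ge{thr:g}"] = value
        for var, per_thr in self.mean_run_days.items():
            for thr, value in per_thr.items():
                flat[f"{var}_run_ge{thr:g}"] = value
        for stratum, dist in self.stress_frequency.items():
            if dist is None:
                continue
            for cls, pct in dist.items():
                flat[f"freq_{stratum}_{cls}"] = pct
        flat.update(self.means)
        return flat

    def to_tidy_frame(self) -> pd.DataFrame:
        rows = []
        for metric, store in (
            ("exceedance_hours_per_year", self.exceedance_hours),
            ("heat_days_per_year", self.heat_days),
            ("mean_consecutive_run_days", self.mean_run_days),
        ):
            for var, per_thr in store.items():
                for thr, value in per_thr.items():
                    rows.append(
                        {
                            "period": self.period,
                            "metric": metric,
                            "variable": var,
                            "threshold": thr,
                            "stratum": "full-year",
                            "value": value,
                        }
                    )
        for stratum, dist in self.stress_frequency.items():
            if dist is None:
                continue
            for cls, pct in dist.items():
                rows.append(
                    {
                        "period": self.period,
                        "metric": "stress_frequency_pct",
                        "variable": "pet",
                        "threshold": cls,
                        "stratum": stratum,
                        "value": pct,
                    }
                )
        for key, value in self.means.items():
            rows.append(
                {
                    "period": self.period,
                    "metric": "mean",
                    "variable": key,
                    "threshold": "",
                    "stratum": "full-year",
                    "value": value,
                }
            )
        return pd.DataFrame(rows)


def compute_report(
    ti: pd.Series,
    pet: pd.Series,
    step_hours: int,
    period: str = "",
    run_method: str = "within-year",
) -> HeatMetricsReport:
    """All exposure statistics for one period (series must be noleap)."""
    _assert_no_leap_day(ti.index)
    _assert_no_leap_day(pet.index)
    n_years = len(np.unique(ti.index.year))
    report = HeatMetricsReport(period=period, n_years=n_years, step_hours=step_hours)
    for var, series, thresholds in (
        ("ti", ti, TI_THRESHOLDS),
        ("pet", pet, PET_THRESHOLDS),
    ):
        report.exceedance_hours[var] = {}
        report.heat_days[var] = {}
        report.mean_run_days[var] = {}
        for thr in thresholds:
            hours, _ = exceedance_hours_per_year(series, thr, step_hours)
            report.exceedance_hours[var][thr] = hours
            days, flags = heat_days_per_year(series, thr, step_hours)
            report.heat_days[var][thr] = days
            report.mean_run_days[var][thr] = mean_consecutive_run(flags, method=run_method)
    for stratum in STRATIFIERS:
        report.stress_frequency[stratum] = stress_frequency(pet, stratum)
    report.means["mean_ti"] = float(ti.mean())
    report.means["mean_pet"] = float(pet.mean())
    for season in ("DJF", "JJA"):
        report.means[f"mean_ti_{season}"] = float(_stratum_subset(ti, season).mean())
        report.means[f"mean_pet_{season}"] = float(_stratum_subset(pet, season).mean())
    return report
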