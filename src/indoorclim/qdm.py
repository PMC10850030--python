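"""Quantile delta mapping (QDM) bias correction.

QDM adjusts a model scenario series against an observed historical
reference while preserving the model's own projected quantile-wise change.
For a future value x with nonexceedance probability tau under the future
sample's empirical distribution, the additive transfer is

    x_hat = F_obs_hist^{-1}(tau) + [x - F_mod_hist^{-1}(tau)]

and the multiplicative transfer (zero-bounded variables) uses the ratio
x / F_mod_hist^{-1}(tau) with denominators floored at a trace threshold.
Empirical quantile functions interpolate linearly between order statistics
at plotting positions (k + 0.5)/n with constant extrapolation beyond the
sampled support (the edge correction is carried outward unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import METEO_VARS, MeteoSeries

#: Default transfer mode per outdoor variable.
DEFAULT_MODES = {
    "ta": "additive",
    "td": "additive",
    "p": "additive",
    "ag": "additive",
    "g": "multiplicative",
    "v": "multiplicative",
}

DEFAULT_TRACE = 0.05


def _plotting_positions(n: int) -> np.ndarray:
    return (np.arange(n) + 0.5) / n


def _quantile(sorted_sample: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """Empirical quantile function with constant tail extrapolation."""
    p = _plotting_positions(len(sorted_sample))
    return np.interp(tau, p, sorted_sample)


def _ecdf(sorted_sample: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Empirical nonexceedance probability, clamped to the plotting range."""
    p = _plotting_positions(len(sorted_sample))
    return np.interp(x, sorted_sample, p)


@dataclass
class QDMMapping:
    """Fitted paired quantile functions for one variable."""

    variable: str
    mode: str  # 'additive' | 'multiplicative'
    obs_sorted: dict[int, np.ndarray]  # group key -> sorted sample
    mod_sorted: dict[int, np.ndarray]
    grouping: str = "pooled"  # 'pooled' | 'monthly'
    trace: float = DEFAULT_TRACE

    def to_json_dict(self) -> dict:
        return {
            "variable": self.variable,
            "mode": self.mode,
            "grouping": self.grouping,
            "trace": self.trace,
            "obs_quantiles": {str(k): v.tolist() for k, v in self.obs_sorted.items()},
            "mod_quantiles": {str(k): v.tolist() for k, v in self.mod_sorted.items()},
        }


def _group_keys(index, grouping: str) -> np.ndarray:
    if grouping == "pooled":
        return np.zeros(len(index), dtype=int)
    if grouping == "monthly":
        return np.asarray(pd.DatetimeIndex(index).month)
    raise ValueError(f"unknown grouping {grouping!r}")


def fit_qdm(
    obs_hist: pd.Series,
    mod_hist: pd.Series,
    variable: str = "",
    mode: str = "additive",
    grouping: str = "pooled",
    trace: float = DEFAULT_TRACE,
) -> QDMMapping:
    """Fit the paired historical quantile functions (deterministic)."""
    if mode not in ("additive", "multiplicative"):
        raise ValueError(f"unknown transfer mode {mode!r}")
    if len(obs_hist) == 0 or len(mod_hist) == 0:
        raise ValueError("historical samples must be non-empty")
    obs = pd.Series(obs_hist).astype(float)
    mod = pd.Series(mod_hist).astype(float)
    if mode == "multiplicative" and ((obs < 0).any() or (mod < 0).any()):
        raise ValueError("multiplicative mode requires non-negative samples")

    obs_groups = _group_keys(obs.index, grouping)
    mod_groups = _group_keys(mod.index, grouping)
    obs_sorted, mod_sorted = {}, {}
    for key in np.unique(obs_groups):
        sample = np.sort(obs.to_numpy()[obs_groups == key])
        if len(sample) == 0:
            raise ValueError(f"empty observed group {key}")
        obs_sorted[int(key)] = sample
    for key in np.unique(mod_groups):
        sample = np.sort(mod.to_numpy()[mod_groups == key])
        mod_sorted[int(key)] = sample
    if set(obs_sorted) != set(mod_sorted):
        raise ValueError("observed and model histories cover different groups")
    return QDMMapping(
        variable=variable,
        mode=mode,
        obs_sorted=obs_sorted,
        mod_sorted=mod_sorted,
        grouping=grouping,
        trace=trace,
    )


def apply_qdm(mapping: QDMMapping, mod_fut: pd.Series) -> pd.Series:
    """Bias-correct a future model series through the fitted mapping.

    The future nonexceedance probability is estimated from the future
    sample itself (per group), so the projected change at each quantile is
    preserved. Output has the same length and index as the input.
    """
    fut = pd.Series(mod_fut).astype(float)
    groups = _group_keys(fut.index, mapping.grouping)
    out = np.empty(len(fut))
    x_all = fut.to_numpy()
    for key in np.unique(groups):
        if int(key) not in mapping.obs_sorted:
            raise ValueError(f"group {key} absent from the fitted mapping")
        sel = groups == key
        x = x_all[sel]
        fut_sorted = np.sort(x)
        tau = _ecdf(fut_sorted, x)
        q_obs = _quantile(mapping.obs_sorted[int(key)], tau)
        q_mod = _quantile(mapping.mod_sorted[int(key)], tau)
        if mapping.mode == "additive":
            corrected = q_obs + (x - q_mod)
        else:
            ratio = np.where(x == 0.0, 0.0, x / np.maximum(q_mod, mapping.trace))
            corrected = q_obs * ratio
        out[sel] = corrected
    return pd.Series(out, index=fut.index, name=fut.name)


@dataclass
class CorrectionLog:
    """Audit record of one scenario correction."""

    modes: dict[str, str] = field(default_factory=dict)
    grouping: str = "pooled"
    repairs: dict[str, int] = field(default_factory=dict)

    def total_repairs(self) -> int:
        return sum(self.repairs.values())


def correct_scenario(
    obs_hist: MeteoSeries,
    mod_hist: MeteoSeries,
    mod_fut: MeteoSeries,
    modes: dict[str, str] | None = None,
    grouping: str = "pooled",
    trace: float = DEFAULT_TRACE,
) -> tuple[MeteoSeries, CorrectionLog]:
    """QDM-correct every variable of a scenario member.

    After per-variable correction the physical invariants are repaired
    (dew point clipped to air temperature, irradiance and wind floored at
    zero); repair counts are reported in the log.
    """
    modes = {**DEFAULT_MODES, **(modes or {})}
    log = CorrectionLog(modes=dict(modes), grouping=grouping)
    corrected = {}
    for var in METEO_VARS:
        for src, name in ((obs_hist, "observed"), (mod_hist, "model-historical"), (mod_fut, "model-future")):
            if var not in src.data.columns:
                raise ValueError(f"variable {var!r} missing from {name} series")
        mapping = fit_qdm(
            obs_hist.data[var],
            mod_hist.data[var],
            variable=var,
            mode=modes[var],
            grouping=grouping,
            trace=trace,
        )
        corrected[var] = apply_qdm(mapping, mod_fut.data[var])
    df = pd.DataFrame(corrected, index=mod_fut.data.index)

    n_td = int((df["td"] > df["ta"]).sum())
    if n_td:
        df["td"] = np.minimum(df["td"], df["ta"])
    log.repairs["td_clipped_to_ta"] = n_td
    for var in ("g", "v"):
        n_neg = int((df[var] < 0).sum())
        if n_neg:
            df[var] = np.maximum(df[var], 0.0)
        log.repairs[f"{var}_floored_at_zero"] = n_neg
    for var, floor in (("p", 1.0), ("ag", 1.0)):
        n_low = int((df[var] < floor).sum())
        if n_low:
            df[var] = np.maximum(df[var], floor)
        log.repairs[f"{var}_floored"] = n_low

    out = MeteoSeries(df, step_hours=mod_fut.step_hours, calendar=mod_fut.calendar)
    return out, log
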