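"""Synthetic outdoor weather, climate scenarios, and indoor sensor series.

Stands in for reanalysis extracts, scenario ensemble members, and indoor
sensor records so that every downstream stage has inputs with known
ground truth. Outdoor variables combine seasonal and diurnal sinusoids
with AR(1) noise under physical couplings (dew point never above air
temperature, irradiance zero outside the daylight window). The indoor
response is a single-node first-order energy balance with solar and
internal gains and an optional heating setpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .comfort import saturation_vapor_pressure
from .series import IndoorSeries, MeteoSeries, SeriesValidationError

_DAYS_PER_YEAR = 365.25
_SUMMER_PEAK_DOY = 197.0  # mid-July


@dataclass
class OutdoorClimateConfig:
    """Statistical recipe for one outdoor reference climate."""

    step_hours: int = 3
    span_years: int = 1
    start_year: int = 2021
    seed: int = 0
    # air temperature
    ta_mean: float = 10.0
    ta_seasonal_amp: float = 9.0
    ta_diurnal_amp: float = 3.0
    ta_ar_coef: float = 0.85
    ta_noise_scale: float = 0.6
    # dew point (as deficit below ta)
    dew_point_deficit: float = 4.0
    td_noise_scale: float = 0.5
    td_ar_coef: float = 0.8
    # wind
    v_mean: float = 2.5
    v_diurnal_amp: float = 0.8
    v_ar_coef: float = 0.7
    v_noise_scale: float = 0.5
    # pressure
    p_mean: float = 1005.0
    p_ar_coef: float = 0.95
    p_noise_scale: float = 1.5
    # global irradiance: mean applies within the daylight window only
    g_mean: float = 0.0
    g_max: float = 450.0
    g_seasonal_frac: float = 0.75
    daylight_start: float = 6.0
    daylight_end: float = 18.0
    # long-wave downwelling
    ag_mean: float = 330.0
    ag_ta_coupling: float = 2.5
    ag_ar_coef: float = 0.8
    ag_noise_scale: float = 2.0

    def validate(self) -> None:
        if self.step_hours not in (1, 3):
            raise ValueError("step_hours must be 1 or 3")
        if self.span_years < 1:
            raise ValueError("span must cover at least one year")
        for name in ("ta_seasonal_amp", "ta_diurnal_amp", "v_diurnal_amp", "g_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("ta_ar_coef", "td_ar_coef", "v_ar_coef", "p_ar_coef", "ag_ar_coef"):
            coef = getattr(self, name)
            if not 0.0 <= coef < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if not 0.0 <= self.daylight_start < self.daylight_end <= 24.0:
            raise ValueError("invalid daylight window")


def _ar1(rng: np.random.Generator, n: int, coef: float, scale: float) -> np.ndarray:
    eps = rng.standard_normal(n) * scale
    if coef == 0.0 or scale == 0.0:
        return eps
    out = np.empty(n)
    out[0] = eps[0] / math.sqrt(1.0 - coef**2)  # stationary start
    for i in range(1, n):
        out[i] = coef * out[i - 1] + eps[i]
    return out


def _time_axis(cfg: OutdoorClimateConfig) -> pd.DatetimeIndex:
    start = pd.Timestamp(year=cfg.start_year, month=1, day=1)
    end = pd.Timestamp(year=cfg.start_year + cfg.span_years, month=1, day=1)
    return pd.date_range(start, end, freq=f"{cfg.step_hours}h", inclusive="left")


def generate_outdoor_series(cfg: OutdoorClimateConfig) -> MeteoSeries:
    """Generate one outdoor reference series; deterministic per seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    index = _time_axis(cfg)
    n = len(index)
    day_frac = (index - index[0]).total_seconds().to_numpy() / 86400.0
    doy = day_frac % _DAYS_PER_YEAR
    hour = index.hour.to_numpy() + index.minute.to_numpy() / 60.0

    seasonal = np.cos(2.0 * math.pi * (doy - _SUMMER_PEAK_DOY) / _DAYS_PER_YEAR)
    diurnal = np.cos(2.0 * math.pi * (hour - 15.0) / 24.0)  # warmest mid-afternoon

    ta = (
        cfg.ta_mean
        + cfg.ta_seasonal_amp * seasonal
        + cfg.ta_diurnal_amp * diurnal
        + _ar1(rng, n, cfg.ta_ar_coef, cfg.ta_noise_scale)
    )
    deficit = cfg.dew_point_deficit + _ar1(rng, n, cfg.td_ar_coef, cfg.td_noise_scale)
    td = ta - np.maximum(deficit, 0.0)

    v = np.maximum(
        cfg.v_mean + cfg.v_diurnal_amp * diurnal + _ar1(rng, n, cfg.v_ar_coef, cfg.v_noise_scale),
        0.0,
    )
    p = cfg.p_mean + _ar1(rng, n, cfg.p_ar_coef, cfg.p_noise_scale)

    in_window = (hour >= cfg.daylight_start) & (hour < cfg.daylight_end)
    shape = np.sin(
        math.pi
        * np.clip(
            (hour - cfg.daylight_start) / (cfg.daylight_end - cfg.daylight_start), 0.0, 1.0
        )
    )
    season_factor = (1.0 - cfg.g_seasonal_frac) + cfg.g_seasonal_frac * 0.5 * (1.0 + seasonal)
    g = np.where(in_window, np.maximum(cfg.g_mean + cfg.g_max * shape * season_factor, 0.0), 0.0)

    ag = np.maximum(
        cfg.ag_mean
        + cfg.ag_ta_coupling * (ta - cfg.ta_mean)
        + _ar1(rng, n, cfg.ag_ar_coef, cfg.ag_noise_scale),
        10.0,
    )

    data = pd.DataFrame(
        {"ta": ta, "td": td, "v": v, "p": p, "g": g, "ag": ag}, index=index
    )
    return MeteoSeries(data, step_hours=cfg.step_hours, calendar="standard")


#: Variables a scenario perturbs multiplicatively (zero-bounded).
MULTIPLICATIVE_VARS = ("g", "v")


@dataclass
class ScenarioConfig:
    """Imposed change and bias of one scenario ensemble member.

    ``trend`` is the total additive change over the series span (applied
    as a linear 0->1 ramp); ``offset`` a constant shift; ``bias`` a static
    model bias to be removed by bias correction. For the zero-bounded
    variables in :data:`MULTIPLICATIVE_VARS` all three are fractional and
    applied multiplicatively.
    """

    label: str = "RCP8.5"
    member: str = "m01"
    seed: int = 0
    trend: dict[str, float] = field(default_factory=dict)
    offset: dict[str, float] = field(default_factory=dict)
    bias: dict[str, float] = field(default_factory=dict)
    summer_amplification: float = 0.0  # extra fractional summer warming on ta trend

    def validate(self) -> None:
        if not self.label:
            raise ValueError("scenario label must be nonempty")
        for d in (self.trend, self.offset, self.bias):
            for key, value in d.items():
                if not np.isfinite(value):
                    raise ValueError(f"non-finite scenario value for {key}")


def apply_climate_scenario(series: MeteoSeries, scenario: ScenarioConfig) -> MeteoSeries:
    """Return a new series with the scenario's bias/offset/trend imposed.

    For additive variables the mean difference to the input equals
    bias + offset + trend/2 (linear ramp). Dew point is re-clipped to the
    (possibly shifted) air temperature afterwards.
    """
    scenario.validate()
    df = series.data.copy()
    n = len(df)
    ramp = np.linspace(0.0, 1.0, n) if n > 1 else np.zeros(n)
    day_frac = (df.index - df.index[0]).total_seconds().to_numpy() / 86400.0
    doy = day_frac % _DAYS_PER_YEAR
    seasonal = np.cos(2.0 * math.pi * (doy - _SUMMER_PEAK_DOY) / _DAYS_PER_YEAR)

    for var in df.columns:
        total = (
            scenario.bias.get(var, 0.0)
            + scenario.offset.get(var, 0.0)
            + scenario.trend.get(var, 0.0) * ramp
        )
        if var == "ta" and scenario.summer_amplification:
            total = total * (1.0 + scenario.summer_amplification * seasonal)
        if var in MULTIPLICATIVE_VARS:
            df[var] = df[var] * (1.0 + total)
        else:
            df[var] = df[var] + total

    df["td"] = np.minimum(df["td"], df["ta"])
    df["g"] = np.maximum(df["g"], 0.0)
    df["v"] = np.maximum(df["v"], 0.0)
    return MeteoSeries(df, step_hours=series.step_hours, calendar=series.calendar)


@dataclass
class BuildingParameters:
    """Single-node building response with inertia, gains, and heating."""

    tau_hours: float = 24.0  # thermal time constant
    solar_gain: float = 0.0015  # K h-1 per W m-2
    internal_gain: float = 0.1  # K h-1 (constant baseline)
    occupancy_gain: float = 0.0  # extra K h-1 during 09-18 UTC
    heating_setpoint: float | None = 21.0  # degC; None = unheated
    heating_gain: float = 2.0  # h-1
    vi_base: float = 0.1  # m s-1 indoor air speed floor
    ventilation_coupling: float = 0.0  # vi = vi_base + coupling * v_out
    radiant_coef: float = 0.004  # K per W m-2: tg = ti + c * g
    rh_floor: float = 5.0  # % clip for indoor RH
    noise_scale: float = 0.3  # K measurement noise on ti
    tg_noise_scale: float = 0.1  # K extra noise on tg

    def validate(self) -> None:
        if self.tau_hours <= 0:
            raise ValueError("tau must be positive")
        if self.solar_gain < 0 or self.heating_gain < 0:
            raise ValueError("gains must be >= 0")
        if self.vi_base < 0 or self.ventilation_coupling < 0:
            raise ValueError("air-speed parameters must be >= 0")


def simulate_indoor(
    series: MeteoSeries, bld: BuildingParameters, seed: int = 0
) -> IndoorSeries:
    """Simulate an indoor sensor series from an outdoor series.

    Integrates dT_i/dt = (T_a - T_i)/tau + a G + q(t) + max(0, k (T_set - T_i))
    with forward-Euler substeps of at most tau/2 (unconditionally stable for
    any recording step), outdoor drivers held constant within each step.
    Indoor RH conserves outdoor specific humidity re-evaluated at T_i; the
    globe channel adds a radiant offset proportional to irradiance.
    Deterministic for a given seed.
    """
    bld.validate()
    rng = np.random.default_rng(seed)
    df = series.data
    n = len(df)
    step = float(series.step_hours)
    # forward Euler is stable for dt * (1/tau + k) <= 1; keep a 2x margin
    rate = 1.0 / bld.tau_hours
    if bld.heating_setpoint is not None:
        rate += bld.heating_gain
    n_sub = max(1, math.ceil(step * rate / 0.5))
    dt = step / n_sub

    ta = df["ta"].to_numpy()
    g = df["g"].to_numpy()
    hour = df.index.hour.to_numpy()
    working = (hour >= 9) & (hour <= 18)

    q = bld.internal_gain + np.where(working, bld.occupancy_gain, 0.0)

    ti = np.empty(n)
    state = ta[0] if bld.heating_setpoint is None else max(ta[0], bld.heating_setpoint)
    for i in range(n):
        for _ in range(n_sub):
            dstate = (ta[i] - state) / bld.tau_hours + bld.solar_gain * g[i] + q[i]
            if bld.heating_setpoint is not None:
                dstate += max(0.0, bld.heating_gain * (bld.heating_setpoint - state))
            state += dt * dstate
        ti[i] = state

    ti_obs = ti + rng.standard_normal(n) * bld.noise_scale
    tg = ti_obs + bld.radiant_coef * g + rng.standard_normal(n) * bld.tg_noise_scale
    vp_out = saturation_vapor_pressure(df["td"].to_numpy())
    rh = np.clip(100.0 * vp_out / saturation_vapor_pressure(ti_obs), bld.rh_floor, 100.0)
    vi = bld.vi_base + bld.ventilation_coupling * df["v"].to_numpy()

    out = pd.DataFrame(
        {"ti": ti_obs, "rh": rh, "tg": tg, "vi": vi, "pet": np.nan}, index=df.index
    )
    return IndoorSeries(out, step_hours=series.step_hours, calendar=series.calendar)


def perturbed_building(base: BuildingParameters, seed: int) -> BuildingParameters:
    """A seeded random variant of a building (workplace heterogeneity)."""
    rng = np.random.default_rng(seed)
    return replace(
        base,
        tau_hours=float(base.tau_hours * rng.uniform(0.5, 1.8)),
        solar_gain=float(base.solar_gain * rng.uniform(0.5, 1.5)),
        internal_gain=float(base.internal_gain * rng.uniform(0.5, 2.0)),
    )
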