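"""Thermal comfort: mean radiant temperature, PET, and stress classes.

PET (physiologically equivalent temperature) is the air temperature of a
standardized reference environment (``t_mrt = t_a``, ``v = 0.1 m/s``,
``VP = 12 hPa``) in which the modeled core and skin state of a reference
person equals the state reached in the actual environment. The underlying
two-node human heat-balance model (MEMI) is solved in
:mod:`indoorclim.memi`; this module wraps it with unit handling, the
globe-thermometer conversion and the stress-class partition.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import memi
from .series import IndoorSeries


@dataclass(frozen=True)
class PersonParameters:
    """Reference person used for PET (the standardized-person convention)."""

    age: float = 35.0
    sex: str = "male"
    height: float = 1.75  # m
    weight: float = 75.0  # kg
    clo: float = 0.9  # clothing insulation
    work: float = 80.0  # activity metabolism, W

    def __post_init__(self) -> None:
        if min(self.age, self.height, self.weight, self.work) <= 0 or self.clo <= 0:
            raise ValueError("person parameters must be positive")
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")


#: Reference person of the PET convention.
REFERENCE_PERSON = PersonParameters()


@dataclass(frozen=True)
class GlobeSpec:
    """Globe thermometer geometry (standard 150 mm matte-black globe)."""

    diameter: float = 0.15  # m
    emissivity: float = 0.95

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("globe diameter must be positive")
        if not 0.0 < self.emissivity <= 1.0:
            raise ValueError("globe emissivity must be in (0, 1]")


STANDARD_GLOBE = GlobeSpec()

# Magnus saturation-vapor-pressure constants (over water), hPa / degC.
_MAGNUS_A = 6.112
_MAGNUS_B = 17.62
_MAGNUS_C = 243.12


def saturation_vapor_pressure(t):
    """Saturation vapor pressure e_s(t) in hPa (Magnus form, over water)."""
    t = np.asarray(t, dtype=float)
    out = _MAGNUS_A * np.exp(_MAGNUS_B * t / (_MAGNUS_C + t))
    return float(out) if out.ndim == 0 else out


def vapor_pressure(t, rh):
    """Actual vapor pressure in hPa from temperature (degC) and RH (%)."""
    rh_arr = np.asarray(rh, dtype=float)
    if ((rh_arr < 0) | (rh_arr > 100)).any():
        raise ValueError("relative humidity must be within [0, 100] %")
    out = rh_arr / 100.0 * saturation_vapor_pressure(t)
    return float(out) if np.ndim(out) == 0 else out


# Forced-convection globe constant for T_mrt recovery (ISO 7726 relation
# with h_cg = 6.3 v^0.6 / D^0.4, expressed against emissivity*sigma).
_GLOBE_C = 1.1e8


def mrt_from_globe(t_g, t_a, v, globe: GlobeSpec = STANDARD_GLOBE):
    """Mean radiant temperature (degC) from globe and air temperature.

    Uses the forced-convection relation

        T_mrt = [(T_g + 273.15)^4 + C v^0.6 (T_g - T_a) / (eps D^0.4)]^(1/4)
                - 273.15

    which reduces to ``T_mrt = T_g`` for ``v = 0`` or ``T_g = T_a``.
    """
    t_g = np.asarray(t_g, dtype=float)
    t_a = np.asarray(t_a, dtype=float)
    v = np.asarray(v, dtype=float)
    if (v < 0).any():
        raise ValueError("air speed must be >= 0")
    tg_k4 = (t_g + 273.15) ** 4
    conv = _GLOBE_C * v**0.6 * (t_g - t_a) / (globe.emissivity * globe.diameter**0.4)
    arg = tg_k4 + conv
    # Strong negative convective term can push the radicand below zero for
    # unphysical inputs; clamp and let callers see the floor explicitly.
    arg = np.maximum(arg, 0.0)
    out = arg**0.25 - 273.15
    return float(out) if out.ndim == 0 else out


class StressClass(enum.Enum):
    """PET stress classes; boundaries at 18, 23, 29, 35, 41 degC."""

    COLD = "cold stress"
    COMFORTABLE = "no thermal stress"
    SLIGHT_HEAT = "slight heat stress"
    MODERATE_HEAT = "moderate heat stress"
    STRONG_HEAT = "strong heat stress"
    EXTREME_HEAT = "extreme heat stress"


#: Upper-exclusive boundaries of the comfortable band and the heat classes.
STRESS_BOUNDARIES = (18.0, 23.0, 29.0, 35.0, 41.0)

_HEAT_ORDER = (
    StressClass.COLD,
    StressClass.COMFORTABLE,
    StressClass.SLIGHT_HEAT,
    StressClass.MODERATE_HEAT,
    StressClass.STRONG_HEAT,
    StressClass.EXTREME_HEAT,
)


def classify_pet(pet_value: float) -> StressClass:
    """Map a PET value to its stress class.

    Heat thresholds are inclusive at the lower edge (">=" semantics);
    the comfortable band is the open interval (18, 23), so PET = 18
    falls to cold stress and PET = 23 to slight heat stress.
    """
    if not np.isfinite(pet_value):
        raise ValueError("PET must be finite")
    if pet_value <= STRESS_BOUNDARIES[0]:
        return StressClass.COLD
    for bound, cls in zip(STRESS_BOUNDARIES[1:], _HEAT_ORDER[2:]):
        if pet_value < bound:
            return _HEAT_ORDER[_HEAT_ORDER.index(cls) - 1]
    return StressClass.EXTREME_HEAT


def classify_pet_series(values) -> list[StressClass]:
    return [classify_pet(v) for v in np.asarray(values, dtype=float)]


def pet(
    t_a: float,
    t_mrt: float,
    vp: float,
    v: float,
    person: PersonParameters = REFERENCE_PERSON,
) -> float:
    """PET (degC) for one environment.

    Parameters are air temperature (degC), mean radiant temperature (degC),
    vapor pressure (hPa) and air speed (m/s). Air speed is floored at
    0.1 m/s per the PET convention. Raises
    :class:`indoorclim.memi.ConvergenceError` on solver failure (never
    returns a silent NaN).
    """
    if vp < 0:
        raise ValueError("vapor pressure must be >= 0")
    v = max(float(v), memi.REFERENCE_AIR_SPEED)
    state = memi.solve_heat_balance(
        t_a=float(t_a),
        t_mrt=float(t_mrt),
        vp=float(vp),
        v=v,
        person=person,
    )
    return memi.reference_temperature(state, person)


def pet_series(
    t_a, t_mrt, vp, v, person: PersonParameters = REFERENCE_PERSON
) -> np.ndarray:
    """Vector loop over :func:`pet` (the balance is solved per point)."""
    t_a, t_mrt, vp, v = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (t_a, t_mrt, vp, v))
    )
    return np.array(
        [pet(a, m, e, w, person) for a, m, e, w in zip(t_a, t_mrt, vp, v)]
    )


def fill_pet(
    indoor: IndoorSeries,
    person: PersonParameters = REFERENCE_PERSON,
    globe: GlobeSpec = STANDARD_GLOBE,
    default_air_speed: float = 0.1,
) -> IndoorSeries:
    """Compute the ``pet`` column of an indoor series in place.

    T_mrt is recovered from the globe column; indoor air speed defaults to
    0.1 m/s where no ``vi`` column is present (still-indoor-air
    assumption, configurable).
    """
    df = indoor.data
    vi = df["vi"].to_numpy() if "vi" in df.columns else np.full(len(df), default_air_speed)
    t_mrt = mrt_from_globe(df["tg"].to_numpy(), df["ti"].to_numpy(), vi, globe)
    vp = vapor_pressure(df["ti"].to_numpy(), df["rh"].to_numpy())
    df["pet"] = pet_series(df["ti"].to_numpy(), t_mrt, vp, vi, person)
    return indoor


def stress_class_order() -> tuple[StressClass, ...]:
    """Classes from cold to extreme heat (the partition order)."""
    return _HEAT_ORDER
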