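"""Two-node human heat-balance model (MEMI) and the PET reference search.

The model balances metabolic heat against radiative, convective,
respiratory and evaporative exchange of a clothed body with three coupled
temperatures: body core, skin, and clothing surface. The published model
equations are implemented directly:

* core node — internal heat plus respiratory exchange is transported to
  the skin through tissue conduction and a skin blood flow that responds
  to core and skin temperature signals;
* skin node — receives the core flux and exchanges by radiation and
  convection over the bare fraction, by vapor diffusion, and by sweat
  evaporation (physiologically driven, capped by the evaporative
  potential of the environment), and conducts into the clothing layer,
  modeled as a cylindrical shell;
* clothing node — conduction from the skin balances radiation and
  convection at the clothing surface.

``solve_heat_balance`` finds (t_core, t_skin, t_clothing) with a
multidimensional root solver. ``reference_temperature`` then bisects the
air temperature of the reference environment (t_mrt = t_a,
v = 0.1 m/s, VP = 12 hPa) at which the frozen physiological state closes
the same balance — that temperature is PET.

An independent re-solve of the same balance by nested scalar bisection
(no scipy) lives in the test suite and serves as the numerical
cross-check oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy import optimize

if TYPE_CHECKING:  # pragma: no cover
    from .comfort import PersonParameters

# Physical constants of the model
SIGMA = 5.67e-8  # Stefan-Boltzmann, W m-2 K-4
C_AIR = 1010.0  # specific heat of air, J kg-1 K-1
L_VAP = 2.42e6  # latent heat of evaporation, J kg-1
RHO_BLOOD = 1.06  # blood density, kg L-1
C_BLOOD = 3640.0  # blood specific heat, J kg-1 K-1
EM_SKIN = 0.99  # skin long-wave emissivity
EM_CLOTHING = 0.95  # clothing long-wave emissivity
P_REF = 1013.25  # reference pressure, hPa
R_DIFF_SKIN = 0.79e7  # skin vapor diffusion resistance
TISSUE_CONDUCTANCE = 5.28  # core-skin tissue conductance, W m-2 K-1
SWEAT_COEF = 304.94  # sweat rate, g m-2 h-1 K-1
CORE_SET = 36.6  # degC, setpoint for blood flow / sweating signals
SKIN_SET = 34.0  # degC, skin signal setpoint
BLOOD_FLOW_MIN = 6.3  # L m-2 h-1
BLOOD_FLOW_MAX = 90.0  # L m-2 h-1
_KELVIN = 273.2  # offset used by the model equations

REFERENCE_AIR_SPEED = 0.1  # m/s
REFERENCE_VP = 12.0  # hPa

RADIATION_AREA_FACTOR = {"standing": 0.725, "sitting": 0.696}


class ConvergenceError(RuntimeError):
    """Heat-balance or reference search failed to converge."""


def sat_vp(t: float) -> float:
    """Saturation vapor pressure (hPa) with the model's own curve."""
    return 6.11 * 10.0 ** (7.45 * t / (235.0 + t))


def heat_transfer_coefficient(v: float, p: float = P_REF) -> float:
    """Convective coefficient h_c (W m-2 K-1) at air speed v and pressure p."""
    return (2.67 + 6.5 * v**0.67) * (p / P_REF) ** 0.55


@dataclass(frozen=True)
class BodyModel:
    """Person-derived quantities entering the balance."""

    a_du: float  # DuBois body surface area, m2
    met: float  # total metabolic rate, W
    internal_heat: float  # M (1 - eta), W
    breath_rate: float  # respiratory mass flow, kg s-1
    sweat_factor: float  # 1.0 male, 0.7 female
    # clothing geometry
    f_covered: float  # fraction of body covered by clothing
    f_cl: float  # clothing area factor
    a_clothed: float  # clothed exchange area, m2
    a_eff_rad: float  # effective radiation area of body, m2
    r_cl: float  # clothing resistance, m2 K W-1
    h_clothing: float  # conduction coefficient through clothing, W m-2 K-1


def build_body(person: "PersonParameters", position: str = "standing") -> BodyModel:
    mbody, ht, age = person.weight, person.height, person.age
    a_du = 0.203 * mbody**0.425 * ht**0.725
    ht_cm_ratio = ht * 100.0 / mbody ** (1.0 / 3.0)
    if person.sex == "male":
        basal = 3.45 * mbody**0.75 * (1 + 0.004 * (30 - age) + 0.010 * (ht_cm_ratio - 43.4))
        sweat_factor = 1.0
    else:
        basal = 3.19 * mbody**0.75 * (1 + 0.004 * (30 - age) + 0.018 * (ht_cm_ratio - 42.1))
        sweat_factor = 0.7
    met = person.work + basal
    internal_heat = met  # mechanical efficiency eta = 0
    breath_rate = 1.44e-6 * met

    icl = person.clo
    f_covered = (-2.36 + 173.51 * icl - 100.76 * icl**2 + 19.28 * icl**3) / 100.0
    f_covered = min(f_covered, 1.0)
    f_cl = 1.0 + 0.31 * icl
    r_cl = icl / 6.45 / f_covered
    if icl >= 2.0:
        y = 1.0
    elif icl > 0.6:
        y = (ht - 0.2) / ht
    elif icl > 0.3:
        y = 0.5
    else:
        y = 0.1
    # cylindrical clothing shell
    circumference = 2.0 * math.pi * ht * y
    r2 = a_du * (f_cl - 1.0 + f_covered) / circumference
    r1 = f_covered * a_du / circumference
    a_clothed = a_du * f_covered + a_du * (f_cl - 1.0)
    h_clothing = (
        2.0 * math.pi * ht * y * (r2 - r1) / (r_cl * math.log(r2 / r1) * a_clothed)
    )
    f_eff = RADIATION_AREA_FACTOR[position]
    return BodyModel(
        a_du=a_du,
        met=met,
        internal_heat=internal_heat,
        breath_rate=breath_rate,
        sweat_factor=sweat_factor,
        f_covered=f_covered,
        f_cl=f_cl,
        a_clothed=a_clothed,
        a_eff_rad=a_du * f_eff,
        r_cl=r_cl,
        h_clothing=h_clothing,
    )


def respiration(t_a: float, vp: float, body: BodyModel, p: float = P_REF) -> float:
    """Respiratory heat exchange (W); negative = loss."""
    t_ex = 0.47 * t_a + 21.0
    sensible = C_AIR * (t_a - t_ex) * body.breath_rate
    vp_ex = sat_vp(t_ex)
    latent = 0.623 * L_VAP / p * (vp - vp_ex) * body.breath_rate
    return sensible + latent


def _sweat_evaporation(
    t_core: float, t_sk: float, vp: float, h_c: float, body: BodyModel, p: float
) -> tuple[float, float]:
    """Sweat evaporation heat flux (W, <= 0) and wetted-skin fraction."""
    t_body = 0.1 * t_sk + 0.9 * t_core
    rate = SWEAT_COEF * (t_body - CORE_SET) * body.a_du / 3.6e6  # kg/s
    rate = max(rate, 0.0) * body.sweat_factor
    e_phys = -rate * L_VAP
    vp_sk = sat_vp(t_sk)
    h_e = 0.633 * h_c / (p * C_AIR)
    f_ec = 1.0 / (1.0 + 0.92 * h_c * body.r_cl)
    e_pot = h_e * (vp - vp_sk) * body.a_du * L_VAP * f_ec
    if e_pot >= 0.0:
        # environment vapor pressure at or above skin saturation: no
        # evaporative cooling is possible
        return 0.0, 1.0
    wetted = min(e_phys / e_pot, 1.0)
    e_sw = max(e_phys, e_pot)  # both negative; capped by the potential
    return e_sw, wetted


def blood_flow(t_core: float, t_sk: float) -> float:
    """Skin blood flow (L m-2 h-1) from core and skin signals."""
    sig_core = max(t_core - CORE_SET, 0.0)
    sig_skin = max(SKIN_SET - t_sk, 0.0)
    return min((BLOOD_FLOW_MIN + 75.0 * sig_core) / (1.0 + 0.5 * sig_skin), BLOOD_FLOW_MAX)


def core_to_skin_flux(t_core: float, t_sk: float, body: BodyModel) -> float:
    """Heat transported from core to skin (W): tissue + blood flow."""
    vb = blood_flow(t_core, t_sk)
    conductance = TISSUE_CONDUCTANCE + vb * RHO_BLOOD * C_BLOOD / 3600.0
    return body.a_du * conductance * (t_core - t_sk)


@dataclass
class BalanceState:
    """Solved heat-balance state in the actual environment."""

    t_core: float
    t_skin: float
    t_clothing: float
    wetted_fraction: float
    e_sweat: float  # W
    body: BodyModel
    t_a: float
    t_mrt: float
    vp: float
    v: float
    pressure: float
    residuals: tuple[float, float, float]


def _residuals(
    x: np.ndarray, t_a: float, t_mrt: float, vp: float, v: float, body: BodyModel, p: float
) -> tuple[float, float, float]:
    t_core, t_sk, t_cl = x
    h_c = heat_transfer_coefficient(v, p)
    a_bare = body.a_du * (1.0 - body.f_covered)
    mrt_k4 = (t_mrt + _KELVIN) ** 4
    r_bare = body.a_eff_rad / body.a_du * a_bare * EM_SKIN * SIGMA * (
        mrt_k4 - (t_sk + _KELVIN) ** 4
    )
    r_clo = (
        RADIATION_AREA_FACTOR["standing"]
        * body.a_clothed
        * EM_CLOTHING
        * SIGMA
        * (mrt_k4 - (t_cl + _KELVIN) ** 4)
    )
    c_bare = h_c * (t_a - t_sk) * a_bare
    c_clo = h_c * (t_a - t_cl) * body.a_clothed

    e_sw, wetted = _sweat_evaporation(t_core, t_sk, vp, h_c, body, p)
    vp_sk = sat_vp(t_sk)
    e_diff = L_VAP / R_DIFF_SKIN * body.a_du * (1.0 - wetted) * (vp - vp_sk)

    ere = respiration(t_a, vp, body, p)
    f_cs = core_to_skin_flux(t_core, t_sk, body)
    f_sk_cl = body.h_clothing * body.a_clothed * (t_sk - t_cl)

    res_core = body.internal_heat + ere - f_cs
    res_skin = f_cs + r_bare + c_bare + e_diff + e_sw - f_sk_cl
    res_cloth = f_sk_cl + r_clo + c_clo
    return res_core, res_skin, res_cloth


_STARTS = (
    (36.9, 34.0, None),
    (37.2, 35.5, None),
    (36.7, 30.0, None),
    (37.5, 36.5, None),
    (36.6, 25.0, None),
)


def solve_heat_balance(
    t_a: float,
    t_mrt: float,
    vp: float,
    v: float,
    person: "PersonParameters",
    pressure: float = P_REF,
    tol: float = 1e-3,
) -> BalanceState:
    """Solve for (t_core, t_skin, t_clothing) in the actual environment."""
    body = build_body(person)

    def fun(x):
        return _residuals(x, t_a, t_mrt, vp, v, body, pressure)

    last = None
    for t_core0, t_sk0, _ in _STARTS:
        t_cl0 = (t_a + t_mrt + t_sk0) / 3.0
        sol = optimize.root(fun, x0=[t_core0, t_sk0, t_cl0], method="hybr")
        res = fun(sol.x)
        last = (sol, res)
        if max(abs(r) for r in res) < 0.1:
            t_core, t_sk, t_cl = (float(w) for w in sol.x)
            h_c = heat_transfer_coefficient(v, pressure)
            e_sw, wetted = _sweat_evaporation(t_core, t_sk, vp, h_c, body, pressure)
            return BalanceState(
                t_core=t_core,
                t_skin=t_sk,
                t_clothing=t_cl,
                wetted_fraction=wetted,
                e_sweat=e_sw,
                body=body,
                t_a=t_a,
                t_mrt=t_mrt,
                vp=vp,
                v=v,
                pressure=pressure,
                residuals=tuple(float(r) for r in res),
            )
    raise ConvergenceError(
        f"heat balance did not converge for t_a={t_a}, t_mrt={t_mrt}, "
        f"vp={vp}, v={v}; last residuals {last[1]}"
    )


def reference_balance(tx: float, state: BalanceState) -> float:
    """Energy balance (W) in the reference environment at air temperature tx.

    The physiological state (skin/clothing temperatures, wetted fraction,
    sweat evaporation) is frozen at the actual-environment solution.
    """
    body = state.body
    p = state.pressure
    h_c = heat_transfer_coefficient(REFERENCE_AIR_SPEED, p)
    a_bare = body.a_du * (1.0 - body.f_covered)
    tx_k4 = (tx + _KELVIN) ** 4
    r_bare = body.a_eff_rad / body.a_du * a_bare * EM_SKIN * SIGMA * (
        tx_k4 - (state.t_skin + _KELVIN) ** 4
    )
    r_clo = (
        RADIATION_AREA_FACTOR["standing"]
        * body.a_clothed
        * EM_CLOTHING
        * SIGMA
        * (tx_k4 - (state.t_clothing + _KELVIN) ** 4)
    )
    c_bare = h_c * (tx - state.t_skin) * a_bare
    c_clo = h_c * (tx - state.t_clothing) * body.a_clothed
    vp_sk = sat_vp(state.t_skin)
    e_diff = (
        L_VAP / R_DIFF_SKIN * body.a_du * (1.0 - state.wetted_fraction)
        * (REFERENCE_VP - vp_sk)
    )
    ere = respiration(tx, REFERENCE_VP, body, p)
    return (
        body.internal_heat + ere + r_bare + r_clo + c_bare + c_clo + e_diff + state.e_sweat
    )


def reference_temperature(
    state: BalanceState,
    person: "PersonParameters",
    lo: float = -50.0,
    hi: float = 80.0,
    tol: float = 0.01,
    max_iter: int = 100,
) -> float:
    """PET: bisect the reference air temperature closing the frozen balance."""
    f_lo = reference_balance(lo, state)
    f_hi = reference_balance(hi, state)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if f_lo * f_hi > 0:
        raise ConvergenceError(
            f"reference balance has no sign change on [{lo}, {hi}] "
            f"(f({lo})={f_lo:.2f}, f({hi})={f_hi:.2f}); "
            f"state: t_skin={state.t_skin:.2f}, t_cl={state.t_clothing:.2f}"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = reference_balance(mid, state)
        if f_mid == 0.0 or (hi - lo) / 2.0 < tol:
            return mid
        if f_lo * f_mid < 0:
            hi = mid
        else:
            lo, f_lo = mid, f_mid
    raise ConvergenceError("reference temperature bisection exceeded max iterations")
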