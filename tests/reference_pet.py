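"""Independent PET reference: the same published heat-balance model,
re-derived from scratch and solved by nested scalar bisection only.

This module deliberately shares no code with the package. Every constant
and flux term is written out again from the published model description,
and the coupled (core, skin, clothing) state is found by nesting three
one-dimensional bisections instead of a multidimensional root solver, so
that solver errors and transcription errors in the package cannot cancel.
"""

from __future__ import annotations

import math

# standardized person
_MBODY = 75.0  # kg
_HT = 1.75  # m
_AGE = 35.0
_WORK = 80.0  # W
_ICL = 0.9  # clo

_SIGMA = 5.67e-8
_CAIR = 1010.0
_LVAP = 2.42e6
_PO = 1013.25
_EMSK, _EMCL = 0.99, 0.95
_FEFF = 0.725


def _sat(t: float) -> float:
    return 6.11 * 10.0 ** (7.45 * t / (235.0 + t))


def _person():
    adu = 0.203 * _MBODY**0.425 * _HT**0.725
    basal = (
        3.45
        * _MBODY**0.75
        * (1 + 0.004 * (30 - _AGE) + 0.010 * (_HT * 100 / _MBODY ** (1 / 3.0) - 43.4))
    )
    met = _WORK + basal
    rtv = 1.44e-6 * met
    facl = (-2.36 + 173.51 * _ICL - 100.76 * _ICL**2 + 19.28 * _ICL**3) / 100.0
    fcl = 1.0 + 0.31 * _ICL
    rcl = _ICL / 6.45 / facl
    y = (_HT - 0.2) / _HT  # 0.6 < icl < 2
    circ = 2.0 * math.pi * _HT * y
    r2 = adu * (fcl - 1.0 + facl) / circ
    r1 = facl * adu / circ
    acl = adu * facl + adu * (fcl - 1.0)
    htcl = circ * (r2 - r1) / (rcl * math.log(r2 / r1) * acl)
    return adu, met, rtv, facl, acl, htcl


_ADU, _MET, _RTV, _FACL, _ACL, _HTCL = _person()


def _hc(v: float) -> float:
    return 2.67 + 6.5 * v**0.67


def _respiration(ta: float, vp: float) -> float:
    tex = 0.47 * ta + 21.0
    return _CAIR * (ta - tex) * _RTV + 0.623 * _LVAP / _PO * (vp - _sat(tex)) * _RTV


def _sweat(tcore: float, tsk: float, vp: float, hc: float):
    tbody = 0.1 * tsk + 0.9 * tcore
    rate = max(304.94 * (tbody - 36.6) * _ADU / 3.6e6, 0.0)
    e_phys = -rate * _LVAP
    he = 0.633 * hc / (_PO * _CAIR)
    rcl = _ICL / 6.45 / _FACL
    fec = 1.0 / (1.0 + 0.92 * hc * rcl)
    e_pot = he * (vp - _sat(tsk)) * _ADU * _LVAP * fec
    if e_pot >= 0.0:
        return 0.0, 1.0
    wet = min(e_phys / e_pot, 1.0)
    return max(e_phys, e_pot), wet


def _core_flux(tcore: float, tsk: float) -> float:
    vb = (6.3 + 75.0 * max(tcore - 36.6, 0.0)) / (1.0 + 0.5 * max(34.0 - tsk, 0.0))
    vb = min(vb, 90.0)
    return _ADU * (5.28 + vb * 1.06 * 3640.0 / 3600.0) * (tcore - tsk)


def _bisect(f, lo, hi, tol=1e-4, it=200):
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    assert flo * fhi < 0, "no sign change in bracket"
    for _ in range(it):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if fm == 0.0 or hi - lo < tol:
            return mid
        if flo * fm < 0:
            hi = mid
        else:
            lo, flo = mid, fm
    return 0.5 * (lo + hi)


def _tcl_for(tsk: float, ta: float, tmrt: float, hc: float) -> float:
    def res(tcl):
        rclo = _FEFF * _ACL * _EMCL * _SIGMA * ((tmrt + 273.2) ** 4 - (tcl + 273.2) ** 4)
        cclo = hc * (ta - tcl) * _ACL
        return _HTCL * _ACL * (tsk - tcl) + rclo + cclo

    return _bisect(res, -100.0, 150.0)


def _tcore_for(tsk: float, ta: float, vp: float) -> float:
    c0 = _MET + _respiration(ta, vp)

    def res(tcore):
        return c0 - _core_flux(tcore, tsk)

    return _bisect(res, tsk, tsk + 60.0)


def _total_balance(tsk: float, ta: float, tmrt: float, vp: float, v: float):
    hc = _hc(max(v, 0.1))
    tcl = _tcl_for(tsk, ta, tmrt, hc)
    tcore = _tcore_for(tsk, ta, vp)
    abare = _ADU * (1.0 - _FACL)
    rbare = _FEFF * abare * _EMSK * _SIGMA * ((tmrt + 273.2) ** 4 - (tsk + 273.2) ** 4)
    rclo = _FEFF * _ACL * _EMCL * _SIGMA * ((tmrt + 273.2) ** 4 - (tcl + 273.2) ** 4)
    cbare = hc * (ta - tsk) * abare
    cclo = hc * (ta - tcl) * _ACL
    esw, wet = _sweat(tcore, tsk, vp, hc)
    ediff = _LVAP / 0.79e7 * _ADU * (1.0 - wet) * (vp - _sat(tsk))
    bal = _MET + _respiration(ta, vp) + rbare + rclo + cbare + cclo + ediff + esw
    return bal, tcore, tcl, esw, wet


def solve_state(ta: float, tmrt: float, vp: float, v: float):
    """Skin-temperature scan + bisection for the coupled balance."""
    grid = [(-40.0 + 0.5 * i) for i in range(165)]  # -40 .. 42
    prev_t, prev_b = None, None
    bracket = None
    for tsk in grid:
        bal = _total_balance(tsk, ta, tmrt, vp, v)[0]
        if prev_b is not None and prev_b * bal <= 0.0:
            bracket = (prev_t, tsk)
            break
        prev_t, prev_b = tsk, bal
    assert bracket is not None, f"no balance root for ta={ta}, tmrt={tmrt}"
    tsk = _bisect(lambda t: _total_balance(t, ta, tmrt, vp, v)[0], *bracket)
    _, tcore, tcl, esw, wet = _total_balance(tsk, ta, tmrt, vp, v)
    return tcore, tsk, tcl, esw, wet


def reference_pet(ta: float, tmrt: float, vp: float, v: float) -> float:
    """PET by frozen-state reference search over a scanned bracket."""
    tcore, tsk, tcl, esw, wet = solve_state(ta, tmrt, vp, v)
    hc = _hc(0.1)
    abare = _ADU * (1.0 - _FACL)

    def ref_balance(tx):
        rbare = _FEFF * abare * _EMSK * _SIGMA * ((tx + 273.2) ** 4 - (tsk + 273.2) ** 4)
        rclo = _FEFF * _ACL * _EMCL * _SIGMA * ((tx + 273.2) ** 4 - (tcl + 273.2) ** 4)
        cbare = hc * (tx - tsk) * abare
        cclo = hc * (tx - tcl) * _ACL
        ediff = _LVAP / 0.79e7 * _ADU * (1.0 - wet) * (12.0 - _sat(tsk))
        return _MET + _respiration(tx, 12.0) + rbare + rclo + cbare + cclo + ediff + esw

    return _bisect(ref_balance, -60.0, 90.0, tol=1e-3)
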