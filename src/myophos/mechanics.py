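"""Force laws of the four MTU elements and the contraction dynamics.

The contractile element (CE, in parallel with the PEE) operates in
series with the serial elastic element (SEE, in parallel with the
damping element SDE).  The contraction velocity follows from the force
balance

    F_CE(vCE) + F_PEE(lCE) = F_SEE(lSEE) + d_SE * (vMTU - vCE),

which per force-velocity branch is a quadratic in vCE, because F_CE is
hyperbolic in vCE and the damping coefficient d_SE depends linearly on
the instantaneous CE force.
"""

from __future__ import annotations

import math

from scipy.optimize import brentq

from .params import MTUKinematics, MTUParameters

__all__ = [
    "isometric_force_length",
    "pee_force",
    "see_force",
    "hill_coefficients",
    "ce_force",
    "serial_damping_coefficient",
    "contraction_velocity",
    "passive_equilibrium",
]

#: residual tolerance of the contraction-velocity force balance, as a
#: fraction of Fmax
BALANCE_RTOL = 1e-9


class ForceBalanceError(RuntimeError):
    """No real root of the contraction force balance; carries the state."""

    def __init__(self, msg: str, state: dict):
        super().__init__(f"{msg}; state={state}")
        self.state = state


def isometric_force_length(lCE: float, p: MTUParameters) -> float:
    """Normalized bell-shaped force-length relation of the CE.

    ``exp(-|(lCE/lCEopt - 1)/dW|**nu)`` with ascending-limb width/exponent
    below the optimal length and descending-limb values above.  Maximum 1
    exactly at ``lCEopt``.
    """
    if lCE <= 0.0:
        raise ValueError(f"lCE must be positive, got {lCE}")
    x = lCE / p.lCEopt - 1.0
    if x < 0.0:
        return math.exp(-((-x / p.dW_asc) ** p.nu_asc))
    return math.exp(-((x / p.dW_des) ** p.nu_des))


def pee_force(lCE: float, p: MTUParameters) -> float:
    """Parallel elastic force: power law above the PEE slack length.

    Normalized so the PEE carries ``F_PEE * Fmax`` at the end of the
    descending limb, ``lCE = lCEopt*(1 + dW_des)``.
    """
    if lCE <= 0.0:
        raise ValueError(f"lCE must be positive, got {lCE}")
    slack = p.L_PEE * p.lCEopt
    if lCE <= slack:
        return 0.0
    span = p.lCEopt * (1.0 + p.dW_des) - slack
    k = p.F_PEE * p.Fmax / span**p.nu_PEE
    return k * (lCE - slack) ** p.nu_PEE


def see_force(lSEE: float, p: MTUParameters) -> float:
    """Serial elastic force: nonlinear toe region, then linear.

    The toe exponent ``dU_SEE_nll/dU_SEE_l`` makes value and slope
    continuous at the transition length ``(1+dU_SEE_nll)*lSEE0``; the
    linear stiffness is ``dF_SEE0/(dU_SEE_l*lSEE0)``.
    """
    if lSEE <= p.lSEE0:
        return 0.0
    l_nll = (1.0 + p.dU_SEE_nll) * p.lSEE0
    if lSEE < l_nll:
        nu = p.dU_SEE_nll / p.dU_SEE_l
        return p.dF_SEE0 * ((lSEE - p.lSEE0) / (l_nll - p.lSEE0)) ** nu
    k_lin = p.dF_SEE0 / (p.dU_SEE_l * p.lSEE0)
    return p.dF_SEE0 + k_lin * (lSEE - l_nll)


def hill_coefficients(
    a: float, lCE_rel: float, p: MTUParameters, activity_scaling: bool = True
) -> tuple[float, float]:
    """Activity- and length-scaled Hill constants (Arel, Brel).

    ``Arel = Arel0 * L_A * Q_A(a)``, ``Brel = Brel0 * Q_B(a)`` with
    ``Q_A = (1+3a)/4``, ``Q_B = (3+4a)/7`` (identity when
    ``activity_scaling`` is off) and ``L_A = 1`` on the ascending limb,
    the force-length value on the descending limb.
    """
    if activity_scaling:
        q_a = (1.0 + 3.0 * a) / 4.0
        q_b = (3.0 + 4.0 * a) / 7.0
    else:
        q_a = q_b = 1.0
    l_a = 1.0 if lCE_rel <= 1.0 else isometric_force_length(lCE_rel * p.lCEopt, p)
    return p.Arel0 * l_a * q_a, p.Brel0 * q_b


def _hyperbola_coeffs(
    a: float, fisom: float, Arel: float, Brel: float, p: MTUParameters, eccentric: bool
) -> tuple[float, float, float]:
    """(P, A, s) of the branch hyperbola F_CE(v) = Fmax*(P/(1 - v/s) - A)."""
    af = a * fisom
    if not eccentric:
        return af + Arel, Arel, Brel * p.lCEopt
    # eccentric: value af and slope S_e * concentric slope at v=0,
    # asymptote F_e*af as v -> +inf
    P = af * (1.0 - p.F_e)
    A = -p.F_e * af
    if P == 0.0:
        return 0.0, 0.0, -1.0  # degenerate: zero activity, F identically 0
    s = Brel * p.lCEopt * P / (p.S_e * (af + Arel))
    return P, A, s


def ce_force(vCE: float, a: float, lCE: float, p: MTUParameters) -> float:
    """Hill hyperbolic CE force at contraction velocity ``vCE`` (m/s).

    Negative ``vCE`` is shortening (concentric branch); positive is
    lengthening (eccentric branch, asymptote ``F_e*a*Fisom*Fmax``).
    """
    fisom = isometric_force_length(lCE, p)
    Arel, Brel = hill_coefficients(a, lCE / p.lCEopt, p)
    P, A, s = _hyperbola_coeffs(a, fisom, Arel, Brel, p, eccentric=vCE > 0.0)
    if P == 0.0 and A == 0.0:
        return 0.0
    return p.Fmax * (P / (1.0 - vCE / s) - A)


def serial_damping_coefficient(F_ce_pee: float, p: MTUParameters) -> float:
    """Damping coefficient of the SDE [N s/m], linear in the CE+PEE force."""
    if F_ce_pee < 0.0:
        raise ValueError(f"F_ce_pee must be non-negative, got {F_ce_pee}")
    d_max = p.D_SDE * p.Fmax * p.Arel0 / (p.lCEopt * p.Brel0)
    return d_max * ((1.0 - p.R_SDE) * F_ce_pee / p.Fmax + p.R_SDE)


def _balance_residual(
    v: float, lMTU: float, vMTU: float, lCE: float, a: float, p: MTUParameters
) -> float:
    f_ce = ce_force(v, a, lCE, p)
    f_pee = pee_force(lCE, p)
    f_see = see_force(lMTU - lCE, p)
    d = serial_damping_coefficient(max(f_ce + f_pee, 0.0), p)
    return f_ce + f_pee - f_see - d * (vMTU - v)


def contraction_velocity(
    kin: MTUKinematics, a: float, p: MTUParameters
) -> float:
    """CE velocity solving the force balance of the four elements.

    Solves the per-branch quadratic analytically and verifies the root by
    substitution; falls back to bracketed root-finding when the analytic
    root is rejected.  Raises :class:`ForceBalanceError` if no root exists.
    """
    lMTU, vMTU, lCE = kin.lMTU, kin.vMTU, kin.lCE
    fisom = isometric_force_length(lCE, p)
    f_pee = pee_force(lCE, p)
    f_see = see_force(lMTU - lCE, p)
    Arel, Brel = hill_coefficients(a, lCE / p.lCEopt, p)
    d_max = p.D_SDE * p.Fmax * p.Arel0 / (p.lCEopt * p.Brel0)
    alpha = d_max * ((1.0 - p.R_SDE) * f_pee / p.Fmax + p.R_SDE)
    beta = d_max * (1.0 - p.R_SDE) / p.Fmax

    af = a * fisom
    f_ce0 = p.Fmax * af
    g0 = f_ce0 + f_pee - f_see - (alpha + beta * f_ce0) * vMTU
    tol = BALANCE_RTOL * p.Fmax
    if abs(g0) <= tol:
        return 0.0
    eccentric = g0 < 0.0

    P, A, s = _hyperbola_coeffs(a, fisom, Arel, Brel, p, eccentric)
    if eccentric and P == 0.0 and A == 0.0:
        # zero activity: balance is linear, F_CE == 0
        # 0 + f_pee - f_see - (alpha)*(vMTU - v) = 0
        if alpha == 0.0:
            raise ForceBalanceError(
                "degenerate balance with zero damping and zero activity",
                {"lMTU": lMTU, "vMTU": vMTU, "lCE": lCE, "a": a},
            )
        return vMTU - (f_pee - f_see) / alpha

    # quadratic in w = v/s (see module docstring); both valid branches
    # have w <= 0 and 1 - w > 0
    C = f_pee - f_see - p.Fmax * A
    D0 = alpha - beta * p.Fmax * A
    E = beta * p.Fmax * P
    a2 = -D0 * s
    a1 = -C + D0 * s + D0 * vMTU + E * s
    a0 = p.Fmax * P + C - (D0 + E) * vMTU

    roots: list[float] = []
    if abs(a2) < 1e-300:
        if a1 != 0.0:
            roots.append(-a0 / a1)
    else:
        disc = a1 * a1 - 4.0 * a2 * a0
        if disc >= 0.0:
            sq = math.sqrt(disc)
            roots.extend(((-a1 + sq) / (2.0 * a2), (-a1 - sq) / (2.0 * a2)))

    best_v, best_res = None, math.inf
    for w in roots:
        if w >= 1.0:
            continue
        v = s * w
        if eccentric and v < -1e-15:
            continue
        if not eccentric and v > 1e-15:
            continue
        res = abs(_balance_residual(v, lMTU, vMTU, lCE, a, p))
        if res < best_res:
            best_v, best_res = v, res
    if best_v is not None and best_res <= tol:
        return best_v

    # bracketed fallback: g is increasing in v away from v=0
    g = lambda v: _balance_residual(v, lMTU, vMTU, lCE, a, p)
    lo, hi = (0.0, 1e-6) if eccentric else (-1e-6, 0.0)
    for _ in range(80):
        if eccentric:
            if g(hi) >= 0.0:
                break
            hi *= 2.0
        else:
            if g(lo) <= 0.0:
                break
            lo *= 2.0
    else:
        raise ForceBalanceError(
            "no real root of the contraction force balance",
            {"lMTU": lMTU, "vMTU": vMTU, "lCE": lCE, "a": a, "g0": g0},
        )
    return brentq(g, lo, hi, xtol=1e-14, rtol=8.9e-16)


def passive_equilibrium(lMTU: float, a_rest: float, p: MTUParameters) -> float:
    """CE length of the static pre-stimulation equilibrium.

    Solves ``F_SEE(lMTU - lCE) = a_rest*Fmax*Fisom(lCE) + F_PEE(lCE)``.
    When both elastic elements are slack and ``a_rest`` vanishes (MTU
    shorter than the combined slack lengths) the balance is degenerate;
    the SEE slack boundary ``lCE = lMTU - lSEE0`` is returned, which is
    the continuous limit of the equilibrium as ``a_rest -> 0+``.
    """
    if lMTU <= p.lSEE0:
        raise ValueError(f"lMTU={lMTU} must exceed the tendon slack length {p.lSEE0}")

    def h(lce: float) -> float:
        return (
            a_rest * p.Fmax * isometric_force_length(lce, p)
            + pee_force(lce, p)
            - see_force(lMTU - lce, p)
        )

    hi = lMTU - p.lSEE0  # SEE slack boundary: F_SEE = 0 at/above
    if h(hi) <= 0.0:
        # no muscle force to stretch the tendon: both elements slack
        return hi
    lo = min(1e-6, 0.5 * hi)
    if h(lo) > 0.0:
        raise ValueError(
            f"no passive equilibrium bracket for lMTU={lMTU}: MTU too short/long"
        )
    return brentq(h, lo, hi, xtol=1e-15, rtol=8.9e-16)
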