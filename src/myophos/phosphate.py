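"""ATP hydrolysis/condensation kinetics with CK/AdK equilibrium pools.

The single dynamic metabolic state is the free inorganic phosphate
concentration [Pi], advanced by the first-order hydrolysis/condensation
ODE

    d[Pi]/dt = k_hyd * [ATP] - k_con * [ADP] * [Pi] / c0,

whose stationary point is the mass-action equilibrium
``[ATP]*c0/([ADP]*[Pi]) = k_con/k_hyd``.  All other concentrations are
slaved to [Pi] through the fast creatine-kinase (CK) and adenylate-kinase
(AdK) equilibria plus conservation of the adenine, creatine and
phosphate pools.  The relative chemical potential of ATP,

    mu_rel = (-dG0_ATP + R*T*ln([ATP]*c0 / ([ADP]*[Pi]))) / mu_ATP_max,

discounts the troponin activity to the muscle activity ``a = q * mu_rel``.

Concentrations are in mM throughout; the standard concentration c0 = 1 M
enters as 1000 mM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = [
    "MetabolicConstants",
    "MetabolicState",
    "hydrolysis_rate",
    "pi_rate",
    "resting_state",
    "equilibrate_pools",
    "chemical_potential",
    "activity",
]


@dataclass
class MetabolicConstants:
    """The metabolic constants of the phosphate sub-model.

    Defaults are literature values for mammalian skeletal muscle; the
    temperature matches the heated (39 C) preparation the mechanical
    parameters were fitted to.  ``dG0_ATP=None`` calibrates the standard
    free-energy offset at startup so that ``mu_rel = 1`` exactly in the
    resting equilibrated fiber.
    """

    ADP0: float = 0.01          # initial [ADP] [mM]
    ATPmin: float = 1.2         # hard floor on [ATP] [mM]
    c_ad: float = 7.0           # total adenine pool [mM]
    c_cr: float = 25.0          # total creatine pool [mM]
    c_ph: float = 46.0          # total phosphate pool [mM]
    K_adk: float = 1.0          # adenylate kinase equilibrium constant
    K_ck: float = 200.0         # creatine kinase equilibrium constant
    k_con: float = 0.1          # condensation rate constant [1/s]
    c0: float = 1000.0          # standard concentration [mM]
    R_gas: float = 8.314e-3     # gas constant [kJ/(mol K)]
    T: float = 312.15           # temperature [K] (39 C)
    mu_ATP_max: float = 60.0    # max chemical potential of resting ATP [kJ/mol]
    dG0_ATP: float | None = None  # standard free energy [kJ/mol]; None = calibrate
    accounting: str = "nucleotide"  # phosphate pool accounting: nucleotide | free

    def __post_init__(self) -> None:
        for name in ("ADP0", "ATPmin", "c_ad", "c_cr", "c_ph", "K_adk", "K_ck",
                     "k_con", "c0", "R_gas", "T", "mu_ATP_max"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")
        if self.ATPmin >= self.c_ad:
            raise ValueError("ATPmin must be below the total adenine pool")
        if self.accounting not in ("nucleotide", "free"):
            raise ValueError("accounting must be 'nucleotide' or 'free'")
        self._dG0_cache: float | None = None

    def dG0(self) -> float:
        """Standard free-energy term; calibrated lazily when unset."""
        if self.dG0_ATP is not None:
            return self.dG0_ATP
        if self._dG0_cache is None:
            st = resting_state(self)
            ratio = st.ATP * self.c0 / (st.ADP * st.Pi)
            self._dG0_cache = self.R_gas * self.T * math.log(ratio) - self.mu_ATP_max
        return self._dG0_cache


@dataclass
class MetabolicState:
    """Concentrations [mM] and the relative chemical potential at one instant."""

    ATP: float
    ADP: float
    AMP: float
    Pi: float
    PCr: float
    Cr: float
    mu_rel: float
    clamped: bool = False  # True when the ATPmin floor binds


def hydrolysis_rate(q: float, lCE_rel: float, khyd_hat: float) -> float:
    """ATP hydrolysis rate constant ``khyd_hat * q / lCE_rel`` [1/s]."""
    if lCE_rel <= 0.0:
        raise ValueError(f"lCE_rel must be positive, got {lCE_rel}")
    return khyd_hat * q / lCE_rel


def pi_rate(state: MetabolicState, k_hyd: float, mc: MetabolicConstants) -> float:
    """d[Pi]/dt [mM/s] of the hydrolysis/condensation ODE."""
    return k_hyd * state.ATP - mc.k_con * state.ADP * state.Pi / mc.c0


def _adp_from_atp(atp: float, mc: MetabolicConstants) -> float:
    """[ADP] on the AdK manifold: ATP*AMP = K_adk*ADP^2 with pool closure."""
    rad = atp * atp + 4.0 * mc.K_adk * atp * (mc.c_ad - atp)
    return (-atp + math.sqrt(rad)) / (2.0 * mc.K_adk)


def _pools_from_atp(atp: float, pi: float, mc: MetabolicConstants):
    adp = _adp_from_atp(atp, mc)
    amp = mc.c_ad - atp - adp
    if mc.accounting == "nucleotide":
        pcr = mc.c_ph - mc.c_ad - pi - 2.0 * atp - adp
    else:
        pcr = mc.c_ph - pi
    cr = mc.c_cr - pcr
    return adp, amp, pcr, cr


def _ck_residual(atp: float, pi: float, mc: MetabolicConstants) -> float:
    adp, _amp, pcr, cr = _pools_from_atp(atp, pi, mc)
    return atp * cr - mc.K_ck * adp * pcr


def _finish_state(atp, adp, amp, pi, pcr, cr, mc, clamped=False) -> MetabolicState:
    mu = chemical_potential_raw(atp, adp, pi, mc)
    return MetabolicState(atp, adp, amp, pi, pcr, cr, mu, clamped)


def resting_state(mc: MetabolicConstants) -> MetabolicState:
    """Resting fiber: [ADP] = ADP0, all pools on the CK/AdK equilibria.

    [Pi] is derived from the phosphate-pool closure (about 5.6 mM under
    the default nucleotide-inclusive accounting).
    """
    adp = mc.ADP0
    # AdK + adenine closure, ATP the dominant root of the quadratic
    b = mc.c_ad - adp
    atp = 0.5 * (b + math.sqrt(b * b - 4.0 * mc.K_adk * adp * adp))
    amp = mc.c_ad - atp - adp
    # CK equilibrium fixes the PCr/Cr split
    r = mc.K_ck * adp / atp  # Cr/PCr
    pcr = mc.c_cr / (1.0 + r)
    cr = mc.c_cr - pcr
    if mc.accounting == "nucleotide":
        pi = mc.c_ph - pcr - 3.0 * atp - 2.0 * adp - amp
    else:
        pi = mc.c_ph - pcr
    if pi <= 0.0:
        raise ValueError("phosphate pool too small for a positive resting [Pi]")
    return MetabolicState(atp, adp, amp, pi, pcr, cr, 1.0 if mc.dG0_ATP is None
                          else chemical_potential_raw(atp, adp, pi, mc))


def equilibrate_pools(
    Pi_target: float, mc: MetabolicConstants, atp_guess: float | None = None
) -> MetabolicState:
    """Project the pools onto the CK/AdK/conservation manifold at given [Pi].

    Scalar root-find in [ATP] (monotone along the manifold, unlike [ADP],
    which folds at ``c_ad/(1+2*sqrt(K_adk))``).  If the solution falls
    below the ``ATPmin`` floor, [ATP] is clamped there, the CK equilibrium
    is released, and the state is flagged so callers can zero the
    hydrolysis flux.
    """
    if Pi_target <= 0.0:
        raise ValueError(f"Pi_target must be positive, got {Pi_target}")
    lo, hi = 1e-12, mc.c_ad - 1e-12
    # warm-started secant, fallback to brentq
    atp = None
    if atp_guess is not None and lo < atp_guess < hi:
        x0 = atp_guess
        f0 = _ck_residual(x0, Pi_target, mc)
        x1 = min(max(x0 * (1.0 + 1e-6) + 1e-9, lo), hi)
        f1 = _ck_residual(x1, Pi_target, mc)
        for _ in range(30):
            if f1 == f0:
                break
            x2 = x1 - f1 * (x1 - x0) / (f1 - f0)
            if not (lo < x2 < hi):
                break
            x0, f0, x1, f1 = x1, f1, x2, _ck_residual(x2, Pi_target, mc)
            if abs(f1) < 1e-11 * mc.c_ad * mc.c_cr:
                atp = x1
                break
    if atp is None:
        f_lo = _ck_residual(lo, Pi_target, mc)
        f_hi = _ck_residual(hi, Pi_target, mc)
        if f_lo * f_hi > 0.0:
            raise ValueError(
                f"Pi_target={Pi_target} mM outside the feasible pool range"
            )
        atp = brentq(_ck_residual, lo, hi, args=(Pi_target, mc),
                     xtol=1e-14, rtol=8.9e-16)

    adp, amp, pcr, cr = _pools_from_atp(atp, Pi_target, mc)
    if min(pcr, cr) < -1e-9:
        raise ValueError(
            f"Pi_target={Pi_target} mM infeasible: creatine pool split "
            f"PCr={pcr}, Cr={cr}"
        )
    if atp < mc.ATPmin:
        return _clamped_state(Pi_target, mc)
    return _finish_state(atp, adp, amp, Pi_target, max(pcr, 0.0), min(cr, mc.c_cr), mc)


def _clamped_state(pi: float, mc: MetabolicConstants) -> MetabolicState:
    """[ATP] held at the floor; AdK and pool conservation kept, CK released."""
    atp = mc.ATPmin
    adp = _adp_from_atp(atp, mc)
    amp = mc.c_ad - atp - adp
    if mc.accounting == "nucleotide":
        pcr = mc.c_ph - mc.c_ad - pi - 2.0 * atp - adp
    else:
        pcr = mc.c_ph - pi
    pcr = min(max(pcr, 0.0), mc.c_cr)
    cr = mc.c_cr - pcr
    return _finish_state(atp, adp, amp, pi, pcr, cr, mc, clamped=True)


def chemical_potential_raw(
    atp: float, adp: float, pi: float, mc: MetabolicConstants
) -> float:
    if min(atp, adp, pi) <= 0.0:
        raise ValueError("concentrations must be positive for the chemical potential")
    rt = mc.R_gas * mc.T
    return (-mc.dG0() + rt * math.log(atp * mc.c0 / (adp * pi))) / mc.mu_ATP_max


def chemical_potential(state: MetabolicState, mc: MetabolicConstants) -> float:
    """Relative chemical potential of ATP (1 in the calibrated resting fiber)."""
    return chemical_potential_raw(state.ATP, state.ADP, state.Pi, mc)


def activity(q: float, mu_rel: float) -> float:
    """Muscle activity: force-producing cross-bridge fraction ``q * mu_rel``."""
    return q * mu_rel
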