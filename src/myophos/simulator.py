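"""Forward simulation of isometric contractions.

State vector (gamma, lCE, Pi): calcium relaxation, contraction dynamics
from the element force balance, and the phosphate ODE, with the
remaining metabolite pools projected onto the CK/AdK equilibrium
manifold at every evaluation (operator splitting of the underlying DAE).
Integration is piecewise between stimulation breakpoints with LSODA and
dense output on the protocol's sampling grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import odeint

from . import activation as act
from . import mechanics as mech
from . import phosphate as phos
from .params import MTUKinematics, MTUParameters
from .phosphate import MetabolicConstants

__all__ = [
    "StimulationProtocol",
    "SimulationResult",
    "default_protocol",
    "constant_protocol",
    "simulate",
    "simulate_batch",
]

log = logging.getLogger("myophos")

#: default integrator tolerances
RTOL = 1e-8
ATOL = (1e-10, 1e-12, 1e-9)  # gamma, lCE [m], Pi [mM]


@dataclass
class StimulationProtocol:
    """Piecewise-constant stimulation u(t) on [0, duration]."""

    breakpoints: tuple[float, ...]  # segment start times, first must be 0
    levels: tuple[float, ...]       # u per segment, each in [0, 1]
    duration: float                 # total runtime [s]
    sample_rate: float = 1000.0     # output grid [Hz]

    def __post_init__(self) -> None:
        b = np.asarray(self.breakpoints, dtype=float)
        u = np.asarray(self.levels, dtype=float)
        if b.size != u.size or b.size == 0:
            raise ValueError("breakpoints and levels must have equal, nonzero length")
        if b[0] != 0.0 or np.any(np.diff(b) <= 0.0):
            raise ValueError("breakpoints must start at 0 and be strictly increasing")
        if np.any((u < 0.0) | (u > 1.0)):
            raise ValueError("stimulation levels must lie in [0, 1]")
        if self.duration <= b[-1] and b.size > 1:
            raise ValueError("duration must exceed the last breakpoint")

    def u(self, t: float) -> float:
        idx = int(np.searchsorted(self.breakpoints, t, side="right")) - 1
        return float(self.levels[max(idx, 0)])

    def time_grid(self) -> np.ndarray:
        n = int(round(self.duration * self.sample_rate))
        return np.linspace(0.0, self.duration, n + 1)

    def segments(self):
        """Yield (t_start, t_end, u) covering [0, duration]."""
        edges = list(self.breakpoints) + [self.duration]
        for i, u in enumerate(self.levels):
            if edges[i] >= self.duration:
                break
            yield edges[i], min(edges[i + 1], self.duration), float(u)


def default_protocol(sample_rate: float = 1000.0) -> StimulationProtocol:
    """The isometric tetanus protocol: 0.1 s rest, 0.7 s full stimulation,
    0.4 s relaxation, sampled at 1 kHz."""
    return StimulationProtocol((0.0, 0.1, 0.8), (0.0, 1.0, 0.0), 1.2, sample_rate)


def constant_protocol(
    u: float, duration: float, sample_rate: float = 100.0
) -> StimulationProtocol:
    """Constant stimulation from t = 0 (used for exhaustion runs)."""
    return StimulationProtocol((0.0,), (float(u),), duration, sample_rate)


@dataclass
class SimulationResult:
    """Trajectories of one forward simulation on the output grid."""

    t: np.ndarray
    F_MTU: np.ndarray
    lCE: np.ndarray
    gamma: np.ndarray
    q: np.ndarray
    a_tilde: np.ndarray
    ATP: np.ndarray
    ADP: np.ndarray
    AMP: np.ndarray
    Pi: np.ndarray
    PCr: np.ndarray
    Cr: np.ndarray
    mu_rel: np.ndarray
    lMTU: float
    params: MTUParameters = field(repr=False)
    metabolic: MetabolicConstants = field(repr=False)


class _RHS:
    """ODE right-hand side with warm-started pool projection."""

    def __init__(self, p: MTUParameters, mc: MetabolicConstants, lMTU: float):
        self.p = p
        self.mc = mc
        self.lMTU = lMTU
        self.atp_guess: float | None = None

    def metabolic_state(self, pi: float) -> phos.MetabolicState:
        st = phos.equilibrate_pools(pi, self.mc, atp_guess=self.atp_guess)
        self.atp_guess = st.ATP
        return st

    def __call__(self, y, t, u: float):
        gamma, lce, pi = float(y[0]), float(y[1]), float(y[2])
        gamma = min(max(gamma, 0.0), 1.0)
        p = self.p
        lrel = lce / p.lCEopt
        q = act.troponin_activity(gamma, lrel, p)
        st = self.metabolic_state(pi)
        a = phos.activity(q, st.mu_rel)
        v = mech.contraction_velocity(MTUKinematics(self.lMTU, 0.0, lce), a, p)
        k_hyd = 0.0 if st.clamped else phos.hydrolysis_rate(q, lrel, p.khyd_hat)
        dpi = phos.pi_rate(st, k_hyd, self.mc)
        return (p.m_act * (u - gamma), v, dpi)


class SolverFailure(RuntimeError):
    """Integration failure; carries the last valid state and time."""

    def __init__(self, msg: str, t: float, y):
        super().__init__(f"{msg} at t={t:.6g}, state={list(y)}")
        self.t = t
        self.y = y


def _integrate_segments(rhs: _RHS, y0, protocol: StimulationProtocol,
                        rtol: float, atol) -> tuple[np.ndarray, np.ndarray]:
    grid = protocol.time_grid()
    out = np.empty((grid.size, 3))
    out[0] = y0
    y = np.asarray(y0, dtype=float)
    filled = 1
    for t0, t1, u in protocol.segments():
        mask = (grid > t0) & (grid <= t1)
        times = np.concatenate(([t0], grid[mask], [] if grid[mask].size and
                                np.isclose(grid[mask][-1], t1) else [t1]))
        sol, info = odeint(
            rhs, y, times, args=(u,), rtol=rtol, atol=atol,
            full_output=True, mxstep=100000,
        )
        if info["message"] != "Integration successful.":
            raise SolverFailure(info["message"], float(times[0]), y)
        n_grid = int(mask.sum())
        out[filled:filled + n_grid] = sol[1:1 + n_grid]
        filled += n_grid
        y = sol[-1]
    return grid, out


def initial_state(
    p: MTUParameters, mc: MetabolicConstants, lMTU: float
) -> tuple[float, float, float]:
    """Rest initial conditions: gamma = 0, metabolites at the resting
    equilibrium, lCE at the passive mechanical equilibrium (which includes
    the q_min-level resting activity)."""
    rest = phos.resting_state(mc)
    a_rest = phos.activity(p.q_min, rest.mu_rel)
    lce0 = mech.passive_equilibrium(lMTU, a_rest, p)
    return 0.0, lce0, rest.Pi


def _observables(rhs: _RHS, grid, states):
    p, lmtu = rhs.p, rhs.lMTU
    n = grid.size
    cols = {k: np.empty(n) for k in
            ("F_MTU", "q", "a_tilde", "ATP", "ADP", "AMP", "PCr", "Cr", "mu_rel")}
    for i in range(n):
        gamma, lce, pi = states[i]
        lrel = lce / p.lCEopt
        q = act.troponin_activity(min(max(gamma, 0.0), 1.0), lrel, p)
        st = rhs.metabolic_state(pi)
        a = phos.activity(q, st.mu_rel)
        v = mech.contraction_velocity(MTUKinematics(lmtu, 0.0, lce), a, p)
        f = mech.ce_force(v, a, lce, p) + mech.pee_force(lce, p)
        cols["F_MTU"][i] = f
        cols["q"][i] = q
        cols["a_tilde"][i] = a
        cols["ATP"][i] = st.ATP
        cols["ADP"][i] = st.ADP
        cols["AMP"][i] = st.AMP
        cols["PCr"][i] = st.PCr
        cols["Cr"][i] = st.Cr
        cols["mu_rel"][i] = st.mu_rel
    return cols


def simulate(
    p: MTUParameters,
    mc: MetabolicConstants,
    lMTU: float,
    protocol: StimulationProtocol | None = None,
    rtol: float = RTOL,
    atol=ATOL,
    y0: tuple[float, float, float] | None = None,
) -> SimulationResult:
    """Run one isometric forward simulation at fixed MTU length [m]."""
    if protocol is None:
        protocol = default_protocol()
    if lMTU <= p.lSEE0:
        raise ValueError(f"lMTU={lMTU} must exceed the tendon slack length")
    rhs = _RHS(p, mc, lMTU)
    if y0 is None:
        y0 = initial_state(p, mc, lMTU)
    grid, states = _integrate_segments(rhs, y0, protocol, rtol, atol)
    obs = _observables(rhs, grid, states)
    return SimulationResult(
        t=grid, lCE=states[:, 1].copy(), gamma=states[:, 0].copy(),
        Pi=states[:, 2].copy(), lMTU=lMTU, params=p, metabolic=mc, **obs,
    )


def simulate_batch(
    p: MTUParameters,
    mc: MetabolicConstants,
    lengths,
    protocol: StimulationProtocol | None = None,
    **kwargs,
) -> list[SimulationResult]:
    """Element-wise :func:`simulate` over a list of MTU lengths, order kept."""
    return [simulate(p, mc, float(l), protocol, **kwargs) for l in lengths]
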