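"""Exhaustion-time analyses and steady-state force/decay relations.

Exhaustion time is the first instant at which force has decayed more
than a threshold fraction (default 5%) below its reference; the default
reference is the running maximum of the trace, which coincides with the
initial value for runs started at an activated quasi-steady state and
remains well-defined for runs started from rest.  The quasi-steady force
decay rate is proportional to Fisom(lCE)/lCE, the same length scaling as
the ATP hydrolysis rate; its proportionality constant kappa is fitted in
closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import mechanics as mech
from . import phosphate as phos
from .params import MTUParameters
from .phosphate import MetabolicConstants
from .simulator import (SimulationResult, _RHS, _integrate_segments,
                        constant_protocol, initial_state, _observables, RTOL, ATOL)

__all__ = [
    "ExhaustionMap",
    "KappaFit",
    "exhaustion_time",
    "steady_decay_rate",
    "theoretical_decay_rate",
    "fit_kappa",
    "steady_state_force",
    "simulate_constant",
    "exhaustion_map",
]


def exhaustion_time(
    t: np.ndarray,
    F: np.ndarray,
    threshold: float = 0.05,
    reference: str = "running_max",
) -> float:
    """First time F drops below (1-threshold) * reference; inf if never.

    ``reference``: "running_max" (default) or "initial" (value at t[0]).
    """
    t = np.asarray(t, dtype=float)
    F = np.asarray(F, dtype=float)
    if t.size == 0:
        raise ValueError("empty trace")
    if reference == "running_max":
        ref = np.maximum.accumulate(F)
    elif reference == "initial":
        ref = np.full_like(F, F[0])
    else:
        raise ValueError(f"unknown reference convention {reference!r}")
    below = F < (1.0 - threshold) * ref
    idx = np.flatnonzero(below)
    return float(t[idx[0]]) if idx.size else math.inf


def steady_decay_rate(
    result: SimulationResult, window: tuple[float, float] = (0.58, 0.68)
) -> float:
    """Mean dF/dt over the near-steady window, normalized to Fmax [1/s]."""
    t0, t1 = window
    if t0 < result.t[0] or t1 > result.t[-1]:
        raise ValueError(f"window {window} outside trace [{result.t[0]}, {result.t[-1]}]")
    mask = (result.t >= t0) & (result.t <= t1)
    if mask.sum() < 2:
        raise ValueError("window contains fewer than two samples")
    dfdt = np.gradient(result.F_MTU[mask], result.t[mask])
    return float(np.mean(dfdt) / result.params.Fmax)


def theoretical_decay_rate(lCE: float, kappa: float, p: MTUParameters) -> float:
    """Model force decay rate -kappa * Fisom(lCE) * lCEopt/lCE [1/s]."""
    if kappa < 0.0:
        raise ValueError("kappa must be non-negative")
    return -kappa * mech.isometric_force_length(lCE, p) * p.lCEopt / lCE


@dataclass
class KappaFit:
    kappa: float                 # [1/s]
    residuals: np.ndarray        # per-length residual of the linear fit
    lCEs: np.ndarray


def fit_kappa(
    rates: Sequence[float], lCEs: Sequence[float], p: MTUParameters
) -> KappaFit:
    """Closed-form least-squares kappa from observed decay rates.

    Minimizes sum_i (rate_i + kappa * Fisom(lCE_i) * lCEopt/lCE_i)^2; the
    minimizer is the ratio of sums -sum(rate*b)/sum(b^2), clamped at 0.
    """
    rates = np.asarray(rates, dtype=float)
    lces = np.asarray(lCEs, dtype=float)
    if rates.size != lces.size or rates.size < 1:
        raise ValueError("rates and lCEs must be non-empty and of equal length")
    b = np.array([mech.isometric_force_length(l, p) * p.lCEopt / l for l in lces])
    denom = float(np.sum(b * b))
    if denom == 0.0:
        raise ValueError("degenerate fit: all basis values zero")
    kappa = max(-float(np.sum(rates * b)) / denom, 0.0)
    return KappaFit(kappa=kappa, residuals=rates + kappa * b, lCEs=lces)


def steady_state_force(
    q: float, mu_rel: float, lCE: float, p: MTUParameters
) -> float:
    """Isometric steady-state MTU force q*mu*Fmax*Fisom(lCE) + F_PEE(lCE) [N]."""
    return (phos.activity(q, mu_rel) * p.Fmax * mech.isometric_force_length(lCE, p)
            + mech.pee_force(lCE, p))


def simulate_constant(
    p: MTUParameters,
    mc: MetabolicConstants,
    lMTU: float,
    u: float,
    horizon: float,
    threshold: float = 0.05,
    sample_rate: float = 100.0,
    chunk: float = 2.0,
    rtol: float = RTOL,
    stop_on_exhaustion: bool = True,
):
    """Constant-stimulation run from rest, integrated in chunks.

    Returns ``(t, F, lCE, t_exh)`` where ``t_exh`` is the exhaustion time
    (running-max reference) or inf.  When ``stop_on_exhaustion`` is set,
    integration stops at the first chunk in which the threshold crossing
    occurs, so high-stimulation cells of an exhaustion map are cheap.
    """
    rhs = _RHS(p, mc, lMTU)
    y = initial_state(p, mc, lMTU)
    ts, fs, ls = [], [], []
    t0 = 0.0
    run_max = -math.inf
    t_exh = math.inf
    while t0 < horizon - 1e-12:
        t1 = min(t0 + chunk, horizon)
        proto = constant_protocol(u, t1 - t0, sample_rate)
        grid, states = _integrate_segments(rhs, y, proto, rtol, ATOL)
        obs = _observables(rhs, grid, states)
        f = obs["F_MTU"]
        start = 1 if ts else 0  # skip duplicated chunk-start sample
        ts.append(grid[start:] + t0)
        fs.append(f[start:])
        ls.append(states[start:, 1])
        run_max_acc = np.maximum.accumulate(np.maximum(f, run_max))
        below = f < (1.0 - threshold) * run_max_acc
        idx = np.flatnonzero(below)
        if idx.size:
            t_exh = float(grid[idx[0]] + t0)
            if stop_on_exhaustion:
                ts[-1] = ts[-1][: idx[0] + 1 - start] if idx[0] + 1 > start else ts[-1][:0]
                fs[-1] = fs[-1][: idx[0] + 1 - start]
                ls[-1] = ls[-1][: idx[0] + 1 - start]
                break
        run_max = float(run_max_acc[-1])
        y = states[-1]
        t0 = t1
    return np.concatenate(ts), np.concatenate(fs), np.concatenate(ls), t_exh


@dataclass
class ExhaustionMap:
    """Grid of exhaustion times over MTU length x stimulation level."""

    lMTU: np.ndarray             # [m]
    u: np.ndarray
    exhaustion_time: np.ndarray  # [s], inf where no decay within horizon
    quasi_steady_force: np.ndarray  # [N], force at min(t_exh, horizon)
    lCE: np.ndarray              # [m], CE length at that instant
    horizon: float = 60.0
    failed: np.ndarray = field(default_factory=lambda: np.empty((0, 0), bool))

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format export; infinite times encoded as -1 with a flag."""
        rows = []
        for i, l in enumerate(self.lMTU):
            for j, u in enumerate(self.u):
                te = self.exhaustion_time[i, j]
                rows.append({
                    "lmtu_mm": 1000.0 * l, "u": u,
                    "t_exh_s": -1.0 if math.isinf(te) else te,
                    "never_exhausts": bool(math.isinf(te)),
                    "f_steady_N": self.quasi_steady_force[i, j],
                    "lce_m": self.lCE[i, j],
                })
        return pd.DataFrame(rows)


def exhaustion_map(
    p: MTUParameters,
    mc: MetabolicConstants,
    lMTU_grid: Sequence[float],
    u_grid: Sequence[float],
    horizon: float = 60.0,
    threshold: float = 0.05,
    sample_rate: float = 100.0,
    rtol: float = RTOL,
) -> ExhaustionMap:
    """One constant-u run per (length, stimulation) cell, from t = 0."""
    lgrid = np.asarray(lMTU_grid, dtype=float)
    ugrid = np.asarray(u_grid, dtype=float)
    shape = (lgrid.size, ugrid.size)
    te = np.full(shape, math.nan)
    fq = np.full(shape, math.nan)
    lce = np.full(shape, math.nan)
    failed = np.zeros(shape, dtype=bool)
    for i, l in enumerate(lgrid):
        for j, u in enumerate(ugrid):
            try:
                t, f, lc, t_exh = simulate_constant(
                    p, mc, float(l), float(u), horizon,
                    threshold=threshold, sample_rate=sample_rate, rtol=rtol,
                )
            except Exception:
                failed[i, j] = True
                continue
            te[i, j] = t_exh
            fq[i, j] = f[-1]
            lce[i, j] = lc[-1]
    return ExhaustionMap(lgrid, ugrid, te, fq, lce, horizon=horizon, failed=failed)
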