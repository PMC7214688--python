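"""Bounded least-squares parameter estimation and local sensitivities.

All experiments of one muscle are fitted simultaneously with shared
parameters.  The objective is the L2 residue scaled to 1000 data points,
minimized by trust-region-reflective least squares inside the parameter
bound hyperrectangle, optionally multi-started from seeded scrambled-
Sobol points.  Local sensitivities are relative central finite
differences of the force trace with respect to each parameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .params import MTUParameters
from .phosphate import MetabolicConstants
from .simulator import StimulationProtocol, default_protocol, simulate

__all__ = [
    "ExperimentRecord",
    "FitResult",
    "SensitivityMatrix",
    "residue_L2_scaled",
    "residue_L1_per_point",
    "fit_parameters",
    "sensitivity_timecourse",
]

log = logging.getLogger("myophos")


@dataclass
class ExperimentRecord:
    """One measured (or synthetic) isometric force-time trace."""

    muscle: str
    lMTU: float                 # [m]
    t: np.ndarray               # [s], strictly increasing
    F: np.ndarray               # [N]
    protocol: StimulationProtocol | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.t.shape != self.F.shape or self.t.ndim != 1:
            raise ValueError("t and F must be 1-D arrays of equal length")
        if np.any(np.diff(self.t) <= 0.0):
            raise ValueError("time grid must be strictly increasing")
        if not np.all(np.isfinite(self.F)):
            raise ValueError("force trace contains non-finite values")


def _stack(model, data) -> np.ndarray:
    """Stacked residual vector over one trace or a sequence of traces."""
    if isinstance(model, np.ndarray) and model.ndim == 1:
        model, data = [model], [data]
    parts = []
    for m, d in zip(model, data, strict=True):
        m = np.asarray(m, dtype=float)
        d = np.asarray(d, dtype=float)
        if m.shape != d.shape:
            raise ValueError(f"trace grids differ: {m.shape} vs {d.shape}")
        parts.append(m - d)
    return np.concatenate(parts)


def residue_L2_scaled(model, data) -> float:
    """L2 residue scaled to 1000 data points: sqrt((1000/N) * sum r^2) [N]."""
    r = _stack(model, data)
    return float(np.sqrt(1000.0 / r.size * np.sum(r * r)))


def residue_L1_per_point(model, data) -> float:
    """Mean absolute residual per data point [N]."""
    r = _stack(model, data)
    return float(np.mean(np.abs(r)))


@dataclass
class FitResult:
    parameters: MTUParameters
    residue_L2_1000: float
    residue_L1_per_point: float
    bounds: dict[str, tuple[float, float]]
    free: tuple[str, ...]
    converged: bool
    iterations: int
    seed: int
    start_objectives: tuple[float, ...] = ()


def _model_forces(
    p: MTUParameters,
    mc: MetabolicConstants,
    experiments: Sequence[ExperimentRecord],
    rtol: float,
) -> list[np.ndarray]:
    out = []
    for exp in experiments:
        proto = exp.protocol or default_protocol()
        res = simulate(p, mc, exp.lMTU, proto, rtol=rtol)
        out.append(np.interp(exp.t, res.t, res.F_MTU))
    return out


def fit_parameters(
    experiments: Sequence[ExperimentRecord],
    p0: MTUParameters,
    mc: MetabolicConstants,
    bounds: dict[str, tuple[float, float]],
    free: Sequence[str],
    seed: int = 0,
    starts: int = 8,
    sim_rtol: float = 1e-8,
    max_nfev: int | None = None,
    include_p0_start: bool = True,
    diff_step: float = 1e-3,
) -> FitResult:
    """Fit the ``free`` parameter subset to the experiment set.

    Multi-start bounded least squares: the first start is ``p0`` (clipped
    into the bounds), further starts are seeded scrambled-Sobol samples
    of the bound hyperrectangle.  The Sobol sequence is prefix-stable,
    so the best objective is non-increasing in ``starts``; deterministic
    for fixed seed.
    """
    if not experiments:
        raise ValueError("at least one experiment is required")
    free = tuple(free)
    for name in free:
        if name not in bounds:
            raise ValueError(f"no bounds given for free parameter {name!r}")
    lo = np.array([bounds[n][0] for n in free])
    hi = np.array([bounds[n][1] for n in free])
    n_total = sum(e.t.size for e in experiments)
    scale = np.sqrt(1000.0 / n_total)

    def residual(theta: np.ndarray) -> np.ndarray:
        p = p0.replace(**dict(zip(free, (float(v) for v in theta))))
        model = _model_forces(p, mc, experiments, sim_rtol)
        return scale * _stack(model, [e.F for e in experiments])

    start_points = []
    if include_p0_start:
        x0 = np.clip([getattr(p0, n) for n in free], lo, hi)
        start_points.append(np.asarray(x0, dtype=float))
    n_qmc = max(starts - len(start_points), 0)
    if n_qmc > 0:
        sampler = qmc.Sobol(d=len(free), scramble=True, seed=seed)
        start_points.extend(lo + (hi - lo) * sampler.random(n_qmc))

    best = None
    start_objs = []
    for x0 in start_points:
        # diff_step keeps the finite-difference force change well above
        # the integrator noise floor (~rtol * F)
        sol = least_squares(
            residual, x0, bounds=(lo, hi), method="trf",
            xtol=1e-10, ftol=1e-12, gtol=1e-10, max_nfev=max_nfev,
            diff_step=diff_step,
        )
        start_objs.append(float(np.sqrt(np.sum(sol.fun**2))))
        if best is None or np.sum(sol.fun**2) < np.sum(best.fun**2):
            best = sol
    assert best is not None
    p_fit = p0.replace(**dict(zip(free, (float(v) for v in best.x))))
    model = _model_forces(p_fit, mc, experiments, sim_rtol)
    data = [e.F for e in experiments]
    result = FitResult(
        parameters=p_fit,
        residue_L2_1000=residue_L2_scaled(model, data),
        residue_L1_per_point=residue_L1_per_point(model, data),
        bounds={n: bounds[n] for n in free},
        free=free,
        converged=bool(best.status > 0),
        iterations=int(best.nfev),
        seed=seed,
        start_objectives=tuple(start_objs),
    )
    log.info("fit: free=%s seed=%d residue_L2_1000=%.4g converged=%s",
             free, seed, result.residue_L2_1000, result.converged)
    return result


@dataclass
class SensitivityMatrix:
    """Relative force sensitivities S_theta(t) = (dF/dtheta)*(theta/F)."""

    names: tuple[str, ...]
    t: np.ndarray
    S: np.ndarray                    # raw values, shape (n_params, n_times)
    truncation: float = 1.0
    absolute_scale: np.ndarray = field(default_factory=lambda: np.empty(0, bool))

    def truncated(self) -> np.ndarray:
        """Export copy with magnitudes clipped at the truncation level."""
        return np.clip(self.S, -self.truncation, self.truncation)


def sensitivity_timecourse(
    p: MTUParameters,
    mc: MetabolicConstants,
    experiment: ExperimentRecord,
    rel_step: float = 1e-4,
    names: Sequence[str] | None = None,
    truncation: float = 1.0,
    sim_rtol: float = 1e-8,
    f_floor: float = 1e-9,
) -> SensitivityMatrix:
    """Central finite-difference sensitivity time courses of the force.

    Where the reference force is (numerically) zero the sensitivity is
    reported on an absolute scale (dF/dtheta * theta) and flagged.
    """
    if names is None:
        names = tuple(f.name for f in p.__dataclass_fields__.values())  # type: ignore[attr-defined]
    names = tuple(names)
    proto = experiment.protocol or default_protocol()
    base = simulate(p, mc, experiment.lMTU, proto, rtol=sim_rtol)
    f0 = np.interp(experiment.t, base.t, base.F_MTU)
    zero_mask = np.abs(f0) <= f_floor
    S = np.empty((len(names), experiment.t.size))
    for i, name in enumerate(names):
        theta = getattr(p, name)
        if theta == 0.0 or rel_step == 0.0:
            S[i] = 0.0
            continue
        h = rel_step * abs(theta)
        fp = _model_forces(p.replace(**{name: theta + h}), mc, [experiment], sim_rtol)[0]
        fm = _model_forces(p.replace(**{name: theta - h}), mc, [experiment], sim_rtol)[0]
        dfdtheta = (fp - fm) / (2.0 * h)
        S[i] = np.where(zero_mask, dfdtheta * theta, dfdtheta * theta / np.where(zero_mask, 1.0, f0))
    return SensitivityMatrix(names=names, t=experiment.t.copy(), S=S,
                             truncation=truncation, absolute_scale=zero_mask)
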