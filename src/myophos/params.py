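"""Parameter containers, presets and config I/O.

The muscle-tendon unit (MTU) is described by 24 parameters: the serial
elastic element (SEE) toe/linear spring, the parallel elastic element
(PEE) power-law spring, the contractile element (CE) force-length bell
and Hill force-velocity constants, the serial damping element (SDE),
the Hatze-type activation constants, and the single kinetic constant
``khyd_hat`` coupling contraction to ATP hydrolysis.

Presets ``GAS_minus``/``GAS_plus``/``PLA_minus``/``PLA_plus`` carry the
fitted values for rabbit gastrocnemius (GAS) and plantaris (PLA); the
``*_minus`` variants are the classical model without phosphate dynamics
(``khyd_hat = 0``), the ``*_plus`` variants include it.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "MTUParameters",
    "MTUKinematics",
    "PRESETS",
    "BOUNDS",
    "get_preset",
    "get_bounds",
    "load_mtu_parameters",
    "save_mtu_parameters",
]


@dataclass
class MTUParameters:
    """All mechanical, activation and kinetic constants of one MTU.

    Lengths are in meters, forces in newtons, rates in 1/s; all other
    quantities are dimensionless.
    """

    lSEE0: float        # tendon slack length [m]
    dU_SEE_nll: float   # relative SEE stretch at toe/linear transition
    dF_SEE0: float      # SEE force at the transition [N]
    dU_SEE_l: float     # relative stretch in the linear part per dF_SEE0
    F_PEE: float        # PEE force at lCEopt*(1+dW_des), as fraction of Fmax
    L_PEE: float        # PEE slack length, as multiple of lCEopt
    nu_PEE: float       # PEE power-law exponent
    dW_asc: float       # force-length width, ascending limb
    dW_des: float       # force-length width, descending limb
    nu_asc: float       # force-length exponent, ascending limb
    nu_des: float       # force-length exponent, descending limb
    Fmax: float         # maximum isometric force [N]
    lCEopt: float       # optimal CE length [m]
    Arel0: float        # Hill constant (normalized force)
    Brel0: float        # Hill constant [1/s]
    D_SDE: float        # serial damping factor
    R_SDE: float        # minimum (force-independent) damping ratio
    S_e: float          # eccentric slope factor at v=0
    F_e: float          # eccentric force asymptote, as multiple of a*Fisom*Fmax
    q_min: float        # minimum troponin activity
    omega_opt: float    # calcium sensitivity at lCEopt
    m_act: float        # activation rate [1/s]
    nu_act: float       # activation sigmoid exponent
    khyd_hat: float     # ATP hydrolysis rate at full activity, optimal length [1/s]

    def validate(self, bounds: Mapping[str, tuple[float, float]] | None = None) -> None:
        """Raise ``ValueError`` on violated invariants (and bounds, if given)."""
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {f.name} is not finite: {v}")
            if f.name == "khyd_hat":
                if v < 0:
                    raise ValueError("khyd_hat must be >= 0")
            elif v <= 0:
                raise ValueError(f"parameter {f.name} must be strictly positive")
        if not (0.0 < self.q_min < 1.0):
            raise ValueError("q_min must lie in (0, 1)")
        if not (0.0 <= self.R_SDE <= 1.0):
            raise ValueError("R_SDE must lie in [0, 1]")
        if self.F_e <= 1.0:
            raise ValueError("F_e must exceed 1")
        if bounds is not None:
            for name, (lo, hi) in bounds.items():
                v = getattr(self, name)
                if not (lo <= v <= hi):
                    raise ValueError(f"parameter {name}={v} outside bounds [{lo}, {hi}]")

    def replace(self, **changes: float) -> "MTUParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "MTUParameters":
        d = dict(d)
        unit = d.pop("length_unit", "m")
        if unit == "mm":
            for key in ("lSEE0", "lCEopt"):
                if key in d:
                    d[key] = float(d[key]) / 1000.0
        elif unit != "m":
            raise ValueError(f"unsupported length_unit: {unit!r}")
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        missing = names - set(d)
        if missing:
            raise ValueError(f"missing parameter keys: {sorted(missing)}")
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass
class MTUKinematics:
    """Instantaneous kinematic state of the MTU (lengths in m, rates m/s)."""

    lMTU: float
    vMTU: float
    lCE: float

    @property
    def lSEE(self) -> float:
        return self.lMTU - self.lCE

    def validate(self) -> None:
        if not (0.0 < self.lCE < self.lMTU):
            raise ValueError(f"require 0 < lCE < lMTU, got lCE={self.lCE}, lMTU={self.lMTU}")


# Fitted parameter columns. *_minus: classical model (khyd_hat = 0);
# *_plus: model with phosphate dynamics.
PRESETS: dict[str, MTUParameters] = {
    "GAS_minus": MTUParameters(
        lSEE0=0.0996, dU_SEE_nll=0.103, dF_SEE0=123.0, dU_SEE_l=0.0524,
        F_PEE=0.133, L_PEE=1.19, nu_PEE=5.00, dW_asc=0.215, dW_des=0.690,
        nu_asc=4.10, nu_des=4.46, Fmax=120.0, lCEopt=0.0160, Arel0=0.0786,
        Brel0=6.30, D_SDE=1.65, R_SDE=0.0233, S_e=1.00, F_e=1.10,
        q_min=0.00576, omega_opt=2.45, m_act=12.8, nu_act=4.99, khyd_hat=0.0,
    ),
    "GAS_plus": MTUParameters(
        lSEE0=0.1017, dU_SEE_nll=0.0785, dF_SEE0=109.0, dU_SEE_l=0.0482,
        F_PEE=0.135, L_PEE=1.02, nu_PEE=3.16, dW_asc=0.404, dW_des=0.330,
        nu_asc=6.75, nu_des=2.36, Fmax=133.0, lCEopt=0.0198, Arel0=0.0655,
        Brel0=2.91, D_SDE=0.149, R_SDE=0.0100, S_e=2.85, F_e=1.14,
        q_min=0.00944, omega_opt=3.47, m_act=13.7, nu_act=4.85, khyd_hat=1.45,
    ),
    "PLA_minus": MTUParameters(
        lSEE0=0.1045, dU_SEE_nll=0.0620, dF_SEE0=69.4, dU_SEE_l=0.0409,
        F_PEE=0.118, L_PEE=1.00, nu_PEE=2.50, dW_asc=0.237, dW_des=0.429,
        nu_asc=1.57, nu_des=3.89, Fmax=57.1, lCEopt=0.0130, Arel0=0.244,
        Brel0=10.0, D_SDE=10.0, R_SDE=1.00, S_e=4.50, F_e=1.61,
        q_min=0.0100, omega_opt=1.82, m_act=8.17, nu_act=3.76, khyd_hat=0.0,
    ),
    "PLA_plus": MTUParameters(
        lSEE0=0.1054, dU_SEE_nll=0.0762, dF_SEE0=68.1, dU_SEE_l=0.0414,
        F_PEE=0.0908, L_PEE=1.00, nu_PEE=2.50, dW_asc=0.268, dW_des=0.570,
        nu_asc=1.84, nu_des=2.83, Fmax=63.7, lCEopt=0.0106, Arel0=0.240,
        Brel0=6.58, D_SDE=3.88, R_SDE=0.356, S_e=3.40, F_e=1.32,
        q_min=0.0100, omega_opt=2.03, m_act=8.22, nu_act=4.77, khyd_hat=2.27,
    ),
}

# Per-muscle estimation bounds (lower, upper) for every parameter.
_BOUNDS_GAS: dict[str, tuple[float, float]] = {
    "lSEE0": (0.09, 0.11), "dU_SEE_nll": (0.04, 0.11), "dF_SEE0": (80.0, 160.0),
    "dU_SEE_l": (0.01, 0.08), "F_PEE": (0.0, 1.2), "L_PEE": (0.9, 1.5),
    "nu_PEE": (2.5, 5.0), "dW_asc": (0.1, 1.0), "dW_des": (0.1, 1.0),
    "nu_asc": (1.5, 8.0), "nu_des": (1.5, 6.0), "Fmax": (80.0, 160.0),
    "lCEopt": (0.014, 0.025), "Arel0": (0.03, 0.5), "Brel0": (1.0, 10.0),
    "D_SDE": (0.1, 10.0), "R_SDE": (0.01, 1.0), "S_e": (1.0, 4.5),
    "F_e": (1.1, 2.0), "q_min": (0.001, 0.01), "omega_opt": (1.5, 10.0),
    "m_act": (5.0, 20.0), "nu_act": (2.0, 8.0), "khyd_hat": (1.0, 3.0),
}
_BOUNDS_PLA: dict[str, tuple[float, float]] = {
    "lSEE0": (0.09, 0.11), "dU_SEE_nll": (0.04, 0.11), "dF_SEE0": (50.0, 70.0),
    "dU_SEE_l": (0.01, 0.08), "F_PEE": (0.0, 1.2), "L_PEE": (1.0, 1.5),
    "nu_PEE": (2.5, 5.0), "dW_asc": (0.1, 1.0), "dW_des": (0.1, 1.0),
    "nu_asc": (1.5, 5.0), "nu_des": (1.5, 5.0), "Fmax": (50.0, 70.0),
    "lCEopt": (0.005, 0.02), "Arel0": (0.03, 0.5), "Brel0": (1.0, 10.0),
    "D_SDE": (0.1, 10.0), "R_SDE": (0.1, 1.0), "S_e": (1.0, 4.5),
    "F_e": (1.1, 2.0), "q_min": (0.001, 0.01), "omega_opt": (1.5, 10.0),
    "m_act": (5.0, 20.0), "nu_act": (2.0, 8.0), "khyd_hat": (1.0, 3.0),
}
BOUNDS: dict[str, dict[str, tuple[float, float]]] = {"GAS": _BOUNDS_GAS, "PLA": _BOUNDS_PLA}

# Experimental MTU length series per muscle [m].
EXPERIMENT_LENGTHS: dict[str, tuple[float, ...]] = {
    "GAS": (0.114, 0.116, 0.118, 0.120, 0.128, 0.130, 0.132),
    "PLA": (0.114, 0.116, 0.118, 0.120, 0.122, 0.124),
}


def get_preset(name: str) -> MTUParameters:
    try:
        return dataclasses.replace(PRESETS[name])
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None


def get_bounds(muscle: str) -> dict[str, tuple[float, float]]:
    try:
        return dict(BOUNDS[muscle])
    except KeyError:
        raise KeyError(f"unknown muscle {muscle!r}; choose from {sorted(BOUNDS)}") from None


def load_mtu_parameters(path: str | Path) -> MTUParameters:
    """Read a parameter config (YAML or JSON mapping of Table-style keys)."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: expected a mapping of parameter names to values")
    return MTUParameters.from_dict(data)


def save_mtu_parameters(p: MTUParameters, path: str | Path) -> None:
    path = Path(path)
    d = p.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
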