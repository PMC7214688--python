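"""Hatze-type calcium/troponin activation dynamics.

Stimulation u drives the normalized free-calcium concentration gamma by
first-order relaxation; troponin activity q (the relative number of
cleared active sites on actin) follows gamma through a length-sensitive
sigmoid.  The cubic length scaling of the calcium sensitivity,
``rho = omega_opt * lCE_rel**3``, is Hatze's classical choice and is
exposed as a module constant.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import MTUParameters

__all__ = ["ActivationState", "calcium_rate", "troponin_activity", "RHO_LENGTH_EXPONENT"]

#: exponent of the length dependence of the calcium sensitivity rho
RHO_LENGTH_EXPONENT = 3.0


@dataclass
class ActivationState:
    """Normalized free calcium ``gamma`` in [0,1] and troponin activity ``q``."""

    gamma: float
    q: float


def calcium_rate(gamma: float, u: float, m_act: float) -> float:
    """d(gamma)/dt = m_act * (u - gamma); zero exactly at the fixed point u."""
    if not (0.0 <= gamma <= 1.0 and 0.0 <= u <= 1.0):
        raise ValueError(f"gamma and u must lie in [0,1], got gamma={gamma}, u={u}")
    return m_act * (u - gamma)


def troponin_activity(
    gamma: float,
    lCE_rel: float,
    p: MTUParameters,
    rho_exponent: float = RHO_LENGTH_EXPONENT,
) -> float:
    """Sigmoid troponin activity in [q_min, 1).

    ``q = (q_min + (rho*gamma)**nu_act) / (1 + (rho*gamma)**nu_act)`` with
    ``rho = omega_opt * lCE_rel**rho_exponent``; q_min at rest, midpoint
    ``(q_min+1)/2`` at ``rho*gamma = 1``.
    """
    if lCE_rel <= 0.0:
        raise ValueError(f"lCE_rel must be positive, got {lCE_rel}")
    if gamma <= 0.0:
        return p.q_min
    rho = p.omega_opt * lCE_rel**rho_exponent
    z = (rho * gamma) ** p.nu_act
    return (p.q_min + z) / (1.0 + z)
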