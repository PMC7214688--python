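"""Trace readers/writers, the synthetic fixture generator, and smoothing.

Trace CSV dialect: comma separator, '.' decimal, mandatory header row,
'#'-prefixed metadata comment lines (``muscle=``, ``lmtu_mm=``,
``protocol=``) preceding the header.

The fixture generator emulates the isometric rabbit experiments the
mechanical parameters were fitted to (which are not available as
machine-readable files): 1.2 s runs sampled at 1 kHz, stimulation 0->1
at 0.1 s for 0.7 s, six to seven MTU lengths per muscle, additive
i.i.d. Gaussian force noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .estimation import ExperimentRecord
from .params import EXPERIMENT_LENGTHS, MTUParameters
from .phosphate import MetabolicConstants
from .simulator import StimulationProtocol, default_protocol, simulate_batch

__all__ = [
    "FixtureSpec",
    "generate_fixtures",
    "read_trace",
    "write_trace",
    "moving_average",
]

log = logging.getLogger("myophos")

#: default additive force-noise standard deviation [N], of the order of
#: the per-point L1 residues of the fits to the measured traces
DEFAULT_NOISE_SD = 0.5


@dataclass
class FixtureSpec:
    """Specification of one synthetic multi-length experiment set."""

    muscle: str = "GAS"
    lengths: tuple[float, ...] = ()   # [m]; defaults to the muscle's series
    noise_sd: float = DEFAULT_NOISE_SD  # [N]
    seed: int = 0
    protocol: StimulationProtocol = field(default_factory=default_protocol)

    def __post_init__(self) -> None:
        if not self.lengths:
            self.lengths = EXPERIMENT_LENGTHS[self.muscle]
        if self.noise_sd < 0.0:
            raise ValueError("noise_sd must be non-negative")
        if any(l <= 0.0 for l in self.lengths):
            raise ValueError("lengths must be positive")


def generate_fixtures(
    spec: FixtureSpec, p: MTUParameters, mc: MetabolicConstants, **sim_kwargs
) -> list[ExperimentRecord]:
    """Simulate each length and add seeded Gaussian noise to the force."""
    rng = np.random.default_rng(spec.seed)
    results = simulate_batch(p, mc, spec.lengths, spec.protocol, **sim_kwargs)
    records = []
    for lmtu, res in zip(spec.lengths, results):
        noise = rng.normal(0.0, spec.noise_sd, res.F_MTU.size) if spec.noise_sd > 0 \
            else np.zeros(res.F_MTU.size)
        records.append(ExperimentRecord(
            muscle=spec.muscle, lMTU=lmtu, t=res.t.copy(),
            F=res.F_MTU + noise, protocol=spec.protocol,
        ))
    log.info("fixtures: muscle=%s n=%d seed=%d noise_sd=%g",
             spec.muscle, len(records), spec.seed, spec.noise_sd)
    return records


class TraceParseError(ValueError):
    def __init__(self, path, line_no, msg):
        super().__init__(f"{path}:{line_no}: {msg}")
        self.line_no = line_no


def write_trace(record: ExperimentRecord, path: str | Path) -> None:
    """Write one trace with metadata comment lines and a header row."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# muscle={record.muscle}\n")
        fh.write(f"# lmtu_mm={float(record.lMTU) * 1000.0!r}\n")
        fh.write("# protocol=default\n")
        fh.write("time_s,force_N\n")
        for t, f in zip(record.t, record.F):
            fh.write(f"{float(t)!r},{float(f)!r}\n")


def read_trace(path: str | Path) -> ExperimentRecord:
    """Read a trace CSV; metadata must carry the MTU length."""
    path = Path(path)
    meta: dict[str, str] = {}
    t_vals: list[float] = []
    f_vals: list[float] = []
    header_seen = False
    with path.open() as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            if not header_seen:
                cols = [c.strip() for c in line.split(",")]
                if cols[:2] != ["time_s", "force_N"]:
                    raise TraceParseError(path, line_no,
                                          f"malformed header {line!r}; expected time_s,force_N")
                header_seen = True
                continue
            parts = line.split(",")
            try:
                t_vals.append(float(parts[0]))
                f_vals.append(float(parts[1]))
            except (ValueError, IndexError):
                raise TraceParseError(path, line_no, f"malformed data row {line!r}") from None
    if not header_seen:
        raise TraceParseError(path, 0, "missing header row")
    if "lmtu_mm" not in meta:
        raise TraceParseError(path, 0, "missing required metadata field 'lmtu_mm'")
    t = np.asarray(t_vals)
    if t.size and np.any(np.diff(t) <= 0.0):
        bad = int(np.flatnonzero(np.diff(t) <= 0.0)[0])
        raise TraceParseError(path, bad + 2, "non-monotone time column")
    return ExperimentRecord(
        muscle=meta.get("muscle", ""),
        lMTU=float(meta["lmtu_mm"]) / 1000.0,
        t=t,
        F=np.asarray(f_vals),
    )


def moving_average(t: np.ndarray, x: np.ndarray, width: float = 0.040) -> np.ndarray:
    """Centered moving average with truncated edge windows (display only).

    ``width`` is in seconds; on a uniform grid of step dt the window spans
    ``2*round(width/(2*dt)) + 1`` samples.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if t.size < 2:
        return x.copy()
    dt = float(np.median(np.diff(t)))
    if width < dt:
        raise ValueError(f"width {width} s below the sample interval {dt} s")
    half = int(round(width / (2.0 * dt)))
    csum = np.concatenate(([0.0], np.cumsum(x)))
    n = x.size
    i = np.arange(n)
    lo = np.maximum(i - half, 0)
    hi = np.minimum(i + half, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi + 1 - lo)
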