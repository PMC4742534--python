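"""Integration of the clock ODEs under square-wave light forcing.

The integrator (scipy's LSODA via ``solve_ivp``) is restarted at every
light switch so that the discontinuous forcing never crosses an adaptive
step.  Output is sampled on a uniform grid; the grid is sampling only and
does not influence the solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np
from scipy.integrate import solve_ivp

from .clock_model import (
    STATE_VARS,
    ClockState,
    Genotype,
    GENOTYPE_PRESETS,
    ParameterSet,
    make_rhs,
)
from .light_protocols import CompositeProtocol, LightProtocol

__all__ = [
    "Trajectory",
    "IntegrationError",
    "integrate",
    "equilibrate",
    "normalize_to_max",
    "DEFAULT_RTOL",
    "DEFAULT_ATOL",
]

Protocol = Union[LightProtocol, CompositeProtocol]

# Period estimates to 0.01 h need tight tolerances.
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class IntegrationError(RuntimeError):
    """Solver failure; carries the time at which integration broke down."""

    def __init__(self, message: str, t_fail: float):
        super().__init__(f"{message} (t = {t_fail:.3f} h)")
        self.t_fail = t_fail


@dataclass
class Trajectory:
    """A simulated time course: uniform time grid x nine state columns."""

    times: np.ndarray
    states: np.ndarray
    labels: Sequence[str] = STATE_VARS
    protocol: Optional[Protocol] = None
    genotype: Optional[Genotype] = None

    def column(self, component: str) -> np.ndarray:
        try:
            i = list(self.labels).index(component)
        except ValueError:
            raise KeyError(
                f"unknown component {component!r}; have {list(self.labels)}"
            ) from None
        return self.states[:, i]

    def window(self, t_start: float, t_end: Optional[float] = None) -> "Trajectory":
        """Sub-trajectory with times in [t_start, t_end]."""
        if t_end is None:
            t_end = float(self.times[-1])
        m = (self.times >= t_start - 1e-9) & (self.times <= t_end + 1e-9)
        return Trajectory(self.times[m], self.states[m], self.labels,
                          self.protocol, self.genotype)

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1].copy()

    def to_tsv(self, path, metadata: Optional[dict] = None) -> None:
        """Write a tab-separated table (10 significant digits) with an
        optional ``#``-prefixed metadata header."""
        with open(path, "w") as fh:
            for key, val in (metadata or {}).items():
                fh.write(f"# {key}: {val}\n")
            fh.write("time_h\t" + "\t".join(self.labels) + "\n")
            for t, row in zip(self.times, self.states):
                vals = "\t".join(f"{v:.10g}" for v in row)
                fh.write(f"{t:.10g}\t{vals}\n")

    @classmethod
    def from_tsv(cls, path) -> "Trajectory":
        with open(path) as fh:
            lines = [ln for ln in fh if not ln.startswith("#")]
        header = lines[0].rstrip("\n").split("\t")
        data = np.array([[float(x) for x in ln.split("\t")] for ln in lines[1:]])
        return cls(times=data[:, 0], states=data[:, 1:], labels=header[1:])


def _segments(protocol: Protocol, t_end: float):
    """Split [0, t_end] into maximal intervals of constant L."""
    switches = [s for s in protocol.switch_times(t_end)]
    bounds = [0.0] + switches + [t_end]
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a > 1e-12:
            yield a, b, protocol.light(a)


def integrate(
    params: ParameterSet,
    genotype: Optional[Genotype] = None,
    protocol: Optional[Protocol] = None,
    t_end: float = 120.0,
    dt_out: float = 0.1,
    initial: Optional[Union[ClockState, np.ndarray]] = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    _rhs=None,
    _n_extra: int = 0,
) -> Trajectory:
    """Integrate the clock under ``protocol`` from 0 to ``t_end`` hours.

    The integration is restarted at every light switch; within a segment
    L is constant and the system autonomous and smooth.  ``dt_out`` is the
    output sampling interval only.  The default initial condition is all
    components at 0.1 except P at 0 (arbitrary; equilibration removes its
    influence).

    ``_rhs``/``_n_extra`` allow coupled output modules (hypocotyl) to
    extend the state vector while reusing the same engine.
    """
    if t_end <= 0 or dt_out <= 0:
        raise ValueError("t_end and dt_out must be > 0")
    if genotype is None:
        genotype = GENOTYPE_PRESETS["wildtype"]
    if protocol is None:
        from .light_protocols import constant
        protocol = constant(1)

    if initial is None:
        y0 = ClockState().as_array()
        if _n_extra:
            y0 = np.concatenate([y0, np.zeros(_n_extra)])
    elif isinstance(initial, ClockState):
        y0 = initial.as_array()
        if _n_extra:
            y0 = np.concatenate([y0, np.zeros(_n_extra)])
    else:
        y0 = np.asarray(initial, dtype=float).copy()

    rhs = _rhs if _rhs is not None else make_rhs(params, genotype)

    n_out = int(np.floor(t_end / dt_out + 1e-9)) + 1
    grid = np.arange(n_out) * dt_out
    out = np.empty((n_out, y0.size))
    out[0] = y0
    filled = 1

    y = y0
    for a, b, L in _segments(protocol, t_end):
        # output points strictly inside (a, b], excluding a (already set or
        # covered by the previous segment's endpoint)
        i0 = int(np.ceil((a + 1e-12) / dt_out))
        i1 = int(np.floor((b + 1e-12) / dt_out))
        t_eval = grid[i0:i1 + 1]
        sol = solve_ivp(
            rhs, (a, b), y, args=(L,), method="LSODA",
            t_eval=t_eval if t_eval.size else None,
            rtol=rtol, atol=atol, dense_output=False,
        )
        if not sol.success:
            raise IntegrationError(sol.message, sol.t[-1] if sol.t.size else a)
        if t_eval.size:
            out[i0:i1 + 1] = sol.y.T
            filled = i1 + 1
        # state at exact segment end to chain into the next segment
        if t_eval.size and abs(t_eval[-1] - b) < 1e-9:
            y = sol.y[:, -1].copy()
        else:
            sol_end = solve_ivp(
                rhs, (t_eval[-1] if t_eval.size else a, b),
                sol.y[:, -1] if t_eval.size else y,
                args=(L,), method="LSODA", rtol=rtol, atol=atol,
            )
            if not sol_end.success:
                raise IntegrationError(sol_end.message, b)
            y = sol_end.y[:, -1].copy()
    if filled < n_out:
        out[filled:] = y

    labels = list(STATE_VARS) if not _n_extra else None
    return Trajectory(times=grid, states=out,
                      labels=labels if labels is not None else
                      list(STATE_VARS) + [f"x{i}" for i in range(_n_extra)],
                      protocol=protocol, genotype=genotype)


def equilibrate(
    params: ParameterSet,
    genotype: Optional[Genotype] = None,
    protocol: Optional[LightProtocol] = None,
    n_cycles: int = 15,
    initial: Optional[Union[ClockState, np.ndarray]] = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> np.ndarray:
    """Run ``n_cycles`` cycles of a cyclic protocol and return the final
    state, for use as the initial condition of analysis windows.  Fifteen
    cycles of a 24 h protocol reproduce the standard 360 h transient
    discard."""
    if protocol is None or protocol.cycle_length is None:
        raise ValueError("equilibrate requires a cyclic protocol")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    t_end = n_cycles * protocol.cycle_length
    traj = integrate(params, genotype, protocol, t_end=t_end,
                     dt_out=t_end, initial=initial, rtol=rtol, atol=atol)
    return traj.final_state


def normalize_to_max(traj: Trajectory, components: Optional[Sequence[str]] = None
                     ) -> Trajectory:
    """Rescale components to peak at 1 over the trajectory window (the
    convention used for expression-profile figures).  All-zero series are
    rejected (division by zero)."""
    if components is None:
        components = list(traj.labels)
    states = traj.states.copy()
    labels = list(traj.labels)
    for comp in components:
        i = labels.index(comp) if comp in labels else None
        if i is None:
            raise KeyError(f"unknown component {comp!r}")
        peak = states[:, i].max()
        if peak <= 0:
            raise ValueError(f"component {comp!r} has no positive values; "
                             "cannot normalize")
        states[:, i] = states[:, i] / peak
    return Trajectory(traj.times.copy(), states, labels,
                      traj.protocol, traj.genotype)
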