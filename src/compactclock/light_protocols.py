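"""Piecewise-constant light environments (square-wave forcing).

A :class:`LightProtocol` is an ordered list of ``(duration, L)`` segments
with ``L`` in {0, 1}; cyclic protocols repeat with period equal to the sum
of their segment durations.  Intervals are half-open ``[start, end)``: at a
switch point the light level of the *starting* segment applies.  A
:class:`CompositeProtocol` chains protocols (e.g. entrainment followed by
release into constant conditions).

Because square-wave forcing makes the ODE right-hand side discontinuous in
time, protocols expose :meth:`switch_times`, and the simulation engine
restarts the integrator at every switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, List, Optional, Sequence, Tuple

__all__ = [
    "LightProtocol",
    "CompositeProtocol",
    "ld_cycle",
    "skeleton",
    "constant",
    "entrain_release",
]


@dataclass(frozen=True)
class LightProtocol:
    """A square-wave light schedule.

    Parameters
    ----------
    segments
        Ordered ``(duration_hours, L)`` pairs, durations > 0, L in {0, 1}.
    cyclic
        If true, the schedule repeats forever with period
        :attr:`cycle_length`; otherwise the last segment's level extends
        beyond the listed segments.
    label
        Human-readable name used in table metadata.
    """

    segments: Tuple[Tuple[float, int], ...]
    cyclic: bool = True
    label: str = ""

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        segs = tuple((float(d), int(L)) for d, L in self.segments)
        for d, L in segs:
            if d <= 0:
                raise ValueError("segment durations must be > 0")
            if L not in (0, 1):
                raise ValueError("L must be 0 or 1")
        object.__setattr__(self, "segments", segs)

    @property
    def cycle_length(self) -> Optional[float]:
        """Repeat period in hours, or None for acyclic protocols."""
        if not self.cyclic:
            return None
        return sum(d for d, _ in self.segments)

    def light(self, t: float) -> int:
        """Evaluate L(t); right-continuous at switch points."""
        if t < 0:
            raise ValueError("t must be >= 0")
        total = sum(d for d, _ in self.segments)
        if self.cyclic:
            t = t % total
        elif t >= total:
            return self.segments[-1][1]
        acc = 0.0
        for d, L in self.segments:
            acc += d
            if t < acc:
                return L
        return self.segments[-1][1]

    def __call__(self, t: float) -> int:
        return self.light(t)

    def switch_times(self, t_end: float) -> Iterator[float]:
        """Yield every interior time in (0, t_end) at which L may change."""
        total = sum(d for d, _ in self.segments)
        bounds = []
        acc = 0.0
        for d, _ in self.segments:
            acc += d
            bounds.append(acc)
        if not self.cyclic:
            # the last level extends forever, so its end is not a switch
            for b in bounds[:-1]:
                if b < t_end:
                    yield b
            return
        cycle = 0
        while True:
            base = cycle * total
            for b in bounds:
                t = base + b
                if t >= t_end:
                    return
                yield t
            cycle += 1


@dataclass(frozen=True)
class CompositeProtocol:
    """Ordered phases of light protocols; only the last may be unbounded.

    ``phases`` is a sequence of ``(protocol, duration)`` with duration in
    hours or ``None`` ("forever", final phase only).  Each phase's protocol
    is evaluated on its own local clock starting at 0, so a release phase
    begins at its own ZT0.
    """

    phases: Tuple[Tuple[LightProtocol, Optional[float]], ...]
    label: str = ""

    def __post_init__(self) -> None:
        phases = tuple((p, None if d is None else float(d)) for p, d in self.phases)
        if not phases:
            raise ValueError("composite protocol needs at least one phase")
        for p, d in phases[:-1]:
            if d is None:
                raise ValueError("only the last phase may be unbounded")
            if d <= 0:
                raise ValueError("phase durations must be > 0")
        object.__setattr__(self, "phases", phases)

    @property
    def cycle_length(self) -> Optional[float]:
        return None

    def phase_starts(self) -> List[float]:
        """Absolute start time of each phase."""
        starts, acc = [], 0.0
        for _, d in self.phases:
            starts.append(acc)
            if d is not None:
                acc += d
        return starts

    def light(self, t: float) -> int:
        if t < 0:
            raise ValueError("t must be >= 0")
        acc = 0.0
        for proto, d in self.phases:
            if d is None or t < acc + d:
                return proto.light(t - acc)
            acc += d
        # past the end of a fully bounded composite: hold the last level
        proto, d = self.phases[-1]
        return proto.light(t - (acc - d))

    def __call__(self, t: float) -> int:
        return self.light(t)

    def switch_times(self, t_end: float) -> Iterator[float]:
        acc = 0.0
        for proto, d in self.phases:
            local_end = t_end - acc if d is None else min(d, t_end - acc)
            if local_end <= 0:
                return
            for s in proto.switch_times(local_end):
                yield acc + s
            if d is None:
                return
            acc += d
            if 0 < acc < t_end:
                yield acc


# ---------------------------------------------------------------------------
# Named constructors
# ---------------------------------------------------------------------------

def ld_cycle(photoperiod: float, cycle_length: float = 24.0) -> LightProtocol:
    """Light/dark cycle: lights on for ``photoperiod`` hours starting at
    ZT0, dark for the remainder of ``cycle_length``.  ``ld_cycle(8)`` is
    the short-day 8L:16D cycle; ``ld_cycle(6, 12)`` the 6L:6D T12 cycle."""
    if not 0 < photoperiod < cycle_length:
        raise ValueError("need 0 < photoperiod < cycle_length")
    dark = cycle_length - photoperiod
    return LightProtocol(
        ((photoperiod, 1), (dark, 0)),
        cyclic=True,
        label=f"{photoperiod:g}L:{dark:g}D",
    )


def skeleton(pulse1: float, gap1: float, pulse2: float, gap2: float) -> LightProtocol:
    """Skeleton photoperiod: two light pulses marking dawn and dusk,
    darkness otherwise.  ``skeleton(3, 6, 3, 12)`` is the 3L:6D:3L:12D
    24-hour skeleton."""
    return LightProtocol(
        ((pulse1, 1), (gap1, 0), (pulse2, 1), (gap2, 0)),
        cyclic=True,
        label=f"{pulse1:g}L:{gap1:g}D:{pulse2:g}L:{gap2:g}D",
    )


def constant(L: int) -> LightProtocol:
    """Constant conditions: ``constant(1)`` is continuous light (LL),
    ``constant(0)`` continuous darkness (DD).  Aperiodic
    (``cycle_length`` is None)."""
    if L not in (0, 1):
        raise ValueError("L must be 0 or 1")
    return LightProtocol(((1.0, L),), cyclic=False, label="LL" if L else "DD")


def entrain_release(entrain: LightProtocol, n_cycles: int,
                    release: LightProtocol) -> CompositeProtocol:
    """Entrain for ``n_cycles`` full cycles, then release into ``release``
    forever.  The release phase starts exactly at the end of the last
    entraining cycle (its dawn, ZT0, coincides with the switch)."""
    if not entrain.cyclic:
        raise ValueError("entraining protocol must be cyclic")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    dur = n_cycles * entrain.cycle_length
    return CompositeProtocol(
        ((entrain, dur), (release, None)),
        label=f"{entrain.label} x{n_cycles} -> {release.label}",
    )
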