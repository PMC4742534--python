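"""Rhythm extraction: periods, phases, rhythmicity calls, photoperiod scans.

Conventions
-----------
* Phases are reported in Zeitgeber Time (ZT): hours after lights-on of the
  entraining cycle, in ``[0, cycle_length)``.
* Peaks and troughs are located from the sampled trajectory and refined by
  a quadratic (three-point parabolic) interpolation, so their timing is
  much finer than the output sampling step.
* A series is called *rhythmic* when it shows at least three peaks whose
  inter-peak intervals have a coefficient of variation below 5% and whose
  last full cycle retains more than 1% of a reference amplitude; *damped*
  when peaks exist but the amplitude decays below that floor; otherwise
  *arrhythmic*.  The period of a rhythmic series is the mean inter-peak
  interval.
* Dawn/dusk sensitivity is quantified as the least-squares slope of peak
  phase (ZT) against photoperiod: 0 for a perfectly dawn-tracking gene,
  1 for a perfectly dusk-tracking one.  This index is a convention of this
  package; the underlying concept is standard in the entrainment
  literature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .clock_model import Genotype, GENOTYPE_PRESETS, ParameterSet
from .light_protocols import LightProtocol, constant, entrain_release, ld_cycle
from .simulate import Trajectory, equilibrate, integrate

__all__ = [
    "PeriodEstimate",
    "find_peaks",
    "find_troughs",
    "estimate_period",
    "entrained_phases",
    "photoperiod_scan",
    "dusk_sensitivity",
    "release_phase_scan",
    "demultiplication_test",
    "DEFAULT_PHOTOPERIODS",
]

#: Standard photoperiod scan: 3 to 21 h in 3 h increments.
DEFAULT_PHOTOPERIODS = (3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 21.0)

RHYTHMIC = "rhythmic"
DAMPED = "damped"
ARRHYTHMIC = "arrhythmic"

#: Relative amplitude floor for the rhythmicity call (fraction of the
#: reference amplitude below which oscillations count as undetectable).
AMPLITUDE_FLOOR_FRACTION = 0.01

#: Maximal coefficient of variation of inter-peak intervals for a
#: rhythmic call.
MAX_INTERVAL_CV = 0.05


@dataclass
class PeriodEstimate:
    """Summary of the rhythmicity of one component over one window."""

    period: float           # hours; NaN when not rhythmic
    sd_of_intervals: float  # hours; NaN with < 3 peaks
    n_peaks: int
    rhythmic: str           # one of RHYTHMIC / DAMPED / ARRHYTHMIC
    amplitude: float        # peak-to-trough of the last full cycle

    @property
    def is_rhythmic(self) -> bool:
        return self.rhythmic == RHYTHMIC


def _refine_parabolic(t: np.ndarray, x: np.ndarray, i: int) -> Tuple[float, float]:
    """Vertex of the parabola through points i-1, i, i+1 (uniform grid)."""
    y0, y1, y2 = x[i - 1], x[i], x[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(t[i]), float(x[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = min(max(delta, -1.0), 1.0)
    dt = t[i + 1] - t[i]
    t_peak = t[i] + delta * dt
    x_peak = y1 - 0.25 * (y0 - y2) * delta
    return float(t_peak), float(x_peak)


def find_peaks(traj: Trajectory, component: str,
               min_prominence: float = 0.0) -> List[Tuple[float, float]]:
    """Local maxima of one component, refined by quadratic interpolation.

    Returns ``(time, value)`` pairs.  Monotone or constant series yield an
    empty list.  ``min_prominence`` drops maxima whose height above the
    adjacent minima is below the given absolute value (guards against
    numerical ripple on nearly flat series).
    """
    x = np.asarray(traj.column(component), dtype=float)
    t = np.asarray(traj.times, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    mid = x[1:-1]
    # strict rise then fall; plateaus (equal neighbours) are skipped
    is_peak = (mid > x[:-2]) & (mid > x[2:])
    idx = np.nonzero(is_peak)[0] + 1
    if idx.size and min_prominence > 0:
        left_min = np.minimum.accumulate(x)[idx - 1]
        right_min = np.minimum.accumulate(x[::-1])[::-1][idx + 1]
        prom = x[idx] - np.maximum(left_min, right_min)
        idx = idx[prom >= min_prominence]
    return [_refine_parabolic(t, x, i) for i in idx]


def find_troughs(traj: Trajectory, component: str) -> List[Tuple[float, float]]:
    """Local minima, symmetric to :func:`find_peaks`."""
    neg = Trajectory(traj.times, -traj.states, traj.labels,
                     traj.protocol, traj.genotype)
    return [(t, -v) for t, v in find_peaks(neg, component)]


def estimate_period(
    traj: Trajectory,
    component: str = "cl_m",
    window: Optional[float] = None,
    reference_amplitude: Optional[float] = None,
) -> PeriodEstimate:
    """Mean inter-peak interval and rhythmicity call over the trailing
    ``window`` hours (whole trajectory if omitted).

    ``reference_amplitude`` sets the detection floor (1% of it); when not
    given, the floor is 1% of the largest peak-to-trough excursion within
    the window itself, which classifies heavily damped series correctly
    without external context.
    """
    t_last = float(traj.times[-1])
    sub = traj if window is None else traj.window(t_last - window, t_last)
    if window is not None and window > t_last + 1e-9:
        raise ValueError("window longer than trajectory span")

    x = sub.column(component)
    full_amp = float(np.max(x) - np.min(x))
    ref = reference_amplitude if reference_amplitude is not None else full_amp
    floor = AMPLITUDE_FLOOR_FRACTION * ref
    # only count substantial peaks: minor light-response bumps riding on the
    # main oscillation (and numerical ripple on flat series) would otherwise
    # corrupt the inter-peak interval statistics
    peaks = find_peaks(sub, component, min_prominence=0.05 * full_amp)
    troughs = find_troughs(sub, component)
    n = len(peaks)

    def trailing_amplitude(cycle_hours: float) -> float:
        """Excursion over the final cycle of the window (a damped series
        must be judged on where it ends, not on its early peaks)."""
        t_hi = float(sub.times[-1])
        m = sub.times >= t_hi - min(cycle_hours, t_hi - float(sub.times[0]))
        seg = x[m]
        return float(seg.max() - seg.min()) if seg.size else 0.0

    if n < 3:
        last_amp = trailing_amplitude(24.0)
        call = DAMPED if (n >= 1 and full_amp > floor) else ARRHYTHMIC
        return PeriodEstimate(float("nan"), float("nan"), n, call, last_amp)

    intervals = np.diff([p[0] for p in peaks])
    mean_T = float(np.mean(intervals))
    sd_T = float(np.std(intervals, ddof=1)) if intervals.size > 1 else 0.0
    cv = sd_T / mean_T if mean_T > 0 else np.inf
    last_amp = trailing_amplitude(mean_T)

    if last_amp <= floor:
        call = DAMPED
    elif cv < MAX_INTERVAL_CV:
        call = RHYTHMIC
    else:
        call = ARRHYTHMIC
    period = mean_T if call == RHYTHMIC else float("nan")
    return PeriodEstimate(period, sd_T, n, call, last_amp)


def entrained_phases(
    traj: Trajectory,
    protocol: LightProtocol,
    component: str = "cl_m",
) -> Tuple[float, float]:
    """Peak and trough phase (ZT hours) of the last full entrained cycle.

    The trajectory must start at a cycle boundary (ZT0 = lights-on), as
    produced by simulating from an equilibrated state.
    """
    cycle = protocol.cycle_length
    if cycle is None:
        raise ValueError("entrained phases require a cyclic protocol")
    t_last = float(traj.times[-1])
    n_full = int(np.floor(t_last / cycle + 1e-9))
    if n_full < 1:
        raise ValueError("trajectory shorter than one cycle")
    # analyse the last complete cycle, padded by one sample on each side so
    # a peak sitting exactly on the boundary is still a local maximum
    sub = traj.window((n_full - 1) * cycle - 2e-9 - 2 * (traj.times[1] - traj.times[0]),
                      n_full * cycle + 2 * (traj.times[1] - traj.times[0]))
    peaks = find_peaks(sub, component)
    troughs = find_troughs(sub, component)
    lo, hi = (n_full - 1) * cycle, n_full * cycle
    peaks = [p for p in peaks if lo - 1e-6 <= p[0] < hi - 1e-6] or peaks
    troughs = [p for p in troughs if lo - 1e-6 <= p[0] < hi - 1e-6] or troughs
    if not peaks or not troughs:
        raise ValueError(f"no full oscillation of {component!r} in the last cycle")
    best_peak = max(peaks, key=lambda p: p[1])
    best_trough = min(troughs, key=lambda p: p[1])
    return (best_peak[0] % cycle, best_trough[0] % cycle)


def photoperiod_scan(
    params: ParameterSet,
    genotype: Optional[Genotype] = None,
    photoperiods: Sequence[float] = DEFAULT_PHOTOPERIODS,
    components: Sequence[str] = ("cl_m", "p97_m", "p51_m", "el_m"),
    cycle_length: float = 24.0,
    n_cycles: int = 16,
    dt_out: float = 0.05,
) -> pd.DataFrame:
    """Entrained peak/trough phases across photoperiods (a phase table).

    For each photoperiod the clock is equilibrated for ``n_cycles`` cycles
    and the phases are read from one further cycle.  Columns:
    ``photoperiod, component, peak_zt, trough_zt``.
    """
    if genotype is None:
        genotype = GENOTYPE_PRESETS["wildtype"]
    rows = []
    for pp in photoperiods:
        proto = ld_cycle(pp, cycle_length)
        y0 = equilibrate(params, genotype, proto, n_cycles=n_cycles)
        # two cycles, so a peak sitting exactly on a cycle boundary is an
        # interior extremum of the analysed window
        traj = integrate(params, genotype, proto, t_end=2 * cycle_length,
                         dt_out=dt_out, initial=y0)
        for comp in components:
            try:
                peak_zt, trough_zt = entrained_phases(traj, proto, comp)
            except ValueError:  # flat under this photoperiod
                peak_zt = trough_zt = float("nan")
            rows.append({"photoperiod": pp, "component": comp,
                         "peak_zt": peak_zt, "trough_zt": trough_zt})
    return pd.DataFrame(rows)


def _unwrap_phases(photoperiods: np.ndarray, phases: np.ndarray,
                   cycle: float) -> np.ndarray:
    """Lift circular phases to a continuous branch (smallest jumps)."""
    out = np.array(phases, dtype=float)
    for i in range(1, out.size):
        d = out[i] - out[i - 1]
        d -= cycle * np.round(d / cycle)
        out[i] = out[i - 1] + d
    return out


def dusk_sensitivity(table: pd.DataFrame, component: str,
                     which: str = "peak_zt", cycle_length: float = 24.0) -> float:
    """Least-squares slope of (unwrapped) peak phase against photoperiod.

    0 means the phase is locked to dawn, 1 that it tracks dusk; values in
    between indicate mixed sensitivity.
    """
    sub = table[table["component"] == component].sort_values("photoperiod")
    if len(sub) < 2:
        raise ValueError("need phases for at least two photoperiods")
    pp = sub["photoperiod"].to_numpy(dtype=float)
    ph = _unwrap_phases(pp, sub[which].to_numpy(dtype=float), cycle_length)
    slope = np.polyfit(pp, ph, 1)[0]
    return float(slope)


def circular_spread(values, period: float) -> float:
    """Smallest arc (in hours) containing all values taken modulo
    ``period``.

    Used for comparing peak times across conditions where a peak sitting
    just before versus just after a cycle boundary should count as nearly
    coincident, not one full period apart.
    """
    v = np.sort(np.asarray(values, dtype=float) % period)
    if v.size < 2:
        return 0.0
    gaps = np.diff(np.concatenate([v, [v[0] + period]]))
    return float(period - gaps.max())


def release_phase_scan(
    params: ParameterSet,
    genotype: Optional[Genotype] = None,
    photoperiods: Sequence[float] = DEFAULT_PHOTOPERIODS,
    component: str = "cl_m",
    cycle_length: float = 24.0,
    n_cycles: int = 16,
    release_into: Optional[LightProtocol] = None,
    follow: float = 48.0,
    dt_out: float = 0.05,
) -> pd.DataFrame:
    """Time of the first free-running peak after release into constant
    conditions, for each entraining photoperiod.

    The clock is entrained for ``n_cycles`` cycles of each photoperiod and
    released at a common reference time (the dawn that ends the last
    cycle, taken as hour 0 of the release).  Columns: ``photoperiod,
    first_peak_h`` (hours after release).
    """
    if genotype is None:
        genotype = GENOTYPE_PRESETS["wildtype"]
    if release_into is None:
        release_into = constant(1)
    rows = []
    for pp in photoperiods:
        proto = ld_cycle(pp, cycle_length)
        y0 = equilibrate(params, genotype, proto, n_cycles=n_cycles)
        traj = integrate(params, genotype, release_into, t_end=follow,
                         dt_out=dt_out, initial=y0)
        peaks = find_peaks(traj, component)
        if not peaks:
            rows.append({"photoperiod": pp, "first_peak_h": float("nan")})
            continue
        amp_ref = max(v for _, v in peaks)
        peaks = [p for p in peaks if p[1] > 0.05 * amp_ref]
        rows.append({"photoperiod": pp, "first_peak_h": peaks[0][0]})
    return pd.DataFrame(rows)


def demultiplication_test(
    params: ParameterSet,
    genotype: Optional[Genotype] = None,
    protocol: Optional[LightProtocol] = None,
    component: str = "cl_m",
    window: float = 96.0,
    n_cycles_equilibrate: int = 20,
    dt_out: float = 0.05,
) -> Tuple[float, str]:
    """Dominant period under a (possibly non-24 h) cycle and its relation
    to the forcing cycle.

    Returns ``(dominant_period, classification)`` with classification
    ``"locked"`` (period ~ cycle length), ``"demultiplied"`` (period ~ an
    integer multiple k >= 2 of the cycle, the frequency-demultiplication
    regime) or ``"neither"``.  The dominant period is the mean inter-peak
    interval of ``component`` over the trailing ``window`` hours after
    equilibration; irregular peak trains (interval CV above the rhythmic
    threshold) are classified ``"neither"``.
    """
    if genotype is None:
        genotype = GENOTYPE_PRESETS["wildtype"]
    if protocol is None or protocol.cycle_length is None:
        raise ValueError("demultiplication test requires a cyclic protocol")
    cycle = protocol.cycle_length
    y0 = equilibrate(params, genotype, protocol, n_cycles=n_cycles_equilibrate)
    traj = integrate(params, genotype, protocol, t_end=window,
                     dt_out=dt_out, initial=y0)
    x = traj.column(component)
    amp = float(np.max(x) - np.min(x))
    # only major peaks: forced oscillators typically show small direct
    # light-response bumps (well under a quarter of the swing) riding on
    # the dominant rhythm, and those must not enter the interval statistics
    peaks = find_peaks(traj, component,
                       min_prominence=0.25 * amp if amp > 0 else 1e-12)
    if len(peaks) < 3:
        return float("nan"), "neither"
    intervals = np.diff([p[0] for p in peaks])
    T = float(np.mean(intervals))
    cv = float(np.std(intervals, ddof=1) / T) if intervals.size > 1 else 0.0
    if cv >= MAX_INTERVAL_CV:
        return T, "neither"
    k = T / cycle
    k_round = round(k)
    if abs(k - k_round) < 0.1 and k_round >= 1:
        return T, "locked" if k_round == 1 else "demultiplied"
    return T, "neither"
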