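"""Clock output module: PIF4/5-driven hypocotyl elongation.

Hypocotyl growth is gated by light and the clock through an external
coincidence mechanism: the Evening Complex represses *PIF4/PIF5*
transcription while it is present, and light rapidly degrades the PIF4/5
protein.  In long days the EC spans the whole (short) night, so PIF
protein never accumulates and growth is suppressed; in short days the EC
decays before dawn, PIF accumulates pre-dawn and drives elongation.

Three variables extend the clock state: ``pif_m`` (merged PIF4/5 mRNA,
repressed by the EC), ``pif_p`` (PIF4/5 protein, degraded much faster in
the light), and ``H`` (hypocotyl length, starting at zero and
accumulating with time).  Coupling is strictly one way — the clock never
sees the hypocotyl state.

Lengths are reported relative to the dark-grown wild type after the same
number of days.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .clock_model import (
    STATE_VARS,
    Genotype,
    GENOTYPE_PRESETS,
    ParameterSet,
    make_rhs,
)
from .light_protocols import LightProtocol, constant, ld_cycle
from .simulate import Trajectory, equilibrate, integrate

__all__ = [
    "HypocotylParams",
    "GrowthResult",
    "HYPOCOTYL_PARAM_NAMES",
    "hypocotyl_rhs",
    "simulate_growth",
    "growth_curve",
    "dark_grown_length",
]

#: The nine free parameters of the output module.
HYPOCOTYL_PARAM_NAMES = (
    "v_pif",      # maximal PIF4/5 transcription rate (1/h)
    "K_ec_pif",   # EC repression constant
    "dm_pif",     # PIF mRNA degradation (1/h)
    "pt_pif",     # PIF translation (1/h)
    "dp_pif_l",   # PIF protein degradation in light (fast)
    "dp_pif_d",   # PIF protein degradation in dark (slow)
    "k_growth",   # growth rate constant
    "K_growth",   # growth saturation constant (saturating law only)
    "g0",         # basal PIF-independent elongation rate
)

HYPOCOTYL_STATE_VARS = ("pif_m", "pif_p", "hyp_len")


@dataclass
class HypocotylParams:
    """Nine positive constants; ``K_growth`` participates only when the
    saturating growth law is selected (the default law is linear in PIF
    protein)."""

    v_pif: float = 1.4
    K_ec_pif: float = 0.25
    dm_pif: float = 0.5
    pt_pif: float = 1.0
    dp_pif_l: float = 3.0
    dp_pif_d: float = 0.1
    k_growth: float = 0.05
    K_growth: float = 1.0
    g0: float = 0.002
    #: growth law selector (structural, not a free parameter)
    saturating: bool = False

    def __post_init__(self) -> None:
        for name in HYPOCOTYL_PARAM_NAMES:
            if getattr(self, name) <= 0:
                raise ValueError(f"hypocotyl parameter {name!r} must be > 0")

    def to_dict(self) -> Dict[str, float]:
        return {k: getattr(self, k) for k in HYPOCOTYL_PARAM_NAMES}

    @classmethod
    def from_dict(cls, d) -> "HypocotylParams":
        unknown = set(d) - set(HYPOCOTYL_PARAM_NAMES)
        if unknown:
            raise KeyError(f"unknown hypocotyl parameter(s): {sorted(unknown)}")
        return cls(**dict(d))

    def replace(self, **changes) -> "HypocotylParams":
        return dataclasses.replace(self, **changes)


@dataclass
class GrowthResult:
    """Simulated hypocotyl length for one photoperiod and genotype,
    relative to the dark-grown wild type."""

    photoperiod: float
    genotype: str
    length: float
    raw_length: float = float("nan")


def hypocotyl_rhs(t, hstate, clock_state, hparams: HypocotylParams, L):
    """Derivatives of (pif_m, pif_p, H) given the current clock state.

    PIF transcription is repressed by the EC (Hill coefficient 2); the
    protein is translated linearly and degraded with a light-switched
    linear rate; length accumulates at ``g0 + k_growth * f(pif_p)`` where
    ``f`` is the identity (default) or a saturating Michaelian term.
    """
    pif_m, pif_p, _H = hstate
    if hasattr(clock_state, "ec_p"):
        ec = clock_state.ec_p
    else:
        ec = np.asarray(clock_state, dtype=float)[STATE_VARS.index("ec_p")]
    K2 = hparams.K_ec_pif ** 2
    tx = hparams.v_pif * K2 / (K2 + ec * ec)
    d_pif = hparams.dp_pif_d + (hparams.dp_pif_l - hparams.dp_pif_d) * L
    if hparams.saturating:
        growth = hparams.k_growth * pif_p / (hparams.K_growth + pif_p)
    else:
        growth = hparams.k_growth * pif_p
    return (
        tx - hparams.dm_pif * pif_m,
        hparams.pt_pif * pif_m - d_pif * pif_p,
        hparams.g0 + growth,
    )


def _combined_rhs(params: ParameterSet, genotype: Genotype,
                  hparams: HypocotylParams):
    clock = make_rhs(params, genotype)
    v_pif, dm_pif = hparams.v_pif, hparams.dm_pif
    K2 = hparams.K_ec_pif ** 2
    pt_pif = hparams.pt_pif
    dp_l, dp_d = hparams.dp_pif_l, hparams.dp_pif_d
    k_g, K_g, g0 = hparams.k_growth, hparams.K_growth, hparams.g0
    sat = hparams.saturating

    def rhs(t, y, L):
        dclock = clock(t, y[:9], L)
        ec = y[7]
        pif_m, pif_p = y[9], y[10]
        tx = v_pif * K2 / (K2 + ec * ec)
        growth = k_g * (pif_p / (K_g + pif_p) if sat else pif_p)
        return dclock + (
            tx - dm_pif * pif_m,
            pt_pif * pif_m - (dp_d + (dp_l - dp_d) * L) * pif_p,
            g0 + growth,
        )

    return rhs


def _growth_protocol(photoperiod: float) -> LightProtocol:
    if photoperiod <= 0:
        return constant(0)
    if photoperiod >= 24:
        return constant(1)
    return ld_cycle(photoperiod)


def simulate_growth_trajectory(
    params: ParameterSet,
    hparams: HypocotylParams,
    genotype: Optional[Genotype] = None,
    photoperiod: float = 8.0,
    days: float = 5.0,
    dt_out: float = 0.1,
    equilibrate_hours: float = 360.0,
) -> Trajectory:
    """Full 12-variable trajectory over the growth window.

    The clock alone is first settled under the growth photoperiod for
    ``equilibrate_hours``; the hypocotyl variables then start from zero at
    the dawn that begins the growth period.
    """
    if genotype is None:
        genotype = GENOTYPE_PRESETS["wildtype"]
    proto = _growth_protocol(photoperiod)
    if proto.cycle_length is not None:
        n_cycles = max(1, int(round(equilibrate_hours / proto.cycle_length)))
        y0_clock = equilibrate(params, genotype, proto, n_cycles=n_cycles)
    else:
        y0_clock = integrate(params, genotype, proto,
                             t_end=equilibrate_hours,
                             dt_out=equilibrate_hours).final_state
    y0 = np.concatenate([y0_clock, [0.0, 0.0, 0.0]])
    traj = integrate(params, genotype, proto, t_end=days * 24.0,
                     dt_out=dt_out, initial=y0,
                     _rhs=_combined_rhs(params, genotype, hparams),
                     _n_extra=3)
    traj.labels = list(STATE_VARS) + list(HYPOCOTYL_STATE_VARS)
    return traj


def dark_grown_length(params: ParameterSet, hparams: HypocotylParams,
                      genotype: Optional[Genotype] = None,
                      days: float = 5.0) -> float:
    """Raw hypocotyl length after growth in complete darkness."""
    traj = simulate_growth_trajectory(params, hparams, genotype,
                                      photoperiod=0.0, days=days, dt_out=days * 24.0)
    return float(traj.column("hyp_len")[-1])


def simulate_growth(
    params: ParameterSet,
    hparams: HypocotylParams,
    genotype: Optional[Genotype] = None,
    photoperiod: float = 8.0,
    days: float = 5.0,
    reference_length: Optional[float] = None,
) -> GrowthResult:
    """Hypocotyl length after ``days`` of growth under the given
    photoperiod, relative to the dark-grown wild type (computed on the fly
    unless ``reference_length`` is supplied)."""
    if genotype is None:
        genotype = GENOTYPE_PRESETS["wildtype"]
    if reference_length is None:
        reference_length = dark_grown_length(
            params, hparams, GENOTYPE_PRESETS["wildtype"], days=days)
    traj = simulate_growth_trajectory(params, hparams, genotype,
                                      photoperiod=photoperiod, days=days,
                                      dt_out=days * 24.0)
    raw = float(traj.column("hyp_len")[-1])
    return GrowthResult(photoperiod=photoperiod, genotype=genotype.name,
                        length=raw / reference_length, raw_length=raw)


def growth_curve(
    params: ParameterSet,
    hparams: HypocotylParams,
    genotype: Optional[Genotype] = None,
    photoperiods: Sequence[float] = tuple(range(0, 25, 2)),
    days: float = 5.0,
) -> List[GrowthResult]:
    """Length versus photoperiod (the photoperiod-response curve of
    seedling growth), sharing one dark-grown wild-type reference."""
    ref = dark_grown_length(params, hparams, GENOTYPE_PRESETS["wildtype"],
                            days=days)
    return [simulate_growth(params, hparams, genotype, pp, days=days,
                            reference_length=ref)
            for pp in photoperiods]
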