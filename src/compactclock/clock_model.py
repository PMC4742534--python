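"""Core nine-variable ODE model of the Arabidopsis circadian clock.

The oscillator merges four pairs of closely related clock genes into
single mRNA/protein variables:

* ``CL``  — the dawn genes *CCA1* and *LHY*;
* ``P97`` — the morning pseudo-response regulators *PRR9* and *PRR7*;
* ``P51`` — the evening pseudo-response regulators *PRR5* and *TOC1*;
* ``EL``  — *ELF4* and *LUX*, whose merged protein stands for the active
  Evening Complex (EC).

A ninth variable, ``P``, is a dark-accumulating activator (a stand-in for
PIF3/PIL1-type factors) that mediates the acute induction of the morning
genes at dawn.  Light is a binary forcing variable ``L`` in {0, 1}
(square-wave light/dark cycles).

Regulatory logic (arrows of the network):

* CL  transcription: acutely light-induced via P, repressed by P97 and P51.
* P97 transcription: acutely light-induced via P, activated by CL,
  repressed by P51 and the EC.
* P51 transcription: repressed by CL and by itself.
* EL  transcription: light-promoted (with a small dark baseline),
  repressed by CL, P51 and the EC.
* P:  produced in darkness (saturating at 1), degraded by light.

All transcription rates use Hill-type terms (coefficient 2); all protein
synthesis, protein degradation and mRNA degradation rates are linear.
Several rates switch value between light and dark.  Time is in hours,
concentrations in arbitrary units, and ZT0 corresponds to lights-on.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import numpy as np

__all__ = [
    "STATE_VARS",
    "GENE_PAIRS",
    "ClockState",
    "ParameterSet",
    "Genotype",
    "GENOTYPE_PRESETS",
    "hill_repression",
    "hill_activation",
    "clock_rhs",
    "apply_genotype",
    "make_rhs",
]

#: Order of the nine state variables everywhere in the package.
STATE_VARS = (
    "cl_m", "cl_p",
    "p97_m", "p97_p",
    "p51_m", "p51_p",
    "el_m", "ec_p",
    "p",
)

#: The four merged gene pairs whose transcription a genotype may rescale.
GENE_PAIRS = ("CL", "P97", "P51", "EL")

#: Hill coefficient used by every transcriptional Hill term (structural
#: constant, not a free parameter).
HILL_N = 2

#: Dark fraction of EL transcription (structural constant): EL expression
#: is light-promoted but keeps a small dark baseline so that the Evening
#: Complex, and hence rhythmicity, persists in constant darkness.
EL_DARK_FRACTION = 0.25


@dataclass
class ClockState:
    """Concentrations of the nine clock variables (arbitrary units)."""

    cl_m: float = 0.1
    cl_p: float = 0.1
    p97_m: float = 0.1
    p97_p: float = 0.1
    p51_m: float = 0.1
    p51_p: float = 0.1
    el_m: float = 0.1
    ec_p: float = 0.1
    p: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in STATE_VARS], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "ClockState":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(STATE_VARS),):
            raise ValueError(f"expected {len(STATE_VARS)} components, got {arr.shape}")
        return cls(**dict(zip(STATE_VARS, arr)))


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

#: The 34 free parameters, in canonical order.  Naming: ``v_*`` maximal
#: transcription rates, ``q_*`` acute-light amplitudes, ``K_<reg>_<target>``
#: Hill constants, ``dm_*`` mRNA degradation, ``pt_*`` translation,
#: ``dp_*`` protein degradation, with ``_l``/``_d`` marking light/dark
#: values of light-switched rates; ``v_p``/``d_p`` produce and degrade P.
PARAM_NAMES = (
    # transcription (4) + acute light amplitudes (2)
    "v_cl", "v_p97", "v_p51", "v_el", "q_cl", "q_p97",
    # Hill constants, one per regulatory arrow (10)
    "K_p97_cl", "K_p51_cl",
    "K_cl_p97", "K_p51_p97", "K_ec_p97",
    "K_cl_p51", "K_p51_p51",
    "K_cl_el", "K_p51_el", "K_ec_el",
    # mRNA degradation (5; CL has separate light/dark rates)
    "dm_cl_l", "dm_cl_d", "dm_p97", "dm_p51", "dm_el",
    # translation (5; CL has separate light/dark rates)
    "pt_cl_l", "pt_cl_d", "pt_p97", "pt_p51", "pt_ec",
    # protein degradation (6; PRR proteins are less stable in darkness)
    "dp_cl", "dp_p97_l", "dp_p97_d", "dp_p51_l", "dp_p51_d", "dp_ec",
    # dark-accumulating activator P (2)
    "v_p", "d_p",
)

N_FREE_PARAMETERS = 34
assert len(PARAM_NAMES) == N_FREE_PARAMETERS


@dataclass
class ParameterSet:
    """The 34 free rate/affinity constants of the clock model.

    All values are strictly positive; rates are per hour, Hill constants in
    the same arbitrary concentration units as the state.  Hill coefficients
    are structural (``HILL_N = 2``) and not counted among the free
    parameters, as is the dark fraction of EL transcription
    (``EL_DARK_FRACTION``).
    """

    v_cl: float = 11.2994264
    v_p97: float = 0.3919474421
    v_p51: float = 1.052985756
    v_el: float = 1.964617876
    q_cl: float = 107.2530112
    q_p97: float = 8.382455194
    K_p97_cl: float = 0.2480838691
    K_p51_cl: float = 0.5039380624
    K_cl_p97: float = 0.6620064699
    K_p51_p97: float = 0.6917542488
    K_ec_p97: float = 0.7216543866
    K_cl_p51: float = 0.4738775956
    K_p51_p51: float = 1.159471671
    K_cl_el: float = 0.7417772963
    K_p51_el: float = 3.923218254
    K_ec_el: float = 1.58211028
    dm_cl_l: float = 0.4138414792
    dm_cl_d: float = 0.1285314515
    dm_p97: float = 0.4825048292
    dm_p51: float = 0.7010692964
    dm_el: float = 0.3324248373
    pt_cl_l: float = 0.8290278823
    pt_cl_d: float = 1.136495317
    pt_p97: float = 12.85180052
    pt_p51: float = 0.6880195381
    pt_ec: float = 0.4067020911
    dp_cl: float = 0.5794017779
    dp_p97_l: float = 0.1235880756
    dp_p97_d: float = 0.3911992919
    dp_p51_l: float = 1.235837507
    dp_p51_d: float = 0.2651822054
    dp_ec: float = 0.5117623838
    v_p: float = 0.2856791101
    d_p: float = 1.041396646

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name!r} must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "ParameterSet":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (N_FREE_PARAMETERS,):
            raise ValueError(f"expected {N_FREE_PARAMETERS} parameters, got {arr.shape}")
        return cls(**dict(zip(PARAM_NAMES, arr)))

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ParameterSet":
        unknown = set(d) - set(PARAM_NAMES)
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**dict(d))

    def to_dict(self) -> Dict[str, float]:
        return {k: getattr(self, k) for k in PARAM_NAMES}

    def replace(self, **changes: float) -> "ParameterSet":
        return dataclasses.replace(self, **changes)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Genotype:
    """A mutant line expressed as transformations of transcription rates.

    ``tx_scale`` multiplies the maximal transcription rate (and, where
    present, the acute-light amplitude) of a gene pair: 0.5 for single
    loss-of-function mutants, 0.1 for double mutants, 0 for null lines.
    ``ox`` maps a gene pair to a constant, unregulated transcription rate,
    modelling constitutive overexpression.
    """

    name: str = "wildtype"
    tx_scale: Mapping[str, float] = field(default_factory=dict)
    ox: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mapping in (self.tx_scale, self.ox):
            for gene, value in mapping.items():
                if gene not in GENE_PAIRS:
                    raise KeyError(
                        f"unknown gene pair {gene!r}; valid: {GENE_PAIRS}"
                    )
                if value < 0:
                    raise ValueError(f"{gene}: multiplier/rate must be >= 0")

    def scale(self, gene: str) -> float:
        return float(self.tx_scale.get(gene, 1.0))


def _presets() -> Dict[str, Genotype]:
    """Mutant conventions, loaded from the packaged ``data/genotypes.yaml``.

    Single loss-of-function mutants halve the relevant mRNA synthesis rate,
    double mutants divide it by 10, null lines set it to zero.  Both members
    of a merged pair map to the same transformation, so e.g. ``cca1`` and
    ``lhy`` are the same simulated line.  The weak Evening Complex mutant
    (*elf3-12*) is modelled as a 0.5 scale on EL; EC-null lines (*elf3*,
    *elf4*, *lux*) zero EL synthesis.  ``cca1-ox`` replaces the regulated CL
    transcription term by a high constant rate (clock-dead overexpressor),
    expressed in the config as a multiple of the wild-type maximal rate.
    """
    from importlib import resources

    import yaml

    text = resources.files("compactclock").joinpath(
        "data", "genotypes.yaml").read_text()
    raw = yaml.safe_load(text)
    g: Dict[str, Genotype] = {}
    for name, spec in raw.items():
        spec = spec or {}
        ox = {}
        if "ox_v_cl_multiple" in spec:
            ox["CL"] = float(spec["ox_v_cl_multiple"]) * ParameterSet().v_cl
        g[name] = Genotype(name, tx_scale=dict(spec.get("tx_scale", {})),
                           ox=ox)
    return g


GENOTYPE_PRESETS: Dict[str, Genotype] = _presets()


def get_genotype(name: str) -> Genotype:
    """Look up a preset genotype by mutant name."""
    try:
        return GENOTYPE_PRESETS[name]
    except KeyError:
        valid = ", ".join(sorted(GENOTYPE_PRESETS))
        raise KeyError(f"unknown genotype {name!r}; presets: {valid}") from None


def apply_genotype(params: ParameterSet, genotype: Genotype) -> ParameterSet:
    """Return a parameter copy with the genotype's transcription scales applied.

    Maximal rates ``v_g`` (and acute amplitudes ``q_g`` where they exist)
    are multiplied by ``tx_scale``.  Overexpression entries are not
    representable as parameter rescaling; they are honoured by the RHS
    (the regulated transcription term is replaced by a constant).

    Scales of exactly zero are replaced by a tiny positive rate (1e-12) so
    the returned set remains a valid strictly-positive ``ParameterSet``;
    dynamically this is indistinguishable from a true null.
    """
    d = params.to_dict()
    pairs = {
        "CL": ("v_cl", "q_cl"),
        "P97": ("v_p97", "q_p97"),
        "P51": ("v_p51",),
        "EL": ("v_el",),
    }
    for gene, s in genotype.tx_scale.items():
        for pname in pairs[gene]:
            d[pname] = max(d[pname] * s, 1e-12)
    return ParameterSet.from_dict(d)


# ---------------------------------------------------------------------------
# Hill terms
# ---------------------------------------------------------------------------

def hill_repression(x: float, K: float, n: float = HILL_N) -> float:
    """Fractional transcription rate under a repressor at concentration ``x``.

    Returns ``K**n / (K**n + x**n)``: 1 with no repressor, 1/2 at
    half-saturation ``x == K``, monotonically decreasing in ``x``.
    """
    if K <= 0:
        raise ValueError("Hill constant K must be > 0")
    if n < 1:
        raise ValueError("Hill coefficient n must be >= 1")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("concentration x must be >= 0")
    Kn = K ** n
    out = Kn / (Kn + x ** n)
    return float(out) if out.ndim == 0 else out


def hill_activation(x: float, K: float, n: float = HILL_N) -> float:
    """Fractional transcription rate under an activator; complement of
    :func:`hill_repression` (the two sum to 1 for every ``x``)."""
    if K <= 0:
        raise ValueError("Hill constant K must be > 0")
    if n < 1:
        raise ValueError("Hill coefficient n must be >= 1")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("concentration x must be >= 0")
    xn = x ** n
    out = xn / (K ** n + xn)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Right-hand side
# ---------------------------------------------------------------------------

def make_rhs(params: ParameterSet, genotype: Optional[Genotype] = None):
    """Build a fast RHS closure ``f(t, y, L) -> dy/dt`` for the integrator.

    Genotype transcription scaling is folded into the rates once, here, so
    the returned function costs a handful of float operations per call.
    Light-switched rates interpolate as ``r(L) = r_dark + (r_light -
    r_dark) * L``, which is exact for square-wave L.
    """
    if genotype is None:
        genotype = GENOTYPE_PRESETS["wildtype"]
    pp = apply_genotype(params, genotype)

    v_cl, q_cl = pp.v_cl, pp.q_cl
    v_p97, q_p97 = pp.v_p97, pp.q_p97
    v_p51, v_el = pp.v_p51, pp.v_el
    K_p97_cl2 = pp.K_p97_cl ** 2
    K_p51_cl2 = pp.K_p51_cl ** 2
    K_cl_p97_2 = pp.K_cl_p97 ** 2
    K_p51_p97_2 = pp.K_p51_p97 ** 2
    K_ec_p97_2 = pp.K_ec_p97 ** 2
    K_cl_p51_2 = pp.K_cl_p51 ** 2
    K_p51_p51_2 = pp.K_p51_p51 ** 2
    K_cl_el2 = pp.K_cl_el ** 2
    K_p51_el2 = pp.K_p51_el ** 2
    K_ec_el2 = pp.K_ec_el ** 2
    dm_cl_l, dm_cl_d = pp.dm_cl_l, pp.dm_cl_d
    dm_p97, dm_p51, dm_el = pp.dm_p97, pp.dm_p51, pp.dm_el
    pt_cl_l, pt_cl_d = pp.pt_cl_l, pp.pt_cl_d
    pt_p97, pt_p51, pt_ec = pp.pt_p97, pp.pt_p51, pp.pt_ec
    dp_cl = pp.dp_cl
    dp_p97_l, dp_p97_d = pp.dp_p97_l, pp.dp_p97_d
    dp_p51_l, dp_p51_d = pp.dp_p51_l, pp.dp_p51_d
    dp_ec = pp.dp_ec
    v_p, d_p = pp.v_p, pp.d_p

    cl_ox = genotype.ox.get("CL")
    p97_ox = genotype.ox.get("P97")
    p51_ox = genotype.ox.get("P51")
    el_ox = genotype.ox.get("EL")
    b_el = EL_DARK_FRACTION

    def rhs(t, y, L):
        cl_m, cl_p, p97_m, p97_p, p51_m, p51_p, el_m, ec_p, p = y

        cl_p2 = cl_p * cl_p
        p97_p2 = p97_p * p97_p
        p51_p2 = p51_p * p51_p
        ec_p2 = ec_p * ec_p

        if cl_ox is None:
            tx_cl = (v_cl + q_cl * L * p) \
                * (K_p97_cl2 / (K_p97_cl2 + p97_p2)) \
                * (K_p51_cl2 / (K_p51_cl2 + p51_p2))
        else:
            tx_cl = cl_ox
        if p97_ox is None:
            tx_p97 = (v_p97 + q_p97 * L * p) \
                * (cl_p2 / (K_cl_p97_2 + cl_p2)) \
                * (K_p51_p97_2 / (K_p51_p97_2 + p51_p2)) \
                * (K_ec_p97_2 / (K_ec_p97_2 + ec_p2))
        else:
            tx_p97 = p97_ox
        if p51_ox is None:
            tx_p51 = v_p51 \
                * (K_cl_p51_2 / (K_cl_p51_2 + cl_p2)) \
                * (K_p51_p51_2 / (K_p51_p51_2 + p51_p2))
        else:
            tx_p51 = p51_ox
        if el_ox is None:
            tx_el = v_el * (b_el + (1.0 - b_el) * L) \
                * (K_cl_el2 / (K_cl_el2 + cl_p2)) \
                * (K_p51_el2 / (K_p51_el2 + p51_p2)) \
                * (K_ec_el2 / (K_ec_el2 + ec_p2))
        else:
            tx_el = el_ox

        return (
            tx_cl - (dm_cl_d + (dm_cl_l - dm_cl_d) * L) * cl_m,
            (pt_cl_d + (pt_cl_l - pt_cl_d) * L) * cl_m - dp_cl * cl_p,
            tx_p97 - dm_p97 * p97_m,
            pt_p97 * p97_m - (dp_p97_d + (dp_p97_l - dp_p97_d) * L) * p97_p,
            tx_p51 - dm_p51 * p51_m,
            pt_p51 * p51_m - (dp_p51_d + (dp_p51_l - dp_p51_d) * L) * p51_p,
            tx_el - dm_el * el_m,
            pt_ec * el_m - dp_ec * ec_p,
            v_p * (1.0 - L) * (1.0 - p) - d_p * L * p,
        )

    return rhs


def clock_rhs(t: float, state, params: ParameterSet, L: int,
              genotype: Optional[Genotype] = None) -> np.ndarray:
    """Time derivatives of the nine clock variables.

    Validating convenience wrapper around :func:`make_rhs`; the integrator
    uses the closure directly.  ``L`` must be 0 or 1 and the state
    non-negative (a negative component signals integrator failure
    upstream).
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (len(STATE_VARS),):
        raise ValueError(f"state must have {len(STATE_VARS)} components")
    if np.any(y < 0):
        raise ValueError("negative concentration in state")
    if L not in (0, 1):
        raise ValueError("L must be 0 or 1")
    return np.array(make_rhs(params, genotype)(t, y, L), dtype=float)
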