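"""Fixed-step RK4 integrator (numba-accelerated when available).

Parameter fitting evaluates the clock model tens of thousands of times;
the adaptive stiff solver used for analysis-grade trajectories is far too
slow for that.  This module provides a fixed-step classical Runge-Kutta
integrator over the square-wave light segments, compiled with numba when
it is importable.  Step size 0.02 h keeps period/phase errors well below
the tolerances of the fitting constraints (cross-checked against the
adaptive path in the test suite).

Not part of the public API.
"""

from __future__ import annotations

import numpy as np

from .clock_model import EL_DARK_FRACTION, ParameterSet, Genotype
from .light_protocols import CompositeProtocol, LightProtocol

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        if args and callable(args[0]):
            return args[0]
        return wrap

#: Layout of the constants vector consumed by the jitted RHS: effective
#: (genotype-folded) rates, squared Hill constants, and the four
#: overexpression overrides (< 0 means "no override").
N_CONST = 39


def pack_constants(params: ParameterSet, genotype: Genotype) -> np.ndarray:
    from .clock_model import apply_genotype

    pp = apply_genotype(params, genotype)
    c = np.empty(N_CONST)
    c[0:6] = [pp.v_cl, pp.q_cl, pp.v_p97, pp.q_p97, pp.v_p51, pp.v_el]
    c[6:16] = [pp.K_p97_cl ** 2, pp.K_p51_cl ** 2,
               pp.K_cl_p97 ** 2, pp.K_p51_p97 ** 2, pp.K_ec_p97 ** 2,
               pp.K_cl_p51 ** 2, pp.K_p51_p51 ** 2,
               pp.K_cl_el ** 2, pp.K_p51_el ** 2, pp.K_ec_el ** 2]
    c[16:21] = [pp.dm_cl_l, pp.dm_cl_d, pp.dm_p97, pp.dm_p51, pp.dm_el]
    c[21:26] = [pp.pt_cl_l, pp.pt_cl_d, pp.pt_p97, pp.pt_p51, pp.pt_ec]
    c[26:32] = [pp.dp_cl, pp.dp_p97_l, pp.dp_p97_d,
                pp.dp_p51_l, pp.dp_p51_d, pp.dp_ec]
    c[32:34] = [pp.v_p, pp.d_p]
    c[34] = EL_DARK_FRACTION
    for i, gene in enumerate(("CL", "P97", "P51", "EL")):
        c[35 + i] = genotype.ox.get(gene, -1.0)
    return c


@njit(cache=True)
def _rhs(y, L, c, dy):
    cl_m, cl_p = y[0], y[1]
    p97_m, p97_p = y[2], y[3]
    p51_m, p51_p = y[4], y[5]
    el_m, ec_p = y[6], y[7]
    p = y[8]

    cl_p2 = cl_p * cl_p
    p97_p2 = p97_p * p97_p
    p51_p2 = p51_p * p51_p
    ec_p2 = ec_p * ec_p

    if c[35] < 0:
        tx_cl = (c[0] + c[1] * L * p) * (c[6] / (c[6] + p97_p2)) \
            * (c[7] / (c[7] + p51_p2))
    else:
        tx_cl = c[35]
    if c[36] < 0:
        tx_p97 = (c[2] + c[3] * L * p) * (cl_p2 / (c[8] + cl_p2)) \
            * (c[9] / (c[9] + p51_p2)) * (c[10] / (c[10] + ec_p2))
    else:
        tx_p97 = c[36]
    if c[37] < 0:
        tx_p51 = c[4] * (c[11] / (c[11] + cl_p2)) * (c[12] / (c[12] + p51_p2))
    else:
        tx_p51 = c[37]
    if c[38] < 0:
        tx_el = c[5] * (c[34] + (1.0 - c[34]) * L) \
            * (c[13] / (c[13] + cl_p2)) * (c[14] / (c[14] + p51_p2)) \
            * (c[15] / (c[15] + ec_p2))
    else:
        tx_el = c[38]

    dy[0] = tx_cl - (c[17] + (c[16] - c[17]) * L) * cl_m
    dy[1] = (c[22] + (c[21] - c[22]) * L) * cl_m - c[26] * cl_p
    dy[2] = tx_p97 - c[18] * p97_m
    dy[3] = c[23] * p97_m - (c[28] + (c[27] - c[28]) * L) * p97_p
    dy[4] = tx_p51 - c[19] * p51_m
    dy[5] = c[24] * p51_m - (c[30] + (c[29] - c[30]) * L) * p51_p
    dy[6] = tx_el - c[20] * el_m
    dy[7] = c[25] * el_m - c[31] * ec_p
    dy[8] = c[32] * (1.0 - L) * (1.0 - p) - c[33] * L * p


@njit(cache=True)
def _rk4_segments(c, y0, seg_bounds, seg_L, dt_out, n_out, h_max):
    """RK4 over [0, seg_bounds[-1]]; states sampled every dt_out."""
    n = y0.shape[0]
    out = np.empty((n_out, n))
    out[0] = y0
    y = y0.copy()
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    yt = np.empty(n)
    next_out = 1
    t = 0.0
    for s in range(seg_bounds.shape[0]):
        t_end = seg_bounds[s]
        L = seg_L[s]
        while t < t_end - 1e-12:
            # step to the next output point or segment end, whichever first
            t_target = t_end
            if next_out < n_out:
                t_next_out = next_out * dt_out
                if t_next_out < t_target:
                    t_target = t_next_out
            h = t_target - t
            n_sub = int(np.ceil(h / h_max - 1e-12))
            if n_sub < 1:
                n_sub = 1
            hs = h / n_sub
            for _ in range(n_sub):
                _rhs(y, L, c, k1)
                for i in range(n):
                    yt[i] = y[i] + 0.5 * hs * k1[i]
                _rhs(yt, L, c, k2)
                for i in range(n):
                    yt[i] = y[i] + 0.5 * hs * k2[i]
                _rhs(yt, L, c, k3)
                for i in range(n):
                    yt[i] = y[i] + hs * k3[i]
                _rhs(yt, L, c, k4)
                for i in range(n):
                    y[i] += hs / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
                    if y[i] < 0.0:
                        y[i] = 0.0
            t = t_target
            if next_out < n_out and abs(t - next_out * dt_out) < 1e-9:
                out[next_out] = y
                next_out += 1
    while next_out < n_out:
        out[next_out] = y
        next_out += 1
    return out


def fast_integrate(params_or_c, genotype: Genotype = None, protocol=None,
                   t_end: float = 120.0, dt_out: float = 0.05,
                   initial=None, h_max: float = 0.02):
    """Sampled trajectory via fixed-step RK4.  Returns (times, states)."""
    if isinstance(params_or_c, ParameterSet):
        c = pack_constants(params_or_c, genotype)
    else:
        c = np.asarray(params_or_c, dtype=float)
    switches = list(protocol.switch_times(t_end))
    seg_bounds = np.array(switches + [t_end], dtype=float)
    starts = np.concatenate(([0.0], seg_bounds[:-1]))
    seg_L = np.array([float(protocol.light(s)) for s in starts])
    if initial is None:
        y0 = np.array([0.1] * 8 + [0.0])
    else:
        y0 = np.asarray(initial, dtype=float).copy()
    n_out = int(np.floor(t_end / dt_out + 1e-9)) + 1
    out = _rk4_segments(c, y0, seg_bounds, seg_L, dt_out, n_out, h_max)
    return np.arange(n_out) * dt_out, out
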