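#!/usr/bin/env python
"""Fit the nine hypocotyl parameters on top of a fixed clock set.

The clock parameters are never touched here (one-way coupling); the
target is the qualitative photoperiod response of seedling growth:

* wild type: long in darkness/short days, short and flat in long days
  (the two-domain shape produced by EC/light coincidence);
* prr9prr7 longer than the wild type, cca1lhy shorter, at matched
  photoperiods.

Because the coupling is one-way, the clock trajectories for every
(genotype, photoperiod) pair are simulated once and cached; each
candidate parameter vector then only requires re-integrating the three
output ODEs against the stored Evening Complex time course, which makes
the fit run in seconds.

Usage::

    python scripts/fit_hypocotyl.py --seed 3 --budget 600 \
        --out src/compactclock/data/params_hypocotyl_ref.txt
"""

from __future__ import annotations

import argparse

import numpy as np

from compactclock.clock_model import GENOTYPE_PRESETS
from compactclock.hypocotyl import (
    HYPOCOTYL_PARAM_NAMES,
    HypocotylParams,
    growth_curve,
)
from compactclock.io import load_reference_parameters, write_param_file
from compactclock.light_protocols import constant, ld_cycle
from compactclock.optimize import stochastic_minimize
from compactclock.simulate import equilibrate, integrate

PHOTOPERIODS = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0)
GENOTYPES = ("wildtype", "cca1lhy", "prr9prr7")
DAYS = 5.0
DT = 0.05


def cache_clock(params):
    """ec_p and L time courses over the growth window, per condition."""
    cache = {}
    for gname in GENOTYPES:
        genotype = GENOTYPE_PRESETS[gname]
        for pp in PHOTOPERIODS:
            proto = constant(0) if pp <= 0 else (
                constant(1) if pp >= 24 else ld_cycle(pp))
            if proto.cycle_length is not None:
                y0 = equilibrate(params, genotype, proto, n_cycles=15)
            else:
                y0 = integrate(params, genotype, proto, t_end=360.0,
                               dt_out=360.0).final_state
            traj = integrate(params, genotype, proto, t_end=DAYS * 24.0,
                             dt_out=DT, initial=y0)
            L = np.array([proto.light(t) for t in traj.times], dtype=float)
            cache[(gname, pp)] = (traj.column("ec_p"), L)
    return cache


def final_length(hp: HypocotylParams, ec: np.ndarray, L: np.ndarray) -> float:
    """Euler-Heun integration of the three output ODEs on the cached grid."""
    K2 = hp.K_ec_pif ** 2
    tx = hp.v_pif * K2 / (K2 + ec * ec)
    dp = hp.dp_pif_d + (hp.dp_pif_l - hp.dp_pif_d) * L
    m = 0.0
    p = 0.0
    H = 0.0
    for i in range(len(ec) - 1):
        # exact-exponential update for the linear decay, trapezoid forcing
        m = m + DT * (0.5 * (tx[i] + tx[i + 1]) - hp.dm_pif * m) \
            / (1.0 + 0.5 * DT * hp.dm_pif)
        p = p + DT * (hp.pt_pif * m - dp[i] * p) / (1.0 + 0.5 * DT * dp[i])
        growth = hp.k_growth * (p / (hp.K_growth + p) if hp.saturating else p)
        H += DT * (hp.g0 + growth)
    return H


def shape_cost(hp: HypocotylParams, cache) -> float:
    """Quadratic penalties on the qualitative growth targets."""
    wt_dark = final_length(hp, *cache[("wildtype", 0.0)])
    if wt_dark <= 0:
        return 1e4
    curves = {g: {pp: final_length(hp, *cache[(g, pp)]) / wt_dark
                  for pp in PHOTOPERIODS} for g in GENOTYPES}
    wt = curves["wildtype"]
    pen = 0.0
    for pp in (16.0, 20.0, 24.0):          # flat-low long-day domain
        pen += max(0.0, wt[pp] - 0.22) ** 2 * 50
    pen += max(0.0, wt[16.0] - wt[24.0] - 0.06) ** 2 * 200
    for lo, hi in ((4.0, 0.0), (8.0, 4.0), (12.0, 8.0)):
        pen += max(0.0, wt[lo] - wt[hi] + 0.02) ** 2 * 100  # monotone rise
    pen += (wt[8.0] - 0.55) ** 2 * 10      # mid-range short-day length
    for pp in (8.0, 12.0, 16.0):           # prr9prr7 long
        pen += max(0.0, 1.15 - curves["prr9prr7"][pp] / max(wt[pp], 1e-6)) ** 2 * 20
    for pp in (4.0, 8.0, 12.0):            # cca1lhy short
        pen += max(0.0, curves["cca1lhy"][pp] / max(wt[pp], 1e-6) - 0.85) ** 2 * 20
    return float(pen)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=3)
    ap.add_argument("--budget", type=int, default=600)
    ap.add_argument("--out", required=True)
    args = ap.parse_args()

    clock = load_reference_parameters()
    cache = cache_clock(clock)
    x0 = np.log10([getattr(HypocotylParams(), n)
                   for n in HYPOCOTYL_PARAM_NAMES])

    def cost(logx):
        try:
            hp = HypocotylParams.from_dict(
                dict(zip(HYPOCOTYL_PARAM_NAMES, 10.0 ** logx)))
        except ValueError:
            return 1e4
        return shape_cost(hp, cache)

    best, f = stochastic_minimize(cost, [(-4.0, 2.0)] * len(x0),
                                  seed=args.seed, budget=args.budget, x0=x0)
    hp = HypocotylParams.from_dict(dict(zip(HYPOCOTYL_PARAM_NAMES,
                                            10.0 ** best)))
    # confirm the shape with the full coupled integrator before shipping
    curve = growth_curve(clock, hp, GENOTYPE_PRESETS["wildtype"],
                         photoperiods=PHOTOPERIODS, days=DAYS)
    write_param_file(hp, args.out,
                     header=("hypocotyl output-module parameters\n"
                             f"seed = {args.seed}, budget = {args.budget}, "
                             f"shape cost = {f:.4f}"))
    print(f"shape cost {f:.4f}")
    for r in curve:
        print(f"  pp {r.photoperiod:4.1f}  rel length {r.length:.3f}")


if __name__ == "__main__":
    main()
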