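"""Shared fixtures: the shipped parameter set and a few expensive
trajectories reused across test modules (session-scoped so the stiff
integrations run once)."""

import numpy as np
import pytest

from compactclock.clock_model import GENOTYPE_PRESETS, ParameterSet
from compactclock.io import (
    load_reference_hypocotyl_parameters,
    load_reference_parameters,
)
from compactclock.light_protocols import constant, ld_cycle
from compactclock.simulate import Trajectory, equilibrate, integrate


@pytest.fixture(scope="session")
def ref_params():
    return load_reference_parameters()


@pytest.fixture(scope="session")
def hyp_params():
    return load_reference_hypocotyl_parameters()


@pytest.fixture(scope="session")
def wt():
    return GENOTYPE_PRESETS["wildtype"]


def entrain_release_traj(params, genotype, release_L, n_cycles=16,
                         release_hours=300.0, dt_out=0.05):
    """Standard protocol: 16 cycles of 8L:16D, then release into constant
    conditions; returns the free-running trajectory (t=0 at release)."""
    proto = ld_cycle(8)
    y0 = equilibrate(params, genotype, proto, n_cycles=n_cycles)
    return integrate(params, genotype, constant(release_L),
                     t_end=release_hours, dt_out=dt_out, initial=y0)


@pytest.fixture(scope="session")
def wt_ll_traj(ref_params, wt):
    return entrain_release_traj(ref_params, wt, release_L=1)


@pytest.fixture(scope="session")
def wt_dd_traj(ref_params, wt):
    return entrain_release_traj(ref_params, wt, release_L=0)


@pytest.fixture(scope="session")
def wt_ld_traj(ref_params, wt):
    """Two entrained short-day (8L:16D) cycles after 14 cycles of discard
    (two cycles so boundary-sitting peaks are interior extrema)."""
    proto = ld_cycle(8)
    y0 = equilibrate(ref_params, wt, proto, n_cycles=14)
    return integrate(ref_params, wt, proto, t_end=48.0, dt_out=0.05,
                     initial=y0)


def synthetic_trajectory(times, values, label="x"):
    values = np.asarray(values, dtype=float)
    return Trajectory(times=np.asarray(times, dtype=float),
                      states=values[:, None], labels=[label])
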