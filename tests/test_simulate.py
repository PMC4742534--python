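"""Integration engine: accuracy, determinism, grid independence,
non-negativity/boundedness, equilibration and trajectory I/O."""

import numpy as np
import pytest

from compactclock.clock_model import Genotype, ParameterSet
from compactclock.light_protocols import constant, ld_cycle
from compactclock.simulate import (
    Trajectory,
    equilibrate,
    integrate,
    normalize_to_max,
)


@pytest.fixture(scope="module")
def params():
    from compactclock.io import load_reference_parameters
    return load_reference_parameters()


class TestIntegrate:
    def test_deterministic(self, params):
        a = integrate(params, protocol=ld_cycle(8), t_end=48, dt_out=0.5)
        b = integrate(params, protocol=ld_cycle(8), t_end=48, dt_out=0.5)
        assert np.array_equal(a.states, b.states)

    def test_grid_independence(self, params):
        coarse = integrate(params, protocol=ld_cycle(8), t_end=48, dt_out=1.0)
        fine = integrate(params, protocol=ld_cycle(8), t_end=48, dt_out=0.5)
        shared = fine.states[::2]
        assert np.allclose(shared, coarse.states, rtol=1e-6, atol=1e-8)

    def test_tolerance_convergence(self, params):
        """Halving tolerances changes outputs by far less than 0.1%."""
        a = integrate(params, protocol=ld_cycle(8), t_end=72, dt_out=1.0)
        b = integrate(params, protocol=ld_cycle(8), t_end=72, dt_out=1.0,
                      rtol=5e-9, atol=5e-11)
        scale = np.abs(a.states).max(axis=0) + 1e-12
        assert np.max(np.abs(a.states - b.states) / scale) < 1e-3

    def test_non_negativity_and_boundedness(self, params):
        rng = np.random.default_rng(3)
        for _ in range(3):
            y0 = rng.uniform(0, 2, size=9)
            y0[8] = rng.uniform(0, 1)
            traj = integrate(params, protocol=ld_cycle(12), t_end=120,
                             dt_out=0.5, initial=y0)
            assert traj.states.min() > -1e-7
            # mRNAs bounded by max production / min degradation
            bound_cl = (params.v_cl + params.q_cl) / min(params.dm_cl_l,
                                                         params.dm_cl_d)
            assert traj.column("cl_m").max() < bound_cl * 1.01
            assert traj.column("p").max() <= 1.0 + 1e-7

    def test_all_null_genotype_decays_to_zero(self, params):
        dead = Genotype("dead", {g: 0.0 for g in ("CL", "P97", "P51", "EL")})
        traj = integrate(params, dead, ld_cycle(8), t_end=120, dt_out=1.0)
        for comp in ("cl_m", "p97_m", "p51_m", "el_m"):
            x = traj.column(comp)
            assert np.all(np.diff(x) <= 1e-9)
            assert x[-1] < 1e-6

    def test_bad_arguments(self, params):
        with pytest.raises(ValueError):
            integrate(params, t_end=-1)
        with pytest.raises(ValueError):
            integrate(params, dt_out=0)


class TestEquilibrate:
    def test_limit_cycle_convergence(self, params):
        proto = ld_cycle(8)
        y15 = equilibrate(params, protocol=proto, n_cycles=15)
        y16 = equilibrate(params, protocol=proto, n_cycles=1, initial=y15)
        rel = np.abs(y16 - y15) / (np.abs(y15) + 1e-9)
        assert rel.max() < 1e-3

    def test_entrained_periodicity(self, params):
        proto = ld_cycle(12)
        y0 = equilibrate(params, protocol=proto, n_cycles=16)
        traj = integrate(params, protocol=proto, t_end=48, dt_out=0.5,
                         initial=y0)
        a = traj.states[traj.times <= 24.0 - 0.25]
        b = traj.states[traj.times >= 24.0][:a.shape[0]]
        scale = np.abs(traj.states).max(axis=0) + 1e-9
        assert np.max(np.abs(a - b) / scale) < 1e-3

    def test_arrhythmic_line_reaches_fixed_point(self, params):
        ox = Genotype("cca1-ox", ox={"CL": 5.0 * params.v_cl})
        y0 = integrate(params, ox, constant(1), t_end=240,
                       dt_out=240).final_state
        y1 = integrate(params, ox, constant(1), t_end=24, dt_out=24,
                       initial=y0).final_state
        assert np.abs(y1 - y0).max() / (np.abs(y0).max()) < 1e-3

    def test_requires_cyclic_protocol(self, params):
        with pytest.raises(ValueError):
            equilibrate(params, protocol=constant(1), n_cycles=10)


class TestNormalizeAndIO:
    def test_normalize_to_max(self, params):
        traj = integrate(params, protocol=ld_cycle(8), t_end=48, dt_out=0.5)
        norm = normalize_to_max(traj, ["cl_m"])
        assert norm.column("cl_m").max() == pytest.approx(1.0)
        # peak time unchanged by a monotone rescale
        assert (np.argmax(norm.column("cl_m"))
                == np.argmax(traj.column("cl_m")))

    def test_normalize_rejects_flat_zero(self):
        traj = Trajectory(times=np.arange(4.0),
                          states=np.zeros((4, 1)), labels=["x"])
        with pytest.raises(ValueError):
            normalize_to_max(traj, ["x"])

    def test_tsv_roundtrip(self, params, tmp_path):
        traj = integrate(params, protocol=ld_cycle(8), t_end=24, dt_out=1.0)
        path = tmp_path / "traj.tsv"
        traj.to_tsv(path, metadata={"genotype": "wildtype"})
        back = Trajectory.from_tsv(path)
        assert list(back.labels) == list(traj.labels)
        assert np.allclose(back.states, traj.states, rtol=1e-9)
        assert np.allclose(back.times, traj.times)
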