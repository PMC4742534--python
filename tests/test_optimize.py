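"""Cost specification, cost evaluation and the seeded fitting engine."""

import numpy as np
import pytest

from compactclock.clock_model import ParameterSet
from compactclock.optimize import (
    BIG_PENALTY,
    Constraint,
    CostSpec,
    default_cost_spec,
    evaluate_cost,
    stochastic_minimize,
)


class TestDefaultSpec:
    def test_eleven_conditions(self):
        spec = default_cost_spec()
        conds = spec.conditions
        assert len(conds) == 11
        # WT in three regimes, four single mutants in two regimes each
        assert ("wildtype", "LD") in conds
        assert ("wildtype", "LL") in conds
        assert ("wildtype", "DD") in conds
        for m in ("cca1", "prr9", "prr5", "elf3-12"):
            assert (m, "LD") in conds and (m, "LL") in conds

    def test_wt_ll_period_target_is_24(self):
        spec = default_cost_spec()
        c = [c for c in spec.constraints
             if c.condition == "wildtype:LL" and c.observable == "period"]
        assert len(c) == 1 and c[0].value == 24.0

    def test_single_mutants_use_half_synthesis(self):
        from compactclock.clock_model import get_genotype
        spec = default_cost_spec()
        for name, _ in spec.conditions:
            if name == "wildtype":
                continue
            g = get_genotype(name)
            assert set(g.tx_scale.values()) == {0.5}

    def test_positive_weights_enforced(self):
        with pytest.raises(ValueError):
            CostSpec([Constraint("wildtype", "LL", "cl_m", "period",
                                 "target", 24.0, weight=0.0)])


class TestEvaluateCost:
    def test_reference_set_satisfies_period_constraints(self, ref_params):
        bd = evaluate_cost(ref_params, default_cost_spec(), fast=False)
        period_pen = {k: v for k, v in bd.penalties.items() if "period" in k}
        assert sum(period_pen.values()) == pytest.approx(0.0, abs=1e-6)
        assert not bd.failures

    def test_dead_cl_incurs_arrhythmicity_penalty(self, ref_params):
        crippled = ref_params.replace(v_cl=1e-6, q_cl=1e-6)
        spec = CostSpec([
            Constraint("wildtype", "LL", "cl_m", "rhythmic", "require",
                       "rhythmic"),
        ])
        bd = evaluate_cost(crippled, spec)
        assert bd.total >= BIG_PENALTY

    def test_weights_scale_total_linearly(self, ref_params):
        base = [Constraint("wildtype", "LL", "cl_m", "period", "target",
                           22.0, scale=0.5, weight=1.0)]
        double = [Constraint("wildtype", "LL", "cl_m", "period", "target",
                             22.0, scale=0.5, weight=2.0)]
        t1 = evaluate_cost(ref_params, CostSpec(base)).total
        t2 = evaluate_cost(ref_params, CostSpec(double)).total
        assert t2 == pytest.approx(2.0 * t1, rel=1e-9)

    def test_order_invariance(self, ref_params):
        spec = default_cost_spec()
        rev = CostSpec(list(reversed(spec.constraints)))
        a = evaluate_cost(ref_params, spec)
        b = evaluate_cost(ref_params, rev)
        assert a.total == pytest.approx(b.total, rel=1e-9)
        assert a.penalties == b.penalties


class TestStochasticMinimize:
    @staticmethod
    def quadratic(x):
        return float((x[0] - 0.7) ** 2 + 2.0 * (x[1] + 0.3) ** 2)

    def test_recovers_toy_optimum(self):
        x, f = stochastic_minimize(self.quadratic, [(-2, 2), (-2, 2)],
                                   seed=1, budget=400)
        assert np.allclose(x, [0.7, -0.3], atol=0.01)

    def test_seeded_determinism(self):
        runs = [stochastic_minimize(self.quadratic, [(-2, 2), (-2, 2)],
                                    seed=5, budget=200) for _ in range(2)]
        assert np.array_equal(runs[0][0], runs[1][0])
        assert runs[0][1] == runs[1][1]

    def test_best_score_non_increasing_in_budget(self):
        _, f_small = stochastic_minimize(self.quadratic, [(-2, 2), (-2, 2)],
                                         seed=9, budget=60)
        _, f_large = stochastic_minimize(self.quadratic, [(-2, 2), (-2, 2)],
                                         seed=9, budget=300)
        assert f_large <= f_small + 1e-12

    def test_budget_validation(self):
        with pytest.raises(ValueError):
            stochastic_minimize(self.quadratic, [(-1, 1)], seed=0, budget=0)
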