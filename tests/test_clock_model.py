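"""Unit and property tests for the core model definition: Hill terms,
genotype transformations, the RHS regulatory logic and the network
topology sign structure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from compactclock.clock_model import (
    GENE_PAIRS,
    GENOTYPE_PRESETS,
    N_FREE_PARAMETERS,
    PARAM_NAMES,
    STATE_VARS,
    ClockState,
    Genotype,
    ParameterSet,
    apply_genotype,
    clock_rhs,
    get_genotype,
    hill_activation,
    hill_repression,
    make_rhs,
)

conc = st.floats(min_value=0.0, max_value=100.0, allow_nan=False)
pos = st.floats(min_value=1e-3, max_value=100.0, allow_nan=False)


class TestHillTerms:
    @pytest.mark.parametrize("x,K,n,expected", [
        (0.0, 0.7, 2, 1.0),      # no repressor: full rate
        (0.7, 0.7, 2, 0.5),      # half-saturation
        (1.4, 0.7, 2, 0.2),      # K^2/(K^2+4K^2)
    ])
    def test_repression_values(self, x, K, n, expected):
        assert hill_repression(x, K, n) == pytest.approx(expected)

    @pytest.mark.parametrize("x,K,expected", [
        (0.0, 0.5, 0.0),
        (0.5, 0.5, 0.5),
    ])
    def test_activation_values(self, x, K, expected):
        assert hill_activation(x, K) == pytest.approx(expected)

    @given(x=conc, K=pos)
    @settings(max_examples=50, derandomize=True)
    def test_activation_repression_complementary(self, x, K):
        assert hill_activation(x, K) + hill_repression(x, K) == pytest.approx(1.0)

    def test_repression_monotone_decreasing(self):
        x = np.linspace(0, 10, 200)
        y = hill_repression(x, 0.8)
        assert np.all(np.diff(y) < 0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            hill_repression(1.0, 0.0)
        with pytest.raises(ValueError):
            hill_repression(-0.1, 1.0)
        with pytest.raises(ValueError):
            hill_activation(1.0, 1.0, n=0.5)


class TestParameterSet:
    def test_exactly_34_free_parameters(self):
        assert N_FREE_PARAMETERS == 34
        assert len(PARAM_NAMES) == 34
        assert len(set(PARAM_NAMES)) == 34

    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            ParameterSet(v_cl=0.0)
        with pytest.raises(ValueError):
            ParameterSet(K_ec_el=-1.0)

    def test_array_roundtrip(self):
        p = ParameterSet()
        assert ParameterSet.from_array(p.as_array()).to_dict() == p.to_dict()

    def test_nine_state_variables(self):
        assert len(STATE_VARS) == 9
        assert ClockState().as_array().shape == (9,)


class TestGenotypes:
    @pytest.mark.parametrize("name,gene,scale", [
        ("prr9", "P97", 0.5),
        ("cca1", "CL", 0.5),
        ("cca1lhy", "CL", 0.1),
        ("prr5toc1", "P51", 0.1),
        ("elf3-12", "EL", 0.5),
        ("elf4lux", "EL", 0.0),
    ])
    def test_preset_conventions(self, name, gene, scale):
        assert GENOTYPE_PRESETS[name].tx_scale[gene] == scale

    def test_apply_genotype_scales_v_and_q(self):
        p = ParameterSet()
        p2 = apply_genotype(p, GENOTYPE_PRESETS["prr9"])
        assert p2.v_p97 == pytest.approx(0.5 * p.v_p97)
        assert p2.q_p97 == pytest.approx(0.5 * p.q_p97)
        assert p2.v_cl == p.v_cl

    def test_wildtype_is_identity(self):
        p = ParameterSet()
        assert apply_genotype(p, GENOTYPE_PRESETS["wildtype"]).to_dict() == p.to_dict()

    def test_ox_replaces_transcription_with_constant(self):
        p = ParameterSet()
        ox = GENOTYPE_PRESETS["cca1-ox"]
        assert ox.ox["CL"] >= 5.0 * p.v_cl
        rhs = make_rhs(p, ox)
        # CL transcription is the same constant whatever the repressor levels
        lo = rhs(0.0, np.array([0, 0, 0, 0, 0, 0, 0, 0, 0.0]), 0)[0]
        hi = rhs(0.0, np.array([0, 0, 0, 5.0, 0, 5.0, 0, 0, 0.0]), 0)[0]
        assert lo == pytest.approx(hi)
        assert lo == pytest.approx(ox.ox["CL"])

    def test_unknown_gene_rejected(self):
        with pytest.raises(KeyError):
            Genotype("bad", {"XYZ": 0.5})
        with pytest.raises(KeyError):
            get_genotype("nonexistent-line")


class TestClockRHS:
    def test_no_mrna_means_pure_protein_decay(self):
        p = ParameterSet()
        state = np.zeros(9)
        state[1] = 2.0  # cl_p only
        d = clock_rhs(0.0, state, p, 0)
        assert d[1] == pytest.approx(-p.dp_cl * 2.0)

    def test_p_decays_toward_zero_in_light(self):
        p = ParameterSet()
        state = np.zeros(9)
        state[8] = 0.8
        d = clock_rhs(0.0, state, p, 1)
        assert d[8] == pytest.approx(-p.d_p * 0.8)

    def test_p_saturates_at_one_in_dark(self):
        p = ParameterSet()
        state = np.zeros(9)
        state[8] = 1.0
        assert clock_rhs(0.0, state, p, 0)[8] == pytest.approx(0.0)

    def test_p51_null_mrna_only_decays(self):
        p = ParameterSet()
        null = Genotype("p51null", {"P51": 0.0})
        rhs = make_rhs(p, null)
        rng = np.random.default_rng(7)
        for _ in range(10):
            y = rng.uniform(0, 3, size=9)
            y[8] = min(y[8], 1.0)
            d = rhs(0.0, y, rng.integers(0, 2))
            assert d[4] <= 1e-10  # p51_m can only fall

    def test_autonomous_given_fixed_light(self):
        p = ParameterSet()
        rhs = make_rhs(p)
        y = np.linspace(0.1, 0.9, 9)
        for L in (0, 1):
            assert np.allclose(rhs(0.0, y, L), rhs(123.4, y, L))

    def test_input_validation(self):
        p = ParameterSet()
        with pytest.raises(ValueError):
            clock_rhs(0.0, -np.ones(9), p, 0)
        with pytest.raises(ValueError):
            clock_rhs(0.0, np.ones(9), p, 2)


class TestTopologyAudit:
    """Perturbing each regulator up from a reference state must move the
    target's transcription term with the sign of the network diagram."""

    REF = np.array([0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5])

    # (regulator state index, target rhs index, sign of d(tx)/d(regulator))
    EDGES = [
        (3, 0, -1),  # P97 protein represses CL
        (5, 0, -1),  # P51 protein represses CL
        (1, 2, +1),  # CL protein activates P97
        (5, 2, -1),  # P51 represses P97
        (7, 2, -1),  # EC represses P97
        (1, 4, -1),  # CL represses P51
        (5, 4, -1),  # P51 represses itself
        (1, 6, -1),  # CL represses EL
        (5, 6, -1),  # P51 represses EL
        (7, 6, -1),  # EC represses EL
    ]

    @pytest.mark.parametrize("reg,target,sign", EDGES)
    def test_edge_sign(self, ref_params, reg, target, sign):
        rhs = make_rhs(ref_params)
        base = np.array(rhs(0.0, self.REF, 0))
        bumped = self.REF.copy()
        bumped[reg] += 0.2
        delta = rhs(0.0, bumped, 0)[target] - base[target]
        assert np.sign(delta) == sign

    @pytest.mark.parametrize("target", [0, 2])
    def test_p_boosts_morning_genes_only_in_light(self, ref_params, target):
        rhs = make_rhs(ref_params)
        bumped = self.REF.copy()
        bumped[8] += 0.3
        for L, expected in ((1, 1), (0, 0)):
            delta = rhs(0.0, bumped, L)[target] - rhs(0.0, self.REF, L)[target]
            assert np.sign(delta) == expected
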