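"""Bioenergetics and mortality: frozen examples, invariants, property tests."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from boldfish import model_core as mc
from boldfish.params import FishingScenario, ModelParams

PARAMS = ModelParams()


class TestLengthWeight:
    @pytest.mark.parametrize("L, W", [(1.0, 0.95), (10.0, 950.0)])
    def test_cubic_map(self, L, W):
        assert mc.weight_from_length(L, PARAMS) == pytest.approx(W)

    @pytest.mark.parametrize("L", [5.0, 37.2, 120.0])
    def test_round_trip(self, L):
        W = mc.weight_from_length(L, PARAMS)
        assert mc.length_from_weight(W, PARAMS) == pytest.approx(L, rel=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            mc.weight_from_length(0.0, PARAMS)
        with pytest.raises(ValueError):
            mc.length_from_weight(-1.0, PARAMS)


class TestIntake:
    @pytest.mark.parametrize("phi, E, h", [(1.4, 6.0, 8.4), (0.0, 3.0, 0.0), (2.0, 2.5, 5.0)])
    def test_food_intake_product(self, phi, E, h):
        assert mc.food_intake(phi, E) == pytest.approx(h)

    def test_negative_food_yields_nothing(self):
        assert mc.food_intake(2.0, -1.0) == 0.0

    def test_net_intake_examples(self):
        # high-precision evaluations of R = h·W^b − b0·(W+G)^a
        assert mc.net_intake(8.4, 1000.0, 0.0, PARAMS) == pytest.approx(
            8.1 * 1000.0**0.7, rel=1e-12)  # ≈ 1019.73
        assert mc.net_intake(0.0, 1000.0, 0.0, PARAMS) == pytest.approx(
            -0.3 * 1000.0**0.7, rel=1e-12)  # ≈ −37.77, starvation

    @given(G=st.floats(1.0, 500.0))
    def test_gonads_raise_metabolic_cost(self, G):
        assert mc.net_intake(8.4, 1000.0, G, PARAMS) < mc.net_intake(8.4, 1000.0, 0.0, PARAMS)


class TestGSI:
    @pytest.mark.parametrize("W, G, Q", [(100.0, 0.0, 0.0), (100.0, 25.0, 0.2),
                                         (50.0, 50.0, 0.5)])
    def test_values(self, W, G, Q):
        assert mc.gsi(W, G) == pytest.approx(Q)


class TestFishingMortality:
    @pytest.mark.parametrize("phi, gamma, F", [
        (0.7, 0.0, 0.1),      # unselective: behavior-independent
        (1.4, 0.5, 0.1),      # reference strategy: components collapse to F0
        (1.4, -0.8, 0.1),
        (2.8, 0.3, 0.13),     # direct substitution
        (7.0, -0.3, 0.0),     # raw value −0.02 floored at zero
    ])
    def test_examples(self, phi, gamma, F):
        sc = FishingScenario(F0=0.1, gamma=gamma)
        assert mc.fishing_mortality(phi, sc, PARAMS) == pytest.approx(F)

    @given(gamma=st.floats(-1.0, 1.0), F0=st.floats(0.0, 1.0))
    def test_reference_phi_fixed_point(self, gamma, F0):
        sc = FishingScenario(F0=F0, gamma=gamma)
        got = mc.fishing_mortality(PARAMS.phi_ref, sc, PARAMS)
        assert got == pytest.approx(F0, abs=1e-12)

    def test_monotone_in_phi_by_gamma_sign(self):
        phis = np.linspace(0, 4, 50)
        up = mc.fishing_mortality(phis, FishingScenario(F0=0.1, gamma=0.4), PARAMS)
        down = mc.fishing_mortality(phis, FishingScenario(F0=0.1, gamma=-0.4), PARAMS)
        flat = mc.fishing_mortality(phis, FishingScenario(F0=0.1, gamma=0.0), PARAMS)
        assert np.all(np.diff(up) > 0)
        assert np.all(np.diff(np.maximum(down, 0)) <= 0)
        assert np.allclose(flat, 0.1)

    def test_clamp_counter(self):
        counter = [0]
        mc.fishing_mortality(np.array([7.0, 1.0]), FishingScenario(F0=0.1, gamma=-0.3),
                             PARAMS, clamp_counter=counter)
        assert counter[0] == 1


class TestNaturalMortalityComponents:
    def test_size_mortality_values(self):
        assert mc.size_mortality(1.0, PARAMS) == pytest.approx(1.2)
        assert mc.size_mortality(30.0, PARAMS) == pytest.approx(1.2 * 30.0**-0.75, rel=1e-12)

    @given(L=st.floats(1.0, 100.0), dL=st.floats(0.5, 30.0))
    def test_size_mortality_declines_with_length(self, L, dL):
        assert mc.size_mortality(L + dL, PARAMS) < mc.size_mortality(L, PARAMS)

    def test_reproduction_mortality_anchors(self):
        m_size = mc.size_mortality(30.0, PARAMS)
        assert mc.reproduction_mortality(0.2, 30.0, PARAMS) == pytest.approx(m_size)
        assert mc.reproduction_mortality(0.0, 30.0, PARAMS) == 0.0
        assert mc.reproduction_mortality(0.4, 30.0, PARAMS) == pytest.approx(4 * m_size)

    def test_foraging_mortality_anchors(self):
        m_size = mc.size_mortality(30.0, PARAMS)
        assert mc.foraging_mortality(0.0, 30.0, PARAMS) == 0.0
        assert mc.foraging_mortality(PARAMS.phi_ref, 30.0, PARAMS) == pytest.approx(m_size)
        assert mc.foraging_mortality(2 * PARAMS.phi_ref, 30.0, PARAMS) == pytest.approx(4 * m_size)

    @given(phi=st.floats(0.1, 4.0), q=st.floats(0.0, 0.8))
    def test_monotone_in_behavior_and_investment(self, phi, q):
        assert mc.foraging_mortality(phi + 0.1, 30.0, PARAMS) > mc.foraging_mortality(phi, 30.0, PARAMS)
        assert mc.reproduction_mortality(q + 0.1, 30.0, PARAMS) >= mc.reproduction_mortality(q, 30.0, PARAMS)


class TestTotalMortality:
    def test_component_sum_example(self):
        state = mc.BodyState.from_length(age=5, L=30.0, params=PARAMS)
        out = mc.total_mortality(state, PARAMS.phi_ref,
                                 FishingScenario(F0=0.1, gamma=0.0), PARAMS)
        m_size = 1.2 * 30.0**-0.75
        assert out.Z_total == pytest.approx(0.05 + m_size + 0.0 + m_size + 0.1)

    def test_no_fishing_no_foraging(self):
        state = mc.BodyState.from_length(age=3, L=20.0, params=PARAMS)
        out = mc.total_mortality(state, 0.0, FishingScenario.unfished(), PARAMS)
        assert out.Z_total == pytest.approx(PARAMS.M_fixed + mc.size_mortality(20.0, PARAMS))

    @given(L=st.floats(2.0, 120.0), phi=st.floats(0.0, 4.0), g=st.floats(0.0, 400.0))
    def test_sum_is_exact(self, L, phi, g):
        state = mc.BodyState.from_length(age=2, L=L, params=PARAMS, G=g)
        out = mc.total_mortality(state, phi, FishingScenario(F0=0.2, gamma=0.3), PARAMS)
        assert out.Z_total == out.M_fixed + out.M_size + out.M_reproduction + out.M_foraging + out.F
        assert min(out.M_fixed, out.M_size, out.M_reproduction, out.M_foraging, out.F) >= 0

    def test_dimensional_sanity_30cm_fish(self):
        # a 30 cm fish foraging at the reference level: natural Z in (0.1, 1)
        state = mc.BodyState.from_length(age=5, L=30.0, params=PARAMS)
        out = mc.total_mortality(state, PARAMS.phi_ref, FishingScenario.unfished(), PARAMS)
        assert 0.1 < out.natural < 1.0


class TestStepWithinYear:
    def test_single_substep_closed_form(self):
        # one Euler step, no food, no foraging: W' = W − b0·W^a and
        # survival = exp(−(M_fixed + M_size)) without fishing
        p = ModelParams(n_substeps=1)
        W = float(mc.weight_from_length(30.0, p))
        out = mc.step_within_year(W, 0.0, 30.0, 0.0, 0.0, 0.0,
                                  FishingScenario.unfished(), p)
        assert float(out.W_end) == pytest.approx(W - p.b0 * W**p.a, rel=1e-12)
        expected_surv = np.exp(-(p.M_fixed + 1.2 * 30.0**-0.75))
        assert float(out.survival) == pytest.approx(expected_surv, rel=1e-12)
        assert float(out.G_spawn) == 0.0

    def test_no_allocation_grows_soma_only(self):
        out = mc.step_within_year(500.0, 0.0, 8.0, 1.4, 0.0, 6.0,
                                  FishingScenario.unfished(), PARAMS)
        assert float(out.G_spawn) == 0.0
        assert float(out.W_end) > 500.0

    def test_full_allocation_never_grows_soma(self):
        out = mc.step_within_year(500.0, 0.0, 8.0, 1.4, 1.0, 6.0,
                                  FishingScenario.unfished(), PARAMS)
        assert float(out.W_end) <= 500.0
        assert float(out.G_spawn) > 0.0

    @given(phi=st.floats(0.0, 4.0), alpha=st.floats(0.0, 1.0), E=st.floats(0.0, 13.0),
           L=st.floats(2.0, 120.0))
    def test_survival_is_a_probability(self, phi, alpha, E, L):
        W = float(mc.weight_from_length(L, PARAMS))
        out = mc.step_within_year(W, 0.0, L, phi, alpha, E,
                                  FishingScenario(F0=0.3, gamma=0.2), PARAMS)
        assert 0.0 <= float(out.survival) <= 1.0
        assert float(out.natural_survival) <= 1.0
        assert float(out.L_end) >= L  # length is irreversible

    def test_starvation_flags_dead(self):
        # a tiny soma carrying a huge gonad load cannot pay its metabolism
        out = mc.step_within_year(1.0, 100.0, 1.02, 0.0, 0.0, 0.0,
                                  FishingScenario.unfished(), PARAMS)
        assert bool(out.starved)
        assert float(out.survival) == 0.0
        assert float(out.G_spawn) == 0.0

    def test_component_integrals_sum_to_natural_rate(self):
        out = mc.step_within_year(800.0, 0.0, 9.5, 2.0, 0.5, 7.0,
                                  FishingScenario(F0=0.1, gamma=-0.2), PARAMS)
        total = out.M_fixed + out.M_size + out.M_reproduction + out.M_foraging
        assert float(out.natural_mortality) == pytest.approx(float(total), rel=1e-14)
        assert float(out.natural_survival) == pytest.approx(
            np.exp(-float(total)), rel=1e-12)
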