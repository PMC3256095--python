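"""Cohort recursion: effect decay, mortality embedding, rewards, conservation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from t2dprev.engine import (
    blend_transition,
    blend_weight,
    embed_mortality,
    intervention_cost_stream,
    microsimulate_cohort,
    simulate_cohort,
)
from t2dprev.mortality import MortalityModel
from t2dprev.parameters import (
    ArmParameters,
    EffectProfile,
    ScenarioConfig,
    TransitionMatrix,
    default_bundle,
)


class TestEffectDecay:
    def test_full_effect_in_year_one(self, bundle):
        tm = blend_transition(1, bundle.arms, bundle.effect, "intervention")
        assert tm.p_igt_t2d == pytest.approx(0.03)

    def test_no_effect_from_horizon_onward(self, bundle):
        for year in (7, 8, 40):
            tm = blend_transition(year, bundle.arms, bundle.effect, "intervention")
            assert tm.p_igt_t2d == pytest.approx(0.06)

    def test_linear_midpoint(self, bundle):
        # year 4 of a 7-year horizon: weight (7-4)/6 = 0.5
        tm = blend_transition(4, bundle.arms, bundle.effect, "intervention")
        assert tm.p_igt_t2d == pytest.approx(0.045)
        assert np.allclose(tm.as_array().sum(axis=1), 1.0, atol=1e-15)

    def test_control_arm_never_blended(self, bundle):
        for year in (1, 4, 10):
            tm = blend_transition(year, bundle.arms, bundle.effect, "control")
            assert tm.p_igt_t2d == pytest.approx(0.06)

    def test_step_decay(self, bundle):
        eff = EffectProfile(effect_horizon=7, decay="none")
        assert blend_weight(6, eff) == 1.0
        assert blend_weight(7, eff) == 0.0

    def test_linear_requires_two_year_horizon(self):
        with pytest.raises(ValueError):
            blend_weight(1, EffectProfile(effect_horizon=1, decay="linear"))


class TestEmbedMortality:
    def test_zero_mortality_keeps_alive_matrix(self, bundle, zero_mortality):
        full = embed_mortality(bundle.arms.control, zero_mortality, 40, "male")
        assert np.allclose(full[:3, :3], bundle.arms.control.as_array())
        assert np.allclose(full[:3, 3], 0.0)

    def test_ngt_row_scaling(self, bundle):
        # intervention NGT row with mr = 0.1: (0.848*0.9, 0.152*0.9, 0, 0.1)
        m = MortalityModel.uniform(0.1)
        full = embed_mortality(bundle.arms.intervention, m, 40, "male")
        assert np.allclose(full[0], [0.848 * 0.9, 0.152 * 0.9, 0.0, 0.1])

    def test_certain_death_in_t2d(self, bundle):
        m = MortalityModel.uniform(0.0, t2d2d=1.0)
        full = embed_mortality(bundle.arms.control, m, 40, "male")
        assert np.allclose(full[2], [0, 0, 0, 1])

    def test_dead_row_absorbing_and_rows_stochastic(self, bundle):
        m = MortalityModel.uniform(0.02, t2d2d=0.01)
        full = embed_mortality(bundle.arms.control, m, 70, "female")
        assert np.allclose(full[3], [0, 0, 0, 1])
        assert np.allclose(full.sum(axis=1), 1.0, atol=1e-12)


class TestCostStream:
    @pytest.mark.parametrize("year,expected", [(1, 390.43), (2, 189.93), (3, 189.93),
                                               (5, 189.93), (6, 0.0), (30, 0.0)])
    def test_five_year_participation(self, bundle, year, expected):
        assert intervention_cost_stream(year, bundle.intervention_cost, bundle.effect) == expected

    def test_zero_participation_years(self, bundle):
        eff = EffectProfile(participation_years=0)
        assert intervention_cost_stream(1, bundle.intervention_cost, eff) == 0.0


class TestCohortRecursion:
    def test_constant_reward_undiscounted(self, bundle, zero_mortality):
        """Identity transitions, no deaths, r=0: QALYs = u * n_cycles."""
        b = bundle.copy()
        b.arms = ArmParameters(
            control=TransitionMatrix(0, 0, 0, 0), intervention=TransitionMatrix(0, 0, 0, 0)
        )
        b.discount.rate_costs = b.discount.rate_qalys = 0.0
        sc = ScenarioConfig("male", 30, (1.0, 0.0, 0.0, 0.0), max_age=39)  # 10 cycles
        res = simulate_cohort(sc, "control", b, zero_mortality)
        assert res.discounted_qalys == pytest.approx(10 * 0.772)
        assert res.undiscounted_qalys == pytest.approx(res.discounted_qalys)

    def test_annuity_closed_form(self, bundle, zero_mortality):
        """Discounted QALYs of an immortal constant-utility cohort equal the
        geometric-series annuity u * sum_{t=0}^{T-1} 1.03^-t."""
        b = bundle.copy()
        b.arms = ArmParameters(
            control=TransitionMatrix(0, 0, 0, 0), intervention=TransitionMatrix(0, 0, 0, 0)
        )
        sc = ScenarioConfig("male", 30, (1.0, 0.0, 0.0, 0.0), max_age=59)  # T = 30
        res = simulate_cohort(sc, "control", b, zero_mortality)
        annuity = sum(1.03 ** (-t) for t in range(30))
        assert res.discounted_qalys == pytest.approx(0.772 * annuity, rel=1e-12)

    def test_single_control_cycle_occupancy(self, bundle, zero_mortality):
        """One control cycle from (0.84, 0.16): NGT share = 0.84*0.837 + 0.16*0.162."""
        sc = ScenarioConfig("male", 30, (0.84, 0.16, 0.0, 0.0), max_age=31)
        res = simulate_cohort(sc, "control", bundle, zero_mortality)
        assert res.occupancy(1)[0] == pytest.approx(0.72900, abs=1e-10)

    def test_occupancy_conservation_and_dead_monotonicity(self, paper_base):
        for sc in paper_base.scenarios:
            for arm in ("control", "intervention"):
                res = simulate_cohort(sc, arm, paper_base.bundle, paper_base.mortality)
                occ = res.trace[["share_ngt", "share_igt", "share_t2d", "share_dead"]]
                assert np.allclose(occ.sum(axis=1), 1.0, atol=1e-12)
                assert (occ >= -1e-15).all().all()
                dead = res.trace["share_dead"].to_numpy()
                assert (np.diff(dead) >= -1e-15).all()

    def test_trace_starts_at_initial_distribution(self, paper_base):
        sc = paper_base.scenarios[0]
        res = simulate_cohort(sc, "control", paper_base.bundle, paper_base.mortality)
        assert np.allclose(res.occupancy(0), sc.initial_distribution)
        assert len(res.trace) == sc.n_cycles

    def test_discounted_below_undiscounted(self, paper_base):
        sc = paper_base.scenarios[0]
        res = simulate_cohort(sc, "intervention", paper_base.bundle, paper_base.mortality)
        assert res.discounted_cost < res.undiscounted_cost
        assert res.discounted_qalys < res.undiscounted_qalys

    def test_equal_utilities_make_arms_equal_qalys(self, bundle, zero_mortality):
        """Without mortality and with state-independent utility, the effect
        moves people between states but cannot change QALYs."""
        b = bundle.copy()
        for sex in ("male", "female"):
            u = b.utilities[sex]
            u.u_ngt = u.u_igt = u.u_t2d = 0.75
        sc = b.scenario("female", 50)
        q_ctrl = simulate_cohort(sc, "control", b, zero_mortality).discounted_qalys
        q_int = simulate_cohort(sc, "intervention", b, zero_mortality).discounted_qalys
        assert q_int == pytest.approx(q_ctrl, rel=1e-12)

    @given(rate=st.floats(0.001, 0.15))
    @settings(max_examples=20, deadline=None)
    def test_discount_monotonicity(self, rate):
        """Discounted QALYs strictly decrease as the discount rate rises."""
        b = default_bundle()
        m = MortalityModel.uniform(0.01)
        sc = b.scenario("male", 50)
        b.discount.rate_qalys = rate
        lo = simulate_cohort(sc, "control", b, m).discounted_qalys
        b.discount.rate_qalys = rate + 0.01
        hi = simulate_cohort(sc, "control", b, m).discounted_qalys
        assert hi < lo


class TestMicrosimOracle:
    def test_cohort_engine_matches_microsimulation(self, paper_base):
        """The cohort recursion is the exact expectation of the individual-level
        model; a seeded 50,000-person microsimulation must agree within
        3 Monte-Carlo standard errors on discounted cost and QALYs."""
        bundle, mortality = paper_base.bundle, paper_base.mortality
        sc = bundle.scenario("female", 70)
        rng = np.random.default_rng(20240917)
        for arm in ("control", "intervention"):
            cohort = simulate_cohort(sc, arm, bundle, mortality)
            micro = microsimulate_cohort(sc, arm, bundle, mortality,
                                         n_individuals=50_000, rng=rng)
            assert abs(micro.discounted_cost - cohort.discounted_cost) < 3 * micro.se_cost
            assert abs(micro.discounted_qalys - cohort.discounted_qalys) < 3 * micro.se_qalys
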