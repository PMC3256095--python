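"""Parameter containers, moment fitting, defaults and config round-trips."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from t2dprev.parameters import (
    ConfigError,
    DistributionSpec,
    TransitionMatrix,
    beta_from_moments,
    bundle_from_dict,
    bundle_to_dict,
    default_bundle,
    default_intervention_breakdown,
    derive_uigt,
    gamma_unit_shape,
    load_config,
    save_config,
)


class TestMomentFitting:
    def test_beta_closed_form(self):
        # mean 0.5, se 0.1: nu = 0.25/0.01 - 1 = 24 -> alpha = beta = 12
        alpha, beta = beta_from_moments(0.5, 0.1)
        assert alpha == pytest.approx(12.0)
        assert beta == pytest.approx(12.0)

    def test_beta_table_pair(self):
        # strict moments on (0.163, 0.037): nu = 98.657..., alpha ~ 16.08
        alpha, beta = beta_from_moments(0.163, 0.037)
        assert alpha == pytest.approx(16.081, abs=5e-3)
        assert beta == pytest.approx(82.576, abs=5e-3)

    def test_beta_sampling_moments_cross_check(self):
        # independent stochastic oracle: 1e6 draws reproduce mean and SD
        alpha, beta = beta_from_moments(0.5, 0.1)
        rng = np.random.default_rng(12345)
        draws = rng.beta(alpha, beta, size=1_000_000)
        assert draws.mean() == pytest.approx(0.5, abs=5e-4)
        assert draws.std() == pytest.approx(0.1, abs=5e-4)

    @pytest.mark.parametrize("mean,se", [(0.5, 0.6), (0.0, 0.1), (1.0, 0.1), (0.5, 0.0)])
    def test_beta_infeasible(self, mean, se):
        with pytest.raises(ValueError):
            beta_from_moments(mean, se)

    @given(
        mean=st.floats(0.01, 0.99),
        frac=st.floats(0.05, 0.95),
    )
    @settings(max_examples=200, deadline=None)
    def test_beta_round_trip_property(self, mean, frac):
        """The fitted Beta's analytic mean and SD equal the inputs to 1e-12."""
        se = frac * math.sqrt(mean * (1 - mean))  # always feasible
        alpha, beta = beta_from_moments(mean, se)
        total = alpha + beta
        assert alpha / total == pytest.approx(mean, abs=1e-12)
        sd = math.sqrt(alpha * beta / (total**2 * (total + 1)))
        assert sd == pytest.approx(se, abs=1e-12)

    @pytest.mark.parametrize("mean", [1744.21, 230.03])
    def test_gamma_unit_shape(self, mean):
        shape, scale = gamma_unit_shape(mean)
        assert shape == pytest.approx(1.0)
        assert scale == pytest.approx(mean)

    def test_gamma_rejects_nonpositive_mean(self):
        with pytest.raises(ValueError):
            gamma_unit_shape(0.0)

    @pytest.mark.parametrize(
        "u_ngt,expected", [(0.772, 0.764), (0.747, 0.740), (1.0, 0.990)]
    )
    def test_derive_uigt(self, u_ngt, expected):
        assert derive_uigt(u_ngt) == expected


class TestTransitionMatrix:
    def test_residuals_and_structural_zeros(self):
        tm = TransitionMatrix(0.163, 0.162, 0.06, 0.005)
        arr = tm.as_array()
        assert arr[0, 2] == 0.0 and arr[2, 0] == 0.0
        assert np.allclose(arr.sum(axis=1), 1.0, atol=1e-15)
        assert tm.p_igt_igt == pytest.approx(1 - 0.162 - 0.06)

    def test_out_of_range_probability_is_flagged_by_name(self):
        problems = TransitionMatrix(0.163, 0.162, 1.2, 0.005).validate()
        assert any("p_igt_t2d" in p for p in problems)


class TestDefaults:
    def test_transition_matrix_cells(self, bundle):
        c, i = bundle.arms.control, bundle.arms.intervention
        assert (c.p_ngt_igt, c.p_igt_ngt, c.p_igt_t2d, c.p_t2d_igt) == (
            0.163, 0.162, 0.06, 0.005)
        assert (i.p_ngt_igt, i.p_igt_ngt, i.p_igt_t2d, i.p_t2d_igt) == (
            0.152, 0.177, 0.03, 0.005)
        assert i.p_igt_t2d <= c.p_igt_t2d

    def test_costs_and_utilities(self, bundle):
        assert (bundle.costs.c_ngt, bundle.costs.c_igt, bundle.costs.c_t2d) == (
            1744.21, 2696.48, 5861.92)
        m, f = bundle.utilities["male"], bundle.utilities["female"]
        assert (m.u_ngt, m.u_igt, m.u_t2d) == (0.772, 0.764, 0.724)
        assert (f.u_ngt, f.u_igt, f.u_t2d) == (0.747, 0.740, 0.701)
        assert m.u_igt == derive_uigt(m.u_ngt)
        assert f.u_igt == derive_uigt(f.u_ngt)

    def test_discount_and_effect(self, bundle):
        assert bundle.discount.rate_costs == bundle.discount.rate_qalys == 0.03
        assert bundle.effect.effect_horizon == 7
        assert bundle.effect.participation_years == 5
        assert bundle.initial_distribution == (0.84, 0.16, 0.0, 0.0)

    def test_distribution_means_match_analytics(self, bundle):
        for name, spec in bundle.distributions.items():
            assert spec.analytic_mean() == pytest.approx(spec.mean, abs=1e-9), name
            assert spec.analytic_sd() == pytest.approx(spec.se, abs=1e-9), name


class TestInterventionCostBuildup:
    """The itemised programme cost reproduces every printed summary row."""

    def test_summary_rows_to_the_cent(self):
        b = default_intervention_breakdown()
        assert b.screening_total() == 113.32
        assert b.course_total() == 109.16
        assert b.course_total_with_transport() == 133.16
        assert b.followup_total() == 183.93
        assert b.year1_followup_total() == 143.95
        assert b.followup_year_total() == 189.93
        assert b.year1_total() == 390.43
        assert b.annualised(5) == 230.03

    def test_schedule_defaults_derive_from_breakdown(self, bundle):
        assert bundle.intervention_cost.year1_total == 390.43
        assert bundle.intervention_cost.followup_total == 189.93


class TestConfigIO:
    def test_empty_config_gives_full_default_bundle(self, tmp_path, bundle):
        p = tmp_path / "empty.yaml"
        p.write_text("")
        loaded = load_config(p)
        assert bundle_to_dict(loaded) == bundle_to_dict(bundle)

    def test_round_trip_identity(self, tmp_path, bundle):
        bundle.discount.rate_costs = 0.05
        bundle.effect.effect_horizon = 10
        p = tmp_path / "cfg.yaml"
        save_config(bundle, p)
        again = load_config(p)
        assert bundle_to_dict(again) == bundle_to_dict(bundle)

    def test_invalid_value_names_every_field(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text(
            "transitions:\n  control: {igt2t2d: 1.2}\ncosts: {cNGT: -5}\n"
        )
        with pytest.raises(ConfigError) as exc:
            load_config(p)
        msg = str(exc.value)
        assert "p_igt_t2d" in msg and "cNGT" in msg

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            load_config("does_not_exist.yaml")

    def test_partial_override_keeps_other_defaults(self):
        b = bundle_from_dict({"discount": {"costs": 0.0}})
        assert b.discount.rate_costs == 0.0
        assert b.discount.rate_qalys == 0.03
        assert b.costs.c_t2d == 5861.92

    def test_distribution_override_forces_printed_shapes(self):
        b = bundle_from_dict(
            {"distributions": {"ngt2igt": {"family": "beta", "mean": 0.163,
                                           "se": 0.037, "alpha": 16.28, "beta": 83.72}}}
        )
        spec = b.distributions["ngt2igt"]
        assert (spec.alpha, spec.beta_param) == (16.28, 83.72)


def test_degenerate_spec_is_point_mass():
    spec = DistributionSpec("beta", 0.3, 0.0)
    rng = np.random.default_rng(0)
    assert spec.degenerate
    assert spec.sample(rng) == 0.3
    assert spec.analytic_sd() == 0.0
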