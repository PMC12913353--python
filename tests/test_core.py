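"""Closed-form likelihoods, causal posterior and estimates against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sifibci as sb
from sifibci.params import ModelParams, SensorySample

from _oracles import (
    fused_estimate_arith,
    pair_likelihood_c1_quad,
    pair_likelihood_c2_quad,
    posterior_c1_quad,
    segregated_estimate_arith,
)


def make_params(**kw) -> ModelParams:
    base = dict(sigma_V=0.63, sigma_A=0.33, p_common=0.62, mu_p=1.43, sigma_p=1.33)
    base.update(kw)
    return ModelParams(**base)


class TestNumerosityLikelihoods:
    def test_coincident_cues_favor_common_cause(self):
        p = make_params(sigma_V=0.5, sigma_A=0.5, sigma_p=0.5, mu_p=1.0)
        L1, L2 = sb.numerosity_likelihoods(1.0, 1.0, p)
        assert L1 > L2 > 0

    def test_matches_quadrature_oracle_on_reference_point(self):
        p = make_params()
        L1, L2 = sb.numerosity_likelihoods(1.0, 2.0, p)
        assert L1 == pytest.approx(
            pair_likelihood_c1_quad(1.0, 2.0, p.sigma_V, p.sigma_A, p.mu_p, p.sigma_p), abs=1e-8
        )
        assert L2 == pytest.approx(
            pair_likelihood_c2_quad(1.0, 2.0, p.sigma_V, p.sigma_A, p.mu_p, p.sigma_p), abs=1e-8
        )

    def test_flat_prior_limit_depends_only_on_cue_conflict(self):
        # with an (effectively) flat prior the common-cause likelihood retains
        # its dependence on x_V - x_A but the absolute level washes out
        p = make_params(sigma_p=1e6)
        L1, _ = sb.numerosity_likelihoods(1.0, 2.0, p)
        assert L1 == pytest.approx(
            pair_likelihood_c1_quad(1.0, 2.0, p.sigma_V, p.sigma_A, p.mu_p, p.sigma_p), abs=1e-8
        )

    def test_non_finite_evidence_rejected(self):
        p = make_params()
        with pytest.raises(ValueError):
            sb.numerosity_likelihoods(np.nan, 1.0, p)
        with pytest.raises(ValueError):
            sb.numerosity_likelihoods(1.0, np.inf, p)


class TestTemporalLikelihoods:
    def test_coincident_onsets_favor_common_cause(self):
        p = make_params()
        L1, L2 = sb.temporal_likelihoods(p.mu_tp, p.mu_tp, p)
        assert L1 > L2 > 0

    def test_matches_quadrature_oracle(self):
        p = make_params()
        L1, L2 = sb.temporal_likelihoods(0.0, 500.0, p)
        assert L1 == pytest.approx(
            pair_likelihood_c1_quad(0.0, 500.0, p.sigma_Vt, p.sigma_At, p.mu_tp, p.sigma_tp),
            abs=1e-8,
        )
        assert L2 == pytest.approx(
            pair_likelihood_c2_quad(0.0, 500.0, p.sigma_Vt, p.sigma_At, p.mu_tp, p.sigma_tp),
            abs=1e-8,
        )

    def test_symmetric_under_modality_swap(self):
        p = make_params()
        swapped = make_params(sigma_Vt=p.sigma_At, sigma_At=p.sigma_Vt)
        L1, _ = sb.temporal_likelihoods(0.0, 300.0, p)
        L1s, _ = sb.temporal_likelihoods(300.0, 0.0, swapped)
        assert L1 == pytest.approx(L1s, rel=1e-12)


@given(
    x_V=st.floats(-2, 4),
    x_A=st.floats(-2, 4),
    sigma_V=st.floats(0.1, 3),
    sigma_A=st.floats(0.1, 3),
    mu_p=st.floats(0, 3),
    sigma_p=st.floats(0.2, 8),
)
@settings(max_examples=40, deadline=None, derandomize=True)
def test_closed_form_agrees_with_quadrature_everywhere(x_V, x_A, sigma_V, sigma_A, mu_p, sigma_p):
    """Property: the analytic Gaussian marginals equal the defining integrals."""
    p = make_params(sigma_V=sigma_V, sigma_A=sigma_A, mu_p=mu_p, sigma_p=sigma_p)
    L1, L2 = sb.numerosity_likelihoods(x_V, x_A, p)
    assert L1 >= 0 and L2 >= 0
    assert abs(L1 - pair_likelihood_c1_quad(x_V, x_A, sigma_V, sigma_A, mu_p, sigma_p)) < 1e-8
    assert abs(L2 - pair_likelihood_c2_quad(x_V, x_A, sigma_V, sigma_A, mu_p, sigma_p)) < 1e-8


class TestPosteriorCommonCause:
    def test_prior_extremes_pin_the_posterior(self):
        s = SensorySample(x_V=0.4, x_A=2.2, t_V=0.0, t_A=400.0)
        assert sb.posterior_common_cause(s, make_params(p_common=1.0)).p_c1 == 1.0
        assert sb.posterior_common_cause(s, make_params(p_common=0.0)).p_c1 == 0.0

    def test_matches_composed_quadrature_oracle(self):
        p = make_params()
        s = SensorySample(x_V=1.0, x_A=2.0, t_V=0.0, t_A=0.0)
        post = sb.posterior_common_cause(s, p)
        assert post.p_c1 == pytest.approx(posterior_c1_quad(1.0, 2.0, 0.0, 0.0, p), abs=1e-8)
        assert 0.0 <= post.p_c1 <= 1.0
        assert min(post.L_num_c1, post.L_num_c2, post.L_t_c1, post.L_t_c2) >= 0

    def test_unisensory_sample_rejected(self):
        s = SensorySample(x_A=1.0, t_A=0.0, has_V=False)
        with pytest.raises(ValueError):
            sb.posterior_common_cause(s, make_params())

    @pytest.mark.parametrize("deltas", [(0.0, 0.5, 1.0, 2.0)])
    def test_monotone_decreasing_in_numerosity_conflict(self, deltas):
        p = make_params()
        vals = [
            sb.posterior_common_cause(
                SensorySample(x_V=1.0, x_A=1.0 + d, t_V=0.0, t_A=0.0), p
            ).p_c1
            for d in deltas
        ]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_monotone_decreasing_in_temporal_conflict(self):
        p = make_params()
        vals = [
            sb.posterior_common_cause(
                SensorySample(x_V=1.0, x_A=1.0, t_V=0.0, t_A=float(d)), p
            ).p_c1
            for d in (0, 150, 300, 500)
        ]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_disabling_time_equals_uninformative_temporal_limit(self):
        p = make_params()
        s = SensorySample(x_V=1.0, x_A=2.0, t_V=0.0, t_A=300.0)
        off = sb.posterior_common_cause(s, p, use_temporal=False).p_c1
        # with enormous onset noise the temporal evidence carries no information
        flat_t = make_params(sigma_Vt=1e9, sigma_At=1e9)
        on = sb.posterior_common_cause(s, flat_t, use_temporal=True).p_c1
        assert off == pytest.approx(on, abs=1e-6)
        assert sb.posterior_common_cause(s, p, use_temporal=False).L_t_c1 == 1.0

    def test_factorized_denominator_stays_in_unit_interval(self):
        p = make_params()
        s = SensorySample(x_V=1.1, x_A=1.2, t_V=0.0, t_A=50.0)
        alt = sb.posterior_common_cause(s, p, denominator="factorized").p_c1
        assert 0.0 <= alt <= 1.0
        # the factorized form is generally a different number
        std = sb.posterior_common_cause(s, p).p_c1
        assert alt != pytest.approx(std, abs=1e-12)


class TestEstimates:
    def test_segregated_formula_and_fixed_point(self):
        p = make_params()
        assert sb.estimate_segregated(2.0, 0.33, p) == pytest.approx(
            segregated_estimate_arith(2.0, 0.33, p.mu_p, p.sigma_p), rel=1e-12
        )
        assert sb.estimate_segregated(p.mu_p, 0.5, p) == pytest.approx(p.mu_p)
        flat = make_params(sigma_p=1e9)
        assert sb.estimate_segregated(2.0, 0.33, flat) == pytest.approx(2.0, abs=1e-6)
        with pytest.raises(ValueError):
            sb.estimate_segregated(1.0, 0.0, p)

    def test_fused_formula_and_limits(self):
        p = make_params()
        assert sb.estimate_fused(1.0, 2.0, p) == pytest.approx(
            fused_estimate_arith(1.0, 2.0, p.sigma_V, p.sigma_A, p.mu_p, p.sigma_p), rel=1e-12
        )
        agree = make_params(mu_p=1.7)
        assert sb.estimate_fused(1.7, 1.7, agree) == pytest.approx(1.7)
        sym = make_params(sigma_V=0.4, sigma_A=0.4, sigma_p=1e9)
        assert sb.estimate_fused(1.0, 2.0, sym) == pytest.approx(1.5, abs=1e-6)
        lo, hi = min(1.0, 2.0, p.mu_p), max(1.0, 2.0, p.mu_p)
        assert lo <= sb.estimate_fused(1.0, 2.0, p) <= hi

    def test_model_average_collapses_at_posterior_extremes(self):
        s = SensorySample(x_V=1.0, x_A=2.0, t_V=0.0, t_A=0.0)
        full = sb.estimate_model_average(s, make_params(p_common=1.0))
        assert full.s_hat_V == pytest.approx(full.s_hat_fused)
        assert full.s_hat_A == pytest.approx(full.s_hat_fused)
        none = sb.estimate_model_average(s, make_params(p_common=0.0))
        assert none.s_hat_A == pytest.approx(none.s_hat_A_seg)
        assert none.s_hat_V == pytest.approx(none.s_hat_V_seg)

    def test_model_average_matches_composed_oracle(self):
        p = make_params()
        s = SensorySample(x_V=1.0, x_A=2.0, t_V=0.0, t_A=300.0)
        est = sb.estimate_model_average(s, p)
        p1 = posterior_c1_quad(1.0, 2.0, 0.0, 300.0, p)
        fused = fused_estimate_arith(1.0, 2.0, p.sigma_V, p.sigma_A, p.mu_p, p.sigma_p)
        seg_V = segregated_estimate_arith(1.0, p.sigma_V, p.mu_p, p.sigma_p)
        seg_A = segregated_estimate_arith(2.0, p.sigma_A, p.mu_p, p.sigma_p)
        assert est.s_hat_V == pytest.approx(p1 * fused + (1 - p1) * seg_V, abs=1e-8)
        assert est.s_hat_A == pytest.approx(p1 * fused + (1 - p1) * seg_A, abs=1e-8)

    @given(
        x_V=st.floats(-1, 3),
        x_A=st.floats(-1, 3),
        t_A=st.floats(0, 600),
        p_common=st.floats(0.05, 0.95),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_model_average_is_convex_combination(self, x_V, x_A, t_A, p_common):
        p = make_params(p_common=p_common)
        est = sb.estimate_model_average(
            SensorySample(x_V=x_V, x_A=x_A, t_V=0.0, t_A=t_A), p
        )
        for s_hat, seg in ((est.s_hat_V, est.s_hat_V_seg), (est.s_hat_A, est.s_hat_A_seg)):
            lo, hi = min(est.s_hat_fused, seg), max(est.s_hat_fused, seg)
            assert lo - 1e-12 <= s_hat <= hi + 1e-12


class TestDiscretizeResponse:
    @pytest.mark.parametrize(
        "value,expected",
        [(1.4, 1), (-0.7, 0), (1.5, 2), (0.5, 1), (2.9, 2), (0.49, 0), (2.5, 2)],
    )
    def test_rounding_clamping_and_tie_rule(self, value, expected):
        assert sb.discretize_response(value) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            sb.discretize_response(float("nan"))


class TestLognormalFamily:
    def test_posterior_valid_and_coincidence_favors_fusion(self):
        p = make_params()
        s = SensorySample(x_V=1.5, x_A=1.5, t_V=0.0, t_A=0.0)
        post = sb.posterior_common_cause(s, p, family="lognormal")
        assert 0.0 <= post.p_c1 <= 1.0
        assert post.L_num_c1 > post.L_num_c2 > 0

    def test_conflict_reduces_common_cause_belief(self):
        p = make_params()
        near = sb.posterior_common_cause(
            SensorySample(x_V=1.0, x_A=1.0, t_V=0.0, t_A=0.0), p, family="lognormal"
        ).p_c1
        far = sb.posterior_common_cause(
            SensorySample(x_V=0.5, x_A=2.5, t_V=0.0, t_A=0.0), p, family="lognormal"
        ).p_c1
        assert near > far

    def test_estimates_positive_and_convex(self):
        p = make_params()
        est = sb.estimate_model_average(
            SensorySample(x_V=0.8, x_A=2.1, t_V=0.0, t_A=0.0), p, family="lognormal"
        )
        assert est.s_hat_fused > 0
        for s_hat, seg in ((est.s_hat_V, est.s_hat_V_seg), (est.s_hat_A, est.s_hat_A_seg)):
            lo, hi = min(est.s_hat_fused, seg), max(est.s_hat_fused, seg)
            assert lo - 1e-9 <= s_hat <= hi + 1e-9


class TestModelParamsValidation:
    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            make_params(sigma_V=0.0)
        with pytest.raises(ValueError):
            make_params(sigma_tp=-1.0)

    def test_p_common_range_enforced(self):
        with pytest.raises(ValueError):
            make_params(p_common=1.2)
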