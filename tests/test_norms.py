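"""Norm-parameter handling and the CFA-to-ANOVA linear propagation."""

import dataclasses
import math

import numpy as np
import pytest

from srmfam.norms import (
    anova_weight_matrix,
    dyad_law,
    reciprocity_to_covariance,
    sampling_distribution,
    validate_params,
)
from srmfam.roundrobin import ValidationError, effect_ids
from srmfam.simulate import SimulationConfig, simulate_families


class TestReciprocityConversion:
    def test_generalized_correlation_to_covariance(self, norm_params):
        cov = reciprocity_to_covariance(norm_params)
        assert cov.reciprocity_scale == "covariance"
        # mother's actor-partner correlation 0.40, vars 0.163 and 0.044
        assert cov.generalized_reciprocity["M"] == pytest.approx(
            0.40 * math.sqrt(0.163 * 0.044), abs=1e-12
        )

    def test_dyadic_correlation_to_covariance(self, norm_params):
        cov = reciprocity_to_covariance(norm_params)
        assert cov.dyadic_reciprocity[("M", "F")] == pytest.approx(
            0.35 * math.sqrt(0.491 * 0.616), abs=1e-12
        )

    def test_zero_correlation_gives_zero_covariance(self, zero_var_params):
        cov = reciprocity_to_covariance(zero_var_params)
        assert all(v == 0.0 for v in cov.generalized_reciprocity.values())

    def test_covariance_input_passes_through(self, norm_params):
        cov = reciprocity_to_covariance(norm_params)
        again = reciprocity_to_covariance(cov)
        assert again is cov

    def test_out_of_range_correlation_rejected(self, norm_params):
        with pytest.raises(ValidationError, match=r"out of \[-1, 1\]"):
            dataclasses.replace(
                norm_params,
                generalized_reciprocity={**norm_params.generalized_reciprocity, "M": 1.2},
            )

    def test_cauchy_schwarz_violation_rejected(self, norm_params):
        cov = reciprocity_to_covariance(norm_params)
        with pytest.raises(ValidationError, match="Cauchy-Schwarz"):
            dataclasses.replace(
                cov,
                dyadic_reciprocity={**cov.dyadic_reciprocity, ("M", "F"): 5.0},
            )


class TestDyadLaw:
    def test_model_implied_mean_single_dyad(self, norm_params):
        law = dyad_law(norm_params)
        idx = norm_params.roles.dyad_index("F", "C2")
        # 1.838 + 0.103 + 0.109 - 0.050
        assert law.mean[idx] == pytest.approx(2.000, abs=1e-9)

    def test_means_match_published_dyad_table(self, norm_params):
        """Model-implied dyad means agree with the norm study's printed
        raw-score means within rounding."""
        from srmfam.fixtures import norm_dyad_summary

        law = dyad_law(norm_params)
        for _, row in norm_dyad_summary().iterrows():
            idx = norm_params.roles.dyad_index(row["actor"], row["partner"])
            assert law.mean[idx] == pytest.approx(row["mean"], abs=0.01), (
                row["actor"],
                row["partner"],
            )

    def test_zero_params_give_zero_covariance(self, zero_var_params):
        law = dyad_law(zero_var_params)
        assert np.allclose(law.covariance, 0.0)

    def test_covariance_symmetric_psd(self, norm_params):
        law = dyad_law(norm_params)
        assert np.allclose(law.covariance, law.covariance.T)
        assert law.min_eigenvalue > -1e-10

    def test_covariance_matches_monte_carlo(self, norm_params):
        """Component-wise simulation reproduces the assembled covariance
        (Frobenius-relative 2% at 200,000 families, fixed seed)."""
        law = dyad_law(norm_params)
        sim = simulate_families(
            SimulationConfig(params=norm_params, n_families=200_000, seed=20)
        )
        emp = np.cov(sim.dyads, rowvar=False)
        rel = np.linalg.norm(emp - law.covariance) / np.linalg.norm(law.covariance)
        assert rel < 0.02


class TestWeightMatrix:
    def test_row_structure(self, roles):
        W = anova_weight_matrix(roles)
        assert W.shape == (21, 12)
        assert np.allclose(W[0], 1.0 / 12.0)
        # grand-mean removal: every non-family row sums to zero
        assert np.allclose(W[1:].sum(axis=1), 0.0, atol=1e-12)

    def test_actor_row_weights(self, roles):
        W = anova_weight_matrix(roles)
        row = W[1 + roles.index("C2")]
        for c, (a, p) in enumerate(roles.dyads):
            if a == "C2":
                assert row[c] == pytest.approx(0.25)
            elif p == "C2":
                assert row[c] == pytest.approx(0.0)
            else:
                assert row[c] == pytest.approx(-0.125)

    def test_actor_row_reproduces_worked_value(self, roles, case_data):
        W = anova_weight_matrix(roles)
        value = W[1 + roles.index("C2")] @ case_data.vector()
        assert value == pytest.approx(1.446, abs=1e-3)


class TestSamplingDistribution:
    def test_family_effect_mean_and_sd(self, norm_params):
        dist = sampling_distribution(norm_params)
        assert dist.mean["family"] == pytest.approx(1.8378, abs=1e-3)
        assert dist.sd["family"] == pytest.approx(0.3945, abs=1e-3)
        # standardizing the worked example's grand mean recovers its
        # published Z score
        z = (2.090 - dist.mean["family"]) / dist.sd["family"]
        assert z == pytest.approx(0.639, abs=0.02)

    def test_actor_mean_close_to_cfa_mean(self, norm_params):
        # printed actor means sum to -0.001, so agreement is to rounding
        dist = sampling_distribution(norm_params)
        assert dist.mean["actor:C2"] == pytest.approx(0.117, abs=2e-3)

    def test_zero_variances_flagged_non_assessable(self, roles, zero_var_params):
        dist = sampling_distribution(zero_var_params)
        assert set(dist.non_assessable) == set(effect_ids(roles))

    def test_unbiased_under_exact_constraints(self, exact_params):
        """When the mean structure satisfies the zero-sum constraints
        exactly, every ANOVA-score mean equals its CFA mean."""
        dist = sampling_distribution(exact_params)
        assert dist.mean["family"] == pytest.approx(exact_params.family_mean, abs=1e-10)
        for r in exact_params.roles.labels:
            assert dist.mean[f"actor:{r}"] == pytest.approx(
                exact_params.actor_mean[r], abs=1e-10
            )
            assert dist.mean[f"partner:{r}"] == pytest.approx(
                exact_params.partner_mean[r], abs=1e-10
            )
        for a, p in exact_params.roles.dyads:
            assert dist.mean[f"rel:{a}->{p}"] == pytest.approx(
                exact_params.rel_mean[(a, p)], abs=1e-10
            )

    @pytest.mark.parametrize("c", [0.5, 3.0])
    def test_scale_equivariance(self, exact_params, c):
        scaled = dataclasses.replace(
            exact_params,
            family_mean=c * exact_params.family_mean,
            family_var=c**2 * exact_params.family_var,
            actor_mean={k: c * v for k, v in exact_params.actor_mean.items()},
            actor_var={k: c**2 * v for k, v in exact_params.actor_var.items()},
            partner_mean={k: c * v for k, v in exact_params.partner_mean.items()},
            partner_var={k: c**2 * v for k, v in exact_params.partner_var.items()},
            rel_mean={k: c * v for k, v in exact_params.rel_mean.items()},
            rel_var={k: c**2 * v for k, v in exact_params.rel_var.items()},
        )
        base = sampling_distribution(exact_params)
        dist = sampling_distribution(scaled)
        for e in base.mean:
            assert dist.mean[e] == pytest.approx(c * base.mean[e], abs=1e-9)
            assert dist.sd[e] == pytest.approx(c * base.sd[e], abs=1e-9)


class TestValidateParams:
    def test_published_tables_are_consistent(self, norm_params):
        assert validate_params(norm_params) == []

    def test_zero_sum_violation_warns(self, norm_params):
        p = dataclasses.replace(
            norm_params, actor_mean=dict.fromkeys(norm_params.roles.labels, 0.5)
        )
        warnings = [d for d in validate_params(p) if d.severity == "warning"]
        assert any("actor means sum" in d.message for d in warnings)

    def test_negative_variance_is_an_error(self, norm_params):
        with pytest.raises(ValidationError, match="variance is negative"):
            dataclasses.replace(norm_params, family_var=-0.01)
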