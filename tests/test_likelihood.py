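import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import expit, logit

from abundint import (
    Coefficients,
    SiteState,
    StudyDesign,
    bernoulli_obs_loglik,
    binomial_obs_loglik,
    build_model_graph,
    linear_predictor,
    rn_detection_prob,
    site_joint_loglik,
)
from abundint.config import InteractionTerm

from conftest import make_data


class TestRnDetectionProb:
    def test_reference_values(self):
        assert rn_detection_prob(0.3, 0) == 0.0
        assert rn_detection_prob(0.5, 1) == pytest.approx(0.5)
        assert rn_detection_prob(0.3, 2) == pytest.approx(0.51)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            rn_detection_prob(1.2, 1)
        with pytest.raises(ValueError):
            rn_detection_prob(-0.1, 1)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        r=st.floats(0.0, 1.0, allow_nan=False),
        n=st.integers(0, 50),
    )
    def test_monotone_in_abundance_and_rate(self, r, n):
        p = rn_detection_prob(r, n)
        assert 0.0 <= p <= 1.0
        assert rn_detection_prob(r, n + 1) >= p
        if r <= 0.99:
            assert rn_detection_prob(min(r + 0.01, 1.0), n) >= p - 1e-12


class TestObservationDensities:
    def test_binomial_reference_values(self):
        assert binomial_obs_loglik(0, 1, 0.3) == pytest.approx(math.log(0.7))
        expected = math.log(math.comb(7, 2)) + 2 * math.log(0.51) + 5 * math.log(0.49)
        assert binomial_obs_loglik(2, 7, 0.51) == pytest.approx(expected)
        assert binomial_obs_loglik(2, 7, 0.51) == pytest.approx(
            stats.binom.logpmf(2, 7, 0.51)
        )
        assert binomial_obs_loglik(3, 7, 0.0) == -np.inf

    def test_binomial_count_bounds(self):
        with pytest.raises(ValueError):
            binomial_obs_loglik(9, 7, 0.5)

    @pytest.mark.parametrize("K", [1, 4, 7, 10])
    @pytest.mark.parametrize("p", [0.0, 0.25, 0.51, 1.0])
    def test_binomial_normalizes(self, K, p):
        total = sum(math.exp(binomial_obs_loglik(y, K, p)) for y in range(K + 1))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_bernoulli_conditional_on_presence(self):
        assert bernoulli_obs_loglik(1, 0.5, 0) == -np.inf
        assert bernoulli_obs_loglik(0, 0.5, 0) == 0.0
        assert bernoulli_obs_loglik(1, 0.5, 1) == pytest.approx(math.log(0.5))


class TestLinearPredictor:
    def _params(self, graph):
        return graph.params_for("S", "state")

    def test_interaction_shifts_logit(self, two_species_graph):
        coefs = Coefficients({"S:state:Intercept": 0.0, "S:state:gamma0<D>": -1.0})
        terms = [
            InteractionTerm(source_species="D", gamma0_name="S:state:gamma0<D>")
        ]
        states = SiteState(N={"D": 2})
        eta = linear_predictor({}, coefs, self._params(two_species_graph), terms, states)
        assert eta == pytest.approx(-2.0)
        assert expit(eta) == pytest.approx(0.11920292, abs=1e-6)

    def test_modifier_can_cancel_interaction(self):
        coefs = Coefficients({"g0": -1.0, "g1": 1.0})
        terms = [
            InteractionTerm(
                source_species="D", gamma0_name="g0",
                modifier_covariate="x", gamma1_name="g1",
            )
        ]
        eta = linear_predictor({"x": 1.0}, coefs, [], terms, SiteState(N={"D": 2}))
        assert eta == pytest.approx(0.0)

    def test_occupancy_mediated_contribution_is_indicator(self):
        coefs = Coefficients({"g0": -1.0})
        terms = [
            InteractionTerm(source_species="D", gamma0_name="g0", occupancy_mediated=True)
        ]
        eta = linear_predictor({}, coefs, [], terms, SiteState(N={"D": 3}))
        assert eta == pytest.approx(-1.0)

    def test_missing_covariate_raises(self, two_species_graph):
        coefs = Coefficients({"g0": -1.0, "g1": 0.5})
        terms = [
            InteractionTerm(source_species="D", gamma0_name="g0",
                            modifier_covariate="x", gamma1_name="g1")
        ]
        with pytest.raises(KeyError):
            linear_predictor({}, coefs, [], terms, SiteState(N={"D": 1}))


class TestSiteJointLoglik:
    def test_single_species_empty_site(self, single_abundance_graph):
        data = make_data(single_abundance_graph, {"D": [[0, 0]]})
        coefs = Coefficients({"D:state:Intercept": math.log(2.0), "D:det:Intercept": 0.0})
        ll = site_joint_loglik(0, SiteState(N={"D": 0}), coefs, data, single_abundance_graph)
        assert ll == pytest.approx(stats.poisson.logpmf(0, 2.0))

    def test_compositional_over_species_and_occasions(self, two_species_graph):
        data = make_data(two_species_graph, {"D": [[1, 0]], "S": [[0, 1]]})
        coefs = Coefficients(
            {
                "D:state:Intercept": 0.1,
                "D:det:Intercept": -0.2,
                "S:state:Intercept": 0.4,
                "S:state:gamma0<D>": -1.0,
                "S:det:Intercept": 0.3,
            }
        )
        states = SiteState(N={"D": 2}, z={"S": 1})
        r = expit(-0.2)
        p_site = 1 - (1 - r) ** 2
        pS = expit(0.3)
        manual = (
            stats.poisson.logpmf(2, math.exp(0.1))
            + stats.binom.logpmf(1, 1, p_site)
            + stats.binom.logpmf(0, 1, p_site)
            + math.log(expit(0.4 - 2.0))
            + math.log(1 - pS)
            + math.log(pS)
        )
        assert site_joint_loglik(0, states, coefs, data, two_species_graph) == pytest.approx(manual)

    def test_masked_occasion_contributes_nothing(self, single_abundance_graph):
        mask = np.array([[True, False]])
        d_full = make_data(single_abundance_graph, {"D": [[1, 0]]})
        d_mask = make_data(
            single_abundance_graph,
            {"D": [[1, 0]]},
            design=StudyDesign(1, 2, observed_mask=mask),
        )
        coefs = Coefficients({"D:state:Intercept": 0.0, "D:det:Intercept": 0.0})
        st_ = SiteState(N={"D": 1})
        full = site_joint_loglik(0, st_, coefs, d_full, single_abundance_graph)
        masked = site_joint_loglik(0, st_, coefs, d_mask, single_abundance_graph)
        # dropping the second (non-detection) occasion removes exactly its term
        assert masked == pytest.approx(full - math.log(0.5))

    def test_detection_at_empty_site_impossible(self, single_abundance_graph):
        data = make_data(single_abundance_graph, {"D": [[1, 0]]})
        coefs = Coefficients({"D:state:Intercept": 0.0, "D:det:Intercept": 0.0})
        assert site_joint_loglik(0, SiteState(N={"D": 0}), coefs, data,
                                 single_abundance_graph) == -np.inf


class TestModelReductions:
    """With interactions off the framework collapses onto the classic
    single-species models."""

    def test_subordinate_reduces_to_single_species_occupancy(self, two_species_graph):
        # gamma0 = 0: the subordinate site likelihood, marginalized over z,
        # is the MacKenzie likelihood psi*prod Bern + (1-psi)*1{no detections}
        data = make_data(two_species_graph, {"D": [[0, 0]], "S": [[1, 0]]})
        base = {
            "D:state:Intercept": 0.0,
            "D:det:Intercept": 0.0,
            "S:state:Intercept": 0.7,
            "S:state:gamma0<D>": 0.0,
            "S:det:Intercept": -0.3,
        }
        psi, p = expit(0.7), expit(-0.3)
        from abundint.likelihood import species_site_loglik

        marg = sum(
            math.exp(
                species_site_loglik(
                    two_species_graph, data, 0, "S",
                    SiteState(N={"D": 1}, z={"S": z}), Coefficients(base),
                )
            )
            for z in (0, 1)
        )
        mackenzie = psi * p * (1 - p)  # detected once in two occasions
        assert marg == pytest.approx(mackenzie)

    def test_dichotomized_rn_matches_occupancy(self):
        # Latent presence with P(z=1) = 1 - e^-lambda and detection r equals
        # the R-N observation model restricted to N in {0, 1}
        lam, r, K = 0.8, 0.35, 3
        y = 2
        psi = 1 - math.exp(-lam)
        occ = (1 - psi) * (1.0 if y == 0 else 0.0) + psi * math.exp(
            binomial_obs_loglik(y, K, r)
        )
        rn = (1 - psi) * (1.0 if y == 0 else 0.0) + psi * math.exp(
            binomial_obs_loglik(y, K, rn_detection_prob(r, 1))
        )
        assert rn == pytest.approx(occ)
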