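import math

import numpy as np
import pytest
from scipy.special import expit

from abundint import (
    DetectionData,
    McmcConfig,
    StudyDesign,
    build_model_graph,
    fit,
    gibbs_latent_draws,
)
from abundint.config import ConfigurationError
from abundint.samplers import compile_model, run_chain
from abundint.simulate import SimulationScenario, simulate_dataset

from conftest import make_data

QUICK = McmcConfig(n_chains=2, n_iterations=1500, burn_in=400, thin=2, seed=7)


class TestMcmcConfig:
    def test_requires_enough_retained_draws(self):
        with pytest.raises(ConfigurationError):
            McmcConfig(n_iterations=300, burn_in=200, thin=2)

    def test_paper_preset_lengths(self):
        m = McmcConfig.paper()
        assert (m.n_iterations, m.burn_in, m.thin) == (50000, 20000, 18)


class TestLatentFullConditionals:
    def test_empty_history_matches_enumeration(self, single_abundance_graph):
        # lambda=1, r=0.5, K=1, J=2, y=(0,0): conditional prop. 0.25^n / n!
        data = make_data(single_abundance_graph, {"D": [[0, 0]]})
        coefs = {"D:state:Intercept": 0.0, "D:det:Intercept": 0.0}
        draws = gibbs_latent_draws(single_abundance_graph, data, coefs, 20000,
                                   seed=3, n_max=15)[:, 0, 0]
        assert np.mean(draws == 0) == pytest.approx(math.exp(-0.25), abs=0.01)

    def test_detection_forces_positive_abundance(self, single_abundance_graph):
        data = make_data(single_abundance_graph, {"D": [[1, 0]]})
        coefs = {"D:state:Intercept": 0.0, "D:det:Intercept": 0.0}
        draws = gibbs_latent_draws(single_abundance_graph, data, coefs, 2000, seed=1)
        assert draws.min() >= 1

    def test_occupancy_conditional_closed_form(self, single_occupancy_graph):
        # psi=0.5, p=0.5, J=2, no detections -> P(z=1) = 0.125/0.625 = 0.2
        data = make_data(single_occupancy_graph, {"S": [[0, 0]]})
        coefs = {"S:state:Intercept": 0.0, "S:det:Intercept": 0.0}
        draws = gibbs_latent_draws(single_occupancy_graph, data, coefs, 30000, seed=4)
        assert draws.mean() == pytest.approx(0.2, abs=0.01)

    def test_occupancy_detection_forces_presence(self, single_occupancy_graph):
        data = make_data(single_occupancy_graph, {"S": [[1, 0]]})
        coefs = {"S:state:Intercept": -5.0, "S:det:Intercept": 0.0}
        draws = gibbs_latent_draws(single_occupancy_graph, data, coefs, 500, seed=5)
        assert np.all(draws == 1)

    def test_downstream_absence_shifts_abundance_up(self, two_species_graph):
        # z_S = 0 with gamma0 < 0 makes larger N more plausible
        data = make_data(two_species_graph, {"D": [[0, 0]], "S": [[0, 0]]})
        coefs = {
            "D:state:Intercept": 0.0, "D:det:Intercept": 0.0,
            "S:state:Intercept": 0.0, "S:det:Intercept": 0.0,
            "S:state:gamma0<D>": -1.0,
        }
        draws = gibbs_latent_draws(two_species_graph, data, coefs, 30000,
                                   seed=5, n_max=15)
        n = np.arange(16)
        logw = -np.array([math.lgamma(k + 1) for k in n]) + 2 * n * math.log(0.5)
        w = np.exp(logw - logw.max())
        w_plain = w / w.sum()
        w_shift = w * (1 - expit(-1.0 * n))
        w_shift /= w_shift.sum()
        assert (w_shift * n).sum() > (w_plain * n).sum()
        z0 = draws[:, 1, 0] == 0
        emp = draws[z0, 0, 0].mean()
        assert emp == pytest.approx((w_shift * n).sum(), abs=0.02)

    def test_missing_coefficient_rejected(self, single_abundance_graph):
        data = make_data(single_abundance_graph, {"D": [[0, 0]]})
        with pytest.raises(ConfigurationError, match="det"):
            gibbs_latent_draws(single_abundance_graph, data,
                               {"D:state:Intercept": 0.0}, 10)


class TestChainMechanics:
    def test_same_seed_bit_identical(self, tiny_rn_scenario):
        data, _ = simulate_dataset(tiny_rn_scenario, seed=2)
        cm = compile_model(tiny_rn_scenario.graph, data)
        a = run_chain(cm, QUICK, chain_id=1)
        b = run_chain(cm, QUICK, chain_id=1)
        assert np.array_equal(a.draws, b.draws)
        c = run_chain(cm, QUICK, chain_id=2)
        assert not np.array_equal(a.draws, c.draws)

    def test_collapsed_and_generic_paths_agree_exactly(self, two_species_graph):
        tv = {
            "D:state:Intercept": 0.0, "D:det:Intercept": 0.0,
            "S:state:Intercept": 1.0, "S:state:gamma0<D>": -1.0,
            "S:det:Intercept": 0.0,
        }
        sc = SimulationScenario("t", StudyDesign(80, 4), two_species_graph, tv, seed=0)
        data, _ = simulate_dataset(sc, seed=9)
        cm = compile_model(two_species_graph, data)
        assert cm.fast_ok
        a = run_chain(cm, QUICK, 0, collapse_sites=False)
        b = run_chain(cm, QUICK, 0, collapse_sites=True)
        assert np.array_equal(a.draws, b.draws)
        assert np.array_equal(a.latent_draws, b.latent_draws)

    def test_adapted_acceptance_rates_reasonable(self, tiny_rn_scenario):
        data, _ = simulate_dataset(tiny_rn_scenario, seed=3)
        cm = compile_model(tiny_rn_scenario.graph, data)
        res = run_chain(cm, McmcConfig(n_chains=1, n_iterations=4000,
                                       burn_in=1500, thin=2, seed=1), 0)
        assert res.ok
        assert np.all(res.acceptance > 0.1) and np.all(res.acceptance < 0.7)

    def test_fit_shape_and_diagnostics_contract(self, tiny_rn_scenario):
        data, _ = simulate_dataset(tiny_rn_scenario, seed=4)
        res = fit(tiny_rn_scenario.graph, data,
                  McmcConfig(n_chains=3, n_iterations=1200, burn_in=300, thin=3, seed=2))
        assert res.draws.shape[0] == 3
        assert res.draws.shape[2] == 2
        assert np.isfinite(res.rhat).all()
        assert res.converged in (True, False)

    def test_single_chain_rhat_unavailable(self, tiny_rn_scenario):
        data, _ = simulate_dataset(tiny_rn_scenario, seed=4)
        res = fit(tiny_rn_scenario.graph, data,
                  McmcConfig(n_chains=1, n_iterations=1200, burn_in=300, thin=3, seed=2))
        assert np.isnan(res.rhat).all()
        assert res.converged is None


class TestPosteriorCorrectness:
    def test_prior_recovered_when_all_data_masked(self, single_occupancy_graph):
        # no occasion contributes: the theta-marginal of the joint sampler
        # must reproduce the Normal(0, 2.5) prior (detailed balance check)
        mask = np.zeros((40, 2), bool)
        design = StudyDesign(40, 2, observed_mask=mask)
        data = DetectionData(design=design, y={"S": np.full((40, 2), -1)})
        res = fit(single_occupancy_graph, data,
                  McmcConfig(n_chains=3, n_iterations=8000, burn_in=1000, thin=4, seed=3))
        pooled = res.draws.reshape(-1, res.draws.shape[2])
        for j, name in enumerate(res.parameter_names):
            assert abs(pooled[:, j].mean()) < 0.15, name
            assert pooled[:, j].std() == pytest.approx(2.5, rel=0.08), name

    def test_single_species_posterior_covers_truth(self, tiny_rn_scenario):
        sc = SimulationScenario(
            "rn300", StudyDesign(300, 4), tiny_rn_scenario.graph,
            dict(tiny_rn_scenario.true_values), seed=0,
        )
        data, _ = simulate_dataset(sc, seed=6)
        res = fit(sc.graph, data, McmcConfig(seed=8))
        assert res.converged
        for name, truth in sc.true_values.items():
            lo, hi = res.cri(name)
            assert lo - 0.05 <= truth <= hi + 0.05, (name, lo, hi)
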