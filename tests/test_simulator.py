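import numpy as np
import pytest
from scipy.special import expit, logit

from abundint import (
    StudyDesign,
    preset_casestudy_synthetic,
    preset_study1,
    preset_study2,
    preset_study3,
    read_dataset,
    simulate_dataset,
    write_dataset,
)
from abundint.simulate import SimulationScenario


class TestPresetStudy1:
    def test_design_and_constants(self):
        sc = preset_study1(0.5)
        d = sc.design
        assert (d.n_sites, d.n_occasions, d.n_subsamples) == (600, 4, 1)
        tv = sc.true_values
        assert tv["D:state:Intercept"] == pytest.approx(np.log(0.5))
        assert expit(tv["D:det:Intercept"]) == pytest.approx(0.3)
        assert expit(tv["S:det:Intercept"]) == pytest.approx(0.5)
        assert tv["S:state:gamma0<D>"] == -1.0

    def test_constant_interaction_has_no_modifier_term(self):
        sc = preset_study1(2)
        assert not any("gamma1" in n for n in sc.graph.parameter_names)

    def test_solved_intercept_hits_mean_occupancy(self):
        sc = preset_study1(0.5)
        b0 = sc.true_values["S:state:Intercept"]
        n = np.arange(60)
        from scipy.stats import poisson

        mean_psi = (poisson.pmf(n, 0.5) * expit(b0 - n)).sum()
        assert mean_psi == pytest.approx(0.75, abs=0.005)

    def test_off_grid_lambda_warns(self):
        with pytest.warns(UserWarning):
            preset_study1(3.0)

    def test_equal_seeds_identical_datasets(self):
        sc = preset_study1(1)
        d1, t1 = simulate_dataset(sc, seed=5)
        d2, t2 = simulate_dataset(sc, seed=5)
        for sp in d1.y:
            assert np.array_equal(d1.y[sp], d2.y[sp])
        assert d1.covariates.equals(d2.covariates)
        assert np.array_equal(t1["latent:D"], t2["latent:D"])


class TestPresetStudy2:
    def test_constant_variant(self):
        sc = preset_study2(300, 4, False)
        assert sc.design.n_sites == 300 and sc.design.n_occasions == 4
        assert expit(sc.true_values["D:det:Intercept"]) == pytest.approx(0.5)
        assert sc.true_values["D:state:Intercept"] == pytest.approx(0.0)
        assert sc.true_values["S:state:gamma0<D>"] == -1.0
        assert not any("gamma1" in n for n in sc.graph.parameter_names)

    def test_varying_variant_adds_exactly_one_parameter(self):
        const = preset_study2(1000, 10, False)
        vary = preset_study2(1000, 10, True)
        assert len(vary.graph.parameter_index) == len(const.graph.parameter_index) + 1
        assert vary.true_values["S:state:gamma1<D*x_int>"] == 1.0
        assert "x_int" in vary.graph.covariate_names

    def test_mean_occupancy_target_met_empirically(self):
        sc = preset_study2(600, 4, False)
        _, truth = simulate_dataset(sc, seed=3)
        assert truth["latent:S"].mean() == pytest.approx(0.5, abs=0.06)


class TestPresetStudy3:
    def test_three_species_structure(self):
        sc = preset_study3(0.5, 0.5)
        g = sc.graph
        assert g.species_names == ["D", "I", "S"]
        assert sc.true_values["I:state:gamma0<D>"] == -1.0
        assert sc.true_values["S:state:gamma0<I>"] == -1.0
        assert sc.true_values["S:state:gamma0<D>"] == 1.0
        assert expit(sc.true_values["I:det:Intercept"]) == pytest.approx(0.5)

    def test_intermediate_detection_fixed_for_any_arguments(self):
        sc = preset_study3(0.05, 0.25)
        assert expit(sc.true_values["I:det:Intercept"]) == pytest.approx(0.5)
        assert expit(sc.true_values["D:det:Intercept"]) == pytest.approx(0.05)
        assert expit(sc.true_values["S:det:Intercept"]) == pytest.approx(0.25)

    def test_negative_interaction_suppresses_subordinate(self):
        sc = preset_study3(0.5, 0.5)
        _, truth = simulate_dataset(sc, seed=2)
        nI, z = truth["latent:I"], truth["latent:S"]
        nD = truth["latent:D"]
        at = nD == 0  # hold the dominant contribution fixed
        occ_low = z[at & (nI == 0)].mean()
        occ_high = z[at & (nI >= 2)].mean()
        assert occ_high < occ_low


class TestSimulatedMoments:
    def test_poisson_mean_recovered(self):
        sc = preset_study1(2)
        _, truth = simulate_dataset(sc, seed=1)
        n = truth["latent:D"]
        assert abs(n.mean() - 2.0) < 3 * np.sqrt(2.0 / 600)

    def test_zero_detection_rate_gives_empty_histories(self, single_abundance_graph):
        sc = SimulationScenario(
            "r0", StudyDesign(200, 3), single_abundance_graph,
            {"D:state:Intercept": np.log(2.0), "D:det:Intercept": -40.0}, seed=0,
        )
        data, _ = simulate_dataset(sc, seed=4)
        assert np.all(data.y["D"] == 0)

    def test_strong_negative_interaction_excludes_subordinate(self, two_species_graph):
        tv = {
            "D:state:Intercept": np.log(2.0), "D:det:Intercept": 0.0,
            "S:state:Intercept": 0.0, "S:state:gamma0<D>": -10.0,
            "S:det:Intercept": 0.0,
        }
        sc = SimulationScenario("gx", StudyDesign(500, 3), two_species_graph, tv, seed=0)
        _, truth = simulate_dataset(sc, seed=8)
        occupied = truth["latent:S"][truth["latent:D"] >= 1]
        assert occupied.mean() < 0.02


class TestCaseStudyShape:
    def test_design_mask_and_years(self):
        sc = preset_casestudy_synthetic()
        d = sc.design
        assert d.n_subsamples == 7
        assert d.n_sites == 195 * 3 and d.n_occasions == 3
        unsampled = ~d.observed_mask.any(axis=1)
        assert unsampled.sum() == 13
        assert np.all(d.year_index[unsampled] == 1)

    def test_year_intercepts_on_every_submodel(self):
        sc = preset_casestudy_synthetic()
        for sp in ("coyote", "fisher", "marten"):
            for tag in ("state", "det"):
                assert f"{sp}:{tag}:year1" in sc.graph.parameter_names
                assert f"{sp}:{tag}:year2" in sc.graph.parameter_names

    def test_counts_bounded_by_subsamples(self):
        sc = preset_casestudy_synthetic()
        data, _ = simulate_dataset(sc, seed=0)
        for sp, m in data.y.items():
            assert m[data.design.observed_mask].max() <= 7


class TestRoundTrip:
    def test_write_read_preserves_everything(self, tmp_path):
        sc = preset_casestudy_synthetic()
        data, truth = simulate_dataset(sc, seed=21)
        write_dataset(data, tmp_path, truth={"note": "synthetic"})
        back = read_dataset(tmp_path)
        assert np.array_equal(back.design.observed_mask, data.design.observed_mask)
        assert np.array_equal(back.design.year_index, data.design.year_index)
        for sp in data.y:
            assert np.array_equal(back.y[sp], data.y[sp])
        got = back.covariates[sorted(back.covariates.columns)].to_numpy()
        want = data.covariates[sorted(data.covariates.columns)].to_numpy()
        assert np.allclose(got, want, rtol=0, atol=0)
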