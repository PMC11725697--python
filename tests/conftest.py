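import numpy as np
import pytest

from abundint import DetectionData, StudyDesign, build_model_graph
from abundint.simulate import SimulationScenario


@pytest.fixture(scope="session")
def two_species_cfg():
    return {
        "species": [
            {"name": "D", "role": "dominant", "state": "abundance"},
            {
                "name": "S",
                "role": "subordinate",
                "state": "occupancy",
                "interactions": [{"source": "D", "target": "state"}],
            },
        ]
    }


@pytest.fixture(scope="session")
def two_species_graph(two_species_cfg):
    return build_model_graph(two_species_cfg)


@pytest.fixture(scope="session")
def single_abundance_graph():
    return build_model_graph(
        {"species": [{"name": "D", "role": "dominant", "state": "abundance"}]}
    )


@pytest.fixture(scope="session")
def single_occupancy_graph():
    return build_model_graph(
        {"species": [{"name": "S", "role": "dominant", "state": "occupancy"}]}
    )


def make_data(graph, y, design=None, covariates=None):
    arrs = {k: np.asarray(v, dtype=int) for k, v in y.items()}
    I, J = next(iter(arrs.values())).shape
    design = design or StudyDesign(n_sites=I, n_occasions=J)
    return DetectionData(design=design, y=arrs, covariates=covariates)


@pytest.fixture(scope="session")
def tiny_rn_scenario(single_abundance_graph):
    """Small single-species Royle-Nichols design for quick fits."""
    return SimulationScenario(
        name="tiny_rn",
        design=StudyDesign(n_sites=100, n_occasions=4),
        graph=single_abundance_graph,
        true_values={"D:state:Intercept": 0.0, "D:det:Intercept": 0.0},
        seed=0,
    )
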