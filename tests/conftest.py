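import numpy as np
import pytest

from scsignet.pathways import build_indicator, decompose_circuits, join_indicators
from scsignet.simulate import SimulationScenario, generate_dataset


def indicator_from_graphs(graphs):
    return join_indicators(
        [build_indicator(decompose_circuits(g), sorted(g.nodes)) for g in graphs]
    )


@pytest.fixture(scope="session")
def small_scenario():
    """The closed-set study design (preset S1) with a fixed seed."""
    from scsignet.simulate import scenario_presets

    scenario = scenario_presets()["S1"]
    scenario.seed = 7
    return scenario


@pytest.fixture(scope="session")
def small_open_scenario(small_scenario):
    from dataclasses import replace

    return replace(small_scenario, n_unknown_cells=150)


@pytest.fixture(scope="session")
def small_dataset(small_scenario):
    graphs, circuits, counts, labels = generate_dataset(small_scenario)
    return graphs, circuits, counts, labels


@pytest.fixture(scope="session")
def small_indicator(small_dataset):
    graphs = small_dataset[0]
    return indicator_from_graphs(graphs)


@pytest.fixture(scope="session")
def small_model(small_dataset, small_indicator):
    """One fitted annotator shared by the read-only orchestration tests."""
    from scsignet import annotator

    _, _, counts, labels = small_dataset
    return annotator.fit(counts, labels, small_indicator, seed=11)
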