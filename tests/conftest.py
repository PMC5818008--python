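import pytest

from rootgrn import (GroundTruthNetwork, ModelParams, TrueEdge,
                     make_ground_truth_network, simulate_genotype_expression)


@pytest.fixture(scope="session")
def small_net() -> GroundTruthNetwork:
    """3 regulators, 8 targets, feedback loop; fixed seed."""
    return make_ground_truth_network(8, edge_density=0.5, seed=11)


@pytest.fixture(scope="session")
def paper_like_net() -> GroundTruthNetwork:
    """The 39-node layout: 3 regulators over 36 shared targets."""
    return make_ground_truth_network(36, seed=5)


@pytest.fixture(scope="session")
def small_expr(small_net):
    return simulate_genotype_expression(small_net, n_reps=3, noise_cv=0.2,
                                        seed=11)


@pytest.fixture()
def one_edge_net() -> GroundTruthNetwork:
    """Single activator edge A -> T01 (hand-checkable propagation)."""
    return GroundTruthNetwork(regulators=["A"], targets=["T01"],
                              edges=[TrueEdge("A", "T01", 1.0)], seed=0)


@pytest.fixture(scope="session")
def wt_params() -> ModelParams:
    return ModelParams()
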