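import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from synmarker.io_network import ExpressionDataset, InteractionNetwork
from synmarker.synthetic_data import SyntheticSpec, generate_expression, generate_network

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_dataset():
    """3 genes x 4 samples, 2 positive / 2 negative."""
    return ExpressionDataset(
        gene_ids=["G1", "G2", "G3"],
        values=np.array(
            [
                [1.0, 3.0, 0.0, 2.0],
                [5.0, 5.0, 5.0, 5.0],
                [2.0, 4.0, -1.0, 1.0],
            ]
        ),
        sample_ids=["S1", "S2", "S3", "S4"],
        labels=np.array([True, True, False, False]),
        name="toy",
    )


@pytest.fixture
def path_network():
    """Path graph a-b-c-d."""
    import networkx as nx

    return InteractionNetwork(graph=nx.path_graph(["a", "b", "c", "d"]))


@pytest.fixture(scope="session")
def small_synthetic():
    """Desk-scale planted-module instance reused across tests.

    300 genes, 3 modules of 6-8 genes, strong shift, two replicates.
    """
    spec = SyntheticSpec(
        n_genes=300,
        n_modules=3,
        module_size_range=(6, 8),
        delta=1.5,
        rho=0.5,
        n_pos=40,
        n_neg=80,
        n_replicate_datasets=2,
        seed=7,
    )
    network, truth = generate_network(spec)
    datasets = generate_expression(network, truth, spec)
    return spec, network, truth, datasets
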