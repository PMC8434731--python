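import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_fixture():
    """Small synthetic dataset: 30 cells x 50 genes x 4 drugs (120 records)."""
    from swnet.synthetic import SyntheticSpec, generate

    spec = SyntheticSpec(n_cells=30, n_genes=50, n_drugs=4, seed=7)
    return generate(spec)


@pytest.fixture()
def tiny_model(tiny_fixture):
    from swnet.model import SwnetModel, TrainingConfig

    drug_table, features, _responses, _truth = tiny_fixture
    cfg = TrainingConfig(epochs=3, batch_size=32, seed=7)
    return SwnetModel(drug_table, features, cfg)


def permute_graph(graph, perm, rng=None):
    """Relabel a MolecularGraph's atoms by ``perm`` (new index of old node i)."""
    from swnet.chem import MolecularGraph

    perm = list(perm)
    inv = [0] * len(perm)
    for old, new in enumerate(perm):
        inv[new] = old
    nodes = [graph.nodes[inv[i]] for i in range(len(perm))]
    edges = []
    for i, j, lab in graph.edges:
        a, b = perm[i], perm[j]
        edges.append((min(a, b), max(a, b), lab))
    return MolecularGraph(nodes=nodes, edges=edges, smiles=graph.smiles, _mol=graph._mol)
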