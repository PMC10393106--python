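from __future__ import annotations

import numpy as np
import pytest

from lapstrat.data_model import GeneNetwork, MutationCohort, align_to_network
from lapstrat.synthetic import SyntheticSpec, generate_cohort


def random_connected_network(n: int, p: float, seed: int) -> GeneNetwork:
    """Erdős–Rényi graph restricted to nodes with degree >= 1."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i:03d}" for i in range(n)]
    edges = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges[(genes[i], genes[j])] = 1.0
    net = GeneNetwork(genes=genes, edges=edges)
    return net.subgraph(genes, drop_isolated=True)


def random_cohort(net: GeneNetwork, n_patients: int, density: float, seed: int) -> MutationCohort:
    rng = np.random.default_rng(seed)
    M = (rng.random((n_patients, net.n)) < density).astype(np.int8)
    return MutationCohort(
        patients=[f"p{i:03d}" for i in range(n_patients)], genes=list(net.genes), M=M
    )


@pytest.fixture(scope="session")
def strong_cohort():
    """The default strong-signal synthetic cohort, aligned to its network."""
    syn = generate_cohort(SyntheticSpec(seed=1))
    cohort, net = align_to_network(syn.cohort, syn.network)
    return syn, cohort, net


@pytest.fixture
def small_net():
    return random_connected_network(25, 0.15, seed=7)


@pytest.fixture
def small_cohort(small_net):
    return random_cohort(small_net, 6, 0.2, seed=11)
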