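"""Seeded synthetic cohorts for end-to-end pipeline testing.

The generator emulates the structural premise of network-based tumor
stratification — patients of the same subtype carry mutations
concentrated in the same region of the gene network:

* the gene network is a stochastic block model with ``n_modules`` equal
  modules, dense within (p_in) and sparse between (p_out);
* each patient gets a subtype uniformly at random; each of its Poisson-
  distributed mutations lands in its subtype's module with probability β
  (the in-module bias), else uniformly among the other genes;
* survival times are exponential with a subtype-specific hazard, and a
  target fraction of patients is right-censored uniformly before their
  event time.

Everything is fully determined by the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data_model import ClinicalTable, GeneNetwork, MutationCohort

logger = logging.getLogger(__name__)

__all__ = ["SyntheticSpec", "SyntheticCohort", "generate_cohort", "perturb_labels"]


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic cohort.

    Defaults give the strong-signal study condition: 150 patients,
    300 genes in 3 modules, within/between edge probabilities 0.1/0.005,
    ~10 mutations per patient with in-module bias β = 0.8, per-subtype
    exponential hazards (per month) spanning a fourfold range, and 30%
    censoring.
    """

    n_patients: int = 150
    n_genes: int = 300
    n_modules: int = 3
    p_in: float = 0.1
    p_out: float = 0.005
    mean_mutations: float = 10.0
    beta: float = 0.8
    hazards: tuple[float, ...] = (0.02, 0.04, 0.08)
    censoring_fraction: float = 0.3
    time_unit: str = "months"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.p_in > self.p_out >= 0:
            raise ValueError("need p_in > p_out >= 0")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must be in [0, 1]")
        if len(self.hazards) != self.n_modules:
            raise ValueError("one hazard per subtype required")
        if any(h <= 0 for h in self.hazards):
            raise ValueError("hazards must be > 0")
        if not 0.0 <= self.censoring_fraction < 1.0:
            raise ValueError("censoring fraction must be in [0, 1)")


@dataclass
class SyntheticCohort:
    network: GeneNetwork
    cohort: MutationCohort
    clinical: ClinicalTable
    true_labels: np.ndarray  # subtype per patient, 1..k
    module_of_gene: np.ndarray = field(default=None)  # module per gene, 1..k


def _sbm_edges(
    modules: np.ndarray, p_in: float, p_out: float, rng: np.random.Generator
) -> list[tuple[int, int]]:
    n = modules.size
    same = modules[:, None] == modules[None, :]
    P = np.where(same, p_in, p_out)
    draw = rng.random((n, n))
    iu = np.triu_indices(n, 1)
    mask = np.zeros((n, n), dtype=bool)
    mask[iu] = draw[iu] < P[iu]
    return list(zip(*np.nonzero(mask)))


def generate_cohort(spec: SyntheticSpec) -> SyntheticCohort:
    """Draw a full synthetic cohort (network, mutations, clinical, truth)."""
    rng = np.random.default_rng(spec.seed)
    k = spec.n_modules

    genes = [f"g{j:04d}" for j in range(spec.n_genes)]
    patients = [f"p{i:04d}" for i in range(spec.n_patients)]

    # equal-size modules, 1..k
    module_of_gene = np.repeat(np.arange(1, k + 1), int(np.ceil(spec.n_genes / k)))[
        : spec.n_genes
    ]
    edge_idx = _sbm_edges(module_of_gene, spec.p_in, spec.p_out, rng)
    edges = {}
    for i, j in edge_idx:
        a, b = genes[i], genes[j]
        edges[(a, b) if a <= b else (b, a)] = 1.0
    network = GeneNetwork(genes=genes, edges=edges)

    # subtype per patient, uniform; redraw in the (vanishingly rare) case
    # a subtype comes out empty
    while True:
        subtype = rng.integers(1, k + 1, size=spec.n_patients)
        if len(np.unique(subtype)) == k:
            break

    gene_arr = np.arange(spec.n_genes)
    module_genes = {c: gene_arr[module_of_gene == c] for c in range(1, k + 1)}
    other_genes = {c: gene_arr[module_of_gene != c] for c in range(1, k + 1)}
    M = np.zeros((spec.n_patients, spec.n_genes), dtype=np.int8)
    for i in range(spec.n_patients):
        m = int(rng.poisson(spec.mean_mutations))
        if m == 0:
            continue
        c = int(subtype[i])
        n_in = int(rng.binomial(m, spec.beta))
        pool_in, pool_out = module_genes[c], other_genes[c]
        n_in = min(n_in, pool_in.size)
        n_out = min(m - n_in, pool_out.size)
        if n_in + n_out < m:
            logger.debug("patient %d: mutation count capped by module size", i)
        if n_in:
            M[i, rng.choice(pool_in, size=n_in, replace=False)] = 1
        if n_out:
            M[i, rng.choice(pool_out, size=n_out, replace=False)] = 1
    cohort = MutationCohort(patients=patients, genes=genes, M=M)

    hazards = np.asarray(spec.hazards, dtype=float)
    event_time = rng.exponential(1.0 / hazards[subtype - 1])
    n_cens = int(round(spec.censoring_fraction * spec.n_patients))
    cens_idx = rng.choice(spec.n_patients, size=n_cens, replace=False)
    event = np.ones(spec.n_patients, dtype=int)
    time = event_time.copy()
    event[cens_idx] = 0
    time[cens_idx] = rng.uniform(0.0, event_time[cens_idx])
    clinical = ClinicalTable(
        patients=patients, time=time, event=event, time_unit=spec.time_unit
    )

    return SyntheticCohort(
        network=network,
        cohort=cohort,
        clinical=clinical,
        true_labels=subtype,
        module_of_gene=module_of_gene,
    )


def perturb_labels(
    labels: np.ndarray, flip_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Reassign exactly round(flip_fraction·n) entries to a different label.

    Used to calibrate how agreement metrics degrade with label noise.
    """
    if not 0.0 <= flip_fraction <= 1.0:
        raise ValueError("flip_fraction must be in [0, 1]")
    labels = np.asarray(labels).copy()
    uniq = np.unique(labels)
    n_flip = int(round(flip_fraction * labels.size))
    if n_flip == 0 or uniq.size < 2:
        return labels
    idx = rng.choice(labels.size, size=n_flip, replace=False)
    for i in idx:
        choices = uniq[uniq != labels[i]]
        labels[i] = rng.choice(choices)
    return labels
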