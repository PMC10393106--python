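# lapstrat

Network-based stratification of cancer patients from somatic mutation
profiles, built around a **shifted-Laplacian label-propagation smoother**.

## The problem

Somatic mutation profiles are extremely sparse and heterogeneous: two
tumors of the same subtype rarely mutate the same genes, but they tend to
mutate genes in the same *region* of the gene–gene interaction network.
Network-based stratification therefore smooths each patient's binary
mutation vector over the network before clustering, so that
network-adjacent genes share signal. The classical smoother is a random
walk with restart (RWR),

    F_{t+1} = α F_t A + (1 − α) F_0,

whose fixed point requires inverting (I − αA). When the network contains
low-degree genes this system approaches singularity — the
ill-conditioning that degrades RWR-based stratification. `lapstrat`
replaces the RWR operator with a shifted graph Laplacian:

    F = (L + σI)^(-1) F_0,      L = D − A,   σ ∈ {0.01, 0.1, 0.2},

the minimizer of the ridge-style objective f̂ᵀLf-coupling + σ‖f̂‖².
With symmetric degree normalization L is positive semidefinite, so
(L + σI) is symmetric positive definite for every σ > 0 — well-posed
regardless of node degrees.

The full pipeline (for each of 100 consensus runs): subsample 80% of
patients and genes → smooth on the induced subnetwork → quantile
normalize → graph-regularized NMF (minimize ‖F − WH‖² + λ·Tr(HLHᵀ) with
L the patient-KNN-graph Laplacian, by multiplicative updates) → assign
each patient to its largest H loading. Pairwise co-assignment frequencies
form a co-clustering matrix whose average-linkage hierarchy, cut at k,
gives the final subtypes. Subtypes are evaluated with silhouette,
Davies–Bouldin, intra-cluster distances (complete/average/centroid), and
Kaplan–Meier / log-rank survival analysis.

An RWR baseline (iterative and closed-form), a seeded synthetic-cohort
generator (stochastic-block-model network, subtype-biased mutations,
subtype-dependent survival) and conditioning diagnostics are included, so
every stage is testable without access to patient data.

## Worked example

```python
import numpy as np
from lapstrat import (SyntheticSpec, generate_cohort, align_to_network,
                      PropagationConfig, GNMFConfig, run_consensus,
                      cluster_metrics, survival_by_cluster, cluster_label_accuracy)
from lapstrat.consensus import _smooth

syn = generate_cohort(SyntheticSpec(seed=1))            # 150 patients, 300 genes, 3 subtypes
cohort, net = align_to_network(syn.cohort, syn.network)

prop = PropagationConfig(method="label_propagation", sigma=0.1)
result = run_consensus(cohort, net, prop, GNMFConfig(k=3),
                       n_runs=30, fraction=0.8, seed=1)

smoothed = _smooth(cohort, net, prop, "symmetric")
report = cluster_metrics(smoothed.F, result.labels)
acc = cluster_label_accuracy(result.labels, syn.true_labels)
surv = survival_by_cluster(syn.clinical, result.patients, result.labels)
```

This prints (formatted):

```
accuracy vs planted subtypes: 0.993
silhouette: 0.296
davies_bouldin: 1.341
intra (complete, average, centroid): 6.093, 4.614, 3.227
log-rank chi2=20.44, df=2, p=3.64e-05
```

The pipeline recovers 149/150 planted subtype memberships; the three
recovered clusters separate survival strongly (the generator plants a
fourfold hazard range across subtypes), which is what the log-rank
p-value measures.

The same pipeline is available from the shell:

```bash
lapstrat simulate --out-dir cohort/ --seed 1
lapstrat cluster --network cohort/net.tsv --mutations cohort/mut.tsv \
    --method lp --sigma 0.1 --k 3 --runs 30 --seed 1 \
    --out-labels labels.tsv --out-consensus consensus.tsv
lapstrat survival --clinical cohort/clinical.tsv --labels labels.tsv \
    --time-unit months --out survival.json
```

plus `smooth`, `gnmf`, `evaluate`, `full` (whole pipeline from a JSON
config) and `repeat` (independent-seed repetitions for method-comparison
boxplots).

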