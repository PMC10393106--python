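# Methods

## Smoothing model

A gene–gene interaction network with raw weighted adjacency W is
normalized before any propagation. Three modes exist; the default is the
symmetric normalization A = Dg^(-1/2) W Dg^(-1/2) (Dg = raw degree
diagonal). The Laplacian is computed from the *normalized* adjacency:
D = diag(row sums of A), L = D − A. Under symmetric normalization A is
symmetric, L is diagonally dominant and hence positive semidefinite, and
L + σI is symmetric positive definite for every shift σ > 0. This is the
deciding reason symmetric is the default: the method's selling point is
well-posedness of the smoothing system, and only the symmetric mode
guarantees it structurally. Row (row-stochastic, Dg^(-1)W) and column
(W Dg^(-1)) modes are provided for fidelity experiments; for every mode
L = D − A entrywise, so L·1 = 0.

**Label propagation.** Each patient's binary mutation vector f0 is
smoothed to f = (L + σI)^(-1) f0, i.e. the minimizer of a graph
quadratic coupling term plus the ridge penalty σ‖f‖². We *solve*
(L + σI) f = f0 (sparse LU factorization shared across patients; a CG
fallback engages above 10,000 genes) and verify the per-patient relative
residual ≤ tol (default 1e-8) before returning.
`stationarity_diagnostics` reports the smoothness quadratic form
Σ A_ij (f_i − f_j)², the sparsity ‖f‖², and the first-order residual
‖(L+σI)f − f0‖, which is the authoritative optimality check.

σ defaults to 0.1 with the grid {0.01, 0.1, 0.2} exercised throughout
tests; smaller σ diffuses further, larger σ pins the result to f0
(as σ → ∞, σf → f0).

**RWR baseline.** The iteration F_{t+1} = α F_t A + (1−α) F0 is taken as
the canonical convention: α multiplies the diffusion term, and the exact
fixed point is F = (1−α) F0 (I − αA)^(-1). A second convention in
circulation prints F = α (I − (1−α)A)^(-1) F0, i.e. the two α roles
swapped; it is reproducible via `eq8_convention=True`. We implement both
because both appear in the stratification literature and they differ
only by the substitution α ↔ 1−α. The iterative solver stops when the
max-norm of successive iterates drops below tol (default 1e-8, cap 500
iterations) and errors out rather than returning an unconverged result.

**Quantile normalization** maps every patient row onto the per-rank mean
reference distribution (ties receive the mean of their tied-rank
reference values). It is applied across patients by default — profiles
are patient vectors — with a per-gene option for sensitivity analysis.
(L + σI)^(-1) is not an M-matrix in general, so smoothed values can be
(slightly) negative; negatives are clipped to zero before NMF and the
clipped mass is logged.

## GNMF

The smoothed patients × genes matrix is transposed to F (genes ×
patients) and factorized as F ≈ WH (W genes × k, H k × patients)
minimizing ‖F − WH‖² + λ·Tr(HLHᵀ), where L = D − A is the unnormalized
Laplacian of a K-nearest-neighbor graph over patients (or-rule
symmetrization, Euclidean distances, weight 1, distance ties broken by
index). The standard multiplicative updates

    W ← W ∘ (FHᵀ)/(WHHᵀ),   H ← H ∘ (WᵀF + λHA)/(WᵀWH + λHD)

preserve nonnegativity and never increase the objective (guarded by
ε = 1e-12 denominators). Initialization is entrywise uniform(0,1) scaled
by mean(F)/k, seeded; multiplicative updates self-correct the scale
within a few iterations, so only the seed matters. Defaults: λ = 1,
knn_k = 11, max 250 iterations, stop at relative objective change
< 1e-4. λ and knn_k have no canonical values in this problem setting;
both are exposed everywhere. The KNN graph is built from the profiles of
the same subsample being factorized (an influence-matrix source is the
historical alternative; profiles are the default because they require no
extra operator and behave equivalently on the cohorts tested).
Patients are assigned to argmax over H rows (ties → lowest index).

## Consensus

Each of n_runs (default 100) runs subsamples floor(0.8·n) patients and
genes without replacement, smooths the subsampled matrix on the induced
subnetwork (genes isolated by the subsample are dropped for that run),
quantile-normalizes, clips, fits GNMF and assigns clusters. Subsampling
*before* smoothing is the default ordering since the subsampled gene set
defines the run's network; `smooth_first` smooths the full matrix once
and subsamples patients only. The co-clustering matrix normalizes
co-assignment counts by **co-sampling** counts, not by n_runs — with 80%
subsampling a pair is absent from ~36% of runs and dividing by the total
would bias every entry downward. Never-co-sampled pairs get C = 0 and
are reported (they must be rare at the defaults). Final labels:
average linkage on 1 − C, tree cut to k clusters — the consensus
clustering standard. Per-run RNG streams are derived from
(master seed, run index), so any single run can be reproduced
independently and the whole result is byte-deterministic.

## Evaluation

All metrics use exact Euclidean distances (`scipy.spatial.distance`);
silhouette and Davies–Bouldin are computed from their definitions rather
than through scikit-learn because the quadratic-expansion distance
shortcut used there costs ~1e-8 of precision, which matters for
oracle-agreement guarantees (sklearn remains an independent cross-check
in the test suite). Conventions: silhouette of singleton-cluster points
is 0 and 0/0 → 0; Davies–Bouldin errors on coincident centroids of
distinct clusters; intra-cluster complete/average/centroid distances are
unweighted means over clusters with singletons contributing 0.
Cluster-to-label accuracy uses optimal one-to-one assignment on the
confusion matrix (Hungarian algorithm); with unequal cluster/label
counts the smaller side is matched and unmatched samples count as wrong.

Survival analysis delegates to lifelines (the standard survival package
in this domain): Kaplan–Meier product-limit curves per cluster and the
g-sample log-rank test (hypergeometric observed-vs-expected, chi-square
with g − 1 df). An optional 5-year truncation right-censors at 1825
days; the time unit is caller-declared metadata throughout.

## Synthetic cohorts

The generator plants exactly the structure the method assumes: a
stochastic-block-model network (equal modules = subtypes), per-patient
Poisson(10) mutation counts placed in the patient's subtype module with
probability β = 0.8 (else uniformly elsewhere), exponential survival
with per-subtype hazards (0.02, 0.04, 0.08)/month — median survivals of
roughly 35/17/9 months, a clinically plausible spread — and 30% of
patients right-censored uniformly before their event time. The default
condition is 150 patients × 300 genes × 3 subtypes with p_in = 0.1,
p_out = 0.005. These defaults are the strong-signal study condition used
by the recovery checks; β = 1/k with equal hazards gives the null
condition used for calibration.

What the generator does *not* emulate: hypermutator patients (heavy-
tailed mutation counts), scale-free network topology (an SBM's degree
distribution is Poisson-like), overlapping pathway modules, and
covariate-dependent censoring. Passing recovery tests therefore
demonstrate correctness of the machinery under the model's own
assumptions, not performance on real cohorts.

## Pipeline defaults and problem sizes

`run_full` applies the low-mutation gene filter (drop genes with < 10
mutations cohort-wide, the standard preprocessing for TCGA-scale
cohorts) before alignment. Synthetic cohorts at the default scale have
per-gene mutation counts near 5 by construction, so synthetic runs use
threshold 0; the threshold is an explicit config field either way.

Verification runs use deliberately modest sizes — random graphs of
25–60 nodes against dense oracles, the 150 × 300 default cohort with 30
consensus runs for recovery, 10-run consensus for the five-repeat
method comparison, 2000 simulations for log-rank calibration — chosen so
the whole verification suite re-derives every claim in well under a
minute while keeping each check statistically meaningful.

## Known limitations

- The semi-supervised known/unknown-label framing sometimes attached to
  label propagation has no operational counterpart here: the smoother
  uses every patient's full mutation vector and no held-out labels.
- Nonnegativity of (L+σI)^(-1) f0 is not guaranteed in general; clipping
  before NMF is a pragmatic fix and the clipped mass is logged so a
  pathological case would be visible.
- `fcluster(..., criterion="maxclust")` can return fewer than k clusters
  on degenerate consensus matrices (e.g. exactly duplicated rows).
- k (the number of subtypes) is an input, matching the predefined-
  subtype-count design; no model-order selection is attempted.
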