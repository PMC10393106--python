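"""End-to-end orchestration: smooth → consensus GNMF → evaluate → survival.

:func:`run_full` executes one complete stratification run from input
files (or in-memory objects) into an artifact directory containing the
final labels, the co-clustering matrix, the internal clustering metrics,
the survival report and the fully resolved configuration; re-running
from that configuration reproduces every numeric output byte-for-byte.
:func:`repeat_runs` repeats the whole pipeline with independent master
seeds and collects the per-repeat metrics in a long-format table.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import consensus as consensus_mod
from .data_model import (
    ClinicalTable,
    GeneNetwork,
    MutationCohort,
    align_to_network,
    filter_low_mutation_genes,
    load_clinical,
    load_mutation_matrix,
    load_network,
    write_labels,
    write_metrics_json,
)
from .evaluation import cluster_metrics, survival_by_cluster
from .gnmf import GNMFConfig
from .smoothing import PropagationConfig

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "run_full", "repeat_runs"]


@dataclass
class RunConfig:
    """All stage parameters of one full stratification run."""

    # inputs (paths; may be left None when objects are passed to run_full)
    network_path: str | None = None
    mutations_path: str | None = None
    mutations_format: str = "matrix"
    clinical_path: str | None = None
    network_has_weights: bool = False
    out_dir: str = "lapstrat_run"

    # gene filter
    min_mutations: int = 10

    # smoothing
    method: str = "label_propagation"
    sigma: float = 0.1
    alpha: float = 0.7
    norm_mode: str = "symmetric"
    quantile_normalize: bool = True
    eq8_convention: bool = False

    # GNMF
    k: int = 4
    lam: float = 1.0
    knn_k: int = 11
    gnmf_max_iter: int = 250
    gnmf_tol: float = 1e-4

    # consensus
    n_runs: int = 100
    fraction: float = 0.8
    smooth_first: bool = False
    seed: int = 0

    # survival
    truncate_5y: bool = False
    time_unit: str = "days"

    def prop_config(self) -> PropagationConfig:
        return PropagationConfig(
            method=self.method,
            sigma=self.sigma,
            alpha=self.alpha,
            quantile_normalize=self.quantile_normalize,
            eq8_convention=self.eq8_convention,
        )

    def gnmf_config(self) -> GNMFConfig:
        return GNMFConfig(
            k=self.k,
            lam=self.lam,
            knn_k=self.knn_k,
            max_iter=self.gnmf_max_iter,
            tol=self.gnmf_tol,
        )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


@dataclass
class RunResult:
    config: RunConfig
    labels: np.ndarray
    patients: list[str]
    metrics: dict
    survival: dict | None
    out_dir: Path
    consensus: "consensus_mod.ConsensusResult" = field(repr=False, default=None)


def _load_inputs(
    config: RunConfig,
    network: GeneNetwork | None,
    cohort: MutationCohort | None,
    clinical: ClinicalTable | None,
):
    if network is None:
        if config.network_path is None:
            raise ValueError("no network given (path or object)")
        network = load_network(config.network_path, has_weights=config.network_has_weights)
    if cohort is None:
        if config.mutations_path is None:
            raise ValueError("no mutation matrix given (path or object)")
        cohort = load_mutation_matrix(config.mutations_path, format=config.mutations_format)
    if clinical is None and config.clinical_path is not None:
        clinical = load_clinical(config.clinical_path, time_unit=config.time_unit)
    return network, cohort, clinical


def run_full(
    config: RunConfig,
    network: GeneNetwork | None = None,
    cohort: MutationCohort | None = None,
    clinical: ClinicalTable | None = None,
) -> RunResult:
    """Execute the full stratification pipeline and write its artifacts.

    Stages: gene filter → network alignment → subsampled consensus
    (smooth, quantile-normalize, GNMF, assign; repeated ``n_runs`` times)
    → hierarchy cut of the co-clustering matrix → internal clustering
    metrics on the full-cohort smoothed profiles → survival analysis if
    clinical data is available. A MANIFEST records stage completion.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}}

    def _stage(name: str, status: str = "done") -> None:
        manifest["stages"][name] = status
        with open(out / "MANIFEST.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

    config.to_json(out / "config.json")
    try:
        network, cohort, clinical = _load_inputs(config, network, cohort, clinical)
        _stage("load")
        if config.min_mutations > 0:
            cohort = filter_low_mutation_genes(cohort, config.min_mutations)
        aligned_cohort, aligned_net = align_to_network(cohort, network)
        _stage("align")

        result = consensus_mod.run_consensus(
            aligned_cohort,
            aligned_net,
            config.prop_config(),
            config.gnmf_config(),
            n_runs=config.n_runs,
            fraction=config.fraction,
            seed=config.seed,
            norm_mode=config.norm_mode,
            smooth_first=config.smooth_first,
        )
        _stage("consensus")

        write_labels(result.patients, result.labels, out / "labels.tsv")
        pd.DataFrame(result.C, index=result.patients, columns=result.patients).to_csv(
            out / "consensus.tsv", sep="\t"
        )

        # metric features: full-cohort smoothed (and QN'd) profiles
        smoothed = consensus_mod._smooth(
            aligned_cohort, aligned_net, config.prop_config(), config.norm_mode
        )
        report = cluster_metrics(smoothed.F, result.labels)
        metrics = report.to_dict()
        metrics["n_patients"] = aligned_cohort.n_patients
        metrics["n_genes"] = aligned_cohort.n_genes
        metrics["n_failed_runs"] = result.n_failed_runs
        metrics["n_masked_pairs"] = result.n_masked_pairs
        write_metrics_json(metrics, out / "metrics.json")
        _stage("evaluate")

        survival = None
        if clinical is not None:
            surv_report = survival_by_cluster(
                clinical, result.patients, result.labels, truncate_5y=config.truncate_5y
            )
            survival = surv_report.to_dict()
            write_metrics_json(survival, out / "survival.json")
            _stage("survival")
        _stage("complete")
    except Exception as exc:
        _stage("FAILED", status=f"error: {exc}")
        raise
    return RunResult(
        config=config,
        labels=result.labels,
        patients=result.patients,
        metrics=metrics,
        survival=survival,
        out_dir=out,
        consensus=result,
    )


def repeat_runs(
    config: RunConfig,
    n_repeats: int = 5,
    network: GeneNetwork | None = None,
    cohort: MutationCohort | None = None,
    clinical: ClinicalTable | None = None,
) -> pd.DataFrame:
    """Repeat the full pipeline with independent master seeds.

    Returns a long-format table (repeat, seed, metric, value) covering
    silhouette, Davies–Bouldin and the three intra-cluster distances —
    the shape needed for method-comparison boxplots.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rows = []
    base = Path(config.out_dir)
    for rep in range(n_repeats):
        seed = int(np.random.default_rng([config.seed, rep]).integers(2**31))
        cfg = dataclasses.replace(
            config, seed=seed, out_dir=str(base / f"repeat_{rep:02d}")
        )
        result = run_full(cfg, network=network, cohort=cohort, clinical=clinical)
        for metric in (
            "silhouette",
            "davies_bouldin",
            "intra_complete",
            "intra_average",
            "intra_centroid",
        ):
            rows.append(
                {"repeat": rep, "seed": seed, "metric": metric, "value": result.metrics[metric]}
            )
    df = pd.DataFrame(rows)
    df.to_csv(base / "repeat_metrics.tsv", sep="\t", index=False)
    return df
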