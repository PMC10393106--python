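"""Core domain types and I/O for network-based tumor stratification.

The three inputs of a stratification run are a gene–gene interaction
network (edge list), a binary somatic mutation matrix (patients × genes,
entries in {0, 1}) and an optional clinical table with survival time and
an event indicator. This module holds those containers, their readers and
writers, and the alignment/filtering steps that precede smoothing:

* :func:`filter_low_mutation_genes` removes genes carrying fewer than a
  threshold number of mutations across the cohort (default 10);
* :func:`align_to_network` restricts the cohort and the network to their
  common gene universe and drops genes that would be isolated there —
  isolated nodes are exactly the ill-conditioning case network smoothing
  must avoid.

All tables are tab-delimited UTF-8 with a header row; the first column
holds row labels. Gene and patient identifiers are case-sensitive strings.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneNetwork",
    "MutationCohort",
    "ClinicalTable",
    "ParseError",
    "load_network",
    "load_mutation_matrix",
    "load_clinical",
    "filter_low_mutation_genes",
    "align_to_network",
    "write_mutation_matrix",
    "write_labels",
    "load_labels",
    "write_metrics_json",
]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


def _edge_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class GeneNetwork:
    """Undirected weighted gene–gene graph.

    ``genes`` is an ordered node list; ``edges`` maps lexicographically
    sorted gene pairs to positive weights. Self-loops are forbidden and
    the graph is stored symmetrically by construction (one entry per
    unordered pair).
    """

    genes: list[str]
    edges: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers in network")
        universe = set(self.genes)
        for (a, b), w in self.edges.items():
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if w <= 0:
                raise ValueError(f"non-positive weight on edge {(a, b)}")
            if a not in universe or b not in universe:
                raise ValueError(f"edge endpoint not in gene list: {(a, b)}")

    @property
    def n(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> dict[str, float]:
        """Weighted degree per gene (0.0 for isolated genes)."""
        deg = {g: 0.0 for g in self.genes}
        for (a, b), w in self.edges.items():
            deg[a] += w
            deg[b] += w
        return deg

    def subgraph(self, keep: Sequence[str], drop_isolated: bool = True) -> "GeneNetwork":
        """Induced subgraph on ``keep`` (order preserved from ``keep``).

        Genes that have no surviving edge are dropped when
        ``drop_isolated`` is set, since downstream operators require
        every node to have degree >= 1.
        """
        keep_set = set(keep)
        edges = {
            k: w for k, w in self.edges.items() if k[0] in keep_set and k[1] in keep_set
        }
        if drop_isolated:
            touched = set()
            for a, b in edges:
                touched.add(a)
                touched.add(b)
            genes = [g for g in keep if g in touched]
        else:
            genes = [g for g in keep if g in set(self.genes)]
        return GeneNetwork(genes=genes, edges=edges)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("gene1\tgene2\tweight\n")
            for (a, b), w in sorted(self.edges.items()):
                fh.write(f"{a}\t{b}\t{w!r}\n")


@dataclass
class MutationCohort:
    """Binary somatic mutation matrix, patients × genes."""

    patients: list[str]
    genes: list[str]
    M: np.ndarray

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M)
        if self.M.shape != (len(self.patients), len(self.genes)):
            raise ValueError(
                f"matrix shape {self.M.shape} does not match "
                f"{len(self.patients)} patients × {len(self.genes)} genes"
            )
        if len(set(self.patients)) != len(self.patients):
            raise ValueError("duplicate patient identifiers")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers")
        bad = ~np.isin(self.M, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary entry {self.M[i, j]!r} at "
                f"(patient {self.patients[i]!r}, gene {self.genes[j]!r})"
            )
        self.M = self.M.astype(np.int8)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str]]
    ) -> "MutationCohort":
        """Build a cohort from (patient, gene) mutation pairs.

        Duplicate pairs are idempotent; patient/gene order is first
        appearance in the pair stream.
        """
        patients: list[str] = []
        genes: list[str] = []
        p_idx: dict[str, int] = {}
        g_idx: dict[str, int] = {}
        coords: list[tuple[int, int]] = []
        for p, g in pairs:
            if p not in p_idx:
                p_idx[p] = len(patients)
                patients.append(p)
            if g not in g_idx:
                g_idx[g] = len(genes)
                genes.append(g)
            coords.append((p_idx[p], g_idx[g]))
        M = np.zeros((len(patients), len(genes)), dtype=np.int8)
        for i, j in coords:
            M[i, j] = 1
        return cls(patients=patients, genes=genes, M=M)

    def restrict_genes(self, genes: Sequence[str]) -> "MutationCohort":
        idx = {g: j for j, g in enumerate(self.genes)}
        cols = [idx[g] for g in genes]
        return MutationCohort(
            patients=list(self.patients), genes=list(genes), M=self.M[:, cols]
        )

    def restrict_patients(self, patients: Sequence[str]) -> "MutationCohort":
        idx = {p: i for i, p in enumerate(self.patients)}
        rows = [idx[p] for p in patients]
        return MutationCohort(
            patients=list(patients), genes=list(self.genes), M=self.M[rows, :]
        )


@dataclass
class ClinicalTable:
    """Per-patient survival time, event indicator and optional covariates.

    ``event`` is 1 when death was observed, 0 for right-censoring. The
    time unit (days/months) is caller-declared metadata and carried along
    unchanged.
    """

    patients: list[str]
    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame | None = None
    time_unit: str = "days"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if len(set(self.patients)) != len(self.patients):
            raise ValueError("duplicate patient identifiers in clinical table")
        if not (len(self.patients) == len(self.time) == len(self.event)):
            raise ValueError("clinical column lengths differ")
        if (self.time < 0).any():
            raise ValueError("negative survival time")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0 or 1")

    def subset(self, patients: Sequence[str]) -> "ClinicalTable":
        idx = {p: i for i, p in enumerate(self.patients)}
        rows = [idx[p] for p in patients if p in idx]
        cov = None
        if self.covariates is not None:
            cov = self.covariates.iloc[rows].reset_index(drop=True)
        return ClinicalTable(
            patients=[self.patients[i] for i in rows],
            time=self.time[rows],
            event=self.event[rows],
            covariates=cov,
            time_unit=self.time_unit,
        )


# ---------------------------------------------------------------------------
# readers


def load_network(path: str | Path, has_weights: bool = False) -> GeneNetwork:
    """Read a 2–3 column edge list into a :class:`GeneNetwork`.

    Duplicate edges collapse to the maximum weight; self-loops are
    dropped (the node is kept); node order is first appearance. A header
    line is tolerated when its weight field is non-numeric.
    """
    path = Path(path)
    genes: list[str] = []
    seen: set[str] = set()
    edges: dict[tuple[str, str], float] = {}

    def add_gene(g: str) -> None:
        if g not in seen:
            seen.add(g)
            genes.append(g)

    n_lines = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected >=2 fields, got {line!r}")
            a, b = fields[0], fields[1]
            if has_weights:
                if len(fields) < 3:
                    raise ParseError(f"{path}:{lineno}: missing weight field")
                try:
                    w = float(fields[2])
                except ValueError:
                    if lineno == 1:  # header row
                        continue
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric weight {fields[2]!r}"
                    ) from None
            else:
                w = 1.0
            n_lines += 1
            add_gene(a)
            if a == b:
                logger.debug("dropping self-loop on %r (%s:%d)", a, path, lineno)
                continue
            add_gene(b)
            key = _edge_key(a, b)
            edges[key] = max(w, edges.get(key, 0.0))
    if n_lines == 0:
        raise ParseError(f"{path}: empty edge list")
    return GeneNetwork(genes=genes, edges=edges)


def load_mutation_matrix(path: str | Path, format: str = "matrix") -> MutationCohort:
    """Read a mutation cohort from TSV.

    ``format='matrix'``: patients as rows, genes as columns, {0,1} cells.
    ``format='pairs'``: two columns (patient, gene), one mutation per line.
    """
    path = Path(path)
    if format == "pairs":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 2:
            raise ParseError(f"{path}: pair list needs 2 columns")
        pairs = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
        return MutationCohort.from_pairs(pairs)
    if format != "matrix":
        raise ValueError(f"unknown mutation format {format!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy()
    bad = ~np.isin(values, (0, 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: non-binary cell {values[i, j]!r} at "
            f"(row {df.index[i]!r}, column {df.columns[j]!r})"
        )
    return MutationCohort(
        patients=[str(p) for p in df.index],
        genes=[str(g) for g in df.columns],
        M=values.astype(np.int8),
    )


_TRUTHY = {"1", "1.0", "true", "yes", "dead", "deceased"}
_FALSY = {"0", "0.0", "false", "no", "alive", "censored"}


def _coerce_event(value) -> int | None:
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return 1
    if s in _FALSY:
        return 0
    return None


def load_clinical(path: str | Path, time_unit: str = "days") -> ClinicalTable:
    """Read a clinical TSV with columns patient, time, event[, covariates].

    Rows with missing time or event are dropped (count logged); negative
    times are an error; TRUE/FALSE-style event flags are coerced to 1/0.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    for required in ("patient", "time", "event"):
        if required not in cols:
            raise ParseError(f"{path}: missing column {required!r}")
    records = []
    dropped = 0
    for _, row in df.iterrows():
        t_raw, e_raw = row[cols["time"]], row[cols["event"]]
        if pd.isna(t_raw) or pd.isna(e_raw):
            dropped += 1
            continue
        try:
            t = float(t_raw)
        except ValueError:
            dropped += 1
            continue
        if t < 0:
            raise ParseError(f"{path}: negative time for {row[cols['patient']]!r}")
        e = _coerce_event(e_raw)
        if e is None:
            dropped += 1
            continue
        records.append((str(row[cols["patient"]]), t, e, row))
    if dropped:
        logger.info("load_clinical: dropped %d rows with missing/invalid fields", dropped)
    extra_cols = [c for c in df.columns if c not in {cols["patient"], cols["time"], cols["event"]}]
    cov = None
    if extra_cols:
        cov = pd.DataFrame([{c: r[3][c] for c in extra_cols} for r in records])
    return ClinicalTable(
        patients=[r[0] for r in records],
        time=np.array([r[1] for r in records]),
        event=np.array([r[2] for r in records]),
        covariates=cov,
        time_unit=time_unit,
    )


# ---------------------------------------------------------------------------
# filtering and alignment


def filter_low_mutation_genes(
    cohort: MutationCohort, min_mutations: int = 10
) -> MutationCohort:
    """Keep genes mutated in at least ``min_mutations`` patients.

    Genes with fewer than the threshold mutations across the cohort are
    removed; column order of the survivors is preserved and the patient
    set is untouched.
    """
    if min_mutations < 0:
        raise ValueError("min_mutations must be >= 0")
    counts = np.asarray(cohort.M, dtype=np.int64).sum(axis=0)
    keep = [g for g, c in zip(cohort.genes, counts) if c >= min_mutations]
    if not keep:
        raise ValueError(
            f"all genes removed at min_mutations={min_mutations}; lower the threshold"
        )
    return cohort.restrict_genes(keep)


def align_to_network(
    cohort: MutationCohort, net: GeneNetwork
) -> tuple[MutationCohort, GeneNetwork]:
    """Restrict cohort and network to their common usable gene universe.

    Both objects end up with the identical gene ordering (cohort column
    order). Genes with no surviving edge inside the intersection are
    dropped from both, so every remaining node has degree >= 1 and the
    smoothing operators are well-posed. The operation is idempotent.
    """
    net_genes = set(net.genes)
    common = [g for g in cohort.genes if g in net_genes]
    if not common:
        raise ValueError("empty gene intersection between cohort and network")
    sub = net.subgraph(common, drop_isolated=True)
    if sub.n == 0:
        raise ValueError("no network edges survive the gene intersection")
    aligned_cohort = cohort.restrict_genes(sub.genes)
    zero_rows = int((aligned_cohort.M.sum(axis=1) == 0).sum())
    if zero_rows:
        logger.info(
            "align_to_network: %d patients have no mutations in the aligned "
            "gene universe (they smooth to the zero vector)",
            zero_rows,
        )
    return aligned_cohort, sub


# ---------------------------------------------------------------------------
# writers


def write_mutation_matrix(cohort: MutationCohort, path: str | Path) -> None:
    df = pd.DataFrame(cohort.M, index=cohort.patients, columns=cohort.genes)
    df.index.name = "patient"
    df.to_csv(path, sep="\t")


def write_labels(patients: Sequence[str], labels: Sequence[int], path: str | Path) -> None:
    df = pd.DataFrame({"patient": list(patients), "cluster": list(labels)})
    df.to_csv(path, sep="\t", index=False)


def load_labels(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", dtype={"patient": str, "cluster": int})
    return list(df["patient"]), df["cluster"].to_numpy()


def write_metrics_json(metrics: Mapping, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
        fh.write("\n")
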