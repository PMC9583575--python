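"""Readers, writers and validated containers for all on-disk artifacts.

Everything is plain TSV: expression / mutation / methylation matrices with
genes (or probes) in rows and samples in columns, two-column edge lists for
the background interaction network, and driver-module files consisting of a
small ``# key: value`` header block followed by a canonical edge list.

Gene identity throughout the package is the bare symbol string,
case-sensitive, with no aliasing or identifier mapping: users must
pre-harmonize symbols across the expression, mutation, methylation and
network files themselves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: Annotation region labels counted as promoter for probe consolidation.
PROMOTER_REGIONS = frozenset({"TSS1500", "TSS200", "5'UTR", "1stExon"})

DRIVER_TYPES = ("mutation", "methylation", "co")


class ValidationError(ValueError):
    """Raised when an input file or container violates its contract."""


def canonical_edge(u: str, v: str) -> tuple[str, str]:
    """Return the undirected edge (u, v) with endpoints in lexicographic order."""
    return (u, v) if u <= v else (v, u)


# ---------------------------------------------------------------------------
# Expression


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of non-negative expression values (FPKM scale).

    Samples are partitioned into a *reference* cohort (normal tissue) and
    *case* samples (tumors); the two sets must be disjoint.
    """

    values: pd.DataFrame  # genes in rows, samples in columns
    reference_ids: list[str]
    case_ids: list[str]

    def __post_init__(self) -> None:
        overlap = set(self.reference_ids) & set(self.case_ids)
        if overlap:
            raise ValidationError(
                f"samples assigned to both reference and case roles: {sorted(overlap)}"
            )
        idx = self.values.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValidationError(f"duplicate gene symbol: {dup!r}")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate sample identifiers")
        missing = (set(self.reference_ids) | set(self.case_ids)) - set(self.values.columns)
        if missing:
            raise ValidationError(f"samples not present in matrix: {sorted(missing)}")
        if self.values.isna().any().any():
            raise ValidationError("expression matrix contains missing values")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("expression matrix contains negative values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def reference(self) -> pd.DataFrame:
        return self.values[self.reference_ids]

    def case(self) -> pd.DataFrame:
        return self.values[self.case_ids]


def read_expression(
    path: str | Path, reference_ids: Iterable[str], case_ids: Iterable[str]
) -> ExpressionMatrix:
    """Load an expression TSV (header row of sample ids, first column genes).

    Rows containing any non-numeric, missing or negative value are dropped,
    with counts logged; a duplicated gene symbol is a hard error.
    """
    reference_ids = list(reference_ids)
    case_ids = list(case_ids)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise ValidationError(f"duplicate gene symbol in {path}: {dup!r}")
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad_numeric = values.isna().any(axis=1)
    bad_negative = (values < 0).any(axis=1) & ~bad_numeric
    for gene in values.index[bad_numeric]:
        logger.warning("dropping gene %s: non-numeric or missing expression value", gene)
    for gene in values.index[bad_negative]:
        logger.warning("dropping gene %s: negative expression value", gene)
    n_dropped = int(bad_numeric.sum() + bad_negative.sum())
    if n_dropped:
        logger.info("read_expression: dropped %d of %d gene rows", n_dropped, len(values))
    values = values.loc[~(bad_numeric | bad_negative)]
    return ExpressionMatrix(values[reference_ids + case_ids], reference_ids, case_ids)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", float_format="%.10g", index_label="gene")


# ---------------------------------------------------------------------------
# Background network


@dataclass
class BackgroundNetwork:
    """Undirected simple graph over gene symbols; the universe of testable edges."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def from_edges(cls, pairs: Iterable[tuple[str, str]]) -> "BackgroundNetwork":
        """Canonicalize an edge iterable: drop self-loops and duplicates (counted)."""
        g = nx.Graph()
        n_self = n_dup = 0
        for u, v in pairs:
            if u == v:
                n_self += 1
                continue
            e = canonical_edge(str(u), str(v))
            if g.has_edge(*e):
                n_dup += 1
                continue
            g.add_edge(*e)
        if n_self or n_dup:
            logger.info(
                "background network: dropped %d self-loops, %d duplicate edges",
                n_self,
                n_dup,
            )
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        """Canonical edges in sorted order (deterministic across runs)."""
        return sorted(canonical_edge(u, v) for u, v in self.graph.edges)

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()


def read_edge_list(path: str | Path) -> BackgroundNetwork:
    """Load a two-column TSV of gene pairs; extra columns are ignored."""
    rows = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if rows.empty:
        raise ValidationError(f"empty edge list: {path}")
    if rows.shape[1] < 2:
        raise ValidationError(f"edge list needs two columns: {path}")
    return BackgroundNetwork.from_edges(
        zip(rows.iloc[:, 0].astype(str), rows.iloc[:, 1].astype(str))
    )


def write_edge_list(network: BackgroundNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v in network.edges:
            fh.write(f"{u}\t{v}\n")


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    """Export a module or network graph for visualization tools."""
    nx.write_graphml(graph, path)


# ---------------------------------------------------------------------------
# Probe annotation and subtype labels


def read_probe_annotation(path: str | Path) -> pd.DataFrame:
    """Load a probe annotation TSV with columns probe_id, gene, region.

    A probe mapping to several genes (comma- or semicolon-separated gene
    field) is expanded to one row per gene and flagged ``multi_mapped``.
    Unknown region labels are preserved but marked non-promoter.
    """
    ann = pd.read_csv(path, sep="\t", dtype=str)
    required = {"probe_id", "gene", "region"}
    if not required.issubset(ann.columns):
        raise ValidationError(f"annotation must have columns {sorted(required)}")
    if ann["probe_id"].duplicated().any():
        raise ValidationError("annotation probe_id column must be unique")
    ann = ann.copy()
    ann["gene"] = ann["gene"].str.replace(";", ",")
    ann["multi_mapped"] = ann["gene"].str.contains(",")
    n_multi = int(ann["multi_mapped"].sum())
    if n_multi:
        logger.info("annotation: %d probes map to multiple genes (kept for each)", n_multi)
    ann = ann.assign(gene=ann["gene"].str.split(",")).explode("gene")
    ann["gene"] = ann["gene"].str.strip()
    ann = ann.drop_duplicates(subset=["probe_id", "gene"])
    ann["is_promoter"] = ann["region"].isin(PROMOTER_REGIONS)
    return ann.reset_index(drop=True)


def read_subtype_labels(path: str | Path, case_ids: Iterable[str] | None = None) -> dict[str, str]:
    """Load a sample -> subtype TSV (two columns, no header required)."""
    rows = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if rows.shape[1] < 2:
        raise ValidationError("subtype label file needs two columns")
    labels: dict[str, str] = {}
    for sample, subtype in zip(rows.iloc[:, 0], rows.iloc[:, 1]):
        if not isinstance(subtype, str) or not subtype.strip():
            raise ValidationError(f"empty subtype name for sample {sample!r}")
        labels[str(sample)] = subtype.strip()
    if case_ids is not None:
        unknown = set(labels) - set(case_ids)
        if unknown:
            raise ValidationError(f"labeled samples not in case set: {sorted(unknown)}")
    return labels


# ---------------------------------------------------------------------------
# Driver modules


@dataclass(frozen=True)
class DriverModule:
    """Per-sample driver module: seed genes plus retained SSN edges.

    ``driver_type`` is one of ``mutation`` (seeded on mutated genes),
    ``methylation`` (seeded on aberrantly methylated genes) or ``co``
    (edge union of the two).
    """

    sample_id: str
    driver_type: str
    seeds: frozenset[str]
    edges: frozenset[tuple[str, str]]
    params: tuple[tuple[str, object], ...] = ()

    def __post_init__(self) -> None:
        if self.driver_type not in DRIVER_TYPES:
            raise ValidationError(f"unknown driver_type: {self.driver_type!r}")
        for u, v in self.edges:
            if (u, v) != canonical_edge(u, v):
                raise ValidationError(f"non-canonical edge ({u!r}, {v!r})")

    @property
    def genes(self) -> frozenset[str]:
        """Endpoint union of the module's edges."""
        return frozenset(g for e in self.edges for g in e)

    @property
    def params_dict(self) -> dict[str, object]:
        return dict(self.params)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_edges_from(self.edges)
        return g


def _format_param(value: object) -> str:
    return repr(value) if isinstance(value, float) else str(value)


def _parse_param(text: str) -> object:
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    return text


def write_module(module: DriverModule, path: str | Path) -> None:
    """Serialize a module: ``# key: value`` header block then a TSV edge list."""
    with open(path, "w") as fh:
        fh.write(f"# sample_id: {module.sample_id}\n")
        fh.write(f"# driver_type: {module.driver_type}\n")
        fh.write(f"# seeds: {','.join(sorted(module.seeds))}\n")
        for key in sorted(module.params_dict):
            fh.write(f"# param.{key}: {_format_param(module.params_dict[key])}\n")
        fh.write("gene_a\tgene_b\n")
        for u, v in sorted(module.edges):
            fh.write(f"{u}\t{v}\n")


def read_module(path: str | Path) -> DriverModule:
    header: dict[str, str] = {}
    edges: set[tuple[str, str]] = set()
    with open(path) as fh:
        lines = fh.read().splitlines()
    body_start = None
    for i, line in enumerate(lines):
        if line.startswith("# "):
            if ": " not in line:
                raise ValidationError(f"malformed header line in {path}: {line!r}")
            key, value = line[2:].split(": ", 1)
            header[key] = value
        else:
            body_start = i
            break
    if body_start is None or lines[body_start] != "gene_a\tgene_b":
        raise ValidationError(f"missing edge-list header row in {path}")
    for key in ("sample_id", "driver_type", "seeds"):
        if key not in header:
            raise ValidationError(f"module header missing {key!r} in {path}")
    for line in lines[body_start + 1 :]:
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValidationError(f"malformed edge row in {path}: {line!r}")
        edges.add(canonical_edge(parts[0], parts[1]))
    seeds = frozenset(s for s in header["seeds"].split(",") if s)
    params = tuple(
        sorted(
            (key[len("param.") :], _parse_param(value))
            for key, value in header.items()
            if key.startswith("param.")
        )
    )
    return DriverModule(
        sample_id=header["sample_id"],
        driver_type=header["driver_type"],
        seeds=seeds,
        edges=frozenset(edges),
        params=params,
    )


# ---------------------------------------------------------------------------
# Generic matrices (mutation / ternary methylation)


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "gene") -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", index_label=index_label)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_methylation(path: str | Path) -> pd.DataFrame:
    """Load a probe x sample beta matrix; values must be in [0, 1] or missing."""
    beta = pd.read_csv(path, sep="\t", index_col=0)
    arr = beta.to_numpy(dtype=float)
    bad = ((arr < 0) | (arr > 1)) & ~pd.isna(arr)
    if bad.any():
        raise ValidationError("methylation beta values must lie in [0, 1]")
    return beta


def labels_to_frame(labels: Mapping[str, str]) -> pd.DataFrame:
    return pd.DataFrame(
        {"sample": list(labels.keys()), "subtype": list(labels.values())}
    )
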