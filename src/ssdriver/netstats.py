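"""Structural analytics on driver modules: centralities, Jaccard similarity, rank tests.

Centralities follow the conventions useful for comparing distributions of
gene classes (seed genes vs their neighbors vs others): degree is the raw
connection count, betweenness is unnormalized shortest-path betweenness
(the 5-node star center scores (n-1)(n-2)/2 = 6), and eigenvector centrality
is computed per connected component and normalized globally to unit maximum.

The Jaccard similarity of a sample's mutation and methylation modules
(gene sets or edge sets) is |A n B| / |A u B|, 0 by convention when both are
empty.  Two-group comparisons use the Wilcoxon rank-sum test (Mann-Whitney U
with continuity correction in the asymptotic regime), multi-group
comparisons the Kruskal-Wallis test, and all-pairs post-hoc comparisons the
Nemenyi test on rank sums via the studentized range distribution.
"""

from __future__ import annotations

import itertools
import logging
from typing import Hashable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import DriverModule, ValidationError

logger = logging.getLogger(__name__)

GENE_CLASSES = (
    "mutation_seed",
    "methylation_seed",
    "mutation_neighbor",
    "methylation_neighbor",
    "other",
)


def centralities(graph: nx.Graph, normalized_betweenness: bool = False) -> pd.DataFrame:
    """Degree, betweenness and eigenvector centrality per node of a module graph.

    Eigenvector centrality is obtained by power iteration (tolerance 1e-10)
    on each connected component separately, then scaled so the global
    maximum is 1; an empty graph yields an empty table.
    """
    if graph.number_of_nodes() == 0:
        return pd.DataFrame(columns=["degree", "betweenness", "eigenvector"])
    degree = dict(graph.degree())
    betweenness = nx.betweenness_centrality(graph, normalized=normalized_betweenness)
    eigen: dict[Hashable, float] = {}
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        if sub.number_of_nodes() == 1:
            eigen[next(iter(comp))] = 0.0
            continue
        eigen.update(nx.eigenvector_centrality(sub, max_iter=10000, tol=1e-10))
    peak = max(eigen.values(), default=0.0)
    if peak > 0:
        eigen = {g: v / peak for g, v in eigen.items()}
    nodes = sorted(graph.nodes)
    return pd.DataFrame(
        {
            "degree": [degree[g] for g in nodes],
            "betweenness": [betweenness[g] for g in nodes],
            "eigenvector": [eigen[g] for g in nodes],
        },
        index=pd.Index(nodes, name="gene"),
    )


def classify_genes(
    graph: nx.Graph,
    mutation_seeds: frozenset[str] | set[str],
    methylation_seeds: frozenset[str] | set[str],
) -> dict[str, frozenset[str]]:
    """Class labels per module gene; a gene may carry several labels."""
    labels: dict[str, set[str]] = {g: set() for g in graph.nodes}
    for g in graph.nodes:
        if g in mutation_seeds:
            labels[g].add("mutation_seed")
        if g in methylation_seeds:
            labels[g].add("methylation_seed")
        neighbors = set(graph.neighbors(g))
        if neighbors & set(mutation_seeds) and g not in mutation_seeds:
            labels[g].add("mutation_neighbor")
        if neighbors & set(methylation_seeds) and g not in methylation_seeds:
            labels[g].add("methylation_neighbor")
        if not labels[g]:
            labels[g].add("other")
    return {g: frozenset(v) for g, v in labels.items()}


def module_centrality_table(
    module: DriverModule,
    mutation_seeds: frozenset[str] | set[str],
    methylation_seeds: frozenset[str] | set[str],
) -> pd.DataFrame:
    """Tidy per-gene centrality table for one module, with class labels."""
    graph = module.graph()
    table = centralities(graph)
    if table.empty:
        return table.assign(classes="", sample_id=module.sample_id)
    labels = classify_genes(graph, mutation_seeds, methylation_seeds)
    table = table.assign(
        classes=[";".join(sorted(labels[g])) for g in table.index],
        sample_id=module.sample_id,
    )
    return table


def jaccard(a: set | frozenset, b: set | frozenset) -> float:
    """|a n b| / |a u b|; 0 by convention when both sets are empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        logger.warning("jaccard of two empty sets; returning 0 by convention")
        return 0.0
    return len(a & b) / len(union)


def module_similarity(
    mutation_module: DriverModule, methylation_module: DriverModule, on: str = "edges"
) -> float:
    """Jaccard similarity of a sample's two driver modules, on edges or genes."""
    if on == "edges":
        return jaccard(mutation_module.edges, methylation_module.edges)
    if on == "genes":
        return jaccard(mutation_module.genes, methylation_module.genes)
    raise ValidationError(f"similarity basis must be 'edges' or 'genes', got {on!r}")


# ---------------------------------------------------------------------------
# Rank-based group comparisons


def compare_two_groups(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    paired: bool = False,
):
    """Wilcoxon test for two groups: rank-sum (unpaired) or signed-rank (paired)."""
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each group needs at least 2 observations")
    if paired:
        return stats.wilcoxon(x, y, alternative=alternative)
    return stats.mannwhitneyu(x, y, alternative=alternative, use_continuity=True)


def kruskal_wallis(groups: Mapping[str, Sequence[float]]):
    """Kruskal-Wallis rank test across named groups."""
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    for name, values in groups.items():
        if len(values) < 2:
            raise ValidationError(f"group {name!r} has fewer than 2 observations")
    return stats.kruskal(*groups.values())


def nemenyi(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """All-pairs Nemenyi post-hoc test on rank sums.

    For groups i, j with mean ranks Rbar_i, Rbar_j over the pooled ranking of
    N observations in k groups, the statistic

        q = |Rbar_i - Rbar_j| / sqrt(N (N + 1) / 12 * (1/n_i + 1/n_j))

    is referred to the studentized range distribution with k groups and
    infinite degrees of freedom (p = P(Q_{k,inf} > q * sqrt(2))).  Returns a
    symmetric DataFrame of pairwise p-values with 1.0 on the diagonal.
    """
    if len(groups) < 3:
        raise ValidationError("Nemenyi post-hoc needs at least 3 groups")
    names = list(groups)
    sizes = {g: len(groups[g]) for g in names}
    pooled = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    ranks = stats.rankdata(pooled)
    mean_rank: dict[str, float] = {}
    offset = 0
    for g in names:
        mean_rank[g] = float(ranks[offset : offset + sizes[g]].mean())
        offset += sizes[g]
    n_total = len(pooled)
    k = len(names)
    out = pd.DataFrame(1.0, index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(n_total * (n_total + 1) / 12.0 * (1.0 / sizes[a] + 1.0 / sizes[b]))
        q = abs(mean_rank[a] - mean_rank[b]) / se
        p = float(stats.studentized_range.sf(q * np.sqrt(2.0), k, np.inf))
        out.loc[a, b] = out.loc[b, a] = min(1.0, p)
    return out
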