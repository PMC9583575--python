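"""Shared fixtures and independent brute-force oracles used across the suite."""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ssdriver.io_formats import BackgroundNetwork, ExpressionMatrix, canonical_edge
from ssdriver.ssn import SampleSpecificNetwork


def ssn_from_edges(sample_id: str, edges, alpha: float = 0.01) -> SampleSpecificNetwork:
    """Wrap a bare edge list as an SSN (dummy statistics), for module-stage tests."""
    edges = [canonical_edge(u, v) for u, v in edges]
    table = pd.DataFrame(
        {
            "gene_a": [e[0] for e in edges],
            "gene_b": [e[1] for e in edges],
            "pcc_n": 0.0,
            "pcc_n1": 0.0,
            "delta": 0.0,
            "z": 0.0,
            "p": alpha / 2 if edges else [],
        }
    )
    return SampleSpecificNetwork(sample_id=sample_id, alpha=alpha, table=table,
                                 n_tested=len(edges))


def brute_force_ssn_edges(ref: np.ndarray, case: np.ndarray, edges, alpha: float, n: int):
    """Naive SSN retention: per-edge correlation loops + normal CDF, no shortcuts."""
    retained = []
    for i, j in edges:
        xr, yr = ref[i], ref[j]
        rn = float(np.corrcoef(xr, yr)[0, 1])
        if abs(rn) >= 1 - 1e-12:
            continue
        rn1 = float(np.corrcoef(np.append(xr, case[i]), np.append(yr, case[j]))[0, 1])
        z = (rn1 - rn) / ((1 - rn**2) / (n - 1))
        p = 2 * stats.norm.sf(abs(z))
        if p < alpha:
            retained.append((i, j))
    return retained


def brute_force_two_order(edges, seeds, hubs):
    """Independent membership test of the 2-order/hub edge-retention rule.

    Enumerates every SSN edge and tests the two retention clauses directly.
    """
    adj: dict = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    seeds = set(seeds) & set(adj)
    kept = set()
    for u, v in edges:
        e = canonical_edge(u, v)
        for s, t in ((u, v), (v, u)):
            # first order: seed -> hub neighbor
            if s in seeds and t in hubs:
                kept.add(e)
            # second order: hub neighbor of a seed -> hub
            if s in hubs and t in hubs and any(w in seeds for w in adj[s]):
                kept.add(e)
    return kept


def brute_force_betweenness(graph: nx.Graph) -> dict:
    """Unnormalized betweenness by explicit all-pairs BFS path counting."""
    bc = {v: 0.0 for v in graph}
    nodes = list(graph)
    for s_idx, s in enumerate(nodes):
        for t in nodes[s_idx + 1 :]:
            try:
                paths = list(nx.all_shortest_paths(graph, s, t))
            except nx.NetworkXNoPath:
                continue
            for path in paths:
                for v in path[1:-1]:
                    bc[v] += 1.0 / len(paths)
    return bc


def brute_force_hampel(values: list[float]) -> list[int]:
    """Literal per-gene Hampel rule on a plain list."""
    med = float(np.median(values))
    mad = float(np.median([abs(v - med) for v in values]))
    out = []
    for v in values:
        if v < med - 3 * mad:
            out.append(-1)
        elif v > med + 3 * mad:
            out.append(1)
        else:
            out.append(0)
    return out


@pytest.fixture
def tiny_expression() -> ExpressionMatrix:
    genes = ["A", "B", "C"]
    values = pd.DataFrame(
        np.array(
            [
                [1.0, 2.0, 3.0, 4.0, 5.0],
                [2.0, 1.0, 4.0, 3.0, 2.0],
                [1.0, 3.0, 2.0, 4.0, 1.0],
            ]
        ),
        index=genes,
        columns=["r1", "r2", "r3", "c1", "c2"],
    )
    return ExpressionMatrix(values, ["r1", "r2", "r3"], ["c1", "c2"])


@pytest.fixture
def star5() -> nx.Graph:
    return nx.star_graph(4)  # center 0, leaves 1..4


@pytest.fixture
def background_abc() -> BackgroundNetwork:
    return BackgroundNetwork.from_edges([("A", "B"), ("B", "C")])


def random_module_instance(rng: np.random.Generator, n_nodes: int = 20):
    """Random SSN edge set, seed set and hub set for oracle comparisons."""
    nodes = [f"g{i}" for i in range(n_nodes)]
    p_edge = 0.18
    edges = [
        (a, b)
        for i, a in enumerate(nodes)
        for b in nodes[i + 1 :]
        if rng.random() < p_edge
    ]
    seeds = set(rng.choice(nodes, size=max(1, n_nodes // 5), replace=False))
    hub_fraction = float(rng.choice([0.2, 0.3, 0.5]))
    return nodes, edges, seeds, hub_fraction


def exact_hub_set(edges, hub_fraction: float):
    """Tie-inclusive top-fraction hub computation, written independently."""
    deg: dict = {}
    for u, v in edges:
        deg[u] = deg.get(u, 0) + 1
        deg[v] = deg.get(v, 0) + 1
    if not deg:
        return set(), 0
    ordered = sorted(deg.values(), reverse=True)
    k = math.ceil(hub_fraction * len(ordered))
    thr = ordered[k - 1]
    return {g for g, d in deg.items() if d >= thr}, thr
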