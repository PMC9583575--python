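"""Cohort- and subtype-level driver modules from per-sample module collections.

An edge's occurrence frequency is the fraction of case samples whose driver
module (of a given type) contains it.  The cohort-level module keeps the
edges whose frequency exceeds a Monte Carlo cutoff: in each of
``iterations`` rounds, ``edges_per_iter`` edges are drawn uniformly from the
background universe and the empirical (1 - alpha) quantile of their observed
frequencies is recorded; the cutoff is the mean of those per-round quantiles
(10,000 rounds of 10,000 edges at alpha = 0.05 by default).  Subtype-level
modules keep the edges present in more than a threshold fraction (default
60%) of that subtype's co-driver modules; edges present in every subtype
module are *shared*, edges in exactly one are *subtype-specific*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import BackgroundNetwork, DriverModule, ValidationError

logger = logging.getLogger(__name__)


def edge_frequencies(
    modules: Sequence[DriverModule], universe: BackgroundNetwork
) -> pd.Series:
    """Occurrence frequency of every universe edge across the given modules.

    Edges never seen in any module have frequency 0; a module edge outside
    the universe is a contract breach upstream and raises.
    """
    if not modules:
        raise ValidationError("need at least one module")
    edges = universe.edges
    index = {e: i for i, e in enumerate(edges)}
    counts = np.zeros(len(edges), dtype=float)
    for module in modules:
        for e in module.edges:
            if e not in index:
                raise ValidationError(f"module edge {e} not in the background universe")
            counts[index[e]] += 1
    freq = counts / len(modules)
    return pd.Series(freq, index=pd.MultiIndex.from_tuples(edges, names=["gene_a", "gene_b"]))


def monte_carlo_cutoff(
    freq_table: pd.Series,
    iterations: int = 10000,
    edges_per_iter: int = 10000,
    alpha: float = 0.05,
    seed: int = 1,
    with_replacement: bool = True,
) -> float:
    """Mean over iterations of the per-iteration (1 - alpha) frequency quantile.

    Each iteration draws ``edges_per_iter`` edges uniformly from the
    universe (with replacement by default; without replacement requires the
    universe to be at least that large) and takes the empirical (1 - alpha)
    quantile (linear/type-7 interpolation) of their frequencies.
    Deterministic given ``seed``.
    """
    if len(freq_table) == 0:
        raise ValidationError("empty edge universe")
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    values = freq_table.to_numpy(dtype=float)
    n_edges = len(values)
    if not with_replacement and edges_per_iter > n_edges:
        raise ValidationError(
            f"cannot draw {edges_per_iter} of {n_edges} edges without replacement"
        )
    rng = np.random.default_rng(seed)
    q = 1.0 - alpha
    cutoffs = np.empty(iterations, dtype=float)
    # chunked so the index matrix never exceeds ~40 MB at full scale
    chunk = max(1, min(iterations, 500))
    done = 0
    while done < iterations:
        m = min(chunk, iterations - done)
        if with_replacement:
            idx = rng.integers(0, n_edges, size=(m, edges_per_iter))
            sampled = values[idx]
        else:
            sampled = np.stack(
                [values[rng.choice(n_edges, size=edges_per_iter, replace=False)] for _ in range(m)]
            )
        cutoffs[done : done + m] = np.quantile(sampled, q, axis=1, method="linear")
        done += m
    cutoff = float(cutoffs.mean())
    logger.info(
        "monte_carlo_cutoff: %d x %d draws, alpha=%g -> cutoff %.6f",
        iterations,
        edges_per_iter,
        alpha,
        cutoff,
    )
    return cutoff


@dataclass(frozen=True)
class CohortDriverModule:
    """Cohort-level module: edges whose frequency strictly exceeds the cutoff."""

    driver_type: str
    edges: frozenset[tuple[str, str]]
    cutoff: float
    mc_params: tuple[tuple[str, object], ...] = ()

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for e in self.edges for g in e)


def cohort_module(
    freq_table: pd.Series,
    cutoff: float,
    driver_type: str,
    mc_params: Mapping[str, object] | None = None,
) -> CohortDriverModule:
    """Edges with occurrence frequency strictly greater than the cutoff."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValidationError(f"cutoff must be in [0, 1], got {cutoff}")
    kept = freq_table[freq_table > cutoff]
    return CohortDriverModule(
        driver_type=driver_type,
        edges=frozenset(kept.index),
        cutoff=cutoff,
        mc_params=tuple(sorted((mc_params or {}).items())),
    )


@dataclass(frozen=True)
class SubtypeModules:
    """Per-subtype edge sets plus the shared and subtype-specific partitions."""

    modules: tuple[tuple[str, frozenset[tuple[str, str]]], ...]
    shared: frozenset[tuple[str, str]]
    specific: tuple[tuple[str, frozenset[tuple[str, str]]], ...]
    threshold: float

    @property
    def modules_dict(self) -> dict[str, frozenset[tuple[str, str]]]:
        return dict(self.modules)

    @property
    def specific_dict(self) -> dict[str, frozenset[tuple[str, str]]]:
        return dict(self.specific)


def subtype_modules(
    modules_by_sample: Mapping[str, DriverModule],
    labels: Mapping[str, str],
    threshold: float = 0.60,
) -> SubtypeModules:
    """Subtype driver modules: edges in more than ``threshold`` of a subtype's modules.

    Subtypes with no labeled sample that has a module are excluded with a
    warning.  ``shared`` is the intersection over all subtype modules;
    ``specific[s]`` holds the edges appearing in subtype s's module and in no
    other subtype's module.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValidationError(f"threshold must be in [0, 1), got {threshold}")
    samples_by_subtype: dict[str, list[str]] = {}
    for sample, subtype in labels.items():
        if sample not in modules_by_sample:
            raise ValidationError(f"labeled sample {sample!r} has no module")
        samples_by_subtype.setdefault(subtype, []).append(sample)

    per_subtype: dict[str, frozenset[tuple[str, str]]] = {}
    for subtype in sorted(samples_by_subtype):
        samples = samples_by_subtype[subtype]
        if not samples:
            logger.warning("subtype %s has no samples; excluded", subtype)
            continue
        counts: dict[tuple[str, str], int] = {}
        for sample in samples:
            for e in modules_by_sample[sample].edges:
                counts[e] = counts.get(e, 0) + 1
        n = len(samples)
        per_subtype[subtype] = frozenset(e for e, c in counts.items() if c / n > threshold)

    names = sorted(per_subtype)
    if names:
        shared = frozenset.intersection(*(per_subtype[s] for s in names))
    else:
        shared = frozenset()
    specific = {}
    for s in names:
        others: frozenset[tuple[str, str]] = frozenset().union(
            *(per_subtype[t] for t in names if t != s)
        )
        specific[s] = per_subtype[s] - others
    return SubtypeModules(
        modules=tuple((s, per_subtype[s]) for s in names),
        shared=shared,
        specific=tuple((s, specific[s]) for s in names),
        threshold=threshold,
    )


def module_sizes_by_subtype(
    modules_by_sample: Mapping[str, DriverModule], labels: Mapping[str, str]
) -> dict[str, list[int]]:
    """Per-sample module edge counts grouped by subtype (for Kruskal-Wallis/Nemenyi)."""
    sizes: dict[str, list[int]] = {}
    for sample, subtype in sorted(labels.items()):
        sizes.setdefault(subtype, []).append(len(modules_by_sample[sample].edges))
    return sizes
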