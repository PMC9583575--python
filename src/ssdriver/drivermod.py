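"""Per-sample driver modules: 2-order neighborhoods of seed genes, constrained to hubs.

A mutated or aberrantly methylated gene is assumed to perturb its SSN
neighbors and their neighbors (2-order network theory), but only through
well-connected genes: hub genes are the top ``hub_fraction`` (default 20%)
of SSN nodes by degree, tie-inclusive.  The retained edges for a seed set S
in an SSN with hub set H are

    { (s, u) : s in S, u adjacent to s, u in H }            (first order)
  U { (u, w) : s in S, u adjacent to s, u in H,
               w adjacent to u, w in H }                    (second order)

Seeds themselves are exempt from the hub requirement (seed genes typically
have low SSN degree); every non-seed module gene is a hub, and every module
gene lies within graph distance 2 of a seed.  The co-driver module of a
sample is the edge union of its mutation and methylation modules.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .io_formats import DriverModule, ValidationError, canonical_edge
from .ssn import SampleSpecificNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HubSet:
    """Hub genes of one sample's SSN: top fraction by degree, tie-inclusive."""

    sample_id: str
    hubs: frozenset[str]
    degree_threshold: int
    hub_fraction: float


def hub_genes(ssn: SampleSpecificNetwork, hub_fraction: float = 0.20) -> HubSet:
    """Rank SSN nodes by degree; hubs are every node whose degree reaches the
    degree of the node at rank ceil(hub_fraction * |nodes|)."""
    if not 0.0 < hub_fraction <= 1.0:
        raise ValidationError(f"hub_fraction must be in (0, 1], got {hub_fraction}")
    deg = ssn.degrees()
    if not deg:
        logger.warning("sample %s: empty SSN, empty hub set", ssn.sample_id)
        return HubSet(ssn.sample_id, frozenset(), 0, hub_fraction)
    ranked = sorted(deg.values(), reverse=True)
    k = math.ceil(hub_fraction * len(ranked))
    threshold = ranked[k - 1]
    hubs = frozenset(g for g, d in deg.items() if d >= threshold)
    return HubSet(ssn.sample_id, hubs, threshold, hub_fraction)


def two_order_module(
    ssn: SampleSpecificNetwork,
    seeds: frozenset[str] | set[str],
    hubs: HubSet,
    driver_type: str,
) -> DriverModule:
    """Apply the 2-order / hub edge-retention rule for one sample."""
    adj: dict[str, set[str]] = {}
    for u, v in ssn.edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    seeds_in = frozenset(seeds) & set(adj)
    if not seeds_in:
        logger.warning(
            "sample %s: no %s seed gene present in the SSN; empty module",
            ssn.sample_id,
            driver_type,
        )
    hub_set = hubs.hubs
    edges: set[tuple[str, str]] = set()
    for s in seeds_in:
        for u in adj[s]:
            if u not in hub_set:
                continue
            edges.add(canonical_edge(s, u))
            for w in adj[u]:
                if w in hub_set:
                    edges.add(canonical_edge(u, w))
    return DriverModule(
        sample_id=ssn.sample_id,
        driver_type=driver_type,
        seeds=frozenset(seeds),
        edges=frozenset(edges),
        params=(("hub_fraction", hubs.hub_fraction),),
    )


def co_driver_module(
    mutation_module: DriverModule, methylation_module: DriverModule
) -> DriverModule:
    """Edge-set union of a sample's mutation and methylation driver modules."""
    if mutation_module.sample_id != methylation_module.sample_id:
        raise ValidationError(
            "co-driver module requires modules of the same sample: "
            f"{mutation_module.sample_id!r} vs {methylation_module.sample_id!r}"
        )
    return DriverModule(
        sample_id=mutation_module.sample_id,
        driver_type="co",
        seeds=mutation_module.seeds | methylation_module.seeds,
        edges=mutation_module.edges | methylation_module.edges,
        params=mutation_module.params,
    )
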