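"""Synthetic multi-omics cohorts with known ground truth.

Every pipeline stage is testable without external data: a scale-free
background network, a reference cohort whose gene-gene correlation is known
on network edges, case samples with planted correlation perturbations,
binary mutation profiles, Beta-distributed promoter methylation with
planted outliers, and subtype-structured module collections.

Correlation on a network edge is induced by a shared latent factor per edge.
A gene's latent value is a loading-weighted sum of its incident edge factors
plus independent noise, with the per-edge loading budget c_e = min(r, 1/deg)
at each endpoint so the construction is valid (unit variances, any graph).
The realized edge correlation is sqrt(c_u * c_v): exactly r whenever
r * deg <= 1 at both endpoints (always true for the disjoint-pair networks
used in calibration), attenuated at hubs.  FPKM-like values are obtained by
exponentiating 0.25 x the latent Gaussian, which keeps pairwise Pearson
correlations within ~1% of their latent targets while giving skewed,
non-negative marginals.

All generators draw from independent child streams of a single master seed,
so adding one generator never perturbs another's output, and a fixed seed
fully determines every artifact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import BackgroundNetwork, ExpressionMatrix, ValidationError, canonical_edge

#: Latent-scale magnitude (in SDs) of a planted correlation perturbation.
PERTURBATION_MAGNITUDE = 5.0

#: Planted methylation outliers: promoter probes set to these beta values.
HYPER_BETA = 0.995
HYPO_BETA = 0.005


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort, fully determined by ``seed``.

    Defaults describe a desk-scale cohort with moderate co-expression
    (r = 0.4 on background edges), a 2% per-gene-per-sample nonsynonymous
    mutation rate, and mid-range Beta(4, 4) promoter methylation with 2%
    missing probe values.
    """

    n_genes: int = 300
    n_reference: int = 100
    n_case: int = 50
    ba_m: int = 2  # preferential-attachment edges per new node
    r: float = 0.4  # target edge correlation
    mutation_rate: float = 0.02
    beta_a: float = 4.0
    beta_b: float = 4.0
    missing_fraction: float = 0.02
    probes_per_gene: int = 4  # 3 promoter + 1 gene-body per gene
    n_perturbed_edges_per_sample: int = 2
    n_perturbed_samples: int = 10
    n_planted_methylation: int = 20
    seed: int = 0
    # explicit plants; generated from the seed when left empty
    perturbed_edges: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    planted_mutations: list[tuple[str, str]] = field(default_factory=list)
    planted_methylation: list[tuple[str, str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_reference", "n_case", "probes_per_gene"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not -1.0 < self.r < 1.0:
            raise ValidationError(f"r must be in (-1, 1), got {self.r}")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValidationError(f"mutation_rate must be in [0, 1], got {self.mutation_rate}")
        if self.beta_a <= 0 or self.beta_b <= 0:
            raise ValidationError("Beta distribution parameters must be positive")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValidationError("missing_fraction must be in [0, 1)")

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    @property
    def reference_ids(self) -> list[str]:
        return [f"N{i:03d}" for i in range(1, self.n_reference + 1)]

    @property
    def case_ids(self) -> list[str]:
        return [f"T{i:03d}" for i in range(1, self.n_case + 1)]

    def _streams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(6)
        names = ("background", "expression", "mutation", "methylation", "plants", "subtypes")
        return {name: np.random.default_rng(s) for name, s in zip(names, children)}


# ---------------------------------------------------------------------------
# Background network


def simulate_background(config: SimulationConfig) -> BackgroundNetwork:
    """Scale-free simple graph by preferential attachment (m(n - m) edges)."""
    n = config.n_genes
    if n < 3:
        raise ValidationError("need at least 3 genes for a background network")
    m = min(config.ba_m, n - 1)
    rng = config._streams()["background"]
    graph = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(0, 2**31)))
    genes = config.gene_ids
    return BackgroundNetwork.from_edges(
        (genes[u], genes[v]) for u, v in graph.edges
    )


def matching_network(n_pairs: int, prefix: str = "G") -> BackgroundNetwork:
    """Disjoint-pair (perfect matching) network: every node has degree 1."""
    width = len(str(2 * n_pairs))
    genes = [f"{prefix}{i:0{width}d}" for i in range(1, 2 * n_pairs + 1)]
    return BackgroundNetwork.from_edges(
        (genes[2 * i], genes[2 * i + 1]) for i in range(n_pairs)
    )


# ---------------------------------------------------------------------------
# Expression


def _edge_loadings(network: BackgroundNetwork, r: float) -> dict[tuple[str, str], tuple[float, float]]:
    deg = dict(network.graph.degree())
    loadings = {}
    for u, v in network.edges:
        cu = min(abs(r), 1.0 / deg[u])
        cv = min(abs(r), 1.0 / deg[v])
        loadings[(u, v)] = (cu, cv)
    return loadings


def planted_perturbations(
    config: SimulationConfig, network: BackgroundNetwork
) -> dict[str, list[tuple[str, str]]]:
    """Deterministic plant of perturbed edges in the first perturbed samples."""
    if config.perturbed_edges:
        return config.perturbed_edges
    rng = config._streams()["plants"]
    edges = network.edges
    plants: dict[str, list[tuple[str, str]]] = {}
    n_samples = min(config.n_perturbed_samples, config.n_case)
    k = min(config.n_perturbed_edges_per_sample, len(edges))
    for sample in config.case_ids[:n_samples]:
        idx = rng.choice(len(edges), size=k, replace=False)
        plants[sample] = [edges[i] for i in sorted(idx)]
    return plants


def simulate_expression(
    config: SimulationConfig,
    network: BackgroundNetwork,
    fpkm: bool = True,
) -> tuple[ExpressionMatrix, dict[str, list[tuple[str, str]]]]:
    """Reference + case expression with correlation r on network edges.

    Case samples are drawn from the reference distribution except at planted
    perturbed edges, where the sample's two endpoint genes are forced to
    opposite latent extremes (+-PERTURBATION_MAGNITUDE SDs), decoupling the
    pair.  Returns the matrix and the plant map (sample -> perturbed edges).
    """
    missing = set(network.nodes) - set(config.gene_ids)
    if missing:
        raise ValidationError(f"network nodes outside the configured gene set: {sorted(missing)}")
    rng = config._streams()["expression"]
    genes = config.gene_ids
    gene_index = {g: i for i, g in enumerate(genes)}
    samples = config.reference_ids + config.case_ids
    n_total = len(samples)
    n_genes = len(genes)

    edges = network.edges
    loadings = _edge_loadings(network, config.r)
    factors = rng.standard_normal((len(edges), n_total))
    noise = rng.standard_normal((n_genes, n_total))

    budget = np.zeros(n_genes)
    latent = np.zeros((n_genes, n_total))
    sign = 1.0 if config.r >= 0 else -1.0
    for e_idx, (u, v) in enumerate(edges):
        cu, cv = loadings[(u, v)]
        iu, iv = gene_index[u], gene_index[v]
        latent[iu] += np.sqrt(cu) * factors[e_idx]
        latent[iv] += sign * np.sqrt(cv) * factors[e_idx]
        budget[iu] += cu
        budget[iv] += cv
    if np.any(budget > 1.0 + 1e-9):
        raise ValidationError("edge loading budget exceeded; use a smaller r")
    latent += np.sqrt(np.clip(1.0 - budget, 0.0, None))[:, None] * noise

    plants = planted_perturbations(config, network)
    sample_index = {s: i for i, s in enumerate(samples)}
    for sample, planted in plants.items():
        j = sample_index[sample]
        for u, v in planted:
            latent[gene_index[u], j] = PERTURBATION_MAGNITUDE
            latent[gene_index[v], j] = -PERTURBATION_MAGNITUDE

    if fpkm:
        base = rng.normal(3.0, 1.0, size=n_genes)  # log-scale abundances, ~e^3 FPKM
        values = np.exp(base[:, None] + 0.25 * latent)
    else:
        # raw latent Gaussians, shifted by a constant (correlation-preserving)
        # to satisfy the non-negativity contract
        values = latent - latent.min() + 1.0
    frame = pd.DataFrame(values, index=genes, columns=samples)
    return (
        ExpressionMatrix(frame, config.reference_ids, config.case_ids),
        plants,
    )


def simulate_correlated_pairs(
    n_pairs: int,
    rho: float,
    n_reference: int,
    n_case: int,
    seed: int,
    fpkm: bool = False,
) -> tuple[ExpressionMatrix, BackgroundNetwork]:
    """Null cohort of independent gene pairs with exact latent correlation rho.

    Every background edge joins one disjoint pair; reference and case
    samples are drawn from the same distribution (no perturbation).  Used by
    the Z-test calibration checks.
    """
    if not -1.0 < rho < 1.0:
        raise ValidationError(f"rho must be in (-1, 1), got {rho}")
    network = matching_network(n_pairs)
    config = SimulationConfig(
        n_genes=2 * n_pairs,
        n_reference=n_reference,
        n_case=n_case,
        r=rho,
        n_perturbed_samples=0,
        seed=seed,
    )
    # matching network: deg = 1 everywhere, so the edge correlation is exactly rho
    expr, _ = simulate_expression(config, network, fpkm=fpkm)
    return expr, network


# ---------------------------------------------------------------------------
# Mutations


def simulate_mutations(config: SimulationConfig) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Binary gene x case-sample mutation matrix: iid Bernoulli + planted entries."""
    rng = config._streams()["mutation"]
    matrix = (
        rng.random((config.n_genes, config.n_case)) < config.mutation_rate
    ).astype(int)
    frame = pd.DataFrame(matrix, index=config.gene_ids, columns=config.case_ids)
    for gene, sample in config.planted_mutations:
        frame.loc[gene, sample] = 1
    return frame, list(config.planted_mutations)


# ---------------------------------------------------------------------------
# Methylation


def make_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Probe annotation: per gene, promoter probes plus one gene-body probe."""
    regions = ["TSS200", "TSS1500", "1stExon", "5'UTR"]
    rows = []
    for gene in config.gene_ids:
        for k in range(config.probes_per_gene):
            region = "Body" if k == config.probes_per_gene - 1 else regions[k % len(regions)]
            rows.append((f"cg_{gene}_{k}", gene, region))
    return pd.DataFrame(rows, columns=["probe_id", "gene", "region"]).assign(
        multi_mapped=False, is_promoter=lambda d: d["region"].isin(
            {"TSS1500", "TSS200", "5'UTR", "1stExon"}
        ),
    )


def planted_methylation(config: SimulationConfig) -> list[tuple[str, str, int]]:
    if config.planted_methylation:
        return config.planted_methylation
    rng = config._streams()["plants"]
    # independent stream position from perturbation plants is not needed for
    # correctness (both are deterministic under the master seed); jump ahead
    rng = np.random.default_rng(rng.integers(0, 2**31) + 1)
    plants = []
    n = min(config.n_planted_methylation, config.n_genes * config.n_case)
    gene_idx = rng.choice(config.n_genes, size=n, replace=False if n <= config.n_genes else True)
    sample_idx = rng.integers(0, config.n_case, size=n)
    directions = rng.choice([-1, 1], size=n)
    for g, s, d in zip(gene_idx, sample_idx, directions):
        plants.append((config.gene_ids[int(g)], config.case_ids[int(s)], int(d)))
    return plants


def simulate_methylation(
    config: SimulationConfig, annotation: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, list[tuple[str, str, int]]]:
    """Probe x case-sample beta matrix with planted outliers and missing entries.

    Betas are iid Beta(a, b); a planted (gene, sample, direction) outlier
    sets every promoter probe of that gene in that sample to an extreme beta
    (0.995 hyper / 0.005 hypo), which lies beyond MED +- 4 MAD of the
    consolidated per-gene distribution for the default Beta(4, 4).  Planted
    cells are never masked missing.
    """
    if annotation is None:
        annotation = make_annotation(config)
    rng = config._streams()["methylation"]
    probes = list(annotation["probe_id"].unique())
    beta = rng.beta(config.beta_a, config.beta_b, size=(len(probes), config.n_case))
    frame = pd.DataFrame(beta, index=probes, columns=config.case_ids)

    plants = planted_methylation(config)
    promoter = annotation[annotation["region"].isin({"TSS1500", "TSS200", "5'UTR", "1stExon"})]
    probes_by_gene = promoter.groupby("gene")["probe_id"].apply(list)
    planted_cells = set()
    for gene, sample, direction in plants:
        value = HYPER_BETA if direction > 0 else HYPO_BETA
        for probe in probes_by_gene.get(gene, []):
            frame.loc[probe, sample] = value
            planted_cells.add((probe, sample))

    if config.missing_fraction > 0:
        mask = rng.random(frame.shape) < config.missing_fraction
        for probe, sample in planted_cells:
            mask[frame.index.get_loc(probe), frame.columns.get_loc(sample)] = False
        frame = frame.mask(mask)
    return frame, plants


# ---------------------------------------------------------------------------
# Subtype-structured module cohorts


def simulate_subtype_modules(
    subtype_sizes: dict[str, int],
    universe: BackgroundNetwork,
    n_specific_edges: int = 5,
    n_shared_edges: int = 5,
    present_prob: float = 0.9,
    background_prob: float = 0.1,
    seed: int = 0,
) -> tuple[dict[str, "DriverModule"], dict[str, str], dict]:
    """Per-sample co-driver modules with planted subtype-specific edges.

    Each subtype receives ``n_specific_edges`` planted edges present with
    probability ``present_prob`` in its own samples and ``background_prob``
    elsewhere; ``n_shared_edges`` further edges are present with
    ``present_prob`` in every sample.  Returns (modules by sample, labels,
    truth dict with the planted shared/specific edge sets).
    """
    from .io_formats import DriverModule  # local import avoids a cycle at module load

    rng = np.random.default_rng(seed)
    edges = universe.edges
    subtypes = sorted(subtype_sizes)
    needed = n_shared_edges + n_specific_edges * len(subtypes)
    if needed > len(edges):
        raise ValidationError("universe too small for the requested plants")
    chosen = rng.choice(len(edges), size=needed, replace=False)
    shared = [edges[i] for i in chosen[:n_shared_edges]]
    specific: dict[str, list[tuple[str, str]]] = {}
    offset = n_shared_edges
    for s in subtypes:
        specific[s] = [edges[i] for i in chosen[offset : offset + n_specific_edges]]
        offset += n_specific_edges

    modules: dict[str, DriverModule] = {}
    labels: dict[str, str] = {}
    counter = 0
    for s in subtypes:
        for _ in range(subtype_sizes[s]):
            counter += 1
            sample = f"T{counter:03d}"
            labels[sample] = s
            kept: set[tuple[str, str]] = set()
            for e in shared:
                if rng.random() < present_prob:
                    kept.add(e)
            for t in subtypes:
                p = present_prob if t == s else background_prob
                for e in specific[t]:
                    if rng.random() < p:
                        kept.add(e)
            modules[sample] = DriverModule(
                sample_id=sample,
                driver_type="co",
                seeds=frozenset(),
                edges=frozenset(canonical_edge(u, v) for u, v in kept),
            )
    truth = {"shared": shared, "specific": specific}
    return modules, labels, truth


# ---------------------------------------------------------------------------
# Fixture export


def write_fixture_set(config: SimulationConfig, out_dir: str | Path) -> dict:
    """Write the full synthetic input set plus a truth JSON; returns the truth."""
    from .io_formats import write_edge_list, write_expression, write_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    network = simulate_background(config)
    expr, perturbations = simulate_expression(config, network)
    mutations, planted_mut = simulate_mutations(config)
    annotation = make_annotation(config)
    methylation, planted_methy = simulate_methylation(config, annotation)

    write_edge_list(network, out / "background_edges.tsv")
    write_expression(expr, out / "expression.tsv")
    write_matrix(mutations, out / "mutations.tsv")
    methylation.to_csv(out / "methylation_beta.tsv", sep="\t", float_format="%.10g",
                       index_label="probe_id", na_rep="NA")
    annotation[["probe_id", "gene", "region"]].to_csv(
        out / "probe_annotation.tsv", sep="\t", index=False
    )
    with open(out / "sample_roles.tsv", "w") as fh:
        for s in config.reference_ids:
            fh.write(f"{s}\treference\n")
        for s in config.case_ids:
            fh.write(f"{s}\tcase\n")
    truth = {
        "seed": config.seed,
        "perturbed_edges": {s: [list(e) for e in v] for s, v in perturbations.items()},
        "planted_mutations": [list(t) for t in planted_mut],
        "planted_methylation": [list(t) for t in planted_methy],
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return truth
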