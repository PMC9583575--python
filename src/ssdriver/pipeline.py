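"""End-to-end orchestration: configuration, staged execution, provenance.

``run_pipeline`` executes the full chain -- reference network, per-sample
SSNs, mutation / methylation profiles, 2-order hub driver modules, module
statistics, cohort- and subtype-level aggregation -- writing every artifact
under an output directory with a provenance record (package version, config
hash, seed).  Each stage is also exposed as a CLI subcommand (see
:mod:`ssdriver.cli`) and can be run in isolation on the previous stage's
outputs.  Filter and drop counts are logged at every step.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from . import cohort as cohort_mod
from . import drivermod, netstats, profiles, ssn
from .io_formats import (
    BackgroundNetwork,
    DriverModule,
    ExpressionMatrix,
    ValidationError,
    write_matrix,
    write_module,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Tunable parameters of the whole pipeline; defaults are the method's own.

    alpha_ssn: per-edge significance level for SSN retention (0.01);
    hub_fraction: top degree fraction defining hub genes (0.20);
    hampel_k: MAD multiplier of the methylation outlier rule (3);
    knn_k: neighbours for probe imputation (10);
    max_na_fraction: probe missingness tolerance (0.10);
    mc_iterations / mc_edges_per_iter / mc_alpha: Monte Carlo null of the
    cohort edge-frequency cutoff (10,000 x 10,000 at 0.05);
    subtype_threshold: within-subtype frequency for subtype modules (0.60).
    """

    alpha_ssn: float = 0.01
    hub_fraction: float = 0.20
    hampel_k: float = 3.0
    knn_k: int = 10
    max_na_fraction: float = 0.10
    mc_iterations: int = 10000
    mc_edges_per_iter: int = 10000
    mc_alpha: float = 0.05
    subtype_threshold: float = 0.60
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("alpha_ssn", "hub_fraction", "max_na_fraction", "mc_alpha", "subtype_threshold"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {value}")
        if self.hampel_k <= 0 or self.knn_k <= 0:
            raise ValidationError("hampel_k and knn_k must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Flat key-value YAML file; explicit keyword overrides win."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def _provenance(config: PipelineConfig) -> dict:
    return {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "seed": config.seed,
    }


def build_profiles_stage(
    mutations_raw: pd.DataFrame,
    methylation_raw: pd.DataFrame,
    annotation: pd.DataFrame,
    case_ids: list[str],
    config: PipelineConfig,
    genes: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mutation matrix + ternary methylation matrix from raw inputs."""
    mutation = profiles.build_mutation_matrix(mutations_raw, case_ids, genes=genes)
    beta = profiles.filter_probes(methylation_raw, config.max_na_fraction)
    beta = profiles.knn_impute(beta, k=config.knn_k)
    consolidated = profiles.consolidate_promoter(beta, annotation)
    ternary = profiles.hampel_ternary(consolidated)
    return mutation, ternary


def build_modules_stage(
    ssns: Mapping[str, ssn.SampleSpecificNetwork],
    mutation: pd.DataFrame,
    ternary: pd.DataFrame,
    config: PipelineConfig,
) -> dict[str, dict[str, DriverModule]]:
    """Per-sample mutation / methylation / co driver modules."""
    out: dict[str, dict[str, DriverModule]] = {}
    for sample_id in sorted(ssns):
        net = ssns[sample_id]
        hubs = drivermod.hub_genes(net, config.hub_fraction)
        mut_seeds = (
            profiles.seed_genes(mutation[sample_id], "mutation")
            if sample_id in mutation.columns
            else frozenset()
        )
        methy_seeds = (
            profiles.seed_genes(ternary[sample_id], "methylation")
            if sample_id in ternary.columns
            else frozenset()
        )
        m_mut = drivermod.two_order_module(net, mut_seeds, hubs, "mutation")
        m_methy = drivermod.two_order_module(net, methy_seeds, hubs, "methylation")
        out[sample_id] = {
            "mutation": m_mut,
            "methylation": m_methy,
            "co": drivermod.co_driver_module(m_mut, m_methy),
        }
    return out


def run_pipeline(
    config: PipelineConfig,
    expr: ExpressionMatrix,
    background: BackgroundNetwork,
    mutations_raw: pd.DataFrame,
    methylation_raw: pd.DataFrame,
    annotation: pd.DataFrame,
    out_dir: str | Path,
    subtype_labels: Mapping[str, str] | None = None,
) -> dict:
    """Run every stage and write all artifacts under ``out_dir``.

    Returns a summary dict (cutoffs, module sizes, file paths).  Outputs are
    byte-stable under a fixed config and seed.
    """
    out = Path(out_dir)
    for sub in ("ssn", "modules", "cohort"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("profiles")
        mutation, ternary = build_profiles_stage(
            mutations_raw, methylation_raw, annotation, expr.case_ids, config,
            genes=expr.genes,
        )
        write_matrix(mutation, out / "mutation_matrix.tsv")
        write_matrix(ternary, out / "methylation_ternary.tsv")
    except ValidationError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError(f"profiles stage failed: {exc}") from exc

    try:
        stage("ssn")
        ref_net = ssn.build_reference_network(expr, background)
        ssns: dict[str, ssn.SampleSpecificNetwork] = {}
        for sample_id in expr.case_ids:
            net = ssn.build_ssn(expr, ref_net, sample_id, alpha=config.alpha_ssn)
            ssns[sample_id] = net
            ssn.write_ssn(net, out / "ssn" / f"{sample_id}.ssn.tsv")
    except ValidationError:
        raise
    except Exception as exc:  # pragma: no cover
        raise StageError(f"ssn stage failed: {exc}") from exc

    try:
        stage("modules")
        modules = build_modules_stage(ssns, mutation, ternary, config)
        for sample_id, per_type in modules.items():
            for dtype, module in per_type.items():
                write_module(module, out / "modules" / f"{sample_id}.{dtype}.module.tsv")
    except Exception as exc:
        raise StageError(f"modules stage failed: {exc}") from exc

    try:
        stage("netstats")
        stats_rows = []
        similarity_rows = []
        for sample_id in sorted(modules):
            per_type = modules[sample_id]
            table = netstats.module_centrality_table(
                per_type["co"], per_type["mutation"].seeds, per_type["methylation"].seeds
            )
            if not table.empty:
                stats_rows.append(table.reset_index())
            similarity_rows.append(
                {
                    "sample_id": sample_id,
                    "jaccard_edges": netstats.module_similarity(
                        per_type["mutation"], per_type["methylation"], on="edges"
                    ),
                    "jaccard_genes": netstats.module_similarity(
                        per_type["mutation"], per_type["methylation"], on="genes"
                    ),
                }
            )
        if stats_rows:
            pd.concat(stats_rows, ignore_index=True).to_csv(
                out / "gene_centralities.tsv", sep="\t", index=False, float_format="%.10g"
            )
        pd.DataFrame(similarity_rows).to_csv(
            out / "module_similarity.tsv", sep="\t", index=False, float_format="%.10g"
        )
    except Exception as exc:
        raise StageError(f"netstats stage failed: {exc}") from exc

    try:
        stage("cohort")
        summary: dict = {"cutoffs": {}, "cohort_edges": {}, "cohort_genes": {}}
        for dtype in ("mutation", "methylation", "co"):
            mods = [modules[s][dtype] for s in sorted(modules)]
            freq = cohort_mod.edge_frequencies(mods, background)
            freq.rename("frequency").to_csv(
                out / "cohort" / f"edge_frequency.{dtype}.tsv", sep="\t",
                float_format="%.10g",
            )
            cutoff = cohort_mod.monte_carlo_cutoff(
                freq,
                iterations=config.mc_iterations,
                edges_per_iter=config.mc_edges_per_iter,
                alpha=config.mc_alpha,
                seed=config.seed,
            )
            module = cohort_mod.cohort_module(freq, cutoff, dtype)
            summary["cutoffs"][dtype] = cutoff
            summary["cohort_edges"][dtype] = len(module.edges)
            summary["cohort_genes"][dtype] = len(module.genes)
            with open(out / "cohort" / f"cohort_module.{dtype}.tsv", "w") as fh:
                fh.write(f"# driver_type: {dtype}\n# cutoff: {cutoff!r}\n")
                fh.write("gene_a\tgene_b\n")
                for u, v in sorted(module.edges):
                    fh.write(f"{u}\t{v}\n")

        if subtype_labels:
            co_modules = {s: modules[s]["co"] for s in modules}
            labeled = {s: t for s, t in subtype_labels.items() if s in co_modules}
            st = cohort_mod.subtype_modules(
                co_modules, labeled, threshold=config.subtype_threshold
            )
            with open(out / "cohort" / "subtype_modules.tsv", "w") as fh:
                fh.write("subtype\tgene_a\tgene_b\tspecific\n")
                for subtype, edges in st.modules:
                    spec = st.specific_dict[subtype]
                    for u, v in sorted(edges):
                        fh.write(f"{subtype}\t{u}\t{v}\t{int((u, v) in spec)}\n")
            summary["subtype_edges"] = {s: len(e) for s, e in st.modules}
            summary["subtype_specific_edges"] = {s: len(e) for s, e in st.specific}
            summary["subtype_shared_edges"] = len(st.shared)
    except Exception as exc:
        raise StageError(f"cohort stage failed: {exc}") from exc

    provenance = _provenance(config)
    provenance["summary"] = summary
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True)
    return provenance
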