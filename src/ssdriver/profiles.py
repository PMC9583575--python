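"""Per-sample omics profiles: binary mutation states and ternary methylation aberrations.

The mutation profile M_ij is 1 when gene i carries a nonsynonymous somatic
mutation in sample j, else 0.  The methylation profile starts from CpG-probe
beta values: probes missing in more than ``max_na_fraction`` of samples are
removed, remaining gaps are filled by 10-nearest-neighbour imputation over
probe rows, promoter probes (TSS1500 / TSS200 / 5'UTR / 1stExon) are
consolidated to one value per gene and sample by the median, and a Hampel
filter flags per-gene outliers across samples:

    MT_ij = -1  if v < MED - 3 * MAD   (hypomethylation)
    MT_ij = +1  if v > MED + 3 * MAD   (hypermethylation)
    MT_ij =  0  otherwise,

with MED and MAD the median and *unscaled* median absolute deviation of gene
i's consolidated value across samples (no 1.4826 consistency factor; strict
inequalities).  A gene with MAD = 0 flags any value that departs from MED;
the per-sample flagged fraction is logged so such pathological genes are
visible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .io_formats import PROMOTER_REGIONS, ValidationError

logger = logging.getLogger(__name__)


def build_mutation_matrix(
    gene_level_calls: pd.DataFrame, case_samples: list[str], genes: list[str] | None = None
) -> pd.DataFrame:
    """Binarize a gene x sample table of nonsynonymous-mutation indicators/counts.

    Any positive count becomes 1; a gene or sample absent from the table is
    all-zero.  Negative counts are a hard error.
    """
    calls = gene_level_calls.apply(pd.to_numeric)
    if (calls.to_numpy() < 0).any():
        raise ValidationError("mutation counts must be non-negative")
    index = genes if genes is not None else list(calls.index)
    out = pd.DataFrame(0, index=index, columns=case_samples, dtype=int)
    common_genes = [g for g in index if g in calls.index]
    common_samples = [s for s in case_samples if s in calls.columns]
    if common_genes and common_samples:
        sub = (calls.loc[common_genes, common_samples] > 0).astype(int)
        out.loc[common_genes, common_samples] = sub
    return out


def filter_probes(beta: pd.DataFrame, max_na_fraction: float = 0.10) -> pd.DataFrame:
    """Remove probes with missing values in strictly more than ``max_na_fraction`` of samples."""
    na_frac = beta.isna().mean(axis=1)
    keep = na_frac <= max_na_fraction
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info(
            "filter_probes: removed %d of %d probes (> %.0f%% missing)",
            n_removed,
            len(beta),
            100 * max_na_fraction,
        )
    return beta.loc[keep]


def knn_impute(beta: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Fill missing betas from the k nearest probe rows (Euclidean over co-observed samples).

    Each missing entry becomes the uniform average of the k nearest probes'
    values in that sample; a probe with no usable neighbour for some sample
    falls back to its own row mean (logged).  Results are clipped to [0, 1].
    """
    if not beta.isna().any().any():
        return beta.copy()
    if len(beta) < 2:
        filled = beta.apply(lambda row: row.fillna(row.mean()), axis=1)
        return filled.clip(0.0, 1.0)
    n_missing = int(beta.isna().sum().sum())
    imputer = KNNImputer(
        n_neighbors=min(k, len(beta) - 1), weights="uniform", keep_empty_features=True
    )
    # probes play the role of sklearn "samples": a probe's gap is filled from
    # the nearest probe rows, matching impute.knn semantics
    values = imputer.fit_transform(beta.to_numpy(dtype=float))
    out = pd.DataFrame(values, index=beta.index, columns=beta.columns)
    still = out.isna()
    if still.any().any():
        n_fallback = int(still.sum().sum())
        logger.warning("knn_impute: %d entries fell back to the probe row mean", n_fallback)
        row_means = out.mean(axis=1)
        out = out.apply(lambda row: row.fillna(row_means[row.name]), axis=1)
    logger.info("knn_impute: imputed %d missing entries (k=%d)", n_missing, k)
    return out.clip(0.0, 1.0)


@dataclass
class ConsolidatedMethylation:
    """One promoter-methylation value per gene and sample (median over promoter probes)."""

    values: pd.DataFrame  # genes x samples, complete, in [0, 1]


def consolidate_promoter(
    beta: pd.DataFrame, annotation: pd.DataFrame
) -> ConsolidatedMethylation:
    """Median beta over each gene's promoter-region probes, per sample.

    Promoter regions are TSS1500, TSS200, 5'UTR and 1stExon; genes with no
    promoter probe in the matrix are omitted.  A probe annotated to several
    genes contributes to every one of them.
    """
    promoter = annotation[annotation["region"].isin(PROMOTER_REGIONS)]
    promoter = promoter[promoter["probe_id"].isin(beta.index)]
    if promoter.empty:
        return ConsolidatedMethylation(pd.DataFrame(columns=beta.columns))
    stacked = beta.loc[promoter["probe_id"]].set_index(promoter["gene"].to_numpy())
    values = stacked.groupby(level=0).median().sort_index()
    return ConsolidatedMethylation(values)


def hampel_ternary(
    consolidated: ConsolidatedMethylation,
    stat_samples: list[str] | None = None,
) -> pd.DataFrame:
    """Ternary methylation-aberration matrix by the per-gene Hampel rule.

    MED and MAD are computed across ``stat_samples`` (default: every column
    of the consolidated matrix, i.e. the case samples the matrix was built
    over).  MAD is the raw median absolute deviation, and both bounds use
    strict inequalities, so a value exactly at MED +- 3*MAD is not flagged.
    """
    v = consolidated.values
    if v.isna().any().any():
        raise ValidationError("consolidated methylation must be complete (impute first)")
    stat = v[stat_samples] if stat_samples is not None else v
    med = stat.median(axis=1)
    mad = (stat.sub(med, axis=0)).abs().median(axis=1)
    lower = med - 3.0 * mad
    upper = med + 3.0 * mad
    mt = pd.DataFrame(0, index=v.index, columns=v.columns, dtype=int)
    # strict inequalities; values exactly at a bound stay 0, so float
    # representation noise at the boundary must not flip them
    arr = v.to_numpy()
    lo = lower.to_numpy()[:, None]
    hi = upper.to_numpy()[:, None]
    at_bound_lo = np.isclose(arr, lo, rtol=1e-9, atol=1e-12)
    at_bound_hi = np.isclose(arr, hi, rtol=1e-9, atol=1e-12)
    mt[(arr < lo) & ~at_bound_lo] = -1
    mt[(arr > hi) & ~at_bound_hi] = 1
    zero_mad = mad == 0
    if zero_mad.any():
        logger.warning(
            "hampel_ternary: %d genes have MAD = 0 (any departure from MED is flagged)",
            int(zero_mad.sum()),
        )
    flagged_fraction = (mt != 0).mean().mean()
    logger.info("hampel_ternary: overall flagged fraction %.4f", flagged_fraction)
    return mt


def seed_genes(profile_column: pd.Series, kind: str) -> frozenset[str]:
    """Seed genes for one sample: mutated (M=1) or aberrantly methylated (MT != 0)."""
    if kind == "mutation":
        return frozenset(profile_column.index[profile_column == 1])
    if kind == "methylation":
        return frozenset(profile_column.index[profile_column != 0])
    raise ValidationError(f"unknown profile kind: {kind!r}")
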