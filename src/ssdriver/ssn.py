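"""Sample-specific network (SSN) construction by single-sample differential correlation.

The reference network weights each background edge by the Pearson correlation
pcc_n of its endpoint genes over the n reference (normal) samples.  Adding a
single case sample d and recomputing gives pcc_{n+1}; the differential
correlation

    delta = pcc_{n+1} - pcc_n

is, for a case sample drawn from the reference population and large n,
normally distributed with mean 0 and a null scale of

    sd(delta) = (1 - pcc_n**2) / (n - 1).

Note that the null dispersion of a one-sample correlation update is O(1/n):
the expression above is the *standard deviation* of delta (verified by
simulation in the test suite), so the calibrated statistic is

    z = delta / ((1 - pcc_n**2) / (n - 1)),

which is approximately standard normal under the null; dividing by the square
root of that quantity instead would deflate z by a factor of ~sqrt(n) and
retain essentially nothing at any sensible alpha.  Edges with a two-tailed
normal p-value below ``alpha`` (default 0.01) constitute the SSN of sample d.

Correlations are computed per background edge, never as a dense gene x gene
matrix, so memory is O(|edges|); per-edge reference sums are cached so each
case sample costs O(|edges|).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import BackgroundNetwork, ExpressionMatrix, ValidationError, canonical_edge

logger = logging.getLogger(__name__)

_EPS = 1e-12


class UndefinedCorrelation(ValueError):
    """Correlation is undefined (constant vector)."""


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Standard Pearson product-moment correlation of two equal-length vectors.

    Raises :class:`UndefinedCorrelation` if either vector is constant, and
    ``ValueError`` for unequal lengths or fewer than 3 observations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelation("constant vector has no defined correlation")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class ReferenceNetwork:
    """Background edges weighted by pcc_n over the reference cohort.

    ``table`` has one row per surviving background edge with columns
    ``gene_a``, ``gene_b``, ``pcc_n``.  Cached per-edge reference sums make
    the per-sample pcc_{n+1} update an O(|edges|) vector operation.
    """

    table: pd.DataFrame
    n: int
    genes: list[str]
    n_dropped_missing: int = 0
    n_dropped_degenerate: int = 0
    # cached reference-cohort sums, aligned with table rows
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(zip(self.table["gene_a"], self.table["gene_b"]))


def build_reference_network(
    expr: ExpressionMatrix, background: BackgroundNetwork
) -> ReferenceNetwork:
    """Correlate every background edge over the reference samples.

    Background edges with an endpoint absent from the expression matrix are
    dropped (counted), as are edges whose reference correlation is undefined
    (a constant gene) or degenerate (|pcc_n| = 1, null scale zero).
    """
    n = len(expr.reference_ids)
    if n < 3:
        raise ValidationError(f"need >= 3 reference samples, got {n}")
    genes = set(expr.genes)
    kept, dropped_missing = [], 0
    for u, v in background.edges:
        if u in genes and v in genes:
            kept.append((u, v))
        else:
            dropped_missing += 1
    if not kept:
        raise ValidationError("no background edge has both endpoints in the expression matrix")
    if dropped_missing:
        logger.info(
            "reference network: dropped %d background edges with missing endpoints",
            dropped_missing,
        )

    ref = expr.reference()
    gene_index = {g: i for i, g in enumerate(ref.index)}
    X = ref.to_numpy(dtype=float)
    ia = np.array([gene_index[u] for u, _ in kept])
    ib = np.array([gene_index[v] for _, v in kept])
    A, B = X[ia], X[ib]

    sa, sb = A.sum(axis=1), B.sum(axis=1)
    saa, sbb, sab = (A * A).sum(axis=1), (B * B).sum(axis=1), (A * B).sum(axis=1)
    var_a = saa - sa * sa / n
    var_b = sbb - sb * sb / n
    cov = sab - sa * sb / n
    denom = np.sqrt(np.clip(var_a, 0, None) * np.clip(var_b, 0, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        pcc = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), np.nan)
    pcc = np.clip(pcc, -1.0, 1.0)

    degenerate = ~np.isfinite(pcc) | (np.abs(pcc) >= 1.0 - _EPS)
    n_degenerate = int(degenerate.sum())
    if n_degenerate:
        logger.info(
            "reference network: excluded %d edges with undefined or degenerate pcc_n",
            n_degenerate,
        )
    keep = ~degenerate
    table = pd.DataFrame(
        {
            "gene_a": [e[0] for e, k in zip(kept, keep) if k],
            "gene_b": [e[1] for e, k in zip(kept, keep) if k],
            "pcc_n": pcc[keep],
        }
    )
    net = ReferenceNetwork(
        table=table,
        n=n,
        genes=list(ref.index),
        n_dropped_missing=dropped_missing,
        n_dropped_degenerate=n_degenerate,
    )
    net._cache = {
        "ia": ia[keep],
        "ib": ib[keep],
        "sa": sa[keep],
        "sb": sb[keep],
        "saa": saa[keep],
        "sbb": sbb[keep],
        "sab": sab[keep],
        "gene_index": gene_index,
    }
    return net


def edge_statistic(pcc_n, pcc_n1, n: int):
    """Differential-correlation statistic for one edge (vectorized).

    Returns ``(delta, z, p)`` with ``delta = pcc_n1 - pcc_n``,
    ``z = delta / ((1 - pcc_n**2) / (n - 1))`` (the denominator is the null
    standard deviation of delta) and ``p`` the two-tailed standard-normal
    tail probability ``2 * (1 - Phi(|z|))``.
    """
    pcc_n = np.asarray(pcc_n, dtype=float)
    pcc_n1 = np.asarray(pcc_n1, dtype=float)
    if n < 3:
        raise ValidationError("need n >= 3 for the differential-correlation test")
    if np.any(np.abs(pcc_n) >= 1.0 - _EPS):
        raise ValidationError("|pcc_n| = 1 has a degenerate null scale; exclude the edge")
    delta = pcc_n1 - pcc_n
    scale = (1.0 - pcc_n**2) / (n - 1)
    z = delta / scale
    p = 2.0 * stats.norm.sf(np.abs(z))
    if np.ndim(delta) == 0:
        return float(delta), float(z), float(p)
    return delta, z, p


@dataclass
class SampleSpecificNetwork:
    """Edges whose correlation shifts significantly when one case sample is added.

    ``table`` holds the retained edges (p < alpha) with their full edge
    statistics; ``n_tested`` counts all testable edges for this sample.
    """

    sample_id: str
    alpha: float
    table: pd.DataFrame  # gene_a, gene_b, pcc_n, pcc_n1, delta, z, p
    n_tested: int
    n_excluded: int = 0

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(
            canonical_edge(u, v) for u, v in zip(self.table["gene_a"], self.table["gene_b"])
        )

    @property
    def nodes(self) -> set[str]:
        return set(self.table["gene_a"]) | set(self.table["gene_b"])

    def degrees(self) -> dict[str, int]:
        deg: dict[str, int] = {}
        for u, v in self.edges:
            deg[u] = deg.get(u, 0) + 1
            deg[v] = deg.get(v, 0) + 1
        return deg


def sample_edge_statistics(
    expr: ExpressionMatrix, ref_net: ReferenceNetwork, sample_id: str
) -> pd.DataFrame:
    """Full edge-statistic table (all testable edges) for one case sample.

    Uses the cached reference sums: pcc_{n+1} over reference + {sample} is an
    O(|edges|) incremental update.  Edges whose (n+1)-sample correlation is
    undefined (combined vector constant) are excluded with ``NaN`` rows
    dropped and counted in the ``attrs['n_excluded']`` of the result.
    """
    if sample_id not in expr.values.columns:
        raise ValidationError(f"sample {sample_id!r} not found in expression matrix")
    c = ref_net._cache
    if not c:
        raise ValidationError("reference network lacks cached sums; rebuild it")
    n = ref_net.n
    x = expr.values[sample_id].to_numpy(dtype=float)
    xa, xb = x[c["ia"]], x[c["ib"]]
    m = n + 1
    sa, sb = c["sa"] + xa, c["sb"] + xb
    saa, sbb = c["saa"] + xa * xa, c["sbb"] + xb * xb
    sab = c["sab"] + xa * xb
    var_a = saa - sa * sa / m
    var_b = sbb - sb * sb / m
    cov = sab - sa * sb / m
    denom = np.sqrt(np.clip(var_a, 0, None) * np.clip(var_b, 0, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        pcc1 = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), np.nan)
    pcc1 = np.clip(pcc1, -1.0, 1.0)

    pcc0 = ref_net.table["pcc_n"].to_numpy()
    ok = np.isfinite(pcc1)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info(
            "sample %s: %d edges untestable with the added sample", sample_id, n_excluded
        )
    delta, z, p = edge_statistic(pcc0[ok], pcc1[ok], n)
    out = pd.DataFrame(
        {
            "gene_a": ref_net.table["gene_a"].to_numpy()[ok],
            "gene_b": ref_net.table["gene_b"].to_numpy()[ok],
            "pcc_n": pcc0[ok],
            "pcc_n1": pcc1[ok],
            "delta": delta,
            "z": z,
            "p": p,
        }
    )
    out.attrs["n_excluded"] = n_excluded
    return out


def build_ssn(
    expr: ExpressionMatrix,
    ref_net: ReferenceNetwork,
    sample_id: str,
    alpha: float = 0.01,
) -> SampleSpecificNetwork:
    """Retain the edges with two-tailed p < alpha for one case sample."""
    if not 0.0 <= alpha < 1.0:
        raise ValidationError(f"alpha must be in [0, 1), got {alpha}")
    stats_table = sample_edge_statistics(expr, ref_net, sample_id)
    retained = stats_table[stats_table["p"] < alpha].reset_index(drop=True)
    if retained.empty:
        logger.warning("sample %s: empty SSN at alpha=%g", sample_id, alpha)
    return SampleSpecificNetwork(
        sample_id=sample_id,
        alpha=alpha,
        table=retained,
        n_tested=len(stats_table),
        n_excluded=stats_table.attrs.get("n_excluded", 0),
    )


# ---------------------------------------------------------------------------
# SSN on-disk format: header block + per-edge statistics TSV

_SSN_COLUMNS = ["gene_a", "gene_b", "pcc_n", "pcc_n1", "delta", "z", "p"]


def write_ssn(ssn: SampleSpecificNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sample_id: {ssn.sample_id}\n")
        fh.write(f"# alpha: {ssn.alpha!r}\n")
        fh.write(f"# n_tested: {ssn.n_tested}\n")
        fh.write(f"# n_excluded: {ssn.n_excluded}\n")
        fh.write("\t".join(_SSN_COLUMNS) + "\n")
        table = ssn.table.sort_values(["gene_a", "gene_b"])
        for row in table.itertuples(index=False):
            fh.write(
                f"{row.gene_a}\t{row.gene_b}\t{row.pcc_n:.10g}\t{row.pcc_n1:.10g}"
                f"\t{row.delta:.10g}\t{row.z:.10g}\t{row.p:.10g}\n"
            )


def read_ssn(path) -> SampleSpecificNetwork:
    header: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines) and lines[i].startswith("# "):
        key, value = lines[i][2:].split(": ", 1)
        header[key] = value
        i += 1
    if i >= len(lines) or lines[i].split("\t") != _SSN_COLUMNS:
        raise ValidationError(f"malformed SSN file: {path}")
    for key in ("sample_id", "alpha", "n_tested"):
        if key not in header:
            raise ValidationError(f"SSN header missing {key!r} in {path}")
    rows = [line.split("\t") for line in lines[i + 1 :] if line]
    table = pd.DataFrame(rows, columns=_SSN_COLUMNS)
    for col in _SSN_COLUMNS[2:]:
        table[col] = table[col].astype(float)
    return SampleSpecificNetwork(
        sample_id=header["sample_id"],
        alpha=float(header["alpha"]),
        table=table,
        n_tested=int(header["n_tested"]),
        n_excluded=int(header.get("n_excluded", 0)),
    )
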