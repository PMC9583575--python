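"""Null-model calibration studies for the differential-correlation statistic.

These routines measure, by simulation, the finite-sample behaviour of the
SSN edge test when the added case sample truly comes from the reference
population: the mean of delta = pcc_{n+1} - pcc_n (which should vanish), the
dispersion of delta against its theoretical null scale (1 - pcc_n^2)/(n - 1),
and the empirical per-edge type-I error of the two-tailed normal p-value at
a given significance level.  They are used by the test suite and by the
acceptance script, and are ordinary library functionality: anyone applying
the method to a new cohort size can rerun them to see how the test behaves
at their n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import synthetic
from .ssn import build_reference_network, sample_edge_statistics


@dataclass(frozen=True)
class NullCalibration:
    """Summary of a null simulation (case samples drawn from the reference law)."""

    n_tests: int
    mean_delta: float
    se_mean_delta: float
    sd_delta: float
    mean_null_scale: float  # average of (1 - pcc_n^2)/(n - 1) over edges
    type_one_error: float
    alpha: float

    @property
    def mean_z_score(self) -> float:
        """|mean delta| in units of its standard error."""
        return abs(self.mean_delta) / self.se_mean_delta

    @property
    def sd_ratio(self) -> float:
        """Empirical sd of delta over the theoretical null scale."""
        return self.sd_delta / self.mean_null_scale


def null_calibration(
    n_pairs: int = 200,
    rho: float = 0.0,
    n_reference: int = 100,
    n_case: int = 50,
    alpha: float = 0.01,
    seed: int = 1,
) -> NullCalibration:
    """Simulate a null cohort of independent gene pairs and score every edge.

    ``n_pairs`` background edges join disjoint gene pairs with latent
    correlation ``rho``; ``n_case`` additional samples are drawn from the
    same distribution and each is tested against the ``n_reference``-sample
    reference network, giving ``n_pairs * n_case`` edge tests.
    """
    expr, network = synthetic.simulate_correlated_pairs(
        n_pairs, rho, n_reference, n_case, seed=seed, fpkm=False
    )
    ref = build_reference_network(expr, network)
    deltas, pvals = [], []
    for sample_id in expr.case_ids:
        table = sample_edge_statistics(expr, ref, sample_id)
        deltas.append(table["delta"].to_numpy())
        pvals.append(table["p"].to_numpy())
    delta = np.concatenate(deltas)
    p = np.concatenate(pvals)
    scale = (1.0 - ref.table["pcc_n"].to_numpy() ** 2) / (ref.n - 1)
    return NullCalibration(
        n_tests=int(delta.size),
        mean_delta=float(delta.mean()),
        se_mean_delta=float(delta.std(ddof=1) / np.sqrt(delta.size)),
        sd_delta=float(delta.std(ddof=1)),
        mean_null_scale=float(scale.mean()),
        type_one_error=float((p < alpha).mean()),
        alpha=alpha,
    )


def per_edge_sd_ratio(
    rho: float,
    n_pairs: int = 100,
    n_reference: int = 100,
    n_case: int = 200,
    seed: int = 1,
) -> float:
    """Mean over edges of sd(delta across case draws) / ((1 - pcc_n^2)/(n - 1)).

    Conditions on one fixed reference cohort, so each edge's theoretical
    scale uses its own realized pcc_n, and averages the per-edge ratio.
    A value near 1 confirms the null scale; the ratio is what the
    acceptance checks bound.
    """
    expr, network = synthetic.simulate_correlated_pairs(
        n_pairs, rho, n_reference, n_case, seed=seed, fpkm=False
    )
    ref = build_reference_network(expr, network)
    per_sample = np.stack(
        [
            sample_edge_statistics(expr, ref, sample_id)["delta"].to_numpy()
            for sample_id in expr.case_ids
        ]
    )
    sd_emp = per_sample.std(axis=0, ddof=1)
    theory = (1.0 - ref.table["pcc_n"].to_numpy() ** 2) / (ref.n - 1)
    return float(np.mean(sd_emp / theory))


def perturbation_detection_rates(
    alphas: tuple[float, ...] = (0.001, 0.01, 0.05),
    n_genes: int = 200,
    n_reference: int = 100,
    n_case: int = 20,
    r: float = 0.4,
    n_perturbed_samples: int = 10,
    n_perturbed_edges: int = 3,
    seed: int = 1,
) -> dict[float, float]:
    """Fraction of planted perturbed edges retained in their sample's SSN,
    per significance level (an ROC-style detection curve over alpha)."""
    from .ssn import build_ssn

    config = synthetic.SimulationConfig(
        n_genes=n_genes,
        n_reference=n_reference,
        n_case=n_case,
        r=r,
        n_perturbed_samples=n_perturbed_samples,
        n_perturbed_edges_per_sample=n_perturbed_edges,
        seed=seed,
    )
    network = synthetic.simulate_background(config)
    expr, plants = synthetic.simulate_expression(config, network)
    ref = build_reference_network(expr, network)
    rates: dict[float, float] = {}
    for alpha in alphas:
        hits = total = 0
        for sample_id, planted in plants.items():
            retained = set(build_ssn(expr, ref, sample_id, alpha=alpha).edges)
            hits += sum(e in retained for e in planted)
            total += len(planted)
        rates[alpha] = hits / total if total else float("nan")
    return rates
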