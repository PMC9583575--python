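"""Sample-specific network construction: correlation, Z-statistic, edge retention."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import brute_force_ssn_edges
from ssdriver import synthetic
from ssdriver.io_formats import BackgroundNetwork, ExpressionMatrix, ValidationError
from ssdriver.ssn import (
    UndefinedCorrelation,
    build_reference_network,
    build_ssn,
    edge_statistic,
    pearson,
    read_ssn,
    sample_edge_statistics,
    write_ssn,
)


class TestPearson:
    def test_identity_and_antisymmetry(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert pearson(x, x) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_textbook_example(self):
        # cov/sigma hand computation for (1,2,3,4) vs (1,3,2,4) gives 0.8
        assert pearson(np.array([1, 2, 3, 4]), np.array([1, 3, 2, 4])) == pytest.approx(0.8)

    def test_constant_vector_is_undefined(self):
        with pytest.raises(UndefinedCorrelation):
            pearson(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))

    def test_length_contracts(self):
        with pytest.raises(ValueError):
            pearson(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            pearson(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0]))


class TestEdgeStatistic:
    def test_null_point(self):
        delta, z, p = edge_statistic(0.3, 0.3, 50)
        assert delta == 0.0 and z == 0.0 and p == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "pcc_n,n,delta",
        [(0.0, 101, 0.02), (0.8, 101, 0.0072), (-0.5, 51, 0.03)],
    )
    def test_against_normal_cdf_oracle(self, pcc_n, n, delta):
        # oracle: z = delta / ((1 - pcc^2)/(n-1)), p = 2(1 - Phi(|z|)), computed here
        # with plain arithmetic + scipy's CDF, independent of the implementation
        d, z, p = edge_statistic(pcc_n, pcc_n + delta, n)
        scale = (1 - pcc_n**2) / (n - 1)
        assert d == pytest.approx(delta)
        assert z == pytest.approx(delta / scale)
        assert p == pytest.approx(2 * (1 - stats.norm.cdf(abs(delta / scale))))

    def test_calibrated_scale_example(self):
        # pcc_n = 0, n = 101: null sd of delta is 1/100, so delta = 0.02 -> z = 2
        _, z, p = edge_statistic(0.0, 0.02, 101)
        assert z == pytest.approx(2.0)
        assert p == pytest.approx(0.0455, abs=1e-4)

    def test_degenerate_reference_correlation_rejected(self):
        with pytest.raises(ValidationError):
            edge_statistic(1.0, 0.5, 100)

    def test_vectorized_matches_scalar(self):
        pcc = np.array([0.0, 0.5, -0.3])
        pcc1 = pcc + np.array([0.01, -0.02, 0.005])
        dv, zv, pv = edge_statistic(pcc, pcc1, 80)
        for i in range(3):
            ds, zs, ps = edge_statistic(pcc[i], pcc1[i], 80)
            assert (dv[i], zv[i], pv[i]) == pytest.approx((ds, zs, ps))


class TestReferenceNetwork:
    def test_missing_endpoint_edges_dropped(self, tiny_expression):
        bg = BackgroundNetwork.from_edges([("A", "B"), ("B", "Z")])
        ref = build_reference_network(tiny_expression, bg)
        assert ref.edges == [("A", "B")]
        assert ref.n_dropped_missing == 1

    def test_two_reference_samples_rejected(self):
        values = pd.DataFrame(
            [[1.0, 2.0, 3.0], [2.0, 1.0, 3.0]], index=["A", "B"],
            columns=["r1", "r2", "c1"],
        )
        expr = ExpressionMatrix(values, ["r1", "r2"], ["c1"])
        with pytest.raises(ValidationError):
            build_reference_network(expr, BackgroundNetwork.from_edges([("A", "B")]))

    def test_empty_intersection_rejected(self, tiny_expression):
        bg = BackgroundNetwork.from_edges([("X", "Y")])
        with pytest.raises(ValidationError):
            build_reference_network(tiny_expression, bg)

    def test_planted_correlation_recovered(self):
        expr, net = synthetic.simulate_correlated_pairs(100, 0.6, 200, 2, seed=13)
        ref = build_reference_network(expr, net)
        assert ref.table["pcc_n"].mean() == pytest.approx(0.6, abs=0.1)

    def test_weights_lie_in_unit_interval(self):
        expr, net = synthetic.simulate_correlated_pairs(50, 0.3, 50, 2, seed=14)
        ref = build_reference_network(expr, net)
        assert ref.table["pcc_n"].between(-1, 1).all()


@pytest.fixture(scope="module")
def null_cohort():
    expr, net = synthetic.simulate_correlated_pairs(200, 0.3, 100, 10, seed=17)
    ref = build_reference_network(expr, net)
    return expr, net, ref


class TestBuildSSN:
    def test_alpha_zero_gives_empty_ssn(self, null_cohort):
        expr, _, ref = null_cohort
        ssn = build_ssn(expr, ref, "T001", alpha=0.0)
        assert len(ssn.table) == 0

    def test_unknown_sample_rejected(self, null_cohort):
        expr, _, ref = null_cohort
        with pytest.raises(ValidationError):
            build_ssn(expr, ref, "nope")

    def test_monotone_in_alpha(self, null_cohort):
        expr, _, ref = null_cohort
        small = set(build_ssn(expr, ref, "T002", alpha=0.01).edges)
        large = set(build_ssn(expr, ref, "T002", alpha=0.10).edges)
        assert small <= large

    def test_sample_order_independence(self, null_cohort):
        expr, _, ref = null_cohort
        first = build_ssn(expr, ref, "T003", alpha=0.05).edges
        build_ssn(expr, ref, "T007", alpha=0.05)  # interleaved other sample
        assert build_ssn(expr, ref, "T003", alpha=0.05).edges == first

    def test_retained_edges_all_significant(self, null_cohort):
        expr, _, ref = null_cohort
        ssn = build_ssn(expr, ref, "T004", alpha=0.05)
        assert (ssn.table["p"] < 0.05).all()
        assert ssn.n_tested == len(ref.table)


def test_brute_force_oracle_equivalence_toy():
    """Retention on a 5-gene, 6-edge instance matches naive loops + normal CDF."""
    rng = np.random.default_rng(23)
    genes = ["A", "B", "C", "D", "E"]
    edges = [("A", "B"), ("A", "C"), ("B", "C"), ("C", "D"), ("D", "E"), ("B", "E")]
    n = 30
    ref_values = rng.standard_normal((5, n)) + 5.0
    case_values = rng.standard_normal((5, 2)) * 3.0 + 5.0
    values = pd.DataFrame(
        np.hstack([ref_values, np.clip(case_values, 0.0, None)]),
        index=genes,
        columns=[f"r{i}" for i in range(n)] + ["c1", "c2"],
    )
    expr = ExpressionMatrix(values, [f"r{i}" for i in range(n)], ["c1", "c2"])
    ref = build_reference_network(expr, BackgroundNetwork.from_edges(edges))
    for sample, col in (("c1", n), ("c2", n + 1)):
        ssn = build_ssn(expr, ref, sample, alpha=0.10)
        gene_idx = {g: i for i, g in enumerate(genes)}
        oracle = brute_force_ssn_edges(
            values.to_numpy()[:, :n],
            values.to_numpy()[:, col],
            [(gene_idx[u], gene_idx[v]) for u, v in ref.edges],
            alpha=0.10,
            n=n,
        )
        expected = sorted(
            tuple(sorted((genes[i], genes[j]))) for i, j in oracle
        )
        assert ssn.edges == expected


def test_null_delta_mean_and_scale():
    """Under the null the mean of delta vanishes and its sd tracks (1-r^2)/(n-1)."""
    expr, net = synthetic.simulate_correlated_pairs(150, 0.5, 100, 40, seed=29)
    ref = build_reference_network(expr, net)
    deltas = np.concatenate(
        [sample_edge_statistics(expr, ref, s)["delta"].to_numpy() for s in expr.case_ids]
    )
    se = deltas.std(ddof=1) / np.sqrt(deltas.size)
    assert abs(deltas.mean()) < 3 * se
    theory = ((1 - ref.table["pcc_n"] ** 2) / (ref.n - 1)).mean()
    assert deltas.std(ddof=1) == pytest.approx(theory, rel=0.15)


def test_planted_perturbation_detected():
    """A planted decoupled edge lands in that sample's SSN; overall retention stays low."""
    config = synthetic.SimulationConfig(
        n_genes=200, n_reference=100, n_case=20, r=0.4,
        n_perturbed_samples=5, n_perturbed_edges_per_sample=3, seed=31,
    )
    net = synthetic.simulate_background(config)
    expr, plants = synthetic.simulate_expression(config, net)
    ref = build_reference_network(expr, net)
    hits = total = 0
    for sample, planted in plants.items():
        retained = set(build_ssn(expr, ref, sample, alpha=0.01).edges)
        hits += sum(e in retained for e in planted)
        total += len(planted)
    assert hits / total > 0.8  # detection rate far above the 0.01 retention level


def test_ssn_file_round_trip(tmp_path):
    expr, net = synthetic.simulate_correlated_pairs(50, 0.3, 50, 3, seed=37)
    ref = build_reference_network(expr, net)
    ssn = build_ssn(expr, ref, "T001", alpha=0.10)
    path = tmp_path / "s.ssn.tsv"
    write_ssn(ssn, path)
    back = read_ssn(path)
    assert back.sample_id == ssn.sample_id
    assert back.alpha == ssn.alpha
    assert back.n_tested == ssn.n_tested
    assert back.edges == ssn.edges
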