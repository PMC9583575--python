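"""Mutation and methylation profiles: binarization, probe filtering, imputation, Hampel."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_hampel
from ssdriver import synthetic
from ssdriver.io_formats import ValidationError
from ssdriver.profiles import (
    ConsolidatedMethylation,
    build_mutation_matrix,
    consolidate_promoter,
    filter_probes,
    hampel_ternary,
    knn_impute,
    seed_genes,
)
from ssdriver.synthetic import SimulationConfig


class TestMutationMatrix:
    def test_counts_threshold_to_binary(self):
        calls = pd.DataFrame({"s1": [3, 0], "s2": [0, 1]}, index=["g1", "g2"])
        m = build_mutation_matrix(calls, ["s1", "s2"])
        assert m.loc["g1", "s1"] == 1 and m.loc["g1", "s2"] == 0
        assert set(np.unique(m.to_numpy())) <= {0, 1}

    def test_requested_gene_absent_from_table_is_zero_row(self):
        calls = pd.DataFrame({"s1": [1]}, index=["g1"])
        m = build_mutation_matrix(calls, ["s1"], genes=["g1", "g9"])
        assert (m.loc["g9"] == 0).all()

    def test_negative_count_rejected(self):
        calls = pd.DataFrame({"s1": [-1]}, index=["g1"])
        with pytest.raises(ValidationError):
            build_mutation_matrix(calls, ["s1"])

    def test_planted_mutations_recovered_exactly(self):
        config = SimulationConfig(
            n_genes=40, n_case=15, mutation_rate=0.0,
            planted_mutations=[("G05", "T002"), ("G17", "T011")], seed=41,
        )
        raw, planted = synthetic.simulate_mutations(config)
        m = build_mutation_matrix(raw, config.case_ids)
        found = [(g, s) for g in m.index for s in m.columns if m.loc[g, s] == 1]
        assert sorted(found) == sorted(planted)


class TestFilterProbes:
    def test_strictly_above_threshold_removed(self):
        beta = pd.DataFrame(
            np.full((1, 100), 0.5), index=["p1"],
            columns=[f"s{i}" for i in range(100)],
        )
        beta.iloc[0, :11] = np.nan  # 11% missing
        assert len(filter_probes(beta)) == 0

    def test_boundary_exactly_at_threshold_kept(self):
        beta = pd.DataFrame(
            np.full((1, 100), 0.5), index=["p1"],
            columns=[f"s{i}" for i in range(100)],
        )
        beta.iloc[0, :10] = np.nan  # exactly 10%
        assert len(filter_probes(beta)) == 1

    def test_complete_matrix_unchanged(self):
        beta = pd.DataFrame(np.random.default_rng(0).random((5, 8)))
        pd.testing.assert_frame_equal(filter_probes(beta), beta)


class TestKnnImpute:
    def test_exact_neighbor_fills_missing_cell(self):
        samples = [f"s{i}" for i in range(6)]
        full = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        beta = pd.DataFrame(
            [full, [0.1, 0.2, 0.3, np.nan, 0.5, 0.6], [0.9] * 6],
            index=["p_full", "p_gap", "p_far"], columns=samples,
        )
        out = knn_impute(beta, k=1)
        assert out.loc["p_gap", "s3"] == pytest.approx(0.4)

    def test_constant_matrix_imputes_constant(self):
        beta = pd.DataFrame(np.full((4, 5), 0.5))
        beta.iloc[1, 2] = np.nan
        out = knn_impute(beta, k=2)
        assert (out.to_numpy() == 0.5).all()

    def test_complete_matrix_is_identity(self):
        beta = pd.DataFrame(np.random.default_rng(1).random((6, 4)))
        pd.testing.assert_frame_equal(knn_impute(beta), beta)

    def test_beats_column_mean_imputation_on_masked_entries(self):
        # correlated probe rows: nearest-neighbour structure is informative
        rng = np.random.default_rng(43)
        base = rng.random((10, 40))
        probes = np.repeat(base, 3, axis=0) + rng.normal(0, 0.02, (30, 40))
        probes = np.clip(probes, 0, 1)
        truth = pd.DataFrame(probes)
        masked = truth.copy()
        cells = [(rng.integers(30), rng.integers(40)) for _ in range(40)]
        for i, j in cells:
            masked.iloc[i, j] = np.nan
        out = knn_impute(masked, k=2)
        col_means = masked.mean(axis=0)
        knn_err, mean_err = [], []
        for i, j in cells:
            knn_err.append((out.iloc[i, j] - truth.iloc[i, j]) ** 2)
            mean_err.append((col_means.iloc[j] - truth.iloc[i, j]) ** 2)
        assert np.sqrt(np.mean(knn_err)) < np.sqrt(np.mean(mean_err))


class TestConsolidatePromoter:
    @pytest.fixture
    def annotation(self):
        return pd.DataFrame(
            {
                "probe_id": ["p1", "p2", "p3", "p4", "p5", "p6"],
                "gene": ["gA", "gA", "gA", "gB", "gB", "gC"],
                "region": ["TSS200", "TSS1500", "1stExon", "5'UTR", "TSS200", "Body"],
            }
        )

    def test_odd_count_median(self, annotation):
        beta = pd.DataFrame(
            {"s1": [0.2, 0.4, 0.9, 0.1, 0.3, 0.8]},
            index=["p1", "p2", "p3", "p4", "p5", "p6"],
        )
        cm = consolidate_promoter(beta, annotation)
        assert cm.values.loc["gA", "s1"] == pytest.approx(0.4)

    def test_even_count_median(self, annotation):
        beta = pd.DataFrame(
            {"s1": [0.2, 0.4, 0.9, 0.2, 0.4, 0.8]},
            index=["p1", "p2", "p3", "p4", "p5", "p6"],
        )
        cm = consolidate_promoter(beta, annotation)
        assert cm.values.loc["gB", "s1"] == pytest.approx(0.3)

    def test_gene_with_only_body_probes_absent(self, annotation):
        beta = pd.DataFrame(
            {"s1": [0.2, 0.4, 0.9, 0.1, 0.3, 0.8]},
            index=["p1", "p2", "p3", "p4", "p5", "p6"],
        )
        cm = consolidate_promoter(beta, annotation)
        assert "gC" not in cm.values.index


class TestHampelTernary:
    def test_hand_computed_bounds_are_strict(self):
        # values (0.2, 0.4, 0.5, 0.6, 0.95): MED=0.5, MAD=0.1, bounds (0.2, 0.8);
        # 0.2 sits exactly on the lower bound and must NOT be flagged
        cm = ConsolidatedMethylation(
            pd.DataFrame([[0.2, 0.4, 0.5, 0.6, 0.95]], index=["g"],
                         columns=list("abcde"))
        )
        mt = hampel_ternary(cm)
        assert list(mt.loc["g"]) == [0, 0, 0, 0, 1]

    def test_zero_mad_flags_any_departure(self):
        cm = ConsolidatedMethylation(
            pd.DataFrame([[0.1, 0.1, 0.1, 0.1, 0.9]], index=["g"],
                         columns=list("abcde"))
        )
        mt = hampel_ternary(cm)
        assert list(mt.loc["g"]) == [0, 0, 0, 0, 1]

    def test_constant_gene_all_zero(self):
        cm = ConsolidatedMethylation(
            pd.DataFrame([[0.5] * 5], index=["g"], columns=list("abcde"))
        )
        assert (hampel_ternary(cm).loc["g"] == 0).all()

    def test_column_order_invariance(self):
        rng = np.random.default_rng(47)
        values = pd.DataFrame(rng.random((6, 12)),
                              columns=[f"s{i}" for i in range(12)])
        mt = hampel_ternary(ConsolidatedMethylation(values))
        shuffled_cols = list(rng.permutation(values.columns))
        mt2 = hampel_ternary(ConsolidatedMethylation(values[shuffled_cols]))
        pd.testing.assert_frame_equal(mt[shuffled_cols], mt2)

    def test_incomplete_matrix_rejected(self):
        values = pd.DataFrame([[0.5, np.nan]], index=["g"], columns=["a", "b"])
        with pytest.raises(ValidationError):
            hampel_ternary(ConsolidatedMethylation(values))

    def test_matches_naive_per_gene_oracle(self):
        rng = np.random.default_rng(53)
        values = pd.DataFrame(
            rng.beta(2, 2, size=(10, 30)), index=[f"g{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(30)],
        )
        mt = hampel_ternary(ConsolidatedMethylation(values))
        for gene in values.index:
            assert list(mt.loc[gene]) == brute_force_hampel(list(values.loc[gene]))


class TestEndToEndMethylation:
    def test_planted_outliers_called_and_high_missing_probe_removed(self):
        config = SimulationConfig(
            n_genes=60, n_case=40, missing_fraction=0.02,
            n_planted_methylation=12, seed=59,
        )
        annotation = synthetic.make_annotation(config)
        beta, plants = synthetic.simulate_methylation(config, annotation)
        # force one probe above the missingness threshold
        beta.loc[beta.index[0], beta.columns[: int(0.2 * len(beta.columns))]] = np.nan
        filtered = filter_probes(beta, 0.10)
        assert beta.index[0] not in filtered.index
        complete = knn_impute(filtered, k=10)
        mt = hampel_ternary(consolidate_promoter(complete, annotation))
        called = sum(
            1 for gene, sample, direction in plants
            if gene in mt.index and mt.loc[gene, sample] == direction
        )
        assert called / len(plants) >= 0.95

    def test_seed_gene_extraction(self):
        mt = pd.DataFrame({"s1": [1, 0, -1]}, index=["g1", "g2", "g3"])
        assert seed_genes(mt["s1"], "methylation") == frozenset({"g1", "g3"})
        m = pd.DataFrame({"s1": [1, 0, 0]}, index=["g1", "g2", "g3"])
        assert seed_genes(m["s1"], "mutation") == frozenset({"g1"})
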