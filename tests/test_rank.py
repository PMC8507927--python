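"""Normalization, depletion fold changes, second-best gene ranking, comparisons."""

import numpy as np
import pandas as pd
import pytest

from dropscreen import (
    ParameterError,
    SampleRecord,
    assemble_count_matrix,
    fold_changes,
    gene_scores_second_best,
    generate_library,
    normalize_counts,
    plant_effects,
    recovery_report,
    replicate_concordance,
    setting_specific_genes,
    simulate_screen_counts,
    top_fraction_set,
)
from dropscreen.rank import FoldChangeTable, GeneRankTable


def matrix_from_columns(design, **columns):
    samples = [SampleRecord(sid, "baseline" if "base" in sid else "setting1", 1,
                            None if "base" in sid else 0.25)
               for sid in columns]
    return assemble_count_matrix(
        {sid: np.asarray(v) for sid, v in columns.items()}, samples, design)


def fc_table(values, genes=None):
    idx = [f"sh{i}" for i in range(len(values))]
    tbl = pd.DataFrame({
        "gene_symbol": genes or ["G"] * len(values),
        "fc_depletion": np.asarray(values, dtype=float),
    }, index=idx)
    tbl["log2_fc"] = np.log2(tbl["fc_depletion"])
    return FoldChangeTable(tbl, "b", "f", 0.5)


class TestNormalizeCounts:
    def test_hand_computed_pseudocount(self, tiny_design):
        counts = np.zeros(10, dtype=int)
        counts[0], counts[1] = 100, 0
        m = matrix_from_columns(tiny_design, s_base=counts)
        norm = normalize_counts(m, pseudocount=0.5)
        total = 100.5 + 9 * 0.5
        np.testing.assert_allclose(norm["s_base"].iloc[0], 100.5 / total * 1e6)
        np.testing.assert_allclose(norm["s_base"].iloc[1], 0.5 / total * 1e6)

    def test_columns_sum_to_one_million(self, tiny_design, rng):
        m = matrix_from_columns(tiny_design,
                                s_base=rng.integers(0, 1000, 10),
                                s_sel=rng.integers(0, 1000, 10))
        norm = normalize_counts(m)
        np.testing.assert_allclose(norm.sum(axis=0), 1e6, rtol=1e-6)

    def test_zero_pseudocount_is_plain_rpm(self, tiny_design):
        counts = np.arange(1, 11)
        m = matrix_from_columns(tiny_design, s_base=counts)
        norm = normalize_counts(m, pseudocount=0.0)
        np.testing.assert_allclose(norm["s_base"].to_numpy(),
                                   counts / counts.sum() * 1e6)

    def test_all_zero_column_raises(self, tiny_design):
        m = matrix_from_columns(tiny_design, s_base=np.zeros(10, dtype=int))
        with pytest.raises(ParameterError, match="s_base"):
            normalize_counts(m, pseudocount=0.0)


class TestFoldChanges:
    def test_identical_columns_give_unit_fc(self, tiny_design, rng):
        c = rng.integers(1, 500, 10)
        m = matrix_from_columns(tiny_design, s_base=c, s_sel=c)
        fc = fold_changes(normalize_counts(m), "s_base", "s_sel", tiny_design)
        np.testing.assert_allclose(fc.fc, 1.0)

    def test_full_depletion_hand_value(self, tiny_design):
        # 100 -> 0 at equal depths with pseudocount 0.5: fc = 100.5 / 0.5 = 201
        base = np.full(10, 100)
        sel = np.full(10, 100)
        sel[0] = 0
        base[1] = 0  # balance depths: both columns sum to 900
        sel[1] = 100
        m = matrix_from_columns(tiny_design, s_base=base, s_sel=sel)
        fc = fold_changes(normalize_counts(m), "s_base", "s_sel", tiny_design)
        np.testing.assert_allclose(fc.fc.iloc[0], 201.0)

    def test_depth_invariance_at_zero_pseudocount(self, tiny_design, rng):
        base = rng.integers(1, 500, 10)
        sel = rng.integers(1, 500, 10)
        m1 = matrix_from_columns(tiny_design, s_base=base, s_sel=sel)
        m2 = matrix_from_columns(tiny_design, s_base=base, s_sel=sel * 7)
        fc1 = fold_changes(normalize_counts(m1, 0.0), "s_base", "s_sel", tiny_design)
        fc2 = fold_changes(normalize_counts(m2, 0.0), "s_base", "s_sel", tiny_design)
        np.testing.assert_allclose(fc1.fc, fc2.fc)

    def test_unknown_sample_raises(self, tiny_design, rng):
        m = matrix_from_columns(tiny_design, s_base=rng.integers(1, 9, 10))
        with pytest.raises(KeyError):
            fold_changes(normalize_counts(m), "s_base", "nope", tiny_design)


class TestSecondBestScores:
    def test_forced_example(self):
        vals = [8.0, 3.0, 2.0, 1.1, 0.9]
        design = generate_library(1, 5, barcode_length=8, seed=0)
        tbl = fc_table(vals, genes=[design.records[0].gene_symbol] * 5)
        tbl.table.index = design.shrna_ids
        ranks = gene_scores_second_best(tbl, design)
        assert ranks.table["score"].iloc[0] == 3.0

    def test_two_gene_ranking(self, tiny_design):
        genes = [r.gene_symbol for r in tiny_design.records]
        vals = [5.0, 5.0, 1.0, 1.0, 1.0, 2.0, 2.0, 0.5, 0.5, 0.5]
        tbl = fc_table(vals, genes=genes)
        tbl.table.index = tiny_design.shrna_ids
        ranks = gene_scores_second_best(tbl, tiny_design)
        g1, g2 = tiny_design.reliable_genes
        assert ranks.table.loc[g1, "rank"] == 1
        assert ranks.table.loc[g2, "rank"] == 2

    def test_brute_force_oracle_on_random_fixtures(self, rng):
        # independent oracle: per-gene numpy sort, take the second element
        design = generate_library(100, 550, barcode_length=10, seed=20)
        for trial in range(50):
            fcs = rng.lognormal(0, 1, design.complexity)
            tbl = fc_table(fcs)
            tbl.table.index = design.shrna_ids
            tbl.table["gene_symbol"] = [r.gene_symbol for r in design.records]
            ranks = gene_scores_second_best(tbl, design)
            for gene in design.reliable_genes:
                rows = design.rows_for_gene(gene)
                expected = np.sort(fcs[rows])[-2]
                assert ranks.table.loc[gene, "score"] == expected

    def test_ties_broken_lexicographically_and_flagged(self, tiny_design):
        tbl = fc_table([2.0] * 10, genes=[r.gene_symbol for r in tiny_design.records])
        tbl.table.index = tiny_design.shrna_ids
        ranks = gene_scores_second_best(tbl, tiny_design)
        assert list(ranks.table.index) == sorted(tiny_design.reliable_genes)
        assert ranks.table["tie_flag"].all()

    def test_gene_with_one_measured_shrna_raises(self, tiny_design):
        tbl = fc_table([2.0] * 10, genes=[r.gene_symbol for r in tiny_design.records])
        tbl.table.index = tiny_design.shrna_ids
        gene = tiny_design.reliable_genes[0]
        rows = tiny_design.rows_for_gene(gene)[1:]
        tbl.table.loc[[tiny_design.shrna_ids[i] for i in rows], "fc_depletion"] = np.nan
        tbl.table = tbl.table.dropna()
        with pytest.raises(ParameterError, match="fewer than 2"):
            gene_scores_second_best(tbl, tiny_design)

    def test_auxiliary_targets_never_ranked(self, small_design):
        tbl = fc_table(np.linspace(1, 5, small_design.complexity),
                       genes=[r.gene_symbol for r in small_design.records])
        tbl.table.index = small_design.shrna_ids
        ranks = gene_scores_second_best(tbl, small_design)
        assert not any(g.startswith("AUX") for g in ranks.table.index)
        assert ranks.n_genes == len(small_design.reliable_genes)


class TestConcordance:
    def test_identical_tables_give_unit_spearman(self):
        t = fc_table([1.0, 2.0, 3.0, 4.0])
        rho, r = replicate_concordance(t, t)
        assert rho == pytest.approx(1.0)
        assert r == pytest.approx(1.0)

    def test_reciprocal_tables_give_negative_unit_spearman(self):
        t1 = fc_table([1.0, 2.0, 3.0, 4.0])
        t2 = fc_table([1.0, 0.5, 1 / 3, 0.25])
        rho, r = replicate_concordance(t1, t2)
        assert rho == pytest.approx(-1.0)
        assert r == pytest.approx(-1.0)

    def test_too_few_shared_shrnas_raises(self):
        with pytest.raises(ParameterError):
            replicate_concordance(fc_table([1.0, 2.0]), fc_table([2.0, 1.0]))

    def test_simulated_duplicates_are_concordant(self):
        rhos = []
        for seed in range(5):
            design = generate_library(300, 1500, barcode_length=12, seed=seed)
            eff = plant_effects(design, 0.05, seed=seed + 50)
            samples, counts = simulate_screen_counts(
                design, eff, ["setting1"], 2, 9.0, 750_000, 0.005, seed=seed + 99)
            m = assemble_count_matrix(counts, samples, design)
            norm = normalize_counts(m)
            fc1 = fold_changes(norm, "baseline_rep1", "setting1_rep1", design)
            fc2 = fold_changes(norm, "baseline_rep2", "setting1_rep2", design)
            rhos.append(replicate_concordance(fc1, fc2)[0])
        assert np.mean(rhos) > 0.7


class TestSetOperations:
    def ranks_of(self, n, seed=0):
        scores = np.linspace(10, 1, n)
        tbl = pd.DataFrame({
            "score": scores,
            "rank": np.arange(1, n + 1),
            "n_shrnas": 5,
            "tie_flag": False,
        }, index=[f"G{i:04d}" for i in range(n)])
        tbl.index.name = "gene_symbol"
        return GeneRankTable(tbl)

    def test_top_fraction_ceiling(self):
        assert len(top_fraction_set(self.ranks_of(4974), 0.01)) == 50
        assert len(top_fraction_set(self.ranks_of(100), 0.01)) == 1
        assert len(top_fraction_set(self.ranks_of(100), 1.0)) == 100

    def test_top_fraction_takes_best_ranks(self):
        top = top_fraction_set(self.ranks_of(100), 0.05)
        assert top == {f"G{i:04d}" for i in range(5)}

    def test_invalid_fraction_raises(self):
        with pytest.raises(ParameterError):
            top_fraction_set(self.ranks_of(10), 0.0)

    def test_setting_specific_set_algebra(self):
        out = setting_specific_genes([{"A", "B", "C"}, {"B", "C", "D"}], [{"C"}])
        assert out == {"B"}

    def test_identical_sets_give_empty_result(self):
        s = {"A", "B"}
        assert setting_specific_genes([s, s], [s]) == set()

    def test_empty_arguments_raise(self):
        with pytest.raises(ParameterError):
            setting_specific_genes([], [{"A"}])


class TestRecoveryReport:
    def test_perfect_ranking_gives_unit_sensitivity(self, small_design):
        eff = plant_effects(small_design, 0.2, background_sd=0.0, seed=3)
        planted = eff.essential_genes
        genes = sorted(small_design.reliable_genes,
                       key=lambda g: (g not in planted, g))
        n = len(genes)
        tbl = pd.DataFrame({"score": np.linspace(10, 1, n),
                            "rank": np.arange(1, n + 1),
                            "n_shrnas": 5, "tie_flag": False}, index=genes)
        tbl.index.name = "gene_symbol"
        ranks = GeneRankTable(tbl)
        sens, prec = recovery_report(ranks, eff, len(planted) / n)
        assert sens == 1.0 and prec == 1.0

    def test_sensitivity_monotone_in_top_fraction(self, small_design):
        eff = plant_effects(small_design, 0.2, background_sd=0.0, seed=3)
        n = len(small_design.reliable_genes)
        genes = sorted(small_design.reliable_genes)
        tbl = pd.DataFrame({"score": np.linspace(10, 1, n),
                            "rank": np.arange(1, n + 1),
                            "n_shrnas": 5, "tie_flag": False}, index=genes)
        tbl.index.name = "gene_symbol"
        ranks = GeneRankTable(tbl)
        prev = 0.0
        for frac in (0.1, 0.3, 0.6, 1.0):
            sens, _ = recovery_report(ranks, eff, frac)
            assert sens >= prev
            prev = sens

    def test_empty_planted_set_raises(self, small_design):
        eff = plant_effects(small_design, 0.0, background_sd=0.0, seed=3)
        tbl = pd.DataFrame({"score": [2.0, 1.0], "rank": [1, 2],
                            "n_shrnas": 5, "tie_flag": False},
                           index=small_design.reliable_genes[:2])
        tbl.index.name = "gene_symbol"
        with pytest.raises(ParameterError):
            recovery_report(GeneRankTable(tbl), eff, 0.5)


class TestNullCalibration:
    def test_scores_exchangeable_without_planted_effects(self):
        # no planted essentials: an arbitrary gene split shows no score shift
        from scipy import stats as sps
        design = generate_library(400, 2000, barcode_length=12, seed=30)
        eff = plant_effects(design, 0.0, background_sd=0.0, seed=31)
        samples, counts = simulate_screen_counts(
            design, eff, ["setting1"], 1, 9.0, 1_000_000, 0.0, seed=32)
        m = assemble_count_matrix(counts, samples, design)
        fc = fold_changes(normalize_counts(m), "baseline_rep1", "setting1_rep1",
                          design)
        scores = gene_scores_second_best(fc, design).table["score"]
        rng = np.random.default_rng(33)
        fake = rng.choice(scores.index, size=20, replace=False)
        group_a = scores.loc[fake]
        group_b = scores.drop(fake)
        p = sps.mannwhitneyu(group_a, group_b).pvalue
        assert p > 0.01
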