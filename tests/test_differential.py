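import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mkptools.differential import (
    adt_score,
    compute_base_mean,
    filter_degs,
    nb_wald_test,
    pseudobulk_aggregate,
    score_adt_table,
    select_adt_candidates,
    size_factors,
)
from mkptools.simulate import generate_pseudobulk_counts


class TestPseudobulk:
    def frame(self):
        counts = pd.DataFrame(
            {"g1": [1, 2, 3, 4], "g2": [0, 0, 5, 0]},
            index=["c1", "c2", "c3", "c4"],
        )
        meta = pd.DataFrame(
            {
                "biosample": ["s1", "s1", "s1", "s2"],
                "condition": ["A", "A", "A", "B"],
            },
            index=counts.index,
        )
        return counts, meta

    def test_sums_cells_within_group(self):
        counts, meta = self.frame()
        agg, sample_meta = pseudobulk_aggregate(counts, meta)
        assert agg.loc["g1", "s1|A"] == 6
        assert agg.loc["g2", "s1|A"] == 5
        assert sample_meta.loc["s1|A", "n_cells"] == 3

    def test_single_cell_group_is_identity(self):
        counts, meta = self.frame()
        agg, _ = pseudobulk_aggregate(counts, meta)
        assert agg.loc["g1", "s2|B"] == 4

    def test_total_counts_conserved(self, small_dataset):
        rna = small_dataset.rna_frame()
        agg, _ = pseudobulk_aggregate(rna, small_dataset.cell_meta)
        assert agg.to_numpy().sum() == rna.to_numpy().sum()


class TestSizeFactors:
    def test_hand_computed_two_samples(self):
        counts = pd.DataFrame({"s1": [2, 4], "s2": [4, 8]})
        np.testing.assert_allclose(
            size_factors(counts), [np.sqrt(2) / 2, np.sqrt(2)], atol=1e-12
        )

    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"s1": [3, 7, 1], "s2": [3, 7, 1], "s3": [3, 7, 1]})
        np.testing.assert_allclose(size_factors(counts), np.ones(3), atol=1e-12)

    def test_scaling_one_sample_scales_its_factor_ratio(self):
        # size factors are defined up to a common scale (the geometric-mean
        # reference moves too), so the invariant is on factor ratios
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(1, 200, size=(50, 4)), columns=list("abcd"))
        base = size_factors(counts)
        scaled = counts.copy()
        scaled["b"] *= 3
        out = size_factors(scaled)
        assert out["b"] / out["a"] == pytest.approx(3 * base["b"] / base["a"], rel=1e-9)
        assert out["c"] / out["a"] == pytest.approx(base["c"] / base["a"], rel=1e-9)

    def test_all_zero_overlap_raises(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [3, 0]})
        with pytest.raises(ValueError):
            size_factors(counts)


class TestNbWald:
    def test_identical_conditions_give_zero_lfc(self):
        block = pd.DataFrame({"g1": [10, 20], "g2": [5, 0]}).T
        counts = pd.concat([block, block], axis=1)
        counts.columns = ["a1", "a2", "b1", "b2"]
        cond = pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        res = nb_wald_test(counts, cond)
        np.testing.assert_allclose(res["log2FC"], 0.0, atol=1e-6)

    def test_all_zero_gene_handling(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.poisson(50, size=(10, 4)), columns=["a1", "a2", "b1", "b2"]
        )
        counts.iloc[3] = 0
        cond = pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        res = nb_wald_test(counts, cond)
        assert res["log2FC"].iloc[3] == 0.0
        assert np.isnan(res["padj"].iloc[3])

    def test_planted_effect_estimates_unbiased(self):
        # a small planted fraction so median-of-ratios normalization is
        # not distorted by the planted genes themselves
        counts, cond, truth = generate_pseudobulk_counts(
            n_genes=400, n_planted=20, planted_log2fc=2.0, seed=5
        )
        res = nb_wald_test(counts, cond)
        assert res["log2FC"].iloc[:20].mean() == pytest.approx(2.0, abs=0.15)
        assert res["log2FC"].iloc[20:].mean() == pytest.approx(0.0, abs=0.05)

    def test_benjamini_hochberg_is_monotone(self):
        counts, cond, _ = generate_pseudobulk_counts(n_genes=500, seed=2)
        res = nb_wald_test(counts, cond).dropna(subset=["pvalue"])
        ordered = res.sort_values("pvalue")
        assert ordered["padj"].is_monotonic_increasing
        assert (res["padj"] >= res["pvalue"]).all()

    def test_agrees_with_deseq2(self):
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.default_inference import DefaultInference
        from pydeseq2.ds import DeseqStats

        counts, cond, _ = generate_pseudobulk_counts(
            n_genes=200, n_planted=20, planted_log2fc=2.0, seed=3
        )
        res = nb_wald_test(counts, cond)

        inference = DefaultInference(n_cpus=1)
        dds = DeseqDataSet(
            counts=counts.T,
            metadata=pd.DataFrame({"condition": cond}),
            design="~condition",
            inference=inference,
            quiet=True,
        )
        dds.deseq2()
        stats = DeseqStats(
            dds, contrast=["condition", "B", "A"], inference=inference, quiet=True
        )
        stats.summary()
        reference = stats.results_df["log2FoldChange"]

        merged = pd.concat([reference, res["log2FC"]], axis=1).dropna()
        assert merged.corr().iloc[0, 1] > 0.99
        assert (merged.iloc[:, 0] - merged.iloc[:, 1]).abs().mean() < 0.05

    def test_requires_two_conditions_with_replicates(self):
        counts = pd.DataFrame({"a1": [1], "b1": [2], "b2": [3]})
        with pytest.raises(ValueError):
            nb_wald_test(counts, pd.Series({"a1": "A", "b1": "B", "b2": "B"}))


class TestBaseMean:
    def test_mean_of_normalized_counts(self):
        counts = pd.DataFrame({"s1": [0], "s2": [5], "s3": [10]})
        factors = pd.Series(1.0, index=counts.columns)
        out = compute_base_mean(counts, ["s1", "s2", "s3"], factors)
        assert out.iloc[0] == pytest.approx(5.0)

    def test_normalization_invariance(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(rng.integers(1, 100, size=(20, 3)), columns=list("xyz"))
        factors = size_factors(counts)
        base = compute_base_mean(counts, ["x", "y"], factors)
        doubled = compute_base_mean(counts * 2, ["x", "y"], factors * 2)
        np.testing.assert_allclose(base, doubled, rtol=1e-12)

    def test_unknown_condition_member_raises(self):
        counts = pd.DataFrame({"s1": [1], "s2": [2]})
        with pytest.raises(KeyError):
            compute_base_mean(counts, ["s1", "nope"])
        with pytest.raises(ValueError):
            compute_base_mean(counts, [])


class TestFilterDegs:
    def test_strict_keeps_high_fc_low_padj(self, toy_deg_table):
        kept = filter_degs(toy_deg_table, "strict", "sc")
        assert list(kept.index) == ["g1"]

    def test_blocklisted_gene_always_dropped(self, toy_deg_table):
        for mode in ("strict", "relaxed"):
            assert "mt-Co1" not in filter_degs(toy_deg_table, mode, "sc").index

    def test_missing_padj_dropped(self, toy_deg_table):
        assert "g5" not in filter_degs(toy_deg_table, "relaxed", "sc").index

    def test_relaxed_or_rule(self, toy_deg_table):
        kept = filter_degs(toy_deg_table, "relaxed", "sc")
        # g4 (log2FC 0.1, padj 0.001) passes via the padj arm of the OR
        assert list(kept.index) == ["g1", "g2", "g3", "g4"]

    def test_abundance_floor_in_both_conditions(self, toy_deg_table):
        low = toy_deg_table.copy()
        low.loc["g1", ["baseMean_A", "baseMean_B"]] = [5.0, 4.0]
        assert "g1" not in filter_degs(low, "strict", "sc").index
        # above the floor in one condition is enough to survive
        one_side = toy_deg_table.copy()
        one_side.loc["g1", ["baseMean_A", "baseMean_B"]] = [5.0, 40.0]
        assert "g1" in filter_degs(one_side, "strict", "sc").index
        # bulk floor is 50
        assert "g1" not in filter_degs(one_side, "strict", "bulk").index

    def test_unknown_mode_or_kind_raises(self, toy_deg_table):
        with pytest.raises(ValueError):
            filter_degs(toy_deg_table, "loose", "sc")
        with pytest.raises(ValueError):
            filter_degs(toy_deg_table, "strict", "spatial")

    @given(st.data())
    def test_strict_is_subset_of_relaxed(self, data):
        n = data.draw(st.integers(3, 25))
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        table = pd.DataFrame(
            {
                "log2FC": rng.normal(0, 2.5, n),
                "padj": rng.random(n),
                "baseMean_A": rng.uniform(0, 100, n),
                "baseMean_B": rng.uniform(0, 100, n),
                "blocklist_category": rng.choice(["none", "mito", "ribo"], n),
            },
            index=[f"g{i}" for i in range(n)],
        )
        strict = set(filter_degs(table, "strict", "sc").index)
        relaxed = set(filter_degs(table, "relaxed", "sc").index)
        assert strict <= relaxed


class TestAdtScore:
    def test_wilcoxon_hand_computed(self):
        # rank-sum of A = 6, E = 10.5, Var = 3*3*7/12 = 5.25
        rec = adt_score([1, 2, 3], [4, 5, 6], method="wilcoxon")
        assert rec.score == pytest.approx(-4.5 / np.sqrt(5.25), abs=1e-9)

    def test_sign_flips_when_groups_swap(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 30), rng.normal(1, 1, 25)
        fwd = adt_score(a, b, method="wilcoxon").score
        rev = adt_score(b, a, method="wilcoxon").score
        assert fwd == pytest.approx(-rev, abs=1e-9)
        # the overestimated-variance t is only symmetric for equal sizes
        # (its denominator is anchored to the first group's size)
        a25, b25 = a[:25], b
        assert adt_score(a25, b25, method="ttest_overestim_var").score == pytest.approx(
            -adt_score(b25, a25, method="ttest_overestim_var").score, abs=1e-9
        )

    def test_near_identical_groups_score_near_zero(self):
        rng = np.random.default_rng(9)
        base = rng.normal(0, 1, 40)
        a = base + rng.normal(0, 1e-9, 40)
        assert abs(adt_score(a, base, method="ttest_overestim_var").score) < 1e-3

    def test_overestim_var_uses_first_group_size(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
        expected = (a.mean() - b.mean()) / np.sqrt(
            a.var(ddof=1) / a.size + b.var(ddof=1) / a.size
        )
        assert adt_score(a, b, method="ttest_overestim_var").score == pytest.approx(
            expected, abs=1e-12
        )

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            adt_score([], [1.0])
        with pytest.raises(ValueError):
            adt_score([1.0, 1.0], [1.0, 1.0], method="wilcoxon")


class TestCandidateSelection:
    def scores(self):
        return pd.DataFrame(
            {
                "score": [-12.0, -6.0, -15.0],
                "method": "wilcoxon",
                "excluded": [False, False, True],  # CD4 is a lineage marker
            },
            index=["CD48", "CD9", "CD4"],
        )

    def test_restrictive_cutoff(self):
        kept = select_adt_candidates(self.scores(), cutoff="restrictive")
        assert list(kept.index) == ["CD48"]
        assert kept.loc["CD48", "direction"] == "B"

    def test_relaxed_cutoff(self):
        kept = select_adt_candidates(self.scores(), cutoff="relaxed")
        assert list(kept.index) == ["CD48", "CD9"]

    def test_empty_scores(self):
        out = select_adt_candidates(self.scores().iloc[:0], cutoff="relaxed")
        assert out.empty

    def test_table_scoring_flags_defining_markers(self, small_dataset, small_clr):
        labels = small_dataset.cell_meta["subtype"]
        scores = score_adt_table(small_clr, labels, "cMkP", "ncMkP")
        assert scores.loc["CD117", "excluded"]
        assert scores.loc["CD4", "excluded"]
        assert not scores.loc["CD48", "excluded"]
        # CD48 is higher in cMkPs, CD9 higher in ncMkPs
        assert scores.loc["CD48", "score"] > 10
        assert scores.loc["CD9", "score"] < -5
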