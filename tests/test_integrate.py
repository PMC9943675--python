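import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clipsite.integrate import (
    build_sets,
    dendritic_consensus,
    hypergeom_enrichment,
    overlap_test,
    proteomics_ratios,
    published_membership,
    shift_test,
    top_terms,
    zscore_rows,
)

from reference_impl import fisher_two_sided_p


def protein_row(pid, kd, ctrl, padj=0.5, gene=None):
    row = {"protein_id": pid, "gene_id": gene or pid}
    row.update({f"KD{i+1}": v for i, v in enumerate(kd)})
    row.update({f"CTRL{i+1}": v for i, v in enumerate(ctrl)})
    row["padj"] = padj
    return row


NA = np.nan


class TestProteomicsRatios:
    def test_all_missing_in_kd_is_infinite_down(self):
        df = pd.DataFrame([protein_row("p", [NA] * 4, [8, 8, 8, 8])])
        out = proteomics_ratios(df, log2_transform=False)
        assert out.loc[0, "ratio_flag"] == "infinite"
        assert out.loc[0, "log2_ratio"] == -np.inf

    def test_all_missing_in_ctrl_is_infinite_up(self):
        df = pd.DataFrame([protein_row("p", [9, 9, 9, 9], [NA] * 4)])
        out = proteomics_ratios(df, log2_transform=False)
        assert out.loc[0, "log2_ratio"] == np.inf

    def test_two_missing_is_non_quantifiable(self):
        df = pd.DataFrame([protein_row("p", [10, NA, NA, 12], [8, 8, 8, 8])])
        out = proteomics_ratios(df, log2_transform=False)
        assert out.loc[0, "ratio_flag"] == "non_quantifiable"
        assert np.isnan(out.loc[0, "log2_ratio"])

    def test_one_missing_uses_three_samples(self):
        df = pd.DataFrame([protein_row("p", [10, 10, 10, NA], [8, 8, 8, 8])])
        out = proteomics_ratios(df, log2_transform=False)
        assert out.loc[0, "ratio_flag"] == "quantified"
        assert out.loc[0, "log2_ratio"] == pytest.approx(2.0)

    def test_raw_intensities_are_log2_transformed(self):
        df = pd.DataFrame([protein_row("p", [1024] * 4, [256] * 4)])
        out = proteomics_ratios(df)  # log2(1024) - log2(256) = 2
        assert out.loc[0, "log2_ratio"] == pytest.approx(2.0)

    def test_non_4v4_design_rejected(self):
        df = pd.DataFrame([protein_row("p", [1] * 4, [1] * 4)])
        with pytest.raises(ValueError, match="4-vs-4"):
            proteomics_ratios(df, kd_cols=["KD1", "KD2"])


class TestBuildSets:
    def _tables(self, genes, rna_sig, prot_sig, flip_sign=()):
        rna = pd.DataFrame(
            dict(
                gene_id=genes,
                log2FoldChange=[
                    (-1.0 if g in flip_sign else 1.0) if g in rna_sig else 0.0
                    for g in genes
                ],
                padj=[0.001 if g in rna_sig else 0.5 for g in genes],
            )
        )
        prot = pd.DataFrame(
            [
                protein_row(
                    f"P_{g}",
                    [20 + (1.0 if g in prot_sig else 0.0)] * 4,
                    [20.0] * 4,
                    padj=0.001 if g in prot_sig else 0.5,
                    gene=g,
                )
                for g in genes
            ]
        )
        prot = proteomics_ratios(prot, log2_transform=False)
        return rna, prot

    def test_triple_intersection_matches_truth(self, small_run):
        truth, omics = small_run["truth"], small_run["omics"]
        prot = proteomics_ratios(omics.protein, log2_transform=False)
        bound = truth.bound_genes
        sets = build_sets(omics.rna, prot, bound)
        expected = truth.validated_targets & set(prot["gene_id"])
        # the generator may leave a regulated protein unquantifiable; every
        # validated set member must still be bound and doubly significant
        assert sets.validated <= expected
        assert len(sets.validated) >= 0.5 * len(expected)

    def test_empty_protein_table_empty_triple(self):
        genes = [f"g{i}" for i in range(6)]
        rna, prot = self._tables(genes, set(genes), set())
        sets = build_sets(rna, prot, genes)
        assert sets.validated == set()

    def test_concordant_fraction_three_of_four(self):
        genes = ["a", "b", "c", "d"]
        rna, prot = self._tables(genes, set(genes), set(genes), flip_sign=("d",))
        sets = build_sets(rna, prot, genes)
        assert sets.concordant_fraction == pytest.approx(0.75)

    def test_duplicate_identifiers_rejected(self):
        genes = ["a", "a", "b"]
        rna, prot = self._tables(genes, set(), set())
        with pytest.raises(ValueError, match="duplicate"):
            build_sets(rna, prot, genes)


class TestOverlapTest:
    def _sets_from_table(self, a, b, c, d):
        universe = [f"e{i}" for i in range(a + b + c + d)]
        A = set(universe[: a + b])
        B = set(universe[:a]) | set(universe[a + b : a + b + c])
        return A, B, universe

    def test_cross_product_odds_ratio(self):
        A, B, U = self._sets_from_table(10, 5, 5, 10)
        res = overlap_test(A, B, U)
        assert res.odds_ratio == pytest.approx(4.0)
        assert res.table == ((10, 5), (5, 10))

    def test_haldane_correction_applied_on_zero_cell(self):
        A, B, U = self._sets_from_table(0, 10, 10, 10)
        res = overlap_test(A, B, U)
        assert res.odds_ratio == pytest.approx((0.5 * 10.5) / (10.5 * 10.5))
        assert np.isfinite(res.ci_low) and np.isfinite(res.ci_high)

    def test_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, 4))
            if a + b + c + d == 0:
                continue
            A, B, U = self._sets_from_table(a, b, c, d)
            res = overlap_test(A, B, U)
            assert res.p_value == pytest.approx(fisher_two_sided_p(a, b, c, d),
                                                rel=1e-8)

    def test_disjoint_halves_depleted(self):
        U = [f"e{i}" for i in range(40)]
        res = overlap_test(U[:20], U[20:], U)
        assert res.odds_ratio < 1
        assert res.p_value == pytest.approx(
            fisher_two_sided_p(0, 20, 20, 0), rel=1e-8
        )

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            overlap_test({"a"}, {"b"}, set())


class TestShiftTest:
    def test_identical_groups_p_near_one(self):
        g = [1.0, 2.0, 3.0, 4.0, 5.0]
        p, med = shift_test(g, g)
        assert p > 0.9
        assert med == 0.0

    def test_large_shift_tiny_p(self):
        rng = np.random.default_rng(1)
        a = rng.normal(10, 1, 50)
        b = rng.normal(0, 1, 50)
        p, med = shift_test(a, b)
        assert p < 1e-10
        assert med == pytest.approx(10, abs=1)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(1, 1, 30), rng.normal(0, 1, 30)
        p1, _ = shift_test(a, b)
        p2, _ = shift_test(np.exp(a), np.exp(b))
        assert p1 == pytest.approx(p2)

    def test_small_group_warns(self):
        with pytest.warns(UserWarning):
            shift_test([1.0, 2.0], [0.0, 1.0, 2.0, 3.0])


class TestMembershipRules:
    def test_published_membership_filter(self):
        table = pd.DataFrame(
            dict(
                gene_id=["a", "b", "c", "d", "e", "f"],
                FDR=[0.005, 0.005, 0.5, 0.001, 0.02, 0.009],
                l2fc=[1.2, -0.2, 1.0, 0.5, 2.0, 0.0],
            )
        )
        assert published_membership(table) == {"a", "d"}

    def test_published_membership_missing_column(self):
        with pytest.raises(ValueError, match="FDR"):
            published_membership(pd.DataFrame({"gene_id": [], "l2fc": []}))

    def test_dendritic_three_of_eight(self):
        flags = pd.DataFrame(
            dict(gene_id=["a", "b", "c"]),
        )
        m = np.array([[1, 0, 0, 1, 0, 0, 1, 0],
                      [1, 1, 0, 0, 0, 0, 0, 0],
                      [1, 1, 1, 1, 1, 1, 1, 1]])
        for j in range(8):
            flags[f"s{j}"] = m[:, j]
        assert dendritic_consensus(flags) == {"a", "c"}
        assert dendritic_consensus(flags, orthologs={"a"}) == {"a"}
        assert dendritic_consensus(flags, expressed={"c"}) == {"c"}

    def test_dendritic_count_matches_row_sums(self):
        rng = np.random.default_rng(3)
        m = rng.integers(0, 2, size=(50, 8))
        flags = pd.DataFrame({"gene_id": [f"g{i}" for i in range(50)]})
        for j in range(8):
            flags[f"s{j}"] = m[:, j]
        expected = {f"g{i}" for i in range(50) if m[i].sum() >= 3}
        assert dendritic_consensus(flags) == expected


class TestZScoreRows:
    def test_simple_row(self):
        out = zscore_rows(pd.DataFrame([[1.0, 2.0, 3.0]]))
        assert np.allclose(out.to_numpy(), [[-1.0, 0.0, 1.0]])

    def test_constant_row_zeros_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = zscore_rows(pd.DataFrame([[2.0, 2.0, 2.0]]))
        assert np.allclose(out.to_numpy(), 0.0)

    def test_rows_standardized(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.normal(5, 3, size=(20, 8)))
        out = zscore_rows(m).to_numpy()
        assert np.allclose(out.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-9)


class TestHypergeomEnrichment:
    def test_exact_enumeration_example(self):
        universe = [f"g{i}" for i in range(10)]
        term = {"T": universe[:4]}
        query = universe[:4] + [universe[5]]
        out = hypergeom_enrichment(query, term, universe)
        assert out.loc[0, "p"] == pytest.approx(6 / 252)
        assert out.loc[0, "gene_ratio"] == pytest.approx(1.0)

    def test_query_equals_background(self):
        universe = [f"g{i}" for i in range(12)]
        sets = {"A": universe[:5], "B": universe[3:9]}
        out = hypergeom_enrichment(universe, sets, universe).set_index("term")
        assert np.allclose(out["p"], 1.0)
        assert np.allclose(out["gene_ratio"], 1.0)

    def test_empty_restricted_term_skipped(self):
        universe = ["a", "b"]
        out = hypergeom_enrichment(["a"], {"T": ["z"], "U": ["a", "b"]}, universe)
        assert list(out["term"]) == ["U"]

    def test_top_terms_capped(self):
        universe = [f"g{i}" for i in range(30)]
        sets = {f"T{i}": universe[i : i + 5] for i in range(28)}
        out = hypergeom_enrichment(universe[:10], sets, universe)
        assert len(top_terms(out)) == 25
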