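"""Promoter differential tests, BH adjustment, enrichment, DEG concordance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mtcal.diffassoc import (
    bh_adjust,
    deg_concordance,
    diff_test_counts,
    gene_set_enrichment,
    promoter_diff_test,
)


class TestBH:
    def test_hand_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == 0.3

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_q_dominates_p_and_is_monotone(self, ps):
        q = bh_adjust(ps)
        assert (q >= np.asarray(ps) - 1e-15).all()
        assert (q <= 1.0).all()
        order = np.argsort(ps, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_matches_reference_implementation(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.random(int(rng.integers(1, 50)))
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.max(np.abs(bh_adjust(p) - ref)) < 1e-12

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestDiffCounts:
    def test_one_sided_fisher_hand_value(self):
        # [[5,995],[0,1000]]: one-sided tail is hypergeom P(X>=5)
        res = diff_test_counts([0], [5], 1000, 1000)
        expect = stats.hypergeom.sf(4, 2000, 1000, 5)
        assert res.loc[0, "p_value"] == pytest.approx(expect, rel=1e-10)
        assert expect == pytest.approx(0.0310944, abs=1e-6)

    def test_identical_counts_are_null(self):
        res = diff_test_counts([7], [7], 500, 500, alternative="two-sided")
        assert res.loc[0, "p_value"] == 1.0
        assert res.loc[0, "log2_effect"] == 0.0
        # one-sided: observed point included in the upper tail, never small
        one = diff_test_counts([7], [7], 500, 500)
        assert one.loc[0, "p_value"] > 0.5

    def test_binomial_variant_close_to_fisher(self):
        f = diff_test_counts([3], [15], 2000, 2000, test="fisher_2x2")
        b = diff_test_counts([3], [15], 2000, 2000, test="binomial")
        assert b.loc[0, "p_value"] == pytest.approx(f.loc[0, "p_value"], rel=0.5)

    def test_zero_focal_pairs_errors(self):
        with pytest.raises(ValueError, match="zero focal"):
            diff_test_counts([1], [1], 0, 10)

    def test_null_simulation_median_zero_discoveries(self):
        rng = np.random.default_rng(1)
        n_disc = []
        for _ in range(25):
            p = np.full(500, 0.5 / 500)
            k_nm = rng.multinomial(2000, np.r_[p, 1 - p.sum()])[:-1]
            k_ht = rng.multinomial(2000, np.r_[p, 1 - p.sum()])[:-1]
            res = diff_test_counts(k_nm, k_ht, 2000, 2000)
            n_disc.append(int((res["q_value"] < 0.05).sum()))
        assert np.median(n_disc) == 0


class TestPromoterDiff:
    def test_planted_gainer_detected_from_pairs(self, bundle):
        """A promoter with a strong planted gain reaches q < 0.05."""
        from mtcal.contacts import ContactPair, pairs_to_frame
        from mtcal.genome import GenomicInterval

        part = bundle.partition
        fps = part.promoter_footprints()
        genes = sorted(fps)
        target, other = genes[0], genes[1]

        def promoter_pair(pid, gid):
            iv = fps[gid][0]
            mid = (iv.start + iv.end) // 2
            return ContactPair(pid, GenomicInterval("chrM", 10, 160, "+"),
                               GenomicInterval(iv.chrom, mid - 20, mid + 20))

        def background_pair(pid):
            return ContactPair(pid, GenomicInterval("chrM", 10, 160, "+"),
                               GenomicInterval("chr1", 799_000, 799_150))

        nm = [promoter_pair(f"n{i}", target) for i in range(4)]
        nm += [background_pair(f"nb{i}") for i in range(996)]
        ht = [promoter_pair(f"h{i}", target) for i in range(40)]
        ht += [promoter_pair(f"ho{i}", other) for i in range(5)]
        ht += [background_pair(f"hb{i}") for i in range(955)]

        def annotate(prs):
            f = pairs_to_frame(prs)
            f["gene_id"] = "MT-RNR1"
            f["rna_class"] = "mt_rRNA"
            return f

        res = promoter_diff_test(annotate(nm), annotate(ht), "MT-RNR1",
                                 part, focal_key="gene_id")
        row = res.set_index("gene_id").loc[target]
        assert row["k_nm"] == 4 and row["k_ht"] == 40
        assert row["q_value"] < 0.05
        assert res.set_index("gene_id").loc[other, "q_value"] > 0.2

    def test_zero_focal_in_condition_errors(self, bundle, pairs_and_truth):
        frame, _ = pairs_and_truth
        from mtcal.cal import annotate_rna_genes

        ann = annotate_rna_genes(frame, bundle.genes)
        with pytest.raises(ValueError, match="zero pairs"):
            promoter_diff_test(ann[ann["condition"] == "NM"],
                               ann[ann["condition"] == "NM"].iloc[0:0],
                               "MT-RNR1", bundle.partition)


class TestEnrichment:
    def test_balanced_table_is_null(self):
        uni = [f"g{i}" for i in range(40)]
        gain = set(uni[:20])
        red = set(uni[:10]) | set(uni[20:30])
        res = gene_set_enrichment(gain, red, uni)
        assert (res.a, res.b, res.c, res.d) == (10, 10, 10, 10)
        assert res.odds_ratio == 1.0
        assert res.chi2 == 0.0 and res.p_value == 1.0

    def test_odds_ratio_closed_form(self):
        uni = [f"g{i}" for i in range(47)]
        gain = set(uni[:30])  # a+b = 30
        red = set(uni[:20]) | set(uni[30:35])  # a = 20, c = 5
        res = gene_set_enrichment(gain, red, uni)
        assert (res.a, res.b, res.c, res.d) == (20, 10, 5, 12)
        assert res.odds_ratio == pytest.approx((20 * 12) / (10 * 5))

    def test_chi2_matches_independent_formula(self):
        uni = [f"g{i}" for i in range(200)]
        gain, red = set(uni[:40]), set(uni[20:80])
        res = gene_set_enrichment(gain, red, uni)
        t = np.array([[res.a, res.b], [res.c, res.d]], dtype=float)
        n = t.sum()
        exp = np.outer(t.sum(1), t.sum(0)) / n
        chi2 = ((t - exp) ** 2 / exp).sum()
        assert res.chi2 == pytest.approx(chi2, rel=1e-10)
        assert res.p_value == pytest.approx(stats.chi2.sf(chi2, 1), rel=1e-10)

    def test_chi2_p_close_to_permutation(self):
        rng = np.random.default_rng(2)
        uni = [f"g{i}" for i in range(300)]
        gain = set(rng.choice(uni, 40, replace=False))
        red = set(rng.choice(uni, 60, replace=False))
        res = gene_set_enrichment(gain, red, uni)
        n_perm, hits = 4000, 0
        gain_n = len(gain)
        red_arr = np.isin(uni, list(red))
        for _ in range(n_perm):
            perm = rng.permutation(len(uni))[:gain_n]
            a = int(red_arr[perm].sum())
            b, c = gain_n - a, int(red_arr.sum()) - a
            d = len(uni) - a - b - c
            t = np.array([[a, b], [c, d]], dtype=float)
            exp = np.outer(t.sum(1), t.sum(0)) / t.sum()
            hits += ((t - exp) ** 2 / exp).sum() >= res.chi2 - 1e-12
        mc_p = hits / n_perm
        mc_err = (mc_p * (1 - mc_p) / n_perm) ** 0.5
        assert res.p_value == pytest.approx(mc_p, abs=2 * mc_err + 0.01)

    def test_universe_and_subset_validation(self):
        with pytest.raises(ValueError, match="universe"):
            gene_set_enrichment({"a"}, {"b"}, {"a", "b"})
        with pytest.raises(ValueError, match="subset"):
            gene_set_enrichment({"z"}, {"b"}, {"a", "b", "c", "d"})


class TestConcordance:
    def table(self, genes, down, fc_scale=1.0):
        fc = np.where(np.isin(genes, list(down)), -2.0, 0.5) * fc_scale
        p = np.where(np.isin(genes, list(down)), 1e-6, 0.6)
        return pd.DataFrame({"gene": genes, "log2FC": fc, "pvalue": p, "padj": p})

    def test_identical_tables(self):
        genes = [f"g{i}" for i in range(100)]
        t = self.table(genes, genes[:17])
        res = deg_concordance({"a": t, "b": t.copy()})
        assert res["per_table_n"] == {"a": 17, "b": 17}
        assert res["kway_n"] == 17
        assert res["pairwise_scc"][("a", "b")] == pytest.approx(1.0)

    def test_anti_monotone_fold_changes(self):
        genes = [f"g{i}" for i in range(50)]
        a = self.table(genes, genes[:10])
        b = a.copy()
        b["log2FC"] = -a["log2FC"]
        res = deg_concordance({"a": a, "b": b})
        assert res["pairwise_scc"][("a", "b")] == pytest.approx(-1.0)

    def test_planted_common_signature_recovered(self):
        from mtcal.simulate import simulate_deg_tables

        genes = [f"g{i}" for i in range(500)]
        planted = genes[:40]
        tables, _ = simulate_deg_tables(
            genes, planted_down=planted, reduced_rate=0.0,
            shared_sd=0.0, noise_sd=0.0, rng=np.random.default_rng(0),
        )
        res = deg_concordance(tables)
        assert res["kway_n"] == 40
        assert sorted(res["kway_genes"]) == sorted(planted)
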