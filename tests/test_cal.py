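"""CAL formula oracles, contrasts, and the group tests behind Fig-style claims."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mtcal.cal import (
    annotate_rna_genes,
    cal_contrast,
    class_cal_test,
    compute_cal,
    compute_region_cal,
    per_gene_condition_contrast,
    region_anova,
    region_cal_table,
)
from mtcal.contacts import ContactPair, pairs_to_frame
from mtcal.genome import GeneModel, GenomicInterval


def mk_pairs(n_class, n_other, dna_chrom="chr1", mt_n=0):
    """A frame with n_class pairs on gene A, n_other on gene B, mt_n on chrM DNA."""
    rows = []
    i = 0
    for _ in range(n_class):
        rows.append(ContactPair(f"p{i}", GenomicInterval("chr1", 100, 250, "+"),
                                GenomicInterval(dna_chrom, 5000, 5150)))
        i += 1
    for _ in range(n_other):
        rows.append(ContactPair(f"p{i}", GenomicInterval("chr1", 9000, 9150, "+"),
                                GenomicInterval(dna_chrom, 5000, 5150)))
        i += 1
    for _ in range(mt_n):
        rows.append(ContactPair(f"p{i}", GenomicInterval("chr1", 100, 250, "+"),
                                GenomicInterval("chrM", 50, 200)))
        i += 1
    frame = pairs_to_frame(rows)
    frame["gene_id"] = (["A"] * n_class) + (["B"] * n_other) + (["A"] * mt_n)
    frame["rna_class"] = "nuclear"
    return frame


class TestComputeCal:
    def test_methods_formula_hand_value(self):
        # 10 class pairs over 2 species, 1000 total -> 1e6*10/(2*1000)
        frame = mk_pairs(6, 4, mt_n=0)
        frame = pd.concat([frame, mk_pairs(0, 990)], ignore_index=True)
        rec = compute_cal(frame, scope="class", target="nuclear")
        assert rec.n_pairs == 1000  # all are nuclear class here
        rec = compute_cal(frame, scope="gene", target="A", total_pairs=1000)
        assert rec.cal == pytest.approx(1e6 * 6 / 1000)

    def test_two_species_normalisation(self):
        frame = mk_pairs(10, 10)
        frame.loc[frame["gene_id"] == "B", "rna_class"] = "nuclear"
        rec = compute_cal(frame, scope="class", target="nuclear", total_pairs=1000)
        # 20 pairs, 2 detected species, 1000 total
        assert rec.n_species == 2
        assert rec.cal == pytest.approx(1e6 * 20 / (2 * 1000))

    def test_gene_with_zero_pairs(self):
        rec = compute_cal(mk_pairs(5, 5), scope="gene", target="missing")
        assert rec.cal == 0.0

    def test_scale_invariance(self):
        a = compute_cal(mk_pairs(10, 90), scope="gene", target="A")
        b = compute_cal(mk_pairs(20, 180), scope="gene", target="A")
        assert a.cal == pytest.approx(b.cal)

    def test_mtdna_end_pairs_excluded_from_counts_but_not_total(self):
        frame = mk_pairs(10, 80, mt_n=10)
        rec = compute_cal(frame, scope="gene", target="A")
        assert rec.n_pairs == 10  # the 10 chrM DNA-end pairs do not count
        assert rec.total_pairs == 100  # but they are library pairs

    def test_zero_species_class_errors(self):
        with pytest.raises(ValueError, match="no detected species"):
            compute_cal(mk_pairs(5, 5), scope="class", target="mt_tRNA")


class TestRegionCal:
    def test_hand_value(self, bundle):
        # 50 of 500 class pairs on promoters spanning K kb -> 50/K/500
        frame = mk_pairs(0, 0)
        part = bundle.partition
        promo_fp = part.footprint("promoter")
        chrom, (s, e) = next(
            (c, iv) for c, ivs in promo_fp.items() for iv in ivs if iv[1] - iv[0] > 200
        )
        inter_fp = part.footprint("intergenic")
        ic, (is_, ie) = next(
            (c, iv) for c, ivs in inter_fp.items() for iv in ivs if iv[1] - iv[0] > 400
        )
        rows = []
        for i in range(50):
            rows.append(ContactPair(f"a{i}", GenomicInterval("chrM", 10, 160, "+"),
                                    GenomicInterval(chrom, s + 50, s + 150)))
        for i in range(450):
            rows.append(ContactPair(f"b{i}", GenomicInterval("chrM", 10, 160, "+"),
                                    GenomicInterval(ic, is_ + 100, is_ + 300)))
        frame = pairs_to_frame(rows)
        frame["gene_id"] = "MT-RNR1"
        frame["rna_class"] = "mt_rRNA"
        rec = compute_region_cal(frame, part, target="mt_rRNA",
                                 region_type="promoter")
        assert rec.cal == pytest.approx(50 / part.total_kb["promoter"] / 500)

    def test_partition_conservation_of_counts(self, bundle, pairs_and_truth):
        frame, _ = pairs_and_truth
        ann = annotate_rna_genes(frame, bundle.genes,
                                 junction_kmer=bundle.junction_kmer,
                                 junction_gene="SncmtRNA")
        table = region_cal_table(ann, bundle.partition, bundle.genes,
                                 scope="class", per_condition=False)
        nuc = ann[(ann["dna_chrom"] != "chrM") & (ann["rna_class"] == "nuclear")]
        got = table[table["target"] == "nuclear"]["n_pairs"].sum()
        assert got == len(nuc)

    def test_unknown_region_errors(self, bundle):
        frame = mk_pairs(5, 5)
        with pytest.raises(ValueError, match="absent or zero"):
            compute_region_cal(frame, bundle.partition, target="nuclear",
                               region_type="promoter_ht_induced"
                               if "promoter_ht_induced" not in bundle.partition.total_kb
                               else "missing_region")


class TestContrast:
    def test_equal_cals_give_zero(self):
        assert cal_contrast(3.5, 3.5).log2_ratio == 0.0

    def test_sixty_four_fold_is_log2_six(self):
        assert cal_contrast(64.0, 1.0).log2_ratio == pytest.approx(6.0)

    def test_zero_with_pseudocount(self):
        c = cal_contrast(0.0, 1.0, pseudocount=1e-3)
        assert c.log2_ratio == pytest.approx(math.log2(1e-3 / 1.001))
        assert c.pseudocount == 1e-3

    def test_zero_without_pseudocount_errors(self):
        with pytest.raises(ValueError, match="pseudocount"):
            cal_contrast(0.0, 1.0, pseudocount=0.0)


class TestGroupTests:
    def test_identical_collections(self):
        stat, p = class_cal_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0, abs=1e-12) or abs(stat) < 1e-12

    def test_student_t_closed_form(self):
        stat, p = class_cal_test([1, 2, 3], [4, 5, 6], test="student_t")
        # pooled sd = 1, se = sqrt(2/3), t = -3/se, df = 4
        t_expect = -3 / math.sqrt(2 / 3)
        assert stat == pytest.approx(t_expect, rel=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(abs(t_expect), 4), rel=1e-12)

    def test_mann_whitney_exact_separated(self):
        _, p = class_cal_test([1, 2, 3], [4, 5, 6], test="mann_whitney")
        assert p == pytest.approx(2 / 20)  # 2 / C(6,3), exact two-sided

    def test_t_needs_two_values(self):
        with pytest.raises(ValueError, match="at least 2"):
            class_cal_test([1.0], [2.0, 3.0])

    def test_anova_hand_value(self):
        f, p = region_anova([[1, 2], [3, 4]])
        assert f == pytest.approx(8.0, rel=1e-12)
        assert p == pytest.approx(stats.f.sf(8.0, 1, 2), rel=1e-12)

    def test_anova_degenerate_variance(self):
        with pytest.raises(ValueError, match="degenerate"):
            region_anova([[2.0, 2.0], [2.0, 2.0]])

    def test_anova_null_p_roughly_uniform(self):
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(300):
            x = rng.normal(size=12)
            ps.append(region_anova([x[:4], x[4:8], x[8:]])[1])
        # Kolmogorov-Smirnov against uniform under the null
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestConditionRecovery:
    def test_planted_class_ranking_recovered(self, bundle):
        """Distinct per-class attachment masses give the planted CAL ranking."""
        from conftest import small_config
        from mtcal.simulate import simulate_pairs

        cfg = small_config()
        cfg.pairs.n_per_library = 30_000
        cfg.pairs.category_weights = {
            "nuRNA-nuDNA": 0.90, "mtRNA-nuDNA": 0.08,
            "mtRNA-mtDNA": 0.015, "nuRNA-mtDNA": 0.005,
        }
        cfg.libraries = [("NM", 1)]
        cfg.pairs.emit_sequences = "none"
        frame, _ = simulate_pairs(bundle, cfg, rng=np.random.default_rng(10))
        ann = annotate_rna_genes(frame, bundle.genes)
        # uniform species draw: per-species expectation is equal across mt
        # classes, so per-species CAL should separate mt (8%/38 species)
        # from nuclear (90%/60 species)
        mt_rec = compute_cal(ann, scope="class", target="mt_mRNA")
        nu_rec = compute_cal(ann, scope="class", target="nuclear")
        assert mt_rec.cal / nu_rec.cal == pytest.approx(
            (0.08 / 38) / (0.90 / 60), rel=0.2
        )

    def test_condition_multiplier_recovered(self, bundle, pairs_and_truth):
        frame, truth = pairs_and_truth
        ann = annotate_rna_genes(frame, bundle.genes,
                                 junction_kmer=bundle.junction_kmer,
                                 junction_gene="SncmtRNA")
        con = per_gene_condition_contrast(ann, bundle.genes, "HT", "NM")
        # theta_mt = 2 against a renormalised composition Z = 1.03
        med = con["log2_ratio"].median()
        assert med == pytest.approx(math.log2(2 / 1.03), abs=0.35)
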