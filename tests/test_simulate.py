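"""Generator contracts: determinism, planted structure, truth labels."""

import numpy as np
import pandas as pd
import pytest

from conftest import small_config
from mtcal.simulate import (
    MT_LEN,
    NumtConfig,
    SNC_GENE_ID,
    SNC_IR_LEN,
    SynthConfig,
    make_toy_genome,
    simulate_deg_tables,
    simulate_mt_reads,
    simulate_pairs,
)


class TestToyGenome:
    def test_mt_roster(self, bundle):
        mt = bundle.mt_genes
        assert len(mt) == 38  # 13 + 2 + 22 + chimeric lncRNA
        by_class = pd.Series([g.rna_class for g in mt]).value_counts()
        assert by_class["mt_mRNA"] == 13
        assert by_class["mt_rRNA"] == 2
        assert by_class["mt_tRNA"] == 22
        assert by_class["mt_lncRNA"] == 1
        assert len(bundle.sequences["chrM"]) == MT_LEN

    def test_chimeric_transcript_geometry(self, bundle):
        from mtcal.numt import revcomp

        t = bundle.transcripts[SNC_GENE_ID]
        assert len(t) == SNC_IR_LEN + 1559
        rnr2 = next(g for g in bundle.mt_genes if g.gene_id == "MT-RNR2")
        body = bundle.sequences["chrM"][rnr2.body.start:rnr2.body.end]
        assert t[SNC_IR_LEN:] == body
        assert t[:SNC_IR_LEN] == revcomp(body[:SNC_IR_LEN])
        # the junction k-mer occurs nowhere on the plain mt sequence
        assert bundle.junction_kmer not in bundle.sequences["chrM"]

    def test_zero_divergence_numts_are_exact_mt_substrings(self):
        cfg = small_config(seed=9)
        cfg.numt = NumtConfig(divergence=0.0)
        b = make_toy_genome(cfg, rng=np.random.default_rng(9))
        for rec in b.numts:
            assert rec.sequence in b.sequences["chrM"]
        assert (b.numt_truth["n_substitutions"] == 0).all()

    def test_planted_substitution_counts_binomial(self):
        cfg = small_config(seed=9)
        cfg.numt = NumtConfig(count=30, min_len=500, max_len=500, divergence=0.1)
        b = make_toy_genome(cfg, rng=np.random.default_rng(9))
        for n_sub in b.numt_truth["n_substitutions"]:
            sigma = (500 * 0.1 * 0.9) ** 0.5
            assert abs(n_sub - 50) <= 3 * sigma

    def test_deterministic_under_seed(self):
        b1 = make_toy_genome(small_config(), rng=np.random.default_rng(3))
        b2 = make_toy_genome(small_config(), rng=np.random.default_rng(3))
        assert b1.sequences == b2.sequences
        assert b1.induced_gene_ids == b2.induced_gene_ids
        assert [g.gene_id for g in b1.genes] == [g.gene_id for g in b2.genes]


class TestSimulatePairs:
    def test_byte_identical_under_seed(self, bundle):
        cfg = small_config()
        f1, t1 = simulate_pairs(bundle, cfg, rng=np.random.default_rng(5))
        f2, t2 = simulate_pairs(bundle, cfg, rng=np.random.default_rng(5))
        pd.testing.assert_frame_equal(f1, f2)
        pd.testing.assert_frame_equal(t1.labels, t2.labels)

    def test_realized_mt_fraction_within_binomial_ci(self, bundle, pairs_and_truth):
        frame, truth = pairs_and_truth
        cfg = truth.config
        w = cfg.pairs.category_weights
        planted = w["mtRNA-nuDNA"] + w["mtRNA-mtDNA"]
        nm = truth.labels[truth.labels["condition"] == "NM"]
        got = nm["true_category"].str.startswith("mtRNA").mean()
        sigma = (planted * (1 - planted) / len(nm)) ** 0.5
        assert abs(got - planted) <= 4 * sigma

    def test_pure_promoter_preference_lands_on_promoters(self, bundle):
        cfg = small_config()
        cfg.pairs.n_per_library = 2000
        cfg.libraries = [("NM", 1)]
        cfg.pairs.emit_sequences = "none"
        cfg.pairs.region_enrichment_mt = {"promoter": 1.0}
        frame, truth = simulate_pairs(bundle, cfg, rng=np.random.default_rng(6))
        lab = truth.labels
        mt_nuc = lab[lab["true_category"] == "mtRNA-nuDNA"]
        assert (mt_nuc["true_region"] == "promoter").all()
        # and the partition agrees with the planted label on every pair
        sub = frame.set_index("pair_id").loc[mt_nuc["pair_id"]]
        got = bundle.partition.assign_many(
            sub["dna_chrom"].to_numpy(),
            ((sub["dna_start"] + sub["dna_end"]) // 2).to_numpy(),
        )
        assert (got == "promoter").all()

    def test_truth_covers_every_pair(self, pairs_and_truth):
        frame, truth = pairs_and_truth
        assert set(frame["pair_id"]) == set(truth.labels["pair_id"])

    def test_junction_reads_identify_the_lncRNA(self, bundle, pairs_and_truth):
        frame, truth = pairs_and_truth
        merged = frame.merge(truth.labels[["pair_id", "true_gene", "numt_derived"]],
                             on="pair_id")
        snc = merged[(merged["true_gene"] == SNC_GENE_ID) & ~merged["numt_derived"]]
        has_j = snc["rna_seq"].map(
            lambda s: isinstance(s, str) and bundle.junction_kmer in s
        )
        # junction-spanning reads exist and only lncRNA reads carry the kmer
        assert has_j.sum() > 0
        other = merged[merged["true_gene"] != SNC_GENE_ID]["rna_seq"]
        assert not other.map(
            lambda s: isinstance(s, str) and bundle.junction_kmer in s
        ).any()


class TestMtReads:
    def test_read_length_and_truth(self, bundle):
        reads = simulate_mt_reads(bundle, 50, rng=np.random.default_rng(0))
        assert (reads["rna_seq"].str.len() == 150).all()
        assert not reads["numt_derived"].any()

    def test_numt_free_restriction(self, bundle):
        reads = simulate_mt_reads(bundle, 50, region="numt_free",
                                  rng=np.random.default_rng(0))
        covered = np.zeros(MT_LEN, dtype=bool)
        for r in bundle.numt_truth.itertuples(index=False):
            covered[r.mt_start:r.mt_end] = True
        mt_seq = bundle.sequences["chrM"]
        for s in reads["rna_seq"]:
            pos = mt_seq.find(s)
            assert pos >= 0 and not covered[pos:pos + 150].any()


class TestDegTables:
    def test_zero_noise_recovers_planted_exactly(self):
        genes = [f"g{i}" for i in range(200)]
        tables, _ = simulate_deg_tables(
            genes, planted_down=genes[:25], reduced_rate=0.0,
            shared_sd=0.0, noise_sd=0.0, rng=np.random.default_rng(1),
        )
        for df in tables.values():
            sig = set(df.loc[(df["padj"] < 0.05) & (df["log2FC"] < 0), "gene"])
            assert sig == set(genes[:25])
            assert (df["padj"] >= df["pvalue"] - 1e-15).all()

    def test_null_or_gives_uniform_enrichment_p(self):
        from mtcal.diffassoc import deg_direction, gene_set_enrichment
        from scipy import stats

        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(2000)]
        ps = []
        for _ in range(40):
            gainers = set(rng.choice(genes, 60, replace=False))
            tables, _ = simulate_deg_tables(
                genes, gainer_set=gainers, planted_or=1.0,
                reduced_rate=0.2, labels=("kd",), rng=rng,
            )
            red = deg_direction(tables["kd"], "down")
            ps.append(gene_set_enrichment(gainers, red, genes).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.005

    def test_planted_or_recovered(self):
        from mtcal.diffassoc import deg_direction, gene_set_enrichment

        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(10_000)]
        ors = []
        for _ in range(30):
            gainers = set(rng.choice(genes, 300, replace=False))
            tables, _ = simulate_deg_tables(
                genes, gainer_set=gainers, planted_or=4.0,
                reduced_rate=0.2, labels=("kd",), rng=rng,
            )
            red = deg_direction(tables["kd"], "down")
            ors.append(gene_set_enrichment(gainers, red, genes).odds_ratio)
        assert abs(np.median(ors) - 4.0) / 4.0 < 0.15
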