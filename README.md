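# mtcal

Analysis of **mitochondria-encoded chromatin-associated RNA (mt-caRNA)** from
RNA–DNA contact pairs.

Proximity-ligation assays such as iMARGI capture chimeric read pairs in which
one end maps to an RNA and the other to the genomic DNA that RNA was attached
to. A surprising fraction of such pairs in human cells has the RNA end mapping
to mitochondria-encoded transcripts — mRNAs, rRNAs, tRNAs, and chimeric
lncRNAs such as SncmtRNA (a 1559 nt 16S rRNA body joined to an 815 nt inverted
repeat) — attached to *nuclear* chromatin, preferentially at gene promoters,
and responsive to stress conditions (e.g. high glucose + TNFα, "HT", versus a
mannitol control, "NM", in endothelial cells). `mtcal` is for analysts who
start from aligned contact pairs (4DN `.pairs` or BEDPE) plus genome
annotations and want to quantify and test that behaviour.

## What it computes

**Chromatin association level (CAL).** For an RNA class *c* in a library,

```
CAL(c) = 1e6 · n_pairs(c) / (n_species(c) · N)        [CPM]
```

where `n_pairs(c)` counts RNA→nuclear-DNA pairs whose RNA end maps to the
class, `n_species(c)` is the number of RNA species of the class involved, and
`N` is the library's total RNA–DNA pair count. The region-restricted variant
on a region type *r* (promoter, 5'/3'UTR, CDS, intron, enhancer, super
enhancer, HT-induced promoter, intergenic) is

```
CAL(c, r) = n_pairs(c, r) / kb(r) / n_pairs(c)        [pairs · kb⁻¹ · pair⁻¹]
```

with `kb(r)` the non-redundant footprint of *r* after precedence masking
(every nuclear base gets exactly one region label). Condition contrasts are
`log2((CAL_a + ε)/(CAL_b + ε))` with a recorded pseudocount.

**NUMT disambiguation.** Reads mapping to mtRNA could instead derive from
nuclear insertions of mitochondrial DNA (NUMTs). A read is `mt_confident`
when its best gapless (Hamming) end-to-end alignment against every NUMT, in
both orientations, still leaves **more than 5 base mismatches** (threshold
configurable); candidate placements come from exact 12-mer seeding and the
seeded minimum is validated against an exhaustive sliding-window scan.

**Differential promoter association.** Per gene promoter, a 2×2 Fisher exact
test (one-sided "increase" by default) of focal-RNA pairs on vs off the
promoter between conditions, with Benjamini–Hochberg adjustment across
promoters; gene-set association between promoter-gaining genes and
knockdown-responsive genes by a chi-square 2×2 test with odds ratio `ad/bc`;
and concordance (intersections, Spearman correlation of log2 fold changes)
across externally produced differential-expression tables.

**Synthetic data.** A generator builds a toy nuclear genome with full gene
structure, enhancers and super enhancers, a 16,569 bp mitochondrial
chromosome carrying 13 mRNAs + 2 rRNAs + 22 tRNAs plus the junction-bearing
chimeric lncRNA, NUMT insertions at controlled divergence, contact-pair
libraries with planted class fractions, region preferences and condition
multipliers, and DEG tables with planted structure — all with per-pair truth
labels, so every stage has a parameter-recovery test.

## Worked example

```python
import numpy as np
from mtcal.simulate import SynthConfig, make_toy_genome, simulate_pairs
from mtcal.cal import (annotate_rna_genes, compute_cal, compute_region_cal,
                       per_gene_condition_contrast)
from mtcal.numt import classify_pairs

cfg = SynthConfig(seed=1)                       # 4 libraries x 50k pairs
rng = np.random.default_rng(cfg.seed)
bundle = make_toy_genome(cfg, rng=rng)
pairs, truth = simulate_pairs(bundle, cfg, rng=rng)

ann = annotate_rna_genes(pairs, bundle.genes,
                         junction_kmer=bundle.junction_kmer,
                         junction_gene="SncmtRNA")

mt_reads = ann[ann["rna_class"].astype(str).str.startswith("mt_")
               & ann["rna_seq"].notna()]
calls, summary = classify_pairs(mt_reads, bundle.numts, threshold=5)
print(f"NUMT-confident mtRNA reads: {100 * summary['fraction_confident']:.1f}%")

rec = compute_cal(ann, scope="class", target="mt_mRNA", condition="NM")
print(f"mt_mRNA CAL (NM): {rec.cal:.0f} CPM ({rec.n_pairs} pairs, "
      f"{rec.n_species} species)")

promo = compute_region_cal(ann, bundle.partition, target="mt_mRNA",
                           region_type="promoter", condition="NM")
inter = compute_region_cal(ann, bundle.partition, target="mt_mRNA",
                           region_type="intergenic", condition="NM")
print(f"promoter vs intergenic per-kb enrichment: {promo.cal / inter.cal:.1f}x")

con = per_gene_condition_contrast(ann, bundle.genes, "HT", "NM")
print(f"median per-mt-gene log2(HT/NM): {con['log2_ratio'].median():.2f}")
```

prints

```
NUMT-confident mtRNA reads: 96.2%
mt_mRNA CAL (NM): 798 CPM (1038 pairs, 13 species)
promoter vs intergenic per-kb enrichment: 8.7x
median per-mt-gene log2(HT/NM): 0.96
```

Reading the output: ~96% of mtRNA-mapped reads carry more than 5 mismatches
to every NUMT and are kept as genuinely mitochondrial (the remainder is the
planted 1.3% NUMT-derived contamination plus short tRNA reads, which carry
fewer informative positions); mitochondrial mRNAs as a class sit at ~800 CPM
chromatin association in the control; their per-kilobase attachment is ~9×
denser on promoters than on intergenic sequence; and the planted 2× stress
multiplier on mitochondrial chromatin attachment is recovered as a median
per-gene log2 ratio of ≈1 (the exact expectation is log2(2/1.03) ≈ 0.96
because CPM normalisation rescales the library composition).

## Command line

```sh
mtcal simulate --seed 1 --out sim/             # toy genome + pairs + truth
mtcal classify-numt --pairs sim/pairs.pairs --numts sim/numts.fa --out calls.tsv
mtcal cal --pairs sim/pairs.pairs --genes sim/genes.gtf --out cal.tsv
mtcal region-cal --pairs ... --genes ... --enhancers ... --out region_cal.tsv
mtcal diff-promoter --pairs ... --genes ... --condition-a NM --condition-b HT --out dp.tsv
mtcal enrich --gainers gainers.txt --deg-table kd.tsv
mtcal concordance --deg-table a.tsv --deg-table b.tsv
mtcal run --config config.yaml --out out/      # full pipeline + manifest
```

`mtcal run` executes every stage from one YAML config (a small example ships
at `src/mtcal/data/smoke.yaml`) and writes a reproducibility manifest with
the tool version, a config hash, per-stage row counts, and the sha256 digest
of every output; identical configs give byte-identical outputs.

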