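# Methods

## The measurement model

The unit of observation is a chimeric RNA-end/DNA-end read pair from an
RNA–genome proximity-ligation library. We treat a library as a multinomial
sample of pairs over (RNA species, DNA-end location) and define the chromatin
association level (CAL) of an RNA class as counts per million library pairs,
normalised by the number of RNA species carrying the signal:

    CAL(class) = 1e6 · n_pairs(class) / (n_species(class) · N_library).

Only pairs whose DNA end maps to a nuclear chromosome enter `n_pairs`;
mitochondrial-DNA-end pairs (intra-organelle ligation background) count only
toward `N_library`. "Species involved" means species of the class with at
least one RNA-end read in the selection; a flag switches to all annotated
species, which shrinks the CAL of sparsely detected classes.

The region-restricted CAL divides a class's pairs falling in one region type
by that type's non-redundant footprint in kilobases and by the class's pair
total:

    CAL(class, region) = n(class, region) / kb(region) / n(class).

This is a per-kilobase attachment density, comparable across region types of
very different sizes; its uniformity assumption (attachment probability
proportional to footprint length within a region type) is the same one the
synthetic generator uses to place DNA ends.

### Region partition

Eight region types plus a ninth, the promoters of stress-induced genes, tile
the nuclear genome. Overlaps are resolved by a precedence order (default:
HT-induced promoter > promoter > 5'UTR > 3'UTR > CDS > intron > super
enhancer > enhancer > intergenic) chosen so gene-proximal regulatory
categories win, mirroring the separate treatment of promoters in the
association analyses. Assignment uses the locus midpoint, which makes the
labelling a true partition — every pair is counted exactly once, and region
counts sum to class totals. Promoters default to TSS −2000/+500 bp,
strand-aware, clipped at chromosome ends; both window and precedence are
configurable because annotation conventions differ. Exons of genes without
an annotated CDS are folded into the CDS category. Internally each
chromosome is segmented at every annotation boundary and painted from lowest
to highest precedence; lookups are binary searches, and the unit tests and
acceptance checks compare the result against a naive full-scan oracle.

### NUMT disambiguation

A read mapped to mtRNA is accepted as mitochondrial when its best gapless
end-to-end comparison against every NUMT sequence, in both orientations,
leaves strictly more than `threshold` (default 5) mismatching bases, `N`
counting as a mismatch. Placements are found by exact `seed_k`-mer match
(default 12) and scored as Hamming distances; placements that would run off
the NUMT are not scored. Reads sharing no 12-mer with any NUMT are called
confident — the absence of any shared word is stronger evidence against NUMT
origin than six mismatches — and are distinct from reads with no sequence
available (`unevaluable`). The comparison is deliberately gapless: the
criterion is a base-mismatch count, the exhaustive sliding-window oracle is
then exact, and the seeded search provably finds the optimum whenever the
optimal window retains an intact seed word (guaranteed when the window has
fewer than read_length/seed_k mismatches). NUMT matches that would need
indels surface as high-mismatch or no-seed placements instead; indel-aware
alignment is out of scope.

Operating characteristics depend on read length: with 150 bp reads and
insertions diverged at 10% per base (the generator default, representative of
ancient insertions), an in-register NUMT placement carries Binomial(150, 0.1)
≈ 15 expected mismatches and the 5-mismatch criterion separates origins
essentially perfectly. At 5% divergence the lower binomial tail is
substantial (P(≤5) ≈ 0.24), so recently inserted, weakly diverged NUMTs are
intrinsically ambiguous under any per-read mismatch rule — a limitation of
the criterion itself, not of the search. Short reads (the toy tRNA
transcripts are ~60–75 nt) likewise carry fewer informative positions and are
more often ambiguous.

### Contrasts and tests

Condition contrasts are log2 ratios of CALs with an explicit pseudocount
(default: the CPM equivalent of half a pair at the relevant depth, recorded
in the output; zero CALs without a pseudocount are an error). Group
comparisons offer Student's t (default, two-sided), Welch's t, exact
Mann–Whitney, and one-way ANOVA across region types; a zero within-group
variance everywhere is surfaced as a degenerate-input error rather than a
silent NaN.

Per-promoter differential association between two conditions uses, for each
gene promoter, the 2×2 table [[k_HT, m_HT], [k_NM, m_NM]] of focal-RNA pairs
on vs off that promoter, tested by Fisher's exact test — robust at the low
per-promoter counts typical of a single focal RNA — one-sided for an
increase by default (two-sided and a margin-conditioned binomial variant are
available), followed by Benjamini–Hochberg adjustment across all promoters
tested. The log2 effect uses per-condition focal totals with a 0.5-pair
pseudocount. Promoter counts use each gene's masked promoter segments;
segments claimed by two overlapping windows go to the nearer TSS.

Gene-set enrichment between promoter-gaining and knockdown-responsive genes
is a chi-square association test on the 2×2 membership table over a stated
universe (default: genes present in the DEG table, i.e. expressed genes),
without Yates correction by default; the odds ratio is ad/bc with Haldane's
0.5 added to every cell only when a cell is zero (flagged in the result).
A degenerate margin (one set empty or exhaustive) returns chi2 = 0, p = 1.
DEG calling itself is out of scope; tables arrive as TSV with gene, log2FC,
p and adjusted p columns.

## The synthetic study

The generator emulates the study design at desk scale, and its defaults are
the conditions under which the package's claims are tested.

* **Genomes.** Two nuclear chromosomes of 2.4 Mb carrying 400 multi-exon
  genes with UTR/CDS structure (gene bodies 3–8 kb, 2–5 exons), 30 enhancers,
  5 super enhancers, and 50 stress-induced genes; a 16,569 bp mitochondrial
  chromosome with the full 37-gene roster in its natural order plus the
  chimeric lncRNA, whose transcript is the reverse-complemented 815 nt prefix
  of the 16S body joined to the 1559 nt body, so the junction word exists
  nowhere in the plain genome and junction-spanning reads identify the
  chimera uniquely.
* **Library composition.** Pair-category weights nuRNA–nuDNA 0.932,
  mtRNA–nuDNA 0.030, mtRNA–mtDNA 0.032, nuRNA–mtDNA 0.006, putting the
  mitochondrial RNA-end share above 6% of the library as observed in real
  contact libraries. Species are drawn uniformly within their origin — equal
  per-species coverage is a simulation design choice that gives every
  mitochondrial gene usable counts for recovery tests; real capture is
  heavily skewed toward rRNA.
* **Region placement.** DNA-end region preferences are per-kilobase densities
  relative to intergenic sequence (mitochondrial classes: induced promoters
  12, promoters 8, enhancers 4, UTRs/SE 3, CDS 2, introns 1.5), converted to
  category probabilities via the partition's actual footprints, then a
  uniform position within the category's masked footprint. Parameterising by
  density rather than category mass keeps the planted per-kb enrichment
  ordering — promoters on top, induced promoters above other promoters
  already at baseline — independent of how much footprint a category
  retains after precedence masking.
* **Condition effects.** Under stress, θ_mt (default 2) multiplies the
  mtRNA–nuDNA weight and θ_promoter (default 2) the induced-promoter density
  for mitochondrial classes. Because libraries are depth-normalised, a
  multiplier θ on a composition share f is observable only as θ/Z with
  Z = 1 + f(θ−1); at the default composition the planted per-gene
  log2(HT/NM) is log2(2/1.03) ≈ 0.957, and the recovery tests check the
  measured median against this renormalised expectation's band.
* **Reads.** 150 bp (clipped to transcript length), iid substitution errors
  at 0.002 per base; sequences emitted for mitochondrial reads by default.
  1.3% of mtRNA-mapped reads are NUMT-derived — their sequence is drawn from
  a nuclear insertion while their mapping stays mitochondrial — emulating
  the small contamination share the mismatch filter is meant to catch. NUMTs
  are 10 substitution-only copies of mt segments (200–1500 bp) at 10%
  per-base divergence, written into the nuclear sequence; substitution-only
  divergence matches the gapless classifier and is a documented limitation.
* **DEG tables.** Per-gene fold changes share a common component across
  datasets (SD 0.9) plus dataset noise (SD 0.3), giving a cross-dataset
  correlation of about 0.9; planted common-down genes shift by −3.5 log2
  units; additional per-dataset membership at a base rate, raised for a
  designated gainer set to achieve a planted odds ratio in expectation.

What the generator does **not** emulate: contact distance decay, chromatin
domain structure, capture and ligation biases, expression-level variation
across nuclear genes, transcript isoforms, and indel-containing NUMTs.
Passing recovery tests therefore demonstrates that the estimators measure
what they claim on data generated under their own assumptions — not that
real libraries satisfy those assumptions. One scale artefact deserves note:
with only 400 nuclear genes, the per-species nuclear share exceeds the
per-species mitochondrial share, so the toy genome does not reproduce the
absolute mt-above-nuclear CAL ordering seen with ~20,000 real genes; all
contrasts, rankings and recovery checks used here are invariant to that
scale choice.

### Calibration of the differential test

The false-discovery calibration study draws per-promoter counts directly
from the generative model (multinomial over 500 promoters plus background,
log-normal baseline affinities with σ = 0.5, promoter share 0.85 of focal
pairs, 10% of promoters gaining a 4× attachment increase against a
renormalised composition) and measures empirical FDR and power of the
Fisher-BH procedure at q < 0.05 over 200 replicate draws. The library size
of 10,000 focal pairs per condition was set by a design power analysis so
the planted effect is detectable with planned power ≈ 0.9; at 2,000 focal
pairs per condition the same effect is information-theoretically too weak
for high power (per-promoter baselines of at most ~4 expected pairs put
one-sided Fisher p-values near 10⁻², above any BH threshold that 500 tests
allow), so small focal libraries should be interpreted with the test's
limited sensitivity in mind. The one-sided test is conservative under the
null by discreteness, so empirical FDR runs well below the nominal level.

## Numerical and interface choices

* Coordinates are 0-based half-open internally; `.pairs` positions (1-based)
  convert at the I/O boundary. The `.pairs` writer emits the documented
  extra columns (end1, end2, library, condition, rna_seq) through the
  format's `#columns:` mechanism so both dialects round-trip losslessly.
* Duplicate pair ids are rejected (deduplication belongs upstream); more
  than 10% malformed lines abort with the first ten line numbers; pairs
  without sequence are accepted everywhere except NUMT classification.
* RNA-end gene assignment is exon-footprint midpoint containment,
  strand-aware, ties broken by largest overlap then lexicographic id. The
  chimeric lncRNA is excluded from the positional index (its footprint
  duplicates the 16S gene) and claimed by junction-word matching on the read
  sequence instead; its non-junction reads count toward the 16S gene, so
  its own CAL reflects only the identifiable junction-spanning subset —
  consistent across conditions, hence contrast-safe.
* BH adjustment is the standard step-up with ties preserved, cross-checked
  against an independent reference implementation at 1e-12.
* All generators are pure functions of (config, seed); the pipeline derives
  every random stream from the config seed, stamps outputs with a
  canonical-JSON config hash, and reruns are byte-identical (verified by
  digest comparison).

## Problem sizes

Recovery analyses run at 200,000 pairs per condition (two replicate
libraries of 100,000); the calibration study at 500 promoters × 200
simulations; interval-assignment validation at 10,000 random loci against a
brute-force scan; classifier validation at 1,000–2,000 reads of 150 bp; the
smoke pipeline at 5,000 pairs per library. The full test suite and the
acceptance script each complete in about a minute on one CPU.
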