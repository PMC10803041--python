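"""Synthetic genomes, annotations, NUMTs, contact pairs and DEG tables.

Every generator is a pure function of (config, seed) and returns, alongside
its data, a truth record with the planted per-pair origin labels so each
pipeline stage has a parameter-recovery test.

The toy system emulates the study design: a small nuclear genome with
annotated genes (promoter / UTR / CDS / intron structure), enhancers and
super enhancers; a 16,569 bp mitochondrial chromosome carrying 13 mRNAs,
2 rRNAs and 22 tRNAs plus a chimeric lncRNA whose transcript is an 815 nt
inverted repeat (reverse complement of the 16S rRNA 5' end) joined to the
1559 nt 16S body, so only junction-spanning reads identify it uniquely;
NUMT insertions copied from the mitochondrial sequence into nuclear
chromosomes at a controlled per-base divergence; and contact-pair libraries
with planted category fractions, per-class region preferences and condition
multipliers (theta_mt scales mitochondrial chromatin attachment under
stress; theta_promoter boosts the HT-induced promoter preference).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .contacts import PAIR_CATEGORIES, PAIR_COLUMNS
from .genome import (
    GeneModel,
    GenomicInterval,
    RegionPartition,
    build_region_partition,
)
from .numt import NumtRecord, revcomp

MT_LEN = 16569
SNC_BODY_LEN = 1559  # 16S rRNA body of the chimeric lncRNA
SNC_IR_LEN = 815  # inverted-repeat appendage at its 5' end
SNC_GENE_ID = "SncmtRNA"
JUNCTION_FLANK = 12  # junction k-mer half-width for read assignment

# (name, class, length, strand) roughly following the human mtDNA gene order;
# MT-RNR2 is the 1559 nt 16S rRNA that also forms the lncRNA body.
MT_ROSTER: List[Tuple[str, str, int, str]] = [
    ("MT-TF", "mt_tRNA", 71, "+"), ("MT-RNR1", "mt_rRNA", 954, "+"),
    ("MT-TV", "mt_tRNA", 69, "+"), ("MT-RNR2", "mt_rRNA", 1559, "+"),
    ("MT-TL1", "mt_tRNA", 71, "+"), ("MT-ND1", "mt_mRNA", 956, "+"),
    ("MT-TI", "mt_tRNA", 69, "+"), ("MT-TQ", "mt_tRNA", 72, "-"),
    ("MT-TM", "mt_tRNA", 68, "+"), ("MT-ND2", "mt_mRNA", 1042, "+"),
    ("MT-TW", "mt_tRNA", 68, "+"), ("MT-TA", "mt_tRNA", 69, "-"),
    ("MT-TN", "mt_tRNA", 73, "-"), ("MT-TC", "mt_tRNA", 66, "-"),
    ("MT-TY", "mt_tRNA", 66, "-"), ("MT-CO1", "mt_mRNA", 1542, "+"),
    ("MT-TS1", "mt_tRNA", 69, "-"), ("MT-TD", "mt_tRNA", 68, "+"),
    ("MT-CO2", "mt_mRNA", 684, "+"), ("MT-TK", "mt_tRNA", 70, "+"),
    ("MT-ATP8", "mt_mRNA", 207, "+"), ("MT-ATP6", "mt_mRNA", 681, "+"),
    ("MT-CO3", "mt_mRNA", 784, "+"), ("MT-TG", "mt_tRNA", 68, "+"),
    ("MT-ND3", "mt_mRNA", 346, "+"), ("MT-TR", "mt_tRNA", 65, "+"),
    ("MT-ND4L", "mt_mRNA", 297, "+"), ("MT-ND4", "mt_mRNA", 1378, "+"),
    ("MT-TH", "mt_tRNA", 69, "+"), ("MT-TS2", "mt_tRNA", 59, "+"),
    ("MT-TL2", "mt_tRNA", 71, "+"), ("MT-ND5", "mt_mRNA", 1812, "+"),
    ("MT-ND6", "mt_mRNA", 525, "-"), ("MT-TE", "mt_tRNA", 69, "-"),
    ("MT-CYB", "mt_mRNA", 1141, "+"), ("MT-TT", "mt_tRNA", 66, "+"),
    ("MT-TP", "mt_tRNA", 69, "-"),
]

#: DNA-end region preferences given the RNA class group, expressed as
#: per-kilobase attachment densities relative to intergenic sequence. The
#: probability of a region category is density x footprint kb, normalised,
#: so the planted per-kb enrichment ordering holds regardless of how large
#: each category's masked footprint happens to be. Mitochondrial caRNAs are
#: promoter-enriched, with the HT-induced promoter category already elevated
#: under baseline conditions.
DEFAULT_REGION_ENRICHMENT_MT = {
    "promoter_ht_induced": 12.0, "promoter": 8.0, "utr5": 3.0, "utr3": 3.0,
    "cds": 2.0, "intron": 1.5, "super_enhancer": 3.0, "enhancer": 4.0,
    "intergenic": 1.0,
}
DEFAULT_REGION_ENRICHMENT_NUCLEAR = {
    "promoter_ht_induced": 2.0, "promoter": 2.0, "utr5": 1.5, "utr3": 1.5,
    "cds": 1.5, "intron": 1.2, "super_enhancer": 1.5, "enhancer": 2.0,
    "intergenic": 1.0,
}

#: Library composition over pair categories (RNA origin x DNA-end origin);
#: mitochondrial RNA-end pairs total ~6% of the library.
DEFAULT_CATEGORY_WEIGHTS = {
    "nuRNA-nuDNA": 0.932, "mtRNA-nuDNA": 0.030,
    "mtRNA-mtDNA": 0.032, "nuRNA-mtDNA": 0.006,
}


@dataclass
class NumtConfig:
    count: int = 10
    min_len: int = 200
    max_len: int = 1500
    divergence: float = 0.10  # per-base substitution rate of the insertions


@dataclass
class PairsConfig:
    n_per_library: int = 50_000
    read_len: int = 150
    error_rate: float = 0.002
    category_weights: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_WEIGHTS)
    )
    region_enrichment_mt: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_ENRICHMENT_MT)
    )
    region_enrichment_nuclear: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_ENRICHMENT_NUCLEAR)
    )
    theta_mt: float = 2.0  # HT multiplier on mtRNA chromatin attachment
    theta_promoter: float = 2.0  # HT boost of induced-promoter preference (mt)
    numt_read_fraction: float = 0.013  # mt-mapped reads actually NUMT-derived
    emit_sequences: str = "mt_only"  # none | mt_only | all


@dataclass
class SynthConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 2_400_000
    n_genes: int = 400
    n_enhancers: int = 30
    n_super_enhancers: int = 5
    n_induced_genes: int = 50
    promoter_window: Tuple[int, int] = (2000, 500)
    mt_chrom: str = "chrM"
    ht_condition: str = "HT"
    libraries: List[Tuple[str, int]] = field(
        default_factory=lambda: [("NM", 1), ("NM", 2), ("HT", 1), ("HT", 2)]
    )
    numt: NumtConfig = field(default_factory=NumtConfig)
    pairs: PairsConfig = field(default_factory=PairsConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        numt = NumtConfig(**d.pop("numt", {}))
        pairs = PairsConfig(**d.pop("pairs", {}))
        libs = [tuple(x) for x in d.pop("libraries", [("NM", 1), ("NM", 2), ("HT", 1), ("HT", 2)])]
        pw = tuple(d.pop("promoter_window", (2000, 500)))
        return cls(numt=numt, pairs=pairs, libraries=libs, promoter_window=pw, **d)

    def validate(self) -> None:
        p = self.pairs
        for fam in (p.category_weights, p.region_enrichment_mt, p.region_enrichment_nuclear):
            if any(w < 0 for w in fam.values()) or sum(fam.values()) <= 0:
                raise ValueError("weights must be nonnegative with positive sum")
        if not (0 <= p.error_rate < 1) or not (0 <= self.numt.divergence < 1):
            raise ValueError("rates must lie in [0, 1)")
        if self.chrom_length <= 0 or self.n_genes <= 0:
            raise ValueError("lengths and counts must be positive")
        if p.emit_sequences not in ("none", "mt_only", "all"):
            raise ValueError("emit_sequences must be none|mt_only|all")


@dataclass
class GenomeBundle:
    """Toy genome plus everything derived from it."""

    sequences: Dict[str, str]
    genes: List[GeneModel]
    enhancers: List[GenomicInterval]
    super_enhancers: List[GenomicInterval]
    numts: List[NumtRecord]
    induced_gene_ids: List[str]
    chrom_sizes: Dict[str, int]  # nuclear only
    mt_chrom: str
    partition: RegionPartition
    transcripts: Dict[str, str]
    junction_kmer: str
    numt_truth: pd.DataFrame  # planted substitutions per NUMT
    config: SynthConfig

    @property
    def nuclear_genes(self) -> List[GeneModel]:
        return [g for g in self.genes if not g.chrom_is_mt]

    @property
    def mt_genes(self) -> List[GeneModel]:
        return [g for g in self.genes if g.chrom_is_mt]


@dataclass
class SynthTruth:
    """Planted origin labels for every emitted pair plus realized fractions."""

    labels: pd.DataFrame
    realized_fractions: Dict[str, float]
    config: SynthConfig


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> Tuple[str, int]:
    """iid substitutions at ``rate``; always to a different base."""
    if rate <= 0:
        return seq, 0
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode("ascii"), len(hits)


def _transcript(seq: Dict[str, str], gene: GeneModel) -> str:
    parts = [seq[gene.body.chrom][ex.start:ex.end] for ex in gene.exons]
    t = "".join(parts)
    return revcomp(t) if gene.strand == "-" else t


def _exon_tmap(gene: GeneModel) -> List[Tuple[int, int, int]]:
    """Exons in transcript order as (t_offset, g_start, g_end)."""
    exons = gene.exons if gene.strand != "-" else gene.exons[::-1]
    out, off = [], 0
    for ex in exons:
        out.append((off, ex.start, ex.end))
        off += len(ex)
    return out


def _transcript_pos_to_genomic(gene_tmap, strand: str, t: int) -> int:
    for off, gs, ge in gene_tmap:
        if off <= t < off + (ge - gs):
            return gs + (t - off) if strand != "-" else ge - 1 - (t - off)
    raise ValueError("transcript position out of range")


def make_toy_genome(config: Optional[SynthConfig] = None,
                    rng: Optional[np.random.Generator] = None) -> GenomeBundle:
    """Generate the toy genome, annotations, NUMTs and region partition."""
    config = config or SynthConfig()
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    sequences: Dict[str, str] = {}
    genes: List[GeneModel] = []

    # --- mitochondrial chromosome: compact roster with 2 bp spacers --------
    mt = config.mt_chrom
    mt_seq = _random_seq(rng, MT_LEN)
    pos = 0
    rnr2_start = None
    for name, cls, length, strand in MT_ROSTER:
        body = GenomicInterval(mt, pos, pos + length, strand)
        genes.append(GeneModel(name, name, cls, body, chrom_is_mt=True))
        if name == "MT-RNR2":
            rnr2_start = pos
        pos += length + 2
    assert pos <= MT_LEN, "mt roster exceeds chromosome"
    sequences[mt] = mt_seq

    # chimeric lncRNA: 815 nt inverted repeat + 1559 nt 16S body
    snc_body = GenomicInterval(mt, rnr2_start, rnr2_start + SNC_BODY_LEN, "+")
    genes.append(
        GeneModel(SNC_GENE_ID, SNC_GENE_ID, "mt_lncRNA", snc_body, chrom_is_mt=True)
    )

    # --- nuclear chromosomes ----------------------------------------------
    chrom_sizes = {
        f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)
    }
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    gene_no = 0
    for ci, (chrom, size) in enumerate(chrom_sizes.items()):
        sequences[chrom] = _random_seq(rng, size)
        n_here = per_chrom[ci]
        if n_here == 0:
            continue
        slot = size // n_here
        if slot < 12_000:
            raise ValueError("chromosome too short for the requested gene count")
        for k in range(n_here):
            gene_no += 1
            gl = int(rng.integers(3000, 8001))
            lo = ci_start = k * slot
            start = int(lo + rng.integers(2500, slot - gl - 600))
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(2, 6))
            ex_lens = rng.integers(150, 501, n_ex)
            intron_total = gl - int(ex_lens.sum())
            gaps = rng.multinomial(intron_total - 100 * (n_ex - 1),
                                   np.full(n_ex - 1, 1.0 / (n_ex - 1))) + 100 \
                if n_ex > 1 else np.array([], dtype=int)
            exons = []
            p = start
            for j in range(n_ex):
                exons.append(GenomicInterval(chrom, p, p + int(ex_lens[j]), strand))
                p += int(ex_lens[j])
                if j < n_ex - 1:
                    p += int(gaps[j])
            body = GenomicInterval(chrom, start, exons[-1].end, strand)
            # CDS occupies the transcript between a 5' and 3' UTR
            T = int(ex_lens.sum())
            u5 = int(rng.integers(80, max(81, min(300, T // 4))))
            u3 = int(rng.integers(150, max(151, min(600, T // 3))))
            tmap_exons = exons if strand != "-" else exons[::-1]
            cds = []
            off = 0
            for ex in tmap_exons:
                exlen = len(ex)
                s = max(u5, off)
                e = min(T - u3, off + exlen)
                if s < e:
                    if strand != "-":
                        cds.append(GenomicInterval(chrom, ex.start + (s - off), ex.start + (e - off), strand))
                    else:
                        cds.append(GenomicInterval(chrom, ex.end - (e - off), ex.end - (s - off), strand))
                off += exlen
            gid = f"G{gene_no:04d}"
            genes.append(GeneModel(gid, gid, "nuclear", body, exons, cds))

    # --- enhancers / super enhancers --------------------------------------
    chrom_names = list(chrom_sizes)
    enhancers, super_enhancers = [], []
    for _ in range(config.n_enhancers):
        chrom = chrom_names[rng.integers(0, len(chrom_names))]
        l = int(rng.integers(1000, 3001))
        s = int(rng.integers(0, chrom_sizes[chrom] - l))
        enhancers.append(GenomicInterval(chrom, s, s + l))
    for _ in range(config.n_super_enhancers):
        chrom = chrom_names[rng.integers(0, len(chrom_names))]
        l = int(rng.integers(8000, 20001))
        s = int(rng.integers(0, chrom_sizes[chrom] - l))
        super_enhancers.append(GenomicInterval(chrom, s, s + l))

    # --- NUMTs: mt segments copied into nuclear sequence with divergence ---
    numts, numt_rows = [], []
    for i in range(config.numt.count):
        seg = int(rng.integers(config.numt.min_len, config.numt.max_len + 1))
        src = int(rng.integers(0, MT_LEN - seg))
        raw = mt_seq[src:src + seg]
        mutated, n_sub = _mutate(rng, raw, config.numt.divergence)
        chrom = chrom_names[rng.integers(0, len(chrom_names))]
        at = int(rng.integers(0, chrom_sizes[chrom] - seg))
        sequences[chrom] = (
            sequences[chrom][:at] + mutated + sequences[chrom][at + seg:]
        )
        nid = f"numt{i + 1}"
        numts.append(
            NumtRecord(nid, mutated, GenomicInterval(chrom, at, at + seg))
        )
        numt_rows.append((nid, src, src + seg, chrom, at, seg, n_sub))
    numt_truth = pd.DataFrame(
        numt_rows,
        columns=["numt_id", "mt_start", "mt_end", "chrom", "insert_at",
                 "length", "n_substitutions"],
    )

    # --- induced gene set and partition ------------------------------------
    nuclear_ids = [g.gene_id for g in genes if not g.chrom_is_mt]
    induced = sorted(
        rng.choice(nuclear_ids, size=min(config.n_induced_genes, len(nuclear_ids)),
                   replace=False).tolist()
    )
    partition = build_region_partition(
        genes,
        enhancers,
        super_enhancers,
        induced,
        promoter_window=config.promoter_window,
        chrom_sizes=chrom_sizes,
    )

    # --- transcripts --------------------------------------------------------
    transcripts = {
        g.gene_id: _transcript(sequences, g)
        for g in genes
        if g.gene_id != SNC_GENE_ID
    }
    body_seq = mt_seq[rnr2_start:rnr2_start + SNC_BODY_LEN]
    transcripts[SNC_GENE_ID] = revcomp(body_seq[:SNC_IR_LEN]) + body_seq
    j = SNC_IR_LEN
    junction_kmer = transcripts[SNC_GENE_ID][j - JUNCTION_FLANK:j + JUNCTION_FLANK]

    return GenomeBundle(
        sequences, genes, enhancers, super_enhancers, numts, induced,
        chrom_sizes, mt, partition, transcripts, junction_kmer, numt_truth,
        config,
    )


# ---------------------------------------------------------------------------
# contact-pair simulation
# ---------------------------------------------------------------------------


def _footprint_sampler(partition: RegionPartition, region_type: str):
    """Uniform position sampler over the masked footprint of a region type."""
    fp = partition.footprint(region_type)
    chroms, starts, lens = [], [], []
    for chrom, ivs in sorted(fp.items()):
        for s, e in ivs:
            chroms.append(chrom)
            starts.append(s)
            lens.append(e - s)
    if not lens:
        raise ValueError(f"empty footprint for weighted region {region_type!r}")
    starts = np.asarray(starts, dtype=np.int64)
    lens = np.asarray(lens, dtype=np.int64)
    cum = np.cumsum(lens)

    def sample(rng: np.random.Generator, k: int):
        u = rng.integers(0, cum[-1], k)
        idx = np.searchsorted(cum, u, side="right")
        pos = starts[idx] + (u - (cum[idx] - lens[idx]))
        return [chroms[i] for i in idx], pos

    return sample


def _condition_weights(p: PairsConfig, condition: str, ht: str) -> np.ndarray:
    w = np.array([p.category_weights[c] for c in PAIR_CATEGORIES], dtype=float)
    if condition == ht:
        # stress scales mtRNA attachment to nuclear chromatin
        w[PAIR_CATEGORIES.index("mtRNA-nuDNA")] *= p.theta_mt
    return w / w.sum()


def _region_weights(p: PairsConfig, group: str, condition: str, ht: str,
                    region_order: List[str], kb: Dict[str, float]) -> np.ndarray:
    """Category probabilities = per-kb density x footprint kb, normalised."""
    base = p.region_enrichment_mt if group == "mt" else p.region_enrichment_nuclear
    w = np.array(
        [base.get(r, 0.0) * kb.get(r, 0.0) for r in region_order], dtype=float
    )
    if condition == ht and group == "mt" and "promoter_ht_induced" in region_order:
        w[region_order.index("promoter_ht_induced")] *= p.theta_promoter
    return w / w.sum()


def simulate_pairs(
    bundle: GenomeBundle,
    config: Optional[SynthConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[pd.DataFrame, SynthTruth]:
    """Simulate contact-pair libraries with planted truth labels.

    Per pair: the category (RNA origin x DNA-end origin) is drawn from the
    condition-scaled library composition; the RNA species uniformly within
    its origin; the nuclear DNA-end region from the class-conditional region
    weights (HT boosts the induced-promoter weight for mt classes), then a
    uniform position within that region's masked footprint; the RNA-end
    locus uniformly within the species' transcript. Read sequences are
    copied from the transcript with iid errors; a planted fraction of
    mt-mapped reads is NUMT-derived (sequence drawn from a NUMT insertion).
    """
    config = config or bundle.config
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    p = config.pairs
    mt_chrom = bundle.mt_chrom
    kbs = bundle.partition.total_kb
    region_order = sorted(
        set(p.region_enrichment_mt) | set(p.region_enrichment_nuclear)
    )
    from .genome import REGION_TYPES

    unknown = [r for r in region_order if r not in REGION_TYPES]
    if unknown:
        raise ValueError(f"unknown region types in enrichment config: {unknown}")
    samplers = {rt: _footprint_sampler(bundle.partition, rt)
                for rt in region_order if kbs.get(rt, 0.0) > 0}
    mt_gene_list = [g.gene_id for g in bundle.mt_genes]
    nu_gene_list = [g.gene_id for g in bundle.nuclear_genes]
    tmaps = {g.gene_id: (_exon_tmap(g), g.strand, g.body.chrom)
             for g in bundle.genes if g.gene_id != SNC_GENE_ID}
    rnr2 = next(g for g in bundle.mt_genes if g.gene_id == "MT-RNR2")
    chrom_size_of = dict(bundle.chrom_sizes)
    chrom_size_of[mt_chrom] = MT_LEN

    rows: List[tuple] = []
    truth_rows: List[tuple] = []

    for cond, rep in config.libraries:
        lib = f"{cond}{rep}"
        n = p.n_per_library
        w_cat = _condition_weights(p, cond, config.ht_condition)
        cat_idx = rng.choice(len(PAIR_CATEGORIES), size=n, p=w_cat)
        cats = [PAIR_CATEGORIES[i] for i in cat_idx]
        is_mt_rna = np.isin(cat_idx, [1, 2])  # mtRNA-nuDNA, mtRNA-mtDNA
        is_nu_dna = np.isin(cat_idx, [0, 1])

        species = np.empty(n, dtype=object)
        n_mt = int(is_mt_rna.sum())
        species[is_mt_rna] = [
            mt_gene_list[i] for i in rng.integers(0, len(mt_gene_list), n_mt)
        ]
        species[~is_mt_rna] = [
            nu_gene_list[i] for i in rng.integers(0, len(nu_gene_list), n - n_mt)
        ]

        # nuclear DNA ends: region then uniform position in its footprint
        region = np.full(n, None, dtype=object)
        dna_chrom = np.empty(n, dtype=object)
        dna_mid = np.empty(n, dtype=np.int64)
        for group, sel in (("mt", is_mt_rna & is_nu_dna),
                           ("nuclear", ~is_mt_rna & is_nu_dna)):
            k = int(sel.sum())
            if k == 0:
                continue
            w_reg = _region_weights(
                p, group, cond, config.ht_condition, region_order, kbs
            )
            if not np.isfinite(w_reg).all():
                raise ValueError(
                    "empty region footprint for every weighted region type"
                )
            reg_idx = rng.choice(len(region_order), size=k, p=w_reg)
            sel_idx = np.flatnonzero(sel)
            for ri in np.unique(reg_idx):
                rt = region_order[ri]
                which = sel_idx[reg_idx == ri]
                chroms_r, pos_r = samplers[rt](rng, len(which))
                region[which] = rt
                dna_chrom[which] = chroms_r
                dna_mid[which] = pos_r
        # mitochondrial DNA ends: uniform over chrM
        mt_dna = ~is_nu_dna
        k = int(mt_dna.sum())
        dna_chrom[mt_dna] = mt_chrom
        dna_mid[mt_dna] = rng.integers(0, MT_LEN, k)

        rl = p.read_len
        dna_start = np.maximum(dna_mid - rl // 2, 0)
        dna_end = np.empty(n, dtype=np.int64)
        for i in range(n):
            size = chrom_size_of[dna_chrom[i]]
            dna_end[i] = min(int(dna_start[i]) + rl, size)

        # RNA ends, grouped by species
        rna_chrom = np.empty(n, dtype=object)
        rna_start = np.empty(n, dtype=np.int64)
        rna_end = np.empty(n, dtype=np.int64)
        rna_strand = np.empty(n, dtype=object)
        t_starts = np.empty(n, dtype=np.int64)
        read_lens = np.empty(n, dtype=np.int64)
        order = np.argsort(species, kind="mergesort")
        sp_sorted = species[order]
        boundaries = np.flatnonzero(
            np.r_[True, sp_sorted[1:] != sp_sorted[:-1]]
        )
        for bi, b in enumerate(boundaries):
            e = boundaries[bi + 1] if bi + 1 < len(boundaries) else n
            gid = sp_sorted[b]
            idxs = order[b:e]
            tl = len(bundle.transcripts[gid])
            rlen = min(rl, tl)
            ts = rng.integers(0, tl - rlen + 1, len(idxs))
            t_starts[idxs] = ts
            read_lens[idxs] = rlen
            tmids = ts + rlen // 2
            if gid == SNC_GENE_ID:
                chrom = mt_chrom
                g_mid = np.where(
                    tmids >= SNC_IR_LEN,
                    rnr2.body.start + (tmids - SNC_IR_LEN),
                    rnr2.body.start + (SNC_IR_LEN - 1 - tmids),
                )
                strands = np.where(tmids >= SNC_IR_LEN, "+", "-")
            else:
                tmap, strand, chrom = tmaps[gid]
                g_mid = np.array(
                    [_transcript_pos_to_genomic(tmap, strand, int(t)) for t in tmids]
                )
                strands = np.full(len(idxs), strand, dtype=object)
            size = chrom_size_of[chrom]
            s = np.clip(g_mid - rlen // 2, 0, None)
            rna_chrom[idxs] = chrom
            rna_start[idxs] = s
            rna_end[idxs] = np.minimum(s + rlen, size)
            rna_strand[idxs] = strands

        # NUMT-derived read planting among mtRNA-mapped pairs
        numt_flag = np.zeros(n, dtype=bool)
        if p.numt_read_fraction > 0 and bundle.numts:
            cand = np.flatnonzero(is_mt_rna)
            hit = cand[rng.random(len(cand)) < p.numt_read_fraction]
            numt_flag[hit] = True

        # sequences
        emit = p.emit_sequences
        seqs = np.full(n, None, dtype=object)
        need = (
            np.zeros(n, dtype=bool) if emit == "none"
            else (is_mt_rna if emit == "mt_only" else np.ones(n, dtype=bool))
        )
        need |= numt_flag
        for i in np.flatnonzero(need):
            if numt_flag[i]:
                rec = bundle.numts[rng.integers(0, len(bundle.numts))]
                rlen = int(read_lens[i])
                if len(rec.sequence) < rlen:
                    rlen = len(rec.sequence)
                    read_lens[i] = rlen
                s0 = int(rng.integers(0, len(rec.sequence) - rlen + 1))
                raw = rec.sequence[s0:s0 + rlen]
            else:
                gid = species[i]
                raw = bundle.transcripts[gid][
                    int(t_starts[i]):int(t_starts[i]) + int(read_lens[i])
                ]
            seqs[i], _ = _mutate(rng, raw, p.error_rate)

        for i in range(n):
            pid = f"{lib}:{i}"
            rows.append((
                pid, rna_chrom[i], int(rna_start[i]), int(rna_end[i]),
                rna_strand[i], dna_chrom[i], int(dna_start[i]), int(dna_end[i]),
                ".", lib, cond, seqs[i],
            ))
            truth_rows.append((
                pid, lib, cond, species[i], cats[i], region[i], bool(numt_flag[i]),
            ))

    frame = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    labels = pd.DataFrame(
        truth_rows,
        columns=["pair_id", "library_id", "condition", "true_gene",
                 "true_category", "true_region", "numt_derived"],
    )
    total = len(labels)
    realized = {
        f"frac_{c}": float((labels["true_category"] == c).sum()) / total
        for c in PAIR_CATEGORIES
    }
    realized["frac_mt_rna"] = float(
        labels["true_category"].isin(["mtRNA-nuDNA", "mtRNA-mtDNA"]).mean()
    )
    return frame, SynthTruth(labels, realized, config)


def simulate_mt_reads(
    bundle: GenomeBundle,
    n: int,
    read_len: int = 150,
    error_rate: float = 0.0,
    from_numt_fraction: float = 0.0,
    region: str = "any",
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Fixed-length reads from the mitochondrial chromosome for NUMT tests.

    ``region`` restricts genuine mt reads to windows fully inside a NUMT
    source segment (``numt_covered``), windows overlapping none
    (``numt_free``), or anywhere (``any``). A ``from_numt_fraction`` of reads
    is instead copied from the NUMT insertion sequences themselves
    (numt_derived truth flag). Errors are iid substitutions.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    mt_seq = bundle.sequences[bundle.mt_chrom]
    starts_all = np.arange(0, len(mt_seq) - read_len + 1)
    if region != "any":
        covered = np.zeros(len(mt_seq), dtype=bool)
        win_cov = np.zeros(len(starts_all), dtype=bool)
        for r in bundle.numt_truth.itertuples(index=False):
            covered[r.mt_start:r.mt_end] = True
            # a "covered" window must sit wholly inside one source segment so
            # a full-length in-register NUMT placement exists
            lo, hi = r.mt_start, r.mt_end - read_len
            if hi >= lo:
                sel = (starts_all >= lo) & (starts_all <= hi)
                win_cov[sel] = True
        win_free = np.array([
            not covered[s:s + read_len].any() for s in starts_all
        ])
        starts_all = starts_all[win_cov if region == "numt_covered" else win_free]
        if len(starts_all) == 0:
            raise ValueError(f"no {region} windows of {read_len} bp available")
    rows = []
    for i in range(n):
        if from_numt_fraction > 0 and rng.random() < from_numt_fraction and bundle.numts:
            rec = bundle.numts[rng.integers(0, len(bundle.numts))]
            rl = min(read_len, len(rec.sequence))
            s = int(rng.integers(0, len(rec.sequence) - rl + 1))
            raw, origin, derived = rec.sequence[s:s + rl], rec.numt_id, True
        else:
            s = int(starts_all[rng.integers(0, len(starts_all))])
            raw, origin, derived = mt_seq[s:s + read_len], "mt", False
        seq, _ = _mutate(rng, raw, error_rate)
        rows.append((f"read{i}", seq, origin, derived))
    return pd.DataFrame(rows, columns=["pair_id", "rna_seq", "origin", "numt_derived"])


# ---------------------------------------------------------------------------
# DEG tables
# ---------------------------------------------------------------------------


def simulate_deg_tables(
    universe: Sequence[str],
    planted_down: Iterable[str] = (),
    gainer_set: Iterable[str] = (),
    planted_or: float = 1.0,
    reduced_rate: float = 0.05,
    effect: float = 3.5,
    shared_sd: float = 0.9,
    noise_sd: float = 0.3,
    labels: Sequence[str] = ("bulk", "sn", "sc"),
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Dict[str, pd.DataFrame], Dict[str, object]]:
    """Simulate DEG tables with a planted common-down set and OR structure.

    Every dataset shares a per-gene baseline fold-change component (giving
    cross-dataset Spearman concordance shared_sd^2/(shared_sd^2+noise_sd^2));
    genes in ``planted_down`` are downregulated in every dataset; additional
    genes are down per dataset with probability ``reduced_rate``, raised for
    ``gainer_set`` members so the down-set associates with the gainers at
    odds ratio ``planted_or`` in expectation.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    universe = list(universe)
    planted_down = set(planted_down)
    gainers = set(gainer_set)
    if not planted_down <= set(universe) or not gainers <= set(universe):
        raise ValueError("planted sets must be subsets of the universe")
    p0 = reduced_rate
    odds1 = planted_or * p0 / (1 - p0) if p0 < 1 else float("inf")
    p1 = odds1 / (1 + odds1)
    base = rng.normal(0.0, 1.0, len(universe)) * shared_sd
    sd0 = float(np.hypot(shared_sd, noise_sd))
    tables: Dict[str, pd.DataFrame] = {}
    members_truth: Dict[str, List[str]] = {}
    for lab in labels:
        u = rng.random(len(universe))
        member = np.array([
            (g in planted_down)
            or (u[i] < (p1 if g in gainers else p0))
            for i, g in enumerate(universe)
        ])
        fc = base + rng.normal(0.0, 1.0, len(universe)) * noise_sd
        fc = fc - member * effect
        if sd0 > 0:
            from scipy import stats as _st

            pv = 2 * _st.norm.sf(np.abs(fc) / sd0)
        else:
            pv = np.where(np.abs(fc) > 0, 0.0, 1.0)
        from .diffassoc import bh_adjust

        padj = bh_adjust(pv)
        tables[lab] = pd.DataFrame(
            {"gene": universe, "log2FC": fc, "pvalue": pv, "padj": padj}
        )
        members_truth[lab] = [g for g, m in zip(universe, member) if m]
    truth = {
        "planted_down": sorted(planted_down),
        "gainers": sorted(gainers),
        "planted_or": planted_or,
        "p0": p0,
        "p1": p1,
        "members": members_truth,
    }
    return tables, truth


# ---------------------------------------------------------------------------
# promoter-count calibration study
# ---------------------------------------------------------------------------


def simulate_promoter_counts(
    n_promoters: int = 500,
    frac_gainers: float = 0.10,
    effect: float = 4.0,
    n_focal: int = 10_000,
    promoter_share: float = 0.85,
    affinity_sigma: float = 0.5,
    rng: Optional[np.random.Generator] = None,
) -> Dict[str, np.ndarray]:
    """One draw of per-promoter focal-pair counts for two conditions.

    Baseline per-promoter attachment weights are log-normal with spread
    ``affinity_sigma``; a random ``frac_gainers`` of promoters gain a
    ``effect``-fold attachment increase in the second condition. Library
    depth is fixed at ``n_focal`` pairs per condition, so the gain is
    realized against a renormalized composition, as in depth-normalized
    sequencing data.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    w = np.exp(rng.normal(0.0, affinity_sigma, n_promoters))
    p_nm = promoter_share * w / w.sum()
    n_gain = int(round(frac_gainers * n_promoters))
    gainers = np.zeros(n_promoters, dtype=bool)
    gainers[rng.choice(n_promoters, size=n_gain, replace=False)] = True
    p_ht = p_nm * np.where(gainers, effect, 1.0)
    bg_nm = 1.0 - p_nm.sum()
    bg_ht = max(1.0 - p_ht.sum(), 0.0)
    probs_nm = np.r_[p_nm, bg_nm]
    probs_ht = np.r_[p_ht, bg_ht]
    probs_ht = probs_ht / probs_ht.sum()
    k_nm = rng.multinomial(n_focal, probs_nm)[:-1]
    k_ht = rng.multinomial(n_focal, probs_ht)[:-1]
    return {
        "k_nm": k_nm,
        "k_ht": k_ht,
        "n_nm": n_focal,
        "n_ht": n_focal,
        "gainers": gainers,
    }


def fdr_power_study(
    n_sims: int = 200,
    q_threshold: float = 0.05,
    rng: Optional[np.random.Generator] = None,
    **kwargs,
) -> Dict[str, float]:
    """Empirical FDR and power of the promoter test over repeated draws."""
    from .diffassoc import diff_test_counts

    rng = rng if rng is not None else np.random.default_rng(0)
    fdps, powers = [], []
    for _ in range(n_sims):
        d = simulate_promoter_counts(rng=rng, **kwargs)
        res = diff_test_counts(d["k_nm"], d["k_ht"], d["n_nm"], d["n_ht"])
        disc = res["q_value"].to_numpy() < q_threshold
        true = d["gainers"]
        n_disc = int(disc.sum())
        fdps.append((disc & ~true).sum() / max(1, n_disc))
        powers.append((disc & true).sum() / max(1, true.sum()))
    return {
        "empirical_fdr": float(np.mean(fdps)),
        "power": float(np.mean(powers)),
        "n_sims": float(n_sims),
    }


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def write_bundle(bundle: GenomeBundle, outdir: str) -> Dict[str, str]:
    """Write genome FASTA, GTF, BEDs, NUMT FASTA and induced-gene list."""
    import os

    from .genome import write_gtf
    from .numt import write_numts_fasta

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    fa = os.path.join(outdir, "genome.fa")
    with open(fa, "w") as fh:
        for chrom in sorted(bundle.sequences):
            fh.write(f">{chrom}\n")
            s = bundle.sequences[chrom]
            for i in range(0, len(s), 80):
                fh.write(s[i:i + 80] + "\n")
    paths["genome_fasta"] = fa

    gtf = os.path.join(outdir, "genes.gtf")
    write_gtf(bundle.genes, gtf)
    paths["genes_gtf"] = gtf

    for name, ivs in (("enhancers", bundle.enhancers),
                      ("super_enhancers", bundle.super_enhancers)):
        path = os.path.join(outdir, f"{name}.bed")
        with open(path, "w") as fh:
            for iv in ivs:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
        paths[name] = path

    nf = os.path.join(outdir, "numts.fa")
    write_numts_fasta(bundle.numts, nf)
    paths["numts_fasta"] = nf

    ind = os.path.join(outdir, "induced_genes.txt")
    with open(ind, "w") as fh:
        fh.write("\n".join(bundle.induced_gene_ids) + "\n")
    paths["induced_genes"] = ind
    return paths
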