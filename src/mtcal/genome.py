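"""Genomes, gene models, RNA classes and the region-type partition.

The central object is :class:`RegionPartition`: an exhaustive, non-overlapping
labelling of every nuclear genomic position with one of nine region types
(HT-induced promoter, promoter, 5'UTR, 3'UTR, CDS, intron, super enhancer,
enhancer, intergenic). Overlaps between annotation layers are resolved by a
configurable precedence order, gene-proximal regulatory types first, so that
any locus midpoint maps to exactly one label. This partition underlies both
the per-kilobase region association statistics and DNA-end attribution of
contact pairs.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._intervals import clip, intersect, merge, subtract, total_length

RNA_CLASSES = ("mt_mRNA", "mt_rRNA", "mt_tRNA", "mt_lncRNA", "nuclear")
MT_CLASSES = ("mt_mRNA", "mt_rRNA", "mt_tRNA", "mt_lncRNA")

#: Region types in the default precedence order (highest first; intergenic is
#: the complement of everything else).
REGION_TYPES = (
    "promoter_ht_induced",
    "promoter",
    "utr5",
    "utr3",
    "cds",
    "intron",
    "super_enhancer",
    "enhancer",
    "intergenic",
)

DEFAULT_PROMOTER_WINDOW = (2000, 500)  # (upstream bp, downstream bp) of TSS


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class GeneModel:
    """A gene with exon structure, optional CDS, and an RNA class label."""

    gene_id: str
    name: str
    rna_class: str
    body: GenomicInterval
    exons: List[GenomicInterval] = field(default_factory=list)
    cds: List[GenomicInterval] = field(default_factory=list)
    chrom_is_mt: bool = False

    def __post_init__(self) -> None:
        if self.rna_class not in RNA_CLASSES:
            raise ValueError(f"unknown rna_class {self.rna_class!r}")
        if self.rna_class.startswith("mt_") != self.chrom_is_mt:
            raise ValueError(
                f"{self.gene_id}: rna_class {self.rna_class} inconsistent "
                f"with chrom_is_mt={self.chrom_is_mt}"
            )
        if not self.exons:
            self.exons = [self.body]
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        prev_end = None
        for ex in self.exons:
            if ex.start < self.body.start or ex.end > self.body.end:
                raise ValueError(f"{self.gene_id}: exon outside gene body")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"{self.gene_id}: overlapping exons")
            prev_end = ex.end

    @property
    def strand(self) -> str:
        return self.body.strand

    @property
    def tss(self) -> int:
        """Transcription start site (body start on +, last base on -)."""
        return self.body.start if self.strand != "-" else self.body.end - 1

    @property
    def exonic_length(self) -> int:
        return sum(len(ex) for ex in self.exons)

    def exon_tuples(self) -> List[Tuple[int, int]]:
        return [(ex.start, ex.end) for ex in self.exons]


def promoter_interval(
    gene: GeneModel,
    window: Tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
    chrom_size: Optional[int] = None,
) -> Optional[GenomicInterval]:
    """Strand-aware promoter window around the TSS, clipped to the chromosome.

    On the + strand the window covers ``[tss - upstream, tss + downstream)``;
    on the - strand, upstream extends toward larger coordinates.
    """
    up, down = window
    if up < 0 or down < 0 or (up == 0 and down == 0):
        raise ValueError("promoter window components must be >= 0, not both 0")
    t = gene.tss
    if gene.strand != "-":
        s, e = t - up, t + down
    else:
        s, e = t + 1 - down, t + 1 + up
    hi = chrom_size if chrom_size is not None else e
    clipped = clip(s, e, 0, max(hi, 0))
    if clipped is None:
        return None
    return GenomicInterval(gene.body.chrom, clipped[0], clipped[1], gene.strand)


class RegionPartition:
    """Exhaustive single-label tiling of the nuclear genome by region type.

    Internally each chromosome is cut into elementary segments whose
    boundaries are the endpoints of every annotated interval; each segment
    carries exactly one region-type label obtained by painting types from
    lowest to highest precedence. Promoter segments additionally record the
    gene they belong to, which the differential promoter test uses.
    """

    def __init__(
        self,
        chrom_sizes: Dict[str, int],
        precedence: Sequence[str],
        bounds: Dict[str, np.ndarray],
        labels: Dict[str, np.ndarray],
        seg_gene: Dict[str, np.ndarray],
        gene_ids: List[str],
    ) -> None:
        self.chrom_sizes = dict(chrom_sizes)
        self.precedence = list(precedence)
        self._bounds = bounds
        self._labels = labels
        self._seg_gene = seg_gene
        self._gene_ids = gene_ids
        self.total_kb: Dict[str, float] = {}
        for chrom, b in bounds.items():
            lens = np.diff(b)
            lab = labels[chrom]
            for i, rt in enumerate(REGION_TYPES):
                kb = float(lens[lab == i].sum()) / 1000.0
                if kb > 0:
                    self.total_kb[rt] = self.total_kb.get(rt, 0.0) + kb

    # -- queries -----------------------------------------------------------

    def assign(self, locus: GenomicInterval) -> str:
        """Region type of the locus midpoint (deterministic, exactly one)."""
        if locus.chrom not in self._bounds:
            raise KeyError(f"chromosome {locus.chrom!r} unknown to partition")
        mid = locus.midpoint
        b = self._bounds[locus.chrom]
        if not (0 <= mid < self.chrom_sizes[locus.chrom]):
            raise ValueError(
                f"midpoint {mid} outside chromosome {locus.chrom}"
            )
        i = int(np.searchsorted(b, mid, side="right") - 1)
        return REGION_TYPES[self._labels[locus.chrom][i]]

    def assign_many(
        self, chroms: Sequence[str], mids: Sequence[int]
    ) -> np.ndarray:
        """Vectorised midpoint labelling; returns an array of type names."""
        chroms = np.asarray(chroms, dtype=object)
        mids = np.asarray(mids, dtype=np.int64)
        out = np.empty(len(mids), dtype=object)
        for chrom in pd.unique(chroms):
            if chrom not in self._bounds:
                raise KeyError(f"chromosome {chrom!r} unknown to partition")
            m = chroms == chrom
            sub = mids[m]
            size = self.chrom_sizes[chrom]
            if (sub < 0).any() or (sub >= size).any():
                offender = int(sub[(sub < 0) | (sub >= size)][0])
                raise ValueError(
                    f"locus midpoint {offender} outside chromosome {chrom} "
                    f"(size {size}); pass chrom_sizes covering the data when "
                    "building the partition"
                )
            idx = np.searchsorted(self._bounds[chrom], sub, side="right") - 1
            lab = self._labels[chrom][idx]
            out[m] = np.array(REGION_TYPES, dtype=object)[lab]
        return out

    def promoter_gene(self, locus: GenomicInterval) -> Optional[str]:
        """Gene owning the promoter segment at the locus midpoint, if any."""
        if locus.chrom not in self._bounds:
            return None
        mid = locus.midpoint
        if not (0 <= mid < self.chrom_sizes[locus.chrom]):
            return None
        b = self._bounds[locus.chrom]
        i = int(np.searchsorted(b, mid, side="right") - 1)
        g = self._seg_gene[locus.chrom][i]
        return self._gene_ids[g] if g >= 0 else None

    def promoter_footprints(self) -> Dict[str, List[GenomicInterval]]:
        """Masked per-gene promoter footprint (promoter + HT-induced labels)."""
        out: Dict[str, List[GenomicInterval]] = {}
        promo = {REGION_TYPES.index("promoter"), REGION_TYPES.index("promoter_ht_induced")}
        for chrom, b in self._bounds.items():
            lab = self._labels[chrom]
            gidx = self._seg_gene[chrom]
            for i in range(len(lab)):
                if lab[i] in promo and gidx[i] >= 0:
                    gid = self._gene_ids[gidx[i]]
                    out.setdefault(gid, []).append(
                        GenomicInterval(chrom, int(b[i]), int(b[i + 1]))
                    )
        return out

    def footprint(self, region_type: str) -> Dict[str, List[Tuple[int, int]]]:
        """Merged footprint of one region type, per chromosome."""
        if region_type not in REGION_TYPES:
            raise KeyError(f"unknown region type {region_type!r}")
        t = REGION_TYPES.index(region_type)
        out: Dict[str, List[Tuple[int, int]]] = {}
        for chrom, b in self._bounds.items():
            lab = self._labels[chrom]
            ivs = [
                (int(b[i]), int(b[i + 1])) for i in range(len(lab)) if lab[i] == t
            ]
            if ivs:
                out[chrom] = merge(ivs)
        return out

    def to_bed(self, path: str) -> None:
        """Export the partition as BED with the region type in the name column."""
        with open(path, "w") as fh:
            for chrom in sorted(self._bounds):
                b = self._bounds[chrom]
                lab = self._labels[chrom]
                for i in range(len(lab)):
                    fh.write(
                        f"{chrom}\t{int(b[i])}\t{int(b[i + 1])}\t"
                        f"{REGION_TYPES[lab[i]]}\n"
                    )


def _gene_structure_footprints(
    gene: GeneModel,
) -> Dict[str, List[Tuple[int, int]]]:
    """Per-gene utr5/utr3/cds/intron footprints from exon and CDS structure.

    Exons of genes without an annotated CDS are counted in the ``cds``
    category (a merged exon category).
    """
    exons = merge(gene.exon_tuples())
    body = (gene.body.start, gene.body.end)
    out = {"utr5": [], "utr3": [], "cds": [], "intron": subtract([body], exons)}
    cds = merge([(c.start, c.end) for c in gene.cds])
    if not cds:
        out["cds"] = exons
        return out
    out["cds"] = intersect(exons, cds)
    cds_lo, cds_hi = cds[0][0], cds[-1][1]
    utr = subtract(exons, cds)
    for s, e in utr:
        if e <= cds_lo:
            key = "utr5" if gene.strand != "-" else "utr3"
        elif s >= cds_hi:
            key = "utr3" if gene.strand != "-" else "utr5"
        else:  # between CDS chunks: group with CDS-internal sequence
            key = "cds"
        out[key].append((s, e))
    return out


def build_region_partition(
    genes: Iterable[GeneModel],
    enhancers: Iterable[GenomicInterval] = (),
    super_enhancers: Iterable[GenomicInterval] = (),
    ht_induced_gene_ids: Iterable[str] = (),
    promoter_window: Tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
    chrom_sizes: Optional[Dict[str, int]] = None,
    precedence: Optional[Sequence[str]] = None,
) -> RegionPartition:
    """Tile the nuclear genome with region types under a precedence order.

    Parameters
    ----------
    genes
        Gene models; mitochondrial genes are ignored (the partition covers
        the nuclear genome only).
    ht_induced_gene_ids
        Genes whose promoters form the separate ``promoter_ht_induced``
        category.
    promoter_window
        ``(upstream, downstream)`` bp around the TSS, strand-aware.
    chrom_sizes
        Nuclear chromosome lengths; inferred from annotation extents when
        omitted.
    precedence
        Region types, highest priority first; defaults to
        :data:`REGION_TYPES`.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene set")
    nuclear = [g for g in genes if not g.chrom_is_mt]
    if not nuclear:
        raise ValueError("no nuclear genes in gene set")
    induced = set(ht_induced_gene_ids)
    known = {g.gene_id for g in nuclear}
    missing = sorted(induced - known)
    if missing:
        raise ValueError(f"ht_induced_gene_ids not found in genes: {missing}")
    precedence = list(precedence) if precedence is not None else list(REGION_TYPES)
    if set(precedence) != set(REGION_TYPES):
        raise ValueError("precedence must be a permutation of REGION_TYPES")

    if chrom_sizes is None:
        chrom_sizes = {}
        feats = (
            [g.body for g in nuclear]
            + list(enhancers)
            + list(super_enhancers)
        )
        for iv in feats:
            chrom_sizes[iv.chrom] = max(chrom_sizes.get(iv.chrom, 0), iv.end)

    # collect per-type, per-chrom raw footprints
    fp: Dict[str, Dict[str, List[Tuple[int, int]]]] = {
        rt: {} for rt in REGION_TYPES
    }

    def add(rt: str, chrom: str, s: int, e: int) -> None:
        size = chrom_sizes.get(chrom)
        if size is None:
            return
        c = clip(s, e, 0, size)
        if c is not None:
            fp[rt].setdefault(chrom, []).append(c)

    promoter_windows: Dict[str, List[Tuple[int, int, int, str, bool]]] = {}
    gene_ids = [g.gene_id for g in nuclear]
    for g in nuclear:
        piv = promoter_interval(g, promoter_window, chrom_sizes.get(g.body.chrom))
        is_ind = g.gene_id in induced
        if piv is not None:
            add("promoter_ht_induced" if is_ind else "promoter", piv.chrom, piv.start, piv.end)
            promoter_windows.setdefault(piv.chrom, []).append(
                (piv.start, piv.end, g.tss, g.gene_id, is_ind)
            )
        for rt, ivs in _gene_structure_footprints(g).items():
            for s, e in ivs:
                add(rt, g.body.chrom, s, e)
    for iv in enhancers:
        add("enhancer", iv.chrom, iv.start, iv.end)
    for iv in super_enhancers:
        add("super_enhancer", iv.chrom, iv.start, iv.end)

    gid_index = {gid: i for i, gid in enumerate(gene_ids)}
    bounds: Dict[str, np.ndarray] = {}
    labels: Dict[str, np.ndarray] = {}
    seg_gene: Dict[str, np.ndarray] = {}
    intergenic_i = REGION_TYPES.index("intergenic")
    for chrom, size in chrom_sizes.items():
        pts = {0, size}
        for rt in REGION_TYPES:
            for s, e in fp[rt].get(chrom, []):
                pts.add(s)
                pts.add(e)
        b = np.array(sorted(pts), dtype=np.int64)
        lab = np.full(len(b) - 1, intergenic_i, dtype=np.int8)
        # paint lowest precedence first so higher types overwrite
        for rt in reversed(precedence):
            if rt == "intergenic":
                continue
            t = REGION_TYPES.index(rt)
            for s, e in merge(fp[rt].get(chrom, [])):
                i0 = int(np.searchsorted(b, s))
                i1 = int(np.searchsorted(b, e))
                lab[i0:i1] = t
        gidx = np.full(len(lab), -1, dtype=np.int64)
        wins = sorted(promoter_windows.get(chrom, []))
        promo_set = {
            REGION_TYPES.index("promoter"),
            REGION_TYPES.index("promoter_ht_induced"),
        }
        if wins:
            wstarts = [w[0] for w in wins]
            for i in range(len(lab)):
                if lab[i] not in promo_set:
                    continue
                mid = (b[i] + b[i + 1]) // 2
                want_induced = lab[i] == REGION_TYPES.index("promoter_ht_induced")
                j = bisect.bisect_right(wstarts, mid)
                best = None
                for s, e, tss, gid, is_ind in wins[:j][::-1]:
                    if e <= mid:
                        continue
                    if is_ind != want_induced:
                        continue
                    key = (abs(tss - mid), gid)
                    if best is None or key < best[0]:
                        best = (key, gid)
                if best is not None:
                    gidx[i] = gid_index[best[1]]
        bounds[chrom] = b
        labels[chrom] = lab
        seg_gene[chrom] = gidx

    return RegionPartition(chrom_sizes, precedence, bounds, labels, seg_gene, gene_ids)


def assign_region(locus: GenomicInterval, partition: RegionPartition) -> str:
    """Region type at the locus midpoint (exactly one, deterministic)."""
    return partition.assign(locus)


def _strand_compatible(locus_strand: str, gene_strand: str) -> bool:
    return "." in (locus_strand, gene_strand) or locus_strand == gene_strand


def assign_rna_gene(
    locus: GenomicInterval,
    genes: Iterable[GeneModel],
    strand_aware: bool = True,
) -> Optional[str]:
    """Gene whose exonic footprint covers the locus midpoint.

    Ties (overlapping genes) are broken by the largest overlap between the
    locus and the exonic footprint, then lexicographic gene id. Returns None
    when no gene matches.
    """
    mid = locus.midpoint
    best: Optional[Tuple[int, str]] = None
    for g in genes:
        if g.body.chrom != locus.chrom:
            continue
        if strand_aware and not _strand_compatible(locus.strand, g.strand):
            continue
        if not any(ex.start <= mid < ex.end for ex in g.exons):
            continue
        ov = sum(
            max(0, min(locus.end, ex.end) - max(locus.start, ex.start))
            for ex in g.exons
        )
        key = (-ov, g.gene_id)
        if best is None or key < best:
            best = key
    return best[1] if best else None


class GeneIndex:
    """Fast midpoint-to-gene lookup over exonic footprints.

    Resolution follows :func:`assign_rna_gene`: overlapping genes are
    disambiguated by largest locus/exon overlap then lexicographic id.
    """

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes = list(genes)
        self._by_chrom: Dict[str, Tuple[np.ndarray, List[Tuple[int, ...]]]] = {}
        per_chrom: Dict[str, List[Tuple[int, int, int]]] = {}
        for i, g in enumerate(self.genes):
            for ex in g.exons:
                per_chrom.setdefault(g.body.chrom, []).append(
                    (ex.start, ex.end, i)
                )
        for chrom, exlist in per_chrom.items():
            pts = sorted({p for s, e, _ in exlist for p in (s, e)})
            b = np.array(pts, dtype=np.int64)
            segs: List[Tuple[int, ...]] = [() for _ in range(len(b) - 1)]
            for s, e, i in exlist:
                i0 = int(np.searchsorted(b, s))
                i1 = int(np.searchsorted(b, e))
                for k in range(i0, i1):
                    segs[k] = segs[k] + (i,)
            self._by_chrom[chrom] = (b, segs)

    def assign(self, locus: GenomicInterval, strand_aware: bool = True) -> Optional[str]:
        entry = self._by_chrom.get(locus.chrom)
        if entry is None:
            return None
        b, segs = entry
        mid = locus.midpoint
        k = int(np.searchsorted(b, mid, side="right") - 1)
        if k < 0 or k >= len(segs) or not segs[k]:
            return None
        cands = [
            self.genes[i]
            for i in segs[k]
            if not strand_aware or _strand_compatible(locus.strand, self.genes[i].strand)
        ]
        if not cands:
            return None
        if len(cands) == 1:
            return cands[0].gene_id
        return assign_rna_gene(locus, cands, strand_aware=strand_aware)

    def assign_frame(
        self,
        chroms: Sequence[str],
        starts: Sequence[int],
        ends: Sequence[int],
        strands: Optional[Sequence[str]] = None,
        strand_aware: bool = True,
    ) -> np.ndarray:
        """Vectorised assignment; returns object array of gene ids / None."""
        chroms = np.asarray(chroms, dtype=object)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if strands is None:
            strands = np.full(len(chroms), ".", dtype=object)
        else:
            strands = np.asarray(strands, dtype=object)
        out = np.full(len(chroms), None, dtype=object)
        mids = (starts + ends) // 2
        for chrom in pd.unique(chroms):
            entry = self._by_chrom.get(chrom)
            if entry is None:
                continue
            b, segs = entry
            sel = np.flatnonzero(chroms == chrom)
            k = np.searchsorted(b, mids[sel], side="right") - 1
            ok = (k >= 0) & (k < len(segs))
            for j, ki in zip(sel[ok], k[ok]):
                cand = segs[ki]
                if not cand:
                    continue
                if len(cand) == 1:
                    g = self.genes[cand[0]]
                    if not strand_aware or _strand_compatible(strands[j], g.strand):
                        out[j] = g.gene_id
                else:
                    out[j] = self.assign(
                        GenomicInterval(chrom, int(starts[j]), int(ends[j]), strands[j]),
                        strand_aware=strand_aware,
                    )
        return out


# ---------------------------------------------------------------------------
# annotation I/O
# ---------------------------------------------------------------------------


def write_gtf(genes: Iterable[GeneModel], path: str, source: str = "mtcal") -> None:
    """Write gene/exon/CDS features as GTF (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = (
                f'gene_id "{g.gene_id}"; gene_name "{g.name}"; '
                f'rna_class "{g.rna_class}";'
            )
            chrom = g.body.chrom
            fh.write(
                f"{chrom}\t{source}\tgene\t{g.body.start + 1}\t{g.body.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for ex in g.exons:
                fh.write(
                    f"{chrom}\t{source}\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )
            for c in g.cds:
                fh.write(
                    f"{chrom}\t{source}\tCDS\t{c.start + 1}\t{c.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )


def read_gtf(path: str, mt_chrom: str = "chrM") -> List[GeneModel]:
    """Read gene models from GTF via gffutils (gene/exon/CDS features)."""
    import gffutils

    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_gene: Dict[str, Dict[str, list]] = {}
    order: List[str] = []
    for feat in db.all_features():
        gid = feat.attributes.get("gene_id", [feat.id])[0]
        rec = by_gene.get(gid)
        if rec is None:
            rec = by_gene[gid] = {"gene": None, "exon": [], "CDS": [], "attrs": feat.attributes}
            order.append(gid)
        if feat.featuretype == "gene":
            rec["gene"] = feat
            rec["attrs"] = feat.attributes
        elif feat.featuretype in ("exon", "CDS"):
            rec[feat.featuretype].append(feat)
    genes: List[GeneModel] = []
    for gid in order:
        rec = by_gene[gid]
        feat = rec["gene"]
        if feat is None:
            continue
        chrom = feat.seqid
        is_mt = chrom == mt_chrom
        rna_class = rec["attrs"].get("rna_class", [None])[0]
        if rna_class is None:
            rna_class = "nuclear" if not is_mt else "mt_mRNA"
        body = GenomicInterval(chrom, feat.start - 1, feat.end, feat.strand)
        exons = [
            GenomicInterval(chrom, f.start - 1, f.end, feat.strand)
            for f in rec["exon"]
        ]
        cds = [
            GenomicInterval(chrom, f.start - 1, f.end, feat.strand)
            for f in rec["CDS"]
        ]
        name = rec["attrs"].get("gene_name", [gid])[0]
        genes.append(
            GeneModel(gid, name, rna_class, body, exons, cds, chrom_is_mt=is_mt)
        )
    return genes


def read_bed(path: str) -> List[GenomicInterval]:
    """Read BED3/BED6 intervals (e.g. enhancers or super enhancers)."""
    out: List[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) > 5 and f[5] in "+-" else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def read_bed12(path: str, mt_chrom: str = "chrM") -> List[GeneModel]:
    """Read gene models from BED12 (thickStart/thickEnd define the CDS)."""
    genes: List[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5] if len(f) > 5 and f[5] in "+-" else "."
            body = GenomicInterval(chrom, start, end, strand)
            thick_s, thick_e = (int(f[6]), int(f[7])) if len(f) > 7 else (start, start)
            if len(f) > 11:
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offs = [int(x) for x in f[11].rstrip(",").split(",")]
                exons = [
                    GenomicInterval(chrom, start + o, start + o + s, strand)
                    for s, o in zip(sizes, offs)
                ]
            else:
                exons = [body]
            cds = []
            if thick_e > thick_s:
                for ex in exons:
                    c = clip(ex.start, ex.end, thick_s, thick_e)
                    if c:
                        cds.append(GenomicInterval(chrom, c[0], c[1], strand))
            is_mt = chrom == mt_chrom
            genes.append(
                GeneModel(
                    name,
                    name,
                    "mt_mRNA" if is_mt else "nuclear",
                    body,
                    exons,
                    cds,
                    chrom_is_mt=is_mt,
                )
            )
    return genes
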