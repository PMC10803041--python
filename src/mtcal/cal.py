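"""Chromatin association level (CAL) statistics and contrasts.

The overall CAL of an RNA class (or single RNA) in a library is

    CAL = 1e6 * n_pairs / (n_species * total_pairs)          [CPM]

where ``n_pairs`` counts RNA-to-nuclear-DNA pairs whose RNA end maps to the
class, ``n_species`` the number of RNA species of the class involved, and
``total_pairs`` all RNA-DNA pairs in the library. The region-restricted CAL
of a class on a region type (e.g. promoters) is

    CAL_region = n_pairs_in_region / region_kb / n_pairs_class

i.e. pairs per kilobase of region footprint per class pair. Contrasts are
log2 ratios with a recorded pseudocount; group comparisons use Student or
Welch t, Mann-Whitney, or one-way ANOVA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .contacts import PairsLike, as_frame
from .genome import GeneIndex, GeneModel, MT_CLASSES, RegionPartition

DEFAULT_MT_CHROM = "chrM"


@dataclass
class CALRecord:
    """One CAL measurement (overall CPM or region-restricted per-kb)."""

    scope: str  # "class" | "gene"
    target: str
    condition: str
    library_id: str
    n_pairs: int
    n_species: int
    total_pairs: int
    cal: float
    region_type: Optional[str] = None
    region_kb: Optional[float] = None


@dataclass
class CALContrast:
    """log2 ratio of two CAL values with the pseudocount used."""

    id: str
    log2_ratio: float
    numerator: str
    denominator: str
    pseudocount: float
    p_value: Optional[float] = None
    test: Optional[str] = None


# ---------------------------------------------------------------------------
# RNA-end annotation
# ---------------------------------------------------------------------------


def annotate_rna_genes(
    pairs: PairsLike,
    genes: Sequence[GeneModel],
    strand_aware: bool = True,
    junction_kmer: Optional[str] = None,
    junction_gene: Optional[str] = None,
    gene_index: Optional[GeneIndex] = None,
) -> pd.DataFrame:
    """Attach ``gene_id`` and ``rna_class`` columns to a pair frame.

    Positional assignment uses the exonic-footprint midpoint rule. A chimeric
    transcript indistinguishable from its parent locus by position (such as a
    mitochondrial lncRNA sharing the 16S rRNA body) can be claimed by
    sequence instead: reads containing ``junction_kmer`` are reassigned to
    ``junction_gene``.
    """
    frame = as_frame(pairs).copy()
    if gene_index is None:
        # the chimeric gene is excluded from the positional index: its exonic
        # footprint duplicates the parent gene and is identified by sequence
        pos_genes = [g for g in genes if g.gene_id != junction_gene]
        gene_index = GeneIndex(pos_genes)
    gid = gene_index.assign_frame(
        frame["rna_chrom"], frame["rna_start"], frame["rna_end"],
        frame["rna_strand"], strand_aware=strand_aware,
    )
    frame["gene_id"] = gid
    if junction_kmer and junction_gene:
        has_j = frame["rna_seq"].map(
            lambda s: isinstance(s, str) and junction_kmer in s
        )
        frame.loc[has_j, "gene_id"] = junction_gene
    class_of = {g.gene_id: g.rna_class for g in genes}
    frame["rna_class"] = frame["gene_id"].map(class_of)
    return frame


def _require_annotation(frame: pd.DataFrame, genes: Optional[Sequence[GeneModel]]):
    if "gene_id" in frame.columns and "rna_class" in frame.columns:
        return frame
    if genes is None:
        raise ValueError("pairs lack gene annotation and no genes were given")
    return annotate_rna_genes(frame, genes)


def _filter(frame: pd.DataFrame, condition: Optional[str], library_id: Optional[str]):
    if condition is not None:
        frame = frame[frame["condition"] == condition]
    if library_id is not None:
        frame = frame[frame["library_id"] == library_id]
    return frame


# ---------------------------------------------------------------------------
# CAL computation
# ---------------------------------------------------------------------------


def compute_cal(
    pairs: PairsLike,
    genes: Optional[Sequence[GeneModel]] = None,
    scope: str = "class",
    target: str = "mt_mRNA",
    condition: Optional[str] = None,
    library_id: Optional[str] = None,
    mt_chrom: str = DEFAULT_MT_CHROM,
    detected_only: bool = True,
    total_pairs: Optional[int] = None,
) -> CALRecord:
    """Overall CAL (CPM) of an RNA class or a single RNA.

    ``n_species`` is 1 for gene scope; for class scope it counts the distinct
    species of the class with at least one RNA-end read in the filtered
    library ("involved"), or all annotated species of the class when
    ``detected_only=False``.
    """
    if scope not in ("class", "gene"):
        raise ValueError("scope must be 'class' or 'gene'")
    frame = _filter(as_frame(pairs), condition, library_id)
    frame = _require_annotation(frame, genes)
    total = int(total_pairs) if total_pairs is not None else int(len(frame))
    if total <= 0:
        raise ValueError("total_pairs must be > 0")
    nuc = frame[frame["dna_chrom"] != mt_chrom]  # RNA-nuDNA pairs only
    if scope == "gene":
        n_pairs = int((nuc["gene_id"] == target).sum())
        n_species = 1
    else:
        in_class = nuc[nuc["rna_class"] == target]
        n_pairs = int(len(in_class))
        if detected_only:
            n_species = int(in_class["gene_id"].nunique())
        else:
            if genes is None:
                raise ValueError("detected_only=False requires the gene set")
            n_species = sum(1 for g in genes if g.rna_class == target)
        if n_species == 0:
            raise ValueError(f"no detected species for class {target!r}")
    cal = 1e6 * n_pairs / (n_species * total)
    return CALRecord(
        scope, target, condition or "", library_id or "", n_pairs, n_species,
        total, cal,
    )


def compute_region_cal(
    pairs: PairsLike,
    partition: RegionPartition,
    genes: Optional[Sequence[GeneModel]] = None,
    scope: str = "class",
    target: str = "mt_mRNA",
    region_type: str = "promoter",
    condition: Optional[str] = None,
    library_id: Optional[str] = None,
    mt_chrom: str = DEFAULT_MT_CHROM,
) -> CALRecord:
    """Region-restricted CAL: pairs per kb of region per class pair."""
    region_kb = partition.total_kb.get(region_type)
    if not region_kb:
        raise ValueError(f"region {region_type!r} absent or zero kb in partition")
    frame = _filter(as_frame(pairs), condition, library_id)
    frame = _require_annotation(frame, genes)
    nuc = frame[frame["dna_chrom"] != mt_chrom]
    key = "gene_id" if scope == "gene" else "rna_class"
    cls = nuc[nuc[key] == target]
    n_class = int(len(cls))
    if n_class == 0:
        raise ValueError(f"{target!r} has no RNA-nuDNA pairs in this selection")
    if "dna_region" in cls.columns:
        regions = cls["dna_region"].to_numpy()
    else:
        regions = partition.assign_many(
            cls["dna_chrom"].to_numpy(),
            ((cls["dna_start"] + cls["dna_end"]) // 2).to_numpy(),
        )
    n_in = int((regions == region_type).sum())
    cal = n_in / region_kb / n_class
    return CALRecord(
        scope, target, condition or "", library_id or "", n_in, 1, n_class,
        cal, region_type=region_type, region_kb=region_kb,
    )


def annotate_dna_regions(frame: pd.DataFrame, partition: RegionPartition,
                         mt_chrom: str = DEFAULT_MT_CHROM) -> pd.DataFrame:
    """Attach a ``dna_region`` column (DNA-end midpoint region label)."""
    frame = frame.copy()
    frame["dna_region"] = None
    nuc = frame["dna_chrom"] != mt_chrom
    if nuc.any():
        frame.loc[nuc, "dna_region"] = partition.assign_many(
            frame.loc[nuc, "dna_chrom"].to_numpy(),
            ((frame.loc[nuc, "dna_start"] + frame.loc[nuc, "dna_end"]) // 2).to_numpy(),
        )
    return frame


def cal_table(
    pairs: PairsLike,
    genes: Sequence[GeneModel],
    scope: str = "class",
    per_library: bool = True,
    mt_chrom: str = DEFAULT_MT_CHROM,
) -> pd.DataFrame:
    """CAL of every class (or every detected gene) per library or condition."""
    frame = _require_annotation(as_frame(pairs), genes)
    group_col = "library_id" if per_library else "condition"
    rows: List[CALRecord] = []
    for gval, sub in frame.groupby(group_col, sort=True):
        targets = (
            sorted(set(c for c in sub["rna_class"].dropna()))
            if scope == "class"
            else sorted(set(g for g in sub["gene_id"].dropna()))
        )
        for t in targets:
            try:
                rec = compute_cal(
                    sub, genes, scope=scope, target=t, mt_chrom=mt_chrom
                )
            except ValueError:
                continue  # class with no RNA-nuDNA pairs in this library
            rec.library_id = str(gval) if per_library else ""
            rec.condition = (
                str(sub["condition"].iloc[0]) if per_library else str(gval)
            )
            rows.append(rec)
    return pd.DataFrame([r.__dict__ for r in rows])


def region_cal_table(
    pairs: PairsLike,
    partition: RegionPartition,
    genes: Sequence[GeneModel],
    scope: str = "class",
    targets: Optional[Sequence[str]] = None,
    per_condition: bool = True,
    mt_chrom: str = DEFAULT_MT_CHROM,
) -> pd.DataFrame:
    """Region CAL for each target x region type (x condition)."""
    frame = _require_annotation(as_frame(pairs), genes)
    frame = annotate_dna_regions(frame, partition, mt_chrom)
    if targets is None:
        key = "rna_class" if scope == "class" else "gene_id"
        targets = sorted(set(t for t in frame[key].dropna()))
    conds = (
        sorted(frame["condition"].unique()) if per_condition else [None]
    )
    rows = []
    for cond in conds:
        sub = frame if cond is None else frame[frame["condition"] == cond]
        for t in targets:
            for rt in sorted(partition.total_kb):
                try:
                    rec = compute_region_cal(
                        sub, partition, genes, scope=scope, target=t,
                        region_type=rt, mt_chrom=mt_chrom,
                    )
                except ValueError:
                    continue
                rec.condition = cond or ""
                rows.append(rec)
    return pd.DataFrame([r.__dict__ for r in rows])


# ---------------------------------------------------------------------------
# contrasts and tests
# ---------------------------------------------------------------------------


def cal_contrast(
    cal_a: Union[float, CALRecord],
    cal_b: Union[float, CALRecord],
    pseudocount: Optional[float] = None,
    id: str = "",
    numerator: str = "a",
    denominator: str = "b",
) -> CALContrast:
    """log2((cal_a + eps) / (cal_b + eps)); positive means a > b.

    When CALRecords are given and no pseudocount is supplied, eps defaults to
    the CPM equivalent of half a pair at the records' depth, and 0 otherwise.
    A zero CAL with eps=0 is an error.
    """
    a = cal_a.cal if isinstance(cal_a, CALRecord) else float(cal_a)
    b = cal_b.cal if isinstance(cal_b, CALRecord) else float(cal_b)
    if pseudocount is None:
        if isinstance(cal_a, CALRecord) and isinstance(cal_b, CALRecord):
            eps_a = 0.5e6 / (cal_a.n_species * cal_a.total_pairs)
            eps_b = 0.5e6 / (cal_b.n_species * cal_b.total_pairs)
            pseudocount = 0.0 if (a > 0 and b > 0) else (eps_a + eps_b) / 2
        else:
            pseudocount = 0.0
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and (a <= 0 or b <= 0):
        raise ValueError("zero CAL requires a positive pseudocount")
    ratio = (a + pseudocount) / (b + pseudocount)
    if isinstance(cal_a, CALRecord):
        numerator = f"{cal_a.target}:{cal_a.condition or cal_a.library_id}"
    if isinstance(cal_b, CALRecord):
        denominator = f"{cal_b.target}:{cal_b.condition or cal_b.library_id}"
    return CALContrast(id, math.log2(ratio), numerator, denominator, pseudocount)


def class_cal_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    test: str = "student_t",
) -> Tuple[float, float]:
    """Two-sided comparison of two CAL collections; returns (stat, p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if test in ("student_t", "welch_t"):
        if len(a) < 2 or len(b) < 2:
            raise ValueError("t-tests need at least 2 values per group")
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            return 0.0, 1.0  # identical constants: no evidence of difference
        res = stats.ttest_ind(a, b, equal_var=(test == "student_t"))
    elif test == "mann_whitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)


def region_anova(groups: Union[Dict[str, Sequence[float]], Sequence[Sequence[float]]]) -> Tuple[float, float]:
    """One-way ANOVA of CAL values across region types; returns (F, p)."""
    if isinstance(groups, dict):
        arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        arrays = [np.asarray(v, dtype=float) for v in groups]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 values each")
    if all(np.ptp(a) == 0 for a in arrays):
        raise ValueError("degenerate ANOVA: zero within-group variance everywhere")
    res = stats.f_oneway(*arrays)
    return float(res.statistic), float(res.pvalue)


def per_gene_condition_contrast(
    pairs: PairsLike,
    genes: Sequence[GeneModel],
    condition_num: str,
    condition_den: str,
    classes: Iterable[str] = MT_CLASSES,
    mt_chrom: str = DEFAULT_MT_CHROM,
    pseudocount_pairs: float = 0.5,
) -> pd.DataFrame:
    """Per-gene log2 CAL ratio between two conditions (e.g. HT vs NM).

    CAL is computed per condition with libraries pooled; the pseudocount is
    ``pseudocount_pairs`` pairs expressed in CPM at each condition's depth.
    """
    frame = _require_annotation(as_frame(pairs), genes)
    classes = set(classes)
    rows = []
    sub_n = frame[frame["condition"] == condition_num]
    sub_d = frame[frame["condition"] == condition_den]
    if len(sub_n) == 0 or len(sub_d) == 0:
        raise ValueError("one of the conditions has no pairs")
    tot_n, tot_d = len(sub_n), len(sub_d)
    gene_ids = [g.gene_id for g in genes if g.rna_class in classes]
    for gid in gene_ids:
        rec_n = compute_cal(sub_n, genes, scope="gene", target=gid, mt_chrom=mt_chrom)
        rec_d = compute_cal(sub_d, genes, scope="gene", target=gid, mt_chrom=mt_chrom)
        eps = pseudocount_pairs * 1e6 * (1.0 / tot_n + 1.0 / tot_d) / 2
        con = cal_contrast(rec_n, rec_d, pseudocount=eps, id=gid)
        rows.append(
            (gid, rec_n.n_pairs, rec_d.n_pairs, rec_n.cal, rec_d.cal, con.log2_ratio)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            f"n_{condition_num}",
            f"n_{condition_den}",
            f"cal_{condition_num}",
            f"cal_{condition_den}",
            "log2_ratio",
        ],
    )
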