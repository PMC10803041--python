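"""Per-promoter differential association, enrichment and DEG concordance.

The per-promoter test asks, for a focal RNA, whether its share of pairs on a
given gene promoter increased between conditions. Each promoter gets a 2x2
table [[k_HT, m_HT], [k_NM, m_NM]] of focal pairs on vs off the promoter per
condition, tested with Fisher's exact test (one-sided "increase" by default)
or a conditional binomial test, followed by Benjamini-Hochberg adjustment
across promoters. Gene-set enrichment between promoter-gaining genes and
knockdown-responsive genes uses a chi-square 2x2 association test with the
odds ratio ad/bc. DEG concordance intersects externally produced
differential-expression tables and reports Spearman correlation of fold
changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .cal import DEFAULT_MT_CHROM, _require_annotation
from .contacts import PairsLike, as_frame
from .genome import GeneModel, RegionPartition


@dataclass
class DiffAssocResult:
    """Per-promoter condition contrast for the focal RNA."""

    gene_id: str
    k_nm: int
    k_ht: int
    m_nm: int
    m_ht: int
    log2_effect: float
    p_value: float
    q_value: float = float("nan")


@dataclass
class EnrichmentResult:
    """2x2 gene-set association (chi-square) with odds ratio."""

    a: int  # gainers & reduced
    b: int  # gainers only
    c: int  # reduced only
    d: int  # neither
    odds_ratio: float
    chi2: float
    p_value: float
    universe: int
    haldane: bool = False


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Standard step-up: q_(i) = min_{j>=i} p_(j) * n / j, clipped to 1, with
    ties preserved and the original order restored.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _one_table_p(k_ht: int, m_ht: int, k_nm: int, m_nm: int,
                 test: str, alternative: str) -> float:
    table = [[k_ht, m_ht], [k_nm, m_nm]]
    if test == "fisher_2x2":
        return float(stats.fisher_exact(table, alternative=alternative).pvalue)
    if test == "binomial":
        # conditional on the promoter total, k_HT ~ Binomial(k, p0) where p0
        # is the HT share of focal pairs
        k = k_ht + k_nm
        n_ht, n_nm = k_ht + m_ht, k_nm + m_nm
        if k == 0:
            return 1.0
        p0 = n_ht / (n_ht + n_nm)
        return float(stats.binomtest(k_ht, k, p0, alternative=alternative).pvalue)
    raise ValueError(f"unknown test {test!r}")


def diff_test_counts(
    k_nm: Sequence[int],
    k_ht: Sequence[int],
    n_nm: int,
    n_ht: int,
    gene_ids: Optional[Sequence[str]] = None,
    test: str = "fisher_2x2",
    alternative: str = "greater",
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Differential-association tests from per-promoter focal counts.

    ``n_nm``/``n_ht`` are the focal RNA's total pairs per condition; the
    off-promoter backgrounds are the complements. ``alternative='greater'``
    tests for an HT increase. BH adjustment runs across all promoters given.
    """
    k_nm = np.asarray(k_nm, dtype=int)
    k_ht = np.asarray(k_ht, dtype=int)
    if len(k_nm) != len(k_ht):
        raise ValueError("count vectors differ in length")
    if gene_ids is None:
        gene_ids = [f"promoter{i}" for i in range(len(k_nm))]
    if n_nm <= 0 or n_ht <= 0:
        raise ValueError("zero focal pairs in a condition")
    m_nm = n_nm - k_nm
    m_ht = n_ht - k_ht
    if (m_nm < 0).any() or (m_ht < 0).any():
        raise ValueError("promoter count exceeds focal total")
    ps = np.array([
        _one_table_p(int(kh), int(mh), int(kn), int(mn), test, alternative)
        for kh, mh, kn, mn in zip(k_ht, m_ht, k_nm, m_nm)
    ])
    qs = bh_adjust(ps)
    eff = np.log2(((k_ht + pseudocount) / n_ht) / ((k_nm + pseudocount) / n_nm))
    return pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "k_nm": k_nm,
            "k_ht": k_ht,
            "m_nm": m_nm,
            "m_ht": m_ht,
            "log2_effect": eff,
            "p_value": ps,
            "q_value": qs,
        }
    )


def promoter_diff_test(
    pairs_nm: PairsLike,
    pairs_ht: PairsLike,
    focal: str,
    partition: RegionPartition,
    genes: Optional[Sequence[GeneModel]] = None,
    focal_key: str = "gene_id",
    test: str = "fisher_2x2",
    alternative: str = "greater",
    pseudocount: float = 0.5,
    mt_chrom: str = DEFAULT_MT_CHROM,
) -> pd.DataFrame:
    """Per-promoter differential association of a focal RNA between conditions.

    ``focal`` selects pairs by ``gene_id`` or, with ``focal_key='rna_class'``,
    a whole RNA class. Promoters are enumerated from the partition's per-gene
    promoter footprint; counts are DNA-end midpoints falling in each gene's
    masked promoter segments.
    """
    fr_nm = _require_annotation(as_frame(pairs_nm), genes)
    fr_ht = _require_annotation(as_frame(pairs_ht), genes)

    def focal_nuc(frame: pd.DataFrame) -> pd.DataFrame:
        sel = frame[frame[focal_key] == focal]
        return sel[sel["dna_chrom"] != mt_chrom]

    f_nm, f_ht = focal_nuc(fr_nm), focal_nuc(fr_ht)
    if len(f_nm) == 0 or len(f_ht) == 0:
        raise ValueError(f"focal RNA {focal!r} has zero pairs in a condition")
    footprints = partition.promoter_footprints()
    promoter_genes = sorted(footprints)

    def counts(frame: pd.DataFrame) -> Dict[str, int]:
        out: Dict[str, int] = {g: 0 for g in promoter_genes}
        from .genome import GenomicInterval

        for r in frame.itertuples(index=False):
            iv = GenomicInterval(r.dna_chrom, int(r.dna_start), int(r.dna_end))
            gid = partition.promoter_gene(iv)
            if gid is not None:
                out[gid] += 1
        return out

    c_nm, c_ht = counts(f_nm), counts(f_ht)
    return diff_test_counts(
        [c_nm[g] for g in promoter_genes],
        [c_ht[g] for g in promoter_genes],
        n_nm=len(f_nm),
        n_ht=len(f_ht),
        gene_ids=promoter_genes,
        test=test,
        alternative=alternative,
        pseudocount=pseudocount,
    )


# ---------------------------------------------------------------------------
# gene-set enrichment
# ---------------------------------------------------------------------------


def gene_set_enrichment(
    set_gainers: Iterable[str],
    set_reduced: Iterable[str],
    universe: Iterable[str],
    correction: str = "none",
) -> EnrichmentResult:
    """Chi-square association between two gene sets within a universe.

    The 2x2 table is (gainers x reduced) membership; the odds ratio is
    ad/bc, with Haldane's 0.5 added to every cell iff any cell is zero
    (recorded in the result).
    """
    if correction not in ("none", "yates"):
        raise ValueError("correction must be 'none' or 'yates'")
    uni: Set[str] = set(universe)
    if len(uni) < 4:
        raise ValueError("universe must contain at least 4 genes")
    gain = set(set_gainers)
    red = set(set_reduced)
    if not gain <= uni or not red <= uni:
        raise ValueError("gene sets must be subsets of the universe")
    a = len(gain & red)
    b = len(gain - red)
    c = len(red - gain)
    d = len(uni) - a - b - c
    haldane = 0 in (a, b, c, d)
    if haldane:
        orat = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        orat = a * d / (b * c)
    table = np.array([[a, b], [c, d]])
    if table.sum() == 0:
        raise ValueError("empty table")
    if 0 in (a + b, c + d, a + c, b + d):
        # degenerate margin (one set empty or exhaustive): no association
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(
            table, correction=(correction == "yates")
        )
    return EnrichmentResult(a, b, c, d, float(orat), float(chi2), float(p),
                            len(uni), haldane)


# ---------------------------------------------------------------------------
# DEG tables
# ---------------------------------------------------------------------------

DEG_COLUMNS = ["gene", "log2FC", "pvalue", "padj"]


def read_deg_table(path: str, label: Optional[str] = None) -> pd.DataFrame:
    """Read an externally produced DEG table (TSV: gene, log2FC, pvalue, padj)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in DEG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: DEG table missing columns {missing}")
    if label is not None:
        df = df.assign(dataset=label)
    return df


def deg_direction(df: pd.DataFrame, direction: str = "down",
                  padj_threshold: float = 0.05) -> Set[str]:
    """Significant gene set of one direction from a DEG table."""
    if direction == "down":
        sel = (df["padj"] < padj_threshold) & (df["log2FC"] < 0)
    elif direction == "up":
        sel = (df["padj"] < padj_threshold) & (df["log2FC"] > 0)
    else:
        raise ValueError("direction must be 'up' or 'down'")
    return set(df.loc[sel, "gene"])


def deg_concordance(
    tables: Dict[str, pd.DataFrame],
    direction: str = "down",
    padj_threshold: float = 0.05,
    scc_genes: Optional[Iterable[str]] = None,
) -> Dict[str, object]:
    """Intersections of significant DEGs across tables plus fold-change SCC.

    Returns per-table counts, pairwise and k-way intersection sizes for the
    chosen direction, the k-way intersection gene list, and the pairwise
    Spearman correlation of log2 fold changes over ``scc_genes`` (default:
    genes shared by all tables), average-rank ties.
    """
    if len(tables) < 2:
        raise ValueError("need at least two DEG tables")
    sets = {
        lab: deg_direction(df, direction, padj_threshold)
        for lab, df in tables.items()
    }
    labels = sorted(tables)
    shared = set.intersection(*(set(tables[l]["gene"]) for l in labels))
    if not shared:
        raise ValueError("tables share no gene ids")
    kway = set.intersection(*(sets[l] for l in labels))
    pairwise_n = {}
    pairwise_scc = {}
    genes_for_scc = sorted(shared if scc_genes is None else set(scc_genes) & shared)
    for i, la in enumerate(labels):
        fa = tables[la].set_index("gene")["log2FC"]
        for lb in labels[i + 1:]:
            pairwise_n[(la, lb)] = len(sets[la] & sets[lb])
            fb = tables[lb].set_index("gene")["log2FC"]
            rho = stats.spearmanr(
                fa.loc[genes_for_scc], fb.loc[genes_for_scc]
            ).statistic
            pairwise_scc[(la, lb)] = float(rho)
    return {
        "per_table_n": {l: len(sets[l]) for l in labels},
        "pairwise_n": pairwise_n,
        "kway_n": len(kway),
        "kway_genes": sorted(kway),
        "pairwise_scc": pairwise_scc,
        "n_scc_genes": len(genes_for_scc),
    }
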