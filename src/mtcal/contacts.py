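"""Contact-pair I/O: 4DN ``.pairs`` dialect and BEDPE, plus pair categories.

One record is a chimeric RNA-end/DNA-end read pair from a proximity-ligation
RNA-genome mapping experiment. The RNA end tells which transcript was caught
on chromatin; the DNA end tells where. Coordinates are 1-based in the
``.pairs`` dialect and 0-based half-open in BEDPE and internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .genome import GeneIndex, GenomicInterval

logger = logging.getLogger("mtcal")

PAIR_COLUMNS = [
    "pair_id",
    "rna_chrom",
    "rna_start",
    "rna_end",
    "rna_strand",
    "dna_chrom",
    "dna_start",
    "dna_end",
    "dna_strand",
    "library_id",
    "condition",
    "rna_seq",
]

PAIR_CATEGORIES = ("nuRNA-nuDNA", "mtRNA-nuDNA", "mtRNA-mtDNA", "nuRNA-mtDNA")

MIN_RNA_SEQ_LEN = 15


@dataclass
class ContactPair:
    """One RNA-end/DNA-end chimeric read pair."""

    pair_id: str
    rna_locus: GenomicInterval
    dna_locus: GenomicInterval
    library_id: str = "lib"
    condition: str = ""
    rna_seq: Optional[str] = None

    def __post_init__(self) -> None:
        if self.rna_seq is not None:
            if len(self.rna_seq) < MIN_RNA_SEQ_LEN:
                raise ValueError(
                    f"{self.pair_id}: rna_seq shorter than {MIN_RNA_SEQ_LEN} nt"
                )
            if set(self.rna_seq) - set("ACGTN"):
                raise ValueError(f"{self.pair_id}: rna_seq not ACGTN")


@dataclass
class Library:
    """Per-library metadata with the pair total used for CPM normalisation."""

    library_id: str
    condition: str = ""
    total_pairs: int = 0
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.total_pairs < 0:
            raise ValueError("total_pairs must be >= 0")


PairsLike = Union[pd.DataFrame, Sequence[ContactPair]]


def pairs_to_frame(pairs: Iterable[ContactPair]) -> pd.DataFrame:
    rows = [
        (
            p.pair_id,
            p.rna_locus.chrom,
            p.rna_locus.start,
            p.rna_locus.end,
            p.rna_locus.strand,
            p.dna_locus.chrom,
            p.dna_locus.start,
            p.dna_locus.end,
            p.dna_locus.strand,
            p.library_id,
            p.condition,
            p.rna_seq,
        )
        for p in pairs
    ]
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def frame_to_pairs(frame: pd.DataFrame) -> List[ContactPair]:
    return [
        ContactPair(
            str(r.pair_id),
            GenomicInterval(r.rna_chrom, int(r.rna_start), int(r.rna_end), r.rna_strand),
            GenomicInterval(r.dna_chrom, int(r.dna_start), int(r.dna_end), r.dna_strand),
            str(r.library_id),
            str(r.condition),
            None if (r.rna_seq is None or (isinstance(r.rna_seq, float) and np.isnan(r.rna_seq))) else str(r.rna_seq),
        )
        for r in frame.itertuples(index=False)
    ]


def as_frame(pairs: PairsLike) -> pd.DataFrame:
    """Normalise either a DataFrame or a ContactPair sequence to a frame."""
    if isinstance(pairs, pd.DataFrame):
        missing = [c for c in PAIR_COLUMNS if c not in pairs.columns and c != "rna_seq"]
        if missing:
            raise ValueError(f"pair frame missing columns: {missing}")
        if "rna_seq" not in pairs.columns:
            pairs = pairs.assign(rna_seq=None)
        return pairs
    return pairs_to_frame(pairs)


def build_libraries(frame: pd.DataFrame, metadata: Optional[Dict[str, dict]] = None) -> List[Library]:
    """Library records (with totals) from a pair frame plus optional metadata."""
    out = []
    for lib_id, sub in frame.groupby("library_id", sort=True):
        meta = (metadata or {}).get(str(lib_id), {})
        conds = sub["condition"].unique()
        cond = meta.get("condition", conds[0] if len(conds) else "")
        out.append(
            Library(
                str(lib_id),
                str(cond),
                total_pairs=int(len(sub)),
                replicate=int(meta.get("replicate", 1)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_PAIRS_HEADER = "## pairs format v1.0"
_PAIRS_COLS = (
    "readID chr1 pos1 chr2 pos2 strand1 strand2 end1 end2 library condition rna_seq"
)


class MalformedPairsError(ValueError):
    pass


def _too_many_malformed(bad: List[int], total: int) -> bool:
    return total > 0 and len(bad) / total > 0.10


def read_pairs(
    path: str,
    dialect: str = "pairs_4dn",
    metadata: Optional[Dict[str, dict]] = None,
) -> Tuple[pd.DataFrame, List[Library]]:
    """Read contact pairs from a ``.pairs`` or BEDPE file.

    The RNA end is side 1 and the DNA end side 2, following the convention of
    RNA-genome proximity-ligation pipelines. ``.pairs`` positions (1-based)
    are converted to 0-based half-open internally. Lines that fail to parse
    are counted and logged; more than 10% malformed lines is an error naming
    the first ten offenders.

    Returns the pair frame plus per-library records with totals.
    """
    if dialect not in ("pairs_4dn", "bedpe"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rows: List[tuple] = []
    bad: List[int] = []
    chrom_sizes: Dict[str, int] = {}
    n_data = 0
    with open(path) as fh:
        first = True
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if dialect == "pairs_4dn":
                if first:
                    if not line.startswith("## pairs format"):
                        raise MalformedPairsError(
                            f"{path}: missing '## pairs format' header line"
                        )
                    first = False
                    continue
                if line.startswith("#"):
                    if line.startswith("#chromsize:"):
                        try:
                            _, chrom, size = line.split()
                            chrom_sizes[chrom] = int(size)
                        except ValueError:
                            bad.append(lineno)
                    continue
            if not line:
                continue
            n_data += 1
            f = line.split("\t")
            try:
                if dialect == "pairs_4dn":
                    pid, c1, p1, c2, p2, s1, s2 = f[:7]
                    e1 = int(f[7]) if len(f) > 7 and f[7] != "." else int(p1)
                    e2 = int(f[8]) if len(f) > 8 and f[8] != "." else int(p2)
                    lib = f[9] if len(f) > 9 else "lib"
                    cond = f[10] if len(f) > 10 else ""
                    seq = f[11] if len(f) > 11 and f[11] not in (".", "") else None
                    row = (pid, c1, int(p1) - 1, e1, s1, c2, int(p2) - 1, e2, s2, lib, cond, seq)
                else:
                    c1, st1, e1, c2, st2, e2 = f[0], int(f[1]), int(f[2]), f[3], int(f[4]), int(f[5])
                    pid = f[6] if len(f) > 6 else f"pair{n_data}"
                    s1 = f[8] if len(f) > 8 and f[8] in "+-." else "."
                    s2 = f[9] if len(f) > 9 and f[9] in "+-." else "."
                    lib = f[10] if len(f) > 10 else "lib"
                    cond = f[11] if len(f) > 11 else ""
                    seq = f[12] if len(f) > 12 and f[12] not in (".", "") else None
                    row = (pid, c1, st1, e1, s1, c2, st2, e2, s2, lib, cond, seq)
                if row[2] < 0 or row[3] <= row[2] or row[6] < 0 or row[7] <= row[6]:
                    raise ValueError("invalid coordinates")
            except (ValueError, IndexError):
                bad.append(lineno)
                continue
            rows.append(row)
    if _too_many_malformed(bad, n_data):
        raise MalformedPairsError(
            f"{path}: {len(bad)}/{n_data} malformed lines; first offenders at "
            f"lines {bad[:10]}"
        )
    if bad:
        logger.warning("%s: skipped %d malformed lines", path, len(bad))
    frame = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    if frame["pair_id"].duplicated().any():
        dups = frame.loc[frame["pair_id"].duplicated(), "pair_id"].head(5).tolist()
        raise ValueError(f"{path}: duplicate pair_ids (e.g. {dups})")
    if metadata:
        cond_map = {k: v.get("condition") for k, v in metadata.items() if "condition" in v}
        if cond_map:
            mapped = frame["library_id"].map(cond_map)
            frame["condition"] = mapped.where(mapped.notna(), frame["condition"])
    frame.attrs["chrom_sizes"] = chrom_sizes
    return frame, build_libraries(frame, metadata)


def write_pairs(pairs: PairsLike, path: str, dialect: str = "pairs_4dn",
                chrom_sizes: Optional[Dict[str, int]] = None) -> None:
    """Write pairs in the chosen dialect (lossless round-trip for both)."""
    if dialect not in ("pairs_4dn", "bedpe"):
        raise ValueError(f"unknown dialect {dialect!r}")
    frame = as_frame(pairs)
    with open(path, "w") as fh:
        if dialect == "pairs_4dn":
            fh.write(_PAIRS_HEADER + "\n")
            for chrom, size in (chrom_sizes or {}).items():
                fh.write(f"#chromsize: {chrom} {size}\n")
            fh.write(f"#columns: {_PAIRS_COLS}\n")
        for r in frame.itertuples(index=False):
            seq = r.rna_seq if isinstance(r.rna_seq, str) and r.rna_seq else "."
            if dialect == "pairs_4dn":
                fh.write(
                    f"{r.pair_id}\t{r.rna_chrom}\t{r.rna_start + 1}\t{r.dna_chrom}\t"
                    f"{r.dna_start + 1}\t{r.rna_strand}\t{r.dna_strand}\t"
                    f"{r.rna_end}\t{r.dna_end}\t{r.library_id}\t{r.condition}\t{seq}\n"
                )
            else:
                fh.write(
                    f"{r.rna_chrom}\t{r.rna_start}\t{r.rna_end}\t{r.dna_chrom}\t"
                    f"{r.dna_start}\t{r.dna_end}\t{r.pair_id}\t.\t{r.rna_strand}\t"
                    f"{r.dna_strand}\t{r.library_id}\t{r.condition}\t{seq}\n"
                )


# ---------------------------------------------------------------------------
# pair categories
# ---------------------------------------------------------------------------


def categorize_pairs(
    pairs: PairsLike,
    gene_index: GeneIndex,
    mt_chrom: str = "chrM",
    strand_aware: bool = True,
) -> Tuple[Dict[str, int], pd.DataFrame]:
    """Count pairs in the four RNA/DNA origin categories.

    Pairs whose RNA end is not assignable to any gene are excluded, so the
    four counts sum to the number of gene-assigned pairs. Also returns
    per-library counts normalised to pairs per million library pairs.
    """
    frame = as_frame(pairs)
    counts = {c: 0 for c in PAIR_CATEGORIES}
    if len(frame) == 0:
        return counts, pd.DataFrame(
            columns=["library_id", "category", "n", "per_million"]
        )
    gene = gene_index.assign_frame(
        frame["rna_chrom"], frame["rna_start"], frame["rna_end"],
        frame["rna_strand"], strand_aware=strand_aware,
    )
    assigned = pd.Series(gene, index=frame.index).notna()
    rna_mt = frame["rna_chrom"].eq(mt_chrom)
    dna_mt = frame["dna_chrom"].eq(mt_chrom)
    cat = pd.Series("nuRNA-nuDNA", index=frame.index, dtype=object)
    cat[rna_mt & ~dna_mt] = "mtRNA-nuDNA"
    cat[rna_mt & dna_mt] = "mtRNA-mtDNA"
    cat[~rna_mt & dna_mt] = "nuRNA-mtDNA"
    sub = frame.loc[assigned].assign(category=cat[assigned])
    for c, n in sub["category"].value_counts().items():
        counts[c] = int(n)
    lib_totals = frame.groupby("library_id").size()
    per_lib = (
        sub.groupby(["library_id", "category"]).size().rename("n").reset_index()
    )
    per_lib["per_million"] = [
        1e6 * n / lib_totals[lib]
        for lib, n in zip(per_lib["library_id"], per_lib["n"])
    ]
    return counts, per_lib


def write_tsv(df: pd.DataFrame, path: str, meta: Optional[Dict[str, str]] = None) -> None:
    """Write a result table as TSV with a commented provenance header."""
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# mtcal v{__version__}\n")
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
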