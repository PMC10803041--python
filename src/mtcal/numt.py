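"""NUMT disambiguation for mtRNA-mapped RNA-end reads.

Nuclear insertions of mitochondrial DNA (NUMTs) can spuriously absorb or emit
reads that look mitochondrial. A read is accepted as genuinely mitochondrial
(``mt_confident``) when its best gapless alignment against every NUMT, in
both orientations, leaves strictly more than ``threshold`` base mismatches
(default 5). Candidate placements are found by exact k-mer seeding and each
is scored as an end-to-end Hamming comparison of the read against the NUMT
window; ``N`` always counts as a mismatch. Reads sharing no seed k-mer with
any NUMT are called confident (nothing in the database resembles them),
which is distinct from ``unevaluable`` (no read sequence available).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .genome import GenomicInterval

DEFAULT_THRESHOLD = 5
DEFAULT_SEED_K = 12

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


_N = ord("N")


def _hamming(a: np.ndarray, b: np.ndarray) -> int:
    """Mismatch count; N mismatches everything, including another N."""
    return int(((a != b) | (a == _N) | (b == _N)).sum())


@dataclass
class NumtRecord:
    """One nuclear mitochondrial-insertion sequence."""

    numt_id: str
    sequence: str
    source: Optional[GenomicInterval] = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 50:
            raise ValueError(f"{self.numt_id}: NUMT sequence shorter than 50 nt")
        if set(self.sequence) - set("ACGTN"):
            raise ValueError(f"{self.numt_id}: sequence not ACGTN")


@dataclass
class NumtCall:
    """Verdict for one mtRNA-mapped pair."""

    pair_id: str
    verdict: str  # mt_confident | numt_ambiguous | unevaluable
    min_mismatches: Optional[int] = None
    best_numt_id: Optional[str] = None


class NumtIndex:
    """Exact k-mer seed index over a NUMT database, both orientations."""

    def __init__(self, numts: Iterable[NumtRecord], seed_k: int = DEFAULT_SEED_K):
        self.numts = list(numts)
        if not self.numts:
            raise ValueError("empty NUMT database")
        if seed_k < 4:
            raise ValueError("seed_k must be >= 4")
        self.seed_k = seed_k
        self._arrays: List[Tuple[str, np.ndarray]] = []
        self._kmers: Dict[str, List[Tuple[int, int]]] = {}
        for rec in self.numts:
            for oriented in (rec.sequence, revcomp(rec.sequence)):
                ai = len(self._arrays)
                self._arrays.append((rec.numt_id, _encode(oriented)))
                for pos in range(len(oriented) - seed_k + 1):
                    kmer = oriented[pos : pos + seed_k]
                    if "N" in kmer:
                        continue
                    self._kmers.setdefault(kmer, []).append((ai, pos))

    def min_mismatches(self, read: str) -> Optional[Tuple[int, str]]:
        """Best (minimum) end-to-end mismatch count over all seeded placements.

        Returns None when no seed k-mer of the read occurs in any NUMT.
        """
        read = read.upper()
        k = self.seed_k
        if len(read) < k:
            raise ValueError(f"read shorter than seed_k={k}")
        arr = _encode(read)
        L = len(arr)
        seen: set = set()
        best: Optional[Tuple[int, str]] = None
        for i in range(L - k + 1):
            kmer = read[i : i + k]
            for ai, pos in self._kmers.get(kmer, ()):
                start = pos - i
                key = (ai, start)
                if key in seen:
                    continue
                seen.add(key)
                numt_id, numt_arr = self._arrays[ai]
                if start < 0 or start + L > len(numt_arr):
                    continue  # read window falls off the NUMT: not a full placement
                mm = _hamming(arr, numt_arr[start : start + L])
                if best is None or (mm, numt_id) < best:
                    best = (mm, numt_id)
                    if mm == 0:
                        return best
        return best


def min_mismatches_to_numts(
    read: str,
    numts: Iterable[NumtRecord],
    seed_k: int = DEFAULT_SEED_K,
) -> Optional[Tuple[int, str]]:
    """Minimum Hamming distance of ``read`` to any full NUMT window.

    Convenience wrapper building a throwaway :class:`NumtIndex`; use the
    index directly when classifying many reads.
    """
    return NumtIndex(numts, seed_k=seed_k).min_mismatches(read)


def min_mismatches_bruteforce(
    read: str, numts: Iterable[NumtRecord]
) -> Optional[Tuple[int, str]]:
    """Exhaustive sliding-window Hamming scan (reference implementation).

    Scores every placement of the read against every NUMT in both
    orientations, with no seeding; used to validate the seeded search.
    """
    read = read.upper()
    arr = _encode(read)
    L = len(arr)
    best: Optional[Tuple[int, str]] = None
    for rec in numts:
        for oriented in (rec.sequence, revcomp(rec.sequence)):
            enc = _encode(oriented)
            if len(enc) < L:
                continue
            wins = np.lib.stride_tricks.sliding_window_view(enc, L)
            mism = ((wins != arr) | (wins == _N) | (arr == _N)).sum(axis=1)
            mm = int(mism.min())
            if best is None or (mm, rec.numt_id) < best:
                best = (mm, rec.numt_id)
    return best


def classify_pairs(
    pairs,
    numts: Iterable[NumtRecord],
    threshold: int = DEFAULT_THRESHOLD,
    seed_k: int = DEFAULT_SEED_K,
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Classify mtRNA-mapped pairs as mitochondrial vs possibly NUMT-derived.

    Parameters
    ----------
    pairs
        Pair frame or ContactPair sequence; only ``pair_id`` and ``rna_seq``
        are used. Pairs without a sequence are ``unevaluable``.
    threshold
        A read is ``mt_confident`` iff its minimum mismatch count is strictly
        greater than this (or it has no seed hit at all).

    Returns
    -------
    calls, summary
        One row per pair (pair_id, verdict, min_mismatches, best_numt_id) and
        a summary with ``fraction_confident`` over evaluable pairs.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if isinstance(pairs, pd.DataFrame) and {"pair_id", "rna_seq"} <= set(pairs.columns):
        frame = pairs
    else:
        from .contacts import as_frame

        frame = as_frame(pairs)
    index = NumtIndex(numts, seed_k=seed_k)
    has_seq = frame["rna_seq"].map(lambda s: isinstance(s, str) and len(s) > 0)
    if not has_seq.any():
        raise ValueError("all pairs lack rna_seq; nothing to classify")
    rows = []
    n_conf = 0
    n_eval = 0
    for pid, seq in zip(frame["pair_id"], frame["rna_seq"]):
        if not (isinstance(seq, str) and seq):
            rows.append((pid, "unevaluable", None, None))
            continue
        hit = index.min_mismatches(seq)
        n_eval += 1
        if hit is None:
            n_conf += 1
            rows.append((pid, "mt_confident", None, None))
        else:
            mm, nid = hit
            verdict = "mt_confident" if mm > threshold else "numt_ambiguous"
            n_conf += verdict == "mt_confident"
            rows.append((pid, verdict, mm, nid))
    calls = pd.DataFrame(
        rows, columns=["pair_id", "verdict", "min_mismatches", "best_numt_id"]
    )
    summary = {
        "n_evaluable": float(n_eval),
        "n_confident": float(n_conf),
        "fraction_confident": n_conf / n_eval if n_eval else float("nan"),
    }
    return calls, summary


# ---------------------------------------------------------------------------
# database I/O
# ---------------------------------------------------------------------------


def read_numts_fasta(path: str) -> List[NumtRecord]:
    from Bio import SeqIO

    return [
        NumtRecord(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")
    ]


def write_numts_fasta(numts: Iterable[NumtRecord], path: str) -> None:
    with open(path, "w") as fh:
        for rec in numts:
            fh.write(f">{rec.numt_id}\n")
            for i in range(0, len(rec.sequence), 80):
                fh.write(rec.sequence[i : i + 80] + "\n")


def numts_from_bed(bed_path: str, genome_fasta: str) -> List[NumtRecord]:
    """Extract NUMT sequences from BED placements plus a genome FASTA."""
    from Bio import SeqIO

    from .genome import read_bed

    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(genome_fasta, "fasta")}
    out = []
    for i, iv in enumerate(read_bed(bed_path)):
        if iv.chrom not in genome:
            raise KeyError(f"{bed_path}: chromosome {iv.chrom!r} not in genome")
        seq = genome[iv.chrom][iv.start : iv.end]
        if iv.strand == "-":
            seq = revcomp(seq)
        out.append(NumtRecord(f"numt{i + 1}_{iv.chrom}_{iv.start}", seq, iv))
    return out


def write_calls_tsv(calls: pd.DataFrame, path: str, meta=None) -> None:
    from .contacts import write_tsv

    write_tsv(calls, path, meta)
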