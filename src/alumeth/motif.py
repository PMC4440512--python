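"""Flanking-sequence motifs and target-site-duplication detection.

Alu elements insert by L1-machinery target-primed reverse transcription,
which nicks at an A-rich consensus (typically TTAAAA) and duplicates a
short target sequence (4-25 bp) at both ends of the new copy.  This
module extracts the +/-20 bp flanks of annotated elements, summarises
them as position probability matrices with per-column information
content (sequence-logo statistics, R = 2 - H bits), ranks bases at a
position, and detects exact target site duplications (TSDs) in flank
pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .formats import GenomeSequence, RepeatAnnotation, reverse_complement

BASES = ("A", "C", "G", "T")


@dataclass
class FlankPair:
    """Element flanks in element orientation (left = upstream of the 5' end)."""

    element_id: str
    left: str
    right: str


def extract_flanks(elements: Sequence[RepeatAnnotation],
                   genome: GenomeSequence,
                   flank: int = 20) -> tuple[list[FlankPair], int]:
    """Per-element (left, right) flank sequences, orientation-normalised.

    For a plus-strand element the left flank is [start-flank, start) and
    the right flank [end, end+flank).  Minus-strand elements have both
    flanks reverse-complemented and swapped, so "left" is always upstream
    in element orientation.  Elements whose flanks would run off the
    chromosome are skipped; the skip count is returned.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    pairs: list[FlankPair] = []
    skipped = 0
    for i, el in enumerate(elements):
        if el.start - flank < 0 or el.end + flank > genome.length(el.chrom):
            skipped += 1
            continue
        left = genome.fetch(el.chrom, el.start - flank, el.start)
        right = genome.fetch(el.chrom, el.end, el.end + flank)
        if el.strand == "-":
            left, right = reverse_complement(right), reverse_complement(left)
        pairs.append(FlankPair(element_id=f"{el.chrom}:{el.start}-{el.end}",
                               left=left, right=right))
    return pairs, skipped


@dataclass
class MotifMatrix:
    """Per-position base counts, probabilities and information content."""

    counts: np.ndarray        # shape (L, 4), ordered A,C,G,T; N excluded
    n_sequences: int

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    @property
    def probabilities(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            return np.where(totals > 0, self.counts / totals, np.nan)

    @property
    def information_bits(self) -> np.ndarray:
        """Per-column information content R = 2 - H, in [0, 2] bits."""
        p = self.probabilities
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log2(p), 0.0)
        h = -np.nansum(terms, axis=1)
        return 2.0 - h


def build_matrix(sequences: Sequence[str]) -> MotifMatrix:
    """Position probability matrix of equal-length sequences.

    N bases are excluded per column (not per sequence); probabilities at
    each position are counts over the non-N observations.  Order of the
    input sequences is irrelevant.
    """
    if not sequences:
        raise ValueError("no sequences")
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("sequences must have equal length")
    counts = np.zeros((length, 4), dtype=float)
    index = {b: i for i, b in enumerate(BASES)}
    for seq in sequences:
        for pos, base in enumerate(seq.upper()):
            i = index.get(base)
            if i is not None:
                counts[pos, i] += 1
    return MotifMatrix(counts=counts, n_sequences=len(sequences))


def rank_position(matrix: MotifMatrix, position: int) -> list[str]:
    """Bases at a position ordered by probability, descending.

    Ties are broken alphabetically, so the order is deterministic.
    """
    p = matrix.probabilities[position]
    return [b for b in sorted(BASES, key=lambda b: (-p[BASES.index(b)], b))]


@dataclass(frozen=True)
class TSDCall:
    element_id: str
    sequence: str
    length: int


def detect_tsd(left: str, right: str, min_len: int = 4, max_len: int = 25,
               element_id: str = "") -> Optional[TSDCall]:
    """Longest exact duplication bridging the element.

    Returns the longest s with min_len <= |s| <= max_len such that the
    left flank ends with s and the right flank begins with s; None when
    no such s exists.  Matching is exact and case-insensitive.
    """
    left, right = left.upper(), right.upper()
    top = min(max_len, len(left), len(right))
    for k in range(top, min_len - 1, -1):
        if left[-k:] == right[:k]:
            return TSDCall(element_id=element_id, sequence=left[-k:], length=k)
    return None


def write_matrix_tsv(matrix: MotifMatrix, path) -> None:
    p = matrix.probabilities
    info = matrix.information_bits
    with open(path, "w") as handle:
        handle.write("position\t" +
                     "\t".join(f"count_{b}" for b in BASES) + "\t" +
                     "\t".join(f"p_{b}" for b in BASES) + "\tinfo_bits\n")
        for i in range(matrix.length):
            counts = "\t".join(f"{int(c)}" for c in matrix.counts[i])
            probs = "\t".join(f"{x:.6f}" for x in p[i])
            handle.write(f"{i + 1}\t{counts}\t{probs}\t{info[i]:.6f}\n")
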