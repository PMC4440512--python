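"""Alu subfamily classification, repeat composition and enrichment tests.

Alu elements are ~300 bp primate SINE retrotransposons; subfamilies J, S
and Y form an age series with Alu Y the youngest and the only one still
retrotranspositionally active.  The questions asked here are: what
fraction of a set of fragments or cytosine loci falls in Alu elements,
how the Alu portion splits across subfamilies, and whether an observed
Alu Y count is enriched relative to an in-silico expectation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .digestion import Fragment
from .formats import RepeatAnnotation


class AluClass(enum.Enum):
    ALU_Y = "AluY"
    ALU_S = "AluS"
    ALU_J = "AluJ"
    ALU_OTHER = "AluOther"
    NON_ALU = "NonAlu"


SUBFAMILIES = (AluClass.ALU_Y, AluClass.ALU_S, AluClass.ALU_J,
               AluClass.ALU_OTHER)


def classify_subfamily(rep_name: str, rep_family: str) -> AluClass:
    """Map a RepeatMasker name/family pair onto an Alu subfamily class.

    Anything outside family "Alu" is NonAlu; within it, the name prefix
    decides: AluY*/AluS*/AluJ* map to the three named subfamilies and
    everything else (FLAM/FRAM-like relics) is AluOther, never folded into
    Y/S/J.
    """
    if not rep_name:
        raise ValueError("empty repeat name")
    if rep_family != "Alu":
        return AluClass.NON_ALU
    for prefix, cls in (("AluY", AluClass.ALU_Y), ("AluS", AluClass.ALU_S),
                        ("AluJ", AluClass.ALU_J)):
        if rep_name.startswith(prefix):
            return cls
    return AluClass.ALU_OTHER


class RepeatIndex:
    """Interval index over repeat annotations for fast overlap queries."""

    def __init__(self, repeats: Iterable[RepeatAnnotation],
                 alu_only: bool = False):
        self._best_cache: dict[tuple, Optional[tuple]] = {}
        self._trees: dict[str, IntervalTree] = {}
        for rep in repeats:
            cls = classify_subfamily(rep.rep_name, rep.rep_family)
            if alu_only and cls is AluClass.NON_ALU:
                continue
            self._trees.setdefault(rep.chrom, IntervalTree()).addi(
                rep.start, rep.end, (rep, cls))

    def overlapping(self, chrom: str, start: int,
                    end: int) -> list[tuple[RepeatAnnotation, AluClass]]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]

    def best_alu(self, chrom: str, start: int, end: int,
                 min_overlap: int = 1) -> Optional[tuple[RepeatAnnotation, AluClass]]:
        """The Alu annotation with the largest overlap with [start, end).

        Ties go to the leftmost annotation; returns None when no Alu
        annotation overlaps by at least ``min_overlap`` bp.  Results are
        memoised: digest fragments recur across millions of reads.
        """
        cache_key = (chrom, start, end, min_overlap)
        if cache_key in self._best_cache:
            return self._best_cache[cache_key]
        best = None
        best_key = None
        for rep, cls in self.overlapping(chrom, start, end):
            if cls is AluClass.NON_ALU:
                continue
            overlap = min(end, rep.end) - max(start, rep.start)
            if overlap < min_overlap:
                continue
            key = (-overlap, rep.start, rep.end)
            if best_key is None or key < best_key:
                best, best_key = (rep, cls), key
        self._best_cache[cache_key] = best
        return best


@dataclass
class CompositionSummary:
    """Alu composition of a set of items (fragments or point loci)."""

    n_items: int
    n_alu: int
    subfamily_counts: dict[AluClass, int]
    label: str = ""

    @property
    def fraction_alu(self) -> Optional[float]:
        if self.n_items == 0:
            return None
        return self.n_alu / self.n_items

    @property
    def subfamily_fractions(self) -> dict[AluClass, Optional[float]]:
        """Per-subfamily fractions among the Alu-assigned items."""
        if self.n_alu == 0:
            return {cls: None for cls in SUBFAMILIES}
        return {cls: self.subfamily_counts.get(cls, 0) / self.n_alu
                for cls in SUBFAMILIES}


Item = Union[Fragment, tuple]  # fragment, or (chrom, pos[, ...]) point locus


def _item_interval(item: Item) -> tuple[str, int, int]:
    if isinstance(item, Fragment):
        return item.chrom, item.start, item.end
    chrom, pos = item[0], item[1]
    return chrom, pos, pos + 1  # point locus: containment test


def composition(items: Sequence[Item],
                repeats: Union[RepeatIndex, Iterable[RepeatAnnotation]],
                min_overlap: int = 1, label: str = "") -> CompositionSummary:
    """Alu composition of fragments or point loci.

    An item is Alu-assigned iff it overlaps an Alu annotation by at least
    ``min_overlap`` bp (point loci use containment); among multiple Alu
    hits the largest overlap wins, ties to the leftmost annotation.
    Assignment is invariant under input order.
    """
    index = repeats if isinstance(repeats, RepeatIndex) else RepeatIndex(repeats)
    counts: dict[AluClass, int] = {cls: 0 for cls in SUBFAMILIES}
    n_alu = 0
    n_items = 0
    for item in items:
        n_items += 1
        chrom, start, end = _item_interval(item)
        hit = index.best_alu(chrom, start, end, min_overlap=min_overlap)
        if hit is not None:
            n_alu += 1
            counts[hit[1]] += 1
    return CompositionSummary(n_items=n_items, n_alu=n_alu,
                              subfamily_counts=counts, label=label)


def enrichment_test(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value for a 2x2 contingency table.

    The two-sided p sums the probabilities of all tables with the same
    margins whose hypergeometric probability does not exceed the observed
    table's (with a small relative tolerance for floating-point ties).
    """
    (a, b), (c, d) = table
    for cell in (a, b, c, d):
        if cell < 0:
            raise ValueError("negative contingency cell")
    if a + b + c + d == 0:
        raise ValueError("all-zero contingency table")
    return float(stats.fisher_exact([[a, b], [c, d]],
                                    alternative="two-sided")[1])


@dataclass
class SweepVariance:
    """Spread of composition fractions across size-selection windows."""

    minimum: float
    maximum: float
    range: float
    variance: float  # sample variance (ddof=1)
    variance_ratio: Optional[float] = None  # other-collection / windows


def _fraction_series(summaries: Sequence[CompositionSummary],
                     which: str) -> np.ndarray:
    vals = []
    for s in summaries:
        if which == "alu":
            v = s.fraction_alu
        else:
            v = s.subfamily_fractions[AluClass.ALU_Y]
        if v is None:
            raise ValueError("undefined fraction in sweep input")
        vals.append(v)
    return np.asarray(vals, dtype=float)


def sweep_variance(summaries: Sequence[CompositionSummary],
                   which: str = "alu",
                   other: Optional[Sequence[CompositionSummary]] = None,
                   ) -> SweepVariance:
    """Min/max/range and sample variance of a composition fraction across
    windows; optionally the ratio of a second collection's variance (for
    example per-sample observed fractions) to the across-window variance."""
    if len(summaries) < 2:
        raise ValueError("need at least 2 summaries")
    vals = _fraction_series(summaries, which)
    var = float(np.var(vals, ddof=1))
    ratio = None
    if other is not None:
        if len(other) < 2:
            raise ValueError("need at least 2 summaries in comparison set")
        other_var = float(np.var(_fraction_series(other, which), ddof=1))
        ratio = other_var / var if var > 0 else float("inf")
    return SweepVariance(minimum=float(vals.min()), maximum=float(vals.max()),
                         range=float(vals.max() - vals.min()), variance=var,
                         variance_ratio=ratio)


def loci_fragment_overlap(loci: Iterable[tuple], fragments: Sequence[Fragment]
                          ) -> tuple[float, list[tuple], list[tuple]]:
    """Partition loci by whether their position lies inside any fragment.

    Returns (overlapping fraction, overlapping loci, non-overlapping
    loci); the partition is exact and disjoint, so the two subsets sum to
    the input.
    """
    trees: dict[str, IntervalTree] = {}
    for f in fragments:
        trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end)
    inside: list[tuple] = []
    outside: list[tuple] = []
    for locus in loci:
        chrom, pos = locus[0], locus[1]
        tree = trees.get(chrom)
        if tree is not None and tree.overlaps_point(pos):
            inside.append(locus)
        else:
            outside.append(locus)
    total = len(inside) + len(outside)
    fraction = len(inside) / total if total else 0.0
    return fraction, inside, outside
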