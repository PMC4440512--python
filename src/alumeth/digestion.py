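"""In-silico restriction digestion and gel size selection.

MspI recognises CCGG and cuts C^CGG, i.e. one base into the site, leaving
CG overhangs; it is insensitive to CpG methylation, which is what makes it
the RRBS workhorse.  A digested chromosome yields interior fragments — the
intervals between consecutive cut positions.  Chromosome-terminal
stretches carry only one MspI end and are excluded by default, because
RRBS library molecules need an MspI end on both sides.

Fragment sizes refer to the genomic insert, not the adaptor-ligated
library molecule.  Size selection keeps fragments whose length falls in an
inclusive window; a sweep produces the slid and extended windows used to
probe how sensitive a composition estimate is to the exact gel cut.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from .formats import GenomeSequence

_ALPHABET = set("ACGT")


@dataclass(frozen=True)
class Fragment:
    """An inter-cut-site interval (0-based, half-open)."""

    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SizeWindow:
    """An inclusive fragment-length selection window [min_len, max_len]."""

    min_len: int
    max_len: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.min_len <= self.max_len):
            raise ValueError(
                f"invalid size window [{self.min_len},{self.max_len}]"
            )

    def contains(self, length: int) -> bool:
        return self.min_len <= length <= self.max_len


def find_cut_positions(sequence: str, site: str = "CCGG",
                       cut_offset: int = 1) -> list[int]:
    """Cut positions (occurrence start + offset) of every exact match.

    Overlapping occurrences each produce a cut.  Occurrences containing N
    never match because matching is exact over {A,C,G,T}.
    """
    site = site.upper()
    if not site or set(site) - _ALPHABET:
        raise ValueError(f"invalid recognition site {site!r}")
    if not 0 <= cut_offset <= len(site):
        raise ValueError(f"cut offset {cut_offset} outside site of length {len(site)}")
    cuts = []
    start = sequence.find(site)
    while start != -1:
        cuts.append(start + cut_offset)
        start = sequence.find(site, start + 1)  # step 1: overlapping hits count
    return cuts


def digest(genome: GenomeSequence, site: str = "CCGG", cut_offset: int = 1,
           include_terminal: bool = False) -> list[Fragment]:
    """Digest every chromosome, returning interior fragments in order.

    With ``include_terminal`` the stretches before the first and after the
    last cut are appended as fragments too (single-MspI-end molecules).
    """
    fragments: list[Fragment] = []
    for chrom in genome.names():
        seq = genome[chrom]
        cuts = find_cut_positions(seq, site, cut_offset)
        if include_terminal and cuts:
            if cuts[0] > 0:
                fragments.append(Fragment(chrom, 0, cuts[0]))
        for left, right in zip(cuts, cuts[1:]):
            if right > left:
                fragments.append(Fragment(chrom, left, right))
        if include_terminal and cuts:
            if cuts[-1] < len(seq):
                fragments.append(Fragment(chrom, cuts[-1], len(seq)))
    return fragments


def size_select(fragments: Iterable[Fragment],
                window: SizeWindow) -> list[Fragment]:
    """Keep fragments with min_len <= length <= max_len, order preserved."""
    return [f for f in fragments if window.contains(f.length)]


def window_sweep(base: SizeWindow, slide_step: int = 50, n_slides: int = 1,
                 extension: int = 50) -> list[SizeWindow]:
    """Base window plus slid and extended variants.

    Slid windows shift both bounds by +/- k*slide_step (k = 1..n_slides),
    clipping min_len at 1; the two extended windows widen the base by
    ``extension`` bp towards smaller and towards larger sizes.  Labels
    record the construction.
    """
    if slide_step <= 0:
        raise ValueError("slide_step must be positive")
    windows = [SizeWindow(base.min_len, base.max_len,
                          label=base.label or "base")]
    for k in range(1, n_slides + 1):
        delta = k * slide_step
        windows.append(SizeWindow(
            max(1, base.min_len - delta), max(1, base.max_len - delta),
            label=f"slide-{delta}"))
        windows.append(SizeWindow(
            base.min_len + delta, base.max_len + delta,
            label=f"slide+{delta}"))
    if extension > 0:
        windows.append(SizeWindow(
            max(1, base.min_len - extension), base.max_len,
            label=f"extend-down{extension}"))
        windows.append(SizeWindow(
            base.min_len, base.max_len + extension,
            label=f"extend-up{extension}"))
    return windows


def write_fragments_bed(fragments: Iterable[Fragment], path) -> None:
    """Fragments as BED with the length in the score column."""
    with open(path, "w") as handle:
        for i, f in enumerate(fragments):
            handle.write(
                f"{f.chrom}\t{f.start}\t{f.end}\tfrag{i}\t{f.length}\t+\n"
            )
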