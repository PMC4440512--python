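"""File formats and core genomic record types.

All coordinates held in memory are 0-based, half-open.  Conversion to and
from 1-based file dialects (the Bismark cytosine report) happens exactly
once, at the file boundary.  Output tables are TSV with a header line;
lines starting with ``#`` carry provenance comments and are skipped on
input.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_CONTEXTS = ("CpG", "CHG", "CHH")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised for malformed input files; carries the offending line number."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeSequence:
    """Named chromosome sequences over {A,C,G,T,N}, stored upper-case."""

    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        upper = {}
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} has an empty sequence")
            upper[name] = seq.upper()
        self.sequences = upper

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def names(self) -> list[str]:
        return list(self.sequences)

    def length(self, name: str) -> int:
        return len(self.sequences[name])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of [start, end); raises if out of bounds."""
        seq = self.sequences[chrom]
        if start < 0 or end > len(seq) or start > end:
            raise IndexError(
                f"window [{start},{end}) out of bounds for {chrom} "
                f"(length {len(seq)})"
            )
        return seq[start:end]


@dataclass(frozen=True)
class RepeatAnnotation:
    """A RepeatMasker-style repeat interval (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    strand: str
    rep_name: str
    rep_family: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid repeat interval [{self.start},{self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class CytosineRecord:
    """One cytosine from a per-sample methylation call file.

    ``level`` is ``n_meth / (n_meth + n_unmeth)`` and is ``None`` when the
    locus is uncovered (total count zero).
    """

    chrom: str
    pos: int  # 0-based
    strand: str
    context: str
    n_meth: int
    n_unmeth: int

    def __post_init__(self) -> None:
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ValueError("negative methylation counts")
        if self.context not in VALID_CONTEXTS:
            raise ValueError(f"invalid context {self.context!r}")

    @property
    def total(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def covered(self) -> bool:
        return self.total > 0

    @property
    def level(self) -> Optional[float]:
        if self.total == 0:
            return None
        return self.n_meth / self.total


@dataclass
class MethylomeSample:
    """A sample's cytosine records, keyed by (chrom, pos, strand)."""

    sample_id: str
    records: list[CytosineRecord] = field(default_factory=list)

    def __iter__(self) -> Iterator[CytosineRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class ReadInterval:
    """A mapped-read interval with uniqueness and 5'-cut-site flags."""

    chrom: str
    start: int
    end: int
    sample_id: str
    unique_flag: bool
    site_at_5prime_flag: bool

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"invalid read interval [{self.start},{self.end})")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence`.

    Chromosome names are the first whitespace-delimited token of each
    header; sequences are upper-cased.  Duplicate names or empty records
    are format errors.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if name in sequences:
            raise FormatError(f"duplicate chromosome name {name!r} in {path}")
        seq = str(record.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for {name!r} in {path}")
        sequences[name] = seq
    if not sequences:
        raise FormatError(f"no FASTA records in {path}")
    return GenomeSequence(sequences)


def write_fasta(genome: GenomeSequence, path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.sequences.items()
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Repeat annotations

_RMSK_COLUMNS = ("genoName", "genoStart", "genoEnd", "strand", "repName",
                 "repClass", "repFamily")


def read_repeat_table(
    path,
    dialect: str = "rmsk",
    genome: Optional[GenomeSequence] = None,
    on_unknown_chrom: str = "error",
) -> list[RepeatAnnotation]:
    """Read repeat annotations.

    ``dialect="rmsk"``: UCSC rmsk column layout (genoName, genoStart
    0-based, genoEnd, strand, repName, repClass, repFamily).
    ``dialect="bed"``: BED6 whose name field is ``repName|repFamily``.

    When a genome is supplied, intervals on unknown chromosomes or beyond
    the chromosome end are an error by default (``on_unknown_chrom="skip"``
    downgrades the unknown-chromosome case to a silent skip; coordinate
    overflow is always an error).
    """
    if dialect not in ("rmsk", "bed"):
        raise ValueError(f"unknown repeat table dialect {dialect!r}")
    out: list[RepeatAnnotation] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "rmsk":
                    chrom, start, end, strand, rep_name = fields[:5]
                    rep_family = fields[6] if len(fields) > 6 else fields[5]
                else:
                    chrom, start, end, name, _score, strand = fields[:6]
                    rep_name, _, rep_family = name.partition("|")
                ann = RepeatAnnotation(
                    chrom=chrom, start=int(start), end=int(end),
                    strand=strand, rep_name=rep_name, rep_family=rep_family,
                )
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if genome is not None:
                if ann.chrom not in genome:
                    if on_unknown_chrom == "skip":
                        continue
                    raise FormatError(
                        f"{path}:{lineno}: unknown chromosome {ann.chrom!r}"
                    )
                if ann.end > genome.length(ann.chrom):
                    raise FormatError(
                        f"{path}:{lineno}: interval end {ann.end} beyond "
                        f"{ann.chrom} length {genome.length(ann.chrom)}"
                    )
            out.append(ann)
    return out


def write_repeat_table(repeats: Iterable[RepeatAnnotation], path,
                       dialect: str = "rmsk") -> None:
    with open(path, "w") as handle:
        if dialect == "rmsk":
            handle.write("#" + "\t".join(_RMSK_COLUMNS) + "\n")
            for r in repeats:
                rep_class = "SINE" if r.rep_family == "Alu" else r.rep_family
                handle.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{r.strand}\t"
                    f"{r.rep_name}\t{rep_class}\t{r.rep_family}\n"
                )
        elif dialect == "bed":
            for r in repeats:
                handle.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t"
                    f"{r.rep_name}|{r.rep_family}\t0\t{r.strand}\n"
                )
        else:
            raise ValueError(f"unknown repeat table dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Bismark-style cytosine reports

def read_cytosine_report(path, sample_id: Optional[str] = None,
                         genome: Optional[GenomeSequence] = None,
                         on_unknown_chrom: str = "error") -> MethylomeSample:
    """Read a Bismark CX-style cytosine report.

    Columns: chrom, pos (1-based in file), strand, count methylated,
    count unmethylated, context, trinucleotide.  Positions are converted
    to 0-based; uncovered records (total 0) are retained.
    """
    if sample_id is None:
        sample_id = str(path)
    records: list[CytosineRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                chrom, pos1, strand, n_meth, n_unmeth, context = fields[:6]
                rec = CytosineRecord(
                    chrom=chrom, pos=int(pos1) - 1, strand=strand,
                    context=context, n_meth=int(n_meth),
                    n_unmeth=int(n_unmeth),
                )
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if genome is not None and rec.chrom not in genome:
                if on_unknown_chrom == "skip":
                    continue
                raise FormatError(
                    f"{path}:{lineno}: unknown chromosome {rec.chrom!r}"
                )
            records.append(rec)
    return MethylomeSample(sample_id=sample_id, records=records)


def write_cytosine_report(sample: MethylomeSample, path,
                          genome: Optional[GenomeSequence] = None) -> None:
    """Write a Bismark CX-style report (positions 1-based on disk)."""
    with open(path, "w") as handle:
        for rec in sample.records:
            tri = ""
            if genome is not None and rec.chrom in genome:
                tri = _trinucleotide(genome, rec.chrom, rec.pos, rec.strand)
            handle.write(
                f"{rec.chrom}\t{rec.pos + 1}\t{rec.strand}\t{rec.n_meth}\t"
                f"{rec.n_unmeth}\t{rec.context}\t{tri}\n"
            )


def _trinucleotide(genome: GenomeSequence, chrom: str, pos: int,
                   strand: str) -> str:
    seq = genome[chrom]
    if strand == "+":
        tri = seq[pos:pos + 3]
    else:
        tri = reverse_complement(seq[max(0, pos - 2):pos + 1])
    return tri if len(tri) == 3 else ""


# ---------------------------------------------------------------------------
# Read intervals (BED6 with flag-encoding name field)

def read_bed_reads(path, sample_id: Optional[str] = None) -> list[ReadInterval]:
    """Read mapped-read intervals from BED6.

    The name field encodes the two filter flags as ``u<0|1>s<0|1>``
    (uniquely-mapped, MspI-site-at-5'-end).
    """
    if sample_id is None:
        sample_id = str(path)
    reads: list[ReadInterval] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                chrom, start, end, name = fields[:4]
                unique = site5 = True
                if name.startswith("u") and "s" in name:
                    u, _, s = name[1:].partition("s")
                    unique, site5 = u == "1", s == "1"
                reads.append(ReadInterval(
                    chrom=chrom, start=int(start), end=int(end),
                    sample_id=sample_id, unique_flag=unique,
                    site_at_5prime_flag=site5,
                ))
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return reads


def write_bed_reads(reads: Iterable[ReadInterval], path) -> None:
    with open(path, "w") as handle:
        for r in reads:
            name = f"u{int(r.unique_flag)}s{int(r.site_at_5prime_flag)}"
            handle.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t0\t+\n")
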