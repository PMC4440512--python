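"""Synthetic genomes, methylomes and read sets with known ground truth.

Every downstream stage of the pipeline is exercised on data from this
module, so each generator plants the structure its consumer is meant to
recover and records it in a truth table:

* ``generate_genome`` builds chromosomes of i.i.d. background sequence
  with MspI sites (CCGG) at geometrically spaced positions and inserts
  Alu-like elements (~300 bp, subfamilies Y/S/J) complete with exact
  target site duplications seeded from the TTAAAA consensus and A-rich
  flanking pads.  Each element body carries its own interior MspI sites,
  and a site-free exclusion zone around every insertion keeps element
  fragments and background fragments cleanly separable, so a designed
  fraction of size-selected digest fragments overlaps Alu elements.
* ``generate_methylomes`` emits Bismark-style cytosine records for a
  3 parental / 3 OxPt-resistant / 3 SN38-resistant cell-line layout plus
  a clinical cohort, planting group-unique loci, sample-specific
  (low-entropy) loci, a dominant cell-line background (so lineages
  cluster together), and outcome-predictive loci in the clinical arm.
* ``generate_read_intervals`` samples mapped-read intervals from digest
  fragments with a per-sample excess multiplier on Alu Y-overlapping
  fragments.

Each generator draws from its own pseudo-random stream, derived from the
master seed and the stage name, so stages are individually reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .digestion import Fragment, SizeWindow, digest, size_select
from .formats import (CytosineRecord, GenomeSequence, MethylomeSample,
                      ReadInterval, RepeatAnnotation, reverse_complement)
from .repeats import AluClass, RepeatIndex
from .annotate import GeneModel
from .sets import call_context

_BASES = np.array(list("ACGT"))


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent stream per generator stage, derived from the master seed."""
    return np.random.default_rng([seed, zlib.crc32(stage.encode())])


@dataclass(frozen=True)
class TruthRecord:
    kind: str    # unique-locus | dmc | predictive-locus | alu-insertion | ...
    key: str
    value: object


@dataclass
class TruthTable:
    records: list[TruthRecord] = field(default_factory=list)

    def add(self, kind: str, key: str, value) -> None:
        self.records.append(TruthRecord(kind, key, value))

    def of_kind(self, kind: str) -> list[TruthRecord]:
        return [r for r in self.records if r.kind == kind]

    def write_tsv(self, path) -> None:
        with open(path, "w") as handle:
            handle.write("kind\tkey\tvalue\n")
            for r in self.records:
                handle.write(f"{r.kind}\t{r.key}\t{r.value}\n")


# ---------------------------------------------------------------------------
# Genome generation

@dataclass
class GenomeDesign:
    """Parameters of the toy genome.

    ``alu_fragment_share`` is the designed fraction of size-selected
    digest fragments (window ``selection_window``) that overlap an Alu
    element; the number of insertions is derived from it unless
    ``n_alu_insertions`` is given explicitly.
    """

    n_chroms: int = 2
    chrom_length: int = 250_000
    ccgg_spacing_mean: int = 400       # mean geometric gap between sites, bp
    gc_content: float = 0.41
    alu_fragment_share: Optional[float] = 0.30
    n_alu_insertions: Optional[int] = None
    subfamily_mix: Mapping[str, float] = field(
        default_factory=lambda: {"Y": 0.5, "S": 0.3, "J": 0.2})
    alu_length: int = 300
    tsd_length: int = 8
    tsd_seed_sequence: str = "TTAAAA"
    pad_length: int = 20               # A-rich pad outside each TSD
    pad_a_fraction: float = 0.65
    selection_window: SizeWindow = field(
        default_factory=lambda: SizeWindow(40, 300, "base"))
    exclusion_zone: int = 320          # site-free bp on each side of an insertion
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.subfamily_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("subfamily mix must sum to 1")
        if not 4 <= self.tsd_length <= 25:
            raise ValueError("TSD length must be within [4, 25]")


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def _destroy_site(seq: list[str], site: str = "CCGG") -> None:
    """Patch occurrences of the site in place (second base -> A).

    Single pass is sufficient: replacing a C with A can never create a
    new CCGG, and CCGG cannot overlap itself at shifts below 4.
    """
    text = "".join(seq)
    start = text.find(site)
    while start != -1:
        seq[start + 1] = "A"
        start = text.find(site, start + len(site))


def _site_free_seq(rng: np.random.Generator, length: int, gc: float,
                   site: str = "CCGG") -> str:
    seq = list(_random_seq(rng, length, gc))
    _destroy_site(seq, site)
    return "".join(seq)


def _alu_body(rng: np.random.Generator, length: int, gc: float,
              n_interior_fragments: int) -> str:
    """An Alu-like body carrying its own MspI sites.

    The body is CCGG + filler + CCGG [+ filler + CCGG] + tail, with
    site-free fillers, so exactly ``n_interior_fragments`` digest
    fragments (each within the 40-300 bp selection window) lie fully
    inside the body.
    """
    site = "CCGG"
    n_sites = n_interior_fragments + 1
    budget = length - 4 * n_sites
    filler_len = min(150, budget // max(1, n_interior_fragments) - 10)
    parts = [site]
    used = 4
    for _ in range(n_interior_fragments):
        parts.append(_site_free_seq(rng, filler_len, gc))
        parts.append(site)
        used += filler_len + 4
    tail = _site_free_seq(rng, length - used, gc)
    parts.append(tail)
    body = "".join(parts)
    assert len(body) == length
    return body


def _apportion(n: int, mix: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n items to the mix keys."""
    keys = sorted(mix)
    exact = {k: n * mix[k] for k in keys}
    out = {k: int(exact[k]) for k in keys}
    short = n - sum(out.values())
    for k in sorted(keys, key=lambda k: (out[k] - exact[k], k))[:short]:
        out[k] += 1
    return out


def generate_genome(design: GenomeDesign) -> tuple[
        GenomeSequence, list[RepeatAnnotation], list[GeneModel], TruthTable]:
    """Build the toy genome, its repeat annotation, gene models and truth.

    Deterministic under a fixed seed.  Raises when the requested number
    of non-overlapping insertions cannot be placed.
    """
    rng = stage_rng(design.seed, "genome")
    truth = TruthTable()
    gc = design.gc_content
    window = design.selection_window

    # 1. background per chromosome, cleared of accidental CCGG so the
    #    inter-site spacing is exactly the planted geometric model
    backgrounds = {}
    for c in range(design.n_chroms):
        name = f"chr{c + 1}"
        seq = list(_random_seq(rng, design.chrom_length, gc))
        _destroy_site(seq)
        backgrounds[name] = seq

    # cassette geometry
    tsd_extra = design.tsd_length - len(design.tsd_seed_sequence)
    cassette_len = (2 * design.pad_length + 2 * design.tsd_length
                    + design.alu_length)
    margin = cassette_len + 2 * design.exclusion_zone

    # 2. choose insertion points (background coordinates); zones around
    #    them stay site-free so element and background fragments separate
    est_sites = (design.n_chroms * design.chrom_length
                 / (design.ccgg_spacing_mean + 4))
    q = 1.0 - 1.0 / design.ccgg_spacing_mean
    p_window = (q ** max(0, window.min_len - 5)
                - q ** max(0, window.max_len - 4))
    if design.n_alu_insertions is not None:
        n_provisional = design.n_alu_insertions
    else:
        if design.alu_fragment_share is None:
            raise ValueError("give n_alu_insertions or alu_fragment_share")
        f = design.alu_fragment_share
        n_provisional = int(np.ceil(
            1.15 * est_sites * p_window * f / ((1 - f) * 2))) + 6

    points: dict[str, list[int]] = {name: [] for name in backgrounds}
    chrom_names = list(backgrounds)
    for _ in range(n_provisional):
        placed = False
        for _attempt in range(200):
            name = chrom_names[rng.integers(len(chrom_names))]
            pos = int(rng.integers(design.exclusion_zone + 50,
                                   design.chrom_length - margin))
            if all(abs(pos - q_) >= margin for q_ in points[name]):
                points[name].append(pos)
                placed = True
                break
        if not placed:
            raise RuntimeError(
                "could not place all Alu insertions; enlarge the genome or "
                "reduce n_alu_insertions")
    for name in points:
        points[name].sort()

    # 3. plant CCGG sites at geometric gaps, skipping exclusion zones
    def in_zone(name: str, pos: int) -> bool:
        return any(abs(pos - q) < design.exclusion_zone
                   for q in points[name])

    for name, seq in backgrounds.items():
        pos = int(rng.geometric(1.0 / design.ccgg_spacing_mean))
        while pos + 4 <= design.chrom_length:
            if not (in_zone(name, pos) or in_zone(name, pos + 4)):
                seq[pos:pos + 4] = list("CCGG")
            pos += 4 + int(rng.geometric(1.0 / design.ccgg_spacing_mean))

    # 4. realised background fragment count within the selection window
    background_genome = GenomeSequence(
        {name: "".join(seq) for name, seq in backgrounds.items()})
    n_background = len(size_select(digest(background_genome), window))

    # 5. number of insertions / interior fragments per insertion
    n_points = sum(len(v) for v in points.values())
    if design.n_alu_insertions is not None:
        n_insertions = design.n_alu_insertions
        frag_target = 2 * n_insertions
    else:
        f = design.alu_fragment_share
        frag_target = int(round(f * n_background / (1 - f)))
        n_insertions = int(np.ceil(frag_target / 2)) if frag_target else 0
        if n_insertions > n_points:
            raise RuntimeError(
                "designed Alu fragment share needs more insertions than "
                "could be placed; enlarge the genome")
    n_single = 2 * n_insertions - frag_target  # cassettes with 1 interior frag

    # per-subfamily cassette counts (largest remainder at fragment level)
    n_double = n_insertions - n_single
    per_sf_double = _apportion(n_double, design.subfamily_mix)
    per_sf_single = _apportion(n_single, design.subfamily_mix)
    assignments: list[tuple[str, int]] = []
    for sf in sorted(design.subfamily_mix):
        assignments += [(sf, 2)] * per_sf_double[sf]
        assignments += [(sf, 1)] * per_sf_single[sf]
    rng.shuffle(assignments)

    # 6. build cassettes and splice them in
    flat_points = sorted(
        (name, pos) for name in points for pos in points[name])[:n_insertions]
    flat_points = flat_points  # sorted by (chrom, position)
    repeats: list[RepeatAnnotation] = []
    genome_seqs: dict[str, str] = {}
    idx = 0
    point_map: dict[str, list[tuple[int, tuple[str, int]]]] = {
        name: [] for name in backgrounds}
    for name, pos in flat_points:
        point_map[name].append((pos, assignments[idx]))
        idx += 1

    for name, seq in backgrounds.items():
        pieces = []
        cursor = 0
        shift = 0
        for pos, (sf, n_frags) in point_map[name]:
            pieces.append("".join(seq[cursor:pos]))
            tsd = (design.tsd_seed_sequence
                   + _site_free_seq(rng, max(0, tsd_extra), gc)
                   )[:design.tsd_length]
            pad_p = np.array([design.pad_a_fraction,
                              (1 - design.pad_a_fraction) / 3,
                              (1 - design.pad_a_fraction) / 3,
                              (1 - design.pad_a_fraction) / 3])
            def a_rich_pad() -> str:
                pad = list("".join(
                    _BASES[rng.choice(4, size=design.pad_length, p=pad_p)]))
                _destroy_site(pad)
                return "".join(pad)
            body = _alu_body(rng, design.alu_length, gc, n_frags)
            cassette = a_rich_pad() + tsd + body + tsd + a_rich_pad()
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                cassette = reverse_complement(cassette)
            body_start = (pos + shift + design.pad_length
                          + design.tsd_length)
            ann = RepeatAnnotation(
                chrom=name, start=body_start,
                end=body_start + design.alu_length, strand=strand,
                rep_name=f"Alu{sf}synth", rep_family="Alu")
            repeats.append(ann)
            key = f"{name}:{ann.start}-{ann.end}"
            truth.add("alu-insertion", key, sf)
            truth.add("tsd", key, tsd)  # in element orientation
            truth.add("alu-interior-fragments", key, n_frags)
            pieces.append(cassette)
            cursor = pos
            shift += cassette_len
        pieces.append("".join(seq[cursor:]))
        genome_seqs[name] = "".join(pieces)

    genome = GenomeSequence(genome_seqs)
    if design.alu_fragment_share is not None and design.n_alu_insertions is None:
        truth.add("alu-fragment-share", "genome", design.alu_fragment_share)
    for sf, p in design.subfamily_mix.items():
        truth.add("subfamily-mix", sf, p)
    truth.add("background-selected-fragments", "genome", n_background)

    genes = _tile_genes(genome)
    return genome, repeats, genes, truth


def _tile_genes(genome: GenomeSequence, spacing: int = 12_000,
                span: int = 2_000) -> list[GeneModel]:
    """Tile part of each chromosome with simple 3-exon gene models."""
    genes = []
    for chrom in genome.names():
        length = genome.length(chrom)
        i = 0
        start = 3_000
        while start + span < length - 3_000:
            strand = "+" if i % 2 == 0 else "-"
            exons = [(start, start + 300), (start + 700, start + 1000),
                     (start + span - 300, start + span)]
            genes.append(GeneModel(
                name=f"{chrom}_g{i + 1}", chrom=chrom, start=start,
                end=start + span, strand=strand, exons=exons))
            start += spacing
            i += 1
    return genes


# ---------------------------------------------------------------------------
# Methylome generation

@dataclass
class MethylomeDesign:
    """Cell-line and clinical cohort layout plus planted methylome structure.

    The cell-line arm mirrors a three-line drug-resistance panel: each of
    ``lines`` has a parental, an OxPt-resistant and an SN38-resistant
    sample.  The clinical arm has ``n_clinical`` samples split into
    benefit / no-benefit outcome groups.
    """

    lines: Sequence[str] = ("line1", "line2", "line3")
    n_clinical: int = 14
    n_benefit: int = 7
    n_baseline_loci: int = 2_000
    n_unique_loci: int = 300          # per group (parental / oxpt / sn38)
    clinical_share_of_unique: float = 0.5  # unique loci also covered in
    # every clinical sample; these form set E = C ∩ (P∪O∪S)
    n_entropy_loci: int = 50          # sample-specific (low-entropy) loci
    n_predictive_loci: int = 50       # separate clinical outcome groups
    coverage_lambda: float = 30.0     # per-locus read depth ~ Poisson
    line_effect: bool = True          # per-line locus means (somatic memory)
    resistance_jitter: float = 0.03   # variant-level noise on cell lines
    unique_level: float = 0.8
    entropy_high: float = 0.9
    entropy_low: float = 0.05
    predictive_low: float = 0.2
    predictive_effect: float = 0.4
    seed: int = 0

    def cell_line_samples(self) -> dict[str, list[str]]:
        return {
            "parental": [f"{ln}_parental" for ln in self.lines],
            "oxpt": [f"{ln}_oxpt" for ln in self.lines],
            "sn38": [f"{ln}_sn38" for ln in self.lines],
        }

    def clinical_samples(self) -> list[str]:
        return [f"clinical_{i + 1:02d}" for i in range(self.n_clinical)]

    def clinical_labels(self) -> dict[str, str]:
        return {sid: ("benefit" if i < self.n_benefit else "no_benefit")
                for i, sid in enumerate(self.clinical_samples())}


def _cytosine_candidates(genome: GenomeSequence,
                         limit: Optional[int] = None) -> list[tuple]:
    """(chrom, pos, strand, context) for plus-strand cytosines with a
    defined context."""
    out = []
    for chrom in genome.names():
        seq = genome[chrom]
        for pos in range(len(seq) - 2):
            if seq[pos] == "C":
                ctx = call_context(genome, chrom, pos, "+")
                if ctx is not None:
                    out.append((chrom, pos, "+", ctx))
                    if limit is not None and len(out) >= limit:
                        return out
    return out


def _binom_level(rng: np.random.Generator, level: float,
                 depth: int) -> tuple[int, int]:
    n_meth = int(rng.binomial(depth, min(max(level, 0.0), 1.0))) if depth else 0
    return n_meth, depth - n_meth


def generate_methylomes(genome: GenomeSequence, design: MethylomeDesign,
                        ) -> tuple[dict[str, MethylomeSample], TruthTable]:
    """Per-sample cytosine reports with planted group structure.

    Returns a mapping sample id -> MethylomeSample covering the cell-line
    panel and the clinical cohort, plus the truth table of planted
    features.
    """
    rng = stage_rng(design.seed, "methylome")
    truth = TruthTable()
    groups = design.cell_line_samples()
    cell_samples = [sid for g in groups.values() for sid in g]
    clinical = design.clinical_samples()
    labels = design.clinical_labels()
    all_samples = cell_samples + clinical

    n_needed = (design.n_baseline_loci + 3 * design.n_unique_loci
                + design.n_entropy_loci + design.n_predictive_loci)
    candidates = _cytosine_candidates(genome)
    if len(candidates) < n_needed:
        raise ValueError(
            f"genome has {len(candidates)} usable cytosines, "
            f"design needs {n_needed}")
    chosen = rng.choice(len(candidates), size=n_needed, replace=False)
    cursor = 0

    def take(n: int) -> list[tuple]:
        nonlocal cursor
        keys = [candidates[i] for i in chosen[cursor:cursor + n]]
        cursor += n
        return keys

    baseline = take(design.n_baseline_loci)
    unique = {g: take(design.n_unique_loci) for g in groups}
    entropy_loci = take(design.n_entropy_loci)
    predictive = take(design.n_predictive_loci)

    records: dict[str, dict[tuple, tuple[int, int]]] = {
        sid: {} for sid in all_samples}

    def depth(min_one: bool = False) -> int:
        if design.coverage_lambda == 0:
            return 0  # degenerate design: everything uncovered
        d = int(rng.poisson(design.coverage_lambda))
        return max(d, 1) if min_one else d

    # baseline: strong per-line means, small variant jitter; clinical near
    # the cross-line mean
    for key in baseline:
        line_means = {ln: float(rng.uniform(0.05, 0.95))
                      for ln in design.lines}
        for ln in design.lines:
            for variant in ("parental", "oxpt", "sn38"):
                sid = f"{ln}_{variant}"
                level = line_means[ln] + float(
                    rng.normal(0.0, design.resistance_jitter))
                records[sid][key] = _binom_level(rng, level, depth(min_one=True))
        base = float(np.mean(list(line_means.values())))
        for sid in clinical:
            level = base + float(rng.normal(0.0, 0.1))
            records[sid][key] = _binom_level(rng, level, depth(min_one=True))

    # group-unique loci: covered only in the owning group's cell-line
    # samples; a planted fraction is additionally covered in every
    # clinical sample (uniqueness concerns the nine cell lines only),
    # and those loci are exactly what set E recovers
    for g, keys in unique.items():
        for key in keys:
            truth.add("unique-locus", "|".join(map(str, key)), g)
            for sid in cell_samples:
                if sid in groups[g]:
                    records[sid][key] = _binom_level(
                        rng, design.unique_level, depth(min_one=True))
                else:
                    records[sid][key] = (0, 0)
            if rng.random() < design.clinical_share_of_unique:
                truth.add("unique-clinical-shared", "|".join(map(str, key)), g)
                for sid in clinical:
                    records[sid][key] = _binom_level(
                        rng, design.unique_level, depth(min_one=True))

    # sample-specific (low-entropy) loci across cell lines and clinical
    for i, key in enumerate(entropy_loci):
        special = all_samples[i % len(all_samples)]
        truth.add("dmc", "|".join(map(str, key)), special)
        for sid in all_samples:
            level = (design.entropy_high if sid == special
                     else design.entropy_low)
            records[sid][key] = _binom_level(rng, level, depth(min_one=True))

    # clinical outcome-predictive loci
    for key in predictive:
        truth.add("predictive-locus", "|".join(map(str, key)),
                  design.predictive_effect)
        for sid in clinical:
            level = design.predictive_low
            if labels[sid] == "no_benefit":
                level += design.predictive_effect
            records[sid][key] = _binom_level(
                rng, level + float(rng.normal(0.0, 0.03)),
                depth(min_one=True))
        for sid in cell_samples:
            records[sid][key] = _binom_level(rng, 0.3, depth(min_one=True))

    samples = {}
    for sid in all_samples:
        recs = [CytosineRecord(chrom=k[0], pos=k[1], strand=k[2],
                               context=k[3], n_meth=m, n_unmeth=u)
                for k, (m, u) in sorted(records[sid].items())]
        samples[sid] = MethylomeSample(sample_id=sid, records=recs)
    return samples, truth


# ---------------------------------------------------------------------------
# Read-interval generation

def generate_read_intervals(
        fragments: Sequence[Fragment],
        repeat_index: RepeatIndex,
        n_reads: Mapping[str, int],
        aluy_multiplier: Mapping[str, float],
        seed: int = 0,
        frac_nonunique: float = 0.02,
        frac_no_site: float = 0.02,
) -> tuple[dict[str, list[ReadInterval]], TruthTable]:
    """Sample per-sample read intervals from digest fragments.

    Fragments overlapping an Alu Y annotation are drawn with probability
    scaled by the sample's multiplier; each read is the fragment interval
    itself.  A small fraction of reads is flagged non-unique or lacking
    the 5' cut site so the read filter has something to remove.
    """
    if not fragments:
        raise ValueError("empty fragment list")
    for sid, mult in aluy_multiplier.items():
        if mult < 0:
            raise ValueError(f"negative multiplier for {sid!r}")
    rng = stage_rng(seed, "reads")
    truth = TruthTable()
    is_aluy = np.array([
        (lambda hit: hit is not None and hit[1] is AluClass.ALU_Y)(
            repeat_index.best_alu(f.chrom, f.start, f.end))
        for f in fragments])
    reads: dict[str, list[ReadInterval]] = {}
    for sid in n_reads:
        mult = aluy_multiplier.get(sid, 1.0)
        truth.add("read-excess", sid, mult)
        weights = np.where(is_aluy, mult, 1.0)
        total = weights.sum()
        if total == 0:
            raise ValueError(f"all fragment weights zero for {sid!r}")
        picks = rng.choice(len(fragments), size=n_reads[sid],
                           p=weights / total)
        sample_reads = []
        for i in picks:
            f = fragments[int(i)]
            sample_reads.append(ReadInterval(
                chrom=f.chrom, start=f.start, end=f.end, sample_id=sid,
                unique_flag=bool(rng.random() >= frac_nonunique),
                site_at_5prime_flag=bool(rng.random() >= frac_no_site)))
        reads[sid] = sample_reads
    return reads, truth
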