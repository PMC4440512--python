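"""Read-level Alu subfamily quantification and the paired log2 t-test.

RRBS reads are filtered to those that are uniquely mapped and carry the
MspI cut site at their 5' end, then counted against Alu subfamily
annotations.  Per-sample totals are equalised by linear scaling to the
mean total before any cross-sample comparison, and resistant-vs-parental
cell-line pairs are compared with a paired t-test on log2 read counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .formats import ReadInterval
from .repeats import SUBFAMILIES, AluClass, RepeatIndex


def filter_reads(reads: Iterable[ReadInterval]) -> list[ReadInterval]:
    """Keep uniquely mapped reads with the cut site at the 5' end."""
    return [r for r in reads if r.unique_flag and r.site_at_5prime_flag]


def normalize_totals(totals: Mapping[str, int]) -> dict[str, float]:
    """Linear scale factor per sample so all scaled totals equal the mean.

    factor_s = mean(totals) / total_s; total scaled reads are conserved
    (sum equals n * mean).
    """
    if not totals:
        raise ValueError("no sample totals")
    for sid, t in totals.items():
        if t <= 0:
            raise ValueError(f"non-positive read total for sample {sid!r}")
    mean_total = sum(totals.values()) / len(totals)
    return {sid: mean_total / t for sid, t in totals.items()}


@dataclass
class SubfamilyCounts:
    """Scaled per-AluClass read counts and percentages for one sample."""

    sample_id: str
    total: float  # scaled total mapped reads (post-filter)
    counts: dict[AluClass, float] = field(default_factory=dict)

    def percentage(self, cls: AluClass) -> float:
        """Percent of (scaled) total mapped reads in the class."""
        return 100.0 * self.counts.get(cls, 0.0) / self.total


def subfamily_counts(reads_by_sample: Mapping[str, Sequence[ReadInterval]],
                     repeat_index: RepeatIndex,
                     factors: Optional[Mapping[str, float]] = None,
                     ) -> dict[str, SubfamilyCounts]:
    """Scaled Alu-subfamily read counts per sample.

    Reads are assumed already filtered.  A read counts toward the Alu
    class of the annotation it overlaps most (ties to the leftmost
    annotation); counts and totals are multiplied by the sample's
    normalisation factor and kept as real numbers.
    """
    if factors is None:
        factors = normalize_totals(
            {sid: len(reads) for sid, reads in reads_by_sample.items()})
    out = {}
    for sid, reads in reads_by_sample.items():
        factor = factors[sid]
        counts = {cls: 0.0 for cls in SUBFAMILIES}
        for read in reads:
            hit = repeat_index.best_alu(read.chrom, read.start, read.end)
            if hit is not None:
                counts[hit[1]] += factor
        out[sid] = SubfamilyCounts(sample_id=sid,
                                   total=len(reads) * factor, counts=counts)
    return out


@dataclass
class PairedTestResult:
    n: int
    mean_log2_diff: float
    t: float
    df: int
    p: float
    degenerate_variance: bool = False


def paired_log2_test(pairs: Sequence[tuple[float, float]]) -> PairedTestResult:
    """Two-sided paired t-test on log2-transformed count pairs.

    Each pair is (resistant count, parental count); d_i = log2(r_i) -
    log2(p_i), t = mean(d) / (sd(d)/sqrt(n)) with the sample sd, p from
    Student t with n-1 df.  Zero counts are an error (log2 undefined).
    A zero sd with non-zero mean yields p = 0 with a degenerate-variance
    flag; zero sd and zero mean yield t = 0, p = 1.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    for r, p in pairs:
        if r <= 0 or p <= 0:
            raise ValueError("counts must be positive for the log2 transform")
    d = np.array([math.log2(r) - math.log2(p) for r, p in pairs])
    n = len(d)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return PairedTestResult(n=n, mean_log2_diff=0.0, t=0.0,
                                    df=n - 1, p=1.0)
        t = math.inf if mean > 0 else -math.inf
        return PairedTestResult(n=n, mean_log2_diff=mean, t=t, df=n - 1,
                                p=0.0, degenerate_variance=True)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return PairedTestResult(n=n, mean_log2_diff=mean, t=t, df=n - 1, p=p)
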