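"""Methylation entropy, differential-cytosine calling and sample clustering.

The differential statistic is the Shannon entropy of a locus's
level-normalised methylation profile across samples.  For levels
m = (m_1..m_N), H(v) = -sum p_i log2 p_i with p_i = v_i / sum(v); a locus
methylated in one sample only has H near 0, a locus methylated equally
everywhere has H = log2 N.  Because entropy of the raw levels only sees
sample-specific HYPERmethylation, the statistic is evaluated on both the
methylation arm m and the demethylation arm 1 - m and the minimum is
taken, so sample-specific hypomethylation scores low too.  An arm whose
sum is zero is treated as maximally entropic, so an all-zero or all-one
profile is non-differential.

Differentially methylated cytosines (DMCs) are loci whose entropy falls
at or below a threshold, given either absolutely (bits) or as a lower
quantile of the entropy distribution over fully covered loci.

Methylation matrices are pandas DataFrames: rows indexed by locus key
tuples, one column per sample, NaN for uncovered cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .formats import MethylomeSample
from .sets import LocusSet, presence


@dataclass(frozen=True)
class EntropyRecord:
    locus: Optional[tuple]
    entropy: float           # bits, in [0, log2 N]
    direction: str           # "hyper-specific" (m arm) or "hypo-specific"
    mean_level: float


def shannon_entropy(v: np.ndarray) -> float:
    """Shannon entropy (bits) of the normalised vector; sum(v)=0 -> log2 N."""
    n = v.size
    total = v.sum()
    if total <= 0:
        return float(np.log2(n))
    p = v / total
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def methylation_entropy(levels: Sequence[float],
                        locus: Optional[tuple] = None) -> EntropyRecord:
    """Entropy record for one locus over >= 2 non-missing levels.

    entropy = min(H(m), H(1-m)); direction records which arm attained the
    minimum ("hyper-specific" when the methylation arm did; ties go to
    hyper-specific).  Invariant under sample permutation and under scaling
    of the levels by a positive constant.
    """
    v = np.asarray(levels, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValueError("entropy needs at least 2 non-missing levels")
    if (v < 0).any():
        raise ValueError("negative methylation levels")
    h_hyper = shannon_entropy(v)
    h_hypo = shannon_entropy(np.clip(1.0 - v, 0.0, None))
    if h_hyper <= h_hypo:
        entropy, direction = h_hyper, "hyper-specific"
    else:
        entropy, direction = h_hypo, "hypo-specific"
    return EntropyRecord(locus=locus, entropy=entropy, direction=direction,
                         mean_level=float(v.mean()))


def entropy_table(matrix: pd.DataFrame,
                  require_full: bool = False) -> pd.DataFrame:
    """Entropy for every matrix row with >= 2 covered samples.

    Returns a DataFrame (index = locus, columns: entropy, direction,
    mean_level, n_covered).  ``require_full`` keeps fully covered rows
    only.
    """
    rows = []
    index = []
    values = matrix.to_numpy(dtype=float)
    n_samples = matrix.shape[1]
    for i, locus in enumerate(matrix.index):
        v = values[i]
        covered = ~np.isnan(v)
        n_cov = int(covered.sum())
        if n_cov < 2 or (require_full and n_cov < n_samples):
            continue
        rec = methylation_entropy(v[covered], locus=locus)
        rows.append((rec.entropy, rec.direction, rec.mean_level, n_cov))
        index.append(locus)
    return pd.DataFrame(rows, index=index,
                        columns=["entropy", "direction", "mean_level",
                                 "n_covered"])


def call_dmcs(matrix: pd.DataFrame,
              threshold: Optional[float] = None,
              quantile: Optional[float] = 0.05) -> set:
    """Loci whose entropy is at or below the resolved threshold.

    Either an absolute entropy cutoff in bits or a lower quantile q of
    the entropy distribution over fully covered loci (default q = 0.05).
    """
    if matrix.empty:
        raise ValueError("empty methylation matrix")
    table = entropy_table(matrix)
    if table.empty:
        return set()
    if threshold is None:
        if quantile is None:
            raise ValueError("provide threshold or quantile")
        full = table[table["n_covered"] == matrix.shape[1]]
        basis = full if not full.empty else table
        threshold = float(basis["entropy"].quantile(quantile))
    return set(table.index[table["entropy"] <= threshold])


def matrix_from_samples(samples: Sequence[MethylomeSample],
                        min_depth: int = 1) -> pd.DataFrame:
    """Level matrix over the union of covered loci; NaN where uncovered."""
    columns = {}
    for s in samples:
        lv = {}
        for r in s:
            if r.total >= min_depth and r.level is not None:
                lv[(r.chrom, r.pos, r.strand, r.context)] = r.level
        columns[s.sample_id] = lv
    df = pd.DataFrame(columns)
    df.index = pd.Index(df.index.tolist(), tupleize_cols=False)
    return df.sort_index(axis=1)


def phenotype_associated_loci(group_a: Sequence[MethylomeSample],
                              group_b: Sequence[MethylomeSample],
                              all_samples: Sequence[MethylomeSample],
                              min_depth: int = 1,
                              threshold: Optional[float] = None,
                              quantile: Optional[float] = 0.05,
                              ) -> dict[str, LocusSet]:
    """Phenotype-associated loci, per context.

    Loci present (>= min_depth) in every sample of both named groups,
    then filtered to DMCs over all samples; returned separately for CpG,
    CHG and CHH.
    """
    ids_a = {s.sample_id for s in group_a}
    ids_b = {s.sample_id for s in group_b}
    if ids_a & ids_b:
        raise ValueError("groups share samples")
    covered = None
    for s in list(group_a) + list(group_b):
        p = presence(s, min_depth)
        covered = p if covered is None else covered & p
    matrix = matrix_from_samples(all_samples, min_depth=min_depth)
    dmcs = call_dmcs(matrix, threshold=threshold, quantile=quantile)
    kept = (covered or set()) & dmcs
    return {ctx: LocusSet(ctx, frozenset(k for k in kept if k[3] == ctx))
            for ctx in ("CpG", "CHG", "CHH")}


# ---------------------------------------------------------------------------
# Unsupervised clustering

def correlation_distance_matrix(matrix: pd.DataFrame,
                                min_covered: int = 10) -> pd.DataFrame:
    """Pairwise 1 - Pearson correlation with pairwise deletion.

    Each sample pair is correlated over the loci covered in both; a pair
    with fewer than ``min_covered`` co-covered loci is an error naming
    the pair.
    """
    cols = sorted(matrix.columns)  # deterministic tie-break by sample name
    values = matrix[cols].to_numpy(dtype=float)
    n = len(cols)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(values[:, i]) & ~np.isnan(values[:, j])
            if both.sum() < min_covered:
                raise ValueError(
                    f"samples {cols[i]!r} and {cols[j]!r} share only "
                    f"{int(both.sum())} covered loci (< {min_covered})"
                )
            x, y = values[both, i], values[both, j]
            sx, sy = x.std(), y.std()
            if sx == 0 or sy == 0:
                r = 1.0 if np.allclose(x, y) else 0.0
            else:
                r = float(np.corrcoef(x, y)[0, 1])
            dist[i, j] = dist[j, i] = 1.0 - r
    return pd.DataFrame(dist, index=cols, columns=cols)


@dataclass
class Dendrogram:
    labels: list[str]
    linkage: np.ndarray  # scipy linkage matrix

    def to_newick(self) -> str:
        n = len(self.labels)
        names = {i: self.labels[i] for i in range(n)}
        heights = {i: 0.0 for i in range(n)}
        for k, (a, b, h, _cnt) in enumerate(self.linkage):
            a, b = int(a), int(b)
            left = f"{names[a]}:{h - heights[a]:.6g}"
            right = f"{names[b]}:{h - heights[b]:.6g}"
            names[n + k] = f"({left},{right})"
            heights[n + k] = h
        return names[n + len(self.linkage) - 1] + ";"

    def merge_order(self) -> list[frozenset]:
        """Sample-label sets of each merge, in merge order."""
        n = len(self.labels)
        members = {i: frozenset([self.labels[i]]) for i in range(n)}
        order = []
        for k, (a, b, _h, _cnt) in enumerate(self.linkage):
            merged = members[int(a)] | members[int(b)]
            members[n + k] = merged
            order.append(merged)
        return order


def cluster_samples(matrix: pd.DataFrame, min_covered: int = 10) -> Dendrogram:
    """Average-linkage agglomerative clustering of samples.

    Distance is 1 - Pearson correlation over co-covered loci.  Columns
    are processed in sorted-name order, which makes exact-tie merges
    deterministic.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples to cluster")
    dist = correlation_distance_matrix(matrix, min_covered=min_covered)
    condensed = dist.to_numpy()[np.triu_indices(len(dist), k=1)]
    linkage = hierarchy.linkage(condensed, method="average")
    return Dendrogram(labels=list(dist.columns), linkage=linkage)
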