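"""Outcome prediction from methylation profiles.

Features (loci) are ranked by a signal-to-noise score between the two
outcome classes, s = (mu0 - mu1) / (sigma0 + sigma1), with each class
standard deviation floored at max(0.2*|mu|, 0.2) so near-constant
features cannot produce unbounded scores.  Classification is k-nearest
neighbours on the selected features with missing cells excluded pairwise
(distances renormalised by sqrt(L / L_used)), and accuracy is estimated
by leave-one-out cross-validation with feature selection re-run inside
each fold by default — the leakage-free protocol.  A global-selection
mode (features chosen once on all samples before validation) is also
available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .repeats import enrichment_test


def signal_to_noise(values: np.ndarray, labels: np.ndarray) -> float:
    """Class-separation score of one feature.

    s = (mu0 - mu1) / (sigma0 + sigma1), sample standard deviations each
    floored at max(0.2*|mu|, 0.2).  Missing values are dropped per class;
    each class needs >= 2 observations.  Antisymmetric under label swap.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    stats = []
    for cls in classes:
        v = values[labels == cls]
        v = v[~np.isnan(v)]
        if v.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 observations")
        mu = float(v.mean())
        sigma = max(float(v.std(ddof=1)), 0.2 * abs(mu), 0.2)
        stats.append((mu, sigma))
    (mu0, s0), (mu1, s1) = stats
    return (mu0 - mu1) / (s0 + s1)


def score_features(matrix: pd.DataFrame, labels: pd.Series) -> np.ndarray:
    """Signal-to-noise score of every feature (row), vectorised.

    Matches :func:`signal_to_noise` exactly (sample sds, same floors,
    missing cells dropped per class).
    """
    y = labels.loc[matrix.columns].to_numpy()
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    values = matrix.to_numpy(dtype=float)
    stats = []
    for cls in classes:
        v = values[:, y == cls]
        n = (~np.isnan(v)).sum(axis=1)
        if (n < 2).any():
            raise ValueError(f"class {cls!r} has fewer than 2 observations "
                             "for some feature")
        mu = np.nanmean(v, axis=1)
        sigma = np.nanstd(v, axis=1, ddof=1)
        sigma = np.maximum(sigma, np.maximum(0.2 * np.abs(mu), 0.2))
        stats.append((mu, sigma))
    (mu0, s0), (mu1, s1) = stats
    return (mu0 - mu1) / (s0 + s1)


def rank_features(matrix: pd.DataFrame, labels: pd.Series,
                  n_features: int) -> list:
    """Top features by |signal-to-noise|; ties broken by feature order."""
    s = score_features(matrix, labels)
    order = np.lexsort((np.arange(len(s)), -np.abs(s)))
    return [matrix.index[i] for i in order[:n_features]]


def _distance(x: np.ndarray, y: np.ndarray) -> float:
    """Euclidean distance with pairwise deletion of missing cells.

    Renormalised by sqrt(L / L_used) so distances over different numbers
    of usable features stay comparable.
    """
    both = ~np.isnan(x) & ~np.isnan(y)
    used = int(both.sum())
    if used == 0:
        raise ValueError("no co-observed features between samples")
    d = float(np.sqrt(((x[both] - y[both]) ** 2).sum()))
    return d * math.sqrt(x.size / used)


def knn_classify(train: pd.DataFrame, train_labels: pd.Series,
                 test_vector: np.ndarray, k: int = 3):
    """Majority vote of the k nearest training samples.

    ``train`` has features as rows and samples as columns.  Distance ties
    are broken by sample-name order; vote ties by the class of the single
    nearest neighbour.
    """
    if not 1 <= k <= train.shape[1]:
        raise ValueError(f"k={k} outside [1, {train.shape[1]}]")
    if train.shape[0] == 0:
        raise ValueError("no usable features")
    neighbours = sorted(
        ((_distance(train[col].to_numpy(dtype=float), test_vector), col)
         for col in train.columns),
        key=lambda dc: (dc[0], dc[1]))
    top = neighbours[:k]
    votes: dict = {}
    for _, col in top:
        lab = train_labels.loc[col]
        votes[lab] = votes.get(lab, 0) + 1
    best = max(votes.values())
    winners = [lab for lab, n in votes.items() if n == best]
    if len(winners) == 1:
        return winners[0]
    return train_labels.loc[top[0][1]]  # vote tie: nearest neighbour decides


@dataclass
class PredictionReport:
    predictions: dict          # sample id -> predicted label
    accuracy: float
    table: list                # 2x2 predicted-vs-actual counts
    fisher_p: float


def loocv(matrix: pd.DataFrame, labels: pd.Series, k: int = 3,
          n_features: int = 50,
          fold_internal_selection: bool = True) -> PredictionReport:
    """Leave-one-out cross-validated KNN prediction.

    By default features are re-selected on the training samples of each
    fold (no information leaks from the held-out sample); with
    ``fold_internal_selection=False`` features are selected once on all
    samples, the protocol implied by selecting key features from the full
    cohort before validating.  The accuracy is tested with a two-sided
    Fisher exact test on the predicted-vs-actual 2x2 table.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples for leave-one-out")
    labels = labels.loc[matrix.columns]
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError("need exactly two outcome classes")

    global_features = None
    if not fold_internal_selection:
        global_features = rank_features(matrix, labels, n_features)

    predictions = {}
    for held_out in matrix.columns:
        train_cols = [c for c in matrix.columns if c != held_out]
        train_labels = labels.loc[train_cols]
        if train_labels.nunique() < 2:
            raise ValueError(f"fold holding out {held_out!r} empties a class")
        features = (global_features if global_features is not None else
                    rank_features(matrix[train_cols], train_labels,
                                  n_features))
        sub = matrix.loc[features]
        predictions[held_out] = knn_classify(
            sub[train_cols], train_labels,
            sub[held_out].to_numpy(dtype=float), k=k)

    correct = sum(predictions[c] == labels.loc[c] for c in matrix.columns)
    accuracy = correct / matrix.shape[1]
    table = [[0, 0], [0, 0]]
    for c in matrix.columns:
        i = classes.index(predictions[c])
        j = classes.index(labels.loc[c])
        table[i][j] += 1
    fisher_p = enrichment_test(table)
    return PredictionReport(predictions=predictions, accuracy=accuracy,
                            table=table, fisher_p=fisher_p)
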