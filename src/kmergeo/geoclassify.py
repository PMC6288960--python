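"""KNN continent-of-origin prediction and its confidence scores.

A query sample is assigned the majority continent among its K nearest
reference samples in a dissimilarity matrix. Accuracy is evaluated over
repeated random train/test splits; per-sample nearest-neighbor link tables
summarise whether each sample's closest matches share its continent.

Two bootstrap-style confidence scores quantify the stability of a
prediction: reference-confidence (RC) resamples the reference panel with
replacement and reports how often the prediction agrees with the
full-reference prediction, and NGS-confidence (NC) re-predicts from disjoint
read subsets of the query and reports the modal-agreement fraction.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dissimilarity import (
    DissimilarityMatrix,
    SampleKmerData,
    build_sample_data,
    cross_distances,
)
from .sequence_io import InsufficientDataError, ReadSet, partition_reads

__all__ = [
    "KNNPrediction",
    "ConfidenceReport",
    "knn_predict",
    "evaluate_splits",
    "nn_link_table",
    "reference_confidence",
    "ngs_confidence",
]


@dataclass
class KNNPrediction:
    query_id: str
    K: int
    predicted: str
    neighbor_ids: list[str]
    neighbor_distances: list[float]
    votes: dict[str, int] = field(default_factory=dict)


def _vote(
    order: Sequence[int],
    distances: np.ndarray,
    labels: Sequence[str],
    K: int,
) -> tuple[str, list[int], dict[str, int]]:
    """Majority vote among the first K entries of a sorted neighbor order.

    Vote ties go to the tied label seen earliest in the neighbor ranking
    (the label owning the nearest neighbor); any residual tie falls back to
    the smallest summed distance.
    """
    top = list(order[:K])
    votes = Counter(labels[i] for i in top)
    best = max(votes.values())
    tied = [lab for lab, v in votes.items() if v == best]
    if len(tied) == 1:
        return tied[0], top, dict(votes)
    first_rank = {lab: next(r for r, i in enumerate(top) if labels[i] == lab) for lab in tied}
    min_rank = min(first_rank.values())
    tied = [lab for lab in tied if first_rank[lab] == min_rank]
    if len(tied) > 1:  # unreachable with a strict ranking; kept for safety
        sums = {lab: sum(distances[i] for i in top if labels[i] == lab) for lab in tied}
        tied = sorted(tied, key=lambda lab: (sums[lab], lab))
    return tied[0], top, dict(votes)


def _neighbor_order(distances: np.ndarray, ids: Sequence[str]) -> list[int]:
    """Indices sorted by ascending distance; distance ties broken by sample id."""
    return sorted(range(len(ids)), key=lambda i: (distances[i], ids[i]))


def knn_predict(
    dm: DissimilarityMatrix,
    train_labels: Mapping[str, str],
    query_id: str,
    K: int,
) -> KNNPrediction:
    """Predict a query's continent by majority vote among its K nearest
    labeled training samples in the matrix. Deterministic: distance ties are
    broken by ascending sample id and vote ties per :func:`_vote`.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    train_ids = [s for s in dm.sample_ids if s in train_labels and s != query_id]
    if K > len(train_ids):
        raise ValueError(f"K={K} exceeds training size {len(train_ids)}")
    row = dm.row(query_id)
    dists = np.array([row[dm.index(s)] for s in train_ids])
    labels = [train_labels[s] for s in train_ids]
    order = _neighbor_order(dists, train_ids)
    predicted, top, votes = _vote(order, dists, labels, K)
    return KNNPrediction(
        query_id=query_id,
        K=K,
        predicted=predicted,
        neighbor_ids=[train_ids[i] for i in top],
        neighbor_distances=[float(dists[i]) for i in top],
        votes=votes,
    )


def evaluate_splits(
    dm: DissimilarityMatrix,
    labels: Mapping[str, str],
    train_size: int,
    K_values: Sequence[int],
    n_splits: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean KNN accuracy over random train/test splits.

    Splits are uniform and unstratified; a split whose training set lacks a
    continent is kept (that label simply cannot be predicted). Returns a long
    table with columns ``train_size, K, accuracy, n_splits, seed``.

    With ``train_size = n − 1`` this reduces to leave-one-out evaluation
    (every sample is the lone test case in some splits).
    """
    ids = [s for s in dm.sample_ids if s in labels]
    n = len(ids)
    if not 1 <= train_size < n:
        raise ValueError(f"train_size must be in [1, {n - 1}]")
    if max(K_values) > train_size:
        raise ValueError("K cannot exceed train_size")
    rng = np.random.default_rng(seed)
    correct = {K: 0 for K in K_values}
    total = 0
    for _ in range(n_splits):
        perm = rng.permutation(n)
        train_ids = [ids[i] for i in perm[:train_size]]
        test_ids = [ids[i] for i in perm[train_size:]]
        train_labels = {s: labels[s] for s in train_ids}
        for q in test_ids:
            row = dm.row(q)
            dists = np.array([row[dm.index(s)] for s in train_ids])
            lab = [train_labels[s] for s in train_ids]
            order = _neighbor_order(dists, train_ids)
            for K in K_values:
                predicted, _, _ = _vote(order, dists, lab, K)
                if predicted == labels[q]:
                    correct[K] += 1
        total += len(test_ids)
    rows = [
        {
            "train_size": train_size,
            "K": K,
            "accuracy": correct[K] / total,
            "n_splits": n_splits,
            "seed": seed,
        }
        for K in K_values
    ]
    return pd.DataFrame(rows)


def leave_one_out_accuracy(
    dm: DissimilarityMatrix, labels: Mapping[str, str], K: int = 1
) -> float:
    """Fraction of samples whose KNN prediction from all others is correct."""
    ids = [s for s in dm.sample_ids if s in labels]
    hits = sum(knn_predict(dm, labels, q, K).predicted == labels[q] for q in ids)
    return hits / len(ids)


def nn_link_table(dm: DissimilarityMatrix, labels: Mapping[str, str]) -> pd.DataFrame:
    """Two nearest neighbors of every sample and whether they share its continent.

    This is the tabular counterpart of the circular link plot: the returned
    frame carries a ``top1_same_continent`` column whose mean is the headline
    linking accuracy.
    """
    if len(dm) < 3:
        raise ValueError("need at least three samples")
    rows = []
    for q in dm.sample_ids:
        others = [s for s in dm.sample_ids if s != q]
        row = dm.row(q)
        dists = np.array([row[dm.index(s)] for s in others])
        order = _neighbor_order(dists, others)
        top1, top2 = others[order[0]], others[order[1]]
        rows.append(
            {
                "sample_id": q,
                "top1_id": top1,
                "top2_id": top2,
                "top1_distance": float(dists[order[0]]),
                "top2_distance": float(dists[order[1]]),
                "top1_same_continent": labels.get(top1) == labels.get(q),
                "top2_same_continent": labels.get(top2) == labels.get(q),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ConfidenceReport:
    query_id: str
    RC: dict[int, float] = field(default_factory=dict)
    NC: float | None = None
    B_bootstrap: int = 0
    n_subsets: int = 0


def reference_confidence(
    dm: DissimilarityMatrix,
    labels: Mapping[str, str],
    query_id: str,
    K_values: Sequence[int] = (1, 3),
    B: int = 1000,
    seed: int = 0,
) -> dict[int, float]:
    """Stability of a prediction under bootstrap resampling of the references.

    The reference panel (every labeled sample except the query) is resampled
    with replacement B times; a sample drawn twice occupies two of the K
    neighbor slots. RC_K is the fraction of resamples whose KNN prediction
    matches the prediction using the full reference panel.
    """
    if B <= 0:
        raise ValueError("B must be positive")
    ref_ids = [s for s in dm.sample_ids if s in labels and s != query_id]
    row = dm.row(query_id)
    dists = np.array([row[dm.index(s)] for s in ref_ids])
    lab = [labels[s] for s in ref_ids]
    full_order = _neighbor_order(dists, ref_ids)
    full_pred = {K: _vote(full_order, dists, lab, K)[0] for K in K_values}

    rng = np.random.default_rng(seed)
    agree = {K: 0 for K in K_values}
    n = len(ref_ids)
    for _ in range(B):
        draw = rng.integers(0, n, size=n)
        d_b = dists[draw]
        ids_b = [ref_ids[i] for i in draw]
        lab_b = [lab[i] for i in draw]
        order_b = _neighbor_order(d_b, ids_b)
        for K in K_values:
            if _vote(order_b, d_b, lab_b, K)[0] == full_pred[K]:
                agree[K] += 1
    return {K: agree[K] / B for K in K_values}


def ngs_confidence(
    query_reads: ReadSet,
    references: Sequence[SampleKmerData],
    ref_labels: Mapping[str, str],
    measure: str = "d2star",
    k: int = 8,
    m: int = 2,
    strand: str = "both",
    K: int = 1,
    n_subsets: int = 10,
    subset_bases: int | None = None,
    seed: int = 0,
) -> tuple[float, str, list[str]]:
    """Stability of a prediction under disjoint resampling of the query reads.

    The query's read pool is partitioned into up to ``n_subsets`` disjoint
    subsets of ``subset_bases`` each; every subset is profiled and classified
    independently against the references. NC is the fraction of subsets
    agreeing with the modal prediction (modal ties broken by the label of the
    subset with the smallest nearest-neighbor distance).

    Returns ``(NC, modal_label, per-subset predictions)``.
    """
    if subset_bases is None:
        subset_bases = query_reads.total_bases // n_subsets
        if subset_bases == 0:
            raise InsufficientDataError(f"query {query_reads.sample_id} has too few bases")
    if n_subsets * subset_bases > query_reads.total_bases:
        warnings.warn(
            f"query {query_reads.sample_id}: {query_reads.total_bases} bases cannot "
            f"fill {n_subsets} subsets of {subset_bases}; fewer subsets will be used",
            stacklevel=2,
        )
    subsets = partition_reads(query_reads, n_subsets, subset_bases, seed)
    if not subsets:
        raise InsufficientDataError(
            f"query {query_reads.sample_id}: no complete subset of {subset_bases} bases"
        )
    ref_list = list(references)
    lab = [ref_labels[r.sample_id] for r in ref_list]
    ref_ids = [r.sample_id for r in ref_list]
    predictions: list[str] = []
    best_1nn: list[float] = []
    for sub in subsets:
        data = build_sample_data(sub, k=k, m=m, measure=measure, strand=strand)
        dists = cross_distances(data, ref_list, measure)
        order = _neighbor_order(dists, ref_ids)
        predictions.append(_vote(order, dists, lab, K)[0])
        best_1nn.append(float(dists[order[0]]))
    counts = Counter(predictions)
    top = max(counts.values())
    tied = [labc for labc, v in counts.items() if v == top]
    if len(tied) == 1:
        modal = tied[0]
    else:
        ranked = sorted(
            range(len(predictions)), key=lambda i: best_1nn[i]
        )
        modal = next(predictions[i] for i in ranked if predictions[i] in tied)
    nc = counts[modal] / len(predictions)
    return nc, modal, predictions
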