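"""Labelled-pair construction, ROC/AUC evaluation and hyperparameter sweeps.

The ROC curve follows the threshold-sweep definition: every distinct sample
score serves as a threshold, a sample is called positive when its score is
strictly greater than the threshold, and TPR/FPR trace the curve; AUC is
the trapezoidal area.  ``auc_rank`` computes the equivalent Mann-Whitney
statistic (ties credited 0.5), which is the probability that a random
positive outscores a random negative; the two agree to floating-point
precision and ``auc_rank`` is what summaries report.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .datamodel import (
    ConfigError,
    DataError,
    DrugRecord,
    LabeledPairSet,
    Pair,
    PathwayUniverse,
    ordered_pair,
)
from .network import all_pairs_shortest_paths, build_network
from .scoring import PairScore, ScoreConfig, score_all_pairs, scores_by_pair


@dataclass(frozen=True)
class RocResult:
    """Threshold-sweep ROC points and trapezoidal AUC."""

    points: tuple[tuple[float, float], ...]  # (FPR, TPR), start (0,0), end (1,1)
    thresholds: tuple[float, ...]
    auc: float


@dataclass(frozen=True)
class SweepResult:
    """AUC per (C, p_threshold) grid point."""

    grid: tuple[tuple[float, float], ...]
    auc_per_setting: Mapping[tuple[float, float], float]


def sample_negatives(
    drugs: Iterable[DrugRecord],
    positives: Iterable[Pair],
    curated_negatives: Iterable[Pair],
    ratio: int,
    seed: int,
) -> LabeledPairSet:
    """Top up curated negatives with a seeded uniform sample of drug pairs.

    Negatives are drawn without replacement from all unordered drug pairs
    excluding positives, curated negatives and self-pairs, until the
    negative set reaches ``ratio`` times the positive set.
    """
    if ratio < 1:
        raise ConfigError(f"negative ratio must be a positive integer, got {ratio}")
    drug_ids = sorted({d.drug_id for d in drugs})
    positives = frozenset(ordered_pair(*p) for p in positives)
    curated = frozenset(ordered_pair(*p) for p in curated_negatives)
    if positives & curated:
        raise DataError("curated negatives overlap the positive set")
    quota = ratio * len(positives)
    n_to_sample = quota - len(curated)
    if n_to_sample < 0:
        raise DataError(
            f"{len(curated)} curated negatives already exceed the quota {quota}"
        )
    candidates = [
        pair
        for pair in itertools.combinations(drug_ids, 2)
        if pair not in positives and pair not in curated
    ]
    if n_to_sample > len(candidates):
        raise DataError(
            f"cannot sample {n_to_sample} negatives: only {len(candidates)} "
            f"unlabelled pairs exist (maximum achievable ratio "
            f"{(len(candidates) + len(curated)) // max(len(positives), 1)})"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n_to_sample, replace=False)
    sampled = {candidates[k] for k in chosen}
    provenance: dict[Pair, str] = {p: "curated_positive" for p in positives}
    provenance.update({p: "curated_ineffective" for p in curated})
    provenance.update({p: "sampled_negative" for p in sampled})
    return LabeledPairSet(positives, curated | sampled, provenance)


def _labelled_scores(
    scores: Iterable[PairScore], labels: LabeledPairSet
) -> tuple[np.ndarray, np.ndarray]:
    """Score arrays for (positives, negatives); every pair must be scored."""
    by_pair = scores_by_pair(scores)
    missing = sorted((labels.positives | labels.negatives) - by_pair.keys())
    if missing:
        raise DataError(f"labelled pairs without a score: {missing}")
    if not labels.positives or not labels.negatives:
        raise DataError("evaluation needs at least one positive and one negative pair")
    pos = np.array([by_pair[p] for p in sorted(labels.positives)])
    neg = np.array([by_pair[p] for p in sorted(labels.negatives)])
    return pos, neg


def roc_curve(scores: Iterable[PairScore], labels: LabeledPairSet) -> RocResult:
    """Threshold-sweep ROC: positive call iff score strictly exceeds t."""
    pos, neg = _labelled_scores(scores, labels)
    all_scores = np.concatenate([pos, neg])
    thresholds = [np.inf, *sorted(set(all_scores.tolist()), reverse=True), -np.inf]
    points = []
    for t in thresholds:
        tp = int(np.sum(pos > t))
        fp = int(np.sum(neg > t))
        points.append((fp / len(neg), tp / len(pos)))
    fpr = np.array([p[0] for p in points])
    tpr = np.array([p[1] for p in points])
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(tuple(points), tuple(float(t) for t in thresholds), auc)


def auc_rank(scores: Iterable[PairScore], labels: LabeledPairSet) -> float:
    """Mann-Whitney AUC: P(random positive > random negative), ties at 0.5."""
    pos, neg = _labelled_scores(scores, labels)
    ranks = rankdata(np.concatenate([pos, neg]))
    rank_sum = float(ranks[: len(pos)].sum())
    return (rank_sum - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg))


def evaluate_method(
    drugs: Iterable[DrugRecord],
    labels: LabeledPairSet,
    method: str,
    distances=None,
    target_network=None,
    config: ScoreConfig = ScoreConfig(),
) -> tuple[list[PairScore], RocResult]:
    """Score the labelled pairs with one method and build its ROC."""
    scores = score_all_pairs(
        list(drugs), labels.all_pairs(), method, distances, target_network, config
    )
    return scores, roc_curve(scores, labels)


def sweep(
    universe: PathwayUniverse,
    drugs: Iterable[DrugRecord],
    labels: LabeledPairSet,
    C_values: Sequence[float],
    p_values: Sequence[float],
    sidedness: str = "greater",
) -> SweepResult:
    """AUC of the flagship score over a (C, p_threshold) grid.

    Pairwise overlap p-values are computed once; each p_threshold re-cuts
    the network and recomputes distances, which are then shared across all
    C values.
    """
    if not C_values or not p_values:
        raise ConfigError("sweep needs non-empty C and p grids")
    drugs = list(drugs)
    base = build_network(universe, p_threshold=float(p_values[0]), sidedness=sidedness)
    grid = []
    aucs: dict[tuple[float, float], float] = {}
    for p in p_values:
        network = base.rethreshold(float(p))
        distances = all_pairs_shortest_paths(network)
        for C in C_values:
            config = ScoreConfig(same_pathway_distance_C=float(C), p_threshold=float(p))
            scores = score_all_pairs(drugs, labels.all_pairs(), "hprna", distances, None, config)
            grid.append((float(C), float(p)))
            aucs[(float(C), float(p))] = auc_rank(scores, labels)
    return SweepResult(tuple(grid), aucs)
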