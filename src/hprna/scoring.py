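"""Drug-pair synergy scores.

The flagship score aggregates pathway-pathway distances over the ordered
product of the two drugs' pathway sets:

    x = sum over (p, q) in P_A x P_B of d(p, q)
    d(p, q) = C                 if p == q (same pathway ID)
            = SPL(p, q, G)      if q is reachable from p
            = 0 (skipped)       if q is unreachable
    SCORE(A, B) = exp(-x / (|P_A| * |P_B|))

C is a tunable same-pathway distance; negative values reward drug pairs
that act on identical pathways, so scores may exceed 1 and are to be read
as ranks, not probabilities.  The four baselines either replace the C term
(PathDis, TarDis: same aggregation with a same-node distance of 0, on the
pathway or target network) or drop the network altogether (TarOverlap,
PathOverlap: cosine similarity of the raw ID sets).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .datamodel import ConfigError, DataError, DrugRecord, Pair, TargetNetwork, ordered_pair
from .network import DistanceMatrix, distance_matrix_from_edges

METHODS = ("hprna", "tar_overlap", "tar_dis", "path_overlap", "path_dis")


@dataclass(frozen=True)
class ScoreConfig:
    """Scoring hyperparameters.

    ``same_pathway_distance_C`` is the dimensionless distance substituted
    when the two drugs act on the identical pathway; ``p_threshold`` is the
    network cut-off carried along for provenance in summaries.
    """

    same_pathway_distance_C: float = -100.0
    p_threshold: float = 0.001

    def __post_init__(self) -> None:
        if not math.isfinite(self.same_pathway_distance_C):
            raise ConfigError("same-pathway distance C must be finite")


@dataclass(frozen=True)
class PairScore:
    drug_a: str
    drug_b: str
    score: float
    method: str


def _mean_distance_exponent(
    set_a: Iterable[str],
    set_b: Iterable[str],
    distances: DistanceMatrix,
    same_node_distance: float,
) -> float:
    set_a, set_b = frozenset(set_a), frozenset(set_b)
    idx = distances.index
    missing = sorted((set_a | set_b) - idx.keys())
    if missing:
        raise DataError(f"nodes not in distance matrix: {missing}")
    values = distances.values
    x = 0.0
    for p in set_a:
        row = values[idx[p]]
        for q in set_b:
            if p == q:
                x += same_node_distance
            else:
                d = row[idx[q]]
                if math.isfinite(d):
                    x += d
                # unreachable pairs contribute nothing
    return x / (len(set_a) * len(set_b))


def hprna_score(
    drug_a: DrugRecord,
    drug_b: DrugRecord,
    distances: DistanceMatrix,
    config: ScoreConfig = ScoreConfig(),
) -> PairScore:
    """Pathway-distance synergy score with same-pathway distance C."""
    for drug in (drug_a, drug_b):
        if not drug.pathway_ids:
            raise DataError(f"drug {drug.drug_id!r} has no pathways and cannot be scored")
    x = _mean_distance_exponent(
        drug_a.pathway_ids, drug_b.pathway_ids, distances, config.same_pathway_distance_C
    )
    return PairScore(drug_a.drug_id, drug_b.drug_id, math.exp(-x), "hprna")


def cosine_set_similarity(set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """|A & B| / sqrt(|A| * |B|) for two non-empty ID sets."""
    set_a, set_b = frozenset(set_a), frozenset(set_b)
    if not set_a or not set_b:
        raise DataError("cosine similarity of an empty set is undefined")
    return len(set_a & set_b) / math.sqrt(len(set_a) * len(set_b))


def mean_network_distance_score(
    set_a: Iterable[str],
    set_b: Iterable[str],
    distances: DistanceMatrix,
    same_node_distance: float = 0.0,
) -> float:
    """exp(-mean network distance) with the same aggregation as hprna_score."""
    set_a, set_b = frozenset(set_a), frozenset(set_b)
    if not set_a or not set_b:
        raise DataError("mean network distance of an empty set is undefined")
    return math.exp(-_mean_distance_exponent(set_a, set_b, distances, same_node_distance))


def _required_sets(drug: DrugRecord, method: str) -> frozenset[str]:
    return drug.pathway_ids if method in ("hprna", "path_overlap", "path_dis") else drug.targets


def score_all_pairs(
    drugs: Iterable[DrugRecord],
    pairs: Iterable[Pair],
    method: str,
    distances: Optional[DistanceMatrix] = None,
    target_network: Optional[TargetNetwork] = None,
    config: ScoreConfig = ScoreConfig(),
) -> list[PairScore]:
    """Score every requested unordered pair with one method.

    Validation runs before any scoring: self-pairs, unknown drugs and drugs
    lacking the sets the method needs are all reported at once.
    """
    if method not in METHODS:
        raise ConfigError(f"unknown method {method!r}; choose from {METHODS}")
    if method in ("hprna", "path_dis") and distances is None:
        raise ConfigError(f"method {method!r} needs a pathway distance matrix")
    if method == "tar_dis" and target_network is None:
        raise ConfigError("method 'tar_dis' needs a target network")
    by_id = {d.drug_id: d for d in drugs}
    canonical = [ordered_pair(a, b) for a, b in pairs]
    unknown = sorted({d for pair in canonical for d in pair if d not in by_id})
    if unknown:
        raise DataError(f"pairs reference unknown drugs: {unknown}")
    unscorable = sorted(
        {d for pair in canonical for d in pair if not _required_sets(by_id[d], method)}
    )
    if unscorable:
        kind = "pathway" if method in ("hprna", "path_overlap", "path_dis") else "target"
        raise DataError(f"drugs without {kind} sets cannot be scored by {method!r}: {unscorable}")

    target_distances: Optional[DistanceMatrix] = None
    if method == "tar_dis":
        assert target_network is not None
        target_distances = distance_matrix_from_edges(
            set(target_network.nodes) | {t for d in by_id.values() for t in d.targets},
            target_network.edges,
        )

    out: list[PairScore] = []
    for a, b in canonical:
        da, db = by_id[a], by_id[b]
        if method == "hprna":
            assert distances is not None
            score = hprna_score(da, db, distances, config).score
        elif method == "tar_overlap":
            score = cosine_set_similarity(da.targets, db.targets)
        elif method == "path_overlap":
            score = cosine_set_similarity(da.pathway_ids, db.pathway_ids)
        elif method == "path_dis":
            assert distances is not None
            score = mean_network_distance_score(da.pathway_ids, db.pathway_ids, distances, 0.0)
        else:  # tar_dis
            assert target_distances is not None
            score = mean_network_distance_score(da.targets, db.targets, target_distances, 0.0)
        out.append(PairScore(a, b, score, method))
    out.sort(key=lambda s: (-s.score, s.drug_a, s.drug_b))
    return out


def write_scores(scores: Sequence[PairScore], path: str | os.PathLike) -> None:
    """TSV sorted by descending score with lexicographic tie-breaking."""
    ordered = sorted(scores, key=lambda s: (-s.score, s.drug_a, s.drug_b))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug_a\tdrug_b\tmethod\tscore\n")
        for s in ordered:
            fh.write(f"{s.drug_a}\t{s.drug_b}\t{s.method}\t{s.score:.12g}\n")


def read_scores(path: str | os.PathLike) -> list[PairScore]:
    scores = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["drug_a", "drug_b", "method", "score"]:
            raise DataError(f"{path}: unexpected score-table header {header}")
        for line in fh:
            if line.strip():
                a, b, method, score = line.rstrip("\n").split("\t")
                scores.append(PairScore(a, b, float(score), method))
    return scores


def scores_by_pair(scores: Iterable[PairScore]) -> Mapping[Pair, float]:
    """Index scores by canonical pair; duplicate pairs are an error."""
    out: dict[Pair, float] = {}
    for s in scores:
        pair = ordered_pair(s.drug_a, s.drug_b)
        if pair in out:
            raise DataError(f"duplicate score for pair {pair}")
        out[pair] = s.score
    return out
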