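"""Core domain types for pathway-based drug-combination scoring.

The central objects are a :class:`PathwayUniverse` (named gene sets plus the
size ``M`` of their union), :class:`DrugRecord` (a drug with its target set
and the pathway set derived from those targets), :class:`LabeledPairSet`
(positive / negative drug pairs for evaluation) and :class:`TargetNetwork`
(an optional protein-protein style interaction graph over targets).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx

#: Canonical unordered drug pair: a lexicographically sorted 2-tuple.
Pair = tuple[str, str]

#: Allowed provenance tags for labelled pairs.
PROVENANCE_TAGS = ("curated_positive", "curated_ineffective", "sampled_negative")


class HprnaError(Exception):
    """Base class for package errors."""


class DataError(HprnaError):
    """Invalid or inconsistent domain data."""


class ConfigError(HprnaError):
    """Invalid configuration or unusable parameter combination."""


def ordered_pair(a: str, b: str) -> Pair:
    """Canonicalise an unordered drug pair; self-pairs are rejected."""
    if a == b:
        raise DataError(f"self-pair ({a!r}, {a!r}) is not a valid drug pair")
    return (a, b) if a < b else (b, a)


class PathwayUniverse:
    """An ordered collection of pathways, each a non-empty gene set.

    ``M`` is the number of distinct genes in the union of all gene sets; it
    is the population size of the 2x2 contingency tables used to test
    pathway-pathway overlap and is invariant under pathway reordering.
    """

    def __init__(self, pathways: Iterable[tuple[str, Iterable[str]]]):
        seen: dict[str, frozenset[str]] = {}
        for pid, genes in pathways:
            if pid in seen:
                raise DataError(f"duplicate pathway id {pid!r}")
            gene_set = frozenset(genes)
            if not gene_set:
                raise DataError(f"pathway {pid!r} has an empty gene set")
            seen[pid] = gene_set
        if not seen:
            raise DataError("a pathway universe needs at least one pathway")
        self._pathways = seen
        self._ids = tuple(seen)
        self._universe = frozenset().union(*seen.values())

    @property
    def pathway_ids(self) -> tuple[str, ...]:
        return self._ids

    @property
    def M(self) -> int:
        """Size of the union of all gene sets."""
        return len(self._universe)

    def gene_universe(self) -> frozenset[str]:
        return self._universe

    def genes(self, pathway_id: str) -> frozenset[str]:
        try:
            return self._pathways[pathway_id]
        except KeyError:
            raise DataError(f"unknown pathway id {pathway_id!r}") from None

    def items(self) -> Iterator[tuple[str, frozenset[str]]]:
        return iter(self._pathways.items())

    def __len__(self) -> int:
        return len(self._ids)

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self._pathways

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PathwayUniverse(n_pathways={len(self)}, M={self.M})"


@dataclass(frozen=True)
class DrugRecord:
    """A drug with its target set and the pathway set those targets map to.

    Drugs whose pathway set is empty are kept through I/O (so provenance is
    not silently lost) but are not admissible to pathway-based scoring.
    """

    drug_id: str
    targets: frozenset[str] = frozenset()
    pathway_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.drug_id:
            raise DataError("drug_id must be non-empty")
        object.__setattr__(self, "targets", frozenset(self.targets))
        object.__setattr__(self, "pathway_ids", frozenset(self.pathway_ids))

    @property
    def scorable(self) -> bool:
        """Whether the drug can enter pathway-based scoring."""
        return bool(self.pathway_ids)


@dataclass(frozen=True)
class LabeledPairSet:
    """Positive and negative drug pairs with per-pair provenance.

    Negatives are the union of curated ineffective combinations and randomly
    sampled non-positive pairs; positives and negatives are disjoint and
    contain no self-pairs by construction of :func:`ordered_pair`.
    """

    positives: frozenset[Pair]
    negatives: frozenset[Pair]
    provenance: Mapping[Pair, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pos = frozenset(ordered_pair(*p) for p in self.positives)
        neg = frozenset(ordered_pair(*p) for p in self.negatives)
        overlap = pos & neg
        if overlap:
            raise DataError(f"pairs labelled both positive and negative: {sorted(overlap)}")
        bad_tags = {t for t in dict(self.provenance).values() if t not in PROVENANCE_TAGS}
        if bad_tags:
            raise DataError(f"unknown provenance tags: {sorted(bad_tags)}")
        object.__setattr__(self, "positives", pos)
        object.__setattr__(self, "negatives", neg)
        object.__setattr__(self, "provenance", dict(self.provenance))

    @property
    def n_pos(self) -> int:
        return len(self.positives)

    @property
    def n_neg(self) -> int:
        return len(self.negatives)

    def all_pairs(self) -> list[Pair]:
        """All labelled pairs, positives first, deterministic order."""
        return sorted(self.positives) + sorted(self.negatives)

    def drug_ids(self) -> frozenset[str]:
        return frozenset(d for pair in self.positives | self.negatives for d in pair)


class TargetNetwork:
    """Simple undirected interaction graph over target IDs (no self-loops)."""

    def __init__(self, nodes: Iterable[str], edges: Iterable[tuple[str, str]]):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for u, v in edges:
            if u == v:
                raise DataError(f"self-loop on target {u!r} not allowed")
            g.add_edge(u, v)
        self._graph = g

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self._graph.nodes))

    @property
    def edges(self) -> tuple[Pair, ...]:
        return tuple(sorted(ordered_pair(u, v) for u, v in self._graph.edges))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"TargetNetwork(n_nodes={self._graph.number_of_nodes()}, "
            f"n_edges={self._graph.number_of_edges()})"
        )
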