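"""Pathway relationship network: gene-set overlap tests and shortest paths.

Two pathways are connected when the overlap of their gene sets is
significant under Fisher's exact test on the 2x2 table

    =================  ===========  ===========
                       in G_j       not in G_j
    =================  ===========  ===========
    in G_i             a            b
    not in G_i         c            d
    =================  ===========  ===========

with population size ``M = a+b+c+d`` equal to the size of the union of all
gene sets in the universe.  The point probability of a table is the
hypergeometric mass

    p = (a+b)! (c+d)! (a+c)! (b+d)! / (a! b! c! d! M!)

and the one-sided "greater" p-value sums that mass over all tables with the
same margins and an intersection at least as large as the observed one.
Edges carry unit length; distances between pathways are unweighted
shortest-path lengths computed with the Floyd-Warshall recurrence.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np
from scipy.special import gammaln

from .datamodel import ConfigError, DataError, PathwayUniverse

SIDEDNESS = ("greater", "point")


@dataclass(frozen=True)
class ContingencyCounts:
    """Gene counts of the 2x2 overlap table for one pathway pair."""

    a: int  # |G_i & G_j|
    b: int  # |G_i - G_j|
    c: int  # |G_j - G_i|
    d: int  # M - |G_i | G_j|

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise DataError(f"contingency count {name}={v!r} must be a non-negative integer")

    @property
    def M(self) -> int:
        return self.a + self.b + self.c + self.d


def contingency(universe: PathwayUniverse, i: str, j: str) -> ContingencyCounts:
    """Overlap table for pathways ``i`` and ``j`` against the universe's M."""
    if i == j:
        raise DataError(f"contingency table of a pathway with itself ({i!r}) is undefined")
    gi, gj = universe.genes(i), universe.genes(j)
    a = len(gi & gj)
    return ContingencyCounts(a, len(gi) - a, len(gj) - a, universe.M - len(gi | gj))


def _log_point_probability(a, ab, ac, M):
    """log of the hypergeometric mass at intersection ``a`` (vectorised)."""
    a = np.asarray(a, dtype=float)
    b = ab - a
    c = ac - a
    d = M - ab - ac + a
    return (
        gammaln(ab + 1)
        + gammaln(c + d + 1)
        + gammaln(ac + 1)
        + gammaln(b + d + 1)
        - gammaln(a + 1)
        - gammaln(b + 1)
        - gammaln(c + 1)
        - gammaln(d + 1)
        - gammaln(M + 1)
    )


def fisher_point_probability(counts: ContingencyCounts) -> float:
    """Probability of the observed table itself, in log-space for stability."""
    p = math.exp(
        float(_log_point_probability(counts.a, counts.a + counts.b, counts.a + counts.c, counts.M))
    )
    return min(max(p, 0.0), 1.0)


def _greater_tail(a, ab, ac, M):
    """P(intersection >= a) over tables with fixed margins (vectorised)."""
    a = np.asarray(a, dtype=float)
    ab = np.broadcast_to(np.asarray(ab, dtype=float), a.shape).copy()
    ac = np.broadcast_to(np.asarray(ac, dtype=float), a.shape).copy()
    amax = np.minimum(ab, ac)
    total = np.zeros_like(a)
    span = int(np.max(amax - a)) if a.size else 0
    for k in range(span + 1):
        ak = a + k
        mask = ak <= amax
        if not mask.any():
            break
        term = np.where(mask, np.exp(_log_point_probability(ak, ab, ac, M)), 0.0)
        total += term
    total = np.clip(total, 0.0, 1.0)
    # a full-support sum is exactly 1 up to rounding; snap it so the strict
    # p < threshold rule at threshold 1.0 behaves as the definition intends
    total[total >= 1.0 - 1e-12] = 1.0
    return total


def fisher_pvalue(counts: ContingencyCounts, sidedness: str = "greater") -> float:
    """Fisher p-value for over-enrichment ("greater") or the point mass."""
    if sidedness not in SIDEDNESS:
        raise ConfigError(f"sidedness must be one of {SIDEDNESS}, got {sidedness!r}")
    if sidedness == "point":
        return fisher_point_probability(counts)
    p = _greater_tail(
        np.array([counts.a]),
        np.array([counts.a + counts.b]),
        np.array([counts.a + counts.c]),
        counts.M,
    )
    return float(p[0])


@dataclass(frozen=True)
class PathwayNetwork:
    """Thresholded pathway relationship graph with cached pairwise p-values.

    Nodes are all pathways of the universe, including isolated ones; an
    undirected unit-length edge joins pathways whose p-value is strictly
    below ``p_threshold``.  The full symmetric p-value matrix is retained so
    the threshold can be re-swept without recomputing the tests.
    """

    ids: tuple[str, ...]
    pvalues: np.ndarray  # symmetric, diagonal NaN
    p_threshold: float
    sidedness: str

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold <= 1.0:
            raise ConfigError(f"p_threshold must be in (0, 1], got {self.p_threshold}")

    @property
    def index(self) -> dict[str, int]:
        return {pid: k for k, pid in enumerate(self.ids)}

    def pvalue(self, i: str, j: str) -> float:
        idx = self.index
        return float(self.pvalues[idx[i], idx[j]])

    @property
    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.ids)
        ii, jj = np.nonzero(np.triu(self.pvalues < self.p_threshold, k=1))
        for u, v in zip(ii, jj):
            g.add_edge(self.ids[u], self.ids[v])
        return g

    def edges(self) -> list[tuple[str, str]]:
        ii, jj = np.nonzero(np.triu(self.pvalues < self.p_threshold, k=1))
        return sorted((self.ids[u], self.ids[v]) for u, v in zip(ii, jj))

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.pvalues < self.p_threshold, k=1)))

    def rethreshold(self, p_threshold: float) -> "PathwayNetwork":
        """Same tests, different cut-off; no p-values recomputed."""
        return PathwayNetwork(self.ids, self.pvalues, p_threshold, self.sidedness)


def pairwise_pvalues(universe: PathwayUniverse, sidedness: str = "greater") -> tuple[tuple[str, ...], np.ndarray]:
    """Symmetric matrix of overlap p-values for all pathway pairs."""
    if sidedness not in SIDEDNESS:
        raise ConfigError(f"sidedness must be one of {SIDEDNESS}, got {sidedness!r}")
    ids = universe.pathway_ids
    genes = sorted(universe.gene_universe())
    gene_index = {g: k for k, g in enumerate(genes)}
    member = np.zeros((len(ids), len(genes)), dtype=np.int32)
    for r, (pid, gene_set) in enumerate(universe.items()):
        for g in gene_set:
            member[r, gene_index[g]] = 1
    inter = member @ member.T  # a_ij
    sizes = member.sum(axis=1)  # |G_i|
    M = universe.M
    iu, ju = np.triu_indices(len(ids), k=1)
    a = inter[iu, ju].astype(float)
    ab = sizes[iu].astype(float)
    ac = sizes[ju].astype(float)
    if sidedness == "point":
        p = np.clip(np.exp(_log_point_probability(a, ab, ac, M)), 0.0, 1.0)
    else:
        p = _greater_tail(a, ab, ac, M)
    mat = np.full((len(ids), len(ids)), np.nan)
    mat[iu, ju] = p
    mat[ju, iu] = p
    return ids, mat


def build_network(
    universe: PathwayUniverse,
    p_threshold: float = 0.001,
    sidedness: str = "greater",
) -> PathwayNetwork:
    """Test every pathway pair and keep edges with p strictly below threshold."""
    ids, pvals = pairwise_pvalues(universe, sidedness)
    return PathwayNetwork(ids, pvals, p_threshold, sidedness)


@dataclass(frozen=True)
class DistanceMatrix:
    """All-pairs shortest-path lengths; ``inf`` marks unreachable pairs."""

    ids: tuple[str, ...]
    values: np.ndarray

    @property
    def index(self) -> dict[str, int]:
        return {pid: k for k, pid in enumerate(self.ids)}

    def distance(self, i: str, j: str) -> float:
        idx = self.index
        try:
            return float(self.values[idx[i], idx[j]])
        except KeyError as exc:
            raise DataError(f"node {exc.args[0]!r} not in distance matrix") from None

    def __contains__(self, node: str) -> bool:
        return node in self.index

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(["pathway_id", *self.ids]) + "\n")
            for k, pid in enumerate(self.ids):
                row = ("inf" if math.isinf(v) else str(int(v)) for v in self.values[k])
                fh.write("\t".join([pid, *row]) + "\n")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "DistanceMatrix":
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            ids = tuple(header[1:])
            values = np.full((len(ids), len(ids)), np.inf)
            for k, line in enumerate(fh):
                fields = line.rstrip("\n").split("\t")
                values[k] = [float(v) for v in fields[1:]]
        return cls(ids, values)


def floyd_warshall(adjacency: np.ndarray) -> np.ndarray:
    """Floyd-Warshall dynamic programme on a weight matrix.

    Applies ``D[i][j] <- min(D[i][j], D[i][k] + D[k][j])`` for every
    intermediate vertex ``k``; entries start at the edge weights, the
    diagonal at 0, and missing edges at ``inf``.
    """
    D = np.array(adjacency, dtype=float)
    n = D.shape[0]
    np.fill_diagonal(D, 0.0)
    for k in range(n):
        np.minimum(D, D[:, k, None] + D[None, k, :], out=D)
    return D


def all_pairs_shortest_paths(network: PathwayNetwork) -> DistanceMatrix:
    """Unit-length all-pairs shortest paths of the thresholded graph."""
    n = len(network.ids)
    adj = np.full((n, n), np.inf)
    edge_mask = network.pvalues < network.p_threshold
    adj[edge_mask] = 1.0
    return DistanceMatrix(network.ids, floyd_warshall(adj))


def distance_matrix_from_edges(nodes: Iterable[str], edges: Iterable[tuple[str, str]]) -> DistanceMatrix:
    """Shortest-path matrix of an arbitrary unit-length undirected graph."""
    ids = tuple(sorted(nodes))
    index = {n: k for k, n in enumerate(ids)}
    adj = np.full((len(ids), len(ids)), np.inf)
    for u, v in edges:
        adj[index[u], index[v]] = 1.0
        adj[index[v], index[u]] = 1.0
    return DistanceMatrix(ids, floyd_warshall(adj))


def write_network(network: PathwayNetwork, edges_path: str | os.PathLike, nodes_path: str | os.PathLike) -> None:
    """Edge list with p-values plus a node list (isolated nodes survive)."""
    idx = network.index
    with open(edges_path, "w", encoding="utf-8") as fh:
        fh.write("pathway_a\tpathway_b\tp_value\n")
        for u, v in network.edges():
            fh.write(f"{u}\t{v}\t{network.pvalues[idx[u], idx[v]]:.6e}\n")
    with open(nodes_path, "w", encoding="utf-8") as fh:
        fh.write("pathway_id\n")
        for pid in network.ids:
            fh.write(pid + "\n")


def read_network_edges(edges_path: str | os.PathLike, nodes_path: str | os.PathLike) -> tuple[tuple[str, ...], list[tuple[str, str]]]:
    """Read back the node list and edge list written by :func:`write_network`."""
    with open(nodes_path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    ids = tuple(line for line in lines[1:] if line)
    edges = []
    with open(edges_path, "r", encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            if line.strip():
                u, v, _p = line.rstrip("\n").split("\t")
                edges.append((u, v))
    return ids, edges
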