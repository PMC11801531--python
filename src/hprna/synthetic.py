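"""Synthetic benchmark generator with planted synergistic drug pairs.

The generator emulates the structure of a curated drug-combination corpus:
a gene universe; pathways organised into overlap clusters (pathways in the
same cluster share a core gene block, so the overlap test links them at
distance 1); bridge gene blocks between consecutive clusters that chain the
clusters into one connected pathway network with large between-cluster
distances; targets that each map to one pathway; drugs whose pathway sets
derive from their targets; and labelled drug pairs.

Positive pairs are planted within a cluster under one of two mechanisms:

* ``same_pathway`` — both drugs receive a target on one common pathway, so
  every positive pair shares at least one pathway ID (the C term fires);
* ``adjacent_pathway`` — the two drugs draw targets from disjoint pathway
  halves of their cluster, so positives share no pathway ID but their
  pathways sit at network distance 1 (only the distance term fires).

Negatives (curated "ineffective" pairs plus the random sample) are drawn
from drug pairs whose home clusters are at least two apart, i.e. pairs with
distant pathway sets.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from . import io as hio
from .datamodel import (
    ConfigError,
    DrugRecord,
    LabeledPairSet,
    Pair,
    PathwayUniverse,
    TargetNetwork,
)

MECHANISMS = ("same_pathway", "adjacent_pathway")

#: File names emitted by :func:`write_synthetic_dataset`.
DATASET_FILES = {
    "gene_sets": "pathways.gmt",
    "drug_targets": "drug_targets.tsv",
    "drug_pathways": "drug_pathways.tsv",
    "target_pathways": "target_pathways.tsv",
    "labels": "labels.tsv",
    "target_network": "target_network.tsv",
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-scale defaults: 94 drugs, 94 positive pairs, 12 ineffective
    pairs, a 1:5 positive:negative ratio and a 330-pathway universe."""

    n_genes: int = 5000
    n_pathways: int = 330
    genes_per_pathway: int = 40
    n_clusters: int = 20
    within_cluster_shared_frac: float = 0.5
    n_drugs: int = 94
    targets_per_drug: int = 3
    n_planted_positive_pairs: int = 94
    mechanism: str = "same_pathway"
    negative_ratio: int = 5
    n_ineffective_pairs: int = 12

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ConfigError(f"mechanism must be one of {MECHANISMS}, got {self.mechanism!r}")
        if self.n_pathways < 2 * self.n_clusters:
            raise ConfigError("need at least two pathways per cluster")
        if self.n_clusters < 3:
            raise ConfigError("need at least three clusters so distant negative pairs exist")
        if not 0.0 < self.within_cluster_shared_frac < 1.0:
            raise ConfigError("within_cluster_shared_frac must be in (0, 1)")
        if self.genes_per_pathway > self.n_genes:
            raise ConfigError("genes_per_pathway cannot exceed the gene universe")
        n_core = round(self.genes_per_pathway * self.within_cluster_shared_frac)
        if n_core < 1 or n_core > self.genes_per_pathway - n_core:
            raise ConfigError("shared core must fit alongside the private gene block")
        if self.n_planted_positive_pairs < 1 or self.n_drugs < 2:
            raise ConfigError("need at least one planted pair and two drugs")
        if self.negative_ratio < 1:
            raise ConfigError("negative_ratio must be a positive integer")
        if self.n_ineffective_pairs > self.negative_ratio * self.n_planted_positive_pairs:
            raise ConfigError("curated ineffective pairs exceed the negative quota")


def _cluster_blocks(n_pathways: int, n_clusters: int) -> list[list[int]]:
    """Contiguous near-equal split of pathway indices into clusters."""
    bounds = np.linspace(0, n_pathways, n_clusters + 1).astype(int)
    return [list(range(bounds[c], bounds[c + 1])) for c in range(n_clusters)]


def generate_synthetic_dataset(
    config: SyntheticConfig, seed: int
) -> tuple[PathwayUniverse, list[DrugRecord], LabeledPairSet, TargetNetwork]:
    """Generate a reproducible benchmark; identical for identical seeds."""
    rng = np.random.default_rng(seed)
    gene_names = np.array([f"g{k:05d}" for k in range(config.n_genes)])
    pathway_ids = [f"PW{k:04d}" for k in range(config.n_pathways)]
    clusters = _cluster_blocks(config.n_pathways, config.n_clusters)
    cluster_of = {q: c for c, block in enumerate(clusters) for q in block}

    n_core = round(config.genes_per_pathway * config.within_cluster_shared_frac)
    n_private = config.genes_per_pathway - n_core

    cores = [rng.choice(config.n_genes, size=n_core, replace=False) for _ in clusters]
    bridges = [rng.choice(config.n_genes, size=n_core, replace=False) for _ in clusters[:-1]]

    gene_sets: list[tuple[str, list[str]]] = []
    for q, pid in enumerate(pathway_ids):
        c = cluster_of[q]
        private = rng.choice(config.n_genes, size=n_private, replace=False)
        genes = set(gene_names[cores[c]]) | set(gene_names[private])
        # bridge blocks replace the private genes of the two endpoint pathways
        if q == clusters[c][-1] and c + 1 < config.n_clusters:
            genes = set(gene_names[cores[c]]) | set(gene_names[bridges[c]])
        elif q == clusters[c][0] and c > 0:
            genes = set(gene_names[cores[c]]) | set(gene_names[bridges[c - 1]])
        gene_sets.append((pid, sorted(genes)))
    universe = PathwayUniverse(gene_sets)

    # one pathway per target, two targets per pathway
    target_to_pathways = {f"T_{pid}_{k}": frozenset({pid}) for pid in pathway_ids for k in (0, 1)}
    targets_of_pathway = {pid: [f"T_{pid}_0", f"T_{pid}_1"] for pid in pathway_ids}

    drug_ids = [f"D{k:03d}" for k in range(config.n_drugs)]
    home_cluster = {d: k % config.n_clusters for k, d in enumerate(drug_ids)}
    drug_targets: dict[str, set[str]] = {}
    for k, d in enumerate(drug_ids):
        block = clusters[home_cluster[d]]
        if config.mechanism == "adjacent_pathway":
            half = len(block) // 2
            # alternate rounds of the round-robin fall in opposite halves
            block = block[:half] if (k // config.n_clusters) % 2 == 0 else block[half:]
        pool = [t for q in block for t in targets_of_pathway[pathway_ids[q]]]
        size = min(config.targets_per_drug, len(pool))
        picks = rng.choice(len(pool), size=size, replace=False)
        drug_targets[d] = {pool[i] for i in picks}

    # plant positive pairs within clusters
    if config.mechanism == "same_pathway":
        candidates = [
            (a, b)
            for a, b in itertools.combinations(drug_ids, 2)
            if home_cluster[a] == home_cluster[b]
        ]
    else:
        half_of = {}
        for k, d in enumerate(drug_ids):
            half_of[d] = (k // config.n_clusters) % 2
        candidates = [
            (a, b)
            for a, b in itertools.combinations(drug_ids, 2)
            if home_cluster[a] == home_cluster[b] and half_of[a] != half_of[b]
        ]
    if config.n_planted_positive_pairs > len(candidates):
        raise ConfigError(
            f"infeasible config: {config.n_planted_positive_pairs} planted pairs "
            f"requested but only {len(candidates)} eligible drug pairs exist"
        )
    chosen = rng.choice(len(candidates), size=config.n_planted_positive_pairs, replace=False)
    positives = {candidates[i] for i in chosen}
    if config.mechanism == "same_pathway":
        for a, b in sorted(positives):
            block = clusters[home_cluster[a]]
            q = pathway_ids[block[rng.integers(len(block))]]
            shared = targets_of_pathway[q][0]
            drug_targets[a].add(shared)
            drug_targets[b].add(shared)

    # negatives: pairs whose home clusters are far apart
    far = [
        (a, b)
        for a, b in itertools.combinations(drug_ids, 2)
        if abs(home_cluster[a] - home_cluster[b]) >= 2
    ]
    quota = config.negative_ratio * config.n_planted_positive_pairs
    if quota > len(far):
        raise ConfigError(
            f"infeasible config: {quota} negatives requested but only "
            f"{len(far)} distant drug pairs exist"
        )
    chosen_neg = rng.choice(len(far), size=quota, replace=False)
    negatives = [far[i] for i in chosen_neg]
    provenance: dict[Pair, str] = {p: "curated_positive" for p in positives}
    for k, pair in enumerate(negatives):
        provenance[pair] = (
            "curated_ineffective" if k < config.n_ineffective_pairs else "sampled_negative"
        )
    labels = LabeledPairSet(frozenset(positives), frozenset(negatives), provenance)

    base = [DrugRecord(d, frozenset(drug_targets[d]), frozenset()) for d in drug_ids]
    drugs = hio.derive_pathways_from_targets(base, target_to_pathways)

    # target network: targets of one pathway interact; a chain of edges
    # between consecutive pathways keeps the network connected
    edges: list[tuple[str, str]] = []
    for pid in pathway_ids:
        t0, t1 = targets_of_pathway[pid]
        edges.append((t0, t1))
    for q in range(config.n_pathways - 1):
        edges.append((targets_of_pathway[pathway_ids[q]][0], targets_of_pathway[pathway_ids[q + 1]][0]))
    target_network = TargetNetwork(sorted(target_to_pathways), edges)

    return universe, drugs, labels, target_network


def write_synthetic_dataset(
    outdir: str | os.PathLike,
    universe: PathwayUniverse,
    drugs: Iterable[DrugRecord],
    labels: LabeledPairSet,
    target_network: TargetNetwork,
    target_to_pathways: dict[str, frozenset[str]] | None = None,
) -> dict[str, str]:
    """Write all dataset files in the formats the readers accept."""
    os.makedirs(outdir, exist_ok=True)
    paths = {key: os.path.join(outdir, name) for key, name in DATASET_FILES.items()}
    hio.write_gene_sets(universe, paths["gene_sets"], format="gmt")
    hio.write_drugs(drugs, paths["drug_targets"], paths["drug_pathways"])
    if target_to_pathways is None:
        target_to_pathways = infer_target_pathway_map(drugs)
    hio.write_target_pathway_map(target_to_pathways, paths["target_pathways"])
    hio.write_labeled_pairs(labels, paths["labels"])
    hio.write_target_network(target_network, paths["target_network"])
    return paths


def infer_target_pathway_map(drugs: Iterable[DrugRecord]) -> dict[str, frozenset[str]]:
    """Recover the target->pathway map from the generator's naming scheme."""
    mapping: dict[str, frozenset[str]] = {}
    for drug in drugs:
        for t in drug.targets:
            # targets are named T_<pathway>_<k>
            pid = t.split("_")[1]
            mapping[t] = frozenset({pid})
    return mapping


def default_config(**overrides) -> SyntheticConfig:
    """The study-scale configuration with selective overrides."""
    return replace(SyntheticConfig(), **overrides)
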