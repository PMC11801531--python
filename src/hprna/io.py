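"""Readers and writers for the plain-text table formats the tool consumes.

Formats
-------
* Gene sets: GMT (``id<TAB>description<TAB>gene...``, one pathway per line)
  or a two-column TSV ``pathway_id<TAB>gene_id`` with a header row.
* Drug tables: headered TSVs ``drug_id<TAB>target_id`` and
  ``drug_id<TAB>pathway_id``.
* Target-to-pathway map: headered TSV ``target_id<TAB>pathway_id``.
* Labelled pairs: headered TSV ``drug_a<TAB>drug_b<TAB>label`` with label in
  {positive, ineffective, negative}.
* Target network: headered two-column edge-list TSV.

All identifiers are opaque non-empty strings; no database-specific
validation is applied.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

from .datamodel import (
    DataError,
    DrugRecord,
    LabeledPairSet,
    Pair,
    PathwayUniverse,
    TargetNetwork,
    ordered_pair,
)


class ParseError(DataError):
    """A malformed input file; carries file path and 1-based line number."""

    def __init__(self, path: str | os.PathLike, line: int, message: str):
        self.path = str(path)
        self.line = line
        super().__init__(f"{path}:{line}: {message}")


def _read_lines(path: str | os.PathLike) -> list[str]:
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not any(line.strip() for line in lines):
        raise DataError(f"{path}: file is empty")
    return lines


def read_gene_sets(path: str | os.PathLike, format: str = "gmt") -> PathwayUniverse:
    """Read pathway gene sets from a GMT or 2-column TSV file.

    Duplicate genes within a pathway are deduplicated; pathway order is file
    order (first occurrence for the TSV dialect).
    """
    if format not in ("gmt", "tsv"):
        raise ValueError(f"unknown gene-set format {format!r}")
    lines = _read_lines(path)
    if format == "gmt":
        pathways: list[tuple[str, list[str]]] = []
        for lineno, line in enumerate(lines, start=1):
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno, f"GMT row needs >=3 tab-separated fields, got {len(fields)}")
            pid, genes = fields[0], [g for g in fields[2:] if g]
            if not pid:
                raise ParseError(path, lineno, "empty pathway id")
            if not genes:
                raise ParseError(path, lineno, f"pathway {pid!r} lists no genes")
            pathways.append((pid, genes))
        return PathwayUniverse(pathways)
    # TSV dialect: header then (pathway_id, gene_id) rows
    table: dict[str, list[str]] = {}
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(path, lineno, f"expected 2 tab-separated fields, got {len(fields)}")
        if lineno == 1:
            continue  # header
        pid, gene = fields
        if not pid or not gene:
            raise ParseError(path, lineno, "empty pathway or gene id")
        table.setdefault(pid, []).append(gene)
    if not table:
        raise DataError(f"{path}: no gene-set rows after the header")
    return PathwayUniverse(list(table.items()))


def write_gene_sets(universe: PathwayUniverse, path: str | os.PathLike, format: str = "gmt") -> None:
    """Write a universe in GMT or 2-column TSV form (genes sorted per set)."""
    if format not in ("gmt", "tsv"):
        raise ValueError(f"unknown gene-set format {format!r}")
    with open(path, "w", encoding="utf-8") as fh:
        if format == "gmt":
            for pid, genes in universe.items():
                fh.write("\t".join([pid, "na", *sorted(genes)]) + "\n")
        else:
            fh.write("pathway_id\tgene_id\n")
            for pid, genes in universe.items():
                for gene in sorted(genes):
                    fh.write(f"{pid}\t{gene}\n")


def _read_two_column(path: str | os.PathLike, expected_header: tuple[str, str]) -> list[tuple[str, str]]:
    lines = _read_lines(path)
    rows: list[tuple[str, str]] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(path, lineno, f"expected 2 tab-separated fields, got {len(fields)}")
        if lineno == 1:
            if tuple(fields) != expected_header:
                raise ParseError(path, lineno, f"expected header {expected_header}, got {tuple(fields)}")
            continue
        if not fields[0] or not fields[1]:
            raise ParseError(path, lineno, "empty identifier")
        rows.append((fields[0], fields[1]))
    return rows


def read_drugs(targets_path: str | os.PathLike, pathways_path: str | os.PathLike) -> list[DrugRecord]:
    """Read drug->target and drug->pathway tables into DrugRecords.

    A drug appearing in only one of the two files gets an empty set for the
    other; drugs without pathways are returned but are not scorable.
    """
    target_rows = _read_two_column(targets_path, ("drug_id", "target_id"))
    pathway_rows = _read_two_column(pathways_path, ("drug_id", "pathway_id"))
    targets: dict[str, set[str]] = {}
    pathways: dict[str, set[str]] = {}
    for drug, target in target_rows:
        targets.setdefault(drug, set()).add(target)
    for drug, pathway in pathway_rows:
        pathways.setdefault(drug, set()).add(pathway)
    drug_ids = sorted(set(targets) | set(pathways))
    return [
        DrugRecord(d, frozenset(targets.get(d, ())), frozenset(pathways.get(d, ())))
        for d in drug_ids
    ]


def write_drugs(drugs: Iterable[DrugRecord], targets_path: str | os.PathLike, pathways_path: str | os.PathLike) -> None:
    drugs = sorted(drugs, key=lambda d: d.drug_id)
    with open(targets_path, "w", encoding="utf-8") as fh:
        fh.write("drug_id\ttarget_id\n")
        for d in drugs:
            for t in sorted(d.targets):
                fh.write(f"{d.drug_id}\t{t}\n")
    with open(pathways_path, "w", encoding="utf-8") as fh:
        fh.write("drug_id\tpathway_id\n")
        for d in drugs:
            for p in sorted(d.pathway_ids):
                fh.write(f"{d.drug_id}\t{p}\n")


def read_target_pathway_map(path: str | os.PathLike) -> dict[str, frozenset[str]]:
    """Read a ``target_id<TAB>pathway_id`` table into a target->pathways map."""
    rows = _read_two_column(path, ("target_id", "pathway_id"))
    mapping: dict[str, set[str]] = {}
    for target, pathway in rows:
        mapping.setdefault(target, set()).add(pathway)
    return {t: frozenset(ps) for t, ps in mapping.items()}


def write_target_pathway_map(mapping: Mapping[str, Iterable[str]], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("target_id\tpathway_id\n")
        for target in sorted(mapping):
            for pathway in sorted(mapping[target]):
                fh.write(f"{target}\t{pathway}\n")


def derive_pathways_from_targets(
    drugs: Iterable[DrugRecord], target_to_pathways: Mapping[str, Iterable[str]]
) -> list[DrugRecord]:
    """Set each drug's pathway set to the union over its targets' pathways.

    Targets missing from the map contribute nothing, mirroring incomplete
    target-to-pathway annotation; drugs may come out with an empty (and
    hence unscorable) pathway set.
    """
    out = []
    for drug in drugs:
        pathway_ids: set[str] = set()
        for target in drug.targets:
            pathway_ids.update(target_to_pathways.get(target, ()))
        out.append(DrugRecord(drug.drug_id, drug.targets, frozenset(pathway_ids)))
    return out


_LABEL_TO_TAG = {
    "positive": "curated_positive",
    "ineffective": "curated_ineffective",
    "negative": "sampled_negative",
}
_TAG_TO_LABEL = {v: k for k, v in _LABEL_TO_TAG.items()}


def read_labeled_pairs(path: str | os.PathLike) -> LabeledPairSet:
    """Read a ``drug_a<TAB>drug_b<TAB>label`` table."""
    lines = _read_lines(path)
    positives: set[Pair] = set()
    negatives: set[Pair] = set()
    provenance: dict[Pair, str] = {}
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ParseError(path, lineno, f"expected 3 tab-separated fields, got {len(fields)}")
        if lineno == 1:
            if tuple(fields) != ("drug_a", "drug_b", "label"):
                raise ParseError(path, lineno, f"expected header ('drug_a', 'drug_b', 'label'), got {tuple(fields)}")
            continue
        a, b, label = fields
        if label not in _LABEL_TO_TAG:
            raise ParseError(path, lineno, f"unknown label {label!r}")
        try:
            pair = ordered_pair(a, b)
        except DataError as exc:
            raise ParseError(path, lineno, str(exc)) from None
        (positives if label == "positive" else negatives).add(pair)
        provenance[pair] = _LABEL_TO_TAG[label]
    return LabeledPairSet(frozenset(positives), frozenset(negatives), provenance)


def write_labeled_pairs(labels: LabeledPairSet, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug_a\tdrug_b\tlabel\n")
        for pair in sorted(labels.positives):
            fh.write(f"{pair[0]}\t{pair[1]}\tpositive\n")
        for pair in sorted(labels.negatives):
            tag = labels.provenance.get(pair, "sampled_negative")
            fh.write(f"{pair[0]}\t{pair[1]}\t{_TAG_TO_LABEL[tag]}\n")


def read_target_network(path: str | os.PathLike) -> TargetNetwork:
    """Read a two-column edge-list TSV into a TargetNetwork."""
    rows = _read_two_column(path, ("target_a", "target_b"))
    nodes = sorted({t for row in rows for t in row})
    return TargetNetwork(nodes, rows)


def write_target_network(network: TargetNetwork, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("target_a\ttarget_b\n")
        for u, v in network.edges:
            fh.write(f"{u}\t{v}\n")
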