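"""Readers/writers for the pipeline's external formats and its core tabular types.

Formats are deliberately minimal and text-based: two-column TSV for
associations and DAG edges, FASTA for miRNA sequences, CSV for ranked
predictions and JSON for evaluation reports.  Comment lines (``#`` prefix)
and blank lines are ignored in TSV files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
from Bio import SeqIO

logger = logging.getLogger(__name__)

_RNA_ALPHABET = frozenset("ACGU")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class AssociationTable:
    """Known (miRNA, disease) association pairs.

    Pairs are unique; ids are stored verbatim.  ``mirna_ids`` /
    ``disease_ids`` give the sorted id lists used everywhere downstream so
    that node indexing never depends on file line order.
    """

    pairs: tuple[tuple[str, str], ...]
    source_tag: str = ""

    def __post_init__(self) -> None:
        seen = set(self.pairs)
        if len(seen) != len(self.pairs):
            raise ValueError("AssociationTable pairs must be unique")
        for m, d in self.pairs:
            if not m or not d:
                raise ValueError("AssociationTable ids must be non-empty")

    @property
    def mirna_ids(self) -> list[str]:
        return sorted({m for m, _ in self.pairs})

    @property
    def disease_ids(self) -> list[str]:
        return sorted({d for _, d in self.pairs})

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class SequenceSet:
    """miRNA sequences keyed by id, normalized to the uppercase RNA alphabet."""

    records: Mapping[str, str]

    def __post_init__(self) -> None:
        for rid, seq in self.records.items():
            if not seq:
                raise ValueError(f"empty sequence for record {rid!r}")
            bad = set(seq) - _RNA_ALPHABET
            if bad:
                raise ValueError(
                    f"record {rid!r} contains non-ACGU characters: {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, rid: str) -> str:
        return self.records[rid]


@dataclass(frozen=True)
class DiseaseDAG:
    """A MeSH-style disease hierarchy stored as child->parent edges.

    The graph is validated to be acyclic; roots are the nodes without a
    parent.  Directed edges in the underlying ``networkx`` graph point from
    child to parent, so ancestor traversal follows edge direction.
    """

    edges: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_edges_from(self.edges)
        for child, parent in self.edges:
            if child == parent:
                raise ValueError(f"self-edge on node {child!r}")
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"disease hierarchy contains a cycle: {cycle}")
        object.__setattr__(self, "_graph", g)

    @property
    def graph(self) -> nx.DiGraph:
        return self._graph  # type: ignore[attr-defined]

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def roots(self) -> set[str]:
        return {n for n in self.graph.nodes if self.graph.out_degree(n) == 0}

    def ancestors(self, node: str) -> set[str]:
        """All strict ancestors of ``node`` (nodes reachable via parent links)."""
        if node not in self.graph:
            raise KeyError(f"unknown disease id {node!r}")
        return nx.descendants(self.graph, node)


def _iter_tsv_rows(path: Path) -> Iterable[tuple[int, list[str]]]:
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_associations(path: str | Path, source_tag: str = "") -> AssociationTable:
    """Load a two-column (miRNA, disease) TSV, collapsing duplicate pairs."""
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    dropped = 0
    for lineno, fields in _iter_tsv_rows(path):
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise ParseError(f"{path}:{lineno}: expected two tab-separated ids")
        pair = (fields[0], fields[1])
        if pair in seen:
            dropped += 1
            continue
        seen.add(pair)
        pairs.append(pair)
    if not pairs:
        raise ParseError(f"{path}: no association pairs found")
    if dropped:
        logger.info("%s: dropped %d duplicate association(s)", path, dropped)
    return AssociationTable(pairs=tuple(pairs), source_tag=source_tag or str(path))


def read_fasta(path: str | Path) -> SequenceSet:
    """Load miRNA sequences from FASTA, mapping T->U (DNA-coded input is common)."""
    path = Path(path)
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        seq = str(rec.seq).upper().replace("T", "U")
        bad = set(seq) - _RNA_ALPHABET
        if bad:
            raise ParseError(
                f"{path}: record {rec.id!r} has characters outside ACGUT: {sorted(bad)}"
            )
        records[rec.id] = seq
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return SequenceSet(records=records)


def read_dag(path: str | Path) -> DiseaseDAG:
    """Load a child->parent edge TSV into a validated disease hierarchy."""
    path = Path(path)
    edges: list[tuple[str, str]] = []
    for lineno, fields in _iter_tsv_rows(path):
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise ParseError(f"{path}:{lineno}: expected child<TAB>parent")
        edges.append((fields[0], fields[1]))
    if not edges:
        raise ParseError(f"{path}: no edges found")
    return DiseaseDAG(edges=tuple(edges))


def filter_to_attributed(
    assoc: AssociationTable,
    seqs: SequenceSet,
    dag: DiseaseDAG,
    allow_missing: bool = False,
) -> AssociationTable:
    """Reconcile the association table with the attribute sources.

    Every association id must carry attributes (a sequence for the miRNA, a
    DAG placement for the disease).  By default a mismatch is an error;
    with ``allow_missing=True`` the offending pairs are dropped and counted.
    """
    missing_m = set(assoc.mirna_ids) - set(seqs.records)
    missing_d = set(assoc.disease_ids) - dag.nodes
    if not missing_m and not missing_d:
        return assoc
    if not allow_missing:
        raise ValueError(
            f"{len(missing_m)} miRNA id(s) lack sequences and "
            f"{len(missing_d)} disease id(s) are absent from the hierarchy; "
            "pass allow_missing=True to drop them"
        )
    kept = tuple(
        (m, d)
        for m, d in assoc.pairs
        if m not in missing_m and d not in missing_d
    )
    logger.info(
        "dropped %d association(s) with missing attributes", len(assoc) - len(kept)
    )
    if not kept:
        raise ValueError("no associations remain after dropping unattributed ids")
    return AssociationTable(pairs=kept, source_tag=assoc.source_tag)


def write_associations(assoc: AssociationTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for m, d in assoc.pairs:
            fh.write(f"{m}\t{d}\n")


def write_fasta(seqs: SequenceSet, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rid in sorted(seqs.records):
            fh.write(f">{rid}\n{seqs.records[rid]}\n")


def write_dag(dag: DiseaseDAG, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for child, parent in dag.edges:
            fh.write(f"{child}\t{parent}\n")


def write_predictions(ranked, path: str | Path) -> None:
    """Write a ranked candidate list as CSV (rank, mirna_id, disease_id, score)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("rank,mirna_id,disease_id,score\n")
        for rank, (mid, score) in enumerate(ranked.entries, start=1):
            fh.write(f"{rank},{mid},{ranked.disease_id},{score!r}\n")


def write_report(report, path: str | Path) -> None:
    """Serialize an evaluation report (per-fold + mean/sd blocks) as JSON."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
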