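"""Self-contained synthetic datasets with planted attribute-structure signal.

The generator emulates the three real inputs of the pipeline at desk scale:

* a bipartite association table with planted group structure (within-group
  association probability ``p_in`` exceeds the cross-group ``p_out``),
* miRNA sequences sharing a per-group sequence motif (mutated per base at
  ``mutation_rate``) embedded in otherwise random ~22 nt sequences,
* a rooted disease hierarchy in which same-group diseases coalesce under a
  deeper shared ancestor than cross-group pairs.

Because the same group labels drive all three components, attribute
similarity correlates with association structure, so the full embedding and
classification pipeline has recoverable signal to find.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from danemda.dataio import AssociationTable, DiseaseDAG, SequenceSet

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGU"))


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the planted-partition generator.

    Defaults mimic miRNA length (~22 nt) and sparse association density at a
    size small enough for exhaustive testing.
    """

    n_mirnas: int = 200
    n_diseases: int = 100
    n_groups: int = 5
    p_in: float = 0.3
    p_out: float = 0.01
    seq_len: int = 22
    motif_len: int = 8
    mutation_rate: float = 0.1
    dag_branching: int = 3
    seed: int = 7

    def __post_init__(self) -> None:
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ValueError("require 0 <= p_out < p_in <= 1")
        if self.n_groups > min(self.n_mirnas, self.n_diseases):
            raise ValueError("n_groups may not exceed min(n_mirnas, n_diseases)")
        if self.n_groups < 1 or self.n_mirnas < 1 or self.n_diseases < 1:
            raise ValueError("counts must be positive")
        if not (0 <= self.mutation_rate <= 1):
            raise ValueError("mutation_rate must be a probability")
        if self.motif_len > self.seq_len:
            raise ValueError("motif_len may not exceed seq_len")
        if self.dag_branching < 2:
            raise ValueError("dag_branching must be >= 2")


class SyntheticDataset(NamedTuple):
    associations: AssociationTable
    sequences: SequenceSet
    dag: DiseaseDAG
    mirna_groups: dict[str, int]
    disease_groups: dict[str, int]


def _pad(prefix: str, i: int, n: int) -> str:
    return f"{prefix}{i:0{len(str(n - 1))}d}"


def _group_sequences(
    cfg: SyntheticConfig, mirna_ids: list[str], groups: dict[str, int],
    rng: np.random.Generator,
) -> SequenceSet:
    # one motif per group, implanted at a random offset, then point-mutated
    motifs = [
        "".join(rng.choice(_BASES, size=cfg.motif_len)) for _ in range(cfg.n_groups)
    ]
    records: dict[str, str] = {}
    for mid in mirna_ids:
        seq = rng.choice(_BASES, size=cfg.seq_len)
        motif = np.array(list(motifs[groups[mid]]))
        mutate = rng.random(cfg.motif_len) < cfg.mutation_rate
        motif = np.where(mutate, rng.choice(_BASES, size=cfg.motif_len), motif)
        offset = int(rng.integers(0, cfg.seq_len - cfg.motif_len + 1))
        seq[offset : offset + cfg.motif_len] = motif
        records[mid] = "".join(seq)
    return SequenceSet(records=records)


def _group_tree(cfg: SyntheticConfig, disease_ids: list[str],
                groups: dict[str, int]) -> DiseaseDAG:
    """Build a rooted arity-b tree whose leaves are the diseases.

    Each group's diseases are agglomerated bottom-up in blocks of
    ``dag_branching`` under fresh internal nodes; the group subtree roots
    hang off the global root.  Same-group leaves therefore share a strictly
    deeper ancestor than cross-group leaves (whose only shared ancestor is
    the root).
    """
    edges: list[tuple[str, str]] = []
    counter = 0
    for g in range(cfg.n_groups):
        level = [d for d in disease_ids if groups[d] == g]
        while len(level) > 1:
            nxt: list[str] = []
            for i in range(0, len(level), cfg.dag_branching):
                block = level[i : i + cfg.dag_branching]
                if len(block) == 1:
                    nxt.extend(block)
                    continue
                parent = f"node{counter:04d}"
                counter += 1
                edges.extend((child, parent) for child in block)
                nxt.append(parent)
            level = nxt
        edges.append((level[0], "root"))
    return DiseaseDAG(edges=tuple(edges))


def generate_synthetic_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate (associations, sequences, hierarchy, group truth) from ``cfg``.

    Randomness is split into independent sub-streams (sequences / hierarchy
    / associations) spawned from the single config seed, so the same seed
    reproduces the dataset exactly and changing e.g. ``p_in`` leaves the
    sequences untouched.
    """
    seq_ss, dag_ss, edge_ss = np.random.SeedSequence(cfg.seed).spawn(3)
    mirna_ids = [_pad("mir", i, cfg.n_mirnas) for i in range(cfg.n_mirnas)]
    disease_ids = [_pad("dis", j, cfg.n_diseases) for j in range(cfg.n_diseases)]
    mirna_groups = {mid: i % cfg.n_groups for i, mid in enumerate(mirna_ids)}
    disease_groups = {did: j % cfg.n_groups for j, did in enumerate(disease_ids)}

    sequences = _group_sequences(
        cfg, mirna_ids, mirna_groups, np.random.default_rng(seq_ss)
    )
    del dag_ss  # tree layout is deterministic; stream reserved for future use
    dag = _group_tree(cfg, disease_ids, disease_groups)

    edge_rng = np.random.default_rng(edge_ss)
    same = np.array(
        [[mirna_groups[m] == disease_groups[d] for d in disease_ids]
         for m in mirna_ids]
    )
    prob = np.where(same, cfg.p_in, cfg.p_out)
    hit = edge_rng.random((cfg.n_mirnas, cfg.n_diseases)) < prob
    pairs = tuple(
        (mirna_ids[i], disease_ids[j]) for i, j in np.argwhere(hit)
    )
    if not pairs:
        raise ValueError("configuration produced zero associations; raise p_in")
    assoc = AssociationTable(pairs=pairs, source_tag=f"synthetic(seed={cfg.seed})")

    n_iso = (cfg.n_mirnas - len(assoc.mirna_ids)) + (
        cfg.n_diseases - len(assoc.disease_ids)
    )
    if n_iso:
        logger.info("synthetic dataset has %d isolated node(s)", n_iso)
    return SyntheticDataset(assoc, sequences, dag, mirna_groups, disease_groups)
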