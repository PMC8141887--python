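"""Attribute features: disease semantic similarity and miRNA sequence similarity.

Disease similarity follows the Wang-style hierarchy measure: every ancestor
``t`` of a disease ``d`` contributes ``D_d(t) = max over paths of
delta^len(path)``, i.e. the contribution decays by a factor ``delta`` per
edge along the best (shortest) path, the disease contributes 1 to itself,
and the semantic value ``DV(d)`` is the sum of all contributions.  Two
diseases are then compared by the contribution mass they share::

    DSS(d1, d2) = sum_{t in T1 ∩ T2} (D_d1(t) + D_d2(t)) / (DV(d1) + DV(d2))

miRNA similarity is the cosine similarity of k-mer count vectors — an
alignment-free measure that is deterministic, linear-time and bounded in
[0, 1].
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from danemda.dataio import DiseaseDAG, SequenceSet


@dataclass(frozen=True)
class SemanticProfile:
    """Per-ancestor contribution map of one disease and its semantic value."""

    disease_id: str
    contributions: Mapping[str, float]

    @property
    def semantic_value(self) -> float:
        return float(sum(self.contributions.values()))


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric similarity matrix with unit diagonal over an ordered id list."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("similarity matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("similarity matrix must have unit diagonal")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("similarity entries must lie in [0, 1]")

    def loc(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])


def semantic_profile(dag: DiseaseDAG, disease_id: str, delta: float = 0.5
                     ) -> SemanticProfile:
    """Ancestor contributions of ``disease_id`` under decay factor ``delta``.

    Computed by breadth-first traversal along child->parent edges: with the
    max-over-parents propagation rule the contribution of an ancestor is
    ``delta`` raised to its minimum edge distance from the disease.
    """
    if not (0 < delta < 1):
        raise ValueError("delta must lie in (0, 1)")
    if disease_id not in dag.graph:
        raise KeyError(f"unknown disease id {disease_id!r}")
    contrib: dict[str, float] = {disease_id: 1.0}
    frontier = [disease_id]
    weight = 1.0
    while frontier:
        weight *= delta
        nxt: list[str] = []
        for node in frontier:
            for parent in dag.graph.successors(node):
                if parent not in contrib:
                    contrib[parent] = weight
                    nxt.append(parent)
        frontier = nxt
    return SemanticProfile(disease_id=disease_id, contributions=contrib)


def disease_semantic_similarity(p1: SemanticProfile, p2: SemanticProfile) -> float:
    shared = set(p1.contributions) & set(p2.contributions)
    if not shared:
        return 0.0
    num = sum(p1.contributions[t] + p2.contributions[t] for t in shared)
    return float(num / (p1.semantic_value + p2.semantic_value))


def all_disease_similarities(
    dag: DiseaseDAG, ids: Sequence[str], delta: float = 0.5
) -> SimilarityMatrix:
    """Pairwise semantic similarity matrix over ``ids`` (order preserved)."""
    profiles = {d: semantic_profile(dag, d, delta) for d in ids}
    n = len(ids)
    values = np.eye(n)
    for (i, a), (j, b) in combinations(enumerate(ids), 2):
        s = disease_semantic_similarity(profiles[a], profiles[b])
        values[i, j] = values[j, i] = s
    return SimilarityMatrix(ids=tuple(ids), values=values)


def _kmer_counts(seq: str, k: int) -> Counter:
    return Counter(seq[i : i + k] for i in range(len(seq) - k + 1))


def mirna_sequence_similarity(seqs: SequenceSet, k: int = 3) -> SimilarityMatrix:
    """Cosine similarity of k-mer count vectors, over ids in sorted order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ids = tuple(sorted(seqs.records))
    for rid in ids:
        if len(seqs.records[rid]) < k:
            raise ValueError(f"sequence {rid!r} shorter than k={k}")
    counts = [_kmer_counts(seqs.records[rid], k) for rid in ids]
    vocab = sorted(set().union(*counts))
    index = {kmer: i for i, kmer in enumerate(vocab)}
    X = np.zeros((len(ids), len(vocab)))
    for row, c in enumerate(counts):
        for kmer, n in c.items():
            X[row, index[kmer]] = n
    norms = np.linalg.norm(X, axis=1)
    values = (X @ X.T) / np.outer(norms, norms)
    values = np.clip(values, 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(ids=ids, values=values)
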