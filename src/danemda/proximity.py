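"""Attributed network construction and the fused multi-order proximity matrix.

Nodes are indexed miRNAs first (sorted), then diseases (sorted).  The
structure channel is the row-normalized bipartite adjacency ``S``; the
attribute channel is the row-normalized block-diagonal similarity matrix
``Z`` (miRNA sequence similarity block and disease semantic similarity
block).  The two are fused into a single transition matrix

    P = alpha * S + (1 - alpha) * Z

and expanded into the enhanced matrix of multi-order proximities

    M = sum_{l=1..t} beta^(l-1) * P^l

where ``beta`` in (0, 1] damps higher-order walks (the first order carries
full weight) and ``t`` bounds the walk length.  Cross-terms between
structure and attributes appear at order >= 2 because fusion happens before
powering.  Matrices are kept dense; at the intended scale (a few thousand
nodes) this is both simpler and faster than sparse machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from danemda.dataio import AssociationTable
from danemda.similarity import SimilarityMatrix


@dataclass(frozen=True)
class AttributedNetwork:
    """Adjacency and raw attribute blocks over the shared node index."""

    mirna_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]
    adjacency: np.ndarray       # (m+d) x (m+d), symmetric 0/1, bipartite blocks
    attribute_raw: np.ndarray   # (m+d) x (m+d), block-diagonal similarities

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def node_ids(self) -> tuple[str, ...]:
        return self.mirna_ids + self.disease_ids

    def node_index(self, node_id: str) -> int:
        ids = self.node_ids
        try:
            return ids.index(node_id)
        except ValueError:
            raise KeyError(f"unknown node id {node_id!r}") from None


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic matrix; rows with no mass stay zero and are recorded."""

    values: np.ndarray
    zero_rows: frozenset[int] = field(default_factory=frozenset)


@dataclass(frozen=True)
class EnhancedMatrix:
    M: np.ndarray
    alpha: float
    beta: float
    t: int


def build_adjacency(
    assoc: AssociationTable,
    mirna_ids: list[str] | tuple[str, ...],
    disease_ids: list[str] | tuple[str, ...],
) -> np.ndarray:
    """Symmetric 0/1 adjacency with associations in the off-diagonal blocks."""
    m_index = {mid: i for i, mid in enumerate(mirna_ids)}
    d_index = {did: j for j, did in enumerate(disease_ids)}
    m, d = len(mirna_ids), len(disease_ids)
    A = np.zeros((m + d, m + d))
    for mid, did in assoc.pairs:
        if mid not in m_index:
            raise KeyError(f"association miRNA {mid!r} not in index")
        if did not in d_index:
            raise KeyError(f"association disease {did!r} not in index")
        i, j = m_index[mid], m + d_index[did]
        A[i, j] = A[j, i] = 1.0
    return A


def build_attribute_matrix(
    mirna_sim: SimilarityMatrix, disease_sim: SimilarityMatrix
) -> np.ndarray:
    """Block-diagonal raw attribute matrix [mirna block, 0; 0, disease block]."""
    m, d = len(mirna_sim.ids), len(disease_sim.ids)
    Z0 = np.zeros((m + d, m + d))
    Z0[:m, :m] = mirna_sim.values
    Z0[m:, m:] = disease_sim.values
    return Z0


def build_network(
    assoc: AssociationTable,
    mirna_sim: SimilarityMatrix,
    disease_sim: SimilarityMatrix,
) -> AttributedNetwork:
    """Assemble the attributed network on the similarity matrices' id order."""
    A = build_adjacency(assoc, list(mirna_sim.ids), list(disease_sim.ids))
    Z0 = build_attribute_matrix(mirna_sim, disease_sim)
    return AttributedNetwork(
        mirna_ids=tuple(mirna_sim.ids),
        disease_ids=tuple(disease_sim.ids),
        adjacency=A,
        attribute_raw=Z0,
    )


def row_normalize(matrix: np.ndarray) -> TransitionMatrix:
    """Divide each nonzero row by its sum; zero rows stay zero and are listed."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.min() < 0:
        raise ValueError("row_normalize requires non-negative entries")
    sums = matrix.sum(axis=1)
    zero = sums == 0
    safe = np.where(zero, 1.0, sums)
    return TransitionMatrix(
        values=matrix / safe[:, None],
        zero_rows=frozenset(int(i) for i in np.flatnonzero(zero)),
    )


def fuse_transition(
    S: TransitionMatrix, Z: TransitionMatrix, alpha: float
) -> TransitionMatrix:
    """Convex combination P = alpha*S + (1-alpha)*Z of the two channels."""
    if not (0 <= alpha <= 1):
        raise ValueError("alpha must lie in [0, 1]")
    if S.values.shape != Z.values.shape:
        raise ValueError("transition matrices must share a shape")
    P = alpha * S.values + (1 - alpha) * Z.values
    return TransitionMatrix(values=P, zero_rows=S.zero_rows & Z.zero_rows)


def enhanced_matrix(P: TransitionMatrix, beta: float = 0.94, t: int = 5,
                    alpha: float | None = None) -> EnhancedMatrix:
    """Accumulate M = sum_{l=1..t} beta^(l-1) P^l with one multiply per order."""
    if not (0 < beta <= 1):
        raise ValueError("beta must lie in (0, 1]")
    if t < 1:
        raise ValueError("t must be a positive integer")
    Pv = P.values
    power = Pv.copy()
    M = Pv.copy()
    coef = 1.0
    for _ in range(2, t + 1):
        power = power @ Pv
        coef *= beta
        M = M + coef * power
    return EnhancedMatrix(M=M, alpha=float("nan") if alpha is None else alpha,
                          beta=beta, t=t)


def enhanced_from_network(
    net: AttributedNetwork,
    alpha: float = 0.85,
    beta: float = 0.94,
    t: int = 5,
    renormalize: bool = False,
) -> EnhancedMatrix:
    """Full proximity stage: normalize both channels, fuse, expand to order t.

    ``renormalize`` rescales the rows of M to sum to 1 before it is fed to
    the auto-encoder; for fully stochastic P the row sums are constant, so
    this only matters when isolated nodes leave zero rows in S.
    """
    S = row_normalize(net.adjacency)
    Z = row_normalize(net.attribute_raw)
    P = fuse_transition(S, Z, alpha)
    enh = enhanced_matrix(P, beta=beta, t=t)
    M = row_normalize(enh.M).values if renormalize else enh.M
    return EnhancedMatrix(M=M, alpha=alpha, beta=beta, t=t)
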