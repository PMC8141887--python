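"""Pair-level classification: negative sampling, features, metrics, CV, ranking.

A candidate (miRNA, disease) pair is represented by the concatenation of the
two nodes' auto-encoder codes.  Negatives are drawn uniformly from the
unlabeled complement of the association matrix, in equal number to the
positives.  Evaluation is k-fold cross-validation where positives and
negatives are folded independently; in the default ``masked`` mode the
adjacency is rebuilt from training-fold positives only before the proximity
and embedding stages, so test edges never leak into the features.  The
``paper`` mode embeds on the full adjacency (the classifier still sees only
training pairs), reproducing the commonly published but leak-prone protocol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier

from danemda.autoencoder import AutoencoderSpec, EmbeddingMatrix, train_autoencoder
from danemda.dataio import AssociationTable, DiseaseDAG, SequenceSet
from danemda.proximity import build_network, enhanced_from_network
from danemda.similarity import (
    SimilarityMatrix,
    all_disease_similarities,
    mirna_sequence_similarity,
)

logger = logging.getLogger(__name__)

CLASSIFIERS = ("random_forest", "naive_bayes", "adaboost", "knn")

_METRIC_NAMES = ("acc", "sen", "spec", "prec", "mcc", "auc", "aupr")


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end hyper-parameters of the embedding + classification pipeline.

    ``alpha`` is the structure/attribute fusion weight (1 = structure only,
    0 = attributes only), ``beta`` damps higher-order walk terms, ``t`` is
    the maximum walk order, ``delta`` the semantic-contribution decay on the
    disease hierarchy and ``kmer_k`` the k-mer length for sequence
    similarity.  Defaults follow the tuned operating point alpha=0.85,
    beta=0.94, t=5.
    """

    alpha: float = 0.85
    beta: float = 0.94
    t: int = 5
    delta: float = 0.5
    kmer_k: int = 3
    autoencoder: AutoencoderSpec = field(default_factory=AutoencoderSpec)
    classifier: str = "random_forest"
    threshold: float = 0.5
    renormalize_m: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.alpha <= 1):
            raise ValueError("alpha must lie in [0, 1]")
        if not (0 < self.beta <= 1):
            raise ValueError("beta must lie in (0, 1]")
        if self.t < 1:
            raise ValueError("t must be >= 1")
        if not (0 < self.delta < 1):
            raise ValueError("delta must lie in (0, 1)")
        if self.kmer_k < 1:
            raise ValueError("kmer_k must be >= 1")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(
                f"unknown classifier {self.classifier!r}; valid: {CLASSIFIERS}"
            )

    def to_dict(self) -> dict:
        ae = self.autoencoder
        return {
            "alpha": self.alpha, "beta": self.beta, "t": self.t,
            "delta": self.delta, "kmer_k": self.kmer_k,
            "classifier": self.classifier, "threshold": self.threshold,
            "renormalize_m": self.renormalize_m,
            "autoencoder": {
                "hidden_dims": list(ae.hidden_dims),
                "epochs_pretrain": ae.epochs_pretrain,
                "epochs_finetune": ae.epochs_finetune,
                "batch_size": ae.batch_size,
                "learning_rate": ae.learning_rate,
                "seed": ae.seed,
            },
        }


@dataclass(frozen=True)
class PairDataset:
    pairs: tuple[tuple[str, str], ...]
    labels: np.ndarray
    features: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.pairs) == len(self.labels) == self.features.shape[0]):
            raise ValueError("pairs, labels and feature rows must align")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate pairs in dataset")


@dataclass(frozen=True)
class Metrics:
    acc: float
    sen: float
    spec: float
    prec: float
    mcc: float
    auc: float
    aupr: float
    threshold: float
    roc_points: tuple[tuple[float, float], ...]  # (FPR, TPR)
    pr_points: tuple[tuple[float, float], ...]   # (recall, precision)

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in _METRIC_NAMES}


@dataclass(frozen=True)
class EvaluationReport:
    per_fold: tuple[Metrics, ...]
    config: dict = field(default_factory=dict)

    def mean(self, name: str) -> float:
        return float(np.mean([getattr(m, name) for m in self.per_fold]))

    def sd(self, name: str) -> float:
        vals = [getattr(m, name) for m in self.per_fold]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "per_fold": [m.to_dict() for m in self.per_fold],
            "mean": {n: self.mean(n) for n in _METRIC_NAMES},
            "sd": {n: self.sd(n) for n in _METRIC_NAMES},
            "config": self.config,
        }


@dataclass(frozen=True)
class RankedPredictions:
    disease_id: str
    entries: tuple[tuple[str, float], ...]
    n_excluded: int


def sample_negatives(
    positives: AssociationTable,
    n: int,
    mirna_ids: list[str] | tuple[str, ...],
    disease_ids: list[str] | tuple[str, ...],
    seed: int = 0,
) -> AssociationTable:
    """Draw ``n`` distinct unlabeled pairs uniformly without replacement."""
    pos = set(positives.pairs)
    universe = [
        (m, d) for m in sorted(mirna_ids) for d in sorted(disease_ids)
        if (m, d) not in pos
    ]
    if n > len(universe):
        raise ValueError(
            f"cannot sample {n} negatives from {len(universe)} unlabeled pairs"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(universe), size=n, replace=False)
    return AssociationTable(
        pairs=tuple(universe[i] for i in idx), source_tag="sampled-negatives"
    )


def build_pair_features(
    H: EmbeddingMatrix,
    pairs: list[tuple[str, str]] | tuple[tuple[str, str], ...],
    labels: np.ndarray | list[int],
) -> PairDataset:
    """Feature row per pair: miRNA code concatenated with disease code."""
    index = {nid: i for i, nid in enumerate(H.ids)}
    rows = np.empty((len(pairs), 2 * H.H.shape[1]))
    for r, (mid, did) in enumerate(pairs):
        if mid not in index:
            raise KeyError(f"miRNA {mid!r} has no embedding")
        if did not in index:
            raise KeyError(f"disease {did!r} has no embedding")
        rows[r] = np.concatenate([H.H[index[mid]], H.H[index[did]]])
    return PairDataset(
        pairs=tuple(pairs), labels=np.asarray(labels, dtype=int), features=rows
    )


def train_classifier(data: PairDataset, name: str = "random_forest", seed: int = 0):
    """Fit one of the supported classifiers with library-default parameters."""
    if name not in CLASSIFIERS:
        raise ValueError(f"unknown classifier {name!r}; valid: {CLASSIFIERS}")
    if len(set(data.labels.tolist())) < 2:
        raise ValueError("training data must contain both classes")
    if name == "random_forest":
        model = RandomForestClassifier(random_state=seed)
    elif name == "naive_bayes":
        model = GaussianNB()
    elif name == "adaboost":
        model = AdaBoostClassifier(random_state=seed)
    else:
        model = KNeighborsClassifier()
    model.fit(data.features, data.labels)
    return model


def score_pairs(model, features: np.ndarray) -> np.ndarray:
    """Probability of association per feature row, in [0, 1]."""
    proba = model.predict_proba(features)
    pos_col = list(model.classes_).index(1)
    return proba[:, pos_col]


# ---------------------------------------------------------------------------
# metrics


def _rank_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) with ties credited 0.5."""
    from scipy.stats import rankdata

    ranks = rankdata(scores, method="average")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _curves(labels: np.ndarray, scores: np.ndarray):
    """ROC and PR points at every distinct score threshold (descending)."""
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # keep only the last index of each tied-score block
    last = np.flatnonzero(np.diff(s, append=-np.inf))
    tpr = tp[last] / n_pos
    fpr = fp[last] / n_neg
    prec = tp[last] / (tp[last] + fp[last])
    roc = [(0.0, 0.0)] + list(zip(fpr, tpr))
    pr = list(zip(tpr, prec))
    return roc, pr


def trapezoid_auc(roc_points) -> float:
    """Trapezoidal area under ROC points; independent check of the rank AUC."""
    pts = sorted(roc_points)
    area = 0.0
    for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
        area += (x1 - x0) * (y0 + y1) / 2.0
    return area


def step_aupr(pr_points) -> float:
    """Non-interpolated area under the PR curve (step-wise precision)."""
    area = 0.0
    prev_r = 0.0
    for r, p in pr_points:
        area += (r - prev_r) * p
        prev_r = r
    return area


def compute_metrics(
    labels, scores, threshold: float = 0.5
) -> Metrics:
    """Thresholded confusion metrics plus rank-statistic AUC and step AUPR."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise ValueError("labels and scores must be 1-d and aligned")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes required (AUC undefined otherwise)")
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    acc = (tp + tn) / len(labels)
    sen = tp / (tp + fn)
    spec_ = tn / (tn + fp)
    prec = tp / (tp + fp) if tp + fp else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    roc, pr = _curves(labels, scores)
    return Metrics(
        acc=acc, sen=sen, spec=spec_, prec=prec, mcc=float(mcc),
        auc=_rank_auc(labels, scores), aupr=step_aupr(pr),
        threshold=threshold,
        roc_points=tuple(roc), pr_points=tuple(pr),
    )


# ---------------------------------------------------------------------------
# cross-validation


def _fold_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    return [np.sort(chunk) for chunk in np.array_split(rng.permutation(n), k)]


def embed_dataset(
    assoc: AssociationTable,
    mirna_sim: SimilarityMatrix,
    disease_sim: SimilarityMatrix,
    config: PipelineConfig,
    seed: int,
) -> EmbeddingMatrix:
    """Proximity + auto-encoder stages for one adjacency realization."""
    net = build_network(assoc, mirna_sim, disease_sim)
    enh = enhanced_from_network(net, alpha=config.alpha, beta=config.beta,
                                t=config.t,
                                renormalize=config.renormalize_m)
    spec = AutoencoderSpec(
        hidden_dims=config.autoencoder.hidden_dims,
        epochs_pretrain=config.autoencoder.epochs_pretrain,
        epochs_finetune=config.autoencoder.epochs_finetune,
        batch_size=config.autoencoder.batch_size,
        learning_rate=config.autoencoder.learning_rate,
        seed=seed,
    )
    model = train_autoencoder(enh.M, spec)
    return model.encode(enh.M, net.node_ids)


def cross_validate(
    assoc: AssociationTable,
    sequences: SequenceSet,
    dag: DiseaseDAG,
    config: PipelineConfig | None = None,
    k: int = 5,
    seed: int = 0,
    mode: str = "masked",
    mirna_ids: list[str] | None = None,
    disease_ids: list[str] | None = None,
    permute_labels: bool = False,
) -> EvaluationReport:
    """k-fold CV of the full pipeline with balanced sampled negatives.

    Positives and negatives are folded independently and deterministically
    from ``seed``.  ``mode='masked'`` rebuilds the adjacency from training
    positives before embedding each fold; ``mode='paper'`` embeds once on
    the full adjacency.  ``permute_labels=True`` shuffles the pair labels
    (a permutation null: features unchanged, association destroyed).
    """
    if config is None:
        config = PipelineConfig()
    if k < 2:
        raise ValueError("k must be >= 2")
    if mode not in ("masked", "paper"):
        raise ValueError("mode must be 'masked' or 'paper'")
    mirna_ids = sorted(mirna_ids) if mirna_ids else assoc.mirna_ids
    disease_ids = sorted(disease_ids) if disease_ids else assoc.disease_ids

    seed_neg, seed_fold, seed_ae, seed_clf, seed_perm = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(5)
    ]

    mirna_sim = mirna_sequence_similarity(
        SequenceSet({m: sequences[m] for m in mirna_ids}), k=config.kmer_k
    )
    disease_sim = all_disease_similarities(dag, disease_ids, delta=config.delta)

    positives = list(assoc.pairs)
    negatives = list(
        sample_negatives(assoc, len(positives), mirna_ids, disease_ids,
                         seed=seed_neg).pairs
    )
    all_pairs = positives + negatives
    labels = np.array([1] * len(positives) + [0] * len(negatives))
    if permute_labels:
        labels = np.random.default_rng(seed_perm).permutation(labels)

    rng = np.random.default_rng(seed_fold)
    pos_folds = _fold_indices(len(positives), k, rng)
    neg_folds = _fold_indices(len(negatives), k, rng)

    full_embedding = None
    if mode == "paper":
        full_embedding = embed_dataset(assoc, mirna_sim, disease_sim, config,
                                       seed=seed_ae)

    per_fold: list[Metrics] = []
    for fold in range(k):
        test_idx = np.concatenate(
            [pos_folds[fold], neg_folds[fold] + len(positives)]
        )
        train_mask = np.ones(len(all_pairs), dtype=bool)
        train_mask[test_idx] = False
        train_idx = np.flatnonzero(train_mask)

        if mode == "masked":
            train_pos = tuple(
                positives[i] for i in range(len(positives))
                if i not in set(pos_folds[fold].tolist())
            )
            fold_assoc = AssociationTable(pairs=train_pos,
                                          source_tag="train-fold")
            H = embed_dataset(fold_assoc, mirna_sim, disease_sim, config,
                              seed=seed_ae + fold)
        else:
            H = full_embedding

        train_pairs = [all_pairs[i] for i in train_idx]
        test_pairs = [all_pairs[i] for i in test_idx]
        train = build_pair_features(H, train_pairs, labels[train_idx])
        test = build_pair_features(H, test_pairs, labels[test_idx])
        if len(set(test.labels.tolist())) < 2:
            raise ValueError(f"fold {fold} contains a single class")
        clf = train_classifier(train, name=config.classifier, seed=seed_clf)
        scores = score_pairs(clf, test.features)
        per_fold.append(
            compute_metrics(test.labels, scores, threshold=config.threshold)
        )
        logger.info("fold %d: auc=%.4f acc=%.4f", fold, per_fold[-1].auc,
                    per_fold[-1].acc)

    return EvaluationReport(
        per_fold=tuple(per_fold),
        config={**config.to_dict(), "k": k, "seed": seed, "mode": mode,
                "n_positives": len(positives), "permuted": permute_labels},
    )


def rank_candidates(
    model,
    H: EmbeddingMatrix,
    disease_id: str,
    training_positives: AssociationTable,
    mirna_ids: list[str] | tuple[str, ...],
    top_n: int = 50,
) -> RankedPredictions:
    """Score every miRNA not already associated with ``disease_id``.

    Known training positives are excluded from the candidate set; ties are
    broken by miRNA id ascending for reproducible top lists.
    """
    if disease_id not in H.ids:
        raise KeyError(f"disease {disease_id!r} has no embedding")
    known = {m for m, d in training_positives.pairs if d == disease_id}
    candidates = [m for m in sorted(mirna_ids) if m not in known]
    if not candidates:
        return RankedPredictions(disease_id=disease_id, entries=(),
                                 n_excluded=len(known))
    data = build_pair_features(
        H, [(m, disease_id) for m in candidates], [0] * len(candidates)
    )
    scores = score_pairs(model, data.features)
    order = sorted(range(len(candidates)),
                   key=lambda i: (-scores[i], candidates[i]))
    entries = tuple(
        (candidates[i], float(scores[i])) for i in order[:top_n]
    )
    return RankedPredictions(disease_id=disease_id, entries=entries,
                             n_excluded=len(known))
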