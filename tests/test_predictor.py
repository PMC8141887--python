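import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from danemda.autoencoder import EmbeddingMatrix
from danemda.dataio import AssociationTable
from danemda.predictor import (
    PipelineConfig,
    build_pair_features,
    compute_metrics,
    cross_validate,
    rank_candidates,
    sample_negatives,
    score_pairs,
    train_classifier,
    trapezoid_auc,
)


class TestSampleNegatives:
    def test_forced_single_remaining_pair(self):
        pos = AssociationTable(pairs=(("m1", "d1"), ("m1", "d2"),
                                      ("m2", "d1")))
        neg = sample_negatives(pos, 1, ["m1", "m2"], ["d1", "d2"], seed=0)
        assert neg.pairs == (("m2", "d2"),)

    def test_seed_determinism_and_variation(self):
        pos = AssociationTable(pairs=(("m00", "d00"),))
        mids = [f"m{i:02d}" for i in range(100)]
        dids = [f"d{i:02d}" for i in range(100)]
        a = sample_negatives(pos, 50, mids, dids, seed=1)
        b = sample_negatives(pos, 50, mids, dids, seed=1)
        c = sample_negatives(pos, 50, mids, dids, seed=2)
        assert a.pairs == b.pairs
        assert a.pairs != c.pairs

    def test_never_overlaps_positives(self):
        pos = AssociationTable(pairs=(("m1", "d1"), ("m2", "d2")))
        neg = sample_negatives(pos, 4, ["m1", "m2", "m3"], ["d1", "d2"],
                               seed=7)
        assert not set(neg.pairs) & set(pos.pairs)

    def test_oversampling_errors(self):
        pos = AssociationTable(pairs=(("m1", "d1"),))
        with pytest.raises(ValueError):
            sample_negatives(pos, 10, ["m1"], ["d1", "d2"], seed=0)


class TestPairFeatures:
    @pytest.fixture
    def embedding(self):
        H = np.arange(12, dtype=float).reshape(4, 3)
        return EmbeddingMatrix(ids=("m1", "m2", "d1", "d2"), H=H)

    def test_concatenation_order_and_width(self, embedding):
        data = build_pair_features(embedding, [("m1", "d1")], [1])
        assert data.features.shape == (1, 6)
        np.testing.assert_array_equal(data.features[0], [0, 1, 2, 6, 7, 8])

    def test_swapping_mirna_changes_first_half_only(self, embedding):
        a = build_pair_features(embedding, [("m1", "d1")], [1]).features[0]
        b = build_pair_features(embedding, [("m2", "d1")], [1]).features[0]
        assert not np.array_equal(a[:3], b[:3])
        np.testing.assert_array_equal(a[3:], b[3:])

    def test_rows_follow_input_order(self, embedding):
        pairs = [("m2", "d2"), ("m1", "d1"), ("m2", "d1")]
        data = build_pair_features(embedding, pairs, [0, 1, 0])
        assert data.pairs == tuple(pairs)
        assert data.features.shape == (3, 6)

    def test_missing_id_errors(self, embedding):
        with pytest.raises(KeyError):
            build_pair_features(embedding, [("mX", "d1")], [0])


class TestClassifiers:
    def _separable(self, n=60):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(n, 4))
        y = (X[:, 0] > 0).astype(int)
        X[:, 0] += y * 5
        ids = [(f"m{i}", "d0") for i in range(n)]
        H = EmbeddingMatrix(
            ids=tuple(f"m{i}" for i in range(n)) + ("d0",),
            H=np.zeros((n + 1, 2)),
        )
        from danemda.predictor import PairDataset
        return PairDataset(pairs=tuple(ids), labels=y, features=X)

    def test_random_forest_separates_separable_data(self):
        data = self._separable()
        clf = train_classifier(data, "random_forest", seed=0)
        scores = score_pairs(clf, data.features)
        assert compute_metrics(data.labels, scores).auc == 1.0

    def test_unknown_classifier_lists_valid_names(self):
        data = self._separable()
        with pytest.raises(ValueError, match="random_forest"):
            train_classifier(data, "svm", seed=0)

    def test_single_class_rejected(self):
        data = self._separable()
        from danemda.predictor import PairDataset
        ones = PairDataset(pairs=data.pairs, labels=np.ones_like(data.labels),
                           features=data.features)
        with pytest.raises(ValueError):
            train_classifier(ones, "random_forest", seed=0)

    def test_random_forest_scores_deterministic(self):
        data = self._separable()
        s1 = score_pairs(train_classifier(data, "random_forest", seed=4),
                         data.features)
        s2 = score_pairs(train_classifier(data, "random_forest", seed=4),
                         data.features)
        np.testing.assert_array_equal(s1, s2)

    @pytest.mark.parametrize("name", ["naive_bayes", "adaboost", "knn"])
    def test_alternative_classifiers_fit_and_score(self, name):
        data = self._separable()
        scores = score_pairs(train_classifier(data, name, seed=0),
                             data.features)
        assert scores.shape == data.labels.shape
        assert ((scores >= 0) & (scores <= 1)).all()

    def test_shuffled_labels_give_chance_level_auc(self):
        """Permutation null: cross-validated AUC ~ 0.5 on random labels."""
        from sklearn.ensemble import RandomForestClassifier
        from sklearn.model_selection import cross_val_predict

        rng = np.random.default_rng(1)
        X = rng.normal(size=(2000, 8))
        y = rng.permutation([0, 1] * 1000)
        scores = cross_val_predict(
            RandomForestClassifier(random_state=0), X, y, cv=5,
            method="predict_proba",
        )[:, 1]
        assert abs(compute_metrics(y, scores).auc - 0.5) < 0.05


class TestMetrics:
    def test_four_sample_worked_example(self):
        m = compute_metrics([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1])
        assert (m.acc, m.sen, m.spec, m.prec) == (0.5, 0.5, 0.5, 0.5)
        assert m.mcc == 0.0
        assert m.auc == 0.75

    def test_perfect_ranking(self):
        m = compute_metrics([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert m.auc == 1.0
        assert (m.acc, m.sen, m.spec, m.prec, m.mcc) == (1, 1, 1, 1, 1)
        assert m.aupr == pytest.approx(1.0)

    def test_all_ties_score_half(self):
        m = compute_metrics([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5])
        assert m.auc == 0.5

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            compute_metrics([1, 1, 1], [0.1, 0.2, 0.3])

    def test_non_finite_scores_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([1, 0], [np.nan, 0.2])

    def test_matches_sklearn_on_random_vectors(self, rng):
        """Independent library cross-check of AUC, AUPR and MCC."""
        from sklearn.metrics import (
            average_precision_score,
            matthews_corrcoef,
            roc_auc_score,
        )

        for _ in range(20):
            n = int(rng.integers(10, 60))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            s = np.round(rng.random(n), 2)  # rounded to force ties
            m = compute_metrics(y, s)
            assert m.auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)
            assert m.aupr == pytest.approx(average_precision_score(y, s),
                                           abs=1e-12)
            assert m.mcc == pytest.approx(
                matthews_corrcoef(y, s >= 0.5), abs=1e-12
            )

    def test_rank_auc_equals_trapezoid_roc_area(self, rng):
        for _ in range(200):
            n = int(rng.integers(6, 40))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            s = np.round(rng.random(n), 1)
            m = compute_metrics(y, s)
            assert abs(m.auc - trapezoid_auc(m.roc_points)) < 1e-12

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        tp=st.integers(0, 30), fn=st.integers(0, 30),
        fp=st.integers(0, 30), tn=st.integers(0, 30),
    )
    def test_confusion_identities_fuzz(self, tp, fn, fp, tn):
        """acc is the class-weighted mean of sen and spec; mcc=0 on
        proportional confusion tables."""
        if tp + fn == 0 or tn + fp == 0:
            return
        y = [1] * (tp + fn) + [0] * (fp + tn)
        s = [0.9] * tp + [0.1] * fn + [0.9] * fp + [0.1] * tn
        m = compute_metrics(y, s)
        npos, nneg = tp + fn, fp + tn
        assert m.acc == pytest.approx(
            (npos * m.sen + nneg * m.spec) / (npos + nneg), abs=1e-12
        )
        # proportional rows => score and label independent => mcc ~ 0
        if tp * nneg == fp * npos and fn * nneg == tn * npos:
            assert m.mcc == pytest.approx(0.0, abs=1e-12)


class TestCrossValidate:
    def test_partition_contract_and_determinism(self, tiny_dataset,
                                                fast_config):
        ds = tiny_dataset
        kwargs = dict(
            config=fast_config, k=3, seed=5, mode="masked",
            mirna_ids=sorted(ds.mirna_groups),
            disease_ids=sorted(ds.disease_groups),
        )
        r1 = cross_validate(ds.associations, ds.sequences, ds.dag, **kwargs)
        r2 = cross_validate(ds.associations, ds.sequences, ds.dag, **kwargs)
        assert len(r1.per_fold) == 3
        assert r1.to_dict() == r2.to_dict()

    def test_mean_sd_recomputable_from_folds(self, tiny_dataset, fast_config):
        ds = tiny_dataset
        rep = cross_validate(
            ds.associations, ds.sequences, ds.dag, fast_config, k=3, seed=5,
            mode="paper", mirna_ids=sorted(ds.mirna_groups),
            disease_ids=sorted(ds.disease_groups),
        )
        aucs = [m.auc for m in rep.per_fold]
        assert rep.mean("auc") == pytest.approx(np.mean(aucs), abs=1e-12)
        assert rep.sd("auc") == pytest.approx(np.std(aucs, ddof=1), abs=1e-12)

    def test_invalid_mode_and_k_rejected(self, tiny_dataset, fast_config):
        ds = tiny_dataset
        with pytest.raises(ValueError):
            cross_validate(ds.associations, ds.sequences, ds.dag,
                           fast_config, k=1)
        with pytest.raises(ValueError):
            cross_validate(ds.associations, ds.sequences, ds.dag,
                           fast_config, mode="bogus")


class TestRankCandidates:
    class _IndexScorer:
        """Oracle model scoring miRNA i as 1 - i/m."""

        classes_ = np.array([0, 1])

        def __init__(self, m):
            self.m = m

        def predict_proba(self, X):
            # first feature value encodes the miRNA index
            p = 1 - X[:, 0] / self.m
            return np.column_stack([1 - p, p])

    def _embedding(self, m):
        ids = tuple(f"m{i:02d}" for i in range(m)) + ("d0",)
        H = np.zeros((m + 1, 2))
        H[:m, 0] = np.arange(m)
        return EmbeddingMatrix(ids=ids, H=H)

    def test_injected_oracle_orders_by_index(self):
        m = 10
        H = self._embedding(m)
        pos = AssociationTable(pairs=(("m00", "dX"),))
        ranked = rank_candidates(self._IndexScorer(m), H, "d0", pos,
                                 [f"m{i:02d}" for i in range(m)], top_n=5)
        assert [e[0] for e in ranked.entries] == [f"m{i:02d}" for i in range(5)]

    def test_known_positives_excluded(self):
        m = 5
        H = self._embedding(m)
        pos = AssociationTable(
            pairs=tuple((f"m{i:02d}", "d0") for i in range(m))
        )
        ranked = rank_candidates(self._IndexScorer(m), H, "d0", pos,
                                 [f"m{i:02d}" for i in range(m)])
        assert ranked.entries == ()
        assert ranked.n_excluded == m

    def test_top_n_larger_than_candidates(self):
        m = 4
        H = self._embedding(m)
        pos = AssociationTable(pairs=(("m00", "d0"),))
        ranked = rank_candidates(self._IndexScorer(m), H, "d0", pos,
                                 [f"m{i:02d}" for i in range(m)], top_n=50)
        assert len(ranked.entries) == 3

    def test_scores_non_increasing_with_lexicographic_ties(self):
        m = 6
        H = self._embedding(m)
        H.H[:m, 0] = [0, 0, 1, 1, 2, 2]  # tied scores in pairs
        pos = AssociationTable(pairs=(("m99", "d9"),))
        ranked = rank_candidates(self._IndexScorer(m), H, "d0", pos,
                                 [f"m{i:02d}" for i in range(m)])
        scores = [s for _, s in ranked.entries]
        assert scores == sorted(scores, reverse=True)
        # within tied score blocks, ids ascend
        assert [e[0] for e in ranked.entries] == [
            "m00", "m01", "m02", "m03", "m04", "m05"
        ]

    def test_unknown_disease_errors(self):
        H = self._embedding(3)
        pos = AssociationTable(pairs=(("m00", "d0"),))
        with pytest.raises(KeyError):
            rank_candidates(self._IndexScorer(3), H, "dZ", pos, ["m00"])
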