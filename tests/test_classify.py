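"""Folds, feature matrices, PCA, models, ranking, top-N and evaluation."""

import numpy as np
import pytest

from frequentmers import (
    Cohort,
    KmerCodec,
    build_features,
    coefficient_report,
    evaluate,
    fit_boosted,
    fit_logistic,
    make_folds,
    run_pca,
    topn_retrain,
)
from frequentmers.classify import FeatureMatrix, ModelResult, _confusion
from frequentmers.core import FrequentmerCatalog

from conftest import kset_from_strings, make_manifest

C4 = KmerCodec(4)


def _manifests(n_pat, n_ctrl):
    return [make_manifest(f"P{i}", "patient") for i in range(n_pat)] + [
        make_manifest(f"C{i}", "control") for i in range(n_ctrl)
    ]


class TestFolds:
    def test_exact_divisibility(self):
        folds = make_folds(_manifests(20, 20), 10, seed=0)
        for f in range(10):
            ids = folds.test_ids(f)
            assert sum(s.startswith("P") for s in ids) == 2
            assert sum(s.startswith("C") for s in ids) == 2

    def test_reference_cohort_sizes_partition(self):
        # 123 patients + 114 controls over 10 folds
        folds = make_folds(_manifests(123, 114), 10, seed=1)
        for f in range(10):
            ids = folds.test_ids(f)
            assert sum(s.startswith("P") for s in ids) in (12, 13)
            assert sum(s.startswith("C") for s in ids) in (11, 12)
        assert len(folds.assignment) == 237

    def test_deterministic_given_seed(self):
        m = _manifests(15, 15)
        assert make_folds(m, 10, seed=3).assignment == make_folds(m, 10, seed=3).assignment
        assert make_folds(m, 10, seed=3).assignment != make_folds(m, 10, seed=4).assignment

    def test_small_cohort_rejected(self):
        with pytest.raises(ValueError, match="fewer"):
            make_folds(_manifests(5, 20), 10, seed=0)


def _toy_matrices():
    """Patients carry k-mer TTTT (patient fm), controls carry GGGG
    (control fm); catalog from a 'training split' with that structure."""
    cat = FrequentmerCatalog(
        0, 2, 4,
        control_fms=np.array([C4.encode("GGGG")], dtype=np.uint64),
        patient_fms=np.array([C4.encode("TTTT")], dtype=np.uint64),
    )
    manifests = _manifests(6, 6)
    ksets = {}
    for m in manifests:
        seqs = ["TTTT", "AAAA"] if m.cohort == Cohort.patient else ["GGGG", "AAAA"]
        ksets[m.sample_id] = kset_from_strings(m.sample_id, 4, seqs)
    ids = [m.sample_id for m in manifests]
    train = build_features(cat, ksets, manifests, ids[:4] + ids[6:10])
    test = build_features(cat, ksets, manifests, ids[4:6] + ids[10:12])
    return cat, train, test


class TestFeatures:
    def test_presence_matrix_and_column_order(self):
        cat, train, _ = _toy_matrices()
        # control block first: column 0 = GGGG, column 1 = TTTT
        assert train.n_control_features == 1
        assert list(train.feature_side) == ["control", "patient"]
        pat_rows = train.X[train.y == 1]
        ctrl_rows = train.X[train.y == 0]
        # structural property: training samples never carry the opposite block
        assert (pat_rows[:, 0] == 0).all() and (pat_rows[:, 1] == 1).all()
        assert (ctrl_rows[:, 0] == 1).all() and (ctrl_rows[:, 1] == 0).all()

    def test_sample_without_features_gets_zero_row(self):
        cat, _, _ = _toy_matrices()
        manifests = [make_manifest("X", "control")]
        ksets = {"X": kset_from_strings("X", 4, ["AAAA"])}
        fm = build_features(cat, ksets, manifests, ["X"])
        assert fm.X.sum() == 0

    def test_empty_catalog_rejected_with_advice(self):
        cat = FrequentmerCatalog(
            0, 99, 4, np.empty(0, np.uint64), np.empty(0, np.uint64)
        )
        with pytest.raises(ValueError, match="recurrency threshold"):
            build_features(cat, {}, [], [])


class TestPCA:
    def test_rank_one_matrix_explained_by_pc1(self):
        X = np.vstack([np.tile([1, 0, 1, 0], (5, 1)), np.tile([0, 1, 0, 1], (5, 1))])
        rep = run_pca(X)
        assert rep.explained_variance_ratio[0] == pytest.approx(1.0)
        assert rep.coords3.shape[1] <= 3

    def test_ratios_non_increasing_and_sum_le_1(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 2, size=(20, 15))
        rep = run_pca(X)
        assert (np.diff(rep.explained_variance_ratio) <= 1e-12).all()
        assert rep.explained_variance_ratio.sum() <= 1 + 1e-9

    def test_full_rank_reconstruction(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(1)
        X = rng.integers(0, 2, size=(12, 8)).astype(float)
        # centered 12x8 matrix has rank <= min(11, 8); all 8 components
        # reconstruct it exactly
        pca = PCA(n_components=8, svd_solver="full")
        Z = pca.fit_transform(X)
        back = pca.inverse_transform(Z)
        assert np.allclose(back, X, atol=1e-8)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            run_pca(np.ones((1, 3)))


class TestLogistic:
    def test_separable_toy_auc_1_and_coefficient_signs(self):
        _, train, test = _toy_matrices()
        res = fit_logistic(train, test)
        assert res.auc == 1.0
        # patient-exclusive feature pushes toward patient, control-exclusive away
        assert res.coefficients[1] > 0 > res.coefficients[0]

    def test_single_class_training_rejected(self):
        _, train, test = _toy_matrices()
        bad = FeatureMatrix(
            0, train.feature_kmers, train.n_control_features,
            train.X[train.y == 1], train.y[train.y == 1],
            [s for s, y in zip(train.sample_ids, train.y) if y == 1],
        )
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(bad, test)

    def test_label_permutation_gives_chance_auc(self):
        rng = np.random.default_rng(0)
        n, p = 400, 20
        X = rng.integers(0, 2, size=(n, p)).astype(np.uint8)
        y = rng.integers(0, 2, size=n)  # labels independent of X
        ids = [str(i) for i in range(n)]
        train = FeatureMatrix(0, np.arange(p, dtype=np.uint64), 10, X[: n // 2],
                              y[: n // 2], ids[: n // 2])
        test = FeatureMatrix(0, np.arange(p, dtype=np.uint64), 10, X[n // 2 :],
                             y[n // 2 :], ids[n // 2 :])
        res = fit_logistic(train, test)
        assert 0.35 < res.auc < 0.65

    def test_deterministic(self):
        _, train, test = _toy_matrices()
        a, b = fit_logistic(train, test), fit_logistic(train, test)
        assert np.array_equal(a.scores, b.scores)
        assert np.array_equal(a.coefficients, b.coefficients)


def _separable_matrices(n_per_class=60):
    """Perfectly separable two-feature matrices, large enough that the
    boosted model's L1 leaf penalty (alpha=6) cannot zero out the split."""
    y = np.array([1] * n_per_class + [0] * n_per_class)
    X = np.column_stack([1 - y, y]).astype(np.uint8)
    ids = [str(i) for i in range(len(y))]
    kmers = np.array([10, 20], dtype=np.uint64)
    train = FeatureMatrix(0, kmers, 1, X, y, ids)
    test = FeatureMatrix(0, kmers, 1, X[::7], y[::7], ids[::7])
    return train, test


class TestBoosted:
    def test_separable_toy_auc_1(self):
        train, test = _separable_matrices()
        assert fit_boosted(train, test, seed=0).auc == 1.0

    def test_seeded_determinism(self):
        train, test = _separable_matrices()
        a = fit_boosted(train, test, seed=5)
        b = fit_boosted(train, test, seed=5)
        assert np.array_equal(a.scores, b.scores)

    def test_constant_features_give_chance_auc(self):
        p = 3
        X = np.ones((20, p), dtype=np.uint8)
        y = np.array([0, 1] * 10)
        ids = [str(i) for i in range(20)]
        fm = FeatureMatrix(0, np.arange(p, dtype=np.uint64), 1, X, y, ids)
        res = fit_boosted(fm, fm, seed=0)
        assert res.auc == pytest.approx(0.5)


class TestRanking:
    def _result(self, coefs, fm):
        return ModelResult(0, "logistic", fm.sample_ids, np.zeros(len(fm.y)),
                           fm.y, 0.5, {}, coefficients=np.asarray(coefs, float))

    def test_rank_by_absolute_value(self):
        _, train, _ = _toy_matrices()
        fm = FeatureMatrix(0, np.array([10, 20, 30], dtype=np.uint64), 1,
                           np.zeros((4, 3), np.uint8), np.array([0, 0, 1, 1]),
                           list("abcd"))
        ranked = coefficient_report(self._result([+2, -1, +0.5], fm), fm)
        assert list(ranked.kmers) == [10, 20, 30]
        assert list(ranked.coefficients) == [2, -1, 0.5]

    def test_all_zero_ties_break_by_code(self):
        fm = FeatureMatrix(0, np.array([30, 10, 20], dtype=np.uint64), 1,
                           np.zeros((2, 3), np.uint8), np.array([0, 1]), list("ab"))
        ranked = coefficient_report(self._result([0, 0, 0], fm), fm)
        assert list(ranked.kmers) == [10, 20, 30]

    def test_side_counts_at_top_n(self):
        kmers = np.arange(10, dtype=np.uint64)
        fm = FeatureMatrix(0, kmers, 1, np.zeros((2, 10), np.uint8),
                           np.array([0, 1]), list("ab"))
        coefs = np.arange(10, 0, -1).astype(float)  # column 0 (control) ranks first
        ranked = coefficient_report(self._result(coefs, fm), fm)
        counts = ranked.side_counts_at(10)
        assert counts == {"patient": 9, "control": 1}

    def test_coefficient_histogram_covers_all_features(self):
        fm = FeatureMatrix(0, np.arange(6, dtype=np.uint64), 3,
                           np.zeros((2, 6), np.uint8), np.array([0, 1]), list("ab"))
        ranked = coefficient_report(self._result([-2, -1, 0, 1, 2, 3], fm), fm)
        hist = ranked.coefficient_histogram(bins=4)
        assert hist["count"].sum() == 6


class TestTopN:
    def test_full_feature_count_reproduces_full_model_exactly(self):
        _, train, test = _toy_matrices()
        full = fit_logistic(train, test)
        ranked = coefficient_report(full, train)
        df = topn_retrain(train, test, ranked, grid=[train.X.shape[1]])
        assert df.iloc[0]["auc"] == full.auc

    def test_auc_flat_once_signal_features_included(self):
        rng = np.random.default_rng(2)
        n, p = 200, 12
        y = rng.integers(0, 2, size=n)
        X = rng.integers(0, 2, size=(n, p)).astype(np.uint8)
        X[:, 0] = y  # two signal columns, rest noise
        X[:, 1] = 1 - y
        ids = [str(i) for i in range(n)]
        train = FeatureMatrix(0, np.arange(p, dtype=np.uint64), 6, X[:150], y[:150], ids[:150])
        test = FeatureMatrix(0, np.arange(p, dtype=np.uint64), 6, X[150:], y[150:], ids[150:])
        ranked = coefficient_report(fit_logistic(train, test), train)
        df = topn_retrain(train, test, ranked, grid=[2, 6, 12])
        assert df["auc"].iloc[0] == 1.0
        assert (df["auc"] >= 0.99).all()

    def test_oversized_n_skipped_with_warning(self):
        _, train, test = _toy_matrices()
        ranked = coefficient_report(fit_logistic(train, test), train)
        with pytest.warns(UserWarning, match="exceeds"):
            df = topn_retrain(train, test, ranked, grid=[2, 99])
        assert list(df["n"]) == [2]


class TestEvaluate:
    def _res(self, scores, y, fold=0):
        scores, y = np.asarray(scores, float), np.asarray(y, int)
        from sklearn.metrics import roc_auc_score

        auc = roc_auc_score(y, scores) if len(np.unique(y)) > 1 else float("nan")
        return ModelResult(fold, "logistic", [str(i) for i in range(len(y))],
                           scores, y, auc, _confusion(y, scores))

    def test_hand_computed_roc_auc(self):
        # brute-force over thresholds: scores .9,.8,.3,.1 labels 1,0,1,0 -> 0.75
        rep = evaluate([self._res([0.9, 0.8, 0.3, 0.1], [1, 0, 1, 0])])
        assert rep.pooled_auc == pytest.approx(0.75)

    def test_perfect_scores(self):
        rep = evaluate([self._res([1, 0, 1, 0], [1, 0, 1, 0])])
        assert rep.pooled_auc == 1.0
        assert rep.confusion_pct["tp"] == 50.0 and rep.confusion_pct["tn"] == 50.0
        assert rep.confusion_pct["fp"] == 0.0

    def test_uninformative_scores(self):
        rep = evaluate([self._res([0.5] * 6, [1, 0, 1, 0, 1, 0])])
        assert rep.pooled_auc == pytest.approx(0.5)

    def test_single_class_fold_excluded_with_warning(self):
        good = self._res([0.9, 0.1], [1, 0], fold=0)
        degenerate = self._res([0.9, 0.8], [1, 1], fold=1)
        with pytest.warns(UserWarning, match="single-class"):
            rep = evaluate([good, degenerate])
        assert rep.excluded_folds == [1]
        assert rep.n_folds_used == 1
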