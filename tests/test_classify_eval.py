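"""SVM evaluation: design assembly, LOO/independent modes, metrics, AUC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import auc as sk_trapezoid
from sklearn.metrics import roc_curve

from stablerec.classify_eval import (
    ClinicalBlock,
    EvaluationReport,
    SvmConfig,
    assemble_design,
    auc,
    fit_design_stats,
    independent_evaluate,
    loo_evaluate,
)
from stablerec.errors import LeakageError
from stablerec.stability_selection import FeatureIndexSet


def _clinical(n, rng):
    return [
        ClinicalBlock(
            age=float(rng.uniform(30, 70)),
            er=int(rng.integers(2)),
            pgr=int(rng.integers(2)),
            her2=int(rng.integers(2)),
        )
        for _ in range(n)
    ]


class TestAuc:
    def test_all_tied_scores_give_half(self):
        y = np.array([0, 1, 0, 1, 1])
        assert auc(np.zeros(5), y) == 0.5

    def test_complete_separation_gives_one(self):
        y = np.array([0, 0, 1, 1])
        assert auc(np.array([-2.0, -1.0, 3.0, 4.0]), y) == 1.0

    @given(st.integers(min_value=0, max_value=100))
    @settings(deadline=None, max_examples=20)
    def test_reversal_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.permutation(np.r_[np.zeros(8), np.ones(7)]).astype(int)
        s = np.round(rng.normal(size=15), 1)  # ties included
        assert auc(-s, y) == pytest.approx(1 - auc(s, y), abs=1e-12)

    def test_equals_trapezoidal_roc_area(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            y = rng.permutation(np.r_[np.zeros(12), np.ones(9)]).astype(int)
            s = np.round(rng.normal(size=21), 1)
            fpr, tpr, _ = roc_curve(y, s)
            assert auc(s, y) == pytest.approx(sk_trapezoid(fpr, tpr), abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auc(np.arange(4.0), np.ones(4, dtype=int))


class TestEvaluationReport:
    def test_definitional_arithmetic(self):
        # confusion tp=2, fn=1, tn=3, fp=1 at threshold 0
        scores = np.array([1.0, 2.0, -1.0, -3.0, -2.0, -1.5, 0.5])
        labels = np.array([1, 1, 1, 0, 0, 0, 0])
        rep = EvaluationReport.from_scores(scores, labels, list("abcdefg"))
        assert (rep.tp, rep.fn, rep.tn, rep.fp) == (2, 1, 3, 1)
        assert rep.sensitivity == pytest.approx(2 / 3)
        assert rep.specificity == pytest.approx(3 / 4)
        assert rep.accuracy == pytest.approx(5 / 7)

    def test_roc_is_monotone(self):
        rng = np.random.default_rng(2)
        y = rng.permutation(np.r_[np.zeros(10), np.ones(10)]).astype(int)
        rep = EvaluationReport.from_scores(rng.normal(size=20), y, [str(i) for i in range(20)])
        fprs = [p[0] for p in rep.roc]
        tprs = [p[1] for p in rep.roc]
        assert fprs == sorted(fprs) and tprs == sorted(tprs)


class TestAssembleDesign:
    def test_column_counts_with_clinical(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 100))
        clin = _clinical(30, rng)
        d18 = assemble_design(X, FeatureIndexSet(range(18)), clin)
        assert d18.shape[1] == 22  # 13 + 5 CNN features + 4 clinical
        d15 = assemble_design(X, FeatureIndexSet(range(15)), clin)
        assert d15.shape[1] == 19  # 15 + 4
        d_no = assemble_design(X, FeatureIndexSet(range(15)))
        assert d_no.shape[1] == 15

    def test_zscoring_uses_training_stats_only(self):
        rng = np.random.default_rng(1)
        Xtr = rng.normal(5.0, 2.0, size=(40, 6))
        st_ = fit_design_stats(Xtr, FeatureIndexSet(range(6)))
        d = assemble_design(Xtr, FeatureIndexSet(range(6)), stats_=st_)
        np.testing.assert_allclose(d.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(d.std(axis=0), 1.0, atol=1e-12)
        # a held-out row is scored with the *training* statistics
        Xte = np.full((1, 6), 5.0)
        dte = assemble_design(Xte, FeatureIndexSet(range(6)), stats_=st_)
        np.testing.assert_allclose(dte, ((5.0 - st_.mean) / st_.sd)[None, :])

    def test_zero_variance_training_column_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 4))
        X[:, 2] = 7.0
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            d = assemble_design(X, FeatureIndexSet(range(4)))
        assert d.shape[1] == 3


class TestLooEvaluate:
    def test_perfectly_separable_feature(self):
        rng = np.random.default_rng(3)
        y = rng.permutation(np.r_[np.zeros(10), np.ones(8)]).astype(int)
        X = rng.normal(size=(18, 5)) * 0.01
        X[:, 2] = y * 4.0 - 2.0
        ids = [f"p{i}" for i in range(18)]
        rep = loo_evaluate(X, y, ids, FeatureIndexSet([2]))
        assert rep.accuracy == 1.0
        assert rep.auc == 1.0

    def test_metrics_invariant_to_patient_order(self):
        rng = np.random.default_rng(4)
        y = rng.permutation(np.r_[np.zeros(12), np.ones(8)]).astype(int)
        X = rng.normal(size=(20, 6))
        X[y == 1] += 0.8
        ids = [f"p{i}" for i in range(20)]
        rep1 = loo_evaluate(X, y, ids, FeatureIndexSet(range(6)))
        perm = rng.permutation(20)
        rep2 = loo_evaluate(
            X[perm], y[perm], [ids[i] for i in perm], FeatureIndexSet(range(6))
        )
        assert rep1.summary_dict() == pytest.approx(rep2.summary_dict())

    def test_label_permutation_null_auc_band(self):
        """On a fixed noise feature matrix, permuting labels gives mean LOO
        AUC inside [0.4, 0.6] over 20 runs."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 10))
        base = np.r_[np.zeros(18), np.ones(12)].astype(int)
        ids = [f"p{i}" for i in range(30)]
        aucs = []
        for r in range(20):
            y = np.random.default_rng(100 + r).permutation(base)
            rep = loo_evaluate(X, y, ids, FeatureIndexSet(range(10)))
            aucs.append(rep.auc)
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_empty_feature_set_gives_chance_scores(self):
        rng = np.random.default_rng(6)
        y = rng.permutation(np.r_[np.zeros(8), np.ones(6)]).astype(int)
        X = rng.normal(size=(14, 4))
        rep = loo_evaluate(X, y, [str(i) for i in range(14)], FeatureIndexSet([]))
        assert rep.auc == 0.5  # all scores tied at zero


class TestIndependentEvaluate:
    def _separable(self, n, seed):
        rng = np.random.default_rng(seed)
        y = rng.permutation(np.r_[np.zeros(n // 2), np.ones(n - n // 2)]).astype(int)
        X = rng.normal(size=(n, 4)) * 0.01
        X[:, 1] = y * 2.0 - 1.0
        return X, y

    def test_resubstitution_ceiling(self):
        X, y = self._separable(20, 7)
        ids = [f"p{i}" for i in range(20)]
        osf = FeatureIndexSet([1], provenance=set(ids))
        rep = independent_evaluate(X, y, ids, X, y, [f"q{i}" for i in range(20)], osf)
        assert rep.accuracy == 1.0

    def test_empty_test_set_raises(self):
        X, y = self._separable(10, 8)
        ids = [f"p{i}" for i in range(10)]
        with pytest.raises(ValueError, match="empty"):
            independent_evaluate(
                X, y, ids, X[:0], y[:0], [], FeatureIndexSet([1])
            )

    def test_leakage_guard(self):
        X, y = self._separable(12, 9)
        ids = [f"p{i}" for i in range(12)]
        osf = FeatureIndexSet([1], provenance=set(ids) | {"q3"})
        with pytest.raises(LeakageError, match="q3"):
            independent_evaluate(
                X, y, ids, X, y, [f"q{i}" for i in range(12)], osf
            )

    def test_generalization_consistency_on_surrogate_data(self):
        """Train/test drawn from the same process: independent-test AUC
        tracks LOO AUC (mean absolute gap <= 0.1 over 10 replicates)."""
        from stablerec.synthetic_data import generate_surrogate_features

        gaps = []
        for r in range(10):
            X, y, planted = generate_surrogate_features(
                n_patients=80, n_non_rfsi=28, n_features=30, n_informative=4,
                effect=1.5, seed=r,
            )
            tr, te = np.arange(80) % 2 == 0, np.arange(80) % 2 == 1
            Xtr, ytr, Xte, yte = X[tr], y[tr], X[te], y[te]
            ids_tr = [f"tr{i}" for i in range(40)]
            ids_te = [f"te{i}" for i in range(40)]
            osf = FeatureIndexSet(planted, provenance=set(ids_tr))
            loo = loo_evaluate(Xtr, ytr, ids_tr, osf)
            ind = independent_evaluate(
                Xtr, ytr, ids_tr, Xte, yte, ids_te, osf
            )
            gaps.append(abs(loo.auc - ind.auc))
        assert np.mean(gaps) <= 0.1


def test_clinical_block_validation():
    with pytest.raises(ValueError):
        ClinicalBlock(age=-1.0, er=0, pgr=0, her2=0)
    with pytest.raises(ValueError):
        ClinicalBlock(age=50.0, er=2, pgr=0, her2=0)
    assert ClinicalBlock(50.0, 1, 0, 1).as_array().tolist() == [50.0, 1, 0, 1]


def test_svm_c_is_configurable():
    rng = np.random.default_rng(11)
    y = rng.permutation(np.r_[np.zeros(10), np.ones(10)]).astype(int)
    X = rng.normal(size=(20, 3))
    X[y == 1] += 1.0
    ids = [str(i) for i in range(20)]
    r1 = loo_evaluate(X, y, ids, FeatureIndexSet(range(3)), svm_config=SvmConfig(C=1.0))
    r2 = loo_evaluate(X, y, ids, FeatureIndexSet(range(3)), svm_config=SvmConfig(C=0.01))
    assert r1.scores != r2.scores
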