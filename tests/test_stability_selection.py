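"""Filter, embedded criterion, dynamic selection and OSF construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from stablerec._forest import gini_importances
from stablerec.errors import ConfigurationError
from stablerec.stability_selection import (
    FeatureIndexSet,
    SelectionConfig,
    compute_osf,
    dynamic_selection,
    forest_embedded_select,
    wilcoxon_filter,
    wilcoxon_pvalues,
)
from stablerec.synthetic_data import generate_surrogate_features


class TestWilcoxonFilter:
    def test_constant_feature_never_selected(self):
        X = np.ones((20, 3))
        X[:, 1] = np.arange(20)
        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        p = wilcoxon_pvalues(X, y)
        assert p[0] == 1.0 and p[2] == 1.0

    def test_full_separation_4v4_not_significant(self):
        # exact two-sided p = 2 / C(8,4) = 2/70, above the 0.001 cutoff
        X = np.array([1, 2, 3, 4, 5, 6, 7, 8], dtype=float)[:, None]
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        p = wilcoxon_pvalues(X, y)
        assert p[0] == pytest.approx(2 / 70)
        assert len(wilcoxon_filter(X, y, alpha=0.001)) == 0

    def test_full_separation_10v10_is_significant(self):
        from math import comb

        X = np.arange(20, dtype=float)[:, None]
        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        p = wilcoxon_pvalues(X, y)
        assert p[0] == pytest.approx(2 / comb(20, 10))
        assert list(wilcoxon_filter(X, y, alpha=0.001)) == [0]

    def test_matches_scipy_asymptotic_with_ties(self):
        rng = np.random.default_rng(3)
        X = np.round(rng.normal(size=(40, 25)), 1)  # coarse grid forces ties
        y = rng.permutation(np.r_[np.zeros(20), np.ones(20)]).astype(int)
        p = wilcoxon_pvalues(X, y)
        for j in range(25):
            ref = mannwhitneyu(
                X[y == 1, j], X[y == 0, j], alternative="two-sided",
                method="asymptotic",
            ).pvalue
            assert p[j] == pytest.approx(ref, rel=1e-10)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="class"):
            wilcoxon_pvalues(np.zeros((5, 2)), np.ones(5, dtype=int))

    @given(st.integers(min_value=1, max_value=20))
    @settings(deadline=None, max_examples=10)
    def test_looser_alpha_never_shrinks_selection(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(30, 40))
        y = rng.permutation(np.r_[np.zeros(12), np.ones(18)]).astype(int)
        tight = set(wilcoxon_filter(X, y, alpha=0.01))
        loose = set(wilcoxon_filter(X, y, alpha=0.10))
        assert tight <= loose


class TestForestEmbeddedSelect:
    def test_empty_candidates_empty_result(self):
        cfg = SelectionConfig()
        out = forest_embedded_select(np.zeros((10, 5)), np.r_[np.zeros(5), np.ones(5)],
                                     cfg, candidates=[])
        assert len(out) == 0

    def test_separating_feature_beats_constants(self):
        y = np.r_[np.zeros(15), np.ones(15)].astype(int)
        X = np.ones((30, 6))
        X[:, 3] = y  # perfect separator among constants
        out = forest_embedded_select(X, y, SelectionConfig(seed=0))
        assert list(out) == [3]

    def test_planted_recovery_across_seeds(self):
        """5 informative among 100 noise, n=60 balanced: mean recovery >= 0.8."""
        recoveries = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = rng.permutation(np.r_[np.zeros(30), np.ones(30)]).astype(int)
            X = rng.normal(size=(60, 105))
            planted = [10, 30, 50, 70, 90]
            X[np.ix_(y == 1, planted)] += 1.5
            out = forest_embedded_select(X, y, SelectionConfig(seed=seed))
            recoveries.append(len(set(out) & set(planted)) / 5)
        assert np.mean(recoveries) >= 0.8

    def test_agrees_with_sklearn_importance_ranking(self):
        """The numba forest is a reimplementation of the standard
        Gini-importance forest; its ranking must track sklearn's."""
        from sklearn.ensemble import RandomForestClassifier

        rng = np.random.default_rng(1)
        y = rng.permutation(np.r_[np.zeros(40), np.ones(40)]).astype(int)
        X = rng.normal(size=(80, 12))
        X[y == 1, 4] += 2.0
        X[y == 1, 9] += 1.0
        imp = gini_importances(X, y, n_trees=300, seed=0)
        sk = RandomForestClassifier(n_estimators=300, random_state=0, n_jobs=1)
        sk.fit(X, y)
        assert np.argmax(imp) == np.argmax(sk.feature_importances_) == 4
        assert np.corrcoef(imp, sk.feature_importances_)[0, 1] > 0.9


class TestFeatureIndexSet:
    def test_sorted_deduplicated_and_timepoints(self):
        s = FeatureIndexSet([50000, 3, 3, 99])
        assert s.indices == (3, 99, 50000)
        assert s.timepoint_counts() == {"T1": 2, "T2": 1}

    def test_intersection_merges_provenance(self):
        a = FeatureIndexSet([1, 2, 3], provenance={"p1"})
        b = FeatureIndexSet([2, 3, 4], provenance={"p2"})
        c = a.intersection(b)
        assert c.indices == (2, 3)
        assert c.provenance == {"p1", "p2"}


class TestComputeOsf:
    def test_idempotent_on_identical_sets(self):
        s = FeatureIndexSet([5, 9, 12])
        assert compute_osf([s, s, s]).indices == (5, 9, 12)

    def test_empty_fold_absorbs(self):
        assert len(compute_osf([FeatureIndexSet([1, 2]), FeatureIndexSet([])])) == 0

    def test_hand_checkable_intersection(self):
        folds = [
            FeatureIndexSet([1, 2, 3, 7]),
            FeatureIndexSet([2, 3, 7, 9]),
            FeatureIndexSet([2, 7, 8]),
        ]
        assert compute_osf(folds).indices == (2, 7)

    def test_no_folds_raises(self):
        with pytest.raises(ValueError):
            compute_osf([])


class TestDynamicSelection:
    def _small_problem(self, seed=0, n=24, p=60, n_pos=8, effect=0.0):
        rng = np.random.default_rng(seed)
        y = np.zeros(n, dtype=int)
        y[:n_pos] = 1
        X = rng.normal(size=(n, p))
        if effect:
            X[y == 1, :5] += effect
        return X, y

    def test_pure_noise_gives_empty_sets_and_early_exit(self):
        X, y = self._small_problem(seed=1)
        cfg = SelectionConfig(seed=0)
        fold_sets, traces = dynamic_selection(X, y, cfg)
        assert all(len(s) == 0 for s in fold_sets.values())
        # loop exits at the first stop check, i.e. after two iterations
        assert len(traces[0].iterations) == 2

    def test_cumulative_sets_never_grow(self):
        X, y = self._small_problem(seed=2, effect=2.0)
        cfg = SelectionConfig(filter_alpha=0.01, seed=0, max_iterations=4)
        _, traces = dynamic_selection(X, y, cfg)
        for tr in traces:
            sizes = [len(rec.cumulative) for rec in tr.iterations]
            assert sizes == sorted(sizes, reverse=True)
            # cumulative is the running intersection of iteration unions
            running = set(tr.iterations[0].union)
            for rec in tr.iterations:
                running &= set(rec.union)
                assert set(rec.cumulative) == running

    def test_deterministic_under_seed(self):
        X, y = self._small_problem(seed=3, effect=1.5)
        cfg = SelectionConfig(filter_alpha=0.01, seed=42, max_iterations=3)
        a, _ = dynamic_selection(X, y, cfg)
        b, _ = dynamic_selection(X, y, cfg)
        assert {k: v.indices for k, v in a.items()} == {
            k: v.indices for k, v in b.items()
        }

    def test_fold_provenance_excludes_held_out_patient(self):
        X, y = self._small_problem(seed=4)
        fold_sets, _ = dynamic_selection(X, y, SelectionConfig(seed=0))
        for pid, s in fold_sets.items():
            assert pid not in s.provenance
            assert len(s.provenance) == X.shape[0] - 1

    def test_infeasible_subset_raises(self):
        X, y = self._small_problem(n=6, n_pos=2)
        with pytest.raises(ConfigurationError, match="fewer than 2"):
            dynamic_selection(X, y, SelectionConfig(seed=0))

    def test_single_class_raises(self):
        X = np.random.default_rng(0).normal(size=(10, 5))
        with pytest.raises(ValueError, match="2 patients per class"):
            dynamic_selection(X, np.ones(10, dtype=int), SelectionConfig())

    def test_planted_block_lands_in_fold_sets(self):
        """At the generator's configured effect size every planted column is
        recovered by nearly every fold (full-scale check is in acceptance)."""
        X, y, planted = generate_surrogate_features(
            n_patients=48, n_non_rfsi=13, n_features=400, n_informative=6,
            seed=5,
        )
        fold_sets, _ = dynamic_selection(X, y, SelectionConfig(seed=0))
        fracs = [
            np.mean([i in set(s.indices) for s in fold_sets.values()])
            for i in planted
        ]
        assert np.mean(fracs) >= 0.8
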