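"""Fold splitting, aggregation formulas, bagging consensus, and pipeline contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydml.core import DMLSet, SampleLabels, ValidationError
from hydml.ensemble import (
    EnsembleConfig,
    aggregate_fold,
    bagging_select,
    iteration_seed,
    run_hydml,
    stratified_folds,
    threshold_filter,
    union_folds,
)
from hydml.selectors import FeatureRanking, SelectorConfig
from hydml.simulate import simulate_cohort


def _rank(ids, weights, name="s"):
    return FeatureRanking(name, list(ids), np.asarray(weights, float))


class TestStratifiedFolds:
    def test_balanced_20_into_10(self):
        y = np.array([0] * 10 + [1] * 10)
        folds = stratified_folds(y, 10, seed=1)
        assert all(len(f) == 2 for f in folds)
        assert all(sorted(y[f]) == [0, 1] for f in folds)

    def test_19_samples_into_10_partitions(self):
        y = np.array([0] * 10 + [1] * 9)
        folds = stratified_folds(y, 10, seed=2)
        sizes = sorted(len(f) for f in folds)
        assert sizes == [1] + [2] * 9
        allidx = np.concatenate(folds)
        assert sorted(allidx) == list(range(19))  # disjoint cover

    def test_class_fractions_within_one_sample(self):
        rng = np.random.default_rng(3)
        for trial in range(100):
            n = int(rng.integers(12, 60))
            k = int(rng.integers(2, 8))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            folds = stratified_folds(y, k, seed=trial)
            for cls in (0, 1):
                per_fold = [int((y[f] == cls).sum()) for f in folds]
                expect = (y == cls).sum() / k
                assert all(abs(c - expect) < 1.0 + 1e-9 for c in per_fold)
            sizes = [len(f) for f in folds]
            assert max(sizes) - min(sizes) <= 1

    def test_reproducible_and_validated(self):
        y = np.array([0, 0, 1, 1, 0, 1])
        a = stratified_folds(y, 3, seed=7)
        b = stratified_folds(y, 3, seed=7)
        assert all(np.array_equal(x, z) for x, z in zip(a, b))
        with pytest.raises(ValueError):
            stratified_folds(y, 1, seed=0)
        with pytest.raises(ValueError):
            stratified_folds(y, 7, seed=0)


class TestAggregation:
    def test_single_selector_identity(self):
        r = _rank("ab", [1.0, 0.3])
        assert np.allclose(aggregate_fold([r], [1.0]), r.weights)

    def test_zero_accuracy_annihilates(self):
        r1, r2 = _rank("ab", [1.0, 0.0]), _rank("ab", [0.0, 1.0])
        assert np.allclose(aggregate_fold([r1, r2], [0.7, 0.0]), [0.7, 0.0])

    def test_printed_formula_substitution(self):
        r1, r2 = _rank("ab", [1.0, 0.0]), _rank("ab", [0.0, 1.0])
        assert np.allclose(aggregate_fold([r1, r2], [0.9, 0.6]), [0.9, 0.6])

    def test_mismatched_axes_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_fold([_rank("ab", [1, 0]), _rank("ac", [1, 0])], [1, 1])

    def test_monotone_in_accuracy(self, rng):
        rankings = [_rank(range(5), rng.random(5)) for _ in range(3)]
        accs = [0.5, 0.6, 0.7]
        base = aggregate_fold(rankings, accs)
        bumped = aggregate_fold(rankings, [0.5, 0.9, 0.7])
        assert (bumped >= base - 1e-12).all()


class TestThresholdAndUnion:
    def test_boundary_kept(self):
        surv = threshold_filter(np.array([0.9, 0.005, 0.01]), ["l1", "l2", "l3"], 0.01)
        assert surv == {"l1", "l3"}

    def test_tau_zero_keeps_all(self):
        assert threshold_filter(np.array([0.0, 0.5]), ["a", "b"], 0.0) == {"a", "b"}

    def test_all_below_gives_empty(self):
        assert threshold_filter(np.array([0.001, 0.002]), ["a", "b"], 0.01) == set()

    def test_union_identical_sets(self):
        u = union_folds([{"a", "b"}] * 4)
        assert u.loci == {"a", "b"} and all(c == 4 for c in u.counts.values())

    def test_union_disjoint_sets(self):
        u = union_folds([{"a"}, {"b"}, {"c"}])
        assert u.loci == {"a", "b", "c"} and all(c == 1 for c in u.counts.values())

    def test_union_sums_weights(self):
        u = union_folds([{"x"}, {"x"}, set()], [{"x": 0.5}, {"x": 0.3}, {}])
        assert u.weights["x"] == pytest.approx(0.8)


class TestBagging:
    def test_threshold_semantics(self):
        sets = (
            [DMLSet(f"i{t}", {"A", "B"}) for t in range(5)]
            + [DMLSet(f"i{t}", {"A", "C"}) for t in range(5, 9)]
            + [DMLSet("i9", {"A"})]
        )
        # occurrences: A 10, B 5, C 4
        final = bagging_select(sets, min_count=5)
        assert final.loci == {"A", "B"}
        assert final.counts == {"A": 10, "B": 5}

    def test_single_iteration_identity(self):
        s = DMLSet("i", {"x", "y"}, weights={"x": 1.0, "y": 0.2}, counts={"x": 1, "y": 1})
        final = bagging_select([s], min_count=1)
        assert final.loci == s.loci and final.weights == s.weights

    def test_all_empty(self):
        assert bagging_select([DMLSet("a"), DMLSet("b")], 1).loci == set()

    def test_final_weight_is_mean_over_containing_iterations(self):
        sets = [
            DMLSet("a", {"x"}, weights={"x": 0.4}),
            DMLSet("b", {"x"}, weights={"x": 0.8}),
            DMLSet("c", set()),
        ]
        final = bagging_select(sets, 2)
        assert final.weights["x"] == pytest.approx(0.6)

    @given(st.lists(st.sets(st.integers(0, 8)), min_size=1, max_size=6),
           st.integers(1, 6))
    @settings(max_examples=60, deadline=None)
    def test_lowering_count_only_grows(self, raw_sets, c):
        sets = [DMLSet(f"i{t}", {str(x) for x in s}) for t, s in enumerate(raw_sets)]
        c = min(c, len(sets))
        strict = bagging_select(sets, c).loci
        lenient = bagging_select(sets, max(c - 1, 1)).loci
        assert strict <= lenient


def _tiny_cfg(seed=0, **kw):
    defaults = dict(
        n_folds=3, n_iterations=2, bagging_min_count=1,
        selectors=("info_gain",), selector_config=SelectorConfig(), seed=seed,
    )
    defaults.update(kw)
    return EnsembleConfig(**defaults)


@pytest.fixture(scope="module")
def cohort():
    return simulate_cohort(n_normal=12, n_tumor=12, n_loci=120, n_dml=8,
                           effect_size=0.45, seed=21)


class TestRunHydml:
    def test_same_seed_identical_results(self, cohort):
        mat, labels, _ = cohort
        r1 = run_hydml(mat, labels, _tiny_cfg(seed=4))
        r2 = run_hydml(mat, labels, _tiny_cfg(seed=4))
        assert r1.final.loci == r2.final.loci
        assert r1.final.weights == r2.final.weights
        a1 = [(f.iteration, f.fold_index, f.accuracies) for f in r1.fold_results]
        a2 = [(f.iteration, f.fold_index, f.accuracies) for f in r2.fold_results]
        assert a1 == a2

    def test_final_subset_of_input_loci(self, cohort):
        mat, labels, _ = cohort
        res = run_hydml(mat, labels, _tiny_cfg(seed=5))
        assert res.final.loci <= set(mat.locus_ids)
        for s in res.iteration_sets:
            assert s.loci <= set(mat.locus_ids)

    def test_raising_tau_shrinks_surviving_sets(self, cohort):
        mat, labels, _ = cohort
        lo = run_hydml(mat, labels, _tiny_cfg(seed=6, weight_threshold=0.01))
        hi = run_hydml(mat, labels, _tiny_cfg(seed=6, weight_threshold=0.3))
        for a, b in zip(hi.fold_results, lo.fold_results):
            assert a.surviving <= b.surviving

    def test_reduction_to_threshold_union_oracle(self, cohort):
        # with one selector, two folds, one iteration the pipeline must equal
        # a direct reimplementation: rank, accuracy-scale, threshold, union
        from hydml.selectors import info_gain_rank, svm_accuracy

        mat, labels, _ = cohort
        cfg = _tiny_cfg(seed=9, n_folds=2, n_iterations=1,
                        selector_config=SelectorConfig(ig_fdr=None))
        res = run_hydml(mat, labels, cfg)
        assert res.final.loci  # raw info gain keeps the instance non-trivial
        folds = stratified_folds(labels, 2, iteration_seed(9, 1))
        expected_weights: dict[str, float] = {}
        expected_counts: dict[str, int] = {}
        for test_idx in folds:
            train_idx = np.setdiff1d(np.arange(mat.n_samples), test_idx)
            mtr = mat.subset_samples(train_idx)
            ltr = SampleLabels(mtr.sample_ids, labels.labels[train_idx])
            mte = mat.subset_samples(test_idx)
            lte = SampleLabels(mte.sample_ids, labels.labels[test_idx])
            rk = info_gain_rank(mtr, ltr, cfg.selector_config)
            support = rk.supported_loci(0.01)
            acc = svm_accuracy(mtr, ltr, mte, lte, support) if support else 0.0
            for l, w in zip(rk.locus_ids, acc * rk.weights):
                if w >= 0.01:
                    expected_weights[l] = expected_weights.get(l, 0.0) + w
                    expected_counts[l] = expected_counts.get(l, 0) + 1
        assert res.final.loci == set(expected_weights)
        # the single iteration set carries fold counts; the bagging consensus
        # re-counts iteration occurrences (all 1 for T = 1)
        assert res.iteration_sets[0].counts == expected_counts
        assert res.final.counts == {l: 1 for l in expected_weights}
        for l, w in expected_weights.items():
            assert res.final.weights[l] == pytest.approx(w)

    def test_empty_final_warns_not_errors(self):
        mat, labels, _ = simulate_cohort(n_normal=10, n_tumor=10, n_loci=60,
                                         n_dml=0, seed=33)
        with pytest.warns(UserWarning, match="empty"):
            res = run_hydml(mat, labels, _tiny_cfg(seed=1, weight_threshold=10.0))
        assert res.final.loci == set()


def test_iteration_seed_is_stable_and_distinct():
    s1, s2 = iteration_seed(42, 1), iteration_seed(42, 2)
    assert s1 == iteration_seed(42, 1)
    assert s1 != s2 and 0 <= s1 < 2**31


def test_config_validation():
    with pytest.raises(ValueError):
        EnsembleConfig(n_folds=1)
    with pytest.raises(ValueError):
        EnsembleConfig(bagging_min_count=11)
    with pytest.raises(ValueError):
        EnsembleConfig(selectors=("bogus",))
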