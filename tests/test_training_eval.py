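import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import isoscan.training_eval as te
from conftest import SMALL_GRID, tiny_builder
from isoscan.errors import ParameterError, TrainingError
from isoscan.isosurface import IsoChannelStack
from isoscan.nn import Hyperparams
from isoscan.training_eval import (
    FoldMetrics,
    cv_error,
    cv_sd_sem,
    nested_cv,
    roc_auc,
    select_levels,
    stratified_kfold,
    train_and_score,
    welch_test,
)

FAST_HP = Hyperparams(learning_rate=0.05, max_epochs=30, patience=None, batch_size=8)


def make_stack(data, subject_id, label, levels=(0.4, 0.7)):
    return IsoChannelStack(
        channels=np.asarray(data, dtype=np.float32),
        levels=levels, subject_id=subject_id, label=label,
    )


def toy_cohort(n=20, grid=(4, 4, 4), separable=True, seed=0):
    """Two-channel stacks; the high channel mean encodes the class."""
    rng = np.random.default_rng(seed)
    cohort, labels = [], {}
    for i in range(n):
        label = "PD" if i % 2 else "NC"
        data = rng.random((2, *grid)) * 0.1
        if separable and label == "PD":
            data[1] += 0.8
        sid = f"S{i:03d}"
        cohort.append((make_stack(data, sid, label), label))
        labels[sid] = label
    return cohort, labels


class TestStratifiedKfold:
    def test_two_class_toy_leave_pairs(self):
        labels = {"a": "NC", "b": "NC", "c": "PD", "d": "PD"}
        fa = stratified_kfold(labels, k=2, seed=0)
        for j in (0, 1):
            test = fa.test_ids(j)
            assert len(test) == 2
            assert {fa.labels[s] for s in test} == {"NC", "PD"}

    def test_folds_partition_subjects(self):
        labels = {f"s{i}": ("PD" if i % 3 else "NC") for i in range(30)}
        fa = stratified_kfold(labels, k=5, seed=3)
        all_test = [s for j in range(5) for s in fa.test_ids(j)]
        assert sorted(all_test) == sorted(labels)
        assert len(set(all_test)) == 30

    def test_deterministic_in_seed(self):
        labels = {f"s{i}": ("PD" if i % 2 else "NC") for i in range(20)}
        a = stratified_kfold(labels, 4, seed=9).fold_of_subject
        b = stratified_kfold(labels, 4, seed=9).fold_of_subject
        assert a == b

    def test_small_class_rejected(self):
        labels = {"a": "NC", "b": "NC", "c": "NC", "d": "PD"}
        with pytest.raises(ParameterError, match="PD"):
            stratified_kfold(labels, k=2, seed=0)

    @given(st.integers(10, 60), st.integers(2, 5), st.integers(0, 100))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_stratification_within_one_subject(self, n, k, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, size=n)
        if min((y == 0).sum(), (y == 1).sum()) < k:
            return
        labels = {f"s{i:03d}": ("PD" if v else "NC") for i, v in enumerate(y)}
        fa = stratified_kfold(labels, k, seed)
        for cls in ("NC", "PD"):
            total = sum(1 for v in labels.values() if v == cls)
            per_fold = [
                sum(1 for s in fa.test_ids(j) if labels[s] == cls) for j in range(k)
            ]
            assert max(per_fold) - min(per_fold) <= 1
            assert sum(per_fold) == total


class TestCvError:
    def test_perfect_hard_predictions(self):
        scores = {"a": 1.0, "b": 0.0}
        labels = {"a": "PD", "b": "NC"}
        assert cv_error((scores, labels)) == 0.0

    def test_hand_arithmetic_example(self):
        scores = {"a": 0.5, "b": 0.5}
        labels = {"a": "PD", "b": "NC"}
        assert cv_error((scores, labels)) == pytest.approx(0.25)

    def test_bounded_by_one_for_probabilities(self, rng):
        scores = {f"s{i}": float(rng.random()) for i in range(30)}
        labels = {f"s{i}": ("PD" if rng.random() > 0.5 else "NC") for i in range(30)}
        assert 0.0 <= cv_error((scores, labels)) <= 1.0

    def test_empty_fold_rejected(self):
        with pytest.raises(ParameterError):
            cv_error(({}, {}))


class TestCvSdSem:
    def test_identical_errors_give_zero(self):
        sd, sem = cv_sd_sem([0.2] * 10)
        assert sd == 0.0 and sem == 0.0

    def test_two_point_brute_force(self):
        errors = [0.1, 0.3]
        sd, sem = cv_sd_sem(errors)
        mean = sum(errors) / 2
        var = sum((e - mean) ** 2 for e in errors) / (2 - 1)
        assert abs(sd - var**0.5) < 1e-12
        assert abs(sem - sd / 2**0.5) < 1e-12

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=12))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_matches_brute_force_variance(self, errors):
        sd, sem = cv_sd_sem(errors)
        k = len(errors)
        mean = sum(errors) / k
        brute_sd = (sum((e - mean) ** 2 for e in errors) / (k - 1)) ** 0.5
        assert abs(sd - brute_sd) < 1e-12
        assert abs(sem - brute_sd / k**0.5) < 1e-12
        assert sem <= sd

    def test_single_fold_rejected(self):
        with pytest.raises(ParameterError):
            cv_sd_sem([0.1])


def pairwise_auc(scores, labels):
    """Exhaustive Mann-Whitney oracle: P(score_PD > score_NC) + ties/2."""
    pd_scores = [scores[s] for s in scores if labels[s] == "PD"]
    nc_scores = [scores[s] for s in scores if labels[s] == "NC"]
    wins = sum(
        1.0 if p > n else (0.5 if p == n else 0.0)
        for p in pd_scores for n in nc_scores
    )
    return wins / (len(pd_scores) * len(nc_scores))


class TestRocAuc:
    def test_perfect_separation(self):
        scores = {"a": 0.9, "b": 0.8, "c": 0.2, "d": 0.1}
        labels = {"a": "PD", "b": "PD", "c": "NC", "d": "NC"}
        _, auc = roc_auc(scores, labels)
        assert auc == 1.0

    def test_matches_exhaustive_pair_oracle_with_ties(self, rng):
        for trial in range(10):
            n = 8
            scores = {f"s{i}": float(rng.integers(0, 4)) / 3 for i in range(n)}
            labels = {f"s{i}": ("PD" if i < 3 else "NC") for i in range(n)}
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(pairwise_auc(scores, labels))

    def test_label_inversion_flips_auc(self, rng):
        scores = {f"s{i}": float(rng.random()) for i in range(12)}
        labels = {f"s{i}": ("PD" if i % 3 else "NC") for i in range(12)}
        flipped = {s: ("NC" if v == "PD" else "PD") for s, v in labels.items()}
        _, auc = roc_auc(scores, labels)
        _, auc_flipped = roc_auc(scores, flipped)
        assert auc_flipped == pytest.approx(1.0 - auc)

    def test_roc_points_monotone(self, rng):
        scores = {f"s{i}": float(rng.random()) for i in range(20)}
        labels = {f"s{i}": ("PD" if i % 2 else "NC") for i in range(20)}
        points, _ = roc_auc(scores, labels)
        fpr = [p[0] for p in points]
        tpr = [p[1] for p in points]
        assert fpr == sorted(fpr) and tpr == sorted(tpr)

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            roc_auc({"a": 0.5, "b": 0.6}, {"a": "PD", "b": "PD"})


class TestWelch:
    def test_identical_samples_give_p_one(self):
        assert welch_test([0.9, 0.9, 0.9], [0.9, 0.9, 0.9]) == 1.0

    def test_separated_samples_significant(self):
        p = welch_test([0.90, 0.91, 0.92], [0.70, 0.71, 0.72])
        assert p < 0.01

    def test_symmetry(self, rng):
        a = list(rng.random(5))
        b = list(rng.random(5))
        assert welch_test(a, b) == pytest.approx(welch_test(b, a))

    def test_matches_scipy_reference(self, rng):
        from scipy import stats

        a, b = list(rng.random(6)), list(rng.random(8) + 0.2)
        assert welch_test(a, b) == pytest.approx(
            stats.ttest_ind(a, b, equal_var=False).pvalue
        )


class TestSelectLevels:
    def test_forward_prefers_fewer_levels_on_tie(self):
        results = {frozenset([0.7]): 0.9, frozenset([0.7, 0.8]): 0.9}
        assert select_levels(results, "forward", [0.7, 0.8]) == frozenset([0.7])

    def test_forward_takes_full_set_when_monotone(self):
        levels = [0.5, 0.6, 0.7]
        results = {}
        for size, acc in [(1, 0.6), (2, 0.7), (3, 0.8)]:
            from itertools import combinations

            for combo in combinations(levels, size):
                results[frozenset(combo)] = acc
        assert select_levels(results, "forward", levels) == frozenset(levels)

    def test_backward_removes_uninformative_level(self):
        full = frozenset([0.4, 0.7])
        results = {full: 0.8, frozenset([0.7]): 0.8, frozenset([0.4]): 0.5}
        assert select_levels(results, "backward", [0.4, 0.7]) == frozenset([0.7])

    def test_backward_keeps_full_set_when_removal_hurts(self):
        full = frozenset([0.4, 0.7])
        results = {full: 0.9, frozenset([0.7]): 0.8, frozenset([0.4]): 0.5}
        assert select_levels(full_results := results, "backward", [0.4, 0.7]) == full

    def test_callable_scores_evaluated_lazily(self):
        calls = []

        def score(s):
            calls.append(s)
            return max(s)  # higher levels better

        got = select_levels(score, "forward", [0.4, 0.7])
        assert got == frozenset([0.7])
        assert frozenset([0.4, 0.7]) in calls  # the addition was tried

    def test_single_candidate_needs_no_scores(self):
        def boom(s):
            raise AssertionError("should not be called")

        assert select_levels(boom, "forward", [0.7]) == frozenset([0.7])

    def test_empty_candidates_rejected(self):
        with pytest.raises(ParameterError):
            select_levels({}, "forward", [])


class TestTrainAndScore:
    def test_separable_cohort_perfect_heldout_accuracy(self):
        cohort, _ = toy_cohort(20, separable=True)
        ids = [s.subject_id for s, _ in cohort]
        spec = tiny_builder((4, 4, 4))(2)
        m = train_and_score(spec, cohort, ids[:16], ids[16:], FAST_HP, seed=0)
        assert m.accuracy == 1.0
        assert m.cv_error < 0.1

    def test_identical_inputs_give_chance_accuracy(self):
        data = np.full((2, 4, 4, 4), 0.5)
        cohort = [
            (make_stack(data, f"S{i}", "PD" if i % 2 else "NC"),
             "PD" if i % 2 else "NC")
            for i in range(16)
        ]
        ids = [s.subject_id for s, _ in cohort]
        spec = tiny_builder((4, 4, 4))(2)
        m = train_and_score(spec, cohort, ids[:12], ids[12:], FAST_HP, seed=0)
        assert m.accuracy == 0.5  # same score for everyone, balanced test fold

    def test_confusion_matrix_oracle(self):
        cohort, labels = toy_cohort(20, separable=False, seed=4)
        ids = [s.subject_id for s, _ in cohort]
        spec = tiny_builder((4, 4, 4))(2)
        m = train_and_score(spec, cohort, ids[:14], ids[14:], FAST_HP, seed=1)
        tp = sum(1 for s, p in m.scores.items() if p >= 0.5 and labels[s] == "PD")
        fn = sum(1 for s, p in m.scores.items() if p < 0.5 and labels[s] == "PD")
        tn = sum(1 for s, p in m.scores.items() if p < 0.5 and labels[s] == "NC")
        fp = sum(1 for s, p in m.scores.items() if p >= 0.5 and labels[s] == "NC")
        if tp + fn:
            assert m.sensitivity == pytest.approx(tp / (tp + fn))
        if tn + fp:
            assert m.specificity == pytest.approx(tn / (tn + fp))
        assert m.accuracy == pytest.approx((tp + tn) / len(m.scores))

    def test_overlapping_ids_rejected(self):
        cohort, _ = toy_cohort(8)
        ids = [s.subject_id for s, _ in cohort]
        with pytest.raises(ParameterError):
            train_and_score(tiny_builder((4, 4, 4))(2), cohort, ids[:5], ids[4:],
                            FAST_HP, seed=0)

    def test_single_class_training_rejected(self):
        cohort, labels = toy_cohort(8)
        nc_ids = [s for s, l in labels.items() if l == "NC"]
        pd_ids = [s for s, l in labels.items() if l == "PD"]
        with pytest.raises(TrainingError):
            train_and_score(tiny_builder((4, 4, 4))(2), cohort, nc_ids, pd_ids,
                            FAST_HP, seed=0)


class TestNestedCV:
    def test_invocation_bookkeeping(self, monkeypatch):
        """k=2, 2 levels, 8 subjects: each visited candidate set is evaluated
        on exactly 2 inner folds per outer fold, plus one outer training."""
        calls = []

        def stub(spec, cohort, train_ids, test_ids, hyperparams=None, seed=0,
                 fold=-1):
            levels = cohort[0][0].levels
            calls.append((levels, tuple(sorted(test_ids))))
            by_id = {s.subject_id: lab for s, lab in cohort}
            acc = {(0.4,): 0.6, (0.7,): 0.9, (0.4, 0.7): 0.9}[levels]
            scores = {s: (0.8 if by_id[s] == "PD" else 0.2) for s in test_ids}
            labels = {s: by_id[s] for s in test_ids}
            return FoldMetrics(fold=fold, n_j=len(test_ids), scores=scores,
                               labels=labels, accuracy=acc, sensitivity=1.0,
                               specificity=1.0, cv_error=0.04)

        monkeypatch.setattr(te, "train_and_score", stub)
        cohort, _ = toy_cohort(8)
        report = te.nested_cv(
            cohort, tiny_builder((4, 4, 4)), [0.4, 0.7], strategy="forward",
            k=2, seed=0, fixed_candidates=None,
        )
        # forward visits {0.4}, {0.7}, {0.4,0.7}: 3 sets x 2 inner folds
        # + 1 outer training, per outer fold
        assert len(calls) == 2 * (3 * 2 + 1)
        for levels in [(0.4,), (0.7,), (0.4, 0.7)]:
            inner = [c for c in calls if c[0] == levels]
            assert len(inner) >= 2
        assert all(sel == frozenset([0.7]) for sel in report.selected_per_fold)
        assert report.selected_levels == frozenset([0.7])

    def test_report_means_bounded_by_fold_extremes(self):
        cohort, _ = toy_cohort(16, separable=True, seed=2)
        report = nested_cv(
            cohort, tiny_builder((4, 4, 4)), [0.4, 0.7], strategy="forward",
            k=2, seed=1, hyperparams=FAST_HP, fixed_candidates=None,
        )
        accs = [m.accuracy for m in report.outer_metrics]
        assert min(accs) <= report.mean_accuracy <= max(accs)
        assert 0.0 <= report.auc <= 1.0
        assert report.accuracy_sem <= report.accuracy_sd or report.accuracy_sd == 0

    def test_fixed_candidate_sweep_reported(self):
        cohort, _ = toy_cohort(16, separable=True, seed=2)
        report = nested_cv(
            cohort, tiny_builder((4, 4, 4)), [0.7], strategy="forward",
            k=2, seed=1, hyperparams=FAST_HP, fixed_candidates="singletons",
        )
        assert frozenset([0.7]) in report.per_candidate
        assert len(report.per_candidate[frozenset([0.7])]) == 2

    def test_report_serializes_to_json(self, tmp_path):
        cohort, _ = toy_cohort(16, separable=True, seed=2)
        report = nested_cv(
            cohort, tiny_builder((4, 4, 4)), [0.7], strategy="forward",
            k=2, seed=1, hyperparams=FAST_HP, fixed_candidates=None,
        )
        import json

        path = tmp_path / "report.json"
        report.to_json(str(path))
        payload = json.loads(path.read_text())
        for key in ("mean_accuracy", "auc", "selected_levels", "outer_folds"):
            assert key in payload
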