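"""Nested stratified cross-validation with greedy isosurface-level selection.

The evaluation protocol is nested CV: an outer stratified k-fold estimates
generalization, and for each outer fold an inner stratified k-fold (on the
outer-training portion only) drives a greedy forward or backward selection
over candidate isosurface levels. The outer test fold is then scored with
the inner-selected level set, so level selection never sees outer test
subjects.

Per-fold error follows the squared-residual convention

    CV_j = (1 / n_j) * sum_{i in fold j} (y_i - p_i)^2

with ``y`` the binary PD indicator and ``p`` the predicted PD probability;
the dispersion of the k fold errors gives SD and SEM = SD / sqrt(k).
"""

from __future__ import annotations

import json
from collections.abc import Callable, Mapping
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from isoscan.cnn_models import ArchitectureSpec, build_model
from isoscan.errors import ParameterError, TrainingError
from isoscan.isosurface import IsoChannelStack, build_channel_stack
from isoscan.nn import Hyperparams
from isoscan.preprocess import BrainVolume

__all__ = [
    "FoldAssignment", "FoldMetrics", "CVReport", "Hyperparams",
    "stratified_kfold", "train_and_score", "cv_error", "cv_sd_sem",
    "roc_auc", "select_levels", "nested_cv", "welch_test",
]

_LABEL_TO_INT = {"NC": 0, "PD": 1}


def _derive_seed(*parts: int) -> int:
    """Deterministic sub-seed below 2**31 from a tuple of integers."""
    return int(np.random.default_rng(list(parts)).integers(0, 2**31))


@dataclass
class FoldAssignment:
    """Stratified partition of subjects into k folds."""

    k: int
    fold_of_subject: dict[str, int]
    labels: dict[str, str]

    def test_ids(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.fold_of_subject.items() if f == fold)

    def train_ids(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.fold_of_subject.items() if f != fold)


@dataclass
class FoldMetrics:
    """Held-out results for one fold at decision threshold 0.5 (PD positive)."""

    fold: int
    n_j: int
    scores: dict[str, float]
    labels: dict[str, str]
    accuracy: float
    sensitivity: float
    specificity: float
    cv_error: float


@dataclass
class CVReport:
    """Aggregated nested-CV results."""

    k: int
    seed: int
    strategy: str
    base_levels: tuple[float, ...]
    selected_per_fold: list[frozenset[float]]
    selected_levels: frozenset[float]
    outer_metrics: list[FoldMetrics]
    per_candidate: dict[frozenset[float], list[FoldMetrics]]
    mean_accuracy: float
    mean_sensitivity: float
    mean_specificity: float
    accuracy_sd: float
    accuracy_sem: float
    error_sd: float
    error_sem: float
    roc_points: list[tuple[float, float]]
    auc: float

    def to_json(self, path: str | None = None) -> str:
        def _set_key(s: frozenset[float]) -> str:
            return ",".join(f"{v:g}" for v in sorted(s))

        payload = {
            "k": self.k, "seed": self.seed, "strategy": self.strategy,
            "base_levels": list(self.base_levels),
            "selected_levels": sorted(self.selected_levels),
            "selected_per_fold": [sorted(s) for s in self.selected_per_fold],
            "mean_accuracy": self.mean_accuracy,
            "mean_sensitivity": self.mean_sensitivity,
            "mean_specificity": self.mean_specificity,
            "accuracy_sd": self.accuracy_sd, "accuracy_sem": self.accuracy_sem,
            "error_sd": self.error_sd, "error_sem": self.error_sem,
            "auc": self.auc, "roc_points": self.roc_points,
            "outer_folds": [
                {"fold": m.fold, "n": m.n_j, "accuracy": m.accuracy,
                 "sensitivity": m.sensitivity, "specificity": m.specificity,
                 "cv_error": m.cv_error}
                for m in self.outer_metrics
            ],
            "per_candidate": {
                _set_key(s): [
                    {"fold": m.fold, "accuracy": m.accuracy, "cv_error": m.cv_error}
                    for m in ms
                ]
                for s, ms in self.per_candidate.items()
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def stratified_kfold(labels: Mapping[str, str], k: int, seed: int) -> FoldAssignment:
    """Partition subjects into k folds preserving class proportions.

    Every fold's class count differs from the ideal proportion by at most
    one subject. Deterministic in (labels, k, seed).
    """
    if k < 2:
        raise ParameterError(f"k must be >= 2, got {k}")
    subjects = sorted(labels)
    y = [labels[s] for s in subjects]
    for cls in set(y):
        if y.count(cls) < k:
            raise ParameterError(
                f"class {cls!r} has {y.count(cls)} members, fewer than k={k}"
            )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**32))
    fold_of_subject: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(len(subjects)), y)):
        for i in test_idx:
            fold_of_subject[subjects[i]] = fold
    return FoldAssignment(k=k, fold_of_subject=fold_of_subject, labels=dict(labels))


def _binary_metrics(scores: Mapping[str, float], labels: Mapping[str, str],
                    threshold: float = 0.5) -> tuple[float, float, float]:
    y = np.array([_LABEL_TO_INT[labels[s]] for s in scores])
    pred = np.array([scores[s] >= threshold for s in scores], dtype=int)
    accuracy = float((pred == y).mean())
    tp = int(((pred == 1) & (y == 1)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) else float("nan")
    return accuracy, sensitivity, specificity


def cv_error(fold: FoldMetrics | tuple[Mapping[str, float], Mapping[str, str]]) -> float:
    """Mean squared residual (y - p)^2 over one fold; y in {0, 1}."""
    if isinstance(fold, FoldMetrics):
        scores, labels = fold.scores, fold.labels
    else:
        scores, labels = fold
    if not scores:
        raise ParameterError("empty fold")
    residuals = [
        (_LABEL_TO_INT[labels[s]] - scores[s]) ** 2 for s in scores
    ]
    return float(np.mean(residuals))


def cv_sd_sem(fold_errors: list[float]) -> tuple[float, float]:
    """Standard deviation of the k fold errors and SEM = SD / sqrt(k).

    Sample variance (ddof=1) is used, the usual convention for a standard
    error of the mean.
    """
    k = len(fold_errors)
    if k < 2:
        raise ParameterError(f"need at least 2 fold errors, got {k}")
    sd = float(np.sqrt(np.var(fold_errors, ddof=1)))
    return sd, sd / np.sqrt(k)


def roc_auc(scores: Mapping[str, float], labels: Mapping[str, str]
            ) -> tuple[list[tuple[float, float]], float]:
    """ROC curve by threshold sweep and its area.

    The area equals the Mann-Whitney statistic: the fraction of (PD, NC)
    pairs with a higher PD score, counting ties as one half.
    """
    subjects = sorted(scores)
    y = np.array([_LABEL_TO_INT[labels[s]] for s in subjects])
    p = np.array([scores[s] for s in subjects], dtype=float)
    if len(np.unique(y)) < 2:
        raise ParameterError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(y, p)
    auc = float(roc_auc_score(y, p))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def train_and_score(
    spec: ArchitectureSpec,
    cohort: list[tuple[IsoChannelStack, str]],
    train_ids: list[str],
    test_ids: list[str],
    hyperparams: Hyperparams | None = None,
    seed: int = 0,
    fold: int = -1,
) -> FoldMetrics:
    """Train a fresh model on ``train_ids`` and score ``test_ids``."""
    if set(train_ids) & set(test_ids):
        raise ParameterError("train and test ids overlap")
    by_id = {stack.subject_id: (stack, label) for stack, label in cohort}
    missing = [s for s in (*train_ids, *test_ids) if s not in by_id]
    if missing:
        raise ParameterError(f"unknown subject ids: {missing[:5]}")
    x_train = np.stack([by_id[s][0].channels for s in train_ids])
    y_train = np.array([_LABEL_TO_INT[by_id[s][1]] for s in train_ids])
    if len(np.unique(y_train)) < 2:
        raise TrainingError("training set contains a single class")
    model = build_model(spec, seed=seed)
    model.fit(x_train, y_train, hyperparams=hyperparams, seed=seed)
    x_test = np.stack([by_id[s][0].channels for s in test_ids])
    probs = model.predict_proba(x_test)[:, 1]
    scores = {s: float(p) for s, p in zip(test_ids, probs)}
    labels = {s: by_id[s][1] for s in test_ids}
    accuracy, sensitivity, specificity = _binary_metrics(scores, labels)
    return FoldMetrics(
        fold=fold, n_j=len(test_ids), scores=scores, labels=labels,
        accuracy=accuracy, sensitivity=sensitivity, specificity=specificity,
        cv_error=cv_error((scores, labels)),
    )


ScoreFn = Callable[[frozenset], float]


def select_levels(
    inner_results: Mapping[frozenset, float] | ScoreFn,
    strategy: str,
    base_levels: list[float],
) -> frozenset:
    """Greedy forward/backward selection over isosurface levels.

    forward
        start from the best single level; add the level giving the largest
        strict improvement of the score, stop when none improves.
    backward
        start from the full set; remove a level while the best resulting
        score does not decrease.

    Ties prefer fewer levels, then higher thresholds. ``inner_results`` is
    either a precomputed ``{frozenset: score}`` mapping (missing sets are
    treated as not selectable) or a callable evaluated lazily on exactly
    the candidate sets the greedy path visits.
    """
    if not base_levels:
        raise ParameterError("base_levels must be non-empty")
    if strategy not in ("forward", "backward"):
        raise ParameterError(f"strategy must be forward|backward, got {strategy!r}")
    base = [float(v) for v in base_levels]
    if len(set(base)) != len(base):
        raise ParameterError(f"duplicate base levels: {base}")

    if callable(inner_results):
        raw_score: ScoreFn = inner_results
    else:
        mapping = dict(inner_results)
        raw_score = lambda s: mapping.get(s, float("-inf"))  # noqa: E731
    cache: dict[frozenset, float] = {}

    def score(s: frozenset) -> float:
        if s not in cache:
            cache[s] = float(raw_score(s))
        return cache[s]

    def pick(cands: list[frozenset], tie_key) -> tuple[frozenset, float]:
        # highest score; ties broken by tie_key (larger wins)
        best = max(cands, key=lambda s: (score(s), tie_key(s)))
        return best, score(best)

    if strategy == "forward":
        singles = [frozenset([lv]) for lv in base]
        if len(singles) == 1:
            return singles[0]
        current, cur_score = pick(singles, lambda s: max(s))
        while True:
            remaining = [lv for lv in base if lv not in current]
            if not remaining:
                return current
            cands = [current | {lv} for lv in remaining]
            best, best_score = pick(cands, lambda s: max(s - current))
            if best_score > cur_score:
                current, cur_score = best, best_score
            else:
                return current

    current = frozenset(base)
    if len(current) == 1:
        return current
    cur_score = score(current)
    while len(current) > 1:
        # removing the lowest level on a tie keeps the higher thresholds
        cands = [current - {lv} for lv in sorted(current)]
        best, best_score = pick(cands, lambda s: -min(current - s))
        if best_score >= cur_score:
            current, cur_score = best, best_score
        else:
            break
    return current


def _as_stacks(
    cohort: list[tuple[BrainVolume | IsoChannelStack, str]],
    levels: list[float],
    mode: str,
) -> list[tuple[IsoChannelStack, str]]:
    out: list[tuple[IsoChannelStack, str]] = []
    for i, (item, label) in enumerate(cohort):
        if isinstance(item, BrainVolume):
            stack = build_channel_stack(item, levels, mode=mode)
        else:
            stack = item.select(levels)
        if not stack.subject_id:
            stack.subject_id = f"S{i:04d}"
        out.append((stack, label))
    ids = [s.subject_id for s, _ in out]
    if len(set(ids)) != len(ids):
        raise ParameterError("cohort subject ids are not unique")
    return out


def nested_cv(
    cohort: list[tuple[BrainVolume | IsoChannelStack, str]],
    spec_builder: Callable[[int], ArchitectureSpec],
    levels: list[float],
    strategy: str = "forward",
    k: int = 10,
    seed: int = 0,
    hyperparams: Hyperparams | None = None,
    mode: str = "binary",
    fixed_candidates: str | list[list[float]] | None = "singletons",
) -> CVReport:
    """Nested stratified k-fold evaluation with inner-loop level selection.

    For each outer fold, an inner k-fold on the outer-training subjects
    scores every candidate level set the greedy selection visits (mean
    inner accuracy); the outer test fold is then scored once with the
    selected set. With ``fixed_candidates="singletons"`` every single level
    is additionally evaluated on each outer fold, mirroring the practice of
    reporting the outer sweep alongside the selected combination.
    """
    levels = sorted(float(v) for v in levels)
    stacks = _as_stacks(cohort, levels, mode)
    labels = {s.subject_id: lab for s, lab in stacks}
    outer = stratified_kfold(labels, k, seed)

    if fixed_candidates == "singletons":
        fixed_sets = [frozenset([lv]) for lv in levels]
    elif fixed_candidates is None:
        fixed_sets = []
    else:
        fixed_sets = [frozenset(float(v) for v in s) for s in fixed_candidates]

    selected_per_fold: list[frozenset] = []
    outer_metrics: list[FoldMetrics] = []
    per_candidate: dict[frozenset, list[FoldMetrics]] = {s: [] for s in fixed_sets}
    pooled_scores: dict[str, float] = {}

    for j in range(k):
        outer_train = outer.train_ids(j)
        outer_test = outer.test_ids(j)
        inner_labels = {s: labels[s] for s in outer_train}
        inner = stratified_kfold(inner_labels, k, _derive_seed(seed, j, 1))

        def evaluate(level_set: frozenset, _j=j, _inner=inner, _train=outer_train) -> float:
            sub = sorted(level_set)
            accs = []
            for i in range(_inner.k):
                m = train_and_score(
                    spec_builder(len(sub)),
                    [(s.select(sub), lab) for s, lab in stacks
                     if s.subject_id in set(_train)],
                    _inner.train_ids(i), _inner.test_ids(i),
                    hyperparams=hyperparams,
                    seed=_derive_seed(seed, _j, 2, i),
                    fold=i,
                )
                accs.append(m.accuracy)
            return float(np.mean(accs))

        selected = select_levels(evaluate, strategy, levels)
        selected_per_fold.append(selected)

        sel = sorted(selected)
        sel_cohort = [(s.select(sel), lab) for s, lab in stacks]
        metrics = train_and_score(
            spec_builder(len(sel)), sel_cohort, outer_train, outer_test,
            hyperparams=hyperparams, seed=_derive_seed(seed, j, 3), fold=j,
        )
        outer_metrics.append(metrics)
        pooled_scores.update(metrics.scores)

        for cand in fixed_sets:
            sub = sorted(cand)
            m = train_and_score(
                spec_builder(len(sub)),
                [(s.select(sub), lab) for s, lab in stacks],
                outer_train, outer_test,
                hyperparams=hyperparams,
                seed=_derive_seed(seed, j, 4, fixed_sets.index(cand)), fold=j,
            )
            per_candidate[cand].append(m)

    # consensus selection: most frequent, ties to fewer levels then higher ones
    counts: dict[frozenset, int] = {}
    for s in selected_per_fold:
        counts[s] = counts.get(s, 0) + 1
    consensus = max(
        counts, key=lambda s: (counts[s], -len(s), tuple(sorted(s, reverse=True)))
    )

    accs = [m.accuracy for m in outer_metrics]
    errors = [m.cv_error for m in outer_metrics]
    acc_sd, acc_sem = cv_sd_sem(accs)
    err_sd, err_sem = cv_sd_sem(errors)
    roc_points, auc = roc_auc(pooled_scores, labels)
    return CVReport(
        k=k, seed=seed, strategy=strategy, base_levels=tuple(levels),
        selected_per_fold=selected_per_fold, selected_levels=consensus,
        outer_metrics=outer_metrics, per_candidate=per_candidate,
        mean_accuracy=float(np.mean(accs)),
        mean_sensitivity=float(np.nanmean([m.sensitivity for m in outer_metrics])),
        mean_specificity=float(np.nanmean([m.specificity for m in outer_metrics])),
        accuracy_sd=acc_sd, accuracy_sem=acc_sem,
        error_sd=err_sd, error_sem=err_sem,
        roc_points=roc_points, auc=auc,
    )


def welch_test(samples_a: list[float], samples_b: list[float]) -> float:
    """Two-sided Welch unequal-variance t-test p-value.

    Degenerate case: when both samples have zero variance the p-value is 1
    for equal means (no evidence of a difference) and 0 otherwise.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("each sample needs at least 2 values")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
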