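"""Sequential backward floating selection (SBFS) over the 26 features.

SBFS starts from the full feature set and repeatedly removes the feature
whose removal gives the lowest cross-validated error rate

    e = N_e / N_a

(misclassified test samples over all test samples, pooled across the
stratified folds).  After each removal, a *floating* step conditionally
re-adds any previously removed feature whenever re-adding strictly
improves on the best error recorded at that subset size — strictness
guarantees termination.  The best subset found at each size k = n..1 is
recorded; the global optimum is the minimum-error subset, ties broken
toward smaller k and then the lexicographically smaller ID set.

Determinism: one set of stratified folds is drawn per run (from the
seed) and reused for every subset evaluated, so subset comparisons are
paired and the whole trajectory is reproducible.  Every tie between
candidate subsets breaks toward the lexicographically smallest ID set.

Feature IDs are 1-based registry IDs throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import cv_confusion, make_folds
from .errors import ValidationError
from .io_core import FeatureMatrix


@dataclass
class SelectionResult:
    """Full SBFS trajectory and its optimum.

    ``trajectory`` maps subset size k to ``(feature_ids, cv_error)`` for
    the best subset recorded at that size.
    """

    trajectory: dict[int, tuple[tuple[int, ...], float]]
    best_subset: tuple[int, ...]
    best_error: float
    rng_seed: int

    def to_rows(self, classifier: str) -> list[dict]:
        """Flatten for TSV export (one row per size, largest first)."""
        return [{"classifier": classifier, "k": k,
                 "feature_ids": ",".join(map(str, ids)), "cv_error": err}
                for k, (ids, err) in sorted(self.trajectory.items(), reverse=True)]


def cv_error(fm: FeatureMatrix, classifier_name: str,
             feature_subset: tuple[int, ...] | None = None,
             folds: int = 10, seed: int = 0,
             fold_indices=None, paper_faithful: bool = False) -> float:
    """Pooled cross-validated error rate e = N_e / N_a on a feature subset."""
    if feature_subset is not None:
        X = fm.values[:, [fid - 1 for fid in feature_subset]]
    else:
        X = fm.values
    cc = cv_confusion(X, fm.labels, classifier_name, folds=folds, seed=seed,
                      fold_indices=fold_indices, paper_faithful=paper_faithful)
    return (cc.fp + cc.fn) / cc.total


class _SubsetEvaluator:
    """Memoised subset -> error evaluation on one shared fold split."""

    def __init__(self, fm: FeatureMatrix, classifier_name: str,
                 folds: int, seed: int, paper_faithful: bool):
        self.fm = fm
        self.classifier_name = classifier_name
        self.folds = folds
        self.seed = seed
        self.paper_faithful = paper_faithful
        self.fold_indices = make_folds(fm.labels, folds, seed)
        self._cache: dict[frozenset, float] = {}

    def __call__(self, subset: frozenset) -> float:
        if subset not in self._cache:
            self._cache[subset] = cv_error(
                self.fm, self.classifier_name,
                tuple(sorted(subset)), folds=self.folds, seed=self.seed,
                fold_indices=self.fold_indices,
                paper_faithful=self.paper_faithful)
        return self._cache[subset]


def _best_candidate(evaluate, candidates: list[frozenset]):
    """Lowest-error candidate subset; ties break toward the
    lexicographically smallest ID set (so low-ID features are retained,
    and re-inclusion prefers the lowest removed ID)."""
    best = None
    for subset in candidates:
        key = (evaluate(subset), sorted(subset))
        if best is None or key < best[0]:
            best = (key, subset)
    return best[0][0], best[1]


def sbfs(fm: FeatureMatrix, classifier_name: str, folds: int = 10,
         seed: int = 0, paper_faithful: bool = False,
         floating: bool = True) -> SelectionResult:
    """Backward feature elimination with conditional re-inclusion.

    ``floating=False`` gives plain sequential backward selection (SBS),
    useful as a baseline: floating can only match or improve the
    recorded per-size best errors.
    """
    n = fm.values.shape[1]
    if n < 2:
        raise ValidationError("need >= 2 features for selection")
    all_ids = frozenset(range(1, n + 1))
    evaluate = _SubsetEvaluator(fm, classifier_name, folds, seed, paper_faithful)

    current = all_ids
    best_at_size: dict[int, tuple[frozenset, float]] = {
        n: (current, evaluate(current))}

    def record(subset: frozenset, err: float) -> None:
        k = len(subset)
        prev = best_at_size.get(k)
        if (prev is None or err < prev[1]
                or (err == prev[1] and sorted(subset) < sorted(prev[0]))):
            best_at_size[k] = (subset, err)

    while len(current) > 1:
        # exclusion: drop the feature whose removal hurts least
        err, current = _best_candidate(
            evaluate, [current - {f} for f in sorted(current)])
        record(current, err)
        # floating: climb back up while re-adding strictly improves the
        # recorded best at the larger size
        while floating and len(current) < n:
            err_up, subset_up = _best_candidate(
                evaluate, [current | {g} for g in sorted(all_ids - current)])
            prev = best_at_size.get(len(subset_up))
            if prev is not None and err_up >= prev[1]:
                break
            current = subset_up
            record(current, err_up)

    trajectory = {k: (tuple(sorted(s)), e) for k, (s, e) in best_at_size.items()}
    best_subset, best_error = _argmin_trajectory(trajectory)
    return SelectionResult(trajectory, best_subset, best_error, seed)


def _argmin_trajectory(trajectory: dict[int, tuple[tuple[int, ...], float]]):
    best = None
    for k in sorted(trajectory):  # smaller k wins ties
        ids, err = trajectory[k]
        if best is None or err < best[1] or (err == best[1] and k == len(best[0])
                                             and list(ids) < list(best[0])):
            best = (ids, err)
    return best


def select_optimal_subset(result: SelectionResult) -> tuple[int, ...]:
    """The minimum-error subset; ties favour smaller k, then smaller IDs."""
    if not result.trajectory:
        raise ValidationError("empty selection trajectory")
    return _argmin_trajectory(result.trajectory)[0]
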