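"""Youden-curve subset selection over ranked features.

From a feature ranking, build nested prefix subsets F_0 ⊂ F_1 ⊂ … and
score each with a linear-kernel maximum-margin classifier on balanced
held-out splits, recording Youden's J = sensitivity + specificity − 1
at the classifier's native decision threshold.  The fold-averaged J
values form the Youden curve; the cutoff is its first (left-to-right)
local maximum, so the selected set is the smallest prefix beyond which
adding lower-ranked features stops paying.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
from sklearn.svm import LinearSVC

if TYPE_CHECKING:  # pragma: no cover
    from .ranking import RankedFeatures


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


def youden_index(c: ConfusionCounts) -> float:
    """J = sensitivity − false positive rate = sensitivity + specificity − 1."""
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise ValueError("Youden index undefined without both classes present")
    return c.sensitivity + c.specificity - 1.0


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def balanced_split(
    labels: np.ndarray, test_fraction: float, rng: np.random.Generator | int
) -> tuple[np.ndarray, np.ndarray]:
    """Class-stratified train/test split.

    The test part holds ``round(test_fraction · n_class)`` members of
    each class, so its case fraction matches the cohort's up to
    rounding.  Raises if either class cannot place at least one member
    in each part.
    """
    labels = np.asarray(labels, dtype=int)
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    quotas = _stratified_quotas(labels, test_fraction)
    train: list[np.ndarray] = []
    test: list[np.ndarray] = []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        n_test = quotas[cls]
        if n_test < 1 or len(idx) - n_test < 1:
            raise ValueError(
                f"class {cls} too small ({len(idx)}) to place one member in each part"
            )
        perm = rng.permutation(idx)
        test.append(perm[:n_test])
        train.append(perm[n_test:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def _stratified_quotas(labels: np.ndarray, fraction: float) -> dict[int, int]:
    """Per-class test-set quotas: global total round(fraction·n), split by
    class proportionally (floor + largest remainder, ties to class 0)."""
    counts = {cls: int((labels == cls).sum()) for cls in (0, 1)}
    if min(counts.values()) == 0:
        absent = min(counts, key=counts.get)
        raise ValueError(f"class {absent} absent from labels")
    n_total = int(round(fraction * len(labels)))
    exact = {cls: fraction * counts[cls] for cls in (0, 1)}
    quotas = {cls: int(np.floor(exact[cls])) for cls in (0, 1)}
    leftover = n_total - sum(quotas.values())
    order = sorted((0, 1), key=lambda cls: (-(exact[cls] - quotas[cls]), cls))
    for cls in order[:leftover]:
        quotas[cls] += 1
    return quotas


@dataclass(frozen=True)
class NestedSubsets:
    """Nested prefix subsets F_0 ⊂ … ⊂ F_{n_steps−1} of the ranked
    feature order; the last subset always contains every feature."""

    subsets: tuple[tuple[int, ...], ...]

    @property
    def n_steps(self) -> int:
        return len(self.subsets)

    def sizes(self) -> list[int]:
        return [len(f) for f in self.subsets]


def build_nested_subsets(ranking: "RankedFeatures", n_steps: int) -> NestedSubsets:
    """Prefixes of the ranked order with sizes (i+1)·⌊p/n_steps⌋, the
    final subset completed to all p features."""
    p = ranking.n_features
    if not 1 <= n_steps <= p:
        raise ValueError(f"n_steps must be in [1, {p}], got {n_steps}")
    n_increment = p // n_steps
    subsets = []
    for i in range(n_steps - 1):
        subsets.append(tuple(int(j) for j in ranking.order[: (i + 1) * n_increment]))
    subsets.append(tuple(int(j) for j in ranking.order))
    return NestedSubsets(subsets=tuple(subsets))


def _make_classifier() -> LinearSVC:
    # linear-kernel max-margin classifier at library-default regularization
    # (L2, C=1); liblinear converges reliably on unseparable label-noise
    # data, and a 1e-3 duality-gap tolerance is far below the J resolution
    # that matters for locating the curve peak
    return LinearSVC(dual="auto", tol=1e-3)


@dataclass(frozen=True)
class YoudenCurve:
    """Fold-averaged Youden scores over the nested subsets, plus the
    selected cutoff."""

    scores: np.ndarray  # length n_steps, fold means
    per_fold: np.ndarray  # n_steps x m_folds
    cutoff_index: int
    subsets: NestedSubsets

    @property
    def selected_features(self) -> tuple[int, ...]:
        return self.subsets.subsets[self.cutoff_index]


def score_subsets(
    X_working: np.ndarray,
    y_working: np.ndarray,
    subsets: NestedSubsets,
    m_folds: int,
    t_test: float,
    rng: np.random.Generator | int,
) -> YoudenCurve:
    """Score every nested subset on ``m_folds`` balanced splits.

    For each fold and subset, the classifier is trained on the train
    rows restricted to the subset's columns and its Youden index is
    recorded on the held-out rows; per-subset scores are averaged over
    folds.  A degenerate subset (all columns constant on the train
    part) scores 0 for that fold, with a warning.
    """
    X_working = np.asarray(X_working, dtype=float)
    y_working = np.asarray(y_working, dtype=int)
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    n_steps = subsets.n_steps
    per_fold = np.zeros((n_steps, m_folds))
    for r in range(m_folds):
        train_idx, test_idx = balanced_split(y_working, t_test, rng)
        y_tr, y_te = y_working[train_idx], y_working[test_idx]
        for i, feats in enumerate(subsets.subsets):
            cols = np.asarray(feats, dtype=int)
            X_tr = X_working[np.ix_(train_idx, cols)]
            if np.ptp(X_tr, axis=0).max() == 0.0:
                warnings.warn(f"subset {i}: all-constant training columns; J := 0")
                per_fold[i, r] = 0.0
                continue
            clf = _make_classifier()
            with warnings.catch_warnings():
                warnings.filterwarnings("ignore", message=".*converge.*")
                clf.fit(X_tr, y_tr)
            pred = clf.predict(X_working[np.ix_(test_idx, cols)])
            per_fold[i, r] = youden_index(confusion_counts(y_te, pred))
    scores = per_fold.mean(axis=1)
    cutoff = first_local_maximum(scores)
    return YoudenCurve(scores=scores, per_fold=per_fold, cutoff_index=cutoff, subsets=subsets)


def first_local_maximum(scores: Sequence[float] | np.ndarray) -> int:
    """First (left-to-right) local maximum of the curve.

    Returns the smallest interior index j with
    scores[j−1] ≤ scores[j] ≥ scores[j+1]; on a plateau the first index
    wins.  If no interior local maximum exists (e.g. a strictly
    monotone curve), falls back to the first global argmax.
    """
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("empty curve")
    # left-to-right scan returns the first qualifying index, which on a
    # plateau is automatically the plateau's first interior index
    for j in range(1, s.size - 1):
        if s[j - 1] <= s[j] >= s[j + 1]:
            return j
    return int(np.argmax(s))


def selected_before_cutoff(subsets: NestedSubsets, j_max: int) -> tuple[int, ...]:
    """Features of the cutoff subset F_{j_max} (the ranked prefix up to
    and including the curve's first local maximum)."""
    if not 0 <= j_max < subsets.n_steps:
        raise ValueError("cutoff index out of range")
    return subsets.subsets[j_max]
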