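"""Comparison methods: linear-kernel SVM, SVM-RFE, and t-test feature ranking.

All three plug into the same evaluation protocol as the multiple-kernel
estimator.  The SVM baseline uses a single trace-normalized linear kernel
over one feature group (whole images, clinical block, or the
concatenation).  The two feature-selection baselines build an elimination
path dropping 5% of the remaining features per stage — multivariately
(recursive elimination on squared SVM weights) or univariately (absolute
two-sample t statistics) — and the retained count is a hyperparameter for
the downstream SVM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.svm import SVC

from .easymkl import trace_normalize
from .io_data import KernelGrouping, LabeledDataset

__all__ = [
    "EliminationPath",
    "LinearSVMModel",
    "linear_svm_baseline",
    "svm_rfe",
    "ttest_rank",
    "rank_elimination_path",
]


@dataclass
class EliminationPath:
    """Ordered record of a feature-elimination run.

    ``stages[t]`` is ``(retained_indices, scores)`` where ``scores`` is the
    per-retained-feature importance computed at that stage.  Retained sets
    are strictly nested and decreasing; the final stage is non-empty.
    """

    stages: list[tuple[np.ndarray, np.ndarray]]
    drop_fraction: float

    def retained_counts(self) -> list[int]:
        return [len(s[0]) for s in self.stages]

    def stage_for_count(self, k: int) -> np.ndarray:
        """Smallest retained set with at least ``k`` features."""
        best = self.stages[0][0]
        for retained, _ in self.stages:
            if len(retained) >= k:
                best = retained
            else:
                break
        return best


@dataclass
class LinearSVMModel:
    """SVM on one trace-normalized linear kernel (baseline families I, C, I+C)."""

    grouping: KernelGrouping
    column_scales: np.ndarray
    train_rows_scaled: np.ndarray
    svc: SVC
    C: float

    def _kernel(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.asarray(X_new, dtype=float)
        if X_new.shape[1] != len(self.column_scales):
            raise ValueError(
                f"expected {len(self.column_scales)} columns, got {X_new.shape[1]}"
            )
        return (X_new * self.column_scales) @ self.train_rows_scaled.T

    def decision_function(self, X_new: np.ndarray) -> np.ndarray:
        return self.svc.decision_function(self._kernel(X_new))

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X_new) >= 0, 1, -1)


def linear_svm_baseline(
    dataset: LabeledDataset, grouping: KernelGrouping, C: float = 1.0
) -> LinearSVMModel:
    """Soft-margin SVM on the single trace-normalized kernel of ``grouping``.

    ``grouping`` must be one of the single-kernel families (I, C, I_plus_C).
    """
    if grouping.R != 1:
        raise ValueError("baseline requires a single-kernel grouping (I, C or I_plus_C)")
    tnf = trace_normalize(dataset.X, grouping)
    K = tnf.Xhat @ tnf.Xhat.T
    K = (K + K.T) / 2.0
    svc = SVC(kernel="precomputed", C=C)
    svc.fit(K, dataset.y)
    return LinearSVMModel(
        grouping=grouping,
        column_scales=tnf.column_scales,
        train_rows_scaled=tnf.Xhat,
        svc=svc,
        C=C,
    )


def _drop_count(retained: int, drop_fraction: float) -> int:
    return max(1, int(round(drop_fraction * retained)))


def svm_rfe(
    dataset: LabeledDataset, drop_fraction: float = 0.05, C: float = 1.0
) -> EliminationPath:
    """Recursive feature elimination with a linear SVM (Guyon-style).

    At each stage a linear SVM is trained on the retained features, each
    feature is scored by its squared primal weight w_j², and the lowest
    max(1, round(drop_fraction · retained)) features are removed.  The full
    path down to a single feature is recorded.
    """
    X, y = dataset.X, dataset.y
    if X.shape[1] < 2:
        raise ValueError("RFE needs at least two features")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if not 0.0 < drop_fraction < 1.0:
        raise ValueError("drop_fraction must lie in (0, 1)")
    retained = np.arange(X.shape[1])
    stages: list[tuple[np.ndarray, np.ndarray]] = []
    while True:
        svc = SVC(kernel="linear", C=C)
        svc.fit(X[:, retained], y)
        scores = np.asarray(svc.coef_).ravel() ** 2
        stages.append((retained.copy(), scores))
        if retained.size == 1:
            break
        k = _drop_count(retained.size, drop_fraction)
        keep_local = np.argsort(scores, kind="stable")[k:]
        retained = np.sort(retained[keep_local])
    return EliminationPath(stages=stages, drop_fraction=drop_fraction)


def ttest_rank(dataset: LabeledDataset) -> np.ndarray:
    """Per-feature |two-sample t| (Welch) between the two classes.

    Constant features (both classes identical) score 0; zero-within-class-
    variance features with different means (t → ∞) are mapped to the
    largest finite score plus one, keeping them at the top of the ranking.
    """
    X, y = dataset.X, dataset.y
    a, b = X[y > 0], X[y < 0]
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each class needs at least two subjects")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, _ = stats.ttest_ind(a, b, axis=0, equal_var=False)
    scores = np.abs(np.asarray(t, dtype=float))
    scores[np.isnan(scores)] = 0.0
    inf = np.isinf(scores)
    if inf.any():
        finite_max = scores[~inf].max(initial=0.0)
        scores[inf] = finite_max + 1.0
    return scores


def rank_elimination_path(
    scores: np.ndarray, drop_fraction: float = 0.05
) -> EliminationPath:
    """Elimination path from a fixed univariate score vector (5% schedule).

    Unlike RFE the scores are not recomputed: each stage just removes the
    lowest-scoring max(1, round(drop_fraction · retained)) features.
    """
    scores = np.asarray(scores, dtype=float)
    if not 0.0 < drop_fraction < 1.0:
        raise ValueError("drop_fraction must lie in (0, 1)")
    retained = np.arange(scores.size)
    stages: list[tuple[np.ndarray, np.ndarray]] = []
    while True:
        stages.append((retained.copy(), scores[retained]))
        if retained.size == 1:
            break
        k = _drop_count(retained.size, drop_fraction)
        keep_local = np.argsort(scores[retained], kind="stable")[k:]
        retained = np.sort(retained[keep_local])
    return EliminationPath(stages=stages, drop_fraction=drop_fraction)
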