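"""Evaluation protocol: balanced accuracy, stratified repeated nested CV,
FDR pre-filtering of clinical features, and paired classifier comparison.

The protocol mirrors common practice in small-sample neuroimaging
classification: 5 repetitions of a nested 10-fold cross-validation with
folds balanced on the diagnostic label and matched on age, inner folds
selecting hyperparameters by mean balanced accuracy, and Wilcoxon
signed-rank tests (Bonferroni-corrected) comparing methods over the paired
per-fold scores.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from . import model as fsmodel
from .baselines import (
    linear_svm_baseline,
    rank_elimination_path,
    svm_rfe,
    ttest_rank,
)
from .easymkl import (
    average_kernel,
    kernel_weights_streaming,
    solve_gamma,
    trace_normalize,
)
from .io_data import LabeledDataset, build_grouping, subset_features

__all__ = [
    "CVPlan",
    "CVResult",
    "balanced_accuracy",
    "stratified_folds",
    "make_cv_plan",
    "nested_cv",
    "bh_adjust",
    "fdr_prefilter",
    "wilcoxon_signed_rank",
    "bonferroni_threshold",
    "METHODS",
]

METHODS = ("easymklfs", "easymkl", "svm", "svm_rfe", "svm_ttest")


# ---------------------------------------------------------------------------
# Scores and folds


def balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """100 · (sensitivity + specificity) / 2 for ±1 labels."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    pos = y_true > 0
    neg = y_true < 0
    if not pos.any() or not neg.any():
        raise ValueError("y_true must contain both classes")
    sens = float(np.mean(y_pred[pos] > 0))
    spec = float(np.mean(y_pred[neg] < 0))
    return 100.0 * (sens + spec) / 2.0


def _safe_balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Grid-scoring variant tolerating a single-class validation fold."""
    y_true = np.asarray(y_true)
    if (y_true > 0).any() and (y_true < 0).any():
        return balanced_accuracy(y_true, y_pred)
    return 100.0 * float(np.mean(np.asarray(y_pred) == y_true))


def stratified_folds(
    y: np.ndarray,
    age: np.ndarray | None,
    k: int,
    seed: int,
) -> np.ndarray:
    """Fold ids (0..k−1) balanced on label and matched on age.

    Within each class, subjects are sorted by age (ties broken by a seeded
    shuffle) and dealt round-robin into the k folds from a random starting
    fold, so per-fold class counts differ by at most one and per-fold age
    distributions track the class age distribution.  With constant (or
    absent) age this reduces to plain label stratification.
    """
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    folds = np.full(len(y), -1, dtype=int)
    for cls in (1, -1):
        idx = np.flatnonzero(y == cls)
        if idx.size < k:
            raise ValueError(
                f"k={k} exceeds class size {idx.size} for class {cls:+d}"
            )
        perm = rng.permutation(idx)
        if age is not None:
            perm = perm[np.argsort(np.asarray(age)[perm], kind="stable")]
        offset = int(rng.integers(k))
        folds[perm] = (np.arange(perm.size) + offset) % k
    return folds


@dataclass
class CVPlan:
    """Repeated-CV layout: per-repeat fold assignment for every subject."""

    n_repeats: int
    n_outer: int
    n_inner: int
    seed: int
    fold_assignments: list[np.ndarray] = field(default_factory=list)


def make_cv_plan(
    y: np.ndarray,
    age: np.ndarray | None,
    n_repeats: int = 5,
    n_outer: int = 10,
    n_inner: int = 10,
    seed: int = 0,
) -> CVPlan:
    """Build the outer fold assignments for every repeat (deterministic)."""
    assignments = [
        stratified_folds(y, age, n_outer, seed + 1000 * rep)
        for rep in range(n_repeats)
    ]
    return CVPlan(
        n_repeats=n_repeats,
        n_outer=n_outer,
        n_inner=n_inner,
        seed=seed,
        fold_assignments=assignments,
    )


# ---------------------------------------------------------------------------
# Grid construction and per-split scoring


def _grid_points(method: str, grids: dict, R: int) -> list[dict]:
    """Hyperparameter grid in declared order (ties break toward the first).

    ``grids["rho"]`` may be the string ``"auto"`` for the rule
    ρ ∈ {i/R : i = 0..20}, R being the number of base kernels.
    """
    if method == "easymklfs":
        rho = grids.get("rho", "auto")
        if isinstance(rho, str):
            rho = [i / R for i in range(21)]
        combos = itertools.product(grids["lam"], rho, grids["C"])
        return [{"lam": l, "rho": r, "C": c} for l, r, c in combos]
    if method == "easymkl":
        combos = itertools.product(grids["lam"], grids["C"])
        return [{"lam": l, "rho": 0.0, "C": c} for l, c in combos]
    if method == "svm":
        return [{"C": c} for c in grids["C"]]
    if method in ("svm_rfe", "svm_ttest"):
        n_feat = grids.get("n_features", "path")
        combos = itertools.product(grids["C"], [n_feat])
        return [
            {"C": c, "n_features": n}
            for c, nf in combos
            for n in (nf if isinstance(nf, (list, tuple)) else [nf])
        ]
    raise ValueError(f"unknown method {method!r}")


def _mkl_split_scores(
    dataset: LabeledDataset,
    grouping,
    tr: np.ndarray,
    va: np.ndarray,
    points: list[dict],
) -> np.ndarray:
    """Balanced accuracy of every (λ, ρ, C) point on one train/val split.

    Factorizes the grid: the normalization and average kernel are computed
    once, γ/η once per λ, the sparse kernel once per (λ, ρ), and only the
    SVM is refit per C.  Grid points whose threshold kills every kernel
    score −inf (never selected while any feasible point exists).
    """
    X, y = dataset.X, dataset.y
    tnf = trace_normalize(X[tr], grouping)
    K_A = average_kernel(tnf, grouping)
    Xhat_tr = tnf.Xhat
    Xhat_va = tnf.transform(X[va])
    scores = np.full(len(points), -np.inf)
    cache_lam: dict[float, np.ndarray] = {}
    for lam in {p["lam"] for p in points}:
        gamma = solve_gamma(K_A, y[tr], lam)
        cache_lam[lam] = kernel_weights_streaming(tnf, grouping, gamma, y[tr]).eta
    group_ids = grouping.column_group_ids(X.shape[1])
    by_lam_rho: dict[tuple[float, float], tuple] = {}
    for i, p in enumerate(points):
        key = (p["lam"], p["rho"])
        if key not in by_lam_rho:
            eta = cache_lam[p["lam"]]
            sel = eta > p["rho"]
            if not sel.any():
                by_lam_rho[key] = None
            else:
                keep = (group_ids >= 0) & sel[np.clip(group_ids, 0, None)]
                cols = np.flatnonzero(keep)
                w = eta[group_ids[cols]]
                Ktr = (Xhat_tr[:, cols] * w) @ Xhat_tr[:, cols].T
                Kva = (Xhat_va[:, cols] * w) @ Xhat_tr[:, cols].T
                by_lam_rho[key] = ((Ktr + Ktr.T) / 2.0, Kva)
        entry = by_lam_rho[key]
        if entry is None:
            continue
        Ktr, Kva = entry
        svc = SVC(kernel="precomputed", C=p["C"])
        svc.fit(Ktr, y[tr])
        pred = np.where(svc.decision_function(Kva) >= 0, 1, -1)
        scores[i] = _safe_balanced_accuracy(y[va], pred)
    return scores


def _svm_split_scores(dataset, grouping, tr, va, points):
    scores = np.empty(len(points))
    sub = _row_subset(dataset, tr)
    for i, p in enumerate(points):
        mdl = linear_svm_baseline(sub, grouping, C=p["C"])
        scores[i] = _safe_balanced_accuracy(
            dataset.y[va], mdl.predict(dataset.X[va])
        )
    return scores


def _fs_split_scores(dataset, method, tr, va, points):
    """RFE / t-test baselines: path once per C, an SVM per retained count."""
    X, y = dataset.X, dataset.y
    sub = _row_subset(dataset, tr)
    scores = np.empty(len(points))
    paths: dict[float, object] = {}
    for i, p in enumerate(points):
        C = p["C"]
        if C not in paths:
            if method == "svm_rfe":
                paths[C] = svm_rfe(sub, C=C)
            else:
                paths[C] = rank_elimination_path(ttest_rank(sub))
        path = paths[C]
        retained = (
            _path_sets(path)
            if p["n_features"] == "path"
            else [path.stage_for_count(p["n_features"])]
        )
        best = -np.inf
        for feats in retained:
            svc = SVC(kernel="linear", C=C)
            svc.fit(X[np.ix_(tr, feats)], y[tr])
            pred = svc.predict(X[np.ix_(va, feats)])
            best = max(best, _safe_balanced_accuracy(y[va], pred))
        scores[i] = best
    return scores


def _path_sets(path):
    return [s[0] for s in path.stages]


def _row_subset(dataset: LabeledDataset, rows: np.ndarray) -> LabeledDataset:
    return LabeledDataset(
        X=dataset.X[rows],
        y=dataset.y[rows],
        sources=dataset.sources,
        subject_ids=[dataset.subject_ids[i] for i in rows],
        age=None if dataset.age is None else dataset.age[rows],
    )


def _split_scores(dataset, method, grouping, tr, va, points):
    if method in ("easymklfs", "easymkl"):
        return _mkl_split_scores(dataset, grouping, tr, va, points)
    if method == "svm":
        return _svm_split_scores(dataset, grouping, tr, va, points)
    return _fs_split_scores(dataset, method, tr, va, points)


def _fit_final(dataset, method, grouping, tr, params):
    """Refit the chosen configuration on the full outer-train set.

    Returns a ``(predict, n_selected_features)`` pair; prediction takes raw
    (unnormalized) rows of the full feature space.
    """
    sub = _row_subset(dataset, tr)
    if method in ("easymklfs", "easymkl"):
        mdl = fsmodel.fit(sub, grouping, params["lam"], params["rho"], params["C"])
        return (lambda Xn: fsmodel.predict(mdl, Xn)), mdl
    if method == "svm":
        mdl = linear_svm_baseline(sub, grouping, C=params["C"])
        return mdl.predict, mdl
    if method == "svm_rfe":
        path = svm_rfe(sub, C=params["C"])
    else:
        path = rank_elimination_path(ttest_rank(sub))
    if params["n_features"] == "path":
        raise ValueError("final fit needs a concrete n_features")
    feats = path.stage_for_count(params["n_features"])
    svc = SVC(kernel="linear", C=params["C"])
    svc.fit(sub.X[:, feats], sub.y)
    return (lambda Xn: svc.predict(np.asarray(Xn)[:, feats])), (svc, feats)


def _select_params(
    dataset, method, grouping, tr, inner_folds, points
) -> tuple[dict, np.ndarray]:
    """Inner-CV selection: mean split score per grid point, first max wins."""
    total = np.zeros(len(points))
    n_folds = inner_folds.max() + 1
    for f in range(n_folds):
        va_local = np.flatnonzero(inner_folds == f)
        tr_local = np.flatnonzero(inner_folds != f)
        total += _split_scores(
            dataset, method, grouping, tr[tr_local], tr[va_local], points
        )
    mean_scores = total / n_folds
    best = int(np.argmax(mean_scores))  # argmax returns the first maximum
    params = dict(points[best])
    if method in ("svm_rfe", "svm_ttest") and params["n_features"] == "path":
        # pick the concrete retained count that won inside the path search
        params = _resolve_path_count(dataset, method, grouping, tr,
                                     inner_folds, params)
    return params, mean_scores


def _resolve_path_count(dataset, method, grouping, tr, inner_folds, params):
    """Replace n_features='path' by the stage count with best mean inner score."""
    sub = _row_subset(dataset, tr)
    if method == "svm_rfe":
        ref_path = svm_rfe(sub, C=params["C"])
    else:
        ref_path = rank_elimination_path(ttest_rank(sub))
    counts = ref_path.retained_counts()
    pts = [{"C": params["C"], "n_features": c} for c in counts]
    total = np.zeros(len(pts))
    n_folds = inner_folds.max() + 1
    for f in range(n_folds):
        va_local = np.flatnonzero(inner_folds == f)
        tr_local = np.flatnonzero(inner_folds != f)
        total += _fs_split_scores(
            dataset, method, tr[tr_local], tr[va_local], pts
        )
    best = int(np.argmax(total))
    return dict(pts[best])


@dataclass
class CVResult:
    """Scores and choices from a repeated nested cross-validation run."""

    method: str
    family_code: str
    per_fold_scores: np.ndarray          # n_repeats × n_outer, flattened
    chosen_hyperparams: list[dict]
    per_subject_predictions: np.ndarray  # (n_repeats, n_subjects), ±1
    fold_assignments: list[np.ndarray]
    n_selected: list[int]

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_fold_scores))

    @property
    def sd(self) -> float:
        return float(np.std(self.per_fold_scores, ddof=1))

    def to_frame(self) -> pd.DataFrame:
        n_outer = len(self.per_fold_scores) // len(self.fold_assignments)
        rows = []
        for i, score in enumerate(self.per_fold_scores):
            rep, fold = divmod(i, n_outer)
            row = {"repeat": rep, "fold": fold, "score": score}
            row.update(self.chosen_hyperparams[i])
            row["n_selected"] = self.n_selected[i]
            rows.append(row)
        return pd.DataFrame(rows)

    def summary_row(self, R: int | None = None) -> dict:
        return {
            "method": self.method,
            "kernels": self.family_code,
            "R": R,
            "balanced_accuracy": f"{self.mean:.2f}±{self.sd:.2f}",
        }


def _outer_fold_fit(dataset, method, grouping, grids, tr, inner_seed):
    """Select hyperparameters on the outer-train set and refit on it.

    Every training-phase statistic (normalization scales, elimination
    paths, hyperparameters) is computed from rows in ``tr`` only, so
    modifying any row outside ``tr`` cannot change the fitted model.
    """
    points = _grid_points(method, grids, grouping.R)
    inner_folds = stratified_folds(
        dataset.y[tr],
        None if dataset.age is None else dataset.age[tr],
        grids.get("_n_inner", 10),
        inner_seed,
    )
    params, _ = _select_params(dataset, method, grouping, tr, inner_folds, points)
    predict_fn, mdl = _fit_final(dataset, method, grouping, tr, params)
    return params, predict_fn, mdl


def nested_cv(
    dataset: LabeledDataset,
    method: str,
    grids: dict,
    plan: CVPlan,
    family_code: str = "V_and_C",
    infold_prefilter_alpha: float | None = None,
) -> CVResult:
    """Repeated nested k-fold cross-validation of one method.

    For every outer fold, an inner ``plan.n_inner``-fold CV on the
    outer-train subjects picks the grid point with the best mean balanced
    accuracy (ties resolved toward the first point in declared grid order);
    the method is refit on the outer-train set and scored on the held-out
    fold.  No outer-test subject influences any training-phase statistic.

    ``infold_prefilter_alpha`` enables the strict mode in which the FDR
    pre-filter of clinical features is recomputed inside every outer-train
    set instead of once on the full dataset.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    scores, chosen, n_sel = [], [], []
    preds = np.zeros((plan.n_repeats, dataset.n_subjects), dtype=int)
    for rep in range(plan.n_repeats):
        folds = plan.fold_assignments[rep]
        for j in range(plan.n_outer):
            te = np.flatnonzero(folds == j)
            tr = np.flatnonzero(folds != j)
            ds, grp = dataset, None
            if infold_prefilter_alpha is not None:
                ds = _apply_infold_prefilter(dataset, tr, infold_prefilter_alpha)
            grp = build_grouping(ds, family_code)
            grids_local = dict(grids)
            grids_local["_n_inner"] = plan.n_inner
            params, predict_fn, mdl = _outer_fold_fit(
                ds, method, grp, grids_local,
                tr, plan.seed + 7919 * rep + 31 * j + 1,
            )
            yhat = predict_fn(ds.X[te])
            scores.append(balanced_accuracy(ds.y[te], yhat))
            chosen.append(params)
            preds[rep, te] = yhat
            n_sel.append(_model_n_selected(method, mdl))
    return CVResult(
        method=method,
        family_code=family_code,
        per_fold_scores=np.array(scores),
        chosen_hyperparams=chosen,
        per_subject_predictions=preds,
        fold_assignments=plan.fold_assignments,
        n_selected=n_sel,
    )


def _model_n_selected(method: str, mdl) -> int:
    if method in ("easymklfs", "easymkl"):
        return mdl.n_selected_features()
    if method == "svm":
        return int(len(mdl.column_scales))
    _, feats = mdl
    return int(len(feats))


def _apply_infold_prefilter(dataset, tr, alpha):
    clin_cols = np.concatenate(
        [s.columns for s in dataset.clinical_sources()]
    ) if dataset.clinical_sources() else np.empty(0, dtype=np.intp)
    if clin_cols.size == 0:
        return dataset
    retained_local = fdr_prefilter(
        dataset.X[np.ix_(tr, clin_cols)], dataset.y[tr], alpha=alpha
    )
    drop = np.setdiff1d(clin_cols, clin_cols[retained_local])
    keep = np.setdiff1d(np.arange(dataset.n_features), drop)
    return subset_features(dataset, keep)


# ---------------------------------------------------------------------------
# Multiple testing and paired comparison


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fdr_prefilter(
    clinical_block: np.ndarray, y: np.ndarray, alpha: float = 0.01
) -> np.ndarray:
    """Drop clinical features statistically tied to the labels.

    Because diagnostic labels are themselves derived from clinical scores,
    features whose two-sample t-test survives BH-FDR at ``alpha`` are
    circular and are *excluded*; the returned indices are the complement
    (the retained columns).
    """
    X = np.asarray(clinical_block, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        return np.empty(0, dtype=np.intp)
    y = np.asarray(y)
    a, b = X[y > 0], X[y < 0]
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each class needs at least two subjects")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    p = np.asarray(p, dtype=float)
    p[np.isnan(p)] = 1.0          # constant in both classes: no evidence
    p[np.isinf(np.asarray(t, dtype=float))] = 0.0
    adjusted = bh_adjust(p)
    return np.flatnonzero(~(adjusted < alpha))


def wilcoxon_signed_rank(
    scores_a: np.ndarray, scores_b: np.ndarray
) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test; returns (W⁺, two-sided p).

    Zero differences are dropped; tied absolute differences share averaged
    ranks.  The p-value is exact (full enumeration of the 2ⁿ sign
    patterns) for n ≤ 15 and a normal approximation with tie and
    continuity corrections otherwise.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score vectors must have equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero: no information")
    absd = np.abs(d)
    ranks = stats.rankdata(absd)
    w_plus = float(ranks[d > 0].sum())
    if n <= 15:
        # distribution of W+ over all sign patterns
        totals = np.zeros(1)
        for r in ranks:
            totals = np.concatenate([totals, totals + r])
        p_low = np.mean(totals <= w_plus + 1e-12)
        p_high = np.mean(totals >= w_plus - 1e-12)
        p = min(1.0, 2.0 * min(p_low, p_high))
        return w_plus, float(p)
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(absd, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
        tie_counts**3 - tie_counts
    ) / 48.0
    if var <= 0:
        raise ValueError("zero variance in signed ranks")
    diff = w_plus - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return w_plus, float(p)


def bonferroni_threshold(alpha: float, n_comparisons: int) -> float:
    """Per-test significance threshold alpha / n under Bonferroni correction."""
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be at least 1")
    return alpha / n_comparisons
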