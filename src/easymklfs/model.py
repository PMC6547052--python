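"""The EasyMKLFS estimator: weight thresholding, sparse combined kernel, SVM.

Pipeline: run EasyMKL over the base-kernel family to get weights η, discard
every kernel with η_r ≤ ρ, form the sparse combined kernel

    K* = Σ_{r : η_r > ρ} η_r K̂_r

(surviving weights are reused as-is, not renormalized), and train a
soft-margin SVM on the precomputed K*.  At ρ = 0 this is exactly plain
EasyMKL followed by an SVM on the full weighted kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .easymkl import (
    GammaSolution,
    KernelWeights,
    TraceNormalizedFeatures,
    average_kernel,
    kernel_weights_streaming,
    solve_gamma,
    trace_normalize,
)
from .io_data import KernelGrouping, LabeledDataset

__all__ = [
    "FSModel",
    "threshold_select",
    "build_combined_kernel",
    "fit",
    "predict",
    "decision_function",
    "sparsity",
    "load_model",
]


def threshold_select(weights: KernelWeights, rho: float) -> np.ndarray:
    """Indices of kernels surviving the threshold: exactly {r : η_r > ρ}.

    The inequality is strict — kernels with weight equal to ρ are removed —
    so ρ = 0 keeps every kernel with nonzero weight.
    """
    if rho < 0:
        raise ValueError("rho must be nonnegative")
    return np.flatnonzero(weights.eta > rho)


def _column_weights(
    selection: np.ndarray, eta: np.ndarray, grouping: KernelGrouping, m: int
) -> np.ndarray:
    """Per-column weight vector: η of the column's group if selected, else 0."""
    w = np.zeros(m)
    group_ids = grouping.column_group_ids(m)
    sel = np.zeros(grouping.R, dtype=bool)
    sel[selection] = True
    ok = group_ids >= 0
    keep = ok & sel[np.clip(group_ids, 0, None)]
    w[keep] = eta[group_ids[keep]]
    return w


def build_combined_kernel(
    A_hat: np.ndarray,
    B_hat: np.ndarray,
    selection: np.ndarray,
    eta: np.ndarray,
    grouping: KernelGrouping,
) -> np.ndarray:
    """|A|×|B| sparse combined kernel K* = Σ_{r selected} η_r K̂_r(a, b).

    ``A_hat``/``B_hat`` are rows already carrying the *training* trace
    normalization.  For linear base kernels the sum collapses to a single
    weighted inner product over the selected columns, so no per-kernel Gram
    is formed.  Symmetric PSD when A_hat is B_hat.
    """
    selection = np.asarray(selection, dtype=np.intp)
    if selection.size == 0:
        raise ValueError("no kernels survived threshold")
    if A_hat.shape[1] != B_hat.shape[1]:
        raise ValueError("row blocks must share the column space")
    w = _column_weights(selection, eta, grouping, A_hat.shape[1])
    cols = np.flatnonzero(w)
    K = (A_hat[:, cols] * w[cols]) @ B_hat[:, cols].T
    if A_hat is B_hat:
        K = (K + K.T) / 2.0
    return K


@dataclass
class FSModel:
    """Fitted sparse multiple-kernel SVM.

    Stores everything prediction needs: the surviving kernel indices and
    their (unrenormalized) weights, the training normalization scales, the
    training rows restricted to the selected columns, and the SVM dual
    solution on the precomputed K*.
    """

    selected_groups: np.ndarray
    eta_selected: np.ndarray
    rho: float
    lam: float
    C: float
    grouping: KernelGrouping
    column_scales: np.ndarray      # training trace-normalization, full length m
    selected_columns: np.ndarray   # columns inside the selected groups
    train_rows_scaled: np.ndarray  # training rows, scaled, selected columns only
    column_weights: np.ndarray     # η per selected column (aligned to selected_columns)
    support_idx: np.ndarray        # training-row indices of the support vectors
    dual_coef: np.ndarray          # y_i·α_i over support vectors, |α| ≤ C
    intercept: float
    gamma: GammaSolution | None = None
    eta_full: np.ndarray | None = None
    n_features_in: int = 0

    def n_selected_features(self) -> int:
        return int(self.selected_columns.size)

    def save(self, path) -> None:
        """Serialize to a single .npz archive (arrays + metadata)."""
        group_sizes = np.array([g.size for g in self.grouping.groups])
        np.savez(
            path,
            selected_groups=self.selected_groups,
            eta_selected=self.eta_selected,
            rho=self.rho,
            lam=self.lam,
            C=self.C,
            family_code=np.array(self.grouping.family_code),
            group_cols=np.concatenate(self.grouping.groups),
            group_sizes=group_sizes,
            column_scales=self.column_scales,
            selected_columns=self.selected_columns,
            train_rows_scaled=self.train_rows_scaled,
            column_weights=self.column_weights,
            support_idx=self.support_idx,
            dual_coef=self.dual_coef,
            intercept=self.intercept,
            n_features_in=self.n_features_in,
            eta_full=np.empty(0) if self.eta_full is None else self.eta_full,
        )


def fit(
    dataset: LabeledDataset,
    grouping: KernelGrouping,
    lam: float,
    rho: float,
    C: float,
) -> FSModel:
    """Fit EasyMKLFS: weights → threshold at ρ → K* → precomputed-kernel SVM.

    Deterministic for fixed inputs.  Raises ValueError (advising a smaller
    ρ) when no kernel survives the threshold.
    """
    tnf = trace_normalize(dataset.X, grouping)
    K_A = average_kernel(tnf, grouping)
    gamma = solve_gamma(K_A, dataset.y, lam)
    weights = kernel_weights_streaming(tnf, grouping, gamma, dataset.y)
    return _fit_from_weights(dataset, grouping, tnf, gamma, weights, lam, rho, C)


def _fit_from_weights(
    dataset: LabeledDataset,
    grouping: KernelGrouping,
    tnf: TraceNormalizedFeatures,
    gamma: GammaSolution,
    weights: KernelWeights,
    lam: float,
    rho: float,
    C: float,
) -> FSModel:
    """Finish the fit given already-computed EasyMKL weights (grid-search reuse)."""
    selection = threshold_select(weights, rho)
    if selection.size == 0:
        raise ValueError(
            "no kernels survived threshold; use a smaller rho"
        )
    m = dataset.n_features
    w_col = _column_weights(selection, weights.eta, grouping, m)
    cols = np.flatnonzero(w_col)
    train_scaled = tnf.Xhat[:, cols]
    K_star = (train_scaled * w_col[cols]) @ train_scaled.T
    K_star = (K_star + K_star.T) / 2.0
    svc = SVC(kernel="precomputed", C=C)
    svc.fit(K_star, dataset.y)
    return FSModel(
        selected_groups=selection,
        eta_selected=weights.eta[selection],
        rho=rho,
        lam=lam,
        C=C,
        grouping=grouping,
        column_scales=tnf.column_scales,
        selected_columns=cols,
        train_rows_scaled=train_scaled,
        column_weights=w_col[cols],
        support_idx=svc.support_.copy(),
        dual_coef=svc.dual_coef_.ravel().copy(),
        intercept=float(svc.intercept_[0]),
        gamma=gamma,
        eta_full=weights.eta,
        n_features_in=m,
    )


def _test_kernel(model: FSModel, X_new: np.ndarray) -> np.ndarray:
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] != model.n_features_in:
        raise ValueError(
            f"expected {model.n_features_in} columns, got "
            f"{X_new.shape[1] if X_new.ndim == 2 else X_new.shape}"
        )
    if not np.isfinite(X_new).all():
        raise ValueError("X_new contains non-finite values")
    cols = model.selected_columns
    X_scaled = X_new[:, cols] * model.column_scales[cols]
    return (X_scaled * model.column_weights) @ model.train_rows_scaled.T


def decision_function(model: FSModel, X_new: np.ndarray) -> np.ndarray:
    """SVM decision values on new rows (training scales and selection applied)."""
    K = _test_kernel(model, X_new)
    return K[:, model.support_idx] @ model.dual_coef + model.intercept


def load_model(path) -> FSModel:
    """Load a model saved with :meth:`FSModel.save`."""
    from .io_data import KernelGrouping

    with np.load(path, allow_pickle=False) as z:
        sizes = z["group_sizes"]
        cols = z["group_cols"]
        groups = np.split(cols, np.cumsum(sizes)[:-1])
        grouping = KernelGrouping(
            family_code=str(z["family_code"]), groups=groups
        )
        return FSModel(
            selected_groups=z["selected_groups"],
            eta_selected=z["eta_selected"],
            rho=float(z["rho"]),
            lam=float(z["lam"]),
            C=float(z["C"]),
            grouping=grouping,
            column_scales=z["column_scales"],
            selected_columns=z["selected_columns"],
            train_rows_scaled=z["train_rows_scaled"],
            column_weights=z["column_weights"],
            support_idx=z["support_idx"],
            dual_coef=z["dual_coef"],
            intercept=float(z["intercept"]),
            eta_full=z["eta_full"] if z["eta_full"].size else None,
            n_features_in=int(z["n_features_in"]),
        )


def predict(model: FSModel, X_new: np.ndarray) -> np.ndarray:
    """Predicted ±1 labels; a decision value of exactly 0 maps to +1."""
    dec = decision_function(model, X_new)
    return np.where(dec >= 0, 1, -1)


def sparsity(model: FSModel) -> tuple[int, float]:
    """(number of distinct selected feature columns, fraction of the m columns)."""
    n = model.n_selected_features()
    return n, n / model.n_features_in
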