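"""EasyMKL: trace normalization, average kernel, the margin QP, and kernel weights.

The method combines a family of R base kernels — here linear kernels over
groups of feature columns, usually a single column each — as a weighted sum
K = Σ_r η_r K_r.  Its defining property is that the weights are obtained
without ever materializing the R Gram matrices: the QP needs only the
average of the trace-normalized base kernels,

    K_A = (1/R) Σ_r K_r / Tr(K_r),

and the per-kernel weights are quadratic forms that reduce, for linear
kernels, to squared projections of a single ℓ-vector onto the scaled
feature columns.  Memory beyond the data matrix is O(ℓ + m).

The QP (a probability distribution per class, γ ∈ Γ):

    minimize  (1 − λ) γᵀ Ŷ K_A Ŷ γ + λ ‖γ‖²
    over      Γ = {γ ≥ 0, Σ_{y_i=+1} γ_i = 1, Σ_{y_i=−1} γ_i = 1},

with Ŷ = diag(y) and λ ∈ [0, 1].  At λ = 1 the solution is uniform within
each class; at λ = 0 it is the distance-between-class-hulls problem.  The
raw weight of kernel r is d_r = γᵀ Ŷ K̂_r Ŷ γ evaluated at the optimum,
normalized to Σ η = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from .io_data import KernelGrouping, LabeledDataset

__all__ = [
    "TraceNormalizedFeatures",
    "GammaSolution",
    "KernelWeights",
    "trace_normalize",
    "average_kernel",
    "solve_gamma",
    "kernel_weights_streaming",
    "kernel_weights_explicit",
    "easymkl_fit",
]


@dataclass
class TraceNormalizedFeatures:
    """Feature matrix rescaled so every base-kernel Gram has unit trace.

    For the linear kernel of group g, Tr(K_g) = Σ_{r∈g} ‖X[:,r]‖², so all
    columns of group g are multiplied by s_g = Tr(K_g)^(−1/2).  Columns of
    zero norm contribute nothing to any kernel; singleton groups made
    entirely of them are dropped (recorded in ``dropped_groups``).
    """

    Xhat: np.ndarray
    group_scales: np.ndarray          # s_g per group; 0 for dropped groups
    dropped_columns: np.ndarray       # zero-norm column indices
    dropped_groups: np.ndarray        # group ids with no surviving column
    column_scales: np.ndarray         # per-column scale actually applied

    @property
    def n_active_groups(self) -> int:
        return int(np.count_nonzero(self.group_scales > 0))

    def transform(self, X_new: np.ndarray) -> np.ndarray:
        """Apply the training scales to new rows (no re-fitting)."""
        X_new = np.asarray(X_new, dtype=float)
        if X_new.shape[1] != self.Xhat.shape[1]:
            raise ValueError(
                f"expected {self.Xhat.shape[1]} columns, got {X_new.shape[1]}"
            )
        return X_new * self.column_scales


@dataclass
class GammaSolution:
    """Optimal γ of the margin QP at a given λ."""

    gamma: np.ndarray
    lam: float
    objective_value: float
    n_iter: int = 0

    def class_sums(self, y: np.ndarray) -> tuple[float, float]:
        return (
            float(self.gamma[y > 0].sum()),
            float(self.gamma[y < 0].sum()),
        )


@dataclass
class KernelWeights:
    """Nonnegative per-kernel weights η, L1-normalized (Σ η = 1 unless all zero)."""

    eta: np.ndarray
    normalization: str = "L1"


def trace_normalize(X: np.ndarray, grouping: KernelGrouping) -> TraceNormalizedFeatures:
    """Scale columns so each group's linear-kernel Gram has trace one.

    Raises
    ------
    ValueError
        If a multi-column group has only zero-norm columns (a dead source).
        Zero-norm *singleton* groups are instead dropped and recorded.
    """
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    m = X.shape[1]
    sqnorms = np.einsum("ij,ij->j", X, X)
    group_ids = grouping.column_group_ids(m)
    R = grouping.R
    group_tr = np.zeros(R)
    np.add.at(group_tr, group_ids[group_ids >= 0], sqnorms[group_ids >= 0])

    dropped_cols = np.flatnonzero(sqnorms == 0)
    dead = np.flatnonzero(group_tr == 0)
    sizes = np.array([g.size for g in grouping.groups])
    multi_dead = dead[sizes[dead] > 1]
    if multi_dead.size:
        raise ValueError(
            f"group {int(multi_dead[0])} has only zero-norm columns"
        )
    if dead.size:
        warnings.warn(
            f"dropping {dead.size} zero-norm base kernel(s)", stacklevel=2
        )
    if dead.size == R:
        raise ValueError("all base kernels have zero trace")

    group_scales = np.zeros(R)
    alive = group_tr > 0
    group_scales[alive] = 1.0 / np.sqrt(group_tr[alive])
    column_scales = np.zeros(m)
    ok = group_ids >= 0
    column_scales[ok] = group_scales[group_ids[ok]]
    return TraceNormalizedFeatures(
        Xhat=X * column_scales,
        group_scales=group_scales,
        dropped_columns=dropped_cols,
        dropped_groups=dead,
        column_scales=column_scales,
    )


def average_kernel(
    tnf: TraceNormalizedFeatures, grouping: KernelGrouping
) -> np.ndarray:
    """The ℓ×ℓ average K_A = (1/R) Σ_g K̂_g of the unit-trace base kernels.

    Computed directly as (1/R)·X̃X̃ᵀ on the scaled matrix — per-kernel Grams
    are never formed.  Symmetric, PSD, Tr(K_A) = 1.
    """
    R = tnf.n_active_groups
    if R < 1:
        raise ValueError("no active base kernels")
    K = tnf.Xhat @ tnf.Xhat.T / R
    return (K + K.T) / 2.0


def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex (Duchi et al.)."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.flatnonzero(u * np.arange(1, len(v) + 1) > css)[-1]
    theta = css[rho] / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


def solve_gamma(K_A: np.ndarray, y: np.ndarray, lam: float) -> GammaSolution:
    """Solve the margin QP for γ over the product of the two class simplices.

    A deterministic accelerated projected-gradient (FISTA with restart) on
    the convex objective (1−λ)·γᵀŶK_AŶγ + λ‖γ‖².  Converged when the fixed
    step-size projected-gradient residual is below 1e−10 in max norm, which
    puts the objective within ~1e−8 of the optimum on unit-trace kernels.
    """
    K_A = np.asarray(K_A, dtype=float)
    y = np.asarray(y)
    if K_A.shape[0] != K_A.shape[1]:
        raise ValueError("K_A must be square")
    if not np.allclose(K_A, K_A.T, atol=1e-8):
        raise ValueError("K_A must be symmetric")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must lie in [0, 1]")
    pos = np.flatnonzero(y > 0)
    neg = np.flatnonzero(y < 0)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")

    n = len(y)
    Q = (1.0 - lam) * (y[:, None] * K_A * y[None, :])
    # objective = γᵀQγ + λ‖γ‖² ; gradient = 2(Qγ + λγ)

    def objective(g: np.ndarray) -> float:
        return float(g @ Q @ g + lam * g @ g)

    def project(g: np.ndarray) -> np.ndarray:
        out = np.empty_like(g)
        out[pos] = _project_simplex(g[pos])
        out[neg] = _project_simplex(g[neg])
        return out

    # Lipschitz constant of the gradient
    L = 2.0 * (max(float(np.linalg.eigvalsh(Q)[-1]), 0.0) + lam)
    if L <= 0:  # lam = 0 with zero kernel: any feasible point is optimal
        g0 = np.zeros(n)
        g0[pos] = 1.0 / pos.size
        g0[neg] = 1.0 / neg.size
        return GammaSolution(gamma=g0, lam=lam, objective_value=0.0)
    step = 1.0 / L

    gamma = np.zeros(n)
    gamma[pos] = 1.0 / pos.size
    gamma[neg] = 1.0 / neg.size
    z = gamma.copy()
    t = 1.0
    max_iter = 100_000
    tol = 1e-10
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        grad = 2.0 * (Q @ z + lam * z)
        gamma_new = project(z - step * grad)
        # restart if momentum points uphill
        if (z - gamma_new) @ (gamma_new - gamma) > 0:
            t = 1.0
            z = gamma
            continue
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        z = gamma_new + ((t - 1.0) / t_new) * (gamma_new - gamma)
        delta = np.abs(gamma_new - gamma).max()
        gamma = gamma_new
        t = t_new
        if delta < tol:
            # fixed-point check at gamma itself
            resid = np.abs(
                project(gamma - step * 2.0 * (Q @ gamma + lam * gamma)) - gamma
            ).max()
            if resid < tol:
                break
    return GammaSolution(
        gamma=gamma, lam=lam, objective_value=objective(gamma), n_iter=n_iter
    )


def kernel_weights_streaming(
    tnf: TraceNormalizedFeatures,
    grouping: KernelGrouping,
    gamma: GammaSolution,
    y: np.ndarray,
) -> KernelWeights:
    """Per-kernel weights η without materializing any Gram matrix.

    With z = Ŷγ, the raw weight of group g is
    d_g = γᵀŶK̂_gŶγ = ‖X̃_gᵀ z‖² = Σ_{r∈g} (x̃_rᵀ z)²,
    so a single matrix–vector product and a grouped sum of squares suffice.
    η = d / ‖d‖₁ (zero vector if every d_g = 0).
    """
    y = np.asarray(y)
    z = y * gamma.gamma
    v = tnf.Xhat.T @ z                        # length m
    m = tnf.Xhat.shape[1]
    group_ids = grouping.column_group_ids(m)
    ok = group_ids >= 0
    d = np.bincount(group_ids[ok], weights=v[ok] ** 2, minlength=grouping.R)
    return _normalize_weights(d)


def kernel_weights_explicit(
    kernels: list[np.ndarray], gamma: GammaSolution, y: np.ndarray
) -> KernelWeights:
    """Oracle form of the weight computation from explicit unit-trace Grams."""
    y = np.asarray(y)
    z = y * gamma.gamma
    d = np.empty(len(kernels))
    for r, K in enumerate(kernels):
        K = np.asarray(K, dtype=float)
        tr = float(np.trace(K))
        if abs(tr - 1.0) > 1e-6:
            raise ValueError(f"kernel {r} has trace {tr}, expected 1")
        d[r] = float(z @ K @ z)
    return _normalize_weights(d)


def _normalize_weights(d: np.ndarray) -> KernelWeights:
    d = np.maximum(d, 0.0)
    total = d.sum()
    if total <= 0:
        return KernelWeights(eta=np.zeros_like(d))
    return KernelWeights(eta=d / total)


def easymkl_fit(
    dataset: LabeledDataset, grouping: KernelGrouping, lam: float
) -> tuple[GammaSolution, KernelWeights]:
    """Trace-normalize, build K_A, solve for γ, and extract kernel weights η."""
    tnf = trace_normalize(dataset.X, grouping)
    K_A = average_kernel(tnf, grouping)
    gamma = solve_gamma(K_A, dataset.y, lam)
    weights = kernel_weights_streaming(tnf, grouping, gamma, dataset.y)
    return gamma, weights
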