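"""Semi-supervised projective NMF: objective, multiplicative updates, fitting.

The model learns non-negative cluster centroids ``W`` (r × m, rows in gene
space) shared by labeled and unlabeled samples.  Labeled-sample coefficients
are pinned to their one-hot class indicator ``Q``; only the unlabeled
coefficients ``H_U`` (n_U × r) are free.  The objective is

    J = 1/2 ||[V_L; V_U] - [Q; H_U] W||_F^2
      + alpha/2 ||W - H_U^T V_U||_F^2
      + beta/2  sum_ij H_U[i,j] * ||V_U[i] - W[j]||^2

where the alpha term ties the centroids to the span of the unlabeled data
(the projective constraint, relaxed) and the beta term is a local
coordinate penalty that pushes each sample onto nearby centroids, inducing
sparse, label-like coefficients.  Both factors are optimized by alternating
multiplicative updates that preserve non-negativity and never increase J.
Unlabeled samples are classified by the argmax of their coefficient row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import (
    UNLABELED,
    DimensionError,
    DomainError,
    ExpressionMatrix,
    PartialLabelSet,
)

__all__ = [
    "SemiPNMFConfig",
    "FactorizationState",
    "FitResult",
    "objective",
    "update_w",
    "update_h",
    "fit",
    "predict",
]


@dataclass
class SemiPNMFConfig:
    """Hyperparameters of the factorization.

    alpha weights centroid consistency (W close to H_U^T V_U), beta the
    local coordinate penalty.  The stopping rule is the relative objective
    change |J_{l+1} - J_l| / |J_l| < tol, evaluated on the full objective,
    with at most max_iter alternating iterations.  denom_guard is a small
    additive constant keeping multiplicative denominators strictly
    positive.
    """

    alpha: float = 0.2
    beta: float = 0.01
    max_iter: int = 1500
    tol: float = 1e-7
    seed: int = 0
    denom_guard: float = 1e-12

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise DomainError("alpha and beta must be non-negative")
        if self.tol <= 0:
            raise DomainError("tol must be positive")
        if self.max_iter < 1:
            raise DomainError("max_iter must be at least 1")
        if self.denom_guard <= 0:
            raise DomainError("denom_guard must be positive")


@dataclass
class FactorizationState:
    """Current factors: centroids W (r × m) and unlabeled coefficients H_U (n_U × r)."""

    W: np.ndarray
    H_U: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.H_U = np.asarray(self.H_U, dtype=float)
        for name, a in (("W", self.W), ("H_U", self.H_U)):
            if a.ndim != 2:
                raise DimensionError(f"{name} must be 2-D")
            if not np.isfinite(a).all():
                raise DomainError(f"{name} must be finite")
            if (a < 0).any():
                raise DomainError(f"{name} must be non-negative")
        if self.H_U.shape[1] != self.W.shape[0]:
            raise DimensionError(
                f"H_U has {self.H_U.shape[1]} columns but W has {self.W.shape[0]} rows"
            )


@dataclass
class FitResult:
    """Outcome of :func:`fit`: final state, objective trace, convergence flag."""

    state: FactorizationState
    objective_trace: np.ndarray
    n_iter: int
    converged: bool
    classes: list[str] = field(default_factory=list)

    def predictions(self) -> np.ndarray:
        """Predicted class index for each unlabeled sample (argmax of H_U rows)."""
        return predict(self.state.H_U)


def _check_inputs(
    V_L: np.ndarray, V_U: np.ndarray, Q: np.ndarray, state: FactorizationState
) -> None:
    d, m = V_L.shape
    n_u, m_u = V_U.shape
    if m_u != m and d > 0:
        raise DimensionError("V_L and V_U must have the same number of genes")
    if Q.shape[0] != d:
        raise DimensionError("Q must have one row per labeled sample")
    r = state.W.shape[0]
    if d > 0 and Q.shape[1] != r:
        raise DimensionError("Q column count must equal the number of centroids")
    if state.W.shape[1] != m_u:
        raise DimensionError("W column count must equal the number of genes")
    if state.H_U.shape[0] != n_u:
        raise DimensionError("H_U must have one row per unlabeled sample")
    for name, a in (("V_L", V_L), ("V_U", V_U), ("Q", Q)):
        if not np.isfinite(a).all():
            raise DomainError(f"{name} must be finite")
        if (a < 0).any():
            raise DomainError(f"{name} must be non-negative")


def objective(
    V_L: np.ndarray,
    V_U: np.ndarray,
    Q: np.ndarray,
    state: FactorizationState,
    alpha: float,
    beta: float,
) -> float:
    """Evaluate the full objective J at the given state.

    With no labeled samples (``d = 0``) the Q-block of the reconstruction
    term vanishes and the model reduces to its unsupervised form.
    """
    V_L = np.atleast_2d(np.asarray(V_L, dtype=float))
    V_U = np.atleast_2d(np.asarray(V_U, dtype=float))
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    if V_L.size == 0:
        V_L = V_L.reshape(0, V_U.shape[1])
        Q = Q.reshape(0, state.W.shape[0])
    _check_inputs(V_L, V_U, Q, state)
    W, H = state.W, state.H_U

    recon = 0.0
    if V_L.shape[0] > 0:
        recon += np.sum((V_L - Q @ W) ** 2)
    recon += np.sum((V_U - H @ W) ** 2)
    j = 0.5 * recon
    j += 0.5 * alpha * np.sum((W - H.T @ V_U) ** 2)
    if beta != 0.0 and H.size:
        # squared distances ||V_U[i] - W[j]||^2, n_U × r
        d2 = (
            np.sum(V_U**2, axis=1)[:, None]
            - 2.0 * V_U @ W.T
            + np.sum(W**2, axis=1)[None, :]
        )
        j += 0.5 * beta * np.sum(np.abs(H) * d2)
    return float(j)


def update_w(
    state: FactorizationState,
    V_L: np.ndarray,
    V_U: np.ndarray,
    Q: np.ndarray,
    alpha: float,
    beta: float,
    denom_guard: float = 1e-12,
) -> np.ndarray:
    """One multiplicative update of the centroid matrix W (H_U held fixed).

    W' = W ⊗ [Q^T V_L + (1+α+β) H_U^T V_U]
           ⊘ [Q^T Q W + H_U^T H_U W + α W + β F_U W + guard]

    with F_U the diagonal matrix of the column sums of H_U.  The update
    never increases the objective.
    """
    V_L = np.atleast_2d(np.asarray(V_L, dtype=float))
    V_U = np.atleast_2d(np.asarray(V_U, dtype=float))
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    if V_L.size == 0:
        V_L = V_L.reshape(0, V_U.shape[1])
        Q = Q.reshape(0, state.W.shape[0])
    _check_inputs(V_L, V_U, Q, state)
    W, H = state.W, state.H_U

    numer = (1.0 + alpha + beta) * (H.T @ V_U)
    if V_L.shape[0] > 0:
        numer = numer + Q.T @ V_L
    f_u = H.sum(axis=0)  # diagonal of F_U, shape (r,)
    denom = (H.T @ H) @ W + alpha * W + beta * f_u[:, None] * W
    if V_L.shape[0] > 0:
        denom = denom + (Q.T @ Q) @ W
    new_w = W * numer / (denom + denom_guard)
    if not np.isfinite(new_w).all():
        raise FloatingPointError("NaN/Inf in W update: zero denominator not guarded")
    return new_w


def update_h(
    state: FactorizationState,
    V_U: np.ndarray,
    alpha: float,
    beta: float,
    denom_guard: float = 1e-12,
) -> np.ndarray:
    """One multiplicative update of the unlabeled coefficients H_U (W fixed).

    H' = H ⊗ [(1+α+β) V_U W^T]
           ⊘ [H W W^T + α V_U V_U^T H + (β/2)(A + B) + guard]

    where A_ij = ||V_U[i]||^2 and B_ij = ||W[j]||^2 broadcast to n_U × r.
    Exact zeros in H_U stay zero (multiplicative zero-locking).
    """
    V_U = np.atleast_2d(np.asarray(V_U, dtype=float))
    W, H = state.W, state.H_U
    if state.W.shape[1] != V_U.shape[1]:
        raise DimensionError("W column count must equal the number of genes")
    if H.shape[0] != V_U.shape[0]:
        raise DimensionError("H_U must have one row per unlabeled sample")
    if not np.isfinite(V_U).all() or (V_U < 0).any():
        raise DomainError("V_U must be finite and non-negative")

    numer = (1.0 + alpha + beta) * (V_U @ W.T)
    a_col = np.sum(V_U**2, axis=1)[:, None]  # A_ij = ||V_U[i]||^2
    b_row = np.sum(W**2, axis=1)[None, :]  # B_ij = ||W[j]||^2
    denom = H @ (W @ W.T) + alpha * (V_U @ (V_U.T @ H)) + 0.5 * beta * (a_col + b_row)
    new_h = H * numer / (denom + denom_guard)
    if not np.isfinite(new_h).all():
        raise FloatingPointError("NaN/Inf in H update: zero denominator not guarded")
    return new_h


def predict(H_U: np.ndarray) -> np.ndarray:
    """Class index per unlabeled sample: argmax of each coefficient row.

    Ties break to the lowest index, so the result is deterministic and
    invariant to positive rescaling of H_U.
    """
    H_U = np.asarray(H_U, dtype=float)
    if H_U.ndim != 2 or H_U.size == 0:
        raise DimensionError("H_U must be a non-empty 2-D matrix")
    if not np.isfinite(H_U).all() or (H_U < 0).any():
        raise DomainError("H_U must be finite and non-negative")
    return np.argmax(H_U, axis=1)


def fit(
    data: ExpressionMatrix,
    labels: PartialLabelSet,
    config: SemiPNMFConfig | None = None,
) -> FitResult:
    """Fit the factorization by alternating multiplicative updates.

    Rows of ``data`` are partitioned by labeled status into (V_L, V_U); Q
    is the one-hot indicator over labeled rows.  W and H_U are initialized
    i.i.d. uniform on (0, 1) from the seeded generator, then updated W
    first, H_U second, each full iteration appending J to the trace.
    Iteration stops when the relative objective change falls below
    ``config.tol`` or at ``config.max_iter`` (``converged=False`` then).
    """
    if config is None:
        config = SemiPNMFConfig()
    if data.has_missing:
        raise DomainError("expression matrix has missing entries; impute first")
    if len(labels.assignment) != data.n_samples:
        raise DimensionError("labels must cover exactly the samples of the matrix")
    r = labels.n_classes
    if r == 0:
        raise ValueError("at least one class must be declared")
    n_u = labels.n_unlabeled
    if n_u == 0:
        raise ValueError("at least one unlabeled sample is required")

    mask = labels.labeled_mask
    V_L = data.values[mask]
    V_U = data.values[~mask]
    Q = labels.indicator()
    if mask.any():
        counts = Q.sum(axis=0)
        for j, c in enumerate(counts):
            if c == 0:
                warnings.warn(
                    f"class {labels.classes[j]!r} has no labeled sample; "
                    "its centroid is data-driven only",
                    stacklevel=2,
                )

    rng = np.random.default_rng(config.seed)
    m = data.n_genes
    state = FactorizationState(
        W=rng.uniform(size=(r, m)), H_U=rng.uniform(size=(n_u, r))
    )

    trace: list[float] = []
    j_prev = objective(V_L, V_U, Q, state, config.alpha, config.beta)
    converged = False
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        state = FactorizationState(
            W=update_w(
                state, V_L, V_U, Q, config.alpha, config.beta, config.denom_guard
            ),
            H_U=state.H_U,
        )
        state = FactorizationState(
            W=state.W,
            H_U=update_h(state, V_U, config.alpha, config.beta, config.denom_guard),
        )
        j_cur = objective(V_L, V_U, Q, state, config.alpha, config.beta)
        trace.append(j_cur)
        if j_cur == 0.0 or (j_prev != 0.0 and abs(j_cur - j_prev) / abs(j_prev) < config.tol):
            converged = True
            break
        j_prev = j_cur

    return FitResult(
        state=state,
        objective_trace=np.asarray(trace),
        n_iter=n_iter,
        converged=converged,
        classes=list(labels.classes),
    )
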