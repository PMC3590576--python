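"""Exact kernel logistic regression in the dual, fitted with IRLS/Newton.

KLR models the posterior turn probability through a logit link,
P(turn | x) = 1 / (1 + exp(−f(x))), with f living in the RKHS of an RBF
kernel K(x, x′) = exp(−γ‖x − x′‖²).  The penalized negative log likelihood

    J(w, b) = ½ wᵀw + (λ/2) Σᵢ log(1 + exp(−yᵢ f(xᵢ)))

is minimised; by the representer property w = Σ αᵢ φ(xᵢ), so in the dual
f(x) = Σ αᵢ K(x, xᵢ) + b and the penalty becomes ½ αᵀKα.  Note λ weights the
loss term (λ plays the role of 2C in the usual C-parameterisation); the
intercept b is unpenalised.

The dense dual solver here is exact and cubic in N — it serves small
problems and acts as the correctness oracle for the fixed-size
approximation in :mod:`turnklr.fsklr`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.linalg import LinAlgError, solve
from scipy.spatial.distance import cdist
from scipy.special import expit


class ConvergenceError(RuntimeError):
    """Solver failed to reach the requested gradient tolerance."""

    def __init__(self, message: str, grad_norm: float):
        super().__init__(f"{message} (last gradient norm {grad_norm:.3e})")
        self.grad_norm = grad_norm


@dataclass
class KernelSpec:
    """RBF kernel width parameter γ (> 0; γ = 0 gives the all-ones kernel)."""

    gamma: float

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError(f"gamma must be non-negative, got {self.gamma}")


@dataclass
class Hyperparams:
    """Loss weight λ, kernel width γ and the decision threshold on P(turn)."""

    lam: float = 1.0
    gamma: float = 0.05
    threshold: float = 0.45

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError(f"lambda must be positive, got {self.lam}")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError(f"threshold must lie in (0,1), got {self.threshold}")

    @property
    def kernel(self) -> KernelSpec:
        return KernelSpec(gamma=self.gamma)


@dataclass
class DualSolution:
    """Fitted dual coefficients α, intercept b and the training rows."""

    alpha: np.ndarray
    b: float
    training_points: np.ndarray
    spec: KernelSpec
    grad_norm: float = 0.0
    objective_history: List[float] = field(default_factory=list)
    n_iter: int = 0


# ---------------------------------------------------------------------------
# kernel evaluations
# ---------------------------------------------------------------------------


def rbf_kernel(x: np.ndarray, x2: np.ndarray, spec: KernelSpec) -> float:
    """Single RBF evaluation exp(−γ‖x − x′‖²) ∈ (0, 1]."""
    x = np.asarray(x, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x.shape != x2.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {x2.shape}")
    d2 = float(np.sum((x - x2) ** 2))
    return float(np.exp(-spec.gamma * d2))


def gram_matrix(A: np.ndarray, B: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Kernel matrix with entries K(Aᵢ, Bⱼ); symmetric PSD in the square case."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"dimension mismatch: {A.shape[1]} vs {B.shape[1]}")
    d2 = cdist(A, B, metric="sqeuclidean")
    return np.exp(-spec.gamma * d2)


def predict_proba_from_f(f) -> Tuple[np.ndarray, np.ndarray]:
    """Map decision values to (P(turn), P(non-turn)); overflow-safe."""
    f = np.asarray(f, dtype=float)
    p_turn = expit(f)
    return p_turn, 1.0 - p_turn


# ---------------------------------------------------------------------------
# objective and IRLS fit
# ---------------------------------------------------------------------------


def pnll_objective(
    alpha: np.ndarray, b: float, K: np.ndarray, y: np.ndarray, lam: float
) -> float:
    """Dual-form penalized negative log likelihood ½αᵀKα + (λ/2)Σ log(1+e^{−y f})."""
    alpha = np.asarray(alpha, dtype=float)
    y = np.asarray(y, dtype=float)
    Ka = K @ alpha
    quad = 0.5 * float(alpha @ Ka)
    scale = 1.0 + float(alpha @ alpha) * max(1.0, float(np.abs(K).max(initial=0.0)))
    if quad < -1e-8 * scale:
        raise ValueError("kernel matrix is not positive semidefinite")
    f = Ka + b
    loss = 0.5 * lam * float(np.logaddexp(0.0, -y * f).sum())
    return max(quad, 0.0) + loss


def fit_dual_irls(
    K: np.ndarray,
    y: np.ndarray,
    lam: float,
    tol: float = 1e-8,
    max_iter: int = 100,
    X: Optional[np.ndarray] = None,
    spec: Optional[KernelSpec] = None,
    jitter: float = 1e-10,
) -> DualSolution:
    """Fit dual KLR by damped Newton / IRLS on (α, b).

    Each iteration solves the weighted least-squares subproblem defined by
    the IRLS weights pᵢ(1 − pᵢ); a step-halving line search keeps the convex
    objective monotonically decreasing.  Terminates when the gradient norm
    drops to ``tol``; raises :class:`ConvergenceError` otherwise.
    """
    K = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if K.shape != (n, n):
        raise ValueError("K must be square and match len(y)")
    if (y > 0).all() or (y < 0).all():
        raise ValueError("both classes must be present")
    t = (y + 1) / 2.0

    alpha = np.zeros(n)
    b = 0.0
    obj = pnll_objective(alpha, b, K, y, lam)
    history = [obj]
    gnorm = np.inf
    for it in range(max_iter):
        f = K @ alpha + b
        p = expit(f)
        g_f = p - t
        w = p * (1.0 - p)
        grad_alpha = K @ (alpha + 0.5 * lam * g_f)
        grad_b = 0.5 * lam * float(g_f.sum())
        gnorm = float(np.sqrt(grad_alpha @ grad_alpha + grad_b**2))
        if gnorm <= tol:
            return DualSolution(
                alpha=alpha,
                b=b,
                training_points=X if X is not None else np.empty((n, 0)),
                spec=spec if spec is not None else KernelSpec(gamma=1.0),
                grad_norm=gnorm,
                objective_history=history,
                n_iter=it,
            )
        KW = K * w  # K @ diag(w)
        H = np.empty((n + 1, n + 1))
        H[:n, :n] = K + 0.5 * lam * (KW @ K)
        Kw = K @ w
        H[:n, n] = 0.5 * lam * Kw
        H[n, :n] = 0.5 * lam * Kw
        H[n, n] = 0.5 * lam * float(w.sum())
        H[np.diag_indices(n + 1)] += jitter
        grad = np.concatenate([grad_alpha, [grad_b]])
        try:
            step = solve(H, -grad, assume_a="sym")
        except LinAlgError:
            step, *_ = np.linalg.lstsq(H, -grad, rcond=None)
        # step halving keeps the objective monotone
        s = 1.0
        while s > 1e-14:
            na = alpha + s * step[:n]
            nb = b + s * step[n]
            nobj = pnll_objective(na, nb, K, y, lam)
            if nobj <= obj + 1e-12 * (1.0 + abs(obj)):
                break
            s *= 0.5
        alpha, b, obj = na, nb, nobj
        history.append(obj)
    raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations", gnorm)


def decision_function_dual(
    sol: DualSolution, X_new: np.ndarray, spec: Optional[KernelSpec] = None
) -> np.ndarray:
    """Evaluate f(x) = Σ αᵢ K(x, xᵢ) + b on new points."""
    spec = spec if spec is not None else sol.spec
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if sol.training_points.size == 0:
        raise ValueError("solution carries no training points")
    if X_new.shape[1] != sol.training_points.shape[1]:
        raise ValueError("dimension mismatch with training features")
    return gram_matrix(X_new, sol.training_points, spec) @ sol.alpha + sol.b
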