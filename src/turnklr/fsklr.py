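"""Fixed-size kernel logistic regression (FS-KLR).

The exact dual KLR of :mod:`turnklr.klr` is cubic in the number of training
residues, so for chain datasets (tens of thousands of residues) the kernel
expansion is restricted to m ≪ n prototype vectors (PVs) chosen by k-means
(a k-center surrogate that minimises the quantization error the Nyström
error bound depends on).  The m×m kernel eigensystem K_m = U Λ Uᵀ induces
the explicit feature map

    Φ = K_{n,m} U_p Λ_p^{−1/2},

whose Gram matrix Φ Φᵀ is the Nyström approximation K_{n,m} K_m⁻¹ K_{m,n};
the classical Nyström eigen-extension λ̃ᵢ = (n/m) λᵢ, ũᵢ = √(m/n) (1/λᵢ)
K_{n,m} uᵢ reappears as the scaled column structure of Φ
(Φ eᵢ = √(λ̃ᵢ · m/n) ũᵢ · √(n/m) — see :func:`nystrom_extension`).

The model is then fitted in the primal on Φ with a trust-region Newton
method (truncated conjugate-gradient inner solves): cheap approximate steps
early, full Newton directions near the optimum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
from scipy.special import expit
from sklearn.cluster import KMeans

from .features import FeatureSelector
from .klr import ConvergenceError, Hyperparams, KernelSpec, gram_matrix


@dataclass
class PrototypeSet:
    """The m landmark training rows that anchor the approximate kernel map."""

    indices: np.ndarray  # distinct row indices into the training matrix
    vectors: np.ndarray  # m×d
    m: int

    def __post_init__(self) -> None:
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("prototype indices must be distinct")
        if self.m != len(self.indices):
            raise ValueError("m must equal the number of prototype indices")


@dataclass
class NystromMap:
    """Retained eigensystem of the prototype kernel matrix."""

    prototypes: PrototypeSet
    gamma: float
    eigvals: np.ndarray  # descending, strictly positive, length p
    eigvecs: np.ndarray  # m×p
    p: int
    eps: float

    def __post_init__(self) -> None:
        if np.any(self.eigvals <= 0) or np.any(np.diff(self.eigvals) > 0):
            raise ValueError("eigvals must be strictly positive and descending")
        if self.p > self.prototypes.m:
            raise ValueError("p cannot exceed the number of prototypes")


@dataclass
class TronResult:
    """Primal fit outcome with the per-iteration gradient-norm trace."""

    w: np.ndarray
    b: float
    objective: float
    grad_norms: List[float]
    n_iter: int


@dataclass
class FSKLRModel:
    """Everything needed for prediction: map, primal weights, hyperparameters."""

    map: NystromMap
    w: np.ndarray
    b: float
    hyper: Hyperparams
    seed: int = 0
    selector: Optional[FeatureSelector] = None
    window: int = 7

    def __post_init__(self) -> None:
        if len(self.w) != self.map.p:
            raise ValueError("weight length must equal the map dimension")
        if not np.all(np.isfinite(self.w)):
            raise ValueError("weights must be finite")


# ---------------------------------------------------------------------------
# prototype selection
# ---------------------------------------------------------------------------


def select_prototypes(
    X: np.ndarray, m: int, seed: int, outlier_min_frac: float = 0.001
) -> PrototypeSet:
    """Pick m prototype vectors by seeded k-means with medoid snapping.

    Each cluster contributes the training row nearest to its centroid, so
    PVs are always actual data points.  Clusters smaller than
    ``outlier_min_frac·n`` are treated as outlier clusters: they are
    discarded and their slots refilled once with additional near-centroid
    rows from the largest remaining clusters.  Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty input")
    if not (1 <= m <= n):
        raise ValueError(f"m must satisfy 1 <= m <= n={n}, got {m}")
    if m == n:
        indices = np.arange(n)
        return PrototypeSet(indices=indices, vectors=X[indices], m=n)

    km = KMeans(
        n_clusters=m, init="k-means++", n_init=1, tol=1e-4, random_state=seed
    ).fit(X)
    labels = km.labels_
    centers = km.cluster_centers_
    sizes = np.bincount(labels, minlength=m)
    min_size = max(1, int(np.ceil(outlier_min_frac * n)))

    used: set = set()
    chosen: List[int] = []

    def nearest_unused(members: np.ndarray, center: np.ndarray) -> Optional[int]:
        d2 = np.sum((X[members] - center) ** 2, axis=1)
        for j in np.argsort(d2, kind="stable"):
            idx = int(members[j])
            if idx not in used:
                return idx
        return None

    kept = [c for c in range(m) if sizes[c] >= min_size]
    for c in kept:
        idx = nearest_unused(np.flatnonzero(labels == c), centers[c])
        if idx is not None:
            used.add(idx)
            chosen.append(idx)

    # one refill pass: outlier-cluster slots re-seeded from the largest clusters
    deficit = m - len(chosen)
    if deficit > 0:
        by_size = sorted(kept, key=lambda c: (-sizes[c], c))
        for c in by_size:
            if deficit == 0:
                break
            idx = nearest_unused(np.flatnonzero(labels == c), centers[c])
            if idx is not None:
                used.add(idx)
                chosen.append(idx)
                deficit -= 1

    indices = np.sort(np.array(chosen, dtype=int))
    return PrototypeSet(indices=indices, vectors=X[indices], m=len(indices))


# ---------------------------------------------------------------------------
# Nyström map
# ---------------------------------------------------------------------------


def build_nystrom_map(
    prototypes: PrototypeSet, gamma: float, eps: float = 1e-12
) -> NystromMap:
    """Eigendecompose the prototype kernel matrix and keep the stable part.

    Components with eigenvalue ≤ eps·λ_max are dropped (rank deficiency from
    duplicated or near-duplicated PVs); at least one component must survive.
    """
    spec = KernelSpec(gamma=gamma)
    K = gram_matrix(prototypes.vectors, prototypes.vectors, spec)
    vals, vecs = np.linalg.eigh(K)
    vals = vals[::-1]
    vecs = vecs[:, ::-1]
    if vals[0] <= 0:
        raise ValueError("all kernel eigenvalues are non-positive")
    keep = vals > eps * vals[0]
    p = int(keep.sum())
    if p == 0:
        raise ValueError("all eigenvalues below the relative cutoff")
    return NystromMap(
        prototypes=prototypes,
        gamma=gamma,
        eigvals=vals[:p].copy(),
        eigvecs=vecs[:, :p].copy(),
        p=p,
        eps=eps,
    )


def apply_nystrom_map(nmap: NystromMap, X: np.ndarray) -> np.ndarray:
    """Explicit approximate feature map Φ = K_{n,m} U_p Λ_p^{−1/2}.

    Φ Φᵀ equals the Nyström approximation K_{n,m} K_m⁻¹ K_{m,n} (restricted
    to the retained components), exact on the landmarks at full rank.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != nmap.prototypes.vectors.shape[1]:
        raise ValueError(
            f"feature width {X.shape[1]} does not match prototypes "
            f"({nmap.prototypes.vectors.shape[1]})"
        )
    Knm = gram_matrix(X, nmap.prototypes.vectors, KernelSpec(gamma=nmap.gamma))
    return (Knm @ nmap.eigvecs) / np.sqrt(nmap.eigvals)


def nystrom_extension(
    nmap: NystromMap, X: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Classical Nyström eigen-extension to n points.

    Returns (λ̃, Ũ) with λ̃ᵢ = (n/m) λᵢ^{(m)} and
    ũᵢ = √(m/n) (1/λᵢ^{(m)}) K_{n,m} uᵢ^{(m)}.  The i-th column of the
    feature map relates to these exactly: Φ eᵢ = √(λᵢ^{(m)}) · √(n/m) · ũᵢ
    = √(λ̃ᵢ) · ũᵢ.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    m = nmap.prototypes.m
    Knm = gram_matrix(X, nmap.prototypes.vectors, KernelSpec(gamma=nmap.gamma))
    lam_tilde = (n / m) * nmap.eigvals
    U_tilde = np.sqrt(m / n) * (Knm @ nmap.eigvecs) / nmap.eigvals
    return lam_tilde, U_tilde


# ---------------------------------------------------------------------------
# trust-region Newton (primal)
# ---------------------------------------------------------------------------


def _steihaug_cg(hess_vec, g: np.ndarray, delta: float, cg_tol: float, max_cg: int):
    """Steihaug truncated CG for the trust-region subproblem.

    Minimises gᵀs + ½ sᵀHs subject to ‖s‖ ≤ delta; returns (s, Hs, hit_boundary).
    """
    s = np.zeros_like(g)
    r = -g.copy()
    d = r.copy()
    Hs = np.zeros_like(g)
    rr = float(r @ r)
    threshold = cg_tol * np.sqrt(float(g @ g))
    for _ in range(max_cg):
        if np.sqrt(rr) <= threshold:
            return s, Hs, False
        Hd = hess_vec(d)
        dHd = float(d @ Hd)
        if dHd <= 0:
            tau = _boundary_step(s, d, delta)
            s = s + tau * d
            return s, hess_vec(s), True
        alpha = rr / dHd
        s_next = s + alpha * d
        if np.sqrt(float(s_next @ s_next)) >= delta:
            tau = _boundary_step(s, d, delta)
            s = s + tau * d
            return s, hess_vec(s), True
        s = s_next
        Hs = Hs + alpha * Hd
        r = r - alpha * Hd
        rr_new = float(r @ r)
        d = r + (rr_new / rr) * d
        rr = rr_new
    return s, Hs, False


def _boundary_step(s: np.ndarray, d: np.ndarray, delta: float) -> float:
    """Positive τ with ‖s + τ d‖ = delta."""
    sd = float(s @ d)
    dd = float(d @ d)
    ss = float(s @ s)
    disc = sd**2 + dd * (delta**2 - ss)
    return (-sd + np.sqrt(max(disc, 0.0))) / dd


def fit_primal_tron(
    Phi: np.ndarray,
    y: np.ndarray,
    lam: float,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> TronResult:
    """Minimise ½wᵀw + (λ/2)Σ log(1+exp(−yᵢ(wᵀφᵢ + b))) by trust-region Newton.

    Inner Newton systems are solved by truncated conjugate gradients with a
    forcing tolerance that tightens as the gradient shrinks, so early
    iterations take cheap approximate steps and late iterations essentially
    full Newton directions.  The trust radius shrinks when the
    actual-vs-predicted reduction ratio falls below 0.25 and expands above
    0.75.  The intercept b is an appended, unpenalised coordinate.
    Terminates when ‖g‖ ≤ tol·max(1, ‖g₀‖).
    """
    Phi = np.asarray(Phi, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = Phi.shape
    if (y > 0).all() or (y < 0).all():
        raise ValueError("both classes must be present")

    def objective(theta: np.ndarray) -> float:
        w, b = theta[:p], theta[p]
        f = Phi @ w + b
        return 0.5 * float(w @ w) + 0.5 * lam * float(np.logaddexp(0.0, -y * f).sum())

    def gradient(theta: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        w, b = theta[:p], theta[p]
        f = Phi @ w + b
        sig = expit(-y * f)
        dloss = -y * sig  # dℓ/df
        g = np.concatenate(
            [w + 0.5 * lam * (Phi.T @ dloss), [0.5 * lam * float(dloss.sum())]]
        )
        D = sig * (1.0 - sig)  # = p(1−p)
        return g, D

    theta = np.zeros(p + 1)
    g, D = gradient(theta)
    g0norm = float(np.linalg.norm(g))
    gnorm = g0norm
    grad_norms = [g0norm]
    delta = max(g0norm, 1.0)
    obj = objective(theta)
    it = 0
    attempts = 0
    while it < max_iter and attempts < 20 * max_iter:
        attempts += 1
        if gnorm <= tol * max(1.0, g0norm):
            return TronResult(
                w=theta[:p].copy(),
                b=float(theta[p]),
                objective=obj,
                grad_norms=grad_norms,
                n_iter=it,
            )
        Dcur = D

        def hess_vec(v: np.ndarray) -> np.ndarray:
            fv = Phi @ v[:p] + v[p]
            t = 0.5 * lam * Dcur * fv
            hv = np.concatenate([v[:p] + Phi.T @ t, [float(t.sum())]])
            return hv

        cg_tol = min(0.1, np.sqrt(gnorm / max(g0norm, 1e-300)))
        s, Hs, _ = _steihaug_cg(hess_vec, g, delta, cg_tol, max_cg=10 * (p + 1))
        predicted = -(float(g @ s) + 0.5 * float(s @ Hs))
        new_theta = theta + s
        new_obj = objective(new_theta)
        actual = obj - new_obj
        rho = actual / predicted if predicted > 0 else -1.0
        snorm = float(np.linalg.norm(s))
        if rho > 1e-4:
            theta, obj = new_theta, new_obj
            g, D = gradient(theta)
            gnorm = float(np.linalg.norm(g))
            grad_norms.append(gnorm)
            it += 1
        if rho < 0.25:
            delta = max(0.25 * min(delta, snorm), 1e-12)
        elif rho > 0.75 and snorm >= 0.99 * delta:
            delta = min(2.0 * delta, 1e12)
    raise ConvergenceError(
        f"trust-region Newton did not converge in {max_iter} iterations", gnorm
    )


# ---------------------------------------------------------------------------
# training / prediction
# ---------------------------------------------------------------------------


def fs_klr_train(
    X: np.ndarray,
    y: np.ndarray,
    hyper: Hyperparams,
    m: int,
    seed: int,
    outlier_min_frac: float = 0.001,
    eps: float = 1e-12,
    selector: Optional[FeatureSelector] = None,
    window: int = 7,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> FSKLRModel:
    """Train FS-KLR: prototypes → Nyström map → Φ → trust-region primal fit."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if (y > 0).all() or (y < 0).all():
        raise ValueError("both classes must be present")
    pvs = select_prototypes(X, m, seed=seed, outlier_min_frac=outlier_min_frac)
    nmap = build_nystrom_map(pvs, gamma=hyper.gamma, eps=eps)
    Phi = apply_nystrom_map(nmap, X)
    res = fit_primal_tron(Phi, y, lam=hyper.lam, tol=tol, max_iter=max_iter)
    return FSKLRModel(
        map=nmap,
        w=res.w,
        b=res.b,
        hyper=hyper,
        seed=seed,
        selector=selector,
        window=window,
    )


def decision_function(model: FSKLRModel, X_new: np.ndarray) -> np.ndarray:
    Phi = apply_nystrom_map(model.map, np.atleast_2d(np.asarray(X_new, dtype=float)))
    return Phi @ model.w + model.b


def fs_klr_predict(
    model: FSKLRModel, X_new: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Return (P(turn), labels); label is 't' iff P(turn) ≥ threshold."""
    f = decision_function(model, X_new)
    probs = expit(f)
    labels = np.where(probs >= model.hyper.threshold, "t", "n")
    return probs, labels


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_model(model: FSKLRModel, path) -> None:
    """Serialise the model to a JSON container (bit-reproducible prediction)."""
    d = {
        "gamma": model.hyper.gamma,
        "lambda": model.hyper.lam,
        "threshold": model.hyper.threshold,
        "seed": model.seed,
        "window": model.window,
        "pv_indices": model.map.prototypes.indices.tolist(),
        "pv_vectors": model.map.prototypes.vectors.tolist(),
        "eigvals": model.map.eigvals.tolist(),
        "eigvecs": model.map.eigvecs.tolist(),
        "eps": model.map.eps,
        "w": model.w.tolist(),
        "b": model.b,
        "selector": None
        if model.selector is None
        else {
            "ranked_indices": model.selector.ranked_indices.tolist(),
            "info_gain": model.selector.info_gain.tolist(),
            "chi_squared": model.selector.chi_squared.tolist(),
            "k": int(model.selector.k),
        },
    }
    Path(path).write_text(json.dumps(d))


def load_model(path) -> FSKLRModel:
    d = json.loads(Path(path).read_text())
    pvs = PrototypeSet(
        indices=np.array(d["pv_indices"], dtype=int),
        vectors=np.array(d["pv_vectors"], dtype=float),
        m=len(d["pv_indices"]),
    )
    nmap = NystromMap(
        prototypes=pvs,
        gamma=float(d["gamma"]),
        eigvals=np.array(d["eigvals"], dtype=float),
        eigvecs=np.array(d["eigvecs"], dtype=float),
        p=len(d["eigvals"]),
        eps=float(d["eps"]),
    )
    selector = None
    if d["selector"] is not None:
        selector = FeatureSelector(
            ranked_indices=np.array(d["selector"]["ranked_indices"], dtype=int),
            info_gain=np.array(d["selector"]["info_gain"], dtype=float),
            chi_squared=np.array(d["selector"]["chi_squared"], dtype=float),
            k=int(d["selector"]["k"]),
        )
    return FSKLRModel(
        map=nmap,
        w=np.array(d["w"], dtype=float),
        b=float(d["b"]),
        hyper=Hyperparams(
            lam=float(d["lambda"]),
            gamma=float(d["gamma"]),
            threshold=float(d["threshold"]),
        ),
        seed=int(d["seed"]),
        selector=selector,
        window=int(d["window"]),
    )
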