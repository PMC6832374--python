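"""Exact t-SNE for component topomap/spectra rows.

High-dimensional similarities are Gaussian conditionals P_{j|i} whose
per-point bandwidth sigma_i is calibrated by bisection so that
2^H(P_i) equals the requested perplexity; the joint distribution is the
symmetrized average p_ij = (P_{j|i} + P_{i|j}) / (2n).  Low-dimensional
similarities q_ij use a Student-t kernel with one degree of freedom, and
the map minimizes KL(P || Q) by gradient descent with momentum, adaptive
gains and early exaggeration.  The implementation is the exact O(n^2)
algorithm — the component matrices here are a few thousand rows at most.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .containers import AffinityModel, EmbeddingMap, FloatArray


def _sq_distances(X: FloatArray) -> FloatArray:
    return squareform(pdist(np.asarray(X, dtype=float), "sqeuclidean"))


def calibrate_affinities(X: FloatArray, perplexity: float = 30.0,
                         tol_rel: float = 1e-4, max_iter: int = 64,
                         ) -> AffinityModel:
    """Per-point bisection on the Gaussian bandwidth to hit the perplexity.

    The entropy H of each conditional row is driven to log2(perplexity)
    within ``tol_rel`` (relative, on the perplexity scale).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not (2 <= perplexity <= n - 1):
        raise ValueError("perplexity must lie in [2, n-1]")
    D = _sq_distances(X)
    off = ~np.eye(n, dtype=bool)
    if np.any((D + ~off) == 0):
        warnings.warn("duplicate points detected; adding tie-breaking jitter")
        rng = np.random.default_rng(0)
        D = D + rng.uniform(0, 1e-12, size=D.shape)
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)

    target = np.log2(perplexity)
    P = np.zeros((n, n))
    sigma = np.zeros(n)
    for i in range(n):
        d = D[i, off[i]]
        beta, lo, hi = 1.0, 0.0, np.inf  # beta = 1 / sigma_i^2
        for _ in range(max_iter):
            w = np.exp(-d * beta)
            w_sum = w.sum()
            if w_sum <= 0:
                h = 0.0
            else:
                p = w / w_sum
                nz = p > 0
                h = -np.sum(p[nz] * np.log2(p[nz]))
            if abs(2.0**h - perplexity) < tol_rel * perplexity:
                break
            if h > target:  # entropy too high -> narrower kernel
                lo = beta
                beta = beta * 2.0 if hi == np.inf else (lo + hi) / 2.0
            else:
                hi = beta
                beta = (lo + hi) / 2.0
            w = np.exp(-d * beta)
        P[i, off[i]] = w / w.sum()
        sigma[i] = 1.0 / np.sqrt(beta)
    P_joint = (P + P.T) / (2.0 * n)
    return AffinityModel(P_conditional=P, P_joint=P_joint, sigma=sigma,
                         perplexity=perplexity)


def _student_t_Q(Y: FloatArray) -> tuple[FloatArray, FloatArray]:
    """Student-t (1 dof) joint distribution Q and the kernel numerators."""
    num = 1.0 / (1.0 + _sq_distances(Y))
    np.fill_diagonal(num, 0.0)
    Q = num / num.sum()
    return Q, num


def kl_divergence(P_joint: FloatArray, Y: FloatArray) -> float:
    """KL(P || Q) of the joint affinities against the Student-t map kernel."""
    Q, _ = _student_t_Q(np.asarray(Y, dtype=float))
    P = np.asarray(P_joint, dtype=float)
    mask = P > 0
    return float(np.sum(P[mask] * np.log(P[mask] / np.maximum(Q[mask], 1e-300))))


def kl_gradient(P_joint: FloatArray, Y: FloatArray) -> FloatArray:
    """Analytic gradient 4 * sum_j (p_ij - q_ij)(y_i - y_j) / (1 + ||y_i-y_j||^2)."""
    Y = np.asarray(Y, dtype=float)
    Q, num = _student_t_Q(Y)
    PQd = (P_joint - Q) * num
    return 4.0 * ((np.diag(PQd.sum(axis=1)) - PQd) @ Y)


def tsne_embed(X: FloatArray, dim: int = 2, perplexity: float = 30.0,
               seed: int = 0, iters: int = 1000,
               learning_rate: float | str = "auto",
               early_exaggeration: float = 12.0, exaggeration_iters: int = 250,
               momentum_switch: int = 250, init: str = "random",
               ) -> EmbeddingMap:
    """Gradient-descent t-SNE map in 2 or 3 dimensions.

    Schedule: seeded Gaussian init (sigma 1e-4; ``init="pca"`` available),
    early exaggeration x``early_exaggeration`` for the first
    ``exaggeration_iters`` iterations, momentum 0.5 switching to 0.8, and
    adaptive per-coordinate gains.  ``learning_rate="auto"`` uses
    max(n / early_exaggeration, 50), which keeps small maps from
    over-expanding while matching the classical eta=200 regime at a few
    thousand points.  The KL divergence (against the unexaggerated P) is
    recorded every iteration.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if dim not in (2, 3):
        raise ValueError("dim must be 2 or 3")
    if n < 5 * perplexity:
        warnings.warn("fewer than 5*perplexity points; embedding may be unstable")
    aff = calibrate_affinities(X, perplexity)
    P = aff.P_joint
    if learning_rate == "auto":
        learning_rate = max(n / early_exaggeration, 50.0)

    rng = np.random.default_rng(seed)
    if isinstance(init, np.ndarray):
        Y = np.array(init, dtype=float)
        if Y.shape != (n, dim):
            raise ValueError("explicit init must have shape (n, dim)")
    elif init == "pca":
        Xc = X - X.mean(axis=0)
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
        Y = Xc @ Vt[:dim].T
        Y = Y / max(Y[:, 0].std(), 1e-12) * 1e-4
    else:
        Y = rng.normal(scale=1e-4, size=(n, dim))

    update = np.zeros_like(Y)
    gains = np.ones_like(Y)
    kl_trace = np.empty(iters)
    for it in range(iters):
        exag = early_exaggeration if it < exaggeration_iters else 1.0
        grad = kl_gradient(exag * P if exag != 1.0 else P, Y)
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError(f"non-finite t-SNE gradient at iteration {it}")
        momentum = 0.5 if it < momentum_switch else 0.8
        same_sign = np.sign(grad) == np.sign(update)
        gains = np.where(same_sign, gains * 0.8, gains + 0.2)
        gains = np.maximum(gains, 0.01)
        update = momentum * update - learning_rate * gains * grad
        Y = Y + update
        Y = Y - Y.mean(axis=0)
        kl_trace[it] = kl_divergence(P, Y)
    return EmbeddingMap(Y=Y, kl_trace=kl_trace, perplexity=perplexity,
                        seed=seed,
                        params={"learning_rate": learning_rate,
                                "momentum": (0.5, 0.8),
                                "momentum_switch": momentum_switch,
                                "early_exaggeration": early_exaggeration,
                                "exaggeration_iters": exaggeration_iters,
                                "iters": iters,
                                "init": "explicit" if isinstance(init, np.ndarray) else init})
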