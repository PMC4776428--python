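"""Curvilinear component analysis: 2-D projection of the source bank.

CCA places one 2-D point per bank column and iteratively moves points so that
output Euclidean distances match the input dissimilarities, but only pairs
whose *output* distance falls below an annealed neighbourhood radius lambda
are corrected.  Large distances are therefore allowed to deviate while the
local cluster geometry is preserved, which is what the cluster-quality index
needs.

Coordinates are initialized from classical metric scaling of the
dissimilarity matrix (Torgerson double-centering), which removes most seed
sensitivity; pure random initialization is available by flag.  The refinement
schedule anneals both lambda (from max(D) down to 1 % of it) and the learning
rate (0.5 down to 0.01) geometrically over 50 sweeps of the point set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

logger = logging.getLogger("stabica.projection")

__all__ = ["Projection2D", "classical_mds", "cca_project", "projection_stress"]


@dataclass
class Projection2D:
    """2-D coordinates per bank column plus the distance-preservation objective.

    ``stress`` is the CCA objective at the final neighbourhood radius: only
    pairs whose output distance falls within the radius are penalized, which
    is the local-distance emphasis that distinguishes CCA from classical
    scaling.  ``stress_history`` holds the per-epoch objective at the then
    current radius.
    """

    coords: np.ndarray
    stress: float
    seed: int
    stress_history: np.ndarray = field(default_factory=lambda: np.empty(0))


def projection_stress(coords: np.ndarray, D: np.ndarray, radius: float | None = None) -> float:
    """CCA distance-preservation stress: sum over pairs of (d - d')^2 F(d').

    ``radius=None`` weights every pair (F = 1, the raw stress); otherwise
    F(d') = 1 if the output distance d' <= radius else 0.
    """
    d_out = pdist(coords)
    iu = np.triu_indices(D.shape[0], k=1)
    sq = (D[iu] - d_out) ** 2
    if radius is not None:
        sq = sq[d_out <= radius]
    return float(np.sum(sq))


def classical_mds(D: np.ndarray, ndim: int = 2) -> np.ndarray:
    """Torgerson metric scaling of a dissimilarity matrix.

    Eigenvector signs are fixed (largest-magnitude entry positive) so the
    embedding is deterministic.
    """
    D = np.asarray(D, float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1][:ndim]
    lam = np.clip(eigval[order], 0.0, None)
    V = eigvec[:, order]
    for j in range(V.shape[1]):
        peak = np.argmax(np.abs(V[:, j]))
        if V[peak, j] < 0:
            V[:, j] *= -1.0
    return V * np.sqrt(lam)


def cca_project(
    D: np.ndarray,
    epochs: int = 50,
    seed: int = 0,
    init: str = "mds",
    lr0: float = 0.5,
    lr_final: float = 0.01,
    lambda_final_frac: float = 0.01,
) -> Projection2D:
    """Project a dissimilarity matrix onto 2-D by curvilinear component analysis.

    One epoch visits every point once in random order as the pivot; all other
    points within the current radius lambda of the pivot (in output space) are
    pulled toward / pushed from it so that their output distance approaches
    the input dissimilarity.  Deterministic given ``seed``.
    """
    D = np.asarray(D, float)
    if not np.all(np.isfinite(D)):
        raise ValueError("dissimilarity matrix contains non-finite entries")
    n = D.shape[0]
    rng = np.random.default_rng(seed)

    if init == "mds":
        X = classical_mds(D, 2).copy()
    elif init == "random":
        scale = max(D.max(), 1e-12)
        X = rng.standard_normal((n, 2)) * scale / 2.0
    else:
        raise ValueError(f"unknown init {init!r}")

    lam0 = float(D.max())
    if lam0 <= 0.0 or epochs == 0 or n < 3:
        return Projection2D(X, projection_stress(X, D, lambda_final_frac * lam0 or None), seed)
    lam_final = lambda_final_frac * lam0

    total = epochs * n
    t = 0
    history = np.empty(epochs)
    for e in range(epochs):
        for i in rng.permutation(n):
            frac = t / max(total - 1, 1)
            lam = lam0 * (lam_final / lam0) ** frac
            alpha = lr0 * (lr_final / lr0) ** frac
            diff = X - X[i]
            dist = np.hypot(diff[:, 0], diff[:, 1])
            mask = (dist <= lam) & (dist > 0.0)
            mask[i] = False
            if np.any(mask):
                factor = alpha * (D[i, mask] - dist[mask]) / dist[mask]
                X[mask] += factor[:, None] * diff[mask]
            t += 1
        history[e] = projection_stress(X, D, lam)
    logger.debug("cca_project: stress %.4g -> %.4g over %d epochs",
                 history[0], history[-1], epochs)
    return Projection2D(X, projection_stress(X, D, lam_final), seed, history)
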