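"""Centering, PCA denoising, the FastICA engine and multi-run source banks.

The consensus procedure rests on running FastICA many times from random
initial demixing matrices.  Each run estimates k sources from the PCA-denoised
score matrix X_d; all runs are pooled column-wise into a *source bank* that
downstream clustering condenses into representative components.

FastICA itself (logcosh contrast, deflation and parallel extraction) is the
standard fixed-point algorithm; scikit-learn provides the iteration.  This
module owns everything around it: whitening is recomputed here from X_d by
SVD so that bootstrap datasets re-entering the engine are whitened on their
own scale, sources are rescaled to exact unit sample variance, and a
deterministic sign convention (non-negative skewness) is applied so that the
sign indeterminacy of ICA cannot split clusters or flip reported components.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .data_io import IntensityMatrix, derive_seed

logger = logging.getLogger("stabica.decomposition")

__all__ = [
    "DenoiseResult",
    "ICARun",
    "SourceBank",
    "DimensionalityError",
    "center",
    "pca_denoise",
    "fastica_run",
    "generate_source_bank",
]

#: logcosh steepness; the contrast is G(u) = log cosh(alpha * u) / alpha
LOGCOSH_ALPHA = 1.0
#: fixed-point stationarity tolerance
FASTICA_TOL = 1e-4
#: iteration cap per run
FASTICA_MAX_ITER = 200


class DimensionalityError(ValueError):
    """Requested more sources than the data can support (k > n - 1)."""


@dataclass
class DenoiseResult:
    """Output of PCA denoising.

    ``X_d = X_centered @ K`` where K holds the first k principal-axis
    loadings (orthonormal columns) and k is the smallest dimension whose
    cumulative explained variance reaches the threshold.
    """

    X_centered: np.ndarray
    X_d: np.ndarray
    K: np.ndarray
    explained: np.ndarray  # per-PC variance fractions, length k
    k: int

    @property
    def cumulative_explained(self) -> float:
        return float(self.explained.sum())


@dataclass
class ICARun:
    """One FastICA run: unit-variance sources and the demixing operator.

    ``S_hat = Z @ W_hat.T`` where Z is the whitened score matrix; rows of
    W_hat are orthonormal in the whitened space.  ``whitening`` maps the
    centered X_d into Z (``Z = (X_d - mean) @ whitening``).
    """

    S_hat: np.ndarray
    W_hat: np.ndarray
    method: str
    W0_seed: int | None
    converged: bool
    n_iter: int
    whitening: np.ndarray


@dataclass
class SourceBank:
    """All k*m estimated sources from m FastICA runs, pooled column-wise."""

    S: np.ndarray            # n x (k*m)
    run_index: np.ndarray    # bank column -> run number
    method: np.ndarray       # bank column -> "deflation" | "parallel"
    converged: np.ndarray    # bank column -> bool of its run
    W_rows: np.ndarray       # (k*m) x k demixing rows (whitened space)
    whitening: np.ndarray    # shared k x k whitening operator for X_d
    k: int
    m: int

    def __post_init__(self) -> None:
        if self.S.shape[1] != self.k * self.m:
            raise ValueError("bank must hold exactly k*m columns")


def center(X: IntensityMatrix | np.ndarray) -> np.ndarray:
    """Subtract the column means; every feature mean becomes 0."""
    values = X.values if isinstance(X, IntensityMatrix) else np.asarray(X, float)
    if values.shape[0] < 2:
        raise ValueError("centering needs at least 2 samples")
    return values - values.mean(axis=0, keepdims=True)


def pca_denoise(X_centered: np.ndarray, variance_threshold: float = 0.90) -> DenoiseResult:
    """Project onto the smallest PC subspace explaining >= the threshold.

    The decomposition is a thin SVD of the centered matrix; principal
    components are ordered by decreasing variance and k is minimal with
    cumulative explained variance >= ``variance_threshold``.
    """
    if not 0.0 < variance_threshold <= 1.0:
        raise ValueError("variance_threshold must lie in (0, 1]")
    Xc = np.asarray(X_centered, float)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 0.0:
        raise ValueError("zero matrix: no variance to denoise")
    frac = var / total
    cum = np.cumsum(frac)
    # minimal k with cumulative >= threshold (tiny slack for float round-off)
    k = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    K = Vt[:k].T
    X_d = Xc @ K
    logger.debug("pca_denoise: k=%d, cumulative R^2=%.4f", k, cum[k - 1])
    return DenoiseResult(Xc, X_d, K, frac[:k].copy(), k)


def _whiten(X_d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Whiten the score matrix: returns (Z, whitening) with cov(Z) = I exactly."""
    Xc = X_d - X_d.mean(axis=0, keepdims=True)
    n, k = Xc.shape
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if s[-1] <= 1e-12 * s[0]:
        raise DimensionalityError(
            "score matrix is rank deficient; reduce the number of components"
        )
    Z = U * math.sqrt(n - 1)
    whitening = Vt.T * (math.sqrt(n - 1) / s)
    return Z, whitening


def _sign_fix(S: np.ndarray, W: np.ndarray | None = None) -> None:
    """Flip columns of S (and matching rows of W) so skewness is non-negative.

    Near-symmetric columns (|skewness| ~ 0) fall back to making the entry of
    largest magnitude positive, which keeps the convention deterministic.
    """
    n = S.shape[0]
    Sc = S - S.mean(axis=0, keepdims=True)
    m2 = (Sc**2).mean(axis=0)
    m3 = (Sc**3).mean(axis=0)
    skew = m3 / np.maximum(m2, 1e-300) ** 1.5
    for j in range(S.shape[1]):
        if abs(skew[j]) > 1e-8:
            flip = skew[j] < 0
        else:
            peak = np.argmax(np.abs(S[:, j]))
            flip = S[peak, j] < 0
        if flip:
            S[:, j] *= -1.0
            if W is not None:
                W[j, :] *= -1.0


def fastica_run(
    X_d: np.ndarray,
    method: str,
    W0: np.ndarray,
    tol: float = FASTICA_TOL,
    max_iter: int = FASTICA_MAX_ITER,
    W0_seed: int | None = None,
) -> ICARun:
    """One FastICA run on the denoised score matrix.

    Parameters
    ----------
    X_d : ndarray of shape (n, k)
        PCA score matrix; it is re-whitened here before iteration.
    method : {"deflation", "parallel"}
        Deflation extracts one source at a time; parallel extracts all
        simultaneously under a symmetric orthonormality constraint.
    W0 : ndarray of shape (k, k)
        Initial demixing matrix, the stochastic element of the algorithm.

    The run is deterministic given (X_d, method, W0).  Non-convergence within
    ``max_iter`` is reported via ``converged=False`` rather than raised.
    """
    if method not in ("deflation", "parallel"):
        raise ValueError(f"unknown extraction method {method!r}")
    X_d = np.asarray(X_d, float)
    n, k = X_d.shape
    if k > n - 1:
        raise DimensionalityError(f"cannot extract k={k} sources from n={n} samples")
    W0 = np.asarray(W0, float)
    if W0.shape != (k, k):
        raise ValueError(f"W0 must be {k}x{k}, got {W0.shape}")
    if np.linalg.matrix_rank(W0) < k:
        logger.warning("singular W0; re-orthonormalizing via QR")
        W0 = np.linalg.qr(W0 + 1e-8 * np.eye(k))[0]

    Z, whitening = _whiten(X_d)
    ica = FastICA(
        algorithm=method,
        whiten=False,
        fun="logcosh",
        fun_args={"alpha": LOGCOSH_ALPHA},
        w_init=W0,
        tol=tol,
        max_iter=max_iter,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        S = ica.fit_transform(Z)
    W = np.array(ica.components_)
    n_iter = int(ica.n_iter_)
    converged = n_iter < max_iter

    # exact unit sample variance per source (W rows rescaled to stay consistent)
    sd = S.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        raise DimensionalityError("FastICA produced a constant source")
    S = S / sd
    W = W / sd[:, None]
    _sign_fix(S, W)
    return ICARun(S, W, method, W0_seed, converged, n_iter, whitening)


def generate_source_bank(
    X_d: np.ndarray,
    m: int,
    master_seed: int,
    k: int | None = None,
) -> SourceBank:
    """Pool k sources from each of m FastICA restarts into one bank.

    The first ceil(m/2) runs use deflation and the rest parallel extraction;
    each run's W0 has i.i.d. standard-normal entries drawn from a seed derived
    from ``master_seed`` and the run index, so identical seeds give
    bit-identical banks.
    """
    if m < 2:
        raise ValueError("need at least m=2 runs (one per extraction method)")
    X_d = np.asarray(X_d, float)
    n, k_data = X_d.shape
    if k is None:
        k = k_data
    elif k != k_data:
        raise ValueError(f"k={k} does not match score matrix dimension {k_data}")
    n_deflation = math.ceil(m / 2)

    S_cols = np.empty((n, k * m))
    run_index = np.empty(k * m, dtype=int)
    methods = np.empty(k * m, dtype=object)
    converged = np.empty(k * m, dtype=bool)
    W_rows = np.empty((k * m, k))
    whitening = None
    n_failed = 0
    for i in range(m):
        method = "deflation" if i < n_deflation else "parallel"
        seed_i = derive_seed(master_seed, "fastica-w0", i)
        W0 = np.random.default_rng(seed_i).standard_normal((k, k))
        try:
            run = fastica_run(X_d, method, W0, W0_seed=seed_i)
        except DimensionalityError as exc:
            raise DimensionalityError(f"run {i} ({method}): {exc}") from exc
        sl = slice(i * k, (i + 1) * k)
        S_cols[:, sl] = run.S_hat
        W_rows[sl] = run.W_hat
        run_index[sl] = i
        methods[sl] = method
        converged[sl] = run.converged
        if not run.converged:
            n_failed += 1
        whitening = run.whitening
    if n_failed:
        logger.info("source bank: %d of %d runs hit the iteration cap", n_failed, m)
    return SourceBank(S_cols, run_index, methods, converged, W_rows, whitening, k, m)
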