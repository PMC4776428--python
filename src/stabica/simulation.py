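"""Simulated data in the style of real non-targeted metabolomics matrices.

Two generators live here.  ``simulate_sx`` follows the study design used to
validate the consensus procedure: starting from a real (or fixture) matrix X,
a multivariate Gaussian background N is drawn with the sample covariance of
the centered X, a signal matrix RX is rebuilt from a chosen set of
non-Gaussian principal components, and the simulated matrix is
``SX = I * N + RX`` where the scalar I sets the noise level.  Recovering the
chosen PCs from SX at increasing I probes how the method degrades with noise.

``make_fixture`` is self-contained: q unit-variance non-Gaussian sources
(super- and sub-Gaussian kinds) are linearly mixed into p features and buried
in Gaussian noise with a realistic low-rank-plus-floor covariance, with the
ground truth returned for recovery scoring.  It emulates the few-samples /
many-features shape of aligned mass-spectral matrices.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import kurtosis as _scipy_kurtosis

from .data_io import IntensityMatrix, derive_seed
from .decomposition import center

logger = logging.getLogger("stabica.simulation")

__all__ = ["SimulationSpec", "simulate_sx", "gaussian_background", "make_fixture"]

#: two-Gaussian mixture separation (mean over component sd) for the
#: sub-Gaussian "bimodal" source kind; gives excess kurtosis ~ -1.49
BIMODAL_SEPARATION = 2.5


@dataclass
class SimulationSpec:
    """Recipe for one simulated matrix SX = I * N + RX.

    ``pc_indices`` are 1-based principal-component numbers (PC1 = largest
    variance) whose scores/loadings rebuild the signal matrix RX; they should
    be non-Gaussian (|excess kurtosis| > 1), and a warning is emitted when a
    chosen PC is not.
    """

    pc_indices: tuple[int, ...]
    noise_level: float
    seed: int = 0

    def __post_init__(self) -> None:
        self.pc_indices = tuple(int(i) for i in self.pc_indices)
        if len(self.pc_indices) == 0:
            raise ValueError("pc_indices must be non-empty")
        if min(self.pc_indices) < 1:
            raise ValueError("pc_indices are 1-based")
        if self.noise_level < 0:
            raise ValueError("noise_level must be non-negative")


def gaussian_background(X: IntensityMatrix | np.ndarray, seed: int) -> np.ndarray:
    """Zero-mean Gaussian noise with the sample covariance of the centered X.

    The covariance factor comes straight from the thin SVD of the centered
    matrix (equivalently an eigendecomposition of the sample covariance with
    negative eigenvalues impossible by construction), which handles the
    rank-deficient p >> n case exactly.
    """
    Xc = center(X)
    n = Xc.shape[0]
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    keep = s > 1e-12 * s[0]
    factor = Vt[keep].T * (s[keep] / math.sqrt(n - 1))  # p x r
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n, factor.shape[1])) @ factor.T


def simulate_sx(X: IntensityMatrix, spec: SimulationSpec) -> IntensityMatrix:
    """Simulated matrix SX = noise_level * N + RX (same shape as X).

    RX is the linear reconstruction ``scores @ loadings.T`` restricted to the
    chosen principal components of the centered X.
    """
    Xc = center(X)
    n = Xc.shape[0]
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    idx = np.array([i - 1 for i in spec.pc_indices])
    if idx.max() >= s.size:
        raise ValueError(
            f"pc_indices go up to PC{idx.max() + 1} but only {s.size} PCs exist"
        )
    scores = U[:, idx] * s[idx]
    for pc, col in zip(spec.pc_indices, scores.T):
        k = float(_scipy_kurtosis(col, fisher=True, bias=True))
        if abs(k) <= 1.0:
            logger.warning(
                "PC%d has excess kurtosis %.2f (|k| <= 1): a near-Gaussian "
                "component makes a weak recovery target", pc, k,
            )
    RX = scores @ Vt[idx]
    N = gaussian_background(X, derive_seed(spec.seed, "sx-background"))
    SX = spec.noise_level * N + RX
    return IntensityMatrix(SX, list(X.sample_ids), list(X.feature_ids))


def _draw_source(kind: str, n: int, rng: np.random.Generator) -> np.ndarray:
    if kind == "laplace":
        return rng.laplace(0.0, 1.0 / math.sqrt(2.0), n)
    if kind == "uniform":
        return rng.uniform(-math.sqrt(3.0), math.sqrt(3.0), n)
    if kind == "bimodal":
        # symmetric two-Gaussian mixture, unit variance, excess kurtosis ~ -1.5
        s = 1.0 / math.sqrt(1.0 + BIMODAL_SEPARATION**2)
        mu = BIMODAL_SEPARATION * s
        signs = rng.choice([-1.0, 1.0], n)
        return signs * mu + rng.normal(0.0, s, n)
    raise ValueError(f"unknown source kind {kind!r}")


def make_fixture(
    n: int,
    p: int,
    q: int,
    source_kinds: tuple[str, ...] = ("laplace", "uniform", "bimodal"),
    snr: float = 10.0,
    seed: int = 0,
) -> tuple[IntensityMatrix, np.ndarray]:
    """Planted-source fixture: q non-Gaussian sources mixed into p features.

    Parameters
    ----------
    n, p, q : int
        Samples, features and planted sources (q < n, q <= p).
    source_kinds : tuple of {"laplace", "uniform", "bimodal"}
        Cycled to supply q source distributions; all are standardized to
        exactly zero mean and unit sample variance.
    snr : float
        Total signal variance over total noise variance.  ``math.inf`` gives
        a noiseless, rank-q matrix.  Low values (< 1) push the planted
        components into the middle of the PC spectrum, emulating real
        matrices where the interesting structure is not the top PC.
    seed : int
        Same seed, identical fixture.

    Returns
    -------
    (IntensityMatrix, ndarray)
        The mixed matrix and the n x q ground-truth sources.

    The noise is i.i.d. Gaussian (white), so the planted sources stay the
    exact optima of an independence search; covariance-matched Gaussian
    backgrounds — the realistic emulation of aligned mass-spectral
    matrices — are the job of :func:`simulate_sx`.
    """
    if q >= n:
        raise ValueError(f"need q < n, got q={q}, n={n}")
    if q > p:
        raise ValueError(f"need q <= p, got q={q}, p={p}")
    rng = np.random.default_rng(seed)
    kinds = [source_kinds[i % len(source_kinds)] for i in range(q)]
    S = np.column_stack([_draw_source(kind, n, rng) for kind in kinds])
    S = S - S.mean(axis=0)
    S = S / S.std(axis=0, ddof=1)

    A_mix = rng.standard_normal((q, p))
    M = S @ A_mix
    if math.isinf(snr):
        X = M
    else:
        if snr <= 0:
            raise ValueError("snr must be positive")
        E = rng.standard_normal((n, p))
        signal_var = M.var(axis=0, ddof=1).sum()
        noise_var = E.var(axis=0, ddof=1).sum()
        E *= math.sqrt(signal_var / (snr * noise_var))
        X = M + E

    fixture = IntensityMatrix(
        X,
        [f"sample{i:03d}" for i in range(n)],
        [f"mz{j:05d}" for j in range(p)],
    )
    return fixture, S
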