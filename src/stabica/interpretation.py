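"""Kurtosis diagnostics, the loadings matrix A, and top-loading extraction.

ICA only has something to find when the data carry non-Gaussian structure, so
features are screened by Fisher excess kurtosis (super-Gaussian above +1,
sub-Gaussian below -1, near-Gaussian otherwise).

Once centrotypes are fixed, the contribution of every feature to every
component is read off the weights matrix A, the right pseudo-inverse of the
feature-to-component operator G (components = X_centered @ G.T), i.e.
A = G.T (G G.T)^-1 so that G A = I on the component space.  Features with the
largest positive / negative / absolute loadings on a component are the mass
signals that drive it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import kurtosis as _scipy_kurtosis

from .clustering import CentrotypeSet
from .data_io import IntensityMatrix
from .decomposition import DenoiseResult, SourceBank

logger = logging.getLogger("stabica.interpretation")

__all__ = [
    "WeightsMatrix",
    "FeatureDiagnostics",
    "excess_kurtosis",
    "diagnose_features",
    "component_operator",
    "weights_matrix",
    "top_loadings",
]

SUPER_GAUSSIAN_CUTOFF = 1.0
SUB_GAUSSIAN_CUTOFF = -1.0


@dataclass
class WeightsMatrix:
    """Feature loadings A (p x c) with aligned feature identifiers."""

    A: np.ndarray
    feature_ids: list[str]


@dataclass
class FeatureDiagnostics:
    """Per-feature excess kurtosis and the non-Gaussianity census."""

    kurtosis: np.ndarray
    n_super: int
    n_sub: int
    n_near: int

    @property
    def fraction_non_gaussian(self) -> float:
        total = self.kurtosis.size
        return (self.n_super + self.n_sub) / total if total else 0.0


def excess_kurtosis(v: np.ndarray) -> float:
    """Fisher excess kurtosis (fourth standardized moment minus 3).

    No small-sample bias correction is applied, so a Gaussian sample gives a
    value near 0, a uniform one -6/5, a Laplace one +3.
    """
    v = np.asarray(v, float)
    if v.size < 4:
        raise ValueError("kurtosis needs at least 4 observations")
    if np.ptp(v) == 0:
        raise ValueError("kurtosis of a constant vector is undefined")
    return float(_scipy_kurtosis(v, fisher=True, bias=True))


def diagnose_features(X: IntensityMatrix | np.ndarray) -> FeatureDiagnostics:
    """Classify every feature by excess kurtosis at the +1 / -1 cutoffs.

    Emits a warning when fewer than 5 % of features are non-Gaussian, in which
    case an independence-seeking decomposition has little to work with.
    """
    values = X.values if isinstance(X, IntensityMatrix) else np.asarray(X, float)
    if values.ndim == 1:
        values = values[:, None]
    kurt = _scipy_kurtosis(values, axis=0, fisher=True, bias=True)
    kurt = np.asarray(kurt, float)
    n_super = int((kurt > SUPER_GAUSSIAN_CUTOFF).sum())
    n_sub = int((kurt < SUB_GAUSSIAN_CUTOFF).sum())
    n_near = int(kurt.size - n_super - n_sub)
    diag = FeatureDiagnostics(kurt, n_super, n_sub, n_near)
    if diag.fraction_non_gaussian < 0.05:
        logger.warning(
            "only %.1f%% of features are non-Gaussian (|excess kurtosis| > 1); "
            "ICA is unlikely to be informative on this matrix",
            100 * diag.fraction_non_gaussian,
        )
    return diag


def component_operator(
    denoise: DenoiseResult,
    bank: SourceBank,
    centrotypes: CentrotypeSet,
) -> np.ndarray:
    """Assemble the c x p feature-to-component operator of the centrotypes.

    Each centrotype is an actual FastICA output, so its exact demixing row
    exists in the bank; chaining the PCA loadings K, the whitening operator
    and those rows gives G with ``OC = X_centered @ G.T``.
    """
    W_sel = bank.W_rows[centrotypes.member_column]      # c x k
    return (denoise.K @ bank.whitening @ W_sel.T).T      # c x p


def weights_matrix(
    G: np.ndarray,
    feature_ids: list[str] | None = None,
    rcond: float = 1e-10,
) -> WeightsMatrix:
    """Right pseudo-inverse of the feature-to-component operator.

    ``A = G.T @ (G @ G.T)^-1`` (p x c), so G @ A is the identity on the
    component space and ``S @ A.T`` reconstructs the centered data up to the
    PCA truncation error.
    """
    G = np.asarray(G, float)
    gram = G @ G.T
    cond = np.linalg.cond(gram)
    if not np.isfinite(cond) or cond > 1.0 / rcond:
        # name the most redundant component for the error message
        c = G.shape[0]
        norms = np.linalg.norm(G, axis=1)
        j = int(np.argmin(norms)) if np.any(norms == 0) else int(np.argmax(np.abs(
            gram - np.diag(np.diag(gram))).sum(axis=1)))
        raise np.linalg.LinAlgError(
            f"feature-to-component operator is rank deficient (component {j}); "
            "centrotypes are linearly dependent"
        )
    A = G.T @ np.linalg.inv(gram)
    if feature_ids is None:
        feature_ids = [str(i) for i in range(G.shape[1])]
    return WeightsMatrix(A, list(feature_ids))


def top_loadings(
    weights: WeightsMatrix | np.ndarray,
    centrotype_index: int,
    n_top: int = 100,
    sign: str = "negative",
    feature_ids: list[str] | None = None,
) -> pd.DataFrame:
    """The n_top features ranked by loading on one centrotype.

    ``sign="negative"`` ranks by most-negative loading first (the convention
    for extracting the masses elevated on the negative side of a component),
    ``"positive"`` by most-positive first, ``"absolute"`` by magnitude.
    Ties keep the original feature order.
    """
    if isinstance(weights, WeightsMatrix):
        A, ids = weights.A, weights.feature_ids
    else:
        A = np.asarray(weights, float)
        ids = feature_ids or [str(i) for i in range(A.shape[0])]
    if n_top > A.shape[0]:
        raise ValueError(f"n_top={n_top} exceeds the number of features {A.shape[0]}")
    col = A[:, centrotype_index]
    if sign == "negative":
        order = np.argsort(col, kind="stable")
    elif sign == "positive":
        order = np.argsort(-col, kind="stable")
    elif sign == "absolute":
        order = np.argsort(-np.abs(col), kind="stable")
    else:
        raise ValueError(f"unknown sign criterion {sign!r}")
    top = order[:n_top]
    return pd.DataFrame(
        {
            "feature_id": [ids[i] for i in top],
            "loading": col[top],
            "rank": np.arange(1, len(top) + 1),
        }
    )
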