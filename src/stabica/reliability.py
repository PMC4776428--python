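"""Bootstrap-based statistical reliability of consensus components.

A centrotype that reflects genuine structure should be recoverable by FastICA
from slightly perturbed data, whereas one driven by a few particular samples
should not.  B bootstrap datasets are built by overwriting ``n_replace`` rows
of X with rows resampled (with replacement) from the remaining rows; each
dataset is centered and PCA-denoised on its own, and FastICA is run once per
dataset from a fixed initial demixing matrix W0 (half the datasets with
parallel, half with deflation extraction).

The similarity score of centrotype OC_a is

    H_a = sum over b of  max_j |Spearman rho(OC_a, S_bj)|

so H is bounded by [0, B].  Because H depends on W0, scoring is repeated with
``n_W0`` randomized initial matrices on the *same* bootstrap datasets; the
median H-hat of the resulting distribution is the component's reliability
score and defines the interpretation order (descending H-hat).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import kurtosis, rankdata

from .clustering import CentrotypeSet, cut_dendrogram, extract_centrotypes
from .data_io import IntensityMatrix, RunConfig, derive_seed
from .decomposition import SourceBank, center, fastica_run, pca_denoise

logger = logging.getLogger("stabica.reliability")

__all__ = [
    "BootstrapDataset",
    "ReliabilityReport",
    "make_bootstrap_datasets",
    "bootstrap_source_sets",
    "score_H",
    "score_H_distribution",
    "monitor_scores_vs_c",
]


@dataclass
class BootstrapDataset:
    """One resampled dataset: n_replace rows of X overwritten in place."""

    X_b: np.ndarray
    replaced_rows: np.ndarray  # positions overwritten
    source_rows: np.ndarray    # rows (from the remainder) that overwrote them


@dataclass
class ReliabilityReport:
    """Per-centrotype H distributions, median scores and interpretation order."""

    H_dist: np.ndarray    # c x n_W0
    H_hat: np.ndarray     # c medians
    kurtosis: np.ndarray  # excess kurtosis of each centrotype
    order: np.ndarray     # centrotype indices sorted by descending H_hat

    @property
    def iqr(self) -> np.ndarray:
        q75, q25 = np.percentile(self.H_dist, [75, 25], axis=1)
        return q75 - q25


def make_bootstrap_datasets(
    X: IntensityMatrix | np.ndarray,
    B: int,
    n_replace: int,
    seed: int,
) -> list[BootstrapDataset]:
    """Build B datasets, each with ``n_replace`` rows overwritten in place.

    Replaced positions are chosen uniformly without replacement; the
    overwriting rows are drawn uniformly *with* replacement from the rows that
    stay, so some samples get duplicated and others vanish while n and p are
    unchanged.
    """
    values = X.values if isinstance(X, IntensityMatrix) else np.asarray(X, float)
    n = values.shape[0]
    if not 0 <= n_replace < n:
        raise ValueError(f"n_replace={n_replace} must lie in [0, n={n})")
    datasets = []
    for b in range(B):
        rng = np.random.default_rng(derive_seed(seed, "bootstrap", b))
        replaced = np.sort(rng.choice(n, size=n_replace, replace=False))
        remaining = np.setdiff1d(np.arange(n), replaced)
        source = rng.choice(remaining, size=n_replace, replace=True) if n_replace else np.empty(0, int)
        X_b = values.copy()
        if n_replace:
            X_b[replaced] = values[source]
        datasets.append(BootstrapDataset(X_b, replaced, source))
    return datasets


def _adapt_w0(W0: np.ndarray, k: int) -> np.ndarray:
    """Truncate or pad W0 to k x k (identity completion for the new rows)."""
    k0 = W0.shape[0]
    if k == k0:
        return W0
    logger.debug("adapting W0 from %d to %d dimensions", k0, k)
    if k < k0:
        return W0[:k, :k].copy()
    out = np.eye(k)
    out[:k0, :k0] = W0
    return out


def _bootstrap_sources_for_w0(
    X_ds: list[np.ndarray],
    W0: np.ndarray,
    variance_threshold: float,
) -> list[np.ndarray]:
    """One FastICA run per denoised bootstrap dataset with a shared W0.

    The first half of the datasets uses parallel extraction, the second half
    deflation.
    """
    B = len(X_ds)
    half = B // 2
    sources = []
    for b, X_d in enumerate(X_ds):
        method = "parallel" if b < half or B == 1 else "deflation"
        k_b = X_d.shape[1]
        run = fastica_run(X_d, method, _adapt_w0(W0, k_b))
        sources.append(run.S_hat)
    return sources


def _score_against_sources(OC: np.ndarray, sources: list[np.ndarray]) -> np.ndarray:
    """H_a = sum over datasets of the best |Spearman rho| with any source."""
    n, c = OC.shape
    ranks_oc = rankdata(OC, axis=0)
    ranks_oc = (ranks_oc - ranks_oc.mean(axis=0)) / ranks_oc.std(axis=0, ddof=1)
    H = np.zeros(c)
    for S_b in sources:
        ranks_s = rankdata(S_b, axis=0)
        sd = ranks_s.std(axis=0, ddof=1)
        ranks_s = (ranks_s - ranks_s.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        rho = ranks_oc.T @ ranks_s / (n - 1)  # c x k_b
        H += np.abs(rho).max(axis=1)
    return H


def _denoise_datasets(
    datasets: list[BootstrapDataset], variance_threshold: float
) -> list[np.ndarray]:
    return [pca_denoise(center(d.X_b), variance_threshold).X_d for d in datasets]


def score_H(
    OC: CentrotypeSet | np.ndarray,
    datasets: list[BootstrapDataset],
    W0: np.ndarray,
    variance_threshold: float = 0.90,
) -> np.ndarray:
    """The similarity score H of every centrotype for one fixed W0.

    Each bootstrap dataset is centered and PCA-denoised independently to the
    variance threshold before its single FastICA run.
    """
    OC_mat = OC.OC if isinstance(OC, CentrotypeSet) else np.asarray(OC, float)
    X_ds = _denoise_datasets(datasets, variance_threshold)
    sources = _bootstrap_sources_for_w0(X_ds, W0, variance_threshold)
    return _score_against_sources(OC_mat, sources)


def bootstrap_source_sets(
    datasets: list[BootstrapDataset],
    n_W0: int,
    seed: int,
    variance_threshold: float = 0.90,
) -> list[list[np.ndarray]]:
    """Precompute bootstrap FastICA sources for every randomized W0.

    Returns ``sets[w][b]``: the estimated source matrix of dataset b under the
    w-th random initial demixing matrix.  The expensive B * n_W0 FastICA runs
    happen once here; scoring any centrotype set against them is then just
    rank correlations, which is what makes score-vs-cluster-number monitoring
    affordable.
    """
    X_ds = _denoise_datasets(datasets, variance_threshold)
    k_ref = max(X_d.shape[1] for X_d in X_ds)
    sets = []
    for w in range(n_W0):
        rng = np.random.default_rng(derive_seed(seed, "reliability-w0", w))
        W0 = rng.standard_normal((k_ref, k_ref))
        sets.append(_bootstrap_sources_for_w0(X_ds, W0, variance_threshold))
    return sets


def score_H_distribution(
    OC: CentrotypeSet | np.ndarray,
    datasets: list[BootstrapDataset],
    n_W0: int,
    seed: int,
    variance_threshold: float = 0.90,
    source_sets: list[list[np.ndarray]] | None = None,
) -> ReliabilityReport:
    """H distributions over randomized W0, median scores and ordering."""
    if n_W0 < 1:
        raise ValueError("n_W0 must be at least 1")
    OC_mat = OC.OC if isinstance(OC, CentrotypeSet) else np.asarray(OC, float)
    if source_sets is None:
        source_sets = bootstrap_source_sets(datasets, n_W0, seed, variance_threshold)
    H_dist = np.column_stack([_score_against_sources(OC_mat, s) for s in source_sets])
    H_hat = np.median(H_dist, axis=1)
    kurt = kurtosis(OC_mat, axis=0, fisher=True, bias=True)
    order = np.argsort(-H_hat, kind="stable")
    return ReliabilityReport(H_dist, H_hat, np.asarray(kurt), order)


def monitor_scores_vs_c(
    bank: SourceBank,
    D: np.ndarray,
    X: IntensityMatrix | np.ndarray,
    cluster_range: tuple[int, int],
    config: RunConfig,
    Z: np.ndarray | None = None,
) -> dict[int, np.ndarray]:
    """Median bootstrap scores of all centrotypes for each cluster number.

    The bootstrap datasets and their FastICA sources are fixed across the
    scan, so the map supports the second model-selection route: counting
    centrotypes whose H-hat exceeds a stability threshold as c varies.
    """
    from .clustering import hca_average_link  # local import avoids cycle at module load

    lo, hi = cluster_range
    if not 2 <= lo <= hi:
        raise ValueError(f"invalid cluster_range {cluster_range}")
    datasets = make_bootstrap_datasets(
        X, config.n_bootstrap, config.n_replace,
        derive_seed(config.master_seed, "bootstrap-data"),
    )
    source_sets = bootstrap_source_sets(
        datasets, config.n_inits,
        derive_seed(config.master_seed, "bootstrap-w0"),
        config.variance_threshold,
    )
    if Z is None:
        Z = hca_average_link(D)
    out: dict[int, np.ndarray] = {}
    for c in range(lo, hi + 1):
        part = cut_dendrogram(Z, c)
        oc = extract_centrotypes(bank, D, part)
        report = score_H_distribution(
            oc, datasets, config.n_inits, 0,
            config.variance_threshold, source_sets=source_sets,
        )
        out[c] = report.H_hat
    return out
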