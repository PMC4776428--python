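"""End-to-end consensus ICA pipeline on an intensity matrix.

Order of operations: prevalence filter -> centering -> PCA denoising ->
multi-run FastICA source bank -> Spearman dissimilarity -> 2-D CCA projection
-> cluster-number selection by the quality index (unless c is fixed) ->
centrotype extraction -> bootstrap reliability scoring and ordering ->
loadings matrix and top-loading features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import clustering, interpretation, projection, reliability
from .data_io import IntensityMatrix, RunConfig, derive_seed, prevalence_filter
from .decomposition import DenoiseResult, SourceBank, center, generate_source_bank, pca_denoise

logger = logging.getLogger("stabica.pipeline")

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Every intermediate and final artifact of one pipeline run."""

    X: IntensityMatrix
    config: RunConfig
    denoise: DenoiseResult
    bank: SourceBank
    D: np.ndarray
    projection: projection.Projection2D
    c: int
    index_curve: dict[int, float] = field(default_factory=dict)
    partition: clustering.Partition | None = None
    centrotypes: clustering.CentrotypeSet | None = None
    reliability: reliability.ReliabilityReport | None = None
    weights: interpretation.WeightsMatrix | None = None


def run_pipeline(
    X: IntensityMatrix,
    config: RunConfig | None = None,
    n_clusters: int | None = None,
    min_prevalence: float = 0.10,
    score_reliability: bool = True,
) -> PipelineResult:
    """Run the full consensus procedure and return all artifacts.

    ``n_clusters=None`` selects c by the quality-index argmin over
    ``config.cluster_range`` (default 2..k); an integer fixes c directly.
    ``score_reliability=False`` skips the bootstrap stage (useful when only
    the algorithmic-reliability half is needed).
    """
    config = config or RunConfig()
    seed = config.master_seed

    if min_prevalence > 0:
        X = prevalence_filter(X, min_prevalence)
    Xc = center(X)
    den = pca_denoise(Xc, config.variance_threshold)
    logger.info("denoised to k=%d PCs (R^2=%.1f%%)", den.k, 100 * den.cumulative_explained)

    bank = generate_source_bank(den.X_d, config.n_runs, derive_seed(seed, "bank"))
    D = clustering.spearman_dissimilarity(bank)
    Z = clustering.hca_average_link(D)
    proj = projection.cca_project(D, seed=derive_seed(seed, "cca"))

    curve: dict[int, float] = {}
    if n_clusters is None:
        lo, hi = config.cluster_range or (2, max(den.k, 2))
        hi = min(hi, D.shape[0] - 1)
        c, curve = clustering.select_cluster_number(D, proj.coords, (lo, hi), Z=Z)
        logger.info("quality index selected c=%d over range %d..%d", c, lo, hi)
    else:
        c = int(n_clusters)
    part = clustering.cut_dendrogram(Z, c)
    oc = clustering.extract_centrotypes(bank, D, part)

    report = None
    if score_reliability:
        datasets = reliability.make_bootstrap_datasets(
            X, config.n_bootstrap, config.n_replace, derive_seed(seed, "bootstrap-data")
        )
        report = reliability.score_H_distribution(
            oc, datasets, config.n_inits, derive_seed(seed, "bootstrap-w0"),
            config.variance_threshold,
        )

    G = interpretation.component_operator(den, bank, oc)
    weights = interpretation.weights_matrix(G, X.feature_ids)

    return PipelineResult(
        X=X, config=config, denoise=den, bank=bank, D=D, projection=proj,
        c=c, index_curve=curve, partition=part, centrotypes=oc,
        reliability=report, weights=weights,
    )
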