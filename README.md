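# stabica

Stability-aware independent component analysis (ICA) for non-targeted
mass-spectrometry metabolomics.

## The problem

Aligned non-targeted metabolomics matrices have few samples (n ≈ 20–60) and
thousands of sparse mass signals. PCA summarizes such matrices by variance,
but biologically interesting structure (strain separations, outlier samples,
batch artifacts) is often non-Gaussian rather than high-variance, which is
what ICA targets. FastICA, however, is a stochastic local optimizer: each
restart from a random initial demixing matrix W₀ can return different
components, so a single run is not trustworthy on ill-posed n ≪ p data.

`stabica` makes ICA answers reproducible and rankable:

1. **Denoise** — center X (n × p) and project onto the smallest PC subspace
   explaining ≥ 90 % of variance: X_d = X̄ K.
2. **Restart** — run FastICA (logcosh contrast; half deflation, half
   parallel extraction) m times from random Gaussian W₀, pooling all
   Ŝ = X_d Ŵ estimates into an n × (k·m) source bank.
3. **Cluster** — compute d_ij = 1 − |Spearman ρ_ij| between bank columns and
   apply average-link hierarchical clustering; recurring estimates form tight
   clusters, and each cluster is represented by its *centrotype* (the member
   with the minimal sum of dissimilarities to the rest).
4. **Select c (algorithmic reliability)** — project the bank to 2-D with
   curvilinear component analysis and pick the cluster count minimizing the
   ratio of average within-cluster to average between-cluster distance.
5. **Score (statistical reliability)** — build B bootstrap datasets by
   replacing `n_replace` rows of X with rows resampled from the remainder,
   run FastICA once per dataset, and score each centrotype

   H_a = Σ_{b=1..B} max_{j=1..k} |ρ(OC_a, Ŝ_bj)|,

   repeating over 50 random W₀; the median Ĥ ranks components for
   interpretation (H is bounded by [0, B]).
6. **Interpret** — per-feature loadings come from the weights matrix
   A = Gᵗ (G Gᵗ)⁻¹, the right pseudo-inverse of the feature→component
   operator G (so G A = I); the top positive/negative loadings per component
   are the mass signals driving it.

A covariance-matched simulator (SX = I·N + RX, with N Gaussian noise sharing
the sample covariance of X̄ and RX rebuilt from chosen non-Gaussian PCs) and
a planted-source fixture generator make the whole pipeline testable without
any real data.

## Worked example

```python
from stabica import RunConfig, make_fixture, run_pipeline

X, S = make_fixture(n=50, p=500, q=3, snr=10.0, seed=1)   # 3 planted sources
cfg = RunConfig(n_runs=100, n_bootstrap=20, n_inits=10, master_seed=42)
result = run_pipeline(X, cfg)
```

This prints (via the run log) and exposes:

```
denoised to k=3 PCs (R2 = 91.6 %)
selected c = 3; index curve: c=2: 0.288, c=3: 0.044
  OC1: H_hat = 18.04 / 20, IQR = 0.24, kurtosis = -1.50
  OC2: H_hat = 17.48 / 20, IQR = 0.17, kurtosis = -1.37
  OC3: H_hat = 17.19 / 20, IQR = 0.26, kurtosis = +0.49
  true source 0: best |rho| = 0.992
  true source 1: best |rho| = 0.993
  true source 2: best |rho| = 0.995
```

Reading: the quality index drops sharply once the three recurring components
are isolated (0.288 → 0.044), every centrotype is refound in essentially all
20 bootstrap resamples (Ĥ ≈ 17–18 of 20) with tiny spread across random
initializations, and each planted source is matched by a centrotype at
|Spearman ρ| ≥ 0.99.

The same pipeline is available from the shell:

```sh
stabica run intensities.tsv --out results/ --runs 800 --bootstrap 100 --seed 1
stabica diagnose intensities.tsv          # kurtosis census of the features
stabica simulate intensities.tsv --pcs 11,15 --noise 0.1 --out sx.tsv
```

`run` writes the sources, weights, cluster labels, Ĥ table, CCA coordinates,
figures and a JSON manifest with per-stage timings and all derived seeds.

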