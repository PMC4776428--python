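# Methods

## Model and assumptions

The observed intensity matrix X (n samples × p mass signals) is assumed to be
a noisy linear mixture X ≈ S A of a handful of mutually independent,
non-Gaussian latent sources S. FastICA estimates a demixing operator by
maximizing approximated negentropy (logcosh contrast) over orthonormal
directions in a whitened representation. Because the contrast is optimized
locally from a random start W₀, the estimate is a random variable; this
package treats the *distribution* of estimates over restarts and over
bootstrap perturbations of the data as the object of inference, following the
consensus ("cluster the restarts, keep the recurring components") family of
methods.

Two distinct reliability notions drive model selection:

- **Algorithmic reliability** — do restarts converge to the same optima?
  Measured by the compactness of bank clusters (quality index below).
- **Statistical reliability** — do the optima survive perturbation of the
  samples? Measured by the bootstrap similarity score H.

## Pipeline stages and parameters

| parameter | default | meaning |
|---|---|---|
| `variance_threshold` | 0.90 | fraction of variance kept by PCA denoising (k is minimal with cumulative R² ≥ threshold) |
| `n_runs` (m) | 800 | FastICA restarts pooled into the source bank |
| `cluster_range` | 2..k | cluster counts scanned by the quality index |
| `n_bootstrap` (B) | 100 | bootstrap datasets for H |
| `n_replace` | 5 | rows of X overwritten per bootstrap dataset |
| `n_inits` | 50 | random W₀ draws per H distribution |
| `min_prevalence` | 0.10 | features observed in fewer than this fraction of samples are dropped (zeros = absent masses) |

FastICA numerics: logcosh steepness α = 1, tolerance 1e-4, 200 iterations
maximum — the defaults of the reference FastICA implementation. Non-converged
runs are kept in the bank: they land in diffuse clusters that the quality
index and the bootstrap score both penalize naturally, so excluding them
would only hide information.

Whitening is recomputed inside every FastICA call from the score matrix it
receives (thin SVD; exact unit sample covariance). This matters because
bootstrap datasets re-enter the engine with their own scale and their own
denoised dimension k_b.

Sign convention: ICA leaves the sign of every source arbitrary. Each bank
column (and its demixing row) is flipped so its skewness is non-negative;
near-symmetric columns fall back to making the largest-magnitude entry
positive. The dissimilarity already uses |ρ|, so this only standardizes the
reported components.

Seeding: every stochastic task (per-run W₀, bootstrap row choices, scoring
W₀ draws, CCA) draws from a child seed obtained by hashing
`master_seed:task:index` (blake2b, reduced mod 2³¹), so runs are exactly
reproducible and independent of execution order.

## Dissimilarity, clustering, centrotypes

Similarity between estimates is |Spearman ρ| (rank-based, so any strictly
monotone distortion of an estimate is recognized as the same component);
d = 1 − |ρ| with average-rank tie handling. Average-link agglomeration is
used; cutting the dendrogram at c clusters and taking each cluster's
centrotype (member with minimal within-cluster distance sum, ties to the
smallest column index) yields the c representative components OC.

## Quality index and cluster-number selection

The index is (mean over clusters of the mean pairwise within-cluster
distance, singletons contributing 0) ÷ (mean distance over all
between-cluster pairs), computed by default on the 2-D CCA coordinates; a
variant computed directly on the dissimilarity matrix is available for
sensitivity checks (`on="dissimilarity"`). Two open choices were resolved as
follows: within-cluster distances are averaged per cluster *before* the
ratio (the pooled-pairs variant is exposed through the same oracle-tested
code path), and the between term uses all inter-cluster point pairs rather
than centroid distances, which is the stricter, parameter-free reading.

The selected c is the argmin of the index over `cluster_range`, ties to the
smallest c; a flat curve warns and returns the smallest candidate.

**Known limitation.** On degenerate banks where every restart converges to
the same optima, clusters are nearly point-like; cutting further only splits
off stray columns, which *lowers* the per-cluster-averaged numerator, so the
index decreases quasi-monotonically and the argmin sits at the top of any
wide scan range. The default range 2..k (k = denoised dimension) keeps the
selection meaningful in that regime — the index is decisive about "too few"
clusters (merging distinct components inflates it sharply) — and the
bootstrap-score route provides the complementary check against "too many":
surplus centrotypes score visibly below the genuine ones. On noisy banks
containing diffuse clusters of non-recurring estimates the curve shows the
expected interior minimum (see the noise-progression test).

## Curvilinear component analysis

CCA places one 2-D point per bank column and pulls pairs toward their input
dissimilarity only when their *output* distance lies within an annealed
radius λ, preserving local cluster geometry at the expense of large
distances. Schedules: λ from max(D) to 1 % of it, learning rate 0.5 → 0.01,
both geometric over 50 sweeps; coordinates are initialized from classical
metric scaling (Torgerson) rather than at random, which removes most seed
sensitivity, with pure random initialization behind a flag. The reported
stress is the CCA objective at the final radius — Σ (d − d′)² over pairs
with d′ ≤ λ_f — which is the quantity CCA actually optimizes; the unweighted
(all-pairs) stress is available from the same function and is *expected* to
grow when CCA unfolds a curved manifold.

## Bootstrap reliability

Each bootstrap dataset overwrites `n_replace` uniformly chosen rows with
rows drawn (with replacement) from the remaining ones — the natural reading
of resampling-with-replacement at fixed n: some samples duplicate, others
vanish. Every dataset is centered and denoised on its own (its k_b may
differ from the original k; the shared W₀ is truncated, or padded with an
identity block, to k_b — W₀ is only an initialization, so completion is
inconsequential and logged). Half of the datasets are scored with parallel
extraction, half with deflation. The B·n_inits FastICA runs are computed
once and reused when Ĥ is monitored as a function of c.

A fixed high-Ĥ cutoff is deliberately not hardcoded: where one is needed the
package scales it as 0.58·B so it tracks the bootstrap count.

**Caveat.** With n_replace = 5 of n = 50, any single sample survives 90 % of
resamples, so even a component driven by one outlying sample retains a
moderate Ĥ; the outlier-sensitivity ordering (outlier below planted
components) is reliable when the genuine components are well estimated and
can invert on draws where one of them is not (see limitations below).

## Simulated data

`simulate_sx` mirrors the validation design used on real data: N is
multivariate Gaussian with the sample covariance of X̄ (sampled exactly
through the thin-SVD factor of X̄, which handles the rank-deficient p ≫ n
covariance without any explicit p × p factorization), RX = scores·loadingsᵗ
restricted to chosen non-Gaussian PCs (the unique linear reconstruction),
and SX = I·N + RX. Choosing a PC with |excess kurtosis| ≤ 1 warns.

`make_fixture` plants q unit-variance non-Gaussian sources — Laplace
(excess kurtosis +3), uniform (−1.2) and a symmetric two-Gaussian mixture
with separation 2.5 component-sd (−1.49; the separation was set by the
target kurtosis, which is the property that matters for a sub-Gaussian
probe) — mixes them into p features with a random full-rank operator, and
adds i.i.d. Gaussian noise scaled so that total signal variance / total
noise variance equals `snr`. White noise keeps the planted sources the exact
optima of the independence search; realistic correlated backgrounds are the
role of `simulate_sx`. What fixture tests therefore do **not** show: bias of
ICA under correlated (non-white) Gaussian noise, sparsity/zero-inflation of
real intensities, or instrument batch structure.

Problem sizes used by the test suite and the acceptance script — chosen to
keep every property measurable at interactive speed — are n = 50, p = 400 or
500, m = 60–100 restarts, B = 20, 10 scoring initializations; the pipeline
defaults above remain the published-scale values.

## Diagnostics and interpretation

Feature and component non-Gaussianity use Fisher excess kurtosis without
small-sample bias correction (the ±1 screening thresholds presuppose the
uncorrected convention); fewer than 5 % non-Gaussian features triggers a
warning that ICA has little to work with. The weights matrix is the right
pseudo-inverse of the feature→component operator assembled from each
centrotype's own originating run (its exact demixing row exists in the
bank), so G A = I holds to machine precision and S Aᵗ reconstructs X̄ up to
exactly the PCA truncation error when c = k.

## Limitations

- With n ≈ 50 samples, FastICA's empirical optimum can sit at Spearman
  |ρ| ≈ 0.89–0.95 from a true source even on noiseless data; the consensus
  machinery cannot exceed the best restart, so near-perfect recovery of
  every planted source is not guaranteed at this sample size (it is at
  n = 200). This is a sample-size property of the estimator, not of the
  consensus layer.
- The quality index's argmin degenerates on clean banks (see above); use the
  default 2..k range and corroborate with the bootstrap scores.
- H scores compare centrotypes against *one* FastICA run per bootstrap
  dataset; they measure stability, not statistical significance in a
  hypothesis-testing sense.
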