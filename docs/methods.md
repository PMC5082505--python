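# Methods

`lesionconn` quantifies how a focal brain lesion (modelled on hippocampal
damage) changes resting-state functional connectivity, at three levels:
individual ROI pairs, network blocks, and whole-connectome graph
structure. Because the clinical datasets such analyses are run on cannot
be redistributed, the package pairs the estimator with a synthetic cohort
generator that plants the qualitative effects of interest, so every stage
is testable end to end.

## Connectivity estimator

For ROIs *i* (target) and *j* (seed), connectivity is the seed coefficient
of the GLM

    y_target = beta * y_seed + N c + e,    Cov(e) = V = sum_k lambda_k Q_k

where `N` is the nuisance design and the error covariance is a
non-negative combination of eight exponential Toeplitz components
`Q_k(t,t') = exp(-ln2 |t-t'| / h_k)` with half-lives h = 0.5, 1, 2, 4, 8,
16, 32, 64 TRs, plus (by default) a white-noise identity component. An
AR(1)-plus-white model is too rigid for resting-state error spectra; the
exponential family spans time scales from sub-TR to minutes.

The nuisance design has three parts:

1. **Artifact series** — white-matter, CSF and whole-brain proxies
   (3 columns).
2. **Motion** — a second-order, lag-five Volterra expansion of the
   relative-displacement (RD) index: 9 first-order columns (RD at lags
   0–4, zero-padded, plus the 4 successive differences between
   consecutive lags) and all 81 ordered products, 90 columns. Symmetric
   duplicate products are kept; the SVD in the next step removes the
   redundancy. The artifact and motion columns are standardized, stacked
   and reduced by SVD to the smallest number of components explaining 99%
   of their variance (m is data-dependent and logged per subject).
3. **Band-pass by regression** — a discrete cosine set containing the
   constant plus every component with frequency `f_k = k / (2 T TR)`
   strictly below 0.009 Hz or strictly above 0.1 Hz. At T = 148, TR = 2 s
   this is 94 columns (1 + 5 + 88). This is the only convention we found
   that yields 94 columns at these settings, so it is fixed and the count
   is exposed for other T/TR choices. Filtering is by projection only;
   the data themselves are never filtered.

### ReML

Hyperparameters are estimated by restricted maximum likelihood. The
problem is first rotated into the residual space of the design (the
restricted likelihood is exactly the likelihood of the rotated data),
which makes iterations cheap when the nuisance design is large (~110
columns at T = 148 leaves a 38-dimensional working space). Fisher-scoring
steps are Levenberg–Marquardt damped against the restricted
log-likelihood.

Hyperparameters are kept non-negative through a log parametrization with
a wide prior (`h ~ N(log s0 - 4, 64)`, s0 the data scale). We initially
allowed signed hyperparameters with a positive-definite projection of V,
but cancelling positive/negative combinations of the nearly collinear
exponential components can overfit a single realization — V collapses
inside the span of the design (which the restricted likelihood cannot
see) and the edge t inflates catastrophically (type-I error 0.59 instead
of 0.05). The log parametrization is the standard stable variant and
restores calibration (measured type-I error 0.046–0.055 at |z| > 1.96).

Convergence: relative hyperparameter change < 1e-6, a restricted
log-likelihood plateau (< 1e-3 nats), or 64 iterations, whichever first.

### From t to Z

Inference is whitened least squares: with `W = V^(-1/2)`, the seed t is
computed from the whitened model with the error scale re-estimated from
whitened residuals at the Satterthwaite effective df
`nu = tr(R V_w)^2 / tr(R V_w R V_w)` (R the residual-forming matrix of
the whitened design). The t is converted to a signed standard-normal
deviate through its two-tailed p (log-space, capped at |z| = 38 so
machine underflow cannot produce infinities). The Z therefore accounts
for dfs lost to confound removal, filtering and autocorrelation; with the
full design at T = 148 about 38–40 residual dfs remain.

### Full matrices: pooled vs per-edge

`connectivity_matrix(..., method="pooled")` (default) performs one ReML
fit per subject on the ROI-pooled sample covariance (the standard pooled
non-sphericity strategy), then whitens once and reads off every edge as a
partial correlation converted to t and Z. Under a shared whitening both
seed/target directions give the identical statistic, so the matrix is
symmetric by construction. `method="per-edge"` runs the literal ordered
loop with one ReML fit per direction and averages the two Z's; it agrees
closely with the pooled path (rank correlation > 0.9 on 8-ROI subjects)
and is used for per-edge unit tests, but is O(N^2) ReML fits and
impractical for 120-ROI cohort sweeps.

After estimation, the mean RD of every participant (patients and controls
pooled) is regressed out of each edge across subjects, preserving the
grand mean.

## Network level

Edge Z matrices are averaged into K x K blocks over a partition:
diagonal = mean over unique within-network pairs, off-diagonal = mean
over spanning pairs. Lesion ROIs are excluded from their host network
(configurable) so the lesion profile — mean Z between the lesion set and
each network — does not double count. Segregation is the mean diagonal
minus the mean off-diagonal (unique pairs; for a symmetric matrix the
full-off-diagonal mean is identical). Group contrasts per cell use the
linear model `value ~ 1 + group + sex`, with Bonferroni families K(K-1)/2
for pairwise cells, K for the diagonal family and K for the lesion row,
mirroring the analysis design (120 pairwise and 16 lesion-row tests at
K = 16).

## Graph metrics

Matrices are binarized by keeping the strongest (100-P)% of unique edges
— exactly round((1-P/100) N(N-1)/2) edges, enforced by ranking with a
deterministic tie-break on (z, i, j) so every subject retains the same
degree. Note the convention: "threshold P = 99%" keeps the top 1% of
edges (a sparse graph with isolates), which reproduces the qualitative
behaviour of high-threshold connectome analyses; the literal "top P% of
edges" reading is available as P' = 100 - P. On the binary graph we
compute global clustering (mean nodal clustering, isolates counting 0),
global efficiency (mean inverse shortest path; disconnected pairs
contribute 0), small-worldness approximated as their product C*E, and the
isolate fraction. The sweep covers P = 85–99% in 1% steps (15
thresholds); group tests at each threshold are Bonferroni-corrected over
the 15.

## Statistics

- **Single case vs controls**: pooled-variance t,
  `t = (x - mean_c) / (sd_c sqrt(1 + 1/n))`, df = n-1 (the classic
  comparison of one case to a normative sample); two-tailed by default
  with a one-tailed option for directional lesion predictions.
- **Group difference with covariate**: `value ~ 1 + group + sex`,
  t on the group coefficient (df = n-3; without covariate the unpaired
  pooled t, df = n-2).
- **Evidence combination**: Stouffer, `Z = sum(z_i)/sqrt(k)`; normative
  percentiles convert to z via the standard-normal quantile (percentile
  bands are taken at their midpoint).
- **Bonferroni**: `min(1, m p)`.
- **Rank-sum**: exact enumeration for combined n <= 10 without ties,
  normal approximation with tie correction otherwise.

## Synthetic cohorts

ROI *i* in network k(i) is generated as

    x_i(t) = a_i g_k(i)(t) + g G(t) + sigma eps_i(t)

with unit-variance AR(1) latents (coefficient 0.4 at TR = 2 s) whose
innovations are correlated across networks (baseline 0.3), an independent
AR(1) global signal, and white noise. Defaults: 120 ROIs, 8 networks of
15 (four named roles: DMN, FEN, thalamic, precuneus), T = 148 volumes at
TR = 2 s (150 acquired, two dummies discarded), a = 0.42, g = 0.32,
sigma = 1.

Patients differ by: lesion-ROI signal amplitude multiplied by
(1 - alpha), alpha = 0.6; within-coupling increment +0.1 (raising
segregation); thalamic–precuneus innovation correlation decremented by
0.4 and DMN–FEN incremented by 0.4, with the matrix eigenvalue-floored at
1e-6 and renormalized to unit diagonal so the generator always stays
valid. These defaults are deliberately large: the effects they emulate
survived Bonferroni correction over 120 network-pair tests with six
patients, and the generator's contract is that each planted direction is
recovered in >= 80% of seeded 20-control/6-patient cohorts (>= 70% for
clustering at the 99% threshold). Closed-form block correlations of the
generative model put each effect several standard errors from zero at
these settings.

Motion is a random-walk in the six rigid-body parameters with
Poisson-thinned spike displacements (default 0.05/volume, 1 mm);
artifact series are low-pass noise plus the spike indicator, so the
confound model has something real to remove. RD uses parameter-step
relative transforms with an 80 mm sphere radius (the common convention;
configurable) — consecutive-volume displacement, not
displacement-to-mean. Motion outliers are flagged above
Q3 + 1.5 IQR of the control mean-RD distribution (type-7 quartiles,
upper fence only), and analyses can run with and without them.

### What the generator does not emulate

No hemodynamics, no spatial structure (the voxel-block fixture exists
only to exercise SVD extraction), no between-subject variability in
coupling strengths beyond sampling noise, no physiological (cardiac or
respiratory) aliasing, and motion corrupts only the artifact channels,
not the ROI signals themselves. Passing recovery tests therefore shows
the pipeline recovers planted covariance structure at realistic T and
cohort sizes — not that it would behave identically on scanner data.

## Numerical choices and degenerate inputs

- ROI extraction: voxel means removed before SVD; the first right
  singular vector is sign-matched to the across-voxel mean and z-scored
  (unit variance over volumes, ddof = 1). All-constant input is an error.
- Rank-deficient designs: collinear nuisance columns are dropped with a
  warning; a rank-deficient seed design is an error.
- Percentile binarization of an all-equal matrix is an error (no
  meaningful ranking).
- Singleton networks leave their diagonal block undefined (NaN) and
  segregation refuses to compute; the pipeline skips the segregation test
  in that case (e.g. the 8-ROI configuration after lesion exclusion).
- All randomness flows through numpy Generators seeded from a single
  master seed (child seeds via SeedSequence), so every run is a pure
  function of (inputs, config, seed).

## Problem sizes

Desk-scale defaults are chosen so the full recovery study (50 cohorts of
26 subjects at 120 ROIs) completes in minutes on one core: the pooled
path costs one ReML fit and one whitening per subject. ReML recovery of
an AR(1) lag ratio is verified at T = 1000 (median over 3 replicates);
null calibration over ~2000 edges; graph-metric oracles over hundreds of
random graphs up to 15 nodes.

## Known limitations

- Only linear dependence is measured; nonlinear coupling is out of scope.
- The pooled non-sphericity assumption (one V per subject) trades
  per-edge autocorrelation detail for tractability; the per-edge path
  exists but is slow.
- Effective df uses the Satterthwaite trace form, which reduces to
  T - rank(design) under exact self-consistent whitening; the "dfs lost"
  accounting is therefore driven by the confound count, as logged.
- The despiker (robust-z + linear interpolation) is deliberately simple
  plumbing, off by default; it is not a wavelet despike.
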