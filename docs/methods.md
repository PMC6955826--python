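# Methods

## Problem setting

Resting-state fMRI decomposes into large-scale resting-state networks
(RSNs); in disorders of consciousness (minimally conscious state, MCS, and
unresponsive wakefulness syndrome, UWS) the coupling *between* RSNs is
degraded relative to healthy controls (HC). `fnconn` implements the full
between-network analysis chain: identification of the 10 canonical RSNs
among independent components, a per-subject 10 × 10 functional network
connectivity (FNC) matrix from lagged distance correlation, graph measures
of integration / segregation / centrality, and between-group Welch tests.
Because the underlying patient scans are not publicly deposited, the
package carries a first-class synthetic-cohort generator whose defaults
mirror the acquisition regime of the original study: 297 retained volumes
at a 2 s sampling interval, 10 networks, and group sizes 27 (HC), 24 (MCS),
24 (UWS).

## Dependency estimation

**Distance correlation.** The connectivity statistic is the biased
V-statistic estimator of distance correlation: pairwise absolute-difference
matrices are double-centered (row, column and grand means removed),
dCov² is the mean of their elementwise product and
dCor = dCov / √(dVar_x · dVar_y), clipped to [0, 1] against negative
rounding. The V-statistic (rather than the unbiased U-statistic) is used
because it is the original estimator of the statistic this analysis is
built on; results are bit-for-bit reproducible.

**Circular-shift lags.** Inter-network coupling can be delayed by a few
volumes, so the FNC entry is the maximum of dCor over circular shifts of
one series within ±`max_lag` samples (default 3 samples = 6 s at TR 2 s; a
positive lag means the second series trails the first). Circular rather
than zero-padded shifts keep every evaluation at full sample size. Exact
ties between lags are broken toward smaller |lag|, then toward the negative
lag, which makes the maximizer deterministic.

**Edge retention.** A V-statistic is strictly positive in finite samples,
so "nonzero correlation" is decided against a surrogate null: the
lag-maximized statistic is recomputed on random large circular rotations of
one series (rotation ≥ max_lag + 1 samples, 100 surrogates, α = 0.05 by
default). Rotations preserve each series' autocorrelation — important,
because the signals are band-limited and strongly autocorrelated — while
destroying cross-dependence. The threshold is the "higher" order statistic
at the 1 − α quantile, which is mildly conservative at small surrogate
counts. A fixed-threshold rule is available as an alternative.

*Numerical note.* Rotating a series circularly permutes its distance
matrix by the same rotation on rows and columns, and double centering
commutes with a simultaneous row/column permutation. Simultaneous rotation
preserves cyclic diagonals of the matrix, so dCov² against **every**
rotation of the partner series is a sum of one-dimensional circular
cross-correlations (one per diagonal), evaluated together in the frequency
domain. Observed per-lag values use exact direct products (the lag-0 value
is bit-identical to the plain estimator); only the surrogate null uses the
FFT path, whose ~1e-15 rounding is irrelevant to a quantile. Unit tests
verify both paths agree to machine precision.

## Network measures

Measures are computed on the retained weighted graph restricted to
neuronal nodes; rows/columns of non-neuronal components are zero.

- **Degree / strength** — count of retained incident edges; sum of their
  dCor weights.
- **Clustering** — Onnela geometric-mean form,
  C_i = Σ (w_ij w_ih w_jh)^{1/3} / (k_i (k_i − 1)), with *raw* weights.
  dCor is already bounded by 1, and renormalizing by the per-subject
  maximum weight (the convention of some toolboxes) would make subjects
  incomparable, so it is deliberately not done.
- **Betweenness** — Brandes accounting with fractional credit for tied
  geodesics on edge lengths 1/w, normalized by (n − 1)(n − 2)/2 with n the
  neuronal node count, so values lie in [0, 1].
- **Eigenvector centrality** — leading eigenvector of the retained
  adjacency over neuronal nodes, nonnegative orientation, unit Euclidean
  norm, by power iteration to tolerance 1e-10. The iteration runs on
  A + sI with s the maximum row sum: the shift leaves eigenvectors
  unchanged but makes the Perron eigenvalue strictly dominant (a bipartite
  component otherwise has −λ_max in its spectrum and the iteration
  oscillates). Disconnected graphs converge to the global leading
  eigenpair; an empty graph returns zeros with a warning.
- **Network averages** — arithmetic means over all 10 nodes, including
  zeroed (non-neuronal or isolated) ones, mirroring the convention that a
  suppressed component contributes zero interaction.

## Group comparison

Welch's unpaired t test (no equal-variance assumption), two-sided, with
Welch–Satterthwaite degrees of freedom, for the contrasts HC–MCS, HC–UWS,
HC–DOC (DOC = pooled MCS + UWS) and MCS–UWS. Nodal tests are Bonferroni
corrected over the family of 10 RSNs (significance at α/10 = 0.005 for
α = 0.05, the reporting convention of the source analysis); network
averages form a family of one. The family size and α are configurable
because the exact family used originally is not stated. A
summary-statistics entry point applies the same formulas to published
means/SDs/ns, which is how the printed t values (3.16 for average degree
HC vs UWS; 2.95 for average clustering HC vs MCS) are recomputed. Note
that the Welch p for the clustering contrast evaluates to 0.006 at the
recomputed df while the source prints .004; the t statistic itself
reproduces exactly to the printed precision.

## RSN identification

**Template matching.** Goodness of fit of a component map to a binary RSN
template is mean(|amplitude| inside mask) − mean(|amplitude| outside mask);
absolute amplitudes make the score invariant to the arbitrary sign of an
independent component. The two matching constraints — every template
assigned, no component claimed twice — define a bipartite matching, solved
as an optimal linear assignment maximizing total goodness of fit (not
greedily), with template-name order as the deterministic tie-break.

**Fingerprints.** Each component gets an 11-feature descriptor: spatial —
degree of clustering (fraction of |z| > 1.5 voxels in the largest
6-connected cluster), skewness, excess kurtosis, histogram entropy;
temporal — one-lag autocorrelation, histogram entropy, and the power
fractions of five bands (0–0.008, 0.008–0.02, 0.02–0.05, 0.05–0.1,
0.1–0.25 Hz) normalized within 0–0.25 Hz, from an averaged-periodogram
(Welch) spectral estimate. Histogram entropies use ⌈√n⌉ equal-width bins
and natural logarithms. These conventions (threshold, connectivity, bin
rule, estimator) are stated choices: the fingerprint features are named
but not formally defined in the source literature.

**Neuronal/artifactual labeling.** A linear maximum-margin classifier
(standardizer + linear SVM) on the fingerprint vector. The original
classifier was trained on fingerprints from 19 independently assessed
healthy subjects, which are unavailable; the packaged classifier trains on
labeled synthetic fingerprints (band-limited neuronal signals vs the three
artifact signatures) and reproduces the contract — label plus signed
margin — rather than the original weights. The fourth artifact rule of the
source (suprathreshold voxels in the superior sagittal sinus) needs an
anatomical atlas and is out of scope.

## Synthetic cohorts

The generator uses a latent-driver model: every edge of a coupling graph
owns a band-limited Gaussian driver injected into both endpoint nodes —
into the second at the edge lag, through the edge nonlinearity (identity,
standardized square, or standardized cube as a rank-preserving monotone
map), with amplitude equal to the edge weight. Independent band-limited
node noise is added and columns are standardized. A full vector-
autoregression would entangle lag and spectrum; the latent-driver model
gives direct, independent control of exactly what the lagged statistic
must detect. The 0.01–0.1 Hz band mirrors the neuronal band implied by
the >0.1 Hz artifact rule.

Defaults (the study conditions of all simulation-based tests): 10 nodes,
edge density 0.4, weights uniform on (0.5, 0.9), lags up to ±3 samples, a
minority of nonlinear edges, node noise SD 0.5, 297 time points at 2 s.
Group degradation: HC (0, 0, 1); MCS (0.25, 0.25, 1.25); UWS (0.5, 0.5,
1.5) for (edge-deletion probability, weight attenuation, noise inflation).
No published effect-size calibration exists for the HC→UWS connectivity
drop, so these are conventions chosen once to produce a graded,
non-degenerate separation; they are not estimates of the clinical effect.
Subject seeds derive from the cohort seed via a seed sequence keyed on
(group index, subject index), so any subject is independently
regenerable.

What the generator does **not** emulate: hemodynamics (no balloon/BOLD
forward model), scanner artifacts beyond the three signatures, spatial
autocorrelation of real component maps, structural lesions, or
between-subject variability in the coupling graph beyond the random
degradation draw. Passing recovery tests therefore demonstrates that the
estimator chain detects the statistical structure it targets, not that it
would reach the same effect sizes on clinical data.

## Motion QC

Frame-wise displacement FWD_t = Σ|Δtranslation| + 50 mm × Σ|Δrotation|
(rotations in radians, arc length on a 50 mm sphere, the standard
convention). The first frame is 0 by definition. Frames above a
configurable threshold (default 0.5 mm — the original threshold is
unstated) are flagged, not censored: scrubbing/repair belongs to the
upstream preprocessing, which is out of scope here.

## Problem sizes and tolerances

Simulation-based checks use the full study geometry (297 × 10 per subject,
27/24/24 groups). The test suite runs 20 cohort replicates for the
ordering/power recovery check and 50 replicate subjects for null
calibration; `scripts/acceptance.py` reports the same quantities with 10
cohort replicates, a size chosen to keep a complete from-scratch
recomputation convenient on a single CPU. Oracle agreements are asserted
at 1e-10 (distance correlation, betweenness) and 1e-8 (eigenvector
centrality, reflecting the 1e-10 iteration tolerance); the surrogate
calibration band [0.02, 0.10] is the binomial tolerance of the 5% nominal
level at 50 × 45 Bernoulli draws.

## Known limitations

- ICA unmixing itself is not performed; the pipeline consumes component
  maps/time-courses (synthetic or user-supplied).
- Only univariate series enter the dependency statistic (no multivariate,
  partial, or frequency-domain variants).
- The lag window of the original analysis is unknown; 3 samples is a
  stated default, configurable.
- The edge-retention rule of the original analysis is undocumented; the
  surrogate rule is this package's operationalization, and group-level
  results depend on it.
- Under the per-edge latent-driver model, the coupling any single pair
  shares scales like 1/k at a node of true degree k, so at the default
  base graph the per-edge detection rate is roughly one half and the
  retained mean degree of a healthy-control subject plateaus near 2 of 9
  — well below the ~3.8 reported for real cohorts — for any node-noise
  level. Degree and strength contrasts between groups are nevertheless
  large and stable; *clustering*, which requires all three edges of a
  triangle to be retained simultaneously, sits near zero for every group
  and its group ordering inverts by sampling noise in roughly one
  replicate in seven (see the cohort-recovery fractions reported by
  `scripts/acceptance.py`). Clustering results on synthetic cohorts
  should therefore be read as qualitative only.
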