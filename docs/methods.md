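# Methods

This note documents the models, parameter choices and numerical decisions
behind `taumri`, and what the synthetic cohorts do and do not establish
about real data.

## Study design emulated by the synthetic cohort

The generator reproduces the design the analysis targets: three groups —
pro-aggregant tauRD transgenic (n = 8), anti-aggregant transgenic (n = 8)
and wildtype littermate controls (n = 7) — each measured at two time
points, baseline (transgene ON) and after eight weeks of doxycycline
switch-off. Functional sessions use T = 105 frames at TR = 2.84 s and a
96×96-style in-plane grid scaled down to block ROIs of 0.182×0.182×0.5 mm
voxels. Transgenic baseline connectivity is scaled to 0.5 of control
strength ("roughly half"), recovering to 1.0 at follow-up; the exact 0.5
is a modeling choice, not a fitted value. Scaling the off-diagonal by s is
the convex combination s·C + (1−s)·I, so positive semidefiniteness is
preserved for any s ∈ (0, 1].

The default base correlation matrix is modular: 16 ROIs in three
functional networks (memory/subcortical, sensorimotor, default-mode), with
within-network r = 0.6 and between-network r = 0.25 — realistic magnitudes
for medetomidine-sedated rodent rs-fMRI.

### BOLD signal model

Per session: each ROI's voxels share a latent signal, band-limited to
0.01–0.08 Hz by FFT masking of white noise. The latent series are
ZCA-whitened on their *realized* sample covariance and mixed with the
symmetric PSD square root of the target matrix, so the latent sample
correlation matrix equals the target exactly (not merely in expectation).
This is deliberately stronger than Cholesky mixing alone: parameter
recovery then measures what the preprocessing and connectivity stages do,
not simulation luck, and every sampling-error tolerance stated for an
in-expectation generator is trivially satisfied. On top of the latents:
per-voxel white noise (SD 0.5 in latent-SD units), per-voxel random linear
and quadratic drifts (SD 0.5/0.25), a respiratory sinusoid at an apparent
(sampled) 0.12 Hz with per-voxel coupling, and six smoothed-random-walk
motion traces with small random voxel couplings (SD 0.1). The returned
nuisance set contains exactly the injected respiration and motion, so the
regression path is exercised end to end.

What the cohort does **not** emulate: spatial autocorrelation of
physiological noise, inter-frame motion requiring realignment, atlas
misregistration and partial-volume effects, hemodynamic nonlinearity.
Passing recovery tests therefore demonstrates correctness of the analysis
chain under its stated assumptions, not robustness to those artifacts.

### Diffusion phantoms

Multi-tensor signal S(g) = S0 · Σ f_k exp(−b gᵀD_k g) with equal fractions
in crossing voxels; axial/radial diffusivities 1.7e−3 / 0.3e−3 mm²/s
(white-matter-like), isotropic 2.0e−3 mm²/s (CSF-like) outside bundles —
standard values giving realistic contrast at b = 2000 s/mm². Noise is
Rician (magnitude MRI): sqrt((S+n₁)² + n₂²) with n ~ N(0, S0/SNR). The
gradient scheme mirrors the acquisition: 126 Fibonacci-spiral half-sphere
directions at b = 2000 with 8 b0 volumes interleaved (one preceding each
block, as acquired in separate scans). Phantom geometries: a 20 mm
straight tube (3×3 voxel cross-section, 0.5 mm voxels, ~1 mm endpoint
ROIs), a 90° in-plane crossing, and isotropic volumes.

## Functional preprocessing

Order: nuisance regression → in-plane smoothing → bandpass → normalize.

* **Nuisance regression.** One OLS per voxel against intercept +
  centered-time polynomials (orders 1..2) + respiration + 6 motion
  columns; linear detrending is subsumed by the drift columns (equivalent
  to detrend-then-regress when the columns are in the design). All-zero
  columns are dropped; a rank-deficient design is an error. Residuals are
  orthogonal to every column to ≤ 1e−8 relative by construction.
* **Smoothing.** Strictly in-plane 2-D Gaussian, σ = FWHM/(2√(2 ln 2))
  per axis converted to pixels (FWHM 0.3 mm on 0.182 mm pixels →
  σ ≈ 0.70 px). Edge handling divides by the smoothed indicator
  (renormalized kernel): constants are preserved exactly and interior mass
  is conserved to machine precision. A plain Gaussian stands in for the
  edge-preserving variant some toolchains use; at sub-2-pixel FWHM the
  difference is negligible.
* **Bandpass.** Order-4 Butterworth, applied forward-backward
  (zero-phase), 0.01–0.08 Hz. Zero phase preserves correlation timing;
  filtfilt squares the magnitude response, giving ≥ 40 dB rejection at
  0.15 Hz while the maximally-flat passband retains ≥ 99% amplitude at
  0.04 Hz. Series must exceed the filter warm-up pad (27 samples).
* **Normalization.** Per-voxel temporal z-score (ddof = 1);
  "normalized" is not uniquely defined in this tradition, but Pearson
  correlations are invariant under any per-voxel affine map, so the choice
  cannot affect connectivity. Zero-variance voxels are zeroed and flagged.

## Connectivity

Fisher z = atanh(r) with |r| clipped at 1−1e−7 (perturbs realistic values
by < 1e−7, keeps degenerate synthetic inputs finite; clipped edges are
counted in metadata). The averaging order is fixed: transform per subject
(or per voxel pair), then average — never average r first. Intra-node
strength is the mean over all unordered voxel pairs within an ROI of the
pair's z; pairs with a degenerate voxel are excluded and counted.
Hemisphere handling: left/right ROI labels sharing a name can be merged
into hemisphere-independent nodes (`merge_hemispheres`), the default
analysis mode.

Expected recovery precision: with the sample-exact generator the group
mean of edge z values estimates atanh(scale·C_ij) with residual error from
voxel noise (attenuation ≈ 1%, shrinking with ROI size) and band-edge
filter reweighting; the acceptance contract (within 2·SE,
SE = 1/√(n(T−3)), for ≥ 90% of edges) passes with ≥ 96% margin across
seeds.

## Group statistics

The connectivity samples fail Shapiro–Wilk normality screening (the screen
is report-level, not a per-edge gate), so inference is nonparametric:

* **Friedman, k = 2** (within-group time effect): implemented in-package
  because scipy requires k ≥ 3. Q = 12n/(k(k+1))·Σ(R̄_j−(k+1)/2)² with the
  standard tie correction; p from χ²(1), or exact by full sign-permutation
  enumeration (2ⁿ) for n ≤ 16. Fully tied edges are undefined (NaN). With
  n = 7 and every subject increasing, Q = 7, p ≈ 0.00815. Note the k = 2
  statistic is discrete (it is a sign test): attainable χ² p-values at
  n ≤ 8 jump between ~0.034 and ~0.157, so α-level calibration statements
  apply to the continuous-data Kruskal–Wallis track, not to Friedman.
* **Kruskal–Wallis + Dunn** (between groups per time point): H from scipy
  (tie-corrected); Dunn z = (R̄_i−R̄_j)/√((N(N+1)/12 − ΣT/(12(N−1)))(1/n_i+1/n_j)),
  two-sided normal p, multiplied by the 3 pairwise comparisons and capped
  at 1 (the Bonferroni-type family adjustment of the graphing packages this
  convention follows). Reported p-values are the adjusted ones.
* **Multiplicity.** No correction across edges, matching the per-edge
  reporting convention; `bh_adjust` provides an optional matrix-wide FDR.
  Significance tiers use strict inequalities: p < 0.05 (*), p < 0.005 (**),
  so p = 0.05 exactly is not significant while p = 0.0498 is.
* **Calibration.** The χ² Kruskal–Wallis approximation at n = (8, 8, 7)
  has true type-I error ≈ 0.045 at α = 0.05 (slightly conservative);
  measured over 10,000 null edges in the acceptance checks.

## Longitudinal slope

The global change index is the least-squares line through the origin over
the unique off-diagonal edges, x = earlier time point, y = later:
slope = Σxy/Σx², minimizing vertical residuals. Each edge enters once
(upper triangle), unweighted, from the group-average matrices (per-subject
pooling is possible by fitting per subject). The orientation is fixed by
the interpretation "slope > 1 = increase upon treatment"; swapping axes
gives Σxy/Σy², not 1/slope. For noise-free proportional matrices the slope
equals the scale factor exactly.

## Q-ball reconstruction

Real, even-order spherical harmonics to L = 8 (45 coefficients; 126
directions make the fit well-posed, and L = 8 is the standard order at
this direction count). Signal normalized by mean b0; coefficients from
(BᵀB + λ·diag(l²(l+1)²))⁻¹Bᵀs with λ = 0.006; ODF via the analytic
Funk–Radon transform, scaling order-l coefficients by 2π·P_l(0). Even-only
orders make the ODF antipodally symmetric by construction; increasing λ
monotonically shrinks the curvature penalty Σl²(l+1)²c².

The ODF is sampled on a 3-fold-subdivided icosphere (642 vertices, 321 per
hemisphere — the 8-fold tessellated icosahedron of the classical
implementations). Strict local maxima over the mesh adjacency (one
representative per antipodal pair) are refined by a tangent-plane
quadratic fit through the vertex and its neighbors (gnomonic projection;
the stationary point is accepted only if it is a nearby maximum), taking
peak accuracy from the ~7° mesh spacing to well under 1° on noiseless
phantoms. QA(peak) = ODF(peak) − min(ODF), normalized to [0, 1] by the
largest value in the mask; a constant ODF has no strict maxima, hence no
peaks and QA = 0.

## Tractography

Deterministic streamlines on the discrete peak field: nearest-voxel peak
lookup (no interpolation — matches discrete-peak deterministic tracking
and keeps the brute-force oracles exact). Seeds at uniform random
sub-voxel positions (reproducible from `rng_seed`) in voxels with top
QA ≥ 0.03; both directions from the seed voxel's strongest peak. Per step:
among peaks with QA ≥ 0.03 in the current voxel, take the one most
parallel to the incoming direction (sign-aligned); stop if none qualifies
or the turn exceeds 55°; advance 0.5 mm along
normalize(0.9·peak + 0.1·d_in) — the "0.1 weighting" is read as momentum
on the propagation direction. Halves are concatenated; lengths outside
5–120 mm are discarded. Tracking is a pure function of (peaks, config).

Fiber density: a streamline contributes once to every ROI pair it touches
(pass through or end in; membership by dense resampling of segments at
half-voxel spacing); density(i,j) = count/(voxels_i + voxels_j) — the
"voxel-normalized" denominator is the sum of the pair's voxel counts.
Densities below one fiber per voxel are zeroed; for groups, raw densities
are averaged first and the zeroing applied to the average (per-matrix
zeroing remains available via a flag).

## Problem sizes and determinism

Default analysis sizes: 16 block ROIs of 18 voxels on a 27×27×11 grid,
T = 105, 46 sessions; diffusion phantoms of ~4–6k voxels with 134 volumes,
one seed per eligible voxel. The full functional arm runs in seconds on
one core, each phantom arm in a few seconds. Every random draw descends
from one master seed via `numpy` SeedSequence spawning; both arms are
bit-reproducible, which the test suite and the acceptance script verify by
re-running.

## Known limitations

* Synthetic BOLD realism is limited to what the statistical contracts
  require (see above); no EPI distortion or registration errors.
* The Q-ball ODF is the classical analytic reconstruction, not
  constant-solid-angle or CSD; at b = 2000 its peaks are broad, which QA
  normalization absorbs but which limits crossing resolution below ~60°.
* Tracking uses nearest-voxel peaks; sub-voxel direction fields would
  require interpolation and would decouple the implementation from its
  enumeration oracles.
* Friedman inference at n ≤ 8 is inherently discrete; exact permutation
  p-values are provided but cannot make the test's level continuous.
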