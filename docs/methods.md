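# Methods

This document describes the model implemented by `arcomp`, the choices
behind its defaults, what the synthetic data generator does and does not
capture, and the numerical decisions that matter for reproducing its
results.

## 1. The two-stage trilinear model

### 1.1 Data representation

A resting-state EEG recording is reduced to a non-negative three-way
array (space × frequency × time) of amplitude spectral densities. The
short-time Fourier transform of channel *m* uses Hann-tapered windows:

    F_m(f, t) = (1/L) Σ_τ x_m(τ) w(τ − t) exp(−2πi f τ / fs)

with window length L samples. Cross-spectral densities between channels
are averaged outer products of these coefficients, normalized by
`2 / (mean(w²) · df)` so that the diagonal integrates to the one-sided
power spectral density; for the periodic Hann taper `mean(w²)` is
exactly 3/8. The amplitude spectral density (ASD) is the square root of
the CSD diagonal. Defaults: 5 s windows, 50 % overlap, band 5–15 Hz
inclusive — at 500 Hz this gives a frequency resolution of 0.2 Hz and
51 bins. Windows never straddle concatenation seams between recording
segments, and each window keeps the absolute-time phase factor so that
per-segment analyses pool exactly into the joint analysis. Windows in
which any channel exceeds a configurable absolute amplitude (default
100 µV) are discarded.

### 1.2 Non-negative PARAFAC

The ASD tensor is decomposed as a sum of K rank-one components,

    X[f, s, t] ≈ Σ_k A[f, k] · B[s, k] · C[t, k],   A, B, C ≥ 0,

fitted by hierarchical alternating least squares (HALS): each loading
column in each free mode is updated by its exact non-negative
coordinate-descent solution, which makes the explained variation
monotonically non-decreasing. Fits are multi-start (default 10 random
initializations) and the best fit wins. Scale indeterminacy is resolved
by pushing all scale into the first free mode and normalizing the other
free modes to unit maximum; permutation indeterminacy is resolved
downstream by congruence-based matching. Degenerate solutions are
flagged when two components exceed 0.98 congruence simultaneously in
all three modes.

The number of components is chosen with the core consistency diagnostic
(CORCONDIA): the least-squares Tucker core of the fitted loadings is
compared with the ideal superdiagonal core, and the largest K whose
core consistency is at least 90 % is selected. For K = 1 the diagnostic
is 100 by convention. The core is computed through mode-wise
pseudo-inverses, which is exact because the pseudo-inverse of a
Kronecker product is the Kronecker product of the pseudo-inverses.

### 1.3 Source imaging and the second stage

Scalp topographies are mapped to the cortex with a LORETA-style
distributed inverse on a three-shell concentric spherical head model
(radii 0.087 / 0.092 / 0.100 m; conductivities 0.33 / 0.0042 / 0.33
S/m). Lead fields for radial dipoles are computed from the per-degree
Legendre series of the layered-sphere potential, solving the 5 × 5
interface-condition system per degree; the homogeneous-sphere closed
form `(2n+1)/n` is kept as an analytic oracle for tests. Gains are
common-average referenced and rescaled so the largest absolute entry
is 1.

Sources live on a quasi-uniform Fibonacci lattice restricted to a
spherical cap (z/r ≥ −0.2) at 92 % of the brain radius — a crude
cortical sheet that keeps all sources under the electrode cap
(electrodes at z/R ≥ −0.35). The inverse is
`T = M Kᵀ (K M Kᵀ + αH)⁺` with the source metric M the inverse of the
squared depth-weighted graph Laplacian of the lattice (weighted
minimum norm, `M = Ω⁻²`, is available as an alternative). The default
regularization is 5 % of the mean eigenvalue of `K M Kᵀ`.

Because each windowed CSD is rank one, the source ASD can be computed
directly as `sqrt(norm) · |T φ|` without materializing any
sources × sources matrix; this fast path is bit-equivalent to the
explicit congruence `T · CSD · Tᴴ` and is what the pipeline uses.

The second PARAFAC stage decomposes the source ASD tensor with the
frequency and temporal loadings held fixed at the sensor-stage
estimates, so only the source-space loadings are estimated. This keeps
the component identities pinned between the two stages.

### 1.4 Component screening and labeling

Sensor-stage components are rejected as noise if the spectral flatness
of the frequency loading (geometric over arithmetic mean) exceeds 0.7,
or if less than half of the spatial loading mass lies over posterior
channels. The paper-level vocabulary is then applied to what remains:
with two retained components the higher-frequency one is ARC1 and the
lower ARC2; with three, the two higher-frequency ones are ARC1a/ARC1b;
a single component stays "unclassified". Peak-frequency ties are broken
by component magnitude.

### 1.5 Group statistics

The ARC1-vs-ARC2 spatial contrast uses a one-sided paired cluster-based
permutation test on the source lattice: per-source paired t values,
cluster-forming threshold at the 99th percentile of t(n−1), clusters as
connected components under lattice adjacency scored by summed t, and a
max-cluster-statistic null from within-subject sign flips. Sign flips
leave per-source sums of squares invariant, so permuted t maps need
only flipped sums — the permutation loop is a single matrix product
plus cheap clustering of suprathreshold nodes. P-values use the strict
count `(null > observed)/n_perm`, clipped below at `1/n_perm`; the
`(count+1)/(n_perm+1)` convention is available via `plus_one=True`.

Replicability is quantified by the Tucker congruence coefficient
(TCC), with 0.85 read as "highly similar" and 0.95 as "nearly
identical"; session-to-session component matching is greedy on
congruence. Temporal stability across resting periods uses per-period
means of max-normalized temporal loadings and a one-way
repeated-measures ANOVA computed from explicit sums of squares.

## 2. Synthetic data generator

No public recordings with known component structure exist, so every
claim is validated against a generator with exact ground truth. A
recording is the sum of:

* **Oscillatory patches.** Each alpha component is band-pass filtered
  Gaussian noise (Gaussian spectral profile; defaults 10.4 Hz / 1.0 Hz
  FWHM and 9.4 Hz / 1.2 Hz FWHM) multiplied by a non-negative envelope
  (rectified low-pass Gaussian noise, ~8 s timescale), placed on a
  compact Gaussian spatial patch of the source lattice and projected
  through the lead field. The default scenario has an occipito-parietal
  and a left occipito-temporal patch.
* **1/f background.** One hundred randomly placed lattice sources
  carrying independent 1/f-spectrum noise, so the background is
  spatially correlated through the head the way real EEG background is.
* **White sensor noise** (1.5 µV SD).

Amplitudes are calibrated so the posterior alpha peak stands roughly
6–7× above the background spectrum — recoverable but not trivial — and
peak sample amplitudes stay below the 100 µV artifact screen. The
ground truth records, per patch: the Gaussian frequency profile on the
analysis grid, the source-lattice spatial weights, the channel-space
profile |K·w|, and the per-window RMS of the envelope on the exact
STFT window layout.

What the generator deliberately does not model: non-radial dipole
orientations, realistic head geometry, correlated or non-stationary
artifacts beyond the optional frontal broadband patch, heart/eye
rhythms, and inter-subject anatomical variability. Group-level
simulations therefore exercise the statistics, not anatomical realism.

## 3. Numerical choices

* **HALS over multiplicative updates or generic NNLS.** Column-wise
  exact updates give monotone convergence, cost O(rank) linear solves
  per sweep, and handle fixed modes naturally (fixed modes are simply
  never updated and are returned bit-identical).
* **Convergence.** Fit-change tolerance 1e-8 with at most 2000 sweeps
  per start. Tests that require machine-precision recovery tighten this
  locally rather than globally.
* **CORCONDIA via Kronecker pseudo-inverses** rather than a dense
  normal-equations solve: exact and O(K³ + K·size) instead of building
  the size × K³ design matrix. The dense solve is kept as a test
  oracle.
* **Series truncation.** Lead-field Legendre series are truncated at
  degree 200 and evaluated in radius-normalized units (outer radius 1)
  so high-degree powers cannot overflow; with the source at 92 % of the
  brain radius the terms decay like (0.8)ⁿ and degree 200 is far past
  convergence.
* **Sign-flip invariance.** The permutation null exploits the fact
  that sign flips leave per-source sums of squares unchanged, reducing
  each permutation's t map to one matrix-vector product.
* **Reproducibility.** All stochastic stages derive their generators
  from a single `numpy` `SeedSequence`; the same seed reproduces the
  same decomposition bit for bit on the same dependency versions. Runs
  invoked through the CLI write a log with the package version, the
  configuration hash, and the seed.

## 4. Problem sizes

The default problem sizes are the package's own choices, selected to
make a single-subject analysis interactive on one CPU: 62 channels,
387 sources, 240 s recordings in four 60 s segments, K searched up to
6 with 10 random starts. A full two-stage decomposition of one such
recording takes on the order of half a minute on a single CPU;
simulation studies in the test suite reuse one lead field across
replicates. Smaller geometries (24 channels, 80 sources) are used in
unit tests where the claim under test does not depend on grid density.

## 5. Limitations

* The spherical three-shell model with purely radial dipoles is a
  deliberate simplification; absolute localization accuracy is not a
  goal, and the source lattice is labeled by crude angular sectors, not
  anatomy.
* LORETA's spatial smoothing biases recovered patch loadings toward
  their surroundings; recovered-vs-true spatial congruences on the
  default scenario sit around 0.85–0.95 depending on patch depth and
  size, not at 1.
* The core-consistency selection rule inherits CORCONDIA's known
  conservatism on noisy data: with short recordings (few spectral
  windows) it can fall back to fewer components than were planted.
* The cluster permutation test controls the familywise error rate per
  contrast; the two one-sided contrasts are reported separately and are
  not jointly corrected.
* Amplitude units are arbitrary after lead-field normalization; only
  ratios (component magnitudes, posterior fractions) are meaningful.
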