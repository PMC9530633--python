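# Methods

## Data model

A **spectral cube** is an (H, W, B) array of non-negative reflectance
intensities with a strictly increasing wavelength axis; the default
acquisition grid is B = 150 bands over 470–900 nm. Cubes travel as ENVI
header/binary pairs (band-sequential, little-endian float32, wavelengths in
the header), the common interchange format of hyperspectral tooling. Cubes
are assumed to already be in reflectance units; whether and how the source
instrument was white-referenced is outside the package's knowledge, so no
radiometric correction is applied. The only built-in preprocessing is an
optional per-pixel mean normalisation (`preprocess_cube(mode="per_pixel_norm")`,
off by default) that removes brightness variation while preserving spectral
shape.

A **basis spectra set** holds pure-component reference spectra — plasma, red
blood cells (RBC), the empty filter substrate that carries the aspirate, and
water ice (samples are imaged frozen) — on a wavelength grid, as CSV. Basis
spectra are resampled to the cube grid by piecewise-linear interpolation
(exact at shared grid points; extrapolation refused).

## Pixel classification (two-pass k-means)

Pixel spectra are clustered with Lloyd's algorithm under squared Euclidean
distance, k-means++ initialisation (scikit-learn's initialiser), best of
`n_restarts` = 25 restarts by within-cluster sum of squares (SSE), stopping
when the largest centroid shift falls below `tol` = 1e-6 or after
`max_iter` = 300 iterations. The per-iteration SSE trace is kept on the
fitted model; Lloyd descent guarantees it is non-increasing, and the test
suite asserts both this and, on small enumerable instances, equality of the
best-restart SSE with the exhaustive-partition optimum. Empty clusters are
re-seeded at the point farthest from its centroid, deterministically.
Assignment ties break toward the lowest cluster id. Everything is
deterministic given the seed (default 0).

The first pass uses K = 11 on pixels **pooled across all samples**: pooling
is essential, because per-sample fits would give each sample its own
centroid identities and the resulting fractions would not be comparable
across patients (per-sample fitting remains available behind a flag). The
second pass re-clusters thrombus pixels only, with K₂ = 7, again pooled; a
sample's **k-fractions** f₁…f₇ are the shares of its thrombus pixels per
cluster. Σf_k = 1 by construction, and permuting cluster ids permutes f
without changing the multiset. Samples with fewer than K₂ thrombus pixels
yield a flagged degenerate profile rather than fabricated fractions. K = 11
and K₂ = 7 are conventional defaults for this assay, exposed as parameters.

**Thrombus-cluster selection.** Thrombus is spectrally an RBC/plasma
mixture, so by default a cluster is selected when its centroid has cosine
similarity ≥ 0.98 to its best non-negative combination of the RBC and plasma
basis spectra and is not better explained by a filter/ice combination. This
rule cannot separate thrombus from contaminating whole blood — both are
RBC/plasma mixtures; spatial context or operator knowledge is needed for
that — so an explicit id override (`thrombus_ids`) reproduces manual
assignment, and the automated rule is treated as a screening default. An
empty automatic selection raises a warning rather than failing.

## Linear unmixing

Each pixel spectrum is fitted to an offset plus the four basis spectra by
least squares. Default mode is NNLS: the four component weights are
constrained non-negative (reflectance contributions are additive; the offset
c₀ stays free). The free offset is handled exactly by writing c₀ = a − b
with a, b ≥ 0 and solving one non-negative least-squares problem on the
augmented design — exact, and much cheaper per pixel than a general
bound-constrained solver. OLS mode (unconstrained, minimum-norm
via `lstsq`, all pixels in one shared factorisation) exists for closed-form
cross-checks; on every pixel OLS χ² ≤ NNLS χ² since the constraint can only
raise the optimum. χ² is the residual sum of squares with dof = B − 5; no
acceptance level is imposed — χ²/dof is reported and judgement left to the
user. A rank-deficient design (e.g. two proportional basis spectra) yields
the minimum-norm solution plus a flag, not a failure.

## Cohort analysis

IMR = hyperaemic mean distal coronary pressure (mmHg) × mean hyperaemic
transit time (s), in U. Dichotomisations use strict inequalities: IMR > 40 U
(clinically significant), MVO > 1.55 % of LV mass (prognostically
significant), severe microvascular dysfunction = both. The
thrombectomy-adequacy filter keeps records with angiographic thrombus score
∈ {4, 5} AND thrombus area fraction ≥ 0.22 (the threshold is a stated
minimum, hence ≥; lower scores are excluded regardless of area). The filter
returns a per-record audit trail and is idempotent and order-independent.

Four regression families link an injury index y to the k-fractions:
linear y = c₀ + Σc_k f_k; power y = c₀·Πf_k^{c_k}; exponential
y = c₀·exp(−Σc_k f_k); saturating exponential y = c₀·[1 − exp(−Σc_k f_k)].
The linear family is solved in closed form (minimum-norm, with the classical
overall-F p-value as a reference); nonlinear families use multi-start
`scipy.optimize.least_squares` (default 20 starts: one linearisation-derived
start — log-linear for exp/power, a saturation-anchored transform for
sat_exp — plus seeded perturbations; best SSE kept; SSE tolerance 1e-10).
R² = 1 − SSE/SST about the target mean; R² > 0.2 is labelled biologically
notable. Records missing one target still contribute to the other target's
fit.

**Gauge freedom.** Because Σf_k = 1, the linear and exponential families are
over-parameterised: adding δ to every c_k is absorbed by the intercept
(linear) or by rescaling c₀ (exp). Predictions and R² are unaffected, but
individual coefficients are only identified up to this shift. Reported
exp-model coefficients are therefore canonicalised to min_k c_k = 0; the
linear fit reports the minimum-norm solution. Tests that assess coefficient
recovery align the gauge (least-squares shift) before comparing to truth.
The power and saturating-exponential families have no such freedom.

**p-values.** The primary p-value is a permutation test: the target is
shuffled across records B times (default 999) and the model refitted;
p = (1 + #{R²_perm ≥ R²_obs}) / (B + 1). Permuted refits use a reduced
multi-start count (max(1, n_starts/5)) — under the null the fitted surface
is flat and extra starts change R²_perm negligibly, while the observed fit
keeps the full multi-start budget; this keeps the test affordable without
biasing it (calibration is verified empirically: null rejection at α = 0.05
stays within [0.02, 0.09] over 500 replicates). Power-model fractions are
floored at 1e-6 before exponentiation so zero fractions cannot produce
infinities.

## Synthetic data

The generator exists because patient datasets of this kind are not publicly
deposited; it provides ground truth for every stage.

**Basis spectra** are smooth analytic shapes with a small seeded smooth
jitter: RBC is low in the green with oxyhaemoglobin-like absorption dips at
542 and 577 nm and a steep rise above ~600 nm to a red/NIR plateau; plasma
is bright with a gentle upward slope; filter is near-flat; ice is flat with
a mild blue-end elevation. All values lie in (0, 1]. The exact shapes are
free parameters of the simulation — only the qualitative haemoglobin
signature matters for discriminability.

**Scenes** are disjoint regions (filter background, ice patch, blood patch
at 90 % RBC / 10 % plasma, and by default three thrombus blocks at 70/30,
50/50 and 30/70 RBC/plasma) whose pixel spectra are the region-weighted
basis mixtures plus additive Gaussian noise truncated at zero — the simplest
noise model consistent with non-negative reflectance. Ground truth (region
map, true mixing weights, thrombus mask, true area fraction) is returned
alongside the cube. The default 64×64 scene is used throughout testing; the
"5 % noise" condition means noise s.d. = 0.05 × (max − min) of the noiseless
cube.

**Cohorts** sample k-fraction vectors from a symmetric Dirichlet
(concentration 1.0 = uniform on the simplex), generate the target from a
chosen family with known coefficients plus Gaussian noise, and attach
thrombus scores (4–5 by default, optionally a share of lower scores) and
area fractions straddling the 0.22 threshold (70 % above by default) so the
adequacy filter has both classes to act on. For IMR targets, consistent
P_d and T_mn columns are emitted (P_d × T_mn = IMR). The default exponential
coefficients (c₀ = 150; c_k = 0…6) give a response spanning roughly 2–55 U
— an IMR-like dynamic range with genuine curvature over the sampled simplex.
Noise levels quoted as "x % of the y-range" use a fixed 2000-draw Dirichlet
probe with a constant seed, so the noise level is a reproducible study
condition, not a per-run random quantity (`reference_noise_sd`).

What the generator does **not** emulate: realistic tissue optics (scattering,
specular glints), camera noise models, spatially correlated composition
gradients, or the empirical joint distribution of thrombus composition and
clinical indices. Passing tests therefore demonstrate correctness of the
algorithms under the stated generative model, not clinical performance on
patient data.

## Problem sizes and determinism

Test and acceptance computations use 64×64×150 cubes (4 096 pixels), cohorts
of n = 100–200, 50–100 Monte-Carlo replicates, and 500 null fits at B = 199
permutations — sizes at which every stage's property is measurable with
comfortable margins on a single CPU. All randomness flows through explicit
integer seeds (numpy `default_rng`; the k-means++ initialiser through a
`RandomState`), and two runs of the full pipeline with identical
configuration produce byte-identical output CSVs.

## Known limitations

- The RBC/plasma-similarity rule cannot distinguish thrombus from
  contaminating whole blood without operator input (see above).
- k-fractions depend on the pooled cluster basis: adding samples to the pool
  can relabel clusters and change all profiles; comparisons are only valid
  within one pooled fit.
- Nonlinear fits report a convergence flag; the saturating-exponential
  family has a flat direction when the data do not constrain saturation
  (c₀ → large), in which case coefficients are reported with
  `converged=False` and only predictions should be trusted.
- The permutation p-value is exchangeable-null exact only up to the reduced
  multi-start approximation noted above.
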