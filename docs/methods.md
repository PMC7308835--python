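# Methods

## Problem

Free proline (FP) is an osmolyte that accumulates in rice leaf tissue under
cadmium stress. `prolspec` implements the full chemometric workflow for
estimating FP (mg/g fresh weight) from visible/NIR reflectance hypercubes:
radiometric calibration, leaf segmentation, spectral averaging, multivariate
calibration, wavelength selection, and pixel-wise concentration mapping.
Because no public hyperspectral rice/FP dataset exists, the package ships a
synthetic-study generator with known ground truth; every claim the tests make
is a claim about recovery of planted signal, not about real leaves.

## Wavelength grid

The emulated line-scan spectrometer covers 400–1000 nm; analyses use 350
consecutive effective bands in 500–950 nm. The local sampling interval is
affine in wavelength, d(λ) = α + βλ with α = 1.12158 nm and
β = 2.13647·10⁻⁴, making the band centre at detector index k

λ(k) = (λ₀ + α/β)·e^{βk} − α/β,  λ₀ = 502.245 nm.

Spacing grows from ≈1.23 nm at the blue end to ≈1.32 nm at the red end. The
three constants were calibrated against the 27 characteristic wavelengths
printed for the reference instrument's CARS selection; each lies within
0.04 nm of a band centre of the default grid (the conformance tests assert
0.15 nm). A quadratic (spacing affine in *index*) cannot do better than
≈0.5 nm and was rejected.

## Synthetic study design

The generator reproduces the reference study layout verbatim: Cd²⁺ at 0
(control), 5, 25, 50 and 100 µM; sampling after 5, 10, 15 and 20 d; 5
samples per (concentration, day) group; each sample the average of 4 leaves
— 100 samples, 400 leaves.

**FP trend table.** Only day-level pooled statistics are available
(mean/SD/min/max for n = 25 per day), plus the ordinal story: at 5 d mild
stress (5 µM) raises FP while higher doses depress it below control; by
15–20 d FP increases monotonically with dose and the control is lowest. The
per-group means in `DEFAULT_TREND` are chosen so that (a) each day's five
group means average exactly to the published day mean (0.1027 / 0.1335 /
0.1622 / 0.1880 mg/g), (b) the ordinal story holds, and (c) between-group
spread plus the within-group SD reproduces each day's pooled SD (exactly for
day 5: 0.0172; within ~10 % elsewhere). The table is editable config, not
ground truth. Per-sample FP is Gaussian around its group mean; per-leaf FP
scatters around the sample value (SD 0.005 mg/g) and is recentred so the
4-leaf mean equals the sample value exactly.

**Forward model.** Leaf-tissue reflectance is a green-leaf baseline (green
bump at 550 nm, red edge at 715 nm, NIR plateau ≈0.5, water shoulder toward
970 nm) plus three stress-scaled nuisance components — pigment (chlorosis
brightens the visible), dry matter (spectral tilt), water (NIR shoulder
lift) — minus an FP-linked absorber:

r(λ) = baseline(λ) + a_pig·pig(λ) + a_dry·dry(λ) + a_wat·wat(λ)
       − 0.45·FP·g(λ) + ε(λ)

g(λ) is a sum of narrow (σ = 0.7 nm) Gaussians at six informative bands —
601.37, 625.18, 626.44, 650.34, 689.56 and 943.52 nm snapped to grid
centres — with relative strengths 0.33/0.30/0.28/0.33/0.32/1.00. The
visible-band strengths are bounded by the ≈0.07 visible baseline
(reflectance must stay positive at the deepest dip); the NIR band is
strongest because it must stand out against the water component's flank.
Abundances are drawn per leaf with means proportional to a stress index
s = (day/20)·log(1+Cd)/log(101) and are deliberately weak
(0.005–0.008·s) so stress-aligned nuisance variation cannot cancel the FP
dip at overlapping bands. Band noise on a leaf mean spectrum is iid Gaussian
with SD 0.004 reflectance — the repeatability of a pushbroom imager after
averaging a few hundred pixels, and the property that makes the six planted
bands mutually non-redundant, so a selection method that drops one pays a
measurable RMSECV cost.

**Cubes.** `render_leaf_cube` draws a tapered leaf blade (sin^0.7 width
profile) on a 48×40 frame; per-pixel FP is the leaf value times a linear
tip-to-petiole gradient over [0.9, 1.15], normalised to mean 1 over the mask
so the leaf mean is preserved. Background pixels carry flat 0.05
reflectance; per-pixel band noise has SD 0.004. `make_dataset` writes raw
intensity cubes (dark + reflectance·(white − dark), halogen-lamp white
profile) so the calibration stage is exercised honestly.

**What the generator does not emulate:** radiative transfer (PROSPECT-style
leaf optics), specular effects, spatially correlated noise, instrument
smile/keystone, or any chemistry of the ninhydrin assay. Passing tests show
the pipeline recovers planted, approximately linear signal at realistic
noise; they say nothing about the spectral detectability of FP in real
leaves.

## Calibration engines

All hyperparameters are selected at the minimum leave-one-out RMSECV
computed by literal per-fold refits (no PRESS shortcuts), ties broken toward
the simpler model; reported RMSECVs are therefore exactly what a naive
double loop computes, and the test suite checks this against independently
written loops.

- **PLS** — NIPALS on mean-centred X and y (no autoscaling: reflectance
  bands share one unit), regression vectors for all component counts from a
  single decomposition, LV chosen over 1..min(n−1, p, 15). At full rank the
  coefficients equal centred OLS (tested at 1e−8); coefficients also match
  scikit-learn's PLSRegression. The regression vector **b** is the Bw
  profile used by the selectors.
- **LS-SVM** — RBF kernel K = exp(−‖xᵢ−xⱼ‖²/sig2); the dual KKT system
  [[0, 1ᵀ], [1, K + I/gam]]·[b; α] = [0; y] is solved densely. The
  (gam, sig2) pair is grid-searched over 10⁰..10⁷ × 10⁰..10⁶ (8×7
  log-spaced) and refined once on a 5×5 half-decade grid around the
  optimum. The KKT residual of the returned model must be ≤1e−8 (scaled).
- **ELM** — single hidden sigmoid layer; input weights and biases are
  uniform(−1, 1) draws from a recorded seed; output weights by least
  squares. Inputs are min-max scaled to [−1, 1] with a single global
  (min, max) pair rather than per band: reflectance bands share a physical
  unit, and per-band scaling inflates low-variance noise bands into unit
  amplitude, degrading the random features badly (held-out r 0.74 vs 0.99
  on the default study). Node count is searched over 1..n_train by LOO
  RMSECV; a `selection="rmsep"` switch reproduces the reference study's
  literal procedure (minimum RMSE on the prediction set), which leaks the
  prediction set into model choice and is therefore not the default.

## Wavelength selection

- **CARS** — at iteration i of N (default 50): Monte-Carlo subsample 80 %
  of calibration samples, fit PLS (10 LV cap), rank bands by |b|; the
  enforced retention ratio follows the exponentially decreasing function
  rᵢ = a·e^{−ki} with a, k fixed by r₁ = 1 and r_N = 2/p; the survivors
  then pass adaptive reweighted sampling — a weighted bootstrap (n_keep
  draws with replacement, probabilities ∝ |b|) whose unique survivors are
  retained, so realized counts can fall below the EDF curve when the
  coefficient profile is spiky. Each iteration's subset is scored by LOO
  RMSECV of a PLS model on all calibration samples; the minimum-RMSECV
  subset is returned. Retained counts are non-increasing by construction.
- **Bw** — strict interior local maxima and minima of the signed PLS
  regression vector (plateaus excluded), optionally filtered by an |b|
  quantile.
- **GA** — binary chromosomes over bands; fitness −(LOO RMSECV of a 10-LV
  PLS on the encoded bands), cached by chromosome; tournament selection
  (size 2), single-point crossover (p = 0.6), bit-flip mutation (p = 0.01),
  elitism of one; population 30, 100 generations. All-zero chromosomes get
  −∞ fitness and cannot be returned.

## Evaluation

The calibration/prediction split ranks samples by FP and sends the third of
every four to prediction (trailing partial blocks go to calibration), which
keeps the prediction set interior to the calibration range: 100 → 75/25.
Rc/RMSECV come from LOO refits on the calibration set with hyperparameters
held fixed; Rp/RMSEP from the untouched prediction set. R metrics are
Pearson correlations between predicted and reference values; a constant
prediction vector yields R = 0 with a warning. Per-band group comparisons
use one-way ANOVA (concentration within day, matching the study's four
panels); group mean comparisons use Tukey HSD at α = 0.05 summarised as a
compact letter display (insert-and-absorb), with letters ordered by group
mean.

## Pipeline

`run_pipeline` produces the 12-cell report ({full, GA, CARS, Bw} × {PLS,
LS-SVM, ELM}) plus a day × concentration map panel rendered with the
best-Rp cell's model on one leaf per group, using a shared 1st–99th
percentile display range; negative pixel estimates are clipped only for
display. By default the 100×350 modelling table is drawn directly from the
leaf-level forward model — statistically equivalent to rendering all 400
hypercubes and extracting masked means, at a small fraction of the size and
I/O — while the full cube path (write → correct → segment → average) is run
end-to-end on reduced designs in the tests. The simulated table is cached
in the run directory keyed by a config hash. The default run sizes (50 CARS
iterations, 30×100 GA, LOO everywhere at n = 75) complete in a few minutes
on one core.

## Numerical choices and degenerate inputs

- NIPALS stops early when the residual is numerically exhausted; later LV
  counts reuse the last valid regression vector.
- Constant y, zero-variance X, empty masks, empty selection sets, inverted
  windows and non-positive hyperparameters raise `ValueError` before any
  computation.
- Rank-split ties are broken by original index (stable sort).
- Reflectance correction guards white − dark ≤ 0 and clips to [0, 1.5]
  (specular ceiling); references are row-averaged by default, configurable
  off.
- Segmentation thresholds the band nearest 800 nm at 0.25 reflectance and
  keeps the largest connected component; leaves under 50 px are rejected.

## Known limitations

- The per-group FP trend table is a calibrated stand-in; only its day-level
  pooled statistics are anchored to published numbers.
- The forward model is linear in FP, so the nonlinear engines cannot
  demonstrate an advantage on synthetic data; their tests verify numerical
  correctness, not superiority.
- CARS subset sizes on synthetic data (≈150 bands at default noise) are
  larger than typical real-data selections: with six redundant planted
  bands plus white noise, pruning beyond the planted set buys little
  RMSECV, so the minimum sits earlier in the schedule than on real spectra.
- GA fitness evaluation dominates pipeline runtime; chromosome caching
  mitigates but does not remove this.
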