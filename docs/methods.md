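# Methods

This note documents the models, numerical choices, and synthetic study
design behind `rapeyield`, and what the passing test suite does and does
not demonstrate about real imagery.

## Linear mixing model and FCLS

A pixel's band reflectance vector is modeled as ρ = E·a, where the columns
of E are the flower (FL), leaf (LF) and soil (SL) endmember spectra
resampled to the sensor's bands and a is the abundance vector on the
probability simplex (a ≥ 0, Σa = 1). The model assumes a single linear
mixing scale — no multiple scattering between components, no within-class
spectral variability, no BRDF or illumination effects.

**Solver.** With three endmembers the fully constrained least-squares
problem is a tiny quadratic program. We solve it exactly by enumerating the
2³−1 = 7 candidate active sets: for each support the sum-to-one
equality-constrained least squares is solved through its KKT system, and
the best feasible candidate is the global optimum. This guarantees simplex
feasibility to machine precision (the package treats Σa = 1 within 1e-9 as
a hard invariant, checked per pixel in tests) and is deterministic. Under
rank deficiency the KKT system is solved by pseudo-inverse, giving the
minimum-norm solution as the tie-break. The classical sum-to-one-augmented
NNLS formulation (penalty weight 10³) is retained in the test suite as an
independent cross-check, as is an exhaustive simplex-lattice search oracle.
Supports are visited largest-first so interior solutions win exact ties.
Candidates with any coordinate below −1e-10 are rejected as infeasible;
accepted solutions are clipped to [0, 1] and renormalized, a correction of
order 1e-12.

**Residual.** Per pixel we report ‖E·a − ρ‖₂/√B, a per-band RMS, so
six-band UAV and four-band satellite residuals are on the same scale.
Pixels with reflectance above 1 (possible after calibration) are unmixed
as-is; no residual-based rejection is applied by default.

## Band resampling

Sensors are described by center@FWHM pairs. The spectral response is taken
as a boxcar over [center − FWHM/2, center + FWHM/2], integrated by the
trapezoid rule on the spectrum's native (1 nm) grid with interpolated
endpoints. This is the simplest defensible response model and makes the
operation exactly testable (a constant spectrum resamples to itself; the
operation is linear in the spectrum). Real relative spectral response
curves are configuration, not code: any sensor can be declared in JSON.
The generic 4-band satellite preset reuses the UAV centers
(blue 490, green 550, red 670, NIR 800 nm, FWHM 10 nm) so synthetic
satellite scenes can share one spectral library.

## Empirical-line calibration

Per band, reflectance = gain·DN + bias, fitted by ordinary least squares on
the panel observations (mean DN over each panel region; median available).
Negative calibrated reflectances are clipped to 0 and counted; values above
1 are kept but counted, preserving information for unmixing diagnostics.
The calibration round-trip test uses a *stratified reflectance sweep* as
its target: eight evenly spaced reflectance values inside every DN
quantization cell. On such a target the encode/decode error is a fixed
stratified population whose RMS is gain/√12·√(1−1/64), i.e. the nominal
uniform-quantization RMS rather than a seed-dependent fluctuation around
it — the appropriate design for verifying that reconstruction is
quantization-limited and calibration itself adds no error.

## Vegetation indices

All nine indices are expressed in band roles (blue/green/red/nir), so the
same formulas serve 6-band and 4-band sensors. Two typographical hazards in
common tabulations are resolved explicitly:

* **RDVI** is implemented as (ρ800−ρ670)/√(ρ800+ρ670), its original
  renormalized form; sources that typeset it identically to NDVI can be
  matched with `rdvi_variant="as_printed"`.
* **TVI** is 0.5·[120(ρ800−ρ550) − 200(ρ670−ρ550)].

Zero denominators produce invalid (NaN) pixels, counted and reported,
never infinities. Plot-level indices are computed from the plot's mean ROI
reflectance (the package default); averaging per-pixel indices instead is
available via `vi_convention="mean_pixel"` and demonstrably differs on
heterogeneous plots.

## Yield models and cross-validation

Each of the nine indices enters three linear families — VI, VI×Abd_FL,
VI×Abd_LF — fitted by OLS against plot yield and scored by leave-one-out
cross-validation. Conventions:

* **R²** is the mean of the per-fold *training* R² values (the only R²
  defined per fold); the pooled predicted-vs-observed R² is reported
  alongside for transparency and is typically slightly lower.
* **RMSE** = √(Σ Eᵢ²/K) over the held-out residuals, in kg/ha.
* **CV** = 100·RMSE/mean(observed yield), in percent. A literal per-fold
  variant (mean over folds of 100·|Eᵢ|/mean(y_train)) is available via
  `cv_variant="mean_fold"`.

Ranking is by R² descending with RMSE as tie-break. No multiple-testing
correction is applied across the 27 models; with 24 plots the ranking
should be read as descriptive, not inferential.

## Synthetic study design

The generator emulates a flowering-stage nitrogen trial:

| parameter | default | rationale |
|---|---|---|
| N rates (kg/ha) | 0, 45, 90, 135, 180, 225, 270, 360 | standard gradient design |
| replicates | 3 (24 plots) | small-plot trial size |
| plot size | 10×10 px, ROI inset 1 px | boundary-avoiding ROI |
| Abd_LF(N) | 0.2 + 0.5·min(N,225)/225 | rises 0.2→0.7, saturates at N225 |
| Abd_FL(N) | 0.22 − 0.04·N/360 | mild decline around 0.2 |
| plot random effects | sd 0.04 (flower), 0.02 (leaf) | plot-to-plot flowering variation |
| within-plot jitter | Dirichlet, concentration 300 | mixed-pixel heterogeneity, exact simplex |
| sensor noise | additive Gaussian per band, 40 dB SNR default | paper-style sensors are unspecified; additive is the simplest defensible model |
| yield | β0 + β1·(EVI_true×Abd_LF), noise sd 150 kg/ha (~6%) | leaf-driven yield; β set per trial so true yields span 1000–3500 kg/ha, peaking at N225 |
| DN encoding | 8-bit, gain 0.006, bias 0 | panels 0.06/0.24/0.48 land on integer DNs 10/40/80 |

The abundance–nitrogen curves are qualitative emulations of observed
trends, not measured responses; their functional forms are package
inventions and are configurable (`flower_trend`, `leaf_trend`). Soil
abundance is the simplex remainder, with random leaf draws clipped so soil
keeps a 0.02 floor; designs whose *trend means* break the simplex raise a
parameter error.

**What passing tests show — and don't.** Synthetic scenes obey the linear
mixing model exactly, with known endmembers and additive Gaussian noise.
Tests therefore verify the estimation machinery (calibration, FCLS,
aggregation, LOOCV) under the model's own assumptions. They do not show
robustness to endmember mis-specification, nonlinear mixing, canopy
structure/BRDF, atmospheric residuals, or georegistration error — all of
which affect real imagery.

**A structural finding worth knowing.** With yield generated from
EVI×Abd_LF, the leaf-product models for NDVI, RDVI and EVI reliably
out-score their plain-VI counterparts (mean LOOCV R² over 20 trials), but
plain VARI does *not* lose to VARI×Abd_LF in this generator: along the
linear mixing line VARI happens to be almost perfectly collinear with the
yield driver (corr² ≈ 0.995 in the noise-free limit) while VARI×Abd_LF
slightly overshoots its curvature (corr² ≈ 0.981). The effect persists
across seeds, flower-variation strengths and covariance structures
(flower trading against soil or occluding leaf), and with true or
estimated abundances. Field reports of large VARI improvements from
abundance weighting evidently rest on real-canopy behavior outside the
linear mixing model; a desk-scale linear simulation cannot reproduce them,
and the corresponding assertion in the acceptance tests fails by design of
the simulation rather than by an implementation defect.

## Numerical and I/O conventions

* Computation in float64; reflectance and abundance rasters stored as
  float32, DN rasters in their native integer dtype (bit-exact round
  trips).
* Pixel rectangles are 0-based and half-open: [row0, row1) × [col0, col1).
* Rasters are multiband TIFFs with the sensor model, band roles, panel
  coordinates and flags serialized as JSON in the ImageDescription tag;
  a round trip rebuilds the full object. Georeferencing is out of scope.
* The pipeline manifest records the seed, all convention flags
  (`rdvi_variant`, `cv_variant`, `vi_convention`), the fitted gains, and
  SHA-256 checksums of every output; identical seeds give byte-identical
  outputs.
* Problem sizes in the shipped tests and acceptance script — 24-plot
  trials of 10×10-pixel plots, 1,000-pixel unmixing batches, 20-trial
  Monte-Carlo summaries, simplex-grid oracle step 1e-3 — were chosen as
  the smallest sizes at which the checked statistics stabilize.

## Known limitations

* Three fixed endmembers; no endmember extraction (N-FINDR/VCA) or
  per-pixel endmember variability.
* Linear mixing only; no radiative-transfer canopy simulation.
* The 2×2 accuracy module generalizes to k×k arithmetically but is only
  exercised against 2×2 references.
* LOOCV R² (mean training R²) is an optimistic summary relative to pooled
  predictive R²; both are reported.
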