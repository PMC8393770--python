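# Methods

This note documents the models implemented in `ibernir`, the choices
made where standard practice leaves room, and what the synthetic data
do and do not establish.

## Spectral pre-treatment

Reflectance R in (0, 1] is transformed to absorbance A = log10(1/R).
Named pre-treatment presets operate on absorbance; a reflectance input
is converted automatically (the `"none"` preset leaves reflectance
untouched, matching the practice of comparing raw and pre-treated
models).

* **SNV** subtracts each spectrum's mean and divides by its own
  standard deviation (n−1 denominator). It removes per-sample
  multiplicative and additive scatter exactly when the underlying
  spectrum is shared.
* **Detrending** subtracts each spectrum's least-squares polynomial in
  wavelength (default degree 2). The fit uses a rescaled wavelength
  basis for conditioning; residuals are identical to the raw-nm fit
  because the column space is the same. `"SNV-DE"` applies SNV first,
  detrending second.
* **Savitzky–Golay derivatives** are parameterised as (derivative
  order d, left points l, right points r, polynomial order q), with
  the study's settings (1,4,4,1) and (2,5,5,2) as presets. Only
  symmetric kernels are allowed, the grid must be uniform, derivatives
  are per nm (scaled by the grid step, so results are step-invariant),
  and the output is trimmed to interior points — every emitted value
  comes from a full symmetric window, no asymmetric edge fits.

## Latent-variable engines

PCA and PLS both use NIPALS on mean-centered data (PLS1 for a single
response, PLS2 for multi-column responses such as the class dummy
matrix). NIPALS converges to ~1e−12 relative change in the score
vector; an SVD/least-squares route exists in the test suite only, as
an independent oracle. PCA components carry a deterministic sign
convention (largest-magnitude loading entry positive).

Leave-one-out cross-validation refits the model — **including the
centering** — in every fold, so no information leaks from the held-out
sample. Reported curves:

* RMSECV(a) = √(Σᵢ (yᵢ − ŷᵢ,cv)² / n)
* 1-VR(a) = 1 − Σ (yᵢ − ŷᵢ,cv)² / Σ (yᵢ − ȳ)²
* SECV(a) = bias-corrected standard deviation of the CV residuals
  (n−1 denominator). RMSECV and SECV differ only by the CV-residual
  mean; both are reported because both conventions circulate.

The number of latent variables A* is the smallest a whose SECV is
within a relative tolerance (default 2 %) of the curve minimum — a
concrete reading of "the error no longer decreases substantially".
The tolerance is exposed (`tol`) because no canonical value exists.

## Outlier screening

Screening fits a PCA (by default the number of components reaching
95 % explained variance, capped at 10) and flags samples on two
criteria:

1. **Residual rule** — standardized orthogonal residual
   (sᵢ − mean s)/SD(s) > 2, where sᵢ is the S-distance (root summed
   squared reconstruction residual). The distance is *centered* before
   scaling: raw S-distances concentrate around a large positive mean
   that grows with the number of channels, so an uncentered ratio
   would flag every sample on wide grids.
2. **Leverage rule** — leverage hᵢ = 1/n + Σₐ tᵢₐ²/Σ tₐ² above 3 ×
   the average leverage. Two average-leverage formulas are selectable:
   the hat-matrix average (1+A)/n (default) and the literal published
   expression 1/(n + A/n), preserved verbatim for reproducibility of
   the source protocol.

Flag–remove–refit is iterated (default at most 5 rounds) and stops
before the retained set would drop below 10 samples. Per-trait
screening before PLSR is what makes each trait model's n differ from
the full calibration count, as in the original report.

## Classification

* **PLS-DA** fits one PLS2 model against the 0/1 class-indicator
  matrix (one model for all three categories, consistent with a single
  reported LV count). A sample is assigned to the class with the
  largest predicted indicator; exact ties (tolerance 1e−9 relative)
  resolve to the first declared class and set an ambiguity flag.
* **SIMCA** fits one PCA per class (class-specific component counts;
  the study-like configuration is 2/1/2). Membership requires both
  (s/s₀)² below a critical value and leverage below 3 × the class
  average. The critical value is the 1−α quantile of the *null
  distribution of the residual quadratic form*: a weighted sum of
  χ²(1) variables whose weights are the eigenvalues of the
  (leverage-corrected) training residual covariance, evaluated by a
  deterministic Monte Carlo draw (4000 samples, fixed internal seed).
  Adjacent NIR channels are strongly correlated, so F-tables indexed
  by the nominal p−A residual dimensions are grossly anticonservative
  here; the quadratic-form quantile keeps the in-class acceptance rate
  near 1−α whatever the residual spectrum looks like. A sample can
  belong to one, several or no classes; multiple memberships resolve
  to the smallest combined normalized distance
  √((s/s₀)² + (h/h̄)²). For reporting, SE/SP are computed per class
  model on *membership* (one-vs-rest) — the only reading under which a
  class-modelling method can simultaneously show near-100 % SE and
  very low SP, the signature pattern of these data.
* **LDA** runs on the scores of a shared PCA compression: the smallest
  dimension reaching 99 % cumulative explained variance (configurable),
  capped at n−K−1 and reduced further if the pooled within-class
  covariance is singular. Classification is by minimum Mahalanobis
  distance to the class centroids under the pooled covariance with
  equal priors.

## Quantitative models

Each trait model runs: pre-treatment preset → per-trait outlier screen
→ LOO-CV over 1..A_max latent variables (default A_max 10) → SECV
selection → final PLS1 fit. External validation reports R²v, RMSEV,
RPDv = SD(y_val)/RMSEV and RERv = range(y_val)/RMSEV. R²v defaults to
the squared Pearson correlation (the common NIRS reading, insensitive
to slope/bias mismatch); `1 − SSE/SST` is available via
`r2_kind="ss"`. RPD/RER use the validation set's own SD and range,
which is what reproduces the published validation indices from the
published descriptive statistics; the cross-validation variant
(SD/SECV) follows from the same function applied to calibration
statistics. Validation spectra must carry the identical pre-treatment
provenance as the calibration set, enforced at call time.

## Synthetic data

The study's 185 spectra were never deposited, so the generator emits
data with the structure the analysis assumes, under the published
design: the exact per-stratum sample layout (3 categories × 4 storage
times, 185 packages, 138/47 calibration/validation manifest),
1000–2500 nm at 1 nm, and reflectance noise inflated tenfold above
1800 nm (the rationale for discarding that region).

Absorbance is built as: Gaussian baseline bands (C–H overtones, the
1450/1940 water bands) + class intensity offsets at 1090/1280/1640 nm
(White > Black ≈ Red, Black–Red separation a quarter of the White
offset) + a small class-specific band-shape component that separates
Black from Red + linear couplings of the eleven quality traits into
trait-specific signature bands + per-sample multiplicative/additive
scatter with a linear tilt; then R = 10^(−A) plus heteroscedastic
noise, clipped to (0, 1].

Key design choices:

* **Class information travels mainly through composition.** Trait
  class offsets follow the feeding regimes (Montanera classes higher
  in C18:3 n-3, oleic acid and α-tocopherol; the fodder-fed White
  class higher in linoleic and palmitic acid); the published tables
  give only pooled trait statistics, so the offsets are free
  parameters of the generator, sized to keep pooled statistics inside
  the published ranges. Because these class differences lie along
  directions that also vary within class, SIMCA class models absorb
  foreign samples (low SP) while discriminant methods still separate
  the categories — the mechanism behind the SIMCA-vs-LDA contrast the
  pipeline reproduces.
* **Traits**: pooled mean/SD/range anchored to the published
  descriptive statistics, with the variance budget split between class
  offsets, within-class spread and reference-measurement noise so the
  *measured* values reproduce the published SD. Right-skewed C18:3
  n-3 uses a shifted lognormal with multiplicative measurement error;
  all emitted values are clipped to the published ranges. Linolenic
  acid has the strongest spectral coupling (hence the best-predicted
  trait); the protein-carbonyl trait has **zero** coupling and serves
  as the built-in null trait (cross-validated R² ≈ 0).
* **Presets**: `paper_like` (the defaults above), `separable` (large,
  class-specific band effects, gentler scatter/noise — every
  classifier should be nearly perfect), `null` (no class information
  at all: direct effects off, trait offsets off).

What the generator does **not** emulate: storage-time drift (T0–T12 is
a stratification label only), instrument artefacts beyond
affine scatter + tilt, packaging-film interference fringes, and any
nonlinearity between composition and absorbance. Passing tests on
synthetic data therefore demonstrate the correctness and calibration
of the *algorithms*, not field performance on real packages.

## Problem sizes and runtime

The test suite and acceptance script use the full study geometry (185
× 1501 spectra, 801 channels after range selection) for single fits,
cross-validated PLS1 per trait, and classifier evaluation; simulation
loops (outlier-recovery sensitivity, null-response cross-validation)
use reduced panels (e.g. 60 × 40, 200 replicates) so the whole suite
runs in well under a minute. Larger validation draws (4× the study
layout) back the classifier-recovery checks to keep binomial noise
small.

## Known limitations

* NIPALS power iteration converges slowly when leading eigenvalues
  nearly tie; the tolerance is set tight (1e−12 relative) at some cost
  in speed.
* SIMCA's Monte-Carlo critical values have a small (±1 quantile-step)
  sampling error; with 4000 draws this moves acceptance rates by well
  under one percentage point.
* With a 5 % residual-test level, SIMCA's expected in-class
  sensitivity is 95 % by construction; demonstrations that require
  near-perfect sensitivity use a smaller α (the acceptance level is a
  model parameter, not a property of the data).
* The largest-remainder stratified split reproduces published totals
  only through the explicit per-stratum manifest; the original
  "manual and random" selection is not an algorithm and cannot be
  replicated exactly.
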