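# Methods

## Problem setting

Leaf nitrogen, phosphorus and potassium contents modulate reflectance in
the visible/NIR range (400–1000 nm), but weakly: pigment-driven features
(green peak near 550 nm, red valley near 670 nm, red edge between 680
and 760 nm) respond mostly to nitrogen status, while leaf structure,
thickness and scattering dominate the broad curve shape. The pipeline
implemented here separates the high-frequency detail of each spectrum
with an undecimated dyadic wavelet transform, screens every detail
coefficient position for correlation with each nutrient, and calibrates
regression models on the three strongest "sensitivity coefficients".
Models are compared by a composite score combining stability (modeling
R²), accuracy (validation MRE) and precision (validation NRMSE).

## Synthetic trial generator

No field data ship with the package; the generator produces trials with
the statistical structure the analysis assumes, at the scale of the
original experiment: three nitrogen treatments (N0 none, N1 low, N2
high), 24 leaves each, one averaged spectrum per leaf on a 400–1000 nm
grid with 1001 bands (0.6 nm spacing — chosen so that all detail-band
indices referenced in the sensitivity analysis, up to 706, exist;
configurable).

Per-treatment mean contents (mass percent of dry matter) satisfy the
trial's ratio structure exactly: N is 2.5% at N0, 1.28× that at N1 and
1.13× at N2 (luxury uptake then inhibition); P is 0.45% at N0, 1/1.47
of that at N1 and 1/1.93 at N2; K is 2.0% at N2 with N0 = 1.40× and
N1 = 1.37× that value. Absolute levels are generator conventions —
only the ratios are externally constrained — chosen as agronomically
plausible leaf values. Per-leaf contents vary around the treatment mean
with coefficient of variation 0.05 (truncated at 20% of the mean).

Each reflectance curve is a parametric sum:

* dark baseline ≈ 0.06, decreasing slightly with N (deeper pigment
  absorption);
* logistic red edge rising to a NIR plateau ≈ 0.46, centered at
  688 + 8·N nm (≈ 708–714 nm over the realistic N range), amplitude
  increasing mildly with K;
* green-peak Gaussian at 548 nm (σ = 16 nm), amplitude decreasing with N;
* four narrow Gaussian bumps at 480, 610, 670 and 820 nm (σ = 5–6 nm)
  whose amplitudes follow mild power laws of P, K, N and N respectively
  (exponents 1.2–1.5). These are the "fluctuation-sensitive" regions:
  they concentrate energy in the level-4/5 detail bands and give the
  wavelet channel its nearly clean, mildly nonlinear nutrient signal;
* per-leaf structural variability: a scattering amplitude factor
  (sd 8%) applied to the broad components only, and a
  nutrient-independent red-edge jitter (sd 2.5 nm);
* optional additive homoscedastic Gaussian band noise (default
  sd 0.004 reflectance units), then clipping to (0, 1).

The structural terms are what make the broad characteristic variables
imperfect proxies (feature–nutrient |r| ≈ 0.6–0.9, univariate modeling
R² ≈ 0.2–0.6) while the narrow-band detail remains informative
(sensitivity-coefficient |r| ≈ 0.7–0.95) — the qualitative regime in
which wavelet-based PLS/NN models outperform univariate feature models
and the network's extra flexibility pays off. What the generator does
**not** emulate: radiative-transfer physics (no PROSPECT/SAIL),
wavelength-correlated instrument noise, atmospheric or illumination
drift, within-leaf spatial heterogeneity, and any nutrient interaction
beyond the fixed treatment ratios. Passing tests therefore demonstrate
correctness and internal consistency of the pipeline, not field-level
predictive validity.

## Preprocessing

* Radiometric correction: I₀ = log₁₀[(I − I_D)/(I_W − I_D)] with white
  board I_W and dark board I_D, as in the source instrument's protocol;
  a plain-ratio mode is provided because the downstream feature windows
  presuppose reflectance-shaped curves. Bands where I_W ≤ I_D, or
  I ≤ I_D in log mode, are reported by wavelength.
* Replicate averaging: band-wise arithmetic mean (protocol default:
  four points per leaf).
* Outlier screening: squared Mahalanobis distance on the first three
  principal-component scores against a χ²(3) cutoff at quantile 0.999.
  No method is canonical for this step; this is a deliberately
  conservative choice that only flags gross anomalies.
* Split: uniform random modeling/validation split, round(2n/3) modeling
  (72 → 48/48+24), seeded; an optional treatment-stratified mode exists.

## Characteristic variables

First derivatives use centered differences ((R[i+1]−R[i−1])/(λ[i+1]−λ[i−1]),
one-sided at the ends). Window conventions (inclusive endpoints, bands
matched by nearest wavelength, ties to the lower band):
blue edge 490–530, yellow edge 560–640, red edge 680–760, green peak
510–560, red valley 650–690 nm. The green-peak and red-valley variables
(R_g, λ_g, R_r, λ_o) are reflectance extrema by default — the standard
red-edge-literature reading of their names — with a literal
first-derivative mode available; likewise areas SD_b/SD_y/SD_r/SD_g are
trapezoidal areas of the reflectance curve by default with a
derivative-area mode available. VI1–VI10 follow the usual definitions
(simple ratio R800/R680, red-edge model R750/R720 − 1, mSR705, mND705,
and ratio/normalized-difference combinations of the extrema and areas).

## Dyadic wavelet transform

The dyadic ("binary") wavelet transform fixes the scale at a = 2^j and
keeps per-band translation, i.e. the stationary (à-trous) transform:
every level j = 1..5 yields approximation A_j and detail D_j series of
the full grid length, indexable by band position — necessary because
the sensitivity analysis addresses individual detail coefficients at
specific band indices, which a decimated transform does not provide.
Implementation rides on PyWavelets (`swt`/`iswt`, `norm=True`, which
applies the 2^(−j/2) per-level normalization; Daubechies db2–db5).
Signals are padded symmetrically to a multiple of 2^levels and trimmed
back, so reconstruction is exact to floating precision (< 1e−8
tolerance asserted over 1000 random spectra). Coefficient indices are
0-based positions on the package's own grid.

## Selection and models

Candidate pool: every (basis, level, band) detail position across db2–db5
and levels 1–5 (20 series × n_bands candidates). Scoring: sample
Pearson r against the nutrient content; significance by the t test
(t = r√((n−2)/(1−r²)), df = n−2, two-sided; flags at 0.05/0.01). The
top k = 3 by |r| are selected (ties: basis order, lower level, lower
band). By default selection sees only the modeling subset, to keep the
validation set untouched — an intentional anti-leakage choice; an
all-samples mode exists for protocol fidelity.

* Univariate families: linear, parabolic and logarithmic by ordinary
  polynomial least squares; exponential y = a·e^{bx} by nonlinear least
  squares initialized at the log-linear solution (log-linear mode
  available). Domain violations (x ≤ 0 for logarithmic, y ≤ 0 for
  exponential) name the offending samples.
* PLS1 on the three selected coefficients, default 2 components
  (configurable; per-component X-variance reported), no predictor
  scaling, collapsed to intercept + 3 coefficients. With all components
  and full-rank predictors it coincides with ordinary least squares
  (asserted to 1e−8).
* Feedforward network: one hidden layer of 10 logistic units, linear
  output, inputs and target min–max scaled to [0, 1] on the modeling
  set, full-batch L-BFGS to tol 1e−6 or 2000 iterations, seeded and
  deterministic. These training details are declared package defaults —
  reasonable for a 48-sample regression — not canonical choices.
* No regularization anywhere; no cross-validation (single fixed split).

## Evaluation

MRE = 100·mean(|yᵢ−ŷᵢ|/yᵢ); RMSE = √(mean((yᵢ−ŷᵢ)²)); NRMSE = RMSE /
mean(y); R² = 1 − SS_res/SS_tot on the modeling set, clipped at 0 (a
squared-correlation mode exists; both coincide for least-squares linear
fits). Composite score:

T = (1/R²)·0.4648 + MRE·0.2958 + NRMSE·0.2394

with MRE entering as a fraction — the reading under which the published
score tables are internally consistent, verified by recomputation — and
the three weights fixed expert-elicited constants (they sum to 1 and
live in one place, `AHPWeights`). T is reported to 4 decimals; lower is
better; a perfect model scores 0.4648. Model comparison takes the
minimum-T model per nutrient and reports signed percent changes of each
metric (R² larger-is-better; MRE/NRMSE/T smaller-is-better, 100·(ref−cand)/ref).

## Numerical and degenerate-input conventions

* Constant response in PLS: NIPALS weights are undefined, so the fit
  short-circuits to zero slopes and intercept = mean(y).
* Constant variables in correlation tables yield an `undefined`-flagged
  NaN row rather than an error; zero-variance detail bands are excluded
  from the candidate pool.
* |r| = 1 reports p = 0 without error.
* R² is undefined (error) for constant measured values; T is undefined
  (error) for R² ≤ 0; MRE requires strictly positive measured contents.
* Curve-fit failure in the exponential family falls back to the
  log-linear solution.

## Problem sizes in tests

The test suite and examples run at the original trial scale (72 samples,
1001 bands) for end-to-end checks; the 10-seed model-ranking property
uses the default generator conditions, and a reduced 30-sample trial is
used where only mechanics are exercised. All randomness is seeded.

## Known limitations

* The published field-data regression metrics are not reproducible —
  the original spectra were never released — so the package demonstrates
  the method's qualitative behavior on synthetic trials and reproduces
  exactly only the score arithmetic and between-model comparisons.
* Whether the original workflow applied the log-ratio or plain-ratio
  correction downstream, which extrema/area convention it used, and the
  network's training details are not documented anywhere; all are
  exposed as modes with declared defaults.
* The expert-elicited weighting (0.4648/0.2958/0.2394) is taken as a
  fixed constant; the elicitation process itself is out of scope.
* Spectra only: no hyperspectral image cubes, camera drivers or
  robot-platform integration.
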