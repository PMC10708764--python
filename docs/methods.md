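# Methods

This note documents the models, defaults and design choices behind
`forestagb`, in the package's own words. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Allometric biomass

Per-tree above-ground biomass follows the power law `W = a·D^b·H^c` with
D in cm and H in m (the convention of the mixed-species calibration the
defaults come from; the source does not restate the units, so they are
documented here rather than guessed differently). Defaults:
`a = 0.0470`, `b = 2.1181`, `c = 0.7088`. The output unit is carried as
opaque "biomass units": the calibration's published range is not
physically consistent with its printed unit (kg/hm² where t/hm² is
plausible), so the package never attaches or converts a physical unit.
Plot biomass is the plain sum over member trees; normalization by plot
area is deliberately not applied because no plot area is part of the
contract. Species shares are biomass fractions, sorted descending.

## Feature catalogue (86 variables)

Band roles follow the Landsat-8 OLI convention: BLUE=B2, RED=B4, NIR=B5,
SWIR1=B6. Two vegetation indices are implemented *as printed in the
calibration source* rather than in their textbook form, because intent
cannot be verified: EVI uses a coefficient of 7 (not 7.5) on the blue
band, and ARVI is `(NIR − 2·RED − BLUE)/(NIR + 2·RED − BLUE)`. Passing
`standard=True` switches both to the conventional definitions. NDPI uses
the weighted red/SWIR mix `0.74·RED + 0.26·SWIR`. SAVI's soil factor
defaults to L = 0.5. Zero denominators yield NaN with no silent
substitution.

Texture measures are Haralick statistics of a grey-level co-occurrence
matrix (GLCM): the window is quantized (per whole band, min–max, 32
levels by default), pairs are counted at offsets
{(0,1), (1,0), (1,1), (1,−1)}, symmetrized, normalized and averaged over
offsets. Window size defaults to 7×7. None of window, levels or offsets
are part of the original calibration's public record; they are explicit,
configurable parameters here, and a model's metadata records the values
used at training time so mapping reuses them. "Second Moment" (optical
naming) and "ASM" (SAR naming) are the same quantity; the SAR set adds
MAX (max probability) and Energy (√ASM), giving 8 optical measures per
band and 10 SAR measures per polarization — hence
6 + 7 + 48 + 2 + 20 + 3 = 86 catalogue variables. Entropy uses natural
log with 0·ln 0 := 0. Correlation of a degenerate (zero-marginal-variance)
GLCM is reported as 1.

## Screening

Outlier removal defaults to *iterative* mean ± 3·SD clipping on recorded
plot biomass: mean and SD are recomputed on the retained set until no
further plot is excluded. The iteration matters because gross one-sided
recording errors at >50% contamination inflate the first-pass SD so much
that a single pass removes nothing; peeling from the extreme tail
converges to the clean sample. The single-pass rule remains available
(`rule="mean_sd"`), and the removal log records each excluded plot and
the band that excluded it.

Pearson `r` uses the standard two-pass product-of-norms form (the
compact single-line rendering of this formula sometimes drops the square
roots in the denominator; |r| ≤ 1 requires them). p-values come from
`t = r·√((n−2)/(1−r²))` against Student's t with n−2 df, two-sided.
No multiple-testing correction is applied — the correlation table
records the number of tests so users can judge family-wise risk.
Selection keeps features with p < α (default 0.01), ordered by |r|.

## Linear models

The published eight-predictor regression (intercept −243.422; Altitude
0.090; Canopy closure 125.943; ARVI −156.917; EVI 73.454; RVI 148.340;
VVEntropy 34.447; B6Mean 24.306; B6 −245.049) is shipped as a frozen,
versioned constant: its calibration data are confidential and cannot be
refit. `stepwise_fit` exists for synthetic and user data: forward entry
at p < 0.05, backward removal at p > 0.10 (the defaults of the SPSS-style
workflow this mirrors), OLS sub-fits via statsmodels, candidates that
would make the design rank-deficient are skipped (so a duplicated
predictor enters once). Predictions are never clipped at zero; negative
estimates are counted in reports.

## Neural network and training

Architecture: one tanh hidden layer, linear output. Inputs and target
are min–max normalized to [−1, 1] with statistics from the training
split, stored with the weights. Initialization is seeded uniform
[−0.5, 0.5] with first-layer weights scaled by 1/√fan-in.

Levenberg–Marquardt training: per-sample output Jacobians from
backpropagation, trial steps solving `(JᵀJ + λI)δ = Jᵀe`; λ starts at
1e−3, divides by 10 on an accepted step (training SSE strictly
decreased) and multiplies by 10 until acceptance or overflow at 1e10.
Early stopping triggers after 6 consecutive validation-MSE increases and
the best-validation weights are returned. These damping/patience values
are the common defaults of this training scheme and are configurable.

Hidden-size tooling implements the three classical heuristics — the
combinatorial bound (smallest M with Σᵢ C(M,i) > k), `⌈√(n+m)⌉ + a` for
a ∈ [0, 10], and `⌈log₂ n⌉` — plus a trial-and-error search over sizes
5..20 selecting the minimum validation MSE (ties to the smaller size).
The additive rendering `n + m + a` of the middle heuristic is available
behind `literal_sum=True`; the square-root form is the default because
the additive form is a recognizable typesetting loss of the radical.
Data are split 70/15/15 (train/validation/test) by seeded permutation
with sizes `⌊0.70n⌋ / ⌊0.15n⌋ / remainder` — 162 plots give 113/24/25.

## Particle swarm optimizer

Canonical global-best PSO with the velocity update
`v ← w·v + c1·r1·(pbest−x) + c2·r2·(gbest−x)`, componentwise clamp,
position bounds, inertia decreasing linearly 0.9 → 0.4, and
c1 = c2 = 1.49445, N = 30 particles, 200 iterations by default. The
update equation and constants are this package's explicit choice of the
standard formulation (the six-step flow it implements is usually stated
without them); all live in `PSOConfig`. Termination: iteration budget
or gbest fitness ≤ tolerance. For network training a particle is the
flattened weight vector and fitness is training-split MSE on the
normalized scale — validation data are reserved for the fine-tuner's
early stopping, so model selection never leaks into the fitness. The
default "PSO network" is PSO followed by an LM polish from the swarm
optimum; `fine_tune=False` gives the pure-PSO variant.

## Evaluation

Both R² conventions are always computed and labelled: `r2_corr` (squared
Pearson correlation; invariant to affine transformation of predictions)
and `r2_cod` (`1 − SSres/SStot`; not invariant). Relative errors are
signed percentages `100·(pred−obs)/obs`; observations of exactly 0 are
flagged NaN. "Mean deviation" is the mean |relative error| after
discarding entries with |error| > 100% (threshold configurable); the
discard count is reported alongside.

## Synthetic data: what it emulates and what it does not

The generator emulates the *structure* of a continuous forest inventory
fused with optical/SAR imagery: 354 plots (default), 8–25 trees each
with a realistic species mix dominated by one oak at ~24%, heights tied
to DBH by `H = 1.3·D^0.6 × lognormal(σ=0.08)`, latent plot biomass from
a truncated normal (mean 100, SD 25, truncated at ±2.2 SD, opaque
units). Tree DBHs are rescaled so the allometric plot sum equals the
latent biomass exactly, making inventory and truth consistent by
construction.

Features are affine in `v = (u + s·tanh(1.5u))/(1+s)` where `u` is
standardized latent biomass and `s = nonlinearity_strength` (default 1):
B2 decreases with biomass, B5 increases (so NDVI-type ratios increase),
VV/VH increase in dB; altitude and canopy closure mix `v` with
independent noise (weight 0.6), slope is independent. With `s = 0`
biomass is affine in every noise-free feature; with `s > 0` inverting
the saturating link is outside the linear model class, which is exactly
the qualitative regime the three-model comparison probes. Per-feature
Gaussian noise has SD `noise_scale × |slope|` (default 0.15).

The default `outlier_fraction = (354 − 162)/354` corrupts recorded plot
biomass multiplicatively by `10^U(1,6)` — one-sided, log-spread gross
errors (decimal/unit mistakes). The spread is what makes iterative 3σ
clipping peel them exactly: the latent truncation at 2.2 SD keeps every
clean plot inside the final 3·SD band while every corrupted value stays
far outside it, so the default run retains exactly the 162 clean plots.

The raster stack hosts each plot at a distinct interior pixel (stamped
with the plot's exact values) over smooth correlated background fields,
with Altitude/Slope/Canopy-closure bands alongside the spectral ones.

What the generator does **not** emulate: radiative transfer, atmosphere,
sensor PSFs, SAR speckle statistics, spatial autocorrelation between
plot biomass and its raster neighbourhood, species-specific allometry,
and geographic realism. Passing tests therefore demonstrate the
correctness and internal consistency of the pipeline and the qualitative
linear-vs-nonlinear model ordering — not expected accuracy on real
imagery.

## Problem sizes and numerical choices

The shipped tests and the demo use sizes chosen for a laptop-class
single-CPU run: 354-plot inventories, 32–48 px grids, 7×7 texture
windows at 32 levels, networks with ≤ 10 hidden units, PSO with 30
particles × 100–200 iterations, and 10-seed replications for the
stochastic model-ordering property (nonlinearity 4.0, noise 0.10 for the
"strongly nonlinear" condition; nonlinearity 0, noise 0.02 for the
"linear" condition). Degenerate inputs are handled explicitly: zero
index denominators → NaN + flag; zero-variance features → NaN r, tier
"none"; constant training targets → constant network output; GLCM with
no co-occurring pairs → error; grids too small to host all plots →
error.

## Known limitations

* Stepwise p-value selection inherits all classical caveats (biased
  post-selection inference); the package reports but does not correct.
* LM training is exact Gauss–Newton on the full parameter vector: fine
  for the ≤ few-hundred-parameter networks used here, quadratic in
  parameter count beyond that.
* Per-pixel texture mapping is a Python loop over windows; fine at demo
  grid sizes, not tuned for province-scale rasters.
* The TIFF + JSON-sidecar raster contract is deliberately minimal; it
  does not interoperate with GDAL georeferencing tags.
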