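# Methods

This note records the modelling assumptions, parameter choices and
numerical decisions behind gabamorph, in the order the pipeline runs.

## Synthetic morphology generator

No public dataset exists for this system, so the generator is the
package's reference experiment.  A trait value is

    trait = baseline(cultivar, trait) · growth(day) · penalty(stress, cultivar)
            · gain(dose) + ε

with

* `baseline` — day-0, unstressed, GABA-free trait mean in cm.  Defaults
  (Atabaki: CD 13.5, PH 110, LLI 4.2, LWI 1.35, LAI 10; Rabab = 0.88×)
  are illustrative: they bracket the optima the demo pipeline reports,
  and are not fitted to any real data.
* `growth(day) = 1 + r·day`, r = 0.008/day for every trait, so 45 days
  of growth add ~36%.  Days are continuous in [0, 45]; day 0 encodes
  the pre-stress measurement.
* `penalty` — control 1.0, drought 0.85, salt 0.80, combined 0.62,
  expressed through a per-cultivar susceptibility (Atabaki 0.7,
  Rabab 1.0) as `1 − (1 − penalty)·susceptibility`.  Validation
  enforces combined < each single stress < control, which is the
  qualitative ordering the system shows.
* `gain` — saturating `1 + g_max·d/(d + d_half)` (g_max 0.25,
  d_half 8 mM) by default, so traits are strictly increasing in dose
  over [0, 40] mM.  Setting an optimum dose switches to the unimodal
  `1 + g_max·(d/d*)·exp(1 − d/d*)`, which peaks exactly at `d*`; the
  optimizer-recovery experiments plant their ground truth this way.
* `ε` — zero-mean Gaussian noise with per-trait sd (defaults ≈ 15% of
  baseline, a realistic replicate-to-replicate spread for potted trees
  that also keeps total trait correlations in the 0.3–0.95 band seen
  in this kind of data) and a configured 5×5 correlation matrix.

**Correlation semantics.** The configured matrix is the *replicate
level* (noise) correlation.  Because every trait shares the same
multiplicative treatment effects, the *total* correlation in a
generated dataset is necessarily higher than the configured value; the
recovery test therefore checks within-cell residuals against the
configured matrix, and only checks qualitatively that total
correlations are positive.  Trait values are floored at 0.01 cm so the
all-positive invariant survives noisy draws.

What the generator does *not* emulate: within-plant repeated-measures
correlation over time, heteroscedastic noise, measurement drift, or any
physiology.  Tests passing on this generator demonstrate that the
pipeline recovers structure it can represent, not that the biological
claims hold.

## Leaf renderer and morphometry

Leaves are superellipse laminas (exponent 2 = ellipse by default) with
an explicit thin petiole stub, dark on a near-white background.  Ground
truth comes from the continuous geometry: length = tip to petiole
intersection (the lamina's major axis), width = minor axis, area =
clean-mask pixel count.  Speckle noise flips background pixels dark,
hole noise flips lamina pixels to background; both affect only the
image, never the ground truth.

Segmentation uses Otsu's threshold on the grayscale image with an
isodata-style refinement (iterate to the midpoint of the two class
means): with the strongly quantized histograms of synthetic renders the
raw Otsu bin edge can land inside a mode, and the refinement is stable
between modes while being a no-op on well-behaved bimodal images.
Foreground polarity is auto-detected from the border pixels.  Cleaning
keeps the single largest connected component (smaller components are
assumed specks) and fills interior holes.

Tip and petiole are localized on a morphological opening of the mask
(disk radius 4 px by default), which suppresses the thin petiole stub;
the endpoints are the extreme pixels along the principal axis, with
near-ties resolved toward the midrib so flat or rounded ends do not
bias the endpoint off-axis.  The returned petiole point is therefore
the lamina base (petiole intersection), and leaf length is the
Euclidean two-point distance between the endpoints — the distance
formula with a plus sign between the squared coordinate differences
(a minus sign would yield imaginary lengths).  Width is the maximum,
over 1-px slabs along the axis, of the perpendicular pixel extent;
area is the cleaned foreground count, and calibration divides by
px/cm (area by its square).  On rendered fixtures with 1% speckle and
2% hole noise, length and width land within 2% and area within 1% of
ground truth (the acceptance suite measures 50 such leaves).

## Preprocessing

Cultivar and stress are single ordinal columns (Atabaki 1, Rabab 2;
control 0, drought 1, salt 2, combined 3), matching the four-input
framing; one-hot encoding is available behind a flag.  Inputs *and*
targets are z-scored with the sample standard deviation (n−1), fitted
on the training rows only; predictions are inverse-transformed so all
reported metrics are in cm.  The 80/20 split shuffles with a seeded
generator and rounds the train size half-to-even (512 → 410/102).

## Surrogate models

The MLP is 4–14–12–5 with tansig hidden layers and a purelin output —
one multi-output network rather than five single-output ones, because
the optimizer consumes all five predictions jointly.  Weights start at
fan-in-scaled uniform values (seeded).  Training minimizes
MSE + λ‖θ‖² with L-BFGS on analytic backpropagation gradients; the
recorded objective is non-increasing over accepted line-search steps,
and non-finite losses abort with a training error.  The default is a
fixed λ = 1e-4 on the standardized scale; an optional evidence-style
(Bayesian-regularization) mode re-estimates λ between refits from the
effective number of parameters γ (Gauss–Newton Hessian eigenvalues):
α = γ/(2E_W), β = (N−γ)/(2E_D), λ = α/(βN).  The fixed-λ mode is the
default because it is simpler, faster and sufficient for the data
sizes here.

The RBF network places K = 25 centers by seeded k-means++ on the
training inputs; each width is the distance to the nearest other
center (zero distances from duplicate centers fall back to the
smallest positive one), and the output weights solve a ridge
least-squares problem (ridge 1e-8).  Passing the training points as
centers with narrow widths gives the interpolation limit used by the
tests.  Both models serialize to JSON together with their encoding and
standardization parameters, so downstream stages reload them
bit-exactly.

## Evaluation

R² is implemented as the squared Pearson correlation between observed
and predicted series, which is invariant to affine transforms of the
predictions; the residual form 1 − SSE/SST is available behind a flag.
RMSE ≥ |MBE| holds for any single series (Cauchy–Schwarz), so the
report module exposes a screen that flags externally supplied metric
rows violating it as internally inconsistent rather than reproducing
them.  MBE = mean(observed − predicted): positive means
under-prediction.

## Sensitivity

VSE is the per-trait RMSE over *all* rows (training and testing
pooled) when one input is unavailable; the default mode retrains the
same architecture with the column removed (the literal reading of
"unavailable"), and a mean-substitution mode offers a fast
approximation.  VSR = VSE / full-model RMSE; inputs are ranked per
trait by descending VSR, ties broken by input-column order.  An input
that carries no information gets VSR ≈ 1; the acceptance suite plants
the importance order cultivar > GABA > stress > day and checks both
the recovered ranking and that a pure-noise decoy stays in
VSR ∈ [0.9, 1.1].  Rankings are invariant to rescaling the outputs
because VSR is a ratio of errors in the same units.

## NSGA-II and the recommendation

The chromosome is (cultivar code, stress code, GABA dose ∈ [0, 40] mM,
day ∈ [0, 45] d): reals for dose/day, integer codes for the
categoricals, all four positions visible to the 2-point crossover, and
mutation redrawing each gene independently (categoricals to a random
valid code, reals uniformly within bounds, with clipping as the
constraint handler).  The method combines a multi-objective search
with a scalar fitness, implemented as: NSGA-II evolves the 5-objective
maximization with standard elitist survival (non-dominated fronts,
then crowding distance, over parents ∪ offspring); roulette-wheel
*mating* selection uses the score 1/(1+F) from the ideal-point
distance F; and F finally selects the single reported solution from
the last front.  This honors both the stated operators and the stated
fitness.

The ideal point defaults to the training-data trait maxima so F is
stable across generations (per-population maxima would make fitness
values incomparable between generations).  Note that F grows again for
solutions that *exceed* the ideal in some trait, so the unconstrained
F-minimizer can be a dominated point; the recommendation is restricted
to the final front as defined.  The individual with the lowest F is
always retained through survival, which guarantees a non-increasing
best-F trajectory.  Objectives enter F unnormalized, which weights
plant height heavily simply because it is the largest trait; this is
the method as defined, and a normalized variant would be a one-line
change in `composite_fitness`.

Bounds are continuous for dose and day even though the experiment used
discrete levels, consistent with the continuous optima the method is
meant to report; stress and cultivar are searchable rather than fixed.

## Problem sizes and determinism

The test and acceptance experiments use the full 512-row factorial,
50 rendered leaves, 1000 random populations for the sorting oracle,
and NSGA-II at population 50 × 100 generations (the production default
is 100 × 800); these sizes give stable recoveries while keeping a full
run of the suite plus the acceptance script in the tens of seconds.
Every stochastic component takes an explicit integer seed
(`numpy.random.default_rng`), k-means included, and reruns are
bit-identical; CSV artifacts embed the config hash and seed in a
comment header.

## Known limitations

* The generator's multiplicative form cannot represent crossover
  interactions (e.g., a cultivar that is better only under salt).
* VSE by retraining inherits the surrogate's seed sensitivity; with
  very small datasets the mean-substitution mode is more stable.
* The tip/petiole localizer assumes a single leaf with one thin
  appendage; multi-leaf scenes and shadows are out of scope.
* R² as squared correlation rewards linear association even with
  systematic bias; consult RMSE/MBE alongside it.
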