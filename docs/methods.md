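# Methods

This note documents the models, protocol, statistics and design
choices behind `glybench`, in the package's own words.

## Data model and preprocessing

A patient record is a uniform 5-minute grid with four channels: CGM
glucose (mg/dL, 40–400 hardware range, gaps allowed), basal insulin
rate, insulin boluses, and carbohydrate intake; a chronological
train/test split labels each step. Preprocessing is deliberately plain:

* **Gap imputation.** Missing glucose is completed by a cubic spline
  through the observed (time, value) points with the not-a-knot
  boundary condition (scipy's default and the one that reproduces
  polynomials up to cubic exactly). Imputation never extrapolates — a
  missing first or last sample is an error — and filled values are
  clipped to 40–400 mg/dL. Gaps longer than 60 minutes are filled but
  flagged, since splines across long gaps are guesses; no maximum gap
  is enforced.
* **Scaling.** Glucose is multiplied by 0.01, placing it on the same
  order as the other channels; basal/bolus/carb channels are min-max
  normalized to [0, 1] with statistics fitted **on the training
  partition only** (test leakage through scaling statistics is a
  classic benchmark bug). A channel constant on the training partition
  maps to zero. The glucose channel is *not* additionally min-max
  normalized; a switch (`normalize_bg`) exposes the alternative
  reading.
* **Windowing.** Each supervised sample is a 25-step window (120
  minutes of history plus the current step) of all four channels, with
  glucose targets 30/60/120 minutes after the window's last step. Both
  the history and the farthest target must lie inside one partition, so
  windows never straddle the train/test boundary and a partition of
  length L yields L − 24 − max(horizon steps) samples.
* **Clipping.** All model outputs are rescaled to mg/dL and clipped to
  40–400 before any metric, mirroring the sensor's own range. A
  non-finite prediction is treated as a model failure, not clipped.

## The synthetic cohort generator

Real CGM study data of this kind is access-restricted, so the package
ships a seeded generator that emulates the *shape* of such a study:
six patients × eight weeks by default, ~3 meals/day drawn from a
Poisson process with 20–100 g carbohydrate, each covered by a bolus at
a 1:10 g/U carb ratio, constant basal, about one sensor dropout per
day of 15–60 minutes, and the last 20 % of each record held out as the
test partition.

Glucose follows a minimal one-compartment balance on the 5-minute
grid,

    G(t+1) = G(t) + k1·(Gb − G(t))·Δt + k2·Ra(t)·Δt − k3·Ia(t)·Δt,

where Ra and Ia are carbohydrate appearance and insulin activity
obtained by convolving the event trains with first-order kernels
(t/τ²)·e^(−t/τ). The defaults (Gb = 140 mg/dL, k1 = 0.02 min⁻¹,
k2 = 3.0, k3 = 25.0, τ_carb = 25 min, τ_ins = 55 min) were calibrated
once so that an uncovered 60 g meal peaks +75 mg/dL at 65 minutes
(postprandial peaks are expected 30–90 minutes after eating) and a
covered meal produces a ±30–50 mg/dL excursion — the ballpark of real
traces.

**Noise placement is a deliberate choice.** The latent trajectory is
deterministic and the observed CGM trace adds independent N(0, 5²)
sensor noise on top. The alternative — noise inside the recursion
(process noise) — makes the glucose a near-random walk whose optimal
30-minute forecast is essentially the last value; we verified
empirically that under process noise no architecture can beat the
persistence baseline, while under sensor noise all of them do, because
a trained model can filter noise the persistence forecast cannot.
Real CGM error is indeed dominated by measurement artifacts.

What the generator does *not* emulate: circadian insulin sensitivity,
exercise, sensor drift/bias runs, meal announcement errors, or any
physiological-simulator-grade dynamics. Passing the benchmark on this
cohort therefore demonstrates that the pipeline is correct and the
architectures can learn genuine carb/insulin/glucose structure — not
that any model is clinically adequate on real patients.

## The model zoo

Ten published architectures are rebuilt from their printed per-layer
hyperparameter tables, all consuming the same (batch, 25, 4) scaled
window. Because no deep-learning framework is assumed, the package
carries a small reverse-mode autodiff core (`glybench.nn`) with the
layers the zoo needs — dense, LSTM (fused 4-gate kernels in
input/forget/cell/output order, unit forget-gate bias),
bidirectional wrappers, vanilla RNNs with dilation, unpadded 1-D
convolutions, floor-division max-pooling, and batch normalization
(trainable scale/shift plus moving statistics) — following the
conventions of the mainstream frameworks so that parameter audits
against published totals are exact. Gradients of every layer are
tested against central finite differences.

Catalog notes where the printed tables left room:

* **meijner** predicts a Gaussian mean and standard deviation with two
  parallel one-unit heads and trains by the full negative
  log-likelihood (including the ½·log(2πσ²) term); the scale head uses
  ELU(x)+1+ε to guarantee positivity.
* **aiello** has two 2×LSTM(64) branches: the full window, and the
  most recent 30 minutes (6 steps) of the three known-future channels;
  final hidden states are concatenated into a single linear unit — the
  only wiring consistent with the published 101 249 parameters.
* **zhu** stacks three vanilla-RNN(32) layers with dilation rates
  1/2/4: layer ℓ's state feeding step t is the state from step t−d,
  growing the receptive field at constant parameter cost.
* **mayo** transforms glucose to the symmetric risk scale
  f(G) = γ((ln G)^α − β), with the classic curvature exponent
  α = 1.084 and (β, γ) calibrated so f(40) = −2 and f(400) = +2, then
  classifies into 100 equal risk bins via softmax cross-entropy;
  regression metrics use the argmax bin's center glucose. The risk
  transform is swappable.
* **munoz** processes each channel in its own LSTM(10)→dense(3)
  branch; the three non-glucose branches merge into an intermediate
  linear unit before joining the glucose branch. This wiring builds to
  2067 parameters against a printed 2075; the residual eight parameters
  are not explained by any obvious variant and the printed total is
  not asserted.
* **khadem** is stacked generalization: dense, LSTM(200) and partial
  least squares (PLSR, via scikit-learn) base learners trained at fixed
  30- and 60-minute targets, with a PLSR meta-learner mapping the six
  base outputs to the requested horizon. Whether the published 369 810
  parameter total counts PLSR coefficients is unclear, so it is not
  asserted; `count_parameters` covers the neural bases.
* The **ensembles** average member predictions arithmetically
  (mirshekarian+meijner+sun; plus zhu for the four-member variant) and
  clip the mean; members are trained independently and cached so each
  is trained exactly once per fold.

## Training protocol

One protocol for every spec: Adam with learning rate 0.01, batch 64 (a
conventional default), up to 100 epochs with early stopping monitoring
validation loss at 10 epochs' patience and best-epoch weight
restoration, MAE tracked as the companion metric. Validation uses ten
repetitions of a *contiguous* 80/20 train/validation split with a
shifting origin rather than classic 10-fold cross-validation (which
would imply 90/10 splits): contiguous blocks preserve temporal order,
and the repetitions cover every window. Classic K-fold partitioning is
available behind the protocol's `classic_kfold` switch. Windows are
never shuffled across the split boundary; batch order within an epoch
is shuffled under the run's seed. The held-out chronological test
partition is predicted once per fold and never touches the optimizer.

Determinism: a protocol seed fixes weight initialization and batch
order; identical seeds give bit-identical weights (single-threaded
numpy).

## Metrics

Seven per-patient metrics over n aligned (actual y, predicted ŷ)
pairs: MSE, RMSE = √MSE, MAE, R² = 1 − Σ(ŷ−y)²/Σ(y−ȳ)², Pearson CC,
Fit = 1 − Σ|ŷ−y|/Σ|y−ȳ|, and MARD = mean |ŷ−y|/y. Fit is defined as
the absolute-residual analogue of R²: zero for the mean predictor, one
for perfect prediction, and negative when predictions are farther from
the targets than the constant mean forecast — which is exactly what
happens to all models at the 120-minute horizon, where glucose is
dominated by yet-unseen events. Aggregation across
patients reports mean ± SEM (sample sd / √k). R², CC and Fit are
undefined for n < 2 or zero actual variance; the lenient path reports
NaN there while error metrics are still computed.

## Parkes error grid

Type-1 consensus grid over (reference, prediction) ∈ (0, 550]² mg/dL,
encoded from the published vertex coordinates (Parkes et al. 2000, as
digitized by Pfützner et al. 2013). Zones are nested polygons —
everything inside the B boundaries is A, inside the C boundaries is
A∪B, and so on; below the diagonal the type-1 grid has no E region.
Classification tests zones inner-first with boundary-inclusive cover,
so boundary ties go to the better zone. Property tests verify the
partition (every lattice point exactly one zone), the diagonal (always
A) and monotone zone degradation along vertical rays away from the
diagonal.

## Model comparison

All three procedures consume a loss matrix of per-fold-per-patient
RMSE (folds × patients rows), the evaluation unit that matches
"ranking models over multiple problems"; per-prediction losses with a
block bootstrap are a configuration away.

* **Plackett–Luce ranking.** Each row is reduced to a ranking (lowest
  loss first; exact ties broken by seeded jitter; fully tied rows are
  dropped as uninformative). The PL likelihood with a
  Dirichlet(1) prior on normalized worths is sampled by the
  latent-exponential Gibbs sampler (Gamma conditionals via the
  Caron–Doucet augmentation) — chosen over a Metropolis-within-Gibbs
  random walk because its conditionals are exact and mix faster; four
  seeded chains of 500 draws after 500 burn-in. Reported: posterior
  mean and 5–95 % interval of each model's probability of ranking
  first (w_k/Σw per draw), which sums to one by construction.
* **Model Confidence Set.** Hansen-style iterative elimination with
  the T_max statistic: per model, the mean loss differential against
  the current-set average, studentized by a stationary-bootstrap
  standard error (Politis–Romano, expected block length 5, 1000
  replicates by default); the max-statistic p-value comes from the
  recentered bootstrap distribution; the worst model is eliminated
  while equivalence is rejected; p-values are monotonized along the
  elimination path and the last survivor gets p = 1, so the survivor
  set is never empty. Zero-variance differentials (exact ties) take a
  floored standard error: tied models have t = 0 and survive together.
* **Superior Predictive Ability.** For benchmark b,
  d_k = loss_b − loss_k per observation; the studentized max over
  competitors is compared with a stationary-bootstrap null under the
  three standard re-centerings — lower μ = min(d̄, 0), consistent
  μ = d̄·1{significantly negative}, upper μ = 0 — giving
  p_lower ≤ p_consistent ≤ p_upper. A high consistent p-value means no
  competitor significantly beats the benchmark.
* **Multi-horizon.** The 30- and 60-minute matrices are concatenated
  row-wise for a combined evaluation.

All three are invariant to a common positive rescaling of losses
(ranks and studentized statistics are scale-free) and bit-reproducible
under a fixed seed. Calibration was checked by simulation: under an
exchangeable i.i.d. null with five models the MCS retains the full set
in ≈95 % of trials at α = 0.05 (the short-block bootstrap on i.i.d.
data over-rejects by a point or two at small n, converging with
sample size).

## Problem sizes

The test suite and the acceptance script run the full pipeline at desk
scale: one to two synthetic patient-weeks (≈1500–3500 windows), a
60-epoch cap with the protocol's 10-epoch patience (most models stop
early), 200 simulation trials for MCS calibration with 500 bootstrap
replicates, and 100 matrices for the SPA ordering check. These sizes
are the package's chosen defaults for a reproducible desk run; the
full-scale protocol values (100 epochs, 1000 replicates, multi-patient
cohorts) remain the library defaults.

## Known limitations

* The autodiff core is correct but not fast; the two largest
  architectures (the two-branch LSTM(64) model and the stacked
  LSTM(200) system) dominate full-zoo runtimes.
* The stacked-generalization spec trains its PLSR meta-learner on
  in-sample base outputs rather than out-of-fold predictions; with the
  early-stopped NN bases this is mild, but it is a simplification.
* The synthetic cohort cannot validate clinical claims; it validates
  pipeline correctness and learnability only.
* MCS/SPA p-values use the bootstrap's finite-replicate resolution
  (1/B); exact ties at the α threshold are resolved conservatively
  (p > α keeps a model in the set).
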