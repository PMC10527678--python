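# Methods

`fermsense` estimates concentrations of soluble compounds (acetate above
all) in fed-batch *E. coli* cultivations from signals that are cheap to
measure on-line — the off-gas oxygen uptake rate (OUR) and carbon dioxide
production rate (CPR), broth weight and feed rates — by combining a
mechanistic inversion of the off-gas signal with an ensemble of recurrent
neural estimators. This note records the model, its assumptions, the
defaults, and the choices made where the design was genuinely open.

## Latent physiological variables

Aerobic growth couples oxygen consumption to biomass formation. The strain
model used throughout is

    OUR(t) = α · dx/dt + β · (x − X_cX) · 1[∫x dt > k_cX]

with `x` the biomass concentration [g/L], `α` [g O₂ / g X] the
oxygen-per-growth yield, `β` [g O₂ g X⁻¹ h⁻¹] a maintenance coefficient
that enters only once the culture's cumulative biomass-time `∫x dt`
[g·h/L] exceeds the threshold `k_cX`, and `X_cX` [g/L] an optional
maintenance reference level (default 0, disabling it; the parameter is kept
explicit because the model family admits it and calibrated parameter sets
may supply it). Inverting this relation turns a measured OUR series into a
*latent biomass* trajectory:

* before the switch, `x` is the cumulative sum `x₀ + Σ OUR·Δt/α`;
* after it, an integrating-factor discretization of the linear ODE is used
  (numerator accumulates `(OUR + β·X_cX)/α · e^{Σβ/α·Δt} · Δt` terms,
  denominator `e^{Σβ/α·Δt}`), with β treated as zero before the switch so
  the trajectory is continuous at the switch instant.

The scheme is first-order in Δt; the test suite verifies against a
tightly-integrated ODE oracle that halving Δt (at least) halves the worst
relative error. The switch condition is evaluated on the cumulative sum up
to the *previous* instant and never re-evaluated once crossed (the
cumulative sum is monotone for positive biomass, so re-switching cannot
occur anyway).

From the biomass trajectory three further descriptors are derived:

* **specific growth rate** μ = (dx/dt)/x, computed with second-order
  central differences on the (possibly non-uniform) grid and one-sided
  differences at the ends. μ of a length-1 series is 0 by convention.
* **average cell age**: every biomass increment ΔX(tⱼ) is a cohort born at
  tⱼ; the inoculum is a cohort of mass x₀ born at t₀ (without this
  convention the sums would ignore the starting population). Then
  `Age_i = Σⱼ (t_i − tⱼ)·ΔX(tⱼ) / x_i`. Negative increments (biomass
  decline) enter the sums signed, not clipped — clipping would silently
  break the identity below.
* **cumulative cell age** `cAge_i = Σⱼ (t_i − tⱼ)·ΔX(tⱼ)` [g·h/L], so that
  `cAge = Age · x` holds exactly; both are computed in O(n) via prefix
  sums, and the test suite checks them against the O(n²) double sum.

Calibration of α, β, k_cX from data is out of scope; they are inputs
(`StrainParams`), constant or per-instant.

## Synthetic cultivations

No public cultivation data with the needed signal set exists, so the
package ships a mechanistic generator whose role is to produce the
couplings the soft sensor exploits, not a thermodynamically rigorous
metabolic model. States are total masses (biomass, glucose, acetate,
optional secondary solutes) plus broth weight; concentrations follow with a
1 kg/L broth density. The rate laws:

* Monod glucose uptake `qS = (μ_max/Y_XS)·s/(K_S+s)`;
* **overflow metabolism**: uptake beyond the critical oxidative capacity
  `qS_crit` is diverted to acetate with yield `Y_AS`; acetate is
  re-consumed (Monod in acetate, inhibited proportionally to `qS/qS_crit`)
  once glucose is limiting — the classic rise-and-fall acetate excursion;
* growth `μ = Y_XS·min(qS, qS_crit) + Y_XA·qA_uptake`;
* an exponential glucose feed from `feed_start` (site-2 scenarios add an
  isoleucine co-feed), adding broth weight at the feed concentration;
* secondary solutes by first-order production/consumption laws tied to μ
  and the induction state — enough structure to exercise the multi-solute
  pipeline without claiming biological fidelity.

The OUR is emitted from the same strain model the physiology module
inverts, with dx/dt taken from the ODE right-hand side (clipped at zero),
so the noiseless OUR→biomass round trip is exact up to discretization
(measured ≈1.2% at the default 0.05 h grid; the suite requires <2%). CPR is
OUR times a slowly drifting respiratory quotient. Observation noise is
relative Gaussian per signal (defaults 2% on OUR/CPR, 0.2% on broth weight;
offline assays get 2% relative plus a 0.01 g/L floor — values chosen as
typical of off-gas analyzers and enzymatic assays, and config-exposed since
no instrument specification was available). Integration is RK45 at
rtol 1e-8, split at the feed discontinuity; identical configs (same seed)
give bit-identical output.

Two scenario families emulate the target regimes: site 1 — 20 h runs,
feed from ~6 h (jittered in [5, 7] h across a campaign), x₀ = 0.2 g/L,
s₀ = 15 g/L, 17 offline assay samples per run (mirroring 287 samples over
17 runs); site 2 — 66 h runs, feed from 21 h, isoleucine co-feed, 18
sparser assays, a wider solute panel and a lower-temperature kinetic
profile. Site-1 kinetics (qS_crit = 0.75 g/g/h, Y_AS = 0.6) were chosen so
acetate peaks around 4–5 g/L — a realistic magnitude that makes the
0.5 g/L model-selection threshold meaningful. Campaigns jitter μ_max,
qS_crit, Y_XS, feed magnitude, x₀ and s₀ log-normally (5% sd) per run.

What the generator does *not* emulate: sensor drift and spikes, pH/DO
control interactions, product-titer dynamics, volume corrections, or the
real (unknown) covariance structure of the proprietary data sets. Passing
tests therefore demonstrate that the pipeline recovers what this data
model contains — not site-specific accuracy figures.

## The recurrent sensor

One estimator maps a sliding window of 23 instants of its input group to
the solute concentration at the window's final instant. The stack is fixed:
LSTM (23 units, ReLU cell activation) → dropout 0.2 → dense (10, ReLU) →
dropout 0.2 → dense (1) with non-negative kernel and bias, so predictions
are non-negative for any input by construction (a final clip at 0 guards
the inverse scaling). The network is implemented in numpy inside the
package (gate order i, f, c, o; sigmoid gate activations; glorot/orthogonal
initialization; unit forget bias; the non-negativity constraint applied by
projection after every Adam step and at initialization); gradients are
exact backpropagation-through-time, verified against finite differences.

Training uses Adam (lr 1e-3), batch size 16 (the desk profile uses 32 —
see below), up to 1000 epochs with early stopping (patience 50, best
weights restored) on a held-out split. The split is always **by
experiment** (~80/20): row-level splits would leak temporal context through
overlapping windows. The same hold-out drives early stopping — a deliberate
simplification over keeping a third split, given how few experiments a
campaign has.

The loss is a modified mean-square error, `mean((|A*−A|+1)²)`, evaluated in
original concentration units (the +1 offset is unit-bearing); its gradient
does not vanish for sub-unit errors, which keeps small errors relevant but
also sets a noise floor near convergence. A linear alternative
`Σ(|e|+1)/(2n)` is one config flag away (`loss="mmse_linear"`).

Inputs and the target are min-max scaled with parameters fitted on the
training split only; values outside the fitted range scale outside [0, 1]
(no clipping); constant features shift by their minimum and scale by 1.
Windows are built only at offline assay instants — targets are
measurements, never interpolations — and the first window positions are
served by edge-padding (replicating the first instant); a strict mode that
drops the first 22 instants exists for sensitivity checks. Padding choice
matters because ~17 assay samples per run cannot afford losing 22 each.

Numerics: parameters and activations default to float32 (the training cost
halves; the float64 path remains available via `SensorConfig.precision` and
is used wherever gradients are compared against finite differences).
Training is single-threaded numpy and deterministic given the seed up to
BLAS-kernel summation-order effects, which after many float32 optimizer
steps can move predictions by order 1e-4 g/L; reproducibility contracts
are therefore stated at that tolerance (simulation and enumeration
artifacts remain bit-identical).

When a whole family of same-size input groups is trained (the campaign
path), all trials of all groups are stacked into one batched parameter
array and trained in lock-step: entries share the experiment split, the
per-feature scaling and the minibatch order, and differ in weight
initialization and dropout draws. The stacked gradients are exactly the
per-model gradients (asserted in tests); sharing the split across a
campaign's groups also matches how a fixed site split would be used in
practice.

## Ensemble and committee sizing

All input groups of sizes 3–11 drawn from the variable pool (time, OUR,
CPR, broth weight, feed rates, initial glucose, induction time, latent
biomass, μ, Age, cAge) are enumerated; the pool is parameterized and the
group count is asserted only as the binomial sum of the configured pool.
Each group's sensors are scored on the validation runs by MAE (averaged
over the trials), RSS, R² and RMSE = √(RSS/n). Two filters follow:

1. groups with MAE above 0.5 g/L are excluded (boundary kept);
2. a group is dropped when a *proper subset* of it achieved a strictly
   lower MAE — its extra variables bought nothing. Ties keep both.

Survivors are ranked by MAE; the best trial model per group is retained as
the committee candidate (a separate retraining pass after filtering is the
full-scale protocol; the desk profile reuses the trial models directly).
Nested committees of sizes 1..14 are formed from the head of the ranking
with weights

    wᵢ = (Σⱼ RMSEⱼ − RMSEᵢ) / (Σⱼ RMSEⱼ · (n−1)),

which sum to one and decrease with RMSE (a single member gets weight 1 by
convention). The committee prediction is the pointwise weighted sum —
a convex combination of member predictions, used as-is without
renormalization.

Committee size is chosen by Shannon entropy over per-variable occurrence
probabilities `p(x) = (members containing x)/n`. These values are used
literally — they do not form a normalized distribution across variables;
entropy `H = −Σ p log₂ p` (0·log 0 := 0) is applied to them as such, with
a normalized variant available for sensitivity analysis. The size with
maximal H wins; ties go to the smallest committee. Probabilities can
instead come from local surrogate explanations: for each validation point
the member's response to Gaussian perturbations of the scaled window is
fitted with a ridge regression, the top-20 window-features by absolute
coefficient are collected (a window-feature maps to its source variable
regardless of time lag), and counts are normalized by the total collected.
If the explanation backend is disabled, occurrence probabilities are used
with a logged warning.

Multi-solute scoring uses nMAE = MAE/(max(A*) − min(A*)), scale-invariant
across compounds of very different magnitudes.

## Desk-scale study conditions

The shipped end-to-end experiment that the tests and `scripts/acceptance.py`
run: 12 training + 5 validation simulated site-1 runs, a pool of 8
variables (time, OUR, CPR, broth weight, glucose feed, latent biomass, μ,
Age) with group sizes 3–5 (182 groups), 3 trials per group, a 30-epoch
training cap, batch size 32, noiseless observations. The batch size is
raised from 16 so the 30-epoch budget contains enough gradient steps per
window; all other sensor settings are the reference stack. The full-scale
profile (pool of 12, sizes 3–11, 20 trials, 1000 epochs, batch 16) is
config-selectable but sized for a compute budget this package does not
assume.

On these conditions (seed 1) the campaign yields: best single sensor
beating the train-mean predictor by ~8×, a 13-member committee whose
validation MAE undercuts the best single member's, and an MAE-vs-size
curve that is steeply falling then flat — the diminishing-returns pattern
the committee-size selection relies on. The numbers themselves are
recomputed, not stored, by the acceptance script.

## Known limitations

* The generator's simplicity means campaign results quantify pipeline
  correctness, not expected accuracy on real cultivations.
* The MMSE loss's non-vanishing gradient limits terminal convergence;
  best-checkpoint restoration mitigates but does not remove this.
* Occurrence-probability entropy saturates as variables approach
  p = 1; with few diverse survivors the selected committee can be large.
* The explanation backend is a perturbation-based linear surrogate; it
  shares the spirit, not the implementation, of the widely used local
  interpretable model-agnostic explanation tooling.
* `X_cX` defaults to 0; no shipped scenario exercises a non-zero value
  beyond unit tests.
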