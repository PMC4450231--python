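# Methods

This note documents the models, defaults, numerical choices and known
limitations of the package. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Transit dissolution simulator

### Compartment train and volume schedule

The apparatus is modeled as a stomach followed by duodenum, jejunum and
ileum, draining into a collection canister. Defaults (fasted state):

| compartment | resting volume | residence time | pH set point |
|---|---|---|---|
| stomach | 30 mL (+ 200 mL dosing water) | 30 min | free (baseline 2.4) |
| duodenum | 33 mL | 10 min | 6.5 |
| jejunum | 33 mL | 60 min | 6.6 |
| ileum | 33 mL | 90 min | 7.4 |

Volume moves on a **plug-flow schedule with well-mixed contents**: the
stomach empties its 200 mL mobile volume at a constant rate over its
residence time, and every intestinal compartment re-emits, during step
*n*, the volume it received at step *n − residence/Δt*. Consequences that
the tests assert: each compartment's volume rises, plateaus and returns
exactly to its resting value; the full 200 mL reaches the canister by
t = 190 min (the sum of the residence times); total volume and drug mass
are conserved to machine precision at all times.

A first-order "excess/τ" drain was considered and rejected: with
residence times of 10/60/90 min a first-order cascade still retains an
exponential tail of order exp(−185/90) ≈ 13% of its content at 215 min,
which contradicts both the finite-time return of the compartment volumes
and the complete 200 mL delivery that the experiment's transfer scheme
defines.

Transfers carry dissolved drug at the bulk concentration and undissolved
drug as a homogeneous suspension (tablets disintegrate within minutes, so
post-disintegration homogeneity is reasonable). Before the disintegration
time (default 3 min) the dose is inert and immobile.

### Dissolution kinetics and solubility

Dissolution uses a cube-root (z-factor) Noyes–Whitney surrogate,
dM/dt = z·U^(2/3)·(S(pH) − C)·V, integrated with an exponential
(exact-in-concentration) relaxation step and Strang splitting around the
transfer step; halving the default 0.25 min step changes reported amounts
by < 0.15%. A stability guard rejects steps larger than one tenth of the
smallest residence time. The kinetic law is a modeling choice — the
experiment constrains outcomes (fast dissolution, saturation), not the
rate law — and z is a per-formulation calibration constant.

Saturation solubility follows the weak-acid Henderson–Hasselbalch total
solubility S(pH) = S₀·(1 + 10^(pH−pKa)), optionally capped by a constant
**salting-out ceiling** standing in for the common-ion effect of a
carbonate buffer's Ca²⁺. Default pKa 4.33 (monoprotic weak acid).

### Formulation presets

* `nonbuffered_amorphous`: S₀ = 1 µg/mL, no ceiling. At gastric pH 2.4 the
  saturation capacity of the stomach is ≈ 0.3% of an 80 mg dose, so
  gastric dissolution rounds to zero — the design dissolves only in the
  intestinal compartments.
* `buffered_crystal`: S₀ = 0.4 µg/mL, gastric pH jumps to 7.5 at
  disintegration, ceiling 0.10 mg/mL. The buffer enables early gastric
  dissolution; the ceiling caps the cumulative dissolved fraction near
  40% over the full run.

Both default to 80 mg dose, z = 0.01, 3 min disintegration.
`formulation_family` derives slow/medium/fast variants by scaling z
(×0.5/1/2), giving the minimal three-release-rate set for model building
and external validation.

### pH, sampling, noise

Intestinal pH is clamped at the set points (controller injections are
treated as volume-free). The stomach pH is 2.4, or jumps instantaneously
to the formulation's buffered value at disintegration — buffering
chemistry is not modeled (no buffer amounts are available to calibrate
it). Sampling events withdraw 1 mL of filtered medium per compartment
(dissolved drug leaves with it, suspended drug is returned); traces are
recorded pre-withdrawal, and the withdrawal ledger allows the cumulative
curves to add the removed dissolved mass back analytically. The simulator
is deterministic; duplicate experimental runs are emulated by optional
seeded multiplicative lognormal noise (suggested σ = 0.05) applied to
observed dissolved amounts only.

### Cumulative fraction dissolved

`cumulative_fraction` sums, per sampling time, the dissolved mass residing
in the included compartments, the canister share **attributable to the
included compartments** (the simulator provenance-tags dissolved mass by
the compartment where it dissolved), and the withdrawal correction. For
imported datasets without provenance the canister is included exactly when
the ileum is (documented limitation). With the stomach excluded for a
buffered formulation, location-based compartment counting combined with
origin-based canister attribution can be locally non-monotone (stomach-
dissolved drug residing in the ileum counts until it reaches the
canister); for nonbuffered formulations — the case where the exclusion
matters in practice — the curve is monotone. Undissolved drug reaching the
canister is never counted as dissolved.

## Synthetic plasma profiles and the unit impulse response

`generate_synthetic_pk` evaluates the closed-form triexponential solution
of the two-compartment disposition model with first-order absorption and
lag. Defaults (ka 2.2 /h, k10 0.35 /h, k12 0.35 /h, k21 0.25 /h, Vc 500 L,
80 mg) give Tmax ≈ 0.8 h and Cmax ≈ 95 ng/mL — an early peak of realistic
magnitude for a high-first-pass statin mean profile. Near-coincident
eigenvalues are perturbed by 1e−9 with a warning.

`default_uir` is the biexponential disposition of that same virtual drug
after an intravenous bolus, so the shipped defaults form one coherent
system: deconvolving the default oral curve against the default UIR
recovers the first-order absorption input. It is a stand-in, not a fitted
reproduction of any published intravenous profile. The bioavailable
fraction defaults to 1 in FABS normalization: the level-A correlation is
built on relative fractions, and absolute bioavailability (confounded by
first-pass metabolism) is out of scope.

## Deconvolution

`convolve` discretizes FABS into per-interval increments on a uniform grid
(default 0.01 h) and sums UIR responses evaluated at the interval
midpoints (second-order accurate; the bolus column uses the exact left
edge so a step input reproduces the scaled UIR identically). `deconvolve`
solves the same lower-triangular system for nonnegative increments with
`scipy.optimize.nnls` — the recovered cumulative curve is nondecreasing by
construction — with an optional second-difference penalty
(`smoothing_lambda`) for noisy data. The terminal value is reported as
estimated, never forced to 1; values above 1.05 raise, values above
1.0001 warn. The reference experiment's own deconvolution settings are
unknown; these defaults are stated, not inferred.

## Level-A correlation

Pairing times default to the dissolution sampling grid converted to hours
and truncated to the plasma observation window (dissolution is the
sparser, bounded signal). The regression is ordinary least squares
(statsmodels) of FABS on FDISS, degree 1 or 2; diagnostics include R²,
residuals and coefficient standard errors. Which compartments feed FDISS
is decided upstream in `cumulative_fraction` (absorption of a weak acid is
assumed to start in the small intestine, so the stomach is typically
excluded); buffered and nonbuffered designs generally need separate
models. Predicted FABS is clipped to [0, 1] and made nondecreasing by
running maximum — the convolution step requires a valid cumulative input —
with a warning when clipping touches more than 20% of points.

## Compartmental direct mapping

The mapping is empirical: the jejunal dissolution curve is similar in
shape to the oral plasma curve when permeability is not limiting, and the
route deliberately avoids deconvolution and intravenous data.

* **Triexponential fit.** Variable projection: the DEPS optimizer searches
  log₁₀ of the three rate constants (bounds 1e−4 to 5 per minute); for
  each candidate the amplitudes are solved by linear least squares, with
  the optional constraint A + B + C = 0 (f(0) = 0, on by default for
  dissolution curves). Goodness is reported as curve RMSE only — sums of
  exponentials are not parameter-identifiable, and coefficients are never
  compared across fits. Nonconvergence flags the result instead of
  raising. The fitted family has no lag term, so curves with a pronounced
  arrival delay (the jejunum is empty until chyme reaches it) fit with a
  small negative dip before onset; downstream predictions clip negatives
  to zero with a warning.
* **Profile extension.** Truncated runs end near the jejunal peak. Two
  synthetic points are appended whose spacing is the full-length reference
  fit's terminal descent timescale 1/|d ln f/dt| and whose values decay
  from the last observed point at that log-slope. Only the procedure is
  specified by the source experiment; the synthetic points are labeled by
  construction, and original points are never altered.
* **Time scaling.** t_scaled = α·ln(1 + β·t) maps in vivo hours to in
  vitro minutes. It is solved through two anchors (in vivo Tmax ↔ in vitro
  jejunal peak time; end of observation ↔ end of run) by a bracketed root
  find on β; the anchor ratio must lie between the linear limit a/b and 1,
  and the linear-compatible edge case degrades gracefully to a near-linear
  map (β = 1e−9). The map is strictly increasing with an exact closed-form
  inverse; mapping outside the calibrated in vivo window raises.
* **Linear rescale.** CONST1 and CONST2 minimize the pooled squared error
  against the observed plasma curves of exactly two training formulations
  (shared constants; `fix_const2` gives the nested one-parameter fit).
  Whether the constants should be refit per formulation design is left to
  the caller — both modes are expressible.

## DEPS optimizer

Per generation each agent takes a DE/rand/1/bin step (mutant
x_r1 + F·(x_r2 − x_r3), binomial crossover, greedy selection) with
probability 0.5, otherwise an inertial PSO step (w = 0.72,
c1 = c2 = 1.49, position accepted regardless, personal/global bests
updated). Defaults: population 40, F = 0.8, CR = 0.9, 2000 generations,
stop after 50 generations with < 1e−10 improvement. Bounds are enforced
by clamping (simplest defensible choice); non-finite objectives count as
+∞. Runs are bitwise deterministic per seed. The hybridization rule is
the package's interpretation of the DEPS concept — the original
spreadsheet solver's internals are not public — and the parameter values
are conventional DE/PSO literature choices.

## Validation metrics

Prediction errors are computed on the observed time grid (the predicted
curve is resampled onto it); the pAUC window defaults to the full common
observation window and is configurable. Verdict thresholds — external:
pass ≤ 10%, inconclusive ≤ 20%, fail > 20%; internal: mean ≤ 10% and no
single PE > 15% — are hard-coded interpretations of the customary
regulatory criteria. f1/f2 are computed in percent-dissolved units on the
reference grid restricted to the common range (≥ 3 points).

## What the synthetic world does and does not establish

The simulator reproduces the structure of the experiment — compartment
volumes and transfer, pH regimes, buffered vs nonbuffered discrimination,
saturation, withdrawal bookkeeping — but its dissolution rate law,
presets, and the synthetic plasma generator are stated stand-ins: no raw
experimental dissolution or PK data are available in numeric form. A green
test therefore establishes that the algorithms are implemented correctly
and self-consistently (round trips, parameter recovery, conservation
laws, worked metric values), not that any particular real formulation
would yield the same correlation quality. Known unmodeled effects: fed
state, enzyme/bile influence on dissolution rate, precipitation kinetics
on pH shift, buffering chemistry, per-subject variability (mean profiles
only), and an arrival-lag term in the triexponential family.
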