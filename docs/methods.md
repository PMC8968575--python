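# Methods

## Model family

All models describe a sealed batch digester as a linear chain (or a
two-branch mixture of chains) of irreversible first-order steps, with the
chemical oxygen demand (COD) as the conserved currency.  The dual-pool,
three-phase model is the centrepiece:

* state `S_A` — remaining biodegradable substrate, split at t = 0 into a
  rapidly biodegradable pool `α·S_A0` and a slowly biodegradable pool
  `(1−α)·S_A0`;
* the slow pool degrades through hydrolysis (`k_L`), acidogenesis (`k_2`)
  and methanogenesis (`k_3`); the fast pool through acidification (`k_R`)
  and the same methanogenesis step (`k_3`);
* `S_B` is the hydrolysis-product pool (fed by the slow branch only), `S_C`
  the volatile fatty acid pool, `S_D` cumulative biogas.

The governing equations are the pool-resolved linear system

    dS_A^R/dt = −k_R S_A^R            dS_A^L/dt = −k_L S_A^L
    dS_B/dt   =  k_L S_A^L − k_2 S_B
    dS_C/dt   =  k_2 S_B + k_R S_A^R − k_3 S_C
    dS_D/dt   =  k_3 S_C

whose exact solution gives the closed forms implemented in
`adkin.models`.  Assumptions worth keeping in mind: reactions are
irreversible and first-order (no Monod saturation, no inhibition), H₂/CO₂
intermediates are neglected, rates are temperature-independent constants,
and total conversion is assumed, so the ultimate biogas potential equals
the initial biodegradable COD (`S_max = S_A0`).  `S_D(0) = 0` by
construction — the property that separates this family from the Modified
Gompertz sigmoid, which is positive at t = 0 for every parameter set.

### Parameters

| parameter | meaning | units | typical fitted range |
|---|---|---|---|
| `s_a0` (= S_max) | ultimate biogas potential | series unit (L, mL/g_VS, g_COD/L) | data-scale |
| `k_l` | slow-pool hydrolysis rate | d⁻¹ | 0.01–0.5; the smallest rate (rate-limiting step) |
| `k_r` | fast-pool acidification rate | d⁻¹ | 5–25 × k_l |
| `k_2` | hydrolysate → VFA rate | d⁻¹ | 2–10 × k_l |
| `k_3` | VFA → biogas rate | d⁻¹ | often close to k_r |
| `alpha` | rapidly biodegradable fraction | – | 0.2–0.75 |

All model functions are unit-agnostic: the amplitude carries the series
unit, rates are always d⁻¹, and times are days.

## Numerical evaluation of the chains

Every chain term is evaluated through confluent divided differences of
`exp(−x t)` (`adkin.kernels`).  For distinct rates this reproduces the
familiar sums of exponentials; when rates approach each other the raw
formulas suffer catastrophic cancellation (the nested second difference
loses ~eps/h² accuracy at node separation h), so rate groups closer than
`COINCIDENCE_RTOL = 3e-5` relative are merged onto their mean and the
analytic limits (t·e^(−kt), t²·e^(−kt)/2) used.  Merging onto the mean
cancels the first-order merge error, leaving both branches accurate to
about 1e−7 at the crossover — the threshold was chosen from that error
balance, not convenience.  Published optima do land exactly on coincidence
manifolds (one reported sludge fit has k_R = k_3), so this is not a corner
case.

Two independent numerical solutions of the pool system back the closed
forms: a machine-precision matrix-exponential solution (`expm(A t) y0`,
Padé-based, sharing no algebra with the divided differences) and an
adaptive DOP853 integration at rtol 1e−12.  The matrix exponential is the
primary oracle — for this linear constant-coefficient system it is exact to
rounding — because no time-stepping solver can track components that have
decayed below ~1e−5 of S_A0 to 1e−7 *relative-to-component* accuracy over
long horizons; the integrator is asserted at amplitude scale instead.

## Fitting

The objective is the unweighted sum of squared residuals
ψ(η) = Σ [y_exp − S_D(t, η)]², including the t = 0 point when present.
Minimisation is staged:

1. The single-phase first-order model is fitted from 5 seeded random
   starts (its optimum is empirically start-independent; the best of the
   five is kept).
2. Its optimum (S^x, k^y) seeds the dual-pool model as
   (S_max, k_L, k_R, k_2, k_3, α) = (S^x, k^y/2, k^y, 2k^y, 3k^y, 0.5);
   comparators use the analogous rate ladders, and the Gompertz model
   starts from curve heuristics (P = 1.05·max, μ = steepest finite
   difference, λ = 0).
3. A Levenberg–Marquardt descent runs to machine-precision tolerances.
4. For the dual-pool model only, a deterministic *reassignment polish*
   follows: at the LM fixed point the four fitted rates are re-assigned to
   the roles (k_L, k_R, k_2, k_3) in every distinct way, the two pool
   amplitudes (α·S_max and (1−α)·S_max, in which the curve is linear) are
   re-solved by non-negative least squares, and LM restarts from the best
   candidate.  Rounds continue while the objective improves by more than
   `residual_tolerance` (default 1e−6, the documented stopping rule) or a
   1e−9 relative floor; a short restart crawl then squeezes the
   ill-conditioned valley.  The polish is a pure descent — no randomness,
   no extra starts — but it escapes the label-swap local minima that plain
   LM cannot leave (on published parameter sets plain LM stalls within
   ~1e−7 of a perfect fit with two rates fused; the polish recovers the
   generating values to 1e−12).

`bounds_mode="none"` (default) optimises raw parameters, matching how
unbounded solvers reach exact rate coincidences; `"positivity"` fits rates
and amplitudes in log-space and α through a logistic transform.  If an
unbounded fit ends unphysical, a final log-space descent from the clamped
endpoint guarantees a physical result.  A Gompertz fit that wants a
negative lag is re-profiled on the λ = 0 boundary.

### Identifiability and canonical labelling

The slow-chain kernel is symmetric in (k_L, k_2, k_3), so a biogas-only
fit cannot distinguish k_L from k_2: the two labels are exactly
interchangeable.  Fits are reported with k_L ≤ k_2, matching the
hydrolysis-rate-limiting interpretation every published fit shows; recovery
tests canonicalise the generating vector the same way.  The dual-pool
comparators carry the analogous pool-swap symmetry, resolved by making the
"rapid" pool the faster one.

Beyond exact symmetries, multi-exponential models are *sloppy*: when the
three non-hydrolysis rates cluster, or rate ratios exceed what the sampling
can resolve, curves within 1e−5 of each other correspond to parameters
10–30% apart, and no optimizer can help.  Per-parameter recovery to 0.1%
is therefore guaranteed (and tested) in the realistic digestion regime the
published fits inhabit — k_L smallest (0.02–0.3 d⁻¹), k_R 8–25 × k_L with
k_3 within ±33% of k_R, k_2 2–5 × k_L, α 0.3–0.75 — which is what
`adkin.synthetic.draw_dual_pool_params` samples.  Outside it, the fitted
*curve* remains excellent but individual rate labels should be read with
care.

## Evaluation protocol

Goodness of fit is reported as R² = 1 − SS_res/SS_tot (about the data
mean, not squared Pearson) and as the signed per-point relative error
(model − observed)/observed, skipping zero observations.

The predictive-capacity (truncation) study refits the model using only
points up to a cutoff time and compares the refitted curve's value at the
final experimental time against the last measured cumulative value:
error = |S_Du − y_expu| / y_expu.  Evaluating at the final time (rather
than t → ∞) keeps the error well-defined without extrapolation ambiguity;
the asymptotic variant (fitted S_max vs last observation) is available as
an option.  The *time reduction* at a threshold (default 5%) is
100·(T − t*)/T where t* is the smallest evaluated cutoff whose error is
below the threshold at t* **and at every later evaluated cutoff** — a
sustained crossing, since a transient dip below the threshold would not
justify stopping an assay.  If no cutoff qualifies the reduction is 0.
Cutoffs that leave fewer than (number of parameters + 1) points are
reported as absent, never as zero.  On noiseless self-generated data the
prediction error is numerically zero from roughly the 25% mark of the
assay onward; at the very earliest feasible cutoffs (7–13 points covering
a small fraction of a fast assay) the staged fit can stall, so default
grids start later.

Model comparison fits each requested model, ranks by R², and flags any
fitted ultimate potential below the last observed cumulative value — a
physically impossible estimate that simpler models do produce on dual-pool
curves (including the known pathology where the three-phase chain drives
its two fast rates to effectively infinite values, erasing the
intermediate pools).

## Synthetic data

`simulate_measurements` evaluates any model's observable (biogas for all
models; substrate and VFA for the dual-pool model) on an arbitrary
schedule containing t = 0 and optionally adds i.i.d. Gaussian noise with
standard deviation `sigma_fraction · S_max`; noisy cumulative biogas is
clipped at zero.  The generator emulates the monotone, irregularly
sampled cumulative curves of real BMP assays but deliberately omits
features of real data: heteroscedastic and autocorrelated measurement
error, temperature drift, inoculum blanks, and inter-replicate
variability.  Passing tests therefore demonstrate correctness of the
machinery and recoverability under the stated noise model, not field
performance.  VFA fixtures are generated in COD units; the stoichiometric
coefficient 2·M(O₂)/M(CH₃COOH) = 1.0657 (printed as 1.07) converts
acetic-acid mass to COD and back.

## Numerical choices and edge cases

* Time grids need not be uniform or include 0; negative times are
  rejected, never extrapolated.
* Degenerate pool fractions (α = 0 or 1) evaluate the reduced model
  directly, avoiding 0·limit products.
* Fits require strictly more points than parameters; all-zero series and
  zero-variance data are rejected with explicit errors.
* Non-finite residuals during optimisation are replaced by a large finite
  penalty, steering the search back rather than aborting.
* Every stochastic choice (first-order multi-start, noise) flows from an
  integer seed; identical seeds give byte-identical outputs.
* Series files round-trip bit-identically at 12 significant digits.

## Known limitations

* First-order, temperature-independent kinetics: no pH or VFA inhibition,
  no biomass growth, no CH₄/CO₂ partitioning of the biogas.
* Per-parameter identifiability degrades outside the documented regime
  (see above); the package reports the curve-optimal fit regardless.
* The truncation study assumes the model family is correct; with real
  (model-misspecified) data its errors include a bias term the synthetic
  studies here do not exhibit.
* No confidence intervals are produced; the objective's flat valleys make
  curvature-based intervals unreliable for this family.
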