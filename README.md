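# adkin — first-order kinetics of batch anaerobic digestion

`adkin` models the cumulative biogas production of batch anaerobic-digestion
(BMP) assays with chains of irreversible first-order reactions, fits those
models to measured curves, and quantifies how much assay time a calibrated
model can save.

It is written for practitioners who run or analyse batch digestion tests:
the library estimates the ultimate biogas potential S_max, the kinetic
constants of each process stage, and — through the truncation protocol —
how early an assay could have been stopped while still predicting its final
production within a chosen error.

## The model

The substrate is split into a rapidly biodegradable fraction α and a slowly
biodegradable fraction 1 − α.  The slow pool passes through hydrolysis
(k_L), acidogenesis (k_2) and methanogenesis (k_3); the fast pool — simple
monomers that need no extracellular breakdown — skips hydrolysis (k_R, then
k_3).  With first-order irreversible steps and COD-based bookkeeping, the
four states have closed forms; cumulative biogas is

    S_D(t) = S_max [ α F(k_R, k_3; t) + (1 − α) F(k_L, k_2, k_3; t) ]

where F(k_1, …, k_n; t) is the completed fraction of a linear first-order
chain (the hypoexponential CDF), evaluated through singularity-safe divided
differences so that coincident rates — which fitted optima actually reach —
are handled exactly.  The mass balance S_A + S_B + S_C + S_D = S_A0 holds
identically, S_D(0) = 0, and S_D → S_max.  The intermediate S_C(t) is the
volatile fatty acid (VFA) pool, the standard inhibition indicator.

Five comparator models from the literature are included under the same
interface: single-phase, two-phase and three-phase first-order chains, the
dual-pool single- and two-phase variants, and the Modified Gompertz
sigmoid (which is structurally unable to pass through zero at t = 0).

Fitting minimises ψ(η) = Σ_t [y_exp(t) − S_D(t, η)]² with a
Levenberg–Marquardt core and a staged initialisation: the single-phase
first-order model is fitted first (its optimum is start-independent), and
its optimum (S^x, k^y) seeds the full model as (S^x, k^y/2, k^y, 2k^y,
3k^y, α = 0.5).  A deterministic rate-role reassignment polish then guards
against the label-swap local minima endemic to multi-exponential fitting
(see `docs/methods.md`).

## Worked example

```python
import numpy as np
from adkin import DualPoolParams, fit_model, simulate_measurements, truncation_study

# a thermophilic sludge assay: S_max in litres, rates in 1/day
truth = DualPoolParams(s_a0=4.775, k_l=0.340, k_r=2.139, k_2=0.417,
                       k_3=2.314, alpha=0.265)
series = simulate_measurements("proposed", truth,
                               np.linspace(0, 14.7, 61), unit="L")

fit = fit_model("proposed", series)
print(fit.params)
print(f"R² = {fit.r_squared:.6f}, ψ = {fit.objective:.3g}")

study = truncation_study(series, ["proposed"], series.times[[15, 30, 45, 60]])
print(f"time reduction at 5% error: {study['proposed'].time_reduction:.1f}%")
```

Output:

```
DualPoolParams(s_a0=4.775000000000002, k_l=0.3399999999999898,
               k_r=2.1390000000001006, k_2=0.41700000000001686,
               k_3=2.313999999999878, alpha=0.2650000000000012)
R² = 1.000000, ψ = 3.16e-29
time reduction at 5% error: 75.0%
```

The fit recovers the generating parameters to machine precision; the
truncation study shows that on this (noiseless) curve the model fitted to
the first quarter of the assay already predicts the final production, so
75% of the assay duration carries no extra information for the endpoint.

The same workflows are available from the shell — `adkin fit`, `adkin
compare`, `adkin simulate`, `adkin truncate`, `adkin profiles` — reading
and writing two-column delimited time-series files with a `# unit:` header.
Short narrative scripts for each capability live in `examples/`.

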