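"""Fit the dual-pool model to a synthetic batch-assay biogas curve.

Builds a noisy cumulative biogas series from known kinetics (a thermophilic
sludge assay: fast rates ~2 d⁻¹, hydrolysis 0.34 d⁻¹), runs the staged fit
and prints the estimates next to the generating values.
"""

import numpy as np

from adkin import DualPoolParams, FitConfig, NoiseModel, fit_model, simulate_measurements

truth = DualPoolParams(s_a0=4.775, k_l=0.340, k_r=2.139, k_2=0.417, k_3=2.314, alpha=0.265)
schedule = np.linspace(0.0, 14.7, 61)  # daily-ish sampling over ~15 d
series = simulate_measurements(
    "proposed", truth, schedule,
    noise=NoiseModel("additive-gaussian", sigma_fraction=0.01, seed=42),
    unit="L",
)

fit = fit_model("proposed", series, FitConfig(seed=0))

print(f"{'parameter':>10} {'true':>9} {'fitted':>9}")
for name in ("s_a0", "k_l", "k_r", "k_2", "k_3", "alpha"):
    print(f"{name:>10} {getattr(truth, name):9.4f} {getattr(fit.params, name):9.4f}")
print(f"\nR² = {fit.r_squared:.5f}   ψ = {fit.objective:.4g}   ({fit.n_iterations} evaluations)")
print(
    "S_max is the ultimate biogas potential (L); rates are d⁻¹; alpha is the\n"
    "rapidly biodegradable fraction. With 1% measurement noise the curve is\n"
    "reproduced almost exactly (R² ≈ 0.999) and S_max comes back within ~1%,\n"
    "but the individual fast rates scatter — the flat valleys typical of\n"
    "multi-exponential fits. Rerun with sigma_fraction=0.0 to see every\n"
    "parameter recovered to machine precision."
)
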