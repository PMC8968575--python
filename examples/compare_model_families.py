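"""Rank the kinetic model families on one biogas curve.

Generates a noiseless dual-pool curve (an untreated secondary-sludge assay)
and fits the dual-pool model, the three-phase chain, the single-phase
first-order model and the Modified Gompertz sigmoid to it, reproducing the
typical ranking and the impossible-potential flag.
"""

from adkin import DualPoolParams, compare_models, make_recovery_fixture

truth = DualPoolParams(287.155, 0.076, 1.378, 0.892, 1.262, 0.511)
series, _ = make_recovery_fixture(truth, horizon=5.0 / 0.076, n_points=61, unit="mL/g_VS")

table = compare_models(series, ["proposed", "three-phase", "first-order", "gompertz"])
print(table.to_string(index=False))
print(
    "\nThe dual-pool model reaches R² = 1 on its own curve; the simpler\n"
    "families top out lower and are flagged 'smax_below_last' where their\n"
    "fitted ultimate potential falls below the last measured value — an\n"
    "impossible estimate, since cumulative production can only grow."
)
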