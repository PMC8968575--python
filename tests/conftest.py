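"""Shared fixtures: published parameter sets and canonical recovery series."""

import numpy as np
import pytest

from adkin import DualPoolParams, make_recovery_fixture

# Optimal parameter sets reported for the three published case studies:
# municipal solid waste (g_COD/L), thermophilic waste-activated sludge at
# three total-solids loadings (L), and secondary sludge with/without thermal
# pre-treatment (mL/g_VS).  TS_1 sits exactly on the k_R = k_3 coincidence
# manifold.
PRINTED_SETS = {
    "msw": DualPoolParams(38.1625, 0.0133, 0.1532, 0.1274, 0.1181, 0.3532),
    "sludge_ts1": DualPoolParams(3.818, 0.421, 3.262, 0.422, 3.262, 0.221),
    "sludge_ts2": DualPoolParams(4.775, 0.340, 2.139, 0.417, 2.314, 0.265),
    "sludge_ts3": DualPoolParams(6.998, 0.301, 1.932, 0.413, 2.180, 0.289),
    "pretreated": DualPoolParams(571.579, 0.047, 0.553, 0.094, 0.450, 0.718),
    "untreated": DualPoolParams(287.155, 0.076, 1.378, 0.892, 1.262, 0.511),
}

PARAM_FIELDS = ("s_a0", "k_l", "k_r", "k_2", "k_3", "alpha")


def param_vector(p: DualPoolParams) -> np.ndarray:
    return np.array([getattr(p, f) for f in PARAM_FIELDS])


def canonical_vector(p: DualPoolParams) -> np.ndarray:
    """Generating vector with the k_L ≤ k_2 labelling a biogas-only fit reports."""
    v = param_vector(p)
    if v[1] > v[3]:
        v[1], v[3] = v[3], v[1]
    return v


def min_rate(p: DualPoolParams) -> float:
    return min(p.k_l, p.k_r, p.k_2, p.k_3)


@pytest.fixture(scope="session")
def recovery_series():
    """Noiseless canonical fixtures (horizon 5/min-rate, 61 points) per set."""
    return {
        name: make_recovery_fixture(p, 5.0 / min_rate(p), 61)[0]
        for name, p in PRINTED_SETS.items()
    }
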