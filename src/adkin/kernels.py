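"""Singularity-safe evaluation of linear first-order reaction chains.

Every cumulative-biogas expression in this package is built from the same
primitive: material flowing through a chain of 1–3 irreversible first-order
steps.  For unit initial mass in the first compartment, the content of
compartment ``j`` at time ``t`` is

    x_j(t) = (k_1 ... k_{j-1}) · (-1)^(j-1) · Δ[k_1, ..., k_j] exp(-x t)

where ``Δ[...]`` is the divided difference of x ↦ exp(-x t) over the first
``j`` rates.  The divided-difference form is equivalent to the familiar
sums of exponentials when the rates are distinct, and its confluent limits
(t e^{-kt}, t² e^{-kt}/2, ...) give the correct values when rates coincide
— the case an optimizer walks through, and one that published fits actually
contain.  Rate groups closer than ``COINCIDENCE_RTOL`` relative are merged
onto their mean, which cancels the first-order error of the merge while
avoiding the catastrophic cancellation the raw formulas suffer near
coincidence.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["chain_states", "chain_kernel", "COINCIDENCE_RTOL"]

#: relative rate difference below which the confluent (equal-rate) limit is
#: used.  The nested divided differences of the three-step chain lose
#: ~eps/h² accuracy at node separation h, so the switch must happen well
#: before h² reaches machine epsilon; 3e-5 keeps both branches accurate to
#: ~1e-7 at the crossover.
COINCIDENCE_RTOL = 3e-5


def _as_time_array(t) -> np.ndarray:
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    return t


def _cluster(nodes: Sequence[float]) -> list[tuple[float, int]]:
    """Group nearly equal rates into (representative, multiplicity) pairs."""
    srt = sorted(nodes)
    groups: list[list[float]] = [[srt[0]]]
    for x in srt[1:]:
        ref = groups[-1][0]
        if abs(x - ref) <= COINCIDENCE_RTOL * max(abs(x), abs(ref)):
            groups[-1].append(x)
        else:
            groups.append([x])
    return [(float(np.mean(g)), len(g)) for g in groups]


def _dd_exp(nodes: Sequence[float], t: np.ndarray) -> np.ndarray:
    """Confluent divided difference of exp(-x t) over 1–3 nodes (rates)."""
    groups = _cluster(nodes)
    n = len(nodes)
    if n == 1:
        (a, _), = groups
        return np.exp(-a * t)
    if n == 2:
        if len(groups) == 1:
            (a, _), = groups
            return -t * np.exp(-a * t)  # d/dx exp(-x t) at x=a
        (a, _), (b, _) = groups
        return (np.exp(-b * t) - np.exp(-a * t)) / (b - a)
    if n == 3:
        if len(groups) == 1:
            (a, _), = groups
            return 0.5 * t * t * np.exp(-a * t)  # (1/2) d²/dx² exp(-x t)
        if len(groups) == 2:
            # one double node a, one simple node c (order irrelevant: Δ is symmetric)
            (g0, m0), (g1, m1) = groups
            a, c = (g0, g1) if m0 == 2 else (g1, g0)
            dd_ac = (np.exp(-c * t) - np.exp(-a * t)) / (c - a)
            dd_aa = -t * np.exp(-a * t)
            return (dd_ac - dd_aa) / (c - a)
        (a, _), (b, _), (c, _) = groups
        dd_ab = (np.exp(-b * t) - np.exp(-a * t)) / (b - a)
        dd_bc = (np.exp(-c * t) - np.exp(-b * t)) / (c - b)
        return (dd_bc - dd_ab) / (c - a)
    raise ValueError("chains longer than 3 steps are not supported")


def _chain_states_unchecked(rates: Sequence[float], t: np.ndarray) -> np.ndarray:
    out = np.empty((len(rates), len(np.atleast_1d(t))), dtype=float)
    tt = np.atleast_1d(t)
    prefix = 1.0
    sign = 1.0
    for j, _ in enumerate(rates, start=1):
        out[j - 1] = prefix * sign * _dd_exp(rates[:j], tt)
        prefix *= rates[j - 1]
        sign = -sign
    return out


def chain_states(rates: Sequence[float], t) -> np.ndarray:
    """Per-compartment content of a 1–3 step first-order chain, unit input.

    Parameters
    ----------
    rates:
        Positive rate constants, in chain order (d⁻¹).
    t:
        Non-negative time or array of times (d).

    Returns
    -------
    Array of shape ``(len(rates), len(t))``; row ``j`` holds the amount
    currently in compartment ``j``.
    """
    rates = [float(k) for k in rates]
    if not 1 <= len(rates) <= 3:
        raise ValueError("rates must contain 1 to 3 entries")
    if any(k <= 0 for k in rates):
        raise ValueError("all rates must be positive")
    return _chain_states_unchecked(rates, _as_time_array(t))


def chain_kernel(rates: Sequence[float], t) -> np.ndarray:
    """Fraction of material that has traversed the whole chain by time t.

    Equals 1 - e^(-k t) for a single step and the hypoexponential (Erlang
    when rates coincide) CDF in general; continuous in the rates, including
    on the coincident-rate manifolds.
    """
    states = chain_states(rates, t)
    return 1.0 - states.sum(axis=0)
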