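"""Closed-form kinetic models of cumulative biogas production in batch assays.

The centrepiece is the dual-pool, three-phase model: substrate split into a
rapidly biodegradable pool (fraction ``alpha``, degraded via acidification
``k_r`` then methanogenesis ``k_3``) and a slowly biodegradable pool
(hydrolysis ``k_l``, acidogenesis ``k_2``, methanogenesis ``k_3``).  Its
four state functions — remaining substrate S_A, hydrolysis products S_B,
volatile fatty acids S_C and cumulative biogas S_D — have closed forms
built from the chain kernels in :mod:`adkin.kernels`.

Five comparator models from the batch-digestion literature are provided
under the same calling convention, plus a registry (`MODELS`) that the
fitting, evaluation and CLI layers use to address models by name.
"""

from __future__ import annotations

import math
from dataclasses import astuple, dataclass, fields
from typing import Callable, Sequence

import numpy as np

from .kernels import _as_time_array, _chain_states_unchecked, chain_kernel, chain_states
from .params import (
    DualPoolParams,
    DualPoolSinglePhaseParams,
    DualPoolTwoPhaseParams,
    FirstOrderParams,
    GompertzParams,
    ThreePhaseParams,
    Trajectory,
    TwoPhaseParams,
)

__all__ = [
    "eval_sa",
    "eval_sb",
    "eval_sc",
    "eval_sd",
    "dual_pool_trajectory",
    "eval_first_order",
    "eval_two_phase",
    "eval_three_phase",
    "eval_dual_pool_single",
    "eval_dual_pool_two_phase",
    "eval_gompertz",
    "MODELS",
    "ModelSpec",
]


# ---------------------------------------------------------------- dual pool

def eval_sa(params: DualPoolParams, times) -> np.ndarray:
    """Remaining biodegradable substrate S_A(t) = S_A0 (α e^{-k_R t} + (1-α) e^{-k_L t})."""
    t = _as_time_array(times)
    a = params.alpha
    return params.s_a0 * (a * np.exp(-params.k_r * t) + (1.0 - a) * np.exp(-params.k_l * t))


def eval_sb(params: DualPoolParams, times) -> np.ndarray:
    """Hydrolysis products S_B(t), fed by the slow pool only; zero at t = 0.

    Evaluated as the second compartment of the (k_L, k_2) chain so that the
    k_2 → k_L coincidence reduces smoothly to S_A0 (1-α) k_L t e^{-k_L t}.
    """
    t = _as_time_array(times)
    if params.alpha == 1.0:
        return np.zeros_like(t)
    x2 = chain_states((params.k_l, params.k_2), t)[1]
    return params.s_a0 * (1.0 - params.alpha) * x2


def eval_sc(params: DualPoolParams, times) -> np.ndarray:
    """Volatile fatty acids S_C(t); zero initial VFA concentration.

    Sum of the fast-pool two-step chain (k_R, k_3) and the slow-pool
    three-step chain (k_L, k_2, k_3), each taken at its VFA compartment.
    """
    t = _as_time_array(times)
    out = np.zeros_like(t)
    a = params.alpha
    if a > 0.0:
        out += a * chain_states((params.k_r, params.k_3), t)[1]
    if a < 1.0:
        out += (1.0 - a) * chain_states((params.k_l, params.k_2, params.k_3), t)[2]
    return params.s_a0 * out


def eval_sd(params: DualPoolParams, times) -> np.ndarray:
    """Cumulative biogas S_D(t); 0 at t = 0, → S_max = s_a0 as t → ∞.

    Mixture of completed-chain fractions: α through (k_R, k_3) and (1-α)
    through (k_L, k_2, k_3).  Degenerate pool fractions evaluate the reduced
    model directly.
    """
    t = _as_time_array(times)
    a = params.alpha
    if a == 0.0:
        frac = chain_kernel((params.k_l, params.k_2, params.k_3), t)
    elif a == 1.0:
        frac = chain_kernel((params.k_r, params.k_3), t)
    else:
        frac = a * chain_kernel((params.k_r, params.k_3), t) + (1.0 - a) * chain_kernel(
            (params.k_l, params.k_2, params.k_3), t
        )
    return params.s_a0 * frac


def dual_pool_trajectory(params: DualPoolParams, times) -> Trajectory:
    """All four state trajectories on a grid, packaged with the mass-balance invariant."""
    t = _as_time_array(np.atleast_1d(times))
    return Trajectory(
        times=t,
        s_a=eval_sa(params, t),
        s_b=eval_sb(params, t),
        s_c=eval_sc(params, t),
        s_d=eval_sd(params, t),
    )


# ---------------------------------------------------------------- comparators

def eval_first_order(params: FirstOrderParams, times) -> np.ndarray:
    """Single-phase first-order cumulative biogas s (1 - e^{-k_1a t})."""
    t = _as_time_array(times)
    return params.s * -np.expm1(-params.k_1a * t)


def eval_two_phase(params: TwoPhaseParams, times) -> np.ndarray:
    """Two-phase (acidification → methanation) cumulative biogas."""
    return params.s * chain_kernel((params.k_2a, params.k_2b), times)


def eval_three_phase(params: ThreePhaseParams, times) -> np.ndarray:
    """Three-phase (hydrolysis → acidogenesis → methanogenesis) cumulative biogas."""
    return params.s * chain_kernel((params.k_3a, params.k_3b, params.k_3c), times)


def eval_dual_pool_single(params: DualPoolSinglePhaseParams, times) -> np.ndarray:
    """Dual-pool single-phase: s (1 - α e^{-k_1R t} - (1-α) e^{-k_1L t})."""
    t = _as_time_array(times)
    a = params.alpha
    return params.s * (1.0 - a * np.exp(-params.k_1r * t) - (1.0 - a) * np.exp(-params.k_1l * t))


def eval_dual_pool_two_phase(params: DualPoolTwoPhaseParams, times) -> np.ndarray:
    """Dual-pool two-phase: pool-specific acidification rates, shared methanation."""
    t = _as_time_array(times)
    a = params.alpha
    out = np.zeros_like(np.atleast_1d(t), dtype=float)
    if a > 0.0:
        out = out + a * chain_kernel((params.k_2r, params.k_2b), t)
    if a < 1.0:
        out = out + (1.0 - a) * chain_kernel((params.k_2l, params.k_2b), t)
    return params.s * out


def eval_gompertz(params: GompertzParams, times) -> np.ndarray:
    """Modified Gompertz sigmoid P exp(-exp(μ e / P (λ - t) + 1)).

    Strictly positive at t = 0 for every valid parameter set — the model is
    a mortality-curve re-parameterisation, not a digestion mass balance, so
    it cannot honour the zero-initial-biogas condition.
    """
    t = _as_time_array(times)
    inner = params.mu * math.e / params.p * (params.lam - t) + 1.0
    return params.p * np.exp(-np.exp(inner))


# ---------------------------------------------------------------- registry

#: parameter kinds drive the positivity re-parameterisation used in fitting
_KIND = {"positive": "positive", "fraction": "fraction", "free": "free"}


@dataclass(frozen=True)
class ModelSpec:
    """Everything the generic fitting/evaluation layers need to know about a model."""

    name: str
    param_cls: type
    kinds: tuple[str, ...]  # one of positive | fraction | free, per field
    amplitude_field: str  # the ultimate-potential parameter

    @property
    def field_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in fields(self.param_cls))

    @property
    def n_params(self) -> int:
        return len(self.kinds)

    def to_vector(self, params) -> np.ndarray:
        if not isinstance(params, self.param_cls):
            raise TypeError(f"expected {self.param_cls.__name__} for model '{self.name}'")
        return np.array(astuple(params), dtype=float)

    def from_vector(self, vec: Sequence[float]):
        return self.param_cls(*[float(v) for v in vec])

    def evaluate(self, params, times) -> np.ndarray:
        return _EVALUATORS[self.name](params, times)

    def evaluate_raw(self, vec: Sequence[float], times) -> np.ndarray:
        """Evaluate from a bare vector without constructing/validating params.

        Used inside optimizer iterations, where intermediate vectors may be
        unphysical when no bounds are imposed.
        """
        return _RAW_EVALUATORS[self.name](np.asarray(vec, dtype=float), np.asarray(times, float))


def _raw_dual_pool(v: np.ndarray, t: np.ndarray) -> np.ndarray:
    s_a0, k_l, k_r, k_2, k_3, a = v
    fast = 1.0 - _chain_states_unchecked([k_r, k_3], t).sum(axis=0)
    slow = 1.0 - _chain_states_unchecked([k_l, k_2, k_3], t).sum(axis=0)
    return s_a0 * (a * fast + (1.0 - a) * slow)


def _raw_first_order(v, t):
    return v[0] * -np.expm1(-v[1] * t)


def _raw_two_phase(v, t):
    return v[0] * (1.0 - _chain_states_unchecked([v[1], v[2]], t).sum(axis=0))


def _raw_three_phase(v, t):
    return v[0] * (1.0 - _chain_states_unchecked([v[1], v[2], v[3]], t).sum(axis=0))


def _raw_dual_pool_single(v, t):
    s, a, k_1r, k_1l = v
    return s * (1.0 - a * np.exp(-k_1r * t) - (1.0 - a) * np.exp(-k_1l * t))


def _raw_dual_pool_two_phase(v, t):
    s, a, k_2r, k_2l, k_2b = v
    fast = 1.0 - _chain_states_unchecked([k_2r, k_2b], t).sum(axis=0)
    slow = 1.0 - _chain_states_unchecked([k_2l, k_2b], t).sum(axis=0)
    return s * (a * fast + (1.0 - a) * slow)


def _raw_gompertz(v, t):
    p, mu, lam = v
    return p * np.exp(-np.exp(mu * math.e / p * (lam - t) + 1.0))


_EVALUATORS: dict[str, Callable] = {
    "proposed": eval_sd,
    "first-order": eval_first_order,
    "two-phase": eval_two_phase,
    "three-phase": eval_three_phase,
    "dual-pool-single": eval_dual_pool_single,
    "dual-pool-two-phase": eval_dual_pool_two_phase,
    "gompertz": eval_gompertz,
}

_RAW_EVALUATORS: dict[str, Callable] = {
    "proposed": _raw_dual_pool,
    "first-order": _raw_first_order,
    "two-phase": _raw_two_phase,
    "three-phase": _raw_three_phase,
    "dual-pool-single": _raw_dual_pool_single,
    "dual-pool-two-phase": _raw_dual_pool_two_phase,
    "gompertz": _raw_gompertz,
}

MODELS: dict[str, ModelSpec] = {
    "proposed": ModelSpec(
        "proposed",
        DualPoolParams,
        ("positive", "positive", "positive", "positive", "positive", "fraction"),
        "s_a0",
    ),
    "first-order": ModelSpec("first-order", FirstOrderParams, ("positive", "positive"), "s"),
    "two-phase": ModelSpec(
        "two-phase", TwoPhaseParams, ("positive", "positive", "positive"), "s"
    ),
    "three-phase": ModelSpec(
        "three-phase", ThreePhaseParams, ("positive",) * 4, "s"
    ),
    "dual-pool-single": ModelSpec(
        "dual-pool-single",
        DualPoolSinglePhaseParams,
        ("positive", "fraction", "positive", "positive"),
        "s",
    ),
    "dual-pool-two-phase": ModelSpec(
        "dual-pool-two-phase",
        DualPoolTwoPhaseParams,
        ("positive", "fraction", "positive", "positive", "positive"),
        "s",
    ),
    "gompertz": ModelSpec("gompertz", GompertzParams, ("positive", "positive", "free"), "p"),
}


def get_model(name: str) -> ModelSpec:
    try:
        return MODELS[name]
    except KeyError:
        valid = ", ".join(sorted(MODELS))
        raise KeyError(f"unknown model '{name}'; valid identifiers: {valid}") from None
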