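"""Parameter containers for the batch anaerobic-digestion kinetic models.

All models describe cumulative biogas production of a sealed batch assay as
chains of irreversible first-order steps.  Rate constants are in d⁻¹; the
amplitude parameter (ultimate biogas potential / initial biodegradable
substrate) carries whatever unit the measured series uses (g_COD/L, L,
mL/g_VS, ...), so the model functions themselves are unit-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "DualPoolParams",
    "FirstOrderParams",
    "TwoPhaseParams",
    "ThreePhaseParams",
    "DualPoolSinglePhaseParams",
    "DualPoolTwoPhaseParams",
    "GompertzParams",
    "Trajectory",
]


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class DualPoolParams:
    """Parameters of the dual-pool, three-phase model.

    The substrate is split into a rapidly biodegradable fraction ``alpha``
    (degraded in two steps: acidification at ``k_r``, then methanogenesis at
    ``k_3``) and a slowly biodegradable fraction ``1 - alpha`` (hydrolysis at
    ``k_l``, acidogenesis at ``k_2``, methanogenesis at ``k_3``).

    Attributes
    ----------
    s_a0:
        Initial biodegradable substrate concentration; equals the ultimate
        biogas potential S_max under the total-conversion assumption.
    k_l, k_r, k_2, k_3:
        First-order rate constants (d⁻¹): slow-pool hydrolysis, fast-pool
        acidification, hydrolysate→VFA, and VFA→biogas respectively.
    alpha:
        Rapidly biodegradable fraction, in [0, 1].
    """

    s_a0: float
    k_l: float
    k_r: float
    k_2: float
    k_3: float
    alpha: float

    def __post_init__(self) -> None:
        _require(self.s_a0 > 0, f"s_a0 must be positive, got {self.s_a0}")
        for name in ("k_l", "k_r", "k_2", "k_3"):
            _require(getattr(self, name) > 0, f"{name} must be positive")
        _require(0.0 <= self.alpha <= 1.0, f"alpha must lie in [0, 1], got {self.alpha}")

    @property
    def c_r(self) -> float:
        """Amount of rapidly biodegradable substrate, alpha * s_a0."""
        return self.alpha * self.s_a0

    @property
    def c_l(self) -> float:
        """Amount of slowly biodegradable substrate, (1 - alpha) * s_a0."""
        return (1.0 - self.alpha) * self.s_a0


@dataclass(frozen=True)
class FirstOrderParams:
    """Single-phase first-order model: S(t) = s (1 - e^(-k_1a t))."""

    s: float
    k_1a: float

    def __post_init__(self) -> None:
        _require(self.s > 0, "s must be positive")
        _require(self.k_1a > 0, "k_1a must be positive")


@dataclass(frozen=True)
class TwoPhaseParams:
    """Two-phase chain: acidification (k_2a) then methanation (k_2b)."""

    s: float
    k_2a: float
    k_2b: float

    def __post_init__(self) -> None:
        for name in ("s", "k_2a", "k_2b"):
            _require(getattr(self, name) > 0, f"{name} must be positive")


@dataclass(frozen=True)
class ThreePhaseParams:
    """Three-phase chain: hydrolysis (k_3a), acidogenesis (k_3b), methanogenesis (k_3c)."""

    s: float
    k_3a: float
    k_3b: float
    k_3c: float

    def __post_init__(self) -> None:
        for name in ("s", "k_3a", "k_3b", "k_3c"):
            _require(getattr(self, name) > 0, f"{name} must be positive")


@dataclass(frozen=True)
class DualPoolSinglePhaseParams:
    """Dual-pool single-phase model: each pool converts to biogas in one step."""

    s: float
    alpha: float
    k_1r: float
    k_1l: float

    def __post_init__(self) -> None:
        for name in ("s", "k_1r", "k_1l"):
            _require(getattr(self, name) > 0, f"{name} must be positive")
        _require(0.0 <= self.alpha <= 1.0, "alpha must lie in [0, 1]")


@dataclass(frozen=True)
class DualPoolTwoPhaseParams:
    """Dual-pool two-phase model: pool-specific acidification, shared methanation."""

    s: float
    alpha: float
    k_2r: float
    k_2l: float
    k_2b: float

    def __post_init__(self) -> None:
        for name in ("s", "k_2r", "k_2l", "k_2b"):
            _require(getattr(self, name) > 0, f"{name} must be positive")
        _require(0.0 <= self.alpha <= 1.0, "alpha must lie in [0, 1]")


@dataclass(frozen=True)
class GompertzParams:
    """Modified Gompertz model: P exp(-exp(mu·e/P (lam - t) + 1)).

    ``p`` is the maximum biogas production, ``mu`` the maximum production
    rate (unit·d⁻¹) and ``lam`` the lag time (d).  Unlike the first-order
    chain models this sigmoid is not zero at t = 0.
    """

    p: float
    mu: float
    lam: float

    def __post_init__(self) -> None:
        _require(self.p > 0, "p must be positive")
        _require(self.mu > 0, "mu must be positive")
        _require(self.lam >= 0, "lam must be non-negative")


@dataclass(frozen=True)
class Trajectory:
    """State trajectories of the dual-pool model on a time grid.

    ``s_a`` is remaining biodegradable substrate, ``s_b`` hydrolysis
    products, ``s_c`` volatile fatty acids and ``s_d`` cumulative biogas.
    The four pools always sum to the initial substrate amount (COD-style
    mass balance).
    """

    times: np.ndarray
    s_a: np.ndarray
    s_b: np.ndarray
    s_c: np.ndarray
    s_d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.times)
        for f in fields(self):
            _require(len(getattr(self, f.name)) == n, "trajectory arrays must share one length")

    @property
    def total(self) -> np.ndarray:
        """Pool sum at every grid point; constant (= s_a0) for a valid trajectory."""
        return self.s_a + self.s_b + self.s_c + self.s_d

    def mass_balance_error(self) -> float:
        """Maximum relative deviation of the pool sum from its t=0 value."""
        total = self.total
        ref = total[0] if len(total) else np.nan
        return float(np.max(np.abs(total - ref)) / abs(ref))
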