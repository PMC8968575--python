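"""Goodness-of-fit diagnostics, model comparison, and the truncation study.

The truncation (predictive-capacity) protocol asks: if the batch assay had
been stopped at time ``t`` and the model fitted only to the data available
by then, how far off would its estimate of the final cumulative production
be?  The prediction error at a cutoff is |S_Du - y_expu| / y_expu, where
``y_expu`` is the last measured cumulative value and ``S_Du`` the truncated
fit evaluated at the final experimental time.  The time reduction at a
threshold is the share of the assay that could have been skipped while
keeping the prediction error below the threshold at the first acceptable
cutoff and every later one (a transient dip below the threshold would not
justify stopping an assay, so the crossing must be sustained).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fitting import FitConfig, fit_model
from .models import get_model
from .series import TimeSeries

__all__ = [
    "RelativeErrorReport",
    "relative_error_series",
    "prediction_error_at_cutoff",
    "TruncationReport",
    "truncation_study",
    "time_reduction_at_threshold",
    "compare_models",
]


@dataclass(frozen=True)
class RelativeErrorReport:
    """Signed per-point relative error (model - observed)/observed."""

    times: np.ndarray
    errors: np.ndarray
    n_skipped: int  # points with a zero observation, excluded from the quotient

    @property
    def max_abs(self) -> float:
        return float(np.max(np.abs(self.errors))) if len(self.errors) else 0.0


def relative_error_series(data: TimeSeries, fitted: Sequence[float]) -> RelativeErrorReport:
    """Per-point (fitted - observed)/observed; zero observations are skipped."""
    fitted = np.asarray(fitted, dtype=float)
    if len(fitted) != len(data):
        raise ValueError("fitted values must match the data length")
    nonzero = data.values != 0.0
    n_skipped = int((~nonzero).sum())
    if n_skipped:
        warnings.warn(
            f"skipping {n_skipped} zero-valued observation(s) in the relative-error series",
            stacklevel=2,
        )
    errors = (fitted[nonzero] - data.values[nonzero]) / data.values[nonzero]
    return RelativeErrorReport(times=data.times[nonzero], errors=errors, n_skipped=n_skipped)


def prediction_error_at_cutoff(
    data: TimeSeries,
    model: str,
    cutoff: float,
    config: Optional[FitConfig] = None,
    endpoint: str = "final_time",
) -> float:
    """Relative error of the final-production estimate from a truncated fit.

    The model is fitted using only points with time ≤ ``cutoff``; its
    prediction is compared against the last observed cumulative value.
    ``endpoint="final_time"`` evaluates the fitted curve at the final
    experimental time; ``endpoint="asymptote"`` uses the fitted ultimate
    potential (the t → ∞ value) instead.
    """
    spec = get_model(model)
    config = config or FitConfig()
    mask = data.times <= cutoff
    n_avail = int(mask.sum())
    n_needed = spec.n_params + 1
    if n_avail < n_needed:
        feasible = data.times[n_needed - 1] if len(data) >= n_needed else np.inf
        raise ValueError(
            f"cutoff {cutoff} leaves {n_avail} points for the {spec.n_params}-parameter "
            f"model '{model}'; the earliest feasible cutoff is t={feasible}"
        )
    truncated = TimeSeries(data.times[mask], data.values[mask], data.unit)
    fit = fit_model(model, truncated, config)
    y_final = float(data.values[-1])
    if y_final == 0.0:
        raise ValueError("final observation is zero; prediction error undefined")
    if endpoint == "final_time":
        pred = float(spec.evaluate(fit.params, np.array([data.duration]))[0])
    elif endpoint == "asymptote":
        pred = float(getattr(fit.params, spec.amplitude_field))
    else:
        raise ValueError("endpoint must be 'final_time' or 'asymptote'")
    return abs(pred - y_final) / abs(y_final)


@dataclass(frozen=True)
class TruncationReport:
    """Prediction errors of one model across truncation cutoffs."""

    model: str
    cutoffs: np.ndarray
    prediction_errors: np.ndarray  # NaN marks an infeasible cutoff
    threshold: float
    time_reduction: float  # % of assay duration that could be skipped

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cutoff_d": self.cutoffs, "prediction_error": self.prediction_errors}
        ).assign(model=self.model)


def time_reduction_at_threshold(
    report: "TruncationReport", total_duration: float
) -> float:
    """Percentage of the assay duration saved at the report's threshold.

    Finds the smallest evaluated cutoff whose prediction error is below the
    threshold at that cutoff *and at every later evaluated cutoff*, and
    returns 100 (T - t*)/T.  Returns 0 when no cutoff qualifies.
    """
    order = np.argsort(report.cutoffs)
    cutoffs = np.asarray(report.cutoffs, dtype=float)[order]
    errors = np.asarray(report.prediction_errors, dtype=float)[order]
    evaluated = np.isfinite(errors)
    if not evaluated.any():
        return 0.0
    ok = errors < report.threshold
    t_star = None
    # scan from the latest cutoff backwards while the criterion holds
    for c, e_ok, seen in zip(cutoffs[::-1], ok[::-1], evaluated[::-1]):
        if not seen:
            continue
        if not e_ok:
            break
        t_star = c
    if t_star is None:
        return 0.0
    return 100.0 * (total_duration - t_star) / total_duration


def truncation_study(
    data: TimeSeries,
    models: Sequence[str],
    cutoffs: Optional[Sequence[float]] = None,
    config: Optional[FitConfig] = None,
    threshold: float = 0.05,
) -> dict[str, TruncationReport]:
    """Prediction error of each model at each cutoff, plus the time reduction.

    When ``cutoffs`` is omitted, every experimental time point from the
    earliest feasible one (per model) is used.  Infeasible cutoffs are
    recorded as NaN, never as zero.
    """
    config = config or FitConfig()
    reports: dict[str, TruncationReport] = {}
    for model in models:
        spec = get_model(model)
        if cutoffs is None:
            model_cutoffs = data.times[data.times >= data.times[spec.n_params]]
        else:
            model_cutoffs = np.asarray(cutoffs, dtype=float)
        errors = np.full(len(model_cutoffs), np.nan)
        for i, c in enumerate(model_cutoffs):
            try:
                errors[i] = prediction_error_at_cutoff(data, model, c, config)
            except ValueError:
                pass  # infeasible cutoff stays NaN
        partial = TruncationReport(model, np.asarray(model_cutoffs, float), errors, threshold, 0.0)
        reduction = time_reduction_at_threshold(partial, data.duration)
        reports[model] = TruncationReport(
            model, partial.cutoffs, errors, threshold, reduction
        )
    return reports


def compare_models(
    data: TimeSeries,
    models: Sequence[str],
    config: Optional[FitConfig] = None,
) -> pd.DataFrame:
    """Fit each model and tabulate parameters, ψ and R², ranked by R².

    A model whose fitted ultimate potential falls below the last observed
    cumulative value is flagged ``smax_below_last`` — a physically
    impossible estimate, since cumulative production can only grow.
    Per-model fit failures are recorded in the ``flags`` column rather than
    aborting the comparison.
    """
    config = config or FitConfig()
    last_obs = float(data.values[-1])
    rows = []
    for model in models:
        spec = get_model(model)
        try:
            fit = fit_model(model, data, config)
        except ValueError as exc:
            rows.append(
                {"model": model, "params": "", "psi": np.nan, "r2": np.nan,
                 "flags": f"error: {exc}"}
            )
            continue
        vec = spec.to_vector(fit.params)
        params_str = ";".join(
            f"{name}={val:.6g}" for name, val in zip(spec.field_names, vec)
        )
        flags = []
        if float(getattr(fit.params, spec.amplitude_field)) < last_obs:
            flags.append("smax_below_last")
        if not fit.converged:
            flags.append("not_converged")
        rows.append(
            {"model": model, "params": params_str, "psi": fit.objective,
             "r2": fit.r_squared, "flags": ",".join(flags)}
        )
    frame = pd.DataFrame(rows, columns=["model", "params", "psi", "r2", "flags"])
    return frame.sort_values("r2", ascending=False, na_position="last").reset_index(drop=True)
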