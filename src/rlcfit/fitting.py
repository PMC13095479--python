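"""Nonlinear least-squares fitting of light-response models to a curve.

A fit minimizes the unweighted residual sum of squares between observed
ETR values and the model prediction over the curve's light steps, using a
Levenberg-Marquardt-contract optimizer (trust-region-reflective when sign
bounds are active) with ftol = xtol = 1e-10 and at most 1000 function
evaluations.  Start parameters default to data-driven heuristics; bounds
default to each model's sign conventions.  Goodness of fit is summarized
as RSS, RMSE = sqrt(RSS/n) and rRMSE = RMSE / mean(observed ETR).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from . import light_models as lm
from .etr_core import MIN_FIT_STEPS

__all__ = [
    "Metrics",
    "FitResult",
    "ComparisonTable",
    "FitError",
    "default_start_params",
    "fit_model",
    "goodness_metrics",
    "compare_models",
]

_FTOL = 1e-10
_XTOL = 1e-10
_MAX_NFEV = 1000


class FitError(RuntimeError):
    """A regression did not converge or could not be attempted."""


@dataclass(frozen=True)
class Metrics:
    rss: float
    rmse: float
    rrmse: Optional[float]  # None when mean(observed) == 0


@dataclass(frozen=True)
class FitResult:
    model: str
    raw_params: lm.ModelParams
    derived: lm.DerivedParams
    metrics: Metrics
    converged: bool
    n_iterations: int
    start_params: lm.ModelParams
    predicted: tuple  # ((par, etr_hat), ...) one per observed light step


@dataclass(frozen=True)
class ComparisonTable:
    """Per-model RSS for one curve; ``best_model`` minimizes RSS among the
    converged fits, ties broken by fewest parameters then model order."""

    per_model: dict  # model -> {"rss": float|None, "converged": bool}
    best_model: str
    fits: dict  # model -> FitResult | None


def goodness_metrics(observed: Sequence[float], predicted: Sequence[float]) -> Metrics:
    """RSS, RMSE and mean-normalized RMSE of a prediction."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape:
        raise ValueError(f"length mismatch: {o.shape} observed vs {p.shape} predicted")
    if o.size < 1:
        raise ValueError("need at least one observation")
    rss = float(np.sum((o - p) ** 2))
    rmse = math.sqrt(rss / o.size)
    mean = float(np.mean(o))
    rrmse = rmse / mean if mean != 0.0 else None
    return Metrics(rss=rss, rmse=rmse, rrmse=rrmse)


def default_start_params(model: str, curve) -> lm.ModelParams:
    """Data-driven start values for ``model`` on ``curve``.

    Heuristics: the initial slope ``alpha0`` is the least-squares line
    through the origin over the three lowest nonzero-PAR steps; the ETR
    ceiling ``etrmax0`` is the maximum observed ETR and ``im0`` its PAR.
    Each model's start is then an approximate inversion of its derived-
    parameter algebra at those anchors.
    """
    par = curve.par
    etr = curve.etr
    if len(par) < MIN_FIT_STEPS:
        raise FitError(
            f"too few points to fit: {len(par)} light steps, need {MIN_FIT_STEPS}")
    if np.all(etr == 0):
        raise FitError("cannot choose start parameters: all observed ETR are zero")

    nz = par > 0
    low = np.argsort(par[nz])[:3]
    p_low, e_low = par[nz][low], etr[nz][low]
    denom = float(np.sum(p_low * p_low))
    alpha0 = float(np.sum(p_low * e_low)) / denom if denom > 0 else 0.0
    if alpha0 <= 0:
        raise FitError("cannot choose start parameters: non-positive initial slope")
    k = int(np.argmax(etr))
    etrmax0 = float(etr[k])
    im0 = float(par[k])

    if model == "platt":
        return lm.PlattParams(ps=1.2 * etrmax0, alpha=alpha0, beta=alpha0 / 100.0)
    if model == "walsby":
        return lm.WalsbyParams(etr_max=1.2 * etrmax0, alpha=alpha0,
                               beta=-alpha0 / 100.0)
    if model == "eilers_peeters":
        c = 1.0 / alpha0
        a = c / im0**2
        b = max(1.0 / etrmax0 - 2.0 * math.sqrt(a * c), 1e-12)
        return lm.EilersPeetersParams(a=a, b=b, c=c)
    if model == "vollenweider":
        return lm.VollenweiderParams(pmax=1.2 * etrmax0,
                                     a=alpha0 / (1.2 * etrmax0),
                                     alpha=1.0 / (2.0 * im0), n=1.0)
    raise ValueError(f"unknown model {model!r}; expected one of {lm.MODEL_ORDER}")


def fit_model(
    curve,
    model: str,
    start: Optional[lm.ModelParams] = None,
    bounds: Optional[tuple] = None,
) -> FitResult:
    """Fit ``model`` to ``curve`` by bounded nonlinear least squares.

    Deterministic given (curve, start, bounds).  Raises :class:`FitError`
    when the optimizer fails, returns non-finite parameters, or ends with
    a worse RSS than the start values — the error message recommends
    adjusting the start parameter values.
    """
    par = curve.par
    etr = curve.etr
    if len(par) < MIN_FIT_STEPS:
        raise FitError(
            f"too few points to fit: {len(par)} light steps, need {MIN_FIT_STEPS}")

    if start is None:
        start = default_start_params(model, curve)
    theta0 = lm.params_to_array(model, start)
    lo, hi = lm.default_bounds(model) if bounds is None else (
        np.asarray(bounds[0], dtype=float), np.asarray(bounds[1], dtype=float))
    theta0 = np.clip(theta0, lo, hi)

    pred_fn = lm._PREDICT[model]

    def residuals(theta):
        return pred_fn(lm.params_from_array(model, theta), par) - etr

    res = least_squares(residuals, theta0, bounds=(lo, hi), method="trf",
                        ftol=_FTOL, xtol=_XTOL, max_nfev=_MAX_NFEV)

    rss_start = float(np.sum(residuals(theta0) ** 2))
    rss_fit = float(np.sum(res.fun**2))
    failed = (
        res.status <= 0
        or not np.all(np.isfinite(res.x))
        or rss_fit > rss_start * (1.0 + 1e-9) + 1e-12
    )
    if failed:
        raise FitError(
            f"{model} regression did not converge on {curve.source_file!r} "
            f"(optimizer status {res.status}); try adjusting the start "
            "parameter values"
        )

    fitted = lm.params_from_array(model, res.x)
    try:
        fitted.validate()
        derived = lm.derive(model, fitted)
    except (lm.InvalidParamsError, lm.NoInteriorMaximumError) as exc:
        raise FitError(
            f"{model} regression on {curve.source_file!r} converged to an "
            f"invalid parameter set ({exc}); try adjusting the start "
            "parameter values"
        ) from exc

    predicted = np.asarray(pred_fn(fitted, par), dtype=float)
    return FitResult(
        model=model,
        raw_params=fitted,
        derived=derived,
        metrics=goodness_metrics(etr, predicted),
        converged=True,
        n_iterations=int(res.nfev),
        start_params=start,
        predicted=tuple(zip(par.tolist(), predicted.tolist())),
    )


def compare_models(curve, models: Sequence[str] = lm.MODEL_ORDER) -> ComparisonTable:
    """Fit every model with default starts and rank them by RSS.

    Models that fail to converge are recorded as such and excluded from
    the ``best_model`` selection; if all fail, a :class:`FitError` is
    raised.
    """
    per_model: dict = {}
    fits: dict = {}
    for model in models:
        try:
            fit = fit_model(curve, model)
            per_model[model] = {"rss": fit.metrics.rss, "converged": True}
            fits[model] = fit
        except FitError:
            per_model[model] = {"rss": None, "converged": False}
            fits[model] = None
    converged = [m for m in models if per_model[m]["converged"]]
    if not converged:
        raise FitError(
            f"all models failed to converge on {curve.source_file!r}; "
            "try adjusting the start parameter values"
        )
    best = min(
        converged,
        key=lambda m: (per_model[m]["rss"], lm.n_params(m), lm.MODEL_ORDER.index(m)),
    )
    return ComparisonTable(per_model=per_model, best_model=best, fits=fits)
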