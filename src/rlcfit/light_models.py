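"""Photosynthesis-irradiance model functions and derived kinetic parameters.

Four classic light-response models are provided, each mapping irradiance
``I`` (PAR, umol photons m-2 s-1) to an electron transport rate (ETR,
umol electrons m-2 s-1):

* Eilers-Peeters:  ``ETR(I) = I / (a*I^2 + b*I + c)``
* Platt:           ``ETR(I) = ps * (1 - exp(-alpha*I/ps)) * exp(-beta*I/ps)``
* Walsby (respiration term removed):
                   ``ETR(I) = etr_max * (1 - exp(-alpha*I/etr_max)) + beta*I``
* Vollenweider:    ``ETR(I) = pmax * (a*I/sqrt(1+(a*I)^2))
                              * (1/sqrt(1+(alpha*I)^2))**n``

Each model's raw regression parameters are mapped onto one standardized
("modified") parameter set so that curves fitted with different models can
be compared field-by-field: the initial slope ``alpha``, the photoinhibition
index ``beta``, the realized curve maximum ``etrmax_with_photoinhibition``
and its location ``im_with_photoinhibition``, the uninhibited saturation
level ``etrmax_without_photoinhibition``, the light-saturation onsets
``ik_* = etrmax_* / alpha``, the Eilers-Peeters peak-sharpness index ``w``,
the Platt inhibition scale ``ib`` and the with/without-photoinhibition
ratio.  Parameters a model does not define are NA (represented as ``None``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Callable, Optional, Union

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "MODEL_ORDER",
    "EilersPeetersParams",
    "PlattParams",
    "WalsbyParams",
    "VollenweiderParams",
    "DerivedParams",
    "ModelParams",
    "predict",
    "derive",
    "derive_eilers_peeters",
    "derive_platt",
    "derive_walsby",
    "derive_vollenweider",
    "numeric_curve_max",
    "params_from_array",
    "params_to_array",
    "default_bounds",
    "n_params",
]

#: canonical model order, also the final tie-break order in comparisons
MODEL_ORDER = ("eilers_peeters", "platt", "walsby", "vollenweider")

#: below this magnitude a photoinhibition slope is treated as exactly zero,
#: avoiding catastrophic cancellation in (beta/(alpha+beta))**(beta/alpha)
BETA_TOL = 1e-12

ArrayLike = Union[float, np.ndarray]


class InvalidParamsError(ValueError):
    """Raised when model parameters violate their domain invariants."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidParamsError(msg)


@dataclass(frozen=True)
class EilersPeetersParams:
    """ETR(I) = I / (a*I^2 + b*I + c); peaked for a,c > 0, b + 2*sqrt(a*c) > 0."""

    a: float
    b: float
    c: float

    def validate(self) -> None:
        _require(self.a > 0, f"eilers_peeters: a must be > 0, got {self.a}")
        _require(self.c > 0, f"eilers_peeters: c must be > 0, got {self.c}")
        _require(
            self.b + 2.0 * math.sqrt(self.a * self.c) > 0,
            "eilers_peeters: b + 2*sqrt(a*c) must be > 0 (positive peaked curve), "
            f"got b={self.b}, a={self.a}, c={self.c}",
        )


@dataclass(frozen=True)
class PlattParams:
    """Exponential saturation with exponential photoinhibition (beta >= 0)."""

    ps: float
    alpha: float
    beta: float

    def validate(self) -> None:
        _require(self.ps > 0, f"platt: ps must be > 0, got {self.ps}")
        _require(self.alpha > 0, f"platt: alpha must be > 0, got {self.alpha}")
        _require(self.beta >= 0, f"platt: beta must be >= 0, got {self.beta}")


@dataclass(frozen=True)
class WalsbyParams:
    """Exponential saturation plus a linear term; beta <= 0 models inhibition."""

    etr_max: float
    alpha: float
    beta: float

    def validate(self) -> None:
        _require(self.etr_max > 0, f"walsby: etr_max must be > 0, got {self.etr_max}")
        _require(self.alpha > 0, f"walsby: alpha must be > 0, got {self.alpha}")
        _require(
            self.alpha + self.beta > 0,
            f"walsby: alpha + beta must be > 0 (non-negative initial slope), "
            f"got alpha={self.alpha}, beta={self.beta}",
        )


@dataclass(frozen=True)
class VollenweiderParams:
    """Saturating hyperbola with an algebraic photoinhibition factor of order n."""

    pmax: float
    a: float
    alpha: float
    n: float

    def validate(self) -> None:
        _require(self.pmax > 0, f"vollenweider: pmax must be > 0, got {self.pmax}")
        _require(self.a > 0, f"vollenweider: a must be > 0, got {self.a}")
        _require(self.alpha >= 0, f"vollenweider: alpha must be >= 0, got {self.alpha}")
        _require(self.n >= 0, f"vollenweider: n must be >= 0, got {self.n}")


ModelParams = Union[EilersPeetersParams, PlattParams, WalsbyParams, VollenweiderParams]

_PARAM_TYPES = {
    "eilers_peeters": EilersPeetersParams,
    "platt": PlattParams,
    "walsby": WalsbyParams,
    "vollenweider": VollenweiderParams,
}


@dataclass(frozen=True)
class DerivedParams:
    """Standardized kinetic parameter set; ``None`` marks NA for the model.

    NA pattern by model:

    ====================================  =======  =====  ======  ============
    field                                 eilers   platt  walsby  vollenweider
    ====================================  =======  =====  ======  ============
    alpha                                 x        x      x       x
    beta                                  NA       x      x       NA
    etrmax_with_photoinhibition           x        x      x       x
    etrmax_without_photoinhibition        NA       x      x       x
    ik_with_photoinhibition               x        x      x       x
    ik_without_photoinhibition            NA       x      x       x
    im_with_photoinhibition               x        x      x       x
    w                                     x        NA     NA      NA
    ib                                    NA       x      NA      NA
    etrmax_without_with_ratio             NA       x      x       x
    ====================================  =======  =====  ======  ============
    """

    alpha: Optional[float]
    beta: Optional[float]
    etrmax_with_photoinhibition: Optional[float]
    etrmax_without_photoinhibition: Optional[float]
    ik_with_photoinhibition: Optional[float]
    ik_without_photoinhibition: Optional[float]
    im_with_photoinhibition: Optional[float]
    w: Optional[float]
    ib: Optional[float]
    etrmax_without_with_ratio: Optional[float]

    @classmethod
    def field_names(cls) -> tuple:
        return tuple(f.name for f in fields(cls))

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in self.field_names()}


# ---------------------------------------------------------------------------
# model curves
# ---------------------------------------------------------------------------

def _predict_eilers_peeters(p: EilersPeetersParams, par: ArrayLike) -> ArrayLike:
    I = np.asarray(par, dtype=float)
    out = I / (p.a * I * I + p.b * I + p.c)
    return out if out.ndim else float(out)


def _predict_platt(p: PlattParams, par: ArrayLike) -> ArrayLike:
    I = np.asarray(par, dtype=float)
    out = p.ps * (1.0 - np.exp(-p.alpha * I / p.ps)) * np.exp(-p.beta * I / p.ps)
    return out if out.ndim else float(out)


def _predict_walsby(p: WalsbyParams, par: ArrayLike) -> ArrayLike:
    I = np.asarray(par, dtype=float)
    out = p.etr_max * (1.0 - np.exp(-p.alpha * I / p.etr_max)) + p.beta * I
    return out if out.ndim else float(out)


def _predict_vollenweider(p: VollenweiderParams, par: ArrayLike) -> ArrayLike:
    I = np.asarray(par, dtype=float)
    aI = p.a * I
    sat = aI / np.sqrt(1.0 + aI * aI)
    inhib = (1.0 / np.sqrt(1.0 + (p.alpha * I) ** 2)) ** p.n
    out = p.pmax * sat * inhib
    return out if out.ndim else float(out)


_PREDICT: dict[str, Callable] = {
    "eilers_peeters": _predict_eilers_peeters,
    "platt": _predict_platt,
    "walsby": _predict_walsby,
    "vollenweider": _predict_vollenweider,
}


def predict(model: str, params: ModelParams, par: ArrayLike) -> ArrayLike:
    """Evaluate ``model`` at irradiance(s) ``par``; vectorized over arrays.

    All four curves satisfy ETR(0) = 0.  Parameters are validated against
    the type invariants; ``par`` must be non-negative.
    """
    if model not in _PREDICT:
        raise ValueError(f"unknown model {model!r}; expected one of {MODEL_ORDER}")
    if not isinstance(params, _PARAM_TYPES[model]):
        raise TypeError(
            f"model {model!r} expects {_PARAM_TYPES[model].__name__}, "
            f"got {type(params).__name__}"
        )
    params.validate()
    if np.any(np.asarray(par) < 0):
        raise ValueError("par must be >= 0")
    return _PREDICT[model](params, par)


# ---------------------------------------------------------------------------
# numeric maximum (needed where the peak has no closed form)
# ---------------------------------------------------------------------------

class NoInteriorMaximumError(RuntimeError):
    """The curve did not decrease within the bracketing budget."""


def numeric_curve_max(
    curve_fn: Callable[[ArrayLike], ArrayLike],
    upper_hint: float,
    max_doublings: int = 20,
) -> tuple:
    """Locate ``(im, etrmax)`` of a continuous single-peaked curve on [0, inf).

    The upper bracket starts at ``upper_hint`` and doubles until the curve
    value at the bracket end falls below the running maximum of a coarse
    scan, then a bounded Brent scalar optimization refines the argmax with
    absolute tolerance ``1e-6 * upper_hint``.
    """
    if upper_hint <= 0:
        raise ValueError("upper_hint must be > 0")
    U = float(upper_hint)
    bracketed = False
    for _ in range(max_doublings + 1):
        grid = np.linspace(0.0, U, 512)
        vals = np.asarray(curve_fn(grid), dtype=float)
        k = int(np.argmax(vals))
        if k < len(grid) - 1 and vals[k] > vals[-1]:
            bracketed = True
            break
        U *= 2.0
    if not bracketed:
        raise NoInteriorMaximumError(
            f"curve did not decrease on [0, {U:g}] after {max_doublings} "
            "bracket doublings; no interior maximum found"
        )
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda x: -float(curve_fn(x)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-6 * float(upper_hint)},
    )
    if not res.success:
        raise NoInteriorMaximumError(f"scalar optimization failed: {res.message}")
    return float(res.x), float(-res.fun)


# ---------------------------------------------------------------------------
# derived ("modified") parameter algebra
# ---------------------------------------------------------------------------

def derive_eilers_peeters(p: EilersPeetersParams) -> DerivedParams:
    """Closed-form kinetic parameters of the Eilers-Peeters curve.

    alpha = 1/c, etrmax = 1/(b + 2*sqrt(a*c)), im = sqrt(c/a),
    ik = etrmax/alpha = c/(b + 2*sqrt(a*c)), w = b/sqrt(a*c).
    The model has no separate uninhibited branch, so the without-
    photoinhibition quantities, beta and ib are NA.
    """
    p.validate()
    sac = math.sqrt(p.a * p.c)
    denom = p.b + 2.0 * sac
    etrmax = 1.0 / denom
    return DerivedParams(
        alpha=1.0 / p.c,
        beta=None,
        etrmax_with_photoinhibition=etrmax,
        etrmax_without_photoinhibition=None,
        ik_with_photoinhibition=p.c / denom,
        ik_without_photoinhibition=None,
        im_with_photoinhibition=math.sqrt(p.c / p.a),
        w=p.b / sac,
        ib=None,
        etrmax_without_with_ratio=None,
    )


def derive_platt(p: PlattParams) -> DerivedParams:
    """Kinetic parameters of the Platt curve, all in closed form.

    With beta > 0 the realized maximum is
    ``pm = ps * (alpha/(alpha+beta)) * (beta/(alpha+beta))**(beta/alpha)``
    at ``im = (ps/alpha) * ln((alpha+beta)/beta)``; ``ib = ps/beta`` is the
    irradiance scale of the inhibition term.  For beta below ``BETA_TOL``
    the curve saturates monotonically at ps.
    """
    p.validate()
    if p.beta <= BETA_TOL:
        return DerivedParams(
            alpha=p.alpha,
            beta=p.beta,
            etrmax_with_photoinhibition=p.ps,
            etrmax_without_photoinhibition=p.ps,
            ik_with_photoinhibition=p.ps / p.alpha,
            ik_without_photoinhibition=p.ps / p.alpha,
            im_with_photoinhibition=None,
            w=None,
            ib=None,
            etrmax_without_with_ratio=1.0,
        )
    ab = p.alpha + p.beta
    pm = p.ps * (p.alpha / ab) * (p.beta / ab) ** (p.beta / p.alpha)
    return DerivedParams(
        alpha=p.alpha,
        beta=p.beta,
        etrmax_with_photoinhibition=pm,
        etrmax_without_photoinhibition=p.ps,
        ik_with_photoinhibition=pm / p.alpha,
        ik_without_photoinhibition=p.ps / p.alpha,
        im_with_photoinhibition=(p.ps / p.alpha) * math.log(ab / p.beta),
        w=None,
        ib=p.ps / p.beta,
        etrmax_without_with_ratio=p.ps / pm,
    )


def derive_walsby(p: WalsbyParams) -> DerivedParams:
    """Kinetic parameters of the Walsby curve.

    The derivative at I=0 is ``alpha_fit + beta``, which is reported as the
    derived initial slope.  With beta < 0 (and ``-beta/alpha_fit < 1``) the
    stationary point is ``im = -(etr_max/alpha_fit) * ln(-beta/alpha_fit)``
    and the realized maximum ``etr_max*(1 + beta/alpha_fit) + beta*im``;
    otherwise the curve is non-decreasing and the with/without quantities
    coincide.
    """
    p.validate()
    slope0 = p.alpha + p.beta  # true initial slope
    ik_without = p.etr_max / slope0
    if p.beta < -BETA_TOL and -p.beta / p.alpha < 1.0:
        im = -(p.etr_max / p.alpha) * math.log(-p.beta / p.alpha)
        etrmax_with = p.etr_max * (1.0 + p.beta / p.alpha) + p.beta * im
        return DerivedParams(
            alpha=slope0,
            beta=p.beta,
            etrmax_with_photoinhibition=etrmax_with,
            etrmax_without_photoinhibition=p.etr_max,
            ik_with_photoinhibition=etrmax_with / slope0,
            ik_without_photoinhibition=ik_without,
            im_with_photoinhibition=im,
            w=None,
            ib=None,
            etrmax_without_with_ratio=p.etr_max / etrmax_with,
        )
    return DerivedParams(
        alpha=slope0,
        beta=p.beta,
        etrmax_with_photoinhibition=p.etr_max,
        etrmax_without_photoinhibition=p.etr_max,
        ik_with_photoinhibition=ik_without,
        ik_without_photoinhibition=ik_without,
        im_with_photoinhibition=None,
        w=None,
        ib=None,
        etrmax_without_with_ratio=1.0,
    )


def derive_vollenweider(p: VollenweiderParams) -> DerivedParams:
    """Kinetic parameters of the Vollenweider curve.

    The initial slope is ``pmax * a`` and the uninhibited saturation scale
    ``ik = 1/a``.  The realized maximum has no closed form and is located
    numerically; with no inhibition factor (alpha = 0 or n = 0) the curve
    approaches pmax asymptotically and im is NA.
    """
    p.validate()
    slope0 = p.pmax * p.a
    ik_without = 1.0 / p.a
    if p.alpha == 0.0 or p.n == 0.0:
        return DerivedParams(
            alpha=slope0,
            beta=None,
            etrmax_with_photoinhibition=p.pmax,
            etrmax_without_photoinhibition=p.pmax,
            ik_with_photoinhibition=ik_without,
            ik_without_photoinhibition=ik_without,
            im_with_photoinhibition=None,
            w=None,
            ib=None,
            etrmax_without_with_ratio=1.0,
        )
    upper_hint = max(ik_without, 1.0 / p.alpha)
    im, etrmax_with = numeric_curve_max(
        lambda I: _predict_vollenweider(p, I), upper_hint
    )
    return DerivedParams(
        alpha=slope0,
        beta=None,
        etrmax_with_photoinhibition=etrmax_with,
        etrmax_without_photoinhibition=p.pmax,
        ik_with_photoinhibition=etrmax_with / slope0,
        ik_without_photoinhibition=ik_without,
        im_with_photoinhibition=im,
        w=None,
        ib=None,
        etrmax_without_with_ratio=p.pmax / etrmax_with,
    )


_DERIVE: dict[str, Callable] = {
    "eilers_peeters": derive_eilers_peeters,
    "platt": derive_platt,
    "walsby": derive_walsby,
    "vollenweider": derive_vollenweider,
}


def derive(model: str, params: ModelParams) -> DerivedParams:
    """Map raw regression parameters to the standardized parameter set."""
    if model not in _DERIVE:
        raise ValueError(f"unknown model {model!r}; expected one of {MODEL_ORDER}")
    return _DERIVE[model](params)


# ---------------------------------------------------------------------------
# fitting plumbing: flat-array views and default sign bounds
# ---------------------------------------------------------------------------

_PARAM_FIELDS = {
    "eilers_peeters": ("a", "b", "c"),
    "platt": ("ps", "alpha", "beta"),
    "walsby": ("etr_max", "alpha", "beta"),
    "vollenweider": ("pmax", "a", "alpha", "n"),
}

# strict positivity approximated by a tiny positive lower bound
_EPS = 1e-12

_BOUNDS = {
    "eilers_peeters": ([_EPS, -np.inf, _EPS], [np.inf, np.inf, np.inf]),
    "platt": ([_EPS, _EPS, 0.0], [np.inf, np.inf, np.inf]),
    "walsby": ([_EPS, _EPS, -np.inf], [np.inf, np.inf, 0.0]),
    "vollenweider": ([_EPS, _EPS, 0.0, 0.0], [np.inf, np.inf, np.inf, np.inf]),
}


def n_params(model: str) -> int:
    return len(_PARAM_FIELDS[model])


def params_to_array(model: str, params: ModelParams) -> np.ndarray:
    return np.array([getattr(params, f) for f in _PARAM_FIELDS[model]], dtype=float)


def params_from_array(model: str, theta: np.ndarray) -> ModelParams:
    names = _PARAM_FIELDS[model]
    if len(theta) != len(names):
        raise ValueError(f"model {model!r} takes {len(names)} parameters")
    return _PARAM_TYPES[model](**dict(zip(names, (float(t) for t in theta))))


def default_bounds(model: str) -> tuple:
    """Sign bounds enforcing each model's parameter conventions."""
    lo, hi = _BOUNDS[model]
    return np.array(lo, dtype=float), np.array(hi, dtype=float)
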