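"""Electron transport rate computation and light-curve row selection.

The (relative) electron transport rate follows the standard PAM convention

    ETR = PAR * Y * F * r

with PAR the actinic irradiance, Y the effective quantum yield of the
photosystem measured (Y(II) or Y(I)), F the ETR factor (fraction of incident
light absorbed, conventionally 0.84) and r the photosystem ratio (fraction
of absorbed light allocated to that photosystem, conventionally 0.5).

Steps with Y = 0 — including a terminal zero-yield light step — are valid
observations (ETR = 0) and are kept for fitting; only rows positively
identified as recovery measurements are excluded.
"""

from __future__ import annotations

from typing import Optional, Sequence

__all__ = [
    "DEFAULT_ETR_FACTOR",
    "DEFAULT_P_RATIO",
    "MIN_FIT_STEPS",
    "compute_etr",
    "schedule_break_index",
    "filter_curve_points",
    "TooFewStepsError",
]

DEFAULT_ETR_FACTOR = 0.84
DEFAULT_P_RATIO = 0.5

#: a fit needs at least as many points as the largest model's parameter count
MIN_FIT_STEPS = 4

#: relative PAR drop that marks the start of post-curve recovery rows
SCHEDULE_BREAK_REL_TOL = 0.01


class TooFewStepsError(ValueError):
    """Filtering left fewer steps than the largest model can be fitted to."""


def compute_etr(par: float, yld: float, etr_factor: float, p_ratio: float) -> float:
    """Return ``par * yld * etr_factor * p_ratio`` after domain validation.

    Parameters
    ----------
    par : float
        Actinic irradiance, umol photons m-2 s-1; must be >= 0.
    yld : float
        Effective quantum yield, in [0, 1].
    etr_factor : float
        Absorbed-light fraction, in (0, 1].
    p_ratio : float
        Photosystem allocation fraction, in (0, 1].
    """
    if par < 0:
        raise ValueError(f"par must be >= 0, got {par}")
    if not 0.0 <= yld <= 1.0:
        raise ValueError(f"yld must be in [0, 1], got {yld}")
    if not 0.0 < etr_factor <= 1.0:
        raise ValueError(f"etr_factor must be in (0, 1], got {etr_factor}")
    if not 0.0 < p_ratio <= 1.0:
        raise ValueError(f"p_ratio must be in (0, 1], got {p_ratio}")
    return par * yld * etr_factor * p_ratio


def schedule_break_index(par_values: Sequence[float],
                         rel_tol: float = SCHEDULE_BREAK_REL_TOL) -> Optional[int]:
    """Index of the first step whose PAR drops below the previous step's.

    A rapid light curve uses a non-decreasing PAR schedule; the first step
    whose PAR falls more than ``rel_tol`` (relative) below its predecessor
    marks the start of recovery measurements.  Returns ``None`` when the
    schedule never breaks.
    """
    for i in range(1, len(par_values)):
        prev = par_values[i - 1]
        if par_values[i] < prev - rel_tol * abs(prev):
            return i
    return None


def filter_curve_points(curve, strategy: str = "schedule_break",
                        indices: Optional[Sequence[int]] = None):
    """Select the light-curve subset of a :class:`~rlcfit.instrument_io.LightCurve`.

    Strategies
    ----------
    ``schedule_break``
        Keep the leading run of steps up to (exclusive) the first PAR drop
        of more than 1% relative — later rows are recovery measurements.
    ``explicit_indices``
        Drop the steps listed in ``indices`` (positions in ``curve.steps``).
    ``none``
        Identity.

    Excluded steps are retained flagged ``is_recovery=True`` when the curve
    was read with ``keep_recovery``; otherwise they are dropped.  Raises
    :class:`TooFewStepsError` when fewer than 4 fittable steps remain
    (4 = the Vollenweider parameter count).
    """
    from .instrument_io import LightCurve  # local import to avoid a cycle

    steps = list(curve.steps)
    if strategy == "none":
        excluded = set()
    elif strategy == "schedule_break":
        brk = schedule_break_index([s.par for s in steps])
        excluded = set(range(brk, len(steps))) if brk is not None else set()
    elif strategy == "explicit_indices":
        if indices is None:
            raise ValueError("strategy 'explicit_indices' requires indices")
        excluded = set(int(i) for i in indices)
        out_of_range = [i for i in excluded if not 0 <= i < len(steps)]
        if out_of_range:
            raise IndexError(f"indices out of range: {sorted(out_of_range)}")
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    kept = []
    for pos, step in enumerate(steps):
        if pos in excluded:
            if curve.keep_recovery:
                kept.append(step.replace(is_recovery=True))
        else:
            kept.append(step)

    n_fittable = sum(1 for s in kept if not s.is_recovery)
    if n_fittable < MIN_FIT_STEPS:
        raise TooFewStepsError(
            f"too few points to fit: {n_fittable} light steps remain after "
            f"filtering, need at least {MIN_FIT_STEPS}"
        )
    return LightCurve(
        steps=tuple(kept),
        source_file=curve.source_file,
        etr_type=curve.etr_type,
        etr_factor=curve.etr_factor,
        p_ratio=curve.p_ratio,
        keep_recovery=curve.keep_recovery,
    )
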