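"""Readers for rapid-light-curve CSV exports and the three-file result export.

Three input dialects are supported:

``universal``
    Comma-separated with a header row; required columns ``PAR`` and
    ``Y(II)`` (or ``Y(I)``); optional ``Date``, ``Time``, ``ID``.
``dual_pam``
    Semicolon-separated, '.' decimal; columns
    ``Date;Time;ID;Action;PAR;Y(I);Y(II)``.  Saturating-pulse rows carry an
    Action value from a configurable allow-list (default ``SP``); recovery
    rows a configurable marker (default ``REC``), falling back to
    PAR-schedule-reset detection when no marker column is present.
``junior_pam``
    Semicolon-separated, ',' decimal (German-locale exports); columns
    ``Datum;Uhrzeit;PAR;Y(II)``.  Recovery rows are detected by the
    PAR-schedule reset.

The instrument vendors do not document a canonical layout, so every column
name, separator and decimal mark is overridable through a :class:`Dialect`;
the defaults above are assumptions, kept in one table.  Files are decoded
as UTF-8 with BOM tolerance (Windows instrument software).

No numeric row is dropped silently: excluded rows are logged with reasons.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import etr_core
from .light_models import DerivedParams

__all__ = [
    "Step",
    "LightCurve",
    "Dialect",
    "UNIVERSAL_DIALECT",
    "DUAL_PAM_DIALECT",
    "JUNIOR_PAM_DIALECT",
    "read_universal",
    "read_dual_pam",
    "read_junior_pam",
    "write_model_results",
    "read_parameters_csv",
    "CurveReadError",
]

logger = logging.getLogger(__name__)

#: numeric formatting for result CSVs: 17 significant digits round-trips
#: an IEEE double exactly
_FLOAT_FMT = "%.17g"


class CurveReadError(ValueError):
    """A CSV export could not be interpreted as a light curve."""


@dataclass(frozen=True)
class Step:
    """One saturating-pulse measurement.

    ``etr`` is always recomputable as
    ``par * quantum_yield * etr_factor * p_ratio`` from the owning curve,
    so it is 0 whenever PAR or the yield is 0.
    """

    index: int
    par: float
    quantum_yield: float
    etr: float
    is_recovery: bool = False

    def replace(self, **changes) -> "Step":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class LightCurve:
    """An ordered rapid light curve plus the provenance of its ETR values."""

    steps: tuple
    source_file: str
    etr_type: str  # "I" or "II"
    etr_factor: float
    p_ratio: float
    keep_recovery: bool = False

    def __post_init__(self):
        if self.etr_type not in ("I", "II"):
            raise ValueError(f"etr_type must be 'I' or 'II', got {self.etr_type!r}")
        if not self.steps:
            raise CurveReadError(f"empty curve: {self.source_file}")

    @property
    def light_steps(self) -> tuple:
        """Steps belonging to the light curve (recovery rows excluded)."""
        return tuple(s for s in self.steps if not s.is_recovery)

    @property
    def par(self) -> np.ndarray:
        return np.array([s.par for s in self.light_steps], dtype=float)

    @property
    def quantum_yield(self) -> np.ndarray:
        return np.array([s.quantum_yield for s in self.light_steps], dtype=float)

    @property
    def etr(self) -> np.ndarray:
        return np.array([s.etr for s in self.light_steps], dtype=float)

    def __len__(self) -> int:
        return len(self.steps)


@dataclass(frozen=True)
class Dialect:
    """Column names, separator and decimal mark of one instrument export."""

    sep: str
    decimal: str
    par_col: str
    yield_cols: dict = field(default_factory=dict)  # etr_type -> column name
    required_cols: tuple = ()
    action_col: Optional[str] = None
    light_actions: tuple = ("SP",)
    recovery_actions: tuple = ("REC",)


UNIVERSAL_DIALECT = Dialect(
    sep=",",
    decimal=".",
    par_col="PAR",
    yield_cols={"II": "Y(II)", "I": "Y(I)"},
)

DUAL_PAM_DIALECT = Dialect(
    sep=";",
    decimal=".",
    par_col="PAR",
    yield_cols={"II": "Y(II)", "I": "Y(I)"},
    required_cols=("Date", "Time", "ID", "Action", "PAR"),
    action_col="Action",
    light_actions=("SP",),
    recovery_actions=("REC",),
)

JUNIOR_PAM_DIALECT = Dialect(
    sep=";",
    decimal=",",
    par_col="PAR",
    yield_cols={"II": "Y(II)"},
    required_cols=("Datum", "Uhrzeit", "PAR"),
)


def _read_raw(path, dialect: Dialect) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")
    try:
        df = pd.read_csv(
            path,
            sep=dialect.sep,
            decimal=dialect.decimal,
            encoding="utf-8-sig",
            dtype=str,
            skipinitialspace=True,
        )
    except pd.errors.EmptyDataError:
        raise CurveReadError(f"empty curve: {path} contains no data") from None
    df.columns = [str(c).strip() for c in df.columns]
    return df


def _require_columns(df: pd.DataFrame, needed: Sequence[str], path, dialect_name: str):
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise CurveReadError(
            f"{path}: not a {dialect_name} export — missing column(s) "
            f"{missing}; found {list(df.columns)}"
        )


def _parse_number(raw, decimal: str, col: str, row: int, path) -> float:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        raise CurveReadError(f"{path}, data row {row}: missing {col} value")
    text = str(raw).strip()
    if not text or text.upper() in ("NA", "NAN"):
        raise CurveReadError(f"{path}, data row {row}: missing {col} value")
    if decimal != ".":
        text = text.replace(decimal, ".")
    try:
        return float(text)
    except ValueError:
        raise CurveReadError(
            f"{path}, data row {row}: non-numeric {col} value {raw!r}"
        ) from None


def _build_steps(rows, etr_factor: float, p_ratio: float, path):
    """rows: iterable of (row_number, par, yld, is_recovery)."""
    steps = []
    for idx, (row_no, par, yld, is_rec) in enumerate(rows):
        if par < 0:
            raise CurveReadError(f"{path}, data row {row_no}: PAR must be >= 0, got {par}")
        if not 0.0 <= yld <= 1.0:
            raise CurveReadError(
                f"{path}, data row {row_no}: yield {yld} outside [0, 1] — "
                "check the decimal mark / column mapping of the dialect"
            )
        etr = etr_core.compute_etr(par, yld, etr_factor, p_ratio)
        steps.append(Step(index=idx, par=par, quantum_yield=yld, etr=etr,
                          is_recovery=is_rec))
    return tuple(steps)


def _yield_column(dialect: Dialect, etr_type: str, path) -> str:
    if etr_type not in dialect.yield_cols:
        raise CurveReadError(
            f"{path}: dialect provides no yield column for ETR {etr_type} "
            f"(available: {sorted(dialect.yield_cols)})"
        )
    return dialect.yield_cols[etr_type]


def read_universal(
    path,
    column_map: Optional[dict] = None,
    etr_type: str = "II",
    etr_factor: float = etr_core.DEFAULT_ETR_FACTOR,
    p_ratio: float = etr_core.DEFAULT_P_RATIO,
    dialect: Dialect = UNIVERSAL_DIALECT,
) -> LightCurve:
    """Read a standardized comma-separated light-curve CSV.

    ``column_map`` renames file columns to the expected names, e.g.
    ``{"irradiance": "PAR", "yield": "Y(II)"}``.  Every row must carry a
    numeric PAR and yield; offending rows raise a row-numbered error.
    """
    df = _read_raw(path, dialect)
    if column_map:
        df = df.rename(columns=column_map)
    ycol = _yield_column(dialect, etr_type, path)
    _require_columns(df, [dialect.par_col, ycol], path, "universal")
    if df.empty:
        raise CurveReadError(f"empty curve: {path} has a header but no data rows")
    rows = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        par = _parse_number(row[dialect.par_col], dialect.decimal, dialect.par_col, i, path)
        yld = _parse_number(row[ycol], dialect.decimal, ycol, i, path)
        rows.append((i, par, yld, False))
    return LightCurve(
        steps=_build_steps(rows, etr_factor, p_ratio, path),
        source_file=str(path),
        etr_type=etr_type,
        etr_factor=etr_factor,
        p_ratio=p_ratio,
    )


def _read_instrument(
    path,
    dialect: Dialect,
    dialect_name: str,
    etr_type: str,
    etr_factor: float,
    p_ratio: float,
    keep_recovery: bool,
) -> LightCurve:
    df = _read_raw(path, dialect)
    ycol = _yield_column(dialect, etr_type, path)
    _require_columns(df, list(dialect.required_cols) + [ycol], path, dialect_name)
    if df.empty:
        raise CurveReadError(f"empty curve: {path} has a header but no data rows")

    n_in = len(df)
    parsed = []  # (row_no, par, yld, is_recovery)
    n_excluded = 0
    for i, row in enumerate(df.to_dict("records"), start=1):
        if dialect.action_col is not None:
            action = str(row.get(dialect.action_col, "")).strip()
            if action in dialect.recovery_actions:
                is_rec = True
            elif action in dialect.light_actions:
                is_rec = False
            else:
                logger.info("%s row %d: Action %r not in allow-list, excluded",
                            path, i, action)
                n_excluded += 1
                continue
        else:
            is_rec = False  # resolved below via the PAR schedule
        par = _parse_number(row[dialect.par_col], dialect.decimal,
                            dialect.par_col, i, path)
        yld = _parse_number(row[ycol], dialect.decimal, ycol, i, path)
        parsed.append((i, par, yld, is_rec))

    if dialect.action_col is None:
        # no marker column: rows after the first PAR drop are recovery
        brk = etr_core.schedule_break_index([p[1] for p in parsed])
        if brk is not None:
            parsed = [(r, p, y, rec or pos >= brk)
                      for pos, (r, p, y, rec) in enumerate(parsed)]

    if not keep_recovery:
        dropped = [p for p in parsed if p[3]]
        for row_no, par, _, _ in dropped:
            logger.info("%s row %d: recovery row (PAR=%g) excluded", path, row_no, par)
        n_excluded += len(dropped)
        parsed = [p for p in parsed if not p[3]]

    logger.debug("%s: %d rows in = %d kept + %d excluded",
                 path, n_in, len(parsed), n_excluded)
    if not parsed:
        raise CurveReadError(f"empty curve: no light-curve rows found in {path}")
    return LightCurve(
        steps=_build_steps(parsed, etr_factor, p_ratio, path),
        source_file=str(path),
        etr_type=etr_type,
        etr_factor=etr_factor,
        p_ratio=p_ratio,
        keep_recovery=keep_recovery,
    )


def read_dual_pam(
    path,
    etr_type: str = "II",
    etr_factor: float = etr_core.DEFAULT_ETR_FACTOR,
    p_ratio: float = etr_core.DEFAULT_P_RATIO,
    keep_recovery: bool = False,
    dialect: Dialect = DUAL_PAM_DIALECT,
) -> LightCurve:
    """Read a Dual-PAM-style semicolon-separated export.

    Only rows whose Action value is in the dialect's allow-list become
    steps; recovery rows are excluded unless ``keep_recovery`` (then kept
    flagged).  A terminal Y(II)=0 light step is a valid observation and is
    retained with ETR = 0.
    """
    return _read_instrument(path, dialect, "dual_pam", etr_type,
                            etr_factor, p_ratio, keep_recovery)


def read_junior_pam(
    path,
    etr_type: str = "II",
    etr_factor: float = etr_core.DEFAULT_ETR_FACTOR,
    p_ratio: float = etr_core.DEFAULT_P_RATIO,
    keep_recovery: bool = False,
    dialect: Dialect = JUNIOR_PAM_DIALECT,
) -> LightCurve:
    """Read a Junior-PAM-style export (semicolon separator, decimal comma)."""
    return _read_instrument(path, dialect, "junior_pam", etr_type,
                            etr_factor, p_ratio, keep_recovery)


# ---------------------------------------------------------------------------
# three-file result export
# ---------------------------------------------------------------------------

def _fmt(value: Optional[float]) -> str:
    return "NA" if value is None else _FLOAT_FMT % value


def write_model_results(fit, curve: LightCurve, out_dir, base_name: str) -> tuple:
    """Write ``<base>_table.csv``, ``<base>_regression.csv`` and
    ``<base>_parameters.csv`` for a converged fit; returns the three paths.

    The table file holds the observed steps, the regression file the model
    curve on a dense PAR grid, and the parameters file one row per
    standardized parameter (plus the raw parameters and goodness metrics)
    with an explicit NA flag.  Values are printed with 17 significant
    digits so that re-reading reproduces them exactly.
    """
    if not fit.converged:
        raise ValueError("refusing to export a non-converged fit")
    os.makedirs(out_dir, exist_ok=True)
    p_table = os.path.join(out_dir, f"{base_name}_table.csv")
    p_reg = os.path.join(out_dir, f"{base_name}_regression.csv")
    p_par = os.path.join(out_dir, f"{base_name}_parameters.csv")

    steps = curve.light_steps
    pd.DataFrame({
        "index": [s.index for s in steps],
        "par": [s.par for s in steps],
        "yield": [s.quantum_yield for s in steps],
        "etr": [s.etr for s in steps],
    }).to_csv(p_table, index=False, float_format=_FLOAT_FMT)

    from .light_models import predict  # deferred: avoids import at module load
    grid = np.linspace(0.0, float(curve.par.max()), 500)
    pd.DataFrame({
        "par": grid,
        "etr_predicted": np.asarray(predict(fit.model, fit.raw_params, grid)),
    }).to_csv(p_reg, index=False, float_format=_FLOAT_FMT)

    from .light_models import params_to_array, _PARAM_FIELDS  # noqa: import-cycle-free
    raw_names = _PARAM_FIELDS[fit.model]
    raw_vals = params_to_array(fit.model, fit.raw_params)
    rows = [("model", fit.model, ""), ("etr_type", curve.etr_type, "")]
    rows += [
        ("etr_factor", _fmt(curve.etr_factor), ""),
        ("p_ratio", _fmt(curve.p_ratio), ""),
        ("residual_sum_of_squares", _fmt(fit.metrics.rss), "false"),
        ("root_mean_squared_error", _fmt(fit.metrics.rmse), "false"),
        ("relative_root_mean_squared_error", _fmt(fit.metrics.rrmse),
         "false" if fit.metrics.rrmse is not None else "true"),
    ]
    for letter, name, val in zip("abcd", raw_names, raw_vals):
        rows.append((letter, _fmt(float(val)), "false"))
    if len(raw_names) < 4:
        rows.append(("d", "NA", "true"))
    for name, val in fit.derived.as_dict().items():
        rows.append((name, _fmt(val), "true" if val is None else "false"))
    pd.DataFrame(rows, columns=["parameter", "value", "na"]).to_csv(
        p_par, index=False)
    return p_table, p_reg, p_par


def read_parameters_csv(path) -> tuple:
    """Read back a ``*_parameters.csv``; returns ``(DerivedParams, full dict)``.

    The dict maps every parameter row to its value (``None`` where NA);
    the DerivedParams is reconstructed exactly as written.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    values: dict = {}
    for rec in df.to_dict("records"):
        name, raw, na = rec["parameter"], rec["value"], rec.get("na", "")
        if name in ("model", "etr_type"):
            values[name] = raw
        elif str(raw).strip() == "NA":
            values[name] = None
        else:
            values[name] = float(raw)
    derived = DerivedParams(**{k: values[k] for k in DerivedParams.field_names()})
    return derived, values
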