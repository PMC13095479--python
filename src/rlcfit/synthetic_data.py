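"""Synthetic rapid light curves and instrument-dialect CSV fixtures.

The generator emulates the shape of a fluorometer rapid-light-curve export:
a 12-step increasing PAR schedule with a saturating-pulse yield at each
step, optional trailing recovery rows at low light, and optionally a
terminal light step whose yield collapsed to 0 (as real exports sometimes
contain).  Observational noise is Gaussian on the ETR scale — the quantity
that is fitted — truncated at 0, with a standard deviation expressed as a
fraction of the curve's realized maximum; yields are back-computed from the
noisy ETR so that they stay in [0, 1].

It does not emulate instrument noise physics (flash artifacts, drift,
autocorrelation between steps).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import light_models as lm
from .etr_core import DEFAULT_ETR_FACTOR, DEFAULT_P_RATIO
from .instrument_io import LightCurve, Step

__all__ = ["SimulationSpec", "generate_curve", "emit_instrument_csv",
           "DEFAULT_PAR_STEPS", "REFERENCE_PARAMS"]

#: 12-step rapid-light-curve PAR schedule, umol photons m-2 s-1
DEFAULT_PAR_STEPS = (0, 25, 50, 100, 150, 200, 300, 400, 600, 800, 1200, 2000)

#: default generating parameters per model: a shade-acclimated organism with
#: clearly expressed photoinhibition, whose low-light quantum yields stay
#: within the physical range (Y <= ~0.75 at the lowest PAR steps) and whose
#: parameters are statistically identifiable on the default schedule
REFERENCE_PARAMS = {
    "platt": lm.PlattParams(ps=15.0, alpha=0.33, beta=0.012),
    "eilers_peeters": lm.EilersPeetersParams(a=3.9e-5, b=0.0234, c=3.5),
    "walsby": lm.WalsbyParams(etr_max=70.0, alpha=0.3, beta=-0.03),
    "vollenweider": lm.VollenweiderParams(pmax=60.0, a=0.005, alpha=0.005,
                                          n=1.0),
}


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions for one simulated rapid light curve."""

    model: str
    params: lm.ModelParams
    par_steps: tuple = DEFAULT_PAR_STEPS
    noise_sd_rel: float = 0.02  # fraction of etrmax_with_photoinhibition
    seed: int = 0
    n_recovery: int = 0
    terminal_zero_yield: bool = False
    etr_factor: float = DEFAULT_ETR_FACTOR
    p_ratio: float = DEFAULT_P_RATIO

    def validate(self) -> None:
        if self.model not in lm.MODEL_ORDER:
            raise ValueError(f"unknown model {self.model!r}")
        self.params.validate()
        steps = np.asarray(self.par_steps, dtype=float)
        if len(steps) < 2 or np.any(np.diff(steps) <= 0):
            raise ValueError("par_steps must be strictly increasing")
        if self.noise_sd_rel < 0:
            raise ValueError("noise_sd_rel must be >= 0")
        if self.n_recovery < 0:
            raise ValueError("n_recovery must be >= 0")


def generate_curve(spec: SimulationSpec) -> tuple:
    """Simulate one curve; returns ``(LightCurve, truth)``.

    ``truth`` records the generating model, its raw parameters, the derived
    parameter set and the noise level.  Reproducible: the same spec (same
    seed) yields an identical curve.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    derived = lm.derive(spec.model, spec.params)
    etrmax = derived.etrmax_with_photoinhibition

    par = np.asarray(spec.par_steps, dtype=float)
    etr_true = np.asarray(lm.predict(spec.model, spec.params, par), dtype=float)
    sd = spec.noise_sd_rel * etrmax
    etr_obs = etr_true + rng.normal(0.0, sd, size=par.shape) if sd > 0 else etr_true.copy()
    etr_obs = np.maximum(etr_obs, 0.0)

    scale = spec.etr_factor * spec.p_ratio
    ylds = np.divide(etr_obs, par * scale,
                     out=np.zeros_like(etr_obs), where=par > 0)
    if np.any(ylds > 1.0):
        warnings.warn(
            "back-computed yields exceeded 1 and were clipped — the "
            "simulation spec is unrealistically bright at low PAR",
            stacklevel=2,
        )
        ylds = np.minimum(ylds, 1.0)
    if spec.terminal_zero_yield:
        ylds[-1] = 0.0
    etr_obs = par * ylds * scale  # keep Step.etr exactly recomputable

    steps = [
        Step(index=i, par=float(p), quantum_yield=float(y), etr=float(e),
             is_recovery=False)
        for i, (p, y, e) in enumerate(zip(par, ylds, etr_obs))
    ]

    # trailing recovery rows: dim light after the schedule, as instruments
    # log post-curve relaxation pulses
    rec_par = float(par[par > 0].min()) if np.any(par > 0) else 10.0
    for j in range(spec.n_recovery):
        e_true = float(lm.predict(spec.model, spec.params, rec_par))
        e = max(e_true + (rng.normal(0.0, sd) if sd > 0 else 0.0), 0.0)
        y = min(e / (rec_par * scale), 1.0)
        steps.append(Step(index=len(steps), par=rec_par, quantum_yield=y,
                          etr=rec_par * y * scale, is_recovery=True))

    curve = LightCurve(
        steps=tuple(steps),
        source_file=f"<simulated:{spec.model}:seed={spec.seed}>",
        etr_type="II",
        etr_factor=spec.etr_factor,
        p_ratio=spec.p_ratio,
        keep_recovery=True,
    )
    truth = {
        "model": spec.model,
        "params": spec.params,
        "derived": derived,
        "noise_sd": sd,
        "seed": spec.seed,
    }
    return curve, truth


# ---------------------------------------------------------------------------
# instrument-dialect emission
# ---------------------------------------------------------------------------

_NUM_FMT = "%.10g"


def _num(value: float, decimal: str = ".") -> str:
    text = _NUM_FMT % value
    return text.replace(".", decimal) if decimal != "." else text


def emit_instrument_csv(curve: LightCurve, dialect: str, path,
                        sample_id: str = "sim") -> str:
    """Write ``curve`` as a CSV in one of the three supported dialects.

    The emitted file parses back to identical steps under the matching
    reader (with ``keep_recovery=True``); recovery steps become marked
    rows (dual_pam) or low-PAR trailing rows (universal/junior_pam).
    """
    lines = []
    if dialect == "universal":
        ycol = "Y(II)" if curve.etr_type == "II" else "Y(I)"
        lines.append(f"ID,PAR,{ycol}")
        for s in curve.steps:
            lines.append(f"{sample_id},{_num(s.par)},{_num(s.quantum_yield)}")
    elif dialect == "dual_pam":
        lines.append("Date;Time;ID;Action;PAR;Y(I);Y(II)")
        for s in curve.steps:
            action = "REC" if s.is_recovery else "SP"
            y1 = _num(s.quantum_yield) if curve.etr_type == "I" else "0"
            y2 = _num(s.quantum_yield) if curve.etr_type == "II" else "0"
            lines.append(
                f"2024-01-01;12:{s.index:02d}:00;{sample_id};{action};"
                f"{_num(s.par)};{y1};{y2}"
            )
    elif dialect == "junior_pam":
        lines.append("Datum;Uhrzeit;PAR;Y(II)")
        for s in curve.steps:
            lines.append(
                f"2024-01-01;12:{s.index:02d}:00;"
                f"{_num(s.par, ',')};{_num(s.quantum_yield, ',')}"
            )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
    return str(path)
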