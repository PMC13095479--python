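# Methods

## Electron transport rates

All fitting operates on the (relative) electron transport rate
`ETR = PAR · Y · F · r`, computed per saturating pulse from the measured
quantum yield Y. The ETR factor `F` (fraction of incident light absorbed)
defaults to 0.84 and the photosystem ratio `r` (fraction of absorbed
light routed to the photosystem measured) to 0.5 — the community
conventions for ETR(II); both are user-settable and are recorded in every
output for auditability. Steps with Y = 0 (including a terminal zero-yield
light step, which some instrument front-ends hide while still writing it
to the CSV export) are valid observations with ETR = 0 and are kept for
fitting. Only rows positively identified as post-curve recovery
measurements are excluded: by an Action marker where the dialect has one,
otherwise by the first relative PAR drop of more than 1% in the schedule
(`etr_core.schedule_break_index`). ETR(I) and ETR(II) use the same
formula; users measuring photosystem I supply their own `F` and `r`.

## Models and derived parameters

Four light-response models are implemented (see README for the closed
forms). Raw regression parameters keep each publication's naming
(`a,b,c`, `ps,alpha,beta`, `etr_max,alpha,beta`, `pmax,a,alpha,n`); the
standardized ("modified") set is derived algebraically:

* **Eilers–Peeters** — all quantities closed-form: α = 1/c,
  ETRmax = 1/(b+2√(ac)) at I_m = √(c/a), I_k = c/(b+2√(ac)),
  w = b/√(ac). The model has no uninhibited branch, so the
  without-photoinhibition quantities, β and I_b are NA.
* **Platt** — ETRmax_with = ps·(α/(α+β))·(β/(α+β))^(β/α) at
  I_m = (ps/α)·ln((α+β)/β); I_b = ps/β; I_k(without) = ps/α.
* **Walsby** — the fitted `alpha` is the slope of the exponential term
  only, so the derived initial slope is defined as the true curve
  derivative at I = 0, `alpha_fit + beta`. With β < 0 the stationary
  point is I_m = −(etr_max/α_fit)·ln(−β/α_fit).
* **Vollenweider** — initial slope pmax·a, I_k(without) = 1/a; the curve
  maximum has no closed form and is located numerically
  (`numeric_curve_max`: bracket doubling + bounded Brent, absolute
  tolerance 1e-6 of the bracket hint, validated against a 10⁶-point grid
  search to 0.1%).

Conventions adopted where the originals are silent: I_k with
photoinhibition is ETRmax_with/α for every model (by analogy with the
Platt convention), which makes the ETRmax ratio and the I_k ratio
identical by construction. A photoinhibition slope below
`beta_tol = 1e-12` is treated as exactly zero to avoid catastrophic
cancellation in the Platt maximum; the curve is then monotone,
ETRmax_with = ETRmax_without, and I_m is NA.

## Fitting

Unweighted least squares via a Levenberg–Marquardt-contract optimizer
(scipy's trust-region-reflective, which is required once the sign bounds
are active), ftol = xtol = 1e-10, at most 1000 function evaluations.
Default bounds encode each model's sign conventions: ETR-scale parameters
> 0, Platt β ≥ 0, Walsby β ≤ 0. Default start parameters are data-driven:
the initial slope estimate is a least-squares line through the origin
over the three lowest nonzero-PAR steps, the ETR ceiling is the maximum
observed ETR and its PAR the I_m guess; each model's start inverts its
derived-parameter algebra at those anchors. A fit fails (with a message
recommending different start values) when the optimizer reports failure,
parameters are non-finite, the result is strictly worse than the start
values, or the optimum violates a model invariant. At least 4 steps
(the Vollenweider parameter count) are required. Model comparison fits
all four models with default starts and ranks converged fits by RSS;
ties break by fewest parameters, then fixed model order.

Goodness metrics: RSS, RMSE = √(RSS/n), rRMSE = RMSE/mean(observed ETR)
(NA when the mean is zero).

## Synthetic data

The generator emulates a fluorometer RLC export: a strictly increasing
12-step PAR schedule (0…2000 µmol photons m⁻² s⁻¹ by default), Gaussian
noise applied on the ETR scale — the quantity that is fitted — with SD
expressed as a fraction of the curve's realized maximum (default 2%),
truncated at 0; yields are back-computed from the noisy ETR so they stay
in [0, 1] (clipping triggers a warning, signalling an unrealistic
specification). Optional features: trailing low-PAR recovery rows and a
terminal zero-yield light step. Not emulated: flash artifacts, drift,
step-to-step autocorrelation — so passing tests demonstrate correctness
of the estimation machinery, not robustness to every instrument
pathology.

The reference parameter sets (`synthetic_data.REFERENCE_PARAMS`)
represent a shade-acclimated organism with clearly expressed
photoinhibition. They were chosen under two constraints: quantum yields
at the lowest PAR steps must stay in the physical range (Y ≲ 0.8, hence
initial slope ≲ 0.33 at F·r = 0.42), and the model parameters should be
statistically identifiable on the 12-step schedule — early saturation
leaves many post-peak points, which is what pins down the
photoinhibition slope. A Fisher-information analysis at this design
shows the 4-parameter Vollenweider model is the exception: its
(pmax, a, α) directions trade along a ridge (at moderate light the
inhibition factor depends essentially on n·α²), so individual raw
parameters carry large uncertainty at 2% noise even though curve
functionals such as ETRmax_with remain precise (< 1% median error). This
is a property of the model, not of the optimizer; noisy-recovery checks
on individual Vollenweider raw parameters reflect it.

## Instrument dialects

The vendors do not document a canonical CSV layout, so the three dialects
are explicit, documented assumptions collected in one table
(`instrument_io.Dialect`) and fully overridable: universal
(comma-separated `PAR`, `Y(II)`/`Y(I)`), Dual-PAM-style
(semicolon-separated `Date;Time;ID;Action;PAR;Y(I);Y(II)`, saturating
pulses marked `SP`, recovery `REC`), Junior-PAM-style
(semicolon-separated `Datum;Uhrzeit;PAR;Y(II)`, decimal comma). Files
are decoded as UTF-8 with BOM tolerance. Yields outside [0, 1] are
rejected (a parse or locale problem), never clamped; no numeric row is
dropped silently — exclusions are logged with reasons. Result CSVs print
17 significant digits so a write/read cycle reproduces every derived
parameter bit-for-bit.

## Problem sizes

The test-suite and acceptance-script simulations use 100 replicates per
model for noisy recovery and model selection, 200 (tests) or 50 (script)
random parameter sets per model against the 10⁶-point grid oracle, and a
20-file batch; these sizes give stable medians and rates while keeping a
full run in the tens of seconds on one CPU.

## Known limitations

* Vollenweider raw-parameter uncertainty (see above).
* No confidence intervals or bootstrap on fitted parameters.
* No NPQ kinetics, dark-adaptation metrics (Fv/Fm) or PSII/PSI yield
  ratios.
* No binary instrument formats and no dialect auto-detection.
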