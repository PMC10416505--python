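# Methods

## The monitoring model

`ulcerguard` tracks a dimensionless running *damaging effect* `I(n)` for one
monitored tissue site with fixed characteristics, fed by a regularly sampled
interface-pressure (or internal stress) signal `P(n)` in kPa. Each sample is
first converted to an incremental damaging effect by the affine
pressure–time estimator

    q(t, P) = c0 + c1 t + c2 P        (t in minutes, P in kPa)

evaluated at `t = dt/60`, the sampling interval expressed in minutes. The
default coefficients (`c0 = 0.55323`, `c1 = 0.14938`/min,
`c2 = 0.0014787`/kPa) were fitted by a Gaussian identity-link GLM (ordinary
least squares) to a small porcine pressure/tissue-damage grading dataset;
they demonstrate the method and carry no claim of clinical validity. The
intercept is statistically weak in that fit; it is kept because it is part
of the published model, and `include_intercept=False` drops it.

The increment is then folded into the accumulator with graded relief:

    linear mode:       I(n) = max( q + I(n-1) - beta (1 - U), 0 )
    exponential mode:  I(n) = q + [1 - beta (1 - U)] I(n-1)

`U` is the relief grade, `U = min(mean(recent q), q_m) / q_m`, where `q_m`
is the estimator output for the lowest damaging pressure (the lower
endurance limit `C`) held for one sample period. Under a sustained damaging
load `mean(q) >= q_m`, so `U = 1` and both modes reduce exactly to a pure
integrator — accumulation and decay never both act at full strength in one
step. Under complete relief `q = 0`, `U = 0`, and the configured decay runs
at full rate. The averaging horizon for `mean(q)` defaults to one sample
(`u_window = 1`): a full-history mean would never return to zero after any
loading, so the instantaneous default is the only horizon that makes `U`
return to 0 during relief; it is configurable for consumers who want a
smoother grade.

## Relief-time calibration

Both proposed decay modes are calibrated by a *relief time* `t_r`, the time
for an accumulated effect to fall to a harmless value under complete
relief:

* **linear**: `beta = dt / t_r`, so a unit effect reaches exactly zero after
  `t_r` seconds (the recursion is clamped at zero — a negative damaging
  effect is meaningless);
* **exponential**: `beta = 1 - exp(-5 dt / t_r)`, constructed so that
  `(1 - beta)^(t_r/dt) = exp(-5)`: after one relief time the effect is
  ~0.67 % of its initial value, treated as "significantly similar to zero".
  No additional truncation to exact zero is applied.

At the standard sampling interval of 0.1 s these give `beta = 0.00033…`
(t_r = 300 s, linear), `0.0016653` (t_r = 300 s, exponential) and
`0.0041580` (t_r = 120 s, exponential).

## Injury-threshold gating and the two alarms

Pressure magnitudes are gated against a sigmoid pressure–time injury
threshold `P(t) = K / (1 + exp(alpha (t - t0))) + C` (an albino-rat
skeletal-muscle parameterisation; defaults `C = 9` kPa, `K + C = 32` kPa).
Only the asymptotes are needed for magnitude gating, and no published values
exist for `t0` and `alpha`, so those ship without defaults — supplying them
enables the full curve via `injury_threshold_pressure`. Ties are
conservative: `P = C` is non-damaging, `P = K + C` is instantaneously
damaging. Samples at or below `C` contribute `q = 0` (sub-threshold load
never accumulates; disable with `gate_below_lower_limit=False`); samples at
or above `K + C` raise the per-sample *redistribution* alarm but still
accumulate their estimated impact. The *relief* alarm fires on every sample
where `I` is at or above `damaging_effect_limit`. Neither alarm latches:
debouncing is a consumer concern, keeping the state machine pure.

No published value exists for a clinically meaningful damaging-effect
limit. The default — 15 minutes of accumulation at the midpoint pressure
`C + K/2` — is an arbitrary, reproducible placeholder; real deployments must
set it per individual and tissue. `cscm_config()` instead translates the
Consortium for Spinal Cord Medicine guidance (relief every 15–30 min for
~2 min) into a limit equal to 15 minutes of accumulation at a stated
pressure plus a 120 s relief time.

## Baseline methods

Three behaviours from the tissue-load-monitoring literature are implemented
for comparison, all driven by the same estimator front-end so the five
methods share one damaging-effect axis (the literature is ambiguous about
whether the moving average runs over raw pressure or damage increments;
averaging the increments is what makes the comparison commensurable):

* **averaging** — arithmetic mean of the last `window_len` increments
  (default 3000 samples), zero-padded before start. Plateaus under constant
  load and totally forgets an impulse one window after it occurred.
* **fixed** — integrator held constant during relief and reset to zero
  (instantaneous total recovery) once continuous relief has lasted `t_r`.
  The value is deliberately *held*, not decayed, before the reset: the rule
  specifies only the endpoint.
* **inverse** — integrator whose displayed value during relief is the held
  accumulation divided by `max(elapsed_relief_seconds, 1)`; the 1 s floor
  avoids the undefined division at relief onset. The decay is hyperbolic
  and never exactly reaches zero (after a 15-min relief phase the value is
  ~0.11 % of the held accumulation). When loading resumes, accumulation
  continues from the decayed displayed value, which is what makes the
  method show an (approximately) zero overall damaging effect after
  prolonged repetitive loading.

A sample counts as "relieving" for this bookkeeping when its increment is
zero, i.e. when the pressure is at or below `C` under the default gate.
Continuous relief is counted in whole samples (`count * dt`) so a relief
time that is an exact multiple of `dt` resets on the expected sample.

## Synthetic signals

The generator emulates the simulated loading regimes used to exercise the
method: constant 10/20 kPa loads, a 20 kPa-amplitude sinusoid at 0.00333 Hz,
per-sample uniform random pressure on 20–120 kPa (mean 70 kPa), a sustained
uniform 20–25 kPa "prolonged sitting" load, a 0–20 kPa repetitive load with
a 30-min period, and a single-sample impulse. Where the regime descriptions
leave the waveform open, the package chooses the simplest consistent form
and documents it in the preset docstrings: the random regimes are i.i.d.
uniform draws per sample (the uniform[20, 120] mean is the stated 70 kPa);
the repetitive load is a 50 %-duty square wave spanning the stated range;
the sinusoid rides on a 20 kPa offset and is clipped at 0 kPa (range
0–40 kPa). Preset durations are the package's own choices: 1 h for the four
short regimes, 2 h for the sustained load, 8 h for the repetitive load.
All signals are clipped at 0 kPa and deterministic given (spec, seed).

These signals are idealised: real pressure-mat recordings carry sensor
noise, drift, spatial structure across channels, and shear/friction,
temperature and moisture effects that the model deliberately ignores
(tissue characteristics are treated as fixed). Passing tests on these
regimes therefore validate the accumulator/relief arithmetic and the alarm
logic, not clinical performance.

## Numerical and design choices

* Units: seconds everywhere at module boundaries and file formats; minutes
  only inside the estimator (the coefficient units), converted internally.
* The linear recursion is clamped at zero; the exponential one is
  non-negative by construction (`beta <= 1`).
* Equality-grade invariants (integrator reduction, method agreement under
  sustained load) hold *exactly*, not approximately, because all integrator
  paths perform the identical sequence of float operations.
* The relief alarm is specified to within one sample: a limit defined as
  `n` steps of accumulation may be crossed at step `n` or `n + 1` depending
  on the rounding of the sequential sum against the product `n * q_step`.
* `run()` is the exact sequential fold of `step()`; a property test pins
  this so no batch fast-path can diverge from the streaming semantics.
* Monitoring multiple sensor sites means one independent `MonitorState` per
  channel; no cross-channel coupling is modelled.
* Refitting: `fit_estimator` requires >= 4 observations and a full-rank
  design, names the degenerate column otherwise, and warns (rather than
  errors) when a fitted slope is negative so the user can inspect the fit.
* The estimator interface accepts alternative coefficient sets but
  implements only the affine form; whether a nonlinear (e.g. hyperbolic)
  estimator would be preferable is an open question that more data would
  have to settle.

## Known limitations

The default coefficients come from a small-sample animal dataset; the
original observation table is not redistributed here, so the package cannot
reproduce that specific fit — `fit_estimator` exists precisely so users can
refit from their own `duration_min,pressure_kpa,damage` tables. Relief as
modelled (linear/exponential toward a harmless value) ignores
ischaemia-reperfusion dynamics and post-load damage evolution; the relief
time is a tunable abstraction, not a physiological constant.
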