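# ulcerguard

Continuous pressure-magnitude-and-duration monitoring for pressure-ulcer
prevention.

Pressure ulcers develop when sustained mechanical loading — not just high
instantaneous pressure — damages skin and deeper tissue, especially over
bony prominences in people with impaired mobility. Classic pressure
monitoring flags the *current* load; it does not account for how the damaging
effect of a load **accumulates** over time and is **relieved** after
off-loading. `ulcerguard` implements a tunable streaming monitor for
clinical-engineering researchers and assistive-technology developers that
tracks the net damaging effect of a load during and after loading.

## The model

Each pressure sample `P` (kPa) at sampling interval `ΔT` contributes an
incremental damaging effect through an affine pressure–time estimator

    q(t, P) = c0 + c1 t + c2 P        (t in minutes)

and is folded into a running damaging effect `I(n)` with graded relief:

    linear relief:       I(n) = max( q + I(n−1) − β (1 − U), 0 )
    exponential relief:  I(n) = q + [1 − β (1 − U)] I(n−1)

where `U = min(mean(q), q_m)/q_m ∈ [0, 1]` grades the relief (0 = complete
relief, 1 = damaging load present) and the relief coefficient `β` is
calibrated from a chosen *relief time* `t_r`:

    linear:       β = ΔT / t_r
    exponential:  β = 1 − exp(−5 ΔT / t_r)

so that under complete relief the accumulated effect decays to zero (linear)
or to e⁻⁵ ≈ 0.67 % of its value (exponential) in exactly `t_r` seconds.
Pressures are gated by a pressure–time injury threshold with lower
endurance limit `C` (non-damaging, default 9 kPa) and upper limit `K + C`
(instantaneously damaging, default 32 kPa). Two per-sample alarms implement
the monitoring scheme: *redistribution* when the instantaneous pressure is
at or above `K + C`, and *relief* when `I` reaches a configurable limit.
Three literature baselines (moving average, fixed-period reset, inverse-time
decay) run in the same loop for comparison, and a signal generator provides
the standard simulated loading regimes. See `docs/methods.md` for the full
account.

## Worked example

Monitor 16 minutes of constant 10 kPa sitting pressure followed by a 2-minute
relief, configured per the Consortium for Spinal Cord Medicine guidance
(relief every 15 min for ~2 min):

```python
import numpy as np
from ulcerguard import cscm_config, run

cfg = cscm_config(dt_s=0.1, pressure_kpa=10.0,
                  accumulation_min=15.0, relief_time_s=120.0)
print("relief-alarm limit:", round(cfg.damaging_effect_limit, 2))

pressures = np.concatenate([np.full(9600, 10.0), np.zeros(1200)])
trace = run(pressures, cfg)
first = int(np.argmax(trace["relief_alarm"].to_numpy()))
print("first relief alarm at t =", trace["time_s"].iloc[first], "s")
print("residual fraction after 2 min relief:",
      trace["I"].iloc[-1] / trace["I"].iloc[9599])
```

prints

```
relief-alarm limit: 5114.39
first relief alarm at t = 900.0 s
residual fraction after 2 min relief: 0.006737946999085567
```

The alarm limit 5114.39 is the damaging effect accumulated by 15 minutes of
10 kPa load (9000 samples × q per sample); the first relief alarm fires at
exactly 15 minutes of sustained load; and after the recommended 2-minute
relief the accumulated effect has decayed to e⁻⁵ ≈ 0.0067 of its peak — the
"harmless" residual the exponential calibration is built around.

The same pipeline is available from the shell:

```sh
ulcerguard simulate --scenario repetitive_0_20kpa_30min --output signal.csv
ulcerguard monitor --input signal.csv --mode exponential --relief-time 300 \
    --output trace.csv
ulcerguard compare --input signal.csv --output methods.csv
ulcerguard fit --input observations.csv
```

`monitor` writes a per-sample trace CSV (`time_s, pressure_kpa, q, U, I,
pressure_class, redistribution_alarm, relief_alarm`); `compare` runs all
five methods over one signal; `fit` refits the estimator coefficients from a
`duration_min,pressure_kpa,damage` table.

## Caveat

The default estimator coefficients and injury-threshold limits derive from
small-sample animal data and demonstrate the method; they are not clinically
validated. Temperature, moisture, shear and friction are out of scope.
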