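"""Streaming damaging-effect monitor and two-alarm scheme.

Each incoming pressure sample is converted to a damaging-effect increment
q(dt, P), graded for relief via

    U = min(mean(recent q), q_m) / q_m,

where q_m is the estimator output at the lowest damaging pressure held for
one sample period, and folded into the running damaging effect I(n):

    linear mode:       I(n) = max(q + I(n-1) - beta * (1 - U), 0)
    exponential mode:  I(n) = q + (1 - beta * (1 - U)) * I(n-1)

Under a sustained damaging load U = 1 and both modes reduce to a pure
integrator; under complete relief (q = 0, U = 0) they decay per the
configured relief function.  The three literature baselines (averaging,
fixed, inverse) plug into the same per-sample loop so all five methods can
be compared on one damaging-effect axis.

Two per-sample alarms implement the monitoring scheme: a *redistribution*
alarm whenever the instantaneous pressure is classed instantaneously
damaging, and a *relief* alarm whenever the accumulated damaging effect
reaches the configured limit.  Alarms are not latched; debouncing is left to
the consumer.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, DomainError
from .estimator import (
    DEFAULT_COEFFICIENTS,
    DEFAULT_THRESHOLD,
    EstimatorCoefficients,
    InjuryThreshold,
    PressureClass,
    classify_pressure,
    compute_q_m,
    estimate_q,
)
from .relief import ReliefSpec, make_baseline, resolve_beta

__all__ = [
    "MonitorConfig",
    "MonitorState",
    "StepOutput",
    "compute_U",
    "initial_state",
    "step",
    "run",
    "compare_methods",
    "standard_method_configs",
    "default_damage_limit",
    "accumulation_limit",
    "cscm_config",
    "TRACE_COLUMNS",
]

TRACE_COLUMNS = [
    "time_s",
    "pressure_kpa",
    "q",
    "U",
    "I",
    "pressure_class",
    "redistribution_alarm",
    "relief_alarm",
]


@dataclass(frozen=True)
class MonitorConfig:
    """Static configuration of one monitored tissue site.

    ``damaging_effect_limit`` is the relief-alarm threshold on I; ``None``
    selects a default equal to 15 minutes of accumulation at the midpoint
    pressure C + K/2 — an arbitrary but reproducible placeholder that real
    deployments must replace per individual and tissue.  ``u_window`` is the
    number of recent q values averaged when grading relief (1 = instantaneous).
    """

    dt_s: float = 0.1
    relief: ReliefSpec = field(default_factory=ReliefSpec)
    coeffs: EstimatorCoefficients = DEFAULT_COEFFICIENTS
    thresholds: InjuryThreshold = DEFAULT_THRESHOLD
    damaging_effect_limit: float | None = None
    u_window: int = 1
    gate_below_lower_limit: bool = True
    include_intercept: bool = True

    def __post_init__(self) -> None:
        if not (self.dt_s > 0):
            raise ConfigurationError(f"dt_s must be > 0 s; got {self.dt_s}")
        if self.u_window < 1:
            raise ConfigurationError(f"u_window must be >= 1; got {self.u_window}")
        if self.damaging_effect_limit is not None and not (self.damaging_effect_limit > 0):
            raise ConfigurationError(
                f"damaging_effect_limit must be > 0; got {self.damaging_effect_limit}"
            )


@dataclass
class MonitorState:
    """Mutable per-channel state; create with :func:`initial_state`."""

    q_m: float
    limit: float
    beta: float | None = None
    baseline: object | None = None
    I: float = 0.0
    n: int = 0
    recent_q: deque = field(default_factory=lambda: deque(maxlen=1))
    relief_samples: int = 0
    relief_elapsed_s: float = 0.0


@dataclass(frozen=True)
class StepOutput:
    """Per-sample monitor output."""

    I: float
    q: float
    U: float
    pressure_class: PressureClass
    redistribution_alarm: bool
    relief_alarm: bool


def compute_U(recent_q: Sequence[float], q_m: float) -> float:
    """Relief grade U = min(mean(recent_q), q_m) / q_m, in [0, 1]."""
    if not (q_m > 0):
        raise ConfigurationError(f"q_m must be > 0; got {q_m}")
    n = len(recent_q)
    if n == 0:
        raise ConfigurationError("recent_q buffer is empty")
    mean_q = sum(recent_q) / n
    if mean_q >= q_m:
        return 1.0
    return mean_q / q_m


def default_damage_limit(config: MonitorConfig, duration_min: float = 15.0) -> float:
    """Damaging effect accumulated by ``duration_min`` of midpoint-pressure load."""
    midpoint = config.thresholds.C + config.thresholds.K / 2.0
    return accumulation_limit(midpoint, duration_min * 60.0, config.dt_s,
                              config.coeffs, config.thresholds,
                              include_intercept=config.include_intercept)


def accumulation_limit(
    pressure_kpa: float,
    duration_s: float,
    dt_s: float,
    coeffs: EstimatorCoefficients = DEFAULT_COEFFICIENTS,
    thresholds: InjuryThreshold = DEFAULT_THRESHOLD,
    *,
    include_intercept: bool = True,
) -> float:
    """Total damaging effect of a constant load held for ``duration_s``.

    This is the integrator value after round(duration_s / dt_s) samples of
    ``pressure_kpa`` with no relief — the natural way to translate a
    guideline of the form "relief every N minutes" into a relief-alarm limit.
    """
    if not (duration_s > 0):
        raise DomainError(f"duration_s must be > 0; got {duration_s}")
    n_steps = round(duration_s / dt_s)
    q_step = estimate_q(dt_s / 60.0, pressure_kpa, coeffs,
                        nondamaging_limit_kpa=thresholds.C,
                        include_intercept=include_intercept)
    if not (q_step > 0):
        raise DomainError(
            f"pressure {pressure_kpa} kPa is non-damaging (<= {thresholds.C} kPa); "
            "an accumulation limit would never be reached"
        )
    return n_steps * q_step


def cscm_config(
    dt_s: float = 0.1,
    pressure_kpa: float = 10.0,
    accumulation_min: float = 15.0,
    relief_time_s: float = 120.0,
    mode: str = "exponential",
) -> MonitorConfig:
    """Monitor configuration implementing the CSCM repositioning guideline.

    The Consortium for Spinal Cord Medicine recommends pressure relief every
    15-30 minutes for about 2 minutes for wheelchair users with spinal cord
    injury.  The relief-alarm limit is set to the damaging effect accumulated
    by ``accumulation_min`` minutes of constant load at ``pressure_kpa``, and
    the relief time to ``relief_time_s`` (2 min).
    """
    limit = accumulation_limit(pressure_kpa, accumulation_min * 60.0, dt_s)
    return MonitorConfig(
        dt_s=dt_s,
        relief=ReliefSpec(mode=mode, relief_time_s=relief_time_s),
        damaging_effect_limit=limit,
    )


def initial_state(config: MonitorConfig) -> MonitorState:
    """Fresh monitor state for one channel under ``config``."""
    spec = config.relief
    beta = baseline = None
    if spec.mode in ("linear", "exponential"):
        beta = resolve_beta(spec, config.dt_s)
    else:
        baseline = make_baseline(spec)
    limit = config.damaging_effect_limit
    if limit is None:
        limit = default_damage_limit(config)
    return MonitorState(
        q_m=compute_q_m(config.dt_s, config.coeffs, config.thresholds),
        limit=limit,
        beta=beta,
        baseline=baseline,
        recent_q=deque(maxlen=config.u_window),
    )


def step(
    state: MonitorState, pressure_kpa: float, config: MonitorConfig
) -> tuple[MonitorState, StepOutput]:
    """Advance the monitor by one sample.

    Mutates and returns ``state`` (single-owner semantics); the returned
    :class:`StepOutput` carries the per-sample trace fields and alarms.
    """
    p = float(pressure_kpa)
    if math.isnan(p) or p < 0:
        raise DataError(f"invalid pressure {pressure_kpa!r} at sample index {state.n}")
    gate = config.thresholds.C if config.gate_below_lower_limit else None
    q = estimate_q(config.dt_s / 60.0, p, config.coeffs,
                   nondamaging_limit_kpa=gate,
                   include_intercept=config.include_intercept)
    cls = classify_pressure(p, config.thresholds)

    # A sample contributing no damaging effect counts as (continuing) relief.
    if q > 0.0:
        state.relief_samples = 0
        state.relief_elapsed_s = 0.0
    else:
        state.relief_samples += 1
        state.relief_elapsed_s = state.relief_samples * config.dt_s

    state.recent_q.append(q)
    u = compute_U(state.recent_q, state.q_m)

    mode = config.relief.mode
    if mode == "linear":
        i_new = q + state.I - state.beta * (1.0 - u)
        if i_new < 0.0:
            i_new = 0.0
    elif mode == "exponential":
        i_new = q + (1.0 - state.beta * (1.0 - u)) * state.I
    else:
        i_new = state.baseline.step(q, state.relief_elapsed_s)

    state.I = i_new
    state.n += 1
    out = StepOutput(
        I=i_new,
        q=q,
        U=u,
        pressure_class=cls,
        redistribution_alarm=cls is PressureClass.INSTANTANEOUSLY_DAMAGING,
        relief_alarm=i_new >= state.limit,
    )
    return state, out


def _pressures_and_times(
    signal, dt_s: float, time_tolerance: float
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(signal, pd.DataFrame):
        if "pressure_kpa" not in signal.columns:
            raise DataError("signal frame is missing the 'pressure_kpa' column")
        pressures = signal["pressure_kpa"].to_numpy(dtype=float)
        if "time_s" in signal.columns and len(signal) > 1:
            times = signal["time_s"].to_numpy(dtype=float)
            diffs = np.diff(times)
            bad = np.nonzero(np.abs(diffs - dt_s) > time_tolerance * max(dt_s, 1e-12))[0]
            if bad.size:
                raise DataError(
                    f"samples are not uniformly spaced at dt={dt_s} s: first offending "
                    f"index {int(bad[0]) + 1} (interval {diffs[bad[0]]:.9g} s)"
                )
            return pressures, times
        times = np.arange(len(pressures)) * dt_s
        return pressures, times
    pressures = np.asarray(list(signal), dtype=float)
    return pressures, np.arange(len(pressures)) * dt_s


def run(
    signal: Union[pd.DataFrame, Iterable[float]],
    config: MonitorConfig,
    *,
    time_tolerance: float = 1e-6,
) -> pd.DataFrame:
    """Monitor a whole uniformly sampled signal; returns the per-sample trace.

    ``signal`` may be a frame with ``time_s``/``pressure_kpa`` columns (time
    spacing is validated against ``config.dt_s`` within a relative
    ``time_tolerance``) or any iterable of pressures in kPa.  The trace is
    the exact sequential fold of :func:`step` over the samples, one row per
    sample, with columns ``TRACE_COLUMNS``.
    """
    pressures, times = _pressures_and_times(signal, config.dt_s, time_tolerance)
    state = initial_state(config)
    n = len(pressures)
    q_arr = np.empty(n)
    u_arr = np.empty(n)
    i_arr = np.empty(n)
    cls_arr = np.empty(n, dtype=object)
    red_arr = np.empty(n, dtype=bool)
    rel_arr = np.empty(n, dtype=bool)
    for k in range(n):
        state, out = step(state, pressures[k], config)
        q_arr[k] = out.q
        u_arr[k] = out.U
        i_arr[k] = out.I
        cls_arr[k] = out.pressure_class.value
        red_arr[k] = out.redistribution_alarm
        rel_arr[k] = out.relief_alarm
    return pd.DataFrame(
        {
            "time_s": times,
            "pressure_kpa": pressures,
            "q": q_arr,
            "U": u_arr,
            "I": i_arr,
            "pressure_class": cls_arr,
            "redistribution_alarm": red_arr,
            "relief_alarm": rel_arr,
        },
        columns=TRACE_COLUMNS,
    )


def standard_method_configs(
    dt_s: float = 0.1,
    relief_time_s: float = 300.0,
    fixed_relief_time_s: float = 60.0,
    window_len: int = 3000,
    **shared,
) -> dict:
    """One :class:`MonitorConfig` per method, sharing estimator and thresholds.

    ``relief_time_s`` calibrates the proposed linear/exponential modes;
    ``fixed_relief_time_s`` the fixed-reset baseline; ``window_len`` the
    averaging filter.  Extra keyword arguments are passed to every config.
    """
    def cfg(spec: ReliefSpec) -> MonitorConfig:
        return MonitorConfig(dt_s=dt_s, relief=spec, **shared)

    return {
        "averaging": cfg(ReliefSpec("averaging", relief_time_s=relief_time_s, window_len=window_len)),
        "fixed": cfg(ReliefSpec("fixed", relief_time_s=fixed_relief_time_s)),
        "inverse": cfg(ReliefSpec("inverse", relief_time_s=relief_time_s)),
        "linear": cfg(ReliefSpec("linear", relief_time_s=relief_time_s)),
        "exponential": cfg(ReliefSpec("exponential", relief_time_s=relief_time_s)),
    }


def compare_methods(
    signal: Union[pd.DataFrame, Iterable[float]],
    configs: Mapping[str, MonitorConfig],
) -> pd.DataFrame:
    """Run several monitoring methods over the identical signal.

    All configs must share the sampling interval, estimator coefficients and
    injury thresholds so the methods are compared on one axis.  Returns a
    long-format frame (sample, time_s, method, q, U, I, alarms).
    """
    if not configs:
        raise ConfigurationError("no configs supplied")
    ref = next(iter(configs.values()))
    for name, cfg in configs.items():
        if cfg.dt_s != ref.dt_s:
            raise ConfigurationError(f"config {name!r} has dt_s={cfg.dt_s}, expected {ref.dt_s}")
        if cfg.coeffs != ref.coeffs or cfg.thresholds != ref.thresholds:
            raise ConfigurationError(
                f"config {name!r} uses different estimator coefficients or thresholds"
            )
    if not isinstance(signal, pd.DataFrame):
        signal = pd.DataFrame({"pressure_kpa": np.asarray(list(signal), dtype=float)})
    frames = []
    for name, cfg in configs.items():
        trace = run(signal, cfg)
        trace.insert(0, "sample", np.arange(len(trace)))
        trace.insert(1, "method", name)
        frames.append(trace)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)
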