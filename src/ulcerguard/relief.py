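"""Relief (decay) functions for the accumulated damaging effect.

Two proposed relief functions are provided, both calibrated by a *relief
time* t_r — the time for an accumulated damaging effect to decay to a
harmless value under complete relief:

* linear: a constant per-step decrement beta = dt / t_r, so a unit effect
  reaches exactly zero after t_r seconds;
* exponential: a leaky-integrator factor beta = 1 - exp(-5 dt / t_r), so the
  effect reaches exp(-5) (~0.67%) of its initial value after t_r seconds,
  taken as "significantly similar to zero".

Both are graded by the relief factor (1 - U), U in [0, 1]: U = 0 is complete
relief, U = 1 a sustained damaging load (no decay).

Three literature baseline behaviours are implemented for comparison:
a moving-average filter over the per-sample damaging-effect increments, a
fixed-period reset (full instantaneous recovery once continuous relief has
lasted t_r), and an inverse-time decay (held accumulation divided by the
elapsed relief time in seconds, floored at 1 s).
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

from .errors import ConfigurationError, DomainError

__all__ = [
    "MODES",
    "ReliefSpec",
    "beta_linear",
    "beta_exponential",
    "resolve_beta",
    "decay_linear",
    "decay_exponential",
    "AveragingFilter",
    "FixedReset",
    "InverseTime",
    "make_baseline",
    "baseline_step",
]

MODES = ("linear", "exponential", "averaging", "fixed", "inverse")
_BASELINE_MODES = ("averaging", "fixed", "inverse")


@dataclass(frozen=True)
class ReliefSpec:
    """Configuration of the relief behaviour.

    ``beta`` normally stays ``None`` and is derived from ``relief_time_s``
    and the sampling interval; set it explicitly to override the calibration.
    ``window_len`` is only used by the averaging baseline.
    """

    mode: str = "exponential"
    relief_time_s: float = 300.0
    beta: float | None = None
    window_len: int = 3000

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(
                f"unknown relief mode {self.mode!r}; expected one of {', '.join(MODES)}"
            )
        if not (self.relief_time_s > 0):
            raise ConfigurationError(f"relief_time_s must be > 0; got {self.relief_time_s}")
        if self.beta is not None and not (0 < self.beta <= 1):
            raise ConfigurationError(f"beta must be in (0, 1]; got {self.beta}")
        if self.mode == "averaging" and self.window_len < 1:
            raise ConfigurationError(f"window_len must be >= 1; got {self.window_len}")

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "relief_time_s": self.relief_time_s,
            "beta": self.beta,
            "window_len": self.window_len,
        }


def _check_times(dt_s: float, relief_time_s: float) -> None:
    if not (dt_s > 0):
        raise DomainError(f"sampling interval dt_s must be > 0 s; got {dt_s}")
    if not (relief_time_s > 0):
        raise DomainError(f"relief_time_s must be > 0 s; got {relief_time_s}")


def beta_linear(dt_s: float, relief_time_s: float) -> float:
    """Linear relief coefficient beta = dt / t_r, in (0, 1]."""
    _check_times(dt_s, relief_time_s)
    if dt_s > relief_time_s:
        raise DomainError(
            f"dt_s ({dt_s} s) exceeds relief_time_s ({relief_time_s} s): "
            "decay would complete in under one sample"
        )
    return dt_s / relief_time_s


def beta_exponential(dt_s: float, relief_time_s: float) -> float:
    """Exponential relief coefficient beta = 1 - exp(-5 dt / t_r), in (0, 1).

    The factor 5 makes (1 - beta)^(t_r/dt) = exp(-5), i.e. the accumulated
    effect decays to ~0.67% of its value over one relief time.
    """
    _check_times(dt_s, relief_time_s)
    return 1.0 - math.exp(-5.0 * dt_s / relief_time_s)


def resolve_beta(spec: ReliefSpec, dt_s: float) -> float:
    """Relief coefficient for a linear/exponential spec at sampling interval dt_s."""
    if spec.mode not in ("linear", "exponential"):
        raise ConfigurationError(f"relief mode {spec.mode!r} has no beta coefficient")
    if spec.beta is not None:
        return spec.beta
    if spec.mode == "linear":
        return beta_linear(dt_s, spec.relief_time_s)
    return beta_exponential(dt_s, spec.relief_time_s)


def _check_decay_args(i_prev: float, beta: float, u: float) -> None:
    if i_prev < 0:
        raise DomainError(f"damaging effect must be >= 0; got {i_prev}")
    if not (0 < beta <= 1):
        raise DomainError(f"beta must be in (0, 1]; got {beta}")
    if not (0 <= u <= 1):
        raise DomainError(f"relief grade U must be in [0, 1]; got {u}")


def decay_linear(i_prev: float, beta: float, u: float) -> float:
    """One linear-decay step: max(I - beta * (1 - U), 0).

    Clamped at zero — a negative damaging effect is meaningless.
    """
    _check_decay_args(i_prev, beta, u)
    return max(i_prev - beta * (1.0 - u), 0.0)


def decay_exponential(i_prev: float, beta: float, u: float) -> float:
    """One exponential-decay step: (1 - beta * (1 - U)) * I."""
    _check_decay_args(i_prev, beta, u)
    return (1.0 - beta * (1.0 - u)) * i_prev


class AveragingFilter:
    """Moving-average baseline over the per-sample damaging-effect increments.

    Output is the arithmetic mean of the last ``window_len`` increments,
    zero-padded before the start of monitoring.  A stationary load therefore
    plateaus after one window and an impulse is fully forgotten one window
    after it occurred.
    """

    mode = "averaging"

    def __init__(self, window_len: int = 3000):
        if window_len < 1:
            raise ConfigurationError(f"window_len must be >= 1; got {window_len}")
        self.window_len = window_len
        self._buf: deque = deque([0.0] * window_len, maxlen=window_len)
        self._sum = 0.0

    def step(self, q_increment: float, relief_elapsed_s: float) -> float:
        oldest = self._buf[0]
        self._buf.append(q_increment)
        self._sum += q_increment - oldest
        if self._sum < 0:  # guard against rounding drift
            self._sum = 0.0
        return self._sum / self.window_len


class FixedReset:
    """Fixed-period baseline: integrate, hold on relief, reset after t_r.

    The accumulated value is held constant while relief is under way and
    resets to zero (full instantaneous recovery) once continuous relief has
    lasted at least ``relief_time_s``.
    """

    mode = "fixed"

    def __init__(self, relief_time_s: float):
        if not (relief_time_s > 0):
            raise ConfigurationError(f"relief_time_s must be > 0; got {relief_time_s}")
        self.relief_time_s = relief_time_s
        self._accum = 0.0

    def step(self, q_increment: float, relief_elapsed_s: float) -> float:
        if q_increment > 0:
            self._accum += q_increment
        elif relief_elapsed_s >= self.relief_time_s:
            self._accum = 0.0
        return self._accum


class InverseTime:
    """Inverse-time baseline: held accumulation over elapsed relief seconds.

    During relief the displayed value is the held accumulation divided by
    max(relief_elapsed_s, 1) — a hyperbolic decay toward (but never exactly
    reaching) zero.  When loading resumes, accumulation continues from the
    decayed displayed value.
    """

    mode = "inverse"

    def __init__(self) -> None:
        self._value = 0.0
        self._held = 0.0

    def step(self, q_increment: float, relief_elapsed_s: float) -> float:
        if q_increment > 0:
            self._value += q_increment
            self._held = self._value
        else:
            self._value = self._held / max(relief_elapsed_s, 1.0)
        return self._value


def make_baseline(spec: ReliefSpec):
    """Instantiate the baseline state object for an averaging/fixed/inverse spec."""
    if spec.mode == "averaging":
        return AveragingFilter(spec.window_len)
    if spec.mode == "fixed":
        return FixedReset(spec.relief_time_s)
    if spec.mode == "inverse":
        return InverseTime()
    raise ConfigurationError(
        f"mode {spec.mode!r} is not a baseline; expected one of {', '.join(_BASELINE_MODES)}"
    )


def baseline_step(mode: str, state, q_increment: float, relief_elapsed_s: float) -> float:
    """Advance a baseline ``state`` one sample and return its displayed value."""
    if mode not in _BASELINE_MODES:
        raise ConfigurationError(
            f"unknown baseline mode {mode!r}; expected one of {', '.join(_BASELINE_MODES)}"
        )
    if getattr(state, "mode", None) != mode:
        raise ConfigurationError(
            f"state object is for mode {getattr(state, 'mode', None)!r}, not {mode!r}"
        )
    if q_increment < 0:
        raise DomainError(f"q_increment must be >= 0; got {q_increment}")
    if relief_elapsed_s < 0:
        raise DomainError(f"relief_elapsed_s must be >= 0; got {relief_elapsed_s}")
    return state.step(q_increment, relief_elapsed_s)
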