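"""Synthetic interface-pressure signal generation.

Provides the simulated loading regimes used to exercise the monitor without
any recorded data: constant loads, a clipped sinusoid, a 50%-duty square
wave (repetitive loading, e.g. active support surfaces or dynamic wheelchair
locomotion), per-sample uniform random pressure, and a single-sample impulse
for studying each method's impulse response.

All signals are uniformly sampled, clipped at 0 kPa, and deterministic for a
given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = ["KINDS", "SignalSpec", "generate", "reference_scenarios"]

KINDS = ("constant", "sine", "square_repetitive", "uniform_random", "impulse")


@dataclass(frozen=True)
class SignalSpec:
    """Recipe for one synthetic pressure signal.

    Field semantics by kind (all pressures kPa):

    * ``constant`` — level ``offset_kpa + amplitude_kpa``;
    * ``sine`` — ``offset_kpa + amplitude_kpa * sin(2 pi f t)``, clipped at 0;
    * ``square_repetitive`` — alternates between ``offset_kpa + amplitude_kpa``
      (first half-period) and ``offset_kpa``, 50% duty cycle;
    * ``uniform_random`` — i.i.d. uniform on
      [``offset_kpa``, ``offset_kpa + amplitude_kpa``];
    * ``impulse`` — baseline ``offset_kpa`` with one sample at
      ``offset_kpa + amplitude_kpa`` at ``impulse_index``.

    Frequency may be given as ``frequency_hz`` or ``period_s`` (exactly one
    required for sine/square kinds).
    """

    kind: str
    duration_s: float
    dt_s: float = 0.1
    amplitude_kpa: float = 0.0
    offset_kpa: float = 0.0
    frequency_hz: float | None = None
    period_s: float | None = None
    seed: int | None = None
    impulse_index: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ConfigurationError(f"unknown signal kind {self.kind!r}; expected one of {', '.join(KINDS)}")
        if not (self.duration_s > 0):
            raise ConfigurationError(f"duration_s must be > 0; got {self.duration_s}")
        if not (self.dt_s > 0):
            raise ConfigurationError(f"dt_s must be > 0; got {self.dt_s}")
        if self.kind in ("sine", "square_repetitive"):
            if (self.frequency_hz is None) == (self.period_s is None):
                raise ConfigurationError(
                    f"kind {self.kind!r} needs exactly one of frequency_hz or period_s"
                )
            f = self.frequency_hz if self.frequency_hz is not None else 1.0 / self.period_s
            if not (f > 0):
                raise ConfigurationError(f"frequency must be > 0 Hz; got {f}")
        if self.kind == "impulse" and self.impulse_index < 0:
            raise ConfigurationError(f"impulse_index must be >= 0; got {self.impulse_index}")

    @property
    def n_samples(self) -> int:
        return round(self.duration_s / self.dt_s)

    def _frequency(self) -> float:
        return self.frequency_hz if self.frequency_hz is not None else 1.0 / self.period_s


def generate(spec: SignalSpec, seed: int | None = None) -> pd.DataFrame:
    """Generate the signal described by ``spec``.

    ``seed`` overrides ``spec.seed`` for stochastic kinds.  Returns a frame
    with ``time_s`` and ``pressure_kpa`` columns, ``round(duration_s/dt_s)``
    rows, all pressures finite and >= 0.
    """
    n = spec.n_samples
    t = np.arange(n) * spec.dt_s
    if spec.kind == "constant":
        p = np.full(n, spec.offset_kpa + spec.amplitude_kpa)
    elif spec.kind == "sine":
        p = spec.offset_kpa + spec.amplitude_kpa * np.sin(2.0 * np.pi * spec._frequency() * t)
    elif spec.kind == "square_repetitive":
        period = 1.0 / spec._frequency()
        high_phase = np.mod(t, period) < period / 2.0
        p = np.where(high_phase, spec.offset_kpa + spec.amplitude_kpa, spec.offset_kpa)
    elif spec.kind == "uniform_random":
        rng = np.random.default_rng(seed if seed is not None else spec.seed)
        p = rng.uniform(spec.offset_kpa, spec.offset_kpa + spec.amplitude_kpa, n)
    else:  # impulse
        p = np.full(n, float(spec.offset_kpa))
        if spec.impulse_index >= n:
            raise ConfigurationError(
                f"impulse_index {spec.impulse_index} is outside the {n}-sample signal"
            )
        p[spec.impulse_index] = spec.offset_kpa + spec.amplitude_kpa
    p = np.clip(p, 0.0, None)
    return pd.DataFrame({"time_s": t, "pressure_kpa": p})


def reference_scenarios(dt_s: float = 0.1) -> dict:
    """Named presets for the simulated loading regimes exercised in testing.

    * ``constant_10kpa`` / ``constant_20kpa`` — steady loads of 10/20 kPa;
    * ``sine_20kpa_0p00333hz`` — 20 kPa amplitude sinusoid at 0.00333 Hz on a
      20 kPa offset (range 0-40 kPa after clipping);
    * ``random_20_120kpa`` — per-sample uniform pressure on 20-120 kPa
      (mean 70 kPa), a highly varying load;
    * ``sustained_20_25kpa`` — uniform 20-25 kPa, prolonged sitting without
      regular relief;
    * ``repetitive_0_20kpa_30min`` — 0-20 kPa square wave with a 30-min
      period over 8 h, cyclic loading with full relief phases.
    """
    hour = 3600.0
    return {
        "constant_10kpa": SignalSpec("constant", duration_s=hour, dt_s=dt_s, amplitude_kpa=10.0),
        "constant_20kpa": SignalSpec("constant", duration_s=hour, dt_s=dt_s, amplitude_kpa=20.0),
        "sine_20kpa_0p00333hz": SignalSpec(
            "sine", duration_s=hour, dt_s=dt_s, amplitude_kpa=20.0, offset_kpa=20.0,
            frequency_hz=0.00333,
        ),
        "random_20_120kpa": SignalSpec(
            "uniform_random", duration_s=hour, dt_s=dt_s, amplitude_kpa=100.0, offset_kpa=20.0,
            seed=0,
        ),
        "sustained_20_25kpa": SignalSpec(
            "uniform_random", duration_s=2 * hour, dt_s=dt_s, amplitude_kpa=5.0, offset_kpa=20.0,
            seed=0,
        ),
        "repetitive_0_20kpa_30min": SignalSpec(
            "square_repetitive", duration_s=8 * hour, dt_s=dt_s, amplitude_kpa=20.0,
            offset_kpa=0.0, period_s=1800.0,
        ),
    }
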