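"""Structured run configuration with lossless YAML round-tripping.

The schema mirrors the monitor's configuration plus run metadata::

    dt_s: 0.1
    relief: {mode: exponential, relief_time_s: 300.0, beta: null, window_len: 3000}
    coefficients: {c0: 0.55323, c1: 0.14938, c2: 0.0014787}
    thresholds: {C_kpa: 9.0, K_kpa: 23.0, t0: null, alpha: null}
    damaging_effect_limit: null
    u_window: 1
    gate_below_lower_limit: true
    include_intercept: true
    output: trace.csv
    log_level: INFO
    seed: 1

Unknown keys are rejected by name so typos never silently fall back to
defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .errors import ConfigurationError
from .estimator import EstimatorCoefficients, InjuryThreshold
from .monitor import MonitorConfig
from .relief import ReliefSpec

__all__ = ["RunConfig"]

_TOP_KEYS = {
    "dt_s", "relief", "coefficients", "thresholds", "damaging_effect_limit",
    "u_window", "gate_below_lower_limit", "include_intercept",
    "output", "log_level", "seed",
}
_RELIEF_KEYS = {"mode", "relief_time_s", "beta", "window_len"}
_COEFF_KEYS = {"c0", "c1", "c2"}
_THRESH_KEYS = {"C_kpa", "K_kpa", "t0", "alpha"}


def _reject_unknown(section: str, data: dict, allowed: set) -> None:
    unknown = sorted(set(data) - allowed)
    if unknown:
        raise ConfigurationError(f"unknown {section} key(s): {', '.join(unknown)}")


@dataclass(frozen=True)
class RunConfig:
    """A full monitor configuration plus output path, log level and seed."""

    monitor: MonitorConfig = field(default_factory=MonitorConfig)
    output: str | None = None
    log_level: str = "INFO"
    seed: int | None = None

    def to_dict(self) -> dict:
        m = self.monitor
        return {
            "dt_s": m.dt_s,
            "relief": m.relief.to_dict(),
            "coefficients": m.coeffs.to_dict(),
            "thresholds": m.thresholds.to_dict(),
            "damaging_effect_limit": m.damaging_effect_limit,
            "u_window": m.u_window,
            "gate_below_lower_limit": m.gate_below_lower_limit,
            "include_intercept": m.include_intercept,
            "output": self.output,
            "log_level": self.log_level,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if not isinstance(data, dict):
            raise ConfigurationError(f"configuration must be a mapping; got {type(data).__name__}")
        _reject_unknown("configuration", data, _TOP_KEYS)
        relief_d = dict(data.get("relief") or {})
        _reject_unknown("relief", relief_d, _RELIEF_KEYS)
        coeff_d = dict(data.get("coefficients") or {})
        _reject_unknown("coefficients", coeff_d, _COEFF_KEYS)
        thresh_d = dict(data.get("thresholds") or {})
        _reject_unknown("thresholds", thresh_d, _THRESH_KEYS)

        relief = ReliefSpec(**relief_d) if relief_d else ReliefSpec()
        coeffs = EstimatorCoefficients(**coeff_d) if coeff_d else EstimatorCoefficients()
        thresholds = InjuryThreshold(
            C=thresh_d.get("C_kpa", 9.0),
            K=thresh_d.get("K_kpa", 23.0),
            t0=thresh_d.get("t0"),
            alpha=thresh_d.get("alpha"),
        ) if thresh_d else InjuryThreshold()

        monitor_kwargs = {}
        for key in ("dt_s", "damaging_effect_limit", "u_window",
                    "gate_below_lower_limit", "include_intercept"):
            if key in data and data[key] is not None:
                monitor_kwargs[key] = data[key]
        if "damaging_effect_limit" in data:
            monitor_kwargs["damaging_effect_limit"] = data["damaging_effect_limit"]
        monitor = MonitorConfig(relief=relief, coeffs=coeffs, thresholds=thresholds,
                                **monitor_kwargs)
        return cls(
            monitor=monitor,
            output=data.get("output"),
            log_level=data.get("log_level", "INFO"),
            seed=data.get("seed"),
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        """Parse from a YAML string or a path to a YAML file."""
        import os

        if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
            with open(source) as fh:
                data = yaml.safe_load(fh)
        else:
            data = yaml.safe_load(source)
        return cls.from_dict(data or {})
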