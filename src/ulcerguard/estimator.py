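"""Pressure-time damaging-effect estimation and injury-threshold gating.

The damaging-effect estimator maps a (duration, pressure) pair to a
dimensionless incremental damaging effect through an affine model

    q(t, P) = c0 + c1 * t + c2 * P,

with t in minutes and P in kPa.  The default coefficients were fitted to
porcine pressure/tissue-damage grading data and serve as a demonstration
parameterisation, not a clinically validated one.

Pressure magnitudes are gated against a sigmoid pressure-time injury
threshold,

    P(t) = K / (1 + exp(alpha * (t - t0))) + C,

whose asymptotes split the pressure axis into three regimes: at or below the
lower endurance limit C the load is non-damaging regardless of duration; at
or above the upper limit K + C it is instantaneously damaging; in between it
accumulates damage over time.  The default limits (C = 9 kPa, K + C = 32 kPa)
come from an albino-rat skeletal-muscle injury-threshold model.  The sigmoid
midpoint t0 and steepness alpha carry no defaults; without them only the two
asymptotic limits are available for gating.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigurationError, DomainError, FitError

__all__ = [
    "EstimatorCoefficients",
    "InjuryThreshold",
    "PressureClass",
    "DamageObservation",
    "EstimatorFit",
    "estimate_q",
    "classify_pressure",
    "injury_threshold_pressure",
    "fit_estimator",
    "compute_q_m",
    "DEFAULT_COEFFICIENTS",
    "DEFAULT_THRESHOLD",
]


@dataclass(frozen=True)
class EstimatorCoefficients:
    """Coefficients of the affine pressure-time damaging-effect model.

    Attributes
    ----------
    c0 : float
        Dimensionless intercept.
    c1 : float
        Damaging effect per minute of application (1/min).
    c2 : float
        Damaging effect per kPa of applied pressure (1/kPa).
    """

    c0: float = 0.55323
    c1: float = 0.14938
    c2: float = 0.0014787

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.c0, self.c1, self.c2)):
            raise DomainError("estimator coefficients must be finite")
        if self.c1 < 0:
            raise DomainError(f"c1 must be >= 0 (damage cannot decrease with duration); got {self.c1}")
        if self.c2 < 0:
            raise DomainError(f"c2 must be >= 0 (damage cannot decrease with pressure); got {self.c2}")

    def to_dict(self) -> dict:
        return {"c0": self.c0, "c1": self.c1, "c2": self.c2}


@dataclass(frozen=True)
class InjuryThreshold:
    """Sigmoid pressure-time injury threshold parameters.

    ``C`` is the lower pressure endurance limit (kPa), ``K`` the sigmoid
    amplitude so the upper limit is ``K + C``.  ``t0`` (midpoint time) and
    ``alpha`` (steepness, inverse time) are optional; when absent only the
    two asymptotic limits are used.
    """

    C: float = 9.0
    K: float = 23.0
    t0: float | None = None
    alpha: float | None = None

    def __post_init__(self) -> None:
        if not (self.C > 0):
            raise DomainError(f"lower endurance limit C must be > 0 kPa; got {self.C}")
        if not (self.K > 0):
            raise DomainError(f"sigmoid amplitude K must be > 0 kPa; got {self.K}")

    @property
    def lower_limit(self) -> float:
        """Non-damaging pressure limit, kPa."""
        return self.C

    @property
    def upper_limit(self) -> float:
        """Instantaneously damaging pressure limit K + C, kPa."""
        return self.K + self.C

    def to_dict(self) -> dict:
        return {"C_kpa": self.C, "K_kpa": self.K, "t0": self.t0, "alpha": self.alpha}


class PressureClass(str, Enum):
    """Magnitude regime of one pressure sample."""

    NON_DAMAGING = "non_damaging"
    ACCUMULATING = "accumulating"
    INSTANTANEOUSLY_DAMAGING = "instantaneously_damaging"


@dataclass(frozen=True)
class DamageObservation:
    """One (duration, pressure, damage) observation for refitting the estimator."""

    duration_min: float
    pressure_kpa: float
    damage: float

    def __post_init__(self) -> None:
        if self.duration_min < 0:
            raise DomainError(f"duration_min must be >= 0; got {self.duration_min}")
        if not (self.pressure_kpa > 0):
            raise DomainError(f"pressure_kpa must be > 0; got {self.pressure_kpa}")


DEFAULT_COEFFICIENTS = EstimatorCoefficients()
DEFAULT_THRESHOLD = InjuryThreshold()


def estimate_q(
    duration_min: float,
    pressure_kpa: float,
    coeffs: EstimatorCoefficients = DEFAULT_COEFFICIENTS,
    *,
    nondamaging_limit_kpa: float | None = DEFAULT_THRESHOLD.C,
    include_intercept: bool = True,
) -> float:
    """Incremental damaging effect of ``pressure_kpa`` applied for ``duration_min``.

    Pressures at or below ``nondamaging_limit_kpa`` contribute exactly 0 so
    that sub-threshold load never accumulates; pass ``None`` to disable the
    gate.  ``include_intercept=False`` drops the (statistically weak) c0 term.
    """
    if duration_min < 0:
        raise DomainError(f"duration_min must be >= 0; got {duration_min}")
    if pressure_kpa < 0:
        raise DomainError(f"pressure_kpa must be >= 0; got {pressure_kpa}")
    if nondamaging_limit_kpa is not None and pressure_kpa <= nondamaging_limit_kpa:
        return 0.0
    q = coeffs.c1 * duration_min + coeffs.c2 * pressure_kpa
    if include_intercept:
        q += coeffs.c0
    return q


def classify_pressure(
    pressure_kpa: float, thr: InjuryThreshold = DEFAULT_THRESHOLD
) -> PressureClass:
    """Classify a pressure magnitude against the injury-threshold limits.

    Ties are conservative: ``P == C`` is non-damaging, ``P == K + C`` is
    instantaneously damaging.
    """
    if pressure_kpa < 0:
        raise DomainError(f"pressure_kpa must be >= 0; got {pressure_kpa}")
    if pressure_kpa <= thr.lower_limit:
        return PressureClass.NON_DAMAGING
    if pressure_kpa >= thr.upper_limit:
        return PressureClass.INSTANTANEOUSLY_DAMAGING
    return PressureClass.ACCUMULATING


def injury_threshold_pressure(time: float, thr: InjuryThreshold) -> float:
    """Injury-threshold pressure (kPa) at application ``time``.

    Evaluates the full sigmoid K / (1 + exp(alpha * (time - t0))) + C, which
    requires ``t0`` and ``alpha``; strictly decreasing in time for alpha > 0,
    from K + C at short times down to C at long times.
    """
    if thr.t0 is None or thr.alpha is None:
        raise ConfigurationError(
            "injury-threshold sigmoid unavailable: t0 and alpha are not set; "
            "only asymptotic limit gating (C, K+C) applies"
        )
    # Guard the exponential against overflow on extreme times.
    x = thr.alpha * (time - thr.t0)
    if x > 700:
        return thr.C
    return thr.K / (1.0 + math.exp(x)) + thr.C


_OBS_COLUMNS = ("duration_min", "pressure_kpa", "damage")


@dataclass(frozen=True)
class EstimatorFit:
    """Fit result of the damaging-effect estimator.

    Per-coefficient statistics are keyed by ``c0``, ``c1``, ``c2``.
    """

    coeffs: EstimatorCoefficients
    n_obs: int
    r_squared: float
    r_squared_adj: float
    f_statistic: float
    f_pvalue: float
    df_model: int
    df_resid: int
    std_errors: Mapping[str, float]
    t_values: Mapping[str, float]
    p_values: Mapping[str, float]
    conf_int_95: Mapping[str, tuple]

    def summary(self) -> str:
        lines = [
            f"n = {self.n_obs}",
            f"R^2 = {self.r_squared:.4f} (adjusted {self.r_squared_adj:.4f})",
            f"F({self.df_model},{self.df_resid}) = {self.f_statistic:.4f}, p = {self.f_pvalue:.3g}",
        ]
        for name in ("c0", "c1", "c2"):
            lo, hi = self.conf_int_95[name]
            lines.append(
                f"{name} = {getattr(self.coeffs, name):.6g} "
                f"(SE {self.std_errors[name]:.4g}, t = {self.t_values[name]:.4g}, "
                f"p = {self.p_values[name]:.3g}, 95% CI {lo:.4g} to {hi:.4g})"
            )
        return "\n".join(lines)


def _observations_frame(
    observations: Union[pd.DataFrame, Iterable[DamageObservation]],
) -> pd.DataFrame:
    if isinstance(observations, pd.DataFrame):
        missing = [c for c in _OBS_COLUMNS if c not in observations.columns]
        if missing:
            raise FitError(f"observation table is missing columns: {', '.join(missing)}")
        return observations.loc[:, list(_OBS_COLUMNS)].astype(float)
    rows = [(o.duration_min, o.pressure_kpa, o.damage) for o in observations]
    return pd.DataFrame(rows, columns=list(_OBS_COLUMNS), dtype=float)


def fit_estimator(
    observations: Union[pd.DataFrame, Iterable[DamageObservation]],
) -> EstimatorFit:
    """Refit the affine damaging-effect model by ordinary least squares.

    The model is damage ~ 1 + duration_min + pressure_kpa, a Gaussian GLM
    with identity link, so the reported R^2, adjusted R^2, F statistic,
    standard errors, t statistics, p values and 95% confidence intervals all
    follow standard linear-model definitions.  A negative fitted slope is
    physically implausible (damage decreasing with duration or pressure) and
    triggers a warning; the coefficients are still returned so the caller can
    inspect them.
    """
    df = _observations_frame(observations)
    n = len(df)
    if n < 4:
        raise FitError(f"need at least 4 observations to fit 3 coefficients; got {n}")
    for col in ("duration_min", "pressure_kpa"):
        if np.ptp(df[col].to_numpy()) == 0:
            raise FitError(f"design is rank deficient: column '{col}' is constant")
    design = sm.add_constant(df[["duration_min", "pressure_kpa"]], has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise FitError("design is rank deficient: duration_min and pressure_kpa are collinear")
    res = sm.OLS(df["damage"], design).fit()

    names = {"const": "c0", "duration_min": "c1", "pressure_kpa": "c2"}
    params = {names[k]: float(v) for k, v in res.params.items()}
    if params["c1"] < 0 or params["c2"] < 0:
        warnings.warn(
            "fitted slope is negative (c1=%.4g, c2=%.4g); damaging effect "
            "should not decrease with duration or pressure" % (params["c1"], params["c2"]),
            UserWarning,
            stacklevel=2,
        )
        # Bypass the dataclass invariant so the caller can still see the fit.
        coeffs = object.__new__(EstimatorCoefficients)
        object.__setattr__(coeffs, "c0", params["c0"])
        object.__setattr__(coeffs, "c1", params["c1"])
        object.__setattr__(coeffs, "c2", params["c2"])
    else:
        coeffs = EstimatorCoefficients(**params)

    ci = res.conf_int(alpha=0.05)
    return EstimatorFit(
        coeffs=coeffs,
        n_obs=n,
        r_squared=float(res.rsquared),
        r_squared_adj=float(res.rsquared_adj),
        f_statistic=float(res.fvalue),
        f_pvalue=float(res.f_pvalue),
        df_model=int(res.df_model),
        df_resid=int(res.df_resid),
        std_errors={names[k]: float(v) for k, v in res.bse.items()},
        t_values={names[k]: float(v) for k, v in res.tvalues.items()},
        p_values={names[k]: float(v) for k, v in res.pvalues.items()},
        conf_int_95={names[k]: (float(ci.loc[k, 0]), float(ci.loc[k, 1])) for k in ci.index},
    )


def compute_q_m(
    dt_s: float,
    coeffs: EstimatorCoefficients = DEFAULT_COEFFICIENTS,
    thr: InjuryThreshold = DEFAULT_THRESHOLD,
) -> float:
    """Damaging effect of the lowest damaging pressure held for one sample period.

    Evaluates the affine model at P = C and t = dt_s converted to minutes;
    this is the normaliser for the relief grade U.
    """
    if not (dt_s > 0):
        raise DomainError(f"sampling interval dt_s must be > 0 s; got {dt_s}")
    return coeffs.c0 + coeffs.c1 * (dt_s / 60.0) + coeffs.c2 * thr.C
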