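"""CSV input/output for pressure time series and monitor traces.

Interchange format is plain CSV: time series carry ``time_s`` and
``pressure_kpa`` columns (optionally ``channel``); traces carry the column
contract in :data:`ulcerguard.monitor.TRACE_COLUMNS`.  Floats are written
with 10 significant digits so a written trace can be re-analysed without
meaningful loss.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["read_timeseries", "write_timeseries", "write_trace"]

_FLOAT_FORMAT = "%.10g"
# Relative tolerance on sample spacing uniformity.
_SPACING_RTOL = 1e-6


def read_timeseries(path, channel=None) -> pd.DataFrame:
    """Read a pressure time series CSV and validate its contract.

    Requires ``time_s`` and ``pressure_kpa`` header columns; rows must be
    finite, pressures >= 0, times strictly increasing and uniformly spaced
    (relative tolerance 1e-6).  If ``channel`` is given, rows are filtered on
    the ``channel`` column first.  The inferred sampling interval is attached
    as ``df.attrs['dt_s']`` (None when fewer than 2 rows).

    Row numbers in error messages count physical file lines (header = 1).
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, ValueError) as exc:
        raise DataError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in ("time_s", "pressure_kpa") if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required column(s): {', '.join(missing)}")
    # Physical file line of each data row, before any filtering.
    df = df.assign(_line=np.arange(2, len(df) + 2))
    if channel is not None:
        if "channel" not in df.columns:
            raise DataError(f"{path}: channel {channel!r} requested but no 'channel' column")
        df = df[df["channel"] == channel]

    for col in ("time_s", "pressure_kpa"):
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        bad = np.nonzero(~np.isfinite(vals))[0]
        if bad.size:
            raise DataError(
                f"{path}: non-finite {col} value at row {int(df['_line'].iloc[bad[0]])}"
            )
        df[col] = vals
    neg = np.nonzero(df["pressure_kpa"].to_numpy() < 0)[0]
    if neg.size:
        raise DataError(
            f"{path}: negative pressure at row {int(df['_line'].iloc[neg[0]])}"
        )

    times = df["time_s"].to_numpy()
    dt = None
    if len(times) > 1:
        diffs = np.diff(times)
        nonpos = np.nonzero(diffs <= 0)[0]
        if nonpos.size:
            raise DataError(
                f"{path}: time_s not strictly increasing at row "
                f"{int(df['_line'].iloc[nonpos[0] + 1])}"
            )
        dt = float(np.median(diffs))
        bad = np.nonzero(np.abs(diffs - dt) > _SPACING_RTOL * dt)[0]
        if bad.size:
            raise DataError(
                f"{path}: non-uniform sample spacing at row "
                f"{int(df['_line'].iloc[bad[0] + 1])} "
                f"(interval {diffs[bad[0]]:.9g} s, expected {dt:.9g} s)"
            )
    out = df.drop(columns="_line").reset_index(drop=True)
    out.attrs["dt_s"] = dt
    return out


def write_timeseries(df: pd.DataFrame, path) -> None:
    """Write a ``time_s``/``pressure_kpa`` frame as CSV."""
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def write_trace(trace: pd.DataFrame, path) -> None:
    """Write a monitor trace as CSV (header always present, 10 sig. digits)."""
    trace.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
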