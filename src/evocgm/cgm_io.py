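"""Reading, validation and regularisation of CGM traces.

CGM exports are handled in a minimal 3-column CSV dialect
(``index,timestamp,value``): a sequential integer index, a timestamp at a
nominal 5-minute cadence, and the glucose reading in mmol/L printed to one
decimal place.  Real device exports carry two artifacts this module deals
with explicitly:

* **interval jitter** -- a large share of consecutive readings arrive at
  4 min 59 s or 5 min 1 s instead of exactly 5 min (a device artifact, not
  a data problem);
* **missing runs** -- dropouts of one or more consecutive readings, which
  are either repaired by time-linear interpolation (short gaps) or left as
  segment boundaries (long gaps) so that no forecasting window ever spans
  a multi-hour hole.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Default cadence of the sensor, seconds.
DEFAULT_INTERVAL_S = 300.0
#: Default tolerance for the device's +-1 s interval artifact, seconds.
DEFAULT_JITTER_TOL_S = 2.0
#: Default plausibility bounds for a CGM reading, mmol/L (typical device
#: reporting range).
DEFAULT_BOUNDS = (2.0, 22.2)
#: Default maximum total gap span repaired by interpolation, seconds.
DEFAULT_MAX_GAP_S = 3600.0

#: Accepted timestamp dialects.  "iso" is the native dialect; "dmy" covers
#: exports that print "DD/MM/YYYY HH:MM:SS".
TIMESTAMP_DIALECTS = ("iso", "dmy")
_DMY_FORMAT = "%d/%m/%Y %H:%M:%S"


class CGMError(ValueError):
    """Base class for CGM input/validation errors."""


class EmptyInputError(CGMError):
    """The file or series contains no readings."""


class CGMParseError(CGMError):
    """A timestamp or glucose value could not be parsed."""


class MonotonicityError(CGMError):
    """Timestamps are not strictly increasing."""


class BoundsError(CGMError):
    """A glucose value lies outside the plausibility bounds."""


@dataclass(frozen=True)
class CGMSeries:
    """A timestamped glucose trace in mmol/L.

    Parameters
    ----------
    timestamps
        Reading instants, strictly increasing (``DatetimeIndex``).
    values
        Glucose readings in mmol/L, one per timestamp.
    nominal_interval
        Nominal sensor cadence in seconds (default 300).
    """

    timestamps: pd.DatetimeIndex
    values: np.ndarray
    nominal_interval: float = DEFAULT_INTERVAL_S

    def __post_init__(self) -> None:
        ts = pd.DatetimeIndex(self.timestamps)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "values", vals)
        if len(ts) != len(vals):
            raise CGMError(
                f"{len(ts)} timestamps but {len(vals)} values"
            )
        if len(ts) == 0:
            raise EmptyInputError("series contains no readings")
        if len(ts) > 1 and not (np.diff(ts.asi8) > 0).all():
            raise MonotonicityError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def seconds(self) -> np.ndarray:
        """Timestamps as float seconds since the first reading."""
        return (self.timestamps.asi8 - self.timestamps.asi8[0]) / 1e9

    def steps(self) -> np.ndarray:
        """Consecutive inter-reading intervals in seconds."""
        return np.diff(self.timestamps.asi8) / 1e9

    def check_bounds(self, bounds: tuple[float, float] = DEFAULT_BOUNDS) -> None:
        lo, hi = bounds
        bad = (self.values < lo) | (self.values > hi)
        if bad.any():
            i = int(np.argmax(bad))
            raise BoundsError(
                f"value {self.values[i]} mmol/L at row {i} outside [{lo}, {hi}]"
            )


@dataclass(frozen=True)
class Segment:
    """A half-open run ``[start, end)`` of contiguous readings.

    Within a segment every inter-reading step agrees with the nominal
    interval up to the jitter tolerance, so sliding windows may be drawn
    freely inside it.
    """

    start: int
    end: int
    origin: CGMSeries = field(repr=False, compare=False)

    def __len__(self) -> int:
        return self.end - self.start


def _parse_timestamps(raw: pd.Series, dialect: str) -> pd.DatetimeIndex:
    if dialect not in TIMESTAMP_DIALECTS:
        raise CGMParseError(f"unknown timestamp dialect {dialect!r}")
    fmt = "ISO8601" if dialect == "iso" else _DMY_FORMAT
    try:
        return pd.DatetimeIndex(pd.to_datetime(raw, format=fmt))
    except (ValueError, TypeError) as exc:
        raise CGMParseError(f"unparseable timestamp: {exc}") from None


def read_cgm_csv(
    path,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    nominal_interval: float = DEFAULT_INTERVAL_S,
    timestamp_dialect: str = "iso",
) -> CGMSeries:
    """Read a 3-column ``index,timestamp,value`` CSV into a :class:`CGMSeries`.

    A single header line is auto-detected (the third field of the first row
    fails to parse as a number).  The index column is only used for a
    monotonicity sanity check and then discarded.
    """
    try:
        df = pd.read_csv(path, header=None, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"empty CGM file: {path}") from None
    if df.shape[1] != 3:
        raise CGMParseError(
            f"expected 3 columns (index, timestamp, value), got {df.shape[1]}"
        )
    # Header auto-detection: a header row has a non-numeric value field AND a
    # non-parseable timestamp field (a bad value next to a valid timestamp is
    # a data error, not a header).
    def _is_header(row) -> bool:
        try:
            float(row.iloc[2])
            return False
        except (TypeError, ValueError):
            pass
        try:
            _parse_timestamps(pd.Series([row.iloc[1]]), timestamp_dialect)
            return False
        except CGMParseError:
            return True

    if _is_header(df.iloc[0]):
        df = df.iloc[1:].reset_index(drop=True)
    if len(df) == 0:
        raise EmptyInputError(f"CGM file has a header but no rows: {path}")

    ts = _parse_timestamps(df.iloc[:, 1], timestamp_dialect)
    try:
        values = df.iloc[:, 2].astype(float).to_numpy()
    except ValueError as exc:
        raise CGMParseError(f"unparseable glucose value: {exc}") from None
    if not np.isfinite(values).all():
        raise CGMParseError("non-finite glucose value in file")

    series = CGMSeries(ts, values, nominal_interval=nominal_interval)
    series.check_bounds(bounds)
    return series


def write_cgm_csv(series: CGMSeries, path, header: bool = False) -> None:
    """Write a series in the 3-column dialect, values at exactly 1 dp."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header:
            fh.write("index,timestamp,glucose_mmol_l\n")
        for i, (ts, v) in enumerate(zip(series.timestamps, series.values)):
            fh.write(f"{i},{ts.isoformat()},{v:.1f}\n")


def interpolate_gaps(
    series: CGMSeries,
    max_gap: float = DEFAULT_MAX_GAP_S,
    jitter_tol: float = DEFAULT_JITTER_TOL_S,
) -> CGMSeries:
    """Fill short missing runs by time-linear interpolation.

    A gap is any inter-reading span exceeding ``nominal_interval +
    jitter_tol``.  Gaps whose total span is at most ``max_gap`` (seconds)
    are filled at nominal-interval grid points measured from the reading
    before the gap; the interpolated values are rounded to 1 dp to match
    the source precision.  Longer gaps are left untouched (they become
    segment boundaries).  Gapless input is returned unchanged.
    """
    if max_gap < series.nominal_interval:
        raise CGMError("max_gap must be at least the nominal interval")
    steps = series.steps()
    gap_at = np.flatnonzero(steps > series.nominal_interval + jitter_tol)
    fillable = [i for i in gap_at if steps[i] <= max_gap + jitter_tol]
    if not fillable:
        return series

    sec = series.seconds
    new_ts: list = []
    new_vals: list = []
    fill_set = set(fillable)
    for i in range(len(series)):
        new_ts.append(series.timestamps[i])
        new_vals.append(series.values[i])
        if i in fill_set:
            span = steps[i]
            n_missing = int(round(span / series.nominal_interval)) - 1
            for k in range(1, n_missing + 1):
                t = series.timestamps[i] + pd.Timedelta(
                    seconds=k * series.nominal_interval
                )
                v = float(
                    np.interp(
                        sec[i] + k * series.nominal_interval,
                        [sec[i], sec[i + 1]],
                        [series.values[i], series.values[i + 1]],
                    )
                )
                new_ts.append(t)
                new_vals.append(round(v, 1))
    return replace(
        series,
        timestamps=pd.DatetimeIndex(new_ts),
        values=np.asarray(new_vals, dtype=float),
    )


def segment_contiguous(
    series: CGMSeries, jitter_tol: float = DEFAULT_JITTER_TOL_S
) -> list[Segment]:
    """Partition a series into maximal runs of near-nominal sampling.

    A break is placed wherever a step deviates from the nominal interval
    by more than ``jitter_tol`` seconds.  The returned segments are
    ordered, disjoint, and jointly cover every reading.
    """
    steps = series.steps()
    breaks = np.flatnonzero(np.abs(steps - series.nominal_interval) > jitter_tol)
    starts = [0] + [int(b) + 1 for b in breaks]
    ends = [int(b) + 1 for b in breaks] + [len(series)]
    return [Segment(s, e, series) for s, e in zip(starts, ends)]
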