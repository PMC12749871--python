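"""Sliding-window supervised dataset construction and chronological splits.

The one-step forecasting problem is framed as supervised regression: each
input row is the ``w`` consecutive glucose readings immediately preceding
a target reading, and the target is the next (5-minutes-ahead) value.
Windows never cross an unfilled gap or trace boundary — a forecast across
a multi-hour hole would be meaningless — so rows are drawn per contiguous
segment.  Splitting is chronological (train, then validation, then test
blocks) to avoid look-ahead leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cgm_io import (
    CGMSeries,
    Segment,
    DEFAULT_JITTER_TOL_S,
    segment_contiguous,
)

#: Inclusive window-size range explored by the sweep.
DEFAULT_WINDOW_RANGE = (3, 10)


class WindowingError(ValueError):
    """Base class for windowing errors."""


class WindowSizeError(WindowingError):
    """Requested window size outside the configured range."""


class EmptyDatasetError(WindowingError):
    """No segment is long enough to produce a single input/target pair."""


class SplitError(WindowingError):
    """Invalid split fractions or an empty split."""


@dataclass(frozen=True)
class WindowDataset:
    """Lagged-input rows paired with one-step-ahead targets.

    ``inputs[i]`` holds the ``window_size`` readings (mmol/L) immediately
    preceding ``targets[i]`` within one contiguous segment; rows are in
    chronological order.
    """

    inputs: np.ndarray  # [N, w]
    targets: np.ndarray  # [N]
    window_size: int
    source_segments: tuple = field(default=(), compare=False)

    def __post_init__(self) -> None:
        inputs = np.asarray(self.inputs, dtype=float)
        targets = np.asarray(self.targets, dtype=float)
        object.__setattr__(self, "inputs", inputs)
        object.__setattr__(self, "targets", targets)
        if inputs.ndim != 2 or targets.ndim != 1:
            raise WindowingError("inputs must be 2-D and targets 1-D")
        if inputs.shape[0] != targets.shape[0]:
            raise WindowingError("inputs and targets disagree on N")
        if inputs.shape[1] != self.window_size:
            raise WindowingError(
                f"inputs have width {inputs.shape[1]}, "
                f"window_size is {self.window_size}"
            )

    def __len__(self) -> int:
        return len(self.targets)


@dataclass(frozen=True)
class SplitSpec:
    """Chronological train/validation/test fractions (must sum to 1)."""

    train_fraction: float = 0.70
    val_fraction: float = 0.15
    test_fraction: float = 0.15

    def validate(self) -> None:
        fracs = (self.train_fraction, self.val_fraction, self.test_fraction)
        if any(f <= 0 for f in fracs):
            raise SplitError(f"all split fractions must be positive: {fracs}")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise SplitError(f"split fractions must sum to 1: {fracs}")


def make_windows(
    series: CGMSeries,
    w: int,
    segments: list[Segment] | None = None,
    window_range: tuple[int, int] = DEFAULT_WINDOW_RANGE,
    jitter_tol: float = DEFAULT_JITTER_TOL_S,
) -> WindowDataset:
    """Build the supervised dataset for window size ``w``.

    Each contiguous segment of length ``L`` contributes ``max(L - w, 0)``
    chronologically ordered pairs.  Raises :class:`EmptyDatasetError`
    when no segment is long enough.
    """
    lo, hi = window_range
    if not lo <= w <= hi:
        raise WindowSizeError(f"window size {w} outside [{lo}, {hi}]")
    if segments is None:
        segments = segment_contiguous(series, jitter_tol=jitter_tol)

    rows: list[np.ndarray] = []
    targets: list[float] = []
    used: list[Segment] = []
    for seg in segments:
        vals = series.values[seg.start : seg.end]
        if len(vals) <= w:
            continue
        # Vectorised sliding windows over this segment.
        windows = np.lib.stride_tricks.sliding_window_view(vals[:-1], w)
        rows.append(windows)
        targets.append(vals[w:])
        used.append(seg)
    if not rows:
        raise EmptyDatasetError(
            f"no segment longer than window size {w}; cannot build dataset"
        )
    return WindowDataset(
        inputs=np.vstack(rows),
        targets=np.concatenate(targets),
        window_size=w,
        source_segments=tuple(used),
    )


def split_chronological(
    ds: WindowDataset, spec: SplitSpec = SplitSpec()
) -> tuple[WindowDataset, WindowDataset, WindowDataset]:
    """Split into contiguous chronological train/validation/test blocks.

    Block sizes are ``floor(N * fraction)`` with the remainder assigned to
    the training block.  Raises :class:`SplitError` if any block would be
    empty.
    """
    spec.validate()
    n = len(ds)
    n_val = int(n * spec.val_fraction)
    n_test = int(n * spec.test_fraction)
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise SplitError(
            f"dataset of {n} pairs too small for split {spec}"
        )

    def block(a: int, b: int) -> WindowDataset:
        return WindowDataset(
            inputs=ds.inputs[a:b],
            targets=ds.targets[a:b],
            window_size=ds.window_size,
            source_segments=ds.source_segments,
        )

    return (
        block(0, n_train),
        block(n_train, n_train + n_val),
        block(n_train + n_val, n),
    )


def standardize_splits(
    train: WindowDataset, val: WindowDataset, test: WindowDataset
) -> tuple[WindowDataset, WindowDataset, WindowDataset, tuple[float, float]]:
    """Optionally z-score inputs and targets using train-set statistics only.

    Off by default throughout the pipeline (raw mmol/L units keep MSEs
    directly interpretable); provided for experimentation.
    """
    mu = float(train.inputs.mean())
    sd = float(train.inputs.std())
    if sd == 0:
        raise WindowingError("cannot standardize a constant training set")

    def scale(ds: WindowDataset) -> WindowDataset:
        return WindowDataset(
            inputs=(ds.inputs - mu) / sd,
            targets=(ds.targets - mu) / sd,
            window_size=ds.window_size,
            source_segments=ds.source_segments,
        )

    return scale(train), scale(val), scale(test), (mu, sd)


def windows_to_csv(ds: WindowDataset, path) -> None:
    """Dump a dataset as CSV (``w`` input columns then the target)."""
    header = ",".join(f"x{i}" for i in range(ds.window_size)) + ",target"
    data = np.column_stack([ds.inputs, ds.targets])
    np.savetxt(path, data, fmt="%.1f", delimiter=",", header=header, comments="")
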