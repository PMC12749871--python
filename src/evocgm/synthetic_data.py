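"""Synthetic CGM trace generator.

Produces glucose traces with the statistical texture of real sensor data
so the whole forecasting pipeline is testable without clinical data: a
baseline level, a slow circadian oscillation, additive meal responses
(linear rise, exponential decay), AR(1) sensor/physiology noise, and —
injected separately — the two artifacts real exports show: clustered
missing runs and a +-1 s interval jitter affecting a configurable
fraction of steps.

The generator makes no attempt at physiological insulin–glucose kinetics;
it only needs CGM-*like* statistics (scale, smoothness, one-step
differences of a few tenths of a mmol/L) for the forecasting task.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd

from .cgm_io import CGMSeries, DEFAULT_BOUNDS, DEFAULT_INTERVAL_S


@dataclass(frozen=True)
class SimParams:
    """Parameters of the synthetic CGM generator.

    Defaults emulate a roughly two-week wear of a 5-minute sensor on a
    person with three daily meals: baseline 6 mmol/L, circadian swing
    0.8 mmol/L, meal bumps of 3 mmol/L rising over 30 min and decaying
    with a 90 min time constant, and AR(1) noise (coefficient 0.85,
    innovation sd 0.15 mmol/L) giving one-step differences of a few
    tenths of a mmol/L.
    """

    duration_days: float = 13.8
    interval: float = DEFAULT_INTERVAL_S
    baseline: float = 6.0
    circadian_amplitude: float = 0.8
    meal_times: tuple[float, ...] = (8.0, 13.0, 19.0)  # clock hours
    meal_amplitude: float = 3.0
    meal_rise_min: float = 30.0
    meal_decay_min: float = 90.0
    ar_coefficient: float = 0.85
    noise_sd: float = 0.15
    missing_rate: float = 0.02
    jitter_fraction: float = 0.41
    seed: int = 0
    bounds: tuple[float, float] = DEFAULT_BOUNDS
    start: str = "2023-01-01T00:00:00"

    def validate(self) -> None:
        if self.duration_days <= 0 or self.interval <= 0:
            raise ValueError("duration_days and interval must be positive")
        for name in ("circadian_amplitude", "meal_amplitude", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.jitter_fraction <= 1.0:
            raise ValueError("jitter_fraction must lie in [0, 1]")
        if self.meal_rise_min <= 0 or self.meal_decay_min <= 0:
            raise ValueError("meal rise/decay durations must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["meal_times"] = list(self.meal_times)
        d["bounds"] = list(self.bounds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        d = dict(d)
        if "meal_times" in d:
            d["meal_times"] = tuple(d["meal_times"])
        if "bounds" in d:
            d["bounds"] = tuple(d["bounds"])
        return cls(**d)


def _meal_response(hours_since_meal: np.ndarray, p: SimParams) -> np.ndarray:
    """Bump shape: linear rise to the peak, then exponential decay."""
    rise_h = p.meal_rise_min / 60.0
    decay_h = p.meal_decay_min / 60.0
    t = hours_since_meal
    out = np.zeros_like(t)
    rising = (t >= 0) & (t < rise_h)
    out[rising] = p.meal_amplitude * t[rising] / rise_h
    decaying = t >= rise_h
    out[decaying] = p.meal_amplitude * np.exp(-(t[decaying] - rise_h) / decay_h)
    return out


def generate_cgm(params: SimParams) -> CGMSeries:
    """Generate a clean (gapless, unjittered) synthetic trace.

    The trace is baseline + circadian sinusoid + meal bumps + AR(1)
    noise, clipped to the plausibility bounds and rounded to 1 dp.
    Deterministic for a given seed.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_days * 86400.0 / params.interval))
    if n < 1:
        raise ValueError("duration too short for one reading")
    t_s = np.arange(n) * params.interval
    hours = t_s / 3600.0

    # Circadian term with its trough in the early hours (~4 am).
    clean = params.baseline + params.circadian_amplitude * np.sin(
        2.0 * np.pi * (hours - 10.0) / 24.0
    )

    clock = hours % 24.0
    day = np.floor(hours / 24.0)
    for meal_h in params.meal_times:
        # Same-day response plus the tail of yesterday's meal.
        clean += _meal_response(clock - meal_h, params)
        clean += _meal_response(clock + 24.0 - meal_h, params) * (day > 0)

    # AR(1) noise started from its stationary distribution.
    noise = np.empty(n)
    stat_sd = params.noise_sd / np.sqrt(1.0 - params.ar_coefficient**2) \
        if params.ar_coefficient > 0 else params.noise_sd
    noise[0] = rng.normal(0.0, stat_sd)
    innov = rng.normal(0.0, params.noise_sd, size=n - 1)
    for i in range(1, n):
        noise[i] = params.ar_coefficient * noise[i - 1] + innov[i - 1]

    values = np.clip(clean + noise, *params.bounds).round(1)
    start = pd.Timestamp(params.start)
    ts = pd.DatetimeIndex(
        [start + pd.Timedelta(seconds=float(s)) for s in t_s]
    )
    return CGMSeries(ts, values, nominal_interval=params.interval)


def inject_artifacts(
    series: CGMSeries,
    missing_rate: float,
    jitter_fraction: float,
    seed: int,
    mean_run_length: float = 3.0,
) -> CGMSeries:
    """Add the two artifacts of real exports: missing runs and step jitter.

    Missing readings are deleted in geometric-length runs (mean
    ``mean_run_length``; dropouts cluster on real devices) such that the
    expected deleted fraction is ``missing_rate``.  Independently, a
    ``jitter_fraction`` share of the surviving inter-reading steps is made
    one second short or long of nominal by nudging timestamps by +-1 s
    (offsets stay within +-1 s of the grid, so monotonicity is
    preserved).  Deterministic for a given seed.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")
    if not 0.0 <= jitter_fraction <= 1.0:
        raise ValueError("jitter_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(series)

    keep = np.ones(n, dtype=bool)
    if missing_rate > 0:
        p_start = missing_rate / mean_run_length
        i = 0
        while i < n:
            if keep[i] and rng.random() < p_start:
                run = rng.geometric(1.0 / mean_run_length)
                keep[i : i + run] = False
                i += run
            else:
                i += 1
        if not keep.any():  # pathological tiny series: keep first reading
            keep[0] = True

    ts = series.timestamps[keep]
    vals = series.values[keep]

    if jitter_fraction > 0 and len(ts) > 1:
        # Per-timestamp offsets in {-1, 0, +1} s chosen so that exactly the
        # Bernoulli(jitter_fraction)-selected steps deviate from nominal by
        # 1 s, reproducing the 4:59 / 5:01 device artifact.
        offsets = np.zeros(len(ts), dtype=np.int64)
        for k in range(len(ts) - 1):
            if rng.random() < jitter_fraction:
                if offsets[k] == 0:
                    offsets[k + 1] = rng.choice([-1, 1])
                else:
                    offsets[k + 1] = 0
            else:
                offsets[k + 1] = offsets[k]
        ts = ts + pd.to_timedelta(offsets, unit="s")

    return replace(series, timestamps=pd.DatetimeIndex(ts), values=vals)


def simulate(params: SimParams) -> CGMSeries:
    """Generate a trace and inject the configured artifacts."""
    clean = generate_cgm(params)
    return inject_artifacts(
        clean,
        params.missing_rate,
        params.jitter_fraction,
        seed=params.seed + 1,
    )
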