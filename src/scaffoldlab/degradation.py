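"""Descriptive analysis of polymer-degradation time series.

Hydrolysing poly(DL-lactide) releases lactic acid, so pH of the surrounding
water falls and ionic strength — measured as electrical conductivity —
rises; a calcium-phosphate core buffers both.  The study design reports the
measured curves without fitting a kinetic model, and this module follows
suit: it loads, summarizes, and compares trajectories (initial/final
levels, total change, maximum finite-difference rate, threshold-crossing
times by linear interpolation).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

__all__ = [
    "DegradationSeries",
    "SeriesSummary",
    "series_summary",
    "time_to_threshold",
    "compare_series",
    "read_degradation_csv",
    "write_degradation_csv",
]


@dataclass(frozen=True)
class DegradationSeries:
    """Timestamped pH and conductivity for one sample group."""

    label: str
    times: np.ndarray  # days, strictly increasing
    ph: np.ndarray
    conductivity: np.ndarray  # µS/cm
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        ph = np.asarray(self.ph, dtype=float)
        cond = np.asarray(self.conductivity, dtype=float)
        if not (times.size == ph.size == cond.size):
            raise ValueError("times, ph and conductivity must have equal lengths")
        if times.size < 1:
            raise ValueError("series must be non-empty")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(ph < 0) or np.any(ph > 14):
            raise ValueError("pH values must lie in [0, 14]")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "ph", ph)
        object.__setattr__(self, "conductivity", cond)

    def channel(self, name: str) -> np.ndarray:
        if name == "ph":
            return self.ph
        if name == "conductivity":
            return self.conductivity
        raise ValueError(f"unknown channel {name!r}; expected 'ph' or 'conductivity'")


@dataclass(frozen=True)
class SeriesSummary:
    label: str
    n: int
    initial_ph: float
    final_ph: float
    delta_ph: float
    max_rate_ph: float  # max |ΔpH/Δt|, per day
    initial_conductivity: float
    final_conductivity: float
    delta_conductivity: float
    max_rate_conductivity: float  # max |Δcond/Δt|, µS/cm per day


def series_summary(series: DegradationSeries) -> SeriesSummary:
    """Initial/final levels, total change, and max per-interval rate per channel."""
    if series.times.size < 2:
        raise ValueError("series summary needs >= 2 time points")
    dt = np.diff(series.times)

    def stats(v: np.ndarray) -> tuple[float, float, float, float]:
        rates = np.abs(np.diff(v) / dt)
        return float(v[0]), float(v[-1]), float(v[-1] - v[0]), float(np.max(rates))

    ph0, ph1, dph, rph = stats(series.ph)
    c0, c1, dc, rc = stats(series.conductivity)
    return SeriesSummary(
        label=series.label, n=int(series.times.size),
        initial_ph=ph0, final_ph=ph1, delta_ph=dph, max_rate_ph=rph,
        initial_conductivity=c0, final_conductivity=c1,
        delta_conductivity=dc, max_rate_conductivity=rc,
    )


def time_to_threshold(
    series: DegradationSeries,
    channel: str,
    threshold: float,
    direction: str = "auto",
) -> Optional[float]:
    """First time (days) the channel crosses the threshold, or ``None``.

    ``direction='auto'`` expects a downward crossing for pH (acidification)
    and an upward crossing for conductivity (ion release); 'below'/'above'
    override.  Crossing times are linearly interpolated between the
    bracketing samples; a series already past the threshold returns 0.
    """
    v = series.channel(channel)
    if direction == "auto":
        direction = "below" if channel == "ph" else "above"
    if direction not in ("below", "above"):
        raise ValueError(f"direction must be 'auto', 'below' or 'above', got {direction!r}")
    crossed = v <= threshold if direction == "below" else v >= threshold
    if crossed[0]:
        return 0.0
    idx = np.flatnonzero(crossed)
    if idx.size == 0:
        return None
    i = int(idx[0])
    t0, t1 = series.times[i - 1], series.times[i]
    v0, v1 = v[i - 1], v[i]
    if v1 == v0:
        return float(t1)
    return float(t0 + (threshold - v0) * (t1 - t0) / (v1 - v0))


@dataclass(frozen=True)
class SeriesComparison:
    label_a: str
    label_b: str
    times: np.ndarray  # intersection grid, days
    ph_difference: np.ndarray  # a - b
    conductivity_difference: np.ndarray  # a - b
    delta_ph_difference: float
    delta_conductivity_difference: float


def compare_series(a: DegradationSeries, b: DegradationSeries) -> SeriesComparison:
    """Pointwise (a − b) differences on the time-range intersection.

    The grid is the union of both sampling times restricted to the
    overlapping range; each series is linearly interpolated onto it.
    Antisymmetric: ``compare(a, b)`` differences are the negation of
    ``compare(b, a)``.
    """
    lo = max(a.times[0], b.times[0])
    hi = min(a.times[-1], b.times[-1])
    if lo > hi:
        raise ValueError("series time ranges do not overlap")
    grid = np.union1d(a.times, b.times)
    grid = grid[(grid >= lo) & (grid <= hi)]
    ph_a = np.interp(grid, a.times, a.ph)
    ph_b = np.interp(grid, b.times, b.ph)
    c_a = np.interp(grid, a.times, a.conductivity)
    c_b = np.interp(grid, b.times, b.conductivity)
    sa, sb = series_summary(a), series_summary(b)
    return SeriesComparison(
        label_a=a.label, label_b=b.label, times=grid,
        ph_difference=ph_a - ph_b, conductivity_difference=c_a - c_b,
        delta_ph_difference=sa.delta_ph - sb.delta_ph,
        delta_conductivity_difference=sa.delta_conductivity - sb.delta_conductivity,
    )


def read_degradation_csv(path: Union[str, Path], label: str = "") -> DegradationSeries:
    """Read ``time_days,ph,conductivity_uScm`` CSV for one sample group."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        need = {"time_days", "ph", "conductivity_uScm"}
        if set(reader.fieldnames or []) < need:
            raise ValueError(f"degradation CSV must have columns {sorted(need)}")
        rows = [
            (float(r["time_days"]), float(r["ph"]), float(r["conductivity_uScm"]))
            for r in reader
        ]
    if not rows:
        raise ValueError(f"{path}: empty series")
    arr = np.asarray(rows, dtype=float)
    return DegradationSeries(
        label=label or str(path), times=arr[:, 0], ph=arr[:, 1], conductivity=arr[:, 2]
    )


def write_degradation_csv(series: DegradationSeries, path: Union[str, Path]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_days", "ph", "conductivity_uScm"])
        for t, p, c in zip(series.times, series.ph, series.conductivity):
            writer.writerow([f"{t:.8g}", f"{p:.8g}", f"{c:.8g}"])
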