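"""Uniformly sampled scalar time series: container, I/O and preprocessing.

All downstream analysis (avalanche segmentation, delay embedding, the
marginal-stability simulators) operates on :class:`UniformSeries`, a thin
immutable wrapper around a float array with a start time and a fixed
sampling interval ``dt``.  Files are 2-column delimited text with a header
(``time,value`` by default); the time column must be strictly increasing
and uniformly spaced.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "UniformSeries",
    "read_series",
    "write_series",
    "linear_detrend",
    "normalize_by_mean",
]

#: relative tolerance for deciding whether time stamps are uniformly spaced
_SPACING_RTOL = 1e-6


@dataclass(frozen=True)
class UniformSeries:
    """A uniformly sampled scalar time series.

    Parameters
    ----------
    t0 : float
        Time of the first sample (arbitrary units).
    dt : float
        Sampling interval, strictly positive.
    values : numpy.ndarray
        Amplitude samples, all finite, length >= 2.
    label : str
        Free-text description (species name, simulation parameters, ...).
    """

    t0: float
    dt: float
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if not np.isfinite(self.dt) or self.dt <= 0:
            raise ValueError(f"dt must be finite and > 0, got {self.dt}")
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError("values must be a 1-d array with length >= 2")
        if not np.all(np.isfinite(vals)):
            bad = int(np.flatnonzero(~np.isfinite(vals))[0])
            raise ValueError(f"non-finite value at index {bad}")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Time stamps ``t0 + i*dt`` for every sample."""
        return self.t0 + self.dt * np.arange(self.values.size)

    def with_values(self, values: np.ndarray, label: str | None = None) -> "UniformSeries":
        """Copy of this series with new amplitude samples on the same time grid."""
        return replace(self, values=np.asarray(values, dtype=float),
                       label=self.label if label is None else label)

    def slice(self, start: int, stop: int) -> "UniformSeries":
        """Contiguous sub-series ``[start:stop)`` (at least 2 samples)."""
        if stop - start < 2:
            raise ValueError("slice must keep at least 2 samples")
        return UniformSeries(t0=self.t0 + start * self.dt, dt=self.dt,
                             values=self.values[start:stop], label=self.label)


def read_series(path, time_col: str = "time", value_col: str = "value") -> UniformSeries:
    """Read a uniformly sampled series from delimited text with a header.

    The time column is optional: if ``time_col`` is absent from the file,
    rows are indexed 0, 1, 2, ... with ``dt = 1`` (simulation output is in
    plain time steps).  Time stamps must be strictly increasing and evenly
    spaced within a relative tolerance of 1e-6.

    Raises
    ------
    ValueError
        On fewer than 2 rows, missing or non-numeric values (the error
        names the first offending row), or non-uniform spacing (the error
        names the first offending row).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if value_col not in df.columns:
        raise ValueError(f"column {value_col!r} not found in {path}")
    if len(df) < 2:
        raise ValueError(f"{path}: need at least 2 rows, got {len(df)}")

    values = pd.to_numeric(df[value_col], errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size:
        # +2: one for the header line, one for 1-based numbering
        raise ValueError(
            f"{path}: missing or non-numeric value in column {value_col!r} "
            f"at row {int(bad[0]) + 2}")

    if time_col in df.columns:
        times = pd.to_numeric(df[time_col], errors="coerce").to_numpy(dtype=float)
        badt = np.flatnonzero(~np.isfinite(times))
        if badt.size:
            raise ValueError(
                f"{path}: missing or non-numeric value in column {time_col!r} "
                f"at row {int(badt[0]) + 2}")
        steps = np.diff(times)
        if np.any(steps <= 0):
            row = int(np.flatnonzero(steps <= 0)[0]) + 2
            raise ValueError(f"{path}: time column not strictly increasing at row {row + 1}")
        dt = float(np.median(steps))
        off = np.abs(steps - dt) > _SPACING_RTOL * max(abs(dt), 1e-300)
        if np.any(off):
            row = int(np.flatnonzero(off)[0]) + 2
            raise ValueError(
                f"{path}: non-uniform time spacing at row {row + 1} "
                f"(step {steps[np.flatnonzero(off)[0]]:g}, expected {dt:g})")
        t0 = float(times[0])
    else:
        t0, dt = 0.0, 1.0

    return UniformSeries(t0=t0, dt=dt, values=values, label=str(path))


def write_series(series: UniformSeries, path, time_col: str = "time",
                 value_col: str = "value") -> None:
    """Write a series as CSV with header, 17 significant digits (round-trip safe)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{time_col},{value_col}\n")
        t = series.times
        for ti, vi in zip(t, series.values):
            fh.write(f"{ti:.17g},{vi:.17g}\n")


def linear_detrend(series: UniformSeries) -> UniformSeries:
    """Residuals after an ordinary least-squares line fit against time.

    Removes slow secular drift (e.g. long-term shifts in productivity)
    so that segmentation sees only the stochastic excursions.  Residuals
    sum to zero by construction of OLS with intercept.
    """
    if len(series) < 3:
        raise ValueError("linear_detrend needs at least 3 samples")
    t = series.times
    # centered design for numerical stability
    tc = t - t.mean()
    slope = float(tc @ (series.values - series.values.mean()) / (tc @ tc))
    resid = series.values - series.values.mean() - slope * tc
    return series.with_values(resid)


def normalize_by_mean(series: UniformSeries) -> UniformSeries:
    """Divide by the series mean so the output has mean exactly 1.

    This is the standard normalization for comparing fluctuation
    amplitudes across data sets with different units.
    """
    mean = float(series.values.mean())
    scale = float(np.max(np.abs(series.values)))
    if abs(mean) <= 1e-12 * max(scale, 1e-300):
        raise ValueError("cannot normalize: series mean is zero")
    return series.with_values(series.values / mean)
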