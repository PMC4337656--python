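"""Data model and I/O for uniformly binned behavioral series and dialysate profiles.

All times are decimal hours from an arbitrary recording origin; bin timestamps
are the *left edges* of half-open bins ``[t, t + dt)``.  Missing data is
carried as a boolean mask and never imputed here — downstream spectral stages
simply drop masked bins (the Lomb-Scargle estimator tolerates the gaps), and
stages that require contiguous data refuse masked input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, RebinError, SpacingError, WindowError

__all__ = [
    "UniformSeries",
    "LightingSchedule",
    "DialysateProfile",
    "AnimalRecord",
    "load_series",
    "write_series",
    "read_awd",
    "rebin",
    "extract_window",
]

_SPACING_RTOL = 1e-6


@dataclass
class UniformSeries:
    """Evenly binned time series of activity counts or body temperature.

    Parameters
    ----------
    t0 : float
        Offset of the first bin's left edge, in hours from the recording origin.
    dt : float
        Bin width in hours (0.1 hr = 6 min for wheel-running data).
    values : ndarray of float
        One value per bin: counts (``kind='activity'``) or degrees C
        (``kind='temperature'``).  Entries under the mask are ignored.
    missing_mask : ndarray of bool
        True where the bin is missing.
    kind : {'activity', 'temperature'}
    """

    t0: float
    dt: float
    values: np.ndarray
    missing_mask: np.ndarray | None = None
    kind: str = "activity"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.values.shape, dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("values and missing_mask must have the same length")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.kind not in ("activity", "temperature"):
            raise ValueError(f"unknown series kind {self.kind!r}")
        if self.kind == "activity":
            ok = self.values[~self.missing_mask]
            if ok.size and np.nanmin(ok) < 0:
                raise ValueError("activity counts must be non-negative")

    # -- derived views -------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.size

    @property
    def span(self) -> float:
        """Total recording span in hours."""
        return self.n * self.dt

    @property
    def times(self) -> np.ndarray:
        """Left bin edges, hours."""
        return self.t0 + np.arange(self.n) * self.dt

    @property
    def midtimes(self) -> np.ndarray:
        """Bin midpoints, hours."""
        return self.times + 0.5 * self.dt

    def valid(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (times, values) of non-missing bins."""
        keep = ~self.missing_mask
        return self.times[keep], self.values[keep]

    def with_values(self, values: np.ndarray) -> "UniformSeries":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class LightingSchedule:
    """Lighting regime of the recording.

    ``regime`` is 'LD' (light:dark cycle), 'DD' (constant dark) or 'dim_red'
    (constant dim red light, behaviorally dark).  ``lights_on`` is the hour
    offset of lights-on within the 24-hr day; ``photoperiod`` the hours of
    light per cycle.  Both are ignored outside LD.
    """

    regime: str = "DD"
    lights_on: float = 0.0
    photoperiod: float = 12.0

    def __post_init__(self) -> None:
        if self.regime not in ("LD", "DD", "dim_red"):
            raise ValueError(f"unknown lighting regime {self.regime!r}")
        if not 0 <= self.lights_on < 24:
            raise ValueError("lights_on must lie in [0, 24)")
        if not 0 <= self.photoperiod <= 24:
            raise ValueError("photoperiod must lie in [0, 24]")

    def is_light(self, t: np.ndarray | float) -> np.ndarray | bool:
        """True where time-of-day falls in the light phase (always False off-LD)."""
        if self.regime != "LD":
            return np.zeros(np.shape(t), dtype=bool) if np.ndim(t) else False
        return ((np.asarray(t) - self.lights_on) % 24.0) < self.photoperiod


@dataclass
class DialysateProfile:
    """Short evenly sampled dopamine concentration trace (microdialysis).

    ``sample_times`` are sample-interval midpoints in hours; ``concentrations``
    in nM.  The canonical protocol is one sample per 20 min for 4 hr
    (12 samples, ``interval = 1/3`` hr).
    """

    sample_times: np.ndarray
    concentrations: np.ndarray
    interval: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.sample_times.size != self.concentrations.size:
            raise ValueError("sample_times and concentrations must match in length")
        if self.sample_times.size < 4:
            raise DataError("dialysate profile needs at least 4 samples")
        d = np.diff(self.sample_times)
        if np.any(d <= 0):
            raise SpacingError("sample_times must be strictly increasing")
        if np.any(np.abs(d - self.interval) > 1e-9 + 1e-9 * self.interval):
            raise SpacingError("sample_times must be evenly spaced at `interval`")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")

    @property
    def n(self) -> int:
        return self.sample_times.size


@dataclass
class AnimalRecord:
    """Container tying one animal's recordings and metadata together."""

    animal_id: str
    genotype_tag: str
    activity: UniformSeries
    lighting: LightingSchedule = field(default_factory=LightingSchedule)
    temperature: UniformSeries | None = None
    episodes: list[tuple[float, float, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        span = (self.activity.t0, self.activity.t0 + self.activity.span)
        prev_end = None
        for start, end, _label, _dose in sorted(self.episodes):
            if start < span[0] - 1e-9 or end > span[1] + 1e-9 or end <= start:
                raise ValueError("episode outside recording span or empty")
            if prev_end is not None and start < prev_end - 1e-9:
                raise ValueError("episodes must not overlap")
            prev_end = end


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_series(
    path: str | Path,
    time_col: str = "time_hr",
    value_col: str = "value",
    missing_col: str = "missing",
    kind: str = "activity",
    sep: str = ",",
) -> UniformSeries:
    """Read a delimited text file into a :class:`UniformSeries`.

    The time column may hold decimal hours or ISO timestamps (converted to
    hours from the first stamp).  Rows absent from the file become masked
    bins on the reconstructed uniform grid; non-monotone times are rejected.
    """
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise FormatError(f"could not parse {path}: {exc}") from exc
    for col in (time_col, value_col):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    t = df[time_col]
    if not pd.api.types.is_numeric_dtype(t):
        try:
            stamps = pd.to_datetime(t)
        except Exception as exc:
            raise FormatError(f"time column is neither hours nor timestamps: {exc}") from exc
        t = (stamps - stamps.iloc[0]).dt.total_seconds() / 3600.0
    t = np.asarray(t, dtype=float)
    v = np.asarray(df[value_col], dtype=float)
    if t.size < 2:
        raise FormatError("need at least two rows to infer bin width")
    d = np.diff(t)
    if np.any(d <= 0):
        raise SpacingError("time column must be strictly increasing")
    dt = float(np.median(d))
    # place every row on the uniform grid anchored at the first stamp
    idx_f = (t - t[0]) / dt
    idx = np.rint(idx_f).astype(int)
    if np.any(np.abs(idx_f - idx) > _SPACING_RTOL):
        raise SpacingError("bin spacing irregular beyond 1e-6 of the bin width")
    if np.unique(idx).size != idx.size:
        raise SpacingError("duplicate time stamps")
    n = idx[-1] + 1
    values = np.zeros(n)
    mask = np.ones(n, dtype=bool)
    values[idx] = v
    mask[idx] = False
    if missing_col in df.columns:
        mask[idx] |= np.asarray(df[missing_col], dtype=float).astype(bool)
    values[mask] = np.nan
    values = np.where(mask, 0.0, values)
    return UniformSeries(t0=float(t[0]), dt=dt, values=values, missing_mask=mask, kind=kind)


def write_series(series: UniformSeries, path: str | Path) -> None:
    """Write a series as CSV ``time_hr,value,missing`` (lossless round-trip)."""
    df = pd.DataFrame(
        {
            "time_hr": series.times,
            "value": np.where(series.missing_mask, np.nan, series.values),
            "missing": series.missing_mask.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_awd(path: str | Path, dt: float = 0.1, kind: str = "activity") -> UniformSeries:
    """Read a ClockLab-style AWD file: a short header block then one count per line.

    The seven header lines (animal id, start date, start time, interval code
    and hardware fields) are skipped; the interval code is not interpreted —
    pass the bin width explicitly via ``dt``.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) <= 7:
        raise FormatError("AWD file too short: expected 7 header lines plus data")
    counts = []
    for ln in lines[7:]:
        ln = ln.strip()
        if not ln:
            continue
        try:
            counts.append(float(ln.split()[0]))
        except ValueError as exc:
            raise FormatError(f"unparseable AWD count line {ln!r}") from exc
    values = np.asarray(counts)
    mask = ~np.isfinite(values) | (values < 0)  # hardware error codes are negative
    values = np.where(mask, 0.0, values)
    return UniformSeries(t0=0.0, dt=dt, values=values, missing_mask=mask, kind=kind)


# ---------------------------------------------------------------------------
# windowing and rebinning
# ---------------------------------------------------------------------------

def rebin(series: UniformSeries, new_dt: float) -> UniformSeries:
    """Rebin to a coarser bin width, conserving total non-missing counts.

    Counts are treated as a uniform density within each source bin and
    integrated over the new bin edges, so the total is conserved exactly even
    when ``new_dt`` is a non-integer multiple of ``dt`` (e.g. 0.1-hr wheel
    bins to 20-min bins).  Temperature is averaged with overlap weights.
    A new bin is missing iff every overlapping source bin is missing; a
    trailing partial new bin is dropped.
    """
    if new_dt < series.dt - 1e-12:
        raise RebinError("new_dt must be at least the current bin width")
    if abs(new_dt - series.dt) < 1e-12:
        return replace(series)
    n_new = int(np.floor(series.span / new_dt + 1e-9))
    if n_new < 1:
        raise RebinError("new_dt exceeds the recording span")
    old_edges = np.arange(series.n + 1) * series.dt
    new_edges = np.arange(n_new + 1) * new_dt

    ok_vals = np.where(series.missing_mask, 0.0, series.values)
    # counts: value per bin is an integral (density = value/dt);
    # temperature: value per bin is a level (density = value)
    dens_v = ok_vals / series.dt if series.kind == "activity" else ok_vals
    dens_w = (~series.missing_mask).astype(float)  # coverage density

    def _integral(dens: np.ndarray) -> np.ndarray:
        cum = np.concatenate([[0.0], np.cumsum(dens * series.dt)])
        at_edges = np.interp(new_edges, old_edges, cum)
        return np.diff(at_edges)

    sums = _integral(dens_v)
    cover = _integral(dens_w)  # hours of non-missing coverage per new bin
    mask_new = cover <= 1e-12
    if series.kind == "activity":
        values_new = np.where(mask_new, 0.0, sums)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            values_new = np.where(mask_new, 0.0, sums / np.maximum(cover, 1e-300))
    return UniformSeries(
        t0=series.t0, dt=new_dt, values=values_new, missing_mask=mask_new, kind=series.kind
    )


def extract_window(series: UniformSeries, start: float, duration: float) -> UniformSeries:
    """Extract ``duration`` hours beginning at absolute time ``start``."""
    i0 = int(np.rint((start - series.t0) / series.dt))
    n = int(np.rint(duration / series.dt))
    if i0 < 0 or n < 1 or i0 + n > series.n:
        raise WindowError(
            f"window [{start}, {start + duration}) outside recording span "
            f"[{series.t0}, {series.t0 + series.span})"
        )
    return UniformSeries(
        t0=series.t0 + i0 * series.dt,
        dt=series.dt,
        values=series.values[i0 : i0 + n].copy(),
        missing_mask=series.missing_mask[i0 : i0 + n].copy(),
        kind=series.kind,
    )
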