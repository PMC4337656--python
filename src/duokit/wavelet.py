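"""Morlet continuous-wavelet scalograms, ridge extraction and period statistics.

The scalogram visualizes how the dominant ultradian period drifts over days —
something a single periodogram peak cannot show.  We use the complex Morlet
wavelet with center frequency ``omega0 = 6`` (the standard
admissibility-respecting default) over log-spaced scales covering 1–12 hr.
Scale maps to Fourier period via

    p = 4*pi*s / (omega0 + sqrt(2 + omega0**2)),

the conventional correspondence for this wavelet, under which a pure
sinusoid's amplitude ridge falls at its true period.  Amplitudes are shown in
decibels relative to the scalogram maximum, so the display is invariant to
positive rescaling of the input.  The cone of influence (COI) marks the
edge-affected region at the e-folding distance ``sqrt(2)*s``; COI points are
excluded from ridge statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .errors import BandError, DataError
from .timeseries import UniformSeries

__all__ = [
    "Scalogram",
    "RidgeTrace",
    "morlet_fourier_factor",
    "compute_cwt",
    "extract_ridge",
    "ridge_period_stats",
]


def morlet_fourier_factor(omega0: float = 6.0) -> float:
    """Period/scale ratio for the Morlet wavelet with center frequency omega0."""
    return 4 * np.pi / (omega0 + np.sqrt(2 + omega0**2))


@dataclass
class Scalogram:
    """Time x period matrix of dB-normalized Morlet amplitude."""

    times: np.ndarray  # hours
    periods: np.ndarray  # hours, ascending, log-spaced
    amp: np.ndarray  # raw |W|, shape (n_periods, n_times)
    amp_db: np.ndarray  # 20*log10(|W| / max|W|)  (<= 0 everywhere)
    coi_mask: np.ndarray  # True where edge-affected (inside the cone)
    omega0: float = 6.0
    voices: int = 32


@dataclass
class RidgeTrace:
    """Per-time dominant period and its summary statistics (COI excluded)."""

    times: np.ndarray
    ridge_periods: np.ndarray  # NaN where inside the COI
    valid: np.ndarray  # boolean: outside the COI
    mean_period: float
    sd_period: float


def compute_cwt(
    series: UniformSeries,
    band: tuple[float, float] = (1.0, 12.0),
    voices: int = 32,
    omega0: float = 6.0,
) -> Scalogram:
    """Morlet scalogram of an activity series over a period band.

    Missing bins are linearly interpolated first (the transform needs a
    contiguous signal); the default analysis window is seven consecutive
    days.  ``voices`` sets the number of log-spaced scales per octave.
    """
    if band[1] >= series.span / 2:
        raise BandError("band maximum must be below half the series span")
    if band[0] <= 2 * series.dt:
        raise BandError("band minimum must exceed twice the bin width")
    values = series.values.astype(float)
    if series.missing_mask.any():
        ok = ~series.missing_mask
        if ok.sum() < 2:
            raise DataError("series almost entirely missing")
        values = np.interp(np.arange(series.n), np.flatnonzero(ok), values[ok])
    values = values - values.mean()

    n_oct = np.log2(band[1] / band[0])
    k = int(np.ceil(n_oct * voices)) + 1
    periods = band[0] * 2.0 ** (np.arange(k) / voices)
    periods = periods[periods <= band[1] * (1 + 1e-12)]
    if periods[-1] < band[1] * (1 - 1e-12):
        periods = np.append(periods, band[1])
    ff = morlet_fourier_factor(omega0)
    scales_hr = periods / ff  # physical scale s in hours
    scales = scales_hr / series.dt  # in samples, pywt convention
    wavelet = f"cmor2.0-{omega0 / (2 * np.pi):.10f}"
    coef, _ = pywt.cwt(values, scales, wavelet, sampling_period=series.dt, method="fft")
    amp = np.abs(coef)
    peak = amp.max()
    amp_db = 20.0 * np.log10(np.maximum(amp, peak * 1e-12) / peak) if peak > 0 else np.zeros_like(amp)

    times = series.times
    t_rel = times - times[0]
    coi_time = np.sqrt(2.0) * scales_hr  # e-folding distance per scale
    dist_edge = np.minimum(t_rel, t_rel[-1] - t_rel)
    coi_mask = dist_edge[None, :] < coi_time[:, None]
    return Scalogram(
        times=times,
        periods=periods,
        amp=amp,
        amp_db=amp_db,
        coi_mask=coi_mask,
        omega0=omega0,
        voices=voices,
    )


def extract_ridge(scal: Scalogram, jump_penalty: float = 0.0) -> RidgeTrace:
    """Trace the ridge of local amplitude maxima through the scalogram.

    Default is the per-time argmax over periods.  A positive ``jump_penalty``
    (dB per voice step) instead runs a dynamic-programming ridge that
    discourages large scale jumps between adjacent time points, useful on
    noisy scalograms.  COI points are flagged invalid and excluded from the
    mean/SD.
    """
    n_p, n_t = scal.amp_db.shape
    if jump_penalty <= 0:
        ridge_idx = np.argmax(scal.amp_db, axis=0)
    else:
        cost = -scal.amp_db  # minimize
        jumps = jump_penalty * np.abs(np.arange(n_p)[:, None] - np.arange(n_p)[None, :])
        acc = cost[:, 0].copy()
        back = np.zeros((n_p, n_t), dtype=np.int32)
        for j in range(1, n_t):
            total = acc[None, :] + jumps  # candidate previous-row costs
            back[:, j] = np.argmin(total, axis=1)
            acc = cost[:, j] + total[np.arange(n_p), back[:, j]]
        ridge_idx = np.zeros(n_t, dtype=np.int32)
        ridge_idx[-1] = int(np.argmin(acc))
        for j in range(n_t - 1, 0, -1):
            ridge_idx[j - 1] = back[ridge_idx[j], j]
    ridge_periods = scal.periods[ridge_idx].astype(float)
    valid = ~scal.coi_mask[ridge_idx, np.arange(n_t)]
    ridge_out = np.where(valid, ridge_periods, np.nan)
    if valid.any():
        mean_p = float(np.mean(ridge_periods[valid]))
        sd_p = float(np.std(ridge_periods[valid]))
    else:
        mean_p = sd_p = float("nan")
    return RidgeTrace(
        times=scal.times, ridge_periods=ridge_out, valid=valid, mean_period=mean_p, sd_period=sd_p
    )


def ridge_period_stats(ridge: RidgeTrace, min_points: int = 100) -> tuple[float, float]:
    """Mean and SD of the dominant period over non-COI ridge points."""
    pts = ridge.ridge_periods[ridge.valid]
    if pts.size < min_points:
        raise DataError(f"need at least {min_points} non-COI ridge points, have {pts.size}")
    return float(np.mean(pts)), float(np.std(pts))
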