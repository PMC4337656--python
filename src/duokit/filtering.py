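"""Zero-phase smoothing/filtering and daily-waveform averaging.

Two zero-phase smoothers are provided for trace display and bout counting:

* a Butterworth low-pass run forward and backward (``filtfilt``), default
  order 2 per pass, cancelling phase distortion exactly;
* a "recursive" smoother — a first-order exponential (single-pole IIR)
  filter with time constant ``span/2``, likewise applied forward then
  backward.  This matches the pandas ``ewm(span=...)`` convention and yields
  a symmetric, unshifted impulse response.

Both smoothers reflect-pad the input by one cutoff/span length before
filtering to suppress endpoint transients on short windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import NyquistError, SpanError
from .timeseries import UniformSeries

__all__ = [
    "FilterSpec",
    "butterworth_zero_phase",
    "recursive_smooth",
    "DailyWaveform",
    "daily_waveform",
    "waveform_peaks",
    "butterworth_two_pass_gain",
    "smoother_two_pass_gain",
]


@dataclass
class FilterSpec:
    """Filter description: Butterworth low-pass or recursive (EMA) smoother.

    ``cutoff_or_span`` is the cutoff period (Butterworth) or smoothing span
    (recursive), in hours.  ``order`` applies to Butterworth only (per pass).
    """

    kind: str = "butterworth_lowpass"
    cutoff_or_span: float = 1.0
    order: int = 2

    def __post_init__(self) -> None:
        if self.kind not in ("butterworth_lowpass", "recursive_smooth"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.cutoff_or_span <= 0:
            raise ValueError("cutoff_or_span must be positive")
        if self.order < 1:
            raise ValueError("order must be >= 1")


def _require_gap_free(series: UniformSeries) -> None:
    if series.missing_mask.any():
        raise ValueError(
            "filtering requires a gap-free window: interpolate or restrict first"
        )


def _pad_filter_trim(series: UniformSeries, pad: int, run) -> UniformSeries:
    values = series.values
    pad = min(pad, values.size - 1)
    ext = np.pad(values, pad, mode="reflect") if pad > 0 else values
    out = run(ext)
    if pad > 0:
        out = out[pad : pad + values.size]
    if series.kind == "activity":
        # filter under/overshoot can dip below zero; counts displays clip there
        out = np.maximum(out, 0.0)
    return series.with_values(out)


def butterworth_zero_phase(
    series: UniformSeries, cutoff_hr: float = 1.0, order: int = 2
) -> UniformSeries:
    """Zero-phase Butterworth low-pass with the cutoff given as a *period* in hours.

    The filter is applied forward and backward, so the effective magnitude
    response is the squared single-pass response and the phase response is
    identically zero.  DC gain is 1.
    """
    _require_gap_free(series)
    if cutoff_hr <= 2 * series.dt:
        raise NyquistError(
            f"cutoff period {cutoff_hr} hr must exceed twice the bin width ({2 * series.dt} hr)"
        )
    fs = 1.0 / series.dt  # samples per hour
    sos = signal.butter(order, 1.0 / cutoff_hr, btype="low", fs=fs, output="sos")
    # generous reflect padding: transients of higher orders ring past one cutoff
    pad = int(round(5 * cutoff_hr / series.dt))

    def run(x: np.ndarray) -> np.ndarray:
        return signal.sosfiltfilt(sos, x, padlen=0)

    return _pad_filter_trim(series, pad, run)


def recursive_smooth(series: UniformSeries, span_hr: float = 2.0) -> UniformSeries:
    """Two-pass exponential smoother with per-pass time constant ``span_hr / 2``."""
    _require_gap_free(series)
    if span_hr <= series.dt:
        raise SpanError(f"span {span_hr} hr must exceed the bin width {series.dt} hr")
    tau = span_hr / 2.0
    a = 1.0 - np.exp(-series.dt / tau)
    b, ar = [a], [1.0, -(1.0 - a)]
    pad = int(round(5 * span_hr / series.dt))
    zi = signal.lfilter_zi(b, ar)  # steady-state init: constants pass exactly

    def run(x: np.ndarray) -> np.ndarray:
        fwd, _ = signal.lfilter(b, ar, x, zi=zi * x[0])
        bwd, _ = signal.lfilter(b, ar, fwd[::-1], zi=zi * fwd[-1])
        return bwd[::-1]

    return _pad_filter_trim(series, pad, run)


def apply_filter(series: UniformSeries, spec: FilterSpec) -> UniformSeries:
    if spec.kind == "butterworth_lowpass":
        return butterworth_zero_phase(series, spec.cutoff_or_span, spec.order)
    return recursive_smooth(series, spec.cutoff_or_span)


# -- analytic gains (closed forms used as test oracles and for documentation)

def butterworth_two_pass_gain(
    f_signal: float, f_cutoff: float, order: int, fs: float
) -> float:
    """Amplitude gain of the forward-backward digital Butterworth filter.

    Closed form of the bilinear-transformed design: the analog response
    ``1 / (1 + (f/fc)^2n)`` evaluated at prewarped frequencies, squared once
    for the two passes (``|H|^2`` overall since filtfilt applies |H| twice).
    Frequencies in cycles per hour; ``fs`` in samples per hour.
    """
    warped = np.tan(np.pi * f_signal / fs) / np.tan(np.pi * f_cutoff / fs)
    return float(1.0 / (1.0 + warped ** (2 * order)))


def smoother_two_pass_gain(f_signal: float, span_hr: float, dt: float) -> float:
    """Amplitude gain of the two-pass exponential smoother at ``f_signal`` (cyc/hr)."""
    tau = span_hr / 2.0
    a = 1.0 - np.exp(-dt / tau)
    w = 2 * np.pi * f_signal * dt  # radians per sample
    h2 = a**2 / (1.0 - 2 * (1 - a) * np.cos(w) + (1 - a) ** 2)  # |H|^2 single pass
    return float(h2)


# ---------------------------------------------------------------------------
# daily (modulo) waveform
# ---------------------------------------------------------------------------


@dataclass
class DailyWaveform:
    """Phase-folded average waveform: per-phase-bin mean and SEM."""

    modulo: float
    dt: float
    phase: np.ndarray  # left edges of phase bins, [0, modulo)
    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray  # cycles contributing per phase bin


def daily_waveform(series: UniformSeries, modulo: float = 24.0) -> DailyWaveform:
    """Fold the series at ``modulo`` hours and average across cycles.

    Missing bins are excluded from their phase bin's mean/SEM.  Requires at
    least two full cycles.
    """
    if series.span < 2 * modulo:
        raise SpanError("need at least two full cycles for a folded waveform")
    nb = int(np.rint(modulo / series.dt))
    if abs(nb * series.dt - modulo) > 1e-6 * series.dt:
        raise ValueError("modulo must be an integer number of bins")
    idx = np.arange(series.n) % nb
    ok = ~series.missing_mask
    counts = np.bincount(idx[ok], minlength=nb).astype(float)
    sums = np.bincount(idx[ok], weights=series.values[ok], minlength=nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    # two-pass variance: stable against cancellation for near-constant cycles
    dev = series.values - np.where(counts[idx] > 0, mean[idx], 0.0)
    sqdev = np.bincount(idx[ok], weights=dev[ok] ** 2, minlength=nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = np.where(counts > 1, sqdev / np.maximum(counts - 1, 1), 0.0)
        sem = np.where(counts > 1, np.sqrt(var / np.maximum(counts, 1)), 0.0)
    phase = np.arange(nb) * series.dt
    return DailyWaveform(modulo=modulo, dt=series.dt, phase=phase, mean=mean, sem=sem, n=counts)


def waveform_peaks(
    wf: DailyWaveform, min_prominence_frac: float = 0.2
) -> np.ndarray:
    """Phases (hours) of local maxima of the folded waveform.

    The mean waveform is treated circularly (extended by one period on each
    side) so bouts spanning the fold boundary are found once.  Prominence
    threshold is a fraction of the waveform's peak-to-trough range.
    """
    m = wf.mean.copy()
    if np.isnan(m).any():
        # fill isolated empty phase bins by interpolation on the circle
        ok = ~np.isnan(m)
        m = np.interp(np.arange(m.size), np.flatnonzero(ok), m[ok], period=m.size)
    rng = float(m.max() - m.min())
    if rng <= 0:
        return np.array([])
    ext = np.concatenate([m, m, m])
    peaks, _ = signal.find_peaks(ext, prominence=min_prominence_frac * rng)
    keep = peaks[(peaks >= m.size) & (peaks < 2 * m.size)] - m.size
    return np.sort(keep * wf.dt)
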