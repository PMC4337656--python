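"""Actogram matrix construction and rendering.

An actogram wraps a long activity record at a chosen modulo period, one row
per cycle; a double plot places consecutive cycles side by side so rhythms
drifting across the fold remain readable.  Plotting modulo the *called*
ultradian period (rather than 24 hr) is the visual check that a periodogram
peak is a genuine rhythm and not a harmonic or side lobe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SpanError
from .timeseries import LightingSchedule, UniformSeries

__all__ = ["ActogramMatrix", "build_actogram", "plot_actogram"]


@dataclass
class ActogramMatrix:
    """Row-per-cycle matrix of binned values (NaN where missing/unfilled)."""

    modulo: float
    dt: float
    rows: np.ndarray  # shape (n_cycles, width) — width doubled when double_plot
    double_plot: bool
    light_columns: np.ndarray | None = None  # per-column light flag (LD only)

    @property
    def n_rows(self) -> int:
        return self.rows.shape[0]


def build_actogram(
    series: UniformSeries,
    modulo: float = 24.0,
    double_plot: bool = False,
    lighting: LightingSchedule | None = None,
) -> ActogramMatrix:
    """Wrap the series row-wise at ``modulo`` hours.

    The trailing partial cycle is dropped.  Missing bins become NaN.  In a
    double plot, row i holds cycles i and i+1; the final row's right half is
    NaN-padded when no further cycle exists.
    """
    nb = int(np.rint(modulo / series.dt))
    if abs(nb * series.dt - modulo) > 1e-6 * series.dt:
        raise ValueError("modulo must be an integer number of bins")
    n_cycles = series.n // nb
    if n_cycles < 1:
        raise SpanError("series shorter than one modulo cycle")
    vals = np.where(series.missing_mask, np.nan, series.values)[: n_cycles * nb]
    single = vals.reshape(n_cycles, nb)
    if double_plot:
        right = np.full_like(single, np.nan)
        right[:-1] = single[1:]
        rows = np.hstack([single, right])
    else:
        rows = single
    light_cols = None
    if lighting is not None and lighting.regime == "LD":
        phases = series.t0 + np.arange(rows.shape[1]) * series.dt
        light_cols = np.asarray(lighting.is_light(phases))
    return ActogramMatrix(
        modulo=modulo, dt=series.dt, rows=rows, double_plot=double_plot, light_columns=light_cols
    )


def plot_actogram(
    mat: ActogramMatrix,
    path: str | None = None,
    ax=None,
    value_range: tuple[float, float] | None = None,
    title: str | None = None,
):
    """Render an actogram as stacked tick rows; returns the matplotlib Axes.

    ``value_range`` maps values to tick height (defaults to the data range;
    use (34, 38) for core body temperature in deg C).
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, max(2, 0.25 * mat.n_rows)))
    finite = mat.rows[np.isfinite(mat.rows)]
    if value_range is None:
        lo, hi = (0.0, float(finite.max())) if finite.size and finite.max() > 0 else (0.0, 1.0)
    else:
        lo, hi = value_range
    heights = np.clip((mat.rows - lo) / (hi - lo if hi > lo else 1.0), 0, 1) * 0.9
    x = np.arange(mat.rows.shape[1]) * mat.dt
    if mat.light_columns is not None:
        spans = np.flatnonzero(np.diff(np.concatenate([[0], mat.light_columns.astype(int), [0]])))
        for a, b in zip(spans[::2], spans[1::2]):
            ax.axvspan(x[a], x[min(b, x.size - 1)], color="#fff3b0", zorder=0)
    for i in range(mat.n_rows):
        h = heights[i]
        ok = np.isfinite(h)
        ax.vlines(x[ok], -i, -i + h[ok], color="black", lw=0.5)
    ax.set_xlim(0, x[-1] + mat.dt)
    ax.set_ylim(-mat.n_rows + 0.5, 1.1)
    ax.set_xlabel(f"time (hr, modulo {mat.modulo:g})")
    ax.set_ylabel("cycle")
    ax.set_yticks([])
    if title:
        ax.set_title(title)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
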