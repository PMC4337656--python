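"""Cosinor modelling and the permutation false-discovery-rate concordance test.

The workflow mirrors the dialysis experiment: the animal's locomotor period
tau is first called from a Lomb-Scargle periodogram of the 20 hr of activity
recorded after dialysate sampling; a least-squares cosinor

    y(t) = M + A * cos(2*pi*t/tau - phi)

is then fit to the (20-min rebinned) activity at that fixed tau, and the
measured dopamine profile is scored against the cosinor evaluated at the
dialysate sample times.  Both traces are min-max normalized to [0, 1] before
the sum of squared errors (SSE) is formed, so the score is dimensionless and
comparable across animals with different absolute dopamine and activity
levels.  Significance is a permutation test: the temporal order of the
dopamine samples is shuffled many times (100,000 in the reference protocol)
and the false discovery rate is the percentage of permutations fitting the
cosinor as well as or better than the measured trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy import stats

from .errors import DataError, DesignError, NormalizationError, ParameterError, SizeError, WindowError
from .timeseries import DialysateProfile, UniformSeries

__all__ = [
    "CosinorModel",
    "ConcordanceResult",
    "RegressionResult",
    "fit_cosinor",
    "rhythm_adjusted_mean",
    "concordance_sse",
    "permutation_fdr",
    "exhaustive_fdr",
    "period_tone_regression",
]

_TIE_RTOL = 1e-9  # float tolerance for the "equal or better" tie rule


@dataclass
class CosinorModel:
    """Single-component cosinor at a fixed trial period ``tau`` (hours)."""

    tau: float
    mesor: float
    amplitude: float
    acrophase: float  # radians in [0, 2*pi)
    fit_sse: float = float("nan")  # residual SS on the fitted activity series

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        self.acrophase = float(self.acrophase) % (2 * math.pi)

    def predict(self, t: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.mesor + self.amplitude * np.cos(2 * np.pi * t / self.tau - self.acrophase)


@dataclass
class ConcordanceResult:
    """Outcome of the cosinor-vs-dopamine permutation test."""

    observed_sse: float
    n_permutations: int
    fdr_percent: float
    seed: int | None = None
    exhaustive: bool = False


def fit_cosinor(series: UniformSeries, tau: float) -> CosinorModel:
    """Least-squares cosinor fit at fixed ``tau`` on a gap-free series.

    Linear regression on {1, cos(2*pi*t/tau), sin(2*pi*t/tau)}; amplitude and
    acrophase recovered from the quadrature coefficients.  Deterministic.
    """
    if series.missing_mask.any():
        raise DataError("cosinor fit requires a gap-free window")
    if series.span < tau:
        raise WindowError("series must span at least one full period")
    if tau <= 2 * series.dt:
        raise DesignError("tau at or below twice the bin width: singular design")
    t = series.times
    w = 2 * np.pi / tau
    X = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    coef, *_ = np.linalg.lstsq(X, series.values, rcond=None)
    mesor, a, b = coef
    amplitude = float(np.hypot(a, b))
    acrophase = float(np.arctan2(b, a)) % (2 * np.pi)
    resid = series.values - X @ coef
    return CosinorModel(
        tau=float(tau),
        mesor=float(mesor),
        amplitude=amplitude,
        acrophase=acrophase,
        fit_sse=float(resid @ resid),
    )


def _minmax(x: np.ndarray, what: str, strict: bool) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo <= 0:
        if strict:
            raise NormalizationError(f"{what} is constant: concordance is incomparable")
        return np.full(x.shape, 0.5)
    return (x - lo) / (hi - lo)


def _normalized_pair(model: CosinorModel, profile: DialysateProfile) -> tuple[np.ndarray, np.ndarray]:
    c = model.predict(profile.sample_times)
    # an amplitude-0 cosinor is flat: map to 0.5 so all permutations tie
    c_n = _minmax(c, "cosinor", strict=False)
    p_n = _minmax(profile.concentrations, "dopamine profile", strict=True)
    return c_n, p_n


def concordance_sse(model: CosinorModel, profile: DialysateProfile) -> float:
    """Dimensionless SSE between min-max-normalized cosinor and dopamine traces."""
    c_n, p_n = _normalized_pair(model, profile)
    return float(np.sum((p_n - c_n) ** 2))


def permutation_fdr(
    model: CosinorModel,
    profile: DialysateProfile,
    n_perm: int = 100_000,
    seed: int | None = None,
) -> ConcordanceResult:
    """Permutation false discovery rate of the cosinor–dopamine concordance.

    Draws ``n_perm`` independent uniform orderings of the dopamine values
    across the fixed sample times (with replacement, so the identity may
    recur) and reports the percentage whose SSE is equal to or better than
    the observed trace's.  Min-max normalization is order-invariant, so it is
    applied once.  Fully reproducible given ``seed``.
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be at least 1")
    c_n, p_n = _normalized_pair(model, profile)
    observed = float(np.sum((p_n - c_n) ** 2))
    rng = np.random.default_rng(seed)
    n = p_n.size
    cutoff = observed * (1 + _TIE_RTOL) + _TIE_RTOL
    hits = 0
    # chunked to bound memory at large n_perm
    chunk = 20_000
    for start in range(0, n_perm, chunk):
        m = min(chunk, n_perm - start)
        idx = rng.permuted(np.broadcast_to(np.arange(n), (m, n)).copy(), axis=1)
        sse = np.sum((p_n[idx] - c_n) ** 2, axis=1)
        hits += int(np.count_nonzero(sse <= cutoff))
    return ConcordanceResult(
        observed_sse=observed,
        n_permutations=n_perm,
        fdr_percent=100.0 * hits / n_perm,
        seed=seed,
        exhaustive=False,
    )


def exhaustive_fdr(model: CosinorModel, profile: DialysateProfile) -> ConcordanceResult:
    """FDR over all n! orderings of a short profile (n <= 8): the exact reference."""
    n = profile.n
    if n > 8:
        raise SizeError("exhaustive enumeration supported for n <= 8 only")
    c_n, p_n = _normalized_pair(model, profile)
    observed = float(np.sum((p_n - c_n) ** 2))
    idx = np.array(list(permutations(range(n))))
    sse = np.sum((p_n[idx] - c_n) ** 2, axis=1)
    cutoff = observed * (1 + _TIE_RTOL) + _TIE_RTOL
    hits = int(np.count_nonzero(sse <= cutoff))
    return ConcordanceResult(
        observed_sse=observed,
        n_permutations=idx.shape[0],
        fdr_percent=100.0 * hits / idx.shape[0],
        seed=None,
        exhaustive=True,
    )


def rhythm_adjusted_mean(profile: DialysateProfile, tau: float) -> float:
    """Mesor of a fixed-``tau`` cosinor fit to a dialysate profile.

    The raw sample mean of a short dialysate window is biased by whatever
    oscillator phase the sampling happened to cover; regressing the cosinor
    {1, cos, sin} basis out at the animal's called period and keeping the
    intercept gives the rhythm-adjusted mean dopamine level.  Unlike
    :func:`fit_cosinor` this accepts windows shorter than one period (the
    4-hr dialysis protocol against a long-period animal); the quadrature
    terms are then partly collinear but the intercept remains estimable.
    """
    t = profile.sample_times
    w = 2 * np.pi / tau
    X = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    coef, *_ = np.linalg.lstsq(X, profile.concentrations, rcond=None)
    return float(coef[0])


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def period_tone_regression(taus: np.ndarray, tones: np.ndarray) -> RegressionResult:
    """OLS regression of called period on mean dopamine concentration.

    ``tones`` are the per-animal mean dopamine levels (nM, the regressor);
    ``taus`` the called periods (hours).  Two-sided test on the slope.
    """
    taus = np.asarray(taus, dtype=float)
    tones = np.asarray(tones, dtype=float)
    if taus.size != tones.size or taus.size < 3:
        raise DataError("need at least 3 paired observations")
    if np.ptp(tones) == 0:
        # degenerate design: slope indeterminate, report the flat fit
        return RegressionResult(
            slope=0.0, intercept=float(taus.mean()), r_squared=0.0, p_value=1.0
        )
    res = stats.linregress(tones, taus)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
    )
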