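import itertools
import math

import numpy as np
import pytest

import duokit as dk
from duokit.errors import (
    DataError,
    DesignError,
    NormalizationError,
    ParameterError,
    SizeError,
    WindowError,
)


def _series(values, dt=1 / 3, kind="temperature"):
    return dk.UniformSeries(0.0, dt, np.asarray(values, float), kind=kind)


def _profile(conc, interval=1 / 3, start=0.0):
    t = start + (np.arange(len(conc)) + 0.5) * interval
    return dk.DialysateProfile(t, np.asarray(conc, float), interval=interval)


def grid_search_cosinor(t, y, tau, rounds=10, pts=21):
    """Brute-force refinement over (mesor, amplitude, acrophase) at fixed tau.

    Independent oracle for the least-squares fit: shrinking dense grids, no
    linear algebra shared with the implementation.
    """
    m_lo, m_hi = y.min(), y.max()
    centers = np.array([(m_lo + m_hi) / 2, (m_hi - m_lo) / 2, np.pi])
    widths = np.array([m_hi - m_lo, m_hi - m_lo, np.pi])
    w = 2 * np.pi / tau
    for _ in range(rounds):
        axes = [c + np.linspace(-h, h, pts) for c, h in zip(centers, widths)]
        axes[1] = np.clip(axes[1], 0.0, None)  # amplitude is non-negative
        M, A, P = np.meshgrid(*axes, indexing="ij")
        pred = M[..., None] + A[..., None] * np.cos(w * t - P[..., None])
        sse = np.sum((pred - y) ** 2, axis=-1)
        i, j, k = np.unravel_index(np.argmin(sse), sse.shape)
        centers = np.array([axes[0][i], axes[1][j], axes[2][k]])
        widths = widths * (2.0 / (pts - 1)) * 1.5  # keep the old best bracketed
    centers[2] %= 2 * np.pi
    return centers  # mesor, amplitude, acrophase


class TestFitCosinor:
    def test_noiseless_recovery(self):
        t = (np.arange(60)) / 3  # 20 hr at 20-min bins
        y = 2 + 1.5 * np.cos(2 * np.pi * t / 4.0 - 1.0)
        model = dk.fit_cosinor(_series(y), tau=4.0)
        assert model.mesor == pytest.approx(2.0, abs=1e-8)
        assert model.amplitude == pytest.approx(1.5, abs=1e-8)
        assert model.acrophase == pytest.approx(1.0, abs=1e-8)
        assert model.fit_sse == pytest.approx(0.0, abs=1e-12)

    def test_constant_series(self):
        model = dk.fit_cosinor(_series(np.full(60, 3.7)), tau=4.0)
        assert model.amplitude == pytest.approx(0.0, abs=1e-9)
        assert model.mesor == pytest.approx(3.7)

    def test_noisy_fit_matches_grid_search_oracle(self, rng):
        t = np.arange(60) / 3
        y = 2 + 1.5 * np.cos(2 * np.pi * t / 4.0 - 1.0) + rng.normal(0, 0.4, t.size)
        model = dk.fit_cosinor(_series(y), tau=4.0)
        m, a, p = grid_search_cosinor(t, y, 4.0)
        assert model.mesor == pytest.approx(m, abs=1e-6)
        assert model.amplitude == pytest.approx(a, abs=1e-6)
        assert model.acrophase == pytest.approx(p, abs=1e-6)

    def test_residual_never_exceeds_mesor_only_model(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            y = r.normal(10, 3, 60)
            model = dk.fit_cosinor(_series(y), tau=4.0)
            assert model.fit_sse <= np.sum((y - y.mean()) ** 2) + 1e-9

    def test_window_and_design_errors(self):
        with pytest.raises(WindowError):
            dk.fit_cosinor(_series(np.ones(6)), tau=4.0)
        with pytest.raises(DesignError):
            dk.fit_cosinor(_series(np.ones(60)), tau=0.5)
        s = _series(np.ones(60))
        s.missing_mask[0] = True
        with pytest.raises(DataError):
            dk.fit_cosinor(s, tau=4.0)


class TestConcordanceSSE:
    def _model(self):
        return dk.CosinorModel(tau=4.0, mesor=2.0, amplitude=1.0, acrophase=0.7)

    def test_perfect_profile_zero_sse(self):
        model = self._model()
        t = (np.arange(12) + 0.5) / 3
        prof = dk.DialysateProfile(t, model.predict(t) + 5.0)  # offset-shifted copy
        assert dk.concordance_sse(model, prof) == pytest.approx(0.0, abs=1e-12)

    def test_antiphase_profile_hand_arithmetic(self):
        model = self._model()
        t = (np.arange(12) + 0.5) / 3
        c = model.predict(t)
        c_n = (c - c.min()) / (c.max() - c.min())
        prof = dk.DialysateProfile(t, 1.0 - c_n)
        expected = float(np.sum((1 - 2 * c_n) ** 2))
        assert dk.concordance_sse(model, prof) == pytest.approx(expected, abs=1e-12)

    def test_noise_profile_positive(self, rng):
        model = self._model()
        prof = _profile(rng.uniform(1, 3, 12))
        assert dk.concordance_sse(model, prof) > 0

    def test_degenerate_profile_rejected(self):
        with pytest.raises(NormalizationError):
            dk.concordance_sse(self._model(), _profile(np.full(12, 2.0)))


class TestPermutationFDR:
    def _model(self):
        return dk.CosinorModel(tau=4.0, mesor=2.0, amplitude=1.0, acrophase=0.7)

    def test_perfect_fit_near_zero_fdr(self):
        model = self._model()
        t = (np.arange(12) + 0.5) / 3
        prof = dk.DialysateProfile(t, model.predict(t))
        res = dk.permutation_fdr(model, prof, n_perm=100_000, seed=1)
        assert res.fdr_percent <= 0.01

    def test_affine_invariance(self, rng):
        model = self._model()
        vals = rng.uniform(1, 3, 12)
        r1 = dk.permutation_fdr(model, _profile(vals), n_perm=5000, seed=42)
        r2 = dk.permutation_fdr(model, _profile(3 * vals + 7), n_perm=5000, seed=42)
        assert r1.fdr_percent == r2.fdr_percent

    def test_reproducible_with_seed(self, rng):
        model = self._model()
        prof = _profile(rng.uniform(1, 3, 12))
        a = dk.permutation_fdr(model, prof, n_perm=3000, seed=9)
        b = dk.permutation_fdr(model, prof, n_perm=3000, seed=9)
        assert a.fdr_percent == b.fdr_percent

    def test_null_profiles_roughly_uniform(self):
        # reduced-size calibration; the full version runs in the acceptance suite
        model = self._model()
        vals = []
        for i in range(60):
            r = np.random.default_rng(500 + i)
            vals.append(
                dk.permutation_fdr(model, _profile(r.uniform(1, 3, 12)), n_perm=2000, seed=i).fdr_percent
            )
        mean = np.mean(vals) / 100
        assert 0.38 <= mean <= 0.62

    def test_invalid_n_perm(self):
        with pytest.raises(ParameterError):
            dk.permutation_fdr(self._model(), _profile(np.arange(1.0, 13.0)), n_perm=0)


class TestExhaustiveFDR:
    def _model(self):
        return dk.CosinorModel(tau=4.0, mesor=2.0, amplitude=1.0, acrophase=0.7)

    def test_enumeration_matches_independent_oracle(self):
        # length-4 profile: enumerate the 24 orderings by hand here
        model = self._model()
        prof = _profile([1.0, 3.0, 2.0, 4.0], interval=1 / 3)
        res = dk.exhaustive_fdr(model, prof)
        c = model.predict(prof.sample_times)
        c_n = (c - c.min()) / (c.max() - c.min())
        p = prof.concentrations
        p_n = (p - p.min()) / (p.max() - p.min())
        obs = np.sum((p_n - c_n) ** 2)
        hits = sum(
            np.sum((p_n[list(perm)] - c_n) ** 2) <= obs * (1 + 1e-9) + 1e-9
            for perm in itertools.permutations(range(4))
        )
        assert res.n_permutations == 24
        assert res.fdr_percent == pytest.approx(100.0 * hits / 24)

    def test_perfect_fit_minimum_fdr_is_tie_count(self):
        model = self._model()
        t = (np.arange(6) + 0.5) / 3
        prof = dk.DialysateProfile(t, model.predict(t))
        res = dk.exhaustive_fdr(model, prof)
        # distinct values: only the identity ordering ties
        assert res.fdr_percent == pytest.approx(100.0 / math.factorial(6))

    def test_flat_cosinor_all_permutations_tie(self):
        model = dk.CosinorModel(tau=4.0, mesor=2.0, amplitude=0.0, acrophase=0.0)
        prof = _profile([1.0, 2.0, 3.0, 4.0, 5.0])
        res = dk.exhaustive_fdr(model, prof)
        assert res.fdr_percent == pytest.approx(100.0)

    def test_size_limit(self):
        with pytest.raises(SizeError):
            dk.exhaustive_fdr(self._model(), _profile(np.arange(1.0, 10.0)))

    def test_monte_carlo_agrees_with_enumeration(self):
        model = self._model()
        rng = np.random.default_rng(7)
        for i in range(3):
            prof = _profile(rng.uniform(1, 3, 6))
            exact = dk.exhaustive_fdr(model, prof).fdr_percent / 100
            mc = dk.permutation_fdr(model, prof, n_perm=20_000, seed=i).fdr_percent / 100
            ci = 2.576 * np.sqrt(exact * (1 - exact) / 20_000)
            assert abs(mc - exact) <= ci + 1e-9


class TestPeriodToneRegression:
    def test_exact_line(self):
        da = np.array([1.0, 1.5, 2.0, 2.5, 3.0])
        taus = 4 + 2 * da
        res = dk.period_tone_regression(taus, da)
        assert res.slope == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_tau_zero_slope(self):
        res = dk.period_tone_regression(np.full(5, 4.0), np.array([1.0, 1.5, 2.0, 2.5, 3.0]))
        assert res.slope == pytest.approx(0.0, abs=1e-12)

    def test_too_few_pairs(self):
        with pytest.raises(DataError):
            dk.period_tone_regression(np.array([4.0, 5.0]), np.array([1.0, 2.0]))
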