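import numpy as np
import pytest

import duokit as dk
from duokit.errors import BandError, DataError, SpanError

from .conftest import make_sinusoid


def classical_periodogram(t, y, freqs_angular):
    """Schuster periodogram of the centered series, variance-normalized.

    Independent oracle for the Lomb-Scargle estimator on even sampling:
    the two coincide exactly at frequencies commensurate with the span.
    """
    yc = y - y.mean()
    var = np.var(yc, ddof=1)
    e = np.exp(-1j * np.outer(freqs_angular, t))
    return np.abs(e @ yc) ** 2 / t.size / var


def span_aligned_periods(span, lo, hi):
    """Period grid whose frequencies are integer cycles per span."""
    k = np.arange(int(np.ceil(span / hi)), int(np.floor(span / lo)) + 1)
    return (span / k)[::-1]


class TestLombScargle:
    def test_matches_classical_periodogram_on_even_sampling(self, rng):
        s = make_sinusoid(4.0, duration=168.0, mesor=5.0)
        s = s.with_values(s.values + rng.normal(0, 0.3, s.n))
        periods = span_aligned_periods(s.span, 1.0, 12.0)
        pg = dk.compute_lomb_scargle(s, periods=periods)
        t, y = s.valid()
        oracle = classical_periodogram(t, y, 2 * np.pi / periods)
        assert np.max(np.abs(pg.power - oracle) / np.maximum(oracle, 1e-12)) < 1e-9

    def test_pure_cosine_peak_at_true_period(self):
        s = make_sinusoid(4.0, duration=168.0)
        pg = dk.compute_lomb_scargle(s, band=(1.0, 12.0))
        assert pg.periods[np.argmax(pg.power)] == pytest.approx(4.0, abs=0.02)

    def test_amplitude_recovers_sinusoid_amplitude(self, rng):
        s = make_sinusoid(4.0, duration=168.0, amplitude=1.5)
        s = s.with_values(s.values + rng.normal(0, 0.2, s.n))
        pg = dk.compute_lomb_scargle(s, band=(1.0, 12.0))
        assert pg.amplitude[np.argmax(pg.power)] == pytest.approx(1.5, rel=0.05)

    def test_constant_series_near_zero_power(self):
        s = dk.UniformSeries(0.0, 0.1, np.full(1680, 4.2), kind="temperature")
        pg = dk.compute_lomb_scargle(s, band=(1.0, 12.0))
        assert np.all(pg.power <= 1e-12)

    def test_gapped_cosine_peak_survives(self, rng):
        s = make_sinusoid(4.0, duration=168.0)
        mask = np.zeros(s.n, bool)
        mask[rng.choice(s.n, size=s.n // 5, replace=False)] = True
        s = dk.UniformSeries(0.0, 0.1, s.values, mask, kind="temperature")
        pg = dk.compute_lomb_scargle(s, band=(1.0, 12.0))
        assert pg.periods[np.argmax(pg.power)] == pytest.approx(4.0, abs=0.02)

    def test_too_few_samples(self):
        s = dk.UniformSeries(0.0, 0.1, np.ones(10))
        with pytest.raises(DataError):
            dk.compute_lomb_scargle(s, band=(1.0, 12.0))

    def test_band_below_nyquist(self):
        s = make_sinusoid(4.0, duration=24.0)
        with pytest.raises(BandError):
            dk.compute_lomb_scargle(s, band=(0.1, 12.0), grid_step=0.02)


class TestEstimatePeriod:
    def test_simulated_clockless_animal_calls_four_hours(self):
        cfg = dk.preset_config("scnx-wt", days=7, seed=3)
        rec, _ = dk.simulate_activity(cfg)
        est = dk.estimate_period(dk.compute_lomb_scargle(rec.activity, band=(1.0, 12.0)))
        assert est.significant
        assert est.tau == pytest.approx(4.0, abs=0.1)
        assert not est.harmonic_flags

    def test_white_noise_not_significant(self, rng):
        s = dk.UniformSeries(0.0, 0.1, rng.normal(5, 1, 1680), kind="temperature")
        est = dk.estimate_period(dk.compute_lomb_scargle(s, band=(1.0, 40.0)))
        assert not est.significant
        assert np.isnan(est.tau)

    def test_pulse_train_fundamental_beats_harmonic(self):
        # 25%-duty 8-hr pulse train has a strong 4-hr harmonic, but the
        # fundamental outpowers it; restricting the band to exclude 8 hr
        # calls 4 hr and raises the double-period flag
        t = np.arange(1680) * 0.1
        y = ((t % 8.0) < 2.0) * 10.0
        s = dk.UniformSeries(0.0, 0.1, y)
        est = dk.estimate_period(dk.compute_lomb_scargle(s, band=(1.0, 12.0)))
        assert est.tau == pytest.approx(8.0, abs=0.1) and not est.harmonic_flags
        est2 = dk.estimate_period(dk.compute_lomb_scargle(s, band=(1.0, 6.0)))
        assert est2.tau == pytest.approx(4.0, abs=0.1)
        assert "double_period_stronger" in est2.harmonic_flags

    def test_scale_invariance(self):
        t = np.arange(1680) * 0.1
        y = ((t % 8.0) < 2.0) * 10.0
        for scale in (0.01, 1.0, 375.0):
            s = dk.UniformSeries(0.0, 0.1, y * scale)
            est = dk.estimate_period(dk.compute_lomb_scargle(s, band=(1.0, 12.0)))
            assert est.tau == pytest.approx(8.0, abs=0.1)


class TestASD:
    def test_single_rhythm_fills_its_band(self):
        s = make_sinusoid(4.0, duration=336.0)
        pg = dk.compute_lomb_scargle(s, band=(1.0, 40.0))
        res = dk.amplitude_spectral_density(pg, (2.0, 8.0))
        assert res.percent == pytest.approx(100.0)
        assert not res.empty_spectrum

    def test_full_range_is_total(self):
        s = make_sinusoid(4.0, duration=336.0)
        pg = dk.compute_lomb_scargle(s, band=(1.0, 40.0))
        res = dk.amplitude_spectral_density(pg, (float(pg.periods[0]), float(pg.periods[-1])))
        assert res.percent == pytest.approx(100.0)

    def test_no_rhythm_gives_zero_with_flag(self, rng):
        s = dk.UniformSeries(0.0, 0.1, rng.normal(5, 1, 3360), kind="temperature")
        pg = dk.compute_lomb_scargle(s, band=(1.0, 40.0))
        res = dk.amplitude_spectral_density(pg, (2.0, 8.0))
        assert res.percent == 0.0
        assert res.empty_spectrum

    def test_adding_circadian_component_decreases_ultradian_share(self):
        t = np.arange(3360) * 0.1
        base = np.cos(2 * np.pi * t / 4.0)
        both = base + np.cos(2 * np.pi * t / 24.0)
        asd = {}
        for name, y in (("alone", base), ("with24", both)):
            s = dk.UniformSeries(0.0, 0.1, 5 + y, kind="temperature")
            pg = dk.compute_lomb_scargle(s, band=(1.0, 40.0))
            asd[name] = dk.amplitude_spectral_density(pg, (2.0, 8.0)).percent
        assert asd["with24"] < asd["alone"]
        assert asd["alone"] == pytest.approx(100.0)

    def test_band_outside_range(self):
        s = make_sinusoid(4.0, duration=336.0)
        pg = dk.compute_lomb_scargle(s, band=(1.0, 12.0))
        with pytest.raises(BandError):
            dk.amplitude_spectral_density(pg, (2.0, 30.0))


class TestCircadianScreen:
    def test_lesioned_animal_is_arrhythmic(self):
        cfg = dk.preset_config("scnx-wt", days=8, seed=5)
        rec, _ = dk.simulate_activity(cfg)
        assert dk.circadian_arrhythmia_screen(rec.activity)

    def test_intact_animal_is_rhythmic(self):
        cfg = dk.preset_config("intact-wt", days=8, seed=5)
        rec, _ = dk.simulate_activity(cfg)
        assert not dk.circadian_arrhythmia_screen(rec.activity)

    def test_22hr_rhythm_inside_band(self):
        s = make_sinusoid(22.0, duration=192.0)
        assert not dk.circadian_arrhythmia_screen(s)

    def test_short_record_rejected(self):
        s = make_sinusoid(24.0, duration=96.0)
        with pytest.raises(SpanError):
            dk.circadian_arrhythmia_screen(s)
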