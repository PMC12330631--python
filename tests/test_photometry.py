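"""Unit tests for the photometry processing chain."""

import numpy as np
import pytest

from swmphot import photometry as ph
from swmphot.photometry import (SpectralTimeseries, TransientParams,
                                band_summed_signal, crosscorr_lagged,
                                detect_transients, detrend_linear,
                                dff_per_trial, distal_delay_score,
                                downsample_mean, linear_unmix, mad,
                                peak_response, peri_event_average,
                                ratio_zscore_trials, spontaneous_stats,
                                validate_trial_table)
from swmphot.synth import event_shape, make_reference_spectra


@pytest.fixture
def grid():
    return np.arange(480.0, 651.0)


@pytest.fixture
def refs(grid):
    return make_reference_spectra(grid)


def _spec(grid, counts, rate=20.0):
    return SpectralTimeseries(wavelengths_nm=grid, counts=counts, rate_hz=rate)


class TestBandSum:
    def test_constant_counts(self, grid):
        spec = _spec(grid, np.ones((grid.size, 5)))
        sel = (grid >= 500) & (grid <= 541)
        np.testing.assert_array_equal(band_summed_signal(spec, (500, 541)),
                                      np.full(5, sel.sum()))

    def test_band_edges_inclusive(self, grid):
        counts = np.zeros((grid.size, 1))
        counts[grid == 500.0] = 1.0
        counts[grid == 541.0] = 1.0
        spec = _spec(grid, counts)
        assert band_summed_signal(spec, (500, 541))[0] == 2.0

    def test_band_outside_grid(self, grid):
        spec = _spec(grid, np.ones((grid.size, 1)))
        with pytest.raises(ValueError):
            band_summed_signal(spec, (900, 950))


class TestUnmix:
    def test_exact_coefficients(self, grid, refs):
        frame = 3.0 * refs.spectra[:, 0] + 5.0 * refs.spectra[:, 1]
        spec = _spec(grid, frame[:, None])
        coef, resid = linear_unmix(spec, refs, background=False)
        assert coef["GCaMP"].iloc[0] == pytest.approx(3.0, abs=1e-10)
        assert coef["tdTomato"].iloc[0] == pytest.approx(5.0, abs=1e-10)
        assert resid[0] == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_references_are_projections(self, grid):
        s = np.zeros((grid.size, 2))
        s[10, 0] = 1.0
        s[50, 1] = 1.0
        refs = ph.ReferenceSpectra(wavelengths_nm=grid, spectra=s)
        frame = 2.0 * s[:, 0] + 7.0 * s[:, 1]
        coef, _ = linear_unmix(_spec(grid, frame[:, None]), refs,
                               background=False)
        np.testing.assert_allclose(coef.iloc[0], [2.0, 7.0], atol=1e-12)

    def test_rank_deficient_rejected(self, grid):
        s = np.ones((grid.size, 2)) / np.sqrt(grid.size)
        refs = ph.ReferenceSpectra(wavelengths_nm=grid, spectra=s)
        with pytest.raises(ValueError):
            linear_unmix(_spec(grid, np.ones((grid.size, 1))), refs)


class TestDetrend:
    def test_ramp_becomes_flat(self):
        t = np.arange(100.0)
        out = detrend_linear(2.0 + 0.5 * t)
        np.testing.assert_allclose(out, np.full(100, out.mean()), atol=1e-9)
        assert out.mean() == pytest.approx((2.0 + 0.5 * t).mean())

    def test_flat_unchanged(self):
        out = detrend_linear(np.full(50, 3.3))
        np.testing.assert_allclose(out, 3.3, atol=1e-12)

    def test_residual_slope_zero(self, rng):
        y = rng.random(500) + 0.01 * np.arange(500)
        out = detrend_linear(y)
        slope = np.polyfit(np.arange(500.0), out, 1)[0]
        assert abs(slope) < 1e-10


class TestDownsample:
    def test_block_means(self):
        np.testing.assert_array_equal(
            downsample_mean([1, 2, 3, 4, 5, 6, 7, 8], 40, 10), [2.5, 6.5])

    def test_constant_preserved(self):
        np.testing.assert_array_equal(downsample_mean(np.ones(20), 20, 10),
                                      np.ones(10))

    def test_bad_ratio(self):
        with pytest.raises(ValueError):
            downsample_mean(np.ones(10), 25, 10)


class TestDff:
    def test_constant_is_zero(self):
        f = np.full(300, 50.0)
        np.testing.assert_allclose(dff_per_trial(f, 10, 0.0), 0.0)

    def test_doubling_is_plus_100(self):
        f = np.full(300, 10.0)
        f[100:] = 20.0
        dff = dff_per_trial(f, 10, 0.0)
        assert dff[150] == pytest.approx(100.0)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            dff_per_trial(np.zeros(300), 10, 0.0)

    def test_peak_response_window(self):
        dff = np.zeros(300)
        dff[120] = 7.5       # 12 s at 10 Hz
        assert peak_response(dff, 10) == 7.5
        assert peak_response(np.zeros(300), 10) == 0.0
        with pytest.raises(ValueError):
            peak_response(np.zeros(50), 10, window_s=(10, 15))


class TestRatioZscore:
    def test_shared_artifact_cancels_exactly(self, rng):
        g = 50 + rng.random(400)
        t = 100 + rng.random(400)
        m = np.exp(0.2 * np.sin(np.arange(400) / 20))
        z1, _ = ratio_zscore_trials(g, t, [(0, 400)])
        z2, _ = ratio_zscore_trials(g * m, t * m, [(0, 400)])
        np.testing.assert_allclose(z1[0], z2[0], atol=1e-10)

    def test_unit_moments(self, rng):
        g = 50 + rng.random(200)
        t = 100 + rng.random(200)
        zs, excl = ratio_zscore_trials(g, t, [(0, 100), (100, 200)])
        assert excl == []
        for z in zs:
            assert abs(z.mean()) < 1e-10
            assert z.std() == pytest.approx(1.0, abs=1e-10)

    def test_near_zero_denominator_excluded(self, rng):
        g = 50 + rng.random(100)
        t = 100 + rng.random(100)
        t[10] = 0.0
        with pytest.warns(UserWarning):
            zs, excl = ratio_zscore_trials(g, t, [(0, 50), (50, 100)])
        assert excl == [0]
        assert zs[0] is None and zs[1] is not None

    def test_zero_variance_trial_excluded(self):
        g = np.ones(60)
        t = np.ones(60)
        with pytest.warns(UserWarning):
            zs, excl = ratio_zscore_trials(g, t, [(0, 60)])
        assert excl == [0]


class TestTransients:
    def test_single_large_event(self, rng):
        ts = 0.1 * rng.standard_normal(1200)
        shape = event_shape(10.0)
        amp = 10 * 2.91 * mad(ts)
        ts[600:600 + shape.size] += amp * shape
        events = detect_transients(ts, 10.0)
        assert len(events) == 1
        assert events[0].magnitude == pytest.approx(amp, rel=0.3)

    def test_nearby_peaks_merged(self, rng):
        # two events 0.5 s apart violate the 1-s separation rule
        ts = 0.05 * rng.standard_normal(1200)
        shape = event_shape(10.0)
        ts[600:600 + shape.size] += 5 * shape
        ts[605:605 + shape.size] += 5 * shape
        events = detect_transients(ts, 10.0)
        assert len(events) == 1

    def test_constant_series_empty(self):
        assert detect_transients(np.ones(500), 10.0) == []

    def test_width_bounds_respected(self, rng):
        ts = 0.05 * rng.standard_normal(2400)
        shape = event_shape(10.0)
        ts[300:300 + shape.size] += 5 * shape
        events = detect_transients(ts, 10.0)
        p = TransientParams()
        for e in events:
            assert p.min_width_s <= e.half_width_s <= p.max_width_s

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            TransientParams(min_width_s=2.0, max_width_s=1.0)


class TestSpontaneousStats:
    def _session(self, rng, amp):
        ts = 0.05 * rng.standard_normal(6000)   # 10 min at 10 Hz
        shape = event_shape(10.0)
        for i in range(200, 6000 - 100, 400):
            ts[i:i + shape.size] += amp * shape
        return ts

    def test_identical_sessions_normalize_to_one(self, rng):
        ts = self._session(rng, 5.0)
        day1 = spontaneous_stats(ts, 10.0)
        norm = spontaneous_stats(ts, 10.0, day1_reference=day1)
        for v in norm.values():
            assert v == pytest.approx(1.0)

    def test_doubled_amplitude(self):
        rng1 = np.random.default_rng(0)
        rng2 = np.random.default_rng(0)
        day1 = spontaneous_stats(self._session(rng1, 5.0), 10.0)
        norm = spontaneous_stats(self._session(rng2, 10.0), 10.0,
                                 day1_reference=day1)
        assert norm["magnitude"] == pytest.approx(2.0, rel=0.1)
        assert norm["frequency"] == pytest.approx(1.0, rel=0.1)

    def test_short_record_rejected(self):
        with pytest.raises(ValueError):
            spontaneous_stats(np.zeros(1000), 10.0)

    def test_zero_reference_rejected(self, rng):
        ts = self._session(rng, 5.0)
        with pytest.raises(ValueError):
            spontaneous_stats(ts, 10.0, day1_reference={"magnitude": 0.0,
                                                        "frequency": 1.0,
                                                        "half_width": 1.0})


class TestPeriEvent:
    def test_single_event_window_copy(self, rng):
        z = rng.random(200)
        off, mean, n = peri_event_average(z, 10.0, [10.0], window_s=(-1, 1))
        assert n == 1
        np.testing.assert_array_equal(mean, z[90:110])

    def test_unit_range_normalization(self, rng):
        z = rng.random(200)
        _, mean, _ = peri_event_average(z, 10.0, [10.0], window_s=(-1, 1),
                                        normalize_unit_range=True)
        assert mean.max() == pytest.approx(1.0)
        assert mean.min() == pytest.approx(-1.0)

    def test_template_recovery(self, rng):
        template = np.sin(np.linspace(0, np.pi, 20))
        z = 0.05 * rng.standard_normal(3000)
        events = [50.0, 100.0, 150.0, 200.0, 250.0]
        for e in events:
            i = int(e * 10)
            z[i:i + 20] += template
        _, mean, n = peri_event_average(z, 10.0, events, window_s=(0, 2))
        assert n == len(events)
        assert np.corrcoef(mean, template)[0, 1] > 0.99

    def test_event_snapping_to_grid(self, rng):
        z = rng.random(200)
        _, a, _ = peri_event_average(z, 10.0, [10.0], window_s=(-1, 1))
        _, b, _ = peri_event_average(z, 10.0, [10.04], window_s=(-1, 1))
        np.testing.assert_array_equal(a, b)

    def test_out_of_record_skipped(self, rng):
        z = rng.random(50)
        with pytest.warns(UserWarning):
            off, mean, n = peri_event_average(z, 10.0, [0.1, 3.0],
                                              window_s=(-1, 1))
        assert n == 1


class TestDistalDelay:
    def test_constant_window(self):
        z = np.full(200, 0.7)
        assert distal_delay_score(z, 10.0, [10.0])[0] == pytest.approx(0.7)

    def test_zero_window(self):
        z = np.zeros(200)
        assert distal_delay_score(z, 10.0, [5.0])[0] == 0.0

    def test_missing_samples_flagged(self):
        z = np.zeros(50)
        with pytest.warns(UserWarning):
            out = distal_delay_score(z, 10.0, [1.0])
        assert np.isnan(out[0])


class TestCrossCorrelation:
    def test_calcium_leads_positive_lag(self, rng):
        ca = rng.standard_normal(500)
        vel = np.roll(ca, 10)      # vel[t] = ca[t-10]: calcium leads by 10
        lags, r = crosscorr_lagged(ca, vel)
        assert lags[np.nanargmax(r)] == 10

    def test_anticorrelated_at_zero(self, rng):
        ca = rng.standard_normal(300)
        lags, r = crosscorr_lagged(ca, -ca)
        assert r[lags == 0][0] == pytest.approx(-1.0)

    def test_independent_series_near_zero(self, rng):
        ca = rng.standard_normal(2000)
        vel = rng.standard_normal(2000)
        lags, r = crosscorr_lagged(ca, vel)
        assert np.nanmax(np.abs(r)) < 3 / np.sqrt(2000 - 50) * 1.8

    def test_zero_variance_is_nan(self):
        lags, r = crosscorr_lagged(np.ones(100), np.arange(100.0))
        assert np.isnan(r).all()

    def test_length_validation(self):
        with pytest.raises(ValueError):
            crosscorr_lagged(np.ones(40), np.ones(40), max_lag_samples=50)


class TestTrialTable:
    def test_validation(self):
        import pandas as pd
        df = pd.DataFrame({
            "mouse_id": ["m0"], "trial_index": [0],
            "training_fraction": [0.0], "outcome": [0],
            "sample_start": [10.0], "sample_end": [15.0],
            "delay_start": [16.0], "choice_start": [26.0],
            "choice_end": [30.0],
        })
        validate_trial_table(df)
        bad = df.copy()
        bad["choice_start"] = 5.0
        with pytest.raises(ValueError):
            validate_trial_table(bad)
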