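"""HRV measures: editing, resampling, time/Poincaré/frequency domains and
their cross-identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import holterhrv as h
from holterhrv.hrv import pnn50_bruteforce
from holterhrv.types import AnalysisError, NNSeries, ResampledNN


def _nn(values_ms, t_s=None):
    values_ms = np.asarray(values_ms, dtype=float)
    if t_s is None:
        t_s = np.cumsum(values_ms) / 1000.0
    return NNSeries(t_s=np.asarray(t_s, dtype=float), nn_ms=values_ms,
                    edited=np.zeros(values_ms.size, dtype=bool))


nn_values = st.lists(
    st.floats(min_value=400.0, max_value=1500.0), min_size=5, max_size=60
).map(np.asarray)


class TestEditRr:
    def test_identity_without_abnormals(self):
        t = np.cumsum(np.full(20, 0.8))
        rr = np.full(20, 800.0)
        nn = h.edit_rr(t, rr, np.zeros(20, dtype=bool))
        assert np.array_equal(nn.nn_ms, rr)
        assert not nn.edited.any()

    def test_linear_ramp_reproduced_exactly(self):
        t = np.cumsum(np.full(20, 0.8))
        rr = 700.0 + 10.0 * np.arange(20)
        bad = np.zeros(20, dtype=bool)
        bad[9] = True
        nn = h.edit_rr(t, rr, bad)
        assert nn.nn_ms[9] == pytest.approx(rr[9], abs=1e-9)  # spline reproduces a line
        assert nn.edited[9] and nn.edited.sum() == 1

    def test_sinusoid_interpolated_close(self):
        t = np.cumsum(np.full(60, 0.8))
        rr = 800.0 + 40.0 * np.sin(2 * np.pi * 0.1 * t)
        corrupted = rr.copy()
        bad = np.zeros(60, dtype=bool)
        bad[[20, 21]] = True
        corrupted[[20, 21]] = [500.0, 1100.0]
        nn = h.edit_rr(t, corrupted, bad)
        assert np.all(np.abs(nn.nn_ms[[20, 21]] - rr[[20, 21]]) < 5.0)

    def test_rejects_excess_abnormal(self):
        t = np.cumsum(np.full(40, 0.8))
        rr = np.full(40, 800.0)
        bad = np.zeros(40, dtype=bool)
        bad[::8] = True
        bad[1::8] = True  # tainted pairs -> >5% abnormal-beat burden
        with pytest.raises(AnalysisError, match="exceeds"):
            h.edit_rr(t, rr, bad)


class TestResample:
    def test_constant_series(self):
        nn = _nn(np.full(30, 800.0))
        rs = h.resample_nn(nn, start_s=nn.t_s[0], duration_s=20.0)
        assert rs.fs_hz == 4.0
        assert rs.values_ms.size == 80
        assert np.allclose(rs.values_ms, 800.0)

    def test_sinusoid_tracked_within_1ms(self):
        t = np.cumsum(np.full(400, 0.8))
        rr = 800.0 + 40.0 * np.sin(2 * np.pi * 0.1 * t)
        nn = _nn(rr, t_s=t)
        rs = h.resample_nn(nn, start_s=10.0, duration_s=300.0)
        grid = 10.0 + np.arange(rs.values_ms.size) / 4.0
        expect = 800.0 + 40.0 * np.sin(2 * np.pi * 0.1 * grid)
        assert np.max(np.abs(rs.values_ms - expect)) < 1.0

    def test_linear_trend_preserved(self):
        t = np.cumsum(np.full(50, 0.8))
        rr = 700.0 + 5.0 * np.arange(50)
        rs = h.resample_nn(_nn(rr, t_s=t), start_s=t[0], duration_s=30.0)
        grid = np.clip(t[0] + np.arange(rs.values_ms.size) / 4.0, t[0], t[-1])
        expect = np.interp(grid, t, rr)
        assert np.max(np.abs(rs.values_ms - expect)) < 1e-6

    def test_too_few_intervals(self):
        with pytest.raises(AnalysisError):
            h.resample_nn(_nn([800.0, 810.0, 820.0]))


class TestDetrend:
    def test_pure_line_removed(self):
        x = ResampledNN(fs_hz=4.0, values_ms=5.0 * np.arange(100) + 300.0)
        out = h.detrend_linear(x)
        assert np.allclose(out.values_ms, 0.0, atol=1e-8)
        assert out.detrended

    def test_sinusoid_survives(self):
        t = np.arange(1200) / 4.0
        x = ResampledNN(fs_hz=4.0, values_ms=2.0 * t + 30.0 * np.sin(2 * np.pi * 0.1 * t))
        out = h.detrend_linear(x)
        assert np.var(out.values_ms) == pytest.approx(30.0**2 / 2, rel=0.02)

    def test_variance_never_increases(self):
        rng = np.random.default_rng(0)
        v = rng.normal(0, 10, 500)
        out = h.detrend_linear(ResampledNN(fs_hz=4.0, values_ms=v))
        assert np.var(out.values_ms) <= np.var(v)


class TestTimeDomain:
    def test_pnn50_printed_convention(self):
        # one of two adjacent differences exceeds 50 ms; denominator is 3
        td = h.time_domain_measures(_nn([800.0, 860.0, 865.0]), detrend=False)
        assert td.pnn50_pct == pytest.approx(33.333, abs=1e-3)

    def test_constant_series_zero_variability(self):
        td = h.time_domain_measures(_nn(np.full(10, 800.0)))
        assert td.mean_nn_ms == 800.0
        assert td.sdnn_ms == pytest.approx(0.0, abs=1e-9)
        assert td.rmssd_ms == pytest.approx(0.0, abs=1e-9)
        assert td.pnn50_pct == 0.0

    def test_alternating_series_rmssd(self):
        td = h.time_domain_measures(_nn(np.tile([800.0, 900.0], 20)), detrend=False)
        assert td.rmssd_ms == pytest.approx(100.0)
        assert td.sdsd_ms == pytest.approx(100.0, rel=0.02)

    @given(nn_values)
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_pnn50_matches_bruteforce(self, values):
        td = h.time_domain_measures(_nn(values), detrend=False)
        assert td.pnn50_pct == pytest.approx(pnn50_bruteforce(values))

    @given(nn_values)
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_rmssd_sdsd_identity(self, values):
        # RMSSD^2 = SDSD_pop^2 + mean(diff)^2 with the population convention
        td = h.time_domain_measures(_nn(values), detrend=False)
        d = np.diff(values)
        assert td.rmssd_ms**2 == pytest.approx(np.var(d) + np.mean(d) ** 2, rel=1e-9)


class TestPoincare:
    def test_alternating_closed_form(self):
        v = np.tile([800.0, 900.0], 50)
        pc = h.poincare_measures(_nn(v))
        d = np.diff(v)
        assert pc.sd1_ms == pytest.approx(np.sqrt(np.var(d) / 2))
        assert pc.sd1_ms == pytest.approx(70.71, abs=0.01)
        assert pc.sd2_ms == pytest.approx(
            np.sqrt(max(2 * np.var(v) - np.var(d) / 2, 0.0)), abs=1e-9)

    def test_constant_series_undefined_ratio(self):
        pc = h.poincare_measures(_nn(np.full(10, 800.0)))
        assert pc.sd1_ms == 0.0 and pc.sd2_ms == 0.0
        assert np.isnan(pc.sd1_sd2)

    def test_white_nn_ratio_near_one(self):
        rng = np.random.default_rng(5)
        v = 800.0 + rng.normal(0, 30, 5000)
        pc = h.poincare_measures(_nn(np.abs(v)))
        assert pc.sd1_sd2 == pytest.approx(1.0, abs=0.1)

    @given(nn_values)
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_sd1_equals_rmssd_over_sqrt2_population(self, values):
        pc = h.poincare_measures(_nn(values))
        d = np.diff(values)
        rmssd_pop = np.sqrt(np.mean((d - d.mean()) ** 2))
        assert pc.sd1_ms == pytest.approx(rmssd_pop / np.sqrt(2), rel=1e-9)


class TestSpectral:
    def _tone_series(self, amp=50.0, freq=0.1, noise=2.0, seed=0, n=1200):
        rng = np.random.default_rng(seed)
        t = np.arange(n) / 4.0
        v = amp * np.sin(2 * np.pi * freq * t) + rng.normal(0, noise, n)
        return ResampledNN(fs_hz=4.0, values_ms=v, detrended=True)

    @pytest.mark.parametrize("method", ["welch", "ar_burg"])
    def test_sinusoid_band_power(self, method):
        x = self._tone_series(amp=50.0, freq=0.1, noise=2.0)
        res = h.band_powers(h.estimate_psd(x, method=method))
        assert res.lf_ms2 == pytest.approx(1250.0, rel=0.10)

    def test_white_noise_parseval(self):
        rng = np.random.default_rng(1)
        v = rng.normal(0, 20, 1200)
        for method in ("welch", "ar_burg"):
            spec = h.estimate_psd(ResampledNN(fs_hz=4.0, values_ms=v), method=method)
            total = np.trapezoid(spec.psd_ms2_per_hz, spec.freqs_hz)
            assert total == pytest.approx(np.var(v), rel=0.10)

    def test_zero_series_zero_psd(self):
        spec = h.estimate_psd(ResampledNN(fs_hz=4.0, values_ms=np.zeros(1200)),
                              method="ar_burg")
        assert np.all(spec.psd_ms2_per_hz == 0)

    def test_too_short_for_welch(self):
        with pytest.raises(AnalysisError, match="Welch"):
            h.estimate_psd(ResampledNN(fs_hz=4.0, values_ms=np.zeros(100)),
                           method="welch")

    def test_band_power_placement(self):
        x = self._tone_series(amp=40.0, freq=0.25, noise=0.5, seed=2)
        res = h.band_powers(h.estimate_psd(x, method="welch"))
        assert res.nhf_nu > 95.0 and res.nlf_nu < 5.0

    def test_normalized_powers_sum_to_100(self):
        rng = np.random.default_rng(3)
        for seed in range(5):
            v = rng.normal(0, 15, 1200)
            res = h.band_powers(h.estimate_psd(
                ResampledNN(fs_hz=4.0, values_ms=v), method="ar_burg"))
            assert res.nlf_nu + res.nhf_nu == pytest.approx(100.0, abs=1e-9)

    def test_methods_agree_on_two_tone(self):
        rng = np.random.default_rng(4)
        t = np.arange(1200) / 4.0
        v = (40 * np.sin(2 * np.pi * 0.1 * t) + 25 * np.sin(2 * np.pi * 0.25 * t)
             + rng.normal(0, 5, 1200))
        x = ResampledNN(fs_hz=4.0, values_ms=v, detrended=True)
        w = h.band_powers(h.estimate_psd(x, method="welch"))
        b = h.band_powers(h.estimate_psd(x, method="ar_burg"))
        assert b.lf_ms2 == pytest.approx(w.lf_ms2, rel=0.10)
        assert b.hf_ms2 == pytest.approx(w.hf_ms2, rel=0.10)


class TestPerPatient:
    def _segments(self, n_seg, value=800.0):
        segs = []
        for k in range(n_seg):
            t = k * 1200.0 + np.cumsum(np.full(400, 0.8))
            rng = np.random.default_rng(k)
            nn = _nn(value + rng.normal(0, 10, 400), t_s=t)
            sel = h.SubsegmentSelection(
                segment_index=k, start_clock_s=k * 1200.0,
                end_clock_s=k * 1200.0 + 300.0, threshold_used=1,
                n_beats=400, n_abnormal=0, accepted=True)
            segs.append((sel, nn))
        return segs

    def test_median_over_segments(self):
        segs = self._segments(5)
        results, medians = h.hrv_for_patient(segs)
        assert len(results) == 5
        vals = [r.mean_nn_ms for r in results]
        assert medians["mean_nn_ms"] == pytest.approx(np.median(vals))

    def test_lf_dominant_patient(self, modulated_record):
        rec, _ = modulated_record
        cfg = h.EcgSimConfig(duration_s=320.0, mean_rr_ms=800.0,
                             lf_mod=(0.10, 40.0), leads=["II"], seed=14)
        rec, _ = h.generate_ecg(cfg)
        bs = h.classify_beats(h.detect_beats(rec, "II"))
        t_s, rr, bad = h.rr_from_beats(bs)
        nn = h.edit_rr(t_s, rr, bad)
        res = h.hrv_for_segment(nn, start_s=10.0)
        assert res.nlf_nu > 85.0

    def test_no_accepted_segments_errors(self):
        with pytest.raises(AnalysisError):
            h.hrv_for_patient([])
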