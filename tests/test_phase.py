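import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import hilbert

from metastab.containers import EpochedEEG
from metastab.phase import (KOPTrace, average_over, bandpass, baseline_normalize,
                            extract_phase, kop, kop_trace, sliding_metastability,
                            MetastabilityTrace)


def _epochs_from(data_2d, fs=1000.0):
    data = data_2d[None, :, :]
    return EpochedEEG(data=data, fs=fs,
                      channel_names=[f"c{i}" for i in range(data.shape[1])],
                      pulse_sample=0)


class TestKOP:
    def test_fully_synchronized(self):
        r, psi = kop(np.full(32, 0.7))
        assert r == pytest.approx(1.0, abs=1e-15)
        assert psi == pytest.approx(0.7)

    def test_uniformly_spaced_phases(self):
        theta = 2 * np.pi * np.arange(360) / 360
        r, _ = kop(theta)
        assert r <= 1e-12

    def test_two_phase_analytic(self):
        r, psi = kop(np.array([0.0, np.pi / 2]))
        assert r == pytest.approx(np.sqrt(2) / 2, rel=1e-12)
        assert psi == pytest.approx(np.pi / 4, rel=1e-12)

    def test_empty_error(self):
        with pytest.raises(ValueError, match="empty"):
            kop(np.empty(0))

    @given(st.integers(2, 40), st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_bounds_and_shift_invariance(self, n, seed):
        rng = np.random.default_rng(seed)
        theta = rng.uniform(-np.pi, np.pi, n)
        r, psi = kop(theta)
        assert 0.0 <= r <= 1.0 + 1e-12
        shift = rng.uniform(-np.pi, np.pi)
        r2, psi2 = kop(theta + shift)
        assert r2 == pytest.approx(r, abs=1e-12)
        dpsi = np.angle(np.exp(1j * (psi2 - psi - shift)))
        assert dpsi == pytest.approx(0.0, abs=1e-9)

    @given(st.integers(2, 30), st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_r_one_iff_equal_phases(self, n, seed):
        rng = np.random.default_rng(seed)
        common = rng.uniform(-np.pi, np.pi)
        wraps = rng.integers(-2, 3, n)
        r, _ = kop(common + 2 * np.pi * wraps)
        assert r == pytest.approx(1.0, abs=1e-9)
        theta = rng.uniform(-np.pi, np.pi, n)
        if np.ptp(np.angle(np.exp(1j * (theta - theta[0])))) > 1e-3:
            r2, _ = kop(theta)
            assert r2 < 1.0 - 1e-9


class TestExtractPhase:
    fs = 1000.0

    def test_pure_tone_phase_slope(self):
        t = np.arange(4000) / self.fs
        x = np.cos(2 * np.pi * 10 * t)
        eeg = _epochs_from(np.stack([x, x]))
        pt = extract_phase(eeg, (8.0, 12.0))
        phase = np.unwrap(pt.phase[0, 0])
        c = slice(400, 3600)  # central 80%
        slope = np.polyfit(t[c], phase[c], 1)[0]
        assert slope == pytest.approx(2 * np.pi * 10, rel=0.01)

    def test_stopband_attenuation(self):
        t = np.arange(4000) / self.fs
        x_in = np.cos(2 * np.pi * 10 * t)
        x_out = np.cos(2 * np.pi * 40 * t)
        y_in, m = bandpass(x_in, (8.0, 12.0), self.fs)
        y_out, _ = bandpass(x_out, (8.0, 12.0), self.fs)
        c = slice(m, -m)
        gain_db = 20 * np.log10(np.std(y_out[c]) / np.std(y_in[c]))
        assert gain_db <= -20.0

    def test_quadrature_pair(self):
        t = np.arange(4000) / self.fs
        x = np.cos(2 * np.pi * 10 * t)
        y = np.sin(2 * np.pi * 10 * t)
        eeg = _epochs_from(np.stack([x, y]))
        pt = extract_phase(eeg, (8.0, 12.0))
        c = slice(800, 3200)
        diff = np.angle(np.exp(1j * (pt.phase[0, 0, c] - pt.phase[0, 1, c])))
        assert np.abs(diff - np.pi / 2).max() < 0.05

    def test_band_above_nyquist_error(self):
        eeg = _epochs_from(np.zeros((2, 100)), fs=100.0)
        with pytest.raises(ValueError, match="Nyquist"):
            extract_phase(eeg, (30.0, 60.0))

    def test_phase_wrapped(self, tiny_epochs):
        pt = extract_phase(tiny_epochs, (8.0, 12.0))
        assert np.isfinite(pt.phase).all()
        assert (pt.phase > -np.pi).all() and (pt.phase <= np.pi).all()


def _brute_force_windowed_std(r, w):
    """Independent oracle: loop over windows, population std."""
    n = r.size
    out = np.full(n, np.nan)
    left = (w - 1) // 2
    for start in range(n - w + 1):
        seg = r[start : start + w]
        out[start + left] = np.sqrt(np.mean((seg - seg.mean()) ** 2))
    return out


class TestSlidingMetastability:
    def _trace(self, r, fs=1000.0):
        r = np.atleast_2d(r)
        return KOPTrace(r=r, psi=np.zeros_like(r),
                        channel_set=["a", "b"], fs=fs)

    def test_constant_r_zero(self):
        out = sliding_metastability(self._trace(np.full(500, 0.6)), 50.0)
        vals = out.value[0][~np.isnan(out.value[0])]
        assert np.allclose(vals, 0.0)

    def test_sinusoid_closed_form(self):
        # full-period window: population std of a sampled sinusoid = amp/sqrt(2)
        fs, period_ms = 1000.0, 200.0
        t = np.arange(2000) / fs
        r = 0.5 + 0.1 * np.sin(2 * np.pi * t * 1000 / period_ms)
        out = sliding_metastability(self._trace(r, fs), period_ms)
        center = out.value[0, 1000]
        assert center == pytest.approx(0.1 / np.sqrt(2), rel=0.01)

    def test_two_point_window(self):
        r = np.tile([0.4, 0.6], 50)
        out = sliding_metastability(self._trace(r), window_ms=2.0)
        vals = out.value[0][~np.isnan(out.value[0])]
        assert np.allclose(vals, 0.1)

    def test_window_longer_than_trace_error(self):
        with pytest.raises(ValueError, match="longer than trace"):
            sliding_metastability(self._trace(np.zeros(10)), window_ms=50.0)

    @given(st.integers(2, 30), st.integers(30, 200), st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_matches_brute_force_oracle(self, w_samples, n, seed):
        rng = np.random.default_rng(seed)
        r = rng.uniform(0, 1, n)
        trace = self._trace(r)
        out = sliding_metastability(trace, window_ms=w_samples)  # 1 kHz: ms==samples
        expected = _brute_force_windowed_std(r, w_samples)
        np.testing.assert_allclose(out.value[0], expected, atol=1e-12)


class TestBaselineNormalize:
    def _meta(self, values, fs=1000.0):
        return MetastabilityTrace(value=np.asarray(values, dtype=float),
                                  window_ms=50.0, fs=fs)

    def test_constant_trace_100pct(self):
        out = baseline_normalize(self._meta(np.full(2000, 0.4)), (525.0, 1525.0))
        assert np.allclose(out.baseline_pct, 100.0)

    def test_fraction_of_baseline(self):
        v = np.ones(2000)
        v[100] = 0.6
        out = baseline_normalize(self._meta(v), (525.0, 1525.0))
        assert out.baseline_pct[100] == pytest.approx(60.0)

    def test_interval_outside_support_error(self):
        with pytest.raises(ValueError, match="outside trace support"):
            baseline_normalize(self._meta(np.ones(100)), (525.0, 1525.0))

    def test_zero_baseline_error(self):
        with pytest.raises(ValueError, match="baseline"):
            baseline_normalize(self._meta(np.zeros(2000)), (525.0, 1525.0))


class TestAverageOver:
    def test_identical_traces(self):
        tr = np.sin(np.linspace(0, 3, 40))
        out = average_over([tr, tr, tr])
        np.testing.assert_allclose(out, tr)

    def test_simple_mean(self):
        out = average_over([np.zeros(5), np.full(5, 2.0)])
        np.testing.assert_allclose(out, 1.0)

    def test_nan_ignored_with_count(self):
        a = np.array([1.0, np.nan])
        b = np.array([3.0, 5.0])
        mean, n = average_over([a, b], return_n=True)
        np.testing.assert_allclose(mean, [2.0, 5.0])
        np.testing.assert_array_equal(n, [2, 1])


class TestPipelineRecovery:
    """Planted phase reset is recovered end-to-end by the phase metrics."""

    def test_metastability_drop_on_planted_reset(self):
        from metastab.pipeline import subject_metastability
        from metastab.stats import wilcoxon_signed_rank
        from metastab.synth import SyntheticCohortSpec, generate_tms_epochs

        spec = SyntheticCohortSpec(
            n_subjects=10, n_epochs=6, n_channels=16, epoch_ms=1200.0,
            pulse_ms=500.0, reset_strength=1.0, seed=200)
        pre_vals, post_vals = [], []
        for subject in range(spec.n_subjects):
            eeg = generate_tms_epochs(spec, subject=subject)
            times, _, meta = subject_metastability(
                eeg, (8.0, 12.0), channels=eeg.planted["cluster_channels"])
            pre = (times >= 250) & (times < 500)
            post = (times > 500) & (times <= 750)
            pre_vals.append(np.nanmean(meta[pre]))
            post_vals.append(np.nanmean(meta[post]))
        _, p = wilcoxon_signed_rank(pre_vals, post_vals, direction="less")
        assert p < 0.05
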