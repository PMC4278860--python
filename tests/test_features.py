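"""Feature-extraction correctness: CAR, filters, smoothing, pipelines."""

import numpy as np
import pytest
from scipy import signal

from ecogkin import (
    BANDS,
    FEATURE_TYPES,
    band_power_feature,
    common_average_reference,
    design_bandpass,
    extract_features,
    lmp_feature,
    moving_average,
    zero_phase_filter,
)
from ecogkin.features import LOG_EPS, band_by_name, _decimate
from ecogkin.synth import RecordingSession


class TestCommonAverageReference:
    def test_two_channel_example(self):
        out = common_average_reference(np.array([[1.0], [3.0]]))
        assert np.allclose(out, [[-1.0], [1.0]])

    def test_identical_channels_zeroed(self):
        x = np.tile(np.random.default_rng(0).standard_normal(100), (4, 1))
        assert np.allclose(common_average_reference(x), 0.0)

    def test_cross_channel_mean_vanishes(self):
        x = np.random.default_rng(1).standard_normal((4, 1000))
        assert np.abs(common_average_reference(x).mean(axis=0)).max() < 1e-12

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError, match="2 channels"):
            common_average_reference(np.ones((1, 10)))


class TestFilterBank:
    @pytest.mark.parametrize("band", BANDS, ids=lambda b: b.name)
    def test_single_pass_response(self, band):
        b = design_bandpass(band, 1000.0)
        assert len(b) == 401
        assert np.allclose(b, b[::-1])  # linear-phase symmetry
        w, h = signal.freqz(b, worN=16384, fs=1000.0)
        gain = np.abs(h)
        center = 0.0 if band.lo == 0 else 0.5 * (band.lo + band.hi)
        assert gain[np.argmin(np.abs(w - center))] >= 0.9
        if band.hi < 60 or band.lo > 60:
            assert gain[np.argmin(np.abs(w - 60.0))] <= 0.01

    def test_delta_passes_dc(self):
        b = design_bandpass(band_by_name("delta"), 1000.0)
        assert abs(b.sum() - 1.0) < 1e-6  # |H(0)| = sum of taps

    def test_band_above_nyquist_rejected(self):
        from ecogkin.features import BandDef

        with pytest.raises(ValueError, match="Nyquist"):
            design_bandpass(BandDef("hg2", 130.0, 200.0), 300.0)


class TestZeroPhase:
    def test_passband_sine_has_zero_delay(self):
        fs, f0 = 1000.0, 10.0
        t = np.arange(5000) / fs
        x = np.sin(2 * np.pi * f0 * t)
        y = zero_phase_filter(x, design_bandpass(band_by_name("mu"), fs))
        xc = np.correlate(y[1500:3500], x[1500:3500], mode="full")
        assert np.argmax(xc) == len(xc) // 2  # peak at lag 0

    def test_constant_through_lowpass_preserved(self):
        x = np.full(3000, 2.5)
        y = zero_phase_filter(x, design_bandpass(band_by_name("delta"), 1000.0))
        assert np.abs(y[1000:2000] - 2.5).max() < 1e-6

    def test_impulse_response_is_autocorrelation_of_taps(self):
        b = design_bandpass(band_by_name("beta"), 1000.0)
        n = 5000
        x = np.zeros(n)
        x[n // 2] = 1.0
        y = zero_phase_filter(x, b)
        acorr = np.correlate(b, b, mode="full")  # length 801, peak center
        got = y[n // 2 - 400 : n // 2 + 401]
        assert np.abs(got - acorr).max() < 1e-12

    def test_short_input_rejected_with_minimum(self):
        b = design_bandpass(band_by_name("mu"), 1000.0)
        with pytest.raises(ValueError, match="1204"):
            zero_phase_filter(np.zeros(100), b)


class TestMovingAverage:
    def test_constant_preserved(self):
        y = moving_average(np.full(500, 5.0), 0.1, 100.0)
        assert np.allclose(y[50:-50], 5.0)

    def test_bidirectional_impulse_is_unit_triangle(self):
        w = 7
        x = np.zeros(201)
        x[100] = 1.0
        y = moving_average(x, w, 1.0, bidirectional=True)
        kernel = y[100 - (w - 1) : 100 + w]
        tri = np.convolve(np.full(w, 1 / w), np.full(w, 1 / w))
        assert np.abs(kernel - tri).max() < 1e-14
        assert abs(y.sum() - 1.0) < 1e-12

    def test_matches_direct_triangle_convolution(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(2000)
        w = 100  # 1 s at 100 Hz
        y = moving_average(x, 1.0, 100.0, bidirectional=True)
        tri = np.convolve(np.full(w, 1 / w), np.full(w, 1 / w))
        direct = np.convolve(x, tri, mode="full")[w - 1 : w - 1 + x.size]
        interior = slice(2 * w, -2 * w)
        assert np.abs(y[interior] - direct[interior]).max() < 1e-12

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError, match="longer"):
            moving_average(np.zeros(10), 1.0, 100.0)


class TestBandPower:
    def test_unit_sine_power_is_half(self):
        t = np.arange(20000) / 1000.0
        x = np.sin(2 * np.pi * 10.0 * t)
        f = band_power_feature(x, band_by_name("mu"))
        interior = f[500:-500]
        assert np.abs(interior - np.log(0.5)).max() < 0.1

    def test_band_selectivity(self):
        t = np.arange(20000) / 1000.0
        x = np.sin(2 * np.pi * 10.0 * t)
        f_mu = band_power_feature(x, band_by_name("mu"))
        f_hg = band_power_feature(x, band_by_name("high_gamma_1"))
        assert np.all(f_mu[300:-300] > f_hg[300:-300])

    def test_zero_signal_gives_log_eps(self):
        f = band_power_feature(np.zeros(5000), band_by_name("beta"))
        assert np.allclose(f, np.log(LOG_EPS))

    def test_oracle_equivalence_stepwise_composition(self):
        """The pipeline equals its five stages composed literally."""
        rng = np.random.default_rng(9)
        x = rng.standard_normal(8000)
        band = band_by_name("beta")
        got = band_power_feature(x, band)
        from ecogkin.features import design_bandpass, moving_average, zero_phase_filter

        stage = zero_phase_filter(x, design_bandpass(band, 1000.0))
        stage = stage[::10]
        stage = np.square(stage)
        stage = moving_average(stage, 1.0, 100.0, bidirectional=True)
        stage = np.log(stage + LOG_EPS)
        assert np.abs(got - stage).max() < 1e-12

    def test_envelope_first_mode_agrees_in_interior(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(20000)
        band = band_by_name("mu")
        a = band_power_feature(x, band, order="paper")
        b = band_power_feature(x, band, order="envelope_first")
        # same smoothed envelope up to estimation differences
        assert np.corrcoef(a[300:-300], b[300:-300])[0, 1] > 0.95

    def test_unknown_order_rejected(self):
        with pytest.raises(ValueError, match="order"):
            band_power_feature(np.zeros(5000), BANDS[0], order="sideways")


class TestLMP:
    def test_constant_preserved(self):
        y = lmp_feature(np.full(10000, 3.0))
        assert np.allclose(y[300:-300], 3.0)

    def test_fast_oscillation_averages_out(self):
        t = np.arange(10000) / 1000.0
        y = lmp_feature(np.sin(2 * np.pi * 50.0 * t))
        assert np.abs(y[300:-300]).max() < 0.01

    def test_slow_ramp_preserved(self):
        x = np.linspace(0.0, 10.0, 10000)
        y = lmp_feature(x)
        slope = np.polyfit(np.arange(300, 700) / 100.0, y[300:700], 1)[0]
        assert abs(slope - 1.0) < 0.01

    def test_short_input_rejected(self):
        with pytest.raises(ValueError, match="4 s"):
            lmp_feature(np.zeros(3000))


class TestExtractFeatures:
    def test_shapes_labels_and_trim(self, small_session, small_features):
        ft = small_features
        T = small_session.kinematics.shape[1]
        m = int(round(ft.trim_margin_s * 100))
        assert ft.values.shape == (small_session.neural.shape[0], 8, T - 2 * m)
        assert ft.feature_types == FEATURE_TYPES
        assert ft.kinematics.shape == (3, T - 2 * m)
        assert np.isfinite(ft.values).all()

    def test_overtrimming_rejected(self):
        rng = np.random.default_rng(0)
        sess = RecordingSession(
            neural=rng.standard_normal((2, 20000)), kinematics=rng.standard_normal((3, 2000))
        )
        with pytest.raises(ValueError, match="10 s"):
            extract_features(sess, trim_margin_s=6.0)


def test_decimation_keeps_every_tenth_sample():
    x = np.arange(25, dtype=float)
    assert np.array_equal(_decimate(x, 1000.0, 100.0), x[::10])
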