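import numpy as np
import pytest

from pwvkit.dspcore import (
    TimeSeries,
    alias_frequency,
    derivative,
    lowpass10,
    nyquist_ok,
    reconstruction_fidelity,
    resample_bandlimited,
    spectral_segments,
    zncc,
)
from pwvkit.errors import (
    InsufficientOverlapError,
    InvalidArgumentError,
    UndefinedCorrelationError,
    UnsupportedRatioError,
)


class TestTimeSeries:
    def test_properties(self):
        ts = TimeSeries(np.zeros(250), 250.0, start_time=1.0)
        assert ts.n == 250
        assert ts.duration == 1.0
        assert ts.period == pytest.approx(0.004)
        assert ts.times[0] == 1.0
        assert ts.times[-1] == pytest.approx(1.0 + 249 / 250)

    def test_rejects_bad_inputs(self):
        with pytest.raises(InvalidArgumentError):
            TimeSeries(np.zeros(10), 0.0)
        with pytest.raises(InvalidArgumentError):
            TimeSeries(np.array([1.0, np.nan]), 100.0)
        with pytest.raises(InvalidArgumentError):
            TimeSeries(np.zeros((2, 2)), 100.0)


class TestNyquistOk:
    def test_250_vs_120(self):
        assert nyquist_ok(250.0, 120.0) is True

    def test_125_vs_120(self):
        assert nyquist_ok(125.0, 120.0) is False

    @pytest.mark.parametrize("band", [0.5, 10.0, 62.5, 1000.0])
    def test_exactly_twice_band_fails(self, band):
        # strict inequality: fs = 2B is not sufficient
        assert nyquist_ok(2 * band, band) is False

    def test_nonpositive_rejected(self):
        with pytest.raises(InvalidArgumentError):
            nyquist_ok(-250.0, 120.0)
        with pytest.raises(InvalidArgumentError):
            nyquist_ok(250.0, 0.0)


class TestAliasFrequency:
    @pytest.mark.parametrize(
        "f,fs,expected",
        [(60.0, 250.0, 60.0), (120.0, 125.0, 5.0), (60.0, 100.0, 40.0), (0.0, 250.0, 0.0)],
    )
    def test_examples(self, f, fs, expected):
        assert alias_frequency(f, fs) == pytest.approx(expected)

    def test_invalid_args(self):
        with pytest.raises(InvalidArgumentError):
            alias_frequency(60.0, 0.0)
        with pytest.raises(InvalidArgumentError):
            alias_frequency(-1.0, 100.0)


class TestResampleBandlimited:
    def test_constant_dc_preserved(self):
        ts = TimeSeries(np.full(100, 2.5), 250.0)
        out = resample_bandlimited(ts, 10_000.0)
        assert out.n == 4000  # ceil(100 * 40)
        assert out.fs == 10_000.0
        np.testing.assert_allclose(out.samples, 2.5, atol=1e-9)

    def test_output_length_ceiling(self):
        ts = TimeSeries(np.zeros(101), 250.0)
        out = resample_bandlimited(ts, 375.0)  # p/q = 3/2
        assert out.n == int(np.ceil(101 * 3 / 2))

    def test_sine_matches_analytic(self):
        t = np.arange(0, 10, 1 / 250)
        ts = TimeSeries(np.sin(2 * np.pi * 2 * t), 250.0)
        out = resample_bandlimited(ts, 10_000.0)
        tt = np.arange(out.n) / 10_000.0
        err = np.abs(out.samples - np.sin(2 * np.pi * 2 * tt))
        trim = 5000  # 0.5 s per edge
        assert err[trim:-trim].max() < 1e-3

    def test_identity_when_rates_equal(self):
        ts = TimeSeries(np.random.default_rng(0).standard_normal(64), 250.0)
        out = resample_bandlimited(ts, 250.0)
        np.testing.assert_array_equal(out.samples, ts.samples)

    def test_irrational_ratio_rejected(self):
        ts = TimeSeries(np.zeros(100), 1.0)
        with pytest.raises(UnsupportedRatioError):
            resample_bandlimited(ts, np.sqrt(2))

    def test_empty_rejected(self):
        with pytest.raises(InvalidArgumentError):
            resample_bandlimited(TimeSeries(np.zeros(0), 250.0), 500.0)


class TestLowpass10:
    def test_constant_preserved(self):
        ts = TimeSeries(np.full(2000, 3.7), 250.0)
        out = lowpass10(ts)
        np.testing.assert_allclose(out.samples, 3.7, atol=1e-3 * 3.7)
        assert out.n == ts.n

    def test_60hz_tone_suppressed(self):
        t = np.arange(5000) / 250.0
        ts = TimeSeries(np.sin(2 * np.pi * 60 * t), 250.0)
        out = lowpass10(ts)
        in_rms = np.sqrt(np.mean(ts.samples**2))
        out_rms = np.sqrt(np.mean(out.samples**2))
        assert out_rms <= 0.01 * in_rms

    def test_slow_peak_not_shifted(self):
        # Gaussian bump (band << 10 Hz) centered mid-signal: argmax moves <= 1 sample
        fs = 250.0
        t = np.arange(0, 8, 1 / fs)
        x = np.exp(-0.5 * ((t - 4.0) / 0.08) ** 2)
        out = lowpass10(TimeSeries(x, fs))
        assert abs(int(np.argmax(out.samples)) - int(np.argmax(x))) <= 1

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(InvalidArgumentError):
            lowpass10(TimeSeries(np.zeros(100), 15.0), cutoff=10.0)

    def test_too_short_signal_rejected(self):
        with pytest.raises(InvalidArgumentError):
            lowpass10(TimeSeries(np.zeros(50), 250.0))


class TestDerivative:
    def test_constant_is_zero(self):
        out = derivative(TimeSeries(np.full(100, 5.0), 100.0))
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-12)
        assert out.n == 100 and out.fs == 100.0

    def test_ramp_slope(self):
        t = np.arange(100) / 100.0
        out = derivative(TimeSeries(3.0 * t, 100.0))
        np.testing.assert_allclose(out.samples, 3.0, atol=1e-9)

    def test_sine_matches_cosine(self):
        fs = 1000.0
        t = np.arange(0, 2, 1 / fs)
        out = derivative(TimeSeries(np.sin(2 * np.pi * t), fs))
        expected = 2 * np.pi * np.cos(2 * np.pi * t)
        assert np.max(np.abs(out.samples[1:-1] - expected[1:-1])) < 1e-3

    def test_single_sample_rejected(self):
        with pytest.raises(InvalidArgumentError):
            derivative(TimeSeries(np.zeros(1), 100.0))


class TestSpectralSegments:
    def test_19s_gives_three_segments(self):
        ts = TimeSeries(np.random.default_rng(0).standard_normal(19 * 250), 250.0)
        segs = spectral_segments(ts, seg_duration=5.0)
        assert len(segs) == 3
        assert [s.index for s in segs] == [0, 1, 2]
        assert segs[1].start_time == pytest.approx(5.0)

    def test_pure_tone_dominant(self):
        t = np.arange(0, 5, 1 / 250)
        ts = TimeSeries(np.sin(2 * np.pi * 2 * t), 250.0)
        (seg,) = spectral_segments(ts, seg_duration=5.0)
        assert seg.dominant_freq == pytest.approx(2.0, abs=0.2)
        assert np.all(seg.magnitudes >= 0)
        assert seg.frequencies[-1] == pytest.approx(125.0)

    def test_constant_has_no_power_above_floor(self):
        ts = TimeSeries(np.full(5 * 250, 4.0), 250.0)
        (seg,) = spectral_segments(ts, seg_duration=5.0)
        above = seg.magnitudes[seg.frequencies >= 0.5]
        assert np.max(above) < 1e-9

    def test_too_short_segment_rejected(self):
        with pytest.raises(InvalidArgumentError):
            spectral_segments(TimeSeries(np.zeros(100), 250.0), seg_duration=0.01)


class TestZncc:
    def test_self_is_one(self):
        a = TimeSeries(np.random.default_rng(1).standard_normal(100), 100.0)
        assert zncc(a, a) == pytest.approx(1.0)

    def test_affine_invariance(self):
        x = np.random.default_rng(2).standard_normal(100)
        a = TimeSeries(x, 100.0)
        b = TimeSeries(2 * x + 3, 100.0)
        assert zncc(a, b) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # centered vectors give dot = -1/3 over norms 2/3 -> -0.5
        a = TimeSeries(np.array([1.0, 0.0, 0.0]), 1.0)
        b = TimeSeries(np.array([0.0, 1.0, 0.0]), 1.0)
        assert zncc(a, b) == pytest.approx(-0.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            zncc(TimeSeries(np.zeros(3), 1.0), TimeSeries(np.zeros(4), 1.0))

    def test_zero_variance_rejected(self):
        a = TimeSeries(np.ones(10), 1.0)
        b = TimeSeries(np.arange(10.0), 1.0)
        with pytest.raises(UndefinedCorrelationError):
            zncc(a, b)


class TestReconstructionFidelity:
    def test_identical_signals(self):
        fs = 250.0
        t = np.arange(0, 5, 1 / fs)
        ts = TimeSeries(np.sin(2 * np.pi * 1.5 * t) + 0.1 * np.sin(2 * np.pi * 4 * t), fs)
        assert reconstruction_fidelity(ts, ts) == pytest.approx(1.0, abs=1e-9)

    def test_decimate_reconstruct_round_trip(self, t1_bundle):
        _, reference, acquired = t1_bundle
        z = reconstruction_fidelity(reference.prox, acquired["prox"])
        assert z >= 0.99

    def test_unrelated_noise_uncorrelated(self):
        rng = np.random.default_rng(3)
        fs = 10_000.0
        n = int(19 * fs)
        a = TimeSeries(rng.standard_normal(n), fs)
        b = TimeSeries(rng.standard_normal(n), fs)
        assert abs(reconstruction_fidelity(a, b)) < 0.2

    def test_insufficient_overlap_rejected(self):
        fs = 250.0
        ts = TimeSeries(np.random.default_rng(4).standard_normal(int(1.5 * fs)), fs)
        with pytest.raises(InsufficientOverlapError):
            reconstruction_fidelity(ts, ts, edge_trim=0.5)


def test_round_trip_invariant():
    """Noiseless band-limited content: 10 kHz -> 250 Hz -> 10 kHz matches the
    original with ZNCC >= 0.99 and max abs error <= 1% of amplitude."""
    from pwvkit.synthwave import SynthConfig, generate_recording

    cfg = SynthConfig(duration=19.0, heart_rate_bpm=75.0, ibi_jitter_sd=0.03,
                      ptt_true=0.008, mains_amps=(0.05,), drift_amp=0.05, seed=1)
    reference = generate_recording(cfg, 10_000.0)
    acq = TimeSeries(reference.prox.samples[::40], 250.0)
    recon = resample_bandlimited(acq, 10_000.0)
    ref_f = lowpass10(reference.prox)
    rec_f = lowpass10(recon)
    k = 5000
    m = min(ref_f.n, rec_f.n)
    r = ref_f.samples[k : m - k]
    c = rec_f.samples[k : m - k]
    amp = r.max() - r.min()
    assert np.max(np.abs(r - c)) <= 0.01 * amp
    assert zncc(TimeSeries(r, 1.0), TimeSeries(c, 1.0)) >= 0.99


def test_aliased_tone_folds():
    """A tone above fs/2 reappears at alias_frequency(f, fs) after reconstruction."""
    fs, f = 125.0, 80.0
    t = np.arange(0, 10, 1 / fs)
    tone = TimeSeries(np.sin(2 * np.pi * f * t), fs)
    up = resample_bandlimited(tone, 1000.0)
    for seg in spectral_segments(up, seg_duration=5.0):
        assert seg.dominant_freq == pytest.approx(alias_frequency(f, fs), abs=0.3)
        assert abs(seg.dominant_freq - f) > 30.0
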