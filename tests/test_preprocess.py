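import numpy as np
import pytest

from gaitnirs import (
    FilterSpec,
    GroundTruth,
    WaveletSpec,
    bandpass,
    build_design,
    default_pairing,
    generate_recording,
    preprocess,
    recording_to_hemoglobin,
    short_channel_regress,
    wavelet_correct,
)
from gaitnirs.optics import HemoTimeSeries

FS = 10.0
N = 6000
T = np.arange(N) / FS
TRIM = slice(1000, -1000)


def series(long=None, short=None):
    long = np.zeros((N, 1)) if long is None else np.atleast_2d(long.T).T
    short = np.zeros((N, 0)) if short is None else np.atleast_2d(short.T).T
    return HemoTimeSeries(
        time=T, hbo=long, hhb=np.zeros_like(long),
        short_hbo=short, short_hhb=np.zeros_like(short),
    )


def amp(x):
    return float(np.sqrt(2 * np.mean(x[TRIM] ** 2)))


class TestBandpass:
    def test_zero_in_zero_out(self):
        assert np.allclose(bandpass(series()).hbo, 0.0)

    def test_passband_sinusoid_preserved(self):
        out = bandpass(series(long=np.sin(2 * np.pi * 0.1 * T))).hbo[:, 0]
        assert 0.9 <= amp(out) <= 1.001

    def test_stopband_sinusoid_suppressed(self):
        out = bandpass(series(long=np.sin(2 * np.pi * 1.5 * T))).hbo[:, 0]
        assert np.abs(out[TRIM]).max() < 0.05

    def test_zero_phase_peak_at_lag_zero(self):
        x = np.sin(2 * np.pi * 0.05 * T) + 0.5 * np.sin(2 * np.pi * 0.2 * T)
        y = bandpass(series(long=x)).hbo[:, 0]
        lags = np.arange(-50, 51)
        cc = [np.corrcoef(x[1000 + l : 5000 + l], y[1000:5000])[0, 1] for l in lags]
        assert lags[int(np.argmax(cc))] == 0

    def test_band_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(series(), FilterSpec(band=(0.01, 6.0)))


class TestWavelet:
    def test_output_length_equals_input_length(self):
        for n in (1000, 1023, 4096):
            t = np.arange(n) / FS
            h = HemoTimeSeries(
                time=t, hbo=np.sin(t)[:, None], hhb=np.zeros((n, 1)),
                short_hbo=np.zeros((n, 0)), short_hhb=np.zeros((n, 0)),
            )
            assert wavelet_correct(h).hbo.shape[0] == n

    def test_clean_signal_barely_distorted(self):
        clean = np.sin(2 * np.pi * 0.0167 * T) + 0.3 * np.sin(2 * np.pi * 0.1 * T + 1.0)
        out = wavelet_correct(series(long=clean)).hbo[:, 0]
        assert np.corrcoef(clean, out)[0, 1] > 0.95

    def test_large_spike_suppressed(self, rng):
        base = np.sin(2 * np.pi * 0.0167 * T) + 0.05 * rng.normal(size=N)
        spiked = base.copy()
        spiked[3000:3010] += 10.0
        out = wavelet_correct(series(long=spiked)).hbo[:, 0]
        dev_before = np.abs(spiked - base).max()
        dev_after = np.abs(out - base).max()
        assert dev_after <= 0.2 * dev_before

    def test_invalid_family_rejected(self):
        with pytest.raises(ValueError, match="wavelet"):
            WaveletSpec(family="nosuchwavelet")

    def test_alpha_bounds(self):
        with pytest.raises(ValueError):
            WaveletSpec(alpha=1.5)


class TestShortChannelRegression:
    def test_zero_short_channel_passes_long_through(self):
        long = np.sin(2 * np.pi * 0.05 * T)
        h = series(long=long, short=np.zeros(N))
        out = short_channel_regress(h, pairing={0: 0})
        assert np.allclose(out.hbo[:, 0], long)

    def test_perfectly_proportional_long_is_zeroed(self):
        s = np.sin(2 * np.pi * 0.1 * T)
        h = series(long=2.0 * s, short=s)
        out = short_channel_regress(h, pairing={0: 0})
        assert np.allclose(out.hbo[:, 0], 0.0, atol=1e-12)

    def test_residual_orthogonal_and_variance_reduced(self, rng):
        s = np.sin(2 * np.pi * 0.1 * T) + 0.2 * rng.normal(size=N)
        y = 0.8 * s + rng.normal(size=N)
        h = series(long=y, short=s)
        out = short_channel_regress(h, pairing={0: 0}).hbo[:, 0]
        assert abs(out @ s) / (np.linalg.norm(s) * np.linalg.norm(out)) < 1e-10
        assert out.var() < y.var()

    def test_idempotent(self, rng):
        s = rng.normal(size=N)
        y = 0.5 * s + rng.normal(size=N)
        h = series(long=y, short=s)
        once = short_channel_regress(h, pairing={0: 0})
        twice = short_channel_regress(once, pairing={0: 0})
        assert np.allclose(once.hbo, twice.hbo, atol=1e-10)

    def test_incomplete_pairing_rejected(self, small_recording, montage):
        hemo = recording_to_hemoglobin(small_recording)
        with pytest.raises(ValueError, match="pairing"):
            short_channel_regress(hemo, pairing={0: 0})

    def test_default_pairing_covers_all_long_channels(self, montage):
        pairing = default_pairing(montage)
        assert set(pairing) == set(range(34))
        assert set(pairing.values()) <= set(range(4))


def test_superficial_contamination_reduced_on_every_coupled_channel(
    montage, short_paradigm
):
    truth = GroundTruth.default(montage, seed=21)
    rec = generate_recording(montage, short_paradigm, truth, fs=FS, seed=21)
    hemo = recording_to_hemoglobin(rec, age=truth.age)
    filt = bandpass(hemo)
    reg = short_channel_regress(filt, montage=montage)
    task = build_design(short_paradigm, FS, hemo.time.size, drift_order=0).X[:, 0]
    task = task - task.mean()
    for c in range(montage.n_long):
        for arr_b, arr_a in ((filt.hbo, reg.hbo), (filt.hhb, reg.hhb)):
            before = arr_b[:, c] - (arr_b[:, c] @ task) / (task @ task) * task
            after = arr_a[:, c] - (arr_a[:, c] @ task) / (task @ task) * task
            assert after.var() < before.var()


def test_preprocess_runs_in_documented_order(small_recording, montage):
    hemo = recording_to_hemoglobin(small_recording)
    manual = short_channel_regress(
        bandpass(wavelet_correct(hemo)), montage=montage
    )
    auto = preprocess(hemo, montage=montage)
    assert np.allclose(manual.hbo, auto.hbo)
    with pytest.raises(ValueError, match="unknown stage"):
        preprocess(hemo, montage=montage, order=("bogus",))
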