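"""Preprocessing chain: filter, epoch, downsample, channels, scaling."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from errpnet.io_store import EpochSet, RawRecording
from errpnet.preprocess import (PROFILES, DatasetProfile, EpochWindow,
                                FilterSpec, bandpass_filter, downsample,
                                extract_epochs, run_pipeline, scale_amplitude,
                                select_channels)


def analytic_filtfilt_gain(f, spec: FilterSpec, fs: float) -> float:
    """Squared Butterworth bandpass magnitude of the forward-backward filter.

    The digital filter is the bilinear transform of the analog prototype
    with prewarped band edges, so its response at frequency f equals the
    analog response at the warped frequency 2*fs*tan(pi*f/fs); zero-phase
    application squares the magnitude.
    """
    warp = lambda g: 2 * fs * np.tan(np.pi * g / fs)
    w, w1, w2 = warp(f), warp(spec.low_hz), warp(spec.high_hz)
    h2 = 1.0 / (1.0 + ((w ** 2 - w1 * w2) / (w * (w2 - w1))) ** (2 * spec.order))
    return h2  # |H|^2 == filtfilt amplitude gain


def measured_gain(f, fs=512.0):
    t = np.arange(int(20 * fs)) / fs
    x = np.sin(2 * np.pi * f * t)[None, :]
    y = bandpass_filter(x, fs)
    mid = y[0, int(5 * fs):int(15 * fs)]
    return np.sqrt(2) * mid.std()


def test_filter_defaults():
    spec = FilterSpec()
    assert (spec.low_hz, spec.high_hz, spec.order) == (1.0, 10.0, 4)


def test_zero_in_zero_out():
    assert np.allclose(bandpass_filter(np.zeros((2, 1000)), 512.0), 0.0)


@pytest.mark.parametrize("freq,low,high", [(5.0, 0.9, 1.0), (40.0, 0.0, 0.05)])
def test_sinusoid_attenuation_bounds(freq, low, high):
    g = measured_gain(freq)
    assert low <= g <= high


@pytest.mark.parametrize("freq", [2.0, 5.0, 8.0, 15.0, 25.0, 40.0])
def test_gain_matches_analytic_oracle(freq):
    """Measured passband/stopband gain within 1% of the analytic response."""
    expected = analytic_filtfilt_gain(freq, FilterSpec(), 512.0)
    assert measured_gain(freq) == pytest.approx(expected, abs=0.01)


def test_filter_linearity():
    rng = np.random.default_rng(0)
    x, y = rng.standard_normal((2, 2, 600))
    a, b = 2.5, -1.3
    lhs = bandpass_filter(a * x + b * y, 512.0)
    rhs = a * bandpass_filter(x, 512.0) + b * bandpass_filter(y, 512.0)
    np.testing.assert_allclose(lhs, rhs, rtol=1e-9, atol=1e-12)


def test_filter_input_validation():
    with pytest.raises(ValueError):
        bandpass_filter(np.zeros((2, 100)), fs=15.0)  # below 2 * high edge
    with pytest.raises(ValueError):
        bandpass_filter(np.full((1, 100), np.nan), fs=512.0)


def test_extract_epochs_window_and_counts():
    rng = np.random.default_rng(1)
    sig = rng.standard_normal((2, 2048))
    events = [(0, 1), (512, 0), (1024, 1)]
    es = extract_epochs(sig, 512.0, events, EpochWindow(1.0))
    assert len(es) == 3
    assert es.epoch_shape == (2, 512)
    np.testing.assert_array_equal(es.labels, [1, 0, 1])  # event order kept
    np.testing.assert_array_equal(es.data[1], sig[:, 512:1024].astype(np.float32))


def test_extract_epochs_empty_and_out_of_bounds():
    sig = np.zeros((2, 1000))
    assert len(extract_epochs(sig, 512.0, [], EpochWindow(1.0))) == 0
    with pytest.raises(ValueError, match="event 0"):
        extract_epochs(sig, 512.0, [(600, 1)], EpochWindow(1.0))


@pytest.mark.parametrize("n_in,fs_in,fs_out,n_out", [
    (512, 512.0, 64.0, 64),   # 1-s trial to canonical rate
    (128, 256.0, 128.0, 64),  # 0.5-s pre-epoched trial
    (100, 100.0, 100.0, 100),
])
def test_downsample_lengths(n_in, fs_in, fs_out, n_out):
    x = np.random.default_rng(2).standard_normal((3, 2, n_in))
    assert downsample(x, fs_in, fs_out).shape[-1] == n_out


def test_downsample_identity_and_errors():
    x = np.random.default_rng(3).standard_normal((2, 100))
    np.testing.assert_array_equal(downsample(x, 64.0, 64.0), x)
    with pytest.raises(ValueError):
        downsample(x, 64.0, 128.0)


def test_select_channels_and_substitution():
    rng = np.random.default_rng(4)
    names = tuple(f"E{i}" for i in range(6)) + ("FCz", "Cz")
    es = EpochSet(rng.standard_normal((4, 8, 64)), np.zeros(4), np.full(4, "a"),
                  np.full(4, "1"), np.full(4, "t"), names, 64.0)
    out = select_channels(es)
    assert out.channel_names == ("FCz", "Cz")
    np.testing.assert_array_equal(out.data[:, 0], es.data[:, 6])
    # montage without FCz: Fz substitutes
    names2 = ("Fz", "Cz", "Pz")
    es2 = EpochSet(rng.standard_normal((4, 3, 64)), np.zeros(4), np.full(4, "a"),
                   np.full(4, "1"), np.full(4, "t"), names2, 64.0)
    out2 = select_channels(es2, substitution={"FCz": "Fz"})
    assert out2.channel_names == ("Fz", "Cz")
    with pytest.raises(ValueError, match="FCz"):
        select_channels(es2)
    # already canonical: unchanged
    out3 = select_channels(out)
    np.testing.assert_array_equal(out3.data, out.data)


@given(st.floats(min_value=1e-3, max_value=1e6))
def test_scale_amplitude_exact_ratio(factor):
    rng = np.random.default_rng(5)
    es = EpochSet(rng.standard_normal((3, 2, 64)) + 1.0, np.zeros(3), np.full(3, "a"),
                  np.full(3, "1"), np.full(3, "t"), ("FCz", "Cz"), 64.0)
    out = scale_amplitude(es, factor)
    np.testing.assert_allclose(out.data / es.data, factor, rtol=1e-6)


def test_scale_amplitude_default_and_errors():
    es = EpochSet(np.ones((1, 2, 64)), np.zeros(1), np.full(1, "a"),
                  np.full(1, "1"), np.full(1, "t"), ("FCz", "Cz"), 64.0)
    assert scale_amplitude(es).data[0, 0, 0] == 1000.0
    np.testing.assert_array_equal(scale_amplitude(
        EpochSet(np.zeros((1, 2, 64)), np.zeros(1), np.full(1, "a"), np.full(1, "1"),
                 np.full(1, "t"), ("FCz", "Cz"), 64.0)).data, 0.0)
    with pytest.raises(ValueError):
        scale_amplitude(es, -1.0)


def _cursor_recording(seed=6, n_ch=4):
    rng = np.random.default_rng(seed)
    names = ("FCz", "Cz") + tuple(f"E{i}" for i in range(n_ch - 2))
    sig = rng.standard_normal((n_ch, 6 * 512)) * 1e-5
    events = [(512, 1), (1536, 0), (2560, 1)]
    return RawRecording(sig, 512.0, names, events)


def test_pipeline_bnci_profile_canonical_shape():
    es = run_pipeline(_cursor_recording(), PROFILES["bnci_cursor"])
    assert es.epoch_shape == (2, 64)
    assert es.sampling_rate == 64.0
    np.testing.assert_array_equal(es.labels, [1, 0, 1])


def test_pipeline_gaze_profile_skips_filter():
    rng = np.random.default_rng(7)
    pre = EpochSet(rng.standard_normal((5, 3, 128)), np.zeros(5), np.full(5, "a"),
                   np.full(5, "1"), np.full(5, "g"), ("FCz", "Cz", "Pz"), 256.0)
    es = run_pipeline(pre, PROFILES["gaze_speller"])
    assert es.epoch_shape == (2, 64)
    # no filtering: output equals decimated, selected, scaled input exactly
    np.testing.assert_allclose(es.data, pre.data[:, :2, ::2] * 1000.0, rtol=1e-6)


def test_pipeline_equals_manual_stage_composition():
    raw = _cursor_recording()
    profile = PROFILES["bnci_cursor"]
    manual = bandpass_filter(raw.signal, raw.sampling_rate, profile.filter_spec)
    manual_set = extract_epochs(manual, raw.sampling_rate, raw.events, profile.window,
                                channel_names=raw.channel_names)
    manual_data = downsample(manual_set.data, raw.sampling_rate, profile.target_rate)
    manual_set = EpochSet(manual_data, manual_set.labels, manual_set.subjects,
                          manual_set.sessions, manual_set.tasks,
                          manual_set.channel_names, profile.target_rate)
    manual_set = scale_amplitude(select_channels(manual_set, profile.channels), 1000.0)
    pipeline = run_pipeline(raw, profile)
    np.testing.assert_allclose(pipeline.data, manual_set.data, rtol=1e-6)


def test_pipeline_rejects_wrong_duration():
    raw = _cursor_recording()
    bad = DatasetProfile("bad", FilterSpec(), EpochWindow(0.5), 64.0)
    with pytest.raises(ValueError):
        run_pipeline(raw, bad)
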