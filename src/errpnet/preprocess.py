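"""Raw EEG to canonical (2, 64) epochs.

The preprocessing chain mirrors standard offline ErrP practice: a 1-10 Hz
fourth-order Butterworth bandpass applied zero-phase to the continuous
recording, epoch extraction over the trial window [onset, onset + duration),
downsampling to 64 samples per epoch, selection of the two frontocentral
channels (FCz, Cz; Fz substitutes for FCz on montages lacking it) and a
x1000 amplitude expansion.  Each stage is exposed separately and
:func:`run_pipeline` composes them according to a dataset profile.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io_store import EpochSet, RawRecording

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth bandpass specification (defaults: 1-10 Hz, order 4)."""

    low_hz: float = 1.0
    high_hz: float = 10.0
    order: int = 4

    def __post_init__(self):
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")


@dataclass(frozen=True)
class EpochWindow:
    """Trial window starting at the event onset, ``duration`` seconds long."""

    duration: float = 1.0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def bandpass_filter(data: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Zero-phase Butterworth bandpass, per channel.

    Forward-backward (``sosfiltfilt``) application doubles the effective
    order of attenuation and keeps Ne/Pe peak latencies undistorted.
    """
    data = np.asarray(data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite samples in input")
    if fs <= 2 * spec.high_hz:
        raise ValueError(f"sampling rate {fs} Hz too low for a {spec.high_hz} Hz passband edge")
    sos = sps.butter(spec.order, [spec.low_hz, spec.high_hz], btype="bandpass",
                     fs=fs, output="sos")
    return sps.sosfiltfilt(sos, data, axis=-1)


def extract_epochs(
    signal: np.ndarray,
    fs: float,
    events: list[tuple[int, int]],
    window: EpochWindow,
    subject_id: str = "s01",
    session_id: str = "1",
    task_id: str = "task",
    channel_names: tuple[str, ...] | None = None,
) -> EpochSet:
    """Cut one epoch per (onset sample, label) event.

    The window is half-open, ``[onset, onset + round(duration * fs))``, so a
    1-s trial at 512 Hz yields exactly 512 samples.
    """
    signal = np.asarray(signal, dtype=np.float64)
    n_ch, n_samp = signal.shape
    if channel_names is None:
        channel_names = tuple(f"ch{i}" for i in range(n_ch))
    length = round(window.duration * fs)
    epochs, labels = [], []
    for k, (onset, label) in enumerate(events):
        if onset < 0 or onset + length > n_samp:
            raise ValueError(
                f"event {k} (onset {onset}) window [{onset}, {onset + length}) "
                f"exceeds recording of {n_samp} samples")
        epochs.append(signal[:, onset:onset + length])
        labels.append(label)
    data = np.asarray(epochs, dtype=np.float64) if epochs else np.empty((0, n_ch, length))
    n = len(labels)
    return EpochSet(data, np.asarray(labels, dtype=np.int8).reshape(n),
                    np.full(n, subject_id), np.full(n, session_id), np.full(n, task_id),
                    channel_names, fs)


def downsample(data: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Reduce the sampling rate of epoched data along the last axis.

    Integer rate ratios use plain decimation (every k-th sample): the 1-10 Hz
    bandpass applied upstream already provides the anti-alias protection for
    the 64 Hz target.  Non-integer ratios fall back to polyphase resampling.
    Output length is ``round(n_in * fs_out / fs_in)``.
    """
    if fs_out > fs_in:
        raise ValueError(f"cannot downsample {fs_in} Hz -> {fs_out} Hz")
    data = np.asarray(data, dtype=np.float64)
    if fs_out == fs_in:
        return data.copy()
    ratio = fs_in / fs_out
    if abs(ratio - round(ratio)) < 1e-9:
        return data[..., ::int(round(ratio))].copy()
    g = math.gcd(int(fs_in), int(fs_out))
    return sps.resample_poly(data, int(fs_out) // g, int(fs_in) // g, axis=-1)


def _downsample_epochset(epochset: EpochSet, fs_out: float) -> EpochSet:
    data = downsample(epochset.data, epochset.sampling_rate, fs_out)
    return EpochSet(data, epochset.labels, epochset.subjects, epochset.sessions,
                    epochset.tasks, epochset.channel_names, fs_out, epochset.metadata)


def select_channels(
    epochset: EpochSet,
    requested: tuple[str, ...] = ("FCz", "Cz"),
    substitution: dict[str, str] | None = None,
) -> EpochSet:
    """Reduce a set to the requested channels, in the requested order.

    When a requested channel is absent and ``substitution`` maps it to a
    present one (e.g. ``{"FCz": "Fz"}`` for montages without FCz), the
    substitute is used and the swap is logged.
    """
    substitution = substitution or {}
    indices = []
    resolved = []
    for name in requested:
        if name in epochset.channel_names:
            chosen = name
        elif name in substitution and substitution[name] in epochset.channel_names:
            chosen = substitution[name]
            logger.info("channel substitution: %s -> %s", name, chosen)
        else:
            raise ValueError(f"channel '{name}' not present and no substitution applies")
        indices.append(epochset.channel_names.index(chosen))
        resolved.append(chosen)
    return EpochSet(epochset.data[:, indices, :], epochset.labels, epochset.subjects,
                    epochset.sessions, epochset.tasks, tuple(resolved),
                    epochset.sampling_rate, epochset.metadata)


def scale_amplitude(epochset: EpochSet, factor: float = 1000.0) -> EpochSet:
    """Multiply every sample by ``factor`` (default: the x1000 expansion)."""
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    return EpochSet(epochset.data.astype(np.float64) * factor, epochset.labels,
                    epochset.subjects, epochset.sessions, epochset.tasks,
                    epochset.channel_names, epochset.sampling_rate, epochset.metadata)


@dataclass(frozen=True)
class DatasetProfile:
    """Per-dataset preprocessing recipe.

    ``filter_spec=None`` skips filtering (for distributions shipped already
    preprocessed, such as the gaze-speller epochs).
    """

    name: str
    filter_spec: FilterSpec | None
    window: EpochWindow
    target_rate: float
    channels: tuple[str, ...] = ("FCz", "Cz")
    substitution: dict[str, str] = field(default_factory=dict)
    scale_factor: float = 1000.0


#: recipes for the three public ErrP datasets
PROFILES: dict[str, DatasetProfile] = {
    # 64ch, 512 Hz, 1-s trials -> 64 Hz
    "bnci_cursor": DatasetProfile("bnci_cursor", FilterSpec(), EpochWindow(1.0), 64.0),
    # 12ch montage lacks FCz; Fz substitutes
    "lsc_speller": DatasetProfile("lsc_speller", FilterSpec(), EpochWindow(1.0), 64.0,
                                  substitution={"FCz": "Fz"}),
    # shipped pre-filtered and pre-epoched; 0.5-s trials at 256 Hz -> 128 Hz
    "gaze_speller": DatasetProfile("gaze_speller", None, EpochWindow(0.5), 128.0),
}


def run_pipeline(raw, profile: DatasetProfile, **epoch_ids) -> EpochSet:
    """Full preprocessing chain for one recording or pre-epoched set.

    ``raw`` is either a :class:`~errpnet.io_store.RawRecording` (filter ->
    epoch -> downsample -> channels -> scale) or an :class:`EpochSet` of
    oversized epochs (downsample -> channels -> scale).  Output epochs are
    always (2, 64).
    """
    if isinstance(raw, RawRecording):
        sig = raw.signal
        if profile.filter_spec is not None:
            sig = bandpass_filter(sig, raw.sampling_rate, profile.filter_spec)
        epochset = extract_epochs(sig, raw.sampling_rate, raw.events, profile.window,
                                  channel_names=raw.channel_names, **epoch_ids)
    elif isinstance(raw, EpochSet):
        epochset = raw
        if profile.filter_spec is not None:
            data = bandpass_filter(epochset.data, epochset.sampling_rate, profile.filter_spec)
            epochset = EpochSet(data, epochset.labels, epochset.subjects, epochset.sessions,
                                epochset.tasks, epochset.channel_names,
                                epochset.sampling_rate, epochset.metadata)
    else:
        raise TypeError(f"unsupported raw input type {type(raw).__name__}")
    epochset = _downsample_epochset(epochset, profile.target_rate)
    epochset = select_channels(epochset, profile.channels, profile.substitution)
    epochset = scale_amplitude(epochset, profile.scale_factor)
    if epochset.epoch_shape[1] != 64:
        raise ValueError(
            f"profile '{profile.name}' produced {epochset.epoch_shape[1]}-sample epochs, expected 64")
    epochset.validate_canonical()
    return epochset
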