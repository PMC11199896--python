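"""Synthetic error-related potential (ErrP) epochs.

Generates labelled (2, 64) epochs at 64 Hz with the statistical structure
the classification method assumes: error epochs carry a sharp negative
deflection (the error-related negativity, Ne) followed by a broader positive
deflection (the error positivity, Pe) on both frontocentral channels;
correct epochs are background activity only.  Both components are modelled
as Gaussian-windowed bumps — a deliberately simple morphology that captures
the biphasic Ne/Pe shape without claiming physiological detail.

Realism knobs: per-subject latency/amplitude jitter (inter-individual
variability), 1/f-shaped background noise, an ~20% error prevalence
matching public ErrP corpora, a per-task distribution shift (global
amplitude scale, latency offset, noise multiplier) for transfer-learning
experiments, and a "degraded subject" preset (near-zero template, doubled
noise) reproducing the low-signal-quality participant pathology seen in
real recordings.

Determinism: a single top-level seed; per-subject streams are spawned via
``np.random.SeedSequence(seed, spawn_key=(subject_index,))`` so output is
independent of generation order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .io_store import EpochSet

SAMPLING_RATE = 64.0
N_SAMPLES = 64
CHANNELS = ("FCz", "Cz")


@dataclass(frozen=True)
class ErpTemplate:
    """Biphasic Ne/Pe waveform parameters (seconds, scaled microvolts)."""

    ne_latency_s: float = 0.25
    ne_width_s: float = 0.05
    ne_amplitude: float = -5.0
    pe_latency_s: float = 0.40
    pe_width_s: float = 0.07
    pe_amplitude: float = 4.0
    channel_gains: tuple[float, float] = (1.0, 0.8)

    def __post_init__(self):
        if not self.ne_latency_s < self.pe_latency_s:
            raise ValueError("Ne must precede Pe")
        if not (self.ne_amplitude <= 0.0 <= self.pe_amplitude):
            raise ValueError("need ne_amplitude <= 0 <= pe_amplitude")
        if min(self.channel_gains) < 0:
            raise ValueError("channel gains must be non-negative")

    def waveform(self, n_samples: int = N_SAMPLES, fs: float = SAMPLING_RATE) -> np.ndarray:
        """Render the template as a (2, n_samples) array."""
        t = np.arange(n_samples) / fs
        ne = self.ne_amplitude * np.exp(-0.5 * ((t - self.ne_latency_s) / self.ne_width_s) ** 2)
        pe = self.pe_amplitude * np.exp(-0.5 * ((t - self.pe_latency_s) / self.pe_width_s) ** 2)
        mono = ne + pe
        return np.asarray(self.channel_gains)[:, None] * mono[None, :]


@dataclass(frozen=True)
class TaskShift:
    """Distributional shift applied to a target task relative to a source."""

    amplitude_scale: float = 1.0
    latency_offset_s: float = 0.0
    noise_multiplier: float = 1.0


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic dataset.

    ``error_fraction`` defaults to 0.205, the error prevalence of public
    ErrP corpora (~1 error in 5 trials).  ``subject_jitter`` is
    (latency sd in s, fractional amplitude sd).
    """

    n_subjects: int = 6
    epochs_per_subject: int = 200
    error_fraction: float = 0.205
    noise_sd: float = 2.5
    noise_spectrum: str = "one_over_f"
    subject_jitter: tuple[float, float] = (0.02, 0.10)
    task_shift: TaskShift = field(default_factory=TaskShift)
    sessions_per_subject: int = 2
    task_id: str = "synthetic"
    template: ErpTemplate = field(default_factory=ErpTemplate)
    degraded_subjects: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.error_fraction < 1.0:
            raise ValueError("error_fraction must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.epochs_per_subject < 0:
            raise ValueError("epochs_per_subject must be >= 0")
        if self.noise_spectrum not in ("white", "one_over_f"):
            raise ValueError("noise_spectrum must be 'white' or 'one_over_f'")
        if self.sessions_per_subject < 1:
            raise ValueError("need at least one session per subject")

    @classmethod
    def from_dict(cls, raw: dict) -> "SynthConfig":
        raw = dict(raw)
        if "template" in raw and isinstance(raw["template"], dict):
            raw["template"] = ErpTemplate(**raw["template"])
        if "task_shift" in raw and isinstance(raw["task_shift"], dict):
            raw["task_shift"] = TaskShift(**raw["task_shift"])
        for key in ("subject_jitter", "degraded_subjects"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown synth config keys: {sorted(unknown)}")
        return cls(**raw)


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(subject_index,)))


def make_template(config: SynthConfig, subject_index: int,
                  rng: np.random.Generator | None = None) -> ErpTemplate:
    """Draw a per-subject template: jittered latencies and amplitudes.

    Latencies receive additive normal jitter (plus the task latency offset);
    amplitudes are scaled by ``N(1, amp_sd)`` truncated positive and by the
    task amplitude scale.  Draws violating the template invariants are
    resampled (bounded retries).
    """
    lat_sd, amp_sd = config.subject_jitter
    if lat_sd < 0 or amp_sd < 0:
        raise ValueError("jitter standard deviations must be >= 0")
    if rng is None:
        rng = _subject_rng(config.seed, subject_index)
    base = config.template
    shift = config.task_shift
    amp_gain = shift.amplitude_scale
    if subject_index in config.degraded_subjects:
        amp_gain *= 0.05  # near-zero template: the degraded-subject preset
    for _ in range(100):
        ne_lat = base.ne_latency_s + shift.latency_offset_s + rng.normal(0.0, lat_sd)
        pe_lat = base.pe_latency_s + shift.latency_offset_s + rng.normal(0.0, lat_sd)
        scale = max(rng.normal(1.0, amp_sd), 0.0) * amp_gain
        try:
            return ErpTemplate(
                ne_latency_s=ne_lat, ne_width_s=base.ne_width_s,
                ne_amplitude=base.ne_amplitude * scale,
                pe_latency_s=pe_lat, pe_width_s=base.pe_width_s,
                pe_amplitude=base.pe_amplitude * scale,
                channel_gains=base.channel_gains,
            )
        except ValueError:
            continue
    raise RuntimeError("could not draw a valid subject template in 100 attempts")


def _noise(rng: np.random.Generator, shape: tuple[int, ...], sd: float,
           spectrum: str) -> np.ndarray:
    """Background activity: white or 1/f-shaped (power ~ 1/f) noise, sd-scaled."""
    if sd == 0.0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    if spectrum == "white":
        return sd * white
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / SAMPLING_RATE)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** -0.5  # amplitude ~ f^-1/2 => power ~ 1/f
    spec = np.fft.rfft(white, axis=-1) * gain
    shaped = np.fft.irfft(spec, n=n, axis=-1)
    shaped /= shaped.std() if shaped.std() > 0 else 1.0
    return sd * shaped


def _subject_epochs(config: SynthConfig, subject_index: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate one subject's epochs: (data, labels, session ids)."""
    rng = _subject_rng(config.seed, subject_index)
    template = make_template(config, subject_index, rng)
    n = config.epochs_per_subject
    n_err = int(round(config.error_fraction * n))
    noise_sd = config.noise_sd * config.task_shift.noise_multiplier
    if subject_index in config.degraded_subjects:
        noise_sd *= 2.0  # degraded subjects: doubled background noise
    data = _noise(rng, (n, 2, N_SAMPLES), noise_sd, config.noise_spectrum)
    labels = np.zeros(n, dtype=np.int8)
    # distribute errors across sessions as evenly as possible, then add the
    # template; error positions are interleaved so each session holds both
    # classes whenever counts allow
    s = config.sessions_per_subject
    bounds = np.linspace(0, n, s + 1).round().astype(int)
    sessions = np.empty(n, dtype=object)
    err_per_session = np.full(s, n_err // s)
    err_per_session[: n_err % s] += 1
    for k in range(s):
        lo, hi = bounds[k], bounds[k + 1]
        sessions[lo:hi] = str(k + 1)
        labels[lo:lo + min(err_per_session[k], hi - lo)] = 1
    data[labels == 1] += template.waveform()
    # shuffle within each session so class order carries no information
    for k in range(s):
        lo, hi = bounds[k], bounds[k + 1]
        perm = rng.permutation(hi - lo) + lo
        data[lo:hi], labels[lo:hi] = data[perm], labels[perm]
    return data, labels, sessions.astype(str)


def generate_epochset(config: SynthConfig) -> EpochSet:
    """Generate a full labelled synthetic dataset at canonical shape.

    Per subject the error count is exactly ``round(error_fraction * n)``.
    Identical config (including seed) yields a bit-identical set.
    """
    if config.n_subjects * config.epochs_per_subject == 0:
        return EpochSet(np.empty((0, 2, N_SAMPLES), dtype=np.float32),
                        np.empty(0, dtype=np.int8), np.empty(0, dtype=str),
                        np.empty(0, dtype=str), np.empty(0, dtype=str),
                        CHANNELS, SAMPLING_RATE)
    blocks, labels, subjects, sessions = [], [], [], []
    for i in range(config.n_subjects):
        d, l, s = _subject_epochs(config, i)
        blocks.append(d)
        labels.append(l)
        sessions.append(s)
        subjects.append(np.full(len(l), f"s{i + 1:02d}"))
    n_total = config.n_subjects * config.epochs_per_subject
    tasks = np.full(n_total, config.task_id)
    return EpochSet(np.concatenate(blocks), np.concatenate(labels),
                    np.concatenate(subjects), np.concatenate(sessions), tasks,
                    CHANNELS, SAMPLING_RATE,
                    metadata={"generator": "errpnet.synth", "seed": config.seed})


def generate_task_pair(source: SynthConfig, target: SynthConfig) -> tuple[EpochSet, EpochSet]:
    """Generate a (source, target) dataset pair for transfer experiments.

    The shared random stream is split deterministically from the source
    seed, so the pair is reproducible as a unit; the target's ``task_shift``
    encodes the cross-task distribution change.
    """
    ss = np.random.SeedSequence(source.seed, spawn_key=(0xE44,))
    src_seed, tgt_seed = (int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(2))
    src = dataclasses.replace(source, seed=src_seed)
    tgt = dataclasses.replace(target, seed=tgt_seed)
    if src.task_id == tgt.task_id:
        tgt = dataclasses.replace(tgt, task_id=src.task_id + "_target")
    return generate_epochset(src), generate_epochset(tgt)
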