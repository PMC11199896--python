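"""Epoched-EEG containers, HDF5 persistence, MAT ingestion and run configs.

The universal currency of the package is the :class:`EpochSet`: a labelled
stack of fixed-shape epochs (canonically 2 channels x 64 samples, in
x1000-scaled microvolts) annotated with subject / session / task
identifiers.  Sets round-trip losslessly through a fixed HDF5 schema::

    /epochs   float32 [N, C, T]
    /labels   int8    [N]          0 = correct, 1 = error
    /subject  str     [N]
    /session  str     [N]
    /task     str     [N]
    attrs: schema_version, sampling_rate_hz, channel_names

MAT-file ingestion for the public ErrP distributions (BNCI moving cursor,
LSC speller, Gaze speller) is a best-effort optional path behind a dialect
registry; the variable layouts assumed by each dialect are documented on
:func:`ingest_mat` and must be confirmed against the actual downloads.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import h5py
import numpy as np
import yaml

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

#: label conventions used throughout the package
CORRECT, ERROR = 0, 1


def configure_logging(level: str = "INFO") -> None:
    """Structured, leveled logging for CLI and script entry points."""
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )


@dataclass(frozen=True)
class Epoch:
    """One labelled EEG trial.

    ``data`` is (n_channels, n_samples); after preprocessing the canonical
    shape is (2, 64).  ``label`` is 0 (correct) or 1 (error).
    """

    data: np.ndarray
    label: int
    subject_id: str
    session_id: str
    task_id: str

    def __post_init__(self):
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch contains non-finite samples")
        if self.label not in (CORRECT, ERROR):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


class EpochSet:
    """Ordered, annotation-carrying stack of same-shape epochs."""

    def __init__(
        self,
        data: np.ndarray,
        labels: np.ndarray,
        subjects: np.ndarray,
        sessions: np.ndarray,
        tasks: np.ndarray,
        channel_names: tuple[str, ...],
        sampling_rate: float,
        metadata: dict | None = None,
    ):
        data = np.asarray(data, dtype=np.float32)
        if data.ndim != 3:
            raise ValueError(f"data must be (n_epochs, n_channels, n_samples), got {data.shape}")
        n = data.shape[0]
        labels = np.asarray(labels, dtype=np.int8)
        subjects = np.asarray(subjects, dtype=str)
        sessions = np.asarray(sessions, dtype=str)
        tasks = np.asarray(tasks, dtype=str)
        for name, arr in (("labels", labels), ("subjects", subjects),
                          ("sessions", sessions), ("tasks", tasks)):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length {n}, got {arr.shape}")
        if n and not np.isin(labels, (CORRECT, ERROR)).all():
            raise ValueError("labels must be 0 (correct) or 1 (error)")
        if n and (np.any(subjects == "") or np.any(sessions == "") or np.any(tasks == "")):
            raise ValueError("subject/session/task identifiers must be non-empty")
        if not np.all(np.isfinite(data)):
            raise ValueError("epoch data contains non-finite values")
        if len(channel_names) != data.shape[1]:
            raise ValueError("channel_names length must match the channel axis")
        self.data = data
        self.labels = labels
        self.subjects = subjects
        self.sessions = sessions
        self.tasks = tasks
        self.channel_names = tuple(str(c) for c in channel_names)
        self.sampling_rate = float(sampling_rate)
        self.metadata = dict(metadata or {})

    # -- basic protocol -------------------------------------------------------

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def epoch_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def __iter__(self) -> Iterator[Epoch]:
        for i in range(len(self)):
            yield Epoch(self.data[i], int(self.labels[i]), str(self.subjects[i]),
                        str(self.sessions[i]), str(self.tasks[i]))

    def subset(self, index) -> "EpochSet":
        """New set holding the epochs selected by a boolean mask or indices."""
        index = np.asarray(index)
        return EpochSet(self.data[index], self.labels[index], self.subjects[index],
                        self.sessions[index], self.tasks[index], self.channel_names,
                        self.sampling_rate, self.metadata)

    def where(self, subject=None, session=None, task=None) -> "EpochSet":
        mask = np.ones(len(self), dtype=bool)
        if subject is not None:
            mask &= self.subjects == str(subject)
        if session is not None:
            mask &= self.sessions == str(session)
        if task is not None:
            mask &= self.tasks == str(task)
        return self.subset(mask)

    @property
    def subject_ids(self) -> list[str]:
        return sorted(set(self.subjects.tolist()))

    @property
    def session_ids(self) -> list[str]:
        return sorted(set(self.sessions.tolist()))

    def validate_canonical(self) -> None:
        """Assert the post-preprocessing contract: shape (2, 64), finite."""
        if self.epoch_shape != (2, 64):
            raise ValueError(f"canonical epochs must be (2, 64), got {self.epoch_shape}")

    def __eq__(self, other) -> bool:
        if not isinstance(other, EpochSet):
            return NotImplemented
        return (
            np.array_equal(self.data, other.data)
            and np.array_equal(self.labels, other.labels)
            and np.array_equal(self.subjects, other.subjects)
            and np.array_equal(self.sessions, other.sessions)
            and np.array_equal(self.tasks, other.tasks)
            and self.channel_names == other.channel_names
            and self.sampling_rate == other.sampling_rate
        )

    @staticmethod
    def concatenate(sets: list["EpochSet"]) -> "EpochSet":
        first = sets[0]
        for s in sets[1:]:
            if s.epoch_shape != first.epoch_shape:
                raise ValueError("cannot concatenate sets with different epoch shapes")
            if s.channel_names != first.channel_names:
                raise ValueError("cannot concatenate sets with different channel names")
        return EpochSet(
            np.concatenate([s.data for s in sets]),
            np.concatenate([s.labels for s in sets]),
            np.concatenate([s.subjects for s in sets]),
            np.concatenate([s.sessions for s in sets]),
            np.concatenate([s.tasks for s in sets]),
            first.channel_names, first.sampling_rate, first.metadata,
        )


# -- HDF5 persistence ---------------------------------------------------------

_STR = h5py.string_dtype(encoding="utf-8")


def save_epochset(epochset: EpochSet, path: str | Path) -> None:
    """Write an :class:`EpochSet` to ``path`` in the package's HDF5 schema."""
    if len(epochset) == 0:
        raise ValueError("refusing to save an empty EpochSet")
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=epochset.data.astype(np.float32))
        f.create_dataset("labels", data=epochset.labels.astype(np.int8))
        f.create_dataset("subject", data=epochset.subjects.astype(object), dtype=_STR)
        f.create_dataset("session", data=epochset.sessions.astype(object), dtype=_STR)
        f.create_dataset("task", data=epochset.tasks.astype(object), dtype=_STR)
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["sampling_rate_hz"] = epochset.sampling_rate
        f.attrs["channel_names"] = list(epochset.channel_names)
    logger.info("saved %d epochs to %s", len(epochset), path)


def load_epochset(path: str | Path) -> EpochSet:
    """Read an epoch store written by :func:`save_epochset`."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise ValueError(f"unknown schema version {version}")
        for name in ("epochs", "labels", "subject", "session", "task"):
            if name not in f:
                raise ValueError(f"epoch store missing dataset '{name}'")
        data = f["epochs"][...]
        labels = f["labels"][...]
        if data.shape[0] != labels.shape[0]:
            raise ValueError("epochs/labels row count mismatch")
        return EpochSet(
            data, labels,
            f["subject"].asstr()[...], f["session"].asstr()[...], f["task"].asstr()[...],
            tuple(str(c) for c in f.attrs["channel_names"]),
            float(f.attrs["sampling_rate_hz"]),
        )


# -- run configuration --------------------------------------------------------

_CONFIG_SECTIONS = ("preprocess", "synth", "model", "train", "eval")


@dataclass
class RunConfig:
    """Nested run configuration: one dict per pipeline section plus a seed.

    Section contents are validated by the consuming module's config class;
    unknown top-level keys are rejected here so typos fail fast.
    """

    seed: int = 0
    preprocess: dict = field(default_factory=dict)
    synth: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    eval: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - set(_CONFIG_SECTIONS) - {"seed"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(seed=int(raw.get("seed", 0)),
                   **{s: dict(raw.get(s, {})) for s in _CONFIG_SECTIONS})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        return cls.from_dict(raw)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)

    def log(self) -> None:
        """Record the fully resolved configuration (reproducibility aid)."""
        logger.info("resolved run config (seed=%d): %s", self.seed, self.to_dict())


# -- MAT ingestion ------------------------------------------------------------

@dataclass
class RawRecording:
    """Continuous multichannel EEG plus an event list (onset sample, label)."""

    signal: np.ndarray  # (n_channels, n_samples)
    sampling_rate: float
    channel_names: tuple[str, ...]
    events: list[tuple[int, int]]


_DIALECT_RATES = {"bnci_cursor": 512.0, "lsc_speller": 256.0, "gaze_speller": 256.0}


def ingest_mat(path: str | Path, dataset_dialect: str):
    """Best-effort reader for the public ErrP MAT distributions.

    Expected variable layouts (to be confirmed against the actual downloads;
    the public archives do not document them in the accompanying text):

    ``bnci_cursor`` / ``lsc_speller``
        ``signal`` (channels x samples or transposed), ``fs`` scalar,
        ``events`` (n x 2: onset sample, label), optional ``channels``
        (names).  Returns a :class:`RawRecording` (512 / 256 Hz).
    ``gaze_speller``
        Pre-epoched: ``epochs`` (n x channels x samples), ``labels`` (n,),
        ``fs`` scalar, optional ``channels``.  Returns an :class:`EpochSet`
        of 0.5-s epochs at 256 Hz.
    """
    from scipy.io import loadmat

    if dataset_dialect not in _DIALECT_RATES:
        raise ValueError(f"unknown dataset dialect '{dataset_dialect}'")
    mat = loadmat(str(path), squeeze_me=True)
    expected_fs = _DIALECT_RATES[dataset_dialect]
    fs = float(np.squeeze(mat.get("fs", expected_fs)))

    def _names(n: int) -> tuple[str, ...]:
        raw = mat.get("channels")
        if raw is None:
            return tuple(f"ch{i}" for i in range(n))
        return tuple(str(c) for c in np.atleast_1d(raw))

    if dataset_dialect == "gaze_speller":
        for var in ("epochs", "labels"):
            if var not in mat:
                raise ValueError(f"gaze_speller MAT file missing variable '{var}'")
        epochs = np.asarray(mat["epochs"], dtype=np.float64)
        labels = np.asarray(mat["labels"]).astype(int).reshape(-1)
        n, n_ch, _ = epochs.shape
        subj = str(mat.get("subject", "s01"))
        return EpochSet(epochs, labels,
                        np.full(n, subj), np.full(n, "1"), np.full(n, "gaze_speller"),
                        _names(n_ch), fs)

    for var in ("signal", "events"):
        if var not in mat:
            raise ValueError(f"{dataset_dialect} MAT file missing variable '{var}'")
    signal = np.asarray(mat["signal"], dtype=np.float64)
    if signal.shape[0] > signal.shape[1]:  # stored samples x channels
        signal = signal.T
    events = np.atleast_2d(np.asarray(mat["events"])).astype(int)
    return RawRecording(signal, fs, _names(signal.shape[0]),
                        [(int(o), int(l)) for o, l in events])
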