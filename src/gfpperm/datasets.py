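"""In-memory containers for epoched EEG data and their HDF5 round-trip.

The package works on already-epoched, already-cleaned data: one
:class:`EpochedDataset` per subject holding a channels x samples x trials
voltage tensor (microvolts) with a per-trial condition label in {"A", "B"}.

The on-disk container is a plain HDF5 file, one subject per file:

``/epochs``         float64, C x S x K, microvolts
``/labels``         integer codes, with attribute ``mapping`` = '{"0": "A", "1": "B"}'
``/times``          float64, seconds relative to stimulus onset
``/channel_names``  variable-length strings
root attributes     ``sampling_rate_hz``, ``subject_id``

Round-trips are bit-exact for float64 payloads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

from .errors import EmptyConditionError, IncompatibleDatasetsError, InvalidMontageError

CONDITIONS = ("A", "B")
_LABEL_TO_CODE = {"A": 0, "B": 1}
_CODE_TO_LABEL = {0: "A", 1: "B"}


@dataclass
class EpochedDataset:
    """Per-subject epoched EEG: voltages plus per-trial condition labels.

    Parameters
    ----------
    subject_id : str
        Opaque subject label.
    data : ndarray, shape (C, S, K)
        Average-referenced (or raw) voltages in microvolts, channels x
        samples x trials.
    labels : ndarray of str, shape (K,)
        Condition tag per trial, each "A" or "B".
    times : ndarray, shape (S,)
        Time of each sample in seconds relative to stimulus onset.
    channel_names : list of str, length C
    sampling_rate : float
        Sampling rate in Hz.
    """

    subject_id: str
    data: np.ndarray
    labels: np.ndarray
    times: np.ndarray
    channel_names: list[str] = field(default_factory=list)
    sampling_rate: float = 256.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be a C x S x K tensor")
        C, S, K = self.data.shape
        if C < 2:
            raise InvalidMontageError(f"need at least 2 channels, got {C}")
        if K < 2:
            raise ValueError(f"need at least 2 trials, got {K}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")
        self.labels = np.asarray(self.labels, dtype="U1")
        if self.labels.shape != (K,):
            raise ValueError(f"labels must have length K={K}")
        bad = set(self.labels) - set(CONDITIONS)
        if bad:
            raise ValueError(f"labels must be in {CONDITIONS}, found {sorted(bad)}")
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.times.shape != (S,):
            raise ValueError(f"times must have length S={S}")
        if not self.channel_names:
            self.channel_names = [f"ch{i:02d}" for i in range(C)]
        if len(self.channel_names) != C:
            raise ValueError("channel_names must have length C")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    def trial_mask(self, condition: str) -> np.ndarray:
        """Boolean mask over trials carrying ``condition``."""
        return self.labels == condition

    def n_trials_in(self, condition: str) -> int:
        return int(np.count_nonzero(self.trial_mask(condition)))

    def require_condition(self, condition: str) -> None:
        if self.n_trials_in(condition) == 0:
            raise EmptyConditionError(
                f"subject {self.subject_id!r} has no trials labeled {condition!r}"
            )

    def with_labels(self, labels: np.ndarray) -> "EpochedDataset":
        """Copy of this dataset with a new per-trial label vector."""
        return replace(self, labels=np.asarray(labels, dtype="U1"))

    def with_data(self, data: np.ndarray) -> "EpochedDataset":
        return replace(self, data=data)


@dataclass
class ERP:
    """Condition-average event-related potential: channels x samples."""

    values: np.ndarray
    times: np.ndarray
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("ERP values must be a C x S matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ERP values must be finite")
        self.times = np.asarray(self.times, dtype=np.float64)


@dataclass
class GFPTrace:
    """Per-timepoint global field power of one condition-average ERP."""

    values: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if np.any(self.values < 0):
            raise ValueError("GFP values must be non-negative")


def check_compatible(datasets: list[EpochedDataset]) -> None:
    """Verify all subjects share montage and time axis.

    Raises
    ------
    IncompatibleDatasetsError
        If channel counts, channel names, sample counts or time axes differ.
    """
    if not datasets:
        raise IncompatibleDatasetsError("no datasets given")
    ref = datasets[0]
    for ds in datasets[1:]:
        if ds.n_channels != ref.n_channels or ds.n_samples != ref.n_samples:
            raise IncompatibleDatasetsError(
                f"subject {ds.subject_id!r} has shape "
                f"({ds.n_channels}, {ds.n_samples}), expected "
                f"({ref.n_channels}, {ref.n_samples})"
            )
        if ds.channel_names != ref.channel_names:
            raise IncompatibleDatasetsError(
                f"subject {ds.subject_id!r} montage differs from {ref.subject_id!r}"
            )
        if not np.allclose(ds.times, ref.times):
            raise IncompatibleDatasetsError(
                f"subject {ds.subject_id!r} time axis differs from {ref.subject_id!r}"
            )


def write_epochs(path, dataset: EpochedDataset) -> None:
    """Write one subject's epochs to an HDF5 container (see module docs)."""
    codes = np.array([_LABEL_TO_CODE[l] for l in dataset.labels], dtype=np.int64)
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=dataset.data, dtype=np.float64)
        dl = f.create_dataset("labels", data=codes)
        dl.attrs["mapping"] = json.dumps({str(c): l for l, c in _LABEL_TO_CODE.items()})
        f.create_dataset("times", data=dataset.times, dtype=np.float64)
        f.create_dataset(
            "channel_names",
            data=np.array(dataset.channel_names, dtype=h5py.string_dtype()),
        )
        f.attrs["sampling_rate_hz"] = float(dataset.sampling_rate)
        f.attrs["subject_id"] = str(dataset.subject_id)


def read_epochs(path) -> EpochedDataset:
    """Read one subject's epochs from an HDF5 container."""
    with h5py.File(path, "r") as f:
        data = f["epochs"][()]
        codes = f["labels"][()]
        mapping = {int(k): v for k, v in json.loads(f["labels"].attrs["mapping"]).items()}
        labels = np.array([mapping[int(c)] for c in codes], dtype="U1")
        times = f["times"][()]
        channel_names = [
            n.decode() if isinstance(n, bytes) else str(n) for n in f["channel_names"][()]
        ]
        return EpochedDataset(
            subject_id=str(f.attrs["subject_id"]),
            data=data,
            labels=labels,
            times=times,
            channel_names=channel_names,
            sampling_rate=float(f.attrs["sampling_rate_hz"]),
        )
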