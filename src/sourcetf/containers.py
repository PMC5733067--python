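"""In-memory containers for continuous and epoched multichannel EEG.

The canonical on-disk form is an HDF5 array container accompanied by a JSON
sidecar that declares the sampling rate, channel names and event latencies,
so every array round-trips losslessly (EDF is supported read-only, see
:mod:`sourcetf.io`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = ["ContinuousRecord", "SensorEpochs"]


def _check_channel_names(names: list[str], n_rows: int) -> None:
    if len(names) != n_rows:
        raise ValueError(
            f"channel_names has {len(names)} entries but data has {n_rows} rows"
        )
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate channel names: {dupes}")


@dataclass
class ContinuousRecord:
    """A continuous multichannel recording in microvolts.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` float array, µV.
    srate
        Sampling rate in Hz.
    channel_names
        One unique name per data row.
    events
        Sample indices of stimulus events.
    """

    data: np.ndarray
    srate: float
    channel_names: list[str]
    events: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.srate <= 0:
            raise ValueError("srate must be positive")
        _check_channel_names(list(self.channel_names), self.data.shape[0])
        self.events = np.asarray(self.events, dtype=int)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    # -- container I/O -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write ``<path>.h5`` plus a ``<path>.json`` sidecar."""
        path = Path(path)
        h5_path = path.with_suffix(".h5")
        with h5py.File(h5_path, "w") as f:
            f.create_dataset("data", data=self.data)
        sidecar = {
            "kind": "continuous",
            "srate": float(self.srate),
            "channel_names": list(self.channel_names),
            "events": [int(e) for e in self.events],
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ContinuousRecord":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        with h5py.File(path.with_suffix(".h5"), "r") as f:
            data = f["data"][()]
        if data.shape[0] != len(sidecar["channel_names"]):
            raise ValueError(
                "sidecar declares a different channel count than the array"
            )
        return cls(
            data=data,
            srate=sidecar["srate"],
            channel_names=sidecar["channel_names"],
            events=np.asarray(sidecar.get("events", []), dtype=int),
        )


@dataclass
class SensorEpochs:
    """Event-aligned sensor epochs, ``channels x samples x trials``, in µV.

    Time of sample ``k`` is ``(k - t0_index) / srate`` seconds relative to the
    event at time zero; every trial shares the same length and alignment.
    """

    data: np.ndarray
    srate: float
    t0_index: int
    channel_names: list[str]
    montage_ref: str = ""
    condition_labels: list[str] | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (channels x samples x trials)")
        if self.srate <= 0:
            raise ValueError("srate must be positive")
        _check_channel_names(list(self.channel_names), self.data.shape[0])
        if not 0 <= self.t0_index <= self.data.shape[1]:
            raise ValueError("t0_index outside the epoch")
        if self.condition_labels is not None and len(self.condition_labels) != self.data.shape[2]:
            raise ValueError("one condition label per trial required")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Per-sample time in seconds relative to the event."""
        return (np.arange(self.n_samples) - self.t0_index) / self.srate

    def time_mask(self, t_lo: float, t_hi: float) -> np.ndarray:
        """Boolean sample mask for the half-open window ``[t_lo, t_hi)`` s."""
        t = self.times
        mask = (t >= t_lo) & (t < t_hi)
        if not mask.any():
            raise ValueError(f"window [{t_lo}, {t_hi}) s contains no samples")
        return mask

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with h5py.File(path.with_suffix(".h5"), "w") as f:
            f.create_dataset("data", data=self.data)
        sidecar = {
            "kind": "epochs",
            "srate": float(self.srate),
            "t0_index": int(self.t0_index),
            "channel_names": list(self.channel_names),
            "montage_ref": self.montage_ref,
            "condition_labels": self.condition_labels,
            "subject_id": self.subject_id,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SensorEpochs":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        with h5py.File(path.with_suffix(".h5"), "r") as f:
            data = f["data"][()]
        return cls(
            data=data,
            srate=sidecar["srate"],
            t0_index=sidecar["t0_index"],
            channel_names=sidecar["channel_names"],
            montage_ref=sidecar.get("montage_ref", ""),
            condition_labels=sidecar.get("condition_labels"),
            subject_id=sidecar.get("subject_id", ""),
        )
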