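"""Containers for continuous EEG recordings and windowed segments, plus file I/O.

Two on-disk formats are supported: European Data Format (EDF), read through
:mod:`mne`, and a plain-text interchange format consisting of a delimited
numeric matrix (rows = channels, microvolts) next to a JSON sidecar holding
``subject_id``, ``label``, ``sampling_rate_hz`` and ``channel_names``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["RawRecording", "Segment", "read_text_recording", "write_text_recording", "read_edf"]


@dataclass
class RawRecording:
    """One subject's continuous multichannel EEG.

    ``label`` is binary: 0 = control, 1 = depressed.  ``data`` has shape
    (n_channels, n_samples) in microvolts.
    """

    subject_id: str
    label: int
    sampling_rate_hz: float
    channel_names: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (channels x samples), got shape {self.data.shape}")
        if self.data.shape[0] < 2:
            raise ValueError("a recording needs at least 2 channels")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} data rows"
            )
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 (control) or 1 (depressed), got {self.label}")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def with_data(self, data: np.ndarray) -> "RawRecording":
        """Copy of this recording with ``data`` replaced (shape-checked)."""
        return replace(self, data=data)


@dataclass
class Segment:
    """A fixed-length window cut from a recording; inherits identity and label."""

    subject_id: str
    label: int
    sampling_rate_hz: float
    start_time_s: float
    data: np.ndarray = field(repr=False)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def write_text_recording(rec: RawRecording, matrix_path: str | Path, sidecar_path: str | Path | None = None) -> None:
    """Write the plain-text matrix + JSON sidecar pair for ``rec``."""
    matrix_path = Path(matrix_path)
    if sidecar_path is None:
        sidecar_path = matrix_path.with_suffix(".json")
    np.savetxt(matrix_path, rec.data, delimiter="\t")
    meta = {
        "subject_id": rec.subject_id,
        "label": rec.label,
        "sampling_rate_hz": rec.sampling_rate_hz,
        "channel_names": rec.channel_names,
    }
    Path(sidecar_path).write_text(json.dumps(meta, indent=2))


def read_text_recording(matrix_path: str | Path, sidecar_path: str | Path | None = None) -> RawRecording:
    """Read a recording from the delimited-matrix + JSON sidecar format."""
    matrix_path = Path(matrix_path)
    if sidecar_path is None:
        sidecar_path = matrix_path.with_suffix(".json")
    meta = json.loads(Path(sidecar_path).read_text())
    data = np.loadtxt(matrix_path, delimiter="\t", ndmin=2)
    return RawRecording(
        subject_id=str(meta["subject_id"]),
        label=int(meta["label"]),
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        channel_names=[str(c) for c in meta["channel_names"]],
        data=data,
    )


def read_edf(path: str | Path, subject_id: str, label: int) -> RawRecording:
    """Read an EDF file into a :class:`RawRecording` (requires the ``edf`` extra).

    EDF stores volts; values are converted to microvolts to match the
    plain-text format.
    """
    import mne  # deferred: optional dependency

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return RawRecording(
        subject_id=subject_id,
        label=label,
        sampling_rate_hz=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        data=raw.get_data() * 1e6,
    )
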