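"""Multichannel hemodynamic recordings and their on-disk dialect.

A :class:`Recording` is the pipeline's universal currency: a labeled
(channels x time) matrix of oxyhemoglobin concentration changes at a fixed
sampling rate, tagged with a subject id and an experimental condition.

On disk a recording is a wide CSV (``time_s, CH01, ..., CH22``) with a JSON
sidecar carrying the metadata (subject, condition, sampling rate, units,
channel order). The writer formats floats with 17 significant digits so that
a read/write round trip is bit-exact for finite values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Experimental conditions: resting segments after the prior, near-transfer
#: and far-transfer learning phases.
CONDITIONS = ("prior", "near", "far")

#: The standard 22-channel prefrontal montage.
DEFAULT_CHANNELS = tuple(f"CH{i:02d}" for i in range(1, 23))


@dataclass
class Recording:
    """Multichannel ΔHbO time series.

    Parameters
    ----------
    subject_id
        Identifier of the participant.
    condition
        One of ``prior``, ``near``, ``far``.
    fs
        Sampling rate in Hz (the reference device samples at 13.33 Hz).
    channel_labels
        Unique channel names, conventionally ``CH01``–``CH22``.
    samples
        Array of shape ``(n_channels, n_samples)`` in concentration units.
    units
        Concentration units of ``samples`` (arbitrary by default).
    events
        Optional event timestamps in seconds.
    """

    subject_id: str
    condition: str
    fs: float
    channel_labels: tuple[str, ...]
    samples: np.ndarray
    units: str = "a.u."
    events: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        self.channel_labels = tuple(self.channel_labels)
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (channels x time) matrix")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{len(self.channel_labels)} labels but "
                f"{self.samples.shape[0]} sample rows"
            )
        if not np.isfinite(self.samples).all():
            raise ValueError("samples must be finite (no missing values)")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return one channel's series by label."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"no channel {label!r}") from None
        return self.samples[idx]

    def with_samples(self, samples: np.ndarray) -> "Recording":
        """Copy of this recording with ``samples`` replaced."""
        return replace(self, samples=samples)


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_recording(rec: Recording, csv_path: str | Path) -> Path:
    """Write ``rec`` as wide CSV plus JSON sidecar; returns the CSV path."""
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(
        {"time_s": rec.times(), **dict(zip(rec.channel_labels, rec.samples))}
    )
    frame.to_csv(csv_path, index=False, float_format="%.17g")
    sidecar = {
        "subject_id": rec.subject_id,
        "condition": rec.condition,
        "fs_hz": rec.fs,
        "units": rec.units,
        "channel_labels": list(rec.channel_labels),
    }
    if rec.events is not None:
        sidecar["events_s"] = [float(t) for t in rec.events]
    _sidecar_path(csv_path).write_text(json.dumps(sidecar, indent=1))
    return csv_path


def read_recording(csv_path: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording`.

    Validates that the CSV channel columns match the sidecar's label set and
    that the time column is strictly increasing.
    """
    csv_path = Path(csv_path)
    sidecar = json.loads(_sidecar_path(csv_path).read_text())
    frame = pd.read_csv(csv_path, float_precision="round_trip")
    labels = list(sidecar["channel_labels"])
    missing = [c for c in labels if c not in frame.columns]
    if missing:
        raise ValueError(f"{csv_path}: channel columns missing from CSV: {missing}")
    t = frame["time_s"].to_numpy()
    if len(t) > 1 and not (np.diff(t) > 0).all():
        raise ValueError(f"{csv_path}: time_s column is not strictly increasing")
    events = sidecar.get("events_s")
    return Recording(
        subject_id=str(sidecar["subject_id"]),
        condition=sidecar["condition"],
        fs=float(sidecar["fs_hz"]),
        channel_labels=tuple(labels),
        samples=frame[labels].to_numpy().T,
        units=sidecar.get("units", "a.u."),
        events=None if events is None else np.asarray(events, dtype=float),
    )
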