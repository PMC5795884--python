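"""Electrode data model, bipolar montages, and annotation / metadata I/O.

A clinical long-term EEG recording is stored referentially: every electrode
is measured against a common reference (here Fpz).  Reviewers and detection
algorithms instead work on *bipolar* channels, each the potential difference
between two named electrodes, so the common reference (and any signal it
carries) cancels.  This module defines the referential :class:`Recording`,
the :class:`BipolarMontage` describing electrode pairs, and the derived
:class:`MultichannelSignal`, plus CSV round-trips for seizure annotations
and the packaged patient-metadata table of the 12-patient cohort.
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Recording",
    "BipolarMontage",
    "MultichannelSignal",
    "SeizureAnnotation",
    "PatientMetadata",
    "SCALP_CHANNEL_PAIRS",
    "EAR_CHANNEL_PAIRS",
    "ALL_ELECTRODES",
    "define_scalp_montage",
    "define_ear_montage",
    "apply_montage",
    "read_annotations",
    "write_annotations",
    "load_patient_metadata",
    "summarize_metadata",
]

#: The 22 clinical bipolar channels (longitudinal + sphenoidal chains).
SCALP_CHANNEL_PAIRS: tuple[tuple[str, str], ...] = (
    ("Fp2", "F8"), ("F8", "T4"), ("T4", "T6"), ("T6", "O2"), ("T4", "Sph2"),
    ("Fp2", "F4"), ("F4", "C4"), ("C4", "P4"), ("P4", "O2"),
    ("Fz", "Cz"), ("Cz", "Pz"), ("Pz", "O2"), ("Pz", "O1"),
    ("Fp1", "F7"), ("F7", "T3"), ("T3", "T5"), ("T5", "O1"), ("T3", "Sph1"),
    ("Fp1", "F3"), ("F3", "C3"), ("C3", "P3"), ("P3", "O1"),
)

#: Behind-the-ear derivations: two cross-head channels (left vs right ear)
#: and one unilateral channel behind each ear.
EAR_CHANNEL_PAIRS: tuple[tuple[str, str], ...] = (
    ("LC", "RC"),  # cross-head 1
    ("LT", "RT"),  # cross-head 2
    ("LT", "LC"),  # unilateral left
    ("RT", "RC"),  # unilateral right
)

#: Closed electrode set: the 21 scalp/sphenoidal labels implied by the
#: clinical montage, the Fpz reference, and the four behind-the-ear
#: electrodes (left/right top and center).
ALL_ELECTRODES: tuple[str, ...] = tuple(
    dict.fromkeys(
        [e for pair in SCALP_CHANNEL_PAIRS for e in pair]
        + ["Fpz", "LT", "LC", "RT", "RC"]
    )
)


@dataclass
class Recording:
    """Referential multi-electrode EEG, microvolts, fixed sampling rate.

    ``data`` has one row per electrode in ``electrode_labels`` order; every
    row shares the common reference electrode (``reference_label``), whose
    own row, when present, is identically zero.
    """

    fs_hz: float
    electrode_labels: list[str]
    data: np.ndarray  # (n_electrodes, n_samples), µV
    reference_label: str = "Fpz"
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.fs_hz <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs_hz}")
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (electrodes x samples)")
        if self.data.shape[0] != len(self.electrode_labels):
            raise ValueError(
                f"{len(self.electrode_labels)} labels but {self.data.shape[0]} rows"
            )
        if len(set(self.electrode_labels)) != len(self.electrode_labels):
            raise ValueError("electrode labels must be unique")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def electrode(self, label: str) -> np.ndarray:
        try:
            idx = self.electrode_labels.index(label)
        except ValueError:
            raise KeyError(f"electrode {label!r} not in recording") from None
        return self.data[idx]

    def copy(self) -> "Recording":
        return Recording(
            fs_hz=self.fs_hz,
            electrode_labels=list(self.electrode_labels),
            data=self.data.copy(),
            reference_label=self.reference_label,
            start_time=self.start_time,
        )


@dataclass
class BipolarMontage:
    """Ordered list of named (anode, cathode) electrode derivations."""

    channels: list[tuple[str, str, str]]  # (name, anode, cathode)

    def __post_init__(self) -> None:
        names = [c[0] for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")

    @property
    def channel_names(self) -> list[str]:
        return [c[0] for c in self.channels]

    def __len__(self) -> int:
        return len(self.channels)

    def subset(self, names: Sequence[str]) -> "BipolarMontage":
        """Montage restricted to ``names``, in the given order."""
        by_name = {c[0]: c for c in self.channels}
        missing = [n for n in names if n not in by_name]
        if missing:
            raise KeyError(f"channels not in montage: {missing}")
        return BipolarMontage([by_name[n] for n in names])


@dataclass
class MultichannelSignal:
    """Derived bipolar channels: (channels x samples) in µV.

    The time axis is half-open, ``[start_time, start_time + n/fs)`` seconds,
    so sample ``k`` covers ``start_time + k/fs``.
    """

    fs_hz: float
    channel_names: list[str]
    data: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_names):
            raise ValueError("data shape inconsistent with channel names")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in signal") from None
        return self.data[idx]

    def copy(self) -> "MultichannelSignal":
        return MultichannelSignal(
            self.fs_hz, list(self.channel_names), self.data.copy(), self.start_time
        )

    def slice_seconds(self, t0: float, t1: float) -> "MultichannelSignal":
        """Half-open slice [t0, t1) in seconds relative to start_time."""
        i0 = int(np.floor(t0 * self.fs_hz))
        i1 = int(np.floor(t1 * self.fs_hz))
        i0 = max(i0, 0)
        i1 = min(i1, self.n_samples)
        return MultichannelSignal(
            self.fs_hz,
            list(self.channel_names),
            self.data[:, i0:i1].copy(),
            self.start_time + i0 / self.fs_hz,
        )


@dataclass(frozen=True)
class SeizureAnnotation:
    """Expert seizure marking: [onset_s, end_s] from recording start."""

    onset_s: float
    end_s: float
    label: str = "seizure"

    def __post_init__(self) -> None:
        if not (0 <= self.onset_s < self.end_s):
            raise ValueError(
                f"invalid annotation: onset {self.onset_s}, end {self.end_s}"
            )

    def shifted(self, offset_s: float) -> "SeizureAnnotation":
        return SeizureAnnotation(self.onset_s + offset_s, self.end_s + offset_s, self.label)


@dataclass(frozen=True)
class PatientMetadata:
    pid: int
    n_seizures: int
    sex: str
    age: float
    focus_side: str  # left | right
    focus_lobe: str  # temporal | parietal | occipital
    recording_h: float


def define_scalp_montage() -> BipolarMontage:
    """The 22-channel clinical bipolar montage (10-20 + sphenoidal)."""
    return BipolarMontage(
        [(f"{a}-{c}", a, c) for a, c in SCALP_CHANNEL_PAIRS]
    )


def define_ear_montage() -> BipolarMontage:
    """The four behind-the-ear channels: LC-RC, LT-RT, LT-LC, RT-RC."""
    return BipolarMontage([(f"{a}-{c}", a, c) for a, c in EAR_CHANNEL_PAIRS])


def apply_montage(rec: Recording, montage: BipolarMontage) -> MultichannelSignal:
    """Derive bipolar channels as anode minus cathode, sample-aligned.

    Raises :class:`KeyError` naming the offending channel if an electrode
    referenced by the montage is missing from the recording.
    """
    index = {lab: i for i, lab in enumerate(rec.electrode_labels)}
    rows = np.empty((len(montage), rec.n_samples))
    for k, (name, anode, cathode) in enumerate(montage.channels):
        missing = [e for e in (anode, cathode) if e not in index]
        if missing:
            raise KeyError(
                f"channel {name!r}: electrode(s) {missing} not in recording"
            )
        rows[k] = rec.data[index[anode]] - rec.data[index[cathode]]
    return MultichannelSignal(
        rec.fs_hz, montage.channel_names, rows, rec.start_time
    )


# ---------------------------------------------------------------------------
# Annotation CSV round-trip (header: patient_id,onset_s,end_s,label)

def write_annotations(
    annotations: Iterable[SeizureAnnotation], path, patient_id: int = 0
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "onset_s", "end_s", "label"])
        for ann in annotations:
            w.writerow([patient_id, repr(ann.onset_s), repr(ann.end_s), ann.label])


def read_annotations(path) -> list[SeizureAnnotation]:
    out: list[SeizureAnnotation] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                SeizureAnnotation(
                    float(row["onset_s"]), float(row["end_s"]),
                    row.get("label", "seizure") or "seizure",
                )
            )
    return out


# ---------------------------------------------------------------------------
# Cohort metadata (12 patients with focal-onset seizures with EEG correlates)

def load_patient_metadata() -> list[PatientMetadata]:
    """Packaged cohort table: seizure counts, demographics, focus, hours."""
    res = importlib.resources.files("earseiz.data").joinpath("patients.csv")
    out = []
    with res.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                PatientMetadata(
                    pid=int(row["pid"]),
                    n_seizures=int(row["n_seizures"]),
                    sex=row["sex"],
                    age=float(row["age"]),
                    focus_side=row["focus_side"],
                    focus_lobe=row["focus_lobe"],
                    recording_h=float(row["recording_h"]),
                )
            )
    return out


def summarize_metadata(meta: Sequence[PatientMetadata]) -> dict:
    """Cohort totals: seizure count, monitored hours, mean age."""
    if not meta:
        raise ValueError("empty metadata list")
    return {
        "total_seizures": sum(m.n_seizures for m in meta),
        "total_hours": sum(m.recording_h for m in meta),
        "mean_age": float(np.mean([m.age for m in meta])),
    }
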