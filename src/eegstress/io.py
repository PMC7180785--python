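"""Reading and writing recordings and participant tables.

EEG recordings travel as plain CSV in the dialect the Emotiv TestBench
exports produce: a header row naming the channels, one numeric row per
sample, comma separated, dot decimal.  Extra columns (timestamps, contact
quality flags) are tolerated and ignored with a logged notice.  Columns
may appear in any order; recordings are always normalised to the
canonical AF3, AF4, T7, T8, Pz order on read.

The package ships the reference participant table of the 33-person study
cohort (gender, age, PSS score, threshold label, expert label) as a
checksummed data file; :func:`load_reference_cohort` returns it.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .bands import CHANNELS
from .labeling import GroupLabel

logger = logging.getLogger(__name__)

#: SHA-256 of the packaged participant table; verified on every load.
_REFERENCE_SHA256 = "5ac9deb2ebb8732bd4331d8f5f1ec2336ea6fb03108e022f41cb9f3d4b8f4ada"


class FixtureError(RuntimeError):
    """The packaged reference table failed its integrity check."""


@dataclass
class EEGRecording:
    """A five-channel resting-state EEG recording in microvolts.

    ``samples`` has shape (5, n_samples) with rows in the canonical
    channel order AF3, AF4, T7, T8, Pz.
    """

    participant_id: str
    sampling_rate: float
    samples: np.ndarray
    channel_names: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if tuple(self.channel_names) != CHANNELS:
            raise ValueError(
                f"channel_names must be {CHANNELS}, got {tuple(self.channel_names)}"
            )
        if self.samples.ndim != 2 or self.samples.shape[0] != len(CHANNELS):
            raise ValueError(
                f"samples must have shape (5, n), got {self.samples.shape}"
            )
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        # Non-finite samples are permitted at construction so that
        # validate_recording can diagnose them; the analysis entry
        # points reject them.

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def channel(self, name: str) -> np.ndarray:
        """Return one channel's samples by electrode name."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None
        return self.samples[idx]

    def copy_with(self, **changes) -> "EEGRecording":
        return replace(self, **changes)


@dataclass
class ParticipantRecord:
    """Demographics and labels for one participant."""

    id: str
    gender: str
    age: float
    pss_score: int
    pss_label: Optional[GroupLabel] = None
    expert_label: Optional[GroupLabel] = None

    def __post_init__(self) -> None:
        if not 0 <= self.pss_score <= 40:
            raise ValueError(
                f"participant {self.id}: PSS score {self.pss_score} outside [0, 40]"
            )
        if self.age <= 0:
            raise ValueError(f"participant {self.id}: age must be positive")
        if self.gender not in ("M", "F"):
            raise ValueError(f"participant {self.id}: gender must be M or F")


def read_eeg_csv(path: str | Path, participant_id: str | None = None,
                 sampling_rate: float = 128.0) -> EEGRecording:
    """Read a TestBench-style CSV export into an :class:`EEGRecording`.

    The header must contain all five channel names; column order is
    irrelevant and any extra columns are dropped (with a log notice).

    Parameters
    ----------
    path
        CSV file with one header row and one numeric row per sample.
    participant_id
        Identifier to attach; defaults to the file stem.
    sampling_rate
        Sampling rate in Hz of the stored samples (the file itself does
        not carry it).
    """
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [ch for ch in CHANNELS if ch not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing channel column(s) {', '.join(missing)}")
    extra = [c for c in frame.columns if c not in CHANNELS]
    if extra:
        logger.info("%s: ignoring non-channel column(s) %s", path, ", ".join(extra))
    data = np.empty((len(CHANNELS), len(frame)))
    for i, ch in enumerate(CHANNELS):
        col = pd.to_numeric(frame[ch], errors="coerce")
        bad = col.index[col.isna() & frame[ch].notna()]
        if frame[ch].isna().any():
            bad = bad.union(col.index[frame[ch].isna()])
        if len(bad):
            # +2: one for the header row, one for 1-based line numbers
            raise ValueError(
                f"{path}: non-numeric value in channel {ch} at row {bad[0] + 2}"
            )
        data[i] = col.to_numpy()
    return EEGRecording(
        participant_id=participant_id or path.stem,
        sampling_rate=sampling_rate,
        samples=data,
    )


def write_eeg_csv(recording: EEGRecording, path: str | Path) -> Path:
    """Write a recording as CSV with canonical header order.

    Floats are written with ``repr`` precision so that a read/write
    round trip is bit-exact.
    """
    path = Path(path)
    frame = pd.DataFrame(recording.samples.T, columns=list(CHANNELS))
    # %.17g guarantees a bit-exact float round trip
    frame.to_csv(path, index=False, float_format="%.17g")
    return path


def read_participants_csv(path: str | Path) -> list[ParticipantRecord]:
    """Read a participant table (id, gender, age, pss_score, labels)."""
    frame = pd.read_csv(Path(path), dtype={"id": str})
    required = {"id", "gender", "age", "pss_score"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(sorted(missing))}")

    def _label(value) -> Optional[GroupLabel]:
        if pd.isna(value) or value == "":
            return None
        return GroupLabel(value)

    records = []
    for _, row in frame.iterrows():
        records.append(
            ParticipantRecord(
                id=str(row["id"]),
                gender=str(row["gender"]),
                age=float(row["age"]),
                pss_score=int(row["pss_score"]),
                pss_label=_label(row.get("pss_label")),
                expert_label=_label(row.get("expert_label")),
            )
        )
    return records


def write_participants_csv(records: list[ParticipantRecord], path: str | Path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "gender": [r.gender for r in records],
            "age": [r.age for r in records],
            "pss_score": [r.pss_score for r in records],
            "pss_label": [r.pss_label.value if r.pss_label else "" for r in records],
            "expert_label": [
                r.expert_label.value if r.expert_label else "" for r in records
            ],
        }
    )
    frame.to_csv(path, index=False)
    return path


def _load_reference_text() -> str:
    return (
        resources.files("eegstress").joinpath("data/participants.csv").read_text()
    )


def load_reference_cohort() -> list[ParticipantRecord]:
    """The packaged 33-participant reference table.

    Returns the study cohort with both label columns populated: the PSS
    threshold label and the expert (hybrid) label, each one of A
    (control), B (stress) or X (neutral).  The file's SHA-256 is checked
    against the recorded value before parsing.
    """
    text = _load_reference_text()
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != _REFERENCE_SHA256:
        raise FixtureError(
            "packaged participant table failed its checksum "
            f"(got {digest}, expected {_REFERENCE_SHA256})"
        )
    import io as _io

    frame = pd.read_csv(_io.StringIO(text), dtype={"id": str})
    return [
        ParticipantRecord(
            id=str(row["id"]),
            gender=row["gender"],
            age=float(row["age"]),
            pss_score=int(row["pss_score"]),
            pss_label=GroupLabel(row["pss_label"]),
            expert_label=GroupLabel(row["expert_label"]),
        )
        for _, row in frame.iterrows()
    ]


def read_eeg_edf(path: str | Path, sampling_rate: float | None = None) -> EEGRecording:
    """Optional EDF adapter (requires the ``mne`` extra).

    Picks the five montage channels out of an EDF file and returns them
    in canonical order, in microvolts.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("EDF support requires mne (pip install eegstress[edf])") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    missing = [ch for ch in CHANNELS if ch not in raw.ch_names]
    if missing:
        raise ValueError(f"{path}: missing channel(s) {', '.join(missing)}")
    picks = [raw.ch_names.index(ch) for ch in CHANNELS]
    data = raw.get_data(picks=picks) * 1e6  # volts -> microvolts
    return EEGRecording(
        participant_id=Path(path).stem,
        sampling_rate=sampling_rate or float(raw.info["sfreq"]),
        samples=data,
    )
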