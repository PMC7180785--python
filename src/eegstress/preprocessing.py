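"""DC-offset removal and protocol validation.

Dry-electrode consumer headsets report samples riding on a large DC
offset (~4200 µV).  The single preprocessing step before spectral
analysis is subtracting each channel's mean over the whole recording;
the device's 1–43 Hz analogue response already excludes mains
interference, so no further filtering is applied by default.  An
optional 1–43 Hz band-pass is available for recordings from other
hardware.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .bands import CHANNELS
from .io import EEGRecording


@dataclass(frozen=True)
class PreprocessReport:
    """What was removed from each channel."""

    removed_offsets: dict[str, float]
    duration: float
    sampling_rate: float


def remove_dc_offset(recording: EEGRecording) -> tuple[EEGRecording, PreprocessReport]:
    """Subtract each channel's full-recording mean.

    Idempotent; leaves all above-DC spectral content untouched.
    """
    if recording.n_samples == 0:
        raise ValueError("cannot remove DC offset from an empty recording")
    means = recording.samples.mean(axis=1)
    cleaned = recording.copy_with(samples=recording.samples - means[:, None])
    report = PreprocessReport(
        removed_offsets={ch: float(m) for ch, m in zip(recording.channel_names, means)},
        duration=recording.duration,
        sampling_rate=recording.sampling_rate,
    )
    return cleaned, report


def bandpass_filter(
    recording: EEGRecording, low: float = 1.0, high: float = 43.0, order: int = 4
) -> EEGRecording:
    """Optional zero-phase Butterworth band-pass for non-native inputs."""
    nyq = recording.sampling_rate / 2
    if not 0 < low < high < nyq:
        raise ValueError(f"band edges must satisfy 0 < {low} < {high} < {nyq}")
    sos = sps.butter(order, [low, high], btype="bandpass",
                     fs=recording.sampling_rate, output="sos")
    return recording.copy_with(samples=sps.sosfiltfilt(sos, recording.samples, axis=1))


def validate_recording(
    recording: EEGRecording,
    expected_rate: float = 128.0,
    min_duration: float = 180.0,
) -> list[str]:
    """Check a recording against the acquisition protocol.

    Returns a list of human-readable diagnostics; the empty list means
    the recording is protocol compliant.  Never raises.
    """
    diagnostics: list[str] = []
    if tuple(recording.channel_names) != CHANNELS:
        diagnostics.append(
            f"unexpected channels {tuple(recording.channel_names)}, expected {CHANNELS}"
        )
    if recording.sampling_rate != expected_rate:
        diagnostics.append(
            f"sampling rate {recording.sampling_rate} Hz, expected {expected_rate} Hz"
        )
    if recording.duration < min_duration:
        diagnostics.append(
            f"short duration: {recording.duration:.1f} s < {min_duration:.1f} s"
        )
    finite = np.isfinite(recording.samples).all(axis=1)
    for ch, ok in zip(recording.channel_names, finite):
        if not ok:
            diagnostics.append(f"non-finite samples in channel {ch}")
    return diagnostics
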