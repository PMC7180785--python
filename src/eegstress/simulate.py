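"""Synthetic resting-state EEG cohorts with a plantable stress contrast.

No public recordings exist for the study protocol this package targets
(five dry electrodes, 128 Hz, three minutes, eyes closed), so the
generator produces seed-reproducible surrogate cohorts carrying exactly
the statistical structure the downstream analysis assumes:

* per channel, a large DC offset plus 1/f-shaped background noise plus
  narrow-band oscillations in the delta, theta, alpha, beta and gamma
  ranges (band powers A²/2 for planted amplitude A);
* a right-lateralised alpha contrast in the stress group — the AF4 and
  T8 alpha amplitudes are multiplied by ``1 + alpha_lateralization_effect``
  — which is the biomarker the screening and classifier stages are meant
  to detect;
* integer PSS scores drawn around group-shifted means, clipped to the
  questionnaire's 0–40 range;
* noisy simulated expert labels (true group kept with probability
  ``1 - flip_prob``, otherwise neutral or the opposite group).

Oscillations default to band-pass-filtered white noise (realistic
continuous spectra); a pure-sinusoid mode exists so that planted powers
can be checked against closed-form variances.

Per-participant seeds derive from the master seed by ``seed + index``,
so enlarging a cohort never reshuffles already-generated participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import signal as sps

from .bands import BAND_REGISTRY, CHANNELS, GENERATION_BANDS
from .io import EEGRecording, ParticipantRecord

GROUPS = ("control", "stress", "neutral")
RIGHT_CHANNELS = ("AF4", "T8")

#: Default planted oscillation amplitudes (µV), identical across
#: channels and groups before lateralization: a closed-eye resting
#: profile with dominant alpha.
DEFAULT_BAND_AMPLITUDES: dict[str, float] = {
    "delta": 4.0,
    "theta": 3.0,
    "alpha": 6.0,
    "beta": 2.0,
    "gamma": 1.0,
}

#: Sinusoid-mode carrier frequencies (Hz), at band centres on the 1 Hz grid.
SINUSOID_FREQUENCIES: dict[str, float] = {
    "delta": 2.0,
    "theta": 5.5,
    "alpha": 10.0,
    "beta": 21.5,
    "gamma": 34.0,
}

_EXPERT_SEED_OFFSET = 999_999_937  # keeps derived seeds distinct and < 2**31


def default_band_amplitudes() -> dict[str, dict[str, dict[str, float]]]:
    """group -> channel -> band amplitude map with the default profile."""
    return {
        group: {ch: dict(DEFAULT_BAND_AMPLITUDES) for ch in CHANNELS}
        for group in GROUPS
    }


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort generator.

    Amplitudes are in µV; ``alpha_lateralization_effect`` is the
    multiplicative right-hemisphere alpha boost applied to the stress
    group (0.5 → a 1.5x amplitude multiplier on AF4/T8).
    """

    n_control: int = 10
    n_stress: int = 10
    n_neutral: int = 0
    sampling_rate: float = 128.0
    duration: float = 180.0
    band_amplitudes: dict = field(default_factory=default_band_amplitudes)
    alpha_lateralization_effect: float = 0.5
    one_over_f_exponent: float = 1.0
    background_scale: float = 3.0
    dc_offset_range: tuple[float, float] = (4100.0, 4300.0)
    pss_group_means: Mapping[str, float] = field(
        default_factory=lambda: {"control": 12.0, "stress": 28.0, "neutral": 20.0}
    )
    pss_sd: float = 4.0
    expert_flip_prob: float = 0.1
    line_noise_amplitude: float = 0.0  # optional 50 Hz component
    oscillation_mode: str = "filtered_noise"  # or "sinusoid"
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_control, self.n_stress, self.n_neutral) < 0:
            raise ValueError("group counts must be non-negative")
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if not 0 <= self.expert_flip_prob <= 0.5:
            raise ValueError("expert_flip_prob must lie in [0, 0.5]")
        if self.pss_sd < 0:
            raise ValueError("pss_sd must be >= 0")
        if self.background_scale < 0:
            raise ValueError("background_scale must be >= 0")
        if self.oscillation_mode not in ("filtered_noise", "sinusoid"):
            raise ValueError(f"unknown oscillation_mode {self.oscillation_mode!r}")
        for group, channels in self.band_amplitudes.items():
            for ch, bands in channels.items():
                for band, amp in bands.items():
                    if amp < 0:
                        raise ValueError(
                            f"negative amplitude for {group}/{ch}/{band}: {amp}"
                        )


@dataclass
class SyntheticCohort:
    """Participants, their recordings and the generating ground truth."""

    participants: list[ParticipantRecord]
    recordings: dict[str, EEGRecording]
    true_group: dict[str, str]

    def validate(self) -> None:
        ids = [p.id for p in self.participants]
        if sorted(ids) != sorted(self.recordings) or sorted(ids) != sorted(
            self.true_group
        ):
            raise ValueError("participants, recordings and true_group are misaligned")


def _one_over_f_noise(
    rng: np.random.Generator, n: int, sampling_rate: float, exponent: float, scale: float
) -> np.ndarray:
    """1/f^exponent-shaped Gaussian noise with standard deviation ``scale``."""
    if scale == 0:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    spectrum = shape * (
        rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    )
    spectrum[0] = 0.0
    noise = np.fft.irfft(spectrum, n=n)
    sd = noise.std()
    return noise * (scale / sd) if sd > 0 else noise


def _band_oscillation(
    rng: np.random.Generator,
    band: str,
    amplitude: float,
    n: int,
    sampling_rate: float,
    mode: str,
) -> np.ndarray:
    """One band's oscillation with variance amplitude²/2."""
    if amplitude == 0:
        return np.zeros(n)
    if mode == "sinusoid":
        t = np.arange(n) / sampling_rate
        phase = rng.uniform(0, 2 * np.pi)
        return amplitude * np.sin(2 * np.pi * SINUSOID_FREQUENCIES[band] * t + phase)
    definition = BAND_REGISTRY[band]
    sos = sps.butter(
        4, [definition.low, definition.high], btype="bandpass",
        fs=sampling_rate, output="sos",
    )
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    target_sd = amplitude / np.sqrt(2.0)
    return x * (target_sd / sd) if sd > 0 else x


def generate_recording(
    config: GeneratorConfig, group: str, participant_seed: int,
    participant_id: str = "synthetic",
) -> EEGRecording:
    """One synthetic five-channel recording for a given group.

    Deterministic in (config, group, participant_seed).
    """
    config.validate()
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
    rng = np.random.default_rng(participant_seed)
    n = int(round(config.sampling_rate * config.duration))
    samples = np.empty((len(CHANNELS), n))
    amplitudes = config.band_amplitudes[group]
    t = np.arange(n) / config.sampling_rate
    for i, ch in enumerate(CHANNELS):
        channel = np.full(n, rng.uniform(*config.dc_offset_range))
        channel += _one_over_f_noise(
            rng, n, config.sampling_rate,
            config.one_over_f_exponent, config.background_scale,
        )
        for band in GENERATION_BANDS:
            amp = amplitudes[ch].get(band, 0.0)
            if group == "stress" and ch in RIGHT_CHANNELS and band == "alpha":
                amp *= 1.0 + config.alpha_lateralization_effect
            channel += _band_oscillation(
                rng, band, amp, n, config.sampling_rate, config.oscillation_mode
            )
        if config.line_noise_amplitude:
            channel += config.line_noise_amplitude * np.sin(
                2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi)
            )
        samples[i] = channel
    return EEGRecording(
        participant_id=participant_id,
        sampling_rate=config.sampling_rate,
        samples=samples,
    )


def _draw_pss_score(config: GeneratorConfig, group: str, index: int) -> int:
    rng = np.random.default_rng([config.seed, index, 1])
    score = rng.normal(config.pss_group_means[group], config.pss_sd)
    return int(np.clip(round(score), 0, 40))


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """A full synthetic cohort: recordings, PSS scores, expert labels.

    Participants are ordered control, stress, neutral with ids like
    ``sub-007``.  Recording seeds follow the ``seed + index`` rule;
    scores and expert labels come from separate derived streams, so the
    three ingredients are independently reproducible.
    """
    config.validate()
    total = config.n_control + config.n_stress + config.n_neutral
    if total == 0:
        raise ValueError("cohort is empty: all group counts are zero")
    groups = (
        ["control"] * config.n_control
        + ["stress"] * config.n_stress
        + ["neutral"] * config.n_neutral
    )
    participants: list[ParticipantRecord] = []
    recordings: dict[str, EEGRecording] = {}
    true_group: dict[str, str] = {}
    demo_rng = np.random.default_rng([config.seed, 2])
    for index, group in enumerate(groups):
        pid = f"sub-{index + 1:03d}"
        recordings[pid] = generate_recording(
            config, group, participant_seed=config.seed + index, participant_id=pid
        )
        true_group[pid] = group
        participants.append(
            ParticipantRecord(
                id=pid,
                gender="F" if demo_rng.random() < 0.4 else "M",
                age=float(demo_rng.integers(18, 41)),
                pss_score=_draw_pss_score(config, group, index),
            )
        )
    cohort = SyntheticCohort(
        participants=participants, recordings=recordings, true_group=true_group
    )
    expert = simulate_expert_labels(
        cohort, config.expert_flip_prob, seed=config.seed + _EXPERT_SEED_OFFSET
    )
    from .labeling import GroupLabel

    for p in participants:
        p.expert_label = GroupLabel(expert[p.id])
    return cohort


def simulate_expert_labels(
    cohort: SyntheticCohort, flip_prob: float, seed: int
) -> dict[str, str]:
    """Noisy stand-in for the psychologist's group assignment.

    Control/stress participants keep their true label with probability
    ``1 - flip_prob``; flips go to neutral or to the opposite group with
    equal probability.  Neutral participants are always labelled X.
    """
    if not cohort.participants:
        raise ValueError("cohort has no participants")
    if not 0 <= flip_prob <= 0.5:
        raise ValueError(f"flip_prob must lie in [0, 0.5], got {flip_prob}")
    rng = np.random.default_rng(seed)
    label_for = {"control": "A", "stress": "B", "neutral": "X"}
    opposite = {"control": "B", "stress": "A"}
    labels: dict[str, str] = {}
    for p in cohort.participants:
        group = cohort.true_group[p.id]
        if group == "neutral":
            labels[p.id] = "X"
            continue
        u = rng.random()
        if u < 1.0 - flip_prob:
            labels[p.id] = label_for[group]
        elif u < 1.0 - flip_prob / 2.0:
            labels[p.id] = "X"
        else:
            labels[p.id] = opposite[group]
    return labels
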