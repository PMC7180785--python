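"""Spectral features: Welch band powers, relative gamma and asymmetries.

Each recording yields 45 features:

* 40 per-channel values — integrated power (µV²) in the seven bands
  delta 1–3, theta 4–7, slow 4–13, alpha 8–12, low beta 13–17,
  beta 13–30 and gamma 25–43 Hz, plus the dimensionless relative gamma
  ratio — for the five channels AF3, T7, Pz, T8, AF4;
* 5 hemispheric asymmetry indices built from the frontal and temporal
  alpha and beta powers.

The power spectral density is estimated with Welch's method: 128-sample
Hann segments with 50 % overlap, constant detrend, which at 128 Hz gives
a 1 Hz grid.  A band power is the density summed over the bins with
``low <= f <= high`` (inclusive at both edges) times the bin width.

The asymmetry indices are normalised right-minus-left differences,

    alpha_frontal  = (a_AF4 - a_AF3) / (a_AF3 + a_AF4)
    alpha_temporal = (a_T8  - a_T7 ) / (a_T8  + a_T7 )
    alpha_asymmetry = alpha_frontal + alpha_temporal

and analogously ``beta_frontal`` / ``beta_temporal`` with beta powers.
Each single-pair index lies in (-1, 1) for positive powers; positive
values mean more right-hemisphere power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .bands import (
    ASYMMETRY_ORDER,
    BAND_REGISTRY,
    FEATURE_BAND_ORDER,
    FEATURE_CHANNEL_ORDER,
    FRONTAL_PAIR,
    TEMPORAL_PAIR,
    BandDefinition,
    feature_names,
)
from .io import EEGRecording

#: Default Welch segment length in samples (1 Hz resolution at 128 Hz).
DEFAULT_SEGMENT_LENGTH = 128
DEFAULT_OVERLAP_FRACTION = 0.5


@dataclass(frozen=True)
class PSDEstimate:
    """One-sided Welch power spectral density (µV²/Hz)."""

    frequencies: np.ndarray
    density: np.ndarray

    @property
    def bin_width(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    def total_power(self) -> float:
        """Integrated density over the whole grid (µV²)."""
        return float(self.density.sum() * self.bin_width)


def compute_psd(
    channel_signal: np.ndarray,
    sampling_rate: float,
    segment_length: int = DEFAULT_SEGMENT_LENGTH,
    overlap_fraction: float = DEFAULT_OVERLAP_FRACTION,
    window: str = "hann",
) -> PSDEstimate:
    """Welch PSD of one channel.

    Raises if the signal is shorter than a single segment.
    """
    x = np.asarray(channel_signal, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"expected a 1-D channel signal, got shape {x.shape}")
    if x.size < segment_length:
        raise ValueError(
            f"signal of {x.size} samples is shorter than one Welch segment "
            f"({segment_length} samples)"
        )
    freqs, density = sps.welch(
        x,
        fs=sampling_rate,
        window=window,
        nperseg=segment_length,
        noverlap=int(round(segment_length * overlap_fraction)),
        detrend="constant",
        scaling="density",
    )
    return PSDEstimate(frequencies=freqs, density=density)


def band_power(psd: PSDEstimate, band: BandDefinition) -> float:
    """Integrated power in ``band`` (inclusive edges), in µV²."""
    f = psd.frequencies
    if band.low < f[0] or band.high > f[-1]:
        raise ValueError(
            f"band {band.name} [{band.low}, {band.high}] Hz outside the "
            f"PSD grid [{f[0]}, {f[-1]}] Hz"
        )
    mask = (f >= band.low) & (f <= band.high)
    return float(psd.density[mask].sum() * psd.bin_width)


def relative_gamma(
    gamma_power: float, slow_power: float, direction: str = "gamma_over_slow"
) -> float:
    """Relative gamma: the gamma-to-slow-rhythm power ratio.

    The default follows the biomarker convention gamma/slow; the
    reciprocal is available via ``direction="slow_over_gamma"``.
    """
    if direction == "gamma_over_slow":
        num, den, name = gamma_power, slow_power, "slow"
    elif direction == "slow_over_gamma":
        num, den, name = slow_power, gamma_power, "gamma"
    else:
        raise ValueError(f"unknown relative-gamma direction {direction!r}")
    if den <= 0:
        raise ValueError(f"relative gamma undefined: {name} power is {den}")
    return num / den


def compute_band_powers(
    recording: EEGRecording,
    segment_length: int = DEFAULT_SEGMENT_LENGTH,
    overlap_fraction: float = DEFAULT_OVERLAP_FRACTION,
    rg_direction: str = "gamma_over_slow",
) -> pd.DataFrame:
    """Per-channel band-power table (channels x 8 columns incl. ``rg``)."""
    rows = {}
    for ch in recording.channel_names:
        psd = compute_psd(
            recording.channel(ch), recording.sampling_rate,
            segment_length=segment_length, overlap_fraction=overlap_fraction,
        )
        powers = {name: band_power(psd, BAND_REGISTRY[name]) for name in BAND_REGISTRY}
        powers["rg"] = relative_gamma(
            powers["gamma"], powers["slow"], direction=rg_direction
        )
        rows[ch] = powers
    table = pd.DataFrame.from_dict(rows, orient="index")
    return table.loc[list(FEATURE_CHANNEL_ORDER), list(FEATURE_BAND_ORDER)]


@dataclass(frozen=True)
class AsymmetryFeatures:
    """The five hemispheric asymmetry indices (dimensionless)."""

    alpha_frontal: float
    alpha_temporal: float
    alpha_asymmetry: float
    beta_frontal: float
    beta_temporal: float

    def as_series(self) -> pd.Series:
        return pd.Series(
            {name: getattr(self, name) for name in ASYMMETRY_ORDER}, dtype=float
        )


def _pair_asymmetry(left: float, right: float, what: str) -> float:
    if left <= 0 or right <= 0:
        raise ValueError(f"nonpositive {what} power (left={left}, right={right})")
    return (right - left) / (left + right)


def compute_asymmetries(band_powers: pd.DataFrame) -> AsymmetryFeatures:
    """Asymmetry indices from a per-channel band-power table.

    ``band_powers`` must be indexed by channel with ``alpha`` and
    ``beta`` columns (as produced by :func:`compute_band_powers`).
    """
    lf, rf = FRONTAL_PAIR
    lt, rt = TEMPORAL_PAIR
    af = _pair_asymmetry(band_powers.loc[lf, "alpha"], band_powers.loc[rf, "alpha"],
                         f"alpha {lf}/{rf}")
    at = _pair_asymmetry(band_powers.loc[lt, "alpha"], band_powers.loc[rt, "alpha"],
                         f"alpha {lt}/{rt}")
    bf = _pair_asymmetry(band_powers.loc[lf, "beta"], band_powers.loc[rf, "beta"],
                         f"beta {lf}/{rf}")
    bt = _pair_asymmetry(band_powers.loc[lt, "beta"], band_powers.loc[rt, "beta"],
                         f"beta {lt}/{rt}")
    return AsymmetryFeatures(
        alpha_frontal=af, alpha_temporal=at, alpha_asymmetry=af + at,
        beta_frontal=bf, beta_temporal=bt,
    )


def extract_features(
    recording: EEGRecording,
    segment_length: int = DEFAULT_SEGMENT_LENGTH,
    overlap_fraction: float = DEFAULT_OVERLAP_FRACTION,
    rg_direction: str = "gamma_over_slow",
    epoch_length: float | None = None,
) -> pd.Series:
    """The canonical 45-element named feature vector of one recording.

    With ``epoch_length`` (seconds) set, features are computed per
    non-overlapping epoch and averaged; the default is a single estimate
    over the whole recording (one value per participant).
    """
    if not np.all(np.isfinite(recording.samples)):
        raise ValueError(
            f"recording {recording.participant_id}: non-finite samples"
        )
    if epoch_length is not None:
        n_epoch = int(round(epoch_length * recording.sampling_rate))
        if n_epoch < segment_length:
            raise ValueError("epoch shorter than one Welch segment")
        starts = range(0, recording.n_samples - n_epoch + 1, n_epoch)
        vectors = [
            extract_features(
                recording.copy_with(samples=recording.samples[:, s:s + n_epoch]),
                segment_length=segment_length,
                overlap_fraction=overlap_fraction,
                rg_direction=rg_direction,
            )
            for s in starts
        ]
        return pd.concat(vectors, axis=1).mean(axis=1)

    table = compute_band_powers(
        recording, segment_length=segment_length,
        overlap_fraction=overlap_fraction, rg_direction=rg_direction,
    )
    per_channel = pd.Series(
        {
            f"{band}_{ch}": table.loc[ch, band]
            for ch in FEATURE_CHANNEL_ORDER
            for band in FEATURE_BAND_ORDER
        },
        dtype=float,
    )
    asym = compute_asymmetries(table).as_series()
    vector = pd.concat([per_channel, asym])
    assert list(vector.index) == feature_names()
    return vector


def feature_matrix(recordings: dict[str, EEGRecording], **kwargs) -> pd.DataFrame:
    """Stack per-recording feature vectors into a participants x 45 frame."""
    frame = pd.DataFrame(
        {pid: extract_features(rec, **kwargs) for pid, rec in recordings.items()}
    ).T
    frame.index.name = "id"
    return frame
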