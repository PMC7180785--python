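"""Channel montage and frequency-band registry.

The headset montage is fixed: five dry electrodes at AF3, AF4, T7, T8 and
Pz referenced to the left mastoid, sampled at 128 Hz.  Eight spectral
quantities are computed per channel — seven band powers plus relative
gamma — and five hemispheric asymmetry indices are derived from the
frontal (AF3/AF4) and temporal (T7/T8) alpha and beta powers, giving the
canonical 45-feature vector.

Bands deliberately overlap: ``slow`` (4–13 Hz) spans theta and alpha, and
``gamma`` (25–43 Hz) shares 25–30 Hz with ``beta``.  Each band power is
computed independently over its own interval.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Canonical channel order of a stored recording.
CHANNELS: tuple[str, ...] = ("AF3", "AF4", "T7", "T8", "Pz")

#: Channel order used in feature vectors and screening reports
#: (frontal-left, temporal-left, midline, temporal-right, frontal-right).
FEATURE_CHANNEL_ORDER: tuple[str, ...] = ("AF3", "T7", "Pz", "T8", "AF4")

FRONTAL_PAIR: tuple[str, str] = ("AF3", "AF4")  # (left, right)
TEMPORAL_PAIR: tuple[str, str] = ("T7", "T8")  # (left, right)


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with inclusive edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(
                f"band {self.name!r}: need 0 < low < high, got "
                f"[{self.low}, {self.high}]"
            )


#: The seven analysis bands, in feature-vector order (relative gamma is
#: appended as the eighth per-channel feature).
BAND_REGISTRY: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 1.0, 3.0),
    "theta": BandDefinition("theta", 4.0, 7.0),
    "slow": BandDefinition("slow", 4.0, 13.0),
    "alpha": BandDefinition("alpha", 8.0, 12.0),
    "low_beta": BandDefinition("low_beta", 13.0, 17.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
    "gamma": BandDefinition("gamma", 25.0, 43.0),
}

#: Per-channel feature order: seven band powers then relative gamma.
FEATURE_BAND_ORDER: tuple[str, ...] = (
    "delta", "theta", "slow", "alpha", "low_beta", "beta", "gamma", "rg",
)

#: Asymmetry feature order appended after the 40 per-channel features.
ASYMMETRY_ORDER: tuple[str, ...] = (
    "alpha_temporal", "alpha_frontal",
    "beta_temporal", "beta_frontal",
    "alpha_asymmetry",
)

#: Non-overlapping subset used by the synthetic generator to plant
#: oscillations (slow and low_beta are derived, not planted).
GENERATION_BANDS: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma")


def feature_names() -> list[str]:
    """The 45 canonical feature names, in canonical order.

    40 per-channel names like ``"alpha_AF3"`` (channels in
    :data:`FEATURE_CHANNEL_ORDER`, bands in :data:`FEATURE_BAND_ORDER`)
    followed by the five asymmetries.
    """
    names = [
        f"{band}_{channel}"
        for channel in FEATURE_CHANNEL_ORDER
        for band in FEATURE_BAND_ORDER
    ]
    names.extend(ASYMMETRY_ORDER)
    return names
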