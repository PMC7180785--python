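"""Welch band powers, relative gamma and asymmetry indices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import eegstress as es
from eegstress.bands import ASYMMETRY_ORDER, BAND_REGISTRY, feature_names
from eegstress.features import PSDEstimate

FS = 128.0


def _sinusoid(freq, duration=180.0, amplitude=1.0):
    t = np.arange(int(FS * duration)) / FS
    return amplitude * np.sin(2 * np.pi * freq * t)


class TestPSD:
    def test_zero_signal_zero_density(self):
        psd = es.compute_psd(np.zeros(4096), FS)
        np.testing.assert_array_equal(psd.density, 0.0)

    def test_one_hz_grid_at_defaults(self):
        psd = es.compute_psd(np.zeros(4096), FS)
        assert psd.bin_width == pytest.approx(1.0)
        assert psd.frequencies[-1] == pytest.approx(64.0)

    def test_sinusoid_power_concentrates_at_its_bin(self):
        psd = es.compute_psd(_sinusoid(10.0), FS)
        # variance of a unit sinusoid is 1/2
        assert psd.total_power() == pytest.approx(0.5, rel=0.02)
        peak = psd.frequencies[np.argmax(psd.density)]
        assert peak == pytest.approx(10.0)

    def test_white_noise_total_power_matches_variance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 2.0, int(FS * 180))
        psd = es.compute_psd(x, FS)
        assert psd.total_power() == pytest.approx(x.var(), rel=0.05)

    def test_signal_shorter_than_segment_rejected(self):
        with pytest.raises(ValueError, match="shorter than one Welch segment"):
            es.compute_psd(np.zeros(100), FS)


class TestBandPower:
    def test_zero_psd_gives_zero_for_every_band(self):
        psd = es.compute_psd(np.zeros(4096), FS)
        for band in BAND_REGISTRY.values():
            assert es.band_power(psd, band) == 0.0

    def test_planted_alpha_sinusoid_lands_in_alpha_not_delta(self):
        psd = es.compute_psd(_sinusoid(10.0), FS)
        alpha = es.band_power(psd, BAND_REGISTRY["alpha"])
        delta = es.band_power(psd, BAND_REGISTRY["delta"])
        assert alpha == pytest.approx(0.5, rel=0.02)
        assert delta < 0.01 * alpha

    def test_flat_density_hand_count(self):
        psd = PSDEstimate(np.arange(65.0), np.full(65, 3.0))
        # alpha = bins 8..12 inclusive -> 5 bins x 1 Hz x 3
        assert es.band_power(psd, BAND_REGISTRY["alpha"]) == pytest.approx(15.0)
        # delta = bins 1..3 -> 3 bins
        assert es.band_power(psd, BAND_REGISTRY["delta"]) == pytest.approx(9.0)

    def test_band_outside_grid_rejected(self):
        psd = PSDEstimate(np.arange(33.0), np.ones(33))
        with pytest.raises(ValueError, match="outside"):
            es.band_power(psd, BAND_REGISTRY["gamma"])


class TestRelativeGamma:
    def test_equal_powers_give_one(self):
        assert es.relative_gamma(2.5, 2.5) == pytest.approx(1.0)

    def test_default_direction_is_gamma_over_slow(self):
        assert es.relative_gamma(2.0, 4.0) == pytest.approx(0.5)

    def test_reciprocal_direction(self):
        assert es.relative_gamma(2.0, 4.0, direction="slow_over_gamma") == pytest.approx(2.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError, match="slow"):
            es.relative_gamma(2.0, 0.0)


def _power_table(alpha, beta):
    """Band-power frame from per-channel (alpha, beta) dicts."""
    frame = pd.DataFrame(
        1.0, index=list(es.CHANNELS), columns=list(BAND_REGISTRY) + ["rg"]
    )
    for ch, v in alpha.items():
        frame.loc[ch, "alpha"] = v
    for ch, v in beta.items():
        frame.loc[ch, "beta"] = v
    return frame


class TestAsymmetries:
    def test_symmetric_powers_give_zero(self):
        table = _power_table({}, {})
        asym = es.compute_asymmetries(table)
        assert asym.alpha_frontal == asym.alpha_temporal == asym.alpha_asymmetry == 0.0
        assert asym.beta_frontal == asym.beta_temporal == 0.0

    def test_hand_computed_case(self):
        table = _power_table({"AF4": 3.0, "AF3": 1.0, "T8": 2.0, "T7": 2.0}, {})
        asym = es.compute_asymmetries(table)
        assert asym.alpha_frontal == pytest.approx(0.5)
        assert asym.alpha_temporal == pytest.approx(0.0)
        assert asym.alpha_asymmetry == pytest.approx(0.5)

    @given(
        powers=st.lists(
            st.floats(min_value=1e-3, max_value=1e3), min_size=8, max_size=8
        )
    )
    def test_swapping_hemispheres_negates_every_index(self, powers):
        a3, a4, t7, t8, b3, b4, bt7, bt8 = powers
        fwd = es.compute_asymmetries(
            _power_table({"AF3": a3, "AF4": a4, "T7": t7, "T8": t8},
                         {"AF3": b3, "AF4": b4, "T7": bt7, "T8": bt8})
        )
        rev = es.compute_asymmetries(
            _power_table({"AF3": a4, "AF4": a3, "T7": t8, "T8": t7},
                         {"AF3": b4, "AF4": b3, "T7": bt8, "T8": bt7})
        )
        for name in ASYMMETRY_ORDER:
            assert getattr(rev, name) == pytest.approx(-getattr(fwd, name), abs=1e-12)

    @given(
        powers=st.lists(
            st.floats(min_value=1e-3, max_value=1e3), min_size=4, max_size=4
        )
    )
    def test_alpha_asymmetry_is_exactly_the_sum_of_its_parts(self, powers):
        a3, a4, t7, t8 = powers
        asym = es.compute_asymmetries(
            _power_table({"AF3": a3, "AF4": a4, "T7": t7, "T8": t8}, {})
        )
        assert asym.alpha_asymmetry == asym.alpha_frontal + asym.alpha_temporal
        assert -1 < asym.alpha_frontal < 1
        assert -2 < asym.alpha_asymmetry < 2

    def test_nonpositive_power_rejected_with_location(self):
        table = _power_table({"AF3": 0.0}, {})
        with pytest.raises(ValueError, match="alpha AF3"):
            es.compute_asymmetries(table)


class TestExtractFeatures:
    def test_vector_has_45_named_entries_in_canonical_order(self, default_recording):
        cleaned, _ = es.remove_dc_offset(default_recording)
        vector = es.extract_features(cleaned)
        assert len(vector) == 45
        assert list(vector.index) == feature_names()

    def test_deterministic(self, default_recording):
        cleaned, _ = es.remove_dc_offset(default_recording)
        a = es.extract_features(cleaned)
        b = es.extract_features(cleaned)
        pd.testing.assert_series_equal(a, b)

    def test_symmetric_recording_has_small_alpha_asymmetry(self):
        config = es.GeneratorConfig(seed=5)  # identical amplitudes everywhere
        values = []
        for seed in range(5):
            rec = es.generate_recording(config, "control", seed)
            cleaned, _ = es.remove_dc_offset(rec)
            values.append(es.extract_features(cleaned)["alpha_asymmetry"])
        assert np.all(np.abs(values) < 0.05)

    def test_scale_equivariance(self, default_recording):
        cleaned, _ = es.remove_dc_offset(default_recording)
        k = 3.0
        base = es.extract_features(cleaned)
        scaled = es.extract_features(cleaned.copy_with(samples=cleaned.samples * k))
        band_cols = [n for n in base.index if n not in ASYMMETRY_ORDER
                     and not n.startswith("rg_")]
        np.testing.assert_allclose(
            scaled[band_cols], base[band_cols] * k**2, rtol=1e-9
        )
        invariant = [n for n in base.index
                     if n in ASYMMETRY_ORDER or n.startswith("rg_")]
        np.testing.assert_allclose(scaled[invariant], base[invariant], rtol=1e-9)

    def test_energy_consistency_for_zero_mean_signal(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(int(FS * 180))
        x -= x.mean()
        psd = es.compute_psd(x, FS)
        assert psd.total_power() == pytest.approx(x.var(), rel=0.05)

    def test_epoch_averaged_features_close_to_whole_recording(self, default_recording):
        cleaned, _ = es.remove_dc_offset(default_recording)
        whole = es.extract_features(cleaned)
        epoched = es.extract_features(cleaned, epoch_length=30.0)
        np.testing.assert_allclose(
            epoched[:40].to_numpy(), whole[:40].to_numpy(), rtol=0.2
        )

    def test_feature_matrix_shape_and_index(self, quiet_config):
        cohort = es.generate_cohort(
            es.GeneratorConfig(n_control=2, n_stress=1, duration=10.0, seed=2)
        )
        matrix = es.feature_matrix(cohort.recordings)
        assert matrix.shape == (3, 45)
        assert sorted(matrix.index) == sorted(cohort.recordings)
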