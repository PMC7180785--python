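"""Synthetic cohort generator: determinism, planted structure, null behaviour."""

import numpy as np
import pytest
from scipy import stats

import eegstress as es
from eegstress.bands import BAND_REGISTRY, GENERATION_BANDS

from conftest import sinusoid_config


def _alpha_asymmetry(recording):
    cleaned, _ = es.remove_dc_offset(recording)
    return es.extract_features(cleaned)["alpha_asymmetry"]


class TestGenerateRecording:
    def test_sample_count_is_rate_times_duration(self):
        rec = es.generate_recording(es.GeneratorConfig(duration=180.0), "control", 0)
        assert rec.samples.shape == (5, 23040)

    def test_degenerate_config_yields_constant_offset(self):
        config = es.GeneratorConfig(
            duration=5.0,
            background_scale=0.0,
            dc_offset_range=(4200.0, 4200.0),
            band_amplitudes={
                g: {ch: {} for ch in es.CHANNELS}
                for g in ("control", "stress", "neutral")
            },
        )
        rec = es.generate_recording(config, "neutral", 3)
        np.testing.assert_array_equal(rec.samples, 4200.0)

    def test_pure_sinusoid_variance_matches_closed_form(self):
        config = sinusoid_config(amplitude=2.0)
        rec = es.generate_recording(config, "control", 1)
        for ch in es.CHANNELS:
            assert rec.channel(ch).var() == pytest.approx(2.0, rel=0.01)  # A^2/2

    def test_deterministic_in_config_group_and_seed(self):
        config = es.GeneratorConfig(duration=10.0, seed=0)
        a = es.generate_recording(config, "stress", 7)
        b = es.generate_recording(config, "stress", 7)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_invalid_group_rejected(self):
        with pytest.raises(ValueError, match="group"):
            es.generate_recording(es.GeneratorConfig(duration=1.0), "patient", 0)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            es.generate_recording(es.GeneratorConfig(duration=0.0), "control", 0)

    @pytest.mark.parametrize("band", GENERATION_BANDS)
    def test_spectral_fidelity_of_each_planted_band(self, band):
        """A lone planted oscillation's band power recovers A^2/2 within 5%."""
        amplitude = 3.0
        amps = {
            g: {ch: {band: amplitude} for ch in es.CHANNELS}
            for g in ("control", "stress", "neutral")
        }
        config = es.GeneratorConfig(
            duration=180.0, background_scale=0.0, dc_offset_range=(0.0, 0.0),
            band_amplitudes=amps, alpha_lateralization_effect=0.0,
        )
        rec = es.generate_recording(config, "control", 2)
        psd = es.compute_psd(rec.channel("Pz"), 128.0)
        power = es.band_power(psd, BAND_REGISTRY[band])
        assert power == pytest.approx(amplitude**2 / 2, rel=0.05)

    def test_optional_line_noise_lands_at_50hz(self):
        config = es.GeneratorConfig(
            duration=30.0, background_scale=0.0, dc_offset_range=(0.0, 0.0),
            band_amplitudes={
                g: {ch: {} for ch in es.CHANNELS}
                for g in ("control", "stress", "neutral")
            },
            line_noise_amplitude=1.0,
        )
        rec = es.generate_recording(config, "control", 0)
        psd = es.compute_psd(rec.channel("AF3"), 128.0)
        assert psd.frequencies[np.argmax(psd.density)] == pytest.approx(50.0)


class TestGenerateCohort:
    def test_counts_and_score_range(self):
        config = es.GeneratorConfig(
            n_control=9, n_stress=12, n_neutral=12, duration=2.0, seed=1
        )
        cohort = es.generate_cohort(config)
        cohort.validate()
        assert len(cohort.participants) == 33
        groups = list(cohort.true_group.values())
        assert groups.count("control") == 9
        assert groups.count("stress") == 12
        assert groups.count("neutral") == 12
        for p in cohort.participants:
            assert isinstance(p.pss_score, int) and 0 <= p.pss_score <= 40

    def test_reproducible_from_seed(self):
        config = es.GeneratorConfig(n_control=2, n_stress=2, duration=3.0, seed=9)
        a = es.generate_cohort(config)
        b = es.generate_cohort(config)
        assert [p.pss_score for p in a.participants] == [
            p.pss_score for p in b.participants
        ]
        assert [p.expert_label for p in a.participants] == [
            p.expert_label for p in b.participants
        ]
        for pid in a.recordings:
            np.testing.assert_array_equal(
                a.recordings[pid].samples, b.recordings[pid].samples
            )

    def test_enlarging_cohort_keeps_earlier_recordings(self):
        small = es.generate_cohort(
            es.GeneratorConfig(n_control=3, n_stress=0, n_neutral=0,
                               duration=2.0, seed=4)
        )
        large = es.generate_cohort(
            es.GeneratorConfig(n_control=5, n_stress=0, n_neutral=0,
                               duration=2.0, seed=4)
        )
        for pid in small.recordings:
            np.testing.assert_array_equal(
                small.recordings[pid].samples, large.recordings[pid].samples
            )

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            es.generate_cohort(
                es.GeneratorConfig(n_control=0, n_stress=0, n_neutral=0)
            )

    def test_null_cohorts_give_uniform_alpha_asymmetry_pvalues(self):
        """With no planted effect the screening p-value is U(0,1)-distributed."""
        config_base = dict(
            n_control=8, n_stress=8, duration=20.0,
            alpha_lateralization_effect=0.0,
        )
        pvalues = []
        for seed in range(200):
            cohort = es.generate_cohort(es.GeneratorConfig(seed=seed, **config_base))
            aa = {
                pid: _alpha_asymmetry(rec) for pid, rec in cohort.recordings.items()
            }
            control = [aa[p] for p, g in cohort.true_group.items() if g == "control"]
            stress = [aa[p] for p, g in cohort.true_group.items() if g == "stress"]
            pvalues.append(es.two_sample_ttest(control, stress)[1])
        assert stats.kstest(pvalues, "uniform").pvalue > 0.01

    def test_planted_lateralization_raises_stress_alpha_asymmetry(self):
        """Right-alpha x1.5 in the stress group shifts the biomarker upward."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            config = es.GeneratorConfig(
                n_control=10, n_stress=10, duration=30.0,
                alpha_lateralization_effect=0.5, seed=seed,
            )
            cohort = es.generate_cohort(config)
            aa = {
                pid: _alpha_asymmetry(rec) for pid, rec in cohort.recordings.items()
            }
            control = np.mean(
                [aa[p] for p, g in cohort.true_group.items() if g == "control"]
            )
            stress = np.mean(
                [aa[p] for p, g in cohort.true_group.items() if g == "stress"]
            )
            hits += stress > control
        assert hits >= 0.9 * n_seeds


class TestExpertLabels:
    def _bare_cohort(self, groups):
        participants = [
            es.ParticipantRecord(id=str(i), gender="M", age=25, pss_score=20)
            for i in range(len(groups))
        ]
        return es.SyntheticCohort(
            participants=participants,
            recordings={},
            true_group={str(i): g for i, g in enumerate(groups)},
        )

    def test_zero_flip_probability_is_identity(self):
        cohort = self._bare_cohort(["control"] * 5 + ["stress"] * 5)
        labels = es.simulate_expert_labels(cohort, 0.0, seed=0)
        expected = {"control": "A", "stress": "B"}
        for pid, group in cohort.true_group.items():
            assert labels[pid] == expected[group]

    def test_half_flip_probability_agrees_half_the_time(self):
        cohort = self._bare_cohort(["control"] * 5000 + ["stress"] * 5000)
        labels = es.simulate_expert_labels(cohort, 0.5, seed=1)
        truth = {"control": "A", "stress": "B"}
        agree = sum(
            labels[p] == truth[g] for p, g in cohort.true_group.items()
        ) / 10000
        assert agree == pytest.approx(0.5, abs=0.02)

    def test_neutral_participants_always_get_x(self):
        cohort = self._bare_cohort(["neutral"] * 10)
        labels = es.simulate_expert_labels(cohort, 0.3, seed=2)
        assert set(labels.values()) == {"X"}

    def test_flip_probability_bounds_enforced(self):
        cohort = self._bare_cohort(["control"])
        with pytest.raises(ValueError, match="flip_prob"):
            es.simulate_expert_labels(cohort, 0.6, seed=0)
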