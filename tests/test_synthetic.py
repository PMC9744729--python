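"""Cohort generator: group effects, beat synthesis, determinism."""

import numpy as np
import pytest

from pulsespec import (
    BeatSpectrum,
    CohortConfig,
    ResolutionError,
    SubjectSpec,
    ValidationError,
    default_base_profile,
    extract_features,
    generate_cohort,
    generate_recording,
    make_group_profiles,
    synthesize_beat,
)
from pulsespec.synthetic import GROUPS


class TestGroupProfiles:
    def test_zero_effect_leaves_profiles_identical(self, base_profile):
        profiles = make_group_profiles(0.0, base_profile)
        for group in GROUPS:
            p = profiles[group]
            np.testing.assert_array_equal(p.mean_amplitude, base_profile.mean_amplitude)
            np.testing.assert_array_equal(p.mean_phase, base_profile.mean_phase)
            np.testing.assert_array_equal(p.amplitude_cv, base_profile.amplitude_cv)

    def test_negative_effect_scale_rejected(self, base_profile):
        with pytest.raises(ValidationError):
            make_group_profiles(-0.5, base_profile)

    def test_sarcopenia_proportions_lower_for_every_harmonic(self, base_profile):
        profiles = make_group_profiles(1.0, base_profile)

        def proportions(p):
            return p.mean_amplitude[1:] / p.mean_amplitude.sum()

        rob, sar = proportions(profiles["robust"]), proportions(profiles["sarcopenia"])
        assert np.all(sar < rob)

    def test_variability_higher_in_sarcopenia(self, base_profile):
        profiles = make_group_profiles(1.0, base_profile)
        assert (
            profiles["sarcopenia"].amplitude_cv[2]
            > profiles["robust"].amplitude_cv[2]
        )

    def test_monotone_severity_ordering(self, base_profile):
        profiles = make_group_profiles(1.0, base_profile)
        amp1 = [profiles[g].mean_amplitude[1] for g in GROUPS]
        assert amp1 == sorted(amp1, reverse=True)
        phase1 = [profiles[g].mean_phase[0] for g in GROUPS]
        assert phase1 == sorted(phase1, reverse=True)
        cv5 = [profiles[g].amplitude_cv[4] for g in GROUPS]
        assert cv5 == sorted(cv5)

    def test_phase_effect_on_selected_harmonics_only(self, base_profile):
        profiles = make_group_profiles(1.0, base_profile)
        delta = profiles["sarcopenia"].mean_phase - base_profile.mean_phase
        np.testing.assert_allclose(delta[[0, 1, 2, 4]], -0.15)
        np.testing.assert_allclose(delta[[3, 5, 6, 7, 8, 9]], 0.0)


class TestSynthesizeBeat:
    def test_single_harmonic_is_cosine(self):
        spec = BeatSpectrum(
            np.concatenate([[0.0], [1.0], np.zeros(9)]), np.zeros(10)
        )
        samples = synthesize_beat(spec, 1.0, 250.0)
        t = np.arange(250) / 250.0
        np.testing.assert_allclose(samples, np.cos(2 * np.pi * t), atol=1e-12)

    def test_constant_offset_only(self):
        spec = BeatSpectrum(
            np.concatenate([[4.2], np.zeros(10)]), np.zeros(10)
        )
        np.testing.assert_array_equal(synthesize_beat(spec, 0.8, 250.0), 4.2)

    def test_resolution_floor(self):
        spec = BeatSpectrum(np.concatenate([[0.0], np.ones(10)]), np.zeros(10))
        with pytest.raises(ResolutionError):
            synthesize_beat(spec, 0.1, 250.0)


class TestGenerateRecording:
    def test_degenerate_dispersion_gives_zero_cv(self, clean_subject):
        rec, truth = clean_subject
        assert np.all(truth.features.cv < 1e-12)
        assert np.all(truth.features.p_sd_deg < 1e-12)
        fv = extract_features(rec)
        # zero up to detrending edge residue, far below physiologic levels
        assert np.all(fv.cv < 5e-3)
        assert np.all(fv.p_sd_deg < 0.5)

    def test_beat_count_arithmetic(self, still_profile, clean_config):
        spec = SubjectSpec("count", "robust", "no_mets", 72.0, 0.0, still_profile)
        _, truth = generate_recording(spec, clean_config)
        assert len(truth.onset_indices) == 72

    def test_fixed_seed_is_bit_identical(self, base_profile):
        cfg = CohortConfig(seed=9)
        spec = SubjectSpec("det", "robust", "no_mets", 70.0, 0.05, base_profile)
        rec1, _ = generate_recording(spec, cfg)
        rec2, _ = generate_recording(spec, cfg)
        assert rec1.samples.tobytes() == rec2.samples.tobytes()

    def test_rr_series_matches_onsets(self, clean_subject):
        rec, truth = clean_subject
        np.testing.assert_allclose(
            np.diff(truth.onset_indices) / rec.sampling_rate, truth.rr_s[:-1]
        )

    def test_parameter_recovery_dispersion_free(self, clean_subject):
        rec, truth = clean_subject
        fv = extract_features(rec)
        assert np.abs(fv.c - truth.features.c).max() <= 1e-3
        assert np.abs(fv.p_deg - truth.features.p_deg).max() <= 0.5


class TestGenerateCohort:
    def test_default_cohort_size_and_groups(self):
        cfg = CohortConfig()
        assert sum(cfg.group_sizes.values()) == 133
        assert cfg.group_sizes["robust"] == 74

    def test_small_cohort_structure(self, small_config):
        cohort = generate_cohort(small_config)
        assert len(cohort.recordings) == 18
        counts = cohort.subjects["group"].value_counts()
        assert counts["robust"] == 9
        assert set(cohort.subjects["mets_status"]) <= {"no_mets", "pre_mets"}

    def test_same_seed_reproduces_cohort(self, small_config):
        a = generate_cohort(small_config)
        b = generate_cohort(small_config)
        assert a.subjects.equals(b.subjects)
        assert all(
            x.samples.tobytes() == y.samples.tobytes()
            for x, y in zip(a.recordings, b.recordings)
        )

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            generate_cohort(
                CohortConfig(group_sizes={g: 0 for g in GROUPS})
            )

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            CohortConfig(sampling_rate=50.0)
        with pytest.raises(ValidationError):
            CohortConfig(effect_scale=-1.0)
        with pytest.raises(ValidationError):
            CohortConfig(mets_fraction=1.5)

    def test_subject_spec_validation(self, base_profile):
        with pytest.raises(ValidationError):
            SubjectSpec("x", "robust", "no_mets", 30.0, 0.0, base_profile)
        with pytest.raises(ValidationError):
            SubjectSpec("x", "unknown", "no_mets", 70.0, 0.0, base_profile)
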