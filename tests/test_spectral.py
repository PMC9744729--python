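"""Per-beat harmonic analysis and the 40-index aggregation."""

import numpy as np
import pytest

from pulsespec import (
    BeatSegment,
    BeatSpectrum,
    DegenerateSpectrumError,
    InsufficientBeatsError,
    ResolutionError,
    ValidationError,
    amplitude_proportions,
    beat_harmonics,
    extract_features,
    hr_cv,
    recording_features,
    synthesize_beat,
)
from pulsespec.spectral import FEATURE_NAMES, SPECTRAL_FEATURE_NAMES


def _spectrum(amps10, phases10, a0=0.0):
    return BeatSpectrum(np.concatenate([[a0], amps10]), np.asarray(phases10))


def _beat(samples, period_s):
    return BeatSegment(np.asarray(samples), 0, period_s)


class TestBeatHarmonics:
    def test_single_cosine(self):
        t = np.arange(250) / 250.0
        beat = _beat(np.cos(2 * np.pi * t / 1.0), 1.0)
        spec = beat_harmonics(beat)
        assert spec.amplitude[1] == pytest.approx(1.0, abs=1e-9)
        assert np.all(spec.amplitude[2:] < 1e-9)
        assert spec.phase[0] == pytest.approx(0.0, abs=1e-6)

    def test_two_harmonic_construction(self):
        t = np.arange(200) / 200.0
        y = 2.0 * np.cos(2 * np.pi * t) + 1.0 * np.cos(4 * np.pi * t + np.pi / 4)
        spec = beat_harmonics(_beat(y, 0.8))
        assert spec.amplitude[1] == pytest.approx(2.0, abs=1e-9)
        assert spec.amplitude[2] == pytest.approx(1.0, abs=1e-9)
        assert spec.phase[1] == pytest.approx(np.pi / 4, abs=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_round_trip_inverts_synthesis(self, seed):
        rng = np.random.default_rng(seed)
        amps = rng.uniform(0.2, 3.0, 10)
        phases = rng.uniform(-np.pi, np.pi, 10)
        spec = _spectrum(amps, phases, a0=rng.uniform(1.0, 10.0))
        n = int(rng.integers(120, 400))
        period = n / 250.0
        samples = synthesize_beat(spec, period, 250.0)
        rec = beat_harmonics(_beat(samples, period))
        np.testing.assert_allclose(rec.amplitude, spec.amplitude, rtol=1e-6, atol=1e-9)
        dphi = np.angle(np.exp(1j * (rec.phase - spec.phase)))
        np.testing.assert_allclose(dphi, 0.0, atol=1e-6)

    def test_too_few_samples(self):
        with pytest.raises(ResolutionError):
            beat_harmonics(_beat(np.zeros(30), 0.12))

    def test_raw_mean_becomes_dc_term(self):
        t = np.arange(250) / 250.0
        beat = BeatSegment(np.cos(2 * np.pi * t), 0, 1.0, raw_mean=88.5)
        assert beat_harmonics(beat).amplitude[0] == pytest.approx(88.5)


class TestAmplitudeProportions:
    def test_sum_mode_matches_hand_values(self):
        spec = _spectrum([2, 1, 0, 0, 0, 0, 0, 0, 0, 0], np.zeros(10))
        c = amplitude_proportions(spec, "sum")
        np.testing.assert_allclose(c[:2], [2 / 3, 1 / 3])
        assert np.all(c[2:] == 0)

    def test_sum_mode_normalizes_to_one(self):
        rng = np.random.default_rng(3)
        spec = _spectrum(rng.uniform(0.1, 2, 10), np.zeros(10))
        assert amplitude_proportions(spec, "sum").sum() == pytest.approx(1.0, abs=1e-12)

    def test_equal_amplitudes_give_tenths(self):
        spec = _spectrum(np.full(10, 0.7), np.zeros(10))
        np.testing.assert_allclose(amplitude_proportions(spec, "sum"), 0.1)

    def test_dc_mode_divides_by_mean_level(self):
        spec = _spectrum([3, 1, 0, 0, 0, 0, 0, 0, 0, 0], np.zeros(10), a0=30.0)
        c = amplitude_proportions(spec, "dc")
        np.testing.assert_allclose(c[:2], [0.1, 1 / 30])

    def test_zero_spectrum_is_degenerate(self):
        spec = _spectrum(np.zeros(10), np.zeros(10), a0=1.0)
        with pytest.raises(DegenerateSpectrumError):
            amplitude_proportions(spec, "sum")

    def test_dc_mode_requires_positive_dc(self):
        spec = _spectrum(np.ones(10), np.zeros(10), a0=0.0)
        with pytest.raises(DegenerateSpectrumError):
            amplitude_proportions(spec, "dc")


class TestRecordingFeatures:
    def test_identical_beats_have_zero_dispersion(self):
        spec = _spectrum(np.linspace(1, 0.1, 10), np.linspace(-1, 1, 10), a0=5.0)
        fv = recording_features([spec] * 25)
        assert np.all(fv.cv < 1e-12)
        assert np.all(fv.p_sd_deg < 1e-12)

    def test_two_beat_hand_arithmetic(self):
        # per-beat C1 of 0.6 and 0.4 in sum mode
        b1 = _spectrum([3, 2, 0, 0, 0, 0, 0, 0, 0, 0], np.zeros(10))
        b2 = _spectrum([2, 3, 0, 0, 0, 0, 0, 0, 0, 0], np.zeros(10))
        fv = recording_features([b1, b2], normalization="sum", min_beats=2)
        assert fv.c[0] == pytest.approx(0.5)
        assert fv.cv[0] == pytest.approx(0.1414213 / 0.5, abs=1e-4)

    def test_forty_spectral_indices(self, noisy_subject):
        rec, _ = noisy_subject
        series = extract_features(rec).to_series()
        assert len(SPECTRAL_FEATURE_NAMES) == 40
        assert list(series.index) == FEATURE_NAMES
        assert series.notna().all()

    def test_insufficient_beats(self):
        spec = _spectrum(np.ones(10), np.zeros(10), a0=1.0)
        with pytest.raises(InsufficientBeatsError):
            recording_features([spec] * 19)

    def test_phase_unwrap_across_seam(self):
        # phases alternating around +/-pi must not produce a ~360 deg SD
        phases = [np.pi - 0.05, -np.pi + 0.05, np.pi - 0.02, -np.pi + 0.03]
        beats = [
            _spectrum(np.ones(10), np.full(10, p), a0=1.0) for p in phases
        ]
        fv = recording_features(beats, normalization="sum", min_beats=2)
        assert np.all(fv.p_sd_deg < 10.0)


class TestHrCv:
    def test_constant_rr_gives_zero(self):
        assert hr_cv(np.full(30, 0.8)) == 0.0

    def test_hand_arithmetic(self):
        assert hr_cv([0.8, 1.0]) == pytest.approx(0.15713, abs=1e-4)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        rr = rng.uniform(0.7, 1.1, 40)
        assert hr_cv(rr) == pytest.approx(hr_cv(3.7 * rr), abs=1e-12)

    def test_nonpositive_interval_rejected(self):
        with pytest.raises(ValidationError):
            hr_cv([0.8, 0.0, 0.9])

    def test_needs_two_intervals(self):
        with pytest.raises(ValidationError):
            hr_cv([0.8])


class TestInvariances:
    def test_amplitude_scale_invariance_end_to_end(self, clean_subject):
        from pulsespec.segmentation import Recording

        rec, _ = clean_subject
        fv1 = extract_features(rec)
        scaled = Recording(rec.samples * 4.2, rec.sampling_rate, rec.rr_intervals)
        fv2 = extract_features(scaled)
        np.testing.assert_allclose(fv1.c, fv2.c, rtol=1e-9)
        np.testing.assert_allclose(fv1.cv, fv2.cv, rtol=1e-6, atol=1e-12)
        np.testing.assert_allclose(fv1.p_deg, fv2.p_deg, atol=1e-9)
        assert fv1.hr_cv == pytest.approx(fv2.hr_cv)

    def test_time_stretch_leaves_c_and_p_unchanged(self):
        rng = np.random.default_rng(7)
        spec = _spectrum(rng.uniform(0.3, 2, 10), rng.uniform(-2, 2, 10), a0=6.0)
        feats = []
        for period in (0.7, 0.994):
            n = int(round(250 * period))
            samples = synthesize_beat(spec, n / 250.0, 250.0)
            beats = [beat_harmonics(_beat(samples, n / 250.0))] * 20
            feats.append(recording_features(beats, normalization="sum"))
        np.testing.assert_allclose(feats[0].c, feats[1].c, atol=1e-9)
        dp = (feats[0].p_deg - feats[1].p_deg + 180) % 360 - 180
        np.testing.assert_allclose(dp, 0.0, atol=1e-4)
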