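"""Feature extraction: temporal stats, spectra vs a direct-DFT oracle,
harmonic features, spectral PCA, and the 96-feature contract."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pulsedx as px
from pulsedx.features import (
    FFT_LENGTH,
    GroupPCA,
    Spectrum,
    _PHASE_LABEL,
    fit_group_pca,
    interpolate_gaps,
)
from conftest import make_phase_signal, naive_dft_magnitudes


class TestTemporalFeatures:
    def test_constant_series(self):
        sig = make_phase_signal(np.full(240, 95.0))
        assert px.temporal_features(sig) == (95.0, 0.0, 0.0)

    def test_population_sd_convention(self):
        sig = make_phase_signal([80.0, 90.0, 100.0])
        mean, sd, rng_ = px.temporal_features(sig)
        assert mean == 90.0
        assert sd == pytest.approx(8.164965809, abs=1e-8)
        assert rng_ == 20.0

    def test_masked_samples_excluded(self):
        mask = np.array([False, True, False, True, False])
        sig = make_phase_signal([80.0, 999.0, 90.0, -999.0, 100.0], mask=mask)
        assert px.temporal_features(sig)[0] == 90.0

    def test_fully_masked_rejected(self):
        sig = make_phase_signal(np.ones(10), mask=np.ones(10, bool))
        with pytest.raises(ValueError):
            px.temporal_features(sig)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_to_mask_position(self, seed):
        """Temporal features depend only on the unmasked sample multiset."""
        rng = np.random.default_rng(seed)
        values = rng.normal(90, 5, 60)
        keep = rng.permutation(60)[:40]
        mask_a = np.ones(60, bool)
        mask_a[keep] = False
        # same observed values packed at the front instead
        packed = np.concatenate([values[np.sort(keep)], np.zeros(20)])
        mask_b = np.zeros(60, bool)
        mask_b[40:] = True
        a = px.temporal_features(make_phase_signal(values, mask=mask_a))
        b = px.temporal_features(make_phase_signal(packed, mask=mask_b))
        assert a == pytest.approx(b, abs=1e-12)


class TestSpectrum:
    def test_matches_naive_dft_oracle_on_random_signals(self):
        """Relative agreement to 1e-9 with an O(N^2) direct DFT on 50 signals."""
        rng = np.random.default_rng(123)
        for i in range(50):
            phase = "walk" if i % 2 == 0 else "recovery"
            n = int(rng.integers(181, 361)) if phase == "walk" else 240
            x = 80 + rng.normal(0, 5, n)
            sig = make_phase_signal(x, phase=phase)
            spec = px.compute_spectrum(sig)
            freqs, mags = naive_dft_magnitudes(x, FFT_LENGTH[phase])
            np.testing.assert_allclose(spec.freqs, freqs, atol=1e-12)
            scale = np.abs(mags).max()
            np.testing.assert_allclose(spec.magnitudes, mags, atol=1e-9 * scale)

    def test_pure_sinusoid_peaks_at_its_frequency(self):
        t = np.arange(360.0)
        sig = make_phase_signal(10 * np.sin(2 * np.pi * 0.05 * t), phase="walk")
        spec = px.compute_spectrum(sig)
        peak_freq = spec.freqs[np.argmax(spec.magnitudes)]
        assert abs(peak_freq - 0.05) <= 1.0 / FFT_LENGTH["walk"]

    def test_two_tone_amplitude_ordering(self):
        t = np.arange(360.0)
        x = 10 * np.sin(2 * np.pi * 0.05 * t) + 4 * np.sin(2 * np.pi * 0.2 * t)
        spec = px.compute_spectrum(make_phase_signal(x, phase="walk"))
        # the global peak sits at the stronger tone; the 0.2 Hz tone dominates
        # its own neighborhood (rectangular-window leakage spreads each tone
        # over adjacent bins, so bin ranks near a tone are leakage-ordered)
        assert abs(spec.freqs[np.argmax(spec.magnitudes)] - 0.05) <= 1.0 / FFT_LENGTH["walk"]
        near_02 = np.abs(spec.freqs - 0.2) <= 0.02
        far = (np.abs(spec.freqs - 0.2) > 0.05) & (np.abs(spec.freqs - 0.05) > 0.05)
        assert spec.magnitudes[near_02].max() > spec.magnitudes[far].max()
        i_005 = np.argmin(np.abs(spec.freqs - 0.05))
        i_02 = np.argmin(np.abs(spec.freqs - 0.2))
        assert spec.magnitudes[i_005] > spec.magnitudes[i_02]

    def test_constant_signal_gives_null_spectrum(self):
        spec = px.compute_spectrum(make_phase_signal(np.full(240, 95.0)))
        np.testing.assert_allclose(spec.magnitudes, 0.0, atol=1e-9)

    def test_dc_bin_removed_and_grid_fixed(self):
        spec = px.compute_spectrum(make_phase_signal(np.random.default_rng(0).normal(size=240)))
        assert spec.freqs[0] == pytest.approx(1 / 256)
        assert spec.freqs[-1] == pytest.approx(0.5)
        assert len(spec.freqs) == 128
        assert np.all(np.diff(spec.freqs) > 0)

    def test_gap_interpolation_is_linear(self):
        mask = np.zeros(240, bool)
        mask[100:110] = True
        x = np.arange(240.0)
        filled = interpolate_gaps(make_phase_signal(x, mask=mask))
        np.testing.assert_allclose(filled, x, atol=1e-12)


class TestHarmonicFeatures:
    def test_single_tone(self):
        t = np.arange(360.0)
        spec = px.compute_spectrum(
            make_phase_signal(10 * np.sin(2 * np.pi * 0.05 * t), phase="walk")
        )
        h = px.harmonic_features(spec)
        assert abs(h.frec_first - 0.05) <= 1.0 / FFT_LENGTH["walk"]
        assert h.first_amp >= h.second_amp
        # the runner-up is the tone's own leakage sidelobe, adjacent in frequency
        assert abs(h.frec_second - h.frec_first) <= 2.0 / FFT_LENGTH["walk"]
        assert h.sum_all >= h.first_amp

    def test_symmetric_spectrum_has_zero_skew(self):
        freqs = np.linspace(0.1, 0.3, 21)
        mags = np.exp(-((freqs - 0.2) ** 2) / 0.001)
        h = px.harmonic_features(Spectrum(freqs, mags, ("HR", "walk")))
        assert h.skew == pytest.approx(0.0, abs=1e-10)

    def test_all_zero_spectrum_flagged(self):
        h = px.harmonic_features(Spectrum(np.linspace(0.01, 0.5, 50), np.zeros(50), ("Ox", "walk")))
        assert h.degenerate
        assert h.as_tuple() == (0, 0, 0, 0, 0, 0, 0)

    def test_tie_breaks_toward_lower_frequency(self):
        freqs = np.array([0.1, 0.2, 0.3, 0.4])
        mags = np.array([5.0, 1.0, 5.0, 1.0])
        h = px.harmonic_features(Spectrum(freqs, mags, ("HR", "walk")))
        assert h.frec_first == 0.1
        assert h.frec_second == 0.3

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_first_harmonic_always_at_least_second(self, seed):
        rng = np.random.default_rng(seed)
        sig = make_phase_signal(rng.normal(90, 4, 240))
        h = px.harmonic_features(px.compute_spectrum(sig))
        assert h.first_amp >= h.second_amp


def _random_spectra(n, n_bins=128, seed=0, phase="recovery"):
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(2 * n_bins, 1.0)[1:]
    return [
        Spectrum(freqs, np.abs(rng.normal(1, 0.3, n_bins)), ("HR", phase))
        for _ in range(n)
    ]


class TestSpectralPCA:
    def test_identical_spectra_have_zero_variance_and_projections(self):
        base = _random_spectra(1, seed=3)[0]
        spectra = [Spectrum(base.freqs, base.magnitudes.copy(), base.source) for _ in range(10)]
        model = fit_group_pca(spectra)
        np.testing.assert_allclose(model.explained_variance_ratio, 0.0, atol=1e-12)
        np.testing.assert_allclose(model.project(base.normalized), 0.0, atol=1e-10)

    def test_rank_one_ensemble_concentrates_on_pc1(self):
        rng = np.random.default_rng(1)
        freqs = np.fft.rfftfreq(256, 1.0)[1:]
        direction = np.abs(rng.normal(0, 1, 128))
        base = np.abs(rng.normal(1, 0.1, 128))
        spectra = [
            Spectrum(freqs, base + rng.normal() * 0.05 * direction, ("Ox", "recovery"))
            for _ in range(20)
        ]
        model = fit_group_pca(spectra)
        assert model.explained_variance_ratio[0] > 0.999
        assert model.explained_variance_ratio[1:].sum() < 1e-3

    def test_components_orthonormal(self):
        model = fit_group_pca(_random_spectra(30, seed=5))
        gram = model.components @ model.components.T
        np.testing.assert_allclose(gram, np.eye(6), atol=1e-8)

    def test_sign_convention_deterministic(self):
        model = fit_group_pca(_random_spectra(30, seed=5))
        for row in model.components:
            assert row[np.argmax(np.abs(row))] > 0

    def test_too_few_spectra_rejected(self):
        with pytest.raises(ValueError):
            fit_group_pca(_random_spectra(6))

    def test_projection_of_corpus_mean_is_zero(self):
        spectra = _random_spectra(25, seed=9)
        model = fit_group_pca(spectra)
        mean_norm = np.mean([s.normalized for s in spectra], axis=0)
        np.testing.assert_allclose(model.project(mean_norm), 0.0, atol=1e-10)


@pytest.fixture(scope="module")
def extracted(small_cohort):
    filtered, _ = px.apply_filters(small_cohort)
    evaluations = [ev for p in filtered for ev in p.evaluations]
    extractor = px.FeatureExtractor(evaluations)
    pca = extractor.fit_pca([ev.eval_id for ev in evaluations])
    return evaluations, extractor, pca


class TestExtractFeatures:
    def test_exactly_96_features_16_per_group(self, extracted):
        evaluations, extractor, pca = extracted
        feats = extractor.features(evaluations[0].eval_id, pca)
        assert len(feats) == 96
        assert list(feats) == px.FEATURE_NAMES
        stats = (
            "mean", "std", "range", "frecFirstArm", "firstArm", "frecSecArm",
            "seconArm", "skewArm", "kurtArm", "sumAllArm",
        )
        for kind in ("HR", "Ox", "HRminusOx"):
            for label in ("Walk", "Recovery"):
                expected = [f"{s}{kind}{label}" for s in stats] + [
                    f"PC{k}-{kind}-{label}" for k in range(1, 7)
                ]
                assert len(expected) == 16
                assert all(name in feats for name in expected), (kind, label)

    def test_identical_evaluations_identical_features(self, extracted):
        evaluations, extractor, pca = extracted
        ev = evaluations[0]
        a = px.extract_features(ev, pca)
        b = px.extract_features(ev, pca)
        assert a == b

    def test_cached_extractor_matches_direct_path(self, extracted):
        evaluations, extractor, pca = extracted
        ev = evaluations[3]
        direct = px.extract_features(ev, pca)
        cached = extractor.features(ev.eval_id, pca)
        assert direct == pytest.approx(cached, abs=1e-12)
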