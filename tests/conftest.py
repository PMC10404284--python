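"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import pulsedx as px


def naive_dft_magnitudes(x: np.ndarray, nfft: int) -> tuple[np.ndarray, np.ndarray]:
    """O(N^2) direct DFT oracle: magnitudes at bins k=1..nfft/2 of the
    zero-padded, mean-removed series.  Independent of numpy.fft."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    padded = np.zeros(nfft)
    padded[: x.size] = x
    ks = np.arange(1, nfft // 2 + 1)
    mags = np.empty(ks.size)
    n_idx = np.arange(nfft)
    for j, k in enumerate(ks):
        re = float(np.sum(padded * np.cos(-2 * np.pi * k * n_idx / nfft)))
        im = float(np.sum(padded * np.sin(-2 * np.pi * k * n_idx / nfft)))
        mags[j] = np.hypot(re, im)
    return ks / nfft, mags


def make_phase_signal(values, kind="HR", phase="recovery", mask=None) -> px.PhaseSignal:
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.zeros(values.size, dtype=bool)
    return px.PhaseSignal(kind, phase, values, np.asarray(mask, dtype=bool))


@pytest.fixture
def noiseless_config() -> px.SimulationConfig:
    """Planted effects with every stochastic nuisance disabled, so the shifts
    can be read back exactly from the generated series."""
    return px.SimulationConfig(
        n_patients=8,
        seed=5,
        decomp_hr_shift=6.0,
        decomp_spo2_drop=1.5,
        noise_sd_hr=0.0,
        noise_sd_spo2=0.0,
        hr_day_sd=0.0,
        spo2_day_sd=0.0,
        walk_duration_sd=0.0,
        dropout_loss_rate_range=(0.0, 0.0),
        p_missing_home_visit=0.0,
    )


@pytest.fixture(scope="session")
def small_cohort() -> list[px.PatientRecord]:
    """A 12-patient default-parameter cohort shared by read-only tests."""
    return px.generate_cohort(px.SimulationConfig(n_patients=12, seed=2))


@pytest.fixture(scope="session")
def small_units_frame(small_cohort):
    """Filtered units table of the shared cohort, with all-data PCA."""
    filtered, _ = px.apply_filters(small_cohort)
    evaluations = [ev for p in filtered for ev in p.evaluations]
    extractor = px.FeatureExtractor(evaluations)
    pca = extractor.fit_pca([ev.eval_id for ev in evaluations])
    units = []
    for patient in filtered:
        feats = {
            ev.visit: extractor.features(ev.eval_id, pca) for ev in patient.evaluations
        }
        if len(feats) >= 2:
            units.extend(px.build_units(patient, feats))
    return px.units_to_frame(units)
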