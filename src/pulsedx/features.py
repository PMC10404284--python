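"""Feature extraction: 96 characteristics per evaluation.

For each of the 3 signals (HR, Ox, HRminusOx) and 2 phases (walk, recovery),
16 characteristics are computed:

* temporal (3): mean, standard deviation (population convention), range;
* harmonic / spectral-moment (7): frequency and amplitude of the two largest
  magnitude bins of the FFT ("first/second harmonic"), magnitude-weighted
  skewness and excess kurtosis of the frequency distribution, and the sum of
  all magnitudes;
* spectral PCA (6): projections of the unit-sum-normalized magnitude spectrum
  onto the first six principal components fitted across the corpus.

Spectra share a fixed frequency grid per phase — zero-padded 512-point FFT
for the walk (<= 360 samples) and 256-point for the recovery (240 samples) —
so that evaluations of unequal duration are comparable and PCA is
well-defined.  Harmonic amplitudes and the magnitude sum use the raw spectrum;
spectral moments and PCA use the unit-sum-normalized spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .preprocessing import evaluation_phase_signals
from .records import PHASES, SIGNAL_KINDS, EvaluationRecord, PhaseSignal

#: FFT lengths per phase (next power of two >= nominal phase length).
FFT_LENGTH = {"walk": 512, "recovery": 256}
N_PCA_COMPONENTS = 6

_PHASE_LABEL = {"walk": "Walk", "recovery": "Recovery"}

_TEMPORAL_STATS = ("mean", "std", "range")
_HARMONIC_STATS = (
    "frecFirstArm",
    "firstArm",
    "frecSecArm",
    "seconArm",
    "skewArm",
    "kurtArm",
    "sumAllArm",
)


def feature_names() -> list[str]:
    """The 96 canonical feature names, grouped by (signal, phase)."""
    names = []
    for kind in SIGNAL_KINDS:
        for phase in PHASES:
            label = _PHASE_LABEL[phase]
            for stat in _TEMPORAL_STATS:
                names.append(f"{stat}{kind}{label}")
            for stat in _HARMONIC_STATS:
                names.append(f"{stat}{kind}{label}")
            for k in range(1, N_PCA_COMPONENTS + 1):
                names.append(f"PC{k}-{kind}-{label}")
    return names


FEATURE_NAMES = feature_names()


def temporal_features(signal: PhaseSignal) -> tuple[float, float, float]:
    """(mean, population standard deviation, max - min) over observed samples."""
    x = signal.unmasked
    if x.size < 2:
        raise ValueError("temporal features need at least 2 unmasked samples")
    return float(x.mean()), float(x.std(ddof=0)), float(x.max() - x.min())


@dataclass
class Spectrum:
    """Magnitude spectrum on the fixed per-phase grid, DC bin removed."""

    freqs: np.ndarray
    magnitudes: np.ndarray
    source: tuple[str, str]  # (signal kind, phase)

    @property
    def normalized(self) -> np.ndarray:
        s = self.magnitudes.sum()
        return self.magnitudes / s if s > 0 else self.magnitudes


def interpolate_gaps(signal: PhaseSignal) -> np.ndarray:
    """Linearly interpolate masked runs (edge gaps held at the nearest value).

    Used only on the way into the FFT, where a contiguous series is required;
    the <= 10% loss-rate filter bounds the distortion.
    """
    x = signal.samples.astype(float)
    mask = signal.missing_mask
    if not mask.any():
        return x.copy()
    idx = np.arange(x.size)
    good = ~mask
    if not good.any():
        raise ValueError("cannot interpolate a fully masked signal")
    return np.interp(idx, idx[good], x[good])


def compute_spectrum(signal: PhaseSignal) -> Spectrum:
    """Magnitude of the real-input FFT after gap interpolation and mean removal.

    The series is zero-padded to the phase's fixed FFT length; the DC bin is
    dropped, leaving bins at k/N Hz for k = 1..N/2 (up to the 0.5 Hz Nyquist
    limit of 1 Hz sampling).
    """
    if len(signal) == 0:
        raise ValueError("cannot compute the spectrum of an empty signal")
    nfft = FFT_LENGTH[signal.phase]
    if len(signal) > nfft:
        raise ValueError(f"{signal.phase} signal longer than FFT length {nfft}")
    x = interpolate_gaps(signal)
    x = x - x.mean()
    mag = np.abs(np.fft.rfft(x, nfft))
    freqs = np.fft.rfftfreq(nfft, d=1.0)
    return Spectrum(freqs[1:], mag[1:], (signal.kind, signal.phase))


@dataclass
class HarmonicFeatures:
    frec_first: float
    first_amp: float
    frec_second: float
    second_amp: float
    skew: float
    kurt: float
    sum_all: float
    degenerate: bool = False

    def as_tuple(self) -> tuple[float, ...]:
        return (
            self.frec_first,
            self.first_amp,
            self.frec_second,
            self.second_amp,
            self.skew,
            self.kurt,
            self.sum_all,
        )


def harmonic_features(spectrum: Spectrum) -> HarmonicFeatures:
    """The two largest harmonics, weighted spectral moments, and magnitude sum.

    Ties between equal-magnitude bins break toward the lower frequency.
    Skewness and kurtosis are the magnitude-weighted moments of frequency
    (weights normalized to unit sum); kurtosis is excess kurtosis.  An
    all-zero spectrum yields all-zero features with a degeneracy flag.
    """
    mag = spectrum.magnitudes
    f = spectrum.freqs
    if mag.max(initial=0.0) <= 0.0:
        return HarmonicFeatures(0, 0, 0, 0, 0, 0, 0, degenerate=True)
    i1 = int(np.argmax(mag))  # argmax takes the first (lowest-frequency) max
    rest = mag.copy()
    rest[i1] = -np.inf
    i2 = int(np.argmax(rest))
    w = mag / mag.sum()
    mu = float((w * f).sum())
    var = float((w * (f - mu) ** 2).sum())
    if var <= 1e-24:
        skew = kurt = 0.0
    else:
        sd = np.sqrt(var)
        skew = float((w * ((f - mu) / sd) ** 3).sum())
        kurt = float((w * ((f - mu) / sd) ** 4).sum() - 3.0)
    return HarmonicFeatures(
        frec_first=float(f[i1]),
        first_amp=float(mag[i1]),
        frec_second=float(f[i2]),
        second_amp=float(mag[i2]),
        skew=skew,
        kurt=kurt,
        sum_all=float(mag.sum()),
    )


@dataclass
class GroupPCA:
    """Fitted PCA of one (signal, phase) group of normalized spectra."""

    mean: np.ndarray
    components: np.ndarray  # (n_components, n_bins), orthonormal rows
    explained_variance_ratio: np.ndarray

    def project(self, normalized_spectrum: np.ndarray) -> np.ndarray:
        return (normalized_spectrum - self.mean) @ self.components.T


@dataclass
class SpectralPCAModel:
    """Per-(signal, phase) spectral PCA bases; six components each."""

    groups: dict[tuple[str, str], GroupPCA] = field(default_factory=dict)

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def fit_group_pca(spectra: list[Spectrum], n_components: int = N_PCA_COMPONENTS) -> GroupPCA:
    """Fit PCA on unit-sum-normalized spectra of one (signal, phase) group.

    Components are ordered by decreasing explained variance with a
    deterministic sign convention: the loading of largest magnitude is
    positive.  Requires more spectra than components.
    """
    if len(spectra) <= n_components:
        raise ValueError(
            f"need more than {n_components} spectra, got {len(spectra)}"
        )
    X = np.stack([s.normalized for s in spectra])
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    comps = pca.components_.copy()
    for row in comps:
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            row *= -1.0
    # a zero-variance ensemble explains nothing (sklearn reports 0/0 as 1)
    total_var = float(X.var(axis=0).sum())
    ratio = (
        np.zeros(n_components)
        if total_var <= 1e-30
        else pca.explained_variance_ratio_.copy()
    )
    return GroupPCA(
        mean=pca.mean_.copy(),
        components=comps,
        explained_variance_ratio=ratio,
    )


def fit_spectral_pca(
    spectra_by_group: dict[tuple[str, str], list[Spectrum]],
    n_components: int = N_PCA_COMPONENTS,
) -> SpectralPCAModel:
    return SpectralPCAModel(
        groups={
            key: fit_group_pca(spectra, n_components)
            for key, spectra in spectra_by_group.items()
        }
    )


# ---------------------------------------------------------------------------
# Per-evaluation extraction, with caching for leave-one-patient-out refits
# ---------------------------------------------------------------------------

def extract_features(
    evaluation: EvaluationRecord, pca: SpectralPCAModel
) -> dict[str, float]:
    """The 96 named characteristics of one evaluation."""
    base, spectra = _base_features_and_spectra(evaluation)
    return _assemble(base, spectra, pca)


def _base_features_and_spectra(
    evaluation: EvaluationRecord,
) -> tuple[dict[str, float], dict[tuple[str, str], Spectrum]]:
    signals = evaluation_phase_signals(evaluation)
    base: dict[str, float] = {}
    spectra: dict[tuple[str, str], Spectrum] = {}
    for (kind, phase), sig in signals.items():
        label = _PHASE_LABEL[phase]
        mean, std, rng_ = temporal_features(sig)
        base[f"mean{kind}{label}"] = mean
        base[f"std{kind}{label}"] = std
        base[f"range{kind}{label}"] = rng_
        spec = compute_spectrum(sig)
        spectra[(kind, phase)] = spec
        harm = harmonic_features(spec)
        for stat, value in zip(_HARMONIC_STATS, harm.as_tuple()):
            base[f"{stat}{kind}{label}"] = value
    return base, spectra


def _assemble(
    base: dict[str, float],
    spectra: dict[tuple[str, str], Spectrum],
    pca: SpectralPCAModel,
) -> dict[str, float]:
    out = dict(base)
    for (kind, phase), spec in spectra.items():
        label = _PHASE_LABEL[phase]
        proj = pca.groups[(kind, phase)].project(spec.normalized)
        for k in range(N_PCA_COMPONENTS):
            out[f"PC{k + 1}-{kind}-{label}"] = float(proj[k])
    return {name: out[name] for name in FEATURE_NAMES}


class FeatureExtractor:
    """Caches per-evaluation spectra and non-PCA features across a cohort.

    Leave-one-patient-out validation refits the spectral PCA once per fold;
    only the six projections per group depend on the basis, so everything else
    is computed once here.
    """

    def __init__(self, evaluations: list[EvaluationRecord]):
        self.evaluations = {ev.eval_id: ev for ev in evaluations}
        self._base: dict[str, dict[str, float]] = {}
        self._spectra: dict[str, dict[tuple[str, str], Spectrum]] = {}
        for ev in evaluations:
            base, spectra = _base_features_and_spectra(ev)
            self._base[ev.eval_id] = base
            self._spectra[ev.eval_id] = spectra

    def fit_pca(self, eval_ids: list[str]) -> SpectralPCAModel:
        grouped: dict[tuple[str, str], list[Spectrum]] = {}
        for eid in eval_ids:
            for key, spec in self._spectra[eid].items():
                grouped.setdefault(key, []).append(spec)
        return fit_spectral_pca(grouped)

    def features(self, eval_id: str, pca: SpectralPCAModel) -> dict[str, float]:
        return _assemble(self._base[eval_id], self._spectra[eval_id], pca)
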