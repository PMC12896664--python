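"""FFT- and CWT-based energy features with the 90%-cumulative-energy rule.

Per sample, squared transform magnitudes are sorted descending and the
smallest prefix reaching ``energy_fraction`` (default 90%) of the total is the
sample's candidate feature count; the minimum count across samples becomes the
uniform feature dimension, and each sample contributes its top energies.

The continuous wavelet transform is computed in the frequency domain over
logarithmic scales (10 voices per octave) with three analytic wavelets:
generalized Morse (gamma = 3, beta = 20), the analytic Morlet ("Amor",
center frequency 6 rad/sample) and the Bump wavelet (mu = 5, sigma = 0.6).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .dataset import SpectraSet, ValidationError

WAVELETS = ("morse", "amor", "bump")


# ---------------------------------------------------------------------------
# FFT features

def _fft_energies(X: np.ndarray) -> np.ndarray:
    """One-sided squared DFT magnitudes per row, zero-frequency term excluded."""
    F = np.fft.rfft(X, axis=1)
    return np.abs(F[:, 1:]) ** 2


def _count_for_fraction(sorted_desc: np.ndarray, fraction: float) -> int:
    total = sorted_desc.sum()
    if total <= 0:
        return 1
    cum = np.cumsum(sorted_desc)
    return int(min(np.searchsorted(cum, fraction * total) + 1, sorted_desc.size))


class FFTEnergyFeaturizer(BaseEstimator, TransformerMixin):
    """Top spectral energies per sample at a common (minimum) feature count."""

    def __init__(self, energy_fraction: float = 0.90):
        self.energy_fraction = energy_fraction

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] < 8:
            raise ValidationError("need at least 8 bands for FFT features")
        E = np.sort(_fft_energies(X), axis=1)[:, ::-1]
        counts = [_count_for_fraction(row, self.energy_fraction) for row in E]
        self.per_sample_counts_ = np.array(counts)
        self.n_features_ = int(min(counts))
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        E = np.sort(_fft_energies(X), axis=1)[:, ::-1]
        return E[:, :self.n_features_]

    def get_feature_names_out(self, input_features=None):
        return np.array([f"FFT_{k + 1}" for k in range(self.n_features_)])


def fft_energy_features(spectra: SpectraSet, energy_fraction: float = 0.90):
    """Featurize a whole SpectraSet; returns (features, n_fft)."""
    f = FFTEnergyFeaturizer(energy_fraction=energy_fraction).fit(spectra.reflectance)
    return f.transform(spectra.reflectance), f.n_features_


# ---------------------------------------------------------------------------
# CWT features

def _wavelet_hat(name: str, omega: np.ndarray) -> np.ndarray:
    """Frequency response psi_hat(omega) of an analytic wavelet (omega >= 0).

    All three are real, non-negative and vanish at omega = 0 (zero mean), with
    peak value 2 following the common analytic-wavelet normalization.
    """
    w = np.asarray(omega, dtype=float)
    out = np.zeros_like(w)
    pos = w > 0
    if name == "morse":
        gamma, beta = 3.0, 20.0
        wp = (beta / gamma) ** (1.0 / gamma)
        x = w[pos] / wp
        # log-space to avoid overflow at large beta
        out[pos] = np.exp(np.log(2.0) + beta * np.log(x) + (beta / gamma) * (1.0 - x ** gamma))
    elif name == "amor":
        out[pos] = 2.0 * np.exp(-0.5 * (w[pos] - 6.0) ** 2)
    elif name == "bump":
        mu, sigma = 5.0, 0.6
        u = (w - mu) / sigma
        inside = pos & (np.abs(u) < 1.0)
        with np.errstate(divide="ignore"):
            out[inside] = 2.0 * np.exp(1.0 - 1.0 / (1.0 - u[inside] ** 2))
    else:
        raise ValidationError(f"unsupported wavelet {name!r}; expected one of {WAVELETS}")
    return out


def _peak_frequency(name: str) -> float:
    return {"morse": (20.0 / 3.0) ** (1.0 / 3.0), "amor": 6.0, "bump": 5.0}[name]


def default_scales(n: int, wavelet: str, voices_per_octave: int = 10) -> np.ndarray:
    """Logarithmic scales from the Nyquist band down over the representable octaves."""
    wp = _peak_frequency(wavelet)
    s0 = wp / np.pi
    octaves = max(1, int(np.floor(np.log2(n / 4))))
    j = np.arange(octaves * voices_per_octave + 1)
    return s0 * 2.0 ** (j / voices_per_octave)


def cwt_coefficients(row, wavelet: str, scales: Optional[np.ndarray] = None) -> np.ndarray:
    """Analytic CWT of one row: coefficient matrix of shape (n_scales, n)."""
    x = np.asarray(row, dtype=float)
    n = x.size
    if wavelet not in WAVELETS:
        raise ValidationError(f"unsupported wavelet {wavelet!r}; expected one of {WAVELETS}")
    if scales is None:
        scales = default_scales(n, wavelet)
    k = np.arange(n)
    omega = 2.0 * np.pi * k / n
    omega = np.where(k <= n // 2, omega, 0.0)  # analytic: negative freqs killed
    xhat = np.fft.fft(x)
    psi = np.stack([_wavelet_hat(wavelet, s * omega) for s in scales])
    return np.fft.ifft(xhat[None, :] * psi, axis=1)


class CWTEnergyFeaturizer(BaseEstimator, TransformerMixin):
    """Top |CWT coefficient|^2 values per sample at a common minimum count."""

    def __init__(self, wavelet: str = "morse", energy_fraction: float = 0.90,
                 voices_per_octave: int = 10):
        self.wavelet = wavelet
        self.energy_fraction = energy_fraction
        self.voices_per_octave = voices_per_octave

    def _energies(self, X: np.ndarray) -> np.ndarray:
        scales = default_scales(X.shape[1], self.wavelet, self.voices_per_octave)
        rows = []
        for row in X:
            W = cwt_coefficients(row, self.wavelet, scales)
            rows.append(np.sort((np.abs(W) ** 2).ravel())[::-1])
        return np.stack(rows)

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        E = self._energies(X)
        counts = [_count_for_fraction(row, self.energy_fraction) for row in E]
        self.per_sample_counts_ = np.array(counts)
        self.n_features_ = int(min(counts))
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self._energies(X)[:, :self.n_features_]

    def get_feature_names_out(self, input_features=None):
        return np.array([f"CWT_{self.wavelet}_{k + 1}" for k in range(self.n_features_)])


def cwt_energy_features(spectra: SpectraSet, wavelet: str = "morse",
                        energy_fraction: float = 0.90):
    """Featurize a whole SpectraSet; returns (features, n_cwt)."""
    f = CWTEnergyFeaturizer(wavelet=wavelet, energy_fraction=energy_fraction)
    f.fit(spectra.reflectance)
    return f.transform(spectra.reflectance), f.n_features_
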