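"""Synthetic diffuse-reflectance NIR benchmark generator with known ground truth.

The generator emulates powdered-sample NIR measurements: a few pure components
with smooth, overlapping Gaussian absorption bands, correlated log-normal
concentrations, a Beer-Lambert-like mixture mapped to reflectance through
exp(-absorbance) (keeping values positive so ratio indices stay well-behaved),
per-sample multiplicative scatter and additive polynomial baseline
distortions, white measurement noise, and four quality indicators that are
affine in the component concentrations.  Everything is seeded and the ground
truth (pure spectra, concentrations, affine maps, planted bands, injected
outliers) is returned alongside the data, so every stage of the calibration
pipeline can be tested end to end without any external dataset.

Two ready-made profiles: ``easy`` (n = 171, 200 bands, 5 informative
single-band perturbations at high signal-to-noise — for wavelength-selection
recovery studies) and ``hard`` (heavy scatter and baseline drift — for
preprocessing ablations).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import (INDICATORS, AlignedDataset, IndicatorTable, SpectraSet,
                      ValidationError, save_indicators, save_spectra)

# typical mass-fraction % levels of the four tea quality indicators
_INDICATOR_LEVELS = {"theanine": 2.0, "tea_polyphenols": 18.0,
                     "soluble_sugar": 5.0, "water_extract": 38.0}


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset; defaults mirror the study scale."""

    n_samples: int = 171
    wavenumber_min: float = 4000.0
    wavenumber_max: float = 10000.0
    n_bands: int = 1500
    n_components: int = 4
    peaks_per_component: int = 4
    peak_width_range: tuple = (120.0, 450.0)
    absorbance_scale: float = 0.6
    background_amplitude: float = 1.0  # shared absorbance shape, all samples
    concentration_corr: float = 0.3
    concentration_cv: float = 0.25
    scatter_slope_sd: float = 0.0
    scatter_offset_sd: float = 0.0
    baseline_amplitude: float = 0.0
    noise_sd: float = 0.0
    indicator_noise_frac: float = 0.0
    outlier_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_samples, self.n_bands, self.n_components,
               self.peaks_per_component) < 1:
            raise ValidationError("all counts must be positive")
        if not self.wavenumber_min < self.wavenumber_max:
            raise ValidationError("wavenumber range is empty")


def generate_dataset(spec: SyntheticSpec):
    """Draw one dataset; returns (SpectraSet, IndicatorTable, ground_truth dict)."""
    rng = np.random.default_rng(spec.seed)
    wn = np.linspace(spec.wavenumber_min, spec.wavenumber_max, spec.n_bands)
    nc = spec.n_components

    # pure-component absorption spectra: sums of Gaussian bands
    S = np.zeros((nc, spec.n_bands))
    peaks = []
    for c in range(nc):
        centers = rng.uniform(spec.wavenumber_min, spec.wavenumber_max,
                              spec.peaks_per_component)
        widths = rng.uniform(*spec.peak_width_range, spec.peaks_per_component)
        amps = rng.uniform(0.4, 1.0, spec.peaks_per_component)
        for mu, w, a in zip(centers, widths, amps):
            S[c] += a * np.exp(-0.5 * ((wn - mu) / w) ** 2)
        peaks.append({"centers": centers.tolist(), "widths": widths.tolist(),
                      "amplitudes": amps.tolist()})

    # correlated log-normal concentrations, one latent per indicator
    corr = np.full((nc, nc), spec.concentration_corr)
    np.fill_diagonal(corr, 1.0)
    L = np.linalg.cholesky(corr)
    z = rng.standard_normal((spec.n_samples, nc)) @ L.T
    sigma = np.sqrt(np.log(1.0 + spec.concentration_cv ** 2))
    C = np.exp(sigma * z - sigma ** 2 / 2.0)  # mean 1 per component

    # shared absorbance background: the dominant common NIR shape that makes
    # sample spectra a tightly correlated family, as in real powder spectra
    bg = np.zeros(spec.n_bands)
    for _ in range(3):
        mu = rng.uniform(spec.wavenumber_min, spec.wavenumber_max)
        wdt = rng.uniform(600.0, 1500.0)
        bg += rng.uniform(0.3, 0.6) * np.exp(-0.5 * ((wn - mu) / wdt) ** 2)
    A = spec.background_amplitude * bg[None, :] + spec.absorbance_scale * (C @ S) / nc
    R = np.exp(-A)

    # log-normal multiplicative scatter keeps slopes positive (physical)
    slope = np.exp(spec.scatter_slope_sd * rng.standard_normal(spec.n_samples))
    offset = spec.scatter_offset_sd * rng.standard_normal(spec.n_samples)
    u = (wn - wn.mean()) / (wn.max() - wn.min())
    base_coef = spec.baseline_amplitude * rng.standard_normal((spec.n_samples, 3))
    baseline = base_coef @ np.vstack([np.ones_like(u), u, u ** 2])
    X = slope[:, None] * R + offset[:, None] + baseline
    X = X + spec.noise_sd * rng.standard_normal(X.shape)

    ids = [f"S{i:03d}" for i in range(spec.n_samples)]
    spectra = SpectraSet(wn, X, ids)

    names = list(INDICATORS)[:nc] + [f"indicator_{k}" for k in range(4, nc)]
    alpha = np.array([_INDICATOR_LEVELS.get(n, 5.0) * 0.5 for n in names])
    beta = np.array([_INDICATOR_LEVELS.get(n, 5.0) * 0.5 for n in names])
    Y = alpha[None, :] + C[:, :len(names)] * beta[None, :]
    if spec.indicator_noise_frac > 0:
        Y = Y + (spec.indicator_noise_frac * Y.std(axis=0, keepdims=True)
                 * rng.standard_normal(Y.shape))
    table = IndicatorTable(ids, pd.DataFrame(Y, columns=names))

    truth = {"spec": spec, "pure_spectra": S, "concentrations": C,
             "peaks": peaks, "alpha": alpha, "beta": beta,
             "scatter": {"slope": slope, "offset": offset, "baseline": baseline}}
    if spec.outlier_rate > 0:
        table, injected = inject_outliers(table, spec.outlier_rate, 4.0,
                                          seed=int(rng.integers(2 ** 31 - 1)))
        truth["injected_outliers"] = injected
    return spectra, table, truth


def inject_outliers(indicators: IndicatorTable, rate: float, magnitude: float,
                    seed: int = 0):
    """Shift selected samples' indicator values beyond the box-plot whiskers.

    Each injected value lands ``magnitude * IQR`` past the Tukey fence
    (randomly above or below), computed from the pre-injection distribution of
    its column.  Returns (new table, list of injected sample ids).
    """
    if not 0 <= rate <= 0.2:
        raise ValidationError("outlier rate must be in [0, 0.2]")
    rng = np.random.default_rng(seed)
    vals = indicators.values.copy()
    n = len(indicators.sample_ids)
    k = int(round(rate * n))
    if k == 0:
        return IndicatorTable(list(indicators.sample_ids), vals), []
    idx = np.sort(rng.choice(n, size=k, replace=False))
    injected = [indicators.sample_ids[i] for i in idx]
    for col in vals.columns:
        v = vals[col].to_numpy(dtype=float)
        q1, q3 = np.nanquantile(v, [0.25, 0.75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        sign = rng.choice([-1.0, 1.0], size=k)
        v[idx] = np.where(sign > 0, hi + magnitude * iqr, lo - magnitude * iqr)
        vals[col] = v
    return IndicatorTable(list(indicators.sample_ids), vals), injected


# ---------------------------------------------------------------------------
# Benchmark profiles

@dataclass
class BenchmarkBundle:
    spectra: SpectraSet
    indicators: IndicatorTable
    truth: dict = field(repr=False, default_factory=dict)


def _easy_bundle(seed: int) -> BenchmarkBundle:
    """High-SNR benchmark: 5 informative of 200 bands, n = 171.

    A smooth correlated background family carries no target signal; five
    single-band reflectance perturbations are driven by latent factors, and
    every indicator is affine in those latents plus small measurement noise —
    so the informative wavelengths are known exactly.
    """
    rng = np.random.default_rng(seed)
    n, nb, n_informative = 171, 200, 5
    wn = np.linspace(4000.0, 10000.0, nb)
    u = (wn - wn.mean()) / (wn.max() - wn.min())
    # smooth background: mean NIR-like curve + low-order random modes
    mean_curve = 0.6 + 0.15 * np.exp(-0.5 * ((wn - 5200) / 700) ** 2) \
        + 0.1 * np.exp(-0.5 * ((wn - 8400) / 900) ** 2)
    modes = np.vstack([u, u ** 2, np.sin(np.pi * u)])
    X = mean_curve[None, :] + 0.01 * rng.standard_normal((n, 3)) @ modes
    planted = np.sort(rng.choice(nb, size=n_informative, replace=False))
    Z = rng.standard_normal((n, n_informative))
    X[:, planted] += 0.05 * Z
    X += 0.0005 * rng.standard_normal(X.shape)

    ids = [f"S{i:03d}" for i in range(n)]
    names = list(INDICATORS)
    W = rng.uniform(0.5, 1.5, (n_informative, 4)) * rng.choice([-1, 1], (n_informative, 4))
    levels = np.array([_INDICATOR_LEVELS[k] for k in names])
    Y = levels[None, :] * (1.0 + 0.1 * (Z @ W))
    Y += 0.03 * Y.std(axis=0, keepdims=True) * rng.standard_normal(Y.shape)
    truth = {"planted_bands": planted.tolist(),
             "planted_wavenumbers": wn[planted].tolist(),
             "latents": Z, "weights": W}
    return BenchmarkBundle(SpectraSet(wn, X, ids),
                           IndicatorTable(ids, pd.DataFrame(Y, columns=names)),
                           truth)


def _hard_bundle(seed: int) -> BenchmarkBundle:
    """Heavy multiplicative scatter + polynomial baseline; preprocessing matters."""
    spec = SyntheticSpec(n_samples=171, n_bands=300, scatter_slope_sd=0.7,
                         scatter_offset_sd=0.3, baseline_amplitude=0.45,
                         noise_sd=0.003, indicator_noise_frac=0.05, seed=seed)
    spectra, indicators, truth = generate_dataset(spec)
    return BenchmarkBundle(spectra, indicators, truth)


def make_benchmark(profile: str = "easy", seed: int = 0, out=None) -> BenchmarkBundle:
    """Build a named benchmark; optionally write spectra/indicators/truth to disk."""
    if profile == "easy":
        bundle = _easy_bundle(seed)
    elif profile == "hard":
        bundle = _hard_bundle(seed)
    else:
        raise ValidationError(f"unknown profile {profile!r}; expected 'easy' or 'hard'")
    if out is not None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        save_spectra(bundle.spectra, out / "spectra.csv")
        save_indicators(bundle.indicators, out / "indicators.csv")
        truth = {k: v for k, v in bundle.truth.items()
                 if k in ("planted_bands", "planted_wavenumbers", "peaks",
                          "injected_outliers")}
        (out / "truth.json").write_text(json.dumps(truth, indent=2))
    return bundle
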