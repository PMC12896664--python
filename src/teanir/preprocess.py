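"""Spectral pretreatments and the 18-variant preprocessing grid.

Five per-spectrum corrections — standard normal variate (SNV), moving average
(MA), Savitzky-Golay smoothing (SG), multiplicative scatter correction (MSC)
and polynomial detrending (DT) — optionally followed by a Savitzky-Golay first
(FD) or second (SD) derivative with respect to wavenumber.  The cross product
{RAW, SNV, MA, SG, MSC, DT} x {RAW, FD, SD} gives the 18 variants swept by the
calibration pipeline; the label grammar is ``"<base>-<RAW|FD|SD>"`` where the
``RAW`` suffix means "no derivative" (so ``"RAW-RAW"`` is the identity).

All transformers are stateless scikit-learn transformers operating on plain
2-D arrays (rows = spectra); module-level helpers lift them to
:class:`~teanir.dataset.SpectraSet`.  MSC is the one exception: its reference
spectrum is learned in ``fit`` (the column-wise mean of the training spectra).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, Optional

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .dataset import SpectraSet, ValidationError

BASES = ("RAW", "SNV", "MA", "SG", "MSC", "DT")
DERIVATIVES = ("RAW", "FD", "SD")  # suffix "RAW" = no derivative


def _as2d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return np.atleast_2d(X)


class SNV(BaseEstimator, TransformerMixin):
    """Standard normal variate: center and scale each spectrum to mean 0, sd 1.

    Removes per-sample multiplicative intensity variation and additive offsets
    (scatter from particle size / optical path differences).
    """

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = _as2d(X)
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=1, keepdims=True)
        zero = np.where(sd[:, 0] == 0)[0]
        if zero.size:
            raise ValidationError(f"SNV: zero-variance spectrum at row(s) {zero.tolist()}")
        return (X - mu) / sd


class MSC(BaseEstimator, TransformerMixin):
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum x is regressed x ~ a + b*ref by ordinary least squares and
    corrected to (x - a)/b.  The reference defaults to the column-wise mean of
    the spectra seen in ``fit``.
    """

    def __init__(self, reference: Optional[np.ndarray] = None, min_slope: float = 1e-12):
        self.reference = reference
        self.min_slope = min_slope

    def fit(self, X, y=None):
        X = _as2d(X)
        if self.reference is not None:
            self.reference_ = np.asarray(self.reference, dtype=float)
        else:
            if X.shape[0] < 2:
                raise ValidationError("MSC needs >= 2 spectra to form a mean reference")
            self.reference_ = X.mean(axis=0)
        return self

    def transform(self, X):
        X = _as2d(X)
        m = self.reference_
        mc = m - m.mean()
        denom = mc @ mc
        b = (X - X.mean(axis=1, keepdims=True)) @ mc / denom
        bad = np.where(np.abs(b) < self.min_slope)[0]
        if bad.size:
            raise ValidationError(f"MSC: near-zero regression slope at row(s) {bad.tolist()}")
        a = X.mean(axis=1) - b * m.mean()
        return (X - a[:, None]) / b[:, None]


class MovingAverage(BaseEstimator, TransformerMixin):
    """Centered running mean with truncated (shrunken) windows at the edges."""

    def __init__(self, window: int = 5):
        self.window = window

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = _as2d(X)
        w = self.window
        if w % 2 == 0 or w < 1:
            raise ValidationError(f"moving-average window must be odd, got {w}")
        if w > X.shape[1]:
            raise ValidationError("moving-average window exceeds band count")
        half = w // 2
        c = np.cumsum(np.pad(X, ((0, 0), (1, 0))), axis=1)
        n = X.shape[1]
        lo = np.maximum(np.arange(n) - half, 0)
        hi = np.minimum(np.arange(n) + half + 1, n)
        return (c[:, hi] - c[:, lo]) / (hi - lo)


class SavgolSmooth(BaseEstimator, TransformerMixin):
    """Savitzky-Golay least-squares local polynomial smoothing."""

    def __init__(self, window: int = 11, polyorder: int = 2):
        self.window = window
        self.polyorder = polyorder

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        if self.window % 2 == 0:
            raise ValidationError(f"SG window must be odd, got {self.window}")
        if self.polyorder >= self.window:
            raise ValidationError("SG polyorder must be < window")
        return savgol_filter(_as2d(X), self.window, self.polyorder, axis=1)


class Detrend(BaseEstimator, TransformerMixin):
    """Subtract a per-spectrum least-squares polynomial in wavenumber.

    Degree 2 by default, removing baseline offset, tilt and curvature.  The
    abscissa defaults to band index; pass the wavenumber grid for physically
    scaled fits (the residual is identical either way up to conditioning).
    """

    def __init__(self, degree: int = 2, x: Optional[np.ndarray] = None):
        self.degree = degree
        self.x = x

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = _as2d(X)
        if self.degree < 1:
            raise ValidationError("detrend degree must be >= 1")
        if X.shape[1] <= self.degree:
            raise ValidationError("detrend needs n_bands > degree")
        x = np.arange(X.shape[1], dtype=float) if self.x is None else np.asarray(self.x, float)
        # orthonormal polynomial basis => residual = X - proj(X)
        V = np.vander((x - x.mean()) / (x.std() or 1.0), self.degree + 1, increasing=True)
        Q, _ = np.linalg.qr(V)
        return X - (X @ Q) @ Q.T


class SGDerivative(BaseEstimator, TransformerMixin):
    """Savitzky-Golay derivative along the wavenumber axis.

    ``delta`` is the grid spacing so a first derivative is in reflectance per
    cm^-1; order 1 defaults to polyorder 2, order 2 to polyorder 3.
    """

    def __init__(self, order: int = 1, window: int = 11,
                 polyorder: Optional[int] = None, delta: float = 1.0):
        self.order = order
        self.window = window
        self.polyorder = polyorder
        self.delta = delta

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        if self.order not in (1, 2):
            raise ValidationError(f"derivative order must be 1 or 2, got {self.order}")
        poly = self.polyorder if self.polyorder is not None else (2 if self.order == 1 else 3)
        if poly < self.order:
            raise ValidationError("polyorder must be >= derivative order")
        if self.window % 2 == 0 or poly >= self.window:
            raise ValidationError("need odd window > polyorder")
        return savgol_filter(_as2d(X), self.window, poly, deriv=self.order,
                             delta=self.delta, axis=1)


# ---------------------------------------------------------------------------
# Variant grid

@dataclass(frozen=True)
class PreprocessVariant:
    """One cell of the 6 x 3 preprocessing grid, e.g. ``MSC-SD`` or ``DT-RAW``."""

    base: str = "RAW"
    derivative: str = "RAW"
    ma_window: int = 5
    sg_window: int = 11
    sg_polyorder: int = 2
    dt_degree: int = 2
    deriv_window: int = 11

    def __post_init__(self):
        if self.base not in BASES:
            raise ValidationError(f"unknown base {self.base!r}; expected one of {BASES}")
        if self.derivative not in DERIVATIVES:
            raise ValidationError(
                f"unknown derivative {self.derivative!r}; expected one of {DERIVATIVES}")

    @property
    def label(self) -> str:
        return f"{self.base}-{self.derivative}"

    @classmethod
    def from_label(cls, label: str, **params) -> "PreprocessVariant":
        base, _, deriv = label.partition("-")
        return cls(base=base.upper(), derivative=(deriv or "RAW").upper(), **params)


def enumerate_variants(**params) -> Iterator[PreprocessVariant]:
    """Yield all 18 preprocessing variants in a fixed (base-major) order."""
    for base in BASES:
        for deriv in DERIVATIVES:
            yield PreprocessVariant(base=base, derivative=deriv, **params)


def _base_transformer(variant: PreprocessVariant):
    if variant.base == "RAW":
        return None
    if variant.base == "SNV":
        return SNV()
    if variant.base == "MA":
        return MovingAverage(window=variant.ma_window)
    if variant.base == "SG":
        return SavgolSmooth(window=variant.sg_window, polyorder=variant.sg_polyorder)
    if variant.base == "MSC":
        return MSC()
    return Detrend(degree=variant.dt_degree)


def apply_variant(spectra: SpectraSet, variant: PreprocessVariant) -> SpectraSet:
    """Apply a variant to a SpectraSet: base correction first, then derivative."""
    X = spectra.reflectance
    if variant.base == "DT":
        base = Detrend(degree=variant.dt_degree, x=spectra.wavenumbers)
    else:
        base = _base_transformer(variant)
    if base is not None:
        X = base.fit_transform(X)
    if variant.derivative != "RAW":
        order = 1 if variant.derivative == "FD" else 2
        delta = float(np.mean(np.diff(spectra.wavenumbers))) if spectra.n_bands > 1 else 1.0
        X = SGDerivative(order=order, window=variant.deriv_window,
                         delta=delta).fit_transform(X)
    return spectra.with_reflectance(X)
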