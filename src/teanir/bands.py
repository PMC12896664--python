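"""Two-band spectral indices and exhaustive band-pair correlation search.

Six index families combine the reflectances Rm, Rn of two bands into a scalar
feature: simple ratio SR = Rm/Rn, its normalized form NSR, the difference
index DSI = Rm - Rn, the normalized difference NDSI, a generalized difference
GDSI mixing Rm^2 with Rn, and a translated NDSI (TNDSI = NDSI + 0.5).  For a
given indicator, the search scans every ordered band pair of a (preprocessed)
spectra matrix and keeps the pair whose feature has the largest absolute
Pearson correlation with the indicator; correlations are screened against the
two-sided Student-t critical value (|r| = 0.196 at n = 171, p < 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .dataset import AlignedDataset, SpectraSet, ValidationError
from .preprocess import PreprocessVariant, apply_variant

INDEX_KINDS = ("SR", "NSR", "DSI", "NDSI", "GDSI", "TNDSI")


def _index_values(kind: str, Rm: np.ndarray, Rn: np.ndarray,
                  tndsi_sqrt: bool = False) -> np.ndarray:
    """Elementwise index formula; non-finite results (zero denominators) -> NaN."""
    with np.errstate(divide="ignore", invalid="ignore"):
        if kind == "SR":
            v = Rm / Rn
        elif kind == "NSR":
            r = Rm / Rn
            v = (r - 1.0) / (r + 1.0)
        elif kind == "DSI":
            v = Rm - Rn
        elif kind == "NDSI":
            v = (Rm - Rn) / (Rm + Rn)
        elif kind == "GDSI":
            v = (Rm ** 2 - Rn) / (Rm ** 2 + Rn)
        elif kind == "TNDSI":
            v = (Rm - Rn) / (Rm + Rn) + 0.5
            if tndsi_sqrt:
                with np.errstate(invalid="ignore"):
                    v = np.sqrt(v)
        else:
            raise ValidationError(f"unknown index kind {kind!r}; expected {INDEX_KINDS}")
    v = np.asarray(v, dtype=float)
    v[~np.isfinite(v)] = np.nan
    return v


def compute_index(spectra: SpectraSet, kind: str, m: float, n: float,
                  tndsi_sqrt: bool = False) -> np.ndarray:
    """Per-sample index values for bands at wavenumbers m and n (must be on grid)."""
    wn = spectra.wavenumbers
    im = int(np.argmin(np.abs(wn - m)))
    iin = int(np.argmin(np.abs(wn - n)))
    if not np.isclose(wn[im], m) or not np.isclose(wn[iin], n):
        raise ValidationError(f"bands ({m}, {n}) not on the wavenumber grid")
    return _index_values(kind, spectra.reflectance[:, im],
                         spectra.reflectance[:, iin], tndsi_sqrt)


def pearson_corr(x, y) -> float:
    """Product-moment correlation; NaN (with a warning-free contract) if constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("pearson_corr needs equal lengths >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc @ xc) * (yc @ yc))
    if den == 0:
        return float("nan")
    return float(np.clip(xc @ yc / den, -1.0, 1.0))


def critical_pcc(n: int, alpha: float = 0.01) -> float:
    """Smallest |r| significant at the two-sided level ``alpha`` with n samples.

    From the exact relation t = r * sqrt(n-2) / sqrt(1-r^2) against
    Student-t(n-2):  r_crit = t_crit / sqrt(n - 2 + t_crit^2).
    At n = 171, alpha = 0.01 this gives 0.196 (3 decimals).
    """
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0,1), got {alpha}")
    if n < 4:
        raise ValidationError("critical_pcc needs n >= 4")
    t = stats.t.isf(alpha / 2.0, n - 2)
    return float(t / np.sqrt(n - 2 + t * t))


@dataclass
class BandPairFeature:
    """Best band pair for one index kind: its bands, correlation, and values."""

    kind: str
    band_m: float
    band_n: float
    pcc: float
    values: np.ndarray
    preprocess_label: str = "RAW-RAW"

    def __post_init__(self):
        if not (np.isnan(self.pcc) or abs(self.pcc) <= 1.0 + 1e-12):
            raise ValidationError("|pcc| > 1")


def _pairwise_pcc_block(V: np.ndarray, y: np.ndarray, max_missing_frac: float):
    """Pairwise-complete Pearson correlations of each column block vs y.

    V has shape (n_samples, ...); NaN entries drop that sample for that pair.
    Pairs with more than ``max_missing_frac`` missing samples get NaN.
    """
    W = np.isfinite(V)
    cnt = W.sum(axis=0)
    frac_bad = 1.0 - cnt / V.shape[0]
    Vz = np.where(W, V, 0.0)
    yb = y.reshape((-1,) + (1,) * (V.ndim - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        Vm = Vz.sum(axis=0) / cnt
        ym = (W * yb).sum(axis=0) / cnt
        Vc = np.where(W, V - Vm, 0.0)
        yc = np.where(W, yb - ym, 0.0)
        num = (Vc * yc).sum(axis=0)
        den = np.sqrt((Vc ** 2).sum(axis=0) * (yc ** 2).sum(axis=0))
        r = num / den
    r = np.where((den > 0) & (frac_bad <= max_missing_frac) & (cnt >= 3), r, np.nan)
    return np.clip(r, -1.0, 1.0)


def search_band_pairs(spectra: SpectraSet, target, kind: str,
                      chunk: int = 16, max_missing_frac: float = 0.05,
                      tndsi_sqrt: bool = False) -> BandPairFeature:
    """Exhaustive ordered-pair search maximizing |PCC| with the target.

    The m-axis is processed in chunks so memory stays at
    O(chunk x n_bands x n_samples).  Ties break to the lower band_m, then the
    lower band_n (ascending scan with strict improvement).  The diagonal
    m == n is excluded (a one-band "pair" is degenerate for every kind).
    """
    y = np.asarray(target, dtype=float)
    R = spectra.reflectance
    nb = spectra.n_bands
    if nb < 2:
        raise ValidationError("need at least 2 bands")
    if y.size != spectra.n_samples:
        raise ValidationError("target length does not match n_samples")
    best = (-np.inf, -1, -1)
    for start in range(0, nb, chunk):
        mm = np.arange(start, min(start + chunk, nb))
        Rm = R[:, mm][:, :, None]           # (ns, c, 1)
        Rn = R[:, None, :]                  # (ns, 1, nb)
        V = _index_values(kind, Rm, Rn, tndsi_sqrt)   # (ns, c, nb)
        r = _pairwise_pcc_block(V, y, max_missing_frac)
        for ci, m in enumerate(mm):
            r[ci, m] = np.nan               # drop diagonal
        a = np.abs(r)
        if np.all(np.isnan(a)):
            continue
        flat = np.nanargmax(a)
        ci, ni = np.unravel_index(flat, a.shape)
        if a[ci, ni] > best[0]:
            best = (float(a[ci, ni]), int(mm[ci]), int(ni))
    if best[1] < 0:
        raise ValidationError(f"all band pairs masked for index kind {kind}")
    _, im, iin = best
    vals = _index_values(kind, R[:, im], R[:, iin], tndsi_sqrt)
    pcc = _pairwise_pcc_block(vals[:, None], y, max_missing_frac)[0]
    return BandPairFeature(kind=kind, band_m=float(spectra.wavenumbers[im]),
                           band_n=float(spectra.wavenumbers[iin]),
                           pcc=float(pcc), values=vals)


def screen_bc_features(dataset: AlignedDataset,
                       variants: Sequence[PreprocessVariant],
                       alpha: float = 0.01,
                       kinds: Sequence[str] = INDEX_KINDS,
                       chunk: int = 16,
                       tndsi_sqrt: bool = False) -> list[BandPairFeature]:
    """Best (variant, band pair) per index kind, dropping insignificant kinds.

    For each of the six index kinds the search runs over every preprocessing
    variant and every ordered band pair; the winner is kept only if its |PCC|
    reaches the two-sided critical value at level ``alpha`` for the dataset's
    sample count (kinds can therefore be absent from the result).
    """
    if not variants:
        raise ValidationError("need at least one preprocessing variant")
    y = dataset.y
    thresh = critical_pcc(dataset.spectra.n_samples, alpha)
    pre = [(v.label, apply_variant(dataset.spectra, v)) for v in variants]
    out: list[BandPairFeature] = []
    for kind in kinds:
        winner: Optional[BandPairFeature] = None
        for label, sp in pre:
            try:
                f = search_band_pairs(sp, y, kind, chunk=chunk, tndsi_sqrt=tndsi_sqrt)
            except ValidationError:
                continue
            f.preprocess_label = label
            if winner is None or abs(f.pcc) > abs(winner.pcc):
                winner = f
        if winner is not None and abs(winner.pcc) >= thresh:
            out.append(winner)
    return out


class BandCombinationFeaturizer(BaseEstimator, TransformerMixin):
    """Supervised transformer: learn the best band pair per index kind on fit.

    Operates on plain reflectance matrices (one preprocessing variant at a
    time) so it can sit inside a scikit-learn pipeline; pairs whose |PCC|
    misses the significance threshold are dropped.  Fitted attributes:
    ``pairs_`` (list of (kind, im, in) band-index triples) and ``pccs_``.
    """

    def __init__(self, kinds: Sequence[str] = INDEX_KINDS, alpha: float = 0.01,
                 chunk: int = 16, tndsi_sqrt: bool = False):
        self.kinds = kinds
        self.alpha = alpha
        self.chunk = chunk
        self.tndsi_sqrt = tndsi_sqrt

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        sp = SpectraSet(np.arange(X.shape[1], dtype=float), X)
        thresh = critical_pcc(X.shape[0], self.alpha)
        self.pairs_ = []
        self.pccs_ = []
        for kind in self.kinds:
            try:
                f = search_band_pairs(sp, y, kind, chunk=self.chunk,
                                      tndsi_sqrt=self.tndsi_sqrt)
            except ValidationError:
                continue
            if abs(f.pcc) >= thresh:
                self.pairs_.append((kind, int(f.band_m), int(f.band_n)))
                self.pccs_.append(float(f.pcc))
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        cols = [_index_values(kind, X[:, im], X[:, iin], self.tndsi_sqrt)
                for kind, im, iin in self.pairs_]
        if not cols:
            return np.empty((X.shape[0], 0))
        out = np.column_stack(cols)
        # residual NaNs (masked samples) -> per-column mean imputation
        mu = np.nanmean(out, axis=0)
        idx = np.where(np.isnan(out))
        out[idx] = np.take(mu, idx[1])
        return out

    def get_feature_names_out(self, input_features=None):
        return np.array([f"BC_{k}_{m}_{n}" for k, m, n in self.pairs_])
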