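"""Containers and I/O for diffuse-reflectance NIR spectra and quality indicators.

A :class:`SpectraSet` holds a sample x band reflectance matrix on a strictly
monotone wavenumber grid (cm^-1); an :class:`IndicatorTable` holds per-sample
measured contents (mass-fraction %) of the four tea quality indicators.  Both
round-trip through plain CSV so every downstream stage is scriptable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

INDICATORS = ("theanine", "tea_polyphenols", "soluble_sugar", "water_extract")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


class ParseError(ValueError):
    """Raised when a cell of an input table cannot be interpreted."""


@dataclass
class SpectraSet:
    """Wavenumber grid plus sample x band reflectance matrix.

    Parameters
    ----------
    wavenumbers : ndarray, shape (n_bands,)
        Strictly ascending grid in cm^-1.
    reflectance : ndarray, shape (n_samples, n_bands)
        Dimensionless reflectance; all values finite.
    sample_ids : list of str
        Unique, opaque sample identifiers.
    """

    wavenumbers: np.ndarray
    reflectance: np.ndarray
    sample_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.reflectance = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
        if not self.sample_ids:
            self.sample_ids = [f"S{i}" for i in range(self.reflectance.shape[0])]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.validate()

    def validate(self) -> None:
        if self.reflectance.shape[1] != self.wavenumbers.size:
            raise ValidationError(
                f"reflectance has {self.reflectance.shape[1]} bands but grid has "
                f"{self.wavenumbers.size}"
            )
        d = np.diff(self.wavenumbers)
        if self.wavenumbers.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValidationError("wavenumbers must be strictly monotone")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValidationError("non-finite reflectance values")
        if len(self.sample_ids) != self.reflectance.shape[0]:
            raise ValidationError("sample_ids length does not match n_samples")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.wavenumbers.size

    def ascending(self) -> "SpectraSet":
        """Return a copy with the wavenumber axis sorted ascending."""
        if self.wavenumbers.size < 2 or self.wavenumbers[1] > self.wavenumbers[0]:
            return SpectraSet(self.wavenumbers.copy(), self.reflectance.copy(),
                              list(self.sample_ids))
        return SpectraSet(self.wavenumbers[::-1].copy(),
                          self.reflectance[:, ::-1].copy(), list(self.sample_ids))

    def with_reflectance(self, r: np.ndarray) -> "SpectraSet":
        return SpectraSet(self.wavenumbers.copy(), r, list(self.sample_ids))

    def subset(self, ids: Sequence[str]) -> "SpectraSet":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        return SpectraSet(self.wavenumbers.copy(), self.reflectance[idx], list(ids))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.reflectance, index=self.sample_ids,
                          columns=[f"{w:.17g}" for w in self.wavenumbers])
        df.index.name = "sample_id"
        return df


@dataclass
class IndicatorTable:
    """Per-sample measured contents of the quality indicators (mass-fraction %)."""

    sample_ids: list
    values: pd.DataFrame  # index sample_ids, one column per indicator, NaN = missing

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids in indicator table")
        self.values = self.values.copy()
        self.values.index = self.sample_ids
        for col in self.values.columns:
            v = self.values[col].to_numpy(dtype=float)
            if np.any(np.isinf(v)):
                raise ValidationError(f"infinite value in indicator {col!r}")

    def indicator(self, name: str) -> pd.Series:
        if name not in self.values.columns:
            raise KeyError(f"unknown indicator {name!r}; have {list(self.values.columns)}")
        return self.values[name]

    def subset(self, ids: Sequence[str]) -> "IndicatorTable":
        return IndicatorTable(list(ids), self.values.loc[list(ids)])


@dataclass
class AlignedDataset:
    """Spectra and one indicator restricted to common samples, same order."""

    spectra: SpectraSet
    indicators: IndicatorTable
    indicator_name: str

    def __post_init__(self):
        if self.spectra.sample_ids != self.indicators.sample_ids:
            raise ValidationError("spectra/indicator sample ids differ or are reordered")
        if self.spectra.n_samples < 2:
            raise ValidationError("aligned dataset needs at least 2 samples")

    @property
    def y(self) -> np.ndarray:
        return self.indicators.indicator(self.indicator_name).to_numpy(dtype=float)

    @property
    def sample_ids(self) -> list:
        return self.spectra.sample_ids


# ---------------------------------------------------------------------------
# I/O

def load_spectra(path, dialect: str = "header") -> SpectraSet:
    """Load a spectra CSV/TSV matrix.

    ``dialect="header"``: header row holds wavenumbers, first column sample ids
    (the package's native layout).  ``dialect="column"``: first column holds
    wavenumbers and each remaining column is one sample.
    Wavenumbers are returned ascending; columns are reordered if needed.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if dialect == "column":
        df = df.T
    try:
        wn = np.array([float(c) for c in df.columns])
    except ValueError as exc:
        raise ParseError(f"non-numeric wavenumber header in {path}: {exc}") from exc
    vals = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = ~np.isfinite(vals)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"non-numeric or missing cell at sample {df.index[i]!r}, "
            f"wavenumber {df.columns[j]!r} in {path}"
        )
    ids = [str(s) for s in df.index]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate sample id in {path}")
    order = np.argsort(wn)
    return SpectraSet(wn[order], vals.astype(float)[:, order], ids)


def save_spectra(spectra: SpectraSet, path) -> None:
    """Write the native layout at full double precision (scientific notation)."""
    df = spectra.to_frame()
    df.to_csv(path, float_format="%.17e")


def load_indicators(path) -> IndicatorTable:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "sample_id" not in df.columns:
        raise ParseError(f"{path} lacks a 'sample_id' column")
    ids = [str(s) for s in df["sample_id"]]
    vals = df.drop(columns=["sample_id"]).apply(pd.to_numeric, errors="coerce")
    return IndicatorTable(ids, vals)


def save_indicators(table: IndicatorTable, path) -> None:
    df = table.values.copy()
    df.insert(0, "sample_id", table.sample_ids)
    df.to_csv(path, index=False, float_format="%.17e")


# ---------------------------------------------------------------------------
# Replicate averaging and outlier screening

def average_replicates(spectra: SpectraSet, replicate_map: Mapping[str, str]) -> SpectraSet:
    """Average replicate acquisitions: one output row per group (arithmetic mean).

    Output groups appear in order of first occurrence among the input rows.
    """
    missing = [s for s in spectra.sample_ids if s not in replicate_map]
    if missing:
        raise ValidationError(f"samples without replicate group: {missing}")
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(spectra.sample_ids):
        groups.setdefault(str(replicate_map[s]), []).append(i)
    for g, idx in groups.items():
        if not idx:
            raise ValidationError(f"empty replicate group {g!r}")
    rows = np.stack([spectra.reflectance[idx].mean(axis=0) for idx in groups.values()])
    return SpectraSet(spectra.wavenumbers.copy(), rows, list(groups.keys()))


def boxplot_filter(values, k: float = 1.5, quantile_method: str = "linear"):
    """Tukey box-plot screen: keep values in [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use linear interpolation between order statistics by default
    (numpy's ``method="linear"``, the common type-7 rule); ``quantile_method``
    selects any numpy quantile method.  A constant vector has IQR 0 and keeps
    everything.  Returns ``(kept_mask, (lo, hi))``.
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() < 4:
        raise ValidationError("boxplot_filter needs at least 4 finite values")
    q1, q3 = np.quantile(v[finite], [0.25, 0.75], method=quantile_method)
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    kept = finite & (v >= lo) & (v <= hi)
    return kept, (lo, hi)


def align(spectra: SpectraSet, indicators: IndicatorTable, indicator_name: str,
          k: float = 1.5, remove_outliers: bool = True) -> AlignedDataset:
    """Intersect sample ids, drop samples with missing or outlying indicator values.

    Ordering follows the spectra's sample order restricted to the intersection,
    which makes the result deterministic for a given pair of tables.
    """
    common = [s for s in spectra.sample_ids if s in set(indicators.sample_ids)]
    if not common:
        raise ValidationError("no common sample ids between spectra and indicators")
    y = indicators.indicator(indicator_name).loc[common].to_numpy(dtype=float)
    present = np.isfinite(y)
    keep = present.copy()
    if remove_outliers and present.sum() >= 4:
        kept_mask, _ = boxplot_filter(y[present], k=k)
        keep[present] = kept_mask
    ids = [s for s, m in zip(common, keep) if m]
    if len(ids) < 2:
        raise ValidationError("fewer than 2 samples survive alignment/outlier removal")
    return AlignedDataset(spectra.subset(ids), indicators.subset(ids), indicator_name)
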