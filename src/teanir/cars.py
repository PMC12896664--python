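"""Competitive adaptive reweighted sampling (CARS) wavelength selection.

CARS iterates a fixed number of rounds.  Each round fits a PLS model on a
Monte-Carlo row subsample of the currently retained bands, then shrinks the
band set in two moves driven by the absolute PLS regression coefficients:
(1) forced removal — the top share of the round's retention count is kept
deterministically by coefficient magnitude, and (2) adaptive reweighted
sampling — the remaining slots are filled by a weighted draw (without
replacement, probability proportional to |coefficient|) among the other
candidates, so weakly weighted bands survive only by competition.  The
retention count follows the exponentially decreasing function (EDF) schedule,
from all p bands at round 1 down to 2 bands at the last round, so every
round retains exactly round(r_i * p) bands and the full-band model itself is
the first candidate.  Every round's subset is scored by cross-validated RMSE
(RMSECV, with the PLS component count itself chosen by the same CV, on a
fixed fold assignment), and the subset with the global RMSECV minimum is
selected — by construction it can never score worse than the full-band model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.cross_decomposition import PLSRegression
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import KFold

from .dataset import ValidationError


def edf_schedule(p: int, n_iterations: int) -> np.ndarray:
    """Exponentially decreasing retention ratios r_i = a*exp(-k*i), i = 1..N.

    The boundary conditions r_1 = 1 (keep all p bands) and r_N = 2/p (keep 2)
    fix a = (p/2)^(1/(N-1)) and k = ln(p/2)/(N-1).
    """
    if p < 4:
        raise ValidationError("EDF schedule needs p >= 4 bands")
    if n_iterations < 2:
        raise ValidationError("EDF schedule needs at least 2 iterations")
    N = n_iterations
    a = (p / 2.0) ** (1.0 / (N - 1))
    k = np.log(p / 2.0) / (N - 1)
    i = np.arange(1, N + 1)
    return a * np.exp(-k * i)


def _pls_coef(X: np.ndarray, y: np.ndarray, n_components: int) -> np.ndarray:
    pls = PLSRegression(n_components=n_components, scale=True)
    pls.fit(X, y)
    return np.ravel(pls.coef_)


def rmsecv(X, y, folds: int = 5, max_components: int = 10,
           random_state=None) -> float:
    """PLS cross-validated RMSE with the component count chosen by the same CV.

    Deterministic for a fixed fold assignment (``random_state=None`` uses
    unshuffled contiguous folds).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if folds < 2:
        raise ValidationError("rmsecv needs >= 2 folds")
    if np.std(y) == 0:
        raise ValidationError("constant target")
    shuffle = random_state is not None
    kf = KFold(n_splits=folds, shuffle=shuffle,
               random_state=random_state if shuffle else None)
    splits = list(kf.split(X))
    ncomp_max = int(min(max_components, X.shape[1],
                        min(len(tr) for tr, _ in splits) - 1))
    best = np.inf
    for nc in range(1, max(ncomp_max, 1) + 1):
        sse = 0.0
        for tr, te in splits:
            pls = PLSRegression(n_components=nc, scale=True)
            pls.fit(X[tr], y[tr])
            pred = np.ravel(pls.predict(X[te]))
            sse += float(np.sum((y[te] - pred) ** 2))
        best = min(best, np.sqrt(sse / len(y)))
    return best


@dataclass
class CARSResult:
    """Per-iteration trace and the RMSECV-minimizing band subset."""

    subsets: list = field(default_factory=list)       # post-ARS band index arrays
    rmsecv_path: np.ndarray = None                    # RMSECV per iteration
    edf_counts: np.ndarray = None                     # forced-removal counts round(r_i*p)
    ratios: np.ndarray = None                         # EDF retention ratios
    best_iteration: int = -1

    @property
    def selected(self) -> np.ndarray:
        return self.subsets[self.best_iteration]


class CARSSelector(SelectorMixin, BaseEstimator):
    """scikit-learn selector exposing CARS as fit + transform.

    Fitted attributes: ``support_`` (boolean band mask), ``result_``
    (:class:`CARSResult` with the full per-iteration trace) and
    ``rmsecv_full_`` (the full-band RMSECV baseline).
    """

    def __init__(self, n_iterations: int = 50, mc_sample_fraction: float = 0.8,
                 cv_folds: int = 5, max_components: int = 10,
                 forced_fraction: float = 0.5, random_state=None):
        self.n_iterations = n_iterations
        self.mc_sample_fraction = mc_sample_fraction
        self.cv_folds = cv_folds
        self.max_components = max_components
        self.forced_fraction = forced_fraction
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if n < 10:
            raise ValidationError("CARS needs at least 10 samples")
        if p < 4:
            raise ValidationError("CARS needs at least 4 bands")
        if not 0 < self.mc_sample_fraction <= 1:
            raise ValidationError("mc_sample_fraction must be in (0, 1]")
        if np.std(y) == 0:
            raise ValidationError("constant target")
        rng = np.random.default_rng(self.random_state)
        ratios = edf_schedule(p, self.n_iterations)
        counts = np.maximum(np.round(ratios * p).astype(int), 2)
        n_mc = max(int(round(self.mc_sample_fraction * n)), 2)
        subset = np.arange(p)
        subsets, errs = [], []
        for i in range(self.n_iterations):
            rows = np.sort(rng.choice(n, size=n_mc, replace=False))
            nc = int(min(self.max_components, subset.size, n_mc - 1))
            w = np.abs(_pls_coef(X[np.ix_(rows, subset)], y[rows], max(nc, 1)))
            keep = max(min(counts[i], subset.size), 2)
            order = np.argsort(-w, kind="stable")
            # forced removal: the strongest bands are immune to competition
            n_forced = min(int(np.ceil(self.forced_fraction * keep)), keep)
            forced = order[:n_forced]
            # adaptive reweighted sampling fills the remaining slots from the
            # other candidates, weighted by |coefficient|, without replacement
            rest = order[n_forced:]
            n_draw = keep - n_forced
            if n_draw > 0 and rest.size > 0:
                wr = w[rest]
                prob = wr / wr.sum() if wr.sum() > 0 else None
                drawn = rng.choice(rest, size=min(n_draw, rest.size),
                                   replace=False, p=prob)
                chosen = np.concatenate([forced, drawn])
            else:
                chosen = forced
            subset = np.sort(subset[chosen])
            errs.append(rmsecv(X[:, subset], y, folds=self.cv_folds,
                               max_components=self.max_components))
            subsets.append(subset.copy())
        best = int(np.argmin(errs))
        self.result_ = CARSResult(subsets=subsets, rmsecv_path=np.array(errs),
                                  edf_counts=counts, ratios=ratios,
                                  best_iteration=best)
        self.rmsecv_full_ = rmsecv(X, y, folds=self.cv_folds,
                                   max_components=self.max_components)
        self.n_features_in_ = p
        self.support_ = np.zeros(p, dtype=bool)
        self.support_[self.result_.selected] = True
        return self

    def _get_support_mask(self):
        return self.support_


def run_cars(X, y, n_iterations: int = 50, mc_sample_fraction: float = 0.8,
             cv_folds: int = 5, max_components: int = 10,
             random_state=None) -> CARSResult:
    """Functional wrapper over :class:`CARSSelector`; returns the CARSResult."""
    sel = CARSSelector(n_iterations=n_iterations,
                       mc_sample_fraction=mc_sample_fraction,
                       cv_folds=cv_folds, max_components=max_components,
                       random_state=random_state)
    sel.fit(X, y)
    return sel.result_
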