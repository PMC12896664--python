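"""Feature fusion, ridge / PLS calibration, and Monte-Carlo repeated k-fold CV.

Model quality is reported with three chemometric metrics:

* R^2 = 1 - SSE/SST (coefficient of determination),
* NRMSE = RMSE / mean(y_actual),
* RPD = sqrt(sum (y_a - mean(y_p))^2 / (n-1)) / RMSE — note the numerator
  takes deviations of the *actuals* around the mean of the *predictions*;
  ``conventional=True`` switches to the textbook sd(actuals)/RMSE form.

Cross-validation draws a fresh random 10-fold partition per Monte-Carlo
repeat; scaling and hyperparameter selection are refit inside each training
fold, so the validation metrics carry no leakage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler

from .dataset import ValidationError

PROVENANCES = ("CARS", "BC", "AFD", "FFT", "CWT")


@dataclass
class FeatureBlock:
    """Named sample x feature matrix with provenance and preprocessing tag."""

    X: np.ndarray
    provenance: str
    preprocess_label: str = "RAW-RAW"
    feature_names: Optional[list] = None

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if not np.all(np.isfinite(self.X)):
            raise ValidationError(f"non-finite values in {self.provenance} feature block")
        if self.feature_names is None:
            self.feature_names = [f"{self.provenance}_{j}" for j in range(self.X.shape[1])]

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def fuse_features(blocks: Sequence[FeatureBlock]) -> FeatureBlock:
    """Column-concatenate blocks and standardize every column to mean 0, sd 1.

    Constant columns carry no calibration information and are dropped with a
    warning.  Provenance is recorded per column through the feature names.
    """
    if not blocks:
        raise ValidationError("no feature blocks to fuse")
    ns = {b.n_samples for b in blocks}
    if len(ns) != 1:
        raise ValidationError(f"sample-count mismatch across blocks: {sorted(ns)}")
    X = np.hstack([b.X for b in blocks])
    names = [f"{b.provenance}:{n}" for b in blocks for n in b.feature_names]
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    const = sd <= 1e-12 * np.maximum(1.0, np.abs(mu))
    if const.any():
        dropped = [names[j] for j in np.where(const)[0]]
        warnings.warn(f"dropping constant fused columns: {dropped}", stacklevel=2)
        X, mu, sd = X[:, ~const], mu[~const], sd[~const]
        names = [n for n, c in zip(names, const) if not c]
    Z = (X - mu) / sd
    label = "+".join(dict.fromkeys(b.preprocess_label for b in blocks))
    return FeatureBlock(Z, provenance="+".join(dict.fromkeys(b.provenance for b in blocks)),
                        preprocess_label=label, feature_names=names)


# ---------------------------------------------------------------------------
# Calibrators

DEFAULT_LAMBDA_GRID = np.logspace(-6, 3, 13)


class RidgeCalibrator(BaseEstimator, RegressorMixin):
    """Ridge regression on standardized predictors with an unpenalized intercept.

    The penalty weight is chosen by inner k-fold CV over a log-spaced grid.
    """

    def __init__(self, lambda_grid=None, inner_folds: int = 5, random_state=None):
        self.lambda_grid = lambda_grid
        self.inner_folds = inner_folds
        self.random_state = random_state

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        if X.shape[0] < 3:
            raise ValidationError("ridge fit needs n >= 3")
        grid = np.asarray(self.lambda_grid if self.lambda_grid is not None
                          else DEFAULT_LAMBDA_GRID, dtype=float)
        self.scaler_ = StandardScaler().fit(X)
        Z = self.scaler_.transform(X)
        if len(grid) > 1 and X.shape[0] >= self.inner_folds + 1:
            kf = KFold(n_splits=self.inner_folds, shuffle=True,
                       random_state=self.random_state)
            splits = list(kf.split(Z))
            sse = np.zeros(len(grid))
            for tr, te in splits:
                sc = StandardScaler().fit(X[tr])
                Ztr, Zte = sc.transform(X[tr]), sc.transform(X[te])
                for g, lam in enumerate(grid):
                    r = Ridge(alpha=lam).fit(Ztr, y[tr])
                    sse[g] += np.sum((y[te] - r.predict(Zte)) ** 2)
            self.lambda_ = float(grid[int(np.argmin(sse))])
        else:
            self.lambda_ = float(grid[0])
        self.ridge_ = Ridge(alpha=self.lambda_).fit(Z, y)
        self.coef_ = self.ridge_.coef_
        self.intercept_ = self.ridge_.intercept_
        return self

    def predict(self, X):
        return self.ridge_.predict(self.scaler_.transform(np.atleast_2d(np.asarray(X, float))))


class PLSCalibrator(BaseEstimator, RegressorMixin):
    """PLS regression with the component count chosen by inner k-fold CV."""

    def __init__(self, max_components: int = 20, inner_folds: int = 5,
                 random_state=None):
        self.max_components = max_components
        self.inner_folds = inner_folds
        self.random_state = random_state

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        cap = int(min(self.max_components, X.shape[1], X.shape[0] - 1))
        if cap < 1:
            raise ValidationError("PLS needs max_components >= 1 within rank limits")
        if cap > 1 and X.shape[0] >= self.inner_folds + 1:
            kf = KFold(n_splits=self.inner_folds, shuffle=True,
                       random_state=self.random_state)
            splits = list(kf.split(X))
            cap_cv = min(cap, min(len(tr) for tr, _ in splits) - 1)
            sse = np.full(cap_cv, np.inf)
            for nc in range(1, cap_cv + 1):
                s = 0.0
                for tr, te in splits:
                    pls = PLSRegression(n_components=nc, scale=True).fit(X[tr], y[tr])
                    s += np.sum((y[te] - np.ravel(pls.predict(X[te]))) ** 2)
                sse[nc - 1] = s
            self.n_components_ = int(np.argmin(sse)) + 1
        else:
            self.n_components_ = 1
        self.pls_ = PLSRegression(n_components=self.n_components_, scale=True).fit(X, y)
        return self

    def predict(self, X):
        return np.ravel(self.pls_.predict(np.atleast_2d(np.asarray(X, float))))


def fit_ridge(X, y, lambda_grid=None, random_state=None) -> RidgeCalibrator:
    return RidgeCalibrator(lambda_grid=lambda_grid, random_state=random_state).fit(X, y)


def fit_plsr(X, y, max_components: int = 20, random_state=None) -> PLSCalibrator:
    return PLSCalibrator(max_components=max_components, random_state=random_state).fit(X, y)


def make_model(name: str, random_state=None) -> BaseEstimator:
    key = name.strip().lower()
    if key in ("rr", "ridge"):
        return RidgeCalibrator(random_state=random_state)
    if key in ("plsr", "pls"):
        return PLSCalibrator(random_state=random_state)
    raise ValidationError(f"unknown model {name!r}; expected 'rr' or 'plsr'")


# ---------------------------------------------------------------------------
# Metrics

def evaluate_metrics(y_actual, y_predicted, conventional_rpd: bool = False):
    """(R^2, NRMSE, RPD) for one set of predictions.

    A perfect fit returns RPD = +inf.  NRMSE is undefined when the actuals
    average to zero.
    """
    ya = np.asarray(y_actual, dtype=float)
    yp = np.asarray(y_predicted, dtype=float)
    n = ya.size
    if n < 2 or yp.size != n:
        raise ValidationError("evaluate_metrics needs equal lengths n >= 2")
    mean_a = ya.mean()
    if mean_a == 0:
        raise ValidationError("NRMSE undefined: actuals average to zero")
    sse = float(np.sum((ya - yp) ** 2))
    sst = float(np.sum((ya - mean_a) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    rmse = np.sqrt(sse / n)
    nrmse = rmse / mean_a
    if conventional_rpd:
        spread = np.sqrt(sst / (n - 1))
    else:
        spread = np.sqrt(float(np.sum((ya - yp.mean()) ** 2)) / (n - 1))
    rpd = float("inf") if rmse == 0 else spread / rmse
    return float(r2), float(nrmse), float(rpd)


@dataclass
class EvaluationResult:
    """Averaged and per-repeat metrics for one (features, model, variant) cell."""

    model: str
    R2_train: float
    R2_validate: float
    NRMSE: float
    RPD: float
    per_repeat: pd.DataFrame = field(repr=False, default=None)
    features: str = ""
    preprocess_label: str = ""


def monte_carlo_cv(features: FeatureBlock, target, model_spec="rr",
                   folds: int = 10, repeats: int = 50, seed: int = 0,
                   pooled: bool = False,
                   conventional_rpd: bool = False) -> EvaluationResult:
    """Repeated k-fold CV with a fresh random partition per repeat.

    Repeat r uses ``seed + r`` for its fold shuffle, so results are
    reproducible for a fixed master seed.  Train R^2 is averaged over each
    fold's training fit; validation metrics are averaged per fold by default
    (``pooled=True`` instead pools each repeat's out-of-fold predictions).
    """
    X = features.X
    y = np.asarray(target, dtype=float)
    n = y.size
    if n < folds:
        raise ValidationError("need n >= folds")
    rows = []
    for r in range(repeats):
        model = (make_model(model_spec, random_state=seed + r)
                 if isinstance(model_spec, str) else clone(model_spec))
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed + r)
        tr_r2, va_r2, va_nrmse, va_rpd = [], [], [], []
        pool_pred = np.empty(n)
        for tr, te in kf.split(X):
            m = clone(model).fit(X[tr], y[tr])
            r2t, _, _ = evaluate_metrics(y[tr], np.ravel(m.predict(X[tr])),
                                         conventional_rpd)
            pred = np.ravel(m.predict(X[te]))
            pool_pred[te] = pred
            tr_r2.append(r2t)
            if not pooled:
                r2v, nr, rp = evaluate_metrics(y[te], pred, conventional_rpd)
                va_r2.append(r2v)
                va_nrmse.append(nr)
                va_rpd.append(rp)
        if pooled:
            r2v, nr, rp = evaluate_metrics(y, pool_pred, conventional_rpd)
            va_r2, va_nrmse, va_rpd = [r2v], [nr], [rp]
        rows.append({"repeat": r, "R2_train": float(np.mean(tr_r2)),
                     "R2_validate": float(np.mean(va_r2)),
                     "NRMSE": float(np.mean(va_nrmse)),
                     "RPD": float(np.mean(va_rpd))})
    per = pd.DataFrame(rows)
    name = model_spec if isinstance(model_spec, str) else type(model_spec).__name__
    return EvaluationResult(model=str(name).upper(),
                            R2_train=float(per["R2_train"].mean()),
                            R2_validate=float(per["R2_validate"].mean()),
                            NRMSE=float(per["NRMSE"].mean()),
                            RPD=float(per["RPD"].mean()),
                            per_repeat=per,
                            preprocess_label=features.preprocess_label)


def feature_combinations(menu: Sequence[str]):
    """All non-empty subsets of the feature menu: singles, duals, triple, ..."""
    if not menu:
        raise ValidationError("empty feature menu")
    for size in range(1, len(menu) + 1):
        for combo in combinations(menu, size):
            yield combo


def model_selection_report(blocks_by_variant, y, menu: Sequence[str],
                           models: Sequence[str] = ("rr", "plsr"),
                           folds: int = 10, repeats: int = 50,
                           seed: int = 0) -> pd.DataFrame:
    """Evaluate every feature combination x variant x model.

    ``blocks_by_variant`` maps a preprocessing label to a dict of
    {feature name -> FeatureBlock} extracted under that variant.  Returns one
    row per cell with the four metrics; the best row per feature combination
    (by validation R^2) is flagged.
    """
    rows = []
    for label, blocks in blocks_by_variant.items():
        for combo in feature_combinations([m for m in menu if m in blocks]):
            fused = fuse_features([blocks[name] for name in combo])
            for model in models:
                res = monte_carlo_cv(fused, y, model_spec=model, folds=folds,
                                     repeats=repeats, seed=seed)
                rows.append({"preprocessing": label,
                             "features": " + ".join(combo), "model": res.model,
                             "R2_train": res.R2_train,
                             "R2_validate": res.R2_validate,
                             "NRMSE": res.NRMSE, "RPD": res.RPD})
    df = pd.DataFrame(rows)
    if not df.empty:
        best = df.groupby("features")["R2_validate"].transform("max")
        df["best"] = df["R2_validate"] == best
    return df
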