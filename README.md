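# teanir

Multi-feature near-infrared (NIR) calibration for tea quality indicators:
spectral pretreatment, adaptive Fourier decomposition (AFD) features,
competitive adaptive reweighted sampling (CARS) wavelength selection,
two-band spectral-index search, FFT/CWT comparison features, and fused
ridge / partial-least-squares calibration evaluated by Monte-Carlo repeated
k-fold cross-validation.

## The problem

Wet-chemistry assays of tea constituents (theanine, tea polyphenols,
soluble sugar, water extract; mass-fraction %) are slow and destructive.
Diffuse-reflectance NIR spectra of powdered samples over 4000–10,000 cm⁻¹
carry that composition in overtone/combination vibrational bands, but
buried under scatter, baseline drift and strong band overlap.  A
calibration must therefore combine per-spectrum correction with feature
extraction before regression.  `teanir` implements three complementary
feature views and their fusion:

* **CARS** — iterative wavelength selection: PLS models on Monte-Carlo
  subsamples, exponentially decreasing retention r_i = a·e^(−k·i)
  (r₁ = 1 keeps all p bands, r_N = 2/p keeps two), retention by
  |regression coefficient| (a deterministic top share plus a weighted
  competitive draw), subset chosen at the global RMSECV minimum.
* **BC** — exhaustive two-band spectral indices (SR = Rm/Rn, DSI = Rm−Rn,
  NDSI = (Rm−Rn)/(Rm+Rn), and variants NSR/GDSI/TNDSI), screened by the
  Pearson significance threshold r = t/√(n−2+t²) (0.196 at n = 171,
  p < 0.01).
* **AFD** — greedy expansion of the analytic signal
  f⁺ = (f + iHf + c₀)/2 in a learned Takenaka–Malmquist system,
  pole a_k = argmax |⟨f_k, e_a⟩|² over the unit disc with Szegő kernel
  e_a(z) = √(1−|a|²)/(1−āz); the squared coefficient moduli |d_k|² are the
  features, with the exact energy ledger ‖f_{k+1}‖² = ‖f_k‖² − |d_k|².

Models are ridge regression (RR) and PLSR; quality is reported as
R² (train/validate), NRMSE = RMSE/ȳ, and RPD (ratio of performance to
deviation).  Because no public dataset exists at this scale, the package
ships a seeded synthetic-spectra generator with full ground truth
(`teanir.simulate`), used by every test.

## Worked example

```python
import teanir as tn

bundle = tn.make_benchmark("easy", seed=0)          # 171 samples x 200 bands
ds = tn.align(bundle.spectra, bundle.indicators, "soluble_sugar")
X, y = ds.spectra.reflectance, ds.y

cars = tn.CARSSelector(random_state=0).fit(X, y)
bc   = tn.BandCombinationFeaturizer().fit(X, y)
afd  = tn.AFDFeaturizer().fit(X)

fused = tn.fuse_features([tn.FeatureBlock(cars.transform(X), "CARS"),
                          tn.FeatureBlock(bc.transform(X), "BC"),
                          tn.FeatureBlock(afd.transform(X), "AFD")])
res = tn.monte_carlo_cv(fused, y, "rr", folds=10, repeats=10, seed=0)
```

Printed results:

```
CARS kept 14 of 200 bands; RMSECV 0.0362 (full-band 0.0503)
BC kept 6 index features, best |PCC| 0.793
AFD depth N_AFD = 1
RR  R2_train=0.999  R2_validate=0.999  NRMSE=0.007  RPD=29.261
```

Reading: CARS reduced 200 wavelengths to 14 (containing all five bands the
generator planted) and its cross-validated error beats the full-band PLS
baseline; all six index kinds passed the 0.196 significance screen; the
smooth, DC-dominated benchmark spectra satisfy the 99.5% energy-retention
criterion after a single AFD atom; the fused ridge model explains 99.9% of
held-out variance with an RMSE of 0.7% of the mean — the benchmark is
deliberately high signal-to-noise, so these numbers validate mechanics, not
real-world accuracy (see `docs/methods.md`).

Estimators follow scikit-learn conventions (`fit`/`transform`,
`get_params`, fitted attributes with trailing underscores), so they compose
with `sklearn` pipelines; `teanir.pipeline.build_nested_estimator` builds a
leakage-free pipeline that re-extracts features inside every CV fold.

## Command line

```sh
teanir simulate --profile easy --seed 1 --out bench/
teanir preprocess bench/spectra.csv snv.csv --variant SNV-RAW
teanir bc-screen bench/spectra.csv bench/indicators.csv bc.csv --indicator soluble_sugar
teanir cars bench/spectra.csv bench/indicators.csv bands.csv --seed 7
teanir afd bench/spectra.csv afd.csv --energy-retention 0.995
teanir xfeat bench/spectra.csv fft.csv --method fft
teanir run-all --config pipeline.yaml
```

`run-all` sweeps preprocessing variants × feature combinations × models and
writes per-indicator results tables (columns: indicator, preprocessing,
features, model, R2_train, R2_validate, NRMSE, RPD) plus a resolved config
and a log of seeds, thresholds and selected bands.  Reruns with the same
config and master seed reproduce the CSVs byte-for-byte.

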