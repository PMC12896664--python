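# Methods

`teanir` calibrates continuous quality indicators of tea powder (theanine,
tea polyphenols, soluble sugar, water extract; mass-fraction %) from
diffuse-reflectance near-infrared spectra on a 4000–10,000 cm⁻¹ grid.  The
pipeline has four stages: per-spectrum pretreatment, feature extraction from
three complementary views (selected wavelengths, two-band indices, adaptive
Fourier decomposition energies), feature fusion, and regularized regression
assessed by Monte-Carlo repeated k-fold cross-validation.  This note records
the models, the parameters that matter, the numerical choices, and what the
synthetic benchmarks can and cannot demonstrate.

## Preprocessing

Five per-spectrum corrections (SNV, moving average, Savitzky–Golay
smoothing, MSC, polynomial detrending) optionally followed by a
Savitzky–Golay first or second derivative give the 18-variant grid
`{RAW, SNV, MA, SG, MSC, DT} × {RAW, FD, SD}` (suffix `RAW` = no
derivative).  The base correction is always applied before the derivative.

Unstated constants are package choices, surfaced in `PreprocessVariant`:
MA window 5; SG smoothing window 11, polyorder 2; detrend degree 2 (offset,
tilt and curvature); derivatives by Savitzky–Golay (window 11, polyorder 2
for FD, 3 for SD) rather than naive differencing, because local
least-squares differentiation bounds noise amplification.  Derivatives are
taken with respect to the wavenumber axis (units: reflectance per cm⁻¹).
Detrending fits an orthonormalized polynomial basis, making it an exact
projection (idempotent to machine precision).

## Band-combination (BC) indices

Six two-band index families are searched exhaustively over ordered band
pairs (m, n), excluding the degenerate diagonal m = n:

| kind | formula |
|------|---------|
| SR   | Rm/Rn |
| NSR  | (Rm/Rn − 1)/(Rm/Rn + 1) |
| DSI  | Rm − Rn |
| NDSI | (Rm − Rn)/(Rm + Rn) |
| GDSI | (Rm² − Rn)/(Rm² + Rn) |
| TNDSI| (Rm − Rn)/(Rm + Rn) + 0.5 |

NSR and NDSI are algebraically identical on positive spectra; both are kept
because derivative-preprocessed spectra can be negative, where they differ.
TNDSI is implemented exactly as the additive form above; the conventional
`sqrt(NDSI + 0.5)` variant is available behind `tndsi_sqrt=True`.  GDSI
deliberately mixes Rm² with Rn and no unit normalization is applied.

For each kind the pair maximizing |Pearson r| with the indicator wins; ties
break to the lower band m, then the lower band n.  Pairs with more than 5%
non-finite values (zero denominators) are excluded; remaining non-finite
entries drop those samples pairwise from the correlation.  A winner is kept
only if |r| reaches the two-sided Student-t critical value
r = t/√(n−2+t²) at level α = 0.01 (r = 0.196 at n = 171).  The search is
chunked along the m axis, bounding memory at O(chunk × n_bands × n_samples).

## Adaptive Fourier decomposition (AFD)

A real spectrum sampled on N uniform points is lifted to the boundary values
of its Hardy-space part, f⁺ = (f + iHf + c₀)/2 (discrete analytic signal;
2·Re f⁺ − c₀ returns the input exactly).  Rows are not centered: the mean
coefficient c₀ is part of the signal and typically dominates reflectance
spectra.

AFD greedily expands f⁺ in a learned Takenaka–Malmquist system.  At level k
the pole a_k inside the unit disc maximizes |⟨f_k, e_a⟩|² (maximal selection
principle), with e_a(z) = √(1−|a|²)/(1−āz) the normalized Szegő kernel; the
coefficient is d_k = ⟨f_k, e_{a_k}⟩ and the residual is updated through the
unimodular Möbius factor (z−a_k)/(1−ā_k z), giving the exact ledger
‖f_{k+1}‖² = ‖f_k‖² − |d_k|².  Squared coefficient moduli |d_k|² are the
features.

Numerical choices:

* **Quadrature.** Inner products are uniform-grid sums (1/N)Σ u·conj(v).
  Under this quadrature the Szegő kernel's norm is not 1 but
  (1−r^{2N})/|1−a^N|² (closed form); the decomposition divides each atom by
  this discrete norm so the energy ledger is exact at every radius, not just
  far from the boundary.
* **Pole grid.** Radii {0, 0.02, …, 0.98} × phases equal to the signal grid.
  With grid phases, all inner products at one radius follow from a single
  inverse FFT via ⟨f, e_a⟩ = √(1−r²)/(1−aᴺ)·Σ_m c_m aᵐ — an exact discrete
  identity, so the fast path matches direct kernel evaluation to rounding
  error.  Arbitrary phase grids fall back to direct evaluation.
* **Ties** break to the smallest radius, then the smallest phase
  (radius-major candidate ordering); the decomposition is fully
  deterministic and scaling-equivariant (c·f ↦ c·d_k, same poles).
* **Stopping.** The depth criterion is retained energy: stop once
  1 − ‖reconstruction‖²/‖f⁺‖² ≤ 1 − `energy_retention` (default 0.995), with
  a `max_level` safety bound of 50.  The relative energy error
  REE = ‖f⁺ − Σd_kB_k‖/‖f⁺‖ is recorded per level and is non-increasing.
* **Common depth.** Datasets are decomposed in two passes: pass one finds
  each sample's depth at the retention threshold; the maximum becomes the
  fixed depth N_AFD of pass two, so all samples yield N_AFD features.  On
  smooth reflectance spectra the DC-dominated first atom often retains
  99.5% energy by itself, so N_AFD can legitimately be small on easy data.
* **Orthonormality caveat.** The learned Blaschke system is orthonormal
  under the *continuous* inner product; grid quadrature adds an aliasing
  error of order r^{2N}.  With the default radius cap 0.98 this is
  negligible for N ≳ 500 but visible for short signals with near-boundary
  poles.  The reconstruction/REE identities are exact regardless (they
  telescope from the residual recursion).

## CARS wavelength selection

Competitive adaptive reweighted sampling runs N = 50 rounds.  Round i fits a
PLS model on a Monte-Carlo subsample (80% of rows) of the currently retained
bands and retains exactly round(r_i·p) bands, where the exponentially
decreasing schedule r_i = a·e^{−k·i} is fixed by r_1 = 1 (all p bands) and
r_N = 2/p (two bands).  Retention combines both CARS mechanisms at the
scheduled count: the top half by |PLS coefficient| is kept deterministically
(forced removal), and the remaining slots are filled by a weighted draw
without replacement among the other candidates with probability ∝
|coefficient| (adaptive competition).  The draw is without replacement so
the retained count honors the schedule exactly — in particular round 1
retains the full band set, which makes the full-band model the first
candidate and guarantees the selected subset never scores worse than it.

Each round's subset is scored by RMSECV: cross-validated PLS RMSE (5
unshuffled folds, fixed assignment) with the component count (≤ 10) chosen
by the same CV.  The subset minimizing RMSECV over all rounds is selected.
On sparse-signal data the RMSECV trace characteristically falls while noise
bands are eliminated and rises sharply once informative bands starve.
Everything is driven by one integer seed.

## Calibration models and metrics

Fused feature blocks are column-concatenated and standardized (constant
columns dropped with a warning).  Two calibrators:

* **Ridge** on standardized predictors with unpenalized intercept; penalty
  chosen by inner 5-fold CV over 13 log-spaced values 10⁻⁶…10³.
* **PLSR** with the component count (1…min(20, rank)) chosen by inner
  5-fold CV.

Metrics, for actuals y_a and predictions y_p:

* R² = 1 − Σ(y_a−y_p)²/Σ(y_a−ȳ_a)²
* NRMSE = RMSE / mean(y_a)
* RPD = √(Σ(y_a−ȳ_p)²/(n−1)) / RMSE, i.e. the spread of the *actuals
  around the mean of the predictions* over the RMSE.  This departs from the
  textbook sd(y_a)/RMSE; the conventional form is available via
  `conventional_rpd=True`.  When ȳ_p = ȳ_a the two coincide and
  RPD = √(n/(n−1))/√(1−R²) exactly — checked numerically in the tests.

Assessment is Monte-Carlo repeated k-fold CV: default 10 folds × 50 repeats
(the test suite and acceptance script use 10 repeats to keep runtimes in
minutes; averages stabilize well before that, and a test asserts doubling
repeats moves mean validation R² by < 0.02).  Repeat r shuffles folds with
seed `master + r`.  Scaling and hyperparameter selection are refit inside
every training fold; a sentinel test demonstrates the optimism incurred by
instead fitting the supervised band-pair selector on the full data.

Supervised feature extraction (CARS, BC screening) by default runs once on
the full dataset before CV — the global protocol matching how such band
tables are usually reported — with a nested mode (`build_nested_estimator`)
that re-extracts features inside each training fold for leakage-free error
estimates.  Both protocols are exposed; the results tables use the global
one unless asked otherwise.

## Synthetic data

No public tea dataset exists at this scale, so the generator fabricates
NIR-like data with known ground truth:

* correlated log-normal component concentrations (4×4 correlation with 0.3
  off-diagonals; CV 0.25),
* pure-component absorbance spectra as sums of Gaussian bands plus a shared
  smooth background (the dominant common shape; pairwise sample
  correlations > 0.9 as in real powder spectra),
* reflectance = exp(−absorbance), keeping values positive so ratio indices
  are safe on raw spectra,
* per-sample log-normal multiplicative scatter, additive offset, random
  quadratic baseline, white noise,
* indicators affine in the concentrations plus measurement noise, centered
  on realistic levels (theanine ≈ 2%, polyphenols ≈ 18%, soluble sugar ≈
  5%, water extract ≈ 38%),
* optional indicator outliers placed a set number of IQRs beyond the Tukey
  fences.

Because indicators are affine in absorbance, ridge on −log(reflectance) of
noiseless, scatter-free data reproduces them to numerical precision — the
generator's internal consistency check.

Two shipped profiles:

* **easy** (n = 171, 200 bands): a smooth correlated background carrying no
  target signal plus five single-band reflectance perturbations driven by
  latent factors; all indicators are affine in those latents at high
  signal-to-noise.  The five informative wavelengths are recorded in the
  ground truth, making wavelength-selection recovery exactly checkable.
* **hard** (n = 171, 300 bands): heavy log-normal scatter (σ = 0.7), offsets
  and quadratic baselines.  Raw-spectrum calibration degrades measurably and
  SNV recovers most of it; MSC can fail under strong random curvature
  (near-zero regression slopes), which is faithful to its known fragility.

What passing tests show — and do not.  The benchmarks exercise every code
path with known truth, but their signal structure is simpler than real tea
spectra: five literally informative bands (real constituents spread
information over broad correlated regions), affine indicator maps, and
Gaussian noise.  Absolute metric values on the benchmarks (validation R²
near 0.97 on "easy") therefore say nothing about attainable accuracy on
real data; they validate mechanics, determinism and the relative ordering
of methods, not field performance.

## Problem sizes used in shipped runs

Test and acceptance runs use the easy benchmark (171 × 200), 20 selection
seeds for the CARS recovery statistics, 5 master seeds × 10-fold × 10
repeats for the fused-model quality, and 64- or 1024-point signals for the
AFD oracles (the long grid keeps the quadrature aliasing term, of order
r^{2N}, far below the orthonormality tolerance).  All sizes are
configuration values, not limits of the implementation.

## Known limitations

* Vendor spectrometer formats (SPC/OPUS), absorbance↔reflectance unit
  conversion, and instrument transfer are out of scope; I/O is plain CSV.
* The exhaustive pair search is O(n_bands²) per index kind and variant;
  at 1500 bands × 18 variants it is minutes, not seconds.
* AFD feature depth collapses to 1 when a single atom retains 99.5% energy;
  lower `energy_retention` or detrend/derivative preprocessing yields
  deeper, more informative decompositions.
* The nested (fold-internal) extraction protocol multiplies CARS cost by
  folds × repeats; use reduced `cars_iterations` there.
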