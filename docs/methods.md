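# Methods

## The problem

Quantifying several analytes from a single UV-VIS absorbance spectrum fails
with univariate calibration when the analytes' bands overlap.  Multivariate
calibration — here partial least squares (PLS) regression of concentrations
on full or selected spectra — resolves the overlap, but a single *global*
model fitted to every calibration sample is biased whenever the data are
heterogeneous (composition groups) or nonlinear (detector saturation at high
absorbance).  This package implements a *local* strategy: for every unknown
spectrum it assembles a fresh calibration subset of the most similar
calibration spectra, optionally selects informative wavelengths, and fits a
dedicated PLS model.

## The pipeline, stage by stage

**Smoothing.**  Savitzky-Golay least-squares polynomial smoothing (degree 2,
21-point window on a 1-nm grid by default).  Interior points use the standard
central convolution; the first/last 10 points are fitted on the truncated
one-sided window, which preserves the output length, reproduces polynomials
up to the fit degree exactly at every point, and keeps the operator linear.

**Similarity: the synthetic degree of grey relational coefficient (S-GRC).**
For a query spectrum x_q and calibration spectrum x_j,

    rho(q, j) = theta * eps_qj + (1 - theta) * gamma_qj,      theta = 0.2

* the *absolute degree* eps compares trapezoid-style sequence sums
  s = sum(x[1..n-1]) + 0.5 x[n] of the two raw spectra:
  eps = (1 + |s_q| + |s_j|) / (1 + |s_q| + |s_j| + |s_q - s_j|);
* the *relative degree* gamma compares, per wavelength k, the deviation
  Delta_j(k) = |x_j(k) - x_q(k)| against the minimum and maximum deviation
  over the whole calibration ensemble:
  gamma(k) = (min_l Delta_l + xi * max_l Delta_l) / (Delta_j + xi * max_l Delta_l),
  averaged over k, with xi = 0.5 and the 0/0 case defined as 1 (the limit
  when all deviations vanish).

rho lies in (0, 1], equals 1 for an identical calibration row, weights the
geometric (shape) agreement four-to-one over magnitude agreement, and is not
symmetric (gamma depends on the ensemble).  Classical grey relational
analysis shifts every sequence to start at zero before the absolute-degree
sums; the raw-sum form is the native definition here and the shift is
available behind `GRCParams.zero_start`.  Comparator criteria (Euclidean,
PCA-score Mahalanobis with 2 components, spectral angle) use their textbook
definitions.

**Subset sizing.**  Candidate sizes N run from `sweep_start` (default 3) to
the calibration size; the top-N samples of the similarity ranking are scored
by leave-one-out RMSECV of a full-spectrum PLS model, and the N with the
smallest RMSECV wins (ties to the smaller N).  Three numerical choices
matter:

* the factor count inside the sweep is selected once per subset from the
  pooled LOO PRESS trace (first-upturn rule below) rather than per fold; the
  nested per-fold variant is available (`factor_rule="per_fold"`) but costs
  O(N^2) PLS fits per candidate size instead of O(N);
* the factor count is capped at half the training-fold size,
  kmax = min(kmax_config, (N-2)//2).  Without this cap a subset of 6-8
  mutually similar spectra can be scored by a model with nearly as many
  factors as samples; its LOO error then measures interpolation inside the
  cluster and small, degenerate subsets win the sweep spuriously.  With the
  cap, RMSECV curves take the decrease-then-increase-then-plateau shape the
  method expects;
* `select_before_sizing` makes the sweep score each candidate subset on its
  own SIMPLISMA-selected wavelengths rather than on full spectra, so the
  chosen size is consistent with the model that will actually predict the
  query.  Sizing blind to the wavelength restriction can pick small subsets
  whose few selected channels are mostly background, with large prediction
  errors the RMSECV never saw.  The default keeps the classical order
  (sizing first on full spectra); the comparison benchmark enables the
  selection-aware variant.

**Wavelength selection: SIMPLISMA.**  On the chosen subset matrix, each
wavelength i is scored by the purity sigma_i / (mu_i + alpha) where alpha is
a noise offset (a percentage of the largest column mean, 1% by default, up
to 5% for noisier data).  After each pick, a determinant weight built on the
correlation-around-the-origin matrix C = (1/m) D_s^T D_s (columns of D
scaled by lambda_i = sqrt(mu_i^2 + (sigma_i + alpha)^2)) annihilates
everything correlated with the already-selected wavelengths; the weight is a
Gram determinant, hence non-negative, and exactly zero at selected indices.
Selection stops when the *relative total intensity* Rs_{j+1} of the next
standard-deviation spectrum (Rs_1 = 1 by normalisation) drops below the
threshold tau (default 2e-5) — the next spectrum then carries essentially
none of the initial intensity, the determining coefficient
R_j = Rs_j / Rs_{j+1} spikes, and J = j wavelengths are kept — or when a
cap (min(m-1, n, 30) by default) is reached.  Thresholding Rs_{j+1} itself,
rather than the step-to-step ratio, is what makes the stop robust: on
subsets of differing rank the per-step decay ratio varies by orders of
magnitude, while the absolute Rs level cleanly separates chemical
components (Rs well above tau) from the noise tail.

**Regression and factor choice.**  The PLS2 core extracts factors
sequentially from mean-centered blocks; each factor's X-weight is the
dominant left singular vector of X_d^T Y_d, obtained from the q x q
eigenproblem of S^T S — iteration-free, deterministic (sign fixed by the
largest-magnitude loading), and equivalent to converged NIPALS.  Both blocks
are deflated by the extracted score, and predictions for all factor counts
1..kmax come from a single pass, which the LOO loops exploit.  The factor
count follows the first-upturn PRESS rule: the smallest k-1 with
PRESS_k / PRESS_{k-1} > 1 (a zero PRESS also stops growth); if the trace
never turns up, the deepest count is used.  All q analytes share one model
(PLS2); PRESS and RMSECV pool squared residuals over analytes, matching the
single subset size reported per query.

**Error metrics.**  RMSEP per analyte over a held-out prediction set;
RMSECV as the root mean squared held-out residual of the LOO procedure,
pooled over analytes.

## The synthetic data generator

No measured spectra ship with the package, so a generator reproduces the
statistical structure the method assumes, on a 407-605 nm grid (1-nm default
step):

* **four components** with Gaussian bands: two nearly coincident "red" bands
  (521/18 nm and 528/24 nm) emulating a strongly overlapping dye pair, an
  isolated narrow blue band (427/16 nm), and a broad band (482/30 nm plus a
  small 430-nm shoulder) overlapping everything.  Peak absorptivities put a
  single component at 200 ug/mL at A ~ 1.0-1.2, inside a real instrument's
  range.  The shapes are synthetic, not digitized from any instrument;
* **grouped mixture design** on a 10-ug/mL concentration grid: ~30%
  single-component samples (20-200 ug/mL), ~40% two-component samples
  restricted to the overlapping pair or the remaining pair, ~30%
  four-component samples confined to 30-110 ug/mL per analyte (a dilution
  volume budget caps how concentrated four simultaneous stocks can be).
  A fixed coverage block guarantees every analyte attains 0 and 200 ug/mL
  inside the calibration set.  97 samples split 70 calibration /
  27 prediction by default;
* **instrument effects**: white photometric noise (sd 0.0016 A — a 10-scan
  average of ~0.005 A single-scan noise), a per-sample baseline offset
  (sd 0.001 A), a smooth per-scan background tilt across the range
  (sd 0.0015 A) representing the background variations wavelength selection
  exists to reject, and per-sample wavelength registration jitter
  (sd 0.05 nm) of a scanning monochromator.  The latter two give smoothed
  spectra an effective rank above the chemical rank, as real scans have;
* **saturation** (optional): A_obs = A_max (1 - exp(-A / A_max)), a smooth
  compressive map bounded by A_max, mimicking detector/stray-light
  nonlinearity at strong bands.

A non-negative least-squares fit against the generator's true pure spectra
(`oracle_predict`) is the noise-floor reference in the linear regime; under
saturation it is biased by construction and only serves as a scale.

What the generator does **not** emulate: real band shapes and their pH or
temperature dependence, scatter, stray light with wavelength structure,
correlated (pink) photometric noise, or operator pipetting error in the
reference concentrations.  Passing tests therefore show the pipeline behaves
as designed under the assumed structure, not that it will match any
particular instrument's error budget.

## Benchmark problem sizes and findings

The multi-seed comparison study (local S-GRC + SIMPLISMA vs global
full-spectrum PLS under saturation, A_max = 1.5) runs the full default
conditions — 70/27 design, 407-605 nm at 1 nm, Savitzky-Golay degree 2 /
window 21, SIMPLISMA alpha 1% / tau 2e-5 — with two desk-scale economies:
the subset sweep starts at 5 samples (one of the three canonical start
sizes) and advances in steps of 3, and sizing is selection-aware (above).
A 20-replicate study then takes about two minutes on one CPU.

Across 20 replicates the local pipeline more than halves the global model's
error for the analytes whose bands are strongly overlapped and deeply
saturated (where the global model is bias-limited), and matches it within
the run-to-run spread for the analytes whose global model already sits near
its variance floor; for those, the wavelength restriction costs about as
much variance as the bias it removes.  Without wavelength selection the
local strategy is at or below the global error for every analyte.  The
exact numbers for any seed come from `scripts/acceptance.py`.

## Degenerate inputs and numerical conventions

* 0-based indices internally; user-facing output reports wavelengths in nm.
* Purity/argmax and ranking ties break toward the lowest index;
  RMSECV ties toward the smaller subset size (parsimony).
* A singular PCA-score covariance in the Mahalanobis criterion receives a
  ridge of 1e-10 tr(COV)/k with a warning.
* Subsets with constant concentrations are skipped in the sweep (logged);
  an all-constant spectral matrix raises `NoInformativeVariableError`.
* Rank-deficient PLS fits warn and truncate to the extractable factors; a
  fit with no extractable covariance predicts the training mean.
* The quadratic form of the Mahalanobis distance and the n x n orientation
  of the correlation matrix follow dimensional necessity.

## Known limitations

* The per-query sweep re-ranks and re-validates from scratch; prediction is
  O(m_c^2) PLS fits per query with the pooled rule.
* With very small chosen subsets (N near the sweep start), SIMPLISMA can
  select at most ~N wavelengths (the correlation matrix has rank <= m), so
  weakly distinguishable analytes may be under-resolved; the factor cap in
  the sweep mitigates but does not remove this.
* The stop threshold tau does not adapt to the data's noise floor
  automatically; it is exposed per run.
* Concentrations are not constrained to be non-negative at prediction time.
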