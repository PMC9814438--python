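# Methods

## Model and decision rule

An agreement table cross-classifies two raters' assignments of the same
`n` subjects into `R` ordered levels. The package treats a grey zone as a
*rater* attribute: a systematic perception difference between two adjacent
levels that inflates one off-diagonal cell `(i, j)` with `|i − j| = 1`
while the mirrored cell `(j, i)` stays put. Two ingredients quantify this:

1. **Deviation from symmetry.** The symmetry model (`p_ij = p_ji`) is the
   no-grey-zone reference. Its ML expectations are
   `mu_ij = (n_ij + n_ji)/2`; standardized residuals
   `r_ij = (n_ij − mu_ij)/sqrt(mu_ij)` are antisymmetric with zero
   diagonal. A residual is set to 0 only when `mu_ij = 0`, i.e. when both
   paired cells are empty. (A cell with `n_ij = 0` but `n_ji > 0` has a
   well-defined negative residual; zeroing it would break antisymmetry and
   contradicts the reference residual tables this implementation
   reproduces.)
2. **Level of agreement.** Unweighted Cohen's kappa
   (`w_ij = 1` iff `i = j`). Weighted variants exist in the package but the
   criterion deliberately uses the identity-weight form: the point is to
   contrast diagonal agreement with adjacent disagreement, not to award
   partial credit.

The criterion is `delta_ij = r_ij / kappa` and `Delta = max delta_ij`
(equal to `max |delta_ij|` by antisymmetry). `Delta` is compared with the
threshold

    tau(kappa, n) = (−0.0080 + 0.4090 kappa² + 3.331e−5 n − 2.467e−8 n²)^(−0.6266)

`Delta > tau` declares a grey zone at the argmax cell; ties are all
reported in row-major order. Secondary grey zones (other cells with
`delta > tau`) are searched only after a positive primary decision. For
cell `(i, j)` with `i > j` Rater I rates higher; with `i < j`, Rater II.

Kappa ≤ 0 aborts the analysis (no meaningful agreement to scale by);
kappa in (0, 0.2) computes with a loud warning — grey zones are
substantively implausible at such low agreement and the threshold is
uncalibrated there. The threshold's calibration envelope is
`n ∈ [50, 1000]`, `kappa ∈ [0.2, 0.85]`; outside it the package warns
rather than fails, and raises only when the back-transform base becomes
non-positive.

### Two parameterizations of the default threshold

`DEFAULT_THRESHOLD_MODEL` evaluates the published rounded constants shown
above (every worked reference value uses them). `CHAIN_THRESHOLD_MODEL`
evaluates the same regression through the exact Box–Cox chain
`tau = (pred·λ + 1)^(1/λ)` with λ = −1.59596 and transformed-scale
coefficients (0.6319, −0.2563, −2.087e−5, 1.546e−8). The two differ by up
to ~0.01 in `tau` on the envelope because the rounded constants are not
exactly the algebraic image of the rounded coefficients (the constant
term's published value is not reachable by rounding from the published
β₀). Reports record which parameterization produced `tau`.

### Threshold and table size

One threshold is used for all `R`. The calibration machinery defaults to
`R = 3` (configurable); the numerical validation covers `R = 3, 4`. For
`R > 4` the ordinal scale starts behaving like a continuous one and the
grey-zone concept itself weakens, so no `R`-specific thresholds are
provided — a known limitation, not an oversight.

## Weighted coefficients

All three coefficients share the form `(P_o − P_e)/(1 − P_e)` with
`P_o = Σ w_ij p_ij`; chance terms: Cohen `Σ w_ij p_i. p_.j`; Gwet AC2
`[T_w/(R(R−1))] Σ π_k(1−π_k)` with `π_k = (p_k. + p_.k)/2`,
`T_w = Σ w_ij`; Brennan–Prediger `T_w/R²`. Weights index 1..R ordinal
positions, never label values. An all-ones weight matrix is rejected by
construction of the schemes: it would force `P_o = 1` and make every
coefficient degenerate.

## Synthetic-data generator

Tables without a grey zone are drawn by categorizing a standard bivariate
normal pair with correlation ρ at shared strictly increasing cutpoints;
the cell grid is computed exactly from the bivariate normal CDF and a
table is one multinomial draw of size `n`. Defaults:

- **Cutpoints**: equal-marginal-probability quantiles `Φ⁻¹(k/R)`. This
  choice reproduces the reference calibration's median-kappa-versus-ρ
  relationship to ±0.01 across ρ ∈ [0.45, 0.90] for R = 3, so it is kept
  as the study condition. `calibrate_rho` inverts the plug-in kappa of the
  analytic grid when a scenario is specified by target kappa instead of ρ.
- **Grid sizes** mirror the reference design: calibration over
  ρ ∈ {0.45, 0.50, …, 0.90} × n ∈ {50, 100, 200, 300, 400, 500, 1000}
  with 1000 replicates per cell; accuracy scenarios at moderate to
  near-perfect agreement (kappa ≈ 0.63/0.75/0.83) for
  n ∈ {50, 100, 250, 500, 1000}, R ∈ {3, 4}, grey zone at each
  diagonal-adjacent cell.

What the generator emulates: a shared ordinal perception continuum with
controllable true agreement, symmetric in the raters. What it does not:
rater-specific marginal shifts (systematic bias), heterogeneous subjects,
or missing ratings — so green simulation tests demonstrate calibration
under the idealized no-grey-zone null, not robustness to those features
of real data.

**Grey-zone injection.** A fraction `f` of the probability mass of a
diagonal donor cell is moved into the adjacent grey-zone cell; the donor
is the diagonal cell of the lower of the two levels (`(j, j)` for cell
`(i, j)` with `j < i`), matching the observed pattern that the inflated
cell sits beside its diagonal source; the donor is overridable. Moving
diagonal mass off-diagonal lowers plug-in kappa monotonically, so `f` is
found by root-finding to match a target kappa. In the accuracy study the
grey-zone arm starts from a boosted grid at `ρ' = ρ + 0.5(1 − ρ)` and is
injected back down to the clean arm's plug-in kappa: both arms then share
the same agreement level and differ only in the grey zone. The boost
factor 0.5 is a design choice — large enough to leave room for a
substantive injection at every studied ρ, small enough that the injected
mass stays realistic (a few percent of subjects).

**Accuracy metrics.** Sensitivity `TP/(TP+FN)`, specificity `TN/(TN+FP)`
(identical to the fixed-denominator forms under the balanced design), and
MCC; an MCC with a zero margin is reported as 0 with an `mcc_undefined`
flag. Replicates with kappa ≤ 0, or with the threshold outside its
domain, count as negative decisions — consistent with the detector's
refusal semantics. One master seed spawns independent per-scenario
substreams, so any scenario is reproducible in isolation.

The Monte-Carlo loops compute kappa and Delta with vectorized array
operations rather than per-table objects; a test pins the vectorized
decisions to the single-table `detect_grey_zones` path.

## Recalibration

`calibration_grid` collects per-(ρ, n) medians of kappa and Delta over
no-grey-zone replicates (medians, not means: the Delta distribution has a
heavy right tail driven by replicates with near-zero kappa, and the
median's influence function is bounded). Replicates with kappa ≤ 0 are
excluded from Delta summaries and counted; grid cells with non-positive
median Delta are dropped and logged. The Box–Cox power is estimated by
profile likelihood (bounded search on [−5, 5], tolerance 1e−6), then the
transformed medians are regressed on `(1, kappa², n, n²)` by OLS — the
model is linear in its parameters, so "nonlinear" refers only to the
back-transformed threshold surface. λ and β are estimated sequentially,
not jointly. An optional exhaustive search over the 2⁴ intercept-bearing
submodels of {kappa, kappa², n, n²} ranks alternatives by adjusted R²;
the default fits the fixed quadratic form. Percentiles use numpy's
linear-interpolation convention.

**Known discrepancy.** A faithful median-based recalibration with this
generator lands systematically *below* the published threshold surface
(by roughly a factor 2–3.5 in Delta terms), with adjusted R² ≈ 0.90
rather than ≈ 0.99, stable across master seeds. Conversely the published
constants sit near the ~95th percentile of this generator's no-grey-zone
Delta distribution — which is exactly what makes the detector's observed
specificity high (≈ 0.98 at ρ = 0.98, n = 1000, R = 3, matching the
reference accuracy results): a threshold at the null *median* could never
achieve specificity above ~0.5. The package therefore ships the published
constants as the default decision threshold (they are the ones validated
by the accuracy study and used in every worked analysis) and documents
that a regenerated median-based surface is not expected to reproduce
them; users recalibrating with `fit_threshold_model` should treat the
refit as a research tool, not a drop-in replacement.

## Numerical choices and degenerate inputs

- Residual antisymmetry is enforced exactly (`(r − rᵀ)/2`) against
  floating-point fuzz; diagonal residuals are stored as exact zeros.
- Bivariate rectangle probabilities come from CDF inclusion–exclusion,
  clipped at 0 and renormalized; accuracy is ~1e−8, verified at 1e−6
  against direct 2-D quadrature.
- Injection root-finding uses Brent's method at xtol 1e−12 on the moved
  fraction; conservation of total probability is asserted at 1e−12.
- Degenerate tables: all mass in one cell → undefined coefficient error;
  exactly symmetric tables → Delta = 0, every off-diagonal cell reported
  as a tied argmax, decision "no asymmetry".
- Long-format input aggregates duplicate (rater1, rater2) rows by
  summation; level order is sorted labels (numeric sort when all labels
  parse as numbers) unless an explicit order is supplied. Unused levels
  keep their place: `R` comes from the declared scale, not observed
  support.

## Problem sizes in the shipped tests

The test suite regenerates the reference distributions at the full
calibration grid (70 cells × 1000 replicates, five master seeds) and runs
the 10,000-replicate specificity check; both complete in seconds thanks to
the vectorized Monte-Carlo path, and the whole suite runs in well under a
minute.

## Limitations

- Two raters only; nominal scales, >2 raters, and missing data are out of
  scope.
- No standard errors or hypothesis-test p-values for Delta; the decision
  is a threshold comparison, not a test with a stated size.
- The threshold is R-free and calibrated on 3×3/4×4 tables for
  n ∈ [50, 1000]; small samples (n < 50) with near-perfect agreement give
  the detector little to work with (few off-diagonal counts), so
  sensitivity degrades there.
- Underestimation of the transformed response at n = 50 grid cells is
  retained in the fit (no robust down-weighting), mirroring the reference
  derivation.
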