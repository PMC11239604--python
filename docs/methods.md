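# Methods

## Model and assumptions

`hierpower` computes power for intervention effects in balanced four-level
trials: participants nested in providers, providers in clinics, clinics in
hospitals, with hospitals the independent sampling units (ISUs). The
data-generating model is Gaussian with additive random effects,

y_ijkl = μ_cell + h_i + c_ij + p_ijk + e_ijkl,

where the components are independent, mean zero, with variances
ρ_h σ², ρ_c σ², ρ_p σ² and ρ_e σ² = (1 − ρ_h − ρ_c − ρ_p) σ². The ICCs are
therefore *additive up the hierarchy*: two participants who share a provider
(and hence its clinic and hospital) correlate at ρ_p + ρ_c + ρ_h; a
same-clinic pair at ρ_c + ρ_h; a same-hospital pair at ρ_h. With m outcomes,
every component carries the same m×m outcome covariance Σ, giving the
within-ISU covariance V ⊗ Σ (cluster structure ⊗ outcome structure). The
package assumes: equal cluster sizes at every level, no missing data, no
covariates, no repeated predictor measurements, ICCs constant across arms
and subgroups. Unequal cluster sizes and more (or fewer) than three
clustering levels are out of scope; the API names the three ICCs explicitly.

## Power-equivalent reduction

The planned analysis is the mixed-model Wald test with Kenward–Roger
denominator df. Under the balance assumptions above, that test's power is
exactly the power of a general linear hypothesis H₀: C B U = Θ₀ on a reduced
multivariate linear model whose rows are independent ISU summaries. The
Kenward–Roger machinery is therefore never computed — the reduction *is* the
computational strategy, not an approximation. The reductions are:

* **Hospital-level randomization.** Row i = ISU grand mean vector
  (p = m, or 1 after composite weighting); cell-means design with two cells
  of N/2; Σ* = v̄·Σ with v̄ = σ²(ρ_h + ρ_c/C + ρ_p/CP + ρ_e/CPS);
  C = (1, −1), U = I (or 1); error df ν = N − 2.
* **Within-ISU randomization** (clinic/provider/participant level, arms
  split equally inside the immediate parent). Row i = the pair
  (intervention-arm mean, control-arm mean) per outcome (p = 2m or 2);
  one-cell design (rank 1, ν = N − 1); Σ* = M ⊗ Σ where M is the 2×2
  arm-mean moment matrix from shared-component counting; the arm difference
  lives in U, which cancels every component both arms share — the hospital
  component always, plus clinic (provider-level randomization) and provider
  (participant-level) components.
* **Subgroup analysis** (composite outcome, hospital-level randomization,
  two subgroups). Pooled: four cells (arm × subgroup), rank 4, ν = N − 4,
  C = ½(1, −1, 1, −1) for the intervention effect averaged over subgroups.
  The interaction parameter is in the model but zero in the population B —
  charging its df is deliberately conservative. Stratified: one two-cell
  model per stratum with N/2 ISUs, ν = N/2 − 2.

All reduced designs use cell-means coding; hypotheses are carried entirely
by C and U, which avoids any ambiguity about dummy-coding conventions.

Two implementations of every ISU-level variance exist on purpose: a
counting evaluator (sums of squared coefficient totals per cluster,
scalable to any balanced design) and brute-force quadratic forms on the
materialized V ⊗ Σ (small designs only). Their agreement to 1e-12 relative
error is a tested invariant; large-design covariances are never materialized
in the computational path.

## Power computation

Noncentrality: Ω = (CBU − Θ₀)′[C(X′X)⁻¹C′]⁻¹(CBU − Θ₀)(U′Σ*U)⁻¹, λ = tr Ω,
invariant to nonsingular rescaling of C's rows and U's columns. Power is the
noncentral-F tail P[F′(ab, ν₂; λ) > F_crit(α)], evaluated with
`scipy.special.ncfdtr` (absolute accuracy well below the 1e-10 we require).
The denominator df:

* b = 1 (univariate response after contrast): ν₂ = ν — exact;
* a = 1, b > 1 (Hotelling T²): ν₂ = ν − b + 1 — exact;
* a > 1 and b > 1: McKeon's ν₂ = 4 + (ab + 2)g with
  g = [ν² − ν(2b+3) + b(b+3)] / [ν(a+b+1) − (a + 2b + b² − 1)]. This
  formula reduces algebraically to ν − b + 1 at a = 1 (verified in tests),
  so the two code paths agree to 1e-10 whenever both are legal. Results
  with min(a, b) > 1 are flagged `approximate`; no default scenario needs
  them.

Power equals α exactly at λ = 0 and increases strictly in λ, so every curve
respects the α floor and is monotone in the effect size for one-outcome
alternatives. Curves are sampled on an evenly spaced grid [0, δ_max] with
δ_max = 1.0 by default (1.0 = one SD of a single outcome) and 100 points,
enough to draw the underlying smooth function faithfully.

## Default (reference) configuration

20 hospitals × 8 clinics × 6 providers × 6 participants (5,760
participants); ICCs ρ_p = 0.05, ρ_c = 0.01, ρ_h = 0.01; σ² = 1; m = 8
outcomes, independent with unit variance (an unstructured Σ is supported
everywhere); unweighted composite = mean of the eight outcomes
(w′Σw = 1/8); the intervention shifts exactly one outcome; α = 0.05;
10 rural + 10 urban hospitals for the subgroup question; equal allocation
at every randomized level. These are the study conditions the package
emulates, not tuning knobs. Under them the key intermediate values are
v̄ = 0.01552083 (ISU-mean variance), 0.00194010 on the composite scale, and
λ = 40.27 δ² for the hospital-level composite test.

## Simulator and what passing tests show

`simulate_trial` realizes the additive-effects model at full resolution
(fixed draw order hospital → clinic → provider → residual, one seed stream,
so replicate r is identical whichever scenario consumes it); `analyze_trial`
applies the aligned cluster-mean test (two-sample t or Hotelling T² on ISU
means, one-sample t/T² on within-ISU arm differences, four-cell contrast F),
which under balance equals the mixed-model Wald decision. `empirical_power`
vectorizes replicates by drawing the sufficient cluster statistics — full
hospital/clinic/provider effects plus residual means over provider
half-groups — which is distribution-identical for every aligned test and
keeps 10,000-replicate validations to seconds; a slow per-replicate
full-data path (`use_full_trials=True`) is retained and cross-checked.

The simulator emulates exactly the assumed model: Gaussian outcomes,
balance, no dropout, no missing data, no contamination, ICCs homogeneous
across arms and subgroups. Agreement between analytic and empirical power
therefore validates the reduction and the F machinery — it does not show
robustness to unbalanced clusters, non-Gaussian outcomes, or missingness,
which real trials exhibit and which are documented non-goals.

## Design choices where the design was open

* **Allocation within parents.** "Randomize within ISUs" is made concrete
  as an equal split inside each immediate parent (4/4 clinics per hospital,
  3/3 providers per clinic, 3/3 participants per provider). Odd counts at
  the randomized level are rejected rather than approximately balanced,
  because the power equivalence requires exact balance.
* **Stratified error df.** The stratified analysis defaults to per-stratum
  df (ν = 8 per stratum for the reference design): the point of the
  comparison is that stratification halves the ISUs. Estimating the error
  variance in the full sample while testing per stratum is exposed as
  `stratified_pooled_variance=True` (ν = 16); it narrows but does not close
  the gap to the pooled analysis.
* **Conclusions are computed.** Which design "wins" each comparison is
  derived from pointwise dominance of the computed curves, never asserted.
* **Subgroup symmetry.** The stratified power is reported once because the
  two strata are exchangeable under the default symmetric alternative; an
  asymmetric per-stratum effect can be supplied to `reduce_subgroup`.
* **Null values.** Θ₀ = 0 throughout; every hypothesis considered is a
  no-effect null.

## Numerical notes and limitations

* Validation thresholds: covariance matrices are accepted as PSD down to
  eigenvalues of −1e-10; counting-vs-brute-force agreement is required to
  1e-12 relative error; exact-vs-McKeon agreement to 1e-10.
* Monte-Carlo checks use 3 binomial standard errors at 10,000 replicates
  (simulation sizes chosen to make the binomial noise small relative to
  every gap being verified); the Type I error check is exact-level because
  the aligned tests are exact under the Gaussian model.
* Degenerate data (zero error variance in the reduced rows) raise
  `DegenerateDataError` rather than returning a decision.
* Sample-size solving (inverting power for N), GEE-based power, binary or
  count outcomes, covariate adjustment, interaction-test power and
  multiplicity-adjusted alternatives to the multivariate test are out of
  scope.
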