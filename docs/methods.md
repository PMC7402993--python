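# Methods

## The reference-distribution model

Each body-composition parameter is modelled, conditionally on age *t* and
separately by sex, with the Box-Cox Cole–Green (BCCG) distribution: a
power transform of the measurement is normal, so the distribution at each
age is fully described by the Box-Cox power **L(t)** (symmetry), the
median **M(t)** (location) and the coefficient of variation **S(t)**
(relative spread). The z-transform and its inverse,

    z = [(y/M)^L − 1]/(L·S),        y = M·(1 + L·S·z)^(1/L),

switch to the lognormal limit (z = ln(y/M)/S, y = M·e^{S·z}) when
|L| < 1e-5; the threshold avoids the numerically explosive 1/L exponent
while the two branches agree to well below 1e-6 there. The log-density is

    log f(y) = (L−1)·ln(y/M) − ln(M·S) − z²/2 − ln(2π)/2.

The transform requires 1 + L·S·z > 0, i.e. the distribution is formally
truncated at z = −1/(L·S). As in classical LMS practice the truncation
constant is ignored in the likelihood by default — for the S values seen
here (≤ ~0.95) the truncated mass is at most ~1e-3 and usually far
smaller — but an exact-truncation option (`truncated=True` in
`bccg_logdensity`) is available.

## Curve representation and fitting

Each of L, M, S is a smooth function of age over [18, 82), with M and S
parameterised on the log scale so positivity is structural. A requested
degrees-of-freedom value df (beyond the intercept) maps to:

* df = 0 — constant;
* df = 1 — linear in (scaled) age;
* df ≥ 2 — cubic B-splines on df equally spaced interior knots (df + 4
  basis functions), with a second-order difference penalty whose strength
  is solved by bisection so the trace of the weighted smoother equals
  df + 1. The λ→∞ limit of this penalty is exactly the linear fit, so the
  df ladder is nested.

Fitting maximises the penalized log-likelihood by Fisher-scoring
backfitting across the three curves (expected-information weights
(1+2L²S²)/S² for log M, 2 for log S, 7S²/4 for L). Each curve update is a
penalized weighted least-squares solve on the working response; a
step-halving guard rejects any update that would lower the penalized
objective, which makes the objective provably non-decreasing once the
penalties are frozen (they are re-solved for the first five iterations
while the weights settle, then held). Initialisation: L ≡ 1, M from a
penalized smooth of log y, S from the residual SD of that smooth.
Convergence is declared when the relative change in the penalized
log-likelihood drops below 1e-6 (maximum 200 iterations; non-convergence
returns the model flagged `converged=False` with a warning). `fix_L`
optionally pins the power (e.g. at 1 for an additive-normal-error
diagnostic fit).

Model selection fits every df triple in a grid and keeps the converged
model with the smallest BIC = −2 logL + k·ln n, k = df_L + df_M + df_S + 3;
ties (within 1e-8 relative) break toward fewer total df, then
lexicographically on (df_M, df_S, df_L). The default grid —
df_L ∈ {0,1,2}, df_M ∈ {1..6}, df_S ∈ {0..3} — covers typical
adult-reference complexity; the analysis drivers use a slightly narrowed
grid (df_L ∈ {0,1}, df_M ≤ 5, df_S ≤ 2) since on cohorts of ~5000 per sex
the selected triples sit comfortably inside it.

Before fitting, gross outliers are screened once per parameter and sex:
ordinary least squares of y on t, drop |standardized residual| > 10. On
clean data this removes essentially nothing (P ≈ 0 under normality); it
exists to stop data-entry-scale errors from leveraging the spline fit.

No extrapolation: evaluating a model outside its half-open age domain
raises rather than extending curves silently.

## Centiles, z-scores, validation

Reference tables tabulate (age, L, M, S, P3, P10, P50, P90, P97) on
integer ages 18–81 by default (both the percentile set and the grid are
configurable); row-wise strict ordering of the centile columns and
P50 = M are asserted at construction. Centile inversion refuses
percentiles outside the attainable Box-Cox range and reports that range.

Adequacy diagnostics mirror standard reference-curve practice: the
fraction of fitting data strictly below each centile curve must lie
within ±2 percentage points of nominal (points exactly on a curve count
as not below; the 2-point tolerance is our quantification of "acceptable
deviation" and is configurable), and the z-scores must pass a one-sample
two-sided Kolmogorov–Smirnov test against the fixed N(0,1) — not against
re-estimated parameters — with Holm correction across the family of
parameter × sex tests at level 0.05.

## Stratified references

FMI strata are defined against the *fitted FMI model's age-specific*
percentiles: low means the subject's FMI is ≤ its age's P25 (boundary
subjects are low, implemented with a 1e-9 z-tolerance so exact boundary
values land on the assigned side), high means ≥ P75. An unconditional
(marginal-quartile) split is available as a config switch
(`fmi_split="marginal"`); the age-specific reading is the default because
the split is derived from the model rather than from the pooled sample.
LMI is then re-fitted within each stratum and sex. BMI stratification
fits LMI and appendicular LMI within the WHO categories normal,
overweight, obese; underweight is excluded from modelling. Any stratum
below a minimum size (default 200) is skipped with a warning rather than
fitted badly.

## Group comparisons

Comparisons between age groups, sexes or strata use a gate-based decision
tree. Per-group Shapiro–Wilk tests and a median-centred Levene test
decide among: ANOVA with Scheffé post-hoc (normal, equal variance; the
two-group analogue is the equal-variance t-test); Kruskal–Wallis with
Welch-t post-hoc (normal, unequal variance; Welch t for two groups);
Kruskal–Wallis with Mann–Whitney post-hoc (non-normal; Mann–Whitney for
two groups). Holm correction applies to the t and Mann–Whitney post-hoc
families; Scheffé is simultaneous by construction and gets none.
Significance is declared at α = 0.01.

The gate level defaults to 0.01, not the conventional 0.05: with three
per-group normality gates plus a variance gate, a 0.05 level misroutes
~19% of genuinely Gaussian comparisons (0.95⁴), degrading the dispatch
operating characteristics, whereas at 0.01 the all-normal branch is taken
~95–96% of the time and heavy-tailed (t₂) samples are still routed to the
rank branch essentially always. It also matches the procedure's overall
significance level. Measured over 1000 Gaussian null replicates the
omnibus rejection rate at α = 0.01 is ~0.008–0.015.

The Holm adjustment is implemented from its step-down definition (sort,
multiply the i-th smallest p by m−i+1, enforce monotonicity, cap at 1)
and is the single implementation used everywhere, including the KS
family in validation.

## The synthetic cohort generator

The generator emulates a population-based adult DXA cohort. Its defaults
are the study conditions:

* **Sample frame** — ages uniform on [18, 82) (or per-age-group counts
  matching the published sample sizes), sex ratio 5147/10894 male, heights
  N(177.6, 7.1²) cm for men and N(164.3, 6.6²) cm for women.
* **True curves** — for each of the seven parameters and each sex, the
  median curve is a monotone (PCHIP) interpolant through the published
  age-group means at the group midpoints, extended to the domain edges by
  linear extrapolation (floored at half the edge value) so the curve has
  no curvature kink; the S curve interpolates the published SD/mean
  ratios the same way. The Box-Cox powers are constants chosen once for
  realism: near-symmetric lean indices (L = 1), right-skewed fat measures
  (FMI 0.3, appendicular FMI 0.4, fat ratios 0.5), strongly skewed VAT
  (0.15). Consequently simulated *medians* match the published means by
  construction while simulated *means* of the strongly skewed parameters
  (VAT especially) sit above them, as they must given the published
  coefficients of variation.
* **Joint structure** — a Gaussian copula on the latent z-scores. The
  published material does not describe the joint distribution, so the
  correlations are ours: 0.3 between fat and lean blocks (the
  conventional weak body-compartment coupling), 0.85 within the lean
  block, 0.5–0.7 between total adiposity and the regional ratios and VAT.
* **Assembly** — fat and lean totals come from the FMI/LMI draws and
  height; limb lean from appendicular LMI; trunk and limb fat are carved
  out of total fat *structurally*: a small stochastic head-fat share
  (2–5%) is removed and the remainder split by the drawn trunk/limbs
  ratio, so fm_trunk + fm_limbs ≤ fm_total holds identically.
  Appendicular FMI is therefore a *derived* quantity, not an independent
  BCCG margin: total, trunk and limb fat are tied by an additive identity
  with only ~3–4% slack, which leaves no room for a seventh free margin
  (any independent draw would violate additivity for a large fraction of
  subjects). Its distribution is nonetheless approximately BCCG with
  location and spread close to the published values, and the built-in
  appendicular-FMI curves remain available as modelling targets. Gynoid
  fat is a smooth, gently age-declining share of total fat (18→16% men,
  22→19% women); android fat is the drawn android/gynoid ratio times
  gynoid fat. VAT volume is VAT mass over 0.94 g/cm³ (the ratio implied
  by the published mass and volume means). Weight solves
  weight = (FM + LM)/(1 − bmc_fraction) with a constant bone-mineral
  fraction of 0.04. A configurable small fraction of women (0.5%) is
  flagged pregnant/breastfeeding purely to exercise the exclusion filter.
* **Truncation** — latent vectors that would leave the attainable Box-Cox
  range, or violate lean additivity, are resampled (truncated-copula
  sampling); for the default curves the rejected mass is negligible, so
  back-computed z-scores remain indistinguishable from N(0,1) at the
  sample sizes tested.

What the generator does **not** emulate: scanner physics and measurement
error, the proprietary VAT estimation algorithm, secular/cohort effects,
non-response and recruitment structure, and any real joint distribution
beyond the chosen copula. Passing tests therefore demonstrate that the
statistical machinery recovers known truth under the stated model — not
that the model captures every feature of real DXA data.

## Numerical choices and degenerate inputs

* Lognormal branch threshold |L| < 1e-5 (both branches agree to <1e-6 well
  beyond it).
* Penalty solve: bisection on log λ to |edf − target| ≤ 1e-8, bracketed by
  λ scaled to trace(B'WB)/trace(P).
* Fits require n ≥ 50; constant y is rejected (scale not estimable); the
  outlier screen requires n ≥ 10 and rejects an all-equal age design.
* Coverage checks require n ≥ 100; the KS test requires n ≥ 20 finite,
  non-constant z-scores.
* BIC ties break toward parsimony (see above); `select_model` ignores
  non-converged fits and errors only if none converge.
* Reference-table construction asserts strict centile ordering; boundary
  stratum assignment carries a 1e-9 z-tolerance.
* Exclusion boundaries are literal: weight strictly greater than 159 kg
  is excluded (159.0 retained); the VAT BMI window [18.5, 40] is
  inclusive; age 82.0 is out of domain.
* %FM uses total body weight (FM + LM + BMC) as denominator — the
  conventional DXA definition; the source material does not state its
  denominator.

## Problem sizes

The test suite and the acceptance script use cohorts of 2000–20000
subjects, 50-replicate selection/dispatch studies and 1000-replicate
null studies; the analysis drivers run the full 10894-subject cohort.
These sizes were chosen so every stochastic check sits far from its
decision boundary while the whole suite runs in minutes on one CPU.

## Known limitations

* Only age enters as a covariate, and only the BCCG family is supported
  (no BCT/BCPE heavier-tailed extensions).
* Effective degrees of freedom are matched per curve, not jointly; BIC
  uses the requested df as the parameter count, as is conventional.
* The generator's copula correlations and Box-Cox powers are assumptions,
  not estimates; analyses that depend on fine features of the joint
  distribution (e.g. exact stratum overlap rates) inherit them.
* Centile thresholds for classifying individuals as abnormal are out of
  scope; the package produces references, not clinical cut-offs.
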