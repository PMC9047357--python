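# Methods

This note documents the statistical model behind `mrkit`, the defaults and
why they were chosen, the synthetic data-generating process used for
validation, and the numerical decisions that are not visible from the API.

## The instrumental-variable model

A genetic variant is a valid instrument for an exposure X on an outcome Y
if it (1) associates with X, (2) is independent of X–Y confounders, and
(3) affects Y only through X. Under these assumptions the per-SNP Wald
ratio θ̂_j = β̂_Yj / β̂_Xj estimates the causal effect θ (a log odds ratio
when Y is binary and the GWAS used logistic regression). All estimators in
the package are functions of the harmonized pairs (β̂_Xj, β̂_Yj) and the
outcome standard errors, which is exactly the information published
summary statistics provide.

## Instrument processing

- **Selection** keeps SNPs with p strictly below the threshold (default
  5×10⁻⁸); **clumping** is greedy by ascending p, rejecting a SNP if any
  accepted SNP on the same chromosome lies within the window (default
  10,000 kb) and has r² at or above the ceiling (default 0.001). Pairs
  absent from the user-supplied LD table count as unlinked, with a logged
  warning — the package ships no reference panel.
- **Harmonization** aligns outcome effects to the exposure effect allele:
  swapped alleles negate β̂_Y and complement the frequency; strand-flipped
  representations of non-palindromic SNPs are recognized via base
  complement. Palindromic SNPs (A/T, C/G) are excluded by default; the
  optional `infer` policy orients them by allele frequency and excludes
  only SNPs falling in the ambiguity band (default 0.42–0.58).
- **Proxies**: an instrument missing from the outcome may be replaced by
  the outcome-present SNP with maximal LD strictly above r² = 0.9.
  Orientation uses the LD table's allele correspondence when present;
  otherwise frequency similarity (within 0.1) must disambiguate, else the
  proxy is skipped. Every exclusion lands in an audit log with a reason.
- **Strength**: per-SNP R² = 2·MAF·(1−MAF)·β̂², applied to the reported
  (log-odds) betas; F = (N−K−1)/K · R²/(1−R²), with K = 1 for per-SNP F.
  F statistics are omitted, not imputed, when N is unknown — as it is for
  the built-in varicose-veins panel, whose source GWAS does not publish N.

## Estimators

- **IVW**: weighted least squares of β̂_Y on β̂_X through the origin with
  weights 1/se_Y². This equals the 1/σ_j²-weighted mean of Wald ratios
  with first-order ratio SEs σ_j = se_Yj/|β̂_Xj| (asserted as a test
  property). The default is multiplicative random effects: the coefficient
  SE is scaled by the residual standard deviation **floored at 1**, so
  heterogeneity widens intervals but under-dispersion never narrows them.
  Cochran's Q and its χ²(n−1) p-value are attached.
- **Weighted median**: ratios sorted ascending with normalized weights
  w_j; cumulative midpoints s_j = Σ_{k≤j} w_k − w_j/2; the estimate
  linearly interpolates the ratio at s = 0.5. It is consistent when valid
  instruments carry ≥ 50% of the weight. SEs come from a parametric
  bootstrap (default 1000 draws, explicit seed) redrawing both betas from
  normals with their reported SEs. The **penalized** variant multiplies
  each weight by min(1, 20·q_j), where q_j is the upper-tail χ²(1)
  probability of the SNP's heterogeneity contribution about the
  unpenalized estimate; the penalty is recomputed inside each bootstrap
  replicate so the bootstrap reflects the full procedure. Note the
  interpolating weighted median is only approximately invariant to
  splitting one SNP's weight across duplicates — the estimate can move by
  at most one inter-ratio gap (tested as such).
- **MR-Egger**: pairs are oriented so β̂_X ≥ 0, then weighted least
  squares with intercept. The slope is the pleiotropy-adjusted causal
  estimate; the intercept estimates mean directional pleiotropy and its
  test is the InSIDE-assumption check. SE scaling as in IVW, floored at 1.
- All p-values are two-sided normal; 95% CIs use ±1.96·SE on the log-OR
  scale and are exponentiated for reporting.

## MR-PRESSO

The observed statistic is the weighted residual sum of squares about
leave-one-out IVW fits, RSS = Σ_j w_j (β̂_Yj − θ̂_{−j} β̂_Xj)². The null
distribution is simulated (default 1000 replicates) by redrawing both
betas from normals centered on the leave-one-out fitted values with the
observed SEs; p-values use add-one smoothing, so the floor is 1/(n_sim+1).
The per-SNP outlier test compares each observed weighted residual with its
simulated distribution, Bonferroni-corrected over the panel; the
distortion test compares the raw-vs-corrected estimate shift with shifts
from 1000 random removals of equally many SNPs (two-sided on the absolute
relative shift). Leave-one-out fits use a totals identity, making the
whole simulation a few vectorized array operations.

## Multivariable and two-step MR

Multivariable MR regresses β̂_Y on the matrix of exposure betas without
intercept, weights 1/se_Y², with the same multiplicative SE floor. The
joint panel is the union of each exposure's clumped significant SNPs,
re-clumped across exposures (keeping the SNP with the smallest minimum p
across exposures within a linked group), looked up in every table and
aligned to a common orientation; anything missing or allele-incompatible
is dropped with an audit reason. A strictly zero column is reported as a
collinearity error rather than a zero estimate, because the design matrix
is genuinely rank-deficient.

Two-step MR runs IVW of the upstream trait's instruments against the
mediator (step 1) and against the outcome (step 2); mediation is
*suggested* when both are significant at α. A descriptive
product-of-coefficients (step-1 β × mediator-on-outcome β) can be attached
as supplementary output; it carries no interval and no formal mediated
proportion is computed.

## Study orchestration

`run_study` executes, per outcome: harmonization → instrument strength →
IVW / weighted median / penalized weighted median / Egger → MR-PRESSO;
then Benjamini–Hochberg FDR per method across outcomes (family size =
number of outcomes, chosen because a 3-outcome family reproduces the
smallest-p pattern FDR = 3×p; an all-tests family is available by flag).
Only outcomes whose IVW survives FDR at α proceed to the downstream
cascade: confounder-excluded rerun (instruments named on a user-supplied
exclusion list — secondary-trait lookups are an input, not an automated
query), validation-cohort rerun, multivariable MR, mediation, and optional
reverse MR. The confounder rerun can be run unconditionally by invoking
`basic_mr` on `dataset.drop(...)` directly. CAUSE-style Bayesian model
comparison is not implemented; the report schema carries externally
computed CAUSE p-values verbatim when supplied. Reports are plain JSON
dictionaries: deterministic given the config seed (all stage seeds derive
from it) and lossless under serialization.

## Synthetic data-generating process

The generator implements the causal diagram literally. For SNP j: MAF_j ~
U(maf_range); true exposure effect γ_j; direct (pleiotropic) outcome
effect α_j; the outcome's true effect is θ·γ_j + α_j. Observed betas add
normal noise with se = 1/√(2·N_eff·MAF(1−MAF)), where N_eff = 4·N·φ(1−φ)
for a binary trait with case fraction φ. Pleiotropy modes: `uncorrelated`
(zero-mean α), `directional` (mean `pleio_scale`, sd half of it, oriented
relative to the exposure-increasing allele — otherwise random γ signs
would cancel the Egger intercept by construction), and `correlated` (α =
confounder_effect · δ_j, with δ_j written to a confounder summary table).
Instruments are simulated independent, as post-clumping panels are, with
non-palindromic alleles; there is no individual-level genotype simulation.

Defaults mirror the motivating study: 21 instruments; |γ| ~ U(0.08, 0.29)
with random sign and MAF ~ U(0.08, 0.5), spanning the published instrument
panel's betas and frequencies; exposure effective sample size 10,600,
which reproduces the panel's reported standard errors (≈ 0.015 at
MAF 0.3); binary outcome with 4,576 cases / 190,028 controls (the
DVT-like configuration); θ = log(1.17). `gamma_dist=("fixed", …)` and
`maf_values` pin the panel exactly, which is how the generator reproduces
the 15% total variance explained in expectation.

What the generator does **not** emulate: LD between instruments, winner's
curse from in-sample selection, sample overlap between exposure and
outcome GWAS, allele-frequency differences between cohorts, and
non-normal effect-size distributions. Passing calibration tests therefore
shows the estimators are correctly implemented and calibrated under the
stated model, not that real-data results are unbiased under violations of
it.

## Validation design and problem sizes

Type-I-error calibration uses 500 null replicates (rejection rate must
lie in [0.02, 0.09] at α = 0.05 — the band accommodates Monte-Carlo noise
and the deliberate conservatism of the SE floor); outlier detection uses
200 replicates with one 10-σ planted outlier among 21 SNPs; parameter
recovery uses 500 replicates at θ = log(1.17), requiring mean bias within
3 Monte-Carlo SEs and CI coverage in [0.92, 0.97]. These sizes give
stable rates while keeping the full validation suite around a minute of
CPU. First-order Wald weights ignore exposure-side noise, producing a
small regression-dilution bias of order Σse_X²/Σγ² (≈ 0.5% of θ under the
default conditions); the 3-MC-SE recovery margin accommodates it, and the
Egger-intercept recovery property is checked at a larger exposure sample
size where dilution is negligible.

## Known limitations

- Published headline odds ratios of the motivating real-data analysis
  require the Pan-UKBB / FinnGen / IEU downloads and are not recomputed
  here; the synthetic recovery study stands in at matched effect size.
- The weighted-median bootstrap is parametric only; no analytic SE option.
- No mode-based estimators, Steiger filtering, MVMR-Egger, conditional F
  statistics, or CAUSE reimplementation.
- LD information is consumed, never computed: clumping and proxy search
  are only as good as the user-supplied LD table.
- The R² formula is applied to log-odds betas exactly as reported
  (standard practice for this panel), not rescaled to SD units.
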