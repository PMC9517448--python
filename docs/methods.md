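# Methods

This note documents the statistical machinery, the choices that were
genuinely open, and what the synthetic validation does and does not
establish.

## Model and estimation

Every model is a recursive (acyclic) linear path diagram over observed
variables and latent factors. In RAM form, collect all directed
coefficients — factor loadings and regression paths — in `A`, and all
residual variances and covariances in `S`; with `P` the selection of
observed rows, the implied covariance of the observed variables is

    Sigma(theta) = P (I - A)^-1 S (I - A)^-T P^T.

Latent scales are set by a *marker*: the first-listed indicator's
loading is fixed to 1 (the reported solutions show no test statistic
for the first indicator per factor, the signature of marker
identification). Exogenous observed covariates (aging rate, household
income) have free variances and a free mutual covariance; this is what
reproduces the published degrees of freedom (22/22/17/24/16/18/21/15),
whereas fixing them to sample moments does not.

Estimation minimizes the normal-theory discrepancy

    F(theta) = ln|Sigma| + tr(S_n Sigma^-1) - ln|S_n| - p

with `S_n` the unbiased (n−1) sample covariance. The model test
statistic is `T = n F` at the optimum — the `n` (not n−1) scaling is
the one consistent with the published χ²/df/RMSEA triples. Gradients
are analytic (d F = tr[(Σ⁻¹ − Σ⁻¹SₙΣ⁻¹) dΣ] propagated through the RAM
structure); standard errors come from the inverse expected information
of `nF/2`, and standardized-solution intervals from a delta-method
Jacobian taken by central differences.

### Numerical choices

* **Starting values.** Paths start at 0, residual variances at half the
  sample variances (the marker's for a latent), exogenous moments at
  their sample values. Free loadings start at the reference-variable
  regression `cov(indicator, marker)/var(marker)`: starting all
  loadings at +1 sends models with strong *negative* loadings (the
  upper-limit indicator loads near −0.9) into a Heywood valley from
  which quasi-Newton iterations do not recover. The regression start is
  deterministic and sign-correct.
* **Optimizer.** BFGS with analytic gradients; if the gradient
  inf-norm is still ≥ 10⁻⁶, an L-BFGS-B polish (which handles the
  ill-conditioned near-Heywood valleys), then a short simplex walk plus
  BFGS as a last resort. `converged` requires gradient inf-norm
  < 10⁻⁶. No randomness anywhere in estimation.
* **Heywood cases.** Negative residual variances are admitted (no
  boundary constraint), flagged in `FitResult.heywood`, and surface as
  honest non-convergence when the likelihood is essentially flat along
  the offending direction. With the breast/cervical generating values
  (standardized interventions → rate paths of 1.14/1.23, i.e. residual
  rate variance near 0.1), n = 47 replicates land in this regime with
  appreciable probability — as the original estimates' magnitude
  suggests happened in the source analysis too.
* **Non-positive-definite excursions.** Where Σ(θ) leaves the PD cone
  the objective returns a smooth pull-back penalty toward the starting
  point rather than infinity, keeping quasi-Newton updates finite.

## Fit indices and the acceptance rule

`T = nF` is referred to χ²(df); RMSEA = √(max(0, (T − df)/(df·n)));
SRMR is the RMS of the unique correlation-metric residuals; CFI
compares `max(T − df, 0)` against an independence baseline
(Σ_b = diag S, df_b = p(p−1)/2); GFI = 1 − tr[(Σ⁻¹S − I)²]/tr[(Σ⁻¹S)²]
with AGFI/PGFI the df-adjusted and parsimony-weighted versions. A model
is accepted iff p > 0.05, RMSEA < 0.10, SRMR < 0.10 and CFI > 0.90, all
strict. All seven indices are always reported; GFI/AGFI are
sample-size-sensitive and do not gate acceptance.

## Preprocessing

Each candidate variable is shifted by `10⁻⁶ − min` when its minimum is
≤ 0, Box-Cox transformed at the exponent maximizing the profile
log-likelihood on [−3, 3] (0.05 grid plus bounded scalar refinement;
deterministic), then z-standardized with the n−1 denominator. The
normality screen fails a variable outright when its modal value holds
more than 30 % of observations (a point mass survives any monotone
transform), and otherwise applies Shapiro–Wilk at α = 0.05 to the
transformed values. The 30 %/0.05 pair is this package's
operationalization of "cannot be approximated by a normal
distribution"; its testable contract is that the generator's degenerate
variables are excluded in 100 % of seeds while the clean skewed ones
survive at the study's sample size. If all candidate indicators of a
latent are excluded, the stratum is reported as unmodelable rather than
silently refit.

## Model catalog

Topologies are shipped as plain-text model files (one per cancer × sex
× stage). The pre-analysis stage has both latent factors acting on the
rate directly and all six resource indicators; the final stages use the
three-indicator resource factor and the per-cancer intervention sets
(upper-limit for gastric/breast/cervical, charge-free for lung,
call/recall only for colorectal). The full hypothesized residual-error
set is call–recall, call–upper-limit, revenue–expense; the published
lung and colorectal degrees of freedom admit exactly *one* residual
pair, and the catalog retains call–recall for lung but revenue–expense
for colorectal — with only two intervention indicators, a call–recall
residual covariance would leave the colorectal interventions
disturbance unidentified (singular information along a ψ–θ ridge).
These reductions are commented in the catalog files.

## Synthetic data

The generator is layered so every pipeline stage is exercised:

1. **Latent scores.** Multivariate-normal rows from the implied
   covariance of a topology at standardized coefficients. Defaults are
   the published standardized solutions; residual variances are solved
   topologically so every variable has unit implied variance. The
   quantities the published solution does not print are fixed once:
   residual-error correlations 0.2 for the hypothesized pairs, and an
   aging–income correlation of −0.3 (rural prefectures are older and
   poorer).
2. **Placement.** Each score is mapped monotonically onto the raw scale
   through an inverse Box-Cox placement anchored exactly at the
   published per-variable medians and IQRs. Right-skewed shares
   (recall, upper-limit, modality extension) use λ = 0.25, heavily
   skewed ones (charge-free, extra-region) λ = 0 (lognormal); shares
   with mass near 100 % (call, after-hours, out-of-evidence) use the
   complementary "headroom" placement on 100 − x so the [0, 100]
   support is respected smoothly; rates and the aging rate are affine.
   The per-variable families were fixed in a one-time design experiment
   at n = 47 choosing, for each variable, the family the normality
   screen retains most reliably while matching the published
   descriptives — the generator must emulate variables the original
   screen *kept*.
3. **Degenerates.** Variables named in the per-cancer degenerate sets
   (after-hours, extra-region, out-of-evidence, modality extension
   everywhere; charge-free except lung; upper-limit for lung and
   colorectal — the set the original screen excluded) are overwritten
   with 70 % point-mass draws, guaranteeing exclusion by the 30 % modal
   rule.
4. **Counts.** Eligible populations are drawn uniformly from
   50 000–500 000 per prefecture, participants binomially at the placed
   rate, and total/employed/primary-industry counts are constructed so
   the eligibility identity reconstructs the drawn eligible pool
   exactly.

A single seed expands into one substream per variable, so adding a
variable never perturbs existing columns; the Cholesky mixing is
lower-triangular in declaration order.

### What the synthetic validation shows — and does not

Recovery runs (n = 2000, 200 replicates) show the estimator is
unbiased at the published generating values with near-nominal 95 %
interval coverage, and oracle tests show the minimizer reaches the same
discrepancy as brute-force search. This validates the *machinery*, not
the substantive findings: the generator is multivariate-normal by
construction (after inverse placement), has no spatial autocorrelation
between prefectures, no municipal-level heterogeneity, and its
unprinted correlations are assumptions. Passing tests therefore says
the pipeline would recover a structure like the published one if the
data carried it — not that the published structure is true.

Two intrinsic limits are worth naming. Bounded percentage variables
whose quartiles sit near a bound (call's upper quartile is 90 %)
necessarily place a few percent of any quartile-anchored draw at the
bound; a powerful normality test at n in the hundreds rejects such
boundary compression with probability approaching 1 — as it would for
the real bounded data. Pipeline-level screen behaviour is therefore
characterized at the study's own n = 47, where measured acceptance of
the true generating model is ~80 %. And at n = 47 the χ²/RMSEA
criteria themselves have substantial sampling noise, so a true model is
rejected in a nontrivial fraction of seeds — the same small-sample
caveat that applies to the original design.

## Degenerate inputs and edge rules

`screened > eligible` warns and computes (municipal registries can
exceed the derived denominator); eligible = 0 is an error; a constant
variable cannot be standardized or screened; saturated models return
p = 1 by convention; df = 0 leaves AGFI/PGFI undefined (NaN); CFI is
clipped to [0, 1]; missing cells are a hard error (no missing-data ML).
Reported rounding follows the published precision: indices to 3
decimals, standardized coefficients to 2.
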