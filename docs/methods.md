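# Methods

## Scope

`constind` implements a two-stage analysis for detecting genetic trade-offs
between constitutive chemical defence and its inducibility in half-sib
family trials, plus a synthetic-data generator that emulates the experiment
the analysis assumes. Stage one estimates per-family least-square means of
each defence trait within each phosphorus level; stage two correlates
constitutive level with inducibility across families and judges the
correlation against a Monte Carlo null of spurious (part–whole)
correlations.

## Generative model (`constind.simulate`)

One seedling per (family, block, phosphorus, induction) cell; the default
design is 33 × 4 × 2 × 2 = 528 seedlings. For each trait and phosphorus
level, family *i* carries latent values

    (C_i, D_i) ~ BVN( (μ_C, μ_D), σ_C, σ_D, ρ )

where C is the true constitutive level, D the true inducibility and ρ
(`rho_tradeoff`) their correlation. Seedling values are

    y = C_i + D_i·1[induced] + b_block + ε,   b ~ N(0, σ_b²),  ε ~ N(0, σ_e²)

with block effects additive and shared across families within a
block × phosphorus stratum (the simplest structure in which blocks are pure
nuisance). Bivariate normality is assumed throughout because the Monte
Carlo null is itself parameterized by means and variances; heavier-tailed
families are out of scope.

Choices worth knowing:

* **Two parameterizations of the trade-off.** `rho_tradeoff` is
  corr(C, D). Hypotheses about allocation are often better expressed on the
  *induced level* I = C + D ("high-constitutive families reach lower induced
  levels"); `PhosphorusTraitParams.from_induced_correlation(σ_C, σ_I, ρ_CI)`
  converts exactly (Var D = σ_C² + σ_I² − 2·cov; cov(C,D) = cov(C,I) − σ_C²).
  The distinction matters: corr(C, D) = 0 does **not** mean "no trade-off"
  in the sense tested by the Monte Carlo procedure, whose null hypothesis is
  corr(C, I) = 0 — with corr(C, D) = 0 the induced level is *positively*
  coupled to C through the shared C term.
* **No truncation by default** (`truncate_at_zero=False`): clamping negative
  concentrations at zero would bias the moments that the parameter-recovery
  and calibration studies rely on. Turn it on for realistic-looking output.
* **Missingness** is modelled as completely-at-random row dropping
  (`missing_fraction`, default 0), enough to exercise the estimator's
  imbalance handling.
* The generator can return the latent (C_i, D_i) pairs (`return_truth=True`)
  so recovery tests need no estimation step.
* All randomness flows from a single `numpy` Generator seeded by
  `config.seed`; identical configs give byte-identical tables.

### The default preset

`maritime_pine_preset()` emulates a maritime-pine trial with two traits,
stem non-volatile resin and needle total phenolics, on the concentration
scale reported for the species (constitutive means 45–110 mg g⁻¹ DW, well
under the ~200 mg g⁻¹ ceiling). Defence investment is higher under low
phosphorus. Low-phosphorus trait models have a strong true trade-off
(ρ_CI = −0.9, i.e. rho_tradeoff ≈ −0.97) with between-family SD three times
the sampling SD of a four-block family mean; high-phosphorus models have
rho_tradeoff = 0 with sampling SD at or above the family SD — the
error-dominated regime in which naive Pearson tests frequently report
significant negative correlations that the Monte Carlo null exposes as
spurious. The preset was fixed by forward simulation of the full pipeline
(the low-P panels must yield `true_tradeoff`, the high-P panels must not,
in ≳90% of replicates) and is not meant to be data-calibrated beyond the
concentration scale; seedling height and growth responses are not simulated.

## Family least-square means (`constind.means`)

Within each phosphorus stratum the default estimator (`ols_lsmeans`) fits
the fixed-effects linear model

    trait ~ block + family + induction + family:induction

by OLS and evaluates each (family, induction) LS mean as the fitted cell
mean averaged with equal weight over blocks; the standard error is
σ̂·√(L(XᵀX)⁻Lᵀ) with σ̂² the residual mean square. Families are deliberately
fixed effects: the estimands are the family means themselves, not variance
components, so no REML machinery is needed. Blocks are likewise fixed —
with the analysis stratified by phosphorus and only family-level means
required downstream, the random-block error structure of a full
split-split-plot ANOVA changes nothing about these estimands under balance
and is out of scope. A `cell_means` estimator (arithmetic cell means,
residual-pooled SE) is provided as a cross-check; on balanced data the two
produce identical estimates, though the cell-means SE pools block variation
into the residual.

Degenerate inputs: an empty (family, induction) cell is an error naming the
cell; zero residual degrees of freedom returns estimates with the SE flagged
unavailable; on rank-deficient designs each LS-mean contrast is checked for
estimability against the row space of the design matrix and non-estimable
cells are dropped with a warning, never imputed. Homoscedastic residuals
within a stratum are assumed throughout.

## Trade-off inference (`constind.tradeoff`)

Constitutive level = control-cell LS mean; inducibility = induced-cell
minus control-cell LS mean; their squared SEs travel along as per-family
sampling variances. Families missing either cell are dropped with a logged
warning (at least three complete families required). The observed statistic
is the Pearson correlation r of (constitutive, inducibility); its two-sided
P-value uses the exact t-transform with n − 2 degrees of freedom.

### Monte Carlo null of spurious correlation

Null hypothesis: true constitutive and true induced family levels are
independent. Each of `n_sims` (default 10,000) simulations draws, per
family,

    C* ~ N( mean(x),  max(S²_x − mean(v_x), 0) )
    I* ~ N( mean(i),  max(S²_i − mean(v_i), 0) )      (independently)

where S² are the between-family sample variances of the observed estimates
and v the per-family sampling variances (squared SEs); the deflation makes
the *noisy* simulated values match the observed marginal variances. Each
draw then receives its family's sampling noise, simulated inducibility is
formed as noisy-induced minus noisy-constitutive, and the Pearson r is
recorded. The reported quantities are the null mean and 2.5/50/97.5%
quantiles of r, a 40-bin histogram on [−1, 1], and

    p_mc = (1 + #{r_sim ≤ r_obs}) / (n_sims + 1)

— lower-tailed, because the alternative of interest is a trade-off (more
negative than chance); the add-one correction avoids zero P-values from
finite simulation. A two-sided mode (doubled smaller tail, capped at 1) is
available via `tail="two_sided"`, and `deflate_sampling_variance=False`
switches to raw between-family variances for sensitivity analysis. The
variance deflation is floored at zero since estimated between-family
variance can fall below the mean sampling variance in small samples. All
simulations come from one seeded generator in a fixed order, so results are
reproducible and independent of execution order; simulations that produce a
constant vector (possible only with zero variances on an axis) are redrawn
and counted; a fully degenerate null (all variances zero) is an error.

### Verdict

With significance level α (default 0.05):

* `true_tradeoff`  — r < 0, Pearson p < α, p_mc < α;
* `spurious_only`  — r < 0, Pearson p < α, p_mc ≥ α;
* `no_tradeoff`    — otherwise.

No multiple-testing correction is applied across trait × phosphorus panels.

## Pipeline and provenance (`constind.pipeline`, CLI)

`run_pipeline` executes generator/loader → means → inference for every
requested (trait, phosphorus) panel, materializes the means table, report
JSON and scatter data to disk, and stamps the report with a config hash,
seed and tool version. Per-panel Monte Carlo seeds are derived from the run
seed and the panel's labels (SeedSequence over CRC32 of the names), so
analysing one panel alone reproduces the joint run's numbers exactly, and
reruns are identical apart from the timestamp. Plot rendering is limited to
plain-text data files (scatter pairs, null histograms, one-line-per-panel
summary); no figure rendering is built in.

## Validation studies (`constind.experiments`) and what they show

All studies run the real pipeline end-to-end on synthetic data and are
reproducible from a single seed; problem sizes are chosen so the whole
battery completes in well under a minute on one CPU.

* **Null centre.** With zero sampling variance and equal between-family
  variances the null mean of r matches the closed form
  −√(VarC/(VarC+VarI)) = −1/√2 (200 families, 2000 simulations, ±0.03).
* **Calibration.** 500 replicates of the 33-family design generated under
  the test's null (ρ_CI = 0) with sampling SD equal to the between-family
  SD: the naive Pearson test rejects in ~99.8% of replicates — the
  part–whole artefact in its starkest form — while the Monte Carlo test
  rejects in ~2%. The Monte Carlo test is thus *conservative* at this
  design size: plugging variance estimates from the same 33 families into
  the null makes the null centre co-vary with the observed r, absorbing
  part of each extreme observation. Re-running the identical procedure with
  the null parameterized by the true generative variances yields ~5.6%
  rejection, confirming the shortfall is this conditioning effect, which
  decays as the family count grows. Practical reading: a significant p_mc
  can be trusted; a marginal non-significant one may understate evidence in
  small designs.
* **Conservativeness under uncorrelated inducibility.** With
  corr(C, D) = 0 — which puts the truth *farther* from a trade-off than the
  test's own null — rejection is essentially 0, as it must be.
* **Power.** With ρ_CI = −0.9, between-family SDs twice the sampling SD and
  33 families, ≥ 99% of 200 replicates are classified `true_tradeoff`.
* **Preset pattern.** The default preset reproduces the four-panel
  qualitative pattern (both traits `true_tradeoff` at low P, neither at
  high P) in ~100% of 50 replicates.
* **Oracles.** LS means agree with an independent normal-equations solver
  (different design-matrix construction, pseudo-inverse solve) to ~1e-13 on
  unbalanced data; Pearson r agrees with the direct-summation formula to
  machine precision.

Because the generator draws exactly the bivariate-normal, homoscedastic,
additive-block world the estimators assume, these results certify internal
correctness and the statistical logic of the null — not robustness to real
data's skewed concentrations, variance heterogeneity between treatments,
family-by-block interactions, or non-random missingness. The module takes
the family count from the data rather than hard-coding a design size.

## Known limitations

* The Monte Carlo null conditions on estimated variances; its finite-sample
  conservatism at ~33 families is documented above and not corrected.
* Normal family effects and homoscedastic residuals only; no REML variance
  components, no random-block error terms, no bootstrap of raw seedlings.
* Inducibility is an absolute difference; ratio or log-scale inducibility
  definitions are not implemented.
* Concentrations can be simulated negative unless `truncate_at_zero` is set.
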