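# Methods

This note records the statistical model behind `mrpipe`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer would want written down.

## Structural model

For instrument *j* of one exposure, the two-sample MR model is

    gamma_j : true SNP -> exposure effect (standardized abundance per allele)
    r_j     : direct (pleiotropic) SNP -> outcome effect, zero for valid IVs
    Gamma_j = theta * gamma_j + r_j   (log-odds per allele)

with observed `gamma_hat_j ~ N(gamma_j, se_x_j^2)` and
`Gamma_hat_j ~ N(Gamma_j, se_y_j^2)` independent across samples (the two
GWAS do not share subjects). `theta` is the causal log-odds effect per SD
of exposure; all estimators report `exp(theta)` as an odds ratio with a
Wald 95% CI.

## Estimators

* **Wald ratio** `Gamma_hat/gamma_hat`, SE by the first-order delta method
  (`se_y/|gamma_hat|`). Exposure-side uncertainty is deliberately ignored
  here; it enters through ML and cML instead. A second-order correction was
  considered and rejected: at the F-statistics this package targets (>10,
  typically >80) the correction is below 1% of the SE.
* **IVW**: precision-weighted mean of Wald ratios with weights
  `w_j = gamma_hat_j^2 / se_y_j^2`, identical to a weighted zero-intercept
  regression of `Gamma_hat` on `gamma_hat`. Default inference is
  multiplicative random effects with a fixed-effect floor: the fixed SE
  `(sum w)^(-1/2)` is inflated by `sqrt(Q/(J-1))` when Cochran's Q exceeds
  its degrees of freedom, never deflated. Both `"mre-floor"` and `"fixed"`
  are exposed because published tables rarely state which was used.
* **Maximum likelihood**: the joint normal likelihood in
  `(theta, gamma_1..gamma_J)`; the per-SNP effects are profiled in closed
  form, `theta` optimized by bounded 1-D search started at the IVW
  estimate, and the SE comes from the observed information with the
  nuisance block inverted analytically. Reduces to fixed-effect IVW as
  `se_x -> 0`.
* **MR-Egger**: weighted regression `Gamma_hat = alpha + theta*gamma_hat`
  with weights `1/se_y^2` after orienting every pair to
  `gamma_hat_j >= 0`. The orientation convention matters — the intercept
  (mean directional pleiotropy) is not invariant to allele relabeling, and
  "directional" is only meaningful on the exposure-increasing orientation.
  SEs carry a residual floor `max(1, sigma)`; p-values use t with J-2 df.
  This floored small-sample inference is conservative by construction: its
  long-run null rejection rate at the 5% level is about 3.1%, not 5%.
* **Weighted median**: ratios sorted, standardized cumulative weights
  `s_j = (cum_j - w_j/2)/sum(w)` with inverse-variance ratio weights,
  linear interpolation at s = 0.5. SE by parametric bootstrap (draw both
  effect vectors from their sampling distributions; SD over draws).
  Consistent while valid instruments carry >= 50% of the weight.
* **Weighted mode**: argmax over a 512-point grid of the normal-kernel
  density of ratios, bandwidth `phi * 0.9 * min(sd, mad/0.6745) * J^(-1/5)`
  (phi = 1 by default), inverse-variance weights; bootstrap SE with the
  bandwidth recomputed per draw. If all ratios coincide the common ratio is
  returned directly. Consistent when the largest homogeneous ratio cluster
  comes from valid instruments.
* **MR-PRESSO**: observed statistic
  `RSS = sum_j (Gamma_hat_j - theta_(-j) gamma_hat_j)^2 / se_y_j^2` with
  leave-one-out IVW predictions; the null distribution comes from
  parametric draws of both effect vectors with the RSS recomputed in full
  (including the leave-one-out estimates). All p-values use the add-one
  rule `(1 + exceedances)/(n_sim + 1)`, so simulation p-values are never
  exactly zero. Outliers: per-SNP residual p below `0.05/J` (Bonferroni).
  The distortion test compares the raw-vs-corrected estimate shift against
  shifts from removing random subsets of the outlier count. The RSS weight
  is `1/se_y^2` — on the Gamma-residual scale this is the weight consistent
  with the IVW ratio weights.
* **cML-MA**: for each candidate count K of invalid instruments, minimize
  `sum_j [(gamma_hat_j - b_j)^2/(2 se_x_j^2) + (Gamma_hat_j - theta b_j - r_j)^2/(2 se_y_j^2)]`
  subject to exactly K nonzero `r_j`, by coordinate descent: the K largest
  standardized outcome residuals are declared invalid each iteration, `b`
  and `theta` update in closed form. The subset-selection objective is
  non-convex, so each K runs 10 starts (IVW estimate plus Gaussian
  perturbations of SD `0.5 * IVW SE`, seeded); the best converged objective
  wins and non-convergence across all starts raises with diagnostics.
  `BIC_K = neg2ll_K + K ln(n_eff)` with `n_eff = min(N_exposure, N_outcome)`
  by default; model-average weights `exp(-(BIC_K - min BIC)/2)` normalized;
  averaged variance adds the between-model spread to within-model
  variances. K = 0 reduces to the ML estimator (checked to 1e-6). The
  data-perturbation cML variant is intentionally not implemented.

P-values are two-sided normal for all estimators except Egger (t, J-2 df).
Every estimator is invariant to jointly flipping `(gamma_hat, Gamma_hat)`
of any instrument.

## Instrument pipeline

Defaults mirror the conventional microbiome-MR settings: screen at
locus-wide p < 1e-5 (genome-wide 5e-8 leaves most genera without
instruments — the cost is weaker instruments, which is why F is reported
per exposure), clump greedily at r^2 < 0.001 within +/-10,000 kb (ties on
p broken lexicographically by SNP id for determinism), remove MAF <= 0.01
(the boundary is treated with a 1e-12 tolerance so that eaf = 0.99 counts
as exactly 0.01), and drop palindromic SNPs whose effect-allele frequency
falls in [0.42, 0.58] on either side; outside that window frequencies on
the same side of 0.5 mean same strand (keep), opposite sides mean flip.
The window is configurable; no cutoff is universal and the original
analyses rarely publish theirs. Instruments missing from the outcome GWAS
are dropped — no proxy-SNP search, because proxies would require an LD
reference beyond the r^2 table this package consumes. LD arrives as a
precomputed pairwise r^2 table; absent pairs mean r^2 = 0.

R^2 per SNP is `2 p (1-p) beta^2` on the standardized-exposure scale, with
the t-statistic fallback `t^2/(t^2 + N - 2)` when the frequency is
missing. Power uses the standard binary-outcome approximation
`Phi(|theta| sqrt(n v (1-v) R^2) - z_{0.975})`.

## FDR and classification

Storey q-values are computed within each (direction, method) family across
exposures — the report layout has one q column per method, so pooling
across methods would mix families of different calibration. pi0 is
estimated from `pi0(lambda) = #{p > lambda}/(m(1-lambda))` on
lambda = 0.05..0.95, smoothed by a weighted cubic polynomial (weights
`sqrt(1-lambda)`, i.e. inverse SD — the tail counts are Poisson-noisy) and
read off at lambda = 0.95, clamped to (0, 1]. Below 12 p-values the tail
estimator is hopeless and pi0 is fixed at 1, which reduces exactly to
Benjamini-Hochberg (as does the explicit `fixed_pi0_1` method). Note the
smoother is intrinsically noisy: at m = 119 uniform p-values its SD is
about 0.25 around a mean of ~1.0, so single-panel pi0 estimates as low as
0.6 are ordinary sampling behaviour.

Classification: significant (p < 0.05 and q < 0.1), suggestive (p < 0.05,
q >= 0.1), null otherwise. Exposures with 1-2 surviving instruments are
analyzed by IVW only (Egger/median/mode need 3, MR-PRESSO 4) and flagged
in the skipped log rather than silently dropped. Reverse MR instruments
the outcome GWAS with the same criteria against every forward hit
(classification better than null on the primary method, IVW by default).

## Synthetic-data generator

The generator emulates the two consortia's *shapes*: a standardized
continuous exposure at n = 13,266 and a binary outcome at n = 166,401 with
case fraction 5731/166401, with GWAS SE approximations
`(2 MAF (1-MAF) n)^(-1/2)` and `(2 MAF (1-MAF) n v (1-v))^(-1/2)`, MAF ~
Uniform(0.05, 0.5). `gamma_sd = 0.15` and 15 candidate SNPs per exposure
are calibrated to the motivating study's printed summaries: per-genus
F-statistics of 85-195 with 6-15 instruments imply selected per-SNP
effects near 0.14, and ~10 of 15 candidates clear p < 1e-5 at that
strength, matching the study's 1232 instruments across 119 genera.

Pleiotropy regimes on a configurable invalid fraction: `balanced`
(mean-zero direct effects), `directional` (shared-sign effects applied
relative to the exposure-increasing allele — allele labels are arbitrary,
so a fixed sign on the raw labels would average out and be
indistinguishable from balanced), `correlated` (direct effects proportional
to instrument strength plus noise, violating InSIDE). LD-block simulation
gives every within-block pair a common r^2 and one shared causal signal
per block, blocks spaced beyond the clumping window.

Not emulated, hence outside what a green test establishes: winner's curse
(instrument effects are not conditioned on selection), sample overlap
between the two GWAS, population stratification, LD beyond equicorrelated
blocks, binary-trait non-collapsibility (outcome effects are generated
directly on the log-odds scale), and any real biology of taxon abundance
distributions.

Seeding: one integer seed feeds a splittable `SeedSequence`; per-exposure
analyses and per-method bootstraps derive child seeds deterministically
(seeds kept below 2^31), so a pipeline run is a pure function of (inputs,
config, seed) down to the byte level of its rendered reports.

## Numerical choices

- Canonical TSV interchange writes floats with 17 significant digits and
  reads them with correctly-rounded parsing; write-read round trips are
  bit-exact (pandas' default fast float path is not correctly rounded and
  is bypassed).
- The ML/cML information matrices are inverted by the analytic block
  formula `Var(theta) = 1/(I_tt - sum_j I_tb_j^2 / I_bb_j)`; non-positive
  information raises instead of returning NaN.
- cML coordinate descent declares convergence at |delta theta| < 1e-8
  (configurable), capped at 500 iterations per start.
- Weighted-mode densities are evaluated in bootstrap chunks of 200 draws
  to bound memory at (200 x 512 x J) doubles.
- Degenerate inputs: empty harmonized sets are skipped with a logged
  reason; single-instrument sets route IVW/ML to the Wald ratio; all-zero
  IVW weights, zero exposure effects in Wald ratios, and out-of-range
  configuration values raise typed errors.

## Known limitations

- No Steiger directionality filtering, multivariable MR, contamination
  mixture, or correlated-instrument (LD-aware) likelihoods.
- MR-Egger power is poor at small J; its CI in reports is Wald-on-t and
  its null rejection rate is conservative (see above).
- The per-SNP outlier test in MR-PRESSO inherits the usual multiplicity
  bluntness of Bonferroni at small J.
- Reverse MR can only instrument the outcome with SNPs present in the
  taxon GWAS tables; with exposure panels restricted to their own mbQTLs
  (as in the synthetic study generator), reverse analyses may legitimately
  come back empty.
- The q-value smoother's variance at panel sizes near 100 means FDR
  control is approximate in small panels; the `fixed_pi0_1` (BH) mode is
  the conservative alternative.
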