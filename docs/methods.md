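# Methods

`sirevar` studies the genetics of *uniformity* — the within-family residual
variance of a quantitative trait — in large half-sib designs of the kind
used in beef-cattle progeny testing: a few hundred genotyped sires, each
with tens to thousands of phenotyped, ungenotyped progeny. This note
records the models, the synthetic-data generator, the numerical choices and
the problem sizes the test suite uses.

## The bivariate sire DHGLM

The core model is a double hierarchical GLM: a linear mixed model for the
trait mean coupled to a log-linear model for the residual variance,

```
y   = X b   + Z s   + e,      Var(e_ij)  = phi_ij
psi = X_v b_v + Z_v s_v + e_v,  phi = exp(X_v b_v + Z_v s_v)
```

with `(s_i, s_vi)' ~ N(0, G0)`, `G0 = [[s2_s, c],[c, s2_sv]]`, and the
genetic correlation `r_mv = c / sqrt(s2_s * s2_sv)`. Fixed effects in both
parts are contemporary group plus linear and quadratic age nested within
sex. The variance part's response is the linearised working variable

```
psi_ij = log(phi_ij) + e_ij^2 / ((1 - h_ij) phi_ij) - 1
```

where `h_ij` is the record's leverage in the mean part; each psi-record
carries the fixed residual variance `2/(1 - h_ij)` (the asymptotic
gamma-GLM value — no extra free dispersion is estimated for psi). The two
residual blocks are uncorrelated (block-diagonal residual structure).

Fitting alternates: (1) a joint solve of the stacked mixed-model equations
given `phi`; (2) rebuild `psi` and its weights from the new residuals and
leverages; (3) an EM-REML update of `G0`,
`G0 <- (S'S + sum_i PEV_i) / q` with `S = [s, s_v]` and `PEV_i` the sire's
2x2 prediction-error block from the inverse coefficient matrix; (4)
`phi <- exp` of the variance part's fitted values. EM keeps the variances
non-negative; if an update leaves the parameter space the 2x2 matrix is
bent back by flooring its eigenvalues at 1e-8 of the largest. With
`mode="rmv_zero"` the covariance is pinned at zero, the system becomes
block-diagonal, and the mean part is *exactly* a stand-alone weighted sire
LMM (a tested invariant). After convergence one extra solve is performed at
the final `phi` so the reported solutions, residuals, leverages and
variance components are mutually consistent.

Convergence: `max |delta log phi| < 1e-6` *and* relative change of every
component of `G0` below `1e-5`, up to 100 outer iterations. EM's tail
convergence is slow when `s2_sv` is near zero; a fit returned with
`converged=False` and a last delta of order 1e-4 is, for every practical
summary, converged. Initialisation: `phi` = variance of the
fixed-effect-adjusted trait, `s2_s = 0.05 Var(y)`, `s2_sv = 0.05 Var(psi)`
at the first pass, covariance 0.

Sire solutions are used directly as EBVs. The transmitting-ability
convention (EBV = 2s) is a global factor that cancels in deregression-based
GWAS ranking, so it is not applied.

## Response variables and deregression

Four per-sire GWAS responses:

* `dEBV_m`, `dEBV_v` — deregressed mean- and variance-part EBVs from the
  free-covariance fit;
* `dEBV_v_r0` — deregressed variance-part EBV from the zero-covariance fit;
* `lnvar` — natural log of the n−1 sample variance of the zero-covariance
  fit's mean-part residuals within each sire family (≥ 2 progeny required;
  degenerate families excluded). `lnvar` is deliberately *not* adjusted for
  contemporary-group effects on the variance; it is the "least processed"
  response and may carry non-genetic dispersion effects.

Deregression is the no-parent-information form: `dEBV = EBV / r^2` with
reliability `r^2 = 1 − PEV / s2` per part, and weight

```
w = (1 − h^2) / ((c + (1 − r^2)/r^2) h^2)
```

with `c = 0.5` by default (the fraction of genetic variance not captured by
markers; configurable). The heritability plugged into the weight comes from
the fit's own components through the sire-model identity
`h^2 = 4 s2_s / (4 s2_s + mean phi)` per part, not from literature values.
The edge case `r^2 = 1` with `c = 0` would give a zero denominator
(infinite weight); by convention the factor is then 1. Parent-average-aware
deregression is an extension point, not implemented: the synthetic sires
are unrelated founders.

## BayesC GWAS

Each response is analysed with a single-trait BayesC model
`y = 1 mu + sum z_i a_i delta_i + e`, `e ~ N(0, R sigma2_e)`, with
`pi = P(delta_i = 0) = 0.999` so that a 333,877-SNP panel admits about 334
nonzero effects. `R` is diagonal and known: `1/w_i` (deregression weight)
for dEBV responses, `1/n_i` (family size) for `lnvar`. Genotypes are
mean-imputed per SNP (the only place missing calls are filled) and centred;
no variance standardisation, so effects stay on the allele-substitution
scale. Scaled inverse chi-squared priors with `nu = 4` on both variances.

The Gibbs sweep samples `mu`; then, per SNP, the indicator from its
collapsed full conditional (effect integrated out) followed by the effect
given inclusion, maintaining the weighted residual incrementally (O(nM) per
sweep, numba-compiled); then the two variances. Thinned post-burn-in
samples (thin 50) feed the posterior inclusion probabilities (PIP),
posterior-mean effects and hyperparameter chains.

Prior scale defaults: `S_e = 0.5 Var(y)`; `S_a = 0.5 Var(y) / (M * mean
2p(1−p))` — the expected genic share spread over **all** M SNPs. Spreading
it instead over only the `M (1−pi)` SNPs expected nonzero makes the effect
prior so wide at `pi = 0.999` that the Occam factor in the collapsed update
suppresses inclusion far below the prior under null data, while SNPs that
chance-correlate with noise at |t| ≈ 3.5 reach Bayes factors near 100. The
/M convention keeps a pure-noise panel calibrated (mean PIP ≈ 1−pi, no
strong hits), which is the behaviour a fixed-π mixture scan needs; the
other convention is available by passing `s_a` explicitly.

Significance uses the Bayes factor `BF = (p/(1−p)) / (q/(1−q))` with `q`
the prior inclusion probability `1−pi`; BF > 3 is read as suggestive and
BF > 20 as strong. A PIP of exactly 1 is capped at `1 − 1/(n_kept+1)` (one
phantom excluded sample) so the BF stays finite; the cap is logged.

Convergence of the hyperparameter chains is monitored with a Geweke test
(first 10% vs last 50% of the chain, spectral density at zero estimated
with a Bartlett window of Newey-West width). Calibration (≈95% of i.i.d.
chains inside |z| < 1.96) is verified by simulation in the tests.

## Windows, overlaps, scale effects

1-Mb windows are `floor((bp − 1)/1e6)` on 1-based positions, labelled
`Chr<c>_<Mb>`. A window's share is `Var(Z_w a_w) / Var(Z a) * 100` over the
realised genotypes with posterior-mean effects (the total-genomic-value
denominator; a `denominator="window_sum"` variant forces shares to add to
100 — under linkage equilibrium the two agree to within a few percent, a
tested invariant). Top-K overlap (default K = 20) uses set semantics with
ties at rank K broken by (chromosome, window index).

The scale-effect test standardises a shared SNP's absolute effect on the
mean response by the trait mean and its effect on the variance response by
the mean residual variance; a strictly larger standardised variance effect
flags dispersion beyond mere mean-variance scaling.

## Genotype QC

Filter cascade, each SNP attributed to the first filter that removes it:
sex chromosomes (codes 30/31 by default) → per-sire call rate ≥ 0.90 → MAF
≥ 0.02 → Hardy-Weinberg 1-df chi-square p ≥ 1e-5 (monomorphic SNPs p = 1
by convention; the MAF filter catches them) → LD pruning, removing the
later SNP of any pair with r² > 0.99 within a sliding window of 100
consecutive retained SNPs per chromosome. The chi-square (not exact) HWE
test matches common chip-QC practice; the later-SNP tie-break is a
deterministic choice. There is no per-SNP call-rate filter. Pruning is
idempotent and the report's counts add up exactly.

## The synthetic-data generator

Per progeny j of sire i:

```
y_ij = mu + cg + beta1(sex) age + beta2(sex) age^2 + A_m[i]/2 + e_ij
e_ij ~ N(0, exp(eta0 + A_v[i]/2))
```

Defaults emulate yearling weight: `mu = 280 kg`, `eta0 = 6.3` (baseline
residual variance ≈ 545 kg², so the mean of `lnvar` sits near 6.3),
contemporary groups ~ N(0, 100 kg²) assigned uniformly, age ~ U(300, 420)
days with small sex-specific growth coefficients, family sizes log-uniform
on [50, 800] (right-skewed like real progeny counts; the full 50–10,180
range is reachable by configuration). Sire genotypes are binomial at
Hardy-Weinberg proportions with MAF ~ U(0.02, 0.5), in linkage equilibrium
(an optional block-LD mode copies neighbour columns with probability rho).

Genetic values are `A = Z a + u` on each scale with `Var(A_m) = sigma2_s`,
`Var(A_v) = sigma2_sv` (generator scale; a sire model sees a quarter of
each, since the sire transmits half his genetic value and Mendelian
sampling is absorbed into the residual). QTL positions are sampled without
replacement; by default the two scales share positions (pleiotropy) with
effect pairs correlated at `r_mv`, and the polygenic pair is drawn at
correlation `r_mv`, so the *total* genetic correlation targets `r_mv` for
any QTL fraction. (With disjoint QTL sets carrying half of each variance,
no polygenic covariance could reach a total correlation of 0.76 — the
configuration is available via `qtl_pleiotropy=False` but attenuates the
total correlation.) QTL effects are rescaled so the marked parts explain
`qtl_frac_*` of each variance exactly in-sample.

What the generator does **not** emulate: pedigree structure beyond
paternal half-sibs (no dams, no maternal effects), selection, genotyped
progeny, linkage disequilibrium beyond the optional copy-block mode,
contemporary-group effects on the *variance*, and genotyping error. Tests
passing on these data therefore show the estimators are correct under the
stated model, not that real yearling-weight data satisfy the model.

## Study regimes and problem sizes used by the tests

Three named designs (`sirevar.designs`) drive the end-to-end checks, at
sizes chosen so the whole suite runs on a single desk CPU in minutes:

* **recovery_design** — 500 sires × 80 progeny, sire-scale variance ratios
  0.05 on both parts, `r_mv = 0.76`; 4 replicates. The free-covariance fit
  recovers `r_mv` within ±0.15 and the dispersion variance within ±20%.
* **null calibration** — 423 sires × 2,000 unlinked SNPs, pure-noise
  response, chains of 20,000 (burn-in 4,000); 4 seeds. Mean PIP within
  [0.0005, 0.002] and no BF > 20.
* **variance_qtl_design** — 423 sires × 100 progeny, 1,000 SNPs, one
  log-variance QTL explaining 20% of Var(lnvar) (the QTL fraction that
  achieves this at family size n is `0.2 (1 + 8/((n−1) sigma2_sv))`);
  5 seeds. The top-BF SNP lands within 1 Mb of the QTL for both the
  `lnvar` and `dEBV_v_r0` responses in ≥ 4/5 seeds.
* **weak_variance_design** — 300 sires, 50–250 progeny, 500 SNPs,
  `r_mv = 0.76` with sire-scale dispersion variance 0.001 (the
  near-zero-heritability-of-variance regime reported for yearling weight);
  4 replicates. `corr(dEBV_m, dEBV_v) > 0.6` while
  `corr(dEBV_m, lnvar) ∈ (−0.25, 0.25)`, and the mean response shares more
  top-20 windows with `dEBV_v` than with `lnvar`. This pattern *requires*
  weak dispersion genetics: with a large `sigma2_sv` the log family
  variance inherits the genetic correlation and tracks the mean response.

`scripts/acceptance.py` reruns these designs from scratch (2 recovery
replicates, 1 null seed, 3 QTL seeds, 1 pattern replicate, plus the
window-additivity check at 2,000 sires) and writes the headline numbers as
JSON.

## Known limitations

* The DHGLM is a sire model; animal-model (pedigree) DHGLMs and the
  heritability-of-residual-variance transformations are out of scope.
* EM-REML is robust but slow near variance boundaries; no AI-REML
  acceleration is provided.
* The BayesC sampler fits an overall mean only; additional fixed effects
  belong in the DHGLM stage that builds the responses.
* Window variance uses posterior-mean effects (GenSel-style); a
  per-posterior-sample variant would propagate effect uncertainty into the
  window shares.
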