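# Methods

## Effect-size harmonization

Reported statistics are converted to Pearson correlations with the standard
meta-analytic formulas: `r = sqrt(t^2/(t^2+df))` for t statistics,
`r = sqrt(F/(F+df))` for F with one numerator df, `r = sqrt(chi2/n)` for a
1-df chi-square, `r = z/sqrt(n)` for a Mann–Whitney normal deviate, and
Pearson's bivariate-normal relation `r = 2 sin(pi rho / 6)` for Spearman
correlations (a passthrough is available where a compiler prefers to treat
rho as r). Signs come from the reported direction of effect; correlations
with latency to pairing or laying are then multiplied by −1 so that a
positive effect always means "more elaborate song, more reproductive
success". Records that supply only a p-value cannot be converted by these
formulas and are rejected by the loader; they must be pre-converted
upstream.

Fisher's transform `z = atanh(r)` stabilizes the variance at exactly
`1/(n-3)`, but at small n it is biased away from zero. By default the
package applies Hotelling's correction

```
z* = z − (3z + r) / (4(n − 1)),
```

a standard small-sample adjustment whose effect the test suite verifies by
simulation (at n = 10 the corrected mean is closer to `atanh(rho)` than the
raw transform). `bias_correct=False` reproduces the uncorrected convention;
the standard error is `1/sqrt(n-3)` either way.

Dataset assembly drops rows flagged as excluded, resolves each
(study, species, metric) pair that reports both a territory-controlled and
an uncontrolled value by keeping the one matching the requested mode, and
restricts to species with repertoire data or known song stability for the
`repertoire` and `stability` variants. A species' ln repertoire uses the
median of its literature-reported values by default; min and max are the
robustness variants. Measurements from fewer than 4 males are outside the
model's domain (the SE is undefined at n ≤ 3) and are rejected at
conversion.

## The multilevel model and its sampler

The response is the per-measurement Fisher's Z. Location structure:
fixed effects plus random intercepts for measurement type, species
(non-phylogenetic), study, and a phylogenetically structured species term
with covariance `sigma^2_Phylo * A`. The categorical stability model is fit
without a global intercept so each group's mean is read off directly.
Measurement error enters as a latent `m_i` with *fixed* variance
`s_i^2 = 1/(n_i - 3)`; a residual variance absorbs everything else.

Priors: each estimated variance component, including the residual, gets a
scalar inverse-Wishart IW(V, nu) — equivalently inverse-gamma — with
`nu = 1` and `V = Var(observed Z) / (#random terms + 1)`: the observed
effect-size variance split evenly across the components, held with minimal
confidence. Whether the residual should share this prior is not decidable
from the conventions the model family inherits; the package applies it
uniformly and exposes `residual_V` / `residual_fixed` overrides. Fixed
effects get zero-mean normal priors with variance 1e8.

Everything is conjugate, so the sampler is blocked Gibbs with exact
conditional updates and no tuning:

1. `(beta, all u)` jointly from its multivariate-normal full conditional
   *with the latent m integrated out* — marginally the noise is independent
   with variance `s_i^2 + sigma^2_res`, making this a GLS draw. Integrating
   m out matters: conditioning on m instead couples `beta` and `m` so
   tightly that mixing stalls as `sigma^2_res → 0` (the regime of the
   conjugate-oracle tests).
2. each `m_i` from its normal full conditional;
3. each `sigma^2_k` from inverse-gamma with shape `(nu + q_k)/2` and scale
   `(nu V + u_k' K_k u_k)/2`, where `K_k` is the identity or `A^{-1}`; the
   residual likewise from the `e = z − W theta − m` sum of squares, unless
   pinned.

Chains default to the published-analysis settings (200,000 iterations,
30,000 burn-in, thinning 10); because the sampler makes exact joint draws,
the analysis scripts and tests use far shorter chains (1,500–20,000
iterations) and verify adequacy through the R-hat column. Multiple chains
get independent streams spawned from the user seed. `A` is validated PSD
(tolerance −1e−8) and jittered by 1e−10 on the diagonal before inversion.

Summaries: posterior means; 95% highest-posterior-density intervals
computed as the shortest contiguous window of sorted draws (ties broken
toward the lower window); `p_MCMC` as the posterior tail mass across zero —
two-sided (twice the smaller tail) by default, with the one-sided
"fraction above zero" convention available, both floored at one over the
number of retained draws. Heterogeneity is reported per component as
`I2_k = 100 * mean(sigma^2_k) / (sum_j mean(sigma^2_j) + s2_typical)` with
the typical sampling variance `s2_typical = sum(w)(k−1)/((sum w)^2 − sum
w^2)`, `w_i = 1/s_i^2`. DIC uses the deviance conditional on the location
effects and variances, with measurement error marginalised into the
residual (`Var = sigma^2_res + s_i^2`); absolute DIC values are therefore
comparative only. R-hat is the classic potential-scale-reduction factor.
The posterior predictive check simulates replicate Z per draw from
`Normal(mu_i, sigma^2_res + s_i^2)`; being in-sample (the random effects
are fitted to the same data), its coverage runs at or above nominal.

## Phylogeny handling

Trees are read and written as Newick via dendropy. Rooting places the root
at the midpoint of the outgroup's subtending edge, optionally dropping the
outgroup afterwards (the order of consensus construction versus outgroup
removal is exposed rather than fixed). The consensus of a tree sample is
majority-rule on clades (threshold 0.5, configurable) with each retained
clade's edge length the arithmetic mean over the trees containing it;
terminal edges average over all trees; below-majority thresholds admit
candidate clades greedily by frequency. Pruning takes induced subtrees with
unifurcations collapsed and branch lengths summed.

The relatedness matrix assumes Brownian motion: the covariance of two tips
is the root-to-MRCA depth, `S_ij`. Because a mean-edge consensus need not
be exactly ultrametric, the matrix is normalised as a correlation,
`A_ij = S_ij / sqrt(S_ii S_jj)` — identical to "MRCA depth over total tree
depth" on an ultrametric tree, and guaranteeing a unit diagonal otherwise.
Rounding-level negatives are clipped at zero.

## Classical meta-analysis and funnel asymmetry

The random-effects meta-analysis estimates the between-study variance tau^2
by REML (Fisher scoring on the REML score, tolerance 1e−8, max 1,000
iterations, truncation at zero) or by the DerSimonian–Laird moment
estimator generalised to moderators; coefficients follow by weighted least
squares with weights `1/(se^2 + tau^2)`. Egger's test regresses the effect
on its own standard error *inside* the REML random-effects model — the
flavor the meta-analytic tooling this pipeline mirrors runs by default —
and reports the moderator's z with a two-sided normal p; a classical
fixed-weights variant sits behind `method="WLS"`. The Begg–Mazumdar test
standardizes effects against the fixed-effect pooled mean with variance
`v_i − 1/sum(1/v_j)` and computes tie-corrected Kendall tau against the
sampling variances; p-values are exact (null enumeration) for k ≤ 10
without ties and otherwise use the normal approximation with continuity
correction. By default the asymmetry tests consume the same
(bias-corrected) Z values as the Bayesian model.

## BEST group comparison

The two-group comparison follows the canonical Bayesian-estimation model:
Student-t likelihoods per group with separate means and scales and a shared
normality parameter, priors `mu_j ~ Normal(pooled mean, (1000 pooled SD)^2)`,
`sigma_j ~ Uniform(pooled SD/1000, 1000 pooled SD)`, `nu ~ 1 +
Exponential(mean 29)`. Sampling is Metropolis-within-Gibbs on `(mu_1, mu_2,
log sigma_1, log sigma_2, log(nu−1))` with Gaussian random walks whose
scales adapt toward ~40% acceptance during burn-in only. The model is
exchangeable in the groups, so the sampler canonicalizes their internal
order and relabels afterwards; swapping the inputs therefore negates the
difference draws exactly at a fixed seed. Inputs are measurement-level Z
values grouped by stability class (species-level aggregation is a caller
choice, not a package default). The decision rule — groups "different" only
if the posterior mass of the difference below zero leaves the 5–95% band —
is attached to the summary as a labeled verdict, never as the only output.

## Synthetic data: what it emulates, what it does not

The generator mirrors the structure of the compiled field data: a Yule tree
scaled to unit height; species repertoire sizes log-normal around ln-mean
3.5 (SD 1.5, truncated to [1, 7.5] — spanning roughly the e^1.6–e^7 range
of the studied species) with 1–3 scattered "literature reports" each;
stability classes ~30% stable / 55% plastic / 15% unknown; per species
1 + Poisson(0.6) studies, each with 1 + Poisson(1.15) measurements over the
seven reproductive-success metrics; per-measurement sample sizes uniform on
8–40 males. True effects are built on the Z scale from the model's own
variance structure (defaults: intercept −0.35, slope 0.15, component
variances 0.01–0.02) and mapped through tanh to a correlation; each
measurement then draws n bivariate-normal pairs and reports the sample
Pearson r (optionally re-expressed as a t statistic to exercise the
conversions). The defaults put ~86 measurements on 25 species, the shape of
the repertoire analysis dataset.

Passing tests on these data show the pipeline is *internally* correct and
calibrated — the generative model is exactly the fitted model. They cannot
show robustness to what real compilations contain: selective reporting,
correlations that are not bivariate-normal sample correlations,
repertoire-size measurement error correlated with study identity, or
misclassified song stability. Publication bias is deliberately not
simulated (the generator is the natural place to add it as a hook).

## Numerical and design choices

- Ties when excluding extreme-repertoire species break lexicographically by
  species name.
- Tree-uncertainty refits report per-tree results plus simple pooling
  (mean of posterior means, union of HPDs); no formal multi-tree posterior
  mixing is attempted.
- Jackknife refits recompute the data-derived prior scale V from each
  reduced dataset (consistent with V's definition); passing an explicit
  prior freezes it instead.
- The relatedness matrix is consumed directly and factorized internally;
  no user-facing inverse.
- Degenerate inputs fail loudly: |r| ≥ 1 conversions name the offending
  record, zero-variance effect sets refuse prior derivation, zero-depth
  trees refuse correlation matrices, rank-deficient designs refuse fitting.

## Known limitations

- Gaussian responses only; no multi-response or parameter-expanded models.
- The Egger REML flavor and the two p_MCMC conventions bracket, but cannot
  pin down, unstated conventions of the upstream tooling; both are exposed.
- Exact rank-test p-values are limited to tie-free rankings (k ≤ 10);
  tied rankings always use the corrected normal approximation.
- In-sample posterior predictive coverage exceeds its nominal level by
  construction; it is a misfit screen, not a calibration proof.
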