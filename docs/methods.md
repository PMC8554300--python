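# Methods

## Generating model

One replication of a design condition draws, for n persons:

- latent skill θ ~ N(0, 1) and covariate C with corr(θ, C) = φ = 0.30,
  jointly bivariate normal;
- k continuous congeneric indicators X*_j = λ_j θ + ε_j with independent
  normal residuals scaled so Var(X*_j) = 1;
- five-category ordinal items X_j by cutting X*_j at (−1.5, −0.5, 0.5, 1.5).
  These symmetric cuts give expected category proportions
  (.067, .242, .383, .242, .067) — a bell-shaped histogram. The cut values
  are a modeling choice of this package (the symmetric-histogram requirement
  does not pin them down uniquely);
- two outcomes Y₁ = 0.35·θ + 0.30·C + e₁ and Y₂ = 0.20·θ + 0.30·C + e₂,
  with residual variances 0.7245 and 0.834 chosen so Var(Y) = 1 exactly.
  The structural coefficients are likewise this package's calibration:
  skill-coefficient bias is essentially invariant to them (the attenuation
  factor of an errors-in-variables regression does not involve β), while
  covariate-coefficient levels do depend on the (β, γ) ratio, so those cells
  are interpreted conditionally on (0.35, 0.30)/(0.20, 0.30). With unit
  outcome variances the generating coefficients coincide with their
  population-standardized versions, which is what makes "percent bias"
  comparable across methods and conditions.

Both outcomes are generated for every sample because both serve as
background variables for the plausible-value conditioning model; each
condition analyzes only its designated outcome.

Loading vectors are fixed: high alternates (0.8, 0.7, …), low alternates
(0.5, 0.4, …), mixed tiles (0.9, 0.7, 0.6, 0.4). These are the simplest
vectors inside the stated ranges whose McDonald's ω
(= (Σλ)²/[(Σλ)² + Σ(1−λ²)]) reproduces all nine calibration values
(0.50–0.94) to two decimals. Many other vectors would; nothing downstream
depends on the within-scale ordering.

## Scoring machinery

**SMS.** Person means of the raw 1–5 responses, z-standardized with the
sample (n−1) standard deviation. The convention matters at O(1/n) only.

**CFA / RFS.** One-factor normal-theory ML on the sample covariance, factor
variance fixed at 1, ordinal items treated as continuous (deliberately — the
applied practice being studied). L-BFGS-B with an analytic gradient;
loadings start at 0.5, residuals at 0.75, residual floor 1e−4 (Heywood cases
are floored and flagged, not raised). RFS = Λ̂'Σ̂⁻¹x on column-centered
responses; the scores shrink (Var < 1).

**GPCM.** The generalized partial credit model is written in log-linear
form P(c|θ) ∝ exp(ξ_c + a·c·θ), which makes the EM M-step a concave Newton
problem. Estimation is marginal ML: rectangular quadrature with 41 equally
spaced nodes on [−6, 6] and renormalized N(0,1) weights; E-step posteriors
over nodes; M-step = three Newton steps per item, batched across items,
with per-item step halving to preserve ascent. Convergence: max parameter
change < 1e−4, cap 500 iterations. Categories unobserved in a replication
(possible at n = 300 with low loadings) are collapsed into their lower
neighbor, the fit is flagged, and scoring proceeds on the collapsed scale —
dropping such replications would bias the summaries.

**WLE / EAP / EBM.** The person log-likelihood depends on the response
pattern only through T = Σ_j a_j x_j, so scoring runs over unique values of
T. EAP is the posterior mean on the quadrature grid. WLE maximizes
log L + ½·log I(θ) (I = Fisher test information), EBM maximizes
log L + log prior; both use a 121-point grid scan followed by golden-section
refinement of the best node's ±0.1 bracket, bounded to [−6, 6]. Refinement
tolerance 1e−5 — an order of magnitude below the 1e−4 resolution of the
brute-force oracles the tests compare against. EBM here is the posterior
mode under the same fitted GPCM used for WLE/EAP; a limited-information
(WLSMV-style) categorical estimation stack is intentionally not maintained —
the property that matters for the bias comparison (EBM ≈ EAP ≈ RFS) is
preserved, and the tests verify it.

**Plausible values.** The conditioning model replaces the N(0,1) prior with
g(θ|c) = N(μ + β'c, σ²), c = (C, Y₁, Y₂) with intercept, no interactions.
Item and conditioning parameters are estimated jointly by EM. A fully free
joint model is unidentified (a location/scale shift of θ can be absorbed by
the item parameters), so after every M-step the latent metric is
renormalized to keep the marginal of θ at mean 0, variance 1 — the same
identification as the plain calibration, and the metric in which the
generating coefficients live. PV are drawn with parameters held fixed at
their ML estimates (the default behavior of the standard toolchain; a known
understatement of imputation-model uncertainty), as draws from the discrete
node posterior plus a uniform jitter within the node spacing. Ten PV per
person; per-draw regressions are pooled by Rubin's rules
(Q̄ = mean, T = W + (1 + 1/m)B).

**SEM.** Items load on θ (variance 1), corr(θ, C) free, Var(C) free,
Y = βθ + γC + e. Normal-theory ML discrepancy
F = log|Σ(ϑ)| + tr(SΣ⁻¹) − log|S| − (k+2), minimized by L-BFGS-B with an
analytic gradient from start values built from a CFA on the item block and
an OLS of Y on (scaled item mean, C). One restart from perturbed starts on
failure. Plain ML rather than a robust (MLR) variant: robust corrections
change standard errors, not the point estimates that the bias outcome is
made of. The exact model-implied population covariance is a zero-discrepancy
fixed point, which the tests verify to optimizer tolerance.

## Study orchestration

Replication seeds follow seed(condition, rep) = base·10⁶ + id·10⁴ + rep,
fed to counter-based Philox generators, so conditions are independent
streams and any run is bit-reproducible. The PV stream is a hashed offset of
the replication seed (kept below 2³¹). Per replication the engine computes
all requested scores, runs OLS of the condition's outcome on (score, C),
pools the PV regressions, fits the SEM, and records percent bias of both
coefficients against the generating (β, γ). Replications where a method
errors out are excluded from that method's average and counted;
non-converged-but-usable fits are included and counted as flagged; a
condition aborts if more than 10% of replications fail outright. Score
correlation matrices (5 scores + 2 outcomes) are averaged across
replications, then across conditions, without a Fisher-z transform.
Standardized-coefficient variants (coef × sd(score)/sd(Y)) are recorded for
EBM/RFS/WLE/EAP alongside the raw ones.

## Problem sizes and Monte-Carlo error

The full design at its original scale (500 replications) reproduces but is
slow on one CPU; the package's reference scale — used by the test suite and
`scripts/acceptance.py` — is 100 replications per condition, about ten
minutes for all 36 conditions with every method. At that scale a cell-level
mean percent bias carries a standard error of roughly sd/10, i.e. 1–1.5
points for SMS/WLE (per-replication sd ≈ 10–13) and up to 2.5–4.5 points
for PV and SEM in the weaker/low-loading/n=300 cells, where the
per-replication sd of percent bias reaches ~45% (sd(β̂) ≈ 0.09 against
β = 0.20). Consequences worth keeping in mind:

- cell-level comparisons use a ±2.5-point band;
- a *maximum* of |mean bias| over 36 conditions is, for the near-unbiased
  methods (SEM, PV), a noise-dominated statistic: even for an exactly
  unbiased estimator its expectation at 100 replications is several points,
  and no feasible replication count brings it under ~1 point. The per-cell
  estimates themselves are clean (the β̂ distributions are symmetric,
  outlier-free, with means within a couple of points of zero); it is the
  max-statistic that inflates.

## What the generator does and does not emulate

It emulates: short unidimensional rating scales with heterogeneous loadings,
5-point ordinal responses with a symmetric bell-shaped margin, a modestly
correlated covariate, and outcomes with realistic effect sizes. It does not
emulate: missing data, non-normal latent distributions, asymmetric category
usage, non-classical measurement error, multidimensional inventories, or
survey weights. Passing tests therefore speak to attenuation/inflation
mechanics under a correctly specified unidimensional model, not to
robustness against those complications.

## Known limitations

- The GPCM is fitted to data generated by categorizing a linear factor
  model, so the measurement model is (mildly) misspecified by construction —
  exactly as in the practice being simulated; discriminations are therefore
  not algebraic transforms of the loadings, though the rank order is
  preserved.
- PV draws condition on estimated, not drawn, parameters; between-imputation
  variance understates parameter uncertainty slightly.
- The SEM reports no fit indices and no robust standard errors; only the
  structural point estimates feed the study outcome.
- 41-node rectangular quadrature limits posterior accuracy to ~0.01 in θ
  for extreme response patterns; immaterial for bias means, visible if one
  inspects individual scores beyond |θ| ≈ 4.
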