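# Methods

## Model

Stage-1 effect estimates for the `K` retained candidates are modelled as
one draw `X = (X_1, ..., X_K) ~ N(mu, V)` with `V` known and positive
definite, `V_ii = sigma_i^2`.  For log odds ratios this normality is
asymptotic; all theory here holds in the same asymptotic sense.  The
candidates are listed in the rank order produced by the selection rule,
and the analysis conditions on that *observed* outcome of selection:

* `effect`: `X_1 >= ... >= X_K` (no threshold);
* `p_one_sided`: `X_1/sigma_1 >= ... >= X_K/sigma_K >= Phi^-1(1 - p_crit)`;
* `p_two_sided`: `|X_1|/sigma_1 >= ... >= |X_K|/sigma_K >= Phi^-1(1 - p_crit/2)`.

Stage-2 estimates are independent normals, `Y_j ~ N(mu_(j), tau_j^2)`,
independent of `X` given the ranking.  The estimand for rank `j` is the
true mean of whichever candidate was observed at rank `j`.

## The conditional estimator

`Z_ij = X_i + (V_ij/tau_j^2) Y_j` (i = 1..K) is complete and sufficient
for `mu`.  Rao–Blackwellizing the unbiased `Y_j` gives the UMVCUE
`U_j = E(Y_j | Z, event)`.  Given `Z`, the law of `Y_j` unconditioned on
the event is `N(m, s^2)` with `m = tau_j^2 Z_jj/(sigma_j^2 + tau_j^2)`
and `s = tau_j^2/sqrt(sigma_j^2 + tau_j^2)` (only the `j`-th component of
`Z` enters, because `V^-1 v_j = e_j` for the `j`-th covariance column
`v_j`).  The event restricts `Y_j` to the set where the implied stage-1
vector `X_i(y) = Z_ij - (V_ij/tau_j^2) y` still satisfies the rule.  Each
constraint is linear in `y`:

* neighbour ordering (effect / one-sided): one half-line per adjacent
  pair;
* two-sided ordering: `|X_i|/sigma_i >= |X_{i+1}|/sigma_{i+1}` factors
  into (difference >= 0 and sum >= 0) or (difference <= 0 and sum <= 0) of
  two linear functions — a union of at most two intervals per pair;
* threshold: a half-line (one-sided) or a two-tailed union (two-sided) in
  the implied `X_K(y)`.

Intersecting across pairs yields a disjoint union of `M >= 1` closed
intervals, and `U_j` is the mean of `N(m, s^2)` truncated to that union.
For `K = 2` with effect ordering this collapses to a closed form with
three branches in the sign of `sigma_1 - rho*sigma_2`; at equality the
constraint is free of `y` and the UMVCUE *equals* the precision-weighted
MLE.  The closed form is kept as an independent code path and the general
machinery is required (by test) to agree with it to 1e-10.

### Numerical choices

* **Linear constraints are solved symbolically** by the sign of the slope
  — never by root finding.  A slope is declared zero at absolute tolerance
  1e-12 on the scale of the constraint coefficients (`max|v|/tau^2`,
  divided by the smallest sigma for z-score rules); exact cancellation
  occurs only at `sigma_i/sigma_j = rho`-type degeneracies, where the
  constraint is checked rather than solved.  A violated y-free constraint
  raises: it means the data never satisfied the selection event.
* **Intervals are closed**; the conditional law is continuous, so the
  boundary convention cannot change any value.  Canonicalization merges
  intervals overlapping within 1e-14 of the endpoint scale (floating-point
  seams from intersecting many half-lines).
* **Tail arithmetic** uses `erfcx`: each interval's phi/Phi contributions
  are scaled by the dominant Gaussian exponent of the whole union, with
  tail masses written as `0.5*erfcx(w/sqrt2)*exp(c - w^2/2)` so that all
  exponents are non-positive.  Estimates remain exact for standardized
  endpoints |W| in the hundreds; the bundled GWAS data (z up to 7.4, where
  naive Phi-differences already lose all precision) sits well inside this
  range.  If the scaled denominator is still non-positive the estimator
  raises with the W-values rather than returning a clamped or NaN value.
* **Ties** in the observed ranking are kept in input order with a logged
  warning (the model is continuous, so exact ties indicate rounded
  inputs); event verification uses the non-strict inequalities of the
  event definitions with relative slack 1e-9.
* When no correlation source is supplied, `V = diag(sigma^2)` is assumed
  and logged prominently.

## Oracles

Two independent ground-truth routes back every estimator path:

* a quadrature oracle that integrates `y * phi((y-m)/s)` against the *raw
  event predicate* (re-ranking the implied stage-1 vector), locating
  predicate flips by bisection — it shares no code with the interval
  algebra and agrees with the estimator to ~1e-14 in practice (1e-6
  asserted over 600 random instances, |rho| up to 0.95, K up to 6);
* a Monte-Carlo simulator of the full two-stage process (correlated
  stage-1 draws, ranking, thresholding by rejection, stage-2 draws) used
  for selection-conditioned sampling checks and a smoke-level
  Rao–Blackwell identity test.

## Simulation engine

The bivariate study conditions are fixed at `sigma_1 = 0.05`,
`sigma_2 = 0.1`, with four scenarios: means `(0.1, 0.1)` or `(0.1, 0.3)`
crossed with stage-2 SD `tau = 0.05` or `tau` *matched* to the winner's
stage-1 SD (the pairing under which the stage-2 estimator's
selection-conditioned MSE is exactly
`sigma_1^2 Phi(d) + sigma_2^2 (1 - Phi(d))`,
`d = (mu_1-mu_2)/sqrt(sigma_1^2+sigma_2^2-2 rho sigma_1 sigma_2)`).
Bias and MSE are selection-conditioned: each replicate is scored against
the true mean of its stage-1 winner, the Monte-Carlo form of weighting
conditional errors by the probability of each candidate winning.  Default
20,000 replicates per correlation grid point keep a desk-scale runtime
while giving Monte-Carlo SEs of ~4e-4 on the bias, ample for the
qualitative structure asserted in tests: the correct-correlation UMVCUE
and the stage-2 estimate unbiased at every rho; the independence-assuming
UMVCUE positively biased for rho < 0 and negatively for rho > 0; MSE
ordered MLE <= UMVCUE <= stage-2 everywhere, with the UMVCUE's MSE
dipping to the MLE's where `sigma_1 = rho*sigma_2`.

## Bootstrap confidence intervals

For a pair of same-region candidates with ranks `(j1, j2)` and assumed
correlation `rho`, the three-step parametric bootstrap treats the
observed UMVCUEs as the truth: (1) draw the pair's stage-1 values from
the bivariate normal centred at the UMVCUEs, conditional (by exact
rejection) on the pair staying inside its observed rank sandwich — the
adjacent observed `|x|/sigma` values bound each member, with the mutual
ordering constraint replacing the inner bounds when the pair is
rank-adjacent; (2) draw stage-2 values independently, centred at the
UMVCUEs with SD `tau_j` by default (`stage2_sd="sigma"` switches to the
stage-1 SE — the `tau` default is the model-consistent choice and the one
that reproduces the published stage-2 interval); (3) recompute each
estimator with all other candidates' observed values fixed.  The
`alpha/2` and `1-alpha/2` empirical quantiles (Hyndman–Fan type 7, linear
interpolation) of the `B` replicates form the interval.  Acceptance rates
are reported; the run aborts if the rate falls below
`1/max_rejection_factor`.

## Synthetic data

The generator emulates the scan-plus-replication pipeline: `K_total`
candidates with point-mass, per-candidate, or spike-mixture true effects;
equicorrelated LD blocks tiling the panel; stage-1 draws from the full
covariance; threshold-and-rank selection; stage-2 draws for survivors.
The covariance handed to the estimators is the exact survivor sub-matrix
of the generating covariance — matching the known-covariance assumption —
with optional symmetric noise for robustness experiments (off by
default).  It does not emulate genotype-level sampling, allele
frequencies, case/control imbalance, or covariance *estimation* error, so
passing recovery tests demonstrate correctness under the model, not
robustness to a misspecified `V`.

## The bundled dataset and what reproduces

The bundled table is the printed two-stage Crohn's disease summary: 11
SNPs as ORs with 95% CIs, at 2 decimal places, ranked by stage-1
significance.  Conversion assumes symmetric log-scale CIs with
`z = 1.959964` (the printing multiplier is not stated; 1.96 is the
conventional choice).  Two pairs share a chromosomal region (ranks 1–2 on
5p13, ranks 5–7 on 5q33); external genotype correlations (-0.28 and 0.78
in 1000 Genomes Europeans) are bundled as sensitivity-analysis inputs
only, never defaults.

Two consequences of the 2-dp rounding matter:

* The z-scores implied by the printed CIs run 7.41 down to 4.06, so the
  scan's genome-wide threshold cannot have been as strict as the printed
  values suggest; the reproduction default is `p_crit = 1e-4`, the
  weakest two-sided screen the printed rank-11 z-score clears.  For this
  dataset the threshold constraint involves only the last-ranked SNP,
  which is uncorrelated with every estimation target, so every reported
  estimate is identical under any `p_crit` at which the event holds.
* The rank-1 estimate sits where the truncated-normal mean is steep in
  the rank-2 z-score (`W ~ -2.3`): perturbing that z-score by the 2-dp
  rounding noise of the CI moves the rank-1 OR by ~0.02.  From the
  printed inputs the pipeline gives 1.19 (independence) and 1.29 (at
  rho = 0.88) for the top SNP versus the published 1.16 and 1.32 computed
  from unrounded allele-frequency data; ranks 2 and 5 reproduce to 1.37
  and 1.40 (published 1.39, 1.40), and the bootstrap intervals shift by
  the same centre offset.  The estimator itself is verified against the
  independent quadrature oracle to 1e-14 on the same inputs.

## Known limitations

* Stage-2 correlation is ignored (independent `Y_j`), as is any
  uncertainty in `V` — both are assumptions of the underlying theory.
* Bootstrap intervals are implemented for a correlated *pair* (which
  covers regions with two SNPs in LD); a general simultaneous K-candidate
  bootstrap is out of scope.
* Confidence-interval coverage is bootstrap-nominal, not exact.
* The `effect` ordering with heterogeneous SEs, and `K > 2` candidates in
  mutual LD, are fully supported by the estimator but exercised only by
  randomized tests, not by a published benchmark.
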