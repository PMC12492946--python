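# Methods

## The model

Daily feed intake (trait 1) of animal *i* on batch-day *d* and a
single-record production trait (trait 2) are modelled jointly:

```
y1_id = x1'β1 + a10_i + p_d a11_i + pe10_i + p_d pe11_i + e1_id
y2_i  = x2'β2 + a2_i + pe2_i + e2_i
```

The covariate `p_d ∈ [0,1]` is the estimated probability that an
unrecorded environmental challenge occurred on that batch-day. It enters
uncentred: `p = 0` is the non-challenging reference environment, so `a10`
is interpretable as merit under good conditions and `a11` as
environmental sensitivity. Random effects: `(a10, a11, a2) ~ N(0, K ⊗ H)`
with H the pedigree/genomic relationship matrix; permanent-environmental
triples iid `N(0, T)`; residuals independent with trait-specific
variances `Q = diag(σ²e1, σ²e2)`. The residual covariance between traits
is structurally zero — the two traits are never observed at the same
time — but a non-zero environmental covariance is still accommodated
through the permanent-environmental block of T (an animal's non-genetic
peculiarity can affect both its feed-intake curve and its single-record
trait). The plain animal model (AM) used as the null drops the two slope
effects, collapsing K and T to 2×2.

## Stage 1: the challenge-probability descriptor

Within each batch-day with at least `min_animals = 5` records (the CV of
fewer observations is too unstable to classify a day), the CV is the
sample standard deviation (n−1 denominator) over the mean of DFI across
animals. Log CVs pooled over all batches are fitted with a two-component
univariate Gaussian mixture by EM: initialization splits the data at the
median, plus 9 randomly perturbed restarts; component standard deviations
are floored at 1e-4 to prevent collapse onto a point mass; components are
stored with means ascending so "component 2" is always the high-CV
(challenge) one. Days are unweighted in the fit regardless of how many
animals contributed to their CV. The descriptor is the posterior
probability of component 2 at the day's log CV.

The presence of two components is tested by a plain parametric-bootstrap
likelihood-ratio test: the statistic is twice the gap between the
2-component EM log-likelihood and the single-Gaussian MLE; its null
distribution is built by refitting both models on samples drawn from the
single-Gaussian MLE, with `p = (1 + #{boot ≥ obs}) / (B + 1)`. No
penalized EM-test variant is attempted. The same EM settings are applied
to the observed and bootstrap datasets so the comparison stays calibrated
even at loose tolerances.

## Stage 2: REML

All likelihood quantities go through the mixed-model equations (MME), so
cost scales with the number of animals, not records:

```
-2 l_R = (n − p) ln 2π + ln|R| + ln|G| + ln|C| + y'Py
```

with C the full MME coefficient matrix, `ln|G| = n_a ln|K| + k ln|H| +
n_pe ln|T|`, and `y'Py = y'R⁻¹y − rhs'·sol`. The data cross-products
(`W'W` per trait, `W'y`) are assembled once from a sparse design and
reused across iterations; only the variance structure added to them
changes. A dense Cholesky of C provides the determinant and solutions;
its inverse provides the trace terms for EM updates and score equations.
Equality of this MME form with the textbook dense-covariance REML formula
is asserted to 1e-6 on small instances in the test suite, which is the
package's primary correctness anchor.

The maximizer takes average-information (AI) steps on the (co)variance
entries directly, with safeguards:

* **Levenberg–Marquardt damping.** The AI matrix is nearly singular along
  weakly identified directions — most prominently the split of the
  single-record trait's variance between `σ²pe2` and `σ²e2`, which the
  likelihood separates only through the cross-trait permanent-environmental
  covariances. An undamped Newton step explodes along such ridges, so the
  step is solved with escalating diagonal damping until it improves the
  restricted likelihood; the damping that worked last is tried first on
  the next iteration.
* **EM fallback with over-relaxation.** When every damped AI candidate
  fails (typically when the optimum sits on the boundary of the PSD cone,
  e.g. a slope variance of zero or a permanent-environmental correlation
  of ±1), the iteration falls back to an EM-REML update, which provably
  never decreases the restricted likelihood. Because EM approaches
  boundaries geometrically, a 4× extrapolation of the EM step is also
  tried and kept when it pays.
* **PSD handling.** Candidate K and T are projected to the PSD cone with
  an eigenvalue floor of 1e-8 of the largest eigenvalue — large enough to
  keep the MME conditioned (condition number of a block ≤ ~1e8), small
  enough that boundary solutions are represented faithfully. Residual
  variances are floored at 1e-6 of the trait's phenotypic variance for
  the same reason.
* **Stopping.** Primary rule: largest relative change of any variance
  component below `tol` (default 1e-8). Secondary rule: two consecutive
  iterations improving the restricted log-likelihood by less than
  `loglik_tol` (default 1e-3; heavy simulation studies in the test suite
  use 2e-2). The secondary rule exists because parameters on a flat ridge
  drift indefinitely while the likelihood — the only thing the ratio test
  and the reported correlations depend on at that point — is finished.
  Fits stopped this way are flagged converged, with per-component
  boundary indicators, and `pe2_profile_flatness` reports the likelihood
  drop from shifting 5% of `σ²e2` into `σ²pe2` so users can see how flat
  that ridge is. A hard bound on `σ²pe2` is deliberately not imposed by
  default.

The reaction-norm fit is warm-started from the converged animal-model fit
with a tiny seeded slope variance (1% of the intercept variance), so the
nested fit starts essentially at the null optimum and the ratio-test
statistic cannot go materially negative; residual negatives within 0.5
(flat-ridge stopping noise) are clamped to zero, larger ones raise.

The ratio test refers `χ² = (−2lnL_AM) − (−2lnL_RNAM)` to the mixture
`0.5·χ²₅ + 0.5·χ²₇`, the published convention for this boundary null. The
null removes six parameters (two variances, four covariances), which the
5/7 mixture does not match exactly; the printed convention is followed
as-is rather than re-derived.

## Relationship matrices

Pedigree A uses the tabular method with inbreeding. SNP QC removes, in
order, SNPs with call rate < 0.90, minor allele frequency < 0.05, and a
1-df chi-square Hardy–Weinberg goodness-of-fit P < 0.05 (each SNP is
attributed to the first rule it fails; the reference evaluation's QC tool
does not document its internal HWE test, so the plain chi-square is
used). G is VanRaden's first method with observed allele frequencies and
per-SNP mean imputation of missing calls, rescaled (tuned) so its mean
diagonal and off-diagonal match the pedigree A22, then blended
`0.95·G + 0.05·A22` to guarantee invertibility; all three choices follow
common single-step practice and are arguments, since the reference
evaluation does not print its G construction. `H⁻¹ = A⁻¹ + [[0,0],[0,
G⁻¹ − A22⁻¹]]` with τ = ω = 1.

## The synthetic-data generator

The generator emulates a nucleus test station: batches of contemporaries
(defaults: 20 batches × 25 animals × 50 recorded days — desk scale,
chosen so a full REML study runs in minutes; the study population was
~74 batches averaging 47 animals × 64 days), a shallow random-mating
pedigree, gene-dropped SNP genotypes, batch fixed effects, and phenotypes
drawn exactly from the model above with the pedigree A as the genetic
kernel (H reduces to A when no genotypes are supplied, so the generating
kernel is exactly known). Default (co)variance magnitudes are the
reference DFI–AGE estimates; the mean DFI of 2.36 kg/day and trait means
match the reference population. Challenge states are iid
Bernoulli(0.3) across batch-days; each day draws a log-CV target from the
corresponding mixture component (means −1.5 and −0.5 on the log-CV scale,
SDs 0.2 and 0.25, chosen to reproduce the reported CV range of roughly
0.10–1.31), and `true_p` is the exact Bayes posterior at that draw — the
quantity the descriptor stage is later scored against.

One generating choice deserves emphasis. At realistic magnitudes the
reaction-norm slope alone moves the within-day standard deviation only
from ~0.49 (p = 0) to ~0.63 (p = 1) — far too little to make the log CV
bimodal, yet a strongly bimodal day CV is the empirical signature the
descriptor relies on. Real challenge days inflate within-day residual
variation directly. The generator therefore has two modes:

* `day_cv_calibration=True` (default): each day's residual variance is
  scaled so the realized within-day CV tracks the day's mixture draw.
  This emulates real data and is what descriptor-recovery checks use. The
  heteroscedasticity it introduces is invisible to the fitted model's
  mean structure but inflates the apparent residual variance, so it is
  not the mode for estimator validation.
* `day_cv_calibration=False`: homoscedastic residuals — the data are
  generated exactly from the fitted model, as parameter-recovery studies
  require.

Consequently, passing descriptor tests say the mixture machinery recovers
a latent day-level signal of the stated separation; they do not certify
the size of that separation in any real herd. Passing recovery tests say
the REML machinery is consistent for the model it fits; they do not test
robustness to day-level heteroscedasticity beyond what the calibrated
mode induces.

For pipelines analysing several traits against the same DFI records,
additional single-record traits are drawn from their exact conditional
distribution given the already-drawn intercept and slope effects
(matrix-normal conditioning under the Kronecker structure), using each
pair's reference covariances, so one simulated population serves all
pairs coherently.

## Scale of the shipped validation studies

The test suite's recovery study runs 5 replicates per scenario at 500
recorded animals × 50 days (100-founder pedigree), checking that mean
REML estimates of the six genetic (co)variances and the DFI residual
variance fall within two empirical standard errors of the generating
values, that the ratio test rejects the null in all replicates when the
generating slope variance is 0.087, and that at most one in five rejects
when it is zero (the sharpest near-nominal bound a 5-replicate binomial
supports). Oracle-equivalence checks run on ≤ 15-animal instances where a
dense-covariance evaluation is exact and cheap.

## Known limitations

* No heterogeneous residual variance along the gradient, no quadratic
  reaction norms, no Bayesian sampler.
* `σ²pe2`/`σ²e2` for single-record traits is weakly identified by design;
  interpret the split (not the sum) with caution and check
  `pe2_profile_flatness`.
* The dense-Cholesky MME is comfortable to a few thousand animals; it is
  not an APY-scale implementation.
* The bootstrap component test is a plain parametric-bootstrap LRT; its
  null distribution is simulated, not asymptotic, so its runtime scales
  with `n_bootstrap`.
* The generator does not simulate selection across generations, litter
  structure, feeder visits within a day, or growth curves; DFI is
  generated directly at the daily level.
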