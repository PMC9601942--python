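# Methods

## Model and design

A two-level step-stress accelerated life test with two independent competing
failure causes. Lifetimes from cause `j` at stress level `i` are exponential
with rate `λ_ij`; the observed lifetime is the minimum of the two latent cause
lifetimes, and the cause label is recorded. The design is progressive Type-II
censoring: `n` units start at stress 1; at the `i`-th observed failure `R_i`
survivors are withdrawn; after `N1` failures the stress is raised and the test
continues to `N1+N2` failures, with `N1 + N2 + ΣR_i = n`.

Two modeling choices deserve emphasis:

* **Stress-change trigger.** The change time `τ` is the `N1`-th observed
  failure time (a failure-count trigger), not a prefixed clock time. This is
  the reading under which the likelihood's exposure decomposition is exact.
* **Cumulative exposure model.** Stage-2 lifetime distributions are the
  stage-1 distributions time-shifted so the accumulated failure probability
  matches at `τ` (`a_j = (1 − λ_1j/λ_2j)τ`). With exponential margins this is
  equivalent to memoryless restart of survivors at the stage-2 rates, which is
  what both the likelihood and the simulator use.

The likelihood factorizes through the sufficient statistics `n_ij` (failure
counts by stress × cause), `T1 + T21` (total time on test at stress 1,
including withdrawals and the pre-τ exposure of stage-2 survivors), and `T22`
(total time on test at stress 2).

## Simulator

The gap-rate construction: with `m` units at risk and total stage rate `θ_i =
λ_i1 + λ_i2`, the next inter-failure gap is Exponential(`m·θ_i`), the cause is
1 with probability `λ_i1/θ_i` independent of the gap, and removed survivors
are exchangeable, so no unit identities are tracked. This is exact (not
approximate) for the stated model and costs O(N1+N2) per dataset. Two exact
distributional consequences, used as test oracles:
`θ_1(T1+T21) ~ Gamma(N1, 1)`, `θ_2·T22 ~ Gamma(N2, 1)`, independent of
`n_i1 ~ Binomial(N_i, λ_i1/θ_i)`. Replications use counter-based child seeds
`SeedSequence((seed, r))`, so streams are collision-free and order-independent.

The simulator emulates exactly the idealized model: exponential margins,
instantaneous memoryless restart at τ, fixed removal schedule, no measurement
error, no tied times, independent causes. Passing tests therefore validate the
estimators under the model's own assumptions; they say nothing about
robustness to dependent causes, non-exponential lifetimes, or random removals,
all of which are out of scope.

## Estimators

* **MLE** `λ̂_1j = n_1j/(T1+T21)`, `λ̂_2j = n_2j/T22`; a cell with `n_ij = 0`
  yields an undefined entry (flagged `None`, never silently zero) so study
  code can count failed replicates. Observed information is diagonal with
  variance `λ̂²/n`.
* **Conjugate Bayes.** Gamma(α, β) priors give Gamma(n+α, β+T) posteriors.
  Squared-error loss → posterior mean `(n+α)/(β+T)`; entropy loss →
  `(n+α−1)/(β+T)` (undefined unless `n+α > 1`); LINEX loss with curvature `k`
  → `((n+α)/k)·ln(1 + k/(β+T))`, the exact negative-log Laplace transform.
* **E-Bayes.** The conjugate estimator averaged over a hyperprior on
  `(α, β) ∈ (0,1)×(0,c)`: uniform density `1/c`, or linear density `2β/c²`
  favoring larger β (thinner prior tails). All six loss × family combinations
  have closed forms, each verified against brute-force 2-D quadrature to
  better than 1e−8 relative error.
* **Hierarchical Bayes.** The posterior under the mixture prior. Every
  functional is a ratio of double integrals of the hyperparameter marginal
  likelihood `w(α,β) = Γ(n+α)β^α / (Γ(α)(β+T)^{n+α})` against the hyperprior.

### Formula dialects

Two printed closed forms are inconsistent with the stated Gamma(n+α, β+T)
posterior: the LINEX coefficient appears as `(n+α−1)/k` where the Laplace
transform yields `(n+α)/k` (and correspondingly `2n−1` vs `2n+1` in the
E-Bayes averages), and the hierarchical integrands carry exponent `n+α−1` on
`(β+T)` where the gamma integral forces `n+α`. The mathematically consistent
forms are the default (`dialect="corrected"`); `dialect="paper_literal"`
reproduces the printed ones. Because `β ∈ (0, c)` with `c ≪ T` in all standard
settings, the hierarchical off-by-one nearly cancels in the ratio (observed
difference < 1% at `c = T/18`).

## Numerics

* **Hierarchical quadrature.** Tensor Gauss–Legendre on `(0,1)×(0,c)`,
  64×64 nodes by default, with all weights in log space (log-gamma +
  log-sum-exp; no overflow up to `n = 10⁴`, `T = 10⁶`). The β axis uses the
  graded map `β = c·u²`: the integrand's `β^α` factor has an algebraic
  endpoint singularity at `β = 0` that reduces plain Gauss–Legendre to ~1e−8
  accuracy, while the graded map restores ~1e−11 node-doubling agreement.
  Every estimate is verified by node doubling to a relative tolerance
  (default 1e−8), with an error raised after two failed doublings.
* **Entropy loss at n = 1.** The integrand `(β+T)/(n+α−1)` appears singular at
  `α → 0`, but the `1/Γ(α)` factor in the weight cancels it; the combined
  log-space evaluation is smooth.
* **Posterior sampling.** Conjugate and E-Bayes posteriors are sampled
  exactly (gamma draws; hyperprior mixture by composition, with the linear-β
  family drawn by inverse CDF `β = c·√U`). The hierarchical posterior is
  sampled by self-normalized importance resampling of hyperprior draws
  (4× oversampling), which is exact up to Monte-Carlo error because the
  weight surface is bounded on a 2-D box; an effective-sample-size warning
  guards degeneracy.
* **Intervals.** Equal-tail credible intervals take the `⌈Nγ/2⌉`-th and
  `⌈N(1−γ/2)⌉`-th order statistics (1-based, with float-noise-tolerant
  ceilings). HPD intervals sweep all windows of `⌈(1−γ)N⌉` order-statistic
  span and return the narrowest, ties broken toward the lowest window — by
  construction never wider than the equal-tail interval. Bootstrap-p uses the
  same order-statistic convention on refitted parametric resamples;
  bootstrap-t studentizes each resample by its own plug-in standard error.
  Bootstrap resamples with an empty count cell are redrawn (logged), which
  slightly biases intervals at very small `N1, N2`. Asymptotic intervals are
  reported untruncated (the symmetric normal formula); a flag clips at zero.

## Small-c behavior

As `c → 0` the hierarchical and E-Bayes estimates do **not** coincide: the
marginal likelihood's `β^α` factor concentrates the hyperposterior at
`α → 0` (mass ∝ `e^{α ln c}`), so the hierarchical squared-error estimate
descends toward `n/T`, while the E-Bayes average ignores the data in the
hyperparameters and stays near `(n+½)/T`. The approach is logarithmically slow
in `c`. This is a genuine property of hierarchical shrinkage, verified against
the importance-sampling oracle, and the tests assert it.

## Study driver and defaults

`run_study` simulates replicated datasets per scheme, applies the requested
estimators and interval methods, and reports AE (mean estimate), MSE, AL
(mean interval length), and CP (coverage) per cell, excluding per method the
replicates with undefined estimates (counted in diagnostics). Defaults mirror
the standard study conditions: true rates (2, 1, 4, 2), 1000 replications,
`c = 0.2`, LINEX `k = 4`, 95% level, `B = 1000` bootstrap resamples, `N =
1000` posterior draws, and a diffuse Gamma(0.5, 0.1) prior for the plain-Bayes
columns (the conjugate analysis needs *some* hyperparameters; these are
illustrative, not canonical). The acceptance script uses 1000 replications of
the 40-unit design — enough for ~0.02 Monte-Carlo standard error on the
stage-1 averages — and coverage tests use `B = 200` resamples, which leaves
percentile endpoints slightly noisier but unbiased.

## Known limitations

* Two stress levels and two causes only; no stress-life extrapolation to use
  conditions.
* Independent causes; dependent-cause (copula) models are out of scope.
* Type-II (failure-count) censoring only; no time or hybrid censoring, no
  random removals.
* The exact sampling distribution of the MLE under this design
  (`E[λ̂_1j] = N1 p_j θ1 /(N1−1)` etc.) implies some published Monte-Carlo
  table values cannot be matched by any correct implementation; the package
  reports what the model actually yields.
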