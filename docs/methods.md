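# Methods

This note records the statistical machinery behind `rbroc`, the defaults
it ships with and why, the numerical choices that matter, and what the
synthetic data used in the test suite can and cannot establish.

## Relative belief inference

All inferences derive from one principle: evidence in favor of a value ψ
is an increase of belief, RB(ψ|x) = π(ψ|x)/π(ψ) > 1.  The engine
(`rbroc.rb_core`) works from Monte Carlo samples:

* **Continuous quantities** (AUC, rates, cmod-transformed cutoffs) are
  discretized into `L` equal-width, lower-exclusive/upper-inclusive bins
  and the RB ratio is formed bin by bin.  Default `L = 25` on (0, 1] —
  midpoints (i − ½)/L — which is coarse but in practice resolves
  estimates to ±0.02 with N = 10⁵ draws; `L` is configurable everywhere.
  Histograms only: no kernel smoothing, because the RB ratio of two
  kernel estimates inherits two bandwidth choices and loses the exact
  "posterior content of the plausible region" accounting that the
  histogram version provides (the content is the exact sum of posterior
  bin masses with RB > 1).
* **Finite quantities** (the discrete model's cutoff) keep their support;
  no binning.
* **Ties** at the RB maximum break to the smallest midpoint and all tied
  bins are reported — determinism matters more than any substantive
  reason to prefer one tied bin.
* **Bins with zero prior mass but positive posterior mass** get an
  infinite-RB marker and are excluded from the estimate unless the caller
  opts in: with finite Monte Carlo they are an artifact of prior
  undersampling in the far tail, not evidence.
* **Credible regions** {RB > c_γ} require γ not to exceed the plausible
  region's posterior content; beyond that the region would include values
  the data argue against.
* **Hypothesis events** report RB together with Monte Carlo standard
  errors and the theoretical maximum 1/prior-probability.  When the prior
  probability is known analytically (the mean ordering under an
  exchangeable binormal prior is exactly ½) the analytic value replaces
  the simulated one, so the reported RB cannot exceed its own bound
  through simulation noise.
* For a binomial proportion with a beta prior the whole analysis is
  closed-form (`beta_binomial_rb`): RB ∝ likelihood, so the estimate is
  the MLE and the plausible interval comes from root finding on the log
  density ratio, its content from the beta cdf.  This is the route used
  for prevalence inference; the histogram route converges to it and the
  test suite checks that.

Reparameterization invariance (the estimate maps through any smooth
increasing transform; contents are unchanged when the grid is transformed
alongside) is exploited for cutoff inference: cutoff distributions are
heavy-tailed, so inference runs on cmod = ½ + arctan(c)/π ∈ [0, 1] — the
Cauchy cdf, chosen over a normal cdf because a shorter-tailed compressor
saturates extreme draws at 0/1 — with an explicit atom at 1 collecting
draws for which no finite cutoff exists.

## Elicitation defaults

"Virtual certainty" means prior probability γ = 0.99 throughout.

* **Prevalence**: beta(1 + τξ, 1 + τ(1−ξ)) parameterized by mode ξ
  (default: interval midpoint) and concentration τ, the smallest value
  putting content γ on the stated interval [l, u].  Coverage is monotone
  in τ, so bisection on [0, 10⁷] suffices (tolerance 10⁻⁶, final nudge to
  land on the ≥ γ side).  l = u marks a known prevalence; [0, 1] gives
  the uniform prior.
* **Normal-gamma**: μ₀ and τ₀ follow from the stated mean interval and
  the upper bound on the observation-interval half-length; (λ₁, λ₂) solve
  the two gamma-coverage equations by alternating one quantile evaluation
  (for λ₂) and one root find (for λ₁) until the σ-interval coverage is
  within 10⁻⁴ of γ.  The iteration is a contraction in practice;
  non-convergence after 500 rounds raises with the last iterate.
* **DP concentration**: the prior probability that a DP(a, H) draw
  differs from H by at least ε on some event is bounded by
  sup_r {1 − Beta([r−ε, r+ε]; ar, a(1−r))}.  The supremum is evaluated on
  a 2001-point r-grid plus bounded local refinement (the integrand is
  smooth away from the endpoints, which contribute 0 because the beta
  degenerates to a point mass inside the window).  The elicited `a` is
  the smallest 0.1-grid value with bound ≤ target, found by doubling
  bracket + bisection (the bound is nonincreasing in `a`).

## Model specifics

**Ordered-discrete.**  Dirichlet priors are conjugate to the multinomial
counts, so prior and posterior sampling are exact.  Conditioning on
AUC > ½ is by rejection on both sides (these give identical conditioned
posteriors — conditioning commutes with updating — which the tests check
by a two-sample statistic); an acceptance rate below 0.1% raises with
advice to use priors concentrated on monotone probability vectors, which
place more prior mass on a useful test.  The monotone-vector map
(simplex → nonincreasing/nondecreasing probability vectors by the
triangular averaging matrix) is provided for such prior studies.  The
error characteristics at the estimated cutoff are a second-stage
inference with the cutoff fixed, reusing the conditioned draws and
discretizing each rate on (0, 1]; draws where a rate is 0/0 (no positive
or no negative calls) are typed "undefined" and dropped from that rate's
histogram, with the dropped fractions reported.

**Binormal.**  Conjugate normal-gamma updates are exact in both
variants; the AUC integral is evaluated by 64-node Gauss–Hermite
quadrature (agreeing with the closed form Φ((μ_D−μ_ND)/√(σ²_D+σ²_ND)) to
10⁻⁸, which the tests verify — the quadrature is the implementation, the
closed form the cross-check).  The optimal-cutoff closed form picks the
stationary local minimum of Error(c) for either variance ordering.  Two
numerical caveats are worth recording: (i) the existence condition
(discriminant ≥ 0) guarantees a stationary minimum, but for a small
corner of parameter space (~4% of unrestricted random draws; both
variances free, no conditioning) that minimum lies above the boundary
infimum min{w, 1−w}, i.e. the truly optimal rule is degenerate — the
oracle tests compare against grid minimization only where the stationary
minimum is globally optimal; (ii) with equal variances the conditioning
event μ_D > μ_ND is handled by importance sampling (truncated-normal
inversion for μ_ND, weight Φ((μ_D − mean_ND)/(√κ_ND σ))), with the
effective sample size reported and a 1% floor, while the unequal-variance
positivity event involves the prevalence draw and is handled by joint
rejection.

**Mixture Dirichlet process.**  Finite approximation with n* atoms and
Dirichlet(a/n*) weights a priori; a posteriori the base parameters update
from the *unique* observed values and atoms come from the predictive
mixture a/(a+n)·base + n/(a+n)·ecdf with Dirichlet((a+n)/n**) weights.
Defaults n* = n** = 1000 (the approximation's moment identities
E F(A) = H(A), Var F(A) = H(A)(1−H(A))/(1+a) hold within Monte Carlo
error at this size, which the tests verify) and N = 5000 process pairs
per side; the full-size run takes a few minutes on one core, and the test
suite uses n* = 300, N ≈ 1200–2000, which reproduces the reference
quantities within the stated bands.  Candidate cutoffs are the union of
the two atom sets — the empirical Error is piecewise constant between
atoms, so nothing finer can help.  The cutoff *posterior* histogram is
smoothed by a centered moving average of width 3 on the cmod grid
(resampling ecdf atoms makes it highly multimodal; the prior does not
need it and is left untouched).  Error characteristics at the estimated
cutoff come from a literal second simulation (child seeds) with the
cutoff fixed.  Adding Uniform(0, 1) jitter to heavily tied integer data
is an explicit flag, never automatic.

## Synthetic data and what the tests show

The test suite runs entirely on synthetic inputs: multinomial counts and
normal samples from stated generating truths, the bundled worked-example
counts/summaries, and a moment-matched synthetic reconstruction of the
continuous sample behind the bundled summary statistics (the raw values
were never recorded; only the empirical mean/spread are faithful, so
DP-model checks on it use band tolerances).  These generators emulate
clean two-group diagnostic data under known truth.  They do not emulate
covariate structure, measurement rounding (beyond the opt-in jitter
scenario), imperfect gold standards, or non-normal shapes other than
those the DP model itself produces — so passing tests demonstrate
correctness of the inferential machinery under its stated models, not
robustness to violations the models exclude.

Monte Carlo problem sizes in the tests (N = 10⁵ for the parametric
models, smaller for the DP loops) were chosen so each stochastic check
resolves its target within ~3 Monte Carlo standard errors; deterministic
closed forms are asserted at the precision they are quoted to.

## Known limitations

* Equal- vs unequal-variance choice is a user flag; normality and
  variance-equality checking are out of scope (assumed done upstream).
* No covariate adjustment, no analysis without a gold standard, no
  cost-weighted utilities — the error profile is reported so such
  judgements can be made downstream.
* The discrete model's monotone-probability priors are supported for
  prior studies only; posterior inference under them is not conjugate and
  is not implemented.
* Histogram granularity bounds the resolution of every continuous
  estimate by one bin width; increase `L` (and N with it) when finer
  resolution is needed.
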