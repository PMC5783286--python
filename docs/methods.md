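# Methods

## Model

The disease process X(t) is a time-homogeneous continuous-time Markov chain
on the ordered state space (R, D0, D1, …, Dm).  R is an absorbing *resolved*
state: once entered, no further symptoms ever occur.  D0 is a transient
symptom-free state, and D1…Dm are increasing severity levels reachable only
through adjacent levels; D0 additionally connects to R.  Adjacency is not
restrictive in continuous time — an apparent two-level jump between visits
passes through the intermediate level unobserved.

Covariates act proportionally on each transition intensity,
λ_rs(z) = λ_rs · exp(β′_rs z), with z taken piecewise-constant on each
inter-visit interval at its left endpoint.  The generator Q(z) has these
intensities off-diagonal, rows summing to zero, and an identically zero row
for R.  Interval transition probabilities are P(Δt) = exp(Q·Δt).

## Observation scheme and likelihood

Subjects are seen only at visit times.  Disability codes identify their
latent state exactly; the symptom-free code 0 is ambiguous between R and
D0.  Writing Ω_j for the set of latent states consistent with the code at
visit j, a subject's marginal likelihood sums over all latent assignments
(x_0, …, x_m) ∈ Ω_0 × … × Ω_m of the product of interval transition
probabilities, weighted by an initial-state distribution on Ω_0.

Rather than the literal nested sums (exponential in the number of ambiguous
visits), the implementation uses the algebraically identical forward
recursion α_{j+1}(s) = Σ_{r∈Ω_j} α_j(r) P(Δt_j)[r, s], restricted to
s ∈ Ω_{j+1}.  The test suite retains a brute-force enumeration oracle and
checks agreement to ~1e−12 relative error.  Assignments that leave R get
zero weight automatically (row R of P is a point mass), and long trailing
runs of code 0 shift posterior mass monotonically onto R — the mechanism by
which the model infers resolution it never observes.

Accumulation is log-domain with per-visit rescaling, so century-long
symptom-free tails cannot underflow.  Subjects whose history has zero
probability under the supplied parameters contribute −∞ with a diagnostic
naming the subject.  Ties in visit times are rejected as data errors rather
than merged.

**Initial-state convention.**  A subject whose first visit shows code 0 is
taken to be in D0 with probability 1.  This is appropriate for cohorts
recruited through symptomatic referral, where entering the clinic already
resolved is implausible; it is a configuration knob
(`ambiguous_split=(p_R, p_D0)`) for sensitivity analyses, since other
recruitment mechanisms may warrant a non-degenerate split.  Subjects with a
single visit carry no interval information and are dropped with a warning
by the CSV reader.

## Estimation and inference

The likelihood is maximised over the working parameters (log λ, β) —
positivity of baselines is automatic — by L-BFGS-B with finite-difference
gradients; convergence at relative log-likelihood change 1e−8, at most 500
iterations.  Log-baselines live in the wide box [−20, 10], which never
binds statistically but keeps unidentified rates (e.g. a resolution rate
the data cannot see) from drifting to ±∞ along flat likelihood plateaus.
The covariance of the estimator is the inverse central-finite-difference
Hessian (step 1e−4) of the negative log-likelihood at the optimum; when the
Hessian is singular or not positive definite — expected under weak
identifiability — the covariance is reported absent rather than patched.

Wald intervals are computed on the working scale and exponentiated for
baselines, so a baseline interval is multiplicatively symmetric about its
estimate.  β intervals are reported on the natural scale.

**Boundary test.**  "No resolution" fixes λ_{D0→R} = 0, on the boundary of
the parameter space, so the LR statistic T = 2(ℓ_full − ℓ_null) is referred
to a 50:50 mixture of a point mass at zero and χ²₁: p = 1 when T = 0, else
p = ½·P(χ²₁ ≥ T).  Differences below optimiser noise (1e−6 relative to the
log-likelihood) are treated as boundary ties.  Null calibration is verified
by simulation in the test suite (~5% rejection at nominal 5%, and
P(T > 0) ≈ ½).

**Probability of resolution.**  p̂_{s0,R}(t) is the (s0, R) entry of
exp(Q(Θ̂, z)·t).  Its confidence interval is obtained by parametric
simulation: draw parameter vectors from N(Θ̂, vcov) on the working scale
(default 1000 draws, seeded), evaluate the same functional at each, report
percentile bounds.  A delta-method interval would be an alternative; the
simulation approach respects the [0, 1] range and the strong nonlinearity
of the functional near identifiability boundaries.

## Simulator

Latent paths are sampled by competing exponentials from the generator:
holding time Exponential(−Q[s,s]), next state proportional to the outgoing
intensities; sampling stops at the horizon or on absorption.  Panel
observation reads the path at scheduled visits (right-continuous: a jump
exactly at a visit reports the new state).  Masking replaces R and D0 by
code 0, producing the partial-observation regime; the complete and partial
datasets from one seed share identical latent paths.

The two standard four-state study designs have 480 subjects, 160 starting
in each transient state, annual visits over 8 years, and a binary covariate
with coefficient 1 on every transition except D0→R (whose identifiability
is the object of study).  Scenario 1 uses fast baselines
(0.4/0.4/0.6/0.6/0.4 per year); Scenario 2 slow ones
(0.06/0.06/0.08/0.08/0.06).  The covariate is assigned *exactly* balanced
within each initial-state group (a Bernoulli mode is available), is
time-fixed per subject, and visits sit exactly on integer years — the
natural reading of an annual-visit design.  Each replicate draws its RNG
stream from (master seed, replicate index).

**Analytic resolved fraction.**  The expected fraction of a cohort resolved
by time t is the average of exp(Q(z)·t)[s0, R] over the design's
initial-state allocation and covariate distribution.  Two conventions are
exposed: the *design* convention (covariate absent from D0→R, matching the
simulator), and a *uniform-covariate* convention in which the same
coefficient also accelerates resolution.  At t = 8 these give 0.59 / 0.71
for Scenario 1 and 0.14 / 0.22 for Scenario 2.  The benchmark values
reproduced by `scripts/acceptance.py` (0.71, 0.22) use the uniform
convention; the simulator's empirical resolved fraction is checked for
self-consistency against the design convention, since that is the process
it actually samples.

**Synthetic five-state cohort.**  `generate_psa_like_dataset` emulates the
*shape* of a tertiary-clinic disability cohort: five latent states, slow
resolution (0.04/year), patient-level covariates (sex, centred age at
onset, centred disease duration, damaged-joint count), visit counts
2 + Poisson(4.4) capped at 18, and irregular inter-visit gaps drawn from a
half-year grid with mean 1.5 years.  All parameters are invented and
documented in `PSA_LIKE_SPEC`; the grid-valued gaps keep the number of
distinct matrix exponentials per likelihood evaluation small.  What it does
*not* emulate: informative visit timing or dropout, covariate measurement
error, time-varying damaged-joint counts, or misclassified disability
codes — so passing recovery tests on it demonstrates correctness of the
estimator under the model, not robustness to those real-data features.

## Replicate studies and problem sizes

The study harness repeats simulate → fit → collect (estimates, Wald
bounds), starting each fit from the generating parameters jittered by
U(−0.3, 0.3) on every working-scale coordinate, and reports means over
converged replicates with failure counts.  The default is 100 replicates of
480 subjects — the package's desk-scale default for a study of this design;
the benchmark tables themselves used 500.  The boundary-test calibration
uses 200 replicates of 240 subjects.  Replicate-mean comparisons use
3 Monte-Carlo standard errors.

Under Scenario 2's partial regime the mean upper Wald bound for λ_D0R is
dominated by occasional replicates in which the likelihood is nearly flat
in log λ_D0R: the estimate lands on a plateau, the local curvature is
almost zero, and the exponentiated upper bound explodes (factors of 10² to
10²⁴⁰ above the estimate).  This heavy tail is the quantitative form of
the identifiability failure — with slow dynamics and little follow-up after
the last disability observation, "still in D0" and "resolved" are nearly
indistinguishable — and is why a Wald interval there should be read as
"unbounded above", not as a usable upper limit.

## Numerical choices

- Matrix exponential: scipy's Padé scaling-and-squaring; a uniformization
  (randomisation) series serves as independent cross-check (agreement to
  1e−10) and as fallback, with its own scaling-and-squaring guard for stiff
  generators.  Tiny negative entries from roundoff are clipped to zero.
- Transition-probability caching: per likelihood evaluation, P(Δt) is
  computed once per distinct (covariate vector, Δt) pair; subjects sharing
  a visit grid and covariates are batched so the forward recursion runs
  vectorised across the batch.  A scenario-design evaluation needs two
  matrix exponentials total.
- Tight-precision fits (closed-form comparisons) use 3-point gradients and
  ftol 1e−15; default fits use 2-point gradients for speed.

## Limitations

Time-homogeneous Markov dynamics (no duration-in-state or calendar-time
effects); no misclassification of disability codes; visit times assumed
non-informative; covariates piecewise-constant between visits.  The Wald
machinery is unreliable exactly where the model warns it is — near the
λ_{D0→R} = 0 boundary — where the boundary LR test and profile-based
reasoning should be preferred.
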