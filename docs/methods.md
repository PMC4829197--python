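# Methods

## The model

The data are covariate/response pairs (x_i, y_i), i = 1..n, with a
declared subgroup label: m minority rows and n−m majority rows, the
minority strictly smaller.  The structural curve is by default the Emax
model f(x) = A + B·x/(C + x); a straight line and a sigmoidal Emax
(Hill exponent h on x and C) are also available.  The hierarchical
model is

    y_i     = y_int,i + ε_i,      ε_i ~ N(0, 1/δ)
    y_int,i = f(x_i; θ) + γ_i,    γ_i ~ N(0, 1/τ_int,i)

with vague zero-mean normal priors on the structural coefficients
(precision 10⁻⁶, i.e. SD 1000; optionally A truncated at 0) and
δ ~ Gamma(0.001, 0.001).  The balancing construction sets
τ_int,i = φ (default 10⁶) on majority rows and φ·(n−m)/m on minority
rows.  The coefficient-prior notation deserves one remark: written as
a variance, "1/10⁶" would pin the coefficients at zero, contradicting
any non-trivial fit, so it is read as a *precision* of 10⁻⁶ —
consistent with the precision notation used for γ and ε.  Both the
precision and the truncation are configuration options.

## Three readings of the balancing prior, and why they differ

The package implements the construction three ways, because they do
not agree — and the disagreement is itself informative.

**power (default).**  Each observation's log-density is multiplied by
w_i = τ_int,i/φ, i.e. minority rows count (n−m)/m times.  This is
Bayesian over-sampling made exact: the posterior is *identical* to a
conventional fit in which every minority row is physically replicated
(n−m)/m times.  The test suite enforces this equivalence as an oracle
(posterior means of the weighted fit vs. the replicated fit agree
within Monte-Carlo error).  This mode genuinely re-balances influence
and is the one the simulation study and the PK pipeline use.

**latent.**  The literal two-layer model above, fitted exactly by
integrating γ out analytically: marginally
y_i ~ N(f(x_i), 1/δ + 1/τ_int,i).  Because every τ_int,i ≥ 10⁶ while
the residual variance is of order 10⁻²–10⁰, the extra term is
negligible: the exact posterior of the literal two-layer model is
indistinguishable from the conventional fit (a test asserts this).
Taken at face value, the construction should barely re-weight
anything.

**latent_gibbs.**  A single-site Gibbs sampler of the kind
general-purpose Bayesian engines apply to the un-marginalised model:
conjugate normal updates for the latents and the linear coefficients,
conjugate gamma for δ, random-walk Metropolis for C.  Given the
latents, the coefficient conditionals have precision of order
Σᵢτ_int,i ≈ 10⁸, so each update moves the curve by ~10⁻⁴ response
units; given the curve, the latents are pinned back onto it.  The
chain therefore cannot leave the neighbourhood of its starting point
within any realistic run length, while producing perfectly
stationary-looking traces that pass Geweke and Heidelberger–Welch.
Initialised at the generating parameter values it reports them back
with relative error under 1% and within-chain SD of order 10⁻³
(a test demonstrates exactly this); initialised elsewhere, it reports
*that* point instead.  Published results obtained by running such a
sampler on the two-layer construction can thus show spectacular
bias ≈ 0 and replicate precision of order 10⁴–10⁵ that reflect the
initialisation, not the posterior.  This mode exists so that the
phenomenon can be reproduced and inspected, not for inference.

## The sampler and its validation

Inference uses emcee's affine-invariant ensemble sampler over
(θ, log δ) with a vectorised log-posterior, initialised from a
deterministic (weighted) least-squares fit with seeded jitter.  Run
lengths are expressed as total draw budgets across the ensemble;
the long-run configuration (10⁵ burn-in, 10⁵ retained, thinning 10)
is the default, and the tests and desk-scale studies pass budgets of
12 800–32 000 draws (800–2000 steps of a 16-walker ensemble), which
give Monte-Carlo SEs one to two orders of magnitude below the
replicate-level spread being measured.  Posterior means are validated
against brute-force quadrature: with δ integrated out analytically
(Gaussian likelihood, gamma prior), the remaining 3-D integral over
(A, B, C) is evaluated on a dense grid and agrees with the sampler to
well under 1%.  One caveat the quadrature made explicit: with sparse
minority data the unweighted posterior carries a heavy (B, C) ridge —
B and C can grow together at nearly constant likelihood, cut off only
by the vague prior — so the posterior *mean* of C is prior-sensitive
and right-skewed.  That is a property of the model, not the sampler,
and it is why conventional fits on imbalanced pairs can be badly and
erratically biased.

Convergence diagnostics follow the classical single-chain
definitions: Geweke's z compares the first 10% and last 50% of a
trace using AR/AIC spectral density estimates at frequency zero;
Heidelberger–Welch applies a Cramér–von-Mises stationarity test with
successive 10% initial discards (up to 40%) and a half-width test
(1.96·√(s₀/n) within 10% of the mean).  Both were checked against an
independent reference implementation on seeded chains and the
resulting z-scores and verdicts are frozen in the test suite.
Diagnostics run on a single walker's trace; the ensemble mean would
shrink the variance ~16-fold without shrinking common-mode drift and
so would flag far more often than the convention intends.  The overall
`converged` flag requires |z| < 1.96 for all structural parameters and
all stationarity passes; non-convergence is recorded, never fatal.

## The simulation study

Population: 200 subjects, age ~ Uniform(2, 25) years, weight
= 2 + 10·age/(10 + age) + N(0, 0.25²).  Pairs: the complete age ≥ 18
stratum (majority) plus a simple random subsample of the age ≤ 5
stratum sized round(fraction × majority count), minimum 1, at
fractions 0.075–0.3; rows between the windows are excluded.  One base
population is shared by all pairs of a study seed (re-simulation per
pair is a flag).  The balancing fit uses the designed multiplier
1/fraction for the minority precision; bias is the mean of
100·(estimate − truth)/truth over replicate pairs (posterior means by
default; medians by configuration) and precision is the inverse sample
variance of those estimates.  The desk-scale default in the acceptance
machinery is 10 pairs per fraction with 12 800-draw chains (about one
minute for four fractions on one CPU); pairs and chain lengths scale
up by configuration.

What these replicas show honestly: with five or six minority points
the Emax fit is weakly identified, so replicate posterior means
scatter widely under *both* approaches, and 10-pair means of A or C
bias can land tens of percent from zero in either sign.  The
replicated-minority equivalence, not a small bias table, is the
verifiable content of the balancing method: it restores the
minority's influence; it cannot manufacture information the minority
does not contain.  Correspondingly, the balancing approach's
replicate precision is of the same order as the conventional one —
the frozen-sampler mechanism above is the only way we could reproduce
published precisions four orders of magnitude higher.

## The synthetic cohort and the dosing pipeline

No clinical dataset ships with the package; `synthetic_cohort`
generates one with the right structure: 570 subjects aged 1–25 y
(60 infants 1–2 y, 100 children 2–10 y, 97 adolescents 10–18 y,
313 adults 18–25 y), body weight an Emax growth curve of age, CL an
Emax curve of age, and V1, Q, V2 Emax curves of weight, each with
log-normal between-subject noise.  All magnitudes are invented but
sized to tobramycin pharmacology in a lean cystic-fibrosis-like
population (adult CL ≈ 5–6 L/h, adult V1 ≈ 0.2 L/kg, infants with the
physiologically higher per-kg volumes).  Tests assert recovery of
whatever values the configuration holds, never the default numbers
themselves.  Model-building subsets take 63 adults, 3 children
(10–13 y) and 3 infants (1–2 y); *all six* paediatric rows are
labelled minority.  (A threshold of age ≤ 10 for the up-weighting
rule would exclude the 10–13 y children that the 63/3/3 design
deliberately includes, so the package applies the rule at age ≤ 13;
the threshold is configurable.)

Two default choices deserve their rationale.  First, the predictive
protocol below re-uses the *adult* stratum's raw SD as the
inter-individual spread at every age, additively.  A wide, heavy
cohort (adults of 70–120 kg) makes that SD so large relative to
infant central values that no dose can reach 90% joint target
attainment at age 1 — the pipeline's own feasibility invariant.  The
default cohort is therefore lean and modestly dispersed
(CV 5–12%, weights ≈ 5–75 kg); wider envelopes remain configurable.
Second, the volumes' half-maximal constants sit inside the observed
weight range (C ≈ 20–25 kg).  With curvature outside the range, B and
C form the ridge described above, and since the predictive protocol
draws A, B and C *independently* from their posterior normal
approximations, ridge-correlated uncertainty turns into nonsensical
volume draws.  Identifiable curvature keeps the posterior SEs small
and the normal approximation honest.

The dosing pipeline per age group: central body weight from a lowess
smooth of weight on age (evaluated on integer ages clipped to the
observed range, no extrapolation), jittered per patient with the
infant-stratum weight SD; structural coefficients drawn from
N(posterior mean, posterior SE²); CL evaluated at the age, V1/Q/V2 at
the patient's weight; an additive deviation ω ~ N(0, η²) with η the
adult-stratum SD of that parameter (additive because that is the
stated protocol; a log-normal option exists but is off by default);
non-positive draws redrawn up to 100 times then floored at 10⁻⁶ of
the central value, with the truncation count reported.  Concentrations
come from the closed-form two-compartment constant-rate-infusion
solution (hybrid exponents from the micro-constants; the repeated-root
case handled by a perturbation tie-break at relative tolerance 10⁻⁹),
validated against stiff ODE integration to < 10⁻⁶ mg/L and against
the AUC identity dose/CL.  A dose (integer mg/kg/day grid, 1–20,
single 0.5 h infusion, no accumulation) passes for a patient when
C(1 h) ≥ 10×MIC (MIC 2 mg/L) and C(24 h) ≤ 1 mg/L, both measured from
infusion start — the standard peak-sampling convention; measuring
from infusion end is a configuration switch.  The minimum effective
dose is the smallest grid dose with joint attainment ≥ 90%, every
grid dose being evaluated.  Default simulated patients per age:
10⁴ in the long-run configuration, 2 000 in the test suite.

What the synthetic pipeline does *not* show: agreement with the
published clinical dose table, which depends on the real cohort's
parameter values and dispersions.  The tested properties are finite
integer doses at every age, monotone attainment in dose, and
generating curves inside the 95% posterior predictive band at ≥ 90%
of paediatric grid points.

## Numerical and interface details

- Seeds: one master seed per run; every stage derives its own stream
  via SHA-256 hashing of (master seed, stage name, indices), all
  below 2³¹.
- Degenerate inputs: balanced data are rejected by the τ constructor
  (a unit multiplier is the explicit no-op escape hatch); constant
  chains return Geweke z = 0 with a warning; identical replicate
  estimates make precision undefined (error) rather than infinite.
- RSS assessment (`compute_rss`) is provided for comparing fits on a
  subgroup slice, e.g. checking that up-weighting the minority has
  not degraded the majority fit — the diagnostic that flags an
  *excessive* (e.g. 100-fold) minority prior.
- The minimum-minority-size rationale is exposed as
  `all_beyond_bound_probability`: six independent points all beyond a
  5% tail bound has probability 0.05⁶ = 1.5625×10⁻⁸ ("1.5 E-8").
- Fit directories serialise `summary.csv`, `chains.csv` and a
  `config.yaml` echo; study and dosing outputs are CSV; everything is
  plain text.

## Known limitations

- Single-covariate structural models only; no multivariable fits.
- Single-dose PK evaluation; no steady state, accumulation, or
  renal-function covariates.
- The posterior-normal predictive approximation ignores posterior
  correlations between A, B and C by design (it follows the stated
  protocol); with ridge-shaped posteriors it overstates predictive
  spread.
- No model-selection machinery (DIC/WAIC); RSS and visual inspection
  are the intended assessment tools.
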