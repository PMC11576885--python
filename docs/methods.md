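# Methods

This note documents the modelling and design decisions behind `pfbt`: the
generative task, the dual-agent learner, the response likelihood, fitting
and model comparison, the model-free metrics, and the simulation harness.
It also records where the design was genuinely open and why each choice was
made.

## Task generation (`task_design`)

Two latent Bernoulli probabilities, `P_Self` and `P_Other`, follow
independent bounded random walks over the 360 sampling trials. Each step is
±0.025 with equal probability, reflected at 0 and 1 (a Gaussian-step
mechanism with SD 0.025 is available via `RandomWalkConfig.mechanism`). The
binary ± step is the simplest mechanism consistent with a fixed step size;
both walks start at 0.5 (the uninformative value; configurable).

Outcome provenance follows trial type: privileged outcomes are Bernoulli
draws from `P_Self`, decoy outcomes from `P_Other`, and each shared outcome
comes from one walk chosen by fair coin (recorded in the serialized file, so
provenance is always reconstructible). Probes are inserted after gaps drawn
uniformly from {4, …, 9} sampling trials; the probed agent is assigned
50/50 at random per probe (strict alternation is available).

**Trial-type proportions.** The defining design property of the task is
that under fully agent-specific updating (λ = 0) the Self and Other belief
trajectories are *uncorrelated*, so that any observed coupling is
attributable to leakage. Shared trials work against this property: a shared
outcome is a common input to both learners, and because it is drawn from
either walk, each belief acquires weight on the other agent's walk. If a
and b are the own-walk and cross-walk input weights, the induced
belief correlation is approximately 2ab/(a² + b²) — about 0.56 with equal
trial-type thirds (α = 0.1, δ = 0), clearly defeating the design. The
default proportions are therefore (shared, privileged, decoy) =
(0.02, 0.49, 0.49): shared trials remain in the design (they anchor the
two perspectives to a common event stream) but are sparse enough that the
zero-leakage correlation is empirically indistinguishable from 0 (mean
r ≈ 0.00 over 200 sequences), while λ_Self = λ_Other = 0.8 yields mean
r ≈ 0.66. Proportions are configurable for studying this trade-off.

Serialization uses an interleaved long-format CSV (one row per sampling or
probe event; schema in `task_design._CSV_COLUMNS`, 1-based `trial_index`)
with a JSON sidecar holding the full generation config and seed. Reading
validates trial types, outcomes and probe agents row by row, and flags —
but does not reject — probe gaps outside [4, 9], since externally produced
schedules may legitimately differ.

## Dual-agent learner (`agent_model`)

The update is the coupled error-driven recursion given in the README. Three
readings of the published form were open:

- **Decay target.** The decay term is written without an agent superscript;
  each agent's belief decays toward 0.5 using *its own* previous value —
  the only reading that keeps the two equations symmetric.
- **Decay timing.** Decay applies on every sampling trial, including trials
  where an agent's prediction error is zeroed: drift toward chance is
  passive forgetting, not an event-driven process.
- **Bounding.** Beliefs are clipped to [0, 1] after each update. The
  likelihood additionally clamps Beta modes into [1e-4, 1 − 1e-4], since a
  modal Beta requires an interior mode.

Initial beliefs are (0.5, 0.5) (chance level; configurable). In the
per-agent learning-rate variant, α^Self scales the whole Self update
(including the leaked Other term) and α^Other the whole Other update.
Parameter containers accept closed bounds (e.g. λ = 0, δ = 0, τ = 0.08
exactly) so boundary settings can be simulated; the fitting transforms map
onto the open intervals.

Probe responses are drawn from the Beta distribution with mode equal to the
probed agent's current belief and variance τ. τ ∈ [0.001, 0.08]: the lower
bound concentrates responses tightly at the belief (SD ≈ 0.032), the upper
bound is near-uniform, i.e. random responding.

## Likelihood, priors, MAP, evidence (`inference`)

**Beta(mode, variance) → shapes.** Parameterised by the concentration
s = a + b with a = 1 + m(s − 2): the mode constraint then holds by
construction and the variance is strictly decreasing in s from 1/12 at the
uniform limit s = 2. A unique solution with a, b ≥ 1 exists iff
0 < variance < 1/12 (so every τ in its box is feasible for every interior
mode); it is found by vectorised bisection to ~1e-12. Variances ≥ 1/12
raise an infeasibility error from the solver; inside the likelihood they
are shrunk to the feasible maximum with a logged warning, keeping the
objective defined everywhere (this path is unreachable for τ ≤ 0.08 and
exists for robustness only). Responses of exactly 0 or 1 are clamped inward
by 1e-4 before evaluating log densities.

**Transforms and priors.** α, δ map through the logistic onto (0, 1); τ
through an affine-scaled logistic onto (0.001, 0.08); λ through
2·logistic − 1 onto (−1, 1). Fitting happens in the unconstrained space
with independent N(0, 1) priors on every transformed parameter — weakly
informative, centring α and δ at 0.5, τ at mid-range, and λ at 0
(agent-specific updating), so the prior is symmetric about "no leakage".
Means and SDs are configurable via `PriorSpec`.

**Optimisation.** L-BFGS-B with numerical gradients, started from the prior
mean plus `n_restarts − 1` random prior draws (default 10 restarts,
tolerance 1e-6, deterministic given the seed). The best optimum is kept; a
fit is flagged unconverged when the reported gradient norm exceeds 1e-2.
Restart count is the main cost dial: the posterior for this model family is
smooth and in practice restarts agree, so the simulation harness and tests
use 3 restarts; single-participant analyses keep the default 10.

**Evidence.** Laplace approximation at the MAP:
log p(y) ≈ log posterior + (d/2)·log 2π − ½·log det H, with H the
finite-difference Hessian of the negative log posterior (positive
definiteness checked by Cholesky). Laplace is the standard choice for MAP
pipelines and is exact in the Gaussian case (verified in the tests). If H
is not positive definite the code falls back to a BIC-style evidence
(log-likelihood − ½·d·log n) with a logged warning.

## Model comparison (`model_comparison`)

Fixed effects: per-model column sums of the participants × models
log-evidence matrix and pairwise Bayes factors exp(ΔlogE). Random effects:
the variational Dirichlet scheme for population model frequencies —
iterate posterior model assignments g_nk ∝ exp(logE_nk + ψ(α_k) − ψ(Σα))
and α = α₀ + Σ_n g_n to convergence (tolerance 1e-8, max 1e4 iterations),
with a uniform Dirichlet prior α₀ = 1. Exceedance probabilities are Monte
Carlo over the posterior Dirichlet (default 1e6 draws, seeded, accurate to
~1e-3). The Bayes omnibus risk compares the variational free energy of
this model against the exact evidence of the null in which all frequencies
equal 1/K; protected exceedance probabilities are
PXP = EP·(1 − BOR) + BOR/K. Best-model counts break evidence ties toward
the model with fewer free parameters (the nested, more parsimonious
variant) and log the tie.

## Model-free metrics (`behavioural_metrics`)

`O^Self` and `O^Other` are exponential recency-weighted averages
(O ← O + w·(outcome − O)) over the outcome streams pertinent to each agent
(Self: privileged + shared; Other: decoy + shared), read out at probe
times. The recency weight defaults to 0.1, matching the learning rate used
in the package's reference simulations, and is reported in outputs; O is
initialised at 0.5 and probes occurring before any pertinent outcome are
flagged. The recency average, not the latent walk, is the tracking target,
so outcome sampling error does not count against the responder.

The per-participant performance statistic pools self- and other-probes into
one Pearson correlation between responses and the probed agent's O. Its
null distribution is built from sets of uniform random responses on the
same sequence (default 1000); the reported score is the raw statistic minus
the null mean (location-only referencing — zero means chance-level), and
a responder is flagged above chance only when the raw statistic strictly
exceeds the null's 95th percentile. Correlations on zero-variance or
too-short inputs are reported as NaN (undefined), never silently 0.

## Simulation harness (`study_harness`)

Cohorts are reproducible from one base seed via spawned per-participant
seed sequences; parameters, task sequence (fresh per participant by
default; a shared-sequence policy is available) and response noise all
derive from them, so parallel fitting (joblib) is bit-identical to serial.
The default parameter sampler resamples each parameter independently, with
replacement, from a synthetic table of plausible values spanning the
ranges typical of fits on tasks of this kind; uniform-in-bounds and fixed
samplers are provided. Parameter recovery reports the full generative ×
fitted Pearson correlation matrix and stratifies the diagonal by quartile
of generative τ. Model recovery gives cohort-level confusion counts by
summed evidence. Group contrasts use the pooled-SD two-sample t and
Cohen's d (pooled SD); a zero pooled SD yields a degenerate-flagged result
with infinite t and undefined d rather than an exception, so that
hand-constructed edge cases remain inspectable.

## Problem sizes

The test suite and `scripts/acceptance.py` use cohort sizes chosen as the
smallest that estimate the quantities with useful precision: recovery
cohorts of 100–200 participants (cross-parameter correlations have
SE ≈ 1/√n, so 200 at low noise), 12 participants × 6 models for the
comparison study, 200–500 replicate responders for null calibration, and
3 optimizer restarts per fit (see above). Each can be scaled up through
the same interfaces.

## What the synthetic data does and does not show

The generator emulates the task's statistical structure: bounded walks,
outcome provenance by trial type, probe schedule, and Beta-distributed
reports around model-derived beliefs. Passing recovery and calibration
tests therefore shows the pipeline is *internally* consistent — the fitting
machinery recovers the parameters of the process that generated the data,
and the model-comparison statistics behave correctly. Real participants
need not follow the learner: lapses, anchoring to the response scale,
sequential response dependencies, asymmetric attention to the two agents,
and model misspecification in general are absent from the simulations, so
recovery quality here is an upper bound on what patient data would allow.
Group-level clinical findings (case–control differences in λ^Self and their
symptom correlates) depend on non-public participant data and are outside
the package's scope; the harness's group contrast demonstrates the
*computation*, on simulated cohorts only.

## Known limitations

- MAP point estimates with Laplace evidence, not full posteriors; no
  hierarchical (empirical-Bayes) pooling across participants.
- The Beta likelihood is unimodal with a single participant-level variance;
  response strategies with point masses (e.g. always answering 0.5 or the
  extremes) are handled only through clamping.
- Belief clipping at [0, 1] makes the trajectory non-smooth at the
  boundaries, which can flatten the likelihood for extreme parameter
  combinations (large α·(1 + |λ|)).
- Numerical gradients and Hessians: curvature estimates near flat optima
  (high τ) can be poorly conditioned; the BIC fallback covers the
  non-positive-definite case.
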