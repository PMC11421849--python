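# Methods

## The choice models

Every model maps an option's reward magnitude `X` and probability `P`
(both rescaled to [0, 1]) to a scalar utility and converts the two
chooseable options' utilities into a choice probability with a softmax of
inverse temperature ϑ ≥ 0.  The third option on distractor trials is never
chooseable and never enters the softmax.

| model    | utility                                             | free parameters |
|----------|-----------------------------------------------------|-----------------|
| EV       | `X·P`                                               | ϑ               |
| AU       | `γX + (1−γ)P`                                       | γ, ϑ            |
| EV+DN    | `EV_i / Σ_j EV_j` over the option set passed in     | ϑ               |
| COMP     | `η·EV + (1−η)·AU`                                   | η, γ, ϑ         |
| PROSPECT | `X^α · exp(−(−ln P)^δ)`                             | α, δ, ϑ         |

η is the integration coefficient (1 = purely multiplicative, 0 = purely
additive), γ the magnitude/probability weight.  EV+DN normalises over
exactly the options supplied; model fitting passes the two chooseable
options only, so N = 2 there.  The PROSPECT parameterisation is the
canonical minimal choice — power utility on magnitude plus the
one-parameter Prelec probability weight `w(P) = exp(−(−ln P)^δ)`; it
reduces to EV at α = δ = 1 and leaves `w(e^{−1}) = e^{−1}` fixed for every
δ.  Richer two-parameter Prelec forms exist; the one-parameter form keeps
the model count and the comparison interpretable, and the package treats
the prospect comparison as supplementary.

The softmax is evaluated max-subtracted, so ϑ·U up to ~1e4 cannot
overflow; at extreme saturation the smaller probability underflows to 0 in
float64, which the likelihood guards against separately (below).

## Fitting

Fitting uses the two-option trials only, so the estimated integration
style is independent of any distractor influence.  Trials on which the
distractor or nothing was chosen are excluded first and counted.

The likelihood is Bernoulli per trial: with `pe` the indicator of the
empirical choice and `pm` the model probability of that choice,
`LL = Σ_t [pe log pm + (1−pe) log(1−pm)]`.  `pm` is clamped to
`[1e−9, 1−1e−9]` inside the log because a saturated softmax otherwise
yields log(0).  Minimisation is bounded L-BFGS-B with step/optimality
tolerances 1e−10 and at most 5000 evaluations/iterations, restarted from
at least 10 random starting points (uniform within bounds; ϑ starts
log-uniform on [0.1, 50] to cover both near-random and near-deterministic
regimes).  Ties between starts (ΔLL < 1e−12) keep the earliest start, for
determinism.  Bounds: η, γ ∈ [0, 1]; ϑ ∈ [0, 100] (unbounded in principle;
100 is an order of magnitude above typical cohort-level sensitivities and
keeps the optimiser stable); α, δ ∈ [1e−3, 5].

Fivefold cross-validation partitions a participant's included trials into
five random near-equal folds (assignment depends only on data size and
seed), refits on four and evaluates the held-out log-likelihood on the
fifth, each fold held out once.  The summed held-out log-likelihood is the
default model evidence for Bayesian model selection; a switch substitutes
the full-data maximum log-likelihood.  The cross-validated evidence is
preferred because it penalises the extra parameters of the composite model
out of sample rather than by an asymptotic correction.

Model recovery ("cross-fitting") fits every candidate model to a dataset,
simulates behaviour from each model's best-fitting parameters on the same
trial schedule, refits all candidates to each simulation, and scores the
winner by cross-validated evidence, yielding a K×K confusion matrix.

## Random-effects model selection

Participants are treated as drawn from a population in which model
frequencies follow a Dirichlet distribution.  The variational loop
alternates `u_nk ∝ exp(lnE_nk + ψ(α_k) − ψ(Σα))` with
`α = α₀ + Σ_n u_n`, starting from the uniform prior α₀ = 1, until the
maximum α change is below 1e−8 (at most 500 iterations; the fixed point is
invariant to per-participant constants added to the evidence rows).
Exceedance probabilities are Monte-Carlo estimates over 10⁶ Dirichlet
samples by default (closed forms exist only for K = 2, which the tests use
as oracles).  The Bayes omnibus risk compares the variational free energy
of the fitted model against the null model in which all frequencies are
equal (`F₀ = Σ_n [logsumexp(L_n) − ln K]`); protected exceedance
probabilities shrink EP toward uniform by that risk:
`pxp = ep(1−bor) + bor/K`.

## Distractor GLMs

Values HV ≥ LV (chooseable) and DV (distractor) are defined per trial by
the chosen value rule — expected value by default, or composite-model
utility with a participant's fitted (η, γ) for the sensitivity variant.
Ties are broken by listed option order and counted.  Accuracy is the
indicator of choosing HV.

GLM1 regresses logit accuracy on z-scored `HV−LV`, `DV−HV` and their
product, separately per trial type.  Because controls have no real
distractor, each distractor trial is matched exactly on its
`(X_HV, P_HV, X_LV, P_LV)` quadruple to the two-option trials sharing that
condition; the matched condition inherits the distractor's value as a
hypothetical DV.  Matching is many-to-one: a unique control condition
enters the combined GLM2 once, with binomial response (HV-choices out of
occurrence count) and the count as observation weight, alongside the
individual distractor trials (T = 1, weight 1).  Where one control
condition matches several distractor conditions, the hypothetical DV comes
from the first matched distractor trial in design order, keeping the
weight bookkeeping exact; a `control_rows="per_trial"` switch disaggregates
the control rows as a sensitivity analysis (identical coefficients, since
the binomial likelihood factorises).

z-scoring is per participant, weighted, with the sample (n−1) denominator,
over exactly the rows entering the fit; interaction and T-product columns
are formed from the z-scored base terms and not re-standardised.  The
weighted logistic fits use iteratively reweighted least squares
(statsmodels GLM, binomial family); perfect separation is flagged on the
result rather than raised.  Group-level inference on the per-participant
coefficients uses two-sided, uncorrected one- and two-sample t-tests and
Pearson correlation — the two-stage summary-statistics approach; no
mixed-effects variant is provided.

The `(DV−HV)T` coefficient is the distractor effect: the change in
relative accuracy attributable to the distractor's value over and above
the matched baseline.  The cohort split at the mean fitted η (ties at the
mean go to the additive group, deterministically) separates multiplicative
from additive integration styles; a filter at η < 1e−6 marks effectively
additive participants for the correlation sensitivity re-test.

## The synthetic-data generator

The generator emulates the structural facts of the paradigm the analyses
rely on, with defaults of 150 distractor and 150 two-option trials per
participant and attributes on a 10×10 grid spanning [0.1, 1.0] per
attribute (avoiding degenerate zero-utility options).  Chooseable (H, L)
pairs are drawn from a pool no larger than the number of two-option
trials; every pair used on a distractor trial is covered by at least one
control trial and remaining control slots resample the pool, reproducing
the many-to-one distractor→control matching with zero unmatched distractor
trials.  Choices are simulated from the softmax of the generating model;
with probability 0.02 by default a distractor trial records an erroneous
choice of the unchooseable option, exercising the exclusion filter.
Parameters are sampled from per-cohort uniform ranges (point masses when
degenerate).  An optional distractor-sensitivity term adds
`bias·(U_D − U_H)` to the log-odds of choosing H on distractor trials;
coupling `bias = 5(η − 0.5)` produces cohorts in which additive-style
agents show negative and multiplicative-style agents positive distractor
effects.  The slope was set once from a power calculation — per-participant
`(DV−HV)T` noise SD near 0.9 under the null and roughly 0.3 coefficient
units per unit bias imply a population correlation around 0.4, detectable
at cohorts of 60–100 — rather than from any empirical dataset.

What the generator does **not** emulate: screen positions and timing
(never used by these analyses), reaction times, attribute-level distortions
of real stimuli, session structure, and the exact attribute tables of the
original experiments (only their matching structure).  Passing tests
therefore certify the statistical machinery — identifiability, calibration,
selection validity — on data that satisfy the models' assumptions, not the
empirical claims themselves.

## Problem sizes and numerical choices

The test suite runs parameter recovery at 50 agents × 300 two-option
trials (Pearson r of true vs fitted η ≥ 0.8 at the suite's fixed seed;
across design realisations this correlation varies by a few hundredths, so
η recovery at this trial count and ϑ ≈ 9.6 sits near that level rather
than safely above it), model recovery at 4 models × 30 agents × 300
trials, and GLM null calibration over 100 replicate cohorts of 40
DV-insensitive agents (rejection of the group `(DV−HV)T` test stays inside
the binomial [1%, 11%] band).  The acceptance script uses the same recovery
settings plus a 60-participant end-to-end cohort — sizes chosen so the full
analysis remains a few minutes on one CPU while keeping every group-level
test adequately powered.

Degenerate inputs are errors, not silent results: empty attribute grids,
distractor trials without any two-option trial, all-zero EV denominators,
datasets with no usable trials, zero-variance regressors or t-test inputs,
and non-finite model evidences all raise with named messages.  All
randomness flows from integer seeds through `numpy.random.SeedSequence`
spawning, one stream per operation, so every result is reproducible from
(inputs, seed).

## Known limitations

* The composite model's η is weakly identified in single participants at
  ~150 trials and moderate ϑ; single-subject η estimates should be read
  with cohort context.
* The EV+DN model normalises over the two chooseable options during
  fitting (the fitting data contain no distractor), so its divisive
  signature enters only through the control-trial denominator, not through
  DV.
* The aggregated-control GLM2 bookkeeping follows the observation-weight
  description directly; other reasonable readings (e.g. baseline-accuracy
  dependent variables) would alter coefficient scales, though the
  disaggregated switch shows the likelihood-equivalent variant agrees.
* Group-level inference is two-stage; heteroscedastic per-participant
  coefficient precision is not propagated.
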