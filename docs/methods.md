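# Methods

## The game and its agents

Each trial has five stages: the client picks an adviser (appraisal), both
advisers see the evidence grid, both commit signed confidence (advice), the
two reports are revealed (showdown), and the urn named by the *selected*
adviser is opened (outcome). All mechanics in `task_core` are deterministic;
every random draw in a simulation flows from one seeded generator per
participant (`numpy` PCG64, sub-seeded from the cohort's master seed via
`SeedSequence.spawn`), and the seed is written into the trial-log header.

**Confidence scale.** Advice is an urn plus a level 1–5, coded signed
(black negative). The zero-deviance policy maps evidence probability p to
the warranted confidence by the linear anchor map `c* = 1 + 8·(p_maj − ½)`:
chance evidence warrants level 1, certain evidence level 5. The map's
functional form between the anchors is a modelling choice; linearity is the
minimal assumption consistent with "confidence matches the evidence ratio".
*Advice deviance* projects the advice onto the evidence-favoured direction
(+level if it backs the majority urn, −level otherwise) and subtracts c*.
At exactly p = ½ neither urn is favoured and the deviance is `level − 1`
(magnitude only). Deviance is measured in confidence-scale units, and all
model parameters live on that scale.

**Rival adviser.** Reports `clip(p + ε, 0, 1)` with ε ~ N(0, 0.08),
discretized through the same anchor map with round-half-up; at exactly
p = ½ the urn is a fair coin and the level is 1. With zero noise the rival
is the zero-deviance policy.

**Client.** Keeps influence weights w_P + w_O = 10, initialised 5/5, and
selects the argmax (exact ties by fair coin). Advice is coded on a 1–10
prognostic scale (black 5B→1 … white 5W→10) and the weights update
multiplicatively from squared prognostic strengths:

    w_P′ = 10 · w_P·PA_P² / (w_P·PA_P² + w_O·PA_O²)

The raw 1–10 code is oriented towards the white urn; used as-is the client
would systematically favour white-advising advisers regardless of outcome.
Because the update is meant to reward predictive strength for the
*realized* outcome, the code is reflected (`11 − PA`) when the coin is in
the black urn, so the strongest correct advice always scores 10. A
`literal_pa_mode` switch disables the reflection for auditing the
literal reading.

**Generative participant.** Inverts the deviance definition: target
projection = c* + model-predicted deviance + N(0, σ_response), flipped to
the other urn if negative, clipped to [1, 5] and rounded half-up. Rounding
and clipping mean realized deviance equals the model prediction only up to
±0.5 discretization and boundary shrinkage near c* ≈ 4.6 (the highest
evidence level in the default schedule); this slightly attenuates
recovered biases, which is visible in the recovery table and accepted.

**Evidence degradation.** Inside a degradation window one adviser's grid
has 20 squares moved from the majority to the minority colour (75/25 →
55/45); the coin is always drawn from the *true* evidence, so the degraded
adviser's advice becomes systematically less accurate and the client
switches — the within-participant selected/ignored contrast needs these
switches. The exact window layout is not canonical: by default each
experiment block gets two 10-trial windows (at ~20% and ~65% of the block)
with the target adviser alternating; all of it is configurable in
`ExperimentSchedule`.

## Merit learning and the model family

Relative merit starts at 0 (neutral prior) and updates by the delta rule
with learning rate γ ∈ [0, 1]. Timing follows the stage order: the
selection covariate S(t) is the appraisal choice of trial t (known before
advising), while RM entering trial t reflects outcomes through t − 1. The
recursion is an exponential filter and is evaluated with
`scipy.signal.lfilter`; the fitting kernel re-implements it in a numba loop
and the two agree to 1e−12 (tested). `sign(0) = +1` everywhere, so the
measure-zero tie is deterministic. With |ΔPV| ≤ 10 the merit trace is
bounded by 10 for any γ.

The six nested models are `bias`, `client`, `merit`, `mixed`,
`interaction` and `amplitude` (the full model with raw RM in place of its
sign). Inactive parameters are structurally fixed at 0, so nesting is
exact: the interaction model with β_int = 0 *is* the mixed model, etc.

## Fitting

The robust cost `L = Σ log(1 + |pred − obs|)` is treated as a negative
log-likelihood (target density ∝ exp(−L)); deviance is D = 2L by analogy.
Priors are independent uniforms — Bias ∈ [−4, 4], each β ∈ [−2, 2],
γ ∈ [0, 1] — generously covering the deviance scale.

Sampling is random-walk Metropolis–Hastings, 4 chains × 10,000 samples with
2,000 burn-in by default (a 2 × 3,000 configuration is provided for batch
replicates). Out-of-bounds proposals are rejected. Two choices matter and
were made for mixing, not convenience:

* **Starting point.** Chains start at the best of 256 seeded prior draws,
  polished by bounded Nelder–Mead (three restarts). When the merit weights
  of the generating process are near zero, γ is unidentified and the
  posterior develops a near-flat slab at small γ where Bias trades off
  against β_mer (and β_sel against β_int); mid-prior starts let chains
  settle into arbitrary points of that slab and the chains then disagree.
* **Proposal adaptation.** During burn-in the proposal covariance is
  re-estimated from the chain's own history (scaled by 2.38²/d) and a
  global scale is tuned towards ~30% acceptance; the kernel is frozen at
  the end of burn-in so kept samples come from a fixed-kernel chain.
  Per-parameter steps traverse the correlated ridges of this model family
  far too slowly.

Point estimates are posterior means (the marginal-integration summary),
with medians reported alongside. Identical seed, config and data give
bit-identical chains. Acceptance rates outside [0.1, 0.6] raise a warning;
constant observed deviance raises for every model but `bias` (the
covariate weights are then unidentifiable).

**DIC.** `DIC = mean(D) + pD` with `pD = mean(D) − D(posterior mean)`;
ranking ties are broken towards fewer free parameters. The posterior-mean
plug-in is the standard but fragile part: on data *without* merit
structure the sign-model posterior is a curved degenerate slab, the
posterior mean can fall off it, and pD goes negative. pD < −1 is treated
as an invalid summary and raises; `compare_models` records such failures
per model without aborting the rest, and cohort-level comparisons
aggregate over complete cases (participants with all six DICs finite).
In the shipped runs this affects ~1/30 fits on the structured cohort and
~5/12 over-parameterized fits on the bias-only control — an honest
property of DIC here, not noise to be suppressed.

## The synthetic cohorts

The generator emulates the statistical structure the analysis assumes:
per-participant randomized evidence sequences (p drawn from
{0.55, …, 0.95} with random colour polarity — the true grid resolution is
not canonical and is configurable), Bernoulli coins, degradation windows,
the noisy rival, the weight-updating client, and model-driven participants
with response noise σ = 0.3 deviance units (chosen so that recovery at 240
trials is achievable but not trivial). Schedule presets: online 130 trials
(2 × 65), lab 4 × 70, scanner 4 × 60. Per-participant generating
parameters are sampled around group means (default sds: bias 0.5, β_sel
0.2, β_mer/β_int 0.15, γ 0.1 clipped to [0.05, 0.95]) — between-
participant spread is required for recovery correlations to be defined at
all. Ground truth is written to a separate table so fitting code cannot
read it by accident. Optional FNE scores are emulated on the brief 12–60
questionnaire range (36 ± 9) with a chosen correlation ρ to the generating
β_sel — positive, so defensive advisers score higher.

What the generator does **not** emulate: reaction times, attention lapses,
learning of the game itself, level-use idiosyncrasies (humans favour round
levels), or any coupling between response noise and trial difficulty.
Passing tests therefore show the pipeline is correct and well-powered for
this data-generating process, not that human data will be as clean.

## Analysis pipeline

Trials are labelled selected/ignored from the appraisal choice and
positive/negative from the sign of the merit trace recomputed with the
*fitted* interaction-model γ. Per-participant 2×2 cell means feed a
two-way repeated-measures ANOVA (statsmodels `AnovaRM`; cross-checked
against an independent implementation in the tests), plus a paired t-test
of overall ignored vs selected deviance. Participants with an empty cell
are excluded with a warning (at least two must remain); participants using
fewer than 3 distinct confidence levels are excluded before fitting
(configurable), mirroring the exclusion of flat responders in human
cohorts. Strategy classes: competitive iff β_sel < 0, the boundary
counting as defensive. The FNE correlation is a plain Pearson r (≥ 10
matched pairs required, constant vectors rejected). Multi-cohort
comparison is a mixed model on cell means with fixed selection × merit and
cohort effects and a participant random intercept. The sliding trial-by-
trial cohort average is a plotting helper only, not a tested statistic.

## Problem sizes and runtime

The shipped analyses use 30 participants × 240 trials for the main cohort
(fit in ~25 s with default chains), 12 × 240 for the bias-only control,
and 50 null-cohort replicates of 12 participants with the short chain
configuration for the type-I-error check. These sizes give the recovery
correlations and test power reported in the README while keeping the whole
suite fast to iterate on.

## Known limitations

* γ recovery is weak (r ≈ 0.36): the sign of a slowly-varying merit trace
  is insensitive to γ over wide ranges; only the cohort-level γ scale is
  meaningful. Bias and β_sel, the parameters the analyses interpret, are
  the well-identified ones.
* The DIC plug-in pathology above: model comparison should be read at the
  cohort level over complete cases.
* The deposited-data reader adapts external column dialects via a mapping
  file and is exercised on a synthetic mimic; the real deposit's dialect
  must be mapped on first contact.
* The amplitude model shares bounds with the sign models although RM spans
  ±10, so its β scale is not directly comparable; it participates in model
  comparison only.
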