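# Methods

## The task

The orthogonalized Go/NoGo paradigm crosses outcome valence with action
requirement: four cards per block (Go-to-Win, NoGo-to-Win, Go-to-Avoid,
NoGo-to-Avoid), each repeated 40 times, 160 trials per block, two blocks
with fresh cards in each. Win cards pay +10 or 0 points, Avoid cards 0 or
−10. Correct responses earn the favorable outcome with 70/30 probability.
Every outcome that follows an active (Go) response is reduced by a fixed
1-point Go-cost, so Go trials deliver 9 / −1 / −11. Go-to-Win and
NoGo-to-Avoid are Pavlovian-congruent (the instrumentally correct action
matches the Pavlovian pull toward reward and away from threat); the other
two cards put the systems in conflict.

The contingency is realised as a fixed proportion by default — exactly
round(0.7 × 40) = 28 favorable flags per card, uniformly shuffled — so the
stated ratio holds exactly in every block and the whole pipeline is
reproducible from seeds. An i.i.d. Bernoulli mode
(`contingency_mode="bernoulli"`) is available since the original design
could be read either way. Card order is a uniform shuffle of the block
with no run-length constraints. No trial timing is modelled; the paradigm
has no usable reaction times.

### Low controllability by yoking

Each LowControl subject is paired with a HighControl subject in the same
stimulation condition (subject k with subject k; sources are recycled
with a warning if a LowControl arm is larger). The source's block-1 base
outcomes are recorded per card label with the Go-cost removed, reshuffled
per card, and replayed to the target: whatever the target does, the next
stream item for the shown card is the base outcome, and only the Go-cost
depends on the target's own response. This severs the response–outcome
contingency while exactly matching per-card reward/loss frequency within
the pair. Whether the original procedure preserved the source's trial
positions or re-randomised per card is not documented; we re-randomise,
which is the plainer reading of a card-specific random replay.

## The decision model

Choice on each trial is Bernoulli in P(Go), a two-option softmax over
action weights in which the temperature β divides the weights (larger β =
more random choice):

    P(Go|s) = exp(W(Go|s)/β) / [exp(W(Go|s)/β) + exp(W(NoGo|s)/β)]

    W(Go|s)   = Q(Go|s) + b_go + π·V(s)
    W(NoGo|s) = Q(NoGo|s)

V(s) is an action-free stimulus value updated by a delta rule on every
trial, V ← V + α(r − V); Q(a|s) is a standard Q-learning value updated by
the same rule for the chosen action only. π scales the learned stimulus
value into the Go weight — the Pavlovian bias, favouring action for
positively valued cards and inaction for negatively valued ones — and
b_go is a valence-independent Go tendency. The implementation computes
the softmax as a logistic of (W_go − W_nogo)/β, which is overflow-safe
and algebraically identical.

Numerical conventions the source description leaves open, fixed here and
exposed as configuration:

* **Reward scaling.** Points are divided by 10 before entering the value
  updates (+1.0, +0.9, 0.0, −0.1, −1.0, −1.1). Unit-range rewards are the
  convention of this model family; the scale factor is a config field
  because posterior temperatures are only comparable under the same
  scale.
* **The learner sees delivered points** (Go-cost included) — the cost was
  visible feedback.
* **Initial values.** V = Q = 0 for all cards at the start of each block;
  each block introduces new cards, so no stimulus knowledge crosses the
  boundary.
* π is unconstrained in sign; ties (P(Go) = 0.5) are resolved by the
  Bernoulli draw itself.

The same recursion is the generative agent and the likelihood; a test
suite oracle re-implements it straight-line (independent code path) and
the two agree to 1e−10 over hundreds of random agents.

### Per-subject maximum likelihood

`fit_ml` minimises the sequence NLL on the linked scale (logit α, log β,
π, b_go; L-BFGS-B, three fixed starts, box bounds ±6 / ±3 / ±10 / ±10).
A light ridge penalty 0.05·‖η‖² (equivalent to a Normal(0, ~3.2) prior)
is added by default: when a subject shows little detectable learning the
likelihood is flat along β and estimates otherwise run to the box bounds.
The penalty is negligible wherever the likelihood is informative;
`ridge=0` gives the bare ML solution and the reported NLL is always
unpenalised.

## Hierarchical inference

Each parameter p ∈ {α, β, π, b_go} has a group-level linear model on its
linked scale with dummy (reference-cell) coding — block 2, LowControl and
Stimulated coded 1, all interactions as products, HighControl-Sham
block 1 as reference — plus a zero-mean Gaussian subject random intercept
shared across blocks (non-centred):

    η_p[i, j] = X[i, j]·b_p + σ_p·z_p[i]

Links: logit for α, log for β, identity for π and b_go. Priors:
Normal(0, 2) on group-level coefficients (weakly informative on these
linked scales), Half-Normal(1) on σ_p, z ~ Normal(0, 1). Design columns
that are constant in the data (single-group cohorts) are dropped, keeping
the intercept. The coding is config-visible because reported coefficient
values are only meaningful under a stated parameterisation.

**Sampler.** The joint posterior is sampled with an affine-invariant
ensemble (emcee) using differential-evolution moves (80% DEMove, 20%
DESnookerMove), which mix far better than stretch moves on this
correlated, ~100-dimensional posterior. The log posterior is fully
vectorised: a compiled kernel evaluates the trial recursion for all
walkers and all subject-block sequences in lock-step (a pure-numpy
reference implementation is kept and cross-checked in the tests).
Independent ensembles serve as chains; each is initialised from an
empirical-Bayes point (OLS on per-subject ML estimates) with 0.4-SD
overdispersed walker jitter, so the ensemble contracts onto the posterior
rather than inflating from a point mass. The desk-scale configuration is
2 chains × 1500 warmup / 700 retained sweeps (post-warmup walker samples
evenly thinned to the retained count); the replication configuration is
6 × 1000/1000. Ensemble sweeps are far cheaper and less statistically
efficient than HMC iterations, which is why the sweep counts are larger
than the draw counts a Stan-style sampler would use.

**Diagnostics and reporting.** Convergence is screened automatically with
the classic Gelman–Rubin statistic on every group-level quantity
(threshold 1.05; violations raise a ConvergenceWarning naming the
offenders — a warning, not a silent failure, because desk-scale runs of
sticky scale parameters routinely sit just above threshold). Summaries
follow the field's reporting convention: posterior mean, 95% highest
density interval (narrowest contiguous window over sorted draws),
P(b > 0), and the evidence ratio ER = posterior odds in the favored
direction, reported as ∞ when every draw is on one side. Alongside the
regression coefficients the fit reports `mu_*`: the posterior of the
cohort-average linked parameter per p, the quantity the data identify
most directly (the intercept trades off against the subject-effect mean
in small cohorts).

## Model-free statistics

Reward-based invigoration is (#Go on Win trials)/(#Go overall);
punishment-based suppression is (#NoGo on Avoid trials)/(#NoGo overall);
the Pavlovian performance index is their mean. The denominators are
block-wise response totals, not within-valence counts. A subject with no
Go (or no NoGo) responses in a block has that sub-measure — and hence the
PPI — undefined; undefined propagates as missing rather than being
clamped. On a balanced block, 0.5 is the neutral baseline (any
valence-blind policy), 1.0 a purely Pavlovian responder.

The mixed ANOVA (one between factor, up to three two-level within
factors) uses the orthonormal-contrast formulation of the classical
split-plot analysis: each within effect maps to a contrast score per
subject, and each stratum is tested by an ordinary between-subjects
linear model (Type III, sum-coded groups, statsmodels). For two-level
factors this is exactly the univariate mixed ANOVA, sphericity holds
trivially (ε = 1), and on balanced inputs the stratum sums of squares add
to the corrected total — a property the tests verify, along with
agreement with an independent implementation on the one-within case.
Partial eta squared is SS_effect/(SS_effect + SS_error) within the
effect's stratum. Between-group degeneracies (zero error variance)
surface as non-finite F rather than exceptions.

Estimation statistics: unpaired Cohen's d with the pooled SD (sign
convention first − second) and bias-corrected and accelerated bootstrap
intervals (5000 resamples by default, jackknife acceleration, independent
resampling of the two samples, seeded). Two comparison layouts are
provided: the three intervention arms against the shared
HighControl-Sham control per block, and stimulated-vs-sham comparisons of
block2 − block1 difference scores within each controllability condition.
Bonferroni adjustment is raw p × family size, capped at 1.

## Synthetic cohorts

`generate_cohort` inverts the hierarchical model exactly: subject linked
parameters = design regression + shared subject effect, transformed
through the links, then simulated through the task engine with
HighControl subjects first so their block-1 records feed the yoked
streams. All randomness derives from one seed through named substreams;
regenerating is bit-for-bit identical.

Two generating regimes are shipped:

* **Demonstration defaults** place the reference cell at α = 0.20,
  β = 2.71, π = 0.59, b_go = 0.30 with a small negative block effect on π
  (−0.08) — central values for this model family on healthy adults — and
  `study_like_coefficients()` adds the full set of condition effects
  (strong Go-bias reduction under low control concentrated in block 1,
  weaker π decline in LowControl groups, block-dependent α and β
  modulations). Subject SDs default to 0.5–1.0 on the linked scales,
  typical of published hierarchical fits.
* **Recovery regime** (`recovery_config`): a sharper-choice cohort
  (β ≈ 0.8, α ≈ 0.35, subject SDs 0.5–0.8, single group, 20 subjects).
  At the demonstration values choice entropy is near its maximum — with
  unit-scaled rewards and β ≈ 2.7 the weight differences rarely move
  P(Go) outside ~[0.32, 0.68] — and per-subject estimates at 320 trials
  are dominated by noise (measured estimate-noise SDs of 2–3.5 linked
  units against 0.5–1.0 of between-subject signal). That is precisely why
  the analysis pools hierarchically, and why recovery validation uses a
  regime in which every parameter leaves a measurable footprint.

What the generator emulates: the group structure, yoked pairing with
frequency matching, exact contingencies, Go-cost arithmetic, and
model-consistent choice behavior. What it does not: questionnaire
covariates, demographics, session order, attention lapses, or any
deviation of real participants from this model family (no lapse
parameter, no separate reward/punishment learning rates — the model is
deliberately the one being studied). Passing tests therefore certify the
machinery, not the model's adequacy for real data.

### What the simulated signatures do and do not reproduce

Fed the condition-effect directions above, the simulated cohort
reproduces lower Go responding in LowControl groups in block 1 (the
Go-bias passivity signature) and higher block-1 PPI under a positive π.
The block-to-block PPI decline does not emerge at the stated magnitude:
a −0.08 block shift on π moves simulated PPI by less than simulation
noise (measured ΔPPI ≈ +0.001 at n = 240), because concurrent block
effects on β, α and b_go push the index in both directions. The
mechanism is verified separately — PPI is strictly monotone in the
generating π, and a sizable block coefficient (−1.2) produces a clear
decline — so the null result reflects the magnitude, not the machinery.

## Recovery checks and their calibration

The recovery analysis scores three things on a known-truth cohort:

1. per-subject ML estimates against generating subject parameters
   (Pearson r on the linked scale, per-subject fits over both blocks);
2. group-level intercept posteriors against the generating population
   values (|posterior mean − truth| / posterior SD);
3. HDI coverage across all group-level coefficients.

At 20 subjects these checks are themselves stochastic: the cohort's
realised parameter mean sits ~σ/√20 from the population value, and a
well-calibrated posterior fails a ±2 SD check on any single coefficient
about 5% of the time by construction. Subject-level scale parameters
(σ_p) are additionally biased upward in weakly-identified regimes —
per-subject estimation noise is partially absorbed into apparent
between-subject spread, which can push the β intercept slightly up.
These are finite-data properties of the model, not sampler artifacts
(they are stable under 3× longer runs), and they bound what desk-scale
recovery can certify.

## Problem sizes

Desk-scale runs use 20-subject recovery cohorts, the 2 × 1500/700
sampler configuration (~3 minutes on one core), 100-agent likelihood
oracles and 5000-resample bootstraps; the analysis drivers fit a
24-subject subsample of the 103-subject demonstration cohort. These sizes
make the full pipeline reproducible on a laptop; the replication
configuration scales the same code to the full cohort and 6 × 1000/1000
sampling.

## Known limitations

* Reported coefficient values depend on the coding scheme, link
  functions, priors and reward scale, none of which are externally fixed;
  replications against real data must state all four.
* The ensemble sampler's effective sample size per sweep is low; σ
  posteriors mix slowest and routinely trip the R-hat screen at desk
  scale. Treat desk-scale σ summaries as approximate.
* The evidence ratio saturates at the draw count (an ER of ∞ means "no
  opposing draws among N", not infinite evidence).
* BCa intervals can be degenerate on tiny or zero-variance samples; the
  EffectSize carries an explicit flag rather than guessing.
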