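# Methods

## The task

A three-option explore–exploit bandit for developmental cohorts: 10
blocks of 15 two-alternative trials. Each block uses three stimuli whose
reward probabilities are a fresh random permutation of the block's
difficulty triple — (0.8, 0.5, 0.2) on the 5 easy blocks, (0.7, 0.5,
0.3) on the 5 hard ones — so values never carry across blocks. Block 1
introduces three never-seen stimuli; every later block reuses two
previously seen stimuli (drawn uniformly without replacement from all
stimuli shown so far) and introduces exactly one new one. Stimulus
*novelty* (lifetime presentation count) is thereby decoupled from reward
*uncertainty* (every option starts every block equally unknown).

Pair scheduling within a block is uniform random over the three possible
option pairs, with random left/right placement. Balanced scheduling
(each pair exactly 5 times) is available as an option, but uniform
scheduling is the default: it reproduces the broad spread of lifetime
presentation counts (single digits up to ~80 across randomizations) that
the balanced schedule — which pins every stimulus at exactly 10 displays
per block — cannot produce.

## The learner

Beliefs are beta distributions over each option's reward probability
with recency-weighted win/loss histories:

    alpha = 1 + sum_{t<T} eta^(T-t) W_t,    beta = 1 + sum_{t<T} eta^(T-t) L_t

where T is the within-block trial index and eta in [0, 1] the recency
weight; eta = 1 recovers exact conjugate counting. The discount advances
with every trial of the block for *all* options (so an unsampled
option's evidence decays and its uncertainty recovers toward the prior),
while only the chosen option's observed outcome appends, entering with
weight eta. Features per option: expected value Q (beta mean),
uncertainty U (beta variance, in (0, 1/12]), novelty (variance of
Beta(n_seen + 1, 1), n_seen the lifetime presentation count, counted per
display and excluding the current trial), familiarity F = 1 − novelty.

## The six choice models

All models choose via softmax p(1) = 1/(1 + exp(beta_SM (V2 − V1))),
beta_SM in (0, 20). Utilities: baseline V = Q; novelty bias additionally
initializes a stimulus's first-ever block at (1 + N, 1) for N ≥ 0 or
(1, 1 + |N|) for N < 0; uncertainty bias V = Q + w_U·U; familiarity gate
V = Q + F·U·w_U; plus the two combinations. For Gaussian-prior fitting,
beta_SM and eta map to the reals through scaled logits; N and w_U are
unconstrained. Missed trials and responses faster than 200 ms contribute
no likelihood, but a revealed outcome still updates beliefs (the
feedback was seen); the recency discount advances on every displayed
trial.

The likelihood replay runs in a numba kernel over precompiled per-session
arrays; block option sets, first-appearance flags, and presentation
counts are all reconstructed from the session CSV alone, so empirical
data conforming to the schema fit identically to simulated data. A
from-scratch Python replay built on the belief-state API serves as the
cross-check in the test suite.

## Two-level fitting and model comparison

Level 1 fits each model to each subject by multi-start L-BFGS MAP
estimation in the unconstrained space under the common prior N(0, 6.25)
per parameter, with the model evidence approximated by Laplace's method
at the mode (finite-difference Hessian, jitter-regularized to positive
definite). Each fit is then refined by adaptive self-normalized
importance sampling (default 200 samples, 3 moment-matched rounds,
proposal 2.5× the Laplace covariance): session likelihoods are skewed in
weakly identified directions (the novelty bonus saturates; the
uncertainty weight multiplies a variance bounded by 1/12), and the
mode/Hessian summary underestimates both the posterior mean and the
evidence there. Refinement falls back to the Laplace summary when the
effective sample size drops below 20.

Model identity is a random effect: responsibilities r_nm ∝ freq_m ·
exp(evidence_nm) are computed from the *common-prior* evidences, which
carry the full Occam penalty for unused parameters. (Re-evaluating
evidence under the tightened empirical priors would let a nested model's
extra parameter cost nothing — its group prior collapses onto the
nesting point — reducing nested-model comparison to noise; this was
observed directly during development.) Frequencies update through a
uniform Dirichlet (alpha_0 = 1), and exceedance probabilities come from
Monte-Carlo sampling of the Dirichlet posterior, with the protected
version PXP = (1 − BOR)·XP + BOR/K using the Bayes omnibus risk computed
from the variational bound of the random-effects model against the
equal-frequency null.

Group-level parameter estimation is hierarchical: each model's group
prior (mean and between-subject variance per parameter) maximizes the
responsibility-weighted sum of subject marginal likelihoods
∫ p(D_n | θ) N(θ; μ, diag(τ²)) dθ, each integral estimated by importance
sampling from the stored per-subject samples and the whole objective
optimized by L-BFGS over (μ, log τ²). This simulated marginal MLE
replaces the more common iterate-and-average-the-modes EM, which in this
task either crawls geometrically (rate 1/(1 + τ²·info)) or, when
accelerated by precision-unshrinking, amplifies noise in nearly flat
directions; both failure modes were measured against pooled-ML and
brute-force quadrature oracles before settling on this design. Subjects
are finally refit under the empirical priors to give shrunken individual
estimates; the group-level t-test divides the responsibility-weighted
group mean by its weighted standard error with fractional degrees of
freedom (Σ r) − 1. A group-variance floor of 0.05 keeps empirical priors
proper.

Key defaults: prior variance 6.25; 10 restarts (full scale) / 2–3 (desk
scale); objective tolerance 1e-6; 100,000 exceedance samples; 200
importance samples per fit (1,500 for the headline group-recovery runs,
where the estimate tracks the pooled-ML value closely).

## Synthetic cohorts

The default cohort mirrors the study design: 30 children (8–12 y)
generated from the novelty-bias model (N ~ Normal(1.49, 0.5), optimistic
initialization), 30 adolescents (13–17 y) and 62 adults (18–27 y) from
the familiarity-gated uncertainty model (w_U ~ Normal(−0.15, 0.1)), all
with beta_SM ~ Normal(6, 1) truncated to (0.1, 19.9) and eta ~
Normal(0.7, 0.05) truncated to (0.01, 0.99). Response times are
log-normal in the chosen option's features — log RT = −0.35 − 0.4·EV +
3·novelty + 3·U + Normal(0, 0.25), floored at 0.25 s and censored at the
4 s deadline — matching the fitted signs (faster for higher value,
slower for higher novelty and uncertainty). 0.6% of trials are injected
as missed responses and 0.4% as fast guesses (< 200 ms, outcome still
shown), approximating the ~0.8% exclusion rate of the reference data.
The memory test probes each block's best option in a five-alternative
array; the simulated responder is correct with probability 0.25 (the
above-chance regime of interest) and otherwise uniform over the four
distractors.

What the generator does *not* emulate: sequential-sampling RT dynamics
(RTs are feature-modulated noise, not a decision process), lapses or
side biases, practice effects, and real memory encoding (memory accuracy
is an independent coin, not a function of experienced reward). Passing
tests therefore validate the estimation and analysis machinery on data
that obey the models exactly, not the models' adequacy for human data.

## Model-free analyses

Inference is two-stage: per-subject regressions (logistic for left
choice on z-scored ΔEV/ΔU/Δnovelty; linear for log RT on the z-scored
chosen-option features), then across-subject one-sample t-tests and
regressions of subject coefficients on z-scored age. Variables are
z-scored across the entire dataset. This preserves the inferential
targets of participant-level random slopes without a mixed-model
dependency; subject regressions hit by separation fall back to a weak
ridge penalty and are flagged. Subjects need 20 valid trials
(configurable) to enter. Age is continuous in all regressions; the
8–12 / 13–17 / 18–27 bins are used only descriptively and for per-group
model comparison. The type-I error of the stage-2 tests is verified by
simulation with feature-blind agents (zero inverse temperature).

## Model recovery and simulation summaries

Recovery reuses each subject's exact trial sequence, simulates from
per-subject parameter tables under each model, refits all models with
the two-level procedure, and aggregates replicate winners (by exceedance
probability) and per-subject winners (by responsibility) into confusion
and inversion matrices. Since fitted individual estimates for the
reference data are not available, the stand-in parameter spread is
anchored to the observed behavioral effect sizes: w_U ~ Normal(−3, 1) at
beta_SM ~ 8–16 reproduces the ~42% uncertain-choice proportion on
similar-expected-value trials that strongly uncertainty-averse groups
show; for the gate-plus-novelty model the separable novelty bias is
drawn small (Normal(0.25, 0.25)), mirroring estimates fitted to data
whose novelty signature the gate already captures. Desk-scale defaults
(10–20 subjects, 2–5 replicates, reduced restarts) keep a run in
minutes; `--scale full` restores 122 subjects × 50 replicates
(hours-scale).

The similar-expected-value summary restricts to valid-choice trials with
|ΔEV| < 0.05 and distinct feature values (ties drop from the
denominator) and reports the proportion choosing the more novel / more
uncertain option, per subject and per age group. The summary accepts the
feature recency weight as a parameter; computing features at the
generating eta isolates the agents' preferences, whereas eta = 1
features on eta < 1 agents add a selection artifact (~+0.03 on the
uncertain-choice proportion for a feature-blind agent) because the band
is then selected on a value estimate that differs from the one driving
choice.

## Known limitations

- Per-subject information about the uncertainty weight is small
  (Fisher information ~0.3 per 150-trial session at beta_SM = 6, since
  U ≤ 1/12): group means of w_U at the printed scale (−0.15) are
  recoverable only to ~±0.3–0.4 at 30 subjects, by any estimator.
- The familiarity gate modulates the uncertainty term by at most
  (1 − F) ≤ 1/12; gated and ungated uncertainty models are separated by
  ~0.05 nats of evidence per subject and are only distinguishable at
  full cohort scale.
- A novelty-biased (optimistic-initialization) agent samples the novel
  option early, lowering its within-block uncertainty; on
  similar-expected-value trials it therefore chooses the more uncertain
  option *below* chance in this implementation, at every generating
  configuration tested.
- The stage-2 tests treat subject coefficients as exchangeable and
  ignore their standard errors; this is calibrated under the null but
  less efficient than a full mixed model.
- HBI t-statistics are computed on shrunken subject estimates and are
  anti-conservative; they are reported for directionality, not as
  calibrated p-values.
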