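# Methods

## Task and synthetic sessions

The generator emulates an operant odor 2AFC session: a set of 2 or 4
concurrently learned odors, each presented `presentations_per_odor`
times (default 200, so 400 or 800 trials), individually and in
pseudorandom interleaved order, with the correct side fixed per odor,
side assignments balanced (half the odors rewarded left), and reward
delivered deterministically for the correct choice.

Schedules are built by concatenating shuffled blocks that contain each
odor exactly once, rejecting any ordering with an immediate same-odor
run longer than 3.  This yields a unimodal distribution of gaps between
successive presentations of the same stimulus, centered at the set size
and bounded by 2·set_size − 1.  The real rig constrains these gaps with
a "normal delay distribution" whose parameters are not public; the block
shuffle is a stated surrogate with the same qualitative property, not a
reconstruction.  One consequence worth knowing: the block structure
makes repeats rarer than under iid sampling — the repeat fraction is
1/set_size² (¼ at set size 2) rather than 1/set_size.  Downstream
statistics that depend on the repeat fraction (e.g. the sign of the
correlation between the *reward* and *reward-repeat* regressors) follow
the schedule's combinatorics; both regimes are unit-tested.

An optional two-odor readiness gate reproduces the session entry
criterion: within the first `readiness_window` trials (default 200),
the fraction correct must reach `readiness_threshold` (default 0.70)
for *each* of the two familiar odors.  It is off by default; analyses
operate on the novel-odor trials.

What the generator deliberately does not emulate: inter-trial timing,
port re-entry and lick dynamics, odorant chemistry, multi-day training
curricula, or satiety/engagement drift within a session.  Passing tests
therefore demonstrate correctness of the algorithms under the model's
own assumptions, not fidelity to every property of animal data.

## Model family

Values Q(o, a) for each odor-action pair start at the uninformative
Q₀ = 0.5 and stay in [0, 1].  Per trial, in order:

1. **Policy.**  P(a | o, Tᵢ) ∝ exp(β [Q(o, a) + bᵢ 1{a = a₍ₜ₋₁₎}]),
   where the trial type Tᵢ crosses (stimulus repeated?) × (previous
   trial rewarded?).  The first trial of a session has no bias term.
2. **Forgetting** (models with φ): all values decay toward Q₀ by φ.
   Decaying before the value update keeps the current trial's new
   information undiluted; the opposite order is a one-line change and
   is covered by a regression test of the likelihood trace.
3. **Delta rule** on the chosen pair only: Q ← Q + α± (r − Q), with the
   learning rate gated on the sign of the prediction error (equivalent
   to gating on r for interior Q).  No fictive updates of the unchosen
   action or the unpresented odor.

Sign convention: strategy weights are reported in the direction their
names describe.  T₁ ("inappropriate lose-shift") names a *shift*
tendency, so its repeat-action bias is b₁ = −s₁ and a positive fitted
s₁ means more shifting; b₂, b₃, b₄ equal +s₂, +s₃, +s₄.  The bias sits
inside the β multiplication exactly as the policy is written, so β and
sᵢ are coupled (doubling β while halving every sᵢ and Q-contrast leaves
the strategy part of the policy unchanged); the recovery study
quantifies what this costs in practice.

The registry grammar (`a`/`aa`, `0`, `b`, `s<digits>`, `-nos`, `-phi`)
ships seven variants: `a0b-nos`, `a0bs1`, `a0bs13`, `a0bs1232`
(winning: five free parameters α₊, β, s₁, s₂, s₃; α₋ = 0 fixed,
s₄ = s₂ tied), `a0bs1234`, `aabs1232`, `a0bs1232-phi`.  Parsing and
re-emission round-trip for all shipped names.

## Fitting

Per-session maximum likelihood over the model's free parameters,
L-BFGS-B in the box α± ∈ [0, 1], β ∈ [0, 50], φ ∈ [0, 1],
sᵢ ∈ [−5, 5], with `n_starts` (default 20) uniform random restarts
drawn sequentially from one seeded stream — so the best objective is
monotone in the number of starts for a fixed seed.  Per-trial
probabilities are clipped at 1e−12 before the log to keep the objective
finite at extreme β; the chosen side's probability is computed from its
own logit so that tiny probabilities retain full relative precision
(the likelihood agrees with an independent brute-force state-chain
trace to ~1e−13).  No priors or MAP shrinkage: with hundreds of trials
per session the simple estimator is well behaved, and avoiding priors
keeps the estimates assumption-free.  AIC = 2·negLL + 2k and
BIC = 2·negLL + k·ln n with n the number of trials.  The inner
likelihood loop is JIT-compiled with numba; a cold process pays a
one-time compile cost of a few seconds.

## Model comparison

Per-session approximate log evidence is −BIC/2.  Random-effects group
Bayesian model selection treats each session's generating model as
drawn from population frequencies r ~ Dirichlet(α₀ = 1): a variational
update iterates responsibilities and concentrations to convergence
(tolerance 1e−6 on α); exceedance probabilities are estimated from 10⁶
seeded Dirichlet draws (the two-model case also has an exact Beta-CDF
route, used as a cross-check); the Bayesian omnibus risk compares the
variational free energy of the random-effects model with the exact
evidence of the null model in which all frequencies are 1/K, and
protected exceedance probabilities are pxp = (1 − bor)·xp + bor/K.
Evidence is invariant to per-session additive constants, and permuting
model columns permutes every output consistently — both are tested.

BIC selection picks the per-session argmin with ties broken toward
fewer free parameters.  The confusion study (simulate → fit → select →
tally) measures identifiability; see "Known limitations" for what it
shows about this family.

## Trial-history regressions

Six per-session logistic regressions predict the per-trial correct
indicator via a logit link.  All include *correct history* — the count
of past rewarded choices for the current trial's odor, transformed as
log(1 + count) because the first reinforcements should matter most
(log1p rather than a bare log so the zero-history trials at the start
of learning remain defined).  With R = 1{repeat} and W = 1{previous
reward}, the remaining columns are:

1. *trial back*: R, 1{o_t = o_{t−2}} (drops the first two trials);
2. *repeat — no repeat*: R, R(2W−1), (1−R)(2W−1);
3. *reward — no reward*: W, W(2R−1), (1−W)(2R−1);
4. *repeat — reward cells*: the four 0/1 cells of R × W;
5. *interaction 1*: R, W, R·W;
6. *interaction 2*: R, W, R(2W−1), (1−R)(2W−1).

All regressors are z-scored within session (population denominator)
after dropping history-incomplete trials; zero-variance columns raise a
named degeneracy error.  Designs 2 and 3 span the same space and fit to
identical likelihoods (tested to 1e−6 across simulated sessions).
Designs 4 and 6 are rank-deficient by construction once an intercept is
included (design 4's cells sum to one; design 6's signed interaction
columns sum to 2W − 1, collinear with W and the intercept): they are
kept in their printed form, fitted by IRLS with a pseudoinverse — which
still maximizes the likelihood — and flagged, with infinite VIF
reported for the collinear columns.  Information criteria (AIC, BIC,
AICc, CAIC) count all columns plus the intercept.  Perfectly predicted
sessions (complete or quasi-complete separation, detected by diverging
coefficients or near-zero deviance) are refit with a small L2 penalty
(λ = 1e−4) and flagged unconverged; their penalized likelihoods are not
comparable across reparameterizations, so design-equivalence claims
apply to the regular fits.  An optional post-hoc filter drops
per-session coefficients beyond |z| > 3 across sessions for downstream
group analyses; it is off by default.

## Behavioral metrics

Learning curves bin each odor's trials by presentation count (25 per
bin, so 200 presentations give 8 bins); the stimulus-averaged curve is
the mean over odors per bin, which makes set sizes directly comparable.
Partial final bins are reported but excluded from the averaged curve.
The repeat split classifies each trial from the second onward as
repeat/non-repeat and reports accuracy and counts per class; the
count-weighted mean of the two accuracies reproduces the overall
fraction correct exactly.

## Validation loop

*Parameter recovery*: draw generating parameters from the documented
prior, simulate one session each, refit, and report Spearman ρ between
generating and recovered values per free parameter (rank-based, so any
monotone reporting scale gives the same answer), over converged fits
only.  Default study size: 30 set-size-2 sessions of 400 trials with 20
restarts — large enough to resolve ρ differences of ~0.3 while keeping
a desk-scale runtime.  *Posterior predictive*: simulate each fitted
session on a fresh schedule of the same design (replaying the source
schedule is available by flag, but a fresh schedule tests the model
rather than schedule memorization), then compare regression #3
coefficients and learning curves between source and simulation, pairing
by session.

The generating prior is α₊ ~ U[0.02, 0.8], β ~ logU[0.5, 10],
s₁, s₃ ~ U[0, 0.6], s₂ (= s₄) ~ U[0, 1]; for variants that free them,
α₋ ~ U[0.2, 0.8] (values near zero would make the variant
indistinguishable from its α₋ = 0 twin by construction) and
φ ~ U[0, 0.3].  These ranges span the regimes a fitted rodent session
plausibly occupies without degenerate corners such as β ≈ 0 everywhere.

## Known limitations

**α₊ is weakly identified at moderate-to-high values.**  With α₋ = 0
and deterministic reward, the unchosen action's value never moves, so
the value contrast saturates at 0.5 after a handful of rewarded trials
for any α₊ above ~0.3; the likelihood is then nearly flat in α₊ and the
MLE often sits at the α = 1 bound.  Recovery of α₊ under the broad
uniform prior is therefore poor (Spearman ρ ≈ 0.2–0.5) even though the
estimator is unbiased at fixed parameter points, and longer sessions do
not help — the information about α₊ lives in the short early transient,
not in session length.  Empirically fitted rodent sessions occupy the
low-α₊ regime, where the parameter is informative.

**α₋ earns little evidence per session.**  Freeing α₋ buys on the
order of one log-likelihood nat per 400-trial session against a BIC
threshold of ln(400)/2 ≈ 3, so per-session selection essentially never
prefers the α₋-free variant, and confusion studies that include it show
systematic off-diagonal mass.  This mirrors the empirical finding that
fitted α₋ is near zero — the very reason the winning family fixes it —
and should be read as a property of the task design (deterministic
reward, two actions), not of the selection machinery, whose calibration
is verified independently on synthetic evidence matrices.

**The synthetic prior is not the empirical parameter distribution.**
Identifiability statements made under the documented prior (broad, with
substantial mass at low β) are conservative relative to studies that
simulate from parameters fit to real sessions.

**Scale choices.**  Default study sizes (30 recovery sessions, 20
confusion cohorts per generator, 10⁶ Dirichlet draws) are the package's
chosen desk-scale defaults; all are parameters, not constants.
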