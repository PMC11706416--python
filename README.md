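# rlstrat

Trial-by-trial modeling of rodent odor-guided two-alternative forced-choice
(2AFC) learning: a reinforcement-learning (RL) model family with one-back
strategy policies, per-session maximum-likelihood fitting, group-level
Bayesian model selection, trial-history logistic regressions, and a
simulate → fit → validate loop, all driven by a synthetic session generator
so every stage is testable without animal data.

The package is for computational cognitive/behavioral neuroscientists who
analyze operant session logs (one row per trial: stimulus, correct side,
choice, reward) and want a reproducible, tested pipeline for asking *how*
an animal solves a 2AFC task: by incremental value learning, by one-back
win-stay/lose-shift heuristics, or a mixture.

## The model

On each trial the agent smells odor *o* and chooses a side *a* ∈ {L, R}.
Values are learned by a delta rule from the uninformative start
Q₀(o, a) = 0.5:

    Q(o, a) ← Q(o, a) + α± (r − Q(o, a))

with α₊ applied to positive prediction errors and α₋ to negative ones
(the winning family fixes α₋ = 0), and optional forgetting
Q ← Q + φ (Q₀ − Q) of all values each trial.  Choice follows a softmax
with inverse temperature β, biased by a one-back strategy weight that
depends on the trial type — the 2×2 of (stimulus repeated vs changed) ×
(previous trial rewarded vs not):

    P(a | o, Tᵢ) ∝ exp( β [ Q(o, a) + bᵢ · 1{a = a₍ₜ₋₁₎} ] )

with T₁ = changed/unrewarded (weight s₁, "inappropriate lose-shift",
b₁ = −s₁ so positive s₁ means more shifting), T₂ = changed/rewarded (s₂,
"stimulus-insensitive win-stay"), T₃ = repeated/unrewarded (s₃,
"inappropriate lose-stay"), T₄ = repeated/rewarded (s₄, win-stay).

Model variants are named by a registry grammar — e.g. the winning model
`a0bs1232` frees {α₊, β, s₁, s₂, s₃} with α₋ = 0 fixed and s₄ = s₂ tied;
`a0b-nos` is the pure-RL baseline; `aabs1232` frees α₋; `a0bs1232-phi`
adds forgetting.  Models are fit per session by bounded multi-start
maximum likelihood and compared by BIC and by random-effects Bayesian
model selection (posterior model frequencies, exceedance probabilities,
Bayesian omnibus risk, and protected exceedance probabilities
pxp = (1 − bor)·xp + bor/K).

Six trial-history logistic regressions predict per-trial accuracy from a
log-transformed per-odor *correct history* count (the incremental-RL
marker) plus one-back repeat/reward codings; designs #2 and #3 span the
same column space and fit identically, which the tests verify.

## Worked example

```python
from rlstrat import task, metrics
from rlstrat.fitting import fit_session, fit_cohort
from rlstrat.selection import evidence_from_fits, group_bms

truth = {"alpha_plus": 0.08, "alpha_minus": 0.0, "beta": 4.0, "phi": 0.0,
         "s1": 0.3, "s2": 0.6, "s3": 0.2, "s4": 0.6}

sched = task.build_schedule(task.SessionSpec(set_size=2, presentations_per_odor=200, seed=11))
session = task.simulate_session(sched, truth, "a0bs1232", seed=12)

split = metrics.repeat_split(session)
print(split.repeat_accuracy, split.nonrepeat_accuracy)   # 0.750  0.426

est = fit_session(session, "a0bs1232", n_starts=20, seed=13)
print(est.negll_, est.bic_)                              # 233.87  497.70
print({k: round(est.params_[k], 3) for k in est.model_spec_.free})
# {'alpha_plus': 0.043, 'beta': 3.598, 's1': 0.282, 's2': 0.63, 's3': 0.247}

sessions = task.generate_sessions(10, task.SessionSpec(2, 200), [truth] * 10, seed=20)
fits = fit_cohort(sessions, ["a0b-nos", "a0bs1", "a0bs1232"], n_starts=10, seed=21)
res = group_bms(evidence_from_fits(fits), seed=22)
print(res.expected_frequency.round(3), res.pxp.round(3))
# [0.077 0.077 0.846] [0.001 0.001 0.998]
```

The simulated agent's strong win-stay weight (s₂ = s₄ = 0.6) makes it
75% correct on repeat trials but *below chance* (43%) when the stimulus
changes — staying after a reward is exactly wrong when the other odor's
correct side is the opposite port.  The session fit recovers the
generating parameters, and group Bayesian model selection across ten such
sessions identifies the generating model with a protected exceedance
probability of 0.998.

The same pipeline runs from the shell:

```
rlstrat simulate --set-size 2 --trials-per-odor 200 --n-sessions 10 --seed 1 --out sessions.csv
rlstrat fit --sessions sessions.csv --models a0b-nos,a0bs1232 --seed 2 --out fits.csv
rlstrat compare --fits fits.csv --method bms --seed 3 --out bms.json
rlstrat run --config examples/demo.yaml     # end-to-end demo with manifest
```

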