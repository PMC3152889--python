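# reachpomdp

Decision-theoretic control of adaptive upper-limb reaching rehabilitation.

After a stroke, reaching exercises are progressed by a therapist who
chooses, trial by trial, how far the target should be and how much
resistance to apply — and when to stop for rest. `reachpomdp` implements an
autonomous controller for that loop as a factored, mixed-observability
**POMDP**: the patient's fatigue, ability *ranges* (the furthest target
distance n(r) reachable at each resistance level r ∈ {none, min, max}) and
learning rate are hidden; the observed trial outcome — time-to-target
(*ttt*), control (*ctrl*) and trunk compensation (*comp*) — is filtered into
a belief state, and a pre-computed policy maps beliefs to one of ten
actions: nine (distance × resistance) targets or *stop*.

The package is aimed at researchers in rehabilitation informatics and
decision-theoretic clinical decision support who want a complete, testable
desk-scale implementation of the model: the enumerable POMDP itself, an
exact Bayes filter, a Perseus-style bounded point-based solver, a
synthetic-patient simulator that closes the loop, and a future-work
continuous-resistance controller based on Beta-mixture success models.

## The model in brief

Each set-target action occupies a ladder position `3(a_r − 1) + a_d`
(a_d, a_r ∈ {1,2,3}); the **stretch** of an action is that position minus
the patient's best attained ladder position, floored at −2, so
s ∈ {−2, …, +9}. Outcome probabilities come from sigmoid **pace
functions** of stretch and fatigue,

```
φ(s, f) = 1 / (1 + exp(−(s − m − m(f)) / σ_s)),
```

one per outcome (reach failure, slow reach, control loss, compensation,
fatigue onset), where `m` is the mean stretch, `σ_s` the slope, and `m(f)`
a horizontal shift applied when the patient is fatigued (negative: adverse
outcomes become more likely at equal stretch). Practising successfully at
or just above range grows the range at the practised resistance with
probability `p_up(learnrate, fatigue)`, subject to the monotonicity
constraint n(none) ≥ n(min) ≥ n(max); a range at d3 spills over, opening
the next resistance from *none* to *d1*. Rewards favour reaching d3 at
maximum resistance (R_goal), targets at or above range (R_stretch) and
clean performance (R_perform); nothing is earned while fatigued, and the
stop action costs C_stop while resetting fatigue (rest). The policy is a
bounded set of α-vectors computed by randomized point-based value
iteration over beliefs sampled by simulation from the 20 admissible
initial range possibilities.

## Worked example

Solve a desk-scale policy and replay the narrative of an able patient who
starts compensating after six clean trials:

```python
import reachpomdp as rp
from reachpomdp import belief as bf
from reachpomdp.simulate import PatientState, run_episode, example1_script

model = rp.RehabModel()                      # default calibration
beliefs = rp.sample_beliefs(model, 500, seed=1)
policy = rp.perseus_solve(model, beliefs, max_alphas=60, iterations=60, seed=1)

patient = PatientState(False, rp.RangeProfile(3, 3, 1), 1)
b0 = rp.initial_belief(model, rp.RangeProfile(3, 3, 1))
log, _, _ = run_episode(policy, model, patient, b0,
                        max_trials=30, scripted=example1_script())
for t in log.trials:
    print(t.trial, t.action.label(), t.perf.comp, round(t.p_fatigue, 3))
print("stopped:", log.stopped)
```

Output:

```
0 d1@max False 0.089
1 d2@max False 0.11
2 d3@max False 0.118
3 d3@max False 0.128
4 d3@max False 0.137
5 d3@max False 0.143
6 d3@max True 0.277
7 d3@max True 0.443
stopped: True
```

The controller escalates the target distance at maximum resistance while
the filtered fatigue probability creeps from 5% to ~14% through clean
repetition, jumps to 28% and then 44% on two consecutive compensations,
and then stops the exercise for rest — the conventional progression
pattern. The same loop is scriptable from the shell:

```bash
reachpomdp solve --out policy.json --seed 1
reachpomdp simulate --policy policy.json --out session.csv --seed 1
reachpomdp sweep --kind stop_cost --values 1,2,4,8 --reps 50 --out sweep.csv
reachpomdp adaptive --out adaptive.csv
reachpomdp export --full --out model.pomdp
```

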