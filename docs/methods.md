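# Methods

This note documents the model implemented by `reachpomdp`, the choices made
where the design was genuinely open, the default parameter values and why
they were chosen, what the synthetic-patient generator does and does not
emulate, and the package's known limitations.

## The decision problem

One reaching *trial* consists of the controller commanding a target
distance d ∈ {d1, d2, d3} at a resistance level r ∈ {none, min, max} (nine
set-target actions) or issuing *stop* (ten actions in all), after which the
trial outcome is observed: time-to-target `ttt ∈ {none, slow, norm}`
(`none` = the target was not reached), control `ctrl ∈ {none, min, max}`,
and compensation `comp ∈ {yes, no}` (improper trunk posture). The
patient's condition is hidden: a binary fatigue state, the *range profile*
n(r) ∈ {none, d1, d2, d3} per resistance (the furthest distance reachable
at that resistance), and a static learning-rate trait in {lo, med, hi}.

### State spaces

Range profiles satisfy monotonicity — a range at a higher resistance never
exceeds one at a lower resistance — giving 20 admissible profiles
(monotone triples over 4 levels, C(6,3)), hence 2 × 20 × 3 = 120
admissible hidden states. A flat product view that mirrors the previous
trial's performance and stretch in the state, with the monotonicity
constraint relaxed (4³ = 64 profiles), has
2 · 64 · 12 · 3 · (3 · 3 · 2) = 82,944 joint configurations; this view is
kept purely as an enumeration cross-check and for the header of the
Cassandra export. All computation — filtering, solving, simulation —
happens on the 120-state mixed-observability form: the performance
variables are observed exactly, so beliefs need only range over the hidden
configurations. The two forms are semantically identical; the reduction is
what makes exact filtering and flat α-vector arithmetic practical.

### Stretch

A set-target action occupies ladder position `3(a_r − 1) + a_d` on the
nine-step difficulty ladder; the patient's attained position is the
maximum of `3(r − 1) + n_r` over resistances with n_r > 0 (0 for an empty
profile). Stretch is the difference, floored at −2, yielding exactly the
twelve integers {−2, …, +9}. The floor treats all deeply-below-range
targets as equivalent ("well within ability"); enumeration confirms that
every one of the twelve values is attained over the 9 × 20 action ×
profile pairs, with extremes +9 (hardest ask against an empty profile) and
−2.

### Pace functions

Every outcome probability is a logistic in stretch,
`φ(s, f) = sigmoid((s − m − m(f)) / σ_s)`, parametrized by the mean
stretch m (φ = 0.5 at s = m when not fatigued), slope scale σ_s (stretch
units), and fatigue shift m(f) (0 when fresh). Curves are stated for the
*adverse* binary event so that each is increasing in stretch, and a
negative shift moves the curve left — the event becomes more likely at
equal stretch when fatigued. Ordinal outcomes are obtained by two-stage
composition, since a logistic defines a binary event only:

- `ttt`: failure pace gives P(none); a slow-given-reached pace splits the
  remainder into slow/norm;
- `ctrl`: a control-loss pace gives P(none); a min-given-some-control pace
  splits min/max;
- `comp` and fatigue onset are directly binary.

The three outcome families are conditionally independent given (stretch,
fatigue). Pace functions can be specified either by (m, σ_s) or by two
anchor points (the "pace limits"), which are fitted in closed form:
σ_s = (s_hi − s_lo) / (logit p_hi − logit p_lo), m = s_lo − σ_s logit p_lo.
The compensation default uses the anchors 0.10 at stretch −1 and 0.90 at
stretch +3 (giving m = 1, σ_s = 2/ln 9 ≈ 0.910).

### Dynamics

Fatigue is *sticky* within an episode: once fatigued, a patient stays
fatigued until the stop/rest boundary. From the fresh state the onset
hazard is the fatigue pace evaluated at the trial's stretch. Range growth
fires only on a successful trial (ttt ≠ none) at stretch 0..1
("at or just above range"), with probability p_up(learnrate, fatigue),
increasing the practised resistance's range one step; a range already at
d3 instead opens the next resistance from none to d1; any growth that
would violate monotonicity is suppressed. Learnrate has no transition —
it is a static trait inferred only through the speed of range growth.

### Reward and the stop action

Per trial: R_stretch if the commanded target was at or above range
(s ≥ 0), R_perform for a clean trial (ttt=norm, ctrl=max, comp=no), and
R_goal when the patient *reaches* d3 at maximum resistance. All positive
components are gated to zero whenever the patient is fatigued, failed to
reach, had no control, or compensated.

Stop is modelled as a one-step *rest* transition: reward −C_stop, fatigue
resets to no, ranges and learnrate carry over. An absorbing-terminal
reading of stop was considered and rejected: with continuation rewards
bounded below by zero (fatigue merely gates rewards to 0) and a
non-negative stop cost, an absorbing stop could never be optimal, so the
controller would never rest — contradicting the behaviours this model
exists to produce (stopping after repeated compensation, episode lengths
that grow with C_stop). The rest reading matches the simulation protocol
exactly (fatigue reset at the boundary, ranges carried over); the
simulator still treats stop as the episode boundary.

## Filtering

Beliefs are exact probability vectors over the 120 hidden states. The
update is `b'(h') ∝ Σ_h b(h) · P(o, h' | h, a)` with the joint kernel
P(o, h' | h, a) = P(perf = o | h, a) · P(f' | h, a) · P(n' | h, a, o)
(ranges condition on the observed success). A zero-likelihood observation
raises an error; the filter never silently renormalises. The episode
boundary applies the rest transform (fatigue mass folded into the fresh
states). Initial beliefs exist for each of the 20 range possibilities:
fatigue no/yes at 0.95/0.05, learnrate uniform (the prior is otherwise
unspecified), and the range mass concentrated on the named profile
(0.85 by default) with the remainder decaying as exp(−d) in the L1
profile distance d — pre-assessment uncertainty sits on adjacent ability
levels, not on the far end of the ladder. A uniform remainder was tried
and discarded: a single clean trial is then strong evidence for distant
high-range profiles (clean performance is most likely at very negative
stretch), which makes the filter leap to abilities no one has assessed.

## Solver

Randomized point-based value iteration in the Perseus style over flat
α-vectors on the 120-dimensional hidden simplex. Belief points are
collected by simulating random set-target actions from the 20 initial
beliefs and filtering (seeded, reproducible). Each stage performs
point-based Bellman backups against the previous stage's value function at
randomly ordered belief points until every sampled belief has improved;
beliefs whose backup would lose value keep their previous maximizing
vector. The α-set is capped at K; when the cap binds, vectors are ranked
by the number of sampled beliefs at which they are maximal (ties: older
first) and the bottom is dropped. Cap pruning can in principle reduce the
value at some beliefs; such stalls are logged, not fatal, and the recorded
per-stage minimum value (`Policy.stage_min_values`) lets callers verify
monotone improvement — at the defaults it is strictly monotone. Greedy
action selection breaks exact value ties toward the lowest action index
(distance before resistance, set-target before stop). Defaults are the
desk scale: 500 belief points, K = 60, 60 stages (≈ 3 s on one CPU);
`config.FULL_SCALE_SOLVER` holds the full-scale preset (3,000 / 150 / 150).

## Synthetic patients and simulation

Patients are simulated from the same parametric family as the planning
model with independently settable pace parameters, enabling both
consistency tests (model-matched patients; observation frequencies agree
with the model by chi-square) and robustness probing. An episode runs
policy → trial → filter until stop or a 50-trial cap; sessions chain
episodes with fatigue reset and range carry-over. A scripted mode replays
fixed or action-conditional observation sequences (manual-entry style);
two bundled scripts encode the worked-example narratives — the able
patient who starts compensating after six clean trials, and the weak
patient who fails at d3@none, the third failure with compensation. The
narratives' trial-by-trial sequences are not fixed by any data; the
bundled scripts are synthetic stand-ins encoding only the qualitative
pattern.

The sweep experiments re-solve the policy per setting and report mean
first-episode run length over 50 randomly drawn patients: over the stop
cost (dearer stop → the controller tolerates higher fatigue beliefs →
longer runs) and over a rightward shift of the fatigue pace curve (lower
onset probability at equal stretch → longer runs). Both trends are
monotone at the default scale.

What the generator does *not* emulate: real patients are not logistic
machines — inter-trial correlation beyond the modelled fatigue/range
state, day-to-day variation, sensor noise in the performance labels, and
any kinematic structure of actual reaching are all absent. Passing tests
therefore demonstrate internal consistency of filter, solver and
controller under the model's own generative assumptions, not clinical
validity.

## Default calibration

No dataset pins the pace parameters or the reward table; all of them
live in the config, and the defaults were calibrated by forward simulation
to reproduce the documented behaviours, then frozen:

| parameter | default | rationale |
|---|---|---|
| comp pace | anchors (−1, 0.10), (3, 0.90), shift −1.0 | the example pace limits; the shift makes a compensation observation strongly diagnostic of fatigue while leaving its absence weak evidence |
| fail pace | anchors (0, 0.10), (4, 0.90), shift −0.25 | at-range trials usually succeed; failure rises steeply beyond range |
| slow pace | anchors (0, 0.15), (4, 0.85), shift −0.25 | normal-time reaches dominate at range |
| ctrl_none / ctrl_min | (1, 0.05), (6, 0.80) / (0, 0.20), (4, 0.80), shifts −0.25 | control degrades with stretch; total loss is rare at range |
| fatigue pace | m = 6.0, σ_s = 2.2 | onset hazard ≈ 0.06–0.12 at stretch 0–2, so the filtered fatigue probability climbs ~5% → ~15–20% over six clean repetitions and episodes end after ~8 trials |
| p_up | 0.4 / 0.7 / 0.9 fresh, halved fatigued | fast enough that two clean trials per distance step plausibly grow the range (and the weak-patient stretch-0 belief reaches ~0.65–0.75), ordered by learnrate, slower when fatigued |
| rewards | R_goal 10, R_stretch 2, R_perform 1, C_stop 3, γ 0.95 | goal dominates; stretching at/above range outweighs milking clean easy trials (otherwise the policy parks below range); C_stop sets the stop threshold so one compensation is tolerated, two are not |

γ is a standard infinite-horizon discount with no canonical value here;
0.95 weights an episode's tail ~8–10 trials deep, matching the intended
session granularity.

## Continuous-resistance controller

The future-work extension replaces the three resistance levels with
u ∈ [0, 20]. Success is modelled per fatigue condition by a latent
failure-threshold curve: the threshold fraction x ~ Beta(a, b) (discretised
on a 201-point grid), and a trial at resistance u succeeds with probability
sigmoid((x·u_max − u)/τ). The posterior-predictive success curve is
smooth, Beta-shaped and non-increasing in u; the not-fatigued prior
Beta(6, 6) dominates the fatigued prior Beta(3.5, 8) in likelihood-ratio
order, so the fatigued curve starts below the fresh one pointwise. The
controller mixes the two curves by the fatigue belief, selects the largest
0.1-grid resistance with mixture ≥ 0.5, and updates by tempered Bayes: the
fatigue belief moves by the κ-tempered likelihood ratio of the outcome
under the two curves, and each threshold posterior is updated with
exponent κ times its fatigue responsibility (κ = 1 is full Bayes; κ = 0
freezes the model). Monotone likelihood ratios guarantee that success
never lowers, and failure lowers, the next selection. β_n/β_y admit two
readings — Beta densities over resistance, or success-probability curves
with Beta-shaped parametrization; the curve reading is adopted because
only it supports a half-probability selection rule (β_sum ≥ 0.5 at a
resistance value).
τ defaults to 0.4 resistance units — a sharp but not degenerate success
transition, under which the selected resistance converges to within one
grid step of a stationary patient's half-success resistance in 200 trials.

## Numerical and interface choices

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; identical seeds give bit-identical trajectories, belief sets and
  policies.
- Distributions are validated to sum to 1 within 1e−9; beliefs reject
  negative entries and re-normalise away float drift.
- Sigmoid evaluation guards overflow; probabilities are strictly inside
  (0, 1) until float saturation (|z| ≳ 37).
- Exact value ties in action selection and α-vector choice break to the
  lowest action index; pruning ties break by age.
- Config files are YAML with unknown-key rejection and field-naming error
  messages; saved configs round-trip exactly.
- Cassandra `.pomdp` export writes complete, re-parseable tables for any
  enumerable model whose kernel factorises as T(s′|s,a)·O(o|a,s′) (verified
  numerically before writing). The mixed-observability hidden model does
  not so factorise — its observation depends on the *previous* hidden
  state — and the flat 82,944-state view would need ~6·10⁷ table lines, so
  both are exported header-only (exact counts, tables omitted with a
  comment). The header is still useful as a structural cross-check.

## Limitations

- Desk-scale solver settings trade a little policy quality for seconds-long
  solves; the full-scale preset is provided but not the default.
- The calibration reproduces documented qualitative behaviour, not any
  clinical dataset; absolute belief values in the replays are
  calibration-dependent.
- The two-stage ordinal composition and outcome independence given
  (stretch, fatigue) are modelling conveniences; real performance
  dimensions are correlated beyond that.
- No 2D targets, no hardware/haptics interfacing, no symbolic (ADD)
  compression — flat enumeration is exact and sufficient at this scale.
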