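# Methods

## Model

Each agent's attitude toward two vehicle options is a localist
parallel-constraint-satisfaction network in the HOTCO tradition: one
clamped *special* unit (the activation source; its links to the five
goal units carry goal importance on [0, 1]), one *valence* unit (its
links to goals and options carry affective associations on [−1, 1]),
five goal units and two option units, with goal–option links carrying
beliefs on [−1, 1]. Links are symmetric, the diagonal is zero, and
three structural exclusions apply: no intra-layer links (a goal–goal
variant exists behind `allow_intra_layer` but is off by default), no
special–option links, and no mutual inhibition between options — the
two vehicles are not treated as antagonists, so an agent can hold two
positive attitudes at once.

Settling starts from zero activations (clamped units at +1), updates
all free units synchronously under the two-branch Grossberg rule with
decay in *both* branches, and stops when the largest per-node change
drops below the convergence threshold. Three numerical choices matter:

- **Net-input clamping.** `net_j` is clipped to [−1, 1] before the
  update; the bounding logic of the rule presumes `|net| ≤ 1`.
- **Activation clipping.** Even with clamped net input the raw rule can
  overshoot the bounds by up to `d` when `|net|` is near 1 (at
  `a = −1, net = 1` one step gives 1.05), so activations are
  hard-clipped to `[min, max]` after every update. This makes the
  boundedness invariant exact rather than approximate.
- **Valence clamping.** The valence unit is clamped at +1.0 by default,
  so valence-link weights act as direct affect injections. Letting it
  settle freely (`clamp_valence=False`) is supported; on synthetic
  populations the two variants produce nearly identical baseline
  attitudes, energies, and condition-level energy shifts, so nothing in
  the shipped analyses hinges on this choice.

Energy is the ordered-pair sum `E = −Σ_i Σ_j w_ij a_i a_j`, so a single
satisfied link between two units at +1 contributes −2.

### Settling speed

With `d = 0.05` and threshold 1e−4, default-population networks settle
in a median of ~15–20 iterations (90th percentile ~55). The tail is
long: frustrated constraint patterns — e.g., a goal whose priority
pulls it positive while affect and beliefs pull it negative — create
slow modes with per-iteration contraction up to ~0.98, and roughly 1–3
networks per 100 need more than 100 iterations (the slowest observed in
1,000 draws needed 272). The iteration cap is therefore a safety valve
set at 400, comfortably above the slowest observed settle; it is not
part of the dynamics. Non-convergent settles (none observed at this
cap on default populations) are flagged and excluded from fitting with
a logged count.

## Communication and learning

Vignettes are structural cells only (condition × vehicle × same-valence
goal pair × valence); no message text is modeled. Negative messages
mirror the positive encoding at −1.0. Set organization is
deterministic: within each condition and vehicle, vignettes are dealt
round-robin to the four sets (positives first, staggered across
vehicles), which yields exactly 5 vignettes per vehicle per set and a
5:5 overall valence split, with per-vehicle valence counts differing by
at most one; a seed permutes goal pairs before the deal.

The weight-adjustment rule is the second-order polynomial in the
receiver's prior weight `w_r` and the dissonance `Δ`. Two conventions
the polynomial itself does not pin down:

- **Sign of the dissonance:** `Δ = w_s − w_r`, so `b1 > 0` means
  assimilation toward the sender.
- **Combination rule:** the new weight is `clip(w_r + Δw, −1, 1)`,
  applied symmetrically; addition is the minimal reading of an
  "adjustment", and clipping keeps the weight admissible.

Treatments are independent by default: every vignette is applied to a
fresh copy of the agent's baseline network, because the reported
attitude is defined per vignette relative to the original attitude. A
cumulative mode (each event hits the network left by the previous one)
is available via `cumulative=True` / the `--cumulative` CLI flag; it
amplifies condition-level energy shifts but does not change their
direction on synthetic populations.

### Fitting b1..b5

`D` is minimized per condition over the lattice of step 0.1 on
`[−1, 1]^5`, matching the granularity of the published optima (0, ±0.3,
±0.7, 1.0). The search is coarse-to-fine and fully seeded:

1. a full factorial grid at step 0.5 (3,125 points) scored on an
   evenly spaced subsample of events;
2. differential evolution (Sobol init, popsize 16, ≤50 generations,
   vectorized over whole candidate populations) on the subsample,
   rounded to the lattice;
3. cyclic coordinate descent (full 21-point line search per
   coordinate) with pairwise ±0.1 escape moves, first on the subsample
   per start, then on all events from the best end points.

Ties within 1e−12 break toward the smallest L1 norm, then
lexicographically — so all-zero data select the zero vector. The
multi-stage design exists because the problem is genuinely multimodal:
senders only ever transmit ±1, which makes the five polynomial features
collinear, and clipping at the weight bounds flattens whole directions
of the landscape. Plain coordinate descent stalls in these valleys;
the global stage does not. Evaluation is vectorized end to end — all
candidate × event networks are settled in one batched, active-set
loop — which is what makes grid-resolution fitting of 1,600-event
conditions take about a minute each.

At full study size (480 agents, 1,600 treatments/condition) the
generating coefficients are recovered exactly at zero noise and at
report-noise sd 0.05 in all three conditions. At small samples
(~160 treatments) the emotional condition is weakly identified: many
of its adjustments clip at the bounds, leaving near-equivalent
coefficient vectors at the noise floor (see
`examples/04_parameter_recovery.py`).

## Synthetic populations

The generator emulates the study's instruments, not its (unavailable)
response distributions. Ratings are truncated-normal latents rounded
onto the integer scale points. Defaults, chosen once for realism:

| field | scale | latent mean (sd) | rationale |
|---|---|---|---|
| goal importance | 1..6 | 4.5 (1.2) | surveyed goals are common motives; skew high |
| goal valence | −4..+4 | 2.5 (1.2) | the five goals are intrinsically desirable; clearly pleasant |
| option valence | −4..+4 | coupled (1.5) | affect tracks beliefs: mean shifts 1.5 differential points per belief scale point above midpoint |
| belief | 1..6 | 3.5 (1.3) | centred at the scale midpoint (zero weight) |

The option-valence/belief coupling encodes within-agent attitude
coherence — real respondents who believe a vehicle serves their goals
also feel positively about it. An optional two-pole mixture
(`polarization` ∈ [0, 1]) splits agents into pro-combustion and
pro-electric clusters by shifting belief latents ±1.5 scale points and
option-valence latents ±2 differential points; the polarized population
is what makes the inverted-U energy–attitude curve pronounced.
Condition assignment is balanced round-robin; every agent draws its
ratings, its set choice (uniform among its condition's four sets) and
its presentation order from an own substream of one master seed, so
all outputs are pure functions of (config, seed).

Reports are generated as `A_emp = A_sim(true b) + ε` with ε Gaussian
(sd configurable) truncated so `A_emp ∈ [−1, 1]`; the equivalent
seven-point change rating is emitted by inverse rescaling and rounding.
What passing recovery tests show is that the *pipeline* is consistent —
the estimator finds the coefficients that generated the data. They do
not show that real respondents follow the polynomial rule, and none of
the synthetic marginals are calibrated to the study's empirical
distributions (which are not printed).

## Analyses

- **Prior-attitude validation:** Pearson r per option between settled
  baseline activations and an importance-weighted mean of rescaled
  beliefs (`Σ p_g·w_go / Σ p_g`). On default populations r ≈ 0.77–0.87.
- **Energy–attitude curve:** least-squares quadratic of baseline energy
  on baseline attitude; the quadratic coefficient is negative (inverted
  U) on polarized populations — extreme attitudes are coherent, ambivalence
  is not.
- **Pre/post coherence:** per-condition means of treatment-level energy
  with a seeded bootstrap interval on the paired difference.
- **Weight-change surfaces:** realized (clipped) Δw binned by prior and
  sender weight (default 0.5-wide bins), per condition and link type;
  empty bins are reported missing, not zero.
- **Backfire rate:** share of events whose attitude movement opposes the
  message valence by more than 1e−9, stratified by condition, valence
  and prior-attitude sign.
- **Agreement analog:** the empirical agreement rating has no synthetic
  counterpart; the regression machinery accepts any supplied proxy and
  defaults to the negative mean absolute sender–receiver dissonance on
  transmitted links. Results using it are structural analogs, not
  replications.

### Known behavior worth stating plainly

With the published emotional-condition coefficients, mean energy
*rises* after treatment on every synthetic population we generated
(unimodal, polarized, extreme-valence, low-importance; clamped or free
valence; independent or cumulative treatments). The mechanism is
mechanical: `b5 = −0.7` times a squared dissonance near 1 pushes
moderate affect links against the message and against the settled goal
activations. The combined condition's energy decrease and the rational
condition's smaller shift do emerge as expected. A population whose
affect-link distribution differs from our synthetic defaults could
shift the emotional condition's balance between reinforcement (which
lowers energy) and dissonance-driven polarization (which raises it);
we did not find a realistic one that does.

Attitude-level backfire also occurs under a pure assimilation rule
(`b1 > 0` only): strengthening a belief about a goal the agent finds
unpleasant *lowers* the advocated option's activation. Backfire at the
attitude level is a network property, not only a learning-rule
property.

## Problem sizes and defaults

Default runs use the study design sizes: 480 agents (160 per
condition), 120 vignettes in 12 sets, 4,800 treatments. The test suite
exercises reduced populations (12–120 agents) for the structural and
directional checks and the full 480-agent size for parameter recovery;
examples use 48 agents. Bootstrap intervals default to 1,000
resamples. All analyses are deterministic given the master seed.

## Limitations

- Vignettes are design cells; message wording, sender credibility and
  source-discounting are out of scope.
- Learning coefficients are per condition, not per agent.
- The synthetic marginals are stand-ins; every directional finding on
  them is a property of the model plus those defaults, not an empirical
  replication.
- Synchronous settling with symmetric weights can produce slowly
  decaying near-oscillations in frustrated networks; the iteration cap
  and convergence flags make this visible rather than silent.
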