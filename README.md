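# pcsattitude

Parallel-constraint-satisfaction (PCS) models of attitude formation and
change under persuasive communication, with an error-correction
learning rule for motivated reasoning, built for the vehicle-choice
domain (combustion vs. electric cars) and runnable end to end on
synthetic survey data.

The package is for computational social scientists and attitude-dynamics
modelers who want a tested, seedable implementation of the
HOTCO-style coherence network — survey ratings in, settled attitudes
and coherence out — plus the communication layer that turns factorial
vignette experiments into weight-transmission events and fits how
receivers update their mental structure.

## The model

**Attitude networks.** Each respondent is a localist network: a clamped
*special* unit whose priority links `p_g ∈ [0, 1]` encode goal
importance, a *valence* unit whose links encode affective associations,
five goal units, and two option units. Symmetric link weights
`w_ij ∈ [−1, 1]` come from rescaled survey ratings. Activations settle
synchronously under the two-branch Grossberg rule

```
a_j(t+1) = a_j(t)(1−d) + net_j · (max − a_j(t))   if net_j > 0
a_j(t+1) = a_j(t)(1−d) + net_j · (a_j(t) − min)   otherwise
net_j    = clip(Σ_i w_ij a_i(t), −1, 1)
```

with decay `d = 0.05` and bounds `[min, max] = [−1, 1]`, until the
largest per-node change falls below 1e−4. The settled activation of an
option unit is the simulated attitude; coherence is the Hopfield-style
energy `E = −Σ_i Σ_j w_ij a_i a_j` (lower = more coherent).

**Persuasion.** A message is a cell of the factorial design condition ×
vehicle × goal-pair × valence (3 × 2 × 10 × 2 = 120 vignettes, organized
into 12 balanced sets of 10). It encodes as a *sender network* whose
five message links carry ±1 and all other links 0.01. Rational messages
transmit the two belief links, emotional ones the three affect links,
combined all five. Each transmitted receiver weight updates by the
second-order polynomial in the dissonance `Δ = w_s − w_r`:

```
Δw = b1·Δ + b2·w_r + b3·Δ·w_r + b4·w_r² + b5·Δ²,   w_r ← clip(w_r + Δw, −1, 1)
```

**Fitting.** The five coefficients per condition are estimated by
minimizing the mean squared error `D = (1/N) Σ (A_sim − A_emp)²`
between simulated and reported post-treatment attitudes, by a seeded
coarse-to-fine search over the lattice of step 0.1 on `[−1, 1]^5`
(coarse factorial grid → vectorized differential evolution →
coordinate descent with pairwise escape moves; ties break toward the
smallest L1 norm).

Because the original survey responses are not public, a first-class
synthetic-data module generates populations with the study's
instruments and scales (six-point importances and beliefs, −4..+4
semantic differentials, a seven-point change report), balanced
condition assignment (3 × 160 agents by default), and a ground-truth
response model for parameter recovery.

## Worked example

`examples/03_persuasion_event.py` sends a positive emotional message
about electric cars to a receiver who dislikes them:

```
link                                    sender     pre    post
comfort -- valence                       +1.00   -0.50   -1.00
eco_friendliness -- valence              +1.00   -0.50   -1.00
e_car -- valence                         +1.00   -0.75   -1.00

attitude toward e_car: -0.952 -> -0.952
network energy: -16.599 -> -15.160
```

All three transmitted affect links move *away* from the +1 message —
the backfire effect: for a receiver with negative prior affect the
dissonance-squared term (`b5 = −0.7` in the emotional condition)
dominates the update and polarizes the mental structure further. The
other examples build and settle a single network (01), enumerate the
vignette design (02), recover known coefficients from noisy synthetic
reports (04), and run the full pipeline with validation (05).

A thin CLI wraps the pipeline:

```bash
pcsattitude run-all --seed 7 --out-dir run_output/full   # full study size
pcsattitude validate run_output/full
```

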