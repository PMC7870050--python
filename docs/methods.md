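# Methods

This note documents the models implemented in `fracturetwist`, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not demonstrate about real cohorts.

## Synthetic cohort model

The generator is class-conditional: each record is first assigned the
further-fracture outcome (exact stratified counts, 93:79 by default —
`round(n_total · 93/172)` fractured), then its 13 variables are drawn from
per-group Gaussians with the published group means and SDs, truncated at
the published whole-cohort minima and maxima. Truncation uses per-value
rejection sampling (bounds sit roughly 2 SD or more from the means, so
acceptance is high); when a within-group correlation matrix is supplied,
sampling switches to a Gaussian copula with truncated-normal marginal
quantile functions, which preserves both the marginals and the rank
correlation structure.

Parameters and units: ages in years, BMI in kg/m², BMC in g, BMD in g/cm²,
SDI and BSI dimensionless. The published tables print no covariances, so
the default is within-group independence; `plausible_correlation(r=0.6)`
offers a preset tying BMC/BMD positively and both negatively to BSI within
each skeletal site (higher strain index = mechanically weaker bone), used
for map-structure tests. Follow-up time is deliberately not modelled: the
published follow-up summary (mean 3.28, SD 2.14, median 4.95, range 1–11
years) is internally inconsistent (median ≫ mean at that skew) and no
stage of the analysis consumes time.

Truncation bias is real and computed, not assumed away: the fractured-group
age distribution N(70.35, 8.95²) truncated to [44, 87] has exact mean
69.744, and generator tests compare sample moments to the truncated-normal
oracle (`scipy.stats.truncnorm`) within 4·σ/√n bands.

Benchmark specs: `planted_signal_spec(shift, shift_idx)` produces 13
unit-variance variables with a known subset shifted between groups
(default two variables at 1.5 SD — strong enough for reliable recovery at
n = 200, weak enough that selection is non-trivial); `null_spec()` removes
all class signal for permutation-style null levels.

What the synthetic cohorts do *not* emulate: measurement error structure,
site- and device-specific calibration, non-Gaussian tails, informative
follow-up, and the true inter-variable dependence of densitometry.
Passing the recovery tests shows the algorithms work when their assumptions
hold, not that the published clinical accuracies are reproduced.

## Scaling and the high/low expansion

Each variable is min-max scaled, x′ = (x − min)/(max − min), with ranges
taken from the data being scaled (matching the published worked example,
where 0.521 and 1.3 are the observed extremes of lumbar BMD and 0.64 maps
to 0.15). For the classifier path, training-set ranges are applied to the
held-out subset with clipping to [0, 1] and a logged warning, so no test
information leaks into the transform. A constant column is an error, never
silently mapped to a constant.

The semantic-map path expands each scaled variable into a "high" node (the
value) and a "low" node (1 − value), plus the two binary outcome nodes
("further fracture", "no further fracture"), 28 columns in all. The map
consumes all 13 variables rather than the TWIST-selected subset, matching
the breadth of the published maps. The classifier path never sees the
complement columns (they are affinely redundant for an MLP).

## Evolutionary core and TWIST

The original "genetic doping" operators are proprietary and unpublished;
this package uses an openly documented stand-in with the same intent:
generational GA, tournament selection (size 3), uniform crossover (rate
0.9), per-bit mutation (0.02), elitism 2, and a doping step replacing 10%
of each offspring generation with recombinations of the incumbent best and
a fresh random genome (diversity injection). Defaults: population 24,
20 generations — at most 24 × 21 fitness evaluations, a few seconds per
run at n = 200. The running best is monotone by construction and the best
genome ever evaluated is returned.

TWIST encodes 13 feature bits plus one split bit per record. Fitness is
the mean balanced accuracy of an inner MLP (4 hidden units, 80 epochs,
learning rate 1.0, fixed seed 17 for every evaluation) trained A→B and
B→A on the masked, cohort-scaled features. Repair, not rejection: an empty
mask receives the best univariately ranked feature; subsets are kept at
≥25% of records and within 5 percentage points of the global class
proportion by deterministic index-ordered moves and swaps. The published
split (A = 90 with 49/41, B = 82 with 44/38) is near-proportional, which
this soft constraint reflects while still letting the search discover the
split. Note the published per-direction test-set counts (99 records,
56/43) are inconsistent with those subset sizes; the package follows the
subset-size description for the protocol and uses the printed counts only
as inputs to the metric worked examples.

Expected null behaviour: because the search maximises over many evaluated
genomes, its best fitness on signal-free data sits above 0.5 (selection
bias of a maximum over noisy scores) — empirically ≈0.55–0.59 at n = 200
with the default budget. This is a property of the procedure, shared by
the original system, and is why validated accuracy, not search fitness, is
the reported quantity.

## MLP classifier

One logistic hidden layer (default 4 units; 8 is equally supported and
logged, since the source analysis reports both), logistic output,
cross-entropy loss, full-batch gradient descent (learning rate 0.5, 400
epochs by default), seeded uniform(−0.5, 0.5) initialisation. Full-batch
updates make training invariant to record order and bit-reproducible under
a fixed seed — a requirement for the A-B/B-A protocol and for checksummed
pipeline reruns, which is why stochastic minibatching and adaptive
optimisers are deliberately absent. The loss uses `xlogy`, so an exactly
wrongly-saturated output produces an infinite loss and training aborts
with the epoch index; no early stopping by default, an optional patience
parameter exists.

## Validation protocol and metrics

"Overall accuracy" is defined as (sensitivity + specificity)/2 — balanced
accuracy. This definition uniquely reproduces the published arithmetic
((67.86 + 83.72)/2 = 75.79, (82.14 + 83.72)/2 = 82.93, pooled
75.00/83.72/79.36), which raw accuracy does not; it is recomputed from the
components in every emitted row, never stored. Metrics are kept at full
precision and rounded half-up to 2 dp only for display. AUC is the
Mann–Whitney probability P(score⁺ > score⁻) + ½·P(tie), computed via
average ranks; the pooled AUC is the mean of the two directions,
(0.782 + 0.896)/2 = 0.839 (the published pooled value 0.83 is this number
truncated). Each direction trains an independent model with a seed derived
from the configured seed (2s+1, 2s+2).

## Auto-CM and the connectivity map

Update equations, per record with node signals in [0, 1] and contraction
parameter C:

    m_h = m_in · (1 − v/C)
    Δv  = (m_in − m_h) · (1 − v/C)
    Net_j = Σ_i m_h_i · (1 − W_ij/C)
    m_out_j = m_h_j · (1 − Net_j/C)
    ΔW_ij = (m_h_j − m_out_j) · (1 − W_ij/C) · m_h_i

There is no learning rate; the (1 − ·/C) factors self-limit every update
and keep all weights in [0, C] (asserted each epoch). C defaults to
⌈√(record count)⌉. Weights are initialised at 1e-3, not 0: zero is a fixed
point of the first-layer update, and without first-layer contraction the
hidden signals never vanish, letting every lateral weight saturate towards
C and erasing the similarity structure. With a small positive start the
first layer contracts in a few epochs, the hidden signals die out, and W
freezes with entries ordered by co-activation — the trained matrix is then
read (symmetrised) as the variable-similarity matrix. Training is
deterministic: fixed record order, constant init, convergence when the
largest epoch-to-epoch weight change falls below 1e-4.

The prior-probability similarity is the concordance index
c/(c + d) with fuzzy concordance c = Σ u·x + (1−u)(1−x) and discordance
d = Σ u(1−x) + (1−u)x — one committed interpretation of a
concordance/discordance ratio, since the original equation is not public.
Both sources are pluggable; the default map uses the Auto-CM weights.

Distances are d_ij = s_max − s_ij (s_max = largest off-diagonal
similarity), so the MST of d equals the maximum spanning tree of s. The
MST is exact Kruskal with lexicographic node-pair tie-breaking (edges
inserted in sorted order under a stable sort), making maps
byte-reproducible. The "maximally regular graph" objective is not publicly
defined; this package scores G_k = MST + top-k non-tree edges (descending
similarity) by H(G_k) = (1 − CV(degree)) · (mean similarity of added
edges), H(MST) = 0, and returns the argmax over k ≤ max_extra (default 6),
logging every (k, H). This is a documented interpretation: it rewards
strong loops while penalising degree concentration. On independent-variable
cohorts H often stays ≤ 0 and the map is the bare MST; correlated or
planted-signal cohorts produce loop edges.

## Pipeline reproducibility

The pipeline derives per-stage seeds from one global seed via
`numpy.random.SeedSequence.spawn`, records every artifact with its SHA-256
checksum in a manifest, and reruns with the same configuration reproduce
all artifact checksums exactly. Stage failures are recorded in the
manifest before the exception propagates.

## Problem sizes

Default study conditions used by the tests and the acceptance script:
cohorts of 172 (published size) or 200 records (benchmark specs), 10,000
records for moment-recovery checks; GA budget 24 × 20; 20 seeded runs for
planted-signal recovery, 10 for the end-to-end accuracy band, 5 for the
null level; 100 random 5-node instances for the MST enumeration oracle.

## Known limitations

- The GenD stand-in and the MRG regularity score are faithful-in-spirit
  interpretations, not reproductions, of proprietary components; published
  map topologies and exact trajectories are out of reach without the
  original data and software.
- Search fitness is optimistically biased (see above); only the A-B/B-A
  validated metrics should be quoted.
- The published headline accuracies were computed on the undeposited
  clinical cohort; this package demonstrates the machinery on synthetic
  cohorts with known structure instead.
- The Auto-CM similarity depends on scaling; variables are comparable only
  because all are min-max scaled to [0, 1] first.
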