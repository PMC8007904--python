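# Methods

`spiketree` infers *effective connectivity* — which recorded units' firing
carries information about an upcoming spike in a chosen target unit — by
casting the question as supervised classification: can a categorical
decision tree predict, from the activity of the other units in the
preceding 50 ms, whether the target fires?  Units the fitted trees rely on
are candidate presynaptic partners.  The package contains a spiking-network
simulator with known wiring to validate that claim, the interval encoder,
the tree learner, the evaluation machinery, and four subset-search
procedures.  This note records the models, the conventions chosen where a
convention was required, and what the synthetic benchmark does and does not
establish.

## The simulated circuit

The benchmark circuit is a scaled-down Izhikevich spiking network: two
*disconnected* subcircuits of 40 neurons (30 regular-spiking excitatory,
a = 0.02, d = 8; 10 fast-spiking inhibitory, a = 0.1, d = 2), every neuron
emitting exactly `m_out = 5` synapses onto distinct partners within its own
subcircuit.  Inhibitory neurons project only onto excitatory ones, with a
fixed 1 ms delay and fixed weight −5 mV.  Excitatory synapses carry integer
conduction delays drawn uniformly from 1–5 ms and evolve under additive
STDP (trace amplitude 0.1 for potentiation, 0.12 for depression, 0.95/ms
trace decay ≈ 20 ms time constant; the eligibility derivative is applied
once per simulated second with a 0.9 decay and a +0.01 constant drift) and
are clipped to `[0, s_max]`.  Membrane dynamics follow the standard form
v' = 0.04v² + 5v + 140 − u + I, u' = a(0.2v − u), spike at v ≥ 30 mV, with
1 ms steps and two 0.5 ms half-steps for v.  Initial excitatory weights are
0.6·`s_max`, keeping the initial-to-maximal ratio of the reference
parameterization as `s_max` is calibrated.

The second subcircuit exists to provide spike trains that are genuinely
unrelated to the target, as blind multielectrode recordings would contain.
Spontaneous activity is maintained by a random external input: each
millisecond, with probability `input_rate` (default 1), one uniformly
chosen neuron from a configurable recipient set receives a current pulse of
`input_strength` mV.

**Target.** The target unit stands in for a primary afferent pooling many
last-order inputs.  It is the excitatory neuron of subcircuit 0 with the
largest number of excitatory monosynaptic inputs (lowest id on ties;
typically 7–9 under these circuit statistics).  Weakly connected targets
are avoided deliberately: a target that fires rarely lets STDP depress some
of its input synapses to zero, and a structurally connected unit with a
silent synapse has *no* effective connectivity left to detect — by any
method.

**Uncertainty levels.** Which neurons receive the external input sets how
much of the target's firing is explainable from the recorded circuit:
*high* — all neurons (some target spikes are driven by unobservable
input); *medium* — all but the target; *low* — all but the target and its
monosynaptic presynaptic neurons, so every target spike must be caused by
recorded activity.

**Coincidence requirement.** The circuit operates in a regime where one
maximal-strength synapse cannot discharge a resting cell but two
simultaneous ones can.  Numerically, a 1 ms pulse fires a resting
regular-spiking cell above ≈ 16.35 mV, so the property restricts
`s_max` to roughly 8.2–16.3 mV; the calibration grid only contains values
it verifies to satisfy the property.

**Calibration.** `s_max` and `input_strength` are per-level knobs adjusted
so the target keeps a comparable, afferent-like firing rate across
uncertainty levels.  `calibrate()` scans a fixed grid (s_max ∈ {8…16},
input_strength ∈ {8…44}), simulates a probe at the *full experiment
duration* — STDP makes rates non-stationary, so a short probe
underestimates the long-run rate severalfold — and picks the in-band
candidate closest to the 0.5 Hz low edge of the 0.5–3 Hz acceptance band.
The low set-point reflects what the target models: primary afferents are
by far the slowest elements of their circuits (an order of magnitude
slower than the interneurons driving them).  The choice of operating point
matters for headline metrics: complete-dataset precision (and hence MCC)
depends on the positive-class prevalence, so a 2 Hz target yields visibly
higher complete-set MCC than a 0.5 Hz target with the identical classifier.

**Ground truth.** Labels are shortest-path synaptic distances to the
target over *all* synapses (BFS on reversed edges): monosynaptic,
disynaptic, trisynaptic, other-connected, disconnected.  Recovery results
are always scored against the *excitatory* monosynaptic set.

## Interval encoding

Each target spike defines a positive interval: the 50 ms window ending at
the spike, whose timestamp it becomes.  Remaining time is tiled forward,
gap by gap, into 50 ms negative blocks (timestamp at block end); a gap's
terminal remainder shorter than 50 ms is discarded, and negative spans
never overlap positive windows.  Target spikes within the first 50 ms of
the recording are dropped.  Overlapping positive windows (target
inter-spike interval < 50 ms) each keep their own row.

Within a window, a predictor unit's spikes become a code: offsets
(timestamp − spike time) are binned half-open at 10 ms — `[0,10) → A`,
`[10,20) → B`, … `[40,50) → E` — one letter per spike, letters sorted, with
`"0"` for silence.  A spike exactly at the timestamp codes `A`; exactly
50 ms before, it is outside the window.  Codes are *atomic* categories:
`"BBD"` is one category, not a combination of three.  The target's own
history is never a predictor column.

With a target near 0.5–1 Hz, a 1000 s recording yields ≈ 19 600–19 800
intervals; the shortfall from the nominal 20 000 is the per-gap remainder
(≈ 25 ms expected per gap) plus positive-window overlap.

## The tree learner

A from-scratch C4.5/C5.0-family learner for categorical attributes:

* **Splits** are multiway (one branch per observed category), chosen by
  gain ratio among attributes whose information gain is at least the
  average gain of the usable candidates; a usable split needs at least two
  populated branches and at least two branches with ≥ `min_cases` (2)
  cases.  A categorical split exhausts its attribute below that node.
  Ties in gain ratio break by attribute order in the table.
* **Pruning** is pessimistic error-based pruning (collapse-only, no
  subtree raising), confidence CF = 0.25, using the exact binomial upper
  confidence limit U such that P(X ≤ e | n, U) = CF.  Pruning is
  deliberately **cost-blind** (majority-class errors): mixing the
  confidence bound with asymmetric costs either collapses perfectly
  predictive subtrees toward all-positive leaves or strips every weak
  split whose small branch flips to the expensive class.  The latter is
  what destroys single-attribute models of weakly informative units — and
  their weak-but-nonzero MCCs are exactly what the iterative elimination
  ranks on.
* **Costs** (default FN = 3.5, FP = 1) act at leaf-class assignment and
  prediction: a leaf predicts firing when `positives·3.5 > negatives·1`
  (ties toward class 0), and a boosted committee votes with those costs.
* **Unseen categories** at prediction route to the branch that received
  the most training cases, so prediction never fails on new codes.
* **Variable importance** is C5.0's "usage": the percentage of training
  cases whose prediction path meets at least one split on the attribute
  (counted once per case, at the shallowest such split); committee members
  are averaged.  The *primary group* is the attribute set with importance
  > 0.
* **Boosting** (`trials` > 1) is AdaBoost-style reweighting with
  per-trial committee weight log((1−err)/err), stopping early on err = 0
  or err ≥ ½.  It exists for the single-tree-versus-committee comparison;
  the default is one tree.
* **Rules** are root-to-leaf conjunctions of category tests (the fallback
  branch's test also accepts unseen codes); rule application reproduces
  tree prediction exactly and is only defined for single trees.

## Evaluation protocol

Positives are rare (a 0.5 Hz target gives ~500 positives against ~19 000
negatives), so models are trained on a **snap** set: all positives plus
`ratio` × positives negatives drawn uniformly without replacement (default
1:4; all negatives, with a warning, if fewer exist).  The snap set splits
80/20 into training and validation, stratified by class, with
floor(0.8·n) per class in training.  Metrics — precision, recall, MCC,
with any zero denominator mapped to 0 — are reported on training,
validation, snap, and the complete table; the complete set is the
headline because it restores the true class balance.  Multi-seed runs
derive per-repetition seeds from one master seed and report mean and SEM
(sample SD/√n, n−1 denominator).

## Search procedures

* **Direct**: one model on everything; its primary group is the estimate.
* **Individual**: one single-attribute model per unit (all sharing one
  snap partition so MCCs are comparable), ranked by complete-set MCC.
* **Combinatory**: all 2ⁿ−1 subsets (guarded to n ≤ 16), one model each,
  sharing one snap partition per seed; subsets ranked by complete-set MCC
  (ties: smaller subset, then lexicographic).  Each unit's frequency in
  the top ceil(0.01·(2ⁿ−1)) subsets is its score; units with at least half
  the maximal frequency form the **relevant group**.  The 50% rule makes
  explicit what reading the frequency histogram by eye does implicitly.
* **Iterative**: units ranked by individual MCC; the worst remaining unit
  is removed each epoch and the full model re-fit.  The **critical point**
  is the smallest subset whose MCC is within 0.01 of the trajectory
  maximum.  An optional prefilter (off by default) first drops units with
  individual MCC ≤ 0, mirroring the practice of excluding units with
  negligible individual metrics before elimination.
* **Recursive**: fit on the current subset, split into primary
  (importance > 0) and secondary children, recurse into both; stop at
  singletons, fit failures (single-leaf models), or `max_depth`.  If every
  unit has positive importance, split at the importance median (strictly
  above → primary).

## Problem sizes and numerical conventions

Reference runs simulate 1000 s (10⁶ 1 ms steps) and encode ~19 700
intervals over 79 predictor units.  The test suite uses this full-scale
reference experiment once (shared fixture), five independent circuit seeds
for recovery properties, 300 s recordings over 10 seeds for the
uncertainty-ordering property, and a 10-unit panel for the boosting
comparison; these sizes were chosen so each property is measured at the
smallest scale where it is stable.  Membrane potential is clamped at
2000 mV inside half-steps as a divergence guard (clamp events are counted
and reported).  Spike times are recorded at 1 ms resolution in seconds.
Encoding edge cases (empty recordings, silent targets, absent units)
return empty tables or raise named errors as documented in the module
docstrings.

## What the benchmark shows — and what it does not

Passing the synthetic benchmark shows that, in a sparse coincidence-driven
circuit whose target is fully (low uncertainty) or mostly (medium/high)
driven by recorded units, cost-sensitive categorical trees on 50 ms
interval codes recover the excitatory monosynaptic partner set and rank
connected above disconnected units.  The simulator does not emulate:
bursting or pacemaker cell types, conduction-velocity jitter, spike-sorting
errors and unit contamination, non-stationary behavioral states, common
drive from unrecorded populations (beyond the uniform external input), or
gap junctions.  Real recordings contain all of these; on biological data
the procedures should be read as producing *candidate* effective
connections, with low complete-set MCC indicating that much of the
target's behavior is driven by unrecorded elements.

## Known limitations

* The learner is a re-implementation of the C4.5/C5.0 family, not the
  C5.0 binary; cost handling during pruning and the boosting variant
  differ in undocumented details, so metric comparisons against published
  C5.0 outputs carry tolerance bands rather than exact equality.
* STDP can silence a structurally present synapse; such connections are
  invisible to effective-connectivity analysis by construction, and
  recovery criteria are therefore stated against units with live synapses
  onto an active target.
* The combinatory search is exponential; beyond ~16 units the iterative
  and recursive procedures are the intended tools.
* Negative-interval tiling discards sub-window gap remainders; interval
  counts are systematically ~1–2% below duration/window for targets near
  1 Hz.
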