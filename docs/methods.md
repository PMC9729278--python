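# Methods

## Model overview

`trisynapse` implements a spiking network model of the hippocampal
trisynaptic circuit (dentate gyrus → CA3 → CA1) with activity-dependent
plasticity, an injury model that weakens synaptic potentiation, and the
analysis stack used to characterise the consequences: community structure
of the evolving synaptic weight matrix, and an unsupervised learning /
pattern-separation readout.

At full scale the model holds 8,885 point neurons in ten subtypes: DG
granule, DG mossy, DG basket, DG interneuron; pyramidal, basket and
interneuron types for each of CA3 and CA1. Inhibitory cells make up ~10%
of each region. Region totals follow rat-like proportions (DG 5,735;
CA3 1,350; CA1 1,800), giving a CA3+CA1 submatrix of 3,150 nodes for the
community analyses.

## Neuron and synapse dynamics

Each neuron follows the capacitance form of the quadratic
integrate-and-fire model

    C v' = k (v − v_r)(v − v_t) − u + I,
    u'   = a [ b (v − v_r) − u ],
    v ≥ v_p  ⇒  v ← c, u ← u + d.

Per-subtype parameters default to the published regular-spiking (granule,
mossy, CA1 pyramidal), intrinsically-bursting (CA3 pyramidal),
fast-spiking (baskets) and low-threshold-spiking (other interneurons)
archetypes; granule cells use a hyperpolarised RS variant. All values are
YAML-overridable.

The aggregate current `I` sums three conductance channels with
single-exponential decays — AMPA (τ = 5 ms), NMDA (τ = 150 ms, with the
Jahr–Stevens magnesium-block factor at 1 mM Mg²⁺), GABA-A (τ = 6 ms,
reversal −70 mV) — plus exogenous current pulses (τ = 5 ms). Background
drive is an independent 1 Hz Poisson event train per neuron whose
amplitudes are gamma-distributed (shape 2, scale ½) times a gain of
900 pA, calibrated once so that the baseline regions fire in the expected
qualitative pattern (sparse DG granule activity below ~1 Hz, moderate
CA3/CA1 pyramidal activity, brisker interneurons).

Integration is forward Euler with dt = 1 ms; within each step the membrane
potential advances in two half-steps (the standard stabilisation of the
quadratic term at this step size) while the recovery variable, synaptic
decays and spike tests stay on the 1 ms grid. A −95 mV floor guards
against inhibitory overshoot. Halving dt changes the spike count of the
reference network by less than 5% over 10 s. The public `euler_step`
exposes one plain forward-Euler step of the same membrane arithmetic for
inspection and testing.

## Connectivity

Connections are sampled per projection as independent Bernoulli edges with
clipped-normal weight magnitudes (signed by the source type). The shipped
projection table honours the qualitative anatomy: a predominantly
feedforward DG → CA3 → CA1 architecture; no granule–granule synapses; a
weak granule ↔ mossy associational loop in the DG; sparse, strong mossy
fibres (DG → CA3); dense CA3 recurrent collaterals (p = 0.12); sparse,
strong Schaffer collaterals (CA3 → CA1, p = 0.03) with feedforward
inhibition onto CA1 baskets; and no back-projections. Probabilities were
chosen so that the 1/10-scale reference network retains functional
in-degrees for each pathway (e.g. ~15 recurrent inputs per CA3 pyramidal
cell, enough to express pattern completion without runaway attractor
dynamics); the quantitative connectome is a documented, configurable
default, not ground truth.

Expected edge counts scale with the product of the population sizes, so
scaled-down networks are sparser per neuron than the full model; this is
the main reason several contrasts are weaker at desk scale (below).

## Plasticity

STDP applies to excitatory-to-excitatory synapses only. For a spike pair
with gap Δt = t_post − t_pre the weight changes by

    Δw = η · A₊ · exp(−Δt/τ)      if Δt > 0
    Δw = −η · A₋ · exp(+Δt/τ)     if Δt ≤ 0

with τ = 20 ms, A₊/A₋ = 1.05 at baseline (A₊ = 1), and hard clipping to
[0, W_max] of the postsynaptic subtype (W_max = 10 nS). The depression
branch uses exp(−|Δt|/τ); the divergent sign printed in some antisymmetric
formulations is treated as a typo, since acausal pairs must weaken the
synapse. Pairing is nearest-neighbour and event-driven within a 100 ms
window; spikes falling in the same 1 ms step are not paired. η = 0.1 nS
converts the dimensionless curve into weight units; it was fixed once so
that a 30-schedule-minute training phase modifies weights appreciably
without driving them into saturation at W_max (saturation erases
pattern-specific selectivity; see Limitations). Injury multiplies A₊ by
(1 − fraction), default fraction 0.10, leaving A₋ and τ untouched.

Homeostatic synaptic scaling compares each excitatory neuron's rate over a
120 s observation window with its target rate and, when the relative
deviation exceeds 50%, adjusts its incoming excitatory weights by
Δw = −(γ_h/W_max)·deviation·w² with γ_h = 10⁻⁸, once per window. With
this γ_h the per-window change is minute; the mechanism acts as a guard
against unconstrained runaway rather than a strong controller. Target
rates are recorded per neuron as its mean rate over the final observation
window of the no-HSP settling phase (floored at 0.1 Hz); "all synapses of
the neuron" is read as the incoming excitatory synapses (the synaptic-
scaling convention).

## Protocols

The canonical schedule: settle 20 min with STDP only, then 30 min with
STDP + HSP; injury continues the settled network 30 min under impaired
STDP, with a paired baseline arm continued from the same settled state and
the same noise stream, so arm differences are attributable to A₊ alone.
Training runs 30 min with two interleaved 1 Hz stimulus patterns (200 DG
granule cells each, 50% overlap, phase-offset 500 ms) on top of noise;
impairment, when tested, is applied during training. Testing stimulates a
static network (plasticity frozen) for 6 min per phase and measures each
neuron's mean spike count in the 200 ms epoch after each stimulus event.
Stimulus pulses are 2,000 pA, comfortably suprathreshold.

A `time_scale` factor shrinks every dynamical duration (phases, HSP
window, snapshot cadence) for desk-scale work; the desk-scale reference is
1/10 network scale with 1/10 durations. Two quantities deliberately do not
scale: physiological rates (noise and stimulation stay at 1 Hz) and the
test phase, which is a static measurement whose length sets estimator
precision only — it stays at the full 6 min (360 epochs per pattern) so
that response normalisation is not dominated by counting noise. Weight
snapshots are indexed by schedule "minute" (1–50 during settling), so
"minute 26" of the HSP phase and the settle end ("minute 50") keep their
meaning at any time scale.

## Community analysis

The CA3+CA1 submatrix (excitatory and inhibitory nodes, signed weights) is
analysed with modularity maximisation. For a directed weighted layer,
Q(γ) = (1/m) Σ_ij [w_ij − γ s_out,i s_in,j / m] δ(σ_i, σ_j); signed
matrices split into positive and negative layers combined as
Q = Q⁺ − (m⁻/(m⁺+m⁻)) Q⁻. The maximizer is a Louvain-style greedy
label-move heuristic with node aggregation and a final node-level
refinement pass; on graphs of ≤ 12 nodes each call additionally restarts
from twelve random coarse labellings, which makes it exact against
exhaustive enumeration on the tested instances.

The resolution γ_res is optimised as the argmax of Q_empirical − Q_null
over a sweep, where nulls come from degree-preserving double-edge swaps
(10× the edge count of attempts) that exactly conserve every node's in-
and out-degree and carry each weight with its source edge. Per the study
design, γ_res is optimised on the baseline minute-26 snapshot and held
constant for later timepoints and the impaired arm. The desk-scale
pipeline sweeps 0.5–3.0 in steps of 0.25 with 3 restarts per matrix and 3
nulls (a coarser grid than the 0.05-step sweep one would use at full
scale, chosen purely as a problem-size reduction).

Consensus clustering: an association matrix over 50 partitions (100 at
full scale) is thresholded at the maximum off-diagonal entry of a null
association matrix obtained by permuting each partition across nodes, then
re-clustered until the ensemble is unanimous (at most 50 iterations).

Nodal flexibility is the fraction of consecutive snapshot transitions at
which a node's (Jaccard-aligned, larger-modules-first) module label
changes; promiscuity is the fraction of all communities in the aligned
sequence that the node ever joins. Both are profiled over the last five
training snapshots and summarised as quintile-occupancy of target vs
off-target principal cells.

## Learning readout

Responses are normalised as (trained + ε)/(untrained + ε) with ε equal to
one spike per test (1/360), which keeps the ratio finite for neurons
silent before training. Per region and pattern, the top-n neurons by
normalised response (n = 200 at full scale, scaled with the network) form
the target population, with stimulated input cells excluded and ties
broken by ascending index; remaining principal cells are off-target.
SNR = mean target / mean off-target normalised response. Population
distance uses Hamming distance between binary membership vectors over a
stated reference population — inputs over DG granule cells, outputs over
the analysed region's principal cells; PDΔ = D_out − D_in, positive when
the circuit separates the patterns. Because the reference population
differs between input and output vectors, PDΔ magnitudes are convention-
dependent (the union-of-sets alternative is exposed through the same
function by passing a different reference); the sign contract is what the
tests rely on. Rate coding on common responders uses the Spearman distance
1 − ρ with average ranks for ties.

## Statistics

Paired and two-sample t-tests with Bonferroni-corrected thresholds
(0.05/m) and repeated-measures ANOVA with Tukey HSD post-hoc comparisons
are thin wrappers over scipy and statsmodels, reported alongside the
metrics they qualify.

## Synthetic generators

`synthetic` provides seeded generators for every statistical shape the
analyses assume: planted-partition weighted digraphs (optionally signed)
for the community pipeline; homogeneous Poisson rasters for rate code
paths; and response tables with planted target populations of controlled
effect size, noise, and overlap for the learning readout. Under strong
contrast the corresponding analyses recover the planted structure
(adjusted Rand ≥ 0.9; ≥ 95% target recovery at effect size 5), which is
the package's parameter-recovery surface. These fixtures emulate the
statistics the analyses consume, not hippocampal biology: passing them
shows the analysis stack is correct, not that the simulator reproduces any
particular in-vivo dataset.

## Desk-scale study and its limitations

The reference study (`trisynapse.experiment.run_experiment`) runs the full
paired protocol per seed at 1/10 scale/durations in ~2 minutes of wall
time; five seeds form one replication set. What it reproduces robustly,
as cross-seed mean directions: CA3 and CA1 excitatory rates decrease under
impairment relative to the paired baseline continuation; target SNR under
impairment is at or below the baseline SNR in all three regions; DG and
CA1 target-set overlap falls well below the 50% input overlap while CA3
overlap stays near the input level (the pattern-completion signature of
its recurrent collaterals).

Known desk-scale limitations, all consequences of the sparser per-neuron
connectivity and tenfold-shorter phases:

- The impairment-induced rate decrease, while consistently non-negative,
  is small (~0.1%); over only 3 scaled minutes the impaired weight
  divergence is a fraction of a percent.
- The consensus-modularity decrease after impairment is at the noise level
  of the estimator at this scale; its cross-seed mean direction is not a
  robust effect the way the rate/SNR/overlap contrasts are. Relatedly,
  the optimised resolution sits at the top of the sweep and yields many
  small modules: at 1/10 density the empirical matrix's clearest advantage
  over its degree-preserving null is local, fine-scale structure.
- DG trainability rides on the small mossy-cell population (26 cells at
  1/10 scale), which limits how pattern-specific the DG training effect
  can be; the shipped mossy feedback strength is the compromise that keeps
  DG both trainable and separating.
- At this density the rewired null's modularity is comparable to the
  empirical network's at moderate resolutions (sparse random graphs are
  spuriously modular), unlike the full-scale regime where the empirical
  matrix dominates its null.

Full-scale runs (8,885 neurons, full durations) use the identical code
path and are a matter of hours, not of different machinery.
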