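# trisynapse

A spiking network model of the hippocampal trisynaptic circuit
(dentate gyrus → CA3 → CA1) for studying how impaired synaptic
potentiation — a candidate mechanism of mild traumatic brain injury —
reshapes circuit structure and function. The package bundles:

- a scalable builder for the 8,885-neuron, ten-subtype hippocampal
  network (signed, weighted, directed connectivity);
- an Izhikevich-dynamics simulator (conductance-based AMPA/NMDA/GABA-A
  synapses, gamma-distributed 1 Hz noise drive) with online
  spike-timing-dependent plasticity (STDP) and threshold homeostatic
  synaptic scaling;
- the injury model: a 10% reduction of the STDP potentiation peak
  (A₊ 1.0 → 0.9, with baseline A₊/A₋ = 1.05, τ = 20 ms);
- consensus community detection for signed weighted directed matrices
  (modularity maximisation, resolution optimisation against
  degree-preserving rewired nulls, association-matrix consensus,
  nodal flexibility/promiscuity);
- an unsupervised learning readout: overlapping 200-cell input patterns,
  normalised stimulus responses, target/off-target selection, SNR, and
  pattern-separation metrics (percent overlap, Hamming population
  distance, Spearman rate distance).

The scientific core, in brief. Synapses between excitatory neurons
change by Δw = A₊e^(−Δt/τ) for causal spike pairs (Δt = t_post − t_pre > 0)
and Δw = −A₋e^(−|Δt|/τ) otherwise; a slow homeostat nudges a neuron's
excitatory inputs by −(γ/W_max)·((v_o − v_t)/v_t)·w² when its rate drifts
more than 50% from target over 120 s. Community structure of the CA3–CA1
weight matrix is scored by Q(γ) = (1/2m) Σ_ij [a_ij − γp_ij] δ(σ_i,σ_j)
generalised to signed directed graphs, and pattern separation by
PDΔ = D_out − D_in (Hamming) and SD = 1 − ρ_Spearman on common responders.

## Worked example

A complete paired baseline/impaired study at the desk-scale reference
(1/10 network scale, 1/10 phase durations; ~2 minutes on one core):

```python
from trisynapse.experiment import ExperimentConfig, run_experiment

r = run_experiment(seed=1, cfg=ExperimentConfig())
print(f"gamma* = {r['gamma_star']:.2f}")
print(f"consensus Q: baseline {r['q_baseline']:.4f} "
      f"impaired {r['q_impaired']:.4f}")
print("CA3 rate (Hz): {:.3f} -> {:.3f}".format(
    r["rates_baseline"]["CA3"], r["rates_impaired"]["CA3"]))
print(r["separation_baseline"][["region", "overlap_pct", "snr"]])
```

prints (seed 1):

```
gamma* = 3.00
consensus Q: baseline 0.2522 impaired 0.2495
CA3 rate (Hz): 0.306 -> 0.305
  region  overlap_pct       snr
0    CA1         30.0  1.907416
1    CA3         55.0  2.881906
2     DG         50.0  7.126814
```

Read: with the resolution optimised on the pre-injury network, impairment
lowers consensus modularity slightly and CA3/CA1 firing marginally; after
training, the CA3 target populations for the two patterns overlap at
roughly the 50% input overlap (pattern completion by its recurrent
collaterals), while CA1 overlap falls below it and the target
signal-to-noise ratio is several-fold (single-seed values are noisy —
cross-seed means are the quantities to interpret).

The same pipeline is scriptable from the shell:

```bash
trisynapse build --scale 0.1 --seed 1 --out net/
trisynapse experiment --seed 1 --out metrics.json
trisynapse analyze-modularity --weights net/weights.mtx --gamma 2.0 --runs 50
```

## Layout

| module | contents |
| --- | --- |
| `trisynapse.config` | subtype parameters, population counts, projection table (YAML-overridable) |
| `trisynapse.network` | network construction, topology validation, Matrix Market / CSV I/O |
| `trisynapse.simulate` | Izhikevich integration (numba kernel), noise, rasters, rates, band power |
| `trisynapse.plasticity` | STDP rule, impairment, homeostatic scaling |
| `trisynapse.protocols` | settle / injure / train / test schedules, stimulus patterns |
| `trisynapse.modularity` | signed directed modularity, Louvain-style maximizer, rewired nulls, consensus, flexibility/promiscuity |
| `trisynapse.separation` | normalised responses, target selection, overlap / PDΔ / Spearman distance / SNR |
| `trisynapse.synthetic` | seeded planted-partition graphs, Poisson rasters, planted response tables |
| `trisynapse.stats` | t-tests with Bonferroni thresholds, repeated-measures ANOVA + Tukey |
| `trisynapse.experiment` | the end-to-end paired study |

See `docs/methods.md` for model assumptions, parameter defaults and their
rationale, numerical choices, and known desk-scale limitations.
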