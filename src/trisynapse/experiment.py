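"""End-to-end scaled experiment: settle, injure, train, test, analyse.

This module reproduces the full study design at a configurable network and
time scale. The reference desk-scale configuration is 1/10 network scale
with phase durations shortened tenfold, which preserves every phase of the
protocol while keeping a complete run to tens of seconds.

Per seed the pipeline

1. builds the network and settles it (STDP-only phase, then STDP + HSP),
2. continues paired baseline / impaired arms from the settled state with a
   shared noise stream,
3. optimises the modularity resolution on the baseline settle-phase
   "minute 26" snapshot of the CA3+CA1 submatrix and, holding it constant,
   computes consensus partitions of the baseline (pre-injury) and impaired
   (post-continuation) matrices,
4. trains the settled network under both conditions with two overlapping
   input patterns and tests untrained/trained responses, and
5. derives the learning readout: normalized responses, target selection,
   SNR, overlap, population-distance change, and Spearman rate distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import NetworkConfig
from .modularity import (ModularityParams, best_partition,
                         consensus_communities, flexibility, module_report,
                         optimize_gamma, promiscuity, quintile_profile)
from .network import build_network, extract_subnetwork
from .plasticity import HSPConfig, STDPConfig
from .protocols import (ProtocolSchedule, build_pattern_pair,
                        principal_populations, run_impairment, settle, test,
                        train)
from .separation import normalize_responses, select_targets, separation_report
from .simulate import SimulationConfig, firing_rates


@dataclass
class ExperimentConfig:
    """Scaled-study configuration (defaults: 1/10 scale, 1/10 durations)."""

    scale: float = 0.1
    time_scale: float = 0.1
    impair_fraction: float = 0.10
    pattern_size_full: int = 200       # scaled by `scale` at run time
    pattern_overlap: float = 0.5
    gamma_sweep: tuple = tuple(np.round(np.arange(0.5, 3.01, 0.25), 2))
    consensus_runs: int = 50
    sweep_runs: int = 3
    n_null: int = 3
    network_config: NetworkConfig | None = None
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    stdp: STDPConfig = field(default_factory=STDPConfig)

    @property
    def pattern_size(self) -> int:
        return max(2, int(round(self.pattern_size_full * self.scale)))

    def schedule(self) -> ProtocolSchedule:
        return ProtocolSchedule(time_scale=self.time_scale)


def _region_rates(net, raster, window) -> dict[str, float]:
    rates = firing_rates(raster, window)
    exc = net.excitatory
    return {r: float(rates[(net.region == r) & exc].mean())
            for r in ("DG", "CA3", "CA1")}


def _submatrix(W, indices):
    return W[np.ix_(indices, indices)].tocsr()


def run_experiment(seed: int, cfg: ExperimentConfig | None = None) -> dict:
    """One complete paired baseline/impaired study; returns a metrics dict.

    Keys include per-region excitatory rates in the final analysis window
    of each continuation arm, consensus modularity of the pre-injury and
    impaired CA3+CA1 matrices at the optimised resolution, and separation
    metrics (overlap %, PDdelta, Spearman distance, SNR) per region for
    both training conditions.
    """
    cfg = cfg or ExperimentConfig()
    sched = cfg.schedule()
    sim = cfg.sim
    net = build_network(cfg.network_config, scale=cfg.scale, seed=seed)

    # -- settle + paired continuations ------------------------------------
    settled = settle(net, sim, sched, seed=seed + 1, stdp=cfg.stdp)
    base = run_impairment(settled, sim, sched, seed=seed + 2, fraction=0.0,
                          stdp=cfg.stdp)
    imp = run_impairment(settled, sim, sched, seed=seed + 2,
                         fraction=cfg.impair_fraction, stdp=cfg.stdp)

    anal_ms = sched.ms(sched.analysis_min)
    out: dict = {"seed": seed, "n_neurons": net.n_neurons}
    for name, arm in (("baseline", base), ("impaired", imp)):
        t1 = arm.raster.t_stop
        out[f"rates_{name}"] = _region_rates(net, arm.raster, (t1 - anal_ms, t1))

    # -- modularity on the CA3+CA1 structural matrix ----------------------
    sub_idx = np.flatnonzero(np.isin(net.region, ("CA3", "CA1")))
    _, meta = extract_subnetwork(net, {"CA3", "CA1"})
    # settle-phase snapshots are numbered 1..50; "minute 26" of the
    # HSP phase is cumulative snapshot 46, the settle end is 50
    n_pre = int(sched.settle_pre_min)
    W_opt = _submatrix(settled.snapshots[n_pre + 26], sub_idx)
    W_base = _submatrix(settled.net.weights, sub_idx)
    W_imp = _submatrix(imp.net.weights, sub_idx)

    params = ModularityParams(n_runs=cfg.consensus_runs, n_null=cfg.n_null,
                              sweep_runs=cfg.sweep_runs, seed=seed + 3)
    gamma_star, sweep_df = optimize_gamma(W_opt, cfg.gamma_sweep, params)
    part_base = consensus_communities(W_base, gamma_star, params)
    part_imp = consensus_communities(W_imp, gamma_star, params)
    comp_base, summ_base = module_report(part_base, meta)
    comp_imp, summ_imp = module_report(part_imp, meta)
    out.update({
        "gamma_star": gamma_star,
        "gamma_sweep": sweep_df,
        "q_baseline": part_base.q,
        "q_impaired": part_imp.q,
        "n_modules_baseline": part_base.n_modules,
        "n_modules_impaired": part_imp.n_modules,
        "size_range_baseline": summ_base["size_range"],
        "size_range_impaired": summ_imp["size_range"],
        "composition_baseline": comp_base,
        "composition_impaired": comp_imp,
        "partition_baseline": part_base,
        "partition_impaired": part_imp,
        "ca3ca1_meta": meta,
    })

    # -- learning and pattern separation ----------------------------------
    pops = principal_populations(net)
    n_pat = cfg.pattern_size
    p1, p2 = build_pattern_pair(pops["DG"], n=n_pat,
                                overlap_fraction=cfg.pattern_overlap,
                                seed=seed + 4,
                                offset_ms=sched.pattern_offset_ms)
    stim_members = np.union1d(p1.members, p2.members)
    resp_untrained = test(settled.net, settled.state, (p1, p2), sim, sched,
                          seed=seed + 5)
    eps = 1.0 / max(1, sched.n_test_epochs)

    for condition in ("baseline", "impaired"):
        trained = train(settled.net, settled.state, (p1, p2), sim, sched,
                        seed=seed + 6, condition=condition,
                        impair_fraction=cfg.impair_fraction,
                        r_target=settled.r_target, stdp=cfg.stdp,
                        snapshot_every=sched.minute_ms)
        resp_tr = test(trained.net, trained.state, (p1, p2), sim, sched,
                       seed=seed + 7)
        norm = normalize_responses(resp_tr, resp_untrained, eps)
        assign = select_targets(norm, n_pat, pops, excluded=stim_members)
        rep = separation_report(
            assign, norm, {"P1": p1.members, "P2": p2.members},
            pops["DG"], pops)
        out[f"separation_{condition}"] = rep.per_region
        out[f"assignment_{condition}"] = assign
        out[f"normalized_{condition}"] = norm
        out[f"dynamics_{condition}"] = _nodal_dynamics(
            trained.snapshots, sub_idx, meta, assign, gamma_star, seed)
    out["patterns"] = (p1, p2)
    out["input_overlap_pct"] = 100.0 * np.intersect1d(
        p1.members, p2.members).size / n_pat
    return out


def _nodal_dynamics(snapshots, sub_idx, meta, assign, gamma_star, seed,
                    n_timepoints: int = 5) -> dict:
    """Flexibility/promiscuity of CA3+CA1 principal cells over the final
    training snapshots, profiled by target vs off-target membership."""
    keys = sorted(snapshots)[-n_timepoints:]
    parts = [best_partition(_submatrix(snapshots[k], sub_idx), gamma_star,
                            n_restarts=3, seed=seed + 11).labels
             for k in keys]
    flex = flexibility(parts)
    prom = promiscuity(parts)

    # map global target indices into the CA3+CA1 submatrix index space
    orig = meta["original_index"].to_numpy()
    lut = {g: i for i, g in enumerate(orig)}
    target_set = set()
    for (region, _pattern), tgt in assign.targets.items():
        if region in ("CA3", "CA1"):
            target_set.update(lut[g] for g in tgt)
    principal = meta.index[
        meta["excitatory"]
        & meta["subtype"].isin(["ca3_pyramidal", "ca1_pyramidal"])].to_numpy()
    groups = np.where(np.isin(principal, list(target_set)), "target",
                      "off_target")
    flex_prof = quintile_profile(flex[principal], groups)
    prom_prof = quintile_profile(prom[principal], groups)
    return {"flexibility": flex, "promiscuity": prom,
            "flexibility_quintiles": flex_prof,
            "promiscuity_quintiles": prom_prof}


def summarize_experiments(runs: list[dict]) -> pd.DataFrame:
    """Cross-seed means of the headline quantities."""
    rows = []
    for r in runs:
        row = {"seed": r["seed"],
               "q_baseline": r["q_baseline"], "q_impaired": r["q_impaired"],
               "n_modules_baseline": r["n_modules_baseline"],
               "n_modules_impaired": r["n_modules_impaired"],
               "size_range_baseline": r["size_range_baseline"],
               "size_range_impaired": r["size_range_impaired"],
               "gamma_star": r["gamma_star"]}
        for arm in ("baseline", "impaired"):
            for reg, v in r[f"rates_{arm}"].items():
                row[f"rate_{reg}_{arm}"] = v
            sep = r[f"separation_{arm}"].set_index("region")
            for reg in sep.index:
                row[f"overlap_{reg}_{arm}"] = sep.loc[reg, "overlap_pct"]
                row[f"snr_{reg}_{arm}"] = sep.loc[reg, "snr"]
                row[f"pd_delta_{reg}_{arm}"] = sep.loc[reg, "pd_delta"]
                row[f"spearman_{reg}_{arm}"] = sep.loc[reg, "spearman_distance"]
        rows.append(row)
    return pd.DataFrame(rows)
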