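"""Experiment schedules: settling, impairment, pattern training, testing.

The canonical schedule settles a fresh network for 20 min of simulated time
with STDP only (synaptic settling), then 30 min with homeostatic scaling
active. Injury continues the settled network for a further 30 min under
impaired STDP (potentiation peak reduced, e.g. by 10%); the paired baseline
arm continues with the intact rule from the same settled state and the same
noise stream, so differences are attributable to the potentiation peak
alone. Learning experiments train the settled network for 30 min with two
interleaved 1 Hz stimulus patterns (200 DG granule cells each, 50% overlap)
and test before and after training by stimulating a static network for
6 min, measuring each neuron's response in the 200 ms epoch after every
stimulus event.

A ``time_scale`` factor shrinks every phase duration (and the homeostatic
observation window and snapshot cadence with them) for desk-scale runs;
physiological rates (noise, stimulation) and the 200 ms response epoch are
never scaled. Weight snapshots are indexed by schedule "minute" so that
minute 26 and minute 30 keep their meaning at any time scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .network import HippocampalNetwork
from .plasticity import HSPConfig, STDPConfig, apply_impairment
from .simulate import (IzhikevichState, SimulationConfig, SpikeRaster,
                       firing_rates, init_state, run_epoch)


@dataclass(frozen=True)
class StimulusPattern:
    """A set of DG input neurons stimulated together at a fixed rate."""

    members: np.ndarray
    label: str
    rate: float = 1.0       # Hz
    phase_offset: float = 0.0  # ms within the common stimulation cycle

    def event_times(self, t0: float, duration: float) -> np.ndarray:
        period = 1000.0 / self.rate
        first = t0 + self.phase_offset
        n = int(np.floor((duration - self.phase_offset) / period))
        return first + period * np.arange(max(n, 0))


@dataclass(frozen=True)
class ProtocolSchedule:
    """Phase durations (minutes of simulated time) and cadences."""

    time_scale: float = 1.0
    settle_pre_min: float = 20.0   # STDP only, no HSP
    settle_hsp_min: float = 30.0   # STDP + HSP
    impair_min: float = 30.0
    train_min: float = 30.0
    test_min: float = 6.0
    analysis_min: float = 5.0      # final analysis window of a phase
    snapshot_min: float = 1.0
    hsp_window_s: float = 120.0
    response_epoch_ms: float = 200.0
    pattern_offset_ms: float = 500.0  # interleaving offset between patterns
    test_time_scale: float = 1.0   # testing is measurement: kept full-length

    def ms(self, minutes: float) -> float:
        return minutes * 60_000.0 * self.time_scale

    @property
    def test_ms(self) -> float:
        return self.test_min * 60_000.0 * self.test_time_scale

    @property
    def n_test_epochs(self) -> int:
        """Stimulus epochs per pattern during one test (1 Hz stimulation)."""
        return int(self.test_ms / 1000.0)

    @property
    def minute_ms(self) -> float:
        return self.ms(self.snapshot_min)

    @property
    def hsp_window_scaled_s(self) -> float:
        return self.hsp_window_s * self.time_scale


def build_pattern_pair(dg_population: np.ndarray, n: int = 200,
                       overlap_fraction: float = 0.5, seed: int = 0,
                       rate: float = 1.0, offset_ms: float = 500.0
                       ) -> tuple[StimulusPattern, StimulusPattern]:
    """Two stimulus patterns of size n sharing round(n * overlap) members."""
    pool = np.asarray(dg_population)
    n_common = int(round(n * overlap_fraction))
    needed = 2 * n - n_common
    if pool.size < needed:
        raise ValueError(
            f"population of {pool.size} too small for two patterns of {n} "
            f"with {n_common} common members")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(pool, size=needed, replace=False)
    common = chosen[:n_common]
    uniq1 = chosen[n_common:n]
    uniq2 = chosen[n:]
    p1 = StimulusPattern(np.sort(np.concatenate([common, uniq1])), "P1",
                         rate, 0.0)
    p2 = StimulusPattern(np.sort(np.concatenate([common, uniq2])), "P2",
                         rate, offset_ms)
    return p1, p2


def _stim_events(patterns, t0: float, duration: float
                 ) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Expand patterns into per-member event arrays plus per-pattern times."""
    times, neurons, per_pattern = [], [], {}
    for p in patterns:
        et = p.event_times(t0, duration)
        per_pattern[p.label] = et
        times.append(np.repeat(et, p.members.size))
        neurons.append(np.tile(p.members, et.size))
    if times:
        return np.concatenate(times), np.concatenate(neurons), per_pattern
    return np.empty(0), np.empty(0, dtype=np.int64), per_pattern


def _with_weights(net: HippocampalNetwork, W: sp.csr_matrix) -> HippocampalNetwork:
    return HippocampalNetwork(layout=net.layout, weights=W, config=net.config,
                              seed=net.seed)


@dataclass
class PhaseResult:
    net: HippocampalNetwork
    state: IzhikevichState
    raster: SpikeRaster
    snapshots: dict[int, sp.csr_matrix] = field(default_factory=dict)


def run_phase(net: HippocampalNetwork, state: IzhikevichState,
              sim: SimulationConfig, duration: float, seed: int,
              stdp: STDPConfig | None = None, hsp: HSPConfig | None = None,
              r_target: np.ndarray | None = None, patterns=None,
              snapshot_every: float | None = None,
              snapshot_offset: int = 0) -> PhaseResult:
    """One simulation phase; returns a new network object with the updated
    weights (inputs are not mutated)."""
    state = state.copy()
    if patterns:
        st, sn, _ = _stim_events(patterns, state.t, duration)
    else:
        st = sn = None
    res = run_epoch(net, state, sim, duration, seed, stdp=stdp, hsp=hsp,
                    r_target=r_target, stim_times=st, stim_neurons=sn,
                    snapshot_every=snapshot_every)
    snaps = {snapshot_offset + k: v for k, v in res.snapshots.items()}
    return PhaseResult(_with_weights(net, res.weights), res.state, res.raster,
                       snaps)


@dataclass
class SettleResult:
    net: HippocampalNetwork
    state: IzhikevichState
    r_target: np.ndarray
    snapshots: dict[int, sp.csr_matrix]
    raster_pre: SpikeRaster
    raster_hsp: SpikeRaster


def settle(net: HippocampalNetwork, sim: SimulationConfig,
           sched: ProtocolSchedule, seed: int,
           stdp: STDPConfig | None = None,
           hsp: HSPConfig | None = None) -> SettleResult:
    """Two-phase settling; homeostatic targets are each neuron's mean rate
    over the final observation window of the no-HSP phase."""
    stdp = stdp if stdp is not None else STDPConfig()
    hsp = hsp if hsp is not None else HSPConfig(window_s=sched.hsp_window_scaled_s)
    state = init_state(net)
    dur1 = sched.ms(sched.settle_pre_min)
    r1 = run_phase(net, state, sim, dur1, seed, stdp=stdp, hsp=None,
                   snapshot_every=sched.minute_ms)
    win_ms = min(sched.hsp_window_scaled_s * 1000.0, dur1)
    r_target = firing_rates(r1.raster, (dur1 - win_ms, dur1))
    r_target = np.maximum(r_target, 0.1)
    dur2 = sched.ms(sched.settle_hsp_min)
    r2 = run_phase(r1.net, r1.state, sim, dur2, seed + 1, stdp=stdp, hsp=hsp,
                   r_target=r_target, snapshot_every=sched.minute_ms,
                   snapshot_offset=len(r1.snapshots))
    snaps = {**r1.snapshots, **r2.snapshots}
    return SettleResult(r2.net, r2.state, r_target, snaps, r1.raster, r2.raster)


def run_impairment(settled: SettleResult, sim: SimulationConfig,
                   sched: ProtocolSchedule, seed: int,
                   fraction: float = 0.10,
                   stdp: STDPConfig | None = None,
                   hsp: HSPConfig | None = None) -> PhaseResult:
    """Continue the settled network under (possibly impaired) STDP.

    ``fraction=0`` reproduces the baseline continuation on the identical
    generator path, so paired baseline/impaired arms share noise exactly.
    """
    stdp = stdp if stdp is not None else STDPConfig()
    hsp = hsp if hsp is not None else HSPConfig(window_s=sched.hsp_window_scaled_s)
    impaired = apply_impairment(stdp, fraction)
    return run_phase(settled.net, settled.state, sim,
                     sched.ms(sched.impair_min), seed, stdp=impaired, hsp=hsp,
                     r_target=settled.r_target,
                     snapshot_every=sched.minute_ms,
                     snapshot_offset=max(settled.snapshots) if settled.snapshots else 0)


def train(net: HippocampalNetwork, state: IzhikevichState,
          patterns: tuple[StimulusPattern, StimulusPattern],
          sim: SimulationConfig, sched: ProtocolSchedule, seed: int,
          condition: str = "baseline", impair_fraction: float = 0.10,
          stdp: STDPConfig | None = None, hsp: HSPConfig | None = None,
          r_target: np.ndarray | None = None,
          snapshot_every: float | None = None) -> PhaseResult:
    """Training phase: noise plus interleaved 1 Hz stimulation of both
    patterns with plasticity active; impairment (when requested) is applied
    during training itself."""
    if condition not in ("baseline", "impaired"):
        raise ValueError(f"unknown condition {condition!r}")
    stdp = stdp if stdp is not None else STDPConfig()
    if condition == "impaired":
        stdp = apply_impairment(stdp, impair_fraction)
    hsp = hsp if hsp is not None else HSPConfig(window_s=sched.hsp_window_scaled_s)
    return run_phase(net, state, sim, sched.ms(sched.train_min), seed,
                     stdp=stdp, hsp=hsp, r_target=r_target, patterns=patterns,
                     snapshot_every=snapshot_every)


def epoch_responses(raster: SpikeRaster, event_times: np.ndarray,
                    epoch_ms: float, n_neurons: int) -> np.ndarray:
    """Mean spike count per neuron over the post-stimulus epochs."""
    event_times = np.asarray(event_times, dtype=float)
    if event_times.size == 0:
        raise ValueError("no stimulus epochs")
    t = raster.times
    counts = np.zeros(n_neurons)
    for te in event_times:
        lo = np.searchsorted(t, te, side="left")
        hi = np.searchsorted(t, te + epoch_ms, side="left")
        if hi > lo:
            counts += np.bincount(raster.neurons[lo:hi], minlength=n_neurons)
    return counts / event_times.size


def test(net: HippocampalNetwork, state: IzhikevichState,
         patterns: tuple[StimulusPattern, StimulusPattern],
         sim: SimulationConfig, sched: ProtocolSchedule, seed: int
         ) -> pd.DataFrame:
    """Static testing: stimulate both patterns with plasticity frozen and
    measure the response in the post-stimulus epoch.

    Returns a response table (neuron, region, pattern, response) where the
    response is the mean spike count in the ``response_epoch_ms`` window
    after each of that pattern's stimulus events. The network weights are
    untouched (plasticity disabled, state copied).
    """
    state = state.copy()
    duration = sched.test_ms
    st, sn, per_pattern = _stim_events(patterns, state.t, duration)
    res = run_epoch(net, state, sim, duration, seed, stdp=None, hsp=None,
                    stim_times=st, stim_neurons=sn)
    region = net.region
    rows = []
    for label, et in per_pattern.items():
        resp = epoch_responses(res.raster, et, sched.response_epoch_ms,
                               net.n_neurons)
        rows.append(pd.DataFrame({
            "neuron": np.arange(net.n_neurons), "region": region,
            "pattern": label, "response": resp}))
    return pd.concat(rows, ignore_index=True)


def principal_populations(net: HippocampalNetwork) -> dict[str, np.ndarray]:
    """Principal excitatory cells per region: DG granule cells and the CA3
    and CA1 pyramidal cells."""
    return {
        "DG": net.layout.indices("dg_granule"),
        "CA3": net.layout.indices("ca3_pyramidal"),
        "CA1": net.layout.indices("ca1_pyramidal"),
    }
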