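"""Izhikevich network simulation with conductance synapses and noise drive.

Membrane dynamics follow the capacitance form of the quadratic
integrate-and-fire model,

    C v' = k (v - v_r)(v - v_t) - u + I
    u'   = a [ b (v - v_r) - u ]
    if v >= v_p:  v <- c, u <- u + d,

with the aggregate current I summing AMPA, NMDA (with the standard
voltage-dependent magnesium-block factor), and GABA-A conductances plus an
exogenous noise/stimulus current. Background drive is a 1 Hz per-neuron
event train whose amplitudes follow a gamma distribution (shape 2,
scale 1/2) times a configurable gain in pA.

Integration is forward Euler (default dt = 1 ms). The heavy loop lives in a
numba kernel; :func:`euler_step` exposes one plain step of the same
arithmetic for direct inspection and testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import signal as _signal

from ._kernel import run_kernel
from .network import HippocampalNetwork
from .plasticity import HSPConfig, STDPConfig


class IntegrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class NoiseConfig:
    """Background drive: per-neuron Poisson events with gamma amplitudes."""

    rate: float = 1.0        # events per second per neuron
    k_noise: float = 2.0     # gamma shape
    theta_noise: float = 0.5  # gamma scale
    gain: float = 900.0      # pA per unit amplitude

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("noise rate must be >= 0")
        if min(self.k_noise, self.theta_noise, self.gain) <= 0:
            raise ValueError("k_noise, theta_noise, gain must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Integration step and synaptic-channel kinetics."""

    dt: float = 1.0           # ms
    tau_ampa: float = 5.0     # ms
    tau_nmda: float = 150.0   # ms
    tau_gaba: float = 6.0     # ms
    tau_noise: float = 5.0    # ms decay of injected current pulses
    nmda_ratio: float = 0.3   # NMDA conductance increment per unit weight
    e_inh: float = -70.0      # GABA-A reversal, mV
    stim_amp: float = 2000.0  # pA per stimulus pulse
    noise: NoiseConfig = field(default_factory=NoiseConfig)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        for t in (self.tau_ampa, self.tau_nmda, self.tau_gaba, self.tau_noise):
            if t <= 0:
                raise ValueError("synaptic time constants must be > 0")


@dataclass
class IzhikevichState:
    """Per-neuron dynamical state plus synaptic/noise currents."""

    v: np.ndarray
    u: np.ndarray
    g_ampa: np.ndarray
    g_nmda: np.ndarray
    g_gaba: np.ndarray
    i_noise: np.ndarray
    last_spike: np.ndarray
    window_counts: np.ndarray
    window_step: int = 0
    t: float = 0.0  # ms

    def copy(self) -> "IzhikevichState":
        return IzhikevichState(
            self.v.copy(), self.u.copy(), self.g_ampa.copy(),
            self.g_nmda.copy(), self.g_gaba.copy(), self.i_noise.copy(),
            self.last_spike.copy(), self.window_counts.copy(),
            self.window_step, self.t)


def init_state(net: HippocampalNetwork) -> IzhikevichState:
    """Resting state: v at v_r, u at its fixed point (0)."""
    p = net.param_arrays()
    n = net.n_neurons
    return IzhikevichState(
        v=p["v_r"].copy(), u=np.zeros(n), g_ampa=np.zeros(n),
        g_nmda=np.zeros(n), g_gaba=np.zeros(n), i_noise=np.zeros(n),
        last_spike=np.full(n, -np.inf), window_counts=np.zeros(n, dtype=np.int64))


@dataclass
class SpikeRaster:
    """Ordered spike events (neuron index, time in ms) over an epoch."""

    neurons: np.ndarray
    times: np.ndarray
    t_start: float
    t_stop: float
    n_neurons: int

    def __post_init__(self) -> None:
        self.neurons = np.asarray(self.neurons, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) < 0):
            order = np.argsort(self.times, kind="stable")
            self.times = self.times[order]
            self.neurons = self.neurons[order]
        if self.neurons.size and (self.neurons.min() < 0
                                  or self.neurons.max() >= self.n_neurons):
            raise ValueError("raster contains out-of-range neuron indices")

    @property
    def n_spikes(self) -> int:
        return self.neurons.size

    def counts(self) -> np.ndarray:
        return np.bincount(self.neurons, minlength=self.n_neurons)

    def window(self, t0: float, t1: float) -> "SpikeRaster":
        m = (self.times >= t0) & (self.times < t1)
        return SpikeRaster(self.neurons[m], self.times[m], t0, t1, self.n_neurons)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"neuron_id": self.neurons, "time_ms": self.times})

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_neurons: int, t_start: float = 0.0,
                 t_stop: float | None = None) -> "SpikeRaster":
        df = pd.read_csv(path)
        stop = t_stop if t_stop is not None else (
            float(df["time_ms"].max()) + 1.0 if len(df) else t_start)
        return cls(df["neuron_id"].to_numpy(), df["time_ms"].to_numpy(),
                   t_start, stop, n_neurons)

    def save_hdf5(self, path) -> None:
        """Binary container for long runs."""
        import h5py
        with h5py.File(path, "w") as fh:
            fh.create_dataset("neurons", data=self.neurons)
            fh.create_dataset("times", data=self.times)
            fh.attrs["t_start"] = self.t_start
            fh.attrs["t_stop"] = self.t_stop
            fh.attrs["n_neurons"] = self.n_neurons

    @staticmethod
    def concat(rasters: list["SpikeRaster"]) -> "SpikeRaster":
        if not rasters:
            raise ValueError("nothing to concatenate")
        return SpikeRaster(
            np.concatenate([r.neurons for r in rasters]),
            np.concatenate([r.times for r in rasters]),
            rasters[0].t_start, rasters[-1].t_stop, rasters[0].n_neurons)


def euler_step(v: np.ndarray, u: np.ndarray, current: np.ndarray,
               params: dict[str, np.ndarray], dt: float
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One plain forward-Euler step of the membrane equations.

    Returns (v_next, u_next, spiked). Neurons at or above the spike peak are
    reset (v <- c, u <- u + d) and flagged in ``spiked``. Raises
    :class:`IntegrationError` naming the first non-finite neuron.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    bad = ~(np.isfinite(v) & np.isfinite(u))
    if np.any(bad):
        raise IntegrationError(
            f"non-finite state at neuron {int(np.flatnonzero(bad)[0])}")
    p = params
    vn = v + dt * (p["k"] * (v - p["v_r"]) * (v - p["v_t_mem"]) - u + current) / p["C"]
    un = u + dt * p["a"] * (p["b"] * (v - p["v_r"]) - u)
    spiked = vn >= p["v_p"]
    vn = np.where(spiked, p["c"], vn)
    un = np.where(spiked, un + p["d"], un)
    return vn, un, spiked


def make_noise_events(cfg: NoiseConfig, n_neurons: int, duration: float,
                      seed: int, t0: float = 0.0
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-neuron Poisson event trains with gamma-distributed amplitudes.

    Returns (times_ms, neuron_ids, amplitudes_pA) sorted by time; amplitudes
    are i.i.d. gamma(k_noise, theta_noise) times the gain.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    lam = cfg.rate * duration / 1000.0
    counts = rng.poisson(lam, size=n_neurons)
    total = int(counts.sum())
    neurons = np.repeat(np.arange(n_neurons), counts)
    times = t0 + rng.uniform(0.0, duration, size=total)
    amps = rng.gamma(cfg.k_noise, cfg.theta_noise, size=total) * cfg.gain
    order = np.argsort(times, kind="stable")
    return times[order], neurons[order], amps[order]


@dataclass
class EpochResult:
    raster: SpikeRaster
    state: IzhikevichState
    weights: sp.csr_matrix
    snapshots: dict[int, sp.csr_matrix] = field(default_factory=dict)


def _edge_arrays(W: sp.csr_matrix, excitatory: np.ndarray):
    """CSR outgoing arrays plus an incoming (CSC) view indexing the same
    edge data, and the E->E eligibility flag per edge."""
    W = W.tocsr().copy()
    W.sort_indices()
    nnz = W.nnz
    eid = sp.csr_matrix((np.arange(nnz, dtype=np.int64), W.indices.copy(),
                         W.indptr.copy()), shape=W.shape).tocsc()
    eid.sort_indices()
    src_of_edge = np.repeat(np.arange(W.shape[0]),
                            np.diff(W.indptr)).astype(np.int64)
    ee = (excitatory[src_of_edge] & excitatory[W.indices]).astype(np.int8)
    return (W, W.indptr.astype(np.int64), W.indices.astype(np.int64),
            W.data, ee, eid.indptr.astype(np.int64),
            eid.indices.astype(np.int64), eid.data.astype(np.int64))


def run_epoch(net: HippocampalNetwork, state: IzhikevichState,
              sim: SimulationConfig, duration: float, seed: int,
              stdp: STDPConfig | None = None, hsp: HSPConfig | None = None,
              r_target: np.ndarray | None = None,
              stim_times: np.ndarray | None = None,
              stim_neurons: np.ndarray | None = None,
              snapshot_every: float | None = None) -> EpochResult:
    """Simulate ``duration`` ms from ``state``; returns raster, final state,
    and final weights (the network object itself is not mutated).

    Plasticity hooks are optional: with both disabled the returned weight
    matrix equals the input bitwise. ``stim_times``/``stim_neurons`` give an
    explicit stimulus schedule (suprathreshold current pulses); indices must
    be valid. Weight snapshots are taken every ``snapshot_every`` ms when
    requested (keyed 1, 2, ... in snapshot order).
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    n = net.n_neurons
    p = net.param_arrays()
    exc = net.excitatory.astype(np.int8)
    dt = sim.dt
    n_steps_total = int(round(duration / dt))

    if stim_times is None:
        stim_times = np.empty(0)
        stim_neurons = np.empty(0, dtype=np.int64)
    else:
        stim_times = np.asarray(stim_times, dtype=float)
        stim_neurons = np.asarray(stim_neurons, dtype=np.int64)
        if stim_neurons.size and (stim_neurons.min() < 0 or stim_neurons.max() >= n):
            raise ValueError("stimulus schedule references invalid neuron indices")

    nz_t, nz_n, nz_a = make_noise_events(sim.noise, n, duration, seed, t0=state.t)

    # merge noise + stimulus into a single step-indexed event list
    ev_t = np.concatenate([nz_t, stim_times])
    ev_n = np.concatenate([nz_n, stim_neurons])
    ev_a = np.concatenate([nz_a, np.full(stim_times.size, sim.stim_amp)])
    ev_step_all = np.floor((ev_t - state.t) / dt).astype(np.int64)
    ev_step_all = np.clip(ev_step_all, 0, n_steps_total - 1)
    order = np.argsort(ev_step_all, kind="stable")
    ev_step_all, ev_n, ev_a = ev_step_all[order], ev_n[order], ev_a[order]

    stdp_on = stdp is not None and stdp.enabled
    hsp_on = hsp is not None and hsp.enabled
    s_cfg = stdp if stdp is not None else STDPConfig(enabled=False)
    h_cfg = hsp if hsp is not None else HSPConfig()
    hsp_window_steps = max(1, int(round(h_cfg.window_s * 1000.0 / dt)))
    if r_target is None:
        r_target = p["r_target"]
    r_target = np.maximum(np.asarray(r_target, dtype=float), 0.1)

    (W, indptr, targets, wdata, ee, in_indptr, in_sources,
     in_eid) = _edge_arrays(net.weights, net.excitatory)

    dec = lambda tau: float(np.exp(-dt / tau))
    chunk_steps = (n_steps_total if snapshot_every is None
                   else max(1, int(round(snapshot_every / dt))))

    rasters_n, rasters_t = [], []
    snapshots: dict[int, sp.csr_matrix] = {}
    step0 = 0
    snap_key = 0
    while step0 < n_steps_total:
        n_steps = min(chunk_steps, n_steps_total - step0)
        m = (ev_step_all >= step0) & (ev_step_all < step0 + n_steps)
        cap = max(200_000, int(n * n_steps * dt / 1000.0 * 100))
        for attempt in range(2):
            out_step = np.empty(cap, dtype=np.int64)
            out_neuron = np.empty(cap, dtype=np.int64)
            if attempt == 0:
                state_backup = state.copy()
                w_backup = wdata.copy()
            n_spk, win_step = run_kernel(
                n_steps, dt,
                state.v, state.u, state.g_ampa, state.g_nmda, state.g_gaba,
                state.i_noise,
                p["a"], p["b"], p["c"], p["d"], p["k"], p["C"], p["v_r"],
                p["v_t_mem"], p["v_p"], p["W_max"], exc,
                indptr, targets, wdata, ee,
                in_indptr, in_sources, in_eid,
                dec(sim.tau_ampa), dec(sim.tau_nmda), dec(sim.tau_gaba),
                dec(sim.tau_noise), sim.nmda_ratio, sim.e_inh,
                ev_step_all[m] - step0, ev_n[m], ev_a[m],
                stdp_on, s_cfg.eta, s_cfg.A_plus, s_cfg.A_minus, s_cfg.tau,
                s_cfg.pair_window,
                hsp_on, h_cfg.gamma_h, h_cfg.threshold, hsp_window_steps,
                r_target, state.window_counts, state.window_step,
                state.last_spike, state.t,
                out_step, out_neuron)
            if n_spk == -1:  # buffer overflow: restore and retry larger
                state.v[:] = state_backup.v
                state.u[:] = state_backup.u
                state.g_ampa[:] = state_backup.g_ampa
                state.g_nmda[:] = state_backup.g_nmda
                state.g_gaba[:] = state_backup.g_gaba
                state.i_noise[:] = state_backup.i_noise
                state.last_spike[:] = state_backup.last_spike
                state.window_counts[:] = state_backup.window_counts
                wdata[:] = w_backup
                cap *= 10
                continue
            break
        if n_spk <= -2:
            raise IntegrationError(
                f"non-finite membrane potential at neuron {-(n_spk + 2)}")
        if n_spk == -1:
            raise IntegrationError("spike buffer overflow after retry")
        state.window_step = int(win_step)
        rasters_n.append(out_neuron[:n_spk].copy())
        rasters_t.append(state.t + out_step[:n_spk] * dt)
        state.t += n_steps * dt
        step0 += n_steps
        if snapshot_every is not None:
            snap_key += 1
            snapshots[snap_key] = sp.csr_matrix(
                (wdata.copy(), targets.copy(), indptr.copy()), shape=W.shape)

    t0 = state.t - duration
    raster = SpikeRaster(np.concatenate(rasters_n), np.concatenate(rasters_t),
                         t0, state.t, n)
    final_W = sp.csr_matrix((wdata, targets, indptr), shape=W.shape)
    return EpochResult(raster=raster, state=state, weights=final_W,
                       snapshots=snapshots)


def firing_rates(raster: SpikeRaster, window: tuple[float, float] | None = None,
                 subset: np.ndarray | None = None) -> np.ndarray:
    """Per-neuron firing rates (Hz) = spike count / window length."""
    if window is None:
        t0, t1 = raster.t_start, raster.t_stop
    else:
        t0, t1 = window
        if not (raster.t_start <= t0 < t1 <= raster.t_stop):
            raise ValueError("window must lie within the raster epoch")
    if t1 <= t0:
        raise ValueError("empty window")
    m = (raster.times >= t0) & (raster.times < t1)
    counts = np.bincount(raster.neurons[m], minlength=raster.n_neurons)
    rates = counts / ((t1 - t0) / 1000.0)
    return rates if subset is None else rates[np.asarray(subset)]


def population_rate_signal(raster: SpikeRaster, bin_ms: float = 1.0,
                           subset: np.ndarray | None = None
                           ) -> tuple[np.ndarray, float]:
    """Binned population spike-count series and its sampling rate (Hz)."""
    if subset is not None:
        m = np.isin(raster.neurons, np.asarray(subset))
        times = raster.times[m]
    else:
        times = raster.times
    n_bins = max(1, int(np.ceil((raster.t_stop - raster.t_start) / bin_ms)))
    edges = raster.t_start + np.arange(n_bins + 1) * bin_ms
    counts, _ = np.histogram(times, bins=edges)
    return counts.astype(float), 1000.0 / bin_ms


def band_power(sig: np.ndarray, fs: float, band: tuple[float, float] = (4.0, 8.0)
               ) -> float:
    """Power of ``sig`` within a frequency band via a windowed-average
    (Welch) periodogram; the theta band default is 4-8 Hz."""
    lo, hi = band
    if not 0 <= lo < hi:
        raise ValueError("band must satisfy 0 <= lo < hi")
    if hi > fs / 2:
        raise ValueError(f"band upper edge {hi} Hz exceeds Nyquist {fs / 2} Hz")
    sig = np.asarray(sig, dtype=float)
    if lo > 0 and sig.size < 2 * fs / lo:
        raise ValueError("window too short for the band's lowest frequency")
    nper = min(sig.size, 4096)
    f, pxx = _signal.welch(sig - sig.mean(), fs=fs, nperseg=nper)
    m = (f >= lo) & (f <= hi)
    if m.sum() < 2:
        return float(pxx[m].sum() * (f[1] - f[0]))
    return float(np.trapezoid(pxx[m], f[m]))


def theta_band_power(raster: SpikeRaster, subset: np.ndarray | None = None,
                     band: tuple[float, float] = (4.0, 8.0)) -> float:
    sig, fs = population_rate_signal(raster, 1.0, subset)
    return band_power(sig, fs, band)
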