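"""Spike-timing-dependent plasticity (STDP) and homeostatic synaptic scaling.

STDP acts on excitatory-to-excitatory synapses only. A causal pair
(presynaptic spike before postsynaptic, dt = t_post - t_pre > 0) potentiates
the synapse by ``A_plus * exp(-dt / tau)``; an acausal pair (dt <= 0)
depresses it by ``A_minus * exp(-|dt| / tau)``. The potentiation/depression
peak ratio is biased toward strengthening (1.05 at baseline), and impairment
scales the potentiation peak down (e.g. A_plus 1.0 -> 0.9 for a 10%
impairment) while leaving depression untouched.

Homeostatic scaling (HSP) compares each neuron's observed rate over a slow
observation window (120 s) with its target rate and, when the relative
deviation exceeds a 50% threshold, nudges its incoming excitatory weights:

    dw = -(gamma_h / W_max) * ((v_o - v_t) / v_t) * w**2

so weights shrink when firing exceeds target and grow when it falls short.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp

#: baseline potentiation/depression peak ratio
BASELINE_RATIO = 1.05


@dataclass(frozen=True)
class STDPConfig:
    """STDP parameters; defaults are the baseline (uninjured) rule."""

    A_plus: float = 1.0
    A_minus: float = 1.0 / BASELINE_RATIO
    tau: float = 20.0           # ms
    pair_window: float = 100.0  # ms; pairs farther apart are ignored
    eta: float = 0.1            # weight units (nS) per unit of the STDP curve
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.A_plus < 0 or self.A_minus < 0:
            raise ValueError("A_plus and A_minus must be >= 0")
        if self.pair_window <= 0:
            raise ValueError("pair_window must be > 0")


@dataclass(frozen=True)
class HSPConfig:
    """Threshold homeostatic-scaling parameters."""

    gamma_h: float = 1e-8      # dimensionless rate of change
    threshold: float = 0.50    # relative rate-deviation threshold
    window_s: float = 120.0    # observation window, seconds
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.gamma_h <= 0:
            raise ValueError("gamma_h must be > 0")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.window_s <= 0:
            raise ValueError("window_s must be > 0")


def stdp_delta(dt: float | np.ndarray, cfg: STDPConfig) -> float | np.ndarray:
    """Weight change for a spike pair with timing gap ``dt = t_post - t_pre``.

    Positive dt (causal) potentiates with peak ``eta * A_plus``; dt <= 0
    (acausal, including exact ties) depresses with peak ``eta * A_minus``.
    Magnitude decays as exp(-|dt| / tau) on both branches.
    """
    dt = np.asarray(dt, dtype=float)
    pot = cfg.eta * cfg.A_plus * np.exp(-dt / cfg.tau)
    dep = -cfg.eta * cfg.A_minus * np.exp(dt / cfg.tau)
    out = np.where(dt > 0, pot, dep)
    return float(out) if out.ndim == 0 else out


def apply_impairment(cfg: STDPConfig, fraction: float) -> STDPConfig:
    """Scale the potentiation peak by (1 - fraction); depression unchanged."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"impairment fraction must lie in [0, 1), got {fraction}")
    return replace(cfg, A_plus=cfg.A_plus * (1.0 - fraction))


def stdp_apply(spike_neurons: np.ndarray, spike_times: np.ndarray,
               weights: sp.spmatrix, ee_mask: sp.spmatrix,
               cfg: STDPConfig, w_max: np.ndarray | float) -> sp.csr_matrix:
    """Apply event-driven nearest-neighbour STDP over a recorded raster.

    Reference (offline) implementation of the rule the simulation kernel
    applies online: at each postsynaptic spike, eligible incoming synapses
    are potentiated against the most recent presynaptic spike; at each
    presynaptic spike, eligible outgoing synapses are depressed against the
    most recent postsynaptic spike. Pairs wider than ``cfg.pair_window`` are
    ignored; simultaneous (equal-time) spikes are not paired. Weights are
    clipped to [0, W_max(post)]. Only entries flagged in ``ee_mask``
    (excitatory -> excitatory) change.

    Parameters are matrices in source x target orientation; ``w_max`` may be
    a scalar or a per-neuron array indexed by the postsynaptic neuron.
    """
    W = sp.lil_matrix(weights, dtype=float)
    mask = sp.csr_matrix(ee_mask, dtype=bool)
    if mask.shape != W.shape:
        raise ValueError("ee_mask shape does not match weight matrix")
    n = W.shape[0]
    w_max = np.broadcast_to(np.asarray(w_max, dtype=float), (n,))
    mask_csc = mask.tocsc()

    order = np.argsort(spike_times, kind="stable")
    neurons = np.asarray(spike_neurons)[order]
    times = np.asarray(spike_times, dtype=float)[order]
    last = np.full(n, -np.inf)

    incoming = {i: mask_csc.indices[mask_csc.indptr[i]:mask_csc.indptr[i + 1]][
        mask_csc.data[mask_csc.indptr[i]:mask_csc.indptr[i + 1]]]
        for i in range(n)}
    outgoing = {i: mask.indices[mask.indptr[i]:mask.indptr[i + 1]][
        mask.data[mask.indptr[i]:mask.indptr[i + 1]]]
        for i in range(n)}

    for i, t in zip(neurons, times):
        # potentiation of incoming eligible synapses (this spike is "post")
        for p in incoming[i]:
            dt = t - last[p]
            if 0 < dt <= cfg.pair_window:
                w = W[p, i] + stdp_delta(dt, cfg)
                W[p, i] = min(max(w, 0.0), w_max[i])
        # depression of outgoing eligible synapses (this spike is "pre")
        for q in outgoing[i]:
            gap = t - last[q]  # time since last postsynaptic spike
            if 0 < gap <= cfg.pair_window:
                w = W[i, q] + stdp_delta(-gap, cfg)
                W[i, q] = min(max(w, 0.0), w_max[q])
        last[i] = t
    return W.tocsr()


def hsp_update(v_o: float | np.ndarray, r_target: float | np.ndarray,
               w: float | np.ndarray, w_max: float | np.ndarray,
               cfg: HSPConfig) -> float | np.ndarray:
    """Homeostatic weight change; exactly zero inside the deviation band.

    ``v_o`` is the observed rate, ``r_target`` the target rate (Hz). The
    update is -(gamma_h / w_max) * deviation * w**2 where
    deviation = (v_o - r_target) / r_target, applied only when
    |deviation| > cfg.threshold.
    """
    r_target = np.asarray(r_target, dtype=float)
    if np.any(r_target <= 0):
        raise ValueError("r_target must be > 0")
    v_o = np.asarray(v_o, dtype=float)
    w = np.asarray(w, dtype=float)
    w_max = np.asarray(w_max, dtype=float)
    dev = (v_o - r_target) / r_target
    dw = -(cfg.gamma_h / w_max) * dev * w ** 2
    out = np.where(np.abs(dev) > cfg.threshold, dw, 0.0)
    return float(out) if out.ndim == 0 else out


def hsp_apply(rates: np.ndarray, weights: sp.spmatrix, excitatory: np.ndarray,
              r_target: np.ndarray, w_max: np.ndarray,
              cfg: HSPConfig) -> sp.csr_matrix:
    """Scale incoming excitatory synapses of neurons past the rate threshold.

    ``rates`` are per-neuron rates observed over one ``cfg.window_s``
    window. Only excitatory -> excitatory synapses of deviating excitatory
    neurons change (synaptic-scaling convention: a neuron adjusts its
    inputs). Returns a new CSR matrix; weights are clipped to
    [0, w_max(post)].
    """
    W = weights.tocsc(copy=True)
    n = W.shape[0]
    excitatory = np.asarray(excitatory, dtype=bool)
    dev = (np.asarray(rates, dtype=float) - r_target) / r_target
    hot = np.flatnonzero((np.abs(dev) > cfg.threshold) & excitatory)
    for j in hot:
        lo, hi = W.indptr[j], W.indptr[j + 1]
        srcs = W.indices[lo:hi]
        vals = W.data[lo:hi]
        plastic = excitatory[srcs] & (vals > 0)
        w = vals[plastic]
        w = w + hsp_update(rates[j], r_target[j], w, w_max[j], cfg)
        vals[plastic] = np.clip(w, 0.0, w_max[j])
        W.data[lo:hi] = vals
    return W.tocsr()
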