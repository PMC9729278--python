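"""Numba integration kernel for the spiking network.

One compiled loop advances membrane state, delivers synaptic and noise
events, records spikes, and applies online STDP and homeostatic scaling.
All state is carried in flat arrays so the kernel is allocation-free; the
Python wrapper in :mod:`trisynapse.simulate` owns array construction.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: Jahr-Stevens magnesium-block constant at 1 mM Mg2+
_MG_FACTOR = 0.28
_V_FLOOR = -95.0  # numerical clamp against inhibitory overshoot, mV


@njit(cache=False)
def run_kernel(n_steps, dt,
               v, u, g_a, g_n, g_g, i_nz,
               a, b, c, d, k, cm, vr, vt, vp, wmax, exc,
               indptr, targets, w, ee,
               in_indptr, in_sources, in_eid,
               dec_a, dec_n, dec_g, dec_nz, nmda_ratio, e_inh,
               ev_step, ev_neuron, ev_amp,
               stdp_on, eta, a_plus, a_minus, tau, pair_window,
               hsp_on, gamma_h, hsp_thresh, hsp_window_steps, r_target,
               win_counts, win_step0,
               last_spike, t_offset,
               out_step, out_neuron):
    """Advance ``n_steps`` steps of size ``dt`` ms. Returns
    (n_spikes_recorded, window_step_counter) or (-1, _) on spike-buffer
    overflow. Mutates state, weights, counts, and last-spike arrays in
    place."""
    n = v.shape[0]
    cap = out_step.shape[0]
    n_spk = 0
    ev_ptr = 0
    n_ev = ev_step.shape[0]
    spk_buf = np.empty(n, dtype=np.int64)
    win_step = win_step0

    for step in range(n_steps):
        t_now = t_offset + step * dt

        # exponential decay of synaptic conductances and noise current
        for i in range(n):
            g_a[i] *= dec_a
            g_n[i] *= dec_n
            g_g[i] *= dec_g
            i_nz[i] *= dec_nz

        # deliver external events scheduled for this step
        while ev_ptr < n_ev and ev_step[ev_ptr] == step:
            i_nz[ev_neuron[ev_ptr]] += ev_amp[ev_ptr]
            ev_ptr += 1

        # forward-Euler membrane update; v advances in two half-steps for
        # stability of the quadratic term at dt = 1 ms (u once per step)
        n_now = 0
        for i in range(n):
            vi = v[i]
            half = 0.5 * dt
            vn = vi
            for _sub in range(2):
                blk = 1.0 / (1.0 + _MG_FACTOR * np.exp(-0.062 * vn))
                i_syn = (-g_a[i] * vn - g_n[i] * blk * vn
                         + g_g[i] * (e_inh - vn) + i_nz[i])
                vn = vn + half * (k[i] * (vn - vr[i]) * (vn - vt[i])
                                  - u[i] + i_syn) / cm[i]
                if vn >= vp[i]:
                    break
            un = u[i] + dt * a[i] * (b[i] * (vi - vr[i]) - u[i])
            if vn < _V_FLOOR:
                vn = _V_FLOOR
            if vn != vn:  # NaN guard
                return -2 - i, win_step
            if vn >= vp[i]:
                v[i] = c[i]
                u[i] = un + d[i]
                spk_buf[n_now] = i
                n_now += 1
            else:
                v[i] = vn
                u[i] = un

        # spike bookkeeping, synaptic delivery, online STDP
        for s_i in range(n_now):
            s = spk_buf[s_i]
            if n_spk >= cap:
                return -1, win_step
            out_step[n_spk] = step
            out_neuron[n_spk] = s
            n_spk += 1
            win_counts[s] += 1

            for e in range(indptr[s], indptr[s + 1]):
                ww = w[e]
                tgt = targets[e]
                if ww > 0.0:
                    g_a[tgt] += ww
                    g_n[tgt] += ww * nmda_ratio
                elif ww < 0.0:
                    g_g[tgt] -= ww

            if stdp_on and exc[s]:
                # potentiation: this spike is postsynaptic
                for idx in range(in_indptr[s], in_indptr[s + 1]):
                    e = in_eid[idx]
                    if ee[e]:
                        p = in_sources[idx]
                        gap = t_now - last_spike[p]
                        if 0.0 < gap <= pair_window:
                            nw = w[e] + eta * a_plus * np.exp(-gap / tau)
                            if nw > wmax[s]:
                                nw = wmax[s]
                            w[e] = nw
                # depression: this spike is presynaptic
                for e in range(indptr[s], indptr[s + 1]):
                    if ee[e]:
                        q = targets[e]
                        gap = t_now - last_spike[q]
                        if 0.0 < gap <= pair_window:
                            nw = w[e] - eta * a_minus * np.exp(-gap / tau)
                            if nw < 0.0:
                                nw = 0.0
                            w[e] = nw

        for s_i in range(n_now):
            last_spike[spk_buf[s_i]] = t_now

        # homeostatic scaling once per observation window
        win_step += 1
        if win_step >= hsp_window_steps:
            if hsp_on:
                window_s = hsp_window_steps * dt / 1000.0
                for j in range(n):
                    if not exc[j]:
                        continue
                    rate = win_counts[j] / window_s
                    dev = (rate - r_target[j]) / r_target[j]
                    if dev > hsp_thresh or dev < -hsp_thresh:
                        for idx in range(in_indptr[j], in_indptr[j + 1]):
                            e = in_eid[idx]
                            if ee[e] and w[e] > 0.0:
                                nw = w[e] - (gamma_h / wmax[j]) * dev * w[e] * w[e]
                                if nw < 0.0:
                                    nw = 0.0
                                elif nw > wmax[j]:
                                    nw = wmax[j]
                                w[e] = nw
            for j in range(n):
                win_counts[j] = 0
            win_step = 0

    return n_spk, win_step
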