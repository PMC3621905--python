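"""Compiled inner loop of the membrane simulator.

All gating units (Markov schemes and independent gates alike) advance through
precomputed backward-Euler propagators tabulated on a voltage grid (0.1 mV by
default) with linear interpolation between grid points; the exact per-step
evaluation used in the kinetics module is the reference path for tests.
Membrane potential advances by exponential Euler (all currents are ohmic in V
once the gating state is frozen for the step), the standard staggered update
for conductance-based point neurons.

Units: ms, mV, nS, pA, pF (pF/nS = ms, pA/nS = mV).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_sim", "propagator_table", "V_MIN", "V_MAX", "DV"]

V_MIN = -150.0
V_MAX = 100.0
DV = 0.1

# channel kinds
KIND_OHMIC = 0
KIND_MARKOV = 1
KIND_CAGATED = 2


def propagator_table(q_of_v, n_states: int, dt: float,
                     v_min: float = V_MIN, v_max: float = V_MAX, dv: float = DV) -> np.ndarray:
    """Backward-Euler propagators inv(I - dt*Q(V)) stacked over the V grid."""
    grid = np.arange(v_min, v_max + 0.5 * dv, dv)
    eye = np.eye(n_states)
    mats = np.empty((len(grid), n_states, n_states))
    for i, v in enumerate(grid):
        mats[i] = eye - dt * q_of_v(float(v))
    return np.linalg.inv(mats)


@njit(cache=True)
def markov_observable(v_trace, props, p, obs_mask):
    """Integrate one Markov scheme along a voltage trace (tabulated
    backward-Euler propagators, linear interpolation in V) and record the
    summed occupancy over ``obs_mask`` at every sample."""
    nv = props.shape[0]
    ns = p.shape[0]
    dv_inv = 1.0 / DV
    out = np.empty(len(v_trace))
    p_new = np.empty(ns)
    for k in range(len(v_trace)):
        vq = (v_trace[k] - V_MIN) * dv_inv
        if vq < 0.0:
            vq = 0.0
        elif vq > nv - 1.000001:
            vq = nv - 1.000001
        i0 = int(vq)
        w = vq - i0
        ssum = 0.0
        for s in range(ns):
            acc = 0.0
            for t in range(ns):
                pv = (1.0 - w) * props[i0, s, t] + w * props[i0 + 1, s, t]
                acc += pv * p[t]
            p_new[s] = acc
            ssum += acc
        obs = 0.0
        for s in range(ns):
            p[s] = p_new[s] / ssum
            obs += obs_mask[s] * p[s]
        out[k] = obs
    return out


@njit(cache=True)
def run_sim(
    n_steps,
    dt,
    v0,
    cap_pF,
    clamp,            # 0 current clamp, 1 voltage clamp
    v_cmd,            # (n_steps,) command voltage if clamp else unused len-1
    i_inj,            # (n_steps,) injected current, pA
    # gating units
    unit_n,           # (U,) states per unit
    unit_ch,          # (U,) owning channel index
    unit_mult,        # (U,) multiplicity (HH exponent)
    props,            # (U, NV, S, S) padded propagator tables
    cond,             # (U, S) 1.0 for conducting states else 0.0
    p_state,          # (U, S) occupancies, modified in place
    # channels
    ch_kind,          # (C,)
    ch_g,             # (C,) nS
    ch_e,             # (C,) mV
    # calcium pool / KCa (indices -1 when absent)
    kca_idx,
    ca_src_idx,
    kca_alpha,        # 1/(uM*ms)
    kca_beta,         # 1/ms
    ca_state,         # (2,) [Ca uM, KCa open fraction]
    ca_rest,
    ca_tau,
    ca_conv,          # uM per (pA*ms) of inward Ca current
    # noise (point-conductance OU pair)
    use_noise,
    noise_state,      # (2,) ge, gi in pS, modified in place
    ge_mean, gi_mean,
    e_fac, i_fac,     # exp(-dt/tau)
    e_amp, i_amp,     # sd*sqrt(1-exp(-2dt/tau))
    e_rev_e, e_rev_i,
    normals,          # (2, n_steps) standard normals (empty if no noise)
    # recording
    record_every,
    rec_v,            # (n_rec,)
    rec_i_ch,         # (C, n_rec) or (C, 0)
    rec_open,         # (C, n_rec) or (C, 0)
    record_currents,
    record_open,
):
    n_units = unit_n.shape[0]
    n_ch = ch_g.shape[0]
    smax = p_state.shape[1]
    dv_inv = 1.0 / DV
    nv = props.shape[1]

    v = v0
    ge = noise_state[0]
    gi = noise_state[1]
    ca = ca_state[0]
    p_new = np.empty(smax)
    open_frac = np.ones(n_ch)
    i_ret = 0  # index into recording buffers

    for step in range(n_steps):
        # --- gating units advance using the current voltage -----------------
        vq = (v - V_MIN) * dv_inv
        if vq < 0.0:
            vq = 0.0
        elif vq > nv - 1.000001:
            vq = nv - 1.000001
        i0 = int(vq)
        w = vq - i0

        for c in range(n_ch):
            open_frac[c] = 1.0

        for u in range(n_units):
            ns = unit_n[u]
            ssum = 0.0
            for s in range(ns):
                acc = 0.0
                for t in range(ns):
                    pv = (1.0 - w) * props[u, i0, s, t] + w * props[u, i0 + 1, s, t]
                    acc += pv * p_state[u, t]
                p_new[s] = acc
                ssum += acc
            of = 0.0
            for s in range(ns):
                p_state[u, s] = p_new[s] / ssum
                of += cond[u, s] * p_state[u, s]
            c = unit_ch[u]
            m = unit_mult[u]
            for _ in range(m):
                open_frac[c] *= of

        # --- calcium pool and calcium-gated gate ---------------------------
        if kca_idx >= 0:
            ica = ch_g[ca_src_idx] * open_frac[ca_src_idx] * (v - ch_e[ca_src_idx])
            if ica < 0.0:
                ca += -ica * ca_conv * dt
            ca += (ca_rest - ca) * (dt / ca_tau)
            if ca < 0.0:
                ca = 0.0
            alpha = kca_alpha * ca
            rate = alpha + kca_beta
            pinf = alpha / rate
            ca_state[1] = pinf + (ca_state[1] - pinf) * np.exp(-dt * rate)
            open_frac[kca_idx] = ca_state[1]

        # --- synaptic noise (exact OU discretization) -----------------------
        ge_pos = 0.0
        gi_pos = 0.0
        if use_noise:
            ge = ge_mean + (ge - ge_mean) * e_fac + e_amp * normals[0, step]
            gi = gi_mean + (gi - gi_mean) * i_fac + i_amp * normals[1, step]
            if ge > 0.0:
                ge_pos = ge * 1e-3  # pS -> nS
            if gi > 0.0:
                gi_pos = gi * 1e-3

        # --- membrane potential ---------------------------------------------
        if clamp == 1:
            v = v_cmd[step]
        else:
            g_tot = ge_pos + gi_pos
            gE = ge_pos * e_rev_e + gi_pos * e_rev_i + i_inj[step]
            for c in range(n_ch):
                gc = ch_g[c] * open_frac[c]
                g_tot += gc
                gE += gc * ch_e[c]
            if g_tot > 1e-12:
                v_inf = gE / g_tot
                v = v_inf + (v - v_inf) * np.exp(-dt * g_tot / cap_pF)
            else:
                v = v + dt * i_inj[step] / cap_pF
            if v > 200.0 or v < -200.0 or v != v:
                # numeric blow-up: report the offending step via sentinel
                noise_state[0] = ge
                noise_state[1] = gi
                ca_state[0] = ca
                return -(step + 1), v

        # --- recording --------------------------------------------------------
        if (step + 1) % record_every == 0:
            rec_v[i_ret] = v
            if record_currents:
                for c in range(n_ch):
                    rec_i_ch[c, i_ret] = ch_g[c] * open_frac[c] * (v - ch_e[c])
            if record_open:
                for c in range(n_ch):
                    rec_open[c, i_ret] = open_frac[c]
            i_ret += 1

    noise_state[0] = ge
    noise_state[1] = gi
    ca_state[0] = ca
    return i_ret, v
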