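"""Compiled inner loops for full-length trials.

The update scheme is identical to :class:`wtanet.dynamics.ReferenceNetwork`
(deliver -> Heun step of gating + membranes -> threshold/enqueue), but the
recurrent weighted sums exploit the block structure of the weight matrix:
for a pyramidal target in group g the weighted gating sum is

    sum_g' Wb[g, g'] * S[g']  -  Wb[g, g] * s_self

where S[g'] are per-group gating totals, so each step costs O(N) rather
than O(N^2).  External Poisson events are drawn by superposition: one
Poisson count per rate-homogeneous pool per step, with each event assigned
to a uniformly random member — distributionally identical to independent
per-cell trains.

Status codes returned by the kernels: 0 ok, 1 spike-record overflow,
2 non-finite state encountered.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_OVERFLOW = 1
STATUS_NONFINITE = 2


@njit(cache=True)
def mg_block(V, Mg):
    return 1.0 / (1.0 + Mg * np.exp(-0.062 * V) / 3.57)


@njit(cache=True)
def run_network(
    n_steps, dt,
    n_exc, n_inh, group_size,
    w_plus, w_minus,
    # neuron constants: index 0 = pyramidal, 1 = interneuron
    VL, Vth, Vreset, Cm, gL, ref_steps,
    # synapse kinetics
    tau_ampa, tau_nmda_d, tau_nmda_r, alpha, tau_gaba, delay_steps, Mg, VE, VI,
    # conductances: index 0 = pyramidal target, 1 = interneuron target
    g_ext, g_rec, g_nmda, g_gaba,
    # external drive (events per step): background lam per cell, extra lam for
    # each selective group during the stimulus step window
    bg_lam, stim_lam_a, stim_lam_b, stim_start, stim_end,
    seed,
    ext_counts,        # (n_steps, N) precomputed external counts, used when use_ext != 0
    use_ext,
    max_spikes,
):
    np.random.seed(seed)
    N = n_exc + n_inh

    # group id per excitatory neuron: 0 = A, 1 = B, 2 = nonselective
    gid = np.empty(n_exc, dtype=np.int64)
    for i in range(n_exc):
        if i < group_size:
            gid[i] = 0
        elif i < 2 * group_size:
            gid[i] = 1
        else:
            gid[i] = 2
    # block weights Wb[target_group, source_group]
    Wb = np.empty((3, 3))
    Wb[0, 0] = w_plus; Wb[0, 1] = w_minus; Wb[0, 2] = w_minus
    Wb[1, 0] = w_minus; Wb[1, 1] = w_plus; Wb[1, 2] = w_minus
    Wb[2, 0] = 1.0; Wb[2, 1] = 1.0; Wb[2, 2] = 1.0

    # state
    V = np.empty(N)
    for i in range(N):
        V[i] = VL[0] if i < n_exc else VL[1]
    refr = np.zeros(N, dtype=np.int64)
    s_ext = np.zeros(N)
    s_ampa = np.zeros(n_exc)
    x_nmda = np.zeros(n_exc)
    s_nmda = np.zeros(n_exc)
    s_gaba = np.zeros(n_inh)
    ring = np.zeros((delay_steps, N), dtype=np.int64)
    ring_pos = 0

    spike_steps = np.empty(max_spikes, dtype=np.int64)
    spike_ids = np.empty(max_spikes, dtype=np.int64)
    n_spikes = 0

    # scratch for Heun stage 2
    s_ext2 = np.empty(N)
    s_ampa2 = np.empty(n_exc)
    x2 = np.empty(n_exc)
    s_nmda2 = np.empty(n_exc)
    s_gaba2 = np.empty(n_inh)

    for step in range(n_steps):
        # --- deliver delayed recurrent spikes ---
        for j in range(N):
            c = ring[ring_pos, j]
            if c > 0:
                if j < n_exc:
                    s_ampa[j] += c
                    x_nmda[j] += c
                else:
                    s_gaba[j - n_exc] += c
                ring[ring_pos, j] = 0
        # advance now so spikes emitted this step land exactly delay_steps later
        ring_pos = (ring_pos + 1) % delay_steps

        # --- external events ---
        if use_ext != 0:
            for i in range(N):
                s_ext[i] += ext_counts[step, i]
        else:
            in_stim = stim_start <= step < stim_end
            # background pool over all N cells
            nev = np.random.poisson(bg_lam * N)
            for _ in range(nev):
                s_ext[np.random.randint(N)] += 1.0
            if in_stim:
                if stim_lam_a > 0.0:
                    nev = np.random.poisson(stim_lam_a * group_size)
                    for _ in range(nev):
                        s_ext[np.random.randint(group_size)] += 1.0
                if stim_lam_b > 0.0:
                    nev = np.random.poisson(stim_lam_b * group_size)
                    for _ in range(nev):
                        s_ext[group_size + np.random.randint(group_size)] += 1.0

        # --- gating Heun stage 1 (provisional full step) ---
        SA1 = np.zeros(3)
        SN1 = np.zeros(3)
        SA2 = np.zeros(3)
        SN2 = np.zeros(3)
        for j in range(n_exc):
            g = gid[j]
            SA1[g] += s_ampa[j]
            SN1[g] += s_nmda[j]
            k1a = -s_ampa[j] / tau_ampa
            k1x = -x_nmda[j] / tau_nmda_r
            k1n = -s_nmda[j] / tau_nmda_d + alpha * x_nmda[j] * (1.0 - s_nmda[j])
            s_ampa2[j] = s_ampa[j] + dt * k1a
            x2[j] = x_nmda[j] + dt * k1x
            s_nmda2[j] = s_nmda[j] + dt * k1n
            SA2[g] += s_ampa2[j]
            SN2[g] += s_nmda2[j]
        G1 = 0.0
        G2 = 0.0
        for j in range(n_inh):
            G1 += s_gaba[j]
            s_gaba2[j] = s_gaba[j] - dt * s_gaba[j] / tau_gaba
            G2 += s_gaba2[j]
        for i in range(N):
            s_ext2[i] = s_ext[i] - dt * s_ext[i] / tau_ampa

        # --- membrane Heun using stage-1 and stage-2 gating ---
        SA1_tot = SA1[0] + SA1[1] + SA1[2]
        SN1_tot = SN1[0] + SN1[1] + SN1[2]
        SA2_tot = SA2[0] + SA2[1] + SA2[2]
        SN2_tot = SN2[0] + SN2[1] + SN2[2]
        for i in range(N):
            if refr[i] > 0:
                refr[i] -= 1
                continue
            if i < n_exc:
                cls = 0
                g = gid[i]
                wa1 = Wb[g, 0] * SA1[0] + Wb[g, 1] * SA1[1] + Wb[g, 2] * SA1[2] - Wb[g, g] * s_ampa[i]
                wn1 = Wb[g, 0] * SN1[0] + Wb[g, 1] * SN1[1] + Wb[g, 2] * SN1[2] - Wb[g, g] * s_nmda[i]
                wa2 = Wb[g, 0] * SA2[0] + Wb[g, 1] * SA2[1] + Wb[g, 2] * SA2[2] - Wb[g, g] * s_ampa2[i]
                wn2 = Wb[g, 0] * SN2[0] + Wb[g, 1] * SN2[1] + Wb[g, 2] * SN2[2] - Wb[g, g] * s_nmda2[i]
                gs1 = G1
                gs2 = G2
            else:
                cls = 1
                wa1 = SA1_tot
                wn1 = SN1_tot
                wa2 = SA2_tot
                wn2 = SN2_tot
                gs1 = G1 - s_gaba[i - n_exc]
                gs2 = G2 - s_gaba2[i - n_exc]
            v = V[i]
            i1 = (g_ext[cls] * (v - VE) * s_ext[i]
                  + g_rec[cls] * (v - VE) * wa1
                  + g_nmda[cls] * (v - VE) * mg_block(v, Mg) * wn1
                  + g_gaba[cls] * (v - VI) * gs1)
            k1 = (-gL[cls] * (v - VL[cls]) - i1) / Cm[cls]
            v2 = v + dt * k1
            i2 = (g_ext[cls] * (v2 - VE) * s_ext2[i]
                  + g_rec[cls] * (v2 - VE) * wa2
                  + g_nmda[cls] * (v2 - VE) * mg_block(v2, Mg) * wn2
                  + g_gaba[cls] * (v2 - VI) * gs2)
            k2 = (-gL[cls] * (v2 - VL[cls]) - i2) / Cm[cls]
            v_new = v + 0.5 * dt * (k1 + k2)
            if v_new >= Vth[cls]:
                V[i] = Vreset[cls]
                refr[i] = ref_steps[cls]
                if n_spikes >= max_spikes:
                    return spike_steps, spike_ids, n_spikes, STATUS_OVERFLOW, V, s_nmda
                spike_steps[n_spikes] = step
                spike_ids[n_spikes] = i
                n_spikes += 1
                slot = (ring_pos + delay_steps - 1) % delay_steps
                ring[slot, i] += 1
            else:
                V[i] = v_new

        # --- gating Heun combine ---
        for j in range(n_exc):
            k1a = -s_ampa[j] / tau_ampa
            k2a = -s_ampa2[j] / tau_ampa
            s_ampa[j] += 0.5 * dt * (k1a + k2a)
            k1x = -x_nmda[j] / tau_nmda_r
            k2x = -x2[j] / tau_nmda_r
            k1n = -s_nmda[j] / tau_nmda_d + alpha * x_nmda[j] * (1.0 - s_nmda[j])
            k2n = -s_nmda2[j] / tau_nmda_d + alpha * x2[j] * (1.0 - s_nmda2[j])
            x_nmda[j] += 0.5 * dt * (k1x + k2x)
            sn = s_nmda[j] + 0.5 * dt * (k1n + k2n)
            if sn < 0.0:
                sn = 0.0
            elif sn > 1.0:
                sn = 1.0
            s_nmda[j] = sn
        for j in range(n_inh):
            s_gaba[j] += 0.5 * dt * (-s_gaba[j] / tau_gaba - s_gaba2[j] / tau_gaba)
        for i in range(N):
            s_ext[i] += 0.5 * dt * (-s_ext[i] / tau_ampa - s_ext2[i] / tau_ampa)

        if step % 5000 == 0:
            tot = 0.0
            for i in range(N):
                tot += V[i]
            if not np.isfinite(tot):
                return spike_steps, spike_ids, n_spikes, STATUS_NONFINITE, V, s_nmda

    return spike_steps, spike_ids, n_spikes, STATUS_OK, V, s_nmda


@njit(cache=True)
def run_single_cell(
    n_steps, dt,
    n_exc_in, n_inh_in, rate_lam,   # rate_lam: events per step per train
    tau_ampa, tau_nmda_d, tau_nmda_r, alpha, tau_gaba, Mg, VE, VI,
    g_ampa, g_nmda, g_gaba,          # per-train conductances (g_nmda already scaled)
    VL, Vth, Vreset, Cm, gL, ref_steps, spiking_enabled,
    seed,
):
    """One conductance-based cell under Poisson bombardment.

    Returns (V_trace, s_nmda_mean_trace, n_spikes, status); traces are
    recorded every step.  With spiking disabled the threshold/reset rule
    is bypassed and the subthreshold trace is continuous.
    """
    np.random.seed(seed)
    s_ampa = np.zeros(n_exc_in)
    x_nmda = np.zeros(n_exc_in)
    s_nmda = np.zeros(n_exc_in)
    s_gaba = np.zeros(n_inh_in)
    s_ampa2 = np.empty(n_exc_in)
    x2 = np.empty(n_exc_in)
    s_nmda2 = np.empty(n_exc_in)
    s_gaba2 = np.empty(n_inh_in)
    v = VL
    refr = 0
    n_spk = 0
    V_trace = np.empty(n_steps)
    nmda_trace = np.empty(n_steps)

    for step in range(n_steps):
        # superposed Poisson events assigned to uniform random trains
        nev = np.random.poisson(rate_lam * n_exc_in)
        for _ in range(nev):
            j = np.random.randint(n_exc_in)
            s_ampa[j] += 1.0
            x_nmda[j] += 1.0
        nev = np.random.poisson(rate_lam * n_inh_in)
        for _ in range(nev):
            s_gaba[np.random.randint(n_inh_in)] += 1.0

        SA1 = 0.0; SN1 = 0.0; SA2 = 0.0; SN2 = 0.0
        for j in range(n_exc_in):
            SA1 += s_ampa[j]
            SN1 += s_nmda[j]
            s_ampa2[j] = s_ampa[j] - dt * s_ampa[j] / tau_ampa
            x2[j] = x_nmda[j] - dt * x_nmda[j] / tau_nmda_r
            s_nmda2[j] = s_nmda[j] + dt * (-s_nmda[j] / tau_nmda_d
                                           + alpha * x_nmda[j] * (1.0 - s_nmda[j]))
            SA2 += s_ampa2[j]
            SN2 += s_nmda2[j]
        G1 = 0.0; G2 = 0.0
        for j in range(n_inh_in):
            G1 += s_gaba[j]
            s_gaba2[j] = s_gaba[j] - dt * s_gaba[j] / tau_gaba
            G2 += s_gaba2[j]

        if refr > 0:
            refr -= 1
        else:
            i1 = (g_ampa * (v - VE) * SA1
                  + g_nmda * (v - VE) * mg_block(v, Mg) * SN1
                  + g_gaba * (v - VI) * G1)
            k1 = (-gL * (v - VL) - i1) / Cm
            v2 = v + dt * k1
            i2 = (g_ampa * (v2 - VE) * SA2
                  + g_nmda * (v2 - VE) * mg_block(v2, Mg) * SN2
                  + g_gaba * (v2 - VI) * G2)
            k2 = (-gL * (v2 - VL) - i2) / Cm
            v_new = v + 0.5 * dt * (k1 + k2)
            if spiking_enabled != 0 and v_new >= Vth:
                v = Vreset
                refr = ref_steps
                n_spk += 1
            else:
                v = v_new

        sn_sum = 0.0
        for j in range(n_exc_in):
            k1a = -s_ampa[j] / tau_ampa
            k2a = -s_ampa2[j] / tau_ampa
            s_ampa[j] += 0.5 * dt * (k1a + k2a)
            k1x = -x_nmda[j] / tau_nmda_r
            k2x = -x2[j] / tau_nmda_r
            k1n = -s_nmda[j] / tau_nmda_d + alpha * x_nmda[j] * (1.0 - s_nmda[j])
            k2n = -s_nmda2[j] / tau_nmda_d + alpha * x2[j] * (1.0 - s_nmda2[j])
            x_nmda[j] += 0.5 * dt * (k1x + k2x)
            sn = s_nmda[j] + 0.5 * dt * (k1n + k2n)
            if sn < 0.0:
                sn = 0.0
            elif sn > 1.0:
                sn = 1.0
            s_nmda[j] = sn
            sn_sum += sn
        for j in range(n_inh_in):
            s_gaba[j] += 0.5 * dt * (-s_gaba[j] / tau_gaba - s_gaba2[j] / tau_gaba)

        V_trace[step] = v
        nmda_trace[step] = sn_sum / n_exc_in
        if step % 5000 == 0 and not np.isfinite(v):
            return V_trace, nmda_trace, n_spk, STATUS_NONFINITE

    return V_trace, nmda_trace, n_spk, STATUS_OK
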