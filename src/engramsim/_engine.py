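"""Clock-driven simulation core (numba).

One jitted loop advances the whole circuit at dt = 0.05 ms: exact
difference-of-exponentials recursion for the receptor kernels, Heun (RK2)
integration of the membrane equation with conductances frozen within the
step, linear spike-time interpolation at threshold crossings, Tsodyks-Markram
short-term plasticity on E presynapses, the composite long-term rule on E->E
synapses, Poisson external drive, and duty-cycled membrane-reset rescue
stimulation.

Randomness: external Poisson input uses numba's numpy RNG seeded with
``ext_seed``; rescue resets use a private xorshift64* stream seeded with
``rescue_seed`` so the two are reproducible independently.

Synaptic latency is honored by circular delay buffers holding pending
weighted increments per receptor class; an increment enters both exponential
accumulators on delivery, so the kernel starts at zero at t_spike + tau_l
and follows the bi-exponential exactly thereafter.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_simulation"]


@njit(cache=True, inline="always")
def _xorshift(state):
    s = state
    s ^= s >> 12
    s ^= (s << 25) & np.uint64(0xFFFFFFFFFFFFFFFF)
    s ^= s >> 27
    return s


@njit(cache=True, inline="always")
def _xs_uniform(state):
    s = _xorshift(state)
    return s, np.float64(s >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True, fastmath=True)
def _core(
    # integration
    dt,
    n_steps,
    # neurons
    is_exc,
    tau_m,
    v_leak,
    v_thresh,
    v_reset,
    e_exc,
    e_inh,
    ref_steps,
    # connectivity (CSR by presynaptic neuron)
    indptr,
    targets,
    syn_w,
    # kernel constants: decay factors and gain per receptor, delay lengths
    fd_ampa,
    fr_ampa,
    gain_ampa,
    d_ampa,
    fd_nmda,
    fr_nmda,
    gain_nmda,
    d_nmda,
    fd_gaba,
    fr_gaba,
    gain_gaba,
    d_gaba,
    # external drive: per-segment rate (events per step) and weight
    seg_end_step,
    ext_rate_per_step,
    g_ext,
    ext_seed,
    # short-term plasticity
    stp_U,
    stp_fu,
    stp_fx,
    # long-term plasticity
    plast_on,
    plast_start_step,
    plast_end_step,
    pA,
    pB,
    p_beta,
    p_wtilde,
    p_delta1,
    fz,
    fz_slow,
    w_min,
    w_max,
    in_indptr,
    in_src,
    in_edge,
    # rescue stimulation
    rescue_on,
    rescue_start_step,
    rescue_period_steps,
    rescue_on_steps,
    rescue_chosen,
    rescue_p,
    rescue_seed,
    # weight monitoring
    plastic_edge,
    edge_group,
    n_groups,
    weight_cadence_steps,
    # recording
    max_spikes,
    ms_steps,
):
    n = tau_m.size
    v = v_leak.copy()
    refrac = np.zeros(n, dtype=np.int64)

    # receptor accumulators (a decays with tau_d, b with tau_r)
    a_ampa = np.zeros(n)
    b_ampa = np.zeros(n)
    a_nmda = np.zeros(n)
    b_nmda = np.zeros(n)
    a_gaba = np.zeros(n)
    b_gaba = np.zeros(n)

    buf_ampa = np.zeros((d_ampa, n))
    buf_nmda = np.zeros((d_nmda, n))
    buf_gaba = np.zeros((d_gaba, n))
    h_ampa = 0
    h_nmda = 0
    h_gaba = 0

    u = np.full(n, stp_U)
    x = np.ones(n)
    z = np.zeros(n)
    z_slow = np.zeros(n)

    np.random.seed(ext_seed)
    rs = np.uint64(rescue_seed * 2685821657736338717 + 1442695040888963407)

    spike_t = np.empty(max_spikes)
    spike_id = np.empty(max_spikes, dtype=np.int32)
    n_spikes = 0
    overflow = False

    n_ms = n_steps // ms_steps
    v_mean = np.zeros(n_ms)
    i_exc_mean = np.zeros(n_ms)
    i_inh_mean = np.zeros(n_ms)
    nE = 0
    for i in range(n):
        if is_exc[i]:
            nE += 1

    n_wrec = n_steps // weight_cadence_steps if weight_cadence_steps > 0 else 0
    w_group_mean = np.zeros((n_wrec, n_groups))
    min_w_seen = 1e300
    if plast_on:
        for e in range(syn_w.size):
            if plastic_edge[e] and syn_w[e] < min_w_seen:
                min_w_seen = syn_w[e]

    spiking = np.empty(n, dtype=np.int64)
    seg = 0

    for step in range(n_steps):
        while seg < seg_end_step.size - 1 and step >= seg_end_step[seg]:
            seg += 1

        # --- kernel recursion: decay accumulators, deliver due increments ---
        h_ampa = (h_ampa + 1) % d_ampa
        h_nmda = (h_nmda + 1) % d_nmda
        h_gaba = (h_gaba + 1) % d_gaba
        for i in range(n):
            a_ampa[i] = a_ampa[i] * fd_ampa + buf_ampa[h_ampa, i] * gain_ampa
            b_ampa[i] = b_ampa[i] * fr_ampa + buf_ampa[h_ampa, i] * gain_ampa
            a_nmda[i] = a_nmda[i] * fd_nmda + buf_nmda[h_nmda, i] * gain_nmda
            b_nmda[i] = b_nmda[i] * fr_nmda + buf_nmda[h_nmda, i] * gain_nmda
            a_gaba[i] = a_gaba[i] * fd_gaba + buf_gaba[h_gaba, i] * gain_gaba
            b_gaba[i] = b_gaba[i] * fr_gaba + buf_gaba[h_gaba, i] * gain_gaba
            buf_ampa[h_ampa, i] = 0.0
            buf_nmda[h_nmda, i] = 0.0
            buf_gaba[h_gaba, i] = 0.0

        # --- external Poisson drive (no latency, no STP) ---
        for i in range(n):
            lam = ext_rate_per_step[seg, i]
            if lam > 0.0:
                k = np.random.poisson(lam)
                if k > 0:
                    inc = k * g_ext[i] * gain_ampa
                    a_ampa[i] += inc
                    b_ampa[i] += inc

        # --- STP relaxation toward (U, 1) ---
        for i in range(n):
            if is_exc[i]:
                u[i] = stp_U + (u[i] - stp_U) * stp_fu
                x[i] = 1.0 + (x[i] - 1.0) * stp_fx

        plast_active = plast_on and plast_start_step <= step < plast_end_step
        if plast_active:
            for i in range(n):
                z[i] *= fz
                z_slow[i] *= fz_slow

        # --- rescue membrane reset ---
        if rescue_on and step >= rescue_start_step:
            phase = (step - rescue_start_step) % rescue_period_steps
            if phase < rescue_on_steps:
                for i in range(n):
                    if rescue_chosen[i] and refrac[i] == 0:
                        rs, r = _xs_uniform(rs)
                        if r < rescue_p:
                            v[i] = v_leak[i]

        # --- membrane integration (Heun, conductances frozen in the step) ---
        t_ms = step * dt
        n_spiking = 0
        for i in range(n):
            if refrac[i] > 0:
                refrac[i] -= 1
                v[i] = v_reset[i]
                continue
            ge = tau_m[i] * (a_ampa[i] - b_ampa[i] + a_nmda[i] - b_nmda[i])
            gi = tau_m[i] * (a_gaba[i] - b_gaba[i])
            v0 = v[i]
            k1 = (
                v_leak[i] - v0 + ge * (e_exc[i] - v0) + gi * (e_inh[i] - v0)
            ) / tau_m[i]
            v1 = v0 + dt * k1
            k2 = (
                v_leak[i] - v1 + ge * (e_exc[i] - v1) + gi * (e_inh[i] - v1)
            ) / tau_m[i]
            vn = v0 + 0.5 * dt * (k1 + k2)
            if vn >= v_thresh[i]:
                # linear spike-time interpolation inside the step
                theta = (v_thresh[i] - v0) / (vn - v0)
                if n_spikes < max_spikes:
                    spike_t[n_spikes] = t_ms + theta * dt
                    spike_id[n_spikes] = i
                    n_spikes += 1
                else:
                    overflow = True
                spiking[n_spiking] = i
                n_spiking += 1
                v[i] = v_reset[i]
                refrac[i] = ref_steps[i]
            else:
                v[i] = vn

        # --- propagate spikes into delay buffers (weights before this
        #     step's plasticity updates; STP release sampled at the spike) ---
        for si in range(n_spiking):
            j = spiking[si]
            if is_exc[j]:
                u[j] = u[j] + stp_U * (1.0 - u[j])
                rel = u[j] * x[j]
                x[j] = x[j] - rel
                for e in range(indptr[j], indptr[j + 1]):
                    amt = syn_w[e] * rel
                    tgt = targets[e]
                    buf_ampa[h_ampa, tgt] += amt
                    buf_nmda[h_nmda, tgt] += amt
            else:
                for e in range(indptr[j], indptr[j + 1]):
                    buf_gaba[h_gaba, targets[e]] += syn_w[e]

        # --- long-term plasticity: pre-spike terms first, then post-spike
        #     terms, with traces at their pre-increment values ---
        if plast_active and n_spiking > 0:
            for si in range(n_spiking):
                j = spiking[si]
                if not is_exc[j]:
                    continue
                for e in range(indptr[j], indptr[j + 1]):
                    if plastic_edge[e]:
                        w = syn_w[e] - pB * z[targets[e]] + p_delta1
                        if w < w_min:
                            w = w_min
                        syn_w[e] = w
                        if w < min_w_seen:
                            min_w_seen = w
            for si in range(n_spiking):
                i = spiking[si]
                if not is_exc[i]:
                    continue
                zi = z[i]
                zsi = z_slow[i]
                het = p_beta * zi * zi * zi
                for q in range(in_indptr[i], in_indptr[i + 1]):
                    e = in_edge[q]
                    w = syn_w[e]
                    dev = (w - p_wtilde) / p_wtilde
                    w = w + pA * z[in_src[q]] * zsi - het * dev * dev * dev
                    if w < w_min:
                        w = w_min
                    if w_max > 0.0 and w > w_max:
                        w = w_max
                    syn_w[e] = w
                    if w < min_w_seen:
                        min_w_seen = w
            for si in range(n_spiking):
                i = spiking[si]
                if is_exc[i]:
                    z[i] += 1.0
                    z_slow[i] += 1.0

        # --- recordings at 1 ms cadence ---
        if (step + 1) % ms_steps == 0:
            idx = (step + 1) // ms_steps - 1
            if idx < n_ms:
                sv = 0.0
                se = 0.0
                si_ = 0.0
                for i in range(n):
                    if is_exc[i]:
                        ge = tau_m[i] * (
                            a_ampa[i] - b_ampa[i] + a_nmda[i] - b_nmda[i]
                        )
                        gi = tau_m[i] * (a_gaba[i] - b_gaba[i])
                        sv += v[i]
                        se += ge * (e_exc[i] - v[i])
                        si_ += gi * (e_inh[i] - v[i])
                v_mean[idx] = sv / nE
                i_exc_mean[idx] = se / nE
                i_inh_mean[idx] = si_ / nE

        if n_wrec > 0 and (step + 1) % weight_cadence_steps == 0:
            idx = (step + 1) // weight_cadence_steps - 1
            if idx < n_wrec:
                gsum = np.zeros(n_groups)
                gcnt = np.zeros(n_groups, dtype=np.int64)
                for e in range(syn_w.size):
                    gidx = edge_group[e]
                    if gidx >= 0:
                        gsum[gidx] += syn_w[e]
                        gcnt[gidx] += 1
                for gidx in range(n_groups):
                    if gcnt[gidx] > 0:
                        w_group_mean[idx, gidx] = gsum[gidx] / gcnt[gidx]

    return (
        spike_t[:n_spikes],
        spike_id[:n_spikes],
        v_mean,
        i_exc_mean,
        i_inh_mean,
        w_group_mean,
        min_w_seen,
        overflow,
    )


def run_simulation(
    *,
    dt,
    n_steps,
    is_exc,
    tau_m,
    v_leak,
    v_thresh,
    v_reset,
    e_exc,
    e_inh,
    ref_steps,
    indptr,
    targets,
    syn_w,
    kernels,
    seg_end_step,
    ext_rate_per_step,
    g_ext,
    ext_seed,
    stp_U,
    stp_fu,
    stp_fx,
    plasticity=None,
    rescue=None,
    edge_group=None,
    n_groups=0,
    weight_cadence_steps=0,
    max_spikes=None,
    ms_steps=20,
):
    """Thin python wrapper assembling arguments for the jitted core.

    ``kernels`` maps receptor name -> (fd, fr, gain, delay_steps);
    ``plasticity`` and ``rescue`` are dicts of the core's respective fields
    or None to disable.  Returns (spike_times_ms, spike_ids, v_mean_E,
    i_exc_mean_E, i_inh_mean_E, w_group_mean, min_weight_seen).
    """
    n = tau_m.size
    if max_spikes is None:
        # generous headroom: 200 Hz mean over the whole population
        max_spikes = int(n * n_steps * dt / 1000.0 * 200.0) + 10_000

    if plasticity is None:
        plast = dict(
            plast_on=False,
            plast_start_step=0,
            plast_end_step=0,
            pA=0.0,
            pB=0.0,
            p_beta=0.0,
            p_wtilde=1.0,
            p_delta1=0.0,
            fz=1.0,
            fz_slow=1.0,
            w_min=0.001,
            w_max=0.0,
            in_indptr=np.zeros(n + 1, dtype=np.int64),
            in_src=np.zeros(0, dtype=np.int32),
            in_edge=np.zeros(0, dtype=np.int64),
        )
    else:
        plast = plasticity

    if rescue is None:
        resc = dict(
            rescue_on=False,
            rescue_start_step=0,
            rescue_period_steps=1,
            rescue_on_steps=0,
            rescue_chosen=np.zeros(n, dtype=np.bool_),
            rescue_p=0.0,
            rescue_seed=1,
        )
    else:
        resc = rescue

    plastic_edge = plast.get("plastic_edge")
    if plastic_edge is None:
        plastic_edge = is_exc[np.asarray(targets)] & np.repeat(
            is_exc[np.arange(n)], np.diff(indptr)
        )
    if edge_group is None:
        edge_group = np.full(targets.size, -1, dtype=np.int32)
        n_groups = 0

    fd_a, fr_a, g_a, d_a = kernels["ampa"]
    fd_n, fr_n, g_n, d_n = kernels["nmda"]
    fd_g, fr_g, g_g, d_g = kernels["gaba"]

    out = _core(
        dt,
        n_steps,
        is_exc,
        tau_m,
        v_leak,
        v_thresh,
        v_reset,
        e_exc,
        e_inh,
        ref_steps,
        indptr,
        targets,
        syn_w,
        fd_a,
        fr_a,
        g_a,
        d_a,
        fd_n,
        fr_n,
        g_n,
        d_n,
        fd_g,
        fr_g,
        g_g,
        d_g,
        seg_end_step,
        ext_rate_per_step,
        g_ext,
        ext_seed,
        stp_U,
        stp_fu,
        stp_fx,
        plast["plast_on"],
        plast["plast_start_step"],
        plast["plast_end_step"],
        plast["pA"],
        plast["pB"],
        plast["p_beta"],
        plast["p_wtilde"],
        plast["p_delta1"],
        plast["fz"],
        plast["fz_slow"],
        plast["w_min"],
        plast["w_max"],
        plast["in_indptr"],
        plast["in_src"],
        plast["in_edge"],
        resc["rescue_on"],
        resc["rescue_start_step"],
        resc["rescue_period_steps"],
        resc["rescue_on_steps"],
        resc["rescue_chosen"],
        resc["rescue_p"],
        resc["rescue_seed"],
        plastic_edge,
        edge_group,
        n_groups,
        weight_cadence_steps,
        max_spikes,
        ms_steps,
    )
    (
        spike_t,
        spike_id,
        v_mean,
        i_exc_mean,
        i_inh_mean,
        w_group_mean,
        min_w,
        overflow,
    ) = out
    if overflow:
        raise RuntimeError(
            "spike buffer overflow: network firing far above expected range "
            "(parameter blow-up?)"
        )
    return spike_t, spike_id, v_mean, i_exc_mean, i_inh_mean, w_group_mean, min_w
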