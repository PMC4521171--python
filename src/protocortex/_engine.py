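"""Clock-driven LIF + STDP kernel.

One numba-compiled function advances the whole LGN + cortex system through a
presentation at a fixed time step.  Synapses are flat arrays indexed two
ways (grouped by presynaptic and by postsynaptic neuron) so that spike
delivery walks outgoing synapses and potentiation walks incoming ones.
Delayed delivery uses a circular current buffer of depth ``max_delay + 1``
steps; all delays are >= 1 step, so a slot is always drained before anything
new lands in it.

The per-step order of operations is the contract the pure-Python reference
in :mod:`protocortex.dynamics` replicates:

1. integrate LGN membranes against the event drive; collect LGN spikes;
2. integrate cortical membranes against the current buffer slot for this
   step; collect cortical spikes;
3. schedule afferent / lateral currents from this step's spikes;
4. register the new spikes in the last-spike tables, then apply STDP:
   potentiation for synapses onto spiking targets (``dt <= 0``, ties
   included), depression for synapses out of spiking sources (``dt > 0``
   strictly).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_kernel"]


@njit(cache=True)
def run_kernel(
    n_steps,
    drive,  # (n_steps, n_lgn) int32 forced input-spike counts per LGN unit
    # LIF parameters
    dt_ms,
    leak,  # dt / tau_m
    v_rest,
    v_reset,
    v_thresh,
    refr_steps,
    relay_gain,
    gain_aff,
    gain_le,
    gain_inh,
    # afferent synapses (LGN -> cortex)
    aff_pre,
    aff_post,
    aff_w,
    aff_delay,
    aff_order_pre,
    aff_indptr_pre,
    aff_order_post,
    aff_indptr_post,
    # lateral excitatory synapses (cortex -> cortex)
    le_pre,
    le_post,
    le_w,
    le_delay,
    le_order_pre,
    le_indptr_pre,
    le_order_post,
    le_indptr_post,
    # lateral inhibitory synapses (cortex -> cortex)
    li_pre,
    li_post,
    li_w,
    li_delay,
    li_order_pre,
    li_indptr_pre,
    li_order_post,
    li_indptr_post,
    # plasticity
    learn_aff,
    learn_lat,
    a_pa,
    a_ma,
    a_pl,
    a_ml,
    tau_ltp,
    tau_ltd,
    window_ms,
    max_delay_steps,
    inh_mode,  # 0 Hebbian, 1 anti-Hebbian, 2 symmetric
):
    n_lgn = drive.shape[1]
    n_ctx = aff_indptr_post.shape[0] - 1

    v_lgn = np.full(n_lgn, v_rest)
    v_ctx = np.full(n_ctx, v_rest)
    refr_lgn = np.zeros(n_lgn, dtype=np.int64)
    refr_ctx = np.zeros(n_ctx, dtype=np.int64)
    last_lgn = np.full(n_lgn, -1e9)
    last_ctx = np.full(n_ctx, -1e9)

    depth = max_delay_steps + 1
    buf = np.zeros((depth, n_ctx))

    cap_lgn = n_lgn * (n_steps // (refr_steps + 1) + 1)
    cap_ctx = n_ctx * (n_steps // (refr_steps + 1) + 1)
    lgn_spike_t = np.empty(cap_lgn, dtype=np.int64)
    lgn_spike_id = np.empty(cap_lgn, dtype=np.int64)
    ctx_spike_t = np.empty(cap_ctx, dtype=np.int64)
    ctx_spike_id = np.empty(cap_ctx, dtype=np.int64)
    n_lgn_sp = 0
    n_ctx_sp = 0

    lgn_now = np.empty(n_lgn, dtype=np.int64)
    ctx_now = np.empty(n_ctx, dtype=np.int64)

    for t in range(n_steps):
        t_ms = t * dt_ms
        slot = t % depth

        # --- LGN layer: relay of forced input spikes -------------------
        k_lgn = 0
        for i in range(n_lgn):
            if refr_lgn[i] > 0:
                refr_lgn[i] -= 1
                v_lgn[i] = v_reset
                continue
            v = v_lgn[i] + leak * (v_rest - v_lgn[i]) + relay_gain * drive[t, i]
            if v >= v_thresh:
                v_lgn[i] = v_reset
                refr_lgn[i] = refr_steps
                lgn_now[k_lgn] = i
                k_lgn += 1
                lgn_spike_t[n_lgn_sp] = t
                lgn_spike_id[n_lgn_sp] = i
                n_lgn_sp += 1
            else:
                v_lgn[i] = v

        # --- cortical layer -------------------------------------------
        k_ctx = 0
        for j in range(n_ctx):
            if refr_ctx[j] > 0:
                refr_ctx[j] -= 1
                v_ctx[j] = v_reset
                continue
            v = v_ctx[j] + leak * (v_rest - v_ctx[j]) + buf[slot, j]
            if v >= v_thresh:
                v_ctx[j] = v_reset
                refr_ctx[j] = refr_steps
                ctx_now[k_ctx] = j
                k_ctx += 1
                ctx_spike_t[n_ctx_sp] = t
                ctx_spike_id[n_ctx_sp] = j
                n_ctx_sp += 1
            else:
                v_ctx[j] = v
        for j in range(n_ctx):
            buf[slot, j] = 0.0

        # --- schedule delayed currents --------------------------------
        for a in range(k_lgn):
            i = lgn_now[a]
            for k in range(aff_indptr_pre[i], aff_indptr_pre[i + 1]):
                s = aff_order_pre[k]
                buf[(t + aff_delay[s]) % depth, aff_post[s]] += (
                    gain_aff * aff_w[s]
                )
        for a in range(k_ctx):
            i = ctx_now[a]
            for k in range(le_indptr_pre[i], le_indptr_pre[i + 1]):
                s = le_order_pre[k]
                buf[(t + le_delay[s]) % depth, le_post[s]] += (
                    gain_le * le_w[s]
                )
            for k in range(li_indptr_pre[i], li_indptr_pre[i + 1]):
                s = li_order_pre[k]
                buf[(t + li_delay[s]) % depth, li_post[s]] -= (
                    gain_inh * li_w[s]
                )

        # --- plasticity ------------------------------------------------
        for a in range(k_lgn):
            last_lgn[lgn_now[a]] = t_ms
        for a in range(k_ctx):
            last_ctx[ctx_now[a]] = t_ms

        if learn_aff:
            for a in range(k_ctx):  # LTP onto cortical spikers
                j = ctx_now[a]
                for k in range(aff_indptr_post[j], aff_indptr_post[j + 1]):
                    s = aff_order_post[k]
                    dt_pair = last_lgn[aff_pre[s]] - t_ms
                    if dt_pair >= -window_ms:
                        aff_w[s] += a_pa * np.exp(dt_pair / tau_ltp)
            for a in range(k_lgn):  # LTD out of LGN spikers
                i = lgn_now[a]
                for k in range(aff_indptr_pre[i], aff_indptr_pre[i + 1]):
                    s = aff_order_pre[k]
                    dt_pair = t_ms - last_ctx[aff_post[s]]
                    if 0.0 < dt_pair <= window_ms:
                        x = dt_pair / tau_ltd
                        aff_w[s] *= 1.0 + a_ma * x * np.exp(1.0 - x)

        if learn_lat:
            for a in range(k_ctx):
                j = ctx_now[a]
                # LTP onto cortical spikers
                for k in range(le_indptr_post[j], le_indptr_post[j + 1]):
                    s = le_order_post[k]
                    dt_pair = last_ctx[le_pre[s]] - t_ms
                    if dt_pair >= -window_ms:
                        le_w[s] += a_pl * np.exp(dt_pair / tau_ltp)
                for k in range(li_indptr_post[j], li_indptr_post[j + 1]):
                    s = li_order_post[k]
                    dt_pair = last_ctx[li_pre[s]] - t_ms
                    if inh_mode == 1:
                        # anti-Hebbian: pre-before-post depresses
                        # (mirrored window; ties go to the LTP branch in
                        # the pre-spiker loop below)
                        if -window_ms <= dt_pair < 0.0:
                            x = -dt_pair / tau_ltd
                            li_w[s] *= 1.0 + a_ml * x * np.exp(1.0 - x)
                    elif inh_mode == 2:
                        # symmetric: near-coincidence potentiates in either
                        # order (ties handled in the pre-spiker loop)
                        if -window_ms <= dt_pair < 0.0:
                            li_w[s] += a_pl * np.exp(dt_pair / tau_ltp)
                    else:
                        if dt_pair >= -window_ms:
                            li_w[s] += a_pl * np.exp(dt_pair / tau_ltp)
                # LTD out of cortical spikers
                for k in range(le_indptr_pre[j], le_indptr_pre[j + 1]):
                    s = le_order_pre[k]
                    dt_pair = t_ms - last_ctx[le_post[s]]
                    if 0.0 < dt_pair <= window_ms:
                        x = dt_pair / tau_ltd
                        le_w[s] *= 1.0 + a_ml * x * np.exp(1.0 - x)
                for k in range(li_indptr_pre[j], li_indptr_pre[j + 1]):
                    s = li_order_pre[k]
                    dt_pair = t_ms - last_ctx[li_post[s]]
                    if inh_mode == 1 or inh_mode == 2:
                        if 0.0 <= dt_pair <= window_ms:
                            li_w[s] += a_pl * np.exp(-dt_pair / tau_ltp)
                    else:
                        if 0.0 < dt_pair <= window_ms:
                            x = dt_pair / tau_ltd
                            li_w[s] *= 1.0 + a_ml * x * np.exp(1.0 - x)

    return (
        lgn_spike_t[:n_lgn_sp],
        lgn_spike_id[:n_lgn_sp],
        ctx_spike_t[:n_ctx_sp],
        ctx_spike_id[:n_ctx_sp],
    )
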