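"""Leaky integrate-and-fire simulation of one stimulus presentation.

All three layers are clock-driven LIF neurons on a 1 ms default grid:

    v(t + dt) = v(t) + (dt / tau_m) * (v_rest - v(t)) + I(t)

with threshold-reset spiking and an absolute refractory period.  Input-layer
neurons are forced to spike at their event timestamps, the LGN relays pooled
input spikes (one afferent input spike drives a relay unit over threshold),
and cortical neurons integrate delayed afferent and lateral currents, with
lateral inhibition entering with negative sign.  Presentations are
independent by construction: each one starts from resting potentials with an
empty delay line, which is the explicit between-pattern reset of the
training procedure.  Only synaptic weights persist across presentations.

Two interchangeable integrators exist: a compiled kernel
(:mod:`protocortex._engine`, the default) and a slow pure-Python reference
used to validate it on small systems (``engine="python"``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .network import Network, Pathway
from .plasticity import (
    STDPParams,
    PairingState,
    on_spike,
    on_spike_anti_hebbian,
    on_spike_symmetric,
)
from .stimulus import EventStream

__all__ = [
    "LIFParams",
    "LearningFlags",
    "SpikeRecord",
    "lif_step",
    "run_presentation",
    "reset_network",
]

# Steps simulated past the last event so delayed volleys and membrane
# tails play out before the presentation ends.
_TAIL_MS = 30.0


@dataclass(frozen=True)
class LIFParams:
    """Membrane and synaptic-gain constants (potentials in threshold units).

    ``syn_gain_exc`` converts a unit afferent weight into membrane drive:
    at the default, a wavefront volley of ~15 near-coincident LGN spikes at
    the mean initial afferent weight reaches threshold, which keeps probe
    responses sparse (a few spikes per sweep).  Lateral excitation is given
    a smaller gain so recurrence biases spike timing rather than driving
    runaway excitation ahead of the slower, distance-delayed inhibition.
    ``relay_gain`` makes a single pooled input spike fire an LGN relay
    unit.
    """

    tau_m_ms: float = 8.0
    v_rest: float = 0.0
    v_reset: float = 0.0
    v_thresh: float = 1.0
    refractory_ms: float = 2.0
    dt_ms: float = 1.0
    syn_gain_exc: float = 0.33
    syn_gain_lateral_exc: float = 0.1
    syn_gain_inh: float = 0.473
    relay_gain: float = 1.2

    def __post_init__(self) -> None:
        if not (self.v_reset <= self.v_rest < self.v_thresh):
            raise ValueError(
                "LIF potentials must satisfy v_reset <= v_rest < v_thresh"
            )
        if self.tau_m_ms <= 0:
            raise ValueError("tau_m_ms must be > 0")
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be > 0")
        if self.refractory_ms < 0:
            raise ValueError("refractory_ms must be >= 0")


@dataclass(frozen=True)
class LearningFlags:
    """Per-pathway plasticity switches."""

    afferent: bool = True
    lateral: bool = True

    @property
    def any(self) -> bool:
        return self.afferent or self.lateral


def lif_step(v, input_current, params: LIFParams):
    """One Euler step of the leaky membrane; returns ``(v', fired)``.

    Pure function (no refractory bookkeeping): the caller must only step
    non-refractory neurons.  Vectorized over ``v``/``input_current``.
    """
    v = np.asarray(v, dtype=float)
    vp = v + (params.dt_ms / params.tau_m_ms) * (params.v_rest - v) + np.asarray(
        input_current, dtype=float
    )
    fired = vp >= params.v_thresh
    vp = np.where(fired, params.v_reset, vp)
    if vp.ndim == 0:
        return float(vp), bool(fired)
    return vp, fired


@dataclass
class SpikeRecord:
    """Per-layer spike times from one presentation."""

    lgn_times_ms: np.ndarray
    lgn_ids: np.ndarray
    cortex_times_ms: np.ndarray
    cortex_ids: np.ndarray
    n_lgn: int
    n_cortex: int
    duration_ms: float
    meta: dict = field(default_factory=dict)

    def cortex_counts(self) -> np.ndarray:
        """Spike count per cortical neuron."""
        return np.bincount(
            self.cortex_ids.astype(int), minlength=self.n_cortex
        )

    def lgn_counts(self) -> np.ndarray:
        return np.bincount(self.lgn_ids.astype(int), minlength=self.n_lgn)

    def neuron_times(self, layer: str, neuron_id: int) -> np.ndarray:
        if layer == "cortex":
            return self.cortex_times_ms[self.cortex_ids == neuron_id]
        if layer == "lgn":
            return self.lgn_times_ms[self.lgn_ids == neuron_id]
        raise ValueError(f"unknown layer {layer!r}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpikeRecord):
            return NotImplemented
        return (
            np.array_equal(self.lgn_times_ms, other.lgn_times_ms)
            and np.array_equal(self.lgn_ids, other.lgn_ids)
            and np.array_equal(self.cortex_times_ms, other.cortex_times_ms)
            and np.array_equal(self.cortex_ids, other.cortex_ids)
        )

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as fh:
            fh.attrs["meta"] = json.dumps(self.meta)
            fh.attrs["n_lgn"] = self.n_lgn
            fh.attrs["n_cortex"] = self.n_cortex
            fh.attrs["duration_ms"] = self.duration_ms
            for name in ("lgn_times_ms", "lgn_ids", "cortex_times_ms",
                         "cortex_ids"):
                fh.create_dataset(name, data=getattr(self, name))

    @classmethod
    def load(cls, path: str | Path) -> "SpikeRecord":
        with h5py.File(path, "r") as fh:
            return cls(
                lgn_times_ms=fh["lgn_times_ms"][:],
                lgn_ids=fh["lgn_ids"][:],
                cortex_times_ms=fh["cortex_times_ms"][:],
                cortex_ids=fh["cortex_ids"][:],
                n_lgn=int(fh.attrs["n_lgn"]),
                n_cortex=int(fh.attrs["n_cortex"]),
                duration_ms=float(fh.attrs["duration_ms"]),
                meta=json.loads(fh.attrs["meta"]),
            )


def reset_network(network: Network) -> Network:
    """Clear transient simulation state; weights are untouched.

    Presentations already start from resting potentials with an empty delay
    line (see module docstring), so this is the explicit form of the
    between-pattern reset: it exists so callers can state the contract, and
    it guarantees no membrane or in-flight-spike state leaks between
    patterns.
    """
    return network


def _event_drive(
    network: Network, stream: EventStream, dt_ms: float
) -> np.ndarray:
    cfg = network.config
    ev = stream.events
    if len(ev):
        if (
            ev["x"].min() < 0
            or ev["x"].max() >= cfg.input_shape[0]
            or ev["y"].min() < 0
            or ev["y"].max() >= cfg.input_shape[1]
        ):
            raise ValueError(
                "stream contains events outside the "
                f"{cfg.input_shape[0]}x{cfg.input_shape[1]} input grid"
            )
    n_steps = int(math.ceil((stream.duration_ms + _TAIL_MS) / dt_ms)) + 1
    drive = np.zeros((n_steps, cfg.n_lgn), dtype=np.int32)
    if len(ev):
        steps = np.floor(ev["t"] / dt_ms).astype(np.int64)
        # Both polarities relay identically onto the single input sheet.
        lgn = (ev["y"] // 4) * cfg.lgn_shape[0] + (ev["x"] // 4)
        np.add.at(drive, (steps, lgn.astype(np.int64)), 1)
    return drive


def _delay_steps(delay_ms: np.ndarray, dt_ms: float) -> np.ndarray:
    """Delays quantized to whole steps, minimum one step (causality)."""
    return np.maximum(np.round(delay_ms / dt_ms), 1).astype(np.int64)


def run_presentation(
    network: Network,
    stream: EventStream,
    learning: LearningFlags | None = None,
    lif: LIFParams | None = None,
    stdp: STDPParams | None = None,
    engine: str = "auto",
) -> SpikeRecord:
    """Simulate one presentation; weights update in place when learning is on.

    The model is fully deterministic given ``(network, stream, flags)``:
    there is no spontaneous activity or synaptic noise, so no random state
    enters the simulation itself.
    """
    learning = learning or LearningFlags()
    lif = lif or LIFParams()
    stdp = stdp or STDPParams()

    drive = _event_drive(network, stream, lif.dt_ms)
    n_steps = drive.shape[0]
    refr_steps = int(round(lif.refractory_ms / lif.dt_ms))

    aff = network.pathways[Pathway.AFFERENT]
    le = network.pathways[Pathway.LATERAL_EXC]
    li = network.pathways[Pathway.LATERAL_INH]

    groups = {}
    max_delay = 1
    for name, grp in ((Pathway.AFFERENT, aff), (Pathway.LATERAL_EXC, le),
                      (Pathway.LATERAL_INH, li)):
        dsteps = _delay_steps(grp.delay_ms, lif.dt_ms)
        if len(dsteps):
            max_delay = max(max_delay, int(dsteps.max()))
        n_pre = network.n_lgn if name == Pathway.AFFERENT else network.n_cortex
        order_pre, indptr_pre = grp.by_pre(n_pre)
        order_post, indptr_post = grp.by_post(network.n_cortex)
        groups[name] = (grp, dsteps, order_pre, indptr_pre, order_post,
                        indptr_post)

    learn_aff = learning.afferent and aff.plastic
    learn_lat = learning.lateral and (le.plastic or li.plastic)

    args = dict(
        n_steps=n_steps,
        drive=drive,
        dt_ms=lif.dt_ms,
        leak=lif.dt_ms / lif.tau_m_ms,
        v_rest=lif.v_rest,
        v_reset=lif.v_reset,
        v_thresh=lif.v_thresh,
        refr_steps=refr_steps,
        relay_gain=lif.relay_gain,
        gain_aff=lif.syn_gain_exc,
        gain_le=lif.syn_gain_lateral_exc,
        gain_inh=lif.syn_gain_inh,
        learn_aff=learn_aff,
        learn_lat=learn_lat,
        a_pa=stdp.a_ltp_afferent,
        a_ma=stdp.a_ltd_afferent,
        a_pl=stdp.a_ltp_lateral,
        a_ml=stdp.a_ltd_lateral,
        tau_ltp=stdp.tau_ltp_ms,
        tau_ltd=stdp.tau_ltd_ms,
        window_ms=stdp.pairing_window_ms,
        max_delay_steps=max_delay,
        inh_mode={'hebbian': 0, 'anti_hebbian': 1, 'symmetric': 2}[stdp.inhibitory_stdp],
    )

    if engine == "python":
        out = _run_python(network, groups, stdp, **args)
    elif engine in ("auto", "numba"):
        from ._engine import run_kernel

        flat = []
        for name in (Pathway.AFFERENT, Pathway.LATERAL_EXC,
                     Pathway.LATERAL_INH):
            grp, dsteps, op, ip, opost, ipost = groups[name]
            flat.extend([
                grp.pre.astype(np.int64), grp.post.astype(np.int64),
                grp.weight, dsteps, op, ip, opost, ipost,
            ])
        out = run_kernel(
            args["n_steps"], args["drive"], args["dt_ms"], args["leak"],
            args["v_rest"], args["v_reset"], args["v_thresh"],
            args["refr_steps"], args["relay_gain"], args["gain_aff"],
            args["gain_le"], args["gain_inh"], *flat, args["learn_aff"], args["learn_lat"],
            args["a_pa"], args["a_ma"], args["a_pl"], args["a_ml"],
            args["tau_ltp"], args["tau_ltd"], args["window_ms"],
            args["max_delay_steps"], args["inh_mode"],
        )
    else:
        raise ValueError(f"unknown engine {engine!r}")

    lgn_t, lgn_id, ctx_t, ctx_id = out
    return SpikeRecord(
        lgn_times_ms=np.asarray(lgn_t, dtype=float) * lif.dt_ms,
        lgn_ids=np.asarray(lgn_id),
        cortex_times_ms=np.asarray(ctx_t, dtype=float) * lif.dt_ms,
        cortex_ids=np.asarray(ctx_id),
        n_lgn=network.n_lgn,
        n_cortex=network.n_cortex,
        duration_ms=stream.duration_ms,
        meta={
            "direction_deg": stream.direction_deg,
            "instance_id": stream.instance_id,
            "learning_afferent": learn_aff,
            "learning_lateral": learn_lat,
        },
    )


def _run_python(network, groups, stdp, *, n_steps, drive, dt_ms, leak,
                v_rest, v_reset, v_thresh, refr_steps, relay_gain, gain_aff,
                gain_le, gain_inh, learn_aff, learn_lat, a_pa, a_ma, a_pl, a_ml,
                tau_ltp, tau_ltd, window_ms, max_delay_steps,
                inh_mode):
    """Reference integrator mirroring the compiled kernel step by step."""
    n_lgn = network.n_lgn
    n_ctx = network.n_cortex
    v_lgn = np.full(n_lgn, v_rest)
    v_ctx = np.full(n_ctx, v_rest)
    refr_lgn = np.zeros(n_lgn, dtype=int)
    refr_ctx = np.zeros(n_ctx, dtype=int)
    depth = max_delay_steps + 1
    buf = np.zeros((depth, n_ctx))

    states = {
        Pathway.AFFERENT: PairingState.empty(n_lgn, n_ctx),
        Pathway.LATERAL_EXC: PairingState.empty(n_ctx, n_ctx),
        Pathway.LATERAL_INH: PairingState.empty(n_ctx, n_ctx),
    }

    lgn_t, lgn_id, ctx_t, ctx_id = [], [], [], []
    for t in range(n_steps):
        t_ms = t * dt_ms
        slot = t % depth

        active = refr_lgn == 0
        refr_lgn[~active] -= 1
        v_lgn[~active] = v_reset
        vp = v_lgn + leak * (v_rest - v_lgn) + relay_gain * drive[t]
        fired_lgn = active & (vp >= v_thresh)
        v_lgn = np.where(active, np.where(fired_lgn, v_reset, vp), v_lgn)
        refr_lgn[fired_lgn] = refr_steps
        lgn_now = np.nonzero(fired_lgn)[0]

        active = refr_ctx == 0
        refr_ctx[~active] -= 1
        v_ctx[~active] = v_reset
        vp = v_ctx + leak * (v_rest - v_ctx) + buf[slot]
        fired_ctx = active & (vp >= v_thresh)
        v_ctx = np.where(active, np.where(fired_ctx, v_reset, vp), v_ctx)
        refr_ctx[fired_ctx] = refr_steps
        ctx_now = np.nonzero(fired_ctx)[0]
        buf[slot] = 0.0

        for i in lgn_now:
            lgn_t.append(t)
            lgn_id.append(i)
        for j in ctx_now:
            ctx_t.append(t)
            ctx_id.append(j)

        # Accumulation order matches the compiled kernel exactly: afferent
        # volleys first, then per cortical spiker excitatory before
        # inhibitory, so both integrators are bit-identical.
        grp, dsteps, order_pre, indptr_pre, _, _ = groups[Pathway.AFFERENT]
        for i in lgn_now:
            for s in order_pre[indptr_pre[i]: indptr_pre[i + 1]]:
                buf[(t + dsteps[s]) % depth, grp.post[s]] += (
                    gain_aff * grp.weight[s]
                )
        le_grp, le_d, le_op, le_ip, _, _ = groups[Pathway.LATERAL_EXC]
        li_grp, li_d, li_op, li_ip, _, _ = groups[Pathway.LATERAL_INH]
        for j in ctx_now:
            for s in le_op[le_ip[j]: le_ip[j + 1]]:
                buf[(t + le_d[s]) % depth, le_grp.post[s]] += (
                    gain_le * le_grp.weight[s]
                )
            for s in li_op[li_ip[j]: li_ip[j + 1]]:
                buf[(t + li_d[s]) % depth, li_grp.post[s]] -= (
                    gain_inh * li_grp.weight[s]
                )

        for name, pre_spikers, post_spikers, flag, rates in (
            (Pathway.AFFERENT, lgn_now, ctx_now, learn_aff, (a_pa, a_ma)),
            (Pathway.LATERAL_EXC, ctx_now, ctx_now, learn_lat, (a_pl, a_ml)),
            (Pathway.LATERAL_INH, ctx_now, ctx_now, learn_lat, (a_pl, a_ml)),
        ):
            grp = groups[name][0]
            state = states[name]
            if not flag:
                state.last_pre[pre_spikers] = t_ms
                state.last_post[post_spikers] = t_ms
            elif name == Pathway.LATERAL_INH and inh_mode == 1:
                on_spike_anti_hebbian(
                    grp.weight, grp.pre, grp.post, state,
                    pre_spikers, post_spikers, t_ms, rates[0], rates[1],
                    stdp,
                )
            elif name == Pathway.LATERAL_INH and inh_mode == 2:
                on_spike_symmetric(
                    grp.weight, grp.pre, grp.post, state,
                    pre_spikers, post_spikers, t_ms, rates[0], stdp,
                )
            else:
                on_spike(
                    grp.weight, grp.pre, grp.post, state,
                    pre_spikers, post_spikers, t_ms, rates[0], rates[1],
                    stdp,
                )

    return (
        np.array(lgn_t, dtype=np.int64),
        np.array(lgn_id, dtype=np.int64),
        np.array(ctx_t, dtype=np.int64),
        np.array(ctx_id, dtype=np.int64),
    )
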