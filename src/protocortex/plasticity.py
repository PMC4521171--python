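"""Asymmetric STDP with additive LTP and multiplicative LTD.

The learning rule pairs pre- and postsynaptic spikes with
``dt = t_pre - t_post``:

* ``dt <= 0`` (pre before or with post, potentially causal) gives LTP with an
  exponential window, ``A_ltp * exp(dt / tau_ltp)``, applied **additively**.
* ``dt > 0`` (post first, anti-causal) gives LTD with an **alpha-function**
  window, ``A_ltd * (dt / tau_ltd) * exp(1 - dt / tau_ltd)``, whose magnitude
  peaks at exactly ``|A_ltd|`` when ``dt = tau_ltd`` and vanishes at
  ``dt -> 0+``; it is applied **multiplicatively**,
  ``w' = w * (1 + dw_ltd)``.

With ``tau_ltd`` (20 ms) longer than ``tau_ltp`` (11 ms) the depression lobe
is deeper and longer-lived than the potentiation lobe, and the LTD rates are
5% larger in magnitude than the LTP rates, so uncorrelated activity drifts
weights downward — stability without hard weight clipping or global
normalization.  The multiplicative LTD also keeps weights non-negative and
preserves zero weights.

Afferent (LGN->cortex) and lateral (cortex->cortex) pathways use separate
rates; spike pairing is nearest-neighbour (each spike pairs with the
partner's most recent spike) within ``pairing_window_ms``, and exact
``dt = 0`` ties are routed to LTP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "STDPParams",
    "ltp_magnitude",
    "ltd_magnitude",
    "apply_ltp",
    "apply_ltd",
    "on_spike",
    "on_spike_anti_hebbian",
    "on_spike_symmetric",
    "PairingState",
]


@dataclass(frozen=True)
class STDPParams:
    """Learning-rule parameters (rates dimensionless, taus in ms)."""

    a_ltp_afferent: float = 0.02
    a_ltp_lateral: float = 0.01
    ltd_ltp_ratio: float = 1.05  # |A_ltd| / A_ltp, slight LTD dominance
    tau_ltp_ms: float = 11.0
    tau_ltd_ms: float = 20.0
    pairing_window_ms: float = 50.0
    #: Pairing convention for inhibitory synapses: "hebbian" reuses the
    #: excitatory window as-is; "anti_hebbian" mirrors it (post-before-pre
    #: potentiates); "symmetric" potentiates near-coincident pairs in
    #: either order, a homeostatic rule that self-limits because stronger
    #: inhibition removes the very coincidences that drive it.
    inhibitory_stdp: str = "anti_hebbian"

    @property
    def a_ltd_afferent(self) -> float:
        return -self.ltd_ltp_ratio * self.a_ltp_afferent

    @property
    def a_ltd_lateral(self) -> float:
        return -self.ltd_ltp_ratio * self.a_ltp_lateral

    def __post_init__(self) -> None:
        if self.a_ltp_afferent <= 0 or self.a_ltp_lateral <= 0:
            raise ValueError("LTP rates must be > 0")
        if self.ltd_ltp_ratio <= 0:
            raise ValueError("ltd_ltp_ratio must be > 0")
        if self.tau_ltp_ms <= 0 or self.tau_ltd_ms <= 0:
            raise ValueError("STDP time constants must be > 0")
        if self.pairing_window_ms <= 0:
            raise ValueError("pairing_window_ms must be > 0")
        if self.inhibitory_stdp not in ("hebbian", "anti_hebbian",
                                        "symmetric"):
            raise ValueError(
                "inhibitory_stdp must be 'hebbian', 'anti_hebbian' or "
                f"'symmetric', got {self.inhibitory_stdp!r}"
            )

    def rates(self, pathway_is_afferent: bool) -> tuple[float, float]:
        if pathway_is_afferent:
            return self.a_ltp_afferent, self.a_ltd_afferent
        return self.a_ltp_lateral, self.a_ltd_lateral


def ltp_magnitude(delta_t_ms, a_ltp: float, tau_ltp_ms: float):
    """Potentiation for a causal pairing (``delta_t = t_pre - t_post <= 0``).

    Vectorized over ``delta_t_ms``.
    """
    dt = np.asarray(delta_t_ms, dtype=float)
    if np.any(dt > 0):
        raise ValueError(
            "ltp_magnitude requires delta_t <= 0 (pre fires before or with "
            "post); positive delta_t is an LTD event"
        )
    out = a_ltp * np.exp(dt / tau_ltp_ms)
    return out if out.ndim else float(out)


def ltd_magnitude(delta_t_ms, a_ltd: float, tau_ltd_ms: float):
    """Depression for an anti-causal pairing (``delta_t > 0``).

    Alpha-function window: zero at the origin, peak ``a_ltd`` (negative) at
    ``delta_t = tau_ltd``, decaying back to zero for large lags.
    """
    dt = np.asarray(delta_t_ms, dtype=float)
    if np.any(dt <= 0):
        raise ValueError(
            "ltd_magnitude requires delta_t > 0 (post fired before pre); "
            "non-positive delta_t is an LTP event"
        )
    x = dt / tau_ltd_ms
    out = a_ltd * x * np.exp(1.0 - x)
    return out if out.ndim else float(out)


def apply_ltp(w, delta_w_ltp):
    """Additive potentiation: ``w' = w + dw``; no hard upper cap."""
    w = np.asarray(w, dtype=float)
    dw = np.asarray(delta_w_ltp, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if np.any(dw < 0):
        raise ValueError("LTP weight change must be non-negative")
    out = w + dw
    return out if out.ndim else float(out)


def apply_ltd(w, delta_w_ltd):
    """Multiplicative depression: ``w' = w * (1 + dw)``, ``dw in (-1, 0]``.

    The multiplicative form cannot cross zero, so weights stay
    non-negative through any update sequence.
    """
    w = np.asarray(w, dtype=float)
    dw = np.asarray(delta_w_ltd, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if np.any(dw <= -1.0):
        raise ValueError(
            "LTD weight change must be in (-1, 0]; a value <= -1 would flip "
            "the weight's sign"
        )
    if np.any(dw > 0):
        raise ValueError("LTD weight change must be <= 0")
    out = w * (1.0 + dw)
    return out if out.ndim else float(out)


@dataclass
class PairingState:
    """Most recent spike time per neuron, for nearest-neighbour pairing.

    ``last_pre[i]`` / ``last_post[j]`` hold the latest spike times of the
    pre- and post-synaptic populations of one pathway (-inf when silent).
    """

    last_pre: np.ndarray
    last_post: np.ndarray

    @classmethod
    def empty(cls, n_pre: int, n_post: int) -> "PairingState":
        return cls(
            np.full(n_pre, -np.inf), np.full(n_post, -np.inf)
        )


def on_spike(
    weights: np.ndarray,
    syn_pre: np.ndarray,
    syn_post: np.ndarray,
    state: PairingState,
    spikers_pre: np.ndarray,
    spikers_post: np.ndarray,
    t_ms: float,
    a_ltp: float,
    a_ltd: float,
    params: STDPParams,
) -> None:
    """Apply one simulation step's worth of pairings for a single pathway.

    All neurons spiking at ``t_ms`` are registered first, then every plastic
    synapse incident on a spiker is updated: synapses onto a postsynaptic
    spiker potentiate against the presynaptic partner's latest spike
    (``dt <= 0``, ties included), synapses out of a presynaptic spiker
    depress against the postsynaptic partner's latest *earlier* spike
    (``dt > 0`` strictly, so a coincident pair is counted once, as LTP).
    Weights are modified in place.
    """
    state.last_pre[spikers_pre] = t_ms
    state.last_post[spikers_post] = t_ms

    if len(spikers_post):
        mask = np.isin(syn_post, spikers_post)
        idx = np.nonzero(mask)[0]
        dt = state.last_pre[syn_pre[idx]] - t_ms
        ok = dt >= -params.pairing_window_ms
        idx = idx[ok]
        if len(idx):
            weights[idx] = apply_ltp(
                weights[idx],
                ltp_magnitude(dt[ok], a_ltp, params.tau_ltp_ms),
            )
    if len(spikers_pre):
        mask = np.isin(syn_pre, spikers_pre)
        idx = np.nonzero(mask)[0]
        dt = t_ms - state.last_post[syn_post[idx]]
        ok = (dt > 0) & (dt <= params.pairing_window_ms)
        idx = idx[ok]
        if len(idx):
            weights[idx] = apply_ltd(
                weights[idx],
                ltd_magnitude(dt[ok], a_ltd, params.tau_ltd_ms),
            )


def on_spike_anti_hebbian(
    weights: np.ndarray,
    syn_pre: np.ndarray,
    syn_post: np.ndarray,
    state: PairingState,
    spikers_pre: np.ndarray,
    spikers_post: np.ndarray,
    t_ms: float,
    a_ltp: float,
    a_ltd: float,
    params: STDPParams,
) -> None:
    """Mirrored pairing rule for inhibitory synapses.

    Potentiation (additive, exponential window) when the postsynaptic
    neuron fired before or with the presynaptic one; depression
    (multiplicative, alpha window) when the presynaptic neuron fired
    first.  The magnitude formulas are those of :func:`ltp_magnitude` /
    :func:`ltd_magnitude` evaluated at the mirrored lag.
    """
    state.last_pre[spikers_pre] = t_ms
    state.last_post[spikers_post] = t_ms

    if len(spikers_pre):
        mask = np.isin(syn_pre, spikers_pre)
        idx = np.nonzero(mask)[0]
        lag = t_ms - state.last_post[syn_post[idx]]  # post-before-pre >= 0
        ok = (lag >= 0) & (lag <= params.pairing_window_ms)
        idx = idx[ok]
        if len(idx):
            weights[idx] = apply_ltp(
                weights[idx],
                ltp_magnitude(-lag[ok], a_ltp, params.tau_ltp_ms),
            )
    if len(spikers_post):
        mask = np.isin(syn_post, spikers_post)
        idx = np.nonzero(mask)[0]
        lag = t_ms - state.last_pre[syn_pre[idx]]  # pre-before-post
        ok = (lag > 0) & (lag <= params.pairing_window_ms)
        idx = idx[ok]
        if len(idx):
            weights[idx] = apply_ltd(
                weights[idx],
                ltd_magnitude(lag[ok], a_ltd, params.tau_ltd_ms),
            )


def on_spike_symmetric(
    weights: np.ndarray,
    syn_pre: np.ndarray,
    syn_post: np.ndarray,
    state: PairingState,
    spikers_pre: np.ndarray,
    spikers_post: np.ndarray,
    t_ms: float,
    a_ltp: float,
    params: STDPParams,
) -> None:
    """Symmetric-window rule for inhibitory synapses.

    Near-coincident pre/post pairings potentiate additively with
    ``a_ltp * exp(-|dt| / tau_ltp)`` regardless of order (ties counted
    once).  There is no timing-driven depression: the rule self-limits
    because potentiated inhibition suppresses the postsynaptic firing that
    feeds it.
    """
    state.last_pre[spikers_pre] = t_ms
    state.last_post[spikers_post] = t_ms

    if len(spikers_pre):
        mask = np.isin(syn_pre, spikers_pre)
        idx = np.nonzero(mask)[0]
        lag = t_ms - state.last_post[syn_post[idx]]
        ok = (lag >= 0) & (lag <= params.pairing_window_ms)
        idx = idx[ok]
        if len(idx):
            weights[idx] = apply_ltp(
                weights[idx],
                ltp_magnitude(-lag[ok], a_ltp, params.tau_ltp_ms),
            )
    if len(spikers_post):
        mask = np.isin(syn_post, spikers_post)
        idx = np.nonzero(mask)[0]
        lag = t_ms - state.last_pre[syn_pre[idx]]
        ok = (lag > 0) & (lag <= params.pairing_window_ms)
        idx = idx[ok]
        if len(idx):
            weights[idx] = apply_ltp(
                weights[idx],
                ltp_magnitude(-lag[ok], a_ltp, params.tau_ltp_ms),
            )
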