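"""Three-layer retino-cortical network topology.

The architecture models the early visual pathway as three sheets of spiking
neurons:

* **Input** (default 128x128) — relays address events one-to-one;
* **LGN** (default 32x32) — each unit pools a 4x4 block of input pixels
  through fixed, non-plastic weight-1 synapses (16:1 down-sampling);
* **Cortex** (default 60x60) — 80% excitatory / 20% inhibitory neurons,
  each receiving a retinotopic afferent connection field from the LGN and
  recurrently coupled through sparse lateral synapses in a Mexican-hat
  layout: presynaptic excitatory neurons project only within a short radius,
  inhibitory neurons within a much larger one.  Lateral conduction delay
  grows linearly with Euclidean grid distance.

This innate wiring (receptive fields + Mexican hat + distance-dependent
delays) is the "proto-architecture" that already carries a weak direction
bias before any learning.  Two lesions used to probe its necessity are
provided: replacing every afferent field with full LGN-cortex connectivity,
and truncating lateral inhibition beyond 8 grid units (shrinking the
inhibitory range from ~5x to 2x the excitatory radius).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "Pathway",
    "Lesion",
    "NetworkConfig",
    "SynapseGroup",
    "Network",
    "build_network",
    "apply_lesion",
]


class Pathway:
    """Synapse pathway tags."""

    INPUT_LGN = "input_lgn"
    AFFERENT = "afferent"
    LATERAL_EXC = "lateral_exc"
    LATERAL_INH = "lateral_inh"

    ALL = (INPUT_LGN, AFFERENT, LATERAL_EXC, LATERAL_INH)


class Lesion:
    """Connectivity lesion tags."""

    FULL_AFFERENT = "FULL_AFFERENT"
    SHORT_INHIBITION = "SHORT_INHIBITION"

    ALL = (FULL_AFFERENT, SHORT_INHIBITION)


@dataclass(frozen=True)
class NetworkConfig:
    """All structural parameters of the three-layer network.

    ``exc_radius``/``inh_radius`` default to 4 and 20 cortical grid units:
    the inhibitory range is ~5x the excitatory one, and the
    SHORT_INHIBITION lesion cutoff of 8 units brings it down to 2x.
    ``afferent_cf_radius`` is in LGN grid units around the cortical
    neuron's retinotopically scaled position (60 -> 32).
    """

    input_shape: tuple[int, int] = (128, 128)
    lgn_shape: tuple[int, int] = (32, 32)
    cortex_shape: tuple[int, int] = (60, 60)
    inhib_fraction: float = 0.20
    afferent_cf_radius: float = 4.0
    exc_radius: float = 4.0
    inh_radius: float = 20.0
    lateral_connection_prob: float = 0.3
    delay_per_unit_ms: float = 1.0
    afferent_delay_ms: float = 1.0
    init_weight_ranges: dict = field(
        default_factory=lambda: {
            Pathway.AFFERENT: (0.05, 0.35),
            Pathway.LATERAL_EXC: (0.0, 0.3),
            Pathway.LATERAL_INH: (0.0, 0.3),
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.inhib_fraction < 1.0:
            raise ValueError(
                f"inhib_fraction must be in (0, 1), got {self.inhib_fraction}"
            )
        if self.inh_radius <= self.exc_radius:
            raise ValueError(
                "inh_radius must exceed exc_radius (Mexican hat), got "
                f"inh_radius={self.inh_radius}, exc_radius={self.exc_radius}"
            )
        for name in ("afferent_cf_radius", "exc_radius", "inh_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.lateral_connection_prob <= 1.0:
            raise ValueError(
                "lateral_connection_prob must be in (0, 1], got "
                f"{self.lateral_connection_prob}"
            )
        if self.delay_per_unit_ms < 0 or self.afferent_delay_ms < 0:
            raise ValueError("delays must be >= 0")
        for pw, (lo, hi) in self.init_weight_ranges.items():
            if lo < 0 or hi < lo:
                raise ValueError(
                    f"init_weight_ranges[{pw!r}] must satisfy 0 <= lo <= hi, "
                    f"got ({lo}, {hi})"
                )
        ix, iy = self.input_shape
        lx, ly = self.lgn_shape
        if ix != 4 * lx or iy != 4 * ly:
            raise ValueError(
                "input_shape must be 4x the lgn_shape (4x4 pooling), got "
                f"input_shape={self.input_shape}, lgn_shape={self.lgn_shape}"
            )

    @property
    def n_input(self) -> int:
        return self.input_shape[0] * self.input_shape[1]

    @property
    def n_lgn(self) -> int:
        return self.lgn_shape[0] * self.lgn_shape[1]

    @property
    def n_cortex(self) -> int:
        return self.cortex_shape[0] * self.cortex_shape[1]


def grid_coords(ids: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Neuron ids -> (n, 2) array of (x, y); id = y * width + x."""
    ids = np.asarray(ids)
    w = shape[0]
    return np.stack([ids % w, ids // w], axis=-1).astype(float)


@dataclass
class SynapseGroup:
    """Flat synapse table for one pathway."""

    pre: np.ndarray
    post: np.ndarray
    weight: np.ndarray
    delay_ms: np.ndarray
    plastic: bool = True

    def __len__(self) -> int:
        return len(self.pre)

    def copy(self) -> "SynapseGroup":
        return SynapseGroup(
            self.pre.copy(),
            self.post.copy(),
            self.weight.copy(),
            self.delay_ms.copy(),
            self.plastic,
        )

    def by_pre(self, n_pre: int) -> tuple[np.ndarray, np.ndarray]:
        """(order, indptr): synapse indices grouped by presynaptic id."""
        order = np.argsort(self.pre, kind="stable")
        indptr = np.searchsorted(self.pre[order], np.arange(n_pre + 1))
        return order.astype(np.int64), indptr.astype(np.int64)

    def by_post(self, n_post: int) -> tuple[np.ndarray, np.ndarray]:
        order = np.argsort(self.post, kind="stable")
        indptr = np.searchsorted(self.post[order], np.arange(n_post + 1))
        return order.astype(np.int64), indptr.astype(np.int64)


@dataclass
class Network:
    """Topology + weights + lesion state of one model instance."""

    config: NetworkConfig
    is_inhibitory: np.ndarray  # (n_cortex,) bool
    pathways: dict[str, SynapseGroup]
    lesions: list[str] = field(default_factory=list)

    @property
    def n_cortex(self) -> int:
        return self.config.n_cortex

    @property
    def n_lgn(self) -> int:
        return self.config.n_lgn

    def copy(self) -> "Network":
        return Network(
            config=self.config,
            is_inhibitory=self.is_inhibitory.copy(),
            pathways={k: g.copy() for k, g in self.pathways.items()},
            lesions=list(self.lesions),
        )

    def weights_snapshot(self) -> dict[str, np.ndarray]:
        """Copies of the plastic weight vectors, keyed by pathway."""
        return {
            k: g.weight.copy()
            for k, g in self.pathways.items()
            if k != Pathway.INPUT_LGN
        }

    # ------------------------------------------------------------------
    # serialization
    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        cfg = self.config.__dict__.copy()
        cfg["input_shape"] = list(cfg["input_shape"])
        cfg["lgn_shape"] = list(cfg["lgn_shape"])
        cfg["cortex_shape"] = list(cfg["cortex_shape"])
        with h5py.File(path, "w") as fh:
            fh.attrs["config"] = json.dumps(cfg)
            fh.attrs["lesions"] = json.dumps(self.lesions)
            fh.create_dataset("is_inhibitory", data=self.is_inhibitory)
            for name, grp in self.pathways.items():
                g = fh.create_group(f"pathways/{name}")
                g.create_dataset("pre", data=grp.pre)
                g.create_dataset("post", data=grp.post)
                g.create_dataset("weight", data=grp.weight)
                g.create_dataset("delay_ms", data=grp.delay_ms)
                g.attrs["plastic"] = grp.plastic

    @classmethod
    def load(cls, path: str | Path) -> "Network":
        with h5py.File(path, "r") as fh:
            cfg = json.loads(fh.attrs["config"])
            cfg["input_shape"] = tuple(cfg["input_shape"])
            cfg["lgn_shape"] = tuple(cfg["lgn_shape"])
            cfg["cortex_shape"] = tuple(cfg["cortex_shape"])
            cfg["init_weight_ranges"] = {
                k: tuple(v) for k, v in cfg["init_weight_ranges"].items()
            }
            config = NetworkConfig(**cfg)
            lesions = json.loads(fh.attrs["lesions"])
            is_inh = fh["is_inhibitory"][:]
            pathways = {}
            for name in fh["pathways"]:
                g = fh[f"pathways/{name}"]
                pathways[name] = SynapseGroup(
                    pre=g["pre"][:],
                    post=g["post"][:],
                    weight=g["weight"][:],
                    delay_ms=g["delay_ms"][:],
                    plastic=bool(g.attrs["plastic"]),
                )
        return cls(config, is_inh, pathways, lesions)


def cortex_to_lgn_position(config: NetworkConfig) -> np.ndarray:
    """Retinotopic position of each cortical neuron in LGN coordinates."""
    pos = grid_coords(np.arange(config.n_cortex), config.cortex_shape)
    scale = np.array(
        [
            config.lgn_shape[0] / config.cortex_shape[0],
            config.lgn_shape[1] / config.cortex_shape[1],
        ]
    )
    return (pos + 0.5) * scale - 0.5


def _build_afferent(
    config: NetworkConfig, rng: np.random.Generator, full: bool = False
) -> SynapseGroup:
    lgn_pos = grid_coords(np.arange(config.n_lgn), config.lgn_shape)
    ctx_pos_lgn = cortex_to_lgn_position(config)
    if full:
        post, pre = np.meshgrid(
            np.arange(config.n_cortex),
            np.arange(config.n_lgn),
            indexing="ij",
        )
        pre = pre.ravel().astype(np.int32)
        post = post.ravel().astype(np.int32)
    else:
        d2 = (
            (ctx_pos_lgn[:, None, 0] - lgn_pos[None, :, 0]) ** 2
            + (ctx_pos_lgn[:, None, 1] - lgn_pos[None, :, 1]) ** 2
        )
        post, pre = np.nonzero(d2 <= config.afferent_cf_radius**2)
        pre = pre.astype(np.int32)
        post = post.astype(np.int32)
    lo, hi = config.init_weight_ranges[Pathway.AFFERENT]
    w = rng.uniform(lo, hi, size=len(pre))
    delays = np.full(len(pre), config.afferent_delay_ms)
    return SynapseGroup(pre, post, w, delays, plastic=True)


def _build_lateral(
    config: NetworkConfig,
    rng: np.random.Generator,
    is_inhibitory: np.ndarray,
) -> tuple[SynapseGroup, SynapseGroup]:
    n = config.n_cortex
    pos = grid_coords(np.arange(n), config.cortex_shape).astype(np.float32)
    d = np.sqrt(
        (pos[:, None, 0] - pos[None, :, 0]) ** 2
        + (pos[:, None, 1] - pos[None, :, 1]) ** 2
    )
    radius = np.where(
        is_inhibitory, config.inh_radius, config.exc_radius
    ).astype(np.float32)
    allowed = (d <= radius[:, None]) & (d > 0)  # open boundary, no self-loops
    sampled = allowed & (
        rng.random(size=d.shape) < config.lateral_connection_prob
    )
    pre, post = np.nonzero(sampled)
    pre = pre.astype(np.int32)
    post = post.astype(np.int32)
    dist = d[pre, post].astype(float)
    delays = np.maximum(config.delay_per_unit_ms * dist, 1e-9)

    groups = {}
    for name, mask in (
        (Pathway.LATERAL_EXC, ~is_inhibitory[pre]),
        (Pathway.LATERAL_INH, is_inhibitory[pre]),
    ):
        lo, hi = config.init_weight_ranges[name]
        w = rng.uniform(lo, hi, size=int(mask.sum()))
        groups[name] = SynapseGroup(
            pre[mask], post[mask], w, delays[mask], plastic=True
        )
    return groups[Pathway.LATERAL_EXC], groups[Pathway.LATERAL_INH]


def build_network(config: NetworkConfig) -> Network:
    """Construct the full three-layer network from a validated config.

    The random draws (inhibitory assignment, lateral sampling, initial
    weights) are all taken from a single generator seeded with
    ``config.seed``, so the same config reproduces an identical synapse
    table.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # Input -> LGN: fixed 4x4 pooling, weight 1.0, non-plastic.
    ids = np.arange(config.n_input, dtype=np.int32)
    px = ids % config.input_shape[0]
    py = ids // config.input_shape[0]
    lgn_id = (py // 4) * config.lgn_shape[0] + (px // 4)
    input_lgn = SynapseGroup(
        pre=ids,
        post=lgn_id.astype(np.int32),
        weight=np.ones(config.n_input),
        delay_ms=np.zeros(config.n_input),
        plastic=False,
    )

    n_inh = round(config.inhib_fraction * config.n_cortex)
    is_inh = np.zeros(config.n_cortex, dtype=bool)
    is_inh[rng.choice(config.n_cortex, size=n_inh, replace=False)] = True

    afferent = _build_afferent(config, rng)
    lat_exc, lat_inh = _build_lateral(config, rng, is_inh)

    return Network(
        config=config,
        is_inhibitory=is_inh,
        pathways={
            Pathway.INPUT_LGN: input_lgn,
            Pathway.AFFERENT: afferent,
            Pathway.LATERAL_EXC: lat_exc,
            Pathway.LATERAL_INH: lat_inh,
        },
    )


def apply_lesion(network: Network, lesion: str) -> Network:
    """Return a lesioned copy of an (untrained) network.

    ``FULL_AFFERENT`` discards the retinotopic connection fields and wires
    every cortical neuron to every LGN unit, with weights re-drawn from the
    afferent init range.  ``SHORT_INHIBITION`` deletes lateral inhibitory
    synapses spanning more than 8 cortical grid units.
    """
    if lesion not in Lesion.ALL:
        raise ValueError(
            f"unknown lesion {lesion!r}; valid lesions: {list(Lesion.ALL)}"
        )
    out = network.copy()
    cfg = out.config
    if lesion == Lesion.FULL_AFFERENT:
        # Re-seeded off the config seed so lesioned weights are reproducible
        # yet distinct from the intact draw.
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(997,))
        )
        out.pathways[Pathway.AFFERENT] = _build_afferent(cfg, rng, full=True)
    elif lesion == Lesion.SHORT_INHIBITION:
        grp = out.pathways[Pathway.LATERAL_INH]
        pos = grid_coords(np.arange(cfg.n_cortex), cfg.cortex_shape)
        dist = np.linalg.norm(pos[grp.pre] - pos[grp.post], axis=1)
        keep = dist <= 8.0
        out.pathways[Pathway.LATERAL_INH] = SynapseGroup(
            grp.pre[keep],
            grp.post[keep],
            grp.weight[keep],
            grp.delay_ms[keep],
            grp.plastic,
        )
    out.lesions.append(lesion)
    return out
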