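"""End-to-end training experiments.

An experiment takes freshly initialized (optionally lesioned) networks
through the training protocol: measure tuning with learning off, train with
randomly drawn moving-bar presentations (resetting the network between
patterns, weights carrying over), measure again at the midpoint and at the
end.  Variants:

* ``INTACT`` — all 8 directions, intact connectivity;
* ``DISRUPTED`` — all 8 directions, afferents fully connected and lateral
  inhibition truncated beyond 8 grid units;
* ``UNIDIR`` — training restricted to direction E (0 deg);
* ``BIDIR`` — E and W with an approximately equal number of presentations;
* ``ABLATE_AFFERENT`` / ``ABLATE_CORTICAL`` — uni-directional training with
  the afferent or the lateral (cortico-cortical) learning flag off.

Every random draw (network wiring, stimulus jitter, presentation order)
descends from the master seed, so a full run is reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import analysis
from .analysis import (
    ResponseTable,
    SelectivityMap,
    build_preference_map,
    measure_tuning,
)
from .dynamics import LIFParams, LearningFlags, run_presentation
from .network import Lesion, Network, NetworkConfig, apply_lesion, build_network
from .plasticity import STDPParams
from .stimulus import BarSpec, COMPASS, generate_bar_stream, make_stimulus_set

__all__ = [
    "EXPERIMENTS",
    "STAGES",
    "ExperimentConfig",
    "NetworkResult",
    "ExperimentReport",
    "ablate_plasticity",
    "run_experiment",
]

EXPERIMENTS = (
    "INTACT",
    "DISRUPTED",
    "UNIDIR",
    "BIDIR",
    "ABLATE_AFFERENT",
    "ABLATE_CORTICAL",
)

STAGES = ("initial", "mid", "final")

_ALL_DIRECTIONS = tuple(sorted(COMPASS.values()))

_PRESETS: dict[str, dict] = {
    "INTACT": {},
    "DISRUPTED": {
        "lesions": [Lesion.FULL_AFFERENT, Lesion.SHORT_INHIBITION],
        "n_networks": 5,
    },
    "UNIDIR": {"train_directions": [0.0]},
    "BIDIR": {"train_directions": [0.0, 180.0]},
    "ABLATE_AFFERENT": {
        "train_directions": [0.0], "plasticity_afferent": False,
    },
    "ABLATE_CORTICAL": {
        "train_directions": [0.0], "plasticity_lateral": False,
    },
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Complete, serializable description of one experiment."""

    experiment: str = "INTACT"
    n_networks: int = 10
    n_presentations: int = 50
    midpoint: int = 25
    train_directions: tuple[float, ...] = _ALL_DIRECTIONS
    lesions: tuple[str, ...] = ()
    n_instances: int = 10
    probe_instances: int = 1
    plasticity_afferent: bool = True
    plasticity_lateral: bool = True
    bar: BarSpec = field(default_factory=BarSpec)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    lif: LIFParams = field(default_factory=LIFParams)
    stdp: STDPParams = field(default_factory=STDPParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; "
                f"valid: {EXPERIMENTS}"
            )
        if self.n_presentations < 0:
            raise ValueError("n_presentations must be >= 0")
        if not 0 <= self.midpoint <= self.n_presentations:
            raise ValueError("midpoint must lie within the training run")
        if self.n_networks < 1:
            raise ValueError("n_networks must be >= 1")
        bad = set(self.train_directions) - set(_ALL_DIRECTIONS)
        if bad:
            raise ValueError(f"invalid training directions {sorted(bad)}")
        if self.experiment == "UNIDIR" and tuple(self.train_directions) != (
            0.0,
        ):
            raise ValueError("UNIDIR trains only direction E (0 deg)")

    @classmethod
    def preset(cls, experiment: str, **overrides) -> "ExperimentConfig":
        """Config for a named experiment with its protocol defaults."""
        if experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {experiment!r}; valid: {EXPERIMENTS}"
            )
        kw = dict(_PRESETS[experiment])
        kw.update(overrides)
        kw.setdefault("experiment", experiment)
        if "train_directions" in kw:
            kw["train_directions"] = tuple(kw["train_directions"])
        if "lesions" in kw:
            kw["lesions"] = tuple(kw["lesions"])
        return cls(**kw)

    # ---------------- YAML round trip ----------------
    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["network"]["input_shape"] = list(self.network.input_shape)
        d["network"]["lgn_shape"] = list(self.network.lgn_shape)
        d["network"]["cortex_shape"] = list(self.network.cortex_shape)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        d = yaml.safe_load(Path(path).read_text())
        net = d.get("network", {})
        for key in ("input_shape", "lgn_shape", "cortex_shape"):
            if key in net:
                net[key] = tuple(net[key])
        if "init_weight_ranges" in net:
            net["init_weight_ranges"] = {
                k: tuple(v) for k, v in net["init_weight_ranges"].items()
            }
        d["network"] = NetworkConfig(**net)
        d["bar"] = BarSpec(**d.get("bar", {}))
        d["lif"] = LIFParams(**d.get("lif", {}))
        d["stdp"] = STDPParams(**d.get("stdp", {}))
        for key in ("train_directions", "lesions"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def ablate_plasticity(config: ExperimentConfig, pathway: str) -> ExperimentConfig:
    """Switch one pathway's learning flag off; everything else unchanged."""
    if pathway == "afferent":
        return replace(config, plasticity_afferent=False)
    if pathway == "lateral":
        return replace(config, plasticity_lateral=False)
    raise ValueError(
        f"unknown pathway {pathway!r}; valid pathways: 'afferent', 'lateral'"
    )


def _child_seed(master: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=master, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def presentation_schedule(
    config: ExperimentConfig, rng: np.random.Generator
) -> list[tuple[float, int]]:
    """Random (direction, instance) sequence for one network's training.

    For bi-directional training the two directions get an equal share
    (within one presentation) in shuffled order; otherwise directions are
    drawn uniformly at random, as are instances.
    """
    n = config.n_presentations
    dirs = list(config.train_directions)
    if config.experiment == "BIDIR" and len(dirs) == 2:
        half = n // 2
        seq = [dirs[0]] * (n - half) + [dirs[1]] * half
        directions = rng.permutation(np.array(seq))
    else:
        directions = rng.choice(np.array(dirs), size=n)
    instances = rng.integers(0, config.n_instances, size=n)
    return [(float(d), int(i)) for d, i in zip(directions, instances)]


def make_test_set(config: ExperimentConfig) -> list:
    """Fixed noise-free probe set, identical at every measurement stage.

    With ``probe_instances == 1`` the single probe per direction is also
    jitter-free; with more, each extra instance carries its own jitter draw
    (seeded independently of the training set) and per-direction responses
    are averaged over them, which smooths the spike-count quantization of
    single sweeps.
    """
    out = []
    for d_idx, d in enumerate(_ALL_DIRECTIONS):
        for inst in range(config.probe_instances):
            jitter = 0.0 if inst == 0 else config.bar.jitter
            probe_bar = replace(config.bar, jitter=jitter, noise_rate=0.0)
            child = np.random.SeedSequence(
                entropy=9000, spawn_key=(d_idx, inst)
            )
            out.append(
                generate_bar_stream(d, probe_bar, instance_id=inst,
                                    seed=child)
            )
    return out


@dataclass
class NetworkResult:
    """Everything retained from one network's run."""

    network_seed: int
    tables: dict[str, ResponseTable]
    maps: dict[str, dict[str, SelectivityMap]]
    initial_weights: dict[str, np.ndarray]
    network_initial: Network
    network_final: Network
    presentation_log: list[dict]

    def stage_si(self, stage: str, mode: str = "DS") -> np.ndarray:
        """SI values of responsive neurons at a stage."""
        m = self.maps[stage][mode]
        return m.si[m.responsive]


@dataclass
class ExperimentReport:
    """Aggregated results across an experiment's networks."""

    config: ExperimentConfig
    networks: list[NetworkResult]

    def pooled_si(self, stage: str, mode: str = "DS") -> np.ndarray:
        """SI of all responsive neurons pooled over networks."""
        return np.concatenate(
            [nr.stage_si(stage, mode) for nr in self.networks]
        )

    def mean_si(self, stage: str, mode: str = "DS") -> float:
        return float(self.pooled_si(stage, mode).mean())

    def cumulative(self, stage: str, mode: str = "DS", n_bins: int = 20):
        return analysis.cumulative_curve(
            self.pooled_si(stage, mode), n_bins=n_bins
        )

    def aligned_mean(self, stage: str) -> np.ndarray:
        """Mean sum-normalized tuning curve, peak aligned at 0 deg."""
        rows = []
        for nr in self.networks:
            prev = None
            if stage != "initial":
                prev = nr.maps["initial"]["DS"].preferred_deg
            aligned, _ = analysis.align_tuning(nr.tables[stage], prev)
            rows.append(aligned)
        return np.concatenate(rows).mean(axis=0)

    def tuning_fit(self, stage: str):
        return analysis.fit_double_gaussian(self.aligned_mean(stage))

    def converted_count(
        self, direction_deg: float, stage: str = "final",
        tol_deg: float = 5.0,
    ) -> int:
        """Total neurons preferring the direction (within tol), all networks."""
        return sum(
            analysis.count_converted(
                nr.maps["initial"]["DS"], nr.maps[stage]["DS"],
                direction_deg, tol_deg,
            )
            for nr in self.networks
        )

    def direction_group_si(
        self, direction_deg: float, stage: str = "final",
        tol_deg: float = 5.0, mode: str = "DS",
    ) -> tuple[np.ndarray, np.ndarray]:
        """Split responsive neurons' SI by final preference for a direction.

        Returns ``(si_toward, si_others)`` pooled over networks, where
        membership means the stage preference lies within ``tol_deg``
        (circular) of ``direction_deg``.
        """
        toward, others = [], []
        for nr in self.networks:
            m = nr.maps[stage][mode]
            ok = m.responsive & np.isfinite(m.preferred_deg)
            period = 360.0 if mode == "DS" else 180.0
            d = np.abs(
                analysis._circ_diff(m.preferred_deg, direction_deg, period)
            )
            toward.append(m.si[ok & (d <= tol_deg)])
            others.append(m.si[ok & (d > tol_deg)])
        return np.concatenate(toward), np.concatenate(others)

    def summary(self) -> dict:
        """JSON-serializable headline numbers."""
        out = {
            "experiment": self.config.experiment,
            "n_networks": len(self.networks),
            "n_presentations": self.config.n_presentations,
            "mean_si": {},
        }
        for stage in STAGES:
            out["mean_si"][stage] = {
                "DS": self.mean_si(stage, "DS"),
                "OR": self.mean_si(stage, "OR"),
            }
        return out

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "summary.json").write_text(
            json.dumps(self.summary(), indent=2)
        )
        for i, nr in enumerate(self.networks):
            d = out_dir / f"network_{i:02d}"
            d.mkdir(exist_ok=True)
            for stage, table in nr.tables.items():
                table.to_csv(d / f"responses_{stage}.csv")
                for mode in ("DS", "OR"):
                    nr.maps[stage][mode].to_csv(
                        d / f"map_{stage}_{mode.lower()}.csv"
                    )
            (d / "presentations.json").write_text(
                json.dumps(nr.presentation_log, indent=1)
            )


def _run_one_network(
    config: ExperimentConfig,
    net_index: int,
    training_streams: dict,
    test_set: list,
    engine: str,
) -> NetworkResult:
    net_seed = _child_seed(config.seed, 1, net_index)
    net = build_network(replace(config.network, seed=net_seed))
    for lesion in config.lesions:
        net = apply_lesion(net, lesion)
    network_initial = net.copy()

    flags = LearningFlags(
        afferent=config.plasticity_afferent,
        lateral=config.plasticity_lateral,
    )
    sched_rng = np.random.default_rng(_child_seed(config.seed, 2, net_index))
    schedule = presentation_schedule(config, sched_rng)

    tables: dict[str, ResponseTable] = {}
    maps: dict[str, dict[str, SelectivityMap]] = {}

    def measure(stage: str) -> None:
        table = measure_tuning(net, test_set, lif=config.lif, engine=engine)
        table.meta.update({"stage": stage, "network": net_index})
        tables[stage] = table
        maps[stage] = {
            mode: build_preference_map(
                table, mode, grid_shape=config.network.cortex_shape
            )
            for mode in ("DS", "OR")
        }

    log: list[dict] = []
    measure("initial")
    for k, (direction, instance) in enumerate(schedule):
        stream = training_streams[(direction, instance)]
        rec = run_presentation(
            net, stream, learning=flags, lif=config.lif, stdp=config.stdp,
            engine=engine,
        )
        log.append({
            "presentation": k,
            "direction_deg": direction,
            "instance": instance,
            "cortex_spikes": int(len(rec.cortex_ids)),
        })
        if k + 1 == config.midpoint:
            measure("mid")
    if "mid" not in tables:  # midpoint at 0 or beyond the run
        measure("mid")
    measure("final")

    return NetworkResult(
        network_seed=net_seed,
        tables=tables,
        maps=maps,
        initial_weights=network_initial.weights_snapshot(),
        network_initial=network_initial,
        network_final=net,
        presentation_log=log,
    )


def run_experiment(
    config: ExperimentConfig,
    out_dir: str | Path | None = None,
    engine: str = "auto",
    progress: bool = False,
) -> ExperimentReport:
    """Run all networks of an experiment and aggregate the results.

    When ``out_dir`` is given, per-network checkpoints
    (``checkpoint_net<i>.h5`` plus response tables) are written as each
    network finishes, and an interrupted run picks up from the last
    completed network.
    """
    stim_seed = _child_seed(config.seed, 0)
    streams = make_stimulus_set(config.bar, config.n_instances, seed=stim_seed)
    training_streams = {
        (s.direction_deg, s.instance_id): s for s in streams
    }
    test_set = make_test_set(config)

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    results = []
    for i in range(config.n_networks):
        ckpt = (
            out_path / f"checkpoint_net{i:02d}.npz" if out_path else None
        )
        if ckpt is not None and ckpt.exists():
            results.append(_load_checkpoint(config, i, ckpt))
            continue
        nr = _run_one_network(config, i, training_streams, test_set, engine)
        results.append(nr)
        if ckpt is not None:
            _save_checkpoint(nr, ckpt)
        if progress:
            print(
                f"[{config.experiment}] network {i + 1}/{config.n_networks} "
                f"done; final mean DS SI = "
                f"{np.mean(nr.stage_si('final', 'DS')):.3f}"
            )

    report = ExperimentReport(config=config, networks=results)
    if out_path is not None:
        report.save(out_path)
    return report


def _save_checkpoint(nr: NetworkResult, path: Path) -> None:
    arrays = {"network_seed": np.array(nr.network_seed)}
    for stage, table in nr.tables.items():
        arrays[f"counts_{stage}"] = table.counts
    for pw, w in nr.initial_weights.items():
        arrays[f"w0_{pw}"] = w
    arrays["log"] = np.frombuffer(
        json.dumps(nr.presentation_log).encode(), dtype=np.uint8
    )
    np.savez_compressed(path, **arrays)
    nr.network_initial.save(path.with_suffix(".initial.h5"))
    nr.network_final.save(path.with_suffix(".final.h5"))


def _load_checkpoint(
    config: ExperimentConfig, net_index: int, path: Path
) -> NetworkResult:
    data = np.load(path)
    tables = {}
    maps = {}
    for stage in STAGES:
        table = ResponseTable(counts=data[f"counts_{stage}"])
        table.meta.update({"stage": stage, "network": net_index})
        tables[stage] = table
        maps[stage] = {
            mode: build_preference_map(
                table, mode, grid_shape=config.network.cortex_shape
            )
            for mode in ("DS", "OR")
        }
    initial_weights = {
        k[len("w0_"):]: data[k] for k in data.files if k.startswith("w0_")
    }
    log = json.loads(bytes(data["log"]).decode())
    return NetworkResult(
        network_seed=int(data["network_seed"]),
        tables=tables,
        maps=maps,
        initial_weights=initial_weights,
        network_initial=Network.load(path.with_suffix(".initial.h5")),
        network_final=Network.load(path.with_suffix(".final.h5")),
        presentation_log=log,
    )
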