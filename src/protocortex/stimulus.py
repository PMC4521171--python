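"""Synthetic DVS-style event streams of a moving bar.

A dynamic vision sensor (DVS) emits an address event -- pixel coordinates,
polarity, timestamp -- whenever the luminance at that pixel changes.  A bright
bar sweeping over a dark background therefore produces an ON event where its
leading edge crosses a pixel and an OFF event where its trailing edge leaves
it.  This module generates such streams analytically for a rigid bar moving at
constant speed in one of the eight compass directions across a 128x128 pixel
array, with optional per-instance jitter (speed and start-time perturbation)
and a Poisson background of spurious events.

Angle convention: 0 deg = E (motion towards increasing x), angles increase
counter-clockwise, so N = 90 deg means motion towards increasing y.

The on-disk format is a plain-text columnar file: ``#key=value`` header lines
(direction, instance, duration) followed by one ``t_ms x y polarity`` row per
event.  See :func:`write_events` / :func:`read_events`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "GRID_SIZE",
    "COMPASS",
    "DIRECTION_TOKENS",
    "BarSpec",
    "EventStream",
    "generate_bar_stream",
    "make_stimulus_set",
    "write_events",
    "read_events",
]

GRID_SIZE = 128

#: Compass token -> direction of motion in degrees (E = 0, counter-clockwise).
COMPASS = {
    "E": 0.0,
    "NE": 45.0,
    "N": 90.0,
    "NW": 135.0,
    "W": 180.0,
    "SW": 225.0,
    "S": 270.0,
    "SE": 315.0,
}

#: Degrees -> compass token.
DIRECTION_TOKENS = {v: k for k, v in COMPASS.items()}

#: Structured dtype of an event record: time (ms), pixel column, pixel row,
#: polarity (1 = ON / leading edge, 0 = OFF / trailing edge).
EVENT_DTYPE = np.dtype(
    [("t", "f8"), ("x", "i2"), ("y", "i2"), ("polarity", "i1")]
)

@dataclass(frozen=True)
class BarSpec:
    """Geometry and kinematics of the moving-bar stimulus.

    Parameters
    ----------
    length_px
        Bar extent perpendicular to the motion axis, in pixels.  The
        default exceeds the array diagonal (128 * sqrt(2) ~ 181 px) so the
        bar covers every pixel for every direction, including diagonals;
        shorter bars leave corner regions unstimulated on diagonal sweeps,
        which imprints a spurious orientation bias on the map.
    width_px
        Bar thickness along the motion axis, in pixels.
    speed_px_per_ms
        Traversal speed.  With the default 0.5 px/ms a cardinal sweep of the
        full array lasts ~260 ms.
    jitter
        Per-instance perturbation scale: the speed is multiplied by a factor
        drawn uniformly from ``[1 - jitter, 1 + jitter]`` and the sweep start
        is delayed by up to ``jitter * 128`` px of travel.
    noise_rate
        Spurious (background) events per millisecond over the whole array,
        drawn from a Poisson process with uniform pixel position and random
        polarity.  The default of 10 events/ms corresponds to ~0.6 Hz of
        background activity per pixel, in the range reported for DVS
        sensors.
    """

    length_px: float = 182.0
    width_px: float = 4.0
    speed_px_per_ms: float = 0.5
    jitter: float = 0.05
    noise_rate: float = 10.0

    def __post_init__(self) -> None:
        if self.length_px < 1:
            raise ValueError(f"length_px must be >= 1, got {self.length_px}")
        if self.width_px < 1:
            raise ValueError(f"width_px must be >= 1, got {self.width_px}")
        if self.speed_px_per_ms <= 0:
            raise ValueError(
                f"speed_px_per_ms must be > 0, got {self.speed_px_per_ms}"
            )
        if self.jitter < 0:
            raise ValueError(f"jitter must be >= 0, got {self.jitter}")
        if self.noise_rate < 0:
            raise ValueError(f"noise_rate must be >= 0, got {self.noise_rate}")


@dataclass
class EventStream:
    """An ordered sequence of address events with a direction label."""

    events: np.ndarray
    direction_deg: float
    instance_id: int = 0
    duration_ms: float = 0.0

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=EVENT_DTYPE)
        if self.direction_deg not in DIRECTION_TOKENS:
            raise ValueError(
                f"direction_deg must be one of {sorted(DIRECTION_TOKENS)} "
                f"(8-point compass), got {self.direction_deg}"
            )
        if len(self.events):
            if self.events["t"].min() < 0:
                raise ValueError("event timestamps must be non-negative")
            if self.duration_ms < self.events["t"].max():
                raise ValueError("duration_ms must cover the last event")

    @property
    def direction_token(self) -> str:
        return DIRECTION_TOKENS[self.direction_deg]

    def __len__(self) -> int:
        return len(self.events)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventStream):
            return NotImplemented
        return (
            self.direction_deg == other.direction_deg
            and self.instance_id == other.instance_id
            and math.isclose(self.duration_ms, other.duration_ms)
            and len(self.events) == len(other.events)
            and bool(np.all(self.events == other.events))
        )


def _sort_events(events: np.ndarray) -> np.ndarray:
    """Order by time, breaking ties by (y, x, polarity)."""
    order = np.lexsort(
        (events["polarity"], events["x"], events["y"], events["t"])
    )
    return events[order]


def _validate_direction(direction_deg: float) -> float:
    if direction_deg not in DIRECTION_TOKENS:
        valid = ", ".join(
            f"{int(d)} ({tok})" for tok, d in COMPASS.items()
        )
        raise ValueError(
            f"direction {direction_deg!r} is not an 8-point compass "
            f"direction; valid values (degrees) are: {valid}"
        )
    return float(direction_deg)


def generate_bar_stream(
    direction_deg: float,
    bar: BarSpec = BarSpec(),
    instance_id: int = 0,
    seed: int | np.random.SeedSequence = 0,
) -> EventStream:
    """Generate one sweep of the bar across the array.

    The bar is treated as a rigid rectangle of perpendicular extent
    ``length_px`` centred on the array midline, moving along the unit vector
    of ``direction_deg``.  For every pixel centre inside the bar's
    perpendicular extent, the leading-edge crossing time yields an ON event
    and the trailing-edge crossing an OFF event; times are computed
    analytically and rounded to 0.1 ms.  ``seed`` fixes the jitter draw and
    the noise events, so identical ``(direction, bar, instance_id, seed)``
    reproduce a byte-identical stream.
    """
    direction_deg = _validate_direction(direction_deg)
    rng = np.random.default_rng(seed)

    theta = math.radians(direction_deg)
    ux, uy = math.cos(theta), math.sin(theta)

    # Pixel centres projected on the motion axis (s) and perpendicular (q).
    xs, ys = np.meshgrid(
        np.arange(GRID_SIZE, dtype=float),
        np.arange(GRID_SIZE, dtype=float),
        indexing="xy",
    )
    s = xs * ux + ys * uy
    q = -xs * uy + ys * ux
    centre = (GRID_SIZE - 1) / 2.0
    q_centre = -centre * uy + centre * ux

    covered = np.abs(q - q_centre) <= bar.length_px / 2.0
    s_cov = s[covered]
    x_cov = xs[covered].astype(np.int16)
    y_cov = ys[covered].astype(np.int16)

    # Per-instance jitter: multiplicative speed factor and a start delay.
    speed = bar.speed_px_per_ms
    offset_px = 0.0
    if bar.jitter > 0:
        speed = speed * (1.0 + bar.jitter * rng.uniform(-1.0, 1.0))
        offset_px = bar.jitter * GRID_SIZE * rng.uniform(0.0, 1.0)

    s0 = s_cov.min() - offset_px  # leading edge position at t = 0
    t_on = (s_cov - s0) / speed
    t_off = t_on + bar.width_px / speed
    # decimal rounding so timestamps survive the "%.1f" text round trip
    t_on = np.round(t_on, 1)
    t_off = np.round(t_off, 1)

    n = len(s_cov)
    bar_events = np.empty(2 * n, dtype=EVENT_DTYPE)
    bar_events["t"][:n] = t_on
    bar_events["t"][n:] = t_off
    bar_events["x"][:n] = x_cov
    bar_events["x"][n:] = x_cov
    bar_events["y"][:n] = y_cov
    bar_events["y"][n:] = y_cov
    bar_events["polarity"][:n] = 1
    bar_events["polarity"][n:] = 0

    duration = float(np.ceil(bar_events["t"].max() + 1.0))

    if bar.noise_rate > 0:
        n_noise = rng.poisson(bar.noise_rate * duration)
        noise = np.empty(n_noise, dtype=EVENT_DTYPE)
        noise["t"] = np.round(rng.uniform(0.0, duration, n_noise), 1)
        noise["x"] = rng.integers(0, GRID_SIZE, n_noise)
        noise["y"] = rng.integers(0, GRID_SIZE, n_noise)
        noise["polarity"] = rng.integers(0, 2, n_noise)
        bar_events = np.concatenate([bar_events, noise])

    return EventStream(
        events=_sort_events(bar_events),
        direction_deg=direction_deg,
        instance_id=instance_id,
        duration_ms=duration,
    )


def make_stimulus_set(
    bar: BarSpec = BarSpec(),
    n_instances_per_direction: int = 10,
    seed: int = 0,
) -> list[EventStream]:
    """Generate ``8 x n`` streams covering every compass direction.

    Each (direction, instance) pair gets its own child seed derived from the
    master seed, so any single stream can be regenerated independently of the
    others.
    """
    if n_instances_per_direction < 1:
        raise ValueError(
            "n_instances_per_direction must be >= 1, "
            f"got {n_instances_per_direction}"
        )
    streams = []
    for d_idx, token in enumerate(sorted(COMPASS, key=COMPASS.get)):
        for inst in range(n_instances_per_direction):
            child = np.random.SeedSequence(
                entropy=seed, spawn_key=(d_idx, inst)
            )
            streams.append(
                generate_bar_stream(
                    COMPASS[token], bar, instance_id=inst, seed=child
                )
            )
    return streams


_POL_TOKEN = {1: "ON", 0: "OFF"}
_POL_VALUE = {"ON": 1, "OFF": 0}


def write_events(stream: EventStream, path: str | Path) -> None:
    """Serialize a stream to the columnar text format (lossless)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#direction={stream.direction_token}\n")
        fh.write(f"#instance={stream.instance_id}\n")
        fh.write(f"#duration_ms={stream.duration_ms!r}\n")
        for ev in stream.events:
            fh.write(
                f"{ev['t']:.1f} {ev['x']} {ev['y']} "
                f"{_POL_TOKEN[int(ev['polarity'])]}\n"
            )


def read_events(path: str | Path) -> EventStream:
    """Read a stream written by :func:`write_events`.

    Raises ``ValueError`` naming the offending line for malformed rows, and
    for missing or unknown header fields.
    """
    path = Path(path)
    header: dict[str, str] = {}
    rows = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" not in line:
                    raise ValueError(
                        f"{path}:{lineno}: malformed header line {line!r}"
                    )
                key, _, value = line[1:].partition("=")
                header[key.strip()] = value.strip()
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 't_ms x y polarity', "
                    f"got {line!r}"
                )
            try:
                t = float(parts[0])
                x = int(parts[1])
                y = int(parts[2])
                pol = _POL_VALUE[parts[3]]
            except (ValueError, KeyError) as exc:
                raise ValueError(
                    f"{path}:{lineno}: malformed event row {line!r}"
                ) from exc
            rows.append((t, x, y, pol))

    for key in ("direction", "instance", "duration_ms"):
        if key not in header:
            raise ValueError(f"{path}: missing required header '#{key}='")
    token = header["direction"]
    if token not in COMPASS:
        raise ValueError(
            f"{path}: unknown direction token {token!r}; "
            f"valid tokens: {sorted(COMPASS)}"
        )
    events = np.array(rows, dtype=EVENT_DTYPE) if rows else np.empty(
        0, dtype=EVENT_DTYPE
    )
    return EventStream(
        events=events,
        direction_deg=COMPASS[token],
        instance_id=int(header["instance"]),
        duration_ms=float(header["duration_ms"]),
    )
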