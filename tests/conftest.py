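"""Shared fixtures: desk-scale networks and hand-built event streams.

Unit tests run on a reduced copy of the architecture (32x32 input, 8x8
relay, 10x10 cortex) so a presentation takes milliseconds; the full-size
geometry is exercised only by the slow end-to-end tests.
"""

import numpy as np
import pytest

from protocortex.network import NetworkConfig, build_network
from protocortex.stimulus import EVENT_DTYPE, EventStream


TINY_SHAPES = dict(
    input_shape=(32, 32),
    lgn_shape=(8, 8),
    cortex_shape=(10, 10),
    afferent_cf_radius=2.0,
    exc_radius=2.0,
    inh_radius=5.0,
    lateral_connection_prob=0.5,
)


@pytest.fixture
def tiny_config():
    return NetworkConfig(seed=7, **TINY_SHAPES)


@pytest.fixture
def tiny_network(tiny_config):
    return build_network(tiny_config)


def make_sweep_stream(direction_deg=0.0, grid=32, band=None, speed=0.5):
    """Hand-built leading/trailing-edge sweep over a small grid.

    Only cardinal E/W are needed by the unit tests; events carry both
    polarities like the generated streams.
    """
    ys = np.arange(grid) if band is None else np.arange(*band)
    xs = np.arange(grid)
    X, Y = np.meshgrid(xs, ys, indexing="xy")
    n = X.size
    ev = np.empty(2 * n, dtype=EVENT_DTYPE)
    if direction_deg == 0.0:
        t_on = X.ravel() / speed
    elif direction_deg == 180.0:
        t_on = (grid - 1 - X.ravel()) / speed
    else:
        raise ValueError("only E/W sweeps supported here")
    ev["t"][:n] = t_on
    ev["t"][n:] = t_on + 4.0 / speed
    ev["x"][:n] = X.ravel()
    ev["x"][n:] = X.ravel()
    ev["y"][:n] = Y.ravel()
    ev["y"][n:] = Y.ravel()
    ev["polarity"][:n] = 1
    ev["polarity"][n:] = 0
    order = np.lexsort((ev["polarity"], ev["x"], ev["y"], ev["t"]))
    ev = ev[order]
    return EventStream(
        events=ev,
        direction_deg=direction_deg,
        instance_id=0,
        duration_ms=float(np.ceil(ev["t"].max() + 1)),
    )


@pytest.fixture
def tiny_stream():
    return make_sweep_stream(0.0)


@pytest.fixture
def tiny_stream_w():
    return make_sweep_stream(180.0)
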