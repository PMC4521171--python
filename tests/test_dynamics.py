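"""LIF integration, presentation contracts, and engine cross-validation."""

import math

import numpy as np
import pytest

from protocortex.dynamics import (
    LIFParams,
    LearningFlags,
    lif_step,
    reset_network,
    run_presentation,
)
from protocortex.network import Pathway
from protocortex.plasticity import STDPParams
from protocortex.stimulus import EVENT_DTYPE, EventStream

from conftest import make_sweep_stream

OFF = LearningFlags(afferent=False, lateral=False)
ON = LearningFlags(afferent=True, lateral=True)


class TestLifStep:
    def test_rest_is_fixed_point(self):
        p = LIFParams()
        v, fired = lif_step(p.v_rest, 0.0, p)
        assert v == p.v_rest and not fired

    def test_threshold_crossing_resets(self):
        p = LIFParams()
        v, fired = lif_step(p.v_rest, 2.0 * p.v_thresh, p)
        assert fired and v == p.v_reset

    def test_constant_drive_gives_periodic_firing(self):
        p = LIFParams()
        refr_steps = int(p.refractory_ms / p.dt_ms)
        v, refr, times = p.v_rest, 0, []
        for t in range(100):
            if refr > 0:
                refr -= 1
                continue
            v, fired = lif_step(v, 0.6, p)
            if fired:
                times.append(t)
                refr = refr_steps
        isis = np.diff(times)
        assert len(times) > 3
        assert (isis >= refr_steps + 1).all()
        assert len(set(isis)) == 1

    def test_free_decay_matches_exponential(self):
        # discrete leak tracks e^{-t/tau} within O(dt/tau) per step
        p = LIFParams(tau_m_ms=10.0, dt_ms=1.0)
        v = 0.9
        for t in range(1, 31):
            v, fired = lif_step(v, 0.0, p)
            assert not fired
            exact = 0.9 * math.exp(-t * p.dt_ms / p.tau_m_ms)
            assert abs(v - exact) <= 0.9 * t * (p.dt_ms / p.tau_m_ms) ** 2


class TestPresentationContracts:
    def test_empty_stream_is_silent(self, tiny_network):
        s = EventStream(
            events=np.empty(0, dtype=EVENT_DTYPE),
            direction_deg=0.0, duration_ms=50.0,
        )
        rec = run_presentation(tiny_network, s, learning=OFF)
        assert len(rec.lgn_ids) == 0 and len(rec.cortex_ids) == 0

    def test_learning_off_leaves_weights_untouched(
        self, tiny_network, tiny_stream
    ):
        before = {
            k: g.weight.copy() for k, g in tiny_network.pathways.items()
        }
        run_presentation(tiny_network, tiny_stream, learning=OFF)
        for k, g in tiny_network.pathways.items():
            assert np.array_equal(g.weight, before[k])

    def test_learning_on_changes_weights(self, tiny_network, tiny_stream):
        net = tiny_network.copy()
        before = net.pathways[Pathway.AFFERENT].weight.copy()
        run_presentation(net, tiny_stream, learning=ON)
        assert not np.array_equal(
            net.pathways[Pathway.AFFERENT].weight, before
        )

    def test_identical_runs_identical_records(
        self, tiny_network, tiny_stream
    ):
        a = run_presentation(tiny_network, tiny_stream, learning=OFF)
        b = run_presentation(tiny_network, tiny_stream, learning=OFF)
        assert a == b

    def test_reset_preserves_weights_and_statelessness(
        self, tiny_network, tiny_stream
    ):
        net = tiny_network.copy()
        w0 = net.pathways[Pathway.AFFERENT].weight.copy()
        first = run_presentation(net, tiny_stream, learning=OFF)
        net = reset_network(net)
        assert np.array_equal(net.pathways[Pathway.AFFERENT].weight, w0)
        second = run_presentation(net, tiny_stream, learning=OFF)
        assert first == second

    def test_presentation_order_does_not_matter_without_learning(
        self, tiny_network, tiny_stream, tiny_stream_w
    ):
        a1 = run_presentation(tiny_network, tiny_stream, learning=OFF)
        b1 = run_presentation(tiny_network, tiny_stream_w, learning=OFF)
        b2 = run_presentation(tiny_network, tiny_stream_w, learning=OFF)
        a2 = run_presentation(tiny_network, tiny_stream, learning=OFF)
        assert a1 == a2 and b1 == b2

    def test_events_outside_grid_rejected(self, tiny_network):
        ev = np.zeros(1, dtype=EVENT_DTYPE)
        ev["x"] = 100  # outside the 32x32 miniature input sheet
        s = EventStream(events=ev, direction_deg=0.0, duration_ms=10.0)
        with pytest.raises(ValueError, match="input grid"):
            run_presentation(tiny_network, s, learning=OFF)

    def test_spiking_confined_to_stimulated_band(self, tiny_network):
        # a narrow sweep only drives cortical neurons whose afferent
        # fields intersect the swept rows (lateral drive alone is
        # subthreshold), verified against a brute-force field intersection
        s = make_sweep_stream(0.0, band=(0, 8))  # rows 0-7 only
        # boosted afferent gain so the narrow band reliably drives its
        # targets; lateral excitation stays subthreshold on its own
        lif = LIFParams(syn_gain_exc=1.2)
        rec = run_presentation(tiny_network, s, learning=OFF, lif=lif)
        fired = np.unique(rec.cortex_ids)
        lgn_rows = np.arange(2)  # rows 0-7 pool into LGN rows 0-1
        grp = tiny_network.pathways[Pathway.AFFERENT]
        lgn_y = grp.pre // 8
        allowed = np.unique(grp.post[np.isin(lgn_y, lgn_rows)])
        assert set(fired) <= set(allowed.tolist())
        assert len(fired) > 0

    def test_total_activity_bounded(self, tiny_network, tiny_stream):
        rec = run_presentation(tiny_network, tiny_stream, learning=ON)
        p = LIFParams()
        n_steps = tiny_stream.duration_ms / p.dt_ms + 40
        cap = tiny_network.n_cortex * n_steps / (p.refractory_ms + 1)
        assert 0 < len(rec.cortex_ids) < cap


class TestEngineEquivalence:
    @pytest.mark.parametrize("inh_rule", ["hebbian", "anti_hebbian",
                                          "symmetric"])
    def test_compiled_kernel_matches_reference(
        self, tiny_network, tiny_stream, inh_rule
    ):
        stdp = STDPParams(inhibitory_stdp=inh_rule)
        nets = {}
        recs = {}
        for engine in ("numba", "python"):
            net = tiny_network.copy()
            recs[engine] = run_presentation(
                net, tiny_stream, learning=ON, stdp=stdp, engine=engine
            )
            nets[engine] = net
        assert recs["numba"] == recs["python"]
        for name in (Pathway.AFFERENT, Pathway.LATERAL_EXC,
                     Pathway.LATERAL_INH):
            np.testing.assert_allclose(
                nets["numba"].pathways[name].weight,
                nets["python"].pathways[name].weight,
                rtol=1e-12, atol=1e-14,
            )

    def test_unknown_engine_rejected(self, tiny_network, tiny_stream):
        with pytest.raises(ValueError, match="engine"):
            run_presentation(
                tiny_network, tiny_stream, learning=OFF, engine="cuda"
            )


class TestLifValidation:
    def test_potential_ordering_enforced(self):
        with pytest.raises(ValueError, match="v_reset"):
            LIFParams(v_thresh=-1.0)

    def test_positive_time_constants(self):
        with pytest.raises(ValueError):
            LIFParams(tau_m_ms=0.0)
        with pytest.raises(ValueError):
            LIFParams(dt_ms=0.0)
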