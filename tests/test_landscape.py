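import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ldfkit import fixtures as fx
from ldfkit.landscape import (
    ISOLATION_WINDOW,
    PERIGLACIAL_LENGTH,
    TEMPERATE_LENGTH,
    DownstreamEdge,
    LandscapeGraph,
    LandscapeSystem,
    SuccessionSchedule,
    assemble_landscape_matrix,
    stage_weights,
)
from ldfkit.object_model import N_COMPARTMENTS, RL, WAT
from ldfkit.series import TimeSeries, constant, interpolate_parameters
from ldfkit.solver import ReleaseScenario, integrate


def make_schedule(**kw):
    defaults = dict(submerged_until=-8000.0, isolation_start=-8000.0,
                    isolation_end=-7500.0)
    defaults.update(kw)
    return SuccessionSchedule(**defaults)


class TestStageWeights:
    def test_fully_sea_before_isolation(self):
        w = stage_weights(make_schedule(), -8500.0)
        assert w == {"sea": 1.0, "lake": 0.0, "wetland": 0.0, "agricultural": 0.0}

    def test_isolation_midpoint_half_sea(self):
        w = stage_weights(make_schedule(), -7750.0)
        assert w["sea"] == pytest.approx(0.5)

    def test_agricultural_takes_over(self):
        sched = make_schedule(agricultural_from=0.0)
        assert stage_weights(sched, 100.0)["agricultural"] == 1.0

    @given(st.floats(min_value=-9000.0, max_value=9400.0))
    @settings(derandomize=True, max_examples=1000)
    def test_weights_sum_to_one(self, t):
        sched = make_schedule(agricultural_from=-4500.0)
        w = stage_weights(sched, t)
        assert sum(w.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(v >= 0.0 for v in w.values())

    def test_continuity_at_every_breakpoint(self):
        sched = make_schedule(agricultural_from=-4500.0)
        eps = 1e-7
        for tb in sched.breakpoints():
            before = stage_weights(sched, tb - eps)
            after = stage_weights(sched, tb + eps)
            for key in before:
                assert after[key] == pytest.approx(before[key], abs=1e-5)

    def test_inconsistent_schedule_rejected(self):
        with pytest.raises(ValueError):
            make_schedule(isolation_end=-8001.0)
        with pytest.raises(ValueError):
            make_schedule(wetland_by=-7600.0)


def test_default_glacial_cycle_constants():
    sched = make_schedule()
    t0, t1 = sched.period("temperate")
    assert t1 - t0 == TEMPERATE_LENGTH == 18_400.0
    p0, p1 = sched.period("periglacial")
    assert p1 - p0 == PERIGLACIAL_LENGTH == 50_200.0
    assert ISOLATION_WINDOW == 500.0


class TestInterpolation:
    def test_single_breakpoint_constant(self):
        s = constant(7.0)
        assert interpolate_parameters(s, -1e6) == 7.0 == interpolate_parameters(s, 1e6)

    def test_linear_midpoint(self):
        s = TimeSeries(t=[0.0, 100.0], v=[0.0, 10.0])
        assert interpolate_parameters(s, 50.0) == pytest.approx(5.0)

    def test_constant_extrapolation(self):
        s = TimeSeries(t=[0.0, 100.0], v=[2.0, 10.0])
        assert interpolate_parameters(s, 1e9) == 10.0
        assert interpolate_parameters(s, -1e9) == 2.0

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            TimeSeries(t=[], v=[])

    def test_unsorted_breakpoints_rejected(self):
        with pytest.raises(ValueError):
            TimeSeries(t=[1.0, 0.0], v=[0.0, 1.0])


class TestGraphValidation:
    def test_fixture_graph_valid(self, graph3):
        assert set(graph3.objects) == {"obj1", "obj2", "obj3", "coast"}

    def test_edge_to_unknown_object_rejected(self, decay_graph):
        data = decay_graph.model_dump()
        data["downstream_edges"][0]["target"] = "ghost"
        with pytest.raises(ValueError, match="ghost"):
            LandscapeGraph.model_validate(data)

    def test_missing_schedule_rejected(self, decay_graph):
        data = decay_graph.model_dump()
        data["schedules"] = {}
        with pytest.raises(ValueError, match="schedule"):
            LandscapeGraph.model_validate(data)

    def test_cycle_rejected(self, decay_graph):
        data = decay_graph.model_dump()
        data["downstream_edges"].append(
            {"source": "obj1", "target": "obj1", "flux": {"t": [0.0], "v": [1.0]}}
        )
        with pytest.raises(ValueError, match="cycle|source"):
            LandscapeGraph.model_validate(data)

    def test_unreachable_outlet_rejected(self, decay_graph):
        data = decay_graph.model_dump()
        data["downstream_edges"] = []
        with pytest.raises(ValueError, match="drainage path"):
            LandscapeGraph.model_validate(data)


class TestLandscapeMatrix:
    def test_single_object_equals_object_matrix(self, decay_graph, chain_library):
        from ldfkit.object_model import assemble_object_matrix

        M = assemble_landscape_matrix(decay_graph, chain_library, "Syn3", 0.0)
        K, _ = assemble_object_matrix(
            decay_graph.objects["obj1"],
            chain_library.elements["Syn"],
            chain_library.nuclides["Syn3"],
            0.0,
        )
        assert np.allclose(M[:N_COMPARTMENTS, :N_COMPARTMENTS], K)

    def test_downstream_export_reappears_as_import(self, graph3, library):
        """Flux-balance audit: A's WATER loss term equals B's gain term."""
        system = LandscapeSystem(graph3, library, "I129syn")
        t = 5000.0  # all objects terrestrial: downstream edges fully active
        M = system.matrix_at(t)
        i = system.idx_inv(0, system.obj_index["obj1"], WAT)
        j = system.idx_inv(0, system.obj_index["obj2"], WAT)
        edge = next(e for e in graph3.downstream_edges if e.source == "obj1")
        vw = graph3.objects["obj1"].geometry_at(t)[WAT].water_volume
        assert M[j, i] == pytest.approx(edge.flux.at(t) / vw, rel=1e-12)

    def test_sea_stage_gating(self, graph3, library):
        system = LandscapeSystem(graph3, library, "I129syn")
        o1 = system.obj_index["obj1"]
        coast = system.obj_index["coast"]
        o2 = system.obj_index["obj2"]

        t_sea = -8500.0  # obj1 submerged
        M = system.matrix_at(t_sea)
        i, c = system.idx_inv(0, o1, WAT), system.idx_inv(0, coast, WAT)
        assert M[c, i] > 0.0 and M[i, c] > 0.0  # bidirectional exchange
        assert M[system.idx_inv(0, o2, WAT), i] == 0.0  # downstream edge off

        t_land = 5000.0  # obj1 terrestrial
        M = system.matrix_at(t_land)
        assert M[c, i] == 0.0 and M[i, c] == 0.0
        assert M[system.idx_inv(0, o2, WAT), i] > 0.0

    def test_decoupled_landscape_equals_independent_objects(self, library):
        """Zero inter-object fluxes: the coupled run is the union of solo runs."""
        spec = fx.FixtureSpec(n_objects=2)
        graph = fx.generate_landscape(spec)
        data = graph.model_dump()
        for edge in data["downstream_edges"]:
            edge["flux"] = {"t": [0.0], "v": [0.0]}
        for ex in data["sea_exchange"].values():
            ex["to_partner"] = {"t": [0.0], "v": [0.0]}
            ex["from_partner"] = {"t": [0.0], "v": [0.0]}
        decoupled = LandscapeGraph.model_validate(data)

        span, grid = (-9000.0, -5000.0), np.linspace(-9000.0, -5000.0, 41)
        scn = ReleaseScenario(
            mode="constant", nuclide="I129syn",
            target_objects={"obj1": 0.5, "obj2": 0.5}, rate=1.0, start=-9000.0,
        )
        coupled = integrate(
            LandscapeSystem(decoupled, library, "I129syn"), scn, span, output_grid=grid
        )

        solo_states = {}
        for oid in ("obj1", "obj2"):
            solo_data = {
                "objects": {oid: data["objects"][oid]},
                "schedules": {oid: data["schedules"][oid]},
                "downstream_edges": [
                    {"source": oid, "target": "outlet", "flux": {"t": [0.0], "v": [0.0]}}
                ],
                "sea_exchange": {},
                "outlet": "outlet",
            }
            solo = LandscapeGraph.model_validate(solo_data)
            scn_solo = ReleaseScenario(
                mode="constant", nuclide="I129syn", target_objects={oid: 1.0},
                rate=0.5, start=-9000.0,
            )
            sol = integrate(
                LandscapeSystem(solo, library, "I129syn"), scn_solo, span,
                output_grid=grid,
            )
            solo_states[oid] = sol.inventories("I129syn")[:, 0, :]

        for oid in ("obj1", "obj2"):
            o = coupled.system.obj_index[oid]
            got = coupled.inventories("I129syn")[:, o, :]
            ref = solo_states[oid]
            scale = max(ref.max(), 1e-300)
            assert np.max(np.abs(got - ref)) / scale < 1e-9
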