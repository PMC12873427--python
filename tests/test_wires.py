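import numpy as np
import pytest

from clcmech import synthetic as syn
from clcmech.core import resolve_region
from clcmech.hbonds import HBondCriteria, detect_hbonds
from clcmech.wires import (WireEndpoints, analyze_wire_trajectory,
                           classify_wire, find_wires, summarize_box,
                           validate_wire, wire_fraction)
from _oracles import exhaustive_shortest_path


def _frame_graph(fx, f):
    topo = fx.trajectory.topology
    frame = fx.trajectory.coordinates[f]
    src = resolve_region(fx.endpoints.source, topo, frame, fx.membrane)
    nodes = set(int(i) for i in topo.water_oxygen_ids()) | src
    return detect_hbonds(frame, topo, nodes, HBondCriteria(), frame_index=f)


class TestFindWires:
    def test_planted_chain_recovered_exactly(self):
        fx = syn.make_wire_fixture(n_frames=3, wire_probability=1.0, seed=4)
        for f in range(3):
            g = _frame_graph(fx, f)
            wires = find_wires(g, fx.endpoints, fx.trajectory.topology,
                               fx.trajectory.coordinates[f], fx.membrane)
            assert len(wires) == 1
            assert wires[0].n_waters == 5
            assert list(wires[0].nodes) == fx.truth["node_ids"][f]

    def test_broken_chain_yields_no_wire(self):
        fx = syn.make_wire_fixture(n_frames=5, wire_probability=0.0, seed=4)
        for f in range(5):
            g = _frame_graph(fx, f)
            assert find_wires(g, fx.endpoints, fx.trajectory.topology,
                              fx.trajectory.coordinates[f], fx.membrane) == []

    def test_bfs_length_matches_exhaustive_oracle(self):
        """On small graphs the BFS wire length equals the exhaustive
        simple-path enumeration optimum."""
        fx = syn.make_wire_fixture(n_frames=8, wire_probability=0.6, seed=9,
                                   n_decoys=12)
        topo = fx.trajectory.topology
        waters = set(int(i) for i in topo.water_oxygen_ids())
        for f in range(8):
            frame = fx.trajectory.coordinates[f]
            g = _frame_graph(fx, f)
            src = resolve_region(fx.endpoints.source, topo, frame,
                                 fx.membrane)
            snk = resolve_region(fx.endpoints.sink, topo, frame,
                                 fx.membrane) & waters
            wires = find_wires(g, fx.endpoints, topo, frame, fx.membrane)
            oracle = exhaustive_shortest_path(g.adjacency(), src, snk, waters)
            if oracle is None:
                assert wires == []
            else:
                assert len(wires[0].nodes) - 1 == oracle

    def test_every_wire_validates_against_its_graph(self):
        fx = syn.make_wire_fixture(n_frames=10, wire_probability=1.0, seed=6)
        for f in range(10):
            g = _frame_graph(fx, f)
            for w in find_wires(g, fx.endpoints, fx.trajectory.topology,
                                fx.trajectory.coordinates[f], fx.membrane):
                assert validate_wire(w, g)

    def test_overlapping_endpoints_rejected(self):
        fx = syn.make_wire_fixture(n_frames=1, seed=0)
        bad = WireEndpoints(source=fx.endpoints.sink, sink=fx.endpoints.sink)
        g = _frame_graph(fx, 0)
        with pytest.raises(ValueError, match="overlap"):
            find_wires(g, bad, fx.trajectory.topology,
                       fx.trajectory.coordinates[0], fx.membrane)


class TestClassification:
    @pytest.mark.parametrize("route,expect", [(2, 2), (3, 3)])
    def test_routed_wire_takes_planted_class(self, route, expect):
        fx = syn.make_wire_fixture(n_frames=3, wire_probability=1.0,
                                   class_route=route, seed=5)
        pf = analyze_wire_trajectory(fx.trajectory, fx.endpoints,
                                     fx.membrane, class_defs=fx.class_defs,
                                     source_tag=fx.source_tag)
        labels = {w.class_label for fr in pf for w in fr}
        assert labels == {expect}

    def test_anion_pathway_source_forces_class_1(self):
        fx = syn.make_wire_fixture(n_frames=3, wire_probability=1.0,
                                   class_route=1, seed=5)
        assert fx.source_tag == "anion_pathway"
        pf = analyze_wire_trajectory(fx.trajectory, fx.endpoints,
                                     fx.membrane, class_defs=fx.class_defs,
                                     source_tag=fx.source_tag)
        labels = {w.class_label for fr in pf for w in fr}
        assert labels == {1}

    def test_wire_contacting_no_shell_is_unclassified(self):
        fx = syn.make_wire_fixture(n_frames=1, wire_probability=1.0, seed=5)
        g = _frame_graph(fx, 0)
        frame = fx.trajectory.coordinates[0]
        wire = find_wires(g, fx.endpoints, fx.trajectory.topology, frame,
                          fx.membrane)[0]
        tight = [type(d)(class_id=d.class_id,
                         required_source=d.required_source,
                         lining_shell=d.lining_shell, contact_radius=0.01)
                 for d in fx.class_defs]
        label = classify_wire(wire, tight, fx.trajectory.topology, frame,
                              fx.membrane)
        assert label == "unclassified"


class TestWireFraction:
    def test_extremes(self):
        assert wire_fraction([[] for _ in range(100)]) == 0.0
        w = object()
        assert wire_fraction([[w]] * 50) == 1.0

    def test_binomial_sampling(self):
        fx = syn.make_wire_fixture(n_frames=2000, wire_probability=0.3,
                                   seed=7, n_decoys=0)
        frac = np.mean(fx.truth["wired_frames"])
        sd = np.sqrt(0.3 * 0.7 / 2000)
        assert abs(frac - 0.3) < 3 * sd

    def test_invariant_to_frame_order(self, rng):
        frames = [[object()] if rng.random() < 0.5 else [] for _ in range(200)]
        f0 = wire_fraction(frames)
        rng.shuffle(frames)
        assert wire_fraction(frames) == f0

    def test_zero_frames_error(self):
        with pytest.raises(ValueError):
            wire_fraction([])


class TestBoxSummary:
    def test_hand_computed_quartiles(self):
        s = summarize_box([0.2, 0.4, 0.6, 0.8])
        assert s.median == pytest.approx(0.5)
        assert s.q1 == pytest.approx(0.35)   # linear-interpolation quartiles
        assert s.q3 == pytest.approx(0.65)
        assert (s.whisker_low, s.whisker_high) == (0.2, 0.8)
        assert s.outliers == ()

    def test_all_equal_zero_width_box(self):
        s = summarize_box([0.4] * 6)
        assert s.q1 == s.median == s.q3 == 0.4
        assert s.whisker_low == s.whisker_high == 0.4

    def test_outlier_flagged_and_whisker_at_last_in_range(self):
        data = [0.30, 0.31, 0.32, 0.33, 0.34, 0.90]
        s = summarize_box(data)
        # hand computation with linear-interpolation quartiles:
        # q1 = 0.3125, q3 = 0.3375, iqr = 0.025, upper fence = 0.375
        assert s.q1 == pytest.approx(0.3125)
        assert s.q3 == pytest.approx(0.3375)
        assert s.outliers == (0.90,)
        assert s.whisker_high == pytest.approx(0.34)

    def test_single_simulation_rejected(self):
        with pytest.raises(ValueError):
            summarize_box([0.5])
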