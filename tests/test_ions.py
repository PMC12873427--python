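import numpy as np
import pytest

from clcmech import synthetic as syn
from clcmech.core import RegionSpec, Topology, Trajectory
from clcmech.ions import (DistanceSeries, IonEventConfig, assign_direction,
                          detect_unbinding, gate_series, min_distance_series,
                          occupancy_fraction, run_shows_leaving,
                          smooth_series, window_frames)


def _static_traj(ion_positions, n_frames=10):
    """Reference Y445 OH at the origin plus fixed-position ions."""
    n_ions = len(ion_positions)
    topo = Topology.from_arrays(
        atom_names=["OH"] + ["CLA"] * n_ions,
        residue_names=["TYR"] + ["CLA"] * n_ions,
        residue_numbers=[445] + [900 + i for i in range(n_ions)])
    coords = np.zeros((n_frames, topo.n_atoms, 3))
    for i, p in enumerate(ion_positions):
        coords[:, 1 + i] = p
    return Trajectory(topology=topo, coordinates=coords,
                      frame_interval_ns=0.2)


class TestMinDistance:
    def test_constant_single_ion(self):
        traj = _static_traj([(5.0, 0, 0)])
        s = min_distance_series(traj, IonEventConfig())
        np.testing.assert_allclose(s.raw_values, 5.0)

    def test_minimum_over_ions(self):
        traj = _static_traj([(9.0, 0, 0), (0, 4.0, 0)])
        s = min_distance_series(traj, IonEventConfig())
        np.testing.assert_allclose(s.raw_values, 4.0)

    def test_matches_brute_force_all_pairs(self, rng):
        n_ions, n_frames = 7, 25
        topo = Topology.from_arrays(
            atom_names=["OH", "OG"] + ["CLA"] * n_ions,
            residue_names=["TYR", "SER"] + ["CLA"] * n_ions,
            residue_numbers=[445, 107] + list(range(900, 900 + n_ions)))
        coords = rng.uniform(-20, 20, size=(n_frames, topo.n_atoms, 3))
        traj = Trajectory(topology=topo, coordinates=coords,
                          frame_interval_ns=0.2)
        cfg = IonEventConfig(reference_region=RegionSpec(
            name="ref", residue_numbers=(445, 107), atom_names=("OH", "OG")))
        s = min_distance_series(traj, cfg)
        for f in range(n_frames):
            expected = min(
                np.linalg.norm(coords[f, r] - coords[f, 2 + i])
                for r in (0, 1) for i in range(n_ions))
            assert s.raw_values[f] == pytest.approx(expected)

    def test_empty_ion_selection_is_distinct_error(self):
        topo = Topology.from_arrays(atom_names=["OH"],
                                    residue_names=["TYR"],
                                    residue_numbers=[445])
        traj = Trajectory(topology=topo, coordinates=np.zeros((3, 1, 3)),
                          frame_interval_ns=0.2)
        with pytest.raises(ValueError, match="ion selection"):
            min_distance_series(traj, IonEventConfig())


class TestSmoothing:
    def test_window_rounds_to_nearest_odd(self):
        assert window_frames(20.0, 0.2) == 101
        assert window_frames(0.2, 0.2) == 1
        assert window_frames(1.0, 0.2) == 5

    def test_constant_series_unchanged(self):
        s = DistanceSeries(times_ns=np.arange(1, 201) * 0.2,
                           raw_values=np.full(200, 5.0))
        sm = smooth_series(s, 20.0)
        np.testing.assert_allclose(sm.smoothed_values, 5.0)

    def test_linear_ramp_unchanged_in_interior(self):
        t = np.arange(1, 501) * 0.2
        s = DistanceSeries(times_ns=t, raw_values=0.05 * t)
        sm = smooth_series(s, 20.0)
        np.testing.assert_allclose(sm.smoothed_values[50:-50],
                                   s.raw_values[50:-50], rtol=1e-10)

    def test_noise_variance_reduction(self, rng):
        raw = np.clip(5.0 + rng.normal(0, 1.0, 5000), 0, None)
        s = DistanceSeries(times_ns=np.arange(1, 5001) * 0.2, raw_values=raw)
        sm = smooth_series(s, 20.0)
        interior = sm.smoothed_values[100:-100]
        expected_sd = 1.0 / np.sqrt(101)
        assert np.std(interior) == pytest.approx(expected_sd, rel=0.2)


class TestUnbinding:
    def test_never_above_threshold_no_events(self):
        s = smooth_series(DistanceSeries(times_ns=np.arange(1, 101) * 0.2,
                                         raw_values=np.full(100, 5.0)), 4.0)
        assert detect_unbinding(s, 12.0) == []

    def test_programmed_exit_recovered_within_half_window(self):
        fx = syn.make_ion_walk(duration_ns=300.0, exit_time_ns=150.0,
                               seed=8)
        s = smooth_series(min_distance_series(fx.trajectory, fx.config),
                          20.0)
        events = detect_unbinding(s, 12.0)
        assert len(events) == 1
        assert abs(events[0].crossing_time_ns - 150.0) <= 10.1

    def test_single_frame_spike_suppressed_by_smoothing(self):
        raw = np.full(300, 5.0)
        raw[150] = 30.0
        s = smooth_series(DistanceSeries(times_ns=np.arange(1, 301) * 0.2,
                                         raw_values=raw), 20.0)
        assert detect_unbinding(s, 12.0) == []
        # the raw trace does cross; sensitivity mode sees it
        assert len(detect_unbinding(s, 12.0, use_raw=True)) == 1

    def test_event_count_invariant_under_bound_padding(self):
        fx = syn.make_ion_walk(duration_ns=200.0, exit_time_ns=120.0, seed=3)
        s = smooth_series(min_distance_series(fx.trajectory, fx.config), 20.0)
        n_pad = 200
        padded_raw = np.concatenate([np.full(n_pad, 5.0), s.raw_values])
        sp = smooth_series(
            DistanceSeries(times_ns=np.arange(1, len(padded_raw) + 1) * 0.2,
                           raw_values=padded_raw), 20.0)
        ev, evp = detect_unbinding(s, 12.0), detect_unbinding(sp, 12.0)
        assert len(ev) == len(evp) == 1
        assert evp[0].crossing_frame == pytest.approx(
            ev[0].crossing_frame + n_pad, abs=1)


class TestDirection:
    @pytest.mark.parametrize("direction", ["extracellular", "intracellular"])
    def test_programmed_direction_recovered(self, direction):
        fx = syn.make_ion_walk(duration_ns=200.0, exit_time_ns=100.0,
                               direction=direction, seed=9)
        s = smooth_series(min_distance_series(fx.trajectory, fx.config), 20.0)
        ev = detect_unbinding(s, 12.0, ion_id=int(
            fx.trajectory.topology.ion_ids()[0]))
        assert len(ev) == 1
        assert assign_direction(fx.trajectory, ev[0], fx.membrane,
                                fx.pathway_sites) == direction

    def test_never_reaching_bulk_is_indeterminate(self):
        # ion hops above threshold but stays inside the bulk cutoff
        topo = Topology.from_arrays(
            atom_names=["OH", "CLA"], residue_names=["TYR", "CLA"],
            residue_numbers=[445, 900])
        coords = np.zeros((50, 2, 3))
        coords[:, 1, 2] = 13.0            # > 12 Å but < 15 Å bulk cutoff
        traj = Trajectory(topology=topo, coordinates=coords,
                          frame_interval_ns=0.2)
        from clcmech.ions import LeavingEvent
        ev = LeavingEvent(simulation_id="t", ion_id=1, crossing_frame=10,
                          crossing_time_ns=2.2)
        assert assign_direction(
            traj, ev, syn.default_membrane(),
            RegionSpec(name="p", residue_numbers=(445,),
                       atom_names=("OH",))) == "indeterminate"


class TestOccupancy:
    def test_constant_bound_and_unbound(self):
        t = np.arange(1, 201) * 0.2
        bound = smooth_series(DistanceSeries(times_ns=t,
                                             raw_values=np.full(200, 5.0)), 20)
        far = smooth_series(DistanceSeries(times_ns=t,
                                           raw_values=np.full(200, 20.0)), 20)
        assert occupancy_fraction(bound, 12.0) == 0.0
        assert occupancy_fraction(far, 12.0) == 1.0

    def test_complement_identity(self):
        fx = syn.make_ion_walk(duration_ns=250.0, exit_time_ns=100.0, seed=2)
        s = smooth_series(min_distance_series(fx.trajectory, fx.config), 20.0)
        unbound = occupancy_fraction(s, 12.0)
        bound = float(np.mean(s.smoothed_values <= 12.0))
        assert unbound + bound == 1.0

    def test_programmed_unbound_fraction(self):
        # bound 120 ns then unbound for the remaining 180 ns of a 300 ns run
        fx = syn.make_ion_walk(duration_ns=300.0, exit_time_ns=120.0, seed=5)
        s = smooth_series(min_distance_series(fx.trajectory, fx.config), 20.0)
        frac = occupancy_fraction(s, 12.0)
        assert frac == pytest.approx(0.6, abs=0.05)   # edge effects of window


class TestGateAndRunLevel:
    def test_static_gate_distance(self):
        fx = syn.make_ion_walk(duration_ns=50.0, exit_time_ns=None, seed=1)
        g = gate_series(fx.trajectory)
        np.testing.assert_allclose(g.series.raw_values, 3.0)
        assert g.open_fraction() == 0.0

    def test_missing_gate_residue_named_in_error(self):
        traj = _static_traj([(5.0, 0, 0)])
        with pytest.raises(ValueError, match="S107 OG"):
            gate_series(traj)

    def test_both_ions_required_for_run_level_leaving(self):
        fx = syn.make_ion_walk(duration_ns=300.0,
                               exit_time_ns=[100.0, None],
                               direction=["extracellular", "extracellular"],
                               seed=4)
        topo = fx.trajectory.topology
        per_ion = []
        for ion in topo.ion_ids():
            cfg = IonEventConfig(ion_selection=RegionSpec(
                name=f"ion{ion}", residue_numbers=(
                    int(topo.residue_numbers[topo.index_of([ion])[0]]),)))
            per_ion.append(smooth_series(
                min_distance_series(fx.trajectory, cfg), 20.0))
        assert not run_shows_leaving(per_ion, 12.0)
        # staggered second exit: now both leave
        fx2 = syn.make_ion_walk(duration_ns=300.0,
                                exit_time_ns=[100.0, 200.0],
                                direction=["extracellular", "extracellular"],
                                seed=4)
        per_ion2 = []
        topo2 = fx2.trajectory.topology
        for ion in topo2.ion_ids():
            cfg = IonEventConfig(ion_selection=RegionSpec(
                name=f"ion{ion}", residue_numbers=(
                    int(topo2.residue_numbers[topo2.index_of([ion])[0]]),)))
            per_ion2.append(smooth_series(
                min_distance_series(fx2.trajectory, cfg), 20.0))
        assert run_shows_leaving(per_ion2, 12.0)
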