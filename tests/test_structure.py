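import numpy as np
import pytest

from clcmech import synthetic as syn
from clcmech.core import Topology, AtomicModel
from clcmech.structure import (DegenerateMapError, DensityMap, kabsch,
                               load_model, map_statistics, pair_residues,
                               read_map, superpose_rmsd, write_map,
                               zscore_at)


class TestMapStatistics:
    def test_constant_map_sd_zero_and_zscore_errors(self):
        dmap = DensityMap(data=np.full((8, 8, 8), 3.0),
                          voxel_size=np.ones(3), origin=np.zeros(3))
        stats = map_statistics(dmap)
        assert stats.sd == 0.0
        with pytest.raises(DegenerateMapError):
            zscore_at(dmap, (4, 4, 4), stats)

    def test_gaussian_noise_moments(self, rng):
        data = rng.normal(0, 1, size=(40, 40, 40))
        dmap = DensityMap(data=data, voxel_size=np.ones(3),
                          origin=np.zeros(3))
        stats = map_statistics(dmap)
        tol = 3 / np.sqrt(data.size)
        assert abs(stats.mean) < tol
        assert abs(stats.sd - 1) < tol

    def test_affine_transformation_of_moments(self, density_fixture):
        dmap = density_fixture.map
        s0 = map_statistics(dmap)
        scaled = DensityMap(data=2.5 * dmap.data - 1.0,
                            voxel_size=dmap.voxel_size, origin=dmap.origin)
        s1 = map_statistics(scaled)
        assert s1.mean == pytest.approx(2.5 * s0.mean - 1.0)
        assert s1.sd == pytest.approx(2.5 * s0.sd)


class TestZScore:
    def test_planted_blob_recovered(self, density_fixture):
        z = zscore_at(density_fixture.map,
                      density_fixture.truth["blob_centers"][0])
        assert z == pytest.approx(
            density_fixture.truth["planted_peak_sigmas"][0], abs=0.2)

    def test_invariant_under_affine_rescaling(self, density_fixture):
        dmap = density_fixture.map
        c = density_fixture.truth["blob_centers"][0]
        scaled = DensityMap(data=7.0 * dmap.data + 2.0,
                            voxel_size=dmap.voxel_size, origin=dmap.origin)
        assert zscore_at(scaled, c) == pytest.approx(zscore_at(dmap, c),
                                                     abs=1e-9)

    def test_grid_node_equals_voxel_lookup(self, density_fixture):
        dmap = density_fixture.map
        stats = map_statistics(dmap)
        for ijk in [(5, 9, 13), (20, 3, 40)]:
            coord = np.array(ijk) * dmap.voxel_size + dmap.origin
            direct = (dmap.data[ijk] - stats.mean) / stats.sd
            assert zscore_at(dmap, coord, stats) == pytest.approx(direct)
            assert zscore_at(dmap, coord, stats,
                             interpolation="nearest") == pytest.approx(direct)

    def test_out_of_bounds_errors(self, density_fixture):
        with pytest.raises(ValueError, match="outside"):
            zscore_at(density_fixture.map, (-5.0, 0.0, 0.0))

    def test_weak_vs_strong_site_ordering_through_files(self, tmp_path):
        """Two maps differing only in planted peak preserve z ordering
        through the MRC write/read round trip (the WT vs binding-deficient
        mutant comparison pattern)."""
        strong = syn.make_density_fixture(blob_peak_sigmas=(11.1,), seed=13)
        weak = syn.make_density_fixture(blob_peak_sigmas=(7.9,), seed=13)
        zs = {}
        for name, fx in [("strong", strong), ("weak", weak)]:
            path = tmp_path / f"{name}.mrc"
            write_map(fx.map, path)
            m = read_map(path)
            zs[name] = zscore_at(m, fx.truth["blob_centers"][0])
        assert zs["strong"] > zs["weak"]
        assert zs["strong"] == pytest.approx(11.1, abs=0.3)
        assert zs["weak"] == pytest.approx(7.9, abs=0.3)


def _toy_model(coords, resnums=None, chain="A", resname="ALA"):
    n = len(coords)
    resnums = resnums if resnums is not None else list(range(1, n + 1))
    topo = Topology.from_arrays(atom_names=["CA"] * n,
                                residue_names=[resname] * n,
                                residue_numbers=resnums,
                                chain_ids=[chain] * n,
                                elements=["C"] * n)
    return AtomicModel(topology=topo, coordinates=np.asarray(coords, float))


def _helix_model(n=30, chain="A", seq=None):
    seq = seq or ("ACDEFGHIKLMNPQRSTVWY" * 2)[:n]
    three = {v: k for k, v in
             {"ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
              "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
              "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
              "SER": "S", "THR": "T", "VAL": "V", "TRP": "W",
              "TYR": "Y"}.items()}
    t = np.arange(n) * 100 * np.pi / 180
    coords = np.stack([2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(n)],
                      axis=1)
    topo = Topology.from_arrays(atom_names=["CA"] * n,
                                residue_names=[three[s] for s in seq],
                                residue_numbers=list(range(1, n + 1)),
                                chain_ids=[chain] * n, elements=["C"] * n)
    return AtomicModel(topology=topo, coordinates=coords), seq


def _rigid_copy(model, rng, shift=12.0):
    a = rng.normal(size=3)
    a /= np.linalg.norm(a)
    angle = 0.9
    k = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    rot = np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
    coords = model.coordinates @ rot.T + shift
    return AtomicModel(topology=model.topology, coordinates=coords)


class TestPairing:
    def test_identical_models_fully_paired(self):
        m, _ = _helix_model()
        pairs = pair_residues(m, m)
        assert len(pairs) == 30
        assert all(ka == kb for _, _, ka, kb in pairs)

    def test_deleted_residues_skipped(self):
        m, seq = _helix_model(30)
        keep = [i for i in range(30) if i not in {5, 6, 7, 8, 9}]
        topo = m.topology
        sub = AtomicModel(
            topology=Topology.from_arrays(
                atom_names=["CA"] * len(keep),
                residue_names=[topo.residue_names[i] for i in keep],
                residue_numbers=[int(topo.residue_numbers[i]) for i in keep],
                chain_ids=["A"] * len(keep), elements=["C"] * len(keep)),
            coordinates=m.coordinates[keep])
        pairs = pair_residues(m, sub)
        assert len(pairs) == 25
        paired_a = {ka[1] for _, _, ka, _ in pairs}
        assert paired_a.isdisjoint({6, 7, 8, 9, 10})

    def test_shuffled_chain_ids_recovered(self, rng):
        a1, _ = _helix_model(25, chain="A")
        b1, _ = _helix_model(25, chain="B",
                             seq="MKTAYIAKQRQISFVKSHFSRQLEE"[:25])
        dimer1 = _concat_models(a1, b1)
        # same two chains with swapped ids
        a2, _ = _helix_model(25, chain="B")
        b2, _ = _helix_model(25, chain="A",
                             seq="MKTAYIAKQRQISFVKSHFSRQLEE"[:25])
        dimer2 = _concat_models(a2, b2)
        pairs = pair_residues(dimer1, dimer2)
        assert len(pairs) == 50
        # every chain-A residue of dimer1 pairs with chain-B of dimer2
        for _, _, ka, kb in pairs:
            assert ka[0] != kb[0] and ka[1] == kb[1]


def _concat_models(m1, m2):
    t1, t2 = m1.topology, m2.topology
    topo = Topology.from_arrays(
        atom_names=list(t1.atom_names) + list(t2.atom_names),
        residue_names=list(t1.residue_names) + list(t2.residue_names),
        residue_numbers=list(t1.residue_numbers) + list(t2.residue_numbers),
        chain_ids=list(t1.chain_ids) + list(t2.chain_ids),
        elements=list(t1.elements) + list(t2.elements))
    return AtomicModel(topology=topo, coordinates=np.vstack(
        [m1.coordinates, m2.coordinates]))


class TestSuperposition:
    def test_rigid_transform_recovery(self, rng):
        m, _ = _helix_model()
        moved = _rigid_copy(m, rng)
        res = superpose_rmsd(m, moved)
        assert res.rmsd < 1e-6
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)
        assert np.allclose(res.rotation @ res.rotation.T, np.eye(3),
                           atol=1e-10)

    def test_three_point_closed_form(self):
        """Collinear triangle vs apex-displaced copy: the optimal RMSD has
        the closed form d*sqrt(2)/3."""
        d = 0.3
        a = _toy_model([(-1, 0, 0), (0, 0, 0), (1, 0, 0)])
        b = _toy_model([(-1, 0, 0), (0, d, 0), (1, 0, 0)])
        res = superpose_rmsd(a, b)
        assert res.rmsd == pytest.approx(d * np.sqrt(2) / 3, rel=1e-9)

    def test_symmetry(self, rng):
        m, _ = _helix_model()
        noisy = AtomicModel(topology=m.topology,
                            coordinates=m.coordinates
                            + rng.normal(0, 0.5, m.coordinates.shape))
        r_ab = superpose_rmsd(m, noisy).rmsd
        r_ba = superpose_rmsd(noisy, m).rmsd
        assert r_ab == pytest.approx(r_ba, rel=1e-9)

    def test_matches_scipy_oracle(self, rng):
        from scipy.spatial.transform import Rotation
        p = rng.normal(size=(20, 3))
        q = rng.normal(size=(20, 3))
        rot, trans, rmsd = kabsch(p, q)
        r_sp, rssd = Rotation.align_vectors(p - p.mean(0), q - q.mean(0))
        assert np.allclose(rot, r_sp.as_matrix(), atol=1e-8)
        assert rmsd == pytest.approx(rssd / np.sqrt(20), rel=1e-6)

    def test_pruning_removes_displaced_tail(self, rng):
        m, _ = _helix_model(40)
        coords = m.coordinates.copy()
        coords[-5:] += np.array([15.0, 0, 0])       # flexible-loop analogue
        shifted = AtomicModel(topology=m.topology, coordinates=coords)
        res = superpose_rmsd(m, shifted, prune_cutoff=2.0)
        assert res.n_pruned == 5
        assert res.rmsd < 0.2 < res.rmsd_all_pairs

    def test_too_few_pairs_rejected(self):
        a = _toy_model([(0, 0, 0), (1, 0, 0)])
        with pytest.raises(ValueError, match="at least 3"):
            superpose_rmsd(a, a, pairing=[(0, 0, "x", "x"), (1, 1, "y", "y")])


def test_model_file_round_trip(tmp_path, rng):
    from clcmech.core import write_pdb
    m, _ = _helix_model()
    path = tmp_path / "helix.pdb"
    write_pdb(m.topology, m.coordinates, path)
    back = load_model(path)
    assert back.topology.n_atoms == 30
    res = superpose_rmsd(m, back)
    assert res.rmsd < 1e-2          # PDB format precision is 1e-3 Å
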