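"""C-alpha RMSD between two structures, with and without pruning.

Builds a helical model, makes a copy with a rigid rotation plus a
displaced 5-residue loop, and superposes the two: the all-pair RMSD
reflects the loop, while matchmaker-style iterative pruning reports the
agreement of the rigid core.
"""

import numpy as np

from clcmech.core import Topology
from clcmech.structure import AtomicModel, superpose_rmsd

n = 40
t = np.arange(n) * 100 * np.pi / 180
coords = np.stack([2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(n)],
                  axis=1)
topo = Topology.from_arrays(atom_names=["CA"] * n,
                            residue_names=["ALA"] * n,
                            residue_numbers=list(range(1, n + 1)),
                            elements=["C"] * n)
ref = AtomicModel(topology=topo, coordinates=coords)

rng = np.random.default_rng(3)
axis = rng.normal(size=3)
axis /= np.linalg.norm(axis)
k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
              [-axis[1], axis[0], 0]])
rot = np.eye(3) + np.sin(0.7) * k + (1 - np.cos(0.7)) * (k @ k)
moved = coords @ rot.T + np.array([5.0, -3.0, 8.0])
moved[-5:] += np.array([6.0, 0.0, 0.0])      # flexible-loop displacement
mobile = AtomicModel(topology=topo, coordinates=moved)

plain = superpose_rmsd(ref, mobile)
pruned = superpose_rmsd(ref, mobile, prune_cutoff=2.0)
print(f"all-pair C-alpha RMSD: {plain.rmsd:.2f} A over "
      f"{len(plain.paired_residues)} residues")
print(f"after 2.0 A iterative pruning: {pruned.rmsd:.3f} A "
      f"({pruned.n_pruned} residues pruned)")
print("The all-pair value includes the displaced loop; the pruned value "
      "shows the rigid core superposes almost exactly.")
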