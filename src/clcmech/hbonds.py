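"""Per-frame geometric hydrogen-bond graphs over water oxygens and
designated protein endpoint heavy atoms.

An edge connects two heavy atoms when the donor--acceptor distance is at
most ``d_da_max`` and, in hydrogen-aware mode, at least one attached
hydrogen gives a D-H...A angle (measured at the hydrogen) of at least
``angle_min_deg`` in either donation direction.  Candidate pairs come from
a KD-tree; the edge test itself is identical to the naive all-pairs
evaluation, so the accelerated and brute-force routes agree bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .core import Topology, minimum_image_deltas

__all__ = ["HBondCriteria", "HBondGraph", "detect_hbonds",
           "attached_hydrogens", "hbond_angle_deg"]

_H_BOND_MAX = 1.25  # Å; covalent X-H detection radius within a residue


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition.

    Defaults (3.5 Å heavy-atom cutoff, 150 deg D-H...A angle) are the
    standard water criteria; both are configuration keys and any wire
    statistic should be reported alongside the criteria used.
    """

    d_da_max: float = 3.5
    angle_min_deg: float = 150.0
    use_hydrogens: bool = True

    def __post_init__(self):
        if not (0 < self.d_da_max <= 6):
            raise ValueError("d_da_max must be in (0, 6] Å")
        if not (0 < self.angle_min_deg <= 180):
            raise ValueError("angle_min_deg must be in (0, 180] degrees")


@dataclass
class HBondGraph:
    """Undirected hydrogen-bond graph for one frame.

    Edges are stored as sorted (min_id, max_id) pairs in lexicographic
    order for deterministic serialization.
    """

    frame_index: int
    nodes: tuple                      # atom_ids
    edges: list                       # [(i, j, distance, angle_or_None)]

    def adjacency(self) -> dict:
        adj: dict = {n: [] for n in self.nodes}
        for i, j, _, _ in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        for k in adj:
            adj[k].sort()
        return adj

    def edge_set(self) -> set:
        return {(i, j) for i, j, _, _ in self.edges}

    def has_edge(self, a: int, b: int) -> bool:
        return (min(a, b), max(a, b)) in self.edge_set()

    def to_records(self):
        return [{"frame": self.frame_index, "atom_i": i, "atom_j": j,
                 "distance": d, "angle": a} for i, j, d, a in self.edges]


def attached_hydrogens(topology: Topology, frame: np.ndarray,
                       heavy_indices: np.ndarray) -> dict:
    """Map heavy-atom row index -> row indices of its covalent hydrogens
    (same residue, within 1.25 Å in this frame)."""
    keys = topology.residue_key_of()
    is_h = np.array([e.upper() == "H" for e in topology.elements])
    h_idx = np.flatnonzero(is_h)
    by_res: dict = {}
    for hi in h_idx:
        by_res.setdefault(keys[hi], []).append(hi)
    out: dict = {}
    for idx in heavy_indices:
        cands = by_res.get(keys[idx], [])
        if not cands:
            out[idx] = np.empty(0, dtype=int)
            continue
        cands = np.asarray(cands)
        d = np.linalg.norm(frame[cands] - frame[idx], axis=1)
        out[idx] = cands[d <= _H_BOND_MAX]
    return out


def hbond_angle_deg(d_pos: np.ndarray, h_pos: np.ndarray,
                    a_pos: np.ndarray) -> float:
    """D-H...A angle at the hydrogen, in degrees (180 = linear)."""
    v1 = d_pos - h_pos
    v2 = a_pos - h_pos
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _best_angle(frame, i, j, hmap) -> Optional[float]:
    """Best D-H...A angle over hydrogens of either partner (both donation
    directions allowed), or None when neither has hydrogens."""
    best = None
    for donor, acceptor in ((i, j), (j, i)):
        for h in hmap.get(donor, ()):
            ang = hbond_angle_deg(frame[donor], frame[h], frame[acceptor])
            if best is None or ang > best:
                best = ang
    return best


def detect_hbonds(frame: np.ndarray, topology: Topology,
                  node_set: Sequence[int], criteria: HBondCriteria,
                  frame_index: int = 0,
                  box: Optional[np.ndarray] = None) -> HBondGraph:
    """Build the hydrogen-bond graph over ``node_set`` (atom_ids) for one
    frame.  Minimum-image distances are used when ``box`` (orthorhombic
    edge lengths) is given; angle geometry uses the stored coordinates,
    which for pre-imaged trajectories are whole-molecule consistent.
    """
    node_ids = sorted(int(n) for n in node_set)
    if not node_ids:
        raise ValueError("node_set must be nonempty")
    frame = np.asarray(frame, dtype=float)
    rows = topology.index_of(node_ids)

    hmap: dict = {}
    if criteria.use_hydrogens:
        hmap = attached_hydrogens(topology, frame, rows)
        if all(len(v) == 0 for v in hmap.values()):
            raise ValueError(
                "use_hydrogens=True but no node atom has attached "
                "hydrogens; use distance-only mode or add hydrogens")

    pos = frame[rows]
    if box is not None:
        tree = cKDTree(np.mod(pos, box), boxsize=box)
    else:
        tree = cKDTree(pos)
    pairs = tree.query_pairs(r=criteria.d_da_max, output_type="ndarray")

    edges = []
    for a, b in pairs:
        ri, rj = rows[a], rows[b]
        delta = minimum_image_deltas(frame[rj] - frame[ri], box)
        dist = float(np.linalg.norm(delta))
        if dist > criteria.d_da_max:
            continue
        angle = None
        if criteria.use_hydrogens:
            angle = _best_angle(frame, ri, rj, hmap)
            if angle is None or angle < criteria.angle_min_deg:
                continue
        ii, jj = node_ids[a], node_ids[b]
        edges.append((min(ii, jj), max(ii, jj), dist,
                      None if angle is None else float(angle)))
    edges.sort(key=lambda e: (e[0], e[1]))
    return HBondGraph(frame_index=frame_index, nodes=tuple(node_ids),
                      edges=edges)
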