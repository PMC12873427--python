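"""Cryo-EM map statistics / z-scores and C-alpha RMSD structure comparison.

The z-score expresses the interpolated map density at a coordinate as the
number of standard deviations above the whole-map mean:

    Z = (density(x) - mean) / sd

with mean and population sd taken over the entire grid (a masked mode is
available but is not the default).  Superposition is a least-squares
Kabsch fit on paired C-alpha atoms, with an optional matchmaker-style
iterative prune (drop pairs deviating more than a cutoff, re-fit until
stable); both the all-pair and post-prune RMSD are reported.

MRC/CCP4 maps and PDB/mmCIF models are read and written through gemmi.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import gemmi
import numpy as np
from scipy.ndimage import map_coordinates

from .core import AtomicModel, Topology

__all__ = ["DensityMap", "MapStatistics", "AlignmentResult",
           "DegenerateMapError", "read_map", "write_map", "map_statistics",
           "zscore_at", "load_model", "pair_residues", "superpose_rmsd",
           "kabsch"]


class DegenerateMapError(ValueError):
    """Raised when a z-score is requested on a zero-variance map."""


@dataclass
class DensityMap:
    """3-D density grid with voxel size and origin in Å (axes x, y, z)."""

    data: np.ndarray            # (nx, ny, nz)
    voxel_size: np.ndarray      # (3,) Å
    origin: np.ndarray          # (3,) Å

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("map grid must be a nonempty 3-D array")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel sizes must be positive")

    def position_to_index(self, xyz) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - self.origin) / self.voxel_size


@dataclass(frozen=True)
class MapStatistics:
    mean: float
    sd: float
    n_voxels: int


@dataclass
class AlignmentResult:
    rotation: np.ndarray        # (3,3), orthonormal, det +1
    translation: np.ndarray     # (3,)
    paired_residues: list       # [(keyA, keyB), ...] surviving pairs
    rmsd: float                 # post-prune (== all-pair when no pruning)
    rmsd_all_pairs: float
    n_pruned: int


# ---------------------------------------------------------------------------
# maps
# ---------------------------------------------------------------------------

def read_map(path) -> DensityMap:
    """Read an MRC/CCP4 map; axis order is normalized to X,Y,Z on read."""
    m = gemmi.read_ccp4_map(str(path), setup=True)
    grid = np.array(m.grid, copy=True)          # indexed (x, y, z) after setup
    cell = m.grid.unit_cell
    nx, ny, nz = m.grid.nu, m.grid.nv, m.grid.nw
    voxel = np.array([cell.a / nx, cell.b / ny, cell.c / nz])
    origin = np.array([m.header_float(50), m.header_float(51),
                       m.header_float(52)])
    return DensityMap(data=grid, voxel_size=voxel, origin=origin)


def write_map(dmap: DensityMap, path) -> None:
    """Write a DensityMap as MRC/CCP4 (orthogonal cell, XYZ axis order)."""
    m = gemmi.Ccp4Map()
    nx, ny, nz = dmap.data.shape
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(dmap.data, dtype=np.float32))
    m.grid.unit_cell = gemmi.UnitCell(nx * dmap.voxel_size[0],
                                      ny * dmap.voxel_size[1],
                                      nz * dmap.voxel_size[2],
                                      90.0, 90.0, 90.0)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    m.set_header_float(50, float(dmap.origin[0]))
    m.set_header_float(51, float(dmap.origin[1]))
    m.set_header_float(52, float(dmap.origin[2]))
    m.write_ccp4_map(str(path))


def map_statistics(dmap: DensityMap,
                   mask: Optional[np.ndarray] = None) -> MapStatistics:
    """Mean and population SD over all voxels (or over an optional mask)."""
    vals = dmap.data if mask is None else dmap.data[mask]
    return MapStatistics(mean=float(vals.mean()),
                         sd=float(vals.std(ddof=0)),
                         n_voxels=int(vals.size))


def zscore_at(dmap: DensityMap, coordinate, stats: Optional[MapStatistics] = None,
              interpolation: str = "trilinear") -> float:
    """Z-score ("sigma") of the map density at a coordinate (Å).

    Trilinear interpolation by default; 'nearest' mode for sensitivity
    checks.  A zero-variance map raises DegenerateMapError; a coordinate
    outside the grid raises ValueError.
    """
    if stats is None:
        stats = map_statistics(dmap)
    if stats.sd == 0:
        raise DegenerateMapError("map has zero variance; z-score undefined")
    idx = dmap.position_to_index(coordinate)
    upper = np.array(dmap.data.shape) - 1
    if np.any(idx < 0) or np.any(idx > upper):
        raise ValueError(f"coordinate {coordinate} outside grid bounds")
    order = {"trilinear": 1, "nearest": 0}.get(interpolation)
    if order is None:
        raise ValueError(f"unknown interpolation '{interpolation}'")
    val = float(map_coordinates(dmap.data, idx.reshape(3, 1), order=order,
                                mode="nearest")[0])
    return (val - stats.mean) / stats.sd


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

def load_model(path) -> AtomicModel:
    """Read a PDB or mmCIF structure into an AtomicModel via gemmi."""
    st = gemmi.read_structure(str(path))
    fmt = "mmCIF" if str(path).lower().endswith((".cif", ".mmcif")) else "PDB"
    st.setup_entities()
    names, resnames, resnums, chains, elements, coords = [], [], [], [], [], []
    model = st[0]
    for chain in model:
        for res in chain:
            for atom in res:
                names.append(atom.name)
                resnames.append(res.name)
                resnums.append(res.seqid.num)
                chains.append(chain.name)
                elements.append(atom.element.name)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    topo = Topology.from_arrays(atom_names=names, residue_names=resnames,
                                residue_numbers=resnums, chain_ids=chains,
                                elements=elements)
    return AtomicModel(topology=topo, coordinates=np.array(coords),
                       source_format=fmt)


_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "HSD": "H", "HSE": "H", "HSP": "H", "CYX": "C",
    "ASH": "D", "GLH": "E", "HID": "H", "HIE": "H", "HIP": "H",
}


def _chain_residues(model: AtomicModel):
    """Per-chain ordered list of (residue_key, one-letter, ca_row)."""
    topo = model.topology
    ca = np.flatnonzero(model.ca_mask())
    chains: dict = {}
    for row in ca:
        ch = topo.chain_ids[row]
        key = (str(ch), int(topo.residue_numbers[row]),
               str(topo.residue_names[row]))
        letter = _AA3TO1.get(str(topo.residue_names[row]).upper(), "X")
        chains.setdefault(str(ch), []).append((key, letter, int(row)))
    return chains


def pair_residues(model_a: AtomicModel, model_b: AtomicModel) -> list:
    """Chain-aware residue pairing by sequence alignment.

    Chains are matched by best pairwise alignment score (so shuffled chain
    ids with identical sequences are recovered); within each matched chain
    pair, residues pair by global sequence alignment, unmatched residues
    excluded.  Returns [(row_a, row_b, keyA, keyB), ...] over CA rows.
    """
    from Bio import Align

    chains_a = _chain_residues(model_a)
    chains_b = _chain_residues(model_b)
    if not chains_a or not chains_b:
        raise ValueError("both models need protein C-alpha atoms")

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0

    seqs_a = {c: "".join(x[1] for x in v) for c, v in chains_a.items()}
    seqs_b = {c: "".join(x[1] for x in v) for c, v in chains_b.items()}

    # greedy best-score chain correspondence
    scored = []
    for ca_id, sa in seqs_a.items():
        for cb_id, sb in seqs_b.items():
            scored.append((float(aligner.score(sa, sb)), ca_id, cb_id))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a, used_b, chain_pairs = set(), set(), []
    for score, ca_id, cb_id in scored:
        if ca_id in used_a or cb_id in used_b:
            continue
        used_a.add(ca_id)
        used_b.add(cb_id)
        chain_pairs.append((ca_id, cb_id))

    pairs = []
    for ca_id, cb_id in chain_pairs:
        va, vb = chains_a[ca_id], chains_b[cb_id]
        aln = aligner.align(seqs_a[ca_id], seqs_b[cb_id])[0]
        for (a0, a1), (b0, b1) in zip(*aln.aligned):
            for off in range(a1 - a0):
                ka, la, ra = va[a0 + off]
                kb, lb, rb = vb[b0 + off]
                pairs.append((ra, rb, ka, kb))
    if not pairs:
        raise ValueError("no common residues between the models")
    return pairs


def kabsch(p: np.ndarray, q: np.ndarray):
    """Least-squares rotation+translation mapping q onto p (no reflection).

    Returns (rotation, translation, rmsd) with rmsd over all points.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    p0, q0 = p - pc, q - qc
    h = q0.T @ p0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = pc - rot @ qc
    moved = q @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - p) ** 2, axis=1))))
    return rot, trans, rmsd


def superpose_rmsd(model_a: AtomicModel, model_b: AtomicModel,
                   pairing: Optional[list] = None,
                   prune_cutoff: Optional[float] = None,
                   max_prune_iter: int = 50) -> AlignmentResult:
    """Kabsch superposition of model_b onto model_a over paired C-alphas.

    With ``prune_cutoff`` set, pairs deviating more than the cutoff (Å)
    after fitting are dropped and the fit repeated until stable
    (matchmaker-style); both the all-pair and post-prune RMSD are kept.
    """
    if pairing is None:
        pairing = pair_residues(model_a, model_b)
    if len(pairing) < 3:
        raise ValueError("superposition requires at least 3 residue pairs")
    rows_a = np.array([p[0] for p in pairing])
    rows_b = np.array([p[1] for p in pairing])
    pa = model_a.coordinates[rows_a]
    pb = model_b.coordinates[rows_b]

    rot, trans, rmsd_all = kabsch(pa, pb)
    keep = np.ones(len(pairing), dtype=bool)
    rmsd_final = rmsd_all
    if prune_cutoff is not None:
        for _ in range(max_prune_iter):
            rot, trans, rmsd_final = kabsch(pa[keep], pb[keep])
            dev = np.linalg.norm(pb @ rot.T + trans - pa, axis=1)
            new_keep = dev <= prune_cutoff
            if new_keep.sum() < 3:
                break
            if np.array_equal(new_keep, keep):
                break
            keep = new_keep
        rot, trans, rmsd_final = kabsch(pa[keep], pb[keep])
    kept_pairs = [(p[2], p[3]) for p, k in zip(pairing, keep) if k]
    return AlignmentResult(rotation=rot, translation=trans,
                           paired_residues=kept_pairs, rmsd=rmsd_final,
                           rmsd_all_pairs=rmsd_all,
                           n_pruned=int((~keep).sum()))
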