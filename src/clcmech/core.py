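"""Domain types and I/O for topologies, trajectories, regions, and atomic models.

Conventions used throughout the package:

* coordinates are in Angstrom (Å);
* the membrane normal is the z axis;
* the extracellular side is +z (structures are drawn extracellular-up);
* trajectory frames are equally spaced; the default spacing is 0.2 ns
  (frames saved every 200 ps).

File I/O goes through MDAnalysis: PDB for topologies and desk-scale
multi-model fixtures, DCD/XTC for production-scale coordinate sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "Topology",
    "Trajectory",
    "RegionSpec",
    "MembraneFrame",
    "AtomicModel",
    "TopologyError",
    "TrajectoryError",
    "RegionError",
    "load_topology",
    "load_trajectory",
    "resolve_region",
    "write_pdb",
    "write_dcd",
]

# Residue-name tables used for role assignment.  User-extensible via the
# keyword arguments of load_topology / Topology.from_arrays.
WATER_RESNAMES = {"HOH", "WAT", "TIP3", "SOL", "TIP", "SPC", "T3P"}
ION_RESNAMES = {
    "CL", "CLA", "CL-", "NA", "SOD", "NA+", "K", "POT", "K+", "MG", "CA",
    "CAL", "ZN", "MN", "CS", "LI", "RB", "BR", "IOD", "F",
}
LIPID_RESNAMES = {
    "POPC", "POPE", "POPS", "POPG", "DPPC", "DOPC", "DMPC", "CHL1", "PA",
    "PC", "PE", "PGR", "OL",
}
PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    # common protonation/capping variants
    "HSD", "HSE", "HSP", "HID", "HIE", "HIP", "CYX", "CYM", "ASH", "GLH",
    "LYN", "ACE", "NME", "NMA",
}

ROLES = ("protein", "water", "ion", "lipid", "other")


class TopologyError(ValueError):
    """Raised when a topology file cannot be parsed or violates invariants."""


class TrajectoryError(ValueError):
    """Raised for frame/atom mismatches or truncated trajectory files."""


class RegionError(ValueError):
    """Raised when a RegionSpec cannot be resolved (missing frame/membrane)."""


def _assign_role(resname: str,
                 water_resnames: set[str],
                 ion_resnames: set[str],
                 lipid_resnames: set[str]) -> str:
    rn = resname.strip().upper()
    if rn in water_resnames:
        return "water"
    if rn in ion_resnames:
        return "ion"
    if rn in PROTEIN_RESNAMES:
        return "protein"
    if rn in lipid_resnames:
        return "lipid"
    return "other"


@dataclass(frozen=True)
class Topology:
    """Atom table shared by all trajectory analyses.

    Stored as parallel numpy arrays for vectorised selection; ``atom_ids``
    are unique and stably ordered (0..n-1 for generated fixtures, the file
    order for loaded ones).
    """

    atom_ids: np.ndarray        # (n,) int
    atom_names: np.ndarray      # (n,) str
    elements: np.ndarray        # (n,) str
    residue_names: np.ndarray   # (n,) str
    residue_numbers: np.ndarray # (n,) int
    chain_ids: np.ndarray       # (n,) str
    roles: np.ndarray           # (n,) str, one of ROLES

    def __post_init__(self):
        n = len(self.atom_ids)
        for arr in (self.atom_names, self.elements, self.residue_names,
                    self.residue_numbers, self.chain_ids, self.roles):
            if len(arr) != n:
                raise TopologyError("topology arrays must have equal length")
        if len(np.unique(self.atom_ids)) != n:
            raise TopologyError("atom_ids must be unique")
        bad = set(np.unique(self.roles)) - set(ROLES)
        if bad:
            raise TopologyError(f"unknown roles: {sorted(bad)}")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_ids)

    @classmethod
    def from_arrays(cls, atom_names, residue_names, residue_numbers,
                    chain_ids=None, elements=None, atom_ids=None,
                    water_resnames: Iterable[str] = WATER_RESNAMES,
                    ion_resnames: Iterable[str] = ION_RESNAMES,
                    lipid_resnames: Iterable[str] = LIPID_RESNAMES) -> "Topology":
        atom_names = np.asarray(atom_names, dtype=object)
        n = len(atom_names)
        residue_names = np.asarray(residue_names, dtype=object)
        residue_numbers = np.asarray(residue_numbers, dtype=int)
        chain_ids = (np.asarray(chain_ids, dtype=object) if chain_ids is not None
                     else np.full(n, "A", dtype=object))
        if elements is None:
            elements = np.array([_guess_element(a) for a in atom_names],
                                dtype=object)
        else:
            elements = np.asarray(elements, dtype=object)
        atom_ids = (np.asarray(atom_ids, dtype=int) if atom_ids is not None
                    else np.arange(n))
        wset = {s.upper() for s in water_resnames}
        iset = {s.upper() for s in ion_resnames}
        lset = {s.upper() for s in lipid_resnames}
        roles = np.array([_assign_role(r, wset, iset, lset)
                          for r in residue_names], dtype=object)
        topo = cls(atom_ids, atom_names, elements, residue_names,
                   residue_numbers, chain_ids, roles)
        topo._check_waters()
        return topo

    def _check_waters(self) -> None:
        # every water residue must contain an oxygen; hydrogens are optional
        wmask = self.roles == "water"
        if not wmask.any():
            return
        keys = _residue_keys(self)[wmask]
        is_ox = np.array([e.upper() == "O" for e in self.elements[wmask]])
        have_ox = set(keys[is_ox])
        missing = set(keys) - have_ox
        if missing:
            raise TopologyError(
                f"{len(missing)} water residue(s) lack an oxygen atom")

    # --- convenience selections -------------------------------------------
    def water_oxygen_ids(self) -> np.ndarray:
        mask = (self.roles == "water") & np.array(
            [e.upper() == "O" for e in self.elements])
        return self.atom_ids[mask]

    def ion_ids(self, element: Optional[str] = None) -> np.ndarray:
        mask = self.roles == "ion"
        if element is not None:
            mask &= np.array([e.upper() == element.upper()
                              for e in self.elements])
        return self.atom_ids[mask]

    def index_of(self, atom_ids) -> np.ndarray:
        """Map atom_ids to row indices (atom_ids are stably ordered)."""
        order = np.argsort(self.atom_ids)
        pos = np.searchsorted(self.atom_ids, atom_ids, sorter=order)
        idx = order[pos]
        if not np.array_equal(self.atom_ids[idx], np.asarray(atom_ids)):
            raise KeyError("unknown atom_id(s)")
        return idx

    def residue_key_of(self) -> np.ndarray:
        return _residue_keys(self)


def _residue_keys(topology: Topology) -> np.ndarray:
    return np.array(
        [f"{c}:{r}:{n}" for c, r, n in zip(topology.chain_ids,
                                           topology.residue_names,
                                           topology.residue_numbers)],
        dtype=object)


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        return "X"
    # strip leading digits (e.g. 1H, 2HB)
    base = name.lstrip("0123456789")
    if not base:
        return "X"
    two = base[:2].upper()
    if two in {"CL", "NA", "MG", "BR", "ZN", "FE", "MN"} and len(base) <= 3:
        return two.capitalize()
    return base[0].upper()


@dataclass
class Trajectory:
    """Topology plus an ordered stack of coordinate frames (Å).

    ``box`` holds per-frame orthorhombic box edge lengths (Å) or None;
    minimum-image distances are applied only when a box is present.
    """

    topology: Topology
    coordinates: np.ndarray           # (n_frames, n_atoms, 3) float
    frame_interval_ns: float = 0.2
    box: Optional[np.ndarray] = None  # (n_frames, 3) or None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise TrajectoryError("coordinates must be (n_frames, n_atoms, 3)")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise TrajectoryError(
                f"frame atom count {self.coordinates.shape[1]} does not match "
                f"topology atom count {self.topology.n_atoms}")
        if not np.isfinite(self.coordinates).all():
            raise TrajectoryError("coordinates must be finite")
        if self.frame_interval_ns <= 0:
            raise TrajectoryError("frame_interval_ns must be positive")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (self.n_frames, 3):
                raise TrajectoryError("box must be (n_frames, 3)")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def duration_ns(self) -> float:
        return self.n_frames * self.frame_interval_ns

    @property
    def times_ns(self) -> np.ndarray:
        return (np.arange(self.n_frames) + 1) * self.frame_interval_ns

    def frame(self, i: int) -> np.ndarray:
        return self.coordinates[i]


@dataclass(frozen=True)
class MembraneFrame:
    """Leaflet planes defining inside/outside along the membrane normal.

    ``extracellular_sign`` is +1 when the extracellular side is +z
    (the package-wide default drawing convention).
    """

    z_inner_leaflet: float
    z_outer_leaflet: float
    normal_axis: str = "z"
    extracellular_sign: int = +1

    def __post_init__(self):
        if self.normal_axis != "z":
            raise RegionError("only a z membrane normal is supported")
        if self.extracellular_sign not in (+1, -1):
            raise RegionError("extracellular_sign must be +1 or -1")
        if self.extracellular_sign * (self.z_outer_leaflet
                                      - self.z_inner_leaflet) <= 0:
            raise RegionError(
                "z_outer_leaflet must lie on the extracellular side of "
                "z_inner_leaflet under the stated sign convention")


@dataclass(frozen=True)
class RegionSpec:
    """Declarative atom selection: attribute filters plus optional spatial
    predicates.  Resolution against a Topology (+frame, +membrane) is
    deterministic; an empty result is legal.
    """

    name: str
    residue_numbers: Optional[tuple] = None
    atom_names: Optional[tuple] = None
    chain_id: Optional[str] = None
    residue_names: Optional[tuple] = None
    role: Optional[str] = None
    # spatial predicates (require a frame; z-relative ones require membrane)
    z_below_inner: bool = False
    z_above_outer: bool = False
    sphere_center: Optional[tuple] = None
    sphere_radius: Optional[float] = None

    def needs_frame(self) -> bool:
        return (self.z_below_inner or self.z_above_outer
                or self.sphere_center is not None)

    def needs_membrane(self) -> bool:
        return self.z_below_inner or self.z_above_outer


def resolve_region(region: RegionSpec, topology: Topology,
                   frame: Optional[np.ndarray] = None,
                   membrane: Optional[MembraneFrame] = None) -> frozenset:
    """Resolve a RegionSpec to the set of matching atom_ids.

    Deterministic and order-independent; spatial predicates are evaluated
    on the supplied frame.
    """
    if region.needs_frame() and frame is None:
        raise RegionError(
            f"region '{region.name}' has a spatial predicate but no frame "
            "was supplied")
    if region.needs_membrane() and membrane is None:
        raise RegionError(
            f"region '{region.name}' has a z-relative predicate but no "
            "MembraneFrame was supplied")

    mask = np.ones(topology.n_atoms, dtype=bool)
    if region.residue_numbers is not None:
        mask &= np.isin(topology.residue_numbers,
                        np.asarray(region.residue_numbers, dtype=int))
    if region.atom_names is not None:
        wanted = {a.upper() for a in region.atom_names}
        mask &= np.array([a.upper() in wanted for a in topology.atom_names])
    if region.chain_id is not None:
        mask &= topology.chain_ids == region.chain_id
    if region.residue_names is not None:
        wanted = {r.upper() for r in region.residue_names}
        mask &= np.array([r.upper() in wanted for r in topology.residue_names])
    if region.role is not None:
        mask &= topology.roles == region.role

    if region.needs_frame():
        frame = np.asarray(frame, dtype=float)
        z = frame[:, 2]
        if region.z_below_inner:
            # "below" = intracellular of the inner leaflet plane
            if membrane.extracellular_sign > 0:
                mask &= z < membrane.z_inner_leaflet
            else:
                mask &= z > membrane.z_inner_leaflet
        if region.z_above_outer:
            if membrane.extracellular_sign > 0:
                mask &= z > membrane.z_outer_leaflet
            else:
                mask &= z < membrane.z_outer_leaflet
        if region.sphere_center is not None:
            if region.sphere_radius is None:
                raise RegionError("sphere_center requires sphere_radius")
            c = np.asarray(region.sphere_center, dtype=float)
            mask &= np.linalg.norm(frame - c, axis=1) <= region.sphere_radius

    return frozenset(int(i) for i in topology.atom_ids[mask])


@dataclass
class AtomicModel:
    """Single-structure atom table + coordinates (cryo-EM/crystal models)."""

    topology: Topology
    coordinates: np.ndarray   # (n_atoms, 3)
    source_format: str = "PDB"

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (self.topology.n_atoms, 3):
            raise TopologyError("one coordinate triple per atom required")

    def ca_mask(self) -> np.ndarray:
        return ((self.topology.roles == "protein")
                & np.array([a.strip().upper() == "CA"
                            for a in self.topology.atom_names]))


# ----------------------------------------------------------------------------
# MDAnalysis-backed file I/O
# ----------------------------------------------------------------------------

def _mda():
    import MDAnalysis as mda
    return mda


def load_topology(path, water_resnames: Iterable[str] = WATER_RESNAMES,
                  ion_resnames: Iterable[str] = ION_RESNAMES,
                  lipid_resnames: Iterable[str] = LIPID_RESNAMES) -> Topology:
    """Read a PDB file into a Topology; roles are assigned from the residue
    name tables (unknown residue names become role 'other' with a warning).
    """
    mda = _mda()
    path = Path(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:  # unparseable file
        raise TopologyError(f"cannot parse topology file {path}: {exc}") from exc
    ag = u.atoms
    chain_ids = (ag.chainIDs if hasattr(ag, "chainIDs")
                 else np.full(len(ag), "A", dtype=object))
    chain_ids = np.array([c if str(c).strip() else "A" for c in chain_ids],
                         dtype=object)
    try:
        elements = np.asarray(ag.elements, dtype=object)
        elements = np.array(
            [e if str(e).strip() else _guess_element(n)
             for e, n in zip(elements, ag.names)], dtype=object)
    except Exception:
        elements = None
    topo = Topology.from_arrays(
        atom_names=np.asarray(ag.names, dtype=object),
        residue_names=np.asarray(ag.resnames, dtype=object),
        residue_numbers=np.asarray(ag.resids, dtype=int),
        chain_ids=chain_ids,
        elements=elements,
        water_resnames=water_resnames, ion_resnames=ion_resnames,
        lipid_resnames=lipid_resnames)
    n_other = int((topo.roles == "other").sum())
    if n_other:
        warnings.warn(f"{n_other} atom(s) with unrecognized residue names "
                      "assigned role 'other'", stacklevel=2)
    return topo


_TRAJ_READERS = {".dcd": "DCD", ".xtc": "XTC", ".pdb": "PDB"}


def load_trajectory(topology: Topology, paths,
                    frame_interval_ns: float = 0.2) -> Trajectory:
    """Read DCD/XTC (or multi-model PDB fixture) frames against a Topology.

    Atom-count mismatch is a hard error; a truncated file raises an error
    naming the last good frame.
    """
    mda = _mda()
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames, boxes = [], []
    for path in paths:
        path = Path(path)
        fmt = _TRAJ_READERS.get(path.suffix.lower())
        if fmt is None:
            raise TrajectoryError(f"unsupported trajectory format: {path}")
        reader_cls = {"DCD": mda.coordinates.DCD.DCDReader,
                      "XTC": mda.coordinates.XTC.XTCReader,
                      "PDB": mda.coordinates.PDB.PDBReader}[fmt]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reader = reader_cls(str(path))
        if reader.n_atoms != topology.n_atoms:
            raise TrajectoryError(
                f"{path}: frame atom count {reader.n_atoms} does not match "
                f"topology atom count {topology.n_atoms}")
        try:
            for ts in reader:
                frames.append(np.array(ts.positions, dtype=float))
                dims = ts.dimensions
                if dims is not None and np.all(np.asarray(dims[:3]) > 0):
                    boxes.append(np.asarray(dims[:3], dtype=float))
                else:
                    boxes.append(None)
        except (EOFError, OSError, ValueError) as exc:
            raise TrajectoryError(
                f"{path}: truncated after frame {len(frames)}: {exc}") from exc
        finally:
            reader.close()
    if not frames:
        raise TrajectoryError("no frames read")
    box = None
    if all(b is not None for b in boxes):
        box = np.stack(boxes)
    return Trajectory(topology=topology, coordinates=np.stack(frames),
                      frame_interval_ns=frame_interval_ns, box=box)


def _to_universe(topology: Topology, coordinates: np.ndarray):
    """Build an in-memory MDAnalysis Universe for writing fixtures."""
    mda = _mda()
    from MDAnalysis.coordinates.memory import MemoryReader
    coords = np.asarray(coordinates, dtype=np.float32)
    if coords.ndim == 2:
        coords = coords[None]
    n = topology.n_atoms
    keys = _residue_keys(topology)
    # residues numbered in file order
    seen, res_of_atom, res_order = {}, np.empty(n, dtype=int), []
    for i, k in enumerate(keys):
        if k not in seen:
            seen[k] = len(seen)
            res_order.append(i)
        res_of_atom[i] = seen[k]
    n_res = len(seen)
    u = mda.Universe.empty(n, n_residues=n_res, atom_resindex=res_of_atom,
                           residue_segindex=np.zeros(n_res, dtype=int),
                           trajectory=True)
    u.add_TopologyAttr("names", [str(a) for a in topology.atom_names])
    u.add_TopologyAttr("elements", [str(e) for e in topology.elements])
    u.add_TopologyAttr("resnames",
                       [str(topology.residue_names[i]) for i in res_order])
    u.add_TopologyAttr("resids",
                       [int(topology.residue_numbers[i]) for i in res_order])
    u.add_TopologyAttr("chainIDs", [str(c) for c in topology.chain_ids])
    u.add_TopologyAttr("segids", ["SYS"])
    u.load_new(coords, format=MemoryReader)
    return u


def write_pdb(topology: Topology, coordinates: np.ndarray, path) -> None:
    """Write a single- or multi-model PDB (fixture format)."""
    mda = _mda()
    u = _to_universe(topology, coordinates)
    multiframe = np.asarray(coordinates).ndim == 3
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=topology.n_atoms,
                        multiframe=multiframe) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


def write_dcd(topology: Topology, coordinates: np.ndarray, path,
              box: Optional[np.ndarray] = None) -> None:
    """Write frames to a DCD file."""
    mda = _mda()
    u = _to_universe(topology, coordinates)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=topology.n_atoms,
                        format="DCD") as w:
            for i, _ in enumerate(u.trajectory):
                if box is not None:
                    u.dimensions = [box[i][0], box[i][1], box[i][2],
                                    90.0, 90.0, 90.0]
                w.write(u.atoms)


def minimum_image_deltas(deltas: np.ndarray,
                         box: Optional[np.ndarray]) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors for an
    orthorhombic box (edge lengths in Å); no-op when box is None."""
    if box is None:
        return deltas
    box = np.asarray(box, dtype=float)
    return deltas - box * np.round(deltas / box)
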