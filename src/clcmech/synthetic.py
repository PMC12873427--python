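"""Seeded generators producing fixtures with known ground truth for every
pipeline stage: planted water-wire trajectories, programmed ion random
walks, density grids with Gaussian blobs, two-timescale deuterium-uptake
curves, and flux traces with programmed per-transporter rates.

Identical generator arguments (including the seed) produce bit-identical
fixtures.  Each generator returns the in-memory objects the analysis
modules consume plus a ground-truth record; optional writers emit the
same standard formats the real pipeline reads (PDB/DCD, MRC, TSV) with a
JSON ground-truth sidecar, so the file readers are exercised rather than
bypassed.

The fixtures are geometric/statistical stand-ins, not physical
simulations: planted water chains have ideal hydrogen-bond geometry with
small positional jitter, ion exits are deterministic drifts, and noise is
Gaussian throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (MembraneFrame, RegionSpec, Topology, Trajectory,
                   write_dcd, write_pdb)
from .flux import AssayParams, FluxTrace, AVOGADRO
from .hdx import FDControl, IntrinsicRateModel, UptakeCurve, intrinsic_rate, \
    PAPER_TIMEPOINTS_S
from .ions import IonEventConfig, default_ion_region, default_reference_region
from .structure import DensityMap
from .wires import WireClassDef, WireEndpoints

__all__ = ["make_wire_fixture", "make_ion_walk", "make_density_fixture",
           "make_hdx_curves", "make_flux_trace", "WireFixture",
           "IonWalkFixture", "DensityFixture", "HdxFixture", "FluxFixture",
           "default_class_defs", "write_wire_fixture", "write_ion_fixture",
           "write_density_fixture", "write_hdx_fixture", "write_flux_fixture"]

_WATER_SPACING_MIN = 2.4
_WATER_SPACING_MAX = 3.4
_OH_BOND = 0.96

# membrane frame shared by MD-like fixtures (Å; extracellular = +z)
_Z_INNER, _Z_OUTER = -15.0, 15.0


# ---------------------------------------------------------------------------
# shared fixture topology for wire scenarios
# ---------------------------------------------------------------------------

# static protein marker atoms: gating glutamate, inner-gate pair, and the
# class-2 (H+-pathway glutamates) and class-3 (interface) shells
_PROTEIN_ATOMS = [
    # (atom_name, element, resname, resnum, position)
    ("OE1", "O", "GLU", 148, (0.0, 0.0, -1.0)),     # E_gate carboxylate
    ("OH", "O", "TYR", 445, (2.0, 0.0, -1.0)),      # anion-pathway proxy
    ("OG", "O", "SER", 107, (2.0, 0.0, -4.0)),
    ("CD", "C", "GLU", 202, (4.0, 0.0, -8.0)),
    ("CD", "C", "GLU", 203, (4.0, 2.0, -10.0)),
    ("CD", "C", "GLU", 113, (4.0, -2.0, -6.0)),
    ("CZ", "C", "PHE", 402, (-4.0, 0.0, -8.0)),
    ("CD1", "C", "LEU", 406, (-4.0, 2.0, -10.0)),
    ("CB", "C", "ALA", 399, (-4.0, -2.0, -6.0)),
]

_ROUTE_DX = {1: 0.0, 2: 2.8, 3: -2.8}   # lateral bend toward each shell


def default_membrane() -> MembraneFrame:
    return MembraneFrame(z_inner_leaflet=_Z_INNER, z_outer_leaflet=_Z_OUTER)


def default_class_defs() -> list:
    """Shipped wire-class shells (interpretive; configurable).

    Class 1: anion-pathway lining (inner-gate S107/Y445 proxies);
    class 2: H+-pathway glutamate shell (E202/E203/E113);
    class 3: adjacent subunit-interface shell.
    """
    return [
        WireClassDef(class_id=1, required_source="anion_pathway",
                     lining_shell=RegionSpec(name="anion_pathway_shell",
                                             residue_numbers=(107, 445))),
        WireClassDef(class_id=2, required_source="egate_out",
                     lining_shell=RegionSpec(name="h_pathway_shell",
                                             residue_numbers=(202, 203, 113))),
        WireClassDef(class_id=3, required_source="egate_out",
                     lining_shell=RegionSpec(name="interface_shell",
                                             residue_numbers=(402, 406, 399))),
    ]


def _wire_topology(chain_length: int, n_decoys: int) -> Topology:
    names, elements, resnames, resnums = [], [], [], []
    for an, el, rn, num, _ in _PROTEIN_ATOMS:
        names.append(an)
        elements.append(el)
        resnames.append(rn)
        resnums.append(num)
    next_res = 1000
    for _ in range(chain_length + n_decoys):
        for an, el in (("O", "O"), ("H1", "H"), ("H2", "H")):
            names.append(an)
            elements.append(el)
            resnames.append("HOH")
            resnums.append(next_res)
        next_res += 1
    return Topology.from_arrays(atom_names=names, residue_names=resnames,
                                residue_numbers=resnums, elements=elements)


def _polyline_points(waypoints: np.ndarray, n_points: int) -> np.ndarray:
    """n_points equally spaced (by arc length) along a polyline, excluding
    the first waypoint and ending exactly at the last."""
    seg = np.diff(waypoints, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    total = seg_len.sum()
    s_targets = np.linspace(total / n_points, total, n_points)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    pts = []
    for s in s_targets:
        k = min(np.searchsorted(cum, s, side="right") - 1, len(seg) - 1)
        frac = (s - cum[k]) / seg_len[k]
        pts.append(waypoints[k] + frac * seg[k])
    return np.array(pts)


def _unit(v):
    return v / np.linalg.norm(v)


@dataclass
class WireFixture:
    trajectory: Trajectory
    endpoints: WireEndpoints
    membrane: MembraneFrame
    class_defs: list
    source_tag: str
    truth: dict


def make_wire_fixture(n_frames: int = 200, chain_length: int = 5,
                      wire_probability: float = 1.0, n_decoys: int = 50,
                      class_route: int = 2, seed: int = 0,
                      frame_interval_ns: float = 0.2,
                      jitter: float = 0.05) -> WireFixture:
    """Trajectory with a planted hydrogen-bonded water chain from the
    source to bulk intracellular solvent, present per frame with
    ``wire_probability``, plus decoy waters disconnected from it.

    The chain runs from the source endpoint through the requested class
    shell to below the inner leaflet; oxygens are spaced evenly along the
    route (error if the spacing leaves the hydrogen-bond window), each
    water's first hydrogen points at the next oxygen and the first water's
    second hydrogen points back at the source, giving ideal near-linear
    geometry.  In unwired frames one mid-chain water is displaced beyond
    the cutoff.  Ground truth lists wired frames and node sequences.
    """
    if chain_length < 2:
        raise ValueError("chain_length must be >= 2")
    if not (0 <= wire_probability <= 1):
        raise ValueError("wire_probability must be in [0, 1]")
    if class_route not in (1, 2, 3):
        raise ValueError("class_route must be 1, 2, or 3")
    rng = np.random.default_rng(seed)
    topo = _wire_topology(chain_length, n_decoys)

    source_tag = "anion_pathway" if class_route == 1 else "egate_out"
    src_atom = 1 if class_route == 1 else 0       # Y445 OH vs E148 OE1
    src_pos = np.array(_PROTEIN_ATOMS[src_atom][4])
    dx = _ROUTE_DX[class_route]
    # route = two straight segments (source -> shell bend -> below leaflet)
    # with total arc length chain_length * 2.8 Å so the waters sit at the
    # canonical O-O hydrogen-bond distance; the inner-leaflet plane is
    # placed 1 Å above the chain terminus so the last water is bulk
    spacing = 2.8
    half = chain_length * spacing / 2.0
    if half ** 2 - dx ** 2 < 1.0:
        raise ValueError(
            f"chain of {chain_length} waters cannot span the class-"
            f"{class_route} route at hydrogen-bond spacing")
    h = np.sqrt(half ** 2 - dx ** 2)
    if 2 * h > 60.0:
        raise ValueError(
            f"chain of {chain_length} waters exceeds the fixture box")
    z_inner = src_pos[2] - 2 * h + 1.0
    membrane = MembraneFrame(z_inner_leaflet=z_inner,
                             z_outer_leaflet=_Z_OUTER)
    waypoints = np.array([src_pos,
                          [src_pos[0] + dx, 0.0, src_pos[2] - h],
                          [src_pos[0], 0.0, src_pos[2] - 2 * h]])
    chain = _polyline_points(waypoints, chain_length)

    # decoy oxygens on a jittered grid in a slab far (in x) from the chain
    grid = []
    for ix in range(6):
        for iy in range(8):
            for iz in range(10):
                grid.append((12.0 + 3.0 * ix, -10.0 + 3.0 * iy,
                             z_inner - 6.0 + 3.0 * iz))
    decoys = np.array(grid[:n_decoys])
    if len(decoys) < n_decoys:
        raise ValueError(f"at most {len(grid)} decoys supported")

    n_prot = len(_PROTEIN_ATOMS)
    prot_pos = np.array([a[4] for a in _PROTEIN_ATOMS])
    chain_oxy_rows = n_prot + 3 * np.arange(chain_length)
    decoy_oxy_rows = n_prot + 3 * (chain_length + np.arange(n_decoys))
    break_row = chain_oxy_rows[chain_length // 2]

    wired = rng.random(n_frames) < wire_probability
    coords = np.empty((n_frames, topo.n_atoms, 3))
    truth_nodes = []
    chain_ids = [int(topo.atom_ids[r]) for r in chain_oxy_rows]
    src_id = int(topo.atom_ids[src_atom])
    for f in range(n_frames):
        frame = np.zeros((topo.n_atoms, 3))
        frame[:n_prot] = prot_pos
        cpos = chain + rng.normal(0.0, jitter, size=chain.shape)
        dpos = decoys + rng.normal(0.0, 0.3, size=decoys.shape)
        for i, row in enumerate(chain_oxy_rows):
            o = cpos[i]
            nxt = cpos[i + 1] if i + 1 < chain_length else \
                o + np.array([0.0, 0.0, -2.75])
            frame[row] = o
            frame[row + 1] = o + _OH_BOND * _unit(nxt - o)       # H1 -> next
            back = src_pos if i == 0 else np.array([0.0, 1.0, 0.0]) + o
            frame[row + 2] = o + _OH_BOND * _unit(back - o)      # H2
        for i, row in enumerate(decoy_oxy_rows):
            o = dpos[i]
            frame[row] = o
            frame[row + 1] = o + np.array([_OH_BOND, 0.0, 0.0])
            frame[row + 2] = o + np.array([0.0, _OH_BOND, 0.0])
        if not wired[f]:
            frame[break_row:break_row + 3] += np.array([0.0, 8.0, 0.0])
            truth_nodes.append(None)
        else:
            truth_nodes.append([src_id] + chain_ids)
        coords[f] = frame

    traj = Trajectory(topology=topo, coordinates=coords,
                      frame_interval_ns=frame_interval_ns)
    if class_route == 1:
        source = RegionSpec(name="anion_pathway_site",
                            residue_numbers=(445,), atom_names=("OH",))
    else:
        source = RegionSpec(name="egate_out", residue_numbers=(148,),
                            atom_names=("OE1", "OE2"))
    sink = RegionSpec(name="bulk_intracellular", role="water",
                      atom_names=("O",), z_below_inner=True)
    truth = {"wired_frames": wired.tolist(),
             "node_ids": truth_nodes,
             "wire_probability": wire_probability,
             "class_route": class_route,
             "chain_length": chain_length,
             "z_inner_leaflet": float(z_inner),
             "seed": seed}
    return WireFixture(trajectory=traj,
                       endpoints=WireEndpoints(source=source, sink=sink),
                       membrane=membrane,
                       class_defs=default_class_defs(),
                       source_tag=source_tag, truth=truth)


# ---------------------------------------------------------------------------
# ion random walks
# ---------------------------------------------------------------------------

@dataclass
class IonWalkFixture:
    trajectory: Trajectory
    config: IonEventConfig
    membrane: MembraneFrame
    pathway_sites: RegionSpec
    truth: dict


def make_ion_walk(duration_ns: float = 1500.0,
                  exit_time_ns=900.0, direction="extracellular",
                  noise: float = 0.5, seed: int = 0,
                  frame_interval_ns: float = 0.2,
                  drift_rate: float = 1.0) -> IonWalkFixture:
    """Ion(s) fluctuating 4-6 Å from the inner-gate reference until a
    programmed exit time, then drifting monotonically past bulk distance
    toward the requested side of the membrane.

    ``exit_time_ns``/``direction`` may be scalars (one ion) or equal-length
    sequences (staggered multi-ion scenarios); exit None keeps the ion
    bound for the whole run.
    """
    exits = exit_time_ns if isinstance(exit_time_ns, (list, tuple)) \
        else [exit_time_ns]
    dirs = direction if isinstance(direction, (list, tuple)) \
        else [direction] * len(exits)
    if len(dirs) != len(exits):
        raise ValueError("exit_time_ns and direction length mismatch")
    for d in dirs:
        if d not in ("extracellular", "intracellular"):
            raise ValueError(f"unknown direction '{d}'")
    for e in exits:
        if e is not None and not (0 < e < duration_ns):
            raise ValueError("exit times must fall inside the run")
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_ns / frame_interval_ns))

    names = ["OH", "OG"] + ["CLA"] * len(exits)
    elements = ["O", "O"] + ["Cl"] * len(exits)
    resnames = ["TYR", "SER"] + ["CLA"] * len(exits)
    resnums = [445, 107] + [900 + i for i in range(len(exits))]
    topo = Topology.from_arrays(atom_names=names, residue_names=resnames,
                                residue_numbers=resnums, elements=elements)

    times = (np.arange(n_frames) + 1) * frame_interval_ns
    coords = np.zeros((n_frames, topo.n_atoms, 3))
    coords[:, 1] = np.array([0.0, 0.0, -3.0])        # S107 OG, static gate
    for k, (e, d) in enumerate(zip(exits, dirs)):
        sign = +1.0 if d == "extracellular" else -1.0
        # bound phase: ion on the pathway axis at 4-6 Å from the reference
        # (distance fluctuates with the requested noise), small xy wobble
        r_bound = np.clip(5.0 + rng.normal(0.0, noise, n_frames), 3.5, 7.0)
        xy = rng.normal(0.0, 0.8, size=(n_frames, 2))
        pos = np.zeros((n_frames, 3))
        pos[:, :2] = xy
        pos[:, 2] = sign * np.sqrt(np.maximum(
            r_bound ** 2 - (xy ** 2).sum(axis=1), 4.0))
        if e is not None:
            after = times > e
            dt = times[after] - e
            # committed exit: monotone drift along the membrane normal,
            # past the 15 Å bulk cutoff and onward
            pos[after, 0] = rng.normal(0.0, 0.3, after.sum())
            pos[after, 1] = rng.normal(0.0, 0.3, after.sum())
            pos[after, 2] = sign * (6.0 + drift_rate * dt)
        coords[:, 2 + k] = pos
    traj = Trajectory(topology=topo, coordinates=coords,
                      frame_interval_ns=frame_interval_ns)
    truth = {"exit_times_ns": [None if e is None else float(e)
                               for e in exits],
             "directions": list(dirs), "noise": noise, "seed": seed,
             "duration_ns": duration_ns}
    return IonWalkFixture(
        trajectory=traj, config=IonEventConfig(),
        membrane=default_membrane(),
        pathway_sites=RegionSpec(name="pathway_sites",
                                 residue_numbers=(445,), atom_names=("OH",)),
        truth=truth)


# ---------------------------------------------------------------------------
# density maps
# ---------------------------------------------------------------------------

@dataclass
class DensityFixture:
    map: DensityMap
    truth: dict


def make_density_fixture(grid_shape=(64, 64, 64), voxel: float = 1.0,
                         blob_centers=((32.0, 32.0, 32.0),),
                         blob_sigmas=(2.0,), blob_peak_sigmas=(8.0,),
                         noise_sd: float = 1.0, noise_mean: float = 0.0,
                         seed: int = 0) -> DensityFixture:
    """Gaussian noise floor with planted blobs of known peak z-score.

    Each blob's center value is set by construction to
    noise_mean_realized + peak_sigma * noise_sd_realized, blended into the
    noise with a Gaussian profile, so the planted z-score at the center is
    exact up to the (negligible for small blobs) effect of the blob on the
    whole-map statistics.
    """
    rng = np.random.default_rng(seed)
    data = rng.normal(noise_mean, noise_sd, size=grid_shape)
    mu, sd = float(data.mean()), float(data.std(ddof=0))
    idx = np.indices(grid_shape).astype(float)
    for c, s, z in zip(blob_centers, blob_sigmas, blob_peak_sigmas):
        cv = np.asarray(c, dtype=float) / voxel
        if np.any(cv < 0) or np.any(cv > np.array(grid_shape) - 1):
            raise ValueError(f"blob center {c} outside the grid")
        r2 = ((idx[0] - cv[0]) ** 2 + (idx[1] - cv[1]) ** 2
              + (idx[2] - cv[2]) ** 2)
        w = np.exp(-r2 / (2.0 * (s / voxel) ** 2))
        data = data * (1 - w) + (mu + z * sd) * w
    dmap = DensityMap(data=data, voxel_size=np.full(3, voxel),
                      origin=np.zeros(3))
    truth = {"blob_centers": [list(map(float, c)) for c in blob_centers],
             "blob_sigmas": list(map(float, blob_sigmas)),
             "planted_peak_sigmas": list(map(float, blob_peak_sigmas)),
             "noise_mean": mu, "noise_sd": sd, "seed": seed}
    return DensityFixture(map=dmap, truth=truth)


# ---------------------------------------------------------------------------
# HDX uptake curves
# ---------------------------------------------------------------------------

@dataclass
class HdxFixture:
    curves: dict        # (peptide_id, pH) -> UptakeCurve
    fd_controls: dict   # peptide_id -> FDControl
    model: IntrinsicRateModel
    truth: dict


def make_hdx_curves(peptides=(("p1", 10, 20),),
                    protection_factors=(1000.0,),
                    pH_list=(6.5, 4.5),
                    timepoints=PAPER_TIMEPOINTS_S,
                    fd_efficiency: float = 0.9, noise: float = 0.02,
                    seed: int = 0,
                    model: Optional[IntrinsicRateModel] = None) -> HdxFixture:
    """Two-timescale exponential uptake curves with known protection
    factors: D(t) = N (1 - exp(-k_int(pH) t / P)) * fd_efficiency + noise.

    ``protection_factors`` may give one P per peptide (same at every pH)
    or a dict {(peptide_id, pH): P} for pH-dependent protection.
    """
    model = model or IntrinsicRateModel()
    rng = np.random.default_rng(seed)
    t = np.asarray(timepoints, dtype=float)
    curves, truth_p = {}, {}
    if not isinstance(protection_factors, dict):
        protection_factors = {
            (pep[0], ph): p
            for pep, p in zip(peptides, protection_factors)
            for ph in pH_list}
    fd_controls = {}
    for pid, start, end in peptides:
        n_amides = max(end - start, 1)
        fd_controls[pid] = FDControl(peptide_id=pid,
                                     fd_level=n_amides * fd_efficiency)
        for ph in pH_list:
            p = protection_factors[(pid, ph)]
            if p <= 0:
                raise ValueError("protection factors must be positive")
            k = intrinsic_rate(model, ph)
            d = n_amides * (1.0 - np.exp(-k * t / p)) * fd_efficiency
            d = np.clip(d + rng.normal(0.0, noise * n_amides, size=t.shape),
                        0.0, None)
            d = np.maximum.accumulate(d)      # uptake is monotone in time
            curves[(pid, ph)] = UptakeCurve(
                peptide_id=pid, start_residue=start, end_residue=end,
                pH=ph, timepoints_s=t, deuteration=d)
            truth_p[f"{pid}@pH{ph}"] = {"protection_factor": float(p),
                                        "k_int": float(k),
                                        "n_amides": n_amides}
    truth = {"per_curve": truth_p, "fd_efficiency": fd_efficiency,
             "noise": noise, "seed": seed}
    return HdxFixture(curves=curves, fd_controls=fd_controls, model=model,
                      truth=truth)


# ---------------------------------------------------------------------------
# flux traces
# ---------------------------------------------------------------------------

@dataclass
class FluxFixture:
    trace: FluxTrace
    params: AssayParams
    truth: dict


def make_flux_trace(cl_rate: float = 2300.0, h_rate: float = 1150.0,
                    n_transporters: float = 1e11,
                    valinomycin_time: float = 10.0,
                    noise: float = 1e-4, seed: int = 0,
                    duration_s: float = 60.0, dt: float = 0.05,
                    volume_L: float = 6e-4,
                    buffering_capacity: float = 1e-3,
                    cl0_mM: float = 0.05, pH0: float = 4.5) -> FluxFixture:
    """Electrode traces: flat before valinomycin, then linear segments
    whose slopes encode the programmed per-transporter rates.

    Defaults mimic a wild-type-like coupled assay (Cl- release and H+
    uptake at a 2:1 rate ratio) in a 600 µL extravesicular volume; the
    transporter count and buffering capacity are stated assumptions.
    ``noise`` is the pH-trace noise SD; the chloride trace uses 10x that
    (mM scale).
    """
    if cl_rate < 0 or h_rate < 0:
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s + dt / 2, dt)
    cl_slope_mM = cl_rate * n_transporters / AVOGADRO / volume_L * 1e3
    ph_slope = h_rate * n_transporters / AVOGADRO / (buffering_capacity
                                                     * volume_L)
    ramp = np.clip(t - valinomycin_time, 0.0, None)
    cl = cl0_mM + cl_slope_mM * ramp + rng.normal(0, noise * 10, t.shape)
    ph = pH0 + ph_slope * ramp + rng.normal(0, noise, t.shape)
    trace = FluxTrace(time_s=t, chloride_mM=cl, pH=ph,
                      valinomycin_time_s=valinomycin_time,
                      calibration={"extravesicular_volume_L": volume_L,
                                   "buffering_capacity": buffering_capacity})
    params = AssayParams(n_transporters=n_transporters,
                         extravesicular_volume_L=volume_L,
                         buffering_capacity=buffering_capacity)
    stoich = cl_rate / h_rate if h_rate > 0 else None
    truth = {"cl_rate": cl_rate, "h_rate": h_rate, "stoichiometry": stoich,
             "n_transporters": n_transporters, "seed": seed}
    return FluxFixture(trace=trace, params=params, truth=truth)


# ---------------------------------------------------------------------------
# writers (fixtures on disk in the formats the pipeline reads)
# ---------------------------------------------------------------------------

def _dump_truth(truth: dict, out_dir: Path, name: str) -> None:
    with open(out_dir / name, "w") as fh:
        json.dump(truth, fh, indent=1)


def write_wire_fixture(fx: WireFixture, out_dir) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_pdb(fx.trajectory.topology, fx.trajectory.coordinates[0],
              out / "topology.pdb")
    write_dcd(fx.trajectory.topology, fx.trajectory.coordinates,
              out / "frames.dcd")
    _dump_truth(fx.truth, out, "truth.json")
    return {"topology": str(out / "topology.pdb"),
            "frames": str(out / "frames.dcd"),
            "truth": str(out / "truth.json")}


def write_ion_fixture(fx: IonWalkFixture, out_dir) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_pdb(fx.trajectory.topology, fx.trajectory.coordinates[0],
              out / "topology.pdb")
    write_dcd(fx.trajectory.topology, fx.trajectory.coordinates,
              out / "frames.dcd")
    _dump_truth(fx.truth, out, "truth.json")
    return {"topology": str(out / "topology.pdb"),
            "frames": str(out / "frames.dcd"),
            "truth": str(out / "truth.json")}


def write_density_fixture(fx: DensityFixture, out_dir) -> dict:
    from .structure import write_map
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_map(fx.map, out / "map.mrc")
    _dump_truth(fx.truth, out, "truth.json")
    return {"map": str(out / "map.mrc"), "truth": str(out / "truth.json")}


def write_hdx_fixture(fx: HdxFixture, out_dir) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for (pid, ph), c in sorted(fx.curves.items()):
        for t, d in zip(c.timepoints_s, c.deuteration):
            rows.append({"peptide": pid, "start": c.start_residue,
                         "end": c.end_residue, "pH": ph, "time_s": t,
                         "deuteration": d, "sd": ""})
    pd.DataFrame(rows).to_csv(out / "uptake.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"peptide": pid, "fd_level": fd.fd_level}
         for pid, fd in sorted(fx.fd_controls.items())]
    ).to_csv(out / "fd_controls.tsv", sep="\t", index=False)
    _dump_truth(fx.truth, out, "truth.json")
    return {"uptake": str(out / "uptake.tsv"),
            "fd_controls": str(out / "fd_controls.tsv"),
            "truth": str(out / "truth.json")}


def write_flux_fixture(fx: FluxFixture, out_dir) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_s": fx.trace.time_s,
                  "chloride_mM": fx.trace.chloride_mM,
                  "pH": fx.trace.pH}).to_csv(out / "flux.tsv", sep="\t",
                                             index=False)
    meta = dict(fx.truth)
    meta["valinomycin_time_s"] = fx.trace.valinomycin_time_s
    meta["extravesicular_volume_L"] = fx.params.extravesicular_volume_L
    meta["buffering_capacity"] = fx.params.buffering_capacity
    _dump_truth(meta, out, "truth.json")
    return {"flux": str(out / "flux.tsv"), "truth": str(out / "truth.json")}
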