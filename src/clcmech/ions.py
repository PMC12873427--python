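"""Ion-residue distance series, smoothing, unbinding-event detection,
exit-direction assignment, occupancy fractions, and inner-gate tracking.

The central observable is the distance from the inner-gate tyrosine
(Y445, hydroxyl oxygen by default) to the nearest Cl- ion: a smoothed
value above 12 Å means no Cl- occupies the anion-binding sites.  Series
are smoothed with a centered moving average whose window is the nearest
odd number of frames to window_ns / frame_interval (20 ns at 0.2 ns per
frame -> 101 frames), with shrinking windows at the edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (MembraneFrame, RegionSpec, Topology, Trajectory,
                   minimum_image_deltas, resolve_region)

__all__ = ["IonEventConfig", "DistanceSeries", "LeavingEvent", "GateSeries",
           "min_distance_series", "smooth_series", "detect_unbinding",
           "assign_direction", "occupancy_fraction", "gate_series",
           "run_shows_leaving"]


def default_reference_region() -> RegionSpec:
    return RegionSpec(name="Y445_OH", residue_numbers=(445,),
                      atom_names=("OH",))


def default_ion_region() -> RegionSpec:
    return RegionSpec(name="chloride", role="ion",
                      residue_names=("CL", "CLA", "CL-"))


@dataclass(frozen=True)
class IonEventConfig:
    reference_region: RegionSpec = field(default_factory=default_reference_region)
    ion_selection: RegionSpec = field(default_factory=default_ion_region)
    unbound_threshold: float = 12.0   # Å
    window_ns: float = 20.0

    def __post_init__(self):
        if self.unbound_threshold <= 0:
            raise ValueError("unbound_threshold must be positive")


@dataclass
class DistanceSeries:
    times_ns: np.ndarray
    raw_values: np.ndarray                 # Å
    smoothed_values: Optional[np.ndarray] = None
    label: str = ""

    def __post_init__(self):
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        self.raw_values = np.asarray(self.raw_values, dtype=float)
        if self.times_ns.shape != self.raw_values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times_ns) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.raw_values < 0):
            raise ValueError("distances must be non-negative")
        if self.smoothed_values is not None:
            self.smoothed_values = np.asarray(self.smoothed_values, dtype=float)
            if self.smoothed_values.shape != self.raw_values.shape:
                raise ValueError("smoothed series length mismatch")

    @property
    def n_frames(self) -> int:
        return len(self.raw_values)

    @property
    def frame_interval_ns(self) -> float:
        return float(self.times_ns[1] - self.times_ns[0])

    @property
    def values(self) -> np.ndarray:
        """Smoothed values when available, raw otherwise."""
        return (self.smoothed_values if self.smoothed_values is not None
                else self.raw_values)

    def to_frame(self) -> pd.DataFrame:
        d = {"time_ns": self.times_ns, "raw": self.raw_values}
        if self.smoothed_values is not None:
            d["smoothed"] = self.smoothed_values
        return pd.DataFrame(d)


@dataclass
class LeavingEvent:
    simulation_id: str
    ion_id: Optional[int]
    crossing_frame: int
    crossing_time_ns: float
    direction: str = "unset"     # extracellular | intracellular | indeterminate


@dataclass
class GateSeries:
    series: DistanceSeries
    open_threshold: float = 6.0

    def open_fraction(self) -> float:
        return float(np.mean(self.series.values > self.open_threshold))


def _pair_min_distances(traj: Trajectory, ref_rows: np.ndarray,
                        ion_rows: np.ndarray) -> np.ndarray:
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        frame = traj.coordinates[f]
        box = traj.box[f] if traj.box is not None else None
        deltas = frame[ion_rows][None, :, :] - frame[ref_rows][:, None, :]
        deltas = minimum_image_deltas(deltas, box)
        out[f] = np.sqrt((deltas ** 2).sum(axis=2)).min()
    return out


def min_distance_series(traj: Trajectory, config: IonEventConfig,
                        label: str = "") -> DistanceSeries:
    """Per-frame minimum distance between the reference atoms and any
    selected ion, minimum-image aware."""
    topo = traj.topology
    ref = resolve_region(config.reference_region, topo)
    ions = resolve_region(config.ion_selection, topo)
    if not ref:
        raise ValueError(
            f"reference region '{config.reference_region.name}' is empty")
    if not ions:
        raise ValueError(
            f"ion selection '{config.ion_selection.name}' is empty "
            "(distinct from ions being far away)")
    ref_rows = topo.index_of(sorted(ref))
    ion_rows = topo.index_of(sorted(ions))
    raw = _pair_min_distances(traj, ref_rows, ion_rows)
    return DistanceSeries(times_ns=traj.times_ns, raw_values=raw,
                          label=label or config.reference_region.name)


def window_frames(window_ns: float, frame_interval_ns: float) -> int:
    """Odd centered-window width in frames for a given time window.

    window_ns / frame_interval rounded to the nearest integer, then up to
    the next odd number (20 ns at 0.2 ns/frame -> 100 -> 101 frames)."""
    if window_ns < frame_interval_ns * (1 - 1e-9):
        raise ValueError("window_ns must be at least the frame interval")
    n = int(round(window_ns / frame_interval_ns))
    return max(n if n % 2 == 1 else n + 1, 1)


def smooth_series(series: DistanceSeries, window_ns: float = 20.0,
                  mode: str = "centered") -> DistanceSeries:
    """Moving-average smoothing.

    'centered' (default) uses an odd window with shrinking edges;
    'trailing' averages over the preceding window only.
    """
    w = window_frames(window_ns, series.frame_interval_ns)
    s = pd.Series(series.raw_values)
    if mode == "centered":
        sm = s.rolling(window=w, center=True, min_periods=1).mean()
    elif mode == "trailing":
        sm = s.rolling(window=w, center=False, min_periods=1).mean()
    else:
        raise ValueError(f"unknown smoothing mode '{mode}'")
    return replace(series, smoothed_values=sm.to_numpy())


def detect_unbinding(series: DistanceSeries, threshold: float = 12.0,
                     simulation_id: str = "", ion_id: Optional[int] = None,
                     use_raw: bool = False) -> list:
    """One event per upward crossing of the threshold by the smoothed
    series (raw-trace mode available for sensitivity analysis).

    A trajectory "shows leaving" when it has at least one event and the
    series ends above threshold.
    """
    if not use_raw and series.smoothed_values is None:
        raise ValueError("series must be smoothed (or pass use_raw=True)")
    vals = series.raw_values if use_raw else series.smoothed_values
    above = vals > threshold
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    events = []
    for f in crossings:
        events.append(LeavingEvent(simulation_id=simulation_id, ion_id=ion_id,
                                   crossing_frame=int(f),
                                   crossing_time_ns=float(series.times_ns[f])))
    return events


def shows_leaving(series: DistanceSeries, threshold: float = 12.0) -> bool:
    events = detect_unbinding(series, threshold)
    return bool(events) and series.values[-1] > threshold


def run_shows_leaving(series_per_ion: Sequence[DistanceSeries],
                      threshold: float = 12.0) -> bool:
    """A run shows Cl- leaving when every pathway ion ends unbound with at
    least one crossing (both ions left the permeation pathway)."""
    return all(shows_leaving(s, threshold) for s in series_per_ion)


def assign_direction(traj: Trajectory, event: LeavingEvent,
                     membrane: MembraneFrame, pathway_sites: RegionSpec,
                     bulk_cutoff: float = 15.0) -> str:
    """Direction of an unbinding event.

    The ion's z displacement from the pathway-site centroid is read at the
    first post-crossing frame where the ion is beyond ``bulk_cutoff`` from
    the centroid (the ion is then committed); 'indeterminate' when the
    ion never reaches bulk within the trajectory.
    """
    if membrane is None:
        raise ValueError("assign_direction requires a MembraneFrame")
    if event.ion_id is None:
        raise ValueError("event must carry an ion_id")
    topo = traj.topology
    sites = resolve_region(pathway_sites, topo)
    if not sites:
        raise ValueError(f"pathway region '{pathway_sites.name}' is empty")
    site_rows = topo.index_of(sorted(sites))
    ion_row = int(topo.index_of([event.ion_id])[0])
    for f in range(event.crossing_frame, traj.n_frames):
        centroid = traj.coordinates[f][site_rows].mean(axis=0)
        delta = traj.coordinates[f][ion_row] - centroid
        if np.linalg.norm(delta) > bulk_cutoff:
            sign = np.sign(delta[2]) * membrane.extracellular_sign
            event.direction = ("extracellular" if sign > 0
                               else "intracellular")
            return event.direction
    event.direction = "indeterminate"
    return event.direction


def occupancy_fraction(series: DistanceSeries,
                       threshold: float = 12.0) -> float:
    """Fraction of frames with the (smoothed) distance above threshold,
    i.e. the unbound fraction; bound fraction is its complement."""
    if series.n_frames == 0:
        raise ValueError("empty series")
    if series.smoothed_values is None:
        raise ValueError("occupancy_fraction expects a smoothed series")
    return float(np.mean(series.smoothed_values > threshold))


def gate_series(traj: Trajectory, open_threshold: float = 6.0,
                ser_residue: int = 107, tyr_residue: int = 445) -> GateSeries:
    """Distance between the inner-gate serine and tyrosine side-chain
    oxygens (S107 OG -- Y445 OH) per frame."""
    topo = traj.topology
    missing = []
    ser = resolve_region(RegionSpec(name="S_gate",
                                    residue_numbers=(ser_residue,),
                                    atom_names=("OG",)), topo)
    tyr = resolve_region(RegionSpec(name="Y_gate",
                                    residue_numbers=(tyr_residue,),
                                    atom_names=("OH",)), topo)
    if not ser:
        missing.append(f"S{ser_residue} OG")
    if not tyr:
        missing.append(f"Y{tyr_residue} OH")
    if missing:
        raise ValueError("gate residues missing: " + ", ".join(missing))
    raw = _pair_min_distances(traj, topo.index_of(sorted(ser)),
                              topo.index_of(sorted(tyr)))
    series = DistanceSeries(times_ns=traj.times_ns, raw_values=raw,
                            label=f"S{ser_residue}-Y{tyr_residue}")
    return GateSeries(series=series, open_threshold=open_threshold)
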