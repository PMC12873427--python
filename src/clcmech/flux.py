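"""Proteoliposome flux-assay quantification: per-transporter turnover
rates and Cl-/H+ stoichiometry with replicate aggregation.

A flux record holds parallel chloride-electrode (mM, extravesicular) and
pH-electrode traces.  Coupled transport only starts once valinomycin
dissipates the membrane potential, so rates are initial least-squares
slopes over a window after valinomycin addition.  Sign conventions:
Cl- release from the vesicles (extravesicular [Cl-] rising) is positive,
H+ uptake into the vesicles (extravesicular pH rising) is positive.  The
assay imposes a twofold outward H+ gradient, so any H+ leak moves H+ out
of the vesicles; a negative post-valinomycin H+ slope is therefore
reported as leak, never as transport.

Stoichiometry is the ratio of the Cl- and H+ turnover rates; replicate
aggregation reports mean +/- SEM, with the stoichiometry aggregated as the
mean of per-replicate ratios (not the ratio of mean rates, which differs
on heterogeneous replicates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["FluxTrace", "AssayParams", "TransportResult", "UncoupledSignal",
           "initial_slope", "turnover_rates", "stoichiometry",
           "aggregate_replicates", "AVOGADRO"]

AVOGADRO = 6.02214076e23


class UncoupledSignal(Exception):
    """Signals an undefined Cl-/H+ stoichiometry (no measurable H+
    transport -- the uncoupled-mutant case, reported as 'n/a')."""


@dataclass
class FluxTrace:
    time_s: np.ndarray
    chloride_mM: np.ndarray       # extravesicular [Cl-]
    pH: np.ndarray
    valinomycin_time_s: float
    calibration: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.chloride_mM = np.asarray(self.chloride_mM, dtype=float)
        self.pH = np.asarray(self.pH, dtype=float)
        if not (self.time_s.shape == self.chloride_mM.shape == self.pH.shape):
            raise ValueError("trace arrays must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if not (self.time_s[0] <= self.valinomycin_time_s <= self.time_s[-1]):
            raise ValueError("valinomycin_time must lie within the record")


@dataclass(frozen=True)
class AssayParams:
    """Conversion constants from electrode signals to ion amounts.

    ``n_transporters`` is user-supplied (directly or computed upstream
    from protein:lipid ratio and reconstitution assumptions -- these are
    assumptions, not measured values).  ``buffering_capacity`` converts a
    pH change to moles of H+ per litre (mol / pH unit / L).
    """

    n_transporters: float
    extravesicular_volume_L: float
    buffering_capacity: float

    def __post_init__(self):
        if self.n_transporters <= 0:
            raise ValueError("transporter count must be positive")
        if self.extravesicular_volume_L <= 0 or self.buffering_capacity <= 0:
            raise ValueError("volume and buffering capacity must be positive")


@dataclass
class TransportResult:
    cl_rate: float                      # ions/s per transporter
    h_rate: Optional[float]             # None => leak / not measurable
    stoichiometry: Optional[float]      # None => uncoupled ("n/a")
    n_replicates: int = 1
    cl_rate_sem: Optional[float] = None
    h_rate_sem: Optional[float] = None
    stoichiometry_sem: Optional[float] = None
    h_leak: bool = False


def initial_slope(trace: FluxTrace, channel: str, window_s: float = 10.0,
                  robust: bool = False, with_se: bool = False):
    """Initial post-valinomycin transport rate in mol/s.

    Least-squares (or Theil-Sen with ``robust=True``) slope of the chosen
    electrode trace over [valinomycin_time, valinomycin_time + window_s],
    converted to mol/s through the extravesicular volume (chloride) or the
    buffering capacity times volume (proton).  Positive = Cl- release /
    H+ uptake.  With ``with_se`` the regression standard error of the
    slope (same units) is returned alongside.
    """
    t0 = trace.valinomycin_time_s
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    mask = (trace.time_s >= t0) & (trace.time_s <= t0 + window_s)
    if mask.sum() < 5:
        raise ValueError(
            f"slope window has {int(mask.sum())} samples; at least 5 required")
    t = trace.time_s[mask]
    if channel == "chloride":
        y = trace.chloride_mM[mask]
    elif channel == "proton":
        y = trace.pH[mask]
    else:
        raise ValueError(f"unknown channel '{channel}'")
    if robust:
        res = sps.theilslopes(y, t)
        slope, se = float(res.slope), float(
            (res.high_slope - res.low_slope) / 4)   # ~1 SE from the 95% CI
    else:
        res = sps.linregress(t, y)
        slope, se = float(res.slope), float(res.stderr)
    vol = trace.calibration["extravesicular_volume_L"]
    if channel == "chloride":
        scale = 1e-3 * vol                   # mM/s -> mol/s
    else:
        scale = trace.calibration["buffering_capacity"] * vol
    return (slope * scale, se * scale) if with_se else slope * scale


def turnover_rates(cl_slope_mol_s: float, h_slope_mol_s: float,
                   params: AssayParams):
    """Convert mol/s slopes to per-transporter turnover (ions/s).

    A negative H+ slope means net H+ efflux, which under the imposed
    twofold H+ gradient can only be leak; it is reported as ``h_rate
    None`` with ``h_leak`` flagged, never as transport.
    """
    cl_rate = cl_slope_mol_s * AVOGADRO / params.n_transporters
    if h_slope_mol_s < 0:
        return max(cl_rate, 0.0), None, True
    h_rate = h_slope_mol_s * AVOGADRO / params.n_transporters
    return max(cl_rate, 0.0), h_rate, False


def stoichiometry(cl_rate: float, h_rate: Optional[float],
                  min_h_rate: float = 0.0) -> float:
    """Cl-/H+ transport stoichiometry = cl_rate / h_rate.

    Raises UncoupledSignal when the H+ rate is absent or not above
    ``min_h_rate`` (the uncoupled case; reported as 'n/a', not a number).
    """
    if h_rate is None or h_rate <= min_h_rate:
        raise UncoupledSignal(
            "no measurable H+ transport; stoichiometry undefined (n/a)")
    return cl_rate / h_rate


def analyze_trace(trace: FluxTrace, params: AssayParams,
                  window_s: float = 10.0, robust: bool = False,
                  detection_z: float = 3.0) -> TransportResult:
    """Full single-trace analysis: slopes -> turnover -> stoichiometry.

    An H+ slope that is not above ``detection_z`` regression standard
    errors is treated as not measurable above background: the H+ rate and
    stoichiometry are reported undefined ('n/a'), matching how uncoupled
    transporters present in this assay.
    """
    trace.calibration.setdefault("extravesicular_volume_L",
                                 params.extravesicular_volume_L)
    trace.calibration.setdefault("buffering_capacity",
                                 params.buffering_capacity)
    cl_slope = initial_slope(trace, "chloride", window_s, robust)
    h_slope, h_se = initial_slope(trace, "proton", window_s, robust,
                                  with_se=True)
    cl_rate, h_rate, leak = turnover_rates(cl_slope, h_slope, params)
    if h_rate is not None and h_slope <= detection_z * h_se:
        h_rate = None                       # below detection, not leak
    try:
        ratio = stoichiometry(cl_rate, h_rate)
    except UncoupledSignal:
        ratio = None
    return TransportResult(cl_rate=cl_rate, h_rate=h_rate,
                           stoichiometry=ratio, h_leak=leak)


def _mean_sem(values: Sequence[float]):
    v = np.asarray(values, dtype=float)
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(len(v)))


def aggregate_replicates(results: Sequence[TransportResult]) -> TransportResult:
    """Mean +/- SEM across replicates.

    Stoichiometry aggregates as the mean of per-replicate ratios; a single
    replicate passes through with SEM undefined (flagged by None).
    Replicates with undefined stoichiometry propagate 'n/a'.
    """
    if len(results) == 0:
        raise ValueError("no replicates")
    if len(results) == 1:
        r = results[0]
        return TransportResult(cl_rate=r.cl_rate, h_rate=r.h_rate,
                               stoichiometry=r.stoichiometry, n_replicates=1,
                               h_leak=r.h_leak)
    cl_mean, cl_sem = _mean_sem([r.cl_rate for r in results])
    h_vals = [r.h_rate for r in results if r.h_rate is not None]
    s_vals = [r.stoichiometry for r in results
              if r.stoichiometry is not None]
    h_mean = h_sem = s_mean = s_sem = None
    if len(h_vals) == len(results):
        h_mean, h_sem = _mean_sem(h_vals)
    if len(s_vals) == len(results):
        s_mean, s_sem = _mean_sem(s_vals)
    return TransportResult(cl_rate=cl_mean, h_rate=h_mean,
                           stoichiometry=s_mean, n_replicates=len(results),
                           cl_rate_sem=cl_sem, h_rate_sem=h_sem,
                           stoichiometry_sem=s_sem,
                           h_leak=any(r.h_leak for r in results))
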