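"""HDX-MS pH normalization: intrinsic-exchange-rate model, cross-pH
correction factors and matched time points, back-exchange correction, and
matched-exposure differential uptake.

The intrinsic (chemical) amide exchange rate is modelled with the
standard three-term form

    k_int(pH) = kA * 10^(-pH) + kB * 10^(pH - pKw) + kW

(acid-, base-, and water-catalysed terms).  Defaults are sequence-averaged
poly-DL-alanine reference constants near the experimental temperature
(~21 C); only rate *ratios* enter the pH correction, so the absolute
scale cancels.  In the base-dominated regime (pH >= 4) the rate falls
about tenfold per pH unit, so exchange at pH 4.5 is ~100-fold slower than
at pH 6.5 and a 20 s exposure at pH 6.5 chemically matches ~2000 s at
pH 4.5.  Below pH ~3.5 the acid and water terms bend the curve away from
linearity and correction factors are flagged approximate.

Observed uptake follows two-timescale (per-amide) exponential kinetics
with a protection factor P slowing the intrinsic rate:

    D(t) = N * (1 - exp(-k_int * t / P))
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = ["IntrinsicRateModel", "UptakeCurve", "FDControl",
           "intrinsic_rate", "correction_factor", "matched_timepoint",
           "back_exchange_correct", "differential_uptake",
           "fit_protection_factor", "PAPER_TIMEPOINTS_S"]

# standard labelling time grid (s) used across all pH conditions
PAPER_TIMEPOINTS_S = (20.0, 63.0, 200.0, 633.0, 2000.0, 6325.0,
                      20000.0, 63000.0)

_LOG_MIN2SEC = math.log10(60.0)
LOW_PH_CAUTION = 3.5   # below this, corrections are flagged approximate


@dataclass(frozen=True)
class IntrinsicRateModel:
    """Three-term intrinsic amide-exchange rate model.

    Constants are log10 values in s^-1 (per M s^-1 for the catalysed
    terms); defaults are the poly-DL-alanine reference constants
    (log10 in per-minute units: kA 1.62, kB 10.18, kW -1.5) converted to
    seconds, with the heavy-water ionic product exponent pKw = 15.05.
    """

    log10_kA: float = 1.62 - _LOG_MIN2SEC
    log10_kB: float = 10.18 - _LOG_MIN2SEC
    log10_kW: float = -1.5 - _LOG_MIN2SEC
    pKw: float = 15.05


@dataclass
class UptakeCurve:
    """Deuterium uptake of one peptide at one pH."""

    peptide_id: str
    start_residue: int
    end_residue: int
    pH: float
    timepoints_s: np.ndarray
    deuteration: np.ndarray          # Da (or fractional, consistently)
    replicate_sd: Optional[np.ndarray] = None

    def __post_init__(self):
        self.timepoints_s = np.asarray(self.timepoints_s, dtype=float)
        self.deuteration = np.asarray(self.deuteration, dtype=float)
        if self.timepoints_s.shape != self.deuteration.shape:
            raise ValueError("timepoints and deuteration length mismatch")
        if np.any(np.diff(self.timepoints_s) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if np.any(self.deuteration < 0):
            raise ValueError("deuteration must be non-negative")

    @property
    def max_exchangeable(self) -> int:
        # backbone amides, excluding the first residue and prolines unknown
        # here; callers may supply the exact count to back_exchange_correct
        return max(self.end_residue - self.start_residue, 1)


@dataclass(frozen=True)
class FDControl:
    """Fully deuterated control level for back-exchange correction."""

    peptide_id: str
    fd_level: float

    def __post_init__(self):
        if self.fd_level <= 0:
            raise ValueError("fully deuterated control level must be > 0")


def intrinsic_rate(model: IntrinsicRateModel, pH: float) -> float:
    """k_int(pH) in s^-1 (relative scale): acid + base + water terms."""
    if not (0 < pH < 14):
        raise ValueError("pH must be in (0, 14)")
    return (10.0 ** (model.log10_kA - pH)
            + 10.0 ** (model.log10_kB + pH - model.pKw)
            + 10.0 ** model.log10_kW)


def correction_factor(model: IntrinsicRateModel, pH_ref: float,
                      pH: float) -> float:
    """k_int(pH_ref) / k_int(pH).

    Multiplying an exposure time at ``pH`` by this factor gives the
    chemically equivalent exposure at ``pH_ref``.  Factors involving a pH
    below 3.5 are flagged approximate (non-linear regime).
    """
    if min(pH_ref, pH) < LOW_PH_CAUTION:
        warnings.warn(
            f"correction factor involves pH < {LOW_PH_CAUTION}; the "
            "intrinsic-rate model is non-linear there and the factor is "
            "approximate", stacklevel=2)
    return intrinsic_rate(model, pH_ref) / intrinsic_rate(model, pH)


def matched_timepoint(model: IntrinsicRateModel, pH_ref: float,
                      t_ref: float, pH: float) -> float:
    """Exposure time at ``pH`` with the same intrinsic exposure
    k_int * t as ``t_ref`` at ``pH_ref`` (e.g. 20 s at pH 6.5 matches
    ~2000 s at pH 4.5)."""
    if t_ref <= 0:
        raise ValueError("t_ref must be positive")
    return t_ref * correction_factor(model, pH_ref, pH)


def back_exchange_correct(curve: UptakeCurve, fd: FDControl,
                          max_exchangeable: int) -> UptakeCurve:
    """Scale deuteration by max_exchangeable / fd_level.

    Warns when a corrected value exceeds the theoretical maximum by more
    than 5% (clipping is left to the caller; the values are preserved)."""
    if fd.peptide_id != curve.peptide_id:
        raise ValueError("FD control is for a different peptide")
    if np.any(curve.deuteration > fd.fd_level * 1.0001):
        warnings.warn(
            f"peptide {curve.peptide_id}: observed deuteration exceeds the "
            "fully deuterated control", stacklevel=2)
    scale = max_exchangeable / fd.fd_level
    corrected = curve.deuteration * scale
    if np.any(corrected > max_exchangeable * 1.05):
        warnings.warn(
            f"peptide {curve.peptide_id}: corrected deuteration exceeds the "
            "theoretical maximum by >5%", stacklevel=2)
    sd = (curve.replicate_sd * scale if curve.replicate_sd is not None
          else None)
    return replace(curve, deuteration=corrected, replicate_sd=sd)


def _uptake_at(curve: UptakeCurve, t: float,
               tolerance_factor: float = 1.5) -> float:
    """Uptake at exposure t: nearest measured timepoint within a factor of
    ``tolerance_factor``, else interpolation on log-time; None outside the
    measured range."""
    tp = curve.timepoints_s
    if t < tp[0] / tolerance_factor or t > tp[-1] * tolerance_factor:
        return None
    ratios = np.maximum(tp, 1e-12) / t
    log_off = np.abs(np.log10(ratios))
    k = int(np.argmin(log_off))
    if log_off[k] <= math.log10(tolerance_factor):
        return float(curve.deuteration[k])
    t_clip = float(np.clip(t, tp[0], tp[-1]))
    return float(np.interp(math.log10(t_clip), np.log10(tp),
                           curve.deuteration))


def differential_uptake(curve_a: UptakeCurve, curve_b: UptakeCurve,
                        model: Optional[IntrinsicRateModel] = None,
                        mode: str = "pH_matched",
                        tolerance_factor: float = 1.5):
    """Per-timepoint uptake difference between two pH conditions.

    In 'pH_matched' mode each timepoint of the higher-pH curve is compared
    with the chemically equivalent exposure of the lower-pH curve
    (nearest timepoint within ``tolerance_factor``, else log-time
    interpolation).  The difference is low-pH minus high-pH, so positive
    values flag faster-than-chemistry exchange at the lower pH -- the
    signature of a conformational change.  'raw' mode differences the
    curves at their common timepoints.

    Returns (times_at_high_pH, differences) as arrays.
    """
    if curve_a.peptide_id != curve_b.peptide_id:
        raise ValueError("curves are for different peptides")
    hi, lo = ((curve_a, curve_b) if curve_a.pH >= curve_b.pH
              else (curve_b, curve_a))
    times, diffs, gaps = [], [], []
    if mode == "raw":
        common = np.intersect1d(hi.timepoints_s, lo.timepoints_s)
        if common.size == 0:
            raise ValueError("no common timepoints for raw differencing")
        for t in common:
            dh = hi.deuteration[hi.timepoints_s == t][0]
            dl = lo.deuteration[lo.timepoints_s == t][0]
            times.append(t)
            diffs.append(dl - dh)
    elif mode == "pH_matched":
        if model is None:
            raise ValueError("pH_matched mode requires an IntrinsicRateModel")
        for t_hi, d_hi in zip(hi.timepoints_s, hi.deuteration):
            t_lo = matched_timepoint(model, hi.pH, float(t_hi), lo.pH)
            d_lo = _uptake_at(lo, t_lo, tolerance_factor)
            if d_lo is None:
                gaps.append((float(t_hi), float(t_lo)))
                continue
            times.append(float(t_hi))
            diffs.append(d_lo - d_hi)
        if not times:
            raise ValueError(
                "no alignable timepoints; unmatched exposures: "
                + ", ".join(f"{a:.3g}s->{b:.3g}s" for a, b in gaps))
    else:
        raise ValueError(f"unknown mode '{mode}'")
    return np.asarray(times), np.asarray(diffs)


def fit_protection_factor(curve: UptakeCurve, model: IntrinsicRateModel,
                          n_amides: Optional[int] = None) -> float:
    """Fit a single protection factor P to an uptake curve assuming
    D(t) = N (1 - exp(-k_int t / P)); returns P."""
    n = n_amides if n_amides is not None else curve.max_exchangeable
    k = intrinsic_rate(model, curve.pH)
    t, d = curve.timepoints_s, curve.deuteration

    def resid(logp):
        return n * (1.0 - np.exp(-k * t / 10.0 ** logp[0])) - d

    # initialize from the timepoint nearest half-saturation
    frac = np.clip(d / n, 1e-6, 1 - 1e-6)
    with np.errstate(divide="ignore"):
        kobs = -np.log(1 - frac) / t
    p0 = np.log10(np.clip(k / np.median(kobs), 1e-3, 1e12))
    fit = least_squares(resid, x0=[p0], bounds=([-3], [15]))
    return float(10.0 ** fit.x[0])
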