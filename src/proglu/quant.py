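"""XIC extraction and conversion-occupancy estimation.

Occupancy (modification stoichiometry) is estimated from MS1
extracted-ion-chromatogram areas of the modified/unmodified precursor
pair:

    occupancy % = 100 * area_mod / (area_mod + area_unmod)

under the equal-ionization assumption — the converted and unconverted
peptide are taken to spray and ionize identically, so the area ratio
equals the molecular ratio. This is the method's core caveat: a
proline-to-glutamate conversion changes hydrophobicity and charge
distribution slightly, and any differential response propagates
directly into the estimate.

Co-elution of the pair (apex retention times within 0.2 min) is the QC
gate: a genuine in-peptide conversion co-elutes with its counterpart,
whereas a different peptide that happens to share the precursor mass
generally does not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .spectra_io import Run

__all__ = [
    "Xic",
    "OccupancyEstimate",
    "extract_xic",
    "coelution_check",
    "occupancy",
    "aggregate_replicates",
    "occupancy_report",
    "replicate_summary",
]


@dataclass
class Xic:
    """An extracted ion chromatogram over MS1 scans."""

    target_mz: float
    tol_ppm: float
    rt: np.ndarray  # minutes, ascending
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.shape != self.intensity.shape:
            raise ValueError("RT and intensity traces must have equal length")
        if self.rt.size > 1 and np.any(np.diff(self.rt) <= 0):
            raise ValueError("XIC trace RT must be strictly ascending")

    @property
    def empty(self) -> bool:
        return self.rt.size == 0 or not np.any(self.intensity > 0)

    @property
    def apex_rt(self) -> float:
        """RT of the maximum after 3-point moving-average smoothing; NaN if empty."""
        if self.empty:
            return math.nan
        smoothed = _smooth3(self.intensity)
        return float(self.rt[int(np.argmax(smoothed))])

    @property
    def area(self) -> float:
        """Trapezoidal area of the trace, intensity × minutes."""
        if self.rt.size < 2:
            return 0.0
        return float(np.trapezoid(self.intensity, self.rt))

    @property
    def apex_intensity(self) -> float:
        """Smoothed intensity at the apex; 0 for an empty trace."""
        if self.empty:
            return 0.0
        return float(np.max(_smooth3(self.intensity)))


def _smooth3(y: np.ndarray) -> np.ndarray:
    if y.size < 3:
        return y.astype(float)
    out = y.astype(float).copy()
    out[1:-1] = (y[:-2] + y[1:-1] + y[2:]) / 3.0
    return out


@dataclass
class OccupancyEstimate:
    """Per-run conversion occupancy for one modified/unmodified pair."""

    run_id: str
    pair_label: str
    modified_area: float
    unmodified_area: float
    occupancy_pct: float
    coelution_shift_min: float
    qc_pass: bool
    qc_reason: str = ""

    def __post_init__(self) -> None:
        if not math.isnan(self.occupancy_pct) and not 0 <= self.occupancy_pct <= 100:
            raise ValueError(f"occupancy {self.occupancy_pct} outside [0, 100]")


def extract_xic(
    run: Run,
    target_mz: float,
    tol_ppm: float = 15.0,
    rt_window: tuple[float, float] | None = None,
) -> Xic:
    """Sum MS1 peak intensity within ±tol_ppm of ``target_mz`` per scan.

    ``rt_window`` restricts the trace to ``(lo, hi)`` minutes; the full
    run is used when omitted.
    """
    if tol_ppm <= 0:
        raise ValueError("tolerance must be > 0")
    half = target_mz * tol_ppm * 1e-6
    rts: list[float] = []
    intensities: list[float] = []
    for scan in run.ms1_scans():
        if rt_window is not None and not rt_window[0] <= scan.rt_min <= rt_window[1]:
            continue
        lo = np.searchsorted(scan.mz, target_mz - half, side="left")
        hi = np.searchsorted(scan.mz, target_mz + half, side="right")
        rts.append(scan.rt_min)
        intensities.append(float(scan.intensity[lo:hi].sum()))
    return Xic(target_mz, tol_ppm, np.array(rts), np.array(intensities))


def coelution_check(
    xic_mod: Xic, xic_unmod: Xic, max_shift_min: float = 0.2
) -> tuple[float, bool, str]:
    """Apex RT shift between the pair and whether it passes the criterion.

    Returns ``(shift_minutes, passed, reason)``; an undefined apex on
    either trace fails with the reason stated.
    """
    apex_mod = xic_mod.apex_rt
    apex_unmod = xic_unmod.apex_rt
    if math.isnan(apex_mod) or math.isnan(apex_unmod):
        which = []
        if math.isnan(apex_mod):
            which.append("modified")
        if math.isnan(apex_unmod):
            which.append("unmodified")
        return math.nan, False, f"undefined apex for {' and '.join(which)} trace"
    shift = abs(apex_mod - apex_unmod)
    passed = shift < max_shift_min
    reason = "" if passed else f"apex shift {shift:.3f} min >= {max_shift_min} min"
    return shift, passed, reason


def occupancy(xic_mod: Xic, xic_unmod: Xic, method: str = "area") -> float:
    """Conversion occupancy percent from the XIC pair.

    ``method="area"`` (default) uses trapezoidal areas; ``"apex"`` uses
    smoothed apex intensities instead. Undefined (NaN) when both
    quantities are zero.
    """
    if method == "area":
        a_mod, a_unmod = xic_mod.area, xic_unmod.area
    elif method == "apex":
        a_mod, a_unmod = xic_mod.apex_intensity, xic_unmod.apex_intensity
    else:
        raise ValueError(f"unknown occupancy method {method!r}")
    if a_mod < 0 or a_unmod < 0:
        raise ValueError("negative XIC area")
    total = a_mod + a_unmod
    if total == 0:
        return math.nan
    return 100.0 * a_mod / total


def aggregate_replicates(
    estimates: list[OccupancyEstimate],
) -> tuple[float, float, int]:
    """Mean, sample (n−1) SD and N of occupancy across QC-passing replicates.

    SD is NaN for a single replicate.
    """
    values = [e.occupancy_pct for e in estimates if e.qc_pass]
    if not values:
        raise ValueError("no QC-passing occupancy estimates to aggregate")
    n = len(values)
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if n > 1 else math.nan
    return mean, sd, n


def occupancy_report(estimates: list[OccupancyEstimate]) -> str:
    """Tab-separated per-run occupancy report."""
    header = (
        "run\tpair\tmodified_area\tunmodified_area\toccupancy_pct\t"
        "coelution_shift_min\tqc_pass\tqc_reason"
    )
    lines = [header]
    for e in estimates:
        lines.append(
            f"{e.run_id}\t{e.pair_label}\t{e.modified_area:.6g}\t"
            f"{e.unmodified_area:.6g}\t{e.occupancy_pct:.4f}\t"
            f"{e.coelution_shift_min:.4f}\t{int(e.qc_pass)}\t{e.qc_reason}"
        )
    return "\n".join(lines) + "\n"


def replicate_summary(estimates: list[OccupancyEstimate]) -> str:
    """Replicate-aggregated summary (QC failures excluded and reported)."""
    n_fail = sum(1 for e in estimates if not e.qc_pass)
    mean, sd, n = aggregate_replicates(estimates)
    sd_text = f"{sd:.2f}" if not math.isnan(sd) else "NA"
    lines = [
        "mean_occupancy_pct\tsd_occupancy_pct\tn\tqc_failed_excluded",
        f"{mean:.2f}\t{sd_text}\t{n}\t{n_fail}",
    ]
    return "\n".join(lines) + "\n"
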