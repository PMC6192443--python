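"""Peptide-spectrum matching and target-decoy FDR.

Candidate peptide forms are indexed by neutral mass; each MS2 scan is
scored against every form whose precursor m/z (at the scan's declared
charge) lies within the precursor ppm tolerance. Fragment matching is
greedy nearest-m/z with one observed peak per theoretical ion, and the
score is a hyperscore-style statistic:

    score = ln(b_matched!) + ln(y_matched!) + ln(1 + sum of matched intensity)

This is deliberately not a re-implementation of SEQUEST XCorr; the
downstream conclusions (mass arithmetic, localization, co-elution,
occupancy) do not depend on the score's absolute value, only on its
ranking behaviour, which the target-decoy q-value calibrates.

q-values follow the standard target-decoy recipe: sort PSMs by score
descending, running FDR estimate = decoys-so-far / targets-so-far
(0/0 -> 0), then take the cumulative minimum from the bottom so
q-values are monotone in rank. Control is at PSM level.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .chem import PROTON_MASS, WATER_MASS, RESIDUE_MASS, mz as _mz, ppm_error
from .digest import PeptideForm
from .spectra_io import Ms2Scan, Run

__all__ = [
    "SearchConfig",
    "Psm",
    "theoretical_fragments",
    "score_psm",
    "search_run",
    "compute_qvalues",
    "filter_psms",
    "psm_table",
]


@dataclass(frozen=True)
class SearchConfig:
    """Search tolerances and filters (defaults follow common Orbitrap practice)."""

    precursor_tol_ppm: float = 15.0
    fragment_tol_da: float = 0.05
    max_dynamic_mods: int = 3
    min_peptide_length: int = 5
    q_value_threshold: float = 0.01
    charges: tuple[int, ...] = (2, 3, 4)
    fragment_series: tuple[str, ...] = ("b", "y")
    #: add 2+ fragments for precursors at z >= 3
    doubly_charged_fragments: bool = False
    min_flanking_ions: int = 1  # localization evidence per flank

    def __post_init__(self) -> None:
        if self.precursor_tol_ppm <= 0 or self.fragment_tol_da <= 0:
            raise ValueError("tolerances must be > 0")
        if not 0 < self.q_value_threshold < 1:
            raise ValueError("q-value threshold must be in (0, 1)")


@dataclass
class Psm:
    """A scored peptide-spectrum match (rank 1 within its scan)."""

    scan_id: str
    form: PeptideForm
    score: float
    matched_fragments: int
    precursor_ppm: float
    charge: int
    rt_min: float
    q_value: float = math.nan
    rank: int = 1

    @property
    def is_decoy(self) -> bool:
        return self.form.is_decoy


def theoretical_fragments(
    form: PeptideForm,
    series: tuple[str, ...] = ("b", "y"),
    charges: tuple[int, ...] = (1,),
) -> list[tuple[str, float]]:
    """Singly (or multiply) protonated b/y fragment m/z ladder.

    For a peptide of length n, emits b1..b(n-1) and y1..y(n-1); a
    modification's delta is included in every fragment containing the
    modified position.
    """
    n = len(form.sequence)
    delta_at = np.zeros(n)
    for pos, mod in form.mods:
        delta_at[pos - 1] += mod.delta_mass
    residue = np.array([RESIDUE_MASS[aa] for aa in form.sequence]) + delta_at
    prefix = np.cumsum(residue)  # prefix[i-1] = mass of residues 1..i
    total = prefix[-1]

    out: list[tuple[str, float]] = []
    for i in range(1, n):
        if "b" in series:
            neutral_b = prefix[i - 1]
            for z in charges:
                label = f"b{i}" if z == 1 else f"b{i}^{z}+"
                out.append((label, (neutral_b + z * PROTON_MASS) / z))
        if "y" in series:
            neutral_y = total - prefix[n - i - 1] + WATER_MASS
            for z in charges:
                label = f"y{i}" if z == 1 else f"y{i}^{z}+"
                out.append((label, (neutral_y + z * PROTON_MASS) / z))
    return out


def match_fragments(
    fragments: list[tuple[str, float]],
    peak_mz: np.ndarray,
    peak_intensity: np.ndarray,
    tol_da: float,
) -> dict[str, tuple[float, float]]:
    """Greedy one-to-one assignment of observed peaks to theoretical ions.

    Each theoretical ion takes the nearest unused peak within ``tol_da``;
    ties in |Δm/z| break toward the more intense peak. Returns
    ``label -> (observed m/z, intensity)``.
    """
    used = np.zeros(len(peak_mz), dtype=bool)
    matches: dict[str, tuple[float, float]] = {}
    # deterministic order: by theoretical m/z then label
    for label, theo in sorted(fragments, key=lambda f: (f[1], f[0])):
        lo = bisect.bisect_left(peak_mz, theo - tol_da)
        hi = bisect.bisect_right(peak_mz, theo + tol_da)
        best = -1
        best_key = None
        for j in range(lo, hi):
            if used[j]:
                continue
            key = (abs(peak_mz[j] - theo), -peak_intensity[j])
            if best_key is None or key < best_key:
                best_key = key
                best = j
        if best >= 0:
            used[best] = True
            matches[label] = (float(peak_mz[best]), float(peak_intensity[best]))
    return matches


def score_psm(
    scan: Ms2Scan, form: PeptideForm, config: SearchConfig
) -> tuple[float, int]:
    """Hyperscore-style score and matched-fragment count for one pairing."""
    charges = (1, 2) if (config.doubly_charged_fragments and scan.precursor_charge >= 3) else (1,)
    frags = theoretical_fragments(form, config.fragment_series, charges)
    if len(scan.mz) == 0:
        return 0.0, 0
    matches = match_fragments(frags, scan.mz, scan.intensity, config.fragment_tol_da)
    if not matches:
        return 0.0, 0
    n_b = sum(1 for label in matches if label.startswith("b"))
    n_y = sum(1 for label in matches if label.startswith("y"))
    intensity_sum = sum(inten for _mz_obs, inten in matches.values())
    score = math.lgamma(n_b + 1) + math.lgamma(n_y + 1) + math.log1p(intensity_sum)
    return score, len(matches)


class _MassIndex:
    """Neutral-mass-sorted candidate index for ppm window queries."""

    def __init__(self, forms: list[PeptideForm]):
        decorated = sorted(((f.neutral_mass, f) for f in forms), key=lambda t: t[0])
        self.masses = [m for m, _ in decorated]
        self.forms = [f for _, f in decorated]

    def query(self, neutral_mass: float, tol_ppm: float) -> list[PeptideForm]:
        half = neutral_mass * tol_ppm * 1e-6
        lo = bisect.bisect_left(self.masses, neutral_mass - half)
        hi = bisect.bisect_right(self.masses, neutral_mass + half)
        return self.forms[lo:hi]


def search_run(
    run: Run,
    forms: list[PeptideForm],
    config: SearchConfig | None = None,
) -> list[Psm]:
    """Score every MS2 scan against mass-matched candidate forms.

    The rank-1 PSM per scan is retained (deterministic tie-break:
    higher score, then more matched fragments, then smaller |ppm|,
    then target before decoy, then lexicographic form identity);
    q-values are assigned across the whole run.
    """
    config = config or SearchConfig()
    index = _MassIndex(forms)
    psms: list[Psm] = []
    for scan in run.ms2_scans():
        if scan.precursor_charge not in config.charges:
            continue
        neutral = scan.precursor_mz * scan.precursor_charge - scan.precursor_charge * PROTON_MASS
        candidates = index.query(neutral, config.precursor_tol_ppm)
        best: Psm | None = None
        best_key = None
        for form in candidates:
            if len(form) < config.min_peptide_length:
                continue
            score, n_matched = score_psm(scan, form, config)
            ppm = ppm_error(scan.precursor_mz, form.mz(scan.precursor_charge))
            key = (-score, -n_matched, abs(ppm), form.is_decoy,
                   form.sequence, form.mod_string())
            if best_key is None or key < best_key:
                best_key = key
                best = Psm(
                    scan_id=scan.scan_id,
                    form=form,
                    score=score,
                    matched_fragments=n_matched,
                    precursor_ppm=ppm,
                    charge=scan.precursor_charge,
                    rt_min=scan.rt_min,
                )
        if best is not None:
            psms.append(best)
    return compute_qvalues(psms)


def compute_qvalues(psms: list[Psm]) -> list[Psm]:
    """Assign target-decoy q-values in place (returned sorted by score desc)."""
    if not psms:
        return []
    ordered = sorted(psms, key=lambda p: (-p.score, p.is_decoy, p.scan_id))
    n_decoy = 0
    n_target = 0
    fdr = np.empty(len(ordered))
    for i, psm in enumerate(ordered):
        if psm.is_decoy:
            n_decoy += 1
        else:
            n_target += 1
        fdr[i] = n_decoy / n_target if n_target else 0.0
    q = np.minimum.accumulate(fdr[::-1])[::-1]
    for psm, qv in zip(ordered, q):
        psm.q_value = float(qv)
    return ordered


def filter_psms(psms: list[Psm], threshold: float = 0.01) -> list[Psm]:
    """Target PSMs passing the q-value threshold."""
    return [p for p in psms if not p.is_decoy and p.q_value <= threshold]


def psm_table(psms: list[Psm]) -> str:
    """Tab-separated PSM report."""
    header = (
        "scan\tpeptide\tmods\tprotein\tstart\tend\tcharge\tppm\t"
        "matched\tscore\tq_value\tis_decoy"
    )
    lines = [header]
    for p in psms:
        f = p.form
        lines.append(
            f"{p.scan_id}\t{f.sequence}\t{f.mod_string()}\t{f.protein}\t"
            f"{f.start}\t{f.end}\t{p.charge}\t{p.precursor_ppm:.3f}\t"
            f"{p.matched_fragments}\t{p.score:.4f}\t{p.q_value:.6f}\t"
            f"{int(p.is_decoy)}"
        )
    return "\n".join(lines) + "\n"
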