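"""Ground-truth LC-MS/MS run simulator.

Emulates the acquisition regime of a 60-min nano-LC gradient on an
Orbitrap-class instrument running data-dependent acquisition: survey
MS1 scans over m/z 300–2000 at a fixed sampling interval, fragmentation
of the top-15 most intense multiply charged (z >= 2) precursors per
cycle, and 20 s dynamic exclusion. Peptides elute as Gaussian peaks;
a stated fraction of the molecules of a site-bearing peptide carries
the residue-conversion mass shift, and the converted/unconverted pair
shares one elution apex exactly — the ground truth the co-elution and
occupancy stages are tested against.

Simplifications (documented, config-extensible): monoisotopic MS1 peaks
only (no isotope envelopes), Gaussian elution without tailing, one
charge state per peptide, and noise that is uniform in m/z with
exponential intensities. Every random draw comes from the single seed,
so identical configs reproduce byte-identical runs and manifests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .chem import ModificationSpec, default_registry, mz as _mz
from .digest import (
    PeptideForm,
    ProteinRecord,
    expand_modified_forms,
    tryptic_digest,
)
from .search import theoretical_fragments
from .spectra_io import Ms1Scan, Ms2Scan, Run

__all__ = [
    "SimConfig",
    "SimSpecies",
    "GroundTruthManifest",
    "elution_profile",
    "generate_ms2",
    "simulate_run",
    "demo_protein",
]

_GAUSS_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class SimConfig:
    """Acquisition and noise model of the simulated run.

    Defaults are the study conditions: 60-min gradient, survey scans
    over m/z 300–2000, top-15 precursor selection at z >= 2, 20 s
    dynamic exclusion. The MS1 sampling interval and chromatographic
    peak width are not instrument settings the acquisition description
    fixes; 2 s cycles and 12 s FWHM peaks are typical of the hardware
    class and are the shipped defaults.
    """

    seed: int
    gradient_min: float = 60.0
    mz_min: float = 300.0
    mz_max: float = 2000.0
    top_n: int = 15
    dynamic_exclusion_s: float = 20.0
    ms1_interval_s: float = 2.0
    peak_fwhm_s: float = 12.0
    #: MS1 chemical-noise peaks per survey scan (Poisson mean)
    noise_peaks_per_ms1: float = 50.0
    noise_intensity_mean: float = 300.0
    #: multiplicative shot-noise CV on each MS1 signal intensity
    intensity_cv: float = 0.15
    #: MS2 noise peaks per spectrum (Poisson mean)
    ms2_noise_peaks: float = 10.0
    mz_jitter_ppm: float = 3.0
    fragment_jitter_da: float = 0.01
    fragment_dropout: float = 0.1
    min_precursor_intensity: float = 500.0
    charge: int = 2
    abundance_min: float = 2e6
    abundance_max: float = 2e7
    rt_margin_frac: float = 0.12

    def __post_init__(self) -> None:
        for name in (
            "gradient_min", "top_n", "dynamic_exclusion_s", "ms1_interval_s",
            "peak_fwhm_s", "mz_jitter_ppm", "fragment_jitter_da",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.fragment_dropout <= 1:
            raise ValueError("fragment_dropout must be in [0, 1]")


@dataclass
class SimSpecies:
    """One eluting precursor species (a peptide form at one charge)."""

    form: PeptideForm
    charge: int
    mz: float
    apex_rt_min: float
    abundance: float
    pair_id: str  # shared by a converted/unconverted pair, else its own label
    converted: bool
    occupancy_pct: float  # truth for the pair; 0 for unpaired species

    @property
    def label(self) -> str:
        mods = self.form.mod_string()
        return f"{self.form.sequence}[{mods}]/{self.charge}+" if mods else \
            f"{self.form.sequence}/{self.charge}+"


@dataclass
class GroundTruthManifest:
    """What the simulator actually put into a run."""

    run_id: str
    species: list[SimSpecies]
    scan_truth: dict[str, str]  # MS2 scan id -> generating species label
    sites: list[tuple[str, int, str, float]]  # (protein, position, conversion, occupancy %)

    def pair(self, pair_id: str) -> tuple[SimSpecies, SimSpecies]:
        """(converted, unconverted) species of a pair."""
        members = [s for s in self.species if s.pair_id == pair_id]
        conv = [s for s in members if s.converted]
        unconv = [s for s in members if not s.converted]
        if len(conv) != 1 or len(unconv) != 1:
            raise KeyError(f"pair {pair_id!r} is not a converted/unconverted pair")
        return conv[0], unconv[0]

    def to_tsv(self) -> str:
        lines = [
            "species\tprotein\tstart\tend\tcharge\tmz\tapex_rt_min\t"
            "abundance\tpair_id\tconverted\toccupancy_pct"
        ]
        for s in self.species:
            lines.append(
                f"{s.label}\t{s.form.protein}\t{s.form.start}\t{s.form.end}\t"
                f"{s.charge}\t{s.mz:.6f}\t{s.apex_rt_min:.6f}\t{s.abundance:.6g}\t"
                f"{s.pair_id}\t{int(s.converted)}\t{s.occupancy_pct:.4f}"
            )
        lines.append("")
        lines.append("scan\tspecies")
        for scan_id, label in self.scan_truth.items():
            lines.append(f"{scan_id}\t{label}")
        return "\n".join(lines) + "\n"


def elution_profile(apex_rt_min: float, fwhm_min: float, abundance: float):
    """Gaussian elution profile integrating analytically to ``abundance``.

    Returns a vectorized function of RT (minutes) giving instantaneous
    intensity; the value at the apex is ``abundance * 2 sqrt(ln2/pi) / FWHM``.
    """
    if fwhm_min <= 0:
        raise ValueError("FWHM must be > 0")
    sigma = fwhm_min / _GAUSS_FWHM_TO_SIGMA
    amplitude = abundance / (sigma * math.sqrt(2.0 * math.pi))

    def profile(rt):
        rt = np.asarray(rt, dtype=float)
        return amplitude * np.exp(-0.5 * ((rt - apex_rt_min) / sigma) ** 2)

    return profile


def _strictly_increasing(mz: np.ndarray, intensity: np.ndarray):
    """Sort peaks by m/z and merge coincident centroids (sum intensity)."""
    order = np.argsort(mz, kind="stable")
    mz = mz[order]
    intensity = intensity[order]
    if mz.size < 2:
        return mz, intensity
    keep_mz: list[float] = []
    keep_int: list[float] = []
    for m, i in zip(mz, intensity):
        if keep_mz and m - keep_mz[-1] < 1e-9:
            keep_int[-1] += i
        else:
            keep_mz.append(float(m))
            keep_int.append(float(i))
    return np.array(keep_mz), np.array(keep_int)


def generate_ms2(
    form: PeptideForm,
    config: SimConfig,
    rng: np.random.Generator,
    base_intensity: float = 1e4,
) -> tuple[np.ndarray, np.ndarray]:
    """Centroided fragment spectrum: jittered b/y ladder plus noise.

    Each ladder ion survives with probability ``1 - fragment_dropout``,
    gets Gaussian m/z jitter (SD ``fragment_jitter_da``) and a lognormal
    intensity around ``base_intensity``. Noise peaks are uniform in m/z
    with exponential intensities well below the ladder.
    """
    frags = theoretical_fragments(form)
    mzs: list[float] = []
    intensities: list[float] = []
    for _label, theo in frags:
        if rng.random() < config.fragment_dropout:
            continue
        mzs.append(theo + rng.normal(0.0, config.fragment_jitter_da))
        intensities.append(base_intensity * rng.lognormal(0.0, 0.5))
    n_noise = rng.poisson(config.ms2_noise_peaks)
    if n_noise:
        lo, hi = 100.0, max(200.0, min(config.mz_max, form.neutral_mass + 20.0))
        mzs.extend(rng.uniform(lo, hi, size=n_noise))
        intensities.extend(
            base_intensity * 0.02 * rng.exponential(1.0, size=n_noise)
        )
    if not mzs:
        return np.array([]), np.array([])
    return _strictly_increasing(np.array(mzs), np.array(intensities))


def _species_for_protein(
    protein: ProteinRecord,
    sites: list[tuple[str, int, str, float]],
    registry: dict[str, ModificationSpec],
    config: SimConfig,
    rng: np.random.Generator,
) -> list[SimSpecies]:
    fixed_registry = {n: m for n, m in registry.items() if m.mode == "fixed"}
    peptides = tryptic_digest(protein, max_missed=0, min_length=5)
    species: list[SimSpecies] = []
    for pep in peptides:
        base = expand_modified_forms(pep, fixed_registry, max_dynamic=0)[0]
        mz_val = base.mz(config.charge)
        if not config.mz_min <= mz_val <= config.mz_max:
            continue
        apex = rng.uniform(
            config.rt_margin_frac * config.gradient_min,
            (1 - config.rt_margin_frac) * config.gradient_min,
        )
        abundance = math.exp(
            rng.uniform(math.log(config.abundance_min), math.log(config.abundance_max))
        )
        # conversion sites falling inside this peptide
        pep_sites = [
            (prot, pos, conv, occ)
            for prot, pos, conv, occ in sites
            if prot == protein.accession and pep.start <= pos <= pep.end
        ]
        if not pep_sites:
            species.append(
                SimSpecies(base, config.charge, mz_val, apex, abundance,
                           base.sequence, False, 0.0)
            )
            continue
        if len(pep_sites) > 1:
            raise ValueError(
                f"peptide {pep.sequence} spans multiple conversion sites; unsupported"
            )
        prot, pos, conv, occ = pep_sites[0]
        if not 0 <= occ <= 100:
            raise ValueError(f"occupancy {occ} outside [0, 100]")
        from_res, to_res = conv.split(">")
        mod_name = f"{ _long_name(from_res) }>{ _long_name(to_res) }"
        mod = registry[mod_name]
        pep_pos = pos - pep.start + 1
        if pep.sequence[pep_pos - 1] != from_res:
            raise ValueError(
                f"site {prot}:{pos} is {pep.sequence[pep_pos - 1]!r}, "
                f"not {from_res!r}"
            )
        converted = base.with_mods(base.mods + ((pep_pos, mod),))
        conv_mz = converted.mz(config.charge)
        pair_id = f"{prot}:{pos}:{conv}"
        species.append(
            SimSpecies(base, config.charge, mz_val, apex,
                       abundance * (1 - occ / 100.0), pair_id, False, occ)
        )
        if occ > 0 and config.mz_min <= conv_mz <= config.mz_max:
            species.append(
                SimSpecies(converted, config.charge, conv_mz, apex,
                           abundance * occ / 100.0, pair_id, True, occ)
            )
    return species


def _long_name(code: str) -> str:
    return {"P": "Pro", "R": "Arg", "E": "Glu"}.get(code, code)


def simulate_run(
    proteins: list[ProteinRecord],
    sites: list[tuple[str, int, str, float]],
    config: SimConfig,
    registry: dict[str, ModificationSpec] | None = None,
    run_id: str = "sim",
) -> tuple[Run, GroundTruthManifest]:
    """Simulate a DDA run over ``proteins`` with planted conversion sites.

    ``sites`` rows are ``(accession, protein_position, "P>E", occupancy_pct)``.
    Returns the in-memory :class:`Run` (write it with
    :func:`proglu.spectra_io.write_mzml` if a file is needed) and the
    ground-truth manifest.
    """
    registry = registry or default_registry()
    rng = np.random.default_rng(config.seed)
    for prot, pos, conv, occ in sites:
        if not 0 <= occ <= 100:
            raise ValueError(f"occupancy {occ} outside [0, 100] for site {prot}:{pos}")

    species: list[SimSpecies] = []
    for protein in proteins:
        species.extend(_species_for_protein(protein, sites, registry, config, rng))
    planted = {(prot, pos) for prot, pos, _c, _o in sites}
    covered = {
        (s.form.protein, s.form.start + p - 1)
        for s in species
        for p, _m in s.form.mods
    }
    for prot, pos, conv, occ in sites:
        if occ > 0 and (prot, pos) not in covered:
            raise ValueError(
                f"site {prot}:{pos} not covered by any detectable tryptic peptide"
            )

    profiles = [
        elution_profile(s.apex_rt_min, config.peak_fwhm_s / 60.0, s.abundance)
        for s in species
    ]

    scans: list = []
    scan_truth: dict[str, str] = {}
    scan_counter = 0
    interval_min = config.ms1_interval_s / 60.0
    exclusion: list[tuple[float, float]] = []  # (mz, excluded-until RT min)
    excl_min = config.dynamic_exclusion_s / 60.0
    n_ms1 = int(config.gradient_min / interval_min)

    for k in range(n_ms1):
        t = k * interval_min
        signal = np.array([p(t) for p in profiles])
        if config.intensity_cv > 0:
            sigma_ln = math.sqrt(math.log1p(config.intensity_cv**2))
            signal = signal * rng.lognormal(0.0, sigma_ln, size=signal.size)
        visible = signal >= 1.0
        sig_mz = np.array([
            s.mz * (1.0 + rng.normal(0.0, config.mz_jitter_ppm) * 1e-6)
            for s in species
        ])
        n_noise = rng.poisson(config.noise_peaks_per_ms1)
        noise_mz = rng.uniform(config.mz_min, config.mz_max, size=n_noise)
        noise_int = rng.exponential(config.noise_intensity_mean, size=n_noise)
        all_mz = np.concatenate([sig_mz[visible], noise_mz])
        all_int = np.concatenate([signal[visible], noise_int])
        all_mz, all_int = _strictly_increasing(all_mz, all_int)
        scan_counter += 1
        ms1_id = f"scan={scan_counter}"
        scans.append(Ms1Scan(ms1_id, t, all_mz, all_int))

        # DDA: top-N multiply charged signal precursors, dynamic exclusion
        exclusion = [(m, until) for m, until in exclusion if until > t]
        candidates = [
            (signal[i], i) for i in range(len(species))
            if visible[i] and signal[i] >= config.min_precursor_intensity
            and species[i].charge >= 2
        ]
        candidates.sort(key=lambda ci: (-ci[0], species[ci[1]].mz))
        selected: list[int] = []
        for inten, i in candidates:
            if len(selected) >= config.top_n:
                break
            m = species[i].mz
            if any(abs(m - em) / em < 1e-5 for em, _u in exclusion):
                continue
            selected.append(i)
            exclusion.append((m, t + excl_min))
        for j, i in enumerate(selected):
            s = species[i]
            frag_mz, frag_int = generate_ms2(
                s.form, config, rng, base_intensity=max(signal[i] * 0.02, 100.0)
            )
            scan_counter += 1
            ms2_id = f"scan={scan_counter}"
            rt = t + (j + 1) * interval_min / (len(selected) + 1)
            scans.append(
                Ms2Scan(ms2_id, rt, float(sig_mz[i]), s.charge, ms1_id,
                        frag_mz, frag_int)
            )
            scan_truth[ms2_id] = s.label

    run = Run(run_id, scans, metadata={"simulated": True, "seed": config.seed})
    manifest = GroundTruthManifest(run_id, species, scan_truth, list(sites))
    return run, manifest


_DEMO_ACCESSION = "PRX6_SYN"


def demo_protein() -> ProteinRecord:
    """A synthetic 224-residue demo protein (not the real Prx6 sequence).

    Places the tryptic peptide DFTPVCTTELGR at residues 42–53, so the
    proline at peptide position 4 sits at protein residue 45 — the
    coordinate arithmetic of the published proline-45 call. The flanking
    sequence is deterministic pseudo-random; substitute the real
    UniProt P30041 entry for work on actual data.
    """
    rng = np.random.default_rng(20250924)
    alphabet = np.array(list("ACDEFGHIKLMNQSTVWY"))  # no P to keep sites unique
    seq = list(rng.choice(alphabet, size=224))
    peptide = "DFTPVCTTELGR"
    seq[40] = "K"  # cleavage before the peptide
    seq[41:53] = list(peptide)
    seq[53] = "A"  # no KP suppression of the cleavage after R53
    return ProteinRecord(
        _DEMO_ACCESSION,
        f"{_DEMO_ACCESSION} synthetic peroxiredoxin-6-like demo protein",
        "".join(seq),
    )
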