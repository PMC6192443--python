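"""Monoisotopic mass bookkeeping.

Residue and atomic masses, the modification registry (carbamidomethyl,
oxidation, deamidation, Pro>Glu and the related carbonylation deltas),
and the peptide/precursor m/z arithmetic the rest of the pipeline is
built on.

All masses are monoisotopic daltons. Average-mass chemistry is
deliberately unsupported: every printed m/z this package reproduces
(698.33, 714.33) and every delta it searches for (+31.990, +0.98402) is
monoisotopic. Charging uses the proton mass (1.007276 Da), not the
hydrogen atom mass.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

__all__ = [
    "ATOM",
    "PROTON_MASS",
    "WATER_MASS",
    "RESIDUE_MASS",
    "CANONICAL_RESIDUES",
    "ModificationSpec",
    "default_registry",
    "registry_to_table",
    "registry_from_table",
    "peptide_neutral_mass",
    "mz",
    "neutral_mass_from_mz",
    "conversion_delta",
    "ppm_error",
]

#: Monoisotopic atomic masses, Da.
ATOM: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}

#: Mass of a proton (charge carrier), Da. Distinct from the H atom mass.
PROTON_MASS: float = 1.00727646688

#: Mass of one water molecule (peptide bond condensation partner), Da.
WATER_MASS: float = 2 * ATOM["H"] + ATOM["O"]

#: Monoisotopic residue (i.e. dehydrated amino acid) masses, Da.
RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146372,
    "A": 71.03711378,
    "S": 87.03202840,
    "P": 97.05276385,
    "V": 99.06841391,
    "T": 101.04767847,
    "C": 103.00918478,
    "L": 113.08406398,
    "I": 113.08406398,
    "N": 114.04292744,
    "D": 115.02694302,
    "Q": 128.05857751,
    "K": 128.09496301,
    "E": 129.04259309,
    "M": 131.04048509,
    "H": 137.05891186,
    "F": 147.06841391,
    "R": 156.10111102,
    "Y": 163.06332853,
    "W": 186.07931295,
}

CANONICAL_RESIDUES: frozenset[str] = frozenset(RESIDUE_MASS)


@dataclass(frozen=True)
class ModificationSpec:
    """A named monoisotopic mass delta with residue targets.

    ``mode`` is ``"fixed"`` (applied to every occurrence of a target
    residue) or ``"dynamic"`` (optional per occurrence, enumerated
    during the search).
    """

    name: str
    delta_mass: float
    targets: frozenset[str]
    mode: str
    note: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "dynamic"):
            raise ValueError(f"mode must be 'fixed' or 'dynamic', got {self.mode!r}")
        bad = set(self.targets) - CANONICAL_RESIDUES
        if bad:
            raise ValueError(f"non-canonical target residue(s): {sorted(bad)}")
        object.__setattr__(self, "targets", frozenset(self.targets))

    def applies_to(self, residue: str) -> bool:
        return residue in self.targets


def default_registry(oxidation_targets: str = "MP") -> dict[str, ModificationSpec]:
    """The shipped modification registry.

    Parameters
    ----------
    oxidation_targets
        Residues eligible for +15.995 oxidation. ``"M"`` restricts it to
        methionine; the default ``"MP"`` also allows proline (whose
        oxidation product, glutamyl semialdehyde, is the chemical
        precursor of the Pro>Glu conversion and has the same delta as
        the separate ``Pro>GSA`` entry).
    """
    mods = [
        ModificationSpec("Carbamidomethyl", 57.02146372, frozenset("C"), "fixed",
                         "iodoacetamide alkylation of cysteine"),
        ModificationSpec("Oxidation", 15.99491462, frozenset(oxidation_targets), "dynamic",
                         "addition of one oxygen atom"),
        ModificationSpec("Deamidation", 0.98401558, frozenset("NQ"), "dynamic",
                         "amide to carboxylic acid on Asn/Gln"),
        ModificationSpec("Pro>Glu", 31.98982924, frozenset("P"), "dynamic",
                         "proline-to-glutamate conversion (two O atoms); "
                         "mass-indistinguishable from dihydroxyproline"),
        ModificationSpec("Arg>Glu", -27.05851793, frozenset("R"), "dynamic",
                         "arginine-to-glutamate conversion"),
        ModificationSpec("Pro>GSA", 15.99491462, frozenset("P"), "dynamic",
                         "proline to glutamyl semialdehyde (carbonyl)"),
        ModificationSpec("Arg>GSA", -43.05343255, frozenset("R"), "dynamic",
                         "arginine to glutamyl semialdehyde (carbonyl)"),
    ]
    return {m.name: m for m in mods}


def registry_to_table(registry: dict[str, ModificationSpec]) -> str:
    """Serialize a registry to a plain-text tab-separated table (Da to 5 dp)."""
    lines = ["name\tdelta_mass\ttargets\tmode\tnote"]
    for m in registry.values():
        lines.append(
            f"{m.name}\t{m.delta_mass:.5f}\t{''.join(sorted(m.targets))}\t{m.mode}\t{m.note}"
        )
    return "\n".join(lines) + "\n"


def registry_from_table(text: str) -> dict[str, ModificationSpec]:
    """Parse the table written by :func:`registry_to_table`."""
    reader = io.StringIO(text)
    header = reader.readline().rstrip("\n").split("\t")
    expected = ["name", "delta_mass", "targets", "mode", "note"]
    if header != expected:
        raise ValueError(f"bad registry header: {header!r}, expected {expected!r}")
    registry: dict[str, ModificationSpec] = {}
    for lineno, line in enumerate(reader, start=2):
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise ValueError(f"registry line {lineno}: expected 5 fields, got {len(parts)}")
        name, delta, targets, mode, note = parts
        registry[name] = ModificationSpec(name, float(delta), frozenset(targets), mode, note)
    return registry


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty peptide sequence")
    for i, aa in enumerate(sequence, start=1):
        if aa not in CANONICAL_RESIDUES:
            raise ValueError(
                f"unknown residue code {aa!r} at position {i} of {sequence!r}"
            )


def peptide_neutral_mass(
    sequence: str,
    mods: tuple[tuple[int, ModificationSpec], ...] | list[tuple[int, ModificationSpec]] = (),
) -> float:
    """Monoisotopic neutral mass of a (possibly modified) peptide.

    ``mods`` is a list of ``(position, ModificationSpec)`` with 1-based
    positions inside the peptide; each position's residue must be a
    target of its modification.
    """
    _check_sequence(sequence)
    mass = sum(RESIDUE_MASS[aa] for aa in sequence) + WATER_MASS
    for pos, mod in mods:
        if not 1 <= pos <= len(sequence):
            raise ValueError(
                f"modification position {pos} outside peptide of length {len(sequence)}"
            )
        residue = sequence[pos - 1]
        if not mod.applies_to(residue):
            raise ValueError(
                f"{mod.name} does not target residue {residue!r} at position {pos}"
            )
        mass += mod.delta_mass
    return mass


def mz(neutral_mass: float, charge: int) -> float:
    """m/z of ``[M + charge·H]^charge+``."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * PROTON_MASS) / charge


def neutral_mass_from_mz(observed_mz: float, charge: int) -> float:
    """Invert :func:`mz`: neutral mass implied by an observed m/z and charge."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return observed_mz * charge - charge * PROTON_MASS


def conversion_delta(from_residue: str, to_residue: str) -> float:
    """Residue-substitution mass difference ``to - from`` in Da.

    ``conversion_delta("P", "E")`` is +31.98983 Da — the two added
    oxygen atoms behind the +31.990 Da shift of the Pro>Glu conversion.
    """
    for code in (from_residue, to_residue):
        if code not in CANONICAL_RESIDUES:
            raise ValueError(f"non-canonical residue code {code!r}")
    return RESIDUE_MASS[to_residue] - RESIDUE_MASS[from_residue]


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be > 0, got {theoretical}")
    return (observed - theoretical) / theoretical * 1e6
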