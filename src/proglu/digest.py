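"""FASTA ingestion and in-silico tryptic digestion.

Peptides carry 1-based inclusive protein coordinates so that a
modification at a peptide position maps directly to a protein residue
number (the peptide DFTPVCTTELGR starting at protein residue 42 puts
its proline, peptide position 4, at protein residue 45).

Trypsin specificity: cleave C-terminal to K or R, except when the next
residue is P. Decoys are reversed whole proteins digested afresh, which
preserves cleavage-site statistics; their accessions carry the
``DECOY_`` prefix.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO

from .chem import (
    CANONICAL_RESIDUES,
    ModificationSpec,
    mz,
    peptide_neutral_mass,
)

logger = logging.getLogger(__name__)

DECOY_PREFIX = "DECOY_"


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.accession}: empty sequence")
        for i, aa in enumerate(self.sequence, start=1):
            if aa not in CANONICAL_RESIDUES:
                raise ValueError(
                    f"protein {self.accession}: non-canonical residue {aa!r} "
                    f"at position {i}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeptideForm:
    """A peptide sequence plus a concrete assignment of modifications.

    ``mods`` is a tuple of ``(peptide_position, ModificationSpec)``,
    1-based, sorted by position. ``start``/``end`` are 1-based inclusive
    coordinates on the parent protein.
    """

    sequence: str
    protein: str
    start: int
    end: int
    missed_cleavages: int = 0
    mods: tuple[tuple[int, ModificationSpec], ...] = ()
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"{self.sequence}: coordinates [{self.start},{self.end}] "
                f"inconsistent with length {len(self.sequence)}"
            )
        for pos, mod in self.mods:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(f"mod position {pos} outside {self.sequence}")
            if not mod.applies_to(self.sequence[pos - 1]):
                raise ValueError(
                    f"{mod.name} does not target {self.sequence[pos - 1]!r} "
                    f"at position {pos} of {self.sequence}"
                )
        object.__setattr__(self, "mods", tuple(sorted(self.mods, key=lambda pm: pm[0])))

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def neutral_mass(self) -> float:
        return peptide_neutral_mass(self.sequence, self.mods)

    def mz(self, charge: int) -> float:
        return mz(self.neutral_mass, charge)

    def mod_string(self) -> str:
        """Compact ``position:name`` summary, e.g. ``4:Pro>Glu;6:Carbamidomethyl``."""
        return ";".join(f"{pos}:{mod.name}" for pos, mod in self.mods)

    def with_mods(self, mods: tuple[tuple[int, ModificationSpec], ...]) -> "PeptideForm":
        return replace(self, mods=mods)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into validated :class:`ProteinRecord` objects.

    Sequences are uppercased and whitespace-stripped; a sequence
    containing a non-canonical code (e.g. ``X``) is rejected with the
    accession and position named.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    with open(path) as handle:
        first = handle.readline()
        if not first:
            raise ValueError(f"{path}: empty FASTA file")
        if not first.startswith(">"):
            raise ValueError(f"{path}: line 1 is not a FASTA header: {first[:40]!r}")
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace(" ", "").replace("*", "")
        records.append(ProteinRecord(rec.id, rec.description, seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.description or rec.accession}\n")
            for i in range(0, len(rec.sequence), 60):
                handle.write(rec.sequence[i : i + 60] + "\n")


def cleavage_sites(sequence: str) -> list[int]:
    """0-based indices *after which* trypsin cleaves (K/R not before P)."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def tryptic_digest(
    protein: ProteinRecord,
    max_missed: int = 2,
    min_length: int = 5,
) -> list[PeptideForm]:
    """All tryptic peptides with up to ``max_missed`` missed cleavages.

    Returns unmodified :class:`PeptideForm` objects with protein
    coordinates, ordered by start position then length.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    seq = protein.sequence
    # Segment boundaries: start-of-protein, each cleavage point, end.
    bounds = [0] + [i + 1 for i in cleavage_sites(seq)] + [len(seq)]
    is_decoy = protein.accession.startswith(DECOY_PREFIX)
    peptides: list[PeptideForm] = []
    for a in range(len(bounds) - 1):
        for b in range(a + 1, min(a + max_missed + 2, len(bounds))):
            s, e = bounds[a], bounds[b]
            if e - s < min_length:
                continue
            peptides.append(
                PeptideForm(
                    sequence=seq[s:e],
                    protein=protein.accession,
                    start=s + 1,
                    end=e,
                    missed_cleavages=b - a - 1,
                    is_decoy=is_decoy,
                )
            )
    return peptides


def expand_modified_forms(
    peptide: PeptideForm,
    registry: dict[str, ModificationSpec],
    max_dynamic: int = 3,
) -> list[PeptideForm]:
    """Enumerate all modified forms of an unmodified peptide.

    Fixed modifications are applied to every target occurrence; dynamic
    modifications are enumerated over all target positions with at most
    one dynamic modification per position and at most ``max_dynamic``
    per peptide. The unmodified (fixed-only) form is always included.
    """
    if peptide.mods:
        raise ValueError("expand_modified_forms expects an unmodified peptide")
    fixed = [m for m in registry.values() if m.mode == "fixed"]
    dynamic = [m for m in registry.values() if m.mode == "dynamic"]

    base: list[tuple[int, ModificationSpec]] = []
    for pos, aa in enumerate(peptide.sequence, start=1):
        for mod in fixed:
            if mod.applies_to(aa):
                base.append((pos, mod))

    # Candidate (position, mod) slots for dynamic modifications.
    slots: list[tuple[int, ModificationSpec]] = [
        (pos, mod)
        for pos, aa in enumerate(peptide.sequence, start=1)
        for mod in dynamic
        if mod.applies_to(aa)
    ]

    forms: list[PeptideForm] = []
    seen: set[tuple] = set()
    for k in range(min(max_dynamic, len(slots)) + 1):
        for combo in itertools.combinations(slots, k):
            positions = [pos for pos, _ in combo]
            if len(set(positions)) != len(positions):
                continue  # one dynamic mod per residue position
            key = tuple(sorted((pos, mod.name) for pos, mod in combo))
            if key in seen:
                continue
            seen.add(key)
            forms.append(peptide.with_mods(tuple(base) + combo))
    return forms


def map_site_to_protein(peptide: PeptideForm, peptide_position: int) -> int:
    """Translate a 1-based peptide position to a protein residue number."""
    if not 1 <= peptide_position <= len(peptide):
        raise ValueError(
            f"position {peptide_position} outside peptide "
            f"{peptide.sequence} (length {len(peptide)})"
        )
    return peptide.start + peptide_position - 1


def make_decoys(proteins: list[ProteinRecord]) -> list[ProteinRecord]:
    """One reversed-sequence decoy per target protein."""
    if not proteins:
        raise ValueError("make_decoys: empty protein list")
    decoys = []
    for prot in proteins:
        rev = prot.sequence[::-1]
        if rev == prot.sequence:
            logger.warning(
                "decoy for %s is identical to its target (palindromic sequence)",
                prot.accession,
            )
        decoys.append(
            ProteinRecord(
                DECOY_PREFIX + prot.accession,
                DECOY_PREFIX + prot.accession + " reversed decoy",
                rev,
            )
        )
    return decoys
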