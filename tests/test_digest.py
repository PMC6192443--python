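"""Digestion against brute-force cleavage enumeration; coordinate tracking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from proglu.chem import default_registry
from proglu.digest import (
    DECOY_PREFIX,
    PeptideForm,
    ProteinRecord,
    cleavage_sites,
    expand_modified_forms,
    make_decoys,
    map_site_to_protein,
    read_fasta,
    tryptic_digest,
    write_fasta,
)


def brute_force_digest(seq: str, max_missed: int, min_length: int) -> set:
    """Oracle: enumerate all substrings bounded by valid cleavage sites."""
    sites = [i + 1 for i in range(len(seq) - 1) if seq[i] in "KR" and seq[i + 1] != "P"]
    bounds = [0] + sites + [len(seq)]
    out = set()
    for s in bounds:
        for e in bounds:
            if e <= s:
                continue
            internal = sum(1 for c in sites if s < c < e)
            if internal <= max_missed and e - s >= min_length:
                out.add((seq[s:e], s + 1, e))
    return out


class TestReadFasta:
    def test_single_record(self, tmp_path, prx6_like):
        path = tmp_path / "one.fasta"
        write_fasta([prx6_like], path)
        records = read_fasta(path)
        assert len(records) == 1
        assert len(records[0].sequence) == 224
        assert records[0].sequence == prx6_like.sequence

    def test_two_records_order_preserved(self, tmp_path):
        path = tmp_path / "two.fasta"
        path.write_text(">A first\nPEPTIDEK\n>B second\nGGGGGR\n")
        records = read_fasta(path)
        assert [r.accession for r in records] == ["A", "B"]

    def test_lowercase_and_wrapped_sequences(self, tmp_path):
        path = tmp_path / "wrapped.fasta"
        path.write_text(">A\npept\nidek\n")
        assert read_fasta(path)[0].sequence == "PEPTIDEK"

    def test_x_rejected_with_accession_and_position(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">BADPROT\nPEXTIDEK\n")
        with pytest.raises(ValueError, match="BADPROT.*'X'.*position 3"):
            read_fasta(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.raises(ValueError, match="empty"):
            read_fasta(path)

    def test_headerless_file_rejected(self, tmp_path):
        path = tmp_path / "noheader.fasta"
        path.write_text("PEPTIDEK\n")
        with pytest.raises(ValueError, match="line 1"):
            read_fasta(path)


class TestTrypticDigest:
    def test_short_flanks_filtered(self):
        prot = ProteinRecord("X", "", "MKRDFTPVCTTELGRA")
        peps = tryptic_digest(prot, max_missed=0, min_length=5)
        assert [(p.sequence, p.start, p.end) for p in peps] == [
            ("DFTPVCTTELGR", 4, 15)
        ]

    def test_no_cleavage_before_proline(self):
        prot = ProteinRecord("X", "", "AKPLR")
        peps = tryptic_digest(prot, max_missed=0, min_length=1)
        assert [p.sequence for p in peps] == ["AKPLR"]

    def test_missed_cleavages_add_longer_forms(self):
        prot = ProteinRecord("X", "", "MKRDFTPVCTTELGRA")
        peps = tryptic_digest(prot, max_missed=1, min_length=5)
        seqs = {p.sequence for p in peps}
        assert seqs == {"DFTPVCTTELGR", "RDFTPVCTTELGR", "DFTPVCTTELGRA"}
        by_seq = {p.sequence: p for p in peps}
        assert by_seq["RDFTPVCTTELGR"].missed_cleavages == 1
        assert by_seq["DFTPVCTTELGR"].missed_cleavages == 0

    def test_zero_missed_concatenation_reconstructs_protein(self, prx6_like):
        peps = tryptic_digest(prx6_like, max_missed=0, min_length=1)
        assert "".join(p.sequence for p in peps) == prx6_like.sequence

    def test_coordinates_substring_match(self, prx6_like):
        for pep in tryptic_digest(prx6_like, max_missed=2, min_length=5):
            assert prx6_like.sequence[pep.start - 1 : pep.end] == pep.sequence

    @settings(deadline=None, max_examples=40)
    @given(
        st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=50, max_size=50),
        st.integers(min_value=0, max_value=2),
        st.integers(min_value=1, max_value=7),
    )
    def test_agrees_with_brute_force_oracle(self, seq, max_missed, min_length):
        prot = ProteinRecord("R50", "", seq)
        got = {
            (p.sequence, p.start, p.end)
            for p in tryptic_digest(prot, max_missed, min_length)
        }
        assert got == brute_force_digest(seq, max_missed, min_length)


class TestExpandModifiedForms:
    def test_one_proline_one_cys_two_forms(self, registry):
        pep = PeptideForm("DFTPVCTTELGR", "X", 1, 12)
        reg = {k: registry[k] for k in ("Carbamidomethyl", "Pro>Glu")}
        forms = expand_modified_forms(pep, reg)
        mods = sorted(f.mod_string() for f in forms)
        assert mods == ["4:Pro>Glu;6:Carbamidomethyl", "6:Carbamidomethyl"]

    def test_no_dynamic_targets_single_fixed_form(self, registry):
        pep = PeptideForm("GGGGGK", "X", 1, 6)
        reg = {k: registry[k] for k in ("Carbamidomethyl", "Pro>Glu")}
        forms = expand_modified_forms(pep, reg)
        assert len(forms) == 1 and forms[0].mods == ()

    def test_deamidation_without_nq_adds_nothing(self, registry):
        pep = PeptideForm("DFTPVCTTELGR", "X", 1, 12)
        reg = {k: registry[k] for k in ("Carbamidomethyl", "Pro>Glu", "Deamidation")}
        assert len(expand_modified_forms(pep, reg)) == 2

    def test_max_dynamic_cap(self, registry):
        pep = PeptideForm("NPNPNPNK", "X", 1, 8)
        reg = {k: registry[k] for k in ("Pro>Glu", "Deamidation")}
        forms = expand_modified_forms(pep, reg, max_dynamic=3)
        assert max(len(f.mods) for f in forms) == 3
        # one dynamic mod per position
        for f in forms:
            positions = [pos for pos, _ in f.mods]
            assert len(positions) == len(set(positions))

    def test_modified_input_rejected(self, prx6_peptide, registry):
        with pytest.raises(ValueError):
            expand_modified_forms(prx6_peptide, registry)


class TestSiteMapping:
    def test_peptide_position_4_is_protein_45(self, prx6_peptide):
        assert map_site_to_protein(prx6_peptide, 4) == 45

    def test_position_1_maps_to_start(self, prx6_peptide):
        assert map_site_to_protein(prx6_peptide, 1) == 42

    def test_out_of_range_rejected(self, prx6_peptide):
        with pytest.raises(ValueError):
            map_site_to_protein(prx6_peptide, 13)


class TestDecoys:
    def test_reversal_and_prefix(self):
        decoys = make_decoys([ProteinRecord("P1", "", "DFTPVCTTELGR")])
        assert decoys[0].sequence == "RGLETTCVPTFD"
        assert decoys[0].accession == DECOY_PREFIX + "P1"

    def test_cardinality(self, prx6_like):
        targets = [prx6_like, ProteinRecord("P2", "", "PEPTIDEK")]
        assert len(make_decoys(targets)) == 2

    def test_palindrome_logged(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            decoys = make_decoys([ProteinRecord("PAL", "", "GAG")])
        assert decoys[0].sequence == "GAG"
        assert any("palindromic" in r.message for r in caplog.records)

    def test_decoy_digestion_flags_peptides(self, prx6_like):
        decoy = make_decoys([prx6_like])[0]
        peps = tryptic_digest(decoy, 0, 5)
        assert peps and all(p.is_decoy for p in peps)
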