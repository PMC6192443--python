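"""Fragment ladders, scoring, brute-force search oracle, and FDR control."""

import math

import numpy as np
import pytest

from proglu.chem import default_registry
from proglu.digest import (
    PeptideForm,
    ProteinRecord,
    expand_modified_forms,
    make_decoys,
    tryptic_digest,
)
from proglu.search import (
    Psm,
    SearchConfig,
    compute_qvalues,
    filter_psms,
    score_psm,
    search_run,
    theoretical_fragments,
)
from proglu.spectra_io import Ms1Scan, Ms2Scan, Run

from conftest import make_ms2


class TestTheoreticalFragments:
    def test_y1_of_arginine_terminal(self, prx6_peptide):
        ladder = dict(theoretical_fragments(prx6_peptide))
        assert ladder["y1"] == pytest.approx(175.119, abs=1e-3)

    def test_b2_of_df(self, prx6_peptide):
        ladder = dict(theoretical_fragments(prx6_peptide))
        assert ladder["b2"] == pytest.approx(263.103, abs=1e-3)

    def test_full_ladder_size(self, prx6_peptide):
        frags = theoretical_fragments(prx6_peptide)
        assert len(frags) == 2 * (len(prx6_peptide) - 1)

    def test_shift_appears_only_in_site_containing_ions(
        self, prx6_peptide, prx6_converted
    ):
        plain = dict(theoretical_fragments(prx6_peptide))
        shifted = dict(theoretical_fragments(prx6_converted))
        # P4 lies in b4..b11 and y9..y11 of the 12-mer
        assert shifted["y9"] - plain["y9"] == pytest.approx(31.990, abs=1e-3)
        assert shifted["y8"] - plain["y8"] == pytest.approx(0.0, abs=1e-9)
        assert shifted["b4"] - plain["b4"] == pytest.approx(31.990, abs=1e-3)
        assert shifted["b3"] - plain["b3"] == pytest.approx(0.0, abs=1e-9)


class TestScorePsm:
    def test_complete_ladder_matches_everything(self, prx6_converted):
        scan = make_ms2(prx6_converted)
        score, matched = score_psm(scan, prx6_converted, SearchConfig())
        assert matched == 2 * (len(prx6_converted) - 1)
        assert score > 0

    def test_no_peaks_in_tolerance_scores_zero(self, prx6_peptide):
        scan = Ms2Scan("s", 1.0, prx6_peptide.mz(2), 2, "",
                       np.array([333.333, 444.444]), np.array([10.0, 10.0]))
        score, matched = score_psm(scan, prx6_peptide, SearchConfig())
        assert (score, matched) == (0.0, 0)

    def test_empty_peak_list_scores_zero(self, prx6_peptide):
        scan = Ms2Scan("s", 1.0, prx6_peptide.mz(2), 2, "",
                       np.array([]), np.array([]))
        assert score_psm(scan, prx6_peptide, SearchConfig()) == (0.0, 0)

    def test_generating_form_outscores_rival(self, prx6_peptide, prx6_converted):
        rng = np.random.default_rng(11)
        scan = make_ms2(prx6_converted, jitter=0.01, rng=rng)
        s_true, _ = score_psm(scan, prx6_converted, SearchConfig())
        s_other, _ = score_psm(scan, prx6_peptide, SearchConfig())
        assert s_true > s_other

    def test_peak_order_invariance(self, prx6_converted):
        scan = make_ms2(prx6_converted, noise=20, rng=np.random.default_rng(3))
        score1 = score_psm(scan, prx6_converted, SearchConfig())
        # rebuilding the scan from shuffled peaks re-sorts them; score unchanged
        rng = np.random.default_rng(5)
        order = rng.permutation(len(scan.mz))
        resorted = np.argsort(scan.mz[order])
        scan2 = Ms2Scan("s2", scan.rt_min, scan.precursor_mz, 2, "",
                        scan.mz[order][resorted], scan.intensity[order][resorted])
        assert score_psm(scan2, prx6_converted, SearchConfig()) == score1


def _forms_for(proteins, registry, mods=("Pro>Glu",), max_missed=1):
    reg = {k: registry[k] for k in ("Carbamidomethyl",) + tuple(mods)}
    forms = []
    for prot in proteins:
        for pep in tryptic_digest(prot, max_missed, 5):
            forms.extend(expand_modified_forms(pep, reg))
    return forms


def brute_force_search(run, forms, config):
    """Oracle: score every form against every scan, no mass index."""
    from proglu.chem import PROTON_MASS, ppm_error

    psms = []
    for scan in run.ms2_scans():
        if scan.precursor_charge not in config.charges:
            continue
        best, best_key = None, None
        for form in forms:
            if len(form) < config.min_peptide_length:
                continue
            theo = form.mz(scan.precursor_charge)
            ppm = ppm_error(scan.precursor_mz, theo)
            if abs(ppm) > config.precursor_tol_ppm:
                continue
            score, matched = score_psm(scan, form, config)
            key = (-score, -matched, abs(ppm), form.is_decoy,
                   form.sequence, form.mod_string())
            if best_key is None or key < best_key:
                best_key = key
                best = (scan.scan_id, form, score, matched)
        if best is not None:
            psms.append(best)
    return psms


class TestSearchRun:
    def _tiny_run(self, forms, rng, n=20):
        """Spectra generated from a rotation of the candidate forms."""
        scans = [Ms1Scan("scan=0", 0.0, np.array([500.0]), np.array([1.0]))]
        generating = []
        usable = [f for f in forms if 300 <= f.mz(2) <= 2000 and not f.is_decoy]
        for i in range(n):
            form = usable[i % len(usable)]
            generating.append(form)
            scans.append(
                make_ms2(form, rt=0.01 * (i + 1), jitter=0.01, dropout=0.1,
                         noise=10, rng=rng, scan_id=f"scan={i + 1}",
                         source="scan=0")
            )
        return Run("tiny", scans), generating

    def test_high_identification_rate_on_clean_run(self, registry):
        rng = np.random.default_rng(42)
        prot = ProteinRecord(
            "T1", "", "MKDFTPVCTTELGRAAGHKLLNDPEWSTRVVYIMQANDERGGFLSTYKPEPTIDESK"
        )
        forms = _forms_for([prot, *make_decoys([prot])], registry)
        run, generating = self._tiny_run(forms, rng)
        psms = search_run(run, forms, SearchConfig())
        by_scan = {p.scan_id: p for p in psms}
        correct = sum(
            1
            for i, form in enumerate(generating)
            if by_scan.get(f"scan={i + 1}")
            and by_scan[f"scan={i + 1}"].form.sequence == form.sequence
            and by_scan[f"scan={i + 1}"].form.mod_string() == form.mod_string()
        )
        assert correct >= 19

    def test_decoy_only_database_flags_everything(self, registry, prx6_like):
        decoys = make_decoys([prx6_like])
        forms = _forms_for(decoys, registry)
        rng = np.random.default_rng(1)
        # generate spectra FROM decoy forms, search against decoys only
        usable = [f for f in forms if 300 <= f.mz(2) <= 2000]
        scans = [Ms1Scan("scan=0", 0.0, np.array([500.0]), np.array([1.0]))]
        for i in range(5):
            scans.append(make_ms2(usable[i], rt=0.01 * (i + 1), rng=rng,
                                  scan_id=f"scan={i + 1}", source="scan=0"))
        psms = search_run(Run("d", scans), forms, SearchConfig())
        assert psms and all(p.is_decoy for p in psms)

    def test_precursor_window_excludes_converted_form(
        self, prx6_peptide, prx6_converted
    ):
        scan = make_ms2(prx6_peptide)  # precursor 698.33, z=2
        run = Run("one", [
            Ms1Scan("scan=1", 0.0, np.array([500.0]), np.array([1.0])),
            Ms2Scan("scan=2", scan.rt_min, scan.precursor_mz, 2, "scan=1",
                    scan.mz, scan.intensity),
        ])
        psms = search_run(run, [prx6_peptide, prx6_converted], SearchConfig())
        assert len(psms) == 1
        assert psms[0].form.mod_string() == prx6_peptide.mod_string()

    def test_matches_brute_force_oracle(self, registry):
        rng = np.random.default_rng(2024)
        prot = ProteinRecord(
            "T2", "", "MKDFTPVCTTELGRAAGHKLLNDPEWSTRVVYIMQANDERGGFLSTYKPEPTIDESK"
        )
        forms = _forms_for([prot, *make_decoys([prot])], registry)[:50]
        run, _ = self._tiny_run(forms, rng, n=20)
        config = SearchConfig()
        fast = {
            p.scan_id: (p.form.sequence, p.form.mod_string(),
                        round(p.score, 9), p.matched_fragments)
            for p in search_run(run, forms, config)
        }
        slow = {
            scan_id: (form.sequence, form.mod_string(), round(score, 9), matched)
            for scan_id, form, score, matched in brute_force_search(run, forms, config)
        }
        assert fast == slow


def _psm(score, decoy, i):
    form = PeptideForm("PEPTIDEK", "D" if decoy else "T", 1, 8, is_decoy=decoy)
    return Psm(f"s{i}", form, score, 1, 0.0, 2, 1.0)


class TestQValues:
    def test_hand_computed_example(self):
        psms = [_psm(10, False, 0), _psm(9, False, 1), _psm(8, True, 2),
                _psm(7, False, 3)]
        out = compute_qvalues(psms)
        assert [round(p.q_value, 6) for p in out] == [0.0, 0.0,
                                                      round(1 / 3, 6),
                                                      round(1 / 3, 6)]

    def test_all_targets_are_zero(self):
        out = compute_qvalues([_psm(10 - i, False, i) for i in range(5)])
        assert all(p.q_value == 0.0 for p in out)

    def test_empty_input(self):
        assert compute_qvalues([]) == []

    def test_alternating_targets_and_decoys_q_near_one(self):
        psms = [_psm(100 - i, i % 2 == 1, i) for i in range(200)]
        out = compute_qvalues(psms)
        targets = [p for p in out if not p.is_decoy]
        assert sum(1 for p in targets if p.q_value > 0.8) >= len(targets) // 2

    def test_qvalues_monotone_in_rank(self):
        rng = np.random.default_rng(9)
        psms = [_psm(float(rng.normal()), bool(rng.random() < 0.5), i)
                for i in range(100)]
        out = compute_qvalues(psms)
        qs = [p.q_value for p in out]
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))

    def test_filter_keeps_targets_under_threshold(self):
        psms = [_psm(10, False, 0), _psm(9, True, 1), _psm(8, False, 2)]
        out = compute_qvalues(psms)
        kept = filter_psms(out, 0.01)
        assert all(not p.is_decoy and p.q_value <= 0.01 for p in kept)


class TestFdrControl:
    def test_empirical_false_proportion_controlled(self, registry):
        """Over >=500 spectra with decoy competition, the false-match
        proportion among q <= 0.01 survivors stays within binomial slack
        of the nominal 1% control (<= 3%)."""
        rng = np.random.default_rng(20240901)
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        proteins = [
            ProteinRecord(f"T{i}", "", "".join(rng.choice(alphabet, size=120)) + "K")
            for i in range(12)
        ]
        forms = _forms_for(proteins + make_decoys(proteins), registry,
                           mods=("Pro>Glu", "Deamidation"), max_missed=1)
        usable = [f for f in forms if not f.is_decoy and 300 <= f.mz(2) <= 2000]
        scans = [Ms1Scan("scan=0", 0.0, np.array([500.0]), np.array([1.0]))]
        truth = {}
        for i in range(550):
            form = usable[int(rng.integers(len(usable)))]
            sid = f"scan={i + 1}"
            truth[sid] = (form.sequence, form.mod_string())
            scans.append(
                make_ms2(form, rt=0.001 * (i + 1), jitter=0.012, dropout=0.3,
                         noise=25, rng=rng, scan_id=sid, source="scan=0")
            )
        run = Run("fdr", scans)
        psms = search_run(run, forms, SearchConfig())
        survivors = filter_psms(psms, 0.01)
        assert len(survivors) >= 300  # the filter must not be vacuous
        false = sum(
            1 for p in survivors
            if (p.form.sequence, p.form.mod_string()) != truth[p.scan_id]
        )
        assert false / len(survivors) <= 0.03
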