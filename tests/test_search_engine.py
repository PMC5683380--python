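import numpy as np
import pytest
from pyteomics import mass as pmass

from proteoforge.db_assembler import add_decoys, assemble_database
from proteoforge.search_engine import (
    MONOISOTOPIC_MASSES,
    PROTON,
    PSM,
    WATER,
    PeptideCandidate,
    SearchSettings,
    Spectrum,
    accepted_psms,
    compute_q_values,
    digest_protein,
    enumerate_mod_isoforms,
    group_proteins,
    peptide_monoisotopic_mass,
    preprocess_spectrum,
    read_mgf,
    run_search,
    score_psm,
    theoretical_fragments,
)
from proteoforge.sequence_core import ProteinEntry

AA20 = "ACDEFGHIKLMNPQRSTVWY"
OPEN = SearchSettings(min_peptide_length=1, max_peptide_length=10_000)


def entry(seq, acc="P1", origin="REF"):
    return ProteinEntry(acc, seq, origin, "")


def brute_force_digest(seq, max_missed=2, lo=1, hi=10_000):
    """Independent oracle: enumerate every substring bounded by cleavage
    sites (or the termini) with at most ``max_missed`` internal sites,
    plus initiator-Met-trimmed variants of N-terminal peptides."""
    def is_boundary(p):
        return p == 0 or p == len(seq) or seq[p - 1] in "KR"

    out = set()
    for a in range(len(seq)):
        for b in range(a + 1, len(seq) + 1):
            if not (is_boundary(a) and is_boundary(b)):
                continue
            internal = sum(1 for p in range(a + 1, b)
                           if seq[p - 1] in "KR")
            if internal > max_missed:
                continue
            pep = seq[a:b]
            if lo <= len(pep) <= hi and "X" not in pep:
                out.add((a, pep))
            if a == 0 and seq[0] == "M" and len(pep) > 1:
                trimmed = pep[1:]
                if lo <= len(trimmed) <= hi and "X" not in trimmed:
                    out.add((1, trimmed))
    return out


class TestDigestion:
    def test_spec_example_mkrpaskr(self):
        got = {c.sequence for c in digest_protein(entry("MKRPASKR"), OPEN)}
        expected = ({"MK", "R", "PASK", "MKR", "RPASK", "PASKR",
                     "MKRPASK", "RPASKR"}
                    | {"K", "KR", "KRPASK"})
        assert got == expected

    def test_no_cleavage_sites(self):
        got = {c.sequence for c in digest_protein(entry("MAGICS"), OPEN)}
        assert got == {"MAGICS", "AGICS"}

    def test_no_proline_rule_cleaves_before_p(self):
        got = {c.sequence for c in digest_protein(entry("AKPR"), OPEN)}
        assert got == {"AK", "PR", "AKPR"}

    def test_x_containing_peptides_dropped(self):
        got = {c.sequence for c in digest_protein(entry("MKXAYR"), OPEN)}
        assert all("X" not in p for p in got)

    def test_matches_brute_force_oracle_on_random_proteins(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 151))
            seq = "".join(rng.choice(list(AA20), size=n))
            got = {(c.start, c.sequence) for c in digest_protein(entry(seq), OPEN)}
            assert got == brute_force_digest(seq)

    def test_length_bounds_respected(self, rng):
        settings = SearchSettings()  # default 6..50
        seq = "".join(rng.choice(list(AA20), size=200))
        got = {(c.start, c.sequence) for c in digest_protein(entry(seq), settings)}
        assert got == brute_force_digest(seq, lo=6, hi=50)


class TestModIsoforms:
    def test_two_met_sites_give_four_isoforms(self):
        (cand,) = [c for c in digest_protein(entry("MAMK"), OPEN)
                   if c.sequence == "MAMK"]
        isoforms = enumerate_mod_isoforms(cand, OPEN)
        oxidized = {tuple(i for i, d in iso.mods if abs(d - 15.99491) < 1e-6)
                    for iso in isoforms}
        assert oxidized == {(), (0,), (2,), (0, 2)}

    def test_fixed_cam_always_applied(self):
        (cand,) = [c for c in digest_protein(entry("ACK"), OPEN)
                   if c.sequence == "ACK"]
        (iso,) = enumerate_mod_isoforms(cand, OPEN)
        assert iso.mods == ((1, 57.02146),)

    def test_isoform_cap(self):
        seq = "A" + "M" * 11 + "K"  # 2^11 = 2048 subsets
        (cand,) = [c for c in digest_protein(entry(seq), OPEN)
                   if c.sequence == seq]
        assert len(enumerate_mod_isoforms(cand, OPEN)) == 1024


def _mass_oracle(seq, mods=()):
    m = pmass.fast_mass(seq)
    return m + sum(d for _, d in mods)


class TestMassesAndFragments:
    def test_peptide_mass_example(self):
        c = PeptideCandidate("PEPTIDE", ("P",), 0, 0)
        assert peptide_monoisotopic_mass(c) == pytest.approx(799.3600, abs=5e-4)

    def test_cam_additivity(self):
        plain = PeptideCandidate("ACK", ("P",), 0, 0)
        cam = PeptideCandidate("ACK", ("P",), 0, 0, ((1, 57.02146),))
        assert peptide_monoisotopic_mass(cam) == pytest.approx(
            peptide_monoisotopic_mass(plain) + 57.02146, abs=1e-9)

    def test_oxidation_delta(self):
        a = PeptideCandidate("AMK", ("P",), 0, 0)
        b = PeptideCandidate("AMK", ("P",), 0, 0, ((1, 15.99491),))
        diff = peptide_monoisotopic_mass(b) - peptide_monoisotopic_mass(a)
        assert diff == pytest.approx(15.99491, abs=1e-9)

    def test_b2_y1_examples(self):
        c = PeptideCandidate("PEPTIDE", ("P",), 0, 0)
        frags = {(t, i): mz for t, i, mz in theoretical_fragments(c)}
        assert frags[("b", 2)] == pytest.approx(227.1026, abs=1e-3)
        assert frags[("y", 1)] == pytest.approx(148.0604, abs=1e-3)

    def test_masses_and_fragments_match_pyteomics_oracle(self, rng):
        for _ in range(1000):
            n = int(rng.integers(2, 30))
            seq = "".join(rng.choice(list(AA20), size=n))
            mods = tuple((i, 57.02146) for i, aa in enumerate(seq) if aa == "C")
            if "M" in seq and rng.random() < 0.5:
                site = seq.index("M")
                mods = tuple(sorted(mods + ((site, 15.99491),)))
            c = PeptideCandidate(seq, ("P",), 0, 0, mods)
            assert peptide_monoisotopic_mass(c) == pytest.approx(
                _mass_oracle(seq, mods), abs=1e-4)
            frags = {(t, i): mz for t, i, mz in theoretical_fragments(c)}
            i = int(rng.integers(1, n))
            b_oracle = (pmass.fast_mass(seq[:i], ion_type="b", charge=1)
                        + sum(d for s, d in mods if s < i))
            y_oracle = (pmass.fast_mass(seq[n - i:], ion_type="y", charge=1)
                        + sum(d for s, d in mods if s >= n - i))
            assert frags[("b", i)] == pytest.approx(b_oracle, abs=1e-4)
            assert frags[("y", i)] == pytest.approx(y_oracle, abs=1e-4)

    def test_by_conservation_identity(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 25))
            seq = "".join(rng.choice(list(AA20), size=n))
            c = PeptideCandidate(seq, ("P",), 0, 0)
            m = peptide_monoisotopic_mass(c)
            frags = {(t, i): mz for t, i, mz in theoretical_fragments(c)}
            for i in range(1, n):
                total = frags[("b", i)] + frags[("y", n - i)]
                assert total == pytest.approx(m + 2 * PROTON, abs=1e-9)


def _spec(mz, intensity, scan="s1", pepmass=500.0, charge=2):
    order = np.argsort(mz)
    return Spectrum(scan, pepmass, charge, np.asarray(mz, float)[order],
                    np.asarray(intensity, float)[order])


class TestSpectrumHandling:
    def test_top_k_peak_filter(self, rng):
        mz = rng.uniform(100, 1500, size=500)
        inten = rng.permutation(np.arange(1.0, 501.0))
        s = preprocess_spectrum(_spec(mz, inten), SearchSettings())
        assert len(s.mz) == 400
        assert sorted(s.intensity) == list(np.sort(inten)[-400:])
        assert np.all(np.diff(s.mz) >= 0)

    def test_small_spectrum_untouched(self):
        s = _spec([100.0, 200.0], [5.0, 7.0])
        out = preprocess_spectrum(s, SearchSettings())
        assert np.array_equal(out.mz, s.mz)

    def test_intensity_ties_keep_lower_mz(self):
        settings = SearchSettings(max_peaks=2)
        s = _spec([100.0, 200.0, 300.0], [5.0, 5.0, 5.0])
        out = preprocess_spectrum(s, settings)
        assert list(out.mz) == [100.0, 200.0]

    def test_mgf_round_trip(self, tmp_path):
        from proteoforge.synthetic_data import write_mgf

        s = _spec([100.0, 200.5, 300.25], [10.0, 20.0, 5.0], scan="scanA",
                  pepmass=433.21, charge=3)
        write_mgf([s], tmp_path / "x.mgf")
        (back,) = read_mgf(tmp_path / "x.mgf")
        assert back.scan_id == "scanA"
        assert back.precursor_charge == 3
        assert back.precursor_mz == pytest.approx(433.21)
        assert np.allclose(back.mz, s.mz)


class TestScoring:
    def test_score_is_count_plus_intensity_fraction(self):
        c = PeptideCandidate("PEPTIDE", ("P",), 0, 0)
        frags = [mz for _, _, mz in theoretical_fragments(c)]
        mz = frags[:4] + [1600.0, 1700.0]
        inten = [200.0] * 4 + [100.0, 100.0]
        s = _spec(mz, inten)
        assert score_psm(s, c, SearchSettings()) == pytest.approx(4 + 800 / 1000)

    def test_no_match_scores_zero(self):
        c = PeptideCandidate("PEPTIDE", ("P",), 0, 0)
        s = _spec([1600.0, 1700.0], [10.0, 10.0])
        assert score_psm(s, c, SearchSettings()) == 0.0

    def test_tolerance_boundary(self):
        c = PeptideCandidate("PEPTIDE", ("P",), 0, 0)
        frags = sorted(mz for _, _, mz in theoretical_fragments(c))
        f = frags[0]
        s = _spec([f + 0.020, f + 0.030], [100.0, 900.0])
        # only the +0.020 peak is inside +/- 0.025
        assert score_psm(s, c, SearchSettings()) == pytest.approx(1 + 100 / 1000)

    def test_empty_spectrum_is_an_error(self):
        c = PeptideCandidate("PEPTIDE", ("P",), 0, 0)
        s = Spectrum("s", 500.0, 2, np.array([]), np.array([]))
        with pytest.raises(ValueError):
            score_psm(s, c, SearchSettings())


class TestRunSearch:
    def _db(self):
        return add_decoys(assemble_database(
            [entry("PEPTIDEK", "A1"), entry("WWWWWWWWK", "A2")]))

    def test_precursor_window_arithmetic(self):
        # neutral mass of PEPTIDE at m/z 400.68725, z=2 is 799.3599
        db = add_decoys(assemble_database([entry("PEPTIDE", "A1")]))
        c = PeptideCandidate("PEPTIDE", ("A1",), 0, 0)
        frags = [mz for _, _, mz in theoretical_fragments(c)]
        s = _spec(frags, [100.0] * len(frags), pepmass=400.68725, charge=2)
        (psm,) = run_search(db, [s], OPEN)
        assert psm.candidate.sequence == "PEPTIDE"
        assert psm.precursor_neutral_mass == pytest.approx(799.3599, abs=1e-4)

    def test_unknown_charge_enumerates_hypotheses(self):
        db = add_decoys(assemble_database([entry("PEPTIDEK", "A1")]))
        c = PeptideCandidate("PEPTIDEK", ("A1",), 0, 0)
        m = peptide_monoisotopic_mass(c)
        frags = [mz for _, _, mz in theoretical_fragments(c)]
        s = Spectrum("s", (m + 3 * PROTON) / 3, None,
                     np.sort(np.asarray(frags)),
                     np.full(len(frags), 50.0))
        (psm,) = run_search(db, [s], OPEN)
        assert psm.charge == 3
        assert psm.candidate.sequence == "PEPTIDEK"

    def test_spectrum_without_candidates_yields_no_psm(self):
        db = self._db()
        s = _spec([500.0], [10.0], pepmass=5000.0, charge=2)
        assert run_search(db, [s], OPEN) == []


class TestQValues:
    def _psms(self, spec_string):
        """'T10,T9,D8.5' -> one PSM per spectrum with the given scores."""
        psms = []
        for i, tok in enumerate(spec_string.split(",")):
            decoy = tok[0] == "D"
            cand = PeptideCandidate("PEPK", ("DECOY_x",) if decoy else ("x",),
                                    0, 0)
            psms.append(PSM(f"s{i}", cand, 2, float(tok[1:]), decoy))
        return psms

    def test_worked_example(self):
        out = compute_q_values(self._psms("T10,T9,D8.5,T8,T7,D6"))
        q = {p.scan_id: p.q_value for p in out}
        assert q["s0"] == q["s1"] == 0.0
        assert q["s3"] == pytest.approx(0.25)
        assert q["s4"] == pytest.approx(0.25)

    def test_no_decoys_all_zero(self):
        out = compute_q_values(self._psms("T5,T4,T3"))
        assert all(p.q_value == 0.0 for p in out)

    def test_all_decoys_above_targets_capped_at_one(self):
        out = compute_q_values(self._psms("D9,D8,T5,T4"))
        assert all(p.q_value == 1.0 for p in out if not p.is_decoy)

    def test_q_values_non_increasing_with_score(self, rng):
        psms = []
        for i in range(200):
            decoy = bool(rng.random() < 0.4)
            cand = PeptideCandidate("PEPK", ("DECOY_x",) if decoy else ("x",),
                                    0, 0)
            psms.append(PSM(f"s{i}", cand, 2, float(rng.uniform(0, 20)), decoy))
        out = compute_q_values(psms)
        scores = [p.score for p in out]
        qs = [p.q_value for p in out]
        assert scores == sorted(scores, reverse=True)
        for a, b in zip(qs, qs[1:]):
            assert a <= b + 1e-12

    def test_accepted_set_monotone_in_fdr_cap(self, rng):
        psms = self._psms("T10,T9,D8.5,T8,T7,D6,T5,D4")
        out = compute_q_values(psms)
        sizes = [len([p for p in out if not p.is_decoy and p.q_value <= cap])
                 for cap in (0.0, 0.01, 0.25, 0.5, 1.0)]
        assert sizes == sorted(sizes)


class TestProteinGroups:
    def _db(self, entries):
        return assemble_database(entries)

    def _psm(self, pep):
        return PSM("s", PeptideCandidate(pep, ("x",), 0, 0), 2, 5.0, False, 0.0)

    def test_single_protein_group(self):
        db = self._db([entry("MKPEPAK", "A")])
        groups = group_proteins([self._psm("MK"), self._psm("PEPAK")], db)
        assert [g.accessions for g in groups] == [("A",)]

    def test_subset_protein_subsumed(self):
        db = self._db([entry("MKPEPAK", "A"), entry("CCCMKCCC", "B")])
        groups = group_proteins([self._psm("MK"), self._psm("PEPAK")], db)
        assert [g.accessions for g in groups] == [("A",)]

    def test_indistinguishable_proteins_merge(self):
        db = self._db([entry("MKPEPAK", "A"), entry("WMKPEPAK", "B")])
        groups = group_proteins([self._psm("MK"), self._psm("PEPAK")], db)
        assert [g.accessions for g in groups] == [("A", "B")]
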