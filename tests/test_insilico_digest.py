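import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import trflptools as t
from trflptools.insilico_digest import (
    IUPAC,
    Enzyme,
    match_table,
    prediction_table,
    reverse_complement,
)

ENZ = [t.MBOI, t.FAUI, t.HHAI]


def brute_force_cuts(seq, enzyme):
    """Exhaustive per-position, per-strand recognition scan (oracle)."""
    L = len(enzyme.recognition)
    rc = reverse_complement(enzyme.recognition)
    cuts = set()
    for i in range(len(seq) - L + 1):
        window = seq[i:i + L]
        if all(w in IUPAC[c] for w, c in zip(window, enzyme.recognition)):
            cuts.add(i + enzyme.cut_offset_top)
        if all(w in IUPAC[c] for w, c in zip(window, rc)):
            cuts.add(i + L - enzyme.cut_offset_bottom)
    return sorted(c for c in cuts if 0 < c < len(seq))


class TestFindCutPositions:
    def test_mboi_cuts_before_site(self):
        assert t.find_cut_positions("AAAGATCAAA", t.MBOI) == [3]

    def test_hhai_cuts_inside_site(self):
        assert t.find_cut_positions("TTGCGCTT", t.HHAI) == [5]

    def test_faui_offset_cut_downstream(self):
        assert t.find_cut_positions("AACCCGCAAAAAA", t.FAUI) == [11]

    def test_faui_bottom_strand_site_cuts_upstream(self):
        # GCGGG at index 10 is CCCGC on the bottom strand; the labeled strand
        # is cut 6 nt before it: 10 + 5 - 11 = 4
        assert t.find_cut_positions("AAAAAAAAAAGCGGGAAA", t.FAUI) == [4]

    def test_overlapping_sites_all_reported(self):
        assert t.find_cut_positions("AGATCGATCA", t.MBOI) == [1, 5]

    def test_invalid_character_reports_index(self):
        with pytest.raises(ValueError, match="index 3"):
            t.find_cut_positions("ACGZACGT", t.MBOI)

    def test_matches_brute_force_on_random_sequences(self, rng):
        for _ in range(100):
            n = int(rng.integers(50, 400))
            seq = "".join(rng.choice(list("ACGT"), n))
            for enz in ENZ:
                assert t.find_cut_positions(seq, enz) == brute_force_cuts(seq, enz)

    def test_matches_biopython_restriction(self, rng):
        from Bio.Restriction import FauI, HhaI, MboI
        from Bio.Seq import Seq

        bio = {"MboI": MboI, "FauI": FauI, "HhaI": HhaI}
        for _ in range(50):
            n = int(rng.integers(100, 600))
            seq = "".join(rng.choice(list("ACGT"), n))
            for enz in ENZ:
                # biopython reports 1-based first base of the downstream fragment
                theirs = sorted({p - 1 for p in bio[enz.name].search(Seq(seq))
                                 if 0 < p - 1 < n})
                assert t.find_cut_positions(seq, enz) == theirs

    def test_palindromic_sites_map_under_reverse_complement(self, rng):
        """Relabeling the other strand of a palindromic site turns each top-strand
        cut at c into a cut at n - (c - cut_top + cut_bottom): the site set is
        strand-symmetric but sticky-end cuts sit off the palindrome's center."""
        for _ in range(25):
            n = int(rng.integers(60, 300)) + 40
            seq = "A" * 20 + "".join(rng.choice(list("ACGT"), n - 40)) + "A" * 20
            for enz in (t.MBOI, t.HHAI):
                shift = enz.cut_offset_bottom - enz.cut_offset_top
                fwd = t.find_cut_positions(seq, enz)
                rev = t.find_cut_positions(reverse_complement(seq), enz)
                assert sorted(n - (c + shift) for c in fwd) == rev

    def test_case_insensitive(self):
        assert t.find_cut_positions("aaagatcaaa", t.MBOI) == [3]

    def test_degenerate_recognition_expansion(self):
        enz = Enzyme("toy", "GANTC", 2, 3)
        assert t.find_cut_positions("AAGATTCAA", enz) == [4]


class TestTerminalFragment:
    def test_nearest_cut_wins_double_digest(self, rng):
        recs, _ = t.generate_sequences(
            1, (600, 700), seed=4,
            planted_sites=[t.PlantedSite(t.MBOI, 149), t.PlantedSite(t.FAUI, 471)])
        _, seq = recs[0]
        pred = t.terminal_fragment(seq, [t.MBOI, t.FAUI])
        assert pred.expected_trf == 149 and pred.cutting_enzyme == "MboI"

    def test_no_cut_sentinel(self):
        pred = t.terminal_fragment("A" * 200, [t.MBOI, t.FAUI])
        assert pred.no_cut and pred.expected_trf is None

    def test_single_digest_equals_double_when_other_absent(self, rng):
        recs, _ = t.generate_sequences(1, (300, 400), seed=5,
                                       planted_sites=[t.PlantedSite(t.MBOI, 120)],
                                       enzymes=ENZ)
        _, seq = recs[0]
        single = t.terminal_fragment(seq, t.MBOI)
        double = t.terminal_fragment(seq, [t.MBOI, t.FAUI])
        assert single.expected_trf == double.expected_trf == 120

    def test_double_digest_is_min_of_singles(self, rng):
        for _ in range(50):
            n = int(rng.integers(200, 800))
            seq = "".join(rng.choice(list("ACGT"), n))
            singles = [t.terminal_fragment(seq, e).expected_trf for e in ENZ]
            combo = t.terminal_fragment(seq, ENZ).expected_trf
            present = [s for s in singles if s is not None]
            assert combo == (min(present) if present else None)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            t.terminal_fragment("", t.MBOI)


class TestPredictFromFasta:
    def test_planted_fixture_predictions(self, tmp_path, rng):
        from trflptools.synthetic_data import ACT_PRIMER
        fasta = tmp_path / "seqs.fasta"
        _, truth = t.generate_sequences(
            3, (400, 700), seed=6, out_fasta=fasta,
            planted_sites=[t.PlantedSite(t.MBOI, 154), t.PlantedSite(t.FAUI, 230)])
        preds = t.predict_from_fasta(fasta, ACT_PRIMER, [t.MBOI, t.FAUI])
        assert len(preds) == 3
        assert all(p.expected_trf == 154 and p.anchoring == "primer" for p in preds)

    def test_missing_primer_assumed_start(self, tmp_path):
        fasta = tmp_path / "s.fasta"
        fasta.write_text(">x\n" + "A" * 50 + "GATC" + "A" * 50 + "\n")
        (pred,) = t.predict_from_fasta(fasta, "CCCCCCCCCC", [t.MBOI])
        assert pred.anchoring == "assumed-start"
        assert pred.expected_trf == 50

    def test_reverse_strand_primer_flips_record(self, tmp_path):
        from trflptools.synthetic_data import ACT_PRIMER
        fasta = tmp_path / "s.fasta"
        recs, _ = t.generate_sequences(1, (300, 400), seed=7,
                                       planted_sites=[t.PlantedSite(t.MBOI, 100)])
        _, seq = recs[0]
        fasta.write_text(">x\n" + reverse_complement(seq) + "\n")
        (pred,) = t.predict_from_fasta(fasta, ACT_PRIMER, [t.MBOI])
        assert pred.anchoring == "revcomp" and pred.expected_trf == 100

    def test_empty_fasta_warns(self, tmp_path):
        fasta = tmp_path / "empty.fasta"
        fasta.write_text("")
        with pytest.warns(UserWarning, match="no records"):
            assert t.predict_from_fasta(fasta, "ACGT", [t.MBOI]) == []

    def test_line_wrapping_and_case_do_not_matter(self, tmp_path):
        recs, _ = t.generate_sequences(1, (300, 400), seed=8,
                                       planted_sites=[t.PlantedSite(t.HHAI, 77)])
        _, seq = recs[0]
        f1 = tmp_path / "a.fasta"
        f1.write_text(">x\n" + seq + "\n")
        f2 = tmp_path / "b.fasta"
        wrapped = "\n".join(seq[i:i + 37].lower() for i in range(0, len(seq), 37))
        f2.write_text(">x\n" + wrapped + "\n")
        p1 = t.predict_from_fasta(f1, "", [t.HHAI])[0]
        p2 = t.predict_from_fasta(f2, "", [t.HHAI])[0]
        assert p1.expected_trf == p2.expected_trf == 77


class TestMatchTrfs:
    def _preds(self, sizes):
        return [t.DigestPrediction(f"c{i}", ("FauI",), s, cutting_enzyme="FauI")
                for i, s in enumerate(sizes)]

    def test_small_downward_drift_matches(self):
        # capillary sizes run a few bp short of the in-silico prediction
        (m,) = t.match_trfs([102.0], self._preds([106]), tolerance_bp=5)
        assert m.matched and m.drift == pytest.approx(-4.0)

    def test_exact_size_matches_with_zero_drift(self):
        (m,) = t.match_trfs([596.0], self._preds([596]), tolerance_bp=5)
        assert m.matched and m.drift == 0.0

    def test_far_observation_unmatched(self):
        (m,) = t.match_trfs([500.0], self._preds([106]), tolerance_bp=5)
        assert not m.matched and m.prediction is None

    def test_nearest_prediction_wins(self):
        (m,) = t.match_trfs([104.0], self._preds([106, 100]), tolerance_bp=5)
        assert m.prediction.expected_trf == 106

    def test_linear_calibration_recovers_systematic_drift(self):
        expected = [106, 230, 366, 476, 596]
        observed = [obs - 0.012 * obs for obs in expected]  # ~1.2% compression
        matches = t.match_trfs(observed, self._preds(expected),
                               mode="linear-calibration", tolerance_bp=3)
        assert all(m.matched for m in matches)
        assert [m.prediction.expected_trf for m in matches] == expected

    def test_tables_render(self):
        preds = self._preds([106, 230]) + [t.DigestPrediction("c9", ("FauI",), None)]
        tab = prediction_table(preds)
        assert tab.loc[2, "expected_trf"] == "no cut"
        matches = t.match_trfs([102.0], preds, tolerance_bp=5)
        assert set(match_table(matches).columns) >= {"observed_trf", "drift", "matched"}


@settings(max_examples=25, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=30, max_size=120))
def test_cut_positions_match_oracle_property(seq):
    for enz in ENZ:
        assert t.find_cut_positions(seq, enz) == brute_force_cuts(seq, enz)
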