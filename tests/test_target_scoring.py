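"""Expectation-score alignment, inhibition calls, and transcript scanning."""

import pytest

from conftest import random_rna
from mirfam.seqio import MatureMiRNA, SequenceRecord, iter_uts_rows, reverse_complement
from mirfam.target_scoring import (
    PenaltyScheme,
    classify_inhibition,
    min_penalty_alignment,
    scan_transcript,
)
from oracles import exhaustive_min_penalty

MIR1 = "UUGGCAUUCUGUCCACCUCC"
SCHEME = PenaltyScheme()


class TestExpectationScore:
    def test_every_printed_row_reproduced(self, tables):
        """All 16 unique target sites: printed E-value and inhibition mode."""
        for row in iter_uts_rows(tables):
            aln = min_penalty_alignment(row["mature_seq"], row["uts_seq"], SCHEME)
            assert aln.E == pytest.approx(row["evalue"]), row["uts_id"]
            assert classify_inhibition(aln, SCHEME) == row["inhibition"], row["uts_id"]

    @pytest.mark.parametrize(
        "site,expected_e",
        [
            ("GGAGGUGGACAGAAUGCCAA", 0.0),  # perfect complement
            ("GGAGGUUGACAGAAUGCCAA", 1.0),  # one non-seed mismatch (pos 14)
            ("GGAGUUGGACAGAAUGCAAA", 2.5),  # non-seed + seed mismatch
            ("GGAUGUGUGCAGAGUGCCAA", 3.0),  # two mismatches + two wobbles
            ("GGAGGAGGACAGAGAUGCCAA", 3.0),  # target bulge + mismatch
        ],
    )
    def test_scheme_arithmetic(self, site, expected_e):
        assert min_penalty_alignment(MIR1, site, SCHEME).E == pytest.approx(expected_e)

    def test_positions_beyond_window_unscored(self):
        mir22 = MIR1 + "AU"
        aln = min_penalty_alignment(mir22, "AAGGAGGUUGACAGAAUGCCAA", SCHEME)
        assert aln.E == pytest.approx(1.0)
        assert aln.states[20] == "unscored" and aln.states[21] == "unscored"

    def test_zero_iff_perfect_complement(self, rng):
        for _ in range(20):
            mir = random_rna(rng, 20)
            aln = min_penalty_alignment(mir, reverse_complement(mir), SCHEME)
            assert aln.E == 0.0
            assert all(s == "WC" for s in aln.states)

    def test_single_extra_mismatch_adds_exactly_one(self, rng):
        # swapping one WC pair at a scored non-seed position raises E by 1.0
        mir = random_rna(rng, 20)
        site = list(reverse_complement(mir))
        pos = 12  # miRNA position, outside seed
        idx = 20 - pos
        wc = site[idx]
        for b in "ACGU":
            if b != wc and (mir[pos - 1], b) not in {("G", "U"), ("U", "G")}:
                site[idx] = b
                break
        base = min_penalty_alignment(mir, reverse_complement(mir), SCHEME).E
        bumped = min_penalty_alignment(mir, "".join(site), SCHEME).E
        assert bumped == pytest.approx(base + 1.0)

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(6, 13))
            mir = random_rna(rng, n)
            site_len = int(rng.integers(max(4, n - 2), n + 3))
            site = random_rna(rng, site_len)
            got = min_penalty_alignment(mir, site, SCHEME).E
            want = exhaustive_min_penalty(mir, site, max_gaps=None)
            assert got == pytest.approx(want), (mir, site)
            # and the affine optimum can only improve on a 2-gap cap
            assert got <= exhaustive_min_penalty(mir, site, max_gaps=2) + 1e-9

    def test_site_length_band_enforced(self):
        with pytest.raises(ValueError):
            min_penalty_alignment(MIR1, "ACGU", SCHEME)


class TestInhibition:
    def test_central_bulge_calls_translation(self):
        # miRNA position 11 left unpaired by a site-side deletion
        aln = min_penalty_alignment(MIR1, "GGAGGUGGAAGAAUGCCGG", SCHEME)
        assert classify_inhibition(aln, SCHEME) == "Translation"

    def test_non_central_mismatch_calls_cleavage(self):
        aln = min_penalty_alignment(MIR1, "GGAGGUUGACAGAAUGCCAA", SCHEME)
        assert classify_inhibition(aln, SCHEME) == "Cleavage"

    def test_perfect_complement_calls_cleavage(self):
        aln = min_penalty_alignment(MIR1, reverse_complement(MIR1), SCHEME)
        assert classify_inhibition(aln, SCHEME) == "Cleavage"

    def test_central_wobble_still_cleavage(self):
        # put a wobble at position 10 (G:U) - central but not disruptive
        site = list(reverse_complement(MIR1))
        assert MIR1[9] == "U"
        site[20 - 10] = "G"
        aln = min_penalty_alignment(MIR1, "".join(site), SCHEME)
        assert aln.states[9] == "wobble"
        assert classify_inhibition(aln, SCHEME) == "Cleavage"


class TestScanTranscript:
    def _transcript(self, rng, site, pos, length=240):
        seq = list(random_rna(rng, length))
        seq[pos - 1 : pos - 1 + len(site)] = list(site)
        return SequenceRecord(id="tx", sequence="".join(seq))

    def test_perfect_implant_found_at_position(self, rng):
        site = reverse_complement(MIR1)
        tx = self._transcript(rng, site, 101)
        hits = scan_transcript(MIR1, tx, SCHEME)
        assert any(h.start == 101 and h.alignment.E == 0.0 for h in hits)

    def test_score_above_cutoff_not_reported(self, rng):
        # one seed mismatch (1.5) + four non-seed mismatches = 5.5 > 5
        site = list(reverse_complement(MIR1))
        for pos in (3, 10, 12, 14, 16):  # miRNA positions; 3 is in the seed
            idx = 20 - pos
            wc = site[idx]
            for b in "ACGU":
                if b != wc and (MIR1[pos - 1], b) not in {("G", "U"), ("U", "G")}:
                    site[idx] = b
                    break
        engineered = "".join(site)
        assert min_penalty_alignment(MIR1, engineered, SCHEME).E == pytest.approx(5.5)
        tx = self._transcript(rng, engineered, 101)
        hits = scan_transcript(MIR1, tx, SCHEME)
        assert not any(h.start == 101 for h in hits)

    def test_two_implants_reported_in_score_order(self, rng):
        perfect = reverse_complement(MIR1)
        weak = list(perfect)
        # seed mismatch at position 3 (1.5) + non-seed at 16 (1.0)
        for pos in (3, 16):
            idx = 20 - pos
            wc = weak[idx]
            for b in "ACGU":
                if b != wc and (MIR1[pos - 1], b) not in {("G", "U"), ("U", "G")}:
                    weak[idx] = b
                    break
        tx = self._transcript(rng, perfect, 151)
        seq = list(tx.sequence)
        seq[50 : 50 + 20] = weak
        tx = SequenceRecord(id="tx", sequence="".join(seq))
        hits = scan_transcript(MIR1, tx, SCHEME)
        es = [h.alignment.E for h in hits[:2]]
        assert es == sorted(es)
        assert hits[0].start == 151 and hits[0].alignment.E == 0.0
        assert any(h.start == 51 and h.alignment.E == pytest.approx(2.5) for h in hits)
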