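"""Ground-truthed generators: family divergence, genomes, transcripts."""

import math

import numpy as np
import pytest

from mirfam.homology_scan import extract_precursor_window, scan_for_mature
from mirfam.seqio import MatureMiRNA, reverse_complement
from mirfam.synthetic_data import (
    Edit,
    RecipeError,
    SyntheticSpec,
    build_site,
    dinucleotide_shuffle,
    evolve_family,
    simulate_family,
    synthesize_genome,
    synthesize_transcripts,
)
from mirfam.target_scoring import PenaltyScheme, classify_inhibition, scan_transcript


class TestFamilySimulation:
    def test_zero_rate_gives_identical_leaves(self):
        spec = SyntheticSpec(seed=1, family_site_rate=0.0)
        leaves, _ = simulate_family(spec)
        assert all(m.sequence == spec.mature_seq for m in leaves)

    def test_same_seed_reproducible(self):
        spec = SyntheticSpec(seed=9)
        a, _ = simulate_family(spec)
        b, _ = simulate_family(spec)
        assert [(m.id, m.sequence) for m in a] == [(m.id, m.sequence) for m in b]

    def test_pairwise_distance_matches_markov_expectation(self):
        """Two leaves at total path length t: the expected p-distance is
        (3/4)(1 - prod_branches(1 - 4q_b/3)) for the per-branch substitution
        probability q_b = 1 - exp(-rate * bl); check within 3 s.e. over 500
        replicates."""
        rate, bl = 0.05, 1.0  # two branches of length 1
        q = 1.0 - math.exp(-rate * bl)
        lam = 1.0 - 4.0 * q / 3.0
        expect = 0.75 * (1.0 - lam**2)
        n_sites = 20
        diffs = []
        for seed in range(500):
            leaves, _ = evolve_family(
                "UUGGCAUUCUGUCCACCUCC", f"(a:{bl},b:{bl});", rate, seed=seed
            )
            a, b = leaves
            diffs.append(sum(x != y for x, y in zip(a.sequence, b.sequence)) / n_sites)
        mean = float(np.mean(diffs))
        se = math.sqrt(expect * (1 - expect) / (500 * n_sites))
        assert abs(mean - expect) <= 3 * se


class TestGenome:
    def test_implants_recovered_at_manifest_coordinates(self):
        spec = SyntheticSpec(seed=3, genome_length=2000, n_hairpin_implants=5, n_decoys=5)
        genome, truth = synthesize_genome(spec)
        hits = scan_for_mature(spec.mature_seq, genome, 0)
        keys = {(h.start, h.strand) for h in hits}
        for e in truth.implants:
            assert (e["mature_start"], e["strand"]) in keys
            assert len(truth.implants) == 5

    def test_arm_mutation_rate_thins_pairing(self):
        """At arm mutation rate 0.15 the mature still scans (it is exact) but
        its paired count drops by about 20 * 0.15 = 3, within 3 s.e. over 200
        replicates."""
        from mirfam.hairpin import fold_structure, validate_precursor

        rate = 0.15
        unpaired_counts = []
        for seed in range(200):
            spec = SyntheticSpec(
                seed=seed,
                genome_length=400,
                n_hairpin_implants=1,
                n_decoys=0,
                arm_mutation_rate=rate,
            )
            genome, truth = synthesize_genome(spec)
            e = truth.implants[0]
            (hit,) = [
                h
                for h in scan_for_mature(spec.mature_seq, genome, 0)
                if (h.start, h.strand) == (e["mature_start"], e["strand"])
            ]
            w = extract_precursor_window(hit, genome, 0, 75, 170)
            report = validate_precursor(w, fold_structure(w.window_seq))
            unpaired_counts.append(20 - report.mature_paired)
        mean = float(np.mean(unpaired_counts))
        expect = 20 * rate
        se = math.sqrt(20 * rate * (1 - rate) / 200)
        # pair maximization can rescue a mutated position via a wobble or an
        # alternative partner, so the observed mean may sit below the
        # binomial expectation but must not exceed it
        assert mean <= expect + 3 * se
        assert mean >= 1.0

    def test_decoys_yield_no_validated_windows(self):
        """Dinucleotide-shuffled decoy loci must produce no hairpin-validated
        window in >= 95% of seeds."""
        from mirfam.hairpin import best_precursor_report

        clean_seeds = 0
        seeds = range(1, 21)
        for seed in seeds:
            spec = SyntheticSpec(seed=seed, genome_length=2000, n_hairpin_implants=3, n_decoys=6)
            genome, truth = synthesize_genome(spec)
            spans = [(d["unit_start"], d["unit_end"]) for d in truth.decoys]
            bad = 0
            for h in scan_for_mature(spec.mature_seq, genome, 0):
                if any(a <= h.start <= b for a, b in spans):
                    report, _ = best_precursor_report(extract_precursor_window(h, genome))
                    bad += report.verdict
            clean_seeds += bad == 0
        assert clean_seeds >= 0.95 * len(seeds)

    def test_bit_reproducible(self):
        spec = SyntheticSpec(seed=12, genome_length=2000, n_hairpin_implants=3, n_decoys=3)
        (g1, t1), (g2, t2) = synthesize_genome(spec), synthesize_genome(spec)
        assert g1.sequence == g2.sequence
        assert t1.implants == t2.implants and t1.decoys == t2.decoys

    def test_capacity_validation(self):
        with pytest.raises(ValueError):
            SyntheticSpec(seed=1, genome_length=500, n_hairpin_implants=5)


class TestDinucleotideShuffle:
    def test_preserves_dinucleotide_counts(self, rng):
        from collections import Counter

        seq = "UUGGCAUUCUGUCCACCUCCGCAAAGCAGGAGGUGGACAGAAUGCCAA"
        shuf = dinucleotide_shuffle(seq, rng)
        assert shuf != seq
        assert Counter(zip(shuf, shuf[1:])) == Counter(zip(seq, seq[1:]))
        assert shuf[0] == seq[0] and shuf[-1] == seq[-1]


class TestTranscripts:
    def test_perfect_recipe_scans_at_manifest_position(self):
        spec = SyntheticSpec(seed=21, transcript_specs=((240, ()),))
        txs, truth = synthesize_transcripts(spec)
        site = truth.transcript_sites[0]
        hits = scan_transcript(spec.mature_seq, txs[0])
        assert any(h.start == site["start"] and h.alignment.E == 0.0 for h in hits)

    @pytest.mark.parametrize(
        "edits,expected_e",
        [
            ((Edit("mismatch", 14),), 1.0),
            ((Edit("mismatch", 3),), 1.5),
            ((Edit("wobble", 7),), 0.5),
            ((Edit("mismatch", 3), Edit("wobble", 7)), 2.0),
            ((Edit("gap_target", 10),), 2.0),
        ],
    )
    def test_recipe_arithmetic_matches_scan(self, edits, expected_e):
        spec = SyntheticSpec(seed=22, transcript_specs=((240, tuple(edits)),))
        txs, truth = synthesize_transcripts(spec)
        site = truth.transcript_sites[0]
        assert site["intended_e"] == pytest.approx(expected_e)
        hits = scan_transcript(spec.mature_seq, txs[0])
        match = [h for h in hits if h.start == site["start"]]
        assert match and match[0].alignment.E == pytest.approx(expected_e)

    def test_central_gap_recipe_calls_translation(self):
        site, intended = build_site(
            "UUGGCAUUCUGUCCACCUCC", (Edit("gap_target", 10),)
        )
        from mirfam.target_scoring import min_penalty_alignment

        aln = min_penalty_alignment("UUGGCAUUCUGUCCACCUCC", site)
        assert aln.E == pytest.approx(intended)
        assert classify_inhibition(aln) == "Translation"

    def test_wobble_recipe_needs_g_or_u(self):
        with pytest.raises(RecipeError):
            build_site("UUGGCAUUCUGUCCACCUCC", (Edit("wobble", 6),))  # A at 6
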