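"""Alignment, p-distance, neighbor joining, bootstrap, bipartitions."""

import numpy as np
import pytest

from conftest import random_rna
from mirfam.phylo import (
    CharacterAlignment,
    UndefinedDistanceError,
    align_family,
    bootstrap_supports,
    build_nj_tree,
    check_bipartition,
    p_distance_matrix,
    parse_newick,
)
from mirfam.seqio import SequenceRecord
from oracles import random_additive_tree


def records(seqs):
    return [SequenceRecord(id=f"s{i}", sequence=s) for i, s in enumerate(seqs)]


class TestAlignFamily:
    def test_identical_sequences_align_gapless(self):
        aln = align_family(records(["ACGUACGU"] * 4))
        assert all(r == "ACGUACGU" for r in aln.rows)

    def test_three_letter_hand_case(self):
        aln = align_family(records(["ACGU", "AGU"]))
        assert aln.rows[0] == "ACGU"
        assert aln.rows[1] == "A-GU"

    def test_degapping_recovers_inputs(self, rng):
        for _ in range(100):
            seqs = [random_rna(rng, int(rng.integers(5, 30))) for _ in range(4)]
            aln = align_family(records(seqs))
            assert max(len(s) for s in seqs) <= aln.n_columns <= sum(len(s) for s in seqs)
            for row, seq in zip(aln.rows, seqs):
                assert row.replace("-", "") == seq

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_family(records(["ACGU"]))


class TestPDistance:
    def test_identical_rows_zero(self):
        aln = CharacterAlignment(("a", "b"), ("ACGU", "ACGU"))
        assert p_distance_matrix(aln).values[0, 1] == 0.0

    def test_hand_counted_distance(self):
        aln = CharacterAlignment(
            ("a", "b"), ("UUGGCAUUCUGUCCACCUCC", "UUGGCAGUAUGCCCACCUCC")
        )
        # differs at positions 7, 9, 12
        assert p_distance_matrix(aln).values[0, 1] == pytest.approx(3 / 20)

    def test_pairwise_deletion(self):
        aln = CharacterAlignment(("a", "b"), ("AC-GU", "ACG-U"))
        dm = p_distance_matrix(aln)
        assert dm.comparable_sites[0, 1] == 3
        assert dm.values[0, 1] == 0.0

    def test_no_comparable_sites_raises(self):
        aln = CharacterAlignment(("a", "b"), ("AC--", "--GU"))
        with pytest.raises(UndefinedDistanceError):
            p_distance_matrix(aln)

    def test_partial_deletion_drops_gappy_columns(self):
        aln = CharacterAlignment(
            ("a", "b", "c", "d"),
            ("ACGU-", "ACGA-", "ACGU-", "ACGUU"),
        )
        full = p_distance_matrix(aln)
        trimmed = p_distance_matrix(aln, site_coverage=0.95)
        # column 5 is non-gap in only 1/4 rows and is dropped globally
        assert trimmed.comparable_sites[0, 3] == 4
        assert full.comparable_sites[0, 3] == 4  # pairwise deletion already drops it
        assert trimmed.values[0, 1] == pytest.approx(1 / 4)

    def test_column_order_invariance(self, rng):
        seqs = [random_rna(rng, 30) for _ in range(5)]
        aln = CharacterAlignment(tuple(f"t{i}" for i in range(5)), tuple(seqs))
        perm = rng.permutation(30)
        shuffled = CharacterAlignment(
            aln.taxa, tuple("".join(r[c] for c in perm) for r in aln.rows)
        )
        assert np.allclose(
            p_distance_matrix(aln).values, p_distance_matrix(shuffled).values
        )


class TestNeighborJoining:
    def _dm(self, taxa, values):
        from mirfam.phylo import DistanceMatrix

        arr = np.array(values, dtype=float)
        return DistanceMatrix(taxa=tuple(taxa), values=arr, comparable_sites=np.ones_like(arr, dtype=int))

    def test_four_taxon_additive_case(self):
        # distances from the tree ((A:1,B:2):1,(C:3,D:4))
        d = [
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ]
        tree = build_nj_tree(self._dm("ABCD", d))
        ok, _ = check_bipartition(tree, {"A", "B"})
        assert ok
        taxa, dist = tree.path_distances()
        idx = {t: i for i, t in enumerate(taxa)}
        for (u, v), want in {
            ("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
            ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7,
        }.items():
            assert dist[idx[u], idx[v]] == pytest.approx(want, abs=1e-12)

    def test_three_taxa_closed_form(self):
        tree = build_nj_tree(self._dm("ABC", [[0, 2, 3], [2, 0, 5], [3, 5, 0]]))
        taxa, dist = tree.path_distances()
        idx = {t: i for i, t in enumerate(taxa)}
        assert dist[idx["A"], idx["B"]] == pytest.approx(2)
        assert dist[idx["A"], idx["C"]] == pytest.approx(3)
        assert dist[idx["B"], idx["C"]] == pytest.approx(5)

    def test_recovers_random_additive_trees(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 9))
            taxa, dist = random_additive_tree(rng, n)
            tree = build_nj_tree(self._dm(taxa, dist))
            got_taxa, got = tree.path_distances()
            idx = {t: i for i, t in enumerate(got_taxa)}
            order = [idx[t] for t in taxa]
            assert np.max(np.abs(got[np.ix_(order, order)] - dist)) < 1e-9

    def test_branch_lengths_non_negative(self, rng):
        # noisy (non-additive) distances may produce negative NJ estimates;
        # they must be clamped
        for _ in range(20):
            n = 6
            taxa, dist = random_additive_tree(rng, n)
            noisy = dist + rng.uniform(0, 0.3, size=dist.shape)
            noisy = (noisy + noisy.T) / 2
            np.fill_diagonal(noisy, 0.0)
            tree = build_nj_tree(self._dm(taxa, noisy))

            def walk(node):
                for ch, bl in node.children:
                    assert bl >= 0
                    walk(ch)

            walk(tree.root)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            build_nj_tree(self._dm("AB", [[0, 1], [1, 0]]))


class TestNewick:
    def test_round_trip_topology_and_supports(self, rng):
        seqs = [random_rna(rng, 60) for _ in range(6)]
        # diverge copies so the tree is non-trivial
        aln = align_family(records(seqs))
        tree = bootstrap_supports(aln, n_replicates=50, seed=3)
        text = tree.newick()
        back = parse_newick(text)
        assert sorted(back.leaf_names()) == sorted(tree.leaf_names())
        orig = {bp: s for bp, (_, s) in tree.bipartitions().items()}
        parsed = {bp: s for bp, (_, s) in back.bipartitions().items()}
        all_leaves = frozenset(tree.leaf_names())
        for bp, support in orig.items():
            assert bp in parsed or (all_leaves - bp) in parsed
            got = parsed.get(bp, parsed.get(all_leaves - bp))
            if support is not None:
                assert got == pytest.approx(support)


class TestBootstrap:
    def test_unanimous_columns_give_full_support(self):
        rows = ("AAAA", "AAAA", "CCCC", "CCCC", "CCGG")
        aln = CharacterAlignment(("a", "b", "c", "d", "e"), rows)
        tree = bootstrap_supports(aln, n_replicates=100, seed=1)
        ok, support = check_bipartition(tree, {"a", "b"})
        assert ok and support == pytest.approx(100.0)

    def test_deterministic_given_seed(self, rng):
        seqs = [random_rna(rng, 40) for _ in range(5)]
        aln = align_family(records(seqs))
        t1 = bootstrap_supports(aln, 100, seed=9)
        t2 = bootstrap_supports(aln, 100, seed=9)
        assert t1.newick() == t2.newick()

    def test_true_bipartitions_strongly_supported(self, rng):
        """Low-divergence simulated 5-taxon family (0.05 substitutions per
        site per branch): the true cherry edges reach high support at 200
        replicates."""
        from mirfam.synthetic_data import evolve_family

        root = "".join(rng.choice(list("ACGU"), size=400))
        fam, _ = evolve_family(root, "((t1:1,t2:1):1,(t3:1,t4:1):1,t5:2);", 0.05, seed=5)
        aln = align_family(fam)
        tree = bootstrap_supports(aln, 200, seed=7)
        ok12, s12 = check_bipartition(tree, {"t1", "t2"})
        ok34, s34 = check_bipartition(tree, {"t3", "t4"})
        assert ok12 and ok34
        assert s12 >= 90 and s34 >= 90

    def test_single_column_rejected(self):
        aln = CharacterAlignment(("a", "b", "c"), ("A", "C", "G"))
        with pytest.raises(ValueError):
            bootstrap_supports(aln, 10, seed=0)


class TestBipartition:
    def _tree(self):
        d = [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]]
        from mirfam.phylo import DistanceMatrix

        return build_nj_tree(
            DistanceMatrix(
                taxa=("A", "B", "C", "D"),
                values=np.array(d, dtype=float),
                comparable_sites=np.ones((4, 4), dtype=int),
            )
        )

    def test_present_and_absent_groups(self):
        tree = self._tree()
        assert check_bipartition(tree, {"A", "B"})[0]
        assert check_bipartition(tree, {"C", "D"})[0]
        assert not check_bipartition(tree, {"A", "C"})[0]

    def test_unknown_taxon_rejected(self):
        with pytest.raises(ValueError):
            check_bipartition(self._tree(), {"A", "Z"})

    def test_five_prime_three_prime_separation(self, tables):
        """The printed unique mature sequences split 5p representatives
        (clusters 1-2) from 3p representatives (clusters 3-8) across one
        internal edge, the family's reported arm-wise clustering."""
        recs = [SequenceRecord(id=cid, sequence=seq) for cid, seq in tables.unique_matures()]
        aln = align_family(recs)
        tree = build_nj_tree(p_distance_matrix(aln))
        ok, _ = check_bipartition(tree, {"UmiR394-1", "UmiR394-2"})
        assert ok
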