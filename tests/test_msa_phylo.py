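"""k-tuple/identity distances, progressive alignment and neighbor joining."""

from collections import Counter

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ph4h3 import msa_phylo as mp
from ph4h3.errors import InputError

gapped_dna = st.text(alphabet="ACGT-", min_size=1, max_size=40)


def _random_dna(rng, n):
    return "".join("ACGT"[b] for b in rng.integers(0, 4, n))


class TestKtupleDistance:
    def test_identical_sequences_have_distance_zero(self, rng):
        s = _random_dna(rng, 60)
        assert mp.ktuple_distance(s, s, 4) == 0.0

    def test_disjoint_word_sets_give_distance_one(self):
        assert mp.ktuple_distance("AAAAAA", "CCCCCC", 3) == 1.0

    def test_matches_naive_multiset_count(self, rng):
        for _ in range(5):
            a, b = _random_dna(rng, 100), _random_dna(rng, 100)
            k = 3
            wa = Counter(a[i : i + k] for i in range(len(a) - k + 1))
            wb = Counter(b[i : i + k] for i in range(len(b) - k + 1))
            shared = sum(min(wa[w], wb[w]) for w in wa)
            expected = 1 - shared / min(sum(wa.values()), sum(wb.values()))
            assert mp.ktuple_distance(a, b, k) == pytest.approx(expected)

    def test_sequence_shorter_than_k_rejected(self):
        with pytest.raises(InputError):
            mp.ktuple_distance("ACG", "ACGT", 4)


class TestIdentityDistance:
    def test_identical_rows_zero(self):
        assert mp.identity_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_hand_counted_example(self):
        # comparable columns 1,2,4,5; identities A,C,G -> 3/4 identical
        assert mp.identity_distance("AC-GT", "ACAGA") == pytest.approx(0.25)

    def test_no_comparable_positions_gives_one(self):
        assert mp.identity_distance("A---", "-CCC") == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            mp.identity_distance("ACGT", "ACG")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(gapped_dna, gapped_dna)
    def test_symmetry_and_range_property(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        d = mp.identity_distance(a, b)
        assert d == mp.identity_distance(b, a)
        assert 0.0 <= d <= 1.0
        assert mp.identity_distance(a, a) in (0.0, 1.0)  # 1.0 iff all-gap


class TestDistanceMatrix:
    def test_identical_rows_give_zero_matrix(self):
        aln = mp.Alignment(["a", "b", "c"], ["ACGT"] * 3)
        D = mp.distance_matrix(aln)
        assert np.all(D.values == 0)

    def test_equals_elementwise_pairwise_recomputation(self, rng):
        rows = []
        for _ in range(6):
            row = list(_random_dna(rng, 40))
            for pos in rng.choice(40, size=6, replace=False):
                row[pos] = "-"
            rows.append("".join(row))
        aln = mp.Alignment([f"s{i}" for i in range(6)], rows)
        D = mp.distance_matrix(aln)
        for i in range(6):
            for j in range(6):
                expected = 0.0 if i == j else mp.identity_distance(rows[i], rows[j])
                assert D.values[i, j] == pytest.approx(expected)

    def test_symmetry_zero_diagonal_and_range(self, rng):
        rows = [_random_dna(rng, 30) for _ in range(5)]
        D = mp.distance_matrix(mp.Alignment(list("abcde"), rows))
        assert np.allclose(D.values, D.values.T)
        assert np.all(np.diag(D.values) == 0)
        assert np.all((D.values >= 0) & (D.values <= 1))

    def test_row_permutation_permutes_matrix(self, rng):
        rows = [_random_dna(rng, 30) for _ in range(4)]
        labels = list("abcd")
        D1 = mp.distance_matrix(mp.Alignment(labels, rows))
        perm = [2, 0, 3, 1]
        D2 = mp.distance_matrix(
            mp.Alignment([labels[i] for i in perm], [rows[i] for i in perm])
        )
        for x in labels:
            for y in labels:
                assert D1[x, y] == pytest.approx(D2[x, y])

    def test_tsv_roundtrip(self, tmp_path, rng):
        rows = [_random_dna(rng, 30) for _ in range(4)]
        D = mp.distance_matrix(mp.Alignment(list("abcd"), rows))
        D.to_tsv(tmp_path / "d.tsv")
        back = mp.DistanceMatrix.from_tsv(tmp_path / "d.tsv")
        assert back.labels == D.labels
        assert np.allclose(back.values, D.values, atol=1e-6)


class TestCountWithin:
    def test_farthest_cutoff_counts_everyone(self):
        vals = np.array(
            [[0, 0.1, 0.2, 0.3], [0.1, 0, 0.15, 0.25], [0.2, 0.15, 0, 0.1], [0.3, 0.25, 0.1, 0]]
        )
        D = mp.DistanceMatrix(list("abcd"), vals)
        assert mp.count_within(D, "a", "d") == 3

    def test_hand_built_matrix(self):
        vals = np.array(
            [[0, 0.1, 0.2, 0.3], [0.1, 0, 0.15, 0.25], [0.2, 0.15, 0, 0.1], [0.3, 0.25, 0.1, 0]]
        )
        D = mp.DistanceMatrix(list("abcd"), vals)
        assert mp.count_within(D, "a", "c") == 2  # b (0.1) and c itself (0.2)

    def test_unknown_label_raises(self):
        D = mp.DistanceMatrix(list("abc"), np.zeros((3, 3)))
        with pytest.raises(InputError):
            mp.count_within(D, "a", "z")


class TestProgressiveAlign:
    def test_identical_sequences_align_gapless(self, rng):
        s = _random_dna(rng, 100)
        aln = mp.progressive_align({f"s{i}": s for i in range(5)})
        assert aln.ncol == 100
        assert all(row == s for row in aln.rows)

    def test_degapping_roundtrip_exact(self, rng):
        seqs = {f"s{i}": _random_dna(rng, 80 + int(rng.integers(0, 30))) for i in range(6)}
        aln = mp.progressive_align(seqs)
        for i, lab in enumerate(aln.labels):
            assert aln.ungapped(i) == seqs[lab]

    def test_two_sequences_reach_global_dp_optimum(self, rng):
        from Bio.Align import PairwiseAligner

        params = mp.AlignParams()
        for _ in range(5):
            a, b = _random_dna(rng, 60), _random_dna(rng, 55)
            aln = mp.progressive_align({"a": a, "b": b}, params=params)
            # score the produced pairwise alignment
            score, in_gap = 0.0, None
            for ca, cb in zip(aln.rows[0], aln.rows[1]):
                if ca != "-" and cb != "-":
                    score += params.match if ca == cb else params.mismatch
                    in_gap = None
                else:
                    which = "a" if ca == "-" else "b"
                    score -= params.gap_extend + (
                        params.gap_open if in_gap != which else 0.0
                    )
                    in_gap = which
            aligner = PairwiseAligner()
            aligner.mode = "global"
            aligner.match_score = params.match
            aligner.mismatch_score = params.mismatch
            aligner.open_gap_score = -(params.gap_open + params.gap_extend)
            aligner.extend_gap_score = -params.gap_extend
            assert score == pytest.approx(aligner.score(a, b))

    def test_label_mismatch_with_guide_rejected(self, rng):
        seqs = {"a": _random_dna(rng, 30), "b": _random_dna(rng, 30)}
        guide = mp.guide_tree({"a": seqs["a"], "x": _random_dna(rng, 30)})
        with pytest.raises(InputError):
            mp.progressive_align(seqs, guide)

    def test_alignment_order_follows_input_labels(self, rng):
        seqs = {f"s{i}": _random_dna(rng, 50) for i in range(4)}
        aln = mp.progressive_align(seqs)
        assert aln.labels == list(seqs)


def _tree_distances(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return labels, vals


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        vals = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        tree = mp.neighbor_joining(mp.DistanceMatrix(list("abc"), vals))
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert lengths["b"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert lengths["c"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    @pytest.mark.parametrize("n", [4, 5])
    def test_additive_matrix_recovered_exactly(self, n, rng):
        # build a random tree, read off its additive distances, re-estimate
        source = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0,
            death_rate=0.0,
            num_extant_tips=n,
            rng=__import__("random").Random(n),
        )
        for i, leaf in enumerate(source.leaf_node_iter()):
            leaf.taxon.label = f"t{i}"
        labels, vals = _tree_distances(source)
        est = mp.neighbor_joining(mp.DistanceMatrix(labels, vals))
        est_labels, est_vals = _tree_distances(est)
        order = [est_labels.index(lab) for lab in labels]
        assert np.allclose(est_vals[np.ix_(order, order)], vals, atol=1e-9)

    def test_internal_node_count(self, rng):
        n = 7
        vals = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                vals[i, j] = vals[j, i] = rng.uniform(0.1, 1.0)
        tree = mp.neighbor_joining(mp.DistanceMatrix([f"t{i}" for i in range(n)], vals))
        internal = sum(1 for nd in tree.preorder_node_iter() if not nd.is_leaf())
        assert internal == n - 2
        for edge in tree.preorder_edge_iter():
            assert edge.length is None or edge.length >= 0

    def test_topology_agrees_with_skbio(self):
        import skbio

        vals = np.array(
            [
                [0, 5, 9, 9, 8],
                [5, 0, 10, 10, 9],
                [9, 10, 0, 8, 7],
                [9, 10, 8, 0, 3],
                [8, 9, 7, 3, 0],
            ],
            dtype=float,
        ) / 10.0
        labels = list("abcde")
        ours = mp.neighbor_joining(mp.DistanceMatrix(labels, vals))
        ref = skbio.tree.nj(skbio.DistanceMatrix(vals, ids=labels))
        tns = dendropy.TaxonNamespace(labels)
        t1 = dendropy.Tree.get(data=ours.as_string(schema="newick"), schema="newick",
                               taxon_namespace=tns)
        t2 = dendropy.Tree.get(data=str(ref), schema="newick", taxon_namespace=tns)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(t1, t2) == 0

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(InputError):
            mp.neighbor_joining(mp.DistanceMatrix(["a", "b"], np.zeros((2, 2))))


class TestAlignmentIO:
    def test_fasta_and_stockholm_roundtrip(self, tmp_path, rng):
        rows = ["ACGT-ACG", "AC-TTACG", "ACGTTAC-"]
        aln = mp.Alignment(["s1", "s2", "s3"], rows)
        aln.write_fasta(tmp_path / "a.fasta")
        aln.write_stockholm(tmp_path / "a.sto")
        assert mp.Alignment.read_fasta(tmp_path / "a.fasta").rows == rows
        assert mp.Alignment.read_stockholm(tmp_path / "a.sto").rows == rows
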