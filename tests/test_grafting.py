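"""Distances, backbone-preserving grafting and site-rate partitioning."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcodetree import DistanceMatrix, assign_site_rates, graft, pairwise_distance
from barcodetree.grafting import (
    _from_dendropy,
    _insert_min_evolution,
    _to_dendropy,
    write_partition_file,
    write_phylip,
)
from barcodetree.trees import (
    leaf_labels,
    read_tree,
    restrict_tree,
    rf_distance,
    splits_of,
    write_tree,
)

DNA = "ACGT"


class TestPairwiseDistance:
    def test_identical_sequences_are_zero(self):
        assert pairwise_distance("ACGTACGT", "ACGTACGT") == 0.0
        assert pairwise_distance("ACGTACGT", "ACGTACGT", model="K2P") == 0.0

    def test_p_distance_one_mismatch_in_four(self):
        assert pairwise_distance("AAAA", "AAAG") == 0.25

    def test_k2p_saturation_marker(self):
        # P=1, Q=0: log argument of 1-2P-Q is negative
        assert math.isinf(pairwise_distance("AAAA", "GGGG", model="K2P"))

    def test_k2p_closed_form(self):
        # 2 transitions + 1 transversion over 8 sites: P=1/4, Q=1/8
        a, b = "AAGGCCTT", "GAAGCCTA"
        P, Q = 2 / 8, 1 / 8
        expected = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
        assert pairwise_distance(a, b, model="K2P") == pytest.approx(expected)

    def test_pairwise_deletion_excludes_gaps_and_ambiguity(self):
        assert pairwise_distance("A-GN", "AAGA") == 0.0
        assert math.isnan(pairwise_distance("NNNN", "----"))

    def test_unaligned_lengths_rejected(self):
        with pytest.raises(ValueError, match="lengths differ"):
            pairwise_distance("ACGT", "ACG")

    @given(
        st.lists(st.sampled_from(DNA), min_size=8, max_size=40),
        st.integers(min_value=0, max_value=10_000),
    )
    @settings(max_examples=150, deadline=None)
    def test_p_bounded_and_below_k2p(self, bases, seed):
        rng = random.Random(seed)
        a = "".join(bases)
        b = "".join(
            rng.choice(DNA) if rng.random() < 0.3 else ch for ch in a
        )
        p = pairwise_distance(a, b)
        k = pairwise_distance(a, b, model="K2P")
        assert 0.0 <= p <= 1.0
        assert math.isnan(k) or k >= p - 1e-12


def _random_binary_tree(labels, rng, blen=lambda r: r.uniform(0.02, 0.15)):
    nodes = [f"{l}:{blen(rng)}" for l in labels]
    while len(nodes) > 1:
        rng.shuffle(nodes)
        a, b = nodes.pop(), nodes.pop()
        nodes.append(f"({a},{b}):{blen(rng)}")
    return read_tree(nodes[0] + ";")


def _patristic(tree):
    """Leaf-to-leaf path lengths by brute force."""
    labels = leaf_labels(tree)
    paths = {}
    # node->root distances per leaf
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        chain = {}
        while node is not None:
            chain[id(node)] = d
            d += node.edge.length or 0.0
            node = node.parent_node
        paths[leaf.taxon.label] = chain
    n = len(labels)
    D = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            b = labels[j]
            # distance through the deepest shared node
            shared = set(paths[a]) & set(paths[b])
            D[i, j] = D[j, i] = min(
                paths[a][k] + paths[b][k] for k in shared
            )
    return DistanceMatrix(labels, D)


class TestGraft:
    def test_empty_query_set_returns_backbone(self):
        backbone = read_tree("((A:1,B:1):1,(C:1,D:1):1);")
        seqs = {l: "ACGTACGT" for l in "ABCD"}
        out = graft(backbone, seqs)
        assert splits_of(out) == splits_of(backbone)

    def test_identical_query_becomes_sister_of_its_twin(self):
        backbone = read_tree("((A,B),(C,D));")
        seqs = {
            "A": "AAAAAAAAGG",
            "B": "AAAAAAGGGG",
            "C": "TTTTAAGGGG",
            "D": "TTTTTTGGGG",
            "Q": "AAAAAAAAGG",  # == A
        }
        for criterion in ("parsimony", "min_evolution"):
            out = graft(backbone, seqs, criterion)
            q = next(l for l in out.leaf_node_iter() if l.taxon.label == "Q")
            sibs = {l.taxon.label for l in q.parent_node.leaf_iter()}
            assert sibs == {"A", "Q"}

    def test_missing_backbone_sequence_is_an_error(self):
        backbone = read_tree("((A,B),(C,D));")
        with pytest.raises(ValueError, match="backbone"):
            graft(backbone, {"A": "ACGT", "B": "ACGT", "C": "ACGT"})

    def test_ragged_alignment_rejected(self):
        backbone = read_tree("((A,B),(C,D));")
        seqs = {"A": "ACGT", "B": "ACGT", "C": "ACGT", "D": "ACG"}
        with pytest.raises(ValueError, match="aligned"):
            graft(backbone, seqs)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None)
    def test_backbone_always_preserved(self, seed):
        """Central contract: RF(backbone, grafted|backbone-leaves) = 0."""
        rng = random.Random(seed)
        n = rng.randint(5, 10)
        labels = [f"T{i}" for i in range(n)]
        tree = _random_binary_tree(labels, rng)
        rng2 = random.Random(seed + 1)
        seqs = {
            l: "".join(rng2.choice(DNA) for _ in range(60)) for l in labels
        }
        n_q = rng.randint(1, 3)
        for q in range(n_q):
            seqs[f"Q{q}"] = "".join(rng2.choice(DNA) for _ in range(60))
        criterion = rng.choice(["parsimony", "min_evolution"])
        out = graft(tree, seqs, criterion)
        assert set(leaf_labels(out)) == set(seqs)
        back = restrict_tree(out, set(labels))
        assert rf_distance(back, tree) == 0

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None)
    def test_min_evolution_recovers_topology_from_additive_distances(
        self, seed
    ):
        """On exact tree metrics, placement is exact (<=10 leaves)."""
        rng = random.Random(seed)
        n = rng.randint(5, 10)
        labels = [f"T{i}" for i in range(n)]
        tree = _random_binary_tree(labels, rng)
        dm = _patristic(tree)
        removed = sorted(rng.sample(labels, 2))
        keep = set(labels) - set(removed)
        root = _from_dendropy(restrict_tree(tree, keep))
        for q in removed:
            _insert_min_evolution(root, q, dm)
        grafted = _to_dendropy(root)
        for x in removed:
            a = restrict_tree(grafted, keep | {x})
            b = restrict_tree(tree, keep | {x})
            assert rf_distance(a, b) == 0

    def test_determinism(self):
        backbone = read_tree("((A,B),(C,D));")
        rng = random.Random(3)
        seqs = {
            l: "".join(rng.choice(DNA) for _ in range(50))
            for l in ["A", "B", "C", "D", "Q1", "Q2"]
        }
        t1 = write_tree(graft(backbone, seqs))
        t2 = write_tree(graft(backbone, seqs))
        assert t1 == t2


class TestSiteRates:
    def test_all_invariant_single_class(self):
        aln = {l: "AAAA" for l in "ABCD"}
        part = assign_site_rates(aln, read_tree("((A,B),(C,D));"), k=1)
        assert list(part.assignment) == [1, 1, 1, 1]

    def test_fitch_counts_match_brute_force_on_four_leaves(self):
        # per-column minimum changes on ((A,B),(C,D)) enumerated by hand:
        # col0 AAAA->0, col1 AACC->1, col2 ACAC->2, col3 ACGT->3
        aln = {"A": "AAAA", "B": "AACC", "C": "ACAG", "D": "ACCT"}
        # columns: (A,A,A,A)=0; (A,A,C,C)=1; (A,C,A,C)=2; (A,C,G,T)=3
        part = assign_site_rates(aln, read_tree("((A,B),(C,D));"), k=4)
        assert list(part.rate_proxy) == [0, 1, 2, 3]
        assert list(part.assignment) == [1, 2, 3, 4]

    def test_column_permutation_equivariance(self):
        rng = random.Random(5)
        aln = {
            l: "".join(rng.choice(DNA) for _ in range(30))
            for l in ["A", "B", "C", "D", "E"]
        }
        tree = read_tree("((A,B),(C,(D,E)));")
        part = assign_site_rates(aln, tree, k=2)
        perm = list(range(30))
        rng.shuffle(perm)
        aln_p = {l: "".join(s[i] for i in perm) for l, s in aln.items()}
        part_p = assign_site_rates(aln_p, tree, k=2)
        assert [part.assignment[i] for i in perm] == list(part_p.assignment)

    def test_k_out_of_range_rejected(self):
        aln = {l: "AAAA" for l in "ABCD"}
        tree = read_tree("((A,B),(C,D));")
        with pytest.raises(ValueError):
            assign_site_rates(aln, tree, k=0)
        with pytest.raises(ValueError, match="distinct"):
            assign_site_rates(aln, tree, k=2)

    def test_partition_file_ranges(self, tmp_path):
        aln = {"A": "AAAA", "B": "AACC", "C": "ACAG", "D": "ACCT"}
        part = assign_site_rates(aln, read_tree("((A,B),(C,D));"), k=4)
        out = tmp_path / "parts.txt"
        write_partition_file(part, str(out))
        lines = out.read_text().splitlines()
        assert lines == [
            "DNA, rate1 = 1",
            "DNA, rate2 = 2",
            "DNA, rate3 = 3",
            "DNA, rate4 = 4",
        ]

    def test_phylip_writer(self, tmp_path):
        aln = {"Taxon_1": "ACGT", "Taxon_2": "ACGA"}
        out = tmp_path / "aln.phy"
        write_phylip(aln, str(out))
        lines = out.read_text().splitlines()
        assert lines[0] == "2 4"
        assert lines[1] == "Taxon_1  ACGT"
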