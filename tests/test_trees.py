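"""NJ reconstruction, bootstrap supports, monophyly and agreement."""

import numpy as np
import pytest

from allelecap.align import Alignment, DistanceMatrix, p_distance_matrix
from allelecap.formats import SpecimenRecord
from allelecap.trees import (
    agreement_table,
    bootstrap_support,
    divergence_summary,
    monophyly,
    nj_tree,
)
from conftest import random_additive_tree, tree_leaf_distances


class TestNeighborJoining:
    def test_recovers_worked_additive_example(self):
        # tree {A-u:1, B-u:2, u-v:3, C-v:4, D-v:5}
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]], float
        )
        t = nj_tree(DistanceMatrix(labels, d))
        assert t.split_set() == frozenset({frozenset({"C", "D"})})
        lens = sorted(ln for _, _, ln in t.edges())
        assert np.allclose(lens, [1, 2, 3, 4, 5])

    def test_three_taxa_three_point_formulas(self):
        dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float))
        t = nj_tree(dm)
        by_leaf = {t.labels[u]: ln for u, v, ln in t.edges() for u in (u,) if u in t.labels}
        assert by_leaf == {"A": 1.0, "B": 2.0, "C": 4.0}

    def test_recovers_random_additive_trees_exactly(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 13))
            true_tree, (labels, D) = random_additive_tree(rng, n)
            est = nj_tree(DistanceMatrix(labels, D))
            assert est.split_set() == true_tree.split_set()
            # branch lengths: leaf-to-leaf path distances must be reproduced
            _, D2 = tree_leaf_distances(est)
            assert np.allclose(D, D2, atol=1e-9)

    def test_tied_q_minima_resolved_deterministically(self):
        # ultrametric with two equal cherries: (A,B) and (C,D)
        d = np.full((4, 4), 4.0)
        np.fill_diagonal(d, 0.0)
        d[0, 1] = d[1, 0] = 2.0
        d[2, 3] = d[3, 2] = 2.0
        t1 = nj_tree(DistanceMatrix(["A", "B", "C", "D"], d))
        t2 = nj_tree(DistanceMatrix(["A", "B", "C", "D"], d))
        assert t1.to_newick() == t2.to_newick()

    def test_requires_three_labels(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["A", "B"], np.zeros((2, 2))))

    def test_agrees_with_independent_nj_implementation(self, rng):
        # scikit-bio's NJ as an external cross-check on noisy (non-additive)
        # distances: same topology up to its own tie handling on clean data
        skbio = pytest.importorskip("skbio")
        for _ in range(5):
            n = 8
            _, (labels, D) = random_additive_tree(rng, n)
            D = (D + D.T) / 2  # BFS summation order leaves ~1e-16 asymmetry
            est = nj_tree(DistanceMatrix(labels, D))
            ref = skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels))
            ref_splits = set()
            all_leaves = frozenset(labels)
            ref_root = min(labels)
            for node in ref.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                if 2 <= len(side) <= n - 2:
                    norm = side if ref_root not in side else all_leaves - side
                    ref_splits.add(norm)
            assert est.split_set() == frozenset(ref_splits)


class TestBootstrap:
    def _two_clade_alignment(self, pad=380, diff=20):
        block_a = "A" * diff
        block_b = "C" * diff
        tail = "G" * pad
        rows = [
            ("a1", block_a + tail),
            ("a2", block_a + tail),
            ("b1", block_b + tail),
            ("b2", block_b + tail),
        ]
        return Alignment(rows)

    def test_strong_split_gets_full_support(self):
        t = bootstrap_support(self._two_clade_alignment(), n_reps=200, seed=1)
        assert t.supports  # the central edge exists
        assert min(t.supports.values()) >= 99

    def test_single_replicate_supports_are_binary(self):
        t = bootstrap_support(self._two_clade_alignment(), n_reps=1, seed=3)
        assert set(t.supports.values()) <= {0, 100}

    def test_identical_sequences_give_star(self):
        aln = Alignment([(f"s{i}", "ACGTACGT" * 5) for i in range(5)])
        t = bootstrap_support(aln, n_reps=10, seed=0)
        assert t.supports == {}
        assert t.split_set() == frozenset()

    def test_supports_invariant_to_leaf_order(self):
        aln = self._two_clade_alignment()
        perm = Alignment(list(reversed(aln.rows)))
        t1 = bootstrap_support(aln, n_reps=100, seed=5)
        t2 = bootstrap_support(perm, n_reps=100, seed=5)
        s1 = {frozenset(t1._side_leaves(*sorted(e))): v for e, v in t1.supports.items()}
        s2 = {frozenset(t2._side_leaves(*sorted(e))): v for e, v in t2.supports.items()}
        norm1 = {min(k, frozenset(t1.labels.values()) - k, key=sorted): v for k, v in s1.items()}
        norm2 = {min(k, frozenset(t2.labels.values()) - k, key=sorted): v for k, v in s2.items()}
        assert norm1 == norm2


def _quartet(split_ab=True):
    """Unrooted quartet with split {A1,A2}|{B1,B2} or {A1,B1}|{A2,B2}."""
    from allelecap.trees import UnrootedTree

    t = UnrootedTree()
    names = ["A1", "A2", "B1", "B2"] if split_ab else ["A1", "B1", "A2", "B2"]
    for i, nm in enumerate(names):
        t.labels[i] = nm
    t._add_edge(4, 0, 1.0)
    t._add_edge(4, 1, 1.0)
    t._add_edge(5, 2, 1.0)
    t._add_edge(5, 3, 1.0)
    t._add_edge(4, 5, 1.0)
    return t


_SPECIMENS = [
    SpecimenRecord("iA1", "SpA", "G1"),
    SpecimenRecord("iA2", "SpA", "G1"),
    SpecimenRecord("iB1", "SpB", "G1"),
    SpecimenRecord("iB2", "SpB", "G1"),
]
_LEAFMAP = {"A1": "iA1", "A2": "iA2", "B1": "iB1", "B2": "iB2"}


class TestMonophyly:
    def test_clean_split_both_species_monophyletic(self):
        calls, indiv = monophyly(_quartet(True), _SPECIMENS, _LEAFMAP)
        assert all(c.monophyletic for c in calls)
        assert all(indiv.values())

    def test_interleaved_split_neither_monophyletic(self):
        calls, indiv = monophyly(_quartet(False), _SPECIMENS, _LEAFMAP)
        assert not any(c.monophyletic for c in calls)
        assert not any(indiv.values())

    def test_single_sequence_species_monophyletic_by_convention(self):
        specimens = _SPECIMENS + [SpecimenRecord("iC1", "SpC", "G2")]
        from allelecap.trees import UnrootedTree

        t = _quartet(True)
        t.labels[6] = "C1"
        t._add_edge(4, 6, 1.0)
        calls, _ = monophyly(t, specimens, {**_LEAFMAP, "C1": "iC1"})
        by = {c.species: c for c in calls}
        assert by["SpC"].monophyletic and by["SpC"].n_individuals == 1

    def test_unmapped_leaf_rejected(self):
        with pytest.raises(ValueError, match="not mapped"):
            monophyly(_quartet(True), _SPECIMENS, {"A1": "iA1"})


class TestAgreement:
    def test_published_style_counts(self):
        sanger = {f"i{k}": k < 56 for k in range(88)}
        ngs = {f"i{k}": k < 80 for k in range(88)}
        at = agreement_table(sanger, ngs)
        assert (at.a, at.b, at.c, at.d) == (56, 0, 24, 8)
        assert at.overall_percent_agreement == pytest.approx(72.727, abs=1e-3)
        assert at.overall_percent_agreement_rounded == 73

    def test_all_concordant_and_all_discordant(self):
        same = {f"i{k}": k % 2 == 0 for k in range(10)}
        assert agreement_table(same, same).overall_percent_agreement == 100.0
        flipped = {k: not v for k, v in same.items()}
        assert agreement_table(same, flipped).overall_percent_agreement == 0.0

    def test_symmetric_under_method_swap(self, rng):
        s = {f"i{k}": bool(rng.integers(0, 2)) for k in range(30)}
        g = {f"i{k}": bool(rng.integers(0, 2)) for k in range(30)}
        at1 = agreement_table(s, g)
        at2 = agreement_table(g, s)
        assert (at1.a, at1.d) == (at2.a, at2.d)
        assert (at1.b, at1.c) == (at2.c, at2.b)
        assert at1.overall_percent_agreement == at2.overall_percent_agreement

    def test_mismatched_keys_rejected(self):
        with pytest.raises(ValueError):
            agreement_table({"a": True}, {"b": True})


class TestDivergenceSummary:
    def _dm(self):
        labels = ["a1", "a2", "b1", "b2"]
        d = np.array(
            [
                [0.00, 0.01, 0.10, 0.10],
                [0.01, 0.00, 0.10, 0.10],
                [0.10, 0.10, 0.00, 0.01],
                [0.10, 0.10, 0.01, 0.00],
            ]
        )
        return DistanceMatrix(labels, d)

    def _meta(self, same_genus=True):
        g2 = "G1" if same_genus else "G2"
        specimens = [
            SpecimenRecord("ia1", "SpA", "G1"),
            SpecimenRecord("ia2", "SpA", "G1"),
            SpecimenRecord("ib1", "SpB", g2),
            SpecimenRecord("ib2", "SpB", g2),
        ]
        leafmap = {"a1": "ia1", "a2": "ia2", "b1": "ib1", "b2": "ib2"}
        return specimens, leafmap

    def test_clear_gap_detected(self):
        specimens, leafmap = self._meta()
        table, gap = divergence_summary(self._dm(), specimens, leafmap)
        by = dict(zip(table["category"], table["mean"]))
        assert by["conspecific"] == pytest.approx(1.0)
        assert by["congeneric"] == pytest.approx(10.0)
        assert gap is True

    def test_single_species_has_no_congeneric_row(self):
        labels = ["a1", "a2"]
        dm = DistanceMatrix(labels, np.array([[0, 0.02], [0.02, 0]]))
        specimens = [SpecimenRecord("i1", "SpA", "G1"), SpecimenRecord("i2", "SpA", "G1")]
        table, gap = divergence_summary(dm, specimens, {"a1": "i1", "a2": "i2"})
        assert "congeneric" not in set(table["category"])
        assert gap is None

    def test_overlapping_ranges_mean_no_gap(self):
        labels = ["a1", "a2", "b1"]
        d = np.array([[0, 0.24, 0.0], [0.24, 0, 0.2], [0.0, 0.2, 0]])
        dm = DistanceMatrix(labels, d)
        specimens = [
            SpecimenRecord("i1", "SpA", "G1"),
            SpecimenRecord("i2", "SpA", "G1"),
            SpecimenRecord("i3", "SpB", "G1"),
        ]
        _, gap = divergence_summary(dm, specimens, {"a1": "i1", "a2": "i2", "b1": "i3"})
        assert gap is False

    def test_genus_exclusion_removes_labels(self):
        specimens, leafmap = self._meta(same_genus=False)
        table, _ = divergence_summary(
            self._dm(), specimens, leafmap, exclude_genera=["G2"]
        )
        assert set(table["category"]) == {"conspecific"}
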