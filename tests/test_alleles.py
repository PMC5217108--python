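"""Greedy identity clustering, consensus calling and allele ranking."""

import numpy as np
import pytest

from allelecap.align import identity_fraction
from allelecap.alleles import (
    call_alleles,
    call_consensus,
    cluster_reads,
    edlib_identity,
    rank_alleles,
)
from allelecap.formats import QualifiedRead


def _reads(seqs, prefix="r", q=35):
    return [
        QualifiedRead(f"{prefix}{i}", s, (q,) * len(s)) for i, s in enumerate(seqs)
    ]


def _mutate(seq, positions, rng):
    arr = list(seq)
    for p in positions:
        arr[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[p]]
    return "".join(arr)


class TestClusterReads:
    def test_identical_reads_form_one_cluster(self):
        clusters = cluster_reads(_reads(["ACGTACGT" * 10] * 100))
        assert len(clusters) == 1 and len(clusters[0]) == 100

    def test_two_groups_at_90pct_identity_split(self, rng):
        base = "".join(rng.choice(list("ACGT"), 100))
        other = _mutate(base, rng.choice(100, 10, replace=False), rng)  # 90%
        reads = _reads([base] * 60 + [other] * 40)
        clusters = cluster_reads(reads, 0.95)
        assert sorted(len(c) for c in clusters) == [40, 60]
        # seeds are the 60-copy then the 40-copy sequence (abundance order)
        assert len(clusters[0]) == 60

    def test_95pct_boundary_is_inclusive(self, rng):
        base = "".join(rng.choice(list("ACGT"), 100))
        near = _mutate(base, rng.choice(100, 5, replace=False), rng)  # exactly 95%
        clusters = cluster_reads(_reads([base] * 60 + [near] * 40), 0.95)
        assert len(clusters) == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cluster_reads([])

    def test_deterministic_under_read_shuffling(self, rng):
        base = "".join(rng.choice(list("ACGT"), 120))
        far = _mutate(base, rng.choice(120, 15, replace=False), rng)
        reads = _reads([base] * 30 + [far] * 20)
        shuffled = list(reads)
        rng.shuffle(shuffled)
        a1 = call_alleles(reads, specimen_id="x")
        a2 = call_alleles(shuffled, specimen_id="x")
        assert [(a.sequence, a.read_count, a.rank) for a in a1.alleles] == [
            (a.sequence, a.read_count, a.rank) for a in a2.alleles
        ]

    def test_lowering_threshold_never_increases_clusters(self, rng):
        base = "".join(rng.choice(list("ACGT"), 150))
        seqs = [base]
        for _ in range(6):
            k = int(rng.integers(3, 25))
            seqs.append(_mutate(base, rng.choice(150, k, replace=False), rng))
        reads = _reads([s for s in seqs for _ in range(int(rng.integers(2, 8)))])
        counts = [
            len(cluster_reads(reads, th)) for th in (0.98, 0.95, 0.92, 0.88, 0.80)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_edlib_identity_agrees_with_affine_aligner(self, rng):
        # the fast clustering route and the package's own affine aligner
        # define the same identity; unit-cost tie paths may trade two
        # substitutions for an indel pair, moving identity by ~1 column
        for _ in range(25):
            base = "".join(rng.choice(list("ACGT"), 80))
            k = int(rng.integers(0, 12))
            other = _mutate(base, rng.choice(80, k, replace=False), rng)
            assert edlib_identity(base, other) == pytest.approx(
                identity_fraction(base, other), abs=0.015
            )

    def test_truncated_read_clusters_with_full_length_seed(self, rng):
        base = "".join(rng.choice(list("ACGT"), 200))
        truncated = base[25:]  # 5'-degraded fragment
        clusters = cluster_reads(_reads([base] * 10 + [truncated] * 3))
        assert len(clusters) == 1


class TestCallConsensus:
    def test_identical_reads(self):
        seq = "ACGTACGTAC"
        assert call_consensus(_reads([seq] * 5)) == seq

    def test_lone_error_outvoted(self, rng):
        base = "".join(rng.choice(list("ACGT"), 50))
        bad = _mutate(base, [20], rng)
        reads = _reads([base] * 9 + [bad], q=30)
        reads[-1] = QualifiedRead("bad", bad, (10,) * len(bad))
        assert call_consensus(reads) == base

    def test_minority_insertion_dropped(self):
        base = "ACGTACGTACGTACGT"
        with_ins = base[:8] + "G" + base[8:]
        reads = _reads([base, base, with_ins])
        assert call_consensus(reads) == base

    def test_majority_deletion_wins(self):
        base = "ACGTAACGTACGTACC"
        deleted = base[:8] + base[9:]
        reads = _reads([deleted, deleted, deleted, base])
        assert call_consensus(reads) == deleted


class TestRankAlleles:
    def test_counts_ranks_and_gap(self):
        clusters = [[f"r{i}" for i in range(60)], [f"s{i}" for i in range(30)],
                    [f"t{i}" for i in range(10)]]
        aset = rank_alleles(clusters, ["AAAA", "CCCC", "GGGG"], 100)
        assert [a.rank for a in aset.alleles] == [1, 2, 3]
        assert [a.read_count for a in aset.alleles] == [60, 30, 10]
        assert aset.top_two_gap_pct == pytest.approx(30.0)

    def test_single_cluster_has_no_gap(self):
        aset = rank_alleles([["r1", "r2"]], ["ACGT"], 2)
        assert aset.top_two_gap_pct is None

    def test_tie_broken_longer_then_lexicographic(self):
        clusters = [["a1", "a2"], ["b1", "b2"]]
        aset = rank_alleles(clusters, ["CCC", "AAAA"], 4)
        assert aset.alleles[0].sequence == "AAAA"  # longer wins the tie
        assert aset.top_two_gap_pct == 0.0

    def test_min_reads_drops_singletons(self):
        aset = rank_alleles([["a", "b"], ["c"]], ["AAAA", "CCCC"], 3, min_reads=2)
        assert len(aset.alleles) == 1


class TestEndToEndRecovery:
    def test_divergent_alleles_recovered_exactly(self, rng):
        # two alleles at ~8% divergence, 60x/40x depth, modest quality
        base = "".join(rng.choice(list("ACGT"), 300))
        allele2 = _mutate(base, rng.choice(300, 24, replace=False), rng)
        reads = []
        for i in range(60):
            reads.append(QualifiedRead(f"a{i}", base, (38,) * 300))
        for i in range(40):
            reads.append(QualifiedRead(f"b{i}", allele2, (38,) * 300))
        aset = call_alleles(reads, specimen_id="sp")
        assert len(aset.alleles) == 2
        assert aset.alleles[0].sequence == base
        assert aset.alleles[1].sequence == allele2
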