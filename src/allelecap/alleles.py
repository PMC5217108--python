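"""Allele calling: greedy 95%-identity clustering, consensus, ranking.

Merged amplicon reads are already full-length, so contig assembly reduces
to clustering: reads are dereplicated, unique sequences are sorted by
multiplicity (ties: longer first, then lexicographic) and seed clusters
greedily — a sequence joins the first seed it matches at or above the
identity threshold, else founds a new cluster. Identity is computed over a
global alignment with terminal gaps excluded (so 5'-degraded, shorter
merged reads still cluster with their full-length allele) and internal
gaps counted as mismatches. The ≥ threshold is inclusive: a pair at
exactly 95.0% identity co-clusters, i.e. variants within 5% collapse into
one allele.

The allele with the most supporting reads is rank 1 — "the most common
allele" — and the gap between the top two read counts (as a percentage of
all reads used) is reported, since a small gap is what lets a Sanger trace
match the second most common allele instead.

High-volume pairwise alignment goes through edlib (unit-cost global
alignment in C); the affine aligner in :mod:`allelecap.align` defines the
same identity and is cross-checked against this route in the test suite.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import edlib

from .formats import QualifiedRead


@dataclass(frozen=True)
class Allele:
    allele_id: str
    sequence: str
    read_count: int
    rank: int


@dataclass(frozen=True)
class AlleleSet:
    specimen_id: str
    alleles: tuple[Allele, ...]
    total_reads_used: int
    top_two_gap_pct: Optional[float]  # absent (None) when a single allele

    def __post_init__(self) -> None:
        counts = [a.read_count for a in self.alleles]
        if any(c2 > c1 for c1, c2 in zip(counts, counts[1:])):
            raise ValueError("allele read counts must be non-increasing in rank")
        if list(a.rank for a in self.alleles) != list(range(1, len(counts) + 1)):
            raise ValueError("allele ranks must be 1..k")

    @property
    def most_common(self) -> Optional[Allele]:
        return self.alleles[0] if self.alleles else None


def _parse_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def edlib_identity(a: str, b: str) -> float:
    """Alignment identity fraction with terminal gaps excluded.

    Matches / aligned columns, where leading and trailing gap runs are not
    counted and internal gaps count as mismatched columns. The shorter
    sequence is aligned within the longer with free end gaps, so a
    5'-degraded (truncated) copy of a sequence scores 100%.
    """
    query, target = (a, b) if len(a) <= len(b) else (b, a)
    res = edlib.align(query, target, mode="HW", task="path")
    ops = list(_parse_cigar(res["cigar"]))
    # strip terminal gap runs (I or D at either end)
    while ops and ops[0][1] in "ID":
        ops = ops[1:]
    while ops and ops[-1][1] in "ID":
        ops = ops[:-1]
    cols = sum(n for n, _ in ops)
    if cols == 0:
        return 0.0
    matches = sum(n for n, op in ops if op == "=")
    return matches / cols


def _seed_order_key(item: tuple[str, int]) -> tuple[int, int, str]:
    seq, count = item
    return (-count, -len(seq), seq)


def cluster_reads(
    merged: Sequence[QualifiedRead],
    identity_threshold: float = 0.95,
    identity_fn: Callable[[str, str], float] = edlib_identity,
) -> list[list[str]]:
    """Greedy abundance-ordered clustering of merged reads.

    Returns clusters as lists of read ids, in seed order. Deterministic:
    unique sequences are processed by (multiplicity desc, length desc,
    lexicographic) and each joins the first seed at identity ≥ threshold.
    """
    if not merged:
        raise ValueError("cluster_reads requires non-empty input")
    if not (0.0 < identity_threshold <= 1.0):
        raise ValueError("identity_threshold must be in (0, 1]")
    counts: Counter[str] = Counter(r.sequence for r in merged)
    ids_by_seq: dict[str, list[str]] = {}
    for r in merged:
        ids_by_seq.setdefault(r.sequence, []).append(r.read_id)
    seeds: list[str] = []
    clusters: list[list[str]] = []
    for seq, _ in sorted(counts.items(), key=_seed_order_key):
        for k, seed in enumerate(seeds):
            if identity_fn(seq, seed) >= identity_threshold - 1e-9:
                clusters[k].extend(ids_by_seq[seq])
                break
        else:
            seeds.append(seq)
            clusters.append(list(ids_by_seq[seq]))
    return clusters


def cluster_seed_sequence(cluster: Sequence[QualifiedRead]) -> str:
    """The seed of a cluster: its most frequent sequence (ties: longer, then
    lexicographically smaller)."""
    counts = Counter(r.sequence for r in cluster)
    return min(counts.items(), key=_seed_order_key)[0]


def call_consensus(cluster: Sequence[QualifiedRead]) -> str:
    """Plurality-vote consensus of a cluster.

    Every read is globally aligned to the cluster seed; per column the
    plurality base wins, ties broken by summed quality then alphabetically;
    columns where gaps hold a strict majority are deleted (so a lone
    1 bp insertion never enters the consensus).
    """
    if not cluster:
        raise ValueError("call_consensus requires a non-empty cluster")
    seed = cluster_seed_sequence(cluster)
    n_reads = len(cluster)
    # column keys: (seed_pos, 0) for seed columns, (seed_pos, k>0) for the
    # k-th inserted column *before* seed_pos
    base_count: dict[tuple[int, int], Counter] = {}
    qual_sum: dict[tuple[int, int], Counter] = {}
    occupancy: Counter = Counter()  # how many reads have a base in the column

    for read in cluster:
        res = edlib.align(read.sequence, seed, mode="NW", task="path")
        qpos = 0
        tpos = 0
        ins_k = 0
        for n, op in _parse_cigar(res["cigar"]):
            if op in "=X":
                for _ in range(n):
                    key = (tpos, 0)
                    c = read.sequence[qpos]
                    q = read.qualities[qpos] if read.qualities else 0
                    base_count.setdefault(key, Counter())[c] += 1
                    qual_sum.setdefault(key, Counter())[c] += q
                    occupancy[key] += 1
                    qpos += 1
                    tpos += 1
                ins_k = 0
            elif op == "I":  # read has extra bases before seed position tpos
                for _ in range(n):
                    ins_k += 1
                    key = (tpos, ins_k)
                    c = read.sequence[qpos]
                    q = read.qualities[qpos] if read.qualities else 0
                    base_count.setdefault(key, Counter())[c] += 1
                    qual_sum.setdefault(key, Counter())[c] += q
                    occupancy[key] += 1
                    qpos += 1
            elif op == "D":  # read lacks these seed positions
                tpos += n
                ins_k = 0

    out = []
    for key in sorted(base_count, key=lambda k: (k[0], 0 if k[1] == 0 else 1, k[1])):
        occupied = occupancy[key]
        gaps = n_reads - occupied
        if gaps > occupied:  # gap-majority column: delete
            continue
        bc = base_count[key]
        top = max(bc.values())
        tied = sorted(b for b, c in bc.items() if c == top)
        if len(tied) > 1:
            qs = qual_sum[key]
            best_q = max(qs[b] for b in tied)
            tied = sorted(b for b in tied if qs[b] == best_q)
        out.append(tied[0])
    return "".join(out)


def rank_alleles(
    clusters: Sequence[Sequence[str]],
    consensuses: Sequence[str],
    total_reads_used: int,
    min_reads: int = 2,
    specimen_id: str = "",
) -> AlleleSet:
    """Rank consensus alleles by supporting-read count.

    Clusters with fewer than ``min_reads`` reads are dropped before
    ranking (suppressing sequencing-error singletons by default). Ties in
    read count are broken by longer then lexicographically smaller
    consensus. Reports the top-two gap, 100·(count1 − count2)/total reads,
    absent for a single allele.
    """
    if len(clusters) != len(consensuses):
        raise ValueError("clusters and consensuses must align 1:1")
    kept = [
        (len(c), cons) for c, cons in zip(clusters, consensuses) if len(c) >= min_reads
    ]
    kept.sort(key=lambda t: (-t[0], -len(t[1]), t[1]))
    prefix = f"{specimen_id}|" if specimen_id else ""
    alleles = tuple(
        Allele(f"{prefix}allele{r}", cons, count, r)
        for r, (count, cons) in enumerate(kept, start=1)
    )
    gap = None
    if len(alleles) >= 2 and total_reads_used > 0:
        gap = 100.0 * (alleles[0].read_count - alleles[1].read_count) / total_reads_used
    return AlleleSet(specimen_id, alleles, total_reads_used, gap)


def call_alleles(
    merged: Sequence[QualifiedRead],
    identity_threshold: float = 0.95,
    min_reads: int = 2,
    specimen_id: str = "",
) -> AlleleSet:
    """Cluster merged reads, call consensi, and rank — the full CAP3-stage
    functional replacement for one specimen."""
    clusters = cluster_reads(merged, identity_threshold)
    by_id = {r.read_id: r for r in merged}
    consensuses = [call_consensus([by_id[i] for i in c]) for c in clusters]
    return rank_alleles(clusters, consensuses, len(merged), min_reads, specimen_id)
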