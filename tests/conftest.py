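"""Shared fixtures and independent oracles used across the test suite.

The oracles here are deliberately naive (exhaustive enumeration, O(n²)
scans) and independent of the library's algorithms; they exist to pin the
optimized implementations down on small random inputs.
"""

from __future__ import annotations

import numpy as np
import pytest

from allelecap.align import Scoring
from allelecap.dna import bases_match
from allelecap.trees import UnrootedTree


# ---------------------------------------------------------------------------
# oracles


def mott_oracle(qualities, error_limit):
    """All-segments best-sum search; ties leftmost start, then longest."""
    scores = [error_limit - 10.0 ** (-q / 10.0) for q in qualities]
    prefix = [0.0]
    for s in scores:
        prefix.append(prefix[-1] + s)
    best = (0.0, 0, 0)  # (sum, start, end)
    for s in range(len(scores)):
        for e in range(s + 1, len(scores) + 1):
            total = prefix[e] - prefix[s]
            cur_sum, cur_s, cur_e = best
            if total > cur_sum + 1e-12:
                best = (total, s, e)
            elif abs(total - cur_sum) <= 1e-12 and total > 1e-12:
                if s < cur_s or (s == cur_s and e > cur_e):
                    best = (total, s, e)
    return best[1], best[2]


def align_score_oracle(a: str, b: str, sc: Scoring) -> int:
    """Exhaustive enumeration of global alignments (affine gap runs).

    A gap of length L costs gap_open + L*gap_extend; feasible only for
    short strings.
    """
    best = -(10**9)

    def rec(i: int, j: int, last: str, score: int) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            s = sc.match if bases_match(a[i], b[j]) else sc.mismatch
            rec(i + 1, j + 1, "M", score + s)
        if i < len(a):  # gap in b, consumes a
            cost = sc.gap_extend + (0 if last == "V" else sc.gap_open)
            rec(i + 1, j, "V", score + cost)
        if j < len(b):  # gap in a, consumes b
            cost = sc.gap_extend + (0 if last == "H" else sc.gap_open)
            rec(i, j + 1, "H", score + cost)

    rec(0, 0, "M", 0)
    return best


def _is_primitive(m: str) -> bool:
    return all(
        not (len(m) % d == 0 and m == m[:d] * (len(m) // d)) for d in range(1, len(m))
    )


def microsat_oracle(seq: str, max_unit: int, min_repeats: int):
    """Brute-force tandem scan: every (start, unit), extended maximally."""
    n = len(seq)
    found = set()
    for start in range(n):
        for u in range(1, max_unit + 1):
            if start + 2 * u > n:
                continue
            motif = seq[start : start + u]
            if not _is_primitive(motif):
                continue
            # left-maximality of the run
            if start >= 1 and start - 1 + u < n and seq[start - 1] == seq[start - 1 + u]:
                continue
            end = start + u
            while end < n and seq[end] == seq[end - u]:
                end += 1
            if (end - start) // u >= min_repeats:
                found.add((start, end, motif))
    kept = []
    for s, e, m in found:
        if not any(
            len(m2) < len(m) and s2 <= s and e <= e2 for s2, e2, m2 in found
        ):
            kept.append((s, e, m))
    return sorted(kept, key=lambda t: (t[0], len(t[2])))


# ---------------------------------------------------------------------------
# random unrooted trees with additive distances


def random_additive_tree(rng: np.random.Generator, n_leaves: int):
    """A random binary unrooted tree with positive branch lengths, plus its
    leaf-to-leaf path-distance matrix (labels sorted)."""
    assert n_leaves >= 3
    tree = UnrootedTree()
    labels = [f"L{i:02d}" for i in range(n_leaves)]
    center = n_leaves  # internal node ids start after leaves
    for i in range(3):
        tree.labels[i] = labels[i]
        tree._add_edge(center, i, float(rng.uniform(0.3, 2.0)))
    next_internal = center + 1
    for i in range(3, n_leaves):
        u, v, ln = tree.edges()[rng.integers(0, len(tree.edges()))]
        mid = next_internal
        next_internal += 1
        frac = float(rng.uniform(0.25, 0.75))
        del tree.adj[u][v]
        del tree.adj[v][u]
        tree._add_edge(u, mid, ln * frac)
        tree._add_edge(mid, v, ln * (1 - frac))
        tree.labels[i] = labels[i]
        tree._add_edge(mid, i, float(rng.uniform(0.3, 2.0)))
    return tree, tree_leaf_distances(tree)


def tree_leaf_distances(tree: UnrootedTree):
    """(labels, matrix) of leaf-to-leaf path lengths via BFS."""
    leaves = sorted(tree.labels, key=lambda n: tree.labels[n])
    labels = [tree.labels[n] for n in leaves]
    n = len(leaves)
    D = np.zeros((n, n))
    for i, src in enumerate(leaves):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, ln in tree.adj[x].items():
                if y not in dist:
                    dist[y] = dist[x] + ln
                    stack.append(y)
        for j, dst in enumerate(leaves):
            D[i, j] = dist[dst]
    return labels, D


@pytest.fixture
def rng():
    return np.random.default_rng(20160915)
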