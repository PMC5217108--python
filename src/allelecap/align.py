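"""Pairwise and progressive multiple alignment, identity and p-distances.

The aligner is a three-state (substitution / gap-in-A / gap-in-B) affine-gap
global dynamic program. A gap of length L costs ``gap_open + L*gap_extend``.
Default scores (+1 match, -1 mismatch, -4 open, -1 extend) make a 1 bp indel
more costly than several substitutions, which suits a marker whose length
variation is dominated by discrete indels and repeat-count changes rather
than scattered single-column gaps.

IUPAC ambiguity codes match a symbol whenever their base sets intersect:
an R in a Sanger heterozygote call is *consistent* with A or G, and must
not be charged as a difference.

p-distance = differing sites / comparable sites, with pairwise deletion of
gap sites by default (length-variable alleles leave few columns shared by
every row, so complete deletion would discard most of the signal).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .dna import IUPAC_SETS, validate_sequence

GAP = "-"

# Bitmask encoding: A=1 C=2 G=4 T=8; an IUPAC code is the OR of its set;
# the gap character is 0 so "comparable" is simply mask != 0.
_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_MASK = {sym: sum(_BASE_BIT[b] for b in bases) for sym, bases in IUPAC_SETS.items()}
_MASK[GAP] = 0

_SYMBOLS = sorted(_MASK)  # deterministic symbol order
_SYM_INDEX = {s: i for i, s in enumerate(_SYMBOLS)}
_MASK_BY_INDEX = np.array([_MASK[s] for s in _SYMBOLS], dtype=np.int16)

_NEG = np.int64(-(10**12))


def encode(seq: str) -> np.ndarray:
    """Encode a (possibly gapped) IUPAC string as symbol indices."""
    try:
        return np.fromiter((_SYM_INDEX[c] for c in seq), dtype=np.int16, count=len(seq))
    except KeyError as exc:  # pragma: no cover - guarded upstream
        raise ValueError(f"unknown symbol {exc}") from exc


def masks(seq: str) -> np.ndarray:
    return _MASK_BY_INDEX[encode(seq)]


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -1
    gap_open: int = -4
    gap_extend: int = -1


DEFAULT_SCORING = Scoring()


@dataclass
class Alignment:
    """Rows of equal-length gapped sequences over IUPAC ∪ {-}."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.rows:
            L = len(self.rows[0][1])
            for rid, seq in self.rows:
                if len(seq) != L:
                    raise ValueError(f"row {rid!r} has length {len(seq)} != {L}")

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i][1].replace(GAP, "")

    def matrix(self) -> np.ndarray:
        """Rows as a bitmask matrix (gap = 0)."""
        return np.vstack([masks(seq) for _, seq in self.rows])

    def drop_allgap_columns(self) -> "Alignment":
        m = self.matrix()
        keep = (m != 0).any(axis=0)
        return Alignment(
            [(rid, "".join(c for c, k in zip(seq, keep) if k)) for rid, seq in self.rows]
        )


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal not zero")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.d[i, j])


def _substitution_matrix(scoring: Scoring) -> np.ndarray:
    """Symbol-index × symbol-index match/mismatch scores (IUPAC-aware)."""
    n = len(_SYMBOLS)
    W = np.full((n, n), scoring.mismatch, dtype=np.int64)
    for i, a in enumerate(_SYMBOLS):
        for j, b in enumerate(_SYMBOLS):
            if a != GAP and b != GAP and _MASK[a] & _MASK[b]:
                W[i, j] = scoring.match
    return W


def _affine_dp(S: np.ndarray, gap_open: float, gap_extend: float):
    """Fill the three DP state matrices over a precomputed score matrix S.

    Returns (T, V, H): T = last column a substitution, V = gap in B
    (consumes A, vertical), H = gap in A (consumes B, horizontal).
    The horizontal state is computed with a prefix-max scan so each row is
    fully vectorized.
    """
    n, m = S.shape
    dt = S.dtype
    neg = dt.type(_NEG)
    T = np.full((n + 1, m + 1), neg, dtype=dt)
    V = np.full((n + 1, m + 1), neg, dtype=dt)
    H = np.full((n + 1, m + 1), neg, dtype=dt)
    T[0, 0] = 0
    j = np.arange(1, m + 1, dtype=dt)
    H[0, 1:] = gap_open + j * gap_extend
    i = np.arange(1, n + 1, dtype=dt)
    V[1:, 0] = gap_open + i * gap_extend

    for r in range(1, n + 1):
        prev_best = np.maximum(np.maximum(T[r - 1], V[r - 1]), H[r - 1])
        T[r, 1:] = prev_best[:-1] + S[r - 1]
        V[r, 1:] = np.maximum(V[r - 1, 1:] + gap_extend, prev_best[1:] + gap_open + gap_extend)
        # H[r, j] = max_{k<j} max(T[r,k], V[r,k]) + gap_open + (j-k)*gap_extend
        t = np.maximum(T[r], V[r])
        jj = np.arange(m + 1, dtype=dt)
        u = t - jj * gap_extend + gap_open
        run = np.maximum.accumulate(u)[:-1]
        H[r, 1:] = np.maximum(H[r, 1:], run + jj[1:] * gap_extend)
    return T, V, H


def _traceback(T, V, H, gap_extend, gap_open):
    """Deterministic traceback: substitution > gap-in-A (H) > gap-in-B (V)."""
    i, j = T.shape[0] - 1, T.shape[1] - 1
    scores = (T[i, j], H[i, j], V[i, j])
    state = ("T", "H", "V")[int(np.argmax(scores))]
    cols: list[tuple[int, int]] = []  # (ai, bj) with -1 for gap
    while i > 0 or j > 0:
        if state == "T":
            cols.append((i - 1, j - 1))
            prev = (T[i - 1, j - 1], H[i - 1, j - 1], V[i - 1, j - 1])
            state = ("T", "H", "V")[int(np.argmax(prev))]
            i, j = i - 1, j - 1
        elif state == "H":
            cols.append((-1, j - 1))
            stay = H[i, j - 1] + gap_extend
            if H[i, j] == stay and j > 1:
                state = "H"
            else:
                prev = (T[i, j - 1], V[i, j - 1])
                state = ("T", "V")[int(np.argmax(prev))]
            j -= 1
        else:
            cols.append((i - 1, -1))
            stay = V[i - 1, j] + gap_extend
            if V[i, j] == stay and i > 1:
                state = "V"
            else:
                prev = (T[i - 1, j], H[i - 1, j])
                state = ("T", "H")[int(np.argmax(prev))]
            i -= 1
    cols.reverse()
    return cols


def global_align(
    a: str,
    b: str,
    scoring: Scoring = DEFAULT_SCORING,
    ids: tuple[str, str] = ("a", "b"),
) -> tuple[Alignment, int]:
    """Optimal affine-gap global alignment of two DNA strings.

    Returns a two-row :class:`Alignment` and the optimal score. Raises on
    empty input.
    """
    if not a or not b:
        raise ValueError("global_align requires non-empty sequences")
    a = validate_sequence(a, "a")
    b = validate_sequence(b, "b")
    W = _substitution_matrix(scoring)
    S = W[np.ix_(encode(a), encode(b))]
    T, V, H = _affine_dp(S, scoring.gap_open, scoring.gap_extend)
    score = int(max(T[-1, -1], V[-1, -1], H[-1, -1]))
    cols = _traceback(T, V, H, scoring.gap_extend, scoring.gap_open)
    row_a = "".join(a[ai] if ai >= 0 else GAP for ai, _ in cols)
    row_b = "".join(b[bj] if bj >= 0 else GAP for _, bj in cols)
    return Alignment([(ids[0], row_a), (ids[1], row_b)]), score


def _terminal_gap_mask(row_masks: np.ndarray) -> np.ndarray:
    """Boolean mask of columns that are terminal gaps of this row."""
    nz = np.nonzero(row_masks)[0]
    term = np.ones(len(row_masks), dtype=bool)
    if len(nz):
        term[nz[0] : nz[-1] + 1] = False
    return term


def percent_identity(
    alignment: Alignment,
    terminal_gaps: Literal["exclude", "include"] = "exclude",
) -> float:
    """Percent identity of a two-row alignment.

    Columns where both symbols' IUPAC sets intersect are matches; columns
    with a gap count as mismatches, except terminal-gap columns which are
    dropped entirely in "exclude" mode. Returns 100*matches/columns.
    """
    if len(alignment.rows) != 2:
        raise ValueError("percent_identity requires exactly 2 rows")
    m = alignment.matrix()
    counted = np.ones(m.shape[1], dtype=bool)
    if terminal_gaps == "exclude":
        counted &= ~_terminal_gap_mask(m[0])
        counted &= ~_terminal_gap_mask(m[1])
    total = int(counted.sum())
    if total == 0:
        return 0.0
    match = (m[0] & m[1]) != 0  # gap has mask 0 -> never a match
    return 100.0 * int((match & counted).sum()) / total


def identity_fraction(a: str, b: str, scoring: Scoring = DEFAULT_SCORING) -> float:
    """Global-alignment identity (terminal gaps excluded), as a fraction."""
    aln, _ = global_align(a, b, scoring)
    return percent_identity(aln) / 100.0


# ---------------------------------------------------------------------------
# progressive multiple alignment


def _kmer_profile(seq: str, k: int = 6) -> dict[str, int]:
    prof: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        prof[w] = prof.get(w, 0) + 1
    return prof


def _kmer_distance(pa: dict[str, int], pb: dict[str, int], na: int, nb: int) -> float:
    common = sum(min(c, pb.get(w, 0)) for w, c in pa.items())
    denom = max(1, min(na, nb))
    return 1.0 - common / denom


def _guide_order(leaf_d: dict[tuple[int, int], float], n: int) -> list[tuple[int, int]]:
    """UPGMA merge order on leaf distances; ties broken by smallest index pair.

    Returns merge pairs of cluster ids; leaves are 0..n-1 and each merge
    creates cluster n, n+1, ...
    """
    D = dict(leaf_d)
    active: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges: list[tuple[int, int]] = []
    next_id = n
    while len(active) > 1:
        i, j = min(D, key=lambda p: (D[p], p))
        merges.append((i, j))
        for p in list(D):
            if i in p or j in p:
                del D[p]
        members = active.pop(i) + active.pop(j)
        for kc, mem in active.items():
            s = sum(
                leaf_d[(min(x, y), max(x, y))] for x in members for y in mem
            )
            D[(min(kc, next_id), max(kc, next_id))] = s / (len(members) * len(mem))
        active[next_id] = members
        next_id += 1
    return merges


def _profile(rows: list[str], scoring: Scoring) -> np.ndarray:
    """Column × symbol-index frequency matrix for a block of gapped rows."""
    n = len(_SYMBOLS)
    L = len(rows[0])
    P = np.zeros((L, n), dtype=np.float64)
    for row in rows:
        enc = encode(row)
        P[np.arange(L), enc] += 1.0
    return P / len(rows)


def _align_profiles(rows_a: list[str], rows_b: list[str], scoring: Scoring) -> tuple[list[str], list[str]]:
    W = _substitution_matrix(scoring).astype(np.float64)
    gi = _SYM_INDEX[GAP]
    # base vs gap scores as extension-level penalty; gap vs gap is neutral
    W[gi, :] = scoring.gap_extend
    W[:, gi] = scoring.gap_extend
    W[gi, gi] = 0.0
    Pa = _profile(rows_a, scoring)
    Pb = _profile(rows_b, scoring)
    S = Pa @ W @ Pb.T
    T, V, H = _affine_dp(S, float(scoring.gap_open), float(scoring.gap_extend))
    cols = _traceback(T, V, H, float(scoring.gap_extend), float(scoring.gap_open))
    out_a = ["".join(r[ai] if ai >= 0 else GAP for ai, _ in cols) for r in rows_a]
    out_b = ["".join(r[bj] if bj >= 0 else GAP for _, bj in cols) for r in rows_b]
    return out_a, out_b


def progressive_msa(
    seqs: Sequence[tuple[str, str]],
    scoring: Scoring = DEFAULT_SCORING,
) -> Alignment:
    """Progressive multiple alignment (k-mer guide tree, profile-profile DP).

    Output row order equals input order; ungapping any row reproduces its
    input sequence exactly. A single sequence is returned trivially aligned.
    """
    if not seqs:
        raise ValueError("progressive_msa requires at least one sequence")
    ids = [rid for rid, _ in seqs]
    raw = [validate_sequence(s, rid) for rid, s in seqs]
    if len(raw) == 1:
        return Alignment([(ids[0], raw[0])])

    profs = [_kmer_profile(s) for s in raw]
    sizes = [max(1, len(s) - 5) for s in raw]
    leaf_d = {
        (i, j): _kmer_distance(profs[i], profs[j], sizes[i], sizes[j])
        for i in range(len(raw))
        for j in range(i + 1, len(raw))
    }
    merges = _guide_order(leaf_d, len(raw))

    blocks: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [raw[i]]) for i in range(len(raw))
    }
    next_id = len(raw)
    for i, j in merges:
        idx_a, rows_a = blocks.pop(i)
        idx_b, rows_b = blocks.pop(j)
        out_a, out_b = _align_profiles(rows_a, rows_b, scoring)
        blocks[next_id] = (idx_a + idx_b, out_a + out_b)
        next_id += 1
    (indices, rows), = blocks.values()
    order = np.argsort(indices)
    aln = Alignment([(ids[indices[k]], rows[k]) for k in order])
    return aln.drop_allgap_columns()


# ---------------------------------------------------------------------------
# p-distances


def p_distance(
    row_i: np.ndarray,
    row_j: np.ndarray,
) -> tuple[float, int]:
    """(distance, comparable sites) for two bitmask-encoded rows."""
    both = (row_i != 0) & (row_j != 0)
    comparable = int(both.sum())
    if comparable == 0:
        return float("nan"), 0
    diffs = int(((row_i & row_j) == 0)[both].sum())
    return diffs / comparable, comparable


def p_distance_matrix(
    alignment: Alignment,
    gap_policy: Literal["pairwise_deletion", "complete_deletion"] = "pairwise_deletion",
) -> DistanceMatrix:
    """Pairwise p-distances over an alignment.

    Sites where either row (pairwise deletion) or any row (complete
    deletion) has a gap are skipped; symbols whose IUPAC sets intersect
    (N against anything, R against A, ...) count as matches.
    """
    if len(alignment.rows) < 2:
        raise ValueError("p_distance_matrix requires at least 2 rows")
    M = alignment.matrix()
    if gap_policy == "complete_deletion":
        M = M[:, (M != 0).all(axis=0)]
    n = M.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dij, comparable = p_distance(M[i], M[j])
            if comparable == 0:
                raise ValueError(
                    f"no comparable sites between {alignment.ids[i]!r} and {alignment.ids[j]!r}"
                )
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(alignment.ids, d)


def read_distance_tsv(path) -> DistanceMatrix:
    """Read a square labelled TSV (or PHYLIP-square) distance matrix."""
    with open(path) as fh:
        first = fh.readline().split()
        rest = [ln.split() for ln in fh if ln.strip()]
    if len(first) == 1 and first[0].isdigit():  # PHYLIP square
        labels = [r[0] for r in rest]
        d = np.array([[float(x) for x in r[1:]] for r in rest])
    else:
        labels = first[1:] if first[0] in ("", "label", "id") else first
        labels = list(labels)
        d = np.array([[float(x) for x in r[1:]] for r in rest])
    return DistanceMatrix(labels, d)


def write_distance_tsv(dm: DistanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(dm.labels) + "\n")
        for lab, row in zip(dm.labels, dm.d):
            fh.write(lab + "\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")
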