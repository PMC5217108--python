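"""Merging of overlapping paired-end reads into full amplicon sequences.

The reverse read is reverse-complemented and every end-overlap of at least
``min_overlap`` bases against the forward read is scored as matches minus
mismatches (N counts as neither). The best-scoring overlap wins; the pair
merges only if its mismatch rate is at or below ``max_mismatch_rate`` and
the best score is strictly better than the runner-up (otherwise the pair
is ambiguous). In the overlap, the consensus takes the higher-quality base;
the consensus quality is max(Q) where the mates agree and |Qf − Qr| where
they disagree.

Amplicons longer than twice the read length cannot produce a genuine
overlap — such pairs fail with ``no_overlap``, which is exactly why a
>500 bp target cannot be assembled from 2×250 bp reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from .dna import revcomp
from .formats import QualifiedRead

Status = Literal["merged", "no_overlap", "ambiguous"]


@dataclass(frozen=True)
class MergeResult:
    merged: Optional[QualifiedRead]
    overlap_len: int
    mismatches_in_overlap: int
    status: Status


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def merge_pair(
    fwd: QualifiedRead,
    rev: QualifiedRead,
    min_overlap: int = 10,
    max_mismatch_rate: float = 0.1,
) -> MergeResult:
    """Merge one read pair; the reverse read is as-sequenced."""
    if len(fwd) == 0 or len(rev) == 0:
        raise ValueError("merge_pair requires non-empty reads")
    if fwd.qualities is None or rev.qualities is None:
        raise ValueError("merge_pair requires qualities on both mates")

    rc_seq = revcomp(rev.sequence)
    rc_qual = tuple(reversed(rev.qualities))
    f = _encode(fwd.sequence)
    r = _encode(rc_seq)
    n_code = ord("N")
    max_l = min(len(f), len(r))

    candidates: list[tuple[int, int, int]] = []  # (score, L, mismatches)
    for L in range(min_overlap, max_l + 1):
        a = f[len(f) - L :]
        b = r[:L]
        informative = (a != n_code) & (b != n_code)
        matches = int(((a == b) & informative).sum())
        mismatches = int(((a != b) & informative).sum())
        candidates.append((matches - mismatches, L, mismatches))

    if not candidates:  # reads shorter than min_overlap
        return MergeResult(None, 0, 0, "no_overlap")

    score = max(c[0] for c in candidates)
    top = [c for c in candidates if c[0] == score]
    _, L, mismatches = top[0]
    if mismatches > max_mismatch_rate * L:
        return MergeResult(None, L, mismatches, "no_overlap")
    if len(top) > 1:
        return MergeResult(None, L, mismatches, "ambiguous")

    # consensus over the overlap
    fs, fq = fwd.sequence, fwd.qualities
    off = len(fs) - L
    seq_chars = list(fs[:off])
    quals = list(fq[:off])
    for k in range(L):
        cf, qf = fs[off + k], fq[off + k]
        cr, qr = rc_seq[k], rc_qual[k]
        if cf == cr:
            seq_chars.append(cf)
            quals.append(max(qf, qr))
        else:
            seq_chars.append(cf if qf >= qr else cr)
            quals.append(abs(qf - qr))
    merged_seq = "".join(seq_chars) + rc_seq[L:]
    quals.extend(rc_qual[L:])
    merged = QualifiedRead(fwd.read_id, merged_seq, tuple(quals), mate="merged")
    assert len(merged) == len(fwd) + len(rev) - L
    return MergeResult(merged, L, mismatches, "merged")
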