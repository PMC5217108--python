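"""Read trimming and filtering.

Two distinct tools live here. The NGS read filter applies four whole-read
rejection rules (runs of Ns, count of low-quality bases, median quality,
minimum length), each evaluated independently so a verdict lists every
violated rule. The Mott-style trimmer finds the contiguous segment that
maximizes Σ(error_limit − p_err) over its bases, the classic way to strip
bad 5'/3' ends of a Sanger trace at a fixed error-probability limit.

Note the low-quality-base rule is a *count*: a read with three or more
bases at or below Q20 is rejected outright, which is strict; the threshold
is configurable. Median quality uses the lower median for even lengths so
the rule stays integer-valued.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

from .formats import QualifiedRead


@dataclass(frozen=True)
class FilterRules:
    max_consecutive_N: int = 3  # reject at >= this many consecutive Ns
    max_lowq_bases: int = 3  # reject at >= this many bases with Q <= lowq_threshold
    lowq_threshold: int = 20
    min_median_q: int = 20  # reject if median Q < this
    min_length: int = 150  # reject if shorter than this

    def __post_init__(self) -> None:
        if min(self.max_consecutive_N, self.max_lowq_bases, self.lowq_threshold,
               self.min_median_q, self.min_length) < 0:
            raise ValueError("filter thresholds must be non-negative")


@dataclass(frozen=True)
class FilterVerdict:
    keep: bool
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.keep != (len(self.reasons) == 0):
            raise ValueError("keep must be equivalent to an empty reason list")


def _longest_N_run(seq: str) -> int:
    best = run = 0
    for c in seq:
        run = run + 1 if c == "N" else 0
        best = max(best, run)
    return best


def lower_median(values: Sequence[int]) -> int:
    """Median; for even-length input, the lower of the two middle values."""
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def filter_read(read: QualifiedRead, rules: FilterRules = FilterRules()) -> FilterVerdict:
    """Evaluate all four rejection rules; the verdict lists every violation."""
    if read.qualities is None:
        raise ValueError(f"read {read.read_id!r} has no qualities")
    reasons = []
    if _longest_N_run(read.sequence) >= rules.max_consecutive_N:
        reasons.append("consecutive_N")
    if sum(q <= rules.lowq_threshold for q in read.qualities) >= rules.max_lowq_bases:
        reasons.append("lowq_bases")
    if len(read) and lower_median(read.qualities) < rules.min_median_q:
        reasons.append("median_q")
    if len(read) < rules.min_length:
        reasons.append("length")
    return FilterVerdict(not reasons, tuple(reasons))


def trim_adapters(
    read: QualifiedRead,
    adapters: Sequence[str],
    min_match: int = 6,
) -> QualifiedRead:
    """Remove adapter read-through from the 3' end (exact matching).

    A full adapter occurrence anywhere truncates the read at its start;
    otherwise the longest read suffix equal to an adapter prefix (at least
    ``min_match`` bases) is removed. No match leaves the read unchanged.
    """
    if not adapters:
        raise ValueError("adapters must be non-empty")
    cut = len(read)
    for ad in adapters:
        pos = read.sequence.find(ad)
        if pos != -1:
            cut = min(cut, pos)
    if cut == len(read):
        best = 0
        for ad in adapters:
            top = min(len(read), len(ad))
            for k in range(top, min_match - 1, -1):
                if read.sequence.endswith(ad[:k]):
                    best = max(best, k)
                    break
        cut = len(read) - best
    return read.slice(0, cut)


def mott_trim(
    read: QualifiedRead,
    error_limit: float = 0.01,
) -> tuple[QualifiedRead, int, int]:
    """Best-segment quality trimming at a fixed error-probability limit.

    Each base contributes ``error_limit − 10^(−Q/10)``; the returned
    segment [start, end) maximizes the contribution sum. Ties are broken
    leftmost-first, then longest. If every base is worse than the limit
    the empty segment (0, 0) is returned.
    """
    if not (0.0 < error_limit < 1.0):
        raise ValueError("error_limit must be in (0, 1)")
    if read.qualities is None:
        raise ValueError(f"read {read.read_id!r} has no qualities")
    scores = [error_limit - 10.0 ** (-q / 10.0) for q in read.qualities]
    best_sum = 0.0
    best = (0, 0)
    prefix = 0.0
    min_prefix = 0.0
    min_prefix_at = 0
    for e, s in enumerate(scores, start=1):
        prefix += s
        cand = prefix - min_prefix
        if cand > best_sum + 1e-15 or (
            abs(cand - best_sum) <= 1e-15
            and cand > 0
            and (min_prefix_at < best[0] or (min_prefix_at == best[0] and e > best[1]))
        ):
            best_sum = cand
            best = (min_prefix_at, e)
        if prefix < min_prefix - 1e-15:
            min_prefix = prefix
            min_prefix_at = e
    start, end = best
    return read.slice(start, end), start, end
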