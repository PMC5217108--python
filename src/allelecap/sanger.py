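"""Sanger-side quality metrics and the Sanger-vs-NGS comparison.

Three small computations mirror how a dideoxy trace is judged against the
alleles recovered from amplicon NGS for the same specimen:

* ``pct_above_q20`` — the fraction of trace bases strictly above Q20, a
  whole-trace quality summary (the evaluated region is configurable, since
  trace ends are instrument-dependent);
* ``match_allele`` — the smallest allele rank whose sequence matches the
  quality-trimmed trace at 100% identity over their aligned overlap,
  IUPAC-aware (an R in the trace is consistent with an A or G allele base)
  and with free terminal overhangs on either side;
* ``coverage_pct`` — trimmed trace length as a percentage of the
  specimen's mean allele length. Values above 100% are real: when the
  amplicon is too long for the paired reads to overlap, the assembled
  alleles are truncated and a good trace can exceed their length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import edlib

from .alleles import AlleleSet
from .dna import IUPAC_SETS
from .formats import QualifiedRead

# every unordered symbol pair whose IUPAC sets intersect
_EXTRA_EQUALITIES = [
    (a, b)
    for a in IUPAC_SETS
    for b in IUPAC_SETS
    if a < b and not IUPAC_SETS[a].isdisjoint(IUPAC_SETS[b])
]


@dataclass(frozen=True)
class SangerComparison:
    specimen_id: str
    pct_above_q20: float
    trimmed_len: int
    matched_rank: Optional[int]
    coverage_pct: float


def pct_above_q20(trace: QualifiedRead, end: Optional[int] = None) -> float:
    """Percent of bases with Q strictly above 20 in [0, end).

    ``end`` defaults to the whole trace.
    """
    if trace.qualities is None or len(trace) == 0:
        raise ValueError("trace must be non-empty with qualities")
    quals = trace.qualities[: end if end is not None else len(trace)]
    if not quals:
        raise ValueError("evaluated region is empty")
    return 100.0 * sum(q > 20 for q in quals) / len(quals)


def _matches_fully(query: str, target: str) -> bool:
    """100% identity of query against target with free target-end gaps."""
    if len(query) > len(target):
        query, target = target, query
    res = edlib.align(query, target, mode="HW", task="distance",
                      additionalEqualities=_EXTRA_EQUALITIES)
    return res["editDistance"] == 0


def match_allele(trimmed_sanger: QualifiedRead, alleles: AlleleSet) -> Optional[int]:
    """Smallest allele rank matching the trimmed trace at 100% identity.

    Returns None if no allele matches (or the trimmed trace is empty).
    """
    if len(trimmed_sanger) == 0:
        import warnings

        warnings.warn("empty trimmed Sanger sequence; no allele match possible")
        return None
    for allele in alleles.alleles:  # alleles are already in rank order
        if _matches_fully(trimmed_sanger.sequence, allele.sequence):
            return allele.rank
    return None


def coverage_pct(trimmed_len: int, allele_lengths: Sequence[int]) -> float:
    """100 · trimmed Sanger length / mean allele length.

    The denominator is the mean over the individual's allele lengths (for
    printed size ranges, the mean of the range endpoints reproduces the
    published per-specimen coverage values).
    """
    if trimmed_len < 0:
        raise ValueError("trimmed_len must be ≥0")
    if not allele_lengths:
        raise ValueError("allele_lengths must be non-empty")
    mean_len = sum(allele_lengths) / len(allele_lengths)
    return 100.0 * trimmed_len / mean_len


def compare_specimen(
    specimen_id: str,
    trace: QualifiedRead,
    alleles: AlleleSet,
    trim_error: float = 0.01,
) -> SangerComparison:
    """Full per-specimen comparison: %>Q20, trim, match, coverage."""
    from .qc import mott_trim

    q20 = pct_above_q20(trace)
    trimmed, _, _ = mott_trim(trace, trim_error)
    rank = match_allele(trimmed, alleles) if alleles.alleles else None
    cov = (
        coverage_pct(len(trimmed), [len(a.sequence) for a in alleles.alleles])
        if alleles.alleles
        else float("nan")
    )
    return SangerComparison(specimen_id, q20, len(trimmed), rank, cov)
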