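"""Perfect tandem-repeat (microsatellite) detection and summaries.

A microsatellite is a maximal perfect tandem run of a primitive motif of
unit length 1–6 bp with at least five complete repeats (homopolymers are
unit length 1). Only perfect repeats are considered. A trailing partial
unit extends the reported span (and the fractional repeat count) but does
not count toward the minimum number of repeats. A locus whose span lies
inside a reported locus of a shorter unit is suppressed, so a G×10 run is
never double-reported as (GG)×5 — class counts stay disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .dna import revcomp


@dataclass(frozen=True)
class MicrosatLocus:
    seq_id: str
    start: int  # 0-based, half-open span
    end: int
    motif: str

    @property
    def unit_len(self) -> int:
        return len(self.motif)

    @property
    def repeat_count(self) -> float:
        return (self.end - self.start) / len(self.motif)

    @property
    def canonical_motif(self) -> str:
        return canonical_motif(self.motif)


def _is_primitive(motif: str) -> bool:
    """True iff the motif is not a power of a shorter motif."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Smallest rotation over the motif and its reverse complement.

    Lets the same repeat be matched across strands and phase offsets when
    comparing species.
    """
    rc = revcomp(motif)
    rots = [m[i:] + m[:i] for m in (motif, rc) for i in range(len(m))]
    return min(rots)


def find_microsatellites(
    seq: str,
    max_unit: int = 6,
    min_repeats: int = 5,
    seq_id: str = "",
) -> list[MicrosatLocus]:
    """All maximal perfect tandem repeats of primitive motifs.

    Sorted by start position. ``min_repeats`` counts complete units;
    spans contained in a shorter-unit locus are suppressed.
    """
    if max_unit < 1:
        raise ValueError("max_unit must be ≥1")
    if min_repeats < 2:
        raise ValueError("min_repeats must be ≥2")
    n = len(seq)
    loci: list[MicrosatLocus] = []
    for u in range(1, max_unit + 1):
        j = u
        while j < n:
            if seq[j] != seq[j - u]:
                j += 1
                continue
            # maximal run of the self-match property starting at j
            run_start = j
            while j < n and seq[j] == seq[j - u]:
                j += 1
            start = run_start - u
            end = j
            motif = seq[start : start + u]
            if _is_primitive(motif) and (end - start) // u >= min_repeats:
                loci.append(MicrosatLocus(seq_id, start, end, motif))
    # containment suppression: drop loci inside a span of a shorter unit
    kept: list[MicrosatLocus] = []
    for loc in loci:
        contained = any(
            o.unit_len < loc.unit_len and o.start <= loc.start and loc.end <= o.end
            for o in loci
        )
        if not contained:
            kept.append(loc)
    kept.sort(key=lambda l: (l.start, l.unit_len))
    return kept


def summarize_by_class(
    loci_by_seq: Mapping[str, Sequence[MicrosatLocus]],
    species_by_seq: Mapping[str, str],
    max_unit: int = 6,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Summaries of detected loci.

    Returns (class_counts, presence_absence, locations):

    * class_counts: per-species and overall counts per unit-length class
      1..max_unit (the homopolymer / di / tri / tetra ... tally);
    * presence_absence: species × canonical motif 0/1 matrix;
    * locations: one row per locus (seq_id, start, end, motif,
      canonical_motif, unit_len, repeat_count).
    """
    rows = []
    for sid, loci in loci_by_seq.items():
        sp = species_by_seq.get(sid, "")
        for loc in loci:
            rows.append(
                (sid, sp, loc.start, loc.end, loc.motif, loc.canonical_motif,
                 loc.unit_len, loc.repeat_count)
            )
    locations = pd.DataFrame(
        rows,
        columns=["seq_id", "species", "start", "end", "motif",
                 "canonical_motif", "unit_len", "repeat_count"],
    ).sort_values(["seq_id", "start"], kind="stable").reset_index(drop=True)

    species = sorted(set(species_by_seq.values()))
    classes = list(range(1, max_unit + 1))
    counts = pd.DataFrame(0, index=species + ["total"], columns=classes)
    if len(locations):
        for (sp, u), c in locations.groupby(["species", "unit_len"]).size().items():
            counts.loc[sp, u] += c
            counts.loc["total", u] += c

    motifs = sorted(set(locations["canonical_motif"])) if len(locations) else []
    presence = pd.DataFrame(0, index=species, columns=motifs)
    for _, row in locations.iterrows():
        if row["species"]:
            presence.loc[row["species"], row["canonical_motif"]] = 1
    return counts, presence, locations
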