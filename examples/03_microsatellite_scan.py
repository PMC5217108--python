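"""Detect perfect microsatellites (unit 1-6 bp, >=5 repeats) in sequences.

Scans a sequence with a homopolymer, a dinucleotide repeat and a
trinucleotide repeat; prints each locus with its span, motif, canonical
rotation and (possibly fractional) repeat count.
"""

from allelecap.repeats import find_microsatellites, summarize_by_class

seq = (
    "GATCGATTACCGTAGGCT"
    + "A" * 8          # homopolymer A x8
    + "TTGACCGT"
    + "CA" * 6          # dinucleotide (CA) x6
    + "GGATCC"
    + "AGT" * 5 + "AG"  # trinucleotide (AGT) x5 + partial trailing unit
    + "CGTCAGA"
)
loci = find_microsatellites(seq, max_unit=6, min_repeats=5, seq_id="demo")
for loc in loci:
    print(f"[{loc.start:3d},{loc.end:3d}) motif {loc.motif:>3s} "
          f"(canonical {loc.canonical_motif}) x{loc.repeat_count:.2f}")

counts, presence, _ = summarize_by_class({"demo": loci}, {"demo": "SpeciesA"})
print("\nrepeat-class counts (unit length 1..6):")
print(counts.loc["total"].to_string())
# unit-1 loci are homopolymers; the partial trailing AG extends the AGT
# span (and the fractional count) but does not add a repeat
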