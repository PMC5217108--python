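"""Small DNA utilities shared across the package.

IUPAC ambiguity codes are first-class here because Sanger heterozygote
calls arrive as single-letter codes (R = A/G etc.) and every identity or
distance computation must treat a code as the *set* of bases it denotes.
"""

from __future__ import annotations

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_ALPHABET = frozenset(IUPAC_SETS)

_CODE_BY_SET = {v: k for k, v in IUPAC_SETS.items()}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN-",
    "TGCAYRSWMKVHDBN-",
)


def revcomp(seq: str) -> str:
    """Reverse-complement an IUPAC DNA string (gaps pass through)."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_code(bases: set[str] | frozenset[str]) -> str:
    """Single-letter code for a non-empty set of A/C/G/T."""
    return _CODE_BY_SET[frozenset(bases)]


def bases_match(a: str, b: str) -> bool:
    """True iff the IUPAC sets of the two symbols intersect."""
    return not IUPAC_SETS[a].isdisjoint(IUPAC_SETS[b])


def validate_sequence(seq: str, where: str = "sequence") -> str:
    """Uppercase and check that every character is an IUPAC DNA code."""
    up = seq.upper()
    bad = set(up) - IUPAC_ALPHABET
    if bad:
        raise ValueError(f"non-IUPAC characters {sorted(bad)!r} in {where}")
    return up
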