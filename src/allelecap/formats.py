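"""Sequence, quality and metadata file formats.

All other modules exchange data through the two records defined here:
:class:`QualifiedRead` (a sequence with per-base Phred qualities) and
:class:`SpecimenRecord` (specimen id → species/genus taxonomy). FASTQ is
Phred+33 (Illumina 1.8+ / Sanger encoding) by default; FASTA sequences
carry no qualities and are flagged as such. Coordinates everywhere in the
package are 0-based, half-open.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .dna import validate_sequence

Mate = Literal["forward", "reverse", "merged", "sanger"]


@dataclass(frozen=True)
class QualifiedRead:
    """A DNA sequence with optional per-base Phred qualities.

    ``qualities is None`` means qualities are absent (e.g. plain FASTA);
    otherwise ``len(qualities) == len(sequence)`` is enforced.
    """

    read_id: str
    sequence: str
    qualities: tuple[int, ...] | None = None
    mate: Mate = "merged"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_sequence(self.sequence, self.read_id or "read"))
        if self.qualities is not None:
            q = tuple(int(x) for x in self.qualities)
            if len(q) != len(self.sequence):
                raise ValueError(
                    f"record {self.read_id!r}: sequence length {len(self.sequence)} "
                    f"!= quality length {len(q)}"
                )
            if any(x < 0 for x in q):
                raise ValueError(f"record {self.read_id!r}: negative quality value")
            object.__setattr__(self, "qualities", q)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def has_qualities(self) -> bool:
        return self.qualities is not None

    def slice(self, start: int, end: int) -> "QualifiedRead":
        """Sub-read over [start, end)."""
        q = None if self.qualities is None else self.qualities[start:end]
        return replace(self, sequence=self.sequence[start:end], qualities=q)


@dataclass(frozen=True)
class SpecimenRecord:
    """One specimen row of the metadata table (optionally with higher taxa)."""

    specimen_id: str
    species: str
    genus: str
    tribe: str = ""
    subfamily: str = ""

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError(f"specimen {self.specimen_id!r}: empty species")


def read_fastq(path: str | Path, quality_offset: int = 33, mate: Mate = "merged") -> list[QualifiedRead]:
    """Parse a 4-line-record FASTQ file into QualifiedReads.

    Qualities are decoded as ``ord(char) - quality_offset``.
    """
    reads: list[QualifiedRead] = []
    with open(path) as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                rid = title.split()[0] if title else ""
                if len(seq) != len(qual):
                    raise ValueError(f"record {rid!r}: sequence/quality length mismatch")
                reads.append(
                    QualifiedRead(rid, seq, tuple(ord(c) - quality_offset for c in qual), mate=mate)
                )
        except ValueError as exc:
            # Biopython raises on structurally broken records; keep the
            # offending record visible in the message.
            raise ValueError(f"malformed FASTQ in {path}: {exc}") from exc
    return reads


def write_fastq(reads: Iterable[QualifiedRead], path: str | Path, quality_offset: int = 33) -> None:
    with open(path, "w") as fh:
        for r in reads:
            if r.qualities is None:
                raise ValueError(f"record {r.read_id!r} has no qualities; cannot write FASTQ")
            qual = "".join(chr(q + quality_offset) for q in r.qualities)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


def read_fasta(path: str | Path) -> list[QualifiedRead]:
    """Parse FASTA; records get ``qualities=None`` (absent)."""
    reads: list[QualifiedRead] = []
    seen: dict[str, int] = {}
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            rid = title.split()[0]
            seen[rid] = seen.get(rid, 0) + 1
            reads.append(QualifiedRead(rid, seq, None))
    dups = sorted(r for r, n in seen.items() if n > 1)
    if dups:
        raise ValueError(f"duplicate FASTA ids in {path}: {dups}")
    return reads


def write_fasta(reads: Iterable[QualifiedRead | tuple[str, str]], path: str | Path, width: int = 70) -> None:
    """Write records (QualifiedReads or (id, seq) pairs) as wrapped FASTA."""
    with open(path, "w") as fh:
        for r in reads:
            rid, seq = (r.read_id, r.sequence) if isinstance(r, QualifiedRead) else r
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_specimen_table(path: str | Path) -> list[SpecimenRecord]:
    """Read the specimen metadata TSV (specimen_id, species, genus[, tribe, subfamily])."""
    out: list[SpecimenRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            sid = row["specimen_id"]
            if sid in seen:
                raise ValueError(f"duplicate specimen_id {sid!r} in {path}")
            seen.add(sid)
            out.append(
                SpecimenRecord(
                    sid,
                    row["species"],
                    row.get("genus", ""),
                    row.get("tribe", "") or "",
                    row.get("subfamily", "") or "",
                )
            )
    return out


def write_specimen_table(records: Sequence[SpecimenRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["specimen_id", "species", "genus", "tribe", "subfamily"])
        for r in records:
            w.writerow([r.specimen_id, r.species, r.genus, r.tribe, r.subfamily])


def write_newick(tree, path: str | Path) -> None:
    """Write an UnrootedTree as Newick with bootstrap supports as internal labels."""
    from .trees import UnrootedTree  # local import to avoid a cycle

    if not isinstance(tree, UnrootedTree):
        raise TypeError("write_newick expects an UnrootedTree")
    tree.write_newick(path)


def read_newick(path: str | Path):
    from .trees import UnrootedTree

    return UnrootedTree.from_newick_file(path)
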