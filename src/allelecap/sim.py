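"""Synthetic species panels, allele sets, read pairs and Sanger-like traces.

The generator emulates the statistical structure of a hypervariable
multi-copy barcode marker such as ITS2:

* species templates 350–600 bp, each carrying at least one embedded
  species-specific microsatellite; congeners derive from a shared genus
  ancestor at a configurable divergence (~10% pairwise);
* individuals carry 1–many distinct alleles derived from the species
  template by SNPs, short (1–30 bp) indels and microsatellite repeat-count
  changes, with a strongly skewed abundance distribution — the most common
  allele is ``dominance`` times more abundant than the second (~20× is the
  magnitude reported for other multi-copy ribosomal markers);
* overlapping 2×250 bp read pairs with linearly decaying base quality and
  quality-driven substitution errors; a configurable fraction of fragments
  loses 1–30 bp at the 5' end (template degradation before library prep),
  which is what allows assembled alleles longer than 2×read_len − overlap;
* Sanger-like traces whose per-base quality collapses downstream of the
  first length-variant position among abundant alleles — the chromatogram
  phenomenology that makes direct sequencing of mixed-length templates
  fail — with IUPAC codes at abundant substitution polymorphisms.

Every function is deterministic under a fixed seed. Reads carry their
source allele index in the read id (``…|a<k>``) so tests never re-derive
the truth from generator internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np

from .align import progressive_msa
from .dna import iupac_code, revcomp
from .formats import QualifiedRead

_BASES = np.array(list("ACGT"))
_MOTIFS = ["A", "T", "C", "G", "AC", "AG", "AT", "CT", "GT", "ACT", "AGT", "ACGT"]


@dataclass(frozen=True)
class SpeciesTemplate:
    species: str
    genus: str
    template_seq: str
    motif_insert_sites: tuple[tuple[int, str, int], ...]  # (position, motif, repeats)


@dataclass(frozen=True)
class IndividualTruth:
    specimen_id: str
    species: str
    alleles: tuple[str, ...]
    abundances: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.alleles:
            raise ValueError("an individual needs at least one allele")
        if len(self.alleles) != len(self.abundances):
            raise ValueError("alleles and abundances must align")
        if abs(sum(self.abundances) - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")
        if any(b > a + 1e-12 for a, b in zip(self.abundances, self.abundances[1:])):
            raise ValueError("abundances must be sorted descending")


@dataclass(frozen=True)
class QualityModel:
    """Positional mean quality decaying linearly along the read, with
    Gaussian jitter — enough structure to exercise Q20-based filters."""

    q_start: float = 38.0
    q_end: float = 25.0
    jitter_sd: float = 3.0
    q_min: int = 2
    q_max: int = 40

    def draw(self, length: int, rng: np.random.Generator) -> np.ndarray:
        mean = np.linspace(self.q_start, self.q_end, max(length, 1))[:length]
        q = mean + rng.normal(0.0, self.jitter_sd, size=length)
        return np.clip(np.rint(q), self.q_min, self.q_max).astype(int)


@dataclass
class ReadPairSet:
    """Simulated pairs; iterable as (forward_reads, reverse_reads)."""

    forward: list[QualifiedRead]
    reverse: list[QualifiedRead]
    truncated_pairs: int = 0  # pairs where read_len exceeded the fragment

    def __iter__(self) -> Iterator[list[QualifiedRead]]:
        return iter((self.forward, self.reverse))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate_substitutions(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def make_panel(
    n_species: int,
    genus_structure: Optional[Mapping[str, int]] = None,
    length_range: tuple[int, int] = (350, 600),
    seed: int = 0,
    congeneric_divergence: float = 0.10,
) -> list[SpeciesTemplate]:
    """Generate species templates, congeners sharing a genus ancestor.

    ``genus_structure`` maps genus name → number of species (must sum to
    ``n_species``); by default every species gets its own genus. Each
    template embeds one species-specific microsatellite (unit 1–4 bp,
    5–8 repeats). Deterministic under ``seed``.
    """
    if n_species < 1:
        raise ValueError("n_species must be ≥1")
    lo, hi = length_range
    if not (0 < lo <= hi):
        raise ValueError(f"invalid length_range {length_range}")
    if genus_structure is None:
        genus_structure = {f"Genus{i + 1:02d}": 1 for i in range(n_species)}
    if sum(genus_structure.values()) != n_species:
        raise ValueError("genus_structure sizes must sum to n_species")
    rng = np.random.default_rng(seed)
    out: list[SpeciesTemplate] = []
    for genus, k in genus_structure.items():
        # leave room for the inserted repeat so lengths stay inside range
        base_len = int(rng.integers(lo, max(lo, hi - 40) + 1))
        ancestor = _random_seq(rng, base_len)
        for s in range(k):
            if k > 1:
                seq = _mutate_substitutions(ancestor, congeneric_divergence / 2.0, rng)
            else:
                seq = ancestor
            motif = _MOTIFS[int(rng.integers(0, len(_MOTIFS)))]
            reps = int(rng.integers(5, 9))
            pos = int(rng.integers(20, len(seq) - 20))
            seq = seq[:pos] + motif * reps + seq[pos:]
            out.append(
                SpeciesTemplate(
                    species=f"{genus} species{s + 1:02d}",
                    genus=genus,
                    template_seq=seq,
                    motif_insert_sites=((pos, motif, reps),),
                )
            )
    return out


def _abundances(n: int, dominance: float, decay: float = 0.6) -> tuple[float, ...]:
    if n == 1:
        return (1.0,)
    w = [dominance] + [decay ** i for i in range(n - 1)]
    total = sum(w)
    return tuple(x / total for x in w)


def make_individual(
    template: SpeciesTemplate,
    n_alleles: int,
    dominance: float = 20.0,
    indel_rate: float = 0.5,
    snp_rate: float = 0.03,
    seed: int = 0,
    specimen_id: str = "",
    min_divergence: Optional[float] = None,
) -> IndividualTruth:
    """Derive an individual's allele set from a species template.

    Each allele receives independent substitutions at ``snp_rate`` per
    base (pairwise allele divergence ≈ 2·snp_rate), with probability
    ``indel_rate`` one short (1–30 bp) indel, and with probability 0.5 a
    repeat-count change of the template microsatellite. The most common
    allele is ``dominance`` times more abundant than the second
    (``dominance=1`` requests a tie).

    ``min_divergence`` (a fraction, e.g. 0.05) enforces a minimum pairwise
    alignment divergence between alleles by rejection sampling — at the
    sampled rates a pair can land below any given threshold by chance, and
    variants closer than the clustering threshold are *by construction*
    indistinguishable from one allele downstream.
    """
    if n_alleles < 1:
        raise ValueError("n_alleles must be ≥1")
    if dominance < 1:
        raise ValueError("dominance must be ≥1")
    from .alleles import edlib_identity  # deferred: avoids a module cycle

    rng = np.random.default_rng(seed)
    alleles: list[str] = []
    attempts = 0
    while len(alleles) < n_alleles:
        attempts += 1
        if attempts > 200 * n_alleles:
            raise RuntimeError(
                "could not generate sufficiently distinct alleles; "
                "raise snp_rate or lower min_divergence"
            )
        seq = _mutate_substitutions(template.template_seq, snp_rate, rng)
        if rng.random() < indel_rate:
            ln = int(rng.integers(1, 31))
            pos = int(rng.integers(0, len(seq)))
            if rng.random() < 0.5:
                seq = seq[:pos] + _random_seq(rng, ln) + seq[pos:]
            else:
                seq = seq[:pos] + seq[pos + ln :]
        if template.motif_insert_sites and rng.random() < 0.5:
            pos, motif, reps = template.motif_insert_sites[0]
            old = motif * reps
            if old in seq:
                delta = int(rng.integers(1, 4)) * (1 if rng.random() < 0.5 else -1)
                new_reps = max(2, reps + delta)
                seq = seq.replace(old, motif * new_reps, 1)
        if seq in alleles:
            continue
        if min_divergence is not None and any(
            1.0 - edlib_identity(seq, prev) < min_divergence for prev in alleles
        ):
            continue
        alleles.append(seq)
    return IndividualTruth(
        specimen_id=specimen_id or template.species.replace(" ", "_"),
        species=template.species,
        alleles=tuple(alleles),
        abundances=_abundances(n_alleles, dominance),
    )


def simulate_reads(
    truth: IndividualTruth,
    n_pairs: int,
    read_len: int = 250,
    error_profile: QualityModel = QualityModel(),
    frag_degradation_rate: float = 0.0,
    seed: int = 0,
) -> ReadPairSet:
    """Paired 2×read_len reads from an individual's allele mixture.

    The source allele of each pair is drawn by abundance and recorded in
    the read id as ``|a<index>``. Substitution errors are drawn per base
    with probability 10^(−Q/10) from the positional quality model.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be ≥1")
    if read_len < 1:
        raise ValueError("read_len must be ≥1")
    rng = np.random.default_rng(seed)
    abund = np.array(truth.abundances)
    fwd: list[QualifiedRead] = []
    rev: list[QualifiedRead] = []
    truncated = 0

    def seq_with_errors(seq: str, quals: np.ndarray) -> str:
        err_p = 10.0 ** (-quals / 10.0)
        hits = np.nonzero(rng.random(len(seq)) < err_p)[0]
        if not len(hits):
            return seq
        arr = np.array(list(seq))
        for i in hits:
            choices = [b for b in "ACGT" if b != arr[i]]
            arr[i] = choices[rng.integers(0, 3)]
        return "".join(arr)

    for p in range(n_pairs):
        k = int(rng.choice(len(abund), p=abund))
        fragment = truth.alleles[k]
        if frag_degradation_rate > 0 and rng.random() < frag_degradation_rate:
            fragment = fragment[int(rng.integers(1, 31)) :]
        if read_len > len(fragment):
            truncated += 1
        rl = min(read_len, len(fragment))
        f_src = fragment[:rl]
        r_src = revcomp(fragment[-rl:])
        fq = error_profile.draw(rl, rng)
        rq = error_profile.draw(rl, rng)
        rid = f"{truth.specimen_id}_p{p}|a{k}"
        fwd.append(QualifiedRead(rid, seq_with_errors(f_src, fq), tuple(int(x) for x in fq), mate="forward"))
        rev.append(QualifiedRead(rid, seq_with_errors(r_src, rq), tuple(int(x) for x in rq), mate="reverse"))
    return ReadPairSet(fwd, rev, truncated)


def simulate_sanger(
    truth: IndividualTruth,
    collapse_quality: int = 10,
    seed: int = 0,
    minor_threshold: float = 0.2,
    clean_quality: int = 45,
    iupac_quality: int = 30,
) -> QualifiedRead:
    """A Sanger-like trace of the individual's allele mixture.

    The trace is the abundance-weighted column consensus over the aligned
    alleles. Columns where two or more bases each reach ``minor_threshold``
    total abundance are emitted as IUPAC codes at reduced quality. From
    the first column where abundant alleles disagree in *length* (an indel
    or repeat-count difference), qualities drop to ≤ ``collapse_quality``
    and bases are drawn randomly among the frame-shifted alternatives —
    a single-allele individual yields a clean, high-quality trace.
    """
    rng = np.random.default_rng(seed)
    sid = f"{truth.specimen_id}_sanger"
    if len(truth.alleles) == 1:
        seq = truth.alleles[0]
        return QualifiedRead(sid, seq, tuple([clean_quality] * len(seq)), mate="sanger")

    msa = progressive_msa(
        [(f"a{i}", s) for i, s in enumerate(truth.alleles)]
    )
    W = np.array(truth.abundances)
    rows = [seq for _, seq in msa.rows]
    ncol = msa.n_columns

    collapse_from = ncol
    for c in range(ncol):
        gap_w = sum(W[i] for i in range(len(rows)) if rows[i][c] == "-")
        base_w = sum(W[i] for i in range(len(rows)) if rows[i][c] != "-")
        if gap_w >= minor_threshold and base_w >= minor_threshold:
            collapse_from = c
            break

    seq_chars: list[str] = []
    quals: list[int] = []
    for c in range(ncol):
        weights: dict[str, float] = {}
        for i, row in enumerate(rows):
            weights[row[c]] = weights.get(row[c], 0.0) + float(W[i])
        if c < collapse_from:
            abundant = {b for b, w in weights.items() if b != "-" and w >= minor_threshold}
            if not abundant:
                # only rare alleles have a base here; emit nothing if the
                # abundant alleles all lack the column
                if weights.get("-", 0.0) >= minor_threshold:
                    continue
                abundant = {max((w, b) for b, w in weights.items() if b != "-")[1]}
            if len(abundant) == 1:
                seq_chars.append(next(iter(abundant)))
                quals.append(clean_quality)
            else:
                seq_chars.append(iupac_code(abundant))
                quals.append(iupac_quality)
        else:
            bases = [(b, w) for b, w in weights.items() if b != "-"]
            if not bases:
                continue
            probs = np.array([w for _, w in bases])
            probs = probs / probs.sum()
            pick = bases[int(rng.choice(len(bases), p=probs))][0]
            seq_chars.append(pick)
            quals.append(int(rng.integers(2, collapse_quality + 1)))
    return QualifiedRead(sid, "".join(seq_chars), tuple(quals), mate="sanger")
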