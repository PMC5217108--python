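# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical conventions. Coordinates are 0-based half-open
throughout; all randomness flows through explicit integer seeds and fixed
seeds give byte-identical outputs.

## Read quality control (`allelecap.qc`)

Reads are rejected — whole-read, no partial rescue — if any of four rules
fires: ≥3 consecutive `N` bases; ≥3 bases with Q ≤ 20; median Q < 20; or
length < 150 nt. Each threshold is configurable in `FilterRules`; the
verdict lists every violated rule, not just the first, so QC reports can
attribute losses. Notes:

* the low-quality rule is a **count** over the whole read, which is
  strict for 250 nt reads; it is kept literal because it is cheap to
  change (`max_lowq_bases`) and the filters only gate the merge stage;
* the median is the **lower median** for even lengths, keeping the rule
  integer-valued;
* filters apply per mate and a pair is dropped when either mate fails,
  since merging needs both;
* adapter trimming is exact-overlap (longest read suffix equal to an
  adapter prefix, ≥6 bases; a full internal adapter occurrence truncates
  at its start). Mismatch-tolerant adapter search is out of scope.

The Mott-style trimmer used for Sanger traces returns the contiguous
segment maximizing Σ(e − 10^(−Qᵢ/10)) with error limit e (default 0.01,
i.e. Q20); ties resolve leftmost-first then longest, and the empty
segment is legal when every base is worse than the limit. It is verified
against an exhaustive all-segments oracle.

## Pair merging (`allelecap.merge`)

The reverse read is reverse-complemented and every end-overlap length
L ≥ `min_overlap` (default 10) is scored matches − mismatches (`N`
contributes neither). The pair merges when the best overlap is unique and
its mismatch rate is ≤ `max_mismatch_rate` (default 0.1); a tied best is
`ambiguous`, a too-noisy best is `no_overlap`. This count-based score
replaces a statistical overlap test deliberately: at amplicon scale the
true overlap dominates by a wide margin, and the deterministic rule is
exactly testable. Consensus in the overlap takes the higher-quality base;
consensus quality is max(Q) at agreements and |Q_f − Q_r| at
disagreements, a conservative "winner minus loser" evidence measure.
Fragments whose 5′ end was lost before library prep merge naturally at a
shorter length, which is how assembled alleles can exceed
2·read_len − overlap for favourable fragments, while amplicons longer
than 2·read_len can never merge — the pipeline flags such specimens
`unmergeable` and excludes them from allele statistics.

## Allele calling (`allelecap.alleles`)

Merged amplicon reads are full-length, so contig assembly reduces to
clustering — the central functional substitution in this package.
Reads are dereplicated; unique sequences ordered by multiplicity (ties:
longer, then lexicographic) seed clusters greedily; a sequence joins the
first seed at alignment identity ≥ the threshold (default 0.95,
inclusive: variants under 5% divergence collapse into one allele, by
construction). Identity is matches / aligned columns with terminal gaps
excluded — so 5′-truncated reads cluster with their full-length allele —
and internal gaps counted as mismatches. The high-volume identity and
per-read alignments run through edlib (unit-cost alignment in C); the
package's own affine aligner defines the same quantity and the two routes
are cross-checked in the tests.

Consensus is per-column plurality over reads aligned to the cluster seed,
ties broken by summed quality then alphabetically; columns where gaps
hold a strict majority are deleted, so a lone insertion never enters the
consensus. Clusters below `min_reads` (default 2) are dropped before
ranking, suppressing sequencing-error singletons; rank 1 is the most
common allele and the top-two read-count gap (as % of reads used) is
reported because a small gap is precisely when the rank-1/rank-2 call is
fragile.

## Alignment and distances (`allelecap.align`)

Pairwise alignment is a three-state affine-gap global DP; a gap of length
L costs `gap_open + L·gap_extend` with defaults +1/−1/−4/−1 so that a
1 bp indel outweighs several substitutions — appropriate for a marker
whose length variation comes in discrete indel/repeat units. Traceback
prefers substitution over gap-in-A over gap-in-B, making output unique.
The DP rows are vectorized (the within-row affine dependency becomes a
prefix-max scan), and scores are verified against exhaustive alignment
enumeration for short strings.

The progressive MSA builds a guide order by average-linkage clustering of
6-mer count distances (deterministic, smallest-pair tie-break) and merges
blocks by profile–profile affine DP. Average linkage was chosen over a
guide NJ tree because it yields a rooted merge order directly; the guide
method only influences intermediate merge order, never the invariants
asserted (row order = input order, ungapping reproduces inputs,
substitution-only families align gap-free).

p-distance = differing sites / comparable sites with pairwise deletion by
default (length-variable alleles leave too few all-row-ungapped columns
for complete deletion, which remains available). IUPAC codes never count
as differences when their sets intersect — a Sanger heterozygote call R
is *consistent with* A — and `N` matches everything. A pair with zero
comparable sites is an error naming the pair.

## Trees, monophyly, agreement (`allelecap.trees`)

NJ is the standard Q-criterion agglomeration with the usual branch-length
formulas; tied minima resolve by the lexicographically smallest pair of
cluster representatives. Exactness on additive matrices (topology and
branch lengths) is property-tested against randomly generated trees and
cross-checked against an independent implementation. Negative branch
lengths are clamped to zero and flagged; internal edges of exactly zero
length (degenerate, e.g. all-identical sequences) are collapsed into
polytomies so that unresolvable structure is not presented as resolved.

Bootstrap resamples alignment columns with replacement; each internal
edge of the full-data tree gets the percentage of replicate trees
containing the same bipartition. Replicates where some pair loses all
comparable sites are skipped, warned about, and removed from the
denominator.

Monophyly is evaluated on the unrooted tree: a species is monophyletic
iff some bipartition separates exactly its leaves (leaves are alleles,
mapped to specimens, so one individual contributes several leaves);
single-leaf species are monophyletic by convention. Individuals inherit
their species' status — the finer alternative (scoring each individual's
own leaves) is noted but not used, since a species split across clades
renders all its members unresolved for barcoding purposes. The
Sanger-vs-NGS agreement table counts individuals in a 2×2 layout
(both monophyletic / Sanger only / NGS only / neither) with overall
percent agreement 100·(a+d)/total, reported exactly and rounded.

Divergence summaries classify pairs as conspecific, congeneric
(same genus, different species), or intergeneric, with optional
tribe/subfamily refinements from the metadata table; a barcoding gap is
declared only when the congeneric minimum exceeds the conspecific
maximum. Genus exclusion reruns support sensitivity analyses against
allele-rich outlier genera.

## Microsatellites (`allelecap.repeats`)

A locus is a maximal perfect tandem run of a primitive motif (not a power
of a shorter motif), unit 1–6 bp, with ≥5 complete repeats by default.
Perfect-only search is the single parameter-free reading of that
definition; an imperfection tolerance is a labelled extension point, and
class counts on real data are sensitive to that convention. A trailing
partial unit extends the span and the fractional repeat count but not the
repeat minimum; spans contained in a reported shorter-unit locus are
suppressed so class counts stay disjoint (an A×10 run is never also
(AA)×5). Motifs are reported as found, with a canonical column (smallest
rotation over motif and reverse complement) for cross-species matching.
The scanner is verified against a brute-force (start, unit) enumeration.

## Sanger comparison (`allelecap.sanger`)

%>Q20 is strict (Q = 20 does not count) over the whole trace by default;
the evaluated end is configurable because the biologically natural
endpoint (the final poly-A peak of a dideoxy run) is not recoverable from
sequence+quality input. Allele matching aligns the trimmed trace within
each allele (free terminal overhangs, IUPAC-aware) and returns the
smallest rank at 100% identity. Coverage is 100·L_trim/mean(allele
lengths); the mean-of-allele-lengths denominator is the definition that
reproduces the bundled study table row-by-row from its printed columns
(exactly for ≤2-allele rows, where the size-range endpoints are the
allele lengths; within ±0.2 via the rounded printed average otherwise).
Coverage above 100% is meaningful: it marks specimens whose assembled
alleles are truncated because the amplicon exceeded the mergeable length.

## Synthetic data (`allelecap.sim`)

The generator emulates the statistical structure the analysis assumes:

* **templates**: random 350–600 bp sequences (the amplicon size range of
  the target marker), one embedded species-specific microsatellite
  (unit 1–4 bp, 5–8 repeats — the observed unit-length classes);
  congeners derive from a shared genus ancestor at ~10% pairwise
  divergence, other genera are independent;
* **individuals**: 1–35 alleles derived from the template by per-base
  substitutions (`snp_rate`, default 0.03 → ~6% pairwise divergence, the
  scale of observed conspecific allele divergence — and deliberately
  above the 5% clustering threshold, since real alleles are distinct
  ≥95%-identity contigs), one optional 1–30 bp indel, and repeat-count
  changes of the embedded microsatellite. Abundances are geometric with
  the most common allele `dominance`× the second (default 20, the
  magnitude reported for other multi-copy rDNA systems; `dominance=1`
  requests a tie). `min_divergence` optionally enforces a pairwise
  divergence floor by rejection sampling, for experiments conditioned on
  "alleles separable at the clustering threshold";
* **reads**: 2×250 bp by default; the source allele is drawn per pair by
  abundance (and recorded in the read id, so tests never re-derive truth
  from generator internals); per-base substitution errors with
  probability 10^(−Q/10) under a positional quality model (mean Q
  decaying linearly 38→25 with Gaussian jitter σ = 3 — no public profile
  exists for the instrument, and this shape exercises the Q20 filters);
  a configurable fraction of fragments loses 1–30 bp at the 5′ end,
  emulating template degradation;
* **Sanger traces**: abundance-weighted column consensus over the aligned
  alleles; columns where ≥2 bases each reach the minor-abundance
  threshold (default 0.2 — the disruption threshold is not quantified
  anywhere, so it is exposed) become IUPAC codes at Q30; from the first
  column where abundant alleles disagree in length, bases are drawn among
  the frame-shifted alternatives at quality ≤ `collapse_quality`
  (default 10). Single-allele individuals give clean Q45 traces.

Not emulated: PCR chimeras, cycle-level amplification bias, true
chromatogram peak shapes, quality-dependent indel errors, and
lane/instrument artefacts. Passing tests therefore demonstrate that the
**analysis logic** is correct under the stated statistical structure, not
that the pipeline is robust to every artefact of real libraries.

## Pipeline defaults and problem sizes

`run_pipeline` defaults to a 3-species panel, 2 specimens per species,
200 pairs per specimen, template range 360–450 bp (within the marker's
natural range and short enough that 2×250 reads overlap; longer
templates exercise the unmergeable path), bootstrap 1000. The acceptance
script measures end-to-end recovery on 20 independent specimens at 400
pairs each (≥50× expected depth per allele with `dominance=2`) and ~6%
allele divergence with a 5% floor; oracle comparisons use 500 random
cases each; NJ recovery uses 40 random trees of up to 12 leaves. These
sizes were chosen as the smallest that make the binomial/bootstrap bounds
in the assertions comfortable.

## Known limitations

* Greedy abundance-seeded clustering is order-dependent by design
  (deterministic, but a borderline sequence joins the first, not the
  closest, qualifying seed), and lowering the identity threshold is only
  empirically — not provably — monotone in cluster count.
* The merge consensus ignores correlated errors between mates.
* The unit-cost (edlib) and affine identity definitions can differ by
  ~1 column when an optimal path trades two substitutions for an indel
  pair; at the 95% threshold this matters only for pairs already on the
  boundary.
* Bootstrap supports are attached to the full-data topology only;
  replicate-majority consensus trees are not built.
* The bundled study table supports printed-number arithmetic; raw-read
  level statistics of that study (per-sample read counts, 85/88
  most-common-allele concordance) require the archived sequencing data
  and are represented here by the synthetic-recovery experiments instead.
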