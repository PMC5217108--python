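"""End-to-end pipeline: simulate → qc → merge → call → microsat → align →
phylo → compare, with a manifest and per-specimen summary report.

The report mirrors the per-specimen summary a barcoding study prints:
number of alleles, allele size range and mean, %>Q20 of the Sanger trace,
post-trim length, coverage of the alleles by the trimmed trace, and the
rank of the allele the trace matches. Specimens whose amplicon is too long
for the read pairs to overlap are flagged unmergeable and excluded from
allele statistics (with a warning in the log), the exact failure mode of a
>2×read_len target.

Identical config + seed ⇒ byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .align import progressive_msa, p_distance_matrix
from .alleles import AlleleSet, call_alleles
from .formats import (
    QualifiedRead,
    SpecimenRecord,
    read_fastq,
    write_fasta,
    write_fastq,
    write_specimen_table,
)
from .merge import merge_pair
from .qc import FilterRules, filter_read, mott_trim, trim_adapters
from .repeats import find_microsatellites, summarize_by_class
from .sanger import compare_specimen
from .sim import QualityModel, make_individual, make_panel, simulate_reads, simulate_sanger
from .trees import agreement_table, bootstrap_support, divergence_summary, monophyly, nj_tree


def _strict(cls, d: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**d)


@dataclass(frozen=True)
class SimulateConfig:
    n_species: int = 3
    species_per_genus: int = 1
    n_specimens_per_species: int = 2
    length_range: tuple[int, int] = (360, 450)
    n_alleles_range: tuple[int, int] = (1, 4)
    dominance: float = 20.0
    snp_rate: float = 0.03
    indel_rate: float = 0.5
    congeneric_divergence: float = 0.10
    n_pairs: int = 200
    read_len: int = 250
    frag_degradation_rate: float = 0.05
    sanger_minor_threshold: float = 0.2
    sanger_collapse_quality: int = 10


@dataclass(frozen=True)
class QcConfig:
    min_length: int = 150
    min_median_q: int = 20
    max_lowq_bases: int = 3
    lowq_threshold: int = 20
    max_consecutive_N: int = 3
    adapters: tuple[str, ...] = ()

    def rules(self) -> FilterRules:
        return FilterRules(
            max_consecutive_N=self.max_consecutive_N,
            max_lowq_bases=self.max_lowq_bases,
            lowq_threshold=self.lowq_threshold,
            min_median_q=self.min_median_q,
            min_length=self.min_length,
        )


@dataclass(frozen=True)
class MergeConfig:
    min_overlap: int = 10
    max_mismatch_rate: float = 0.1


@dataclass(frozen=True)
class CallConfig:
    identity: float = 0.95
    min_reads: int = 2


@dataclass(frozen=True)
class MicrosatConfig:
    max_unit: int = 6
    min_repeats: int = 5


@dataclass(frozen=True)
class PhyloConfig:
    bootstrap: int = 1000
    gap_policy: str = "pairwise_deletion"


@dataclass(frozen=True)
class CompareConfig:
    trim_error: float = 0.01


@dataclass(frozen=True)
class RunConfig:
    outdir: str = "run"
    seed: int = 0
    simulate: SimulateConfig = SimulateConfig()
    qc: QcConfig = QcConfig()
    merge: MergeConfig = MergeConfig()
    call: CallConfig = CallConfig()
    microsat: MicrosatConfig = MicrosatConfig()
    phylo: PhyloConfig = PhyloConfig()
    compare: CompareConfig = CompareConfig()

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        blocks = {
            "simulate": SimulateConfig,
            "qc": QcConfig,
            "merge": MergeConfig,
            "call": CallConfig,
            "microsat": MicrosatConfig,
            "phylo": PhyloConfig,
            "compare": CompareConfig,
        }
        kwargs: dict = {}
        for key, sub in blocks.items():
            if key in d:
                block = dict(d.pop(key))
                for f in dataclasses.fields(sub):
                    if f.name in block and isinstance(block[f.name], list):
                        block[f.name] = tuple(block[f.name])
                kwargs[key] = _strict(sub, block)
        unknown = set(d) - {"outdir", "seed"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(d)
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class RunResult:
    outdir: Path
    report: pd.DataFrame
    allele_sets: dict[str, AlleleSet]
    agreement: Optional[tuple[int, int, int, int]]
    unmergeable: list[str]


def _spawn_seed(base: int, *indices: int) -> int:
    h = hashlib.sha256(("/".join(map(str, (base,) + indices))).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(config: RunConfig) -> RunResult:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def note(msg: str) -> None:
        log.append(msg)

    sim = config.simulate
    genus_structure = None
    if sim.species_per_genus > 1:
        n_genera = -(-sim.n_species // sim.species_per_genus)
        left = sim.n_species
        genus_structure = {}
        for g in range(n_genera):
            k = min(sim.species_per_genus, left)
            genus_structure[f"Genus{g + 1:02d}"] = k
            left -= k
    panel = make_panel(
        sim.n_species,
        genus_structure=genus_structure,
        length_range=sim.length_range,
        seed=_spawn_seed(config.seed, 1),
        congeneric_divergence=sim.congeneric_divergence,
    )
    rng = np.random.default_rng(_spawn_seed(config.seed, 2))
    specimens: list[SpecimenRecord] = []
    truths = {}
    truth_rows = []
    for si, tpl in enumerate(panel):
        for k in range(sim.n_specimens_per_species):
            sid = f"SP{si + 1:02d}{chr(ord('A') + k)}"
            n_alleles = int(rng.integers(sim.n_alleles_range[0], sim.n_alleles_range[1] + 1))
            truth = make_individual(
                tpl,
                n_alleles,
                dominance=sim.dominance,
                indel_rate=sim.indel_rate,
                snp_rate=sim.snp_rate,
                seed=_spawn_seed(config.seed, 3, si, k),
                specimen_id=sid,
            )
            specimens.append(SpecimenRecord(sid, tpl.species, tpl.genus))
            truths[sid] = truth
            for ai, (seq, ab) in enumerate(zip(truth.alleles, truth.abundances)):
                truth_rows.append((sid, ai, f"{ab:.6f}", seq))
    write_specimen_table(specimens, out / "specimens.tsv")
    with open(out / "truth.tsv", "w") as fh:
        fh.write("specimen_id\tallele_index\tabundance\tsequence\n")
        for row in truth_rows:
            fh.write("\t".join(map(str, row)) + "\n")

    rules = config.qc.rules()
    report_rows = []
    allele_sets: dict[str, AlleleSet] = {}
    unmergeable: list[str] = []
    sanger_traces: dict[str, QualifiedRead] = {}
    all_alleles: list[tuple[str, str]] = []  # (allele_id, sequence)
    leaf_to_specimen: dict[str, str] = {}

    for sid, truth in truths.items():
        pairs = simulate_reads(
            truth,
            sim.n_pairs,
            read_len=sim.read_len,
            frag_degradation_rate=sim.frag_degradation_rate,
            seed=_spawn_seed(config.seed, 4, sid),
        )
        write_fastq(pairs.forward, out / f"{sid}_R1.fastq")
        write_fastq(pairs.reverse, out / f"{sid}_R2.fastq")
        trace = simulate_sanger(
            truth,
            collapse_quality=sim.sanger_collapse_quality,
            minor_threshold=sim.sanger_minor_threshold,
            seed=_spawn_seed(config.seed, 5, sid),
        )
        sanger_traces[sid] = trace

        # qc: a pair is dropped when either mate fails
        kept = []
        for f, r in zip(pairs.forward, pairs.reverse):
            if config.qc.adapters:
                f = trim_adapters(f, config.qc.adapters)
                r = trim_adapters(r, config.qc.adapters)
            if filter_read(f, rules).keep and filter_read(r, rules).keep:
                kept.append((f, r))
        note(f"{sid}: {len(kept)}/{sim.n_pairs} pairs passed QC")

        merged: list[QualifiedRead] = []
        for f, r in kept:
            res = merge_pair(f, r, config.merge.min_overlap, config.merge.max_mismatch_rate)
            if res.status == "merged":
                merged.append(res.merged)
        note(f"{sid}: {len(merged)}/{len(kept)} pairs merged")

        if len(merged) < config.call.min_reads:
            unmergeable.append(sid)
            warnings.warn(f"specimen {sid}: unmergeable (amplicon too long for read overlap?)")
            note(f"{sid}: unmergeable, excluded from allele statistics")
            continue
        aset = call_alleles(
            merged, config.call.identity, config.call.min_reads, specimen_id=sid
        )
        allele_sets[sid] = aset
        for a in aset.alleles:
            all_alleles.append((a.allele_id, a.sequence))
            leaf_to_specimen[a.allele_id] = sid

    write_fastq(sanger_traces.values(), out / "sanger.fastq")
    write_fasta(all_alleles, out / "alleles.fasta")

    # microsatellites over all called alleles
    species_by_seq = {
        aid: next(s.species for s in specimens if s.specimen_id == leaf_to_specimen[aid])
        for aid, _ in all_alleles
    }
    loci_by_seq = {
        aid: find_microsatellites(seq, config.microsat.max_unit, config.microsat.min_repeats, aid)
        for aid, seq in all_alleles
    }
    class_counts, presence, locations = summarize_by_class(loci_by_seq, species_by_seq,
                                                           config.microsat.max_unit)
    class_counts.to_csv(out / "microsat_classes.tsv", sep="\t")
    locations.to_csv(out / "microsat_loci.tsv", sep="\t", index=False)

    # alignment, tree, monophyly over NGS alleles
    ngs_status: dict[str, bool] = {}
    agreement = None
    if len(all_alleles) >= 4:
        msa = progressive_msa(all_alleles)
        tree = bootstrap_support(
            msa, config.phylo.bootstrap, config.phylo.gap_policy,
            seed=_spawn_seed(config.seed, 6),
        )
        tree.write_newick(out / "ngs_tree.nwk")
        calls, ngs_status = monophyly(tree, specimens, leaf_to_specimen)
        with open(out / "monophyly_ngs.tsv", "w") as fh:
            fh.write("species\tmonophyletic\tn_individuals\n")
            for c in calls:
                fh.write(f"{c.species}\t{int(c.monophyletic)}\t{c.n_individuals}\n")
        dm = p_distance_matrix(msa, config.phylo.gap_policy)
        div, gap_present = divergence_summary(dm, specimens, leaf_to_specimen)
        div.to_csv(out / "divergence.tsv", sep="\t", index=False)
        note(f"barcoding gap present: {gap_present}")

        # Sanger-side tree from the trimmed traces
        trimmed = {
            sid: mott_trim(tr, config.compare.trim_error)[0]
            for sid, tr in sanger_traces.items()
        }
        usable = [(sid, t.sequence) for sid, t in trimmed.items() if len(t) >= 50]
        sanger_status = {sid: False for sid in sanger_traces}
        if len(usable) >= 4:
            smsa = progressive_msa(usable)
            try:
                stree = nj_tree(p_distance_matrix(smsa, config.phylo.gap_policy))
                stree.write_newick(out / "sanger_tree.nwk")
                scalls, sstat = monophyly(
                    stree, specimens, {sid: sid for sid, _ in usable}
                )
                sanger_status.update(sstat)
            except ValueError as exc:
                note(f"sanger tree skipped: {exc}")
        if ngs_status:
            # individuals without an NGS status (unmergeable) are excluded
            common = sorted(set(ngs_status) & set(sanger_status))
            at = agreement_table(
                {k: sanger_status[k] for k in common},
                {k: ngs_status[k] for k in common},
            )
            agreement = (at.a, at.b, at.c, at.d)
            with open(out / "agreement.tsv", "w") as fh:
                fh.write("a_both_mono\tb_sanger_only\tc_ngs_only\td_neither\tpercent_agreement\n")
                fh.write(
                    f"{at.a}\t{at.b}\t{at.c}\t{at.d}\t{at.overall_percent_agreement:.1f}\n"
                )

    # per-specimen comparison and report
    for s in specimens:
        sid = s.specimen_id
        trace = sanger_traces[sid]
        if sid in allele_sets:
            aset = allele_sets[sid]
            cmpres = compare_specimen(sid, trace, aset, config.compare.trim_error)
            lens = [len(a.sequence) for a in aset.alleles]
            report_rows.append(
                dict(
                    specimen_id=sid,
                    species=s.species,
                    n_alleles=len(aset.alleles),
                    size_min=min(lens),
                    size_max=max(lens),
                    avg_size=round(sum(lens) / len(lens)),
                    pct_q20=round(cmpres.pct_above_q20, 1),
                    post_trim=cmpres.trimmed_len,
                    coverage=round(cmpres.coverage_pct, 1),
                    matched_rank="" if cmpres.matched_rank is None else cmpres.matched_rank,
                    top_two_gap="" if aset.top_two_gap_pct is None else round(aset.top_two_gap_pct, 1),
                    unmergeable=0,
                )
            )
        else:
            trimmed, _, _ = mott_trim(trace, config.compare.trim_error)
            from .sanger import pct_above_q20 as _q20

            report_rows.append(
                dict(
                    specimen_id=sid,
                    species=s.species,
                    n_alleles="",
                    size_min="",
                    size_max="",
                    avg_size="",
                    pct_q20=round(_q20(trace), 1),
                    post_trim=len(trimmed),
                    coverage="",
                    matched_rank="",
                    top_two_gap="",
                    unmergeable=1,
                )
            )
    report = pd.DataFrame(report_rows)
    report.to_csv(out / "report.tsv", sep="\t", index=False)

    cfg_dict = asdict(config)
    manifest = {
        "tool": "allelecap",
        "version": __version__,
        "seed": config.seed,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "n_specimens": len(specimens),
        "unmergeable": unmergeable,
        "log": log,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return RunResult(out, report, allele_sets, agreement, unmergeable)
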