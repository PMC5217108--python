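"""The synthetic-data generator: determinism and statistical structure."""

import numpy as np
import pytest
from scipy import stats

from allelecap.align import Alignment, p_distance_matrix
from allelecap.dna import IUPAC_SETS, revcomp
from allelecap.sim import (
    IndividualTruth,
    QualityModel,
    make_individual,
    make_panel,
    simulate_reads,
    simulate_sanger,
)


class TestMakePanel:
    def test_deterministic_under_seed(self):
        assert make_panel(2, seed=7) == make_panel(2, seed=7)

    def test_template_lengths_within_amplicon_range(self):
        panel = make_panel(26, length_range=(350, 600), seed=1)
        assert len(panel) == 26
        assert all(350 <= len(t.template_seq) <= 600 for t in panel)

    def test_each_template_embeds_a_microsatellite(self):
        for t in make_panel(5, seed=2):
            (pos, motif, reps) = t.motif_insert_sites[0]
            assert t.template_seq[pos : pos + len(motif) * reps] == motif * reps
            assert 1 <= len(motif) <= 4 and reps >= 5

    def test_congeneric_divergence_near_target(self):
        panel = make_panel(2, genus_structure={"G": 2}, seed=5,
                           congeneric_divergence=0.10)
        a, b = panel
        assert a.genus == b.genus
        # compare over the shared ancestor part (strip each inserted repeat)
        def stripped(t):
            p, m, r = t.motif_insert_sites[0]
            s = t.template_seq
            return s[:p] + s[p + len(m) * r :]
        sa, sb = stripped(a), stripped(b)
        d = np.mean([x != y for x, y in zip(sa, sb)])
        assert 0.07 <= d <= 0.13  # 10% ± 3% (binomial sampling)

    def test_inverted_length_range_rejected(self):
        with pytest.raises(ValueError):
            make_panel(2, length_range=(600, 350))


class TestMakeIndividual:
    def _template(self):
        return make_panel(1, length_range=(380, 420), seed=11)[0]

    def test_single_allele_has_unit_abundance(self):
        truth = make_individual(self._template(), 1, seed=0)
        assert truth.abundances == (1.0,)

    def test_dominance_ratio(self):
        truth = make_individual(self._template(), 3, dominance=20, seed=0)
        assert truth.abundances[0] / truth.abundances[1] == pytest.approx(20.0)
        assert sum(truth.abundances) == pytest.approx(1.0)

    def test_alleles_distinct_and_divergent(self):
        truth = make_individual(self._template(), 4, snp_rate=0.03, seed=3)
        assert len(set(truth.alleles)) == 4

    def test_zero_alleles_rejected(self):
        with pytest.raises(ValueError):
            make_individual(self._template(), 0)

    def test_repeat_expansion_changes_length_by_unit_multiples(self):
        # drive indels off so only SNPs and repeat-count changes occur
        tpl = self._template()
        unit = len(tpl.motif_insert_sites[0][1])
        for seed in range(8):
            truth = make_individual(tpl, 2, indel_rate=0.0, seed=seed)
            delta = abs(len(truth.alleles[1]) - len(truth.alleles[0]))
            assert delta % unit == 0


class TestSimulateReads:
    def _truth(self, n_alleles=1, seed=4):
        tpl = make_panel(1, length_range=(390, 410), seed=21)[0]
        return make_individual(tpl, n_alleles, seed=seed, specimen_id="sx")

    def test_deterministic_under_seed(self):
        t = self._truth()
        r1 = simulate_reads(t, 20, seed=9)
        r2 = simulate_reads(t, 20, seed=9)
        assert [x.sequence for x in r1.forward] == [x.sequence for x in r2.forward]
        assert [x.qualities for x in r1.reverse] == [x.qualities for x in r2.reverse]

    def test_high_quality_reads_nearly_error_free(self):
        t = self._truth()
        model = QualityModel(q_start=40, q_end=40, jitter_sd=0.0)
        rp = simulate_reads(t, 100, error_profile=model, seed=1)
        allele = t.alleles[0]
        total = wrong = 0
        for read in rp.forward:
            total += len(read)
            wrong += sum(a != b for a, b in zip(read.sequence, allele))
        assert wrong / total < 0.01

    def test_overlap_arithmetic(self):
        # a 400 bp allele read as 2x250 leaves a 100 bp overlap
        t = self._truth()
        allele = t.alleles[0]
        rp = simulate_reads(t, 1, read_len=250, seed=2,
                            error_profile=QualityModel(jitter_sd=0.0, q_start=40, q_end=40))
        f, r = rp.forward[0], rp.reverse[0]
        expected_overlap = 2 * 250 - len(allele)
        assert f.sequence == allele[:250]
        assert r.sequence == revcomp(allele[-250:])
        assert expected_overlap == 500 - len(allele)

    def test_read_ids_record_source_allele(self):
        t = self._truth(n_alleles=3, seed=6)
        rp = simulate_reads(t, 50, seed=3)
        for read in rp.forward:
            k = int(read.read_id.rsplit("|a", 1)[1])
            assert 0 <= k < 3

    def test_assignment_frequencies_match_abundances(self):
        # chi-square goodness of fit at n_pairs = 5000 over 3 alleles
        t = self._truth(n_alleles=3, seed=8)
        rp = simulate_reads(t, 5000, seed=10)
        counts = np.zeros(3)
        for read in rp.forward:
            counts[int(read.read_id.rsplit("|a", 1)[1])] += 1
        expected = np.array(t.abundances) * 5000
        _, p = stats.chisquare(counts, expected)
        assert p > 0.01

    def test_short_fragment_yields_full_amplicon_reads(self):
        t = self._truth()
        rp = simulate_reads(t, 5, read_len=1000, seed=4)
        assert rp.truncated_pairs == 5
        assert all(len(f) == len(t.alleles[0]) for f in rp.forward)

    def test_degradation_truncates_five_prime(self):
        t = self._truth()
        rp = simulate_reads(
            t, 200, frag_degradation_rate=0.5, seed=5,
            error_profile=QualityModel(q_start=40, q_end=40, jitter_sd=0.0),
        )
        allele = t.alleles[0]
        shorter = sum(
            1 for f in rp.forward
            if not allele.startswith(f.sequence) and f.sequence in allele
        )
        assert shorter > 50  # roughly half the pairs lost their 5' start


class TestSimulateSanger:
    def _template(self):
        return make_panel(1, length_range=(380, 420), seed=31)[0]

    def test_single_allele_trace_clean(self):
        truth = make_individual(self._template(), 1, seed=1, specimen_id="s")
        trace = simulate_sanger(truth, seed=0)
        assert trace.sequence == truth.alleles[0]
        assert min(trace.qualities) >= 40

    def test_snp_heterozygote_emits_iupac(self):
        base = "ACGTACGTACGTACGTACGT" * 3
        other = base[:30] + "T" + base[31:]
        assert base[30] != "T"
        truth = IndividualTruth("s", "Sp", (base, other), (0.5, 0.5))
        trace = simulate_sanger(truth, seed=0)
        assert len(trace) == len(base)
        amb = [i for i, c in enumerate(trace.sequence) if c not in "ACGT"]
        assert amb == [30]
        assert IUPAC_SETS[trace.sequence[30]] == {base[30], "T"}
        assert all(q >= 40 for i, q in enumerate(trace.qualities) if i != 30)

    def test_indel_collapses_downstream_quality(self, rng):
        base = "".join(rng.choice(list("ACGT"), 400))
        deleted = base[:200] + base[201:]  # 1 bp deletion at position 200
        truth = IndividualTruth("s", "Sp", (base, deleted), (0.5, 0.5))
        trace = simulate_sanger(truth, collapse_quality=10, seed=0)
        quals = trace.qualities
        assert all(q >= 30 for q in quals[:200])
        assert all(q <= 10 for q in quals[201:])

    def test_rare_minor_allele_does_not_disrupt_trace(self, rng):
        base = "".join(rng.choice(list("ACGT"), 300))
        deleted = base[:150] + base[160:]
        truth = IndividualTruth("s", "Sp", (base, deleted), (0.95, 0.05))
        trace = simulate_sanger(truth, seed=0, minor_threshold=0.2)
        assert trace.sequence == base
        assert min(trace.qualities) >= 40
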