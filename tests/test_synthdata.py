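"""Synthetic-data generator: determinism, truth-manifest closure, fixture structure."""

import numpy as np
import pytest
from scipy import stats

from bactarget import synthdata as sd
from bactarget.dna import revcomp, translate


class TestGenome:
    def test_focal_gene_encodes_610_residues(self, genome):
        protein = translate(genome.gene_sequence(genome.focal_gene))
        assert len(protein) == 611 and protein.endswith("*")
        assert "*" not in protein[:-1]
        assert genome.focal_gene.length == 1833

    def test_engineered_codons(self):
        gene = sd.build_focal_gene_sequence(3)
        codons = {i: gene[(i - 1) * 3 : i * 3] for i in (104, 177, 377, 387, 395, 425, 428)}
        assert codons == {
            104: "CGA", 177: "TTC", 377: "GCG", 387: "TCT",
            395: "TGG", 425: "ATG", 428: "CAT",
        }

    def test_deterministic_per_seed(self):
        a = sd.build_genome(seed=5)
        b = sd.build_genome(seed=5)
        c = sd.build_genome(seed=6)
        assert a.contigs == b.contigs and a.genes == b.genes
        assert a.contigs != c.contigs

    def test_gene_invariants(self, genome):
        for g in genome.genes:
            assert 1 <= g.start <= g.end <= len(genome.contigs[g.contig])
            assert g.length % 3 == 0

    def test_repeat_copies_at_least_95pct_identical(self, genome):
        assert genome.repeats
        for r in genome.repeats:
            copy = genome.contigs[r.contig][r.start - 1 : r.end]
            src = genome.contigs[r.source_contig][
                r.source_start - 1 : r.source_start + len(copy) - 1
            ]
            identity = sum(a == b for a, b in zip(copy, src)) / len(copy)
            assert identity >= 0.95

    def test_single_contig_without_repeats(self):
        g = sd.build_genome(n_contigs=1, total_length=12_000, gene_density=0.3,
                            repeat_spec=None, seed=0)
        assert list(g.contigs) == ["contig_1"]
        assert g.repeats == []

    def test_infeasible_gene_density_reports_values(self):
        with pytest.raises(ValueError, match="density"):
            sd.build_genome(total_length=10_000, gene_density=20, seed=0)

    def test_too_small_genome_rejected(self):
        with pytest.raises(ValueError, match="10 kb"):
            sd.build_genome(total_length=5_000)


class TestInjectMutations:
    def test_nonsense_at_codon_104_truncates_to_103(self, genome):
        focal = genome.focal_gene
        spec = sd.MutationSpec(focal.contig, focal.start + 309, "C", "T", ("JK3",))
        strains = sd.inject_mutations(genome, [spec])
        gene_seq = strains["JK3"][focal.contig][focal.start - 1 : focal.end]
        assert len(translate(gene_seq, to_stop=True)) == 103

    def test_insertion_at_codon_177_shifts_frame(self, genome):
        focal = genome.focal_gene
        spec = sd.MutationSpec(focal.contig, focal.start + 528, "T", "TT", ("JK4",))
        strains = sd.inject_mutations(genome, [spec])
        mutant = strains["JK4"][focal.contig]
        assert len(mutant) == len(genome.contigs[focal.contig]) + 1
        # frame intact up to codon 176, shifted (+1) beyond the insertion run
        assert mutant[: focal.start + 527] == genome.contigs[focal.contig][: focal.start + 527]
        assert len(translate(mutant[focal.start - 1 :], to_stop=True)) == 190

    def test_empty_specs_leave_wildtype(self, genome):
        strains = sd.inject_mutations(genome, [])
        assert strains[sd.WILD_TYPE] == genome.contigs

    def test_ref_mismatch_aborts_with_position(self, genome):
        focal = genome.focal_gene
        bad_ref = "A" if genome.contigs[focal.contig][focal.start + 9] != "A" else "C"
        spec = sd.MutationSpec(focal.contig, focal.start + 10, bad_ref, "G", ("JK1",))
        with pytest.raises(ValueError, match=str(focal.start + 10)):
            sd.inject_mutations(genome, [spec])

    def test_truth_manifest_closure(self, genome):
        """Every strain genome equals the wild type with exactly its manifest
        entries applied — no more, no fewer."""
        specs = sd.study_mutation_specs(genome, seed=2)
        strains = sd.inject_mutations(genome, specs)
        for strain, contigs in strains.items():
            if strain == sd.WILD_TYPE:
                continue
            for name, wt in genome.contigs.items():
                expected = wt
                mine = sorted(
                    (s for s in specs if strain in s.strains and s.contig == name),
                    key=lambda s: -s.position,
                )
                for s in mine:
                    p = s.position
                    if s.kind == "deletion":
                        expected = expected[: p - 1] + expected[p:]
                    else:
                        expected = expected[: p - 1] + s.alt + expected[p:]
                assert contigs[name] == expected


class TestSimulateReads:
    def test_error_free_reads_are_exact_substrings(self):
        g = sd.build_genome(n_contigs=1, total_length=10_000, gene_density=0.2,
                            repeat_spec=None, seed=1)
        params = sd.ReadSimParams(mean_coverage=5, error_rate=0.0, seed=4)
        reads = sd.simulate_reads(g.contigs, params)
        seq = g.contigs["contig_1"]
        rc = revcomp(seq)
        for r in reads[:500]:
            assert r.sequence in seq or r.sequence in rc

    def test_realized_coverage_within_10pct(self):
        g = sd.build_genome(seed=2)
        params = sd.ReadSimParams(mean_coverage=50, seed=9)
        reads = sd.simulate_reads(g.contigs, params)
        total = sum(len(r.sequence) for r in reads)
        coverage = total / g.total_length
        assert abs(coverage - 50) / 50 < 0.10

    def test_seed_changes_reads_not_coverage(self):
        g = {"c": sd.build_genome(seed=3).contigs["contig_1"]}
        a = sd.simulate_reads(g, sd.ReadSimParams(mean_coverage=20, seed=1))
        b = sd.simulate_reads(g, sd.ReadSimParams(mean_coverage=20, seed=2))
        assert [r.sequence for r in a] != [r.sequence for r in b]
        assert len(a) == len(b)

    def test_deterministic_per_seed(self):
        g = {"c": sd.build_genome(seed=3).contigs["contig_1"]}
        a = sd.simulate_reads(g, sd.ReadSimParams(seed=7))
        b = sd.simulate_reads(g, sd.ReadSimParams(seed=7))
        assert [(r.id, r.sequence) for r in a] == [(r.id, r.sequence) for r in b]

    def test_strand_counts_within_binomial_bounds(self):
        """At deep sites, forward/reverse sampling is binomial(0.5): the 99%
        two-sided bound should hold at ~99% of positions."""
        L = 20_000
        rng = np.random.default_rng(0)
        g = {"c": "".join("ACGT"[b] for b in rng.integers(0, 4, size=L))}
        reads = sd.simulate_reads(g, sd.ReadSimParams(mean_coverage=40, error_rate=0, seed=3))
        fwd = np.zeros(L + 1)
        tot = np.zeros(L + 1)
        for r in reads:
            tot[r.start - 1] += 1
            tot[r.start + len(r.sequence) - 1] -= 1
            if r.strand == "+":
                fwd[r.start - 1] += 1
                fwd[r.start + len(r.sequence) - 1] -= 1
        fwd, tot = np.cumsum(fwd)[:-1], np.cumsum(tot)[:-1]
        inner = slice(600, L - 600)
        n, k = tot[inner], fwd[inner]
        lo = stats.binom.ppf(0.005, n, 0.5)
        hi = stats.binom.ppf(0.995, n, 0.5)
        frac_outside = np.mean((k < lo) | (k > hi))
        assert frac_outside < 0.05

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            sd.ReadSimParams(error_rate=0.1)
        with pytest.raises(ValueError):
            sd.ReadSimParams(read_length=0)


class TestCrudeAssembly:
    def test_zero_fraction_gives_identical_contigs(self, genome):
        params = sd.AssemblyEmulationParams(
            low_coverage_fraction=0.0, consensus_error_rate_in_low_coverage=0.0, seed=1
        )
        crude = sd.emulate_crude_assembly(genome, params)
        assert crude.contigs == genome.contigs
        assert crude.consensus_errors == []

    def test_errors_only_in_low_coverage_or_repeats(self, genome):
        crude = sd.emulate_crude_assembly(genome, sd.AssemblyEmulationParams(seed=2))
        assert crude.consensus_errors
        for contig, pos, truth, new in crude.consensus_errors:
            assert genome.contigs[contig][pos - 1] == truth
            assert crude.contigs[contig][pos - 1] == new
            in_low = crude.coverage[contig][pos - 1] <= 5
            in_repeat = any(
                s <= pos <= e for s, e in genome.repeat_intervals(contig)
            )
            assert in_low or in_repeat

    def test_wildtype_vs_crude_differs_exactly_at_errors(self, genome):
        crude = sd.emulate_crude_assembly(genome, sd.AssemblyEmulationParams(seed=2))
        observed = set()
        for name in genome.contigs:
            wt, cr = genome.contigs[name], crude.contigs[name]
            observed.update((name, i + 1) for i in range(len(wt)) if wt[i] != cr[i])
        assert observed == {(c, p) for c, p, _, _ in crude.consensus_errors}


class TestDifferenceFixture:
    def test_structure_58_11_11_36(self, fixture_records):
        assert len(fixture_records) == 58
        wt = [r for r in fixture_records if r.presence[sd.WILD_TYPE]]
        assert len(wt) == 11
        assert all(r.assembly_coverage <= 5 for r in wt)
        lowcov = [
            r for r in fixture_records
            if not r.presence[sd.WILD_TYPE] and r.assembly_coverage is not None
            and r.assembly_coverage <= 5 and len(r.strains_present) >= 2
        ]
        assert len(lowcov) == 11

    def test_seven_distinct_focal_gene_sites(self, fixture_records):
        gene = sd.fixture_gene_models()[0]
        sites = {
            r.position
            for r in fixture_records
            if r.contig == gene.contig and gene.start <= r.position <= gene.end
        }
        assert sites == {2518, 2739, 3337, 3367, 3393, 3482, 3491}

    def test_retained_rows_carry_printed_values(self, fixture_records):
        by_pos = {(r.contig, r.position): r for r in fixture_records}
        rec = by_pos[("Contig 10", 2518)]
        assert rec.assembly_coverage == 44
        assert rec.strains_present == ("JK3",)
        assert "104R-stop" in rec.annotation
        rec = by_pos[("Contig 10", 2739)]
        assert rec.assembly_coverage == 30
        assert rec.strains_present == ("JK4", "JK5", "JK6")
        assert rec.kind == "insertion"
        rec = by_pos[("Contig 3", 15305)]
        assert rec.assembly_coverage == 5 and rec.strains_present == ("JK8",)

    def test_fixture_contig_matches_record_alleles(self, fixture_records):
        contig = sd.fixture_contigs()["Contig 10"]
        for r in fixture_records:
            if r.contig != "Contig 10" or not (2209 <= r.position <= 4041):
                continue
            if r.kind == "substitution":
                assert contig[r.position - 1] == r.ref

    def test_deterministic(self):
        a = sd.make_difference_fixture()
        b = sd.make_difference_fixture()
        assert [(r.key, r.depth, r.alt_fwd) for r in a] == [
            (r.key, r.depth, r.alt_fwd) for r in b
        ]


class TestDoseResponse:
    def test_noise_free_recovers_true_mic(self):
        from bactarget import micassay

        series = sd.make_dose_response(0.5, noise_sd=0.0, seed=0)
        res = micassay.mic(series)
        assert res.censored is None
        assert abs(np.log2(res.mic / 0.5)) <= 0.5

    def test_mic_above_top_means_full_growth(self):
        from bactarget import micassay

        series = sd.make_dose_response(100.0, top_concentration=10.0, dilution_steps=8,
                                       noise_sd=0.0, seed=0)
        inh = micassay.inhibition_fractions(series)
        assert np.all(inh < 0.5)
        assert micassay.mic(series).censored == "above_top"

    def test_deterministic_per_seed(self):
        a = sd.make_dose_response(0.5, noise_sd=0.02, seed=3)
        b = sd.make_dose_response(0.5, noise_sd=0.02, seed=3)
        assert np.array_equal(a.od, b.od)
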