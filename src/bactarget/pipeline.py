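"""End-to-end orchestration of the simulated resequencing study.

``run_simulated_study`` generates a truth genome and mutant panel,
emulates the crude wild-type assembly, simulates reads for the wild
type and every mutant, maps and calls each strain against the draft
contigs, merges, filters, annotates consequences, localizes them on the
transporter topology, computes the MIC fold-resistance table, and
scores recovery against the injected truth.  ``replay_fixture`` runs
only the filtering/annotation/ranking stages on a prebuilt difference
report (by default the packaged 58-record study fixture).

Every stage derives its random stream from the single run seed, so a
seed fully determines all outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from bactarget import consequence, filtering, formats, mapping, micassay, synthdata, varcall
from bactarget.filtering import FilterPolicy
from bactarget.synthdata import (
    ALL_STRAINS,
    WILD_TYPE,
    AssemblyEmulationParams,
    ReadSimParams,
    RepeatSpec,
)
from bactarget.topology import TopologyModel, localize

logger = logging.getLogger(__name__)

# Fold-resistance scenario (per-strain MIC fold increase over wild type)
DEFAULT_FOLD_SCENARIO: dict[str, float] = {
    "JK1": 100, "JK2": 300, "JK3": 300, "JK4": 600, "JK5": 600, "JK6": 600,
    "JK8": 300, "JK9": 300, "JK10": 100, "JK11": 400,
}
DEFAULT_WILDTYPE_MIC = 0.5  # nmol/L


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str | None = None
    # genome
    n_contigs: int = 5
    total_length: int = 50_000
    gene_density: float = 0.5
    repeat_spec: RepeatSpec = field(default_factory=RepeatSpec)
    # reads / assembly emulation
    read_params: ReadSimParams = field(default_factory=ReadSimParams)
    assembly_params: AssemblyEmulationParams = field(default_factory=AssemblyEmulationParams)
    n_background_mutations: int = 18
    # calling / filtering
    min_alt_fraction: float = varcall.DEFAULT_MIN_ALT_FRACTION
    min_depth: int = varcall.DEFAULT_MIN_DEPTH
    policy: FilterPolicy = field(default_factory=FilterPolicy)
    # MIC scenario
    wildtype_mic: float = DEFAULT_WILDTYPE_MIC
    fold_scenario: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_FOLD_SCENARIO))
    mic_noise_sd: float = 0.02
    mic_replicates: int = 3
    # stage toggles
    run_mic: bool = True
    write_reads: bool = False

    @classmethod
    def desk(cls, seed: int = 0, **kw) -> "RunConfig":
        return cls(seed=seed, **kw)

    @classmethod
    def large(cls, seed: int = 0, **kw) -> "RunConfig":
        """The study-scale profile (1.59 Mb, 243 contigs); hours of CPU, not the test default."""
        kw.setdefault("n_contigs", 243)
        kw.setdefault("total_length", 1_590_000)
        return cls(seed=seed, **kw)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fold_scenario"] = dict(self.fold_scenario)
        return d

    def science_dict(self) -> dict:
        """Parameters that determine the results (output paths excluded)."""
        d = self.as_dict()
        d.pop("out_dir", None)
        return d


@dataclass
class Scorecard:
    n_truth: int
    n_retained: int
    n_true_retained: int
    sensitivity: float
    precision: float
    missed: list[tuple] = field(default_factory=list)
    spurious: list[tuple] = field(default_factory=list)


@dataclass
class StudyResult:
    config: RunConfig
    genome: synthdata.GenomeModel
    crude: synthdata.CrudeAssembly
    truth_specs: list[synthdata.MutationSpec]
    merged_records: list[varcall.DifferenceRecord]
    filter_result: filtering.FilterResult
    consequences: list[consequence.ConsequenceCall]
    localizations: dict[int, str]  # focal-gene record position -> descriptor
    ranking: pd.DataFrame
    scorecard: Scorecard
    mic_table: pd.DataFrame | None
    config_hash: str
    timings: dict[str, float] = field(default_factory=dict)


def _seed_ints(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def score_recovery(
    truth_specs: list[synthdata.MutationSpec],
    retained: list[varcall.DifferenceRecord],
) -> Scorecard:
    truth = {s.key for s in truth_specs}
    found = {r.key for r in retained}
    true_retained = truth & found
    return Scorecard(
        n_truth=len(truth),
        n_retained=len(found),
        n_true_retained=len(true_retained),
        sensitivity=len(true_retained) / len(truth) if truth else 1.0,
        precision=len(true_retained) / len(found) if found else 1.0,
        missed=sorted(truth - found),
        spurious=sorted(found - truth),
    )


def mic_fold_table(
    fold_scenario: Mapping[str, float],
    wildtype_mic: float,
    noise_sd: float,
    replicates: int,
    seed: int,
) -> pd.DataFrame:
    """Simulate dilution plates for the wild type and each mutant and recover folds."""
    seeds = iter(_seed_ints(seed, (len(fold_scenario) + 1) * replicates))
    top = wildtype_mic * max(fold_scenario.values()) * 8
    steps = int(np.ceil(np.log2(top / (wildtype_mic / 8)))) + 1

    def plate(true_mic: float) -> micassay.MicResult:
        series = synthdata.make_dose_response(
            true_mic, dilution_steps=steps, top_concentration=top,
            noise_sd=noise_sd, seed=next(seeds),
        )
        return micassay.mic(series)

    wt_reps = [plate(wildtype_mic) for _ in range(replicates)]
    rows = [{
        "strain": WILD_TYPE, "true_mic": wildtype_mic,
        "mic": np.median([r.mic for r in wt_reps]), "fold_increase": "1",
    }]
    for strain, fold in fold_scenario.items():
        true_mic = wildtype_mic * fold
        reps = [plate(true_mic) for _ in range(replicates)]
        fi = micassay.fold_increase(
            reps[0], wt_reps[0], replicates=list(zip(reps, wt_reps))
        )
        rows.append({
            "strain": strain, "true_mic": true_mic,
            "mic": np.median([r.mic for r in reps if r.mic is not None]),
            "fold_increase": fi.text,
        })
    return pd.DataFrame(rows)


def run_simulated_study(config: RunConfig) -> StudyResult:
    """Execute the full simulated study; see module docstring for the stage list."""
    timings: dict[str, float] = {}
    seeds = _seed_ints(config.seed, 16 + len(ALL_STRAINS))

    def _stage(name):
        timings[name] = time.perf_counter()
        logger.info("stage %s", name)

    def _done(name):
        timings[name] = time.perf_counter() - timings[name]
        logger.info("stage %s done in %.1fs", name, timings[name])

    try:
        _stage("genome")
        genome = synthdata.build_genome(
            n_contigs=config.n_contigs,
            total_length=config.total_length,
            gene_density=config.gene_density,
            repeat_spec=config.repeat_spec,
            seed=seeds[0],
        )
        _done("genome")

        _stage("assembly")
        crude = synthdata.emulate_crude_assembly(
            genome,
            dataclasses.replace(config.assembly_params, seed=seeds[1]),
        )
        _done("assembly")

        _stage("mutants")
        truth_specs = synthdata.study_mutation_specs(
            genome,
            seed=seeds[2],
            n_background=config.n_background_mutations,
            avoid=crude.low_coverage_intervals,
        )
        strain_genomes = synthdata.inject_mutations(genome, truth_specs)
        _done("mutants")

        _stage("map_call")
        index = mapping.build_index(crude.contigs)
        per_strain: dict[str, list[varcall.DifferenceRecord]] = {}
        for i, strain in enumerate(ALL_STRAINS):
            params = dataclasses.replace(config.read_params, seed=seeds[16 + i])
            reads = synthdata.simulate_reads(strain_genomes[strain], params, strain=strain)
            alignments = mapping.map_reads(reads, index, crude.contigs)
            pileup = mapping.build_pileup(alignments, crude.contigs, unique_only=True)
            per_strain[strain] = varcall.call_differences(
                pileup,
                min_alt_fraction=config.min_alt_fraction,
                min_depth=config.min_depth,
                strain=strain,
            )
        merged = varcall.merge_strains(per_strain, strains=ALL_STRAINS)
        _done("map_call")

        _stage("filter")
        filt = filtering.apply_filters(merged, crude.coverage, config.policy)
        ranking = filtering.rank_candidate_genes(filt.retained, genome.genes)
        scorecard = score_recovery(truth_specs, filt.retained)
        _done("filter")

        _stage("annotate")
        calls = [
            consequence.classify(rec, genome.genes, crude.contigs)
            for rec in filt.retained
        ]
        topo = TopologyModel(helices=list(synthdata.DESIGNED_HELICES))
        focal = genome.focal_gene
        localizations = {}
        for rec, call in zip(filt.retained, calls):
            if call.gene == focal.name:
                localizations[rec.position] = localize(call, topo).descriptor
        _done("annotate")

        mic_table = None
        if config.run_mic:
            _stage("mic")
            mic_table = mic_fold_table(
                config.fold_scenario, config.wildtype_mic,
                config.mic_noise_sd, config.mic_replicates, seeds[3],
            )
            _done("mic")
    except Exception as exc:
        failed = [k for k, v in timings.items() if v > 1e6]
        stage = failed[-1] if failed else "unknown"
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    result = StudyResult(
        config=config,
        genome=genome,
        crude=crude,
        truth_specs=truth_specs,
        merged_records=merged,
        filter_result=filt,
        consequences=calls,
        localizations=localizations,
        ranking=ranking,
        scorecard=scorecard,
        mic_table=mic_table,
        config_hash=formats.config_hash(config.science_dict()),
        timings=timings,
    )
    if config.out_dir:
        write_report_bundle(result, Path(config.out_dir))
    return result


def write_report_bundle(result: StudyResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    formats.write_fasta(out_dir / "truth_genome.fasta", result.genome.contigs)
    formats.write_fasta(out_dir / "crude_assembly.fasta", result.crude.contigs)
    formats.write_gff3(out_dir / "genes.gff3", result.genome.genes)
    formats.write_truth_manifest(out_dir / "truth_manifest.tsv", result.truth_specs)
    formats.write_difference_report(out_dir / "differences_all.tsv", result.merged_records)
    formats.write_difference_report(out_dir / "retained.tsv", result.filter_result.retained)
    excl = formats.records_to_frame([r for r, _ in result.filter_result.excluded])
    excl["exclusion_reason"] = [reason for _, reason in result.filter_result.excluded]
    excl.to_csv(out_dir / "exclusions.tsv", sep="\t", index=False)
    result.ranking.to_csv(out_dir / "gene_ranking.tsv", sep="\t", index=False)
    ann = pd.DataFrame(
        [{
            "contig": c.contig, "position": c.position, "gene": c.gene or "",
            "codon": c.codon_index or "", "class": c.kind,
            "truncation_after": c.truncation_after or "",
            "localization": result.localizations.get(c.position, ""),
            "annotation": c.annotation,
        } for c in result.consequences]
    )
    ann.to_csv(out_dir / "consequences.tsv", sep="\t", index=False)
    if result.mic_table is not None:
        result.mic_table.to_csv(out_dir / "mic_table.tsv", sep="\t", index=False)
    sc = result.scorecard
    meta = {
        "seed": result.config.seed,
        "config_hash": result.config_hash,
        "sensitivity": sc.sensitivity,
        "precision": sc.precision,
        "n_truth": sc.n_truth,
        "n_retained": sc.n_retained,
        "exclusion_counts": result.filter_result.counts,
    }
    formats.dump_yaml(out_dir / "run_meta.yaml", meta)


@dataclass
class ReplayResult:
    filter_result: filtering.FilterResult
    ranking: pd.DataFrame
    consequences: list[consequence.ConsequenceCall]


def replay_fixture(
    records: list[varcall.DifferenceRecord] | None = None,
    genes: list[synthdata.GeneModel] | None = None,
    contigs: Mapping[str, str] | None = None,
    policy: FilterPolicy = FilterPolicy(),
) -> ReplayResult:
    """Filtering + consequence + ranking on a difference report alone.

    Defaults to the packaged 58-record study fixture with its focal gene
    model and synthetic focal contig; annotations for records inside
    supplied gene models are regenerated from sequence, not copied from
    the report.
    """
    if records is None:
        records = synthdata.make_difference_fixture()
    if genes is None:
        genes = synthdata.fixture_gene_models()
    if contigs is None:
        contigs = synthdata.fixture_contigs()
    filt = filtering.apply_filters(records, coverage_track=None, policy=policy)
    ranking = filtering.rank_candidate_genes(filt.retained, genes)
    calls = []
    for rec in filt.retained:
        if rec.contig in contigs:
            calls.append(consequence.classify(rec, genes, contigs))
    return ReplayResult(filter_result=filt, ranking=ranking, consequences=calls)
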