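"""Synthetic study generator: truth genome, mutant strains, reads, crude assembly, fixtures.

Everything the discovery pipeline consumes can be generated here with a
known ground truth: a small multi-contig genome carrying a designated
focal gene (a 610-residue APC-superfamily transporter analogue), mutant
strain genomes with engineered point mutations and 1-bp indels, paired
250-nt read sets, a "crude assembly" of the wild-type genome with
consensus errors confined to low-coverage and repeat-derived regions,
the 58-record difference-report fixture that mirrors the study's
accounting (11 wild-type-shared + 11 low-coverage exclusions + 36
retained), and two-fold dilution dose-response plates for MIC recovery.

Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from bactarget.dna import STOP_CODONS, revcomp, translate
from bactarget.micassay import DilutionSeries

# ---------------------------------------------------------------------------
# Strain panel: one sensitive wild type and ten independently selected
# resistant isolates (JK7 was never obtained in the selection).
WILD_TYPE = "VT1"
MUTANT_STRAINS = ("JK1", "JK2", "JK3", "JK4", "JK5", "JK6", "JK8", "JK9", "JK10", "JK11")
ALL_STRAINS = (WILD_TYPE,) + MUTANT_STRAINS

FOCAL_GENE_NAME = "APC family amino acid-polyamine-organocation transporter"
FOCAL_GENE_LENGTH = 1833  # nt including the stop codon -> 610-aa product
FOCAL_PROTEIN_LENGTH = 610


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class GeneModel:
    contig: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # '+' or '-'
    name: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.name}: start {self.start} > end {self.end}")
        if (self.end - self.start + 1) % 3 != 0:
            raise ValueError(
                f"gene {self.name}: length {self.end - self.start + 1} not a multiple of 3"
            )
        if self.strand not in "+-":
            raise ValueError(f"gene {self.name}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class RepeatRegion:
    contig: str
    start: int
    end: int
    source_contig: str
    source_start: int


@dataclass
class GenomeModel:
    contigs: dict[str, str]
    genes: list[GeneModel]
    repeats: list[RepeatRegion]
    seed: int

    @property
    def focal_gene(self) -> GeneModel:
        for g in self.genes:
            if g.name == FOCAL_GENE_NAME:
                return g
        raise ValueError("genome has no focal gene")

    def gene_sequence(self, gene: GeneModel) -> str:
        s = self.contigs[gene.contig][gene.start - 1 : gene.end]
        return s if gene.strand == "+" else revcomp(s)

    def repeat_intervals(self, contig: str) -> list[tuple[int, int]]:
        out = []
        for r in self.repeats:
            if r.contig == contig:
                out.append((r.start, r.end))
            if r.source_contig == contig:
                out.append((r.source_start, r.source_start + (r.end - r.start)))
        return out

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


@dataclass(frozen=True)
class MutationSpec:
    """One engineered difference from the wild-type genome.

    Representation (shared with the variant caller):
      substitution  ref and alt are single differing bases at ``position``;
      insertion     ref is the base at ``position`` (first base of the
                    homopolymer run when the inserted base extends one),
                    alt = ref + inserted base;
      deletion      ref is the deleted base at ``position`` (run start),
                    alt is the empty string.
    """

    contig: str
    position: int
    ref: str
    alt: str
    strains: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if abs(len(self.ref) - len(self.alt)) > 1:
            raise ValueError("only substitutions and 1-bp indels are supported")

    @property
    def kind(self) -> str:
        if len(self.ref) == len(self.alt):
            return "substitution"
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.position, self.ref, self.alt)


@dataclass(frozen=True)
class ReadSimParams:
    read_length: int = 250
    mean_coverage: float = 50.0
    error_rate: float = 0.005
    insert_mean: float = 550.0
    insert_sd: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length <= 0:
            raise ValueError(f"read_length must be positive, got {self.read_length}")
        if not 0 <= self.error_rate < 0.05:
            raise ValueError(f"error_rate must be in [0, 0.05), got {self.error_rate}")
        if self.mean_coverage <= 0:
            raise ValueError(f"mean_coverage must be positive, got {self.mean_coverage}")


@dataclass(frozen=True)
class AssemblyEmulationParams:
    low_coverage_fraction: float = 0.03
    consensus_error_rate_in_low_coverage: float = 0.01
    mean_coverage: float = 50.0
    seed: int = 0


@dataclass(frozen=True)
class RepeatSpec:
    n_repeats: int = 2
    length: int = 800
    identity: float = 0.97

    def __post_init__(self) -> None:
        if not 0.95 <= self.identity <= 1.0:
            raise ValueError(f"repeat identity must be >= 0.95, got {self.identity}")


@dataclass(frozen=True)
class SimRead:
    id: str
    sequence: str
    # truth fields, for debugging/oracles only
    contig: str
    start: int  # 1-based position of the first template base on the forward strand
    strand: str


@dataclass
class CrudeAssembly:
    """Emulated draft assembly: contigs with consensus errors plus its coverage track."""

    contigs: dict[str, str]
    coverage: dict[str, np.ndarray]  # per-position assembly coverage, index = position-1
    consensus_errors: list[tuple[str, int, str, str]]  # (contig, pos, truth base, assembly base)
    low_coverage_intervals: dict[str, list[tuple[int, int]]]


# ---------------------------------------------------------------------------
# Focal gene engineering
#
# The focal gene is built codon by codon so that the study's mutation
# archetypes hold exactly on the synthetic sequence: codon 104 is CGA
# (one substitution away from the TGA stop), codon 177 is TTC (a 1-bp T
# insertion yields TTTC and shifts the frame), codon 395 is TGG (TGA one
# substitution away), and codons 377/387/425/428 carry the reference
# codons of the four missense sites.  Codons 190/191 are fixed so that
# the +1 frame entered at codon 177 reads through to its first stop
# immediately after residue 190.  All remaining codons end in C or G,
# which keeps both the coding frame and the +1 frame between codons 177
# and 190 free of stop codons.

_ENGINEERED_CODONS: dict[int, str] = {
    1: "ATG",
    104: "CGA",
    177: "TTC",
    190: "GCT",  # third base T, pairs with codon 191 to form TAA in the +1 frame
    191: "AAA",
    377: "GCG",
    387: "TCT",
    395: "TGG",
    425: "ATG",
    428: "CAT",
    611: "TAA",
}

_SAFE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "CG"
    if a + b + c not in STOP_CODONS
)

# 1-based offsets of the seven study mutations relative to the focal gene
# start, with their ref/alt alleles in caller representation, and the
# strains carrying each of them.
FOCAL_MUTATIONS: tuple[tuple[int, str, str, tuple[str, ...]], ...] = (
    (310, "C", "T", ("JK3",)),  # codon 104 CGA->TGA, nonsense
    (529, "T", "TT", ("JK4", "JK5", "JK6")),  # codon 177 TTC->TTTC, frameshift
    (1129, "G", "A", ("JK2",)),  # codon 377 GCG->ACG, A377T
    (1159, "T", "C", ("JK1",)),  # codon 387 TCT->CCT, S387P
    (1185, "G", "A", ("JK10",)),  # codon 395 TGG->TGA, nonsense
    (1274, "T", "A", ("JK11",)),  # codon 425 ATG->AAG, M425K
    (1283, "A", "G", ("JK8", "JK9")),  # codon 428 CAT->CGT, H428R
)


def build_focal_gene_sequence(seed: int = 0) -> str:
    """The 1,833-nt focal gene (610-aa product) with engineered mutation sites."""
    rng = np.random.default_rng(seed)
    n_codons = FOCAL_GENE_LENGTH // 3
    picks = rng.integers(0, len(_SAFE_CODONS), size=n_codons)
    codons = [_SAFE_CODONS[i] for i in picks]
    for idx, codon in _ENGINEERED_CODONS.items():
        codons[idx - 1] = codon
    return "".join(codons)


def _random_gene_sequence(rng: np.random.Generator, length: int) -> str:
    """A stop-free ORF of the requested length (multiple of 3, incl. stop codon)."""
    n_codons = length // 3
    picks = rng.integers(0, len(_SAFE_CODONS), size=n_codons - 2)
    body = "".join(_SAFE_CODONS[i] for i in picks)
    return "ATG" + body + "TAA"


# ---------------------------------------------------------------------------
# Genome construction


def build_genome(
    n_contigs: int = 5,
    total_length: int = 50_000,
    gene_density: float = 0.5,
    repeat_spec: RepeatSpec | None = RepeatSpec(),
    seed: int = 0,
) -> GenomeModel:
    """Build a deterministic truth genome hosting the focal-gene scenario.

    ``gene_density`` is in genes per kb (the focal gene counts toward it).
    The focal gene is placed on the middle contig at position 2209 when
    the contig allows it, so that its printed-style coordinates
    (2209-4041) mirror the draft-assembly coordinates of the study.
    """
    if total_length < 10_000:
        raise ValueError(f"total_length must be >= 10 kb, got {total_length}")
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    rng = np.random.default_rng(seed)

    base_len = total_length // n_contigs
    lengths = [base_len] * n_contigs
    lengths[-1] += total_length - base_len * n_contigs
    names = [f"contig_{i + 1}" for i in range(n_contigs)]

    n_genes = max(1, round(gene_density * total_length / 1000))
    mean_gene_len = 900
    if n_genes * mean_gene_len > 0.6 * total_length:
        raise ValueError(
            f"gene density {gene_density}/kb infeasible: ~{n_genes * mean_gene_len} nt of genes "
            f"requested in a {total_length} nt genome"
        )

    contigs = {
        name: "".join("ACGT"[b] for b in rng.integers(0, 4, size=L))
        for name, L in zip(names, lengths)
    }
    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name in names}
    genes: list[GeneModel] = []

    def _place(contig: str, start: int, seq: str, strand: str, name: str) -> None:
        end = start + len(seq) - 1
        inserted = seq if strand == "+" else revcomp(seq)
        s = contigs[contig]
        s = s[: start - 1] + inserted + s[end:]
        # in-frame stop just upstream of the start codon, so the gene is a maximal ORF
        if strand == "+" and start >= 4:
            s = s[: start - 4] + "TAA" + s[start - 1 :]
        elif strand == "-" and end + 3 <= len(s):
            s = s[:end] + "TTA" + s[end + 3 :]
        contigs[contig] = s
        occupied[contig].append((max(1, start - 33), min(len(s), end + 33)))
        genes.append(GeneModel(contig, start, end, strand, name))

    # focal gene on the middle contig at the printed-style position
    focal_contig = names[min(len(names) - 1, n_contigs // 2)]
    focal_start = 2209 if lengths[0] >= 2209 + FOCAL_GENE_LENGTH + 100 else 101
    _place(focal_contig, focal_start, build_focal_gene_sequence(seed), "+", FOCAL_GENE_NAME)

    def _free_slot(length: int) -> tuple[str, int] | None:
        for _ in range(200):
            contig = names[int(rng.integers(0, n_contigs))]
            L = len(contigs[contig])
            if L < length + 2:
                continue
            start = int(rng.integers(1, L - length))
            end = start + length - 1
            if all(e < start or s > end for s, e in occupied[contig]):
                return contig, start
        return None

    for i in range(n_genes - 1):
        length = int(rng.integers(100, 501)) * 3  # 300-1503 nt
        slot = _free_slot(length)
        if slot is None:
            raise ValueError(
                f"could not place gene {i + 1}/{n_genes} of {length} nt; "
                f"gene density {gene_density}/kb is too high for {total_length} nt"
            )
        contig, start = slot
        strand = "+" if rng.random() < 0.5 else "-"
        _place(contig, start, _random_gene_sequence(rng, length), strand, f"gene_{i + 1:03d}")

    repeats: list[RepeatRegion] = []
    if repeat_spec is not None and repeat_spec.n_repeats > 0:
        for j in range(repeat_spec.n_repeats):
            src = _free_slot(repeat_spec.length)
            if src is None:
                break
            src_contig, src_start = src
            occupied[src_contig].append((src_start, src_start + repeat_spec.length - 1))
            dst = _free_slot(repeat_spec.length)
            if dst is None:
                break
            dst_contig, dst_start = dst
            occupied[dst_contig].append((dst_start, dst_start + repeat_spec.length - 1))
            unit = contigs[src_contig][src_start - 1 : src_start + repeat_spec.length - 1]
            copy = list(unit)
            n_div = rng.binomial(repeat_spec.length, 1.0 - repeat_spec.identity)
            div_pos = rng.choice(repeat_spec.length, size=n_div, replace=False)
            for p in div_pos:
                copy[p] = "ACGT"[(("ACGT".index(copy[p])) + int(rng.integers(1, 4))) % 4]
            s = contigs[dst_contig]
            contigs[dst_contig] = (
                s[: dst_start - 1] + "".join(copy) + s[dst_start + repeat_spec.length - 1 :]
            )
            repeats.append(
                RepeatRegion(
                    dst_contig,
                    dst_start,
                    dst_start + repeat_spec.length - 1,
                    src_contig,
                    src_start,
                )
            )

    genome = GenomeModel(contigs=contigs, genes=sorted(genes, key=lambda g: (g.contig, g.start)),
                         repeats=repeats, seed=seed)
    _validate_genome(genome)
    return genome


def _validate_genome(genome: GenomeModel) -> None:
    for g in genome.genes:
        if g.end > len(genome.contigs[g.contig]):
            raise ValueError(f"gene {g.name} extends past contig {g.contig}")
        protein = translate(genome.gene_sequence(g))
        if "*" in protein[:-1]:
            raise ValueError(f"gene {g.name} has an internal stop codon")


# ---------------------------------------------------------------------------
# Mutant strain construction


def study_mutation_specs(
    genome: GenomeModel,
    seed: int = 0,
    n_background: int = 18,
    avoid: Mapping[str, Sequence[tuple[int, int]]] | None = None,
) -> list[MutationSpec]:
    """The canonical mutation panel: seven focal-gene mutations plus background noise.

    The seven focal mutations reproduce the study's strain assignment
    (JK4/5/6 and JK8/9 behave as clonal groups).  Background mutations
    are substitutions scattered over well-assembled unique regions
    (``avoid`` intervals, typically repeats plus low-coverage assembly
    patches, are excluded: the discovery method is blind there by
    design and the study's causal mutations all lay in well-covered
    sequence).  JK3 carries only its focal mutation.
    """
    rng = np.random.default_rng(seed)
    focal = genome.focal_gene
    contig_seq = genome.contigs[focal.contig]
    specs: list[MutationSpec] = []
    for offset, ref, alt, strains in FOCAL_MUTATIONS:
        pos = focal.start + offset - 1
        have = contig_seq[pos - 1 : pos - 1 + len(ref)]
        if have != ref:
            raise ValueError(f"focal ref mismatch at {focal.contig}:{pos}: genome has {have!r}")
        specs.append(MutationSpec(focal.contig, pos, ref, alt, strains))

    blocked: dict[str, list[tuple[int, int]]] = {name: [] for name in genome.contigs}
    blocked[focal.contig].append((focal.start, focal.end))
    for name in genome.contigs:
        blocked[name].extend(genome.repeat_intervals(name))
        if avoid and name in avoid:
            blocked[name].extend(tuple(iv) for iv in avoid[name])

    # carriers for background mutations; clonal groups share some sites
    carriers: list[tuple[str, ...]] = [
        ("JK1",), ("JK1",), ("JK1",), ("JK2",), ("JK2",),
        ("JK4", "JK5", "JK6"), ("JK4", "JK5", "JK6"), ("JK4",), ("JK5",), ("JK6",),
        ("JK8", "JK9"), ("JK8", "JK9"), ("JK8",), ("JK9",),
        ("JK10",), ("JK10",), ("JK11",), ("JK11",),
    ]
    names = list(genome.contigs)
    used: set[tuple[str, int]] = {(s.contig, s.position) for s in specs}
    margin = 300  # keep background sites clear of blocked intervals and contig edges
    for group in carriers[:n_background]:
        for _ in range(500):
            contig = names[int(rng.integers(0, len(names)))]
            L = len(genome.contigs[contig])
            pos = int(rng.integers(margin, L - margin))
            if (contig, pos) in used:
                continue
            if any(s - margin <= pos <= e + margin for s, e in blocked[contig]):
                continue
            ref = genome.contigs[contig][pos - 1]
            alt = "ACGT"[("ACGT".index(ref) + int(rng.integers(1, 4))) % 4]
            specs.append(MutationSpec(contig, pos, ref, alt, group))
            used.add((contig, pos))
            break
        else:
            raise ValueError("could not place a background mutation outside blocked regions")
    return specs


def inject_mutations(
    genome: GenomeModel, specs: Iterable[MutationSpec]
) -> dict[str, dict[str, str]]:
    """Apply mutation specs, returning per-strain contig sequences (wild type included).

    Every ref allele is checked against the truth genome; a mismatch
    aborts with the offending position and the observed base(s).
    """
    specs = list(specs)
    for spec in specs:
        seq = genome.contigs[spec.contig]
        n = max(1, len(spec.ref))
        have = seq[spec.position - 1 : spec.position - 1 + n]
        want = spec.ref if spec.ref else None
        if spec.kind == "deletion":
            want = spec.ref
        if want is not None and have[: len(want)] != want:
            raise ValueError(
                f"ref allele mismatch at {spec.contig}:{spec.position}: "
                f"spec says {spec.ref!r}, genome has {have[: len(want)]!r}"
            )

    strains = sorted({s for spec in specs for s in spec.strains})
    out: dict[str, dict[str, str]] = {WILD_TYPE: dict(genome.contigs)}
    for strain in strains:
        contigs = dict(genome.contigs)
        mine = sorted(
            (s for s in specs if strain in s.strains),
            key=lambda s: (s.contig, -s.position),
        )
        for spec in mine:
            seq = contigs[spec.contig]
            p = spec.position
            if spec.kind == "substitution":
                seq = seq[: p - 1] + spec.alt + seq[p:]
            elif spec.kind == "insertion":
                # alt = ref + inserted base; replaces the anchor base in place
                seq = seq[: p - 1] + spec.alt + seq[p:]
            else:  # deletion of the base at p
                seq = seq[: p - 1] + seq[p:]
            contigs[spec.contig] = seq
        out[strain] = contigs
    return out


# ---------------------------------------------------------------------------
# Read simulation

_RC_TABLE = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGT", b"TGCA"):
    _RC_TABLE[_a] = _b


def simulate_reads(
    strain_genome: Mapping[str, str],
    params: ReadSimParams,
    strain: str = "S",
) -> list[SimRead]:
    """Paired-end reads at the requested coverage with uniform substitution errors.

    Each fragment yields one forward and one reverse-strand read, so
    strand sampling at any deep site is balanced.  Sequencing errors are
    i.i.d. substitutions; indel errors are not simulated (length-changing
    alleles in this model come from the genome, not the sequencer).
    """
    rng = np.random.default_rng(params.seed)
    rl = params.read_length
    reads: list[SimRead] = []
    for contig, seq in strain_genome.items():
        L = len(seq)
        if L < rl:
            continue
        n_pairs = int(round(params.mean_coverage * L / (2 * rl)))
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        inserts = np.clip(
            rng.normal(params.insert_mean, params.insert_sd, size=n_pairs).round().astype(int),
            rl,
            L,
        )
        starts = (rng.random(n_pairs) * (L - inserts + 1)).astype(int)  # 0-based
        ends = starts + inserts
        fwd = np.empty((n_pairs, rl), dtype=np.uint8)
        rev = np.empty((n_pairs, rl), dtype=np.uint8)
        idx = np.arange(rl)
        fwd[:] = arr[starts[:, None] + idx]
        rev[:] = _RC_TABLE[arr[ends[:, None] - rl + idx]][:, ::-1]
        for mat in (fwd, rev):
            if params.error_rate > 0:
                mask = rng.random(mat.shape) < params.error_rate
                n_err = int(mask.sum())
                if n_err:
                    shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
                    codes = np.frombuffer(b"ACGT", dtype=np.uint8)
                    lut = np.zeros(256, dtype=np.uint8)
                    lut[codes] = np.arange(4)
                    mat[mask] = codes[(lut[mat[mask]] + shift) % 4]
        for i in range(n_pairs):
            reads.append(
                SimRead(
                    f"{strain}:{contig}:{i}/1",
                    fwd[i].tobytes().decode(),
                    contig,
                    int(starts[i]) + 1,
                    "+",
                )
            )
            reads.append(
                SimRead(
                    f"{strain}:{contig}:{i}/2",
                    rev[i].tobytes().decode(),
                    contig,
                    int(ends[i]) - rl + 1,
                    "-",
                )
            )
    return reads


# ---------------------------------------------------------------------------
# Crude assembly emulation


def emulate_crude_assembly(
    genome: GenomeModel, params: AssemblyEmulationParams
) -> CrudeAssembly:
    """Emulate a draft assembly: consensus errors confined to low-coverage/repeat regions.

    The coverage track mimics what an assembler reports: roughly the
    sequencing depth genome-wide, with scattered patches collapsed to
    1-5x where the consensus is unreliable.  Consensus errors
    (substitutions relative to the truth genome) are injected only
    inside those patches or inside repeat-derived sequence.  The focal
    gene is kept clear of low-coverage patches, emulating the study's
    situation where the causal gene lay in well-assembled sequence.
    """
    rng = np.random.default_rng(params.seed)
    focal = genome.focal_gene
    contigs: dict[str, str] = {}
    coverage: dict[str, np.ndarray] = {}
    errors: list[tuple[str, int, str, str]] = []
    low_iv: dict[str, list[tuple[int, int]]] = {}

    for name, seq in genome.contigs.items():
        L = len(seq)
        cov = np.maximum(
            np.round(rng.normal(params.mean_coverage, params.mean_coverage / 8, size=L)), 6
        ).astype(int)
        # place low-coverage patches
        target = params.low_coverage_fraction * L
        placed = 0
        intervals: list[tuple[int, int]] = []
        guard = 0
        while placed < target and guard < 1000:
            guard += 1
            plen = int(rng.integers(80, 300))
            start = int(rng.integers(1, max(2, L - plen)))
            end = start + plen - 1
            if name == focal.contig and not (end < focal.start - 300 or start > focal.end + 300):
                continue
            if any(not (end < s - 50 or start > e + 50) for s, e in intervals):
                continue
            intervals.append((start, end))
            placed += plen
        low_iv[name] = sorted(intervals)
        mutable = np.zeros(L, dtype=bool)
        for s, e in intervals:
            cov[s - 1 : e] = rng.integers(1, 6, size=e - s + 1)
            mutable[s - 1 : e] = True
        for s, e in genome.repeat_intervals(name):
            mutable[s - 1 : e] = True
        err_mask = mutable & (rng.random(L) < params.consensus_error_rate_in_low_coverage)
        chars = list(seq)
        for p0 in np.flatnonzero(err_mask):
            truth = chars[p0]
            new = "ACGT"[("ACGT".index(truth) + int(rng.integers(1, 4))) % 4]
            chars[p0] = new
            errors.append((name, int(p0) + 1, truth, new))
        contigs[name] = "".join(chars)
        coverage[name] = cov
    return CrudeAssembly(contigs, coverage, errors, low_iv)


# ---------------------------------------------------------------------------
# Difference-report fixture (the study's 58-record accounting)

# The 36 retained records: contig, position, assembly coverage (None when
# not reported), annotation string, strains carrying the difference.
_TABLE_RETAINED: tuple[tuple[str, int, int | None, str, tuple[str, ...]], ...] = (
    ("Contig 3", 15305, 5, "Silent mutation in D-Ala-D-Ala carboxypeptidase", ("JK8",)),
    ("Contig 7", 17428, 16, "ACG-ATG = 40T-M in S4 RNA-binding domain protein", ("JK4", "JK5")),
    ("Contig 10", 2518, 44,
     "CGA-TGA = 104R-stop in APC family amino acid-polyamine-organocation transporter, 610 aa",
     ("JK3",)),
    ("Contig 10", 2739, 30,
     "TTC-TTTC = 177F-frameshift in APC family amino acid-polyamine-organocation transporter",
     ("JK4", "JK5", "JK6")),
    ("Contig 10", 3337, 18,
     "GCG-ACG = 377A-T in APC family amino acid-polyamine-organocation transporter", ("JK2",)),
    ("Contig 10", 3367, 19,
     "TCT-CCT = 387S-P in APC family amino acid-polyamine-organocation transporter", ("JK1",)),
    ("Contig 10", 3393, 23,
     "TGG-TGA = 395W-stop in APC family amino acid-polyamine-organocation transporter", ("JK10",)),
    ("Contig 10", 3482, 21,
     "ATG-AAG = 425M-K in APC family amino acid-polyamine-organocation transporter", ("JK11",)),
    ("Contig 10", 3491, 22,
     "CAT-CGT = 428H-R in APC family amino acid-polyamine-organocation transporter",
     ("JK8", "JK9")),
    ("Contig 10", 12129, 6, "GGT-AGT = G-S in nucleic acid-binding protein", ("JK9",)),
    ("Contig 11", 2629, 6, "GTA-ATA = V-I in predicted metal-dependent hydrolase", ("JK5",)),
    ("Contig 12", 3366, 15, "GTG-GCG = V-A in Met-tRNA formyl transferase", ("JK2",)),
    ("Contig 15", 5486, 18, "Intergenic region according to Glimmer, no BlastX hits", ("JK10",)),
    ("Contig 17", 10149, 45,
     "Just downstream of Glimmer orf 10 branched chain amino acid aminotransferase", ("JK1",)),
    ("Contig 23", 2907, 10, "ATT-GTT = I-V in UTP-glucose-1-P uridylyltransferase", ("JK4",)),
    ("Contig 23", 13717, 32,
     "GTG-GGTG = frameshift in glutamine ABC transporter, permease/substrate-binding protein",
     ("JK8", "JK9")),
    ("Contig 26", 9532, 60,
     "ATT-GTT = I-V in purH, bifunctional phosphoribosylaminoimidazolecarboxamide "
     "formyltransferase/IMP cyclohydrolase", ("JK8", "JK9")),
    ("Contig 28", 11172, 14,
     "GGA-GGGA = frameshift 55 aa from end of integral membrane protein", ("JK1",)),
    ("Contig 36", 7084, 57, "GCT-GTT = A-V in oxoacyl-ACP synthase", ("JK2",)),
    ("Contig 37", 167, None, "GAA-GAG = E-E silent mutation in aspartate kinase", ("JK2",)),
    ("Contig 42", 4874, 6,
     "CTA-CCA = L-P in putative dienelactone hydrolase (no gene predicted by Glimmer)",
     ("JK4", "JK5", "JK6")),
    ("Contig 47", 2473, 7, "Deletion of T in Intergenic region according to Glimmer", ()),
    ("Contig 64", 3734, 4, "AGT-AGC = silent mutation in nucleotide-binding protein", ("JK4",)),
    ("Contig 69", 1283, 14,
     "GGT-AGT = G-S in gene with similarity to HTH AraC regulatory protein", ("JK1",)),
    ("Contig 73", 2467, 19,
     "Frameshift after amino acid 187 in PTS system mannose family transporter subunit IID "
     "protein", ("JK1",)),
    ("Contig 77", 233, 28, "CAC-CAT = Silent mutation in pyruvate carboxylase",
     ("JK4", "JK5", "JK6")),
    ("Contig 79", 2182, 15, "GAC-AAC = D-N in putative uncharacterized protein", ("JK1",)),
    ("Contig 84", 4263, 8,
     "BLAST and Glimmer: not coding region, downstream of GTP-binding protein TypA gene",
     ("JK11",)),
    ("Contig 85", 8117, 5,
     "AAA-AAAA = frameshift toward end of Glimmer prediction, no Blast similarity", ("JK11",)),
    ("Contig 103", 928, 81, "ATT-ATC = silent mutation in glutathione reductase", ("JK10",)),
    ("Contig 111", 1948, 30, "AAT-AAC = silent mutation in oxidoreductase", ("JK5",)),
    ("Contig 114", 6645, 2, "GGA-GAA = G-E in MccC family protein - putative peptidase",
     ("JK6",)),
    ("Contig 132", 1556, 6, "Intergenic region", ("JK11",)),
    ("Contig 146", 971, 23, "CAG-CGG = Q-R in acetylornithine deacetylase", ("JK5",)),
    ("Contig 153", 1131, 2, "6 nt downstream of penicillin-binding protein/beta-lactamase",
     ("JK2",)),
    ("Contig 160", 2010, 5,
     "6 nt downstream of conserved hypothetical protein, putative receptor", ("JK10",)),
)

# Synthetic stand-ins for the 22 excluded records (the study prints only
# their counts and flag structure; positions/alleles here are invented).
_WT_SHARED_SYNTH: tuple[tuple[str, int, tuple[str, ...]], ...] = (
    ("Contig 2", 4410, MUTANT_STRAINS),
    ("Contig 5", 887, MUTANT_STRAINS),
    ("Contig 9", 12044, ("JK1", "JK2", "JK4", "JK5", "JK6")),
    ("Contig 14", 3310, MUTANT_STRAINS),
    ("Contig 19", 7725, ("JK2", "JK3", "JK8", "JK9")),
    ("Contig 31", 1518, MUTANT_STRAINS),
    ("Contig 40", 6023, ("JK1", "JK3", "JK10", "JK11")),
    ("Contig 55", 2291, MUTANT_STRAINS),
    ("Contig 61", 930, ("JK4", "JK5", "JK6", "JK8", "JK9", "JK10")),
    ("Contig 90", 5174, MUTANT_STRAINS),
    ("Contig 120", 341, ("JK1", "JK2", "JK5", "JK11")),
)
_LOWCOV_SHARED_SYNTH: tuple[tuple[str, int, tuple[str, ...]], ...] = (
    ("Contig 4", 9981, ("JK1", "JK2", "JK3")),
    ("Contig 6", 2250, ("JK4", "JK5")),
    ("Contig 8", 15660, ("JK8", "JK9", "JK10")),
    ("Contig 13", 4448, ("JK2", "JK6")),
    ("Contig 18", 812, ("JK1", "JK11")),
    ("Contig 25", 6107, ("JK3", "JK4", "JK5", "JK6")),
    ("Contig 33", 3029, ("JK8", "JK11")),
    ("Contig 48", 1194, ("JK2", "JK9", "JK10")),
    ("Contig 66", 7333, ("JK1", "JK4")),
    ("Contig 95", 2856, ("JK5", "JK6", "JK8")),
    ("Contig 140", 518, ("JK3", "JK10", "JK11")),
)

_FIXTURE_SEED = 20160505  # fixed: the fixture is a constant dataset, not a simulation


def _alleles_from_annotation(annotation: str) -> tuple[str, str, str]:
    """Derive (kind, ref, alt) in caller representation from a codon-pair annotation."""
    head = annotation.split(" = ")[0].replace("‐", "-")
    if "-" in head and all(set(p) <= set("ACGT") and p for p in head.split("-", 1)):
        c1, c2 = head.split("-", 1)
        if len(c1) == len(c2):
            for a, b in zip(c1, c2):
                if a != b:
                    return "substitution", a, b
        if len(c2) == len(c1) + 1:
            # find the duplicated/inserted base
            for i in range(len(c2)):
                if c2[: i] + c2[i + 1 :] == c1:
                    b = c2[i]
                    return "insertion", b, b + b
    if annotation.startswith("Deletion of "):
        b = annotation[len("Deletion of ")]
        return "deletion", b, ""
    if "rameshift" in annotation.lower():
        return "insertion", "A", "AA"
    return "substitution", "A", "G"


def make_difference_fixture() -> list["varcall.DifferenceRecord"]:
    """The 58-record difference report mirroring the study's filtering structure.

    11 records are present in the wild type (and several/all mutants) at
    assembly coverage 1-5x; 11 more are shared among several mutants in
    low-coverage positions; the remaining 36 reproduce the retained
    table (contig, position, assembly coverage, strain presence,
    annotation).  Read-level metrics (depth 154-484x, balanced strands,
    alt fraction >= 0.92) are synthesized deterministically.
    """
    from bactarget import varcall  # local import to avoid a cycle

    rng = np.random.default_rng(_FIXTURE_SEED)
    records: list[varcall.DifferenceRecord] = []

    def _metrics(depth_lo: int, depth_hi: int) -> tuple[int, int, int, float]:
        depth = int(rng.integers(depth_lo, depth_hi + 1))
        frac = float(rng.uniform(0.92, 1.0))
        alt = int(round(frac * depth))
        fwd = alt // 2 + int(rng.integers(0, 2))
        fwd = min(fwd, alt)
        return depth, fwd, alt - fwd, alt / depth

    def _presence(strains: Iterable[str], with_wt: bool = False) -> dict[str, bool]:
        p = {s: False for s in ALL_STRAINS}
        for s in strains:
            p[s] = True
        if with_wt:
            p[WILD_TYPE] = True
        return p

    for contig, pos, strains in _WT_SHARED_SYNTH:
        depth, fwd, rev, frac = _metrics(30, 90)
        records.append(
            varcall.DifferenceRecord(
                contig=contig, position=pos, ref="A", alt="G", kind="substitution",
                presence=_presence(strains, with_wt=True), depth=depth,
                alt_fwd=fwd, alt_rev=rev, alt_fraction=frac,
                assembly_coverage=int(rng.integers(1, 6)),
                annotation="synthetic: shared with wild type, low-coverage assembly region",
            )
        )
    for contig, pos, strains in _LOWCOV_SHARED_SYNTH:
        depth, fwd, rev, frac = _metrics(30, 90)
        records.append(
            varcall.DifferenceRecord(
                contig=contig, position=pos, ref="C", alt="T", kind="substitution",
                presence=_presence(strains), depth=depth,
                alt_fwd=fwd, alt_rev=rev, alt_fraction=frac,
                assembly_coverage=int(rng.integers(1, 6)),
                annotation="synthetic: shared among mutants, low-coverage assembly region",
            )
        )
    for contig, pos, cov, annotation, strains in _TABLE_RETAINED:
        kind, ref, alt = _alleles_from_annotation(annotation)
        depth, fwd, rev, frac = _metrics(154, 484)
        records.append(
            varcall.DifferenceRecord(
                contig=contig, position=pos, ref=ref, alt=alt, kind=kind,
                presence=_presence(strains), depth=depth,
                alt_fwd=fwd, alt_rev=rev, alt_fraction=frac,
                assembly_coverage=cov, annotation=annotation,
            )
        )
    return records


def fixture_gene_models() -> list[GeneModel]:
    """Gene models accompanying the difference fixture (the focal gene)."""
    return [GeneModel("Contig 10", 2209, 4041, "+", FOCAL_GENE_NAME)]


def fixture_contigs() -> dict[str, str]:
    """A synthetic 'Contig 10' hosting the engineered focal gene at 2209-4041.

    Lets the consequence annotator regenerate codon-level annotations for
    the fixture's focal-gene records from sequence rather than copy them.
    """
    rng = np.random.default_rng(_FIXTURE_SEED)
    L = 31_000
    seq = "".join("ACGT"[b] for b in rng.integers(0, 4, size=L))
    gene = build_focal_gene_sequence(_FIXTURE_SEED)
    seq = seq[:2208] + gene + seq[2208 + len(gene):]
    return {"Contig 10": seq}


# ---------------------------------------------------------------------------
# Engineered 12-helix membrane protein (topology fixture)

_HYDROPHOBIC = "IVIL"  # Kyte-Doolittle strongly positive
_HYDROPHILIC = "STGSNTGQ"  # mildly negative on average

DESIGNED_HELICES: tuple[tuple[int, int], ...] = (
    (20, 39), (60, 79), (110, 129), (145, 164), (181, 200), (215, 234),
    (250, 269), (285, 304), (320, 339), (370, 389), (405, 424), (440, 459),
)


def engineered_apc_protein() -> tuple[str, tuple[tuple[int, int], ...]]:
    """A 610-residue protein with 12 designed TM stretches, mirroring the
    topology of the focal transporter (truncation points 103/190/394 fall
    between helices 2-3, inside helix 5, and just after helix 10)."""
    residues = []
    for i in range(1, FOCAL_PROTEIN_LENGTH + 1):
        in_helix = any(s <= i <= e for s, e in DESIGNED_HELICES)
        pool = _HYDROPHOBIC if in_helix else _HYDROPHILIC
        residues.append(pool[i % len(pool)])
    return "".join(residues), DESIGNED_HELICES


# ---------------------------------------------------------------------------
# Dose-response plates


def make_dose_response(
    true_mic: float,
    dilution_steps: int = 11,
    top_concentration: float | None = None,
    noise_sd: float = 0.02,
    seed: int = 0,
    hill: float = 6.0,
    blank_od: float = 0.05,
    control_od: float = 1.0,
) -> DilutionSeries:
    """A two-fold dilution series whose sharp sigmoidal response crosses
    50% inhibition at ``true_mic``, with Gaussian OD noise."""
    if top_concentration is None:
        top_concentration = true_mic * 2 ** (dilution_steps // 2)
    rng = np.random.default_rng(seed)
    conc = top_concentration / 2.0 ** np.arange(dilution_steps)
    inhibition = 1.0 / (1.0 + (true_mic / conc) ** hill)
    od = blank_od + (1.0 - inhibition) * (control_od - blank_od)
    if noise_sd > 0:
        od = od + rng.normal(0.0, noise_sd, size=od.shape)
    od = np.maximum(od, 0.0)
    return DilutionSeries(
        concentrations=conc, od=od, blank_od=blank_od, control_od=control_od
    )
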