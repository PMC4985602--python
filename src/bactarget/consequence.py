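"""Codon-level consequence annotation of retained differences.

Gene models come from GFF or from a simple ORF finder (both strands,
bacterial start codons ATG/GTG/TTG, translation table 11).  A contig
position maps to its 1-based codon index by integer arithmetic on the
gene span; substitutions are classified silent/missense/nonsense by
codon translation, length-changing variants inside a gene are
frameshifts whose truncation point is found by translating the shifted
frame to its first stop, and variants outside genes are intergenic or
proximal-downstream of a gene end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from bactarget.dna import START_CODONS, STOP_CODONS, codon_residue, revcomp, translate
from bactarget.synthdata import GeneModel
from bactarget.varcall import DifferenceRecord

DEFAULT_PROXIMAL_WINDOW = 50
DEFAULT_MIN_ORF_LENGTH = 300


@dataclass(frozen=True)
class OrfCall:
    contig: str
    start: int  # 1-based inclusive, forward-contig coordinates
    end: int
    strand: str
    protein: str

    def as_gene(self, name: str) -> GeneModel:
        return GeneModel(self.contig, self.start, self.end, self.strand, name)


@dataclass
class ConsequenceCall:
    gene: str | None
    contig: str
    position: int
    codon_index: int | None
    ref_codon: str | None
    alt_codon: str | None
    ref_residue: str | None
    alt_residue: str | None
    kind: str  # silent | missense | nonsense | frameshift | intergenic | downstream_proximal
    truncation_after: int | None
    annotation: str
    tail_length: int | None = None  # aberrant residues appended by a frameshift
    in_frame_restored: bool = False
    also_in: tuple[str, ...] = ()  # other genes overlapping the site (ambiguous)


@dataclass(frozen=True)
class FrameshiftEffect:
    truncation_after: int | None  # residues translated before the premature stop
    tail_length: int  # aberrant residues after the last in-frame codon
    in_frame_restored: bool
    hit_contig_end: bool


def find_orfs(
    contigs: Mapping[str, str],
    min_length: int = DEFAULT_MIN_ORF_LENGTH,
    start_codons: frozenset[str] = START_CODONS,
) -> list[OrfCall]:
    """All maximal ORFs (first start codon per stop, both strands) of at least min_length nt."""
    if min_length < 90:
        raise ValueError(f"min_length must be >= 90 nt, got {min_length}")
    orfs: list[OrfCall] = []
    for contig in sorted(contigs):
        fwd = contigs[contig]
        L = len(fwd)
        for strand, seq in (("+", fwd), ("-", revcomp(fwd))):
            for frame in range(3):
                start_of_orf: int | None = None
                for i in range(frame, len(seq) - 2, 3):
                    codon = seq[i : i + 3]
                    if codon in STOP_CODONS:
                        if start_of_orf is not None:
                            s0, e0 = start_of_orf, i + 3  # 0-based half-open incl. stop
                            if e0 - s0 >= min_length:
                                if strand == "+":
                                    start, end = s0 + 1, e0
                                else:
                                    start, end = L - e0 + 1, L - s0
                                orfs.append(
                                    OrfCall(
                                        contig,
                                        start,
                                        end,
                                        strand,
                                        translate(seq[s0 : e0 - 3]),
                                    )
                                )
                            start_of_orf = None
                    elif start_of_orf is None and codon in start_codons:
                        start_of_orf = i
    return sorted(orfs, key=lambda o: (o.contig, o.start, o.end))


def map_position_to_codon(gene: GeneModel, position: int) -> int:
    """1-based codon index containing a contig position, strand-aware."""
    if not gene.start <= position <= gene.end:
        raise ValueError(
            f"position {position} outside gene {gene.name} ({gene.start}-{gene.end}); "
            "classify as intergenic instead"
        )
    if gene.strand == "+":
        return (position - gene.start) // 3 + 1
    return (gene.end - position) // 3 + 1


def protein_length(gene: GeneModel) -> int:
    """Residues encoded by a gene whose span includes the stop codon."""
    if gene.length % 3 != 0:
        raise ValueError(f"gene {gene.name} length {gene.length} is not a multiple of 3")
    return gene.length // 3 - 1


def _codon_at(gene: GeneModel, contigs: Mapping[str, str], codon_index: int) -> str:
    seq = contigs[gene.contig][gene.start - 1 : gene.end]
    if gene.strand == "-":
        seq = revcomp(seq)
    return seq[(codon_index - 1) * 3 : codon_index * 3]


def _inserted_base(record: DifferenceRecord) -> str:
    if record.alt.startswith(record.ref):
        return record.alt[len(record.ref) :]
    return record.alt[:-1] if record.alt.endswith(record.ref) else record.alt


def _affected_position(
    record: DifferenceRecord, contigs: Mapping[str, str] | None = None
) -> int:
    """Position of the first base touched by a record (codon-assignment anchor).

    An insertion whose anchor starts a homopolymer run of the inserted
    base affects that run from the anchor on; an anchor before a
    non-run insertion puts the new base one position downstream.  A
    printed-style anchor inside the affected codon (where the record's
    ref does not match the contig) is used as is.
    """
    if record.kind != "insertion":
        return record.position
    if contigs is None:
        return record.position
    seq = contigs.get(record.contig)
    if seq is None:
        return record.position
    base_here = seq[record.position - 1]
    ins = _inserted_base(record)
    if base_here == record.ref and record.ref != ins:
        return record.position + 1
    return record.position


def _apply_record(seq: str, record: DifferenceRecord) -> str:
    """Apply one difference to a contig sequence (insertion anchors tolerated
    in both left-normalized and printed-table conventions)."""
    p = record.position
    if record.kind == "substitution":
        return seq[: p - 1] + record.alt + seq[p:]
    if record.kind == "insertion":
        if seq[p - 1] == record.ref and record.alt.startswith(record.ref):
            return seq[: p - 1] + record.alt + seq[p:]
        return seq[: p - 1] + _inserted_base(record) + seq[p - 1 :]
    return seq[: p - 1] + seq[p:]


def frameshift_effect(
    gene: GeneModel,
    contigs: Mapping[str, str],
    records: DifferenceRecord | Sequence[DifferenceRecord],
) -> FrameshiftEffect:
    """Translate through a frameshift to its first stop.

    ``truncation_after`` is the number of residues produced before the
    premature stop (the reported "truncated after amino acid N").
    When the combined records restore the frame before any shifted stop
    is reached the effect is flagged in-frame-restored instead; when no
    stop occurs before the contig end, the count is reported with the
    ``hit_contig_end`` flag.
    """
    if isinstance(records, DifferenceRecord):
        records = [records]
    contig_seq = contigs[gene.contig]
    mutant = contig_seq
    for rec in sorted(records, key=lambda r: -r.position):
        mutant = _apply_record(mutant, rec)
    net = len(mutant) - len(contig_seq)
    plen = protein_length(gene)
    if gene.strand == "+":
        coding = mutant[gene.start - 1 :]
    else:
        coding = revcomp(mutant[: gene.end + net])
    first_codon = min(
        map_position_to_codon(gene, min(_affected_position(r, contigs), gene.end))
        for r in records
    )
    n = 0
    hit_end = True
    for i in range(0, len(coding) - 2, 3):
        if coding[i : i + 3] in STOP_CODONS:
            hit_end = False
            break
        n += 1
    restored = net % 3 == 0 and n == plen
    return FrameshiftEffect(
        truncation_after=None if restored else n,
        tail_length=0 if restored else max(0, n - (first_codon - 1)),
        in_frame_restored=restored,
        hit_contig_end=hit_end,
    )


def _containing_genes(
    genes: Sequence[GeneModel], contig: str, position: int
) -> list[GeneModel]:
    return [
        g
        for g in sorted(genes, key=lambda g: (g.contig, g.start))
        if g.contig == contig and g.start <= position <= g.end
    ]


def _substitution_call(
    record: DifferenceRecord,
    gene: GeneModel,
    contigs: Mapping[str, str],
    also_in: tuple[str, ...],
) -> ConsequenceCall:
    idx = map_position_to_codon(gene, record.position)
    ref_codon = _codon_at(gene, contigs, idx)
    if gene.strand == "+":
        offset = (record.position - gene.start) % 3
        alt_base = record.alt
    else:
        offset = (gene.end - record.position) % 3
        alt_base = revcomp(record.alt)
    alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1 :]
    ref_aa = codon_residue(ref_codon)
    alt_aa = codon_residue(alt_codon)
    if alt_aa == ref_aa:
        kind, trunc = "silent", None
        annotation = f"{ref_codon}-{alt_codon} = silent mutation in {gene.name}"
    elif alt_aa == "*":
        kind, trunc = "nonsense", idx - 1
        annotation = (
            f"{ref_codon}-{alt_codon} = {idx}{ref_aa}-stop in {gene.name}, "
            f"{protein_length(gene)} aa"
        )
    else:
        kind, trunc = "missense", None
        annotation = f"{ref_codon}-{alt_codon} = {idx}{ref_aa}-{alt_aa} in {gene.name}"
    return ConsequenceCall(
        gene=gene.name,
        contig=record.contig,
        position=record.position,
        codon_index=idx,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_residue=ref_aa,
        alt_residue="*" if alt_aa == "*" else alt_aa,
        kind=kind,
        truncation_after=trunc,
        annotation=annotation,
        also_in=also_in,
    )


def _frameshift_call(
    record: DifferenceRecord,
    gene: GeneModel,
    contigs: Mapping[str, str],
    also_in: tuple[str, ...],
) -> ConsequenceCall:
    idx = map_position_to_codon(gene, min(_affected_position(record, contigs), gene.end))
    ref_codon = _codon_at(gene, contigs, idx)
    effect = frameshift_effect(gene, contigs, record)
    if record.kind == "insertion":
        # rebuild the codon with the extra base for the TTC-TTTC style annotation
        if gene.strand == "+":
            off = min(max(record.position - (gene.start + (idx - 1) * 3), 0), 3)
            alt_codon = ref_codon[:off] + _inserted_base(record) + ref_codon[off:]
        else:
            alt_codon = ref_codon + "+1"
    else:
        alt_codon = ref_codon.replace(record.ref, "", 1) if gene.strand == "+" else ref_codon + "-1"
    ref_aa = codon_residue(ref_codon)
    annotation = f"{ref_codon}-{alt_codon} = {idx}{ref_aa}-frameshift in {gene.name}"
    return ConsequenceCall(
        gene=gene.name,
        contig=record.contig,
        position=record.position,
        codon_index=idx,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_residue=ref_aa,
        alt_residue=None,
        kind="frameshift",
        truncation_after=effect.truncation_after,
        annotation=annotation,
        tail_length=effect.tail_length,
        in_frame_restored=effect.in_frame_restored,
        also_in=also_in,
    )


def _intergenic_call(
    record: DifferenceRecord,
    genes: Sequence[GeneModel],
    proximal_window: int,
) -> ConsequenceCall:
    position = record.position
    nearest: tuple[int, GeneModel] | None = None
    for g in genes:
        if g.contig != record.contig:
            continue
        # downstream of a gene means past its 3' end, strand-aware
        dist = position - g.end if g.strand == "+" else g.start - position
        if 0 < dist <= proximal_window and (nearest is None or dist < nearest[0]):
            nearest = (dist, g)
    if nearest is not None:
        dist, g = nearest
        return ConsequenceCall(
            gene=None, contig=record.contig, position=position,
            codon_index=None, ref_codon=None, alt_codon=None,
            ref_residue=None, alt_residue=None,
            kind="downstream_proximal", truncation_after=None,
            annotation=f"{dist} nt downstream of {g.name}",
        )
    return ConsequenceCall(
        gene=None, contig=record.contig, position=position,
        codon_index=None, ref_codon=None, alt_codon=None,
        ref_residue=None, alt_residue=None,
        kind="intergenic", truncation_after=None,
        annotation="Intergenic region",
    )


def classify(
    record: DifferenceRecord,
    genes: Sequence[GeneModel],
    contigs: Mapping[str, str],
    proximal_window: int = DEFAULT_PROXIMAL_WINDOW,
) -> ConsequenceCall:
    """Annotate one retained difference against the gene models.

    A record overlapping several genes is annotated against the
    first (lowest start) with the others listed in ``also_in``.
    """
    hits = _containing_genes(genes, record.contig, _affected_position(record, contigs))
    if not hits:
        return _intergenic_call(record, genes, proximal_window)
    gene, also_in = hits[0], tuple(g.name for g in hits[1:])
    if record.kind == "substitution":
        return _substitution_call(record, gene, contigs, also_in)
    return _frameshift_call(record, gene, contigs, also_in)
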