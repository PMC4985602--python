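"""Pileup-to-difference conversion and cross-strain merging.

A difference record is emitted where the majority non-reference allele
reaches the calling fraction at sufficient depth.  Bacteria are
haploid: mixed sites below the calling fraction are treated as absence
rather than heterozygosity.  Calling is deliberately generous (the
default fraction is below the verification fraction applied later) so
that the explicit filter stage is the decision point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from bactarget.mapping import Pileup

DEFAULT_MIN_ALT_FRACTION = 0.8
DEFAULT_MIN_DEPTH = 10


@dataclass
class DifferenceRecord:
    """One candidate polymorphism between a read set and the draft contigs.

    Positions are 1-based; indels are left-normalized to the start of
    their homopolymer run (an insertion has alt = ref + inserted base, a
    deletion has an empty alt).  ``presence`` maps every strain in the
    analysis to whether the difference was called there.
    """

    contig: str
    position: int
    ref: str
    alt: str
    kind: str  # substitution | insertion | deletion
    presence: dict[str, bool]
    depth: int
    alt_fwd: int
    alt_rev: int
    alt_fraction: float
    assembly_coverage: float | None = None
    wildtype_shared: bool = False
    low_coverage_region: bool = False
    failed_verification: bool = False
    annotation: str = ""
    per_strain: dict[str, tuple[int, int, int, float]] = field(default_factory=dict)
    # per strain: (depth, alt_fwd, alt_rev, alt_fraction)

    def __post_init__(self) -> None:
        if not 0.0 <= self.alt_fraction <= 1.0:
            raise ValueError(f"alt fraction {self.alt_fraction} outside [0, 1]")
        if self.alt_fwd + self.alt_rev > self.depth:
            raise ValueError("alt-supporting reads exceed depth")
        if self.kind not in ("substitution", "insertion", "deletion"):
            raise ValueError(f"bad record kind {self.kind!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.position, self.ref, self.alt)

    @property
    def strains_present(self) -> tuple[str, ...]:
        return tuple(s for s, p in self.presence.items() if p)


def call_differences(
    pileup: Pileup,
    contigs: Mapping[str, str] | None = None,
    min_alt_fraction: float = DEFAULT_MIN_ALT_FRACTION,
    min_depth: int = DEFAULT_MIN_DEPTH,
    strain: str = "S",
) -> list[DifferenceRecord]:
    """Candidate differences for one strain's pileup against the draft contigs.

    Only event positions can be non-reference, so calling scans the
    sparse event set: at each position the majority non-reference allele
    is tested against ``min_alt_fraction`` and ``min_depth``.  Alleles
    are reported on the contig forward strand; indels arrive
    left-normalized from the aligner.
    """
    pileup.finalize()
    if contigs is None:
        contigs = pileup.contigs
    by_pos: dict[tuple[str, int], list[tuple[str, str, str, int, int]]] = {}
    for (contig, pos, kind, ref, alt), (nf, nr) in pileup.events.items():
        by_pos.setdefault((contig, pos), []).append((kind, ref, alt, nf, nr))
    records: list[DifferenceRecord] = []
    for (contig, pos), alleles in sorted(by_pos.items()):
        depth = int(pileup.depth[contig][pos - 1])
        if depth < min_depth:
            continue
        kind, ref, alt, nf, nr = max(alleles, key=lambda a: a[3] + a[4])
        fraction = (nf + nr) / depth
        if fraction < min_alt_fraction:
            continue
        records.append(
            DifferenceRecord(
                contig=contig,
                position=pos,
                ref=ref,
                alt=alt,
                kind={"X": "substitution", "I": "insertion", "D": "deletion"}[kind],
                presence={strain: True},
                depth=depth,
                alt_fwd=nf,
                alt_rev=nr,
                alt_fraction=min(fraction, 1.0),
            )
        )
    return records


def merge_strains(
    per_strain: Mapping[str, Sequence[DifferenceRecord]],
    strains: Iterable[str] | None = None,
) -> list[DifferenceRecord]:
    """Unify per-strain records called against the same contigs.

    Records identical in (contig, position, ref, alt) are merged; the
    merged record's headline metrics come from the deepest strain, with
    per-strain detail retained.  Two different reference alleles
    claimed at one position indicate inconsistent inputs and raise.
    """
    strain_list = list(strains) if strains is not None else sorted(per_strain)
    ref_seen: dict[tuple[str, int], str] = {}
    merged: dict[tuple[str, int, str, str], DifferenceRecord] = {}
    for strain in sorted(per_strain):
        for rec in per_strain[strain]:
            if rec.kind == "substitution":
                prev = ref_seen.setdefault((rec.contig, rec.position), rec.ref)
                if prev != rec.ref:
                    raise ValueError(
                        f"conflicting reference alleles at {rec.contig}:{rec.position}: "
                        f"{prev!r} vs {rec.ref!r}"
                    )
            key = rec.key
            if key not in merged:
                merged[key] = DifferenceRecord(
                    contig=rec.contig,
                    position=rec.position,
                    ref=rec.ref,
                    alt=rec.alt,
                    kind=rec.kind,
                    presence={s: False for s in strain_list},
                    depth=rec.depth,
                    alt_fwd=rec.alt_fwd,
                    alt_rev=rec.alt_rev,
                    alt_fraction=rec.alt_fraction,
                    assembly_coverage=rec.assembly_coverage,
                )
            m = merged[key]
            m.presence[strain] = True
            m.per_strain[strain] = (rec.depth, rec.alt_fwd, rec.alt_rev, rec.alt_fraction)
            if rec.depth > m.depth or (
                m.depth == rec.depth and not any(m.per_strain)
            ):
                m.depth = rec.depth
                m.alt_fwd = rec.alt_fwd
                m.alt_rev = rec.alt_rev
                m.alt_fraction = rec.alt_fraction
    return sorted(merged.values(), key=lambda r: (r.contig, r.position, r.ref, r.alt))
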