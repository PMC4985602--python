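"""False-positive exclusion and verification of candidate differences.

A draft assembly built from the wild type's own reads contains
consensus errors, concentrated where assembly coverage collapses (1-5x
against a ~50x average) and in repeat-derived sequence.  Such errors
surface as apparent polymorphisms in every strain compared against the
assembly.  Two exclusion rules remove them: (1) differences also called
in the wild type's own reads are assembly errors by self-comparison;
(2) differences shared by several mutants and sitting in low-coverage
assembly regions are untrustworthy consensus.  Surviving records are
verified site by site: high read depth, the alternate allele in nearly
all reads, and both strands represented (a two-sided binomial test —
the operationalization of "equally represented" is a policy choice and
is swappable via FilterPolicy).

Exclusion reasons are evaluated in that order and a record is
attributed to the first reason that fires, which makes the accounting
(input = retained + excluded per reason) well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from bactarget.synthdata import GeneModel, WILD_TYPE
from bactarget.varcall import DifferenceRecord

EXCLUSION_ORDER = ("wildtype_shared", "low_coverage_region", "failed_verification")


@dataclass(frozen=True)
class FilterPolicy:
    low_coverage_max: float = 5.0  # assembly coverage at/below which consensus is unreliable
    verify_min_depth: int = 20  # read depth a trusted site must reach
    verify_min_alt_fraction: float = 0.9  # alternate allele in >= 90% of reads
    strand_balance_alpha: float = 0.01  # two-sided binomial(0.5) significance level
    shared_strain_min: int = 2  # mutants sharing a low-coverage hit to trigger exclusion

    def __post_init__(self) -> None:
        if not 0.0 < self.verify_min_alt_fraction <= 1.0:
            raise ValueError("verify_min_alt_fraction must be in (0, 1]")
        if self.low_coverage_max < 1:
            raise ValueError("low_coverage_max must be >= 1")


@dataclass
class FilterResult:
    retained: list[DifferenceRecord]
    excluded: list[tuple[DifferenceRecord, str]]  # (record, first reason that fired)
    counts: dict[str, int]

    @property
    def n_input(self) -> int:
        return len(self.retained) + len(self.excluded)


def _mutant_carriers(record: DifferenceRecord) -> int:
    return sum(1 for s, p in record.presence.items() if p and s != WILD_TYPE)


def flag_wildtype_shared(records: Iterable[DifferenceRecord]) -> list[DifferenceRecord]:
    """Mark records also present in the wild type (assembly errors by self-comparison)."""
    records = list(records)
    for rec in records:
        rec.wildtype_shared = bool(rec.presence.get(WILD_TYPE, False))
    return records


def flag_low_coverage_region(
    records: Iterable[DifferenceRecord],
    coverage_track: Mapping[str, np.ndarray] | None = None,
    policy: FilterPolicy = FilterPolicy(),
) -> list[DifferenceRecord]:
    """Mark records shared by several mutants in unreliable low-coverage assembly regions.

    Coverage comes from ``coverage_track`` when given (also backfilled
    onto the record), otherwise from the record's own assembly_coverage
    field.  A record that is not shared widely enough is never flagged,
    so its coverage may be absent; a shared record with no coverage
    available raises.
    """
    records = list(records)
    for rec in records:
        if coverage_track is not None:
            rec.assembly_coverage = float(coverage_track[rec.contig][rec.position - 1])
        if _mutant_carriers(rec) < policy.shared_strain_min:
            rec.low_coverage_region = False
            continue
        if rec.assembly_coverage is None:
            raise ValueError(
                f"no assembly coverage available for shared record at "
                f"{rec.contig}:{rec.position}"
            )
        rec.low_coverage_region = rec.assembly_coverage <= policy.low_coverage_max
    return records


def verify_record(
    record: DifferenceRecord, policy: FilterPolicy = FilterPolicy()
) -> tuple[bool, list[str]]:
    """Site-level verification: depth, allele fraction, and strand balance.

    Passes iff read depth >= verify_min_depth, the alternate allele
    fraction >= verify_min_alt_fraction, and a two-sided binomial(0.5)
    test on forward vs reverse alt-supporting reads is not rejected at
    strand_balance_alpha.
    """
    reasons: list[str] = []
    if record.depth < policy.verify_min_depth:
        reasons.append(f"depth {record.depth} < {policy.verify_min_depth}")
    if record.alt_fraction < policy.verify_min_alt_fraction:
        reasons.append(
            f"alt fraction {record.alt_fraction:.3f} < {policy.verify_min_alt_fraction}"
        )
    n = record.alt_fwd + record.alt_rev
    if n == 0:
        reasons.append("no alt-supporting reads")
    else:
        p = stats.binomtest(record.alt_fwd, n, 0.5, alternative="two-sided").pvalue
        if p < policy.strand_balance_alpha:
            reasons.append(
                f"strand imbalance {record.alt_fwd}F/{record.alt_rev}R (p={p:.2e})"
            )
    record.failed_verification = bool(reasons)
    return (not reasons, reasons)


def apply_filters(
    records: Iterable[DifferenceRecord],
    coverage_track: Mapping[str, np.ndarray] | None = None,
    policy: FilterPolicy = FilterPolicy(),
) -> FilterResult:
    """Run the full exclusion/verification scheme and account for every record."""
    records = flag_wildtype_shared(records)
    records = flag_low_coverage_region(records, coverage_track, policy)
    retained: list[DifferenceRecord] = []
    excluded: list[tuple[DifferenceRecord, str]] = []
    counts = {reason: 0 for reason in EXCLUSION_ORDER}
    for rec in records:
        if rec.wildtype_shared:
            excluded.append((rec, "wildtype_shared"))
            counts["wildtype_shared"] += 1
            continue
        if rec.low_coverage_region:
            excluded.append((rec, "low_coverage_region"))
            counts["low_coverage_region"] += 1
            continue
        ok, _reasons = verify_record(rec, policy)
        if not ok:
            excluded.append((rec, "failed_verification"))
            counts["failed_verification"] += 1
            continue
        retained.append(rec)
    return FilterResult(retained=retained, excluded=excluded, counts=counts)


def rank_candidate_genes(
    records: Sequence[DifferenceRecord], genes: Sequence[GeneModel]
) -> pd.DataFrame:
    """Genes ordered by distinct mutated sites, then by mutant strains hit.

    Ties are broken by (contig, start) for a deterministic report.  Only
    records lying within a gene's span contribute.
    """
    rows = []
    for gene in genes:
        sites: set[int] = set()
        strains: set[str] = set()
        for rec in records:
            if rec.contig == gene.contig and gene.start <= rec.position <= gene.end:
                sites.add(rec.position)
                strains.update(s for s in rec.strains_present if s != WILD_TYPE)
        if sites:
            rows.append(
                {
                    "gene": gene.name,
                    "contig": gene.contig,
                    "start": gene.start,
                    "end": gene.end,
                    "n_sites": len(sites),
                    "n_strains": len(strains),
                    "positions": ",".join(str(p) for p in sorted(sites)),
                    "strains": ",".join(sorted(strains)),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene", "contig", "start", "end", "n_sites", "n_strains", "positions", "strains",
        ],
    )
    if not df.empty:
        df = df.sort_values(
            ["n_sites", "n_strains", "contig", "start"],
            ascending=[False, False, True, True],
        ).reset_index(drop=True)
    return df
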