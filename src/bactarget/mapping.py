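"""Seed-and-extend read mapping onto draft contigs, and pileup construction.

Reads are seeded with non-overlapping k-mers against an exact k-mer
index of the contigs; seed hits voting for the same diagonal (within
±1, to tolerate a 1-bp indel) form candidate loci, which are scored by
edit-distance alignment (edlib) restricted to at most one 1-bp indel
and a mismatch budget.  Ties between equally scoring loci are broken by
lowest (contig, position) and recorded in the alignment's ``unique``
flag; pileups exclude non-unique alignments by default, mirroring the
exclusion of repeat-confounded evidence downstream.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np

from bactarget.dna import revcomp

logger = logging.getLogger(__name__)

DEFAULT_K = 21
DEFAULT_MAX_MISMATCHES = 5
MAX_CANDIDATE_LOCI = 8


@dataclass
class KmerIndex:
    k: int
    index: dict[str, list[tuple[str, int]]]  # k-mer -> [(contig, 0-based position)]

    def hits(self, kmer: str) -> list[tuple[str, int]]:
        return self.index.get(kmer, [])


@dataclass(frozen=True)
class Edit:
    """One deviation from the contig, 1-based, indels left-normalized.

    kind 'X': ref/alt are the contig and read base at ``pos``.
    kind 'I': ref is the base at ``pos`` (run start), alt = ref + inserted.
    kind 'D': ref is the deleted base at ``pos`` (run start), alt = ''.
    """

    kind: str
    pos: int
    ref: str
    alt: str


@dataclass
class ReadAlignment:
    read_id: str
    contig: str
    start: int  # 1-based first contig position covered
    end: int  # 1-based last contig position covered
    strand: str
    edits: tuple[Edit, ...]
    n_mismatches: int
    n_indels: int
    unique: bool
    read_length: int


def build_index(contigs: Mapping[str, str], k: int = DEFAULT_K) -> KmerIndex:
    """Complete forward-strand k-mer index; queries try both read orientations."""
    if k < 11:
        raise ValueError(f"k must be >= 11, got {k}")
    if not contigs:
        raise ValueError("no contigs to index")
    index: dict[str, list[tuple[str, int]]] = {}
    for name in sorted(contigs):
        seq = contigs[name]
        if len(seq) < k:
            logger.warning("contig %s shorter than k=%d; skipped from index", name, k)
            continue
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append((name, i))
    return KmerIndex(k=k, index=index)


def _seed_clusters(
    seq: str, index: KmerIndex
) -> list[tuple[str, int, int]]:
    """Candidate loci as (contig, approx 0-based start, seed support)."""
    k = index.k
    offsets = list(range(0, len(seq) - k + 1, k))
    if offsets and offsets[-1] != len(seq) - k:
        offsets.append(len(seq) - k)
    votes: Counter[tuple[str, int]] = Counter()
    for off in offsets:
        for contig, pos in index.hits(seq[off : off + k]):
            votes[(contig, pos - off)] += 1
    clusters: list[tuple[str, int, int]] = []
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for (contig, diag), n in votes.items():
        by_contig.setdefault(contig, []).append((diag, n))
    for contig, diags in by_contig.items():
        diags.sort()
        cur_start, cur_n, last = diags[0][0], 0, None
        for diag, n in diags:
            if last is not None and diag - last > 2:
                clusters.append((contig, cur_start, cur_n))
                cur_start, cur_n = diag, 0
            cur_n += n
            last = diag
        clusters.append((contig, cur_start, cur_n))
    clusters = [c for c in clusters if c[2] >= 2]
    clusters.sort(key=lambda c: (-c[2], c[0], c[1]))
    return clusters[:MAX_CANDIDATE_LOCI]


def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    out = []
    n = ""
    for ch in cigar:
        if ch.isdigit():
            n += ch
        else:
            out.append((int(n), ch))
            n = ""
    return out


def _normalize_insertion(contig_seq: str, anchor: int, inserted: str) -> tuple[int, str, str]:
    """Left-shift a 1-bp insertion; returns (pos, ref, alt) in run-start representation."""
    b = inserted
    a = anchor  # 1-based base after which the insertion sits
    while a >= 1 and contig_seq[a - 1] == b:
        a -= 1
    # run of b (possibly empty) spans a+1 .. anchor
    if a + 1 <= len(contig_seq) and contig_seq[a] == b:
        return a + 1, b, b + b
    if a == 0:
        return 1, contig_seq[0], b + contig_seq[0]
    return a, contig_seq[a - 1], contig_seq[a - 1] + b


def _normalize_deletion(contig_seq: str, pos: int) -> tuple[int, str, str]:
    """Left-shift a 1-bp deletion to the start of its homopolymer run."""
    b = contig_seq[pos - 1]
    while pos > 1 and contig_seq[pos - 2] == b:
        pos -= 1
    return pos, b, ""


def _alignment_edits(
    read: str, contig_seq: str, window_start0: int, loc_start: int, cigar: str
) -> tuple[list[Edit], int, int]:
    edits: list[Edit] = []
    qi = 0
    ti = window_start0 + loc_start  # 0-based contig position
    n_mm = n_ind = 0
    for n, op in _parse_cigar(cigar):
        if op == "=":
            qi += n
            ti += n
        elif op == "X":
            for j in range(n):
                edits.append(
                    Edit("X", ti + j + 1, contig_seq[ti + j], read[qi + j])
                )
            n_mm += n
            qi += n
            ti += n
        elif op == "I":  # extra read base(s)
            pos, ref, alt = _normalize_insertion(contig_seq, ti, read[qi : qi + n])
            edits.append(Edit("I", pos, ref, alt))
            n_ind += 1
            qi += n
        elif op == "D":  # contig base(s) absent from the read
            pos, ref, alt = _normalize_deletion(contig_seq, ti + 1)
            edits.append(Edit("D", pos, ref, alt))
            n_ind += 1
            ti += n
        else:  # pragma: no cover - edlib emits only =XID
            raise ValueError(f"unexpected cigar op {op!r}")
    return edits, n_mm, n_ind


def map_read(
    read: str,
    index: KmerIndex,
    contigs: Mapping[str, str],
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    read_id: str = "read",
) -> ReadAlignment | None:
    """Best-scoring locus for a read, or None when unmapped.

    Seeds require support from at least two non-overlapping k-mers; the
    extension allows at most one 1-bp indel and ``max_mismatches``
    substitutions.  Both orientations are tried.  Reads whose best
    alignment would overhang a contig edge are discarded rather than
    clip-aligned.
    """
    if len(read) < index.k:
        return None
    best: list[tuple[int, str, int, str, str, int, str]] = []
    best_score = None
    for strand, seq in (("+", read), ("-", revcomp(read))):
        for contig, diag, _support in _seed_clusters(seq, index):
            cseq = contigs[contig]
            ws0 = diag - 2
            we0 = diag + len(seq) + 2
            if ws0 < 0 or we0 > len(cseq):
                continue  # soft-discard at contig edges
            res = edlib.align(seq, cseq[ws0:we0], mode="HW", task="path")
            if res["editDistance"] < 0:
                continue
            ops = _parse_cigar(res["cigar"])
            n_mm = sum(n for n, op in ops if op == "X")
            indel_events = [(n, op) for n, op in ops if op in "ID"]
            if n_mm > max_mismatches:
                continue
            if len(indel_events) > 1 or any(n > 1 for n, _ in indel_events):
                continue
            score = res["editDistance"]
            loc = res["locations"][0]
            entry = (score, contig, ws0 + loc[0], strand, res["cigar"], ws0, seq)
            if best_score is None or score < best_score:
                best = [entry]
                best_score = score
            elif score == best_score and (entry[1], entry[2]) not in {
                (e[1], e[2]) for e in best
            }:
                best.append(entry)
    if not best:
        return None
    best.sort(key=lambda e: (e[1], e[2], e[3]))
    score, contig, start0, strand, cigar, ws0, seq = best[0]
    edits, n_mm, n_ind = _alignment_edits(
        seq, contigs[contig], ws0, start0 - ws0, cigar
    )
    ref_span = len(seq) - sum(
        (n if op == "I" else -n) for n, op in _parse_cigar(cigar) if op in "ID"
    )
    return ReadAlignment(
        read_id=read_id,
        contig=contig,
        start=start0 + 1,
        end=start0 + ref_span,
        strand=strand,
        edits=tuple(edits),
        n_mismatches=n_mm,
        n_indels=n_ind,
        unique=len(best) == 1,
        read_length=len(read),
    )


def map_reads(
    reads: Iterable,
    index: KmerIndex,
    contigs: Mapping[str, str],
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> list[ReadAlignment]:
    """Map a collection of reads (objects with .id/.sequence, or plain strings)."""
    out = []
    for i, r in enumerate(reads):
        seq = getattr(r, "sequence", None) or str(r)
        rid = getattr(r, "id", f"read_{i}")
        aln = map_read(seq, index, contigs, max_mismatches=max_mismatches, read_id=rid)
        if aln is not None:
            out.append(aln)
    return out


@dataclass
class PileupColumn:
    contig: str
    position: int
    depth: int
    counts: dict[str, int]  # A/C/G/T counts (deletions excluded)
    insertions: dict[str, int]  # alt allele string -> count (anchored here)
    deletions: int
    fwd_depth: int
    rev_depth: int


class Pileup:
    """Per-position coverage plus the sparse set of non-reference events.

    Internally, depth and strand depth are dense arrays and everything
    that deviates from the contig (mismatches, indels) is an event
    keyed by (contig, pos, kind, ref, alt) with forward/reverse counts;
    a read contributes to the reference base count wherever it has no
    event.  This makes depth = base counts + deletion count by
    construction.
    """

    def __init__(self, contigs: Mapping[str, str]):
        self.contigs = dict(contigs)
        self.depth = {c: np.zeros(len(s) + 1, dtype=np.int32) for c, s in contigs.items()}
        self.fwd = {c: np.zeros(len(s) + 1, dtype=np.int32) for c, s in contigs.items()}
        self.events: dict[tuple[str, int, str, str, str], list[int]] = {}
        self.n_alignments = 0
        self._finalized = False

    def add(self, aln: ReadAlignment) -> None:
        if aln.end > len(self.contigs[aln.contig]):
            logger.warning("alignment %s past contig end rejected", aln.read_id)
            return
        d = self.depth[aln.contig]
        d[aln.start - 1] += 1
        d[aln.end] -= 1
        if aln.strand == "+":
            f = self.fwd[aln.contig]
            f[aln.start - 1] += 1
            f[aln.end] -= 1
        si = 0 if aln.strand == "+" else 1
        for e in aln.edits:
            key = (aln.contig, e.pos, e.kind, e.ref, e.alt)
            self.events.setdefault(key, [0, 0])[si] += 1
        self.n_alignments += 1

    def finalize(self) -> None:
        if not self._finalized:
            for c in self.depth:
                self.depth[c] = np.cumsum(self.depth[c])[:-1]
                self.fwd[c] = np.cumsum(self.fwd[c])[:-1]
            self._finalized = True

    def depth_at(self, contig: str, pos: int) -> int:
        self.finalize()
        return int(self.depth[contig][pos - 1])

    def column(self, contig: str, pos: int) -> PileupColumn:
        self.finalize()
        depth = int(self.depth[contig][pos - 1])
        fwd = int(self.fwd[contig][pos - 1])
        counts = {b: 0 for b in "ACGT"}
        insertions: dict[str, int] = {}
        deletions = 0
        non_ref_here = 0
        for (c, p, kind, ref, alt), (nf, nr) in self.events.items():
            if c != contig or p != pos:
                continue
            n = nf + nr
            if kind == "X":
                counts[alt] += n
                non_ref_here += n
            elif kind == "D":
                deletions += n
                non_ref_here += n
            elif kind == "I":
                insertions[alt] = insertions.get(alt, 0) + n
        ref_base = self.contigs[contig][pos - 1]
        if ref_base in counts:
            counts[ref_base] += depth - non_ref_here
        return PileupColumn(
            contig=contig,
            position=pos,
            depth=depth,
            counts=counts,
            insertions=insertions,
            deletions=deletions,
            fwd_depth=fwd,
            rev_depth=depth - fwd,
        )


def build_pileup(
    alignments: Iterable[ReadAlignment],
    contigs: Mapping[str, str],
    unique_only: bool = True,
) -> Pileup:
    """Accumulate alignments into a pileup; multi-mapping reads excluded by default."""
    pile = Pileup(contigs)
    for aln in alignments:
        if unique_only and not aln.unique:
            continue
        pile.add(aln)
    pile.finalize()
    return pile
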