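"""Mapper and pileup: index completeness, edit handling, brute-force oracle agreement."""

import numpy as np
import pytest

from bactarget import mapping, synthdata as sd
from bactarget.dna import revcomp


def _random_seq(n, seed=0):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[b] for b in rng.integers(0, 4, size=n))


class TestIndex:
    def test_kmer_count_is_length_minus_k_plus_1(self):
        idx = mapping.build_index({"c": "ACGTACGT"}, k=11)  # too short -> skipped
        assert idx.index == {}
        idx = mapping.build_index({"c": _random_seq(100, 1)}, k=11)
        assert sum(len(v) for v in idx.index.values()) == 90

    def test_absent_kmer_has_no_hits(self):
        idx = mapping.build_index({"c": _random_seq(100, 1)}, k=11)
        assert idx.hits("A" * 11) == [] or all(
            "A" * 11 != _random_seq(100, 1)[p : p + 11] for _, p in idx.hits("A" * 11)
        )

    def test_every_indexed_position_recovers_its_kmer(self):
        contigs = {"a": _random_seq(200, 2), "b": _random_seq(150, 3)}
        idx = mapping.build_index(contigs, k=13)
        for kmer, hits in idx.index.items():
            for contig, pos in hits:
                assert contigs[contig][pos : pos + 13] == kmer

    def test_small_k_rejected(self):
        with pytest.raises(ValueError):
            mapping.build_index({"c": _random_seq(100)}, k=5)


@pytest.fixture(scope="module")
def ref():
    contigs = {"c1": _random_seq(3000, 7)}
    return contigs, mapping.build_index(contigs)


class TestMapRead:

    def test_exact_read_maps_uniquely(self, ref):
        contigs, idx = ref
        read = contigs["c1"][500:750]
        aln = mapping.map_read(read, idx, contigs)
        assert aln is not None
        assert (aln.contig, aln.start, aln.strand) == ("c1", 501, "+")
        assert aln.n_mismatches == 0 and aln.unique and aln.edits == ()

    def test_reverse_complement_read(self, ref):
        contigs, idx = ref
        read = revcomp(contigs["c1"][800:1050])
        aln = mapping.map_read(read, idx, contigs)
        assert (aln.contig, aln.start, aln.strand) == ("c1", 801, "-")

    def test_read_with_insertion_yields_one_insertion_edit(self, ref):
        contigs, idx = ref
        seq = contigs["c1"]
        # mutant genome with 1-bp insertion after position 1000
        read = seq[875:1000] + "A" + seq[1000:1124]
        aln = mapping.map_read(read, idx, contigs)
        assert aln.n_indels == 1 and aln.n_mismatches == 0
        ins = [e for e in aln.edits if e.kind == "I"]
        assert len(ins) == 1
        # left-normalized: anchor at the start of the run of inserted base
        e = ins[0]
        p = 1000
        while p > 1 and seq[p - 1] == "A":
            p -= 1
        expected = p + 1 if seq[p] == "A" else p
        assert e.pos in (expected, 1000)

    def test_read_with_deletion(self, ref):
        contigs, idx = ref
        seq = contigs["c1"]
        read = seq[1200:1325] + seq[1326:1451]  # base at 1326 (1-based) deleted
        aln = mapping.map_read(read, idx, contigs)
        assert aln.n_indels == 1
        assert [e.kind for e in aln.edits if e.kind != "X"] == ["D"]

    def test_repeat_read_flagged_non_unique(self):
        unit = _random_seq(600, 9)
        contigs = {"c1": _random_seq(400, 1) + unit + _random_seq(400, 2),
                   "c2": _random_seq(300, 3) + unit + _random_seq(500, 4)}
        idx = mapping.build_index(contigs)
        read = unit[100:350]
        aln = mapping.map_read(read, idx, contigs)
        assert aln is not None and not aln.unique
        # deterministic tie-break: lowest (contig, position)
        assert aln.contig == "c1"

    def test_unmappable_read_returns_none(self, ref):
        contigs, idx = ref
        assert mapping.map_read("A" * 250, idx, contigs) is None

    def test_too_many_mismatches_unmapped(self, ref):
        contigs, idx = ref
        read = list(contigs["c1"][2000:2250])
        for i in range(40, 240, 30):  # 7 scattered mismatches > budget of 5
            read[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[i]]
        assert mapping.map_read("".join(read), idx, contigs) is None


def _brute_force_best(read, contigs, max_mm=5):
    """Exhaustive best locus over all offsets/strands: edit distance with at
    most one 1-bp indel (independent scoring; no seeding, no libraries)."""
    best = None  # (score, contig, pos0, strand)
    for strand, seq in (("+", read), ("-", revcomp(read))):
        L = len(seq)
        for name in sorted(contigs):
            ref = contigs[name]
            for o in range(len(ref) - L + 2):
                # ungapped
                if o + L <= len(ref):
                    mm = sum(a != b for a, b in zip(seq, ref[o : o + L]))
                    cand = [(mm, 0)]
                else:
                    cand = []
                # one read-insertion (read has an extra base): ref span L-1
                if o + L - 1 <= len(ref):
                    pre = np.cumsum(
                        [0] + [seq[i] != ref[o + i] for i in range(L - 1)]
                    )
                    suf = np.cumsum(
                        [0] + [seq[L - 1 - i] != ref[o + L - 2 - i] for i in range(L - 1)]
                    )
                    mm = min(pre[j] + suf[L - 1 - j] for j in range(L))
                    cand.append((int(mm), 1))
                # one read-deletion (ref has an extra base): ref span L+1
                if o + L + 1 <= len(ref):
                    pre = np.cumsum([0] + [seq[i] != ref[o + i] for i in range(L)])
                    suf = np.cumsum(
                        [0] + [seq[L - 1 - i] != ref[o + L - i] for i in range(L)]
                    )
                    mm = min(pre[j] + suf[L - j] for j in range(L + 1))
                    cand.append((int(mm), 1))
                for mm, gap in cand:
                    if mm > max_mm:
                        continue
                    score = mm + gap
                    key = (score, name, o, strand)
                    if best is None or score < best[0]:
                        best = key
    return best


class TestBruteForceOracle:
    def test_agrees_with_exhaustive_alignment(self):
        """On small genomes the seed-and-extend mapper finds the same best
        score as exhaustive scoring over every locus, orientation, and
        single-indel placement."""
        contigs = {"c1": _random_seq(1200, 21), "c2": _random_seq(800, 22)}
        idx = mapping.build_index(contigs)
        rng = np.random.default_rng(5)
        cases = []
        for trial in range(8):
            name = "c1" if trial % 2 == 0 else "c2"
            seq = contigs[name]
            # stay clear of contig edges: edge-overhanging loci are soft-discarded
            o = int(rng.integers(5, len(seq) - 265))
            read = list(seq[o : o + 250])
            for _ in range(int(rng.integers(0, 4))):  # up to 3 errors
                i = int(rng.integers(0, 250))
                read[i] = "ACGT"[int(rng.integers(0, 4))]
            if trial % 3 == 0:  # sometimes add a 1-bp indel
                i = int(rng.integers(30, 220))
                if trial % 2 == 0:
                    read.insert(i, "ACGT"[int(rng.integers(0, 4))])
                else:
                    del read[i]
            cases.append("".join(read))
        for read in cases:
            oracle = _brute_force_best(read, contigs)
            aln = mapping.map_read(read, idx, contigs)
            assert oracle is not None and aln is not None
            assert aln.n_mismatches + aln.n_indels == oracle[0]
            assert (aln.contig, aln.start - 1, aln.strand) == oracle[1:]


class TestPileup:
    def test_identical_reads_pile_to_depth_10(self):
        contigs = {"c": _random_seq(600, 3)}
        idx = mapping.build_index(contigs)
        read = contigs["c"][100:350]
        alns = [
            mapping.map_read(read, idx, contigs, read_id=f"r{i}") for i in range(10)
        ]
        pile = mapping.build_pileup(alns, contigs)
        col = pile.column("c", 200)
        assert col.depth == 10
        assert col.counts[contigs["c"][199]] == 10
        assert sum(col.counts.values()) + col.deletions == col.depth

    def test_strand_depths(self):
        contigs = {"c": _random_seq(600, 3)}
        idx = mapping.build_index(contigs)
        fwd = contigs["c"][100:350]
        rev = revcomp(fwd)
        alns = [mapping.map_read(fwd, idx, contigs) for _ in range(5)] + [
            mapping.map_read(rev, idx, contigs) for _ in range(5)
        ]
        pile = mapping.build_pileup(alns, contigs)
        col = pile.column("c", 200)
        assert col.fwd_depth == 5 and col.rev_depth == 5

    def test_error_free_pileup_is_monoallelic(self):
        g = sd.build_genome(n_contigs=1, total_length=10_000, gene_density=0.2,
                            repeat_spec=None, seed=4)
        reads = sd.simulate_reads(
            g.contigs, sd.ReadSimParams(mean_coverage=10, error_rate=0.0, seed=1)
        )
        idx = mapping.build_index(g.contigs)
        alns = mapping.map_reads(reads, idx, g.contigs)
        pile = mapping.build_pileup(alns, g.contigs)
        assert pile.events == {}  # every column matches the contig base

    def test_mapping_rate_and_mean_coverage(self):
        g = sd.build_genome(n_contigs=1, total_length=20_000, gene_density=0.2,
                            repeat_spec=None, seed=6)
        reads = sd.simulate_reads(
            g.contigs, sd.ReadSimParams(mean_coverage=50, error_rate=0.005, seed=2)
        )
        idx = mapping.build_index(g.contigs)
        alns = mapping.map_reads(reads, idx, g.contigs)
        assert len(alns) / len(reads) >= 0.99
        pile = mapping.build_pileup(alns, g.contigs)
        pile.finalize()
        inner = pile.depth["contig_1"][600:-600]
        assert abs(inner.mean() - 50) / 50 < 0.10
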