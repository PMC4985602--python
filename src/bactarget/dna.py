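"""Small shared DNA/protein helpers (translation table 11, reverse complement)."""

from __future__ import annotations

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

TRANSLATION_TABLE = 11
STOP_CODONS = frozenset(unambiguous_dna_by_id[TRANSLATION_TABLE].stop_codons)
START_CODONS = frozenset({"ATG", "GTG", "TTG"})

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str, *, to_stop: bool = False) -> str:
    """Translate a nucleotide string with the bacterial code (trailing partial codon dropped)."""
    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate(table=TRANSLATION_TABLE, to_stop=to_stop))


def codon_residue(codon: str) -> str:
    """Single-letter residue for a codon; '*' for a stop codon."""
    return translate(codon)
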