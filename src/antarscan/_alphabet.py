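"""Nucleotide alphabet constants shared across the package.

Genomes are stored as DNA (A/C/G/T/N); motif logic operates on an RNA view
(T -> U on the fly). N is permitted in genomes but never inside a motif.
"""

from __future__ import annotations

DNA_ALPHABET = frozenset("ACGTN")
RNA_ALPHABET = frozenset("ACGUN")
NUCLEOTIDES = "ACGU"
NT_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}

_DNA_COMP = str.maketrans("ACGTN", "TGCAN")
_RNA_COMP = str.maketrans("ACGUN", "UGCAN")

#: canonical RNA pairs, wobble included
PAIR_TYPES = ("AU", "UA", "GC", "CG", "GU", "UG")
CANONICAL_PAIRS = frozenset(PAIR_TYPES)

PURINES = frozenset("AG")


def dna_to_rna(seq: str) -> str:
    return seq.replace("T", "U")


def rna_to_dna(seq: str) -> str:
    return seq.replace("U", "T")


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMP)[::-1]


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMP)[::-1]


def is_canonical(a: str, b: str) -> bool:
    return a + b in CANONICAL_PAIRS
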