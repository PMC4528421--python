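"""Genetic-code tables and codon/nucleotide index conversions.

Nucleotides are indexed 0..3 in the fixed order A, C, G, T; codons are
indexed 0..63 as ``16*i1 + 4*i2 + i3``.  The standard genetic code is used
throughout (the heavy-chain locus is nuclear).
"""

from __future__ import annotations

import numpy as np

NUCLEOTIDES = "ACGT"
NT_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

ALL_CODONS = tuple(sorted(_CODON_TABLE))
CODON_INDEX = {c: 16 * NT_INDEX[c[0]] + 4 * NT_INDEX[c[1]] + NT_INDEX[c[2]]
               for c in ALL_CODONS}

#: amino acid (one letter, '*' for stop) indexed by codon index 0..63
AA_BY_CODON = np.array(
    [_CODON_TABLE[a + b + c]
     for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES]
)

#: indices of the 61 sense codons in ascending codon-index order
SENSE_CODONS = np.flatnonzero(AA_BY_CODON != "*")
STOP_CODONS = frozenset(int(i) for i in np.flatnonzero(AA_BY_CODON == "*"))

#: True where a nucleotide pair (i, j) is a transition (A<->G, C<->T)
IS_TRANSITION = np.zeros((4, 4), dtype=bool)
for _i, _j in ((0, 2), (2, 0), (1, 3), (3, 1)):
    IS_TRANSITION[_i, _j] = True


def codon_index(codon: str) -> int:
    """Index 0..63 of a codon string (uppercase ACGT)."""
    return 16 * NT_INDEX[codon[0]] + 4 * NT_INDEX[codon[1]] + NT_INDEX[codon[2]]


def index_codon(idx: int) -> str:
    """Codon string for an index 0..63."""
    return NUCLEOTIDES[(idx >> 4) & 3] + NUCLEOTIDES[(idx >> 2) & 3] + NUCLEOTIDES[idx & 3]


def translate(codon: str) -> str:
    """One-letter amino acid for a codon ('*' for a stop codon)."""
    return _CODON_TABLE[codon.upper()]


def is_stop(idx: int) -> bool:
    return idx in STOP_CODONS


def seq_to_indices(seq: str) -> np.ndarray:
    """Nucleotide string -> int array with A,C,G,T -> 0..3 and anything else -> -1."""
    table = np.full(256, -1, dtype=np.int8)
    for b, i in NT_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].astype(np.int64)


def codon_indices(seq: str) -> np.ndarray:
    """Codon-index array for an in-frame nucleotide string; -1 where any base is ambiguous."""
    nts = seq_to_indices(seq)
    if nts.size % 3:
        raise ValueError("sequence length is not a multiple of 3")
    trip = nts.reshape(-1, 3)
    idx = 16 * trip[:, 0] + 4 * trip[:, 1] + trip[:, 2]
    idx[(trip < 0).any(axis=1)] = -1
    return idx


def substitution_is_synonymous(codon_idx: int, pos: int, new_base: int) -> bool:
    """Classify a single-nucleotide change in a codon.

    Parameters are the current codon index, the position 0..2 within the
    codon, and the replacement base index.  Changes that create a stop codon
    are classified as non-synonymous (they never survive to an observed
    endpoint because stop-containing sequences are filtered upstream).
    """
    shift = (2 - pos) * 2
    new_idx = (codon_idx & ~(3 << shift)) | (new_base << shift)
    a0, a1 = AA_BY_CODON[codon_idx], AA_BY_CODON[new_idx]
    return a0 == a1 and a0 != "*"


def mutate_codon(codon_idx: int, pos: int, new_base: int) -> int:
    """Codon index after replacing the base at ``pos`` with ``new_base``."""
    shift = (2 - pos) * 2
    return (codon_idx & ~(3 << shift)) | (new_base << shift)
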