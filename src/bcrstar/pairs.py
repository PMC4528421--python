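"""Codon-aligned germline/query pair: the unit of the selection analysis.

Both sequences are held as codon-index arrays (0..63) in germline
coordinates; ``-1`` on the query side marks codons the read does not cover
(or covers only partially, or with an ambiguous base).  A codon is part of
the analysis only when both sides are unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codons import AA_BY_CODON


@dataclass
class CodonPair:
    id: str
    germline: np.ndarray  # codon indices, length L
    query: np.ndarray     # codon indices, -1 where uncovered

    def __post_init__(self) -> None:
        self.germline = np.asarray(self.germline, dtype=np.int64)
        self.query = np.asarray(self.query, dtype=np.int64)
        if self.germline.shape != self.query.shape:
            raise ValueError("germline and query must have equal codon length")

    @property
    def n_sites(self) -> int:
        return int(self.germline.size)

    @property
    def covered(self) -> np.ndarray:
        """Mask of codon sites usable for analysis."""
        return (self.query >= 0) & (self.germline >= 0) & (AA_BY_CODON[self.query] != "*")

    def nucleotide_columns(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(site, codon_position, germline_base, query_base) arrays over the
        covered codons, three columns per codon."""
        sel = np.flatnonzero(self.covered)
        sites = np.repeat(sel, 3)
        pos = np.tile(np.arange(3), sel.size)
        shift = (2 - pos) * 2
        g = (self.germline[sites] >> shift) & 3
        q = (self.query[sites] >> shift) & 3
        return sites, pos, g, q

    def position_count_matrices(self) -> np.ndarray:
        """(3, 4, 4) germline->query base count matrices by codon position."""
        _, pos, g, q = self.nucleotide_columns()
        mats = np.zeros((3, 4, 4), dtype=np.int64)
        np.add.at(mats, (pos, g, q), 1)
        return mats

    @property
    def n_mismatches(self) -> int:
        _, _, g, q = self.nucleotide_columns()
        return int((g != q).sum())
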