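"""Germline V/D/J assignment and rearrangement frame classification.

Each observed sequence is locally aligned against every germline V gene;
the 3' portion of the read not covered by the winning V alignment is then
aligned against all D and J genes.  The best raw Smith-Waterman score wins
per segment; score ties are resolved by a seeded random choice among alleles
present at abundance >= 10%.  A rearrangement is *productive* when the V and
J segments are in the same reading frame across the junction,
*out_of_frame* otherwise, and *has_stop* (excluded downstream) when a
templated region contains an in-frame stop codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .align import AlignmentResult, smith_waterman_affine
from .codons import NT_INDEX, seq_to_indices, translate
from .seqio import read_fasta

PRODUCTIVE = "productive"
OUT_OF_FRAME = "out_of_frame"
HAS_STOP = "has_stop"
UNANNOTATABLE = "unannotatable"


@dataclass(frozen=True)
class GermlineGene:
    """A named germline segment sequence.

    ``abundance`` is the allele's frequency within its gene (used only for
    tie-breaking); ``frame`` is the codon phase of the first base relative
    to the gene's reading frame (0 for IMGT-gapped V genes starting at a
    codon boundary).
    """

    name: str
    segment: str  # 'V', 'D' or 'J'
    nucleotides: str
    abundance: float = 1.0
    frame: int = 0

    def __post_init__(self) -> None:
        if self.segment not in ("V", "D", "J"):
            raise ValueError(f"bad segment {self.segment!r}")
        if not self.nucleotides:
            raise ValueError(f"{self.name}: empty sequence")
        if not 0.0 <= self.abundance <= 1.0:
            raise ValueError(f"{self.name}: abundance outside [0, 1]")


def read_germline_db(path: str | Path) -> list[GermlineGene]:
    """Read a germline database FASTA with headers ``name|segment|abundance[|frame]``."""
    genes = []
    for header, seq in read_fasta(path):
        parts = header.split("|")
        if len(parts) < 3:
            raise ValueError(f"germline header {header!r}: expected name|segment|abundance")
        frame = int(parts[3]) if len(parts) > 3 else 0
        genes.append(GermlineGene(parts[0], parts[1], seq, float(parts[2]), frame))
    return genes


def write_germline_db(path: str | Path, genes) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f">{g.name}|{g.segment}|{g.abundance:g}|{g.frame}\n{g.nucleotides}\n")


@dataclass
class SegmentHit:
    gene: GermlineGene
    alignment: AlignmentResult
    query_offset: int = 0  # offset of the aligned subsequence within the full query

    @property
    def query_interval(self) -> tuple[int, int]:
        a, b = self.alignment.query_interval
        return a + self.query_offset, b + self.query_offset

    @property
    def mismatches(self) -> int:
        n = 0
        for q, r in self.alignment.pairs:
            if q is None or r is None:
                continue
            if self.gene.nucleotides[r] != self._query[q]:
                n += 1
        return n


@dataclass
class AnnotatedPair:
    """An observed sequence aligned to its assigned germline template.

    Per-query-position arrays give the aligned germline base (index 0..3,
    -1 where non-templated or gapped), the segment label and, for V columns,
    the coordinate within the germline V gene.  N-region columns are
    excluded from all evolutionary analyses.
    """

    query_id: str
    query: str
    v_gene: GermlineGene
    j_gene: GermlineGene | None
    d_gene: GermlineGene | None
    frame_class: str
    germline_nt: np.ndarray = field(repr=False)
    query_nt: np.ndarray = field(repr=False)
    segment_labels: np.ndarray = field(repr=False)  # 'V','N1','D','N2','J' or ''
    v_ref_positions: np.ndarray = field(repr=False)
    v_mismatches: int = 0
    junction: str = ""

    def segment_count_matrix(self, segment: str) -> np.ndarray:
        """4x4 germline->query substitution count matrix for one segment."""
        sel = (self.segment_labels == segment) & (self.germline_nt >= 0) & (self.query_nt >= 0)
        mat = np.zeros((4, 4), dtype=np.int64)
        np.add.at(mat, (self.germline_nt[sel], self.query_nt[sel]), 1)
        return mat

    def v_codon_alignment(self) -> tuple[np.ndarray, np.ndarray]:
        """(germline_bases, query_bases) in germline-V coordinates, -1 where uncovered.

        Arrays span the whole germline V gene; positions not covered by the
        read (or aligned through an indel / ambiguous base) are -1 on the
        query side.
        """
        glen = len(self.v_gene.nucleotides)
        g = seq_to_indices(self.v_gene.nucleotides)
        q = np.full(glen, -1, dtype=np.int64)
        sel = (self.segment_labels == "V") & (self.v_ref_positions >= 0)
        q[self.v_ref_positions[sel]] = self.query_nt[sel]
        return g, q


def _choose_hit(hits: list[SegmentHit], rng: np.random.Generator) -> SegmentHit:
    """Best raw score; ties broken randomly among alleles at abundance >= 0.10."""
    best = max(h.alignment.score for h in hits)
    tied = [h for h in hits if h.alignment.score == best]
    if len(tied) == 1:
        return tied[0]
    tied.sort(key=lambda h: h.gene.name)
    common = [h for h in tied if h.gene.abundance >= 0.10]
    pool = common if common else tied
    return pool[int(rng.integers(len(pool)))]


def _phase_at(query_pos: int, hit: SegmentHit) -> int:
    """Codon phase at ``query_pos`` implied by a segment alignment.

    Propagated from the nearest aligned column, so junction positions get
    the phase the germline reading frame would predict.
    """
    anchor_q, anchor_r = None, None
    for q, r in hit.alignment.pairs:
        if q is None or r is None:
            continue
        anchor_q, anchor_r = q + hit.query_offset, r
        if anchor_q >= query_pos:
            break
    phase_r = (anchor_r - hit.gene.frame) % 3
    return (phase_r + (query_pos - anchor_q)) % 3


class VDJAnnotator:
    """Assigns germline V/D/J genes to query sequences by local alignment."""

    def __init__(
        self,
        germline_db: list[GermlineGene],
        match: int = 2,
        mismatch: int = -3,
        gap_open: int = 5,
        gap_extend: int = 1,
        min_score_fraction: float = 0.5,
        seed: int = 0,
    ):
        self.v_genes = [g for g in germline_db if g.segment == "V"]
        self.d_genes = [g for g in germline_db if g.segment == "D"]
        self.j_genes = [g for g in germline_db if g.segment == "J"]
        if not self.v_genes or not self.j_genes:
            raise ValueError("germline db must contain at least one V and one J gene")
        self.scoring = dict(match=match, mismatch=mismatch,
                            gap_open=gap_open, gap_extend=gap_extend)
        # minimum acceptable segment score: fraction of a 20-nt perfect match
        self.min_score = min_score_fraction * 20 * match
        self.rng = np.random.default_rng(seed)

    def _align_all(self, query: str, genes, offset: int = 0) -> list[SegmentHit]:
        hits = []
        for gene in genes:
            aln = smith_waterman_affine(query, gene.nucleotides, **self.scoring)
            hit = SegmentHit(gene, aln, offset)
            hit._query = query  # for mismatch counting
            hits.append(hit)
        return hits

    def annotate(self, query_id: str, query: str) -> AnnotatedPair | None:
        """Annotate one sequence; returns None when unannotatable."""
        query = query.upper()
        v_hit = _choose_hit(self._align_all(query, self.v_genes), self.rng)
        if v_hit.alignment.score < self.min_score:
            return None
        v_end = v_hit.query_interval[1]
        tail = query[v_end:]
        j_hit = d_hit = None
        if tail:
            j_hits = self._align_all(tail, self.j_genes, offset=v_end)
            j_hit = _choose_hit(j_hits, self.rng)
            if j_hit.alignment.score < self.min_score:
                j_hit = None
        if j_hit is not None and self.d_genes:
            mid = query[v_end:j_hit.query_interval[0]]
            if len(mid) >= 5:
                d_hits = self._align_all(mid, self.d_genes, offset=v_end)
                d_best = _choose_hit(d_hits, self.rng)
                if d_best.alignment.score >= self.scoring["match"] * 5:
                    d_hit = d_best
        return self._build_pair(query_id, query, v_hit, d_hit, j_hit)

    def _build_pair(self, query_id, query, v_hit, d_hit, j_hit) -> AnnotatedPair:
        n = len(query)
        germ = np.full(n, -1, dtype=np.int64)
        labels = np.full(n, "", dtype="U2")
        vref = np.full(n, -1, dtype=np.int64)
        qnt = seq_to_indices(query)

        def paint(hit: SegmentHit, label: str, ref_track: bool = False) -> None:
            for q, r in hit.alignment.pairs:
                if q is None or r is None:
                    continue
                pos = q + hit.query_offset
                germ[pos] = NT_INDEX.get(hit.gene.nucleotides[r], -1)
                labels[pos] = label
                if ref_track:
                    vref[pos] = r

        paint(v_hit, "V", ref_track=True)
        if d_hit is not None:
            paint(d_hit, "D")
        if j_hit is not None:
            paint(j_hit, "J")
        # label the non-templated columns between segments
        v_end = v_hit.query_interval[1]
        j_start = j_hit.query_interval[0] if j_hit is not None else n
        if d_hit is not None:
            d0, d1 = d_hit.query_interval
            labels[(labels == "") & (np.arange(n) >= v_end) & (np.arange(n) < d0)] = "N1"
            labels[(labels == "") & (np.arange(n) >= d1) & (np.arange(n) < j_start)] = "N2"
        else:
            labels[(labels == "") & (np.arange(n) >= v_end) & (np.arange(n) < j_start)] = "N1"

        junction = query[v_end:j_start]
        if j_hit is None:
            frame_class = UNANNOTATABLE
        else:
            frame_class = classify_frame(query, v_hit, j_hit)
        pair = AnnotatedPair(
            query_id=query_id, query=query,
            v_gene=v_hit.gene, j_gene=j_hit.gene if j_hit else None,
            d_gene=d_hit.gene if d_hit else None,
            frame_class=frame_class,
            germline_nt=germ, query_nt=qnt, segment_labels=labels,
            v_ref_positions=vref,
            v_mismatches=v_hit.mismatches, junction=junction,
        )
        return pair


def classify_frame(query: str, v_hit: SegmentHit, j_hit: SegmentHit) -> str:
    """Productive iff V and J imply the same reading frame across the junction."""
    j_start = j_hit.query_interval[0]
    phase_from_v = _phase_at(j_start, v_hit)
    phase_from_j = _phase_at(j_start, j_hit)
    if phase_from_v != phase_from_j:
        return OUT_OF_FRAME
    if _has_templated_stop(query, v_hit, j_hit):
        return HAS_STOP
    return PRODUCTIVE


def _has_templated_stop(query: str, v_hit: SegmentHit, j_hit: SegmentHit) -> bool:
    """Scan in-frame codons (V-derived frame) of the templated span for stops."""
    v_start = v_hit.query_interval[0]
    phase = _phase_at(v_start, v_hit)
    first = v_start + ((3 - phase) % 3)
    end = j_hit.query_interval[1]
    for i in range(first, end - 2, 3):
        codon = query[i:i + 3]
        if set(codon) <= set("ACGT") and translate(codon) == "*":
            return True
    return False


def write_aligned_pairs(path, pairs: list[AnnotatedPair]) -> None:
    """Write germline-template/query pairs as FASTA, one record pair per
    sequence; non-templated columns are '-' on the germline side."""
    from .codons import NUCLEOTIDES

    with open(path, "w") as fh:
        for p in pairs:
            template = "".join(NUCLEOTIDES[b] if b >= 0 else "-"
                               for b in p.germline_nt)
            fh.write(f">{p.query_id}|germline {p.v_gene.name}\n{template}\n")
            fh.write(f">{p.query_id}|query\n{p.query}\n")


def annotation_table(pairs: list[AnnotatedPair]):
    """Annotation summary as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    rows = [
        dict(query_id=p.query_id, v_gene=p.v_gene.name,
             d_gene=p.d_gene.name if p.d_gene else "",
             j_gene=p.j_gene.name if p.j_gene else "",
             frame_class=p.frame_class, v_mismatches=p.v_mismatches,
             junction=p.junction)
        for p in pairs
    ]
    return pd.DataFrame(rows)
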