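"""FASTA/TSV input-output and well-level consensus collapsing.

Deep repertoire sequencing "over-sequences" each template so that several
reads of the same molecule land in the same plate well.  Reads within a well
are grouped by single-linkage at Hamming distance <= 2 and each group is
reduced to a per-position majority (parsimony) consensus; groups with a
single member are discarded, which suppresses sequencing error at the cost
of singleton templates.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path

from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger(__name__)

_ALPHABET = set("ACGTN")


class FastaParseError(ValueError):
    """Raised for structurally invalid FASTA input; names the offending line."""


@dataclass(frozen=True)
class Read:
    """A single sequencing read with its well-of-origin label."""

    id: str
    well: str
    nucleotides: str

    def __post_init__(self) -> None:
        if not self.nucleotides:
            raise ValueError(f"read {self.id}: empty sequence")
        bad = set(self.nucleotides) - _ALPHABET
        if bad:
            raise ValueError(f"read {self.id}: invalid characters {sorted(bad)}")


@dataclass(frozen=True)
class ConsensusSequence:
    """Majority consensus of a group of >= 2 reads collapsed within one well."""

    nucleotides: str
    support: int
    well: str

    def __post_init__(self) -> None:
        if self.support < 2:
            raise ValueError("consensus support must be >= 2 (singletons are discarded)")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into an order-preserving list of (id, sequence).

    Sequences are uppercased with whitespace removed.  Duplicate ids are
    kept (a warning is logged).  Empty files and sequence data before the
    first header raise :class:`FastaParseError` naming the line.
    """
    path = Path(path)
    with open(path) as handle:
        first = None
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                first = (lineno, line)
                break
        if first is None:
            raise FastaParseError(f"{path}: empty FASTA file")
        if not first[1].startswith(">"):
            raise FastaParseError(
                f"{path}: line {first[0]}: expected '>' header, got {first[1].strip()!r}"
            )
    with open(path) as handle:
        records = [(header.split()[0], "".join(seq.split()).upper())
                   for header, seq in SimpleFastaParser(handle)]
    seen: Counter[str] = Counter(rid for rid, _ in records)
    for rid, k in seen.items():
        if k > 1:
            logger.warning("duplicate FASTA id %r (%d records kept)", rid, k)
    return records


def write_fasta(path: str | Path, records, width: int = 70) -> None:
    """Write (id, sequence) pairs as FASTA with line wrapping."""
    with open(path, "w") as handle:
        for rid, seq in records:
            handle.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i:i + width] + "\n")


def read_well_map(path: str | Path) -> dict[str, str]:
    """Read a TSV with columns read_id, well_id into a dict."""
    mapping: dict[str, str] = {}
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header[:2] != ["read_id", "well_id"]:
            raise ValueError(f"{path}: expected columns read_id, well_id; got {header}")
        for line in handle:
            if not line.strip():
                continue
            rid, well = line.rstrip("\n").split("\t")[:2]
            mapping[rid] = well
    return mapping


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("Hamming distance undefined for unequal lengths")
    return sum(x != y for x, y in zip(a, b))


def _majority_consensus(seqs: list[str]) -> str:
    """Per-position majority; ties broken in alphabet order A<C<G<T; N votes
    ignored unless every read has N at the position."""
    out = []
    for column in zip(*seqs):
        votes = Counter(b for b in column if b != "N")
        if not votes:
            out.append("N")
            continue
        best = max(votes.items(), key=lambda kv: (kv[1], -("ACGT".index(kv[0]))))
        out.append(best[0])
    return "".join(out)


def _single_linkage_groups(seqs: list[str], max_dist: int) -> list[list[int]]:
    """Connected components of the <=max_dist Hamming graph (equal lengths only)."""
    n = len(seqs)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if len(seqs[i]) == len(seqs[j]) and hamming(seqs[i], seqs[j]) <= max_dist:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[int]] = defaultdict(list)
    for i in range(n):
        groups[find(i)].append(i)
    return [groups[r] for r in sorted(groups)]


def collapse_well(reads: list[Read], max_dist: int = 2) -> list[ConsensusSequence]:
    """Collapse the reads of one well into majority-consensus sequences.

    Reads are joined by single-linkage transitive closure at Hamming
    distance <= ``max_dist``; reads of unequal length are never joined.
    Each group of size >= 2 yields one consensus; singletons are discarded.
    The result is invariant to input order (groups are emitted sorted by
    consensus sequence).
    """
    if not reads:
        return []
    wells = {r.well for r in reads}
    if len(wells) != 1:
        raise ValueError(f"collapse_well expects reads from a single well, got {sorted(wells)}")
    order = sorted(range(len(reads)), key=lambda i: (reads[i].nucleotides, reads[i].id))
    seqs = [reads[i].nucleotides for i in order]
    out = []
    for group in _single_linkage_groups(seqs, max_dist):
        if len(group) < 2:
            continue
        out.append(ConsensusSequence(
            nucleotides=_majority_consensus([seqs[i] for i in group]),
            support=len(group),
            well=reads[0].well,
        ))
    out.sort(key=lambda c: c.nucleotides)
    return out


def collapse_reads(reads: list[Read], max_dist: int = 2) -> list[ConsensusSequence]:
    """Collapse reads well by well (wells are independent)."""
    by_well: dict[str, list[Read]] = defaultdict(list)
    for r in reads:
        by_well[r.well].append(r)
    out: list[ConsensusSequence] = []
    for well in sorted(by_well):
        out.extend(collapse_well(by_well[well], max_dist=max_dist))
    return out


def write_consensus_fasta(path: str | Path, consensuses) -> None:
    """Write consensus sequences with support/well key-value tags in headers."""
    records = [
        (f"consensus_{i} support={c.support} well={c.well}", c.nucleotides)
        for i, c in enumerate(consensuses)
    ]
    with open(path, "w") as handle:
        for rid, seq in records:
            handle.write(f">{rid}\n{seq}\n")
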