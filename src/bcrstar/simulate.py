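"""Synthetic-data generation: GY94 star-tree codon simulation and a BCR
repertoire generator with motif-biased hypermutation.

The GY94 simulator evolves each sequence independently from a known root
along a fixed-length branch by exact continuous-time Markov simulation
(Gillespie per codon site), with per-site selection multipliers ``omega``.
Branch lengths are in expected substitutions per codon site at ``omega = 1``
(the normalization is computed at neutrality, so changing ``omega`` changes
the realized rate, as it should).

The repertoire generator emulates the structure of deep BCR sequencing
data: V(D)J rearrangements with junctional deletion and non-templated
insertion, a configurable fraction of out-of-frame rearrangements,
context-(motif-)biased point mutation, per-site selective filtering applied
only to productive sequences, and left-truncated read coverage.  Every
simulation emits machine-readable truth alongside the sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotate import GermlineGene, OUT_OF_FRAME, PRODUCTIVE
from .codons import (AA_BY_CODON, IS_TRANSITION, NUCLEOTIDES, SENSE_CODONS,
                     index_codon, mutate_codon, seq_to_indices, translate)
from .pairs import CodonPair

# ---------------------------------------------------------------------------
# GY94 codon model


def _single_step_table():
    """All ordered sense-codon pairs differing at exactly one position.

    Returns arrays (i, j, transition?, synonymous?) over sense-codon
    *local* indices 0..60.
    """
    sense = SENSE_CODONS
    local = {int(c): k for k, c in enumerate(sense)}
    rows, cols, is_ts, is_syn = [], [], [], []
    for ci in sense:
        for pos in range(3):
            shift = (2 - pos) * 2
            old_base = (ci >> shift) & 3
            for nb in range(4):
                if nb == old_base:
                    continue
                cj = mutate_codon(int(ci), pos, nb)
                if AA_BY_CODON[cj] == "*":
                    continue
                rows.append(local[int(ci)])
                cols.append(local[cj])
                is_ts.append(IS_TRANSITION[old_base, nb])
                is_syn.append(AA_BY_CODON[ci] == AA_BY_CODON[cj])
    return (np.array(rows), np.array(cols),
            np.array(is_ts, dtype=bool), np.array(is_syn, dtype=bool))


_STEP_I, _STEP_J, _STEP_TS, _STEP_SYN = _single_step_table()


@dataclass
class GY94Params:
    """Goldman-Yang codon model parameters for a star-tree simulation.

    ``omega`` may be a scalar or a length-L array of per-site selection
    multipliers; ``codon_frequencies`` is a 61-simplex over sense codons in
    ascending codon-index order (uniform by default, i.e. F61 with equal
    frequencies); ``t`` is the branch length in expected substitutions per
    codon site at ``omega = 1``.
    """

    kappa: float = 2.0
    omega: float | np.ndarray = 1.0
    codon_frequencies: np.ndarray | None = None
    t: float = 0.05

    def __post_init__(self) -> None:
        if self.codon_frequencies is None:
            self.codon_frequencies = np.full(61, 1.0 / 61.0)
        self.codon_frequencies = np.asarray(self.codon_frequencies, dtype=float)
        if self.codon_frequencies.shape != (61,) or (self.codon_frequencies < 0).any():
            raise ValueError("codon_frequencies must be a 61-vector of non-negative reals")
        self.codon_frequencies = self.codon_frequencies / self.codon_frequencies.sum()
        if np.any(np.asarray(self.omega) <= 0):
            raise ValueError("omega must be positive")

    def omega_at(self, site: int) -> float:
        w = np.asarray(self.omega)
        return float(w) if w.ndim == 0 else float(w[site])


def gy94_q(params: GY94Params, site: int = 0) -> np.ndarray:
    """61x61 GY94 rate matrix for one site (sense codons, ascending index).

    Off-diagonal entries are nonzero only for single-nucleotide changes:
    ``q_xy = pi_y * kappa^[transition] * omega_l^[non-synonymous]``,
    normalized so the expected rate at stationarity is 1 when ``omega = 1``.
    """
    w = params.omega_at(site)
    pi = params.codon_frequencies
    q = np.zeros((61, 61))
    base = pi[_STEP_J] * np.where(_STEP_TS, params.kappa, 1.0)
    q[_STEP_I, _STEP_J] = base * np.where(_STEP_SYN, 1.0, w)
    neutral = np.zeros((61, 61))
    neutral[_STEP_I, _STEP_J] = base
    np.fill_diagonal(neutral, -neutral.sum(axis=1))
    scale = -(pi * np.diag(neutral)).sum()
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q / scale


def stop_codon_q_index(codon_idx: int) -> None:
    if AA_BY_CODON[codon_idx] == "*":
        raise ValueError(f"stop codon {index_codon(codon_idx)} has no row in the GY94 matrix")


def simulate_star(
    root_codons: np.ndarray,
    n_seqs: int,
    t: float,
    params: GY94Params,
    seed: int | np.random.Generator = 0,
    return_counts: bool = False,
):
    """Evolve ``n_seqs`` sequences independently from the root along branch t.

    ``root_codons`` are codon indices 0..63 (no stops).  Returns an
    (n_seqs, L) codon-index array; with ``return_counts`` also the true
    per-site non-synonymous and synonymous event counts summed over
    sequences (the simulation truth).  Exact Gillespie simulation per site.
    """
    rng = np.random.default_rng(seed)
    root = np.asarray(root_codons)
    if np.any(AA_BY_CODON[root] == "*"):
        raise ValueError("root contains a stop codon")
    local = np.full(64, -1, dtype=np.int64)
    local[SENSE_CODONS] = np.arange(61)
    L = root.size
    out = np.empty((n_seqs, L), dtype=np.int64)
    true_n = np.zeros(L)
    true_s = np.zeros(L)
    aa = AA_BY_CODON[SENSE_CODONS]
    for l in range(L):
        q = gy94_q(params, l)
        exit_rate = -np.diag(q)
        jump_p = q.copy()
        np.fill_diagonal(jump_p, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            jump_p = jump_p / exit_rate[:, None]
        start = local[root[l]]
        # first waiting time for every sequence at once; most exceed t
        wait = rng.exponential(1.0, size=n_seqs) / exit_rate[start]
        states = np.full(n_seqs, start)
        active = np.flatnonzero(wait < t)
        for k in active:
            s = start
            elapsed = wait[k]
            while elapsed < t:
                s_new = rng.choice(61, p=jump_p[s])
                if aa[s_new] == aa[s]:
                    true_s[l] += 1
                else:
                    true_n[l] += 1
                s = s_new
                rate = exit_rate[s]
                if rate <= 0:
                    break
                elapsed += rng.exponential(1.0 / rate)
            states[k] = s
        out[:, l] = SENSE_CODONS[states]
    if return_counts:
        return out, true_n, true_s
    return out


# ---------------------------------------------------------------------------
# Coverage


@dataclass
class CoverageScheme:
    """Left-truncation plan: each sequence starts at one of a few codon
    positions with given probabilities and covers through the end.

    ``blocks`` is a list of (probability, start_codon); probabilities must
    sum to 1.
    """

    blocks: list[tuple[float, int]]

    def __post_init__(self) -> None:
        probs = [p for p, _ in self.blocks]
        if any(p < 0 or p > 1 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("block probabilities must be in [0,1] and sum to 1")

    @classmethod
    def full(cls) -> "CoverageScheme":
        return cls([(1.0, 0)])

    @classmethod
    def validation(cls) -> "CoverageScheme":
        """No coverage of the first 10 codons; half the sequences cover
        codons 10..L, the other half only 50..L."""
        return cls([(0.5, 10), (0.5, 50)])


def apply_coverage(
    alignment: np.ndarray,
    scheme: CoverageScheme,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mask codons outside each sequence's covered interval with -1.

    Returns (masked alignment, per-sequence start codon).
    """
    rng = np.random.default_rng(seed)
    n, L = alignment.shape
    probs = np.array([p for p, _ in scheme.blocks])
    start_opts = np.array([s for _, s in scheme.blocks])
    starts = start_opts[rng.choice(len(start_opts), size=n, p=probs)]
    masked = alignment.copy()
    cols = np.arange(L)
    masked[cols[None, :] < starts[:, None]] = -1
    return masked, starts


# ---------------------------------------------------------------------------
# The validation-design preset


@dataclass
class ValidationData:
    """A star-tree GY94 simulation with the three-tier omega layout and
    left-truncated coverage, plus full truth."""

    germline: np.ndarray          # codon indices, length L
    pairs: list[CodonPair]
    true_omega: np.ndarray        # length L
    coverage_start: np.ndarray    # per-sequence start codon
    params: GY94Params
    true_n_events: np.ndarray | None = None   # per-site truth, pre-coverage
    true_s_events: np.ndarray | None = None

    def truth_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "site": np.arange(self.true_omega.size),
            "true_omega": self.true_omega,
            "coverage": [(np.array([p.query[l] for p in self.pairs]) >= 0).sum()
                         for l in range(self.true_omega.size)],
        })


def validation_omega_layout(L: int = 100) -> np.ndarray:
    """85 purifying sites (omega 0.1), 5 neutral (1.0), 10 positive (10.0)."""
    if L != 100:
        raise ValueError("the validation layout is defined for L = 100")
    return np.concatenate([np.full(85, 0.1), np.full(5, 1.0), np.full(10, 10.0)])


def simulate_validation(
    n_seqs: int = 1000,
    t: float = 0.05,
    kappa: float = 2.0,
    seed: int = 0,
) -> ValidationData:
    """The full validation design: GY94 star simulation of 100-codon
    sequences at branch length ``t`` with the three-tier omega layout and
    the 0%/50%/100% coverage blocks."""
    rng = np.random.default_rng(seed)
    omega = validation_omega_layout()
    params = GY94Params(kappa=kappa, omega=omega, t=t)
    root = SENSE_CODONS[rng.choice(61, size=100, p=params.codon_frequencies)]
    aln, true_n, true_s = simulate_star(root, n_seqs, t, params, rng,
                                        return_counts=True)
    masked, starts = apply_coverage(aln, CoverageScheme.validation(), rng)
    pairs = [CodonPair(id=f"sim_{i}", germline=root, query=masked[i])
             for i in range(n_seqs)]
    return ValidationData(germline=root, pairs=pairs, true_omega=omega,
                          coverage_start=starts, params=params,
                          true_n_events=true_n, true_s_events=true_s)


# ---------------------------------------------------------------------------
# Nucleotide-level GTR+Gamma star-tree pair simulation


def simulate_gtr_pairs(
    n_pairs: int,
    site_counts: dict[str, int],
    gtr: dict,
    gamma_shape: dict[str, float],
    relative_rate: dict[str, float],
    t,
    seed: int | np.random.Generator = 0,
    n_categories: int = 4,
):
    """Simulate germline-query pairs under a partitioned GTR+Gamma model.

    For each pair and segment, sites draw an i.i.d. discrete-Gamma rate
    category and a germline base from the stationary frequencies; the query
    base is drawn from ``P(t_i * r_seg * rate_c)``.  Returns
    (list of PairCounts, branch-length array) -- count matrices are the
    sufficient statistics for star-tree fitting.
    """
    from .starmodel import PairCounts
    from .substitution import EigenQ, build_q, discrete_gamma_rates

    rng = np.random.default_rng(seed)
    t = np.broadcast_to(np.asarray(t, dtype=float), (n_pairs,)).copy()
    eigs = {s: EigenQ(build_q(gtr[s]), gtr[s].base_frequencies) for s in site_counts}
    rates = {s: discrete_gamma_rates(gamma_shape[s], n_categories) for s in site_counts}
    pairs = []
    for i in range(n_pairs):
        counts = {}
        for s, L in site_counts.items():
            p_cat = eigs[s].expm(t[i] * relative_rate.get(s, 1.0) * rates[s])  # (C,4,4)
            cats = rng.integers(n_categories, size=L)
            g = rng.choice(4, size=L, p=gtr[s].base_frequencies)
            rows = p_cat[cats, g]                      # (L, 4)
            u = rng.random(L)
            q = (u[:, None] > np.cumsum(rows, axis=1)).sum(axis=1)
            mat = np.zeros((4, 4), dtype=np.int64)
            np.add.at(mat, (g, q), 1)
            counts[s] = mat
        pairs.append(PairCounts(id=f"pair_{i}", counts=counts))
    return pairs, t


# ---------------------------------------------------------------------------
# Repertoire simulation


def toy_germline_db(seed: int = 0, n_v: int = 2, v_len: int = 150,
                    n_j: int = 2, j_len: int = 36) -> list[GermlineGene]:
    """A small synthetic germline database (stop-free in-frame V genes)."""
    rng = np.random.default_rng(seed)
    genes = []
    for k in range(n_v):
        while True:
            seq = "".join(rng.choice(list(NUCLEOTIDES), size=v_len))
            if all(translate(seq[i:i + 3]) != "*" for i in range(0, v_len - 2, 3)):
                break
        genes.append(GermlineGene(f"SYNV{k + 1}-1*01", "V", seq, abundance=1.0, frame=0))
    for k in range(2):
        seq = "".join(rng.choice(list(NUCLEOTIDES), size=15))
        genes.append(GermlineGene(f"SYND{k + 1}-1*01", "D", seq, abundance=1.0))
    for k in range(n_j):
        while True:
            seq = "".join(rng.choice(list(NUCLEOTIDES), size=j_len))
            if all(translate(seq[i:i + 3]) != "*" for i in range(0, j_len - 2, 3)):
                break
        genes.append(GermlineGene(f"SYNJ{k + 1}*01", "J", seq, abundance=1.0, frame=0))
    return genes


@dataclass
class RepertoireConfig:
    """Settings for the synthetic BCR repertoire generator.

    ``hotspot_motifs`` maps an IUPAC motif to (offset of the mutating base
    within the motif, rate multiplier); the defaults are the classic AID
    WRC/GYW hotspots at 1x (no bias) unless overridden.  ``selection`` maps
    germline-V codon sites to the probability that a non-synonymous change
    is *accepted* in a productive sequence (1.0 everywhere = no selection);
    it is never applied to out-of-frame sequences.
    """

    germline_db: list[GermlineGene] = field(default_factory=toy_germline_db)
    fraction_out_of_frame: float = 0.25
    shm_rate: float = 0.02
    hotspot_motifs: dict[str, tuple[int, float]] = field(default_factory=dict)
    selection: dict[int, float] = field(default_factory=dict)
    read_window: int | None = None
    n1_length_range: tuple[int, int] = (2, 8)
    v_deletion_range: tuple[int, int] = (0, 3)
    j_deletion_range: tuple[int, int] = (0, 3)

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_out_of_frame <= 1.0:
            raise ValueError("fraction_out_of_frame must be in [0, 1]")
        if not 0.0 <= self.shm_rate < 1.0:
            raise ValueError("shm_rate must be in [0, 1)")
        if any(not 0.0 <= p <= 1.0 for p in self.selection.values()):
            raise ValueError("selection acceptance probabilities must be in [0, 1]")


_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "W": "AT", "S": "CG", "R": "AG", "Y": "CT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


def motif_multipliers(seq: str, motifs: dict[str, tuple[int, float]]) -> np.ndarray:
    """Per-position mutation-rate multipliers from IUPAC context motifs.

    A position matched by several motifs takes the largest multiplier.
    """
    mult = np.ones(len(seq))
    for motif, (offset, factor) in motifs.items():
        m = len(motif)
        for start in range(len(seq) - m + 1):
            if all(seq[start + k] in _IUPAC[motif[k]] for k in range(m)):
                pos = start + offset
                mult[pos] = max(mult[pos], factor)
    return mult


@dataclass
class SimulatedSequence:
    """One simulated rearrangement with its truth labels."""

    id: str
    sequence: str
    v_gene: str
    j_gene: str
    frame_class: str
    v_start: int          # first germline-V position covered by the read
    v_end: int            # germline-V coverage end (exclusive)
    mutated_v_positions: tuple[int, ...]  # germline-V coordinates


@dataclass
class SimulatedRepertoire:
    sequences: list[SimulatedSequence]
    config: RepertoireConfig

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for s in self.sequences:
                fh.write(f">{s.id}\n{s.sequence}\n")

    def truth_frame(self):
        import pandas as pd

        return pd.DataFrame([
            dict(id=s.id, v_gene=s.v_gene, j_gene=s.j_gene,
                 frame_class=s.frame_class, v_start=s.v_start, v_end=s.v_end,
                 n_mutations=len(s.mutated_v_positions),
                 mutated_v_positions=",".join(map(str, s.mutated_v_positions)))
            for s in self.sequences
        ])

    def write_truth(self, path: str | Path) -> None:
        self.truth_frame().to_csv(path, sep="\t", index=False)

    def v_codon_pairs(self, v_gene: str) -> tuple[list[CodonPair], list[str]]:
        """Truth-based codon-aligned pairs in germline-V coordinates.

        Returns (pairs, frame_class labels) for sequences assigned to
        ``v_gene``; codons partially covered or containing an ambiguous
        base are masked.
        """
        gene = next(g for g in self.config.germline_db
                    if g.segment == "V" and g.name == v_gene)
        g_nt = seq_to_indices(gene.nucleotides)
        L = len(gene.nucleotides) // 3
        g_cod = (16 * g_nt[0:3 * L:3] + 4 * g_nt[1:3 * L:3] + g_nt[2:3 * L:3])
        pairs, labels = [], []
        for s in self.sequences:
            if s.v_gene != v_gene:
                continue
            q_nt = np.full(len(gene.nucleotides), -1, dtype=np.int64)
            read_v = seq_to_indices(s.sequence)[: s.v_end - s.v_start]
            q_nt[s.v_start:s.v_end] = read_v
            trip = q_nt[:3 * L].reshape(-1, 3)
            q_cod = 16 * trip[:, 0] + 4 * trip[:, 1] + trip[:, 2]
            q_cod[(trip < 0).any(axis=1)] = -1
            pairs.append(CodonPair(id=s.id, germline=g_cod.copy(), query=q_cod))
            labels.append(s.frame_class)
        return pairs, labels


def simulate_repertoire(
    config: RepertoireConfig,
    n: int,
    seed: int | np.random.Generator = 0,
) -> SimulatedRepertoire:
    """Generate ``n`` rearranged, hypermutated sequences with truth labels.

    Construction per sequence: choose V and J (abundance-weighted), delete
    junction nucleotides, insert a non-templated region whose length is
    adjusted to realize the drawn frame class, apply motif-biased point
    mutation, reject non-synonymous changes at selected sites of productive
    sequences, revert mutations creating in-frame stop codons, and finally
    truncate to the read window (3' anchored, as in short-read BCR assays).
    """
    rng = np.random.default_rng(seed)
    v_genes = [g for g in config.germline_db if g.segment == "V"]
    j_genes = [g for g in config.germline_db if g.segment == "J"]
    if not v_genes or not j_genes:
        raise ValueError("germline db must contain V and J genes")

    def pick(genes):
        w = np.array([g.abundance for g in genes], dtype=float)
        return genes[int(rng.choice(len(genes), p=w / w.sum()))]

    sequences = []
    for i in range(n):
        v, j = pick(v_genes), pick(j_genes)
        del_v = int(rng.integers(config.v_deletion_range[0], config.v_deletion_range[1] + 1))
        del_j = int(rng.integers(config.j_deletion_range[0], config.j_deletion_range[1] + 1))
        n1_base = int(rng.integers(config.n1_length_range[0], config.n1_length_range[1] + 1))
        out_of_frame = rng.random() < config.fraction_out_of_frame

        v_part = v.nucleotides[: len(v.nucleotides) - del_v]
        j_part = j.nucleotides[del_j:]
        # phase the J must start at (relative to the V reading frame) to be in frame
        j_needed_phase = (del_j - j.frame) % 3
        for extra in range(3):
            n1_len = n1_base + extra
            phase = (len(v_part) + n1_len - v.frame) % 3
            if (phase == j_needed_phase) != out_of_frame:
                break
        n1 = "".join(rng.choice(list(NUCLEOTIDES), size=n1_len))
        seq = v_part + n1 + j_part
        frame_class = OUT_OF_FRAME if out_of_frame else PRODUCTIVE

        mult = motif_multipliers(seq, config.hotspot_motifs)
        p_mut = np.clip(config.shm_rate * mult, 0.0, 0.95)
        hits = np.flatnonzero(rng.random(len(seq)) < p_mut)
        mutated = list(seq)
        accepted_v_positions = []
        for pos in hits:
            old = seq[pos]
            new = rng.choice([b for b in NUCLEOTIDES if b != old])
            in_v = pos < len(v_part)
            if frame_class == PRODUCTIVE and in_v and config.selection:
                codon_site = pos // 3
                accept_p = config.selection.get(codon_site, 1.0)
                codon_start = codon_site * 3
                codon = "".join(mutated[codon_start:codon_start + 3])
                if set(codon) <= set("ACGT"):
                    syn = translate(codon) == translate(
                        codon[: pos - codon_start] + new + codon[pos - codon_start + 1:])
                    if not syn and rng.random() > accept_p:
                        continue
            mutated[pos] = new
            if in_v:
                accepted_v_positions.append(int(pos))
        # revert mutations that create an in-frame stop in the productive frame
        if frame_class == PRODUCTIVE:
            for start in range(0, len(seq) - 2, 3):
                codon = "".join(mutated[start:start + 3])
                if set(codon) <= set("ACGT") and translate(codon) == "*":
                    for k in range(start, start + 3):
                        mutated[k] = seq[k]
                        if k in accepted_v_positions:
                            accepted_v_positions.remove(k)
        final = "".join(mutated)
        v_cov_end = len(v_part)
        read_start = 0
        if config.read_window is not None and config.read_window < len(final):
            read_start = len(final) - config.read_window
            final = final[read_start:]
        v_start = min(read_start, v_cov_end)
        sequences.append(SimulatedSequence(
            id=f"seq_{i}", sequence=final, v_gene=v.name, j_gene=j.name,
            frame_class=frame_class, v_start=v_start, v_end=v_cov_end,
            mutated_v_positions=tuple(p for p in sorted(accepted_v_positions)
                                      if p >= v_start),
        ))
    return SimulatedRepertoire(sequences=sequences, config=config)
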