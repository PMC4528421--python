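"""Stochastic mapping of substitution histories on germline-query branches.

Conditional on the observed endpoints of every nucleotide column, a full
substitution path is drawn from the endpoint-conditioned continuous-time
Markov chain by uniformization: the number of (real or virtual) jumps is
sampled from its exact conditional distribution, intermediate states from
the discrete bridge, and jump times as uniform order statistics.  Events
from the three columns of a codon are then merged in time order and each
event is classified synonymous or non-synonymous against the *current*
codon (so multiple hits in one codon are handled correctly); events that
create a stop codon mid-path count as non-synonymous.

"Unconditional" counts forward-simulate from the germline state along the
same branch lengths with no endpoint conditioning; the ratio of conditional
to unconditional rates is what a selection estimator needs when no neutral
sequence class is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .codons import mutate_codon, substitution_is_synonymous
from .hky import HKYTriple
from .pairs import CodonPair

_NMAX = 60  # uniformized jump-count cap; P(N > _NMAX) is negligible here


class Event(NamedTuple):
    site: int
    time: float
    from_base: int
    to_base: int
    position_in_codon: int


@dataclass
class _Uniformized:
    """Per-codon-position uniformization tables for an HKY triple."""

    q: list          # Q'_p = m_p * Q_p
    lam: np.ndarray  # (3,) uniformization rates
    r_pow: np.ndarray  # (3, _NMAX+1, 4, 4) powers of R_p = I + Q'_p / lam_p

    @classmethod
    def from_hky(cls, hky: HKYTriple) -> "_Uniformized":
        cached = getattr(hky, "_uniformized_cache", None)
        if cached is not None:
            return cached
        qs, lams, pows = [], [], []
        for p in range(3):
            q = hky.q(p)
            lam = float(-np.diag(q).min()) * 1.05 + 1e-12
            r = np.eye(4) + q / lam
            rp = np.empty((_NMAX + 1, 4, 4))
            rp[0] = np.eye(4)
            for k in range(1, _NMAX + 1):
                rp[k] = rp[k - 1] @ r
            qs.append(q)
            lams.append(lam)
            pows.append(rp)
        uni = cls(q=qs, lam=np.array(lams), r_pow=np.stack(pows))
        hky._uniformized_cache = uni
        return uni


def _sample_bridge_states(rng, rp, n, a, b):
    """Intermediate states of the uniformized bridge with n jumps from a to b."""
    states = [a]
    s = a
    for k in range(1, n + 1):
        w = rp[1][s, :] * rp[n - k][:, b]
        tot = w.sum()
        if tot <= 0:           # numerically degenerate; force the endpoint
            s = b
        else:
            s = int(rng.choice(4, p=w / tot))
        states.append(s)
    return states


def _column_path(rng, uni: _Uniformized, p: int, a: int, b: int, t: float,
                 p_ab: float) -> list[tuple[float, int, int]]:
    """One endpoint-conditioned path for a single column: [(time, from, to)]."""
    lam_t = uni.lam[p] * t
    u = rng.random()
    log_pref = -lam_t
    acc = 0.0
    n = _NMAX
    term = np.exp(log_pref)  # n = 0 factor, multiplied by R^0_ab / P_ab below
    for k in range(_NMAX + 1):
        if k > 0:
            term = term * lam_t / k
        prob = term * uni.r_pow[p, k, a, b] / p_ab
        acc += prob
        if u < acc:
            n = k
            break
    if n == 0:
        return []
    states = _sample_bridge_states(rng, uni.r_pow[p], n, a, b)
    times = np.sort(rng.random(n)) * t
    out = []
    for k in range(1, n + 1):
        if states[k] != states[k - 1]:
            out.append((float(times[k - 1]), states[k - 1], states[k]))
    return out


def sample_history(
    germline_codons: np.ndarray,
    query_codons: np.ndarray,
    t: float,
    hky: HKYTriple,
    seed: int | np.random.Generator = 0,
) -> list[Event]:
    """Draw one substitution history conditional on the observed endpoints.

    Every covered nucleotide column gets an endpoint-conditioned path over
    the branch; events are merged within codons and returned ordered by
    (site, time).  Columns with a masked codon (query index -1) are
    skipped; requires t > 0.
    """
    if t <= 0:
        raise ValueError("sample_history requires t > 0")
    rng = np.random.default_rng(seed)
    pair = CodonPair(id="", germline=np.asarray(germline_codons),
                     query=np.asarray(query_codons))
    sites, pos, g, q = pair.nucleotide_columns()
    uni = _Uniformized.from_hky(hky)
    pmats = hky.transition_matrices(float(t))
    events: list[Event] = []
    for c in range(sites.size):
        p = int(pos[c])
        path = _column_path(rng, uni, p, int(g[c]), int(q[c]), t,
                            float(max(pmats[p, g[c], q[c]], 1e-300)))
        for time, fr, to in path:
            events.append(Event(int(sites[c]), time, fr, to, p))
    events.sort(key=lambda e: (e.site, e.time))
    return events


def count_syn_nonsyn(history: list[Event], germline_codons: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Replay a history in time order and tally per-site (N_l, S_l).

    Each event is classified against the codon state at its moment;
    events creating stop codons count as non-synonymous.
    """
    germ = np.asarray(germline_codons)
    n_counts = np.zeros(germ.size)
    s_counts = np.zeros(germ.size)
    current: dict[int, int] = {}
    for ev in sorted(history, key=lambda e: (e.site, e.time)):
        codon = current.get(ev.site, int(germ[ev.site]))
        if substitution_is_synonymous(codon, ev.position_in_codon, ev.to_base):
            s_counts[ev.site] += 1
        else:
            n_counts[ev.site] += 1
        current[ev.site] = mutate_codon(codon, ev.position_in_codon, ev.to_base)
    return n_counts, s_counts


# ---------------------------------------------------------------------------
# Batch (vectorized) mapping over posterior branch-length samples


def conditional_counts(
    pair: CodonPair,
    t_samples: np.ndarray,
    hky: HKYTriple,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site syn/nonsyn counts averaged over posterior branch samples.

    For each of the J branch-length samples a full stochastic mapping of
    the pair is drawn; the returned (N_l, S_l) arrays are means over the J
    histories.  The jump-count sampling is vectorized over
    (sample, column) cells; only cells with at least one jump are walked
    individually.
    """
    rng = np.random.default_rng(seed)
    t_samples = np.asarray(t_samples, dtype=float)
    L = pair.n_sites
    J = t_samples.size
    sites, pos, g, q = pair.nucleotide_columns()
    C = sites.size
    n_out = np.zeros(L)
    s_out = np.zeros(L)
    if C == 0 or J == 0:
        return n_out, s_out
    uni = _Uniformized.from_hky(hky)
    pmats = hky.transition_matrices(t_samples)                  # (J, 3, 4, 4)
    p_ab = np.maximum(pmats[:, pos, g, q], 1e-300)              # (J, C)
    lam_t = t_samples[:, None] * uni.lam[pos][None, :]          # (J, C)

    # vectorized jump-count sampling by inversion
    u = rng.random((J, C))
    n_jumps = np.full((J, C), -1, dtype=np.int64)
    term = np.exp(-lam_t)                                       # Poisson factor, k=0
    acc = term * uni.r_pow[pos, 0, g, q][None, :] / p_ab
    n_jumps[u < acc] = 0
    k = 0
    while (n_jumps < 0).any() and k < _NMAX:
        k += 1
        term = term * lam_t / k
        acc = acc + term * uni.r_pow[pos, k, g, q][None, :] / p_ab
        n_jumps[(n_jumps < 0) & (u < acc)] = k
    n_jumps[n_jumps < 0] = _NMAX

    # walk the cells that actually jump, grouped per (sample, site)
    jj, cc = np.nonzero(n_jumps > 0)
    events_by_js: dict[tuple[int, int], list] = {}
    for j, c in zip(jj.tolist(), cc.tolist()):
        p = int(pos[c])
        n = int(n_jumps[j, c])
        a, b = int(g[c]), int(q[c])
        states = _sample_bridge_states(rng, uni.r_pow[p], n, a, b)
        if all(s == a for s in states):
            continue
        times = np.sort(rng.random(n)) * t_samples[j]
        lst = events_by_js.setdefault((j, int(sites[c])), [])
        for k2 in range(1, n + 1):
            if states[k2] != states[k2 - 1]:
                lst.append((float(times[k2 - 1]), p, states[k2 - 1], states[k2]))

    germ = pair.germline
    for (j, site), evts in events_by_js.items():
        evts.sort(key=lambda e: e[0])
        codon = int(germ[site])
        for _, p, fr, to in evts:
            if substitution_is_synonymous(codon, p, to):
                s_out[site] += 1.0
            else:
                n_out[site] += 1.0
            codon = mutate_codon(codon, p, to)
    return n_out / J, s_out / J


def unconditional_counts(
    germline_codons: np.ndarray,
    t_samples: np.ndarray,
    hky: HKYTriple,
    seed: int | np.random.Generator = 0,
    sites_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-simulated per-site syn/nonsyn counts from the germline state.

    For each branch-length sample the germline sequence evolves freely
    (no endpoint conditioning) under the same per-position HKY process;
    counts are averaged over samples.  ``sites_mask`` restricts simulation
    to the codon sites a read actually covers, keeping exposures comparable
    with the conditional counts.
    """
    rng = np.random.default_rng(seed)
    germ = np.asarray(germline_codons)
    t_samples = np.asarray(t_samples, dtype=float)
    L = germ.size
    J = t_samples.size
    n_out = np.zeros(L)
    s_out = np.zeros(L)
    use = np.ones(L, dtype=bool) if sites_mask is None else np.asarray(sites_mask, dtype=bool)
    use = use & (germ >= 0)
    sel = np.flatnonzero(use)
    if sel.size == 0 or J == 0:
        return n_out, s_out
    sites = np.repeat(sel, 3)
    pos = np.tile(np.arange(3), sel.size)
    shift = (2 - pos) * 2
    a = (germ[sites] >> shift) & 3

    qmats = [hky.q(p) for p in range(3)]
    exit_rate = np.stack([-np.diag(qm) for qm in qmats])        # (3, 4)
    jump_p = []
    for qm in qmats:
        jp = qm.copy()
        np.fill_diagonal(jp, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            jp = jp / (-np.diag(qm))[:, None]
        jump_p.append(jp)

    rate_a = exit_rate[pos, a]                                  # (C,)
    first = rng.exponential(1.0, size=(J, sites.size)) / rate_a[None, :]
    hit = first < t_samples[:, None]
    jj, cc = np.nonzero(hit)
    events_by_js: dict[tuple[int, int], list] = {}
    for j, c in zip(jj.tolist(), cc.tolist()):
        p = int(pos[c])
        s = int(a[c])
        tt = float(first[j, c])
        t_end = float(t_samples[j])
        lst = events_by_js.setdefault((j, int(sites[c])), [])
        while tt < t_end:
            s_new = int(rng.choice(4, p=jump_p[p][s]))
            lst.append((tt, p, s, s_new))
            s = s_new
            tt += rng.exponential(1.0 / exit_rate[p, s])

    for (j, site), evts in events_by_js.items():
        evts.sort(key=lambda e: e[0])
        codon = int(germ[site])
        for _, p, fr, to in evts:
            if substitution_is_synonymous(codon, p, to):
                s_out[site] += 1.0
            else:
                n_out[site] += 1.0
            codon = mutate_codon(codon, p, to)
    return n_out / J, s_out / J
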