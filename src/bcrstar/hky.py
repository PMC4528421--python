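"""Per-codon-position HKY model fitting and branch-length MCMC.

The selection machinery maps substitution histories under a deliberately
simple nucleotide model: an independent HKY85 process for each of the three
codon positions, with relative rates between positions, fitted once by
maximum likelihood on the whole dataset and then held fixed.  Branch
lengths leading to each query sequence get an exponential prior with mean
0.1 substitutions/site and are sampled by Metropolis-Hastings with a
multiplicative scaling proposal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .substitution import EigenQ, hky_q

T_BOUNDS = (1e-6, 10.0)


@dataclass
class HKYTriple:
    """HKY parameters for the three codon positions.

    ``rel_rate`` holds the relative substitution rates of the positions,
    normalized to mean 1 so branch lengths are in average substitutions
    per nucleotide site.
    """

    kappa: np.ndarray            # (3,)
    pi: np.ndarray               # (3, 4)
    rel_rate: np.ndarray         # (3,), mean 1
    converged: bool = True
    _eigens: list = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.kappa = np.asarray(self.kappa, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        self.rel_rate = np.asarray(self.rel_rate, dtype=float)
        self.rel_rate = 3.0 * self.rel_rate / self.rel_rate.sum()
        self._eigens = [EigenQ(hky_q(self.kappa[p], self.pi[p]), self.pi[p])
                        for p in range(3)]
        # stacked spectral pieces for fast vectorized P(t) evaluation
        self._vals = np.stack([e.eigvals for e in self._eigens])    # (3,4)
        self._right = np.stack([e.right for e in self._eigens])     # (3,4,4)
        self._left = np.stack([e.left for e in self._eigens])       # (3,4,4)

    def q(self, position: int) -> np.ndarray:
        """Rate matrix of one codon position including its relative rate."""
        return self._eigens[position].q * self.rel_rate[position]

    def transition_matrices(self, t) -> np.ndarray:
        """``P_p(t * m_p)`` for all three positions.

        Scalar ``t`` -> (3, 4, 4); array of shape (k,) -> (k, 3, 4, 4).
        """
        t = np.asarray(t, dtype=float)
        scaled = np.multiply.outer(t, self.rel_rate)                # (..., 3)
        e = np.exp(scaled[..., :, None] * self._vals)               # (..., 3, 4)
        p = np.einsum("pij,...pj,pjk->...pik", self._right, e, self._left)
        return np.clip(p, 0.0, None)

    def pair_loglik(self, counts: np.ndarray, t: float) -> float:
        """Log-likelihood of a pair's (3, 4, 4) count matrices at branch t."""
        p = self.transition_matrices(float(t))
        return float((counts * np.log(np.maximum(p, 1e-300))).sum())


def _counts_of(pair) -> np.ndarray:
    return pair if isinstance(pair, np.ndarray) else pair.position_count_matrices()


def fit_hky_triple(pairs, tol: float = 1e-3, max_rounds: int = 50) -> HKYTriple:
    """Joint ML fit of kappa_p, pi_p, relative rates and per-pair branch
    lengths on the star tree; the branch lengths are discarded.

    Base frequencies are fixed at their empirical values (pooled germline
    and query bases per position).  When the data carry no variation the
    branch lengths collapse to the lower bound, kappa is unidentifiable and
    the result is flagged ``converged=False``.
    """
    counts = np.stack([_counts_of(p) for p in pairs])   # (n, 3, 4, 4)
    n = counts.shape[0]
    pos_tot = counts.sum(axis=0)                        # (3, 4, 4)
    pi = pos_tot.sum(axis=2) + pos_tot.sum(axis=1) + 1.0
    pi = pi / pi.sum(axis=1, keepdims=True)

    sites = counts.sum(axis=(1, 2, 3))
    mism = sites - np.einsum("npii->n", counts)
    if mism.sum() == 0:
        return HKYTriple(np.full(3, 1.0), pi, np.ones(3), converged=False)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.clip(np.where(sites > 0, mism / np.maximum(sites, 1), 0.0),
                    1e-4, 0.75)
    kappa = np.full(3, 2.0)
    m = np.ones(3)  # position 1 fixed to 1 during fitting

    def loglik_given(kap, mm, tv) -> float:
        eigs = [EigenQ(hky_q(kap[p], pi[p]), pi[p]) for p in range(3)]
        total = 0.0
        for p in range(3):
            pm = eigs[p].expm(tv * mm[p])               # (n, 4, 4)
            total += (counts[:, p] * np.log(np.maximum(pm, 1e-300))).sum()
        return float(total)

    last = loglik_given(kappa, m, t)
    converged = False
    for _ in range(max_rounds):
        # substitution block: kappa (3) and relative rates m2, m3
        x0 = np.concatenate([np.log(kappa), np.log(m[1:])])
        bounds = [(np.log(0.05), np.log(100.0))] * 3 + [(np.log(1e-2), np.log(1e2))] * 2

        def neg(x):
            kap = np.exp(x[:3])
            mm = np.array([1.0, np.exp(x[3]), np.exp(x[4])])
            return -loglik_given(kap, mm, t)

        res = minimize(neg, x0, method="Powell", bounds=bounds,
                       options={"xtol": 1e-6, "ftol": 1e-8, "maxiter": 10})
        kappa = np.exp(res.x[:3])
        m = np.array([1.0, np.exp(res.x[3]), np.exp(res.x[4])])

        # branch-length block
        eigs = [EigenQ(hky_q(kappa[p], pi[p]), pi[p]) for p in range(3)]
        for i in range(n):
            if sites[i] == 0:
                t[i] = T_BOUNDS[0]
                continue

            def neg_t(log_t, i=i):
                ti = np.exp(log_t)
                return -sum((counts[i, p] *
                             np.log(np.maximum(eigs[p].expm(ti * m[p]), 1e-300))).sum()
                            for p in range(3))

            r = minimize_scalar(neg_t, bounds=(np.log(T_BOUNDS[0]), np.log(T_BOUNDS[1])),
                                method="bounded", options={"xatol": 1e-6})
            t[i] = float(np.exp(r.x))

        cur = loglik_given(kappa, m, t)
        if cur - last < tol:
            converged = True
            break
        last = cur
    return HKYTriple(kappa, pi, m, converged=converged)


def mcmc_branch_length(
    pair,
    hky: HKYTriple,
    prior_mean: float = 0.1,
    iters: int = 20000,
    thin: int = 40,
    seed: int | np.random.Generator = 0,
    proposal_scale: float = 1.2,
) -> np.ndarray:
    """Posterior branch-length samples for one germline-query pair.

    Metropolis-Hastings on t with a multiplicative scaling proposal
    ``t' = t * exp(scale * (u - 1/2))`` (Hastings correction t'/t), an
    Exp(mean ``prior_mean``) prior and the per-position HKY pair
    likelihood.  Returns ``iters // thin`` retained samples.  With no data
    (zero-length alignment) the posterior equals the prior and is sampled
    directly.
    """
    rng = np.random.default_rng(seed)
    counts = _counts_of(pair)
    n_keep = iters // thin
    if counts.sum() == 0:
        return rng.exponential(prior_mean, size=n_keep)

    sites = counts.sum()
    mism = sites - np.einsum("pii->", counts)
    t = float(np.clip(mism / sites if sites else 0.01, 1e-3, 1.0))
    ll = hky.pair_loglik(counts, t)
    log_prior = -t / prior_mean
    samples = np.empty(n_keep)
    k = 0
    us = rng.random(iters)
    zs = rng.random(iters)
    for it in range(iters):
        t_new = t * np.exp(proposal_scale * (zs[it] - 0.5))
        if T_BOUNDS[0] <= t_new <= T_BOUNDS[1]:
            ll_new = hky.pair_loglik(counts, t_new)
            lp_new = -t_new / prior_mean
            log_alpha = (ll_new + lp_new) - (ll + log_prior) + np.log(t_new / t)
            if np.log(us[it]) < log_alpha:
                t, ll, log_prior = t_new, ll_new, lp_new
        if (it + 1) % thin == 0:
            samples[k] = t
            k += 1
    return samples
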