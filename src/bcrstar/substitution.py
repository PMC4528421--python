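"""Nucleotide substitution-model primitives.

Rate matrices follow the standard time-reversible parameterization
``q_ij = s_ij * pi_j`` (i != j) with the diagonal set so rows sum to zero,
normalized so that the expected number of substitutions per site per unit
time at stationarity is one: ``-sum_i pi_i q_ii = 1``.  Transition matrices
are computed from a cached symmetric eigendecomposition (a reversible Q is
similar to a symmetric matrix via ``diag(sqrt(pi))``), which makes repeated
``P(t)`` evaluations cheap inside optimizers and MCMC.

Across-site rate variation uses Yang's four-category discretized Gamma with
equal-probability bins and category means, rescaled to mean exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as _gamma_dist

from .codons import IS_TRANSITION

#: order of the six exchangeability parameters: AC, AG, AT, CG, CT, GT
EXCHANGE_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


@dataclass
class GTRParams:
    """GTR exchangeabilities and stationary base frequencies.

    ``exchangeabilities`` holds the six symmetric rates in the order
    AC, AG, AT, CG, CT, GT; GT is conventionally fixed to 1 for
    identifiability, leaving 5 + 3 = 8 free parameters.
    """

    exchangeabilities: np.ndarray
    base_frequencies: np.ndarray

    def __post_init__(self) -> None:
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.base_frequencies = np.asarray(self.base_frequencies, dtype=float)
        if self.exchangeabilities.shape != (6,) or (self.exchangeabilities <= 0).any():
            raise ValueError("need 6 positive exchangeabilities")
        if self.base_frequencies.shape != (4,) or (self.base_frequencies <= 0).any():
            raise ValueError("need 4 positive base frequencies")
        s = self.base_frequencies.sum()
        if abs(s - 1.0) > 1e-8:
            raise ValueError("base frequencies must sum to 1")
        self.base_frequencies = self.base_frequencies / s

    @classmethod
    def jukes_cantor(cls) -> "GTRParams":
        return cls(np.ones(6), np.full(4, 0.25))


def build_q(params: GTRParams) -> np.ndarray:
    """GTR instantaneous rate matrix, normalized to 1 expected substitution/site.

    Satisfies detailed balance ``pi_i q_ij = pi_j q_ji`` by construction.
    """
    pi = params.base_frequencies
    q = np.zeros((4, 4))
    for s, (i, j) in zip(params.exchangeabilities, EXCHANGE_PAIRS):
        q[i, j] = s * pi[j]
        q[j, i] = s * pi[i]
    np.fill_diagonal(q, -q.sum(axis=1))
    rate = -(pi * np.diag(q)).sum()
    return q / rate


def hky_q(kappa: float, pi: np.ndarray) -> np.ndarray:
    """HKY85 rate matrix (transitions scaled by kappa), normalized like :func:`build_q`."""
    pi = np.asarray(pi, dtype=float)
    s = np.where(IS_TRANSITION, kappa, 1.0)[np.triu_indices(4, 1)]
    return build_q(GTRParams(s, pi))


class EigenQ:
    """Cached spectral decomposition of a reversible rate matrix.

    ``P(t) = exp(Qt)`` is evaluated as ``B exp(L t) B^-1`` where the
    decomposition is done on the symmetrized matrix for numerical stability.
    """

    def __init__(self, q: np.ndarray, pi: np.ndarray):
        pi = np.asarray(pi, dtype=float)
        sq = np.sqrt(pi)
        sym = q * (sq[:, None] / sq[None, :])
        vals, vecs = np.linalg.eigh((sym + sym.T) / 2.0)
        self.eigvals = vals
        self.right = vecs / sq[:, None]        # B = D^-1 U
        self.left = vecs.T * sq[None, :]       # B^-1 = U^T D
        self.q = q
        self.pi = pi

    def expm(self, t: float | np.ndarray) -> np.ndarray:
        """Transition matrix/matrices ``exp(Q t)``.

        Scalar ``t`` gives a (4, 4) array; a length-k array gives (k, 4, 4).
        Negative branch lengths are rejected.
        """
        t = np.asarray(t, dtype=float)
        if (t < 0).any():
            raise ValueError("branch length must be non-negative")
        e = np.exp(np.multiply.outer(t, self.eigvals))
        p = np.einsum("ij,...j,jk->...ik", self.right, e, self.left)
        return np.clip(p, 0.0, None)


def transition_matrix(q: np.ndarray, t: float, pi: np.ndarray | None = None) -> np.ndarray:
    """``P = exp(Q t)`` for a reversible Q; rows sum to 1, requires t >= 0."""
    if pi is None:
        pi = stationary_distribution(q)
    return EigenQ(q, pi).expm(float(t))


def stationary_distribution(q: np.ndarray) -> np.ndarray:
    """Left null vector of Q normalized to a probability vector."""
    vals, vecs = np.linalg.eig(q.T)
    k = int(np.argmin(np.abs(vals)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


@dataclass
class GammaRates:
    """Discretized Gamma across-site rate variation (equal-probability bins).

    Category rates are the bin means of a Gamma(shape, shape) density
    (mean 1), renormalized so their average is exactly 1.0.
    """

    shape: float
    n_categories: int = 4
    category_rates: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.shape <= 0:
            raise ValueError("gamma shape must be positive")
        self.category_rates = discrete_gamma_rates(self.shape, self.n_categories)


def discrete_gamma_rates(shape: float, n_categories: int = 4) -> np.ndarray:
    """Mean rates of the equal-probability bins of Gamma(shape, rate=shape).

    The bin mean of a Gamma(a, b) between quantiles is computed through the
    incomplete-gamma identity ``E[X; X<x] = (a/b) F_{a+1,b}(x)``; the result
    is rescaled to mean exactly one.
    """
    a = float(shape)
    edges = _gamma_dist.ppf(np.linspace(0.0, 1.0, n_categories + 1), a, scale=1.0 / a)
    cdf_hi = _gamma_dist.cdf(edges, a + 1.0, scale=1.0 / a)
    rates = (cdf_hi[1:] - cdf_hi[:-1]) * n_categories  # (a/b)=1 cancels
    return rates / rates.mean()


def clr_transform(p: np.ndarray) -> np.ndarray:
    """Row-wise centred log-ratio of a strictly positive row-stochastic matrix.

    Each row ``p`` maps to ``log p - mean(log p)``; the rows are concatenated
    into a flat vector (16 entries for a 4x4 matrix), each 4-block summing
    to zero.
    """
    p = np.asarray(p, dtype=float)
    if (p <= 0).any():
        raise ValueError("clr requires strictly positive entries")
    lp = np.log(p)
    return (lp - lp.mean(axis=-1, keepdims=True)).reshape(*p.shape[:-2], -1)
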