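"""Partitioned GTR+Gamma fitting on germline-query star trees.

Every observed sequence is related to its known germline root by a single
independent branch, so the likelihood of a pair factorizes over sites:

    logL = sum_sites log sum_c (1/4) P(t_eff * r_c)[g_s, x_s]

with ``t_eff`` the branch length scaled by the segment's relative rate and
``r_c`` the four discrete-Gamma category rates.  Because rate categories
are i.i.d. across sites, the 4x4 germline->query count matrix per
(sequence, segment) is a sufficient statistic, which keeps fitting cheap
even for thousands of sequences.

Four model variants are supported, differing in whether branch lengths,
GTR matrices and Gamma shapes are shared across the V/D/J segments:

==========  =========================  ==========  =======  ============
name        branch length              GTR         Gamma    free params
==========  =========================  ==========  =======  ============
tiQiGi      per segment per sequence   per segment  per seg  3n + 27
trQiGi      per sequence + 2 rates     per segment  per seg  n + 29
trQiGs      per sequence + 2 rates     per segment  shared   n + 27
trQsGs      per sequence + 2 rates     shared       shared   n + 11
==========  =========================  ==========  =======  ============

Fitting alternates derivative-free (Powell) optimization of substitution
parameters with bracketed scalar optimization of each branch length until
the log-likelihood improves by less than ``tol`` (default 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import spearmanr

from .substitution import (EigenQ, GTRParams, build_q, clr_transform,
                           discrete_gamma_rates)

MODEL_NAMES = ("tiQiGi", "trQiGi", "trQiGs", "trQsGs")
SEGMENTS = ("V", "D", "J")
T_BOUNDS = (1e-6, 10.0)
_SHAPE_BOUNDS = (np.log(0.05), np.log(50.0))
_RATE_BOUNDS = (np.log(1e-3), np.log(1e3))
_EXCH_BOUNDS = (np.log(1e-3), np.log(1e3))
_LOGIT_BOUNDS = (-8.0, 8.0)


@dataclass
class PairCounts:
    """Sufficient statistics of one germline-query pair: a 4x4
    substitution count matrix per segment."""

    id: str
    counts: dict[str, np.ndarray]

    @classmethod
    def from_annotated(cls, pair) -> "PairCounts":
        counts = {s: pair.segment_count_matrix(s) for s in SEGMENTS}
        return cls(id=pair.query_id, counts={s: c for s, c in counts.items() if c.sum()})


def n_parameters(model_name: str, n_seqs: int) -> int:
    """Free-parameter count for each model variant (see module table)."""
    return {
        "tiQiGi": 3 * n_seqs + 27,
        "trQiGi": n_seqs + 29,
        "trQiGs": n_seqs + 27,
        "trQsGs": n_seqs + 11,
    }[model_name]


def _unpack_gtr(x: np.ndarray) -> GTRParams:
    """8-vector (5 log exchangeabilities, GT fixed at 1; 3 frequency logits)."""
    exch = np.append(np.exp(x[:5]), 1.0)
    logits = np.append(x[5:8], 0.0)
    e = np.exp(logits - logits.max())
    return GTRParams(exch, e / e.sum())


def _pack_gtr(params: GTRParams) -> np.ndarray:
    exch = params.exchangeabilities / params.exchangeabilities[5]
    pi = params.base_frequencies
    return np.concatenate([np.log(exch[:5]), np.log(pi[:3] / pi[3])])


class PartitionedStarModel:
    """Maximum-likelihood partitioned substitution model on a star tree.

    Parameters
    ----------
    pairs
        ``PairCounts`` (or annotated pairs convertible with
        :meth:`PairCounts.from_annotated`) with at least one segment each.
    model_name
        One of ``tiQiGi, trQiGi, trQiGs, trQsGs``.
    """

    def __init__(self, pairs, model_name: str = "trQiGi", n_categories: int = 4):
        if model_name not in MODEL_NAMES:
            raise ValueError(f"unknown model {model_name!r}; expected one of {MODEL_NAMES}")
        self.model_name = model_name
        self.n_categories = n_categories
        self.pairs = [p if isinstance(p, PairCounts) else PairCounts.from_annotated(p)
                      for p in pairs]
        if not self.pairs:
            raise ValueError("need at least one pair")
        self.segments = [s for s in SEGMENTS if any(s in p.counts for p in self.pairs)]
        # stacked per-segment count arrays (n, 4, 4); zeros where absent
        n = len(self.pairs)
        self._N = {s: np.zeros((n, 4, 4)) for s in self.segments}
        for i, p in enumerate(self.pairs):
            for s, c in p.counts.items():
                self._N[s][i] = c
        self._sites = {s: self._N[s].sum(axis=(1, 2)) for s in self.segments}

    # -- likelihood ---------------------------------------------------------

    def _seg_loglik(self, seg: str, gtr: GTRParams, shape: float,
                    t_eff: np.ndarray) -> float:
        """Sum over pairs of the segment log-likelihood at effective branch
        lengths ``t_eff`` (already scaled by the relative rate)."""
        rates = discrete_gamma_rates(shape, self.n_categories)
        eig = EigenQ(build_q(gtr), gtr.base_frequencies)
        p = eig.expm(np.multiply.outer(t_eff, rates))      # (n, C, 4, 4)
        m = p.mean(axis=1)
        return float((self._N[seg] * np.log(np.maximum(m, 1e-300))).sum())

    def _total_loglik(self, state: dict) -> float:
        total = 0.0
        for s in self.segments:
            t_eff = self._t_eff(state, s)
            total += self._seg_loglik(s, state["gtr"][s], state["shape"][s], t_eff)
        return total

    def _t_eff(self, state: dict, seg: str) -> np.ndarray:
        if self.model_name == "tiQiGi":
            return state["t"][seg]
        return state["t"] * state["rate"][seg]

    # -- initialization -----------------------------------------------------

    def _initial_state(self) -> dict:
        state: dict = {"gtr": {}, "shape": {}, "rate": {s: 1.0 for s in self.segments}}
        for s in self.segments:
            tot = self._N[s].sum(axis=0)
            pi = (tot.sum(axis=0) + tot.sum(axis=1) + 1.0)
            state["gtr"][s] = GTRParams(np.ones(6), pi / pi.sum())
            state["shape"][s] = 1.0
        if self.model_name == "trQsGs":
            state["gtr"] = {s: state["gtr"][self.segments[0]] for s in self.segments}
        # p-distance starting branch lengths
        def pdist(N):
            sites = N.sum(axis=(1, 2))
            diff = sites - np.trace(N, axis1=1, axis2=2)
            with np.errstate(invalid="ignore", divide="ignore"):
                d = np.where(sites > 0, diff / np.maximum(sites, 1), 0.0)
            return np.clip(d, T_BOUNDS[0], 0.75)

        if self.model_name == "tiQiGi":
            state["t"] = {s: pdist(self._N[s]) for s in self.segments}
        else:
            allN = sum(self._N[s] for s in self.segments)
            state["t"] = pdist(allN)
        return state

    # -- optimization blocks ------------------------------------------------

    def _per_pair_loglik_at(self, segs, state, t_vec) -> np.ndarray:
        """Vector of per-pair log-likelihoods over ``segs`` at branch
        lengths ``t_vec`` (one value per pair)."""
        out = np.zeros(len(self.pairs))
        for s in segs:
            gtr = state["gtr"][s]
            eig = EigenQ(build_q(gtr), gtr.base_frequencies)
            rates = discrete_gamma_rates(state["shape"][s], self.n_categories)
            scale = 1.0 if self.model_name == "tiQiGi" else state["rate"][s]
            p = eig.expm(np.multiply.outer(t_vec * scale, rates))   # (n, C, 4, 4)
            m = p.mean(axis=1)
            out += (self._N[s] * np.log(np.maximum(m, 1e-300))).sum(axis=(1, 2))
        return out

    def _optimize_branch_lengths(self, state: dict) -> None:
        """Golden-section search on log t, vectorized across all pairs."""
        phi = (np.sqrt(5.0) - 1.0) / 2.0
        lo, hi = np.log(T_BOUNDS[0]), np.log(T_BOUNDS[1])
        n_steps = int(np.ceil(np.log(1e-4 / (hi - lo)) / np.log(phi)))
        for s_or_all in (self.segments if self.model_name == "tiQiGi" else [None]):
            segs = [s_or_all] if self.model_name == "tiQiGi" else self.segments
            a = np.full(len(self.pairs), lo)
            b = np.full(len(self.pairs), hi)
            c = b - phi * (b - a)
            d = a + phi * (b - a)
            fc = -self._per_pair_loglik_at(segs, state, np.exp(c))
            fd = -self._per_pair_loglik_at(segs, state, np.exp(d))
            for _ in range(n_steps):
                left = fc < fd  # minimum bracketed in [a, d]
                b = np.where(left, d, b)
                a = np.where(left, a, c)
                c_old, fc_old = c, fc
                c = np.where(left, b - phi * (b - a), d)
                d = np.where(left, c_old, a + phi * (b - a))
                probe = np.where(left, c, d)
                f_new = -self._per_pair_loglik_at(segs, state, np.exp(probe))
                fc, fd = (np.where(left, f_new, fd),
                          np.where(left, fc_old, f_new))
            t_opt = np.exp((a + b) / 2.0)
            has_data = np.zeros(len(self.pairs), dtype=bool)
            for s in segs:
                has_data |= self._sites[s] > 0
            t_opt[~has_data] = T_BOUNDS[0]
            if self.model_name == "tiQiGi":
                state["t"][s_or_all] = t_opt
            else:
                state["t"] = t_opt

    def _optimize_substitution(self, state: dict) -> None:
        """Blockwise Powell over substitution parameters."""
        shared_q = self.model_name == "trQsGs"
        shared_shape = self.model_name in ("trQiGs", "trQsGs")
        has_rates = self.model_name != "tiQiGi"

        if shared_q:
            self._powell_shared_block(state, shared_shape=True, has_rates=has_rates)
        else:
            for s in self.segments:
                self._powell_segment_block(s, state, own_shape=not shared_shape,
                                           own_rate=has_rates and s != self.segments[0])
            if shared_shape:
                self._powell_shape_block(state)

    def _powell_segment_block(self, seg, state, own_shape, own_rate):
        x0 = [_pack_gtr(state["gtr"][seg])]
        bounds = [(_EXCH_BOUNDS)] * 5 + [(_LOGIT_BOUNDS)] * 3
        if own_shape:
            x0.append([np.log(state["shape"][seg])])
            bounds.append(_SHAPE_BOUNDS)
        if own_rate:
            x0.append([np.log(state["rate"][seg])])
            bounds.append(_RATE_BOUNDS)
        x0 = np.concatenate(x0)

        def neg(x):
            gtr = _unpack_gtr(x[:8])
            k = 8
            shape = np.exp(x[k]) if own_shape else state["shape"][seg]
            k += own_shape
            rate = np.exp(x[k]) if own_rate else state["rate"][seg]
            t_eff = (state["t"][seg] if self.model_name == "tiQiGi"
                     else state["t"] * rate)
            return -self._seg_loglik(seg, gtr, shape, t_eff)

        res = minimize(neg, x0, method="Powell", bounds=bounds,
                       options={"xtol": 1e-6, "ftol": 1e-8, "maxiter": 6})
        x = res.x
        state["gtr"][seg] = _unpack_gtr(x[:8])
        k = 8
        if own_shape:
            state["shape"][seg] = float(np.exp(x[k]))
            k += 1
        if own_rate:
            state["rate"][seg] = float(np.exp(x[k]))

    def _powell_shape_block(self, state):
        def neg(x):
            shape = float(np.exp(x[0]))
            trial = dict(state)
            trial["shape"] = {s: shape for s in self.segments}
            return -self._total_loglik(trial)

        res = minimize(neg, [np.log(state["shape"][self.segments[0]])],
                       method="Powell", bounds=[_SHAPE_BOUNDS],
                       options={"xtol": 1e-6, "ftol": 1e-8})
        state["shape"] = {s: float(np.exp(res.x[0])) for s in self.segments}

    def _powell_shared_block(self, state, shared_shape, has_rates):
        lead = self.segments[0]
        x0 = [_pack_gtr(state["gtr"][lead]), [np.log(state["shape"][lead])]]
        bounds = [_EXCH_BOUNDS] * 5 + [_LOGIT_BOUNDS] * 3 + [_SHAPE_BOUNDS]
        free_rate_segs = [s for s in self.segments[1:]] if has_rates else []
        for s in free_rate_segs:
            x0.append([np.log(state["rate"][s])])
            bounds.append(_RATE_BOUNDS)
        x0 = np.concatenate(x0)

        def neg(x):
            gtr = _unpack_gtr(x[:8])
            shape = float(np.exp(x[8]))
            rates = dict(state["rate"])
            for k, s in enumerate(free_rate_segs):
                rates[s] = float(np.exp(x[9 + k]))
            total = 0.0
            for s in self.segments:
                t_eff = state["t"] * rates[s]
                total += self._seg_loglik(s, gtr, shape, t_eff)
            return -total

        res = minimize(neg, x0, method="Powell", bounds=bounds,
                       options={"xtol": 1e-6, "ftol": 1e-8, "maxiter": 6})
        x = res.x
        gtr = _unpack_gtr(x[:8])
        state["gtr"] = {s: gtr for s in self.segments}
        state["shape"] = {s: float(np.exp(x[8])) for s in self.segments}
        for k, s in enumerate(free_rate_segs):
            state["rate"][s] = float(np.exp(x[9 + k]))

    # -- public API ---------------------------------------------------------

    def fit(self, tol: float = 1e-3, max_rounds: int = 100) -> "PartitionedStarResults":
        """Alternate substitution-parameter and branch-length optimization
        until the log-likelihood gain in a round falls below ``tol``."""
        state = self._initial_state()
        self._optimize_branch_lengths(state)
        last = self._total_loglik(state)
        converged = False
        for _ in range(max_rounds):
            self._optimize_substitution(state)
            self._optimize_branch_lengths(state)
            cur = self._total_loglik(state)
            if cur - last < tol:
                converged = cur >= last - tol
                last = max(cur, last)
                break
            last = cur
        return PartitionedStarResults(model=self, state=state, loglik=last,
                                      converged=converged)

    def loglik_at(self, gtr: dict, shape: dict, rate: dict, t) -> float:
        """Log-likelihood at explicitly given parameters (no fitting)."""
        state = {"gtr": gtr, "shape": shape, "rate": rate, "t": t}
        return self._total_loglik(state)


@dataclass
class PartitionedStarResults:
    """Fitted partitioned star-tree model."""

    model: PartitionedStarModel
    state: dict
    loglik: float
    converged: bool = True

    @property
    def model_name(self) -> str:
        return self.model.model_name

    @property
    def n_seqs(self) -> int:
        return len(self.model.pairs)

    @property
    def df(self) -> int:
        return n_parameters(self.model_name, self.n_seqs)

    @property
    def aic(self) -> float:
        return 2.0 * self.df - 2.0 * self.loglik

    def bic(self, n_obs: int | None = None) -> float:
        n = self.n_seqs if n_obs is None else n_obs
        return self.df * np.log(n) - 2.0 * self.loglik

    @property
    def branch_lengths(self):
        return self.state["t"]

    @property
    def relative_rates(self) -> dict:
        return dict(self.state["rate"])

    def gtr(self, segment: str) -> GTRParams:
        return self.state["gtr"][segment]

    def gamma_shape(self, segment: str) -> float:
        return self.state["shape"][segment]

    def median_branch_length(self) -> float:
        t = self.state["t"]
        if isinstance(t, dict):
            return float(np.median(np.concatenate([t[s] for s in t])))
        return float(np.median(t))

    def transition_summary(self, segment: str = "V", t: float | None = None) -> np.ndarray:
        """Transition matrix ``exp(Q_seg * r_seg * t)`` at the median (or a
        supplied) branch length, each row an equally weighted conditional
        distribution given the starting state."""
        if t is None:
            t = self.median_branch_length()
        rate = self.state["rate"].get(segment, 1.0) if self.model_name != "tiQiGi" else 1.0
        gtr = self.state["gtr"][segment]
        eig = EigenQ(build_q(gtr), gtr.base_frequencies)
        return eig.expm(float(t) * rate)

    def clr_vector(self, segment: str = "V", t: float | None = None) -> np.ndarray:
        return clr_transform(self.transition_summary(segment, t))

    def summary(self) -> str:
        lines = [
            f"Partitioned star-tree model: {self.model_name}",
            f"  sequences: {self.n_seqs}   segments: {','.join(self.model.segments)}",
            f"  logL = {self.loglik:.3f}   d.f. = {self.df}   AIC = {self.aic:.3f}",
            f"  converged: {self.converged}",
        ]
        for s in self.model.segments:
            g = self.gtr(s)
            lines.append(
                f"  [{s}] shape={self.gamma_shape(s):.4g}"
                + (f" rel_rate={self.state['rate'][s]:.4g}"
                   if self.model_name != "tiQiGi" else "")
            )
            lines.append(f"      exch(AC,AG,AT,CG,CT,GT)="
                         f"{np.array2string(g.exchangeabilities, precision=3)}")
            lines.append(f"      freqs(ACGT)={np.array2string(g.base_frequencies, precision=3)}")
        t = self.state["t"]
        tm = self.median_branch_length()
        lines.append(f"  median branch length: {tm:.5f}")
        return "\n".join(lines)

    def params_dict(self) -> dict:
        """JSON-serializable parameter dump."""
        out = {"model": self.model_name, "loglik": self.loglik, "df": self.df,
               "aic": self.aic, "segments": {}}
        for s in self.model.segments:
            g = self.gtr(s)
            out["segments"][s] = {
                "exchangeabilities": g.exchangeabilities.tolist(),
                "base_frequencies": g.base_frequencies.tolist(),
                "gamma_shape": self.gamma_shape(s),
                "relative_rate": (self.state["rate"].get(s, None)
                                  if self.model_name != "tiQiGi" else None),
            }
        return out


def aic(results: PartitionedStarResults) -> float:
    """AIC = 2k - 2 logL."""
    return results.aic


def bic(results: PartitionedStarResults, n_obs: int) -> float:
    """BIC = k ln(n_obs) - 2 logL."""
    return results.bic(n_obs)


def rank_models(results_list) -> pd.DataFrame:
    """Ranking table in the standard report layout:
    model, LogL, d.f., AIC, dAIC (ascending AIC)."""
    rows = [dict(model=r.model_name, LogL=r.loglik, **{"d.f.": r.df}, AIC=r.aic)
            for r in results_list]
    df = pd.DataFrame(rows).sort_values("AIC").reset_index(drop=True)
    df["dAIC"] = df["AIC"] - df["AIC"].iloc[0]
    return df


def pca_models(vectors: np.ndarray, labels=None):
    """Centred PCA of clr-transformed transition matrices.

    Returns (scores, loadings, explained_variance_ratio); scores has one
    row per input vector.
    """
    x = np.asarray(vectors, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("pca_models needs at least two vectors")
    centred = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    scores = u * s
    var = s ** 2
    evr = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    return scores, vt, evr


def model_sequence_distance_correlation(germline_seqs: list[str],
                                        clr_vectors: np.ndarray):
    """Spearman correlation between germline Hamming distances and
    Euclidean distances between clr-transformed transition vectors.

    Sequences must be pre-aligned to equal length, one clr vector per gene.
    Returns (rho, p); (nan, nan) when either distance set is constant.
    """
    n = len(germline_seqs)
    if n < 3:
        raise ValueError("need at least 3 genes")
    if len({len(s) for s in germline_seqs}) != 1:
        raise ValueError("germline sequences must be aligned to equal length")
    v = np.asarray(clr_vectors, dtype=float)
    if v.shape[0] != n:
        raise ValueError("one clr vector per gene required")
    ham, euc = [], []
    for i in range(n):
        for j in range(i + 1, n):
            ham.append(sum(a != b for a, b in zip(germline_seqs[i], germline_seqs[j])))
            euc.append(float(np.linalg.norm(v[i] - v[j])))
    ham, euc = np.array(ham), np.array(euc)
    if np.ptp(ham) == 0 or np.ptp(euc) == 0:
        return float("nan"), float("nan")
    rho, p = spearmanr(ham, euc)
    return float(rho), float(p)
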