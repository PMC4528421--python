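"""Per-residue selection estimation with empirical-Bayes shrinkage.

The estimator combines, per codon site of a germline gene:

1. posterior branch-length samples per sequence (star-tree MCMC under a
   per-codon-position HKY model),
2. stochastically mapped synonymous / non-synonymous substitution counts,
   summed over sequences after averaging over posterior samples,
3. a Gamma-Poisson hierarchical model per count class: counts
   ``C_l ~ Poisson(lambda_l t_l)`` with site exposure ``t_l`` (summed mean
   branch length of the sequences covering site l) and
   ``lambda_l ~ Gamma(alpha, beta)`` fitted empirically across sites,
   giving conjugate posteriors ``Gamma(alpha + C_l, beta + t_l)``,
4. a ratio-of-ratios selection coefficient.  With out-of-frame (O)
   rearrangements as the neutral control for productive (P) sequences:

       omega_l = (lambda^N_P / lambda^N_O) / (lambda^S_P / lambda^S_O)

   and, for validation against simulations with no neutral class, the
   original form with forward-simulated unconditional (U) rates:

       omega_l = (lambda^CN / lambda^UN) / (lambda^CS / lambda^US).

Sites are classified positively/negatively selected when the 95% credible
interval of omega excludes 1; sites with fewer than ``min_coverage``
sequences in a required class, or whose germline codon encodes Trp or Met
(no synonymous change possible), are unclassifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln

from .annotate import OUT_OF_FRAME, PRODUCTIVE
from .codons import AA_BY_CODON
from .hky import HKYTriple, fit_hky_triple, mcmc_branch_length
from .mapping import conditional_counts, unconditional_counts
from .pairs import CodonPair

MODES = ("outofframe", "unconditional", "naive")


# ---------------------------------------------------------------------------
# Count aggregation


@dataclass
class SiteCountTable:
    """Per-site aggregated substitution counts and exposures for one
    (rearrangement class, conditional/unconditional) stratum."""

    n_counts: np.ndarray     # summed sampled non-synonymous counts per site
    s_counts: np.ndarray     # summed sampled synonymous counts per site
    exposure: np.ndarray     # sum over covering sequences of mean branch length
    coverage: np.ndarray     # number of sequences covering each site

    def __post_init__(self) -> None:
        bad = (self.exposure > 0) != (self.coverage > 0)
        if bad.any():
            raise ValueError("exposure and coverage must vanish together")

    @classmethod
    def empty(cls, L: int) -> "SiteCountTable":
        return cls(np.zeros(L), np.zeros(L), np.zeros(L), np.zeros(L, dtype=np.int64))

    def add(self, n_l: np.ndarray, s_l: np.ndarray, t_mean: float,
            covered: np.ndarray) -> None:
        self.n_counts += n_l
        self.s_counts += s_l
        self.exposure += t_mean * covered
        self.coverage += covered.astype(np.int64)


def aggregate(per_seq_counts, per_seq_t_mean, per_seq_covered, L: int) -> SiteCountTable:
    """Element-wise sum of per-sequence (N_l, S_l) count vectors with
    coverage-aware exposures; order-invariant."""
    table = SiteCountTable.empty(L)
    for (n_l, s_l), t_mean, cov in zip(per_seq_counts, per_seq_t_mean, per_seq_covered):
        table.add(np.asarray(n_l), np.asarray(s_l), float(t_mean),
                  np.asarray(cov, dtype=bool))
    return table


# ---------------------------------------------------------------------------
# Empirical-Bayes Gamma-Poisson fit


@dataclass
class GammaPoissonFit:
    """Fitted hyperparameters of the site-rate prior.

    ``fit_mode`` is ``gamma`` (hierarchical Gamma-Poisson) or
    ``pooled_poisson`` (single shared rate; used when the
    exposure-weighted count variance falls below the weighted mean, where
    the Gamma likelihood degenerates).
    """

    alpha: float | None
    beta: float | None
    lam: float | None
    fit_mode: str
    loglik: float = float("nan")


def gamma_poisson_marginal_loglik(alpha: float, beta: float,
                                  counts: np.ndarray, exposure: np.ndarray) -> float:
    """Marginal log-likelihood of counts with per-site exposures.

    Integrating the Poisson rate against its Gamma(alpha, beta) prior gives
    a negative-binomial-type term per site; a continuous-count variant
    (Gamma function in place of the factorial) accommodates the
    posterior-averaged, non-integer mapped counts.
    """
    c, t = counts, exposure
    return float(np.sum(
        gammaln(alpha + c) - gammaln(alpha) - gammaln(c + 1.0)
        + alpha * np.log(beta) + c * np.log(np.maximum(t, 1e-300))
        - (alpha + c) * np.log(beta + t)
    ))


def fit_gamma_poisson(counts: np.ndarray, exposure: np.ndarray) -> GammaPoissonFit:
    """Empirical-Bayes fit of the Gamma rate prior across sites.

    Only sites with positive exposure enter.  When the exposure-weighted
    sample variance of the counts is below the weighted mean, the Gamma fit
    degenerates and a pooled-Poisson rate (lambda-hat = sum C / sum t) is
    used instead.
    """
    counts = np.asarray(counts, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    use = exposure > 0
    if not use.any():
        raise ValueError("all exposures are zero")
    c, t = counts[use], exposure[use]
    if c.size < 2:
        raise ValueError("need at least 2 sites with positive exposure")
    lam_pool = c.sum() / t.sum()

    w = t / t.sum()
    wmean = float((w * c).sum())
    wvar = float((w * (c - wmean) ** 2).sum())
    if wvar < wmean or c.sum() == 0:
        return GammaPoissonFit(None, None, lam_pool, "pooled_poisson",
                               loglik=float(np.sum(c * np.log(lam_pool * t + 1e-300)
                                                   - lam_pool * t - gammaln(c + 1))))

    # moment-based start: prior mean = pooled rate; prior variance from the
    # count overdispersion beyond Poisson
    excess = float((w * ((c - lam_pool * t) ** 2 - lam_pool * t) / t ** 2).sum())
    var0 = max(excess, 1e-3 * lam_pool ** 2)
    beta0 = lam_pool / var0
    alpha0 = lam_pool * beta0

    best = None
    for a0, b0 in ((alpha0, beta0), (1.0, 1.0 / lam_pool)):
        res = minimize(
            lambda x: -gamma_poisson_marginal_loglik(np.exp(x[0]), np.exp(x[1]), c, t),
            [np.log(a0), np.log(b0)], method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    alpha, beta = np.exp(best.x)
    if not np.isfinite(best.fun) or alpha > 1e6:
        return GammaPoissonFit(None, None, lam_pool, "pooled_poisson")
    return GammaPoissonFit(float(alpha), float(beta), None, "gamma",
                           loglik=float(-best.fun))


def posterior_rate_draws(
    count: float,
    exposure: float,
    fit: GammaPoissonFit,
    n_draws: int = 500,
    seed: int | np.random.Generator = 0,
) -> np.ndarray | None:
    """Draws from the per-site rate posterior.

    Gamma mode: the conjugate posterior
    ``Gamma(shape = alpha + C, rate = beta + t)`` in closed form.  Pooled
    mode: Jeffreys-style ``Gamma(C + 1/2, t)`` draws so interval widths
    remain defined; ``None`` when a pooled-mode site has no exposure.
    """
    rng = np.random.default_rng(seed)
    if fit.fit_mode == "gamma":
        shape = fit.alpha + count
        rate = fit.beta + exposure
        return rng.gamma(shape, 1.0 / rate, size=n_draws)
    if exposure <= 0:
        return None
    return rng.gamma(count + 0.5, 1.0 / exposure, size=n_draws)


# ---------------------------------------------------------------------------
# Omega


NEGATIVE, NEUTRAL, POSITIVE, UNCLASSIFIABLE = (
    "negative", "neutral", "positive", "unclassifiable")


@dataclass
class OmegaEstimate:
    """Posterior summary of the selection coefficient at one codon site."""

    site: int
    median: float
    lo: float
    hi: float
    classification: str
    coverage_productive: int
    coverage_control: int
    draws: np.ndarray | None = field(default=None, repr=False)


def omega_per_site(
    site: int,
    num_n: np.ndarray | None,
    num_s: np.ndarray | None,
    den_n: np.ndarray | None,
    den_s: np.ndarray | None,
    coverage_productive: int = 0,
    coverage_control: int = 0,
    min_coverage: int = 100,
    bci_level: float = 0.95,
    germline_aa: str | None = None,
    keep_draws: bool = False,
) -> OmegaEstimate:
    """Combine paired rate posteriors into an omega estimate for one site.

    ``num_*`` are the productive (conditional) N and S rate draws;
    ``den_*`` the control (out-of-frame or unconditional) draws, index-
    paired.  Pass ``den_n = den_s = None`` for the naive, uncontrolled
    N/S-ratio estimator.
    """
    if num_n is None or num_s is None:
        return OmegaEstimate(site, np.nan, np.nan, np.nan, UNCLASSIFIABLE,
                             coverage_productive, coverage_control)
    with np.errstate(divide="ignore", invalid="ignore"):
        if den_n is None or den_s is None:
            draws = num_n / num_s
        else:
            if (den_n <= 0).all() or (den_s <= 0).all():
                return OmegaEstimate(site, np.nan, np.nan, np.nan, UNCLASSIFIABLE,
                                     coverage_productive, coverage_control)
            draws = (num_n / den_n) / (num_s / den_s)
    draws = draws[np.isfinite(draws)]
    if draws.size == 0:
        return OmegaEstimate(site, np.nan, np.nan, np.nan, UNCLASSIFIABLE,
                             coverage_productive, coverage_control)
    tail = (1.0 - bci_level) / 2.0
    lo, med, hi = np.quantile(draws, [tail, 0.5, 1.0 - tail])
    if (coverage_productive < min_coverage or coverage_control < min_coverage
            or germline_aa in ("W", "M")):
        cls = UNCLASSIFIABLE
    elif lo > 1.0:
        cls = POSITIVE
    elif hi < 1.0:
        cls = NEGATIVE
    else:
        cls = NEUTRAL
    return OmegaEstimate(site, float(med), float(lo), float(hi), cls,
                         coverage_productive, coverage_control,
                         draws=draws if keep_draws else None)


# ---------------------------------------------------------------------------
# The model object


class SiteSelectionModel:
    """Per-residue selection model for one germline gene.

    Parameters
    ----------
    pairs
        Codon-aligned germline/query pairs, all sharing the same germline.
    frame_classes
        Per-pair labels (``productive`` / ``out_of_frame``); required for
        the out-of-frame-controlled mode.
    mode
        ``outofframe`` (neutral control from out-of-frame rearrangements),
        ``unconditional`` (forward-simulation control, used for
        simulation validation) or ``naive`` (uncontrolled N/S ratio).
    hky
        Pre-fitted :class:`HKYTriple`; fitted from the pairs when omitted.
    """

    def __init__(
        self,
        pairs: list[CodonPair],
        frame_classes: list[str] | None = None,
        mode: str = "outofframe",
        hky: HKYTriple | None = None,
        prior_mean: float = 0.1,
        mcmc_iters: int = 20000,
        mcmc_thin: int = 40,
        min_coverage: int = 100,
        bci_level: float = 0.95,
        n_rate_draws: int = 500,
    ):
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if not pairs:
            raise ValueError("need at least one pair")
        L = pairs[0].n_sites
        if any(p.n_sites != L for p in pairs):
            raise ValueError("all pairs must share the germline coordinate system")
        if not np.all([np.array_equal(p.germline, pairs[0].germline) for p in pairs]):
            raise ValueError("all pairs must share the same germline sequence")
        if mode == "outofframe":
            if frame_classes is None:
                raise ValueError("outofframe mode requires frame_classes")
        if frame_classes is None:
            frame_classes = [PRODUCTIVE] * len(pairs)
        if len(frame_classes) != len(pairs):
            raise ValueError("one frame class per pair required")
        self.pairs = pairs
        self.frame_classes = list(frame_classes)
        self.mode = mode
        self.hky = hky
        self.prior_mean = prior_mean
        self.mcmc_iters = mcmc_iters
        self.mcmc_thin = mcmc_thin
        self.min_coverage = min_coverage
        self.bci_level = bci_level
        self.n_rate_draws = n_rate_draws
        self.L = L

    def fit(self, seed: int = 0) -> "SelectionResults":
        """Run the whole chain: HKY fit, branch MCMC, stochastic mapping,
        aggregation, empirical-Bayes shrinkage and omega estimation."""
        rng = np.random.default_rng(seed)
        hky = self.hky
        if hky is None:
            hky = fit_hky_triple([p for p, f in zip(self.pairs, self.frame_classes)
                                  if f != OUT_OF_FRAME] or self.pairs)
        L = self.L
        tables: dict[str, SiteCountTable] = {
            "P_cond": SiteCountTable.empty(L),
            "O_cond": SiteCountTable.empty(L),
            "P_uncond": SiteCountTable.empty(L),
        }
        branch_means = np.zeros(len(self.pairs))
        for i, (pair, fc) in enumerate(zip(self.pairs, self.frame_classes)):
            t_samples = mcmc_branch_length(
                pair, hky, prior_mean=self.prior_mean, iters=self.mcmc_iters,
                thin=self.mcmc_thin, seed=rng.integers(2 ** 31))
            t_mean = float(t_samples.mean())
            branch_means[i] = t_mean
            covered = pair.covered
            n_l, s_l = conditional_counts(pair, t_samples, hky,
                                          seed=rng.integers(2 ** 31))
            key = "O_cond" if fc == OUT_OF_FRAME else "P_cond"
            tables[key].add(n_l, s_l, t_mean, covered)
            if self.mode == "unconditional" and fc != OUT_OF_FRAME:
                un_l, us_l = unconditional_counts(pair.germline, t_samples, hky,
                                                  seed=rng.integers(2 ** 31),
                                                  sites_mask=covered)
                tables["P_uncond"].add(un_l, us_l, t_mean, covered)
        return self._estimate(hky, tables, branch_means, rng)

    def _estimate(self, hky, tables, branch_means, rng) -> "SelectionResults":
        strata = {
            "outofframe": [("P_cond", "n"), ("P_cond", "s"),
                           ("O_cond", "n"), ("O_cond", "s")],
            "unconditional": [("P_cond", "n"), ("P_cond", "s"),
                              ("P_uncond", "n"), ("P_uncond", "s")],
            "naive": [("P_cond", "n"), ("P_cond", "s")],
        }[self.mode]
        fits: dict[tuple[str, str], GammaPoissonFit] = {}
        draws: dict[tuple[str, str], list] = {}
        for key, kind in strata:
            table = tables[key]
            counts = table.n_counts if kind == "n" else table.s_counts
            fit = fit_gamma_poisson(counts, table.exposure)
            fits[(key, kind)] = fit
            draws[(key, kind)] = [
                posterior_rate_draws(counts[l], table.exposure[l], fit,
                                     n_draws=self.n_rate_draws,
                                     seed=rng.integers(2 ** 31))
                for l in range(self.L)
            ]
        rate_means = {key: np.array([
            float(np.mean(d)) if d is not None else np.nan for d in draws[key]])
            for key in draws}
        germ_aa = AA_BY_CODON[self.pairs[0].germline]
        cov_p = tables["P_cond"].coverage
        cov_o = (tables["O_cond"].coverage if self.mode == "outofframe" else cov_p)
        estimates = []
        for l in range(self.L):
            if self.mode == "outofframe":
                args = (draws[("P_cond", "n")][l], draws[("P_cond", "s")][l],
                        draws[("O_cond", "n")][l], draws[("O_cond", "s")][l])
            elif self.mode == "unconditional":
                args = (draws[("P_cond", "n")][l], draws[("P_cond", "s")][l],
                        draws[("P_uncond", "n")][l], draws[("P_uncond", "s")][l])
            else:
                args = (draws[("P_cond", "n")][l], draws[("P_cond", "s")][l],
                        None, None)
            estimates.append(omega_per_site(
                l, *args,
                coverage_productive=int(cov_p[l]),
                coverage_control=int(cov_o[l]),
                min_coverage=self.min_coverage, bci_level=self.bci_level,
                germline_aa=str(germ_aa[l])))
        return SelectionResults(model=self, hky=hky, tables=tables, fits=fits,
                                estimates=estimates, branch_means=branch_means,
                                rate_means=rate_means)


@dataclass
class SelectionResults:
    """Per-site selection estimates with their provenance."""

    model: SiteSelectionModel
    hky: HKYTriple
    tables: dict[str, SiteCountTable]
    fits: dict
    estimates: list[OmegaEstimate]
    branch_means: np.ndarray
    rate_means: dict = field(default_factory=dict)

    @property
    def table(self) -> pd.DataFrame:
        p = self.tables["P_cond"]
        ctrl_key = {"outofframe": "O_cond", "unconditional": "P_uncond",
                    "naive": "P_cond"}[self.model.mode]
        o = self.tables[ctrl_key]
        num_key, den_key = "P_cond", ctrl_key
        rows = []
        for e in self.estimates:
            l = e.site
            width = e.hi - e.lo

            def rate(key, kind):
                arr = self.rate_means.get((key, kind))
                return float(arr[l]) if arr is not None else np.nan

            rows.append(dict(
                site=l,
                n_productive=int(p.coverage[l]), n_control=int(o.coverage[l]),
                c_n=p.n_counts[l], c_s=p.s_counts[l],
                ctrl_n=o.n_counts[l], ctrl_s=o.s_counts[l],
                exposure=p.exposure[l],
                lambda_n=rate(num_key, "n"), lambda_s=rate(num_key, "s"),
                lambda_ctrl_n=rate(den_key, "n"), lambda_ctrl_s=rate(den_key, "s"),
                omega_median=e.median, bci_lo=e.lo, bci_hi=e.hi,
                bci_width=width,
                bci_rel_width=(width / e.median if e.median and np.isfinite(e.median)
                               and e.median > 0 else np.nan),
                classification=e.classification,
            ))
        return pd.DataFrame(rows)

    def plot_omega(self, ax=None, log_scale: bool = True):
        """Per-site omega medians with 95% credible intervals.

        Negatively selected sites are drawn red, positive blue, neutral
        grey; unclassifiable sites are skipped.  Returns the axis.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3.2))
        colors = {NEGATIVE: "#c0392b", POSITIVE: "#2e6da4", NEUTRAL: "#777777"}
        for e in self.estimates:
            color = colors.get(e.classification)
            if color is None or not np.isfinite(e.median):
                continue
            ax.vlines(e.site, e.lo, e.hi, color=color, alpha=0.6, lw=1.2)
            ax.plot(e.site, e.median, "o", color=color, ms=3)
        ax.axhline(1.0, color="black", lw=0.8, ls="--")
        if log_scale:
            ax.set_yscale("log")
        ax.set_xlabel("codon site")
        ax.set_ylabel(r"$\omega$ (95% BCI)")
        return ax

    def classification_counts(self) -> dict[str, int]:
        out = {NEGATIVE: 0, NEUTRAL: 0, POSITIVE: 0, UNCLASSIFIABLE: 0}
        for e in self.estimates:
            out[e.classification] += 1
        return out

    def summary(self) -> str:
        t = self.table
        classified = t[t.classification != UNCLASSIFIABLE]
        counts = self.classification_counts()
        lines = [
            f"Site-specific selection estimates ({self.model.mode} control)",
            f"  sites: {len(t)}   classifiable: {len(classified)}",
            f"  negative: {counts[NEGATIVE]}  neutral: {counts[NEUTRAL]}  "
            f"positive: {counts[POSITIVE]}  unclassifiable: {counts[UNCLASSIFIABLE]}",
        ]
        if len(classified):
            lines += [
                f"  mean omega (classifiable sites): {classified.omega_median.mean():.3f}",
                f"  fraction median omega < 1: "
                f"{(classified.omega_median < 1).mean():.3f}",
                f"  fraction confidently negative: "
                f"{(classified.classification == NEGATIVE).mean():.3f}",
            ]
        lines.append(f"  median branch length: {np.median(self.branch_means):.5f}")
        return "\n".join(lines)


def reestimate_mode(results: SelectionResults, mode: str, seed: int = 0) -> SelectionResults:
    """Re-derive omega estimates from already-computed count tables under a
    different control mode (no MCMC or mapping is redone).

    Useful for comparing the out-of-frame-controlled estimator with the
    naive N/S-ratio estimator on identical counts.
    """
    import copy

    if mode == "unconditional" and results.tables["P_uncond"].exposure.sum() == 0:
        raise ValueError("unconditional counts were not computed in the original fit")
    model = copy.copy(results.model)
    model.mode = mode
    rng = np.random.default_rng(seed)
    return model._estimate(results.hky, results.tables, results.branch_means, rng)


def selection_report(results: SelectionResults, gene: str) -> tuple[pd.DataFrame, dict]:
    """Per-site report table plus per-gene classification summary."""
    t = results.table.copy()
    t.insert(0, "gene", gene)
    t.insert(2, "imgt_site", t["site"] + 1)  # 1-based display numbering
    classified = t[t.classification != UNCLASSIFIABLE]
    summary = dict(
        gene=gene,
        n_sites=len(t),
        n_classifiable=len(classified),
        mean_omega=float(classified.omega_median.mean()) if len(classified) else np.nan,
        frac_median_lt_1=float((classified.omega_median < 1).mean())
        if len(classified) else np.nan,
        frac_negative=float((classified.classification == NEGATIVE).mean())
        if len(classified) else np.nan,
        **{f"n_{k}": v for k, v in results.classification_counts().items()},
    )
    return t, summary


def amino_acid_profile(pairs: list[CodonPair], frame_classes=None) -> pd.DataFrame:
    """Per-site amino-acid frequencies among productive sequences."""
    if frame_classes is None:
        frame_classes = [PRODUCTIVE] * len(pairs)
    L = pairs[0].n_sites
    rows = []
    for l in range(L):
        counts: dict[str, int] = {}
        for pair, fc in zip(pairs, frame_classes):
            if fc != PRODUCTIVE or pair.query[l] < 0:
                continue
            aa = str(AA_BY_CODON[pair.query[l]])
            counts[aa] = counts.get(aa, 0) + 1
        total = sum(counts.values())
        for aa, c in sorted(counts.items()):
            rows.append(dict(site=l, amino_acid=aa, count=c,
                             frequency=c / total if total else np.nan))
    return pd.DataFrame(rows)
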