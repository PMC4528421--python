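# Methods

`bcrstar` analyses B-cell receptor (BCR) heavy-chain sequences as a set of
independent germline-rooted pairs: every observed sequence is related to
its known germline V(D)J template by a single branch of a star phylogeny.
This note records the models, the estimation procedures, the synthetic-data
generators, and the numerical and design choices behind them.

## The star-tree setting

Affinity maturation mutates each rearranged BCR away from a germline
template that is *known* (the assigned V, D and J genes), and the chance
that two sampled sequences share post-rearrangement ancestry is small in a
deep repertoire. The likelihood of an observed sequence therefore
conditions on the germline root state and integrates only over the single
branch leading to the observation — no tree search, no root frequency
term. Non-templated (N-region) columns have no germline state and are
excluded from all evolutionary computations, as are codons containing
gaps or ambiguous bases.

Out-of-frame rearrangements — V and J joined in different reading
frames — ride along in cells whose second allele is productive. They are
hypermutated by the same machinery but encode no protein, so they evolve
free of selection; the package uses them as the neutral control for
selection inference. Sequences whose templated region contains an in-frame
stop codon are excluded entirely, since a stop can reflect either a failed
rearrangement or a lethal mutation.

## Preprocessing and annotation

*Consensus collapsing.* Reads within a sequencing well are joined by
single-linkage transitive closure at Hamming distance ≤ 2 (reads of
unequal length are never joined, as the distance is undefined) and reduced
to a per-position majority consensus; ties go to the alphabetically first
base and `N` votes are ignored unless unanimous. Groups of one read are
discarded. The linkage rule and tie-breaks are our choices — the procedure
is deterministic and order-invariant, which we prioritized.

*VDJ assignment.* Local alignment uses an affine-gap Smith–Waterman
(three-matrix Gotoh) DP with deterministic traceback (diagonal ≻ vertical
≻ horizontal on ties). Defaults: match +2, mismatch −3, gap open 5, gap
extend 1 — standard nucleotide scoring; nothing in the analysis pins these
down, so they are configuration, and reported scores are raw (not
length-normalized). The best-scoring V gene is found over the whole read;
D and J are fitted to the 3′ remainder. Score ties between alleles are
resolved by a seeded uniform choice among alleles at abundance ≥ 10%. A
segment hit is accepted when its score reaches half the score of a perfect
20-nt match (configurable). A read is *productive* when the V- and
J-implied reading frames agree across the junction, *out-of-frame*
otherwise; frame phases are propagated from the nearest aligned column so
junction indels are tolerated.

## Partitioned substitution models

Four nested GTR+Γ model variants describe how the substitution process may
differ among the V, D and J segments (branch lengths per sequence or per
sequence×segment; GTR matrices and discrete-Gamma shapes shared or
per-segment; relative segment rates r_D, r_J with r_V ≡ 1):

| name   | branch lengths | GTR | Γ | free parameters |
|--------|----------------|-----|---|-----------------|
| tiQiGi | per segment × sequence | per segment | per segment | 3n + 27 |
| trQiGi | per sequence + 2 rates | per segment | per segment | n + 29 |
| trQiGs | per sequence + 2 rates | per segment | shared | n + 27 |
| trQsGs | per sequence + 2 rates | shared | shared | n + 11 |

Each GTR matrix is built as q_ij = s_ij π_j with the GT exchangeability
fixed to 1, normalized to one expected substitution per site per unit
time, and satisfies detailed balance by construction. Across-site rate
variation uses a four-category discretized Gamma with equal-probability
bins and category means (rescaled to mean exactly 1). Because categories
are i.i.d. across sites and the root is known, the 4×4 germline→query
count matrix per (sequence, segment) is a sufficient statistic; all
likelihood evaluations are vectorized over sequences through a cached
symmetric eigendecomposition of Q.

Fitting alternates (a) derivative-free box-constrained Powell passes over
substitution parameters, blockwise by segment, with log/logit
reparameterizations, and (b) a golden-section search on log branch length
run simultaneously for all sequences, until the round-to-round
log-likelihood gain falls below `tol` (default 0.001, matching the
published stopping rule). Models are compared by AIC (2k − 2 logL) and
BIC (k ln n − 2 logL, with n the number of sequences — a choice we record
since the observation count is ambiguous in a partitioned pairwise
setting).

*Compositional PCA.* A fitted model is summarized by the transition matrix
P = exp(Q·r·t̂) at the median fitted branch length, interpreted as four
conditional distributions given an equiprobable starting state (no
π-weighting of rows). Each row is mapped by the centred log-ratio
transform and the concatenated 16-vectors are analysed by ordinary
centred PCA (SVD). Model–sequence distance association is the Spearman
correlation between pairwise germline Hamming distances and pairwise
Euclidean clr distances.

## Per-residue selection estimation

The estimator has five stages, run per germline V gene.

1. **Mapping model.** A deliberately simple nucleotide model — independent
   HKY85 per codon position with relative position rates (normalized to
   mean 1) — is fitted by ML to the whole pair set (alternating Powell /
   scalar passes; empirical base frequencies) and then held fixed. A full
   codon model would be preferable in principle but is computationally
   prohibitive at repertoire scale; the mapping model's role is only to
   propose substitution histories.

2. **Branch-length posteriors.** Each sequence's branch length gets an
   Exp(mean 0.1 substitutions/site) prior and is sampled by
   Metropolis–Hastings with a multiplicative scaling proposal
   (t′ = t·exp(s(u−½)), Hastings factor t′/t, s = 1.2). The production
   default (20 000 iterations thinned by 40) and the validation setting
   (4000/8) both retain 500 samples. With an empty alignment the
   posterior equals the prior and is sampled directly.

3. **Stochastic mapping.** For every retained branch length, a full
   substitution history of each nucleotide column is drawn from the
   endpoint-conditioned chain by uniformization: the jump count from its
   exact conditional distribution (Poisson–bridge mixture), intermediate
   states from the discrete bridge, jump times as uniform order
   statistics. Events from the three columns of a codon are merged in
   time order and classified synonymous/non-synonymous against the
   *current* codon, so multiple hits are replayed correctly; events that
   create a stop codon count as non-synonymous and the path is kept
   (observed endpoints are stop-free because such sequences are removed
   upstream; resampling would bias the counts). Per-site counts are
   averaged over the 500 samples and then summed across sequences —
   averaging first keeps exposures on the per-sequence scale.
   "Unconditional" counts forward-simulate from the germline state along
   the same sampled branch lengths with no endpoint conditioning,
   restricted to the codons the read covers.

4. **Empirical-Bayes shrinkage.** Per count class, site counts follow
   C_l ~ Poisson(λ_l t_l) with exposure t_l = Σ_i t̄_i over the sequences
   covering site l, and λ_l ~ Gamma(α, β) across sites. (α, β) maximize
   the marginal likelihood — a product of negative-binomial-type terms
   with a Gamma-function (continuous-count) generalization, since the
   posterior-averaged counts are not integers — by Nelder–Mead from a
   moment-based start. When the exposure-weighted count variance falls
   below the weighted mean the Gamma fit degenerates and a pooled Poisson
   rate λ̂ = ΣC/Σt is used; per-site uncertainty then comes from
   Jeffreys-style Gamma(C_l + ½, t_l) draws so intervals stay defined (a
   choice of ours — the fallback's downstream uncertainty is otherwise
   unspecified). Rate posteriors in the Gamma mode are conjugate:
   Gamma(α̂ + C_l, β̂ + t_l), sampled in closed form. The four count
   classes (N/S × productive/control) are fitted independently — the
   least-coupled reading; sharing hyperparameters across classes is a
   config switch away.

5. **Selection coefficient.** With productive (P) and out-of-frame (O)
   conditional rates,

       ω_l = (λ^N_{P,l} / λ^N_{O,l}) / (λ^S_{P,l} / λ^S_{O,l}),

   computed over index-paired posterior draws (500 by default); the
   out-of-frame denominator absorbs motif-driven rate variation because
   both classes are mutated by the same context-biased machinery. The
   alternative "unconditional" mode replaces the out-of-frame rates with
   the forward-simulated ones (the original formulation; used for
   simulation validation where no out-of-frame class exists), and a
   "naive" mode (λ^N_P / λ^S_P, no control) exists as the cautionary
   baseline. Sites are classified positive/negative when the equal-tailed
   95% credible interval of ω excludes 1, and unclassifiable when either
   class covers the site with fewer than 100 sequences, or the germline
   codon encodes Trp or Met (no synonymous move exists, so ω is
   undefined at the root state). All thresholds are configuration with
   these defaults.

## Synthetic data

*GY94 star simulator.* Codon sequences evolve from a root by exact
Gillespie simulation under the Goldman–Yang codon model
(q_xy = π_y · κ^[transition] · ω_l^[non-synonymous] for single-nucleotide
changes), with per-site ω multipliers. Q is normalized so one unit of
branch length equals one expected substitution per codon site at ω = 1;
the normalizer deliberately excludes ω so that selection changes the
realized rate, and the truth tables record the convention. The validation
preset reproduces the three-tier design: 100 codons, branch length 0.05,
85 sites at ω = 0.1, 5 at ω = 1, 10 at ω = 10, 1000 sequences, with
left-truncated coverage (first 10 codons uncovered, next 40 covered by
half the sequences, last 50 by all). κ = 2 and uniform sense-codon (F61)
frequencies are our choices where the design leaves them open — a
transition bias of about two is typical of somatic hypermutation data.
The simulator also emits the true per-site event counts.

*Repertoire generator.* V(D)J rearrangements are built from a synthetic
germline mini-database with junctional deletions and a non-templated
insertion whose length is adjusted to realize a drawn frame class
(out-of-frame fraction configurable). Point mutations arrive with
per-site probabilities scaled by IUPAC-motif context multipliers (e.g.
WRC/GYW hotspots); selection is emulated by rejecting non-synonymous
changes at designated sites with configurable acceptance probability, in
productive sequences only — a simple stand-in for affinity selection, not
a mechanistic claim. Mutations creating in-frame stops in productive
sequences are reverted, mirroring the upstream has-stop filter. Reads may
be truncated to a 3′-anchored window. Every simulation emits a truth
table (genes, frame class, mutated positions, coverage), and downstream
tests consume truth rather than re-deriving it.

What the generators do *not* emulate: lineage structure (clonal
expansions), indels, sequencing error profiles, primer bias, and the full
complexity of AID targeting beyond configurable motif multipliers. Tests
passing on these simulations therefore demonstrate the statistical
machinery under its own assumptions — known root, star genealogy,
point-mutation evolution — not robustness to those real-data features.

## Validation behaviour and known limitations

The built-in benchmark (`bcrstar.validation.run_validation_analysis`)
runs the full chain on the three-tier design (1000 sequences; MCMC
4000/8, retaining the standard 500 samples — the problem size completes
in a few minutes on one CPU). Typical recovery, median of per-site
posterior medians per tier: purifying ≈ 0.07–0.11 (truth 0.1), neutral
≈ 0.5–0.9 (truth 1), positive ≈ 4.3–6.3 (truth 10), with the 95%
interval covering 1 at essentially all neutral sites.

Two systematic effects compress estimates toward unity from above and
deflate them from below, and both are inherent to mapping with a fixed,
dataset-wide nucleotide model rather than artifacts of this
implementation (the path sampler and the conjugate posteriors are verified
against exact oracles in the test suite):

- *Multiple-hit saturation.* Endpoint-conditioned counts under a
  rate-homogeneous mapping model cannot impute the extra hits that
  accumulate at sites evolving an order of magnitude faster than the
  model rate, so strongly positively selected sites are reported around
  5 rather than 10.
- *Mixture contamination.* The HKY parameters are fitted to all sites
  jointly; purifying and positively selected sites distort the fitted
  position rates and κ, tilting the forward-simulated (unconditional)
  N/S opportunity ratio above the truly neutral one and deflating ω by
  roughly 20% even at neutral sites. In the out-of-frame-controlled mode
  this cancels, because numerator and denominator classes are mapped with
  the same model; it matters only for the unconditional mode used in
  simulation validation.

Precision tracks coverage: relative interval widths over the
half-coverage block exceed those over the full-coverage block (comparing
raw widths across blocks conflates coverage with the positive-selection
tier that happens to sit in the full-coverage block; matched-tier raw
widths also shrink with coverage).

With hotspot-driven mutation and no selection, the out-of-frame-controlled
estimator calls ≤ 5% of sites non-neutral while the naive N/S estimator
flags nearly all hotspot-overlapping sites — the false-positive-control
property that motivates the estimator.

## Numerical choices

- Branch-length box [1e−6, 10] substitutions/site; golden-section
  resolution 1e−4 in log-t; Powell tolerances 1e−6 (parameters), 1e−8
  (function).
- Transition matrices via cached symmetric eigendecompositions; entries
  clipped at 0 and log-likelihood floored at 1e−300 before logs.
- Uniformization rate 1.05 × the maximum exit rate; jump counts capped at
  60 (the tail probability is negligible at the branch lengths involved).
- Every stochastic stage takes an explicit seed; the pipeline derives
  per-stage, per-gene seeds by hashing (run seed, stage, item), so
  parallel per-gene execution reproduces serial output byte for byte.
- Degenerate inputs: empty read sets collapse to empty output; all-
  identical pair sets drive branch lengths to the lower bound and flag
  the HKY fit unconverged; zero-exposure sites fall back to the prior and
  are unclassifiable by coverage.
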