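"""GY94 simulator, coverage schemes and the repertoire generator."""

import numpy as np
import pytest
from scipy.stats import binomtest, chi2_contingency

from bcrstar.codons import AA_BY_CODON, SENSE_CODONS, codon_index, translate
from bcrstar.simulate import (CoverageScheme, GY94Params, RepertoireConfig,
                              apply_coverage, gy94_q, motif_multipliers,
                              simulate_repertoire, simulate_star,
                              simulate_validation, toy_germline_db,
                              validation_omega_layout)


class TestGY94Q:
    def test_rows_sum_to_zero_and_single_steps_only(self):
        q = gy94_q(GY94Params(kappa=1.0, omega=1.0))
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)
        codons = [SENSE_CODONS[i] for i in range(61)]
        for i in range(61):
            for j in range(61):
                if i == j:
                    continue
                diff = sum(((codons[i] >> s) & 3) != ((codons[j] >> s) & 3)
                           for s in (0, 2, 4))
                if diff != 1:
                    assert q[i, j] == 0.0

    def test_neutral_mean_rate_is_one(self):
        p = GY94Params(kappa=3.0, omega=1.0)
        q = gy94_q(p)
        assert np.isclose(-(p.codon_frequencies * np.diag(q)).sum(), 1.0)

    def test_tta_ttg_entry_carries_kappa_not_omega(self):
        """TTA->TTG is synonymous (both Leu) via an A->G transition, so the
        entry is kappa * pi and unchanged by omega."""
        local = {int(c): k for k, c in enumerate(SENSE_CODONS)}
        i, j = local[codon_index("TTA")], local[codon_index("TTG")]
        q1 = gy94_q(GY94Params(kappa=2.0, omega=1.0))
        q5 = gy94_q(GY94Params(kappa=2.0, omega=5.0))
        assert q1[i, j] == pytest.approx(q5[i, j])
        # within one matrix, syn transition / syn transversion = kappa
        # (uniform codon frequencies): CTA->CTC is a synonymous transversion
        k, m = local[codon_index("CTA")], local[codon_index("CTC")]
        assert q1[i, j] / q1[k, m] == pytest.approx(2.0)

    def test_omega_scales_nonsyn_entries_exactly(self):
        local = {int(c): k for k, c in enumerate(SENSE_CODONS)}
        i, j = local[codon_index("TTA")], local[codon_index("TCA")]  # Leu->Ser
        q1 = gy94_q(GY94Params(omega=1.0))
        q2 = gy94_q(GY94Params(omega=2.0))
        assert q2[i, j] == pytest.approx(2.0 * q1[i, j])

    def test_stop_root_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            simulate_star(np.array([codon_index("TAA")]), 2, 0.1, GY94Params())


class TestSimulateStar:
    def test_t_zero_identity(self):
        root = SENSE_CODONS[:20]
        aln = simulate_star(root, 5, 0.0, GY94Params(), seed=1)
        assert (aln == root).all()

    def test_nonsyn_fraction_monotone_in_omega(self):
        rng = np.random.default_rng(0)
        root = SENSE_CODONS[rng.choice(61, size=40)]
        fracs = []
        for w in (0.1, 1.0, 10.0):
            aln = simulate_star(root, 400, 0.2, GY94Params(omega=w), seed=3)
            changed_aa = (AA_BY_CODON[aln] != AA_BY_CODON[root]).mean()
            changed_nt = (aln != root).mean()
            fracs.append(changed_aa / changed_nt)
        assert fracs[0] < fracs[1] < fracs[2]

    def test_true_event_counts_scale_with_omega(self):
        root = np.array([codon_index("CTT")] * 30)
        _, n01, s01 = simulate_star(root, 200, 0.1, GY94Params(omega=0.1),
                                    seed=5, return_counts=True)
        _, n10, s10 = simulate_star(root, 200, 0.1, GY94Params(omega=10.0),
                                    seed=5, return_counts=True)
        assert n10.sum() > 10 * n01.sum() * 0.5
        assert s10.sum() < 5 * max(s01.sum(), 1)

    def test_stationary_codon_frequencies_at_large_t(self):
        """At t >> 1 the codon distribution converges to pi (chi-square GoF)."""
        rng = np.random.default_rng(2)
        root = SENSE_CODONS[rng.choice(61, size=4)]
        aln = simulate_star(root, 2500, 50.0, GY94Params(kappa=2.0), seed=8)
        counts = np.bincount(
            np.searchsorted(SENSE_CODONS, aln.ravel()), minlength=61)
        expected = np.full(61, counts.sum() / 61.0)
        chi2 = ((counts - expected) ** 2 / expected).sum()
        # 60 dof: 99th percentile ~ 88.4
        assert chi2 < 88.4


class TestCoverage:
    def test_all_ones_scheme_unchanged(self):
        aln = np.arange(40).reshape(4, 10)
        masked, starts = apply_coverage(aln, CoverageScheme.full(), seed=0)
        assert (masked == aln).all()
        assert (starts == 0).all()

    def test_validation_scheme_block_fractions(self):
        aln = np.zeros((600, 100), dtype=np.int64)
        masked, starts = apply_coverage(aln, CoverageScheme.validation(), seed=1)
        cov = (masked >= 0).mean(axis=0)
        assert (cov[:10] == 0.0).all()
        assert (cov[50:] == 1.0).all()
        frac_half = cov[10:50].mean()
        ci = binomtest(int(frac_half * 600), 600, 0.5).proportion_ci(0.999)
        assert ci.low <= 0.5 <= ci.high

    def test_site_coverage_equals_interval_sum(self):
        aln = np.zeros((50, 20), dtype=np.int64)
        masked, starts = apply_coverage(
            aln, CoverageScheme([(0.3, 0), (0.7, 12)]), seed=3)
        for l in range(20):
            assert (masked[:, l] >= 0).sum() == (starts <= l).sum()

    def test_bad_probabilities_rejected(self):
        with pytest.raises(ValueError):
            CoverageScheme([(0.5, 0), (0.6, 5)])


def test_validation_layout_and_truth():
    w = validation_omega_layout()
    assert (w[:85] == 0.1).all() and (w[85:90] == 1.0).all() and (w[90:] == 10.0).all()
    val = simulate_validation(n_seqs=50, seed=4)
    truth = val.truth_frame()
    assert list(truth.columns) == ["site", "true_omega", "coverage"]
    assert truth.coverage[:10].sum() == 0
    assert val.true_n_events is not None
    # positive block generated many more non-synonymous events per site
    assert val.true_n_events[90:].mean() > 5 * val.true_n_events[:85].mean()


class TestMotifMultipliers:
    def test_wrc_hotspot_positions(self):
        # WRC motif, mutable base C at offset 2
        seq = "TACGGG"  # TAC matches WRC at start
        mult = motif_multipliers(seq, {"WRC": (2, 5.0)})
        assert mult[2] == 5.0
        assert mult[0] == mult[1] == 1.0

    def test_overlapping_motifs_take_max(self):
        seq = "AACAAC"
        mult = motif_multipliers(seq, {"AAC": (2, 3.0), "ACA": (1, 7.0)})
        assert mult[2] == 7.0


class TestRepertoire:
    def test_no_mutation_reads_are_germline(self):
        cfg = RepertoireConfig(germline_db=toy_germline_db(1), shm_rate=0.0)
        rep = simulate_repertoire(cfg, 25, seed=2)
        for s in rep.sequences:
            assert s.mutated_v_positions == ()
        pairs, labels = rep.v_codon_pairs(rep.sequences[0].v_gene)
        for p in pairs:
            cov = p.query >= 0
            assert (p.query[cov] == p.germline[cov]).all()

    def test_out_of_frame_fraction_within_binomial_ci(self):
        cfg = RepertoireConfig(germline_db=toy_germline_db(1),
                               fraction_out_of_frame=0.3, shm_rate=0.01)
        rep = simulate_repertoire(cfg, 500, seed=6)
        k = sum(s.frame_class == "out_of_frame" for s in rep.sequences)
        ci = binomtest(k, 500, 0.3).proportion_ci(0.999)
        assert ci.low <= 0.3 <= ci.high

    def test_hotspot_without_selection_frames_indistinguishable(self):
        """With a 5x hotspot and no selection, per-site mutation counts in
        productive and out-of-frame sequences are statistically
        indistinguishable (this is the premise of the neutral control)."""
        cfg = RepertoireConfig(germline_db=toy_germline_db(3, n_v=1, n_j=1),
                               fraction_out_of_frame=0.5, shm_rate=0.03,
                               hotspot_motifs={"WRC": (2, 5.0), "GYW": (0, 5.0)})
        rep = simulate_repertoire(cfg, 1200, seed=9)
        v_len = len(cfg.germline_db[0].nucleotides)
        counts = {"productive": np.zeros(v_len), "out_of_frame": np.zeros(v_len)}
        totals = {"productive": 0, "out_of_frame": 0}
        for s in rep.sequences:
            totals[s.frame_class] += 1
            for p in s.mutated_v_positions:
                counts[s.frame_class][p] += 1
        # aggregate chi-square over position blocks with decent counts
        block = 10
        p_blocks = counts["productive"][: v_len // block * block].reshape(-1, block).sum(1)
        o_blocks = counts["out_of_frame"][: v_len // block * block].reshape(-1, block).sum(1)
        keep = (p_blocks + o_blocks) >= 10
        _, pval, _, _ = chi2_contingency(np.vstack([p_blocks[keep], o_blocks[keep]]))
        assert pval > 0.01

    def test_selection_reduces_nonsyn_in_productive_only(self):
        sel = {l: 0.0 for l in range(50)}  # reject every nonsyn change in V
        cfg = RepertoireConfig(germline_db=toy_germline_db(3, n_v=1, n_j=1),
                               fraction_out_of_frame=0.5, shm_rate=0.03,
                               selection=sel)
        rep = simulate_repertoire(cfg, 600, seed=12)
        gene = cfg.germline_db[0]
        rate = {"productive": [0, 0], "out_of_frame": [0, 0]}  # [nonsyn, syn]
        for s in rep.sequences:
            for p in s.mutated_v_positions:
                codon_start = (p // 3) * 3
                germ_codon = gene.nucleotides[codon_start:codon_start + 3]
                mut = s.sequence[p - s.v_start]
                new_codon = (germ_codon[: p - codon_start] + mut
                             + germ_codon[p - codon_start + 1:])
                syn = translate(germ_codon) == translate(new_codon)
                rate[s.frame_class][1 if syn else 0] += 1
        # productive kept syn changes but its nonsyn were rejected
        assert rate["productive"][0] < 0.2 * rate["out_of_frame"][0]
        assert rate["productive"][1] > 0

    def test_productive_sequences_stop_free(self):
        cfg = RepertoireConfig(germline_db=toy_germline_db(5), shm_rate=0.05)
        rep = simulate_repertoire(cfg, 300, seed=13)
        for s in rep.sequences:
            if s.frame_class != "productive":
                continue
            seq = s.sequence
            for i in range(0, s.v_end - s.v_start - 2, 3):
                assert translate(seq[i:i + 3]) != "*"
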