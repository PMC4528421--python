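"""Endpoint-conditioned path sampling and syn/nonsyn counting oracles."""

import numpy as np
import pytest
from scipy.linalg import expm

from bcrstar.codons import (AA_BY_CODON, codon_index,
                            substitution_is_synonymous)
from bcrstar.hky import HKYTriple
from bcrstar.mapping import (Event, conditional_counts, count_syn_nonsyn,
                             sample_history, unconditional_counts)
from bcrstar.pairs import CodonPair


@pytest.fixture(scope="module")
def hky():
    return HKYTriple(kappa=[2.0, 1.5, 3.0],
                     pi=[[0.3, 0.2, 0.3, 0.2], [0.25] * 4, [0.1, 0.4, 0.3, 0.2]],
                     rel_rate=[1.0, 0.8, 1.2])


def codon_generator(hky):
    """64-state Kronecker-sum generator of the three independent
    per-position chains (independent oracle machinery)."""
    I4 = np.eye(4)
    return (np.kron(np.kron(hky.q(0), I4), I4)
            + np.kron(np.kron(I4, hky.q(1)), I4)
            + np.kron(np.kron(I4, I4), hky.q(2)))


def labelled_count_oracle(hky, a, b, t):
    """Exact E[N], E[S] for an endpoint-conditioned codon path, via the
    auxiliary-matrix integral  int_0^t P(s) B P(t-s) ds = expm([[Q,B],[0,Q]] t)
    restricted to the label sets."""
    Q = codon_generator(hky)
    Bn = np.zeros((64, 64))
    Bs = np.zeros((64, 64))
    for i in range(64):
        for j in range(64):
            if i == j or Q[i, j] == 0:
                continue
            diff = [(p, (j >> (2 * (2 - p))) & 3) for p in range(3)
                    if ((i >> (2 * (2 - p))) & 3) != ((j >> (2 * (2 - p))) & 3)]
            if len(diff) != 1:
                continue
            p, nb = diff[0]
            if substitution_is_synonymous(i, p, nb):
                Bs[i, j] = Q[i, j]
            else:
                Bn[i, j] = Q[i, j]
    p_ab = expm(Q * t)[a, b]
    out = []
    for B in (Bn, Bs):
        aux = np.zeros((128, 128))
        aux[:64, :64] = Q
        aux[64:, 64:] = Q
        aux[:64, 64:] = B
        out.append(expm(aux * t)[a, 64 + b] / p_ab)
    return out


class TestSampleHistory:
    def test_differing_endpoints_have_events(self, hky):
        g = np.array([codon_index("AAA")])
        q = np.array([codon_index("AAG")])
        for seed in range(20):
            h = sample_history(g, q, 0.05, hky, seed=seed)
            assert len(h) >= 1
            assert all(isinstance(e, Event) for e in h)

    def test_identical_endpoints_small_t_jump_probability(self, hky):
        """For matching endpoints at tiny t the chance of any event per
        column approximates the exact conditional P(>=1 jump | a -> a)."""
        g = np.array([codon_index("AAA")])
        t = 0.02
        n_draws = 3000
        nonempty = sum(
            bool(sample_history(g, g, t, hky, seed=s)) for s in range(n_draws))
        # exact P(path not constant | endpoints equal), summed over columns
        p_any = 0.0
        for p in range(3):
            qm = hky.q(p)
            pt = expm(qm * t)
            # probability the column path has >= 1 real jump given a -> a:
            # 1 - P(no jump)/P_aa, with P(no jump) = exp(q_aa t)
            a = 0  # germline codon AAA: base A at every position
            p_any += 1.0 - np.exp(qm[a, a] * t) / pt[a, a]
        se = np.sqrt(p_any * (1 - p_any) / n_draws)
        assert nonempty / n_draws == pytest.approx(p_any, abs=4 * se + 1e-3)

    def test_t_zero_rejected(self, hky):
        with pytest.raises(ValueError):
            sample_history(np.array([0]), np.array([0]), 0.0, hky)

    @pytest.mark.parametrize("case", range(5))
    def test_mean_counts_match_eigen_oracle(self, hky, case):
        """Monte-Carlo mean N/S counts on a one-codon pair match the exact
        labelled-count expectation within 3 standard errors."""
        rng = np.random.default_rng(1000 + case)
        sense = np.flatnonzero(AA_BY_CODON != "*")
        a = int(rng.choice(sense))
        t = float(rng.uniform(0.05, 0.4))
        Q = codon_generator(hky)
        b = int(rng.choice(64, p=expm(Q * t)[a]))
        en, es = labelled_count_oracle(hky, a, b, t)
        g, q = np.array([a]), np.array([b])
        ns, ss = [], []
        for k in range(4000):
            h = sample_history(g, q, t, hky, seed=rng.integers(2 ** 31))
            n_l, s_l = count_syn_nonsyn(h, g)
            ns.append(n_l[0])
            ss.append(s_l[0])
        for mc, exact in ((np.array(ns), en), (np.array(ss), es)):
            se = mc.std(ddof=1) / np.sqrt(len(mc)) + 1e-9
            assert mc.mean() == pytest.approx(exact, abs=3 * se + 5e-3)


class TestCountSynNonsyn:
    def test_empty_history(self):
        n, s = count_syn_nonsyn([], np.array([0, 1, 2]))
        assert (n == 0).all() and (s == 0).all()

    def test_single_synonymous_event(self):
        # GGG -> GGA: Gly -> Gly at position 3
        g = np.array([codon_index("GGG")])
        ev = [Event(0, 0.1, 2, 0, 2)]  # G -> A at codon position 3
        n, s = count_syn_nonsyn(ev, g)
        assert n[0] == 0 and s[0] == 1

    def test_order_dependent_classification_matches_replay(self):
        """Two events in one codon: classification depends on time order and
        matches an exhaustive replay of both orders."""
        g = np.array([codon_index("TTA")])  # Leu

        def replay(order):
            codon = "TTA"
            n = s = 0
            for pos, new in order:
                new_codon = codon[:pos] + new + codon[pos + 1:]
                from bcrstar.codons import translate
                if translate(new_codon) == translate(codon) and translate(codon) != "*":
                    s += 1
                else:
                    n += 1
                codon = new_codon
            return n, s

        # TTA -> TTG (syn) then TTG -> CTG (syn: Leu) vs
        # TTA -> CTA (syn) then CTA -> CTG (syn)
        ev_a = [Event(0, 0.1, 3, 2, 2), Event(0, 0.2, 3, 1, 0)]
        got = count_syn_nonsyn(ev_a, g)
        exp = replay([(2, "G"), (0, "C")])
        assert (got[0][0], got[1][0]) == exp

        # reversed order must agree with its own replay
        ev_b = [Event(0, 0.05, 3, 1, 0), Event(0, 0.2, 3, 2, 2)]
        got_b = count_syn_nonsyn(ev_b, g)
        exp_b = replay([(0, "C"), (2, "G")])
        assert (got_b[0][0], got_b[1][0]) == exp_b

    def test_stop_creating_event_counts_nonsynonymous(self):
        g = np.array([codon_index("TGC")])  # Cys; C->A at pos 3 gives TGA stop
        ev = [Event(0, 0.1, 1, 0, 2)]
        n, s = count_syn_nonsyn(ev, g)
        assert n[0] == 1 and s[0] == 0


class TestBatchConditional:
    def test_matches_single_history_sampler(self, hky):
        """The vectorized batch counter agrees with averaging explicit
        single-history draws."""
        rng = np.random.default_rng(3)
        germ = np.array([codon_index(c) for c in ("CTT", "GAA", "TTA", "GGC")])
        quer = np.array([codon_index(c) for c in ("CTC", "GAA", "TCA", "GGC")])
        pair = CodonPair("x", germ, quer)
        t_samples = rng.uniform(0.05, 0.15, size=400)
        n_b, s_b = conditional_counts(pair, t_samples, hky, seed=7)
        ns = np.zeros(4)
        ss = np.zeros(4)
        reps = 400
        for k in range(reps):
            h = sample_history(germ, quer, float(t_samples[k % len(t_samples)]),
                               hky, seed=10 ** 6 + k)
            n_l, s_l = count_syn_nonsyn(h, germ)
            ns += n_l
            ss += s_l
        assert np.allclose(n_b, ns / reps, atol=0.25)
        assert np.allclose(s_b, ss / reps, atol=0.25)

    def test_masked_sites_contribute_nothing(self, hky):
        germ = np.array([codon_index("CTT"), codon_index("GAA")])
        quer = np.array([codon_index("CTC"), -1])
        pair = CodonPair("x", germ, quer)
        n, s = conditional_counts(pair, np.full(50, 0.1), hky, seed=1)
        assert n[1] == 0 and s[1] == 0
        assert n[0] + s[0] > 0.5  # the changed covered site maps events


class TestUnconditional:
    def test_counts_vanish_as_t_to_zero(self, hky):
        germ = np.array([codon_index("CTT")] * 10)
        n, s = unconditional_counts(germ, np.full(200, 1e-5), hky, seed=2)
        assert n.sum() + s.sum() <= 0.05

    def test_tryptophan_first_events_never_synonymous(self, hky):
        """TGG (Trp): every single-nucleotide change is non-synonymous or a
        stop, so synonymous events can only arise from rare multi-hit paths
        that first leave Trp; at small t they are absent."""
        germ = np.array([codon_index("TGG")] * 5)
        n, s = unconditional_counts(germ, np.full(400, 0.05), hky, seed=3)
        assert n.sum() > 0
        assert s.sum() < 0.05 * n.sum()
        n2, s2 = unconditional_counts(germ, np.full(400, 0.004), hky, seed=4)
        assert s2.sum() == 0.0

    def test_first_order_rate_oracle(self, hky):
        """At small t, expected counts approach rate * t computed from the
        germline codon's labelled exit rates (first-order expansion)."""
        a = codon_index("CTT")
        germ = np.array([a])
        t = 0.01
        en = es = 0.0
        for p in range(3):
            qm = hky.q(p)
            base = (a >> (2 * (2 - p))) & 3
            for nb in range(4):
                if nb == base:
                    continue
                rate = qm[base, nb]
                if substitution_is_synonymous(a, p, nb):
                    es += rate * t
                else:
                    en += rate * t
        J = 3000
        n, s = unconditional_counts(germ, np.full(J, t), hky, seed=5)
        se_n = np.sqrt(en / J)
        se_s = np.sqrt(es / J)
        assert n[0] == pytest.approx(en, abs=3 * se_n + 1e-3)
        assert s[0] == pytest.approx(es, abs=3 * se_s + 1e-3)
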