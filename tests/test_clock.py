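"""Likelihood engine oracles and clock-model fitting contracts."""
import itertools
import math

import dendropy
import numpy as np
import pytest

from luxerode import clock as ck
from luxerode import simulate as sim
from luxerode.io import MultipleAlignment


def brute_force_loglik(tree_nwk, aln, model):
    """Sum over all internal-state assignments (exhaustive oracle)."""
    t = dendropy.Tree.get(data=tree_nwk, schema="newick")
    nodes = list(t.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    leaves = [n for n in nodes if n.is_leaf()]
    P = {}
    for n in nodes:
        if n.parent_node is not None:
            P[id(n)] = model.transition_matrices(
                np.array([n.edge.length or 0.0]))[0]
    code = {c: i for i, c in enumerate(model.states)}
    ll = 0.0
    ns = model.n_states
    for site in range(aln.n_columns):
        leaf_state = {id(n): code[aln[n.taxon.label][site]] for n in leaves}
        total = 0.0
        for assign in itertools.product(range(ns), repeat=len(internal)):
            states = dict(zip((id(n) for n in internal), assign))
            states.update(leaf_state)
            p = model.pi[states[id(t.seed_node)]]
            for n in nodes:
                if n.parent_node is not None:
                    p *= P[id(n)][states[id(n.parent_node)], states[id(n)]]
            total += p
        ll += math.log(total)
    return ll


@pytest.fixture(scope="module")
def jc():
    return ck.jc()


class TestPruneLikelihood:
    def test_zero_branch_identical_sequences_closed_form(self, jc):
        aln = MultipleAlignment(["A", "B"], ["ACGTACGT", "ACGTACGT"])
        ll = ck.prune_likelihood("(A:0.0,B:0.0);", aln, jc)
        assert ll == pytest.approx(8 * math.log(0.25), abs=1e-9)

    @pytest.mark.parametrize("nwk,n_taxa", [
        ("((A:0.1,B:0.2):0.05,(C:0.3,D:0.1):0.15);", 4),
        ("(((A:0.1,B:0.2):0.1,C:0.25):0.05,(D:0.3,E:0.02):0.1);", 5),
    ])
    def test_matches_exhaustive_summation(self, nwk, n_taxa, jc, rng):
        n_sites = 30
        labels = "ABCDE"[:n_taxa]
        seqs = ["".join(rng.choice(list("ACGT"), n_sites)) for _ in labels]
        aln = MultipleAlignment(list(labels), seqs)
        ll = ck.prune_likelihood(nwk, aln, jc)
        ll_bf = brute_force_loglik(nwk, aln, jc)
        assert abs(ll - ll_bf) < 1e-8

    def test_gtr_gamma_matches_exhaustive(self, rng):
        model = ck.gtr([1.2, 2.5, 0.8, 1.1, 3.0, 1.0],
                       [0.35, 0.2, 0.25, 0.2], gamma_shape=0.6, gamma_ncat=4)
        nwk = "((A:0.12,B:0.3):0.08,C:0.2);"
        seqs = ["".join(rng.choice(list("ACGT"), 20)) for _ in "ABC"]
        aln = MultipleAlignment(list("ABC"), seqs)
        # mix categories per site with equal weights
        per_site_bf = 0.0
        for site in range(20):
            sub = MultipleAlignment(list("ABC"),
                                    [aln[x][site] for x in "ABC"])
            ps = [brute_force_scaled(nwk, sub, model, r)
                  for r in model.gamma_rates()]
            per_site_bf += math.log(sum(ps) / len(ps))
        ll = ck.prune_likelihood(nwk, aln, model)
        assert abs(ll - per_site_bf) < 1e-8

    def test_reroot_invariance(self, jc, rng):
        nwk = "((A:0.1,B:0.2):0.05,(C:0.3,D:0.1):0.15);"
        seqs = ["".join(rng.choice(list("ACGT"), 40)) for _ in "ABCD"]
        aln = MultipleAlignment(list("ABCD"), seqs)
        ll0 = ck.prune_likelihood(nwk, aln, jc)
        t = dendropy.Tree.get(data=nwk, schema="newick")
        for leaf in ["A", "C", "D"]:
            t2 = dendropy.Tree.get(data=nwk, schema="newick")
            e = t2.find_node_with_taxon_label(leaf).edge
            half = e.length / 2
            t2.reroot_at_edge(e, length1=half, length2=half)
            assert abs(ck.prune_likelihood(t2, aln, jc) - ll0) < 1e-8

    def test_pattern_compression_equals_weighted_columns(self, jc):
        # an alignment of repeated columns must score as weight * single column
        aln1 = MultipleAlignment(["A", "B"], ["AAAGGG", "AAAAAA"])
        aln2 = MultipleAlignment(["A", "B"], ["AG", "AA"])
        nwk = "(A:0.07,B:0.07);"
        ll6 = ck.prune_likelihood(nwk, aln1, jc)
        llAA = ck.prune_likelihood(nwk, MultipleAlignment(["A", "B"],
                                                          ["A", "A"]), jc)
        llGA = ck.prune_likelihood(nwk, MultipleAlignment(["A", "B"],
                                                          ["G", "A"]), jc)
        assert ll6 == pytest.approx(3 * llAA + 3 * llGA, abs=1e-10)

    def test_missing_taxon_raises(self, jc):
        aln = MultipleAlignment(["A", "B"], ["ACGT", "ACGT"])
        with pytest.raises(ValueError, match="C"):
            ck.prune_likelihood("((A:1,B:1):1,C:1);", aln, jc)


def brute_force_scaled(nwk, aln, model, rate):
    t = dendropy.Tree.get(data=nwk, schema="newick")
    for n in t.postorder_node_iter():
        if n.parent_node is not None:
            n.edge.length *= rate
    base = ck.SubstitutionModel(model.alphabet, model.exchangeabilities,
                                model.freqs)
    ll = brute_force_loglik(t.as_string(schema="newick").replace("[&U] ", ""),
                            aln, base)
    return math.exp(ll)


class TestClockFits:
    def test_two_taxon_jc_distance_recovery(self, jc):
        d = 0.2
        aln = sim.simulate_alignment(f"(A:{d / 2},B:{d / 2});", jc,
                                     n_sites=50_000, seed=21)
        fit = ck.fit_global_clock(f"(A:{d / 2},B:{d / 2});", aln, jc)
        total = 2 * max(fit.node_heights.values())
        p = sum(a != b for a, b in zip(aln["A"], aln["B"])) / aln.n_columns
        d_hat = -0.75 * math.log(1 - 4 * p / 3)
        assert total == pytest.approx(d_hat, rel=0.02)
        assert fit.converged

    def test_identical_sequences_collapse_to_zero(self, jc):
        aln = MultipleAlignment(["A", "B", "C"], ["ACGT" * 25] * 3)
        fit = ck.fit_global_clock("((A:1,B:1):1,C:2);", aln, jc)
        assert max(fit.node_heights.values()) < 1e-4
        # heights sit at the 1e-6 lower bound, not exactly 0
        assert fit.log_likelihood == pytest.approx(100 * math.log(0.25),
                                                   abs=5e-4)

    def test_global_fit_close_to_generating_likelihood(self, jc):
        tree = sim.random_ultrametric_tree(5, height=0.1, seed=22)
        aln = sim.simulate_alignment(tree, jc, n_sites=10_000, seed=23)
        ll_true = ck.prune_likelihood(tree, aln, jc)
        fit = ck.fit_global_clock(tree, aln, jc)
        assert fit.log_likelihood >= ll_true - 2.0

    def test_unrooted_topology_rejected(self, jc):
        aln = MultipleAlignment(["A", "B", "C"], ["ACGT"] * 3)
        with pytest.raises(ValueError, match="rooted"):
            ck.fit_global_clock("(A:1,B:1,C:1);", aln, jc)

    def test_nonmonophyletic_foreground_rejected(self, jc):
        tree = "((A:1,B:1):1,(C:1,D:1):1);"
        aln = MultipleAlignment(list("ABCD"), ["ACGTACGT"] * 4)
        with pytest.raises(ValueError, match="monophyletic"):
            ck.fit_local_clock(tree, aln, jc, {"A", "C"})

    def test_local_clock_recovers_rate(self, jc):
        tree = sim.random_ultrametric_tree(8, height=0.12, seed=24)
        from luxerode.pipeline import _pick_clade
        fg = _pick_clade(tree)
        aln = sim.simulate_alignment(tree, jc, foreground_clade=fg,
                                     rate_multiplier=3.0, n_sites=6000,
                                     seed=25)
        null_fit, alt_fit = ck.fit_clock_pair(tree, aln, jc, fg)
        res = ck.lrt(null_fit, alt_fit)
        assert res.lr > 0
        assert res.p_value < 0.01
        assert 2.0 < res.rate_multiplier < 4.5
        # nesting invariant
        assert alt_fit.log_likelihood >= null_fit.log_likelihood - 1e-6

    def test_foreground_all_taxa_warns_but_converges(self, jc, caplog):
        tree = "((A:0.05,B:0.05):0.05,(C:0.05,D:0.05):0.05);"
        aln = sim.simulate_alignment(tree, jc, n_sites=2000, seed=26)
        import logging
        with caplog.at_level(logging.WARNING, logger="luxerode.clock"):
            fit = ck.fit_local_clock(tree, aln, jc, {"A", "B", "C", "D"})
        assert fit.converged
        assert any("identifiab" in r.message for r in caplog.records)


class TestLRT:
    def test_paper_style_arithmetic(self):
        res = ck.lrt_from_neg_lnl(33576.04, 33443.95, df=1)
        assert res.lr == pytest.approx(264.18, abs=1e-9)
        assert res.p_value < 1e-10

    def test_equal_likelihoods_lr_zero_p_one(self):
        res = ck.lrt_from_neg_lnl(33576.04, 33576.04, df=1)
        assert res.lr == 0.0
        assert res.p_value == 1.0

    def test_chi_square_tail(self):
        # LR = 12.26, df = 1: survival function of chi-square
        res = ck.lrt_from_neg_lnl(33576.04, 33569.91, df=1)
        assert res.lr == pytest.approx(12.26, abs=1e-9)
        assert res.p_value == pytest.approx(4.65e-4, rel=0.01)

    def test_df_zero_rejected(self):
        with pytest.raises(ValueError):
            ck.lrt_from_neg_lnl(10.0, 9.0, df=0)

    def test_nesting_violation_raises(self):
        a = ck.ClockFit("", {}, 1.0, None, 1.0, -100.0, True, 5)
        b = ck.ClockFit("", {}, 1.0, frozenset({"A"}), 2.0, -105.0, True, 6)
        with pytest.raises(RuntimeError, match="nesting"):
            ck.lrt(a, b)


def test_empirical_frequencies_counts_states():
    aln = MultipleAlignment(["a", "b"], ["AACG-T", "AAAA-A"])
    f = ck.empirical_frequencies(aln)
    assert f == pytest.approx([7 / 10, 1 / 10, 1 / 10, 1 / 10])


class TestPAMLMatrix:
    def test_roundtrip_read(self, tmp_path):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0.1, 5.0, 190)
        freqs = rng.uniform(0.01, 1.0, 20)
        freqs /= freqs.sum()
        lines = []
        k = 0
        for i in range(1, 20):
            lines.append(" ".join(f"{vals[k + j]:.6f}" for j in range(i)))
            k += i
        lines.append(" ".join(f"{f:.6f}" for f in freqs))
        (tmp_path / "m.dat").write_text("\n".join(lines) + "\n")
        model = ck.read_paml_rate_matrix(tmp_path / "m.dat")
        assert model.n_states == 20
        assert model.pi == pytest.approx(freqs, abs=1e-5)  # file has 6 decimals
        # rows normalized: mean rate 1
        assert -(model.pi * np.diag(model.Q)).sum() == pytest.approx(1.0)
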