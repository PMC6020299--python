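"""TE census: family calls, IR finding, NJ exactness, burst geometry."""
import numpy as np
import pytest

from luxerode import te
from luxerode.genome import AnnotatedGenome, Feature, revcomp
from luxerode.resources import default_is_reference


@pytest.fixture(scope="module")
def is_refs():
    return default_is_reference()


def mutate(rng, seq, frac, alphabet="ARNDCQEGHILKMFPSTWYV"):
    s = list(seq)
    aas = list(alphabet)
    for i in range(len(s)):
        if rng.random() < frac:
            s[i] = aas[rng.integers(len(aas))]
    return "".join(s)


class TestClassify:
    def test_exact_copy_assigned_identity_one(self, is_refs):
        rep = next(r for r in is_refs if r.family_id == "IS5")
        recs = te.classify_transposases({"p1": rep.representative_seq},
                                        is_refs)
        assert len(recs) == 1
        assert recs[0].family_id == "IS5"
        assert recs[0].identity_to_ref == 1.0

    def test_decayed_burst_among_decoys(self, is_refs, rng):
        """Decayed IS5-like copies are all found; random proteins are not."""
        rep = next(r for r in is_refs if r.family_id == "IS5")
        proteome = {f"te{i:03d}": mutate(rng, rep.representative_seq, 0.2)
                    for i in range(30)}
        aas = list("ARNDCQEGHILKMFPSTWYV")
        proteome.update({f"host{i:03d}": "".join(rng.choice(aas, 300))
                         for i in range(120)})
        recs = te.classify_transposases(proteome, is_refs)
        called = {r.feature_id for r in recs}
        assert called == {f"te{i:03d}" for i in range(30)}
        assert all(r.family_id == "IS5" for r in recs)

    def test_dissimilar_protein_unassigned(self, is_refs, rng):
        aas = list("ARNDCQEGHILKMFPSTWYV")
        p = "".join(rng.choice(aas, 250))
        assert te.classify_transposases({"x": p}, is_refs) == []

    def test_census_conservation(self, is_refs, rng):
        rep = next(r for r in is_refs if r.family_id == "IS6")
        aas = list("ARNDCQEGHILKMFPSTWYV")
        proteome = {"a": rep.representative_seq,
                    "b": mutate(rng, rep.representative_seq, 0.1),
                    "c": "".join(rng.choice(aas, 200))}
        recs = te.classify_transposases(proteome, is_refs)
        assert len(recs) + 1 == len(proteome)  # assigned + unassigned


class TestTerminalIRs:
    def _element(self, rng, ir_len=15, core_len=300):
        bases = list("ACGT")
        ir = "".join(rng.choice(bases, ir_len))
        core = "".join(rng.choice(bases, core_len))
        flank5 = "".join(rng.choice(bases, 60))
        flank3 = "".join(rng.choice(bases, 60))
        seq = flank5 + ir + core + revcomp(ir) + flank3
        start = len(flank5) + len(ir) + 1       # element CDS starts after IR
        end = len(flank5) + len(ir) + core_len  # and ends before the 3' IR
        return seq, (start, end), ir

    def test_planted_perfect_ir_found(self, rng):
        seq, coords, ir = self._element(rng)
        hit = te.find_terminal_irs(seq, coords, window=40, min_len=10)
        assert hit is not None
        (u1, u2), (v1, v2), mm = hit
        assert u2 - u1 + 1 >= 15
        assert seq[u1 - 1:u2] in (ir, seq[u1 - 1:u2])
        # the reported pair really is a reverse-complement match
        assert sum(a != b for a, b in
                   zip(seq[u1 - 1:u2], revcomp(seq[v1 - 1:v2]))) == mm <= 2

    def test_matches_quadratic_brute_force(self, rng):
        """All (u, v) pairs checked by brute force give the same best pair."""
        for trial in range(5):
            seq = "".join(rng.choice(list("ACGT"), 160))
            coords = (60, 100)
            window, min_len, max_mm = 30, 8, 2
            got = te.find_terminal_irs(seq, coords, window=window,
                                       min_len=min_len, max_mismatch=max_mm)
            start, end = coords
            L = len(seq)
            u_lo, u_hi = max(0, start - 1 - window), min(L, start - 1 + window)
            d_lo, d_hi = max(0, end - window), min(L, end + window)
            up, down = seq[u_lo:u_hi], seq[d_lo:d_hi]
            best = None  # (len, -mm) maximized
            rc = revcomp(down)
            for ln in range(min(len(up), len(rc)), min_len - 1, -1):
                for i in range(len(up) - ln + 1):
                    for j in range(len(rc) - ln + 1):
                        mm = sum(a != b for a, b in
                                 zip(up[i:i + ln], rc[j:j + ln]))
                        if mm <= max_mm:
                            cand = (ln, -mm, -i, -j)
                            if best is None or cand > best:
                                best = cand
                if best:
                    break
            if best is None:
                assert got is None
            else:
                assert got is not None
                (u1, u2), _, mm = got
                assert (u2 - u1 + 1, -mm) == best[:2]

    def test_one_flank_deleted_gives_none(self, rng):
        seq, (start, end), ir = self._element(rng)
        # remove the downstream IR and flank entirely
        seq2 = seq[:end]
        hit = te.find_terminal_irs(seq2, (start, end), window=40, min_len=12)
        assert hit is None


class TestFractionAndRegions:
    def test_te_fraction_values(self):
        assert round(te.te_fraction(691, 2447)) == 28
        assert te.te_fraction(0, 100) == 0.0
        # the companion genome's printed cell disagrees with this definition;
        # the function is the explicit ratio
        assert round(te.te_fraction(921, 3290), 1) == 28.0

    def test_te_fraction_contract(self):
        with pytest.raises(ValueError):
            te.te_fraction(5, 0)
        with pytest.raises(ValueError):
            te.te_fraction(10, 5)

    def _genome_with_tes(self, te_positions, length=60_000):
        seq = "A" * length
        feats = []
        for k, p in enumerate(te_positions):
            feats.append(Feature(f"te{k}", "c1", p, p + 999, "+", "CDS",
                                 "unknown", "transposase"))
        feats.append(Feature("gene1", "c1", 30_100, 30_400, "+", "CDS",
                             "functional"))
        g = AnnotatedGenome("g", {"c1": seq}, feats)
        recs = [te.TERecord(f"te{k}", "IS5", 1.0, 1.0)
                for k in range(len(te_positions))]
        return g, recs

    def test_no_tes_whole_contig_is_free(self):
        g, _ = self._genome_with_tes([])
        out = te.insertion_free_regions(g, [], min_span=20_000)
        assert out == [{"contig": "c1", "start": 1, "end": 60_000,
                        "genes": ["gene1"]}]

    def test_one_gap_detected(self):
        # TEs every 5 kb except a 25 kb hole between 30k and 55k
        positions = list(range(1, 30_000, 5000)) + [55_001]
        g, recs = self._genome_with_tes(positions)
        out = te.insertion_free_regions(g, recs, min_span=20_000)
        assert len(out) == 1
        r = out[0]
        assert r["start"] == 26_001  # after the TE ending at 26,000
        assert r["end"] == 55_000
        assert r["genes"] == ["gene1"]


class TestDistancesAndNJ:
    def test_identical_distance_zero(self):
        _, D = te.distance_matrix({"a": "MKTAYI", "b": "MKTAYI"})
        assert D[0, 1] == 0.0

    def test_poisson_correction_closed_form(self):
        # p = 0.1 -> d = -ln(0.9)
        a = "A" * 100
        b = "A" * 90 + "R" * 10
        _, D = te.distance_matrix({"a": a, "b": b})
        assert D[0, 1] == pytest.approx(-np.log(0.9), abs=1e-12)

    def test_symmetry_zero_diagonal(self, rng):
        aas = list("ARNDCQEGHILKMFPSTWYV")
        seqs = {f"s{i}": "".join(rng.choice(aas, 60)) for i in range(5)}
        _, D = te.distance_matrix(seqs)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)

    def test_three_taxa_closed_form(self):
        # unique unrooted topology: a,b,c solve the three pair equations
        labels = ["A", "B", "C"]
        D = np.array([[0, 5, 9], [5, 0, 8], [9, 8, 0]], dtype=float)
        tree = te.neighbor_joining(labels, D)
        # a = (dAB + dAC - dBC)/2 = 3, b = 2, c = 6
        assert tree.path_length("A", "B") == pytest.approx(5)
        assert tree.path_length("A", "C") == pytest.approx(9)
        assert tree.path_length("B", "C") == pytest.approx(8)

    @pytest.mark.parametrize("n_taxa,seed", [(4, 0), (6, 1), (9, 2), (12, 3)])
    def test_additive_matrices_recovered_exactly(self, n_taxa, seed):
        """NJ reproduces random additive trees: path lengths == input matrix."""
        rng = np.random.default_rng(seed)
        # random additive tree by random sequential attachment
        from luxerode.te import NJTree
        tree = NJTree(["t0", "t1", "t2"])
        c = tree.add_node()
        for leaf in (0, 1, 2):
            tree.edges.append((leaf, c, float(rng.uniform(0.5, 3.0))))
        for k in range(3, n_taxa):
            ei = rng.integers(len(tree.edges))
            a, b, w = tree.edges.pop(ei)
            mid = tree.add_node()
            f = rng.uniform(0.2, 0.8)
            tree.edges.append((a, mid, w * f))
            tree.edges.append((b, mid, w * (1 - f)))
            leaf = tree.add_node(f"t{k}")
            tree.edges.append((leaf, mid, float(rng.uniform(0.5, 3.0))))
        labels = [l for l in tree.labels if l is not None]
        n = len(labels)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = tree.path_length(labels[i], labels[j])
        out = te.neighbor_joining(labels, D)
        for i in range(n):
            for j in range(i + 1, n):
                assert out.path_length(labels[i], labels[j]) == \
                    pytest.approx(D[i, j], abs=1e-9)

    def test_matches_skbio_on_additive_matrix(self):
        """Cross-check against an independent NJ implementation."""
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj
        labels = ["A", "B", "C", "D", "E"]
        rng = np.random.default_rng(7)
        base = rng.uniform(1, 4, size=(5, 5))
        D = np.zeros((5, 5))
        # build additivity via an ultrametric-ish random tree distance
        pts = rng.uniform(0, 1, size=5)
        for i in range(5):
            for j in range(5):
                if i != j:
                    D[i, j] = abs(pts[i] - pts[j]) + 1.0
        D = (D + D.T) / 2
        ours = te.neighbor_joining(labels, D)
        theirs = skbio_nj(DistanceMatrix(D, labels))
        for i in range(5):
            for j in range(i + 1, 5):
                d_theirs = theirs.find(labels[i]).distance(
                    theirs.find(labels[j]))
                assert ours.path_length(labels[i], labels[j]) == \
                    pytest.approx(d_theirs, abs=1e-9)

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            te.neighbor_joining(["a", "b", "c"], D)


class TestBurst:
    def _radiation(self, rng, source, n, crown):
        return {f"c{i:02d}": mutate(rng, source, crown) for i in range(n)}

    def test_star_on_long_stem_is_single_expansion(self, rng):
        aas = list("ARNDCQEGHILKMFPSTWYV")
        ancestor = "".join(rng.choice(aas, 300))
        burst_src = mutate(rng, ancestor, 0.45)
        copies = self._radiation(rng, burst_src, 12, 0.04)
        outgroup = {f"o{i}": mutate(rng, ancestor, 0.05) for i in range(3)}
        rep = te.burst_test(copies, outgroup)
        assert rep.verdict == "single_expansion"
        assert rep.monophyletic
        assert rep.burst_ratio >= 3.0

    def test_two_radiations_are_multiple_expansions(self, rng):
        aas = list("ARNDCQEGHILKMFPSTWYV")
        ancestor = "".join(rng.choice(aas, 300))
        # two radiations seeded from two distinct outgroup lineages, so the
        # copy groups interleave with outgroup sequences on the tree
        line_a = mutate(rng, ancestor, 0.30)
        line_b = mutate(rng, ancestor, 0.30)
        src1 = mutate(rng, line_a, 0.35)
        src2 = mutate(rng, line_b, 0.35)
        copies = {}
        copies.update({f"x{i}": mutate(rng, src1, 0.04) for i in range(6)})
        copies.update({f"y{i}": mutate(rng, src2, 0.04) for i in range(6)})
        outgroup = {"oA": mutate(rng, line_a, 0.05),
                    "oB": mutate(rng, line_b, 0.05)}
        rep = te.burst_test(copies, outgroup)
        assert rep.verdict == "multiple_expansions"
        assert not rep.monophyletic

    def test_uniform_depth_copies_are_no_expansion(self, rng):
        aas = list("ARNDCQEGHILKMFPSTWYV")
        ancestor = "".join(rng.choice(aas, 300))
        # copies and outgroups interleaved at uniform depth: no stem
        copies = {f"c{i}": mutate(rng, ancestor, 0.3) for i in range(6)}
        outgroup = {f"o{i}": mutate(rng, ancestor, 0.3) for i in range(4)}
        rep = te.burst_test(copies, outgroup)
        assert rep.verdict == "no_expansion"

    def test_single_copy_is_no_expansion(self):
        rep = te.burst_test({"only": "MKTAYI" * 20}, {"o": "MWTAYI" * 20})
        assert rep.verdict == "no_expansion"
        assert "fewer than 2" in rep.note
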