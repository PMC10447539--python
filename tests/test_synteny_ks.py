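"""Collinearity chaining, NG86 Ka/Ks (with an exhaustive oracle), mixture
peak selection and synteny depth."""

import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st

from paleoploid.io_formats import Interval
from paleoploid.synteny_ks import (
    Anchor,
    CollinearBlock,
    GeneModel,
    KsEstimate,
    block_median_ks,
    chain_collinear,
    export_dotplot,
    fit_ks_peaks,
    ng86_ks,
    synteny_depth,
)

SENSE_CODONS = [
    "".join(c) for c in itertools.product("TCAG", repeat=3)
    if str(Seq("".join(c)).translate()) != "*"
]


def make_genes(chrom, n, prefix):
    return {
        f"{prefix}{i}": GeneModel(
            gene_id=f"{prefix}{i}", chrom=chrom,
            interval=Interval(chrom, i * 100, i * 100 + 90, "+"), rank=i)
        for i in range(n)
    }


# ---------------------------------------------------------------------------
# NG86 oracle: first-principles site/path counting using Biopython's
# translation as the independent genetic-code source


def oracle_ng86(c1: str, c2: str):
    def aa(codon):
        return str(Seq(codon).translate())

    def syn_sites(codon):
        if aa(codon) == "*":
            return 0.0
        s = 0.0
        for pos in range(3):
            for b in "ACGT":
                if b != codon[pos]:
                    mut = codon[:pos] + b + codon[pos + 1:]
                    if aa(mut) == aa(codon):
                        s += 1 / 3
        return s

    S = (syn_sites(c1) + syn_sites(c2)) / 2
    N = 3 - (syn_sites(c1) + syn_sites(c2)) / 2
    diff = [i for i in range(3) if c1[i] != c2[i]]
    paths = []
    for order in itertools.permutations(diff):
        cur, sd, nd, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if aa(nxt) == "*" and nxt != c2:
                ok = False
                break
            sd += aa(nxt) == aa(cur)
            nd += aa(nxt) != aa(cur)
            cur = nxt
        if ok:
            paths.append((sd, nd))
    if not paths:  # all blocked by stops: fall back to every path
        for order in itertools.permutations(diff):
            cur, sd, nd = c1, 0, 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                sd += aa(nxt) == aa(cur)
                nd += aa(nxt) != aa(cur)
                cur = nxt
            paths.append((sd, nd))
    Sd = sum(p[0] for p in paths) / len(paths)
    Nd = sum(p[1] for p in paths) / len(paths)
    return S, N, Sd, Nd


class TestNg86:
    def test_identical_cds(self):
        cds = "ATGGCTTTA"
        e = ng86_ks(cds, cds)
        assert (e.Sd, e.Nd, e.Ks, e.Ka) == (0.0, 0.0, 0.0, -0.0)

    def test_synonymous_leucine_change(self):
        # TTA<->TTG is Leu<->Leu: one synonymous difference, Ka = 0
        filler = "GGG" * 9
        e = ng86_ks("TTA" + filler, "TTG" + filler)
        assert e.Sd == 1.0 and e.Nd == 0.0
        assert e.Ka == pytest.approx(0.0)
        S = 2 / 3 + 9.0  # Leu codon: 2/3 syn sites; GGG: 1 each
        expect = -0.75 * math.log(1 - 4 * (1 / S) / 3)
        assert e.Ks == pytest.approx(expect)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_oracle_on_codon_pairs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 4))
        c1 = "".join(SENSE_CODONS[i]
                     for i in rng.integers(0, len(SENSE_CODONS), n))
        c2 = "".join(SENSE_CODONS[i]
                     for i in rng.integers(0, len(SENSE_CODONS), n))
        e = ng86_ks(c1, c2)
        S = N = Sd = Nd = 0.0
        for i in range(0, 3 * n, 3):
            s, nn, sd, nd = oracle_ng86(c1[i:i + 3], c2[i:i + 3])
            S += s
            N += nn
            Sd += sd
            Nd += nd
        assert e.S == pytest.approx(S)
        assert e.N == pytest.approx(N)
        assert e.Sd == pytest.approx(Sd)
        assert e.Nd == pytest.approx(Nd)

    @given(st.integers(0, 100_000))
    @settings(max_examples=25, deadline=None)
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        c1 = "".join(SENSE_CODONS[i] for i in rng.integers(0, 61, 5))
        c2 = "".join(SENSE_CODONS[i] for i in rng.integers(0, 61, 5))
        a, b = ng86_ks(c1, c2), ng86_ks(c2, c1)
        assert a.S == pytest.approx(b.S)
        assert a.Sd == pytest.approx(b.Sd)
        assert (a.Ks == pytest.approx(b.Ks)) or (a.saturated_s
                                                 and b.saturated_s)

    def test_length_mismatch_and_internal_stop_rejected(self):
        with pytest.raises(ValueError):
            ng86_ks("ATGGCT", "ATG")
        with pytest.raises(ValueError):
            ng86_ks("ATGTAAGCT", "ATGTAAGCT")


class TestChainCollinear:
    def test_perfectly_collinear_single_block(self):
        ga = make_genes("a1", 20, "a")
        gb = make_genes("b1", 20, "b")
        anchors = [Anchor(f"a{i}", f"b{i}") for i in range(20)]
        blocks = chain_collinear(anchors, ga, gb)
        assert len(blocks) == 1
        assert len(blocks[0]) == 20
        assert blocks[0].orientation == "same"

    def test_inverted_segment_forms_own_block(self):
        ga = make_genes("a1", 20, "a")
        gb = make_genes("b1", 26, "b")
        anchors = []
        for i in range(20):
            if 7 <= i <= 12:
                anchors.append(Anchor(f"a{i}", f"b{25 - (i - 7)}"))
            else:
                anchors.append(Anchor(f"a{i}", f"b{i}"))
        blocks = chain_collinear(anchors, ga, gb)
        assert len(blocks) == 2
        by_orient = {b.orientation: b for b in blocks}
        assert len(by_orient["same"]) == 14
        assert len(by_orient["inverted"]) == 6

    def test_scattered_anchors_below_min_block(self):
        ga = make_genes("a1", 100, "a")
        gb = make_genes("b1", 100, "b")
        anchors = [Anchor("a5", "b90"), Anchor("a40", "b2"),
                   Anchor("a70", "b55"), Anchor("a99", "b30")]
        assert chain_collinear(anchors, ga, gb, min_block=5) == []

    def test_anchor_in_at_most_one_block_and_monotone(self):
        ga = make_genes("a1", 40, "a")
        gb = make_genes("b1", 40, "b")
        anchors = [Anchor(f"a{i}", f"b{i}") for i in range(40)]
        anchors += [Anchor(f"a{i}", f"b{i + 1}") for i in range(0, 39, 2)]
        blocks = chain_collinear(anchors, ga, gb)
        seen = set()
        for blk in blocks:
            ranks_a = [ga[a.gene_a].rank for a in blk.anchors]
            ranks_b = [gb[a.gene_b].rank for a in blk.anchors]
            assert ranks_a == sorted(ranks_a)
            diffs = np.diff(ranks_b)
            assert (diffs > 0).all() or (diffs < 0).all()
            for a in blk.anchors:
                key = (a.gene_a, a.gene_b)
                assert key not in seen
                seen.add(key)


class TestBlockMedian:
    def _block(self, pairs):
        return CollinearBlock("b0", "c1", "c2", "same",
                              [Anchor(a, b) for a, b in pairs])

    def _ks(self, val, pair, saturated=False):
        return KsEstimate(pair=pair, S=100, N=200, Sd=10, Nd=5, pS=0.1,
                          pN=0.025, Ks=val, Ka=0.01, saturated_s=saturated)

    def test_odd_count(self):
        blk = self._block([("a", "x"), ("b", "y"), ("c", "z")])
        ks = {("a", "x"): self._ks(0.1, ("a", "x")),
              ("b", "y"): self._ks(0.2, ("b", "y")),
              ("c", "z"): self._ks(0.9, ("c", "z"))}
        assert block_median_ks(blk, ks) == pytest.approx(0.2)

    def test_even_count_midpoint(self):
        blk = self._block([("a", "x"), ("b", "y")])
        ks = {("a", "x"): self._ks(0.1, ("a", "x")),
              ("b", "y"): self._ks(0.3, ("b", "y"))}
        assert block_median_ks(blk, ks) == pytest.approx(0.2)

    def test_saturated_pairs_excluded(self):
        blk = self._block([("a", "x"), ("b", "y"), ("c", "z")])
        ks = {("a", "x"): self._ks(0.2, ("a", "x")),
              ("b", "y"): self._ks(float("inf"), ("b", "y"),
                                   saturated=True),
              ("c", "z"): self._ks(0.4, ("c", "z"))}
        assert block_median_ks(blk, ks) == pytest.approx(0.3)

    def test_all_saturated_returns_none(self):
        blk = self._block([("a", "x")])
        ks = {("a", "x"): self._ks(float("inf"), ("a", "x"),
                                   saturated=True)}
        assert block_median_ks(blk, ks) is None


class TestKsPeaks:
    def test_single_component(self):
        rng = np.random.default_rng(1)
        vals = np.exp(rng.normal(np.log(0.5), 0.2, 1000))
        assert fit_ks_peaks(vals, seed=1).n_components == 1

    def test_three_components_recovered(self):
        rng = np.random.default_rng(11)
        vals = np.exp(np.concatenate(
            [rng.normal(np.log(m), 0.15, 1000) for m in (0.15, 0.6, 1.5)]
        ))
        fit = fit_ks_peaks(vals, seed=11)
        assert fit.n_components == 3
        assert fit.peaks_ks == sorted(fit.peaks_ks)
        for peak, true in zip(fit.peaks_ks, (0.15, 0.6, 1.5)):
            assert abs(peak - true) / true < 0.15
        assert sum(fit.weights) == pytest.approx(1.0)
        assert min(fit.bic, key=fit.bic.get) == 3

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_ks_peaks([], seed=0)
        with pytest.raises(ValueError):
            fit_ks_peaks([0.5] * 10, seed=0)


class TestSyntenyDepth:
    def test_one_to_one_gives_modal_one(self):
        ga = make_genes("q1", 30, "q")
        gr = make_genes("r1", 30, "r")
        anchors = [Anchor(f"q{i}", f"r{i}") for i in range(30)]
        blocks = chain_collinear(anchors, ga, gr)
        prof = synteny_depth(blocks, gr, query_side="a")
        assert prof.modal_depth == 1
        assert prof.histogram[1] == 30

    def test_double_wgd_gives_modal_four(self, depth_sim):
        sim, ref_blocks = depth_sim
        prof = synteny_depth(ref_blocks, sim.ref_genes, query_side="a")
        assert prof.modal_depth == 4
        frac4 = prof.histogram[4] / len(sim.ref_genes)
        assert frac4 >= 0.90

    def test_modal_tie_breaks_to_smaller_depth(self):
        from paleoploid.synteny_ks import DepthProfile  # noqa: F401

        ga = make_genes("q1", 10, "q")
        gr = make_genes("r1", 10, "r")
        # two blocks covering ranks 0-4 doubly and 5-9 singly won't tie;
        # construct equal counts instead: 5 genes at depth 1, 5 at 2
        b1 = chain_collinear([Anchor(f"q{i}", f"r{i}")
                              for i in range(10)], ga, gr)
        b2 = chain_collinear([Anchor(f"q{i}", f"r{i}")
                              for i in range(5)], ga, gr)
        prof = synteny_depth(b1 + b2, gr, query_side="a")
        assert prof.histogram == {1: 5, 2: 5}
        assert prof.modal_depth == 1


class TestDotplot:
    def test_rows_and_determinism(self):
        ga = make_genes("a1", 20, "a")
        gb = make_genes("b1", 20, "b")
        anchors = [Anchor(f"a{i}", f"b{i}") for i in range(20)]
        blocks = chain_collinear(anchors, ga, gb)
        df1 = export_dotplot(blocks, ga, gb)
        df2 = export_dotplot(blocks, ga, gb)
        assert len(df1) == 20
        assert df1.block_id.nunique() == 1
        assert df1.equals(df2)

    def test_empty_blocks_give_header_only(self):
        df = export_dotplot([], {}, {})
        assert len(df) == 0
        assert "block_id" in df.columns
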