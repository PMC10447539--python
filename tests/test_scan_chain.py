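"""Scanner and hit-chaining tests, including the exhaustive chaining
oracle on small hit groups."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paleoploid.io_formats import DnaSeq, Interval, LocalHit
from paleoploid.ltr_inventory import chain_hits
from paleoploid.scan import scan_genome
from paleoploid.synthetic import mutate_seq, _random_dna


def make_hit(qs, qe, ss, se, ident=0.9, strand="+", q="q", s="s"):
    return LocalHit(
        query_id=q, subject_id=s,
        query_interval=Interval(q, qs, qe, "+"),
        subject_interval=Interval(s, ss, se, strand),
        identity=ident, aligned_length=qe - qs, score=float(qe - qs),
    )


# ---------------------------------------------------------------------------
# brute-force oracle: enumerate every ordered subset of hits, keep valid
# colinear chains, maximise total aligned length


def _valid_chain(hits, max_gap):
    for a, b in zip(hits, hits[1:]):
        if b.query_interval.start < a.query_interval.end:
            return False
        if b.query_interval.start - a.query_interval.end > max_gap:
            return False
        if a.subject_interval.strand == "-":
            if b.subject_interval.end > a.subject_interval.start:
                return False
            if a.subject_interval.start - b.subject_interval.end > max_gap:
                return False
        else:
            if b.subject_interval.start < a.subject_interval.end:
                return False
            if b.subject_interval.start - a.subject_interval.end > max_gap:
                return False
    return True


def brute_force_best(hits, max_gap, query_len):
    best = None
    for r in range(1, len(hits) + 1):
        for combo in itertools.permutations(hits, r):
            if not _valid_chain(list(combo), max_gap):
                continue
            total = sum(h.aligned_length for h in combo)
            if best is None or total > best[0]:
                ivs = sorted((h.query_interval.start, h.query_interval.end)
                             for h in combo)
                cov = 0
                cur_s, cur_e = ivs[0]
                for s, e in ivs[1:]:
                    if s > cur_e:
                        cov += cur_e - cur_s
                        cur_s, cur_e = s, e
                    else:
                        cur_e = max(cur_e, e)
                cov += cur_e - cur_s
                ident = sum(h.identity * h.aligned_length for h in combo) \
                    / total
                best = (total, cov / query_len, ident)
    return best


class TestChainHits:
    def test_single_hit_chain(self):
        hits = [make_hit(0, 50, 100, 150)]
        (ch,) = chain_hits(hits, max_gap=100, query_lengths={"q": 100})
        assert ch.coverage == pytest.approx(0.5)
        assert ch.identity == pytest.approx(0.9)

    def test_two_colinear_hits_union_coverage(self):
        hits = [make_hit(0, 30, 100, 130), make_hit(40, 70, 140, 170)]
        (ch,) = chain_hits(hits, max_gap=100, query_lengths={"q": 100})
        assert len(ch.member_hits) == 2
        assert ch.coverage == pytest.approx(0.6)

    def test_crossing_hits_split_into_two_chains(self):
        # subject order contradicts query order: no valid 2-chain exists
        hits = [make_hit(0, 40, 200, 240), make_hit(50, 100, 100, 150)]
        chains = chain_hits(hits, max_gap=1000, query_lengths={"q": 100})
        assert len(chains) == 2
        assert all(len(c.member_hits) == 1 for c in chains)
        # larger chain (higher aligned length) reported first
        assert chains[0].total_aligned >= chains[1].total_aligned

    def test_gap_constraint_breaks_chain(self):
        hits = [make_hit(0, 30, 100, 130), make_hit(40, 70, 5000, 5030)]
        chains = chain_hits(hits, max_gap=100, query_lengths={"q": 100})
        assert len(chains) == 2

    @pytest.mark.parametrize("seed", range(8))
    def test_best_chain_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        hits = []
        for _ in range(n):
            qs = int(rng.integers(0, 160))
            ln = int(rng.integers(10, 40))
            ss = int(rng.integers(0, 400))
            hits.append(make_hit(qs, qs + ln, ss, ss + ln,
                                 ident=float(rng.uniform(0.5, 1.0))))
        max_gap = 80
        chains = chain_hits(hits, max_gap=max_gap,
                            query_lengths={"q": 200})
        oracle = brute_force_best(hits, max_gap, 200)
        best = chains[0]
        assert best.total_aligned == oracle[0]
        assert best.coverage == pytest.approx(oracle[1])
        assert best.identity == pytest.approx(oracle[2])

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_every_hit_in_exactly_one_chain(self, seed):
        rng = np.random.default_rng(seed)
        hits = []
        for _ in range(int(rng.integers(1, 8))):
            qs = int(rng.integers(0, 150))
            ln = int(rng.integers(5, 50))
            ss = int(rng.integers(0, 300))
            hits.append(make_hit(qs, qs + ln, ss, ss + ln))
        chains = chain_hits(hits, max_gap=60, query_lengths={"q": 200})
        seen = [id(h) for c in chains for h in c.member_hits]
        assert sorted(seen) == sorted(id(h) for h in hits)


class TestScanner:
    def test_finds_diverged_copy(self):
        rng = np.random.default_rng(1)
        query = _random_dna(rng, 400)
        copy = mutate_seq(query, 0.03, rng)
        background = _random_dna(rng, 5000)
        genome = {"s": DnaSeq("s", background[:2000] + copy
                              + background[2000:])}
        hits = scan_genome({"q": query}, genome)
        best = max(hits, key=lambda h: h.aligned_length)
        assert best.subject_interval.start == pytest.approx(2000, abs=25)
        assert best.aligned_length >= 380
        assert best.identity > 0.9

    def test_reverse_strand_hit(self):
        from paleoploid.io_formats import revcomp

        rng = np.random.default_rng(2)
        query = _random_dna(rng, 300)
        genome = {"s": DnaSeq("s", _random_dna(rng, 1000) + revcomp(query)
                              + _random_dna(rng, 1000))}
        hits = scan_genome({"q": query}, genome)
        best = max(hits, key=lambda h: h.aligned_length)
        assert best.subject_interval.strand == "-"
        assert best.subject_interval.start == 1000
        assert best.subject_interval.end == 1300
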