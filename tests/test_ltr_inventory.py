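"""Inventory classification rules, solo filters and simulator recovery."""

import pytest

from paleoploid.io_formats import Interval
from paleoploid.ltr_inventory import (
    ChainedMatch,
    FilterThresholds,
    LtrElement,
    apply_solo_filters,
    classify_intact,
    solo_intact_ratio,
)

TH = FilterThresholds()
DOMS = ("GAG", "AP", "INT", "RT", "RH")


def candidate(eid="e1"):
    return LtrElement(
        element_id=eid,
        ltr5=Interval("s", 10_000, 10_400, "+"),
        internal=Interval("s", 10_400, 14_400, "+"),
        ltr3=Interval("s", 14_400, 14_800, "+"),
    )


def domain_chain(name, cov, ident):
    return ChainedMatch(query_id=name, subject_id="_int", member_hits=[],
                        coverage=cov, identity=ident)


class TestClassifyIntact:
    def test_all_five_domains_present(self):
        chains = [domain_chain(d, 0.5, 0.6) for d in DOMS]
        out = classify_intact(candidate(), chains, TH)
        assert out.class_state == "intact"
        assert len(out.decisions) == 5

    def test_missing_domain_blocks_intact(self):
        chains = [domain_chain(d, 0.5, 0.6) for d in DOMS if d != "INT"]
        out = classify_intact(candidate(), chains, TH)
        assert out.class_state == "candidate"

    def test_low_coverage_domain_blocks_intact(self):
        chains = [domain_chain(d, 0.5, 0.6) for d in DOMS if d != "RH"]
        chains.append(domain_chain("RH", 0.2, 0.9))
        out = classify_intact(candidate(), chains, TH)
        assert out.class_state == "candidate"

    def test_threshold_is_strict(self):
        # exactly 30% coverage does not pass a ">30%" rule
        chains = [domain_chain(d, 0.5, 0.6) for d in DOMS if d != "RT"]
        chains.append(domain_chain("RT", 0.30, 0.9))
        assert classify_intact(candidate(), chains, TH).class_state \
            == "candidate"

    def test_missing_ltr_is_error(self):
        c = candidate()
        c.ltr3 = None
        with pytest.raises(ValueError):
            classify_intact(c, [], TH)


def solo(eid, seq="s", start=50_000, end=50_400, cov=0.9, ident=0.9):
    return LtrElement(element_id=eid,
                      ltr5=Interval(seq, start, end, "+"),
                      coverage=cov, identity=ident)


class TestSoloFilters:
    LENGTHS = {"s": 200_000}
    NO_GAPS = {"s": []}

    def run(self, cands, truncated=(), gaps=None, th=TH):
        return apply_solo_filters(cands, truncated, gaps or self.NO_GAPS,
                                  self.LENGTHS, th)

    def test_clean_candidate_accepted(self):
        accepted, report = self.run([solo("a")])
        assert len(accepted) == 1
        assert report["accepted"] == 1
        assert accepted[0].class_state == "solo"

    def test_rule_a_overlap_with_truncated(self):
        trunc = LtrElement(element_id="t",
                           ltr5=Interval("s", 50_300, 54_000, "+"),
                           class_state="truncated")
        accepted, report = self.run([solo("a")], truncated=[trunc])
        assert not accepted
        assert report["a_overlap_truncated"] == 1

    def test_rule_b_scaffold_edge(self):
        accepted, report = self.run([solo("a", start=3_000, end=3_400)])
        assert not accepted
        assert report["b_scaffold_edge"] == 1
        # near the far end as well
        accepted, report = self.run([solo("b", start=196_000, end=196_400)])
        assert report["b_scaffold_edge"] == 1

    def test_rule_c_coverage_or_identity(self):
        accepted, report = self.run([solo("a", cov=0.9, ident=0.65)])
        assert not accepted
        assert report["c_cov_identity"] == 1

    def test_rule_c_literal_and_variant(self):
        th = FilterThresholds(rule_c_mode="literal_and")
        accepted, _ = self.run([solo("a", cov=0.9, ident=0.65)], th=th)
        assert len(accepted) == 1  # only one criterion short: survives
        accepted, _ = self.run([solo("a", cov=0.6, ident=0.65)], th=th)
        assert not accepted

    def test_rule_d_near_gap(self):
        gaps = {"s": [(50_850, 51_000)]}  # 450 bp away: rejected
        accepted, report = self.run([solo("a")], gaps=gaps)
        assert not accepted
        assert report["d_near_gap"] == 1
        gaps = {"s": [(50_900, 51_100)]}  # exactly 500 bp: survives "<"
        accepted, _ = self.run([solo("a")], gaps=gaps)
        assert len(accepted) == 1

    def test_partition_property(self):
        cands = [
            solo("a"),
            solo("b", start=1_000, end=1_400),
            solo("c", cov=0.5),
            solo("d", start=80_000, end=80_400),
        ]
        accepted, report = self.run(cands)
        rejected = sum(v for k, v in report.items() if k != "accepted")
        assert report["accepted"] + rejected == len(cands)
        states = {c.class_state for c in cands}
        assert states <= {"solo", "rejected"}

    def test_monotone_filtering(self):
        # adding a gap annotation can only shrink the accepted set
        cands = [solo(f"c{i}", start=20_000 + 5_000 * i,
                      end=20_400 + 5_000 * i) for i in range(10)]
        acc_all, _ = self.run(list(cands))
        cands2 = [solo(f"c{i}", start=20_000 + 5_000 * i,
                       end=20_400 + 5_000 * i) for i in range(10)]
        gaps = {"s": [(30_500, 30_700)]}
        acc_gap, _ = self.run(cands2, gaps=gaps)
        assert len(acc_gap) <= len(acc_all)
        assert {c.element_id for c in acc_gap} <= \
            {c.element_id for c in acc_all}

    def test_missing_scaffold_length_is_error(self):
        with pytest.raises(KeyError):
            apply_solo_filters([solo("a", seq="unknown")], [], {}, {}, TH)


class TestSoloIntactRatio:
    def test_published_style_values(self):
        assert solo_intact_ratio(98_465, 25_792) == \
            pytest.approx(3.8176, abs=5e-4)
        assert solo_intact_ratio(5_444, 1_069) == \
            pytest.approx(5.0925, abs=5e-4)

    def test_zero_solo(self):
        assert solo_intact_ratio(0, 10) == 0.0

    def test_zero_intact_is_error(self):
        with pytest.raises(ValueError):
            solo_intact_ratio(5, 0)


class TestSimulatorRecovery:
    def test_intact_recall(self, ltr_sim, ltr_inventory_result):
        n_true = int((ltr_sim.truth.true_class == "intact").sum())
        recall = len(ltr_inventory_result["intact"]) / n_true
        assert recall >= 0.95

    def test_all_decoys_rejected_by_their_rule(self, ltr_sim,
                                               ltr_inventory_result):
        report = ltr_inventory_result["report"]
        cfg = ltr_sim.config
        assert report["b_scaffold_edge"] >= cfg.n_edge_decoys
        assert report["d_near_gap"] >= cfg.n_gap_decoys
        # no decoy reaches the accepted set
        truth = ltr_sim.truth
        decoys = truth[truth.true_class.isin(["edge_decoy", "gap_decoy"])]
        for c in ltr_inventory_result["solos"]:
            hits = decoys[(decoys.seq_id == c.ltr5.seq_id)
                          & (decoys.start < c.ltr5.end)
                          & (decoys.end > c.ltr5.start)]
            assert hits.empty

    def test_solo_precision(self, ltr_sim, ltr_inventory_result):
        truth = ltr_sim.truth
        solos_true = truth[truth.true_class == "solo"]
        solos = ltr_inventory_result["solos"]
        n_match = 0
        for c in solos:
            hits = solos_true[(solos_true.seq_id == c.ltr5.seq_id)
                              & (solos_true.start < c.ltr5.end)
                              & (solos_true.end > c.ltr5.start)]
            n_match += int(not hits.empty)
        assert solos
        assert n_match / len(solos) >= 0.95
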