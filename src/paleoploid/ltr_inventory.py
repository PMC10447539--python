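"""Classify LTR-retrotransposon loci as intact, truncated or solo.

The inventory follows the solo-LTR detection procedure used for large
plant genomes: candidate elements with paired LTRs are accepted as intact
when all five internal protein domains (GAG, AP, INT, RT, RH) are
detected; truncated copies are genome loci matching a full-length
exemplar at >80% coverage and >60% identity; solo-LTR candidates are
genome matches of intact elements' LTR sequences, filtered by four rules:
(a) overlap with a truncated element, (b) proximity (<5 kb) to a scaffold
edge, (c) coverage or identity below 0.7, (d) proximity (<500 bp) to an
assembly gap. The solo:intact ratio summarises recombination-driven DNA
removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .io_formats import DnaSeq, Interval, LocalHit
from .scan import scan_genome

__all__ = [
    "FilterThresholds",
    "LtrElement",
    "ChainedMatch",
    "InventorySummary",
    "chain_hits",
    "classify_intact",
    "detect_truncated",
    "find_solo_candidates",
    "apply_solo_filters",
    "solo_intact_ratio",
    "run_inventory",
    "DOMAIN_NAMES",
]

DOMAIN_NAMES = ("GAG", "AP", "INT", "RT", "RH")


@dataclass(frozen=True)
class FilterThresholds:
    """Classification and filtering cut-offs.

    Comparisons are strict (>) for the retention and truncation rules and
    "below threshold rejects" for the solo coverage/identity rule,
    mirroring how the cut-offs are usually quoted (>30%, >80%/>60%, <0.7).
    """

    retain_cov: float = 0.30
    retain_id: float = 0.30
    trunc_cov: float = 0.80
    trunc_id: float = 0.60
    solo_cov: float = 0.70
    solo_id: float = 0.70
    edge_dist: int = 5_000
    gap_dist: int = 500
    # "require_both": survive only when coverage >= solo_cov AND
    # identity >= solo_id (default). "literal_and": reject only when both
    # fall short.
    rule_c_mode: str = "require_both"

    def __post_init__(self) -> None:
        for name in ("retain_cov", "retain_id", "trunc_cov", "trunc_id",
                     "solo_cov", "solo_id"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name}={v} outside (0, 1]")
        if self.edge_dist <= 0 or self.gap_dist <= 0:
            raise ValueError("distances must be positive")
        if self.rule_c_mode not in ("require_both", "literal_and"):
            raise ValueError(f"unknown rule_c_mode {self.rule_c_mode!r}")


@dataclass
class LtrElement:
    """A candidate LTR-RT locus with its classification audit trail.

    ``decisions`` records every rule applied as (rule_id, passed, value).
    For solo/truncated records only ``ltr5`` (the matched locus) is set.
    """

    element_id: str
    ltr5: Interval
    internal: Interval | None = None
    ltr3: Interval | None = None
    family: str = ""
    class_state: str = "candidate"
    coverage: float | None = None
    identity: float | None = None
    decisions: list[tuple[str, bool, float]] = field(default_factory=list)

    @property
    def span(self) -> Interval:
        if self.ltr3 is not None:
            return Interval(self.ltr5.seq_id,
                            min(self.ltr5.start, self.ltr3.start),
                            max(self.ltr5.end, self.ltr3.end),
                            self.ltr5.strand)
        return self.ltr5


@dataclass
class ChainedMatch:
    """A colinear chain of local hits between one query and one subject."""

    query_id: str
    subject_id: str
    member_hits: list[LocalHit]
    coverage: float
    identity: float
    strand: str = "+"

    @property
    def subject_span(self) -> Interval:
        ivs = [h.subject_interval for h in self.member_hits]
        return Interval(self.subject_id, min(i.start for i in ivs),
                        max(i.end for i in ivs), self.strand)

    @property
    def total_aligned(self) -> int:
        return sum(h.aligned_length for h in self.member_hits)


@dataclass(frozen=True)
class InventorySummary:
    n_intact: int
    n_truncated: int
    n_solo: int
    solo_intact_ratio: float


# ---------------------------------------------------------------------------
# hit chaining


def _union_len(intervals: Iterable[tuple[int, int]]) -> int:
    total, cur_s, cur_e = 0, None, None
    for s, e in sorted(intervals):
        if cur_s is None:
            cur_s, cur_e = s, e
        elif s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_s is not None:
        total += cur_e - cur_s
    return total


def _colinear(a: LocalHit, b: LocalHit, max_gap: int) -> bool:
    """True when hit b may follow hit a in one chain (both axes in order)."""
    qa, qb = a.query_interval, b.query_interval
    sa, sb = a.subject_interval, b.subject_interval
    if qb.start < qa.end:
        return False
    if qb.start - qa.end > max_gap:
        return False
    if sa.strand == "-":
        # forward subject coordinates run opposite to the query
        if sb.end > sa.start:
            return False
        gap = sa.start - sb.end
    else:
        if sb.start < sa.end:
            return False
        gap = sb.start - sa.end
    return gap <= max_gap


def _chain_group(hits: list[LocalHit], max_gap: int, query_len: int,
                 strand: str) -> list[ChainedMatch]:
    """Extract disjoint maximal-score chains from one (q, s, strand) group."""
    remaining = sorted(hits, key=lambda h: (h.query_interval.start,
                                            h.query_interval.end,
                                            h.subject_interval.start))
    chains: list[ChainedMatch] = []
    while remaining:
        n = len(remaining)
        best = [h.aligned_length for h in remaining]
        prev = [-1] * n
        for j in range(n):
            for i in range(j):
                if _colinear(remaining[i], remaining[j], max_gap):
                    cand = best[i] + remaining[j].aligned_length
                    if cand > best[j]:
                        best[j], prev[j] = cand, i
        end = max(range(n), key=lambda j: best[j])
        path = []
        j = end
        while j != -1:
            path.append(j)
            j = prev[j]
        path.reverse()
        members = [remaining[j] for j in path]
        taken = set(path)
        remaining = [h for j, h in enumerate(remaining) if j not in taken]
        cov = _union_len(
            (h.query_interval.start, h.query_interval.end) for h in members
        ) / query_len
        total = sum(h.aligned_length for h in members)
        ident = sum(h.identity * h.aligned_length for h in members) / total
        chains.append(
            ChainedMatch(
                query_id=members[0].query_id,
                subject_id=members[0].subject_id,
                member_hits=members,
                coverage=cov,
                identity=ident,
                strand=strand,
            )
        )
    chains.sort(key=lambda c: (-c.total_aligned,
                               c.subject_span.start))
    return chains


def chain_hits(hits: Sequence[LocalHit], max_gap: int,
               query_lengths: Mapping[str, int]) -> list[ChainedMatch]:
    """Link local hits into colinear chains per (query, subject, strand).

    A dynamic programme maximises total aligned length subject to colinear
    order on both axes and inter-hit gaps <= ``max_gap`` on each axis;
    chains are extracted greedily by score so every hit belongs to exactly
    one chain. Chain coverage is the query-interval union over the query
    length; identity is the aligned-length-weighted mean.
    """
    groups: dict[tuple[str, str, str], list[LocalHit]] = {}
    for h in hits:
        key = (h.query_id, h.subject_id, h.subject_interval.strand)
        groups.setdefault(key, []).append(h)
    chains: list[ChainedMatch] = []
    for (qid, _sid, strand), group in sorted(groups.items()):
        if qid not in query_lengths:
            raise KeyError(f"no length known for query {qid!r}")
        chains.extend(_chain_group(group, max_gap, query_lengths[qid], strand))
    chains.sort(key=lambda c: (-c.total_aligned, c.query_id, c.subject_id,
                               c.subject_span.start))
    return chains


# ---------------------------------------------------------------------------
# intact classification


def classify_intact(candidate: LtrElement,
                    domain_chains: Sequence[ChainedMatch],
                    thresholds: FilterThresholds = FilterThresholds()
                    ) -> LtrElement:
    """Promote a paired-LTR candidate to intact when all five internal
    protein domains are detected at > retain_cov coverage and > retain_id
    identity. The per-domain best chain is recorded in ``decisions``.
    """
    if candidate.ltr5 is None or candidate.ltr3 is None:
        raise ValueError(f"candidate {candidate.element_id} lacks paired LTRs")
    decisions: list[tuple[str, bool, float]] = []
    all_ok = True
    for dom in DOMAIN_NAMES:
        best = None
        for ch in domain_chains:
            if ch.query_id != dom:
                continue
            if best is None or (ch.coverage, ch.identity) > (best.coverage,
                                                             best.identity):
                best = ch
        if best is None:
            decisions.append((f"domain_{dom}", False, 0.0))
            all_ok = False
        else:
            ok = (best.coverage > thresholds.retain_cov
                  and best.identity > thresholds.retain_id)
            decisions.append((f"domain_{dom}", ok,
                              min(best.coverage, best.identity)))
            all_ok = all_ok and ok
    return replace(
        candidate,
        class_state="intact" if all_ok else "candidate",
        decisions=candidate.decisions + decisions,
    )


# ---------------------------------------------------------------------------
# truncated detection


def _merge_loci(elements: list[LtrElement]) -> list[LtrElement]:
    """Merge overlapping single-interval element calls, keeping the best
    (coverage, identity) of each merged cluster."""
    by_seq: dict[str, list[LtrElement]] = {}
    for e in elements:
        by_seq.setdefault(e.ltr5.seq_id, []).append(e)
    merged: list[LtrElement] = []
    for seq_id in sorted(by_seq):
        elems = sorted(by_seq[seq_id], key=lambda e: (e.ltr5.start, e.ltr5.end))
        cluster: list[LtrElement] = []
        cur_end = -1
        for e in elems:
            if cluster and e.ltr5.start >= cur_end:
                merged.append(_best_of(cluster))
                cluster = []
            cluster.append(e)
            cur_end = max(cur_end, e.ltr5.end)
        if cluster:
            merged.append(_best_of(cluster))
    return merged


def _best_of(cluster: list[LtrElement]) -> LtrElement:
    best = max(cluster, key=lambda e: ((e.coverage or 0.0), (e.identity or 0.0)))
    start = min(e.ltr5.start for e in cluster)
    end = max(e.ltr5.end for e in cluster)
    return replace(best, ltr5=Interval(best.ltr5.seq_id, start, end,
                                       best.ltr5.strand))


def detect_truncated(genome: Mapping[str, DnaSeq],
                     exemplar_seqs: Mapping[str, str],
                     thresholds: FilterThresholds = FilterThresholds(),
                     hits: Sequence[LocalHit] | None = None,
                     intact_spans: Sequence[Interval] = (),
                     max_gap: int = 500) -> list[LtrElement]:
    """Find truncated element loci: chained matches of a full-length
    exemplar at > trunc_cov coverage and > trunc_id identity, excluding
    loci that overlap an already-classified intact element (precedence:
    intact > truncated). Overlapping calls from different exemplars are
    merged.
    """
    if not exemplar_seqs:
        raise ValueError("empty exemplar set")
    if hits is None:
        hits = scan_genome(exemplar_seqs, genome, min_len=100,
                           min_identity=0.5)
    qlens = {q: len(s) for q, s in exemplar_seqs.items()}
    chains = chain_hits(hits, max_gap=max_gap, query_lengths=qlens)
    calls: list[LtrElement] = []
    for i, ch in enumerate(chains):
        if not (ch.coverage > thresholds.trunc_cov
                and ch.identity > thresholds.trunc_id):
            continue
        span = ch.subject_span
        if any(span.overlaps(iv) for iv in intact_spans):
            continue
        calls.append(
            LtrElement(
                element_id=f"trunc_{i}",
                ltr5=span,
                class_state="truncated",
                coverage=ch.coverage,
                identity=ch.identity,
                decisions=[("trunc_cov", True, ch.coverage),
                           ("trunc_id", True, ch.identity)],
            )
        )
    merged = _merge_loci(calls)
    for i, e in enumerate(merged):
        e.element_id = f"trunc_{i}"
    return merged


# ---------------------------------------------------------------------------
# solo-LTR candidates and filters


def find_solo_candidates(genome: Mapping[str, DnaSeq],
                         ltr_exemplars: Mapping[str, str],
                         intact_elements: Sequence[LtrElement] = (),
                         hits: Sequence[LocalHit] | None = None,
                         max_gap: int = 100) -> list[LtrElement]:
    """Match intact elements' LTR sequences against the genome to produce
    solo-LTR candidates. Overlapping candidates from multiple exemplars
    are merged (best coverage/identity kept); candidates falling inside an
    intact element's own LTRs are excluded.
    """
    if not ltr_exemplars:
        raise ValueError("need at least one exemplar LTR")
    if hits is None:
        hits = scan_genome(ltr_exemplars, genome, min_len=50,
                           min_identity=0.5)
    qlens = {q: len(s) for q, s in ltr_exemplars.items()}
    chains = chain_hits(hits, max_gap=max_gap, query_lengths=qlens)
    own_spans = [e.span for e in intact_elements]
    cands: list[LtrElement] = []
    for i, ch in enumerate(chains):
        span = ch.subject_span
        # anything inside an intact element (its own LTRs in particular)
        # is not a solo remnant
        if any(span.overlaps(s) for s in own_spans):
            continue
        cands.append(
            LtrElement(
                element_id=f"solo_{i}",
                ltr5=span,
                class_state="candidate",
                coverage=ch.coverage,
                identity=ch.identity,
            )
        )
    merged = _merge_loci(cands)
    for i, e in enumerate(merged):
        e.element_id = f"solo_{i}"
    return merged


def _dist_to_interval(iv: Interval, start: int, end: int) -> int:
    if iv.end <= start:
        return start - iv.end
    if end <= iv.start:
        return iv.start - end
    return 0


def apply_solo_filters(candidates: Sequence[LtrElement],
                       truncated_elements: Sequence[LtrElement],
                       gap_runs: Mapping[str, Sequence[tuple[int, int]]],
                       scaffold_lengths: Mapping[str, int],
                       thresholds: FilterThresholds = FilterThresholds()
                       ) -> tuple[list[LtrElement], dict[str, int]]:
    """Apply the four solo-LTR false-positive filters.

    A candidate is rejected when it (a) overlaps a truncated element by
    >= 1 bp, (b) lies within edge_dist of either scaffold end, (c) falls
    below the coverage/identity cut-off, or (d) lies within gap_dist of an
    assembly gap. Filters run a->b->c->d; the first failing rule is
    recorded. Returns (accepted, rejection counts per rule).
    """
    trunc_by_seq: dict[str, list[Interval]] = {}
    for t in truncated_elements:
        trunc_by_seq.setdefault(t.ltr5.seq_id, []).append(t.span)
    report = {"a_overlap_truncated": 0, "b_scaffold_edge": 0,
              "c_cov_identity": 0, "d_near_gap": 0, "accepted": 0}
    accepted: list[LtrElement] = []
    for cand in candidates:
        iv = cand.ltr5
        if iv.seq_id not in scaffold_lengths:
            raise KeyError(f"no scaffold length for {iv.seq_id!r}")
        slen = scaffold_lengths[iv.seq_id]
        cov = cand.coverage if cand.coverage is not None else 0.0
        ident = cand.identity if cand.identity is not None else 0.0

        if any(iv.overlaps(t) for t in trunc_by_seq.get(iv.seq_id, ())):
            cand.decisions.append(("a_overlap_truncated", False, 1.0))
            cand.class_state = "rejected"
            report["a_overlap_truncated"] += 1
            continue
        edge = min(iv.start, slen - iv.end)
        if edge < thresholds.edge_dist:
            cand.decisions.append(("b_scaffold_edge", False, float(edge)))
            cand.class_state = "rejected"
            report["b_scaffold_edge"] += 1
            continue
        if thresholds.rule_c_mode == "require_both":
            fail_c = cov < thresholds.solo_cov or ident < thresholds.solo_id
        else:
            fail_c = cov < thresholds.solo_cov and ident < thresholds.solo_id
        if fail_c:
            cand.decisions.append(("c_cov_identity", False, min(cov, ident)))
            cand.class_state = "rejected"
            report["c_cov_identity"] += 1
            continue
        gap_d = min(
            (_dist_to_interval(iv, gs, ge)
             for gs, ge in gap_runs.get(iv.seq_id, ())),
            default=None,
        )
        if gap_d is not None and gap_d < thresholds.gap_dist:
            cand.decisions.append(("d_near_gap", False, float(gap_d)))
            cand.class_state = "rejected"
            report["d_near_gap"] += 1
            continue
        cand.decisions.append(("solo_filters", True, min(cov, ident)))
        cand.class_state = "solo"
        report["accepted"] += 1
        accepted.append(cand)
    return accepted, report


def solo_intact_ratio(n_solo: int, n_intact: int) -> float:
    """Ratio of solo-LTRs to intact LTR-RTs (recombination efficiency)."""
    if n_intact <= 0:
        raise ValueError("n_intact must be positive")
    if n_solo < 0:
        raise ValueError("n_solo must be non-negative")
    return n_solo / n_intact


# ---------------------------------------------------------------------------
# end-to-end inventory


def run_inventory(genome: Mapping[str, DnaSeq],
                  candidates: Sequence[LtrElement],
                  domain_seqs: Mapping[str, str],
                  thresholds: FilterThresholds = FilterThresholds(),
                  exemplars_per_family: int = 2):
    """Classify candidates and scan for truncated and solo loci.

    ``candidates`` are paired-LTR element calls (e.g. from a structural
    detector or the simulator's annotation); ``domain_seqs`` maps the five
    domain names to reference nucleotide sequences searched inside each
    candidate's internal region.

    Returns (intact, truncated, accepted solos, filter report, summary).
    """
    genome_seqs = genome
    intact: list[LtrElement] = []
    not_intact: list[LtrElement] = []
    for cand in candidates:
        internal_seq = genome_seqs[cand.internal.seq_id].subseq(cand.internal)
        dom_hits = scan_genome(domain_seqs, {"_int": DnaSeq("_int", internal_seq)},
                               k=7, min_len=15, min_identity=0.5)
        dom_chains = chain_hits(dom_hits, max_gap=50,
                                query_lengths={d: len(s)
                                               for d, s in domain_seqs.items()})
        out = classify_intact(cand, dom_chains, thresholds)
        (intact if out.class_state == "intact" else not_intact).append(out)

    # one full-length exemplar and one LTR exemplar pair per family keeps
    # the scan cost linear in genome size
    fam_seen: dict[str, int] = {}
    exemplar_full: dict[str, str] = {}
    exemplar_ltrs: dict[str, str] = {}
    for e in intact:
        fam = e.family or "fam"
        k = fam_seen.get(fam, 0)
        if k >= exemplars_per_family:
            continue
        fam_seen[fam] = k + 1
        seq = genome_seqs[e.ltr5.seq_id]
        exemplar_full[f"{e.element_id}_full"] = genome_seqs[
            e.span.seq_id].subseq(Interval(e.span.seq_id, e.span.start,
                                           e.span.end))
        exemplar_ltrs[f"{e.element_id}_5ltr"] = seq.subseq(e.ltr5)
        exemplar_ltrs[f"{e.element_id}_3ltr"] = seq.subseq(e.ltr3)

    intact_spans = [e.span for e in intact]
    truncated = (
        detect_truncated(genome_seqs, exemplar_full, thresholds,
                         intact_spans=intact_spans)
        if exemplar_full else []
    )
    solo_cands = (
        find_solo_candidates(genome_seqs, exemplar_ltrs, intact)
        if exemplar_ltrs else []
    )
    gap_runs = {sid: s.gap_runs for sid, s in genome_seqs.items()}
    lengths = {sid: len(s) for sid, s in genome_seqs.items()}
    accepted, report = apply_solo_filters(solo_cands, truncated, gap_runs,
                                          lengths, thresholds)
    summary = InventorySummary(
        n_intact=len(intact),
        n_truncated=len(truncated),
        n_solo=len(accepted),
        solo_intact_ratio=(solo_intact_ratio(len(accepted), len(intact))
                           if intact else float("nan")),
    )
    return intact, truncated, accepted, report, summary
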