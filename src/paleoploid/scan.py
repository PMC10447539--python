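"""A small exact-seed / ungapped-extension similarity scanner.

Produces the same :class:`~paleoploid.io_formats.LocalHit` records as an
external search engine's tabular output, so desk-scale runs need no
external binary. The scanner is ungapped: seeds on the same diagonal are
merged and extended with an X-drop criterion. That is sufficient for
detecting diverged copies of known elements (substitution-only divergence);
it is not a general-purpose gapped aligner.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping

from .io_formats import DnaSeq, Interval, LocalHit, revcomp

__all__ = ["scan_genome"]


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer:
            idx[kmer].append(i)
    return idx


def _extend_diagonal(q: str, t: str, qlo: int, qhi: int, diag: int,
                     xdrop: int, match: int = 1, mismatch: int = -3
                     ) -> tuple[int, int, int, int]:
    """Extend the seed span [qlo, qhi) on one diagonal in both directions.

    Returns (qstart, qend, n_match, n_mismatch) of the extended segment.
    diag = t_pos - q_pos.
    """
    # right extension
    best_end, best_score = qhi, 0
    score = 0
    i = qhi
    while i < len(q) and i + diag < len(t):
        score += match if q[i] == t[i + diag] else mismatch
        i += 1
        if score > best_score:
            best_score, best_end = score, i
        elif best_score - score > xdrop:
            break
    # left extension
    best_start, best_score = qlo, 0
    score = 0
    i = qlo - 1
    while i >= 0 and i + diag >= 0:
        score += match if q[i] == t[i + diag] else mismatch
        if score > best_score:
            best_score, best_start = score, i
        elif best_score - score > xdrop:
            break
        i -= 1
    nm = sum(1 for j in range(best_start, best_end) if q[j] == t[j + diag])
    return best_start, best_end, nm, (best_end - best_start) - nm


def _scan_one_strand(qid: str, q: str, tid: str, t: str,
                     index: dict[str, list[int]], k: int, strand: str,
                     t_len: int, min_len: int, min_identity: float,
                     xdrop: int) -> list[LocalHit]:
    # collect seed spans per diagonal
    diags: dict[int, list[int]] = defaultdict(list)
    for i in range(len(q) - k + 1):
        kmer = q[i : i + k]
        if "N" in kmer:
            continue
        for j in index.get(kmer, ()):
            diags[j - i].append(i)
    hits: list[LocalHit] = []
    for diag, seeds in diags.items():
        seeds.sort()
        # merge seed clusters on the diagonal, then extend each cluster once
        clusters: list[tuple[int, int]] = []
        lo = hi = None
        for s in seeds:
            if lo is None:
                lo, hi = s, s + k
            elif s <= hi + xdrop:
                hi = max(hi, s + k)
            else:
                clusters.append((lo, hi))
                lo, hi = s, s + k
        if lo is not None:
            clusters.append((lo, hi))
        for lo, hi in clusters:
            qs, qe, nmatch, nmis = _extend_diagonal(q, t, lo, hi, diag, xdrop)
            alen = qe - qs
            if alen < min_len:
                continue
            ident = nmatch / alen
            if ident < min_identity:
                continue
            ts, te = qs + diag, qe + diag
            if strand == "-":
                # map back to forward-strand coordinates of the target
                ts, te = t_len - te, t_len - ts
            hits.append(
                LocalHit(
                    query_id=qid,
                    subject_id=tid,
                    query_interval=Interval(qid, qs, qe, "+"),
                    subject_interval=Interval(tid, ts, te, strand),
                    identity=ident,
                    aligned_length=alen,
                    score=2.0 * nmatch - 3.0 * nmis,
                )
            )
    return hits


def scan_genome(queries: Mapping[str, str] | Iterable[tuple[str, str]],
                genome: Mapping[str, DnaSeq],
                k: int = 13,
                min_len: int = 30,
                min_identity: float = 0.5,
                xdrop: int = 20,
                both_strands: bool = True) -> list[LocalHit]:
    """Find ungapped local matches of each query in each genome sequence.

    Duplicate hits (same query span found from several seeds) are collapsed.
    Hits are returned sorted by (query_id, subject_id, subject start) for
    deterministic downstream behaviour.
    """
    if isinstance(queries, Mapping):
        qitems = list(queries.items())
    else:
        qitems = list(queries)
    hits: list[LocalHit] = []
    for tid, tseq in genome.items():
        fwd = tseq.residues
        idx_f = _kmer_index(fwd, k)
        rev = revcomp(fwd) if both_strands else ""
        idx_r = _kmer_index(rev, k) if both_strands else {}
        for qid, q in qitems:
            hits.extend(
                _scan_one_strand(qid, q, tid, fwd, idx_f, k, "+",
                                 len(fwd), min_len, min_identity, xdrop)
            )
            if both_strands:
                hits.extend(
                    _scan_one_strand(qid, q, tid, rev, idx_r, k, "-",
                                     len(fwd), min_len, min_identity, xdrop)
                )
    seen: dict[tuple, LocalHit] = {}
    for h in hits:
        key = (h.query_id, h.subject_id, h.query_interval.start,
               h.query_interval.end, h.subject_interval.start,
               h.subject_interval.strand)
        if key not in seen or h.score > seen[key].score:
            seen[key] = h
    out = list(seen.values())
    out.sort(key=lambda h: (h.query_id, h.subject_id,
                            h.subject_interval.start, -h.score))
    return out
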