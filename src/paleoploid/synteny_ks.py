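"""Collinearity, synonymous-substitution rates and WGD peak detection.

A whole-genome duplication leaves two signatures that this module
recovers: (1) paralogous synteny blocks whose gene pairs share a common
synonymous distance Ks, producing a peak in the distribution of
block-median Ks; and (2) a uniform k:1 synteny-depth ratio against a
reference genome that escaped the duplication.

Ks/Ka are estimated with the Nei–Gojobori (1986) counting method:
synonymous and nonsynonymous site fractions per codon, observed
differences averaged over all minimal mutational pathways, and a
Jukes–Cantor multiple-hit correction Ks = -3/4 ln(1 - 4 pS / 3).
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .io_formats import Interval

__all__ = [
    "GeneModel",
    "Anchor",
    "CollinearBlock",
    "KsEstimate",
    "MixtureFit",
    "DepthProfile",
    "chain_collinear",
    "collapse_tandem_anchors",
    "ng86_ks",
    "block_median_ks",
    "fit_ks_peaks",
    "synteny_depth",
    "export_dotplot",
    "STANDARD_TABLE",
]


@dataclass(frozen=True)
class GeneModel:
    """A gene with its chromosome-order rank (0-based along its chromosome)."""

    gene_id: str
    chrom: str
    interval: Interval
    rank: int
    cds: str | None = None

    def __post_init__(self) -> None:
        if self.cds is not None and len(self.cds) % 3 != 0:
            raise ValueError(f"CDS of {self.gene_id} not a multiple of 3")


@dataclass(frozen=True)
class Anchor:
    """One homologous gene pair used as a unit in collinearity chaining."""

    gene_a: str
    gene_b: str
    score: float = 1.0


@dataclass
class CollinearBlock:
    """An ordered chain of anchors collinear between two chromosomes."""

    block_id: str
    chrom_a: str
    chrom_b: str
    orientation: str  # "same" | "inverted"
    anchors: list[Anchor]
    median_ks: float | None = None

    def __len__(self) -> int:
        return len(self.anchors)


@dataclass(frozen=True)
class KsEstimate:
    """NG86 site counts and Jukes–Cantor-corrected Ka/Ks for one CDS pair."""

    pair: tuple[str, str]
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float
    Ka: float
    saturated_s: bool = False
    saturated_n: bool = False


@dataclass
class MixtureFit:
    """Gaussian mixture on ln(Ks) block medians; peaks mark WGD events."""

    n_components: int
    weights: list[float]
    means_log: list[float]
    sds_log: list[float]
    peaks_ks: list[float]
    bic: dict[int, float] = field(default_factory=dict)


@dataclass
class DepthProfile:
    """Per-reference-gene block coverage depth and the modal depth."""

    depths: dict[str, int]
    modal_depth: int
    histogram: dict[int, int]


# ---------------------------------------------------------------------------
# genetic code and NG86

_BASES = "TCAG"
_CODONS = ["".join(c) for c in itertools.product(_BASES, repeat=3)]
_AA = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
STANDARD_TABLE: dict[str, str] = dict(zip(_CODONS, _AA))


def _syn_sites(codon: str) -> float:
    """Synonymous site count of one codon (changes to stops count as
    nonsynonymous; stop codons themselves contribute no sites)."""
    aa = STANDARD_TABLE[codon]
    if aa == "*":
        return 0.0
    s = 0.0
    for pos in range(3):
        for b in "TCAG":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if STANDARD_TABLE[mut] == aa:
                s += 1.0 / 3.0
    return s


_SYN_SITES = {c: _syn_sites(c) for c in _CODONS}


@functools.lru_cache(maxsize=None)
def _codon_path_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous difference counts over all minimal
    mutational pathways between two codons, skipping pathways that pass
    through a stop codon (all-blocked pairs fall back to every pathway)."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if STANDARD_TABLE[nxt] == "*" and nxt != c2:
                blocked = True
                break
            if STANDARD_TABLE[nxt] == STANDARD_TABLE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            paths.append((sd, nd))
    if not paths:
        for order in itertools.permutations(diff):
            cur = c1
            sd = nd = 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if STANDARD_TABLE[nxt] == STANDARD_TABLE[cur]:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            paths.append((sd, nd))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def ng86_ks(cds_a: str, cds_b: str,
            pair: tuple[str, str] = ("a", "b")) -> KsEstimate:
    """Nei–Gojobori (1986) Ka/Ks for two aligned, equal-length CDSs."""
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if len(cds_a) != len(cds_b):
        raise ValueError("CDS lengths differ")
    if len(cds_a) % 3 != 0 or not cds_a:
        raise ValueError("CDS length must be a positive multiple of 3")
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(cds_a), 3):
        c1, c2 = cds_a[i : i + 3], cds_b[i : i + 3]
        if set(c1 + c2) - set("TCAG"):
            continue  # ambiguous codon: skipped entirely
        if STANDARD_TABLE[c1] == "*" or STANDARD_TABLE[c2] == "*":
            if i + 3 < len(cds_a):
                raise ValueError(f"internal stop codon at position {i}")
            continue  # terminal stop excluded from counting
        n_codons += 1
        S += (_SYN_SITES[c1] + _SYN_SITES[c2]) / 2.0
        sd, nd = _codon_path_counts(c1, c2)
        Sd += sd
        Nd += nd
    N = 3.0 * n_codons - S
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    sat_s = (1.0 - 4.0 * pS / 3.0) <= 0.0
    sat_n = (1.0 - 4.0 * pN / 3.0) <= 0.0
    Ks = math.inf if sat_s else -0.75 * math.log(1.0 - 4.0 * pS / 3.0)
    Ka = math.inf if sat_n else -0.75 * math.log(1.0 - 4.0 * pN / 3.0)
    return KsEstimate(pair=pair, S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN,
                      Ks=Ks, Ka=Ka, saturated_s=sat_s, saturated_n=sat_n)


# ---------------------------------------------------------------------------
# collinearity chaining


def _chain_dp(points: list[tuple[int, int, float, int]], max_gap: int
              ) -> list[int]:
    """Best increasing chain over (x, y, score, idx) points with rank gaps
    <= max_gap on both axes. Returns original indices of the best chain."""
    pts = sorted(points, key=lambda p: (p[0], p[1]))
    n = len(pts)
    best = [p[2] for p in pts]
    prev = [-1] * n
    gap_pen = 0.01
    for j in range(n):
        xj, yj, sj, _ = pts[j]
        for i in range(j):
            xi, yi, _, _ = pts[i]
            if xi < xj and yi < yj and xj - xi <= max_gap and yj - yi <= max_gap:
                cand = best[i] + sj - gap_pen * ((xj - xi - 1) + (yj - yi - 1))
                if cand > best[j]:
                    best[j], prev[j] = cand, i
    end = max(range(n), key=lambda j: best[j])
    chain = []
    j = end
    while j != -1:
        chain.append(pts[j][3])
        j = prev[j]
    chain.reverse()
    return chain


def chain_collinear(anchors: Sequence[Anchor],
                    genes_a: Mapping[str, GeneModel],
                    genes_b: Mapping[str, GeneModel],
                    min_block: int = 5,
                    max_rank_gap: int = 25) -> list[CollinearBlock]:
    """Chain anchors into collinear blocks per chromosome pair.

    Within each (chrom_a, chrom_b) pair and orientation, a dynamic
    programme finds maximal-score chains (anchor scores minus small gap
    penalties) with rank gaps <= max_rank_gap on both axes; chains are
    peeled off greedily by score, each anchor joining at most one block;
    chains shorter than min_block are discarded.
    """
    by_pair: dict[tuple[str, str], list[tuple[Anchor, int, int]]] = {}
    for anc in anchors:
        ga = genes_a.get(anc.gene_a)
        gb = genes_b.get(anc.gene_b)
        if ga is None or gb is None:
            raise KeyError(f"anchor references unknown gene: {anc}")
        by_pair.setdefault((ga.chrom, gb.chrom), []).append(
            (anc, ga.rank, gb.rank)
        )
    blocks: list[CollinearBlock] = []
    counter = 0
    for (ca, cb), items in sorted(by_pair.items()):
        remaining = list(range(len(items)))
        while remaining:
            candidates = []
            for orient in ("same", "inverted"):
                pts = []
                for idx in remaining:
                    anc, ra, rb = items[idx]
                    y = rb if orient == "same" else -rb
                    pts.append((ra, y, anc.score, idx))
                chain = _chain_dp(pts, max_rank_gap)
                score = sum(items[i][0].score for i in chain)
                candidates.append((score, len(chain), orient, chain))
            # prefer the higher-scoring orientation, ties to "same"
            candidates.sort(key=lambda c: (-c[0], -c[1], c[2] != "same"))
            score, length, orient, chain = candidates[0]
            if length < min_block:
                break
            blocks.append(
                CollinearBlock(
                    block_id=f"blk_{counter}",
                    chrom_a=ca,
                    chrom_b=cb,
                    orientation=orient,
                    anchors=[items[i][0] for i in chain],
                )
            )
            counter += 1
            taken = set(chain)
            remaining = [i for i in remaining if i not in taken]
    blocks.sort(key=lambda b: (b.chrom_a, b.chrom_b, b.block_id))
    return blocks


def collapse_tandem_anchors(anchors: Sequence[Anchor],
                            genes_a: Mapping[str, GeneModel],
                            genes_b: Mapping[str, GeneModel],
                            window: int = 10) -> list[Anchor]:
    """Collapse local duplicate arrays before collinearity chaining.

    Homologous genes within ``window`` ranks of each other on the same
    chromosome (tandem/proximal arrays) otherwise contribute stacked
    anchors that either chain into spurious near-diagonal self-blocks or
    get absorbed into genuine blocks in place of their parents. Each such
    array is reduced to one representative — the member with the
    strongest anchor outside the array (ties to the smaller rank) — and
    anchors involving non-representatives, as well as intra-array
    anchors, are dropped.
    """
    genes_all: dict[str, GeneModel] = {**genes_a, **genes_b}

    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    intra: list[Anchor] = []
    for anc in anchors:
        ga, gb = genes_all.get(anc.gene_a), genes_all.get(anc.gene_b)
        if ga is None or gb is None:
            continue
        if ga.chrom == gb.chrom and abs(ga.rank - gb.rank) <= window:
            intra.append(anc)
            ra, rb = find(anc.gene_a), find(anc.gene_b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    arrays: dict[str, list[str]] = {}
    for g in list(parent):
        arrays.setdefault(find(g), []).append(g)
    member_of = {g: root for root, members in arrays.items()
                 for g in members}
    # representative = member with the best anchor score outside its array
    best_outside: dict[str, float] = {}
    for anc in anchors:
        for g, other in ((anc.gene_a, anc.gene_b),
                         (anc.gene_b, anc.gene_a)):
            if g in member_of and member_of.get(other) != member_of[g]:
                best_outside[g] = max(best_outside.get(g, 0.0), anc.score)
    rep: dict[str, str] = {}
    for root, members in arrays.items():
        chosen = min(
            members,
            key=lambda g: (-best_outside.get(g, 0.0), genes_all[g].rank,
                           g),
        )
        for g in members:
            rep[g] = chosen
    out: list[Anchor] = []
    for anc in anchors:
        a, b = anc.gene_a, anc.gene_b
        if a in rep and rep[a] != a:
            continue
        if b in rep and rep[b] != b:
            continue
        ga, gb = genes_all.get(a), genes_all.get(b)
        if ga is not None and gb is not None and ga.chrom == gb.chrom \
                and abs(ga.rank - gb.rank) <= window:
            continue  # the intra-array anchor itself
        out.append(anc)
    return out


def block_median_ks(block: CollinearBlock,
                    ks_by_pair: Mapping[tuple[str, str], KsEstimate]
                    ) -> float | None:
    """Median of the block's unflagged per-pair Ks values (even count:
    midpoint of the central two). Returns None when every pair is
    saturated; such blocks are excluded from peak fitting."""
    vals = []
    for anc in block.anchors:
        est = ks_by_pair.get((anc.gene_a, anc.gene_b)) or ks_by_pair.get(
            (anc.gene_b, anc.gene_a)
        )
        if est is not None and not est.saturated_s:
            vals.append(est.Ks)
    if not vals:
        block.median_ks = None
        return None
    med = float(np.median(vals))
    block.median_ks = med
    return med


def fit_ks_peaks(block_medians: Iterable[float],
                 max_components: int = 5,
                 ks_range: tuple[float, float] = (0.005, 3.0),
                 seed: int = 0,
                 min_points: int = 30,
                 n_init: int = 20) -> MixtureFit:
    """Fit Gaussian mixtures with 1..max_components components to ln(Ks)
    block medians (values outside ks_range dropped) and pick the component
    count by minimum BIC. Peak locations are the back-transformed means.
    """
    vals = np.asarray([v for v in block_medians
                       if ks_range[0] <= v <= ks_range[1]])
    if vals.size < min_points:
        raise ValueError(
            f"need >= {min_points} block medians in range, got {vals.size}"
        )
    x = np.log(vals).reshape(-1, 1)
    bic: dict[int, float] = {}
    fits: dict[int, GaussianMixture] = {}
    for k in range(1, max_components + 1):
        gm = GaussianMixture(n_components=k, covariance_type="full",
                             n_init=n_init, init_params="kmeans",
                             random_state=seed)
        gm.fit(x)
        bic[k] = float(gm.bic(x))
        fits[k] = gm
    k_best = min(bic, key=lambda k: (bic[k], k))
    gm = fits[k_best]
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.reshape(-1)[order])
    weights = gm.weights_[order]
    return MixtureFit(
        n_components=k_best,
        weights=[float(w) for w in weights],
        means_log=[float(m) for m in means],
        sds_log=[float(s) for s in sds],
        peaks_ks=[float(np.exp(m)) for m in means],
        bic=bic,
    )


# ---------------------------------------------------------------------------
# synteny depth and dot plots


def synteny_depth(blocks: Sequence[CollinearBlock],
                  ref_genes: Mapping[str, GeneModel],
                  query_side: str = "a") -> DepthProfile:
    """Depth of query-block coverage over each reference gene.

    ``query_side`` names the block side holding the query genome ("a" or
    "b"); the other side is the reference. A block covers every reference
    gene whose rank falls within the block's reference-side rank span.
    The modal depth over genes with depth >= 1 (ties broken toward the
    smaller depth) is the query side of the "modal:1" syntenic ratio.
    """
    ref_side = "b" if query_side == "a" else "a"
    depths = {gid: 0 for gid in ref_genes}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in ref_genes.values():
        by_chrom.setdefault(g.chrom, []).append(g)
    for blk in blocks:
        ref_chrom = blk.chrom_b if ref_side == "b" else blk.chrom_a
        ranks = []
        for anc in blk.anchors:
            gid = anc.gene_b if ref_side == "b" else anc.gene_a
            g = ref_genes.get(gid)
            if g is not None:
                ranks.append(g.rank)
        if not ranks:
            continue
        lo, hi = min(ranks), max(ranks)
        for g in by_chrom.get(ref_chrom, ()):
            if lo <= g.rank <= hi:
                depths[g.gene_id] += 1
    hist: dict[int, int] = {}
    for d in depths.values():
        hist[d] = hist.get(d, 0) + 1
    covered = {d: c for d, c in hist.items() if d >= 1}
    if covered:
        modal = min(
            (d for d in covered),
            key=lambda d: (-covered[d], d),
        )
    else:
        modal = 0
    return DepthProfile(depths=depths, modal_depth=modal, histogram=hist)


def export_dotplot(blocks: Sequence[CollinearBlock],
                   genes_a: Mapping[str, GeneModel],
                   genes_b: Mapping[str, GeneModel],
                   ks_by_pair: Mapping[tuple[str, str], KsEstimate]
                   | None = None) -> pd.DataFrame:
    """One row per anchor with ranks on both axes, block id, orientation
    and Ks; rows sorted by (chrom pair, rank) for stable output."""
    rows = []
    for blk in blocks:
        for anc in blk.anchors:
            ks = None
            if ks_by_pair is not None:
                est = ks_by_pair.get((anc.gene_a, anc.gene_b)) or \
                    ks_by_pair.get((anc.gene_b, anc.gene_a))
                if est is not None and not est.saturated_s:
                    ks = est.Ks
            rows.append({
                "chrom_a": blk.chrom_a, "chrom_b": blk.chrom_b,
                "rank_a": genes_a[anc.gene_a].rank,
                "rank_b": genes_b[anc.gene_b].rank,
                "gene_a": anc.gene_a, "gene_b": anc.gene_b,
                "block_id": blk.block_id, "orientation": blk.orientation,
                "ks": ks,
            })
    df = pd.DataFrame(rows, columns=["chrom_a", "chrom_b", "rank_a",
                                     "rank_b", "gene_a", "gene_b",
                                     "block_id", "orientation", "ks"])
    if len(df):
        df = df.sort_values(["chrom_a", "chrom_b", "rank_a", "rank_b"],
                            kind="mergesort").reset_index(drop=True)
    return df
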