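"""Synthetic genomes and gene complements with known ground truth.

Two generators drive every recovery test in the package:

* :func:`simulate_ltr_genome` writes scaffolds carrying intact LTR
  retrotransposons (paired LTRs identical at insertion, each accruing
  substitutions independently at rate r so the expected pairwise LTR
  divergence of an element of age t is 2·r·t), solo-LTRs, truncated
  copies, and decoy solo-LTRs near scaffold edges or assembly gaps.

* :func:`simulate_wgd_genomes` evolves a gene complement through 0-2
  whole-genome duplications with per-copy gene loss, an optional
  speciation (before or after the WGDs, giving shared or lineage-specific
  duplications), and injected tandem/proximal/transposed/dispersed
  duplicates. Coding sequences evolve by synonymous-only substitution to
  target Ks values, so the Nei-Gojobori estimator can recover event ages.

Both are deterministic for a given (config, seed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import DnaSeq, Interval
from .synteny_ks import STANDARD_TABLE, GeneModel, Anchor, _SYN_SITES

__all__ = [
    "LtrSimConfig",
    "WgdSimConfig",
    "LtrSim",
    "WgdSim",
    "simulate_ltr_genome",
    "simulate_wgd_genomes",
    "evolve_cds_pair",
    "DOMAIN_MOTIFS",
]

# fixed 30-bp sentinel motifs standing in for the five internal protein
# domains of an intact element; every simulated family embeds the same set
DOMAIN_MOTIFS: dict[str, str] = {
    "GAG": "ATGGCAAGACTCGTTCCAGGTGACTTAGCC",
    "AP":  "TGCCGTATCAAGGAGCTTTACGATCCAGTA",
    "INT": "GGATCATACGTTGCCAAGTCTTGAGCCATA",
    "RT":  "CCTAGGTTCGAAGACATGCTTGGACGTATC",
    "RH":  "TACGGCTTAGATCCGAACGGTTCAATGCTG",
}

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)
_TRANSITION = {65: 71, 71: 65, 67: 84, 84: 67}  # A<->G, C<->T
_TRANSVERSIONS = {65: (67, 84), 71: (67, 84), 67: (65, 71), 84: (65, 71)}


def _random_dna(rng: np.random.Generator, n: int, gc: float = 0.4) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(_BASE_ARR, size=n, p=p)
    return arr.tobytes().decode()


def mutate_seq(seq: str, p: float, rng: np.random.Generator,
               ts_ratio: float = 2.0) -> str:
    """Substitute each site independently with probability p.

    Substitutions are transitions with odds ts_ratio : 1 against
    transversions (the two transversion targets equiprobable). N bases
    are left untouched.
    """
    if p <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(arr.size) < p)
    if hit.size == 0:
        return seq
    is_ts = rng.random(hit.size) < ts_ratio / (ts_ratio + 1.0)
    which_tv = rng.integers(0, 2, size=hit.size)
    for idx, ts, tv in zip(hit, is_ts, which_tv):
        b = arr[idx]
        if b not in _TRANSITION:  # N or ambiguity: untouched
            continue
        arr[idx] = _TRANSITION[b] if ts else _TRANSVERSIONS[b][tv]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# LTR genome simulation


@dataclass(frozen=True)
class LtrSimConfig:
    """Study conditions for the LTR genome generator.

    Ages are in years; the substitution rate r is per site per year. Each
    LTR of an intact element accrues substitutions independently with
    per-site probability r*age, so the expected pairwise LTR divergence
    is about 2*r*age.
    """

    n_intact: int = 50
    n_solo: int = 100
    n_truncated: int = 20
    n_edge_decoys: int = 8
    n_gap_decoys: int = 8
    ltr_length: int = 400
    internal_length: int = 4000
    age_range: tuple[float, float] = (1e6, 8e6)
    rate: float = 2.5e-9
    background_length: int = 400_000
    gc: float = 0.40
    n_scaffolds: int = 4
    n_families: int = 2
    family_names: tuple[str, ...] = ("Copia", "Gypsy")
    ts_ratio: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_intact", "n_solo", "n_truncated", "n_edge_decoys",
                     "n_gap_decoys"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0, 1)")
        if self.age_range[0] < 0 or self.age_range[1] < self.age_range[0]:
            raise ValueError("invalid age_range")
        if self.rate <= 0:
            raise ValueError("rate must be positive")


@dataclass
class LtrSim:
    """Output bundle of :func:`simulate_ltr_genome`."""

    genome: dict[str, DnaSeq]
    truth: pd.DataFrame
    config: LtrSimConfig

    def intact_candidates(self):
        """Paired-LTR candidate elements from the truth annotation, the
        input a structural detector would provide."""
        from .ltr_inventory import LtrElement

        out = []
        for row in self.truth.itertuples():
            if row.true_class != "intact":
                continue
            out.append(
                LtrElement(
                    element_id=row.element_id,
                    ltr5=Interval(row.seq_id, row.start,
                                  row.start + self.config.ltr_length, "+"),
                    internal=Interval(row.seq_id,
                                      row.start + self.config.ltr_length,
                                      row.end - self.config.ltr_length, "+"),
                    ltr3=Interval(row.seq_id,
                                  row.end - self.config.ltr_length,
                                  row.end, "+"),
                    family=row.family,
                )
            )
        return out


def _build_family_ancestors(cfg: LtrSimConfig, rng: np.random.Generator
                            ) -> dict[str, tuple[str, str]]:
    """Per family: (ancestral LTR, ancestral internal region with the five
    sentinel motifs embedded at spread positions)."""
    fams = {}
    names = list(cfg.family_names[: cfg.n_families])
    while len(names) < cfg.n_families:
        names.append(f"fam{len(names)}")
    motif_list = list(DOMAIN_MOTIFS.values())
    for name in names:
        ltr = _random_dna(rng, cfg.ltr_length, cfg.gc)
        internal = list(_random_dna(rng, cfg.internal_length, cfg.gc))
        slot = cfg.internal_length // (len(motif_list) + 1)
        for i, motif in enumerate(motif_list, start=1):
            pos = i * slot
            internal[pos : pos + len(motif)] = motif
        fams[name] = (ltr, "".join(internal))
    return fams


def simulate_ltr_genome(config: LtrSimConfig) -> LtrSim:
    """Generate scaffolds with implanted LTR elements and a truth table.

    Implants are separated by background spacers drawn from the
    background budget; ordinary implants stay clear of scaffold edges
    (> edge margin) and of gaps, so only the decoys trip the edge/gap
    filters. Raises if implants cannot fit in background_length.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    fams = _build_family_ancestors(cfg, rng)
    fam_names = list(fams)

    implants: list[dict] = []  # {kind, family, age, seq, pre_gap/post_gap}

    def _draw_age() -> float:
        return float(rng.uniform(cfg.age_range[0], cfg.age_range[1]))

    def _ltr_copy(fam: str, age: float) -> str:
        # family radiation + post-insertion divergence of a single copy
        base = mutate_seq(fams[fam][0], float(rng.uniform(0.0, 0.03)), rng,
                          cfg.ts_ratio)
        return mutate_seq(base, cfg.rate * age, rng, cfg.ts_ratio)

    for i in range(cfg.n_intact):
        fam = fam_names[i % len(fam_names)]
        age = _draw_age()
        radiation = float(rng.uniform(0.0, 0.03))
        ltr_at_insert = mutate_seq(fams[fam][0], radiation, rng, cfg.ts_ratio)
        internal_at_insert = mutate_seq(fams[fam][1], radiation, rng,
                                        cfg.ts_ratio)
        p = cfg.rate * age
        ltr5 = mutate_seq(ltr_at_insert, p, rng, cfg.ts_ratio)
        ltr3 = mutate_seq(ltr_at_insert, p, rng, cfg.ts_ratio)
        internal = mutate_seq(internal_at_insert, p, rng, cfg.ts_ratio)
        implants.append({"kind": "intact", "family": fam, "age": age,
                         "seq": ltr5 + internal + ltr3})
    for i in range(cfg.n_solo):
        fam = fam_names[i % len(fam_names)]
        age = _draw_age()
        implants.append({"kind": "solo", "family": fam, "age": age,
                         "seq": _ltr_copy(fam, age)})
    for i in range(cfg.n_truncated):
        fam = fam_names[i % len(fam_names)]
        age = _draw_age()
        ltr, internal = fams[fam]
        full = ltr + internal + ltr
        frac = float(rng.uniform(0.83, 0.91))
        seq = mutate_seq(full[: int(len(full) * frac)],
                         float(rng.uniform(0.0, 0.03)) + cfg.rate * age, rng,
                         cfg.ts_ratio)
        implants.append({"kind": "truncated", "family": fam, "age": age,
                         "seq": seq})
    for i in range(cfg.n_edge_decoys):
        fam = fam_names[i % len(fam_names)]
        age = _draw_age()
        implants.append({"kind": "edge_decoy", "family": fam, "age": age,
                         "seq": _ltr_copy(fam, age)})
    for i in range(cfg.n_gap_decoys):
        fam = fam_names[i % len(fam_names)]
        age = _draw_age()
        gap = "N" * int(rng.integers(100, 300))
        spacer = _random_dna(rng, int(rng.integers(50, 400)), cfg.gc)
        implants.append({"kind": "gap_decoy", "family": fam, "age": age,
                         "seq": gap + spacer + _ltr_copy(fam, age),
                         "ltr_offset": len(gap) + len(spacer)})

    total_implant = sum(len(im["seq"]) for im in implants)
    margin = 6_000
    min_budget = cfg.n_scaffolds * 2 * margin + len(implants) * 700
    if min_budget > cfg.background_length:
        raise ValueError(
            f"implants ({total_implant} bp plus margins, needing "
            f">= {min_budget} bp of background) exceed background_length "
            f"{cfg.background_length}"
        )

    # edge decoys occupy scaffold starts/ends (one each); everything else
    # is laid out round-robin in the scaffold interiors
    edge = [im for im in implants if im["kind"] == "edge_decoy"]
    if len(edge) > 2 * cfg.n_scaffolds:
        raise ValueError("n_edge_decoys exceeds 2 * n_scaffolds edge slots")
    inner = [im for im in implants if im["kind"] != "edge_decoy"]
    order = rng.permutation(len(inner))
    inner = [inner[i] for i in order]
    start_decoy: list[dict | None] = [None] * cfg.n_scaffolds
    end_decoy: list[dict | None] = [None] * cfg.n_scaffolds
    for i, im in enumerate(edge):
        s = i % cfg.n_scaffolds
        if start_decoy[s] is None:
            start_decoy[s] = im
        else:
            end_decoy[s] = im
    per_scaffold: list[list[dict]] = [[] for _ in range(cfg.n_scaffolds)]
    for i, im in enumerate(inner):
        per_scaffold[i % cfg.n_scaffolds].append(im)

    budget_per = cfg.background_length // cfg.n_scaffolds
    genome: dict[str, DnaSeq] = {}
    rows = []
    eid = itertools.count()
    for s in range(cfg.n_scaffolds):
        sid = f"scaf{s + 1}"
        items = per_scaffold[s]
        spare = budget_per - 2 * margin - len(items) * 700
        extra = max(0, spare) // max(1, len(items) + 1)
        parts: list[str] = []
        pos = 0

        def _emit(seq: str) -> None:
            nonlocal pos
            parts.append(seq)
            pos += len(seq)

        def _record(im: dict, start: int, end: int) -> None:
            off = im.get("ltr_offset", 0)
            rows.append({
                "element_id": f"elem{next(eid)}",
                "true_class": im["kind"],
                "implant_age": im["age"],
                "family": im["family"],
                "seq_id": sid,
                "start": start + off,
                "end": end,
            })

        if start_decoy[s] is not None:
            _emit(_random_dna(rng, int(rng.integers(500, 4_000)), cfg.gc))
            a = pos
            _emit(start_decoy[s]["seq"])
            _record(start_decoy[s], a, pos)
        first = True
        for im in items:
            base = margin if first else 700
            _emit(_random_dna(rng, base + int(rng.integers(0, extra + 1)),
                              cfg.gc))
            a = pos
            _emit(im["seq"])
            _record(im, a, pos)
            first = False
        _emit(_random_dna(rng, margin + int(rng.integers(0, extra + 1)),
                          cfg.gc))
        if end_decoy[s] is not None:
            a = pos
            _emit(end_decoy[s]["seq"])
            _record(end_decoy[s], a, pos)
            _emit(_random_dna(rng, int(rng.integers(500, 4_000)), cfg.gc))
        genome[sid] = DnaSeq(id=sid, residues="".join(parts))
    truth = pd.DataFrame(rows)
    return LtrSim(genome=genome, truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# CDS evolution (synonymous-only)


def _codon_syn_options(codon: str) -> tuple[tuple[int, str], ...]:
    """(position-in-codon, alternative base) synonymous changes of a codon."""
    aa = STANDARD_TABLE.get(codon)
    if aa is None or aa == "*":
        return ()
    opts = []
    for pos in range(3):
        for b in "TCAG":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if STANDARD_TABLE[mut] == aa:
                opts.append((pos, b))
    return tuple(opts)


_CODON_SYN_OPTIONS = {c: _codon_syn_options(c) for c in STANDARD_TABLE}


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """A random CDS of n_codons sense codons (no stops)."""
    sense = [c for c, aa in STANDARD_TABLE.items() if aa != "*"]
    idx = rng.integers(0, len(sense), size=n_codons)
    return "".join(sense[i] for i in idx)


def ng86_site_count(cds: str) -> float:
    """NG86 synonymous site count of one sequence."""
    S = 0.0
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if codon in _SYN_SITES and STANDARD_TABLE[codon] != "*":
            S += _SYN_SITES[codon]
    return S


def evolve_cds_pair(cds: str, target_ks: float,
                    seed: int | np.random.Generator) -> str:
    """Evolve a copy of a CDS to a target synonymous distance.

    Applies Poisson(target_ks * S) substitution events, S being the NG86
    synonymous site count; each event picks one synonymous single-base
    change of the current sequence uniformly at random, so no stop codon
    and no amino-acid change is ever introduced. The expected NG86 Ks of
    (input, output) is approximately target_ks (exactly for small Ks; the
    Jukes-Cantor correction absorbs multiple hits).
    """
    if len(cds) % 3 != 0 or not cds:
        raise ValueError("CDS length must be a positive multiple of 3")
    for i in range(0, len(cds) - 3, 3):
        if STANDARD_TABLE.get(cds[i : i + 3]) == "*":
            raise ValueError(f"internal stop codon at {i}")
    if target_ks < 0:
        raise ValueError("target_ks must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if target_ks == 0:
        return cds
    S = ng86_site_count(cds)
    n_events = int(rng.poisson(target_ks * S))
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    counts = np.array([len(_CODON_SYN_OPTIONS[c]) for c in codons],
                      dtype=np.int64)
    for _ in range(n_events):
        total = int(counts.sum())
        if total == 0:
            break
        # uniform over all synonymous change options of the current
        # sequence: codon weighted by its option count, option uniform
        target = int(rng.integers(0, total))
        ci = int(np.searchsorted(np.cumsum(counts), target, side="right"))
        opts = _CODON_SYN_OPTIONS[codons[ci]]
        pos, b = opts[int(rng.integers(0, len(opts)))]
        codons[ci] = codons[ci][:pos] + b + codons[ci][pos + 1 :]
        counts[ci] = len(_CODON_SYN_OPTIONS[codons[ci]])
    return "".join(codons)


# ---------------------------------------------------------------------------
# WGD gene-complement simulation


@dataclass(frozen=True)
class WgdSimConfig:
    """Study conditions for the WGD gene-complement generator.

    ``wgd_events`` lists (Ks_age, per-copy loss probability) pairs, oldest
    first; Ks_age is the expected pairwise synonymous distance between the
    two copies created by that event. ``speciation_ks`` is the expected
    ortholog Ks between species A and B; with ``shared_wgd`` the
    duplications predate the split, otherwise each species duplicates
    independently after it.
    """

    n_ancestral_genes: int = 300
    n_chromosomes: int = 2
    wgd_events: tuple[tuple[float, float], ...] = ((0.9, 0.1), (0.3, 0.1))
    rate_tandem: float = 0.03
    rate_proximal: float = 0.03
    rate_transposed: float = 0.03
    rate_dispersed: float = 0.03
    cds_length: int = 300  # codons
    speciation_ks: float | None = None
    shared_wgd: bool = True
    ref_divergence_ks: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ancestral_genes <= 0:
            raise ValueError("n_ancestral_genes must be positive")
        for ks, lp in self.wgd_events:
            if ks < 0 or not 0 <= lp <= 1:
                raise ValueError("invalid wgd event")
        for r in (self.rate_tandem, self.rate_proximal,
                  self.rate_transposed, self.rate_dispersed):
            if not 0 <= r <= 1:
                raise ValueError("duplication rates must be in [0, 1]")


@dataclass
class WgdSim:
    """Output bundle of :func:`simulate_wgd_genomes`."""

    ref_genes: dict[str, GeneModel]
    genes_a: dict[str, GeneModel]
    genes_b: dict[str, GeneModel]
    cds: dict[str, str]
    anchors_a_ref: list[Anchor]
    anchors_within_a: list[Anchor]
    anchors_within_b: list[Anchor]
    anchors_ab: list[Anchor]
    truth: pd.DataFrame
    config: WgdSimConfig


@dataclass
class _Lineage:
    """One gene copy evolving along the duplication/speciation history."""

    family: int
    seq: str
    wgd_round: int  # 0 = never duplicated by WGD on this branch yet
    depth_ks: float = 0.0  # cumulated per-lineage Ks since the root
    uid: int = -1


def _evolve_genome(chroms: list[list[_Lineage]], delta: float,
                   rng: np.random.Generator) -> None:
    if delta <= 0:
        return
    for chrom in chroms:
        for lin in chrom:
            lin.seq = evolve_cds_pair(lin.seq, delta, rng)
            lin.depth_ks += delta


def _apply_wgd(chroms: list[list[_Lineage]], loss_prob: float, round_no: int,
               rng: np.random.Generator) -> list[list[_Lineage]]:
    out: list[list[_Lineage]] = []
    for chrom in chroms:
        out.append(chrom)
        copy: list[_Lineage] = []
        for lin in chrom:
            if rng.random() < loss_prob:
                continue
            copy.append(_Lineage(family=lin.family, seq=lin.seq,
                                 wgd_round=round_no,
                                 depth_ks=lin.depth_ks))
        if copy:
            out.append(copy)
    return out


def simulate_wgd_genomes(config: WgdSimConfig) -> WgdSim:
    """Simulate a reference genome plus one or two descendant species.

    The reference keeps the ancestral single-copy gene order. Species A
    (and B, when ``speciation_ks`` is set) descends from the ancestor
    through the configured WGD events; per-lineage branch lengths are in
    Ks/2 units so that copies created by an event at Ks_age k show an
    expected pairwise Ks of k. Tandem/proximal/transposed/dispersed
    duplicates are injected into each species afterwards. Anchor tables
    carry similarity scores 1/(1+Ks) from true lineage divergences.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_per_chrom = cfg.n_ancestral_genes // cfg.n_chromosomes

    # ancestral complement and the (static) reference genome
    anc_cds = [random_cds(rng, cfg.cds_length)
               for _ in range(cfg.n_ancestral_genes)]
    ref_genes: dict[str, GeneModel] = {}
    cds: dict[str, str] = {}
    fam_of_ref: dict[str, int] = {}
    fam_assign: list[list[int]] = []
    fams_left = list(range(cfg.n_ancestral_genes))
    for c in range(cfg.n_chromosomes):
        take = n_per_chrom if c < cfg.n_chromosomes - 1 else len(fams_left)
        fam_assign.append(fams_left[:take])
        fams_left = fams_left[take:]
    for c, fams in enumerate(fam_assign):
        for rank, fam in enumerate(fams):
            gid = f"R{fam:04d}"
            ref_genes[gid] = GeneModel(
                gene_id=gid, chrom=f"rchr{c + 1}",
                interval=Interval(f"rchr{c + 1}", rank * 1000,
                                  rank * 1000 + 900, "+"),
                rank=rank)
            ref_cds = evolve_cds_pair(anc_cds[fam],
                                      cfg.ref_divergence_ks / 2, rng)
            cds[gid] = ref_cds
            fam_of_ref[gid] = fam

    # the evolving descendant genome starts as the ancestral complement
    chroms: list[list[_Lineage]] = []
    for fams in fam_assign:
        chroms.append([_Lineage(family=fam, seq=anc_cds[fam], wgd_round=0,
                                depth_ks=cfg.ref_divergence_ks / 2)
                       for fam in fams])

    events = sorted(cfg.wgd_events, key=lambda e: -e[0])
    species: dict[str, list[list[_Lineage]]] = {}

    def _clone(ch: list[list[_Lineage]]) -> list[list[_Lineage]]:
        return [[_Lineage(l.family, l.seq, l.wgd_round, l.depth_ks)
                 for l in chrom] for chrom in ch]

    if cfg.speciation_ks is None or cfg.shared_wgd:
        # WGDs on the shared stem, speciation (if any) afterwards;
        # event ages (pairwise Ks) convert to per-lineage depths k/2
        depths = [k / 2 for k, _ in events]
        if cfg.speciation_ks is not None and depths \
                and cfg.speciation_ks / 2 > min(depths):
            raise ValueError("shared WGDs must predate the speciation")
        now = depths[0] if depths else (cfg.speciation_ks or 0.0) / 2
        for i, ((_ks_age, loss), d) in enumerate(zip(events, depths)):
            _evolve_genome(chroms, now - d, rng)
            now = d
            chroms = _apply_wgd(chroms, loss, round_no=i + 1, rng=rng)
        if cfg.speciation_ks is not None:
            ds = cfg.speciation_ks / 2
            _evolve_genome(chroms, now - ds, rng)
            a = _clone(chroms)
            b = _clone(chroms)
            _evolve_genome(a, ds, rng)
            _evolve_genome(b, ds, rng)
            species["A"], species["B"] = a, b
        else:
            _evolve_genome(chroms, now, rng)
            species["A"] = chroms
    else:
        # speciation first, then independent WGDs in each species
        ds = cfg.speciation_ks / 2
        depths = [k / 2 for k, _ in events]
        if depths and depths[0] > ds:
            raise ValueError("independent WGDs must postdate the split")
        a = _clone(chroms)
        b = _clone(chroms)
        for ch in (a, b):
            now = ds
            for i, ((_ks_age, loss), d) in enumerate(zip(events, depths)):
                _evolve_genome(ch, now - d, rng)
                now = d
                new = _apply_wgd(ch, loss, round_no=i + 1, rng=rng)
                ch.clear()
                ch.extend(new)
            _evolve_genome(ch, now, rng)
        species["A"], species["B"] = a, b

    # small-scale duplications per species, then freeze gene tables
    truth_rows = []
    genes_by_species: dict[str, dict[str, GeneModel]] = {}
    next_fam = cfg.n_ancestral_genes
    uid_counter = itertools.count()
    for sp, ch_list in species.items():
        prefix = sp
        # inject TD/PD/TRD/dispersed
        n_genes = sum(len(c) for c in ch_list)
        ssd_rows = []  # (kind, chrom_idx, insert_pos, lineage)
        for ci, chrom in enumerate(ch_list):
            for gi, lin in enumerate(list(chrom)):
                u = rng.random()
                ks_young = float(rng.uniform(0.02, 0.12))
                if u < cfg.rate_tandem:
                    dup = _Lineage(lin.family,
                                   evolve_cds_pair(lin.seq, ks_young, rng),
                                   wgd_round=-1,
                                   depth_ks=lin.depth_ks + ks_young)
                    dup._partner = lin  # type: ignore[attr-defined]
                    ssd_rows.append(("td", ci, gi, dup))
                elif u < cfg.rate_tandem + cfg.rate_proximal:
                    off = int(rng.integers(2, 11))
                    dup = _Lineage(lin.family,
                                   evolve_cds_pair(lin.seq, ks_young, rng),
                                   wgd_round=-2,
                                   depth_ks=lin.depth_ks + ks_young)
                    dup._partner = lin  # type: ignore[attr-defined]
                    ssd_rows.append(("pd", ci, gi + off, dup))
                elif u < (cfg.rate_tandem + cfg.rate_proximal
                          + cfg.rate_transposed):
                    dup = _Lineage(lin.family,
                                   evolve_cds_pair(lin.seq, ks_young, rng),
                                   wgd_round=-3,
                                   depth_ks=lin.depth_ks + ks_young)
                    dup._partner = lin  # type: ignore[attr-defined]
                    tc = int(rng.integers(0, len(ch_list)))
                    tp = int(rng.integers(0, len(ch_list[tc]) + 1))
                    ssd_rows.append(("trd", tc, tp, dup))
        # dispersed: novel families, two copies at random loci
        n_disp = rng.binomial(n_genes, cfg.rate_dispersed)
        for _ in range(n_disp):
            seq0 = random_cds(rng, cfg.cds_length)
            ksy = float(rng.uniform(0.02, 0.12))
            pair = []
            for _copy in range(2):
                dup = _Lineage(next_fam, evolve_cds_pair(seq0, ksy / 2, rng),
                               wgd_round=-4, depth_ks=ksy / 2)
                pair.append(dup)
                tc = int(rng.integers(0, len(ch_list)))
                tp = int(rng.integers(0, len(ch_list[tc]) + 1))
                ssd_rows.append(("dispersed", tc, tp, dup))
            pair[0]._partner = pair[1]  # type: ignore[attr-defined]
            pair[1]._partner = pair[0]  # type: ignore[attr-defined]
            next_fam += 1
        # apply insertions (sort by position descending so indices hold)
        for kind, ci, pos, dup in sorted(ssd_rows, key=lambda r: -r[2]):
            pos = min(pos, len(ch_list[ci]))
            ch_list[ci].insert(pos, dup)
            dup._ssd_kind = kind  # type: ignore[attr-defined]

        # realised positions first: insertion shifts can change a copy's
        # final rank distance to its partner, and the duplicate categories
        # are positional by definition
        pos_of: dict[int, tuple[str, int]] = {}
        for ci, chrom in enumerate(ch_list):
            cname = f"{prefix.lower()}chr{ci + 1}"
            for rank, lin in enumerate(chrom):
                pos_of[id(lin)] = (cname, rank)

        table: dict[str, GeneModel] = {}
        for ci, chrom in enumerate(ch_list):
            cname = f"{prefix.lower()}chr{ci + 1}"
            for rank, lin in enumerate(chrom):
                gid = f"{prefix}{next(uid_counter):05d}"
                lin.gid = gid  # type: ignore[attr-defined]
                table[gid] = GeneModel(
                    gene_id=gid, chrom=cname,
                    interval=Interval(cname, rank * 1000, rank * 1000 + 900,
                                      "+"),
                    rank=rank)
                cds[gid] = lin.seq
                kind = getattr(lin, "_ssd_kind", None)
                if kind is None:
                    kind = "wgd" if lin.wgd_round > 0 else "ancestral"
                else:
                    partner = getattr(lin, "_partner", None)
                    ppos = pos_of.get(id(partner)) if partner is not None \
                        else None
                    if ppos is not None and ppos[0] == cname:
                        d = abs(rank - ppos[1])
                        if d == 1:
                            kind = "td"
                        elif 2 <= d <= 10:
                            kind = "pd"
                        elif kind in ("td", "pd"):
                            kind = "dispersed"
                    elif kind in ("td", "pd"):
                        kind = "dispersed"
                truth_rows.append({
                    "gene_id": gid, "species": sp, "family": lin.family,
                    "category": kind, "wgd_round": max(lin.wgd_round, 0),
                    "depth_ks": lin.depth_ks, "chrom": cname, "rank": rank,
                })
        genes_by_species[sp] = table

    truth = pd.DataFrame(truth_rows)

    # refine truth: ancestral-lineage genes with >= 2 surviving family
    # members in their species are WGD duplicates; a lone survivor whose
    # family gained a small-scale duplicate takes that pair's label (the
    # ancestral partner of a transposed copy stays at its old locus, so
    # its own class is dispersed), and genes with no homolog at all are
    # singletons
    for sp in genes_by_species:
        m = truth.species == sp
        fam_sizes = truth[m & truth.category.isin(["ancestral", "wgd"])] \
            .groupby("family").size()
        ssd_kind: dict[int, str] = {}
        for row in truth[m & truth.category.isin(["td", "pd", "trd"])] \
                .itertuples():
            label = {"td": "td", "pd": "pd", "trd": "dispersed"}[row.category]
            ssd_kind.setdefault(row.family, label)
        anc_mask = m & truth.category.isin(["ancestral", "wgd"])
        truth.loc[anc_mask, "category"] = [
            "wgd" if fam_sizes.get(f, 0) >= 2
            else ssd_kind.get(f, "singleton")
            for f in truth.loc[anc_mask, "family"]
        ]

    # anchor tables with similarity scores from true divergences
    def _score(da: float, db: float, mrca_extra: float = 0.0) -> float:
        ks = da + db + mrca_extra
        return 1.0 / (1.0 + ks)

    fam_index: dict[str, dict[int, list[str]]] = {}
    for sp, table in genes_by_species.items():
        d: dict[int, list[str]] = {}
        for row in truth[truth.species == sp].itertuples():
            d.setdefault(row.family, []).append(row.gene_id)
        fam_index[sp] = d
    depth_of = {row.gene_id: row.depth_ks for row in truth.itertuples()}
    depth_of.update({g: cfg.ref_divergence_ks / 2 for g in ref_genes})

    def _within(sp: str) -> list[Anchor]:
        out = []
        for fam, gids in sorted(fam_index[sp].items()):
            for g1, g2 in itertools.combinations(sorted(gids), 2):
                out.append(Anchor(g1, g2,
                                  score=_score(depth_of[g1], depth_of[g2])))
        return out

    anchors_within_a = _within("A")
    anchors_within_b = _within("B") if "B" in genes_by_species else []

    ref_by_fam = {fam_of_ref[g]: g for g in ref_genes}
    anchors_a_ref = []
    for fam, gids in sorted(fam_index["A"].items()):
        rg = ref_by_fam.get(fam)
        if rg is None:
            continue
        for g in sorted(gids):
            anchors_a_ref.append(
                Anchor(g, rg, score=_score(depth_of[g], depth_of[rg]))
            )
    anchors_ab = []
    if "B" in genes_by_species:
        for fam, ga in sorted(fam_index["A"].items()):
            gb = fam_index["B"].get(fam, [])
            for g1 in sorted(ga):
                for g2 in sorted(gb):
                    anchors_ab.append(
                        Anchor(g1, g2,
                               score=_score(depth_of[g1], depth_of[g2]))
                    )

    return WgdSim(
        ref_genes=ref_genes,
        genes_a=genes_by_species["A"],
        genes_b=genes_by_species.get("B", {}),
        cds=cds,
        anchors_a_ref=anchors_a_ref,
        anchors_within_a=anchors_within_a,
        anchors_within_b=anchors_within_b,
        anchors_ab=anchors_ab,
        truth=truth,
        config=cfg,
    )
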