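"""End-to-end orchestration: simulate -> analyse -> score against truth.

A single :class:`RunConfig` carries every tunable; unknown keys are
rejected up front. The global seed fans out to per-stage seeds as
seed + stage index, so any stage can be reproduced in isolation. Every
parameter is echoed into a machine-readable run manifest and identical
configs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dup_classify import classify_duplicates, summarize_classes
from .io_formats import write_fasta, write_tsv
from .ltr_dating import age_profile, date_elements
from .ltr_inventory import FilterThresholds, run_inventory
from .synteny_ks import (
    block_median_ks,
    chain_collinear,
    collapse_tandem_anchors,
    export_dotplot,
    fit_ks_peaks,
    ng86_ks,
    synteny_depth,
)
from .synthetic import (
    DOMAIN_MOTIFS,
    LtrSimConfig,
    WgdSimConfig,
    simulate_ltr_genome,
    simulate_wgd_genomes,
)
from .wgd_topology import (
    build_gene_tree,
    classify_topology,
    consensus_support,
    extract_ortholog_groups,
)

log = logging.getLogger("paleoploid")

_STAGE_OFFSETS = {"ltr_sim": 1, "wgd_sim": 2, "ks_peaks": 3}


@dataclass
class RunConfig:
    """Declarative configuration of a full simulate-and-analyse run."""

    seed: int = 0
    stages: tuple[str, ...] = ("ltr", "wgd")
    rate: float = 2.5e-9
    bin_width_mya: float = 0.5
    min_block: int = 5
    max_rank_gap: int = 25
    max_components: int = 5
    min_peak_points: int = 30
    proximal_window: int = 10
    ltr: dict = field(default_factory=dict)  # LtrSimConfig overrides
    wgd: dict = field(default_factory=dict)  # WgdSimConfig overrides
    thresholds: dict = field(default_factory=dict)  # FilterThresholds kw

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for sub, target in (("ltr", LtrSimConfig), ("wgd", WgdSimConfig),
                            ("thresholds", FilterThresholds)):
            sub_known = {f.name for f in dataclasses.fields(target)}
            bad = set(d.get(sub, {})) - sub_known
            if bad:
                raise ValueError(f"unknown {sub} config keys: {sorted(bad)}")
        if "stages" in d:
            d = {**d, "stages": tuple(d["stages"])}
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the configured stages and write all outputs plus a
    manifest. Returns the manifest dictionary."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    thresholds = FilterThresholds(**config.thresholds)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "stage_seeds": {k: config.seed + v for k, v in
                        _STAGE_OFFSETS.items()},
        "outputs": {},
        "metrics": {},
    }
    metrics: dict[str, float] = {}

    if "ltr" in config.stages:
        ltr_cfg = LtrSimConfig(**{"rate": config.rate, **config.ltr,
                                  "seed": config.seed +
                                  _STAGE_OFFSETS["ltr_sim"]})
        sim = simulate_ltr_genome(ltr_cfg)
        write_fasta(sim.genome, out / "ltr_genome.fasta")
        write_tsv(sim.truth, out / "ltr_truth.tsv")
        candidates = sim.intact_candidates()
        intact, truncated, solos, report, summary = run_inventory(
            sim.genome, candidates, DOMAIN_MOTIFS, thresholds
        )
        log.info("inventory: %d intact, %d truncated, %d solo (%s)",
                 summary.n_intact, summary.n_truncated, summary.n_solo,
                 report)
        inv_rows = [
            {"element_id": e.element_id, "class": e.class_state,
             "seq_id": e.ltr5.seq_id, "start": e.span.start,
             "end": e.span.end, "coverage": e.coverage,
             "identity": e.identity}
            for e in [*intact, *truncated, *solos]
        ]
        write_tsv(pd.DataFrame(inv_rows), out / "ltr_inventory.tsv")
        write_tsv(pd.DataFrame([report]), out / "ltr_filter_report.tsv")
        pairs = {
            e.element_id: (sim.genome[e.ltr5.seq_id].subseq(e.ltr5),
                           sim.genome[e.ltr3.seq_id].subseq(e.ltr3))
            for e in intact
        }
        fams = {e.element_id: e.family for e in intact}
        datings, divergences = date_elements(pairs, r=config.rate,
                                             families=fams)
        write_tsv(
            pd.DataFrame([
                {"element_id": d.element_id, "K": d.K, "r": d.r,
                 "T_years": d.T_years, "T_mya": d.T_mya, "family": d.family}
                for d in datings
            ]),
            out / "ltr_dating.tsv",
        )
        if datings:
            write_tsv(age_profile(datings, config.bin_width_mya),
                      out / "ltr_age_profile.tsv")
        metrics.update(
            score_ltr_against_truth(sim.truth, intact, solos, datings,
                                    summary)
        )

    if "wgd" in config.stages:
        wgd_cfg = WgdSimConfig(**{**config.wgd,
                                  "seed": config.seed +
                                  _STAGE_OFFSETS["wgd_sim"]})
        sim = simulate_wgd_genomes(wgd_cfg)
        anchors_aa = collapse_tandem_anchors(sim.anchors_within_a,
                                             sim.genes_a, sim.genes_a,
                                             window=config.proximal_window)
        blocks_self = chain_collinear(anchors_aa, sim.genes_a,
                                      sim.genes_a,
                                      min_block=config.min_block,
                                      max_rank_gap=config.max_rank_gap)
        ks_by_pair = {}
        for blk in blocks_self:
            for anc in blk.anchors:
                key = (anc.gene_a, anc.gene_b)
                if key not in ks_by_pair:
                    ks_by_pair[key] = ng86_ks(sim.cds[anc.gene_a],
                                              sim.cds[anc.gene_b], pair=key)
        medians = [m for blk in blocks_self
                   if (m := block_median_ks(blk, ks_by_pair)) is not None]
        write_tsv(export_dotplot(blocks_self, sim.genes_a, sim.genes_a,
                                 ks_by_pair), out / "wgd_dotplot_self.tsv")
        write_tsv(pd.DataFrame({"block_median_ks": medians}),
                  out / "wgd_block_medians.tsv")
        peak_fit = None
        if len(medians) >= config.min_peak_points:
            peak_fit = fit_ks_peaks(medians,
                                    max_components=config.max_components,
                                    seed=config.seed +
                                    _STAGE_OFFSETS["ks_peaks"],
                                    min_points=config.min_peak_points)
            write_tsv(
                pd.DataFrame({
                    "component": range(1, peak_fit.n_components + 1),
                    "weight": peak_fit.weights,
                    "mean_log_ks": peak_fit.means_log,
                    "sd_log_ks": peak_fit.sds_log,
                    "peak_ks": peak_fit.peaks_ks,
                }),
                out / "wgd_ks_peaks.tsv",
            )
        blocks_ref = chain_collinear(sim.anchors_a_ref, sim.genes_a,
                                     sim.ref_genes,
                                     min_block=config.min_block,
                                     max_rank_gap=config.max_rank_gap)
        depth = synteny_depth(blocks_ref, sim.ref_genes, query_side="a")
        write_tsv(
            pd.DataFrame(sorted(depth.histogram.items()),
                         columns=["depth", "n_ref_genes"]),
            out / "wgd_depth_histogram.tsv",
        )
        dup_report = classify_duplicates(sim.genes_a, sim.anchors_within_a,
                                         blocks_self, blocks_ref,
                                         proximal_window=config.
                                         proximal_window)
        write_tsv(summarize_classes(dup_report), out / "dup_classes.tsv")
        topo_summary = None
        if sim.genes_b:
            blocks_ab = chain_collinear(
                collapse_tandem_anchors(sim.anchors_ab, sim.genes_a,
                                        sim.genes_b,
                                        window=config.proximal_window),
                sim.genes_a, sim.genes_b,
                min_block=config.min_block,
                max_rank_gap=config.max_rank_gap)
            blocks_bb = chain_collinear(
                collapse_tandem_anchors(sim.anchors_within_b, sim.genes_b,
                                        sim.genes_b,
                                        window=config.proximal_window),
                sim.genes_b, sim.genes_b,
                min_block=config.min_block,
                max_rank_gap=config.max_rank_gap)
            groups = extract_ortholog_groups(blocks_ab, blocks_self,
                                             blocks_bb, sim.genes_a,
                                             sim.genes_b)
            species_of = {g: "A" for g in sim.genes_a}
            species_of.update({g: "B" for g in sim.genes_b})
            calls = []
            for grp in groups:
                tree = build_gene_tree(grp, sim.cds)
                if tree is None:
                    continue
                call = classify_topology(tree, species_of)
                calls.append(dataclasses.replace(call,
                                                 group_id=grp.group_id))
            if calls:
                write_tsv(
                    pd.DataFrame([dataclasses.asdict(c) for c in calls]),
                    out / "wgd_topology_calls.tsv",
                )
                topo_summary = consensus_support(calls)
        metrics.update(
            score_wgd_against_truth(sim.truth, dup_report, depth, peak_fit,
                                    topo_summary,
                                    n_events=len(wgd_cfg.wgd_events))
        )

    metrics_df = pd.DataFrame(sorted(metrics.items()),
                              columns=["metric", "value"])
    write_tsv(metrics_df, out / "score_metrics.tsv")
    manifest["metrics"] = metrics
    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# scoring against simulator truth


def _overlap_match(calls, truth_rows) -> tuple[int, int]:
    """(# calls matching a truth interval, # truth intervals matched)."""
    matched_truth = set()
    matched_calls = 0
    for c in calls:
        hit = False
        for i, row in enumerate(truth_rows):
            if c.ltr5.seq_id == row["seq_id"] and \
                    c.ltr5.start < row["end"] and row["start"] < c.ltr5.end:
                matched_truth.add(i)
                hit = True
        if hit:
            matched_calls += 1
    return matched_calls, len(matched_truth)


def score_ltr_against_truth(truth: pd.DataFrame, intact, solos, datings,
                            summary) -> dict[str, float]:
    """Recall/precision of element classes plus insertion-age RMSE."""
    m: dict[str, float] = {}
    n_true_intact = int((truth.true_class == "intact").sum())
    m["intact_recall"] = (len(intact) / n_true_intact) if n_true_intact \
        else 0.0
    solo_rows = truth[truth.true_class == "solo"][
        ["seq_id", "start", "end"]].to_dict("records")
    ok_calls, ok_truth = _overlap_match(solos, solo_rows)
    m["solo_precision"] = ok_calls / len(solos) if solos else 0.0
    m["solo_recall"] = ok_truth / len(solo_rows) if solo_rows else 0.0
    decoy_rows = truth[truth.true_class.isin(["edge_decoy", "gap_decoy"])][
        ["seq_id", "start", "end"]].to_dict("records")
    bad_calls, _ = _overlap_match(solos, decoy_rows)
    m["decoy_leakage"] = bad_calls / len(decoy_rows) if decoy_rows else 0.0
    ages = truth.set_index("element_id")["implant_age"]
    errs = [(d.T_years - ages[d.element_id]) / 1e6 for d in datings
            if d.element_id in ages.index]
    m["age_rmse_mya"] = float(np.sqrt(np.mean(np.square(errs)))) if errs \
        else float("nan")
    m["solo_intact_ratio"] = summary.solo_intact_ratio
    return m


def score_wgd_against_truth(truth: pd.DataFrame, dup_report, depth,
                            peak_fit, topo_summary,
                            n_events: int) -> dict[str, float]:
    """Duplicate-class accuracy, modal depth and Ks-peak count match."""
    m: dict[str, float] = {}
    truth_a = truth[truth.species == "A"].set_index("gene_id")
    for cls in ("wgd", "td", "pd", "trd", "dispersed"):
        idx = truth_a.index[truth_a.category == cls]
        if len(idx) == 0:
            continue
        correct = sum(1 for g in idx if dup_report.classes.get(g) == cls)
        m[f"dup_{cls}_accuracy"] = correct / len(idx)
    m["depth_modal"] = float(depth.modal_depth)
    m["depth_expected"] = float(2 ** n_events)
    m["depth_match"] = float(depth.modal_depth == 2 ** n_events)
    if peak_fit is not None:
        m["ks_peak_count"] = float(peak_fit.n_components)
        m["ks_peak_count_match"] = float(peak_fit.n_components == n_events)
    if topo_summary is not None:
        m["fraction_shared"] = topo_summary["fraction_shared"]
    return m
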