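"""Shared fixtures: simulated datasets are expensive, so they are built
once per session and reused across test modules."""

from __future__ import annotations

import pytest

from paleoploid.dup_classify import classify_duplicates
from paleoploid.ltr_inventory import run_inventory
from paleoploid.synteny_ks import chain_collinear, collapse_tandem_anchors
from paleoploid.synthetic import (
    DOMAIN_MOTIFS,
    LtrSimConfig,
    WgdSimConfig,
    simulate_ltr_genome,
    simulate_wgd_genomes,
)


@pytest.fixture(scope="session")
def ltr_sim():
    """Default-condition LTR genome: 50 intact, 100 solo, 20 truncated,
    8 edge decoys, 8 gap decoys."""
    return simulate_ltr_genome(LtrSimConfig(seed=7))


@pytest.fixture(scope="session")
def ltr_inventory_result(ltr_sim):
    intact, truncated, solos, report, summary = run_inventory(
        ltr_sim.genome, ltr_sim.intact_candidates(), DOMAIN_MOTIFS
    )
    return {"intact": intact, "truncated": truncated, "solos": solos,
            "report": report, "summary": summary}


@pytest.fixture(scope="session")
def wgd_sim():
    """Two shared WGDs (Ks 0.9 and 0.3, 10% loss) plus small-scale
    duplications, single species vs reference."""
    return simulate_wgd_genomes(
        WgdSimConfig(n_ancestral_genes=360, n_chromosomes=6,
                     wgd_events=((0.9, 0.1), (0.3, 0.1)), seed=11)
    )


@pytest.fixture(scope="session")
def wgd_blocks(wgd_sim):
    sim = wgd_sim
    anchors_aa = collapse_tandem_anchors(sim.anchors_within_a, sim.genes_a,
                                         sim.genes_a)
    self_blocks = chain_collinear(anchors_aa, sim.genes_a, sim.genes_a)
    ref_blocks = chain_collinear(sim.anchors_a_ref, sim.genes_a,
                                 sim.ref_genes)
    return {"self": self_blocks, "ref": ref_blocks}


@pytest.fixture(scope="session")
def dup_report(wgd_sim, wgd_blocks):
    return classify_duplicates(wgd_sim.genes_a, wgd_sim.anchors_within_a,
                               wgd_blocks["self"], wgd_blocks["ref"])


@pytest.fixture(scope="session")
def depth_sim():
    """Double WGD (10% loss) over two long chromosomes against the
    single-copy reference — the depth-ratio study condition."""
    sim = simulate_wgd_genomes(
        WgdSimConfig(n_ancestral_genes=400, n_chromosomes=2,
                     wgd_events=((0.9, 0.1), (0.3, 0.1)),
                     rate_tandem=0.0, rate_proximal=0.0,
                     rate_transposed=0.0, rate_dispersed=0.0, seed=11)
    )
    ref_blocks = chain_collinear(sim.anchors_a_ref, sim.genes_a,
                                 sim.ref_genes)
    return sim, ref_blocks


def _two_species_run(shared: bool, events, speciation_ks: float, seed: int):
    from paleoploid.wgd_topology import (
        build_gene_tree,
        classify_topology,
        consensus_support,
        extract_ortholog_groups,
    )

    sim = simulate_wgd_genomes(
        WgdSimConfig(n_ancestral_genes=120, n_chromosomes=2,
                     wgd_events=events, speciation_ks=speciation_ks,
                     shared_wgd=shared, seed=seed)
    )

    def blocks(anc, ga, gb):
        return chain_collinear(collapse_tandem_anchors(anc, ga, gb), ga, gb)

    groups = extract_ortholog_groups(
        blocks(sim.anchors_ab, sim.genes_a, sim.genes_b),
        blocks(sim.anchors_within_a, sim.genes_a, sim.genes_a),
        blocks(sim.anchors_within_b, sim.genes_b, sim.genes_b),
        sim.genes_a, sim.genes_b,
    )
    species_of = {g: "A" for g in sim.genes_a}
    species_of.update({g: "B" for g in sim.genes_b})
    calls = []
    for grp in groups:
        tree = build_gene_tree(grp, sim.cds)
        if tree is None:
            continue
        calls.append(classify_topology(tree, species_of))
    return consensus_support(calls), len(groups)


@pytest.fixture(scope="session")
def shared_wgd_summary():
    return _two_species_run(True, ((0.9, 0.1), (0.3, 0.1)), 0.15, seed=3)


@pytest.fixture(scope="session")
def independent_wgd_summary():
    return _two_species_run(False, ((0.4, 0.1), (0.15, 0.1)), 0.9, seed=3)
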