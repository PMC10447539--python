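"""Test whether WGDs are shared between two genomes via collinear
ortholog groups and gene-tree topology.

If two rounds of duplication predate the split of species A and B, a
4:4 (or 4:3, one copy lost) collinear gene group yields a tree whose
clades mix the two species — each paralog lineage contains an A and a B
ortholog. If instead the duplications postdate the split, the deepest
split separates all A copies from all B copies. Each group is scored by
neighbour-joining on K2P distances and the fraction of groups whose tree
supports the shared scenario summarises the test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio import Phylo
from Bio.Phylo.BaseTree import Tree
from Bio.Phylo.TreeConstruction import DistanceMatrix, DistanceTreeConstructor

from .ltr_dating import k2p_distance, p_distance
from .synteny_ks import CollinearBlock

__all__ = [
    "OrthologGroup",
    "TopologyCall",
    "extract_ortholog_groups",
    "build_gene_tree",
    "classify_topology",
    "consensus_support",
]

_ALLOWED_PATTERNS = {(4, 4), (4, 3), (3, 4)}


@dataclass(frozen=True)
class OrthologGroup:
    """Copies of one ancestral locus: 4 in one species, 3-4 in the other."""

    group_id: str
    copies_a: tuple[str, ...]
    copies_b: tuple[str, ...]


@dataclass(frozen=True)
class TopologyCall:
    group_id: str
    call: str  # shared | independent | ambiguous
    support: float


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def extract_ortholog_groups(blocks_ab: Sequence[CollinearBlock],
                            blocks_aa: Sequence[CollinearBlock],
                            blocks_bb: Sequence[CollinearBlock],
                            genes_a: Mapping[str, object],
                            genes_b: Mapping[str, object]
                            ) -> list[OrthologGroup]:
    """Cluster genes connected by collinear anchors (between the species
    and within each) and keep clusters matching the 4:4 or 4:3 pattern.
    Clusters with any extra copy are discarded."""
    uf = _UnionFind()
    for blocks in (blocks_ab, blocks_aa, blocks_bb):
        for blk in blocks:
            for anc in blk.anchors:
                uf.union(anc.gene_a, anc.gene_b)
    comps: dict[str, list[str]] = {}
    for gid in list(uf.parent):
        comps.setdefault(uf.find(gid), []).append(gid)
    groups: list[OrthologGroup] = []
    for i, (_root, members) in enumerate(sorted(comps.items())):
        a = tuple(sorted(m for m in members if m in genes_a))
        b = tuple(sorted(m for m in members if m in genes_b))
        if len(a) + len(b) != len(members):
            continue
        if (len(a), len(b)) in _ALLOWED_PATTERNS:
            groups.append(OrthologGroup(group_id=f"og_{len(groups)}",
                                        copies_a=a, copies_b=b))
    return groups


def build_gene_tree(group: OrthologGroup, cds: Mapping[str, str],
                    use_p_distance: bool = False) -> Tree | None:
    """Neighbour-joining tree from pairwise K2P distances over the
    group's coding sequences. Members are taken in lexicographic order so
    the result is deterministic. Returns None (group skipped) when the
    sequences are length-incompatible or any pairwise distance is
    saturated."""
    members = sorted(group.copies_a + group.copies_b)
    if len(members) < 4:
        raise ValueError("need >= 4 members with CDS")
    seqs = {}
    for m in members:
        if m not in cds:
            return None
        seqs[m] = cds[m].upper()
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        return None
    dist_fn = p_distance if use_p_distance else k2p_distance
    matrix = []
    for i, m1 in enumerate(members):
        row = []
        for m2 in members[: i + 1]:
            if m1 == m2:
                row.append(0.0)
                continue
            d = dist_fn((seqs[m1], seqs[m2]))
            if d.saturated:
                return None
            row.append(d.K)
        matrix.append(row)
    dm = DistanceMatrix(names=members, matrix=matrix)
    tree = DistanceTreeConstructor().nj(dm)
    for clade in tree.get_nonterminals():
        clade.name = None  # drop constructor's inner labels
    return tree


def _bipartitions(tree: Tree) -> list[frozenset[str]]:
    """Non-trivial bipartitions (as the leaf set of one side) after
    collapsing internal branches shorter than 1e-9."""
    all_leaves = frozenset(t.name for t in tree.get_terminals())
    n = len(all_leaves)
    sides = []
    for clade in tree.get_nonterminals():
        if clade is tree.root:
            continue
        if clade.branch_length is not None and clade.branch_length < 1e-9:
            continue
        side = frozenset(t.name for t in clade.get_terminals())
        if 2 <= len(side) <= n - 2:
            sides.append(side)
    return sides


def classify_topology(tree: Tree, species_of: Mapping[str, str]
                      ) -> TopologyCall:
    """Call a gene tree shared / independent / ambiguous.

    ``independent``: some bipartition separates all A leaves from all B
    leaves (the deepest split is the speciation, so the duplications are
    lineage-specific). ``shared``: no such split and at least one
    bipartition has both species on both sides (paralog clades mix the
    species). ``ambiguous``: no informative bipartition survives the
    collapse of near-zero branches. Support is the fraction of internal
    bipartitions consistent with the call; the call is invariant to leaf
    order and rooting.
    """
    leaves = [t.name for t in tree.get_terminals()]
    labels = {species_of[l] for l in leaves}
    if len(labels) < 2:
        raise ValueError("gene tree contains a single species")
    set_a = frozenset(l for l in leaves if species_of[l] == "A")
    set_b = frozenset(l for l in leaves if species_of[l] == "B")
    sides = _bipartitions(tree)
    if not sides:
        return TopologyCall(group_id="", call="ambiguous", support=0.0)

    def _pure(side: frozenset[str]) -> bool:
        return side <= set_a or side <= set_b

    species_split = any(s == set_a or s == set_b for s in sides)
    mixed = [s for s in sides
             if not _pure(s) and not _pure(frozenset(leaves) - s)]
    if species_split:
        consistent = sum(
            1 for s in sides
            if _pure(s) or _pure(frozenset(leaves) - s)
        )
        return TopologyCall(group_id="", call="independent",
                            support=consistent / len(sides))
    if mixed:
        return TopologyCall(group_id="", call="shared",
                            support=len(mixed) / len(sides))
    return TopologyCall(group_id="", call="ambiguous", support=0.0)


def consensus_support(calls: Sequence[TopologyCall]
                      ) -> dict[str, float | int]:
    """Fraction of non-ambiguous gene trees supporting a shared WGD
    history, plus the raw counts."""
    n_shared = sum(1 for c in calls if c.call == "shared")
    n_indep = sum(1 for c in calls if c.call == "independent")
    n_amb = sum(1 for c in calls if c.call == "ambiguous")
    if n_shared + n_indep == 0:
        raise ValueError("all gene trees are ambiguous")
    return {
        "n_shared": n_shared,
        "n_independent": n_indep,
        "n_ambiguous": n_amb,
        "fraction_shared": n_shared / (n_shared + n_indep),
    }
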