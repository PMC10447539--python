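# Methods

This note records the models implemented, the defaults and why, what the
synthetic data do and do not emulate, and the numerical choices made
where the design was genuinely open.

## Coordinates and formats

All internal coordinates are 0-based half-open on the forward strand;
the 1-based inclusive conventions of GFF3 and tabular similarity output
are converted at the I/O boundary only. Similarity hits may come from an
external search engine's 12-column tabular output or from the built-in
scanner; both are normalised to the same record type. The built-in
scanner is an exact-seed (k-mer), ungapped X-drop extender — sufficient
for locating substitution-diverged copies of known elements, and not a
general gapped aligner. Ambiguity characters other than N count as
mismatches in every distance computation; N-columns are excluded.

## LTR-retrotransposon inventory

Chained matches (dynamic programming over colinear hits, maximising
total aligned length, inter-hit gaps bounded on both axes) carry a
coverage (union of query intervals over query length) and an
aligned-length-weighted identity. The classification rules:

* **intact** — paired-LTR candidate with all five internal domains
  (GAG, AP, INT, RT, RH) detected at coverage and identity >0.30.
  Comparisons are strict where the rule is quoted as ">30%".
* **truncated** — genome locus matching a full-length exemplar at
  coverage >0.80 and identity >0.60; loci overlapping intact elements
  are excluded (precedence intact > truncated); overlapping calls merge.
* **solo** — chained matches of intact elements' LTR sequences, after
  removing candidates inside intact elements, filtered a→d:
  (a) ≥1 bp overlap with a truncated element; (b) <5,000 bp from either
  scaffold end; (c) coverage or identity below 0.70; (d) <500 bp from an
  N-run. The first failing rule is recorded; the filters are
  independent, so order affects only the attribution in the report.

Rule (c) is applied as *both coverage ≥0.7 and identity ≥0.7 are
required to survive*. The literal reading — reject only when both fall
short — would admit hits that are essentially random on one axis; it
remains available as `rule_c_mode="literal_and"`. Coverage in rule (c)
is of the exemplar LTR (query side).

## Insertion dating

LTR pairs are aligned globally with affine gaps (match +2, mismatch −3,
open −5, extend −2); gap and ambiguous columns are dropped pairwise
(the behaviour of the classic distance utilities), and the Kimura
2-parameter distance K = ½ ln 1/(1−2P−Q) + ¼ ln 1/(1−2Q) is computed
from transition/transversion proportions. T = K/(2r): the divergence is
split across both LTR copies, each accumulating substitutions at rate r
after insertion. r defaults to 2.5×10⁻⁹ site⁻¹ yr⁻¹ but is an explicit,
logged parameter — it is species-specific. Saturated pairs
(1−2P−Q ≤ 0 or 1−2Q ≤ 0) are flagged and excluded from age summaries
rather than capped, since capping would bias the modal (burst) age.
A raw p-distance is available behind a flag for sensitivity analyses.
Dating operates on the LTR sequences themselves, not on flanking
sequence.

## Collinearity, Ks and WGD peaks

Anchors (homologous gene pairs) are chained per chromosome pair and
orientation by a score-maximising dynamic programme (MCScanX-style):
score = Σ anchor scores − 0.01·(rank gaps), rank gaps ≤ 25 on both axes,
blocks of ≥5 anchors, each anchor in at most one block, chains peeled
greedily by score. Before chaining, homologs within 10 ranks on the same
chromosome (tandem/proximal arrays) are collapsed to the member with the
strongest external anchor; without this, stacked copy anchors either
form spurious near-diagonal self-blocks or displace their parents inside
genuine blocks.

Ka/Ks uses Nei–Gojobori (1986): per-codon synonymous site fractions
(changes to stop codons count as nonsynonymous), observed differences
averaged over all minimal mutational pathways that avoid stop codons
(with a fall-back to all pathways when every one is blocked), and the
Jukes–Cantor correction Ks = −¾ ln(1 − 4pS/3). NG86 was chosen over
likelihood estimators because it is exactly verifiable by hand and by
exhaustive path enumeration on short codon pairs; at high divergence
(Ks ≳ 0.9) it over-corrects by roughly 10–15% under the synonymous-only
substitution process used in simulation, which shifts peak *locations*
upward slightly but not peak *counts*.

Each block is summarised by the median of its unflagged pair Ks values
(even count → midpoint). Peak counting fits Gaussian mixtures to ln Ks
for 1..5 components (k-means initialisation, 20 restarts, fixed seed)
and selects the count by minimum BIC; medians outside (0.005, 3.0) are
discarded first to remove allelic noise and saturation. At least 30
medians are required.

Synteny depth: a block covers every reference gene whose rank lies in
the block's reference-side rank span; the modal depth over covered genes
(ties toward the smaller depth — the conservative polyploidy call) is
the query side of the "modal:1" ratio.

## Shared-WGD gene-tree test

4:4 and 4:3 (one copy lost) collinear groups are connected components of
the anchor graph restricted to blocks (between species and within each);
components with any extra copy are discarded. Trees are neighbour
joining on K2P distances over the group's coding sequences
(deterministic, lexicographic member order); groups with incompatible
CDS lengths or saturated distances are skipped with a reason. A tree is
*independent* when some bipartition separates all A-leaves from all
B-leaves, *shared* when no such split exists but at least one
bipartition has both species on both sides, *ambiguous* otherwise;
internal branches <10⁻⁹ collapse first. Support is the fraction of
internal bipartitions consistent with the call — a per-tree quartet-like
score standing in for a full quartet-based consensus machinery, which
would add nothing at this scale. The summary statistic is
shared / (shared + independent), with ambiguous trees reported
separately.

## Duplicate classification

Priority cascade per gene: WGD (participates in a self-collinear block
anchor) > tandem (homolog at rank distance 1, same chromosome) >
proximal (distance 2–10) > transposed (its pair partner is collinear
with the outgroup reference while the gene itself is not; the
novel-locus copy is the transposed gene) > dispersed; genes without
homologs are singletons. The proximal window (10) and the cascade order
follow the convention popularised by DupGen_finder. Transposed detection
requires reference blocks; without them those genes report as dispersed
and the summary says so.

## Synthetic data: what it emulates and what it does not

The LTR generator implants, on several scaffolds of background sequence
with a configurable GC content: intact elements (5′LTR + internal region
+ 3′LTR, the LTRs identical at insertion and then mutated independently
with per-site probability r·age, transition:transversion 2:1 by default
so K2P genuinely exceeds the raw distance), solo-LTRs, truncated copies
(a contiguous 83–91% prefix of the full element, so they pass the >80%
coverage rule), and solo-like decoys placed <5 kb from scaffold ends or
<500 bp from implanted N-runs. Internal domains are fixed 30-bp sentinel
motifs rather than real protein profiles: the classification logic, not
profile search, is what the package tests. Ordinary implants keep clear
of edges and gaps so that only decoys trip filters (b) and (d). Not
emulated: element nesting, indel evolution inside LTRs, target-site
duplications — so recovery rates here are upper bounds for real genomes.

The WGD generator evolves a gene complement along an explicit history:
branch lengths in Ks/2 units, each WGD duplicating every chromosome and
deleting each new gene copy with the event's loss probability, an
optional speciation before (shared) or after (independent) the WGDs, and
injected tandem/proximal/transposed duplicates (young, Ks 0.02–0.12 from
their parents) plus dispersed pairs from novel families. Coding
sequences evolve by synonymous-only substitution: Poisson(Ks·S) events,
each picking a random synonymous single-base change of the current
sequence — never a stop, never an amino-acid change — so the NG86
round-trip recovers the target within ~10% at Ks ≤ 0.5. Truth categories
for small-scale duplicates are assigned from *realised* final rank
distances (insertions shift neighbours), because the categories are
positional by definition. Not emulated: nonsynonymous evolution and
selection, inversions inside blocks, chromosome fusions/fissions,
gene conversion.

## Problem sizes and defaults

Default study conditions: 50 intact / 100 solo / 20 truncated elements
with 8 + 8 decoys on ~400 kb of background across 4 scaffolds; element
ages uniform on 1–8 Myr. WGD analyses use 300–500 ancestral genes on
2–6 chromosomes with events at Ks 0.9 and 0.3 and 10% per-copy loss —
large enough that recovery rates are stable across seeds, small enough
that the whole suite runs in well under a minute. The synteny-depth
condition uses two long chromosomes (200+ genes each); on many short
chromosomes block-edge effects lower the fraction of reference genes at
full depth even though the modal depth is unchanged.

## Reproducibility

Every generator and fit takes an explicit seed; the pipeline fans a
single global seed out as seed + stage index so stages can be re-run in
isolation. Identical configuration yields byte-identical outputs, and
the run manifest records the package version, every parameter, all
stage seeds and SHA-256 checksums of each output file.

## Known limitations

* The built-in scanner misses copies diverged far beyond the seed length
  (~30%+); for real genomes, feed external tabular hits instead.
* NG86's upward bias at high Ks shifts old-peak locations; peak counts
  and the ordering of peaks are unaffected.
* The shared/independent tree call assumes duplication events are
  either all-shared or all-independent per group; mixed histories map
  to whichever signal dominates the bipartitions.
* Solo-LTR dating is out of scope (solo elements have no partner to
  align against), as are structural de-novo element discovery and
  profile-HMM domain search.
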