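# paleoploid

Genome-evolution analyses for plant genomes shaped by transposable
elements and polyploidy: an LTR-retrotransposon inventory (intact /
truncated / solo-LTR) with insertion-time dating, and whole-genome
duplication (WGD) detection from synonymous-substitution (Ks) peaks,
synteny-depth ratios and collinear gene trees — plus a synthetic-genome
generator with known ground truth, so every stage is testable end to end
without any external dataset.

It is aimed at comparative genomicists who want the standard
desk-checkable machinery behind statements like *"the solo:intact LTR
ratio is 3.8"*, *"both element families burst ~4 Mya"*, *"the Ks
distribution shows two peaks"*, *"the synteny depth ratio is 4:1"* or
*"84% of collinear gene trees support shared WGDs"* in a reusable,
tested form.

## The models at the core

**LTR dating.** The two long terminal repeats of a retrotransposon are
identical at insertion and then diverge neutrally and independently.
With the Kimura 2-parameter distance *K* between the aligned LTRs and a
substitution rate *r* (default 2.5×10⁻⁹ site⁻¹ yr⁻¹),

> *T* = *K* / (2 *r*),

where *K* = ½ ln 1/(1−2*P*−*Q*) + ¼ ln 1/(1−2*Q*) from the transition
(*P*) and transversion (*Q*) proportions.

**Solo-LTR inventory.** Candidates with paired LTRs are *intact* when
all five internal domains (GAG, AP, INT, RT, RH) are detected with
coverage and identity >30%; genome loci matching a full-length exemplar
at >80% coverage and >60% identity are *truncated*; matches of intact
elements' LTRs are solo-LTR candidates, filtered by four rules —
(a) overlap with a truncated element, (b) <5 kb from a scaffold edge,
(c) coverage or identity <0.7, (d) <500 bp from an assembly gap. The
solo:intact ratio measures DNA removal by unequal recombination.

**WGD detection.** Homologous anchors are chained into collinear blocks
by dynamic programming; each block is summarised by its median
Nei–Gojobori (1986) Ks; Gaussian mixtures on ln Ks (component count by
BIC) count duplication events; the modal number of query blocks covering
each reference gene gives the *k*:1 synteny-depth ratio; and 4:4 / 4:3
collinear ortholog groups between two genomes yield neighbour-joining
gene trees whose topology (species-split vs mixed paralog clades)
classifies the WGDs as lineage-specific or shared.

**Duplicate classes.** Each duplicated gene falls into one of five
categories by a priority cascade: WGD (in a self-collinear block), then
tandem (rank distance 1), proximal (2–10), transposed (partner collinear
with an outgroup reference while the gene is not), else dispersed.

## Worked example

```bash
paleoploid simulate ltr --seed 7 --outdir demo
paleoploid ltr-scan --genome demo/genome.fasta \
    --candidates demo/candidates.gff3 --out-prefix demo/scan
paleoploid ltr-date --elements demo/candidates.gff3 \
    --genome demo/genome.fasta --rate 2.5e-9 --out-prefix demo/date
```

prints

```
50 intact, 20 truncated, 100 solo; solo:intact = 2.00
dated 50 elements (0 saturated)
```

i.e. all 50 implanted intact elements were recovered (five domains each),
all 100 genuine solo-LTRs survived the four filters while every edge and
gap decoy was rejected, and the solo:intact ratio for this synthetic
genome is 100/50 = 2.00. `demo/date.dating.tsv` then lists each
element's *P*, *Q*, *K* and age; an element with *K* = 0.02 dates to
4.0 Mya at the default rate.

The full simulate→analyse→score loop, including the WGD side (Ks peaks,
depth ratio, duplicate classes, shared-WGD test):

```bash
paleoploid run --seed 2 --outdir demo_run
```

which ends by printing truth-recovery metrics such as
`"intact_recall": 1.0`, `"depth_modal": 4.0` and per-class duplicate
accuracies.

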