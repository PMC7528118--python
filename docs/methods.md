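# Methods

## Setting and data model

The package analyses a diploid SNP panel called against a transcriptome
reference derived from one of two progenitor species. The panel holds, per
locus and sample, an unordered pair of alleles (or a missing call) and,
optionally, per-allele read depths. Samples carry roles: exactly one
`progenitor_a` (the reference-species accession, "A"), exactly one
`progenitor_b` ("B"), optional outgroup species, and cultivars labelled
with a growth habit (trailing, mounded, mounding/trailing, upright). All
coordinates are 1-based inclusive (VCF/GFF convention); multiallelic
records are kept as single loci with the record's alt order; strand is
ignored.

## Genotype re-calling

Variant callers under-call heterozygotes at modest transcriptome coverage,
so genotypes are re-defined from allele read fractions. With total depth
*n*, reference fraction *r* and best-alternative fraction *a* (the single
most supported alternative allele; ties broken by alt order):

* missing if *n* < 5 (``min_depth``);
* hom-ref if *r* ≥ 0.80;
* else hom-alt if *a* > 0.80;
* else het (ref/alt) if *r* > 0.3 and *a* > 0.3 and *r* + *a* ≥ 0.8;
* else missing.

The mixed strict/non-strict inequalities are deliberate and preserved
exactly; an exhaustive test compares the implementation against a literal
re-implementation of the three rules for every depth vector with total
≤ 30 over up to three alleles. Two consequences worth knowing:

* the fractions are taken over reads of **all** observed alleles of the
  locus (the alternative — ref+alt1 only — is not used);
* a heterozygote between two *alternative* alleles is unreachable: such
  sites come back missing. Re-calling therefore imposes an ascertainment
  towards ref-containing genotypes, which depresses the post-recall
  heterozygosity of the non-reference progenitor.

Two locus filters define the working datasets: the *entire* dataset keeps
loci where at least one cultivar has a non-missing call different from
progenitor A's (loci carrying no ancestry information are dropped), and
the *no-missing* subset keeps loci called in every sample.

## The 12-category origin classification

Let *A* and *B* be the progenitor allele sets at a locus. A cultivar
genotype {x, y} maps to:

| # | label | fires when |
|---|-------|------------|
| 1 | AX_HOM | genotype fully within *A* (hom) |
| 2 | INT_HOM | fully within *B* |
| 3 | SHARED_HOM | hom for an allele in *A* ∩ *B* |
| 4 | AX_INT_HET | one allele only in *A*, one only in *B* |
| 5 | SHARED_HET | het equal to a common heterozygous progenitor genotype |
| 6 | AX_OUT_HET | one allele only in *A*, one in neither |
| 7 | SHARED_OUT_HET | one allele in *A* ∩ *B*, one in neither |
| 8 | INT_OUT_HET | one allele only in *B*, one in neither |
| 9 | OUT_HOM | hom for an allele in neither |
| 10 | OUT_OUT_HET | two distinct alleles, both in neither |
| 11 | UNKNOWN | a progenitor call missing (or unusable, see below) |
| 12 | MISSING | the cultivar call missing |

The out categories are exactly {6…10}; category 7 — the progenitors'
common allele paired with a novel one — is the diagnostic class for
third-species introgression on a shared background.

Two modes handle heterozygous progenitor calls. In **strict** mode (the
default, matching the homozygous-parents assumption of the direct
approach) a heterozygous progenitor whose allele set differs from the
other progenitor's renders the locus UNKNOWN. In **containment** mode
genotypes match by set containment: fully inside *A* ∩ *B* → shared,
fully inside one set → that progenitor (the "HOM" labels then read
"fully derived from that progenitor"), otherwise per-copy assignment.
Both modes are total functions; an exhaustive enumeration over all
genotype combinations with ≤ 4 alleles verifies totality, the category-7
characterisation and the out-set identity.

A missing cultivar call is reported as MISSING whenever both progenitor
calls are present, including at strict-mode-unusable loci; UNKNOWN is
reserved for loci whose progenitor information is absent or unusable.

## Ancestry models

All three models report five proportions (p_ax, p_int, p_shared, p_out,
p_unknown) over one common denominator — two allele copies per panel
locus — so they always sum to 1.

**Approach 1 (allele counting).** Each classified locus contributes two
copies: hom categories give both copies to their origin; het categories
one copy each (so a het A/B locus carries 50 % of the A alleles of a
hom-A locus, and a het out genotype 50 % of the out alleles of a hom out
genotype). The headline numbers follow the reporting convention of
hybrid-dissection studies and are exposed as extras: `p_ax_polymorphic`
and `p_int_polymorphic` are computed over progenitor-polymorphic
classified loci only (shared loci carry no A-vs-B information), and
`p_out_overall` over all classified loci. These convention-specific
numbers use different denominators and are not expected to sum to 1;
the five primary fields are.

**Pure parents.** Boundary model assuming idealised fully homozygous,
fully polymorphic parents: A is "0/0", B is "1/1". Each cultivar copy is
scored by its VCF allele index — reference → A, first alternative → B,
anything else → out — without ever reading the observed progenitor
genotypes (the estimate is invariant to them).

**Exact parents.** Boundary model assuming the sampled progenitor
genotypes are exactly ancestral: each copy is assigned by containment in
the observed sets (*A* only → A, *B* only → B, both → shared, neither →
out); loci with a missing progenitor or cultivar call count as unknown.

Pure parents inflates the A share (shared alleles equal the reference)
while exact parents moves shared alleles into their own class, so the two
bracket the direct estimate; on simulated panels the approach-1
progenitor-A percentage falls inside the interval for every tested
cultivar, and with homozygous disjoint progenitors all three models
coincide with the simulated truth to within sampling noise.

## Diversity statistics

Heterozygosity is het calls / non-missing calls of the sample ("total
SNPs" is ambiguous under missing data; dividing by non-missing calls
avoids deflating low-coverage samples — an `all_loci` denominator is
available). Pairwise SNP counts use the pairwise-complete convention
(both members called) and count any inequality of unordered allele pairs;
a lenient mode counting only disjoint allele sets is provided.

## Map projection

Transcripts are placed on the genetic map at every marker whose scaffold
position falls inside one of the transcript's genomic anchors. Placements
on one linkage group are merged by single-linkage clustering at a 1 cM
radius (merged position = unweighted mean cM); more distant placements
are all retained — the few transcripts anchored >20 cM apart keep both
locations. Per-SNP similarity rates (1.0 for categories 1 and 3, 0.5 for
4, 5, 6 and 7, 0.0 for 2, 8, 9 and 10; 11 and 12 excluded) are averaged
per transcript and pooled per placed position with per-SNP weighting.
Map gaps wider than `gap_cm` (default 5 cM) between consecutive markers
are masked from tracks: sparse-marker low-recombination regions would
otherwise be summarised by a handful of unrepresentative SNPs. The
masking rule is an explicit, configurable reconstruction of the
"not plotted" convention; no threshold is canonical.

## Habit-contrast enrichment

Two locus predicates are exposed because the field's phrasing covers
both: *between-group polymorphic* (some cross-group pair of non-missing
calls differs — the default subset) and *fixed differences* (each group
internally monomorphic and fully called, the two shared genotypes
differing). Enrichment compares each category's proportion inside the
subset with its proportion in the whole (entire-dataset) panel, per
cultivar and as group means; ratios are descriptive, matching the
source analysis — an optional permutation-of-group-labels p-value is
provided as an extra beyond it. Introgression tracks count out-category
and category-7 SNPs per placed map position, per cultivar and pooled per
group (summed member counts), restricted to between-group-polymorphic
loci. Transcript-level candidate lists require category-7 SNPs in every
group-A cultivar and none in any group-B cultivar.

## Synthetic panels

The simulator draws, per locus: whether the progenitors share a common
homozygous allele (`shared_allele_prob`, default 0.35, matching the
roughly one-third shared-allele fraction such panels show); otherwise
disjoint primary alleles with per-locus heterozygosity `het_ax` (default
0.08 — the reference progenitor is nearly homozygous) and `het_int`
(default 0.593, the high heterozygosity of the second progenitor). Half
of progenitor-B het sites pair the B allele with the reference allele,
the rest with a third nucleotide, mirroring how transcriptome SNPs
against a progenitor-A reference are constituted. Each cultivar allele
copy draws its origin independently from (p_ax, p_int, p_out); defaults
give three trailing cultivars (p_ax 0.45–0.50, p_out 0.07–0.10) and
three upright cultivars (p_ax 0.62–0.68, p_out 0.03–0.04). Inside
configured hotspot map intervals, p_out is multiplied by
`out_multiplier` (capped at 0.9) for cultivars of the target habit only.
Loci where the progenitors exhaust all four nucleotides cannot express a
novel allele; such out draws fall back to a progenitor origin (≲ 0.2 %
of copies at default rates). Ground truth records every copy's origin
(ax / int / shared / out), the per-locus progenitor-polymorphism flag
and hotspot membership.

Read depths are negative-binomial per cell (`depth_mean` 20,
`depth_dispersion` 2 — overdispersed like RNA-seq coverage), split
between the two true alleles by a symmetric binomial, with per-read
uniform miscalls at `error_rate` 0.005. Map geometry is deliberately
simple: each transcript sits on its own scaffold with one map marker
inside it, scaffolds spread uniformly in cM over 7 linkage groups.

What the generator does *not* emulate: linkage disequilibrium and
recombination-block structure (loci are independent given the hotspot
pattern), expression-level coverage variation between genes, allele-
specific expression, and reference-alignment bias. Consequently the
simulated cultivars' heterozygosity exceeds the second progenitor's —
real cultivars carry long homozygous blocks that independent loci cannot
produce — so passing recovery tests demonstrate correctness of the
estimators under the stated sampling model, not realism of genome-scale
haplotype structure.

## Numerical and validation choices

Everything is deterministic: a single seed drives one named generator,
ties break by VCF allele order, outputs are written with fixed float
formatting, and repeated runs are byte-identical. Validation problem
sizes were chosen to make sampling noise negligible relative to the
tolerances: ancestry recovery uses ~50,000 loci (binomial SE ≈ 0.002
per proportion against a 0.01 tolerance), heterozygosity recovery
~10,000 loci against a 99 % binomial interval, bracketing 20 cultivars
across five random configurations at ~15,000 loci, hotspot recovery 20
seeds at ~10,000 loci with five planted intervals and a 10× out-rate
multiplier, and the null enrichment control 100 seeds at ~10,000 loci.
The null control and hotspot recovery run on the informative ("entire")
dataset, the locus set the enrichment stage consumes in the pipeline;
on the raw simulated panel the monomorphic shared loci would deflate
the subset denominator and bias all ratios upward by a constant factor.

## Known limitations

* Re-calling cannot produce alt/alt heterozygotes, so panels dominated
  by non-reference variation lose heterozygosity under re-calling; use
  the caller GTs (`recall: false`) when that matters.
* Strict-mode classification discards heterozygous-progenitor loci as
  UNKNOWN; with a highly heterozygous progenitor this is a large
  fraction of the panel. The containment mode and the exact-parents
  model retain them.
* The exact numbering of categories 1–6 and 8–12 follows the published
  constraints that pin category 7 and the out set {6…10}; a differently
  numbered external table would need remapping.
* cM positions are genetic, not physical; tracks cannot be interpreted
  as base-pair densities.
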