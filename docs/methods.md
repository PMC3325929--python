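# Methods

This note documents the models, estimators and design choices behind
`mtpop`, in the spirit of the methods documentation of mature population
genetics packages.

## Coordinate frame and reference model

All coordinates are 1-based, inclusive, in rCRS numbering (16,569 bp) —
the frame in which mtDNA variants are universally reported.  The bundled
annotation carries the standard heavy-strand protein gene starts
(ND1 3307, ND2 4470, COI 5904, COII 7586, ATP8 8366, ATP6 8527,
COIII 9207, ND3 10059, ND4L 10470, ND4 10760, ND5 12337, CYTB 14747),
ND6 on the light strand (14149–14673), the rRNAs (12S 648–1601,
16S 1671–3229), and the control region wrapping the origin
(16024–576, with HVRI 16024–16383 and HVRII 57–372 as sub-features).
These constants are verifiable in-repo: the test suite checks that they
reproduce twelve independently published protein positions of the bundled
cohort's coding variants.

The full rCRS base string is deliberately not bundled; the package is
buildable and testable fully offline.  A sparse `known_bases` map carries
the reference alleles at every position used by the bundled datasets.
Operations that need bases (effect annotation, sequence realisation,
variant calling) require an explicit sequence and raise
`MissingSequenceError` rather than silently returning NA.

Genes with polyadenylation-completed stop codons are flagged
`incomplete_stop`; a substitution falling in the incomplete terminal
codon fragment is annotated `not_applicable` rather than modelling the
poly-A completion.

### Overlapping genes and strand

In the ATP8/ATP6 and ND4L/ND4 overlaps (and the single shared base
ATP6/COIII 9207), `locate_all_features` returns every containing feature
with the conventionally reported reading frame first (ATP6, ND4).  ND6
codon arithmetic runs on the reverse-complement frame, counting from the
gene's 3'-most heavy-strand coordinate.

### Back-mutation notation

A profile or motif entry `4769!` is stored as an explicit assertion of
the reference-state allele, not as mere absence of a variant.  This
matters because one bundled sub-haplotype (B4a1a1a3) is *defined* partly
by the 4769 reversion: a classifier that ignored reference-state
assertions could not separate it from its siblings.  In the site
spectrum, back-mutation assertions are not counted as derived carriers —
at 4769 the carriers of the non-reference allele G are counted (13/20 in
the bundled cohort), matching the published counting convention.

## Haplotype classification

A motif is a set of requirements: derived alleles, indels, and
reference-state assertions checked actively (the profile must *not*
carry a derived allele there).  Among fully satisfied motifs the most
specific wins (most derived requirements, then most total requirements);
residual ties break lexicographically and are flagged ambiguous.  The
acceptance threshold for partial matches defaults to 1.0 (exact match),
because published haplotype assignments are exact motif matches; a
`min_score` parameter relaxes it.  Classification is invariant under
addition or removal of variants at positions no motif references, and a
motif's own induced profile always classifies back to it — both are
property-tested.

The bundled motif table includes the four B4a1a1 sub-haplotype rows plus
a Polynesian-motif entry.  The motif is variously described with three or
four control-region substitutions alongside the 9-bp deletion; the
bundled entry includes all four (16189C, 16217C, 16247G, 16261T) and the
deletion, and the config file documents the discrepancy.

## Diversity statistics

Haplotype diversity uses Nei's unbiased estimator
h = n(1 − Σ pᵢ²)/(n − 1), the convention of the standard DNA
polymorphism software; the maximum-likelihood 1 − Σ pᵢ² is available via
`unbiased=False`.  Haplotype identity is sequence identity of the full
variant set (indels included; back-mutation assertions change no base and
are ignored).

Nucleotide diversity is π = Σ_{i<j} d_ij / C(n,2) / L_eff, where d_ij
counts differing substitution sites and L_eff excludes every position
involved in an indel in *any* sample (complete-deletion convention).
Because the Polynesian 9-bp deletion is fixed in cohorts like the bundled
one, its exclusion does not perturb within-cohort π.  π computed from
profiles is tested equal to a brute-force all-pairs Hamming computation
over the realised sequences.

## TN93 distances and neighbour joining

The Tamura–Nei distance separates purine transitions (P1), pyrimidine
transitions (P2) and transversions (Q) with unequal base frequencies:

d = −(2g_A g_G/g_R)·ln(1 − g_R P1/(2 g_A g_G) − Q/(2 g_R))
  − (2g_C g_T/g_Y)·ln(1 − g_Y P2/(2 g_C g_T) − Q/(2 g_Y))
  − 2(g_R g_Y − g_A g_G g_Y/g_R − g_C g_T g_R/g_Y)·ln(1 − Q/(2 g_R g_Y))

Base frequencies are pooled over the two sequences of each pair
(`global_freqs=True` switches to alignment-wide frequencies; the choice
is exposed because distance tools differ and the convention is often
left unstated).  Sites with non-ACGT codes in either sequence are ignored
pairwise.  A non-positive logarithm argument marks the pair *saturated*
(distance +inf) instead of raising; saturated matrices are rejected by
tree building with an explicit message.  With equal base frequencies and
P1 = P2 the formula reduces to the Kimura two-parameter distance — this
closed-form limit is a test oracle.

Neighbour joining minimises the standard Q criterion.  Two numerical
choices make runs exactly reproducible: the Q matrix is evaluated on the
upper triangle only (floating-point subtraction order otherwise makes
Q(i,j) and Q(j,i) differ in the last ulp), and ties break on the lowest
(i, j) index pair.  Negative branch lengths are clamped to zero with the
total deficit logged.  NJ consistency on additive matrices is tested by
exact topology-and-length recovery from randomly generated 5- and 8-leaf
trees, and topologies are cross-checked against an independent
neighbour-joining implementation (scikit-bio) on random matrices.

Bootstrap support resamples alignment columns with replacement (default
500 replicates, the conventional figure); supports are the percentage of
replicate NJ trees containing each bipartition of the *full-data* tree
("consensus" here means supports mapped onto the full-data topology, not
a majority-rule consensus — the phrase is ambiguous in the field and this
is the self-consistent reading).  A degenerate alignment with no variable
sites yields supports defined as 100 with a warning.  The examples and
tests use smaller alignments and replicate counts than the 500-replicate
default, which is the package's choice of desk-scale problem sizes.

## Frequency tables and novelty screen

Frequency rows are keyed by labels of the form `<major><pos><rare>`
(e.g. `C7028T`): the counted allele is the label's final base, and the
frequency is carriers of that allele divided by group size, so
frequency × n is always an integer carrier count.  This "rare allele
versus rCRS" convention has a twist worth stating: at 4769 the rCRS
itself carries a rare allele (A), so the counted rare allele *is* the
reference state and carriers are samples with no derived variant there
(7/20 = 0.35 in the bundled cohort).  Auto-derived rows (when no queries
are given) orient toward the non-reference allele.

The novelty screen compares observed variants against a local catalog
snapshot (TSV of position, change, source) — deliberately not a live
database query, for reproducibility.  A novel-variant count is therefore
a function of the supplied snapshot, and the report shrinks monotonically
as the catalog grows (property-tested).

## Simulator

The simulator emulates the founder-effect regime: a single founder
haplotype (optionally a motif's induced variant set), n independent
lineages (star genealogy), and Poisson(μ·L·G) substitutions per lineage
placed uniformly without repeated positions, each to a uniformly chosen
different base.  Mutations landing on a founder site can revert it —
true back mutation.  Expected pairwise difference between lineages is
≈ 2μLG, and regressing observed mean pairwise differences on the rate
recovers a slope of 2LG within 20% at n = 100 (tested).  A serial-founder
mode routes lineages through scheduled bottlenecks to create shared
internal branches.  Configurations whose expected load exceeds half the
genome are refused as saturated.

Default study conditions mirror the bundled cohort's regime: 20 lineages
on a 16,569-bp genome with μLG = 1.5, giving ≈ 3 expected pairwise
differences and π ≈ 1.8×10⁻⁴; the high-diversity comparison regime uses
μLG = 14 (≈ 28 differences, π ≈ 1.7×10⁻³).  Both are fixed analytically
from the target mean pairwise differences, not fitted.

What the simulator does *not* model: coalescent genealogies with shared
drift (beyond the optional serial-founder mode), rate heterogeneity
among sites, transition/transversion bias, heteroplasmy, and the
16189 length-heteroplasmy artefacts of real control-region data.  Tests
passing on simulated cohorts therefore validate the estimators and
plumbing under idealised neutral star-like ancestry, not the full
complexity of real mtDNA alignments.

## Pipeline

`run_all` chains call → classify → diversity → tree → freqs → novel.
Each output table begins with a `# mtpop <version> config=<hash>` header;
the hash covers every analytic parameter (not the output path), so
identical analyses into different directories produce byte-identical
tables.  Stage failures raise a stage-named error with a distinct exit
code, and partially written outputs are renamed `.partial`.  The tree
stage requires realisable sequences; with profile-only input and a
sequence-less reference (e.g. the bundled cohort) it is skipped and the
skip is recorded in the run report.  The bundled rCRS motif table is
applied only when the reference has rCRS length; shorter synthetic
references skip classification unless a custom motif table is supplied.

## Known limitations

* The bundled cohort covers the published 23-position coding/HVRII panel
  only; HVRI singleton placements were never published per sample, so the
  full-genome haplotype partition (11 classes) and π (1.8×10⁻⁴) are
  reproduced in regime by simulation rather than cell-by-cell.
* Variant calling assumes sequences are already aligned to the reference
  frame; no pairwise aligner is included.
* No variance or confidence intervals for h and π, and no neutrality
  tests.
* Effect annotation ignores the incomplete terminal codon rather than
  modelling polyadenylation, and does not annotate tRNA structure.
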