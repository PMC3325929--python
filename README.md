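# mtpop

Population analysis of complete human mitochondrial genomes: variant
profiling against the revised Cambridge Reference Sequence (rCRS),
motif-based haplotype classification, diversity statistics, distance-based
phylogenies, cross-population variant frequency tables, and a
founder-effect cohort simulator.

The package is written for population geneticists working with small mtDNA
cohorts — in particular recently founded island populations such as
Polynesian groups, whose maternal lineages descend from few founders and
whose genomes therefore show many *fixed* haplogroup-defining variants,
few *shared* sub-clade variants, and a handful of *singletons*.

## What it computes

Given full-length mtDNA sequences aligned to the rCRS frame (or pre-called
variant profiles), `mtpop` provides:

* **Variant profiles** — every difference from the rCRS in 1-based rCRS
  coordinates, with the standard label dialects (`m.1806T>C`, `3909T`,
  `m.16295C insA`, `8281-8289d`, and the phylotree back-mutation notation
  `4769!` asserting the reference-state allele on a derived background).
* **Coding-effect annotation** — gene lookup from the bundled rCRS gene
  map, codon index `⌊(pos − start)/3⌋ + 1`, and synonymous /
  non-synonymous calls under the vertebrate mitochondrial code.
* **Haplotype motif classification** — named motifs are sets of required
  states (derived alleles, indels, and *active* reference-state
  assertions); a bundled table carries the B4a1a1 sub-haplotypes
  (B4a1a1c, B4a1a1a, B4a1a1a3, B4a1a1a5) and the Polynesian motif
  (9-bp deletion + 16189C, 16217C, 16247G, 16261T).
* **Diversity statistics** — Nei's unbiased haplotype diversity
  h = n(1 − Σ pᵢ²)/(n − 1) over identical-sequence classes, and
  nucleotide diversity π = Σ_{i<j} d_ij / C(n,2) / L_eff with
  complete-deletion handling of indel columns.
* **Phylogenies** — Tamura–Nei (TN93) pairwise distances (purine
  transitions P1, pyrimidine transitions P2, transversions Q, unequal base
  frequencies), neighbour joining with deterministic tie-breaking, and
  site-resampling bootstrap support mapped onto the full-data tree;
  newick output.
* **Population comparison** — per-gene rare-allele frequency tables
  across labelled groups (`C7028T` style labels, frequency = carriers of
  the named allele / group size) and a novelty screen against a local
  known-variant catalog snapshot.
* **Simulation** — star-genealogy founder cohorts with
  Poisson(μ·L·G) private mutations per lineage and full truth labels, so
  every stage of the pipeline is testable without any download.

A bundled dataset (`mtpop.datasets`) reconstructs a published 20-genome
Māori (Ngāti Rakaipaaka) cohort as variant profiles over its 23-position
coding/HVRII panel, together with the matching motif table and frequency
queries.

## Worked example

```python
from mtpop.datasets import (maori_cohort, maori_motifs,
                            maori_frequency_queries, COHORT_POSITIONS)
from mtpop.motifs import restrict_motifs, motif_frequencies
from mtpop.diversity import diversity_table
from mtpop.populations import frequency_table
from mtpop.reference import rcrs

cohort = maori_cohort()
print(diversity_table([cohort]).to_string(index=False))
panel = restrict_motifs(maori_motifs(), COHORT_POSITIONS)
print(motif_frequencies(cohort, panel).to_string(index=False))
print(frequency_table([cohort], rcrs(),
                      queries=maori_frequency_queries()).head(5).to_string(index=False))
```

prints

```
population  N_ind  N_haplo     h      pi
     Maori     20       10 0.879 0.00016

       motif  count  fraction
     B4a1a1c      0      0.00
     B4a1a1a     13      0.65
    B4a1a1a3      7      0.35
    B4a1a1a5      0      0.00
unclassified      0      0.00

gene variant  freq_Maori  carriers_Maori  n_Maori
 ND1  C3909T        0.15               3       20
 ND2  G4769A        0.35               7       20
 ND2  T5465C        1.00              20       20
 COI  G6261A        0.10               2       20
 COI  T6719C        1.00              20       20
```

Reading the output: the 20 samples collapse into 10 distinct haplotypes on
the bundled panel (h = 0.879 here; the full-genome figure is slightly
higher because HVRI singletons, whose per-sample placement is not part of
the bundled panel, split two more classes).  π ≈ 1.6×10⁻⁴ is the
reduced-diversity signature of a founder population — roughly ten-fold
below typical continental cohorts.  Seven samples (35%) carry the
B4a1a1a3 motif, defined by 1185T together with the 4769 reversion to the
reference-state allele; the remaining thirteen are compatible with the
other three sub-haplotypes, which the panel positions alone cannot
separate (their HVRI markers lie outside the panel, so the classifier
flags them ambiguous).  In the frequency table, `G4769A` counts carriers
of the *rCRS* allele A — rare globally because the reference itself
carries a rare state there — giving 7/20 = 0.35.

## Command line

```sh
mtpop simulate --length 16569 --n 20 --mu 9e-5 --seed 1 --out-dir sim/
mtpop run-all --fasta sim/cohort.fasta --reference sim/reference.fasta \
      --out results/ --seed 1 --reps 500
```

`run-all` chains call → classify → diversity → tree → freqs → novel,
writes one table per stage plus `report.json`, stamps every output with a
config hash, and is byte-reproducible for a fixed seed.  Subcommands
(`call`, `classify`, `diversity`, `tree`, `freqs`, `novel`) expose the
individual stages.

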