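# hybscan

Comparative-genomic detection of **intraspecific hybridization** in clonal
fungi.

Some fungal species — the extremely halotolerant black yeast *Hortaea
werneckii* is the motivating case — contain both haploid strains and
diploid strains whose two subgenomes differ by ~10% of nucleotides.  Two
histories can produce such diploids: endoreduplication (genome doubling,
which yields two *identical* subgenomes) or hybridization between two
diverged conspecific haploids.  `hybscan` implements the comparative
pipeline that discriminates these hypotheses and characterizes the events,
for genomicists working with assemblies and short reads of a strain
cohort:

1. **Ploidy classification** — copy counts of planted/universal
   single-copy marker genes; a diploid hybrid shows >50% duplicated
   markers, a haploid ~0%.
2. **Subgenome painting** — reads from two haploid strains are uniquely
   mapped onto each diploid assembly; per-contig fractions of sites
   covered by *only source 1 / only source 2 / both / neither* classify
   each diploid as a parental partition (hybrid of those very lineages), a
   shared half (one parent close to both donors), or uniform (both
   parents distant).
3. **Ploidy-aware SNP calling** against a haploid reference, with a depth
   filter that removes loci where only one subgenome's reads were
   recruited (those sites hide heterozygosity).
4. **Neighbor-Net** — a circular split system fitted to the SNP
   dissimilarity matrix; reticulation (incompatible splits with weight)
   is the signature of conflicting phylogenetic signal.
5. **Core-gene trees** — CDS families with exactly 2 copies per diploid
   and 1 per haploid proxy the subgenomes; NJ trees on TN93 distances are
   clustered by normalized Robinson–Foulds similarity (complete linkage,
   minimum within-cluster similarity 0.80), summarized by majority-rule
   consensus, and read out as **hybridization events** (distinct parent
   lineage pairs).
6. **Clonality test** — the standardized index of association

   r̄_d = (V_O − V_E) / (2 Σ_{j<k} √(var_j · var_k)),

   where V_O is the variance over strain pairs of summed per-locus
   distances and V_E = Σ_j var_j; under free recombination r̄_d ≈ 0.
   Significance by permuting genotypes among strains per locus
   (999 permutations, add-one p-value).
7. **Subgenome heterozygosity** — maximal unique matches (MUMs, found via
   a generalized suffix array), colinear chaining and banded gap closure
   give the alignable fraction between the two subgenomes and their
   percent identity.

A bundled simulator (`hybscan.synth`) generates haploid lineages along a
newick tree, hybrid diploids (unions of two haploid genomes with
post-hybridization drift), planted marker and core genes, and error-prone
reads — with full ground truth, so every inference step is scored against
a known answer.  The `cohort12` preset mirrors a 12-strain study design:
2 sequenced haploids plus 10 diploids created by 7 hybridization events
among 8 lineages diverged by ~8–13%.

## Worked example

```python
from hybscan import synth, ploidy, painting, heterozygosity as het

# two haploids (C, D) at ~10% divergence and their hybrid A
cohort = synth.generate(synth.preset_scenario("trio", seed=1))

calls = ploidy.classify_cohort(cohort.assemblies, cohort.markers)
for sid, c in sorted(calls.items()):
    print(f"{sid}: duplicated={c.duplicated_fraction:.2f} -> {c.call}")

cov = painting.paint(cohort.assemblies["A"],
                     cohort.reads("C"), cohort.reads("D"))
profile = painting.contig_categories(cov)
print("pattern:", painting.classify_pattern(profile).pattern)

table = ploidy.find_marker_copies(cohort.assemblies["A"], cohort.markers)
part = het.separate_by_markers(cohort.assemblies["A"], table,
                               cohort.assemblies["C"])
rep = het.subgenome_alignment_stats(part, cohort.assemblies["A"])
print(f"alignable={rep.alignable_fraction:.1%} identity={rep.identity:.1%}")
```

prints

```
A: duplicated=1.00 -> diploid
C: duplicated=0.00 -> haploid
D: duplicated=0.00 -> haploid
pattern: parental_partition
alignable=99.4% identity=88.6%
```

Every marker is duplicated in A and single-copy in C and D, so A is
diploid and the others haploid.  Reads of C and D each cover their own
half of A's contigs (`parental_partition`): A is a hybrid of these two
lineages.  99.4% of A's genome aligns between its two subgenomes at 88.6%
identity — high heterozygosity, incompatible with endoreduplication
(identity would be ~100%).

The same analyses are available as a CLI over a run directory:

```bash
hybscan --seed 1 --outdir run all       # simulate trio + all stages
hybscan --config my.yaml --outdir run paint
```

Each stage writes TSV/NEXUS/newick outputs and is re-runnable from the
intermediates of earlier stages; reruns with the same seed are
byte-identical.

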