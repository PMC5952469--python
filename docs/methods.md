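# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `hybscan`, in the spirit of a methods supplement.

## The inference problem

Given assemblies and short reads for a cohort of conspecific fungal
strains — some haploid, some diploid with highly diverged subgenomes —
decide whether the diploids arose by endoreduplication or by
hybridization between diverged haploids, identify which lineages were the
parents, count distinct hybridization events, and test whether the
species recombines freely or is essentially clonal.  Every module is
exercised against a simulator with complete ground truth; the package is
equally usable on real FASTA/FASTQ inputs through the CLI.

## Synthetic cohorts (`hybscan.synth`)

**Model.** An i.i.d. ancestor genome (default 200 kb in 10 contigs at GC
0.535, matching the ~53.5% GC of the motivating genomes) carries planted
single-copy marker genes (60 × 400 bp, the ortholog-completeness proxies)
and core genes (150 × 600 bp).  The ancestor evolves along a user-supplied
newick lineage tree; branch lengths are expected substitutions per site.
Per branch, each site mutates with probability 1 − e^(−b); substitutions
follow a K2P-like kernel with a 2:1 transition bias, so TN93 distance
estimation is exercised non-trivially.  Indels are supported (placed
outside planted features so feature coordinates remain exact truth) but
are off in the presets; all controlled-divergence statements below are
therefore substitution-only.

**Hybridization.** A diploid is the union of two leaf lineages' genomes,
contigs relabelled and shuffled.  Diploids sharing a parent pair descend
from the *same* event: the event ancestor accumulates `event_drift`
(default 0.008 substitutions/site) before the strains split, and every
strain (and each subgenome copy within a diploid, independently)
accumulates `strain_drift` (default 0.004) afterwards.  Without drift,
diploids from a shared event would carry byte-identical subgenomes, the
true strain tree would contain polytomies, and gene-tree concordance
would be an artifact of arbitrary tie-breaking; with drift the truth is a
fully resolved tree.  Drift values are small relative to lineage
divergences (0.04–0.15) and keep hybrid-pair identities in the observed
~86–92% window.

**Presets.** `trio` = haploids C, D at total divergence 0.10 plus their
hybrid A.  `cohort12` = 8 lineages (C, D sequenced; P3–P8 unsampled), 10
diploids from 7 events: A,B ← (C,D); E ← (P3,P4); F ← (P3,P5);
G ← (P6,P7); H ← (P6,P8); I,J ← (P7,P8); K,L ← (P4,P5).  The tree was
chosen so that (i) hybrid-pair divergences span 0.085–0.13, (ii) P3 is
close to C and D (0.06/0.07) so E and F show the shared-half painting
pattern, (iii) every pair of parents differs in distance to C by ≥ 0.015
(needed to orient subgenome labels consistently), and (iv) no lineage
parents more than two events (keeps the strain tree resolved).

**Reads.** Uniform forward-strand single-end reads (default 30×, 150 bp,
0.5% flat error — the published cohort was sequenced at 23–35×).  No
quality-score realism beyond a flat Q; no reverse-complement sampling
(and, consistently, no reverse-complement matching anywhere in the
package — a documented limitation for real data).

**Divergence parameterization.** Where an experiment specifies "subgenome
divergence p", branch lengths are obtained by inverting the simulator's
own substitution process (p = 1 − (1−q)² − 0.375 q², q = 1 − e^(−b/2)), so
the planted quantity is the realized nucleotide difference — the scale on
which identities are reported.

## Sequence primitives (`hybscan.seqcore`)

Maximal unique matches (MUMs) are found with a generalized suffix array
(prefix doubling) and Kasai LCP array; every N is replaced by a fresh
symbol so N never matches.  Chaining maximizes total anchor length over
strictly colinear, non-overlapping subsets (quadratic DP; ties towards
smaller reference start).  Gap closure uses a banded global aligner with
linear gap costs (+1/−1/−2 defaults); the band must cover the length
difference, and callers are told to widen it otherwise.  Distances:
p-distance, Jukes–Cantor, and TN93 in closed form.  TN93 replaces the
HKY85 model often used for likelihood tree inference because HKY85 has no
closed-form pairwise distance; TN93 shares its transition/transversion
structure.  Saturated distances are capped (default 5.0) and treated as
"undefined" by consumers that need finite values.

## Read mapping (`hybscan.mapping`)

A k-mer-seeded (k = 17), ungapped-scored unique mapper: candidate
diagonals are voted by 8 evenly spaced seeds; candidates are scored +1/−1
over the read span; a read is placed only if its best locus beats every
other locus by ≥ 10 score units *and* reaches a minimum identity.  This
mirrors the "discard reads mapping to more than one locus" strategy;
acceptance is by truth recovery, not by equivalence with any particular
aligner.  Scoring is substitution-only, matching the simulator's
indel-free reads.  Painting uses min identity 0.90 (so reads from
lineages ≥ ~10% diverged are not recruited — that is what creates the
"none" category); variant calling uses 0.84 so that a ~11%-diverged
subgenome's reads (identity ≈ 0.885) are still recruited.

## Painting (`hybscan.painting`)

A site is "covered" at depth ≥ 1 (configurable; real data would warrant
more).  Contigs < 20 kb are excluded.  The three-pattern taxonomy is
qualitative in origin; the quantitative thresholds here are package
choices, all exposed in configuration: parental partition when ≥ 70% of
contigs are dominated by one source (max(f_only1, f_only2) ≥ 0.5) with
both orientations holding ≥ 15% of dominated contigs; shared half when
≥ 40% of contigs are mostly covered by both sources while ≥ 30% are
mostly covered by neither; otherwise uniform.

## Variant calling (`hybscan.variants`)

Pileup from uniquely placed reads.  Haploid call: majority allele at
depth ≥ 8 and majority fraction ≥ 0.9.  Diploid: homozygous at top-allele
fraction ≥ 0.8; heterozygous when the second allele's fraction lies in
[0.2, 0.8]; otherwise missing.  The depth filter keeps loci whose depth
in every diploid lies in [0.7, 2.0] × that strain's genome-wide median:
for a diploid mapped onto a haploid reference the single-subgenome mode
sits at ~0.5 × median, so a 0.5 lower bound would straddle exactly the
loci the filter exists to remove (heterozygosity-hiding half-depth
sites).  Diploid references are refused outright.  Genotype dissimilarity
treats genotypes as allele multisets, d = 1 − |intersection| / max
ploidy, averaged over loci typed in both strains.

## Neighbor-Net (`hybscan.network`)

The agglomeration follows the published scheme: components of linked
nodes are merged by the neighbor-joining criterion on component-averaged
distances, the node pair is chosen by the analogous criterion treating
the two components' nodes as singletons, 3-node paths are reduced with
the 2/3–1/3 distance reduction (4-node paths twice), agglomeration
continues until a single linked path remains, and reductions are expanded
in reverse to recover the circular ordering.  Ties break towards the
lowest-index pair, so orderings are deterministic.  Split weights are
fitted by non-negative least squares (scipy `nnls`) of the full circular
split basis against the input distances; splits below 1e-8 are dropped.
Correctness is checked against tree metrics (exact recovery), random
circular-decomposable metrics, and the independent phangorn
implementation in R.  Raw SNP dissimilarities are used without
transformation.

## Core-gene phylogenies (`hybscan.phylo`)

Families are connected components of a CDS similarity graph (edges at
identity ≥ 0.80 over ≥ 60% of the shorter sequence; candidate pairs
prefiltered by shared 15-mers).  The identity/coverage rule replaces
BLAST e-value clustering, whose statistic is aligner-specific.  The core
filter keeps families with exactly 2 members per diploid and 1 per
haploid.  Copies are phased onto subgenomes via the contig partition from
the heterozygosity module, so ``X#1`` denotes the same subgenome in every
family; families whose copies cannot be phased are dropped.  Alignment is
a star around the longest member; trimming emulates conserved-block
cleaning: all gap-containing columns are removed, runs of > 10
consecutive non-conserved columns (no strict-majority residue) are
masked, and conserved blocks < 3 columns are dropped.  A family is usable
if the trimmed alignment exceeds 200 columns with ≥ 15 mean pairwise
differences.  Trees are neighbor joining on TN93 distances — a
deterministic, seconds-scale replacement for maximum-likelihood
inference; only topology-level concordance is consumed downstream.
Normalized RF uses 2(n−3) for resolved trees and the total bipartition
count otherwise.  Tree clustering is complete-linkage at within-cluster
similarity ≥ 0.80 ("strict consensus … nodes occurring more than 50%" in
the source tradition is internally contradictory; majority-rule > 50% is
used).  Hybridization events: leaves of the largest cluster's trees are
grouped by single-linkage on mean patristic distance at cutoff 0.02
(well above within-lineage drift noise, well below the ≥ 0.085 lineage
divergences); each diploid's parent pair is the pair of groups holding
its two copies, and events are distinct parent pairs.

## Clonality (`hybscan.clonality`)

I_A and r̄_d use population (1/n_pairs) variances over all strain pairs,
matching the original construction of the statistic; zero-variance loci
contribute nothing to V_E or to the denominator sum.  The permutation
test shuffles whole genotypes among strains independently per locus —
this leaves every per-locus variance invariant (the pair multiset is
permuted), so only V_O varies across permutations, which the
implementation exploits.  p uses the add-one rule; with 999 permutations
the smallest attainable p is 1/1000.  The panmixia simulator draws
biallelic loci with per-locus frequencies U(0.2, 0.8) and independent
genotypes for type-I calibration.

## Heterozygosity (`hybscan.heterozygosity`)

Two separation routes, tagged in output because the under-specified
original procedure admits both reconstructions: (i) painting-based
(argmax of exclusive coverage, confidence |f1 − f2|, default threshold
0.10); (ii) marker-graph (the two copies of a duplicated marker lie in
opposite subgenomes; components of the contig graph are 2-coloured and
oriented by length-weighted 13-mer similarity to a reference haploid, so
labels are globally consistent).  Alignment statistics: MUMs (min length
20) between the concatenated subgenome sets, chained per contig pair,
inter-anchor gaps ≤ 5 kb closed by banded alignment (equal-length gaps by
positional comparison, which is optimal without indels).  The alignable
fraction counts aligned bp on both sides against the whole diploid
length, unassigned contigs included; identity is length-weighted over all
aligned columns, gap-filled regions included (noted because anchor-only
identity would be upward-biased).  The two subgenome groups are
canonically ordered internally, so the report is exactly invariant under
label swaps.

## What the simulator does and does not establish

Passing tests show the algorithms recover planted truth under
substitution-only divergence, uniform coverage, flat error rates, and
complete assemblies.  Real data add indels and structural variation,
repeat families, coverage and error heterogeneity, fragmented assemblies,
and annotation noise; the thresholds exposed in configuration (mapper
identity, depth band, painting cutoffs, family identity) are the knobs a
real-data analysis would revisit.  Reverse-complement handling is absent
throughout and would be required for real assemblies.

## Problem sizes

Desk-scale defaults (200 kb genomes, 10 contigs, 60 markers, 150 core
genes, 30× reads) keep the full test suite at a few minutes while leaving
the 20 kb contig filter, the depth statistics and the concordance
clustering meaningful.  The acceptance script uses one generated scenario
per quantity (two for ploidy accuracy) with all seeds derived from its
`--seed` argument.
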