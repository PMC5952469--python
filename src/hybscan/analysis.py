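"""End-to-end workflows over a synthetic cohort, plus truth scoring.

These convenience drivers chain the library modules the way the pipeline
stages do, but in memory: marker search -> ploidy calls -> subgenome
partitions -> core-gene families -> gene trees -> concordance clustering
-> hybridization inference.  They are used by the acceptance machinery
and are handy for notebook-style exploration.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from . import heterozygosity, phylo, ploidy
from .synth import SyntheticCohort


@dataclass
class CohortAnalysis:
    ploidy_calls: dict[str, str]
    partitions: dict[str, heterozygosity.SubgenomePartition]
    trees: dict[str, phylo.Tree]
    clustering: phylo.TreeClustering | None
    inference: phylo.HybridizationInference | None
    marker_tables: dict = field(default_factory=dict)


def analyze_cohort(cohort: SyntheticCohort, reference: str | None = None,
                   min_similarity: float = 0.80) -> CohortAnalysis:
    """Run ploidy, phasing, gene-tree and hybridization inference."""
    tables = {s: ploidy.find_marker_copies(cohort.assemblies[s], cohort.markers)
              for s in cohort.strains()}
    calls = {s: ploidy.call_ploidy(t).call for s, t in tables.items()}
    haploids = sorted(s for s, c in calls.items() if c == "haploid")
    diploids = sorted(s for s, c in calls.items() if c == "diploid")
    ref = reference or haploids[0]
    parts = {s: heterozygosity.separate_by_markers(
        cohort.assemblies[s], tables[s], cohort.assemblies[ref])
        for s in diploids}
    fams = phylo.cluster_cds(cohort.cds_by_strain())
    core = phylo.filter_core(fams, calls)
    phased = phylo.phase_families(core, parts)
    trees: dict[str, phylo.Tree] = {}
    for fam in phased:
        trimmed = phylo.align_and_trim(fam)
        if trimmed is None:
            continue
        mat, labels = trimmed
        if not phylo.usable_family(mat):
            continue
        tree = phylo.build_tree(mat, labels)
        if tree is not None:
            trees[fam.family_id] = tree
    clustering = inference = None
    if len(trees) >= 2:
        clustering = phylo.cluster_trees(trees, min_similarity)
        largest = [trees[clustering.tree_ids[i]]
                   for i in np.flatnonzero(clustering.assignment == 0)]
        inference = phylo.infer_hybridizations(largest, diploids, haploids)
    return CohortAnalysis(calls, parts, trees, clustering, inference, tables)


def leaf_true_lineage(cohort: SyntheticCohort,
                      analysis: CohortAnalysis) -> dict[str, str]:
    """Truth lineage behind every gene-tree leaf label.

    A haploid leaf is its own lineage; a diploid copy leaf (``X#k``) maps
    to the majority truth parent of the contigs in subgenome group k.
    """
    out = {}
    for sid, call in analysis.ploidy_calls.items():
        if call == "haploid":
            out[sid] = sid
            continue
        part = analysis.partitions.get(sid)
        if part is None:
            continue
        for k, group in (("1", part.group1), ("2", part.group2)):
            parents = Counter(cohort.truth.contig_parent(sid, c)
                              for c in group)
            if parents:
                out[f"{sid}#{k}"] = parents.most_common(1)[0][0]
    return out


def score_event_recovery(cohort: SyntheticCohort,
                         analysis: CohortAnalysis) -> dict:
    """Compare inferred parent pairs and event count with the truth."""
    inf = analysis.inference
    truth = cohort.truth
    leaf_lineage = leaf_true_lineage(cohort, analysis)
    group_lineage = {}
    for gname, members in inf.groups.items():
        lins = Counter(leaf_lineage[m] for m in members if m in leaf_lineage)
        group_lineage[gname] = lins.most_common(1)[0][0] if lins else None
    n_correct = 0
    diploids = sorted(truth.hybrid_parents)
    for did in diploids:
        pair = inf.parent_pair.get(did)
        if pair is None:
            continue
        inferred = {group_lineage.get(g) for g in pair}
        if inferred == set(truth.hybrid_parents[did]):
            n_correct += 1
    return {
        "n_events_inferred": inf.n_events,
        "n_events_true": truth.n_events(),
        "n_diploids": len(diploids),
        "n_correct_pairs": n_correct,
        "pair_accuracy": n_correct / len(diploids) if diploids else 1.0,
    }
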