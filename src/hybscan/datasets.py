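"""Published genome statistics for the twelve *Hortaea werneckii* strains.

The black yeast *H. werneckii* is an extremely halotolerant fungus whose
reference strain carries a diploid genome built from two highly diverged
subgenomes.  The published per-strain assembly statistics for the reference
strain (A), the two haploid isolates (C, D) and the nine other diploid
isolates (B, E-L) are embedded here as a small table: they are inputs to
cohort-level summaries (the diploid cohort mean genome size and gene count,
and the reference strain's CDS fraction) and serve as a realism yardstick
for the bundled simulator (GC content ~53.5%, coverage 23-35x).
"""

from __future__ import annotations

import pandas as pd

from .seqio import CohortSummary, cohort_summary

STRAINS = list("ABCDEFGHIJKL")

#: haploid isolates; every other strain is diploid
HAPLOID_STRAINS = ["C", "D"]

#: the nine newly sequenced diploids, i.e. all strains except the reference
#: assembly A and the two haploids C and D.  Cohort summaries are computed
#: over this group.
DIPLOID_COHORT = ["B", "E", "F", "G", "H", "I", "J", "K", "L"]

_TABLE = {
    "coverage_x": [None, 35, 34, 34, 26, 25, 33, 28, 23, 26, 28, 28],
    "assembly_size_mb": [49.9, 49.4, 25.2, 25.3, 45.2, 48.1,
                         50.5, 49.2, 48.6, 48.5, 48.4, 48.7],
    "n_contigs": [651, 1568, 447, 425, 1679, 2042,
                  5740, 4192, 5073, 5127, 4335, 4146],
    "contig_n50_bp": [153735, 89304, 183917, 238279, 100620, 83336,
                      17360, 25995, 19686, 19095, 24150, 24982],
    "cds_total_mb": [24.14, 27.07, 13.71, 13.70, 24.31, 25.84,
                     24.45, 24.98, 24.54, 24.41, 25.10, 24.91],
    "cds_fraction_pct": [48.38, 54.82, 54.42, 54.26, 53.81, 53.68,
                         48.44, 50.78, 50.47, 50.29, 51.91, 51.13],
    "gene_models": [15974, 17329, 8690, 8674, 15340, 16354,
                    17094, 16775, 16845, 16712, 16886, 16583],
    "n_exons": [38282, 38881, 19797, 19586, 37036, 38738,
                36837, 36596, 36685, 37384, 37202, 38880],
    "exons_per_gene": [2.40, 2.24, 2.28, 2.26, 2.41, 2.37,
                       2.15, 2.18, 2.18, 2.24, 2.20, 2.34],
    "gc_content_pct": [53.50, 53.58, 53.35, 53.43, 53.25, 53.25,
                       53.40, 53.10, 53.16, 53.16, 53.22, 53.16],
}


def genome_statistics() -> pd.DataFrame:
    """Per-strain published genome statistics, indexed by strain name."""
    return pd.DataFrame(_TABLE, index=pd.Index(STRAINS, name="strain"))


def diploid_cohort_summaries() -> dict[str, CohortSummary]:
    """Cohort mean/SD of assembly size and gene count over strains B, E-L."""
    tab = genome_statistics().loc[DIPLOID_COHORT]
    return {
        "assembly_size_mb": cohort_summary(
            tab["assembly_size_mb"], DIPLOID_COHORT, "assembly_size_mb"),
        "gene_models": cohort_summary(
            tab["gene_models"], DIPLOID_COHORT, "gene_models"),
    }
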