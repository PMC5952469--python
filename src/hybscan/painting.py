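"""Subgenome painting: coverage of diploid contigs by haploid reads.

Reads from two candidate parent (haploid) strains are mapped uniquely onto
a diploid assembly; every site of every retained contig is then classified
as covered exclusively by source 1, exclusively by source 2, by both, or
by neither.  The per-contig fraction profile distinguishes three
genome-wide patterns: a *parental partition* (each haploid covers its own
half of the contigs — the hybrid-of-these-parents signature), a *shared
half* (both haploids pile onto the same subgenome because one hybrid
parent is close to both read donors), and *uniform* (no contig-level
structure; both subgenomes equidistant from the donors).

The pattern taxonomy is qualitative in origin; the quantitative thresholds
used here are explicit, configurable choices (see `classify_pattern`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import logger
from .mapping import ReferenceIndex, build_index, depth_track, place_reads
from .seqio import Assembly
from .synth import ReadSet


@dataclass
class SiteCoverage:
    """Per-contig depth arrays for the two haploid read sources."""

    genome_id: str
    source_ids: tuple[str, str]
    depth1: dict[str, np.ndarray]
    depth2: dict[str, np.ndarray]


def map_reads_unique(reads: ReadSet, assembly: Assembly | ReferenceIndex,
                     k: int = 17, min_score_margin: int = 10,
                     min_identity: float = 0.90) -> dict[str, np.ndarray]:
    """Unique-placement mapping of one read set; returns per-contig depth."""
    index = (assembly if isinstance(assembly, ReferenceIndex)
             else build_index(assembly, k=k))
    pl = place_reads(reads, index, min_score_margin=min_score_margin,
                     min_identity=min_identity)
    return depth_track(pl, index, reads.codes.shape[1])


def paint(diploid: Assembly, reads1: ReadSet, reads2: ReadSet,
          k: int = 17, min_score_margin: int = 10,
          min_identity: float = 0.90) -> SiteCoverage:
    """Map both haploid read sets onto one diploid assembly."""
    index = build_index(diploid, k=k)
    d1 = map_reads_unique(reads1, index, min_score_margin=min_score_margin,
                          min_identity=min_identity)
    d2 = map_reads_unique(reads2, index, min_score_margin=min_score_margin,
                          min_identity=min_identity)
    return SiteCoverage(diploid.strain_id, (reads1.strain_id, reads2.strain_id),
                        d1, d2)


def contig_categories(coverage: SiteCoverage, min_depth: int = 1,
                      min_contig_len: int = 20_000) -> pd.DataFrame:
    """Per-contig coverage-category fractions (the painting profile).

    A site counts as covered by a source iff its depth is >= min_depth.
    Contigs shorter than min_contig_len are excluded.  Columns f_only1,
    f_only2, f_both, f_none sum to 1 per contig.
    """
    rows = []
    for cid, d1 in coverage.depth1.items():
        n = len(d1)
        if n < min_contig_len:
            continue
        c1 = d1 >= min_depth
        c2 = coverage.depth2[cid] >= min_depth
        both = int(np.sum(c1 & c2))
        only1 = int(np.sum(c1 & ~c2))
        only2 = int(np.sum(c2 & ~c1))
        rows.append({
            "contig_id": cid, "length": n,
            "f_only1": only1 / n, "f_only2": only2 / n,
            "f_both": both / n, "f_none": (n - both - only1 - only2) / n,
        })
    if not rows:
        logger.warning("all contigs of %s below %d bp; empty painting profile",
                       coverage.genome_id, min_contig_len)
    df = pd.DataFrame(rows, columns=["contig_id", "length", "f_only1",
                                     "f_only2", "f_both", "f_none"])
    df.attrs["genome_id"] = coverage.genome_id
    df.attrs["source_ids"] = coverage.source_ids
    return df


@dataclass
class PatternCall:
    genome_id: str
    pattern: str                      # parental_partition | shared_half | uniform
    stats: dict = field(default_factory=dict)


def classify_pattern(profile: pd.DataFrame,
                     parental_strong: float = 0.5,
                     parental_fraction: float = 0.7,
                     side_fraction: float = 0.15,
                     shared_both: float = 0.4,
                     shared_none: float = 0.3,
                     min_contigs: int = 5) -> PatternCall:
    """Classify a diploid's painting profile into one of three patterns.

    parental_partition: >= `parental_fraction` of contigs are dominated by a
    single source (max(f_only1, f_only2) >= `parental_strong`) and both
    orientations hold >= `side_fraction` of those contigs.  shared_half:
    >= `shared_both` of contigs are mostly covered by both sources while
    >= `shared_none` are mostly covered by neither.  Anything else is
    uniform.  All thresholds are package choices, exposed in configuration.
    """
    n = len(profile)
    if n < min_contigs:
        raise ValueError(f"need >= {min_contigs} retained contigs, got {n}")
    fmax = profile[["f_only1", "f_only2"]].max(axis=1)
    strong = fmax >= parental_strong
    strong_frac = float(strong.mean())
    side1 = ((profile["f_only1"] >= profile["f_only2"]) & strong).sum()
    side2 = int(strong.sum()) - int(side1)
    both_frac = float((profile["f_both"] >= 0.5).mean())
    none_frac = float((profile["f_none"] >= 0.5).mean())
    stats = {
        "n_contigs": n,
        "mean_f_only1": float(profile["f_only1"].mean()),
        "mean_f_only2": float(profile["f_only2"].mean()),
        "mean_f_both": float(profile["f_both"].mean()),
        "mean_f_none": float(profile["f_none"].mean()),
        "strong_fraction": strong_frac,
        "bimodality": float(np.abs(profile["f_only1"] - profile["f_only2"]).mean()),
    }
    min_side = max(1, int(np.ceil(side_fraction * max(int(strong.sum()), 1))))
    if strong_frac >= parental_fraction and side1 >= min_side and side2 >= min_side:
        pattern = "parental_partition"
    elif both_frac >= shared_both and none_frac >= shared_none:
        pattern = "shared_half"
    else:
        pattern = "uniform"
    return PatternCall(profile.attrs.get("genome_id", "?"), pattern, stats)


def assign_contigs(profile: pd.DataFrame) -> pd.DataFrame:
    """Assign each retained contig to the dominant read source (1 or 2).

    Confidence is |f_only1 - f_only2|; downstream consumers may threshold.
    """
    out = profile.copy()
    out["assigned_source"] = np.where(out["f_only1"] >= out["f_only2"], 1, 2)
    out["confidence"] = (out["f_only1"] - out["f_only2"]).abs()
    return out
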