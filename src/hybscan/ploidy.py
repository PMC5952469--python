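"""Ploidy classification from copy counts of single-copy marker genes.

The logic mirrors completeness/duplication assessment with universal
single-copy orthologs: in a haploid assembly nearly every marker occurs
once; in an unreduced hybrid diploid most markers occur twice (one
diverged copy per subgenome).  Markers are located by k-mer seeding of the
assembly followed by alignment of the candidate region; a hit counts as a
copy when it reaches a minimum identity over a minimum fraction of the
marker length.  The haploid/diploid decision thresholds sit far from both
observed regimes (0% vs >60% duplicated) and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from ._util import logger
from .mapping import build_index
from .seqio import Assembly


def find_marker_copies(assembly: Assembly, markers: list[tuple[str, str]],
                       min_identity: float = 0.80, min_coverage: float = 0.70,
                       k: int = 13, min_seeds: int = 3,
                       diag_slack: int = 40) -> pd.DataFrame:
    """Locate copies of each marker gene in an assembly.

    Returns one row per accepted copy: marker_id, contig_id, start, end,
    identity.  Candidate loci are diagonal clusters of exact k-mer seeds
    (>= min_seeds seeds); overlapping candidates for the same marker are
    merged before alignment.  Identity is computed from a semi-global
    alignment of the marker against the candidate region and is measured
    over the full marker length, so a partially present marker fails the
    coverage criterion through its identity.
    """
    if not markers:
        raise ValueError("no markers supplied")
    index = build_index(assembly, k=k, max_occurrences=64)
    rows = []
    for marker_id, mseq in markers:
        mlen = len(mseq)
        kv = _marker_kmers(mseq, k)
        lo = np.searchsorted(index.sorted_kmers, kv, side="left")
        hi = np.searchsorted(index.sorted_kmers, kv, side="right")
        counts = hi - lo
        counts[kv < 0] = 0
        total = int(counts.sum())
        if total == 0:
            continue
        within = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
        occ = index.sorted_positions[np.repeat(lo, counts) + within]
        offs = np.repeat(np.arange(len(kv)), counts)
        diag = occ - offs
        for region in _diag_regions(diag, mlen, min_seeds, diag_slack):
            g0, g1 = region
            ci = int(np.searchsorted(index.offsets, g0, side="right") - 1)
            cid = index.contig_ids[ci]
            c_start = int(max(g0 - index.offsets[ci], 0))
            c_end = int(min(g1 - index.offsets[ci], index.lengths[ci]))
            target = index.genome[index.offsets[ci] + c_start:
                                  index.offsets[ci] + c_end]
            res = edlib.align(mseq, _to_str(target), mode="HW",
                              task="locations")
            identity = 1.0 - res["editDistance"] / mlen
            loc = res["locations"][0]
            span = (loc[1] - loc[0] + 1) if loc[0] is not None else 0
            coverage = min(span / mlen, 1.0)
            if identity >= min_identity and coverage >= min_coverage:
                rows.append({"marker_id": marker_id, "contig_id": cid,
                             "start": c_start + (loc[0] or 0),
                             "end": c_start + (loc[1] + 1 if loc[1] is not None
                                               else span),
                             "identity": identity})
    table = pd.DataFrame(rows, columns=["marker_id", "contig_id", "start",
                                        "end", "identity"])
    table.attrs["strain_id"] = assembly.strain_id
    table.attrs["n_markers"] = len(markers)
    return table


def _to_str(codes: np.ndarray) -> str:
    from ._util import decode
    return decode(codes)


def _marker_kmers(seq: str, k: int) -> np.ndarray:
    from ._util import encode
    codes = encode(seq).astype(np.int64)
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.int64)
    bad = codes >= 4
    vals = np.zeros(n - k + 1, dtype=np.int64)
    anybad = np.zeros(n - k + 1, dtype=bool)
    for j in range(k):
        vals = vals * 4 + np.where(bad[j:n - k + 1 + j], 0, codes[j:n - k + 1 + j])
        anybad |= bad[j:n - k + 1 + j]
    vals[anybad] = -1
    return vals


def _diag_regions(diag: np.ndarray, mlen: int, min_seeds: int, slack: int):
    """Cluster seed diagonals and emit merged candidate (start, end) spans."""
    if len(diag) == 0:
        return []
    ds = np.sort(diag)
    breaks = np.flatnonzero(np.diff(ds) > slack)
    spans = []
    start = 0
    for b in list(breaks) + [len(ds) - 1]:
        cluster = ds[start:b + 1]
        if len(cluster) >= min_seeds:
            spans.append((int(cluster[0]) - slack,
                          int(cluster[-1]) + mlen + slack))
        start = b + 1
    # merge overlapping spans (same-marker hits joined before alignment)
    spans.sort()
    merged = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class PloidyCall:
    strain_id: str
    complete_fraction: float
    single_fraction: float
    duplicated_fraction: float
    call: str    # haploid | diploid | ambiguous


def call_ploidy(table: pd.DataFrame, dup_hi: float = 0.50,
                dup_lo: float = 0.10, min_markers: int = 20) -> PloidyCall:
    """Haploid/diploid call from the duplicated-marker fraction.

    duplicated_fraction >= dup_hi -> diploid; <= dup_lo -> haploid;
    in between -> ambiguous.
    """
    n_markers = table.attrs.get("n_markers", 0)
    if n_markers < min_markers:
        raise ValueError(f"need >= {min_markers} markers, got {n_markers}")
    copy_counts = table.groupby("marker_id").size() if len(table) else pd.Series(dtype=int)
    single = int((copy_counts == 1).sum())
    dup = int((copy_counts >= 2).sum())
    complete = (single + dup) / n_markers
    single_f, dup_f = single / n_markers, dup / n_markers
    if dup_f >= dup_hi:
        call = "diploid"
    elif dup_f <= dup_lo:
        call = "haploid"
    else:
        call = "ambiguous"
    sid = table.attrs.get("strain_id", "?")
    logger.info("%s: %.0f%% complete, %.0f%% duplicated -> %s",
                sid, 100 * complete, 100 * dup_f, call)
    return PloidyCall(sid, complete, single_f, dup_f, call)


def classify_cohort(assemblies: dict[str, Assembly],
                    markers: list[tuple[str, str]],
                    **kwargs) -> dict[str, PloidyCall]:
    """Marker search + ploidy call for every strain in a cohort."""
    call_kw = {k: kwargs.pop(k) for k in ("dup_hi", "dup_lo", "min_markers")
               if k in kwargs}
    return {sid: call_ploidy(find_marker_copies(asm, markers, **kwargs), **call_kw)
            for sid, asm in assemblies.items()}
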