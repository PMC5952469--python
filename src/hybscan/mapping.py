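"""Unique-placement read mapping by k-mer seeding and window scoring.

A read is placed only when its best candidate locus beats the second-best
locus by a configurable score margin (the analogue of discarding reads
that map to more than one locus) and reaches a minimum identity.  This is
an alignment-score mapper, not a full short-read aligner: candidate loci
are diagonals voted for by exact k-mer seeds, and each candidate is scored
by ungapped comparison over the read span (the bundled simulator produces
indel-free reads; scoring uses +1/-1 match/mismatch).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import encode, logger
from .seqio import Assembly
from .synth import ReadSet


@dataclass
class ReferenceIndex:
    """Sorted k-mer index over the concatenated contigs of an assembly."""

    assembly: Assembly
    k: int
    contig_ids: list[str]
    offsets: np.ndarray        # start of each contig in the concatenation
    lengths: np.ndarray
    genome: np.ndarray         # concatenated codes, padded with N
    sorted_kmers: np.ndarray
    sorted_positions: np.ndarray


def build_index(assembly: Assembly, k: int = 17, max_occurrences: int = 16,
                pad: int = 512) -> ReferenceIndex:
    contig_ids = [cid for cid, _ in assembly.contigs]
    lengths = np.array([len(s) for _, s in assembly.contigs])
    offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]]) + pad
    parts = [np.full(pad, 4, dtype=np.uint8)]
    for _, seq in assembly.contigs:
        parts.append(encode(seq))
    parts.append(np.full(pad, 4, dtype=np.uint8))
    genome = np.concatenate(parts)
    kmers = _kmer_values(genome, k)
    valid = kmers >= 0
    pos = np.flatnonzero(valid)
    kv = kmers[pos]
    order = np.argsort(kv, kind="stable")
    kv, pos = kv[order], pos[order]
    # drop hyper-repetitive seeds
    uniq, start, counts = np.unique(kv, return_index=True, return_counts=True)
    keep = np.ones(len(kv), dtype=bool)
    for s, c in zip(start[counts > max_occurrences],
                    counts[counts > max_occurrences]):
        keep[s:s + c] = False
    return ReferenceIndex(assembly, k, contig_ids, offsets, lengths, genome,
                          kv[keep], pos[keep])


def _kmer_values(codes: np.ndarray, k: int) -> np.ndarray:
    """Pack k-mers into int64; windows containing N get value -1."""
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.int64)
    c = codes.astype(np.int64)
    bad = (c >= 4)
    vals = np.zeros(n - k + 1, dtype=np.int64)
    anybad = np.zeros(n - k + 1, dtype=bool)
    for j in range(k):
        vals = vals * 4 + np.where(bad[j:n - k + 1 + j], 0, c[j:n - k + 1 + j])
        anybad |= bad[j:n - k + 1 + j]
    vals[anybad] = -1
    return vals


@dataclass
class Placements:
    """Unique placements of a read set on a reference assembly."""

    strain_id: str
    reference_id: str
    contig_ids: list[str]
    read_index: np.ndarray     # indices into the original ReadSet
    contig_idx: np.ndarray     # per placed read
    start: np.ndarray          # 0-based start within the contig
    mismatches: np.ndarray
    n_reads: int = 0
    n_ambiguous: int = 0
    n_low_identity: int = 0

    def __len__(self) -> int:
        return len(self.read_index)


def place_reads(reads: ReadSet, index: ReferenceIndex,
                min_score_margin: int = 10, min_identity: float = 0.90,
                n_seeds: int = 8) -> Placements:
    """Place each read at its unique best locus, or discard it.

    Candidate diagonals are collected from `n_seeds` evenly spaced exact
    k-mer seeds; each candidate is scored +1/-1 over the full read span.
    A read is placed iff its best candidate has identity >= min_identity
    and out-scores every candidate at a different locus by
    >= min_score_margin (score units: 2 per mismatch).
    """
    R, L = reads.codes.shape
    k = index.k
    seed_offsets = np.unique(np.linspace(0, L - k, n_seeds).astype(int))
    S = len(seed_offsets)
    # seed k-mer values for every read
    c = reads.codes.astype(np.int64)
    bad = c >= 4
    vals = np.zeros((R, S), dtype=np.int64)
    anybad = np.zeros((R, S), dtype=bool)
    for j in range(k):
        cols = seed_offsets + j
        vals = vals * 4 + np.where(bad[:, cols], 0, c[:, cols])
        anybad |= bad[:, cols]
    vals[anybad] = -1
    lo = np.searchsorted(index.sorted_kmers, vals.ravel(), side="left")
    hi = np.searchsorted(index.sorted_kmers, vals.ravel(), side="right")
    counts = hi - lo
    counts[vals.ravel() < 0] = 0
    total = int(counts.sum())
    if total == 0:
        logger.warning("no seed hits for %s on %s", reads.strain_id,
                       index.assembly.strain_id)
        return Placements(reads.strain_id, index.assembly.strain_id,
                          index.contig_ids, *(np.empty(0, dtype=int),) * 4,
                          n_reads=R)
    # expand [lo, hi) ranges into flat occurrence arrays
    rep = np.repeat(np.arange(R * S), counts)
    within = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    occ_pos = index.sorted_positions[np.repeat(lo, counts) + within]
    read_id = rep // S
    seed_off = seed_offsets[rep % S]
    diag = occ_pos - seed_off            # candidate read start in genome coords
    # vote per (read, diagonal); allow +-2 jitter by rounding is unnecessary
    key = read_id.astype(np.int64) * np.int64(2 ** 34) + diag
    uk, first = np.unique(key, return_index=True)
    cand_read = read_id[first]
    cand_diag = diag[first]
    # score all candidates by ungapped comparison
    windows = index.genome[cand_diag[:, None] + np.arange(L)[None, :]]
    eq = (windows == reads.codes[cand_read]) & (windows < 4)
    matches = eq.sum(axis=1)
    score = 2 * matches - L
    # per read: best and second-best at a distinct locus
    order = np.lexsort((-score, cand_read))
    cr, cd, sc, mt = cand_read[order], cand_diag[order], score[order], matches[order]
    starts = np.flatnonzero(np.concatenate([[True], cr[1:] != cr[:-1]]))
    ends = np.concatenate([starts[1:], [len(cr)]])
    placed_rd, placed_diag, placed_mm = [], [], []
    n_amb = n_low = 0
    min_matches = min_identity * L
    for s, e in zip(starts, ends):
        best_d, best_s = cd[s], sc[s]
        if mt[s] < min_matches:
            n_low += 1
            continue
        second = None
        for i in range(s + 1, e):
            if abs(cd[i] - best_d) > 5:
                second = sc[i]
                break
        if second is not None and best_s - second < min_score_margin:
            n_amb += 1
            continue
        placed_rd.append(cr[s])
        placed_diag.append(best_d)
        placed_mm.append(L - mt[s])
    placed_rd = np.array(placed_rd, dtype=int)
    placed_diag = np.array(placed_diag, dtype=int)
    contig_idx = np.searchsorted(index.offsets, placed_diag, side="right") - 1
    start = placed_diag - index.offsets[contig_idx]
    # discard placements that would overhang the contig
    ok = (start >= 0) & (start + L <= index.lengths[contig_idx])
    logger.info("%s -> %s: placed %d/%d reads (%d ambiguous, %d low identity)",
                reads.strain_id, index.assembly.strain_id, int(ok.sum()), R,
                n_amb, n_low)
    return Placements(reads.strain_id, index.assembly.strain_id,
                      index.contig_ids, placed_rd[ok], contig_idx[ok],
                      start[ok], np.array(placed_mm, dtype=int)[ok],
                      n_reads=R, n_ambiguous=n_amb, n_low_identity=n_low)


def depth_track(placements: Placements, index: ReferenceIndex,
                read_length: int) -> dict[str, np.ndarray]:
    """Per-contig read depth arrays implied by a set of placements."""
    track = {cid: np.zeros(int(ln) + 1, dtype=np.int32)
             for cid, ln in zip(index.contig_ids, index.lengths)}
    for ci in np.unique(placements.contig_idx):
        cid = index.contig_ids[int(ci)]
        sel = placements.contig_idx == ci
        diff = track[cid]
        np.add.at(diff, placements.start[sel], 1)
        np.add.at(diff, placements.start[sel] + read_length, -1)
    return {cid: np.cumsum(d[:-1]).astype(np.int32) for cid, d in track.items()}
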