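"""Sequence-algorithm primitives shared by the rest of the pipeline.

The unit of whole-genome comparison here is the *maximal unique match*
(MUM): an exact match that cannot be extended in either direction and whose
matched string occurs exactly once in the reference and exactly once in the
query.  MUMs are found with a generalized suffix array, chained into a
colinear backbone, and the gaps between chained anchors are closed with a
banded global alignment.  Pairwise distances on aligned sequences are
available as p-distance, Jukes-Cantor and Tamura-Nei (TN93); TN93 is the
closed-form model used throughout (it shares the transition/transversion
structure of HKY85 but, unlike HKY85, has an analytic distance).

Reverse-complement matching is deliberately not performed anywhere: the
bundled simulator never inverts segments, and the limitation is documented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._util import encode

# ---------------------------------------------------------------------------
# suffix array / LCP machinery


def suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (numpy lexsort), O(n log^2 n)."""
    n = len(codes)
    rank = codes.astype(np.int64)
    k = 1
    sa = np.argsort(rank, kind="stable")
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[:-k] = rank[k:]
        sa = np.lexsort((key2, rank))
        r1, r2 = rank[sa], key2[sa]
        changed = np.ones(n, dtype=bool)
        changed[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[sa] = np.cumsum(changed) - 1
        rank = new_rank
        if rank[sa[-1]] == n - 1:
            return sa
        k *= 2


def lcp_array(codes: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """Kasai's algorithm; lcp[i] = LCP of suffixes sa[i-1] and sa[i]."""
    n = len(codes)
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    lcp = np.zeros(n, dtype=np.int64)
    h = 0
    c = codes
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = sa[r - 1]
            while i + h < n and j + h < n and c[i + h] == c[j + h]:
                h += 1
            lcp[r] = h
            if h:
                h -= 1
        else:
            h = 0
    return lcp


# ---------------------------------------------------------------------------
# anchors


@dataclass(frozen=True)
class Anchor:
    """Exact match of `length` bp at ref_start/qry_start (0-based)."""

    ref_start: int
    qry_start: int
    length: int
    unique: bool = True

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.length

    @property
    def qry_end(self) -> int:
        return self.qry_start + self.length


def _unique_symbolize(codes: np.ndarray, start_symbol: int) -> tuple[np.ndarray, int]:
    """Replace every N (code 4) by a fresh symbol so that N never matches."""
    out = codes.astype(np.int64)
    ns = np.flatnonzero(out == 4)
    out[ns] = start_symbol + np.arange(len(ns))
    return out, start_symbol + len(ns)


def find_unique_anchors(ref_seq: str, qry_seq: str, min_len: int = 20) -> list[Anchor]:
    """All maximal unique exact matches of length >= min_len (MUMs).

    The matched substring must occur exactly once in the reference and
    exactly once in the query; N never matches anything.  Coordinates are
    0-based offsets into the input strings.  Anchors are returned sorted by
    reference start.
    """
    if min_len < 12:
        raise ValueError("min_len must be >= 12")
    n1, n2 = len(ref_seq), len(qry_seq)
    if n1 < min_len or n2 < min_len:
        return []
    a, nxt = _unique_symbolize(encode(ref_seq), 10)
    b, nxt = _unique_symbolize(encode(qry_seq), nxt)
    sep = np.array([nxt], dtype=np.int64)
    s = np.concatenate([a, sep, b])
    sa = suffix_array(s)
    lcp = lcp_array(s, sa)
    n = len(s)
    from_ref = sa < n1
    from_qry = sa > n1
    anchors = []
    for i in range(1, n):
        length = int(lcp[i])
        if length < min_len:
            continue
        p, q = int(sa[i - 1]), int(sa[i])
        if not ((from_ref[i - 1] and from_qry[i]) or (from_qry[i - 1] and from_ref[i])):
            continue
        # uniqueness: no neighbouring suffix shares this min_len+ prefix
        if lcp[i - 1] >= length or (i + 1 < n and lcp[i + 1] >= length):
            continue
        # left-maximality: preceding characters must differ
        if p > 0 and q > 0 and s[p - 1] == s[q - 1]:
            continue
        if from_qry[i - 1]:
            p, q = q, p
        anchors.append(Anchor(p, q - n1 - 1, length))
    anchors.sort(key=lambda x: (x.ref_start, x.qry_start))
    return anchors


def chain_anchors(anchors: list[Anchor]) -> list[Anchor]:
    """Maximum-total-length strictly colinear, non-overlapping anchor chain.

    Anchor j may follow anchor i only if it starts after i ends in both the
    reference and the query.  Ties are broken towards smaller ref_start.
    """
    if not anchors:
        return []
    anc = sorted(anchors, key=lambda x: (x.ref_start, x.qry_start))
    n = len(anc)
    rs = np.array([x.ref_start for x in anc])
    qs = np.array([x.qry_start for x in anc])
    re = np.array([x.ref_end for x in anc])
    qe = np.array([x.qry_end for x in anc])
    ln = np.array([x.length for x in anc])
    best = np.zeros(n, dtype=np.int64)   # best chain total ending at i
    prev = np.full(n, -1, dtype=np.int64)
    for j in range(n):
        mask = (re[:j] <= rs[j]) & (qe[:j] <= qs[j])
        if mask.any():
            cand = np.where(mask, best[:j], -1)
            k = int(np.argmax(cand))     # first max = smallest ref_start
            best[j] = cand[k] + ln[j]
            prev[j] = k
        else:
            best[j] = ln[j]
    j = int(np.argmax(best))
    chain = []
    while j >= 0:
        chain.append(anc[j])
        j = int(prev[j])
    return chain[::-1]


# ---------------------------------------------------------------------------
# banded global alignment


class BandExceededError(ValueError):
    """The band is too narrow for the length difference of the inputs."""


@dataclass
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    identity: float          # match columns / columns without a gap
    aligned_ref_span: int
    aligned_qry_span: int

    def match_columns(self) -> int:
        return sum(1 for x, y in zip(self.aligned_a, self.aligned_b)
                   if x == y and x not in "-N")


NEG_INF = -1e18


def banded_global_align(a: str, b: str, band_width: int = 50,
                        match: float = 1.0, mismatch: float = -1.0,
                        gap: float = -2.0) -> PairwiseAlignment:
    """Optimal global alignment restricted to the diagonal band |i-j|<=band.

    Linear gap penalties; N matches nothing.  Raises
    :class:`BandExceededError` when the band cannot contain the global path.
    """
    m, n = len(a), len(b)
    if abs(m - n) > band_width:
        raise BandExceededError(
            f"length difference {abs(m - n)} exceeds band {band_width}; widen the band")
    if m == 0 or n == 0:
        aa = a + "-" * n
        bb = "-" * m + b
        return PairwiseAlignment(aa, bb, gap * (m + n), 0.0, m, n)
    ca, cb = encode(a), encode(b)
    w = 2 * band_width + 1
    score = np.full((m + 1, w), NEG_INF)
    ptr = np.zeros((m + 1, w), dtype=np.int8)  # 0 diag, 1 up(gap in b), 2 left(gap in a)
    # j maps to offset j - i + band_width in row i
    off0 = band_width
    js0 = np.arange(w) - band_width          # j values in row 0
    row0 = np.where((js0 >= 0) & (js0 <= n), gap * np.maximum(js0, 0), NEG_INF)
    score[0] = row0
    ptr[0] = 2
    for i in range(1, m + 1):
        js = np.arange(w) + i - band_width   # j value at each offset
        valid = (js >= 0) & (js <= n)
        jsc = np.clip(js, 1, n)
        sub = np.where((cb[jsc - 1] == ca[i - 1]) & (ca[i - 1] != 4) & (cb[jsc - 1] != 4),
                       match, mismatch)
        diag = score[i - 1] + sub                       # same offset previous row
        up = np.concatenate([score[i - 1][1:], [NEG_INF]]) + gap
        cur = np.maximum(diag, up)
        p = np.where(diag >= up, 0, 1).astype(np.int8)
        # left moves are within-row; sequential but rare to matter: do a scan
        left_src = np.concatenate([[NEG_INF], cur[:-1]])
        improved = left_src + gap > cur
        while improved.any():
            cur = np.where(improved, left_src + gap, cur)
            p = np.where(improved, 2, p).astype(np.int8)
            left_src = np.concatenate([[NEG_INF], cur[:-1]])
            improved = left_src + gap > cur
        cur[js == 0] = gap * i
        p[js == 0] = 1
        cur[~valid] = NEG_INF
        score[i], ptr[i] = cur, p
    end_off = n - m + off0
    if not (0 <= end_off < w) or score[m, end_off] <= NEG_INF / 2:
        raise BandExceededError("global path leaves the band; widen the band")
    # traceback
    i, off = m, end_off
    out_a, out_b = [], []
    while i > 0 or off + i - band_width > 0:
        j = off + i - band_width
        move = ptr[i, off]
        if i > 0 and j > 0 and move == 0:
            out_a.append(a[i - 1]); out_b.append(b[j - 1])
            i -= 1
        elif i > 0 and move == 1:
            out_a.append(a[i - 1]); out_b.append("-")
            i -= 1
            off += 1
        else:
            out_a.append("-"); out_b.append(b[j - 1])
            off -= 1
    aa = "".join(reversed(out_a))
    bb = "".join(reversed(out_b))
    ungapped = [(x, y) for x, y in zip(aa, bb) if x != "-" and y != "-"]
    matches = sum(1 for x, y in ungapped if x == y and x != "N")
    identity = matches / len(ungapped) if ungapped else 0.0
    return PairwiseAlignment(aa, bb, float(score[m, end_off]), identity, m, n)


# ---------------------------------------------------------------------------
# distances


class UndefinedDistanceError(ValueError):
    """No comparable columns, or saturation beyond the model's range."""


@dataclass
class DistanceInfo:
    model: str
    n_sites: int
    p_distance: float
    transitions_ag: float = 0.0
    transitions_ct: float = 0.0
    transversions: float = 0.0
    base_frequencies: tuple = ()


def _comparable(a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    ca, cb = encode(a.replace("-", "N")), encode(b.replace("-", "N"))
    keep = (ca < 4) & (cb < 4)
    return ca[keep], cb[keep]


def nucleotide_distance(aligned_a: str, aligned_b: str, model: str = "p",
                        max_distance: float = 5.0,
                        return_info: bool = False):
    """Pairwise distance between two rows of an alignment.

    Columns containing a gap or N in either row are skipped.  `model` is
    one of "p" (mismatch fraction), "jc" (Jukes-Cantor) or "tn93"
    (Tamura-Nei closed form).  Saturated distances (non-positive logarithm
    arguments) are capped at `max_distance`.
    """
    ca, cb = _comparable(aligned_a, aligned_b)
    n = len(ca)
    if n == 0:
        raise UndefinedDistanceError("no comparable columns")
    p = float(np.mean(ca != cb))
    if model == "p":
        d = p
    elif model == "jc":
        arg = 1 - 4 * p / 3
        d = max_distance if arg <= 0 else -0.75 * math.log(arg)
    elif model == "tn93":
        d = _tn93(ca, cb, n, max_distance)
    else:
        raise ValueError(f"unknown model {model!r}")
    if not return_info:
        return d
    info = _pair_info(ca, cb, n, model, p)
    return d, info


def _pair_counts(ca, cb, n):
    both = np.concatenate([ca, cb])
    freqs = np.bincount(both, minlength=4)[:4] / (2 * n)
    diff = ca != cb
    pair_min = np.minimum(ca, cb)[diff]
    pair_max = np.maximum(ca, cb)[diff]
    p1 = float(np.sum((pair_min == 0) & (pair_max == 2))) / n  # A<->G
    p2 = float(np.sum((pair_min == 1) & (pair_max == 3))) / n  # C<->T
    q = float(np.sum(diff)) / n - p1 - p2
    return freqs, p1, p2, q


def _pair_info(ca, cb, n, model, p):
    freqs, p1, p2, q = _pair_counts(ca, cb, n)
    return DistanceInfo(model, n, p, p1, p2, q, tuple(freqs))


def _tn93(ca, cb, n, max_distance):
    freqs, p1, p2, q = _pair_counts(ca, cb, n)
    ga, gc, gg, gt = freqs
    gr, gy = ga + gg, gc + gt
    if gr == 0 or gy == 0:
        return max_distance if (p1 + p2 + q) > 0 else 0.0
    terms = 0.0
    k1 = 2 * ga * gg / gr if gr else 0.0
    k2 = 2 * gc * gt / gy if gy else 0.0
    # purine transitions
    if p1 > 0 or q > 0:
        if k1 > 0:
            w1 = 1 - p1 / k1 - q / (2 * gr)
            if w1 <= 0:
                return max_distance
            terms += -k1 * math.log(w1)
        elif p1 > 0:
            return max_distance
    # pyrimidine transitions
    if p2 > 0 or q > 0:
        if k2 > 0:
            w2 = 1 - p2 / k2 - q / (2 * gy)
            if w2 <= 0:
                return max_distance
            terms += -k2 * math.log(w2)
        elif p2 > 0:
            return max_distance
    w3 = 1 - q / (2 * gr * gy)
    if w3 <= 0:
        return max_distance
    k3 = 2 * (gr * gy - ga * gg * gy / gr - gc * gt * gr / gy)
    terms += -k3 * math.log(w3)
    return min(max(terms, 0.0), max_distance)
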