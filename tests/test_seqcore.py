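"""Oracle-backed tests for the sequence primitives.

Brute-force oracles are implemented here, independently of the library:
common-substring enumeration for MUMs, exhaustive subset search for
chaining, and an unbanded Needleman-Wunsch for the banded aligner.
"""

import itertools
import math

import numpy as np
import pytest

from hybscan import seqcore
from hybscan.seqcore import Anchor

from conftest import random_seq


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_force_mums(ref, qry, min_len):
    """Enumerate maximal matches, keep those unique in both sequences."""
    out = set()
    for i in range(len(ref)):
        for j in range(len(qry)):
            if ref[i] != qry[j] or ref[i] == "N":
                continue
            if i > 0 and j > 0 and ref[i - 1] == qry[j - 1] and ref[i - 1] != "N":
                continue  # not left-maximal
            ln = 0
            while (i + ln < len(ref) and j + ln < len(qry)
                   and ref[i + ln] == qry[j + ln] and ref[i + ln] != "N"):
                ln += 1
            if ln < min_len:
                continue
            sub = ref[i:i + ln]
            if ref.count(sub) == 1 and qry.count(sub) == 1:
                out.add((i, j, ln))
    return out


def brute_force_chain(anchors):
    """Best colinear subset by exhaustive search over all subsets."""
    best, best_len = [], -1
    for r in range(len(anchors) + 1):
        for raw in itertools.combinations(anchors, r):
            subset = sorted(raw, key=lambda x: x.ref_start)
            ok = all(a.ref_end <= b.ref_start and a.qry_end <= b.qry_start
                     for a, b in itertools.combinations(subset, 2))
            if ok:
                total = sum(a.length for a in subset)
                if total > best_len:
                    best, best_len = list(subset), total
    return best_len


def full_needleman_wunsch(a, b, match=1.0, mismatch=-1.0, gap=-2.0):
    m, n = len(a), len(b)
    sc = np.zeros((m + 1, n + 1))
    sc[0, :] = gap * np.arange(n + 1)
    sc[:, 0] = gap * np.arange(m + 1)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else mismatch
            sc[i, j] = max(sc[i - 1, j - 1] + s, sc[i - 1, j] + gap,
                           sc[i, j - 1] + gap)
    return sc[m, n]


# ---------------------------------------------------------------------------
# unique anchors


class TestUniqueAnchors:
    def test_identical_sequences_single_anchor(self, rng):
        s = random_seq(rng, 1000)
        anchors = seqcore.find_unique_anchors(s, s, 20)
        assert [(a.ref_start, a.qry_start, a.length) for a in anchors] == [(0, 0, 1000)]

    def test_unrelated_sequences_no_anchor(self, rng):
        a, b = random_seq(rng, 1000), random_seq(rng, 1000)
        assert seqcore.find_unique_anchors(a, b, 20) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        block = random_seq(rng, 50)
        ref = random_seq(rng, 80) + block + random_seq(rng, 70)
        qry = random_seq(rng, 60) + block + random_seq(rng, 90)
        got = {(a.ref_start, a.qry_start, a.length)
               for a in seqcore.find_unique_anchors(ref, qry, 15)}
        assert got == brute_force_mums(ref, qry, 15)

    @pytest.mark.parametrize("seed", range(3))
    def test_diverged_pair_matches_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        ref = random_seq(rng, 400)
        qry = list(ref)
        for pos in rng.choice(400, 30, replace=False):
            qry[pos] = "ACGT"[(("ACGT".index(qry[pos])) + 1) % 4]
        qry = "".join(qry)
        got = {(a.ref_start, a.qry_start, a.length)
               for a in seqcore.find_unique_anchors(ref, qry, 12)}
        assert got == brute_force_mums(ref, qry, 12)

    def test_n_never_matches(self):
        s = "ACGTACGTAC" + "N" * 12 + "GTACGTACGT"
        anchors = seqcore.find_unique_anchors(s, s, 12)
        assert all("N" not in s[a.ref_start:a.ref_end] for a in anchors)

    def test_symmetry(self, rng):
        block = random_seq(rng, 40)
        ref = random_seq(rng, 50) + block + random_seq(rng, 50)
        qry = random_seq(rng, 30) + block + random_seq(rng, 60)
        fwd = seqcore.find_unique_anchors(ref, qry, 15)
        rev = seqcore.find_unique_anchors(qry, ref, 15)
        assert {(a.ref_start, a.qry_start, a.length) for a in fwd} == \
               {(a.qry_start, a.ref_start, a.length) for a in rev}

    def test_min_len_floor(self):
        with pytest.raises(ValueError):
            seqcore.find_unique_anchors("ACGT" * 10, "ACGT" * 10, 5)


class TestChaining:
    def test_single_anchor(self):
        a = Anchor(0, 0, 30)
        assert seqcore.chain_anchors([a]) == [a]

    def test_crossing_anchors_heavier_wins(self):
        heavy = Anchor(0, 100, 30)
        light = Anchor(50, 0, 20)
        assert seqcore.chain_anchors([heavy, light]) == [heavy]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        anchors = [Anchor(int(rng.integers(0, 200)), int(rng.integers(0, 200)),
                          int(rng.integers(5, 40))) for _ in range(10)]
        chain = seqcore.chain_anchors(anchors)
        # output must be colinear
        for x, y in zip(chain, chain[1:]):
            assert x.ref_end <= y.ref_start and x.qry_end <= y.qry_start
        assert sum(a.length for a in chain) == brute_force_chain(anchors)


class TestBandedAlignment:
    def test_identical(self):
        aln = seqcore.banded_global_align("ACGTACGT", "ACGTACGT", 5)
        assert aln.identity == 1.0 and aln.score == 8

    def test_all_mismatch(self):
        aln = seqcore.banded_global_align("AAAA", "TTTT", 4)
        assert aln.identity == 0.0

    def test_gap_recovery(self):
        aln = seqcore.banded_global_align("ACGTAACGT", "ACGTACGT", 3)
        assert aln.aligned_a.replace("-", "") == "ACGTAACGT"
        assert aln.aligned_b.replace("-", "") == "ACGTACGT"
        assert aln.score == 6  # 8 matches - one gap

    def test_band_violation_raises(self):
        with pytest.raises(seqcore.BandExceededError):
            seqcore.banded_global_align("A" * 30, "A" * 5, 10)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_full_dp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = random_seq(rng, 20)
        b = random_seq(rng, int(rng.integers(12, 21)))
        aln = seqcore.banded_global_align(a, b, 20)
        assert aln.score == pytest.approx(full_needleman_wunsch(a, b))


class TestDistances:
    @pytest.mark.parametrize("model", ["p", "jc", "tn93"])
    def test_identical_is_zero(self, model, rng):
        s = random_seq(rng, 300)
        assert seqcore.nucleotide_distance(s, s, model) == 0.0

    def test_p_distance_fraction(self):
        a = "A" * 90 + "C" * 10
        b = "A" * 90 + "G" * 10
        assert seqcore.nucleotide_distance(a, b, "p") == pytest.approx(0.10)

    def test_gap_and_n_columns_skipped(self):
        assert seqcore.nucleotide_distance("AC-GN", "ACTGN"[:5], "p") == 0.0

    def test_zero_comparable_columns(self):
        with pytest.raises(seqcore.UndefinedDistanceError):
            seqcore.nucleotide_distance("NNN", "ACG", "p")

    def test_p_le_tn93_and_symmetry(self, rng):
        a = random_seq(rng, 2000)
        b = list(a)
        for pos in rng.choice(2000, 200, replace=False):
            b[pos] = "ACGT"[("ACGT".index(b[pos]) + int(rng.integers(1, 4))) % 4]
        b = "".join(b)
        p = seqcore.nucleotide_distance(a, b, "p")
        t = seqcore.nucleotide_distance(a, b, "tn93")
        assert p <= t
        assert t == pytest.approx(seqcore.nucleotide_distance(b, a, "tn93"))

    def test_tn93_simulation_consistency(self):
        # pair simulated at a true distance of 0.12 with 2:1 transition bias
        from hybscan.synth import divergence_to_branch_length, _mutate
        from hybscan._util import encode, decode
        rng = np.random.default_rng(7)
        L = 50_000
        anc = rng.integers(0, 4, L).astype(np.uint8)
        b = 0.12
        x, y = anc.copy(), anc.copy()
        _mutate(x, b / 2, rng)
        _mutate(y, b / 2, rng)
        est = seqcore.nucleotide_distance(decode(x), decode(y), "tn93")
        assert est == pytest.approx(0.12, abs=0.005)
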