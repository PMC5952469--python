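import numpy as np
import pytest

from hybscan import synth, variants
from hybscan.seqio import Assembly
from hybscan.synth import ReadSet
from hybscan._util import encode
from conftest import random_seq


def make_matrix(strain_geno, ploidy, ref=0, depths=30):
    """Build a small SnpMatrix from {strain: [genotype per locus]} where a
    genotype is an int (haploid), a pair, or None (missing)."""
    strains = sorted(strain_geno)
    L = len(next(iter(strain_geno.values())))
    geno = np.full((len(strains), L, 2), -1, dtype=np.int8)
    for si, s in enumerate(strains):
        for li, g in enumerate(strain_geno[s]):
            if g is None:
                continue
            if isinstance(g, int):
                geno[si, li] = (g, -2)
            else:
                geno[si, li] = tuple(sorted(g))
    return variants.SnpMatrix(
        "ref", strains, dict(ploidy),
        np.array(["c1"] * L, dtype=object), np.arange(L),
        np.full(L, ref, dtype=np.int8), geno,
        np.full((len(strains), L), depths, dtype=np.int32),
        {s: float(depths) for s in strains})


@pytest.fixture(scope="module")
def toy():
    # one 4 kb contig; helper builds read sets carrying planted mutations
    ref_seq = random_seq(np.random.default_rng(42), 4000)
    ref = Assembly("R", [("c1", ref_seq)], "haploid")

    def reads_with(mutations, n_reads, seed, only_span=None):
        rng2 = np.random.default_rng(seed)
        seq = list(ref_seq)
        for pos, base in mutations:
            seq[pos] = base
        codes = encode("".join(seq))
        span = only_span or (0, 4000 - 150)
        starts = rng2.integers(span[0], span[1], n_reads)
        arr = codes[starts[:, None] + np.arange(150)[None, :]]
        return starts, arr

    return ref, ref_seq, reads_with


class TestPileupToyCases:
    def test_haploid_alt_call_and_diploid_het(self, toy):
        ref, ref_seq, reads_with = toy
        alt = "A" if ref_seq[1000] != "A" else "C"
        alt2 = "A" if ref_seq[2000] != "A" else "C"
        s_h, a_h = reads_with([(1000, alt)], 900, 1)
        s1, a1 = reads_with([], 450, 2)
        s2, a2 = reads_with([(2000, alt2)], 450, 3)
        hap = ReadSet("hap", a_h, ["c1"] * 900, s_h)
        dip = ReadSet("dip", np.vstack([a1, a2]), ["c1"] * 900,
                      np.concatenate([s1, s2]))
        m = variants.pileup_call({"hap": hap, "dip": dip}, ref,
                                 {"hap": 1, "dip": 2})
        loci = {int(p): i for i, p in enumerate(m.pos0)}
        gi = m.strain_index("hap")
        assert 1000 in loci
        g = m.genotypes[gi, loci[1000]]
        assert g[0] == "ACGT".index(alt) and g[1] == -2
        gi = m.strain_index("dip")
        g = m.genotypes[gi, loci[2000]]
        assert g[0] != g[1] and -1 not in g

    def test_low_depth_missing(self, toy):
        ref, ref_seq, reads_with = toy
        alt = "G" if ref_seq[500] != "G" else "T"
        s, a = reads_with([(500, alt)], 12, 7)   # ~0.4x depth: below min_depth
        rs = ReadSet("thin", a, ["c1"] * 12, s)
        m = variants.pileup_call({"thin": rs}, ref, {"thin": 2}, min_depth=8)
        for i, p in enumerate(m.pos0):
            if int(p) == 500:
                assert m.genotypes[0, i, 0] == -1

    def test_diploid_reference_refused(self, toy):
        ref, _, reads_with = toy
        s, a = reads_with([], 10, 9)
        rs = ReadSet("x", a, ["c1"] * 10, s)
        with pytest.raises(variants.ReferenceNotHaploidError):
            variants.pileup_call({"x": rs}, ref, {"x": 1, "R": 2})


@pytest.fixture(scope="module")
def called():
    cohort = synth.generate(synth.preset_scenario("trio", seed=21))
    reads = {s: cohort.reads(s) for s in cohort.strains()}
    m = variants.pileup_call(reads, cohort.assemblies["C"],
                             {"A": 2, "C": 1, "D": 1})
    t = variants.matrix_from_truth(cohort, "C")
    return cohort, m, t


class TestTrioTruthRecovery:
    def test_called_sites_are_true_variants(self, called):
        _, m, t = called
        called_sites = set(zip(m.contig, m.pos0))
        true_sites = set(zip(t.contig, t.pos0))
        assert len(called_sites & true_sites) / len(called_sites) >= 0.99
        # false calls as a fraction of all assessed reference positions
        n_false = len(called_sites - true_sites)
        assert n_false / 200_000 < 0.001

    def test_overall_genotype_concordance(self, called):
        _, m, t = called
        mf = variants.depth_filter(m)
        t_idx = {(c, p): i for i, (c, p) in enumerate(zip(t.contig, t.pos0))}
        match = tot = 0
        for si, sid in enumerate(mf.strain_ids):
            ti_s = t.strain_index(sid)
            for li, key in enumerate(zip(mf.contig, mf.pos0)):
                ti = t_idx.get(key)
                if ti is None or mf.genotypes[si, li, 0] < 0:
                    continue
                tot += 1
                match += (tuple(mf.genotypes[si, li])
                          == tuple(t.genotypes[ti_s, ti]))
        assert match / tot >= 0.98

    def test_depth_filter_raises_heterozygosity(self, called):
        _, m, _ = called
        mf = variants.depth_filter(m)
        assert (variants.heterozygous_fraction(mf, "A")
                >= variants.heterozygous_fraction(m, "A"))

    def test_depth_filter_rule(self):
        m = make_matrix({"d": [(0, 0), (0, 0), (0, 1)]}, {"d": 2})
        m.depths[0] = [30, 9, 45]      # median stored as 30
        kept = variants.depth_filter(m, low=0.5, high=2.0)
        assert list(kept.pos0) == [0, 2]


class TestDissimilarity:
    def test_identical_strains_zero(self):
        m = make_matrix({"a": [0, 1, 2], "b": [0, 1, 2]}, {"a": 1, "b": 1})
        D = variants.dissimilarity(m)
        assert D.loc["a", "b"] == 0.0

    def test_haploids_all_different(self):
        m = make_matrix({"a": [0, 1], "b": [1, 2]}, {"a": 1, "b": 1})
        assert variants.dissimilarity(m).loc["a", "b"] == 1.0

    def test_hand_computed_toy_matrix(self):
        # 3 strains x 4 loci; per-locus multiset dissimilarity, mean over
        # loci typed in both
        m = make_matrix({
            "h1": [0, 1, 2, None],
            "h2": [0, 2, 2, 3],
            "d1": [(0, 1), (1, 1), (0, 2), (3, 3)],
        }, {"h1": 1, "h2": 1, "d1": 2})
        D = variants.dissimilarity(m)
        assert D.loc["h1", "h2"] == pytest.approx((0 + 1 + 0) / 3)
        assert D.loc["h1", "d1"] == pytest.approx((0.5 + 0.5 + 0.5) / 3)
        assert D.loc["h2", "d1"] == pytest.approx((0.5 + 1.0 + 0.5 + 0.5) / 4)

    def test_order_invariance(self, rng):
        g = {f"s{i}": [int(x) for x in rng.integers(0, 4, 20)]
             for i in range(4)}
        m = make_matrix(g, {s: 1 for s in g})
        D1 = variants.dissimilarity(m)
        perm = rng.permutation(20)
        m2 = m.subset(perm)
        D2 = variants.dissimilarity(m2)
        assert np.allclose(D1.values, D2.values)

    def test_no_shared_loci_error(self):
        m = make_matrix({"a": [0, None], "b": [None, 1]}, {"a": 1, "b": 1})
        with pytest.raises(variants.UndefinedPairError):
            variants.dissimilarity(m)


class TestVcfRoundTrip:
    def test_single_locus_row_and_het_rendering(self, tmp_path):
        m = make_matrix({"d": [(0, 1)], "h": [0]}, {"d": 2, "h": 1})
        path = tmp_path / "v.tsv"
        variants.write_vcf_like(m, path)
        lines = path.read_text().splitlines()
        data = [l for l in lines if not l.startswith("#")]
        assert len(data) == 1
        assert "0/1" in data[0]
        assert data[0].split("\t")[1] == "1"   # 1-based position

    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(3)
        g = {"a": [int(x) for x in rng.integers(0, 4, 15)],
             "d": [(int(x), int(y)) for x, y in rng.integers(0, 4, (15, 2))]}
        g["d"][3] = None
        m = make_matrix(g, {"a": 1, "d": 2})
        path = tmp_path / "v.tsv"
        variants.write_vcf_like(m, path)
        back = variants.read_vcf_like(path)
        assert back.strain_ids == m.strain_ids
        assert np.array_equal(back.genotypes, m.genotypes)
        assert np.array_equal(back.pos0, m.pos0)
        assert np.array_equal(back.depths, m.depths)
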