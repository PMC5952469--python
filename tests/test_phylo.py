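import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from hybscan import phylo
from hybscan.phylo import FamilyMember, GeneFamily
from hybscan._util import encode
from conftest import random_seq


def random_binary_tree(labels, rng):
    """Random unrooted binary tree with random branch lengths, as newick."""
    nodes = [f"{lab}:{rng.uniform(0.1, 1.0):.3f}" for lab in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(0.1, 1.0):.3f}")
    return "(" + ",".join(nodes) + ");"


def dendropy_rf(nw1, nw2):
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=nw1, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=nw2, schema="newick", taxon_namespace=tns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(t1, t2)


class TestTreesAndRF:
    def test_nj_recovers_additive_four_leaf(self):
        # ((a:1,b:2):1.5,(c:1,d:3)) -> known pairwise distances
        labs = list("abcd")
        D = pd.DataFrame([[0, 3, 3.5, 5.5], [3, 0, 4.5, 6.5],
                          [3.5, 4.5, 0, 4], [5.5, 6.5, 4, 0]],
                         index=labs, columns=labs)
        t = phylo.nj_tree(D)
        assert t.bipartitions() == {frozenset({"c", "d"})}
        pat = t.patristic()
        assert np.allclose(pat.loc[labs, labs].values, D.values)

    def test_nj_three_leaves_closed_form(self):
        labs = list("abc")
        D = pd.DataFrame([[0, .3, .5], [.3, 0, .4], [.5, .4, 0]],
                         index=labs, columns=labs)
        pat = phylo.nj_tree(D).patristic()
        assert np.allclose(pat.loc[labs, labs].values, D.values)

    def test_rf_identical_zero(self, rng):
        nw = random_binary_tree(list("abcdefgh"), rng)
        t = phylo.parse_newick(nw)
        assert phylo.rf_normalized(t, t) == 0.0

    def test_rf_disjoint_five_leaf(self):
        t1 = phylo.parse_newick("((a:1,b:1):1,(c:1,d:1):1,e:1);")
        t2 = phylo.parse_newick("((a:1,c:1):1,(b:1,e:1):1,d:1);")
        assert phylo.rf_normalized(t1, t2) == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_rf_matches_independent_implementation(self, seed):
        rng = np.random.default_rng(seed)
        labs = list("abcdefgh")
        nw1 = random_binary_tree(labs, rng)
        nw2 = random_binary_tree(labs, rng)
        t1, t2 = phylo.parse_newick(nw1), phylo.parse_newick(nw2)
        expected = dendropy_rf(nw1, nw2) / (2 * (len(labs) - 3))
        assert phylo.rf_normalized(t1, t2) == pytest.approx(expected)

    def test_rf_metric_properties_on_triples(self, rng):
        labs = list("abcdefg")
        trees = [phylo.parse_newick(random_binary_tree(labs, rng))
                 for _ in range(5)]
        for x, y, z in itertools.combinations(trees, 3):
            dxy = phylo.rf_normalized(x, y)
            assert dxy == phylo.rf_normalized(y, x)
            assert dxy <= phylo.rf_normalized(x, z) + phylo.rf_normalized(z, y) + 1e-12

    def test_rf_leaf_mismatch(self, rng):
        t1 = phylo.parse_newick(random_binary_tree(list("abcd"), rng))
        t2 = phylo.parse_newick(random_binary_tree(list("abce"), rng))
        with pytest.raises(ValueError):
            phylo.rf_normalized(t1, t2)


class TestConsensus:
    def test_single_tree_is_itself(self, rng):
        t = phylo.parse_newick(random_binary_tree(list("abcdef"), rng))
        cons = phylo.consensus_tree([t])
        assert cons.bipartitions() == t.bipartitions()

    def test_two_of_three_majority(self):
        t1 = phylo.parse_newick("((a:1,b:1):1,(c:1,d:1):1,e:1);")
        t2 = phylo.parse_newick("((a:1,b:1):1,(c:1,e:1):1,d:1);")
        t3 = phylo.parse_newick("((a:1,b:1):1,(d:1,e:1):1,c:1);")
        cons = phylo.consensus_tree([t1, t2, t3])
        assert frozenset({"a", "b"}) in {frozenset(b) if "a" in b else b
                                         for b in cons.bipartitions()} or \
               any(b == frozenset({"c", "d", "e"}) for b in cons.bipartitions())
        assert len(cons.bipartitions()) == 1

    def test_exactly_half_excluded(self):
        t1 = phylo.parse_newick("((a:1,b:1):1,(c:1,d:1):1,e:1);")
        t2 = phylo.parse_newick("((a:1,c:1):1,(b:1,d:1):1,e:1);")
        cons = phylo.consensus_tree([t1, t2])
        assert cons.bipartitions() == set()   # each bipartition in exactly 1/2


class TestClusterCds:
    def test_trio_families_have_expected_membership(self, trio_cohort):
        fams = phylo.cluster_cds(trio_cohort.cds_by_strain())
        assert len(fams) == 150
        for fam in fams:
            assert fam.counts() == {"A": 2, "C": 1, "D": 1}

    def test_unrelated_cds_stay_separate(self, rng):
        class R:
            def __init__(self, g, c, s):
                self.gene_id, self.copy_tag, self.sequence = g, c, s
        cds = {"x": [R("g1", "c1", random_seq(rng, 500)),
                     R("g2", "c2", random_seq(rng, 500))]}
        fams = phylo.cluster_cds(cds)
        assert len(fams) == 2

    def test_identical_duplicates_merge(self, rng):
        class R:
            def __init__(self, g, c, s):
                self.gene_id, self.copy_tag, self.sequence = g, c, s
        s = random_seq(rng, 500)
        cds = {"x": [R("g1", "c1", s), R("g1b", "c2", s)]}
        fams = phylo.cluster_cds(cds)
        assert len(fams) == 1 and len(fams[0].members) == 2


class TestFilterCoreAndPhasing:
    def make_family(self, counts):
        members = []
        for sid, k in counts.items():
            for i in range(k):
                members.append(FamilyMember(sid, f"{sid}_ct{i}", "ACGT" * 50))
        return GeneFamily("f1", members)

    def test_correct_family_kept(self):
        fam = self.make_family({"d1": 2, "d2": 2, "h1": 1, "h2": 1})
        calls = {"d1": "diploid", "d2": "diploid", "h1": "haploid",
                 "h2": "haploid"}
        assert phylo.filter_core([fam], calls) == [fam]

    @pytest.mark.parametrize("counts", [
        {"d1": 1, "d2": 2, "h1": 1, "h2": 1},   # missing diploid copy
        {"d1": 3, "d2": 2, "h1": 1, "h2": 1},   # extra diploid copy
        {"d1": 2, "d2": 2, "h1": 2, "h2": 1},   # duplicated haploid
        {"d1": 2, "d2": 2, "h1": 1},            # absent strain
    ])
    def test_violations_dropped(self, counts):
        fam = self.make_family(counts)
        calls = {"d1": "diploid", "d2": "diploid", "h1": "haploid",
                 "h2": "haploid"}
        assert phylo.filter_core([fam], calls) == []

    def test_missing_ploidy_call_errors(self):
        fam = self.make_family({"d1": 2, "h1": 1})
        with pytest.raises(ValueError):
            phylo.filter_core([fam], {"d1": "diploid", "h1": "ambiguous"})

    def test_fuzzed_families_never_pass_when_violating(self, rng):
        calls = {"d1": "diploid", "d2": "diploid", "h1": "haploid"}
        want = {"d1": 2, "d2": 2, "h1": 1}
        for _ in range(50):
            counts = {s: int(rng.integers(0, 4)) for s in calls}
            fam = self.make_family({s: c for s, c in counts.items() if c})
            kept = phylo.filter_core([fam], calls)
            assert bool(kept) == (counts == want)


class TestAlignAndTrim:
    def fam(self, seqs):
        return GeneFamily("f", [FamilyMember(f"s{i}", "1" if i % 2 else "2", s)
                                for i, s in enumerate(seqs)])

    def test_identical_sequences_unchanged(self, rng):
        s = random_seq(rng, 300)
        mat, labels = phylo.align_and_trim(self.fam([s, s, s]))
        assert mat.shape == (3, 300)

    def test_gap_column_removed(self, rng):
        s = random_seq(rng, 300)
        deleted = s[:100] + s[101:]
        mat, _ = phylo.align_and_trim(self.fam([s, s, deleted]))
        assert mat.shape[1] == 299
        assert not (mat == 5).any()

    def test_noisy_stretch_removed_hand_oracle(self, rng):
        base = random_seq(rng, 300)
        # plant a 15-column fully random stretch at 100..115 in 3 of 6 copies
        seqs = []
        for i in range(6):
            s = list(base)
            if i < 3:
                for j in range(100, 115):
                    s[j] = "ACGT"[(("ACGT".index(s[j])) + 1 + i) % 4]
            seqs.append("".join(s))
        mat, _ = phylo.align_and_trim(self.fam(seqs), max_nonconserved=10)
        # hand-applied filter: columns 100..114 are non-conserved (3/6 max
        # residue count = 3, not > 3), a 15-long run > 10 -> masked
        assert mat.shape[1] == 285

    def test_short_blocks_dropped(self, rng):
        base = random_seq(rng, 60)
        seqs = [base]
        # every 3rd and 4th column non-conserved: conserved blocks of 2
        for i in range(5):
            s = list(base)
            for j in range(0, 60, 4):
                s[j] = "ACGT"[("ACGT".index(s[j]) + 1 + i) % 4]
                if j + 1 < 60:
                    s[j + 1] = "ACGT"[("ACGT".index(s[j + 1]) + 1 + i) % 4]
            seqs.append("".join(s))
        out = phylo.align_and_trim(self.fam(seqs), max_nonconserved=0,
                                   min_block=3)
        assert out is None   # all conserved blocks have length 2

    @pytest.mark.parametrize("L,diffs,expect", [
        (150, 20, False), (300, 20, True), (300, 3, False)])
    def test_usable_family(self, L, diffs, expect, rng):
        a = random_seq(rng, L)
        b = list(a)
        for pos in rng.choice(L, diffs, replace=False):
            b[pos] = "ACGT"[("ACGT".index(b[pos]) + 1) % 4]
        mat = np.stack([encode(a), encode("".join(b))])
        assert phylo.usable_family(mat) is expect


class TestClusterTrees:
    def test_identical_trees_one_cluster(self, rng):
        nw = random_binary_tree(list("abcdef"), rng)
        trees = {f"t{i}": phylo.parse_newick(nw) for i in range(10)}
        cl = phylo.cluster_trees(trees)
        assert cl.cluster_sizes() == [10]

    def test_two_topology_groups(self, rng):
        nw1 = "((a:1,b:1):1,(c:1,d:1):1,(e:1,f:1):1);"
        nw2 = "((a:1,c:1):1,(b:1,e:1):1,(d:1,f:1):1);"
        trees = {f"x{i}": phylo.parse_newick(nw1) for i in range(6)}
        trees |= {f"y{i}": phylo.parse_newick(nw2) for i in range(4)}
        cl = phylo.cluster_trees(trees)
        assert cl.cluster_sizes() == [6, 4]
        assert len(cl.consensus) == 2


class TestInferHybridizations:
    def test_trio_single_event(self):
        # hybrid X of haploids h1, h2 at divergence 0.1
        nw = "((X#1:0.004,h1:0.004):0.05,(X#2:0.004,h2:0.004):0.05);"
        t = phylo.parse_newick(nw)
        inf = phylo.infer_hybridizations([t], ["X"], ["h1", "h2"])
        assert inf.n_events == 1
        assert inf.parent_pair["X"] == ("h1", "h2")

    def test_shared_event_merged(self):
        nw = ("(((X#1:0.003,Y#1:0.003):0.004,h1:0.005):0.05,"
              "((X#2:0.003,Y#2:0.003):0.004,h2:0.005):0.05);")
        t = phylo.parse_newick(nw)
        inf = phylo.infer_hybridizations([t], ["X", "Y"], ["h1", "h2"])
        assert inf.n_events == 1
        assert inf.parent_pair["X"] == inf.parent_pair["Y"] == ("h1", "h2")

    def test_ambiguous_copies_flagged(self):
        # both copies in the same lineage group -> unassigned
        nw = "((X#1:0.001,X#2:0.001):0.05,(h1:0.004,h2:0.004):0.05);"
        t = phylo.parse_newick(nw)
        inf = phylo.infer_hybridizations([t], ["X"], ["h1", "h2"])
        assert inf.unassigned == ["X"]
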