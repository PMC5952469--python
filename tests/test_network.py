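import itertools

import numpy as np
import pandas as pd
import pytest

from hybscan import network, phylo


def tree_metric_5leaf():
    """Additive distances from ((a:1,b:2):3,(c:1.5,d:2.5):1,e:4)."""
    leaves = dict(a=("u", 1.0), b=("u", 2.0), c=("v", 1.5), d=("v", 2.5),
                  e=("r", 4.0))
    nd = {("u", "r"): 3.0, ("v", "r"): 1.0, ("u", "v"): 4.0}

    def node_d(x, y):
        return 0.0 if x == y else nd.get((x, y), nd.get((y, x)))

    labs = list("abcde")
    D = pd.DataFrame(0.0, index=labs, columns=labs)
    for x, y in itertools.combinations(labs, 2):
        nx, lx = leaves[x]
        ny, ly = leaves[y]
        D.loc[x, y] = D.loc[y, x] = lx + ly + node_d(nx, ny)
    return D


def circular_metric(taxa, splits, rng):
    """Sum of weighted circular splits of the ordering `taxa`."""
    n = len(taxa)
    D = np.zeros((n, n))
    weights = {}
    for side in splits:
        w = float(rng.uniform(0.1, 1.0))
        weights[frozenset(side)] = w
        mask = np.zeros(n, dtype=bool)
        mask[list(side)] = True
        D += w * (mask[:, None] ^ mask[None, :])
    return pd.DataFrame(D, index=taxa, columns=taxa), weights


class TestNeighborNet:
    def test_three_taxon_closed_form(self):
        D = pd.DataFrame([[0, .3, .5], [.3, 0, .4], [.5, .4, 0]],
                         index=list("abc"), columns=list("abc"))
        ss = network.neighbor_net(D)
        assert ss.weight_of({"a"}) == pytest.approx(0.2)
        assert ss.weight_of({"b"}) == pytest.approx(0.1)
        assert ss.weight_of({"c"}) == pytest.approx(0.3)

    def test_additive_tree_metric_recovery(self):
        D = tree_metric_5leaf()
        ss = network.neighbor_net(D)
        expected = {frozenset("a"): 1.0, frozenset("b"): 2.0,
                    frozenset("c"): 1.5, frozenset("d"): 2.5,
                    frozenset("e"): 4.0, frozenset("ab"): 3.0,
                    frozenset("cd"): 1.0}
        assert len(ss.splits) == 7
        for side, w in expected.items():
            assert ss.weight_of(side) == pytest.approx(w, abs=1e-6)
        assert np.abs(ss.split_metric().values - D.values).max() < 1e-6

    @pytest.mark.parametrize("seed", range(4))
    def test_circular_decomposable_recovery(self, seed):
        rng = np.random.default_rng(seed)
        taxa = list("abcdefg")
        n = len(taxa)
        arcs = [tuple(range(p, q + 1)) for p in range(1, n)
                for q in range(p, n)]
        chosen = [arcs[i] for i in rng.choice(len(arcs), 12, replace=False)]
        D, weights = circular_metric(taxa, chosen, rng)
        ss = network.neighbor_net(D)
        assert np.abs(ss.split_metric().values - D.values).max() < 1e-6
        for side, w in weights.items():
            got = ss.weight_of({taxa[i] for i in side})
            assert got == pytest.approx(w, abs=1e-6)

    def test_label_equivariance(self):
        D = tree_metric_5leaf()
        perm = ["c", "e", "a", "d", "b"]
        Dp = D.loc[perm, perm]
        s1 = network.neighbor_net(D)
        s2 = network.neighbor_net(Dp)
        w1 = {frozenset(s): round(w, 9) for s, w in s1.splits}
        w2 = {frozenset(s): round(w, 9) for s, w in s2.splits}
        canon1 = {frozenset(min(s, frozenset(D.index) - s, key=sorted)): w
                  for s, w in w1.items()}
        canon2 = {frozenset(min(s, frozenset(D.index) - s, key=sorted)): w
                  for s, w in w2.items()}
        assert canon1 == canon2

    def test_residual_not_worse_than_nj_tree(self):
        rng = np.random.default_rng(5)
        n = 6
        base = tree_metric_5leaf().values
        D = np.zeros((n, n))
        D[:5, :5] = base
        D[5, :5] = D[:5, 5] = rng.uniform(3, 8, 5)
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        labs = list("abcdef")
        Df = pd.DataFrame(D, index=labs, columns=labs)
        ss = network.neighbor_net(Df)
        res_net = ((ss.split_metric().values - D) ** 2).sum()
        tree = phylo.nj_tree(Df)
        res_tree = ((tree.patristic().loc[labs, labs].values - D) ** 2).sum()
        assert res_net <= res_tree + 1e-9

    def test_input_validation(self):
        with pytest.raises(ValueError):
            network.neighbor_net(np.zeros((2, 2)))
        bad = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]])
        with pytest.raises(ValueError):
            network.neighbor_net(bad)


class TestNexusRoundTrip:
    def test_three_taxon_file(self, tmp_path):
        D = pd.DataFrame([[0, .3, .5], [.3, 0, .4], [.5, .4, 0]],
                         index=list("abc"), columns=list("abc"))
        ss = network.neighbor_net(D)
        network.write_splits_nexus(ss, tmp_path / "s.nex")
        text = (tmp_path / "s.nex").read_text()
        assert "NSPLITS=3" in text and "CYCLE" in text

    def test_round_trip(self, tmp_path):
        ss = network.neighbor_net(tree_metric_5leaf())
        network.write_splits_nexus(ss, tmp_path / "s.nex")
        back = network.read_splits_nexus(tmp_path / "s.nex")
        assert back.order == ss.order
        got = {s: w for s, w in back.splits}
        for side, w in ss.splits:
            assert got[side] == pytest.approx(w, abs=1e-9)

    def test_empty_split_system(self, tmp_path, caplog):
        ss = network.SplitSystem(list("abc"), list("abc"), [])
        with caplog.at_level("WARNING", logger="hybscan"):
            network.write_splits_nexus(ss, tmp_path / "e.nex")
        back = network.read_splits_nexus(tmp_path / "e.nex")
        assert back.splits == []


class TestAgainstIndependentImplementation:
    @pytest.mark.parametrize("seed", [3, 11])
    def test_matches_phangorn_neighbor_net(self, seed, tmp_path):
        """Same split system and weights as the R phangorn implementation."""
        import subprocess
        rng = np.random.default_rng(seed)
        n = 7
        D = np.abs(rng.normal(0.3, 0.1, (n, n)))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        path = tmp_path / "D.tsv"
        np.savetxt(path, D, delimiter="\t")
        script = f'''
        suppressMessages(library(phangorn))
        D <- as.matrix(read.table("{path}"))
        rownames(D) <- colnames(D) <- paste0("t", 0:{n - 1})
        nn <- neighborNet(as.dist(D))
        cat("TIPS", paste(nn$tip.label, collapse=" "), "\\n")
        sp <- attr(nn, "splits"); if (is.null(sp)) sp <- nn$splits
        w <- attr(sp, "weights")
        for (i in seq_along(sp))
            cat("SPLIT", paste(sp[[i]], collapse=","), w[i], "\\n")
        '''
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr[-500:]
        tips, r_splits = [], {}
        for line in out.stdout.splitlines():
            parts = line.split()
            if parts and parts[0] == "TIPS":
                tips = parts[1:]
            elif parts and parts[0] == "SPLIT":
                side = frozenset(tips[int(i) - 1] for i in parts[1].split(","))
                r_splits[side] = float(parts[2])
        labels = [f"t{i}" for i in range(n)]
        ss = network.neighbor_net(pd.DataFrame(D, index=labels, columns=labels))
        full = frozenset(labels)

        def canon(side):
            comp = full - side
            return min(side, comp, key=lambda s: sorted(s))

        ours = {canon(s): w for s, w in ss.splits}
        theirs = {canon(s): w for s, w in r_splits.items() if w > 1e-8}
        assert set(ours) == set(theirs)
        for side in ours:
            assert ours[side] == pytest.approx(theirs[side], abs=1e-4)


class TestReticulationSignal:
    def test_cohort_distances_show_boxes(self, cohort12):
        from hybscan import variants
        m = variants.matrix_from_truth(cohort12, "C")
        D = variants.dissimilarity(m)
        ss = network.neighbor_net(D)
        nontrivial = [(s, w) for s, w in ss.splits
                      if 1 < len(s) < len(ss.taxa) - 1 and w > 1e-7]
        taxa = set(ss.taxa)

        def incompatible(s1, s2):
            a, b = set(s1), set(s2)
            return all([a & b, a - b, b - a, taxa - (a | b)])

        boxes = [(s1, s2) for (s1, _), (s2, _)
                 in itertools.combinations(nontrivial, 2)
                 if incompatible(s1, s2)]
        assert len(boxes) >= 1
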