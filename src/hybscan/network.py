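"""Neighbor-Net: a circular split system fitted to a distance matrix.

Neighbor-Net generalizes neighbor joining: instead of a tree it returns a
*circular split system* — an ordering of the taxa around a circle plus
weighted splits, each of which cuts a contiguous arc of the ordering.
Conflicting phylogenetic signal (e.g. hybridization) shows up as pairs of
incompatible splits with substantial weight ("boxes" in the drawn
network), whereas an additive (tree-like) matrix yields exactly the
tree's splits.

The implementation follows the published agglomerative scheme: components
of linked nodes are merged by a neighbor-joining-style criterion, paths of
three nodes are reduced with the 2/3-1/3 distance reduction, and the final
circular ordering is recovered by expanding the reductions in reverse.
Split weights are then fitted by non-negative least squares of the
circular split metric against the input distances.  Agglomeration ties
break towards the lowest-index pair so orderings are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from ._util import logger


@dataclass
class SplitSystem:
    taxa: list[str]
    order: list[str]                       # circular ordering of taxa
    splits: list[tuple[frozenset, float]]  # (one side as taxon set, weight)

    def n_nontrivial(self) -> int:
        n = len(self.taxa)
        return sum(1 for s, _ in self.splits if 1 < len(s) < n - 1)

    def split_metric(self) -> pd.DataFrame:
        """Distance matrix implied by the weighted splits."""
        n = len(self.taxa)
        idx = {t: i for i, t in enumerate(self.taxa)}
        m = np.zeros((n, n))
        for side, w in self.splits:
            mask = np.zeros(n, dtype=bool)
            mask[[idx[t] for t in side]] = True
            m += w * (mask[:, None] ^ mask[None, :])
        return pd.DataFrame(m, index=self.taxa, columns=self.taxa)

    def weight_of(self, side) -> float:
        side = frozenset(side)
        comp = frozenset(self.taxa) - side
        for s, w in self.splits:
            if s == side or s == comp:
                return w
        return 0.0


def _as_matrix(D) -> tuple[np.ndarray, list[str]]:
    if isinstance(D, pd.DataFrame):
        return D.to_numpy(dtype=float), list(D.index)
    D = np.asarray(D, dtype=float)
    return D, [f"t{i}" for i in range(len(D))]


def neighbor_net(D, taxa: list[str] | None = None,
                 epsilon: float = 1e-8) -> SplitSystem:
    """Build a circular split system from a symmetric dissimilarity matrix.

    Accepts a pandas DataFrame (labels from the index) or a square array.
    Splits with fitted weight < epsilon are dropped.
    """
    mat, labels = _as_matrix(D)
    if taxa is not None:
        labels = list(taxa)
    n = len(mat)
    if n < 3:
        raise ValueError("Neighbor-Net needs at least 3 taxa")
    if mat.shape != (n, n) or not np.allclose(mat, mat.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    if np.any(np.diag(mat) != 0) or np.any(mat < 0):
        raise ValueError("distances must be non-negative with zero diagonal")
    order_idx = _circular_ordering(mat)
    weights, splits_sides = _fit_weights(mat, order_idx, epsilon)
    order = [labels[i] for i in order_idx]
    splits = [(frozenset(labels[i] for i in side), float(w))
              for side, w in zip(splits_sides, weights) if w >= epsilon]
    logger.info("neighbor-net: %d taxa, %d splits (%d non-trivial)",
                n, len(splits),
                sum(1 for s, _ in splits if 1 < len(s) < n - 1))
    return SplitSystem(list(labels), order, splits)


# ---------------------------------------------------------------------------
# agglomeration


def _circular_ordering(D: np.ndarray) -> list[int]:
    n = len(D)
    if n == 3:
        return [0, 1, 2]
    d: dict[int, dict[int, float]] = {
        i: {j: float(D[i, j]) for j in range(n) if j != i} for i in range(n)}
    components: list[list[int]] = [[i] for i in range(n)]
    expansions: list[tuple[int, int, int, int, int]] = []
    next_id = n

    def cdist(ci: list[int], cj: list[int]) -> float:
        return float(np.mean([[d[x][y] for y in cj] for x in ci]))

    while len(components) > 1:
        N = len(components)
        # --- criterion 1: choose two components
        cd = np.zeros((N, N))
        for i in range(N):
            for j in range(i + 1, N):
                cd[i, j] = cd[j, i] = cdist(components[i], components[j])
        rowsum = cd.sum(axis=1)
        best, bi, bj = None, -1, -1
        for i in range(N):
            for j in range(i + 1, N):
                q = (N - 2) * cd[i, j] - rowsum[i] - rowsum[j]
                if best is None or q < best - 1e-14:
                    best, bi, bj = q, i, j
        c1, c2 = components[bi], components[bj]
        # --- criterion 2: choose one node in each chosen component
        others = [components[k] for k in range(N) if k not in (bi, bj)]
        single = c1 + c2
        m = len(others) + len(single)
        best2, bx, by = None, -1, -1
        for x in c1:
            for y in c2:
                s_x = (sum(cdist([x], o) for o in others)
                       + sum(d[x][z] for z in single if z != x))
                s_y = (sum(cdist([y], o) for o in others)
                       + sum(d[y][z] for z in single if z != y))
                q = (m - 2) * d[x][y] - s_x - s_y
                if best2 is None or q < best2 - 1e-14:
                    best2, bx, by = q, x, y
        # --- merge into a path with bx and by adjacent
        p1 = c1 if c1[-1] == bx else c1[::-1]
        p2 = c2 if c2[0] == by else c2[::-1]
        path = p1 + p2
        while len(path) > 2:
            a, b, c = path[0], path[1], path[2]
            u, v = next_id, next_id + 1
            next_id += 2
            du, dv = {}, {}
            for t in d:
                if t in (a, b, c):
                    continue
                du[t] = (2 / 3) * d[a][t] + (1 / 3) * d[b][t]
                dv[t] = (1 / 3) * d[b][t] + (2 / 3) * d[c][t]
            duv = (d[a][b] + d[a][c] + d[b][c]) / 3
            for t in list(d):
                if t in (a, b, c):
                    continue
                d[t][u], d[t][v] = du[t], dv[t]
            du[v] = dv[u] = duv
            d[u], d[v] = du, dv
            for t in (a, b, c):
                del d[t]
                for rest in d.values():
                    rest.pop(t, None)
            expansions.append((u, v, a, b, c))
            path = [u, v] + path[3:]
        components = ([components[k] for k in range(N) if k not in (bi, bj)]
                      + [path])
    # assemble the final cycle and expand reductions in reverse
    cycle: list[int] = [x for comp in components for x in comp]
    for u, v, a, b, c in reversed(expansions):
        iu = cycle.index(u)
        if cycle[(iu + 1) % len(cycle)] == v:
            repl = [a, b, c]
        else:
            iu = cycle.index(v)
            repl = [c, b, a]
        # cycle[iu], cycle[iu+1] replaced by repl (u side gets a)
        if iu + 1 < len(cycle):
            cycle = cycle[:iu] + repl + cycle[iu + 2:]
        else:
            cycle = repl[1:] + cycle[1:iu] + [repl[0]]
    return cycle


def _fit_weights(D: np.ndarray, order: list[int], epsilon: float):
    n = len(order)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    sides = []
    for p in range(1, n):
        for q in range(p, n):
            sides.append([order[t] for t in range(p, q + 1)])
    A = np.zeros((len(pairs), len(sides)))
    for si, side in enumerate(sides):
        mask = np.zeros(n, dtype=bool)
        mask[side] = True
        for pi, (i, j) in enumerate(pairs):
            A[pi, si] = mask[i] ^ mask[j]
    dvec = np.array([D[i, j] for i, j in pairs])
    w, _ = nnls(A, dvec)
    return w, sides


# ---------------------------------------------------------------------------
# NEXUS output (SplitsTree-compatible)


def write_splits_nexus(splits: SplitSystem, path) -> None:
    taxa = splits.taxa
    idx = {t: i + 1 for i, t in enumerate(taxa)}
    kept = splits.splits
    if not kept:
        logger.warning("split system is empty; writing a 0-split NEXUS file")
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN TAXA;\n")
        fh.write(f"DIMENSIONS NTAX={len(taxa)};\n")
        fh.write("TAXLABELS " + " ".join(taxa) + ";\nEND;\n\n")
        fh.write("BEGIN SPLITS;\n")
        fh.write(f"DIMENSIONS NTAX={len(taxa)} NSPLITS={len(kept)};\n")
        fh.write("FORMAT WEIGHTS=YES;\n")
        fh.write("CYCLE " + " ".join(str(idx[t]) for t in splits.order) + ";\n")
        fh.write("MATRIX\n")
        for i, (side, w) in enumerate(kept, start=1):
            members = sorted(idx[t] for t in side)
            fh.write(f"{i}\t{w:.10g}\t" + " ".join(map(str, members)) + ",\n")
        fh.write(";\nEND;\n")


def read_splits_nexus(path) -> SplitSystem:
    taxa: list[str] = []
    order: list[str] = []
    splits: list[tuple[frozenset, float]] = []
    with open(path) as fh:
        in_matrix = False
        for raw in fh:
            line = raw.strip()
            if line.upper().startswith("TAXLABELS"):
                taxa = line[len("TAXLABELS"):].strip().rstrip(";").split()
            elif line.upper().startswith("CYCLE"):
                order = [taxa[int(x) - 1]
                         for x in line[len("CYCLE"):].strip().rstrip(";").split()]
            elif line.upper().startswith("MATRIX"):
                in_matrix = True
            elif in_matrix:
                if line.startswith(";"):
                    in_matrix = False
                    continue
                parts = line.rstrip(",").split()
                w = float(parts[1])
                side = frozenset(taxa[int(x) - 1] for x in parts[2:])
                splits.append((side, w))
    return SplitSystem(taxa, order or list(taxa), splits)
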