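"""Core-gene families, distance trees, tree concordance and hybridization
inference.

Core genes are CDSs present in exactly two copies in every diploid and one
copy in every haploid: each diploid copy then proxies one subgenome.
Copies are phased onto subgenomes via the contig partition from the
heterozygosity module, so leaf labels like ``E#1``/``E#2`` mean the same
subgenome in every family and gene trees become comparable.  Trees are
built by neighbor joining on TN93 distances (a deterministic, desk-scale
replacement for likelihood inference; topology-level concordance is what
is consumed downstream).  Concordance is measured by normalized
Robinson-Foulds distance, trees are clustered by complete linkage at a
minimum within-cluster similarity, majority-rule consensus trees summarize
clusters, and hybridization events are read off the lineage groups that
the two copies of each diploid join.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ._util import encode, logger
from . import seqcore

# ---------------------------------------------------------------------------
# unrooted leaf-labelled trees


@dataclass
class Tree:
    """Unrooted tree: adjacency lists with branch lengths, labelled leaves."""

    adj: dict[int, list[tuple[int, float]]]
    leaves: dict[int, str]          # node id -> leaf label

    def leaf_labels(self) -> frozenset:
        return frozenset(self.leaves.values())

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each as the side without the reference
        (lexicographically smallest) leaf."""
        labels = self.leaf_labels()
        ref = min(labels)
        out = set()
        for a, b, _ in self._edges():
            side = self._leaves_beyond(a, b)
            if ref in side:
                side = labels - side
            if 1 < len(side) < len(labels) - 1:
                out.add(frozenset(side))
        return out

    def is_resolved(self) -> bool:
        return len(self.bipartitions()) == max(len(self.leaf_labels()) - 3, 0)

    def _edges(self):
        seen = set()
        for a, nbrs in self.adj.items():
            for b, ln in nbrs:
                if (b, a) not in seen:
                    seen.add((a, b))
                    yield a, b, ln

    def _leaves_beyond(self, a: int, b: int) -> frozenset:
        """Leaves on b's side of edge (a, b)."""
        stack, seen, out = [b], {a, b}, []
        while stack:
            node = stack.pop()
            if node in self.leaves:
                out.append(self.leaves[node])
            for nbr, _ in self.adj[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        return frozenset(out)

    def patristic(self) -> pd.DataFrame:
        labels = sorted(self.leaves.values())
        node_of = {lab: n for n, lab in self.leaves.items()}
        out = pd.DataFrame(0.0, index=labels, columns=labels)
        for lab in labels:
            dist = {node_of[lab]: 0.0}
            stack = [node_of[lab]]
            while stack:
                node = stack.pop()
                for nbr, ln in self.adj[node]:
                    if nbr not in dist:
                        dist[nbr] = dist[node] + ln
                        stack.append(nbr)
            for other in labels:
                out.loc[lab, other] = dist[node_of[other]]
        return out

    def newick(self) -> str:
        root = next(iter(self.adj))
        # prefer an internal node as the display root
        for n in self.adj:
            if n not in self.leaves:
                root = n
                break

        def sub(node, parent, length):
            children = [(nbr, ln) for nbr, ln in self.adj[node] if nbr != parent]
            if not children:
                return f"{self.leaves[node]}:{length:.6g}"
            inner = ",".join(sub(c, node, ln) for c, ln in children)
            if parent is None:
                return f"({inner})"
            return f"({inner}):{length:.6g}"

        return sub(root, None, 0.0) + ";"


def parse_newick(text: str) -> Tree:
    import dendropy
    dt = dendropy.Tree.get(data=text, schema="newick")
    adj: dict[int, list[tuple[int, float]]] = {}
    leaves: dict[int, str] = {}
    ids: dict = {}

    def nid(node):
        if node not in ids:
            ids[node] = len(ids)
            adj[ids[node]] = []
        return ids[node]

    for edge in dt.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        a, b = nid(edge.tail_node), nid(edge.head_node)
        ln = float(edge.length or 0.0)
        adj[a].append((b, ln))
        adj[b].append((a, ln))
    for leaf in dt.leaf_node_iter():
        leaves[nid(leaf)] = leaf.taxon.label
    # collapse a degree-2 artificial root if present
    for n, nbrs in list(adj.items()):
        if len(nbrs) == 2 and n not in leaves:
            (x, lx), (y, ly) = nbrs
            adj[x] = [(y, lx + ly) if p == n else (p, l) for p, l in adj[x]]
            adj[y] = [(x, lx + ly) if p == n else (p, l) for p, l in adj[y]]
            del adj[n]
    return Tree(adj, leaves)


def nj_tree(D: pd.DataFrame) -> Tree:
    """Neighbor joining; negative branch lengths are clamped to zero.

    Deterministic: joins break ties towards the lowest-index pair.
    """
    labels = list(D.index)
    n = len(labels)
    if n < 2:
        raise ValueError("need >= 2 taxa")
    d = D.to_numpy(dtype=float).copy()
    active = list(range(n))
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n)}
    leaves = {i: labels[i] for i in range(n)}
    next_id = n
    idx = {i: i for i in active}     # node -> row in d

    def connect(a, b, ln):
        ln = max(ln, 0.0)
        adj[a].append((b, ln))
        adj[b].append((a, ln))

    while len(active) > 3:
        m = len(active)
        rows = np.array([idx[a] for a in active])
        sub = d[np.ix_(rows, rows)]
        sums = sub.sum(axis=1)
        q = (m - 2) * sub - sums[:, None] - sums[None, :]
        np.fill_diagonal(q, np.inf)
        bi, bj = np.unravel_index(np.argmin(q), q.shape)
        if bi > bj:
            bi, bj = bj, bi
        a, b = active[bi], active[bj]
        dij = sub[bi, bj]
        la = dij / 2 + (sums[bi] - sums[bj]) / (2 * (m - 2))
        lb = dij - la
        u = next_id
        next_id += 1
        adj[u] = []
        connect(u, a, la)
        connect(u, b, lb)
        newd = (sub[bi] + sub[bj] - dij) / 2
        # grow matrix
        nd = np.zeros((d.shape[0] + 1, d.shape[0] + 1))
        nd[:-1, :-1] = d
        for pos, other in enumerate(active):
            nd[-1, idx[other]] = nd[idx[other], -1] = newd[pos]
        d = nd
        idx[u] = d.shape[0] - 1
        active = [x for x in active if x not in (a, b)] + [u]
    if len(active) == 3:
        a, b, c = active
        dab = d[idx[a], idx[b]]
        dac = d[idx[a], idx[c]]
        dbc = d[idx[b], idx[c]]
        u = next_id
        adj[u] = []
        connect(u, a, (dab + dac - dbc) / 2)
        connect(u, b, (dab + dbc - dac) / 2)
        connect(u, c, (dac + dbc - dab) / 2)
    elif len(active) == 2:
        a, b = active
        connect(a, b, d[idx[a], idx[b]])
    return Tree(adj, leaves)


def rf_normalized(t1: Tree, t2: Tree) -> float:
    """Normalized Robinson-Foulds distance in [0, 1].

    For two fully resolved unrooted trees the denominator is 2(n-3); for
    multifurcating trees it is the total number of non-trivial
    bipartitions in both.
    """
    if t1.leaf_labels() != t2.leaf_labels():
        raise ValueError("trees must share an identical leaf set")
    b1, b2 = t1.bipartitions(), t2.bipartitions()
    n = len(t1.leaf_labels())
    sym = len(b1 ^ b2)
    if len(b1) == len(b2) == max(n - 3, 0):
        denom = 2 * (n - 3)
    else:
        denom = len(b1) + len(b2)
    return sym / denom if denom else 0.0


def consensus_tree(trees: list[Tree], min_frequency: float = 0.5) -> Tree:
    """Majority-rule consensus: bipartitions in > min_frequency of trees.

    Branch lengths are the mean over the trees containing the bipartition
    (mean leaf-edge length for terminal edges).
    """
    if not trees:
        raise ValueError("need >= 1 tree")
    labels = trees[0].leaf_labels()
    for t in trees[1:]:
        if t.leaf_labels() != labels:
            raise ValueError("trees must share an identical leaf set")
    ref = min(labels)
    counts: dict[frozenset, list[float]] = {}
    for t in trees:
        for a, b, ln in t._edges():
            side = t._leaves_beyond(a, b)
            if ref in side:
                side = labels - side
            if 0 < len(side) < len(labels):
                counts.setdefault(frozenset(side), []).append(ln)
    thresh = min_frequency * len(trees)
    kept = {s: float(np.mean(v)) for s, v in counts.items()
            if len(v) > thresh and len(s) > 1 and len(s) < len(labels) - 1}
    leaf_len = {lab: float(np.mean(counts.get(frozenset([lab]), [0.0])))
                for lab in labels}
    # build the tree from the laminar family of kept clusters (all exclude ref)
    clusters = sorted(kept, key=len, reverse=True)
    adj: dict[int, list[tuple[int, float]]] = {0: []}
    leaves: dict[int, str] = {}
    node_of_cluster: dict[frozenset, int] = {}
    next_id = 1

    def parent_of(cl):
        best = None
        for other in clusters:
            if len(other) > len(cl) and cl < other:
                if best is None or len(other) < len(best):
                    best = other
        return node_of_cluster[best] if best is not None else 0

    for cl in clusters:
        node = next_id
        next_id += 1
        adj[node] = []
        node_of_cluster[cl] = node
    for cl in clusters:
        p = parent_of(cl)
        node = node_of_cluster[cl]
        ln = kept[cl]
        adj[p].append((node, ln))
        adj[node].append((p, ln))
    for lab in sorted(labels):
        holder = 0
        best = None
        for cl in clusters:
            if lab in cl and (best is None or len(cl) < len(best)):
                best = cl
        if best is not None:
            holder = node_of_cluster[best]
        node = next_id
        next_id += 1
        adj[node] = [(holder, leaf_len[lab])]
        adj[holder].append((node, leaf_len[lab]))
        leaves[node] = lab
    return Tree(adj, leaves)


# ---------------------------------------------------------------------------
# gene families


@dataclass
class FamilyMember:
    strain_id: str
    copy_tag: str       # contig id (pre-phasing) or subgenome tag
    sequence: str


@dataclass
class GeneFamily:
    family_id: str
    members: list[FamilyMember]
    passes_copy_rule: bool | None = None
    gene_ids: list[str] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m in self.members:
            out[m.strain_id] = out.get(m.strain_id, 0) + 1
        return out


def cluster_cds(cds_by_strain: dict[str, list], min_identity: float = 0.80,
                min_coverage: float = 0.60, k: int = 15) -> list[GeneFamily]:
    """Group CDSs into families = connected components of a similarity graph.

    An edge joins two CDSs when their (banded) alignment identity is
    >= min_identity over >= min_coverage of the shorter sequence.
    Candidate pairs are prefiltered by shared k-mers.
    """
    entries = []      # (strain, copy_tag, gene_id, codes)
    for sid in sorted(cds_by_strain):
        for rec in cds_by_strain[sid]:
            entries.append((sid, rec.copy_tag, rec.gene_id,
                            encode(rec.sequence), rec.sequence))
    n = len(entries)
    kmer_map: dict[int, list[int]] = {}
    for gi, (_, _, _, codes, _) in enumerate(entries):
        c = codes.astype(np.int64)
        L = len(c)
        if L < k:
            continue
        vals = np.zeros(L - k + 1, dtype=np.int64)
        for j in range(k):
            vals = vals * 4 + c[j:L - k + 1 + j]
        for v in np.unique(vals):
            kmer_map.setdefault(int(v), []).append(gi)
    cand = set()
    for lst in kmer_map.values():
        if 1 < len(lst) <= 64:
            for x, y in itertools.combinations(lst, 2):
                cand.add((x, y))
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for x, y in cand:
        if find(x) == find(y):
            continue
        sa, sb = entries[x][4], entries[y][4]
        short = min(len(sa), len(sb))
        if short < min_coverage * max(len(sa), len(sb)):
            continue
        if len(sa) == len(sb):
            ident = float(np.mean(entries[x][3] == entries[y][3]))
        else:
            aln = seqcore.banded_global_align(sa, sb, abs(len(sa) - len(sb)) + 16)
            ident = aln.identity
        if ident >= min_identity:
            parent[find(x)] = find(y)
    comps: dict[int, list[int]] = {}
    for gi in range(n):
        comps.setdefault(find(gi), []).append(gi)
    families = []
    for fi, members in enumerate(sorted(comps.values(), key=lambda m: m[0])):
        fam = GeneFamily(
            f"fam_{fi + 1:04d}",
            [FamilyMember(entries[m][0], entries[m][1], entries[m][4])
             for m in members],
            gene_ids=sorted({entries[m][2] for m in members}))
        families.append(fam)
    logger.info("clustered %d CDS into %d families", n, len(families))
    return families


def filter_core(families: list[GeneFamily],
                ploidy_calls: dict[str, str]) -> list[GeneFamily]:
    """Keep families with exactly 2 members per diploid, 1 per haploid."""
    strains = set(ploidy_calls)
    for sid, call in ploidy_calls.items():
        if call not in ("haploid", "diploid"):
            raise ValueError(f"strain {sid} has no usable ploidy call ({call})")
    kept = []
    for fam in families:
        counts = fam.counts()
        ok = set(counts) == strains and all(
            counts[s] == (2 if ploidy_calls[s] == "diploid" else 1)
            for s in strains)
        fam.passes_copy_rule = ok
        if ok:
            kept.append(fam)
    logger.info("%d/%d families pass the copy-number rule", len(kept),
                len(families))
    return kept


def phase_families(families: list[GeneFamily],
                   partitions: dict[str, "object"]) -> list[GeneFamily]:
    """Relabel diploid copies by subgenome so labels agree across families.

    Diploid members get copy tags ``1``/``2`` from the contig partition of
    their strain; when only one of the two copies sits on an assigned
    contig the other copy takes the opposite tag.  Families where both
    copies of some diploid remain unassignable are dropped.
    """
    out = []
    for fam in families:
        by_strain: dict[str, list[FamilyMember]] = {}
        for m in fam.members:
            by_strain.setdefault(m.strain_id, []).append(m)
        ok = True
        newmembers = []
        for sid, members in sorted(by_strain.items()):
            if sid not in partitions:
                newmembers.extend(members)   # haploid: label is the strain
                continue
            part = partitions[sid]
            tags = []
            for m in members:
                if m.copy_tag in part.group1:
                    tags.append(1)
                elif m.copy_tag in part.group2:
                    tags.append(2)
                else:
                    tags.append(0)
            if sorted(tags) == [1, 2]:
                pass
            elif 0 in tags and sum(tags) in (1, 2):
                tags = [tags[0] or (3 - tags[1]), tags[1] or (3 - tags[0])]
            else:
                ok = False
                break
            for m, t in zip(members, tags):
                newmembers.append(FamilyMember(sid, str(t), m.sequence))
        if ok:
            out.append(GeneFamily(fam.family_id, newmembers, True,
                                  fam.gene_ids))
    logger.info("phased %d/%d families onto subgenomes", len(out),
                len(families))
    return out


def member_label(m: FamilyMember) -> str:
    """Leaf label: strain alone for single-copy members, strain#subgenome
    for phased diploid copies."""
    if m.copy_tag in ("1", "2"):
        return f"{m.strain_id}#{m.copy_tag}"
    return m.strain_id


# ---------------------------------------------------------------------------
# alignment filtering (emulating conserved-block trimming)


def align_and_trim(family: GeneFamily, max_nonconserved: int = 10,
                   min_block: int = 3, allow_gaps: bool = False,
                   ) -> tuple[np.ndarray, list[str]] | None:
    """Star-align family members and trim to conserved gap-free blocks.

    The longest member anchors a star alignment (banded pairwise against
    the anchor; insertions relative to the anchor are discarded, which is
    equivalent under the no-gap column rule).  Column filtering then
    drops every column containing a gap (unless allow_gaps), masks runs of
    more than `max_nonconserved` consecutive non-conserved columns, and
    drops conserved blocks shorter than `min_block`.  Returns the trimmed
    column matrix and row labels, or None when nothing survives.
    """
    members = sorted(family.members, key=member_label)
    labels = [member_label(m) for m in members]
    anchor = max(members, key=lambda m: len(m.sequence))
    L = len(anchor.sequence)
    mat = np.full((len(members), L), 5, dtype=np.uint8)   # 5 = gap
    for row, m in enumerate(members):
        if m.sequence == anchor.sequence or len(m.sequence) == L:
            mat[row] = encode(m.sequence)
            continue
        aln = seqcore.banded_global_align(anchor.sequence, m.sequence,
                                          abs(L - len(m.sequence)) + 16)
        pos = 0
        arow = np.full(L, 5, dtype=np.uint8)
        for x, y in zip(aln.aligned_a, aln.aligned_b):
            if x != "-":
                arow[pos] = 5 if y == "-" else encode(y)[0]
                pos += 1
        mat[row] = arow
    nmem = len(members)
    has_gap = (mat == 5).any(axis=0)
    keep = ~has_gap if not allow_gaps else np.ones(L, dtype=bool)
    # conserved = a strict-majority residue
    conserved = np.zeros(L, dtype=bool)
    for col in np.flatnonzero(keep):
        vals, cnts = np.unique(mat[:, col], return_counts=True)
        conserved[col] = cnts.max() > nmem / 2
    # mask runs of more than max_nonconserved consecutive non-conserved
    # columns; gap columns (already excluded) break runs
    run = 0
    gap_cols = ~keep.copy()
    for col in range(L):
        if gap_cols[col]:
            run = 0
        elif conserved[col]:
            run = 0
        else:
            run += 1
            if run > max_nonconserved:
                keep[col - run + 1:col + 1] = False
    # drop conserved blocks shorter than min_block
    kept_idx = np.flatnonzero(keep)
    if len(kept_idx) == 0:
        logger.info("family %s empty after trimming", family.family_id)
        return None
    blocks = np.split(kept_idx, np.flatnonzero(np.diff(kept_idx) > 1) + 1)
    final = np.concatenate([b for b in blocks if len(b) >= min_block]) \
        if any(len(b) >= min_block for b in blocks) else np.empty(0, dtype=int)
    if len(final) == 0:
        logger.info("family %s empty after trimming", family.family_id)
        return None
    return mat[:, final], labels


def usable_family(trimmed: np.ndarray, min_len: int = 200,
                  min_mean_diffs: float = 15.0) -> bool:
    """Alignment usable iff longer than min_len with enough mean pairwise
    differences."""
    nmem, L = trimmed.shape
    if L <= min_len:
        return False
    diffs = [int(np.sum(trimmed[i] != trimmed[j]))
             for i in range(nmem) for j in range(i + 1, nmem)]
    return float(np.mean(diffs)) >= min_mean_diffs


def build_tree(trimmed: np.ndarray, labels: list[str],
               model: str = "tn93") -> Tree | None:
    """NJ tree from pairwise model distances on the trimmed alignment.

    Returns None (family dropped) when any pairwise distance saturates.
    """
    from ._util import decode
    nmem = len(labels)
    D = np.zeros((nmem, nmem))
    rows = [decode(trimmed[i]) for i in range(nmem)]
    for i in range(nmem):
        for j in range(i + 1, nmem):
            try:
                d = seqcore.nucleotide_distance(rows[i], rows[j], model)
            except seqcore.UndefinedDistanceError:
                return None
            if d >= 5.0:
                logger.info("saturated distance %s-%s; family dropped",
                            labels[i], labels[j])
                return None
            D[i, j] = D[j, i] = d
    return nj_tree(pd.DataFrame(D, index=labels, columns=labels))


# ---------------------------------------------------------------------------
# concordance clustering and hybridization inference


@dataclass
class TreeClustering:
    tree_ids: list[str]
    rf_matrix: np.ndarray
    assignment: np.ndarray            # cluster id per tree, 0 = largest
    consensus: dict[int, Tree]

    def cluster_sizes(self) -> list[int]:
        ids, counts = np.unique(self.assignment, return_counts=True)
        return sorted(counts.tolist(), reverse=True)


def cluster_trees(trees: dict[str, Tree],
                  min_similarity: float = 0.80) -> TreeClustering:
    """Complete-linkage clustering of trees at 1 - nRF >= min_similarity.

    Complete linkage guarantees that every within-cluster pair satisfies
    the minimum-similarity bound.  Clusters are renumbered by size
    (0 = largest) and each receives a majority-rule consensus tree.
    """
    ids = sorted(trees)
    if len(ids) < 2:
        raise ValueError("need >= 2 trees")
    n = len(ids)
    base = trees[ids[0]].leaf_labels()
    for tid in ids[1:]:
        if trees[tid].leaf_labels() != base:
            raise ValueError(f"tree {tid} has a different leaf set")
    rf = np.zeros((n, n))
    bips = {tid: trees[tid].bipartitions() for tid in ids}
    resolved = {tid: trees[tid].is_resolved() for tid in ids}
    nl = len(trees[ids[0]].leaf_labels())
    for i in range(n):
        for j in range(i + 1, n):
            b1, b2 = bips[ids[i]], bips[ids[j]]
            sym = len(b1 ^ b2)
            if resolved[ids[i]] and resolved[ids[j]]:
                denom = 2 * (nl - 3)
            else:
                denom = len(b1) + len(b2)
            rf[i, j] = rf[j, i] = sym / denom if denom else 0.0
    z = linkage(squareform(rf, checks=False), method="complete")
    raw = fcluster(z, t=1 - min_similarity, criterion="distance")
    order = sorted(set(raw), key=lambda c: (-np.sum(raw == c), c))
    remap = {c: i for i, c in enumerate(order)}
    assignment = np.array([remap[c] for c in raw])
    consensus = {}
    for c in sorted(set(assignment)):
        members = [trees[ids[i]] for i in np.flatnonzero(assignment == c)]
        consensus[c] = consensus_tree(members, 0.5)
    return TreeClustering(ids, rf, assignment, consensus)


@dataclass
class HybridizationInference:
    parent_pair: dict[str, tuple[str, str]]   # diploid -> lineage group names
    groups: dict[str, list[str]]              # group name -> leaf labels
    n_events: int
    unassigned: list[str] = field(default_factory=list)


def infer_hybridizations(trees: list[Tree], diploids: list[str],
                         haploids: list[str],
                         group_cutoff: float = 0.02) -> HybridizationInference:
    """Read hybridization events off concordant gene trees.

    Leaves are grouped into parental lineages by single-linkage on the
    mean patristic distance (cutoff `group_cutoff` substitutions/site —
    well below any lineage divergence, well above within-lineage noise).
    Each diploid's parent pair is the pair of groups holding its two
    copies; the event count is the number of distinct parent pairs, with
    diploids sharing both parents merged into one event.  Groups
    containing a sequenced haploid are named after it; unsampled lineage
    groups get stable synthetic names (L1, L2, ...).
    """
    if not trees:
        raise ValueError("need >= 1 tree")
    mean_d = trees[0].patristic()
    for t in trees[1:]:
        mean_d = mean_d + t.patristic().loc[mean_d.index, mean_d.columns]
    mean_d = mean_d / len(trees)
    labels = list(mean_d.index)
    # single-linkage groups under the cutoff
    n = len(labels)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    dmat = mean_d.to_numpy()
    for i in range(n):
        for j in range(i + 1, n):
            if dmat[i, j] < group_cutoff:
                parent[find(i)] = find(j)
    comps: dict[int, list[str]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(labels[i])
    groups: dict[str, list[str]] = {}
    anon = 0
    for members in sorted(comps.values(), key=lambda m: sorted(m)[0]):
        named = sorted(set(members) & set(haploids))
        if named:
            gname = "+".join(named)
        else:
            anon += 1
            gname = f"L{anon}"
        groups[gname] = sorted(members)
    group_of = {leaf: g for g, mem in groups.items() for leaf in mem}
    pairs: dict[str, tuple[str, str]] = {}
    unassigned = []
    for did in diploids:
        copies = [f"{did}#1", f"{did}#2"]
        gs = [group_of.get(c) for c in copies]
        if None in gs or gs[0] == gs[1]:
            unassigned.append(did)
            continue
        pairs[did] = tuple(sorted(gs))
    n_events = len({p for p in pairs.values()})
    logger.info("inferred %d hybridization events for %d diploids "
                "(%d unassigned)", n_events, len(diploids), len(unassigned))
    return HybridizationInference(pairs, groups, n_events, unassigned)
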