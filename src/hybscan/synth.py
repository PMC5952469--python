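"""Synthetic cohorts of haploid lineages and hybrid diploids, with truth.

The generator emulates the study system: a clonal fungal species in which
haploid lineages diverge by roughly 4-15% substitutions and diploid strains
arise by intraspecific hybridization — the union of two haploid genomes in
one nucleus, with essentially no recombination afterwards.  A scenario is
described by a lineage tree (newick, branch lengths in expected
substitutions per site), a list of hybridization events pairing two leaf
lineages into a named diploid strain, and sequencing parameters.  Planted
single-copy marker genes (orthology proxies) and core genes are laid down
in the common ancestor so that every haploid lineage carries one diverged
copy at homologous coordinates and every hybrid carries two.

Substitutions follow a K2P-like process with a 2:1 transition bias, so
that distance estimation under TN93 is exercised non-trivially.  Indels
are optional (off in the presets) and are placed outside planted features
so that feature coordinates remain exact ground truth.  Reads are sampled
uniformly from the forward strand with a flat per-base error rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import dendropy
import numpy as np

from ._util import decode, encode, logger, rng_from, spawn_seeds
from .seqio import Assembly

TRANSITION = np.array([2, 3, 0, 1], dtype=np.uint8)  # A<->G, C<->T via code^2
TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]], dtype=np.uint8)


# ---------------------------------------------------------------------------
# scenario description and ground truth containers


@dataclass
class ScenarioSpec:
    """Everything needed to generate one synthetic cohort."""

    name: str
    lineage_tree: str                      # newick over haploid lineage names
    hybridizations: list[tuple[str, str, str]]  # (parent1, parent2, diploid id)
    haploid_strains: list[str]             # leaves that are sequenced as strains
    genome_size: int = 200_000
    n_contigs: int = 10
    n_markers: int = 60
    marker_length: int = 400
    n_core_genes: int = 150
    gene_length: int = 600
    gc: float = 0.535
    indel_rate: float = 0.0                # events per site per unit branch length
    indel_mean_length: float = 3.0
    #: substitutions/site accumulated by a hybrid ancestor between the
    #: hybridization event and the split of the strains it produced
    event_drift: float = 0.008
    #: substitutions/site accumulated independently by every sequenced
    #: strain (and, within diploids, by each subgenome copy) afterwards
    strain_drift: float = 0.004
    coverage: float = 30.0
    read_length: int = 150
    error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.indel_rate < 0.5 and 0 <= self.error_rate < 0.5):
            raise ValueError("rates must lie in [0, 0.5)")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.genome_size < self.n_contigs * 1000:
            raise ValueError("genome_size must allow >= 1 kb per contig")
        leaves = set(self.leaf_names())
        for p1, p2, did in self.hybridizations:
            if p1 not in leaves or p2 not in leaves:
                raise ValueError(f"hybrid {did} parents must be tree leaves")

    def leaf_names(self) -> list[str]:
        tree = dendropy.Tree.get(data=self.lineage_tree, schema="newick")
        return [lf.taxon.label for lf in tree.leaf_node_iter()]

    def diploid_strains(self) -> list[str]:
        return [did for _, _, did in self.hybridizations]

    def strains(self) -> list[str]:
        return sorted(self.haploid_strains + self.diploid_strains())


@dataclass
class Feature:
    kind: str        # "marker" | "gene"
    feature_id: str
    contig_id: str   # ancestral contig
    start: int       # 0-based, half-open, in lineage coordinates
    end: int


@dataclass
class Truth:
    """Ground truth sufficient to score every downstream inference."""

    lineage_tree: str
    hybrid_parents: dict[str, tuple[str, str]]
    # (strain, strain contig id) -> (parent lineage, ancestral contig id)
    contig_source: dict[tuple[str, str], tuple[str, str]]
    # lineage -> contig -> list of Feature (coordinates in that lineage)
    features: dict[str, dict[str, list[Feature]]]
    lineage_distances: dict[tuple[str, str], float]   # expected path lengths
    realized_distances: dict[tuple[str, str], float]  # p-distance between leaves
    mutations: dict[str, np.ndarray]  # lineage -> mutated ancestral positions

    def contig_parent(self, strain: str, contig_id: str) -> str:
        return self.contig_source[(strain, contig_id)][0]

    def n_events(self) -> int:
        return len({frozenset(p) for p in self.hybrid_parents.values()})


@dataclass
class ReadSet:
    """Simulated single-end reads for one strain, as coded arrays."""

    strain_id: str
    codes: np.ndarray          # (n_reads, read_length) uint8
    origin_contig: list[str]   # truth: source contig per read
    origin_pos: np.ndarray     # truth: 0-based start in the source contig

    def __len__(self) -> int:
        return len(self.codes)

    def sequences(self) -> list[str]:
        return [decode(row) for row in self.codes]

    def to_fastq(self, path, quality: int = 30) -> None:
        q = chr(33 + quality)
        with open(path, "w") as fh:
            for i, row in enumerate(self.codes):
                seq = decode(row)
                fh.write(f"@{self.strain_id}_r{i}\n{seq}\n+\n{q * len(seq)}\n")


def read_fastq(path, strain_id: str) -> ReadSet:
    """Load single-end reads of uniform length into a :class:`ReadSet`."""
    seqs = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            seqs.append(encode(seq))
    codes = np.vstack(seqs)
    n = len(seqs)
    return ReadSet(strain_id, codes, ["?"] * n, np.full(n, -1))


# ---------------------------------------------------------------------------
# elementary generators


def simulate_ancestor(genome_size: int, n_contigs: int, gc: float = 0.535,
                      seed=0) -> Assembly:
    """I.i.d. ancestral genome at the requested GC, split into contigs."""
    rng = rng_from(seed)
    weights = rng.dirichlet(np.full(n_contigs, 5.0))
    sizes = np.maximum((weights * genome_size).astype(int), 1000)
    sizes[-1] += genome_size - sizes.sum()
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    contigs = []
    for i, size in enumerate(sizes):
        codes = rng.choice(4, size=int(size), p=probs).astype(np.uint8)
        contigs.append((f"anc_{i + 1}", decode(codes)))
    return Assembly("ancestor", contigs)


def plant_markers(ancestor: Assembly, n_markers: int, gene_length: int,
                  seed=0, kind: str = "marker",
                  reserved: dict[str, list[Feature]] | None = None,
                  ) -> tuple[list[tuple[str, str]], dict[str, list[Feature]]]:
    """Designate non-overlapping marker intervals in the ancestral genome.

    Returns the ancestral marker sequences (the marker FASTA content) and
    the per-contig feature lists.  Because markers are planted before
    lineage divergence, each haploid descendant carries exactly one
    diverged copy at homologous coordinates and each hybrid carries two.
    """
    rng = rng_from(seed)
    contig_ids = [cid for cid, _ in ancestor.contigs]
    lengths = {cid: len(seq) for cid, seq in ancestor.contigs}
    occupied = {cid: sorted((f.start, f.end) for f in (reserved or {}).get(cid, []))
                for cid in contig_ids}
    features: dict[str, list[Feature]] = {cid: [] for cid in contig_ids}
    seqs = ancestor.contig_dict()
    records = []
    for i in range(n_markers):
        fid = f"{kind}_{i + 1:03d}"
        placed = False
        order = rng.permutation(len(contig_ids))
        for ci in order:
            cid = contig_ids[ci]
            spot = _find_slot(lengths[cid], gene_length, occupied[cid], rng)
            if spot is not None:
                occupied[cid].append((spot, spot + gene_length))
                occupied[cid].sort()
                features[cid].append(Feature(kind, fid, cid, spot, spot + gene_length))
                records.append((fid, seqs[cid][spot:spot + gene_length]))
                placed = True
                break
        if not placed:
            raise ValueError(f"insufficient space to plant {fid}")
    return records, features


def _find_slot(contig_len, flen, occupied, rng, tries=40):
    for _ in range(tries):
        pos = int(rng.integers(0, max(contig_len - flen, 1)))
        if all(pos + flen <= s or pos >= e for s, e in occupied):
            return pos
    return None


def evolve_lineages(ancestor: Assembly, lineage_tree: str, seed=0,
                    indel_rate: float = 0.0, indel_mean_length: float = 3.0,
                    features: dict[str, list[Feature]] | None = None,
                    ) -> tuple[dict[str, Assembly], Truth]:
    """Evolve the ancestor along a newick lineage tree.

    Branch lengths are expected substitutions per site; per branch the
    number of mutated sites is Binomial(L, 1 - e^-b) and substitutions use
    a 2:1 transition bias.  Indels (optional) are placed outside planted
    features so feature coordinates remain exact.  Returns one Assembly
    per leaf lineage plus a partially filled :class:`Truth`.
    """
    rng = rng_from(seed)
    tree = dendropy.Tree.get(data=lineage_tree, schema="newick")
    boundaries, anc_codes = _concat(ancestor)
    feat0 = {cid: list((features or {}).get(cid, [])) for cid, _ in ancestor.contigs}

    leaf_codes: dict[str, np.ndarray] = {}
    leaf_feats: dict[str, dict[str, list[Feature]]] = {}

    def walk(node, genome, feats):
        for child in node.child_nodes():
            b = child.edge.length or 0.0
            g = genome.copy()
            f = {cid: list(v) for cid, v in feats.items()}
            _mutate(g, b, rng)
            if indel_rate > 0 and b > 0:
                g, f = _apply_indels(g, f, boundaries, b * indel_rate,
                                     indel_mean_length, rng)
            if child.is_leaf():
                name = child.taxon.label
                leaf_codes[name] = g
                leaf_feats[name] = f
            else:
                walk(child, g, f)

    walk(tree.seed_node, anc_codes.copy(), feat0)

    assemblies = {}
    for name, codes in leaf_codes.items():
        contigs = _split(codes, boundaries, [cid for cid, _ in ancestor.contigs])
        assemblies[name] = Assembly(name, contigs, "haploid")

    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    names = sorted(leaf_codes)
    lineage_d, realized_d, mutations = {}, {}, {}
    for i, a in enumerate(names):
        if len(leaf_codes[a]) == len(anc_codes):
            mutations[a] = np.flatnonzero(leaf_codes[a] != anc_codes)
        for b in names[i + 1:]:
            lineage_d[(a, b)] = lineage_d[(b, a)] = float(
                pdm.distance(taxa[a], taxa[b]))
            if len(leaf_codes[a]) == len(leaf_codes[b]):
                p = float(np.mean(leaf_codes[a] != leaf_codes[b]))
                realized_d[(a, b)] = realized_d[(b, a)] = p
    truth = Truth(lineage_tree, {}, {}, leaf_feats, lineage_d, realized_d,
                  mutations)
    return assemblies, truth


def _concat(assembly: Assembly):
    offsets = {}
    pos = 0
    parts = []
    for cid, seq in assembly.contigs:
        offsets[cid] = (pos, pos + len(seq))
        parts.append(encode(seq))
        pos += len(seq)
    return offsets, np.concatenate(parts)


def _split(codes, boundaries, order):
    return [(cid, decode(codes[boundaries[cid][0]:boundaries[cid][1]]))
            for cid in order]


def _mutate(genome: np.ndarray, branch_length: float, rng) -> None:
    if branch_length <= 0:
        return
    L = len(genome)
    p_hit = 1 - math.exp(-branch_length)
    m = rng.binomial(L, p_hit)
    if m == 0:
        return
    pos = rng.choice(L, size=m, replace=False)
    orig = genome[pos]
    is_transition = rng.random(m) < 0.5
    new = np.where(is_transition, TRANSITION[orig],
                   TRANSVERSIONS[orig, rng.integers(0, 2, m)])
    genome[pos] = new.astype(np.uint8)


def _apply_indels(genome, feats, boundaries, rate, mean_len, rng):
    # indel events avoid planted features and contig boundaries; the genome
    # is rebuilt contig by contig so downstream coordinates stay consistent
    out_parts = []
    new_feats = {}
    new_boundaries = {}
    pos0 = 0
    for cid, (s, e) in boundaries.items():
        contig = genome[s:e]
        flist = sorted(feats.get(cid, []), key=lambda f: f.start)
        n_ev = rng.poisson(rate * (e - s))
        events = []
        for _ in range(n_ev):
            ln = 1 + rng.geometric(1.0 / mean_len)
            p = int(rng.integers(0, len(contig)))
            kind = "ins" if rng.random() < 0.5 else "del"
            span = (p, p + (ln if kind == "del" else 0))
            if any(f.start - 1 < span[1] and span[0] < f.end + 1 for f in flist):
                continue
            if span[1] >= len(contig):
                continue
            events.append((p, ln, kind))
        for p, ln, kind in sorted(events, reverse=True):
            if kind == "del":
                contig = np.concatenate([contig[:p], contig[p + ln:]])
                shift = -ln
            else:
                ins = rng.integers(0, 4, ln).astype(np.uint8)
                contig = np.concatenate([contig[:p], ins, contig[p:]])
                shift = ln
            flist = [replace(f, start=f.start + shift, end=f.end + shift)
                     if f.start >= p else f for f in flist]
        new_feats[cid] = flist
        out_parts.append(contig)
        new_boundaries[cid] = (pos0, pos0 + len(contig))
        pos0 += len(contig)
    # note: boundaries dict passed by caller is ancestral; rebuild genome with
    # updated boundaries only if lengths changed
    boundaries.clear()
    boundaries.update(new_boundaries)
    return np.concatenate(out_parts), new_feats


def _drift_assembly(assembly: Assembly, amount: float, rng) -> Assembly:
    """Apply post-divergence substitutions to every contig independently."""
    if amount <= 0:
        return assembly
    contigs = []
    for cid, seq in assembly.contigs:
        codes = encode(seq)
        _mutate(codes, amount, rng)
        contigs.append((cid, decode(codes)))
    return Assembly(assembly.strain_id, contigs, assembly.ploidy_label)


def make_hybrid(haploid_a: Assembly, haploid_b: Assembly, diploid_id: str,
                shuffle_seed=0) -> tuple[Assembly, dict[tuple[str, str], tuple[str, str]]]:
    """Union of two haploid genomes: relabeled, order-shuffled contigs.

    Returns the diploid assembly and the contig-source map
    (diploid_id, new contig id) -> (parent lineage, ancestral contig id).
    """
    rng = rng_from(shuffle_seed)
    pool = ([(haploid_a.strain_id, cid, seq) for cid, seq in haploid_a.contigs]
            + [(haploid_b.strain_id, cid, seq) for cid, seq in haploid_b.contigs])
    order = rng.permutation(len(pool))
    contigs, source = [], {}
    for rank, idx in enumerate(order):
        parent, anc_cid, seq = pool[idx]
        new_cid = f"{diploid_id}_c{rank + 1:02d}"
        contigs.append((new_cid, seq))
        source[(diploid_id, new_cid)] = (parent, anc_cid)
    return Assembly(diploid_id, contigs, "diploid"), source


def simulate_reads(assembly: Assembly, coverage: float, read_length: int = 150,
                   error_rate: float = 0.005, seed=0) -> ReadSet:
    """Uniform single-end reads with a flat per-base error rate."""
    rng = rng_from(seed)
    if min(len(s) for _, s in assembly.contigs) < read_length:
        raise ValueError("read_length exceeds the shortest contig")
    all_codes, contigs_out, pos_out = [], [], []
    for cid, seq in assembly.contigs:
        codes = encode(seq)
        n_reads = int(round(coverage * len(seq) / read_length))
        starts = rng.integers(0, len(seq) - read_length + 1, n_reads)
        reads = codes[starts[:, None] + np.arange(read_length)[None, :]].copy()
        if error_rate > 0:
            errs = rng.random(reads.shape, dtype=np.float32) < error_rate
            n_err = int(errs.sum())
            if n_err:
                shift = rng.integers(1, 4, n_err).astype(np.uint8)
                reads[errs] = (reads[errs] + shift) % 4
        all_codes.append(reads)
        contigs_out.extend([cid] * n_reads)
        pos_out.append(starts)
    return ReadSet(assembly.strain_id, np.vstack(all_codes), contigs_out,
                   np.concatenate(pos_out))


# ---------------------------------------------------------------------------
# whole-cohort orchestration


@dataclass
class CdsRecord:
    strain_id: str
    gene_id: str
    contig_id: str
    copy_tag: str      # provisional copy label (contig-derived, not phased)
    start: int
    end: int
    sequence: str


@dataclass
class SyntheticCohort:
    spec: ScenarioSpec
    assemblies: dict[str, Assembly]            # strain -> assembly
    lineage_assemblies: dict[str, Assembly]    # all leaf lineages
    markers: list[tuple[str, str]]             # ancestral marker FASTA records
    truth: Truth

    def strains(self) -> list[str]:
        return sorted(self.assemblies)

    def reads(self, strain_id: str, coverage: float | None = None) -> ReadSet:
        """Simulate (deterministically per scenario seed) reads for a strain."""
        idx = self.strains().index(strain_id)
        seed = spawn_seeds(self.spec.seed + 7_001, len(self.assemblies))[idx]
        return simulate_reads(self.assemblies[strain_id],
                              coverage or self.spec.coverage,
                              self.spec.read_length, self.spec.error_rate, seed)

    def cds_records(self, strain_id: str) -> list[CdsRecord]:
        """Planted core-gene sequences for one strain (annotation truth)."""
        out = []
        asm = self.assemblies[strain_id]
        seqs = asm.contig_dict()
        for cid in seqs:
            lineage, anc_cid = self.truth.contig_source[(strain_id, cid)]
            for f in self.truth.features[lineage][anc_cid]:
                if f.kind != "gene":
                    continue
                out.append(CdsRecord(strain_id, f.feature_id, cid, cid,
                                     f.start, f.end,
                                     seqs[cid][f.start:f.end]))
        return sorted(out, key=lambda r: (r.gene_id, r.contig_id))

    def cds_by_strain(self) -> dict[str, list[CdsRecord]]:
        return {s: self.cds_records(s) for s in self.strains()}


def generate(spec: ScenarioSpec) -> SyntheticCohort:
    """Generate a full cohort (assemblies + truth) from a scenario spec."""
    s_anc, s_feat, s_evo, s_hyb = spawn_seeds(spec.seed, 4)
    ancestor = simulate_ancestor(spec.genome_size, spec.n_contigs, spec.gc, s_anc)
    markers, mfeat = plant_markers(ancestor, spec.n_markers, spec.marker_length,
                                   s_feat, kind="marker")
    _, gfeat = plant_markers(ancestor, spec.n_core_genes, spec.gene_length,
                             s_feat + 1, kind="gene", reserved=mfeat)
    features = {cid: mfeat.get(cid, []) + gfeat.get(cid, [])
                for cid, _ in ancestor.contigs}
    lineages, truth = evolve_lineages(ancestor, spec.lineage_tree, s_evo,
                                      spec.indel_rate, spec.indel_mean_length,
                                      features)
    assemblies: dict[str, Assembly] = {}
    rng = rng_from(s_hyb)
    for sid in spec.haploid_strains:
        lin = _drift_assembly(lineages[sid], spec.strain_drift, rng)
        contigs, source = [], {}
        for i, (anc_cid, seq) in enumerate(lin.contigs):
            new_cid = f"{sid}_c{i + 1:02d}"
            contigs.append((new_cid, seq))
            source[(sid, new_cid)] = (sid, anc_cid)
        assemblies[sid] = Assembly(sid, contigs, "haploid")
        truth.contig_source.update(source)
    # diploids sharing a parent pair descend from the same hybridization
    # event: they share the event ancestor's drift, then drift apart
    ev_order: list[tuple[str, str]] = []
    ev_members: dict[tuple[str, str], list[str]] = {}
    for p1, p2, did in spec.hybridizations:
        key = (p1, p2)
        if key not in ev_members:
            ev_members[key] = []
            ev_order.append(key)
        ev_members[key].append(did)
    for key in ev_order:
        p1, p2 = key
        pool = ([(p1, cid, seq) for cid, seq in lineages[p1].contigs]
                + [(p2, cid, seq) for cid, seq in lineages[p2].contigs])
        event = Assembly("event", [(f"{par}|{cid}|{i}", seq)
                                   for i, (par, cid, seq) in enumerate(pool)],
                         "diploid")
        event = _drift_assembly(event, spec.event_drift, rng)
        for did in ev_members[key]:
            dasm = _drift_assembly(event, spec.strain_drift, rng)
            order = rng.permutation(len(dasm.contigs))
            contigs, source = [], {}
            for rank, idx in enumerate(order):
                tag, seq = dasm.contigs[idx]
                par, anc_cid, _ = tag.split("|")
                new_cid = f"{did}_c{rank + 1:02d}"
                contigs.append((new_cid, seq))
                source[(did, new_cid)] = (par, anc_cid)
            assemblies[did] = Assembly(did, contigs, "diploid")
            truth.contig_source.update(source)
            truth.hybrid_parents[did] = (p1, p2)
    logger.info("generated scenario %s: %d strains, %d hybridizations",
                spec.name, len(assemblies), len(spec.hybridizations))
    return SyntheticCohort(spec, assemblies, lineages, markers, truth)


# ---------------------------------------------------------------------------
# presets

#: two haploids at total divergence 0.10 and one hybrid of both — the
#: reference-strain situation (diploid A with close haploid relatives C, D)
TRIO_TREE = "(C:0.045,D:0.055);"

#: eight haploid lineages; C and D are sequenced, P3-P8 are unsampled
#: parents.  Hybrid-pair divergences span ~0.085-0.13, each pair differs
#: in its distance to reference haploid C (needed for subgenome phasing),
#: and no lineage parents more than two events (so the strain tree stays
#: fully resolved and gene trees can be concordant).
COHORT12_TREE = ("(C:0.045,D:0.055,P3:0.015,"
                 "(P4:0.07,(P5:0.035,P6:0.035,(P7:0.04,P8:0.055):0.01):0.02)"
                 ":0.03);")

COHORT12_HYBRIDIZATIONS = [
    ("C", "D", "A"), ("C", "D", "B"),
    ("P3", "P4", "E"), ("P3", "P5", "F"),
    ("P6", "P7", "G"), ("P6", "P8", "H"),
    ("P7", "P8", "I"), ("P7", "P8", "J"),
    ("P4", "P5", "K"), ("P4", "P5", "L"),
]


def divergence_to_branch_length(p_target: float) -> float:
    """Total branch length giving an expected realized difference p_target.

    Two sequences at total path b (split evenly) under the simulator's
    substitution process differ at a site with probability
    p = 1 - (1-q)^2 - 0.375 q^2 where q = 1 - e^(-b/2): a mutated site
    never retains its base, and two independently mutated copies coincide
    with probability 0.375 under the 2:1 transition bias.  Solved by
    bisection; used to parameterize scenarios by nucleotide difference.
    """
    if not 0 <= p_target < 0.7:
        raise ValueError("p_target must be in [0, 0.7)")

    def realized(b):
        q = 1 - math.exp(-b / 2)
        return 1 - (1 - q) ** 2 - 0.375 * q * q

    lo, hi = 0.0, 3.0
    for _ in range(80):
        mid = (lo + hi) / 2
        if realized(mid) < p_target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def divergence_pair_scenario(p_target: float, seed: int = 0,
                             **overrides) -> ScenarioSpec:
    """Two haploids at a given realized nucleotide divergence + one hybrid.

    A controlled-divergence experiment: no post-hybridization drift, so the
    hybrid's subgenome difference equals the planted divergence exactly in
    expectation.
    """
    b = divergence_to_branch_length(p_target)
    tree = f"(C:{b / 2:.8f},D:{b / 2:.8f});"
    spec = ScenarioSpec(f"pair_d{p_target:g}", tree, [("C", "D", "A")],
                        ["C", "D"], seed=seed, event_drift=0.0,
                        strain_drift=0.0)
    return replace(spec, **overrides) if overrides else spec


def preset_scenario(name: str, seed: int = 0, **overrides) -> ScenarioSpec:
    """Preset scenarios: "trio" (A/C/D situation) or "cohort12".

    "trio": two haploids plus one hybrid of both.  "cohort12": 12 strains —
    2 sequenced haploids and 10 diploids produced by 7 distinct
    hybridization events among 8 haploid lineages.
    """
    if name == "trio":
        spec = ScenarioSpec("trio", TRIO_TREE, [("C", "D", "A")],
                            ["C", "D"], seed=seed)
    elif name == "cohort12":
        spec = ScenarioSpec("cohort12", COHORT12_TREE,
                            list(COHORT12_HYBRIDIZATIONS), ["C", "D"],
                            seed=seed)
    else:
        raise ValueError(f"unknown preset {name!r}")
    return replace(spec, **overrides) if overrides else spec
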