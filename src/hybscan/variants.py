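"""Ploidy-aware SNP calling against a haploid reference, with depth filter.

Reads of every strain are uniquely placed on a haploid reference assembly
and piled up per site.  Haploid strains are genotyped as the majority
allele; diploids may be heterozygous.  Mapping highly heterozygous
diploids onto a haploid reference risks recruiting only the reads of the
closer subgenome, which halves the depth at the affected sites and hides
heterozygosity — the depth filter therefore keeps only loci whose depth
lies inside a quantile band of each diploid's genome-wide depth.

The reference must be haploid: calling against a diploid reference is
refused outright rather than attempting multi-mapping workarounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import ALPHABET, logger
from .mapping import ReferenceIndex, build_index, place_reads
from .seqio import Assembly
from .synth import ReadSet, SyntheticCohort


class ReferenceNotHaploidError(ValueError):
    """The chosen variant-calling reference is not a haploid strain."""


@dataclass
class SnpMatrix:
    """Strains x loci genotype calls with read depths.

    Genotypes are stored as allele-code pairs (codes 0-3 = A,C,G,T); for
    haploid strains the second entry is -2, missing genotypes are (-1,-1).
    Positions are 1-based in emitted tables, 0-based internally.
    """

    reference_id: str
    strain_ids: list[str]
    ploidy: dict[str, int]
    contig: np.ndarray          # locus -> contig id (object array)
    pos0: np.ndarray            # locus -> 0-based position
    ref_allele: np.ndarray      # locus -> code
    genotypes: np.ndarray       # (n_strains, n_loci, 2) int8
    depths: np.ndarray          # (n_strains, n_loci) int32
    genome_median_depth: dict[str, float] = field(default_factory=dict)

    @property
    def n_loci(self) -> int:
        return len(self.pos0)

    def strain_index(self, sid: str) -> int:
        return self.strain_ids.index(sid)

    def typed(self) -> np.ndarray:
        """(n_strains, n_loci) bool: genotype present."""
        return self.genotypes[:, :, 0] >= 0

    def allele_counts(self) -> np.ndarray:
        """(n_strains, n_loci, 4) per-genotype allele multiset counts."""
        S, L, _ = self.genotypes.shape
        counts = np.zeros((S, L, 4), dtype=np.int8)
        for slot in (0, 1):
            g = self.genotypes[:, :, slot]
            ok = g >= 0
            s_idx, l_idx = np.nonzero(ok)
            np.add.at(counts, (s_idx, l_idx, g[ok]), 1)
        return counts

    def subset(self, locus_idx: np.ndarray) -> "SnpMatrix":
        return SnpMatrix(self.reference_id, list(self.strain_ids),
                         dict(self.ploidy), self.contig[locus_idx],
                         self.pos0[locus_idx], self.ref_allele[locus_idx],
                         self.genotypes[:, locus_idx], self.depths[:, locus_idx],
                         dict(self.genome_median_depth))


def pileup_call(reads_by_strain: dict[str, ReadSet], reference: Assembly,
                ploidy: dict[str, int], min_depth: int = 8,
                het_band: tuple[float, float] = (0.2, 0.8),
                min_identity: float = 0.84, min_score_margin: int = 10,
                k: int = 17) -> SnpMatrix:
    """Unique-map every strain's reads to a haploid reference and call SNPs.

    Haploid call: majority allele when depth >= min_depth and majority
    fraction >= 0.9.  Diploid call: homozygous when the top allele fraction
    is >= het_band[1], heterozygous when the second allele's fraction falls
    inside het_band; otherwise missing.
    """
    if reference.ploidy_label == "diploid" or ploidy.get(reference.strain_id, 1) != 1:
        raise ReferenceNotHaploidError(
            f"reference {reference.strain_id} must be haploid")
    index = build_index(reference, k=k)
    glen = int(index.lengths.sum())
    goff = np.concatenate([[0], np.cumsum(index.lengths)[:-1]])
    strains = sorted(reads_by_strain)
    counts = {}     # strain -> (4, glen) allele count arrays
    medians = {}
    for sid in strains:
        reads = reads_by_strain[sid]
        L = reads.codes.shape[1]
        pl = place_reads(reads, index, min_score_margin=min_score_margin,
                         min_identity=min_identity)
        depth = np.zeros(glen + 1, dtype=np.int32)
        gstart = goff[pl.contig_idx] + pl.start
        np.add.at(depth, gstart, 1)
        np.add.at(depth, gstart + L, -1)
        depth = np.cumsum(depth[:-1])
        acount = np.zeros((4, glen), dtype=np.int32)
        if len(pl):
            windows = index.genome[(pl.start + index.offsets[pl.contig_idx])[:, None]
                                   + np.arange(L)[None, :]]
            rc = reads.codes[pl.read_index]
            neq = (windows != rc) & (rc < 4)
            ridx, off = np.nonzero(neq)
            np.add.at(acount, (rc[ridx, off], gstart[ridx] + off), 1)
        refc = depth - acount.sum(axis=0)
        counts[sid] = (acount, refc, depth)
        medians[sid] = float(np.median(depth))
    # reference genome codes per global position
    ref_codes = np.concatenate(
        [index.genome[index.offsets[i]:index.offsets[i] + int(index.lengths[i])]
         for i in range(len(index.contig_ids))])
    # candidate sites: any strain with >= 2 reads of a non-reference allele
    cand = np.zeros(glen, dtype=bool)
    for sid in strains:
        acount, refc, depth = counts[sid]
        cand |= acount.max(axis=0) >= 2
    sites = np.flatnonzero(cand)
    S, L = len(strains), len(sites)
    genotypes = np.full((S, L, 2), -1, dtype=np.int8)
    depths_out = np.zeros((S, L), dtype=np.int32)
    for si, sid in enumerate(strains):
        acount, refc, depth = counts[sid]
        table = acount[:, sites].copy()
        ref_at = ref_codes[sites]
        table[ref_at, np.arange(L)] += refc[sites]
        d = table.sum(axis=0)
        depths_out[si] = d
        order = np.argsort(table, axis=0)
        top = order[-1]
        second = order[-2]
        topc = table[top, np.arange(L)]
        secc = table[second, np.arange(L)]
        with np.errstate(invalid="ignore", divide="ignore"):
            ftop = np.where(d > 0, topc / np.maximum(d, 1), 0.0)
            fsec = np.where(d > 0, secc / np.maximum(d, 1), 0.0)
        enough = d >= min_depth
        if ploidy[sid] == 1:
            ok = enough & (ftop >= 0.9)
            genotypes[si, ok, 0] = top[ok]
            genotypes[si, ok, 1] = -2
        else:
            hom = enough & (ftop >= het_band[1])
            het = enough & ~hom & (fsec >= het_band[0]) & (fsec <= het_band[1])
            genotypes[si, hom, 0] = top[hom]
            genotypes[si, hom, 1] = top[hom]
            a = np.minimum(top, second)
            b = np.maximum(top, second)
            genotypes[si, het, 0] = a[het]
            genotypes[si, het, 1] = b[het]
    # keep loci where at least one typed strain differs from the reference
    ref_at = ref_codes[sites]
    alt0 = (genotypes[:, :, 0] >= 0) & (genotypes[:, :, 0] != ref_at[None, :])
    alt1 = (genotypes[:, :, 1] >= 0) & (genotypes[:, :, 1] != ref_at[None, :])
    keep = (alt0 | alt1).any(axis=0)
    sites = sites[keep]
    contig_idx = np.searchsorted(goff, sites, side="right") - 1
    contig = np.array([index.contig_ids[i] for i in contig_idx], dtype=object)
    matrix = SnpMatrix(reference.strain_id, strains,
                       {s: ploidy[s] for s in strains}, contig,
                       sites - goff[contig_idx], ref_codes[sites],
                       genotypes[:, keep], depths_out[:, keep], medians)
    logger.info("called %d SNP loci over %d strains against %s",
                matrix.n_loci, S, reference.strain_id)
    return matrix


def depth_filter(matrix: SnpMatrix, low: float = 0.7, high: float = 2.0) -> SnpMatrix:
    """Keep loci where every diploid's depth is inside its genome-wide band.

    The band is [low x median, high x median] of that strain's genome-wide
    depth.  Loci where only one subgenome's reads were recruited sit near
    half depth and systematically hide heterozygosity; they are removed.
    The default lower bound is 0.7 rather than 0.5 because for a diploid
    mapped to a haploid reference the single-subgenome mode sits at about
    half the genome-wide median, exactly on a 0.5 cutoff.
    """
    keep = np.ones(matrix.n_loci, dtype=bool)
    for si, sid in enumerate(matrix.strain_ids):
        if matrix.ploidy[sid] != 2:
            continue
        med = matrix.genome_median_depth.get(sid)
        if not med:
            continue
        d = matrix.depths[si]
        keep &= (d >= low * med) & (d <= high * med)
    logger.info("depth filter kept %d/%d loci", int(keep.sum()), matrix.n_loci)
    return matrix.subset(np.flatnonzero(keep))


def heterozygous_fraction(matrix: SnpMatrix, strain_id: str) -> float:
    si = matrix.strain_index(strain_id)
    g = matrix.genotypes[si]
    typed = g[:, 0] >= 0
    if not typed.any():
        return float("nan")
    het = typed & (g[:, 1] >= 0) & (g[:, 0] != g[:, 1])
    return float(het.sum() / typed.sum())


# ---------------------------------------------------------------------------
# dissimilarity


class UndefinedPairError(ValueError):
    """A strain pair shares no typed loci."""


def per_locus_dissimilarity(matrix: SnpMatrix) -> np.ndarray:
    """(n_pairs, n_loci) allele-multiset dissimilarities, NaN where untyped.

    Per locus: genotypes are compared as allele multisets and the
    dissimilarity is 1 - |intersection| / max(ploidy of the pair); for two
    haploids this is plain 0/1 mismatch.  Pair order is (0,1), (0,2), ...
    """
    counts = matrix.allele_counts()
    typed = matrix.typed()
    pl = np.array([matrix.ploidy[s] for s in matrix.strain_ids])
    S = len(matrix.strain_ids)
    pairs = [(i, j) for i in range(S) for j in range(i + 1, S)]
    out = np.full((len(pairs), matrix.n_loci), np.nan)
    for pi, (i, j) in enumerate(pairs):
        inter = np.minimum(counts[i], counts[j]).sum(axis=1)
        pmax = max(pl[i], pl[j])
        d = 1.0 - inter / pmax
        ok = typed[i] & typed[j]
        out[pi, ok] = d[ok]
    return out


def dissimilarity(matrix: SnpMatrix) -> pd.DataFrame:
    """Mean per-locus dissimilarity over loci typed in both strains."""
    S = len(matrix.strain_ids)
    if S < 2:
        raise ValueError("need at least two strains")
    d_pl = per_locus_dissimilarity(matrix)
    out = np.zeros((S, S))
    pi = 0
    for i in range(S):
        for j in range(i + 1, S):
            row = d_pl[pi]
            ok = ~np.isnan(row)
            if not ok.any():
                raise UndefinedPairError(
                    f"{matrix.strain_ids[i]} and {matrix.strain_ids[j]} share no loci")
            out[i, j] = out[j, i] = float(row[ok].mean())
            pi += 1
    return pd.DataFrame(out, index=matrix.strain_ids, columns=matrix.strain_ids)


# ---------------------------------------------------------------------------
# truth-derived genotypes and VCF-like round trip


def matrix_from_truth(cohort: SyntheticCohort, reference: str = "C") -> SnpMatrix:
    """Exact assembly-derived SNP matrix against a haploid strain.

    Uses the simulator's strain assemblies directly (no reads): because
    every contig descends from a known ancestral contig and the indel-free
    regime preserves coordinates, each strain's allele(s) at every
    reference position can be read off its assembly.  Depths are nominal
    (coverage) and the genome median depth equals the coverage.
    """
    from ._util import encode
    if reference not in cohort.spec.haploid_strains:
        raise ReferenceNotHaploidError(f"{reference} is not a haploid strain")
    strains = cohort.strains()
    src = cohort.truth.contig_source
    # strain -> ancestral contig -> list of coded copy sequences
    copies: dict[str, dict[str, list[np.ndarray]]] = {s: {} for s in strains}
    for sid in strains:
        items = []
        for cid, seq in cohort.assemblies[sid].contigs:
            lineage, anc = src[(sid, cid)]
            items.append((anc, lineage, cid, seq))
        for anc, lineage, cid, seq in sorted(items):
            copies[sid].setdefault(anc, []).append(encode(seq))
    ploidy_of = {s: (1 if s in cohort.spec.haploid_strains else 2)
                 for s in strains}
    cov = int(round(cohort.spec.coverage))
    ref_items = sorted((src[(reference, cid)][1], cid, seq)
                       for cid, seq in cohort.assemblies[reference].contigs)
    all_contig, all_pos, all_ref, all_geno = [], [], [], []
    for anc, cid, rseq in ref_items:
        ref = encode(rseq)
        rows = []
        for sid in strains:
            cp = copies[sid][anc]
            rows.append(np.stack(cp if len(cp) == 2 else cp * 2))
        alleles = np.stack(rows)                 # (S, 2, len)
        var = (alleles != ref[None, None, :]).any(axis=(0, 1))
        idx = np.flatnonzero(var)
        if not len(idx):
            continue
        g = np.sort(alleles[:, :, idx].astype(np.int8), axis=1)
        all_contig.append(np.array([cid] * len(idx), dtype=object))
        all_pos.append(idx)
        all_ref.append(ref[idx])
        all_geno.append(np.transpose(g, (0, 2, 1)))
    contig = np.concatenate(all_contig)
    pos0 = np.concatenate(all_pos)
    refa = np.concatenate(all_ref)
    geno = np.concatenate(all_geno, axis=1)
    for si, sid in enumerate(strains):
        if ploidy_of[sid] == 1:
            geno[si, :, 1] = -2
    depths = np.full((len(strains), len(pos0)), cov, dtype=np.int32)
    return SnpMatrix(reference, strains, ploidy_of, contig, pos0,
                     refa.astype(np.int8), geno, depths,
                     {s: float(cov) for s in strains})


def write_vcf_like(matrix: SnpMatrix, path) -> None:
    """Tab-separated VCF-style table: CHROM POS REF ALT then GT:DP columns."""
    with open(path, "w") as fh:
        fh.write("#reference=" + matrix.reference_id + "\n")
        fh.write("#ploidy=" + ",".join(f"{s}:{matrix.ploidy[s]}"
                                       for s in matrix.strain_ids) + "\n")
        fh.write("#median_depth=" + ",".join(
            f"{s}:{matrix.genome_median_depth.get(s, 0):g}"
            for s in matrix.strain_ids) + "\n")
        fh.write("\t".join(["#CHROM", "POS", "REF", "ALT"] + matrix.strain_ids) + "\n")
        for li in range(matrix.n_loci):
            ref = int(matrix.ref_allele[li])
            alts = sorted({int(a) for a in matrix.genotypes[:, li, :].ravel()
                           if a >= 0 and a != ref})
            amap = {ref: 0, **{a: i + 1 for i, a in enumerate(alts)}}
            cols = [str(matrix.contig[li]), str(int(matrix.pos0[li]) + 1),
                    ALPHABET[ref], ",".join(ALPHABET[a] for a in alts) or "."]
            for si, sid in enumerate(matrix.strain_ids):
                a, b = (int(x) for x in matrix.genotypes[si, li])
                dp = int(matrix.depths[si, li])
                if a < 0:
                    gt = "." if matrix.ploidy[sid] == 1 else "./."
                elif b == -2:
                    gt = str(amap[a])
                else:
                    gt = f"{amap[a]}/{amap[b]}"
                cols.append(f"{gt}:{dp}")
            fh.write("\t".join(cols) + "\n")


def read_vcf_like(path) -> SnpMatrix:
    code = {c: i for i, c in enumerate(ALPHABET)}
    with open(path) as fh:
        ref_id = fh.readline().strip().split("=", 1)[1]
        ploidy = {kv.split(":")[0]: int(kv.split(":")[1])
                  for kv in fh.readline().strip().split("=", 1)[1].split(",")}
        med = {kv.split(":")[0]: float(kv.split(":")[1])
               for kv in fh.readline().strip().split("=", 1)[1].split(",")}
        header = fh.readline().strip().split("\t")
        strains = header[4:]
        contig, pos0, refa, geno, depths = [], [], [], [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            contig.append(parts[0])
            pos0.append(int(parts[1]) - 1)
            ref = code[parts[2]]
            refa.append(ref)
            alleles = [ref] + ([code[a] for a in parts[3].split(",")]
                               if parts[3] != "." else [])
            grow, drow = [], []
            for cell in parts[4:]:
                gt, dp = cell.rsplit(":", 1)
                drow.append(int(dp))
                if gt in (".", "./."):
                    grow.append((-1, -1))
                elif "/" in gt:
                    a, b = (alleles[int(x)] for x in gt.split("/"))
                    grow.append((min(a, b), max(a, b)))
                else:
                    grow.append((alleles[int(gt)], -2))
            geno.append(grow)
            depths.append(drow)
    geno_arr = np.array(geno, dtype=np.int8).transpose(1, 0, 2)
    return SnpMatrix(ref_id, strains, ploidy, np.array(contig, dtype=object),
                     np.array(pos0), np.array(refa, dtype=np.int8), geno_arr,
                     np.array(depths, dtype=np.int32).T, med)
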