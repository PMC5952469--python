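"""Multilocus linkage disequilibrium: index of association and r̄_d.

Under free recombination, the per-locus genetic distances between
individuals are independent across loci, so the variance of the summed
pairwise distances V_O equals the sum of per-locus variances V_E.  Under
clonality, distances are correlated across loci and V_O exceeds V_E.  The
index of association is I_A = V_O/V_E - 1, and its standardized form

    r̄_d = (V_O - V_E) / (2 Σ_{j<k} sqrt(var_j var_k))

lies in [-1, 1] and is comparable across locus counts.  Significance is
assessed by permuting genotypes among strains independently at every
locus (which preserves allele frequencies but destroys between-locus
association) with the add-one rule, so the smallest attainable p-value
with 999 permutations is 1/1000.

Variances use the population (1/n_pairs) denominator over all strain
pairs, matching the original construction of the statistic; monomorphic
loci contribute nothing to V_E or the denominator sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import logger, rng_from
from .variants import SnpMatrix, per_locus_dissimilarity


@dataclass
class IaResult:
    v_observed: float
    v_expected: float
    ia: float
    r_bar_d: float
    n_strains: int
    n_loci: int
    p_value: float | None = None
    n_permutations: int = 0
    subset_id: str = ""
    seed: int | None = None
    permutation_r_bar_d: np.ndarray | None = None


def sample_subsets(matrix: SnpMatrix, subset_size: int = 1000,
                   n_subsets: int = 10, seed=0) -> list[np.ndarray]:
    """Random locus subsets (without replacement within each subset)."""
    rng = rng_from(seed)
    L = matrix.n_loci
    if L < subset_size:
        logger.warning("only %d loci (< %d); using a single full subset",
                       L, subset_size)
        return [np.arange(L)]
    return [np.sort(rng.choice(L, size=subset_size, replace=False))
            for _ in range(n_subsets)]


def _pair_distance_tensor(matrix: SnpMatrix) -> np.ndarray:
    """(L, S, S) per-locus genotype dissimilarity between all strain pairs.

    Loci typed in every strain only; the caller gets the filtered tensor.
    """
    counts = matrix.allele_counts()           # (S, L, 4)
    typed_all = matrix.typed().all(axis=0)
    counts = counts[:, typed_all, :]
    S = counts.shape[0]
    pl = np.array([matrix.ploidy[s] for s in matrix.strain_ids])
    L = counts.shape[1]
    out = np.zeros((L, S, S))
    for i in range(S):
        for j in range(i + 1, S):
            inter = np.minimum(counts[i], counts[j]).sum(axis=1)
            d = 1.0 - inter / max(pl[i], pl[j])
            out[:, i, j] = out[:, j, i] = d
    return out


def _ia_from_pair_distances(dmat: np.ndarray) -> IaResult:
    """dmat: (L, S, S) symmetric per-locus pair distances."""
    L, S, _ = dmat.shape
    iu = np.triu_indices(S, 1)
    d_pl = dmat[:, iu[0], iu[1]]              # (L, n_pairs)
    var_j = d_pl.var(axis=1)                  # population denominator
    v_e = float(var_j.sum())
    if v_e == 0:
        raise ValueError("all loci are monomorphic; r_bar_d undefined")
    total = d_pl.sum(axis=0)
    v_o = float(total.var())
    sq = np.sqrt(var_j)
    denom = float(sq.sum() ** 2 - (var_j).sum())
    r_bar_d = (v_o - v_e) / denom if denom > 0 else float("nan")
    return IaResult(v_o, v_e, v_o / v_e - 1, r_bar_d, S, L)


def index_of_association(matrix: SnpMatrix,
                         locus_subset: np.ndarray | None = None) -> IaResult:
    """I_A and r̄_d for a SNP matrix (optionally a locus subset)."""
    if len(matrix.strain_ids) < 3:
        raise ValueError("need >= 3 strains")
    sub = matrix.subset(locus_subset) if locus_subset is not None else matrix
    if sub.n_loci < 2:
        raise ValueError("need >= 2 loci")
    return _ia_from_pair_distances(_pair_distance_tensor(sub))


def permutation_test(matrix: SnpMatrix, locus_subset: np.ndarray | None = None,
                     n_perm: int = 999, seed=0,
                     subset_id: str = "") -> IaResult:
    """Permutation test of the free-recombination null on r̄_d.

    Each permutation shuffles whole genotypes among strains independently
    at every locus.  Shuffling leaves every per-locus variance unchanged
    (the multiset of pair distances is permuted), so only V_O varies and
    p = (1 + #{perm r̄_d >= observed}) / (n_perm + 1).
    """
    rng = rng_from(seed)
    sub = matrix.subset(locus_subset) if locus_subset is not None else matrix
    dmat = _pair_distance_tensor(sub)
    obs = _ia_from_pair_distances(dmat)
    L, S, _ = dmat.shape
    iu = np.triu_indices(S, 1)
    var_j = dmat[:, iu[0], iu[1]].var(axis=1)
    v_e = float(var_j.sum())
    denom = float(np.sqrt(var_j).sum() ** 2 - var_j.sum())
    n_pairs = len(iu[0])
    perm_r = np.empty(n_perm)
    l_idx = np.arange(L)[:, None]
    n_ge = 0
    for b in range(n_perm):
        perms = np.argsort(rng.random((L, S)), axis=1)
        rows = perms[:, iu[0]]
        cols = perms[:, iu[1]]
        vals = dmat[l_idx, rows, cols]
        v_o = float(vals.sum(axis=0).var())
        perm_r[b] = (v_o - v_e) / denom if denom > 0 else float("nan")
        if perm_r[b] >= obs.r_bar_d:
            n_ge += 1
    p = (1 + n_ge) / (n_perm + 1)
    logger.info("r_bar_d=%.4f, p=%.4g (%d permutations)%s", obs.r_bar_d, p,
                n_perm, f" [{subset_id}]" if subset_id else "")
    return IaResult(obs.v_observed, obs.v_expected, obs.ia, obs.r_bar_d,
                    S, L, p, n_perm, subset_id,
                    seed if isinstance(seed, int) else None, perm_r)


def ia_over_subsets(matrix: SnpMatrix, subset_size: int = 1000,
                    n_subsets: int = 10, n_perm: int = 999,
                    seed=0) -> list[IaResult]:
    """The standard protocol: r̄_d with permutation p on random SNP subsets."""
    rng = rng_from(seed)
    subsets = sample_subsets(matrix, subset_size, n_subsets,
                             rng.integers(2**31))
    return [permutation_test(matrix, idx, n_perm, rng.integers(2**31),
                             subset_id=f"subset_{i + 1}")
            for i, idx in enumerate(subsets)]


def simulate_panmictic_matrix(n_strains: int, n_loci: int, ploidy: int = 1,
                              seed=0) -> SnpMatrix:
    """Null-model genotypes: biallelic loci, free recombination.

    Allele frequencies are drawn per locus from U(0.2, 0.8) and genotypes
    independently per strain, emulating a freely recombining population
    for type-I-error calibration.
    """
    rng = rng_from(seed)
    freqs = rng.uniform(0.2, 0.8, n_loci)
    strains = [f"s{i + 1:03d}" for i in range(n_strains)]
    geno = np.full((n_strains, n_loci, 2), -1, dtype=np.int8)
    alleles = np.array([0, 1], dtype=np.int8)  # A vs C
    draws = (rng.random((n_strains, n_loci, ploidy)) <
             freqs[None, :, None]).astype(np.int8)
    if ploidy == 1:
        geno[:, :, 0] = alleles[draws[:, :, 0]]
        geno[:, :, 1] = -2
    else:
        g = np.sort(alleles[draws], axis=2)
        geno[:, :, :] = g
    return SnpMatrix("null", strains, {s: ploidy for s in strains},
                     np.array(["sim"] * n_loci, dtype=object),
                     np.arange(n_loci), np.zeros(n_loci, dtype=np.int8),
                     geno, np.full((n_strains, n_loci), 30, dtype=np.int32),
                     {s: 30.0 for s in strains})
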