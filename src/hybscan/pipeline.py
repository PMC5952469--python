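"""Stage-based pipeline orchestration with re-runnable intermediates.

A run directory holds one scenario (simulated or user-supplied) and one
subdirectory of tabular outputs per stage.  Each stage reads only
documented intermediates and fails with :class:`StageDependencyError`
when an upstream stage has not produced them.  All stochastic stages are
seeded from the scenario seed, so a rerun with the same configuration is
byte-identical.

Configuration is a single YAML file; every threshold exposed by the
library modules can be set under a per-stage section, e.g.::

    scenario: {preset: trio, seed: 1}
    paint:    {min_identity: 0.90, min_contig_len: 20000}
    call:     {reference: C, min_depth: 8, use_truth_genotypes: false}
    ia:       {subset_size: 1000, n_subsets: 10, n_perm: 999}
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import asdict

import numpy as np
import pandas as pd
import yaml

from ._util import logger, spawn_seeds
from . import (clonality, datasets, heterozygosity, network, painting, phylo,
               ploidy, seqio, synth, variants)


class StageDependencyError(RuntimeError):
    """An upstream intermediate required by this stage is missing."""


class ConfigError(ValueError):
    pass


STAGES = ["simulate", "stats", "ploidy", "paint", "call", "net",
          "coregenes", "trees", "ia", "het"]

FLOAT_FMT = "%.6g"


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "scenario" not in cfg:
        raise ConfigError("config needs a 'scenario' section")
    if "seed" not in cfg["scenario"]:
        raise ConfigError("scenario.seed is required (stochastic stages)")
    return cfg


class Pipeline:
    """One run directory + one configuration."""

    def __init__(self, config: dict, outdir: str):
        if "seed" not in config.get("scenario", {}):
            raise ConfigError("scenario.seed is required")
        self.cfg = config
        self.outdir = outdir
        os.makedirs(outdir, exist_ok=True)
        self._cohort = None

    # -- helpers ----------------------------------------------------------

    def path(self, *parts) -> str:
        p = os.path.join(self.outdir, *parts)
        os.makedirs(os.path.dirname(p), exist_ok=True)
        return p

    def _require(self, relpath: str, stage: str, needed_by: str) -> str:
        p = os.path.join(self.outdir, relpath)
        if not os.path.exists(p):
            raise StageDependencyError(
                f"stage '{needed_by}' needs {relpath} — run stage '{stage}' first")
        return p

    def cohort(self) -> synth.SyntheticCohort:
        """Regenerate the scenario deterministically from its spec."""
        if self._cohort is None:
            p = self._require("scenario.yaml", "simulate", "downstream")
            with open(p) as fh:
                stored = yaml.safe_load(fh)
            spec = synth.ScenarioSpec(**{
                k: (tuple(v) if k == "hybridizations" else v)
                for k, v in stored.items()})
            spec.hybridizations = [tuple(h) for h in stored["hybridizations"]]
            self._cohort = synth.generate(spec)
        return self._cohort

    def _write_tsv(self, df: pd.DataFrame, *parts) -> str:
        p = self.path(*parts)
        df.to_csv(p, sep="\t", index=False, float_format=FLOAT_FMT)
        return p

    # -- stages -----------------------------------------------------------

    def run(self, stages: list[str]) -> None:
        if stages == ["all"]:
            stages = STAGES
        for st in stages:
            if st not in STAGES:
                raise ConfigError(f"unknown stage {st!r}")
            logger.info("=== stage %s ===", st)
            getattr(self, "stage_" + st)()

    def stage_simulate(self) -> None:
        sc = dict(self.cfg["scenario"])
        preset = sc.pop("preset", "trio")
        seed = sc.pop("seed")
        spec = synth.preset_scenario(preset, seed=seed, **sc)
        with open(self.path("scenario.yaml"), "w") as fh:
            yaml.safe_dump(asdict(spec), fh, sort_keys=True)
        self._cohort = None
        cohort = self.cohort()
        for sid, asm in sorted(cohort.assemblies.items()):
            seqio.write_fasta(asm, self.path("assemblies", f"{sid}.fasta"))
        seqio.write_fasta(cohort.markers, self.path("markers.fasta"))
        rows = [{"strain": s, "contig": c, "parent_lineage": lin,
                 "ancestral_contig": anc}
                for (s, c), (lin, anc) in sorted(cohort.truth.contig_source.items())]
        self._write_tsv(pd.DataFrame(rows), "truth", "contig_sources.tsv")
        rows = [{"diploid": d, "parent1": p[0], "parent2": p[1]}
                for d, p in sorted(cohort.truth.hybrid_parents.items())]
        self._write_tsv(pd.DataFrame(rows), "truth", "hybridizations.tsv")
        if self.cfg.get("simulate", {}).get("write_reads", False):
            for sid in cohort.strains():
                cohort.reads(sid).to_fastq(self.path("reads", f"{sid}.fastq"))

    def stage_stats(self) -> None:
        cohort = self.cohort()
        rows = []
        for sid, asm in sorted(cohort.assemblies.items()):
            st = seqio.assembly_stats(asm)
            rows.append({"strain": sid, "total_bp": st.total_size_bp,
                         "n_contigs": st.n_contigs, "n50_bp": st.n50_bp,
                         "gc_fraction": round(st.gc_fraction, 6)})
        self._write_tsv(pd.DataFrame(rows), "stats", "assembly_stats.tsv")
        summaries = datasets.diploid_cohort_summaries()
        rows = [{"statistic": name, "mean": s.mean, "sd": s.sd,
                 "n": len(s.group)} for name, s in summaries.items()]
        self._write_tsv(pd.DataFrame(rows), "stats", "published_cohort_summary.tsv")

    def _marker_tables(self) -> dict[str, pd.DataFrame]:
        cohort = self.cohort()
        kw = self.cfg.get("ploidy", {})
        search_kw = {k: kw[k] for k in ("min_identity", "min_coverage", "k")
                     if k in kw}
        return {sid: ploidy.find_marker_copies(asm, cohort.markers, **search_kw)
                for sid, asm in sorted(cohort.assemblies.items())}

    def stage_ploidy(self) -> None:
        tables = self._marker_tables()
        kw = self.cfg.get("ploidy", {})
        call_kw = {k: kw[k] for k in ("dup_hi", "dup_lo") if k in kw}
        rows = []
        for sid, table in tables.items():
            call = ploidy.call_ploidy(table, **call_kw)
            rows.append({"strain": sid, "complete": call.complete_fraction,
                         "single": call.single_fraction,
                         "duplicated": call.duplicated_fraction,
                         "call": call.call})
            self._write_tsv(table, "ploidy", f"markers_{sid}.tsv")
        self._write_tsv(pd.DataFrame(rows), "ploidy", "ploidy_calls.tsv")

    def _ploidy_calls(self) -> dict[str, str]:
        p = self._require("ploidy/ploidy_calls.tsv", "ploidy", "downstream")
        df = pd.read_csv(p, sep="\t")
        return dict(zip(df["strain"], df["call"]))

    def stage_paint(self) -> None:
        cohort = self.cohort()
        calls = self._ploidy_calls()
        haploids = [s for s, c in calls.items() if c == "haploid"]
        diploids = [s for s, c in calls.items() if c == "diploid"]
        if len(haploids) < 2:
            raise StageDependencyError("painting needs two haploid strains")
        h1, h2 = sorted(haploids)[:2]
        kw = self.cfg.get("paint", {})
        map_kw = {k: kw[k] for k in ("k", "min_score_margin", "min_identity")
                  if k in kw}
        cat_kw = {k: kw[k] for k in ("min_depth", "min_contig_len") if k in kw}
        reads1, reads2 = cohort.reads(h1), cohort.reads(h2)
        patterns = []
        for did in diploids:
            cov = painting.paint(cohort.assemblies[did], reads1, reads2, **map_kw)
            profile = painting.contig_categories(cov, **cat_kw)
            self._write_tsv(painting.assign_contigs(profile), "paint",
                            f"profile_{did}.tsv")
            call = painting.classify_pattern(profile)
            patterns.append({"strain": did, "pattern": call.pattern,
                             **{k: v for k, v in call.stats.items()}})
        self._write_tsv(pd.DataFrame(patterns), "paint", "patterns.tsv")

    def stage_call(self) -> None:
        cohort = self.cohort()
        calls = self._ploidy_calls()
        kw = dict(self.cfg.get("call", {}))
        ref_id = kw.pop("reference", None) or sorted(
            [s for s, c in calls.items() if c == "haploid"])[0]
        if calls.get(ref_id) != "haploid":
            raise variants.ReferenceNotHaploidError(
                f"reference {ref_id} is not haploid")
        use_truth = kw.pop("use_truth_genotypes", False)
        if use_truth:
            matrix = variants.matrix_from_truth(cohort, ref_id)
        else:
            pl = {s: 2 if c == "diploid" else 1 for s, c in calls.items()}
            reads = {s: cohort.reads(s) for s in sorted(cohort.assemblies)}
            reference = cohort.assemblies[ref_id]
            matrix = variants.pileup_call(reads, reference, pl, **kw)
        matrix = variants.depth_filter(
            matrix, **{k: kw[k] for k in ("low", "high") if k in kw})
        variants.write_vcf_like(matrix, self.path("call", "snps.tsv"))

    def _matrix(self, needed_by: str) -> variants.SnpMatrix:
        p = self._require("call/snps.tsv", "call", needed_by)
        return variants.read_vcf_like(p)

    def stage_net(self) -> None:
        matrix = self._matrix("net")
        D = variants.dissimilarity(matrix)
        D.to_csv(self.path("net", "dissimilarity.tsv"), sep="\t",
                 float_format=FLOAT_FMT)
        splits = network.neighbor_net(D)
        network.write_splits_nexus(splits, self.path("net", "splits.nex"))
        rows = [{"split": "|".join(sorted(s)), "weight": w}
                for s, w in splits.splits]
        self._write_tsv(pd.DataFrame(rows), "net", "splits.tsv")

    def _partitions(self):
        cohort = self.cohort()
        calls = self._ploidy_calls()
        tables = self._marker_tables()
        ref = sorted([s for s, c in calls.items() if c == "haploid"])[0]
        parts = {}
        for sid, c in calls.items():
            if c != "diploid":
                continue
            parts[sid] = heterozygosity.separate_by_markers(
                cohort.assemblies[sid], tables[sid], cohort.assemblies[ref])
        return parts

    def stage_coregenes(self) -> None:
        cohort = self.cohort()
        calls = self._ploidy_calls()
        fams = phylo.cluster_cds(cohort.cds_by_strain())
        core = phylo.filter_core(fams, calls)
        phased = phylo.phase_families(core, self._partitions())
        rows = [{"family": f.family_id, "n_members": len(f.members),
                 "genes": ";".join(f.gene_ids),
                 "members": ";".join(phylo.member_label(m) for m in f.members)}
                for f in phased]
        self._write_tsv(pd.DataFrame(rows), "coregenes", "families.tsv")
        self._phased = phased

    def stage_trees(self) -> None:
        if not hasattr(self, "_phased"):
            self.stage_coregenes()
        kw = self.cfg.get("trees", {})
        trees: dict[str, phylo.Tree] = {}
        for fam in self._phased:
            trimmed = phylo.align_and_trim(fam)
            if trimmed is None:
                continue
            mat, labels = trimmed
            if not phylo.usable_family(mat, kw.get("min_len", 200),
                                       kw.get("min_mean_diffs", 15)):
                continue
            t = phylo.build_tree(mat, labels)
            if t is not None:
                trees[fam.family_id] = t
        with open(self.path("trees", "gene_trees.nwk"), "w") as fh:
            for fid in sorted(trees):
                fh.write(f"{fid}\t{trees[fid].newick()}\n")
        if len(trees) < 2:
            raise StageDependencyError("fewer than 2 usable gene trees")
        clustering = phylo.cluster_trees(trees,
                                         kw.get("min_similarity", 0.80))
        rows = [{"family": tid, "cluster": int(c)}
                for tid, c in zip(clustering.tree_ids, clustering.assignment)]
        self._write_tsv(pd.DataFrame(rows), "trees", "clusters.tsv")
        with open(self.path("trees", "consensus.nwk"), "w") as fh:
            for c, t in sorted(clustering.consensus.items()):
                fh.write(f"cluster_{c}\t{t.newick()}\n")
        largest = [trees[clustering.tree_ids[i]]
                   for i in np.flatnonzero(clustering.assignment == 0)]
        calls = self._ploidy_calls()
        inf = phylo.infer_hybridizations(
            largest, sorted(s for s, c in calls.items() if c == "diploid"),
            sorted(s for s, c in calls.items() if c == "haploid"))
        rows = [{"diploid": d, "parent1": p[0], "parent2": p[1]}
                for d, p in sorted(inf.parent_pair.items())]
        self._write_tsv(pd.DataFrame(rows), "trees", "events.tsv")
        with open(self.path("trees", "events_summary.json"), "w") as fh:
            json.dump({"n_events": inf.n_events,
                       "unassigned": inf.unassigned}, fh, indent=1)

    def stage_ia(self) -> None:
        matrix = self._matrix("ia")
        kw = self.cfg.get("ia", {})
        seed = spawn_seeds(self.cfg["scenario"]["seed"] + 101, 1)[0]
        results = clonality.ia_over_subsets(
            matrix, kw.get("subset_size", 1000), kw.get("n_subsets", 10),
            kw.get("n_perm", 999), seed)
        rows = [{"subset": r.subset_id, "n_loci": r.n_loci,
                 "V_O": r.v_observed, "V_E": r.v_expected, "I_A": r.ia,
                 "r_bar_d": r.r_bar_d, "p": r.p_value} for r in results]
        self._write_tsv(pd.DataFrame(rows), "ia", "index_of_association.tsv")
        dist = pd.DataFrame({r.subset_id: r.permutation_r_bar_d
                             for r in results})
        self._write_tsv(dist, "ia", "permutation_distribution.tsv")

    def stage_het(self) -> None:
        cohort = self.cohort()
        parts = self._partitions()
        rows = []
        for sid, part in sorted(parts.items()):
            rep = heterozygosity.subgenome_alignment_stats(
                part, cohort.assemblies[sid])
            rows.append({"strain": sid, "method": part.method,
                         "n_group1": len(part.group1),
                         "n_group2": len(part.group2),
                         "n_unassigned": len(part.unassigned),
                         "alignable_fraction": rep.alignable_fraction,
                         "identity": (round(rep.identity, 6)
                                      if not math.isnan(rep.identity) else "NA")})
        self._write_tsv(pd.DataFrame(rows), "het", "heterozygosity.tsv")


def run_pipeline(config: dict | str, outdir: str,
                 stages: list[str] | None = None) -> Pipeline:
    """Run pipeline stages; `config` is a dict or a YAML path."""
    if isinstance(config, str):
        config = load_config(config)
    pipe = Pipeline(config, outdir)
    pipe.run(stages or ["all"])
    return pipe
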