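"""Assemblies, FASTA/FASTQ input-output and per-genome summary statistics.

An :class:`Assembly` is an ordered set of named contigs with a ploidy label.
Statistics follow the conventions of standard assembly reports: N50 is the
largest length L such that contigs of length >= L jointly cover at least
half of the assembly, GC is computed over non-N bases only, and cohort
means/SDs use the sample (n-1) standard deviation.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser

from ._util import logger


class FastaFormatError(ValueError):
    """Raised for unreadable or structurally invalid FASTA input."""


@dataclass
class Assembly:
    """A named genome: ordered contigs plus a ploidy label."""

    strain_id: str
    contigs: list[tuple[str, str]]
    ploidy_label: str = "unknown"

    def __post_init__(self):
        if self.ploidy_label not in ("unknown", "haploid", "diploid"):
            raise ValueError(f"bad ploidy label {self.ploidy_label!r}")
        ids = [cid for cid, _ in self.contigs]
        if len(set(ids)) != len(ids):
            raise FastaFormatError(f"duplicate contig ids in {self.strain_id}")
        if any(len(seq) == 0 for _, seq in self.contigs):
            raise FastaFormatError(f"empty contig in {self.strain_id}")

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.contigs)

    def contig_dict(self) -> dict[str, str]:
        return dict(self.contigs)

    def __len__(self) -> int:
        return len(self.contigs)


@dataclass
class AssemblyStats:
    total_size_bp: int
    n_contigs: int
    n50_bp: int
    gc_fraction: float
    cds_fraction: float | None = None


@dataclass
class CohortSummary:
    group: list[str]
    mean: float
    sd: float
    statistic_name: str = ""


_VALID = re.compile(r"[^ACGTN]")


def sanitize_sequence(seq: str, context: str = "") -> str:
    """Uppercase and replace characters outside A/C/G/T/N by N."""
    up = seq.upper()
    bad = _VALID.findall(up)
    if bad:
        logger.warning(
            "replaced %d non-ACGTN characters by N%s",
            len(bad), f" in {context}" if context else "",
        )
        up = _VALID.sub("N", up)
    return up


def read_fasta(path, strain_id: str | None = None,
               ploidy_label: str = "unknown") -> Assembly:
    """Read a FASTA file into an :class:`Assembly`.

    Sequences are uppercased; characters outside the A/C/G/T/N alphabet are
    replaced by N with a logged warning.  An empty file or a duplicate
    contig id raises :class:`FastaFormatError`.
    """
    path = str(path)
    contigs: list[tuple[str, str]] = []
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            cid = header.split()[0]
            contigs.append((cid, sanitize_sequence(seq, context=cid)))
    if not contigs:
        raise FastaFormatError(f"no sequences in {path}")
    if strain_id is None:
        strain_id = path.rsplit("/", 1)[-1].split(".")[0]
    return Assembly(strain_id, contigs, ploidy_label)


def write_fasta(assembly_or_records, path, width: int = 80) -> None:
    """Write an Assembly or an iterable of (id, seq) pairs as FASTA."""
    records = (assembly_or_records.contigs
               if isinstance(assembly_or_records, Assembly)
               else assembly_or_records)
    with open(path, "w") as fh:
        for cid, seq in records:
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def n50(lengths) -> int:
    lengths = sorted(lengths, reverse=True)
    half = sum(lengths) / 2
    acc = 0
    for ln in lengths:
        acc += ln
        if acc >= half:
            return ln
    return 0


def assembly_stats(assembly: Assembly,
                   cds_total_bp: int | None = None) -> AssemblyStats:
    """Summary statistics for one assembly (sizes, N50, GC, CDS share)."""
    if not assembly.contigs:
        raise ValueError("empty assembly")
    lengths = [len(s) for _, s in assembly.contigs]
    total = sum(lengths)
    gc = at = 0
    for _, seq in assembly.contigs:
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
    gc_fraction = gc / (gc + at) if gc + at else math.nan
    cds_fraction = None
    if cds_total_bp is not None:
        if cds_total_bp > total:
            raise ValueError("cds_total_bp exceeds assembly size")
        cds_fraction = cds_total_bp / total
    return AssemblyStats(total, len(lengths), n50(lengths), gc_fraction,
                         cds_fraction)


def cohort_summary(values, group, statistic_name: str = "") -> CohortSummary:
    """Mean and sample (n-1) SD of a statistic over a group of strains."""
    values = np.asarray(list(values), dtype=float)
    if values.size < 2:
        raise ValueError("cohort summary needs at least two values")
    return CohortSummary(list(group), float(values.mean()),
                         float(values.std(ddof=1)), statistic_name)
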