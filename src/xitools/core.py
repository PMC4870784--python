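"""Shared genomic data model and interval arithmetic.

Coordinate conventions are centralised here: intervals (BED, bedGraph,
peaks, genes, CGIs, repeats) are 0-based half-open; point positions (SNPs,
CpGs) are 1-based, following the VCF convention.  :func:`point_in_interval`
is the single converter between the two.  Strand is carried on intervals
but ignored by every coverage/overlap computation in the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("xitools")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def point_in_interval(pos_1based: int, iv: GenomicInterval) -> bool:
    """Whether a 1-based point position falls inside a half-open interval.

    A 1-based position ``p`` corresponds to the 0-based offset ``p - 1``,
    so membership is ``iv.start <= p - 1 < iv.end``.
    """
    return iv.start <= pos_1based - 1 < iv.end


def overlap_bp(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Overlap in bp between two half-open intervals on the same chromosome."""
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def interval_distance(a: GenomicInterval, b: GenomicInterval) -> int | None:
    """Edge-to-edge distance in bp; 0 if overlapping; None on different chroms."""
    if a.chrom != b.chrom:
        return None
    if a.start < b.end and b.start < a.end:
        return 0
    if a.end <= b.start:
        return b.start - a.end
    return a.start - b.end


def nearest_distance(iv: GenomicInterval, others: list[GenomicInterval]) -> int | None:
    """Distance to the nearest interval in ``others`` (same chromosome only)."""
    dists = [d for o in others if (d := interval_distance(iv, o)) is not None]
    return min(dists) if dists else None


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/adjacent intervals into a sorted, disjoint set."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda i: (i.chrom, i.start, i.end)):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            prev = out.pop()
            out.append(
                GenomicInterval(prev.chrom, prev.start, max(prev.end, iv.end),
                                label=prev.label)
            )
        else:
            out.append(iv)
    return out


@dataclass
class Gene:
    """A gene with exon sub-intervals (all 0-based half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid gene body for {self.gene_id}")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(
                    f"exon {s}-{e} not nested within gene {self.gene_id}"
                )

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end,
                               self.strand, self.gene_id)

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


REPEAT_CLASSES = ("LTR", "LINE", "SINE", "DNA", "Simple", "Other")


@dataclass
class GenomeAnnotation:
    """Genome-wide annotation: genes with exons, pseudogenes, CGIs, repeats, SNPs.

    ``snps`` is a DataFrame with columns ``chrom, pos, ref, alt, strain``
    (``pos`` 1-based; ``strain`` records the allele of origin used to call
    the Xi, e.g. CAST).  ``repeats`` carry their class in ``label``.
    """

    chrom_lengths: dict[str, int]
    genes: list[Gene] = field(default_factory=list)
    pseudogenes: list[GenomicInterval] = field(default_factory=list)
    cgis: list[GenomicInterval] = field(default_factory=list)
    repeats: list[GenomicInterval] = field(default_factory=list)
    snps: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt", "strain"]
        )
    )

    def validate(self) -> None:
        for g in self.genes:
            if g.end > self.chrom_lengths.get(g.chrom, -1):
                raise ValueError(f"gene {g.gene_id} exceeds chromosome length")
        for name, ivs in (
            ("pseudogene", self.pseudogenes),
            ("CGI", self.cgis),
            ("repeat", self.repeats),
        ):
            for iv in ivs:
                if iv.end > self.chrom_lengths.get(iv.chrom, -1):
                    raise ValueError(f"{name} {iv} exceeds chromosome length")
        for iv in self.repeats:
            if iv.label not in REPEAT_CLASSES:
                raise ValueError(f"unknown repeat class {iv.label!r}")
        if self.snps.duplicated(subset=["chrom", "pos"]).any():
            raise ValueError("duplicate SNP positions on a chromosome")

    def exonic_snps(self) -> pd.DataFrame:
        """SNPs inside exons, annotated with their gene id.

        Returns a copy of ``snps`` with ``gene_id`` and ``exonic`` columns.
        """
        snps = self.snps.copy()
        gene_id = np.full(len(snps), None, dtype=object)
        exonic = np.zeros(len(snps), dtype=bool)
        pos0 = snps["pos"].to_numpy() - 1
        chrom = snps["chrom"].to_numpy()
        for g in self.genes:
            in_gene = (chrom == g.chrom) & (pos0 >= g.start) & (pos0 < g.end)
            if not in_gene.any():
                continue
            gene_id[in_gene] = g.gene_id
            for s, e in g.exons:
                exonic |= in_gene & (pos0 >= s) & (pos0 < e)
        snps["gene_id"] = gene_id
        snps["exonic"] = exonic
        return snps


@dataclass
class SampleMeta:
    """Sample-sheet record for one sequencing library."""

    sample_id: str
    sex: str = "female"
    genotype: str = ""
    hairpin: str = "Nons"
    timepoint: str = "NA"
    replicate: int = 1
    library_size: int = 1

    def __post_init__(self) -> None:
        if self.sex not in {"female", "male"}:
            raise ValueError("sex must be 'female' or 'male'")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")
        if self.library_size <= 0:
            raise ValueError("library_size must be > 0")


def log_filter(name: str, n_in: int, n_out: int) -> None:
    """INFO-log a filter's input/output record counts (greppable bookkeeping)."""
    logger.info("filter %s: %d in, %d surviving, %d removed",
                name, n_in, n_out, n_in - n_out)
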