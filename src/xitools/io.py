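"""Readers and writers for the plain-text formats the pipeline consumes.

BED and bedGraph are 0-based half-open.  Count tables (allelic SNP counts,
CpG methylation calls, hairpin counts) travel as TSV with a header row.
Floats are written with ``repr``-level precision so write→read round-trips
are exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from xitools.core import GenomicInterval


class BedParseError(ValueError):
    pass


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED file (>=3 columns) into a list of intervals, in file order."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            label = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            try:
                intervals.append(GenomicInterval(fields[0], start, end, strand, label))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: list[GenomicInterval], path: str | Path,
              scores: list[float] | None = None) -> None:
    """Write intervals as BED4 (or BED5 when per-interval scores are given)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            cols = [iv.chrom, str(iv.start), str(iv.end), iv.label or "."]
            if scores is not None:
                cols.append(repr(float(scores[i])))
            fh.write("\t".join(cols) + "\n")


def write_bedgraph(track, path: str | Path) -> None:
    """Write a :class:`~xitools.chip.BinnedTrack` as 4-column bedGraph.

    Sliding windows (step < width) are flattened to step-width records, each
    taking the value of the window centred on it; non-sliding tracks emit one
    record per bin.  Values are written with full float precision.
    """
    records = track.to_records()
    starts = records["start"].to_numpy()
    if len(starts) > 1 and (np.diff(starts) <= 0).any():
        raise ValueError("bedGraph records must be sorted and non-overlapping")
    with open(path, "w") as fh:
        for row in records.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.value!r}\n")


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph into a DataFrame with columns chrom,start,end,value."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise BedParseError(f"{path}:{lineno}: expected 4 columns")
            rows.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


# ---------------------------------------------------------------------------
# TSV tables

def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


ALLELIC_COLUMNS = ["chrom", "pos", "gene_id", "exonic", "sample_id",
                   "hairpin", "timepoint", "replicate", "xi_count", "xa_count"]


def read_allelic_counts(path: str | Path) -> pd.DataFrame:
    """Read a VCF-lite allelic count table (per-SNP Xi/Xa read counts)."""
    df = read_tsv(path)
    missing = [c for c in ("chrom", "pos", "xi_count", "xa_count")
               if c not in df.columns]
    if missing:
        raise ValueError(f"allelic count table missing columns: {missing}")
    if (df[["xi_count", "xa_count"]] < 0).any().any():
        raise ValueError("negative allelic counts")
    return df


def read_cpg_table(path: str | Path) -> pd.DataFrame:
    """Read a CpG methylation-call table (chrom,pos,allele,condition,replicate,meth,unmeth)."""
    df = read_tsv(path)
    missing = [c for c in ("chrom", "pos", "meth", "unmeth") if c not in df.columns]
    if missing:
        raise ValueError(f"CpG table missing columns: {missing}")
    return df


def write_ground_truth(truth, path: str | Path) -> None:
    """Serialise a :class:`~xitools.simulate.GroundTruth` to JSON."""
    payload = {
        "reactivating_genes": sorted(truth.reactivating_genes),
        "enriched_regions": {
            mark: [[iv.chrom, iv.start, iv.end] for iv in ivs]
            for mark, ivs in truth.enriched_regions.items()
        },
        "demethylated_cgis": [[iv.chrom, iv.start, iv.end]
                              for iv in truth.demethylated_cgis],
        "screen_hits": sorted(truth.screen_hits),
        "if_peak_positions": truth.if_peak_positions,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
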