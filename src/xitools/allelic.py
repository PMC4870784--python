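"""Allele-specific RNA-seq computations.

The atom is a per-SNP, per-sample pair of read counts assigned to the
inactive-X (Xi, CAST) and active-X (Xa, domesticus) alleles.  The module
implements the Xi/Xa ratio with its +1 pseudocount, the rule-based
reactivating-SNP classifier (both knockdown hairpins above the
non-silencing control, in every replicate), gene-level aggregation to
reactivating-gene sets, the informative-SNP rule for a PGK-marked cross,
and gene-level allelic contingency testing with Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from xitools.core import log_filter
from xitools.simulate import CONTROL_HAIRPIN, KNOCKDOWN_HAIRPINS

SNP_KEY = ["chrom", "pos"]


def filter_snps(counts: pd.DataFrame, min_total: int = 10,
                exonic_only: bool = True) -> pd.DataFrame:
    """Keep exonic SNP records covered by at least ``min_total`` reads.

    Coverage is assessed per (SNP, sample) record: a SNP may pass in one
    sample and fail in another.
    """
    total = counts["xi_count"] + counts["xa_count"]
    keep = total >= min_total
    if exonic_only and "exonic" in counts.columns:
        keep &= counts["exonic"].astype(bool)
    out = counts.loc[keep].reset_index(drop=True)
    log_filter("snp_min_total", len(counts), len(out))
    return out


def xi_xa_ratio(filtered: pd.DataFrame) -> pd.DataFrame:
    """Xi/Xa expression ratio per record, with a +1 pseudocount on each count."""
    out = filtered.copy()
    out["total"] = out["xi_count"] + out["xa_count"]
    out["ratio"] = (out["xi_count"] + 1) / (out["xa_count"] + 1)
    return out


def classify_reactivating(
    ratios: pd.DataFrame,
    timepoint: str = "day5",
    control: str = CONTROL_HAIRPIN,
    knockdowns: tuple[str, str] = KNOCKDOWN_HAIRPINS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call reactivating SNPs: both knockdown ratios above the control ratio.

    Per replicate, a SNP is reactivating iff its Xi/Xa ratio is strictly
    larger under *both* knockdown hairpins than under the control; ties
    fail.  The consensus set contains SNPs called reactivating in every
    replicate (SNPs lacking a condition in a replicate are excluded from
    that replicate and cannot reach consensus).

    Returns (per-replicate calls, consensus SNP table).
    """
    sub = ratios[ratios["timepoint"] == timepoint]
    wide = sub.pivot_table(index=SNP_KEY + ["gene_id", "replicate"],
                           columns="hairpin", values="ratio", aggfunc="first")
    needed = [control, *knockdowns]
    missing_cols = [c for c in needed if c not in wide.columns]
    if missing_cols:
        raise ValueError(f"conditions absent from ratio table: {missing_cols}")
    n_before = len(wide)
    wide = wide.dropna(subset=needed)
    log_filter("reactivation_complete_conditions", n_before, len(wide))
    calls = wide.reset_index()
    calls["is_reactivating"] = (
        (calls[knockdowns[0]] > calls[control])
        & (calls[knockdowns[1]] > calls[control])
    )
    calls = calls[SNP_KEY + ["gene_id", "replicate", "is_reactivating"]]

    n_reps = ratios["replicate"].nunique()
    per_snp = calls.groupby(SNP_KEY + ["gene_id"], dropna=False).agg(
        n_replicates=("replicate", "nunique"),
        n_reactivating=("is_reactivating", "sum"),
    ).reset_index()
    consensus = per_snp[(per_snp["n_replicates"] == n_reps)
                        & (per_snp["n_reactivating"] == n_reps)]
    return calls, consensus.reset_index(drop=True)


@dataclass
class ReactivatingGenes:
    """Per-replicate reactivating-gene sets and their intersection."""

    per_replicate: dict[int, set[str]]
    intersection: set[str]
    n_snp_genes: int

    @property
    def fraction_of_snp_genes(self) -> float:
        return len(self.intersection) / self.n_snp_genes if self.n_snp_genes else 0.0


def reactivating_genes(calls: pd.DataFrame,
                       snp_genes: set[str] | None = None) -> ReactivatingGenes:
    """Aggregate SNP calls to gene sets: a gene is reactivating in a replicate
    iff at least one of its SNPs is; the headline set is the intersection
    across replicates, reported as a fraction of genes with >=1 filtered SNP.
    """
    if snp_genes is None:
        snp_genes = set(calls["gene_id"].dropna().unique())
    per_rep: dict[int, set[str]] = {}
    for rep, grp in calls.groupby("replicate"):
        per_rep[int(rep)] = set(
            grp.loc[grp["is_reactivating"], "gene_id"].dropna().unique())
    inter = set.intersection(*per_rep.values()) if per_rep else set()
    return ReactivatingGenes(per_rep, inter, len(snp_genes))


def mean_xi_expression(ratios: pd.DataFrame, group_col: str,
                       group_a: str, group_b: str,
                       pooled_var: bool = False) -> dict:
    """Two-group comparison of Xi/Xa ratios (two-tailed t; Welch by default).

    Returns the per-group means and the p-value; groups of size < 2 are
    flagged and yield no p-value.
    """
    a = ratios.loc[ratios[group_col] == group_a, "ratio"].to_numpy(float)
    b = ratios.loc[ratios[group_col] == group_b, "ratio"].to_numpy(float)
    result = {"mean_a": float(np.mean(a)) if a.size else np.nan,
              "mean_b": float(np.mean(b)) if b.size else np.nan,
              "n_a": int(a.size), "n_b": int(b.size),
              "p_value": np.nan, "flag": ""}
    if a.size < 2 or b.size < 2:
        result["flag"] = "group_too_small"
        return result
    t = stats.ttest_ind(a, b, equal_var=pooled_var)
    p = float(t.pvalue)
    if not np.isfinite(p):
        # both groups constant: no evidence either way if means agree
        p = 1.0 if np.isclose(result["mean_a"], result["mean_b"]) else 0.0
        result["flag"] = "degenerate_zero_variance"
    result["p_value"] = p
    return result


def call_informative_snps(variants: pd.DataFrame, pgk_sample: str,
                          control_samples: list[str],
                          predominance_threshold: float = 0.5) -> pd.DataFrame:
    """Informative (PGK) SNPs: reference allele absent from the PGK sample and
    the alternate allele not predominating in the pooled control samples.

    ``variants`` is long-form with columns chrom, pos, sample_id, ref_count,
    alt_count.  A variant with zero control coverage is excluded (logged).
    """
    wide_ref = variants.pivot_table(index=SNP_KEY, columns="sample_id",
                                    values="ref_count", aggfunc="sum", fill_value=0)
    wide_alt = variants.pivot_table(index=SNP_KEY, columns="sample_id",
                                    values="alt_count", aggfunc="sum", fill_value=0)
    if pgk_sample not in wide_ref.columns:
        raise ValueError(f"PGK sample {pgk_sample!r} absent from table")
    ctrl_ref = wide_ref[control_samples].sum(axis=1)
    ctrl_alt = wide_alt[control_samples].sum(axis=1)
    ctrl_total = ctrl_ref + ctrl_alt
    n_zero = int((ctrl_total == 0).sum())
    if n_zero:
        log_filter("informative_zero_control", len(wide_ref),
                   len(wide_ref) - n_zero)
    ok = ctrl_total > 0
    alt_frac = ctrl_alt[ok] / ctrl_total[ok]
    keep = (wide_ref.loc[ok, pgk_sample] == 0) & \
        (alt_frac <= predominance_threshold)
    out = keep[keep].index.to_frame(index=False)
    log_filter("informative_snps", len(wide_ref), len(out))
    return out


def gene_level_allelic_test(variants: pd.DataFrame, genes: pd.DataFrame,
                            control_samples: list[str],
                            treated_samples: list[str]) -> pd.DataFrame:
    """Per-gene 2x2 allelic contingency test between conditions.

    Allele counts of all variants falling between a gene's start and end are
    summed into a (ref, alt) x (control, treated) table tested with a
    two-sided Fisher's exact test; Benjamini-Hochberg q-values are added
    across genes.  ``genes`` needs columns gene_id, chrom, start, end
    (half-open); variant positions are 1-based.
    """
    var = variants.copy()
    agg = var.groupby(SNP_KEY + ["sample_id"])[["ref_count", "alt_count"]] \
             .sum().reset_index()
    in_ctrl = agg["sample_id"].isin(control_samples)
    in_trt = agg["sample_id"].isin(treated_samples)
    rows = []
    for g in genes.itertuples(index=False):
        inside = ((agg["chrom"] == g.chrom) & (agg["pos"] - 1 >= g.start)
                  & (agg["pos"] - 1 < g.end))
        if not inside.any():
            continue
        rc = int(agg.loc[inside & in_ctrl, "ref_count"].sum())
        ac = int(agg.loc[inside & in_ctrl, "alt_count"].sum())
        rt = int(agg.loc[inside & in_trt, "ref_count"].sum())
        at = int(agg.loc[inside & in_trt, "alt_count"].sum())
        table = [[rc, rt], [ac, at]]
        degenerate = (rc + rt == 0) or (ac + at == 0) or \
                     (rc + ac == 0) or (rt + at == 0)
        if degenerate:
            p, odds = 1.0, np.nan
        else:
            odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append({"gene_id": g.gene_id, "ref_control": rc, "alt_control": ac,
                     "ref_treated": rt, "alt_treated": at,
                     "odds_ratio": odds, "p_value": p,
                     "degenerate": degenerate})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
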