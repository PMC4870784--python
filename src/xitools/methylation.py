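"""Allele-aware differential DNA methylation at CpG islands.

Input is a long-form table of bisulphite methylation calls: one row per
(CpG, allele, condition, replicate) with methylated/unmethylated read
counts.  The stages are a strict >20-read coverage filter, per-CpG
two-tailed t-tests on percentage methylation across replicates, an Xi vs
Xa log2(mC/C) contrast, CGI-level pooled calls with a >20 %-mC methylated
class, and a CGI-length-normalised methylation profile.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from xitools.core import GenomicInterval, log_filter

CPG_KEY = ["chrom", "pos"]


def add_derived_columns(sites: pd.DataFrame, pseudocount: int = 1) -> pd.DataFrame:
    """Attach coverage, pct_mc and log2((meth+pc)/(unmeth+pc)) columns."""
    out = sites.copy()
    out["coverage"] = out["meth"] + out["unmeth"]
    out["pct_mc"] = 100.0 * out["meth"] / out["coverage"].replace(0, np.nan)
    out["log2_ratio"] = np.log2((out["meth"] + pseudocount)
                                / (out["unmeth"] + pseudocount))
    return out


def filter_cpgs(sites: pd.DataFrame, min_coverage_exclusive: int = 20) -> pd.DataFrame:
    """Keep CpG records covered by strictly more than ``min_coverage_exclusive`` reads."""
    coverage = sites["meth"] + sites["unmeth"]
    out = sites.loc[coverage > min_coverage_exclusive].reset_index(drop=True)
    log_filter("cpg_min_coverage", len(sites), len(out))
    return add_derived_columns(out)


def _welch_rows(a: np.ndarray, b: np.ndarray) -> tuple[float, str]:
    """Two-tailed Welch t p-value with explicit degenerate handling."""
    if np.var(a) == 0 and np.var(b) == 0:
        if np.isclose(a.mean(), b.mean()):
            return 1.0, "degenerate_equal"
        return 0.0, "degenerate_separated"
    with warnings.catch_warnings():
        # near-identical replicate values trip scipy's precision warning
        warnings.simplefilter("ignore", RuntimeWarning)
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return p, ""


def differential_cpgs(
    filtered: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    alpha: float = 0.05,
    min_replicates: int = 2,
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-CpG differential methylation between conditions across replicates.

    A two-tailed t-test (Welch) compares the per-replicate percentage
    methylation of the two conditions at each CpG with at least
    ``min_replicates`` replicates in both; CpGs with fewer are excluded
    (logged).  Direction is the sign of the B - A mean difference.  With
    ``adjust`` set, significance uses Benjamini-Hochberg q-values instead of
    raw p-values.
    """
    sub = filtered[filtered["condition"].isin([condition_a, condition_b])]
    group_cols = CPG_KEY + (["allele"] if "allele" in sub.columns else [])
    rows = []
    n_groups = 0
    for key, grp in sub.groupby(group_cols):
        n_groups += 1
        a = grp.loc[grp["condition"] == condition_a, "pct_mc"].to_numpy(float)
        b = grp.loc[grp["condition"] == condition_b, "pct_mc"].to_numpy(float)
        if len(a) < min_replicates or len(b) < min_replicates:
            continue
        p, flag = _welch_rows(a, b)
        rec = dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
        rec.update({"mean_a": a.mean(), "mean_b": b.mean(),
                    "delta_pct_mc": b.mean() - a.mean(),
                    "p_value": p, "flag": flag})
        rows.append(rec)
    out = pd.DataFrame(rows)
    log_filter("cpg_enough_replicates", n_groups, len(out))
    if out.empty:
        return out
    crit = multipletests(out["p_value"], method="fdr_bh")[1] if adjust \
        else out["p_value"]
    out["significant"] = np.asarray(crit) < alpha
    out["direction"] = np.where(out["delta_pct_mc"] > 0, "gain",
                                np.where(out["delta_pct_mc"] < 0, "loss", "none"))
    return out


def xi_xa_contrast(filtered: pd.DataFrame, condition: str | None = None) -> dict:
    """Xi vs Xa log2(mC/C) distributions with medians and a two-tailed t-test."""
    sub = filtered if condition is None else \
        filtered[filtered["condition"] == condition]
    xi = sub.loc[sub["allele"] == "Xi", "log2_ratio"].to_numpy(float)
    xa = sub.loc[sub["allele"] == "Xa", "log2_ratio"].to_numpy(float)
    if xi.size == 0:
        raise ValueError("no Xi-assigned CpGs")
    p, flag = _welch_rows(xi, xa) if xa.size >= 2 and xi.size >= 2 else (np.nan, "too_few")
    return {"xi_median": float(np.median(xi)),
            "xa_median": float(np.median(xa)) if xa.size else np.nan,
            "xi_mean": float(np.mean(xi)),
            "xa_mean": float(np.mean(xa)) if xa.size else np.nan,
            "n_xi": int(xi.size), "n_xa": int(xa.size),
            "p_value": p, "flag": flag}


def cgi_calls(
    filtered: pd.DataFrame,
    cgis: list[GenomicInterval],
    condition_a: str,
    condition_b: str,
    alpha: float = 0.05,
    methylated_class_threshold: float = 20.0,
) -> pd.DataFrame:
    """CGI-level differential methylation calls.

    Per CGI, the per-replicate pct_mc values of all member CpGs are pooled
    within each condition and compared with a two-tailed t-test; the class
    is 'methylated' when the control-condition mean is strictly above the
    class threshold (20 % mC); a CGI has reduced methylation when the test
    is significant and the mean dropped in condition B.
    """
    sub = filtered[filtered["condition"].isin([condition_a, condition_b])]
    chrom_arr = sub["chrom"].to_numpy()
    pos_arr = sub["pos"].to_numpy()
    rows = []
    for iv in sorted(cgis, key=lambda i: (i.chrom, i.start)):
        inside = (chrom_arr == iv.chrom) & (pos_arr - 1 >= iv.start) \
            & (pos_arr - 1 < iv.end)
        grp = sub.loc[inside]
        n_cpgs = grp[CPG_KEY].drop_duplicates().shape[0]
        rec = {"chrom": iv.chrom, "start": iv.start, "end": iv.end,
               "label": iv.label, "n_cpgs": n_cpgs}
        if n_cpgs == 0:
            rec.update({"mean_a": np.nan, "mean_b": np.nan, "p_value": np.nan,
                        "cgi_class": "no_data", "significant": False,
                        "reduced": False})
            rows.append(rec)
            continue
        a = grp.loc[grp["condition"] == condition_a, "pct_mc"].to_numpy(float)
        b = grp.loc[grp["condition"] == condition_b, "pct_mc"].to_numpy(float)
        p, flag = _welch_rows(a, b) if min(a.size, b.size) >= 2 else (np.nan, "too_few")
        significant = bool(p < alpha) if np.isfinite(p) else False
        rec.update({
            "mean_a": a.mean() if a.size else np.nan,
            "mean_b": b.mean() if b.size else np.nan,
            "p_value": p,
            "cgi_class": ("methylated"
                          if a.size and a.mean() > methylated_class_threshold
                          else "unmethylated"),
            "significant": significant,
            "reduced": significant and b.mean() < a.mean(),
        })
        rows.append(rec)
    return pd.DataFrame(rows)


def cgi_meta_profile(
    filtered: pd.DataFrame,
    cgis: list[GenomicInterval],
    n_positions: int = 100,
    by_condition: bool = True,
) -> pd.DataFrame:
    """Mean %mC along the length-normalised CGI axis.

    Each CpG maps to its relative position (pos - start) / (end - start)
    within its CGI; pct_mc values are averaged within ``n_positions`` equal
    relative-width bins across all CGIs (per condition).  CGIs with fewer
    than 2 passing CpGs are skipped (logged).
    """
    frames = []
    n_skipped = 0
    chrom_arr = filtered["chrom"].to_numpy()
    pos_arr = filtered["pos"].to_numpy()
    for iv in cgis:
        inside = (chrom_arr == iv.chrom) & (pos_arr - 1 >= iv.start) \
            & (pos_arr - 1 < iv.end)
        grp = filtered.loc[inside]
        if grp[CPG_KEY].drop_duplicates().shape[0] < 2:
            n_skipped += 1
            continue
        rel = (grp["pos"].to_numpy() - 1 - iv.start) / (iv.end - iv.start)
        grp = grp.assign(rel_bin=np.minimum((rel * n_positions).astype(int),
                                            n_positions - 1))
        frames.append(grp)
    log_filter("cgi_profile_usable", len(cgis), len(cgis) - n_skipped)
    if not frames:
        return pd.DataFrame(columns=["condition", "rel_position", "mean_pct_mc"])
    allcpg = pd.concat(frames, ignore_index=True)
    keys = ["condition", "rel_bin"] if by_condition else ["rel_bin"]
    prof = allcpg.groupby(keys)["pct_mc"].mean().reset_index()
    prof["rel_position"] = (prof["rel_bin"] + 0.5) / n_positions
    return prof.rename(columns={"pct_mc": "mean_pct_mc"}).drop(columns="rel_bin")
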