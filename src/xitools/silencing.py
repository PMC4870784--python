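"""Gene-silencing classification during differentiation and repeat enrichment.

Genes are classed from their control (Nons) expression across the
differentiation time course relative to nearby Setdb1 peaks: *silenced*
(> 2 log2 drop between consecutive time points, within 200 kb of a peak),
*stable* (< 0.5 log2 fold change between Nons samples), *maintained
silent* (expression below 0.5 at all time points), with maintained-silent
taking precedence over silenced over stable.  The module also compares
class expression between knockdown and control, tests repeat-class
over-representation among differentially expressed repeats by chi-square,
and provides RPKM and the 2^-ddCt qRT-PCR quantitation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from xitools.core import GenomicInterval, interval_distance


def rpkm(counts: pd.DataFrame, gene_lengths_bp: pd.Series,
         library_sizes: pd.Series) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads, per gene x sample."""
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be > 0")
    if (gene_lengths_bp <= 0).any():
        raise ValueError("gene lengths must be > 0")
    kb = gene_lengths_bp.loc[counts.index] / 1000.0
    millions = library_sizes.loc[counts.columns] / 1e6
    return counts.div(kb, axis=0).div(millions, axis=1)


def nearest_peak_distance(gene: GenomicInterval,
                          peaks: list[GenomicInterval]) -> float:
    """Edge-to-edge distance from a gene body to its nearest peak (0 if
    overlapping, inf if no peak shares the chromosome)."""
    dists = [d for p in peaks if (d := interval_distance(gene, p)) is not None]
    return float(min(dists)) if dists else np.inf


def classify_genes(
    expression: pd.DataFrame,
    gene_intervals: dict[str, GenomicInterval],
    setdb1_peaks: list[GenomicInterval],
    timepoints: tuple[str, ...] = ("day0", "day3", "day5"),
    proximity_bp: int = 200_000,
    silenced_log2fc: float = 2.0,
    stable_log2fc: float = 0.5,
    silent_level: float = 0.5,
    pseudocount: float = 0.1,
) -> pd.DataFrame:
    """Silencing classification from replicate-averaged control expression.

    ``expression`` is genes x timepoints (replicate-averaged Nons values).
    Precedence: maintained_silent > silenced (earliest qualifying interval)
    > stable > unclassified; genes missing a time point are unclassified.
    """
    rows = []
    for gene_id, expr in expression.iterrows():
        iv = gene_intervals.get(gene_id)
        dist = nearest_peak_distance(iv, setdb1_peaks) if iv is not None else np.inf
        rec = {"gene_id": gene_id, "nearest_peak_bp": dist}
        vals = expr.reindex(list(timepoints))
        if vals.isna().any():
            rec["silencing_class"] = "unclassified"
            rows.append(rec)
            continue
        v = vals.to_numpy(float)
        logv = np.log2(v + pseudocount)
        if (v < silent_level).all():
            rec["silencing_class"] = "maintained_silent"
        else:
            silenced = None
            for i in range(len(timepoints) - 1):
                drop = logv[i] - logv[i + 1]
                if drop > silenced_log2fc and dist <= proximity_bp:
                    silenced = f"silenced_{timepoints[i]}_{timepoints[i + 1]}"
                    break
            if silenced is not None:
                rec["silencing_class"] = silenced
            else:
                pairwise_max = max(abs(logv[i] - logv[j])
                                   for i in range(len(logv))
                                   for j in range(i + 1, len(logv)))
                rec["silencing_class"] = ("stable" if pairwise_max < stable_log2fc
                                          else "unclassified")
        rows.append(rec)
    return pd.DataFrame(rows)


def compare_classes(
    expression: pd.DataFrame,
    classes: pd.DataFrame,
    knockdown_col: str,
    control_col: str,
    paired: bool = False,
) -> pd.DataFrame:
    """Per-class knockdown vs control expression comparison (two-tailed t).

    ``expression`` is genes x samples with at least the two named columns.
    Classes with fewer than 2 genes are flagged and carry no p-value.
    """
    rows = []
    for cls, grp in classes.groupby("silencing_class"):
        ids = [g for g in grp["gene_id"] if g in expression.index]
        kd = expression.loc[ids, knockdown_col].to_numpy(float)
        ct = expression.loc[ids, control_col].to_numpy(float)
        rec = {"silencing_class": cls, "n_genes": len(ids),
               "mean_knockdown": float(np.mean(kd)) if len(ids) else np.nan,
               "mean_control": float(np.mean(ct)) if len(ids) else np.nan,
               "p_value": np.nan, "flag": ""}
        if len(ids) < 2:
            rec["flag"] = "class_too_small"
        else:
            test = stats.ttest_rel(kd, ct) if paired else \
                stats.ttest_ind(kd, ct, equal_var=False)
            p = float(test.pvalue)
            rec["p_value"] = p if np.isfinite(p) else 1.0
        rows.append(rec)
    return pd.DataFrame(rows)


def repeat_de(
    repeats: pd.DataFrame,
    knockdown_col: str,
    control_col: str,
    log2fc_threshold: float = 1.0,
    pseudocount: float = 0.1,
) -> dict:
    """Repeat-class enrichment among differentially expressed repeats.

    A repeat is differentially expressed when |log2 fold change| between the
    (replicate-averaged) knockdown and control expression exceeds the
    threshold.  The class x {DE, not-DE} contingency table is tested with a
    chi-square test of independence; adjusted standardised residuals
    identify the over-represented classes.  When more than 20 % of expected
    cells fall below 1, a warning flag suggests an exact-test fallback.
    """
    df = repeats.copy()
    df["log2fc"] = np.log2((df[knockdown_col] + pseudocount)
                           / (df[control_col] + pseudocount))
    df["is_de"] = df["log2fc"].abs() > log2fc_threshold
    table = pd.crosstab(df["repeat_class"], df["is_de"]) \
        .reindex(columns=[False, True], fill_value=0)
    chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
    row_frac = table.sum(axis=1).to_numpy()[:, None] / table.to_numpy().sum()
    col_frac = table.sum(axis=0).to_numpy()[None, :] / table.to_numpy().sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        resid = (table.to_numpy() - expected) / np.sqrt(
            expected * (1 - row_frac) * (1 - col_frac))
    residuals = pd.DataFrame(resid, index=table.index,
                             columns=["not_de", "de"])
    small_expected = float((expected < 1).mean())
    return {"per_repeat": df, "contingency": table,
            "chi2": float(chi2), "p_value": float(p), "dof": int(dof),
            "residuals": residuals,
            "warning": ("sparse_expected_counts; consider an exact test"
                        if small_expected > 0.2 else "")}


def ddct(
    target_ct: pd.Series,
    housekeeping_ct: pd.DataFrame | pd.Series,
    reference_sample: str,
) -> pd.Series:
    """Relative expression by the 2^-ddCt method.

    dCt = target Ct minus the mean housekeeping Ct (equivalent to the
    geometric mean of housekeeping expression when several controls are
    given); expression is 2^-(dCt_sample - dCt_reference), so the reference
    sample is 1 by construction.
    """
    hk = housekeeping_ct if isinstance(housekeeping_ct, pd.DataFrame) \
        else housekeeping_ct.to_frame()
    if not np.isfinite(target_ct).all() or not np.isfinite(hk.to_numpy()).all():
        raise ValueError("Ct values must be finite")
    dct = target_ct - hk.mean(axis=1)
    ddct_values = dct - dct.loc[reference_sample]
    return 2.0 ** (-ddct_values)
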