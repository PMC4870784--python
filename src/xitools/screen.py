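"""Pooled shRNA screen readout.

Reads carry a hairpin sequence and a sample barcode at fixed offsets;
matched reads are tallied into a hairpin x sample count matrix.  Hairpins
with fewer than 1000 reads in any initial-time-point replicate are
excluded.  Differential abundance between the sorted populations is
assessed with a conditional exact test — binomial at dispersion 0
(conditioning each hairpin's total on the group library-size proportion),
or a negative-binomial exact test on equalised libraries for a supplied
common dispersion — with Benjamini-Hochberg FDR across hairpins.  A hit is
a hairpin with p < 0.1 and a positive fold change in the GFP+ population.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from xitools.core import log_filter


def tally_hairpins(
    reads: list[str] | pd.Series,
    library: pd.DataFrame,
    barcodes: pd.DataFrame,
    hairpin_slice: tuple[int, int],
    barcode_slice: tuple[int, int],
) -> tuple[pd.DataFrame, int]:
    """Tally reads into a hairpin x sample count matrix by exact matching.

    ``library`` maps hairpin_id -> sequence, ``barcodes`` maps sample_id ->
    sequence; the hairpin and barcode are extracted from each read at the
    given (start, end) offsets.  Returns (counts, n_unmatched); matched +
    unmatched always equals the number of reads.
    """
    if library["sequence"].duplicated().any():
        raise ValueError("duplicate hairpin sequences in library")
    if barcodes["sequence"].duplicated().any():
        raise ValueError("duplicate barcode sequences")
    hp_map = dict(zip(library["sequence"], library["hairpin_id"]))
    bc_map = dict(zip(barcodes["sequence"], barcodes["sample_id"]))
    counts = pd.DataFrame(0, index=library["hairpin_id"],
                          columns=barcodes["sample_id"], dtype=int)
    hs, he = hairpin_slice
    bs, be = barcode_slice
    unmatched = 0
    for read in reads:
        hp = hp_map.get(read[hs:he])
        bc = bc_map.get(read[bs:be])
        if hp is None or bc is None:
            unmatched += 1
            continue
        counts.loc[hp, bc] += 1
    counts.index.name = "hairpin_id"
    return counts, unmatched


def filter_hairpins(counts: pd.DataFrame, initial_columns: list[str],
                    min_initial: int = 1000) -> pd.DataFrame:
    """Keep hairpins with at least ``min_initial`` reads in *every* initial
    replicate (a single replicate below threshold excludes the hairpin)."""
    keep = (counts[initial_columns] >= min_initial).all(axis=1)
    out = counts.loc[keep]
    log_filter("hairpin_min_initial", len(counts), len(out))
    return out


def binomial_exact_pvalue(a: int, n: int, p0: float) -> float:
    """Two-sided exact binomial p-value by the minimum-likelihood rule.

    Sums the probabilities of all outcomes no more likely than the observed
    one (the classic two-sided exact test); equals full enumeration by
    construction.
    """
    if n == 0:
        return 1.0
    k = np.arange(n + 1)
    pmf = stats.binom.pmf(k, n, p0)
    return float(min(1.0, pmf[pmf <= pmf[a] * (1 + 1e-7)].sum()))


def nb_exact_pvalue(a: int, b: int, dispersion: float) -> float:
    """Two-sided exact negative-binomial p-value on equalised libraries.

    Conditional on the total n = a + b, outcome probabilities are the
    normalised products of two NB(size = 1/dispersion, mean = n/2) masses;
    the p-value sums outcomes no more likely than the observed split.
    """
    n = a + b
    if n == 0:
        return 1.0
    size = 1.0 / dispersion
    k = np.arange(n + 1)
    mu = n / 2.0
    logp = stats.nbinom.logpmf(k, size, size / (size + mu)) + \
        stats.nbinom.logpmf(n - k, size, size / (size + mu))
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    return float(min(1.0, prob[prob <= prob[a] * (1 + 1e-7)].sum()))


def exact_test(
    counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    dispersion: float = 0.0,
    alpha: float = 0.1,
    library_sizes: pd.Series | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Exact differential-abundance test per hairpin between two groups.

    Group counts are summed per hairpin.  At dispersion 0 the test is the
    two-sided exact binomial of the group-A sum against the group
    library-size proportion, conditional on the hairpin total; for
    dispersion > 0 the negative-binomial exact test is applied to
    library-equalised counts.  Fold change is computed on reads-per-million
    with a pseudocount; a hit requires p < ``alpha`` and enrichment in
    group A.
    """
    if library_sizes is None:
        library_sizes = counts[group_a + group_b].sum(axis=0)
    lib_a = float(library_sizes[group_a].sum())
    lib_b = float(library_sizes[group_b].sum())
    p0 = lib_a / (lib_a + lib_b)
    a = counts[group_a].sum(axis=1)
    b = counts[group_b].sum(axis=1)
    if dispersion == 0:
        pvals = [binomial_exact_pvalue(int(ai), int(ai + bi), p0)
                 for ai, bi in zip(a, b)]
    else:
        # equalise libraries before conditioning at mean = total/2
        a_eq = np.rint(a * (lib_a + lib_b) / (2 * lib_a)).astype(int)
        b_eq = np.rint(b * (lib_a + lib_b) / (2 * lib_b)).astype(int)
        pvals = [nb_exact_pvalue(int(ai), int(bi), dispersion)
                 for ai, bi in zip(a_eq, b_eq)]
    cpm_a = (a / lib_a + pseudocount / 1e6) * 1e6
    cpm_b = (b / lib_b + pseudocount / 1e6) * 1e6
    out = pd.DataFrame({
        "hairpin_id": counts.index,
        "count_a": a.to_numpy(), "count_b": b.to_numpy(),
        "log2_fold_change": np.log2(cpm_a / cpm_b).to_numpy(),
        "p_value": pvals,
    })
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["is_hit"] = (out["p_value"] < alpha) & (out["log2_fold_change"] > 0)
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)
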