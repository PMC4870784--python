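"""Windowed broad-domain ChIP-seq analysis against an H3 control.

Broad repressive-mark domains are called with a windowed Poisson enrichment
test at 10-kb resolution: per non-overlapping window, the expected count is
the library-scaled H3 (control) count floored at the genome-wide background
rate, a window is significant when the upper-tail Poisson probability of
the observed count falls below the threshold, and adjacent significant
windows merge into one peak.  The same engine covers narrow calling at a
smaller window.  Around it sit peak densities per Mb, percentage bin
coverage and Pearson correlation between tracks, allelic read counting at
peaks with a paired t-test, match (distribution-matching) normalisation
with H3 subtraction, length-normalised meta-profiles and TMM effective
library sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from xitools.core import GenomicInterval, log_filter, overlap_bp

logger = logging.getLogger("xitools")


@dataclass
class BinnedTrack:
    """Fixed-width windowed quantitation along one chromosome.

    Windows start at 0 and advance by ``step`` (< ``width`` means sliding
    windows); window i spans [i*step, i*step + width).
    """

    chrom: str
    width: int
    values: np.ndarray
    step: int | None = None
    normalization: str = "raw"

    def __post_init__(self) -> None:
        if self.step is None:
            self.step = self.width
        if self.step > self.width:
            raise ValueError("step must be <= width")
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    def window_start(self, i: int) -> int:
        return i * self.step

    def to_records(self) -> pd.DataFrame:
        """Flatten to step-width bedGraph records.

        Sliding windows emit one record per step, valued by the window
        centred on it (the window whose centre falls inside the record).
        """
        n = len(self.values)
        starts = np.arange(n) * self.step
        if self.step == self.width:
            rec_starts, rec_values = starts, self.values
        else:
            centers = starts + self.width / 2.0
            rec_starts = np.floor(centers / self.step).astype(int) * self.step
            rec_values = self.values
            # deduplicate: keep the window whose centre is closest to record centre
            order = np.argsort(np.abs(centers - (rec_starts + self.step / 2.0)),
                               kind="stable")
            seen: dict[int, float] = {}
            for i in order:
                seen.setdefault(int(rec_starts[i]), float(rec_values[i]))
            rec_starts = np.array(sorted(seen))
            rec_values = np.array([seen[s] for s in rec_starts])
        return pd.DataFrame({"chrom": self.chrom, "start": rec_starts,
                             "end": rec_starts + self.step,
                             "value": rec_values})


@dataclass
class PeakSet:
    """Sorted, non-overlapping peak intervals with -log10 p scores."""

    mark: str
    intervals: list[GenomicInterval] = field(default_factory=list)
    scores: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.intervals)


def window_counts(reads: pd.DataFrame, chrom: str, length: int,
                  window: int) -> np.ndarray:
    """Read-start counts in non-overlapping windows tiling one chromosome."""
    n = -(-length // window)
    pos = reads.loc[reads["chrom"] == chrom, "pos"].to_numpy()
    return np.bincount(pos // window, minlength=n)[:n].astype(float)


def poisson_window_pvalues(observed: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Upper-tail Poisson probability P(X >= observed | lam) per window."""
    return stats.poisson.sf(np.asarray(observed) - 1, np.asarray(lam))


def call_broad_peaks(
    mark_reads: pd.DataFrame,
    control_reads: pd.DataFrame,
    chrom_lengths: dict[str, int],
    window: int = 10_000,
    p_threshold: float = 1e-5,
    merge_gap: int = 0,
    mark: str = "mark",
) -> PeakSet:
    """Windowed Poisson broad-peak calling against a control track.

    Per window, lambda is the control count scaled by the mark/control
    library-size ratio, floored at the genome-wide mean mark rate per window
    (so empty control regions cannot produce zero-lambda blowups).  Windows
    with Poisson upper-tail probability below ``p_threshold`` are
    significant; runs of significant windows separated by at most
    ``merge_gap`` non-significant windows merge into one peak scored by the
    best window's -log10 p.
    """
    mark_lib = len(mark_reads)
    control_lib = len(control_reads)
    if control_lib == 0:
        raise ValueError("control library is empty")
    scale = mark_lib / control_lib
    total_windows = sum(-(-ln // window) for ln in chrom_lengths.values())
    background = mark_lib / total_windows

    peaks: list[GenomicInterval] = []
    scores: list[float] = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        obs = window_counts(mark_reads, chrom, length, window)
        ctl = window_counts(control_reads, chrom, length, window)
        lam = np.maximum(ctl * scale, background)
        pvals = poisson_window_pvalues(obs, lam)
        sig = pvals < p_threshold
        i = 0
        n = len(sig)
        while i < n:
            if not sig[i]:
                i += 1
                continue
            j = i
            last_sig = i
            while j + 1 < n:
                if sig[j + 1]:
                    j += 1
                    last_sig = j
                elif j + 1 - last_sig <= merge_gap and \
                        np.any(sig[j + 2: j + 2 + merge_gap]):
                    j += 1
                else:
                    break
            start = i * window
            end = min((last_sig + 1) * window, length)
            with np.errstate(divide="ignore"):
                score = float(np.max(-np.log10(pvals[i:last_sig + 1][sig[i:last_sig + 1]])))
            peaks.append(GenomicInterval(chrom, start, end, label=mark))
            scores.append(score)
            i = last_sig + 1
    logger.info("called %d peaks for %s at window=%d p<%g",
                len(peaks), mark, window, p_threshold)
    return PeakSet(mark, peaks, scores)


def peaks_per_mb(peaks: PeakSet, chrom_lengths: dict[str, int],
                 x_chrom: str = "chrX") -> pd.DataFrame:
    """Peak density (peaks per Mb) per chromosome, for X, and pooled autosomes."""
    counts: dict[str, int] = {c: 0 for c in chrom_lengths}
    for iv in peaks.intervals:
        if iv.chrom not in chrom_lengths:
            raise ValueError(f"peak on unknown chromosome {iv.chrom}")
        counts[iv.chrom] += 1
    rows = [{"group": c, "n_peaks": counts[c],
             "length_bp": chrom_lengths[c],
             "peaks_per_mb": counts[c] / chrom_lengths[c] * 1e6}
            for c in sorted(chrom_lengths)]
    auto = [c for c in chrom_lengths if c != x_chrom]
    auto_peaks = sum(counts[c] for c in auto)
    auto_len = sum(chrom_lengths[c] for c in auto)
    if auto_len:
        rows.append({"group": "autosomes", "n_peaks": auto_peaks,
                     "length_bp": auto_len,
                     "peaks_per_mb": auto_peaks / auto_len * 1e6})
    if x_chrom in chrom_lengths:
        rows.append({"group": "X", "n_peaks": counts[x_chrom],
                     "length_bp": chrom_lengths[x_chrom],
                     "peaks_per_mb": counts[x_chrom] / chrom_lengths[x_chrom] * 1e6})
    return pd.DataFrame(rows)


def bin_coverage(intervals: list[GenomicInterval], chrom: str, length: int,
                 bin_width: int = 50_000) -> BinnedTrack:
    """Percentage of each fixed-width bin covered by the (disjoint) intervals."""
    n = -(-length // bin_width)
    covered = np.zeros(n)
    for iv in intervals:
        if iv.chrom != chrom:
            continue
        first = iv.start // bin_width
        last = (iv.end - 1) // bin_width
        for b in range(first, min(last, n - 1) + 1):
            covered[b] += overlap_bp(iv.start, iv.end,
                                     b * bin_width, (b + 1) * bin_width)
    widths = np.full(n, bin_width, dtype=float)
    widths[-1] = length - (n - 1) * bin_width
    return BinnedTrack(chrom, bin_width, 100.0 * covered / widths,
                       normalization="coverage_pct")


def correlate_bins(a: np.ndarray, b: np.ndarray) -> dict:
    """Pearson correlation between two equal-grid bin tracks.

    NaN bins are dropped pairwise; zero variance in either vector leaves r
    undefined (NaN) with a flag.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("bin grids differ")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < 2 or np.std(a) == 0 or np.std(b) == 0:
        return {"r": np.nan, "n": int(len(a)), "flag": "zero_variance"}
    r, p = stats.pearsonr(a, b)
    return {"r": float(r), "n": int(len(a)), "p_value": float(p), "flag": ""}


def allelic_peak_enrichment(
    tagged_reads: pd.DataFrame,
    peaks: PeakSet,
    chrom_lengths: dict[str, int] | None = None,
    non_peak_control: bool = True,
    seed: int = 0,
) -> dict:
    """Xi vs Xa read totals per peak with a paired two-tailed t-test.

    Reads must carry an ``allele`` column ('Xi', 'Xa' or '').  Peaks without
    informative reads are excluded (logged).  When ``non_peak_control`` is
    set, size-matched regions are drawn from the non-peak complement with a
    fixed seed and summarised the same way.
    """
    informative = tagged_reads[tagged_reads["allele"].isin(["Xi", "Xa"])]

    def _summarise(regions: list[GenomicInterval], label: str) -> pd.DataFrame:
        rows = []
        for iv in regions:
            sub = informative[(informative["chrom"] == iv.chrom)
                              & (informative["pos"] >= iv.start)
                              & (informative["pos"] < iv.end)]
            xi = int((sub["allele"] == "Xi").sum())
            xa = int((sub["allele"] == "Xa").sum())
            if xi + xa == 0:
                continue
            rows.append({"chrom": iv.chrom, "start": iv.start, "end": iv.end,
                         "region_type": label, "xi_reads": xi, "xa_reads": xa})
        log_filter(f"allelic_{label}_informative", len(regions), len(rows))
        return pd.DataFrame(rows)

    per_peak = _summarise(peaks.intervals, "peak")
    result: dict = {"per_region": per_peak}
    if len(per_peak) < 2:
        result.update({"p_value": np.nan, "flag": "too_few_regions"})
        return result
    diffs = (per_peak["xi_reads"] - per_peak["xa_reads"]).to_numpy(float)
    if np.var(diffs) == 0:
        result["p_value"] = 1.0 if diffs.mean() == 0 else 0.0
    else:
        t = stats.ttest_rel(per_peak["xi_reads"], per_peak["xa_reads"])
        result["p_value"] = float(t.pvalue)
    result["mean_fold_xi_xa"] = float(
        per_peak["xi_reads"].sum() / max(1, per_peak["xa_reads"].sum()))
    result["flag"] = ""

    if non_peak_control and chrom_lengths is not None:
        rng = np.random.default_rng(seed)
        complement: list[GenomicInterval] = []
        for iv in peaks.intervals:
            size = len(iv)
            length = chrom_lengths[iv.chrom]
            for _ in range(50):
                s = int(rng.integers(0, max(1, length - size)))
                cand = GenomicInterval(iv.chrom, s, s + size)
                if not any(cand.overlaps(p) for p in peaks.intervals):
                    complement.append(cand)
                    break
        ctrl = _summarise(complement, "non_peak")
        result["per_region"] = pd.concat([per_peak, ctrl], ignore_index=True)
        if len(ctrl) >= 2:
            t0 = stats.ttest_rel(ctrl["xi_reads"], ctrl["xa_reads"])
            result["non_peak_p_value"] = float(t0.pvalue)
            result["non_peak_mean_fold_xi_xa"] = float(
                ctrl["xi_reads"].sum() / max(1, ctrl["xa_reads"].sum()))
    return result


# ---------------------------------------------------------------------------
# normalisation


def match_normalize(tracks: dict[str, BinnedTrack]) -> dict[str, BinnedTrack]:
    """Distribution-matching normalisation across samples on one bin grid.

    Every sample's values are replaced by the average empirical distribution
    at equal ranks (quantile normalisation with average order statistics);
    ties within a sample share the mean of their rank range.  Rank order
    within each sample is preserved and the mapping is idempotent.
    """
    names = sorted(tracks)
    lengths = {len(tracks[n]) for n in names}
    grids = {(tracks[n].width, tracks[n].step) for n in names}
    if len(lengths) != 1 or len(grids) != 1:
        raise ValueError("tracks are not on a common bin grid")
    n_bins = lengths.pop()
    ref = np.mean([np.sort(tracks[n].values) for n in names], axis=0)
    out = {}
    for name in names:
        tr = tracks[name]
        ranks = stats.rankdata(tr.values, method="average")
        new = np.interp(ranks, np.arange(1, n_bins + 1), ref)
        out[name] = BinnedTrack(tr.chrom, tr.width, new, tr.step, "match")
    return out


def normalize_tracks(tracks: dict[str, BinnedTrack], h3_name: str = "H3",
                     method: str = "match") -> dict[str, BinnedTrack]:
    """Match-normalise a set of tracks and subtract the H3 control windowwise."""
    if h3_name not in tracks:
        raise ValueError(f"H3 track {h3_name!r} missing")
    if method != "match":
        raise ValueError(f"unknown normalisation method {method!r}")
    matched = match_normalize(tracks)
    h3 = matched[h3_name].values
    out = {}
    for name, tr in matched.items():
        if name == h3_name:
            continue
        out[name] = BinnedTrack(tr.chrom, tr.width, tr.values - h3,
                                tr.step, "h3_subtracted")
    return out


def trend_profile(
    mark_reads: pd.DataFrame,
    features: list[GenomicInterval],
    h3_reads: pd.DataFrame,
    window: int = 10_000,
    step: int = 5_000,
    n_positions: int = 50,
) -> pd.DataFrame:
    """Length-normalised meta-profile of a mark over features, H3-subtracted.

    Each feature is scanned with sliding windows; window centres map to the
    relative position (0..1) along the feature; windowed mark and H3 counts
    (each scaled to reads per million of its library) are averaged in
    ``n_positions`` relative bins and the H3 profile subtracted.
    """
    if not features:
        raise ValueError("feature list is empty")
    mark_lib = max(1, len(mark_reads))
    h3_lib = max(1, len(h3_reads))
    sums = np.zeros((2, n_positions))
    counts = np.zeros(n_positions)
    n_used = 0
    for iv in features:
        span = len(iv)
        if span < window:
            continue
        n_used += 1
        starts = np.arange(iv.start, iv.end - window + 1, step)
        centers = (starts + window / 2.0 - iv.start) / span
        rel_bin = np.minimum((centers * n_positions).astype(int), n_positions - 1)
        for k, reads, lib in ((0, mark_reads, mark_lib), (1, h3_reads, h3_lib)):
            pos = reads.loc[reads["chrom"] == iv.chrom, "pos"].to_numpy()
            pos = pos[(pos >= iv.start) & (pos < iv.end)]
            cum = np.searchsorted(np.sort(pos), np.stack([starts, starts + window]))
            win_counts = (cum[1] - cum[0]) / lib * 1e6
            np.add.at(sums[k], rel_bin, win_counts)
        np.add.at(counts, rel_bin, 1)
    log_filter("trend_features_long_enough", len(features), n_used)
    if n_used == 0:
        raise ValueError("no feature is at least one window long")
    with np.errstate(invalid="ignore"):
        mark_prof = sums[0] / counts
        h3_prof = sums[1] / counts
    return pd.DataFrame({"rel_position": (np.arange(n_positions) + 0.5) / n_positions,
                         "mark": mark_prof, "h3": h3_prof,
                         "h3_subtracted": mark_prof - h3_prof})


def tmm_library_sizes(counts: pd.DataFrame, logratio_trim: float = 0.3,
                      sum_trim: float = 0.05) -> pd.Series:
    """TMM normalisation factors from a bins x libraries count matrix.

    Trimmed mean of M-values: each library is compared with the reference
    library (upper quartile of rates closest to the mean upper quartile);
    log-ratios are trimmed 30 % two-sided, intensities 5 %, the remaining
    M-values averaged with inverse-variance (delta-method binomial) weights,
    and the factors are centred to a geometric mean of 1.  Effective library
    size = raw size x factor.
    """
    mat = counts.to_numpy(dtype=float)
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 libraries")
    lib = mat.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("library of all zeros")
    f75 = np.array([np.quantile(mat[:, i] / lib[i], 0.75)
                    for i in range(mat.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(mat.shape[1])
    for i in range(mat.shape[1]):
        if i == ref:
            continue
        obs, nobs = mat[:, i], lib[i]
        refc, nref = mat[:, ref], lib[ref]
        ok = (obs > 0) & (refc > 0)
        obs, refc = obs[ok], refc[ok]
        m = np.log2((obs / nobs) / (refc / nref))
        a = 0.5 * np.log2((obs / nobs) * (refc / nref))
        w = (nobs - obs) / (nobs * obs) + (nref - refc) / (nref * refc)
        finite = np.isfinite(m) & np.isfinite(a)
        m, a, w = m[finite], a[finite], w[finite]
        n = len(m)
        if n == 0:
            continue
        lo_m = np.floor(n * logratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * sum_trim) + 1
        hi_a = n + 1 - lo_a
        rm = stats.rankdata(m)
        ra = stats.rankdata(a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if keep.any():
            tmm = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
            factors[i] = 2.0 ** tmm
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")
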