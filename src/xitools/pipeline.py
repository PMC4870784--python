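"""Experiment-level pipeline driver.

``run_pipeline`` takes a configuration mapping (usually loaded from YAML),
dispatches on the experiment type and writes per-stage TSV/BED outputs plus
a run log recording package versions, the seed and every threshold in
effect.  Runs are deterministic given the configuration (including the
simulation seed): re-running a config produces byte-identical tables.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

import xitools
from xitools import allelic, chip, methylation, profiles, screen, simulate
from xitools.io import (read_allelic_counts, read_bed, read_cpg_table,
                        read_tsv, write_bed, write_tsv)

logger = logging.getLogger("xitools")

EXPERIMENT_TYPES = ("es_timecourse", "mef_chip", "errbs", "screen", "if")


class ConfigurationError(ValueError):
    pass


def _require(config: dict, fields: list[str]) -> None:
    missing = [f for f in fields if f not in config]
    if missing:
        raise ConfigurationError(f"missing required configuration fields: {missing}")


def _sim_config(config: dict) -> simulate.SimConfig:
    block = dict(config.get("simulation", {}))
    unknown = [k for k in block if not hasattr(simulate.SimConfig, k)]
    if unknown:
        raise ConfigurationError(f"unknown simulation parameters: {unknown}")
    return simulate.SimConfig(**block)


def _write_log(out: Path, config: dict, thresholds: dict) -> None:
    lines = [
        f"xitools {xitools.__version__}",
        f"numpy {np.__version__}; scipy {scipy.__version__}; "
        f"pandas {pd.__version__}",
        f"experiment: {config['experiment']}",
        f"seed: {config.get('simulation', {}).get('seed', 'NA')}",
        "thresholds:",
    ]
    lines += [f"  {k}: {v}" for k, v in sorted(thresholds.items())]
    (out / "run_log.txt").write_text("\n".join(lines) + "\n")


def run_pipeline(config: dict, out_dir: str | Path) -> Path:
    """Run one experiment end-to-end and write its result directory."""
    _require(config, ["experiment"])
    experiment = config["experiment"]
    if experiment not in EXPERIMENT_TYPES:
        raise ConfigurationError(
            f"unknown experiment type {experiment!r}; expected one of "
            f"{EXPERIMENT_TYPES}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _HANDLERS[experiment]
    thresholds = handler(config, out)
    _write_log(out, config, thresholds)
    return out


def _run_es_timecourse(config: dict, out: Path) -> dict:
    min_total = int(config.get("min_total", 10))
    timepoint = config.get("timepoint", "day5")
    if "simulation" in config:
        cfg = _sim_config(config)
        rng = np.random.default_rng(cfg.seed)
        ann = simulate.simulate_annotation(cfg, rng)
        counts, truth = simulate.simulate_allelic_rnaseq(ann, cfg, rng)
        write_tsv(pd.DataFrame({"gene_id": sorted(truth.reactivating_genes)}),
                  out / "ground_truth_genes.tsv")
    else:
        _require(config, ["allelic_counts"])
        counts = read_allelic_counts(config["allelic_counts"])
    filtered = allelic.filter_snps(counts, min_total=min_total)
    ratios = allelic.xi_xa_ratio(filtered)
    write_tsv(ratios, out / "xi_xa_ratios.tsv")
    calls, consensus = allelic.classify_reactivating(ratios, timepoint=timepoint)
    write_tsv(calls, out / "reactivation_calls.tsv")
    write_tsv(consensus, out / "consensus_reactivating_snps.tsv")
    genes = allelic.reactivating_genes(calls)
    summary = pd.DataFrame(
        [{"replicate": rep, "n_genes": len(s)}
         for rep, s in sorted(genes.per_replicate.items())]
        + [{"replicate": "intersection", "n_genes": len(genes.intersection)}])
    summary["fraction_of_snp_genes"] = genes.fraction_of_snp_genes
    write_tsv(summary, out / "reactivating_genes_summary.tsv")
    write_tsv(pd.DataFrame({"gene_id": sorted(genes.intersection)}),
              out / "reactivating_genes.tsv")
    return {"min_total": min_total, "timepoint": timepoint}


def _run_mef_chip(config: dict, out: Path) -> dict:
    window = int(config.get("window", 10_000))
    p_threshold = float(config.get("p_threshold", 1e-5))
    bin_width = int(config.get("bin_width", 50_000))
    cfg = _sim_config(config) if "simulation" in config else None
    if cfg is not None:
        rng = np.random.default_rng(cfg.seed)
        ann = simulate.simulate_annotation(cfg, rng)
        tables, _ = simulate.simulate_chip(ann, cfg, rng)
        chrom_lengths = ann.chrom_lengths
        gene_ivs = [g.interval for g in ann.genes]
    else:
        _require(config, ["read_tables", "chrom_lengths", "control"])
        tables = {mark: read_tsv(path)
                  for mark, path in config["read_tables"].items()}
        chrom_lengths = {k: int(v) for k, v in config["chrom_lengths"].items()}
        gene_ivs = read_bed(config["genes"]) if "genes" in config else []
    control_name = config.get("control", "H3")
    control = tables[control_name]
    cov_tracks = {}
    for mark, reads in tables.items():
        if mark == control_name:
            continue
        peaks = chip.call_broad_peaks(reads, control, chrom_lengths,
                                      window=window, p_threshold=p_threshold,
                                      mark=mark)
        write_bed(peaks.intervals, out / f"peaks_{mark}.bed", peaks.scores)
        write_tsv(chip.peaks_per_mb(peaks, chrom_lengths),
                  out / f"peak_density_{mark}.tsv")
        cov_tracks[mark] = chip.bin_coverage(
            peaks.intervals, "chrX", chrom_lengths["chrX"], bin_width)
    if gene_ivs:
        cov_tracks["genes"] = chip.bin_coverage(
            [iv for iv in gene_ivs if iv.chrom == "chrX"],
            "chrX", chrom_lengths["chrX"], bin_width)
    rows = []
    names = sorted(cov_tracks)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            res = chip.correlate_bins(cov_tracks[a].values, cov_tracks[b].values)
            rows.append({"track_a": a, "track_b": b, **res})
    write_tsv(pd.DataFrame(rows), out / "bin_correlations.tsv")
    return {"window": window, "p_threshold": p_threshold, "bin_width": bin_width}


def _run_errbs(config: dict, out: Path) -> dict:
    min_cov = int(config.get("min_coverage", 20))
    alpha = float(config.get("alpha", 0.05))
    n_bins = int(config.get("profile_bins", 100))
    if "simulation" in config:
        cfg = _sim_config(config)
        rng = np.random.default_rng(cfg.seed)
        ann = simulate.simulate_annotation(cfg, rng)
        sites, _ = simulate.simulate_errbs(ann, cfg, rng)
        cgis = [iv for iv in ann.cgis if iv.chrom == "chrX"]
        cond_a, cond_b = simulate.CONTROL_HAIRPIN, "shSetdb1"
    else:
        _require(config, ["cpg_table", "cgi_bed", "condition_a", "condition_b"])
        sites = read_cpg_table(config["cpg_table"])
        cgis = read_bed(config["cgi_bed"])
        cond_a, cond_b = config["condition_a"], config["condition_b"]
    filtered = methylation.filter_cpgs(sites, min_coverage_exclusive=min_cov)
    xi = filtered[filtered["allele"] == "Xi"] if "allele" in filtered.columns \
        else filtered
    diff = methylation.differential_cpgs(xi, cond_a, cond_b, alpha=alpha)
    write_tsv(diff, out / "differential_cpgs.tsv")
    calls = methylation.cgi_calls(xi, cgis, cond_a, cond_b, alpha=alpha)
    write_tsv(calls, out / "cgi_calls.tsv")
    prof = methylation.cgi_meta_profile(xi, cgis, n_positions=n_bins)
    write_tsv(prof, out / "cgi_profile.tsv")
    return {"min_coverage": min_cov, "alpha": alpha, "profile_bins": n_bins}


def _run_screen(config: dict, out: Path) -> dict:
    min_initial = int(config.get("min_initial", 1000))
    alpha = float(config.get("alpha", 0.1))
    dispersion = float(config.get("dispersion", 0.0))
    if "simulation" in config:
        cfg = _sim_config(config)
        counts, _ = simulate.simulate_screen(cfg)
        counts = counts.set_index("hairpin_id")
        initial_cols = [c for c in counts.columns if c.startswith("initial")]
        group_a, group_b = ["GFP_pos"], ["GFP_neg"]
    else:
        _require(config, ["counts", "initial_columns", "group_a", "group_b"])
        counts = read_tsv(config["counts"]).set_index("hairpin_id")
        initial_cols = config["initial_columns"]
        group_a, group_b = config["group_a"], config["group_b"]
    filtered = screen.filter_hairpins(counts, initial_cols, min_initial)
    write_tsv(filtered.reset_index(), out / "filtered_counts.tsv")
    results = screen.exact_test(filtered, group_a, group_b,
                                dispersion=dispersion, alpha=alpha)
    write_tsv(results, out / "screen_results.tsv")
    return {"min_initial": min_initial, "alpha": alpha, "dispersion": dispersion}


def _run_if(config: dict, out: Path) -> dict:
    window = int(config.get("smoothing_window", 5))
    if "simulation" in config:
        cfg = _sim_config(config)
        table, _ = simulate.simulate_if_profiles(cfg)
    else:
        _require(config, ["profiles"])
        table = read_tsv(config["profiles"])
    calls = profiles.call_profile_table(table, window=window)
    write_tsv(calls, out / "peak_calls.tsv")
    channels = sorted(calls["channel"].unique()) if len(calls) else []
    if len(channels) == 2:
        overlap = profiles.count_overlaps(
            calls[calls["channel"] == channels[0]],
            calls[calls["channel"] == channels[1]])
        write_tsv(overlap["per_cell"], out / "overlap_per_cell.tsv")
        write_tsv(pd.DataFrame([{"pooled_fraction": overlap["pooled_fraction"],
                                 "n_peaks_a": overlap["n_peaks_a"],
                                 "n_overlapping": overlap["n_overlapping"]}]),
                  out / "overlap_summary.tsv")
    return {"smoothing_window": window}


_HANDLERS = {
    "es_timecourse": _run_es_timecourse,
    "mef_chip": _run_mef_chip,
    "errbs": _run_errbs,
    "screen": _run_screen,
    "if": _run_if,
}
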