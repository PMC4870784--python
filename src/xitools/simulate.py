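"""Synthetic-data generator with planted ground truth.

Every analysis stage in the package has a corresponding simulator here that
emulates the statistical structure the stage assumes, so each stage can be
exercised end-to-end with parameter-recovery tests and no external data:

* a genome annotation with alternating gene-dense and gene-poor blocks
  (genes and promoter CGIs in dense blocks; pseudogenes and repeats in poor
  blocks; strain-SNP density lower outside genes);
* allele-specific RNA-seq counts across a differentiation time course with
  a decaying Xi fraction of expression and a planted subset of genes whose
  Xi expression is lifted under knockdown at the last time point;
* ChIP-seq read-start tables in which one mark is enriched over gene-dense
  blocks and another over gene-poor blocks, with an H3 control carrying no
  planted enrichment and an Xi-skewed allele tag inside female peaks;
* bisulphite CpG count tables with CGI-concentrated CpGs, Xi
  hypermethylation and a planted subset of CGIs losing methylation
  uniformly under knockdown;
* pooled shRNA hairpin count matrices with planted enriched hairpins;
* two-channel 1-D fluorescence cross-sections with planted Gaussian peaks.

Sequencing depths are negative-binomial (dispersion ``nb_dispersion``,
variance ``m + d m^2``); allelic and methylation splits are binomial.  One
RNG stream per simulation, seeded once; each simulator draws from it in a
fixed documented order so runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from xitools.core import (REPEAT_CLASSES, Gene, GenomeAnnotation,
                          GenomicInterval)

KNOCKDOWN_HAIRPINS = ("shSetdb1.4", "shSetdb1.6")
CONTROL_HAIRPIN = "Nons"
TIMEPOINTS = ("day0", "day3", "day5")


@dataclass
class SimConfig:
    """Parameters of the synthetic study; defaults are the study conditions.

    Fractions are in [0, 1]; fold changes are >= 1; methylation levels are
    percentages; coverages are mean read depths (reads per SNP/CpG for count
    tables, read starts per bp for ChIP).
    """

    seed: int = 0
    # genome layout
    n_chrom_autosome: int = 2
    chrom_length_bp: int = 10_000_000
    n_genes_x: int = 200
    n_genes_autosome: int = 200
    block_size_bp: int = 500_000
    frac_gene_dense_bins: float = 0.5
    gene_fill_fraction: float = 0.5     # of gene-dense bp covered by gene bodies
    exon_fraction: float = 0.5          # of a gene body that is exonic
    n_exons_per_gene: int = 5
    snp_density_genic: float = 0.5      # SNPs per kb inside genes
    snp_density_intergenic: float = 0.1
    pseudogene_density: float = 0.02    # per gene-poor kb... interpreted per 50 kb
    repeat_density_per_kb: float = 0.2
    cgi_length_bp: int = 1000
    # allelic RNA-seq
    xi_silencing_trajectory: dict[str, float] = field(
        default_factory=lambda: {"day0": 0.5, "day3": 0.3, "day5": 0.1})
    reactivating_gene_fraction: float = 0.15
    reactivation_effect: float = 3.0    # multiplicative lift of Xi:Xa odds
    mean_coverage_rna: float = 30.0
    n_replicates_rna: int = 2
    # ChIP
    chip_enrichment_fold: dict[str, tuple[str, float]] = field(
        default_factory=lambda: {"H3K27me3": ("gene_dense", 5.0),
                                 "H3K9me3": ("gene_poor", 5.0),
                                 "H3": ("none", 1.0)})
    xi_chip_fold: float = 3.0           # Xi:Xa odds of allele tags inside peaks
    mean_coverage_chip: float = 0.05    # read starts per bp, background
    chip_informative_fraction: float = 0.05
    # eRRBS
    mean_coverage_cpg: float = 30.0
    cpg_spacing_bp: int = 25            # within CGIs
    cgi_xi_meth_level: float = 80.0
    cgi_xa_meth_level: float = 5.0
    meth_loss_cgi_fraction: float = 0.1
    meth_loss_delta: float = 20.0       # percentage points, uniform over the CGI
    n_replicates_meth_control: int = 3
    n_replicates_meth_kd: int = 2
    # screen
    screen_n_hairpins: int = 1000
    screen_hit_fraction: float = 0.01
    screen_hit_fold: float = 8.0
    screen_depth: int = 1_000_000
    screen_n_initial_replicates: int = 2
    # immunofluorescence
    if_n_cells: int = 100
    if_peaks_per_cell: int = 3
    if_profile_length: int = 400
    if_peak_sigma: float = 3.0
    if_peak_height: float = 10.0
    if_baseline_amplitude: float = 0.2
    if_noise_sd: float = 0.3
    if_colocalisation_prob: float = 0.5
    # shared
    nb_dispersion: float = 0.2

    def validate(self) -> None:
        fracs = [self.frac_gene_dense_bins, self.gene_fill_fraction,
                 self.exon_fraction, self.reactivating_gene_fraction,
                 self.meth_loss_cgi_fraction, self.screen_hit_fraction,
                 self.if_colocalisation_prob, self.chip_informative_fraction]
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("all fractions must lie in [0, 1]")
        if any(not 0 <= v <= 1 for v in self.xi_silencing_trajectory.values()):
            raise ValueError("trajectory Xi fractions must lie in [0, 1]")
        folds = [self.reactivation_effect, self.xi_chip_fold,
                 self.screen_hit_fold] + [f for _, f in
                                          self.chip_enrichment_fold.values()]
        if any(f < 1 for f in folds):
            raise ValueError("fold changes must be >= 1")
        if min(self.mean_coverage_rna, self.mean_coverage_chip,
               self.mean_coverage_cpg) <= 0:
            raise ValueError("coverages must be > 0")


@dataclass
class GroundTruth:
    """Planted truth of one simulation, for recovery tests."""

    reactivating_genes: set[str] = field(default_factory=set)
    enriched_regions: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    demethylated_cgis: list[GenomicInterval] = field(default_factory=list)
    screen_hits: set[str] = field(default_factory=set)
    if_peak_positions: dict[str, dict[str, list[int]]] = field(default_factory=dict)


def _nb_depths(rng: np.random.Generator, mean: float, dispersion: float,
               size) -> np.ndarray:
    """Negative-binomial depths with Var = m + d m^2 (Poisson when d == 0)."""
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean), size=size)


# ---------------------------------------------------------------------------
# annotation


def _block_classes(length: int, cfg: SimConfig) -> list[tuple[int, int, bool]]:
    """Partition a chromosome into (start, end, is_gene_dense) blocks.

    Dense blocks are interleaved among the first blocks deterministically so
    the configured dense fraction is met to within one block.
    """
    n_blocks = max(1, length // cfg.block_size_bp)
    n_dense = round(n_blocks * cfg.frac_gene_dense_bins)
    # spread dense blocks evenly: block i is dense iff its index hits the stride
    dense_idx = set(np.linspace(0, n_blocks - 1, n_dense).round().astype(int)) \
        if n_dense else set()
    blocks = []
    for i in range(n_blocks):
        start = i * cfg.block_size_bp
        end = length if i == n_blocks - 1 else (i + 1) * cfg.block_size_bp
        blocks.append((start, end, i in dense_idx))
    return blocks


def simulate_annotation(cfg: SimConfig,
                        rng: np.random.Generator | None = None) -> GenomeAnnotation:
    """Simulate a genome annotation with banded gene-density structure.

    Gene-dense blocks hold genes (with exons and a promoter CGI); gene-poor
    blocks hold pseudogenes and repeats.  SNPs fall as a Poisson process at
    ``snp_density_genic`` per kb inside gene bodies and
    ``snp_density_intergenic`` per kb elsewhere.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    chroms = {"chrX": cfg.chrom_length_bp}
    for i in range(cfg.n_chrom_autosome):
        chroms[f"chr{i + 1}"] = cfg.chrom_length_bp

    genes: list[Gene] = []
    pseudogenes: list[GenomicInterval] = []
    cgis: list[GenomicInterval] = []
    repeats: list[GenomicInterval] = []
    snp_rows: list[tuple[str, int]] = []

    for chrom, length in chroms.items():
        n_genes = cfg.n_genes_x if chrom == "chrX" else cfg.n_genes_autosome
        blocks = _block_classes(length, cfg)
        dense = [(s, e) for s, e, d in blocks if d]
        poor = [(s, e) for s, e, d in blocks if not d]
        dense_bp = sum(e - s for s, e in dense)
        if not dense or dense_bp * cfg.gene_fill_fraction < n_genes * 200:
            raise ValueError(
                f"{chrom} too short for {n_genes} genes at the configured "
                "gene-dense fraction")

        # lay genes out evenly inside dense blocks at the configured fill
        gene_len = int(dense_bp * cfg.gene_fill_fraction / n_genes)
        per_block = [round(n_genes * (e - s) / dense_bp) for s, e in dense]
        while sum(per_block) > n_genes:
            per_block[int(np.argmax(per_block))] -= 1
        while sum(per_block) < n_genes:
            per_block[int(np.argmin(per_block))] += 1
        gi = 0
        for (bs, be), k in zip(dense, per_block):
            if k <= 0:
                continue
            pitch = (be - bs) // k
            for j in range(k):
                g_start = bs + j * pitch + (pitch - gene_len) // 2
                g_end = g_start + gene_len
                gene_id = f"{chrom}_G{gi:04d}"
                gi += 1
                # exons: n equal exons alternating with introns
                n_ex = cfg.n_exons_per_gene
                ex_len = int(gene_len * cfg.exon_fraction / n_ex)
                gap = (gene_len - n_ex * ex_len) // max(1, n_ex - 1) if n_ex > 1 else 0
                exons = []
                for x in range(n_ex):
                    s = g_start + x * (ex_len + gap)
                    exons.append((s, min(s + ex_len, g_end)))
                genes.append(Gene(gene_id, chrom, g_start, g_end, exons))
                # promoter CGI upstream of the gene start
                cgi_s = max(0, g_start - cfg.cgi_length_bp)
                if cgi_s < g_start:
                    cgis.append(GenomicInterval(chrom, cgi_s, g_start,
                                                label=f"CGI_{gene_id}"))

        for bs, be in poor:
            n_pg = rng.poisson(cfg.pseudogene_density * (be - bs) / 50_000)
            for j in range(n_pg):
                s = int(rng.integers(bs, max(bs + 1, be - 2000)))
                pseudogenes.append(GenomicInterval(chrom, s, min(s + 2000, be),
                                                   label=f"PG_{chrom}_{bs}_{j}"))
            n_rep = rng.poisson(cfg.repeat_density_per_kb * (be - bs) / 1000)
            if n_rep:
                starts = np.sort(rng.integers(bs, max(bs + 1, be - 500), n_rep))
                classes = rng.choice(REPEAT_CLASSES, size=n_rep)
                for s, c in zip(starts, classes):
                    repeats.append(GenomicInterval(chrom, int(s),
                                                   min(int(s) + 500, be), label=str(c)))

        # SNPs: piecewise-constant Poisson process over gene bodies vs rest
        gene_ivs = sorted((g.start, g.end) for g in genes if g.chrom == chrom)
        cursor = 0
        segments = []
        for s, e in gene_ivs:
            if s > cursor:
                segments.append((cursor, s, cfg.snp_density_intergenic))
            segments.append((s, e, cfg.snp_density_genic))
            cursor = e
        if cursor < length:
            segments.append((cursor, length, cfg.snp_density_intergenic))
        for s, e, dens in segments:
            n = rng.poisson(dens * (e - s) / 1000)
            if n:
                pos = np.unique(rng.integers(s + 1, e + 1, n))  # 1-based
                snp_rows.extend((chrom, int(p)) for p in pos)

    snps = pd.DataFrame(snp_rows, columns=["chrom", "pos"])
    snps["ref"] = "C"
    snps["alt"] = "T"
    snps["strain"] = "CAST"
    ann = GenomeAnnotation(chrom_lengths=chroms, genes=genes,
                           pseudogenes=pseudogenes, cgis=cgis,
                           repeats=repeats, snps=snps)
    ann.validate()
    return ann


# ---------------------------------------------------------------------------
# allele-specific RNA-seq


def _lift_xi_fraction(p: float, effect: float) -> float:
    """Multiply the Xi:Xa odds by ``effect`` and return the new Xi fraction."""
    odds = effect * p / (1.0 - p) if p < 1 else np.inf
    return float(odds / (1.0 + odds))


def simulate_allelic_rnaseq(
    annotation: GenomeAnnotation, cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate per-SNP allelic counts over the differentiation time course.

    For each exonic X-linked SNP and each (hairpin, timepoint, replicate)
    sample, total depth is negative-binomial around ``mean_coverage_rna`` and
    the Xi count is binomial with p equal to the time point's Xi fraction —
    lifted by ``reactivation_effect`` (on the Xi:Xa odds) for planted
    reactivating genes in knockdown samples at day 5 only.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    snps = annotation.exonic_snps()
    snps = snps[(snps["chrom"] == "chrX") & snps["exonic"]].reset_index(drop=True)
    if snps.empty:
        raise ValueError("annotation has no exonic SNPs on chrX")

    x_genes = sorted({g.gene_id for g in annotation.genes if g.chrom == "chrX"})
    n_react = round(len(x_genes) * cfg.reactivating_gene_fraction)
    react = set(rng.choice(x_genes, size=n_react, replace=False)) if n_react else set()

    hairpins = (CONTROL_HAIRPIN,) + KNOCKDOWN_HAIRPINS
    rows = []
    n = len(snps)
    snp_react = snps["gene_id"].isin(react).to_numpy()
    for rep in range(1, cfg.n_replicates_rna + 1):
        for tp in TIMEPOINTS:
            base_p = cfg.xi_silencing_trajectory[tp]
            for hp in hairpins:
                lifted = (hp != CONTROL_HAIRPIN) and tp == "day5"
                p = np.full(n, base_p)
                if lifted and react:
                    p[snp_react] = _lift_xi_fraction(base_p, cfg.reactivation_effect)
                depth = _nb_depths(rng, cfg.mean_coverage_rna, cfg.nb_dispersion, n)
                xi = rng.binomial(depth, p)
                sample_id = f"{hp}_{tp}_rep{rep}"
                rows.append(pd.DataFrame({
                    "chrom": snps["chrom"], "pos": snps["pos"],
                    "gene_id": snps["gene_id"], "exonic": True,
                    "sample_id": sample_id, "hairpin": hp, "timepoint": tp,
                    "replicate": rep, "xi_count": xi, "xa_count": depth - xi,
                }))
    counts = pd.concat(rows, ignore_index=True)
    return counts, GroundTruth(reactivating_genes=react)


# ---------------------------------------------------------------------------
# ChIP-seq


def simulate_chip(
    annotation: GenomeAnnotation, cfg: SimConfig,
    rng: np.random.Generator | None = None,
    sex: str = "female",
) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Simulate per-mark read-start tables with banded enrichment.

    Reads arrive as a Poisson process at ``mean_coverage_chip`` starts per bp,
    multiplied by the mark's fold inside its region class (gene-dense or
    gene-poor blocks).  H3 carries no planted enrichment.  A fraction of
    reads is informative at strain SNPs and carries an Xi/Xa allele tag with
    Xi:Xa odds ``xi_chip_fold`` inside the mark's enriched regions in
    females, and balanced odds elsewhere and in males.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    tables: dict[str, pd.DataFrame] = {}
    truth = GroundTruth()
    for mark in sorted(cfg.chip_enrichment_fold):
        region_class, fold = cfg.chip_enrichment_fold[mark]
        chrom_frames = []
        enriched: list[GenomicInterval] = []
        for chrom, length in annotation.chrom_lengths.items():
            blocks = _block_classes(length, cfg)
            rates = []
            for s, e, dense in blocks:
                in_class = (region_class == "gene_dense" and dense) or \
                           (region_class == "gene_poor" and not dense)
                rate = cfg.mean_coverage_chip * (fold if in_class else 1.0)
                rates.append((s, e, rate))
                if in_class and fold > 1:
                    enriched.append(GenomicInterval(chrom, s, e, label=mark))
            pos_parts = []
            for s, e, rate in rates:
                k = rng.poisson(rate * (e - s))
                if k:
                    pos_parts.append(rng.integers(s, e, k))
            pos = np.sort(np.concatenate(pos_parts)) if pos_parts else \
                np.empty(0, dtype=int)
            frame = pd.DataFrame({"chrom": chrom, "pos": pos})
            # allele tags
            n = len(frame)
            informative = rng.random(n) < cfg.chip_informative_fraction
            allele = np.full(n, "", dtype=object)
            if informative.any():
                in_enriched = np.zeros(n, dtype=bool)
                for iv in enriched:
                    if iv.chrom == chrom:
                        in_enriched |= (pos >= iv.start) & (pos < iv.end)
                odds = np.where(in_enriched, cfg.xi_chip_fold, 1.0)
                p_xi = odds / (1.0 + odds)
                if sex != "female":
                    p_xi = np.full(n, 0.5)
                is_xi = rng.random(n) < p_xi
                allele[informative & is_xi] = "Xi"
                allele[informative & ~is_xi] = "Xa"
            frame["allele"] = allele
            chrom_frames.append(frame)
        tables[mark] = pd.concat(chrom_frames, ignore_index=True)
        if enriched:
            truth.enriched_regions[mark] = enriched
    return tables, truth


# ---------------------------------------------------------------------------
# eRRBS


def simulate_errbs(
    annotation: GenomeAnnotation, cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate CGI-concentrated CpG methylation count tables.

    CpGs sit every ``cpg_spacing_bp`` inside each CGI.  Per CpG, allele,
    condition and replicate: coverage is negative-binomial around
    ``mean_coverage_cpg`` and the methylated count binomial at the allele
    mean (Xi hypermethylated, Xa hypomethylated).  A planted fraction of
    X-linked CGIs loses ``meth_loss_delta`` points on the Xi in the
    knockdown condition, uniformly across the CGI.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    cgis = [iv for iv in annotation.cgis]
    if not cgis:
        raise ValueError("annotation has no CGIs")
    x_cgis = [iv for iv in cgis if iv.chrom == "chrX"]
    n_loss = round(len(x_cgis) * cfg.meth_loss_cgi_fraction)
    loss_idx = set(rng.choice(len(x_cgis), size=n_loss, replace=False)) if n_loss \
        else set()
    loss_set = {(x_cgis[i].chrom, x_cgis[i].start) for i in loss_idx}

    conditions = [(CONTROL_HAIRPIN, cfg.n_replicates_meth_control),
                  ("shSetdb1", cfg.n_replicates_meth_kd)]
    rows = []
    for iv in cgis:
        positions = np.arange(iv.start + 1, iv.end + 1, cfg.cpg_spacing_bp)
        is_loss = (iv.chrom, iv.start) in loss_set
        for allele, level in (("Xi", cfg.cgi_xi_meth_level),
                              ("Xa", cfg.cgi_xa_meth_level)):
            for cond, n_reps in conditions:
                p = level / 100.0
                if is_loss and allele == "Xi" and cond != CONTROL_HAIRPIN:
                    p = max(0.0, p - cfg.meth_loss_delta / 100.0)
                for rep in range(1, n_reps + 1):
                    cov = _nb_depths(rng, cfg.mean_coverage_cpg,
                                     cfg.nb_dispersion, len(positions))
                    meth = rng.binomial(cov, p)
                    rows.append(pd.DataFrame({
                        "chrom": iv.chrom, "pos": positions, "allele": allele,
                        "condition": cond, "replicate": rep,
                        "meth": meth, "unmeth": cov - meth,
                    }))
    table = pd.concat(rows, ignore_index=True)
    truth = GroundTruth(demethylated_cgis=[x_cgis[i] for i in sorted(loss_idx)])
    return table, truth


# ---------------------------------------------------------------------------
# shRNA screen


def simulate_screen(
    cfg: SimConfig, rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a pooled-screen hairpin count matrix.

    Baseline hairpin abundances are log-normal; planted hit hairpins are
    multiplied by ``screen_hit_fold`` in the GFP+ sorted population only;
    per-sample counts are multinomial at ``screen_depth`` reads.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.screen_n_hairpins
    ids = [f"HP{i:04d}" for i in range(n)]
    base = rng.lognormal(mean=0.0, sigma=0.8, size=n)
    n_hits = round(n * cfg.screen_hit_fraction)
    hit_idx = rng.choice(n, size=n_hits, replace=False) if n_hits else \
        np.empty(0, dtype=int)
    gfp_pos = base.copy()
    gfp_pos[hit_idx] *= cfg.screen_hit_fold

    data = {"hairpin_id": ids}
    for rep in range(1, cfg.screen_n_initial_replicates + 1):
        data[f"initial_rep{rep}"] = rng.multinomial(cfg.screen_depth,
                                                    base / base.sum())
    data["GFP_pos"] = rng.multinomial(cfg.screen_depth, gfp_pos / gfp_pos.sum())
    data["GFP_neg"] = rng.multinomial(cfg.screen_depth, base / base.sum())
    counts = pd.DataFrame(data)
    truth = GroundTruth(screen_hits={ids[i] for i in hit_idx})
    return counts, truth


# ---------------------------------------------------------------------------
# immunofluorescence profiles


def simulate_if_profiles(
    cfg: SimConfig, rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate two-channel per-cell intensity cross-sections.

    Each profile is a smooth low-frequency baseline plus Gaussian bumps at
    planted positions plus white noise.  Channel B peaks co-locate with
    channel A peaks with probability ``if_colocalisation_prob``; otherwise
    they land at independent positions.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    L = cfg.if_profile_length
    x = np.arange(L)
    margin = int(4 * cfg.if_peak_sigma) + 3
    rows = []
    truth = GroundTruth()
    for c in range(cfg.if_n_cells):
        cell = f"cell{c:03d}"
        min_sep = int(10 * cfg.if_peak_sigma)
        pos_a = np.sort(rng.choice(np.arange(margin, L - margin),
                                   size=cfg.if_peaks_per_cell, replace=False))
        # enforce separation so bumps stay distinct (bounded rejection)
        for _ in range(200):
            if len(pos_a) < 2 or np.diff(pos_a).min() >= min_sep:
                break
            pos_a = np.sort(rng.choice(np.arange(margin, L - margin),
                                       size=cfg.if_peaks_per_cell, replace=False))
        pos_b: list[int] = []
        for p in pos_a:
            if rng.random() < cfg.if_colocalisation_prob:
                pos_b.append(int(p))
            else:
                q = int(rng.integers(margin, L - margin))
                for _ in range(200):
                    if all(abs(q - r) >= min_sep for r in list(pos_a) + pos_b):
                        break
                    q = int(rng.integers(margin, L - margin))
                pos_b.append(q)
        truth.if_peak_positions[cell] = {"A": [int(p) for p in pos_a],
                                         "B": sorted(pos_b)}
        for channel, positions in (("A", pos_a), ("B", np.array(pos_b))):
            baseline = 2.0 + cfg.if_baseline_amplitude * np.sin(
                2 * np.pi * x / L + rng.uniform(0, 2 * np.pi))
            signal = baseline.copy()
            for p in positions:
                signal += cfg.if_peak_height * np.exp(
                    -0.5 * ((x - p) / cfg.if_peak_sigma) ** 2)
            signal += rng.normal(0, cfg.if_noise_sd, L)
            rows.append(pd.DataFrame({"cell_id": cell, "channel": channel,
                                      "index": x, "intensity": signal}))
    return pd.concat(rows, ignore_index=True), truth
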