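"""Seeded synthetic study generator with ground truth for every planted feature.

The generator emulates the design of a CTCF/BORIS ChIP-seq + RNA-seq study in
WT versus compound-mutant (CM) germ cells:

* a toy genome with planted CTCF motif instances: single sites (1x), clustered
  sites with two motifs separated by a fixed spacer (2x, 31 bp by default),
  BORIS-only sites, and motif-free decoy peaks;
* WT and CM CTCF coverage tracks in which each planted CTCF site is a
  triangular tag-density bump whose CM amplitude is reduced by a per-site
  fraction drawn around the class mean (25% at 1x/CTCF-only sites, 50% at
  2x/CTCF-BORIS sites), on top of shared Poisson background noise;
* a CM peak set that drops sites whose reduced amplitude falls below a
  retention threshold ("complete loss" of strongly reduced sites);
* negative-binomial expression counts for two conditions in which a stated
  fraction of true DEGs carries a lost CTCF site in its promoter.

Per-site reductions are drawn from a two-component Beta mixture (severe
Beta(8,2), mild Beta(2,8)) whose mixing weight matches the class mean; this
reproduces the empirical picture of a subpopulation of sites losing occupancy
completely while the class average stays at the planted value, and it is what
makes the retention threshold meaningful.

All randomness flows from one seed through per-component child streams, so a
seed reproduces the study byte-for-byte.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ctsdimer.coverage_profiles import CoverageTrack, TARGET_LIBRARY
from ctsdimer.genomic_io import (
    CountMatrix,
    GeneModel,
    GeneSet,
    Peak,
    ValidationError,
    write_coverage,
    write_fasta,
    write_gene_table,
    write_gmt,
    write_peaks,
)
from ctsdimer.genomic_io import write_counts
from ctsdimer.motif_cts import PWM

# fixed CTCF-like 20-mer used as the deterministic toy consensus
_CONSENSUS_CYCLE = "CCACCAGGTGGCAGCACCTA"

DOMINANT_FREQ = 0.85
OTHER_FREQ = 0.05


def make_toy_pwm(width: int = 20) -> PWM:
    """Deterministic toy PWM: one dominant base (0.85) per column.

    The consensus is a fixed CTCF-like 20-mer, tiled/truncated to ``width``.
    """
    if width < 4:
        raise ValidationError(f"PWM width must be >= 4, got {width}")
    cycle = (_CONSENSUS_CYCLE * (width // len(_CONSENSUS_CYCLE) + 1))[:width]
    freq = np.full((width, 4), OTHER_FREQ)
    for i, base in enumerate(cycle):
        freq[i, "ACGT".index(base)] = DOMINANT_FREQ
    return PWM(freq=freq)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the emulated study design."""

    seed: int
    n_chroms: int = 4
    chrom_length: int = 5_000_000
    # planted site counts
    n_sites_1x: int = 1000
    n_sites_2x: int = 1000
    n_boris_only: int = 200
    n_decoy: int = 300
    spacing_2x: int = 31  # bp between the two motifs of a clustered site
    # mean fractional occupancy loss in CM, per site class
    reduction_1x: float = 0.25
    reduction_2x: float = 0.50
    # expression
    n_genes: int = 1500
    n_samples_per_condition: int = 3
    n_true_degs: int = 500
    deg_log2fc: float = 2.0
    nb_dispersion: float = 0.001
    frac_deg_bound: float = 0.37  # fraction of true DEGs with a lost promoter site
    frac_bound_background: float = 0.10  # non-DEG genes with a retained promoter site
    # signal model
    amp_median: float = 50.0
    amp_sdlog: float = 0.3
    bump_half_width: int = 150
    peak_half_width: int = 100
    noise_frac: float = 0.05  # background mean as fraction of median amplitude
    noise_bin: int = 20
    retention_frac: float = 0.30  # CM peak kept iff amplitude >= frac * WT median
    mapped_reads_wt: int = 20_000_000
    mapped_reads_cm: int = 15_000_000
    # expression level model
    expr_meanlog: float = math.log(2000.0)
    expr_sdlog: float = 0.5
    pathway_size: int = 52
    pwm_width: int = 20
    # layout constants
    gene_length: int = 3000
    gene_slot: int = 10_000

    def __post_init__(self) -> None:
        for name in ("reduction_1x", "reduction_2x", "frac_deg_bound", "frac_bound_background"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "n_chroms", "chrom_length", "n_sites_1x", "n_sites_2x", "n_boris_only",
            "n_decoy", "n_genes", "n_samples_per_condition", "n_true_degs",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.n_true_degs > self.n_genes:
            raise ValidationError("n_true_degs exceeds n_genes")


@dataclass
class TruthTable:
    """Ground truth: one row per planted site and one per gene."""

    sites: pd.DataFrame
    genes: pd.DataFrame


@dataclass
class SimulatedStudy:
    genome: dict[str, str]
    pwm: PWM
    peaks: dict[str, list[Peak]]
    coverage: dict[str, CoverageTrack]
    genes: list[GeneModel]
    counts: CountMatrix
    gene_sets: list[GeneSet]
    truth: TruthTable
    config: SimulationConfig


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _draw_reductions(mean: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Per-site loss fractions with the requested mean.

    For means in [0.2, 0.8] a mixture of a severe (Beta(8,2), mean 0.8) and a
    mild (Beta(2,8), mean 0.2) component with weight w = (mean-0.2)/0.6; for
    more extreme means a single Beta with concentration 10.  A mean of 0
    plants no reduction at all.
    """
    if n == 0:
        return np.empty(0)
    if mean == 0.0:
        return np.zeros(n)
    if mean == 1.0:
        return np.ones(n)
    if 0.2 <= mean <= 0.8:
        w = (mean - 0.2) / 0.6
        severe = rng.random(n) < w
        out = np.where(severe, rng.beta(8, 2, n), rng.beta(2, 8, n))
    else:
        out = rng.beta(10 * mean, 10 * (1 - mean), n)
    return np.clip(out, 0.0, 1.0)


def _add_bump(arr: np.ndarray, center: int, amplitude: float, half_width: int) -> None:
    lo = max(0, center - half_width)
    hi = min(arr.size, center + half_width + 1)
    d = np.abs(np.arange(lo, hi) - center)
    arr[lo:hi] += amplitude * (1.0 - d / half_width)


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate the full toy study (genome, peaks, coverage, counts, truth)."""
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng_layout, rng_genome, rng_sites, rng_cov, rng_expr = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    offset = min(50_000, cfg.chrom_length // 10)

    # ---- gene layout on a fixed grid of slots --------------------------------
    slots_per_chrom = (cfg.chrom_length - 2 * offset) // cfg.gene_slot
    if slots_per_chrom * cfg.n_chroms < cfg.n_genes:
        raise ValidationError(
            f"genome capacity {slots_per_chrom * cfg.n_chroms} gene slots < n_genes={cfg.n_genes}"
        )
    genes: list[GeneModel] = []
    gap_slots: list[tuple[str, int]] = []  # candidate intergenic site centers
    gi = 0
    for chrom in chroms:
        for j in range(slots_per_chrom):
            if gi >= cfg.n_genes:
                break
            s = offset + j * cfg.gene_slot
            strand = "+" if rng_layout.random() < 0.5 else "-"
            genes.append(
                GeneModel(f"gene_{gi + 1:05d}", chrom, s, s + cfg.gene_length, strand)
            )
            gap_slots.append((chrom, s + 5400))
            gap_slots.append((chrom, s + 7400))
            gi += 1

    # ---- true DEGs and their directions --------------------------------------
    deg_idx = rng_layout.choice(cfg.n_genes, cfg.n_true_degs, replace=False)
    true_l2fc = np.zeros(cfg.n_genes)
    signs = rng_layout.choice([-1.0, 1.0], cfg.n_true_degs)
    true_l2fc[deg_idx] = signs * cfg.deg_log2fc

    # ---- planted sites --------------------------------------------------------
    classes = (
        ["1x"] * cfg.n_sites_1x
        + ["2x"] * cfg.n_sites_2x
        + ["boris_only"] * cfg.n_boris_only
        + ["decoy"] * cfg.n_decoy
    )
    n_sites = len(classes)
    site_ids = [f"{cls}_{i + 1:05d}" for i, cls in enumerate(classes)]
    amplitude = rng_sites.lognormal(math.log(cfg.amp_median), cfg.amp_sdlog, n_sites)
    reduction = np.zeros(n_sites)
    cls_arr = np.asarray(classes)
    reduction[cls_arr == "1x"] = _draw_reductions(
        cfg.reduction_1x, cfg.n_sites_1x, rng_sites
    )
    reduction[cls_arr == "2x"] = _draw_reductions(
        cfg.reduction_2x, cfg.n_sites_2x, rng_sites
    )
    ctcf_mask = np.isin(cls_arr, ["1x", "2x", "decoy"])
    cm_amp = amplitude * (1.0 - reduction)
    retention_threshold = cfg.retention_frac * float(np.median(amplitude[ctcf_mask]))
    lost = ctcf_mask & (cm_amp < retention_threshold)

    # ---- place sites: promoter-linked lost sites, background-bound, gaps ------
    n_link = int(round(cfg.frac_deg_bound * cfg.n_true_degs))
    lost_2x_pool = [i for i in np.flatnonzero(lost & (cls_arr == "2x"))]
    if cfg.reduction_2x == 0.0:
        # null effect: nothing can be lost, so promoter links use retained sites
        lost_2x_pool = list(np.flatnonzero(cls_arr == "2x"))
    if len(lost_2x_pool) < n_link:
        raise ValidationError(
            f"only {len(lost_2x_pool)} lost 2x sites available for {n_link} promoter links; "
            "increase n_sites_2x or reduction_2x"
        )
    linked_gene_idx = rng_layout.choice(deg_idx, n_link, replace=False)
    linked_site_idx = rng_layout.permutation(np.array(lost_2x_pool, dtype=int))[:n_link]

    non_deg_idx = np.setdiff1d(np.arange(cfg.n_genes), deg_idx)
    n_bg = int(round(cfg.frac_bound_background * non_deg_idx.size))
    retained_pool = [i for i in np.flatnonzero(ctcf_mask & ~lost & (cls_arr != "2x"))]
    if len(retained_pool) < n_bg:
        raise ValidationError(
            f"only {len(retained_pool)} retained sites available for {n_bg} background-bound genes"
        )
    bg_gene_idx = rng_layout.choice(non_deg_idx, n_bg, replace=False)
    bg_site_idx = rng_layout.permutation(np.array(retained_pool, dtype=int))[:n_bg]

    center = np.full(n_sites, -1, dtype=int)
    site_chrom = np.empty(n_sites, dtype=object)
    linked_gene = np.full(n_sites, None, dtype=object)

    def promoter_center(g: GeneModel) -> int:
        return g.tss - 300 if g.strand == "+" else g.tss + 300

    for site_i, gene_i in zip(linked_site_idx, linked_gene_idx):
        g = genes[gene_i]
        center[site_i] = promoter_center(g)
        site_chrom[site_i] = g.chrom
        linked_gene[site_i] = g.gene_id
    for site_i, gene_i in zip(bg_site_idx, bg_gene_idx):
        g = genes[gene_i]
        center[site_i] = promoter_center(g)
        site_chrom[site_i] = g.chrom
        linked_gene[site_i] = g.gene_id

    unplaced = np.flatnonzero(center < 0)
    if unplaced.size > len(gap_slots):
        raise ValidationError(
            f"planted sites ({unplaced.size}) exceed genome capacity ({len(gap_slots)} slots)"
        )
    order = rng_layout.permutation(len(gap_slots))[: unplaced.size]
    for site_i, slot_i in zip(unplaced, order):
        chrom, pos = gap_slots[slot_i]
        center[site_i] = pos
        site_chrom[site_i] = chrom

    # ---- genome with planted motif instances ----------------------------------
    pwm = make_toy_pwm(cfg.pwm_width)
    consensus = pwm.consensus
    W = pwm.width
    base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)
    cons_idx = np.array(["ACGT".index(b) for b in consensus], dtype=np.uint8)
    genome_arr = {
        chrom: base_bytes[rng_genome.integers(0, 4, cfg.chrom_length)].copy()
        for chrom in chroms
    }
    span2 = 2 * W + cfg.spacing_2x
    motif1_start = np.full(n_sites, -1, dtype=int)
    motif2_start = np.full(n_sites, -1, dtype=int)
    for i in range(n_sites):
        c = center[i]
        chrom = site_chrom[i]
        if cls_arr[i] in ("1x", "boris_only"):
            m1 = c - W // 2
            genome_arr[chrom][m1:m1 + W] = base_bytes[cons_idx]
            motif1_start[i] = m1
        elif cls_arr[i] == "2x":
            m1 = c - span2 // 2
            m2 = m1 + W + cfg.spacing_2x
            if m1 < 0 or m2 + W > cfg.chrom_length:
                raise ValidationError(f"site {site_ids[i]} exceeds chromosome bounds")
            genome_arr[chrom][m1:m1 + W] = base_bytes[cons_idx]
            genome_arr[chrom][m2:m2 + W] = base_bytes[cons_idx]
            motif1_start[i] = m1
            motif2_start[i] = m2
    genome = {c: a.tobytes().decode() for c, a in genome_arr.items()}

    # ---- peak sets -------------------------------------------------------------
    def make_peak(i: int, score: float) -> Peak:
        hw = cfg.peak_half_width + (10 if cls_arr[i] == "2x" else 0)
        return Peak(
            chrom=site_chrom[i],
            start=int(center[i] - hw),
            end=int(center[i] + hw),
            name=site_ids[i],
            score=float(score),
            summit=int(center[i]),
        )

    wt_ctcf = [make_peak(i, amplitude[i]) for i in np.flatnonzero(ctcf_mask)]
    wt_boris = [
        make_peak(i, amplitude[i])
        for i in np.flatnonzero(np.isin(cls_arr, ["2x", "boris_only"]))
    ]
    cm_ctcf = [make_peak(i, cm_amp[i]) for i in np.flatnonzero(ctcf_mask & ~lost)]

    # ---- coverage --------------------------------------------------------------
    noise_mean = cfg.noise_frac * cfg.amp_median
    coverage = {}
    for label, mapped in (("wt", cfg.mapped_reads_wt), ("cm", cfg.mapped_reads_cm)):
        data: dict[str, np.ndarray] = {}
        for chrom in chroms:
            n_bins = cfg.chrom_length // cfg.noise_bin + 1
            noise = rng_cov.poisson(noise_mean, n_bins).astype(float)
            arr = np.repeat(noise, cfg.noise_bin)[: cfg.chrom_length]
            data[chrom] = arr
        for i in np.flatnonzero(ctcf_mask):
            amp = amplitude[i] if label == "wt" else cm_amp[i]
            _add_bump(data[site_chrom[i]], int(center[i]), float(amp), cfg.bump_half_width)
        factor = mapped / TARGET_LIBRARY
        data = {c: a * factor for c, a in data.items()}
        coverage[label] = CoverageTrack(data=data, mapped_reads=mapped, normalized=False)

    # ---- expression counts -----------------------------------------------------
    mu = rng_expr.lognormal(cfg.expr_meanlog, cfg.expr_sdlog, cfg.n_genes)
    nsc = cfg.n_samples_per_condition
    depth = rng_expr.uniform(0.8, 1.2, 2 * nsc)
    r_nb = 1.0 / cfg.nb_dispersion
    sample_ids = [f"WT_{j + 1}" for j in range(nsc)] + [f"CM_{j + 1}" for j in range(nsc)]
    cond_of = {s: ("A" if s.startswith("WT") else "B") for s in sample_ids}
    counts = np.empty((cfg.n_genes, 2 * nsc), dtype=np.int64)
    for j in range(2 * nsc):
        mean_j = mu * (2.0 ** true_l2fc if j >= nsc else 1.0) * depth[j]
        counts[:, j] = rng_expr.negative_binomial(r_nb, r_nb / (r_nb + mean_j))
    count_matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=[g.gene_id for g in genes], columns=sample_ids),
        condition_of=cond_of,
    )

    # ---- gene sets -------------------------------------------------------------
    gene_sets: list[GeneSet] = []
    up_idx = np.flatnonzero(true_l2fc > 0)
    if up_idx.size >= 2:
        k = min(cfg.pathway_size, up_idx.size)
        chosen = rng_expr.choice(up_idx, k, replace=False)
        gene_sets.append(
            GeneSet(
                "PATHWAY_UP_TRUE",
                "planted concordant pathway (upregulated true DEGs)",
                frozenset(genes[i].gene_id for i in chosen),
            )
        )
    if non_deg_idx.size >= 2:
        k = min(cfg.pathway_size, non_deg_idx.size)
        chosen = rng_expr.choice(non_deg_idx, k, replace=False)
        gene_sets.append(
            GeneSet(
                "PATHWAY_NULL",
                "random non-DEG control set",
                frozenset(genes[i].gene_id for i in chosen),
            )
        )

    # ---- truth tables ----------------------------------------------------------
    sites_df = pd.DataFrame(
        {
            "site_id": site_ids,
            "chrom": site_chrom,
            "center": center,
            "cls": classes,
            "amplitude": amplitude,
            "reduction": reduction,
            "cm_amplitude": cm_amp,
            "lost": lost,
            "linked_gene": [g if g is not None else "" for g in linked_gene],
            "motif1_start": motif1_start,
            "motif2_start": motif2_start,
            "spacing": np.where(cls_arr == "2x", cfg.spacing_2x, -1),
        }
    ).set_index("site_id")
    site_of_gene: dict[str, str] = {}
    for site_i in np.concatenate([linked_site_idx, bg_site_idx]).astype(int):
        site_of_gene[str(linked_gene[site_i])] = site_ids[site_i]
    genes_df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "tss": [g.tss for g in genes],
            "true_deg": true_l2fc != 0,
            "true_log2fc": true_l2fc,
            "promoter_site": [site_of_gene.get(g.gene_id, "") for g in genes],
            "linked_lost_site": [
                site_of_gene.get(g.gene_id, "")
                if site_of_gene.get(g.gene_id, "").startswith("2x")
                and bool(sites_df.loc[site_of_gene[g.gene_id], "lost"])
                else ""
                for g in genes
            ],
        }
    ).set_index("gene_id")

    return SimulatedStudy(
        genome=genome,
        pwm=pwm,
        peaks={"wt_ctcf": wt_ctcf, "wt_boris": wt_boris, "cm_ctcf": cm_ctcf},
        coverage=coverage,
        genes=genes,
        counts=count_matrix,
        gene_sets=gene_sets,
        truth=TruthTable(sites=sites_df, genes=genes_df),
        config=cfg,
    )


def write_study(study: SimulatedStudy, outdir: str | os.PathLike) -> None:
    """Write every component of a simulated study as plain-text files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(out / "genome.fa", study.genome)
    for name, peaks in study.peaks.items():
        write_peaks(out / f"{name}.narrowPeak", peaks, dialect="narrowPeak")
    for name, track in study.coverage.items():
        write_coverage(out / f"{name}.bedGraph", track)
    write_gene_table(out / "genes.tsv", study.genes)
    write_counts(out / "counts.tsv", study.counts, out / "conditions.tsv")
    write_gmt(out / "gene_sets.gmt", study.gene_sets)
    with open(out / "pwm.tsv", "w") as fh:
        for row in study.pwm.freq:
            fh.write("\t".join(str(x) for x in row) + "\n")
    study.truth.sites.to_csv(out / "truth_sites.tsv", sep="\t")
    study.truth.genes.to_csv(out / "truth_genes.tsv", sep="\t")
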