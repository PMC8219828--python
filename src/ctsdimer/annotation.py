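"""Genomic-context classification of peaks and peak-to-gene assignment.

Peaks are placed into one of three exclusive location classes keyed on the
summit: promoter/5'UTR (within a fixed flank of a TSS, 3 kb by default),
gene body, or intergenic.  Separately, peaks are linked to genes by interval
proximity (gene body extended by a flank, 2 kb by default), and genes get a
promoter-bound flag when any peak summit falls within a TSS window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from intervaltree import IntervalTree

from ctsdimer.genomic_io import GeneModel, Peak

PROMOTER = "promoter_5utr"
GENE_BODY = "gene_body"
INTERGENIC = "intergenic"


@dataclass(frozen=True)
class LocationClass:
    peak_id: str
    label: str
    linked_gene: str | None


def _gene_trees(genes: Sequence[GeneModel], pad: int = 0) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for i, g in enumerate(genes):
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start - pad, g.end + pad, i)
    return trees


def classify_location(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    promoter_flank: int = 3000,
) -> list[LocationClass]:
    """Assign each peak summit to promoter_5utr, gene_body, or intergenic.

    A summit within ``[tss - flank, tss + flank]`` (inclusive) of any gene is
    promoter/5'UTR regardless of gene-body overlap; otherwise a summit inside
    a gene body is gene_body; everything else is intergenic.  When several
    genes qualify, the gene with the nearest TSS is linked.
    """
    body_trees = _gene_trees(genes)
    tss_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for i, g in enumerate(genes):
        tss_by_chrom.setdefault(g.chrom, []).append((g.tss, i))

    out: list[LocationClass] = []
    for p in peaks:
        s = p.summit
        promoter_hits = [
            (abs(s - tss), i) for tss, i in tss_by_chrom.get(p.chrom, []) if abs(s - tss) <= promoter_flank
        ]
        if promoter_hits:
            _, gi = min(promoter_hits)
            out.append(LocationClass(p.name, PROMOTER, genes[gi].gene_id))
            continue
        tree = body_trees.get(p.chrom)
        body_hits = sorted(tree.overlap(s, s + 1), key=lambda iv: iv.data) if tree else []
        if body_hits:
            gi = min((abs(s - genes[iv.data].tss), iv.data) for iv in body_hits)[1]
            out.append(LocationClass(p.name, GENE_BODY, genes[gi].gene_id))
        else:
            out.append(LocationClass(p.name, INTERGENIC, None))
    return out


def assign_peaks_to_genes(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    flank: int = 2000,
) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Link peaks to genes they touch within +-``flank`` of the gene body.

    A peak is assigned to a gene iff its interval intersects
    ``[start - flank, end + flank)``; a peak may map to several genes.
    Returns ``(gene_to_peaks, peak_to_genes)``.
    """
    trees = _gene_trees(genes, pad=flank)
    gene_to_peaks: dict[str, list[str]] = {g.gene_id: [] for g in genes}
    peak_to_genes: dict[str, list[str]] = {}
    for p in peaks:
        tree = trees.get(p.chrom)
        hits = sorted(tree.overlap(p.start, p.end), key=lambda iv: iv.data) if tree else []
        linked = [genes[iv.data].gene_id for iv in hits]
        peak_to_genes[p.name] = linked
        for gid in linked:
            gene_to_peaks[gid].append(p.name)
    return gene_to_peaks, peak_to_genes


def promoter_bound_flags(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    tss_flank: int = 2000,
) -> dict[str, bool]:
    """Per-gene flag: any peak summit within ``[tss - flank, tss + flank]``."""
    summits: dict[str, list[int]] = {}
    for p in peaks:
        summits.setdefault(p.chrom, []).append(p.summit)
    arrs = {c: np.sort(np.asarray(v)) for c, v in summits.items()}
    flags: dict[str, bool] = {}
    for g in genes:
        arr = arrs.get(g.chrom)
        if arr is None:
            flags[g.gene_id] = False
            continue
        lo = np.searchsorted(arr, g.tss - tss_flank, side="left")
        hi = np.searchsorted(arr, g.tss + tss_flank, side="right")
        flags[g.gene_id] = bool(hi > lo)
    return flags
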