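"""Occupancy classes from peak-set overlap and WT-vs-mutant tag density.

Two peak sets are compared by the reciprocal-intersection rule: a peak is
"shared" if it intersects a peak of the other set by at least 1 bp
(half-open coordinates).  Differential occupancy between genotypes is judged
on a composite peak set (the merged union of both genotypes' peaks) with a
more-than-``fold`` ratio of mean normalized tag densities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from intervaltree import IntervalTree

from ctsdimer.coverage_profiles import CoverageTrack
from ctsdimer.genomic_io import Peak, ValidationError

EPSILON_DENSITY = 0.1  # normalized units added to both densities before ratios

WT_GT_CM = "WT_gt_CM"
WT_EQ_CM = "WT_eq_CM"
WT_LT_CM = "WT_lt_CM"


@dataclass
class OverlapClassification:
    """Peaks of two sets split into shared and set-exclusive classes."""

    a_shared: list[Peak]
    a_only: list[Peak]
    b_shared: list[Peak]
    b_only: list[Peak]
    pairs: list[tuple[Peak, Peak]]

    @property
    def summary(self) -> dict:
        n_a = len(self.a_shared) + len(self.a_only)
        n_b = len(self.b_shared) + len(self.b_only)
        pct = lambda k, n: int(round(100.0 * k / n)) if n else 0
        return {
            "n_a": n_a,
            "n_b": n_b,
            "a_shared": len(self.a_shared),
            "a_only": len(self.a_only),
            "b_shared": len(self.b_shared),
            "b_only": len(self.b_only),
            "a_shared_pct": pct(len(self.a_shared), n_a),
            "a_only_pct": pct(len(self.a_only), n_a),
            "b_shared_pct": pct(len(self.b_shared), n_b),
            "b_only_pct": pct(len(self.b_only), n_b),
        }


def _trees(peaks: Sequence[Peak]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for i, p in enumerate(peaks):
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, i)
    return trees


def classify_overlap(set_a: Sequence[Peak], set_b: Sequence[Peak]) -> OverlapClassification:
    """Split two peak sets by the >=1 bp reciprocal-intersection rule.

    Shared status is per peak (a peak may match several on the other side);
    ``pairs`` lists every intersecting (A, B) pair.
    """
    trees_b = _trees(set_b)
    a_shared: list[Peak] = []
    a_only: list[Peak] = []
    b_matched: set[int] = set()
    pairs: list[tuple[Peak, Peak]] = []
    for pa in set_a:
        tree = trees_b.get(pa.chrom)
        matches = sorted(tree.overlap(pa.start, pa.end), key=lambda iv: iv.begin) if tree else []
        if matches:
            a_shared.append(pa)
            for iv in matches:
                b_matched.add(iv.data)
                pairs.append((pa, set_b[iv.data]))
        else:
            a_only.append(pa)
    b_shared = [p for i, p in enumerate(set_b) if i in b_matched]
    b_only = [p for i, p in enumerate(set_b) if i not in b_matched]
    return OverlapClassification(a_shared, a_only, b_shared, b_only, pairs)


def build_composite(set_wt: Sequence[Peak], set_cm: Sequence[Peak]) -> list[Peak]:
    """Merge two peak sets into a composite set of binding sites.

    Overlapping (>=1 bp, transitively) peaks collapse into one interval
    spanning their union; the merged summit and score come from the
    highest-scoring constituent.
    """
    by_chrom: dict[str, list[Peak]] = {}
    for p in list(set_wt) + list(set_cm):
        by_chrom.setdefault(p.chrom, []).append(p)
    composite: list[Peak] = []
    idx = 0
    for chrom in sorted(by_chrom):
        peaks = sorted(by_chrom[chrom], key=lambda p: (p.start, p.end))
        cluster: list[Peak] = []
        cluster_end = -1
        for p in peaks + [None]:
            if p is not None and (not cluster or p.start < cluster_end):
                cluster.append(p)
                cluster_end = max(cluster_end, p.end)
                continue
            if cluster:
                best = max(cluster, key=lambda q: q.score)
                composite.append(
                    Peak(
                        chrom=chrom,
                        start=min(q.start for q in cluster),
                        end=cluster_end,
                        name=f"composite_{idx}",
                        score=best.score,
                        summit=best.summit,
                    )
                )
                idx += 1
            if p is not None:
                cluster = [p]
                cluster_end = p.end
    return composite


def categorize_differential(
    composite: Sequence[Peak],
    cov_wt: CoverageTrack,
    cov_cm: CoverageTrack,
    fold: float = 2.0,
    eps: float = EPSILON_DENSITY,
) -> pd.DataFrame:
    """Label composite peaks WT_gt_CM / WT_eq_CM / WT_lt_CM by density ratio.

    Densities are mean normalized coverage over the peak interval, with a
    pseudocount ``eps`` stabilising complete-loss sites.  "More than
    ``fold``" is strict on both sides, so a ratio of exactly ``fold`` falls
    into WT_eq_CM.  Returns a DataFrame indexed by peak name with columns
    ``wt_density``, ``cm_density``, ``label``.
    """
    if not (cov_wt.normalized and cov_cm.normalized):
        raise ValidationError("categorize_differential requires normalized tracks")
    records = []
    for p in composite:
        wt = cov_wt.mean(p.chrom, p.start, p.end)
        cm = cov_cm.mean(p.chrom, p.start, p.end)
        # strict ">" comparisons, written multiplicatively so an exact ratio of
        # `fold` lands in WT_eq_CM and zero densities need no special-casing
        if wt + eps > fold * (cm + eps):
            label = WT_GT_CM
        elif cm + eps > fold * (wt + eps):
            label = WT_LT_CM
        else:
            label = WT_EQ_CM
        records.append((p.name, wt, cm, label))
    return pd.DataFrame.from_records(
        records, columns=["peak", "wt_density", "cm_density", "label"]
    ).set_index("peak")
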