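"""Normalized tag densities, anchored profiles, clustering and occupancy loss.

The central conventions follow common ChIP-seq practice: per-base coverage is
scaled to a common library size of 10 million mapped reads, anchored profile
matrices are binned at 10 bp resolution, and occupancy loss between genotypes
is summarised as a percentage reduction of the mean normalized density with a
two-sided rank-sum (Wilcoxon/Mann-Whitney) test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from ctsdimer.genomic_io import Peak, ValidationError

TARGET_LIBRARY = 10_000_000  # reads; common scale for all tracks


@dataclass
class CoverageTrack:
    """Piecewise-constant per-base coverage for a set of chromosomes."""

    data: dict[str, np.ndarray]
    mapped_reads: int | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        for chrom, arr in self.data.items():
            if np.any(arr < 0):
                raise ValidationError(f"negative coverage on {chrom}")

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Mean coverage over ``[start, end)``, clipped to the chromosome."""
        if end <= start:
            raise ValidationError(f"empty interval [{start}, {end}) on {chrom}")
        arr = self.data.get(chrom)
        if arr is None:
            return 0.0
        s, e = max(0, start), min(arr.size, end)
        if e <= s:
            return 0.0
        # positions outside the chromosome contribute 0
        return float(arr[s:e].sum() / (end - start))

    def chrom_sizes(self) -> dict[str, int]:
        return {c: a.size for c, a in self.data.items()}


def normalize_to_10M(track: CoverageTrack) -> CoverageTrack:
    """Scale a raw track to a 10-million-read library (factor 1e7 / mapped)."""
    if track.normalized:
        raise ValidationError("track already normalized")
    if track.mapped_reads is None or track.mapped_reads <= 0:
        raise ValidationError(f"mapped_reads must be positive, got {track.mapped_reads}")
    factor = TARGET_LIBRARY / track.mapped_reads
    data = {c: a * factor for c, a in track.data.items()}
    return CoverageTrack(data=data, mapped_reads=track.mapped_reads, normalized=True)


# ---------------------------------------------------------------------------
# anchored profiles
# ---------------------------------------------------------------------------


@dataclass
class ProfileMatrix:
    """Anchors x bins matrix of mean coverage around anchor points."""

    anchors: list[str]
    values: np.ndarray
    flank: int
    bin_width: int

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


def profile_matrix(
    track: CoverageTrack,
    anchors: Sequence[tuple],
    flank: int,
    bin_width: int = 10,
) -> ProfileMatrix:
    """Bin coverage around anchor points into a profile matrix.

    ``anchors`` are ``(id, chrom, position)`` or ``(id, chrom, position,
    strand)`` tuples; minus-strand anchors have their bins reversed so that
    bin 0 is always the upstream side.  Windows reaching past a chromosome
    end are padded with zeros (with a warning).
    """
    if not track.normalized:
        raise ValidationError("profile_matrix requires a normalized track")
    if (2 * flank) % bin_width != 0:
        raise ValidationError(f"2*flank ({2 * flank}) not divisible by bin_width ({bin_width})")
    n_bins = 2 * flank // bin_width
    csums = {c: np.concatenate(([0.0], np.cumsum(a))) for c, a in track.data.items()}

    ids: list[str] = []
    rows = np.zeros((len(anchors), n_bins), dtype=float)
    for i, anchor in enumerate(anchors):
        if len(anchor) == 3:
            aid, chrom, pos = anchor
            strand = "+"
        else:
            aid, chrom, pos, strand = anchor
        ids.append(str(aid))
        cs = csums.get(chrom)
        size = track.data[chrom].size if chrom in track.data else 0
        lo, hi = pos - flank, pos + flank
        if cs is None or lo < 0 or hi > size:
            warnings.warn(
                f"anchor {aid}: window [{lo}, {hi}) off chromosome {chrom}; clipping"
            )
        if cs is None:
            continue
        edges = lo + bin_width * np.arange(n_bins + 1)
        clipped = np.clip(edges, 0, size)
        sums = cs[clipped[1:]] - cs[clipped[:-1]]
        rows[i] = sums / bin_width
        if strand == "-":
            rows[i] = rows[i][::-1]
    return ProfileMatrix(anchors=ids, values=rows, flank=flank, bin_width=bin_width)


def average_profile(matrix: ProfileMatrix) -> np.ndarray:
    """Per-bin mean over all anchors (the classic 'average plot')."""
    if matrix.values.shape[0] == 0:
        raise ValidationError("empty profile matrix")
    return matrix.values.mean(axis=0)


# ---------------------------------------------------------------------------
# k-means with deterministic, prescribed behaviour
# ---------------------------------------------------------------------------


def kmeans_rows(
    matrix: ProfileMatrix | np.ndarray,
    k: int,
    seed: int,
    rank_normalize: bool = False,
    n_restarts: int = 100,
    max_iter: int = 300,
) -> np.ndarray:
    """Cluster profile rows by k-means, optionally on within-row ranks.

    Deterministic for a fixed seed: seeded farthest-point initialisation,
    ``n_restarts`` restarts of Lloyd iterations (at most ``max_iter`` each),
    keeping the labelling with the best within-cluster sum of squares.
    Assignment ties go to the lowest cluster index.
    """
    X = matrix.values if isinstance(matrix, ProfileMatrix) else np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValidationError(f"k={k} outside [1, {n}]")
    if rank_normalize:
        X = np.apply_along_axis(stats.rankdata, 1, X)
    if k == 1:
        return np.zeros(n, dtype=int)

    rng = np.random.default_rng(seed)
    best_labels = None
    best_obj = np.inf
    for _ in range(n_restarts):
        centers = _farthest_point_init(X, k, rng)
        labels = None
        for _ in range(max_iter):
            d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            new_labels = np.argmin(d2, axis=1)  # argmin takes the lowest index on ties
            if labels is not None and np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for j in range(k):
                mask = labels == j
                if mask.any():
                    centers[j] = X[mask].mean(axis=0)
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        obj = float(d2[np.arange(n), labels].sum())
        if obj < best_obj - 1e-12:
            best_obj = obj
            best_labels = labels
    return best_labels


def _farthest_point_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """First center random; each next center maximises distance to the chosen set."""
    n = X.shape[0]
    centers = [int(rng.integers(n))]
    d2 = ((X - X[centers[0]]) ** 2).sum(axis=1)
    for _ in range(1, k):
        nxt = int(np.argmax(d2))
        centers.append(nxt)
        d2 = np.minimum(d2, ((X - X[nxt]) ** 2).sum(axis=1))
    return X[centers].copy()


# ---------------------------------------------------------------------------
# rank-sum test and occupancy reduction
# ---------------------------------------------------------------------------


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided two-sample rank-sum test; returns ``(W, p)``.

    ``W`` is the rank sum of ``x`` in the pooled midrank ranking.  For group
    sizes both <= 8 the p-value is exact, from full enumeration of the
    permutation distribution of ``W`` (ties handled via midranks); otherwise a
    tie-corrected normal approximation with continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    if n == 0 or m == 0:
        raise ValidationError("rank_sum_test requires non-empty samples")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n].sum())
    mu = n * (ranks.sum()) / (n + m)  # = n*(N+1)/2 with midranks

    if n <= 8 and m <= 8:
        dev = abs(w - mu)
        count = 0
        total = 0
        for combo in itertools.combinations(range(n + m), n):
            total += 1
            if abs(ranks[list(combo)].sum() - mu) >= dev - 1e-9:
                count += 1
        return w, count / total

    N = n + m
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (N * (N - 1)))
    var = n * m / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return w, 1.0
    z = (abs(w - mu) - 0.5) / np.sqrt(var)
    return w, float(2 * stats.norm.sf(max(z, 0.0)))


@dataclass
class ReductionReport:
    """Occupancy loss at a set of sites: per-site densities and summary."""

    wt_density: np.ndarray
    cm_density: np.ndarray
    mean_reduction_pct: float
    rank_sum_p: float
    n_sites: int = field(default=0)


def occupancy_reduction(
    cov_wt: CoverageTrack, cov_cm: CoverageTrack, sites: Sequence[Peak]
) -> ReductionReport:
    """Mean occupancy reduction (%) across sites, with a rank-sum test.

    Per-site density is the mean normalized coverage over the peak interval.
    The reported reduction is ``100 * (1 - mean(cm) / mean(wt))``; the p-value
    is a two-sided unpaired rank-sum test of the two per-site density samples.
    """
    if len(sites) == 0:
        raise ValidationError("occupancy_reduction requires a non-empty site set")
    if not (cov_wt.normalized and cov_cm.normalized):
        raise ValidationError("occupancy_reduction requires normalized tracks")
    wt = np.array([cov_wt.mean(p.chrom, p.start, p.end) for p in sites])
    cm = np.array([cov_cm.mean(p.chrom, p.start, p.end) for p in sites])
    mean_wt = wt.mean()
    if mean_wt == 0:
        raise ValidationError("zero mean WT density across sites")
    reduction = 100.0 * (1.0 - cm.mean() / mean_wt)
    _, p = rank_sum_test(wt, cm)
    return ReductionReport(
        wt_density=wt,
        cm_density=cm,
        mean_reduction_pct=float(reduction),
        rank_sum_p=p,
        n_sites=len(sites),
    )
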