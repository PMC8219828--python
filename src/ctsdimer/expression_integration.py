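"""Differential expression and binding-expression integration.

The differential-expression procedure is deliberately simple and fully
specified: median-of-ratios size factors, per-gene Welch t-tests on
log2-transformed normalized counts, Benjamini-Hochberg adjustment, and the
strict DEG rule (adjusted p < 0.001 and linear fold change > 2).  Integration
with binding uses a two-sided Fisher exact test on the DEG x bound 2x2 table
over an explicit gene universe, plus a percentage-lost statistic, and a
gene-set-permutation enrichment analysis (ES/NES) with the t statistic as the
ranking metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ctsdimer.genomic_io import CountMatrix, GeneSet, ValidationError

PSEUDOCOUNT = 0.5  # added in fold-change and log transforms


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


# ---------------------------------------------------------------------------
# size factors and differential expression
# ---------------------------------------------------------------------------


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    The reference is the per-gene geometric mean across samples, computed on
    genes with all-positive counts; each sample's factor is the median over
    those genes of count / reference.
    """
    mat = counts.counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValidationError("size_factors: no gene with all-positive counts")
    sub = mat[positive]
    log_ref = np.log(sub).mean(axis=1)
    factors = np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def differential_expression(
    counts: CountMatrix,
    alpha: float = 0.001,
    fc: float = 2.0,
    condition_a: str = "A",
    condition_b: str = "B",
) -> pd.DataFrame:
    """Per-gene differential expression of condition B versus A.

    Counts are scaled by median-of-ratios size factors; ``log2fc`` is
    ``log2((mean_B + 0.5) / (mean_A + 0.5))`` on normalized means; the raw
    p-value comes from a two-sided Welch t-test on ``log2(normalized + 0.5)``
    and is BH-adjusted over all genes.  A gene is a DEG iff its adjusted p is
    below ``alpha`` AND its linear fold change exceeds ``fc`` in either
    direction, both strictly.

    Returns a DataFrame indexed by gene with columns ``base_mean``,
    ``log2fc``, ``t``, ``raw_p``, ``adj_p``, ``deg``, ``direction``.
    """
    samples_a = counts.samples_of(condition_a)
    samples_b = counts.samples_of(condition_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValidationError("differential_expression requires >= 2 replicates per condition")
    factors = size_factors(counts)
    norm = counts.counts / factors
    a = norm[samples_a].to_numpy(dtype=float)
    b = norm[samples_b].to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    base_mean = norm.mean(axis=1).to_numpy()
    ratio = (mean_b + PSEUDOCOUNT) / (mean_a + PSEUDOCOUNT)
    log2fc = np.log2(ratio)
    la, lb = np.log2(a + PSEUDOCOUNT), np.log2(b + PSEUDOCOUNT)
    with np.errstate(all="ignore"):
        t, raw_p = stats.ttest_ind(lb, la, axis=1, equal_var=False)
    t = np.where(np.isnan(t), 0.0, t)
    raw_p = np.where(np.isnan(raw_p), 1.0, raw_p)
    adj_p = multipletests(raw_p, method="fdr_bh")[1]
    deg = (adj_p < alpha) & ((ratio > fc) | (ratio < 1.0 / fc))
    direction = np.where(~deg, "ns", np.where(log2fc > 0, "up", "down"))
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "t": t,
            "raw_p": raw_p,
            "adj_p": adj_p,
            "deg": deg,
            "direction": direction,
        },
        index=counts.counts.index,
    )


def select_markers(
    de: pd.DataFrame, alpha: float = 1e-6, log2fc_min: float = 4.0
) -> set[str]:
    """Stringent upregulated marker genes: adj_p < alpha and log2fc > log2fc_min."""
    mask = (de["adj_p"] < alpha) & (de["log2fc"] > log2fc_min)
    return set(de.index[mask])


# ---------------------------------------------------------------------------
# Fisher association and percentage-lost arithmetic
# ---------------------------------------------------------------------------


@dataclass
class AssociationResult:
    """2x2 DEG x bound association over a stated gene universe."""

    table: np.ndarray  # [[deg&bound, deg&!bound], [!deg&bound, !deg&!bound]]
    odds_ratio: float
    exact_p: float
    bound_fraction_pct: int


def fisher_two_sided(table: np.ndarray) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities of all
    tables (with the observed margins) no more probable than the observed."""
    a, b = int(table[0, 0]), int(table[0, 1])
    c, d = int(table[1, 0]), int(table[1, 1])
    N = a + b + c + d
    row1 = a + b
    col1 = a + c
    rv = stats.hypergeom(N, col1, row1)
    k = np.arange(max(0, row1 + col1 - N), min(row1, col1) + 1)
    pmf = rv.pmf(k)
    p_obs = rv.pmf(a)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def fisher_association(
    degs: Iterable[str], bound: Iterable[str], universe: Iterable[str]
) -> AssociationResult:
    """Association between DEG status and binding over a gene universe.

    The odds ratio is the sample odds ratio ``ad / bc`` with a Haldane
    correction (+0.5 per cell) when any cell is zero;
    ``bound_fraction_pct`` is the rounded percentage of DEGs that are bound.
    """
    universe = set(universe)
    degs = set(degs)
    bound = set(bound)
    if not degs or not universe:
        raise ValidationError("fisher_association: empty DEG set or universe")
    if not degs <= universe or not bound <= universe:
        raise ValidationError("fisher_association: degs and bound must be subsets of universe")
    a = len(degs & bound)
    b = len(degs - bound)
    c = len(bound - degs)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]], dtype=int)
    if min(a, b, c, d) == 0:
        oa, ob, oc, od = (x + 0.5 for x in (a, b, c, d))
    else:
        oa, ob, oc, od = a, b, c, d
    odds = (oa * od) / (ob * oc)
    p = fisher_two_sided(table)
    pct = _round_half_up(100.0 * a / len(degs))
    return AssociationResult(table=table, odds_ratio=float(odds), exact_p=p, bound_fraction_pct=pct)


def percent_lost(bound_genes: Iterable[str], lost_genes: Iterable[str]) -> int:
    """Rounded percentage of bound genes that lost binding."""
    bound_genes = set(bound_genes)
    lost_genes = set(lost_genes)
    if not bound_genes:
        raise ValidationError("percent_lost: empty bound gene set")
    if not lost_genes <= bound_genes:
        raise ValidationError("percent_lost: lost_genes must be a subset of bound_genes")
    return _round_half_up(100.0 * len(lost_genes) / len(bound_genes))


# ---------------------------------------------------------------------------
# gene-set enrichment (gene-set permutation, weight 1)
# ---------------------------------------------------------------------------


@dataclass
class GseaResult:
    es: float
    nes: float
    perm_p: float
    n_perm: int
    seed: int


def _enrichment_score(order_stats: np.ndarray, member_mask: np.ndarray) -> float:
    """ES of a ranked list: weighted running sum, extremum by magnitude."""
    absw = np.abs(order_stats)
    total = absw[member_mask].sum()
    n = order_stats.size
    n_miss = n - int(member_mask.sum())
    steps = np.where(
        member_mask,
        absw / total if total > 0 else 0.0,
        -1.0 / n_miss,
    )
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def gsea_lite(
    ranking: pd.Series,
    gene_set: GeneSet,
    n_perm: int = 1000,
    seed: int = 0,
) -> GseaResult:
    """Gene-set enrichment with a gene-set-permutation null.

    Genes are sorted by decreasing ranking statistic (typically the per-gene
    t statistic).  The running sum gains ``|stat| / sum_set|stat|`` at member
    genes and loses ``1 / (N - set size)`` elsewhere; the enrichment score is
    the extremum.  The null re-draws ``n_perm`` random same-size gene sets;
    NES is the ES divided by the mean of same-sign null scores and the
    permutation p compares magnitudes among same-sign null scores.
    """
    if n_perm < 100:
        raise ValidationError("gsea_lite: n_perm must be >= 100")
    # stable sort after ordering by gene id makes tie order deterministic
    ranked = ranking.loc[sorted(ranking.index)].sort_values(ascending=False, kind="mergesort")
    genes = np.asarray(ranked.index)
    values = ranked.to_numpy(dtype=float)
    members = gene_set.members & set(genes)
    if not members:
        raise ValidationError(f"gsea_lite: gene set {gene_set.set_id} disjoint from ranking")
    if len(members) >= genes.size:
        raise ValidationError("gsea_lite: gene set covers the whole ranked list")
    mask = np.isin(genes, sorted(members))
    es = _enrichment_score(values, mask)

    rng = np.random.default_rng(seed)
    n_set = int(mask.sum())
    null = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(genes.size, size=n_set, replace=False)
        m = np.zeros(genes.size, dtype=bool)
        m[idx] = True
        null[i] = _enrichment_score(values, m)
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    # dividing by the mean magnitude of same-sign null scores preserves the sign
    nes = float(es / np.abs(same_sign).mean()) if same_sign.size else 0.0
    perm_p = (1 + int((np.abs(same_sign) >= abs(es)).sum())) / (1 + same_sign.size)
    return GseaResult(es=float(es), nes=float(nes), perm_p=float(perm_p), n_perm=n_perm, seed=seed)
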