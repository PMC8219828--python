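import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from ctsdimer.expression_integration import (
    differential_expression,
    fisher_association,
    fisher_two_sided,
    gsea_lite,
    percent_lost,
    select_markers,
    size_factors,
)
from ctsdimer.genomic_io import CountMatrix, GeneSet, ValidationError


def matrix(arr, samples=("s1", "s2", "s3", "s4"), conds=("A", "A", "B", "B")):
    arr = np.asarray(arr)
    df = pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])], columns=samples)
    return CountMatrix(counts=df, condition_of=dict(zip(samples, conds)))


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------


def test_identical_columns_give_equal_factors():
    cm = matrix(np.tile([[10], [20], [5]], (1, 4)))
    f = size_factors(cm)
    assert np.allclose(f, f.iloc[0])


def test_doubled_column_gives_doubled_factor():
    base = np.array([[10, 10, 20, 20], [40, 40, 80, 80], [7, 7, 14, 14]])
    f = size_factors(matrix(base))
    assert f["s3"] / f["s1"] == pytest.approx(2.0)
    assert f["s4"] / f["s2"] == pytest.approx(2.0)


def test_all_zero_gene_excluded_from_reference():
    base = np.array([[10, 10, 20, 20], [40, 40, 80, 80]])
    with_zero = np.vstack([base, [0, 0, 0, 0]])
    assert np.allclose(size_factors(matrix(base)), size_factors(matrix(with_zero)))


def test_no_positive_gene_is_error():
    with pytest.raises(ValidationError, match="all-positive"):
        size_factors(matrix([[0, 1, 1, 1], [1, 0, 1, 1]]))


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------


def test_deg_rule_strict_boundaries():
    rng = np.random.default_rng(0)
    n = 400
    base = rng.integers(500, 2000, n).astype(float)
    a = np.column_stack([rng.poisson(base) for _ in range(3)])
    b_means = base.copy()
    b_means[:50] *= 6.0  # unambiguous DEGs
    b = np.column_stack([rng.poisson(b_means) for _ in range(3)])
    cm = matrix(
        np.hstack([a, b]).astype(int),
        samples=("a1", "a2", "a3", "b1", "b2", "b3"),
        conds=("A", "A", "A", "B", "B", "B"),
    )
    de = differential_expression(cm)
    assert de.loc["g0", "deg"]
    assert de.loc["g0", "direction"] == "up"
    # unchanged genes are not called
    assert not de.loc["g399", "deg"]
    # the flag is exactly the stated strict rule
    ratio = 2.0 ** de["log2fc"]
    expected = (de["adj_p"] < 0.001) & ((ratio > 2.0) | (ratio < 0.5))
    assert (de["deg"] == expected).all()


def test_exact_twofold_change_is_not_deg():
    # construct normalized means whose ratio with pseudocount is exactly 2
    a = np.tile([[100]], (1, 4)).repeat(20, axis=0)
    cm = matrix(a)
    de = differential_expression(cm)
    assert not de["deg"].any()


def test_bh_adjustment_is_monotone():
    rng = np.random.default_rng(1)
    counts = rng.poisson(200, size=(300, 6))
    cm = matrix(
        counts, samples=tuple(f"s{i}" for i in range(6)), conds=("A",) * 3 + ("B",) * 3
    )
    de = differential_expression(cm)
    order = de.sort_values("raw_p")
    assert (np.diff(order["adj_p"]) > -1e-12).all()
    assert (de["adj_p"] >= de["raw_p"] - 1e-12).all()


def test_two_replicates_required():
    cm_bad = matrix(
        np.ones((5, 4), dtype=int),
        samples=("s1", "s2", "s3", "s4"),
        conds=("A", "A", "B", "B"),
    )
    cm_bad.condition_of = {"s1": "A", "s2": "A", "s3": "B", "s4": "B"}
    # removing a condition's replicate must raise
    df = cm_bad.counts[["s1", "s2", "s3"]]
    with pytest.raises(ValidationError):
        CountMatrix(counts=df, condition_of={"s1": "A", "s2": "A", "s3": "B"})


def test_marker_selection_boundaries():
    de = pd.DataFrame(
        {
            "log2fc": [4.5, 3.9, 4.2, -5.0],
            "adj_p": [1e-7, 1e-9, 1e-5, 1e-9],
        },
        index=["hit", "low_fc", "weak_p", "down"],
    )
    assert select_markers(de) == {"hit"}
    assert select_markers(pd.DataFrame({"log2fc": [], "adj_p": []})) == set()


# ---------------------------------------------------------------------------
# Fisher association
# ---------------------------------------------------------------------------


def brute_force_fisher(table):
    """Enumerate all tables with the observed margins; sum P(table) <= P(obs)."""
    a, b = table[0]
    c, d = table[1]
    row1, col1, N = a + b, a + c, a + b + c + d

    def prob(k):
        return (
            comb(col1, k, exact=True)
            * comb(N - col1, row1 - k, exact=True)
            / comb(N, row1, exact=True)
        )

    p_obs = prob(a)
    return sum(
        prob(k)
        for k in range(max(0, row1 + col1 - N), min(row1, col1) + 1)
        if prob(k) <= p_obs * (1 + 1e-9)
    )


def test_fisher_matches_enumeration_for_all_small_margins():
    for a, b, c, d in itertools.product(range(5), repeat=4):
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            continue
        table = np.array([[a, b], [c, d]])
        assert fisher_two_sided(table) == pytest.approx(brute_force_fisher(table.tolist()))


def test_fisher_matches_scipy_cross_check():
    rng = np.random.default_rng(2)
    for _ in range(25):
        table = rng.integers(0, 40, size=(2, 2))
        if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
            continue
        expected = stats.fisher_exact(table, alternative="two-sided")[1]
        assert fisher_two_sided(table) == pytest.approx(expected, rel=1e-6)


def test_independence_table_or_one_p_one():
    universe = [f"g{i}" for i in range(150)]
    degs = set(universe[:50])  # 50 of 150
    bound = set(universe[:10]) | set(universe[50:70])  # 10/50 vs 20/100
    res = fisher_association(degs, bound, universe)
    assert res.odds_ratio == pytest.approx(1.0)
    assert res.exact_p == pytest.approx(1.0)


def test_bound_fraction_pct_printed_example():
    universe = [f"g{i}" for i in range(20_000)]
    degs = set(universe[:1513])
    bound = set(universe[:557]) | set(universe[5000:8000])
    res = fisher_association(degs, bound, universe)
    assert res.table[0, 0] == 557
    assert res.bound_fraction_pct == 37


def test_fisher_validations_and_haldane():
    with pytest.raises(ValidationError, match="empty"):
        fisher_association(set(), {"a"}, {"a"})
    with pytest.raises(ValidationError, match="subset"):
        fisher_association({"x"}, set(), {"a"})
    res = fisher_association({"a"}, {"a"}, {"a", "b", "c"})
    assert math.isfinite(res.odds_ratio) and res.odds_ratio > 0


# ---------------------------------------------------------------------------
# percentage-lost arithmetic
# ---------------------------------------------------------------------------


def test_percent_lost_printed_examples():
    bound = {f"g{i}" for i in range(475)}
    lost = {f"g{i}" for i in range(327)}
    assert percent_lost(bound, lost) == 69
    bound = {f"g{i}" for i in range(205)}
    lost = {f"g{i}" for i in range(157)}
    assert percent_lost(bound, lost) == 77
    assert percent_lost({"a", "b"}, set()) == 0
    with pytest.raises(ValidationError):
        percent_lost(set(), set())
    with pytest.raises(ValidationError):
        percent_lost({"a"}, {"b"})


# ---------------------------------------------------------------------------
# GSEA
# ---------------------------------------------------------------------------


def test_es_matches_hand_computed_running_sum():
    stats_series = pd.Series([5.0, 4.0, 3.0, 2.0, 1.0], index=list("abcde"))
    gs = GeneSet("top2", "", frozenset({"a", "b"}))
    res = gsea_lite(stats_series, gs, n_perm=100, seed=0)
    # running sum: +5/9, +4/9, then -1/3 three times -> max at 1.0
    assert res.es == pytest.approx(1.0)
    assert res.nes > 0


def test_gsea_rejects_degenerate_sets():
    s = pd.Series([3.0, 2.0, 1.0], index=list("abc"))
    with pytest.raises(ValidationError, match="whole"):
        gsea_lite(s, GeneSet("all", "", frozenset("abc")), n_perm=100, seed=0)
    with pytest.raises(ValidationError, match="disjoint"):
        gsea_lite(s, GeneSet("none", "", frozenset({"zzz"})), n_perm=100, seed=0)
    with pytest.raises(ValidationError, match="n_perm"):
        gsea_lite(s, GeneSet("a", "", frozenset({"a"})), n_perm=10, seed=0)


def test_gsea_deterministic_for_fixed_seed():
    rng = np.random.default_rng(3)
    s = pd.Series(rng.normal(size=200), index=[f"g{i}" for i in range(200)])
    gs = GeneSet("set", "", frozenset({f"g{i}" for i in range(0, 40, 2)}))
    r1 = gsea_lite(s, gs, n_perm=200, seed=9)
    r2 = gsea_lite(s, gs, n_perm=200, seed=9)
    assert (r1.es, r1.nes, r1.perm_p) == (r2.es, r2.nes, r2.perm_p)
    assert 0 < r1.perm_p <= 1
    assert np.sign(r1.nes) == np.sign(r1.es)


def test_gsea_null_distribution_invariant_to_label_permutation():
    """Permuting which genes carry which statistic leaves the null in law."""
    rng = np.random.default_rng(4)
    values = rng.normal(size=100)
    idx = np.array([f"g{i}" for i in range(100)])
    s1 = pd.Series(values, index=idx)
    s2 = pd.Series(values, index=idx[rng.permutation(100)])
    gs1 = GeneSet("set", "", frozenset(s1.nlargest(10).index))
    gs2 = GeneSet("set", "", frozenset(s2.nlargest(10).index))
    r1 = gsea_lite(s1, gs1, n_perm=300, seed=5)
    r2 = gsea_lite(s2, gs2, n_perm=300, seed=5)
    assert r1.es == pytest.approx(r2.es)
    assert r1.nes == pytest.approx(r2.nes)
    assert r1.perm_p == pytest.approx(r2.perm_p)
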