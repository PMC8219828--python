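import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from ctsdimer.coverage_profiles import (
    CoverageTrack,
    average_profile,
    kmeans_rows,
    normalize_to_10M,
    occupancy_reduction,
    profile_matrix,
    rank_sum_test,
)
from ctsdimer.genomic_io import Peak, ValidationError


def track_of(values, mapped=None, normalized=False, chrom="chr1"):
    return CoverageTrack(
        data={chrom: np.asarray(values, dtype=float)},
        mapped_reads=mapped,
        normalized=normalized,
    )


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def test_normalize_factor_one_at_ten_million():
    t = normalize_to_10M(track_of(np.arange(10.0), mapped=10_000_000))
    assert np.array_equal(t.data["chr1"], np.arange(10.0))
    assert t.normalized


def test_normalize_factor_two_at_five_million():
    t = normalize_to_10M(track_of([1.0, 2.0], mapped=5_000_000))
    assert np.array_equal(t.data["chr1"], [2.0, 4.0])


def test_normalize_zero_track_stays_zero():
    t = normalize_to_10M(track_of(np.zeros(5), mapped=3_000_000))
    assert np.array_equal(t.data["chr1"], np.zeros(5))


def test_normalize_rejects_double_and_bad_mapped():
    t = normalize_to_10M(track_of([1.0], mapped=1))
    with pytest.raises(ValidationError, match="already"):
        normalize_to_10M(t)
    with pytest.raises(ValidationError, match="positive"):
        normalize_to_10M(track_of([1.0], mapped=0))


def test_normalization_conserves_ratios():
    values = np.array([1.0, 4.0, 0.5, 8.0])
    t = normalize_to_10M(track_of(values, mapped=7_345_111))
    out = t.data["chr1"]
    assert out[1] / out[0] == pytest.approx(4.0)
    assert out[3] / out[2] == pytest.approx(16.0)


# ---------------------------------------------------------------------------
# profile matrices
# ---------------------------------------------------------------------------


def naive_profile(values, pos, flank, bin_width, strand="+"):
    """Per-base oracle: mean of explicit base slices per bin."""
    padded = np.concatenate([np.zeros(flank), values, np.zeros(flank)])
    window = padded[pos:pos + 2 * flank]
    row = window.reshape(-1, bin_width).mean(axis=1)
    return row[::-1] if strand == "-" else row


def test_uniform_track_gives_constant_matrix():
    t = track_of(np.full(2000, 3.25), normalized=True)
    m = profile_matrix(t, [("a", "chr1", 1000)], flank=200, bin_width=10)
    assert np.allclose(m.values, 3.25)
    assert m.n_bins == 40


def test_unit_impulse_lands_in_center_bin():
    values = np.zeros(2000)
    values[1000] = 10.0
    t = track_of(values, normalized=True)
    m = profile_matrix(t, [("a", "chr1", 1000)], flank=100, bin_width=10)
    assert m.values[0, 10] == pytest.approx(1.0)  # first downstream bin
    assert np.count_nonzero(m.values) == 1


def test_bin_count_arithmetic_and_divisibility():
    t = track_of(np.zeros(5000), normalized=True)
    m = profile_matrix(t, [("a", "chr1", 2500)], flank=1000, bin_width=10)
    assert m.n_bins == 200
    with pytest.raises(ValidationError, match="divisible"):
        profile_matrix(t, [("a", "chr1", 2500)], flank=1001, bin_width=10)


def test_profile_matches_per_base_oracle_with_strand_flip():
    rng = np.random.default_rng(0)
    values = rng.uniform(0, 5, 3000)
    t = track_of(values, normalized=True)
    anchors = [("f", "chr1", 700, "+"), ("r", "chr1", 2100, "-")]
    m = profile_matrix(t, anchors, flank=150, bin_width=10)
    assert np.allclose(m.values[0], naive_profile(values, 700 - 150 + 150, 150, 10))
    assert np.allclose(m.values[1], naive_profile(values, 2100 - 150 + 150, 150, 10, "-"))


def test_off_chromosome_window_clipped_with_warning():
    t = track_of(np.full(100, 2.0), normalized=True)
    with pytest.warns(UserWarning, match="clipping"):
        m = profile_matrix(t, [("a", "chr1", 10)], flank=50, bin_width=10)
    # bins before base 0 are zero-padded
    assert m.values[0, 0] == 0.0
    assert m.values[0, -1] == 2.0


def test_profile_requires_normalized_track():
    with pytest.raises(ValidationError, match="normalized"):
        profile_matrix(track_of(np.zeros(100), mapped=1), [("a", "chr1", 50)], 10, 10)


def test_average_profile_identity_and_mean():
    t = track_of(np.zeros(100), normalized=True)
    m = profile_matrix(t, [("a", "chr1", 50)], flank=20, bin_width=10)
    m.values = np.array([[1.0, 2.0, 3.0, 4.0]])
    assert np.array_equal(average_profile(m), m.values[0])
    m.values = np.array([[0.0, 0.0], [4.0, 6.0]])
    assert np.array_equal(average_profile(m), [2.0, 3.0])


# ---------------------------------------------------------------------------
# k-means
# ---------------------------------------------------------------------------


def test_kmeans_recovers_separated_groups():
    rng = np.random.default_rng(1)
    a = rng.normal(0, 0.1, (20, 6))
    b = rng.normal(5, 0.1, (15, 6))
    X = np.vstack([a, b])
    labels = kmeans_rows(X, k=2, seed=0)
    assert len(set(labels[:20])) == 1
    assert len(set(labels[20:])) == 1
    assert labels[0] != labels[-1]


def test_kmeans_k1_and_determinism():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(30, 4))
    assert set(kmeans_rows(X, k=1, seed=3)) == {0}
    l1 = kmeans_rows(X, k=3, seed=42, n_restarts=5)
    l2 = kmeans_rows(X, k=3, seed=42, n_restarts=5)
    assert np.array_equal(l1, l2)
    with pytest.raises(ValidationError):
        kmeans_rows(X, k=31, seed=0)


def test_kmeans_rank_normalization_ignores_row_scale():
    rng = np.random.default_rng(3)
    base = np.vstack([np.tile([1.0, 2.0, 3.0, 4.0], (10, 1)), np.tile([4.0, 3.0, 2.0, 1.0], (10, 1))])
    scaled = base * rng.uniform(0.1, 100, size=(20, 1))  # wild per-row scales
    labels = kmeans_rows(scaled, k=2, seed=0, rank_normalize=True)
    assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1 and labels[0] != labels[-1]


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------


def enumeration_rank_sum(x, y):
    """Independent oracle: exhaustive relabelling of the pooled sample."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n = len(x)
    mu = n * ranks.sum() / len(pooled)
    obs = abs(ranks[:n].sum() - mu)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        total += 1
        if abs(ranks[list(combo)].sum() - mu) >= obs - 1e-9:
            hits += 1
    return hits / total


@given(
    st.lists(st.integers(0, 60), min_size=2, max_size=6),
    st.lists(st.integers(0, 60), min_size=2, max_size=6),
)
def test_exact_rank_sum_matches_enumeration_oracle(x, y):
    _, p = rank_sum_test(x, y)
    assert p == pytest.approx(enumeration_rank_sum(np.array(x, float), np.array(y, float)))


def test_exact_rank_sum_matches_scipy_without_ties():
    rng = np.random.default_rng(4)
    for _ in range(20):
        pooled = rng.permutation(100)[:12].astype(float)
        x, y = pooled[:6], pooled[6:]
        _, p = rank_sum_test(x, y)
        expected = stats.mannwhitneyu(x, y, method="exact", alternative="two-sided").pvalue
        assert p == pytest.approx(expected)


def test_large_sample_matches_scipy_asymptotic():
    rng = np.random.default_rng(5)
    x = rng.normal(0, 1, 40)
    y = rng.normal(0.7, 1, 35)
    _, p = rank_sum_test(x, y)
    expected = stats.mannwhitneyu(
        x, y, method="asymptotic", use_continuity=True, alternative="two-sided"
    ).pvalue
    assert p == pytest.approx(expected, rel=1e-9)


def test_large_sample_with_ties_matches_scipy():
    rng = np.random.default_rng(6)
    x = rng.integers(0, 5, 30).astype(float)
    y = rng.integers(1, 6, 25).astype(float)
    _, p = rank_sum_test(x, y)
    expected = stats.mannwhitneyu(
        x, y, method="asymptotic", use_continuity=True, alternative="two-sided"
    ).pvalue
    assert p == pytest.approx(expected, rel=1e-9)


# ---------------------------------------------------------------------------
# occupancy reduction
# ---------------------------------------------------------------------------


def test_exact_halving_reports_fifty_percent():
    rng = np.random.default_rng(7)
    values = rng.uniform(1, 10, 5000)
    wt = track_of(values, normalized=True)
    cm = track_of(values / 2, normalized=True)
    sites = [Peak("chr1", i * 100, i * 100 + 50, f"s{i}", 1.0, i * 100 + 25) for i in range(40)]
    rep = occupancy_reduction(wt, cm, sites)
    assert rep.mean_reduction_pct == pytest.approx(50.0)
    assert rep.rank_sum_p < 1e-6


def test_null_reduction_is_zero_with_p_near_one():
    values = np.random.default_rng(8).uniform(1, 10, 5000)
    wt = track_of(values, normalized=True)
    cm = track_of(values.copy(), normalized=True)
    sites = [Peak("chr1", i * 100, i * 100 + 50, f"s{i}", 1.0, i * 100 + 25) for i in range(40)]
    rep = occupancy_reduction(wt, cm, sites)
    assert rep.mean_reduction_pct == pytest.approx(0.0)
    assert rep.rank_sum_p > 0.9


def test_empty_site_set_rejected():
    t = track_of(np.ones(10), normalized=True)
    with pytest.raises(ValidationError, match="non-empty"):
        occupancy_reduction(t, t, [])
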