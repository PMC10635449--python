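import itertools
import math

import numpy as np
import pytest

from recyclesim.stats import (
    cov,
    exposure_test,
    hotspot_mask,
    hotspot_overlap,
    local_g,
    skewness,
    spearman,
)

# ---------------------------------------------------------------------------
# coefficient of variation
# ---------------------------------------------------------------------------

def test_cov_examples():
    assert cov([1, 2, 3]) == pytest.approx(0.5)  # sd 1, mean 2
    assert cov([4, 4, 4, 4]) == 0.0
    assert math.isnan(cov([np.nan, np.nan]))


def test_cov_zero_mean_warns_and_is_missing():
    with pytest.warns(RuntimeWarning):
        assert math.isnan(cov([-1.0, 1.0]))


def test_cov_matches_naive_two_pass():
    rng = np.random.default_rng(1)
    for _ in range(5):
        x = rng.gamma(2.0, 3.0, size=25)
        mean = sum(x) / len(x)
        sd = math.sqrt(sum((v - mean) ** 2 for v in x) / (len(x) - 1))
        assert cov(x) == pytest.approx(sd / mean, rel=1e-12)


# ---------------------------------------------------------------------------
# skewness
# ---------------------------------------------------------------------------

def test_skewness_examples():
    assert skewness([-1, 0, 1]) == pytest.approx(0.0)
    # hand-computed m3 / m2^(3/2): m2 = 0.1875, m3 = 0.09375
    assert skewness([0, 0, 0, 1]) == pytest.approx(1.1547005383792515)
    assert math.isnan(skewness([5, 5, 5]))
    assert math.isnan(skewness([1, 2]))


def test_skewness_matches_moment_oracle():
    rng = np.random.default_rng(2)
    for _ in range(5):
        x = rng.exponential(1.0, size=10)
        mean = sum(x) / len(x)
        m2 = sum((v - mean) ** 2 for v in x) / len(x)
        m3 = sum((v - mean) ** 3 for v in x) / len(x)
        assert skewness(x) == pytest.approx(m3 / m2 ** 1.5, rel=1e-12)


def test_negative_skew_marks_older_assemblages():
    older = [1, 2, 3, 4, 5, 50]   # mostly early first-discard years
    younger = [1, 46, 47, 48, 49, 50]
    assert skewness(older) > 0 > skewness(younger)


# ---------------------------------------------------------------------------
# exposure (rank-sum) test
# ---------------------------------------------------------------------------

def _exact_ranksum_p_less(x, y):
    """Independent oracle: exact permutation distribution of the
    Mann-Whitney U statistic, P(U <= observed)."""
    def u_stat(a, b):
        # U of the first sample: pairs where a exceeds b (ties half)
        u = 0.0
        for ai in a:
            for bj in b:
                u += (ai > bj) + 0.5 * (ai == bj)
        return u

    obs = u_stat(x, y)
    combined = list(x) + list(y)
    n1 = len(x)
    count = total = 0
    for idx in itertools.combinations(range(len(combined)), n1):
        a = [combined[i] for i in idx]
        b = [combined[i] for i in range(len(combined)) if i not in idx]
        total += 1
        if u_stat(a, b) <= obs + 1e-9:
            count += 1
    return count / total


def test_exposure_clear_separation_exact_p():
    stat, p = exposure_test([1, 2, 3], [10, 11, 12])
    assert p == pytest.approx(1 / 20)  # 1 of C(6,3) arrangements


def test_exposure_matches_enumeration_oracle():
    rng = np.random.default_rng(3)
    for _ in range(4):
        x = list(rng.choice(np.arange(1, 100), size=4, replace=False))
        y = list(rng.choice(np.arange(101, 200), size=5, replace=False))
        rng.shuffle(y)
        _, p = exposure_test(x, y)
        assert p == pytest.approx(_exact_ranksum_p_less(x, y), abs=1e-9)


def test_exposure_identical_samples_uninformative():
    _, p = exposure_test([1, 2, 3, 4], [1, 2, 3, 4])
    assert p == pytest.approx(0.5, abs=0.1)


def test_exposure_direction_flips_on_swap():
    x, y = [1, 2, 3, 7], [5, 8, 9, 10]
    _, p_xy = exposure_test(x, y)
    _, p_yx = exposure_test(y, x)
    assert p_xy < 0.5 < p_yx


def test_exposure_empty_sample_is_missing():
    stat, p = exposure_test([], [1, 2])
    assert math.isnan(stat) and math.isnan(p)


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def _rank_average(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def test_spearman_examples():
    x = [1, 2, 3, 4]
    assert spearman(x, x) == pytest.approx(1.0)
    assert spearman(x, [-v for v in x]) == pytest.approx(-1.0)
    assert spearman(x, [2, 1, 4, 3]) == pytest.approx(0.6)
    assert math.isnan(spearman([1, 1, 1], [1, 2, 3]))  # zero rank variance
    assert math.isnan(spearman([1, 2], [1, 2]))  # n < 3


def test_spearman_matches_rank_oracle_with_ties():
    rng = np.random.default_rng(4)
    for _ in range(5):
        x = list(rng.integers(0, 5, size=10))
        y = list(rng.integers(0, 5, size=10))
        rx, ry = _rank_average(x), _rank_average(y)
        if len(set(rx)) < 2 or len(set(ry)) < 2:
            continue
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y) == pytest.approx(expected, rel=1e-10)


# ---------------------------------------------------------------------------
# local G
# ---------------------------------------------------------------------------

def _local_g_bruteforce(field):
    """Independent oracle: explicit queen weight matrix and the direct
    Gi formula with all-but-focal moments."""
    x = np.asarray(field, float)
    h, w = x.shape
    n = h * w
    cells = [(r, c) for r in range(h) for c in range(w)]
    W = np.zeros((n, n))
    for i, (r, c) in enumerate(cells):
        for j, (rr, cc) in enumerate(cells):
            if (r, c) != (rr, cc) and abs(r - rr) <= 1 and abs(c - cc) <= 1:
                W[i, j] = 1.0
    flat = x.ravel()
    out = np.zeros(n)
    for i in range(n):
        others = np.delete(flat, i)
        wi = W[i].sum()
        mean_i = others.mean()
        var_i = (others ** 2).mean() - mean_i ** 2
        denom = math.sqrt(var_i * ((n - 1) * wi - wi ** 2) / (n - 2))
        num = W[i] @ flat - wi * mean_i
        out[i] = num / denom if denom > 0 else 0.0
    return out.reshape(h, w)


def test_local_g_matches_bruteforce_on_toy_grids():
    rng = np.random.default_rng(5)
    for _ in range(3):
        field = rng.poisson(3.0, size=(5, 5)).astype(float)
        if np.unique(field).size < 2:
            continue
        np.testing.assert_allclose(local_g(field),
                                   _local_g_bruteforce(field), atol=1e-10)


def test_local_g_constant_field_is_zero():
    assert (local_g(np.full((4, 4), 3.0)) == 0.0).all()


def test_local_g_spike_elevates_neighbors_not_self():
    field = np.zeros((5, 5))
    field[2, 2] = 10.0
    g = local_g(field)
    peak = g.max()
    neighbors = [g[r, c] for r in (1, 2, 3) for c in (1, 2, 3)
                 if (r, c) != (2, 2)]
    assert all(v == pytest.approx(peak) for v in neighbors)
    assert g[2, 2] < peak  # the focal cell is not its own neighbor


def test_local_g_missing_cells_stay_missing():
    field = np.arange(16, dtype=float).reshape(4, 4)
    field[0, 0] = np.nan
    g = local_g(field)
    assert math.isnan(g[0, 0])
    assert np.isfinite(np.delete(g.ravel(), 0)).all()


# ---------------------------------------------------------------------------
# hotspots
# ---------------------------------------------------------------------------

def test_hotspot_threshold_flags_expected_tail():
    """Over many standard-normal fields, mean + 2 SD flags about the
    upper 2.3% of cells."""
    rng = np.random.default_rng(6)
    fractions = [hotspot_mask(rng.normal(size=(10, 10))).count / 100
                 for _ in range(2000)]
    assert np.mean(fractions) == pytest.approx(0.0228, abs=0.01)


def test_hotspot_constant_field_flags_nothing():
    assert hotspot_mask(np.full((3, 3), 2.0)).count == 0


def test_hotspot_flags_invariant_to_constant_shift():
    rng = np.random.default_rng(7)
    g = rng.normal(size=(6, 6))
    np.testing.assert_array_equal(hotspot_mask(g).mask,
                                  hotspot_mask(g + 17.3).mask)


def test_hotspot_overlap_bounds():
    rng = np.random.default_rng(8)
    a = hotspot_mask(rng.normal(size=(10, 10)))
    b = hotspot_mask(rng.normal(size=(10, 10)))
    assert hotspot_overlap(a, a) == a.count
    assert hotspot_overlap(a, b) <= min(a.count, b.count)
    disjoint = np.zeros((10, 10), bool)
    assert hotspot_overlap(a.mask, disjoint) == 0
    with pytest.raises(ValueError):
        hotspot_overlap(a.mask, np.zeros((5, 5), bool))
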