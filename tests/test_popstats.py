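"""Core statistics against brute-force pair-enumeration oracles and
hand-computed worked examples."""

import itertools
import math

import numpy as np
import pytest
import scipy.stats

from balsel import popstats
from conftest import random_haplotype_matrix


# ---------------------------------------------------------------- oracles

def brute_pi_total(mat):
    n = mat.shape[0]
    total = 0
    for i, j in itertools.combinations(range(n), 2):
        total += int((mat[i] != mat[j]).sum())
    return total / (n * (n - 1) / 2)


def brute_fst(g1, g2):
    hw_site, hb_site = [], []
    for s in range(g1.shape[1]):
        w1 = [int(a != b) for a, b in itertools.combinations(g1[:, s], 2)]
        w2 = [int(a != b) for a, b in itertools.combinations(g2[:, s], 2)]
        hb = [int(a != b) for a in g1[:, s] for b in g2[:, s]]
        hw_site.append((np.mean(w1) + np.mean(w2)) / 2)
        hb_site.append(np.mean(hb))
    hw_site, hb_site = np.array(hw_site), np.array(hb_site)
    keep = hb_site > 0
    return 1 - hw_site[keep].mean() / hb_site[keep].mean()


def brute_mean_r2(mat, maf_min=0.05):
    p = mat.mean(axis=0)
    keep = np.minimum(p, 1 - p) >= maf_min
    cols = np.where(keep)[0]
    vals = []
    for a, b in itertools.combinations(cols, 2):
        pa, pb = mat[:, a].mean(), mat[:, b].mean()
        pab = (mat[:, a] * mat[:, b]).mean()
        d = pab - pa * pb
        vals.append(d**2 / (pa * (1 - pa) * pb * (1 - pb)))
    return np.mean(vals), len(vals)


def oracle_tajimas_d(mat):
    """Independent implementation of the 1989 constants, straight from the
    published formulas (kept separate from the package's code path)."""
    n, _ = mat.shape
    counts = mat.sum(axis=0)
    counts = counts[(counts > 0) & (counts < n)]
    S = len(counts)
    if S == 0:
        return math.nan
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1 * a1 + a2)
    pi = sum(c * (n - c) for c in counts) / (n * (n - 1) / 2)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


# ------------------------------------------------------------ diversity

def test_pi_three_haplotypes_worked_example():
    m = np.array([[0, 0], [0, 1], [1, 1]], dtype=np.int8)
    res = popstats.nucleotide_diversity(m)
    assert res.pi_total == pytest.approx(4 / 3)


def test_pi_identical_haplotypes_is_zero():
    m = np.tile(np.array([[0, 1, 1, 0]], dtype=np.int8), (6, 1))
    assert popstats.nucleotide_diversity(m).pi_total == 0.0


def test_pi_matches_bruteforce_on_random_matrices(rng):
    for _ in range(25):
        m = random_haplotype_matrix(rng)
        assert popstats.nucleotide_diversity(m).pi_total == pytest.approx(
            brute_pi_total(m), abs=1e-12
        )


def test_pi_requires_two_haplotypes():
    with pytest.raises(ValueError):
        popstats.nucleotide_diversity(np.array([[0, 1]], dtype=np.int8))


@pytest.mark.parametrize(
    "S,n,expected",
    [
        (5, 10, 5 / sum(1 / j for j in range(1, 10))),
        (0, 10, 0.0),
        (7, 2, 7.0),  # a_1 = 1
    ],
)
def test_watterson_theta(S, n, expected):
    assert popstats.watterson_theta(S, n) == pytest.approx(expected)


def test_watterson_theta_rejects_n_below_two():
    with pytest.raises(ValueError):
        popstats.watterson_theta(3, 1)


# ------------------------------------------------------------ Tajima's D

def test_tajimas_d_three_singletons_worked_example():
    m = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [0, 0, 0]], dtype=np.int8)
    res = popstats.tajimas_d(m)
    assert res.defined
    assert res.D == pytest.approx(-0.7544, abs=5e-4)
    assert res.D == pytest.approx(oracle_tajimas_d(m), abs=1e-12)


def test_tajimas_d_undefined_without_segregating_sites():
    m = np.zeros((4, 3), dtype=np.int8)
    res = popstats.tajimas_d(m)
    assert not res.defined and math.isnan(res.D)


def test_tajimas_d_matches_oracle_and_allele_relabel_invariance(rng):
    for _ in range(20):
        m = random_haplotype_matrix(rng)
        d = popstats.tajimas_d(m).D
        assert d == pytest.approx(oracle_tajimas_d(m), abs=1e-12)
        flip = rng.integers(0, 2, size=m.shape[1]).astype(bool)
        m2 = m.copy()
        m2[:, flip] = 1 - m2[:, flip]
        assert popstats.tajimas_d(m2).D == pytest.approx(d, abs=1e-12)


def test_tajima_p_center_and_extreme_of_null():
    p_center = popstats.tajima_p_by_simulation(0.0, 20, 10, reps=1000, seed=7)
    assert p_center >= 0.9
    p_extreme = popstats.tajima_p_by_simulation(10.0, 20, 10, reps=1000, seed=7)
    assert p_extreme == pytest.approx(1 / 1001)


def test_tajima_p_large_positive_D_is_significant():
    p = popstats.tajima_p_by_simulation(2.5, 20, 30, reps=10_000, seed=11)
    assert p < 0.05


def test_tajima_p_rejects_too_few_reps():
    with pytest.raises(ValueError):
        popstats.tajima_p_by_simulation(0.0, 10, 5, reps=50)


# ------------------------------------------------------------------ F_ST

def test_fst_fixed_difference_is_one():
    g1 = np.ones((4, 1), dtype=np.int8)
    g2 = np.zeros((4, 1), dtype=np.int8)
    assert popstats.hudson_fst_from_groups(g1, g2).region_fst == pytest.approx(1.0)


def test_fst_identical_frequencies_near_zero():
    # with equal sample frequencies the estimate is -1/(n-1) from the
    # unbiased within-population correction; it vanishes as n grows
    n = 40
    g = np.array([[1]] * (n // 2) + [[0]] * (n // 2), dtype=np.int8)
    fst = popstats.hudson_fst_from_groups(g, g.copy()).region_fst
    assert fst == pytest.approx(0.0, abs=2 / (n - 1))


def test_fst_single_site_worked_example():
    g1 = np.array([[1], [1], [1], [0]], dtype=np.int8)
    g2 = np.zeros((4, 1), dtype=np.int8)
    res = popstats.hudson_fst_from_groups(g1, g2)
    assert res.region_fst == pytest.approx(2 / 3)


def test_fst_matches_bruteforce_and_bounded(rng):
    for _ in range(15):
        g1 = random_haplotype_matrix(rng, n=6)
        g2 = random_haplotype_matrix(rng, n=8)
        res = popstats.hudson_fst_from_groups(g1, g2)
        assert res.region_fst == pytest.approx(brute_fst(g1, g2), abs=1e-12)
        assert res.region_fst <= 1.0
        assert np.nanmax(res.per_site_fst) <= 1.0 + 1e-12


def test_fst_monomorphic_sites_excluded_from_aggregate():
    g1 = np.array([[1, 0], [1, 0], [0, 0]], dtype=np.int8)  # site 2 monomorphic
    g2 = np.array([[0, 0], [0, 0], [0, 0]], dtype=np.int8)
    res = popstats.hudson_fst_from_groups(g1, g2)
    assert math.isnan(res.per_site_fst[1])
    only_site1 = popstats.hudson_fst_from_groups(g1[:, :1], g2[:, :1])
    assert res.region_fst == pytest.approx(only_site1.region_fst)


# -------------------------------------------------------------------- LD

def test_r2_perfectly_correlated_pair():
    m = np.array([[0, 0], [0, 0], [1, 1], [1, 1]], dtype=np.int8)
    r2, n_pairs = popstats.mean_pairwise_r2(m)
    assert r2 == pytest.approx(1.0) and n_pairs == 1


def test_r2_worked_example_one_third():
    m = np.array([[0, 0], [0, 0], [1, 1], [0, 1]], dtype=np.int8)
    r2, _ = popstats.mean_pairwise_r2(m)
    assert r2 == pytest.approx(1 / 3)


def test_r2_equifrequent_gametes_zero():
    m = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.int8)
    r2, _ = popstats.mean_pairwise_r2(m)
    assert r2 == pytest.approx(0.0, abs=1e-12)


def test_r2_matches_bruteforce(rng):
    for _ in range(15):
        m = random_haplotype_matrix(rng)
        got, n_got = popstats.mean_pairwise_r2(m)
        want, n_want = brute_mean_r2(m)
        assert n_got == n_want
        assert got == pytest.approx(want, abs=1e-10)


def test_r2_undefined_below_two_sites():
    m = np.array([[0], [1], [0], [1]], dtype=np.int8)
    r2, n_pairs = popstats.mean_pairwise_r2(m)
    assert math.isnan(r2) and n_pairs == 0


# ------------------------------------------------- pairwise differences

def test_pairwise_differences_single_vs_set():
    a = np.array([0, 0, 0], dtype=np.int8)
    b = np.array([[0, 1, 0], [0, 1, 1]], dtype=np.int8)
    assert popstats.pairwise_differences(a, b).tolist() == [1, 2]


def test_pairwise_differences_identical_sets_zero_diagonal(rng):
    m = random_haplotype_matrix(rng, n=5)
    d = popstats.pairwise_differences(m, m)
    assert np.all(np.diag(d) == 0)


def test_pairwise_differences_match_bruteforce(rng):
    a = random_haplotype_matrix(rng, n=4)
    b = random_haplotype_matrix(rng, n=6)
    d = popstats.pairwise_differences(a, b)
    for i in range(4):
        for j in range(6):
            assert d[i, j] == int((a[i] != b[j]).sum())


def test_pairwise_differences_site_mismatch_raises(rng):
    with pytest.raises(ValueError):
        popstats.pairwise_differences(
            random_haplotype_matrix(rng, n=3, n_sites=5),
            random_haplotype_matrix(rng, n=3, n_sites=6),
        )


# ------------------------------------------------------------ rank tests

def test_mann_whitney_exact_worked_example():
    u, p = popstats.mann_whitney_u([1, 2], [3, 4])
    assert u == 0
    assert p == pytest.approx(1 / 3)


def test_mann_whitney_identical_samples_p_one():
    u, p = popstats.mann_whitney_u([1, 2, 3], [1, 2, 3])
    assert p == pytest.approx(1.0)


def test_mann_whitney_large_shift_detected(rng):
    x = rng.normal(0, 1, 200)
    y = rng.normal(2, 1, 200)
    _, p = popstats.mann_whitney_u(x, y)
    assert p < 1e-3
    # agrees with the large-sample reference implementation
    ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
    assert p == pytest.approx(ref, rel=1e-6)


def test_mann_whitney_rejects_empty():
    with pytest.raises(ValueError):
        popstats.mann_whitney_u([], [1.0])


def test_spearman_monotone_and_reversed():
    assert popstats.spearman_assoc([0, 1, 2, 0, 1], [1.0, 2.0, 3.0, 1.0, 2.0]).rho == pytest.approx(1.0)
    assert popstats.spearman_assoc([0, 1, 2, 0, 1], [-1.0, -2.0, -3.0, -1.0, -2.0]).rho == pytest.approx(-1.0)


def test_spearman_constant_genotype_flagged():
    res = popstats.spearman_assoc([1] * 10, list(range(10)))
    assert not res.defined and math.isnan(res.rho)


def test_spearman_eqtl_detected_after_bonferroni(rng):
    g = rng.integers(0, 3, size=100)
    e = 1.0 * g + rng.normal(0, 0.5, size=100)
    res = popstats.spearman_assoc(g, e, m_tests=21_800)
    assert res.p_bonferroni < 0.05
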