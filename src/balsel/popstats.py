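"""Per-region population-genetic statistics.

Conventions:

* pi (nucleotide diversity) is the mean Hamming distance over all unordered
  haplotype pairs, summed over sites — no finite-sample n/(n-1) correction.
  ``pi_per_site`` divides by the region length in bases (the spanned
  positions by default), not by the number of SNPs.
* Tajima's D follows the 1989 normalization; its significance is assessed by
  neutral coalescent simulation conditional on the observed number of
  segregating sites.
* F_ST is Hudson's 1 - Hw/Hb, aggregated over sites as a ratio of averages.
* r^2 is computed directly from phased haplotypes (no EM), with a minor
  allele frequency filter (default 0.05).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import scipy.stats

from .coalescent import sim_sfs_counts
from .hapio import HaplotypeMatrix

__all__ = [
    "harmonic_number",
    "DiversityResult",
    "TajimaResult",
    "FstResult",
    "nucleotide_diversity",
    "watterson_theta",
    "tajimas_d",
    "tajima_p_by_simulation",
    "hudson_fst",
    "mean_pairwise_r2",
    "pairwise_differences",
    "mann_whitney_u",
    "spearman_assoc",
]


def harmonic_number(m: int) -> float:
    """a_m = sum_{j=1}^{m} 1/j (a_{n-1} is Watterson's denominator)."""
    return float(sum(1.0 / j for j in range(1, m + 1)))


@dataclass
class DiversityResult:
    pi_per_site: float
    pi_total: float
    S: int
    theta_w: float
    n_haplotypes: int
    a_n: float


@dataclass
class TajimaResult:
    D: float
    defined: bool
    p_two_sided: float | None = None


@dataclass
class FstResult:
    per_site_fst: np.ndarray
    region_fst: float
    populations: tuple[str, str]


def _derived_counts(alleles: np.ndarray) -> np.ndarray:
    return alleles.sum(axis=0).astype(np.int64)


def _pi_total_from_counts(counts: np.ndarray, n: int) -> float:
    """Sum over sites of mean pairwise difference: c(n-c)/C(n,2)."""
    pairs = n * (n - 1) / 2.0
    return float(np.sum(counts * (n - counts)) / pairs)


def nucleotide_diversity(
    m: HaplotypeMatrix | np.ndarray, region_length: int | None = None
) -> DiversityResult:
    """pi, S and Watterson's theta for one region.

    ``region_length`` (bases) sets the per-site normalization; by default the
    span of the matrix positions is used (1 if the matrix carries no
    positions or a single site).
    """
    alleles, positions = _as_alleles(m)
    n = alleles.shape[0]
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    counts = _derived_counts(alleles)
    seg = (counts > 0) & (counts < n)
    S = int(seg.sum())
    pi_total = _pi_total_from_counts(counts[seg], n)
    if region_length is None:
        region_length = (
            int(positions.max() - positions.min() + 1) if len(positions) > 1 else 1
        )
    a_n = harmonic_number(n - 1)
    return DiversityResult(
        pi_per_site=pi_total / region_length,
        pi_total=pi_total,
        S=S,
        theta_w=S / a_n,
        n_haplotypes=n,
        a_n=a_n,
    )


def _as_alleles(m) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(m, HaplotypeMatrix):
        return m.alleles, m.positions
    arr = np.asarray(m, dtype=np.int8)
    return arr, np.arange(1, arr.shape[1] + 1)


def watterson_theta(S: int, n: int) -> float:
    """Watterson's estimator S / a_{n-1} (per region)."""
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    if S < 0:
        raise ValueError("S must be >= 0")
    return S / harmonic_number(n - 1)


def _tajima_constants(n: int) -> tuple[float, float]:
    """(e1, e2) of Tajima (1989) for sample size n."""
    a1 = harmonic_number(n - 1)
    a2 = float(sum(1.0 / j**2 for j in range(1, n)))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return e1, e2


def _tajimas_d_from_counts(counts: np.ndarray, n: int) -> float:
    counts = counts[(counts > 0) & (counts < n)]
    S = len(counts)
    if S == 0:
        return math.nan
    e1, e2 = _tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return math.nan
    pi = _pi_total_from_counts(counts, n)
    theta_w = S / harmonic_number(n - 1)
    return (pi - theta_w) / math.sqrt(var)


def tajimas_d(m: HaplotypeMatrix | np.ndarray) -> TajimaResult:
    """Tajima's D; undefined (NaN, defined=False) when S = 0."""
    alleles, _ = _as_alleles(m)
    n = alleles.shape[0]
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    d = _tajimas_d_from_counts(_derived_counts(alleles), n)
    return TajimaResult(D=d, defined=not math.isnan(d))


def tajima_p_by_simulation(
    D_obs: float, n: int, S: int, reps: int = 10_000, seed: int | None = None
) -> float:
    """Two-sided coalescent-simulation p-value for Tajima's D.

    Neutral genealogies for ``n`` tips carry exactly ``S`` mutations placed
    multinomially along branches (conditional on S); the add-one convention
    keeps p in (0, 1].
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(reps):
        counts = sim_sfs_counts(n, rng, S=S)
        d = _tajimas_d_from_counts(counts, n)
        if not math.isnan(d) and abs(d) >= abs(D_obs) - 1e-12:
            hits += 1
    return (1 + hits) / (1 + reps)


def hudson_fst(
    m: HaplotypeMatrix, pops: tuple[str, str]
) -> FstResult:
    """Hudson's F_ST = 1 - Hw/Hb between two populations.

    Hw is the average of the two within-population mean pairwise differences
    at a site, Hb the mean between-population pairwise difference.  Sites
    with Hb = 0 have undefined per-site values (NaN) and are excluded from
    the region ratio-of-averages aggregate.
    """
    rows1 = m.haplotype_rows_for_population(pops[0])
    rows2 = m.haplotype_rows_for_population(pops[1])
    return hudson_fst_from_groups(m.alleles[rows1], m.alleles[rows2], pops)


def hudson_fst_from_groups(
    g1: np.ndarray, g2: np.ndarray, pops: tuple[str, str] = ("pop1", "pop2")
) -> FstResult:
    n1, n2 = g1.shape[0], g2.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("both populations need >= 2 haplotypes")
    c1 = g1.sum(axis=0).astype(float)
    c2 = g2.sum(axis=0).astype(float)
    p1, p2 = c1 / n1, c2 / n2
    h1 = c1 * (n1 - c1) / (n1 * (n1 - 1) / 2.0)
    h2 = c2 * (n2 - c2) / (n2 * (n2 - 1) / 2.0)
    hw = (h1 + h2) / 2.0
    hb = p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_site = np.where(hb > 0, 1.0 - hw / np.where(hb > 0, hb, 1.0), np.nan)
    defined = hb > 0
    region = float(1.0 - hw[defined].mean() / hb[defined].mean()) if defined.any() else math.nan
    return FstResult(per_site_fst=per_site, region_fst=region, populations=tuple(pops))


def mean_pairwise_r2(
    m: HaplotypeMatrix | np.ndarray, maf_min: float = 0.05
) -> tuple[float, int]:
    """Mean pairwise LD r^2 over all SNP pairs passing the MAF filter.

    r^2 = D^2 / (pA qA pB qB) computed from phased haplotype frequencies,
    which equals the squared Pearson correlation of the two 0/1 site columns.
    Returns (mean r^2, number of pairs); (nan, 0) when fewer than two sites
    qualify.
    """
    alleles, _ = _as_alleles(m)
    n = alleles.shape[0]
    p = alleles.mean(axis=0)
    maf = np.minimum(p, 1 - p)
    keep = maf >= maf_min
    if keep.sum() < 2:
        return math.nan, 0
    x = alleles[:, keep].astype(float)
    corr = np.corrcoef(x, rowvar=False)
    iu = np.triu_indices(corr.shape[0], k=1)
    r2 = corr[iu] ** 2
    return float(np.mean(r2)), len(r2)


def pairwise_differences(a, b) -> np.ndarray:
    """Hamming distances between haplotype sets over an identical site set.

    ``a`` may be a single haplotype (1-D) — one distance per row of ``b`` —
    or a matrix — the full cross-distance matrix.  When ``a is b``, callers
    usually want the upper-triangle (use :func:`within_pairwise_differences`).
    """
    single = False
    if isinstance(a, HaplotypeMatrix):
        A = a.alleles
    else:
        A = np.asarray(a, dtype=np.int8)
        if A.ndim == 1:
            A = A[None, :]
            single = True
    B, _ = _as_alleles(b)
    if A.shape[1] != B.shape[1]:
        raise ValueError("site sets differ between the two haplotype sets")
    d = (A[:, None, :] != B[None, :, :]).sum(axis=2)
    return d[0] if single else d


def within_pairwise_differences(m) -> np.ndarray:
    """All unordered within-set pairwise Hamming distances."""
    A, _ = _as_alleles(m)
    d = (A[:, None, :] != A[None, :, :]).sum(axis=2)
    iu = np.triu_indices(A.shape[0], k=1)
    return d[iu]


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U with exact enumeration for small samples.

    For n_x + n_y <= 12 the two-sided p-value is computed by enumerating all
    labelings (midranks for ties); otherwise the tie-corrected normal
    approximation with continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    u_obs = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)
    if nx + ny <= 12:
        mu = nx * ny / 2.0
        dev_obs = abs(u_obs - mu)
        hits = total = 0
        for idx in itertools.combinations(range(nx + ny), nx):
            u = ranks[list(idx)].sum() - nx * (nx + 1) / 2.0
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
        return u_obs, hits / total
    if np.ptp(pooled) == 0:
        return u_obs, 1.0
    res = scipy.stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


@dataclass
class SpearmanResult:
    rho: float
    p: float
    p_bonferroni: float
    defined: bool


def spearman_assoc(genotype, expression, m_tests: int = 1) -> SpearmanResult:
    """Spearman rank association of allele dosage (0/1/2) with expression.

    Ties get average ranks; p comes from the t approximation; Bonferroni
    multiplies by the number of tests.  A constant genotype vector yields an
    undefined (flagged) result rather than an error.
    """
    g = np.asarray(genotype, dtype=float)
    e = np.asarray(expression, dtype=float)
    if len(g) < 5:
        raise ValueError("need at least 5 samples")
    if np.ptp(g) == 0:
        return SpearmanResult(math.nan, math.nan, math.nan, defined=False)
    rho, p = scipy.stats.spearmanr(g, e)
    return SpearmanResult(
        rho=float(rho), p=float(p), p_bonferroni=min(1.0, m_tests * float(p)),
        defined=True,
    )
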