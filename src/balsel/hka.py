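"""Maximum-likelihood HKA test for balancing selection.

Multilocus Poisson model: for locus i with length L_i, sample size n (shared
across loci), scaled mutation parameter theta_i, species divergence time T
(coalescent units) and selection parameter k_i (fixed to 1 for neutral loci):

    S_i ~ Poisson(k_i * theta_i * L_i * a_n),   a_n = sum_{j=1}^{n-1} 1/j
    D_i ~ Poisson(theta_i * L_i * (T + k_i))

A selection parameter k_i > 1 inflates within-species polymorphism and, by
deepening within-locus coalescence, adds ancestral polymorphism to the
divergence mean — the signature of long-term balancing selection.  The
neutral model fixes all k_i = 1; a likelihood-ratio test with df equal to the
number of selected loci assesses significance.

theta_i is profiled out analytically (Poisson means are linear in theta_i),
leaving a low-dimensional maximization over T and the free k's, done by
multi-start Nelder-Mead in log-parameter space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .popstats import harmonic_number


@dataclass
class HKADataset:
    """Per-locus segregating sites S, divergence counts D, lengths L, shared n."""

    locus_ids: list[str]
    S: np.ndarray
    D: np.ndarray
    L: np.ndarray
    n: int
    selected: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=np.int64)
        self.D = np.asarray(self.D, dtype=np.int64)
        self.L = np.asarray(self.L, dtype=float)
        k = len(self.locus_ids)
        if not (len(self.S) == len(self.D) == len(self.L) == k):
            raise ValueError("per-locus arrays must match locus_ids length")
        if (self.S < 0).any() or (self.D < 0).any():
            raise ValueError("S and D must be non-negative")
        if (self.L <= 0).any():
            raise ValueError("L must be positive")
        if self.n < 2:
            raise ValueError("n must be >= 2")
        unknown = set(self.selected) - set(self.locus_ids)
        if unknown:
            raise ValueError(f"selected loci not in dataset: {sorted(unknown)}")

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def a_n(self) -> float:
        return harmonic_number(self.n - 1)

    @property
    def selected_idx(self) -> np.ndarray:
        sel = set(self.selected)
        return np.array([i for i, x in enumerate(self.locus_ids) if x in sel], dtype=int)

    @classmethod
    def read_tsv(cls, path, n: int) -> "HKADataset":
        df = pd.read_csv(path, sep="\t")
        return cls(
            locus_ids=list(df["locus_id"].astype(str)),
            S=df["S"].to_numpy(),
            D=df["D"].to_numpy(),
            L=df["L"].to_numpy(),
            n=n,
            selected=list(df.loc[df["is_selected"].astype(bool), "locus_id"].astype(str)),
        )


@dataclass
class HKAFit:
    theta: np.ndarray
    T: float
    k: np.ndarray
    logL: float
    converged: bool


def hka_loglik(data: HKADataset, theta: np.ndarray, T: float, k: np.ndarray) -> float:
    """Poisson log-likelihood (additive constants dropped)."""
    theta = np.asarray(theta, dtype=float)
    k = np.asarray(k, dtype=float)
    lam_s = k * theta * data.L * data.a_n
    lam_d = theta * data.L * (T + k)
    if np.any((lam_s <= 0) & (data.S > 0)) or np.any((lam_d <= 0) & (data.D > 0)):
        return -math.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        ls = np.where(data.S > 0, data.S * np.log(np.maximum(lam_s, 1e-300)), 0.0)
        ld = np.where(data.D > 0, data.D * np.log(np.maximum(lam_d, 1e-300)), 0.0)
    return float(np.sum(ls - lam_s + ld - lam_d))


def _profile_theta(data: HKADataset, T: float, k: np.ndarray) -> np.ndarray:
    """MLE of theta_i given (T, k): Poisson means are linear in theta_i."""
    denom = data.L * (k * data.a_n + T + k)
    return (data.S + data.D) / denom


def _profiled_negloglik(data: HKADataset, T: float, k: np.ndarray) -> float:
    theta = _profile_theta(data, T, k)
    theta = np.maximum(theta, 1e-12)
    return -hka_loglik(data, theta, T, k)


def fit_hka(
    data: HKADataset,
    free_k: list[str] | None = None,
    seed: int | None = None,
    n_starts: int = 4,
    max_cycles: int = 200,
) -> HKAFit:
    """Maximize the HKA likelihood over (theta_i, T, free k's).

    Optimization is a seeded multi-start direct search (Nelder-Mead on
    log-transformed T and k, theta profiled analytically); convergence is
    declared when the likelihood improves by < 1e-8 over a cycle.
    """
    free_k = list(free_k or [])
    unknown = set(free_k) - set(data.locus_ids)
    if unknown:
        raise ValueError(f"free_k loci not in dataset: {sorted(unknown)}")
    if data.n_loci < 2:
        raise ValueError("need at least 2 loci")
    if free_k and len(free_k) >= data.n_loci:
        raise ValueError("at least one locus must remain neutral")
    free_idx = np.array(
        [i for i, x in enumerate(data.locus_ids) if x in set(free_k)], dtype=int
    )
    rng = np.random.default_rng(seed)
    dim = 1 + len(free_idx)

    def unpack(z: np.ndarray) -> tuple[float, np.ndarray]:
        T = math.exp(z[0])
        k = np.ones(data.n_loci)
        if len(free_idx):
            k[free_idx] = np.exp(z[1:])
        return T, k

    def objective(z: np.ndarray) -> float:
        if np.any(np.abs(z) > 30):
            return 1e12
        T, k = unpack(z)
        return _profiled_negloglik(data, T, k)

    # moment-flavoured start: T from pooled D/S ratio, k = 1
    with np.errstate(divide="ignore", invalid="ignore"):
        t0 = max(float(data.D.sum()) / max(float(data.S.sum()), 1.0) * data.a_n - 1.0, 0.1)
    starts = [np.concatenate([[math.log(t0)], np.zeros(len(free_idx))])]
    for _ in range(n_starts - 1):
        starts.append(starts[0] + rng.normal(0, 1.0, size=dim))

    best = None
    for z0 in starts:
        res = scipy.optimize.minimize(
            objective, z0, method="Nelder-Mead",
            options=dict(maxiter=max_cycles * 50, xatol=1e-10, fatol=1e-10),
        )
        if best is None or res.fun < best.fun:
            best = res
    T, k = unpack(best.x)
    theta = np.maximum(_profile_theta(data, T, k), 1e-12)
    logL = hka_loglik(data, theta, T, k)
    return HKAFit(theta=theta, T=T, k=k, logL=logL, converged=bool(best.success))


@dataclass
class HKALrt:
    lrt: float
    df: int
    p: float | None
    fit_neutral: HKAFit
    fit_selection: HKAFit
    converged: bool


def hka_lrt(data: HKADataset, selected: list[str] | None = None, seed: int | None = None) -> HKALrt:
    """Likelihood-ratio test of the selection model against the neutral model.

    LRT = 2(logL_sel - logL_neutral) with chi-square df = number of selected
    loci.  The selection fit is seeded from the neutral optimum (k = 1), so
    model nesting guarantees LRT >= 0.  If either fit fails to converge the
    p-value is withheld (None).
    """
    selected = list(selected if selected is not None else data.selected)
    if not selected:
        raise ValueError("selected set must be non-empty")
    if len(selected) >= data.n_loci:
        raise ValueError("selected must be a proper subset of loci")
    fit0 = fit_hka(data, free_k=[], seed=seed)
    fit1 = fit_hka(data, free_k=selected, seed=seed)
    # nesting guard: the selection model can always reproduce the neutral fit
    if fit1.logL < fit0.logL:
        fit1 = HKAFit(
            theta=fit0.theta, T=fit0.T, k=np.ones(data.n_loci),
            logL=fit0.logL, converged=fit1.converged,
        )
    lrt = max(2.0 * (fit1.logL - fit0.logL), 0.0)
    df = len(selected)
    converged = fit0.converged and fit1.converged
    p = float(scipy.stats.chi2.sf(lrt, df)) if converged else None
    return HKALrt(lrt=lrt, df=df, p=p, fit_neutral=fit0, fit_selection=fit1,
                  converged=converged)


def simulate_hka_dataset(
    n_loci: int,
    theta: float,
    T: float,
    n: int,
    rng: np.random.Generator,
    L: float = 1.0,
    k_selected: float = 1.0,
    selected_idx: int | None = None,
    polymorphism_only: bool = False,
) -> HKADataset:
    """Draw S and D from the model's own Poisson distributions (the
    parametric-bootstrap generator used for LRT calibration and power).

    With ``polymorphism_only`` the selected locus has its polymorphism mean
    inflated by ``k_selected`` while divergence stays neutral — the classic
    excess-polymorphism signature of balancing selection.
    """
    a_n = harmonic_number(n - 1)
    ids = [f"locus{i}" for i in range(n_loci)]
    k = np.ones(n_loci)
    selected = []
    if selected_idx is not None:
        k[selected_idx] = k_selected
        selected = [ids[selected_idx]]
    S = rng.poisson(k * theta * L * a_n)
    k_div = np.ones(n_loci) if polymorphism_only else k
    D = rng.poisson(theta * L * (T + k_div))
    return HKADataset(
        locus_ids=ids, S=S, D=D, L=np.full(n_loci, L), n=n, selected=selected
    )


def divergence_to_outgroup(alleles: np.ndarray, outgroup: np.ndarray) -> int:
    """Divergence count: differences between the focal-sample consensus
    (majority allele per site, ties broken to REF = 0) and a single outgroup
    sequence."""
    alleles = np.asarray(alleles)
    outgroup = np.asarray(outgroup)
    if alleles.shape[1] != len(outgroup):
        raise ValueError("outgroup must cover the same sites")
    consensus = (2 * alleles.sum(axis=0) > alleles.shape[0]).astype(np.int8)
    return int(np.sum(consensus != outgroup))


def fit_table(data: HKADataset, fit: HKAFit) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "locus_id": data.locus_ids,
            "L": data.L,
            "S": data.S,
            "D": data.D,
            "theta_hat": fit.theta,
            "k_hat": fit.k,
        }
    )
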