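"""Neutral Kingman coalescent with infinite-sites mutations.

Time is measured in units of 2N generations; a lineage pair coalesces at rate
1 (divided by an optional effective-size scale).  Mutations fall on branches
as a Poisson process of rate theta/2 per unit time, or, for null distributions
conditioned on the observed number of segregating sites, a fixed number of
mutations is placed multinomially with probabilities proportional to branch
length (the convention of standard coalescent-simulation significance tests
for Tajima's D).

This module is the generative core shared by the synthetic-data generator and
the simulation-based p-values; it deliberately stays minimal (no
recombination, no migration) — windows are treated as independent,
non-recombining blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Lineage:
    """An active lineage: the set of sample tips it subtends and its birth time."""

    tips: np.ndarray  # boolean mask over samples
    birth: float


@dataclass
class BranchSet:
    """Completed branches of (part of) a genealogy."""

    masks: list[np.ndarray] = field(default_factory=list)
    lengths: list[float] = field(default_factory=list)

    def add(self, mask: np.ndarray, length: float) -> None:
        if length > 0:
            self.masks.append(mask)
            self.lengths.append(length)

    def extend(self, other: "BranchSet") -> None:
        self.masks.extend(other.masks)
        self.lengths.extend(other.lengths)

    @property
    def total_length(self) -> float:
        return float(sum(self.lengths))


def _pick_pair(k: int, rng: np.random.Generator) -> tuple[int, int]:
    i = int(rng.integers(k))
    j = int(rng.integers(k - 1))
    if j >= i:
        j += 1
    return i, j


def coalesce(
    lineages: list[Lineage],
    rng: np.random.Generator,
    t_start: float = 0.0,
    t_stop: float = np.inf,
    scale: float = 1.0,
) -> tuple[list[Lineage], BranchSet, float]:
    """Run the coalescent on ``lineages`` from ``t_start`` until a single
    lineage remains or ``t_stop`` is reached.

    ``scale`` multiplies the effective size (pairwise coalescence rate is
    ``1/scale``), so a clade restricted to a fraction ``p`` of the population
    coalesces on scale ``p``.

    Returns the surviving lineages, the completed branches, and the time at
    which the process stopped.
    """
    t = t_start
    branches = BranchSet()
    lineages = list(lineages)
    while len(lineages) > 1:
        k = len(lineages)
        rate = k * (k - 1) / 2.0 / scale
        t_next = t + rng.exponential(1.0 / rate)
        if t_next >= t_stop:
            t = t_stop
            break
        t = t_next
        i, j = _pick_pair(k, rng)
        a, b = lineages[i], lineages[j]
        branches.add(a.tips, t - a.birth)
        branches.add(b.tips, t - b.birth)
        merged = Lineage(a.tips | b.tips, t)
        lineages = [lin for idx, lin in enumerate(lineages) if idx not in (i, j)]
        lineages.append(merged)
    return lineages, branches, t


def close_stems(lineages: list[Lineage], branches: BranchSet, t_end: float) -> None:
    """Terminate surviving lineages at ``t_end``, recording their stem branches."""
    for lin in lineages:
        branches.add(lin.tips, t_end - lin.birth)


def sim_genealogy(
    n: int, rng: np.random.Generator, scale: float = 1.0
) -> tuple[BranchSet, float]:
    """Full genealogy of ``n`` tips; returns branches and the TMRCA."""
    if n < 2:
        raise ValueError("need at least 2 tips")
    eye = np.eye(n, dtype=bool)
    lineages = [Lineage(eye[i], 0.0) for i in range(n)]
    _, branches, tmrca = coalesce(lineages, rng, scale=scale)
    return branches, tmrca

def _sfs_branches(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Branch (descendant count, length) pairs without tip bookkeeping.

    Cheaper than :func:`sim_genealogy` when only the site-frequency spectrum
    is needed (Tajima-D null distributions, calibration suites).
    """
    counts = [1] * n
    births = [0.0] * n
    out_counts: list[int] = []
    out_lengths: list[float] = []
    t = 0.0
    k = n
    while k > 1:
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = _pick_pair(k, rng)
        out_counts.append(counts[i])
        out_lengths.append(t - births[i])
        out_counts.append(counts[j])
        out_lengths.append(t - births[j])
        merged_count = counts[i] + counts[j]
        for idx in sorted((i, j), reverse=True):
            del counts[idx]
            del births[idx]
        counts.append(merged_count)
        births.append(t)
        k -= 1
    return np.asarray(out_counts), np.asarray(out_lengths)


def sim_sfs_counts(
    n: int,
    rng: np.random.Generator,
    theta: float | None = None,
    S: int | None = None,
) -> np.ndarray:
    """Derived-allele counts (one per segregating site) for one neutral genealogy.

    Exactly one of ``theta`` (Poisson mutations, rate theta/2 per unit branch
    length) or ``S`` (place exactly S mutations, probabilities proportional to
    branch length) must be given.  Counts exclude fixed classes 0 and n by
    construction.
    """
    if (theta is None) == (S is None):
        raise ValueError("give exactly one of theta or S")
    counts, lengths = _sfs_branches(n, rng)
    if theta is not None:
        if theta < 0:
            raise ValueError("theta must be >= 0")
        muts = rng.poisson(theta / 2.0 * lengths)
    else:
        total = lengths.sum()
        muts = rng.multinomial(int(S), lengths / total)
    return np.repeat(counts, muts)


def mutations_on_branches(
    branches: BranchSet, theta: float, rng: np.random.Generator
) -> np.ndarray:
    """Infinite-sites mutation matrix (haplotypes x sites) from a branch set.

    Column order is arbitrary (callers sort by assigned positions).
    """
    n = len(branches.masks[0]) if branches.masks else 0
    cols = []
    for mask, length in zip(branches.masks, branches.lengths):
        for _ in range(rng.poisson(theta / 2.0 * length)):
            cols.append(mask.astype(np.int8))
    if not cols:
        return np.zeros((n, 0), dtype=np.int8)
    return np.column_stack(cols)


def assign_positions(
    n_sites: int, interval_start: int, interval_end: int, rng: np.random.Generator
) -> np.ndarray:
    """Distinct, sorted 1-based positions drawn uniformly on an interval."""
    span = interval_end - interval_start + 1
    if n_sites > span:
        raise ValueError("more sites than bases in interval")
    offs = rng.choice(span, size=n_sites, replace=False)
    return np.sort(offs) + interval_start
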