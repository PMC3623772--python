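"""Genome-scale window machinery: tiling, per-window statistics, empirical
outlier p-values against the genome-wide background, stratified comparisons,
the four-statistic "quadrant" filter and inter-statistic correlations.

Empirical p-values use the add-one convention, p = (1 + #{extreme}) / (1 + N),
so p is never 0 and the smallest attainable value from N background windows is
1/(N+1).  Windows whose statistic is undefined (e.g. Tajima's D with S = 0)
are excluded from null distributions, never treated as zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from . import popstats
from .hapio import GenomicInterval, HaplotypeMatrix, extract_region

SCAN_COLUMNS = [
    "contig", "start", "end", "n", "S", "pi_total", "pi_per_site",
    "theta_w", "tajima_D", "tajima_p", "fst", "mean_r2", "pair_count",
]


def make_windows(
    contig_lengths: dict[str, int], size: int, step: int | None = None
) -> list[GenomicInterval]:
    """Tile contigs with 1-based inclusive windows; the last window truncates.

    ``step == size`` (default) gives a non-overlapping tiling whose coverage
    sums exactly to the contig length.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    step = size if step is None else step
    if step < 1:
        raise ValueError("step must be >= 1")
    windows = []
    for contig, length in contig_lengths.items():
        start = 1
        while start <= length:
            windows.append(GenomicInterval(contig, start, min(start + size - 1, length)))
            start += step
    return windows


@dataclass
class ScanConfig:
    """Configuration of a window scan."""

    population_pair: tuple[str, str] | None = None  # F_ST populations
    focal_population: str | None = None  # None = all haplotypes pooled
    maf_min: float = 0.05
    tajima_p_reps: int = 0  # 0 = skip simulation p-values
    seed: int | None = None


def window_scan(
    m: HaplotypeMatrix,
    windows: list[GenomicInterval],
    config: ScanConfig | None = None,
) -> pd.DataFrame:
    """One row of statistics per window (a WindowStats table).

    pi, S, Tajima's D and mean r^2 are computed on the focal population (all
    haplotypes when unset); F_ST on the configured population pair.
    Undefined statistics are NaN.
    """
    config = config or ScanConfig()
    if config.focal_population is None:
        focal_rows = np.arange(m.n_haplotypes)
    else:
        focal_rows = m.haplotype_rows_for_population(config.focal_population)
    rows = []
    for iv in windows:
        sub = extract_region(m, iv)
        focal = sub.alleles[focal_rows]
        n = focal.shape[0]
        length = iv.length
        div = popstats.nucleotide_diversity(focal, region_length=length)
        taj = popstats.tajimas_d(focal)
        taj_p = math.nan
        if config.tajima_p_reps and taj.defined:
            taj_p = popstats.tajima_p_by_simulation(
                taj.D, n, div.S, reps=config.tajima_p_reps, seed=config.seed
            )
        fst = math.nan
        if config.population_pair is not None:
            r1 = sub.haplotype_rows_for_population(config.population_pair[0])
            r2 = sub.haplotype_rows_for_population(config.population_pair[1])
            if len(r1) >= 2 and len(r2) >= 2 and sub.n_sites:
                fst = popstats.hudson_fst_from_groups(
                    sub.alleles[r1], sub.alleles[r2], config.population_pair
                ).region_fst
        r2_mean, pair_count = popstats.mean_pairwise_r2(focal, maf_min=config.maf_min)
        rows.append(
            dict(
                contig=iv.contig, start=iv.start, end=iv.end, n=n, S=div.S,
                pi_total=div.pi_total, pi_per_site=div.pi_per_site,
                theta_w=div.theta_w, tajima_D=taj.D, tajima_p=taj_p,
                fst=fst, mean_r2=r2_mean, pair_count=pair_count,
            )
        )
    return pd.DataFrame(rows, columns=SCAN_COLUMNS)


def empirical_pvalue(observed: float, background, tail: str = "upper") -> float:
    """Empirical rank p-value of an observed statistic within a background.

    Non-finite background entries are dropped first; the add-one convention
    bounds p in (0, 1].
    """
    bg = np.asarray(background, dtype=float)
    bg = bg[np.isfinite(bg)]
    if len(bg) == 0:
        raise ValueError("empty background after removing undefined values")
    if not math.isfinite(observed):
        raise ValueError("observed value is not finite")
    if tail == "upper":
        hits = int(np.sum(bg >= observed))
    elif tail == "lower":
        hits = int(np.sum(bg <= observed))
    else:
        raise ValueError(f"tail must be 'upper' or 'lower', got {tail!r}")
    return (1 + hits) / (1 + len(bg))


def stratified_comparison(
    rows: pd.DataFrame,
    observed: float,
    statistic: str,
    predicate,
    tail: str = "upper",
) -> float:
    """Empirical p-value of ``observed`` within the stratum of background
    windows satisfying ``predicate`` (a boolean function of the row table,
    e.g. high-LD windows)."""
    mask = predicate(rows)
    stratum = rows.loc[mask, statistic]
    if len(stratum) == 0:
        raise ValueError(f"empty stratum for predicate {getattr(predicate, '__name__', predicate)!r}")
    return empirical_pvalue(observed, stratum.to_numpy(), tail=tail)


@dataclass
class QuadrantThresholds:
    """The four joint outlier thresholds of the genome-wide filter."""

    pi_per_site: float = 0.002
    mean_r2: float = 0.5
    tajima_D: float = 4.5
    fst: float = 0.2


def quadrant_filter(
    rows: pd.DataFrame, thresholds: QuadrantThresholds | None = None
) -> list[GenomicInterval]:
    """Windows exceeding all four thresholds, merged into maximal runs of
    abutting windows (adjacent qualifying windows denote a single locus)."""
    t = thresholds or QuadrantThresholds()
    ok = (
        (rows["pi_per_site"] > t.pi_per_site)
        & (rows["mean_r2"] > t.mean_r2)
        & (rows["tajima_D"] > t.tajima_D)
        & (rows["fst"] > t.fst)
    )
    qual = rows[ok.fillna(False)].sort_values(["contig", "start"])
    regions: list[GenomicInterval] = []
    for _, row in qual.iterrows():
        if (
            regions
            and regions[-1].contig == row["contig"]
            and row["start"] == regions[-1].end + 1
        ):
            regions[-1] = GenomicInterval(regions[-1].contig, regions[-1].start, int(row["end"]))
        else:
            regions.append(GenomicInterval(str(row["contig"]), int(row["start"]), int(row["end"])))
    return regions


def stat_correlation(
    rows: pd.DataFrame, stat_a: str, stat_b: str
) -> tuple[float, float]:
    """Pearson correlation between two window statistics over windows where
    both are defined; p from the t distribution."""
    sub = rows[[stat_a, stat_b]].dropna()
    if len(sub) < 10:
        raise ValueError(f"need >= 10 windows with both {stat_a} and {stat_b} defined")
    r, p = scipy.stats.pearsonr(sub[stat_a], sub[stat_b])
    return float(r), float(p)
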