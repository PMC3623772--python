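"""Coalescent synthetic-data generator for the ancient-substructure locus.

Generates every input the pipeline consumes, with the statistical structure
the analysis assumes:

* neutral background windows (standard coalescent, infinite sites, no
  intra-window recombination, windows independent);
* a substructure locus where two deeply diverged haplogroups (NE1-like and
  nonNE1-like) coalesce internally, join at ``t_split`` (units of 2N
  generations), and differ by clade-fixed stem mutations plus a planted
  panel of tag SNPs in perfect LD with clade membership;
* a deletion allele carried by every derived-haplogroup haplotype;
* an archaic haplotype drawn from the derived clade's stem (the clade root
  consensus);
* expression values linearly coupled to genotype dosage, and per-base read
  depth profiles for deletion genotyping.

Haplogroup frequencies per population are hit exactly by label assignment
(controlled conditions for power analyses), not by drift.  Within-clade
coalescence runs on an effective-size scale equal to the clade's pooled
frequency by default, as for an allelic class maintained at that frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coalescent as coal
from .archaic import DepthProfile
from .hapio import (
    GenomicInterval,
    HaplotypeMatrix,
    PopulationPanel,
    write_bed,
    write_fasta,
    write_phased_vcf,
    write_population_panel,
)
from .haplogroups import NE1, NON_NE1, TagSnpPanel

# the locus analog reuses the printed hg18 geometry of the real block
LOCUS_INTERVAL = GenomicInterval("chr22", 37_600_063, 37_636_026)
DELETION_INTERVAL = GenomicInterval("chr22", 37_624_055, 37_628_634)


@dataclass
class SubstructureConfig:
    """Study conditions for the two-haplogroup locus.

    ``n_per_pop`` counts haplotypes (2 per diploid sample; keep it even).
    ``ne1_freq`` are exact per-population frequencies of the derived
    haplogroup; ``freq * n`` must be an integer.  ``t_split`` is the
    haplogroup divergence in units of 2N generations; ``theta_locus`` the
    scaled mutation rate of the whole locus.  ``pop_time_scale`` optionally
    deepens/shallows within-clade coalescence per population (e.g. a deep
    African and shallow European derived clade).
    """

    n_per_pop: dict[str, int] = field(default_factory=lambda: {"AFR": 100, "EUR": 100})
    ne1_freq: dict[str, float] = field(default_factory=lambda: {"AFR": 0.2, "EUR": 0.5})
    t_split: float = 8.0
    theta_locus: float = 36.0
    locus_interval: GenomicInterval = LOCUS_INTERVAL
    deletion_interval: GenomicInterval = DELETION_INTERVAL
    n_tag_snps: int = 12
    archaic_from: str = NE1
    clade_scale: dict[str, float] | None = None  # default: pooled clade frequency
    pop_time_scale: dict[str, float] | None = None
    seed: int | None = None

    def ne1_counts(self) -> dict[str, int]:
        counts = {}
        for pop, n in self.n_per_pop.items():
            f = self.ne1_freq.get(pop, 0.0)
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency {f} for {pop} outside [0,1]")
            c = f * n
            if abs(c - round(c)) > 1e-9:
                raise ValueError(
                    f"NE1 frequency {f} x {n} haplotypes in {pop} is not an integer count"
                )
            counts[pop] = int(round(c))
        return counts


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a simulated locus."""

    clade_of: np.ndarray  # per haplotype row: NE1 / nonNE1
    tag_positions: np.ndarray
    deletion_carriers: np.ndarray  # boolean per haplotype row
    archaic: np.ndarray  # 0/1 over matrix sites
    tmrca_ne1: float
    tmrca_non_ne1: float
    t_split: float
    deletion_interval: GenomicInterval

    def tag_panel(self) -> TagSnpPanel:
        k = len(self.tag_positions)
        return TagSnpPanel(
            snp_ids=[f"tag{i+1}" for i in range(k)],
            positions=self.tag_positions,
            consensus_ne1=np.ones(k, dtype=np.int8),
            consensus_non_ne1=np.zeros(k, dtype=np.int8),
        )

    def deletion_dosage(self) -> np.ndarray:
        """Deletion copies (0/1/2) per diploid sample."""
        c = self.deletion_carriers.astype(int)
        return c[0::2] + c[1::2]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "haplotype_row": np.arange(len(self.clade_of)),
                "clade": self.clade_of,
                "deletion": self.deletion_carriers.astype(int),
            }
        )


def _clade_genealogy(
    members: dict[str, list[int]],
    n_total: int,
    scale: float,
    pop_time_scale: dict[str, float] | None,
    t_split: float,
    rng: np.random.Generator,
) -> tuple[coal.BranchSet, float, np.ndarray, float]:
    """Coalesce one clade's members, return (branches incl. the stem up to
    t_split, clade TMRCA, clade-root tip mask, stem length)."""
    eye = np.eye(n_total, dtype=bool)
    branches = coal.BranchSet()
    if pop_time_scale is None:
        lineages = [coal.Lineage(eye[i], 0.0) for ms in members.values() for i in ms]
        lineages, br, t = coal.coalesce(lineages, rng, t_stop=t_split, scale=scale)
        branches.extend(br)
    else:
        # per-population subclades, then their roots join at the clade scale
        roots = []
        t_join = 0.0
        for pop, ms in members.items():
            s = scale * pop_time_scale.get(pop, 1.0)
            lins = [coal.Lineage(eye[i], 0.0) for i in ms]
            lins, br, t_pop = coal.coalesce(lins, rng, t_stop=t_split, scale=s)
            branches.extend(br)
            roots.extend(lins)
            t_join = max(t_join, t_pop)
        for lin in roots:  # carry subclade roots up to the joint start
            branches.add(lin.tips, t_join - lin.birth)
        lineages = [coal.Lineage(lin.tips, t_join) for lin in roots]
        if len(lineages) > 1:
            lineages, br, t = coal.coalesce(
                lineages, rng, t_start=t_join, t_stop=t_split, scale=scale
            )
            branches.extend(br)
        else:
            t = t_join
    if len(lineages) > 1:  # did not fully coalesce by t_split: star-join there
        coal.close_stems(lineages, branches, t_split)
        tmrca = t_split
        stem_len = 0.0
    else:
        tmrca = lineages[0].birth
        stem_len = t_split - tmrca
    mask = np.zeros(n_total, dtype=bool)
    for ms in members.values():
        mask[ms] = True
    return branches, tmrca, mask, stem_len


def simulate_substructure_locus(
    cfg: SubstructureConfig, rng: np.random.Generator | None = None
) -> tuple[HaplotypeMatrix, SyntheticTruth]:
    """Simulate the two-haplogroup locus; see the module docstring.

    Haplotype rows are ordered population by population, with NE1/nonNE1
    membership shuffled into random diploid pairings within each population.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    counts = cfg.ne1_counts()
    pops = list(cfg.n_per_pop)
    n_total = int(sum(cfg.n_per_pop.values()))

    clade_of = np.empty(n_total, dtype=object)
    members: dict[str, dict[str, list[int]]] = {NE1: {}, NON_NE1: {}}
    row = 0
    sample_ids: list[str] = []
    population_of: dict[str, str] = {}
    for pop in pops:
        n = cfg.n_per_pop[pop]
        if n % 2:
            raise ValueError(f"{pop}: haplotype count {n} must be even (diploids)")
        labels = np.array([NE1] * counts[pop] + [NON_NE1] * (n - counts[pop]))
        rng.shuffle(labels)  # random pairing into diploid samples
        for j in range(n):
            clade_of[row + j] = labels[j]
            members[labels[j]].setdefault(pop, []).append(row + j)
        for s in range(n // 2):
            sid = f"{pop}_{s:04d}"
            sample_ids.append(sid)
            population_of[sid] = pop
        row += n

    pooled = {
        NE1: sum(counts.values()) / n_total,
        NON_NE1: 1.0 - sum(counts.values()) / n_total,
    }
    scales = cfg.clade_scale or {c: max(pooled[c], 1e-6) for c in (NE1, NON_NE1)}

    all_branches = coal.BranchSet()
    tmrca = {}
    for clade in (NE1, NON_NE1):
        if not members[clade]:
            tmrca[clade] = np.nan
            continue
        idx_lists = members[clade]
        total_members = sum(len(v) for v in idx_lists.values())
        if total_members == 1:
            # a single haplotype: its branch is the full stem
            mask = np.zeros(n_total, dtype=bool)
            mask[[i for v in idx_lists.values() for i in v][0]] = True
            all_branches.add(mask, cfg.t_split)
            tmrca[clade] = 0.0
            stem_mask, stem_len = mask, 0.0
        else:
            branches, t_c, stem_mask, stem_len = _clade_genealogy(
                idx_lists, n_total, scales[clade], cfg.pop_time_scale, cfg.t_split, rng
            )
            all_branches.extend(branches)
            all_branches.add(stem_mask, stem_len)  # clade-fixed stem mutations
            tmrca[clade] = t_c

    alleles = coal.mutations_on_branches(all_branches, cfg.theta_locus, rng)

    # planted tag SNPs: exact clade-fixed differences on the derived clade
    ne1_mask = np.array([c == NE1 for c in clade_of])
    if cfg.n_tag_snps < 1:
        raise ValueError("n_tag_snps must be >= 1")
    tag_cols = np.tile(ne1_mask.astype(np.int8)[:, None], (1, cfg.n_tag_snps))
    alleles = np.column_stack([alleles, tag_cols]) if alleles.size else tag_cols

    # uniform positions, assigned to columns in random order so the tag SNPs
    # scatter across the locus like the rest
    n_sites = alleles.shape[1]
    sorted_pos = coal.assign_positions(
        n_sites, cfg.locus_interval.start, cfg.locus_interval.end, rng
    )
    col_pos = np.empty(n_sites, dtype=np.int64)
    col_pos[rng.permutation(n_sites)] = sorted_pos
    tag_positions = col_pos[-cfg.n_tag_snps:].copy()

    # archaic consensus: the derived clade's root haplotype over these sites
    # (carries the clade-fixed stem + tag alleles, ancestral elsewhere)
    arch_clade_mask = np.array([c == cfg.archaic_from for c in clade_of])
    archaic = (alleles[arch_clade_mask].min(axis=0) > 0).astype(np.int8)

    order = np.argsort(col_pos, kind="stable")
    m = HaplotypeMatrix(
        alleles=alleles[:, order],
        positions=col_pos[order],
        contig=cfg.locus_interval.contig,
        sample_ids=sample_ids,
        population_of=population_of,
    )
    archaic = archaic[order]

    truth = SyntheticTruth(
        clade_of=np.asarray(clade_of),
        tag_positions=np.sort(tag_positions),
        deletion_carriers=ne1_mask.copy(),
        archaic=archaic,
        tmrca_ne1=tmrca.get(NE1, np.nan),
        tmrca_non_ne1=tmrca.get(NON_NE1, np.nan),
        t_split=cfg.t_split,
        deletion_interval=cfg.deletion_interval,
    )
    return m, truth


def simulate_neutral_sample(
    n: int,
    theta: float,
    rng: np.random.Generator | int | None = None,
    interval: GenomicInterval = GenomicInterval("bg", 1, 10_000),
    sample_prefix: str = "S",
    population: str = "POP",
) -> HaplotypeMatrix:
    """One neutral coalescent sample (Hudson model, infinite sites) as a
    haplotype matrix over ``interval``.  ``n`` must be even (diploids)."""
    if n < 2 or n % 2:
        raise ValueError("n must be an even number >= 2")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    branches, _ = coal.sim_genealogy(n, rng)
    alleles = coal.mutations_on_branches(branches, theta, rng)
    positions = coal.assign_positions(alleles.shape[1], interval.start, interval.end, rng)
    order = np.argsort(positions, kind="stable")
    ids = [f"{sample_prefix}{i:04d}" for i in range(n // 2)]
    return HaplotypeMatrix(
        alleles=alleles[:, order],
        positions=positions[order],
        contig=interval.contig,
        sample_ids=ids,
        population_of={s: population for s in ids},
    )


def simulate_genome_background(
    n_windows: int,
    n: int,
    theta: float,
    rng: np.random.Generator | int | None = None,
    window_size: int = 10_000,
    contig: str = "bg1",
) -> tuple[HaplotypeMatrix, list[GenomicInterval]]:
    """Independent neutral windows tiled on one synthetic contig.

    Returns a single concatenated haplotype matrix plus the window intervals
    (free recombination between windows is implied by their independence).
    """
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    if n < 2 or n % 2:
        raise ValueError("n must be an even number >= 2")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    cols, poss = [], []
    windows = []
    for w in range(n_windows):
        start = 1 + w * window_size
        iv = GenomicInterval(contig, start, start + window_size - 1)
        windows.append(iv)
        branches, _ = coal.sim_genealogy(n, rng)
        alleles = coal.mutations_on_branches(branches, theta, rng)
        if alleles.shape[1]:
            p = coal.assign_positions(alleles.shape[1], iv.start, iv.end, rng)
            order = np.argsort(p, kind="stable")
            cols.append(alleles[:, order])
            poss.append(p[order])
    ids = [f"S{i:04d}" for i in range(n // 2)]
    alleles = np.column_stack(cols) if cols else np.zeros((n, 0), dtype=np.int8)
    positions = np.concatenate(poss) if poss else np.array([], dtype=np.int64)
    m = HaplotypeMatrix(
        alleles=alleles,
        positions=positions,
        contig=contig,
        sample_ids=ids,
        population_of={s: "POP" for s in ids},
    )
    return m, windows


def plant_locus_in_background(
    cfg: SubstructureConfig,
    n_background: int,
    theta_background: float,
    rng: np.random.Generator,
    window_size: int = 10_000,
) -> tuple[HaplotypeMatrix, list[GenomicInterval], GenomicInterval, SyntheticTruth]:
    """A synthetic genome: neutral windows plus the substructure locus in the
    final window (locus geometry rescaled to one window).

    All windows share the same samples and populations as the locus scenario.
    Returns (matrix, all windows, the planted window, truth).
    """
    contig = "synth1"
    locus_win_start = 1 + n_background * window_size
    locus_cfg = SubstructureConfig(
        **{
            **cfg.__dict__,
            "locus_interval": GenomicInterval(
                contig, locus_win_start, locus_win_start + window_size - 1
            ),
            "deletion_interval": GenomicInterval(
                contig,
                locus_win_start + window_size // 2,
                locus_win_start + window_size // 2 + 4_579,
            ),
        }
    )
    locus_m, truth = simulate_substructure_locus(locus_cfg, rng)
    n = locus_m.n_haplotypes

    cols, poss = [], []
    windows = []
    for w in range(n_background):
        start = 1 + w * window_size
        iv = GenomicInterval(contig, start, start + window_size - 1)
        windows.append(iv)
        branches, _ = coal.sim_genealogy(n, rng)
        alleles = coal.mutations_on_branches(branches, theta_background, rng)
        if alleles.shape[1]:
            p = coal.assign_positions(alleles.shape[1], iv.start, iv.end, rng)
            order = np.argsort(p, kind="stable")
            cols.append(alleles[:, order])
            poss.append(p[order])
    locus_window = locus_cfg.locus_interval
    windows.append(locus_window)
    cols.append(locus_m.alleles)
    poss.append(locus_m.positions)
    m = HaplotypeMatrix(
        alleles=np.column_stack(cols),
        positions=np.concatenate(poss),
        contig=contig,
        sample_ids=locus_m.sample_ids,
        population_of=locus_m.population_of,
    )
    return m, windows, locus_window, truth


def simulate_expression(
    genotypes,
    beta: float,
    sigma: float,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Expression linearly coupled to dosage: beta * g + N(0, sigma^2)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    g = np.asarray(genotypes, dtype=float)
    return beta * g + rng.normal(0.0, sigma, size=g.shape)


def simulate_depth_profile(
    deletion: GenomicInterval,
    coverage: float,
    zygosity: str,
    rng: np.random.Generator | int | None = None,
    flank: int = 2_000,
) -> DepthProfile:
    """Per-base Poisson read depth across a deletion candidate plus flanks.

    Dose inside the interval is 0 / 0.5 / 1 for hom_del / het_del / no_del;
    1 outside.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    dose_map = {"hom_del": 0.0, "het_del": 0.5, "no_del": 1.0}
    if zygosity not in dose_map:
        raise ValueError(f"zygosity must be one of {sorted(dose_map)}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    positions = np.arange(deletion.start - flank, deletion.end + flank + 1)
    dose = np.ones(len(positions))
    inside = (positions >= deletion.start) & (positions <= deletion.end)
    dose[inside] = dose_map[zygosity]
    depth = rng.poisson(coverage * dose)
    return DepthProfile(positions=positions, depth=depth)


def simulate_reference_with_deletion(
    locus: GenomicInterval,
    deletion: GenomicInterval,
    rng: np.random.Generator | int | None = None,
) -> tuple[str, str]:
    """Random reference sequence over ``locus`` and a sample sequence with
    the deletion interval removed (for breakpoint-mapping exercises)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    seq = "".join(rng.choice(list("ACGT"), size=locus.length))
    s = deletion.start - locus.start
    e = deletion.end - locus.start + 1
    return seq, seq[:s] + seq[e:]


def write_scenario(
    outdir,
    m: HaplotypeMatrix,
    truth: SyntheticTruth,
    windows: list[GenomicInterval] | None = None,
) -> dict[str, Path]:
    """Emit the standard file bundle for a simulated scenario: phased VCF,
    population panel, truth table, tag panel, deletion BED."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "haplotypes.vcf",
        "panel": outdir / "panel.tsv",
        "truth": outdir / "truth.tsv",
        "tags": outdir / "tag_panel.tsv",
        "deletion_bed": outdir / "deletion.bed",
    }
    write_phased_vcf(m, paths["vcf"])
    panel = PopulationPanel(
        pd.DataFrame(
            {
                "sample": m.sample_ids,
                "pop": [m.population_of[s] for s in m.sample_ids],
                "super_pop": [m.population_of[s] for s in m.sample_ids],
            }
        )
    )
    write_population_panel(panel, paths["panel"])
    truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    truth.tag_panel().write_tsv(paths["tags"])
    write_bed([truth.deletion_interval], paths["deletion_bed"])
    if windows is not None:
        paths["windows_bed"] = outdir / "windows.bed"
        write_bed(windows, paths["windows_bed"])
    return paths
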