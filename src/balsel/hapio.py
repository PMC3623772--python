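"""Phased-haplotype I/O and the shared data model.

All user-facing genomic coordinates are 1-based inclusive (the convention of
the hg18 coordinates the locus was described in).  BED input/output is 0-based
half-open and converted at the boundary.

Sites with any missing or unphased genotype, indels and multiallelic sites are
dropped at load time and tallied in a :class:`LoadReport`; nothing is imputed.
Allele 0/1 encodes REF/ALT exactly as in the VCF; polarising against an
ancestral state is always an explicit, separate step.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be interpreted; names the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive genomic interval."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    @classmethod
    def from_bed_row(cls, contig: str, bed_start: int, bed_end: int) -> "GenomicInterval":
        """Convert a 0-based half-open BED row to 1-based inclusive."""
        return cls(contig, bed_start + 1, bed_end)

    def to_bed_row(self) -> tuple[str, int, int]:
        return self.contig, self.start - 1, self.end


@dataclass
class LoadReport:
    """Tally of records kept/excluded while reading a VCF."""

    n_records: int = 0
    n_kept: int = 0
    n_multiallelic: int = 0
    n_indel: int = 0
    n_missing_or_unphased: int = 0
    n_outside_region: int = 0
    n_monomorphic: int = 0
    contig_missing: bool = False

    @property
    def n_excluded(self) -> int:
        return self.n_records - self.n_kept


@dataclass
class HaplotypeMatrix:
    """Phased haplotypes x biallelic sites.

    Rows are haplotypes (two per diploid sample, sample order preserved,
    phase 0 before phase 1); columns are sites with strictly increasing
    1-based positions.  Entries are 0 (REF) or 1 (ALT) with no missing data.
    """

    alleles: np.ndarray
    positions: np.ndarray
    contig: str
    sample_ids: list[str]
    population_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if self.alleles.shape[0] != 2 * len(self.sample_ids):
            raise ValueError(
                f"{self.alleles.shape[0]} haplotype rows for "
                f"{len(self.sample_ids)} samples (expected 2 per sample)"
            )
        if self.alleles.shape[1] != len(self.positions):
            raise ValueError("positions length must match number of sites")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        bad = (self.alleles < 0) | (self.alleles > 1)
        if bad.any():
            raise ValueError("alleles must be 0/1 with no missing entries")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def haplotype_ids(self) -> list[str]:
        return [f"{s}_{p}" for s in self.sample_ids for p in (0, 1)]

    def population_of_haplotype(self, row: int) -> str:
        return self.population_of.get(self.sample_ids[row // 2], "")

    def haplotype_rows_for_population(self, population: str) -> np.ndarray:
        rows = [
            i
            for i in range(self.n_haplotypes)
            if self.population_of_haplotype(i) == population
        ]
        return np.asarray(rows, dtype=int)

    def subset_rows(self, rows) -> "HaplotypeMatrix":
        """Restrict to a set of haplotype row indices.

        Rows must come in phase pairs is *not* required here: statistics on an
        arbitrary haplotype subset are legitimate, so sample bookkeeping keeps
        synthetic per-row ids.
        """
        rows = np.asarray(rows, dtype=int)
        ids = self.haplotype_ids
        sel_ids = [ids[r] for r in rows]
        pops = {ids[r]: self.population_of_haplotype(r) for r in rows}
        return _loose_matrix(self.alleles[rows], self.positions, self.contig,
                             sel_ids, pops)

    def genotype_dosage(self) -> pd.Series:
        """ALT-allele dosage (0/1/2) per sample, summed over ... per-site use
        :meth:`site_dosage`; this sums the two phases per sample per site and
        is only meaningful for single-site matrices."""
        if self.n_sites != 1:
            raise ValueError("genotype_dosage requires a single-site matrix")
        d = self.alleles[0::2, 0] + self.alleles[1::2, 0]
        return pd.Series(d, index=self.sample_ids)


class _LooseHaplotypeMatrix(HaplotypeMatrix):
    """Haplotype matrix whose rows are individual haplotypes, not sample pairs."""

    def __post_init__(self) -> None:  # relax the 2-per-sample invariant
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.alleles.shape[1] != len(self.positions):
            raise ValueError("positions length must match number of sites")

    @property
    def haplotype_ids(self) -> list[str]:
        return list(self.sample_ids)

    def population_of_haplotype(self, row: int) -> str:
        return self.population_of.get(self.sample_ids[row], "")


def _loose_matrix(alleles, positions, contig, hap_ids, pops) -> _LooseHaplotypeMatrix:
    return _LooseHaplotypeMatrix(alleles, positions, contig, list(hap_ids), dict(pops))


@dataclass
class PopulationPanel:
    """Sample -> (population, super-population) table."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample", "pop", "super_pop"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"panel missing columns: {sorted(missing)}")
        dup = self.table["sample"][self.table["sample"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate sample id in panel: {dup.iloc[0]!r}")
        if (self.table["pop"].astype(str).str.len() == 0).any():
            raise ValueError("empty population label in panel")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def population_of(self) -> dict[str, str]:
        return dict(zip(self.table["sample"], self.table["pop"]))

    def restrict_to(self, sample_ids) -> "PopulationPanel":
        keep = self.table["sample"].isin(set(sample_ids))
        return PopulationPanel(self.table[keep].reset_index(drop=True))


def read_population_panel(path) -> PopulationPanel:
    table = pd.read_csv(path, sep="\t", dtype=str)
    return PopulationPanel(table)


def write_population_panel(panel: PopulationPanel, path) -> None:
    panel.table.to_csv(path, sep="\t", index=False)


def read_phased_vcf(
    path,
    region: GenomicInterval | None = None,
    population_of: dict[str, str] | None = None,
) -> tuple[HaplotypeMatrix, LoadReport]:
    """Read phased diploid genotypes from a VCF into a haplotype matrix.

    Only biallelic SNPs with fully phased, non-missing genotypes are kept;
    everything else is excluded and tallied in the returned
    :class:`LoadReport`.  ``region`` restricts to 1-based inclusive
    coordinates on one contig; if the contig never appears the matrix is
    empty and ``report.contig_missing`` is set.
    """
    from cyvcf2 import VCF

    report = LoadReport()
    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError on malformed headers
        raise VcfParseError(f"cannot open VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)

    columns: list[np.ndarray] = []
    positions: list[int] = []
    contig = region.contig if region is not None else None
    seen_region_contig = False
    for var in vcf:
        report.n_records += 1
        if region is not None:
            if var.CHROM != region.contig:
                report.n_outside_region += 1
                continue
            seen_region_contig = True
            if not region.contains(var.POS):
                report.n_outside_region += 1
                continue
        if contig is None:
            contig = var.CHROM
        elif var.CHROM != contig:
            raise VcfParseError(
                f"multiple contigs in one read ({contig!r} and {var.CHROM!r}); "
                "pass a region to select one"
            )
        if len(var.ALT) != 1:
            report.n_multiallelic += 1
            continue
        if len(var.REF) != 1 or len(var.ALT[0]) != 1 or var.ALT[0] not in "ACGT":
            report.n_indel += 1
            continue
        gts = var.genotype.array()  # (n_samples, 3): allele0, allele1, phased
        if (gts[:, :2] < 0).any() or not gts[:, 2].all():
            report.n_missing_or_unphased += 1
            continue
        col = gts[:, :2].reshape(-1).astype(np.int8)
        columns.append(col)
        positions.append(var.POS)
        report.n_kept += 1
    vcf.close()

    if region is not None and not seen_region_contig:
        report.contig_missing = True
        warnings.warn(
            f"contig {region.contig!r} absent from {path!r}; returning empty matrix",
            stacklevel=2,
        )

    alleles = (
        np.column_stack(columns)
        if columns
        else np.zeros((2 * len(samples), 0), dtype=np.int8)
    )
    m = HaplotypeMatrix(
        alleles=alleles,
        positions=np.asarray(positions, dtype=np.int64),
        contig=contig or (region.contig if region else ""),
        sample_ids=samples,
        population_of=dict(population_of or {}),
    )
    report.n_monomorphic = int(
        sum(1 for j in range(m.n_sites) if len(np.unique(m.alleles[:, j])) == 1)
    )
    return m, report


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=balsel
##contig=<ID={contig}>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def write_phased_vcf(m: HaplotypeMatrix, path, ref_alt: list[tuple[str, str]] | None = None) -> None:
    """Write a haplotype matrix as a minimal phased VCF (REF=A, ALT=G unless given)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_VCF_HEADER.format(contig=m.contig or "1", samples="\t".join(m.sample_ids)))
        for j in range(m.n_sites):
            ref, alt = ("A", "G") if ref_alt is None else ref_alt[j]
            gts = "\t".join(
                f"{m.alleles[2 * i, j]}|{m.alleles[2 * i + 1, j]}"
                for i in range(len(m.sample_ids))
            )
            fh.write(
                f"{m.contig or '1'}\t{m.positions[j]}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def extract_region(m: HaplotypeMatrix, iv: GenomicInterval) -> HaplotypeMatrix:
    """Columns of ``m`` whose position lies inside ``iv`` (1-based inclusive)."""
    keep = (m.positions >= iv.start) & (m.positions <= iv.end)
    out = dataclasses.replace(m)
    out.alleles = m.alleles[:, keep]
    out.positions = m.positions[keep]
    return out


def read_bed(path) -> list[GenomicInterval]:
    ivs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            ivs.append(GenomicInterval.from_bed_row(parts[0], int(parts[1]), int(parts[2])))
    return ivs


def write_bed(intervals, path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            c, s, e = iv.to_bed_row()
            fh.write(f"{c}\t{s}\t{e}\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_depth_profile(path) -> pd.DataFrame:
    """Tab-separated (pos, depth) table -> DataFrame with int columns."""
    df = pd.read_csv(path, sep="\t", names=["pos", "depth"], comment="#")
    return df.astype({"pos": np.int64, "depth": np.int64})
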