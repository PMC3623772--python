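"""Tag-SNP haplogroup classification, haplotype PCA, within-group diversity
and genotype-set concordance.

The two deeply diverged haplogroups at the locus are distinguishable by a
small panel of tag SNPs (12 genome-wide, 6 in sparser reference panels).  A
haplotype is assigned to the consensus it matches more closely, provided the
mismatch count is within ``max_mismatch`` and strictly smaller than for the
other consensus; ties or poor matches are left unclassified rather than
assigned arbitrarily.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import popstats
from .hapio import HaplotypeMatrix

NE1 = "NE1"
NON_NE1 = "nonNE1"
UNCLASSIFIED = "unclassified"


@dataclass
class TagSnpPanel:
    """Tag-SNP positions with the two haplogroup consensus allele vectors."""

    snp_ids: list[str]
    positions: np.ndarray
    consensus_ne1: np.ndarray
    consensus_non_ne1: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.consensus_ne1 = np.asarray(self.consensus_ne1, dtype=np.int8)
        self.consensus_non_ne1 = np.asarray(self.consensus_non_ne1, dtype=np.int8)
        k = len(self.positions)
        if not (len(self.snp_ids) == len(self.consensus_ne1) == len(self.consensus_non_ne1) == k):
            raise ValueError("panel fields must have equal length")
        if np.any(self.consensus_ne1 == self.consensus_non_ne1):
            raise ValueError("consensus vectors must differ at every tag SNP")

    def __len__(self) -> int:
        return len(self.positions)

    @classmethod
    def read_tsv(cls, path) -> "TagSnpPanel":
        df = pd.read_csv(path, sep="\t")
        return cls(
            snp_ids=list(df["snp_id"].astype(str)),
            positions=df["position"].to_numpy(),
            consensus_ne1=df["allele_NE1"].to_numpy(),
            consensus_non_ne1=df["allele_nonNE1"].to_numpy(),
        )

    def write_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "position": self.positions,
                "allele_NE1": self.consensus_ne1,
                "allele_nonNE1": self.consensus_non_ne1,
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass
class HaplogroupCall:
    haplotype_id: str
    label: str
    mismatches: int


def classify_by_tag_snps(
    m: HaplotypeMatrix, panel: TagSnpPanel, max_mismatch: int | None = None
) -> list[HaplogroupCall]:
    """Assign each haplotype to NE1/nonNE1 by nearest tag-SNP consensus.

    ``max_mismatch`` defaults to 1 for panels of 12 or more tag SNPs and 0
    for smaller panels (near-exact matching; real singleton haplotypes that
    match neither consensus stay unclassified).
    """
    if max_mismatch is None:
        max_mismatch = 1 if len(panel) >= 12 else 0
    pos_index = {int(p): j for j, p in enumerate(m.positions)}
    cols = []
    for snp_id, p in zip(panel.snp_ids, panel.positions):
        if int(p) not in pos_index:
            raise KeyError(f"tag SNP {snp_id} at position {int(p)} absent from matrix")
        cols.append(pos_index[int(p)])
    tags = m.alleles[:, cols]
    mm_ne1 = (tags != panel.consensus_ne1[None, :]).sum(axis=1)
    mm_non = (tags != panel.consensus_non_ne1[None, :]).sum(axis=1)
    calls = []
    for hap_id, a, b in zip(m.haplotype_ids, mm_ne1, mm_non):
        if a < b and a <= max_mismatch:
            calls.append(HaplogroupCall(hap_id, NE1, int(a)))
        elif b < a and b <= max_mismatch:
            calls.append(HaplogroupCall(hap_id, NON_NE1, int(b)))
        else:
            calls.append(HaplogroupCall(hap_id, UNCLASSIFIED, int(min(a, b))))
    return calls


def calls_to_frame(calls: list[HaplogroupCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "haplotype_id": [c.haplotype_id for c in calls],
            "label": [c.label for c in calls],
            "mismatches": [c.mismatches for c in calls],
        }
    )


def haplogroup_frequencies(
    m: HaplotypeMatrix, calls: list[HaplogroupCall]
) -> pd.DataFrame:
    """Haplogroup counts per population (rows sum to haplotype counts)."""
    rows = []
    for i, call in enumerate(calls):
        rows.append({"pop": m.population_of_haplotype(i), "label": call.label})
    df = pd.DataFrame(rows)
    return df.value_counts(["pop", "label"]).unstack(fill_value=0)


def within_group_diversity(
    m: HaplotypeMatrix,
    calls: list[HaplogroupCall],
    region_length: int | None = None,
) -> pd.DataFrame:
    """Nucleotide diversity per (population x haplogroup) group.

    Groups with fewer than 2 haplotypes are skipped (noted with NaN pi and
    their size)."""
    groups: dict[tuple[str, str], list[int]] = {}
    for i, call in enumerate(calls):
        key = (m.population_of_haplotype(i), call.label)
        groups.setdefault(key, []).append(i)
    rows = []
    for (pop, label), idx in sorted(groups.items()):
        if len(idx) < 2:
            rows.append(dict(pop=pop, label=label, n=len(idx), pi_total=np.nan,
                             pi_per_site=np.nan, S=0))
            continue
        div = popstats.nucleotide_diversity(m.alleles[idx], region_length=region_length)
        rows.append(dict(pop=pop, label=label, n=len(idx), pi_total=div.pi_total,
                         pi_per_site=div.pi_per_site, S=div.S))
    return pd.DataFrame(rows)


def group_pairwise_distances(
    m: HaplotypeMatrix, calls: list[HaplogroupCall], label: str, population: str | None = None
) -> np.ndarray:
    """Within-group pairwise Hamming distances (the distributions compared
    across continents for the derived haplogroup)."""
    idx = [
        i
        for i, c in enumerate(calls)
        if c.label == label
        and (population is None or m.population_of_haplotype(i) == population)
    ]
    return popstats.within_pairwise_differences(m.alleles[idx])


@dataclass
class PcaResult:
    coordinates: np.ndarray  # haplotypes x k
    explained_variance_ratio: np.ndarray
    k: int


def haplotype_pca(m: HaplotypeMatrix | np.ndarray, k: int = 2) -> PcaResult:
    """PCA of the column-centered 0/1 allele matrix via SVD.

    Alleles are centered but not frequency-standardized.  If ``k`` exceeds
    the matrix rank the result is truncated.
    """
    alleles = m.alleles if isinstance(m, HaplotypeMatrix) else np.asarray(m)
    if alleles.shape[0] < 3 or alleles.shape[1] < 2:
        raise ValueError("need >= 3 haplotypes and >= 2 sites")
    x = alleles.astype(float)
    x -= x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(s > 1e-10))
    k_eff = min(k, rank)
    coords = u[:, :k_eff] * s[:k_eff]
    total_var = float(np.sum(s**2)) or 1.0
    return PcaResult(
        coordinates=coords,
        explained_variance_ratio=s[:k_eff] ** 2 / total_var,
        k=k_eff,
    )


def genotype_concordance(calls_a: dict, calls_b: dict) -> float:
    """Fraction of shared samples with identical genotype class (0/1/2)."""
    shared = sorted(set(calls_a) & set(calls_b))
    if not shared:
        raise ValueError("no shared samples between the two call sets")
    agree = sum(1 for s in shared if calls_a[s] == calls_b[s])
    return agree / len(shared)
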