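"""Archaic-haplotype comparison, read-depth deletion genotyping and
deletion breakpoint mapping.

The archaic (Neandertal/Denisovan-style) haplotype is a single consensus
sequence over the sites shared with the modern sample; sites where the
consensus is undefined are dropped pairwise.  Deletion zygosity is called
from the ratio of mean read depth inside a candidate interval to the mean
flanking depth; breakpoints of a single contiguous deletion are mapped by
longest common prefix/suffix with the leftmost equivalent placement reported
together with the width of the micro-homology ambiguity range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import popstats
from .hapio import GenomicInterval, HaplotypeMatrix

HOM_DEL = "hom_del"
HET_DEL = "het_del"
NO_DEL = "no_del"
INDETERMINATE = "indeterminate"


@dataclass
class DepthProfile:
    """Per-position read depth over a region (1-based positions)."""

    positions: np.ndarray
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if len(self.positions) != len(self.depth):
            raise ValueError("positions and depth must have equal length")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if (self.depth < 0).any():
            raise ValueError("depths must be non-negative")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DepthProfile":
        return cls(df["pos"].to_numpy(), df["depth"].to_numpy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"pos": self.positions, "depth": self.depth})


@dataclass
class DepthCall:
    zygosity: str
    mean_inside: float
    mean_flank: float

    @property
    def normalized_depth(self) -> float:
        return self.mean_inside / self.mean_flank


@dataclass
class ArchaicComparison:
    distances: np.ndarray  # per modern haplotype
    group_labels: list[str]
    u_statistic: float
    p_two_sided: float
    mean_by_group: dict[str, float]


def distance_to_archaic(
    m: HaplotypeMatrix,
    archaic: np.ndarray,
    groups: dict[str, np.ndarray] | None = None,
) -> ArchaicComparison | np.ndarray:
    """Hamming distance of each modern haplotype to the archaic consensus.

    ``archaic`` is a 0/1 vector over the matrix's sites; entries < 0 mark
    undefined consensus sites, which are dropped pairwise.  If ``groups``
    maps two group names to haplotype row indices, a Mann-Whitney comparison
    of their distance distributions is returned as well.
    """
    archaic = np.asarray(archaic)
    if len(archaic) != m.n_sites:
        raise ValueError("archaic haplotype must cover the matrix's sites")
    defined = archaic >= 0
    if not defined.any():
        raise ValueError("no shared (defined) sites with the archaic haplotype")
    d = popstats.pairwise_differences(
        archaic[defined].astype(np.int8), m.alleles[:, defined]
    )
    if groups is None:
        return d
    if len(groups) != 2:
        raise ValueError("exactly two groups required for the comparison")
    (la, ia), (lb, ib) = groups.items()
    u, p = popstats.mann_whitney_u(d[np.asarray(ia)], d[np.asarray(ib)])
    return ArchaicComparison(
        distances=d,
        group_labels=[la, lb],
        u_statistic=u,
        p_two_sided=p,
        mean_by_group={la: float(d[np.asarray(ia)].mean()), lb: float(d[np.asarray(ib)].mean())},
    )


def call_deletion_from_depth(
    profile: DepthProfile,
    candidate: GenomicInterval,
    hom_max: float = 0.1,
    het_range: tuple[float, float] = (0.35, 0.65),
    no_del_min: float = 0.8,
) -> DepthCall:
    """Deletion zygosity from normalized depth inside a candidate interval.

    The inside mean is divided by the mean flanking depth; ratios below
    ``hom_max`` call a homozygous deletion, within ``het_range`` a
    heterozygous one, above ``no_del_min`` no deletion; anything else is
    indeterminate.  Thresholds are configurable.
    """
    inside = (profile.positions >= candidate.start) & (profile.positions <= candidate.end)
    if not inside.any():
        raise ValueError("candidate interval contains no profiled positions")
    flank = ~inside
    if not flank.any() or profile.depth[flank].mean() <= 0:
        raise ValueError("zero flanking coverage; cannot normalize")
    mean_in = float(profile.depth[inside].mean())
    mean_fl = float(profile.depth[flank].mean())
    ratio = mean_in / mean_fl
    if ratio < hom_max:
        z = HOM_DEL
    elif het_range[0] <= ratio <= het_range[1]:
        z = HET_DEL
    elif ratio > no_del_min:
        z = NO_DEL
    else:
        z = INDETERMINATE
    return DepthCall(zygosity=z, mean_inside=mean_in, mean_flank=mean_fl)


@dataclass
class BreakpointCall:
    """A mapped deletion: leftmost placement plus micro-homology ambiguity."""

    interval: GenomicInterval
    length: int
    ambiguity_width: int


def map_deletion_breakpoints(
    reference: str, sample: str, offset: int = 0
) -> BreakpointCall:
    """Map the breakpoints of a single contiguous deletion.

    ``sample`` must equal ``reference`` with one contiguous block removed.
    The deleted interval is reported at its leftmost equivalent placement in
    1-based reference coordinates (plus ``offset``); ``ambiguity_width``
    counts the equivalent placements across the micro-homology range.
    """
    ref = reference.upper()
    sam = sample.upper()
    for name, seq in (("reference", ref), ("sample", sam)):
        if set(seq) - set("ACGT"):
            raise ValueError(f"{name} contains non-ACGT characters")
    d = len(ref) - len(sam)
    if d <= 0:
        raise ValueError("sample is not shorter than reference (no deletion)")
    lcp = 0
    while lcp < len(sam) and ref[lcp] == sam[lcp]:
        lcp += 1
    lcs = 0
    while lcs < len(sam) and ref[len(ref) - 1 - lcs] == sam[len(sam) - 1 - lcs]:
        lcs += 1
    # valid 1-based deletion starts p: prefix p-1 <= lcp and suffix constraint
    p_min = max(1, len(sam) - lcs + 1)
    p_max = min(lcp + 1, len(sam) + 1)
    if p_min > p_max:
        raise ValueError("sample is not derivable from reference by one contiguous deletion")
    start = p_min + offset
    return BreakpointCall(
        interval=GenomicInterval("ref", start, start + d - 1),
        length=d,
        ambiguity_width=p_max - p_min + 1,
    )


def apply_deletion(reference: str, interval: GenomicInterval, offset: int = 0) -> str:
    """Remove a 1-based inclusive interval from a reference sequence."""
    s = interval.start - 1 - offset
    e = interval.end - offset
    return reference[:s] + reference[e:]
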