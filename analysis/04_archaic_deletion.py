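#!/usr/bin/env python
"""Archaic comparison and deletion characterization.

Three exercises: (1) Hamming distance of every modern haplotype to the
archaic consensus, compared between haplogroups (the archaic lineage was
sampled from the derived clade, so derived haplotypes should be closer);
(2) read-depth deletion genotyping of an archaic-style profile (homozygous
deletion: depth drops to ~0 inside the interval); (3) breakpoint mapping of
the deletion from a reference/sample sequence pair, reporting the leftmost
placement and micro-homology ambiguity.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from balsel import archaic, hapio, synthdata

SCENARIO = Path("results/scenario")
OUT = Path("results")
SEED = 404


def main() -> None:
    panel = hapio.read_population_panel(SCENARIO / "panel.tsv")
    m, _ = hapio.read_phased_vcf(SCENARIO / "haplotypes.vcf",
                                 population_of=panel.population_of)
    arch = pd.read_csv(SCENARIO / "archaic_haplotype.tsv", sep="\t")
    truth = pd.read_csv(SCENARIO / "truth.tsv", sep="\t")
    assert (arch["pos"].to_numpy() == m.positions).all()

    ne1 = np.where(truth["clade"] == "NE1")[0]
    non = np.where(truth["clade"] != "NE1")[0]
    res = archaic.distance_to_archaic(
        m, arch["allele"].to_numpy(), groups={"NE1": ne1, "nonNE1": non}
    )
    pd.DataFrame({
        "haplotype_id": m.haplotype_ids,
        "clade": truth["clade"],
        "distance_to_archaic": res.distances,
    }).to_csv(OUT / "archaic_distances.tsv", sep="\t", index=False)
    print(f"mean distance to archaic: NE1 {res.mean_by_group['NE1']:.1f}, "
          f"nonNE1 {res.mean_by_group['nonNE1']:.1f} "
          f"(Mann-Whitney p = {res.p_two_sided:.2g})")

    (deletion,) = hapio.read_bed(SCENARIO / "deletion.bed")
    rng = np.random.default_rng(SEED)
    calls = []
    for label, zyg in [("archaic_genome", "hom_del"),
                       ("derived_heterozygote", "het_del"),
                       ("ancestral_homozygote", "no_del")]:
        prof = synthdata.simulate_depth_profile(deletion, 30, zyg, rng)
        prof.to_frame().to_csv(OUT / f"depth_{label}.tsv", sep="\t", index=False)
        call = archaic.call_deletion_from_depth(prof, deletion)
        calls.append({"sample": label, "true_zygosity": zyg,
                      "called": call.zygosity,
                      "normalized_depth": round(call.normalized_depth, 3)})
    depth_table = pd.DataFrame(calls)
    depth_table.to_csv(OUT / "deletion_depth_calls.tsv", sep="\t", index=False)
    print(depth_table.to_string(index=False))

    ref, sample = synthdata.simulate_reference_with_deletion(
        synthdata.LOCUS_INTERVAL, deletion, rng
    )
    hapio.write_fasta({"reference": ref, "deletion_carrier": sample},
                      OUT / "breakpoint_sequences.fa")
    call = archaic.map_deletion_breakpoints(
        ref, sample, offset=synthdata.LOCUS_INTERVAL.start - 1
    )
    print(f"breakpoints: {call.interval.start}-{call.interval.end} "
          f"({call.length} bp, {call.ambiguity_width} equivalent placements)")


if __name__ == "__main__":
    main()
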