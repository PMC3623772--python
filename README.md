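# balsel

Population-genetic detection and dating of **ancient balanced polymorphism**
at a non-recombining haplotype block — the analysis pipeline behind a study
of a ~36-kb region on chr22 (hg18 chr22:37,600,063–37,636,026) whose
variation segregates as two deeply diverged haplogroups. The derived
haplogroup carries a 4,580-bp deletion (breakpoints 37,624,055–37,628,634)
in perfect linkage disequilibrium with 12 tag SNPs, matches the archaic
(Neandertal/Denisovan-like) sequence, and is best explained by African
substructure predating the human–archaic split, maintained by balancing
selection.

The package is written for population geneticists who want to re-run this
kind of inference end-to-end on phased VCFs — or on the bundled coalescent
generator that emulates the locus's assumed structure.

## What it computes

For phased haplotypes *h₁…hₙ* over biallelic SNPs:

* **Diversity** — π (mean pairwise difference, per region and per base),
  segregating sites *S*, Watterson's θ̂_W = S/a_n with a_n = Σ_{j<n} 1/j.
* **Tajima's D** — (π − θ̂_W)/√(e₁S + e₂S(S−1)), with significance from
  neutral coalescent simulations conditional on *S*; strongly positive D
  (excess intermediate-frequency variants) is the balancing-selection
  signature.
* **Hudson's F_ST** — 1 − H_w/H_b per SNP, ratio-of-averages per window.
* **LD** — mean pairwise r² from phased haplotypes.
* **Genome scan** — 10-kb window statistics, empirical outlier p-values
  (add-one convention), stratified comparisons, and the four-statistic
  quadrant filter (π > 0.002, r² > 0.5, D > 4.5, F_ST > 0.2).
* **Haplogroups** — tag-SNP classification (nearest consensus within a
  mismatch budget), haplotype PCA, within-group diversity, genotype-set
  concordance.
* **Archaic & deletion** — distances to an archaic consensus with
  Mann-Whitney group comparison, read-depth deletion zygosity calls, and
  breakpoint mapping with leftmost placement plus micro-homology ambiguity.
* **Network dating** — median-joining haplotype networks, the ρ statistic
  (mean mutational steps to an ancestral node), and age = ρ/(μL) with the
  mutation-rate units declared explicitly.
* **ML-HKA** — multilocus Poisson model S_i ~ Pois(k_i θ_i L_i a_n),
  D_i ~ Pois(θ_i L_i (T + k_i)), with per-locus selection parameters k_i,
  profile-likelihood fitting and a χ² likelihood-ratio test.
* **Synthetic data** — a Hudson coalescent (infinite sites, no intra-window
  recombination) generating neutral windows, the two-haplogroup locus with
  planted tag SNPs/deletion/archaic lineage, expression vectors coupled to
  genotype, and Poisson read-depth profiles.

## Worked example

```sh
python analysis/01_simulate_locus.py
python analysis/02_locus_stats.py
```

prints (seeded run):

```
simulated 200 haplotypes x 452 SNPs on chr22:37600115-37635913
derived haplogroup: 70 haplotypes (35.0%), 12 tag SNPs, deletion 37624055-37628634
...
locus Tajima's D = 2.84 (coalescent p = 0.0021); a strongly positive D with
high LD is the balanced-polymorphism signature
```

200 haplotypes (an African-like and a European-like population, derived-
haplogroup frequencies 0.20/0.50) carry 452 SNPs over the 36-kb analog. The
locus-wide Tajima's D of 2.84 sits in the far upper tail of the neutral
null (p = 0.0021 from 10,000 conditional coalescent simulations): the two
deeply diverged haplogroups at intermediate frequency create exactly the
excess of common variants that balancing selection predicts. The remaining
drivers classify haplogroups (03), compare against the archaic consensus
and call the deletion from read depth (04), scan a synthetic genome and
apply the quadrant filter (05), date the derived clade with a
median-joining network (06; the two literature mutation rates give ages in
a fixed 25/11 ratio), run the 100-locus ML-HKA test (07), and screen
cis-eQTL associations (08). Each writes its tables under `results/`.

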