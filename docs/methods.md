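# Methods

This note documents the models, estimators, numerical choices and known
limitations of `balsel`. It is the package's own account of its science;
every number quoted here is recomputed by the test suite or by
`scripts/acceptance.py`.

## Statistical model of the locus

The pipeline targets a single non-recombining haplotype block whose
variation segregates as two deeply diverged haplogroups (a derived,
deletion-bearing clade and an ancestral clade). Under long-term balancing
selection such a block shows, relative to the genome-wide background:

* elevated nucleotide diversity π, because most haplotype pairs straddle the
  deep split;
* strongly positive Tajima's D, because the clade-fixed differences are
  intermediate-frequency variants;
* elevated LD r², because the clade-fixed differences are mutually
  perfectly correlated in the absence of recombination;
* elevated between-population F_ST when the haplogroup frequencies differ
  between populations;
* excess polymorphism relative to divergence in an HKA comparison, because
  the within-species coalescence at the locus is far older than the neutral
  expectation.

All five signatures are computed from one substrate, a phased haplotype
matrix (rows = haplotypes, two per diploid sample; columns = biallelic SNPs
with strictly increasing 1-based positions; 0/1 = REF/ALT). Sites with any
missing or unphased genotype, indels and multiallelic records are dropped
at load time and tallied; nothing is imputed. Ancestral-state polarisation
is never implicit — the archaic/outgroup comparisons take an explicit
consensus vector.

## Estimators and conventions

**π** is the mean pairwise Hamming distance over all unordered haplotype
pairs (per site: divided by the region length in bases, not the SNP count).
No n/(n−1) finite-sample factor is applied to region totals.

**Tajima's D** uses the 1989 constants. Significance comes from neutral
coalescent simulations *conditional on S*: a genealogy is drawn, S
mutations are placed multinomially with probabilities proportional to
branch lengths, and the two-sided p-value is (1 + #{|D_sim| ≥ |D_obs|}) /
(1 + reps). The worked three-singleton configuration at n=4 gives
D = −0.7545.

**F_ST** is Hudson's 1 − H_w/H_b with H_w the average of the two
within-population mean pairwise differences (which carries the unbiased
n/(n−1) correction) and H_b the between-population mean difference.
Windows aggregate as a ratio of averages, the form recommended for
combining loci. A consequence worth knowing: at identical sample
frequencies the per-site estimate is −1/(n−1), not exactly 0; it vanishes
with sample size. Sites with H_b = 0 are undefined and excluded from the
aggregate.

**r²** is computed directly from phased haplotype frequencies (equivalently
the squared Pearson correlation of the two 0/1 site columns); no EM is
needed. The MAF filter defaults to 0.05 and is configurable.

**Mann-Whitney** p-values are exact by full enumeration of labelings
(midranks for ties) when n_x + n_y ≤ 12, otherwise the tie-corrected normal
approximation with continuity correction.

**Empirical outlier p-values** use the add-one convention,
p = (1 + #extreme)/(1 + N), so p is never 0 and the floor from N background
windows is 1/(N+1). Windows with undefined statistics are excluded from
null distributions rather than treated as zeros. The quadrant filter takes
its four thresholds (π > 0.002/bp, r² > 0.5, D > 4.5, F_ST > 0.2) as
configuration and merges abutting qualifying windows into single regions.

**Tag-SNP classification** assigns a haplotype to the consensus with
strictly fewer mismatches, provided that count is within the mismatch
budget (default 1 for panels of ≥12 tags, 0 for smaller panels); ties and
poor matches are left unclassified, never assigned arbitrarily.

**PCA** decomposes the column-centered 0/1 matrix by SVD, without
frequency standardisation (configurable choice; standardisation would
up-weight rare variants, which is not wanted when the signal is a deep
frequency split).

**Breakpoint mapping** of a single contiguous deletion uses longest common
prefix/suffix. When micro-homology at the breakpoints makes several
placements equivalent, the leftmost is reported along with the number of
equivalent placements (`ambiguity_width`). Depth-based zygosity calls use
normalized mean depth inside the candidate interval with thresholds
<0.1 (homozygous deletion), 0.35–0.65 (heterozygous), >0.8 (no deletion),
otherwise indeterminate; thresholds are configurable and the defaults give
≥99% accuracy at 30× coverage.

**Median-joining networks** follow the binary-data construction: the
minimum-spanning network (greedy distance levels, tolerance ε = 0 by
default), then iterative addition of the median (site-wise majority) of
linked triplets whenever it strictly reduces the minimum-spanning cost;
redundant inferred nodes (unsampled, degree ≤ 2) are pruned. ρ is the
multiplicity-weighted mean shortest-path mutational distance from a
designated ancestral node to the derived sampled haplotypes; ties among
shortest paths are immaterial since only the length enters. Age conversion
ρ/(μL) requires the mutation-rate units (`per_year` or `per_generation`)
to be declared — there is no silent default, because the two readings
differ by the generation time.

**ML-HKA.** For locus i with length L_i, shared sample size n, divergence
time T (coalescent units) and selection parameter k_i (1 for neutral
loci):

    S_i ~ Poisson(k_i θ_i L_i a_n)      a_n = Σ_{j=1}^{n−1} 1/j
    D_i ~ Poisson(θ_i L_i (T + k_i))

k_i > 1 inflates polymorphism and adds ancestral polymorphism to the
divergence mean — deepened within-locus coalescence, the balancing
signature. θ_i is profiled out analytically (the MLE given (T, k) is
(S_i + D_i)/(L_i(k_i a_n + T + k_i))), leaving a 1–2 dimensional
maximisation done by seeded multi-start Nelder-Mead in log space;
convergence at likelihood improvement < 1e−8. The selection fit is seeded
from the neutral optimum, so nesting (logL_sel ≥ logL_neutral) holds by
construction and the LRT 2ΔlogL is compared to χ² with df = number of
selected loci. The symmetric two-locus case (S=D=10, L=1, n=10) has the
closed form θ̂ = 10/a_10 = 3.5349, T̂ = a_10 − 1 = 1.8290, which the
optimizer reproduces to 4 decimals; the LRT's type-I error at α = 0.05 is
calibrated within the binomial 95% CI over 500 parametric replicates.
The power simulator can inflate the polymorphism mean alone
(`polymorphism_only`), the classic excess-polymorphism alternative.

## The synthetic-data generator

The generator defines the study conditions; it is first-class, tested code.

*Core:* a Kingman coalescent in units of 2N generations with infinite-sites
mutations at rate θ/2 per unit branch length and uniform positions. There
is no recombination within a window; windows are independent (free
recombination between them). No growth, migration or selection dynamics are
simulated — the haplogroup structure is built by construction, which is
what controlled power analyses need.

*Substructure locus:* each haplogroup coalesces internally on an
effective-size scale equal to its pooled frequency (an allelic class
maintained at frequency p behaves as a population of size pN), the two
clade roots join at `t_split`, and the stems carry Poisson stem mutations
plus exactly `n_tag_snps` planted tag SNPs — clade-fixed differences, hence
in perfect LD with clade membership and with the deletion, which every
derived haplotype carries. Haplogroup frequencies per population are hit
exactly by label assignment (`freq × n` must be an integer). The archaic
haplotype is the derived clade's root consensus over the emitted sites.
An optional per-population time scale deepens or shallows within-clade
coalescence (e.g. a 3× deeper African derived clade, the dated ratio of
the African and European clade ages); in that mode per-population
subclades coalesce first and their roots then join at the clade scale.

*Default scenario* (the locus analog): 100 haplotypes each in an
African-like and a European-like population, derived-haplogroup
frequencies 0.20/0.50, θ_locus = 36 over the 36-kb geometry (0.001/bp,
human-typical), t_split = 8 — about 3.2 My at N = 10⁴ and 20-year
generations, inside the dated range for the two haplogroups' divergence.
Under these conditions the deletion-containing 10-kb window shows D > 2
and the locus-wide D ≈ 2.8. Per-population depth is uniform by default;
the deep-African variant is explicit because applying it to both clades
inflates within-clade variation enough to erode the positive-D signature,
which the locus analysis is meant to display.

*Power scenario* (for the quadrant filter): one 10-kb locus window,
θ = 10, 100 haplotypes per population, frequencies 0.25/0.75. The D > 4.5
threshold sits near Tajima's D's theoretical plateau at n = 200
((π − θ_W)/sd saturates as clade-fixed differences m grows, at ≈6.3), and
crossing it with ≥90% probability requires m ≳ 250 clade-fixed
differences; with θ = 10 that means t_split ≈ 30. This is deliberately far
deeper than the dated history of the real locus: the scenario probes the
filter's operating regime — the thresholds were published as joint extreme
cutoffs — rather than re-enacting the locus. The pooled derived frequency
of 0.5 maximises the per-site π of clade-fixed differences while the
0.25/0.75 split keeps F_ST well above 0.2. Background windows are neutral
at the same θ; none passes all four thresholds in any tested seed.

*Other inputs:* expression = β·dosage + N(0, σ²); read depth =
Poisson(coverage × dose) with dose 0/0.5/1 inside the deletion by
zygosity; reference/sample FASTA pairs with the deletion excised for
breakpoint exercises.

What passing tests on these data do **not** show: robustness to
recombination within the block, to imputation or phasing error, to
ascertainment bias in SNP discovery, or to demographic confounders
(bottlenecks and growth also move D). The generator's clean clade
structure makes classification and deletion-LD exact by construction, so
the 100% tag-classification accuracy is a consistency check of the
pipeline, not an estimate of real-data performance.

## Problem sizes and determinism

Simulation-based checks use 10,000 replicates for neutral calibration and
Tajima p-values, 500 replicates for LRT calibration, 50 seeded genomes of
100 background windows for scan power, and 50 replicates for dating
recovery — sizes at which the Monte-Carlo error is several times smaller
than each assertion's tolerance. Every stochastic routine takes an
explicit seed or `numpy` Generator; identical configuration and seed give
byte-identical outputs (asserted for the generator and the scan).

## Known limitations

* The coalescent core is O(n) per event with Python-level loops; it is
  sized for hundreds of haplotypes and hundreds of windows, not for
  whole-genome scans with thousands of samples (the window/scan API is
  agnostic, only the generator would need vectorising).
* The median-joining search adds one best median per iteration and caps
  iterations; for large, reticulate samples it is a faithful but not
  optimised implementation — analyses restrict to within-clade segregating
  sites, where networks are small.
* The HKA divergence counts treat the outgroup as a single sequence
  (consensus differences, ties to REF); no alignment uncertainty or
  multiple-hit correction is modelled, consistent with count-based inputs.
* `read_phased_vcf` handles one contig per call and loads into memory; it
  is not a streaming reader.
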