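# Methods

This note documents the models, estimators, numerical conventions and
design choices behind `oryzagen`, and what the synthetic-data tests do
and do not establish about real data.

## Data model and conventions

Genotypes are biallelic SNPs held at haplotype resolution
(`(n_samples, 2, n_sites)`, missing = −1), with 1-based VCF positions.
All window and interval arithmetic is half-open `[start, end)` with
windows tiled from position 1 (1, 10001, …), so 10 kb windows partition
a chromosome unambiguously. Missing genotypes are never imputed;
every statistic uses pairwise-available data, with a site's sample size
`n_s` equal to its number of called haplotypes.

## Window statistics

π is the mean pairwise difference per *accessible* site — a site with a
call rate of at least 80%, aligning the window denominator with the
genome-wide site filter; the count of accessible sites is reported as
`n_sites_typed` and windows with under 30% accessible sites are
discarded (both thresholds configurable). Per site,
π_s = 2c(n_s−c)/(n_s(n_s−1)) for alt count c, and θ_w sums 1/a_{n_s−1}
over segregating sites (a_k = Σ_{i≤k} 1/i). Tajima's D uses the
standard e₁, e₂ constants evaluated at the rounded mean per-site
haplotype count; when every site has the same n this reduces exactly to
the published formulas (verified against an independent implementation),
and with variable n it is the natural pairwise-deletion extension. D is
reported as undefined for n < 4 or S = 0.

Hudson's Fst is the ratio-of-averages estimator (numerator with the
(n−1) sampling correction, denominator p₁(1−p₂)+p₂(1−p₁)). Two
consequences are worth knowing: comparing a sample set against itself
yields exactly −1/(n−1), not 0 (the estimator is unbiased, not
idempotent), and windows whose denominator sums to zero are omitted.

LD r² is the squared Pearson correlation of alt-dosages over samples
called at both sites (phase-free, matching the common PLINK-style
genotype r²), restricted to pairs within the same 1 Mb window and
averaged in 1 kb distance bins. A centered moving-average smoother is
provided for plots; no LOESS fitting is attempted.

f4(A,B;C,D) is the site-mean of (p_A−p_B)(p_C−p_D) over sites typed in
all four groups, with a delete-one-block jackknife over consecutive
100-SNP blocks (the final partial block is kept).

The sweep scan flags windows whose π_wild/π_domesticate ratio strictly
exceeds the empirical 99th percentile of finite ratios (linear
interpolation); infinite ratios (zero domesticate diversity where the
wild retains diversity) are always flagged. Strict exceedance means a
degenerate, all-equal ratio distribution flags nothing. In the
end-to-end analysis the domesticate panel is restricted to carriers of
the derived allele, since a sweep ablates diversity only on the swept
background; non-carrier haplotypes would otherwise dilute the signal.

## Grouping and curation

Distances are 1 − IBS over mutually typed sites, computed on filtered
(80% call rate, 2% MAF) and LD-thinned sites (one polymorphic site per
50 kb window, at least 25 kb apart, uniform choice under a seed).
Neighbor joining is delegated to scikit-bio (branch lengths clamped at
zero); classical MDS is Torgerson double-centering with axes ordered by
eigenvalue and a first-nonzero-loading-positive sign convention.

The silhouette score is s(i) = (b−a)/max(a,b) with a the mean distance
to the own group (excluding self) and b, by default, the mean distance
to the *nearest* foreign group (the convention of the silhouette's
original definition; the wording "the foreign group" is ambiguous when
more than two groups exist, so an all-foreign-mean option is exposed).
The iterative core filter removes, per pass, all samples with negative
scores if any exist, otherwise all with s ≤ threshold; it stops when
every remaining score exceeds the threshold or when a removal would
leave a group with fewer than 2 members (stopped runs are flagged).
Batch removal keeps the procedure deterministic and order-free. The
default threshold is 0.1, with 0.12 reachable through configuration —
the two published descriptions of the cutoff differ and neither is
asserted as exact.

## Deletion genotyping

A deletion call compares the median read depth over the candidate gene
with a control gene outside the deleted region: `deleted` when the
target median is 0 or target/control ≤ 0.1, `present` otherwise,
`no_call` when the control median is below 1× (low overall coverage
cannot distinguish deletion from missing data). The ratio rule makes
calls invariant to depth scaling; the target-zero rule keeps them
robust down to ~1× coverage, where the synthetic concordance with truth
stays above 95%. Group frequencies count individuals (deleted /
(deleted + present)), rounded to whole percent; heterozygous deletions
are not modelled — intermediate ratios are reported but classified by
the single threshold. SNP deserts (runs with no filter-passing site of
at least a minimum gap, 8 kb for the synthetic gene spans) localise
candidate deletions independently of depth.

## Haplotype networks

Regions are screened with the four-gamete test on every site pair,
separately within the wild and domesticate partitions. A fourth gamete
below 1% frequency is treated as genotyping error. Domesticate-side
recombination rejects the region (the caller should shrink it);
wild-only recombination removes the wild haplotypes carrying the
minority gamete (ties broken toward the gamete holding the rarer allele
at the first, then second site), iterating until the region is clean —
the output always passes a full re-scan. Haplotypes with any missing
site in the region are excluded up front (counts logged) since
imputation is out of scope.

Identical haplotypes are collapsed into nodes keyed by allele string
*and* causal status, so a shared string splits into carrier and
non-carrier nodes (as a shared haplotype does when subdivided by
deletion status); labels are roman numerals in descending-count order.
The minimum spanning tree is Kruskal over the complete hamming graph
with ties broken toward the smallest node-index pair — MSTs are not
unique, and a fixed tie-break makes outputs reproducible. Weights are
cross-checked against exhaustive spanning-tree enumeration in tests.

## Origin inference

For each derived node the nearest ancestral node is found by tree-path
distance; ties are all reported, and the derived node at globally
minimal distance is the putative founding haplotype (later derived
haplotypes record range expansion, not origin). Regions are scored by
min(freq_ancestral, freq_derived) — rewarding joint presence without
letting one abundant haplotype dominate — with a frequency-product
option; frequencies are carriers over the region's sampled haplotypes.
When several ancestral nodes tie, their geographic distributions are
aggregated before scoring. Disjoint ranges yield an explicit
"indeterminate" status rather than a forced call, and every report
carries the per-haplotype sample sizes because ancestral carriers are
typically few; no confidence level is asserted.

## Threshability

Percent shattering maps to the SES panicle threshability scale:
<1% → 1, 1–5% → 3, 6–15% → 5, 26–50% → 7, 51–100% → 9. The printed
scale omits 16–25%; the SES convention assigns 6–25% to the middle
score, so that gap maps to 5, keeping the scale monotone. Group
comparisons use two-sided Mann-Whitney tests — exact by enumeration of
all group assignments (tie-safe, via the rank-sum identity with
midranks) for combined n ≤ 20, scipy's tie-corrected normal
approximation above — with Bonferroni correction over all pairs. The
concordance table cross-tabulates (sh1 status × sh4 status × score
band) per group and flags genotype combinations spanning more than one
band, the signature of unmodelled shattering loci.

## The synthetic-data generator

The generator is a founder-haplotype pool model, not a coalescent; it
produces the structure the analysis assumes in well under a second per
dataset, and an optional coalescent backend could replace it without
changing the output contract.

Wild structure: each of 5 regions on a west-to-east axis holds k = 8
founder haplotypes around a regional consensus; consensuses form a
stepping-stone chain (Poisson(60) mutations per step and chromosome)
and founders add Poisson(12) private mutations. Every mutation hits a
previously unused site (infinite sites), so wild variation is
homoplasy-free and — with no within-chromosome recombination — the
four-gamete test is clean by construction; recombinant fixtures for the
scan are built explicitly in tests.

Domesticate structure: all domesticate groups share a bottlenecked
"domestication core" of 4 founders sampled across the regional pools,
mixed with a region-local component (25% of haplotype draws come from
3 local founders). The shared core is what makes domesticate groups
weakly differentiated from each other (mean Fst ≈ 0.05) while strongly
differentiated from any wild group (≈ 0.4), and it is why a feral
mosaic — each chromosome copied from a random domesticate with
probability 0.75, else from a random wild sample — sits close to the
domesticate (Fst ≈ 0.05) and far from the wild (≈ 0.35), reproducing
the qualitative ordering seen between feral, domesticated and wild
African rice. A purely region-local bottleneck model was tried first
and fails that ordering: a mosaic across five narrow, mutually
divergent pools differs more from each of them than from the diverse
wild groups.

Causal loci: one nonsense-SNP locus and two whole-gene deletion loci,
each seeded on a single parent founder in one origin region. The
derived haplotype is the parent plus the causal change and one linked
marker mutation; the parent founder is excluded from all domesticate
pools, so the ancestral haplotype survives only in wild samples — the
situation in which the range-overlap origin logic is informative. A
domesticate in region r carries the derived haplotype with probability
d^|r−origin| (d = 0.5 by default) and carriers are homozygous for the
derived haplotype across the ±25 kb sweep interval, making carrier
diversity there exactly zero. Deletions additionally blank genotypes
across the 10 kb gene span and zero the gene's median depth; depth for
present genes is the median of per-base Poisson(coverage) draws.

Site placement concentrates 120 of the 1,000 per-chromosome sites
inside each locus's focal (network) region so local SNP density there
resembles resequencing data while the genome stays desk-scale.
Geography is a 1-D axis of cells mapped to country labels, with
coordinates jittered within cells — sufficient for the coastal/inland
contrasts the origin inference exercises.

Phenotypes follow a threshold model on the two shattering loci: double
mutants shatter <5%, single mutants 6–30%, non-carriers and wild plants
55–95%. This is deliberately simple — enough to drive the trait
analyses, not a model of threshability genetics.

What passing tests show, and don't: the generator has no recombination
within chromosomes, no genotyping error, no recurrent mutation, no
heterozygous deletions, and its geographic diffusion is monotone in
distance. Success on it demonstrates that the pipeline's logic is
correct under the assumptions the original analysis itself makes, not
that those assumptions hold in any particular real dataset; with d
near 1 the derived range saturates and the origin signal rests entirely
on the few wild ancestral carriers, which is why reports surface those
sample sizes.

## Problem sizes

Default datasets are 215 samples × 3,000 sites over three 1 Mb
chromosomes (300 analysis windows); the recovery study runs 20
replicates at seeds 1–20 under the default conditions (5 regions,
d = 0.5, 30 domesticates per group, 15× coverage). These sizes were
chosen so a full replicate — simulation through origin inference —
takes about a second while every window, network and frequency estimate
remains well populated.

## Known limitations

Tajima's D with heterogeneous per-site sample sizes uses a single
rounded mean n for the variance constants; estimates from
genotype-likelihood machinery (empirical-Bayes SFS priors) will differ
numerically from these genotype-based ones, and no reconciliation is
attempted. Unphased input is accepted for all dosage-based statistics
but haplotype networks require phased data. The CLI's `hapnet`,
`origin` and `traits` subcommands run the full synthetic pipeline
because locus definitions and carrier sets on real data come from the
study design, not from a file format this package defines.
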