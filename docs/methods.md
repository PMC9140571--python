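# Methods

`divscan` implements the standard analysis battery for assessing the
genomic diversity and selection history of small livestock populations
genotyped on a medium-density SNP chip: quality control and relatedness
pruning, heterozygosity and Wright's F_IS, rarefied allelic richness,
effective population size from linkage-disequilibrium (LD) decay, runs
of homozygosity (ROH) with the genomic inbreeding coefficient F_ROH, a
standardized-FST (d_i) window scan, and a cross-population extended
haplotype homozygosity (XPEHH) scan. A forward Wright–Fisher simulator
provides cohorts with known demography, inbreeding and sweeps, so every
stage is validated against ground truth.

## Data model and conventions

Genotypes are diploid dosages of a designated counted allele
(`allele_b`, the PLINK A2 analog) in {0, 1, 2} with a distinct missing
sentinel; phased haplotypes are binary matrices with two rows per
sample. Coordinates are 1-based inclusive base pairs and all interval
arithmetic (windows, ROH, regions) is on closed intervals. Only
autosomes (1–26, the ovine count) are analyzed; other records are
dropped at read time. The genetic map is linear in position at a
configurable rate (cM/Mb).

## Quality control

Filter order is fixed and logged: sample missingness (> 5% removed) →
SNP call rate (< 95% removed) → minor allele frequency (< 5% removed) →
relatedness. Relatedness uses the KING-robust between-pair kinship

    phi = (N_het,het − 2 N_opposite-hom) / (N_het(i) + N_het(j))

over jointly observed loci; the "IBD proportion" threshold (default
0.35) is applied on the 2·phi scale, clipped to [0, 1]. Pruning is
greedy and deterministic: repeatedly drop the sample in the most
over-threshold pairs (ties: higher missingness, then later sample
order). LD pruning mirrors PLINK's `--indep-pairwise 50 5 0.5`: within
each sliding 50-SNP window the lower-MAF member of any pair with
r² > 0.5 is removed (tie: later map position), iterated to a fixpoint;
pairs whose r² is undefined after subsetting carry no information and
never trigger removal. Both pruning procedures are verified against
independent brute-force fixpoint oracles rather than against PLINK
binaries, whose tie-breaking is not fully documented.

## Diversity

Per SNP, observed heterozygosity is the heterozygote fraction among
non-missing calls and expected heterozygosity the plug-in 2p(1−p);
population values are unweighted means over retained SNPs. The plug-in
form is the default because the published F_IS values this package
reproduces are consistent with it; the small-sample correction
2n/(2n−1) is available by flag. F_IS = (He − Ho)/He, negative under
heterozygote excess, undefined for monomorphic cohorts.

Allelic richness is hypergeometric rarefaction to a standardized number
of gene copies g (default 2 × the smallest population): the expected
number of distinct alleles in a g-copy draw without replacement,
Σ_i [1 − C(N−N_i, g)/C(N, g)], averaged over loci; missing data are
handled locus-wise through the per-locus N. Private allelic richness
multiplies the focal population's capture probability by the product of
non-capture probabilities in every other population, treating the
per-population draws as independent. Both are tested against exhaustive
enumeration of all draws on small allele-count configurations.

## Effective population size from LD decay

Intra-chromosomal SNP pairs are binned on genetic distance c
(default 20 log-spaced bins over 50 kb–4 Mb); bin-mean genotype r² is
adjusted for sample size by subtracting 1/(2n) (unphased; 1/n for
phased input). Each bin inverts the Sved relation

    Ne(t) = (1/(4c)) (1/E[r²'] − α),   t ≈ 1/(2c)

with α selectable from {1, 2, 2.2}: α = 2.2 (mutation-drift
correction) is the default for real chip data, α = 2 the no-mutation
preset, and α = 1 the original phased/full-population form. Ne at a
target generation count is read from the nearest-t bin; targets outside
the trajectory span are served from the nearest bin but flagged
extrapolated. On the simulator's constant-Ne cohorts the α = 1 preset
is the calibrated choice — the simulation is mutation-free and the full
population is genotyped — and recovers the truth within the tested
±40%; the α = 2/2.2 presets are biased low at small Ne under MAF
conditioning, a known property of segregation-conditioned r² that users
should keep in mind when comparing presets.

## Runs of homozygosity

Detection reproduces the classic sliding-window scan: 50-SNP windows
advance one SNP at a time; a window passes with ≤ 1 heterozygous and
≤ 1 missing call; a SNP is in a run when ≥ 5% of its covering windows
pass. Maximal flagged stretches become candidates; a candidate admits
at most one heterozygous call (an excess het ends the run before it and
restarts after it), splits at inter-SNP gaps > 250 kb (each piece
re-tested), and must be ≥ 1 Mb long, contain ≥ l SNPs and average at
most 100 kb/SNP. The false-positive-controlling minimum SNP count

    l = ln(α / (ns · ni)) / ln(1 − het),   floored to an integer

uses the cohort's SNP count, sample count and mean observed
heterozygosity; flooring (rather than rounding) is the documented
choice and reproduces the published per-breed thresholds either way.
F_ROH divides a sample's summed ROH length above a minimum (1, 5 or
10 Mb) by the autosomal SNP coverage (2.648 Gb for the ovine 50K map;
configurable). Length classes are [1–5], (5–10], (10, ∞) Mb with the
5 Mb boundary closed in the first class. The recent-inbreeding share is
100 × F_ROH(10 Mb)/F_ROH(1 Mb). The detector's correctness reference is
an independent direct-scan oracle that recounts windows per SNP.

## d_i standardized-FST scan

Per-SNP two-population FST is the Weir–Cockerham (1984) variance
components estimator θ = a/(a+b+c) computed from sample sizes, allele
frequencies and observed heterozygosities; negative estimates are kept.
For focal population i,

    d_i = Σ_{j≠i} (FST_ij − E[FST_ij]) / sd(FST_ij)

with pair means and SDs taken genome-wide over the SNPs defined in
every pair. The per-pair sum is the primary mode; a pooled
(focal-vs-rest) two-population mode is available because study
descriptions sometimes collapse the comparison group. d_i is averaged
over a fixed, non-overlapping 1-Mb grid anchored at position 1 per
chromosome; windows with < 5 scored SNPs are uninformative; the top 1%
(count by ceiling, ties at the cut included) are putative selection
regions. A Hudson-estimator flag supports sensitivity analysis.

## XPEHH scan

Site-EHH at offset k from a core SNP is the probability two random
haplotypes are identical over [core … core±k] (allele-agnostic,
matching the site-integrated construction); EHH at the core is 1 by
definition. Curves truncate when EHH < 0.05 or at gaps > 250 kb (both
configurable; these are scan-context conventions, not published
values). iES integrates the bidirectional curve over genetic distance
by the trapezoid rule. XPEHH is ln(iES_A/iES_B) standardized by one
genome-wide mean and SD (no frequency binning), and significance is
expressed as

    pXPEHH = −log10(1 − |2Φ(XPEHH) − 1|) = −log10(two-sided p)

so the threshold 5 is exactly p = 1e−5. SNPs significant in every
pairwise comparison are chained per chromosome into candidate regions;
chaining closes a region when adding the next SNP would push its span
past ~1 Mb, which keeps the stated chaining rule and the region-span
bound simultaneously consistent. Regions from both scans intersect into
overlap regions by plain interval algebra. A numba kernel accelerates
the per-core iES sweep; a pure-numpy twin of the kernel is the tested
reference and the automatic fallback.

## Synthetic cohorts

The generator runs a discrete-generation Wright–Fisher forward
simulation on haplotypes: Poisson crossovers on the linear map,
multinomial parent sampling weighted by additive sweep fitness
(1 + s per derived copy), optional partial selfing, an ancestral
burn-in to build LD, then a split into labeled populations. Sweeps are
hard by default: one derived copy injected on a single haplotype at the
split (re-injected on early loss), so hitchhiking traces one origin.
All randomness derives from a single seed through `SeedSequence`
spawning; identical configurations are byte-reproducible.

Default conditions emulate a four-breed Balkan-sheep chip study at desk
scale: pre-QC cohorts of 45/29/23/16 diploids, six 40-Mb autosomes at
~1 SNP/50 kb (chip-like density), ancestral Ne 200 with a 40-generation
burn-in, a split 20 generations before sampling at per-breed Ne 300,
and 3% selfing in the focal breed, which gives it the lowest
heterozygosity, the highest F_ROH and its own MDS cluster, in the
proportions the published diversity tables show. The 3 cM/Mb map rate
is a deliberate desk-scale compression: it shrinks the sweep footprint
relative to the 1-Mb window grid so that a scan over ~480 windows
resolves a sweep the way the full 26-autosome scan (~2,500 windows)
does. Dose–response checks (selfing vs F_ROH, split depth vs FST,
bottlenecks vs Ne trajectories) use dedicated single-knob
configurations.

What the simulator does not emulate: chip ascertainment bias beyond a
uniform founder MAF ≥ 0.05, variable recombination maps, genotyping
error, mutation, and overlapping-generation herd structure. Passing
power tests therefore show the scans behave correctly under idealized
textbook genetics at reduced scale — not that the pipeline's power on a
real 50K dataset equals the measured rates.

## Numerical and testing choices

Undefined quantities are explicit: NaN r² pairs never prune, NaN FST
SNPs are excluded from d_i and its standardization, zero-iES SNPs are
skipped and logged, degenerate XPEHH standardization (zero variance) is
flagged rather than silently zeroed. Determinism is enforced by
canonical tie-breaks (later map order, later sample order, sign
canonicalization of MDS axes by largest loading). Test problem sizes
are chosen for single-CPU desk runs: oracle equivalences use ≤ 160-SNP
chromosomes; recovery and power suites use 5–10 fixed seeds of the
default-scale simulation, with the sweep and neutral cohorts shared
across tests. Known limitations: the BED codec supports SNP-major
PLINK 1.9 only; multiallelic sites, sex chromosomes and dosage formats
are out of scope; phasing is an input requirement (the pipeline never
phases); binned standardization of XPEHH by allele frequency is not
implemented.
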