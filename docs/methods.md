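# Methods

`fadsmets` re-implements, as a tested pipeline over synthetic cohorts, a
two-part analysis of metabolic syndrome (MetS): (1) discovery of two
fatty-acid (FA) phenotypes by stepwise discriminant variable selection and
Ward clustering of the plasma-phospholipid FA panel, and (2) association of
*FADS1*/*FADS2* genotypes, alleles and EM-inferred haplotypes with those
phenotypes. Because no individual-level data are deposited with the source
study, a synthetic-cohort generator reproduces the published study
conditions, and all simulation-based checks are run against its known
ground truth.

## Synthetic cohort generator

The generator follows the causal chain

    haplotype pair -> latent cluster -> (FA profile, clinical traits, group label)

**Genotypes.** Eight biallelic SNPs in map order rs174537, rs174545,
rs174546, rs968567, rs174570 (the haplotype block), then rs174575,
rs174602, rs174589. Each subject receives two independent draws from a
haplotype pool (random mating, hence Hardy-Weinberg equilibrium in
expectation) and phase is discarded. The pool's five-SNP core frequencies
are the published block haplotypes GGGCC/TCATC/TCACT/TCACC at
66.2/14.9/13.0/4.9%, renormalized by 0.990 to sum to one (the remaining
published haplotypes are each below 1%). rs174545 and rs174546 states are
deterministic copies of the rs174537 state, so their pairwise r² is exactly
1 by construction. The three non-block SNPs are appended per core haplotype
from a conditional minor-allele table (`cohort.TAIL_CONDITIONALS`)
calibrated so the marginal minor-allele frequencies approximate the
published stratum tables (~0.235, ~0.176, ~0.180) while keeping their D′
with the block below the block-defining threshold. Map positions are
approximate but order-correct within chr11:61.79-61.86 Mb.

**Latent clusters.** P(cluster 1) = logistic(β₀ + e(h₁) + e(h₂)) with
β₀ = −0.25 and e = +0.45 for GGGCC-core haplotypes, −0.45 otherwise. These
three numbers were derived in closed form from the published margins: they
give P(cluster 1) = 0.514 (published 180/354 = 0.508), a 57% major-allele
homozygote share in cluster 1 (published 55.3%) and 32% in cluster 2
(published 32.1%).

**FA profiles.** Each of the 18 panel FAs is drawn log-normally per
cluster, parameterized by the published cluster medians and IQRs (rows
published as mean ± SD are converted with IQR = 1.349·SD); σ of the log
follows from asinh(IQR/2m)/0.6745. Rows are renormalized to the cluster's
location total (percent-of-total scale). Draws are independent across FAs
within subject; we examined within-family correlated noise and found it
only degrades cluster recoverability, so the simpler independent model is
kept. The generator therefore reproduces marginal locations, spreads, skew
and compositional closure, but not the cross-FA correlation structure of
real plasma phospholipid data — pass/fail results on synthetic cohorts
speak to the machinery, not to biological effect sizes.

**Clinical traits and groups.** Weight, waist, glucose, insulin and
triacylglycerols are drawn per (group, cluster) from the published
summaries (log-normal for skewed traits, normal for waist); HOMA-IR is
computed as insulin·glucose/22.5. Group sizes are exact (166 MetS/188 CON
by default): the MetS total is split between the clusters in proportion to
n_c·P(MetS|c) with P(MetS|cluster 1) = 109/180 and P(MetS|cluster 2) =
57/174, and subjects are picked uniformly within cluster. A configurable
genotyped subset (330 by default) emulates sample attrition. A single RNG
seeded from the config drives every draw; sub-operations take explicit RNG
handles.

## FA metrics

Family sums use fixed membership lists (ΣSFA = {14:0, 16:0, 18:0}; ΣMFA =
the four 16:1/18:1 isomers; Σn-6 and Σn-3 = the panel's n-6/n-3 members),
which partition the 18-key panel. Desaturase indices are per-subject
product/precursor ratios — D9D-16 = 16:1n-7/16:0, D9D-18 = 18:1n-9/18:0,
D6D = 18:3n-6/18:2n-6, D5D = 20:4n-6/20:3n-6 — never ratios of group
summaries; zero denominators yield NaN rather than an error. Group
comparisons use Student's t when both samples pass Shapiro-Wilk at 0.05 and
the Wilcoxon rank-sum otherwise, with Benjamini-Hochberg adjustment across
a trait family; covariate adjustment is an OLS ANCOVA (trait ~ group +
covariate). These classical tests are delegated to scipy/statsmodels.

## Stepwise discriminant selection

Wilks' Λ = det(W)/det(T) on the candidate subset (within-group and total
corrected SSCP matrices; Λ = 1 for the empty subset). Variables enter
greedily by the partial-Wilks F-to-enter,
F = ((n−g−p)/(g−1))(Λ_before/Λ_after − 1), which for the first entered
variable with two groups reduces exactly to the one-way ANOVA F (a tested
identity). Defaults: entry threshold F = 4.0 (the conventional stepwise
default; the source names the criterion but no threshold), at most six
variables (the source outcome), ties broken by variable name. The fitted
discriminant is Fisher's direction W⁻¹(m₁−m₂) — computed with a
pseudo-inverse so exact collinearity degrades gracefully — with a midpoint
threshold (equal priors) and resubstitution accuracy, matching the
protocol that reported a 69.8% correct classification.

On synthetic cohorts the selection typically admits only one to four FAs,
dominated by 18:2n-6: with FA distributions tied to the latent cluster
only, the group signal is the cluster signal diluted by the cluster-group
mixing, and two of the six source-selected FAs (14:0, 18:0) have
near-identical cluster medians in the published tables, leaving them
nothing to contribute. The printed per-variable F values are final-model
statistics on the unavailable real data and are not reproducible.

## Ward clustering

Agglomerative minimum-variance clustering via the Lance-Williams
recurrence on d(i,j) = ||xᵢ−xⱼ||²/2, so that each merge height is exactly
the increase in total within-cluster sum of squares and the heights sum to
the total SS about the grand mean (an exact, tested invariant; the common
"Ward on Euclidean distance" convention reports √(2·ΔSS) and is verified
equivalent against scipy). Merge ties break on the smallest (min leaf of
A, min leaf of B). Cutting at k undoes the last k−1 merges; with k = 2 the
cluster with the higher MetS fraction is named "1" (ties broken by higher
mean 20:3n-6). Clustering runs on the raw percent scale by default: the
source protocol ("Ward's minimum variance method with Euclidean measure"
in classical statistics software) does not auto-standardize, and on the
generator's own cohorts z-scoring up-weights the ~12 no-signal FAs and
measurably degrades recovery; a `standardize` flag provides the z-scored
mode.

**Known limitation.** With latent clusters calibrated literally to the
published observed-cluster medians/IQRs, cluster recovery tops out below
the generator's information content: the Bayes rule on the true generative
parameters reaches mean Rand ≈ 0.92 and k-means ≈ 0.88, but greedy Ward
attains mean Rand ≈ 0.82 with ≥ 0.8 in only ~76% of seeds (best variable
set). Published cluster summaries describe clustering *output* (boundary-
sharpened), so calibrating latent components to them understates
separability; we deliberately do not sharpen the generator to compensate.
The corresponding recovery check in the acceptance suite fails at its
stated 90% bar and is reported as-is.

## Genetic association

Genotype case-control tables (2×3, ordered AA/Aa/aa by the declared major
allele) are tested with the uncorrected Pearson χ²; allele tables (2×2,
derived by A = 2·AA + Aa) with Yates' correction (|O−E|−0.5 floored at 0).
This combination reproduces every printed statistic from the published
count tables to the printed precision, including the 2×2 cluster-by-group
statistic (χ² = 26.35). Genotype classes absent from both strata are
dropped before the test (df adjusts); missing calls are excluded pairwise
per SNP with a logged count. The Hardy-Weinberg test compares (AA, Aa, aa)
to n(p², 2pq, q²) with df = 1 — the standard for a biallelic locus with
one estimated allele frequency; the source's stated "d.f. = N−2" is
nonstandard and ambiguous and was deliberately not used. BH adjustment is
applied per scan family (genotype family and allele family separately).

## Haplotype inference

Multilocus haplotype frequencies are estimated by the classical EM for
unphased genotypes (Excoffier-Slatkin style): compatible haplotype pairs
are enumerated once per subject (2^(h−1) pairs for h heterozygous loci,
bitmask-coded), the E-step weights each pair by 2f_af_b (f_a² if
homozygous) normalized within subject, and the M-step re-estimates
frequencies from expected counts; iterations run as vectorized segment
sums. Defaults: product-of-marginals start plus two seeded Dirichlet
restarts (best likelihood kept), tolerance 1e-6 on the max frequency
change, 1000 iterations cap, 1% reporting floor. The log-likelihood is
non-decreasing by construction and asserted in tests; on two-locus toys
the EM optimum matches an exhaustive simplex-grid likelihood search, and
on 2000-subject cohorts it recovers the configured block frequencies
within ±0.006.

Pairwise LD derives from two-locus EM frequencies: D = f(AB) − f(A)f(B),
D′ = |D|/D_max (D_max = min(f(A)f(b), f(a)f(B)) for D > 0, else
min(f(A)f(B), f(a)f(b))), r² = D²/(f(A)f(a)f(B)f(b)). Monomorphic loci
yield flagged undefined LD. Blocks are maximal contiguous runs of loci
with every within-run D′ ≥ 0.8 — a documented, deterministic substitute
for likelihood-based block/phasing software (GERBIL/Haploview), whose
internals are out of scope. Per-subject phasing is the MAP compatible pair
under the fitted frequencies with its posterior; ties break
lexicographically and incompatible genotypes fall back, flagged, to a
uniform choice.

The haplotype-cluster scan converts per-group EM frequencies to expected
allele counts (2n_g·f, kept at 0.01 resolution), tests each common
haplotype against the pooled remainder in a 2×2 χ², and corrects for
multiplicity with a max-statistic label permutation: for every permuted
labeling the per-group EM is re-fitted (the candidate haplotype list
depends only on the genotypes and stays fixed) and the corrected p-value
is the fraction of permutations whose maximum statistic reaches the
observed one, with the usual (1+b)/(1+B) estimator. Under null cohorts the
family-wise error sits at ~0.05; on default-effect cohorts the GGGCC and
TCACT haplotypes emerge as the significant pair, mirroring the published
pattern.

## Problem sizes and numerical choices

Simulation-based checks use: 2000 subjects for EM frequency recovery, 50
seeded cohorts of 354 for cluster recovery, 120-150 null cohorts with 500
permutations each for calibration, and exhaustive Ward oracles up to
n = 40 — sizes chosen so each check is statistically informative while the
whole suite runs in a few minutes. Degenerate inputs are contracts, not
crashes: empty haplotype pools, monomorphic loci, zero-margin tables,
constant traits and missing prerequisite files raise typed errors or
flagged fallbacks as described above. All randomness flows from explicit
integer seeds; every pipeline artifact is byte-identical across reruns
with the same seed.
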