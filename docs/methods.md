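# Methods

This note records the models behind `breedrisk`, the defaults and why
they were chosen, what the synthetic cohort does and does not emulate,
and the numerical decisions a maintainer would want to know.

## Association model

Case/control status is analysed on the observed 0/1 scale with the exact
linear mixed model

    y = Wα + xβ + u + ε,  u ~ N(0, σ²_g K),  ε ~ N(0, σ²_e I).

`K` is the centered cross-product relatedness matrix over polymorphic
SNPs, `K = X_c X_cᵀ / p`; missing dosages contribute the SNP mean (zero
after centering). The variance ratio δ = σ²_g/σ²_e is profiled per SNP by
restricted maximum likelihood on the eigenbasis of `K`: after rotating by
the eigenvectors the covariance is diagonal, every REML evaluation is
O(n·c²), and a 1-D bounded Brent search over log δ ∈ [−12, 12]
(argument tolerance 1e-8) finds the optimum. The Wald statistic
(β/se)² is referred to an F(1, n−c) null, i.e. a t-test with the REML
variance estimate; with `K = I` this reduces *exactly* to ordinary least
squares, which the tests assert at 1e-6 relative tolerance against an
independent OLS fit.

A SNP that is numerically collinear with the fixed covariates — the
self-conditioning case where the lead SNP's own dosage is the covariate —
carries no additional information; it is reported with β = 0 and p = 1
rather than a spuriously finite Wald value. Monomorphic SNPs yield NaN
rows. SNPs with missing genotypes are tested on the called subset with
the kinship sub-matrix re-factorised (pairwise exclusion, never silent
imputation); this is exact but slow, so cohorts with pervasive
missingness should be filtered first.

Binary traits on the observed scale follow the convention of the Wald
analyses this package mirrors: reported PVE percentages are
observed-scale, and no liability transform is applied.

### Genome-wide thresholds

λ is the median association χ²₁ over its null median 0.4549. Bonferroni
is α/m with a −log10 accessor. The permutation threshold permutes
phenotype labels jointly against genotype and covariate rows, records the
genome-wide minimum p per permutation, and reports the α-quantile of that
null plus max-T–adjusted per-SNP empirical p-values `(r+1)/(B+1)`; the
seed is a required argument of the stochastic path.

### Variance explained

Per-region PVE uses a GRM built from the region's SNPs, normalised to
unit mean diagonal so PVE = σ²_g/(σ²_g+σ²_e). The SE comes from the
inverse numerical Hessian of the restricted likelihood in (σ²_g, σ²_e)
(central differences, step 1e-4·(σ²_g+σ²_e)) via the delta method; the
LRT against σ²_g = 0 uses the ½χ²₁ boundary mixture. The joint model
fits one variance component per region plus a whole-genome component by
direct Nelder–Mead on log-variances with Cholesky solves; it is O(n³)
per evaluation and intended for n ≲ 1,000. Non-convergence is flagged on
the result object, never silently zeroed.

## Risk-haplotype delineation

Carriers are cases with ≥ 1 copy of the risk allele at the lead SNP (the
array data are unphased). At every other SNP the *case-associated
allele* is the majority allele among carriers — a consensus-haplotype
surrogate that needs no phasing — with ties broken toward the allele
whose dosage correlates positively with the lead risk-allele dosage.
Walking outward from the lead, a carrier is *lost* once it fails to
carry the case-associated allele at any intervening SNP (continuous
sharing; missing genotypes do not break sharing). The boundary is the
last SNP before the first position where the cumulative loss count
reaches the threshold (default 3 carriers) and remains there for the
persistence window (default 1,000 bp). Because cumulative losses are
monotone the persistence check is a direct scan of the next kilobase.
With losses below threshold the haplotype extends to the chromosome
ends, which is the honest answer on a cohort with no recombinant
carriers.

Sharing profiles report, per SNP and group (case/control carriers), the
fraction still in continuous sharing and the fraction matching the
case-associated allele after an interruption ("re-gain"); a group with
no carriers is flagged empty rather than reported as zero sharing.
Haplotype dosage for penetrance-style tables is 2 when homozygous for
the case-associated allele at every interval SNP, 1 when carrying at
least one copy throughout, else 0.

Block uniqueness on phased panels reports *minimal private blocks*:
windows of consecutive sites whose joint allele string occurs in no
background haplotype, minimal in the sense that every proper sub-window
does occur. Maximality in the opposite direction is vacuous (any
superset of a unique window is unique), so minimal windows are the
informative objects.

## Variant filter cascade

Stage 1 retains variants whose alternate-allele dosage equals each WGS
genome's known haplotype dosage exactly (het samples must be 0/1, not
1/1 — a variant riding the shared haplotype appears on exactly that copy
number). Missing calls exclude the variant unless `allow_missing` is
set. Stage 2 keeps panel allele frequency strictly below the cutoff
(default 0.5), with panel-absent variants treated as frequency 0 and
logged; the panel must exclude the focal breeds. Stage 3 keeps variants
inside ≥ 1 regulatory interval, recording which sources overlap. Stages
2 and 3 are per-variant predicates, so their order cannot change the
final set — a property the tests assert. Multi-allelic records are
decomposed to per-alternate rows before filtering. A logging hook flags
mostly-missing genotype patterns as candidates for read-level
inspection, which is outside this package's scope.

## Motif scoring

PWM probabilities are (pfm + pc·background)/(1 + pc) with residual zeros
floored at 1e-9. Log2 odds scores are discretised to a 1e-3 bin before
scanning, so the reported best-site score and its p-value live on the
same grid and the p-value — the tail mass of the exact DP convolution of
per-column score distributions under the background — is *exact* for
that grid. The tests assert bit-level equality against exhaustive 4^k
enumeration up to k = 8. The scan statistic is the best site over both
strands (motif-occurrence semantics); q-values are BH across motifs per
window.

The affinity path follows the TRAP formulation: per-site mismatch energy
E = λ⁻¹ Σ_j ln(w_max,j/w_j(base)) with λ = 0.7, site occupancy
R₀e⁻ᴱ/(1+R₀e⁻ᴱ) with ln R₀ = 0.584·w − 5.66, summed over all positions
and both strands. Ambiguous bases contribute the column-mean energy in
the affinity path and zero log-odds in the scan path.

A consensus call requires the same motif significant in the scan path
(BH-adjusted p < α in either allele window) *and* an allele affinity
log10-ratio of magnitude ≥ 0.5; the affinity criterion operationalises a
"half a log" difference because the affinity statistic has no
distributional null here. Indel windows differ in length and are scored
independently, without alignment.

## Expression

Size factors are median-of-ratios over genes expressed in every sample.
The DE test is a deliberately compact negative-binomial Wald: per-gene
method-of-moments dispersions (floor 1e-8) are empirical-Bayes squeezed
toward the genome-wide median with 10 prior degrees of freedom, the
log2 fold-change SE comes from the delta method on NB group means (a
half-count stabiliser guards near-zero means), and the statistic is
referred to t with prior_df + n_A + n_B − 2 df. The squeeze is the
smallest moderation that keeps the null calibrated (KS < 0.05, type-I
≈ 5% at 4–6 samples/group) while retaining power for a ten-fold spike
under BH across 2,000 genes; an unmoderated normal reference fails the
first property, an unmoderated t the second. This stage is a documented
simplification, not a reproduction of any published DE package: no
count-model GLM, no dispersion trend, no LFC shrinkage.

The variance-stabilising transform is log2(count/size_factor + 1).
Individual z-scores compare one sample to the control mean and (n−1) SD
per gene on the VST scale, flagging |z| ≥ 2.5; zero-variance genes are
flagged undefined. ASE records are tested by 1-df chi-square against a
configurable expected ratio (default 0.5, no reference-bias correction),
records below depth 10 are skipped, and a variant is prioritised when
significant in ≥ 2 individuals. The rank-sum test enumerates the exact
tie-aware null by a subset-sum DP over doubled midranks for ≤ 25 total
observations (two-sided p doubles the smaller tail), switching to the
tie-corrected normal approximation with continuity correction above
that.

## Penetrance and cohort statistics

Penetrance is round(100·cases/(cases+controls)) per two-locus genotype
class, with empty classes reported "−" rather than 0. Fisher's exact
two-sided p sums hypergeometric outcome probabilities no larger than the
observed one (scipy's implementation of the minimum-likelihood rule; an
independent enumeration oracle backs it in the tests); the OR is ad/bc
with Woolf log-method CIs and the Haldane–Anscombe 0.5 correction when
any cell is zero. Allelic vs genotypic 2×2 construction is the caller's
choice; the examples use allele counts (2n per group). Fisher
combination refers −2Σln p to χ²_2k; Stouffer halves two-sided inputs,
applies per-cohort effect directions (all-concordant by default, the
shared-risk-allele assumption), and doubles the combined tail — it is
only a calibrated p-value when true directions are supplied.

## Synthetic cohort: what it emulates, and what it does not

Defaults are the study conditions wherever a printed value exists: 177
cases/132 controls at ~108k SNPs on 38 autosomes (desk-scale runs use
`CohortConfig.desk_scale`, which shrinks the map but keeps frequencies
and penetrances); the two-locus penetrance table with never-observed
classes at a 5% background risk (unobserved ≠ impossible); risk
frequencies 0.403 (haplotype) and 0.786 (second-locus allele)
recomputed from the printed control genotype counts; control ages ≥ 10
years. Where no value is printed, one realistic choice was fixed:
uniform control ages over [min_age, min_age+4]; case ages uniform on
[4, 12) (matching an upper age quartile near 10); a two-subpopulation
Balding–Nichols F_ST of 0.05 with a 50/50 split; LD blocks of 500 kb
copied from pools of 16 founder haplotypes per subpopulation (a breed
bottleneck analogue); RNA-seq with NB dispersion 0.1, a 10.9-fold spike
gene, and allelic imbalance 0.7 at depth 60; a WGS layer whose
rare/regulatory fractions mirror the shape of the published cascade
(218/284 below the frequency cutoff, 98/218 in regulatory DNA).

Case status is Bernoulli per genotype-class penetrance. Quota-filling
(fixed case/control counts) *conditions* the sample, so empirical
penetrance and allele-frequency checks use the `unconditional_n` path,
which draws dogs with their natural status; the generative SE of a
cohort allele frequency includes founder-pool and between-subpopulation
variance, pq(1/n_founders + F/2 + 1/(2n)) against which the 3-SE
convergence test is run.

Not emulated: coalescent-accurate breed demography, recombination
hotspots, genotyping error, read-level data (FASTQ/BAM), reference
bias in allelic counts, and LD decay within blocks (block copying gives
piecewise-constant haplotypes). Passing tests therefore demonstrate the
statistical machinery — calibration, recovery of embedded truth, oracle
equivalence — not robustness to artefacts of real array or sequencing
data.

## Problem sizes and runtime

The test and acceptance runs use sizes chosen to make every property
measurable on one CPU in minutes: null calibration at 500 samples ×
1,000 SNPs (type-I error) and × 5,000 SNPs (λ); PVE recovery at 1,000
samples × 500 SNPs over a {0, 0.1, 0.22, 0.35} grid; permutation checks
at 40 × 25 with up to 49 permutations; the end-to-end synthetic GWAS at
309 dogs × 2,000 SNPs; penetrance convergence at 10,000 dogs. The
full-scale default map (~108k SNPs) is practical for the generator and
a single scan (a few minutes) but not for permutation studies.

## Known limitations

- The LMM is linear on 0/1 status; no logistic mixed model or
  liability-scale PVE.
- Per-SNP REML optimisation is exact but Python-loop bound: ~2 ms/SNP at
  n = 500, so multi-million-SNP scans belong in specialised tools.
- The joint multi-GRM fit reports no SE (the profiled Hessian is not
  computed for the multi-component case); its PVE and LRT are.
- `block_uniqueness` is O(targets × backgrounds × sites) and intended
  for candidate regions (~10² sites), not chromosomes.
- The DE stage's moderation is global (one prior df, one prior value);
  genes with strongly mean-dependent dispersion are mildly mis-served.
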