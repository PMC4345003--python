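# Methods

## Search strategy

The pipeline searches for two-locus (epistatic) effects on transcript
abundance without enumerating all SNP pairs. For each tissue run it

1. filters SNPs (autosomal; MAF strictly > 0.2; missingness ≤ 0.2;
   Hardy-Weinberg chi-squared p ≥ 0.05) and keeps the most variable
   transcripts (top ⌈5 %⌉ by interquartile range, after removing
   probes whose genomic footprint contains a catalogued SNP);
2. estimates population stratification by genotype PCA with iterative
   outlier removal, retaining the components that are significant
   under a Tracy-Widom test as regression covariates;
3. scans every (selected probe, SNP) combination with rank-transform
   regression, labels each test cis or trans by the distance between
   the SNP and the probe midpoint, and applies Benjamini-Hochberg
   FDR separately within the cis and trans pools;
4. forms candidate pairs from SNPs gated at FDR < 0.5 — cis × trans
   under a 1 Mb cis window, or unordered cis × cis under a 10 Mb
   window with pair distance in [100 kb, 10 Mb] — excluding
   intra-chromosomal pairs with LD r² ≥ 0.01 and any pair with fewer
   than 10 complete-case individuals in one of the nine two-locus
   genotype cells;
5. fits `rank(y) ~ gA + gB + gA·gB + PCs` per surviving pair and
   declares significance by the t test of the product coefficient at
   the Bonferroni level α/(number of tests actually fitted in the
   run). Cell-filtered and rank-deficient pairs are excluded from the
   denominator.

The liberal FDR gate at the marginal stage is intentional: the gate
only has to *enrich* the pair search space, and the family-wise error
of the final interaction calls is controlled by the Bonferroni step,
not by the gate.

### Conventions

* SNP positions are 1-based; intervals (probes, tracks, Hi-C
  fragments) are 0-based half-open. A SNP at position p lies in
  [s, e) iff s ≤ p − 1 < e.
* "Within X" windows are inclusive (≤) everywhere: cis classification,
  the cis-cis distance band, and the ±5 kb Hi-C mapping window.
* Genotypes always count the minor allele; readers flip any column
  whose coded-allele frequency exceeds 0.5. In PED input the minor
  allele is the rarer observed allele; on an exact frequency tie the
  lexically smaller allele is taken as major.
* Probe midpoint is ⌊(start + end)/2⌋; quartiles for the IQR use
  linear interpolation between order statistics (type 7); the
  top-fraction probe count rounds up, so small panels never select
  zero probes; ties at the cutoff break by probe id.
* Marginal FDR is computed per run per class (cis vs trans pools
  across all tested SNP-probe combinations), not per probe.
* Each test is complete-case: individuals missing that SNP, that
  probe, or any covariate are dropped for that test only, and the
  response ranks are recomputed within the retained subset.

## Component details

**Rank-transform regression.** Non-missing response values are mapped
to ranks 1..m with midranks for ties; covariates and genotypes enter
on their raw scale. Under the global null the resulting t-test
p-values are uniform for any continuous error distribution (ranks are
exchangeable), which the suite verifies by KS test under gaussian and
lognormal noise.

**Hardy-Weinberg test.** Pearson chi-squared of the three observed
genotype counts against n·(p², 2pq, q²) from the observed allele
frequency, 1 df, no continuity correction; monomorphic SNPs carry no
evidence of departure (p = 1).

**PCA and Tracy-Widom.** Each SNP column is mean-centred and scaled
by √(p̂(1−p̂)); missing entries become zero after centring (mean
imputation for the decomposition only — downstream regressions stay
complete-case). The individual × individual covariance is
eigendecomposed via the smaller Gram matrix; component signs are fixed
by making the largest-magnitude loading positive. Successive lead
eigenvalues are normalised with an effective marker number estimated
from the first two moments of the remaining spectrum and compared with
embedded TW₁ upper quantiles (α ∈ {0.1, 0.05, 0.01, 0.001}); testing
stops at the first non-significant component. Outlier removal uses
the conventional defaults: up to 5 refit iterations removing
individuals beyond 6 SD on any of the top 10 components. The number
of PCs used as covariates equals the Tracy-Widom count unless the
configuration pins `n_pcs` explicitly (runs on real cohorts sometimes
use more components than are formally significant).

**LD r².** Maximum-likelihood haplotype frequencies are estimated by
EM over the 3×3 genotype table (only the double heterozygote is phase
ambiguous; convergence tolerance 10⁻¹⁰, ≤ 1000 iterations), then
r² = D²/(pA(1−pA)pB(1−pB)). A monomorphic margin makes r² undefined
and is reported as 0 with a warning. The estimator requires ≥ 20
complete individuals (EM is unstable below that). A composite
(dosage-correlation) estimator is available behind a keyword for
sensitivity analysis.

**Redundancy grouping.** Two significant interactions for one probe
merge when their SNP pairs can be matched in either orientation with
each matched pair identical or in LD at r² ≥ 0.5 (configurable — the
collapse threshold is a package choice; observed redundancy clusters
in practice sit at r² > 0.9) and their interaction coefficients agree
in sign; groups are the transitive closure.

**Stepwise AIC.** Bidirectional selection from the full model over
all main and interaction terms, AIC = n·ln(RSS/n) + 2k; the single
best move is taken per step until no move lowers the AIC. Aliased
columns are dropped from the full model first. By default a hierarchy
rule lets an interaction stay only alongside both of its main effects;
`hierarchy=False` reproduces unconstrained selection.

**Nested-model comparison.** Main-effects vs full model: adjusted R²
for both, LRT = n·ln(RSS_main/RSS_full) with a 1-df chi-squared p, and
the interaction variance share as the difference of adjusted R²
(negative values are possible for null pairs).

**Enrichment.** A pair maps to a Hi-C contact when its SNPs lie one
each within ±5 kb (inclusive) of the two fragment alignment starts, in
either orientation. SNP-to-track mapping uses the half-open interval
rule. Enrichment of the significant set over the tested background is
a 2×2 Pearson chi-squared test of independence (1 df, no continuity
correction); the Haldane-Anscombe +0.5 correction applies to the odds
ratio only, and only when a cell is zero. Backgrounds are the tested
non-significant pairs (Hi-C) or the tested SNPs not in any significant
interaction (tracks), with set semantics for SNPs in several
interactions. Sweeps over several tracks/tissues use Bonferroni
α/(number of track × tissue combinations).

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes.

* *Genotypes*: SNPs at evenly spaced positions on one or more
  chromosomes; one ancestral MAF per LD block drawn uniformly from
  `maf_range`. Within a block each haplotype allele copies its left
  neighbour with probability `ld_rho` and is otherwise drawn fresh at
  the block frequency, so adjacent haplotype correlation is exactly
  `ld_rho` and marginal frequencies are preserved; genotype = sum of
  two independent haplotypes. `maf_overrides` pins individual SNPs
  and removes them from the copying chain. Population structure uses
  the Balding-Nichols Beta construction with parameter `fst`
  (subpopulation draws resampled into (0.01, 0.99), error after 100
  attempts). Missingness is uniform at `missing_rate`. Everything is
  bit-reproducible from the seed.
* *Expression*: a planted probe is β1·gA + β2·gB + β3·gA·gB + ε with
  effects on the raw scale (the rank transform is thereby exercised
  nontrivially); unplanted probes are pure noise. Noise options are
  standardised to unit SD before scaling: gaussian, centred lognormal
  (LogNormal(0,1)), and t₃. Individuals missing a causal genotype
  receive noise-only values; complete-case handling downstream is the
  scan's job. `beta3_for_partial_r2` inverts the partial-R²
  relationship at the realised genotypes so studies can plant a chosen
  interaction variance share.
* *Annotations*: causal SNP pairs receive a Hi-C fragment pair (starts
  within 5 kb of their SNPs) with probability fold × base-rate,
  background pairs at base-rate, plus uniformly placed decoy contacts;
  promoter intervals cover causal-pair SNPs at the enriched rate and
  the rest at base rate, enhancer intervals cover all SNPs at base
  rate.

What the generator does **not** emulate: realistic allele-frequency
spectra or LD decay of genotyping arrays, disease-status structure in
the expression, probe-level technical artefacts, or genuine chromatin
geometry. Passing tests therefore demonstrate the statistical
machinery, not performance on any real cohort.

## Calibration studies and their problem sizes

The simulation studies (in `epiqtl.calibration`, re-run by
`scripts/acceptance.py`) use sizes chosen to give stable estimates at
interactive runtimes:

* **Null calibration**: 2000 replicates at n = 500, MAF 0.3, main
  effects β1 = β2 = 0.5σ, gaussian and lognormal noise.
* **End-to-end recovery**: 100 seeded runs of the full cis-trans
  pipeline on 500 individuals × 60 SNPs over two chromosomes (LD
  blocks of 5 at ρ = 0.5, 2 % missingness), one planted pair at MAF
  0.45 with raw-scale interaction partial R² = 0.05 and main effects
  0.5σ. The causal MAF sits in the common-variant regime because the
  9-cell minimum-count filter makes rarer interactions untestable at
  this sample size — the same reason the SNP QC uses a high MAF
  threshold.
* **Distance shift**: 150 significant distances below 2 Mb against
  3000 tested distances uniform on [100 kb, 10 Mb], two-sample KS.

## Known limitations

* **The rank transform does not protect interaction tests under
  skewed noise with strong main effects.** Ranking is a nonlinear
  monotone map, so a response that is additive on the raw scale is
  generally *not* additive on the rank scale. Measured at n = 500
  with β1 = β2 = 0.5σ: type-I error of the β3 test is ≈ 0.041 under
  gaussian noise (mildly conservative) but ≈ 0.22 under lognormal
  noise — far above nominal, while the raw-scale fit stays near 0.05
  there. Under the global null (no genotype effects at all) the rank
  test is exactly calibrated under both noises. Interaction calls on
  strongly skewed expression with large main effects should therefore
  be treated with caution and checked on the raw scale.
* For the same reason, a raw-scale interaction partial R² of 0.05 is
  attenuated roughly twofold on the rank scale, and in the noiseless
  limit the rank-scale p-value saturates at a lack-of-fit floor
  instead of vanishing.
* Stepwise AIC retains a 1-df noise term whenever its LRT exceeds 2
  (probability ≈ 0.16 per candidate), so "no spurious interactions"
  cannot be guaranteed when many candidates enter the search.
* No dominance or four-parameter epistasis models (sample sizes in
  scope cannot support them), no mixed models or kinship correction,
  no permutation-based significance, no imputation of missing
  genotypes, no VCF/BGEN input, no genome-build conversion.
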