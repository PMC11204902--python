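# Methods

## Scope and model

`prscad` evaluates published additive polygenic scores in a biallelic-SNP
case-control panel. The score for individual *i* is the unnormalized
weighted dosage sum PRS_i = Σⱼ β̂ⱼ G_ij with G_ij the ALT-allele dosage in
[0, 2] (imputed dosages are used as-is, never re-hard-called for scoring).
No per-variant normalization is applied — the published weights define the
score. Missing dosages are mean-imputed per variant by default, so a
sporadically missing variant shifts all affected samples by the same
constant and leaves between-sample contrasts untouched (`zero` and
`drop_variant` policies are selectable).

Association is by nested logistic regression of case status. The null
model holds the clinical covariates plus genotype principal components;
the full model adds the z-scored PRS. Both are compared to the
intercept-only fit through Nagelkerke's pseudo-R²
(Cox–Snell R² = 1 − exp((2/n)(ℓ₀ − ℓ₁)) rescaled by its maximum
1 − exp((2/n)ℓ₀)), and the score's contribution is the difference
R²(full) − R²(null). For maximum-likelihood nested fits this difference is
non-negative; the property is asserted across all simulation suites. The
pseudo-R² is on the observed scale; no liability-scale or prevalence
adjustment is applied.

## Harmonization

Score variants are matched to panel variants by (chromosome, position),
with rsID as fallback when the scoring file lacks positions. Orientation
against panel REF/ALT:

| condition                                 | action            | weight  |
|-------------------------------------------|-------------------|---------|
| (effect, other) = (ALT, REF)              | exact             | kept    |
| (effect, other) = (REF, ALT)              | switched          | negated |
| complement(effect, other) = (ALT, REF)    | flipped           | kept    |
| complement(effect, other) = (REF, ALT)    | flipped_switched  | negated |
| {effect, other} ∈ {A/T, C/G}              | ambiguous_dropped | —       |
| anything else                             | dropped           | —       |

Palindromic pairs are strand-unresolvable from alleles alone and are
dropped by default (`assume_same_strand` is available for panels known to
share the score's strand). When the scoring file omits the other allele,
only direct exact/switched matching on the effect allele is attempted;
strand flips are unverifiable with one allele.

Variants absent from the panel are replaced by the panel variant with the
highest r² strictly above 0.8 within ±500 kb (ties: smallest position
distance, then lowest position); the proxy's alleles are re-classified
against the score variant's alleles to orient the weight. r² comes from an
explicit pairwise reference when supplied, else from squared dosage
correlation in the target panel itself. Limitation: r² is unsigned, so a
negatively correlated proxy whose alleles happen to match directly would
keep an uncorrected sign — supplying a phased or signed reference is the
caller's responsibility when that matters; the synthetic proxies used in
testing are exact duplicates (r² = 1), for which the issue cannot arise.

Two score variants never resolve to the same panel column (the second
becomes `dropped: duplicate_target`), and harmonization is deterministic:
identical inputs give identical audits.

## Quality control

Samples: call rate ≥ 0.95 (boundary kept), then genome-wide
heterozygosity within ±3 SD of the panel mean. Heterozygosity and
Hardy–Weinberg counts use hard calls obtained by rounding dosages with
ties-to-even; dosages themselves are retained for scoring. With zero SD
of heterozygosity no sample can deviate, so none are removed. Note the
±3 SD cut flags ≈0.3% of samples of any finite clean panel — its nominal
false-positive rate, which the self-consistency tests account for.

Variants: call rate ≥ 0.98 and HWE exact p ≥ 10⁻⁴, tested on all samples
pooled (controls-only is configurable; pooling is the conservative default
when the provenance of the cohort's convention is unknown). The HWE test
is the standard (not mid-p) exact conditional test: given the observed
allele totals, the p-value sums the probabilities of all heterozygote
counts of the same parity whose conditional probability does not exceed
that of the observed count. Probabilities are computed in log space with
`gammaln`; an exhaustive sweep against exact rational enumeration for all
genotype triples with total ≤ 25 bounds the relative error at ~10⁻¹⁴.

## PCA and Tracy–Widom selection

Dosages are mean-imputed, each variant column is centered by 2p̂ and
scaled by its binomial genotype SD √(2p̂(1−p̂)) (p̂ = mean dosage / 2);
monomorphic columns are removed. The samples × samples covariance
X·Xᵀ/(n−1) is eigendecomposed; coordinates follow the
eigenvector × √eigenvalue convention with each component's
largest-magnitude loading made positive.

Significant components are counted sequentially: for the leading remaining
eigenvalue, the effective number of independent markers is estimated by
matching the first two white-Wishart spectral moments
(E[tr A] = Mp, E[tr A²] = Mp(M+p+1) for A ~ W_p(M), M = number of
remaining eigenvalues), giving n_eff = (M+1)S₁²/(M·S₂ − S₁²); the
eigenvalue is standardized with the Johnstone centering and scaling
constants and compared to the TW1 (1−α) quantile (α = 0.05). Testing
stops at the first non-significant eigenvalue; the count is capped at 15.

The TW1 distribution is evaluated from a numeric CDF table embedded in the
package (grid −6…4.5, step 0.1) with linear interpolation. The table was
computed from the Painlevé II representation of the Tracy–Widom laws
(Hastings–McLeod solution integrated backwards from Airy asymptotics); the
test suite re-derives the CDF with an independent ODE solve and checks the
published 95/99/99.9 percentiles (0.9793, 2.0234, 3.2724). Monte-Carlo
calibration on unstructured binomial panels (n = 200, m = 1000) yields
zero significant PCs in ≳95% of replicates at α = 0.05; two-population
panels at Fst = 0.05 (n = 400, m = 2000) are detected essentially always.

Under strong local LD the leading eigenvalues are inflated and the TW
count tends to hit the cap — a known property of eigenanalysis on
unpruned data. An optional fixed-15 policy is provided; the default
passes the TW-selected count (≤ 15) to the association models. No LD
pruning is applied by default.

## Association details

Logistic fits use Newton iterations (≤ 100, log-likelihood tolerance
10⁻¹⁰) via statsmodels behind the `fit_logistic` surface. Perfect or
quasi-separation (runaway coefficients or non-finite standard errors) is
reported as `converged = False` and the affected score's result is marked
unusable rather than raising. A constant response is an error. Samples
are matched between PRS and phenotypes by id (inner join, logged);
rows with missing covariates are excluded (complete-case, logged).

The PRS enters z-scored, so exp(β̂ₚ) is the odds ratio per score SD; the
per-raw-unit ratio exp(β̂ₚ/SD) is recorded alongside, since published
replication tables do not always declare their scale. The p-value is a
two-sided Wald test; the 95% CI is exp(β̂ₚ ± 1.96·SE). Bonferroni
significance across m scores uses threshold α/m with strict inequality.
Calibration at n = 2000: type-I error 0.03–0.07 at α = 0.05 across
400-replicate batches; planted per-SD OR 1.5 recovered with mean ≈ 1.50
and CI coverage ≈ 0.95 over 200 replicates.

## Synthetic data generator

The generator emulates the study conditions the pipeline targets —
defaults: 924 samples, case fraction 390/924, two subpopulations,
Fst 0.01, 1000 variants in 10-variant LD blocks, MAF ∈ (0.05, 0.5),
20 causal variants, planted per-SD OR 1.5 — while remaining fully seeded
(numpy SeedSequence spawning; identical configs are byte-identical).

* **Structure**: ancestral frequencies are drawn per LD block (with
  SD-0.03 per-site jitter, clipped to the MAF range — neighbouring sites
  must have similar frequencies for the copy model below to generate high
  adjacent r²); subpopulation frequencies follow the Balding–Nichols beta
  model Beta(p(1−F)/F, (1−p)(1−F)/F). Samples alternate between
  subpopulations.
* **LD**: haplotypes are built by a block-copy walk — within a block each
  site copies the previous site's latent uniform with probability
  `ld_decay` (0.9 default) or redraws it, so adjacent r² ≈ ld_decay² and
  blocks are independent. Genotypes are the sum of two haplotypes, hence
  in HWE within subpopulation. Optional N(0, 0.05) dosage jitter (clipped
  to [0, 2]) mimics imputation; optional uniform missingness exercises
  call-rate QC. Variant REF/ALT pairs are drawn from the eight
  non-palindromic ordered pairs so emitted score files are never
  strand-ambiguous by construction.
* **Phenotypes**: covariates are calibrated to the cohort's descriptive
  table — age ~ N(57.7, 12.4) years, 63.9% male, SBP ~ N(132.6, 19.7)
  mmHg, total cholesterol ~ N(200.7, 44.6) mg/dl, 23.5% T2DM, 65%
  smokers. Body weight is not tabulated in the source (only BMI
  28.3 ± 4.4 kg/m²); N(78, 14) kg matches that BMI at typical stature.
  Case status is Bernoulli(logistic(α + log(OR_SD)·z_PRS + Σβ_c·(x_c −
  mean))) with fixed plausible covariate log-odds (0.03/year age, 0.5
  male, 0.4 T2DM, 0.3 smoking) and α solved by root-finding so the
  expected case fraction hits the target.
* **Scoring-file corruption**: emitted files can allele-switch a fraction
  of entries (weight re-expressed for the swapped effect allele, so a
  correct consumer must negate it back), strand-flip a fraction
  (complemented alleles, weight unchanged), or drop a fraction from the
  panel while planting an exact duplicate dosage column 1 kb away as an
  r² = 1 proxy, with the pair written to an external-LD TSV. Every action
  lands in the ground-truth ledger, enabling exact round-trip tests:
  full allele-switch corruption recovers the true weights bit-exactly,
  and proxy substitution reproduces the uncorrupted PRS to ≤ 10⁻¹².

What the generator does **not** emulate: coalescent-realistic haplotype
diversity and recombination maps, allele-frequency/LD differences between
real ancestries, genotyping batch effects, X chromosome, indels,
covariate-genotype correlation, and non-logistic disease architecture.
Passing tests therefore demonstrate the correctness and calibration of
the *pipeline machinery* under its stated assumptions, not the field
performance of any particular published score.

## Problem sizes and numerical choices

Test and acceptance simulations use deliberately compact sizes chosen to
make Monte-Carlo bands tight enough to be meaningful while keeping the
suites quick: association calibration at n = 2000 with 60-variant panels
(400 null / 200 effect replicates), TW calibration at 200×1000 (100
replicates) and power at 400×2000, end-to-end runs at the full 924×1500.
Bit-exactness claims (round-trips, oracles) are independent of size.

Other numerics: dosage hard calls round ties-to-even; HWE tie detection
uses a 10⁻¹² log-probability tolerance; eigenvalues are clipped at zero
and the TW recursion stops if the moment denominator becomes
non-positive; p-values are floored at the smallest positive double;
report percentages print with one decimal and ORs with three.

## Design choices where the design was open

* Variant call-rate criterion implemented as *retain* iff ≥ 0.98 (the
  inverted reading of a self-contradictory exclusion list).
* HWE on pooled samples by default, controls-only available.
* TW-selected PC count (capped 15) is the default covariate policy;
  `fixed15` forces the conventional 15.
* OR reported on both per-SD and raw scales, per-SD as headline.
* Palindromic variants dropped by default.
* Positions are assumed on a shared genome build; no liftover, no
  BGEN/PLINK readers, no indel or multiallelic support (multiallelic VCF
  records are skipped with a warning).
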