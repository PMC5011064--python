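# Methods

`gxeqtl` maps context-specific regulatory variation: genetic variants whose
effect on gene expression depends on a continuous physiological exposure —
here adiposity, measured as BMI (kg/m²) or DXA visceral-fat mass — in a
cohort of MZ/DZ twins with exon-level RNA-seq quantifications and imputed
dosages. This note documents the models, the synthetic-data generator used to
validate them, the numerical choices, and the limits of what the validation
shows.

## Quantification

The unit of analysis is the **meta-exon**: the interval union of all
overlapping (or bookended) annotated exons of a gene. Coordinates are
1-based inclusive internally; BED I/O converts to 0-based half-open.
Counts are depth-corrected by scaling each sample to the **median number of
well-mapped reads**; meta-exons quantified (nonzero) in **strictly more than
90%** of samples are retained ("more than 90%" is read literally as a strict
inequality; the fraction is configurable). Expression is then rank-based
inverse-normal transformed (INT) per meta-exon: Φ⁻¹((r − ½)/n) with average
ranks for ties (rankit offset; Blom available). Missing values keep their
position and are excluded from n. "Quantified" is implemented as a nonzero
count; a minimum-count rule can be substituted by pre-thresholding the matrix.

When the generator's optional count layer is active, a fragment is assigned
to a meta-exon if either aligned end coordinate falls inside [start, end].

## Twin mixed model (phenotype association)

Each meta-exon's INT expression y is modelled as

    y = Xβ + u_family + u_zygosity + ε,

with fixed effects X = {intercept, phenotype, age, age² (from centered age),
mean GC content, insert-size mode} and independent random intercepts for
**family** (shared by co-twins) and **zygosity** (shared only by MZ
co-twins — the extra MZ covariance identifies the additional genetic
sharing of MZ over DZ pairs). The phenotype is tested by a one-degree-of-
freedom likelihood ratio against the same model with the phenotype omitted;
**both fits use maximum likelihood** (REML log-likelihoods are not comparable
across fixed-effect structures), with REML available for variance-component
reporting. The LRT statistic is clipped at 0 and referred to χ²₁. A gene is
called phenotype-associated if any of its meta-exons passes the per-scan
q-value threshold (default 5%).

The solver exploits the pair-block covariance: rotating each twin pair onto
its within-pair sum and difference diagonalizes the model into five
homoscedastic observation classes, leaving a two-parameter profiled
likelihood maximized by L-BFGS-B with per-class Gram matrices (O(p²) per
evaluation). It agrees with `statsmodels` `MixedLM` to ~1e-6 in
log-likelihood, coefficients and variance components, and is roughly two
orders of magnitude faster, which is what makes a 10,000-test type-I
calibration affordable. The cost of this design is that only family and
zygosity can be random effects: primer index and batch, when present, enter
as fixed-effect dummy columns (`categorical_covariates`). Families larger
than two are not supported; non-convergence of the 2-parameter optimizer
falls back to a family-only random intercept and flags the result. If π₀ is
not estimable (panels under 100 exons), q-values fall back to π₀ = 1
(Benjamini–Hochberg).

## Family-structure correction for the scan branches

Interaction scans are OLS-based and need expression residuals "corrected for
family structure and technical variables". These are computed as
**GLS-whitened residuals** from the twin model with fixed effects
{intercept, technical covariates}: in the rotated pair space each GLS
residual coordinate is scaled by 1/√w (w = its variance class weight) and
rotated back. Under the model the result is exactly decorrelated, which
keeps downstream per-pair OLS p-values calibrated; full BLUP subtraction
(1/w) would over-shrink pair sums and induce negative within-pair
correlation. The price is some attenuation of between-family signal — an
inherent cost of removing family structure, visible as a mild power loss
relative to the latent-scale fit.

## Latent factors

Hidden confounders are estimated on the family/technical-corrected residuals
as the top-k left singular directions of the per-feature standardized matrix
(k = 50 by default, clamped below the matrix rank; an EM factor analysis is
available). Factors are ordered by variance explained with the
largest-|loading| entry of each factor forced positive, and each factor's
Pearson correlation with the phenotype is reported. The **cis interaction
scan runs on factor-corrected residuals**, optionally dropping factors whose
|r| with the phenotype exceeds a threshold first (both behaviours are
exposed because removing phenotype-correlated factors reduces collinearity
with the interaction term, while retaining them removes more variance; the
package asserts neither as the only valid choice). The **phenotype
association and the trans scan never use factor correction**: broad factors
absorb multi-gene trans-regulator signal — the validation suite shows a
mediated trans network being captured as a leading factor and its cis
mediator's interaction vanishing from the factor-corrected scan.

## Interaction scans and permutation FDR

The cis scan tests every SNP with |position − TSS| ≤ 1 Mb (MAF ≥ 5%) per
meta-exon under

    y ~ intercept + age + age² + phenotype + dosage + phenotype × dosage

by OLS, with a Wald t-test on the interaction coefficient (equivalent to the
1-df F) and, from the same model without the interaction term, a main-effect
eQTL p-value. Phenotype and dosage are mean-centered before forming the
product; with all main effects present this leaves the interaction
coefficient, SE and p identical to the raw-product parameterization but far
better conditioned. Monomorphic SNPs in the analysis subset are skipped and
logged; exons without cis SNPs produce no rows.

Significance is calibrated by permutation: per exon–SNP pair, all main
effects (phenotype, dosage, age) are regressed out, the residuals are
permuted across samples (the same n_perm = 100 sample permutations for all
pairs, preserving genotype structure; main effects are removed **per pair**
so that the permuted null is exact for the interaction term), and the
interaction p recomputed — vectorized as a single multi-RHS solve per pair.
Because multi-exon genes get more chances at a small p, genes are binned
into quartiles (n_strata = 4) of expressed-exon count and

    FDR(t) = mean permuted count of p ≤ t per permutation
             ÷ observed count of p ≤ t

is computed within stratum and monotonized (suffix-minimum) to be
non-decreasing in p. Pairs with FDR ≤ 0.05 are significant; an estimate of
exactly 0 means no permuted statistic beat the threshold and has resolution
floor 1/(n_perm × observed count).

The trans scan takes the FDR-significant step-1 variants from the
**non-factor-corrected** cis scan and tests them against every expressed
exon farther than 5 Mb (or on another chromosome, distances measured to the
TSS), at the Bonferroni threshold 0.05/(n_variants × n_exons) — with 4
variants and 116,643 exons, 1.1 × 10⁻⁷. For each trans hit, mediation
through the seed variant's top cis exon is then tested.

## Mediation (Sobel) and RTC

For a trans target y, cis mediator expression E, dosage G and phenotype P:

    Model A: y ~ β₁A + β₂A² + β₃P + β₄G + β₅(P×G) + ε
    Model B: y ~ β₁E + β₂A + β₃A² + β₄P + β₅G + β₆(P×G) + ε

    mediation score = (β₅ᴬ − β₆ᴮ)/β₅ᴬ
    Z = β₅ᴬ·β₆ᴮ / sqrt((β₆ᴮ)²·s²(β₅ᴬ) + (β₅ᴬ)²·s²(β₆ᴮ)),

with a two-sided normal p (sidedness is a package choice) and a configurable
call threshold (default p ≤ 0.001). Note a structural property of this Z: it
is a test that the interaction survives in *both* models, so it loses power
as mediation approaches 1 (β₆ᴮ → 0) and is best powered at partial
mediation; the validation suite therefore demonstrates Sobel significance at
fraction 0.5 and score recovery at {0, 0.5, 1}. β₅ᴬ = 0 makes the score
undefined and is flagged rather than propagated. When mediation runs inside
the pipeline it uses family-whitened residuals; because mediator and target
are whitened with their own variance-class weights, the mediated share is no
longer transmitted exactly and the score attenuates somewhat toward zero
(the validation suite measures score recovery on the unwhitened generating
scale, where it is unbiased).

Regulatory trait concordance (RTC) asks whether a GWAS SNP and an eQTL tag
the same signal. Within a window (default 250 kb) around the index SNP, for
every window SNP_N the model

    interaction mode:  y ~ 1 + P×SNP_N + P×eQTL
    main mode:         y ~ 1 + SNP_N   + P×eQTL

records the conditional p of the P×eQTL (or eQTL) term. SNPs are ranked by
**decreasing** conditional p — rank 1 is the SNP whose conditioning
abrogates the signal most — and RTC = (N − Rank_GWAS)/N, so RTC → 1 when the
GWAS SNP explains the regulatory signal and hovers near 0.5 for an unlinked
SNP (its rank is near-uniform among the window's non-LD SNPs). Ties break by
genomic position; a window SNP numerically collinear with the eQTL regressor
(including the eQTL SNP itself) is assigned conditional p = 1. The rank
direction is a documented package convention: it is the one that makes a
perfect proxy score (N−1)/N.

Replication across annotation sets matches meta-exons by **reciprocal
overlap**: with f_A = overlap/len_A and f_B = overlap/len_B, a pair is
`matched` iff both fractions exceed 0.90, `unmatched` with zero overlap, and
`partial` otherwise; when only a partial match exists, all exons of the gene
can be tested with an exon-count Bonferroni correction (0.001 over 30 exons
→ 0.03).

## π₀/π₁

π₀ is estimated on the Storey grid λ = 0.05, 0.10, …, 0.95 via
π₀(λ) = #{p > λ}/(m(1−λ)), smoothed by a **cubic smoothing spline with the
penalty calibrated to 3 effective degrees of freedom** (the smoother-matrix
trace is computed by smoothing unit vectors and the penalty bisected),
evaluated at λ = 0.95 and clipped to [0,1]; a bootstrap minimizer is
available. q-values are q(p₍ᵢ₎) = min_{j≥i} π₀ m p₍ⱼ₎/j. π₁ = 1 − π₀
measures sharing, e.g. of discovery exon–SNP pairs in a replication tissue's
matched p-values; estimates from fewer than 100 matched pairs are flagged
unstable.

## Synthetic cohort generator

The generator is the package's test bed and defines its study conditions.
Defaults: 700 samples (120 MZ pairs, 170 DZ pairs, 120 unrelated — the scale
of a single-tissue slice of an ~856-twin cohort), phenotype ~ BMI with mean
25, SD 4 and a 0.4 within-family variance share, ages uniform on 38–84 years
shared within pairs, 20,000 dosages with MAF uniform on [0.05, 0.5], 1,000
genes with 1–12 meta-exons. MZ co-twins receive identical genotypes; DZ
co-twins share each haplotype with probability ½ (per locus when loci are
independent; whole haplotypes in LD mode, which uses a latent AR(1) Gaussian
per chromosome with slowly drifting allele frequencies as a haplotype-block
surrogate — not a coalescent model).

Expression is Gaussian on the latent (≈INT) scale: per meta-exon small
age/age² and GC effects, loadings on latent factor scores (by default three
factors correlated with the phenotype at r = 0.5/0.35/0.2, echoing the
situation where leading expression factors track adiposity), gene-level
family and zygosity intercepts (variances 0.06/0.06, noise 0.09 — free
parameters of the generator, chosen to give MZ/DZ within-pair correlations
of ~0.57/0.29 for a purely familial gene, not estimates for any real
cohort), plus planted effects. Interactions are generated as
β·(G−1)·(P−P̄), so homozygote classes carry expression-on-BMI slopes of
opposite sign (±β) and the fitted interaction coefficient equals β under any
dosage coding. Planted β magnitudes default to 0.02–0.06 per
allele·phenotype-unit, the magnitude range of interest for this design at
n ≈ 700. Trans networks route a configurable fraction of each target's
interaction signal through the realized mediator expression (its first
meta-exon) and the rest directly, so conditioning on the mediator removes
exactly the mediated share. The optional count layer draws Poisson counts
around depth-scaled, per-exon base abundances with a low-expression slice to
exercise the ≥90% filter.

What the generator does **not** emulate: read-level sequencing noise,
population structure, sex chromosomes, realistic LD from a demographic
model, non-Gaussian expression tails, or cell-type composition shifts with
adiposity. Passing tests therefore demonstrate that the statistical
machinery is correct and calibrated under its assumed model — not that the
biological findings of any particular cohort would be reproduced.

## Validation problem sizes

The acceptance checks (tests/test_acceptance.py, scripts/acceptance.py) use:
1,000 random small designs (n = 12–30) for OLS-oracle agreement; 20 null
cohorts of n = 700 with 500 single-exon genes each for the 10,000-test LMM
type-I calibration (single-exon so the tests are independent; latent factors
are off in null cohorts because factor scores shared across exons would
correlate the tests cohort-wide) plus 100 genes with 1–20 exons each
(~175,000 cis pairs, n_perm = 100) for the permutation-FDR and
stratification checks; 200 replicates for interaction-coefficient recovery;
100 replicates for mediation; 100,000-test p-value mixtures (alternatives as
two-sided p of N(4,1) scores) for π₁; and 50 replicates of 250-SNP AR(1)
windows for RTC (colocalized proxy constructed at r² > 0.9 by perturbing 3%
of the causal dosages; independent control drawn from the r² < 0.1
remainder). The full script runs in roughly 8 minutes on one CPU.

## Known limitations

- Only family/zygosity random effects; no crossed random effects and no
  families beyond pairs.
- The permutation FDR's empirical floor means very small FDRs are reported
  as 0 with resolution 1/(n_perm × count).
- The Sobel statistic as defined has vanishing power at complete mediation
  (see above); the mediation score itself remains unbiased there.
- LD simulation is an AR(1) surrogate adequate for RTC-style local-LD tests,
  not for fine-mapping realism.
- π₀ estimation needs ≥100 p-values; small panels silently use π₀ = 1
  (documented, conservative).
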