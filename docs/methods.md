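# Methods

## Generative model

One biallelic SNP and *m* quantitative traits for *n* unrelated
individuals.

**Genotypes.** Allele A has frequency *p*; under Hardy–Weinberg
equilibrium the two alleles of an individual are independent, so the
allele-A count is Binomial(2, p) (genotype frequencies p², 2p(1−p),
(1−p)²). The default p = 0.3 gives 0.09/0.42/0.49 for AA/AB/BB.

**Phenotypes.** Row *i* is drawn from an m-variate normal with covariance
equal to the equicorrelation matrix R(r) (unit diagonal, constant
off-diagonal r; positive definite iff r > −1/(m−1)) and an
all-coordinate mean determined by the genotype: 1, δ, δ² for 0/1/2 copies
of allele A. This is the multiplicative analogue of the genotypic
relative-risk model — each additional risk allele scales the mean by δ —
and δ = 1 is the null of no association. All trait variances are fixed at
1 for every genotype, so the effect is purely a mean shift; nothing in
the model specifies a trait scale, and every test in the package is
invariant to positive rescaling of individual traits.

**Non-normal families.** The `lognormal` and `chisq` families apply a
strictly monotone marginal map to the normal draw *after* the genotype
mean shift: exp(x), and the χ²₃ quantile transform F⁻¹(Φ(x)). Monotone
maps preserve the ordinal genotype effect and the Spearman correlation
between traits exactly, which is what the robustness question — "do the
four methods keep their relative ordering when marginals are skewed?" —
requires. These families are stand-ins for distributional deviations in
general, not fits to any particular dataset.

**Seeding.** A root integer seed plus a (stream, replicate) spawn key
drive a counter-based `numpy` `SeedSequence`. Replicate *k* of any stream
is reproducible in isolation; calibration and power-evaluation sets use
distinct streams and therefore never share randomness; grids are
bit-identical for a fixed root seed at any parallelism level.

## The four tests

Let Y be the n×m trait matrix, g the allele counts.

- **one_by_one** — per-trait p-values p₁…p_m from either a 1-df F-test of
  the regression of y_j on g (default: additive coding matches the
  multiplicative mean model after a log transform, and spends one degree
  of freedom) or a 2-df one-way ANOVA across genotype groups (k−1 df for
  k observed groups). Reported p-value: min(1, m·min_j p_j), the
  Bonferroni family-wise correction; comparing it to α is equivalent to
  comparing min p to α/m. Each trait uses its pairwise-complete samples.
- **permutation** — the observed statistic is P_min = min_j p_j on
  complete cases. B permutations shuffle the rows of Y jointly (keeping
  genotypes in place), which destroys genotype–phenotype association
  while preserving the trait intercorrelation, and P_min is recomputed for
  each. The p-value is (1 + #{P_min^perm ≤ P_min^obs}) / (B + 1) — the
  add-one estimator is a valid p-value under exchangeability and can
  never be zero; ties count as ≤ (inclusive). An exhaustive mode
  enumerates all n! orderings (n ≤ 8) and returns the exact tail
  proportion. For the regression kernel the permuted minimum p is
  computed from the maximum squared correlation per permutation in a
  single matrix product, so B = 200 costs well under a millisecond at
  n = 300, m = 10.
- **manova** — one-way MANOVA of Y on genotype as a categorical factor,
  from the between-group (H) and within-group (E) SSCP matrices. Pillai's
  trace tr(H(H+E)⁻¹) with its standard F approximation is the default for
  robustness; Wilks' Λ = |E|/|H+E| with Rao's F (exact when
  min(m, k−1) ≤ 2) is available. Complete cases only; requires
  n > m + k; a singular E raises an error naming the collinear traits.
- **pca** — PCA on the column-standardized traits (correlation-matrix
  PCA: weights depend on inverse variances, not trait units;
  covariance-matrix PCA is available behind `standardize=False`).
  Loadings are orthonormal, components ordered by decreasing variance,
  each loading column's sign fixed so its sum is ≥ 0. The test regresses
  the PC1 scores on g (k = 1, default) or runs the 2-response
  multivariate test on the first two score columns through the MANOVA
  machinery (k = 2). PCA and MANOVA require complete trait rows; the
  number of samples analyzed is always reported.

Design choices where the field offers alternatives: the per-trait default
is the 1-df regression (the 2-df ANOVA is a flag); the two-PC variant is
a joint test rather than a min-p over components, keeping it a single
2-df-numerator decision; the Bonferroni p is capped at 1.

## Calibrated thresholds and power

With correlated traits the four methods have different true sizes at a
nominal 0.05 cutoff (Bonferroni is conservative; MANOVA's F approximation
drifts), so raw power comparisons would be confounded by type-I error.
Each method's threshold is therefore calibrated: simulate R_null
replicates under the matched null (δ = 1, same n, m, r), and take the
empirical α-quantile of the method's p-values with the *lower*
order-statistic convention — the ⌈α·R_null⌉-th smallest value — so the
rule p ≤ t rejects exactly ⌈α·R_null⌉/R_null of the calibration set.
Power is the fraction of p ≤ t over an independent replicate set
(binomial standard error √(power·(1−power)/R) reported alongside).
Calibration and evaluation always use disjoint seed streams, avoiding the
selection bias of calibrating and evaluating on the same draws. At each
grid point of a power surface the thresholds are re-calibrated under that
point's own null. All methods at a grid point share the same simulated
datasets (paired comparison), which reduces the Monte-Carlo noise of
between-method contrasts.

Default replicate counts follow the reference design (R = 10,000); the
test suite and examples run desk-scale versions (hundreds to a few
thousand replicates, permutation B = 200) chosen so that the 3-standard-
error tolerances used in the assertions are decisive for the effect sizes
involved. The acceptance script reports the problem size next to each
quantity; the PCA peak-location target uses 20,000 replicates per grid
point because the power curve is nearly flat (within a few 10⁻⁴) across
neighbouring correlation values near its maximum, and the argmax needs
resolution finer than those differences.

## Candidate-SNP studies

`read_study` joins tab-delimited genotype and phenotype tables on their
sample-ID column. Genotypes may be numeric allele counts or two-letter
strings; for strings the counted allele defaults to the alphabetically
first letter observed in the column (an explicit per-SNP designation can
be supplied via the `allele_a` mapping on the study object). Non-numeric
phenotype columns become sample metadata usable for subsetting (e.g.
patients only). `rank_snps` runs the requested methods on every SNP,
sorts ascending by p-value with ties broken by SNP label, reports top-k
per method plus the mean pairwise trait correlation (r̄) and
complete-case count, and converts per-SNP failures (monomorphic SNPs,
insufficient complete cases) into logged NA rows rather than aborts.
Permutation seeds are keyed to the SNP label, so results are invariant to
the column order of the input file.

`make_fixture` builds synthetic studies: `schizophrenia_like` mimics the
shape of a candidate-gene cognition panel (456 samples = 216 cases + 240
controls, 51 SNPs with per-SNP missing-genotype rates uniform on
[0.21, 0.56], five traits at r = 0.6, one or more planted SNPs whose
multiplicative effect δ drives all traits, remaining SNPs null, planted
allele frequency 0.3, other frequencies uniform on [0.1, 0.5]); `tiny` is
a 20-sample unit-test profile. A `.truth.json` sidecar records the
planted ground truth. Fixture phenotypes are complete by default; the
`add_missingness` injector exists for experiments with incomplete traits.

## What the simulations do and do not show

The generator reproduces the study conditions the package is built to
explore: a single causal SNP, exchangeable equicorrelated traits, a mean
shift identical across traits, no covariates, no linkage disequilibrium,
no population structure, phenotype variance independent of genotype.
Real endophenotype panels violate several of these (heterogeneous
pairwise correlations, trait-specific effect sizes, informative
missingness), so passing results demonstrate correct behaviour of the
methods under the stated model, not performance guarantees on any given
dataset. In particular the PCA method's advantage depends on the effect
loading onto the leading correlation eigenvector — an effect confined to
one trait of a strongly correlated block can favour the univariate
strategies instead.

## Numerical notes and limitations

- Constant traits get p = 1 by convention; monomorphic genotypes raise.
- Squared correlations are clipped to [0, 1]; F statistics may overflow
  to infinity for perfect associations, where the survival function
  correctly returns 0.
- Permutation tie detection uses a 10⁻⁹ relative tolerance so that
  permutations reproducing the observed pairing count as ties despite
  floating-point summation-order noise.
- Pillai's F approximation is approximate for min(m, k−1) > 2 at small n;
  Wilks/Rao is exact for the 3-genotype-group design whenever q = 2.
- The power engine assumes each replicate's test succeeds; scenarios
  where a method can fail stochastically (e.g. tiny n with monomorphic
  draws) are outside its design range.
- No analytic power formulas, FDR thresholds, covariate adjustment,
  family-based designs, genotype imputation, or missing-data PCA.
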