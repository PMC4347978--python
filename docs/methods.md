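# Methods

This note documents the models, numerical choices and known limitations of
`eduroh`: what the synthetic cohort generator emulates, how each statistic
is computed, and what passing the test suite does and does not establish
about real data.

## The synthetic two-generation cohort

The generator produces, per family, parental and offspring educational
attainment (EA, ordinal 1–4), birthplaces, religion and city-size
indicators, and an offspring genotype matrix whose homozygosity structure
reflects parental birthplace proximity.

### Ordinal assortment via a Gaussian copula

Father EA is drawn from the published marginal distribution of the spouse
crosstab (18.0 / 35.6 / 19.9 / 26.5 %).  Mother EA comes from a latent
bivariate normal discretised at the same marginal thresholds.  The latent
correlation is calibrated by root bracketing so that the *population*
Spearman correlation of the discretised pair (computed from exact
bivariate-normal rectangle probabilities and midrank grades) equals the
target, 0.66 by default; no Monte Carlo enters the calibration, so a
cohort of n ≥ 2,000 reproduces the target within sampling error.
Offspring EA uses the same machinery on a mid-parent latent blend
calibrated to a parent–offspring Spearman correlation of 0.40.

A Gaussian copula matches the published table's margins and rank
correlation but is less diagonally concentrated than the real table (real
assortment has more exact-level matching than any bivariate-normal
discretisation); consequently the simulated diagonal share (~52 %) falls
below the published 58.5 %.  The crosstab *statistics* are still
recovered exactly from the printed counts, which ship with the package as
reference inputs.

### Migration on a deme grid

Birthplaces live on a 20 × 30 grid of demes spaced 10 km apart (about the
shape of the Netherlands).  The father's birthplace is a uniformly chosen
deme.  The mother's is displaced by an exponential distance whose mean is
the average of the two spouses' EA-specific migration scales — default
(19.2, 16.3, 28.7, 49.8) km for fathers and (19.2, 24.1, 34.6, 56.7) km
for mothers, the published per-level means — then snapped to the nearest
deme.  Displacement *angles* (never distances) are resampled until the
point lands inside the grid, so expected distances are not truncated at
the study-region border.

The offspring birthplace starts from the migration-weighted point
F + w·(M − F) with w = μ_f/(μ_f + μ_m), which makes the expected
father–offspring base distance exactly μ_f/2 regardless of the spouse's
scale, and adds an isotropic exponential kick with mean 0.74·μ_f.  The
kick is tied to the *father's* scale (a patrilocal settlement convention):
a kick scaled by the couple's average inflates the father–offspring
distance for cross pairs (low-EA father, high-EA mother).  The constant
0.74 was calibrated once by simulation so that the mean father–offspring
distance per paternal EA level matches the paternal migration scale
(all four levels land within 5 % at n = 5,000).  Mother–offspring
distances inherit the correct ordering but run slightly off their nominal
scales for strongly discordant couples; no analysis depends on them
quantitatively.

### Kinship, HBD tracts and genotypes

Parental kinship follows a one-parameter isolation-by-distance kernel
φ = φ₀·exp(−d/λ) with birthplace distance d.  Offspring
homozygous-by-descent (HBD) tracts are laid down as a two-state Markov
(alternating-renewal) process along each chromosome with stationary HBD
fraction φ/2 and exponential tract lengths; the expected HBD genome
fraction is therefore φ/2 exactly, which the tests verify by long-run
simulation.  This Markov construction — rather than an explicit pedigree
or coalescent — gives direct control over the F_roh expectation, which is
what every downstream statistic consumes.

Allele frequencies follow per-SNP logistic clines: each SNP gets an
independent random logit slope per axis (SD 0.08 per degree), and each
deme's realised frequency is a binomial draw of 2 × 500 haplotypes around
the cline value (finite-pool drift).  Outside HBD tracts the offspring
receives one allele from the father's-deme pool and one from the
mother's; inside a tract, both alleles copy a single draw at the averaged
parental frequency.  Drawing from *parental* demes is deliberate: it makes
offspring ancestry reflect parental origins, so migration decouples the
offspring's own birthplace from its genotype — the mechanism behind the
declining PC–geography correlation with parental education.

Defaults: 5 chromosomes × 2,000 SNPs over 30 Mb each (evenly spaced,
~15 kb apart; the pipeline uses 1,600 SNPs per chromosome), mean HBD
tract 0.03 Morgan mapped at 1 cM/Mb (3 Mb), φ₀ = 0.05, λ = 20 km.  The
kinship kernel is a free knob with no published estimate; these values
were chosen so that a desk-scale cohort (n ≈ 1,500–2,000) reproduces the
published *effect-size regime* — a paternal-EA R² change on F_roh of
roughly 0.006–0.009 — while keeping ≥ 65-SNP runs detectable.  Mean
simulated F_roh (~0.011) remains several-fold higher than the published
~0.0018; matching both the effect size and the absolute level at desk
scale is not possible because the real signal rests on ~500k SNPs and a
much longer genome.

### What the generator does *not* emulate

No haplotype-level linkage disequilibrium (SNPs are conditionally
independent given deme and HBD state), so VIF pruning removes almost
nothing on synthetic data — it is exercised functionally, with dedicated
correlated-SNP tests, rather than at real-data pruning rates.  No
recombination realism, no X chromosome, no secular EA trends across birth
cohorts, no missing data by default.  Religion and city size are
independent of EA.  Passing tests therefore demonstrate the *methods*
(calling, statistics, inference machinery) and the qualitative
sign/ordering structure, not the numeric values of the original cohort.

## Statistical components

**ROH calling.**  A run is ≥ `min_snps` (default 65) consecutive
homozygous calls; a heterozygote always terminates it.  Missing calls
terminate by default — the conservative reading of the strict
no-heterozygote rule — with `missing_breaks=False` available, under which
missing calls are skipped (inside the span, not counted).  Runs never
cross chromosome boundaries.  Segment length is end − start (the PLINK KB
convention, not +1).  The caller is verified exhaustively against a
brute-force start/end-pair scan.

**F_roh.**  Summed segment length over a denominator: 2.77 × 10⁹ bp for
the real genotyping array, or the mapped length of the cohort's own SNP
map (Σ per-chromosome last − first) for synthetic data — applying the
real-array constant to a 150 Mb synthetic genome would only rescale
F_roh by a constant and distort nothing, but the mapped length keeps the
statistic interpretable as a genome fraction.

**VIF pruning.**  Sliding windows of 50 SNPs advancing by 5 per
chromosome; within a window the SNP with the largest variance inflation
factor (from the inverse of the window correlation matrix, with a
least-squares fallback when it is singular) is removed until all VIFs
fall below 2.  Ties are broken by removing the lower-MAF SNP.  The
procedure names only window/step/threshold in its classic description;
greedy max-VIF removal with this tie-break is this package's
concretisation.

**Permutation R²-change test.**  The observed increment from adding one
predictor to a nested OLS model is ranked among increments computed after
randomly shuffling the outcome (vectorised through fixed orthonormal
bases of both design spaces).  The default empirical p-value is
(#{null ≥ observed} + 1)/(n_perm + 1), which cannot return zero; the
plain rank/n_perm convention is available as `convention="rank"`.  The
pipeline default is 10,000 permutations (100,000 — the convention in the
original analysis — is a config choice; the Monte-Carlo SE at p ≈ 0.05
with 10,000 permutations is ~0.002).

**Sobel mediation.**  Two OLS equations on listwise-complete cases:
m ~ x + covariates gives α; y ~ x + m + covariates gives β and τ′.  The
indirect effect is tested with the classic second-order standard error
√(β²·SE_α² + α²·SE_β²) (not the Aroian variant), the full-mediation test
is the t-test of τ′.  For this just-identified path model the two-equation
estimates coincide with a covariance-structure fit, which the exact
identity τ = τ′ + αβ (asserted to 10⁻⁸) certifies.

**PCA.**  Missing calls mean-imputed per SNP, monomorphic SNPs dropped,
centring by 2p̂ and scaling by √(2p̂(1−p̂)), exact eigendecomposition of
the n × n kernel (no approximation at desk scale).  Scores are unit-norm
eigenvectors; all geographic comparisons use |correlation| or explicitly
re-orient the sign, since eigenvector sign is arbitrary.

**Moderated correlation.**  The full model maximises the bivariate-normal
log-likelihood over shared means and variances plus (ρ₀, ρ₁), with
ρ_g = ρ₀ + g·ρ₁ constrained to (−0.999, 0.999) via SLSQP linear
constraints; the null fixes ρ₁ = 0 and the LRT is referred to χ²(1).
Sharing moments across groups isolates the correlation trend and keeps
the test on 1 df; a per-group-moments variant (`group_moments="free"`)
exists and, in the unconstrained two-group limit, reproduces the
per-group sample correlations — the oracle check in the tests.
Correlations are optimised on the natural ρ scale (not Fisher-z) because
the trend is linear in ρ.  The full fit is initialised at the null
optimum, so log-likelihood nesting holds by construction; a boundary flag
is raised if any fitted ρ_g approaches the constraint.  SE(ρ₁) comes from
the inverse numerical Hessian at the optimum.

**Distances.**  Spherical law of cosines on a 6371.0 km sphere, the
classic geodatasource-style formula, with the arccos argument clamped;
cross-checked against an independent haversine implementation.

**t-tests and ANOVA.**  Consecutive-level post-hoc t-tests are
pooled-variance by default (the classic SPSS-style output); Welch is a
flag.  Groups with n < 2 are excluded from the ANOVA with a warning.

## Pipeline and reproducibility

All randomness flows from one root seed: the pipeline draws six named
stage seeds (families, genotypes, three permutation streams, one spare)
from a generator seeded with the config seed.  Every report TSV carries a
hash of the analysis-relevant configuration (output paths excluded);
re-running the same configuration reproduces byte-identical files.  The
run log records package versions, per-stage seeds, and dropped-SNP /
sample counts at each filter.

Degenerate inputs: a cohort simulated with φ₀ = 0 has every F_roh equal
to zero; regression, permutation and mediation stages then report zero
effects with p = 1 and a "constant outcome" flag in the log rather than
failing, which keeps global-null runs well defined.

Problem sizes: the default pipeline simulates 1,500 families × 8,000
SNPs; the test suite's end-to-end checks use 400–2,000 families and its
calibration studies use 100–1,000 replicates of covariate-level cohorts.
These sizes were chosen so the full suite runs in a few minutes on one
CPU while keeping every recovery rate comfortably away from its
threshold.

## Known limitations

* The generator's spatial kinship decay (φ₀, λ) is a modelling stand-in,
  not an estimate for any real population.
* Real-data mode supports PLINK 1 text and binary formats and the
  covariate TSV layout, but has only been exercised on synthetic
  round-trips; the text reader assigns the counted allele as the
  alphabetically first observed, which is only guaranteed faithful for
  maps whose first allele sorts first (as in the synthetic A/B maps).
* The spouse crosstab's exact cell pattern (hypergamy asymmetry,
  diagonal excess) is beyond a Gaussian copula; only margins and rank
  correlation are matched.
* Permutation p-values are exchangeability-based; covariates are not
  residualised out before shuffling (matching the original shuffle-the-
  outcome design), so the test is exact only under the global null of no
  outcome–predictor association.
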