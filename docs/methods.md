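# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of `methquake`. It is the package's own
account of its science; every number quoted here is computed by the test
suite or by `scripts/acceptance.py`, not asserted from memory.

## Scope and shape

The package implements a desk-scale version of a WGBS meQTL analysis:
synthetic data generation, methylome I/O and filtering, local smoothing,
PCA/ANOVA variance structure, the cis-meQTL scan, gDMR construction,
Storey π₁ replication sharing, mediation by coefficient attenuation,
moderated-t differential methylation, and heritability / stratified
LD-score enrichment. Fit-shaped stages are scikit-learn style estimators
(`MeQtlScanner`, `ModeratedDiffMeth`, `RemlHeritability`,
`StratifiedLdRegression`, plus the `LocalSmoother` and `MethylationPCA`
transformers); interval and streaming utilities remain plain functions.
Module-level wrappers (`meqtl.scan`, `varstruct.pca`, ...) stay thin.

## The synthetic-data generator (`simdata`)

The generator defines the study conditions the rest of the package is
validated under. Defaults:

| parameter | default | rationale |
| --- | --- | --- |
| `n_samples` | 165 | cohort scale of a single brain region |
| `n_snps` / `n_cpg` | 500 / 5000 | desk-scale panel |
| `chrom_length` | 250 kb | 1 CpG per 50 bp — CpG-dense regulatory DNA, where meQTLs concentrate; also keeps the ≥70-site smoothing window (~3.5 kb) well inside the ~14.5 kb effect windows |
| `maf_range` | 0.05–0.5 | common variants only (MAF > 5 %) |
| `ld_block_size`, `ld_rho` | 10, 0.8 | blocks of correlated SNPs; Gaussian-copula AR(1) haplotypes give exact marginal MAFs and tunable adjacent r² |
| `mean_coverage` | 17.3 | zero-truncated Poisson, rate solved so the mean matches |
| `baseline_mixture` | 0.78 / 0.14 / 0.08 | high (>0.8) / intermediate / low (<0.2) methylation classes |
| `effect_mean_cpg` | 0.026 | mean per-allele methylation shift; magnitudes ~ Gamma(2), random sign |
| `effect_width_mean` | 14.5 kb | effect windows contiguous in bp, widths ~ Gamma(2) |
| `effect_mean_cph` | 0.27 | sparse large CpH effects |
| `age_site_fraction`, `age_increase_fraction` | 0.10, 0.94 | age effects are region-coherent blocks (default 3 kb) — aging-related methylation drift spans kilobases, and isolated single-site effects would vanish under smoothing |
| `age_slope_sd` | 5·10⁻⁴ per year | gives few-percent shifts across an 18–96-year range |
| `batch_var_share` | ~0.10 | per-site batch offsets |
| `noise_sd` | 0.02 | biological site×sample noise |

Within-class baseline shapes are skewed away from the hard 0/1 boundaries
(high class = 0.8 + 0.2·Beta(1.5, 4)): highly methylated cytosines average
~85–90 %, not full saturation, and a generator that piles mass at 1.0 turns
additive allelic shifts into clipping artifacts. Clipping still occurs
(≈1 % of cells at defaults) and is recorded in the truth table's mask.

Expression for mediation triplets is built as E = direct·G + δ·M + ε with
the indirect share δ·α/(direct + δ·α) set to the requested mediation
proportion. Triplets are designated at loci with |per-allele effect| ≥ 0.02
and low clipping, mirroring the double-significance (eQTL and meQTL)
precondition of the real procedure — a locus with a near-zero marginal
genotype coefficient makes the retained proportion a ratio of noise, and a
saturated site could never pass the expression–methylation correlation
gate. GWAS z-scores are drawn from the stratified model
z_j ~ N(0, 1 + N Σ_c τ_c ℓ_{j,c}).

What the generator does **not** emulate: bisulfite-conversion failure,
strand-specific counts, sequence context beyond the CpG/CpH label,
real-genome positions, population structure beyond LD blocks, and
trans-chromosomal effects. Passing tests therefore demonstrate that the
estimators recover what they claim under the stated generative model — not
that a real cohort satisfies that model.

## Preprocessing (`methio`)

- **Coordinates.** Site positions are 1-based everywhere in memory; BED is
  0-based half-open; the conversion lives in one place.
- **CpG filter.** "coverage ≥ 3" is applied to the *mean* coverage across
  samples. A per-sample hard filter at 3 would discard most sites at 17×
  mean coverage with Poisson dispersion; the mean-based rule matches the
  scale of retained sites. The threshold and rule are configurable.
- **CpH filter.** (coverage > 3 AND methylated > 0) evaluated jointly per
  sample, required in ≥ half the samples.
- **Smoothing.** Per sample, per chromosome: at each site the smallest
  symmetric window holding ≥ 70 sites and spanning ≥ 2 kb is selected (the
  half-width equals the 69th-smallest neighbor distance, floored at 1 kb);
  a local linear fit with tricube(distance/half-width) × coverage weights
  is evaluated at the site and clipped to [0, 1]. Zero-coverage sites get
  the local fit (imputation). Window geometry is shared across samples and
  the per-sample fit is a set of segmented weighted sums, so smoothing a
  5000-site × 165-sample matrix takes under a second. Exact parity with any
  external smoother is not a contract; the contracts are the constant fixed
  point, locality, and MSE improvement on smooth truth, all tested.
- **Genotypes.** VCF via cyvcf2; dosage = alternate-allele count; filters
  MAF > 5 %, missingness < 10 %, Hardy–Weinberg χ² (1 df) p > 10⁻⁶.

## The scan (`meqtl`)

OLS of smoothed fractions on [1, dosage, covariates]. The vectorized path
residualizes methylation and dosage against the covariate span once
(Frisch–Waugh–Lovell) and reproduces the full per-pair OLS exactly; SNPs
with missing dosages fall back to per-pair complete-case fits. Constant
responses and constant dosages short-circuit to defined results rather than
ratios of floating-point dust. The FDR-equivalent p cutoff is the largest
p(i) ≤ q·i/m over the total test count m, which may exceed the number of
recorded p-values when a keep-threshold was used (unsaved tests count as
non-discoveries). Window boundaries are inclusive; cis/trans labels use
250 kb in index-SNP mode. The number of methylation-PC covariates is a
config parameter defaulting to min(28, n/6); at desk scale, recovery
experiments adjust for the known generative confounders instead, because
with only thousands of sites the top PCs absorb the genetic signal itself
(at 5000 sites and n = 165, 27 PCs cut the recovered slope to ~13 % of
truth; a cohort-scale panel of tens of millions of sites does not have
this pathology).

## gDMRs (`gdmr`)

Sites are clustered by genomic gap (default maxgap 1 kb, configurable and
recorded in output metadata — the clustering gap is not pinned by any
printed value); within clusters, maximal sign-homogeneous runs with
|t| ≥ cutoff (5.0 default, 3.5 liberal) and ≥ 2 sites become regions.
Raising the cutoff can only shrink or split regions, never create one
outside a liberal-cutoff region (the nesting property, tested on 500 random
instances). Region replication in a second dataset is the mean member-site
p-value compared with 0.05.

## π₁ sharing (`sharing`)

π̂₀(λ) = #{p > λ} / (m(1 − λ)) over λ = 0.05…0.95; the smoother is a
least-squares cubic fit over the grid evaluated at λ_max — the behavior of
the reference implementation's df = 3 smoothing spline. (An *interpolating*
natural spline evaluated at λ_max would simply return the noisiest raw
estimate, so the literal "natural cubic spline" reading is not used.) A
fixed-λ = 0.5 fallback exists for small m. Estimates are clamped to [0, 1]
with the raw value kept in the record. The recovery experiment
(`evaluate.pi1_recovery`) uses unlinked SNPs and mostly disjoint effect
windows because pairs of one SNP are strongly correlated — the effective
sample size of π̂₁ is the number of independent effect loci, not the pair
count. Truth labels are computed on the smoothed noiseless retained signal
(the quantity the scan actually tests), with pairs whose induced per-allele
slope is below 0.002 (≈1 standard error at n = 165) counted as null.

## Mediation (`mediation`)

Two nested OLS fits on identical samples; retained proportion β₂/β₁;
mediated iff < 0.75. The correlation gate uses |r| > 0.3 (signed mode
available). Records with |β₁| < 10⁻⁶ in standardized units or with a
materially negative ratio (< −0.1) are flagged unstable and never counted
as mediated; a *slightly* negative ratio is the noise signature of full
mediation (β₂ ≈ 0), not a sign flip. The "< 75 %" rule is applied per CpG
with a per-locus roll-up available in the summaries.

## Differential methylation (`diffmeth`)

Per-site OLS with one shared design, then empirical-Bayes moderation:
log s² moment-matching via digamma/trigamma relations (trigamma inverted by
Newton iteration, tolerance 10⁻⁸) yields the prior (d₀, s₀²); posterior
variances (d₀s₀² + d·s²)/(d₀ + d); moderated t on d₀ + d df, capped at the
pooled residual df across sites; d₀ = ∞ (no excess dispersion) uses the
plain mean of s² as prior variance. These conventions match the reference
R implementation, and one test cross-checks d₀, s₀², t and p against it on
a fixture. BH adjustment is delegated to statsmodels.

## Heritability (`herit`)

- **GRM**: A = ZZᵀ/m from dosages standardized by √(2p(1−p)) with
  in-sample allele frequencies (which makes the expected off-diagonal
  −1/(n−1), not 0 — a property the tests assert rather than fight).
- **Pruning**: greedy removal of the member of each offending pair with the
  most offending partners, ties by sample order, until all off-diagonals
  are below 0.025.
- **REML**: one genetic component. Covariates are projected out, the
  projected GRM is rotated into its eigenbasis, the total variance is
  profiled analytically, and the restricted likelihood is maximized over
  h² ∈ [0, 1] by bounded 1-D search (xatol 10⁻⁸) — an exact replacement
  for AI-REML in the single-component case. The LRT against h² = 0 uses
  the ½χ²₀ + ½χ²₁ boundary mixture. Standard errors come from the profile
  curvature and are undefined (NaN) at the boundary.
- **LD scores**: ℓ_{j,c} = Σ r²_adj over window SNPs in c, with
  r²_adj = r² − (1 − r²)/(n − 2). The window is in bp (default 1 Mb)
  because synthetic chromosomes have no genetic map.
- **Stratified regression**: weighted least squares of χ² on N·ℓ per
  annotation plus an intercept, weights 1/max(ℓ, 1); h² share of an
  annotation is the per-SNP τ-contribution summed over members, enrichment
  is share over SNP proportion, and uncertainty is a delete-one jackknife
  over 20 contiguous SNP blocks (sized for desk-scale panels). The
  identifiability caveat: with a near-constant LD score the slope is
  collinear with the intercept, so enrichment experiments need LD blocks
  and a sub-chromosome window. The 53-annotation baseline model of the
  full method is out of scope; annotations arrive as BED files (gDMR
  output plugs in directly).

## Validation experiments (`evaluate`) and problem sizes

The built-in simulation studies, run by both `tests/test_acceptance.py`
and `scripts/acceptance.py`:

- slope recovery at n = 165, coverage 17.3, default panel (≈380 k tests);
- null calibration at 200 samples × 5000 CpGs × 500 SNPs;
- π₁ recovery on 120 unlinked SNPs × 36 000 CpGs over 1.8 Mb at shared
  fractions {0, 0.5, 0.8, 1.0};
- mediation recovery at truths {0, 0.3, 0.6, 0.9}, 200 replicate draws;
- REML recovery at h² = 0.5, n = 160, 200 replicates;
- stratified-regression CI coverage on 20 000 SNPs, 100 replicate GWAS;
- smoother fixed-point and MSE-gain checks (200 replicates);
- bitwise determinism of the full pipeline at 200 × 5000 × 500.

These sizes are the package's chosen experiment scale: large enough that
Monte-Carlo error sits well inside the stated tolerances, small enough to
run on a laptop.

## Known limitations

- The scan's q-values assume all unsaved p-values exceed the saved ones
  (true when a keep-threshold is used, the intended mode).
- Smoothing leaks signal ~one window half-width beyond effect boundaries;
  width summaries measured from significant sites inherit that blur.
- π₀ smoothing by cubic fit can exceed [0, 1] on pathological inputs;
  values are clamped and the raw estimate is recorded.
- The stratified regression supports overlapping annotations but reports
  shares that need not sum to the total h² unless annotations partition
  the panel.
- CpH handling is minimal: low Beta(1.5, 30) baselines and sparse large
  effects; the CpH baseline distribution is a free choice of this package.
- `TruthTable.true_pairs()` reports the CpG-scale effect for CpH members
  of a window; CpH-specific magnitudes live in `snp_effect_cph`.
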