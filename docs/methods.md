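# Methods

This note documents the models implemented in `smokewas`, the synthetic
data they are exercised on, the numerical choices, and the limits of what
the tests demonstrate.

## The association model

For each CpG site the response is the M-value, the logit-base-2 of the
Illumina beta value `β = M/(M+U+100)`; M-values are preferred for linear
modelling because beta values are bounded and heteroscedastic near 0 and 1.
The per-CpG model is ordinary least squares:

DNAm = b0 + b1·IC50 + b2·Smoking + b3·IC50×Smoking + b4·Age + b5·PC1 + b6·PC2 + b7·PC3 + ε

- **IC50** (µM): ex-vivo half-maximal inhibitory concentration of the drug
  on osteoclastic bone resorption, one value per donor.
- **Smoking**: the raw lifetime cigarette count. No transform is applied by
  default; optional log transforms exist in the cohort config but are off,
  because the covariate is defined as the raw count and the interaction is
  to be interpreted on that scale.
- **Age** in years at sampling.
- **PC1–PC3**: reference-free cell-composition components (below). Three
  are included by default, a sample-size-driven choice.

The tested effects are b1, b2 and b3, each with a two-sided t-test on
n − 8 residual degrees of freedom. Fits use a QR decomposition shared
across probes (the design is identical for every CpG), which is both fast
(one decomposition for an entire matrix of probes) and numerically stable
under the raw covariate scales, whose interaction column reaches ~1e6.
Covariates are deliberately *not* centered by default; a `center=True`
flag improves conditioning without changing the interaction test.

Degenerate probes (numerically zero residual variance, e.g. constant
M-values after clipping) report t = 0 and p = 1 rather than failing the
run. A rank-deficient design (e.g. a cohort of never-smokers only, making
Smoking and the interaction identically zero) raises immediately: no
per-probe result is meaningful in that case.

### Multiple testing and tiers

Benjamini–Hochberg adjustment is applied per effect. `bh_fdr(p, m_total)`
supports an adjustment count `m_total` larger than the list adjusted —
the standard situation when a printed top list must be adjusted against
the full number of tests performed. The step-up rule is
`adj_i = min over ranks j ≥ i of min(1, m_total·p_(j)/j)`. Significance
tiers: *genome-wide* iff FDR < 0.05, else *suggestive* iff p < 1e−05. The
bundled 59-row top table (from a published EWAS of this design, 683,408
CpGs after QC) provides the worked example: BH with m_total = 683,408
reproduces its printed FDR values at the top and bottom ranks.

## Preprocessing

1. **Detection filter**: a probe is dropped when its detection p-value
   exceeds 0.01 in *strictly more than* 5% of samples. With 34 samples the
   cut-off is 1.7, so 2 failing samples trigger removal and 1 does not.
2. **Chromosome/SNP filter** on the annotated matrix: chrY probes are
   removed (single-sex cohort), probes physically overlapping SNPs are
   removed, chrX probes are retained. When a probe trips both rules the
   dropped-probe report records chrY (filter order mirrors the processing
   narrative; precedence only affects reporting).
3. **Scales**: β = M/(M+U+100) with the Illumina +100 offset; the logit is
   taken after clipping β to [1e−6, 1−1e−6], since the transform is
   undefined at 0/1 and zero-signal synthetic probes would otherwise
   produce infinities.

Between-array normalization requires raw control-probe data that synthetic
tables do not carry; `normalize_intensities` is an identity hook that
keeps the pipeline graph explicit.

## Reference-free cell composition

Whole blood is a mixture of leukocyte types with cell-specific methylation;
donor-to-donor composition differences confound association tests. Rather
than estimating absolute cell counts against a reference panel, the
implementation follows the feature-selection-then-PCA scheme: standardize
each probe across samples; form the best rank-d approximation of the
standardized matrix (d = assumed number of cell types); rank probes by the
Euclidean distance between observed and reconstructed rows; keep the t
best-captured probes (the most cell-type-informative sites); PCA on that
sub-matrix and return the first k sample-score components. Components are
sign-fixed (largest-magnitude loading positive) so output is fully
deterministic; constant probes are excluded with a warning, detected by an
exact max=min test because floating-point `std` of a constant row is
O(eps) rather than zero.

Defaults d=5, t=500, k=3. d and t are exposed because the right values are
data-dependent; k=3 matches the association model above.

**Caveat measured during development**: when the analysis panel is small
(10²–10³ probes) and a block of probes shares one covariate-driven signal,
that block is itself dominant low-rank structure; the selection step then
absorbs it into the components and the regression loses the signal. For
this reason the power benchmark (below) adjusts with components built from
the generator's true cell proportions, while component *estimation* is
scored by its own benchmark. At epigenome scale (signal probes a ~1e−4
fraction) the absorption regime does not arise.

## Synthetic data

The generator emulates the study structure; its defaults are the study
conditions, not tuning knobs.

- **Cohort** (n configurable, study-like at 34): ages uniform integers on
  [40, 66]; smoker classes (never, past, current) with probabilities
  (12, 16, 6)/34; lifetime cigarettes 0 for never-smokers and log-uniform
  on [100, 268,800] otherwise (median ≈ 5,200, matching the observed
  median of ~6,100 including never-smokers); IC50 lognormal with median
  0.28 µM and log-sd 1.3, clipped to [0.061, 9.49] µM so the configured
  range brackets the observed one (a 156-fold spread).
- **Methylome**: per probe and sample, an M-scale value composed of a
  bimodal baseline (levels −3/0/+3 with sd 1, echoing the bimodality of
  real methylomes), cell-mixture shifts Σc w_ic·δ_jc with w ~ Dirichlet
  (geometric alpha, unequal mean proportions) and δ sparse (20% of probes
  cell-informative, sd 1.5), planted covariate effects, and Gaussian noise.
  M is clipped to ±6 and converted to an intensity pair at fixed total
  signal S = 10,000 via Msig = β·S, U = S − Msig − 100, which makes
  β = Msig/(Msig+U+100) exactly invertible and keeps U ≥ 0. Detection
  p-values are near zero except for a 0.2% fraction of failing probes.
  Annotation includes chrY and SNP-overlap probes so the filters have work
  to do; the genome model is desk-scale (2×10 Mb autosomes plus X and Y).
- **GWAS catalogs**: phenotype-grouped SNPs; a configured fraction of a
  group is planted strictly within a configured distance of target CpGs,
  the rest uniform on the genome model; planted status is recorded.
- **Gene sets**: GMT-writable random sets; optionally one set over-samples
  a query 3-fold to give ORA a known positive.
- **Validation tables**: a configured fraction of discovery CpGs get a
  q < 0.05 site planted within the window; background sites are uniform
  with q ~ U(0,1).

Everything is deterministic under its seed. What the generator does *not*
emulate: probe-type chemistry and dye bias, genomic autocorrelation of
methylation, LD structure among SNPs, realistic gene-set topology.
Passing tests therefore demonstrate correctness and calibration of the
statistics under the assumed model, not robustness to array artefacts.

## Enrichment statistics

- **ORA**: one-sided upper-tail hypergeometric p = P(X ≥ k) with population
  N (universe), K set members in the universe, n query genes after
  intersection with the universe. BH across sets; the q-value column equals
  the BH-adjusted column (a Storey estimator is out of scope; for
  well-behaved collections the two are near-identical).
- **Success ratios**: success iff same chromosome and |SNP − CpG| < D
  (strict, per the definition "less than the stated maximal distance");
  cross-chromosome pairs are never successful. The per-CpG ratio is
  successes over all SNPs in the group. Distance ladder default
  {1,000; 2,500; 5,000; 10,000; 25,000; 50,000} bp.
- **Group comparison**: one-tailed Mann–Whitney U. For pooled sizes ≤ 12
  the p-value is exact by enumeration of all C(na+nb, na) label assignments
  of the midranked pooled values (tie-safe); larger samples use the normal
  approximation with tie correction. Swapping the groups together with the
  tail leaves p invariant.
- **Per-locus test**: the per-gene enrichment table is produced by a
  one-sided Fisher's exact test on the 2×2 within-D/beyond-D ×
  relevant/control counts, BH-adjusted across loci at each D; the reported
  per-locus "max distance" is the largest tested D with FDR < 0.05. This
  2×2 construction is this package's documented interpretation of a
  per-locus test; the Mann–Whitney group comparison remains the headline
  statistic.
- **SNP filter**: catalogs are restricted to association-significant SNPs,
  p < 5e−6 retained by default (enrichment needs associated SNPs); the
  direction is config-invertible. Dataset-level filtering keeps
  high-confidence traits with h² > 0.01 and h² z-score ≥ 7.

## Replication

A discovery CpG is validated iff a same-chromosome validation site with
q < 0.05 (strict) lies within ±5,000 bp (inclusive — "within 5 kb" is read
as a closed interval). Matching runs on sorted per-chromosome position
arrays (binary search, O(log n) per query); chromosome labels in UCSC or
bare convention are normalized, with a warning when tables mix them.

## Benchmarks and problem sizes

The calibration/recovery suite (also run by `scripts/acceptance.py`) uses
sizes chosen to give stable rates at desk scale:

- **Null calibration**: 20 replicates of a 2,000-probe, 50-sample null
  methylome (cell structure present, no covariate effects), analyzed with
  fully data-driven components (d=5, t=500, k=3); the pooled interaction
  rejection rate at α=0.05 over 40,000 tests should sit within 3 binomial
  SE of 0.05.
- **Power/FDR**: 20 replicates, 100 samples, 100 probes of which 10 carry
  an interaction effect sized for expected |t| = 8 via
  `effect_size_for_t` (the exact design-based identity
  b3 = t·σ·√[(XᵀX)⁻¹]₃₃); adjustment uses true-proportion components (see
  caveat above). Expected: ≥ 90% of planted probes at FDR < 0.05, pooled
  empirical FDR ≤ 0.075.
- **Composition recovery**: 20 replicates, 60 samples, 500 probes, noise
  0.1; per replicate the mean canonical correlation between the top-3
  components and the true 3-type proportions (2 free dimensions), median
  over replicates ≥ 0.9.
- **Proximity detection**: 50 replicates, 30 CpGs, two 200-SNP groups, one
  planted at 50% clustering within 10 kb; one-tailed Mann–Whitney at the
  planted distance should reject at p < 0.05 in ≥ 90% of replicates, and
  per-CpG success ratios must be monotone non-decreasing in D on every run.

## Known limitations

- OLS with homoscedastic errors only; no robust/sandwich standard errors,
  mixed models or surrogate-variable alternatives.
- The reference-free components are linear transformations of composition,
  not absolute cell counts, and are vulnerable to signal absorption on
  small panels (documented above).
- No genome-build liftover, no LD-aware SNP clumping, no GO term topology.
- The intensity model is an exact algebraic stand-in, not a physical model
  of two-channel array chemistry.
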