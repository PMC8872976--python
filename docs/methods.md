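# Methods

## The phenotype grid

A phenotype definition is a subset of five binary diagnostic components
(`recurrence`, `symptoms5`, `duration`, `impairment`, `persistence`)
layered on an implicit cardinal-symptom requirement; enumerating all
subsets gives 32 definitions, stored with `enrichment = 1 + |components|`
so the cardinal-only baseline is level 1 and the full definition level 6.
(Other conventions count only the added components, 1–5; outputs label the
level explicitly to avoid the ambiguity.)

The case/control rule is asymmetric by design. Case status requires every
required element observed and endorsed; control status requires only one
required element observed and *not* endorsed. Controls are therefore not
screened for partial endorsement — a deliberate choice that avoids
upwardly biasing heritability by over-cleaning the control set. Rows that
cannot be resolved either way because of missing responses are set to
missing, not control (the conservative reading where the source convention
is silent). Exclusion flags (screening analog for schizophrenia, bipolar
disorder, substance abuse) override case/control status, but the sample
prevalence attached to each definition is computed *before* exclusions,
because that pre-exclusion prevalence doubles as the population prevalence
K in the liability conversion.

Differences between definitions are attributed via the 80 ordered pairs
that differ by exactly one component (16 per component), grouped into 25
(component × base-enrichment) cells.

## Heritability estimator

The estimator is PCGC regression under random ascertainment. Because K is
set equal to the sample prevalence, the full ascertainment correction
collapses and PCGC coincides with Haseman–Elston regression: the 0/1
status is residualized on covariates (OLS with intercept; mean-centering
when no covariates are supplied), standardized, and the products yᵢyⱼ are
regressed (with intercept) on GRM entries gᵢⱼ over all i<j pairs. The GRM
is (1/m)X_sX_sᵀ on column-standardized dosages, after removing the MHC
analog (chr 6, 28,866,528–33,775,446 bp, closed interval) whose extreme LD
would otherwise distort the relatedness estimates. Diagonal entries never
enter the regression. The slope is the observed-scale h², converted by
K²(1−K)²/(z²P(1−P)). The regression is computed from closed-form
sufficient statistics (pair sums derived from G, G², Gy), never from an
explicit pair list; the brute-force pair loop exists only as a test oracle.

Limitations: under genuine case-control ascertainment (K ≠ P) this
reduction is not the fully corrected PCGC estimator, and covariates enter
by pre-residualization of the observed status rather than through a
fixed-effect liability model. Both are exact under the sampling model used
here and are documented as the boundary of validity.

## GWAS, LD scores and genetic correlation

Per-SNP association is simple linear regression of the residualized status
on dosage (z = β/SE(β)); monomorphic SNPs yield missing z and are logged.
LD scores are computed on the panel itself: for SNP j,
ℓⱼ = Σ_k [r²ⱼₖ − (1−r²ⱼₖ)/(n−2)] over same-chromosome SNPs within a
window (default 1 Mb, standing in for the conventional 1 cM), self term
included. The bias adjustment keeps the expected score at 1 on a
linkage-equilibrium panel.

Univariate LDSC regresses χ² on ℓ by weighted least squares with a free
intercept and single-pass weights 1/max(ℓ,1) — a deliberate desk-scale
simplification of the two-step iterative variance weighting used at
biobank scale. h² = slope·M/N̄. Bivariate LDSC regresses z₁z₂ on ℓ the
same way; alleles are harmonized by SNP id with sign flips for swapped
allele pairs and irreconcilable SNPs dropped. r_g jackknife replicates
recompute the entire ratio (both univariate slopes and the cross slope)
per left-out SNP block; replicates with a non-positive univariate slope
are dropped from the SE. An r_g exceeding 1.25 in magnitude is flagged as
noise. Internal LDSC standard errors use 200 contiguous blocks in genome
order (respecting local LD); the cross-phenotype difference machinery
instead passes in its shared shuffled partition (below).

## Difference tests

All 32 phenotypes are defined on one cohort and all GWAS on one panel, so
naive SEs of differences would ignore near-total sampling overlap. One
seeded shuffle fixes a partition of the shared axis (individuals for h²,
SNPs for r_g) into 200 contiguous blocks; every estimate is recomputed on
each leave-one-block-out subset, and the SE of a difference is the
jackknife SE of the paired replicate differences,
se² = (B−1)/B·Σ(δ₍b₎−δ̄)². The delete-one-block form was chosen over the
pseudovalue form; for a linear statistic the two agree with the closed
form, which the tests verify to six decimals. Two-sided normal p-values
are used throughout (B = 200 makes a t correction immaterial). The HE
replicates hold the full-sample residualization and standardization of y
fixed and resample only the pairwise quadratic form; at these sizes the
neglected refit changes nothing detectable, and it keeps each replicate an
O(|B|²) update. Group summaries pool member differences by fixed-effect
inverse-variance weighting (zero-SE members carry infinite weight and
dominate); cells with no estimable member are reported missing, never
zero. Bonferroni thresholds are α/32 for per-phenotype tests and α/25 for
the attribution cells.

## The synthetic cohort

The generator defines the study conditions everywhere the restricted data
would have:

* **Genotypes.** m SNPs in Hardy–Weinberg equilibrium, allele frequency
  uniform on [0.05, 0.5], on a regular base-pair grid over 10 chromosomes
  (default spacing 300 kb, so chromosomes span ~45 Mb and the real MHC
  coordinates remove ~1% of chr-6 SNPs, matching the proportion removed at
  biobank scale). Optional block LD: adjacent SNPs in blocks of cycling
  size 1..4 copy a latent block genotype with probability 0.9, giving
  pairwise r = 0.81 and LD scores varying between ~1 and ~3 — enough
  regressor variance for LDSC without modelling human LD maps.
* **Traits.** Seven liabilities (cardinal, five components, one external
  trait): a polygenic score on standardized dosages with per-SNP effects
  drawn once per seed and correlated across traits by the architecture's
  genetic correlation matrix, plus environmental deviates with their own
  correlation matrix; total variance 1 by construction. Indicators are 1
  for the top round(nK) realized liabilities, so the sample prevalence is
  exact by construction (a stabilizing choice at desk scale, in place of
  the theoretical Φ⁻¹(1−K) threshold).
* **Defaults.** Prevalences 0.56 (cardinal) and 0.30–0.45 (components),
  chosen so roughly half the cohort endorses the baseline item and ~10%
  the full definition; liability h² 0.10–0.16; genetic correlation 0.9
  among internal traits and 0.75 with the external trait; environmental
  correlation 0.5 internally, 0 externally; exclusion rate 0.0245.
* **The external cohort** (default 20,000 individuals — external GWAS are
  typically larger than the deeply phenotyped cohort) is drawn on the same
  SNP map, frequencies and LD structure, using the *same* effect vectors,
  so the true genetic correlation between the cohorts' traits equals the
  architecture entry exactly — the ground truth for recovery tests.
* **Missingness** is a uniform per-cell masking knob (default 0). Real
  questionnaire skip logic induces structured missingness that is not
  modelled; the case/control rule handles missing values explicitly
  either way.

What passing tests show, and what they do not: recovery and calibration
hold under linkage(-block) equilibrium, random ascertainment, an
infinitesimal effect model and a homogeneous unrelated cohort. They do not
probe human LD structure, relatedness, ancestry stratification, batch
artifacts, or ascertained sampling — all out of scope by design.

## Sizes and numerical choices

Default run: n = 4,000 individuals, m = 1,500 SNPs, one external cohort of
20,000, 200 jackknife blocks; a full pipeline run takes ~15 s and the
heritability-recovery simulations use n = 4,000 × m = 6,000. These sizes
were fixed after a signal-to-noise analysis of the LDSC slope (the
univariate signal per unit ℓ is N·h²_obs/M, and its sampling noise grows
with √m), the binding constraint being a positive univariate slope for
every phenotype's r_g denominator; at these sizes non-positive slopes
still occur occasionally and propagate as missing estimates, logged and
excluded from pooling, never imputed.

Ties at the liability threshold break by stable sort order; correlation
matrices are factored by Cholesky with an eigendecomposition fallback for
semi-definite inputs; degenerate phenotypes (zero cases or controls) are
refused by the estimators and reported as missing downstream. Floats are
written with `%.10g` so equal configurations produce byte-identical
artifacts; every output header carries the configuration hash and seed.
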