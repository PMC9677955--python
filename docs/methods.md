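# Methods

`ldmr` implements the analytical chain that links a panel of exposure GWAS
(here: gut-microbiota taxon abundances) to a disease outcome GWAS (here:
deep venous thrombosis): cross-trait LD-score regression to screen for
genetic correlation, then two-sample Mendelian randomization with a
heterogeneity/pleiotropy sensitivity battery on the exposures that clear
the screen.  Everything operates on GWAS summary statistics; no
individual-level phenotype data are required.  A synthetic-data module
generates all inputs with known ground truth so that every stage is
testable offline.

## LD-score regression

Under a polygenic model in which per-variant effect variances scale with
1/(p(1−p)), the expected association statistic of variant *j* is

    E[χ²_j | ℓ_j] = N h² ℓ_j / M + N a + 1,

where ℓ_j = Σ_k r²_jk is the LD score (including the self term, so the
null value is 1), M the variant count, N the GWAS sample size, h² the
observed-scale SNP heritability, and *a* the mean contribution of
confounding (cryptic relatedness, stratification).  Regressing χ² on ℓ
therefore gives h² from the slope (times M/N) and the confounding
inflation from the intercept minus one.  For two traits, the slope of the
per-variant product z₁z₂ on ℓ estimates the genetic covariance (times
M/√(N₁N₂)); the genetic correlation is

    rg = gencov / sqrt(h²₁ h²₂).

Implementation choices:

* **Weights.** Baseline heteroskedasticity weights 1/max(ℓ, 1).  The
  fuller iteratively-reweighted variance weights of common LDSC software
  are deliberately out of scope; the model defines the regression, not the
  weighting, and the recovery and calibration tests below quantify what
  the baseline weights achieve.  The choice is recorded in each fit's
  metadata.
* **Intercept** is always free (never constrained to 1), preserving the
  confounding interpretation.  A cross-trait intercept (sample overlap) is
  reported but the generator defaults to non-overlapping cohorts.
* **Uncertainty** is a delete-one-block jackknife over contiguous variant
  blocks (default 200 blocks, automatically reduced to about one block per
  50 variants on small data).  For rg the full ratio statistic —
  all three component regressions — is re-evaluated per deleted block, via
  per-block sufficient statistics so each delete-block fit is O(1).
  p-values are two-sided normal.
* **Out-of-range rg** (|rg| > 1.25) is flagged, never clamped; a
  non-positive component heritability raises an explicit undefined-rg
  error rather than returning a silent NaN.
* **Extreme χ² capping** (as some reference software applies) is off by
  default and available behind a flag, logged when used.
* Per-variant sample sizes are averaged when present; a study-level N can
  be supplied explicitly.

## Instrument selection

The six quality-control steps, in order: (1) exposure association
p < 1×10⁻⁵; (2) greedy LD clumping at r² < 0.001 within 10,000 kb against
the reference panel; (3) exclusion of variants associated with the outcome
at p < 1×10⁻⁵; (4) exclusion of variants on a user-supplied confounder
list (a local, reproducible stand-in for querying a live
confounder-association database); (5) removal of palindromic variants with
intermediate allele frequency during harmonization; (6) proxy substitution
(panel r² ≥ 0.8) for instruments missing from the outcome study.  Proxy
search runs before steps 3–5 in the code because those steps need outcome
statistics, but exclusions are logged under their protocol step numbers.

Design points: palindromic variants are dropped **only** when their
frequency is inside the configurable band [0.42, 0.58] (or missing);
informative palindromes are oriented by frequency and retained, matching
protocols that keep some palindromic instruments.  Candidates absent from
the panel cannot be clumped and are kept with a prominent `no_ld_info`
flag (favouring recall).  Per-instrument F statistics are reported but not
filtered on.  Every candidate surviving step 1 appears exactly once in the
kept set or the exclusion log.

## MR estimators

All five estimators consume the per-instrument Wald ratios β_out/β_exp
with first-order delta-method SEs se_out/|β_exp| (a second-order variant
that adds the exposure-noise term is available behind a flag; first-order
is the ecosystem default).

* **Random-effects IVW** (primary): inverse-variance-weighted mean;
  multiplicative random effects scale the SE by √(Q/(k−1)) when that
  exceeds 1, never below.
* **MR-Egger**: weighted regression of outcome on exposure effects with a
  free intercept after orienting exposure effects non-negative; the
  intercept estimates average directional pleiotropy.  The intercept test
  uses the same multiplicative overdispersion floor.
* **Weighted median**: interpolated 50th percentile of the
  inverse-variance-weighted ratio distribution; parametric-bootstrap SE.
* **Simple/weighted mode**: Gaussian-kernel density mode of the ratios
  with the MAD-based bandwidth rule h = φ·0.9·min(sd, 1.4826·MAD)·k^(−1/5)
  (bandwidth factor φ configurable, default 1), evaluated on a 512-point
  grid; degenerate densities return the heaviest ratio.  SEs by
  parametric bootstrap (default 1,000 resamples, seeded).

Estimates are reported per unit exposure with exp(β) as odds ratio and a
95% CI; p-values are two-sided normal throughout (bootstrap-SE based for
median/mode).

## Sensitivity battery

Cochran's Q (about the IVW estimate, k−1 df) and Rucker's Q (about the
Egger fit, k−2 df) share the same outcome-scale weights, so Q′ ≤ Q holds
by nesting.  MR-PRESSO follows the canonical role assignment: the *global*
test compares the observed weighted leave-one-out residual sum of squares
with parametric simulations under no pleiotropy; the *outlier* test gives
per-instrument simulation p-values, Bonferroni-corrected over k; the
*distortion* test compares the estimate shift after outlier removal
against shifts from random instrument subsets of the non-outlier size.
Some reports swap the global/distortion descriptions; this package keeps
the canonical definitions.  When no outlier is flagged the distortion
field reports `NA`, matching the usual table convention.  Note that with
n_sim simulations the smallest achievable Bonferroni-corrected outlier
p-value is k/(n_sim+1): the default n_sim = 1,000 supports k up to ~50 at
the 0.05 level.

## Screening pipeline

The screen estimates rg for every exposure against the outcome, applies
the Bonferroni threshold α/n_tests (displayed at two significant figures:
0.05/74 → 0.00068) and Benjamini–Hochberg q-values, and assigns tiers:
*significant* (below Bonferroni), *suggestive* (between Bonferroni and α),
*null*.  MR plus the full sensitivity battery run on suggestive-and-better
exposures (configurable).  Exposures whose rg fails (e.g. non-positive
fitted heritability) are tier `null` with a recorded reason.  Reports are
deterministic: identical inputs, configuration and master seed give
byte-identical output files, and the manifest (config echo + seed)
suffices to re-run the screen.

## Synthetic data: what it emulates and what it does not

The bivariate GWAS generator is **summary-statistics-first**: it draws
per-variant z-score pairs whose first and second moments satisfy the LDSC
expectation model exactly (variance N h² ℓ/M + N a + 1 per trait,
cross-moment √(N₁N₂)·rg·√(h²₁h²₂)·ℓ/M), with betas z/√N and SEs 1/√N.
This is exact for the quantities the regression estimates and keeps
desk-scale M feasible; confounding a enters as a shared variance component
so the fitted intercept targets N·a+1 exactly.  Synthetic LD scores are
1 + Gamma-distributed (default mean excess 4), mimicking the right-skewed
genome-wide distribution at desk scale.  What this generator does **not**
emulate: LD-induced correlation between neighbouring z-scores (variants
are exchangeable given ℓ), minor-allele-frequency-dependent architectures,
liability-scale binary traits, and real microbiome abundance
distributions.  Passing tests therefore demonstrate correctness of the
estimators under their own model assumptions, not robustness to every
feature of real data.  Individual-level dosage panels (block-exchangeable
latent-Gaussian haplotypes) back the LD-score, clumping and proxy oracles
at small M.

The MR scenario generator defaults were fixed once, from design analysis:
exposure GWAS N₁ = 50,000 and per-instrument true effects U[0.15, 0.35],
so instruments are strong (F ≫ 100, I²_GX > 0.99) and the relevance
assumption holds with margin — the regime in which Egger-intercept
calibration is meaningful at all (with a weak-instrument exposure panel,
e.g. N₁ ≈ 2,000, the known NOME violation makes the intercept test
intrinsically anti-conservative regardless of implementation); outcome
GWAS N₂ = 200,000 (biobank scale).  Balanced pleiotropy defaults to
direct-effect SD 0.005 (about 2× the outcome SE — heterogeneity clearly
above sampling noise without drowning the signal); directional pleiotropy
defaults to +0.05; the planted outlier defaults to 10 outcome-SEs.  The
homogeneity-null scenario used for Q calibration sets the causal effect to
zero, because with a nonzero effect the first-order Wald SE deliberately
ignores the exposure-side variance term β²·se_exp², and E[Q] then exceeds
k−1 by that (documented) approximation rather than by any property of the
Q statistic.  The screening battery uses a 2,000-variant genome with an
exposure cohort of N = 2,000 — the scale of a single microbiome GWAS —
which yields roughly ten suggestive-threshold instruments per exposure,
comparable to the 12–18 instruments typical of such analyses.

## Numerical choices and degenerate inputs

* The WLS kernel is closed-form normal equations on (per-block) sufficient
  statistics; it agrees with an independent statsmodels solve to 1e-10 and
  makes the 200-block jackknife O(M) total.
* Rank-deficient designs (all LD scores equal) raise an explicit error.
* Harmonization is idempotent; allele re-encoding (swap/complement) of
  both inputs negates aligned effects exactly (involution).
* Mode bandwidth ties are broken toward the lowest grid point; identical
  ratios short-circuit to the common value.
* p-values are floored at 1e-300 so they remain strictly positive.
* All random draws flow from explicit integer seeds; bootstrap and PRESSO
  results are bit-reproducible given the seed.

## Known limitations

* Observed-scale heritability only; no liability-scale conversion for
  binary traits, no partitioned heritability, no iterative LDSC weights.
* First-order Wald SEs understate heterogeneity when instruments are weak
  and the causal effect large (see the Q discussion above).
* No multivariable MR, MR-RAPS, Steiger filtering, leave-one-out forest
  output, or I² statistic.
* Clumping and proxy search trust the supplied panel; candidates missing
  from it are kept, flagged, rather than dropped.
* The confounder-screening step is a local identifier list; it does not
  reproduce a live database query.
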