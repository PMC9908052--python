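# Methods notes

## The estimation problem

Maternal exposures measured in observational cohorts are confounded with
offspring outcomes by shared environment and physiology. Mendelian
randomization (MR) replaces the measured exposure with genetic predictors of
it: because alleles segregate randomly at conception, a variant that raises
the exposure is (under the instrumental-variable assumptions) independent of
the confounders, and the outcome regression of per-SNP outcome effects on
per-SNP exposure effects identifies the causal effect.

Two complications are specific to the maternal setting and drive this
package's design:

1. **The fetal genome.** A mother transmits half her alleles, so an
   exposure-associated maternal variant is correlated (r = 0.5 in dosage)
   with the offspring's genotype, which can affect the outcome directly.
   Raw "offspring birthweight" GWAS effects in mothers therefore mix the
   maternal (intrauterine) path with the fetal path, violating the exclusion
   restriction. The weighted linear model (WLM) solves the two-equation
   system

       E[beta_own]       = beta_F + 0.5 beta_M
       E[beta_offspring] = beta_M + 0.5 beta_F

   per SNP, giving beta_M = (4 beta_offspring − 2 beta_own)/3 and
   beta_F = (4 beta_own − 2 beta_offspring)/3, with variances by the linear
   combination and an optional per-SNP sampling covariance between the two
   input estimates. The covariance defaults to zero — appropriate when the
   own- and offspring-birthweight GWAS come from (nearly) disjoint samples,
   which is the design this emulates; `own_offspring_sampling_cov` provides
   the empirical covariance (≈ 0.5 · se_own · se_off) when both scans share
   one cohort, and the coverage test shows it is needed in that case.

2. **Horizontal pleiotropy.** Instruments may act on the outcome through
   paths other than the exposure. The estimator battery spans the standard
   robustness ladder: fixed-effects IVW (efficient, assumes no unbalanced
   pleiotropy), MR–Egger (consistent under InSIDE, intercept = test for
   directional pleiotropy), weighted and penalized weighted median
   (consistent when ≥ 50% of weight is valid), plus leave-one-out and
   explicit SNP-exclusion re-estimation driven by an external-trait lookup.

## Estimator conventions

- **IVW** uses first-order (outcome-SE-only) weights w = se_y⁻², the
  fixed-effects standard error (Σ w β_x²)^(−1/2), and the normal reference.
  CIs use the 1.96 multiplier.
- **MR–Egger** orients instruments so β_x ≥ 0 (flipping β_y in tandem),
  estimates the residual scale from the weighted fit, and uses t(J−2) for
  slope and intercept. With the scale estimated, the intercept test remains
  calibrated under balanced pleiotropy (verified empirically at 0.05 ± 0.02
  over 1000 replicates). Egger's consistency additionally assumes
  near-noiseless exposure betas: with weak instruments, orientation flips
  re-introduce a small bias (visible in simulation and documented in the
  test suite).
- **Weighted median** uses ratio weights β_x²/se_y² (first-order inverse
  ratio variance), linear interpolation of the weighted empirical CDF at
  probability 0.5, and a seeded parametric bootstrap (default 1000
  replicates) for the SE. The **penalized** variant down-weights SNP j by
  min(1, 20·p_j) where p_j is the χ²₁ upper tail of its heterogeneity
  contribution about the plain weighted median; at penalty scale → 0 the
  weights degenerate gracefully to w_j·p_j.
- **Cochran's Q** is computed about the fixed-effects IVW fit with the same
  first-order weights; the weighting scheme is recorded in the diagnostics
  output because Q's magnitude depends on it.
- **Mean F** is the summary-data approximation mean((β_x/se_x)²); with
  per-SNP r² and GWAS size n it behaves as ≈ 1 + n·r²_j/(1−R²).
- **2SLS** regresses exposure on the standardized genetic score, then the
  outcome on fitted exposure, with the IV variance formula applied to
  residuals against the *observed* exposure; the first-stage F accompanies
  every estimate and an exactly-zero first-stage association raises an
  error rather than returning an exploding ratio.
- **Mediation** is the informal product-of-paths expectation a·b under full
  mediation with first-order delta SE √(a²se_b² + b²se_a²); it is an
  expectation to compare against the total-effect MR estimate, not a formal
  mediation analysis.

## Harmonization rules

Tables are keyed on rsid (1-based GRCh37 positions are carried but not used
as keys). At each shared SNP the outcome record is aligned to the exposure's
effect allele, directly or after strand complement, flipping the beta sign
and complementing the frequency when the allele pair is swapped. Palindromic
(A/T, G/C) SNPs are dropped when min(eaf, 1−eaf) > 0.42 — with frequencies
that close to 0.5 the strand cannot be inferred from frequency; the
threshold is configurable and the screen uses the exposure frequency,
falling back to the outcome's. Irreconcilable allele pairs are dropped with
a per-SNP reason, never a fatal error, and |pairs| + |dropped| equals the
rsid intersection by construction. Proxy substitution takes a
(target, proxy, r²) table — the file-based stand-in for a web LD service —
and substitutes the highest-r² qualifying proxy (default r² ≥ 0.8), breaking
exact ties lexicographically so runs are reproducible.

## The synthetic cohort generator

The generator emulates the statistical structure of the consortium data the
analysis design consumes, not any individual-level dataset:

- 114 independent biallelic SNPs, MAF ~ U(0.05, 0.5), with per-allele
  exposure weights rescaled so the panel explains exactly 6.4% of exposure
  variance (the published instrument strength for serum urate); raw-scale
  summary statistics use the published phenotypic variance 1.767 so the
  variance-explained formula recovers that share from the emitted table.
- Offspring genotypes are one transmitted maternal allele plus one paternal
  allele drawn from the population frequency; fathers are otherwise
  unmodelled, which is adequate because the partition uses only
  mother/offspring duos.
- The causal chain is exposure → mediator → outcome with defaults
  a = 0.07 SD mediator per SD exposure and SD(mediator) = 24.23 mmHg (the
  published SBP values). The mediator → outcome path `b_sbp_to_bw` has **no
  default**: its point value lives in supplementary material not available
  to this implementation, so it must be set by the caller. All
  simulation-based tests and the acceptance script use −12/0.07 ≈ −171.4 g
  per SD, the value implied by the published mediation arithmetic.
- A single standard-Gaussian latent confounder loads on exposure (0.32 SD)
  and outcome (−50 g), chosen so the confounded observational regression
  lands near −28 g/SD against a causal −12 g/SD — the qualitative contrast
  the method exists to expose. Covariates (age, BMI, smoking, offspring sex,
  gestational age) are drawn at realistic means/SDs but independent of the
  causal chain; they exercise the adjustment machinery without changing the
  estimand, while the latent confounder remains deliberately unadjustable.
- Pleiotropy scenarios put per-allele direct maternal effects on a fraction
  of SNPs: mean zero for balanced (InSIDE-satisfying) pleiotropy, nonzero
  mean for directional. The default is no pleiotropy.
- Birthweight is centred at 3503 g with residual SD 430 g, giving a total SD
  near the observed ≈ 477 g once the mediator, genetic and confounder
  channels are added. Note that a mediator path of −171 g/SD makes the
  mediator channel account for a larger share of outcome variance than in
  real cohorts; this inflates nothing downstream (estimators see only
  per-SNP effects) but is worth knowing when reading raw phenotypes.
- `simulate_summary_instruments` draws instrument sets directly from the
  betas' asymptotic sampling distributions around the generative truth; it
  is used for replicate-heavy Monte Carlo (type-I error, estimator-bias
  studies) where individual-level simulation would be wastefully slow.

What the generator does **not** emulate: linkage disequilibrium between
instruments (the emulated panel is independent by construction), non-European
allele-frequency spectra, per-SNP heterogeneity in meta-analysis sample
sizes, gestational-duration effects, and assortative mating. Consequently,
passing tests demonstrate correctness of the estimators and pipeline under
the stated generative model, not robustness to those real-data features. Two
published diagnostics are not reproducible from this structure: a uniform
n = 288,649 exposure GWAS explaining 6.4% over 114 SNPs implies a mean F
near 175 (the published 126.9 embeds heterogeneous per-SNP sample sizes),
and the generator's pleiotropy-free default concentrates Cochran's Q at its
degrees of freedom (the published 257.1 reflects real-instrument
heterogeneity). Both computations run and are asserted against the published
values in the acceptance suite, where they fail for exactly these reasons;
we chose not to tune unpublished nuisance distributions to force agreement.

## Numerical and reporting choices

- Per-SNP GWAS scans are moment-based vectorized simple regressions;
  monomorphic SNPs are excluded with a warning. p-values are clipped into
  (0, 1] to respect the record invariant at extreme z.
- Genetic scores mean-impute missing dosages per SNP and z-score against the
  analysis sample (ddof = 1); an all-missing SNP is excluded with a warning.
- The observational stage standardizes the exposure within the
  complete-case analysis sample (listwise deletion, counts reported) and
  names collinear columns on rank deficiency instead of failing opaquely.
- Problem sizes in the test suite are chosen to make each Monte Carlo check
  decisive at its stated tolerance: 1000 replicates for type-I error
  (±0.02), 500 for estimator-bias contrasts, ≥ 300 intervals for CI
  coverage (±0.03), n = 20,000 duos for transmission/variance-share checks
  (±0.02 / ±0.01), n = 50,000 for recovery of the −12 g/SD truth within two
  standard errors. The acceptance script uses the published sample sizes
  directly.
- Pipeline reports contain no timestamps, carry config/input SHA-256 hashes,
  the seed and the package version, and serialize with sorted keys, so a
  fixed config + seed reproduces `report.json` byte for byte. Bootstrap
  seeds are derived deterministically from the config seed.
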