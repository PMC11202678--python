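# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices and the known limitations of `phsgp`.

## Trait definitions

Five PHS-related traits are carried through the pipeline as trait columns:
lab sprouting score (LS, ordinal 1–9), germination index (GI, in [0, 1]),
falling number at maturity (FN1), after rain/delayed harvest (FN2), and
falling number stability after a controlled after-ripening and wetting
protocol (FNS); FN traits are in seconds.  The wet-lab protocols themselves
are out of scope — computationally each trait is a plot-level column.

The germination index weights early germination highest:

    GI = Σ_d (D − d + 1) n_d / (D · n_total),   d = 1..D days,

with n_d seeds germinating on day d.  GI = 1 iff every seed germinates on
day one, GI = 0 with no germination, and moving any germination event one
day earlier never decreases GI.  The weighted form with D = 6 observation
days is the package default; the day count is a parameter.

## Trial models (module `phsgp.trial`)

The field layout is an unreplicated augmented design: entries appear once
per location, and three check varieties are repeated in every one of ten
blocks, which makes the residual variance estimable.  Three REML models are
used:

* **Per-environment repeatability** — y = μ + block + entry + e with block
  and entry random; rep² = σ²_entry / (σ²_entry + σ²_e).
* **Adjusted means (BLUEs)** — genotype and location fixed,
  block-within-location and genotype×location random.  The reported mean is
  the genotype BLUE plus the average location effect (lsmeans-style).
  Genotype is fixed here deliberately: shrinking twice (BLUP means into
  GBLUP) would attenuate the prediction targets.
* **Heritability** — the all-random variant of the same model, on an
  entry-mean basis with one replicate per location:
  h² = σ²_g / (σ²_g + σ²_g×l / L + σ²_e / L), with L the number of
  locations carrying the trait (traits absent at a location are handled by
  per-trait location subsetting).

Location main effects enter the across-location models as fixed effects;
blocks nested within locations are random.  In an unreplicated design the
genotype×location term is separable from the residual only through the
checks; the two components trade off, but the h² denominator involves only
their L-weighted sum, so the estimate is insensitive to that confounding.

### REML engine (`phsgp.mixed`)

All trial models are instances of y = Xβ + Σ Z_i u_i + e with
u_i ~ N(0, σ_i² I).  With θ_i = σ_i²/σ_e² and H(θ) = I + Σ θ_i Z_i Z_i',
β and σ_e² profile out analytically and the restricted likelihood is
optimized over the ≤3 log-ratios only — Brent's bounded method for one
ratio, a coarse 3-per-dimension grid scan followed by Nelder-Mead
(tolerance 1e-8 on −2ℓ) for two or three.  Each evaluation is one dense
Cholesky of H, exact and fast at trial sizes (a few hundred to a couple
thousand plots).  Boundary solutions (a ratio collapsing to zero) are
clamped to exactly zero; variance ratios are clamped to [0, 1] with a flag.
Data that interpolate the fixed effects exactly (zero residual) short-
circuit to the least-squares solution with σ_e² = 0 rather than chasing a
divergent log-likelihood.  The engine reproduces lme4 REML fits to the
printed precision on the package's crossed trial models, and equals
closed-form ANOVA estimators on balanced designs (tested).

## Genotypes (module `phsgp.genotypes`)

Dosages count minor-allele copies (0/1/2, NaN missing).  QC order: lines
first (missing fraction > 20%, or heterozygosity > 12.5% as the proxy for
residual heterogeneity in F6 material, whose expectation is ~3%), then
markers (MAF > 0.01 strict, missing fraction < 5% strict, exact duplicate
columns collapsed to the lexicographically smallest marker id so the
retained set is independent of column order).  Missing calls are imputed
by Binomial(2, p̂) draws.  The VanRaden matrix uses centering frequencies
estimated once from the full genotyped panel and is computed once and
sliced per cross-validation fold, so every fold sees the same kinship.

## GBLUP (module `phsgp.gblup`)

With A = U D U', rotating by U' diagonalizes the covariance and the REML
profile over λ = σ_t²/σ_e² is a one-dimensional bounded search on log λ
(bounds [1e-6, 1e6], xatol 1e-10).  A ridge of 1e-6 is added to the
eigenvalues only when the smallest is below 1e-8 (A built from fewer
markers than lines is typically rank n−1 because of the centering).
Fixed-effect covariates are additive 0/1/2 dosages; aliased columns are
removed by pivoted QR at relative tolerance 1e-8 and recorded.  Variance
components are re-estimated inside every training fold.  Prediction of
unphenotyped lines uses the conditional expectation
t̂_new = A_cross A_train⁻¹ t̂_train, which is algebraically identical to
solving the joint mixed-model equations with the new lines' records
missing (tested) and cheaper per fold.  The GBLUP fit equals matched-
variance ridge-regression marker predictions when A = ZZ'/d (tested to
1e-6), the standard GBLUP↔RRBLUP identity.

## Evaluation (module `phsgp.evaluation`)

Cross-validation stratifies folds by breeding program: within each program
the lines are permuted and dealt to a randomly ordered cycle of the k
folds, so per-program fold sizes differ by at most one.  One fold plan
(identified by a content hash) is shared across model variants; the paired
t-test pairs runs by (replicate, fold).  Predictive ability is the Pearson
correlation; runs with a constant prediction or response are recorded as
missing and excluded from means.  Across-season scenarios train on one
season's adjusted means (all 298 lines, or the 199 calibration-set lines)
and correlate predictions with the other season's means for either the
calibration set (199) or that season's validation set (99); the
between-season block reports r(OBV, OBV) and r(GEBV, GEBV) on calibration
lines from per-season full-data fits.  The haplotype analysis groups lines
by homozygous two-marker dosage classes at the major locus (heterozygous
or missing calls excluded, logged) and compares class means by pairwise
Welch tests with Bonferroni correction at α = 0.05.

## Synthetic data (module `phsgp.synthetic`)

The generator emulates the cohort the analysis targets:

* **Population** — 400 F6 lines from six programs (80/80/80/94/20/46), a
  200-line calibration set evaluated in both seasons and two 100-line
  season-specific validation sets, allocated across programs by largest
  remainder.  Loci are independent (no linkage map): ancestral frequencies
  uniform on the MAF bounds, program frequencies diverged by a
  Balding–Nichols Beta draw whose parameter plays the role of F_ST
  (default 0.02 — elite material shows weak structure).  Default MAF bounds
  (0.02, 0.45) give a realized mean MAF ≈ 0.23, matching the emulated SNP
  panel; columns whose realized frequency leaves the bounds are redrawn, so
  generated panels pass QC unchanged.  Residual heterozygosity is overlaid
  at 1% (F6 expectation ~3%, breeders' panels usually lower after QC).
* **Architecture** — a polygenic background of N(0, ·) effects plus one
  major locus on two markers with equal effects, scaled to a target share
  of genetic variance (default 30%, the regime where weighting a major QTL
  helps); a third marker tags the same locus so the 17-marker tracked panel
  contains one three-marker QTL group (the *Phs-A1* analogue) and 14
  single-marker groups.  Three further markers are flagged as FN-per-se
  loci with no effect on the PHS trait.  The variance share is approximate
  (covariance with the background is not orthogonalized); the realized
  share is within a few points of the target.
* **Trials** — plot records y = μ + loc + block(loc) + g + g×loc + e with
  every entry once per location in a random block and every check in every
  block.  Defaults: 5 locations, 10 blocks, 3 checks, σ²_loc = 1,
  σ²_block = 0.25, σ²_g×l = 0.05 on a unit-genetic-variance scale, trait
  mean 300 (falling-number seconds).  The residual variance is back-solved
  from a target entry-mean heritability (default 0.85, the
  falling-number-stability regime; the emulated study spans ~0.58–0.88), so
  the generator's parameters are exactly the values the estimators are
  asked to recover.  Bounded traits are truncated to scale and LS rounded
  to its ordinal grid.
* **Germination** — each seed germinates on day d with geometric hazard
  propensity·(1−propensity)^(d−1); propensity 1 puts all seeds on day one,
  0 none, and the first-day count is monotone in propensity in expectation.
* **Two-season cohort** (`simulate_study_cohort`) — drops one line per
  cohort to mimic QC losses (397 lines: 199 + 99 + 99, reproducing the
  bookkeeping N_ES ∈ {298, 199}, N_TS ∈ {199, 99}) and produces per-season
  line-level means sharing genetic values (a genetic correlation < 1 can be
  requested).

What the generator does **not** emulate: linkage disequilibrium, selection
within programs, genotype-by-season interaction of environmental origin,
spatial field trend, and weather-driven trait expression.  Consequently
passing tests demonstrate the correctness of the estimators and the
direction of the modeling effects under the stated assumptions — not the
reproduction of any particular field study's numbers, which depend on LD
structure and season quality.  One practical consequence: with independent
loci the number of simulated markers sets the effective dimensionality of
the prediction problem, so cohort-level predictive abilities are calibrated
by marker count.  The "FNS regime" used in examples and reported quantities
(n = 300, 600 markers, 150 polygenic loci, major-locus share 30%,
h² = 0.85) was chosen so that the plain GBLUP model's mean predictive
ability falls in the ~0.5–0.6 range typical of high-heritability PHS traits
in breeding material; the QTL-direction checks also hold at 2,000 markers,
where absolute abilities are lower.

## Problem sizes used in tests and reported quantities

REML recovery of trial statistics runs at 60 unreplicated entries plus the
full check/block/location design (10 blocks, 3 checks, 5 locations; 450
plots per season) over 100 simulation seeds; GBLUP variance-ratio recovery
at n = 400 over 100 replicates per heritability; cross-validation checks at
n = 300 with 2 replicates × 5 folds per seed; the across-season scenario
checks on the full 397-line cohort bookkeeping.  These sizes keep the whole
suite to a few minutes while leaving Monte-Carlo error well inside the
stated tolerances (mean-of-seeds standard errors ≲ 0.01 for the variance
ratios).

## Known limitations

* The REML engine is dense; it targets trial-sized data (≲ a few thousand
  plots), not national multi-environment networks.
* Heterozygotes are kept as dosage 1 in covariates and haplotype classes
  are restricted to homozygotes — adequate for inbred line material, lossy
  for outbred panels.
* The paired t-test over cross-validation runs ignores the dependence
  between runs within a replicate, as is conventional; its type-I rate is
  therefore approximate, and the test suite checks calibration only within
  a widened band.
* Ordinal LS is modeled as rounded Gaussian; no threshold model is fit.
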