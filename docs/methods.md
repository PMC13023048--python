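# Methods

This package studies genotype-by-environment interaction (GxE) for
birth weight (BW) and weaning weight (WW) in beef cattle exposed to
prenatal drought and heat stress, using pedigree-based reaction-norm
animal models. Everything runs on synthetic herdbook data generated by
the package itself, so every estimate can be checked against the truth
that generated it.

## Environmental conditions

Four environmental conditions (EC) summarise the weather before an
animal's birth, each anchored at the birth date:

* `sumPrec365`, `sumPrec280`, `sumPrec90` — cumulative precipitation
  (mm) over the 365, 280 and 90 days before birth (pre-conception
  through late gestation drought exposure);
* `meanTHI90` — mean hourly temperature-humidity index over the 90 days
  before birth (late-gestation heat load).

THI is the outdoor-cattle form `THI = (1.8 T + 32) − (0.55 − 0.0055 RH)
(1.8 T − 26)` with T the air temperature in °C and RH the relative
humidity in percent (the 0.0055 coefficient makes the adjustment vanish
exactly at RH = 100, which fixes the percent convention). RH comes from
the August–Roche–Magnus saturation ratio
`RH = 100 · exp(17.625·DT/(243.04+DT)) / exp(17.625·T/(243.04+T))`
with DT the dewpoint. The additive Magnus denominator `243.04 + x` is
used; the multiplicative variant is not the named formula and
degenerates at DT → 0.

Window conventions: half-open `[birth − w, birth)` — the birth day
itself is excluded, so the 365-day sum decomposes exactly into the
280-day sum plus the preceding 85 days. `meanTHI90` averages the hourly
THI values (not the THI of averaged inputs); at least 95% of the
expected hours must be present (configurable).

Each EC is rescaled linearly onto [−1, 1] from its min/max over the
post-QC analysis records, and the reaction-norm covariates are the
first-order Legendre pair φ(t) = (1, t). The (min, max) pair is
persisted so new animals can be projected onto the same gradient.

## Data quality control

Rules, applied in this order: (1) drop records with no birth date or
with neither trait; (2) per trait, set values beyond mean ± 3.5 SD to
missing, with mean/SD computed once on the pre-filter distribution (no
iterative re-trimming) within breed and trait; (3) re-apply the
no-trait rule; (4) recode dam parity to classes 1–7 (7 pools > 6);
(5) form contemporary groups (CG) as farm × birth year × season —
early rainy Oct–Dec, late rainy Jan–Apr, early dry May–Jul, late dry
Aug–Sep — and drop groups with five or fewer records. The order is a
choice (the rules themselves don't prescribe one); it is deterministic,
conservative, and idempotent, and every exclusion is logged with a
reason code so retained + excluded always reconciles with the input.

## Phenotypic screen

Before the genetic models, each trait is regressed on each raw EC in a
univariate linear mixed model: fixed sex×birth-type class, parity
class, vegetation zone, weaning-age covariate (WW only) and the raw EC;
random intercepts for dam (no pedigree) and CG. The EC coefficient is
reported per raw unit (kg/mm, kg/THI-unit) with a Wald z test. Raw EC
is used here — the coefficients are meant to be read in physical units —
whereas the reaction-norm models use the scaled EC.

## The bivariate maternal reaction-norm model

For traits 1 = BW, 2 = WW:

    y_t = X_t a_t + Q_t b_t + R_t c_t + Z_t u_t + W_t v_t + e_t

with fixed effects `a_t` (sex×birth-type, parity class, vegetation
zone, weaning age for WW, and a fixed regression on the scaled EC whose
intercept is absorbed into the overall intercept), CG effects `b`, MPE
(maternal permanent environment, per dam) effects `c`, and direct (`u`)
and maternal (`v`) additive-genetic random regressions with intercept
and slope on the scaled EC. The maternal covariate is evaluated at the
record's own EC and attaches to the record's dam; records with an
unknown dam get a zero maternal row and no MPE term, and are counted.

The stacked per-animal coefficient vector

    [u_bw0, u_bw1, u_ww0, u_ww1, v_bw0, v_bw1, v_ww0, v_ww1]

has prior covariance A ⊗ G8 with A the pedigree numerator relationship
matrix, so the unstructured 8×8 G8 carries the direct 4×4, maternal
4×4 and direct-maternal cross blocks jointly. CG and MPE effects have
unstructured 2×2 covariances across traits (Cg, Pm); residuals have an
unstructured 2×2 R, with partially observed records contributing
through the inverse of the residual sub-block of their observed traits.
Genetic coefficients span *all* pedigree animals (a dam without her own
record is still estimable through her progeny and the pedigree). Each
EC defines its own model; four ECs mean four independent fits.

## Pedigree machinery

A is never built at model scale: the mixed-model equations use the
sparse Henderson inverse with inbreeding, assembled from per-animal
Mendelian-sampling variances d_i = 0.5 − 0.25(F_s + F_d) (an unknown
parent enters with F = −1, i.e. one phantom founder population, no
genetic groups). Inbreeding coefficients come from the Meuwissen–Luo
recursion; `log|A| = Σ log d_i` falls out of the same decomposition and
enters the likelihood exactly. The dense tabular A exists only as a
test oracle (capped at 5,000 animals).

## EM-REML

Variance components are estimated by EM-REML on Henderson's mixed-model
equations. Each iteration solves the MME at the current components and
applies the exact EM updates

    B_k ← (Û' K⁻¹ Û + tr-block(K⁻¹ C_kk)) / q_k          (each term)
    R   ← mean over records of E[e e' | y]                (missing-data E-step)

where C is the inverse of the MME coefficient matrix. The trace terms
need only *selected* entries of C: prediction-error covariance blocks
on the pattern of K⁻¹ and record-level quadratic forms, all of which lie
on the nonzero pattern of the MME matrix itself. A hand-written sparse
LDL' factorization with a Takahashi selected inverse (numba kernels,
minimum-degree ordering obtained from SuperLU's symmetric mode) delivers
exactly these entries at roughly the cost of one factorization, so no
dense inverse is ever formed; a dense LAPACK backend covers small
problems and cross-checks the sparse path in the tests. Because the
assembled matrix has an identical sparsity structure every iteration,
the ordering, symbolic analysis and index maps are computed once per
problem and only the numeric factorization is repeated.

The restricted log-likelihood is evaluated every iteration from the
same factorization via −2lR = log|R*| + log|G| + log|M| + y'Py +
(n−p)·log 2π and is non-decreasing across EM iterations; the fitter's
trace records it and the test-suite asserts the monotonicity on every
fit.

### Acceleration

Plain EM stalls in this model class: variance components of weakly
informed directions (above all the genetic slope blocks, whose
per-animal coefficients have prediction-error variance close to their
prior variance) contract by factors like 0.999 per iteration. Two
monotonicity-preserving devices fix this without leaving the EM
framework:

* **Safeguarded squared extrapolation.** Each cycle takes two exact EM
  steps and proposes an entry-wise squared-extrapolation jump along the
  EM trajectory (step factors clipped to [−32, −1]); the jump is kept
  only if a cheap likelihood evaluation shows no decrease, otherwise
  the plain double step stands. Either way the accepted sequence is
  non-decreasing in the restricted likelihood.
* **Likelihood scale searches (ECME-style moves).** For designated
  coordinate subsets — all genetic slope coordinates, the maternal
  block, and the MPE and CG blocks — a multiplicative scale is
  line-searched directly against the restricted likelihood on a small
  grid. A group is searched every cycle until the unit scale wins twice
  in a row, then only re-checked occasionally. Accepted moves strictly
  increase the likelihood. These searches break the slow geometric
  modes in a handful of evaluations where bare EM would need thousands
  of iterations.

Convergence is declared when the largest relative component change
falls below `tol` or the likelihood improvement falls below
`loglik_tol`; defaults are 1e-6 / 1e-8 with `max_iter` 500, and the
analysis scripts use desk-scale settings (60 iterations, tol 1e-3)
documented in their headers. Indefinite updates are clamped to the
nearest PSD matrix with an eigenvalue floor of 1e-8 × trace/dim, and
every clamp is counted. Starting values split each trait's
fixed-effect-adjusted phenotypic variance (OLS residual variance —
adjusting first matters for WW, whose raw variance is dominated by the
weaning-age covariate): 10% per genetic intercept, 5% per genetic
slope, 10% each MPE and CG, 50% residual, zero covariances.

## Derived parameters

With φ(t) = (1, t) and a fitted 2×2 coefficient block B, the genetic
variance at gradient t is φ(t)'Bφ(t). Direct and maternal
heritabilities at t divide the respective genetic variance by
σ²u + σ²v + σuv + σ²mpe + σ²cg + σ²e, with the direct-maternal
covariance σuv entering the denominator once (coefficient exactly 1 —
not 2σuv, not Willham's 1.5σuv) and evaluated at the record's gradient
via the cross 2×2 block of the same trait. Cross-gradient correlations
rEC(a,b) = φ(a)'Bφ(b)/√(v(a)v(b)) quantify GxE (values below ~0.8 read
as meaningful re-ranking potential); cross-trait correlations use the
BW-WW cross block at a common gradient; r_{μ0μ1} and the
slope-to-intercept variance ratio σ²μ1/σ²μ0 summarise how much genetic
variation is environmental sensitivity rather than baseline merit. All
ratios guard their denominators and raise a flagged error rather than
return silent nonsense. The default gradient grid is 11 equally spaced
points on [−1, 1].

## Breeding values and plasticity

Direct EBVs along the gradient are the affine trajectories
EBV_i(t) = μ0_i + μ1_i·t from the BLUP solutions. Plasticity classes
follow the |slope|-versus-population-SD rule: robust (|μ1| < σμ1),
plastic (σμ1 ≤ |μ1| < 2σμ1), extremely plastic (|μ1| ≥ 2σμ1), with σμ1
the SD of μ1 over *all* animals of the fitted pedigree (not elite sires
only) and left-closed boundaries. Elite sires are those with at least
20 QC-retained progeny records; re-ranking across gradients is reported
as Spearman rank correlations and top-10 overlap at t ∈ {−1, 0, +1},
ties broken by animal id.

## The synthetic herdbook generator

The generator emulates the structure such an analysis meets in a
Southern-African herdbook: discrete generations with repeated dams
(calves at successive parities in successive years on the dam's farm),
widely used AI sires linking farms, calving concentrated in the early
rainy season but present year-round, farm × year × season contemporary
groups, seasonal rainfall (Bernoulli occurrence × gamma amounts with
lognormal drought-year and farm effects around 350 mm/yr), and hourly
temperature/dewpoint as annual + diurnal sinusoids with noise, dewpoint
clamped at saturation. Default counts mirror a single breed's herdbook
proportions (~13–15k records, ~600 potential contemporary groups, 12
farms); all counts are configurable and the analysis scripts use a
smaller herd (~1,900 animals on 6 farms) as their desk-scale default.

Phenotypes are drawn under exactly the model fitted: genetic
coefficients by the recursive parent-average + Mendelian-sampling
construction (covariance A ⊗ G8 without ever forming A), maternal
contributions from the dam's coefficients at the record's EC, MPE per
dam, CG effects per group, 2×2 residuals, WW set missing at a
configurable rate, weaning age uniform on 180–260 d (a stated choice;
the real distribution is only known to lie in 150–300 d). One integer
seed drives everything through `SeedSequence` spawning, one child
stream per stage, so outputs are byte-identical across runs.

What the generator does *not* emulate: spatial weather correlation
between farms, selection (parents are sampled at random, so no genetic
trend), heterogeneous residual variance along the EC, preferential
treatment, or pedigree errors. Passing recovery tests therefore shows
the estimator is correct under the stated model, not that real
herdbook data meet these assumptions.

## Verification strategy and problem sizes

Every layer has an independent oracle: THI/RH closed-form identities;
the tabular A and the Meuwissen–Luo recursion against the sparse
Henderson inverse (50 random pedigrees); MME solutions against dense
GLS/BLUP with explicitly built V (20 toy problems, tolerance 1e-8); the
restricted likelihood against the dense textbook expression; the EM
fixed point against a generic optimizer of the dense REML likelihood
(within 2% per component, on problems of ≤ 300 records where the dense
path is exact); and parameter recovery on a ten-scenario battery
spanning direct h² 0.1–0.5, maternal h² 0.05–0.2 and slope-to-intercept
ratios 0.1–2 (median absolute heritability error at gradients −1, 0, +1
below 0.08; median cross-gradient correlation error within 0.15).

The battery runs at ~2,300 pedigree animals per scenario (280 founders,
three generations, six farms) — the package's desk-scale choice; the
estimator is size-agnostic. At these sizes one caveat is visible and
expected: when the true slope variance is a very small fraction of the
phenotypic variance (ratio 0.1), its REML estimate is noisy upward —
the restricted likelihood is nearly flat in these directions and its
maximiser sits above the tiny truth — which inflates the apparent GxE
(lowers rEC between extremes) for those scenarios. The battery medians
absorb this; single low-ratio fits should be read with that caveat.
Larger herds tighten the heritability errors but the flat-ridge noise
on near-zero slope variances shrinks only slowly.

## Known limitations

* No standard errors for variance components or derived parameters (no
  AI-REML information matrix; an optional bootstrap would be the
  package-consistent route).
* First-order (intercept + slope) Legendre regressions only; no
  higher-order norms, no heterogeneous residual classes along the EC.
* The univariate screen's dam effect is a plain random intercept, not a
  pedigree-linked effect.
* Single-breed runs only; multi-breed analyses are separate runs by
  design.
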