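# Methods

## Degradation model

Meropenem loss in an infusate or in buffered serum is modelled as a single
first-order process, `C(t) = C0·exp(−k·t)`. `fit_first_order_decay`
estimates `(C0, k)` by unweighted least squares on the linear
concentration scale, with all replicates entering as independent
observations; `C0` is estimated jointly with `k` rather than pinned to the
t = 0 sample, so a noisy baseline does not bias the rate. A log-linear
ordinary-least-squares fit is provided as a cross-check
(`fit_log_linear`); the two agree exactly on noise-free data but weight
noise differently, and the linear-scale fit is the default because assay
error is proportional to concentration, not to its logarithm. The standard
error of `k` comes from the curvature of the least-squares objective at
the optimum (the Jacobian-based covariance of `scipy.optimize.curve_fit`).
Fits are rejected with a diagnostic when the series is all-zero,
non-finite, has fewer than three distinct time points, or the rate runs
into the 10/h divergence bound.

Derived quantities are closed-form: recovery `100·e^{−kt}`, stability
window `−ln(θ)/k` for threshold θ (default 0.90, the pharmacopoeial
criterion; `k = 0` yields an infinite window, returned as `inf`),
half-life `ln 2/k`. Stability verdicts are inclusive (`recovery ≥ 90.0%`).
Report output rounds half-up to one decimal, the convention of clinical
stability tables.

The theoretical ORM curve assumes every degraded parent molecule becomes
one metabolite molecule: `ORM_theo(t) = (C0 − C(t))·MM_ORM/MM_mero` with
MM 383.46 and 401.16 g/mol. The observed shortfall — ORM is itself further
converted, e.g. by decarboxylation — is summarised per time point as
`1 − ORM_obs/ORM_theo`, undefined (and flagged) at t = 0.

## Synthetic data

`gen_decay_series` emulates the stability experiments: sampling at
t = 0, 0.5, 1, 2, 4, 6, 8, 10, 12, 14, 16, 20, 24 h in duplicate, with
multiplicative Gaussian noise of CV 5% by default (the assay's typical
imprecision; its stated bound is 8%), truncated at zero rather than
redrawn — the truncation bias is negligible at CV ≤ 8%. The ORM is
generated as the theoretical curve scaled by a constant
`metabolite_yield` (default 0.8). No study quantifies the ORM recovery
deficit numerically, so this default is a placeholder of plausible
magnitude, not a measured value; at yield 1 and zero noise the generator
conserves moles exactly, which the tests exploit.

`gen_cohort` emulates the patient study: by default six ICU patients with
GFR uniform on 28–307 mL/min (only the range and median are reported, so
uniform is the least-committal choice), constant infusion rates uniform on
125–250 mg/h (3–6 g/24 h), and one sample per day on four consecutive
steady-state days (sampling starts at 48 h, matching the >48 h infusion
criterion; time is bookkeeping only since Css is flat). Clearance gets one
exponential random effect on the whole partitioned sum, `ω = 0.149`
(≈14.9% CV), and observations carry proportional error `σ = 0.135`.

ORM concentrations are co-simulated from a steady-state surrogate: the
non-renal clearance `CL_nonGFR + CL_decay` converts meropenem to ORM,
which is eliminated renally at `0.06·GFR`, giving
`C_ORM = C_mero·(CL_nonGFR + CL_decay)/(0.06·GFR)` in molar terms. This is
deliberately the simplest mass-balance closure consistent with the
partitioned model; it reproduces the qualitative clinical pattern (higher
metabolic ratio at lower GFR, ratios of roughly 0.2–0.5 across the GFR
range) but is not a fitted ORM disposition model — real ORM kinetics
include tubular handling and further degradation that this surrogate
ignores. Passing tests therefore validate the estimators under the stated
statistical assumptions, not the ORM physiology.

All randomness flows from one integer seed through a
`numpy.random.default_rng` handle; identical seeds give byte-identical
CSVs.

## Population model and estimation

The steady-state concentration under zero-order input is `Css = R/CL`,
independent of V. Total clearance is partitioned as

    CL_i = (0.06·GFR_i + CL_nonGFR + CL_decay)·e^{η_i}

with `CL_decay = k_serum·V` fixed (V = 26.2 L from the literature,
k_serum from the serum decay fit) and the GFR term fixed per patient. The
single η multiplies the whole sum, following the reading that
between-patient variability acts on total clearance; a variant with η on
`CL_nonGFR` alone would attribute all variability to the residual
component and is not the default. The reported cohort-level renal
clearance is a summary (mean GFR × 0.06); per-patient values are what
enter the likelihood. ORM concentrations do not enter the likelihood.

The marginal likelihood per patient integrates η out of a proportional-
error Gaussian. The inner problem — the posterior mode of η — is solved by
damped Newton iteration with analytic first and second derivatives (with
`u_ij = (y_ij/Css_i(0))·e^η`, the gradient is
`n_i − Σ(u−1)u/σ² − η/ω²` and the curvature `−Σ(2u²−u)/σ² − 1/ω²`),
vectorised across patients; the curvature is floored away from zero so the
Laplace scale stays defined for pathological patients. The integral is
then approximated by

* **Laplace** (default): `l(η̂) + ½log 2π − ½log(−l''(η̂))`;
* **adaptive Gauss–Hermite quadrature**: ≥ 21 nodes centred at η̂ and
  scaled by `1/√(−l'')`, evaluated with log-sum-exp.

A 201-node trapezoid integration over η ∈ [−6ω, 6ω]
(`neg2ll_bruteforce`) serves as the independent oracle in the tests; on
the fixtures Laplace agrees within 0.05 and quadrature to ~1e−6. `ω = 0`
bypasses the integral with the closed-form fixed-effects likelihood.
The objective is reported in two conventions: the full −2 log-likelihood
including all 2π constants, and a NONMEM-comparable value with
`n_obs·log 2π` removed.

The outer maximisation over `(CL_nonGFR, ω, σ)` runs Nelder-Mead on
log-transformed parameters from five jittered starts (seeded, so fits are
deterministic); tolerances 1e−8. Standard errors come from a central
finite-difference Hessian of −2LL on the natural scale with step
1e−4·|estimate| and `Cov = 2·H⁻¹`; a non-positive-definite Hessian
downgrades the status to `no-standard-errors` with partial results rather
than failing. η-shrinkage is `100·(1 − SD(EBE)/ω̂)`, ε-shrinkage
`100·(1 − SD(IWRES))`. ω is reported as CV% via the exact lognormal
transform `100·√(exp(ω²)−1)`; σ as `100·σ`.

Two properties of proportional-error maximum likelihood are worth knowing
when reading tests: because the residual variance depends on the
prediction, (i) the MLE of θ on noise-free data is exactly the truth only
in the σ→0 limit, and (ii) the posterior mode of η for a patient observed
exactly at the typical prediction is offset from zero by O(n·σ²). Both are
features of the model, not estimator bugs. Noise-free recovery is
therefore tested with the variance components pinned
(`fit_poppk(..., fix={"omega": 0, "sigma": 1e-5})`); estimating them from
noise-free data is unidentified (a likelihood ridge with σ→0 and θ
absorbed by the η's).

Integer clearance fractions use largest-remainder apportionment so the
printed percentages always total exactly 100; naive per-component
rounding does not (and sits on a knife edge for these particular
components).

## Clinical metrics

The metabolic ratio is `C_ORM/(C_ORM + C_mero)`. The explicit formula is
defined on concentrations, so mass basis is the default; the molar basis
(each analyte divided by its molar mass) is available and both are
order-preserving transformations of each other. Per-patient summaries are
medians of per-sample ratios; both per-sample and per-patient tables are
emitted because summaries of ratios and ratios of summaries differ.
The ratio–GFR association is the squared Pearson correlation on
per-sample pairs with a permutation p-value (10⁴ seeded permutations,
add-one correction). Creatinine clearance is the urine-collection
quotient `(crea_U·V_U)/(t·crea_P)` in mL/min; GFR converts to clearance
units by ×0.06 (mL/min → L/h).

## Pipeline

`run_full_pipeline` chains simulate → decay fits (saline, serum) →
`CL_decay = k·V` → population fit → clearance partition → metrics, with
stage-attributed failures (disabling the serum stage makes the population
stage refuse for lack of its `CL_decay` input). Each stage writes tidy
CSV/JSON artifacts consumed by the next without manual editing; the run
manifest records the configuration, package version, and SHA-256 checksum
of every artifact, so identical config + seed reproduces identical
checksums. Configuration is a flat YAML file; `configs/study_defaults.yaml`
holds the defaults.

## Problem sizes and defaults

The parameter-recovery checks use 300 simulated patients (CV-level
quantities stabilise to a few percent relative at that size, matching the
±10–15% recovery tolerances) and 50 replicates of 100 patients for bias
and Wald-coverage checks; decay-fit calibration uses 200 simulated
duplicate experiments. The full default test suite runs in well under a
minute.

## Known limitations

* No absorption/distribution phases, non-steady-state accumulation,
  multi-compartment structure, covariate search, or time-varying
  clearance; the data the model targets are flat steady-state samples.
* No Arrhenius temperature extrapolation, pH dependence, or
  concentration-dependent (aminolysis) kinetics in the degradation model.
* The ORM co-simulation is a surrogate (see above); ratio-based results
  on synthetic cohorts demonstrate estimator behaviour, not ORM biology.
* The sandwich (robust) covariance estimator is not implemented; RSEs are
  Wald/Hessian-based.
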