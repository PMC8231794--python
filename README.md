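# meropk

Meropenem, a carbapenem beta-lactam given to critically ill patients by
continuous infusion, hydrolyses spontaneously to a microbiologically
inactive open-ring metabolite (ORM) — in the infusion syringe, and in the
patient's bloodstream. `meropk` is a Python package for quantifying both
sides of that process:

* **Degradation kinetics** — fit the first-order model
  `C(t) = C0·exp(−k·t)` to replicated concentration–time series, derive
  the pharmacopoeial stability window (time above 90% of the initial
  concentration), half-life, and the ORM mass balance against the
  theoretical equimolar-conversion curve.
* **Population pharmacokinetics** — a steady-state one-compartment model
  with zero-order input whose total clearance is partitioned as

  `CL_i = (0.06·GFR_i + CL_nonGFR + CL_decay)·e^{η_i}`,  `η_i ~ N(0, ω²)`

  with `CL_decay = k_serum·V` fixed from the in vitro serum experiment,
  the renal component fixed to each patient's measured GFR, and the
  residual component `CL_nonGFR` estimated by from-scratch nonlinear
  mixed-effects maximum likelihood (Laplace approximation or adaptive
  Gauss–Hermite quadrature), with proportional residual error
  `y = Css·(1+ε)`, `ε ~ N(0, σ²)`. Standard errors, η/ε-shrinkage,
  empirical Bayes estimates and NONMEM-style goodness-of-fit tables are
  reported.
* **Clinical metrics** — the ORM metabolic ratio
  `C_ORM/(C_ORM + C_meropenem)` (mass or molar basis), urine-collection
  creatinine clearance, and the ratio–GFR association with a permutation
  p-value.
* **Synthetic data** — seeded generators for decay experiments and
  steady-state TDM cohorts with exactly the statistical structure the
  fits assume, so every estimator is exercised against known truth.

It is written for clinical pharmacologists and pharmacometricians who
want the full bottle-to-body stability analysis as a tested, reproducible
pipeline rather than a spreadsheet plus a NONMEM run.

## Worked example

```sh
meropk run-all --seed 1 --out results/demo
```

simulates both stability experiments (duplicate sampling at
0–24 h, 5% proportional assay noise), fits the decay rates, bridges the
serum rate into `CL_decay = k·V`, simulates and fits a six-patient
steady-state cohort, partitions the clearance and summarises the
metabolic ratios. It prints:

```
  k_saline_per_h: 0.006921
  recovery_24h_saline_percent: 84.7
  k_serum_per_h: 0.0247
  recovery_24h_serum_percent: 55.27
  stability_window_saline_h: 15.22
  half_life_serum_h: 28.06
  cl_decay_L_h: 0.6472
  theta_cl_nongfr_L_h: 3.555
  omega_cl_cv_percent: 13.3
  sigma_prop_cv_percent: 10.46
  cl_total_L_h: 15.68
  ratio_gfr_r_squared: 0.672
  median_ratio: 0.2968
```

Reading this: the fitted saline degradation rate (truth 0.006/h; here
0.0069/h from one noisy duplicate experiment) leaves 84.7% of the
infusate after 24 h and crosses the 90% stability limit at 15.2 h, so a
syringe should be replaced about every 12 h. The serum rate 0.0247/h
(half-life 28.1 h) times the 26.2 L volume of distribution gives a
spontaneous-decay clearance of 0.65 L/h — a small slice of the 15.7 L/h
total clearance of this (hyperfiltrating) simulated cohort. The
mixed-effects fit recovers the residual clearance `CL_nonGFR` ≈ 3.6 L/h
and the variability components, and the ORM ratio falls with GFR
(R² 0.67). `meropk report --manifest results/demo/manifest.json` renders
the same numbers as a markdown report; every artifact is listed in the
manifest with a SHA-256 checksum, and rerunning with the same seed
reproduces the checksums byte for byte.

The same stages are available individually (`simulate decay`,
`simulate cohort`, `fit-decay`, `fit-poppk`, `metrics`), and
`configs/study_defaults.yaml` holds the default study configuration. The
library API mirrors the CLI: see `meropk.fit_first_order_decay`,
`meropk.fit_poppk`, `meropk.partition_clearance`.

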