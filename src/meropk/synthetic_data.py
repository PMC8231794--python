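"""Seeded generators for infusate/serum decay series and TDM cohorts.

These generators emulate the study conditions of the stability experiments
and the patient cohort: first-order parent decay with non-equimolar ORM
formation, multiplicative proportional assay noise in duplicate, and a
steady-state cohort drawn from the partitioned-clearance population model
with exponential between-patient variability.  Every generator is
deterministic under an explicit integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import constants as C
from .degradation_kinetics import ConcentrationSeries
from .poppk import FixedParams, PopPKDataset, individual_clearance, predict_css


@dataclass(frozen=True)
class AssayNoiseModel:
    """Proportional (CV) assay noise with replicate structure.

    The LC-MS/MS assay of the study had proportional imprecision <= 8%
    (typically < 5%); concentrations are truncated at zero after noising.
    """

    cv_proportional: float = 0.05
    replicates: int = 2
    lloq_meropenem: float = C.LLOQ_MEROPENEM
    lloq_orm: float = C.LLOQ_ORM

    def __post_init__(self) -> None:
        if not 0 <= self.cv_proportional < 1:
            raise ValueError("cv_proportional must be in [0, 1)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def apply(self, rng: np.random.Generator, true_values: np.ndarray) -> np.ndarray:
        """Replicate-wise multiplicative noise, shape (n_times, replicates)."""
        true_values = np.asarray(true_values, dtype=float)
        eps = rng.normal(0.0, self.cv_proportional,
                         size=(true_values.size, self.replicates))
        return np.maximum(true_values[:, None] * (1.0 + eps), 0.0)


@dataclass(frozen=True)
class CohortSpec:
    """Size and covariate ranges of a simulated steady-state TDM cohort.

    Defaults emulate the study population: six ICU patients with
    creatinine-clearance GFR between 28 and 307 mL/min, continuous
    infusion of 3-6 g meropenem per 24 h (125-250 mg/h), sampled once
    daily on four consecutive steady-state days.
    """

    n_patients: int = 6
    gfr_range: tuple = (28.0, 307.0)        # mL/min
    dose_range: tuple = (125.0, 250.0)      # mg/h
    samples_per_patient: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.samples_per_patient < 1:
            raise ValueError("samples_per_patient must be >= 1")
        for lo, hi in (self.gfr_range, self.dose_range):
            if lo > hi or lo <= 0:
                raise ValueError("ranges must be positive and ordered low <= high")


def gen_decay_series(k: float, c0: float,
                     times=C.STABILITY_SCHEDULE_H,
                     noise: AssayNoiseModel | None = None,
                     mm_parent: float = C.MM_MEROPENEM,
                     mm_metabolite: float = C.MM_ORM,
                     metabolite_yield: float = 0.8,
                     seed: int = 0,
                     matrix: str = "saline",
                     temperature: float = 22.0) -> ConcentrationSeries:
    """Simulate a replicated parent/metabolite decay experiment.

    Parent follows ``c0 * exp(-k t)``; the metabolite is the equimolar
    conversion curve scaled by ``metabolite_yield`` (< 1 models the
    observed ORM shortfall from further conversion, e.g. decarboxylation).
    Proportional noise is applied independently per analyte and replicate.
    """
    if k < 0:
        raise ValueError("rate constant k must be non-negative")
    if c0 <= 0:
        raise ValueError("c0 must be positive")
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be non-empty")
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    if not 0 <= metabolite_yield <= 1:
        raise ValueError("metabolite_yield must be in [0, 1]")
    noise = noise or AssayNoiseModel()
    rng = np.random.default_rng(seed)

    parent_true = c0 * np.exp(-k * times)
    metab_true = metabolite_yield * (c0 - parent_true) * mm_metabolite / mm_parent
    parent = noise.apply(rng, parent_true)
    metab = noise.apply(rng, metab_true)
    return ConcentrationSeries(times, parent, metab,
                               matrix=matrix, temperature=temperature)


def gen_cohort(spec: CohortSpec,
               fixed: FixedParams | None = None,
               theta_cl_nongfr: float = C.THETA_CL_NONGFR,
               omega_cl: float = C.OMEGA_CL,
               sigma_prop: float = C.SIGMA_PROP,
               mm_parent: float = C.MM_MEROPENEM,
               mm_metabolite: float = C.MM_ORM) -> PopPKDataset:
    """Simulate a steady-state TDM cohort from the partitioned-clearance model.

    Per patient: GFR uniform over ``spec.gfr_range``, a constant infusion
    rate uniform over ``spec.dose_range``, ``eta ~ N(0, omega_cl^2)``, and
    observed meropenem ``y = Css * (1 + eps)`` with
    ``eps ~ N(0, sigma_prop^2)``, truncated at zero.  Sampling times start
    at 48 h (steady state) and advance one day per sample.

    ORM concentrations are co-simulated from a steady-state surrogate: the
    non-renal clearance converts meropenem to ORM, which is eliminated
    renally, giving ``C_ORM = C_mero * (CL_nonGFR + CL_decay)/(0.06*GFR)``
    on the molar scale (times the molar-mass ratio on the mass scale) with
    its own proportional error.  This reproduces the study's pattern of
    higher metabolic ratios at lower GFR.
    """
    fixed = fixed or FixedParams()
    if omega_cl < 0 or sigma_prop < 0:
        raise ValueError("omega_cl and sigma_prop must be non-negative")
    rng = np.random.default_rng(spec.seed)

    rows = []
    for i in range(spec.n_patients):
        gfr = rng.uniform(*spec.gfr_range)
        rate = rng.uniform(*spec.dose_range)
        eta = rng.normal(0.0, omega_cl) if omega_cl > 0 else 0.0
        cl = individual_clearance(fixed, theta_cl_nongfr, gfr, eta)
        css = predict_css(rate, cl)
        orm_css = (css * (theta_cl_nongfr + fixed.cl_decay)
                   / (fixed.gfr_to_clearance_factor * gfr)
                   * mm_metabolite / mm_parent)
        for j in range(spec.samples_per_patient):
            t = 48.0 + 24.0 * j
            y = max(css * (1.0 + rng.normal(0.0, sigma_prop)), 0.0) \
                if sigma_prop > 0 else css
            y_orm = max(orm_css * (1.0 + rng.normal(0.0, sigma_prop)), 0.0) \
                if sigma_prop > 0 else orm_css
            rows.append((i + 1, t, y, "meropenem", rate, gfr))
            rows.append((i + 1, t, y_orm, "orm", rate, gfr))

    return PopPKDataset(pd.DataFrame(rows, columns=PopPKDataset.COLUMNS))
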