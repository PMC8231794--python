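"""Metabolic-ratio and renal-function metrics for meropenem TDM.

The ORM metabolic ratio ``C_ORM / (C_ORM + C_meropenem)`` summarises what
fraction of circulating drug-related material is the inactive open-ring
form; it rises with impaired renal function because the ORM is cleared
renally.  This module computes the ratio on mass or molar basis,
urine-collection creatinine clearance, the GFR unit bridge, and the
ratio-GFR association with a permutation p-value.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .constants import GFR_TO_L_PER_H, MM_MEROPENEM, MM_ORM
from .poppk import PopPKDataset


def orm_ratio(c_orm, c_mero, basis: str = "mass",
              mm_mero: float = MM_MEROPENEM, mm_orm: float = MM_ORM):
    """ORM metabolic ratio C_ORM / (C_ORM + C_meropenem), in [0, 1].

    ``basis="mass"`` uses the concentrations as given (mg/L); ``"molar"``
    divides each analyte by its molar mass first.  Samples with both
    concentrations zero have an undefined ratio and return NaN with a
    warning.  Vectorized over array inputs.
    """
    if basis not in ("mass", "molar"):
        raise ValueError(f"unknown basis {basis!r}")
    c_orm = np.asarray(c_orm, dtype=float)
    c_mero = np.asarray(c_mero, dtype=float)
    if np.any(c_orm < 0) or np.any(c_mero < 0):
        raise ValueError("concentrations must be non-negative")
    if basis == "molar":
        c_orm = c_orm / mm_orm
        c_mero = c_mero / mm_mero
    denom = c_orm + c_mero
    undefined = denom == 0
    if np.any(undefined):
        warnings.warn("ratio undefined where both concentrations are zero",
                      RuntimeWarning, stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(undefined, np.nan, c_orm / np.where(undefined, 1.0, denom))
    return float(out) if out.ndim == 0 else out


def creatinine_clearance(crea_urine: float, urine_volume: float,
                         collection_time: float, crea_plasma: float) -> float:
    """Urine-collection creatinine clearance, mL/min.

    CrCl = (crea_urine * urine_volume) / (collection_time * crea_plasma),
    with urine volume in mL, collection time in minutes, and both
    creatinine concentrations in the same units.
    """
    if collection_time <= 0 or crea_plasma <= 0:
        raise ValueError("collection time and plasma creatinine must be positive")
    if crea_urine <= 0 or urine_volume <= 0:
        raise ValueError("urine creatinine and volume must be positive")
    return (crea_urine * urine_volume) / (collection_time * crea_plasma)


def gfr_to_clearance(gfr: float) -> float:
    """mL/min -> L/h (x 60/1000)."""
    if gfr < 0:
        raise ValueError("gfr must be non-negative")
    return gfr * GFR_TO_L_PER_H


def ratio_gfr_association(ratios, gfrs, n_permutations: int = 10_000,
                          seed: int = 0) -> dict:
    """Squared Pearson correlation of ratio vs GFR with a permutation p-value.

    The p-value is the fraction of ``n_permutations`` random pairings (plus
    the observed one) with |r| at least as large as observed.
    """
    ratios = np.asarray(ratios, dtype=float)
    gfrs = np.asarray(gfrs, dtype=float)
    if ratios.size != gfrs.size or ratios.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(ratios) == 0 or np.std(gfrs) == 0:
        raise ValueError("correlation undefined for constant input")
    r_obs = float(np.corrcoef(ratios, gfrs)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        r = float(np.corrcoef(ratios, rng.permutation(gfrs))[0, 1])
        if abs(r) >= abs(r_obs) - 1e-15:
            count += 1
    return {"r": r_obs, "r_squared": r_obs ** 2,
            "p_value": (count + 1) / (n_permutations + 1),
            "n": int(ratios.size)}


def cohort_ratio_table(data: PopPKDataset, basis: str = "mass") -> pd.DataFrame:
    """Per-sample ORM ratios for every (patient, time) with both analytes."""
    f = data.frame
    wide = (f.pivot_table(index=["id", "time_h", "gfr_ml_min"],
                          columns="analyte", values="dv_mg_L")
            .reset_index())
    if "orm" not in wide.columns:
        raise ValueError("dataset has no ORM observations")
    wide = wide.dropna(subset=["meropenem", "orm"])
    wide["ratio"] = orm_ratio(wide["orm"].to_numpy(),
                              wide["meropenem"].to_numpy(), basis=basis)
    wide["basis"] = basis
    return wide[["id", "time_h", "gfr_ml_min", "meropenem", "orm",
                 "ratio", "basis"]]


def patient_ratio_summary(sample_table: pd.DataFrame) -> pd.DataFrame:
    """Per-patient median ratio and GFR from a per-sample ratio table."""
    return (sample_table.groupby("id")
            .agg(median_ratio=("ratio", "median"),
                 gfr_ml_min=("gfr_ml_min", "first"),
                 n_samples=("ratio", "size"))
            .reset_index())
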