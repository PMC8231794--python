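"""First-order degradation kinetics of meropenem and ORM mass balance.

Meropenem hydrolyses by opening of its beta-lactam ring, so its
concentration in an infusate or in serum follows

    C(t) = C0 * exp(-k * t)

with a first-order rate constant ``k`` (1/h).  This module fits that model
to concentration-time series, derives pharmacopoeial stability windows
(time above 90% of the initial concentration), half-lives, and the
theoretical equimolar open-ring-metabolite (ORM) curve against which the
observed ORM shortfall (further conversion of the ORM) is quantified.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from ._utils import round_half_up
from .constants import MM_MEROPENEM, MM_ORM, STABILITY_THRESHOLD


class FitError(RuntimeError):
    """Raised when a decay fit cannot be computed or diverges."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ConcentrationSeries:
    """Replicated meropenem/ORM concentration-time series in one matrix.

    Parameters
    ----------
    times
        Sampling times in hours, sorted ascending.
    parent_conc
        Meropenem concentrations, mg/L, shape ``(n_times, n_replicates)``.
    metabolite_conc
        ORM concentrations, mg/L, same shape, or ``None`` if not assayed.
    matrix
        ``"saline"`` or ``"serum"``.
    temperature
        Incubation temperature, °C.
    """

    times: np.ndarray
    parent_conc: np.ndarray
    metabolite_conc: np.ndarray | None = None
    matrix: str = "saline"
    temperature: float = 22.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.parent_conc = np.atleast_2d(np.asarray(self.parent_conc, dtype=float))
        if self.parent_conc.shape[0] != self.times.size:
            self.parent_conc = self.parent_conc.T
        if self.parent_conc.shape[0] != self.times.size:
            raise ValueError("parent_conc rows must match number of times")
        if self.metabolite_conc is not None:
            self.metabolite_conc = np.atleast_2d(
                np.asarray(self.metabolite_conc, dtype=float))
            if self.metabolite_conc.shape[0] != self.times.size:
                self.metabolite_conc = self.metabolite_conc.T
            if self.metabolite_conc.shape != self.parent_conc.shape:
                raise ValueError("metabolite_conc shape must match parent_conc")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be sorted ascending")
        if np.any(self.times < 0):
            raise ValueError("times must be non-negative")
        if np.any(self.parent_conc < 0):
            raise ValueError("concentrations must be non-negative")
        if self.matrix not in ("saline", "serum"):
            raise ValueError(f"unknown matrix {self.matrix!r}")

    @property
    def n_replicates(self) -> int:
        return self.parent_conc.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-form table: time_h, analyte, conc_mg_L, replicate, matrix."""
        rows = []
        for j in range(self.n_replicates):
            for i, t in enumerate(self.times):
                rows.append((t, "meropenem", self.parent_conc[i, j], j + 1,
                             self.matrix, self.temperature))
                if self.metabolite_conc is not None:
                    rows.append((t, "orm", self.metabolite_conc[i, j], j + 1,
                                 self.matrix, self.temperature))
        return pd.DataFrame(rows, columns=["time_h", "analyte", "conc_mg_L",
                                           "replicate", "matrix", "temperature_c"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ConcentrationSeries":
        times = np.sort(df["time_h"].unique())
        reps = np.sort(df["replicate"].unique())
        parent = np.full((times.size, reps.size), np.nan)
        has_orm = (df["analyte"] == "orm").any()
        metab = np.full((times.size, reps.size), np.nan) if has_orm else None
        t_idx = {t: i for i, t in enumerate(times)}
        r_idx = {r: j for j, r in enumerate(reps)}
        for _, row in df.iterrows():
            i, j = t_idx[row["time_h"]], r_idx[row["replicate"]]
            if row["analyte"] == "meropenem":
                parent[i, j] = row["conc_mg_L"]
            else:
                metab[i, j] = row["conc_mg_L"]
        matrix = df["matrix"].iloc[0]
        temp = float(df["temperature_c"].iloc[0]) if "temperature_c" in df else 22.0
        return cls(times, parent, metab, matrix=matrix, temperature=temp)

    @classmethod
    def from_csv(cls, path) -> "ConcentrationSeries":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class DecayFit:
    """Result of a first-order decay fit."""

    k: float                 # 1/h
    c0_hat: float            # mg/L
    se_k: float              # 1/h
    residual_sd: float       # mg/L
    half_life: float         # h
    r_squared: float


@dataclass(frozen=True)
class StabilityReport:
    """Pharmacopoeial stability summary derived from a decay fit."""

    threshold: float
    stability_time: float          # h; inf when k == 0
    recovery_at_24h: float         # percent of initial
    verdict_per_timepoint: tuple   # bool per sampling time, recovery >= threshold
    times: tuple = field(default=())

    def to_dict(self) -> dict:
        st = self.stability_time
        return {
            "threshold": self.threshold,
            "stability_time_h": None if math.isinf(st) else round_half_up(st, 2),
            "recovery_at_24h_percent": round_half_up(self.recovery_at_24h, 1),
            "times_h": list(self.times),
            "stable_at_timepoint": list(self.verdict_per_timepoint),
        }


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _model(t, c0, k):
    return c0 * np.exp(-k * t)


def fit_first_order_decay(series: ConcentrationSeries) -> DecayFit:
    """Fit C(t) = C0*exp(-k t) by unweighted least squares on the linear scale.

    All replicates enter as independent observations.  ``c0`` is estimated
    jointly with ``k`` (robust to assay noise in the t=0 sample).  The
    standard error of ``k`` comes from the curvature of the least-squares
    objective at the optimum.

    Raises
    ------
    FitError
        If the series is all-zero or non-finite, has fewer than 3 distinct
        time points, or the fitted rate diverges (> 10/h).
    """
    t = np.repeat(series.times, series.n_replicates)
    y = series.parent_conc.ravel()
    if not np.all(np.isfinite(y)):
        raise FitError("non-finite concentrations in series")
    if np.unique(series.times).size < 3:
        raise FitError("need >= 3 distinct time points to fit a decay")
    if not np.any(y > 0):
        raise FitError("all-zero series: no decay to fit")

    # log-linear start values from the positive observations
    pos = y > 0
    slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
    p0 = (float(np.exp(intercept)), max(-float(slope), 1e-9))

    try:
        popt, pcov = curve_fit(_model, t, y, p0=p0,
                               bounds=([0.0, 0.0], [np.inf, 10.0]),
                               maxfev=20000)
    except Exception as exc:  # pragma: no cover - scipy failure paths
        raise FitError(f"decay fit did not converge: {exc}") from exc
    c0_hat, k = float(popt[0]), float(popt[1])
    if k > 10.0 - 1e-9:
        raise FitError(f"fitted rate k={k:.3g}/h at the divergence bound")

    resid = y - _model(t, c0_hat, k)
    dof = max(y.size - 2, 1)
    residual_sd = float(np.sqrt(resid @ resid / dof))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else float("nan")
    se_k = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else float("nan")
    hl = math.log(2) / k if k > 0 else math.inf
    return DecayFit(k=k, c0_hat=c0_hat, se_k=se_k, residual_sd=residual_sd,
                    half_life=hl, r_squared=r2)


def fit_log_linear(series: ConcentrationSeries) -> DecayFit:
    """Log-scale cross-check fit: ordinary least squares on log concentration.

    Equivalent to the nonlinear fit on noise-free data; used as an
    independent check, not as the default estimator.
    """
    t = np.repeat(series.times, series.n_replicates)
    y = series.parent_conc.ravel()
    pos = y > 0
    if pos.sum() < 3:
        raise FitError("need >= 3 positive observations for the log-linear fit")
    slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
    k = max(-float(slope), 0.0)
    c0 = float(np.exp(intercept))
    resid = np.log(y[pos]) - (intercept + slope * t[pos])
    sd = float(np.sqrt(resid @ resid / max(pos.sum() - 2, 1)))
    hl = math.log(2) / k if k > 0 else math.inf
    return DecayFit(k=k, c0_hat=c0, se_k=float("nan"), residual_sd=sd,
                    half_life=hl, r_squared=float("nan"))


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def recovery_at(k: float, t: float):
    """Percent of the initial concentration remaining after ``t`` hours.

    ``100 * exp(-k t)``; vectorized over ``t``.
    """
    if k < 0:
        raise ValueError("rate constant k must be non-negative")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = 100.0 * np.exp(-k * t)
    return float(out) if out.ndim == 0 else out


def stability_window(k: float, threshold: float = STABILITY_THRESHOLD) -> float:
    """Hours until recovery falls to ``threshold`` of the initial concentration.

    Returns ``math.inf`` when ``k == 0`` (no degradation, infinite window).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if k < 0:
        raise ValueError("rate constant k must be non-negative")
    if k == 0:
        return math.inf
    return -math.log(threshold) / k


def half_life(k: float) -> float:
    """ln(2)/k, hours."""
    if k <= 0:
        raise ValueError("half-life requires k > 0")
    return math.log(2) / k


def theoretical_metabolite_curve(c0: float, k: float, times,
                                 mm_parent: float = MM_MEROPENEM,
                                 mm_metabolite: float = MM_ORM):
    """Equimolar-conversion ORM curve: every degraded parent molecule becomes ORM.

    ORM_theo(t) = (c0 - c0*exp(-k t)) * mm_metabolite / mm_parent, mg/L.
    """
    if c0 <= 0:
        raise ValueError("c0 must be positive")
    if mm_parent <= 0 or mm_metabolite <= 0:
        raise ValueError("molar masses must be positive")
    if k < 0:
        raise ValueError("rate constant k must be non-negative")
    t = np.asarray(times, dtype=float)
    out = (c0 - c0 * np.exp(-k * t)) * mm_metabolite / mm_parent
    return float(out) if out.ndim == 0 else out


def mass_balance_deficit(series: ConcentrationSeries, fit: DecayFit,
                         mm_parent: float = MM_MEROPENEM,
                         mm_metabolite: float = MM_ORM) -> pd.DataFrame:
    """Fraction of theoretical ORM not recovered at each time point.

    deficit(t) = 1 - observed_ORM(t) / ORM_theo(t), using replicate means
    and the fitted (c0, k).  Where the theoretical curve is zero (t = 0)
    the deficit is undefined and flagged.
    """
    if series.metabolite_conc is None:
        raise ValueError("series has no metabolite concentrations")
    theo = theoretical_metabolite_curve(fit.c0_hat, fit.k, series.times,
                                        mm_parent, mm_metabolite)
    theo = np.atleast_1d(theo)
    obs = series.metabolite_conc.mean(axis=1)
    defined = theo > 0
    deficit = np.full_like(theo, np.nan)
    deficit[defined] = 1.0 - obs[defined] / theo[defined]
    return pd.DataFrame({"time_h": series.times, "deficit": deficit,
                         "defined": defined})


def stability_report(fit: DecayFit, times: Sequence[float],
                     threshold: float = STABILITY_THRESHOLD) -> StabilityReport:
    """Assemble the pharmacopoeial stability verdict for a fitted series.

    A time point is stable when recovery is >= 100*threshold (inclusive).
    """
    rec = recovery_at(fit.k, np.asarray(times, dtype=float))
    verdicts = tuple(bool(v) for v in rec >= 100.0 * threshold - 1e-12)
    return StabilityReport(
        threshold=threshold,
        stability_time=stability_window(fit.k, threshold),
        recovery_at_24h=recovery_at(fit.k, 24.0),
        verdict_per_timepoint=verdicts,
        times=tuple(float(t) for t in times),
    )


def write_stability_json(fit: DecayFit, report: StabilityReport, path) -> None:
    """Write the fit + stability summary as a JSON report."""
    payload = {
        "k_per_h": fit.k,
        "se_k_per_h": fit.se_k,
        "c0_hat_mg_L": fit.c0_hat,
        "half_life_h": fit.half_life,
        "r_squared": fit.r_squared,
        "residual_sd_mg_L": fit.residual_sd,
        **report.to_dict(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
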