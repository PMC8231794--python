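"""Steady-state population pharmacokinetics with partitioned clearance.

Model
-----
Under continuous (zero-order) infusion at rate :math:`R` (mg/h), a
one-compartment model with first-order elimination predicts the flat
steady-state concentration

    Css = R / CL        (mg/L; independent of V at steady state)

Total clearance of patient *i* is partitioned into a renal component fixed
to the measured glomerular filtration rate, a spontaneous in-vitro
degradation component fixed from the serum decay rate, and an estimated
residual component, with a single exponential between-patient random
effect on the whole sum:

    CL_i = (0.06 * GFR_i + CL_nonGFR + CL_decay) * exp(eta_i),
    eta_i ~ N(0, omega^2)

Observed concentrations carry proportional residual error,
``y_ij = Css_i * (1 + eps)``, ``eps ~ N(0, sigma^2)``.

Estimation
----------
The marginal likelihood integrates the random effect per patient; the
integral is approximated by a Laplace expansion around the per-patient
posterior mode (default) or by adaptive Gauss-Hermite quadrature centred
and scaled at that mode.  The outer maximisation over
``(CL_nonGFR, omega, sigma)`` runs Nelder-Mead from several jittered
starts; standard errors come from a central finite-difference Hessian of
the -2 log-likelihood.  Empirical Bayes estimates (EBEs), eta- and
epsilon-shrinkage, and NONMEM-style goodness-of-fit tables are provided.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import logsumexp

from ._utils import round_half_up
from .constants import GFR_TO_L_PER_H, K_SERUM_37C, V_LITERATURE_L

_LOG2PI = math.log(2.0 * math.pi)


class EstimationError(RuntimeError):
    """Raised when the mixed-effects fit fails outright."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixedParams:
    """Parameters fixed (not estimated) in the population model.

    ``cl_decay`` is the spontaneous-degradation clearance ``k_serum * V``
    obtained from the in vitro serum experiment; ``v`` is the literature
    volume of distribution (not estimable from steady-state data alone).
    """

    v: float = V_LITERATURE_L                       # L
    cl_decay: float = K_SERUM_37C * V_LITERATURE_L  # L/h
    gfr_to_clearance_factor: float = GFR_TO_L_PER_H  # (L/h) per (mL/min)

    def __post_init__(self) -> None:
        if self.v <= 0 or self.cl_decay < 0 or self.gfr_to_clearance_factor <= 0:
            raise ValueError("fixed parameters must be positive")

    @classmethod
    def from_invitro(cls, k_serum: float, v: float = V_LITERATURE_L,
                     gfr_to_clearance_factor: float = GFR_TO_L_PER_H
                     ) -> "FixedParams":
        return cls(v=v, cl_decay=cl_decay_from_invitro(k_serum, v),
                   gfr_to_clearance_factor=gfr_to_clearance_factor)


@dataclass
class PatientRecord:
    """One patient's steady-state therapeutic-drug-monitoring record."""

    id: object
    gfr: float                    # mL/min
    infusion_rate: float          # mg/h
    observations: list            # of (time_h, meropenem_mg_L, orm_mg_L or None)

    def __post_init__(self) -> None:
        if self.gfr <= 0:
            raise ValueError("gfr must be positive")
        if self.infusion_rate < 0:
            raise ValueError("infusion_rate must be non-negative")
        if len(self.observations) < 1:
            raise ValueError("patient needs at least one observation")


class PopPKDataset:
    """Steady-state TDM cohort held as a tidy table.

    Columns: ``id, time_h, dv_mg_L, analyte, rate_mg_h, gfr_ml_min``; one
    row per observed concentration.  Only meropenem rows enter the
    likelihood; ORM rows are carried for the metabolic-ratio analyses.
    """

    COLUMNS = ["id", "time_h", "dv_mg_L", "analyte", "rate_mg_h", "gfr_ml_min"]

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"dataset is missing columns: {sorted(missing)}")
        if len(frame) == 0:
            raise ValueError("empty dataset")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_records(cls, patients: list) -> "PopPKDataset":
        rows = []
        for p in patients:
            for obs in p.observations:
                t, mero = obs[0], obs[1]
                orm = obs[2] if len(obs) > 2 else None
                rows.append((p.id, t, mero, "meropenem", p.infusion_rate, p.gfr))
                if orm is not None:
                    rows.append((p.id, t, orm, "orm", p.infusion_rate, p.gfr))
        return cls(pd.DataFrame(rows, columns=cls.COLUMNS))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PopPKDataset":
        return cls(pd.read_csv(path))

    @property
    def n_patients(self) -> int:
        return self.frame["id"].nunique()

    def patient_table(self) -> pd.DataFrame:
        """One row per patient: id, rate_mg_h, gfr_ml_min."""
        mero = self.frame[self.frame["analyte"] == "meropenem"]
        return (mero.groupby("id", sort=False)
                .agg(rate_mg_h=("rate_mg_h", "first"),
                     gfr_ml_min=("gfr_ml_min", "first"))
                .reset_index())


@dataclass(frozen=True)
class ClearancePartition:
    """Total clearance split into renal (GFR), residual, and decay components."""

    cl_gfr: float
    cl_nongfr: float
    cl_decay: float
    cl_total: float
    fractions: tuple  # percent (gfr, nongfr, decay)

    @classmethod
    def from_components(cls, cl_gfr: float, cl_nongfr: float,
                        cl_decay: float) -> "ClearancePartition":
        total = cl_gfr + cl_nongfr + cl_decay
        if total <= 0:
            raise ValueError("total clearance must be positive")
        fr = tuple(100.0 * c / total for c in (cl_gfr, cl_nongfr, cl_decay))
        return cls(cl_gfr, cl_nongfr, cl_decay, total, fr)

    def integer_fractions(self) -> tuple:
        """Integer percentages by largest-remainder apportionment.

        Guarantees the printed fractions total exactly 100, which naive
        per-component rounding does not.
        """
        floors = [math.floor(f) for f in self.fractions]
        remainder = 100 - sum(floors)
        order = sorted(range(3), key=lambda i: self.fractions[i] - floors[i],
                       reverse=True)
        for i in order[:remainder]:
            floors[i] += 1
        return tuple(floors)

    def summary(self) -> dict:
        return {
            "cl_gfr_L_h": round_half_up(self.cl_gfr, 1),
            "cl_nongfr_L_h": round_half_up(self.cl_nongfr, 1),
            "cl_decay_L_h": round_half_up(self.cl_decay, 2),
            "cl_total_L_h": round_half_up(self.cl_total, 1),
            "fractions_percent": list(self.integer_fractions()),
        }


@dataclass
class EstimationResult:
    """Population estimates with uncertainty, shrinkage and EBEs."""

    theta_cl_nongfr: float       # L/h
    omega_cl: float              # SD of log CL
    sigma_prop: float            # proportional error SD (fraction)
    rse: dict                    # percent, keys theta/omega/sigma
    eta_shrinkage: float         # percent
    eps_shrinkage: float         # percent
    minus2ll: float              # full -2 log L (with 2*pi constants)
    ofv_nonmem: float            # minus2ll - n_obs*log(2*pi)
    ebe: pd.DataFrame            # per-patient eta estimates
    status: str = "converged"
    warnings_: list = field(default_factory=list)

    @property
    def omega_cv_percent(self) -> float:
        """IIV as CV% under the lognormal model, 100*sqrt(exp(omega^2)-1)."""
        return 100.0 * math.sqrt(math.expm1(self.omega_cl ** 2))

    @property
    def sigma_cv_percent(self) -> float:
        return 100.0 * self.sigma_prop


# ---------------------------------------------------------------------------
# structural model
# ---------------------------------------------------------------------------

def cl_decay_from_invitro(k_serum: float, v: float = V_LITERATURE_L) -> float:
    """Spontaneous-degradation clearance k*V, L/h."""
    if k_serum < 0:
        raise ValueError("k_serum must be non-negative")
    if v <= 0:
        raise ValueError("volume must be positive")
    return k_serum * v


def individual_clearance(fixed: FixedParams, theta_cl_nongfr: float,
                         gfr: float, eta: float = 0.0) -> float:
    """CL_i = (0.06*GFR + CL_nonGFR + CL_decay) * exp(eta), L/h."""
    if gfr <= 0:
        raise ValueError("gfr must be positive")
    if not math.isfinite(eta):
        raise ValueError("eta must be finite")
    tv = fixed.gfr_to_clearance_factor * gfr + theta_cl_nongfr + fixed.cl_decay
    return tv * math.exp(eta)


def predict_css(infusion_rate: float, cl: float) -> float:
    """Steady-state concentration rate/CL, mg/L."""
    if cl <= 0:
        raise ValueError("clearance must be positive")
    if infusion_rate < 0:
        raise ValueError("infusion rate must be non-negative")
    return infusion_rate / cl


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

class _Design:
    """Padded per-patient arrays for vectorised likelihood evaluation."""

    def __init__(self, data: PopPKDataset, fixed: FixedParams):
        mero = data.frame[data.frame["analyte"] == "meropenem"]
        if mero.empty:
            raise ValueError("dataset has no meropenem observations")
        ids, rates, gfrs, obs = [], [], [], []
        for pid, grp in mero.groupby("id", sort=False):
            ids.append(pid)
            rates.append(float(grp["rate_mg_h"].iloc[0]))
            gfrs.append(float(grp["gfr_ml_min"].iloc[0]))
            obs.append(grp["dv_mg_L"].to_numpy(dtype=float))
        self.ids = ids
        self.rate = np.array(rates)
        self.gfr = np.array(gfrs)
        self.n_pat = len(ids)
        self.n_obs_i = np.array([len(o) for o in obs])
        self.n_obs = int(self.n_obs_i.sum())
        m = self.n_obs_i.max()
        self.y = np.zeros((self.n_pat, m))
        self.mask = np.zeros((self.n_pat, m), dtype=bool)
        for i, o in enumerate(obs):
            self.y[i, :len(o)] = o
            self.mask[i, :len(o)] = True
        self.fixed = fixed

    def typical_cl(self, theta: float) -> np.ndarray:
        return (self.fixed.gfr_to_clearance_factor * self.gfr
                + theta + self.fixed.cl_decay)


def _joint_loglik(eta, d: _Design, theta, omega, sigma):
    """log p(y_i | eta_i) + log p(eta_i), vectorised over patients.

    ``eta`` has shape (n_pat,) or (n_pat, n_nodes).
    """
    eta = np.asarray(eta, dtype=float)
    c = d.rate / d.typical_cl(theta)          # Css at eta = 0
    if eta.ndim == 1:
        f = c[:, None] * np.exp(-eta)[:, None]        # (n_pat, m) prediction
        resid = np.where(d.mask, (d.y - f) / (sigma * f), 0.0)
        ll = (-0.5 * d.n_obs_i * _LOG2PI
              - np.where(d.mask, np.log(sigma * f), 0.0).sum(axis=1)
              - 0.5 * (resid ** 2).sum(axis=1))
        ll += -0.5 * _LOG2PI - math.log(omega) - 0.5 * (eta / omega) ** 2
        return ll
    # quadrature path: (n_pat, n_nodes)
    f = c[:, None, None] * np.exp(-eta)[:, :, None]   # (n_pat, K, m)
    y = d.y[:, None, :]
    mask = d.mask[:, None, :]
    resid = np.where(mask, (y - f) / (sigma * f), 0.0)
    ll = (-0.5 * d.n_obs_i[:, None] * _LOG2PI
          - np.where(mask, np.log(sigma * f), 0.0).sum(axis=2)
          - 0.5 * (resid ** 2).sum(axis=2))
    ll += -0.5 * _LOG2PI - math.log(omega) - 0.5 * (eta / omega) ** 2
    return ll


def _inner_modes(d: _Design, theta, omega, sigma, max_iter=100, tol=1e-12):
    """Per-patient posterior modes of eta and the curvature there.

    The scalar inner problem has analytic first and second derivatives:
    with u_ij = (y_ij/c_i) * exp(eta),
        l'(eta)  = n_i - (1/sigma^2) * sum_j (u_ij - 1) u_ij - eta/omega^2
        l''(eta) = -(1/sigma^2) * sum_j (2 u_ij^2 - u_ij) - 1/omega^2
    Newton iterations with step clipping; curvature is floored away from
    zero so the Laplace scale stays defined for pathological patients.
    """
    a = np.where(d.mask, d.y / (d.rate / d.typical_cl(theta))[:, None], 0.0)
    eta = np.zeros(d.n_pat)
    inv_s2 = 1.0 / sigma ** 2
    inv_o2 = 1.0 / omega ** 2
    for _ in range(max_iter):
        u = a * np.exp(eta)[:, None]
        g = d.n_obs_i - inv_s2 * ((u - 1.0) * u).sum(axis=1) - eta * inv_o2
        h = -inv_s2 * ((2.0 * u - 1.0) * u).sum(axis=1) - inv_o2
        h = np.minimum(h, -1e-8)
        step = np.clip(-g / h, -1.0, 1.0)
        eta = np.clip(eta + step, -15.0, 15.0)
        if np.max(np.abs(step)) < tol:
            break
    u = a * np.exp(eta)[:, None]
    h = -inv_s2 * ((2.0 * u - 1.0) * u).sum(axis=1) - inv_o2
    h = np.minimum(h, -1e-8)
    return eta, h


def neg2ll(theta: float, omega: float, sigma: float, data: PopPKDataset,
           fixed: FixedParams, method: str = "laplace",
           n_nodes: int = 21) -> float:
    """Marginal -2 log-likelihood of (theta, omega, sigma).

    ``method`` is ``"laplace"`` (second-order expansion at the posterior
    mode) or ``"quadrature"`` (adaptive Gauss-Hermite with ``n_nodes``
    nodes centred and scaled at the mode).  ``omega = 0`` collapses to the
    closed-form fixed-effects Gaussian likelihood.  The value includes all
    2*pi constants; subtract ``n_obs*log(2*pi)`` for the NONMEM convention.
    """
    if omega < 0 or sigma < 0:
        raise ValueError("omega and sigma must be non-negative")
    if sigma == 0:
        raise ValueError("sigma = 0 gives a degenerate likelihood")
    d = data if isinstance(data, _Design) else _Design(data, fixed)
    if omega == 0.0:
        c = d.rate / d.typical_cl(theta)
        f = np.where(d.mask, c[:, None], 1.0)
        resid = np.where(d.mask, (d.y - f) / (sigma * f), 0.0)
        ll = (-0.5 * d.n_obs * _LOG2PI
              - np.where(d.mask, np.log(sigma * f), 0.0).sum()
              - 0.5 * (resid ** 2).sum())
        return -2.0 * ll
    eta_hat, h = _inner_modes(d, theta, omega, sigma)
    if method == "laplace":
        ll_i = (_joint_loglik(eta_hat, d, theta, omega, sigma)
                + 0.5 * _LOG2PI - 0.5 * np.log(-h))
    elif method == "quadrature":
        if n_nodes < 3:
            raise ValueError("need at least 3 quadrature nodes")
        x, w = hermgauss(n_nodes)
        s = 1.0 / np.sqrt(-h)
        nodes = eta_hat[:, None] + math.sqrt(2.0) * s[:, None] * x[None, :]
        lj = _joint_loglik(nodes, d, theta, omega, sigma)
        ll_i = logsumexp(lj + x[None, :] ** 2 + np.log(w)[None, :], axis=1)
        ll_i += 0.5 * math.log(2.0) + np.log(s)
    else:
        raise ValueError(f"unknown method {method!r}")
    return -2.0 * float(ll_i.sum())


def empirical_bayes(theta: float, omega: float, sigma: float,
                    data: PopPKDataset, fixed: FixedParams) -> pd.DataFrame:
    """Per-patient posterior modes (EBEs) of the clearance random effect."""
    d = data if isinstance(data, _Design) else _Design(data, fixed)
    if omega == 0.0:
        eta = np.zeros(d.n_pat)
    else:
        eta, _ = _inner_modes(d, theta, omega, sigma)
    return pd.DataFrame({"id": d.ids, "eta": eta})


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

def fit_poppk(data: PopPKDataset, fixed: FixedParams,
              method: str = "laplace", n_starts: int = 5,
              seed: int = 0, start: tuple = (3.0, 0.2, 0.15),
              fix: dict | None = None) -> EstimationResult:
    """Maximise the marginal likelihood over (CL_nonGFR, omega, sigma).

    Nelder-Mead on log-transformed parameters from ``n_starts`` jittered
    starting points (deterministic under ``seed``); standard errors from a
    central finite-difference Hessian of -2LL on the natural scale
    (step 1e-4 * |estimate|); eta-shrinkage ``100*(1 - SD(EBE)/omega)``
    and epsilon-shrinkage ``100*(1 - SD(IWRES))``.

    ``fix`` may pin ``"omega"`` and/or ``"sigma"`` to known values (e.g.
    ``fix={"omega": 0.0, "sigma": 0.05}`` for a fixed-effects fit to
    noise-free data, where estimating the variance components alongside
    theta is unidentified).  Fixed parameters get no standard error.
    """
    d = _Design(data, fixed)
    if d.n_pat < 2:
        raise EstimationError("need at least 2 patients")
    fix = fix or {}
    bad = set(fix) - {"omega", "sigma"}
    if bad:
        raise ValueError(f"can only fix omega/sigma, got {sorted(bad)}")
    names = ["theta"] + [n for n in ("omega", "sigma") if n not in fix]
    start_map = dict(zip(("theta", "omega", "sigma"), start))

    def unpack(x):
        vals = dict(zip(names, np.exp(x)))
        return (vals["theta"], fix.get("omega", vals.get("omega")),
                fix.get("sigma", vals.get("sigma")))

    def objective(x):
        th, om, sg = unpack(x)
        try:
            return neg2ll(th, om, sg, d, fixed, method=method)
        except (ValueError, FloatingPointError):
            return 1e12

    rng = np.random.default_rng(seed)
    x0 = np.log(np.array([start_map[n] for n in names], dtype=float))
    starts = [x0] + [x0 + rng.normal(0.0, 0.4, size=x0.size)
                     for _ in range(max(n_starts - 1, 0))]
    best = None
    for s in starts:
        res = minimize(objective, s, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-8,
                                "maxiter": 4000, "maxfev": 6000})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise EstimationError("no start converged")

    theta, omega, sigma = (float(v) for v in unpack(best.x))
    m2ll = float(best.fun)
    warns = []
    status = "converged" if best.success else "max-iterations"
    if not best.success:
        warns.append("Nelder-Mead hit its iteration budget")

    # finite-difference Hessian of -2LL over the free parameters, natural scale
    full = {"theta": theta, "omega": omega, "sigma": sigma}
    est = np.array([full[n] for n in names])
    key_of = {"theta": "theta_cl_nongfr", "omega": "omega_cl",
              "sigma": "sigma_prop"}
    rse = {v: float("nan") for v in key_of.values()}
    try:
        k_free = len(names)
        hsteps = 1e-4 * np.abs(est)
        H = np.zeros((k_free, k_free))

        def f_nat(p):
            vals = dict(zip(names, p))
            return neg2ll(vals["theta"], fix.get("omega", vals.get("omega")),
                          fix.get("sigma", vals.get("sigma")), d, fixed,
                          method=method)

        f0 = m2ll
        for i in range(k_free):
            for j in range(i, k_free):
                ei = np.zeros(k_free); ei[i] = hsteps[i]
                ej = np.zeros(k_free); ej[j] = hsteps[j]
                if i == j:
                    H[i, i] = (f_nat(est + ei) - 2 * f0 + f_nat(est - ei)) / hsteps[i] ** 2
                else:
                    H[i, j] = H[j, i] = (
                        f_nat(est + ei + ej) - f_nat(est + ei - ej)
                        - f_nat(est - ei + ej) + f_nat(est - ei - ej)
                    ) / (4 * hsteps[i] * hsteps[j])
        cov = 2.0 * np.linalg.inv(H)          # Var = I^{-1}, I = H/2 for -2LL
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.diag(cov))
        if np.any(~np.isfinite(se)):
            raise np.linalg.LinAlgError("non-finite SE")
        for i, n in enumerate(names):
            rse[key_of[n]] = 100.0 * se[i] / est[i]
    except np.linalg.LinAlgError as exc:
        status = "no-standard-errors"
        warns.append(f"Hessian not positive definite: {exc}")

    ebe = empirical_bayes(theta, omega, sigma, d, fixed)
    eta = ebe["eta"].to_numpy()
    eta_shr = (100.0 * (1.0 - eta.std(ddof=1) / omega)
               if omega > 0 and len(eta) > 1 else float("nan"))

    # IWRES at individual predictions
    c = d.rate / d.typical_cl(theta)
    ipred = c[:, None] * np.exp(-eta)[:, None]
    iwres = ((d.y - ipred) / (sigma * ipred))[d.mask]
    eps_shr = 100.0 * (1.0 - iwres.std(ddof=1)) if iwres.size > 1 else float("nan")

    return EstimationResult(
        theta_cl_nongfr=theta, omega_cl=omega, sigma_prop=sigma, rse=rse,
        eta_shrinkage=float(eta_shr), eps_shrinkage=float(eps_shr),
        minus2ll=m2ll, ofv_nonmem=m2ll - d.n_obs * _LOG2PI,
        ebe=ebe, status=status, warnings_=warns,
    )


# ---------------------------------------------------------------------------
# post-fit summaries
# ---------------------------------------------------------------------------

def partition_clearance(result: EstimationResult, fixed: FixedParams,
                        gfr_summary: float) -> ClearancePartition:
    """Partition total clearance at a cohort GFR summary (e.g. the mean).

    ``cl_gfr = 0.06 * gfr_summary``; the residual component is the fitted
    CL_nonGFR and the decay component the fixed in-vitro value.
    """
    if gfr_summary <= 0:
        raise ValueError("gfr summary must be positive")
    return ClearancePartition.from_components(
        fixed.gfr_to_clearance_factor * gfr_summary,
        result.theta_cl_nongfr, fixed.cl_decay)


def gof_tables(result: EstimationResult, data: PopPKDataset,
               fixed: FixedParams) -> pd.DataFrame:
    """NONMEM-style goodness-of-fit table.

    One row per meropenem observation with the population prediction
    (eta = 0), individual prediction (eta = EBE), residual, and
    individual weighted residual.
    """
    d = _Design(data, fixed)
    eta = result.ebe.set_index("id")["eta"]
    rows = []
    for i, pid in enumerate(d.ids):
        tv = d.typical_cl(result.theta_cl_nongfr)[i]
        pred = d.rate[i] / tv
        ipred = pred * math.exp(-eta.loc[pid])
        for y in d.y[i, d.mask[i]]:
            rows.append((pid, y, pred, ipred, y - pred,
                         (y - ipred) / (result.sigma_prop * ipred)))
    return pd.DataFrame(rows, columns=["id", "dv_mg_L", "pred_mg_L",
                                       "ipred_mg_L", "res_mg_L", "iwres"])


def neg2ll_bruteforce(theta: float, omega: float, sigma: float,
                      data: PopPKDataset, fixed: FixedParams,
                      n_grid: int = 201, width: float = 6.0) -> float:
    """Brute-force trapezoid integration of the marginal likelihood.

    Independent oracle for the Laplace/quadrature approximations:
    integrates each patient's joint density over eta in
    [-width*omega, width*omega] on a uniform grid.
    """
    if omega <= 0:
        raise ValueError("brute-force oracle requires omega > 0")
    d = data if isinstance(data, _Design) else _Design(data, fixed)
    grid = np.linspace(-width * omega, width * omega, n_grid)
    nodes = np.broadcast_to(grid, (d.n_pat, n_grid))
    lj = _joint_loglik(nodes, d, theta, omega, sigma)
    # log trapezoid: interior points weight h, endpoints h/2
    h = grid[1] - grid[0]
    logw = np.full(n_grid, math.log(h))
    logw[0] = logw[-1] = math.log(h / 2.0)
    ll_i = logsumexp(lj + logw[None, :], axis=1)
    return -2.0 * float(ll_i.sum())
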