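"""End-to-end pipeline: simulate -> decay fits -> popPK -> partition -> metrics.

Mirrors the study flow: infusate and serum stability experiments give the
degradation rates; the serum rate times the fixed volume gives the
spontaneous-decay clearance, which is fixed inside the population model
fitted to the steady-state cohort; the fitted clearance is partitioned and
the metabolic-ratio metrics summarised.  A manifest with SHA-256 checksums
of every artifact makes runs content-addressable: identical config + seed
gives identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import constants as C
from ._utils import round_half_up
from .clinical_metrics import (cohort_ratio_table, patient_ratio_summary,
                               ratio_gfr_association)
from .degradation_kinetics import (fit_first_order_decay, stability_report,
                                   write_stability_json)
from .poppk import (FixedParams, cl_decay_from_invitro, fit_poppk, gof_tables,
                    partition_clearance)
from .synthetic_data import AssayNoiseModel, CohortSpec, gen_cohort, gen_decay_series

log = logging.getLogger("meropk")

__version__ = "0.1.0"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Full configuration of one reproducible pipeline run."""

    seed: int = 1
    out_dir: str = "results"
    # stability experiments
    k_saline: float = C.K_SALINE_22C
    k_serum: float = C.K_SERUM_37C
    c0_saline: float = 20000.0          # 2% infusate, mg/L
    c0_serum: float = 50.0              # top of therapeutic range, mg/L
    assay_cv: float = 0.05
    replicates: int = 2
    metabolite_yield: float = 0.8
    stability_threshold: float = C.STABILITY_THRESHOLD
    run_serum_stage: bool = True
    # population model
    v: float = C.V_LITERATURE_L
    theta_cl_nongfr: float = C.THETA_CL_NONGFR
    omega_cl: float = C.OMEGA_CL
    sigma_prop: float = C.SIGMA_PROP
    n_patients: int = 6
    gfr_range: tuple = (28.0, 307.0)
    dose_range: tuple = (125.0, 250.0)
    samples_per_patient: int = 4
    estimation_method: str = "laplace"
    n_starts: int = 5
    ratio_basis: str = "mass"

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["gfr_range"] = list(d["gfr_range"])
        d["dose_range"] = list(d["dose_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("gfr_range", "dose_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    headline: dict[str, float] = {}
    t_start = time.perf_counter()

    def _stage(name):
        log.info("stage %-12s t=%.2fs", name, time.perf_counter() - t_start)

    noise = AssayNoiseModel(cv_proportional=config.assay_cv,
                            replicates=config.replicates)

    # --- stability experiments -------------------------------------------
    fits = {}
    seed_offset = {"saline": 11, "serum": 23}   # fixed, not hash(): reproducible
    stages = [("saline", config.k_saline, config.c0_saline, 22.0)]
    if config.run_serum_stage:
        stages.append(("serum", config.k_serum, config.c0_serum, 37.0))
    for matrix, k_true, c0, temp in stages:
        _stage(f"decay-{matrix}")
        try:
            series = gen_decay_series(k_true, c0, noise=noise,
                                      metabolite_yield=config.metabolite_yield,
                                      seed=config.seed + seed_offset[matrix],
                                      matrix=matrix, temperature=temp)
            csv_path = out / f"series_{matrix}.csv"
            series.to_csv(csv_path)
            fit = fit_first_order_decay(series)
            rep = stability_report(fit, series.times, config.stability_threshold)
            json_path = out / f"stability_{matrix}.json"
            write_stability_json(fit, rep, json_path)
        except Exception as exc:
            raise PipelineError(f"stage decay-{matrix}: {exc}") from exc
        fits[matrix] = (fit, rep)
        artifacts[f"series_{matrix}.csv"] = _sha256(csv_path)
        artifacts[f"stability_{matrix}.json"] = _sha256(json_path)
        headline[f"k_{matrix}_per_h"] = fit.k
        headline[f"recovery_24h_{matrix}_percent"] = rep.recovery_at_24h
    headline["stability_window_saline_h"] = fits["saline"][1].stability_time
    headline["half_life_serum_h"] = fits["serum"][0].half_life \
        if "serum" in fits else float("nan")

    # --- decay-clearance bridge ------------------------------------------
    _stage("cl-decay")
    if "serum" not in fits:
        raise PipelineError(
            "stage poppk: serum decay stage disabled, cl_decay input missing")
    cl_decay = cl_decay_from_invitro(fits["serum"][0].k, config.v)
    fixed = FixedParams(v=config.v, cl_decay=cl_decay)
    headline["cl_decay_L_h"] = cl_decay

    # --- cohort simulation and population fit ----------------------------
    _stage("poppk")
    try:
        spec = CohortSpec(n_patients=config.n_patients,
                          gfr_range=config.gfr_range,
                          dose_range=config.dose_range,
                          samples_per_patient=config.samples_per_patient,
                          seed=config.seed)
        cohort = gen_cohort(spec, fixed,
                            theta_cl_nongfr=config.theta_cl_nongfr,
                            omega_cl=config.omega_cl,
                            sigma_prop=config.sigma_prop)
        cohort_path = out / "cohort.csv"
        cohort.to_csv(cohort_path)
        result = fit_poppk(cohort, fixed, method=config.estimation_method,
                           n_starts=config.n_starts, seed=config.seed)
        mean_gfr = float(cohort.patient_table()["gfr_ml_min"].mean())
        part = partition_clearance(result, fixed, mean_gfr)
        gof = gof_tables(result, cohort, fixed)
        gof_path = out / "gof.csv"
        gof.to_csv(gof_path, index=False)
        est_path = out / "estimates.json"
        with open(est_path, "w") as fh:
            json.dump({
                "theta_cl_nongfr_L_h": result.theta_cl_nongfr,
                "omega_cl_sd": result.omega_cl,
                "omega_cl_cv_percent": result.omega_cv_percent,
                "sigma_prop_cv_percent": result.sigma_cv_percent,
                "rse_percent": result.rse,
                "eta_shrinkage_percent": result.eta_shrinkage,
                "eps_shrinkage_percent": result.eps_shrinkage,
                "minus2ll_full": result.minus2ll,
                "ofv_nonmem_convention": result.ofv_nonmem,
                "status": result.status,
                "clearance_partition": part.summary(),
                "cohort_mean_gfr_ml_min": mean_gfr,
            }, fh, indent=2)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage poppk: {exc}") from exc
    artifacts["cohort.csv"] = _sha256(cohort_path)
    artifacts["gof.csv"] = _sha256(gof_path)
    artifacts["estimates.json"] = _sha256(est_path)
    headline["theta_cl_nongfr_L_h"] = result.theta_cl_nongfr
    headline["omega_cl_cv_percent"] = result.omega_cv_percent
    headline["sigma_prop_cv_percent"] = result.sigma_cv_percent
    headline["cl_total_L_h"] = part.cl_total

    # --- metabolic-ratio metrics -----------------------------------------
    _stage("metrics")
    try:
        samples = cohort_ratio_table(cohort, basis=config.ratio_basis)
        ratio_path = out / "ratios.csv"
        samples.to_csv(ratio_path, index=False)
        per_patient = patient_ratio_summary(samples)
        assoc = ratio_gfr_association(samples["ratio"], samples["gfr_ml_min"],
                                      seed=config.seed)
        metrics_path = out / "metrics.json"
        with open(metrics_path, "w") as fh:
            json.dump({"association": assoc,
                       "per_patient_median_ratio":
                           per_patient.to_dict(orient="records"),
                       "basis": config.ratio_basis}, fh, indent=2)
    except Exception as exc:
        raise PipelineError(f"stage metrics: {exc}") from exc
    artifacts["ratios.csv"] = _sha256(ratio_path)
    artifacts["metrics.json"] = _sha256(metrics_path)
    headline["ratio_gfr_r_squared"] = assoc["r_squared"]
    headline["median_ratio"] = float(per_patient["median_ratio"].median())

    # --- manifest ---------------------------------------------------------
    config_path = out / "config.yaml"
    config.to_yaml(config_path)
    artifacts["config.yaml"] = _sha256(config_path)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "artifacts": artifacts,
        "headline": headline,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=list)
    _stage("done")
    return manifest


def render_report(manifest: dict) -> str:
    """Human-readable markdown summary of a pipeline run."""
    h = manifest.get("headline", {})
    lines = [f"# meropk run report (seed {manifest.get('seed')})", ""]

    lines.append("## Stability")
    if "k_saline_per_h" in h:
        lines += [
            "| matrix | k (1/h) | 24 h recovery (%) | 90% window (h) |",
            "|---|---|---|---|",
            f"| saline 22 °C | {h['k_saline_per_h']:.4f} | "
            f"{round_half_up(h['recovery_24h_saline_percent'], 1)} | "
            f"{round_half_up(h['stability_window_saline_h'], 1)} |",
        ]
        if "k_serum_per_h" in h:
            lines.append(
                f"| serum 37 °C | {h['k_serum_per_h']:.4f} | "
                f"{round_half_up(h['recovery_24h_serum_percent'], 1)} | "
                f"half-life {round_half_up(h['half_life_serum_h'], 1)} h |")
    else:
        lines.append("stability stage: not run")
    lines.append("")

    lines.append("## Population pharmacokinetics")
    if "theta_cl_nongfr_L_h" in h:
        lines += [
            f"- CL_nonGFR: {round_half_up(h['theta_cl_nongfr_L_h'], 1)} L/h",
            f"- CL_decay (k x V): {round_half_up(h['cl_decay_L_h'], 2)} L/h",
            f"- total clearance at cohort mean GFR: "
            f"{round_half_up(h['cl_total_L_h'], 1)} L/h",
            f"- IIV on CL: {round_half_up(h['omega_cl_cv_percent'], 1)} CV%",
            f"- proportional residual error: "
            f"{round_half_up(h['sigma_prop_cv_percent'], 1)} CV%",
        ]
    else:
        lines.append("population PK stage: not run")
    lines.append("")

    lines.append("## Metabolic ratio")
    if "median_ratio" in h:
        lines += [
            f"- cohort median ORM/(ORM+meropenem): "
            f"{round_half_up(h['median_ratio'], 2)}",
            f"- ratio-GFR R^2: {round_half_up(h['ratio_gfr_r_squared'], 2)}",
        ]
    else:
        lines.append("metrics stage: not run")
    lines += ["", "## Artifacts", ""]
    for name, digest in manifest.get("artifacts", {}).items():
        lines.append(f"- `{name}` sha256 `{digest[:16]}...`")
    return "\n".join(lines) + "\n"
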