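"""End-to-end orchestration: data -> covariates -> QC -> screen -> RNM
fits -> genetic parameters -> EBV/plasticity -> report tables.

A run is configured by :class:`RunConfig` (either a synthetic scenario or
paths to pedigree/phenotype/weather tables), executes one reaction-norm
fit per requested EC (each EC is a separate model, as the four ECs are
alternative definitions of the same gradient), and writes all stage
outputs as CSV under the output directory together with a manifest
recording the seed, configuration hash and per-stage record counts.
Identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import qc
from .design import (RNM_SCALE_GROUPS, ModelSpec, VarianceComponents,
                     build_design, start_values)
from .ebv import ebv_trajectories, rerank_analysis, select_elite_sires
from .enviro import ECDefinition, compute_ec_table, scale_ec
from .params import (GradientGrid, gradient_parameter_table,
                     intercept_slope_table, rec_matrix)
from .pedigree import validate_and_sort
from .reml import EMControls, em_reml_fit
from .screen import fit_phenotypic_screen
from .simulate import SimScenario, simulate_dataset


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one breed-scoped analysis run."""

    out_dir: str
    scenario: SimScenario | None = None      # simulate, or ...
    pedigree_path: str | None = None         # ... load from tables
    phenotype_path: str | None = None
    weather_daily_path: str | None = None
    weather_hourly_path: str | None = None
    breed_label: str = "synthetic"
    ec_names: tuple = ("sumPrec365",)
    reml: EMControls = field(default_factory=lambda: EMControls(
        max_iter=60, tol=1e-3, loglik_tol=1e-6, scale_search=RNM_SCALE_GROUPS))
    gradient_points: int = 11
    rerank_gradients: tuple = (-1.0, 0.0, 1.0)
    min_progeny: int = 20
    run_screen: bool = True
    seed: int = 1

    def validate(self) -> None:
        if not self.ec_names:
            raise PipelineError("config", "at least one EC must be requested")
        bad = [e for e in self.ec_names
               if e not in ("sumPrec365", "sumPrec280", "sumPrec90", "meanTHI90")]
        if bad:
            raise PipelineError("config", f"unknown EC name(s): {bad}")
        if self.scenario is None and not (self.pedigree_path and self.phenotype_path
                                          and self.weather_daily_path):
            raise PipelineError(
                "config", "either a scenario or pedigree/phenotype/weather paths")
        for p in (self.pedigree_path, self.phenotype_path,
                  self.weather_daily_path, self.weather_hourly_path):
            if p is not None and not Path(p).exists():
                raise PipelineError("config", f"input file not found: {p}")

    def digest(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if hasattr(o, "__dict__"):
                return {k: v for k, v in o.__dict__.items()
                        if not k.startswith("_") and k != "out_dir"}
            return str(o)
        payload = {k: v for k, v in self.__dict__.items()
                   if not k.startswith("_") and k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, default=default, sort_keys=True).encode()
        ).hexdigest()[:16]


STAGES = ("load", "covariates", "qc", "screen", "fit", "params", "ebv")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk).

    A failure in any stage is re-raised as :class:`PipelineError` naming
    the stage; the manifest on disk then lists the stages that completed
    and is marked incomplete.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"breed": config.breed_label, "seed": config.seed,
                      "config_hash": config.digest(), "stages": {}, "complete": False}

    def stage_done(name, **counts):
        manifest["stages"][name] = counts

    try:
        return _run_stages(config, out, manifest, stage_done)
    except PipelineError:
        raise
    except Exception as exc:
        done = list(manifest["stages"])
        current = STAGES[len(done)] if len(done) < len(STAGES) else STAGES[-1]
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise PipelineError(
            current,
            f"{exc} (completed stages: {', '.join(done) or 'none'}; "
            "partial outputs are marked incomplete)") from exc


def _run_stages(config: RunConfig, out: Path, manifest: dict, stage_done):

    # ---- load ------------------------------------------------------------
    if config.scenario is not None:
        scenario = config.scenario
        if config.seed is not None:
            scenario = SimScenario(**{**scenario.__dict__, "seed": config.seed})
        pedf, weather, records, truth = simulate_dataset(scenario)
        daily = {f: w.daily for f, w in weather.items()}
        hourly = {f: w.hourly for f, w in weather.items()}
    else:
        pedf = pd.read_csv(config.pedigree_path, parse_dates=["birth_date"])
        records = pd.read_csv(config.phenotype_path, parse_dates=["birth_date"])
        wd = pd.read_csv(config.weather_daily_path, parse_dates=["date"])
        daily = {f: g.drop(columns="farm") for f, g in wd.groupby("farm")}
        hourly = {}
        if config.weather_hourly_path:
            wh = pd.read_csv(config.weather_hourly_path, parse_dates=["timestamp"])
            hourly = {f: g.drop(columns="farm") for f, g in wh.groupby("farm")}
        truth = None
    stage_done("load", animals_in_pedigree=len(pedf), phenotype_rows=len(records))

    # ---- covariates ------------------------------------------------------
    ec_defs = [ECDefinition.from_name(n) for n in config.ec_names]
    ec_table = compute_ec_table(records, daily, hourly, ec_defs)
    ec_wide = ec_table.pivot(index="animal", columns="ec_name", values="raw")
    ec_wide.to_csv(out / "ec_values.csv")
    stage_done("covariates", animals=ec_wide.shape[0], ecs=len(ec_defs))

    # ---- qc --------------------------------------------------------------
    records_qc, report = qc.run_qc(records)
    report.exclusions.to_csv(out / "qc_exclusions.csv", index=False)
    stage_done("qc", **{"input": report.n_input, "retained": report.n_retained,
                        "dropped_groups": len(report.dropped_groups)})

    ped = validate_and_sort(pedf[["animal", "sire", "dam", "birth_date"]])

    # ---- screen (phenotypic regressions, raw EC) -------------------------
    screen_rows = []
    if config.run_screen:
        for ec in config.ec_names:
            rec_ec = records_qc.merge(
                ec_wide[ec].rename("ec_raw"), left_on="animal", right_index=True,
                suffixes=("_sim", ""))
            for trait in ("bw", "ww"):
                res = fit_phenotypic_screen(rec_ec, ec, trait)
                screen_rows.append({
                    "ec_name": ec, "trait": trait, "estimate": res.estimate,
                    "se": res.se, "z": res.z_value, "p_value": res.p_value,
                    "n": res.n_records, "var_dam": res.components["dam"],
                    "var_cg": res.components["cg"],
                    "var_residual": res.components["residual"]})
        pd.DataFrame(screen_rows).to_csv(out / "screen_regressions.csv", index=False)
    stage_done("screen", fits=len(screen_rows))

    # ---- fit (one bivariate RNM per EC) ----------------------------------
    fits = {}
    scales = {}
    for ec in config.ec_names:
        rec_ec = records_qc.copy()
        raw = rec_ec["animal"].map(ec_wide[ec])
        scaled, scale = scale_ec(raw.to_numpy(), ec)
        rec_ec["ec_raw"], rec_ec["ec_scaled"] = raw, scaled
        scales[ec] = scale
        problem, info = build_design(rec_ec, ped, ModelSpec(ec_name=ec), ec_scale=scale)
        fit = em_reml_fit(problem, start_values(rec_ec).as_engine_dict(), config.reml)
        fits[ec] = (fit, info)
        vc = VarianceComponents.from_engine_dict(fit.components)
        np.savetxt(out / f"components_g8_{ec}.csv", vc.g8, delimiter=",")
        fit.trace[["iteration", "loglik", "max_rel_change"]].to_csv(
            out / f"reml_trace_{ec}.csv", index=False)
    stage_done("fit", models=len(fits),
               converged=sum(f.converged for f, _ in fits.values()),
               mme_order=problem.n_cols)

    # ---- params ----------------------------------------------------------
    param_tables = []
    isl_tables = []
    for ec, (fit, info) in fits.items():
        vc = VarianceComponents.from_engine_dict(fit.components)
        grid = GradientGrid.default(ec, scales[ec], config.gradient_points)
        param_tables.append(gradient_parameter_table(vc, grid))
        isl_tables.append(intercept_slope_table(vc, ec))
        for trait in ("bw", "ww"):
            rec_matrix(vc.direct_block(trait), grid).to_csv(
                out / f"rec_direct_{trait}_{ec}.csv")
            rec_matrix(vc.maternal_block(trait), grid).to_csv(
                out / f"rec_maternal_{trait}_{ec}.csv")
    params_df = pd.concat(param_tables, ignore_index=True)
    params_df.to_csv(out / "gradient_parameters.csv", index=False)
    isl_df = pd.concat(isl_tables, ignore_index=True)
    isl_df.to_csv(out / "intercept_slope.csv", index=False)
    stage_done("params", rows=len(params_df))

    # ---- ebv / plasticity ------------------------------------------------
    ebv_frames = []
    rerank_rows = []
    for ec, (fit, info) in fits.items():
        coefs = fit.term_solutions["genetic"]
        for trait, (i0, i1) in (("bw", (0, 1)), ("ww", (2, 3))):
            coef_df = pd.DataFrame({"animal": info.animal_ids,
                                    "mu0": coefs[:, i0], "mu1": coefs[:, i1]})
            traj = ebv_trajectories(coef_df, trait, config.rerank_gradients)
            traj.insert(0, "ec_name", ec)
            ebv_frames.append(traj)
            elite, counts = select_elite_sires(records_qc, config.min_progeny)
            if len(elite) >= 3:
                rr = rerank_analysis(traj[traj["animal"].isin(elite)],
                                     config.rerank_gradients)
                for (a, b), rho in rr["spearman"].items():
                    rerank_rows.append({"ec_name": ec, "trait": trait,
                                        "gradient_a": a, "gradient_b": b,
                                        "spearman_rho": rho,
                                        "top10_overlap": rr["top_overlap"][(a, b)],
                                        "n_elite": len(elite)})
    ebv_df = pd.concat(ebv_frames, ignore_index=True)
    ebv_df.to_csv(out / "ebv_trajectories.csv", index=False)
    rerank_df = pd.DataFrame(rerank_rows)
    rerank_df.to_csv(out / "sire_reranking.csv", index=False)
    stage_done("ebv", animals=ebv_df["animal"].nunique(), rerank_rows=len(rerank_df))

    manifest["complete"] = True
    manifest["outputs"] = sorted(p.name for p in out.glob("*.csv"))
    result = {"manifest": manifest, "records_qc": records_qc, "qc_report": report,
              "ec_values": ec_wide, "screen": pd.DataFrame(screen_rows),
              "fits": fits, "scales": scales, "params": params_df,
              "intercept_slope": isl_df, "ebv": ebv_df, "rerank": rerank_df,
              "truth": truth, "pedigree": ped}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return result


def summarize_run(result: dict) -> dict:
    """Report tables: data structure, EC correlations, screen
    coefficients, and intercept-slope statistics."""
    rec = result["records_qc"]
    struct = pd.DataFrame({
        "quantity": ["records_bw", "records_ww", "records_total",
                     "animals_in_pedigree", "contemporary_groups", "farms",
                     "mean_bw_kg", "sd_bw_kg", "mean_ww_kg", "sd_ww_kg"],
        "value": [int(rec["bw_kg"].notna().sum()), int(rec["ww_kg"].notna().sum()),
                  len(rec), len(result["pedigree"]), rec["cg_id"].nunique(),
                  rec["farm"].nunique(),
                  float(rec["bw_kg"].mean()), float(rec["bw_kg"].std()),
                  float(rec["ww_kg"].mean()), float(rec["ww_kg"].std())],
    })
    ec_corr = result["ec_values"].corr()
    return {"data_structure": struct, "ec_correlations": ec_corr,
            "screen": result["screen"], "intercept_slope": result["intercept_slope"],
            "gradient_parameters": result["params"]}
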