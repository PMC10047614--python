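"""End-to-end orchestration: simulate/load -> metrics -> filter -> adjust -> fit.

``run_pipeline`` is the single entry point behind the numbered analysis
drivers. Every stage writes its artifact under the configured output
directory and the manifest echoes the full configuration and seed, so a run
is reproducible from the manifest alone: identical config + seed gives
byte-identical outputs.

Failure modes are typed so shell drivers can map them to exit codes:
ConfigurationError (bad config), SchemaError (invalid data),
ConvergenceError (model fitting failed).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fid_adjust import adjust_table
from .filtering import apply_exclusions, validate_sampling_criteria
from .glmm import (ConvergenceError, check_collinearity, fit_glmm,
                   fit_with_overdispersion_fallback, influence_refit,
                   model1_spec, model2_spec, overdispersion_check)
from .metrics import annotate_encounters
from .raster import (read_ascii_grid, read_perches_geojson, write_ascii_grid,
                     write_perches_geojson)
from .report import render_results_table, results_frame
from .simulate import (ConfigurationError, LandscapeConfig, SimulationParams,
                       SpatialEscapeParams, generate_landscape, read_encounters,
                       simulate_encounters_spatial, simulate_encounters_tabular,
                       write_encounters)


@dataclass
class PipelineConfig:
    mode: str = "tabular"                  # tabular | spatial | real_csv
    outdir: str = "results/run"
    seed: int = 0
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    sim: SimulationParams = field(default_factory=SimulationParams)
    escape: SpatialEscapeParams = field(default_factory=SpatialEscapeParams)
    encounters_path: Optional[str] = None  # real_csv mode
    raster_path: Optional[str] = None
    perches_path: Optional[str] = None
    model1_family: str = "gaussian"
    model2_family: str = "auto"            # auto: poisson -> NB on overdispersion,
                                           # or gaussian_log for non-integer distances

    def validate(self) -> None:
        if self.mode not in ("tabular", "spatial", "real_csv"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.mode == "real_csv" and not self.encounters_path:
            raise ConfigurationError("real_csv mode needs encounters_path")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigurationError("seed must be an integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, val in raw.items():
            if key == "landscape":
                cfg.landscape = LandscapeConfig(**val)
            elif key == "sim":
                val = dict(val)
                if "std_range_m" in val:
                    val["std_range_m"] = tuple(val["std_range_m"])
                cfg.sim = SimulationParams(**val)
            elif key == "escape":
                cfg.escape = SpatialEscapeParams(**val)
            elif hasattr(cfg, key):
                setattr(cfg, key, val)
            else:
                raise ConfigurationError(f"unknown config key {key!r}")
        return cfg


def _seeded(cfg: PipelineConfig) -> PipelineConfig:
    """Push the pipeline seed into the generator configs (kept below 2^31)."""
    base = int(cfg.seed) % (2 ** 31 - 1)
    cfg.landscape = LandscapeConfig(**{**asdict(cfg.landscape), "seed": base + 1})
    sim = asdict(cfg.sim)
    sim["seed"] = base + 2
    sim["std_range_m"] = tuple(sim["std_range_m"])
    cfg.sim = SimulationParams(**sim)
    return cfg


def _choose_model2_family(distances: pd.Series) -> str:
    d = distances.dropna().astype(float)
    if len(d) and np.allclose(d, np.round(d)):
        return "poisson"          # counts-like: NB fallback applies downstream
    return "gaussian_log"


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write all artifacts; returns them in memory too."""
    config.validate()
    config = _seeded(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    # --- stage 1: obtain encounters -------------------------------------
    raster = perches = None
    if config.mode == "tabular":
        table = simulate_encounters_tabular(config.sim)
    elif config.mode == "spatial":
        raster, perches = generate_landscape(config.landscape)
        write_ascii_grid(raster, outdir / "landscape.asc")
        write_perches_geojson(perches, outdir / "perches.geojson")
        table = simulate_encounters_spatial(raster, perches, config.sim,
                                            config.escape)
    else:
        table = read_encounters(config.encounters_path)
        if config.raster_path:
            raster = read_ascii_grid(config.raster_path)
        if config.perches_path:
            perches = read_perches_geojson(config.perches_path)
    write_encounters(table, outdir / "encounters.csv")
    log.append(f"encounters: {len(table)} rows")

    # --- stage 2: spatial metrics ---------------------------------------
    if raster is not None or perches is not None:
        table = annotate_encounters(table, raster, perches)
    elif not {"rc_prop", "pd_per_m"}.issubset(table.columns):
        raise ConfigurationError(
            "no raster/perch layers and no rc_prop/pd_per_m columns: "
            "metrics cannot be computed")
    table.to_csv(outdir / "encounters_with_metrics.csv", index=False)

    warnings_list = validate_sampling_criteria(table)
    log.append(f"sampling-protocol warnings: {len(warnings_list)}")

    # --- stage 3: exclusion cascade -------------------------------------
    analysis, report = apply_exclusions(table)
    report.to_frame().to_csv(outdir / "exclusion_report.csv", index=False)
    log.append(f"exclusions: {report.n_non_response} non-response, "
               f"{report.n_non_flight} non-flight, "
               f"{report.n_refuge_unknown} refuge-unknown, "
               f"{report.n_dropped_species_threshold} below species threshold; "
               f"{report.n_retained} retained")

    # --- stage 4: FID adjustment ----------------------------------------
    analysis, adj_params = adjust_table(analysis)
    adj_params.to_csv(outdir / "fid_adjustment_params.csv", index=False)
    analysis.to_csv(outdir / "analysis_table.csv", index=False)

    # --- stage 5: per-species models ------------------------------------
    fits1: dict = {}
    fits2: dict = {}
    diagnostics: dict = {}
    for sp, sub in analysis.groupby("species", sort=True):
        sub = sub.dropna(subset=["rc_prop", "pd_per_m", "fid_m", "std_m",
                                 "distance_fled_m", "fid_adj_m"])
        diag: dict = {}
        spec1 = model1_spec(config.model1_family)
        diag["model1_collinearity"] = vars(check_collinearity(
            sub, ["rc_prop", "pd_per_m", "std_m"]))
        fits1[sp] = fit_glmm(spec1, sub, label=str(sp))

        fam2 = config.model2_family
        if fam2 == "auto":
            fam2 = _choose_model2_family(sub["distance_fled_m"])
        diag["model2_collinearity"] = vars(check_collinearity(
            sub, ["fid_adj_m", "rc_prop", "pd_per_m"]))
        if fam2 == "poisson":
            if (sub["distance_fled_m"] <= 0).any():
                sub = sub[sub["distance_fled_m"] > 0]
            fit2, disp = fit_with_overdispersion_fallback(
                model2_spec(), sub, label=str(sp))
            diag["model2_dispersion_ratio"] = disp.dispersion_ratio
        else:
            if fam2 == "gaussian_log":
                sub = sub[sub["distance_fled_m"] > 0]
            fit2 = fit_glmm(model2_spec(fam2), sub, label=str(sp))
        fits2[sp] = fit2
        try:
            infl = influence_refit(model2_spec(fit2.family), sub, fit2)
            diag["model2_influential_rows"] = list(map(int, np.atleast_1d(
                infl.cooks_influential_rows))) if infl.cooks_influential_rows else []
            diag["model2_refit_qualitative_change"] = infl.refit_qualitative_change
        except (ValueError, ConvergenceError) as exc:
            diag["model2_influence"] = f"skipped: {exc}"
        diagnostics[str(sp)] = diag
        log.append(f"{sp}: model1 family={fits1[sp].family}, "
                   f"model2 family={fit2.family} "
                   f"(random SD {fit2.random_sd:.3f})")

    frame1 = results_frame(fits1)
    frame2 = results_frame(fits2)
    frame1.to_csv(outdir / "model1_results.csv", index=False)
    frame2.to_csv(outdir / "model2_results.csv", index=False)
    text = ("Model 1: FID ~ RC + PD + StD + (1 | park)\n"
            + render_results_table(fits1)
            + "\n\nModel 2: distance fled ~ FID_Adj * (RC + PD) + (1 | park)\n"
            + render_results_table(fits2) + "\n")
    (outdir / "results_table.txt").write_text(text)

    with open(outdir / "diagnostics.yaml", "w") as fh:
        yaml.safe_dump(_plain(diagnostics), fh, sort_keys=True)

    manifest = {
        "package_version": __version__,
        "seed": int(config.seed),
        "mode": config.mode,
        "config": _plain({
            "landscape": asdict(config.landscape),
            "sim": asdict(config.sim),
            "escape": asdict(config.escape),
            "model1_family": config.model1_family,
            "model2_family": config.model2_family,
        }),
        "log": log,
        "warnings": warnings_list,
        "exclusions": _plain(report.percentages()),
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(_plain(manifest), fh, sort_keys=True)
    return {"table": table, "analysis": analysis, "exclusion_report": report,
            "adjustment": adj_params, "model1": fits1, "model2": fits2,
            "diagnostics": diagnostics, "manifest": manifest}


def _plain(obj):
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
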