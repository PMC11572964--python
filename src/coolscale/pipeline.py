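"""End-to-end orchestration: aggregate -> estimate -> fit -> predict.

A :class:`RunConfig` (YAML-serializable) describes either real raster
inputs or a simulation, the scale ladder, fit options and prediction
targets. :func:`run_pipeline` executes the stages, archives every
intermediate table beside the outputs, and returns a manifest recording
package versions, the seed, a hash of the config and per-stage row counts,
so any run can be audited and reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregate import aggregate, make_ladder, write_unit_tables
from .errors import CoolscaleError, PipelineError, ValidationError
from .raster import coarsen_canopy, load_raster_pair
from .regression import estimate_all, estimates_to_frame
from .scaling import fit_power_law, pool_fits, select_model
from .prediction import predict_city
from .synthetic import (
    RasterSimConfig,
    TabularSimConfig,
    simulate_raster_pair,
    simulate_unit_tables,
)
from .weather import correlate_exponents, read_weather_csv, results_to_frame


@dataclass
class RunConfig:
    """Everything one pipeline run needs, fully serializable to YAML."""

    # input: either a simulation...
    simulate: dict | None = None          # {"kind": "tabular"|"raster", ...config fields}
    n_dates: int = 1                      # >1 simulates repeat dates and pools the fits
    betas_per_date: list[float] | None = None   # per-date exponent truths (tabular sims)
    # ...or real rasters (single date) / a list of dates
    lst_path: str | None = None
    canopy_path: str | None = None
    boundary_path: str | None = None
    dates: list[dict] | None = None       # [{"date_id", "lst_path", "canopy_path"}, ...]
    # ladder and aggregation
    base_pixel_m: float = 120.0
    w_max: int = 23
    min_valid_fraction: float = 0.5
    # fitting
    fit_method: str = "select"            # "power" | "quadratic" | "select"
    fit_space: str = "log-log"
    alpha: float = 0.01
    weights: str | None = None
    # prediction
    s_city_m: float | None = None         # default: largest ladder size
    delta_t_target: float | None = None   # skip prediction when None
    # weather
    weather_csv: str | None = None
    # bookkeeping
    out_dir: str = "coolscale_run"
    seed: int = 0

    def validate(self) -> None:
        if self.simulate is None and self.lst_path is None and self.dates is None:
            raise ValidationError("config needs a simulation or raster input paths")
        if self.w_max < 1 or self.w_max % 2 == 0:
            raise ValidationError(f"w_max must be odd and positive, got {self.w_max}")
        if not 0 < self.min_valid_fraction <= 1:
            raise ValidationError("min_valid_fraction must be in (0, 1]")
        if self.n_dates < 1:
            raise ValidationError("n_dates must be >= 1")
        if self.betas_per_date is not None and len(self.betas_per_date) != self.n_dates:
            raise ValidationError("betas_per_date length must equal n_dates")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, default_flow_style=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def sha256(self) -> str:
        canon = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


def _simulate_date_tables(cfg: RunConfig, date_seed: int, beta: float | None):
    sim = dict(cfg.simulate)
    kind = sim.pop("kind", "tabular")
    if kind == "tabular":
        tab = TabularSimConfig(**sim)
        tab.seed = date_seed
        if beta is not None:
            tab.beta = beta
        return simulate_unit_tables(tab)
    if kind == "raster":
        ras = RasterSimConfig(**sim)
        ras.seed = date_seed
        pair = simulate_raster_pair(ras, max_unit_width_px=cfg.w_max)
        pair = coarsen_canopy(pair)
        ladder = make_ladder(ras.pixel_size, cfg.w_max)
        return aggregate(pair, ladder, cfg.min_valid_fraction)
    raise ValidationError(f"unknown simulation kind {kind!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and return the run manifest.

    Stage order: input (load or simulate) -> aggregate -> estimate ->
    fit (power law with quadratic fallback) -> optional whole-city
    prediction -> optional weather correlation (multi-date runs only).
    Failures carry the stage name via :class:`PipelineError`.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest: dict = {
        "package": "coolscale",
        "version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": config.seed,
        "config_sha256": config.sha256(),
        "stages": {},
    }
    ladder = make_ladder(config.base_pixel_m, config.w_max)
    seed_seq = np.random.SeedSequence(config.seed)
    date_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(max(config.n_dates, 1))]

    # ---- stage: input + aggregate -> per-date unit tables -------------
    per_date_tables: list[tuple[str, list]] = []
    try:
        if config.simulate is not None:
            for i in range(config.n_dates):
                beta = config.betas_per_date[i] if config.betas_per_date else None
                tables = _simulate_date_tables(config, date_seeds[i], beta)
                per_date_tables.append((f"d{i:02d}", tables))
        elif config.dates is not None:
            for d in config.dates:
                pair = load_raster_pair(
                    d["lst_path"], d["canopy_path"], d.get("boundary_path")
                )
                pair = coarsen_canopy(pair)
                tables = aggregate(pair, ladder, config.min_valid_fraction)
                per_date_tables.append((str(d["date_id"]), tables))
        else:
            pair = load_raster_pair(
                config.lst_path, config.canopy_path, config.boundary_path
            )
            pair = coarsen_canopy(pair)
            tables = aggregate(pair, ladder, config.min_valid_fraction)
            per_date_tables.append(("d00", tables))
    except CoolscaleError as exc:
        raise PipelineError("aggregate", str(exc)) from exc

    units_manifest = {}
    for date_id, tables in per_date_tables:
        units_manifest[date_id] = write_unit_tables(tables, out / "units" / date_id)
    manifest["stages"]["aggregate"] = {
        "n_dates": len(per_date_tables),
        "units": units_manifest,
    }

    # ---- stage: estimate ---------------------------------------------
    try:
        per_date_estimates = []
        frames = []
        for date_id, tables in per_date_tables:
            est = estimate_all(tables)
            per_date_estimates.append(est)
            frame = estimates_to_frame(est)
            frame.insert(0, "date_id", date_id)
            frames.append(frame)
    except CoolscaleError as exc:
        raise PipelineError("estimate", str(exc)) from exc
    est_df = pd.concat(frames, ignore_index=True)
    est_df.to_csv(out / "ce_estimates.csv", index=False)
    manifest["stages"]["estimate"] = {
        "n_rows": len(est_df),
        "scales_per_date": {d: len(e) for (d, _), e in zip(per_date_tables, per_date_estimates)},
    }

    # ---- stage: fit ---------------------------------------------------
    try:
        if len(per_date_estimates) > 1:
            fit = pool_fits(per_date_estimates, fit_space=config.fit_space)
            for (date_id, _), dfit in zip(per_date_tables, fit.per_date or []):
                dfit.to_json(out / f"fit_{date_id}.json")
        else:
            if config.fit_method == "power":
                fit = fit_power_law(
                    per_date_estimates[0], fit_space=config.fit_space,
                    weights=config.weights,
                )
            else:
                fit = select_model(
                    per_date_estimates[0], alpha=config.alpha,
                    fit_space=config.fit_space,
                )
    except CoolscaleError as exc:
        raise PipelineError("fit", str(exc)) from exc
    fit.to_json(out / "fit.json")
    np.savetxt(
        out / "fit_curve.csv", fit.curve_samples(),
        delimiter=",", header="scale_m,ce_fit", comments="",
    )
    manifest["stages"]["fit"] = fit.to_dict()

    # ---- stage: predict (optional) ------------------------------------
    if config.delta_t_target is not None:
        s_city = config.s_city_m if config.s_city_m is not None else max(ladder.sizes_m)
        try:
            pred = predict_city(fit, s_city, config.delta_t_target)
        except CoolscaleError as exc:
            raise PipelineError("predict", str(exc)) from exc
        pred.to_json(out / "prediction.json")
        manifest["stages"]["predict"] = pred.to_dict()

    # ---- stage: weather (multi-date only, optional) --------------------
    if config.weather_csv is not None:
        if len(per_date_estimates) < 3:
            warnings.warn("weather stage needs >= 3 dates; skipping")
        else:
            try:
                records = read_weather_csv(config.weather_csv)
                betas = {}
                for (date_id, _), dfit in zip(per_date_tables, fit.per_date or []):
                    if dfit.model_form == "power":
                        betas[date_id] = dfit.beta
                results = correlate_exponents(betas, records)
            except CoolscaleError as exc:
                raise PipelineError("weather", str(exc)) from exc
            wdf = results_to_frame(results)
            wdf.to_csv(out / "exponent_weather.csv", index=False)
            manifest["stages"]["weather"] = wdf.to_dict(orient="records")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
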