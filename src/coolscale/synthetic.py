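"""Synthetic inputs with the statistical structure the scaling analysis assumes.

Two generators:

* :func:`simulate_unit_tables` draws per-scale unit samples whose LST-vs-
  canopy slope follows the power law CE(S) = k * S**beta exactly, plus
  additive Gaussian noise — the ground-truth model for parameter-recovery
  experiments on the estimation and fitting stages.

* :func:`simulate_raster_pair` builds a canopy / temperature raster pair in
  which cooling has a local component plus a neighborhood-smoothed
  component. Averaging over larger analytical units captures more of the
  neighborhood term, so the estimated cooling efficiency grows with unit
  size — a caricature of the patch-size dependence of evapotranspiration
  thought to drive the empirical scaling.

All randomness flows from a single integer seed through a splittable
``numpy.random.SeedSequence``, so reruns are bit-for-bit reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .aggregate import UNIT_COLUMNS, UnitTable
from .errors import ConfigurationError
from .raster import RasterPair

#: the 12-step ladder of unit sizes used as the default study condition
DEFAULT_SCALES_M = tuple(float(120 * w) for w in range(1, 24, 2))


def _require(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ConfigurationError(f"{fieldname}: {msg}")


@dataclass
class TabularSimConfig:
    """Truth model for per-scale unit samples.

    LST = intercept - (k * S**beta) * Ptree + Normal(0, noise_sd**2),
    with Ptree drawn on ``ptree_range`` percent. Defaults are the pooled
    power-law parameters (k = 0.057 degC per %UTC, beta = 0.165) on the
    twelve 120–2760 m scales with 1000 units per scale and 0.5 degC
    residual noise.
    """

    k: float = 0.057
    beta: float = 0.165
    scales: tuple[float, ...] = DEFAULT_SCALES_M
    n_per_scale: int = 1000
    intercept: float = 40.0
    noise_sd: float = 0.5
    ptree_range: tuple[float, float] = (0.0, 100.0)
    seed: int = 0
    # optional structure flags
    intercept_per_scale: bool = False   # free baseline per scale, like free per-scale OLS intercepts
    ptree_dist: str = "uniform"         # "uniform" | "beta" (Beta(2,2) rescaled to ptree_range)

    def validate(self) -> None:
        _require(self.k > 0, "k", "must be > 0")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        lo, hi = self.ptree_range
        _require(0 <= lo < hi <= 100, "ptree_range", "requires 0 <= low < high <= 100")
        s = np.asarray(self.scales, dtype=float)
        _require(len(s) > 0 and np.all(s > 0), "scales", "must be positive")
        _require(np.all(np.diff(s) > 0), "scales", "must be strictly increasing")
        _require(self.n_per_scale >= 3, "n_per_scale", "must be >= 3")
        _require(self.ptree_dist in ("uniform", "beta"), "ptree_dist",
                 "must be 'uniform' or 'beta'")


@dataclass
class RasterSimConfig:
    """Truth model for a simulated canopy / LST raster pair.

    The canopy is a correlated Gaussian random field thresholded at the
    quantile matching ``canopy_cover_target``. LST is

        intercept_c - local_effect * cover
                    - neighborhood_effect * smooth(cover, neighborhood_range)
                    + Normal(0, noise_sd**2)

    per base pixel, with cover in [0, 1]. ``fine_factor`` > 1 instead
    emits a binary canopy at that many times finer resolution (cover at
    base resolution is its block mean). Defaults place the base-scale
    cooling efficiency near the 0.05–0.2 degC/% range typical of summer
    daytime LST analyses.
    """

    n_rows: int = 120
    n_cols: int = 120
    pixel_size: float = 120.0
    canopy_corr_range: float = 360.0
    canopy_cover_target: float = 0.3
    local_effect: float = 5.0
    neighborhood_effect: float = 5.0
    neighborhood_range: float = 600.0
    noise_sd: float = 1.0
    intercept_c: float = 40.0
    fine_factor: int = 1
    seed: int = 0

    def validate(self) -> None:
        _require(self.n_rows >= 3 and self.n_cols >= 3, "n_rows/n_cols", "must be >= 3")
        _require(self.pixel_size > 0, "pixel_size", "must be > 0")
        _require(self.canopy_corr_range > 0, "canopy_corr_range", "must be > 0")
        _require(self.neighborhood_range > 0, "neighborhood_range", "must be > 0")
        _require(0 < self.canopy_cover_target < 1, "canopy_cover_target", "must be in (0, 1)")
        _require(self.local_effect >= 0, "local_effect", "must be >= 0")
        _require(self.neighborhood_effect >= 0, "neighborhood_effect", "must be >= 0")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _require(self.fine_factor >= 1 and int(self.fine_factor) == self.fine_factor,
                 "fine_factor", "must be a positive integer")


def simulate_unit_tables(config: TabularSimConfig) -> list[UnitTable]:
    """Draw per-scale unit samples under the power-law truth model.

    Returns one :class:`UnitTable` per scale, in ladder order. With
    ``noise_sd=0`` the per-scale OLS slope equals -k * S**beta exactly.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(config.scales))
    lo, hi = config.ptree_range
    tables = []
    for child, s in zip(children, config.scales):
        rng = np.random.default_rng(child)
        n = config.n_per_scale
        if config.ptree_dist == "beta":
            ptree = lo + (hi - lo) * rng.beta(2.0, 2.0, n)
        else:
            ptree = rng.uniform(lo, hi, n)
        intercept = config.intercept
        if config.intercept_per_scale:
            intercept = intercept + rng.normal(0.0, 1.0)
        ce_true = config.k * s ** config.beta
        lst = intercept - ce_true * ptree
        if config.noise_sd > 0:
            lst = lst + rng.normal(0.0, config.noise_sd, n)
        df = pd.DataFrame(
            {
                "unit_id": np.arange(n),
                "ptree_pct": ptree,
                "lst_mean_c": lst,
                "n_valid_px": np.ones(n, dtype=int),
                "valid_fraction": np.ones(n),
            }
        )[UNIT_COLUMNS]
        tables.append(UnitTable(scale_m=float(s), data=df))
    return tables


def _correlated_field(shape: tuple[int, int], sigma_px: float,
                      rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(shape)
    if sigma_px > 0:
        noise = ndimage.gaussian_filter(noise, sigma=sigma_px, mode="wrap")
    return noise


def simulate_raster_pair(
    config: RasterSimConfig, max_unit_width_px: int | None = None
) -> RasterPair:
    """Simulate a co-registered canopy / LST raster pair.

    ``max_unit_width_px``, when given, is the largest tile width the pair
    will be aggregated at; grids smaller than 3x that width are rejected so
    the top scale retains at least ~9 units.
    """
    config.validate()
    if max_unit_width_px is not None and (
        config.n_rows < 3 * max_unit_width_px or config.n_cols < 3 * max_unit_width_px
    ):
        raise ConfigurationError(
            f"grid {config.n_rows}x{config.n_cols} is smaller than 3x the largest "
            f"requested unit width ({max_unit_width_px} px); use a larger grid"
        )
    ss = np.random.SeedSequence(config.seed)
    rng_field, rng_noise = (np.random.default_rng(c) for c in ss.spawn(2))

    f = int(config.fine_factor)
    fine_px = config.pixel_size / f
    fine_shape = (config.n_rows * f, config.n_cols * f)
    field_ = _correlated_field(fine_shape, config.canopy_corr_range / fine_px, rng_field)
    # empirical quantile threshold pins realized cover to the target
    thresh = np.quantile(field_, 1.0 - config.canopy_cover_target)
    canopy_fine = (field_ > thresh).astype(float)

    cover = canopy_fine.reshape(config.n_rows, f, config.n_cols, f).mean(axis=(1, 3))
    smooth = ndimage.gaussian_filter(
        cover, sigma=config.neighborhood_range / config.pixel_size, mode="wrap"
    )
    lst = (
        config.intercept_c
        - config.local_effect * cover
        - config.neighborhood_effect * smooth
    )
    if config.noise_sd > 0:
        lst = lst + rng_noise.normal(0.0, config.noise_sd, lst.shape)

    if f > 1:
        return RasterPair(
            lst=lst, canopy=canopy_fine, pixel_size_m=config.pixel_size,
            canopy_is_binary=True, fine_factor=f,
        )
    return RasterPair(
        lst=lst, canopy=cover, pixel_size_m=config.pixel_size,
        canopy_is_binary=False, fine_factor=1,
    )


def config_to_yaml(config, path) -> None:
    """Archive a simulation config as YAML beside its outputs."""
    with open(path, "w") as fh:
        yaml.safe_dump({"type": type(config).__name__, **asdict(config)}, fh,
                       default_flow_style=False)


def config_from_yaml(path):
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    kind = raw.pop("type")
    cls = {"TabularSimConfig": TabularSimConfig, "RasterSimConfig": RasterSimConfig}[kind]
    for key in ("scales", "ptree_range"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return cls(**raw)
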