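"""Multi-scale grid aggregation of the raster pair into unit samples.

The scaling design tiles the city with square analytical units of growing
side length — 1x1, 3x3, 5x5, ... base pixels — and reduces each unit to a
(percent canopy cover, mean LST) sample. Regressing mean LST on cover
within one tile size gives the cooling efficiency at that scale; repeating
over the ladder of sizes traces how the efficiency scales.

Tiles are anchored at the raster's top-left corner and partial tiles at
the right/bottom edges are discarded, so every unit has equal support.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .raster import RasterPair

logger = logging.getLogger(__name__)

UNIT_COLUMNS = ["unit_id", "ptree_pct", "lst_mean_c", "n_valid_px", "valid_fraction"]


@dataclass(frozen=True)
class ScaleLadder:
    """The ladder of analytical-unit sizes.

    widths_px are odd positive pixel counts (1, 3, 5, ..., w_max);
    sizes_m = widths_px * base_pixel_m exactly.
    """

    base_pixel_m: float
    widths_px: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.base_pixel_m <= 0:
            raise ValidationError("base_pixel_m must be > 0")
        w = self.widths_px
        if len(w) == 0 or any(int(x) != x or x < 1 for x in w):
            raise ValidationError("widths_px must be positive integers")
        if any(b <= a for a, b in zip(w, w[1:])):
            raise ValidationError("widths_px must be strictly increasing")

    @property
    def sizes_m(self) -> tuple[float, ...]:
        return tuple(w * self.base_pixel_m for w in self.widths_px)

    def __len__(self) -> int:
        return len(self.widths_px)


def make_ladder(
    base_pixel_m: float, w_max: int, widths: tuple[int, ...] | None = None
) -> ScaleLadder:
    """Build the odd-width ladder 1, 3, 5, ..., w_max.

    With 120 m base pixels, w_max=23 tops out at 2760 m and w_max=37 at
    4440 m. Pass ``widths`` explicitly to use an arbitrary (e.g. even)
    ladder for sensitivity analysis; w_max is then ignored.
    """
    if widths is not None:
        return ScaleLadder(base_pixel_m, tuple(int(w) for w in widths))
    if w_max < 1 or int(w_max) != w_max:
        raise ValidationError(f"w_max must be a positive integer, got {w_max!r}")
    if w_max % 2 == 0:
        raise ValidationError(f"w_max must be odd, got {w_max}")
    return ScaleLadder(base_pixel_m, tuple(range(1, int(w_max) + 1, 2)))


@dataclass
class UnitTable:
    """Per-analytical-unit samples at one scale.

    ``data`` columns: unit_id, ptree_pct (percent cover in [0, 100]),
    lst_mean_c (degC), n_valid_px, valid_fraction.
    """

    scale_m: float
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in UNIT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"UnitTable missing columns: {missing}")
        p = self.data["ptree_pct"].to_numpy()
        if len(p) and (np.nanmin(p) < -1e-9 or np.nanmax(p) > 100 + 1e-9):
            raise ValidationError("ptree_pct must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def degenerate(self) -> bool:
        """True when the units carry no slope information (zero Ptree variance)."""
        p = self.data["ptree_pct"].to_numpy()
        return len(p) < 2 or float(np.var(p)) == 0.0

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "scale_m", self.scale_m)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "UnitTable":
        df = pd.read_csv(path)
        scale = float(df["scale_m"].iloc[0])
        return cls(scale_m=scale, data=df.drop(columns=["scale_m"]))


def _valid_mask(pair: RasterPair) -> np.ndarray:
    valid = np.isfinite(pair.lst) & np.isfinite(pair.canopy)
    if pair.boundary_mask is not None:
        valid &= pair.boundary_mask
    return valid


def aggregate(
    pair: RasterPair, ladder: ScaleLadder, min_valid_fraction: float = 0.5
) -> list[UnitTable]:
    """Aggregate the pair into (Ptree, mean LST) samples at every ladder size.

    For each width w, the raster is tiled by w x w blocks of base pixels
    anchored at the top-left. Per tile, ptree_pct is 100 x the mean
    fractional cover over valid pixels and lst_mean_c the mean LST over the
    same pixels. Tiles whose valid fraction falls below
    ``min_valid_fraction`` and partial edge tiles are dropped.

    The pair must hold fractional cover at base resolution (run
    :func:`coolscale.raster.coarsen_canopy` first for fine binary maps).
    """
    if pair.fine_factor != 1:
        raise ValidationError(
            "aggregate requires canopy at base resolution; run coarsen_canopy first"
        )
    if not 0 < min_valid_fraction <= 1:
        raise ValidationError("min_valid_fraction must be in (0, 1]")

    valid = _valid_mask(pair)
    lst = np.where(valid, pair.lst, 0.0)
    cover = np.where(valid, pair.canopy, 0.0)
    rows, cols = pair.lst.shape

    tables: list[UnitTable] = []
    for w, size_m in zip(ladder.widths_px, ladder.sizes_m):
        nr, nc = rows // w, cols // w
        if nr == 0 or nc == 0:
            warnings.warn(f"no complete {w}x{w} tile fits the raster; empty table")
            tables.append(UnitTable(size_m, pd.DataFrame(columns=UNIT_COLUMNS)))
            continue
        v = valid[: nr * w, : nc * w].reshape(nr, w, nc, w)
        l = lst[: nr * w, : nc * w].reshape(nr, w, nc, w)
        c = cover[: nr * w, : nc * w].reshape(nr, w, nc, w)
        n_valid = v.sum(axis=(1, 3))
        with np.errstate(invalid="ignore", divide="ignore"):
            lst_mean = np.where(n_valid > 0, l.sum(axis=(1, 3)) / np.maximum(n_valid, 1), np.nan)
            cov_mean = np.where(n_valid > 0, c.sum(axis=(1, 3)) / np.maximum(n_valid, 1), np.nan)
        frac = n_valid / (w * w)
        keep = frac >= min_valid_fraction
        if not keep.any():
            warnings.warn(f"no tile at scale {size_m:g} m meets the validity threshold")
            tables.append(UnitTable(size_m, pd.DataFrame(columns=UNIT_COLUMNS)))
            continue
        unit_ids = (np.arange(nr)[:, None] * nc + np.arange(nc)[None, :])[keep]
        df = pd.DataFrame(
            {
                "unit_id": unit_ids,
                "ptree_pct": 100.0 * cov_mean[keep],
                "lst_mean_c": lst_mean[keep],
                "n_valid_px": n_valid[keep],
                "valid_fraction": frac[keep],
            }
        )
        table = UnitTable(size_m, df)
        if table.degenerate:
            logger.warning("scale %g m: zero Ptree variance; no slope information", size_m)
        tables.append(table)
    return tables


def write_unit_tables(tables: list[UnitTable], out_dir) -> dict:
    """Write one CSV per scale plus a manifest of scales and unit counts."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"scales": []}
    for t in tables:
        name = f"units_{t.scale_m:g}m.csv"
        t.to_csv(out / name)
        manifest["scales"].append(
            {"scale_m": t.scale_m, "n_units": len(t), "file": name}
        )
    return manifest
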