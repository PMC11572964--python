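"""GeoTIFF-backed raster containers for the LST / canopy pair.

The pipeline consumes two co-registered single-band rasters: land surface
temperature (LST, degC) at a base resolution (e.g. 120 m Landsat-derived),
and tree canopy as either fractional cover in [0, 1] at the base resolution
or a binary map at a finer resolution that divides the base cell evenly
(e.g. 1 m aerial classifications under 120 m thermal pixels).

I/O is deliberately minimal: single-band GeoTIFFs with the standard
ModelPixelScale / ModelTiepoint geo tags and a GDAL-style nodata tag.
Grids are row-major with the origin at the top-left corner; no implicit
resampling or reprojection is ever performed — mismatched grids are
rejected so the multi-scale design cannot be silently corrupted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

from .errors import AlignmentError, CoverRangeError, ResolutionRatioError, ValidationError

logger = logging.getLogger(__name__)

# TIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GDAL_METADATA = 42112
_GDAL_NODATA = 42113

#: nodata sentinel used when writing float rasters
FLOAT_NODATA = -9999.0
#: nodata sentinel used when writing binary (uint8) rasters
BINARY_NODATA = 255


@dataclass
class RasterPair:
    """Co-registered LST and canopy rasters sharing one footprint.

    Attributes
    ----------
    lst : ndarray
        2-D float array of land surface temperature (degC) at base
        resolution; NaN marks nodata.
    canopy : ndarray
        Either fractional cover in [0, 1] at base resolution (NaN nodata),
        or binary {0, 1} cover at ``fine_factor`` times finer resolution.
    pixel_size_m : float
        Side length of a base (LST) pixel in meters.
    origin : tuple of float
        (x, y) map coordinates of the top-left raster corner.
    crs_id : str
        Coordinate-system identifier (free-form, e.g. ``"EPSG:32618"``).
    canopy_is_binary : bool
        True when ``canopy`` holds a {0, 1} classification.
    fine_factor : int
        Ratio of base to canopy pixel size (1 when canopy is at base
        resolution).
    boundary_mask : ndarray or None
        Optional boolean in-city indicator at base resolution.
    """

    lst: np.ndarray
    canopy: np.ndarray
    pixel_size_m: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs_id: str = "local"
    canopy_is_binary: bool = False
    fine_factor: int = 1
    boundary_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.lst = np.asarray(self.lst, dtype=float)
        self.canopy = np.asarray(self.canopy, dtype=float)
        if self.lst.ndim != 2 or self.canopy.ndim != 2:
            raise ValidationError("lst and canopy must be 2-D grids")
        if self.pixel_size_m <= 0:
            raise ValidationError("pixel_size_m must be > 0")
        if self.fine_factor < 1 or int(self.fine_factor) != self.fine_factor:
            raise ValidationError("fine_factor must be a positive integer")
        expected = (self.lst.shape[0] * self.fine_factor, self.lst.shape[1] * self.fine_factor)
        if self.canopy.shape != expected:
            raise AlignmentError(
                f"canopy shape {self.canopy.shape} is not lst shape {self.lst.shape} "
                f"times fine_factor {self.fine_factor}"
            )
        if not self.canopy_is_binary:
            finite = self.canopy[np.isfinite(self.canopy)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise CoverRangeError(
                    f"fractional cover outside [0, 1]: range "
                    f"[{finite.min():.4g}, {finite.max():.4g}]"
                )
        if self.boundary_mask is not None:
            self.boundary_mask = np.asarray(self.boundary_mask, dtype=bool)
            if self.boundary_mask.shape != self.lst.shape:
                raise AlignmentError("boundary_mask shape must match the LST grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.lst.shape

    @property
    def canopy_pixel_size_m(self) -> float:
        return self.pixel_size_m / self.fine_factor


def write_geotiff(
    path: str | Path,
    data: np.ndarray,
    pixel_size_m: float,
    origin: tuple[float, float] = (0.0, 0.0),
    crs_id: str = "local",
    binary: bool = False,
) -> Path:
    """Write a single-band GeoTIFF with geo tags and explicit nodata.

    Float rasters are stored float32 with NaN mapped to ``FLOAT_NODATA``;
    binary rasters are stored uint8 with NaN mapped to ``BINARY_NODATA``.
    """
    path = Path(path)
    data = np.asarray(data, dtype=float)
    if binary:
        out = np.where(np.isnan(data), BINARY_NODATA, data).astype(np.uint8)
        nodata = BINARY_NODATA
    else:
        out = np.where(np.isnan(data), FLOAT_NODATA, data).astype(np.float32)
        nodata = FLOAT_NODATA
    meta_xml = (
        '<GDALMetadata>\n'
        f'  <Item name="crs_id">{crs_id}</Item>\n'
        "</GDALMetadata>"
    )
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (float(pixel_size_m), float(pixel_size_m), 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(origin[0]), float(origin[1]), 0.0)),
        (_GDAL_NODATA, "s", 0, str(nodata)),
        (_GDAL_METADATA, "s", 0, meta_xml),
    ]
    tifffile.imwrite(path, out, extratags=extratags)
    return path


def read_geotiff(path: str | Path) -> dict:
    """Read a single-band GeoTIFF written by :func:`write_geotiff` (or any
    GeoTIFF carrying pixel-scale / tiepoint / nodata tags).

    Returns a dict with keys ``data`` (float array, NaN for nodata),
    ``pixel_size_m``, ``origin``, ``crs_id`` and ``dtype``.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        tags = page.tags
        if _MODEL_PIXEL_SCALE not in tags or _MODEL_TIEPOINT not in tags:
            raise ValidationError(f"{path} lacks GeoTIFF pixel-scale/tiepoint tags")
        scale = tags[_MODEL_PIXEL_SCALE].value
        tie = tags[_MODEL_TIEPOINT].value
        pixel_size = float(scale[0])
        origin = (float(tie[3]), float(tie[4]))
        nodata = None
        if _GDAL_NODATA in tags:
            nodata = float(str(tags[_GDAL_NODATA].value).strip("\x00").strip())
        crs_id = "local"
        if _GDAL_METADATA in tags:
            xml = str(tags[_GDAL_METADATA].value)
            marker = 'name="crs_id">'
            if marker in xml:
                crs_id = xml.split(marker, 1)[1].split("<", 1)[0]
    raw_dtype = data.dtype
    out = data.astype(float)
    if nodata is not None:
        out[data == nodata] = np.nan
    return {
        "data": out,
        "pixel_size_m": pixel_size,
        "origin": origin,
        "crs_id": crs_id,
        "dtype": raw_dtype,
    }


def write_raster_pair(
    pair: RasterPair, lst_path: str | Path, canopy_path: str | Path,
    boundary_path: str | Path | None = None,
) -> None:
    """Write both bands (and optional boundary mask) of a pair as GeoTIFFs."""
    write_geotiff(lst_path, pair.lst, pair.pixel_size_m, pair.origin, pair.crs_id)
    write_geotiff(
        canopy_path, pair.canopy, pair.canopy_pixel_size_m, pair.origin,
        pair.crs_id, binary=pair.canopy_is_binary,
    )
    if boundary_path is not None and pair.boundary_mask is not None:
        write_geotiff(
            boundary_path, pair.boundary_mask.astype(float), pair.pixel_size_m,
            pair.origin, pair.crs_id, binary=True,
        )


def _is_binary(values: np.ndarray) -> bool:
    finite = values[np.isfinite(values)]
    return finite.size > 0 and np.all(np.isin(finite, (0.0, 1.0)))


def load_raster_pair(
    lst_path: str | Path,
    canopy_path: str | Path,
    boundary_path: str | Path | None = None,
) -> RasterPair:
    """Load, validate and co-register an LST / canopy GeoTIFF pair.

    The canopy raster is auto-detected as binary when its finite values are
    all in {0, 1}; otherwise it must be fractional cover in [0, 1] at the
    base resolution. The base-to-canopy resolution ratio must be an exact
    integer and footprints must agree to within half a base pixel.
    """
    lst = read_geotiff(lst_path)
    can = read_geotiff(canopy_path)

    base_px = lst["pixel_size_m"]
    ratio = base_px / can["pixel_size_m"]
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise ResolutionRatioError(
            f"base pixel {base_px} m is not an integer multiple of canopy pixel "
            f"{can['pixel_size_m']} m (ratio {ratio:.6g})"
        )
    ratio = int(round(ratio))
    logger.info("canopy/LST resolution ratio: %d", ratio)

    half_px = base_px / 2.0
    if (abs(lst["origin"][0] - can["origin"][0]) > half_px
            or abs(lst["origin"][1] - can["origin"][1]) > half_px):
        raise AlignmentError(
            f"raster origins differ by more than half a base pixel: "
            f"{lst['origin']} vs {can['origin']}"
        )
    lr, lc = lst["data"].shape
    cr, cc = can["data"].shape
    if abs(cr / ratio - lr) * base_px > half_px or abs(cc / ratio - lc) * base_px > half_px:
        raise AlignmentError(
            f"raster footprints differ: LST {lr}x{lc} at {base_px} m vs "
            f"canopy {cr}x{cc} at {can['pixel_size_m']} m"
        )
    if cr != lr * ratio or cc != lc * ratio:
        raise ResolutionRatioError(
            f"canopy grid {cr}x{cc} is not exactly {ratio}x the LST grid {lr}x{lc}"
        )

    canopy_is_binary = _is_binary(can["data"])
    if not canopy_is_binary:
        if ratio != 1:
            raise ResolutionRatioError(
                "non-binary (fractional) canopy must be at the base resolution"
            )
        finite = can["data"][np.isfinite(can["data"])]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise CoverRangeError(
                f"fractional cover outside [0, 1]: "
                f"[{finite.min():.4g}, {finite.max():.4g}]"
            )

    boundary = None
    if boundary_path is not None:
        b = read_geotiff(boundary_path)
        if b["data"].shape != lst["data"].shape:
            raise AlignmentError("boundary mask grid must match the LST grid")
        boundary = np.nan_to_num(b["data"], nan=0.0) > 0.5

    return RasterPair(
        lst=lst["data"],
        canopy=can["data"],
        pixel_size_m=base_px,
        origin=lst["origin"],
        crs_id=lst["crs_id"],
        canopy_is_binary=canopy_is_binary,
        fine_factor=ratio,
        boundary_mask=boundary,
    )


def coarsen_canopy(pair: RasterPair, max_nodata_fraction: float = 0.5) -> RasterPair:
    """Reduce a fine binary canopy to fractional cover at base resolution.

    Each base cell's cover is the fraction of its valid fine pixels equal
    to 1; base cells with more than ``max_nodata_fraction`` of their fine
    pixels missing become nodata. A pair already holding fractional cover
    at base resolution is returned unchanged.
    """
    if not pair.canopy_is_binary:
        if pair.fine_factor == 1:
            return pair
        raise ValidationError("fractional canopy must already be at base resolution")
    f = pair.fine_factor
    rows, cols = pair.lst.shape
    blocks = pair.canopy.reshape(rows, f, cols, f)
    valid = np.isfinite(blocks)
    n_valid = valid.sum(axis=(1, 3))
    ones = np.nansum(np.where(valid, blocks, 0.0), axis=(1, 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        cover = np.where(n_valid > 0, ones / np.maximum(n_valid, 1), np.nan)
    too_sparse = n_valid < (1.0 - max_nodata_fraction) * f * f
    cover = np.where(too_sparse, np.nan, cover)
    return replace(
        pair, canopy=cover, canopy_is_binary=False, fine_factor=1,
    )
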