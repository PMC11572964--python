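"""GeoTIFF round-trips, pair validation, and canopy coarsening."""

import numpy as np
import pytest

from coolscale.errors import AlignmentError, CoverRangeError, ResolutionRatioError
from coolscale.raster import (
    RasterPair,
    coarsen_canopy,
    load_raster_pair,
    read_geotiff,
    write_geotiff,
    write_raster_pair,
)
from coolscale.synthetic import RasterSimConfig, simulate_raster_pair


def write_pair(tmp_path, pair):
    lst, can = tmp_path / "lst.tif", tmp_path / "canopy.tif"
    write_raster_pair(pair, lst, can)
    return lst, can


class TestGeoTiffIO:
    def test_float_round_trip(self, tmp_path, rng):
        data = rng.normal(30, 3, (15, 20)).astype(np.float32).astype(float)
        data[0, 0] = np.nan
        write_geotiff(tmp_path / "x.tif", data, 120.0, origin=(5000.0, 41000.0),
                      crs_id="EPSG:32618")
        back = read_geotiff(tmp_path / "x.tif")
        np.testing.assert_array_equal(back["data"], data)
        assert back["pixel_size_m"] == 120.0
        assert back["origin"] == (5000.0, 41000.0)
        assert back["crs_id"] == "EPSG:32618"

    def test_binary_round_trip_with_nodata(self, tmp_path, rng):
        data = (rng.random((8, 8)) > 0.5).astype(float)
        data[3, 3] = np.nan
        write_geotiff(tmp_path / "b.tif", data, 1.0, binary=True)
        back = read_geotiff(tmp_path / "b.tif")
        np.testing.assert_array_equal(back["data"], data)
        assert back["dtype"] == np.uint8

    def test_simulated_pair_round_trips(self, tmp_path):
        """load(write(x)) == x for grids, transforms and masks."""
        pair = simulate_raster_pair(RasterSimConfig(n_rows=10, n_cols=10, seed=1))
        lst, can = write_pair(tmp_path, pair)
        back = load_raster_pair(lst, can)
        np.testing.assert_allclose(back.lst, pair.lst, atol=1e-6)  # float32 storage
        np.testing.assert_array_equal(back.canopy, pair.canopy)
        assert back.pixel_size_m == pair.pixel_size_m
        assert back.origin == pair.origin


class TestLoadValidation:
    def test_fine_binary_ratio_accepted(self, tmp_path, rng, caplog):
        """1 m binary canopy under 120 m LST: ratio 120 accepted and logged."""
        import logging

        lst = rng.normal(30, 2, (3, 3))
        canopy = (rng.random((360, 360)) > 0.7).astype(float)
        write_geotiff(tmp_path / "lst.tif", lst, 120.0)
        write_geotiff(tmp_path / "can.tif", canopy, 1.0, binary=True)
        with caplog.at_level(logging.INFO, logger="coolscale.raster"):
            pair = load_raster_pair(tmp_path / "lst.tif", tmp_path / "can.tif")
        assert pair.fine_factor == 120
        assert pair.canopy_is_binary
        assert any("120" in rec.message for rec in caplog.records)

    def test_non_integer_ratio_rejected(self, tmp_path, rng):
        """50 m canopy under 120 m LST (ratio 2.4) is a design violation."""
        write_geotiff(tmp_path / "lst.tif", rng.normal(30, 2, (5, 5)), 120.0)
        write_geotiff(tmp_path / "can.tif", (rng.random((12, 12)) > 0.5).astype(float),
                      50.0, binary=True)
        with pytest.raises(ResolutionRatioError):
            load_raster_pair(tmp_path / "lst.tif", tmp_path / "can.tif")

    def test_origin_mismatch_rejected(self, tmp_path, rng):
        write_geotiff(tmp_path / "lst.tif", rng.normal(30, 2, (5, 5)), 120.0)
        write_geotiff(tmp_path / "can.tif", rng.random((5, 5)), 120.0,
                      origin=(400.0, 0.0))
        with pytest.raises(AlignmentError):
            load_raster_pair(tmp_path / "lst.tif", tmp_path / "can.tif")

    def test_cover_out_of_range_rejected(self, tmp_path, rng):
        write_geotiff(tmp_path / "lst.tif", rng.normal(30, 2, (5, 5)), 120.0)
        write_geotiff(tmp_path / "can.tif", rng.random((5, 5)) * 3, 120.0)
        with pytest.raises(CoverRangeError):
            load_raster_pair(tmp_path / "lst.tif", tmp_path / "can.tif")

    def test_boundary_mask_loaded(self, tmp_path, rng):
        write_geotiff(tmp_path / "lst.tif", rng.normal(30, 2, (4, 4)), 120.0)
        write_geotiff(tmp_path / "can.tif", rng.random((4, 4)), 120.0)
        mask = np.zeros((4, 4))
        mask[:2] = 1
        write_geotiff(tmp_path / "bnd.tif", mask, 120.0, binary=True)
        pair = load_raster_pair(tmp_path / "lst.tif", tmp_path / "can.tif",
                                tmp_path / "bnd.tif")
        assert pair.boundary_mask.sum() == 8


class TestCoarsenCanopy:
    def test_all_ones(self):
        pair = RasterPair(lst=np.zeros((4, 4)), canopy=np.ones((8, 8)),
                          pixel_size_m=120.0, canopy_is_binary=True, fine_factor=2)
        assert np.all(coarsen_canopy(pair).canopy == 1.0)

    def test_checkerboard_is_half(self):
        board = np.indices((8, 8)).sum(axis=0) % 2
        pair = RasterPair(lst=np.zeros((4, 4)), canopy=board.astype(float),
                          pixel_size_m=120.0, canopy_is_binary=True, fine_factor=2)
        assert np.all(coarsen_canopy(pair).canopy == 0.5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_per_cell_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        f, rows, cols = 5, 6, 7
        fine = (rng.random((rows * f, cols * f)) > 0.6).astype(float)
        fine[rng.random(fine.shape) < 0.05] = np.nan  # sparse nodata
        pair = RasterPair(lst=np.zeros((rows, cols)), canopy=fine,
                          pixel_size_m=100.0, canopy_is_binary=True, fine_factor=f)
        got = coarsen_canopy(pair).canopy
        for r in range(rows):
            for c in range(cols):
                block = fine[r * f:(r + 1) * f, c * f:(c + 1) * f]
                vals = block[np.isfinite(block)]
                expect = vals.mean() if len(vals) >= 0.5 * f * f else np.nan
                if np.isnan(expect):
                    assert np.isnan(got[r, c])
                else:
                    assert got[r, c] == pytest.approx(expect, abs=1e-12)

    def test_mostly_nodata_cell_becomes_nodata(self):
        fine = np.ones((4, 4))
        fine[:2, :2] = np.nan
        fine[0:1, 2:4] = np.nan  # top-right block: 2/4 nodata -> kept
        pair = RasterPair(lst=np.zeros((2, 2)), canopy=fine,
                          pixel_size_m=10.0, canopy_is_binary=True, fine_factor=2)
        out = coarsen_canopy(pair).canopy
        assert np.isnan(out[0, 0])        # 100% nodata
        assert out[0, 1] == 1.0           # 50% nodata: at threshold, kept
        assert out[1, 0] == 1.0 and out[1, 1] == 1.0

    @pytest.mark.parametrize("seed", [3, 4])
    def test_global_mean_preserved_without_nodata(self, seed):
        rng = np.random.default_rng(seed)
        fine = (rng.random((30, 30)) > 0.5).astype(float)
        pair = RasterPair(lst=np.zeros((10, 10)), canopy=fine,
                          pixel_size_m=90.0, canopy_is_binary=True, fine_factor=3)
        assert abs(coarsen_canopy(pair).canopy.mean() - fine.mean()) <= 1e-12

    def test_fractional_at_base_passes_through(self):
        pair = RasterPair(lst=np.zeros((3, 3)), canopy=np.full((3, 3), 0.4),
                          pixel_size_m=120.0)
        assert coarsen_canopy(pair) is pair
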