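"""Raster overlay, boxplot summaries, Welch's t-test, hotspot contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spatialphylo.env import (
    EnvironmentRaster,
    contrast_hotspots,
    extract_cell_values,
    group_stats,
    read_ascii_grid,
    welch_t_test,
)
from spatialphylo.grid import GridSpec


def _raster(data, cellsize=0.05, xll=0.0, yll=0.0, **kw):
    return EnvironmentRaster(np.asarray(data, float), xll, yll, cellsize, **kw)


class TestAsciiGrid:
    def test_round_trip(self, tmp_path):
        r = _raster([[1.0, 2.0], [3.0, np.nan]], name="elevation", units="m")
        p = tmp_path / "r.asc"
        r.write_ascii(p)
        back = read_ascii_grid(p, name="elevation", units="m")
        assert back.cellsize == pytest.approx(r.cellsize)
        assert back.xllcorner == pytest.approx(0.0)
        assert np.allclose(back.data, r.data, equal_nan=True)

    def test_header_validation(self, tmp_path):
        p = tmp_path / "bad.asc"
        p.write_text("ncols 2\n1 2\n")
        with pytest.raises(ValueError):
            read_ascii_grid(p)


class TestExtractCellValues:
    def test_mean_of_pixels(self):
        # one 0.1° cell covering a 2×2 pixel block
        r = _raster([[100.0, 200.0], [300.0, 400.0]])
        vals = extract_cell_values(r, [(0, 0)], GridSpec(0.1))
        assert vals.iloc[0] == pytest.approx(250.0)

    def test_nodata_excluded(self):
        r = _raster([[100.0, np.nan], [np.nan, np.nan]])
        vals = extract_cell_values(r, [(0, 0)], GridSpec(0.1))
        assert vals.iloc[0] == pytest.approx(100.0)

    def test_fully_nodata_cell_is_nan(self):
        r = _raster([[np.nan, np.nan], [np.nan, np.nan]])
        vals = extract_cell_values(r, [(0, 0)], GridSpec(0.1))
        assert np.isnan(vals.iloc[0])

    def test_no_overlap_error(self):
        r = _raster([[1.0]])
        with pytest.raises(ValueError, match="overlap"):
            extract_cell_values(r, [(50, 50)], GridSpec(0.1))

    def test_linearity_in_raster_values(self):
        rng = np.random.default_rng(3)
        data = rng.random((8, 8)) * 100
        r1 = _raster(data, cellsize=0.025)
        r3 = _raster(3 * data, cellsize=0.025)
        cells = [(0, 0), (1, 0), (1, 1)]
        v1 = extract_cell_values(r1, cells, GridSpec(0.1))
        v3 = extract_cell_values(r3, cells, GridSpec(0.1))
        assert np.allclose(v3.to_numpy(), 3 * v1.to_numpy(), equal_nan=True)


class TestGroupStats:
    def test_singleton(self):
        s = group_stats([186.0])
        assert s["median"] == 186.0
        assert s["max"] == 186.0
        assert s["n"] == 1

    def test_interpolated_quartiles(self):
        s = group_stats([1, 2, 3, 4, 5])
        assert s["median"] == 3
        assert s["q1"] == 2
        assert s["q3"] == 4

    def test_constant_data_whiskers(self):
        s = group_stats([5, 5, 5])
        assert s["whisker_low"] == 5
        assert s["whisker_high"] == 5

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=50)
        a = group_stats(x)
        b = group_stats(x[::-1])
        assert a == pytest.approx(b, rel=1e-12)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            group_stats([])


class TestWelch:
    def test_textbook_toy_groups(self):
        # {1,2,3} vs {2,4,6}: means 2 and 4, variances 1 and 4;
        # t = -2/sqrt(1/3 + 4/3), df via Welch–Satterthwaite
        t, df, p = welch_t_test([1, 2, 3], [2, 4, 6])
        assert t == pytest.approx(-1.549, abs=1e-3)
        assert df == pytest.approx(2.941, abs=1e-3)

    def test_identical_groups(self):
        t, df, p = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=10), rng.normal(1, 2, size=15)
        t1, df1, p1 = welch_t_test(a, b)
        t2, df2, p2 = welch_t_test(b, a)
        assert t1 == pytest.approx(-t2)
        assert df1 == pytest.approx(df2)
        assert p1 == pytest.approx(p2)

    def test_agrees_with_reference_implementation(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            a = rng.normal(0, rng.uniform(0.5, 3), size=rng.integers(2, 40))
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), size=rng.integers(2, 40))
            t, df, p = welch_t_test(a, b)
            ref = stats.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-9)
            assert df == pytest.approx(ref.df, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            welch_t_test([2.0, 2.0], [2.0, 2.0])

    def test_small_group_error(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])


class TestContrastHotspots:
    def _setup(self, classes):
        cells = [(i, 0) for i in range(len(classes))]
        rng = np.random.default_rng(21)
        # raster spanning all cells: 2 px per cell side at 0.05°
        data = rng.normal(100, 5, size=(2, 2 * len(cells)))
        r = _raster(data, cellsize=0.05, name="elevation", units="m")
        return pd.Series(classes), cells, [r]

    def test_planted_gap_detected(self):
        # neo cells drawn around 0, palaeo around 10: t-test must reject
        rng = np.random.default_rng(33)
        n = 40
        cells = [(i, 0) for i in range(2 * n)]
        classes = pd.Series(["neo"] * n + ["palaeo"] * n)
        data = np.concatenate([rng.normal(0, 1, n), rng.normal(10, 1, n)])
        r = _raster(np.tile(data, (2, 2)).reshape(2, -1, order="F")[:, : 2 * 2 * n],
                    cellsize=0.05, name="temperature", units="degC")
        # simpler: 2x(2*2n) raster where each cell's 4 pixels share its value
        pix = np.repeat(data, 2)
        r = _raster(np.vstack([pix, pix]), cellsize=0.05, name="temperature", units="degC")
        out = contrast_hotspots(classes, cells, [r], GridSpec(0.1))
        assert out[0].p < 1e-3
        assert out[0].t < 0  # neo colder than palaeo

    def test_missing_class_error(self):
        classes, cells, rasters = self._setup(["neo"] * 5)
        with pytest.raises(ValueError, match="palaeo"):
            contrast_hotspots(classes, cells, rasters, GridSpec(0.1))

    def test_constant_raster_error_path(self):
        classes, cells, _ = self._setup(["neo", "neo", "palaeo", "palaeo"])
        r = _raster(np.full((2, 8), 7.0), cellsize=0.05)
        with pytest.raises(ValueError, match="zero variance"):
            contrast_hotspots(classes, cells, [r], GridSpec(0.1))
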