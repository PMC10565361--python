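"""Environmental overlay: attach raster values (elevation, temperature,
rainfall) to classified grid cells and contrast cradles vs museums.

Rasters are ESRI ASCII grids in the same geographic CRS as the cell grid.
A cell's value is the mean of the raster pixels whose centres fall inside
it (nodata excluded); cells with no valid pixel are dropped downstream with
a logged count.  Group contrasts use five-number boxplot summaries and
Welch's unequal-variance t-test — the form identified by fractional degrees
of freedom — with the Welch–Satterthwaite approximation for d.f.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grid import GridSpec

__all__ = [
    "EnvironmentRaster",
    "read_ascii_grid",
    "extract_cell_values",
    "group_stats",
    "welch_t_test",
    "GroupComparison",
    "contrast_hotspots",
]


@dataclass
class EnvironmentRaster:
    """Rectangular raster; row 0 of ``data`` is the northernmost row."""

    data: np.ndarray
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata: float = -9999.0
    name: str = "value"
    units: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    def pixel_centres(self):
        """(x_centres, y_centres) with y ordered to match row 0 = north."""
        xs = self.xllcorner + (np.arange(self.ncols) + 0.5) * self.cellsize
        ys = self.yllcorner + (np.arange(self.nrows)[::-1] + 0.5) * self.cellsize
        return xs, ys

    def write_ascii(self, path):
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"ncols {self.ncols}\n")
            fh.write(f"nrows {self.nrows}\n")
            fh.write(f"xllcorner {self.xllcorner:.10g}\n")
            fh.write(f"yllcorner {self.yllcorner:.10g}\n")
            fh.write(f"cellsize {self.cellsize:.10g}\n")
            fh.write(f"NODATA_value {self.nodata:.10g}\n")
            out = np.where(np.isnan(self.data), self.nodata, self.data)
            for row in out:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def read_ascii_grid(path, name: str = "value", units: str = "") -> EnvironmentRaster:
    """Read an ESRI ASCII grid (.asc)."""
    header = {}
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value", "xllcenter", "yllcenter",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh)
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"ASCII grid header missing {key}")
    cellsize = header["cellsize"]
    if "xllcorner" in header:
        xll, yll = header["xllcorner"], header["yllcorner"]
    else:  # centre-registered variant
        xll = header["xllcenter"] - cellsize / 2
        yll = header["yllcenter"] - cellsize / 2
    data = np.atleast_2d(data)
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("ASCII grid data shape does not match header")
    nodata = header.get("nodata_value", -9999.0)
    data = np.where(data == nodata, np.nan, data)
    return EnvironmentRaster(data, xll, yll, cellsize, nodata, name=name, units=units)


def extract_cell_values(raster: EnvironmentRaster, cells, grid: GridSpec) -> pd.Series:
    """Mean raster value per cell (pixel centres inside the cell; nodata
    ignored).  Cells with no valid pixel get NaN."""
    xs, ys = raster.pixel_centres()
    res = grid.resolution
    values = {}
    any_overlap = False
    for cell in cells:
        x0, y0 = cell[0] * res, cell[1] * res
        ci = np.flatnonzero((xs >= x0) & (xs < x0 + res))
        ri = np.flatnonzero((ys >= y0) & (ys < y0 + res))
        if ci.size == 0 or ri.size == 0:
            values[cell] = np.nan
            continue
        any_overlap = True
        block = raster.data[np.ix_(ri, ci)]
        valid = block[~np.isnan(block)]
        values[cell] = float(valid.mean()) if valid.size else np.nan
    if not any_overlap:
        raise ValueError("raster does not overlap the cell grid")
    idx = pd.Index(list(values.keys()), dtype=object)  # keep tuples atomic
    return pd.Series(list(values.values()), index=idx, name=raster.name)


def group_stats(values) -> dict:
    """Boxplot five-number summary with 1.5×IQR whiskers clipped to data."""
    x = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if x.size == 0:
        raise ValueError("no values")
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation (type 7)
    iqr = q3 - q1
    lo_candidates = x[x >= q1 - 1.5 * iqr]
    hi_candidates = x[x <= q3 + 1.5 * iqr]
    return {
        "n": int(x.size),
        "mean": float(x.mean()),
        "variance": float(x.var(ddof=1)) if x.size > 1 else 0.0,
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(lo_candidates.min()),
        "whisker_high": float(hi_candidates.max()),
        "min": float(x.min()),
        "max": float(x.max()),
    }


def welch_t_test(group_a, group_b):
    """Welch's unequal-variance t-test.

    t = (x̄_a − x̄_b) / sqrt(s²_a/n_a + s²_b/n_b); d.f. by the
    Welch–Satterthwaite approximation; two-sided p from Student's t.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both groups have zero variance; t undefined")
    sa, sb = va / a.size, vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


@dataclass
class GroupComparison:
    """Cradle-vs-museum contrast for one environmental variable."""

    variable: str
    units: str
    stats_neo: dict
    stats_palaeo: dict
    t: float
    df: float
    p: float
    n_missing: int = 0

    def as_row(self) -> dict:
        return {
            "variable": self.variable,
            "units": self.units,
            "n_neo": self.stats_neo["n"],
            "n_palaeo": self.stats_palaeo["n"],
            "median_neo": self.stats_neo["median"],
            "median_palaeo": self.stats_palaeo["median"],
            "max_neo": self.stats_neo["max"],
            "max_palaeo": self.stats_palaeo["max"],
            "t": self.t,
            "df": self.df,
            "p": self.p,
            "n_missing": self.n_missing,
        }


def contrast_hotspots(
    classification: pd.Series,
    cells: list,
    rasters,
    grid: GridSpec,
) -> list:
    """One :class:`GroupComparison` per raster between neo and palaeo cells.

    ``classification`` is indexed like ``cells`` with values in
    {"neo", "palaeo", ...}.  Raises if either class is empty.
    """
    cls = np.asarray(classification, dtype=object)
    neo_cells = [c for c, k in zip(cells, cls) if k == "neo"]
    pal_cells = [c for c, k in zip(cells, cls) if k == "palaeo"]
    for name, group in (("neo", neo_cells), ("palaeo", pal_cells)):
        if len(group) < 2:
            raise ValueError(f"class {name} empty or too small for contrast")
    out = []
    for raster in rasters:
        vals = extract_cell_values(raster, list(cells), grid)
        v_neo = vals.reindex(pd.Index(neo_cells, dtype=object)).to_numpy(dtype=float)
        v_pal = vals.reindex(pd.Index(pal_cells, dtype=object)).to_numpy(dtype=float)
        missing = int(np.isnan(v_neo).sum() + np.isnan(v_pal).sum())
        v_neo = v_neo[~np.isnan(v_neo)]
        v_pal = v_pal[~np.isnan(v_pal)]
        t, df, p = welch_t_test(v_neo, v_pal)
        out.append(
            GroupComparison(
                variable=raster.name,
                units=raster.units,
                stats_neo=group_stats(v_neo),
                stats_palaeo=group_stats(v_pal),
                t=t,
                df=df,
                p=p,
                n_missing=missing,
            )
        )
    return out
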