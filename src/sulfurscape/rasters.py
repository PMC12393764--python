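"""Raster grids, covariate stacks and the geographic primitives of the pipeline.

Grids are plain 2-D numpy arrays with an upper-left-corner origin; row 0 is
the northern edge and rows increase southward. Two coordinate regimes are
supported, declared through ``crs_id``:

* ``"EPSG:4326"`` — geographic WGS84, cell size in decimal degrees,
  distances by haversine on a sphere of radius 6371 km;
* ``"local-km"`` — a planar kilometre grid (used by the synthetic world),
  distances Euclidean.

Cells are half-open: a point lying exactly on a cell edge belongs to the
cell to its north-west.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

EARTH_RADIUS_KM = 6371.0

#: the 21 environmental predictors of the covariate stack
STACK_VARIABLES = (
    "r.elevation", "r.bouger", "r.distance", "r.sr",
    "r.mat", "r.map", "r.ai", "r.pet", "r.ph", "r.clay", "r.cec",
    "r.bulk", "r.dust", "r.salt", "r.ssa", "r.ssaw", "r.fert",
    "r.age", "r.minage_geol", "r.meanage_geol", "r.maxage_geol",
)

#: layers resampled by nearest neighbour (categorical / age attributes)
CATEGORICAL_VARIABLES = ("r.age", "r.minage_geol", "r.meanage_geol", "r.maxage_geol")


@dataclass
class RasterGrid:
    """A single co-registered raster layer.

    Parameters
    ----------
    values : 2-D float array. ``nodata`` marks invalid cells.
    origin : (x, y) of the upper-left *corner* of the grid.
    cell_size : cell edge length, degrees or km depending on ``crs_id``.
    """

    values: np.ndarray
    origin: tuple[float, float]
    cell_size: float
    crs_id: str = "EPSG:4326"
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if not np.isfinite(self.cell_size) or self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def valid_mask(self) -> np.ndarray:
        return (self.values != self.nodata) & np.isfinite(self.values)

    def same_grid(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin)
            and math.isclose(self.cell_size, other.cell_size)
            and self.crs_id == other.crs_id
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of all cell centres, each shaped like values."""
        x0, y0 = self.origin
        cols = x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        rows = y0 - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(cols, rows)

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Cell (row, col) containing the point; edge points go north-west."""
        x0, y0 = self.origin
        col = math.ceil((x - x0) / self.cell_size) - 1
        row = math.ceil((y0 - y) / self.cell_size) - 1
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"point ({x}, {y}) outside raster extent")
        return row, col

    def center_of(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + (col + 0.5) * self.cell_size, y0 - (row + 0.5) * self.cell_size)

    def copy_with(self, values: np.ndarray) -> "RasterGrid":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class CovariateStack:
    """Named co-registered raster layers sharing one grid definition."""

    layers: dict[str, RasterGrid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        grids = list(self.layers.values())
        for g in grids[1:]:
            if not g.same_grid(grids[0]):
                raise ValueError("all stack layers must share one grid")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def grid(self) -> RasterGrid:
        return next(iter(self.layers.values()))

    def __getitem__(self, name: str) -> RasterGrid:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers


# ---------------------------------------------------------------------------
# ASCII-grid I/O (ESRI .asc: a plain-text georeferenced raster format)
# ---------------------------------------------------------------------------

def write_ascii_grid(grid: RasterGrid, path) -> None:
    x0, y0 = grid.origin
    yll = y0 - grid.n_rows * grid.cell_size
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {float(x0)!r}\n")
        fh.write(f"yllcorner {float(yll)!r}\n")
        fh.write(f"cellsize {float(grid.cell_size)!r}\n")
        fh.write(f"NODATA_value {float(grid.nodata)!r}\n")
        fh.write(f"# crs {grid.crs_id}\n")
        for row in grid.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path) -> RasterGrid:
    header: dict[str, float] = {}
    crs_id = "EPSG:4326"
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
                header[key] = float(parts[1])
            elif parts[0] == "#" and len(parts) >= 3 and parts[1] == "crs":
                crs_id = parts[2]
            else:
                rows.append([float(v) for v in parts])
    missing = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"} - set(header)
    if missing:
        raise ValueError(f"raster header lacks georeference fields: {sorted(missing)}")
    values = np.array(rows, dtype=float)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (n_rows, n_cols):
        raise ValueError("raster body shape disagrees with header")
    cs = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + n_rows * cs)
    return RasterGrid(values, origin, cs, crs_id=crs_id,
                      nodata=header.get("nodata_value", -9999.0))


# ---------------------------------------------------------------------------
# Resampling and stack loading
# ---------------------------------------------------------------------------

def resample(src: RasterGrid, target: RasterGrid, method: str = "bilinear") -> RasterGrid:
    """Resample ``src`` onto the grid of ``target``; nodata propagates."""
    if src.same_grid(target):
        return src.copy_with(src.values)
    if src.crs_id != target.crs_id:
        raise ValueError(f"CRS not convertible: {src.crs_id} vs {target.crs_id}")
    xs, ys = target.cell_centers()
    # fractional source indices of the target cell centres
    ci = (xs - src.origin[0]) / src.cell_size - 0.5
    ri = (src.origin[1] - ys) / src.cell_size - 0.5
    vals = np.where(src.valid_mask(), src.values, np.nan)
    order = 1 if method == "bilinear" else 0
    out = ndimage.map_coordinates(vals, [ri, ci], order=order,
                                  mode="nearest", cval=np.nan)
    out = np.where(np.isfinite(out), out, target.nodata)
    return RasterGrid(out, target.origin, target.cell_size,
                      crs_id=target.crs_id, nodata=target.nodata)


def load_stack(paths: dict[str, str], target_grid: RasterGrid) -> CovariateStack:
    """Read rasters and co-register them on ``target_grid``.

    Continuous layers are resampled bilinearly; age/categorical layers
    (``CATEGORICAL_VARIABLES``) by nearest neighbour.
    """
    layers = {}
    for name, path in paths.items():
        src = read_ascii_grid(path)
        method = "nearest" if name in CATEGORICAL_VARIABLES else "bilinear"
        layers[name] = resample(src, target_grid, method=method)
    return CovariateStack(layers)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def _haversine_km(lon1, lat1, lon2, lat2):
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def point_distance_km(grid: RasterGrid, x1, y1, x2, y2):
    if grid.crs_id == "local-km":
        return np.hypot(np.asarray(x2) - x1, np.asarray(y2) - y1)
    return _haversine_km(x1, y1, x2, y2)


def sea_mask(elev_or_mask: RasterGrid, sea_level: float = 0.0) -> np.ndarray:
    """Sea cells: valid cells at or below ``sea_level``."""
    return elev_or_mask.valid_mask() & (elev_or_mask.values <= sea_level)


def distance_to_coast(elev_or_mask: RasterGrid, sea_level: float = 0.0) -> RasterGrid:
    """Great-circle (or planar, for km grids) distance to the nearest sea cell.

    Every land cell holds the distance in km to the nearest sea-cell
    *centre*; sea cells hold 0. Ties are irrelevant for the distance value.
    """
    sea = sea_mask(elev_or_mask, sea_level)
    if not sea.any():
        raise ValueError("grid contains no sea cells")
    xs, ys = elev_or_mask.cell_centers()
    if elev_or_mask.crs_id == "local-km":
        # exact Euclidean distance between cell centres in index space
        dist = ndimage.distance_transform_edt(~sea) * elev_or_mask.cell_size
    else:
        sx, sy = xs[sea], ys[sea]
        dist = np.zeros(elev_or_mask.shape)
        land_idx = np.flatnonzero(~sea.ravel())
        fx, fy = xs.ravel(), ys.ravel()
        chunk = 2000
        flat = dist.ravel()
        for start in range(0, land_idx.size, chunk):
            idx = land_idx[start:start + chunk]
            d = _haversine_km(fx[idx][:, None], fy[idx][:, None], sx[None, :], sy[None, :])
            flat[idx] = d.min(axis=1)
        dist = flat.reshape(elev_or_mask.shape)
    out = np.where(elev_or_mask.valid_mask(), dist, elev_or_mask.nodata)
    return elev_or_mask.copy_with(out)


def nearest_sea_cell(elev_or_mask: RasterGrid, row: int, col: int,
                     sea_level: float = 0.0) -> tuple[int, int]:
    """Nearest sea cell to (row, col) by centre distance; ties row-major."""
    sea = sea_mask(elev_or_mask, sea_level)
    if not sea.any():
        raise ValueError("grid contains no sea cells")
    xs, ys = elev_or_mask.cell_centers()
    x, y = elev_or_mask.center_of(row, col)
    d = point_distance_km(elev_or_mask, x, y, xs[sea], ys[sea])
    srows, scols = np.nonzero(sea)
    best = np.argmin(d)  # argmin on row-major-ordered sea cells breaks ties
    return int(srows[best]), int(scols[best])


def supercover_line(r0: int, c0: int, r1: int, c1: int) -> list[tuple[int, int]]:
    """All cells intersected by the segment joining two cell centres.

    Grid traversal stepping through every crossed cell boundary; when the
    segment passes exactly through a cell corner both adjacent cells are
    included (supercover convention).
    """
    cells = [(r0, c0)]
    dr, dc = r1 - r0, c1 - c0
    n_steps = max(abs(dr), abs(dc))
    if n_steps == 0:
        return cells
    # parametrise p(t) = (r0 + t*dr, c0 + t*dc), t in [0, 1]
    ts: list[float] = []
    if dr != 0:
        for k in range(1, abs(dr) + 1):
            ts.append((k - 0.5) / abs(dr))
    if dc != 0:
        for k in range(1, abs(dc) + 1):
            ts.append((k - 0.5) / abs(dc))
    sr = 1 if dr > 0 else -1
    sc = 1 if dc > 0 else -1
    r, c = r0, c0
    eps = 1e-12
    ts.sort()
    i = 0
    while i < len(ts):
        t = ts[i]
        # does this crossing hit a row boundary, a column boundary, or both?
        cross_r = dr != 0 and any(abs(t - (k - 0.5) / abs(dr)) < eps
                                  for k in range(1, abs(dr) + 1))
        cross_c = dc != 0 and any(abs(t - (k - 0.5) / abs(dc)) < eps
                                  for k in range(1, abs(dc) + 1))
        if cross_r and cross_c:  # corner: include both neighbours
            cells.append((r + sr, c))
            cells.append((r, c + sc))
            r += sr
            c += sc
            # skip the duplicate entry of the simultaneous crossing
            if i + 1 < len(ts) and abs(ts[i + 1] - t) < eps:
                i += 1
        elif cross_r:
            r += sr
        else:
            c += sc
        cells.append((r, c))
        i += 1
    return cells


def classify_site(site, elev: RasterGrid, dist: RasterGrid,
                  threshold_km: float = 30.0, barrier_m: float = 500.0,
                  sea_level: float = 0.0) -> str:
    """Coastal/inland rule: within ``threshold_km`` of the coast and no cell
    above ``barrier_m`` on the straight transect to the nearest sea cell.

    ``site`` needs ``lon``/``lat`` attributes (or a mapping with those keys).
    The transect includes the site's own cell.
    """
    lon = site["lon"] if isinstance(site, dict) else site.lon
    lat = site["lat"] if isinstance(site, dict) else site.lat
    row, col = elev.index_of(lon, lat)
    if not elev.valid_mask()[row, col]:
        raise ValueError(f"site at ({lon}, {lat}) lies on nodata elevation")
    if dist.values[row, col] >= threshold_km:
        return "inland"
    sr_, sc_ = nearest_sea_cell(elev, row, col, sea_level)
    transect = supercover_line(row, col, sr_, sc_)
    elevs = [elev.values[r, c] for r, c in transect if elev.valid_mask()[r, c]]
    if elevs and max(elevs) >= barrier_m:
        return "inland"
    return "coastal"


# ---------------------------------------------------------------------------
# Point extraction and the regression matrix
# ---------------------------------------------------------------------------

def extract_at(stack: CovariateStack, sites: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Covariate vector of the cell containing each site.

    ``sites`` needs columns site_id, lon, lat. Returns (table indexed by
    site_id, warning messages for nodata hits). A site outside the stack
    extent raises, naming the site.
    """
    grid = stack.grid
    records = {}
    warnings_log: list[str] = []
    for _, s in sites.iterrows():
        try:
            row, col = grid.index_of(s["lon"], s["lat"])
        except IndexError as exc:
            raise ValueError(f"site {s['site_id']} outside stack extent") from exc
        vec = {}
        for name, layer in stack.layers.items():
            v = layer.values[row, col]
            if not layer.valid_mask()[row, col]:
                vec[name] = np.nan
                warnings_log.append(f"site {s['site_id']}: nodata in layer {name}")
            else:
                vec[name] = v
        records[s["site_id"]] = vec
    return pd.DataFrame.from_dict(records, orient="index"), warnings_log


def build_matrix(samples: pd.DataFrame, sites: pd.DataFrame,
                 stack: CovariateStack) -> pd.DataFrame:
    """Regression matrix: one row per sample with a δ³⁴S response.

    Columns: site_id, d34S (response) and one column per stack layer.
    Rows whose site has any absent predictor are dropped with a warning
    naming the offending layers.
    """
    covars, logs = extract_at(stack, sites)
    for msg in logs:
        warnings.warn(msg, stacklevel=2)
    usable = samples[samples["d34S"].notna()].copy()
    rows = []
    for _, s in usable.iterrows():
        if s["site_id"] not in covars.index:
            warnings.warn(f"sample {s['sample_id']}: site {s['site_id']} has no covariates",
                          stacklevel=2)
            continue
        vec = covars.loc[s["site_id"]]
        if vec.isna().any():
            bad = list(vec.index[vec.isna()])
            warnings.warn(f"sample {s['sample_id']} dropped: nodata in {bad}", stacklevel=2)
            continue
        rows.append({"sample_id": s["sample_id"], "site_id": s["site_id"],
                     "d34S": s["d34S"], **vec.to_dict()})
    if not rows:
        raise ValueError("no usable rows for the regression matrix")
    return pd.DataFrame(rows)
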