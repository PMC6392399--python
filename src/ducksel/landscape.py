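"""Classified landscape raster: reclassification and covariate extraction.

Coordinates are planar (projected, e.g. UTM) and expressed in kilometres;
raster resolution is given in metres. The raster is stored row-major with
row 0 at the northern edge, matching the ESRI ASCII grid convention used
for input/output. Cell membership in any query region is decided by
cell-center containment in half-open intervals to avoid double counting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely

from .catalog import (
    NODATA_CODE,
    OTHER_CODE,
    OWNERSHIP_PRIORITY,
    VariableCatalog,
)


@dataclass
class LandscapeGrid:
    """Integer raster of covariate (or source land-class) codes.

    ``origin_x``/``origin_y`` are the coordinates (km) of the lower-left
    corner of the lower-left cell; ``resolution_m`` is the square cell side
    in metres. ``codes[0, 0]`` is the north-west cell.
    """

    origin_x: float
    origin_y: float
    resolution_m: float
    codes: np.ndarray
    catalog: VariableCatalog | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.resolution_m <= 0:
            raise ValueError("resolution must be positive")
        self.codes = np.asarray(self.codes, dtype=np.int32)
        if self.codes.ndim != 2 or self.codes.size == 0:
            raise ValueError("raster must be a non-empty 2-D integer array")

    @property
    def res_km(self) -> float:
        return self.resolution_m / 1000.0

    @property
    def n_rows(self) -> int:
        return self.codes.shape[0]

    @property
    def n_cols(self) -> int:
        return self.codes.shape[1]

    @property
    def cell_area_ha(self) -> float:
        return self.resolution_m**2 / 10_000.0

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in km."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.n_cols * self.res_km,
            self.origin_y + self.n_rows * self.res_km,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Center coordinates (km) as broadcastable (x of cols, y of rows)."""
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.res_km
        ys = self.origin_y + (self.n_rows - np.arange(self.n_rows) - 0.5) * self.res_km
        return xs, ys

    def contains(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.bounds
        return xmin <= x < xmax and ymin <= y < ymax

    # --- ESRI ASCII grid I/O (text; cellsize in km to match coordinates) ---

    def to_ascii(self, path: str | Path) -> None:
        header = (
            f"ncols {self.n_cols}\n"
            f"nrows {self.n_rows}\n"
            f"xllcorner {self.origin_x!r}\n"
            f"yllcorner {self.origin_y!r}\n"
            f"cellsize {self.res_km!r}\n"
            f"NODATA_value {NODATA_CODE}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.codes, fmt="%d")

    @classmethod
    def from_ascii(cls, path: str | Path, catalog: VariableCatalog | None = None) -> "LandscapeGrid":
        meta: dict[str, float] = {}
        with open(path) as fh:
            lines = fh.readlines()
        i = 0
        while i < len(lines):
            parts = lines[i].split()
            if len(parts) == 2 and not _is_number_row(parts):
                meta[parts[0].lower()] = float(parts[1])
                i += 1
            else:
                break
        codes = np.loadtxt(lines[i:], dtype=np.int32, ndmin=2)
        return cls(
            origin_x=meta["xllcorner"],
            origin_y=meta["yllcorner"],
            resolution_m=meta["cellsize"] * 1000.0,
            codes=codes,
            catalog=catalog,
        )


def _is_number_row(parts: list[str]) -> bool:
    try:
        [int(p) for p in parts]
    except ValueError:
        return False
    return True


# ---------------------------------------------------------------------------
# Reclassification
# ---------------------------------------------------------------------------

#: default mapping of source land-class codes in a base raster
DEFAULT_BASE_CLASSES = {1: "agriculture", 2: "water", 3: "marsh", 4: "other"}


def rasterize_ownership(
    grid: LandscapeGrid,
    ownership: list[tuple[str, shapely.Geometry]],
) -> np.ndarray:
    """Ownership label per raster cell by cell-center containment.

    Overlaps are resolved by a fixed priority (CWS > Walpole > MICH-DNR >
    Michigan > private > public); uncovered cells get the empty string.
    """
    xs, ys = grid.cell_centers()
    xx, yy = np.meshgrid(xs, ys)
    labels = np.full(grid.codes.shape, "", dtype=object)
    rank = {name: i for i, name in enumerate(OWNERSHIP_PRIORITY)}
    for name, geom in sorted(ownership, key=lambda p: rank[p[0]], reverse=True):
        # lower-priority first so higher priority overwrites
        shapely.prepare(geom)
        inside = shapely.contains_xy(geom, xx, yy)
        labels[inside] = name
    return labels


def reclassify(
    base: LandscapeGrid,
    ownership: list[tuple[str, shapely.Geometry]] | np.ndarray,
    feed_sites: np.ndarray | None,
    catalog: VariableCatalog,
    *,
    base_classes: dict[int, str] | None = None,
    flooded_parcels: list[shapely.Geometry] | None = None,
    buffer_km: float = 0.4,
) -> LandscapeGrid:
    """Cross a source land-class raster with ownership into covariate codes.

    Source classes are grouped into the foraging classes of ``catalog`` and
    crossed with the ownership stratum of each cell. Agriculture cells inside
    a flooded parcel become flooded agriculture. Every cell whose center lies
    within ``buffer_km`` (Euclidean) of a feed site is recoded to the
    supplemental-feeding-refuge variable of its ownership — the buffer changes
    the resource class only, never the ownership. Crossings with no catalog
    variable map to OTHER; cells without ownership coverage become NODATA.

    ``ownership`` is either a list of (name, polygon) pairs or a pre-computed
    per-cell label array. An already-crossed raster (all codes registered in
    ``catalog``) passes through unchanged, making the operation idempotent.
    """
    base_classes = dict(DEFAULT_BASE_CLASSES if base_classes is None else base_classes)
    if base.codes.size == 0:
        raise ValueError("empty raster")

    # an already-crossed grid (it carries a catalog and every code is
    # registered) passes through unchanged: reclassification is idempotent
    if base.catalog is not None:
        registered = set(base.catalog.codes) | {OTHER_CODE, NODATA_CODE}
        if set(np.unique(base.codes)) <= registered:
            return LandscapeGrid(
                base.origin_x, base.origin_y, base.resolution_m, base.codes.copy(), base.catalog
            )

    known = set(base_classes) | {NODATA_CODE}
    bad = set(np.unique(base.codes)) - known
    if bad:
        raise ValueError(f"unknown source class code(s): {sorted(bad)}")

    if isinstance(ownership, np.ndarray):
        own_labels = ownership
    else:
        own_labels = rasterize_ownership(base, ownership)

    xs, ys = base.cell_centers()
    xx, yy = np.meshgrid(xs, ys)

    # resource class per cell
    rclass = np.full(base.codes.shape, "", dtype=object)
    for code, name in base_classes.items():
        rclass[base.codes == code] = name

    if flooded_parcels:
        for parcel in flooded_parcels:
            inside = shapely.contains_xy(parcel, xx, yy)
            rclass[inside & (rclass == "agriculture")] = "flooded agriculture"

    if feed_sites is not None and len(feed_sites):
        sites = np.atleast_2d(np.asarray(feed_sites, dtype=float))
        xmin, ymin, xmax, ymax = base.bounds
        for sx, sy in sites:
            if not (xmin <= sx <= xmax and ymin <= sy <= ymax):
                raise ValueError(f"feed site ({sx}, {sy}) outside raster extent")
        near = np.zeros(base.codes.shape, dtype=bool)
        for sx, sy in sites:
            near |= (xx - sx) ** 2 + (yy - sy) ** 2 <= buffer_km**2
        rclass[near] = "supplemental feeding refuge"

    out = np.full(base.codes.shape, NODATA_CODE, dtype=np.int32)
    pairs = {
        (rc, ow): catalog.crossing_code(rc, ow)
        for rc in np.unique(rclass[rclass != ""])
        for ow in np.unique(own_labels[own_labels != ""])
    }
    for (rc, ow), code in pairs.items():
        out[(rclass == rc) & (own_labels == ow)] = code
    out[base.codes == NODATA_CODE] = NODATA_CODE
    return LandscapeGrid(base.origin_x, base.origin_y, base.resolution_m, out, catalog)


# ---------------------------------------------------------------------------
# Covariate extraction
# ---------------------------------------------------------------------------


def covariate_areas(
    grid: LandscapeGrid,
    square: tuple[float, float, float, float],
    catalog: VariableCatalog | None = None,
) -> tuple[np.ndarray, dict]:
    """Area (ha) of each catalog variable inside an axis-aligned square.

    ``square`` is (xmin, ymin, xmax, ymax) in km. A raster cell contributes
    its full area when its center falls in [xmin, xmax) x [ymin, ymax).
    Returns (areas aligned with catalog order, info) where info carries the
    OTHER/NODATA areas and a ``warn`` flag set when the square misses the
    raster extent entirely (all-zero vector).
    """
    catalog = catalog or grid.catalog
    if catalog is None:
        raise ValueError("a variable catalog is required")
    xmin, ymin, xmax, ymax = square
    res = grid.res_km
    # integer ranges of cols/rows whose centers fall inside the square
    c0 = int(np.ceil((xmin - grid.origin_x) / res - 0.5))
    c1 = int(np.ceil((xmax - grid.origin_x) / res - 0.5))  # exclusive
    # rows: center_y = origin_y + (n_rows - r - 0.5) * res
    r0 = int(np.ceil(grid.n_rows - (ymax - grid.origin_y) / res - 0.5))
    r1 = int(np.ceil(grid.n_rows - (ymin - grid.origin_y) / res - 0.5))  # exclusive
    c0, c1 = max(c0, 0), min(c1, grid.n_cols)
    r0, r1 = max(r0, 0), min(r1, grid.n_rows)
    areas = np.zeros(len(catalog))
    info = {"other_ha": 0.0, "nodata_ha": 0.0, "warn": False}
    if c0 >= c1 or r0 >= r1:
        info["warn"] = True
        warnings.warn("query square does not intersect the raster extent", stacklevel=2)
        return areas, info
    block = grid.codes[r0:r1, c0:c1]
    cell_ha = grid.cell_area_ha
    counts = np.bincount((block + 1).ravel(), minlength=max(catalog.codes) + 2)
    # shift by +1 so NODATA (-1) lands at index 0
    for i, code in enumerate(catalog.codes):
        areas[i] = counts[code + 1] * cell_ha
    info["nodata_ha"] = counts[NODATA_CODE + 1] * cell_ha
    info["other_ha"] = counts[OTHER_CODE + 1] * cell_ha
    if info["nodata_ha"] == block.size * cell_ha:
        info["warn"] = True
    return areas, info


def aggregate_covariates(
    grid: LandscapeGrid,
    origin: tuple[float, float],
    spacing_km: float,
    n_x: int,
    n_y: int,
    catalog: VariableCatalog | None = None,
) -> np.ndarray:
    """Per-variable area (ha) for every cell of a coarse analysis grid.

    One vectorised pass: each raster cell center is binned into the analysis
    cell that contains it. Returns an array of shape (n_y, n_x, n_vars + 2)
    where the trailing two planes are OTHER and NODATA area.
    """
    catalog = catalog or grid.catalog
    if catalog is None:
        raise ValueError("a variable catalog is required")
    ox, oy = origin
    xs, ys = grid.cell_centers()
    ix = np.floor((xs - ox) / spacing_km).astype(np.int64)
    iy = np.floor((ys - oy) / spacing_km).astype(np.int64)
    valid_x = (ix >= 0) & (ix < n_x)
    valid_y = (iy >= 0) & (iy < n_y)
    code_index = np.full(max(catalog.codes) + 2, -1, dtype=np.int64)
    for i, code in enumerate(catalog.codes):
        code_index[code + 1] = i
    code_index[OTHER_CODE + 1] = len(catalog)
    code_index[NODATA_CODE + 1] = len(catalog) + 1

    n_planes = len(catalog) + 2
    out = np.zeros((n_y, n_x, n_planes))
    rows = np.where(valid_y)[0]
    cols = np.where(valid_x)[0]
    if rows.size == 0 or cols.size == 0:
        return out
    sub = grid.codes[np.ix_(rows, cols)]
    ci = code_index[sub + 1]
    flat = (iy[rows][:, None] * n_x + ix[cols][None, :]) * n_planes + ci
    counts = np.bincount(flat.ravel(), minlength=n_y * n_x * n_planes)
    out[:] = counts.reshape(n_y, n_x, n_planes) * grid.cell_area_ha
    return out


# ---------------------------------------------------------------------------
# Vector-input helpers
# ---------------------------------------------------------------------------


def load_ownership_geojson(path: str | Path) -> list[tuple[str, shapely.Geometry]]:
    """Read ownership polygons from GeoJSON (property ``ownership``)."""
    with open(path) as fh:
        gj = json.load(fh)
    out = []
    for feat in gj["features"]:
        name = feat["properties"]["ownership"]
        out.append((name, shapely.geometry.shape(feat["geometry"])))
    return out


def dump_ownership_geojson(ownership: list[tuple[str, shapely.Geometry]], path: str | Path) -> None:
    feats = [
        {
            "type": "Feature",
            "properties": {"ownership": name},
            "geometry": json.loads(shapely.to_geojson(geom)),
        }
        for name, geom in ownership
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
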