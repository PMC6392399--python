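"""Discrete choice-set construction and design-matrix preparation.

The analysis grid tiles the study plane with square cells; the cell that
contains a retained GPS fix is the *used* resource unit and every in-extent
cell whose center lies within the availability radius of the used cell's
center is *available*. The radius defaults to the 97.5th percentile of
local-scale step lengths. Covariates (area in ha of each catalog variable)
are attached per unit, screened for pairwise correlation, and put on a
common scale by two-standard-deviation standardization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import VariableCatalog
from .landscape import LandscapeGrid, aggregate_covariates

DEFAULT_SPACING_KM = 2.12
DEFAULT_RADIUS_KM = 9.6
DEFAULT_QUANTILE = 0.975


# ---------------------------------------------------------------------------
# Grid
# ---------------------------------------------------------------------------


@dataclass
class ChoiceGrid:
    """Square analysis grid; cell (ix, iy) spans half-open intervals from the
    origin so every point maps to exactly one cell."""

    origin_x: float
    origin_y: float
    spacing_km: float
    n_x: int
    n_y: int

    def __post_init__(self) -> None:
        if self.spacing_km <= 0:
            raise ValueError("spacing must be positive")

    @classmethod
    def covering(cls, landscape: LandscapeGrid, spacing_km: float = DEFAULT_SPACING_KM) -> "ChoiceGrid":
        xmin, ymin, xmax, ymax = landscape.bounds
        n_x = int(np.ceil((xmax - xmin) / spacing_km))
        n_y = int(np.ceil((ymax - ymin) / spacing_km))
        return cls(xmin, ymin, spacing_km, n_x, n_y)

    def cell_of(self, x: float | np.ndarray, y: float | np.ndarray):
        ix = np.floor((np.asarray(x) - self.origin_x) / self.spacing_km).astype(np.int64)
        iy = np.floor((np.asarray(y) - self.origin_y) / self.spacing_km).astype(np.int64)
        return ix, iy

    def center(self, ix, iy) -> tuple[np.ndarray, np.ndarray]:
        return (
            self.origin_x + (np.asarray(ix) + 0.5) * self.spacing_km,
            self.origin_y + (np.asarray(iy) + 0.5) * self.spacing_km,
        )

    def in_bounds(self, ix, iy):
        return (np.asarray(ix) >= 0) & (np.asarray(ix) < self.n_x) & (np.asarray(iy) >= 0) & (
            np.asarray(iy) < self.n_y
        )

    def cell_id(self, ix, iy):
        return np.asarray(iy) * self.n_x + np.asarray(ix)

    def square(self, ix: int, iy: int) -> tuple[float, float, float, float]:
        x0 = self.origin_x + ix * self.spacing_km
        y0 = self.origin_y + iy * self.spacing_km
        return (x0, y0, x0 + self.spacing_km, y0 + self.spacing_km)


# ---------------------------------------------------------------------------
# Availability
# ---------------------------------------------------------------------------


def availability_radius(local_step_lengths_km, q: float = DEFAULT_QUANTILE) -> float:
    """q-quantile (linear interpolation between order statistics) of local
    step lengths; the unrounded value is used internally, reports round it to
    0.1 km."""
    lengths = np.asarray(local_step_lengths_km, dtype=float)
    if lengths.size < 2:
        raise ValueError("need at least two local steps to estimate the radius")
    return float(np.quantile(lengths, q, method="linear"))


def lattice_offsets(spacing_km: float, radius_km: float) -> np.ndarray:
    """Integer offsets (di, dj) of lattice cells whose centers lie within
    radius of a reference center, on an unbounded grid."""
    if spacing_km <= 0:
        raise ValueError("spacing must be positive")
    if radius_km < 0:
        raise ValueError("radius must be non-negative")
    m = int(np.floor(radius_km / spacing_km))
    di, dj = np.meshgrid(np.arange(-m, m + 1), np.arange(-m, m + 1))
    keep = (di**2 + dj**2) * spacing_km**2 <= radius_km**2
    return np.column_stack([di[keep], dj[keep]])


def count_available_cells(spacing_km: float, radius_km: float) -> int:
    """Maximum possible choice-set size for a given grid spacing and
    availability radius (the used cell counts itself)."""
    return len(lattice_offsets(spacing_km, radius_km))


# ---------------------------------------------------------------------------
# Choice sets
# ---------------------------------------------------------------------------


@dataclass
class ChoiceSetCollection:
    """Long-format choice sets: ``sets`` has one row per choice set,
    ``units`` one row per alternative (the used unit flagged 1)."""

    sets: pd.DataFrame
    units: pd.DataFrame
    var_names: list[str]

    def __len__(self) -> int:
        return len(self.sets)

    def stratum(self, season: str, diel: str) -> "ChoiceSetCollection":
        s = self.sets[(self.sets["season"] == season) & (self.sets["diel"] == diel)]
        u = self.units[self.units["set_id"].isin(s["set_id"])]
        return ChoiceSetCollection(s.reset_index(drop=True), u.reset_index(drop=True), self.var_names)

    def strata(self) -> list[tuple[str, str]]:
        pairs = self.sets[["season", "diel"]].drop_duplicates()
        return [tuple(r) for r in pairs.itertuples(index=False)]

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.units.to_csv(path, index=False)
        sidecar = {
            "var_names": self.var_names,
            "n_sets": len(self.sets),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
        self.sets.to_csv(path.with_name(path.stem + "_sets.csv"), index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ChoiceSetCollection":
        path = Path(path)
        units = pd.read_csv(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        sets = pd.read_csv(path.with_name(path.stem + "_sets.csv"))
        return cls(sets, units, sidecar["var_names"])


def build_choice_sets(
    fixes: pd.DataFrame,
    grid: ChoiceGrid,
    landscape: LandscapeGrid,
    radius_km: float = DEFAULT_RADIUS_KM,
    catalog: VariableCatalog | None = None,
) -> tuple[ChoiceSetCollection, int]:
    """One choice set per retained fix.

    The used unit is the grid cell containing the fix; alternatives are all
    in-extent cells (centers inside the landscape bounds) whose center lies
    within ``radius_km`` of the used cell's center. Fixes whose used cell is
    out of extent are dropped and counted (second return value).
    """
    if radius_km <= 0:
        raise ValueError("radius must be positive")
    catalog = catalog or landscape.catalog
    cov = aggregate_covariates(
        landscape, (grid.origin_x, grid.origin_y), grid.spacing_km, grid.n_x, grid.n_y, catalog
    )
    var_names = catalog.abbreviations
    offsets = lattice_offsets(grid.spacing_km, radius_km)

    # in-extent = cell center inside the landscape bounding box
    xmin, ymin, xmax, ymax = landscape.bounds
    ix_all, iy_all = np.meshgrid(np.arange(grid.n_x), np.arange(grid.n_y))
    cx, cy = grid.center(ix_all, iy_all)
    in_extent = (cx >= xmin) & (cx < xmax) & (cy >= ymin) & (cy < ymax)

    set_rows, unit_frames = [], []
    n_out = 0
    set_id = 0
    for fix in fixes.itertuples(index=False):
        ix, iy = grid.cell_of(fix.easting_km, fix.northing_km)
        ix, iy = int(ix), int(iy)
        if not (0 <= ix < grid.n_x and 0 <= iy < grid.n_y) or not in_extent[iy, ix]:
            n_out += 1
            continue
        alt_ix = ix + offsets[:, 0]
        alt_iy = iy + offsets[:, 1]
        ok = grid.in_bounds(alt_ix, alt_iy)
        alt_ix, alt_iy = alt_ix[ok], alt_iy[ok]
        ok2 = in_extent[alt_iy, alt_ix]
        alt_ix, alt_iy = alt_ix[ok2], alt_iy[ok2]
        used_mask = (alt_ix == ix) & (alt_iy == iy)
        order = np.argsort(~used_mask, kind="stable")  # used unit first
        alt_ix, alt_iy, used_mask = alt_ix[order], alt_iy[order], used_mask[order]
        covs = cov[alt_iy, alt_ix, : len(var_names)]
        frame = pd.DataFrame(covs, columns=var_names)
        frame.insert(0, "used", used_mask.astype(int))
        frame.insert(0, "cell_id", grid.cell_id(alt_ix, alt_iy))
        frame.insert(0, "set_id", set_id)
        unit_frames.append(frame)
        set_rows.append(
            (
                set_id,
                fix.animal_id,
                fix.timestamp,
                getattr(fix, "season", None),
                getattr(fix, "diel", None),
                int(grid.cell_id(ix, iy)),
                int(len(frame)),
            )
        )
        set_id += 1

    sets = pd.DataFrame(
        set_rows,
        columns=["set_id", "animal_id", "timestamp", "season", "diel", "used_cell", "n_alternatives"],
    )
    units = (
        pd.concat(unit_frames, ignore_index=True)
        if unit_frames
        else pd.DataFrame(columns=["set_id", "cell_id", "used", *var_names])
    )
    return ChoiceSetCollection(sets, units, var_names), n_out


# ---------------------------------------------------------------------------
# Correlation screening
# ---------------------------------------------------------------------------


def screen_correlation(
    rows: pd.DataFrame,
    threshold: float = 0.8,
    priority: list[str] | None = None,
) -> tuple[list[str], list[dict]]:
    """Greedy removal of the lower-priority member of each highly correlated
    pair (|Pearson r| >= threshold) until no offending pair remains.

    ``rows`` holds one column per variable over the union of a stratum's
    alternative rows; ``priority`` lists variables best-first (defaults to
    column order). Zero-variance columns are removed first.
    """
    if len(rows) < 2:
        raise ValueError("need at least two rows to screen correlations")
    variables = list(rows.columns)
    priority = priority or variables
    missing = set(variables) - set(priority)
    if missing:
        raise ValueError(f"priority list does not cover: {sorted(missing)}")
    rank = {v: i for i, v in enumerate(priority)}

    retained = list(variables)
    log: list[dict] = []
    for v in list(retained):
        if rows[v].nunique() <= 1:
            retained.remove(v)
            log.append({"removed": v, "with": None, "r": None, "reason": "zero variance"})

    while len(retained) >= 2:
        corr = rows[retained].corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        a, b = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        r = corr[a, b]
        if abs(r) < threshold:
            break
        va, vb = retained[a], retained[b]
        drop, keep = (va, vb) if rank[va] > rank[vb] else (vb, va)
        retained.remove(drop)
        log.append({"removed": drop, "with": keep, "r": float(r), "reason": "high correlation"})
    return retained, log


# ---------------------------------------------------------------------------
# 2-SD standardization
# ---------------------------------------------------------------------------


@dataclass
class StandardizationParams:
    var_names: list[str]
    mean: np.ndarray
    sd: np.ndarray  # sample SD (ddof=1)

    @property
    def excluded(self) -> list[str]:
        return [v for v, s in zip(self.var_names, self.sd) if s == 0]

    def transform(self, rows: pd.DataFrame) -> pd.DataFrame:
        sd = np.where(self.sd > 0, self.sd, np.inf)  # zero-SD columns -> 0
        return (rows[self.var_names] - self.mean) / (2.0 * sd)

    def inverse(self, z: pd.DataFrame) -> pd.DataFrame:
        return z[self.var_names] * (2.0 * self.sd) + self.mean


def standardize_2sd(
    rows: pd.DataFrame, params: StandardizationParams | None = None
) -> tuple[pd.DataFrame, StandardizationParams]:
    """(x - mean) / (2 SD) per column, putting continuous covariates on a
    scale comparable with binary predictors. Columns with zero SD are flagged
    via ``params.excluded`` and mapped to zero."""
    if params is None:
        params = StandardizationParams(
            var_names=list(rows.columns),
            mean=rows.to_numpy(dtype=float).mean(axis=0),
            sd=rows.to_numpy(dtype=float).std(axis=0, ddof=1),
        )
    return params.transform(rows), params
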