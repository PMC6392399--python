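"""Synthetic landscape and telemetry generator.

Everything the analysis consumes can be generated here: a patch-mosaic
land-class raster crossed with ownership strata, feed sites, and GPS-fix
trajectories whose local-scale moves are sequential draws from the mixed
conditional-logit model with known coefficients. The generator's defaults
mirror the study conditions: 57 animals, 6 or 8 fixes per day from late
August through 31 January, a 38.7 m raster, and a step-length mixture
dominated by fine-scale moves with rare (>25 km) relocations.

The simulator deliberately anchors availability on the *previous* used unit
(a movement process) while the analysis anchors on the destination, so
estimation is tested under the same asymmetry real data impose.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from shapely import voronoi_polygons

from .catalog import VariableCatalog, default_catalog
from .choiceset import ChoiceGrid, StandardizationParams, lattice_offsets
from .dcm import ChoiceData
from .landscape import DEFAULT_BASE_CLASSES, LandscapeGrid, reclassify

#: step-scale mixture matching the observed movement composition
DEFAULT_SCALE_PROBS = {"fine": 0.7232, "local": 0.2744, "relocation": 0.0024}

DEFAULT_MU_STAR = {
    "CWS-MARSH": 1.0,
    "PRI-SUPP": 0.8,
    "PRI-MARSH": 0.5,
    "PRI-WATER": 0.4,
    "PUB-MARSH": -0.5,
}


@dataclass
class SimConfig:
    seed: int = 0
    n_animals: int = 57
    fixes_per_day: tuple[int, ...] = (6, 8)
    start: date = date(2015, 8, 27)
    end: date = date(2016, 1, 31)
    # landscape
    n_rows: int = 800
    n_cols: int = 800
    resolution_m: float = 38.7
    class_freq: dict[str, float] = field(
        default_factory=lambda: {"agriculture": 0.50, "water": 0.33, "marsh": 0.07, "other": 0.10}
    )
    ownership_freq: dict[str, float] = field(
        default_factory=lambda: {
            "public": 0.30,
            "private": 0.40,
            "Walpole": 0.10,
            "CWS": 0.07,
            "MICH-DNR": 0.05,
            "Michigan": 0.08,
        }
    )
    mean_patch_area_km2: float = 0.5
    ownership_parcel_area_km2: float = 8.0
    n_feed_sites: int = 3
    n_flooded_parcels: int = 3
    flooded_parcel_side_km: float = 1.0
    # choice model
    spacing_km: float = 2.12
    radius_km: float = 9.6
    mu_star: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MU_STAR))
    sigma_star: float | dict[str, float] = 0.3
    scale_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SCALE_PROBS))
    fine_max_km: float = 0.33
    relocation_min_km: float = 25.0

    def __post_init__(self) -> None:
        total = sum(self.scale_probs.values())
        if not np.isclose(total, 1.0):
            raise ValueError("scale-mixture proportions must sum to 1")
        width = self.n_cols * self.resolution_m / 1000.0
        height = self.n_rows * self.resolution_m / 1000.0
        if min(width, height) < 2 * self.radius_km:
            raise ValueError("landscape extent too small to contain the availability radius")

    def mu_vector(self, catalog: VariableCatalog) -> np.ndarray:
        return np.array([self.mu_star.get(a, 0.0) for a in catalog.abbreviations])

    def sigma_vector(self, catalog: VariableCatalog) -> np.ndarray:
        if isinstance(self.sigma_star, dict):
            return np.array([self.sigma_star.get(a, 0.0) for a in catalog.abbreviations])
        return np.full(len(catalog), float(self.sigma_star))


@dataclass
class LandscapeBundle:
    landscape: LandscapeGrid  # crossed covariate raster
    base: LandscapeGrid  # source land classes
    catalog: VariableCatalog
    ownership: list[tuple[str, shapely.Geometry]]
    feed_sites: np.ndarray
    flooded_parcels: list[shapely.Geometry]


@dataclass
class GroundTruth:
    mu_star: np.ndarray
    sigma_star: np.ndarray
    beta: np.ndarray  # (animals, vars)
    var_names: list[str]
    animal_ids: list[str]
    chosen: pd.DataFrame  # animal_id, timestamp, cell_id of model-driven choices
    std_params: StandardizationParams

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mu_star": self.mu_star.tolist(),
            "sigma_star": self.sigma_star.tolist(),
            "beta": self.beta.tolist(),
            "var_names": self.var_names,
            "animal_ids": self.animal_ids,
            "chosen": self.chosen.assign(
                timestamp=self.chosen["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
            ).to_dict(orient="list"),
            "std_mean": self.std_params.mean.tolist(),
            "std_sd": self.std_params.sd.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        chosen = pd.DataFrame(d["chosen"])
        if len(chosen):
            chosen["timestamp"] = pd.to_datetime(chosen["timestamp"], utc=True)
        return cls(
            mu_star=np.array(d["mu_star"]),
            sigma_star=np.array(d["sigma_star"]),
            beta=np.array(d["beta"]),
            var_names=d["var_names"],
            animal_ids=d["animal_ids"],
            chosen=chosen,
            std_params=StandardizationParams(
                d["var_names"], np.array(d["std_mean"]), np.array(d["std_sd"])
            ),
        )


# ---------------------------------------------------------------------------
# Landscape generation
# ---------------------------------------------------------------------------


def _seed_counts(freq: dict[str, float], n: int) -> dict[str, int]:
    counts = {k: max(1, round(v * n)) for k, v in freq.items() if v > 0}
    return counts


def generate_landscape(cfg: SimConfig, catalog: VariableCatalog | None = None) -> LandscapeBundle:
    """Random patch mosaic of land classes crossed with Voronoi ownership
    parcels; feed sites fall in private ownership. Deterministic under seed."""
    rng = np.random.default_rng([cfg.seed % (2**31), 101])
    catalog = catalog or default_catalog()
    res_km = cfg.resolution_m / 1000.0
    width, height = cfg.n_cols * res_km, cfg.n_rows * res_km
    base_codes_by_name = {v: k for k, v in DEFAULT_BASE_CLASSES.items()}

    # --- land-class mosaic: nearest-seed (Voronoi) patches
    n_class_seeds = max(len(cfg.class_freq), int(width * height / cfg.mean_patch_area_km2))
    counts = _seed_counts(cfg.class_freq, n_class_seeds)
    seed_xy, seed_label = [], []
    for name, k in counts.items():
        pts = rng.uniform([0, 0], [width, height], size=(k, 2))
        seed_xy.append(pts)
        seed_label.extend([name] * k)
    seed_xy = np.vstack(seed_xy)
    xs = (np.arange(cfg.n_cols) + 0.5) * res_km
    ys = (cfg.n_rows - np.arange(cfg.n_rows) - 0.5) * res_km
    xx, yy = np.meshgrid(xs, ys)
    _, nearest = cKDTree(seed_xy).query(np.column_stack([xx.ravel(), yy.ravel()]))
    labels = np.asarray(seed_label, dtype=object)[nearest].reshape(cfg.n_rows, cfg.n_cols)
    codes = np.vectorize(base_codes_by_name.get)(labels).astype(np.int32)
    base = LandscapeGrid(0.0, 0.0, cfg.resolution_m, codes)

    # --- ownership parcels: clipped Voronoi polygons
    n_own_seeds = max(len(cfg.ownership_freq), int(width * height / cfg.ownership_parcel_area_km2))
    own_counts = _seed_counts(cfg.ownership_freq, n_own_seeds)
    own_xy, own_label = [], []
    for name, k in own_counts.items():
        pts = rng.uniform([0, 0], [width, height], size=(k, 2))
        own_xy.append(pts)
        own_label.extend([name] * k)
    own_xy = np.vstack(own_xy)
    box = shapely.box(0, 0, width, height)
    cells = voronoi_polygons(shapely.MultiPoint(own_xy), extend_to=box, ordered=True)
    ownership = [
        (own_label[i], geom.intersection(box)) for i, geom in enumerate(cells.geoms)
    ]

    # --- feed sites inside private parcels
    private = shapely.union_all([g for n, g in ownership if n == "private"])
    feed_sites = []
    while len(feed_sites) < cfg.n_feed_sites:
        cand = rng.uniform([0.05 * width, 0.05 * height], [0.95 * width, 0.95 * height])
        if private.is_empty or shapely.contains_xy(private, cand[0], cand[1]):
            feed_sites.append(cand)
    feed_sites = np.array(feed_sites)

    # --- flooded-agriculture parcels: squares centred in private land
    parcels = []
    half = cfg.flooded_parcel_side_km / 2
    tries = 0
    while len(parcels) < cfg.n_flooded_parcels and tries < 200:
        tries += 1
        c = rng.uniform([half, half], [width - half, height - half])
        if private.is_empty or shapely.contains_xy(private, c[0], c[1]):
            parcels.append(shapely.box(c[0] - half, c[1] - half, c[0] + half, c[1] + half))

    landscape = reclassify(
        base, ownership, feed_sites, catalog, flooded_parcels=parcels
    )
    return LandscapeBundle(landscape, base, catalog, ownership, feed_sites, parcels)


# ---------------------------------------------------------------------------
# Trajectory simulation
# ---------------------------------------------------------------------------


def _standardized_cell_covariates(
    bundle: LandscapeBundle, grid: ChoiceGrid
) -> tuple[np.ndarray, np.ndarray, StandardizationParams]:
    from .landscape import aggregate_covariates

    cov = aggregate_covariates(
        bundle.landscape, (grid.origin_x, grid.origin_y), grid.spacing_km, grid.n_x, grid.n_y,
        bundle.catalog,
    )[:, :, : len(bundle.catalog)]
    xmin, ymin, xmax, ymax = bundle.landscape.bounds
    ix, iy = np.meshgrid(np.arange(grid.n_x), np.arange(grid.n_y))
    cx, cy = grid.center(ix, iy)
    in_extent = (cx >= xmin) & (cx < xmax) & (cy >= ymin) & (cy < ymax)
    rows = cov[in_extent]
    mean = rows.mean(axis=0)
    sd = rows.std(axis=0, ddof=1)
    params = StandardizationParams(bundle.catalog.abbreviations, mean, sd)
    safe_sd = np.where(sd > 0, sd, np.inf)
    z = (cov - mean) / (2.0 * safe_sd)
    return z, in_extent, params


def simulate_trajectories(
    cfg: SimConfig, bundle: LandscapeBundle
) -> tuple[pd.DataFrame, GroundTruth]:
    """GPS-fix trajectories from the generative mixed-logit movement model.

    At each scheduled fix time an animal makes a fine move (< 0.33 km
    jitter), a rare relocation (> 25 km), or — with the local-scale
    probability — selects its next resource unit by conditional-logit
    probabilities over the cells within the availability radius of its
    current unit, using its own coefficients on globally 2-SD standardized
    covariates, then lands uniformly inside the chosen cell.
    """
    rng = np.random.default_rng([cfg.seed % (2**31), 202])
    catalog = bundle.catalog
    grid = ChoiceGrid.covering(bundle.landscape, cfg.spacing_km)
    z, in_extent, std_params = _standardized_cell_covariates(bundle, grid)
    offsets = lattice_offsets(cfg.spacing_km, cfg.radius_km)
    mu = cfg.mu_vector(catalog)
    sig = cfg.sigma_vector(catalog)
    animal_ids = [f"duck{i:03d}" for i in range(cfg.n_animals)]
    beta = mu + sig * rng.standard_normal((cfg.n_animals, len(catalog)))

    xmin, ymin, xmax, ymax = bundle.landscape.bounds
    center = np.array([(xmin + xmax) / 2, (ymin + ymax) / 2])
    scales = list(cfg.scale_probs)
    scale_p = np.array([cfg.scale_probs[s] for s in scales])

    in_cells = np.argwhere(in_extent)  # (iy, ix)
    records, chosen_records = [], []
    t0_base = datetime(cfg.start.year, cfg.start.month, cfg.start.day, tzinfo=timezone.utc)
    horizon = datetime(cfg.end.year, cfg.end.month, cfg.end.day, 23, 59, tzinfo=timezone.utc)

    for i, aid in enumerate(animal_ids):
        f = int(rng.choice(cfg.fixes_per_day))
        dt = timedelta(hours=24.0 / f)
        t = t0_base + timedelta(minutes=float(rng.uniform(0, 24 * 60)))
        iy0, ix0 = in_cells[rng.integers(len(in_cells))]
        pos = np.array(grid.center(int(ix0), int(iy0)), dtype=float)
        pos += rng.uniform(-0.4, 0.4, size=2) * grid.spacing_km
        while t <= horizon:
            records.append((aid, t, pos[0], pos[1]))
            kind = scales[rng.choice(len(scales), p=scale_p)]
            if kind == "fine":
                for _ in range(10):
                    theta = rng.uniform(0, 2 * np.pi)
                    r = rng.uniform(0.02, cfg.fine_max_km * 0.9)
                    cand = pos + r * np.array([np.cos(theta), np.sin(theta)])
                    if xmin <= cand[0] < xmax and ymin <= cand[1] < ymax:
                        pos = cand
                        break
            elif kind == "relocation":
                theta = rng.uniform(0, 2 * np.pi)
                r = rng.uniform(cfg.relocation_min_km + 1, cfg.relocation_min_km + 15)
                pos = pos + r * np.array([np.cos(theta), np.sin(theta)])
            else:  # local
                inside = xmin <= pos[0] < xmax and ymin <= pos[1] < ymax
                if inside:
                    ix, iy = grid.cell_of(pos[0], pos[1])
                    cand_ix = int(ix) + offsets[:, 0]
                    cand_iy = int(iy) + offsets[:, 1]
                    ok = grid.in_bounds(cand_ix, cand_iy)
                    cand_ix, cand_iy = cand_ix[ok], cand_iy[ok]
                    ok2 = in_extent[cand_iy, cand_ix]
                    cand_ix, cand_iy = cand_ix[ok2], cand_iy[ok2]
                    util = z[cand_iy, cand_ix] @ beta[i]
                    p = np.exp(util - util.max())
                    p /= p.sum()
                    j = rng.choice(len(p), p=p)
                    cx, cy = grid.center(int(cand_ix[j]), int(cand_iy[j]))
                    for _ in range(30):
                        cand = np.array(
                            [cx, cy]
                        ) + rng.uniform(-0.5, 0.5, size=2) * grid.spacing_km
                        d = np.hypot(*(cand - pos))
                        if cfg.fine_max_km <= d <= cfg.relocation_min_km:
                            break
                    pos = cand
                    chosen_records.append(
                        (aid, t + dt, int(grid.cell_id(int(cand_ix[j]), int(cand_iy[j]))))
                    )
                else:
                    # off-layer: drift back toward the study area
                    direction = center - pos
                    direction /= max(np.hypot(*direction), 1e-9)
                    theta = np.arctan2(direction[1], direction[0]) + rng.normal(0, 0.3)
                    r = rng.uniform(1.0, 15.0)
                    pos = pos + r * np.array([np.cos(theta), np.sin(theta)])
            t = t + dt

    fixes = pd.DataFrame(records, columns=["animal_id", "timestamp", "easting_km", "northing_km"])
    fixes["timestamp"] = pd.to_datetime(fixes["timestamp"], utc=True)
    chosen = pd.DataFrame(chosen_records, columns=["animal_id", "timestamp", "cell_id"])
    if len(chosen):
        chosen["timestamp"] = pd.to_datetime(chosen["timestamp"], utc=True)
    truth = GroundTruth(
        mu_star=mu,
        sigma_star=sig,
        beta=beta,
        var_names=catalog.abbreviations,
        animal_ids=animal_ids,
        chosen=chosen,
        std_params=std_params,
    )
    return fixes, truth


# ---------------------------------------------------------------------------
# Direct choice-set simulator (no landscape): parameter-recovery workhorse
# ---------------------------------------------------------------------------


def simulate_choice_data(
    n_animals: int = 40,
    sets_per_animal: int = 150,
    n_alternatives: int = 10,
    mu: np.ndarray | list[float] = (1.0, -0.5),
    sigma: np.ndarray | list[float] | float = 0.3,
    seed: int = 0,
    covariate_sd: float = 0.5,
) -> tuple[ChoiceData, dict]:
    """Choice sets drawn straight from the hierarchical conditional logit.

    Covariates are i.i.d. Normal(0, covariate_sd) — already on the 2-SD
    standardized scale — so the fitted population means are directly
    comparable with ``mu``. The chosen alternative is moved to index 0.
    """
    rng = np.random.default_rng(seed % (2**31))
    mu = np.asarray(mu, dtype=float)
    k = mu.size
    sigma = np.full(k, float(sigma)) if np.isscalar(sigma) else np.asarray(sigma, dtype=float)
    beta = mu + sigma * rng.standard_normal((n_animals, k))
    n = n_animals * sets_per_animal
    X = rng.normal(0.0, covariate_sd, size=(n, n_alternatives, k))
    animal = np.repeat(np.arange(n_animals), sets_per_animal)
    util = np.einsum("njk,nk->nj", X, beta[animal])
    gumbel = rng.gumbel(size=util.shape)
    choice = np.argmax(util + gumbel, axis=1)
    # swap chosen alternative to slot 0
    rows = np.arange(n)
    X[rows, [0] * n], X[rows, choice] = X[rows, choice].copy(), X[rows, 0].copy()
    data = ChoiceData(
        X=X,
        mask=np.ones((n, n_alternatives), dtype=bool),
        animal=animal,
        animal_ids=[f"duck{i:03d}" for i in range(n_animals)],
        var_names=[f"x{j}" for j in range(k)],
    )
    return data, {"mu": mu, "sigma": sigma, "beta": beta, "choice_index": choice}
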