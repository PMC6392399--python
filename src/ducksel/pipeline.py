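"""End-to-end orchestration: fixes + landscape -> selection estimates.

`run_analysis` chains the movement filter, choice-set construction,
per-stratum screening/standardization, the four candidate-model fits, DIC
ranking, and posterior summaries, writing every artifact (filter ledger,
descriptive table, screening log, DIC table, caterpillar data, manifest)
to the output directory. `run_simulation_study` runs the replicate
parameter-recovery study on data simulated from the model itself.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import choiceset as cs
from . import dcm, movement, synthetic
from .catalog import VariableCatalog, default_catalog
from .config import RunConfig
from .landscape import LandscapeGrid, load_ownership_geojson, reclassify
from .movement import FilterLedger
from .solar import NoaaSolar

log = logging.getLogger("ducksel")

#: screening priority: marsh variables outrank water within each ownership
DEFAULT_PRIORITY = [
    "MICH-DNR",
    "PUB-MARSH", "PRI-MARSH", "WAL-MARSH", "CWS-MARSH",
    "PUB-WATER", "PRI-WATER", "WAL-WATER", "MICH-WATER", "CWS-WATER",
    "PRI-FLAG", "PRI-SUPP", "PRI-AGRI", "WAL-AGRI",
]


def _load_landscape(config: RunConfig) -> LandscapeGrid:
    catalog = (
        VariableCatalog.from_csv(config.paths.catalog) if config.paths.catalog else default_catalog()
    )
    grid = LandscapeGrid.from_ascii(config.paths.raster, catalog=catalog)
    if config.paths.ownership:
        ownership = load_ownership_geojson(config.paths.ownership)
        feed = (
            pd.read_csv(config.paths.feed_sites)[["easting_km", "northing_km"]].to_numpy()
            if config.paths.feed_sites
            else None
        )
        grid = reclassify(grid, ownership, feed, catalog, buffer_km=config.thresholds.buffer_km)
    return grid


def prepare_fixes(config: RunConfig, fixes: pd.DataFrame | None = None):
    """Censor, label (diel, season), classify step scales; return the
    labelled fixes, steps, descriptive table, and a partial ledger."""
    thr = config.thresholds
    if fixes is None:
        fixes = movement.read_fixes(config.paths.fixes)
    fixes, censor = movement.censor_initial(fixes, days=thr.censor_days)
    solar = NoaaSolar(config.solar_lat, config.solar_lon)
    fixes = movement.label_diel(fixes, solar, margin_min=thr.diel_margin_min)
    fixes = movement.label_seasons(fixes, config.season_windows)
    steps, fixes, ledger = movement.steps_and_scales(
        fixes, fine_max_km=thr.fine_max_km, relocation_min_km=thr.relocation_min_km
    )
    ledger.censored_initial = censor["fixes_removed"]
    ledger.animals_marked = censor["animals_marked"]
    ledger.animals_censored = censor["animals_censored"]
    ledger.animals_analysed = censor["animals_analysed"]
    table2 = movement.descriptive_table(fixes[fixes["retained"] & (fixes["season"] != "out_of_window")])
    return fixes, steps, table2, ledger


def build_sets(config: RunConfig, fixes: pd.DataFrame, steps: pd.DataFrame,
               landscape: LandscapeGrid, ledger: FilterLedger):
    """Availability radius, analysis grid and choice sets; settles the
    ledger's out-of-extent and final counts."""
    thr = config.thresholds
    local_lengths = steps.loc[steps["scale"] == "local", "step_km"].to_numpy()
    radius = thr.radius_km if thr.radius_km else cs.availability_radius(local_lengths, thr.quantile)
    grid = cs.ChoiceGrid.covering(landscape, thr.spacing_km)
    usable = fixes[fixes["retained"] & (fixes["season"] != "out_of_window")]
    coll, n_out = cs.build_choice_sets(usable, grid, landscape, radius, landscape.catalog)
    dropped_out_of_window = int((fixes["retained"] & (fixes["season"] == "out_of_window")).sum())
    ledger.out_of_extent = n_out
    ledger.local -= dropped_out_of_window  # out-of-window locals leave the accounting
    ledger.total -= dropped_out_of_window
    ledger.final = ledger.local - ledger.out_of_extent
    ledger.validate()
    return coll, radius, grid


def fit_stratum(
    coll_stratum: cs.ChoiceSetCollection,
    catalog: VariableCatalog,
    config: RunConfig,
    priority: list[str] | None = None,
) -> dict:
    """Screen, standardize, and fit every candidate model on one
    season x diel stratum; returns fits, the DIC ranking, and the logs."""
    thr = config.thresholds
    units = coll_stratum.units
    rows = units[coll_stratum.var_names]
    retained, screen_log = cs.screen_correlation(
        rows, thr.corr_threshold, priority or [v for v in DEFAULT_PRIORITY if v in rows.columns]
    )
    out = {"retained": retained, "screen_log": screen_log, "models": {}, "fits": {}}
    results = {}
    for model in config.models:
        cols = dcm.candidate_columns(units, catalog, model, retained)
        if cols.shape[1] == 0:
            base = dcm.ChoiceData.from_frames(
                coll_stratum.sets, units.assign(_z=0.0), ["_z"]
            )
            data = dcm.ChoiceData(
                base.X[:, :, :0], base.mask, base.animal, base.animal_ids, []
            )
            d = dcm.null_dic(data)
            results[model] = {"DIC": d, "fingerprint": data.fingerprint()}
            out["models"][model] = {"dic": {"Dbar": d, "pD": 0.0, "DIC": d}, "converged": True}
            continue
        z, params = cs.standardize_2sd(cols)
        keep = [v for v in z.columns if v not in params.excluded]
        frame = pd.concat([units[["set_id", "used"]], z[keep]], axis=1)
        data = dcm.ChoiceData.from_frames(coll_stratum.sets, frame, keep)
        fit = dcm.fit_model(data, model, config.priors, config.mcmc)
        results[model] = {"DIC": fit.dic["DIC"], "fingerprint": fit.fingerprint}
        out["fits"][model] = fit
        out["models"][model] = {
            "dic": fit.dic,
            "converged": fit.converged,
            "summary": fit.summary,
        }
    out["ranking"] = dcm.rank_models(results, thr.delta_dic)
    return out


def run_analysis(config: RunConfig, *, fixes: pd.DataFrame | None = None,
                 landscape: LandscapeGrid | None = None) -> dict:
    """Full pipeline; writes artifacts to ``config.paths.output_dir``."""
    t0 = time.time()
    outdir = Path(config.paths.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if landscape is None:
        landscape = _load_landscape(config)
    catalog = landscape.catalog

    fixes, steps, table2, ledger = prepare_fixes(config, fixes)
    log.info("movement filter: %s", ledger.as_dict())
    coll, radius, grid = build_sets(config, fixes, steps, landscape, ledger)
    log.info("choice sets: %d (radius %.1f km)", len(coll), radius)

    table2.to_csv(outdir / "table2.csv", index=False)
    (outdir / "ledger.json").write_text(json.dumps(ledger.as_dict(), indent=1))
    coll.to_csv(outdir / "choice_sets.csv")

    strata_out = {}
    dic_rows, summary_frames, screen_entries = [], [], []
    for season, diel in sorted(coll.strata()):
        sub = coll.stratum(season, diel)
        if sub.sets["animal_id"].nunique() < 2 or len(sub) < 4:
            log.info("skipping sparse stratum %s/%s", season, diel)
            continue
        res = fit_stratum(sub, catalog, config)
        strata_out[(season, diel)] = res
        rank = res["ranking"].assign(season=season, diel=diel)
        dic_rows.append(rank)
        screen_entries.append({"season": season, "diel": diel,
                               "retained": res["retained"], "log": res["screen_log"]})
        top = rank.iloc[0]["model"]
        if top in res["fits"]:
            summary_frames.append(
                res["fits"][top].summary.assign(season=season, diel=diel, model=top)
            )

    if dic_rows:
        pd.concat(dic_rows, ignore_index=True).to_csv(outdir / "dic_table.csv", index=False)
    if summary_frames:
        pd.concat(summary_frames, ignore_index=True).to_csv(outdir / "caterpillar.csv", index=False)
    (outdir / "screening.json").write_text(json.dumps(screen_entries, indent=1))
    manifest = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "radius_km": radius,
        "radius_km_reported": round(radius, 1),
        "n_choice_sets": len(coll),
        "elapsed_s": round(time.time() - t0, 2),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return {
        "ledger": ledger,
        "table2": table2,
        "collection": coll,
        "radius": radius,
        "strata": strata_out,
        "manifest": manifest,
    }


def run_simulation_study(
    n_replicates: int = 5,
    n_animals: int = 40,
    sets_per_animal: int = 150,
    n_alternatives: int = 10,
    mu=(1.0, -0.5),
    sigma=0.3,
    seed: int = 0,
    mcmc: dcm.McmcConfig | None = None,
    priors: dcm.Priors | None = None,
    output_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Replicate recovery study: simulate from known (mu, sigma), refit, and
    report per-variable coverage, bias and interval width, plus whether the
    true model beats the null by more than 5 DIC units."""
    priors = priors or dcm.Priors()
    rows = []
    for rep in range(n_replicates):
        rep_seed = (seed * 1000 + rep) % (2**31)
        data, truth = synthetic.simulate_choice_data(
            n_animals, sets_per_animal, n_alternatives, mu=mu, sigma=sigma, seed=rep_seed
        )
        cfg = mcmc or dcm.McmcConfig(seed=rep_seed)
        cfg = dcm.McmcConfig(**{**cfg.__dict__, "seed": rep_seed})
        fit = dcm.fit_model(data, "full", priors, cfg)
        null = dcm.null_dic(data)
        for k, name in enumerate(data.var_names):
            s = fit.summary.iloc[k]
            rows.append(
                {
                    "replicate": rep,
                    "variable": name,
                    "mu_true": truth["mu"][k],
                    "mu_hat": s["mean"],
                    "cri_lo": s["cri_lo"],
                    "cri_hi": s["cri_hi"],
                    "covered": bool(s["cri_lo"] <= truth["mu"][k] <= s["cri_hi"]),
                    "bias": s["mean"] - truth["mu"][k],
                    "converged": fit.converged,
                    "dic_full": fit.dic["DIC"],
                    "dic_null": null,
                    "full_beats_null": bool(null - fit.dic["DIC"] > dcm.DELTA_DIC_COMPETITIVE),
                }
            )
    report = pd.DataFrame(rows)
    if output_dir is not None:
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.to_csv(outdir / "recovery.csv", index=False)
        agg = {
            "coverage": float(report["covered"].mean()),
            "mean_bias": float(report["bias"].mean()),
            "rmse": float(np.sqrt((report["bias"] ** 2).mean())),
            "all_full_beat_null": bool(report["full_beats_null"].all()),
            "n_replicates": n_replicates,
        }
        (outdir / "recovery.json").write_text(json.dumps(agg, indent=1))
    return report


def simulate_bundle(cfg: synthetic.SimConfig, outdir: str | Path) -> dict:
    """Generate a complete synthetic input bundle on disk (raster, catalog,
    ownership, feed sites, fixes, ground truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = synthetic.generate_landscape(cfg)
    fixes, truth = synthetic.simulate_trajectories(cfg, bundle)
    bundle.landscape.to_ascii(outdir / "landscape.asc")
    bundle.catalog.to_csv(outdir / "catalog.csv")
    from .landscape import dump_ownership_geojson

    dump_ownership_geojson(bundle.ownership, outdir / "ownership.geojson")
    pd.DataFrame(bundle.feed_sites, columns=["easting_km", "northing_km"]).to_csv(
        outdir / "feed_sites.csv", index=False
    )
    movement.write_fixes(fixes, outdir / "fixes.csv")
    truth.to_json(outdir / "truth.json")
    return {"bundle": bundle, "fixes": fixes, "truth": truth}
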