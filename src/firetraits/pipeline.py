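"""End-to-end orchestration and descriptive summaries.

``run_pipeline`` drives the full analysis from a config: (optionally)
simulate a fire landscape, virtual species and trait observations; clean
the occurrence records; estimate per-species fire frequency; classify
strategies; fit the quadratic-logit fire-response model and the leaf-trait
linear models; and write every stage's output as flat files plus a JSON
manifest of record counts, so any stage can be re-run and checked in
isolation. Deterministic given (inputs, master seed).

Also here: family-level summaries (median of species-level mean fire
frequencies, strategy proportions, medians of species-mean leaf traits)
and the per-cell strategy-proportion raster.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import cleaning, firefreq, models, synthetic, traits
from .grid import FireEventRaster, LandscapeSpec

__all__ = ["PipelineConfig", "run_pipeline", "family_summary",
           "cell_strategy_proportions", "simulate_study"]


@dataclasses.dataclass
class PipelineConfig:
    """Inputs and options for one pipeline run.

    Either the three input paths (occurrences CSV, trait CSV, raster
    counts/events pair) or ``simulate=True`` with simulation parameters.
    """

    out_dir: str = "firetraits_out"
    seed: int = 0
    # real inputs
    occurrences_csv: str | None = None
    traits_csv: str | None = None
    raster_nc: str | None = None
    raster_events_csv: str | None = None
    # or simulation
    simulate: bool = False
    n_species: int = 500
    grid_rows: int = 100
    grid_cols: int = 100
    # ranges span many cells so each species' fire history holds tens of
    # events and its measured log10 F carries little sampling noise,
    # mirroring real ranges that cover thousands of burnt-area cells
    block_rows: int = 16
    block_cols: int = 16
    n_occurrences: int = 200
    n_obs_per_species: int = 5
    flip_prob: float = 0.05
    resprout_curve: synthetic.ResponseCurve = dataclasses.field(
        default_factory=lambda: synthetic.ResponseCurve(0.88, 0.70, -1.17))
    seed_curve: synthetic.ResponseCurve = dataclasses.field(
        default_factory=lambda: synthetic.ResponseCurve(1.55, 0.66, -1.22))
    # analysis options
    min_cells: int = 10
    threshold: float = 0.30
    drop_infraspecific: bool = False
    drop_annuals: bool = False
    cleaning_config: cleaning.CleaningConfig = dataclasses.field(
        default_factory=cleaning.CleaningConfig)

    def config_hash(self) -> str:
        # output location does not affect what is computed
        payload = {k: repr(v) for k, v in dataclasses.asdict(self).items()
                   if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def simulate_study(config: PipelineConfig):
    """Generate the synthetic landscape, species, occurrences and traits."""
    spec = LandscapeSpec(n_rows=config.grid_rows, n_cols=config.grid_cols)
    rates = synthetic.gradient_rate_field(spec)
    raster = synthetic.simulate_fire_history(spec, rates, seed=config.seed)
    occurrences, truth = synthetic.simulate_species_ranges(
        spec, rates, config.n_species, seed=config.seed,
        block_rows=config.block_rows, block_cols=config.block_cols,
        n_occurrences=config.n_occurrences)
    trait_obs = synthetic.assign_fire_traits(
        truth, config.resprout_curve, config.seed_curve,
        n_obs_per_species=config.n_obs_per_species,
        flip_prob=config.flip_prob, seed=config.seed)
    return raster, occurrences, trait_obs, truth


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; persist outputs under ``config.out_dir``.

    Returns a results bundle: ``fire_summary`` (per-species F table),
    ``profiles``, ``resprout_fit`` (FireResponseResults or None),
    ``removal_log``, ``manifest`` (all counts + provenance), ``truth``
    (simulation only).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash(), "seed": config.seed}
    truth = None

    if config.simulate:
        raster, occurrences, trait_obs, truth = simulate_study(config)
        raster.to_files(out / "fire_counts.nc", out / "fire_events.csv")
        occurrences.to_csv(out / "occurrences_raw.csv", index=False)
        trait_obs.to_csv(out / "trait_observations.csv", index=False)
        truth.species.to_csv(out / "truth_species.csv", index=False)
    else:
        missing = [name for name, path in [
            ("occurrences", config.occurrences_csv),
            ("traits", config.traits_csv),
            ("fire raster", config.raster_nc),
            ("fire raster events", config.raster_events_csv),
        ] if path is None or not Path(path).exists()]
        if missing:
            raise FileNotFoundError(f"missing pipeline inputs: {missing}")
        raster = FireEventRaster.from_files(config.raster_nc,
                                            config.raster_events_csv)
        occurrences = pd.read_csv(config.occurrences_csv)
        trait_obs = pd.read_csv(config.traits_csv)

    manifest["n_occurrences_in"] = len(occurrences)

    kept, log = cleaning.clean_occurrences(occurrences, config.cleaning_config)
    kept.to_csv(out / "occurrences_clean.csv", index=False)
    log.to_frame().to_csv(out / "removal_log.csv", index=False)
    manifest["cleaning"] = {"kept": log.kept_count, "removed": log.removed}

    occupancy, n_oob = firefreq.map_occurrences_to_cells(kept, raster.spec)
    manifest["n_out_of_bounds"] = n_oob
    fire_summary = firefreq.summarize_all_species(
        occupancy, raster, min_cells=config.min_cells)
    fire_summary.to_csv(out / "fire_summary.csv", index=False)
    manifest["fire_frequency"] = {
        "n_species": len(fire_summary),
        "n_excluded_too_few_cells":
            int((fire_summary["exclusion_reason"] == "too_few_cells").sum()),
        "n_excluded_all_unburnt":
            int((fire_summary["exclusion_reason"] == "all_unburnt").sum()),
    }

    profiles = traits.build_profiles(
        trait_obs, threshold=config.threshold,
        drop_infraspecific=config.drop_infraspecific)
    if config.drop_annuals:
        profiles = profiles[profiles["life_history"] != "annual"]
    profiles.to_csv(out / "profiles.csv", index=False)
    manifest["n_profiles"] = len(profiles)

    table = profiles.rename(columns={"taxon": "species"}).merge(
        fire_summary.loc[~fire_summary["excluded"],
                         ["species", "fires_per_century"]],
        on="species", how="inner")
    table.to_csv(out / "model_table.csv", index=False)
    manifest["n_model_rows"] = len(table)

    resprout_fit = None
    has_gf = table["growth_form"].notna().any()
    model_rows = table.dropna(subset=["resprouter", "fires_per_century"])
    if len(model_rows) and model_rows["resprouter"].astype(bool).nunique() == 2:
        resprout_fit = models.fit_logistic_quadratic(
            table, response="resprouter",
            group_col="growth_form" if has_gf else None)
        summary = resprout_fit.summary()
        summary.to_csv(out / "resprout_glm.csv")
        manifest["resprout_glm"] = {
            "nobs": resprout_fit.nobs,
            "tjur_r2": resprout_fit.tjur_r2,
            "converged": resprout_fit.converged,
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)

    return {
        "raster": raster,
        "fire_summary": fire_summary,
        "profiles": profiles,
        "model_table": table,
        "resprout_fit": resprout_fit,
        "removal_log": log,
        "manifest": manifest,
        "truth": truth,
    }


def family_summary(profiles: pd.DataFrame, fire_summary: pd.DataFrame,
                   family_map: pd.DataFrame) -> pd.DataFrame:
    """Per-family medians and strategy proportions.

    ``family_map`` has columns ``taxon``, ``family``. Per family: the
    median of species-level mean fire frequencies; the proportion of
    resprouters / seeders among species with data; the median over species
    of the species-mean LMA and leaf N. Species without a family mapping
    are excluded (count returned in ``attrs['n_unmapped']``).
    """
    prof = profiles.merge(family_map, on="taxon", how="left")
    n_unmapped = int(prof["family"].isna().sum())
    prof = prof.dropna(subset=["family"])
    fs = fire_summary.loc[~fire_summary["excluded"],
                          ["species", "fires_per_century"]]
    prof = prof.merge(fs, left_on="taxon", right_on="species", how="left")

    def agg(grp: pd.DataFrame) -> pd.Series:
        def prop(col):
            with_data = grp[col].dropna()
            return with_data.eq(True).mean() if len(with_data) else np.nan
        return pd.Series({
            "n_species": len(grp),
            "median_fires_per_century": grp["fires_per_century"].median(),
            "prop_resprouters": prop("resprouter"),
            "prop_seeders": prop("seeder"),
            "median_lma": grp["mean_lma"].median(),
            "median_leaf_n": grp["mean_leaf_n"].median(),
        })

    out = prof.groupby("family").apply(agg, include_groups=False).reset_index()
    out.attrs["n_unmapped"] = n_unmapped
    return out


def cell_strategy_proportions(occupancy: pd.DataFrame, profiles: pd.DataFrame,
                              grid: LandscapeSpec,
                              growth_form: str = "woody",
                              strategy: str = "resprouter") -> np.ndarray:
    """Per-cell proportion of strategy-positive species of one growth form.

    For each grid cell: (number of strategy-positive species of that growth
    form occurring there) / (number of that growth form's species with
    strategy data occurring there). Cells with no such species are NaN.
    """
    prof = profiles[(profiles["growth_form"] == growth_form)
                    & profiles[strategy].notna()]
    occ = occupancy.merge(prof[["taxon", strategy]], left_on="species",
                          right_on="taxon", how="inner")
    denom = np.zeros((grid.n_rows, grid.n_cols))
    numer = np.zeros((grid.n_rows, grid.n_cols))
    rows = occ["row"].to_numpy(dtype=int)
    cols = occ["col"].to_numpy(dtype=int)
    pos = occ[strategy].eq(True).to_numpy(dtype=float)
    np.add.at(denom, (rows, cols), 1.0)
    np.add.at(numer, (rows, cols), pos)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = numer / denom
    out[denom == 0] = np.nan
    return out
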