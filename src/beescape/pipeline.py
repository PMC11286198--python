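"""End-to-end orchestration: traits -> energetics -> metaweb -> landscape -> model.

Each stage consumes validated CSV tables, writes its outputs back as CSV,
and logs provenance.  ``run_pipeline`` executes the stages in order and
ends with error-family comparison, all-subsets AICc selection, Nakagawa R²,
VIF screening, effect translation, and a plain-markdown report.
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd

from .allometry import AllometricMassModel, predict_mass, species_mean_mass
from .energetics import build_plant_resources, pollen_content_from_calorimetry
from .inference import (
    TwoSDScaler,
    all_subsets_selection,
    build_design,
    effect_translation,
    family_comparison,
    r2_nakagawa,
    vif,
)
from .io import RunConfig, read_table, write_table
from .landscape import (
    apply_nominal_density,
    availability_table,
    density_from_transects,
    energy_correlation,
)
from .metaweb import build_all_site_networks, network_summaries, pool_metaweb

log = logging.getLogger("beescape")

#: Fixed-effect terms of the global abundance model (2-SD standardized).
GLOBAL_TERMS = (
    "z_ln_mass",
    "z_patch",
    "z_landscape",
    "z_patch_area",
    "z_ln_mass:z_patch",
    "z_ln_mass:z_landscape",
)


class PipelineError(RuntimeError):
    pass


def build_model_frame(
    abundance: pd.DataFrame | None,
    traits: pd.DataFrame,
    availability: pd.DataFrame,
    composition: pd.DataFrame,
    effort: pd.DataFrame,
) -> tuple[pd.DataFrame, TwoSDScaler]:
    """Assemble the species x site modelling frame with standardized predictors.

    The grid is the full cross of bee species (union of trait and
    availability tables) and sites, zeros included.  Continuous predictors
    (ln body mass, patch energy, landscape energy, patch area) are 2-SD
    standardized; the scaler is returned for back-transformation.
    """
    bees = sorted(set(availability["bee_species"]) | set(traits["species"]))
    sites = sorted(set(availability["site"]))
    grid = pd.MultiIndex.from_product(
        [bees, sites], names=["bee_species", "site"]
    ).to_frame(index=False)

    frame = grid.merge(availability, on=["bee_species", "site"], how="left")
    # bees absent from the metaweb have empty partner sets: zero energy
    frame[["patch_Mcal", "landscape_Mcal"]] = frame[
        ["patch_Mcal", "landscape_Mcal"]
    ].fillna(0.0)

    mass = traits.set_index("species")["mass_mg_mean"]
    missing_mass = [b for b in bees if b not in mass.index]
    if missing_mass:
        raise PipelineError(f"no body-mass estimate for bee species {missing_mass}")
    frame["mass_mg"] = frame["bee_species"].map(mass)

    patch_area = composition.drop_duplicates("site").set_index("site")["patch_area_ha"]
    frame["patch_area_ha"] = frame["site"].map(patch_area)
    eff = effort.set_index("site")["effort_h"]
    missing_eff = [s for s in sites if s not in eff.index]
    if missing_eff:
        raise PipelineError(f"no sampling effort for site(s) {missing_eff}")
    frame["effort_h"] = frame["site"].map(eff)
    if frame[["patch_area_ha"]].isna().any().any():
        raise PipelineError("missing patch area for some site in the frame")

    frame["ln_mass"] = np.log(frame["mass_mg"])
    scaler = TwoSDScaler().fit(
        frame[["ln_mass", "patch_Mcal", "landscape_Mcal", "patch_area_ha"]]
    )
    z = scaler.transform(
        frame[["ln_mass", "patch_Mcal", "landscape_Mcal", "patch_area_ha"]]
    )
    frame["z_ln_mass"] = z["ln_mass"]
    frame["z_patch"] = z["patch_Mcal"]
    frame["z_landscape"] = z["landscape_Mcal"]
    frame["z_patch_area"] = z["patch_area_ha"]

    if abundance is not None:
        frame = frame.merge(abundance, on=["bee_species", "site"], how="left")
        frame["count"] = frame["count"].fillna(0).astype(int)
    return frame, scaler


def run_pipeline(config: RunConfig, outdir: str | os.PathLike) -> dict:
    """Execute every stage in order; returns the result bundle.

    Writes per-stage CSV tables and ``report.md`` into *outdir*.  Any stage
    failure is re-raised as :class:`PipelineError` naming the stage.
    """
    config.validate()
    os.makedirs(outdir, exist_ok=True)
    results: dict = {"config": config}

    def _stage(name):
        log.info("stage %s (seed=%s)", name, config.seed)

    try:
        _stage("inputs")
        tables = {name: read_table(path, name) for name, path in config.paths.items()}
        for required in ("interactions", "specimens", "nectar", "pollen",
                         "taxonomy", "composition", "effort"):
            if required not in tables:
                raise PipelineError(f"config.paths lacks required table {required!r}")
        if len(tables["interactions"]) == 0:
            raise PipelineError("no interactions")
    except Exception as err:
        raise PipelineError(f"stage 'inputs' failed: {err}") from err

    try:
        _stage("traits")
        spec = tables["specimens"]
        if "mass_mg" in spec.columns:
            model = AllometricMassModel().fit(
                spec[["length_mm", "family", "sex"]],
                pd.to_numeric(spec["mass_mg"]),
            )
        else:
            raise PipelineError(
                "specimen table lacks calibration masses (mass_mg); supply "
                "allometry coefficients or calibration data"
            )
        predicted = predict_mass(spec[["species", "length_mm", "family", "sex"]], model)
        traits = species_mean_mass(predicted)
        write_table(traits, os.path.join(outdir, "traits.csv"))
        results["traits"], results["allometry_model"] = traits, model
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(f"stage 'traits' failed: {err}") from err

    try:
        _stage("energetics")
        pollen_content = config.pollen_cal_per_mg
        if "calorimetry" in tables and len(tables["calorimetry"]):
            pollen_content, pollen_se = pollen_content_from_calorimetry(
                tables["calorimetry"]
            )
            results["pollen_content_se"] = pollen_se
        resources = build_plant_resources(
            tables["nectar"], tables["pollen"], tables["taxonomy"],
            sugar_constants=config.sugar_constants,
            pollen_cal_per_mg=pollen_content,
            literature_overrides=config.literature_overrides,
            impute_genus=config.impute_genus,
            impute_family=config.impute_family,
        )
        write_table(resources, os.path.join(outdir, "plant_resources.csv"))
        r_log, p_log = energy_correlation(resources, scale="log")
        results["resources"] = resources
        results["pollen_content"] = pollen_content
        results["energy_correlation_log"] = (r_log, p_log)
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(f"stage 'energetics' failed: {err}") from err

    try:
        _stage("metaweb")
        networks = build_all_site_networks(tables["interactions"])
        web, web_summary = pool_metaweb(networks)
        site_table, richness = network_summaries(networks)
        web.to_csv(os.path.join(outdir, "metaweb.csv"))
        write_table(site_table, os.path.join(outdir, "site_networks.csv"))
        results.update(
            {"networks": networks, "metaweb": web, "metaweb_summary": web_summary,
             "richness": richness}
        )
    except Exception as err:
        raise PipelineError(f"stage 'metaweb' failed: {err}") from err

    try:
        _stage("landscape")
        if "density" in tables:
            density = tables["density"]
        elif "transects" in tables:
            density = density_from_transects(tables["transects"])
        else:
            raise PipelineError("need a 'density' or 'transects' table")
        density_full = apply_nominal_density(
            list(web.columns), density, config.matrix_classes
        )
        write_table(density_full, os.path.join(outdir, "flower_density.csv"))
        avail = availability_table(
            web, tables["composition"], density_full, resources,
            patch_class=config.patch_class, matrix_classes=config.matrix_classes,
        )
        write_table(avail, os.path.join(outdir, "energy_availability.csv"))
        results["density"], results["availability"] = density_full, avail
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(f"stage 'landscape' failed: {err}") from err

    try:
        _stage("model")
        abundance = tables.get("abundance")
        if abundance is None:
            abundance = (
                tables["interactions"]
                .groupby(["site", "bee_species"], as_index=False)["count"]
                .sum()
            )
        frame, scaler = build_model_frame(
            abundance, traits, avail, tables["composition"], tables["effort"]
        )
        write_table(frame, os.path.join(outdir, "model_frame.csv"))
        offset = np.log(frame["effort_h"].to_numpy(float))
        y = frame["count"].to_numpy()
        groups = frame["bee_species"].to_numpy()

        fam_table, fam_fits = family_comparison(
            frame, y, list(GLOBAL_TERMS), groups=groups, offset=offset,
            families=config.families, zero_inflation=config.zero_inflation,
            n_quad=config.n_quad, n_restarts=config.n_restarts, seed=config.seed,
        )
        write_table(fam_table, os.path.join(outdir, "family_comparison.csv"))
        best_family = fam_table.iloc[0]
        family = str(best_family["family"])
        zi = bool(best_family["zero_inflated"])

        vifs = vif(frame[[t for t in GLOBAL_TERMS if ":" not in t]])
        high_vif = vifs[vifs >= config.vif_threshold]

        selection, fits = all_subsets_selection(
            frame, y, list(GLOBAL_TERMS), groups=groups, offset=offset,
            window=config.aicc_window, family=family, zero_inflated=zi,
            n_quad=config.n_quad, n_restarts=config.n_restarts, seed=config.seed,
        )
        sel_out = selection.drop(columns=["terms"]).copy()
        write_table(sel_out, os.path.join(outdir, "model_selection.csv"))
        best_terms = selection.loc[selection["best"], "terms"].iloc[0]
        best_model = fits[best_terms]
        coef_table = best_model.wald_table()
        write_table(coef_table, os.path.join(outdir, "best_model_coefficients.csv"))

        X_best = build_design(frame, best_terms)
        r2_m, r2_c = r2_nakagawa(best_model, X_best, offset=offset)
        translations = {}
        if "z_landscape" in best_terms:
            for level in ("mean", "+1sd", "-1sd"):
                translations[level] = effect_translation(
                    best_model, frame, y, frame["effort_h"], "z_landscape",
                    mass_level=level,
                )
        results.update(
            {"frame": frame, "scaler": scaler, "family_table": fam_table,
             "family_fits": fam_fits, "vif": vifs, "high_vif": high_vif,
             "selection": selection, "fits": fits, "best_terms": best_terms,
             "best_model": best_model, "coef_table": coef_table,
             "r2_marginal": r2_m, "r2_conditional": r2_c,
             "effect_translation": translations}
        )
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(f"stage 'model' failed: {err}") from err

    report = _render_report(results)
    with open(os.path.join(outdir, "report.md"), "w", encoding="utf-8") as fh:
        fh.write(report)
    results["report"] = report
    return results


def _render_report(res: dict) -> str:
    cfg: RunConfig = res["config"]
    ws = res["metaweb_summary"]
    rich = res["richness"]
    lines = [
        "# Landscape floral-energetics pipeline report",
        "",
        f"Seed: {cfg.seed}",
        "",
        "## Networks",
        f"- interaction events: {ws['total_events']}",
        f"- unique links: {ws['n_links']}",
        f"- bee species: {ws['n_bee_species']}, plant species: {ws['n_plant_species']}",
        f"- per-site richness: {rich['bee_richness_mean']:.1f} bees, "
        f"{rich['plant_richness_mean']:.1f} plants (means across sites)",
        "",
        "## Floral energetics",
        f"- pollen calorific content used: {res['pollen_content']:.3f} cal/mg",
        f"- log-scale pollen-nectar energy correlation: "
        f"r = {res['energy_correlation_log'][0]:.3f}",
        "",
        "## Error-family comparison (AICc)",
        res["family_table"].to_string(index=False),
        "",
        "## Collinearity (VIF, mains only)",
        res["vif"].round(3).to_string(),
        "",
        "## All-subsets AICc selection",
        res["selection"].drop(columns=["terms"]).head(10).to_string(index=False),
        "",
        "## Best model coefficients",
        res["coef_table"].to_string(index=False),
        "",
        f"R2 (Nakagawa): marginal {res['r2_marginal']:.3f}, "
        f"conditional {res['r2_conditional']:.3f}",
    ]
    if res.get("effect_translation"):
        lines += [
            "",
            "## Landscape-energy effect as % of observed capture-rate range",
        ]
        for level, val in res["effect_translation"].items():
            lines.append(f"- body mass at {level}: {val:.1f}%")
    lines.append("")
    return "\n".join(lines)
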