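"""Synthetic study generator with known ground truth.

Emulates the statistical structure of a woodland-remnant pollination
study — 23 remnant sites, 53 bee and 56 plant species, three dominant
land-use classes — so that every pipeline stage has a recovery test
against known parameters:

* per-flower nectar and pollen energies are bivariate log-normal with a
  configurable log-scale correlation (default 0.79), split into three sugar
  masses; a configurable fraction of species lacks nectar or pollen
  measurements (exercising taxonomic imputation);
* flower densities per land-use class are long-tailed log-normals, with a
  fraction of network plants absent from every transect (exercising the
  nominal-density rule); class means are ordered woodland > cleared > pine;
* bee specimens have female-biased size dimorphism and true dry masses that
  follow the configured allometry exactly;
* site visitation networks arise from a Bernoulli metaweb whose link
  probability increases with plant energy and bee mass;
* abundance counts on the full species x site grid are drawn from exactly
  the NB2 random-intercept GLMM the pipeline fits, with the linear
  predictor built from the pipeline's own standardized covariates.

A single integer seed drives everything; per-stage substreams are derived
deterministically so partial re-runs reproduce bit-identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .allometry import AllometricMassModel, predict_mass, species_mean_mass
from .energetics import build_plant_resources
from .io import DEFAULT_SUGAR_CONSTANTS, SUGARS
from .landscape import apply_nominal_density, availability_table
from .metaweb import build_all_site_networks, pool_metaweb

_STAGES = {"plants": 1, "landscape": 2, "bees": 3, "networks": 4,
           "effort": 5, "abundance": 6}

PLANT_FAMILIES = {
    "Asteraceae": ("Podotheca", "Waitzia"),
    "Fabaceae": ("Gompholobium", "Jacksonia", "Daviesia"),
    "Myrtaceae": ("Regelia", "Calytrix", "Melaleuca"),
    "Proteaceae": ("Banksia", "Petrophile"),
    "Goodeniaceae": ("Lechenaultia", "Dampiera"),
    "Dilleniaceae": ("Hibbertia",),
}

BEE_FAMILIES = ("Apidae", "Colletidae", "Halictidae", "Megachilidae",
                "Stenotritidae")


class SimulationError(ValueError):
    pass


@dataclass
class SimParams:
    """Ground-truth parameters of the synthetic study."""

    n_sites: int = 23
    n_bee_species: int = 53
    n_plant_species: int = 56
    land_classes: tuple[str, ...] = ("woodland", "cleared", "pine")

    # flower-density log-normals (natural-log scale, units m^-2)
    density_logmean: dict = field(default_factory=lambda: {
        "woodland": -2.56, "cleared": -2.64, "pine": -4.03})
    density_logsd: dict = field(default_factory=lambda: {
        "woodland": 1.8, "cleared": 1.8, "pine": 1.8})
    class_presence_prob: dict = field(default_factory=lambda: {
        "woodland": 1.0, "cleared": 0.54, "pine": 0.32})
    frac_plants_absent: float = 0.232  # absent from every transect

    # per-flower energetics (natural-log cal scale)
    energy_corr: float = 0.79
    nectar_logmean: float = 0.0
    nectar_logsd: float = 1.5
    pollen_logmean: float = 0.3
    pollen_logsd: float = 1.5
    frac_missing_nectar: float = 23.0 / 56.0
    frac_missing_pollen: float = 20.0 / 56.0
    pollen_cal_per_mg: float = 4.11
    pollen_content_between_sd: float = 0.4
    n_calorimetry_species: int = 7

    # allometry (ln mg vs ln mm); sex offset is the male offset
    allom_intercept: float = -3.1
    allom_slope: float = 2.9
    allom_family_offsets: dict = field(default_factory=lambda: {
        "Apidae": 0.0, "Colletidae": -0.15, "Halictidae": -0.25,
        "Megachilidae": 0.10, "Stenotritidae": 0.20})
    allom_sex_offset: float = -0.25
    allom_resid_sd: float = 0.15
    bee_length_logmean: float = 2.08  # ln(8 mm)
    bee_length_logsd: float = 0.5
    length_sex_gap: float = 0.08  # ln-scale female-male length gap
    length_within_sd: float = 0.08
    max_specimens_per_sex: int = 10

    # metaweb / site networks
    link_intercept: float = -2.9
    link_energy_slope: float = 0.6
    link_mass_slope: float = 0.6
    site_link_prob: float = 0.10
    link_count_mean: float = 2.0

    # landscape composition
    patch_area_range_ha: tuple[float, float] = (1.0, 31.0)
    buffer_radius_m: float = 1000.0
    modelled_cover_frac: float = 0.97
    class_cover_base: dict = field(default_factory=lambda: {
        "woodland": 0.35, "cleared": 0.52, "pine": 0.10})
    cover_concentration: float = 30.0

    # abundance GLMM truth (on 2-SD standardized covariates)
    beta: dict = field(default_factory=lambda: {
        "Intercept": -2.5,
        "z_ln_mass": 0.3,
        "z_patch": 0.0,
        "z_landscape": 1.313,
        "z_patch_area": 0.0,
        "z_ln_mass:z_patch": 0.0,
        "z_ln_mass:z_landscape": 1.235,
    })
    sigma_re: float = 0.5
    theta: float = 2.0
    effort_range_h: tuple[float, float] = (5.0, 10.0)

    seed: int = 0

    def validate(self) -> "SimParams":
        if min(self.n_sites, self.n_bee_species, self.n_plant_species) < 1:
            raise SimulationError("counts must be >= 1")
        if not -1.0 < self.energy_corr < 1.0:
            raise SimulationError(
                f"energy correlation must be in (-1, 1), got {self.energy_corr}")
        if self.theta <= 0:
            raise SimulationError("theta must be > 0")
        if self.sigma_re < 0:
            raise SimulationError("sigma_re must be >= 0")
        for name in ("frac_plants_absent", "frac_missing_nectar",
                     "frac_missing_pollen"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1], got {v}")
        return self

    def replace(self, **kw) -> "SimParams":
        return dataclasses.replace(self, **kw)


def _rng(params: SimParams, stage: str) -> np.random.Generator:
    """Deterministic per-stage substream of the global seed."""
    return np.random.default_rng([params.seed, _STAGES[stage]])


# ---------------------------------------------------------------------------
# Plants


def generate_plants(params: SimParams) -> dict[str, pd.DataFrame]:
    """Taxonomy, nectar, pollen and calorimetry tables plus energy truth."""
    params.validate()
    rng = _rng(params, "plants")
    n = params.n_plant_species
    species = [f"P{i + 1:03d}" for i in range(n)]

    fam_names = list(PLANT_FAMILIES)
    genus_pool = [(f, g) for f in fam_names for g in PLANT_FAMILIES[f]]
    assignment = [genus_pool[i % len(genus_pool)] for i in range(n)]
    taxonomy = pd.DataFrame(
        {
            "species": species,
            "genus": [g for _, g in assignment],
            "family": [f for f, _ in assignment],
            "origin": rng.choice(["native", "non-native"], size=n, p=[0.85, 0.15]),
            "flower_unit": ["capitulum" if f == "Asteraceae" else "flower"
                            for f, _ in assignment],
        }
    )
    # a few species scored per whole inflorescence (Proteaceae habit)
    prot = taxonomy.index[taxonomy["family"] == "Proteaceae"][:3]
    taxonomy.loc[prot, "flower_unit"] = "inflorescence"

    # bivariate log-normal (nectar, pollen) energy per counting unit
    cov = params.energy_corr * params.nectar_logsd * params.pollen_logsd
    S = np.array([[params.nectar_logsd**2, cov], [cov, params.pollen_logsd**2]])
    ln_e = rng.multivariate_normal(
        [params.nectar_logmean, params.pollen_logmean], S, size=n,
        method="cholesky",
    )
    nectar_e, pollen_e = np.exp(ln_e[:, 0]), np.exp(ln_e[:, 1])
    # inflorescence units aggregate many flowers: scale energy up
    infl = (taxonomy["flower_unit"] == "inflorescence").to_numpy()
    nectar_e[infl] *= 50.0
    pollen_e[infl] *= 50.0

    contents = {
        s: DEFAULT_SUGAR_CONSTANTS[s]["heat_of_combustion_kcal_mol"]
        / DEFAULT_SUGAR_CONSTANTS[s]["molecular_weight_g_mol"]
        for s in SUGARS
    }
    props = rng.dirichlet([2.0, 2.0, 2.0], size=n)  # energy share per sugar
    nectar_rows, pollen_rows = [], []

    def _mark_missing(frac: float) -> np.ndarray:
        k = int(round(frac * n))
        miss = np.zeros(n, dtype=bool)
        if k:
            miss[rng.choice(n, size=k, replace=False)] = True
        # keep at least one measured species per family so imputation works
        for f in taxonomy["family"].unique():
            idx = taxonomy.index[taxonomy["family"] == f]
            if miss[idx].all():
                miss[idx[0]] = False
        return miss

    miss_nectar = _mark_missing(params.frac_missing_nectar)
    miss_pollen = _mark_missing(params.frac_missing_pollen)

    for i, sp in enumerate(species):
        if not miss_nectar[i]:
            for j, sug in enumerate(SUGARS):
                nectar_rows.append(
                    {"species": sp, "sugar": sug,
                     "mass_mg_per_flower": nectar_e[i] * props[i, j] / contents[sug]}
                )
        if not miss_pollen[i]:
            pollen_rows.append(
                {"species": sp,
                 "mass_mg_per_flower": pollen_e[i] / params.pollen_cal_per_mg}
            )

    measured_pollen = [s for i, s in enumerate(species) if not miss_pollen[i]]
    cal_rows = []
    for sp in measured_pollen[: params.n_calorimetry_species]:
        content = rng.normal(params.pollen_cal_per_mg,
                             params.pollen_content_between_sd)
        content = max(content, 0.5)
        for _ in range(int(rng.integers(2, 10))):
            cal_rows.append(
                {"species": sp, "cal_per_mg": max(rng.normal(content, 0.1), 0.1)}
            )

    truth = pd.DataFrame(
        {
            "species": species,
            "nectar_cal_true": nectar_e,
            "pollen_cal_true": pollen_e,
            "total_cal_true": nectar_e + pollen_e,
            "nectar_measured": ~miss_nectar,
            "pollen_measured": ~miss_pollen,
        }
    )
    return {
        "taxonomy": taxonomy,
        "nectar": pd.DataFrame(nectar_rows),
        "pollen": pd.DataFrame(pollen_rows),
        "calorimetry": pd.DataFrame(cal_rows),
        "plant_truth": truth,
    }


# ---------------------------------------------------------------------------
# Landscape composition and flower densities


def generate_landscape_and_densities(
    params: SimParams, plants: dict
) -> dict[str, pd.DataFrame]:
    """Per-site composition table and surveyed per-class density table."""
    params.validate()
    rng = _rng(params, "landscape")
    species = list(plants["taxonomy"]["species"])
    n = len(species)
    sites = [f"S{i + 1:02d}" for i in range(params.n_sites)]

    lo, hi = params.patch_area_range_ha
    patch_ha = np.exp(rng.uniform(np.log(lo), np.log(hi), size=params.n_sites))
    patch_r = np.sqrt(patch_ha * 1e4 / np.pi)
    buffer_area = np.pi * ((patch_r + params.buffer_radius_m) ** 2 - patch_r**2)

    base = np.array([params.class_cover_base[c] for c in params.land_classes])
    base = base / base.sum()
    comp_rows = []
    for s_i, site in enumerate(sites):
        fr = rng.dirichlet(params.cover_concentration * base)
        for c_i, cls in enumerate(params.land_classes):
            comp_rows.append(
                {"site": site, "patch_area_ha": patch_ha[s_i], "land_class": cls,
                 "buffer_area_m2": params.modelled_cover_frac * fr[c_i]
                 * buffer_area[s_i]}
            )
        comp_rows.append(
            {"site": site, "patch_area_ha": patch_ha[s_i], "land_class": "other",
             "buffer_area_m2": (1.0 - params.modelled_cover_frac)
             * buffer_area[s_i]}
        )
    composition = pd.DataFrame(comp_rows)

    k_absent = int(round(params.frac_plants_absent * n))
    absent = np.zeros(n, dtype=bool)
    if k_absent:
        absent[rng.choice(n, size=k_absent, replace=False)] = True

    unit = plants["taxonomy"].set_index("species")["flower_unit"]
    dens_rows = []
    for cls in params.land_classes:
        present = rng.random(n) < params.class_presence_prob[cls]
        present &= ~absent
        if not present.any():
            present[int(np.argmax(~absent))] = True
        draws = rng.lognormal(params.density_logmean[cls],
                              params.density_logsd[cls], size=n)
        for i, sp in enumerate(species):
            if present[i]:
                dens_rows.append(
                    {"land_class": cls, "species": sp,
                     "density_per_m2": draws[i], "unit": unit[sp],
                     "provenance": "surveyed"}
                )
    density = pd.DataFrame(dens_rows)
    truth = pd.DataFrame({"species": species, "absent_everywhere": absent})
    return {"composition": composition, "density": density,
            "density_truth": truth, "sites": pd.DataFrame({"site": sites})}


# ---------------------------------------------------------------------------
# Bees, specimens, site networks


def generate_bees_and_networks(
    params: SimParams, plants: dict, sites: list[str]
) -> dict[str, pd.DataFrame]:
    """Specimen measurements, true masses, and site interaction records."""
    params.validate()
    rng = _rng(params, "bees")
    nb = params.n_bee_species
    bees = [f"B{i + 1:02d}" for i in range(nb)]
    fams = [BEE_FAMILIES[i % len(BEE_FAMILIES)] for i in range(nb)]
    ln_len_sp = rng.normal(params.bee_length_logmean, params.bee_length_logsd,
                           size=nb)

    def true_mass(ln_len: np.ndarray, family: str, sex: str) -> np.ndarray:
        off = params.allom_family_offsets[family]
        off += params.allom_sex_offset if sex == "male" else 0.0
        return np.exp(params.allom_intercept + params.allom_slope * ln_len + off)

    spec_rows = []
    for i, (bee, fam) in enumerate(zip(bees, fams)):
        n_f = int(rng.integers(1, params.max_specimens_per_sex + 1))
        n_m = int(rng.integers(0, params.max_specimens_per_sex + 1))
        for sex, count in (("female", n_f), ("male", n_m)):
            gap = 0.0 if sex == "female" else -params.length_sex_gap
            ln_l = ln_len_sp[i] + gap + rng.normal(
                0.0, params.length_within_sd, size=count)
            tm = true_mass(ln_l, fam, sex)
            noisy = tm * np.exp(rng.normal(0.0, params.allom_resid_sd, size=count))
            for j in range(count):
                spec_rows.append(
                    {"specimen": f"{bee}-{sex[0]}{j + 1:02d}", "species": bee,
                     "family": fam, "sex": sex,
                     "length_mm": float(np.exp(ln_l[j])),
                     "true_mass_mg": float(tm[j]), "mass_mg": float(noisy[j])}
                )
    specimens = pd.DataFrame(spec_rows)

    # species-level true mass (female at the species mean length)
    sp_mass = np.array(
        [true_mass(np.array([ln_len_sp[i]]), fams[i], "female")[0]
         for i in range(nb)]
    )

    rng_net = _rng(params, "networks")
    e_total = plants["plant_truth"]["total_cal_true"].to_numpy()
    z_e = (np.log(e_total) - np.log(e_total).mean()) / np.log(e_total).std()
    z_m = (np.log(sp_mass) - np.log(sp_mass).mean()) / np.log(sp_mass).std()
    p_link = expit(
        params.link_intercept
        + params.link_energy_slope * z_e[None, :]
        + params.link_mass_slope * z_m[:, None]
    )
    potential = rng_net.random(p_link.shape) < p_link
    for i in range(nb):  # every recorded bee interacted at least once
        if not potential[i].any():
            potential[i, int(np.argmax(p_link[i]))] = True

    plant_ids = list(plants["plant_truth"]["species"])
    int_rows = []
    links = np.argwhere(potential)
    for site in sites:
        present = rng_net.random(len(links)) < params.site_link_prob
        if not present.any():
            present[int(rng_net.integers(0, len(links)))] = True
        for li in np.flatnonzero(present):
            bi, pi = links[li]
            count = 1 + int(rng_net.poisson(max(params.link_count_mean - 1.0, 0.0)))
            int_rows.append(
                {"site": site, "bee_species": bees[bi],
                 "plant_species": plant_ids[pi], "count": count}
            )
    interactions = pd.DataFrame(int_rows)
    bee_truth = pd.DataFrame(
        {"species": bees, "family": fams, "true_species_mass_mg": sp_mass,
         "n_potential_partners": potential.sum(axis=1)}
    )
    bookkeeping = {
        "n_potential_links": int(potential.sum()),
        "realized_events": int(interactions["count"].sum()),
        "realized_links": int(
            len(interactions.groupby(["bee_species", "plant_species"]))
        ),
    }
    return {"specimens": specimens, "interactions": interactions,
            "bee_truth": bee_truth, "bookkeeping": bookkeeping}


# ---------------------------------------------------------------------------
# Abundance from the NB2 random-intercept GLMM


def generate_abundance(
    params: SimParams, covariates: pd.DataFrame, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw counts for every species x site cell from the true GLMM.

    *covariates* must hold one row per cell with columns ``bee_species``,
    ``site``, ``effort_h`` and every standardized predictor named in the
    true coefficient vector (interaction terms are formed as products).
    Counts are NB2 via the gamma-Poisson mixture; sigma_re = 0 disables the
    random intercept and theta -> inf approaches Poisson.
    """
    params.validate()
    if rng is None:
        rng = _rng(params, "abundance")
    need = {"bee_species", "site", "effort_h"}
    if not need.issubset(covariates.columns):
        raise SimulationError(f"covariates missing columns {need - set(covariates.columns)}")
    eta = np.log(covariates["effort_h"].to_numpy(float))
    for term, b in params.beta.items():
        if term == "Intercept":
            eta = eta + b
        elif ":" in term:
            a, c = term.split(":")
            eta = eta + b * covariates[a].to_numpy(float) * covariates[c].to_numpy(float)
        else:
            eta = eta + b * covariates[term].to_numpy(float)
    species, sp_idx = np.unique(covariates["bee_species"], return_inverse=True)
    u = (rng.normal(0.0, params.sigma_re, size=len(species))
         if params.sigma_re > 0 else np.zeros(len(species)))
    mu = np.exp(eta + u[sp_idx])
    lam = rng.gamma(params.theta, mu / params.theta)
    counts = rng.poisson(lam)
    out = covariates[["site", "bee_species"]].copy()
    out["count"] = counts.astype(int)
    return out


# ---------------------------------------------------------------------------
# Full dataset


def full_dataset(params: SimParams | None = None) -> dict:
    """Generate every input table plus ground truth for recovery tests.

    The abundance response is drawn from the true GLMM using covariates
    computed by the pipeline's own stages (allometry fit on the synthetic
    calibration masses, energetics with imputation, metaweb pooling,
    nominal-density completion, availability scaling), so the fitted model
    is exactly correctly specified with respect to the generator.
    """
    from .pipeline import build_model_frame, GLOBAL_TERMS

    params = (params or SimParams()).validate()
    plants = generate_plants(params)
    land = generate_landscape_and_densities(params, plants)
    sites = list(land["sites"]["site"])
    bees = generate_bees_and_networks(params, plants, sites)

    rng_eff = _rng(params, "effort")
    effort = pd.DataFrame(
        {"site": sites,
         "effort_h": rng_eff.uniform(*params.effort_range_h, size=len(sites))}
    )

    # pipeline-computed covariates
    allom = AllometricMassModel().fit(
        bees["specimens"][["length_mm", "family", "sex"]],
        bees["specimens"]["mass_mg"],
    )
    predicted = predict_mass(
        bees["specimens"][["species", "length_mm", "family", "sex"]], allom
    )
    traits = species_mean_mass(predicted)

    resources = build_plant_resources(
        plants["nectar"], plants["pollen"], plants["taxonomy"],
        pollen_cal_per_mg=params.pollen_cal_per_mg,
    )
    networks = build_all_site_networks(bees["interactions"])
    web, web_summary = pool_metaweb(networks)
    density_full = apply_nominal_density(
        list(web.columns), land["density"], params.land_classes
    )
    avail = availability_table(
        web, land["composition"], density_full, resources,
        patch_class="woodland", matrix_classes=params.land_classes,
    )

    frame, scaler = build_model_frame(
        abundance=None, traits=traits, availability=avail,
        composition=land["composition"], effort=effort,
    )
    counts = generate_abundance(
        params, frame[["bee_species", "site", "effort_h",
                       "z_ln_mass", "z_patch", "z_landscape", "z_patch_area"]],
    )
    frame = frame.merge(counts, on=["site", "bee_species"], how="left")
    frame["count"] = frame["count"].fillna(0).astype(int)

    return {
        **plants, **land, **bees,
        "effort": effort,
        "abundance": counts,
        "traits": traits,
        "resources": resources,
        "metaweb": web,
        "metaweb_summary": web_summary,
        "availability": avail,
        "frame": frame,
        "scaler": scaler,
        "allometry_model": allom,
        "global_terms": list(GLOBAL_TERMS),
        "truth": {
            "beta": dict(params.beta),
            "sigma_re": params.sigma_re,
            "theta": params.theta,
            "params": params,
        },
    }
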