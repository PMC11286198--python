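"""Nectar and pollen energy per flower, with taxonomic imputation.

Per-flower nectar energy is the sum over the three dominant nectar sugars
(fructose, glucose, sucrose) of sugar mass (mg) times that sugar's energy
content.  Energy content of a sugar is its heat of combustion (kcal/mol)
divided by its molecular weight (g/mol), which is numerically cal/mg.
Pollen energy per flower is pollen mass (mg) times a mean pollen calorific
content (cal/mg) estimated by bomb calorimetry over a handful of species.

Species without direct nectar or pollen measurements get masses imputed from
the mean of measured congeners, then confamilials, then a configured
literature value; the tier used is recorded as provenance.

Energies are carried per *counting unit* — a single flower for most species,
a capitulum for Asteraceae, a whole inflorescence for a few species — and
the unit label travels with the value so density tables can be checked for
unit agreement downstream.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .io import DEFAULT_POLLEN_CAL_PER_MG, DEFAULT_SUGAR_CONSTANTS, SUGARS


class EnergeticsError(ValueError):
    pass


def sugar_energy_content(
    sugar: str,
    constants: Mapping[str, Mapping[str, float]] | None = None,
) -> float:
    """Energy content of a nectar sugar in cal/mg.

    Computed as heat of combustion (kcal/mol) / molecular weight (g/mol);
    kcal/g equals cal/mg, so the ratio is already in the right unit.
    """
    constants = constants if constants is not None else DEFAULT_SUGAR_CONSTANTS
    if sugar not in constants:
        raise EnergeticsError(f"unknown sugar {sugar!r}; known: {sorted(constants)}")
    c = constants[sugar]
    return c["heat_of_combustion_kcal_mol"] / c["molecular_weight_g_mol"]


def nectar_energy_per_flower(
    sugar_masses_mg: Mapping[str, float],
    constants: Mapping[str, Mapping[str, float]] | None = None,
) -> float:
    """Nectar energy (cal) per flower from per-sugar masses (mg)."""
    total = 0.0
    for sugar, mass in sugar_masses_mg.items():
        if mass < 0:
            raise EnergeticsError(f"negative {sugar} mass: {mass}")
        total += mass * sugar_energy_content(sugar, constants)
    return total


def pollen_energy_per_flower(
    pollen_mass_mg: float, content_cal_per_mg: float = DEFAULT_POLLEN_CAL_PER_MG
) -> float:
    """Pollen energy (cal) per flower: mass (mg) x calorific content (cal/mg)."""
    if pollen_mass_mg < 0:
        raise EnergeticsError(f"negative pollen mass: {pollen_mass_mg}")
    if content_cal_per_mg <= 0:
        raise EnergeticsError(f"non-positive pollen content: {content_cal_per_mg}")
    return pollen_mass_mg * content_cal_per_mg


def pollen_content_from_calorimetry(calorimetry: pd.DataFrame) -> tuple[float, float]:
    """Mean pollen calorific content (cal/mg) across calorimetry species.

    Each species' replicate measurements are averaged first; the grand mean
    is the unweighted mean of species means and the s.e. is taken across
    species means (NaN with a single species).
    """
    if len(calorimetry) == 0:
        raise EnergeticsError("empty calorimetry table")
    means = calorimetry.groupby("species")["cal_per_mg"].mean()
    grand = float(means.mean())
    se = float(means.std(ddof=1) / np.sqrt(len(means))) if len(means) > 1 else float("nan")
    return grand, se


def impute_missing(
    species: str,
    resource: str,
    values: pd.Series,
    taxonomy: pd.DataFrame,
    literature: Mapping[str, Mapping[str, float]],
    use_genus: bool = True,
    use_family: bool = True,
) -> tuple[float, str]:
    """Impute one missing mass value; returns (value, provenance tier)."""
    tax = taxonomy.set_index("species")
    if species not in tax.index:
        raise EnergeticsError(f"species {species!r} missing from taxonomy table")
    genus, family = tax.loc[species, "genus"], tax.loc[species, "family"]
    measured = values.dropna()
    if use_genus:
        congeners = tax.index[(tax["genus"] == genus) & (tax.index != species)]
        pool = measured.reindex(congeners).dropna()
        if len(pool):
            return float(pool.mean()), "genus"
    if use_family:
        confam = tax.index[(tax["family"] == family) & (tax.index != species)]
        pool = measured.reindex(confam).dropna()
        if len(pool):
            return float(pool.mean()), "family"
    if species in literature and resource in literature[species]:
        return float(literature[species][resource]), "literature"
    raise EnergeticsError(
        f"cannot impute {resource!r} for species {species!r}: no measured "
        "congener, no measured confamilial, no literature override"
    )


def build_plant_resources(
    nectar: pd.DataFrame,
    pollen: pd.DataFrame,
    taxonomy: pd.DataFrame,
    sugar_constants: Mapping[str, Mapping[str, float]] | None = None,
    pollen_cal_per_mg: float = DEFAULT_POLLEN_CAL_PER_MG,
    literature_overrides: Mapping[str, Mapping[str, float]] | None = None,
    impute_genus: bool = True,
    impute_family: bool = True,
) -> pd.DataFrame:
    """Per-species per-unit resource table with derived energies.

    Returns one row per taxonomy species with columns for per-sugar nectar
    masses, pollen mass, nectar/pollen/total energy (cal per counting unit),
    the unit label, and provenance flags (``measured`` / ``genus`` /
    ``family`` / ``literature``) for nectar and pollen.
    """
    literature_overrides = literature_overrides or {}
    species = list(taxonomy["species"])
    if len(set(species)) != len(species):
        raise EnergeticsError("duplicate species in taxonomy table")

    # Per-species mean mass per sugar (mg per unit); absent -> NaN.
    nectar_wide = (
        nectar.groupby(["species", "sugar"])["mass_mg_per_flower"]
        .mean()
        .unstack("sugar")
        .reindex(index=species, columns=list(SUGARS))
    )
    pollen_mean = (
        pollen.groupby("species")["mass_mg_per_flower"].mean().reindex(species)
    )

    rows = []
    for sp in species:
        sugars = nectar_wide.loc[sp]
        nectar_prov = "measured"
        if sugars.isna().all():
            vals = {}
            for sug in SUGARS:
                vals[sug], nectar_prov = impute_missing(
                    sp, f"nectar_{sug}", nectar_wide[sug], taxonomy,
                    literature_overrides, impute_genus, impute_family,
                )
            sugars = pd.Series(vals)
        elif sugars.isna().any():
            # partial measurement: unmeasured sugars treated as zero mass
            sugars = sugars.fillna(0.0)
        pmass = pollen_mean.loc[sp]
        pollen_prov = "measured"
        if pd.isna(pmass):
            pmass, pollen_prov = impute_missing(
                sp, "pollen", pollen_mean, taxonomy,
                literature_overrides, impute_genus, impute_family,
            )
        nectar_cal = nectar_energy_per_flower(
            {s: float(sugars[s]) for s in SUGARS}, sugar_constants
        )
        pollen_cal = pollen_energy_per_flower(float(pmass), pollen_cal_per_mg)
        rows.append(
            {
                "species": sp,
                **{f"{s}_mg": float(sugars[s]) for s in SUGARS},
                "pollen_mg": float(pmass),
                "nectar_cal": nectar_cal,
                "pollen_cal": pollen_cal,
                "total_cal": nectar_cal + pollen_cal,
                "nectar_provenance": nectar_prov,
                "pollen_provenance": pollen_prov,
            }
        )
    out = pd.DataFrame(rows)
    out = out.merge(
        taxonomy[[c for c in ("species", "genus", "family", "origin", "flower_unit")
                  if c in taxonomy.columns]],
        on="species",
    )
    return out
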