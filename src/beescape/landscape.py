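"""Scaling per-flower energy to patch- and landscape-level availability.

Flower densities (counting units per m²) per land-use class come from belt
transects; network plants missed by every transect of a class receive a
nominal density of half the smallest surveyed value in that class.  Energy
per unit area for a bee species in a class is the sum, over its metaweb
partner plants, of density x energy per counting unit.  Patch energy is the
woodland energy-per-area times remnant area; landscape (matrix) energy sums
energy-per-area times class area over the matrix land-use classes inside a
1 km buffer.  Both are reported in megacalories (1 Mcal = 1e6 cal).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

M2_PER_HA = 1e4
CAL_PER_MCAL = 1e6


class LandscapeError(ValueError):
    pass


def density_from_transects(transects: pd.DataFrame) -> pd.DataFrame:
    """Pooled flower-unit densities per (land class, species).

    Density = total units counted across a class's transects / total area
    surveyed in that class.  A transect's area counts once even though the
    table has one row per species observed on it.
    """
    if len(transects) == 0:
        raise LandscapeError("empty transect table")
    areas = (
        transects.drop_duplicates(["land_class", "transect_id"])
        .assign(area_m2=lambda d: d["length_m"] * d["width_m"])
        .groupby("land_class")["area_m2"]
        .sum()
    )
    if (areas <= 0).any():
        raise LandscapeError("zero surveyed area in a land class")
    counts = transects.groupby(["land_class", "species"])["count"].sum()
    out = counts.reset_index()
    out["density_per_m2"] = out.apply(
        lambda r: r["count"] / areas[r["land_class"]], axis=1
    )
    out["provenance"] = "surveyed"
    return out[["land_class", "species", "density_per_m2", "provenance"]]


def apply_nominal_density(
    network_plants, density: pd.DataFrame, land_classes=None
) -> pd.DataFrame:
    """Complete a density table with nominal values for unsurveyed plants.

    Every network plant lacking a surveyed density in a class receives half
    the smallest surveyed density of any species in that class (provenance
    ``nominal``) — the species occurs in the region but below the detection
    threshold of the transects.
    """
    classes = sorted(land_classes) if land_classes is not None else sorted(
        density["land_class"].unique()
    )
    rows = [density]
    for cls in classes:
        surveyed = density[
            (density["land_class"] == cls) & (density["provenance"] == "surveyed")
        ]
        if len(surveyed) == 0:
            raise LandscapeError(f"no surveyed species in land class {cls!r}")
        nominal = 0.5 * float(surveyed["density_per_m2"].min())
        have = set(surveyed["species"])
        missing = [p for p in sorted(set(network_plants)) if p not in have]
        if missing:
            rows.append(
                pd.DataFrame(
                    {
                        "land_class": cls,
                        "species": missing,
                        "density_per_m2": nominal,
                        "provenance": "nominal",
                    }
                )
            )
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["land_class", "species"], ignore_index=True)


def energy_per_area(
    land_class: str,
    partner_plants,
    density: pd.DataFrame,
    resources: pd.DataFrame,
) -> float:
    """Total partner-plant floral energy per m² (cal/m²) in one land class.

    The density table may carry a ``unit`` column; when present it must
    agree with each plant's counting unit in the resource table.
    """
    res = resources.set_index("species")
    dens = density[density["land_class"] == land_class].set_index("species")
    total = 0.0
    for plant in partner_plants:
        if plant not in dens.index:
            raise LandscapeError(
                f"no density for plant {plant!r} in class {land_class!r}; "
                "run apply_nominal_density first"
            )
        if plant not in res.index:
            raise LandscapeError(f"plant {plant!r} missing from resource table")
        if "unit" in dens.columns and not pd.isna(dens.loc[plant, "unit"]):
            if dens.loc[plant, "unit"] != res.loc[plant, "flower_unit"]:
                raise LandscapeError(
                    f"counting-unit mismatch for {plant!r}: density in "
                    f"{dens.loc[plant, 'unit']!r}, energy per "
                    f"{res.loc[plant, 'flower_unit']!r}"
                )
        total += float(dens.loc[plant, "density_per_m2"]) * float(
            res.loc[plant, "total_cal"]
        )
    return total


def availability_table(
    metaweb: pd.DataFrame,
    composition: pd.DataFrame,
    density: pd.DataFrame,
    resources: pd.DataFrame,
    patch_class: str = "woodland",
    matrix_classes=("woodland", "cleared", "pine"),
) -> pd.DataFrame:
    """Per-bee, per-site patch and landscape energy availability (Mcal).

    patch_Mcal  = patch-class energy/m² x remnant area
    landscape_Mcal = sum over matrix classes of energy/m² x buffer class area

    The patch class inside the buffer uses the same density table as the
    remnant itself.
    """
    comp = composition.copy()
    sites = sorted(comp["site"].unique())
    need = set(matrix_classes)
    bees = sorted(metaweb.index)

    # energy per area per bee per class (bees x classes), vectorized
    classes = sorted(need | {patch_class})
    res = resources.set_index("species")
    dens_wide = (
        density.pivot_table(
            index="species", columns="land_class", values="density_per_m2",
            aggfunc="first",
        )
    )
    plants = sorted(metaweb.columns)
    missing_res = [p for p in plants if p not in res.index]
    if missing_res:
        raise LandscapeError(f"plants missing from resource table: {missing_res}")
    for cls in classes:
        if cls not in dens_wide.columns:
            raise LandscapeError(f"no densities for land class {cls!r}")
        gap = [p for p in plants if pd.isna(dens_wide.reindex(plants)[cls]).loc[p]]
        if gap:
            raise LandscapeError(
                f"plants lacking density in class {cls!r}: {gap}; "
                "run apply_nominal_density first"
            )
    D = dens_wide.reindex(index=plants)[classes].to_numpy(float)  # plants x classes
    e = res.reindex(plants)["total_cal"].to_numpy(float)  # plants
    A = (metaweb.reindex(index=bees, columns=plants).to_numpy() > 0).astype(float)
    epa = A @ (D * e[:, None])  # bees x classes, cal/m2
    epa = pd.DataFrame(epa, index=bees, columns=classes)

    patch_area = comp.drop_duplicates("site").set_index("site")["patch_area_ha"] * M2_PER_HA
    buf = comp.pivot_table(
        index="site", columns="land_class", values="buffer_area_m2", aggfunc="sum"
    )
    rows = []
    for site in sites:
        if site not in patch_area.index:
            raise LandscapeError(f"no patch area for site {site!r}")
        for cls in matrix_classes:
            if cls not in buf.columns or pd.isna(buf.loc[site, cls]):
                raise LandscapeError(f"missing buffer area for class {cls!r} at site {site!r}")
        for bee in bees:
            patch_mcal = epa.loc[bee, patch_class] * float(patch_area[site]) / CAL_PER_MCAL
            land_mcal = sum(
                epa.loc[bee, cls] * float(buf.loc[site, cls]) for cls in matrix_classes
            ) / CAL_PER_MCAL
            rows.append(
                {"bee_species": bee, "site": site,
                 "patch_Mcal": patch_mcal, "landscape_Mcal": land_mcal}
            )
    return pd.DataFrame(rows)


def energy_correlation(
    resources: pd.DataFrame, scale: str = "log"
) -> tuple[float, float]:
    """Pearson correlation between pollen and nectar energy per flower.

    On the default log scale, correlation is computed on log10 energies over
    species with both energies positive, excluding species whose energies
    are reported per whole inflorescence (their counting unit makes them
    incommensurable with per-flower/capitulum values).  ``scale='raw'`` uses
    all species on the raw calorie scale.
    """
    if scale not in ("log", "raw"):
        raise LandscapeError(f"scale must be 'log' or 'raw', got {scale!r}")
    df = resources
    if scale == "log":
        df = df[df["flower_unit"] != "inflorescence"]
        df = df[(df["nectar_cal"] > 0) & (df["pollen_cal"] > 0)]
        if len(df) < 3:
            raise LandscapeError("need >=3 species with positive energies")
        x, y = np.log10(df["nectar_cal"]), np.log10(df["pollen_cal"])
    else:
        if len(df) < 3:
            raise LandscapeError("need >=3 species")
        x, y = df["nectar_cal"], df["pollen_cal"]
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
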