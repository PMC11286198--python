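import numpy as np
import pandas as pd
import pytest

from beescape.landscape import (
    LandscapeError,
    apply_nominal_density,
    availability_table,
    density_from_transects,
    energy_correlation,
    energy_per_area,
)


def _density(rows):
    return pd.DataFrame(
        rows, columns=["land_class", "species", "density_per_m2", "provenance"]
    )


def _resources(rows):
    return pd.DataFrame(rows, columns=["species", "total_cal", "flower_unit"])


class TestDensityFromTransects:
    def test_single_transect(self):
        tr = pd.DataFrame(
            [("woodland", "t1", "P", 24, 50.0, 4.0)],
            columns=["land_class", "transect_id", "species", "count",
                     "length_m", "width_m"],
        )
        out = density_from_transects(tr)
        assert out.loc[0, "density_per_m2"] == pytest.approx(24 / 200.0)
        assert out.loc[0, "provenance"] == "surveyed"

    def test_pooling_identity(self):
        # pooled transects equal density of concatenated counts/areas
        tr = pd.DataFrame(
            [
                ("cleared", "t1", "P", 6, 30.0, 4.0),
                ("cleared", "t2", "P", 18, 30.0, 4.0),
            ],
            columns=["land_class", "transect_id", "species", "count",
                     "length_m", "width_m"],
        )
        out = density_from_transects(tr)
        assert out.loc[0, "density_per_m2"] == pytest.approx(24 / 240.0)

    def test_transect_area_counted_once_across_species(self):
        tr = pd.DataFrame(
            [
                ("pine", "t1", "P", 4, 30.0, 4.0),
                ("pine", "t1", "Q", 8, 30.0, 4.0),
            ],
            columns=["land_class", "transect_id", "species", "count",
                     "length_m", "width_m"],
        )
        out = density_from_transects(tr).set_index("species")
        assert out.loc["P", "density_per_m2"] == pytest.approx(4 / 120.0)
        assert out.loc["Q", "density_per_m2"] == pytest.approx(8 / 120.0)


class TestNominalDensity:
    def test_half_of_class_minimum(self):
        dens = _density([("woodland", "P", 0.02, "surveyed"),
                         ("woodland", "Q", 0.50, "surveyed")])
        out = apply_nominal_density(["P", "Q", "R"], dens, ["woodland"])
        nominal = out[(out["species"] == "R")]
        assert nominal["density_per_m2"].iloc[0] == pytest.approx(0.01)
        assert nominal["provenance"].iloc[0] == "nominal"

    def test_surveyed_entries_unchanged(self):
        dens = _density([("woodland", "P", 0.02, "surveyed")])
        out = apply_nominal_density(["P", "R"], dens, ["woodland"])
        surveyed = out[out["species"] == "P"]
        assert surveyed["density_per_m2"].iloc[0] == pytest.approx(0.02)

    def test_per_class_minima_differ(self):
        dens = _density(
            [("woodland", "P", 0.2, "surveyed"), ("pine", "P", 0.04, "surveyed")]
        )
        out = apply_nominal_density(["P", "R"], dens, ["woodland", "pine"])
        r = out[out["species"] == "R"].set_index("land_class")
        assert r.loc["woodland", "density_per_m2"] == pytest.approx(0.1)
        assert r.loc["pine", "density_per_m2"] == pytest.approx(0.02)

    def test_class_without_surveys_rejected(self):
        dens = _density([("woodland", "P", 0.2, "surveyed")])
        with pytest.raises(LandscapeError, match="pine"):
            apply_nominal_density(["P"], dens, ["woodland", "pine"])


class TestEnergyPerArea:
    def test_single_partner_product(self):
        dens = _density([("woodland", "P", 2.0, "surveyed")])
        res = _resources([("P", 5.0, "flower")])
        assert energy_per_area("woodland", ["P"], dens, res) == pytest.approx(10.0)

    def test_empty_partner_set_zero(self):
        dens = _density([("woodland", "P", 2.0, "surveyed")])
        res = _resources([("P", 5.0, "flower")])
        assert energy_per_area("woodland", [], dens, res) == 0.0

    def test_superset_monotonicity(self):
        dens = _density([("woodland", "P", 2.0, "surveyed"),
                         ("woodland", "Q", 1.0, "surveyed")])
        res = _resources([("P", 5.0, "flower"), ("Q", 3.0, "flower")])
        sub = energy_per_area("woodland", ["P"], dens, res)
        sup = energy_per_area("woodland", ["P", "Q"], dens, res)
        assert sup >= sub

    def test_unit_mismatch_rejected(self):
        dens = _density([("woodland", "P", 2.0, "surveyed")])
        dens["unit"] = "flower"
        res = _resources([("P", 5.0, "capitulum")])
        with pytest.raises(LandscapeError, match="P"):
            energy_per_area("woodland", ["P"], dens, res)


class TestAvailability:
    def _setup(self):
        web = pd.DataFrame(
            [[1, 0], [1, 1]], index=["A", "B"], columns=["P", "Q"]
        )
        comp = pd.DataFrame(
            [
                ("s1", 1.0, "woodland", 1e4),
                ("s1", 1.0, "cleared", 2e4),
                ("s1", 1.0, "pine", 0.0),
            ],
            columns=["site", "patch_area_ha", "land_class", "buffer_area_m2"],
        )
        dens = _density(
            [(c, s, d, "surveyed")
             for c, s, d in [("woodland", "P", 2.0), ("woodland", "Q", 1.0),
                             ("cleared", "P", 0.5), ("cleared", "Q", 0.25),
                             ("pine", "P", 0.1), ("pine", "Q", 0.1)]]
        )
        res = _resources([("P", 5.0, "flower"), ("Q", 4.0, "flower")])
        return web, comp, dens, res

    def test_hand_computed_patch_energy(self):
        web, comp, dens, res = self._setup()
        out = availability_table(web, comp, dens, res).set_index(
            ["bee_species", "site"]
        )
        # A: partner P only; woodland 2*5=10 cal/m2 over 1e4 m2 = 0.1 Mcal
        assert out.loc[("A", "s1"), "patch_Mcal"] == pytest.approx(0.1)
        # landscape: woodland 10*1e4 + cleared 2.5*2e4 + pine 0.5*0 = 0.15 Mcal
        assert out.loc[("A", "s1"), "landscape_Mcal"] == pytest.approx(0.15)

    def test_zero_matrix_area_zero_landscape_energy(self):
        web, comp, dens, res = self._setup()
        comp["buffer_area_m2"] = 0.0
        out = availability_table(web, comp, dens, res)
        assert np.allclose(out["landscape_Mcal"], 0.0)

    def test_scale_equivariance_in_areas(self):
        web, comp, dens, res = self._setup()
        base = availability_table(web, comp, dens, res)
        comp2 = comp.copy()
        comp2["buffer_area_m2"] *= 2.0
        doubled = availability_table(web, comp2, dens, res)
        assert np.allclose(doubled["landscape_Mcal"], 2.0 * base["landscape_Mcal"])
        assert np.allclose(doubled["patch_Mcal"], base["patch_Mcal"])

    def test_additivity_over_disjoint_partner_sets(self):
        web, comp, dens, res = self._setup()
        web_a = web.copy(); web_a.loc["B", "Q"] = 0  # B-P only
        web_b = web.copy(); web_b.loc["B", "P"] = 0  # B-Q only
        full = availability_table(web, comp, dens, res).set_index(["bee_species", "site"])
        pa = availability_table(web_a, comp, dens, res).set_index(["bee_species", "site"])
        pb = availability_table(web_b, comp, dens, res).set_index(["bee_species", "site"])
        assert full.loc[("B", "s1"), "landscape_Mcal"] == pytest.approx(
            pa.loc[("B", "s1"), "landscape_Mcal"] + pb.loc[("B", "s1"), "landscape_Mcal"]
        )

    def test_missing_class_area_rejected(self):
        web, comp, dens, res = self._setup()
        with pytest.raises(LandscapeError, match="pine"):
            availability_table(web, comp[comp["land_class"] != "pine"], dens, res)

    def test_brute_force_oracle_on_preset(self, preset_data):
        """Triple-loop recomputation equals the vectorized pipeline output."""
        web = preset_data["metaweb"]
        comp = preset_data["composition"]
        dens = preset_data["density"]
        params = preset_data["truth"]["params"]
        dens_full = apply_nominal_density(
            list(web.columns), dens, params.land_classes
        )
        res = preset_data["resources"]
        out = preset_data["availability"].set_index(["bee_species", "site"])
        d = dens_full.set_index(["land_class", "species"])["density_per_m2"]
        e = res.set_index("species")["total_cal"]
        patch_area = comp.drop_duplicates("site").set_index("site")["patch_area_ha"]
        buf = comp.set_index(["site", "land_class"])["buffer_area_m2"]
        rng = np.random.default_rng(0)
        bees = rng.choice(web.index, size=8, replace=False)
        sites = rng.choice(comp["site"].unique(), size=4, replace=False)
        for bee in bees:
            partners = [p for p in web.columns if web.loc[bee, p] > 0]
            epa = {
                cls: sum(d.loc[(cls, p)] * e.loc[p] for p in partners)
                for cls in params.land_classes
            }
            for site in sites:
                patch = epa["woodland"] * patch_area[site] * 1e4 / 1e6
                land = sum(
                    epa[cls] * buf.loc[(site, cls)] for cls in params.land_classes
                ) / 1e6
                assert out.loc[(bee, site), "patch_Mcal"] == pytest.approx(
                    patch, rel=1e-9
                )
                assert out.loc[(bee, site), "landscape_Mcal"] == pytest.approx(
                    land, rel=1e-9
                )


class TestEnergyCorrelation:
    def _res(self, nectar, pollen, unit="flower"):
        return pd.DataFrame(
            {"species": [f"s{i}" for i in range(len(nectar))],
             "nectar_cal": nectar, "pollen_cal": pollen, "flower_unit": unit}
        )

    def test_proportional_gives_unit_correlation(self):
        n = np.array([1.0, 2.0, 4.0, 8.0])
        res = self._res(n, 3.0 * n)
        assert energy_correlation(res)[0] == pytest.approx(1.0)

    def test_antiproportional_raw_gives_minus_one(self):
        x = np.array([1.0, 2.0, 3.0])
        res = self._res(x, 10.0 - 3.0 * x)
        assert energy_correlation(res, scale="raw")[0] == pytest.approx(-1.0)

    def test_inflorescence_species_excluded_in_log_mode(self):
        n = np.array([1.0, 2.0, 4.0, 8.0])
        res = self._res(n, 3.0 * n)
        res.loc[0, "flower_unit"] = "inflorescence"
        res.loc[0, "pollen_cal"] = 1e6  # would wreck the correlation if included
        assert energy_correlation(res)[0] == pytest.approx(1.0)

    def test_insufficient_species_rejected(self):
        res = self._res(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        with pytest.raises(LandscapeError):
            energy_correlation(res)
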