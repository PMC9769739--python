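"""Medium element accounting, Liebig limitation, and basis conversions."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cellcomp import (
    MediumComponent,
    MediumRecipe,
    MetallomeProfile,
    QuotaError,
    geobacter_medium,
    limiting_nutrient,
    max_cell_density,
    max_current,
    medium_element_concentration,
    nmol_per_mg_protein_to_ug_per_g_dw,
    per_cell_content,
    protein_basis_to_dw,
)


def _recipe(*components):
    return MediumRecipe("test medium", list(components))


IRON_STOCK = MediumComponent("iron", "FeSO4·7H2O", stock_mM=0.36, dose_mL_per_L=10)
IRON_SUPPLEMENT = MediumComponent("iron2", "FeCl2·4H2O", final_uM=20, supplement=True)
ZINC_STOCK = MediumComponent("zinc", "ZnCl2", stock_mM=0.95, dose_mL_per_L=10)


class TestMediumElementConcentration:
    def test_stock_times_dose_gives_micromolar(self):
        profile = medium_element_concentration(_recipe(IRON_STOCK))
        assert profile.umol_per_L["Fe"] == pytest.approx(3.6)
        assert profile.ug_per_L["Fe"] == pytest.approx(201.04, abs=0.01)

    def test_supplements_excluded_by_default_included_on_request(self):
        recipe = _recipe(IRON_STOCK, IRON_SUPPLEMENT)
        without = medium_element_concentration(recipe)
        with_supp = medium_element_concentration(recipe, include_supplements=True)
        assert without.umol_per_L["Fe"] == pytest.approx(3.6)
        assert with_supp.umol_per_L["Fe"] == pytest.approx(23.6)
        assert with_supp.supplements_included and not without.supplements_included

    def test_zinc_concentration(self):
        profile = medium_element_concentration(_recipe(ZINC_STOCK))
        assert profile.umol_per_L["Zn"] == pytest.approx(9.5)
        assert profile.ug_per_L["Zn"] == pytest.approx(9.5 * 65.38, rel=1e-6)

    def test_additive_over_components(self):
        merged = medium_element_concentration(_recipe(IRON_STOCK, ZINC_STOCK))
        fe_only = medium_element_concentration(_recipe(IRON_STOCK))
        zn_only = medium_element_concentration(_recipe(ZINC_STOCK))
        for el in set(fe_only.umol_per_L) | set(zn_only.umol_per_L):
            assert merged.umol_per_L[el] == pytest.approx(
                fe_only.umol_per_L.get(el, 0) + zn_only.umol_per_L.get(el, 0)
            )

    def test_hydrate_water_and_counterions_counted(self):
        profile = medium_element_concentration(_recipe(IRON_STOCK))
        # FeSO4·7H2O: 11 O and 14 H per formula unit
        assert profile.umol_per_L["O"] == pytest.approx(3.6 * 11)
        assert profile.umol_per_L["H"] == pytest.approx(3.6 * 14)
        assert profile.provenance["Fe"] == ["iron"]

    def test_bundled_geobacter_medium_iron(self):
        profile = medium_element_concentration(geobacter_medium())
        assert profile.umol_per_L["Fe"] == pytest.approx(3.6)
        with_supp = medium_element_concentration(geobacter_medium(), include_supplements=True)
        assert with_supp.umol_per_L["Fe"] == pytest.approx(23.6)


class TestMaxCellDensity:
    def test_published_iron_ceiling(self):
        # 201 μg Fe/L over a 1,970 μg/g quota: 0.10 g cells per litre
        assert round(max_cell_density(1970, 201.042), 2) == 0.10

    def test_unit_quota(self):
        assert max_cell_density(100, 100) == 1

    def test_empty_medium_supports_no_growth(self):
        assert max_cell_density(50, 0) == 0

    def test_zero_quota_reported_unbounded_not_divided(self):
        with pytest.raises(QuotaError, match="unbounded"):
            max_cell_density(0, 100)


class TestLimitingNutrient:
    def test_iron_limits_geobacter_medium(self):
        quotas = MetallomeProfile({"Fe": 1970})
        profile = medium_element_concentration(geobacter_medium())
        result = limiting_nutrient(quotas, profile)
        assert result.limiting_element == "Fe"
        assert round(result.limiting_density, 2) == 0.10

    def test_single_element_limiting_by_construction(self):
        quotas = MetallomeProfile({"Zn": 100})
        profile = medium_element_concentration(_recipe(ZINC_STOCK))
        assert limiting_nutrient(quotas, profile).limiting_element == "Zn"

    def test_minimum_rule(self):
        quotas = MetallomeProfile({"Fe": 402.084, "Zn": 3105.55})
        profile = medium_element_concentration(_recipe(IRON_STOCK, ZINC_STOCK))
        result = limiting_nutrient(quotas, profile)
        # densities 0.5 (Fe) and 0.2 (Zn): the smaller wins
        assert result.limiting_element == "Zn"
        assert result.limiting_density == pytest.approx(0.2, rel=1e-3)

    def test_unmatched_elements_reported_not_dropped(self):
        quotas = MetallomeProfile({"Fe": 1970, "Se": 10})
        profile = medium_element_concentration(_recipe(IRON_STOCK))
        result = limiting_nutrient(quotas, profile)
        assert "Se" in result.not_evaluable  # quota but no medium source
        assert "S" in result.not_evaluable  # medium S but no quota

    def test_empty_intersection_is_domain_error(self):
        with pytest.raises(QuotaError, match="no element"):
            limiting_nutrient(
                MetallomeProfile({"Se": 1}),
                medium_element_concentration(_recipe(MediumComponent("salt", "NaCl", final_uM=1))),
            )

    @given(
        quotas=st.dictionaries(
            st.sampled_from(["Fe", "Zn", "Cu", "Mn"]),
            st.floats(1, 1e4),
            min_size=1,
        ),
        avail=st.dictionaries(
            st.sampled_from(["Fe", "Zn", "Cu", "Mn"]),
            st.floats(1, 1e4),
            min_size=4,
            max_size=4,
        ),
    )
    def test_limiting_density_is_the_minimum(self, quotas, avail):
        from cellcomp.metallome import MediumElementProfile
        from cellcomp.chem import ATOMIC_WEIGHTS

        profile = MediumElementProfile(
            "random", umol_per_L={el: v / ATOMIC_WEIGHTS[el] for el, v in avail.items()},
            ug_per_L=dict(avail),
        )
        result = limiting_nutrient(MetallomeProfile(quotas), profile)
        assert all(result.limiting_density <= d + 1e-12 for d in result.density_g_per_L.values())

    def test_monotonicity_in_availability_and_quota(self):
        quotas = MetallomeProfile({"Fe": 1970})
        base = limiting_nutrient(quotas, medium_element_concentration(_recipe(IRON_STOCK)))
        richer = limiting_nutrient(
            quotas, medium_element_concentration(_recipe(IRON_STOCK, IRON_SUPPLEMENT), True)
        )
        hungrier = limiting_nutrient(
            MetallomeProfile({"Fe": 3000}), medium_element_concentration(_recipe(IRON_STOCK))
        )
        assert richer.limiting_density >= base.limiting_density
        assert hungrier.limiting_density <= base.limiting_density


class TestPerCellContent:
    def test_iron_per_cell_at_one_picogram(self):
        assert per_cell_content(1970, 1.0) == pytest.approx(1.97e-6)

    def test_iron_per_cell_range(self):
        lo, hi = per_cell_content(1970, (0.1, 1.0))
        assert lo == pytest.approx(1.97e-7)
        assert hi == pytest.approx(1.97e-6)

    def test_zero_quota_gives_zero(self):
        assert per_cell_content(0, 0.5) == 0

    @given(quota=st.floats(1, 1e4), mass_pg=st.floats(0.01, 10))
    def test_round_trip_against_cells_per_gram(self, quota, mass_pg):
        ng_per_cell = per_cell_content(quota, mass_pg)
        cells_per_g = 1.0 / (mass_pg * 1e-12)
        ug_per_g = ng_per_cell * cells_per_g * 1e-3  # ng -> μg
        assert ug_per_g == pytest.approx(quota, rel=1e-12)


class TestMaxCurrent:
    def test_iron_limited_medium_supports_60_mA(self):
        profile = medium_element_concentration(geobacter_medium())
        density = limiting_nutrient(MetallomeProfile({"Fe": 1970}), profile).limiting_density
        amps = max_current(0.6, round(density, 2), 1.0)
        assert round(amps * 1000) == 60

    def test_zero_density_zero_current(self):
        assert max_current(0.6, 0, 1.0) == 0

    def test_protein_basis_specific_current(self):
        # 0.28 A per g protein at a 215 mg/g protein fraction
        assert protein_basis_to_dw(0.28, 0.215) == pytest.approx(0.0602)


class TestProteinBasisConversions:
    def test_molar_protein_quota_to_dry_weight(self):
        # 4.985 nmol Fe per mg protein at 52.8% protein content
        out = nmol_per_mg_protein_to_ug_per_g_dw(4.985, "Fe", 0.528)
        assert round(out) == 147

    def test_factor_one_is_identity(self):
        assert protein_basis_to_dw(123.4, 1.0) == 123.4

    def test_protein_to_volatile_solids_factor(self):
        # 1,731 μg Fe per g protein with the 0.55 protein->VS factor
        assert round(protein_basis_to_dw(1731, 0.55)) == 952

    def test_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(QuotaError):
            protein_basis_to_dw(1, 1.5)
        with pytest.raises(QuotaError):
            protein_basis_to_dw(1, 0)
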