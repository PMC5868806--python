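"""Budget closure, NGE, processed totals and stoichiometry."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tracerbudget as tb

# Published whole-experiment mean budget terms (umol C per chamber), keyed
# (taxon, food): tissue, respiration, calcification, added.
PUBLISHED_MEANS = {
    ("coral", "bacteria"): (14.8, 256.1, 2.3, 8125.0),
    ("coral", "algae"): (9.4, 98.5, 3.1, 2708.0),
    ("sponge", "bacteria"): (37.2, 308.2, 0.0, 8125.0),
    ("sponge", "algae"): (8.0, 210.7, 0.0, 2708.0),
}


def budget_from_amounts(taxon, food_name, tissue, respiration, calcification, added,
                        biomass=10.0, skeleton=50.0, days=10.0):
    """Push whole-experiment amounts through carbon_budget as constant
    daily rates (the division is undone exactly by the integration)."""
    food = tb.FoodSource(food_name, "C", 0.25, 5.0, added_c=added)
    return tb.carbon_budget(
        tissue_rate=tissue / biomass / days,
        respiration_rate=respiration / biomass / days,
        calcification_rate=calcification / skeleton / days,
        biomass_mmol=biomass,
        skeleton_mmol=skeleton,
        feeding_days=days,
        food=food,
        taxon=taxon,
    )


class TestCarbonBudget:
    @pytest.mark.parametrize(
        "key, expected_unaccounted",
        [
            (("coral", "bacteria"), 7852),
            (("coral", "algae"), 2597),
            (("sponge", "algae"), 2489),
        ],
    )
    def test_closure_matches_published_values(self, key, expected_unaccounted):
        row = budget_from_amounts(*key, *PUBLISHED_MEANS[key])
        assert round(row.unaccounted) == expected_unaccounted

    @pytest.mark.parametrize(
        "key, expected_total",
        [
            (("coral", "bacteria"), 273),
            (("coral", "algae"), 111),
            (("sponge", "bacteria"), 345),
            (("sponge", "algae"), 219),
        ],
    )
    def test_total_processed_matches_published_values(self, key, expected_total):
        row = budget_from_amounts(*key, *PUBLISHED_MEANS[key])
        assert round(tb.total_processed(row)) == expected_total

    def test_zero_rates_leave_everything_unaccounted(self):
        row = budget_from_amounts("coral", "algae", 0.0, 0.0, 0.0, 2708.0)
        assert row.unaccounted == row.added == 2708.0
        assert tb.total_processed(row) == 0.0

    @settings(max_examples=200, derandomize=True)
    @given(
        tissue=st.floats(0, 500),
        resp=st.floats(0, 5000),
        calc=st.floats(0, 50),
        added=st.floats(1, 10000),
    )
    def test_conservation(self, tissue, resp, calc, added):
        row = budget_from_amounts("coral", "algae", tissue, resp, calc, added)
        closure = row.tissue + row.respiration + row.calcification + row.unaccounted
        assert closure == pytest.approx(row.added, abs=1e-9)

    def test_budget_linearity(self):
        one = budget_from_amounts("coral", "algae", 10.0, 100.0, 2.0, 2708.0)
        two = budget_from_amounts("coral", "algae", 20.0, 200.0, 4.0, 2708.0)
        assert two.tissue == pytest.approx(2 * one.tissue)
        assert two.respiration == pytest.approx(2 * one.respiration)
        assert two.calcification == pytest.approx(2 * one.calcification)
        assert two.added == one.added

    def test_negative_component_is_flagged_not_dropped(self):
        row = budget_from_amounts("coral", "algae", -1.0, 100.0, 0.0, 2708.0)
        assert row.flagged_negative
        assert row.tissue < 0  # preserved as-is

    def test_fraction_accounted(self):
        row = budget_from_amounts("coral", "algae", *PUBLISHED_MEANS[("coral", "algae")])
        assert tb.fraction_accounted(row) == pytest.approx(111.0 / 2708.0, abs=5e-4)
        full = budget_from_amounts("coral", "algae", 0.0, 2708.0, 0.0, 2708.0)
        assert tb.fraction_accounted(full) == pytest.approx(1.0)
        empty = budget_from_amounts("coral", "algae", 0.0, 0.0, 0.0, 2708.0)
        assert tb.fraction_accounted(empty) == 0.0


class TestNGE:
    @pytest.mark.parametrize(
        "tissue, resp, expected",
        [(1.0, 1.0, 0.5), (1.0, 0.0, 1.0), (1.0, 9.0, 0.10)],
    )
    def test_reference_values(self, tissue, resp, expected):
        assert tb.net_growth_efficiency(tissue, resp).value == pytest.approx(expected)

    def test_both_zero_is_missing(self):
        assert math.isnan(tb.net_growth_efficiency(0.0, 0.0).value)

    @settings(max_examples=100, derandomize=True)
    @given(
        tissue=st.floats(0.0, 100.0),
        resp=st.floats(0.0, 100.0),
        scale=st.floats(0.01, 100.0),
    )
    def test_bounds_and_scale_invariance(self, tissue, resp, scale):
        if tissue + resp == 0:
            return
        nge = tb.net_growth_efficiency(tissue, resp).value
        assert 0.0 <= nge <= 1.0
        scaled = tb.net_growth_efficiency(tissue * scale, resp * scale).value
        assert scaled == pytest.approx(nge, rel=1e-9)


class TestStoichiometry:
    def test_ratio_of_means(self):
        food = tb.FoodSource("bacteria", "C", 0.25, 4.5, 8125.0)
        rec = tb.stoichiometric_uptake(0.12, 0.08, food, tissue_cn=4.5)
        assert rec.uptake_cn == pytest.approx(1.5)
        assert rec.food_cn == 4.5
        assert tb.stoichiometric_uptake(0.1, 0.1, food, 4.5).uptake_cn == pytest.approx(1.0)

    def test_nonpositive_n_rate_is_undefined(self):
        food = tb.FoodSource("algae", "C", 0.25, 6.6, 2708.0)
        assert tb.stoichiometric_uptake(0.1, 0.0, food, 4.5).uptake_cn is None

    def test_generator_recovers_food_cn(self):
        """With true molar uptake C:N set equal to each food's C:N, the
        recovered stoichiometric ratio lands near the food ratio."""
        base = tb.TruthConfig()
        food_cn = {"algae": 6.6, "bacteria": 4.5}
        # biomass-normalized rates: molar C:N of uptake is
        # (rate_C / rate_N) * tissue C:N, so choose rate_N accordingly
        rates = {
            (taxon, food): tb.TrueRates(
                r.incorporation_c,
                r.incorporation_c * base.tissue_cn[taxon] / food_cn[food],
                r.respiration,
                r.calcification,
            )
            for (taxon, food), r in base.rates.items()
        }
        cfg = tb.TruthConfig(seed=5, noise_sd_permil=0.1, rates=rates)
        exp = tb.generate_experiment(cfg)
        res = tb.analyze(exp.measurements, exp.chambers, exp.foods, run_anova=False)
        stoich = res.stoichiometry
        molar = stoich["uptake_cn"] * stoich["tissue_cn"]
        assert molar.to_numpy() == pytest.approx(
            stoich["food_cn"].to_numpy(), rel=0.15
        )


class TestChamber:
    def test_composition_must_match_specimens(self):
        coral = tb.Specimen("coral", 10.0, 2.0, skeleton_c=100.0)
        food = tb.FoodSource("algae", "C", 0.25, 6.6, 2708.0)
        with pytest.raises(ValueError, match="composition"):
            tb.Chamber("t", "coral+sponge", 1, 10.0, (coral,), (food,))
        chamber = tb.Chamber("t", "coral", 1, 10.0, (coral,), (food,))
        assert chamber.tissue_c_mmol == 10.0
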