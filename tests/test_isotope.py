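"""Delta/fraction arithmetic and the tracer conversion chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tracerbudget as tb
from tracerbudget.isotope import ReferenceRatio


def food(enrichment=0.25, name="algae", element="C", cn=6.6, added_c=2708.0):
    return tb.FoodSource(name, element, enrichment, cn, added_c)


class TestDeltaRatioFraction:
    @pytest.mark.parametrize(
        "delta, element, expected",
        [
            (0.0, "C", 0.0111797),
            (1000.0, "C", 0.0223594),
            (-5.0, "N", 0.0036581175),  # 0.0036765 * 0.995, 6 significant digits
        ],
    )
    def test_delta_to_ratio_reference_cases(self, delta, element, expected):
        assert tb.delta_to_ratio(delta, element) == pytest.approx(expected, rel=1e-5)

    @pytest.mark.parametrize(
        "r, expected",
        [(1.0, 0.5), (0.0111797, 0.0111797 / 1.0111797), (1e-12, 1e-12)],
    )
    def test_ratio_to_fraction(self, r, expected):
        assert tb.ratio_to_fraction(r) == pytest.approx(expected, rel=1e-9)

    def test_fraction_to_delta_inverse_cases(self):
        assert tb.fraction_to_delta(0.0111797 / 1.0111797, "C") == pytest.approx(
            0.0, abs=1e-9
        )
        expected = (1.0 / 0.0111797 - 1.0) * 1000.0
        assert tb.fraction_to_delta(0.5, "C") == pytest.approx(expected, rel=1e-12)

    def test_element_mismatch_names_both_elements(self):
        ref_n = ReferenceRatio.for_element("N")
        with pytest.raises(ValueError, match="'C'.*'N'"):
            tb.delta_to_ratio(0.0, "C", ref=ref_n)

    @pytest.mark.parametrize(
        "func, bad",
        [
            (lambda: tb.delta_to_ratio(-1000.0, "C"), "non-positive"),
            (lambda: tb.ratio_to_fraction(0.0), "must be > 0"),
            (lambda: tb.ratio_to_fraction(-1.0), "must be > 0"),
            (lambda: tb.fraction_to_delta(0.0, "C"), "in \\(0, 1\\)"),
            (lambda: tb.fraction_to_delta(1.0, "N"), "in \\(0, 1\\)"),
            (lambda: tb.delta_to_ratio(0.0, "O"), "unknown element"),
        ],
    )
    def test_domain_errors(self, func, bad):
        with pytest.raises(ValueError, match=bad):
            func()

    @settings(max_examples=300, derandomize=True)
    @given(
        delta=st.floats(-900.0, 50000.0),
        element=st.sampled_from(["C", "N"]),
    )
    def test_roundtrip_identity(self, delta, element):
        back = tb.fraction_to_delta(tb.delta_to_fraction(delta, element), element)
        assert back == pytest.approx(delta, abs=1e-9)

    @settings(max_examples=100, derandomize=True)
    @given(
        d1=st.floats(-900.0, 50000.0),
        d2=st.floats(-900.0, 50000.0),
        element=st.sampled_from(["C", "N"]),
    )
    def test_monotonicity(self, d1, d2, element):
        lo, hi = sorted([d1, d2])
        r_lo, r_hi = tb.delta_to_ratio(lo, element), tb.delta_to_ratio(hi, element)
        assert r_lo <= r_hi
        assert tb.ratio_to_fraction(r_lo) <= tb.ratio_to_fraction(r_hi)


class TestExcessAndUptake:
    def test_excess_is_signed_difference(self):
        assert tb.excess_fraction(0.0150, 0.0110) == pytest.approx(0.0040)
        assert tb.excess_fraction(0.0110, 0.0110) == 0.0
        # unlabeled replicate slightly below its control: sign preserved
        assert tb.excess_fraction(0.01099, 0.0110) < 0

    @pytest.mark.parametrize(
        "excess, pool, enrichment, expected",
        [
            (0.0, 10_000.0, 0.5, 0.0),
            (0.001, 10_000.0, 0.5, 20.0),
            (0.0005, 451.0, 0.25, 0.902),  # mean sponge biomass pool
        ],
    )
    def test_tracer_uptake(self, excess, pool, enrichment, expected):
        got = tb.tracer_uptake(excess, pool, food(enrichment))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_zero_enrichment_is_division_error(self):
        f = food()
        object.__setattr__(f, "enrichment", 0.0)
        with pytest.raises(ZeroDivisionError, match="enrichment"):
            tb.tracer_uptake(0.001, 100.0, f)

    @settings(max_examples=100, derandomize=True)
    @given(
        excess=st.floats(-0.01, 0.1),
        pool=st.floats(1.0, 1e6),
        enrichment=st.floats(0.01, 1.0),
    )
    def test_uptake_linearity(self, excess, pool, enrichment):
        base = tb.tracer_uptake(excess, pool, food(enrichment))
        assert tb.tracer_uptake(2 * excess, pool, food(enrichment)) == pytest.approx(
            2 * base, rel=1e-12, abs=1e-15
        )
        # halving the enrichment doubles the inferred uptake
        assert tb.tracer_uptake(excess, pool, food(enrichment / 2)) == pytest.approx(
            2 * base, rel=1e-12, abs=1e-15
        )


class TestRates:
    def test_biomass_normalized_rate_in_observed_coral_range(self):
        # 14.8 umol over 10 d on 10.128 mmol tissue C
        rate = tb.biomass_normalized_rate(14.8, 10.128, 10.0)
        assert rate == pytest.approx(0.146, abs=5e-4)
        assert 0.08 <= rate <= 0.17

    def test_rate_proportionality(self):
        assert tb.biomass_normalized_rate(0.0, 5.0, 10.0) == 0.0
        one = tb.biomass_normalized_rate(10.0, 5.0, 10.0)
        assert tb.biomass_normalized_rate(10.0, 10.0, 10.0) == pytest.approx(one / 2)

    def test_respiration_rate_worked_example(self):
        # excess 0.0005 in a 2000 umol/L, 10 L chamber, 0.25 enrichment,
        # 2-d incubation, 10 mmol organic C present -> 2.0 umol/mmol/d
        f_start = 0.011
        rate = tb.respiration_rate(
            f_start + 0.0005, f_start, 2000.0, 10.0, food(0.25), 2.0, 10.0
        )
        assert rate == pytest.approx(2.0, rel=1e-12)

    def test_respiration_zero_when_no_enrichment_change(self):
        assert tb.respiration_rate(0.011, 0.011, 2000.0, 10.0, food(), 2.0, 10.0) == 0.0

    def test_calcification_by_subtraction(self):
        assert tb.calcification_uptake(12.0, 9.4) == pytest.approx(2.6)
        assert tb.calcification_uptake(9.4, 9.4) == 0.0
        # as a skeletal rate: 2.6 umol / 100 mmol skeleton / 10 d = 2.6 nmol/mmol/d
        rate_nmol = tb.biomass_normalized_rate(2.6, 100.0, 10.0) * 1000.0
        assert 2.1 <= rate_nmol <= 9.7

    def test_zero_label_identity(self):
        """Sample delta equal to control delta everywhere -> every rate 0."""
        f = tb.delta_to_fraction(-20.0, "C")
        e = tb.excess_fraction(f, f)
        assert tb.tracer_uptake(e, 1e4, food()) == 0.0
        assert tb.respiration_rate(f, f, 2000.0, 10.0, food(), 2.0, 10.0) == 0.0

    def test_chained_operations_match_single_expression_oracle(self):
        """The op chain equals a one-line recomputation from raw deltas."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            d_sample = rng.uniform(-20, 5000)
            d_control = rng.uniform(-25, -15)
            pool = rng.uniform(100, 1e5)
            enr = rng.uniform(0.05, 0.99)
            days = rng.uniform(1, 20)
            r_ref = 0.0111797
            r_s = r_ref * (d_sample / 1000 + 1)
            r_c = r_ref * (d_control / 1000 + 1)
            oracle = (
                (r_s / (r_s + 1) - r_c / (r_c + 1)) * pool / enr / (pool / 1000) / days
            )
            chained = tb.biomass_normalized_rate(
                tb.tracer_uptake(
                    tb.excess_fraction(
                        tb.delta_to_fraction(d_sample, "C"),
                        tb.delta_to_fraction(d_control, "C"),
                    ),
                    pool,
                    food(enr),
                ),
                pool / 1000,
                days,
            )
            assert chained == pytest.approx(oracle, rel=1e-12, abs=1e-15)


class TestDomainTypes:
    def test_food_source_validation(self):
        with pytest.raises(ValueError, match="enrichment"):
            tb.FoodSource("algae", "C", 0.0, 6.6, 100.0)
        with pytest.raises(ValueError, match="cn_ratio"):
            tb.FoodSource("algae", "C", 0.5, -1.0, 100.0)

    def test_specimen_validation(self):
        with pytest.raises(ValueError, match="tissue"):
            tb.Specimen("coral", 0.0, 1.0)
        with pytest.raises(ValueError, match="skeleton"):
            tb.Specimen("coral", 1.0, 0.2, skeleton_c=-5.0)
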