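"""Age-specific rates and direct standardization."""

import numpy as np
import pandas as pd
import pytest

import mcodrates as m
from mcodrates.rates import age_specific_rates, person_years, standardize


def count_table(rows):
    """(period, sex, age_group, group, deaths, ssw) -> weighted count frame."""
    df = pd.DataFrame(
        rows,
        columns=["period", "sex", "age_group", "group", "weighted_deaths", "sum_sq_weights"],
    )
    df.insert(4, "scheme", "UCOD")
    return df


def pop_table(rows):
    return pd.DataFrame(rows, columns=["period", "sex", "age_group", "person_years"])


def simple_std(age_groups, weights):
    return pd.DataFrame({"age_group": age_groups, "std_weight": weights})


class TestPersonYears:
    def test_year_resolution_identity(self):
        pop = pd.DataFrame(
            {"year": [2020], "sex": ["M"], "age_group": ["60-64"], "population": [120000.0]}
        )
        py = person_years(pop, "year")
        assert py.loc[0, "period"] == "2020"
        assert py.loc[0, "person_years"] == 120000.0

    def test_month_resolution_divides_by_twelve(self):
        pop = pd.DataFrame(
            {"year": [2020], "sex": ["M"], "age_group": ["60-64"], "population": [120000.0]}
        )
        py = person_years(pop, "month")
        assert len(py) == 12
        assert (py["person_years"] == 10000.0).all()
        assert sorted(py["period"])[0] == "2020-01"
        # leap/non-leap years treated identically by construction
        pop24 = pop.assign(year=2024)
        assert (person_years(pop24, "month")["person_years"] == 10000.0).all()


class TestAgeSpecificRates:
    def test_rate_arithmetic(self):
        counts = count_table([("2020", "M", "60-64", "DM", 50.0, 50.0)])
        pop = pop_table([("2020", "M", "60-64", 100000.0)])
        rt = age_specific_rates(counts, pop)
        assert rt.loc[0, "rate"] == 50.0
        assert rt.loc[0, "rate_var"] == pytest.approx(1e10 * 50 / 1e10)

    def test_zero_deaths_zero_variance(self):
        counts = count_table([("2020", "M", "60-64", "DM", 0.0, 0.0)])
        pop = pop_table([("2020", "M", "60-64", 1000.0)])
        rt = age_specific_rates(counts, pop)
        assert rt.loc[0, "rate"] == 0.0 and rt.loc[0, "rate_var"] == 0.0

    def test_variance_options_agree_when_weights_are_one(self):
        counts = count_table([("2020", "M", "60-64", "DM", 17.0, 17.0)])
        pop = pop_table([("2020", "M", "60-64", 50000.0)])
        a = age_specific_rates(counts, pop, "poisson")
        b = age_specific_rates(counts, pop, "weighted")
        assert a.loc[0, "rate_var"] == b.loc[0, "rate_var"]

    def test_weighted_variance_smaller_for_fractional_weights(self):
        counts = count_table([("2020", "M", "60-64", "DM", 10.0, 4.0)])
        pop = pop_table([("2020", "M", "60-64", 50000.0)])
        a = age_specific_rates(counts, pop, "poisson")
        b = age_specific_rates(counts, pop, "weighted")
        assert b.loc[0, "rate_var"] < a.loc[0, "rate_var"]

    def test_missing_population_stratum_is_hard_error(self):
        counts = count_table([("2020", "M", "60-64", "DM", 1.0, 1.0)])
        pop = pop_table([("2020", "F", "60-64", 1000.0)])
        with pytest.raises(ValueError, match="2020"):
            age_specific_rates(counts, pop)


class TestStandardize:
    def two_band_rates(self, r1, r2, py=100000.0):
        counts = count_table(
            [("2020", "M", "0-49", "DM", r1 * py / 1e5, 0.0),
             ("2020", "M", "50+", "DM", r2 * py / 1e5, 0.0)]
        )
        pop = pop_table([("2020", "M", "0-49", py), ("2020", "M", "50+", py)])
        return age_specific_rates(counts, pop)

    def test_uniform_rates_reproduced_for_any_standard(self):
        rt = self.two_band_rates(40.0, 40.0)
        for w in ([0.5, 0.5], [0.9, 0.1], [0.123, 0.877]):
            out = standardize(rt, simple_std(["0-49", "50+"], w))
            assert out.loc[0, "asmr"] == pytest.approx(40.0, abs=1e-9)

    def test_degenerate_standard_selects_one_band(self):
        rt = self.two_band_rates(40.0, 200.0)
        out = standardize(rt, simple_std(["0-49", "50+"], [0.0 + 1e-12, 1.0]))
        assert out.loc[0, "asmr"] == pytest.approx(200.0, rel=1e-9)

    def test_hand_computed_fixture(self):
        """Spreadsheet-style oracle: asmr = sum(w_a * 1e5 * d_a / n_a)."""
        deaths = {"0-49": 12.0, "50+": 88.0}
        pops = {"0-49": 400000.0, "50+": 150000.0}
        w = {"0-49": 0.7, "50+": 0.3}
        expected = sum(w[a] * 1e5 * deaths[a] / pops[a] for a in deaths)
        expected_var = sum(w[a] ** 2 * 1e10 * deaths[a] / pops[a] ** 2 for a in deaths)
        counts = count_table(
            [("2020", "M", a, "DM", deaths[a], deaths[a]) for a in deaths]
        )
        pop = pop_table([("2020", "M", a, pops[a]) for a in pops])
        out = standardize(age_specific_rates(counts, pop), simple_std(list(w), list(w.values())))
        assert out.loc[0, "asmr"] == pytest.approx(expected, rel=1e-12)
        assert out.loc[0, "asmr_var"] == pytest.approx(expected_var, rel=1e-12)
        assert out.loc[0, "ci_low"] <= out.loc[0, "asmr"] <= out.loc[0, "ci_high"]

    def test_age_structure_invariance(self):
        """Same age-specific rates, different population structure -> same ASMR."""
        rates = {"0-49": 30.0, "50+": 250.0}
        std = simple_std(list(rates), [0.6, 0.4])
        results = []
        for pops in ({"0-49": 500000.0, "50+": 100000.0}, {"0-49": 80000.0, "50+": 900000.0}):
            counts = count_table(
                [("2020", "M", a, "DM", rates[a] * pops[a] / 1e5, 0.0) for a in rates]
            )
            pop = pop_table([("2020", "M", a, pops[a]) for a in pops])
            results.append(standardize(age_specific_rates(counts, pop), std).loc[0, "asmr"])
        assert results[0] == pytest.approx(results[1], abs=1e-9)

    def test_monotone_in_counts(self):
        rt1 = self.two_band_rates(40.0, 200.0)
        rt2 = self.two_band_rates(40.0, 201.0)
        std = simple_std(["0-49", "50+"], [0.5, 0.5])
        assert (
            standardize(rt2, std).loc[0, "asmr"] > standardize(rt1, std).loc[0, "asmr"]
        )

    def test_gamma_and_normal_agree_at_large_counts(self):
        counts = count_table(
            [("2020", "M", "0-49", "DM", 2500.0, 2500.0),
             ("2020", "M", "50+", "DM", 4000.0, 4000.0)]
        )
        pop = pop_table([("2020", "M", "0-49", 2e6), ("2020", "M", "50+", 1e6)])
        rt = age_specific_rates(counts, pop)
        std = simple_std(["0-49", "50+"], [0.6, 0.4])
        g = standardize(rt, std, ci="gamma").iloc[0]
        n = standardize(rt, std, ci="normal").iloc[0]
        assert g["ci_low"] == pytest.approx(n["ci_low"], rel=0.02)
        assert g["ci_high"] == pytest.approx(n["ci_high"], rel=0.02)

    def test_unnormalized_standard_is_normalized_with_warning(self, caplog):
        rt = self.two_band_rates(40.0, 40.0)
        with caplog.at_level("WARNING", logger="mcodrates.rates"):
            out = standardize(rt, simple_std(["0-49", "50+"], [50.0, 50.0]))
        assert "normaliz" in caplog.text
        assert out.loc[0, "asmr"] == pytest.approx(40.0, abs=1e-9)

    def test_missing_standard_band_is_error(self):
        rt = self.two_band_rates(40.0, 40.0)
        std = simple_std(["0-49", "50+", "unseen"], [0.3, 0.3, 0.4])
        with pytest.raises(ValueError, match="missing standard age bands"):
            standardize(rt, std)

    def test_zero_asmr_gamma_ci(self):
        counts = count_table([("2020", "M", "0-49", "DM", 0.0, 0.0),
                              ("2020", "M", "50+", "DM", 0.0, 0.0)])
        pop = pop_table([("2020", "M", "0-49", 1e5), ("2020", "M", "50+", 1e5)])
        out = standardize(age_specific_rates(counts, pop), simple_std(["0-49", "50+"], [0.5, 0.5]))
        assert out.loc[0, "asmr"] == 0.0
        assert out.loc[0, "ci_low"] == 0.0
        assert out.loc[0, "ci_high"] > 0.0
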