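"""Synthetic registry generator and its closed-form truth tables."""

import dataclasses
import io

import numpy as np
import pandas as pd
import pytest

import mcodrates as m
from mcodrates.icd import CD, COVID19, CVD, DM, GROUPS, ILL_DEFINED, NEOPLASMS, OTHER
from mcodrates.simulate import (
    GROUP_CODES,
    SimConfig,
    default_config,
    simulate_deaths,
    true_asmr,
    true_expected_counts,
)
from mcodrates.weighting import MCOD_EQUAL, MCOD_HALF, SCHEMES, UCOD


def flat_config(hazards_by_group, years=(2021,), pop_per_stratum=50_000.0,
                part2_zero_prob=0.5, part2_lambda=1.0, profile=None,
                competition_prob=0.0, pandemic=False, seed=0, **kw):
    """Single flat hazard per group across all ages and sexes."""
    years = list(years)
    labels = m.age_group_labels(m.DEFAULT_AGE_BREAKS)
    pop = pd.DataFrame(
        [
            {"year": y, "sex": s, "age_group": a, "population": pop_per_stratum}
            for y in years
            for s in ("M", "F")
            for a in labels
        ]
    )
    hz = pd.DataFrame(
        [
            {"group": g, "sex": s, "age_group": a, "rate": hazards_by_group.get(g, 0.0)}
            for g in GROUPS
            for s in ("M", "F")
            for a in labels
        ]
    )
    profile = profile or {g: {OTHER: 1.0} for g in GROUPS}
    return SimConfig(
        years=years,
        population=pop,
        hazards=hz,
        part2_zero_prob={y: part2_zero_prob for y in years},
        part2_lambda={y: part2_lambda for y in years},
        comorbidity_profile=profile,
        pandemic_months={y: list(range(1, 13)) for y in years} if pandemic else {},
        competition_prob=competition_prob,
        seed=seed,
        **kw,
    )


class TestSimulateDeaths:
    def test_zero_hazards_give_empty_output(self):
        cfg = flat_config({})
        assert len(simulate_deaths(cfg)) == 0

    def test_part2_zero_prob_one_gives_empty_part2(self):
        cfg = flat_config({DM: 50.0}, part2_zero_prob=1.0)
        d = simulate_deaths(cfg)
        cc = [c for c in d.columns if c.startswith("cc")]
        assert len(d) > 0
        assert all(d[c].isna().all() for c in cc) or not cc

    def test_poisson_death_count(self):
        """DM hazard 30/100k on 1e6 person-years -> about 300 deaths."""
        cfg = flat_config({DM: 30.0}, pop_per_stratum=1e6 / 36.0, seed=42)
        d = simulate_deaths(cfg)
        n = (m.default_cause_map().map_codes(d["ucod"]) == DM).sum()
        assert abs(n - 300) <= 3 * np.sqrt(300)

    def test_seed_determinism_byte_identical(self, tmp_path):
        cfg = default_config(scale=0.002, seed=9)
        a, b = simulate_deaths(cfg), simulate_deaths(dataclasses.replace(cfg))
        pd.testing.assert_frame_equal(a, b)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        m.write_deaths(a, pa)
        m.write_deaths(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_codes_come_from_group_lists(self):
        d = simulate_deaths(default_config(scale=0.002, seed=3))
        allcodes = {c for codes in GROUP_CODES.values() for c in codes}
        assert set(d["ucod"]) <= allcodes

    def test_missingness_rates(self):
        cfg = default_config(scale=0.02, seed=4)
        d = simulate_deaths(cfg)
        assert d["sex"].isna().mean() == pytest.approx(cfg.missing_sex_prob, abs=3e-4)
        assert d["age"].isna().mean() == pytest.approx(cfg.missing_age_prob, abs=7e-4)

    def test_competition_preserves_total_deaths(self):
        base = flat_config({CVD: 80.0, DM: 40.0}, pandemic=True, seed=11)
        high = dataclasses.replace(base, competition_prob=0.4)
        d0, d1 = simulate_deaths(base), simulate_deaths(high)
        assert len(d0) == len(d1)
        cmap = m.default_cause_map()
        covid0 = (cmap.map_codes(d0["ucod"]) == COVID19).sum()
        covid1 = (cmap.map_codes(d1["ucod"]) == COVID19).sum()
        assert covid1 > covid0


class TestConfigValidation:
    def test_bad_probability_names_field(self):
        with pytest.raises(ValueError, match="competition_prob"):
            flat_config({DM: 10.0}, competition_prob=1.5)

    def test_missing_year_entry(self):
        cfg = flat_config({DM: 10.0})
        with pytest.raises(ValueError, match="part2_lambda"):
            dataclasses.replace(cfg, part2_lambda={})

    def test_non_distribution_profile(self):
        with pytest.raises(ValueError, match="comorbidity_profile"):
            flat_config({DM: 10.0}, profile={DM: {OTHER: 0.7}})

    def test_negative_hazard(self):
        cfg = flat_config({DM: 10.0})
        bad = cfg.hazards.copy()
        bad.loc[0, "rate"] = -1.0
        with pytest.raises(ValueError, match="hazards"):
            dataclasses.replace(cfg, hazards=bad)


def _by_group(truth, sex="M"):
    sub = truth[truth["sex"] == sex]
    return sub.set_index("group")["asmr"]


class TestTruth:
    def test_empty_part2_makes_schemes_identical(self, std):
        cfg = flat_config({DM: 40.0, CVD: 70.0}, part2_zero_prob=1.0)
        tables = [true_asmr(cfg, s, std).set_index(["year", "sex", "group"]) for s in SCHEMES]
        for t in tables[1:]:
            pd.testing.assert_frame_equal(
                tables[0].drop(columns="scheme"), t.drop(columns="scheme")
            )

    def test_forced_single_part2_splits_half(self, std):
        """Only DM deaths, every certificate listing exactly one CVD cause."""
        cfg = flat_config(
            {DM: 40.0},
            part2_zero_prob=0.0,
            part2_lambda=1e-9,  # truncated Poisson collapses onto k=1
            profile={g: {CVD: 1.0} for g in GROUPS},
        )
        t = _by_group(true_asmr(cfg, MCOD_HALF, std))
        ucod = _by_group(true_asmr(cfg, UCOD, std))
        h = ucod[DM]
        assert t[DM] == pytest.approx(0.5 * h, rel=1e-6)
        assert t[CVD] == pytest.approx(0.5 * h, rel=1e-6)

    def test_ill_defined_truth_is_zero(self, std):
        cfg = flat_config({ILL_DEFINED: 30.0, DM: 10.0})
        for s in SCHEMES:
            t = true_asmr(cfg, s, std)
            assert (t.loc[t["group"] == ILL_DEFINED, "asmr"] == 0.0).all()

    def test_truth_conserves_total_across_schemes(self, std):
        cfg = default_config(scale=0.01, seed=0)
        totals = []
        for s in SCHEMES:
            t = true_asmr(cfg, s, std)
            totals.append(
                t.groupby(["year", "sex"])["asmr"].sum().sort_index().to_numpy()
            )
        assert np.allclose(totals[0], totals[1], rtol=1e-12)
        assert np.allclose(totals[0], totals[2], rtol=1e-12)

    def test_competition_shifts_ucod_truth_not_total(self, std):
        base = flat_config({CVD: 80.0, DM: 40.0, COVID19: 20.0}, pandemic=True)
        high = dataclasses.replace(base, competition_prob=0.3)
        t0 = _by_group(true_asmr(base, UCOD, std))
        t1 = _by_group(true_asmr(high, UCOD, std))
        assert t1[COVID19] > t0[COVID19]
        assert t1[CVD] < t0[CVD]
        assert t1.sum() == pytest.approx(t0.sum(), rel=1e-12)

    def test_empirical_matches_truth_large_n(self, cmap, std, small_sim_config):
        """Monte-Carlo check of the closed-form truth on a moderate simulation."""
        cfg = small_sim_config(seed=13, total=2_000_000)
        cleaned = m.clean_records(simulate_deaths(cfg), cmap)
        pop_py = m.person_years(cfg.population, "year")
        for scheme in (UCOD, MCOD_HALF):
            counts = m.aggregate_weights(cleaned, scheme, cmap)
            asmr = m.standardize(m.age_specific_rates(counts, pop_py), std)
            truth = true_asmr(cfg, scheme, std)
            se = m.true_asmr_mc_se(cfg, scheme, std)
            tm = truth.merge(se, on=["year", "sex", "group", "scheme"])
            tm["period"] = tm["year"].astype(str)
            j = asmr.merge(tm, on=["period", "sex", "group"], suffixes=("_emp", "_true"))
            assert len(j) == 14
            z = (j["asmr_emp"] - j["asmr_true"]) / j["mc_se"].replace(0, np.nan)
            assert np.nanmax(np.abs(z)) < 4.0
            exact = j[j["mc_se"] == 0]
            assert (exact["asmr_emp"] == exact["asmr_true"]).all()


def test_part2_completion_drift_reproduced(cmap):
    """Declining empty-Part-II probability shows up in the tabulation."""
    cfg = dataclasses.replace(default_config(scale=0.05, seed=6), competition_prob=0.0)
    cleaned = m.clean_records(simulate_deaths(cfg), cmap)
    t1 = m.characteristics_table(cleaned)
    zero = t1[(t1["section"] == "part2_completion") & (t1["category"] == "0")]
    zero = zero.sort_values("year")
    assert list(zero["year"]) == [2019, 2020, 2021, 2022]
    expected = [cfg.part2_zero_prob[y] * 100 for y in cfg.years]
    assert np.allclose(zero["pct"], expected, atol=1.5)
    # the configured completion gradient (empty share falling over years)
    assert zero["pct"].iloc[0] > zero["pct"].iloc[1] > zero["pct"].iloc[2]
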