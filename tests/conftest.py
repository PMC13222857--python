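import numpy as np
import pandas as pd
import pytest

import mcodrates as m
from mcodrates.icd import COVID19
from mcodrates.simulate import (
    SimConfig,
    _DEFAULT_PROFILE,
    default_hazards,
    default_population,
)


@pytest.fixture(scope="session")
def cmap():
    return m.default_cause_map()


@pytest.fixture(scope="session")
def std():
    return m.default_standard_population()


def make_records(rows):
    """Build a death-record frame from (record_id, year, month, sex, age, ucod, part2)."""
    max_cc = max((len(r[6]) for r in rows), default=0)
    data = []
    for rid, year, month, sex, age, ucod, part2 in rows:
        rec = {
            "record_id": rid,
            "year": year,
            "month": month,
            "sex": sex,
            "age": age,
            "ucod": ucod,
        }
        for j in range(max_cc):
            rec[f"cc{j + 1}"] = part2[j] if j < len(part2) else None
        data.append(rec)
    df = pd.DataFrame(data)
    df["sex"] = df["sex"].astype("string")
    df["age"] = pd.to_numeric(df["age"], errors="coerce")
    return df


@pytest.fixture
def small_sim_config():
    """One-year, small-population config with every mechanism switched on."""

    def _make(seed=0, total=300_000, competition_prob=0.25, part2_zero_prob=0.55,
              missing_sex_prob=0.0, missing_age_prob=0.0, years=(2021,)):
        years = list(years)
        return SimConfig(
            years=years,
            population=default_population(years, total=total),
            hazards=default_hazards(),
            part2_zero_prob={y: part2_zero_prob for y in years},
            part2_lambda={y: 1.0 for y in years},
            comorbidity_profile={g: dict(p) for g, p in _DEFAULT_PROFILE.items()},
            year_multipliers={(y, COVID19): 2.0 for y in years},
            pandemic_months={y: list(range(1, 13)) for y in years},
            competition_prob=competition_prob,
            missing_sex_prob=missing_sex_prob,
            missing_age_prob=missing_age_prob,
            seed=seed,
        )

    return _make
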