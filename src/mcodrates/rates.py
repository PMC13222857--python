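"""Age-specific and directly age-standardized mortality rates per 100,000.

Weighted death counts from the weighting module are divided by person-years
from population projections to give age-specific rates, which are then
directly standardized onto a fixed standard age distribution (the packaged
default is the WHO world standard population 2000-2025, collapsed to 5-year
bands 0-4 ... 80-84, 85+).

Variance of a weighted count is treated, by default, as Poisson with mean
equal to the weighted count ("poisson" option): under the UCOD scheme the
weights are all 1 and this reduces exactly to the classical rate variance.
Because fractional weights are at most 1, the sum of squared weights never
exceeds the weighted count, so the alternative "weighted" option (variance
numerator = sum of squared weights) is never larger.

Confidence intervals for the standardized rate use the Fay-Feuer gamma
method by default (well-behaved at low counts); a symmetric normal interval
is available for cross-checking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "load_population",
    "load_standard_population",
    "default_standard_population",
    "person_years",
    "age_specific_rates",
    "standardize",
]

logger = logging.getLogger(__name__)

PER = 1e5  # rates are reported per 100,000 person-years
Z95 = stats.norm.ppf(0.975)


def load_population(path: str | Path) -> pd.DataFrame:
    """Read a population table ``year,sex,age_group,population``."""
    pop = pd.read_csv(path, dtype={"sex": "string", "age_group": "string"})
    required = {"year", "sex", "age_group", "population"}
    if not required.issubset(pop.columns):
        raise ValueError(f"population file {path} must have columns {sorted(required)}")
    if (pop["population"] <= 0).any():
        raise ValueError("population counts must be positive")
    return pop


def load_standard_population(path: str | Path) -> pd.DataFrame:
    """Read a standard population ``age_group,std_weight`` and normalize.

    Weights are rescaled to sum to 1; a warning is logged if they did not
    already (printed standards often sum to 100 or 100,000).
    """
    std = pd.read_csv(path, dtype={"age_group": "string"})
    required = {"age_group", "std_weight"}
    if not required.issubset(std.columns):
        raise ValueError(f"standard population {path} must have columns {sorted(required)}")
    if (std["std_weight"] <= 0).any():
        raise ValueError("standard weights must be positive")
    total = std["std_weight"].sum()
    if not np.isclose(total, 1.0):
        logger.warning("standard population weights sum to %g; normalizing to 1", total)
        std = std.assign(std_weight=std["std_weight"] / total)
    return std


def default_standard_population() -> pd.DataFrame:
    """The packaged WHO world standard population (2000-2025), normalized."""
    src = resources.files("mcodrates.data") / "who_std_population.csv"
    with resources.as_file(src) as p:
        std = pd.read_csv(p, dtype={"age_group": "string"})
    # the packaged table carries the printed per-100 weights; normalize quietly
    return std.assign(std_weight=std["std_weight"] / std["std_weight"].sum())


def person_years(pop: pd.DataFrame, resolution: str = "year") -> pd.DataFrame:
    """Convert an annual population table into period person-years.

    Annual resolution keys each row by the year; monthly resolution assigns
    each calendar month population/12 person-years (month lengths and leap
    years are deliberately ignored).  Returns columns
    ``period,sex,age_group,person_years``.
    """
    out = pop.copy()
    if resolution == "year":
        out["period"] = out["year"].astype(int).astype(str)
        out["person_years"] = out["population"].astype(float)
        return out[["period", "sex", "age_group", "person_years"]]
    if resolution == "month":
        months = pd.DataFrame({"month": np.arange(1, 13)})
        out = out.merge(months, how="cross")
        out["period"] = (
            out["year"].astype(int).astype(str)
            + "-"
            + out["month"].astype(int).astype(str).str.zfill(2)
        )
        out["person_years"] = out["population"].astype(float) / 12.0
        return out[["period", "sex", "age_group", "person_years"]]
    raise ValueError(f"resolution must be 'year' or 'month', got {resolution!r}")


def age_specific_rates(
    counts: pd.DataFrame,
    pop: pd.DataFrame,
    variance: str = "poisson",
) -> pd.DataFrame:
    """Rates per 100,000 person-years for every stratum in ``counts``.

    ``counts`` is a weighted count table (period, sex, age_group, group,
    scheme, weighted_deaths, sum_sq_weights); ``pop`` is the person-years
    table from :func:`person_years`.  Every count stratum must be covered by
    a person-years row.  ``variance`` selects the numerator of the rate
    variance: the weighted count ("poisson") or the sum of squared weights
    ("weighted"); the two coincide when all weights are 1.
    """
    if variance not in ("poisson", "weighted"):
        raise ValueError(f"variance must be 'poisson' or 'weighted', got {variance!r}")
    merged = counts.merge(pop, on=["period", "sex", "age_group"], how="left")
    missing = merged["person_years"].isna()
    if missing.any():
        strata = (
            merged.loc[missing, ["period", "sex", "age_group"]]
            .drop_duplicates()
            .to_dict("records")
        )
        raise ValueError(f"population table does not cover strata: {strata}")
    py = merged["person_years"].to_numpy(float)
    d = merged["weighted_deaths"].to_numpy(float)
    vnum = d if variance == "poisson" else merged["sum_sq_weights"].to_numpy(float)
    merged["rate"] = PER * d / py
    merged["rate_var"] = PER**2 * vnum / py**2
    return merged


def _gamma_ci(asmr: float, var: float, wmax: float, alpha: float = 0.05):
    """Fay-Feuer gamma interval for a directly standardized rate."""
    if asmr <= 0:
        hi = stats.gamma.ppf(1 - alpha / 2, a=1.0, scale=wmax) if wmax > 0 else 0.0
        return 0.0, float(hi)
    lo = stats.gamma.ppf(alpha / 2, a=asmr**2 / var, scale=var / asmr) if var > 0 else asmr
    shift = asmr + wmax
    vshift = var + wmax**2
    hi = stats.gamma.ppf(1 - alpha / 2, a=shift**2 / vshift, scale=vshift / shift)
    return float(lo), float(hi)


def standardize(
    rates: pd.DataFrame,
    std: pd.DataFrame | None = None,
    ci: str = "gamma",
) -> pd.DataFrame:
    """Directly standardize age-specific rates onto a standard population.

    ``rates`` is the output of :func:`age_specific_rates`.  Every standard
    age band must be present in every stratum (zero-count bands included,
    as :func:`~mcodrates.weighting.aggregate_weights` guarantees).  Returns
    one row per (period, sex, group, scheme) with the age-standardized rate
    per 100,000, its variance, and a 95% confidence interval ("gamma" =
    Fay-Feuer, "normal" = symmetric).
    """
    if ci not in ("gamma", "normal"):
        raise ValueError(f"ci must be 'gamma' or 'normal', got {ci!r}")
    if std is None:
        std = default_standard_population()
    total = std["std_weight"].sum()
    if not np.isclose(total, 1.0):
        logger.warning("standard weights sum to %g; normalizing", total)
        std = std.assign(std_weight=std["std_weight"] / total)

    keys = ["period", "sex", "group", "scheme"]
    merged = rates.merge(std, on="age_group", how="inner")
    got = merged.groupby(keys, observed=True)["age_group"].nunique()
    if (got < len(std)).any():
        bad = got[got < len(std)].index.tolist()
        raise ValueError(f"strata missing standard age bands: {bad}")

    w = merged["std_weight"].to_numpy(float)
    merged["_wr"] = w * merged["rate"].to_numpy(float)
    merged["_wv"] = w**2 * merged["rate_var"].to_numpy(float)
    merged["_winc"] = w * PER / merged["person_years"].to_numpy(float)

    g = merged.groupby(keys, observed=True)
    out = g[["_wr", "_wv"]].sum().rename(columns={"_wr": "asmr", "_wv": "asmr_var"})
    out["_wmax"] = g["_winc"].max()
    out = out.reset_index()

    if ci == "normal":
        half = Z95 * np.sqrt(out["asmr_var"])
        out["ci_low"] = out["asmr"] - half
        out["ci_high"] = out["asmr"] + half
    else:
        los, his = [], []
        for a, v, wm in zip(out["asmr"], out["asmr_var"], out["_wmax"]):
            lo, hi = _gamma_ci(a, v, wm)
            los.append(lo)
            his.append(hi)
        out["ci_low"] = los
        out["ci_high"] = his
    return out.drop(columns="_wmax")
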