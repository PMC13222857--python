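"""Synthetic death-certificate and population generator with closed-form truth.

The generator emulates the statistical structure of national vital-registry
microdata so the whole pipeline (cleaning, imputation, weighting, rates,
contrasts) can be exercised and validated without registry downloads:

* stratified death counts — per (year, sex, 5-year age band, cause group)
  the number of deaths is Poisson with mean ``hazard x population / 1e5``;
* certificate content — a UCOD code drawn uniformly from a small per-group
  code list; a Part II mention count from a zero-inflated Poisson truncated
  at 6 (certificate line limits), whose zero probability and mean drift
  over calendar years the way Part II completeness improves in real data;
  Part II cause groups drawn from a per-UCOD-group comorbidity profile
  (which may include ill-defined mentions, later dropped by cleaning);
* pandemic cause competition — in configured pandemic months, a decedent
  whose UCOD is a chronic circulatory or diabetes cause has, with
  probability ``competition_prob``, COVID-19 recorded as the UCOD while the
  chronic cause is demoted to Part II (total deaths unchanged);
* small missing-completely-at-random gaps in sex and age, at registry-like
  fractions.

Because every ingredient is parametric, the expected weighted cause-
specific rates are available in closed form (:func:`true_asmr`), giving an
exact oracle for parameter-recovery testing.  All randomness flows from one
seed through independent named streams, so the files are byte-identical
under a fixed seed, and enlarging one mechanism's draw does not perturb the
others (e.g. raising ``competition_prob`` relabels a superset of the same
deaths).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .ages import DEFAULT_AGE_BREAKS, age_group_labels
from .icd import CD, COVID19, CVD, DM, GROUPS, ILL_DEFINED, NEOPLASMS, OTHER
from .weighting import MCOD_EQUAL, MCOD_HALF, SCHEMES, UCOD

__all__ = [
    "GROUP_CODES",
    "SimConfig",
    "default_config",
    "simulate_deaths",
    "true_asmr",
    "true_expected_counts",
    "true_asmr_mc_se",
]

#: Small per-group ICD-10 code lists used for sampling certificate codes.
GROUP_CODES: dict[str, list[str]] = {
    NEOPLASMS: ["C16", "C18", "C34", "C50", "C61", "C911"],
    CVD: ["I10", "I21", "I219", "I25", "I50", "I63", "I64"],
    DM: ["E10", "E11", "E119", "E14"],
    CD: ["A09", "A41", "B24", "J15", "J18", "J189"],
    COVID19: ["U071", "U072"],
    ILL_DEFINED: ["R54", "R57", "R99"],
    OTHER: ["K70", "N18", "G30", "F03", "W19", "X95"],
}

#: Chronic UCOD groups subject to pandemic cause competition with COVID-19.
COMPETING_GROUPS = (CVD, DM)

MAX_PART2 = 6  # certificate line limit for Part II mentions


def _stream(seed: int, name: str) -> np.random.Generator:
    """Independent named RNG stream derived from the master seed."""
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


@dataclass
class SimConfig:
    """Full parameterization of the synthetic registry.

    ``population`` has columns (year, sex, age_group, population);
    ``hazards`` has (group, sex, age_group, rate) in deaths per 100,000
    person-years, optionally scaled per calendar year by
    ``year_multipliers[(year, group)]`` (default 1; this is how COVID-19
    absent in 2019 and surging in 2021 is expressed).  ``part2_zero_prob``
    and ``part2_lambda`` give, per year, the probability of an empty Part II
    and the mean of the truncated Poisson governing non-empty counts.
    ``comorbidity_profile`` maps each UCOD group to a categorical
    distribution over Part II cause groups.  ``pandemic_months`` lists, per
    year, the calendar months in which cause competition operates.
    """

    years: list[int]
    population: pd.DataFrame
    hazards: pd.DataFrame
    part2_zero_prob: dict[int, float]
    part2_lambda: dict[int, float]
    comorbidity_profile: dict[str, dict[str, float]]
    year_multipliers: dict[tuple[int, str], float] = field(default_factory=dict)
    pandemic_months: dict[int, list[int]] = field(default_factory=dict)
    competition_prob: float = 0.0
    missing_sex_prob: float = 0.0
    missing_age_prob: float = 0.0
    age_breaks: list[int] = field(default_factory=lambda: list(DEFAULT_AGE_BREAKS))
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("competition_prob", "missing_sex_prob", "missing_age_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"SimConfig.{name} must be in [0, 1], got {v}")
        for y in self.years:
            for name in ("part2_zero_prob", "part2_lambda"):
                d = getattr(self, name)
                if y not in d:
                    raise ValueError(f"SimConfig.{name} lacks year {y}")
            if not 0.0 <= self.part2_zero_prob[y] <= 1.0:
                raise ValueError(f"SimConfig.part2_zero_prob[{y}] outside [0, 1]")
            if self.part2_lambda[y] <= 0:
                raise ValueError(f"SimConfig.part2_lambda[{y}] must be > 0")
        if (self.hazards["rate"] < 0).any():
            raise ValueError("SimConfig.hazards contains negative rates")
        if (self.population["population"] < 0).any():
            raise ValueError("SimConfig.population contains negative counts")
        for g, prof in self.comorbidity_profile.items():
            total = sum(prof.values())
            if abs(total - 1.0) > 1e-9 or any(p < 0 for p in prof.values()):
                raise ValueError(
                    f"SimConfig.comorbidity_profile[{g!r}] must be a distribution "
                    f"(sums to {total})"
                )
        for y, months in self.pandemic_months.items():
            if any(m < 1 or m > 12 for m in months):
                raise ValueError(f"SimConfig.pandemic_months[{y}] outside 1..12")

    def multiplier(self, year: int, group: str) -> float:
        return float(self.year_multipliers.get((year, group), 1.0))


# ---------------------------------------------------------------------------
# Default configuration: a Colombia-like registry, 2019-2022
# ---------------------------------------------------------------------------

_POP_SHARES = {
    "0-4": 0.071, "5-9": 0.074, "10-14": 0.078, "15-19": 0.082,
    "20-24": 0.084, "25-29": 0.082, "30-34": 0.077, "35-39": 0.072,
    "40-44": 0.066, "45-49": 0.059, "50-54": 0.056, "55-59": 0.051,
    "60-64": 0.044, "65-69": 0.035, "70-74": 0.026, "75-79": 0.018,
    "80-84": 0.014, "85+": 0.011,
}

# baseline hazard at ages 60-64 (per 100,000 per year) and log-slope per decade
_HAZARD_SHAPE = {
    NEOPLASMS: (300.0, 0.45),
    CVD: (330.0, 0.80),
    DM: (70.0, 0.65),
    CD: (90.0, 0.50),
    COVID19: (150.0, 0.85),
    ILL_DEFINED: (15.0, 0.50),
    OTHER: (450.0, 0.35),
}

_SEX_MULT = {
    NEOPLASMS: {"M": 1.15, "F": 0.9},
    CVD: {"M": 1.2, "F": 0.9},
    DM: {"M": 1.0, "F": 1.0},
    CD: {"M": 1.2, "F": 0.9},
    COVID19: {"M": 1.3, "F": 0.9},
    ILL_DEFINED: {"M": 1.1, "F": 0.9},
    OTHER: {"M": 1.25, "F": 0.85},
}

_DEFAULT_PROFILE = {
    NEOPLASMS: {CVD: 0.25, DM: 0.12, CD: 0.08, NEOPLASMS: 0.05, OTHER: 0.45, ILL_DEFINED: 0.05},
    CVD: {CVD: 0.20, DM: 0.20, CD: 0.05, NEOPLASMS: 0.03, OTHER: 0.47, ILL_DEFINED: 0.05},
    DM: {CVD: 0.35, DM: 0.05, CD: 0.05, NEOPLASMS: 0.02, OTHER: 0.48, ILL_DEFINED: 0.05},
    CD: {CVD: 0.20, DM: 0.15, CD: 0.05, NEOPLASMS: 0.03, OTHER: 0.52, ILL_DEFINED: 0.05},
    COVID19: {CVD: 0.30, DM: 0.22, CD: 0.04, NEOPLASMS: 0.04, OTHER: 0.35, ILL_DEFINED: 0.05},
    ILL_DEFINED: {OTHER: 0.90, CVD: 0.10},
    OTHER: {CVD: 0.22, DM: 0.10, CD: 0.06, NEOPLASMS: 0.05, OTHER: 0.52, ILL_DEFINED: 0.05},
}


def _age_mid(label: str, breaks: list[int]) -> float:
    labels = age_group_labels(breaks)
    i = labels.index(label)
    if i < len(breaks) - 1:
        return (breaks[i] + breaks[i + 1]) / 2.0
    return breaks[-1] + 5.0


def default_hazards(age_breaks: list[int] = DEFAULT_AGE_BREAKS) -> pd.DataFrame:
    """Gompertz-like default hazards per (group, sex, age band)."""
    rows = []
    for g, (base, slope) in _HAZARD_SHAPE.items():
        for sex in ("M", "F"):
            for lab in age_group_labels(age_breaks):
                mid = _age_mid(lab, age_breaks)
                rate = base * _SEX_MULT[g][sex] * np.exp(slope * (mid - 62.5) / 10.0)
                rows.append({"group": g, "sex": sex, "age_group": lab, "rate": rate})
    return pd.DataFrame(rows)


def default_population(
    years: list[int], total: float = 51_000_000, age_breaks: list[int] = DEFAULT_AGE_BREAKS
) -> pd.DataFrame:
    """A static Colombia-scale population pyramid replicated across years."""
    rows = []
    for y in years:
        for sex, frac in (("M", 0.49), ("F", 0.51)):
            for lab in age_group_labels(age_breaks):
                rows.append(
                    {
                        "year": y,
                        "sex": sex,
                        "age_group": lab,
                        "population": total * frac * _POP_SHARES[lab],
                    }
                )
    return pd.DataFrame(rows)


def default_config(scale: float = 1.0, seed: int = 0) -> SimConfig:
    """The packaged study conditions: a Colombia-like registry, 2019-2022.

    Part II completeness drifts upward over years (empty-Part-II share
    falling from about 67% to 54%), COVID-19 mortality is absent in 2019,
    peaks in 2021 and recedes in 2022, and cause competition operates from
    March 2020 through December 2021.  ``scale`` multiplies the population
    (hence expected death counts) without changing any rate.
    """
    years = [2019, 2020, 2021, 2022]
    return SimConfig(
        years=years,
        population=default_population(years, total=51_000_000 * scale),
        hazards=default_hazards(),
        part2_zero_prob={2019: 0.667, 2020: 0.588, 2021: 0.549, 2022: 0.536},
        part2_lambda={2019: 0.6, 2020: 0.9, 2021: 1.0, 2022: 1.1},
        comorbidity_profile={g: dict(p) for g, p in _DEFAULT_PROFILE.items()},
        year_multipliers={
            (2019, COVID19): 0.0,
            (2020, COVID19): 1.0,
            (2021, COVID19): 2.0,
            (2022, COVID19): 0.15,
        },
        pandemic_months={2020: list(range(3, 13)), 2021: list(range(1, 13))},
        competition_prob=0.25,
        missing_sex_prob=0.0003,
        missing_age_prob=0.0015,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _part2_pmf(cfg: SimConfig, year: int) -> np.ndarray:
    """P(Part II mention count = k), k = 0..6 (zero-inflated, truncated)."""
    pi0 = cfg.part2_zero_prob[year]
    lam = cfg.part2_lambda[year]
    k = np.arange(1, MAX_PART2 + 1)
    pk = stats.poisson.pmf(k, lam)
    pk = pk / pk.sum()
    return np.concatenate([[pi0], (1.0 - pi0) * pk])


def simulate_deaths(cfg: SimConfig) -> pd.DataFrame:
    """Generate one synthetic registry extract as a record frame.

    Columns: ``record_id, year, month, sex, age, ucod, cc1..cc7`` (the
    extra seventh slot holds a demoted chronic cause when competition has
    fired on a certificate already carrying six mentions).  Deterministic
    under ``cfg.seed``.
    """
    labels = age_group_labels(cfg.age_breaks)
    strata = cfg.population.merge(cfg.hazards, on=["sex", "age_group"], how="inner")
    strata["mult"] = [
        cfg.multiplier(y, g) for y, g in zip(strata["year"], strata["group"])
    ]
    strata["mean"] = strata["rate"] * strata["mult"] * strata["population"] / 1e5
    strata = strata.sort_values(["year", "sex", "age_group", "group"], kind="stable")
    strata = strata.reset_index(drop=True)

    n = _stream(cfg.seed, "counts").poisson(strata["mean"].to_numpy())
    rec = strata.loc[strata.index.repeat(n), ["year", "sex", "age_group", "group"]]
    rec = rec.reset_index(drop=True)
    m = len(rec)
    if m == 0:
        cols = ["record_id", "year", "month", "sex", "age", "ucod"]
        return pd.DataFrame(columns=cols)

    # single-year ages uniform within the band (open band: 15-year width)
    rng_age = _stream(cfg.seed, "ages")
    lower = np.array([cfg.age_breaks[labels.index(l)] for l in rec["age_group"]])
    widths_map = {
        l: (hi - lo)
        for l, lo, hi in zip(labels, cfg.age_breaks, cfg.age_breaks[1:])
    }
    widths_map[labels[-1]] = 15
    width = np.array([widths_map[l] for l in rec["age_group"]])
    rec["age"] = lower + rng_age.integers(0, width, size=m)

    rec["month"] = _stream(cfg.seed, "months").integers(1, 13, size=m)

    # UCOD codes uniform within each group's code list
    rng_codes = _stream(cfg.seed, "ucod_codes")
    u = rng_codes.random(m)
    ucod = np.empty(m, dtype=object)
    for g, codes in GROUP_CODES.items():
        mask = (rec["group"] == g).to_numpy()
        ucod[mask] = np.array(codes, dtype=object)[
            (u[mask] * len(codes)).astype(int)
        ]
    rec["ucod"] = ucod

    # Part II mention count: zero-inflated truncated Poisson, per year
    rng_k = _stream(cfg.seed, "part2_count")
    uk = rng_k.random(m)
    k = np.zeros(m, dtype=int)
    for y in cfg.years:
        mask = (rec["year"] == y).to_numpy()
        cum = np.cumsum(_part2_pmf(cfg, y))
        k[mask] = np.searchsorted(cum, uk[mask], side="right")
    k = np.minimum(k, MAX_PART2)

    # pandemic cause competition: chronic UCOD -> COVID-19, chronic demoted
    rng_c = _stream(cfg.seed, "competition")
    uc = rng_c.random(m)
    in_pandemic = np.zeros(m, dtype=bool)
    for y, months in cfg.pandemic_months.items():
        in_pandemic |= (rec["year"] == y).to_numpy() & np.isin(
            rec["month"].to_numpy(), months
        )
    chronic = rec["group"].isin(COMPETING_GROUPS).to_numpy()
    competed = chronic & in_pandemic & (uc < cfg.competition_prob)
    demoted_code = np.where(competed, rec["ucod"].to_numpy(object), None)
    rec.loc[competed, "ucod"] = GROUP_CODES[COVID19][0]
    profile_group = rec["group"].copy()  # comorbidity profile follows original UCOD
    rec.loc[competed, "group"] = COVID19

    # Part II codes from the comorbidity profile of the (original) UCOD group
    rng_p2 = _stream(cfg.seed, "part2_codes")
    total = int(k.sum())
    row_of_code = np.repeat(np.arange(m), k)
    prof_of_code = profile_group.to_numpy(object)[row_of_code]
    up = rng_p2.random(total)
    ug = rng_p2.random(total)
    code_group = np.empty(total, dtype=object)
    for g, prof in cfg.comorbidity_profile.items():
        mask = prof_of_code == g
        if not mask.any():
            continue
        items = sorted(prof.items())
        cum = np.cumsum([p for _, p in items])
        idx = np.searchsorted(cum, up[mask], side="right")
        idx = np.minimum(idx, len(items) - 1)
        code_group[mask] = np.array([lab for lab, _ in items], dtype=object)[idx]
    codes = np.empty(total, dtype=object)
    for g, clist in GROUP_CODES.items():
        mask = code_group == g
        if mask.any():
            codes[mask] = np.array(clist, dtype=object)[
                (ug[mask] * len(clist)).astype(int)
            ]

    # assemble wide cc columns: demoted chronic cause first, then profile draws
    n_cc = k + competed.astype(int)
    max_cc = int(n_cc.max()) if m else 0
    wide = np.full((m, max_cc), None, dtype=object)
    offset = competed.astype(int)
    if competed.any():
        wide[competed, 0] = demoted_code[competed]
    if total:
        pos_within = np.concatenate([np.arange(c) for c in k])
        wide[row_of_code, offset[row_of_code] + pos_within] = codes

    out = pd.DataFrame(
        {
            "record_id": np.char.add("d", np.arange(m).astype(str)),
            "year": rec["year"].to_numpy(),
            "month": rec["month"].to_numpy(),
            "sex": rec["sex"].to_numpy(object),
            "age": rec["age"].to_numpy(float),
            "ucod": rec["ucod"].to_numpy(object),
        }
    )
    for j in range(max_cc):
        out[f"cc{j + 1}"] = wide[:, j]

    # MCAR missingness in demographics
    rng_ms = _stream(cfg.seed, "missing_sex")
    rng_ma = _stream(cfg.seed, "missing_age")
    out.loc[rng_ms.random(m) < cfg.missing_sex_prob, "sex"] = None
    out.loc[rng_ma.random(m) < cfg.missing_age_prob, "age"] = np.nan
    out["sex"] = out["sex"].astype("string")
    return out


# ---------------------------------------------------------------------------
# Closed-form truth
# ---------------------------------------------------------------------------


def _j_distribution(pmf_k: np.ndarray, rho: float) -> np.ndarray:
    """Distribution of the cleaned Part II count j after ill-defined drops.

    Each of the k drawn mentions survives cleaning independently with
    probability 1 - rho, so j | k is binomial.
    """
    pj = np.zeros(MAX_PART2 + 1)
    for k, pk in enumerate(pmf_k):
        for j in range(k + 1):
            pj[j] += pk * stats.binom.pmf(j, k, 1.0 - rho)
    return pj


def _contribution_vector(
    cfg: SimConfig, year: int, g: str, scheme: str, competed: bool
) -> dict[str, float]:
    """Expected weight to each cause group per death with (original) UCOD g."""
    out = {h: 0.0 for h in GROUPS}
    if g == ILL_DEFINED and not competed:
        return out  # excluded from every numerator
    prof = cfg.comorbidity_profile.get(g, {})
    rho = prof.get(ILL_DEFINED, 0.0)
    qprime = {
        h: p / (1.0 - rho) for h, p in prof.items() if h != ILL_DEFINED
    } if rho < 1.0 else {}
    pj = _j_distribution(_part2_pmf(cfg, year), rho)
    j = np.arange(MAX_PART2 + 1)

    ucod_group = COVID19 if competed else g
    if scheme == UCOD:
        out[ucod_group] = 1.0
        return out

    if not competed:
        if scheme == MCOD_HALF:
            p0 = pj[0]
            out[g] += p0 + (1.0 - p0) * 0.5
            for h, q in qprime.items():
                out[h] += (1.0 - p0) * 0.5 * q
        else:  # MCOD_EQUAL
            e1 = float((pj / (j + 1.0)).sum())
            out[g] += e1
            for h, q in qprime.items():
                out[h] += (1.0 - e1) * q
        return out

    # competed: Part II = demoted chronic cause + j surviving profile draws
    if scheme == MCOD_HALF:
        e1 = float((pj / (j + 1.0)).sum())  # E[1/(j+1)]
        out[COVID19] += 0.5
        out[g] += 0.5 * e1
        for h, q in qprime.items():
            out[h] += 0.5 * (1.0 - e1) * q
    else:  # MCOD_EQUAL over j + 2 mentioned causes
        e2 = float((pj / (j + 2.0)).sum())
        ej = float((pj * j / (j + 2.0)).sum())
        out[COVID19] += e2
        out[g] += e2
        for h, q in qprime.items():
            out[h] += ej * q
    return out


def true_expected_counts(cfg: SimConfig, scheme: str) -> pd.DataFrame:
    """Expected weighted deaths per (year, sex, age_group, group) stratum."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    strata = cfg.population.merge(cfg.hazards, on=["sex", "age_group"], how="inner")
    rows = []
    contrib_cache: dict[tuple[int, str, bool], dict[str, float]] = {}
    for (year, sex, age_group), sub in strata.groupby(
        ["year", "sex", "age_group"], observed=True, sort=True
    ):
        totals = {h: 0.0 for h in GROUPS}
        for _, r in sub.iterrows():
            g = r["group"]
            deaths = r["rate"] * cfg.multiplier(year, g) * r["population"] / 1e5
            frac_pandemic = len(cfg.pandemic_months.get(year, [])) / 12.0
            c_eff = (
                cfg.competition_prob * frac_pandemic if g in COMPETING_GROUPS else 0.0
            )
            for competed, share in ((False, 1.0 - c_eff), (True, c_eff)):
                if share == 0.0:
                    continue
                key = (year, g, competed)
                if key not in contrib_cache:
                    contrib_cache[key] = _contribution_vector(
                        cfg, year, g, scheme, competed
                    )
                for h, c in contrib_cache[key].items():
                    totals[h] += deaths * share * c
        pop = sub["population"].iloc[0]
        for h in GROUPS:
            rows.append(
                {
                    "year": year,
                    "sex": sex,
                    "age_group": age_group,
                    "group": h,
                    "expected_weighted_deaths": totals[h],
                    "population": pop,
                }
            )
    return pd.DataFrame(rows)


def true_asmr(cfg: SimConfig, scheme: str, std: pd.DataFrame) -> pd.DataFrame:
    """Closed-form expected ASMR per (year, sex, group) under a scheme.

    ``std`` is a normalized standard population on the same age bands.
    This is the recovery-test oracle: it involves no simulation, only the
    configured hazards, the Part II count distribution, the comorbidity
    profiles, and the competition mechanism.
    """
    ec = true_expected_counts(cfg, scheme)
    ec = ec.merge(std, on="age_group", how="inner")
    ec["wr"] = (
        ec["std_weight"] * 1e5 * ec["expected_weighted_deaths"] / ec["population"]
    )
    out = (
        ec.groupby(["year", "sex", "group"], observed=True)["wr"]
        .sum()
        .rename("asmr")
        .reset_index()
    )
    out["scheme"] = scheme
    return out


def true_asmr_mc_se(cfg: SimConfig, scheme: str, std: pd.DataFrame) -> pd.DataFrame:
    """Conservative Monte-Carlo standard error of the empirical ASMR.

    Weighted per-record contributions lie in (0, 1], so the variance of a
    stratum's weighted count is at most its expectation (compound-Poisson
    bound); the returned SE uses that bound, making 3-SE recovery bands
    slightly conservative.
    """
    ec = true_expected_counts(cfg, scheme)
    ec = ec.merge(std, on="age_group", how="inner")
    ec["v"] = (
        ec["std_weight"] ** 2
        * 1e10
        * ec["expected_weighted_deaths"]
        / ec["population"] ** 2
    )
    out = (
        ec.groupby(["year", "sex", "group"], observed=True)["v"]
        .sum()
        .pow(0.5)
        .rename("mc_se")
        .reset_index()
    )
    out["scheme"] = scheme
    return out
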