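"""Fractional cause-of-death attribution schemes and weighted tabulation.

A death certificate names one underlying cause of death (UCOD) and zero or
more contributing causes in Part II.  Traditional mortality statistics count
each death once, under its UCOD.  The weighted multiple-cause (MCOD)
approach keeps each decedent as the unit of analysis (total weight exactly
1) but splits that weight across the causes mentioned:

* ``UCOD`` — weight 1 on the underlying cause (the traditional statistic);
* ``MCOD_HALF`` — weight 0.5 on the UCOD and 0.5 shared equally among the
  Part II causes (all weight on the UCOD when Part II is empty);
* ``MCOD_EQUAL`` — weight shared equally among UCOD and Part II causes
  (sensitivity scheme: every mentioned cause equally important).

Because each decedent contributes total weight 1 under every scheme, extra
reported causes redistribute weight rather than inflate counts, and summing
weighted deaths over all cause groups always returns the number of analyzed
certificates.

Certificates whose UCOD is an ill-defined cause (chapter XVIII) are excluded
from the numerators entirely — they carry no usable cause information and
cannot enter the weighting.  Ill-defined *mentions* in Part II are likewise
dropped before weights are computed.

Two code paths are provided on purpose: per-record dataclass operations
(:func:`clean_certificate`, :func:`assign_weights`) that implement the rules
literally, and a vectorized :func:`aggregate_weights` over data frames used
by the pipeline.  The two are checked against each other in the test suite.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ages import DEFAULT_AGE_BREAKS, age_group_labels, assign_age_group
from .icd import (
    GROUPS,
    ILL_DEFINED,
    CauseMap,
    normalize_icd10,
    normalize_icd10_series,
)

__all__ = [
    "SCHEMES",
    "UCOD",
    "MCOD_HALF",
    "MCOD_EQUAL",
    "DeathRecord",
    "CleanedRecord",
    "CauseWeight",
    "CleanedData",
    "clean_certificate",
    "assign_weights",
    "read_deaths",
    "write_deaths",
    "clean_records",
    "aggregate_weights",
]

UCOD = "UCOD"
MCOD_HALF = "MCOD_HALF"
MCOD_EQUAL = "MCOD_EQUAL"

#: The three attribution schemes.
SCHEMES = (UCOD, MCOD_HALF, MCOD_EQUAL)

SEXES = ("M", "F")


@dataclass
class DeathRecord:
    """One parsed death certificate (before cleaning)."""

    record_id: str
    year: int
    month: int
    sex: str | None
    age_years: int | None
    ucod: str
    part2: list[str] = field(default_factory=list)


@dataclass
class CleanedRecord:
    """A certificate after normalization, grouping, and exclusion rules.

    ``part2_clean`` keeps the original Part II order but drops codes that
    fail ICD-10 normalization and codes mapping to the ill-defined group.
    ``excluded`` is true exactly when the UCOD maps to the ill-defined group.
    """

    record_id: str
    year: int
    month: int
    sex: str | None
    age_years: int | None
    ucod: str
    ucod_group: str
    excluded: bool
    part2_clean: list[tuple[str, str]] = field(default_factory=list)  # (code, group)


@dataclass(frozen=True)
class CauseWeight:
    """Fractional attribution of one certificate to one mentioned cause."""

    record_id: str
    code: str
    group: str
    weight: float


def clean_certificate(rec: DeathRecord, cmap: CauseMap) -> CleanedRecord:
    """Apply normalization, grouping, and the ill-defined exclusion rules."""
    ucod = normalize_icd10(rec.ucod)
    if ucod is None:
        raise ValueError(f"record {rec.record_id}: UCOD {rec.ucod!r} is not a valid ICD-10 code")
    ucod_group = cmap.group_of(ucod)
    part2_clean = []
    for raw in rec.part2:
        code = normalize_icd10(raw)
        if code is None:
            continue
        group = cmap.group_of(code)
        if group == ILL_DEFINED:
            continue
        part2_clean.append((code, group))
    return CleanedRecord(
        record_id=rec.record_id,
        year=rec.year,
        month=rec.month,
        sex=rec.sex,
        age_years=rec.age_years,
        ucod=ucod,
        ucod_group=ucod_group,
        excluded=(ucod_group == ILL_DEFINED),
        part2_clean=part2_clean,
    )


def assign_weights(rec: CleanedRecord, scheme: str) -> list[CauseWeight]:
    """Fractional weights for one cleaned certificate under one scheme.

    Weights always sum to exactly 1.  Duplicate Part II codes (and Part II
    codes equal to the UCOD) each receive their own weight; accumulation
    into groups happens downstream.  Calling this on an excluded record is
    an error: ill-defined-UCOD deaths carry no weight under any scheme.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if rec.excluded:
        raise ValueError(
            f"record {rec.record_id} is excluded (ill-defined UCOD) and cannot be weighted"
        )
    k = len(rec.part2_clean)
    out: list[CauseWeight] = []
    if scheme == UCOD or k == 0:
        return [CauseWeight(rec.record_id, rec.ucod, rec.ucod_group, 1.0)]
    if scheme == MCOD_HALF:
        out.append(CauseWeight(rec.record_id, rec.ucod, rec.ucod_group, 0.5))
        share = 0.5 / k
    else:  # MCOD_EQUAL
        share = 1.0 / (k + 1)
        out.append(CauseWeight(rec.record_id, rec.ucod, rec.ucod_group, share))
    out.extend(CauseWeight(rec.record_id, code, group, share) for code, group in rec.part2_clean)
    return out


# ---------------------------------------------------------------------------
# Frame-level path (used by the pipeline)
# ---------------------------------------------------------------------------

RECORD_COLUMNS = ["record_id", "year", "month", "sex", "age", "ucod"]


def read_deaths(path: str | Path | io.IOBase) -> pd.DataFrame:
    """Read a delimited death-record file.

    Columns ``record_id,year,month,sex,age,ucod,cc1..ccN`` with a variable
    number of contributing-cause columns; blank cells are ignored.  Sex and
    age may be blank (missing) — they are imputed downstream.
    """
    df = pd.read_csv(path, dtype="string")
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"death-record file lacks required columns {missing}")
    df["year"] = pd.to_numeric(df["year"]).astype(int)
    df["month"] = pd.to_numeric(df["month"]).astype(int)
    df["age"] = pd.to_numeric(df["age"], errors="coerce").astype(float)
    return df


def write_deaths(df: pd.DataFrame, path: str | Path) -> None:
    """Write records in the same delimited layout :func:`read_deaths` reads."""
    out = df.copy()
    out["age"] = out["age"].astype("Int64")
    out.to_csv(path, index=False)


@dataclass
class CleanedData:
    """Frame-level result of cleaning a batch of certificates.

    ``records`` has one row per parse-accepted certificate with columns
    ``record_id, year, month, sex, age, ucod, ucod_group, excluded,
    n_part2, n_part2_clean`` (``n_part2`` counts valid Part II mentions
    before the ill-defined drop, ``n_part2_clean`` after).  ``part2`` is a
    long frame ``record_id, pos, code, group`` of the cleaned mentions.
    """

    records: pd.DataFrame
    part2: pd.DataFrame
    n_rejected: int = 0

    @property
    def n_excluded(self) -> int:
        return int(self.records["excluded"].sum())

    @property
    def n_analyzed(self) -> int:
        return int((~self.records["excluded"]).sum())


def clean_records(df: pd.DataFrame, cmap: CauseMap) -> CleanedData:
    """Vectorized cleaning of a record frame (see :func:`clean_certificate`).

    Records whose UCOD fails ICD-10 normalization are rejected (dropped and
    counted), mirroring registry practice of setting aside unparseable rows.
    """
    df = df.reset_index(drop=True)
    ucod = normalize_icd10_series(df["ucod"])
    rejected = ucod.isna()
    rec = df.loc[~rejected].copy()
    rec["ucod"] = ucod[~rejected]
    rec["ucod_group"] = cmap.map_codes(rec["ucod"])
    rec["excluded"] = rec["ucod_group"] == ILL_DEFINED

    cc_cols = [c for c in df.columns if c.startswith("cc")]
    if cc_cols:
        long = rec.melt(
            id_vars=["record_id"],
            value_vars=cc_cols,
            var_name="pos",
            value_name="raw",
        ).dropna(subset=["raw"])
        long["pos"] = long["pos"].str.removeprefix("cc").astype(int)
        long["code"] = normalize_icd10_series(long["raw"])
        long = long.dropna(subset=["code"])
        long["group"] = cmap.map_codes(long["code"])
        n_part2 = long.groupby("record_id", observed=True).size()
        long = long[long["group"] != ILL_DEFINED]
        n_clean = long.groupby("record_id", observed=True).size()
        part2 = long[["record_id", "pos", "code", "group"]].sort_values(
            ["record_id", "pos"], kind="stable"
        )
        part2 = part2.reset_index(drop=True)
    else:
        n_part2 = pd.Series(dtype=int)
        n_clean = pd.Series(dtype=int)
        part2 = pd.DataFrame(columns=["record_id", "pos", "code", "group"])

    rec["n_part2"] = rec["record_id"].map(n_part2).fillna(0).astype(int)
    rec["n_part2_clean"] = rec["record_id"].map(n_clean).fillna(0).astype(int)
    keep = ["record_id", "year", "month", "sex", "age", "ucod", "ucod_group",
            "excluded", "n_part2", "n_part2_clean"]
    return CleanedData(
        records=rec[keep].reset_index(drop=True),
        part2=part2,
        n_rejected=int(rejected.sum()),
    )


def _period_series(rec: pd.DataFrame, resolution: str) -> pd.Series:
    if resolution == "year":
        return rec["year"].astype(int).astype(str)
    if resolution == "month":
        return (
            rec["year"].astype(int).astype(str)
            + "-"
            + rec["month"].astype(int).astype(str).str.zfill(2)
        )
    raise ValueError(f"period_resolution must be 'year' or 'month', got {resolution!r}")


def _full_grid(periods, age_labels, groups) -> pd.MultiIndex:
    return pd.MultiIndex.from_product(
        [sorted(periods), SEXES, age_labels, list(groups)],
        names=["period", "sex", "age_group", "group"],
    )


def aggregate_weights(
    cleaned: CleanedData,
    scheme: str,
    cmap: CauseMap | None = None,
    period_resolution: str = "year",
    age_breaks: list[int] = DEFAULT_AGE_BREAKS,
) -> pd.DataFrame:
    """Sum fractional weights into a stratified weighted count table.

    Returns one row per (period, sex, age_group, cause group) with the
    scheme label, the weighted death count, and the sum of squared weights
    (kept for the weighted variance option of the rates module).  Strata
    with zero deaths are emitted with zeros so that downstream rate tables
    are complete.  Excluded (ill-defined-UCOD) records contribute nothing.

    Records must be complete on sex and age: imputation runs first.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    rec = cleaned.records.loc[~cleaned.records["excluded"]].copy()
    if rec["sex"].isna().any() or rec["age"].isna().any():
        raise ValueError(
            "records contain missing sex or age; run the imputation module first"
        )

    rec["period"] = _period_series(rec, period_resolution)
    rec["age_group"] = assign_age_group(rec["age"], age_breaks).astype(str)
    k = rec["n_part2_clean"].to_numpy()

    if scheme == UCOD:
        ucod_w = np.ones(len(rec))
    elif scheme == MCOD_HALF:
        ucod_w = np.where(k == 0, 1.0, 0.5)
    else:
        ucod_w = 1.0 / (k + 1.0)

    parts = [
        pd.DataFrame(
            {
                "period": rec["period"].to_numpy(),
                "sex": rec["sex"].to_numpy(),
                "age_group": rec["age_group"].to_numpy(),
                "group": rec["ucod_group"].to_numpy(),
                "weight": ucod_w,
            }
        )
    ]
    if scheme != UCOD and len(cleaned.part2):
        p2 = cleaned.part2.merge(
            rec[["record_id", "period", "sex", "age_group", "n_part2_clean"]],
            on="record_id",
            how="inner",
        )
        kk = p2["n_part2_clean"].to_numpy()
        w = 0.5 / kk if scheme == MCOD_HALF else 1.0 / (kk + 1.0)
        parts.append(
            pd.DataFrame(
                {
                    "period": p2["period"].to_numpy(),
                    "sex": p2["sex"].to_numpy(),
                    "age_group": p2["age_group"].to_numpy(),
                    "group": p2["group"].to_numpy(),
                    "weight": w,
                }
            )
        )

    long = pd.concat(parts, ignore_index=True)
    long["wsq"] = long["weight"] ** 2
    agg = long.groupby(["period", "sex", "age_group", "group"], observed=True)[
        ["weight", "wsq"]
    ].sum()

    groups = cmap.groups if cmap is not None else GROUPS
    grid = _full_grid(rec["period"].unique(), age_group_labels(age_breaks), groups)
    agg = agg.reindex(grid, fill_value=0.0).reset_index()
    agg = agg.rename(columns={"weight": "weighted_deaths", "wsq": "sum_sq_weights"})
    agg.insert(4, "scheme", scheme)
    return agg
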