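"""Discrepancy indicators: MCOD-versus-UCOD rate differences and ratios.

For each stratum (period, sex, cause group) the standardized rate difference
``rd = ASMR_mcod - ASMR_ucod`` and rate ratio ``rr = ASMR_mcod / ASMR_ucod``
quantify how much the weighted multiple-cause attribution moves the
cause-specific mortality estimate away from the traditional single-cause
one.  The null values (0 and 1) mean the two attributions agree.

Two confidence-interval routes are provided.  The analytic route treats the
two ASMRs as independent (variance of the difference = sum of variances,
log-normal interval for the ratio).  Since both rates are computed from the
same decedents they are in fact strongly positively correlated, which makes
the independence interval very conservative — often dramatically so.  The
record-resampling bootstrap (:func:`bootstrap_contrast`) respects that
correlation and is what the pipeline uses by default when the record-level
data are available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .ages import DEFAULT_AGE_BREAKS, age_group_labels
from .icd import GROUPS
from .weighting import MCOD_EQUAL, MCOD_HALF, SCHEMES, UCOD, CleanedData

__all__ = ["rate_contrast", "bootstrap_contrast"]

Z95 = stats.norm.ppf(0.975)
PER = 1e5


def rate_contrast(mcod: pd.DataFrame, ucod: pd.DataFrame) -> pd.DataFrame:
    """Analytic rate difference / ratio between two standardized-rate tables.

    ``mcod`` and ``ucod`` are outputs of :func:`mcodrates.rates.standardize`
    for an MCOD scheme and the UCOD scheme on the same strata.  CIs use the
    independence approximation (see module docstring).  When the UCOD ASMR
    is 0 the ratio is undefined and reported as NaN; the difference is still
    reported.
    """
    keys = ["period", "sex", "group"]
    m = mcod[keys + ["scheme", "asmr", "asmr_var"]].rename(
        columns={"asmr": "asmr_m", "asmr_var": "var_m"}
    )
    u = ucod[keys + ["asmr", "asmr_var"]].rename(
        columns={"asmr": "asmr_u", "asmr_var": "var_u"}
    )
    df = m.merge(u, on=keys, how="inner", validate="one_to_one")
    if len(df) != len(m) or len(df) != len(u):
        raise ValueError("MCOD and UCOD rate tables do not share identical strata")

    df["rd"] = df["asmr_m"] - df["asmr_u"]
    sd = np.sqrt(df["var_m"] + df["var_u"])
    df["rd_lo"] = df["rd"] - Z95 * sd
    df["rd_hi"] = df["rd"] + Z95 * sd

    with np.errstate(divide="ignore", invalid="ignore"):
        rr = np.where(df["asmr_u"] > 0, df["asmr_m"] / df["asmr_u"], np.nan)
        var_log = np.where(
            (df["asmr_m"] > 0) & (df["asmr_u"] > 0),
            df["var_m"] / df["asmr_m"] ** 2 + df["var_u"] / df["asmr_u"] ** 2,
            np.nan,
        )
        df["rr"] = rr
        df["rr_lo"] = np.where(rr == 0, 0.0, rr * np.exp(-Z95 * np.sqrt(var_log)))
        df["rr_hi"] = np.where(rr == 0, 0.0, rr * np.exp(Z95 * np.sqrt(var_log)))
    df.loc[df["rr"] == 0, ["rr_lo", "rr_hi"]] = 0.0
    cols = keys + ["scheme", "asmr_m", "asmr_u", "rd", "rd_lo", "rd_hi", "rr", "rr_lo", "rr_hi"]
    return df[cols]


def _record_contributions(
    cleaned: CleanedData,
    scheme: str,
    pop_py: pd.DataFrame,
    std: pd.DataFrame,
    period_resolution: str,
    age_breaks: list[int],
    groups: tuple[str, ...],
) -> pd.DataFrame:
    """Per-record additive contribution to each group's ASMR under a scheme.

    The ASMR is linear in the per-record weights: record i in age band a of
    cell (period, sex) adds ``std_weight_a * 1e5 / person_years_a * w_ig``
    to group g's ASMR.  Returns a long frame (period, sex, rec_idx, group,
    contrib).
    """
    from .weighting import _period_series, assign_age_group  # local reuse

    rec = cleaned.records.loc[~cleaned.records["excluded"]].copy()
    if rec["sex"].isna().any() or rec["age"].isna().any():
        raise ValueError("records contain missing sex or age; impute first")
    rec["period"] = _period_series(rec, period_resolution)
    rec["age_group"] = assign_age_group(rec["age"], age_breaks).astype(str)
    rec["rec_idx"] = np.arange(len(rec))

    factor = pop_py.merge(std, on="age_group", how="inner")
    factor["f"] = factor["std_weight"] * PER / factor["person_years"]
    rec = rec.merge(
        factor[["period", "sex", "age_group", "f"]],
        on=["period", "sex", "age_group"],
        how="left",
    )
    if rec["f"].isna().any():
        raise ValueError("population/standard tables do not cover all record strata")

    k = rec["n_part2_clean"].to_numpy()
    if scheme == UCOD:
        ucod_w = np.ones(len(rec))
    elif scheme == MCOD_HALF:
        ucod_w = np.where(k == 0, 1.0, 0.5)
    elif scheme == MCOD_EQUAL:
        ucod_w = 1.0 / (k + 1.0)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    parts = [
        pd.DataFrame(
            {
                "period": rec["period"],
                "sex": rec["sex"],
                "rec_idx": rec["rec_idx"],
                "group": rec["ucod_group"],
                "contrib": ucod_w * rec["f"].to_numpy(),
            }
        )
    ]
    if scheme != UCOD and len(cleaned.part2):
        p2 = cleaned.part2.merge(
            rec[["record_id", "period", "sex", "rec_idx", "n_part2_clean", "f"]],
            on="record_id",
            how="inner",
        )
        kk = p2["n_part2_clean"].to_numpy()
        w = 0.5 / kk if scheme == MCOD_HALF else 1.0 / (kk + 1.0)
        parts.append(
            pd.DataFrame(
                {
                    "period": p2["period"],
                    "sex": p2["sex"],
                    "rec_idx": p2["rec_idx"],
                    "group": p2["group"],
                    "contrib": w * p2["f"].to_numpy(),
                }
            )
        )
    long = pd.concat(parts, ignore_index=True)
    return long.groupby(["period", "sex", "rec_idx", "group"], observed=True)[
        "contrib"
    ].sum().reset_index()


def bootstrap_contrast(
    cleaned: CleanedData,
    pop_py: pd.DataFrame,
    std: pd.DataFrame,
    mcod_scheme: str = MCOD_HALF,
    n_boot: int = 500,
    seed: int = 0,
    period_resolution: str = "year",
    age_breaks: list[int] = DEFAULT_AGE_BREAKS,
    groups: tuple[str, ...] = GROUPS,
) -> pd.DataFrame:
    """Record-resampling percentile CIs for the MCOD-vs-UCOD contrast.

    Certificates are resampled with replacement within each (period, sex)
    cell via Poisson(1) resampling weights; both ASMRs, their difference and
    ratio are recomputed per replicate, and 2.5/97.5 percentiles give the
    intervals.  Because each replicate reuses the same certificates for both
    schemes, the MCOD-UCOD correlation is preserved.  Point estimates are
    the full-sample values, identical to the analytic route.
    """
    if mcod_scheme not in (MCOD_HALF, MCOD_EQUAL):
        raise ValueError(f"mcod_scheme must be an MCOD scheme, got {mcod_scheme!r}")
    glist = list(groups)
    gidx = {g: i for i, g in enumerate(glist)}
    cm = _record_contributions(
        cleaned, mcod_scheme, pop_py, std, period_resolution, age_breaks, groups
    )
    cu = _record_contributions(
        cleaned, UCOD, pop_py, std, period_resolution, age_breaks, groups
    )
    rng = np.random.default_rng(seed)
    rows = []
    cells = sorted(set(map(tuple, cm[["period", "sex"]].drop_duplicates().to_numpy())))
    for period, sex in cells:
        sm = cm[(cm["period"] == period) & (cm["sex"] == sex)]
        su = cu[(cu["period"] == period) & (cu["sex"] == sex)]
        ridx = np.unique(np.concatenate([sm["rec_idx"].to_numpy(), su["rec_idx"].to_numpy()]))
        remap = {r: i for i, r in enumerate(ridx)}
        n = len(ridx)
        Am = np.zeros((n, len(glist)))
        Au = np.zeros((n, len(glist)))
        np.add.at(
            Am,
            (sm["rec_idx"].map(remap).to_numpy(), sm["group"].map(gidx).to_numpy()),
            sm["contrib"].to_numpy(),
        )
        np.add.at(
            Au,
            (su["rec_idx"].map(remap).to_numpy(), su["group"].map(gidx).to_numpy()),
            su["contrib"].to_numpy(),
        )
        asmr_m = Am.sum(axis=0)
        asmr_u = Au.sum(axis=0)
        # Poisson(1) multiplier bootstrap, chunked to bound memory
        reps_m = np.empty((n_boot, len(glist)))
        reps_u = np.empty((n_boot, len(glist)))
        chunk = max(1, min(200, int(2e7 // max(n, 1))))
        done = 0
        while done < n_boot:
            b = min(chunk, n_boot - done)
            W = rng.poisson(1.0, size=(b, n)).astype(float)
            reps_m[done : done + b] = W @ Am
            reps_u[done : done + b] = W @ Au
            done += b
        rd_reps = reps_m - reps_u
        with np.errstate(divide="ignore", invalid="ignore"):
            rr_reps = np.where(reps_u > 0, reps_m / reps_u, np.nan)
        for g in glist:
            j = gidx[g]
            rd = asmr_m[j] - asmr_u[j]
            rr = asmr_m[j] / asmr_u[j] if asmr_u[j] > 0 else np.nan
            rd_lo, rd_hi = np.percentile(rd_reps[:, j], [2.5, 97.5])
            col = rr_reps[:, j]
            col = col[np.isfinite(col)]
            if len(col):
                rr_lo, rr_hi = np.percentile(col, [2.5, 97.5])
            else:
                rr_lo = rr_hi = np.nan
            rows.append(
                {
                    "period": period,
                    "sex": sex,
                    "group": g,
                    "scheme": mcod_scheme,
                    "asmr_m": asmr_m[j],
                    "asmr_u": asmr_u[j],
                    "rd": rd,
                    "rd_lo": rd_lo,
                    "rd_hi": rd_hi,
                    "rr": rr,
                    "rr_lo": rr_lo,
                    "rr_hi": rr_hi,
                }
            )
    return pd.DataFrame(rows)
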