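"""Single imputation of missing sex and age on death records.

Registry death files carry small fractions of missing demographics (on the
order of 0.01-0.25%).  Before stratified tabulation these are completed by
single imputation conditional on the observed record-level variables: year,
month, cause group of the UCOD, number of Part II mentions, and the other
demographic where observed.

* sex — logistic regression; the imputed value is a draw from the fitted
  conditional probability (not the modal class), so imputation preserves
  the conditional sex distribution.
* age — either "multinomial_groups" (multinomial logistic regression over
  age bands, then a uniform draw of single years within the sampled band)
  or "pmm" (predictive mean matching: a linear model predicts age, each
  missing record copies the observed age of one of its ``donor_k`` nearest
  donors by predicted mean).

This is deliberately single (not multiple) imputation: downstream rate
variances ignore imputation uncertainty, which is negligible at these
missingness fractions.  Observed values are never modified, the record
count never changes, and a fixed seed gives identical output.  Degenerate
fits (constant predictors, single observed class) fall back to a marginal
draw, with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression, LogisticRegression

from .ages import DEFAULT_AGE_BREAKS, age_group_labels, assign_age_group

__all__ = ["ImputationConfig", "impute_sex", "impute_age", "impute_records"]

logger = logging.getLogger(__name__)


@dataclass
class ImputationConfig:
    """Settings for single imputation of sex and age."""

    sex_method: str = "logistic"
    age_method: str = "pmm"  # or "multinomial_groups"
    seed: int = 0
    donor_k: int = 5
    age_breaks: list[int] = field(default_factory=lambda: list(DEFAULT_AGE_BREAKS))
    #: ceiling used when drawing single years within the open-ended band
    open_band_width: int = 15

    def __post_init__(self) -> None:
        if self.sex_method != "logistic":
            raise ValueError(f"unsupported sex_method {self.sex_method!r}")
        if self.age_method not in ("pmm", "multinomial_groups"):
            raise ValueError(f"unsupported age_method {self.age_method!r}")


def _design_matrix(rec: pd.DataFrame, extra: pd.Series | None = None) -> np.ndarray:
    """Numeric design matrix from the always-observed record covariates."""
    cols = [
        rec["year"].astype(float),
        rec["month"].astype(float),
        rec["n_part2_clean"].astype(float)
        if "n_part2_clean" in rec
        else pd.Series(0.0, index=rec.index),
    ]
    dummies = pd.get_dummies(rec["ucod_group"], prefix="g", dtype=float)
    X = pd.concat(cols + [dummies], axis=1)
    if extra is not None:
        X = pd.concat([X, extra.rename("extra")], axis=1)
    return X.to_numpy(float)


def _standardize_columns(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def impute_sex(
    records: pd.DataFrame, cfg: ImputationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Fill missing sex by a draw from a fitted logistic regression.

    Age enters the model where observed (missing ages are mean-filled with
    an indicator for the fit only).  Raises if no sex is observed.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    rec = records.copy()
    miss = rec["sex"].isna()
    if not miss.any():
        return rec
    obs = ~miss
    if not obs.any():
        raise ValueError("all records have missing sex; imputation model is unfittable")

    y = (rec.loc[obs, "sex"] == "M").to_numpy()
    age_filled = rec["age"].astype(float)
    age_ind = age_filled.isna().astype(float)
    age_filled = age_filled.fillna(age_filled.median() if age_filled.notna().any() else 0.0)
    X = np.column_stack(
        [_design_matrix(rec), age_filled.to_numpy(float), age_ind.to_numpy(float)]
    )
    X = _standardize_columns(X)

    p_miss = None
    if y.all() or not y.any():
        logger.warning("sex observed as a single class; falling back to marginal draw")
        p_miss = np.full(int(miss.sum()), float(y.mean()))
    elif np.allclose(X[obs.to_numpy()].std(axis=0), 0):
        logger.warning("degenerate (constant) predictors; marginal draw for sex")
        p_miss = np.full(int(miss.sum()), float(y.mean()))
    else:
        try:
            model = LogisticRegression(max_iter=200)
            model.fit(X[obs.to_numpy()], y)
            p_miss = model.predict_proba(X[miss.to_numpy()])[:, 1]
        except Exception:  # pragma: no cover - safety net
            logger.warning("logistic fit failed; marginal draw for sex")
            p_miss = np.full(int(miss.sum()), float(y.mean()))

    draws = np.where(rng.random(len(p_miss)) < p_miss, "M", "F")
    rec.loc[miss, "sex"] = draws
    logger.info("imputed sex for %d records", int(miss.sum()))
    return rec


def _sex_numeric(rec: pd.DataFrame) -> pd.Series:
    s = rec["sex"].map({"M": 1.0, "F": 0.0}).astype(float)
    return s.fillna(0.5)


def impute_age(
    records: pd.DataFrame, cfg: ImputationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Fill missing ages by PMM or multinomial age-band imputation."""
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    rec = records.copy()
    miss = rec["age"].isna()
    if not miss.any():
        return rec
    obs = ~miss
    if not obs.any():
        raise ValueError("all records have missing age; imputation model is unfittable")

    X = np.column_stack([_design_matrix(rec), _sex_numeric(rec).to_numpy()])
    X = _standardize_columns(X)
    Xo, Xm = X[obs.to_numpy()], X[miss.to_numpy()]
    y_obs = rec.loc[obs, "age"].to_numpy(float)

    if cfg.age_method == "pmm":
        imputed = _pmm_draw(Xo, y_obs, Xm, cfg.donor_k, rng)
    else:
        imputed = _multinomial_band_draw(rec, obs, miss, Xo, Xm, y_obs, cfg, rng)
    rec.loc[miss, "age"] = imputed
    logger.info("imputed age for %d records", int(miss.sum()))
    return rec


def _pmm_draw(Xo, y_obs, Xm, donor_k, rng) -> np.ndarray:
    """Predictive mean matching: copy the age of a nearby donor."""
    if np.allclose(Xo.std(axis=0), 0):
        logger.warning("degenerate predictors; PMM falls back to random observed donors")
        return y_obs[rng.integers(0, len(y_obs), size=len(Xm))]
    model = LinearRegression().fit(Xo, y_obs)
    pred_obs = model.predict(Xo)
    pred_mis = model.predict(Xm)
    order = np.argsort(pred_obs, kind="stable")
    pred_sorted = pred_obs[order]
    y_sorted = y_obs[order]
    k = min(donor_k, len(y_obs))
    pos = np.searchsorted(pred_sorted, pred_mis)
    out = np.empty(len(Xm))
    for i, (p, j) in enumerate(zip(pred_mis, pos)):
        lo = max(0, j - k)
        hi = min(len(y_sorted), j + k)
        cand = np.arange(lo, hi)
        dist = np.abs(pred_sorted[cand] - p)
        donors = cand[np.argsort(dist, kind="stable")[:k]]
        out[i] = y_sorted[rng.choice(donors)]
    return out


def _multinomial_band_draw(rec, obs, miss, Xo, Xm, y_obs, cfg, rng) -> np.ndarray:
    """Draw an age band from a multinomial logit, then a year within it."""
    labels = age_group_labels(cfg.age_breaks)
    band_obs = assign_age_group(y_obs, cfg.age_breaks).astype(str)
    if band_obs.nunique() < 2 or np.allclose(Xo.std(axis=0), 0):
        logger.warning("degenerate age-band model; marginal band draw")
        probs = np.tile(
            band_obs.value_counts(normalize=True).reindex(labels, fill_value=0.0).to_numpy(),
            (len(Xm), 1),
        )
        classes = np.array(labels)
    else:
        model = LogisticRegression(max_iter=200)
        model.fit(Xo, band_obs.to_numpy())
        probs = model.predict_proba(Xm)
        classes = model.classes_
    cum = probs.cumsum(axis=1)
    u = rng.random(len(Xm))
    pick = (u[:, None] > cum).sum(axis=1)
    bands = classes[pick]
    lowers = {lab: lo for lab, lo in zip(labels, cfg.age_breaks)}
    widths = {
        lab: (hi - lo)
        for lab, lo, hi in zip(labels, cfg.age_breaks, cfg.age_breaks[1:])
    }
    widths[labels[-1]] = cfg.open_band_width
    out = np.array(
        [lowers[b] + rng.integers(0, widths[b]) for b in bands], dtype=float
    )
    return out


def impute_records(
    records: pd.DataFrame, cfg: ImputationConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Impute sex then age with independent seeded streams.

    Returns the completed frame and a small accounting dict (counts of
    values imputed per variable).
    """
    cfg = cfg or ImputationConfig()
    n_sex = int(records["sex"].isna().sum())
    n_age = int(records["age"].isna().sum())
    rec = records
    if n_sex:
        rec = impute_sex(rec, cfg, np.random.default_rng([cfg.seed, 101]))
    if n_age:
        rec = impute_age(rec, cfg, np.random.default_rng([cfg.seed, 202]))
    return rec, {"imputed_sex": n_sex, "imputed_age": n_age}
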