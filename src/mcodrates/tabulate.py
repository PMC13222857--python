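"""Descriptive characteristics tables for a batch of death certificates.

Produces the registry-style overview used to describe the study data: per
calendar year, the number of decedents, the sex split, the distribution
over coarse age bands, deaths by UCOD cause group, and the Part II
completion distribution (how many contributing causes each certificate
carries: 0, 1, 2, 3+).  The completion distribution is reported both for
all valid Part II mentions and after dropping ill-defined mentions, since
the two counts answer different questions about certification practice.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ages import REPORTING_AGE_BREAKS, age_group_labels, assign_age_group
from .weighting import CleanedData

__all__ = ["characteristics_table"]


def _completion_bucket(n: pd.Series) -> pd.Series:
    return pd.cut(
        n, bins=[-0.5, 0.5, 1.5, 2.5, np.inf], labels=["0", "1", "2", "3+"]
    ).astype(str)


def characteristics_table(
    cleaned: CleanedData,
    reporting_breaks: list[int] = REPORTING_AGE_BREAKS,
) -> pd.DataFrame:
    """Long-format characteristics table: year, section, category, n, pct.

    Sections: ``total``, ``sex``, ``age_group`` (records with observed age
    only), ``ucod_group`` (before the ill-defined exclusion, so the
    ill-defined share is visible), ``part2_completion`` (valid mentions)
    and ``part2_completion_clean`` (after dropping ill-defined mentions).
    Percentages are within year.
    """
    rec = cleaned.records
    rows = []

    def add(section: str, series: pd.Series) -> None:
        counts = (
            pd.DataFrame({"year": rec.loc[series.index, "year"], "category": series})
            .groupby(["year", "category"], observed=True)
            .size()
            .rename("n")
            .reset_index()
        )
        totals = counts.groupby("year")["n"].transform("sum")
        counts["pct"] = 100.0 * counts["n"] / totals
        counts.insert(1, "section", section)
        rows.append(counts)

    add("total", pd.Series("all", index=rec.index))
    add("sex", rec["sex"].fillna("missing"))
    aged = rec[rec["age"].notna()]
    age_cat = assign_age_group(aged["age"], reporting_breaks).astype(str)
    labels = age_group_labels(reporting_breaks)
    first = labels[0]
    add("age_group", age_cat.replace({first: f"<{reporting_breaks[1]}"}))
    add("ucod_group", rec["ucod_group"])
    add("part2_completion", _completion_bucket(rec["n_part2"]))
    add("part2_completion_clean", _completion_bucket(rec["n_part2_clean"]))
    return pd.concat(rows, ignore_index=True)
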