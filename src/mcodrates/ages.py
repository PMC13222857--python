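"""Age-band helpers shared by the weighting, rates, and simulation modules.

Two groupings are used throughout: 5-year bands (0-4 ... 80-84, 85+), on
which the WHO world standard population weights are defined and on which all
standardization happens, and coarser reporting bands (<20, decades, 80+)
used for descriptive tabulations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Lower bounds of the 5-year standardization bands; last band is open (85+).
DEFAULT_AGE_BREAKS: list[int] = list(range(0, 90, 5))

#: Lower bounds of the coarser descriptive reporting bands (<20, decades, 80+).
REPORTING_AGE_BREAKS: list[int] = [0, 20, 30, 40, 50, 60, 70, 80]


def age_group_labels(breaks: list[int]) -> list[str]:
    """Labels "b-(next-1)" for each band, open-ended "b+" for the last."""
    _check_breaks(breaks)
    labels = [f"{lo}-{hi - 1}" for lo, hi in zip(breaks[:-1], breaks[1:])]
    labels.append(f"{breaks[-1]}+")
    return labels


def assign_age_group(ages, breaks: list[int] = DEFAULT_AGE_BREAKS) -> pd.Series:
    """Assign each age (in completed years) to its band label.

    Ages below ``breaks[0]`` or missing raise; callers impute first.
    """
    _check_breaks(breaks)
    a = pd.Series(ages).astype(float)
    if a.isna().any():
        raise ValueError("ages contain missing values; run imputation first")
    if (a < breaks[0]).any():
        raise ValueError(f"ages below the first break {breaks[0]} present")
    labels = age_group_labels(breaks)
    idx = np.digitize(a.to_numpy(), breaks[1:], right=False)
    return pd.Series(pd.Categorical.from_codes(idx, categories=labels), index=a.index)


def _check_breaks(breaks: list[int]) -> None:
    if len(breaks) < 1 or any(b >= c for b, c in zip(breaks, breaks[1:])):
        raise ValueError(f"age breaks must be strictly increasing, got {breaks}")
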