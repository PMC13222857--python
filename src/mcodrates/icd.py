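"""ICD-10 code normalization and mapping to condensed cause-of-death groups.

Death registries mix 3- and 4-character ICD-10 codes ("I21", "E119").  For
cause-specific mortality tabulation these are collapsed into a small set of
groups in the spirit of the PAHO/WHO condensed 6/67 list: neoplasms,
circulatory system diseases (CVD), diabetes mellitus (DM), communicable
diseases (CD, excluding COVID-19), COVID-19, ill-defined causes
(chapter XVIII, R00-R99), and a residual.

The group definitions are not hard-coded: a :class:`CauseMap` is an ordered
list of inclusive code-prefix intervals loaded from a delimited text file, so
alternative readings of the condensed list can be dropped in.  Matching is
first-match-wins in file order, which is how the COVID-19 carve-out from the
communicable-diseases chapter is expressed (U071/U072 are listed first).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "GROUPS",
    "NEOPLASMS",
    "CVD",
    "DM",
    "CD",
    "COVID19",
    "ILL_DEFINED",
    "OTHER",
    "normalize_icd10",
    "normalize_icd10_series",
    "CauseRange",
    "CauseMap",
    "load_cause_map",
    "default_cause_map",
]

NEOPLASMS = "NEOPLASMS"
CVD = "CVD"
DM = "DM"
CD = "CD"
COVID19 = "COVID19"
ILL_DEFINED = "ILL_DEFINED"
OTHER = "OTHER"

#: The fixed cause-group labels, in canonical display order.
GROUPS = (NEOPLASMS, CVD, DM, CD, COVID19, ILL_DEFINED, OTHER)

_ICD_RE = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]?$")


def normalize_icd10(raw: object) -> str | None:
    """Normalize a raw cause-of-death code to canonical ICD-10 form.

    Strips whitespace and dots and upper-cases, then validates against the
    pattern letter + two digits + optional alphanumeric 4th character
    ("e11.9" -> "E119").  Returns ``None`` (a rejection value, not an
    exception) when the result is not pattern-valid; the caller decides how
    to treat rejected codes.
    """
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    code = str(raw).strip().upper().replace(".", "")
    return code if _ICD_RE.fullmatch(code) else None


def normalize_icd10_series(raw: pd.Series) -> pd.Series:
    """Vectorized :func:`normalize_icd10`; rejected codes become NaN."""
    s = raw.astype("string").str.strip().str.upper().str.replace(".", "", regex=False)
    ok = s.str.fullmatch(_ICD_RE.pattern, na=False)
    return s.where(ok)


@dataclass(frozen=True)
class CauseRange:
    """One inclusive code-prefix interval belonging to a cause group.

    ``start`` and ``end`` must have equal length (3 or 4 characters); a code
    matches when its prefix of that length falls in ``[start, end]``.  A
    3-character code never matches a 4-character range (its 3-character
    prefix sorts below the range start).
    """

    group: str
    start: str
    end: str

    def __post_init__(self) -> None:
        for bound in (self.start, self.end):
            if not _ICD_RE.fullmatch(bound):
                raise ValueError(f"invalid range bound {bound!r} for group {self.group}")
        if len(self.start) != len(self.end):
            raise ValueError(
                f"range bounds {self.start}-{self.end} for group {self.group} "
                "must have equal length"
            )
        if self.end < self.start:
            raise ValueError(
                f"inverted range {self.start}-{self.end} for group {self.group}"
            )

    def contains(self, code: str) -> bool:
        prefix = code[: len(self.start)]
        return self.start <= prefix <= self.end

    def overlaps(self, other: "CauseRange") -> bool:
        n = min(len(self.start), len(other.start))
        return self.start[:n] <= other.end[:n] and other.start[:n] <= self.end[:n]


@dataclass
class CauseMap:
    """Ordered cause-group mapping; first matching range wins.

    Every syntactically valid code maps to exactly one group: the first
    range (in ``entries`` order) whose interval contains it, else
    ``residual``.  Overlap between ranges of *different* groups is permitted
    (order resolves it); overlap within one group is rejected at load time.
    """

    entries: list[CauseRange]
    residual: str = OTHER

    def __post_init__(self) -> None:
        by_group: dict[str, list[CauseRange]] = {}
        for r in self.entries:
            for prev in by_group.get(r.group, []):
                if r.overlaps(prev):
                    raise ValueError(
                        f"overlapping ranges within group {r.group}: "
                        f"{prev.start}-{prev.end} and {r.start}-{r.end}"
                    )
            by_group.setdefault(r.group, []).append(r)

    @property
    def groups(self) -> tuple[str, ...]:
        seen = dict.fromkeys(r.group for r in self.entries)
        seen.setdefault(self.residual)
        return tuple(seen)

    def group_of(self, code: str) -> str:
        """Map one normalized code to its cause group (never raises)."""
        for r in self.entries:
            if r.contains(code):
                return r.group
        return self.residual

    def map_codes(self, codes: pd.Series) -> pd.Series:
        """Vectorized :meth:`group_of` over a Series of normalized codes.

        NaN codes map to NaN (the caller drops or rejects them upstream).
        """
        s = codes.astype("string")
        out = pd.Series(pd.NA, index=s.index, dtype="string")
        unset = s.notna()
        for r in self.entries:
            prefix = s.str[: len(r.start)]
            hit = unset & (prefix >= r.start) & (prefix <= r.end)
            out[hit] = r.group
            unset &= ~hit
        out[unset] = self.residual
        return out


def load_cause_map(path: str | Path, residual: str = OTHER) -> CauseMap:
    """Load a :class:`CauseMap` from a delimited file.

    Expected columns: ``group,range_start,range_end``.  Row order is the
    match order.  A malformed row (inverted range, bad bound, within-group
    overlap) raises :class:`ValueError` naming the offending row.
    """
    df = pd.read_csv(path, dtype="string")
    required = {"group", "range_start", "range_end"}
    if not required.issubset(df.columns):
        raise ValueError(f"cause map {path} must have columns {sorted(required)}")
    entries = []
    for i, row in df.iterrows():
        try:
            entries.append(
                CauseRange(
                    group=str(row["group"]).strip(),
                    start=str(row["range_start"]).strip().upper(),
                    end=str(row["range_end"]).strip().upper(),
                )
            )
        except ValueError as exc:
            raise ValueError(f"cause map {path}, row {i + 2}: {exc}") from exc
    return CauseMap(entries=entries, residual=residual)


def default_cause_map() -> CauseMap:
    """The packaged default mapping for the seven study groups.

    COVID-19 (U071/U072) is listed before the communicable-diseases ranges
    so that it is carved out of CD by match order.
    """
    with resources.as_file(resources.files("mcodrates.data") / "cause_map.csv") as p:
        return load_cause_map(p)
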