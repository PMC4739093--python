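"""Cohort classification of register records.

Every female resident whose origin traces to one of the listed countries is
assigned to exactly one analysis group, driven by three ages: age at arrival
in the host country, age at the reference date, and the origin country's
customary cutting-age window ``[cut_age_min, cut_age_max]``.

First generation (she migrated herself), with ``a_arr`` = age at arrival and
``a_ref`` = age at the reference date:

* ``1a`` — arrived strictly older than the window (``a_arr > cut_age_max``):
  assumed already cut in proportion to the origin country's 15–49 prevalence.
* ``1c`` — arrived at or below the window's upper bound and still within or
  below it at the reference date (``a_ref <= cut_age_max``).
* ``1b`` — arrived at or below the window's upper bound, now past it but
  still a minor (``cut_age_max < a_ref < 18``).
* ``1x`` — arrived at or below the window's upper bound but 18 or older at
  the reference date.  The model assumes no post-migration cutting, so this
  residual group is neither counted as already cut nor as at risk; it is
  carried explicitly (and can be folded into ``1a`` for table-shape
  compatibility with publications that print only five groups).

Second generation (born in the host country to two parents from listed
countries): ``2a`` if under 18 at the reference date, else ``2b``.

Records that cannot be attributed to a listed country — first generation
born elsewhere, or second generation with fewer than two parents from listed
countries — are ``excluded``.  When the two parents come from two different
listed countries the record is attributed to the mother's country of birth.

Ages are completed years, incrementing on the birthday anniversary.  A
calendar-year mode (age = reference year − birth year), common in register
statistics, is available behind ``age_mode="calendar"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Iterable, TYPE_CHECKING

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .country_profiles import CountryProfile, ProfileSet
    from .synthetic_register import RegisterRecord

__all__ = [
    "Group",
    "GroupCounts",
    "age_on",
    "attributed_country",
    "classify",
    "tabulate",
    "AGE_OF_MAJORITY",
]

AGE_OF_MAJORITY = 18


class Group(str, Enum):
    """Mutually exclusive, exhaustive analysis groups."""

    G1A = "1a"
    G1B = "1b"
    G1C = "1c"
    G1X = "1x"
    G2A = "2a"
    G2B = "2b"
    EXCLUDED = "excluded"


COUNT_COLUMNS = [Group.G1A.value, Group.G1B.value, Group.G1C.value,
                 Group.G1X.value, Group.G2A.value, Group.G2B.value]
_CSV_COLUMNS = ["country", "g1a", "g1b", "g1c", "g1x", "g2a", "g2b"]


def age_on(birth_date: date, at_date: date) -> int:
    """Completed years between ``birth_date`` and ``at_date``.

    Age increments on the anniversary of the birth date (the anniversary day
    itself counts as attained).  Raises ``ValueError`` if ``at_date``
    precedes ``birth_date``.
    """
    if at_date < birth_date:
        raise ValueError(f"at_date {at_date} precedes birth_date {birth_date}")
    years = at_date.year - birth_date.year
    if (at_date.month, at_date.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


def attributed_country(record: "RegisterRecord", profiles: "ProfileSet") -> str | None:
    """Resolve which listed country a record is analysed under.

    First generation: her own country of birth, if listed.  Second
    generation: the mother's country of birth, but only when *both* parents
    were born in listed countries; with one or neither parent from a listed
    country the risk is considered too uncertain and the record is excluded.
    Returns the profile's display name, or ``None`` for excluded records.
    """
    if record.generation == 1:
        profile = profiles.get(record.country_of_birth)
        return profile.country if profile is not None else None
    mother = profiles.get(record.mother_country)
    father = profiles.get(record.father_country)
    if mother is None or father is None:
        return None
    return mother.country


def classify(record: "RegisterRecord", profile: "CountryProfile",
             reference_date: date, age_mode: str = "birthday") -> Group:
    """Assign one record (already attributed to ``profile``) to its group."""
    if age_mode == "birthday":
        a_ref = age_on(record.birth_date, reference_date)
    elif age_mode == "calendar":
        a_ref = reference_date.year - record.birth_date.year
    else:
        raise ValueError(f"unknown age_mode {age_mode!r}")
    if record.generation == 2:
        return Group.G2A if a_ref < AGE_OF_MAJORITY else Group.G2B
    if record.arrival_date is None:
        raise ValueError(f"first-generation record {record.person_id} lacks arrival_date")
    if age_mode == "birthday":
        a_arr = age_on(record.birth_date, record.arrival_date)
    else:
        a_arr = record.arrival_date.year - record.birth_date.year
    if a_arr > profile.cut_age_max:
        return Group.G1A
    if a_ref <= profile.cut_age_max:
        return Group.G1C
    if a_ref < AGE_OF_MAJORITY:
        return Group.G1B
    return Group.G1X


@dataclass
class GroupCounts:
    """Per-country group counts (the publishable tabulation of a register).

    ``counts`` is indexed by country display name with the six group columns
    ``1a,1b,1c,1x,2a,2b``; ``excluded`` holds records attributable to no
    listed country and is kept out of every country row.
    """

    counts: pd.DataFrame
    excluded: int = 0

    def __post_init__(self) -> None:
        self.counts = self.counts.reindex(columns=COUNT_COLUMNS, fill_value=0).astype(int)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("group counts must be non-negative")

    @classmethod
    def empty(cls) -> "GroupCounts":
        frame = pd.DataFrame(columns=COUNT_COLUMNS, index=pd.Index([], name="country"))
        return cls(frame)

    @property
    def group_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def country_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def grand_total(self, include_g1x: bool = True, include_excluded: bool = False) -> int:
        cols = COUNT_COLUMNS if include_g1x else [c for c in COUNT_COLUMNS if c != "1x"]
        total = int(self.counts[cols].to_numpy().sum())
        return total + (self.excluded if include_excluded else 0)

    def fold_g1x_into_g1a(self) -> "GroupCounts":
        """Return counts with the residual 1x group merged into 1a.

        Compatibility shim for the five-group table shape used in
        publications that do not carry the residual group separately.
        """
        folded = self.counts.copy()
        folded["1a"] = folded["1a"] + folded["1x"]
        folded["1x"] = 0
        return GroupCounts(folded, excluded=self.excluded)

    def to_csv(self, path: str | Path) -> None:
        frame = self.counts.copy()
        frame.index.name = "country"
        frame.columns = _CSV_COLUMNS[1:]
        frame.to_csv(path, sep=";")

    @classmethod
    def from_csv(cls, path: str | Path) -> "GroupCounts":
        frame = pd.read_csv(path, sep=";", comment="#", index_col="country")
        rename = dict(zip(_CSV_COLUMNS[1:], COUNT_COLUMNS))
        frame = frame.rename(columns=rename)
        missing = [c for c in COUNT_COLUMNS if c != "1x" and c not in frame.columns]
        if missing:
            raise ValueError(f"{path}: missing group columns {missing}")
        if "1x" not in frame.columns:
            frame["1x"] = 0
        return cls(frame[COUNT_COLUMNS])


def tabulate(records: Iterable["RegisterRecord"], profiles: "ProfileSet",
             reference_date: date, age_mode: str = "birthday") -> GroupCounts:
    """Classify every record and tally per-country group counts.

    Each record is counted exactly once: under its attributed country for the
    six analysis groups, or in the excluded bucket.
    """
    tallies: dict[str, dict[str, int]] = {}
    excluded = 0
    for record in records:
        country = attributed_country(record, profiles)
        if country is None:
            excluded += 1
            continue
        group = classify(record, profiles[country], reference_date, age_mode=age_mode)
        row = tallies.setdefault(country, {c: 0 for c in COUNT_COLUMNS})
        row[group.value] += 1
    frame = pd.DataFrame.from_dict(tallies, orient="index").sort_index()
    frame.index.name = "country"
    if frame.empty:
        return GroupCounts(GroupCounts.empty().counts, excluded=excluded)
    return GroupCounts(frame, excluded=excluded)
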