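"""Origin-country FGM/C reference profiles.

Each of the 29 countries where FGM/C is concentrated gets one profile
carrying the survey-based (DHS/MICS) inputs of the extrapolation model:

* ``prev_15_49`` — share of women aged 15–49 who have undergone FGM/C; used
  to estimate how many first-generation women arriving past the customary
  cutting age had already been cut.
* ``prev_15_19`` — the same share among girls 15–19; used for the at-risk
  scenarios, since it reflects the practice among the youngest surveyed
  cohort.
* ``cut_age_min``/``cut_age_max`` — the customary age window within which
  cutting is traditionally performed; the window's upper bound is the
  classification cut-off for age at arrival.
* ``type3_15_49``/``type3_15_19`` — the infibulation (type III) share of each
  prevalence cohort.  Where the source survey reports no typology the share
  is stored as zero with ``type3_assumed_zero`` set, so downstream tables can
  distinguish "measured zero" from "assumed zero".

Profiles live in a delimiter-separated reference file (the packaged fixture
transcribes the published survey values, decimal commas and all); rates may
be written either as printed percentages (``97,9 %``) or plain decimals.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

__all__ = [
    "CountryProfile",
    "ProfileSet",
    "ProfileError",
    "load_profiles",
    "write_profiles",
    "parse_rate",
]

_DELIM = ";"
_COLUMNS = [
    "country",
    "prev_15_49",
    "prev_15_19",
    "cut_age_min",
    "cut_age_max",
    "type3_15_49",
    "type3_15_19",
    "source",
]
_MAX_CUT_AGE = 18


class ProfileError(ValueError):
    """Raised when the reference table is malformed."""


def _normalize_name(name: str) -> str:
    # Case-fold and collapse whitespace; unify typographic apostrophes so
    # "Côte d’Ivoire" and "Côte d'Ivoire" are the same key.
    return " ".join(name.replace("’", "'").split()).casefold()


def parse_rate(text: str | float | None) -> float | None:
    """Parse a proportion written as ``97,9 %``, ``97.9%`` or ``0.979``.

    Values carrying a percent sign are divided by 100; bare numbers are taken
    as proportions already.  Empty/missing values return ``None``.
    """
    if text is None:
        return None
    if isinstance(text, (int, float)):
        return float(text)
    text = text.strip()
    if not text:
        return None
    percent = text.endswith("%")
    if percent:
        text = text[:-1].strip()
    value = float(text.replace(",", "."))
    return value / 100.0 if percent else value


@dataclass(frozen=True)
class CountryProfile:
    """Survey-derived FGM/C inputs for one origin country."""

    country: str
    prev_15_49: float
    prev_15_19: float
    cut_age_min: int
    cut_age_max: int
    type3_15_49: float = 0.0
    type3_15_19: float = 0.0
    type3_assumed_zero: bool = False
    source: str = ""

    def __post_init__(self) -> None:
        for field_name in ("prev_15_49", "prev_15_19", "type3_15_49", "type3_15_19"):
            value = getattr(self, field_name)
            if not 0.0 <= value <= 1.0:
                raise ProfileError(
                    f"{self.country}: {field_name}={value!r} is outside [0, 1]"
                )
        if not 0 <= self.cut_age_min <= self.cut_age_max <= _MAX_CUT_AGE:
            raise ProfileError(
                f"{self.country}: customary age window "
                f"{self.cut_age_min}-{self.cut_age_max} is malformed"
            )

    @property
    def other_types_15_49(self) -> float:
        """Non-type-III share, stored implicitly as the complement."""
        return 1.0 - self.type3_15_49

    @property
    def other_types_15_19(self) -> float:
        return 1.0 - self.type3_15_19


class ProfileSet(Mapping[str, CountryProfile]):
    """Country profiles keyed by normalized country name.

    Lookups are whitespace- and case-insensitive.  A missing country is a
    legitimate outcome (the record belongs to a country where FGM/C is not
    concentrated), so :meth:`get` returning ``None`` — not an exception — is
    the idiomatic probe.
    """

    def __init__(self, profiles: Iterator[CountryProfile] | list[CountryProfile],
                 provenance: str = ""):
        self._profiles: dict[str, CountryProfile] = {}
        self.provenance = provenance
        for profile in profiles:
            key = _normalize_name(profile.country)
            if key in self._profiles:
                raise ProfileError(f"duplicate country in reference table: {profile.country!r}")
            self._profiles[key] = profile

    def __getitem__(self, country: str) -> CountryProfile:
        return self._profiles[_normalize_name(country)]

    def __iter__(self) -> Iterator[str]:
        return iter(self._profiles)

    def __len__(self) -> int:
        return len(self._profiles)

    def __contains__(self, country: object) -> bool:
        return isinstance(country, str) and _normalize_name(country) in self._profiles

    def get(self, country: str, default=None):
        if country is None:
            return default
        return self._profiles.get(_normalize_name(country), default)

    @property
    def countries(self) -> list[str]:
        """Display names, in file order."""
        return [p.country for p in self._profiles.values()]


def _builtin_reference() -> io.StringIO:
    text = resources.files("fgmc.data").joinpath("country_reference.csv").read_text("utf-8")
    return io.StringIO(text)


def load_profiles(path: str | Path | None = None) -> ProfileSet:
    """Load and validate the country reference table.

    With ``path=None`` the packaged 29-country table is used.  Hard errors:
    duplicate countries, proportions outside [0, 1], an age window with
    min > max, all named with the offending row.
    """
    if path is None:
        handle = _builtin_reference()
        provenance = "packaged reference table (DHS/MICS country reports)"
    else:
        handle = open(path, "r", encoding="utf-8", newline="")
        provenance = str(path)
    with handle:
        rows = [row for row in csv.DictReader(
            (line for line in handle if not line.startswith("#")),
            delimiter=_DELIM,
        )]
    profiles = []
    for i, row in enumerate(rows, start=2):
        missing = [c for c in _COLUMNS[:5] if not (row.get(c) or "").strip()]
        if missing:
            raise ProfileError(f"row {i} ({row.get('country', '?')}): missing {missing}")
        try:
            type3_49 = parse_rate(row.get("type3_15_49"))
            type3_19 = parse_rate(row.get("type3_15_19"))
            assumed_zero = type3_49 is None and type3_19 is None
            profiles.append(CountryProfile(
                country=row["country"].strip(),
                prev_15_49=parse_rate(row["prev_15_49"]),
                prev_15_19=parse_rate(row["prev_15_19"]),
                cut_age_min=int(row["cut_age_min"]),
                cut_age_max=int(row["cut_age_max"]),
                type3_15_49=type3_49 if type3_49 is not None else 0.0,
                type3_15_19=type3_19 if type3_19 is not None else 0.0,
                type3_assumed_zero=assumed_zero,
                source=(row.get("source") or "").strip(),
            ))
        except ProfileError:
            raise
        except (TypeError, ValueError) as exc:
            raise ProfileError(f"row {i} ({row.get('country', '?')}): {exc}") from exc
    return ProfileSet(profiles, provenance=provenance)


def write_profiles(profiles: ProfileSet, path: str | Path) -> None:
    """Serialize a profile set back to the reference-table format.

    Rates are written as plain decimals; assumed-zero typology is written as
    empty cells so the flag survives a round trip.
    """
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter=_DELIM)
        writer.writerow(_COLUMNS)
        for profile in profiles.values():
            if profile.type3_assumed_zero:
                t49, t19 = "", ""
            else:
                t49, t19 = repr(profile.type3_15_49), repr(profile.type3_15_19)
            writer.writerow([
                profile.country,
                repr(profile.prev_15_49),
                repr(profile.prev_15_19),
                profile.cut_age_min,
                profile.cut_age_max,
                t49,
                t19,
                profile.source,
            ])
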