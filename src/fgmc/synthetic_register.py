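"""Seeded synthetic register microdata.

The real input of the pipeline is individual-level population-register data
(one row per female resident with birth date, generation, origin countries
and arrival date), which cannot be redistributed.  This module generates
register files with the same structure, in two modes:

* **marginal mode** — the caller requests per-country group counts and the
  generator constructs birth/arrival dates *inside* the age intervals that
  define each group, so classifying the output at the spec's reference date
  reproduces the requested counts exactly.  This makes the
  generator→classifier round trip an oracle for both modules and lets the
  full pipeline run end-to-end from published aggregate counts.
* **rates mode** — per-country totals are split across groups by a
  multinomial draw over caller-supplied group probabilities, then dates are
  constructed as above; useful for property tests over random registers.

Everything is driven by one integer seed; the same spec and seed produce
byte-identical register files.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from dateutil.relativedelta import relativedelta

from .cohort_classifier import AGE_OF_MAJORITY, Group, age_on
from .country_profiles import CountryProfile, ProfileSet

__all__ = [
    "RegisterRecord",
    "GeneratorSpec",
    "CountryRates",
    "InfeasibleGroupError",
    "RegisterFormatError",
    "generate_register",
    "feasible_groups",
    "write_register",
    "read_register",
]

_CSV_COLUMNS = ["person_id", "birth_date", "generation", "country_of_birth",
                "mother_country", "father_country", "arrival_date"]
_GEN_ORDER = [Group.G1A, Group.G1B, Group.G1C, Group.G1X, Group.G2A, Group.G2B]
# Upper bounds (exclusive) for sampled ages; wide enough to span the adult
# register population without affecting group membership.
_MAX_ARRIVAL_AGE = 45
_MAX_ADULT_AGE = 60


class InfeasibleGroupError(ValueError):
    """A requested group cannot be populated for the country's age window."""


class RegisterFormatError(ValueError):
    """A register file row violates the record invariants."""


@dataclass(frozen=True)
class RegisterRecord:
    """One female resident of the register extract."""

    person_id: str
    birth_date: date
    generation: int
    country_of_birth: str | None = None
    mother_country: str | None = None
    father_country: str | None = None
    arrival_date: date | None = None

    def validate(self) -> None:
        if self.generation not in (1, 2):
            raise RegisterFormatError(
                f"{self.person_id}: generation must be 1 or 2, got {self.generation!r}")
        if self.generation == 1:
            if self.arrival_date is None:
                raise RegisterFormatError(f"{self.person_id}: first generation needs arrival_date")
            if self.arrival_date < self.birth_date:
                raise RegisterFormatError(
                    f"{self.person_id}: arrival_date {self.arrival_date} precedes "
                    f"birth_date {self.birth_date}")
        elif self.arrival_date is not None:
            raise RegisterFormatError(
                f"{self.person_id}: second generation must not carry an arrival_date")


@dataclass(frozen=True)
class CountryRates:
    """Rates-mode input: country total and group probabilities."""

    size: int
    group_probs: Mapping[Group, float]


@dataclass
class GeneratorSpec:
    """What to generate: exact marginals or stochastic rates, plus seed."""

    reference_date: date = date(2013, 1, 1)
    seed: int = 0
    marginals: Mapping[str, Mapping[Group | str, int]] | None = None
    rates: Mapping[str, CountryRates] | None = None

    def __post_init__(self) -> None:
        if (self.marginals is None) == (self.rates is None):
            raise ValueError("specify exactly one of marginals= or rates=")


def feasible_groups(profile: CountryProfile) -> set[Group]:
    """Groups that can be populated given the country's customary window.

    Group 1b needs an age strictly between the window's upper bound and 18,
    which does not exist when the window reaches 17 or beyond.
    """
    groups = {Group.G1A, Group.G1C, Group.G1X, Group.G2A, Group.G2B}
    if profile.cut_age_max + 1 < AGE_OF_MAJORITY:
        groups.add(Group.G1B)
    return groups


def _birth_for_age(reference: date, a_ref: int, rng: np.random.Generator) -> date:
    """A birth date with exactly ``a_ref`` completed years at ``reference``."""
    candidate = reference - relativedelta(years=a_ref) - timedelta(days=int(rng.integers(0, 365)))
    # Leap-day arithmetic can land one day outside the target year of age;
    # nudge until the completed-years age matches exactly.
    while age_on(candidate, reference) > a_ref:
        candidate += timedelta(days=1)
    while age_on(candidate, reference) < a_ref:
        candidate -= timedelta(days=1)
    return candidate


def _arrival_for_age(birth: date, a_arr: int, reference: date,
                     rng: np.random.Generator) -> date:
    """An arrival date at which exactly ``a_arr`` years were completed.

    Sampled uniformly over the intersection of the age-``a_arr`` year of life
    with ``[birth, reference]``; the caller guarantees ``a_arr`` does not
    exceed the age at the reference date, so the window is never empty.
    """
    start = birth + relativedelta(years=a_arr)
    while age_on(birth, start) < a_arr:
        start += timedelta(days=1)
    end = birth + relativedelta(years=a_arr + 1) - timedelta(days=1)
    while age_on(birth, end) > a_arr:
        end -= timedelta(days=1)
    end = min(end, reference)
    offset = int(rng.integers(0, (end - start).days + 1))
    return start + timedelta(days=offset)


def _draw_ages(group: Group, profile: CountryProfile, rng: np.random.Generator,
               country: str) -> tuple[int, int | None]:
    """Target (age at reference, age at arrival) for one record."""
    cmax = profile.cut_age_max
    if group is Group.G1A:
        a_arr = int(rng.integers(cmax + 1, _MAX_ARRIVAL_AGE))
        return int(rng.integers(a_arr, min(a_arr + 26, _MAX_ADULT_AGE))), a_arr
    if group is Group.G1B:
        if cmax + 1 >= AGE_OF_MAJORITY:
            raise InfeasibleGroupError(
                f"{country}: group 1b is empty by construction (customary window "
                f"reaches {cmax}, leaving no age between the window and 18)")
        a_ref = int(rng.integers(cmax + 1, AGE_OF_MAJORITY))
        return a_ref, int(rng.integers(0, cmax + 1))
    if group is Group.G1C:
        a_ref = int(rng.integers(0, cmax + 1))
        return a_ref, int(rng.integers(0, a_ref + 1))
    if group is Group.G1X:
        return int(rng.integers(AGE_OF_MAJORITY, _MAX_ARRIVAL_AGE)), int(rng.integers(0, cmax + 1))
    if group is Group.G2A:
        return int(rng.integers(0, AGE_OF_MAJORITY)), None
    if group is Group.G2B:
        return int(rng.integers(AGE_OF_MAJORITY, _MAX_ADULT_AGE - 10)), None
    raise ValueError(f"cannot generate records for group {group}")


def _coerce_marginals(marginals: Mapping[Group | str, int]) -> dict[Group, int]:
    out: dict[Group, int] = {}
    for key, count in marginals.items():
        group = Group(key)
        if count < 0:
            raise ValueError(f"negative count for group {group.value}")
        out[group] = int(count)
    return out


def generate_register(spec: GeneratorSpec, profiles: ProfileSet) -> list[RegisterRecord]:
    """Generate records deterministically under ``spec.seed``.

    In marginal mode, tabulating the output at ``spec.reference_date``
    reproduces the requested per-country group counts exactly.  Requesting an
    infeasible group (see :func:`feasible_groups`) is a hard error naming the
    country and group.
    """
    rng = np.random.default_rng(spec.seed)
    per_country: dict[str, dict[Group, int]] = {}
    if spec.marginals is not None:
        for country in sorted(spec.marginals):
            per_country[country] = _coerce_marginals(spec.marginals[country])
    else:
        for country in sorted(spec.rates):
            rates = spec.rates[country]
            groups = list(rates.group_probs)
            probs = np.asarray([rates.group_probs[g] for g in groups], dtype=float)
            if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
                raise ValueError(f"{country}: group probabilities must be a distribution")
            draws = rng.multinomial(rates.size, probs)
            per_country[country] = {Group(g): int(n) for g, n in zip(groups, draws)}

    records: list[RegisterRecord] = []
    serial = 0
    for country, marg in per_country.items():
        profile = profiles.get(country)
        if profile is None:
            raise KeyError(f"no country profile for {country!r}")
        allowed = feasible_groups(profile)
        for group in _GEN_ORDER:
            count = marg.get(group, 0)
            if count and group not in allowed:
                raise InfeasibleGroupError(
                    f"{country}: group {group.value} is infeasible for customary "
                    f"window {profile.cut_age_min}-{profile.cut_age_max}")
            for _ in range(count):
                serial += 1
                a_ref, a_arr = _draw_ages(group, profile, rng, country)
                birth = _birth_for_age(spec.reference_date, a_ref, rng)
                if group in (Group.G2A, Group.G2B):
                    records.append(RegisterRecord(
                        person_id=f"P{serial:06d}", birth_date=birth, generation=2,
                        mother_country=profile.country, father_country=profile.country))
                else:
                    arrival = _arrival_for_age(birth, a_arr, spec.reference_date, rng)
                    records.append(RegisterRecord(
                        person_id=f"P{serial:06d}", birth_date=birth, generation=1,
                        country_of_birth=profile.country,
                        mother_country=profile.country, father_country=profile.country,
                        arrival_date=arrival))
    return records


def write_register(records: Iterable[RegisterRecord], path: str | Path) -> None:
    """Write records as delimiter-separated values with ISO-8601 dates."""
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter=";")
        writer.writerow(_CSV_COLUMNS)
        for record in records:
            record.validate()
            writer.writerow([
                record.person_id,
                record.birth_date.isoformat(),
                record.generation,
                record.country_of_birth or "",
                record.mother_country or "",
                record.father_country or "",
                record.arrival_date.isoformat() if record.arrival_date else "",
            ])


def _parse_date(text: str, line: int, column: str) -> date | None:
    text = text.strip()
    if not text:
        return None
    try:
        return date.fromisoformat(text)
    except ValueError as exc:
        raise RegisterFormatError(f"line {line}: malformed {column} {text!r}") from exc


def read_register(path: str | Path) -> list[RegisterRecord]:
    """Read a register file, enforcing the record invariants row by row."""
    records: list[RegisterRecord] = []
    with open(path, "r", encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter=";")
        if reader.fieldnames != _CSV_COLUMNS:
            raise RegisterFormatError(
                f"{path}: expected columns {_CSV_COLUMNS}, got {reader.fieldnames}")
        for line, row in enumerate(reader, start=2):
            try:
                generation = int(row["generation"])
            except (TypeError, ValueError):
                raise RegisterFormatError(
                    f"line {line}: malformed generation {row.get('generation')!r}") from None
            birth = _parse_date(row["birth_date"], line, "birth_date")
            if birth is None:
                raise RegisterFormatError(f"line {line}: missing birth_date")
            record = RegisterRecord(
                person_id=row["person_id"],
                birth_date=birth,
                generation=generation,
                country_of_birth=row["country_of_birth"].strip() or None,
                mother_country=row["mother_country"].strip() or None,
                father_country=row["father_country"].strip() or None,
                arrival_date=_parse_date(row["arrival_date"], line, "arrival_date"),
            )
            try:
                record.validate()
            except RegisterFormatError as exc:
                raise RegisterFormatError(f"line {line}: {exc}") from None
            records.append(record)
    return records
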