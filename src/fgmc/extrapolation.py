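"""Extrapolation of origin-country FGM/C rates to the diaspora population.

Given the per-country group counts and the country profiles, this module
computes every headline quantity of the indirect estimation model:

* **undergone** — women in group 1a (arrived past the customary cutting
  window) times the origin country's 15–49 prevalence.  The model assumes no
  cutting after migration, so no other group contributes.
* **type split of undergone** — the type-III (infibulation) share of the
  15–49 cohort applied to the unrounded undergone figure; the non-type-III
  remainder is the complement of the rounded total, so the pair always sums
  exactly ("complement" convention).
* **potentially at risk** — raw head counts of groups 1b + 1c + 2a, with no
  prevalence applied: the target population of universal preventive
  measures.
* **at risk, low/high scenario** — the recommended European risk model with
  a migration-and-acculturation impact factor f for the second generation:
  ``(N1b + N1c + (1-f)·N2a) × prev_15_19``.  f=1 is the low-risk scenario
  (migration removes second-generation risk), f=0 the high-risk scenario
  (risk as if migration never happened); any f in [0,1] is accepted as a
  continuous extension of the binary model.
* **type split of at-risk** — the 15–19 type-III share applied to the
  unrounded scenario figure, with type-III and other rounded independently
  ("independent" convention, so the pair may differ from the rounded
  scenario total by one).

Rounding is half-away-from-zero per country by default (half-even is
available), and national totals are sums of the rounded per-country values.
Unrounded values are carried alongside because the type splits feed on them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort_classifier import GroupCounts
from .country_profiles import ProfileSet

__all__ = [
    "ScenarioConfig",
    "NationalSummary",
    "round_count",
    "estimate_undergone",
    "split_undergone_types",
    "potentially_at_risk",
    "estimate_risk",
    "split_risk_types",
    "estimate_all",
    "national_summary",
    "format_percent",
]

DEFAULT_SCENARIOS: Mapping[str, float] = {"low": 1.0, "high": 0.0}


@dataclass(frozen=True)
class ScenarioConfig:
    """Reference date, scenario factors, rounding and population settings.

    ``scenarios`` maps a scenario name to the second-generation migration-
    and-acculturation impact factor f in [0, 1]; the defaults are the binary
    low (f=1) and high (f=0) scenarios.  ``include_g1x_in_population``
    controls whether the residual group 1x counts toward the denominator of
    the national prevalence share (it does by default: those women are part
    of the resident population even though the model assumes them uncut).
    """

    reference_date: date = date(2013, 1, 1)
    scenarios: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SCENARIOS))
    rounding: str = "half-away"
    include_g1x_in_population: bool = True

    def __post_init__(self) -> None:
        if self.rounding not in ("half-away", "half-even"):
            raise ValueError(f"unknown rounding mode {self.rounding!r}")
        for name, factor in self.scenarios.items():
            if not 0.0 <= factor <= 1.0:
                raise ValueError(
                    f"scenario {name!r}: acculturation factor {factor} outside [0, 1]")


def round_count(value: float, mode: str = "half-away") -> int:
    """Round a non-negative estimate to a whole person count."""
    if value < 0:
        raise ValueError("estimates are non-negative")
    if mode == "half-away":
        return int(math.floor(value + 0.5))
    if mode == "half-even":
        return int(round(value))
    raise ValueError(f"unknown rounding mode {mode!r}")


def _round_series(values: pd.Series, mode: str) -> pd.Series:
    return values.map(lambda v: round_count(v, mode)).astype(int)


def _profile_column(counts: GroupCounts, profiles: ProfileSet, attr: str) -> pd.Series:
    values = {}
    for country in counts.counts.index:
        profile = profiles.get(country)
        if profile is None:
            raise KeyError(f"no country profile for counted country {country!r}")
        values[country] = getattr(profile, attr)
    return pd.Series(values, dtype=float).reindex(counts.counts.index)


def estimate_undergone(counts: GroupCounts, profiles: ProfileSet,
                       cfg: ScenarioConfig | None = None) -> pd.DataFrame:
    """Per-country estimate of women and girls who have undergone FGM/C.

    ``undergone_unrounded = N1a × prev_15_49``; the rounded column applies
    the configured rounding per country.
    """
    cfg = cfg or ScenarioConfig()
    prev = _profile_column(counts, profiles, "prev_15_49")
    unrounded = counts.counts["1a"] * prev
    return pd.DataFrame({
        "undergone_unrounded": unrounded,
        "undergone": _round_series(unrounded, cfg.rounding),
    })


def split_undergone_types(undergone: pd.DataFrame, profiles: ProfileSet,
                          cfg: ScenarioConfig | None = None) -> pd.DataFrame:
    """Type-III / other split of the undergone estimate (complement convention).

    Type III is rounded from the unrounded base; "other" is the rounded
    total minus type III, so the split always sums to the published total.
    """
    cfg = cfg or ScenarioConfig()
    share = pd.Series(
        {c: profiles[c].type3_15_49 for c in undergone.index}, dtype=float)
    type3 = _round_series(undergone["undergone_unrounded"] * share, cfg.rounding)
    return pd.DataFrame({
        "undergone_type3": type3,
        "undergone_other": undergone["undergone"] - type3,
    })


def potentially_at_risk(counts: GroupCounts) -> pd.Series:
    """Head count of girls potentially at risk: groups 1b + 1c + 2a.

    No prevalence adjustment — this is the target population of universal
    preventive measures.
    """
    return (counts.counts["1b"] + counts.counts["1c"] + counts.counts["2a"]).rename(
        "potentially_at_risk")


def estimate_risk(counts: GroupCounts, profiles: ProfileSet,
                  cfg: ScenarioConfig | None = None,
                  factor: float | None = None) -> pd.DataFrame:
    """Scenario estimates of girls at risk.

    With second-generation impact factor f, the unrounded per-country risk is
    ``(N1b + N1c + (1-f)·N2a) × prev_15_19``.  By default both configured
    scenarios are computed (columns ``risk_<name>[_unrounded]``); passing
    ``factor`` computes that single scenario instead (columns
    ``risk[_unrounded]``).
    """
    cfg = cfg or ScenarioConfig()
    prev = _profile_column(counts, profiles, "prev_15_19")
    scenarios = {"": factor} if factor is not None else dict(cfg.scenarios)
    out: dict[str, pd.Series] = {}
    for name, f in scenarios.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"acculturation factor {f} outside [0, 1]")
        base = counts.counts["1b"] + counts.counts["1c"] + (1.0 - f) * counts.counts["2a"]
        unrounded = base * prev
        prefix = f"risk_{name}" if name else "risk"
        out[f"{prefix}_unrounded"] = unrounded
        out[prefix] = _round_series(unrounded, cfg.rounding)
    return pd.DataFrame(out)


def split_risk_types(risk: pd.DataFrame, profiles: ProfileSet,
                     cfg: ScenarioConfig | None = None) -> pd.DataFrame:
    """Type-III / other split of every risk scenario (independent convention).

    Both halves are rounded independently from the unrounded scenario base,
    so they may differ from the rounded scenario total by one.
    """
    cfg = cfg or ScenarioConfig()
    share = pd.Series({c: profiles[c].type3_15_19 for c in risk.index}, dtype=float)
    out: dict[str, pd.Series] = {}
    for column in risk.columns:
        if not column.endswith("_unrounded"):
            continue
        prefix = column[: -len("_unrounded")]
        out[f"{prefix}_type3"] = _round_series(risk[column] * share, cfg.rounding)
        out[f"{prefix}_other"] = _round_series(risk[column] * (1.0 - share), cfg.rounding)
    return pd.DataFrame(out)


def estimate_all(counts: GroupCounts, profiles: ProfileSet,
                 cfg: ScenarioConfig | None = None) -> pd.DataFrame:
    """Full per-country estimate table: counts, undergone, type splits, risk."""
    cfg = cfg or ScenarioConfig()
    undergone = estimate_undergone(counts, profiles, cfg)
    pieces = [
        counts.counts,
        undergone,
        split_undergone_types(undergone, profiles, cfg),
        potentially_at_risk(counts).to_frame(),
        estimate_risk(counts, profiles, cfg),
    ]
    risk = pieces[-1]
    pieces.append(split_risk_types(risk, profiles, cfg))
    table = pd.concat(pieces, axis=1)
    table.index.name = "country"
    return table


def format_percent(proportion: float, decimals: int = 1) -> str:
    """Render a proportion the way the published tables print it: ``38.9 %``."""
    return f"{proportion * 100:.{decimals}f} %"


@dataclass(frozen=True)
class NationalSummary:
    """National totals and shares; totals are sums of rounded country values."""

    population: int
    undergone_total: int
    undergone_share: float
    undergone_type3_total: int
    type3_share_of_undergone: float
    potentially_at_risk_total: int
    risk_totals: Mapping[str, int]
    risk_type3_totals: Mapping[str, int]
    type3_share_of_risk: Mapping[str, float]

    def as_dict(self) -> dict:
        out = {
            "population": self.population,
            "undergone_total": self.undergone_total,
            "undergone_share": self.undergone_share,
            "undergone_share_pct": format_percent(self.undergone_share),
            "undergone_type3_total": self.undergone_type3_total,
            "type3_share_of_undergone": self.type3_share_of_undergone,
            "type3_share_of_undergone_pct": format_percent(self.type3_share_of_undergone),
            "potentially_at_risk_total": self.potentially_at_risk_total,
        }
        for name, total in self.risk_totals.items():
            out[f"risk_{name}_total"] = total
        for name, total in self.risk_type3_totals.items():
            out[f"risk_{name}_type3_total"] = total
        for name, share in self.type3_share_of_risk.items():
            out[f"type3_share_of_risk_{name}"] = share
        return out


def national_summary(estimates: pd.DataFrame, counts: GroupCounts,
                     cfg: ScenarioConfig | None = None) -> NationalSummary:
    """Aggregate the estimate table into the headline national figures."""
    cfg = cfg or ScenarioConfig()
    population = counts.grand_total(include_g1x=cfg.include_g1x_in_population)
    undergone_total = int(estimates["undergone"].sum())
    type3_total = int(estimates["undergone_type3"].sum())
    scenario_names = [c[len("risk_"):] for c in estimates.columns
                      if c.startswith("risk_") and not c.endswith(("_unrounded", "_type3", "_other"))]
    risk_totals = {name: int(estimates[f"risk_{name}"].sum()) for name in scenario_names}
    risk_type3 = {name: int(estimates[f"risk_{name}_type3"].sum()) for name in scenario_names}
    type3_share_risk = {
        name: (risk_type3[name] / risk_totals[name]) if risk_totals[name] else 0.0
        for name in scenario_names
    }
    return NationalSummary(
        population=population,
        undergone_total=undergone_total,
        undergone_share=undergone_total / population if population else 0.0,
        undergone_type3_total=type3_total,
        type3_share_of_undergone=type3_total / undergone_total if undergone_total else 0.0,
        potentially_at_risk_total=int(estimates["potentially_at_risk"].sum()),
        risk_totals=risk_totals,
        risk_type3_totals=risk_type3,
        type3_share_of_risk=type3_share_risk,
    )
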