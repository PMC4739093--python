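"""Statistical disclosure control and report rendering.

Register-based tables of small populations cannot publish cells that would
expose near-identifiable individuals.  Two standard safeguards are applied
here, mirroring national-statistics practice:

* **small-cell suppression** — any cell whose value lies in the inclusive
  band [suppress_low, suppress_high] (default 1–9) is replaced by a marker.
  Zero is information-free and is rendered as ``0``; totals are computed
  *before* suppression and printed exactly, so visible cells deliberately do
  not sum to the totals.
* **small-country pooling** — countries whose total resident count falls
  below a threshold (default 20) are pooled into one residual row.  Pool
  membership is decided on counts; estimates are computed per constituent
  country with its own prevalence and then summed into the pooled row, so
  pooling never changes national totals.

:func:`run_pipeline` orchestrates the whole analysis — load profiles, obtain
group counts (from microdata or an aggregate counts file), estimate, pool,
suppress, render — and writes the report tables plus a machine-readable run
manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from datetime import date
from pathlib import Path

import pandas as pd

from . import extrapolation
from .cohort_classifier import COUNT_COLUMNS, GroupCounts, tabulate
from .country_profiles import ProfileSet, load_profiles
from .synthetic_register import read_register

__all__ = [
    "DisclosureConfig",
    "ReportTable",
    "PipelineError",
    "small_countries",
    "pool_small_countries",
    "pool_estimates",
    "suppress_cells",
    "parse_report",
    "run_pipeline",
]

_TABLE_FILES = {
    "group_counts": "group_counts.csv",
    "undergone": "undergone.csv",
    "undergone_types": "undergone_types.csv",
    "potentially_at_risk": "potentially_at_risk.csv",
    "risk_scenarios": "risk_scenarios.csv",
    "risk_types": "risk_types.csv",
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class DisclosureConfig:
    """Suppression band, pooling threshold and rendering settings."""

    suppress_low: int = 1
    suppress_high: int = 9
    pool_threshold: int = 20
    pooled_label: str = "Other countries"
    marker: str = ":"

    def __post_init__(self) -> None:
        if not 0 < self.suppress_low <= self.suppress_high < self.pool_threshold:
            raise ValueError(
                "need 0 < suppress_low <= suppress_high < pool_threshold, got "
                f"{self.suppress_low}/{self.suppress_high}/{self.pool_threshold}")


def small_countries(counts: GroupCounts, cfg: DisclosureConfig | None = None) -> list[str]:
    """Countries whose total resident count is strictly below the threshold."""
    cfg = cfg or DisclosureConfig()
    totals = counts.country_totals
    return sorted(totals.index[totals < cfg.pool_threshold])


def pool_small_countries(counts: GroupCounts,
                         cfg: DisclosureConfig | None = None) -> GroupCounts:
    """Merge below-threshold countries into one pooled row (placed last)."""
    cfg = cfg or DisclosureConfig()
    small = small_countries(counts, cfg)
    if not small:
        return counts
    frame = counts.counts
    pooled = frame.loc[small].sum(axis=0)
    kept = frame.drop(index=small).sort_index()
    pooled_frame = pd.DataFrame([pooled], index=pd.Index([cfg.pooled_label], name="country"))
    return GroupCounts(pd.concat([kept, pooled_frame]), excluded=counts.excluded)


def pool_estimates(estimates: pd.DataFrame, small: list[str],
                   pooled_label: str = "Other countries") -> pd.DataFrame:
    """Sum the estimate rows of pooled countries into one residual row.

    Summing the already-computed per-country estimates (each made with its
    own country's prevalence) keeps national totals identical to the
    unpooled table.
    """
    present = [c for c in small if c in estimates.index]
    if not present:
        return estimates
    pooled = estimates.loc[present].sum(axis=0)
    kept = estimates.drop(index=present).sort_index()
    pooled_frame = pd.DataFrame([pooled], index=pd.Index([pooled_label], name="country"))
    out = pd.concat([kept, pooled_frame])
    out.index.name = estimates.index.name
    return out


@dataclass
class ReportTable:
    """A disclosure-safe table: string cells, exact totals, footnotes."""

    cells: pd.DataFrame
    totals: pd.Series
    footnotes: list[str] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> None:
        frame = self.cells.copy()
        frame.loc["Total"] = self.totals.astype(str)
        frame.index.name = "country"
        frame.to_csv(path, sep=";")
        if self.footnotes:
            with open(path, "a", encoding="utf-8") as handle:
                for note in self.footnotes:
                    handle.write(f"# {note}\n")


def suppress_cells(table: pd.DataFrame | ReportTable,
                   cfg: DisclosureConfig | None = None,
                   footnotes: list[str] | None = None) -> ReportTable:
    """Apply small-cell suppression to an integer table.

    Totals are column sums of the *unsuppressed* table and remain exact;
    re-suppressing a :class:`ReportTable` is the identity (exact totals are
    carried over and no in-band integer survives a pass).
    """
    cfg = cfg or DisclosureConfig()
    def _mask(value):
        if value == cfg.marker:
            return value
        value = int(value)
        if cfg.suppress_low <= value <= cfg.suppress_high:
            return cfg.marker
        return str(value)

    if isinstance(table, ReportTable):
        # exact pre-suppression totals are carried over, never recomputed
        return ReportTable(cells=table.cells.map(_mask), totals=table.totals,
                           footnotes=list(table.footnotes))
    totals = table.sum(axis=0).astype(int)
    masked = table.astype(object).map(_mask)
    notes = list(footnotes or [])
    notes.append(
        f"{cfg.marker} = suppressed: more than 0 and less than "
        f"{cfg.suppress_high + 1} per cell; totals computed before suppression")
    return ReportTable(cells=masked, totals=totals, footnotes=notes)


def parse_report(path: str | Path, cfg: DisclosureConfig | None = None
                 ) -> tuple[pd.DataFrame, pd.Series]:
    """Read a rendered report back; suppressed cells become missing values.

    Returns ``(cells, totals)`` with non-suppressed integers recovered
    exactly.
    """
    cfg = cfg or DisclosureConfig()
    frame = pd.read_csv(path, sep=";", comment="#", index_col="country", dtype=str)
    totals = frame.loc["Total"].astype(int)
    cells = frame.drop(index="Total")
    cells = cells.map(lambda v: pd.NA if v == cfg.marker else int(v))
    return cells, totals


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _report_tables(estimates: pd.DataFrame, pooled_counts: GroupCounts,
                   scenario_names: list[str]) -> dict[str, pd.DataFrame]:
    counts_table = pooled_counts.counts.copy()
    counts_table["total"] = counts_table.sum(axis=1)
    risk_cols = [f"risk_{n}" for n in scenario_names]
    risk_type_cols = [c for n in scenario_names
                      for c in (f"risk_{n}_type3", f"risk_{n}_other")]
    par = estimates[["1b", "1c", "2a", "potentially_at_risk"]].copy()
    undergone_types = estimates[["undergone_type3", "undergone_other", "undergone"]]
    return {
        "group_counts": counts_table,
        "undergone": estimates[["undergone"]],
        "undergone_types": undergone_types,
        "potentially_at_risk": par,
        "risk_scenarios": estimates[risk_cols],
        "risk_types": estimates[risk_type_cols],
    }


def run_pipeline(out_dir: str | Path,
                 register_path: str | Path | None = None,
                 counts_path: str | Path | None = None,
                 counts: GroupCounts | None = None,
                 profiles_path: str | Path | None = None,
                 scenario: extrapolation.ScenarioConfig | None = None,
                 disclosure: DisclosureConfig | None = None) -> dict:
    """Run the full analysis and write disclosure-safe report files.

    Input is either register microdata (classified internally), an aggregate
    group-counts file, or an in-memory :class:`GroupCounts`.  Outputs: the
    six report tables, ``summary.json`` with the national headline figures,
    and ``manifest.json`` recording configuration and input digests.  Any
    stage failure raises :class:`PipelineError` naming the stage, and no
    partial outputs are left behind (files are written only after every
    table has been computed).
    """
    scenario = scenario or extrapolation.ScenarioConfig()
    disclosure = disclosure or DisclosureConfig()
    sources = [s for s in (register_path, counts_path, counts) if s is not None]
    if len(sources) != 1:
        raise PipelineError("configure", "provide exactly one of register_path, "
                            "counts_path or counts")

    try:
        profiles = load_profiles(profiles_path)
    except (OSError, ValueError) as exc:
        raise PipelineError("load-profiles", str(exc)) from exc

    digests = {}
    try:
        if register_path is not None:
            records = read_register(register_path)
            counts = tabulate(records, profiles, scenario.reference_date)
            digests["register"] = _digest(Path(register_path))
        elif counts_path is not None:
            counts = GroupCounts.from_csv(counts_path)
            digests["counts"] = _digest(Path(counts_path))
    except (OSError, ValueError) as exc:
        raise PipelineError("load-input", str(exc)) from exc
    if profiles_path is not None:
        digests["profiles"] = _digest(Path(profiles_path))

    try:
        estimates = extrapolation.estimate_all(counts, profiles, scenario)
        summary = extrapolation.national_summary(estimates, counts, scenario)
    except (KeyError, ValueError) as exc:
        raise PipelineError("estimate", str(exc)) from exc

    try:
        small = small_countries(counts, disclosure)
        pooled_counts = pool_small_countries(counts, disclosure)
        pooled_estimates = pool_estimates(estimates, small, disclosure.pooled_label)
        scenario_names = list(scenario.scenarios)
        tables = _report_tables(pooled_estimates, pooled_counts, scenario_names)
        reports = {}
        pooled_note = (f"'{disclosure.pooled_label}' pools countries with fewer than "
                       f"{disclosure.pool_threshold} residents in total: "
                       + ", ".join(small)) if small else None
        for name, frame in tables.items():
            notes = [pooled_note] if pooled_note else []
            reports[name] = suppress_cells(frame, disclosure, footnotes=notes)
    except (KeyError, ValueError) as exc:
        raise PipelineError("report", str(exc)) from exc

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        for name, report in reports.items():
            target = out_dir / _TABLE_FILES[name]
            report.to_csv(target)
            written.append(target)
        summary_path = out_dir / "summary.json"
        summary_path.write_text(json.dumps(summary.as_dict(), indent=2) + "\n")
        written.append(summary_path)
        manifest = {
            "reference_date": scenario.reference_date.isoformat(),
            "scenarios": dict(scenario.scenarios),
            "rounding": scenario.rounding,
            "disclosure": asdict(disclosure),
            "inputs": digests,
            "profiles": profiles.provenance,
            "tables": sorted(_TABLE_FILES.values()),
        }
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
        written.append(manifest_path)
    except OSError as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError("write", str(exc)) from exc

    return {"out_dir": out_dir, "summary": summary, "estimates": estimates,
            "counts": counts, "manifest": manifest}
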