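"""Descriptive profiling of drug cohorts.

Covers the demographic/outcome characteristics table (sex, age group,
reporter occupation, outcome codes, top reporting countries), per-drug death
shares, annual report trends and time-to-onset (TTO) distributions.

Conventions mirror how such tables are conventionally rendered: percentages
are count/denominator rounded half-up to two decimals; sex, age, reporter
and country blocks use the cohort's report count as the denominator, while
the outcome block uses the number of outcome *entries* (a report can carry
several outcome codes).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .faers_io import (
    CaseReport,
    OUTCOME_CODES,
    SEVERE_OUTCOMES,
    UNKNOWN,
    drug_matches,
    normalize_drug_name,
)

#: Outcome code → label used in published characteristics tables.
OUTCOME_LABELS = {
    "CA": "Congenital Anomaly",
    "DE": "Death",
    "DS": "Disability",
    "HO": "Hospitalization initial or prolonged",
    "LT": "Life threatening",
    "OT": "Other serious (important medical event)",
    "RI": "Required intervention to prevent permanent impairment/damage",
}

AGE_GROUP_LABELS = {
    "under18": "0~18",
    "from18to65": "18~65",
    "over65": ">=65",
    UNKNOWN: "Unknown",
}

#: Default TTO bins, in days: [0,7], (7,28], (28,60], (60,inf).
DEFAULT_TTO_BINS = ((0, 7), (7, 28), (28, 60), (60, None))
TTO_BIN_NAMES = ("d0_7", "d7_28", "d28_60", "over60")


def pct(count: int, denom: int) -> float:
    """100·count/denom rounded half-up to 2 decimals (0.0 when denom=0)."""
    if denom == 0:
        return 0.0
    return float(
        (Decimal(100) * Decimal(count) / Decimal(denom)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


@dataclass
class BlockRow:
    label: str
    count: int
    pct: float


@dataclass
class ProfileTable:
    """One drug's characteristics table, block by block."""

    drug: str
    total_reports: int
    gender: list[BlockRow] = field(default_factory=list)
    age: list[BlockRow] = field(default_factory=list)
    reporter: list[BlockRow] = field(default_factory=list)
    outcomes: list[BlockRow] = field(default_factory=list)
    severe_outcomes: list[BlockRow] = field(default_factory=list)
    country: list[BlockRow] = field(default_factory=list)
    outcome_entries: int = 0

    def block(self, name: str) -> list[BlockRow]:
        return getattr(self, name)

    def to_dict(self) -> dict:
        def rows(block):
            return [{"label": r.label, "count": r.count, "pct": r.pct} for r in block]
        return {
            "drug": self.drug,
            "total_reports": self.total_reports,
            "outcome_entries": self.outcome_entries,
            "gender": rows(self.gender),
            "age": rows(self.age),
            "reporter": rows(self.reporter),
            "outcomes": rows(self.outcomes),
            "severe_outcomes": rows(self.severe_outcomes),
            "country": rows(self.country),
        }


def _categorical_block(counts: Mapping[str, int], denom: int,
                       order: Sequence[str] | None = None) -> list[BlockRow]:
    if order is None:
        order = sorted(counts, key=lambda k: (-counts[k], k))
    return [BlockRow(label, counts.get(label, 0), pct(counts.get(label, 0), denom))
            for label in order]


def demographic_summary(
    cohort: Sequence[CaseReport],
    drug: str = "",
    top_countries: int | None = 3,
) -> ProfileTable:
    """Characteristics table for one (deduplicated) cohort.

    Gender/age/reporter/country blocks use the report count as denominator;
    the outcome blocks use the outcome-entry count — one entry per
    (report, outcome code).  An empty cohort yields an all-zero table.
    """
    total = len(cohort)
    sex_counts: dict[str, int] = {"male": 0, "female": 0, UNKNOWN: 0}
    age_counts: dict[str, int] = {g: 0 for g in
                                  ("under18", "from18to65", "over65", UNKNOWN)}
    reporter_counts: dict[str, int] = {}
    country_counts: dict[str, int] = {}
    outcome_counts: dict[str, int] = {}
    for rep in cohort:
        sex_counts[rep.sex if rep.sex in sex_counts else UNKNOWN] += 1
        age_counts[rep.age_group if rep.age_group in age_counts else UNKNOWN] += 1
        reporter_counts[rep.reporter] = reporter_counts.get(rep.reporter, 0) + 1
        country_counts[rep.country] = country_counts.get(rep.country, 0) + 1
        for code in rep.outcomes:
            outcome_counts[code] = outcome_counts.get(code, 0) + 1

    entries = sum(outcome_counts.values())
    table = ProfileTable(drug=drug, total_reports=total, outcome_entries=entries)
    table.gender = _categorical_block(sex_counts, total,
                                      order=("male", "female", UNKNOWN))
    table.age = _categorical_block(
        age_counts, total, order=("under18", "from18to65", "over65", UNKNOWN))
    table.reporter = _categorical_block(reporter_counts, total)
    table.outcomes = [
        BlockRow(OUTCOME_LABELS[code], outcome_counts.get(code, 0),
                 pct(outcome_counts.get(code, 0), entries))
        for code in sorted(OUTCOME_CODES, key=lambda c: OUTCOME_LABELS[c])
    ]
    severe_entries = sum(outcome_counts.get(c, 0) for c in SEVERE_OUTCOMES)
    table.severe_outcomes = [
        BlockRow(OUTCOME_LABELS[code], outcome_counts.get(code, 0),
                 pct(outcome_counts.get(code, 0), severe_entries))
        for code in sorted(SEVERE_OUTCOMES, key=lambda c: OUTCOME_LABELS[c])
    ]
    country_rows = _categorical_block(country_counts, total)
    if top_countries is not None:
        country_rows = [r for r in country_rows if r.label != UNKNOWN][:top_countries]
    table.country = country_rows
    return table


def profile_from_counts(
    drug: str,
    total: int,
    gender: Mapping[str, int] | None = None,
    age: Mapping[str, int] | None = None,
    reporter: Sequence[tuple[str, int]] | None = None,
    outcomes: Mapping[str, int] | None = None,
    country: Sequence[tuple[str, int]] | None = None,
) -> ProfileTable:
    """Build a ProfileTable directly from marginal counts.

    Reporter and country are ordered (label, count) sequences so that
    verbatim source categories — including duplicated labels — are carried
    unmerged.
    """
    table = ProfileTable(drug=drug, total_reports=total)
    if gender:
        table.gender = _categorical_block(
            dict(gender), total, order=list(gender))
    if age:
        table.age = _categorical_block(dict(age), total, order=list(age))
    if reporter:
        table.reporter = [BlockRow(lbl, n, pct(n, total)) for lbl, n in reporter]
    if outcomes:
        entries = sum(outcomes.values())
        table.outcome_entries = entries
        table.outcomes = [
            BlockRow(OUTCOME_LABELS.get(code, code), n, pct(n, entries))
            for code, n in outcomes.items()
        ]
        severe = sum(n for c, n in outcomes.items() if c in SEVERE_OUTCOMES)
        table.severe_outcomes = [
            BlockRow(OUTCOME_LABELS.get(code, code), n, pct(n, severe))
            for code, n in outcomes.items() if code in SEVERE_OUTCOMES
        ]
    if country:
        table.country = [BlockRow(lbl, n, pct(n, total)) for lbl, n in country]
    return table


def death_share(deaths_per_drug: Mapping[str, int]) -> dict[str, float] | None:
    """Each drug's share (percent) of all death entries; None if no deaths."""
    total = sum(deaths_per_drug.values())
    if total == 0:
        return None
    return {drug: pct(n, total) for drug, n in deaths_per_drug.items()}


def annual_trend(
    cohort: Sequence[CaseReport],
    start_year: int | None = None,
    end_year: int | None = None,
) -> dict[int, int]:
    """Report counts per FDA receipt year, zero-filled over the window."""
    counts: dict[int, int] = {}
    for rep in cohort:
        if rep.receipt_year is not None:
            counts[rep.receipt_year] = counts.get(rep.receipt_year, 0) + 1
    if not counts and (start_year is None or end_year is None):
        return {}
    lo = start_year if start_year is not None else min(counts)
    hi = end_year if end_year is not None else max(counts)
    return {y: counts.get(y, 0) for y in range(lo, hi + 1)}


# ---------------------------------------------------------------------------
# time-to-onset


@dataclass
class TTORecord:
    primary_id: str
    onset_days: int
    bin: str


@dataclass
class TTOResult:
    records: list[TTORecord]
    bin_counts: dict[str, int]
    excluded_negative: int
    excluded_incomplete: int  # missing/partial event or start date

    @property
    def bin_shares(self) -> dict[str, float]:
        total = len(self.records)
        return {b: pct(n, total) for b, n in self.bin_counts.items()}


def assign_tto_bin(onset_days: int,
                   bins=DEFAULT_TTO_BINS, names=TTO_BIN_NAMES) -> str:
    """First bin is closed [lo,hi]; later bins are half-open (lo,hi]."""
    for i, ((lo, hi), name) in enumerate(zip(bins, names)):
        if hi is None:
            if onset_days > lo:
                return name
        elif (onset_days >= lo if i == 0 else onset_days > lo) and onset_days <= hi:
            return name
    raise ValueError(f"onset {onset_days} fits no bin")


def time_to_onset(
    cohort: Sequence[CaseReport],
    target_drug_names: Sequence[str],
    bins=DEFAULT_TTO_BINS,
    names=TTO_BIN_NAMES,
) -> TTOResult:
    """Days from earliest target-drug therapy start to the event date.

    Only complete (8-digit) dates enter the arithmetic; reports with a
    partial or missing date, or with the event before therapy start, are
    excluded and counted.
    """
    targets_norm = {normalize_drug_name(t) for t in target_drug_names}
    records: list[TTORecord] = []
    bin_counts = {name: 0 for name in names}
    excluded_negative = 0
    excluded_incomplete = 0
    for rep in cohort:
        starts = [
            e.start_date for e in rep.drugs
            if e.start_date is not None and drug_matches(e, targets_norm)
        ]
        if rep.event_date is None or not starts:
            excluded_incomplete += 1
            continue
        onset = (rep.event_date - min(starts)).days
        if onset < 0:
            excluded_negative += 1
            continue
        b = assign_tto_bin(onset, bins, names)
        records.append(TTORecord(rep.primary_id, onset, b))
        bin_counts[b] += 1
    return TTOResult(records, bin_counts, excluded_negative, excluded_incomplete)


# ---------------------------------------------------------------------------
# tabular output


def profile_frames(table: ProfileTable) -> dict[str, pd.DataFrame]:
    """One DataFrame per block, mirroring the published table layout."""
    frames = {}
    for name in ("gender", "age", "reporter", "outcomes",
                 "severe_outcomes", "country"):
        rows = table.block(name)
        frames[name] = pd.DataFrame(
            [{"label": r.label, "count": r.count, "pct": r.pct} for r in rows]
        )
    return frames


def write_profile(table: ProfileTable, directory, drug: str | None = None) -> None:
    """Write per-block TSVs plus a JSON profile document."""
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = (drug or table.drug or "cohort").lower().replace(" ", "_")
    for name, df in profile_frames(table).items():
        df.to_csv(directory / f"{stem}_{name}.tsv", sep="\t", index=False)
    with open(directory / f"{stem}_profile.json", "w", encoding="utf-8") as fh:
        json.dump(table.to_dict(), fh, indent=2)
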