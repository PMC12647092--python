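"""Reading and assembling FAERS-dialect quarterly extracts.

The FDA Adverse Event Reporting System distributes each quarter as seven
``$``-delimited ASCII tables: DEMO (demographics/administrative), DRUG,
REAC (MedDRA preferred terms), OUTC (outcome codes), RPSR (report source),
THER (therapy dates) and INDI (indications).  This module parses that
dialect, deduplicates cases the conventional way (one report per case id,
keeping the latest FDA receipt date), harmonizes ages and dates, attaches
system-organ-class annotations from a user-supplied MedDRA mapping, and
assembles per-drug case cohorts for downstream signal analysis.

MedDRA itself is licensed and never bundled; the PT→SOC mapping is a plain
two-column delimited file supplied by the user.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import logging
import re
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: Declared column schema of the seven quarterly tables (the dialect this
#: package reads and writes).  Real extracts carry more columns; unknown
#: header columns are carried opaquely in the record payload.
TABLE_SCHEMAS: dict[str, list[str]] = {
    "DEMO": [
        "primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod",
        "sex", "reporter_country", "occp_cod",
    ],
    "DRUG": ["primaryid", "caseid", "drug_seq", "role_cod", "drugname", "prod_ai"],
    "REAC": ["primaryid", "caseid", "pt"],
    "OUTC": ["primaryid", "caseid", "outc_cod"],
    "RPSR": ["primaryid", "caseid", "rpsr_cod"],
    "THER": ["primaryid", "caseid", "dsg_drug_seq", "start_dt"],
    "INDI": ["primaryid", "caseid", "indi_drug_seq", "indi_pt"],
}

MANDATORY_TABLES = ("DEMO", "DRUG", "REAC")

#: The seven FAERS outcome codes: death, life-threatening, hospitalization,
#: disability, congenital anomaly, required intervention, other serious.
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

#: Severe outcomes: hospitalization, disability, life-threatening, death.
SEVERE_OUTCOMES = frozenset({"DE", "LT", "HO", "DS"})

#: Reporter occupation codes as labelled in FAERS documentation.
OCCP_LABELS = {
    "CN": "Consumer",
    "MD": "Physician",
    "HP": "Health professional",
    "PH": "Pharmacist",
    "OT": "Other health professional",
    "LW": "Lawyer",
}

UNKNOWN = "unknown"
UNMAPPED = "UNMAPPED"

#: Age-unit → years conversion factors.
AGE_UNIT_YEARS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.0,
    "DY": 1.0 / 365.0,
    "HR": 1.0 / 8760.0,
}

_FILENAME_RE = re.compile(r"^(DEMO|DRUG|REAC|OUTC|RPSR|THER|INDI)(\d{2})Q([1-4])", re.I)


class FaersDataError(Exception):
    """Fatal problem with the input data (missing mandatory table, ...)."""


# ---------------------------------------------------------------------------
# dates


def parse_faers_date(raw: str) -> tuple[_dt.date | None, int | None]:
    """Parse a FAERS date field.

    8-digit YYYYMMDD gives a full date; 6-digit YYYYMM and 4-digit YYYY are
    partial — usable for the year but excluded from day arithmetic.

    Returns ``(date_or_None, year_or_None)``.
    """
    s = (raw or "").strip()
    if not s.isdigit():
        return None, None
    try:
        if len(s) == 8:
            d = _dt.date(int(s[:4]), int(s[4:6]), int(s[6:8]))
            return d, d.year
        if len(s) == 6:
            year, month = int(s[:4]), int(s[4:6])
            if 1 <= month <= 12:
                return None, year
            return None, None
        if len(s) == 4:
            return None, int(s)
    except ValueError:
        return None, None
    return None, None


def format_faers_date(d: _dt.date) -> str:
    return f"{d.year:04d}{d.month:02d}{d.day:02d}"


# ---------------------------------------------------------------------------
# raw records and parsing


@dataclass
class RawCaseRecord:
    """One data row of one quarterly table, fields as read."""

    primary_id: str
    case_id: str
    fda_receipt_date: _dt.date | None
    source_table: str
    payload: dict[str, str]


@dataclass
class ParseResult:
    """Parsed rows of one or more quarters, grouped by table."""

    records: dict[str, list[RawCaseRecord]] = field(
        default_factory=lambda: {t: [] for t in TABLE_SCHEMAS}
    )
    row_counts: dict[str, int] = field(
        default_factory=lambda: {t: 0 for t in TABLE_SCHEMAS}
    )
    skipped_counts: dict[str, int] = field(
        default_factory=lambda: {t: 0 for t in TABLE_SCHEMAS}
    )

    def extend(self, other: "ParseResult") -> None:
        for t in TABLE_SCHEMAS:
            self.records[t].extend(other.records[t])
            self.row_counts[t] += other.row_counts[t]
            self.skipped_counts[t] += other.skipped_counts[t]


def table_of_filename(path: str | Path) -> str | None:
    """Infer the table name from a ``{TABLE}{YY}Q{Q}.txt`` file name."""
    m = _FILENAME_RE.match(Path(path).name)
    return m.group(1).upper() if m else None


def parse_table(path: str | Path, table: str) -> tuple[list[RawCaseRecord], int]:
    """Parse one ``$``-delimited table file.

    Rows whose field count disagrees with the header are logged and skipped;
    the skip count is returned alongside the records.  Header columns not in
    the declared schema are warned about and carried opaquely.
    """
    table = table.upper()
    if table not in TABLE_SCHEMAS:
        raise FaersDataError(f"unknown FAERS table {table!r}")
    records: list[RawCaseRecord] = []
    skipped = 0
    with open(path, "r", encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n").rstrip("\r")
        if not header_line:
            return records, skipped
        header = [h.strip() for h in header_line.split("$")]
        known = set(TABLE_SCHEMAS[table])
        for col in header:
            if col not in known:
                logger.warning(
                    "%s: unknown column %r in %s header; carried opaquely",
                    path, col, table,
                )
        ncol = len(header)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("$")
            if len(fields) != ncol:
                skipped += 1
                logger.info("%s:%d: wrong field count (%d != %d), skipped",
                            path, lineno, len(fields), ncol)
                continue
            payload = dict(zip(header, fields))
            fda_date, _ = parse_faers_date(payload.get("fda_dt", ""))
            records.append(
                RawCaseRecord(
                    primary_id=payload.get("primaryid", "").strip(),
                    case_id=payload.get("caseid", "").strip(),
                    fda_receipt_date=fda_date,
                    source_table=table,
                    payload=payload,
                )
            )
    return records, skipped


def parse_quarter(files: Iterable[str | Path] | Mapping[str, str | Path]) -> ParseResult:
    """Parse one quarter's files (a path iterable or a table→path mapping).

    Missing mandatory tables (DEMO, DRUG, REAC) are fatal; the other four are
    optional and simply absent from the result if not provided.
    """
    if isinstance(files, Mapping):
        table_paths = {t.upper(): Path(p) for t, p in files.items()}
    else:
        table_paths = {}
        for p in files:
            t = table_of_filename(p)
            if t is None:
                raise FaersDataError(f"cannot infer table from file name {p}")
            table_paths[t] = Path(p)
    for t in MANDATORY_TABLES:
        if t not in table_paths:
            raise FaersDataError(f"missing mandatory table {t}")
    result = ParseResult()
    for t, p in sorted(table_paths.items()):
        records, skipped = parse_table(p, t)
        result.records[t].extend(records)
        result.row_counts[t] += len(records)
        result.skipped_counts[t] += skipped
    return result


def parse_dataset(directory: str | Path) -> ParseResult:
    """Parse every recognisable quarterly file under ``directory``."""
    directory = Path(directory)
    by_quarter: dict[str, dict[str, Path]] = {}
    for p in sorted(directory.glob("*.txt")):
        m = _FILENAME_RE.match(p.name)
        if not m:
            continue
        key = m.group(2) + "Q" + m.group(3)
        by_quarter.setdefault(key, {})[m.group(1).upper()] = p
    if not by_quarter:
        raise FaersDataError(f"no FAERS-dialect files found under {directory}")
    result = ParseResult()
    for key in sorted(by_quarter):
        result.extend(parse_quarter(by_quarter[key]))
    return result


# ---------------------------------------------------------------------------
# deduplication


@dataclass
class DedupResult:
    retained: set[str]
    no_case_id: int  # records retained as singletons for lack of a case id


def deduplicate(demo_records: Sequence[RawCaseRecord]) -> DedupResult:
    """Keep one report per case: the one with the latest FDA receipt date.

    Ties are broken by the numerically largest primary id.  Records lacking a
    case id cannot be grouped and are retained as singletons (counted).
    The operation is idempotent.
    """
    def _pid_key(pid: str):
        try:
            return (1, int(pid))
        except ValueError:
            return (0, pid)

    best: dict[str, RawCaseRecord] = {}
    retained: set[str] = set()
    no_case_id = 0
    for rec in demo_records:
        if not rec.case_id:
            retained.add(rec.primary_id)
            no_case_id += 1
            continue
        cur = best.get(rec.case_id)
        if cur is None:
            best[rec.case_id] = rec
            continue
        key_new = (rec.fda_receipt_date or _dt.date.min, _pid_key(rec.primary_id))
        key_cur = (cur.fda_receipt_date or _dt.date.min, _pid_key(cur.primary_id))
        if key_new > key_cur:
            best[rec.case_id] = rec
    retained.update(r.primary_id for r in best.values())
    return DedupResult(retained=retained, no_case_id=no_case_id)


# ---------------------------------------------------------------------------
# harmonization


def harmonize_age(age_value, age_unit_code: str) -> float | None:
    """Convert an (age value, unit code) pair to years; None when unknown.

    Total function: absent or invalid input and negative ages give None
    (negative ages with a warning).
    """
    code = (age_unit_code or "").strip().upper()
    try:
        value = float(age_value)
    except (TypeError, ValueError):
        return None
    if code not in AGE_UNIT_YEARS:
        return None
    if value < 0:
        logger.warning("negative age %r %s treated as unknown", age_value, code)
        return None
    return value * AGE_UNIT_YEARS[code]


def assign_age_group(age_years: float | None) -> str:
    """Half-open age bins: [0,18) under18, [18,65) from18to65, [65,∞) over65."""
    if age_years is None:
        return UNKNOWN
    if age_years < 18:
        return "under18"
    if age_years < 65:
        return "from18to65"
    return "over65"


_PUNCT_TABLE = str.maketrans({c: " " for c in string.punctuation})


def normalize_drug_name(name: str) -> str:
    """Lower-case, strip punctuation, collapse whitespace."""
    return " ".join((name or "").translate(_PUNCT_TABLE).lower().split())


def normalize_pt(pt: str) -> str:
    return " ".join((pt or "").strip().lower().split())


# ---------------------------------------------------------------------------
# MedDRA PT → SOC mapping


class MedDRAMap:
    """User-supplied preferred-term → system-organ-class mapping.

    Lookup is case-insensitive after whitespace normalization; terms not in
    the mapping resolve to the explicit :data:`UNMAPPED` marker.
    """

    def __init__(self, pt_to_soc: Mapping[str, str] | None = None):
        self._map: dict[str, str] = {}
        if pt_to_soc:
            for pt, soc in pt_to_soc.items():
                self._map[normalize_pt(pt)] = soc.strip()

    @classmethod
    def from_file(cls, path: str | Path) -> "MedDRAMap":
        """Read a two-column (pt, soc) comma- or tab-delimited file."""
        mapping: dict[str, str] = {}
        with open(path, "r", encoding="utf-8") as fh:
            first = fh.readline()
            sep = "\t" if "\t" in first else ","
            header = [h.strip().lower() for h in first.rstrip("\n").split(sep)]
            if header[:2] != ["pt", "soc"]:
                raise FaersDataError(
                    f"{path}: expected header 'pt{sep}soc', got {first!r}"
                )
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                # split on the first separator only: SOC names may contain
                # commas ("Respiratory, thoracic and mediastinal disorders")
                parts = line.split(sep, 1)
                if len(parts) < 2 or not parts[1].strip():
                    raise FaersDataError(f"{path}: malformed mapping line {line!r}")
                mapping[parts[0]] = parts[1]
        return cls(mapping)

    def soc_of(self, pt: str) -> str:
        return self._map.get(normalize_pt(pt), UNMAPPED)

    def __len__(self) -> int:
        return len(self._map)


# ---------------------------------------------------------------------------
# assembled case reports


@dataclass
class DrugEntry:
    name: str
    role: str  # PS, SS, C, I ... as read
    start_date: _dt.date | None = None
    alias: str | None = None  # active-ingredient field, when it differs


@dataclass
class CaseReport:
    """One deduplicated spontaneous report with all tables joined."""

    primary_id: str
    case_id: str
    sex: str  # "male" | "female" | "unknown"
    age_years: float | None
    age_group: str
    country: str  # verbatim code or "unknown"
    reporter: str  # occupation label or "unknown"
    outcomes: frozenset[str]
    drugs: list[DrugEntry]
    reactions: list[str]  # distinct PTs, input order
    reaction_socs: dict[str, str]
    event_date: _dt.date | None
    receipt_year: int | None
    indications: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        d = {
            "primary_id": self.primary_id,
            "case_id": self.case_id,
            "sex": self.sex,
            "age_years": self.age_years,
            "age_group": self.age_group,
            "country": self.country,
            "reporter": self.reporter,
            "outcomes": sorted(self.outcomes),
            "drugs": [
                [e.name, e.role,
                 e.start_date.isoformat() if e.start_date else None, e.alias]
                for e in self.drugs
            ],
            "reactions": self.reactions,
            "reaction_socs": self.reaction_socs,
            "event_date": self.event_date.isoformat() if self.event_date else None,
            "receipt_year": self.receipt_year,
            "indications": self.indications,
        }
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, line: str) -> "CaseReport":
        d = json.loads(line)
        return cls(
            primary_id=d["primary_id"],
            case_id=d["case_id"],
            sex=d["sex"],
            age_years=d["age_years"],
            age_group=d["age_group"],
            country=d["country"],
            reporter=d["reporter"],
            outcomes=frozenset(d["outcomes"]),
            drugs=[
                DrugEntry(n, r, _dt.date.fromisoformat(s) if s else None, alias)
                for n, r, s, alias in d["drugs"]
            ],
            reactions=d["reactions"],
            reaction_socs=d["reaction_socs"],
            event_date=_dt.date.fromisoformat(d["event_date"]) if d["event_date"] else None,
            receipt_year=d["receipt_year"],
            indications=d.get("indications", []),
        )


def write_cohort(reports: Iterable[CaseReport], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in reports:
            fh.write(r.to_json() + "\n")


def read_cohort(path: str | Path) -> list[CaseReport]:
    with open(path, "r", encoding="utf-8") as fh:
        return [CaseReport.from_json(line) for line in fh if line.strip()]


def _sex_label(raw: str) -> str:
    s = (raw or "").strip().upper()
    if s == "M":
        return "male"
    if s == "F":
        return "female"
    return UNKNOWN


def assemble_reports(
    parsed: ParseResult,
    retained: set[str],
    meddra: MedDRAMap | None = None,
) -> dict[str, CaseReport]:
    """Join the seven tables into :class:`CaseReport` objects by primary id.

    Only the retained (deduplicated) primary ids are assembled.  Result is
    independent of input row order up to the stable ordering of list fields.
    """
    meddra = meddra or MedDRAMap()
    ther_by_key: dict[tuple[str, str], _dt.date] = {}
    for rec in parsed.records["THER"]:
        d, _ = parse_faers_date(rec.payload.get("start_dt", ""))
        if d is not None:
            key = (rec.primary_id, rec.payload.get("dsg_drug_seq", "").strip())
            prev = ther_by_key.get(key)
            if prev is None or d < prev:
                ther_by_key[key] = d

    reports: dict[str, CaseReport] = {}
    for rec in parsed.records["DEMO"]:
        if rec.primary_id not in retained or rec.primary_id in reports:
            continue
        p = rec.payload
        age = harmonize_age(p.get("age", ""), p.get("age_cod", ""))
        event_date, _ = parse_faers_date(p.get("event_dt", ""))
        _, receipt_year = parse_faers_date(p.get("fda_dt", ""))
        occp = (p.get("occp_cod", "") or "").strip().upper()
        country = (p.get("reporter_country", "") or "").strip()
        reports[rec.primary_id] = CaseReport(
            primary_id=rec.primary_id,
            case_id=rec.case_id,
            sex=_sex_label(p.get("sex", "")),
            age_years=age,
            age_group=assign_age_group(age),
            country=country if country else UNKNOWN,
            reporter=OCCP_LABELS.get(occp, UNKNOWN if not occp else occp),
            outcomes=frozenset(),
            drugs=[],
            reactions=[],
            reaction_socs={},
            event_date=event_date,
            receipt_year=receipt_year,
        )

    for rec in parsed.records["DRUG"]:
        rep = reports.get(rec.primary_id)
        if rep is None:
            continue
        p = rec.payload
        seq = p.get("drug_seq", "").strip()
        rep.drugs.append(
            DrugEntry(
                name=p.get("drugname", "").strip(),
                role=(p.get("role_cod", "") or "").strip().upper(),
                start_date=ther_by_key.get((rec.primary_id, seq)),
            )
        )
        ai = p.get("prod_ai", "").strip()
        if ai and normalize_drug_name(ai) != normalize_drug_name(rep.drugs[-1].name):
            rep.drugs[-1].alias = ai

    for rec in parsed.records["REAC"]:
        rep = reports.get(rec.primary_id)
        if rep is None:
            continue
        pt = rec.payload.get("pt", "").strip()
        if pt and pt not in rep.reactions:
            rep.reactions.append(pt)
            rep.reaction_socs[pt] = meddra.soc_of(pt)

    for rec in parsed.records["INDI"]:
        rep = reports.get(rec.primary_id)
        if rep is None:
            continue
        indi = rec.payload.get("indi_pt", "").strip()
        if indi and indi not in rep.indications:
            rep.indications.append(indi)

    outc_seen: set[tuple[str, str]] = set()
    for rec in parsed.records["OUTC"]:
        rep = reports.get(rec.primary_id)
        if rep is None:
            continue
        code = rec.payload.get("outc_cod", "").strip().upper()
        if code in OUTCOME_CODES and (rec.primary_id, code) not in outc_seen:
            outc_seen.add((rec.primary_id, code))
            rep.outcomes = rep.outcomes | {code}

    return reports


def drug_matches(
    entry: DrugEntry,
    targets_norm: set[str],
    substring: bool = False,
) -> bool:
    """Match a drug row against normalized target names.

    Exact normalized match by default; substring match optional.  Both the
    verbatim drug-name field and (when present) the active-ingredient alias
    are consulted.
    """
    candidates = [normalize_drug_name(entry.name)]
    if entry.alias:
        candidates.append(normalize_drug_name(entry.alias))
    for cand in candidates:
        if not cand:
            continue
        if substring:
            if any(t in cand for t in targets_norm):
                return True
        elif cand in targets_norm:
            return True
    return False


def strip_indication_reactions(report: CaseReport) -> CaseReport:
    """Copy of a report with PTs equal to a treated indication removed.

    Optional filter for analyses where the indication itself (e.g. the
    treated disease) should not compete as an adverse-event term; off by
    default throughout, since published analyses generally keep such PTs.
    """
    indi_norm = {normalize_pt(i) for i in report.indications}
    if not indi_norm:
        return report
    kept = [pt for pt in report.reactions if normalize_pt(pt) not in indi_norm]
    if len(kept) == len(report.reactions):
        return report
    return dataclasses.replace(
        report,
        reactions=kept,
        reaction_socs={pt: soc for pt, soc in report.reaction_socs.items()
                       if normalize_pt(pt) not in indi_norm},
    )


DEFAULT_ROLE_CODES = frozenset({"PS", "SS"})


def build_cohort(
    reports: Mapping[str, CaseReport],
    target_drug_names: Sequence[str],
    substring: bool = False,
    role_codes: frozenset[str] | None = DEFAULT_ROLE_CODES,
) -> list[CaseReport]:
    """Select the reports in which any drug row matches a target name.

    Primary- and secondary-suspect roles are included by default; pass
    ``role_codes=None`` to accept any role.  An empty cohort warns but is
    not fatal.  Output order is by primary id, so the cohort is independent
    of input row order.
    """
    targets_norm = {normalize_drug_name(t) for t in target_drug_names}
    cohort = []
    for rep in reports.values():
        for entry in rep.drugs:
            if role_codes is not None and entry.role not in role_codes:
                continue
            if drug_matches(entry, targets_norm, substring=substring):
                cohort.append(rep)
                break
    if not cohort:
        logger.warning("empty cohort for targets %s", sorted(target_drug_names))
    cohort.sort(key=lambda r: (len(r.primary_id), r.primary_id))
    return cohort


def write_records(result: ParseResult, directory: str | Path,
                  year: int, quarter: int) -> None:
    """Write parsed records back out in the same quarterly dialect.

    Together with :func:`parse_quarter` this makes parsing a fixed point at
    field level (used by the round-trip tests).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    yy = year % 100
    for table, records in result.records.items():
        if not records:
            continue
        columns: list[str] = []
        for rec in records:
            for k in rec.payload:
                if k not in columns:
                    columns.append(k)
        path = directory / f"{table}{yy:02d}Q{quarter}.txt"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("$".join(columns) + "\n")
            for rec in records:
                fh.write("$".join(rec.payload.get(c, "") for c in columns) + "\n")
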