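"""End-to-end orchestration: ingest → dedup → cohorts → signals → outputs.

The functions here wire the stage modules together the way the CLI and the
reproduction script use them; each stage remains individually importable.
Runs are deterministic for fixed inputs, and a manifest records the
configuration hash and input checksums so any output can be regenerated.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import faers_io, profiles, signals
from .faers_io import CaseReport, MedDRAMap
from .signals import SignalConfig, SignalResult

logger = logging.getLogger(__name__)


@dataclass
class SignalRun:
    """Everything the signal stage produced, for inspection or writing."""

    reports: dict[str, CaseReport]
    cohorts: dict[str, list[CaseReport]]
    results: list[SignalResult]
    dedup_retained: int
    dedup_no_case_id: int
    parse_row_counts: dict[str, int]
    parse_skipped: dict[str, int]
    empty_cohorts: list[str] = field(default_factory=list)

    def positive_sets(self) -> dict[str, set]:
        sets: dict[str, set] = {d: set() for d in self.cohorts}
        for r in self.results:
            if r.any_positive:
                sets[r.drug].add(r.pt)
        return sets

    def strong_counts(self) -> dict[str, int]:
        return signals.strong_signal_counts(self.results)


def run_signal_stage(
    data_dir: str | Path,
    target_drugs: Sequence[str],
    meddra: MedDRAMap | None = None,
    config: SignalConfig | None = None,
    substring_match: bool = False,
    role_codes=faers_io.DEFAULT_ROLE_CODES,
    exclude_indication_pts: bool = False,
) -> SignalRun:
    """Parse a quarterly dataset and evaluate each target drug's signals.

    The background for every 2×2 table is the full deduplicated dataset.
    An empty cohort for one target is recorded and the run continues for
    the others.  ``exclude_indication_pts`` drops reaction PTs equal to a
    report's treated indication before counting (off by default).
    """
    config = config or SignalConfig()
    parsed = faers_io.parse_dataset(data_dir)
    dedup = faers_io.deduplicate(parsed.records["DEMO"])
    reports = faers_io.assemble_reports(parsed, dedup.retained, meddra)
    if exclude_indication_pts:
        reports = {pid: faers_io.strip_indication_reactions(rep)
                   for pid, rep in reports.items()}
    background = list(reports.values())
    cohorts: dict[str, list[CaseReport]] = {}
    empty = []
    for drug in target_drugs:
        cohort = faers_io.build_cohort(
            reports, [drug], substring=substring_match, role_codes=role_codes)
        cohorts[drug] = cohort
        if not cohort:
            empty.append(drug)
            logger.warning("empty cohort for %s; continuing", drug)
    results = signals.signal_scan(
        {d: c for d, c in cohorts.items() if c}, background,
        meddra=meddra, config=config)
    return SignalRun(
        reports=reports,
        cohorts=cohorts,
        results=results,
        dedup_retained=len(dedup.retained),
        dedup_no_case_id=dedup.no_case_id,
        parse_row_counts=dict(parsed.row_counts),
        parse_skipped=dict(parsed.skipped_counts),
        empty_cohorts=empty,
    )


def write_signal_outputs(run: SignalRun, outdir: str | Path) -> None:
    """Signal TSV/JSON, SOC aggregation, overlap summary, profile tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    signals.write_results(run.results, outdir / "signals.tsv")
    soc = signals.soc_aggregate(run.results)
    soc.to_csv(outdir / "soc_aggregate.tsv", sep="\t", index=False)
    overlap = signals.overlap_pts(run.positive_sets())
    overlap_doc = {
        "|".join(sorted(k)): sorted(v) for k, v in overlap.regions.items()
    }
    summary = {
        "dedup_retained": run.dedup_retained,
        "dedup_no_case_id": run.dedup_no_case_id,
        "parse_row_counts": run.parse_row_counts,
        "parse_skipped": run.parse_skipped,
        "cohort_sizes": {d: len(c) for d, c in run.cohorts.items()},
        "empty_cohorts": run.empty_cohorts,
        "strong_signal_counts": run.strong_counts(),
        "any_positive_counts": {
            d: len(s) for d, s in run.positive_sets().items()
        },
        "overlap_regions": overlap_doc,
    }
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    for drug, cohort in run.cohorts.items():
        table = profiles.demographic_summary(cohort, drug=drug)
        profiles.write_profile(table, outdir / "profiles", drug=drug)


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir: str | Path, config_doc: Mapping,
                   input_paths: Sequence[str | Path]) -> None:
    """Run manifest: config hash plus input checksums."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config_json = json.dumps(config_doc, sort_keys=True, default=str)
    manifest = {
        "config": json.loads(config_json),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "inputs": {
            str(p): file_checksum(p) for p in sorted(map(str, input_paths))
            if Path(p).is_file()
        },
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
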