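"""Generate a synthetic quarterly dataset, parse it and build drug cohorts.

Emulates a spontaneous-reporting download: seven $-delimited tables per
quarter, planted duplicate cases, and a known drug catalog.  The ingestion
stage parses the files, keeps one report per case (latest FDA receipt date)
and selects the reports mentioning each target drug as a suspect.
"""

import tempfile
from pathlib import Path

from faersig.faers_io import (
    MedDRAMap, assemble_reports, build_cohort, deduplicate, parse_dataset,
)
from faersig.synthetic import SyntheticConfig, generate_faers_data, write_meddra_map

with tempfile.TemporaryDirectory() as td:
    out = Path(td)
    config = SyntheticConfig(
        rng_seed=7,
        n_reports=2000,
        duplicate_rate=0.1,
        planted_signals=(("RILUZOLE", "HEPATIC ENZYME INCREASED", 8.0),),
    )
    truth = generate_faers_data(config, out)
    write_meddra_map(config, out / "meddra_map.csv")

    parsed = parse_dataset(out)
    print("rows per table:", dict(sorted(parsed.row_counts.items())))
    print("skipped rows:  ", sum(parsed.skipped_counts.values()))

    dedup = deduplicate(parsed.records["DEMO"])
    print(f"DEMO rows {parsed.row_counts['DEMO']} -> retained "
          f"{len(dedup.retained)} unique cases "
          f"(generator planted {truth.unique_case_count})")

    meddra = MedDRAMap.from_file(out / "meddra_map.csv")
    reports = assemble_reports(parsed, dedup.retained, meddra)
    for drug in ("Riluzole", "Edaravone", "Tofersen"):
        cohort = build_cohort(reports, [drug])
        print(f"{drug:10s} cohort: {len(cohort)} reports")

# The retained count equals the planted unique-case count: the 10% planted
# duplicates (same case id, earlier receipt date) were all removed.  Cohort
# sizes reflect each drug's configured use probability.
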