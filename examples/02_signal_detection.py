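"""Disproportionality scan: four algorithms, classification and overlap.

Runs the full 2×2-table analysis over a synthetic dataset with one planted
drug–event association and prints that drug's top-ranked signals together
with the per-drug strong-signal counts and overlap regions.
"""

import tempfile
from pathlib import Path

from faersig import pipeline
from faersig.faers_io import MedDRAMap
from faersig.signals import overlap_pts, soc_aggregate
from faersig.synthetic import SyntheticConfig, generate_faers_data, write_meddra_map

with tempfile.TemporaryDirectory() as td:
    out = Path(td)
    config = SyntheticConfig(
        rng_seed=3,
        n_reports=20_000,
        planted_signals=(
            ("RILUZOLE", "HEPATIC ENZYME INCREASED", 8.0),
            ("EDARAVONE", "GAIT DISTURBANCE", 4.0),
        ),
    )
    generate_faers_data(config, out)
    write_meddra_map(config, out / "meddra_map.csv")
    meddra = MedDRAMap.from_file(out / "meddra_map.csv")

    run = pipeline.run_signal_stage(
        out, ["Riluzole", "Edaravone", "Tofersen"], meddra=meddra)

    print("drug      a     ROR    [95% CI]        PRR    chi2    IC025  EBGM05 strong")
    for res in run.results:
        if res.drug != "Riluzole":
            continue
        if res.table.a < 10:
            continue
        r = res
        print(f"{r.pt[:24]:24s} a={r.table.a:4d} ror={r.ror.ror:6.2f} "
              f"[{r.ror.ci95_low:5.2f},{r.ror.ci95_high:6.2f}] "
              f"prr={r.prr.prr:5.2f} chi2={r.prr.chi2:7.1f} "
              f"ic025={r.bcpnn.ic025:6.2f} ebgm05={r.ebgm.ebgm05:5.2f} "
              f"{'STRONG' if r.strong else ''}")

    print("\nstrong signals per drug:", run.strong_counts())
    overlap = overlap_pts(run.positive_sets())
    print("shared by Riluzole & Edaravone only:",
          sorted(overlap.pair_only("Riluzole", "Edaravone")))
    print("\nSOC aggregation (head):")
    print(soc_aggregate(run.results).head(6).to_string(index=False))

# The planted pair surfaces at the top of the ranking with all four
# algorithms positive (STRONG); background pairs hover around ROR ≈ 1.
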