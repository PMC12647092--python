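"""Shared fixtures: synthetic datasets reused across test modules.

The expensive session fixtures run the full pipeline once on generated
data; individual tests then only inspect the results.
"""

from __future__ import annotations

import pytest

from faersig import pipeline
from faersig.faers_io import MedDRAMap
from faersig.synthetic import (
    SyntheticConfig,
    generate_faers_data,
    generic_pt_catalog,
    write_meddra_map,
)

TARGET_DRUGS = ("Riluzole", "Edaravone", "Tofersen")

#: Planted reporting-rate ratios for the recovery experiment.
RECOVERY_SIGNALS = (
    ("RILUZOLE", "ABDOMINAL DISCOMFORT", 2.0),
    ("EDARAVONE", "GAIT DISTURBANCE", 5.0),
    ("TOFERSEN", "FALL", 10.0),
)


def run_pipeline_on(config: SyntheticConfig, directory, targets=TARGET_DRUGS):
    truth = generate_faers_data(config, directory)
    write_meddra_map(config, directory / "meddra_map.csv")
    meddra = MedDRAMap.from_file(directory / "meddra_map.csv")
    run = pipeline.run_signal_stage(directory, list(targets), meddra=meddra)
    return config, truth, run


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small quarterly dataset with one planted signal and duplicates."""
    directory = tmp_path_factory.mktemp("small_faers")
    config = SyntheticConfig(
        rng_seed=11,
        n_reports=1500,
        duplicate_rate=0.2,
        planted_signals=(("RILUZOLE", "HEPATIC ENZYME INCREASED", 10.0),),
    )
    return run_pipeline_on(config, directory) + (directory,)


@pytest.fixture(scope="session")
def recovery_dataset(tmp_path_factory):
    """n=50,000 reports with planted RR ∈ {2, 5, 10} on three drug–PT pairs."""
    directory = tmp_path_factory.mktemp("recovery_faers")
    config = SyntheticConfig(
        rng_seed=2024,
        n_reports=50_000,
        planted_signals=RECOVERY_SIGNALS,
    )
    return run_pipeline_on(config, directory)


@pytest.fixture(scope="session")
def null_dataset_10k(tmp_path_factory):
    """n=10,000 reports, 50 PTs, nothing planted — type-I error control."""
    directory = tmp_path_factory.mktemp("null_faers_10k")
    config = SyntheticConfig(
        rng_seed=7,
        n_reports=10_000,
        pt_catalog=generic_pt_catalog(50),
        planted_signals=(),
    )
    return run_pipeline_on(config, directory, targets=tuple(config.drug_catalog))


@pytest.fixture(scope="session")
def null_dataset_20k(tmp_path_factory):
    """n=20,000 null reports — ROR false-positive calibration."""
    directory = tmp_path_factory.mktemp("null_faers_20k")
    config = SyntheticConfig(
        rng_seed=13,
        n_reports=20_000,
        pt_catalog=generic_pt_catalog(50),
        planted_signals=(),
    )
    return run_pipeline_on(config, directory, targets=tuple(config.drug_catalog))
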