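"""Synthetic spontaneous-report and PPI data with known ground truth.

Real quarterly extracts of a spontaneous-reporting system cannot be bundled,
so every pipeline stage is exercised against generated data whose generative
model is fully known:

* per report, drugs are drawn independently by their marginal use
  probabilities (a report whose draws all come up empty is assigned a
  catch-all filler drug, so each catalog drug's marginal stays exact);
* each preferred term (PT) is then drawn independently with probability
  background × RR, where the reporting-rate ratio RR > 1 only for planted
  drug–PT signals carried by a drug present in the report;
* demographics (sex, age, country, reporter occupation) and outcome codes
  follow configurable categorical/Bernoulli distributions;
* receipt and therapy-start dates are uniform within the report's quarter,
  event dates are therapy start plus a Weibull-distributed onset;
* a configurable fraction of cases is emitted twice under the same case id
  with an earlier receipt date (duplicates the deduplication stage must
  remove), and a fraction of event dates is truncated to partial YYYYMM
  precision;
* PPI edge lists contain two planted high-score cliques over an
  Erdős–Rényi background.

Because every marginal is explicit, closed-form expectations of the 2×2
contingency cells are available (:func:`expected_contingency`, by exact
enumeration over drug subsets) and serve as the analytic oracle in tests.
Identical config + seed produces byte-identical files.
"""

from __future__ import annotations

import datetime as _dt
import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .faers_io import (
    CaseReport,
    DrugEntry,
    OUTCOME_CODES,
    UNMAPPED,
    UNKNOWN,
    assign_age_group,
    format_faers_date,
)

FILLER_DRUG = "OTHERDRUG"
DEFAULT_INDICATION = "PRODUCT USED FOR UNKNOWN INDICATION"


class ConfigError(Exception):
    """Infeasible synthetic configuration (e.g. probability above 1)."""


@dataclass(frozen=True)
class PTSpec:
    name: str
    background: float  # per-report background reporting probability
    soc: str


@dataclass
class SyntheticConfig:
    """Full recipe for one synthetic quarterly dataset.

    Defaults describe a mid-sized cohort shaped like published ALS-drug
    report demographics: three target drugs with distinct use probabilities
    plus common co-medication, ~30 PTs across several organ classes, a
    mostly-US reporting mix, consumer-dominated reporter occupations, and
    heavy-tailed Weibull onsets.
    """

    rng_seed: int = 0
    n_reports: int = 5000
    quarters: tuple[tuple[int, int], ...] = (
        (2023, 1), (2023, 2), (2023, 3), (2023, 4),
    )
    quarter_weights: tuple[float, ...] | None = None
    drug_catalog: dict[str, float] = field(default_factory=lambda: {
        "RILUZOLE": 0.10,
        "EDARAVONE": 0.12,
        "TOFERSEN": 0.04,
        "BACLOFEN": 0.25,
        "GABAPENTIN": 0.20,
        "OMEPRAZOLE": 0.30,
    })
    pt_catalog: tuple[PTSpec, ...] = ()
    planted_signals: tuple[tuple[str, str, float], ...] = ()
    sex_dist: dict[str, float] = field(default_factory=lambda: {
        "M": 0.45, "F": 0.35, "": 0.20,
    })
    age_known_prob: float = 0.65
    age_mean: float = 58.0
    age_sd: float = 14.0
    country_dist: dict[str, float] = field(default_factory=lambda: {
        "US": 0.65, "JP": 0.10, "DE": 0.06, "GB": 0.06,
        "CA": 0.04, "IT": 0.04, "": 0.05,
    })
    reporter_dist: dict[str, float] = field(default_factory=lambda: {
        "CN": 0.50, "MD": 0.12, "PH": 0.20, "OT": 0.12, "LW": 0.01, "": 0.05,
    })
    outcome_probs: dict[str, float] = field(default_factory=lambda: {
        "DE": 0.28, "LT": 0.03, "HO": 0.30, "DS": 0.02,
        "CA": 0.001, "RI": 0.005, "OT": 0.25,
    })
    duplicate_rate: float = 0.05
    partial_date_rate: float = 0.10
    tto_shape: float = 1.2
    tto_scale: float = 45.0
    indication_by_drug: dict[str, str] = field(default_factory=lambda: {
        "RILUZOLE": "AMYOTROPHIC LATERAL SCLEROSIS",
        "EDARAVONE": "AMYOTROPHIC LATERAL SCLEROSIS",
        "TOFERSEN": "AMYOTROPHIC LATERAL SCLEROSIS",
    })

    def __post_init__(self):
        if not self.pt_catalog:
            self.pt_catalog = default_pt_catalog()
        self.validate()

    def validate(self) -> None:
        for dist_name in ("sex_dist", "country_dist", "reporter_dist"):
            probs = list(getattr(self, dist_name).values())
            if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
                raise ConfigError(f"{dist_name} must be a probability distribution")
        for p in itertools.chain(self.drug_catalog.values(),
                                 self.outcome_probs.values()):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("probabilities must lie in [0, 1]")
        bg = {p.name: p.background for p in self.pt_catalog}
        drugs = set(self.drug_catalog)
        for drug, pt, rr in self.planted_signals:
            if rr <= 0:
                raise ConfigError(f"planted RR must be > 0 for ({drug}, {pt})")
            if drug not in drugs:
                raise ConfigError(f"planted signal names unknown drug {drug!r}")
            if pt not in bg:
                raise ConfigError(f"planted signal names unknown PT {pt!r}")
            if bg[pt] * rr > 1.0:
                raise ConfigError(
                    f"planted pair ({drug}, {pt}): background {bg[pt]} × RR {rr} "
                    "exceeds probability 1"
                )


def default_pt_catalog() -> tuple[PTSpec, ...]:
    """~30 PTs with background rates and SOC assignments."""
    soc_nerv = "Nervous system disorders"
    soc_gen = "General disorders and administration site conditions"
    soc_gi = "Gastrointestinal disorders"
    soc_resp = "Respiratory, thoracic and mediastinal disorders"
    soc_inj = "Injury, poisoning and procedural complications"
    soc_inv = "Investigations"
    soc_musc = "Musculoskeletal and connective tissue disorders"
    soc_vasc = "Vascular disorders"
    entries = [
        ("DEATH", 0.030, soc_gen), ("ASTHENIA", 0.025, soc_gen),
        ("FATIGUE", 0.030, soc_gen), ("DISEASE PROGRESSION", 0.015, soc_gen),
        ("GAIT DISTURBANCE", 0.020, soc_gen), ("MALAISE", 0.015, soc_gen),
        ("HEADACHE", 0.035, soc_nerv), ("DIZZINESS", 0.030, soc_nerv),
        ("HYPOAESTHESIA ORAL", 0.004, soc_nerv), ("APHASIA", 0.005, soc_nerv),
        ("SOMNOLENCE", 0.012, soc_nerv), ("TREMOR", 0.010, soc_nerv),
        ("NAUSEA", 0.040, soc_gi), ("DIARRHOEA", 0.030, soc_gi),
        ("ABDOMINAL DISCOMFORT", 0.010, soc_gi), ("VOMITING", 0.020, soc_gi),
        ("CONSTIPATION", 0.015, soc_gi), ("DYSPHAGIA", 0.008, soc_gi),
        ("DYSPNOEA", 0.025, soc_resp), ("RESPIRATORY FAILURE", 0.008, soc_resp),
        ("ASPIRATION PNEUMONIA", 0.005, soc_resp), ("COUGH", 0.015, soc_resp),
        ("FALL", 0.020, soc_inj), ("PROCEDURAL PAIN", 0.004, soc_inj),
        ("POST LUMBAR PUNCTURE SYNDROME", 0.002, soc_inj),
        ("CONTUSION", 0.008, soc_inj),
        ("HEPATIC ENZYME INCREASED", 0.006, soc_inv),
        ("CSF RED BLOOD CELL COUNT POSITIVE", 0.002, soc_inv),
        ("MUSCULAR WEAKNESS", 0.018, soc_musc),
        ("MUSCLE TWITCHING", 0.006, soc_musc),
        ("LIMB DISCOMFORT", 0.005, soc_musc),
        ("THROMBOSIS", 0.005, soc_vasc),
    ]
    return tuple(PTSpec(n, b, s) for n, b, s in entries)


def generic_pt_catalog(n: int, bg_low: float = 0.002,
                       bg_high: float = 0.03) -> tuple[PTSpec, ...]:
    """n generic PTs with background rates evenly spread over [bg_low,
    bg_high] and SOCs cycling over five organ classes; deterministic."""
    socs = [
        "Nervous system disorders",
        "General disorders and administration site conditions",
        "Gastrointestinal disorders",
        "Respiratory, thoracic and mediastinal disorders",
        "Investigations",
    ]
    step = (bg_high - bg_low) / max(n - 1, 1)
    return tuple(
        PTSpec(f"EVENT {i + 1:03d}", bg_low + i * step, socs[i % len(socs)])
        for i in range(n)
    )


def meddra_map_rows(config: SyntheticConfig) -> list[tuple[str, str]]:
    return [(p.name, p.soc) for p in config.pt_catalog]


def write_meddra_map(config: SyntheticConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("pt,soc\n")
        for pt, soc in meddra_map_rows(config):
            fh.write(f"{pt},{soc}\n")


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    unique_case_count: int
    duplicate_count: int
    planted_signals: list[tuple[str, str, float]]
    expected_tables: dict[str, tuple[float, float, float, float]]
    per_quarter_counts: dict[str, int]
    per_year_counts: dict[int, int]
    tto_bin_probs: dict[str, float]

    def to_json(self) -> str:
        d = asdict(self)
        d["per_year_counts"] = {str(k): v for k, v in self.per_year_counts.items()}
        return json.dumps(d, indent=2, sort_keys=True)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")


def _rate(config: SyntheticConfig, pt: str, present: Sequence[str]) -> float:
    bg = next(p.background for p in config.pt_catalog if p.name == pt)
    rr = 1.0
    present_set = set(present)
    for d, p, r in config.planted_signals:
        if p == pt and d in present_set:
            rr = max(rr, r)
    return bg * rr


def _subset_probs(config: SyntheticConfig):
    """Exact probability of each drug subset under independent draws.

    The empty subset maps to the filler drug, which carries no planted
    signal, so its PT rates are pure background.
    """
    drugs = list(config.drug_catalog)
    if len(drugs) > 16:
        raise ConfigError("subset enumeration supports at most 16 catalog drugs")
    probs = [config.drug_catalog[d] for d in drugs]
    for subset_bits in range(2 ** len(drugs)):
        members = [d for i, d in enumerate(drugs) if subset_bits >> i & 1]
        p = 1.0
        for i, q in enumerate(probs):
            p *= q if subset_bits >> i & 1 else (1.0 - q)
        yield members, p


def expected_contingency(
    config: SyntheticConfig, drug: str, pt: str
) -> tuple[float, float, float, float]:
    """Closed-form E[a], E[b], E[c], E[d] for one drug–PT pair.

    Exact under the generative model, by enumeration over drug subsets;
    the counting unit is the (report, distinct PT) pair, matching the
    contingency construction.
    """
    if drug not in config.drug_catalog:
        raise KeyError(f"unknown drug {drug!r}")
    if pt not in {p.name for p in config.pt_catalog}:
        raise KeyError(f"unknown PT {pt!r}")
    n = config.n_reports
    e_a = e_ab = e_ac = e_n = 0.0
    pts = [p.name for p in config.pt_catalog]
    for members, p_s in _subset_probs(config):
        row_total = sum(_rate(config, q, members) for q in pts)
        r_pt = _rate(config, pt, members)
        e_n += p_s * row_total
        e_ac += p_s * r_pt
        if drug in members:
            e_a += p_s * r_pt
            e_ab += p_s * row_total
    e_a *= n
    e_ab *= n
    e_ac *= n
    e_n *= n
    return (e_a, e_ab - e_a, e_ac - e_a, e_n - e_ab - e_ac + e_a)


def expected_total_pairs(config: SyntheticConfig) -> float:
    """E[total (report, PT) pair count] — the N of the 2×2 tables."""
    n = 0.0
    pts = [p.name for p in config.pt_catalog]
    for members, p_s in _subset_probs(config):
        n += p_s * sum(_rate(config, q, members) for q in pts)
    return n * config.n_reports


# ---------------------------------------------------------------------------
# FAERS-dialect file generation


def _quarter_bounds(year: int, quarter: int) -> tuple[_dt.date, int]:
    start = _dt.date(year, 3 * (quarter - 1) + 1, 1)
    if quarter == 4:
        end = _dt.date(year + 1, 1, 1)
    else:
        end = _dt.date(year, 3 * quarter + 1, 1)
    return start, (end - start).days


def generate_faers_data(config: SyntheticConfig, outdir: str | Path) -> GroundTruth:
    """Write seven quarterly tables per configured quarter, plus ground truth.

    Returns the :class:`GroundTruth` (also serialized to
    ``groundtruth.json`` alongside the tables).  Same config + seed gives
    byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_reports
    drugs = list(config.drug_catalog)
    drug_probs = np.array([config.drug_catalog[d] for d in drugs])
    pts = [p.name for p in config.pt_catalog]
    bg = np.array([p.background for p in config.pt_catalog])

    nq = len(config.quarters)
    qw = (np.array(config.quarter_weights, dtype=float)
          if config.quarter_weights is not None else np.full(nq, 1.0 / nq))
    qw = qw / qw.sum()
    q_idx = rng.choice(nq, size=n, p=qw)

    present = rng.random((n, len(drugs))) < drug_probs  # (n, K)
    rates = np.tile(bg, (n, 1))
    for drug, pt, rr in config.planted_signals:
        di, pi = drugs.index(drug), pts.index(pt)
        mask = present[:, di]
        rates[mask, pi] = np.maximum(rates[mask, pi], bg[pi] * rr)
    reac = rng.random((n, len(pts))) < rates

    sex_labels = list(config.sex_dist)
    sex = rng.choice(len(sex_labels), size=n,
                     p=list(config.sex_dist.values()))
    age_known = rng.random(n) < config.age_known_prob
    ages = np.clip(rng.normal(config.age_mean, config.age_sd, n), 1, 95)
    ages = np.round(ages).astype(int)
    country_labels = list(config.country_dist)
    country = rng.choice(len(country_labels), size=n,
                         p=list(config.country_dist.values()))
    occp_labels = list(config.reporter_dist)
    occp = rng.choice(len(occp_labels), size=n,
                      p=list(config.reporter_dist.values()))
    out_codes = list(OUTCOME_CODES)
    out_probs = np.array([config.outcome_probs.get(c, 0.0) for c in out_codes])
    outc = rng.random((n, len(out_codes))) < out_probs
    rpsr_labels = ["HP", "CSM", "FGN"]
    rpsr = rng.choice(3, size=n, p=[0.5, 0.3, 0.2])

    q_days = np.array([_quarter_bounds(y, q)[1] for y, q in config.quarters])
    q_starts = [_quarter_bounds(y, q)[0] for y, q in config.quarters]
    receipt_off = rng.integers(0, q_days[q_idx])
    start_off = rng.integers(0, q_days[q_idx])
    onset = np.floor(rng.weibull(config.tto_shape, n) * config.tto_scale).astype(int)
    event_partial = rng.random(n) < config.partial_date_rate

    n_dup = int(round(config.duplicate_rate * n))
    dup_idx = np.sort(rng.choice(n, size=n_dup, replace=False)) if n_dup else np.array([], dtype=int)
    dup_back = rng.integers(30, 200, size=n_dup) if n_dup else np.array([], dtype=int)

    demo_rows: list[tuple] = []
    drug_rows: list[tuple] = []
    reac_rows: list[tuple] = []
    outc_rows: list[tuple] = []
    rpsr_rows: list[tuple] = []
    ther_rows: list[tuple] = []
    indi_rows: list[tuple] = []
    per_quarter: dict[str, int] = {}
    per_year: dict[int, int] = {}

    dup_map = {int(i): int(back) for i, back in zip(dup_idx, dup_back)}

    for i in range(n):
        caseid = 30000000 + i
        qi = int(q_idx[i])
        year, quarter = config.quarters[qi]
        qkey = f"{year}Q{quarter}"
        per_quarter[qkey] = per_quarter.get(qkey, 0) + 1

        receipt = q_starts[qi] + _dt.timedelta(days=int(receipt_off[i]))
        per_year[receipt.year] = per_year.get(receipt.year, 0) + 1
        start = q_starts[qi] + _dt.timedelta(days=int(start_off[i]))
        event = start + _dt.timedelta(days=int(onset[i]))
        event_str = (format_faers_date(event)[:6] if event_partial[i]
                     else format_faers_date(event))

        present_drugs = [d for d, flag in zip(drugs, present[i]) if flag]
        if not present_drugs:
            present_drugs = [FILLER_DRUG]
        report_pts = [p for p, flag in zip(pts, reac[i]) if flag]
        report_outc = [c for c, flag in zip(out_codes, outc[i]) if flag]

        versions = [(caseid * 10 + 2, receipt)]
        if i in dup_map:
            versions.append((caseid * 10 + 1,
                             receipt - _dt.timedelta(days=dup_map[i])))
        for pid, rdate in versions:
            pid_s, case_s = str(pid), str(caseid)
            demo_rows.append((
                qi, pid_s, case_s, format_faers_date(rdate), event_str,
                str(int(ages[i])) if age_known[i] else "",
                "YR" if age_known[i] else "",
                sex_labels[int(sex[i])],
                country_labels[int(country[i])],
                occp_labels[int(occp[i])],
            ))
            for seq, dname in enumerate(present_drugs, start=1):
                role = "PS" if seq == 1 else "SS"
                drug_rows.append((qi, pid_s, case_s, str(seq), role, dname, dname))
                ther_rows.append((qi, pid_s, case_s, str(seq),
                                  format_faers_date(start)))
                indi_rows.append((
                    qi, pid_s, case_s, str(seq),
                    config.indication_by_drug.get(dname, DEFAULT_INDICATION),
                ))
            for pt in report_pts:
                reac_rows.append((qi, pid_s, case_s, pt))
            for code in report_outc:
                outc_rows.append((qi, pid_s, case_s, code))
            rpsr_rows.append((qi, pid_s, case_s, rpsr_labels[int(rpsr[i])]))

    tables = {
        "DEMO": (demo_rows, ["primaryid", "caseid", "fda_dt", "event_dt",
                             "age", "age_cod", "sex", "reporter_country",
                             "occp_cod"]),
        "DRUG": (drug_rows, ["primaryid", "caseid", "drug_seq", "role_cod",
                             "drugname", "prod_ai"]),
        "REAC": (reac_rows, ["primaryid", "caseid", "pt"]),
        "OUTC": (outc_rows, ["primaryid", "caseid", "outc_cod"]),
        "RPSR": (rpsr_rows, ["primaryid", "caseid", "rpsr_cod"]),
        "THER": (ther_rows, ["primaryid", "caseid", "dsg_drug_seq", "start_dt"]),
        "INDI": (indi_rows, ["primaryid", "caseid", "indi_drug_seq", "indi_pt"]),
    }
    for qi, (year, quarter) in enumerate(config.quarters):
        yy = year % 100
        for tname, (rows, cols) in tables.items():
            path = outdir / f"{tname}{yy:02d}Q{quarter}.txt"
            with open(path, "w", encoding="utf-8") as fh:
                fh.write("$".join(cols) + "\n")
                for row in rows:
                    if row[0] == qi:
                        fh.write("$".join(row[1:]) + "\n")

    expected = {
        f"{d}|{p}": expected_contingency(config, d, p)
        for d, p, _ in config.planted_signals
    }
    truth = GroundTruth(
        unique_case_count=n,
        duplicate_count=n_dup,
        planted_signals=list(config.planted_signals),
        expected_tables=expected,
        per_quarter_counts=per_quarter,
        per_year_counts=per_year,
        tto_bin_probs=tto_bin_probs(config.tto_shape, config.tto_scale),
    )
    truth.write(outdir / "groundtruth.json")
    return truth


def tto_bin_probs(shape: float, scale: float) -> dict[str, float]:
    """Planted probabilities of the four onset bins for integer-floored
    Weibull onsets: floor(W) ∈ [0,7] iff W < 8, etc."""
    def cdf(t: float) -> float:
        return 1.0 - math.exp(-((t / scale) ** shape))
    return {
        "d0_7": cdf(8.0),
        "d7_28": cdf(29.0) - cdf(8.0),
        "d28_60": cdf(61.0) - cdf(29.0),
        "over60": 1.0 - cdf(61.0),
    }


# ---------------------------------------------------------------------------
# Table-style replay cohorts


def cohort_from_marginals(
    drug: str,
    total: int,
    sex_counts: Mapping[str, int] | None = None,
    age_counts: Mapping[str, int] | None = None,
    reporter_labels: Sequence[tuple[str, int]] | None = None,
    outcome_counts: Mapping[str, int] | None = None,
    country_counts: Sequence[tuple[str, int]] | None = None,
    receipt_year: int = 2020,
) -> list[CaseReport]:
    """Deterministic cohort with EXACTLY the requested marginal counts.

    Each categorical block is assigned independently (first ``n1`` reports
    male, and so on), since the descriptive layer only consumes marginals.
    Outcome codes are laid out cyclically so a report never carries the same
    code twice.  Sampling would only match the marginals in expectation;
    this constructor matches them exactly.
    """
    rep_age_years = {"under18": 10.0, "from18to65": 40.0, "over65": 70.0,
                     UNKNOWN: None}

    def expand(counts: Mapping[str, int] | Sequence[tuple[str, int]],
               block: str) -> list[str]:
        items = list(counts.items()) if isinstance(counts, Mapping) else list(counts)
        labels: list[str] = []
        for label, cnt in items:
            labels.extend([label] * cnt)
        if len(labels) > total:
            raise ValueError(f"{block} counts sum to {len(labels)} > total {total}")
        labels.extend([UNKNOWN] * (total - len(labels)))
        return labels

    sexes = expand(sex_counts or {}, "sex")
    age_groups = expand(age_counts or {}, "age")
    reporters = expand(reporter_labels or [], "reporter")
    countries = expand(country_counts or [], "country")

    outcome_sets: list[set[str]] = [set() for _ in range(total)]
    offset = 0
    for code, cnt in (outcome_counts or {}).items():
        if cnt > total:
            raise ValueError(f"outcome {code} count {cnt} exceeds total {total}")
        for j in range(cnt):
            outcome_sets[(offset + j) % total].add(code)
        offset += cnt

    reports = []
    for i in range(total):
        age = rep_age_years.get(age_groups[i])
        reports.append(CaseReport(
            primary_id=str(10_000_000 + i),
            case_id=str(20_000_000 + i),
            sex=sexes[i],
            age_years=age,
            age_group=assign_age_group(age),
            country=countries[i],
            reporter=reporters[i],
            outcomes=frozenset(outcome_sets[i]),
            drugs=[DrugEntry(drug, "PS")],
            reactions=["ADVERSE EVENT"],
            reaction_socs={"ADVERSE EVENT": UNMAPPED},
            event_date=None,
            receipt_year=receipt_year,
        ))
    return reports


# ---------------------------------------------------------------------------
# synthetic PPI networks


@dataclass
class PPIGroundTruth:
    clique_members: list[list[str]]
    background_nodes: list[str]

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2), encoding="utf-8")


def generate_ppi(
    path: str | Path,
    rng_seed: int = 0,
    clique_sizes: tuple[int, ...] = (8, 10),
    n_background: int = 60,
    background_edge_prob: float = 0.05,
) -> PPIGroundTruth:
    """Edge list with planted high-score cliques over an Erdős–Rényi
    background.

    Planted clique edges score Uniform(0.90, 0.99) — always above the
    conventional 0.700 threshold; background edges (any pair not inside one
    clique) appear with ``background_edge_prob`` and score
    Uniform(0.40, 0.95).  Same seed gives identical files.
    """
    if any(s < 3 for s in clique_sizes):
        raise ValueError("clique sizes must be >= 3")
    rng = np.random.default_rng(rng_seed)
    cliques: list[list[str]] = []
    for ci, size in enumerate(clique_sizes):
        letter = chr(ord("A") + ci)
        cliques.append([f"HUB{letter}{j + 1:02d}" for j in range(size)])
    background = [f"BG{j + 1:03d}" for j in range(n_background)]
    nodes = [v for clique in cliques for v in clique] + background
    in_same_clique = set()
    for clique in cliques:
        for a, b in itertools.combinations(clique, 2):
            in_same_clique.add((a, b))

    lines = []
    for a, b in itertools.combinations(nodes, 2):
        if (a, b) in in_same_clique:
            score = 0.90 + 0.09 * rng.random()
            lines.append(f"{a}\t{b}\t{score:.3f}")
        elif rng.random() < background_edge_prob:
            score = 0.40 + 0.55 * rng.random()
            lines.append(f"{a}\t{b}\t{score:.3f}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        fh.write("\n".join(lines) + "\n")
    return PPIGroundTruth(clique_members=cliques, background_nodes=background)
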