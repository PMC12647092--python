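"""Disproportionality signal detection on drug–event 2×2 tables.

Spontaneous-report signal mining compares how often an adverse-event
preferred term (PT) is reported with a target drug against how often it is
reported with everything else.  For a drug–PT pair the familiar 2×2 table
is

    =============  ================  ===================
    .              target PT         other PTs
    =============  ================  ===================
    target drug    a                 b
    other drugs    c                 d
    =============  ================  ===================

counted over (report, distinct PT) pairs: a report listing k distinct PTs
contributes k pairs, and never the same PT twice.

Four detection algorithms are implemented, each with its conventional
positivity criterion:

* ROR  — reporting odds ratio ad/bc with a Wald interval on the log scale;
  positive when the 95% CI lower bound exceeds 1 and a > 3.
* PRR  — proportional reporting ratio [a/(a+b)] / [c/(c+d)] with the
  (uncorrected) Pearson chi-square; positive when PRR > 2, χ² > 4 and a > 3.
* BCPNN — the information component IC = log2(a·N/((a+b)(a+c))) with
  Bayesian shrinkage (Bate-style closed forms); positive when the lower
  2-SD credibility bound IC025 > 0.
* EBGM — the relative reporting ratio a·N/((a+b)(a+c)) with a log-normal
  95% interval (simplified, non-shrinkage form); positive when EBGM05 > 2.

A pair is *any-positive* when at least one algorithm flags it and *strong*
when all four do; the strong rule is the false-positive guard (no multiple
testing correction is applied).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .faers_io import CaseReport, MedDRAMap, UNMAPPED

_Z95 = 1.96
_LN2 = math.log(2.0)


@dataclass(frozen=True)
class ContingencyTable:
    """The a/b/c/d counts of one drug–event pair."""

    a: int
    b: int
    c: int
    d: int

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class SignalConfig:
    """Knobs shared by the four statistics.

    zero_cell_policy: "strict" leaves a statistic undefined (never positive)
    when a zero cell makes its standard error incomputable; "haldane" adds
    0.5 to every cell first (Haldane–Anscombe).
    a_threshold: the "N > 3" criterion read as a (case count of the target
    pair) > threshold.
    priors: BCPNN Dirichlet hyperparameters (alpha1, beta1, alpha, beta,
    gamma11).
    """

    zero_cell_policy: str = "strict"
    a_threshold: int = 3
    priors: tuple[float, float, float, float, float] = (1.0, 1.0, 2.0, 2.0, 1.0)

    def __post_init__(self):
        if self.zero_cell_policy not in ("strict", "haldane"):
            raise ValueError(f"unknown zero_cell_policy {self.zero_cell_policy!r}")


DEFAULT_CONFIG = SignalConfig()


@dataclass(frozen=True)
class RORResult:
    ror: float
    se_ln_ror: float
    ci95_low: float
    ci95_high: float
    positive: bool


@dataclass(frozen=True)
class PRRResult:
    prr: float
    chi2: float
    positive: bool


@dataclass(frozen=True)
class BCPNNResult:
    ic: float
    e_ic: float
    v_ic: float
    ic025: float
    positive: bool


@dataclass(frozen=True)
class EBGMResult:
    ebgm: float
    ebgm05: float
    positive: bool


@dataclass(frozen=True)
class SignalResult:
    drug: str
    pt: str
    soc: str
    table: ContingencyTable
    ror: RORResult
    prr: PRRResult
    bcpnn: BCPNNResult
    ebgm: EBGMResult

    @property
    def any_positive(self) -> bool:
        return (self.ror.positive or self.prr.positive
                or self.bcpnn.positive or self.ebgm.positive)

    @property
    def strong(self) -> bool:
        return (self.ror.positive and self.prr.positive
                and self.bcpnn.positive and self.ebgm.positive)


def _adjusted_cells(t: ContingencyTable, config: SignalConfig) -> tuple[float, ...] | None:
    """Apply the zero-cell policy; None means 'undefined under strict'."""
    if all(x > 0 for x in t.cells()):
        return tuple(float(x) for x in t.cells())
    if config.zero_cell_policy == "haldane":
        return tuple(x + 0.5 for x in t.cells())
    return None


def ror_stat(t: ContingencyTable, config: SignalConfig = DEFAULT_CONFIG) -> RORResult:
    """Reporting odds ratio ad/bc with 95% Wald interval on the log scale."""
    cells = _adjusted_cells(t, config)
    if cells is None:
        return RORResult(math.nan, math.nan, math.nan, math.nan, False)
    a, b, c, d = cells
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(ror) - _Z95 * se)
    hi = math.exp(math.log(ror) + _Z95 * se)
    positive = lo > 1.0 and t.a > config.a_threshold
    return RORResult(ror, se, lo, hi, positive)


def prr_stat(t: ContingencyTable, config: SignalConfig = DEFAULT_CONFIG) -> PRRResult:
    """Proportional reporting ratio with uncorrected Pearson chi-square."""
    cells = _adjusted_cells(t, config)
    if cells is None:
        return PRRResult(math.nan, math.nan, False)
    a, b, c, d = cells
    n = a + b + c + d
    prr = (a / (a + b)) / (c / (c + d))
    chi2 = ((a * d - b * c) ** 2) * n / ((a + b) * (c + d) * (a + c) * (b + d))
    positive = prr > 2.0 and chi2 > 4.0 and t.a > config.a_threshold
    return PRRResult(prr, chi2, positive)


def bcpnn_stat(t: ContingencyTable, config: SignalConfig = DEFAULT_CONFIG) -> BCPNNResult:
    """Information component with Bate-style Bayesian shrinkage.

    Point estimate IC = log2(a·N/((a+b)(a+c))).  The expectation E(IC) and
    variance V(IC) use the closed-form Dirichlet scheme with priors
    (alpha1, beta1, alpha, beta, gamma11), default (1, 1, 2, 2, 1); the
    lower credibility bound is IC025 = E(IC) − 2·sqrt(V(IC)).  Shrinkage
    vanishes as counts grow, so IC025 → IC for large a.
    """
    if t.a == 0 and config.zero_cell_policy == "strict":
        return BCPNNResult(math.nan, math.nan, math.nan, math.nan, False)
    if config.zero_cell_policy == "haldane" and any(x == 0 for x in t.cells()):
        a, b, c, d = (x + 0.5 for x in t.cells())
    else:
        a, b, c, d = (float(x) for x in t.cells())
    n = a + b + c + d
    alpha1, beta1, alpha, beta, gamma11 = config.priors

    ic = math.log2(a * n / ((a + b) * (a + c))) if a > 0 else math.nan

    gamma = gamma11 * (n + alpha) * (n + beta) / ((a + b + alpha1) * (a + c + beta1))
    e_ic = math.log2(
        (a + gamma11) * (n + alpha) * (n + beta)
        / ((n + gamma) * (a + b + alpha1) * (a + c + beta1))
    )
    v_ic = (
        (n - a + gamma - gamma11) / ((a + gamma11) * (1 + n + gamma))
        + (n - a - b + alpha - alpha1) / ((a + b + alpha1) * (1 + n + alpha))
        + (n - a - c + beta - beta1) / ((a + c + beta1) * (1 + n + beta))
    ) / (_LN2 ** 2)
    ic025 = e_ic - 2.0 * math.sqrt(v_ic)
    return BCPNNResult(ic, e_ic, v_ic, ic025, ic025 > 0.0)


def ebgm_stat(t: ContingencyTable, config: SignalConfig = DEFAULT_CONFIG) -> EBGMResult:
    """Relative reporting ratio a·N/((a+b)(a+c)) with log-normal interval.

    This is the simplified (non-shrinkage) form: identically 2**IC of the
    same table.  EBGM05 = exp(ln EBGM − 1.96·sqrt(1/a+1/b+1/c+1/d)).
    """
    cells = _adjusted_cells(t, config)
    if cells is None:
        return EBGMResult(math.nan, math.nan, False)
    a, b, c, d = cells
    n = a + b + c + d
    ebgm = a * n / ((a + c) * (a + b))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ebgm05 = math.exp(math.log(ebgm) - _Z95 * se)
    return EBGMResult(ebgm, ebgm05, ebgm05 > 2.0)


def evaluate_pair(
    drug: str,
    pt: str,
    t: ContingencyTable,
    soc: str = UNMAPPED,
    config: SignalConfig = DEFAULT_CONFIG,
) -> SignalResult:
    """All four statistics plus the positive/strong classification."""
    return SignalResult(
        drug=drug, pt=pt, soc=soc, table=t,
        ror=ror_stat(t, config),
        prr=prr_stat(t, config),
        bcpnn=bcpnn_stat(t, config),
        ebgm=ebgm_stat(t, config),
    )


# ---------------------------------------------------------------------------
# building tables from cohorts


def report_pairs(reports: Iterable[CaseReport]) -> list[tuple[str, str]]:
    """Distinct (primary_id, PT) pairs — the counting unit of the analysis."""
    pairs = []
    for rep in reports:
        seen = set()
        for pt in rep.reactions:
            if pt not in seen:
                seen.add(pt)
                pairs.append((rep.primary_id, pt))
    return pairs


def build_contingency(
    cohort: Sequence[CaseReport],
    background: Sequence[CaseReport],
    pt: str,
) -> ContingencyTable:
    """2×2 counts for one drug cohort and one PT over the full background.

    ``background`` must contain every report (it is a superset of the
    cohort); a PT absent everywhere legally yields a = c = 0.
    """
    cohort_ids = {r.primary_id for r in cohort}
    bg_pairs = report_pairs(background)
    n = len(bg_pairs)
    a = sum(1 for pid, p in bg_pairs if p == pt and pid in cohort_ids)
    drug_total = sum(1 for pid, _ in bg_pairs if pid in cohort_ids)
    pt_total = sum(1 for _, p in bg_pairs if p == pt)
    b = drug_total - a
    c = pt_total - a
    d = n - a - b - c
    return ContingencyTable(a, b, c, d)


def signal_scan(
    cohorts: Mapping[str, Sequence[CaseReport]],
    background: Sequence[CaseReport],
    meddra: MedDRAMap | None = None,
    config: SignalConfig = DEFAULT_CONFIG,
) -> list[SignalResult]:
    """Evaluate every drug–PT pair observed in each cohort.

    Returns one :class:`SignalResult` per (drug, PT observed in that drug's
    cohort), ranked within drug by descending a, then descending ROR, then
    PT lexicographically.
    """
    meddra = meddra or MedDRAMap()
    bg_pairs = report_pairs(background)
    n = len(bg_pairs)
    pt_total: dict[str, int] = {}
    for _, p in bg_pairs:
        pt_total[p] = pt_total.get(p, 0) + 1

    results: list[SignalResult] = []
    for drug, cohort in cohorts.items():
        cohort_ids = {r.primary_id for r in cohort}
        drug_total = 0
        a_counts: dict[str, int] = {}
        for pid, p in bg_pairs:
            if pid in cohort_ids:
                drug_total += 1
                a_counts[p] = a_counts.get(p, 0) + 1
        drug_results = []
        for pt, a in a_counts.items():
            b = drug_total - a
            c = pt_total[pt] - a
            d = n - a - b - c
            t = ContingencyTable(a, b, c, d)
            soc = None
            for rep in cohort:
                if pt in rep.reaction_socs:
                    soc = rep.reaction_socs[pt]
                    break
            if soc is None:
                soc = meddra.soc_of(pt)
            drug_results.append(evaluate_pair(drug, pt, t, soc=soc, config=config))
        drug_results.sort(
            key=lambda r: (-r.table.a,
                           -(r.ror.ror if r.ror.ror == r.ror.ror else -math.inf),
                           r.pt)
        )
        results.extend(drug_results)
    return results


def strong_signal_counts(results: Iterable[SignalResult]) -> dict[str, int]:
    """Per-drug count of strong-signal PTs."""
    counts: dict[str, int] = {}
    for r in results:
        counts.setdefault(r.drug, 0)
        if r.strong:
            counts[r.drug] += 1
    return counts


# ---------------------------------------------------------------------------
# aggregation and overlap


def soc_aggregate(results: Iterable[SignalResult]) -> pd.DataFrame:
    """Per-(drug, SOC): summed report count (a) and positive-signal PT count.

    Unmapped PTs are grouped under the explicit UNMAPPED label.
    """
    rows = []
    for r in results:
        rows.append({
            "drug": r.drug,
            "soc": r.soc if r.soc else UNMAPPED,
            "reports": r.table.a,
            "signals": 1 if r.any_positive else 0,
        })
    if not rows:
        return pd.DataFrame(columns=["drug", "soc", "reports", "signals"])
    df = pd.DataFrame(rows)
    out = (df.groupby(["drug", "soc"], as_index=False)[["reports", "signals"]]
             .sum()
             .sort_values(["drug", "reports"], ascending=[True, False])
             .reset_index(drop=True))
    return out


@dataclass
class OverlapResult:
    """Exclusive set-algebra regions over per-drug positive-PT sets.

    ``regions`` maps each non-empty drug subset (frozenset of drug names) to
    the PTs positive in exactly those drugs.  Helpers expose per-drug unique
    sets, pairwise-only intersections and the full intersection.
    """

    drugs: tuple[str, ...]
    regions: dict[frozenset, set] = field(default_factory=dict)

    def unique(self, drug: str) -> set:
        return set(self.regions.get(frozenset({drug}), set()))

    def pair_only(self, d1: str, d2: str) -> set:
        return set(self.regions.get(frozenset({d1, d2}), set()))

    def full_intersection(self) -> set:
        return set(self.regions.get(frozenset(self.drugs), set()))


def overlap_pts(positive_sets: Mapping[str, set]) -> OverlapResult:
    """Partition the union of positive-PT sets into exclusive regions.

    The regions are a disjoint partition: the union's size equals the sum of
    all region sizes.
    """
    drugs = tuple(sorted(positive_sets))
    result = OverlapResult(drugs=drugs)
    universe = set().union(*positive_sets.values()) if positive_sets else set()
    for pt in universe:
        members = frozenset(d for d in drugs if pt in positive_sets[d])
        result.regions.setdefault(members, set()).add(pt)
    return result


# ---------------------------------------------------------------------------
# tabular output


def results_dataframe(results: Iterable[SignalResult]) -> pd.DataFrame:
    """Long-format table: one row per drug–PT with all statistics and flags."""
    rows = []
    for r in results:
        rows.append({
            "drug": r.drug, "pt": r.pt, "soc": r.soc,
            "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
            "ror": r.ror.ror, "ror_ci_low": r.ror.ci95_low,
            "ror_ci_high": r.ror.ci95_high,
            "prr": r.prr.prr, "chi2": r.prr.chi2,
            "ic": r.bcpnn.ic, "ic025": r.bcpnn.ic025,
            "ebgm": r.ebgm.ebgm, "ebgm05": r.ebgm.ebgm05,
            "ror_positive": r.ror.positive, "prr_positive": r.prr.positive,
            "bcpnn_positive": r.bcpnn.positive, "ebgm_positive": r.ebgm.positive,
            "any_positive": r.any_positive, "strong": r.strong,
        })
    return pd.DataFrame(rows)


def write_results(results: Iterable[SignalResult], path: str | Path) -> None:
    """Write the long-format signal table as TSV plus a JSON mirror."""
    df = results_dataframe(results)
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    df.to_json(path.with_suffix(".json"), orient="records", indent=2)
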