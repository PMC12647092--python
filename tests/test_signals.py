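"""The four disproportionality statistics, classification and set algebra."""

from __future__ import annotations

import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from faersig.faers_io import CaseReport, DrugEntry
from faersig.signals import (
    ContingencyTable,
    SignalConfig,
    bcpnn_stat,
    build_contingency,
    ebgm_stat,
    evaluate_pair,
    overlap_pts,
    prr_stat,
    ror_stat,
    signal_scan,
    soc_aggregate,
)

HAND = ContingencyTable(10, 90, 100, 9800)
NULL = ContingencyTable(10, 10, 10, 10)

cells = st.integers(min_value=1, max_value=500)
tables = st.builds(ContingencyTable, cells, cells, cells, cells)


class TestROR:
    def test_hand_arithmetic(self):
        r = ror_stat(HAND)
        assert r.ror == pytest.approx(98000 / 9000)
        se = math.sqrt(1 / 10 + 1 / 90 + 1 / 100 + 1 / 9800)
        assert r.se_ln_ror == pytest.approx(se)
        assert r.ci95_low == pytest.approx(math.exp(math.log(98000 / 9000) - 1.96 * se))
        assert r.ci95_high == pytest.approx(math.exp(math.log(98000 / 9000) + 1.96 * se))
        assert r.positive

    def test_symmetric_table_not_positive(self):
        r = ror_stat(NULL)
        assert r.ror == pytest.approx(1.0) and not r.positive

    @given(tables)
    @settings(deadline=None, derandomize=True)
    def test_drug_swap_inverts_ror(self, t):
        swapped = ContingencyTable(t.c, t.d, t.a, t.b)
        assert ror_stat(swapped).ror == pytest.approx(1.0 / ror_stat(t).ror)

    def test_ci_brackets_the_estimate(self):
        r = ror_stat(HAND)
        assert r.ci95_low <= r.ror <= r.ci95_high

    def test_zero_cell_strict_policy(self):
        r = ror_stat(ContingencyTable(5, 0, 3, 7))
        assert math.isnan(r.ror) and not r.positive

    def test_zero_cell_haldane_policy(self):
        cfg = SignalConfig(zero_cell_policy="haldane")
        r = ror_stat(ContingencyTable(5, 0, 3, 7), cfg)
        assert r.ror == pytest.approx((5.5 * 7.5) / (0.5 * 3.5))

    def test_a_threshold_blocks_small_counts(self):
        # strong disproportion but only 3 cases: not positive under a > 3
        t = ContingencyTable(3, 5, 10, 10_000)
        assert ror_stat(t).ci95_low > 1 and not ror_stat(t).positive


class TestPRR:
    def test_null_table(self):
        r = prr_stat(NULL)
        assert r.prr == pytest.approx(1.0) and r.chi2 == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        r = prr_stat(HAND)
        assert r.prr == pytest.approx((10 / 100) / (100 / 9900))
        assert r.prr == pytest.approx(9.9)

    @given(tables)
    @settings(deadline=None, derandomize=True)
    def test_chi2_equals_observed_expected_sum(self, t):
        # brute-force Σ(O−E)²/E over the four cells
        a, b, c, d = t.cells()
        n = t.n
        obs = np.array([[a, b], [c, d]], dtype=float)
        expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
        brute = float(((obs - expected) ** 2 / expected).sum())
        assert prr_stat(t).chi2 == pytest.approx(brute, rel=1e-12)

    @given(tables)
    @settings(deadline=None, derandomize=True)
    def test_chi2_matches_scipy_uncorrected(self, t):
        scipy_stats = pytest.importorskip("scipy.stats")
        chi2 = scipy_stats.chi2_contingency(
            [[t.a, t.b], [t.c, t.d]], correction=False)[0]
        assert prr_stat(t).chi2 == pytest.approx(chi2, rel=1e-12)


class TestBCPNN:
    def test_hand_arithmetic_ic(self):
        r = bcpnn_stat(HAND)
        assert r.ic == pytest.approx(math.log2(100000 / 11000))
        assert r.ic == pytest.approx(3.184, abs=5e-4)

    def test_independence_gives_zero_ic(self):
        # a/N == (a+b)(a+c)/N²  →  IC = 0
        t = ContingencyTable(10, 90, 90, 810)
        assert bcpnn_stat(t).ic == pytest.approx(0.0, abs=1e-12)

    def test_credibility_interval_definition(self):
        r = bcpnn_stat(HAND)
        assert r.ic025 == pytest.approx(r.e_ic - 2 * math.sqrt(r.v_ic))
        assert r.v_ic >= 0

    def test_shrinkage_vanishes_with_counts(self):
        # proportions fixed, counts scaled: ic025 → ic
        gaps = []
        for scale in (1, 10, 100):
            t = ContingencyTable(10 * scale, 90 * scale,
                                 100 * scale, 9800 * scale)
            r = bcpnn_stat(t)
            assert r.ic == pytest.approx(math.log2(100000 / 11000))
            gaps.append(r.ic - r.ic025)
        assert gaps[0] > gaps[1] > gaps[2] > 0
        # the credibility gap shrinks roughly like 1/sqrt(a)
        assert gaps[2] < gaps[0] / 10

    def test_zero_a_strict_not_positive(self):
        r = bcpnn_stat(ContingencyTable(0, 100, 50, 9000))
        assert math.isnan(r.ic) and not r.positive


class TestEBGM:
    def test_hand_arithmetic(self):
        r = ebgm_stat(HAND)
        assert r.ebgm == pytest.approx(10 * 10000 / (110 * 100))
        assert r.ebgm == pytest.approx(9.091, abs=5e-4)
        se = math.sqrt(1 / 10 + 1 / 90 + 1 / 100 + 1 / 9800)
        assert r.ebgm05 == pytest.approx(math.exp(math.log(r.ebgm) - 1.96 * se))

    def test_null_table_unity(self):
        r = ebgm_stat(NULL)
        assert r.ebgm == pytest.approx(1.0) and not r.positive

    @given(tables)
    @settings(deadline=None, derandomize=True)
    def test_ebgm_identically_two_to_the_ic(self, t):
        assert ebgm_stat(t).ebgm == pytest.approx(
            2.0 ** bcpnn_stat(t).ic, rel=1e-12)


class TestCrossStatisticInvariants:
    @given(tables)
    @settings(deadline=None, derandomize=True)
    def test_all_four_agree_on_direction(self, t):
        sign = (t.a * t.d > t.b * t.c) - (t.a * t.d < t.b * t.c)
        ror = ror_stat(t).ror
        prr = prr_stat(t).prr
        ic = bcpnn_stat(t).ic
        ebgm = ebgm_stat(t).ebgm
        if sign > 0:
            assert ror > 1 and prr > 1 and ic > 0 and ebgm > 1
        elif sign < 0:
            assert ror < 1 and prr < 1 and ic < 0 and ebgm < 1
        else:
            assert ror == pytest.approx(1) and prr == pytest.approx(1)
            assert ic == pytest.approx(0, abs=1e-12)

    @given(st.integers(1, 200), st.integers(1, 200), st.integers(1, 200),
           st.integers(1, 200))
    @settings(deadline=None, derandomize=True)
    def test_monotone_in_a(self, a, b, c, d):
        # ROR and PRR strictly increase in a with b, c, d fixed.  The
        # observed-to-expected ratio behind IC/EBGM is not monotone in a
        # (it tends to 1 as a dominates the margins), so for those two only
        # the direction-agreement invariant applies (tested above).
        t1 = ContingencyTable(a, b, c, d)
        t2 = ContingencyTable(a + 1, b, c, d)
        assert ror_stat(t2).ror > ror_stat(t1).ror
        assert prr_stat(t2).prr > prr_stat(t1).prr


class TestClassification:
    def test_all_four_positive_is_strong(self):
        res = evaluate_pair("D", "P", HAND)
        assert res.any_positive and res.strong

    def test_partial_positivity_is_not_strong(self):
        # ROR CI low > 1 but PRR < 2: not all algorithms fire
        t = ContingencyTable(60, 40, 350, 550)
        res = evaluate_pair("D", "P", t)
        assert res.ror.positive and not res.prr.positive
        assert res.any_positive and not res.strong

    def test_nothing_positive(self):
        res = evaluate_pair("D", "P", NULL)
        assert not res.any_positive and not res.strong

    def test_planted_signal_classified_strong(self, recovery_dataset):
        config, truth, run = recovery_dataset
        by_pair = {(r.drug.upper(), r.pt): r for r in run.results}
        strong_pair = by_pair[("TOFERSEN", "FALL")]
        assert strong_pair.strong
        null_pairs = [
            r for r in run.results
            if (r.drug.upper(), r.pt, ) not in
            {(d, p) for d, p, _ in config.planted_signals}
        ]
        frac_strong = sum(r.strong for r in null_pairs) / len(null_pairs)
        assert frac_strong <= 0.05


class TestContingencyConstruction:
    def _mk(self, pid, drug, pts):
        return CaseReport(
            primary_id=pid, case_id=pid, sex="unknown", age_years=None,
            age_group="unknown", country="unknown", reporter="unknown",
            outcomes=frozenset(), drugs=[DrugEntry(drug, "PS")],
            reactions=list(pts), reaction_socs={p: "SOC" for p in pts},
            event_date=None, receipt_year=2023)

    def test_enumerated_pair_example(self):
        background = [
            self._mk("1", "X", ["P", "Q"]),
            self._mk("2", "Y", ["P"]),
            self._mk("3", "Y", ["R"]),
            self._mk("4", "Z", ["Q"]),
        ]
        cohort = [background[0]]
        t = build_contingency(cohort, background, "P")
        assert t.cells() == (1, 1, 1, 2)

    def test_pt_unique_to_target_drug_gives_zero_c(self):
        background = [self._mk("1", "X", ["P"]), self._mk("2", "Y", ["Q"])]
        t = build_contingency([background[0]], background, "P")
        assert t.c == 0

    def test_pt_absent_everywhere_is_legal(self):
        background = [self._mk("1", "X", ["P"])]
        t = build_contingency([background[0]], background, "ZZZ")
        assert t.a == 0 and t.c == 0

    def test_duplicate_pt_within_report_counted_once(self):
        rep = self._mk("1", "X", ["P", "P", "Q"])
        t = build_contingency([rep], [rep, self._mk("2", "Y", ["P"])], "P")
        assert t.a == 1 and t.b == 1

    def test_observed_a_close_to_analytic_expectation(self, small_dataset):
        from faersig.synthetic import expected_contingency
        config, truth, run, directory = small_dataset
        drug, pt, rr = config.planted_signals[0]
        res = next(r for r in run.results
                   if r.drug.upper() == drug and r.pt == pt)
        e_a = expected_contingency(config, drug, pt)[0]
        assert abs(res.table.a - e_a) <= 3 * math.sqrt(e_a)

    def test_ranking_tie_breaks(self, small_dataset):
        config, truth, run, directory = small_dataset
        for drug in {r.drug for r in run.results}:
            rows = [r for r in run.results if r.drug == drug]
            keys = [(-r.table.a,
                     -(r.ror.ror if not math.isnan(r.ror.ror) else -math.inf),
                     r.pt) for r in rows]
            assert keys == sorted(keys)


class TestSOCAggregate:
    def test_additive_over_pts(self):
        results = [
            evaluate_pair("D", "P1", ContingencyTable(3, 10, 10, 100), soc="S"),
            evaluate_pair("D", "P2", ContingencyTable(5, 8, 4, 120), soc="S"),
        ]
        df = soc_aggregate(results)
        row = df[(df.drug == "D") & (df.soc == "S")].iloc[0]
        assert row.reports == 8
        assert row.signals == sum(r.any_positive for r in results)

    def test_empty_results(self):
        assert soc_aggregate([]).empty

    def test_planted_socs_only(self, small_dataset):
        config, truth, run, directory = small_dataset
        df = soc_aggregate(run.results)
        strong_socs = set()
        for r in run.results:
            if r.strong:
                strong_socs.add((r.drug, r.soc))
        for drug, soc in strong_socs:
            sub = df[(df.drug == drug) & (df.soc == soc)]
            assert sub.signals.iloc[0] >= 1


class TestOverlap:
    def test_three_set_example(self):
        res = overlap_pts({"d1": {"P", "Q"}, "d2": {"Q", "R"}, "d3": {"S"}})
        assert res.pair_only("d1", "d2") == {"Q"}
        assert res.full_intersection() == set()
        assert res.unique("d1") == {"P"}
        assert res.unique("d2") == {"R"}
        assert res.unique("d3") == {"S"}

    def test_identical_sets_all_in_triple(self):
        s = {"A", "B"}
        res = overlap_pts({"d1": set(s), "d2": set(s), "d3": set(s)})
        assert res.full_intersection() == s
        assert res.unique("d1") == set()

    def test_regions_partition_the_union(self):
        rng = np.random.default_rng(5)
        universe = [f"pt{i}" for i in range(40)]
        sets = {
            f"d{k}": {p for p in universe if rng.random() < 0.3}
            for k in range(3)
        }
        res = overlap_pts(sets)
        union = set().union(*sets.values())
        assert sum(len(v) for v in res.regions.values()) == len(union)
        # brute-force membership check
        for members, pts in res.regions.items():
            for pt in pts:
                assert all((pt in sets[d]) == (d in members) for d in sets)
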