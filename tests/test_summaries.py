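"""Demographic/seriousness composition, SOC rollups, label annotation."""

import math

import pytest

from vigilstat.contingency import TwoByTwo
from vigilstat.model import SignalResult
from vigilstat.contingency import RatioResult
from vigilstat.reports import Occupation, Outcome, ReportSet, Sex
from vigilstat.summaries import (
    LabelList,
    SocMap,
    annotate_labels,
    demographics_summary,
    round_percent,
    soc_rollup,
)

from conftest import make_report

NAN_RATIO = RatioResult(math.nan, math.nan, math.nan)


def stub_signal(pt, a, is_signal=True):
    return SignalResult(
        pt=pt,
        a=a,
        report_fraction=0.0,
        prr=NAN_RATIO,
        ror=NAN_RATIO,
        eic=0.0,
        vic=0.0,
        ic_minus_2sd=0.0,
        passes_prr=is_signal,
        passes_ror=is_signal,
        passes_bcpnn=is_signal,
        is_signal=is_signal,
        table=TwoByTwo(a, 1, 1, 1),
    )


def published_cohort():
    """3,587 reports whose marginal compositions match a published
    demographic table: sex 1954/1486/147, age bands 6/157/1122/587/299/1416,
    occupation 775/218/529/67/1386/612, outcomes 202/1110/1/121/123."""
    n = 3587
    sexes = [Sex.MALE] * 1954 + [Sex.FEMALE] * 1486 + [Sex.UNKNOWN] * 147
    ages = (
        [10.0] * 6
        + [30.0] * 157
        + [50.0] * 1122
        + [70.0] * 587
        + [80.0] * 299
        + [None] * 1416
    )
    occs = (
        [Occupation.DOCTOR] * 775
        + [Occupation.PHARMACIST] * 218
        + [Occupation.OTHER_MEDICAL] * 529
        + [Occupation.LAWYER] * 67
        + [Occupation.CONSUMER_NONMEDICAL] * 1386
        + [Occupation.UNKNOWN] * 612
    )
    outs = (
        [frozenset({Outcome.DEATH})] * 202
        + [frozenset({Outcome.HOSPITALIZATION})] * 1110
        + [frozenset({Outcome.CONGENITAL_ANOMALY})] * 1
        + [frozenset({Outcome.DISABLING})] * 121
        + [frozenset({Outcome.LIFE_THREATENING})] * 123
        + [frozenset()] * (n - 1557)
    )
    assert len(sexes) == len(ages) == len(occs) == len(outs) == n
    return ReportSet(
        [
            make_report(f"C{i}", {"Nausea"}, sex=s, age=a, occupation=o, outcomes=out)
            for i, (s, a, o, out) in enumerate(zip(sexes, ages, occs, outs))
        ]
    )


@pytest.fixture(scope="module")
def table():
    return demographics_summary(published_cohort())


class TestDemographicsSummary:
    @pytest.mark.parametrize(
        "block,label,count,percent",
        [
            ("Gender", "Male", 1954, 54.47),
            ("Gender", "Female", 1486, 41.43),
            ("Gender", "Unknown", 147, 4.10),
            ("Age, years", "<18", 6, 0.17),
            ("Age, years", "18-44", 157, 4.38),
            ("Age, years", "45-64", 1122, 31.28),
            ("Age, years", "65-74", 587, 16.36),
            ("Age, years", ">=75", 299, 8.34),
            ("Age, years", "Unknown", 1416, 39.48),
            ("Occupation", "Pharmacist", 218, 6.08),
            ("Occupation", "Other medical staff", 529, 14.75),
            ("Occupation", "Lawyer", 67, 1.87),
            ("Occupation", "Consumer or non-medical staff", 1386, 38.64),
            ("Occupation", "Unknown", 612, 17.06),
            ("Serious adverse events", "Death", 202, 5.63),
            ("Serious adverse events", "Hospitalization", 1110, 30.95),
            ("Serious adverse events", "Congenital anomalies", 1, 0.03),
            ("Serious adverse events", "Disabling", 121, 3.37),
            ("Serious adverse events", "Life threatening", 123, 3.43),
            ("Serious adverse events", "Serious total", 1557, 43.41),
        ],
    )
    def test_published_composition_reproduced(self, table, block, label, count, percent):
        row = table.lookup(block, label)
        assert row.count == count
        assert row.percent == percent

    def test_blocks_sum_to_100(self, table):
        for block in ("Gender", "Age, years", "Occupation"):
            total = sum(r.percent for r in table.rows if r.block == block)
            assert abs(total - 100.0) <= 0.05

    def test_permutation_invariant(self):
        rs = published_cohort()
        shuffled = ReportSet(list(reversed(rs.reports)))
        a = demographics_summary(rs)
        b = demographics_summary(shuffled)
        assert a.rows == b.rows

    def test_all_unknown_corpus(self):
        rs = ReportSet([make_report(f"C{i}", {"Nausea"}) for i in range(4)])
        table = demographics_summary(rs)
        assert table.lookup("Gender", "Unknown").percent == 100.0
        assert table.lookup("Gender", "Male").count == 0
        assert table.lookup("Age, years", "Unknown").percent == 100.0

    def test_report_counted_once_under_highest_priority_outcome(self):
        rs = ReportSet(
            [
                make_report(
                    "C1",
                    {"Nausea"},
                    outcomes={Outcome.HOSPITALIZATION, Outcome.DEATH},
                )
            ]
        )
        table = demographics_summary(rs)
        assert table.lookup("Serious adverse events", "Death").count == 1
        assert table.lookup("Serious adverse events", "Hospitalization").count == 0
        assert table.lookup("Serious adverse events", "Serious total").count == 1


class TestSocRollup:
    GASTRO_COUNTS = (112, 92, 47, 34, 34, 31, 25, 22, 21, 17, 14, 10, 9)

    def test_gastro_block_totals(self):
        signals = [stub_signal(f"GI{i}", a) for i, a in enumerate(self.GASTRO_COUNTS)]
        soc = SocMap({f"GI{i}": "Gastrointestinal disorders" for i in range(13)})
        table = soc_rollup(signals, soc, total_reports=3587)
        row = table.rows[0]
        assert row.label == "Gastrointestinal disorders"
        assert row.count == 468
        assert row.percent == 13.05

    def test_singleton_rollup_equals_pt_row(self):
        table = soc_rollup([stub_signal("Nausea", 7)], SocMap({"Nausea": "GI"}), 100)
        assert table.rows[0].count == 7
        assert table.rows[0].percent == 7.0

    def test_counts_conserved_under_any_partition(self):
        import random

        rng = random.Random(42)
        signals = [stub_signal(f"PT{i}", rng.randint(1, 50)) for i in range(30)]
        soc = SocMap({f"PT{i}": f"SOC{rng.randint(0, 5)}" for i in range(30)})
        table = soc_rollup(signals, soc, total_reports=5000)
        assert sum(r.count for r in table.rows) == sum(s.a for s in signals)

    def test_unmapped_pt_grouped_under_sentinel(self):
        table = soc_rollup([stub_signal("Oddity", 4)], SocMap({}), 100)
        assert table.rows[0].label == "Unmapped"

    def test_duplicate_pt_rejected(self):
        sig = stub_signal("Nausea", 5)
        with pytest.raises(ValueError, match="more than once"):
            soc_rollup([sig, sig], SocMap({}), 100)

    def test_rows_sorted_by_count_descending(self):
        signals = [stub_signal("A", 5), stub_signal("B", 50), stub_signal("C", 20)]
        soc = SocMap({"A": "S1", "B": "S2", "C": "S3"})
        table = soc_rollup(signals, soc, 100)
        assert [r.count for r in table.rows] == [50, 20, 5]


class TestAnnotateLabels:
    def test_listed_unlisted_counts(self):
        signals = [stub_signal(f"PT{i}", 5) for i in range(68)]
        labels = LabelList({f"PT{i}" for i in range(40)})
        annotated, counts = annotate_labels(signals, labels)
        assert counts == {"listed": 40, "unlisted": 28}
        assert round_percent(counts["listed"], 68) == 58.82
        assert round_percent(counts["unlisted"], 68) == 41.18

    def test_empty_label_list(self):
        signals = [stub_signal("Nausea", 5)]
        _, counts = annotate_labels(signals, LabelList(set()))
        assert counts == {"listed": 0, "unlisted": 1}

    def test_all_listed(self):
        signals = [stub_signal("Nausea", 5), stub_signal("Pain", 4)]
        _, counts = annotate_labels(signals, LabelList({"nausea", "PAIN"}))
        assert counts == {"listed": 2, "unlisted": 0}

    def test_non_signal_rows_not_counted(self):
        signals = [stub_signal("Nausea", 5, is_signal=False)]
        _, counts = annotate_labels(signals, LabelList({"Nausea"}))
        assert counts == {"listed": 0, "unlisted": 0}


class TestRounding:
    @pytest.mark.parametrize(
        "count,den,expected",
        [(1954, 3587, 54.47), (1557, 3587, 43.41), (112, 3587, 3.12), (1, 8, 12.5)],
    )
    def test_half_up_two_decimals(self, count, den, expected):
        assert round_percent(count, den) == expected

    def test_half_up_at_exact_midpoint(self):
        assert round_percent(125, 1000) == 12.5
        assert round_percent(1, 16) == 6.25
        # 0.125% -> midpoint at 2 decimals rounds up
        assert round_percent(125, 100_000) == 0.13

    def test_zero_denominator(self):
        assert round_percent(5, 0) == 0.0
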