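"""Report domain types, deduplication, and inclusion/exclusion filters."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vigilstat.reports import (
    DrugEntry,
    DrugRole,
    ReportSet,
    deduplicate,
    exclude_terms,
    filter_first_suspect,
    normalize_drug_name,
)

from conftest import make_report


class TestDomainTypes:
    def test_drug_name_normalization(self):
        assert normalize_drug_name("  Rosuvastatin   Calcium ") == "rosuvastatin calcium"
        assert DrugEntry(" FENOFIBRATE ", DrugRole.PRIMARY_SUSPECT).name == "fenofibrate"

    def test_empty_drug_name_rejected(self):
        with pytest.raises(ValueError):
            DrugEntry("   ", DrugRole.CONCOMITANT)

    def test_report_requires_reactions(self):
        with pytest.raises(ValueError, match="reaction"):
            make_report("C1", set())

    def test_duplicate_pts_collapse(self):
        rec = make_report("C1", ["Nausea", "Nausea"])
        assert rec.reactions == frozenset({"Nausea"})

    def test_age_bound(self):
        with pytest.raises(ValueError, match="age"):
            make_report("C1", {"Nausea"}, age=180)


class TestDeduplicate:
    def test_keeps_highest_version(self):
        rs = ReportSet(
            [
                make_report("C1", {"Nausea"}, version=1),
                make_report("C1", {"Myalgia"}, version=2),
                make_report("C2", {"Rash"}, version=1),
            ]
        )
        out = deduplicate(rs)
        assert {(r.case_id, r.case_version) for r in out} == {("C1", 2), ("C2", 1)}

    def test_version_tie_broken_by_latest_date(self):
        rs = ReportSet(
            [
                make_report("C1", {"Nausea"}, version=2, date="2019-01-01"),
                make_report("C1", {"Myalgia"}, version=2, date="2019-06-01"),
            ]
        )
        (kept,) = deduplicate(rs).reports
        assert kept.reactions == frozenset({"Myalgia"})

    def test_full_tie_keeps_last_occurrence(self):
        rs = ReportSet(
            [
                make_report("C1", {"First"}, version=1),
                make_report("C1", {"Second"}, version=1),
            ]
        )
        (kept,) = deduplicate(rs).reports
        assert kept.reactions == frozenset({"Second"})

    def test_output_size_equals_distinct_ids_on_generated_corpus(self):
        from vigilstat.simulate import generate, independence_config
        from dataclasses import replace

        cfg = replace(independence_config(n_reports=300, n_pts=20, seed=5), duplicate_fraction=0.1)
        rs, _ = generate(cfg)
        assert len(rs) == 330  # 10% duplicates appended
        out = deduplicate(rs)
        assert len(out) == len(rs.case_ids()) == 300
        # every survivor is the max version of its case
        assert all(r.case_version == 2 for r in out if sum(
            1 for x in rs.reports if x.case_id == r.case_id) == 2)

    def test_idempotent(self):
        rs = ReportSet(
            [
                make_report("C1", {"Nausea"}, version=1),
                make_report("C1", {"Myalgia"}, version=3),
                make_report("C2", {"Rash"}, version=1),
            ]
        )
        once = deduplicate(rs)
        twice = deduplicate(once)
        assert once.reports == twice.reports


class TestFilterFirstSuspect:
    def test_both_primary_suspect_retained(self):
        rs = ReportSet([make_report("C1", {"Nausea"})])
        out = filter_first_suspect(rs, {"rosuvastatin", "fenofibrate"})
        assert len(out) == 1

    def test_concomitant_role_excluded(self):
        rs = ReportSet(
            [
                make_report(
                    "C1",
                    {"Nausea"},
                    drugs=(
                        ("rosuvastatin", DrugRole.PRIMARY_SUSPECT),
                        ("fenofibrate", DrugRole.CONCOMITANT),
                    ),
                )
            ]
        )
        assert len(filter_first_suspect(rs, {"rosuvastatin", "fenofibrate"})) == 0
        assert (
            len(
                filter_first_suspect(
                    rs, {"rosuvastatin", "fenofibrate"}, allow_secondary=True
                )
            )
            == 0
        )  # concomitant is not a suspect role either

    def test_case_insensitive_match(self):
        rs = ReportSet([make_report("C1", {"Nausea"})])
        assert len(filter_first_suspect(rs, {"ROSUVASTATIN", "Fenofibrate"})) == 1

    def test_recovers_generator_exposed_set(self):
        from vigilstat.simulate import generate, independence_config

        rs, truth = generate(independence_config(n_reports=500, n_pts=30, seed=7))
        out = filter_first_suspect(rs, {"rosuvastatin", "fenofibrate"})
        assert out.case_ids() == truth.exposed_case_ids

    def test_empty_drug_set_rejected(self):
        with pytest.raises(ValueError):
            filter_first_suspect(ReportSet([]), set())


class TestExcludeTerms:
    def test_term_removed_report_kept(self):
        rs = ReportSet([make_report("C1", {"Hyperlipidaemia", "Nausea"})])
        out = exclude_terms(rs, {"Hyperlipidaemia"})
        assert out.reports[0].reactions == frozenset({"Nausea"})

    def test_emptied_report_dropped(self):
        rs = ReportSet([make_report("C1", {"Hyperlipidaemia"})])
        assert len(exclude_terms(rs, {"Hyperlipidaemia"})) == 0

    def test_empty_exclusion_is_identity(self):
        rs = ReportSet([make_report("C1", {"Nausea"})])
        assert exclude_terms(rs, set()) == rs

    def test_match_is_case_insensitive(self):
        rs = ReportSet([make_report("C1", {"HYPERLIPIDAEMIA", "Nausea"})])
        out = exclude_terms(rs, {"hyperlipidaemia"})
        assert out.reports[0].reactions == frozenset({"Nausea"})


# ---------------------------------------------------------------------------
# algebraic properties of the filters

pt_strategy = st.sets(st.sampled_from(["Nausea", "Myalgia", "Rash", "Pain", "Headache"]), min_size=1)
role_strategy = st.sampled_from(list(DrugRole))


@st.composite
def report_sets(draw):
    n = draw(st.integers(0, 12))
    reports = []
    for i in range(n):
        drugs = [
            ("rosuvastatin", draw(role_strategy)),
            ("fenofibrate", draw(role_strategy)),
        ]
        reports.append(make_report(f"C{i}", draw(pt_strategy), drugs=drugs))
    return ReportSet(reports)


@given(rs=report_sets())
@settings(max_examples=60, deadline=None)
def test_filter_and_exclusion_commute(rs):
    """Suspect-drug filtering and term exclusion touch disjoint fields, so
    their order cannot matter (on corpora where exclusion never empties a
    report the drop rules cannot interact either way)."""
    drugs = {"rosuvastatin", "fenofibrate"}
    excl = {"Rash"}  # never the only PT? guard below
    safe = ReportSet([r for r in rs.reports if r.reactions != frozenset({"Rash"})])
    ab = exclude_terms(filter_first_suspect(safe, drugs), excl)
    ba = filter_first_suspect(exclude_terms(safe, excl), drugs)
    assert ab.reports == ba.reports


@given(rs=report_sets())
@settings(max_examples=60, deadline=None)
def test_filter_monotone_in_drug_set(rs):
    one = filter_first_suspect(rs, {"rosuvastatin"})
    both = filter_first_suspect(rs, {"rosuvastatin", "fenofibrate"})
    assert set(both.case_ids()) <= set(one.case_ids())


@given(rs=report_sets())
@settings(max_examples=60, deadline=None)
def test_dedup_idempotent_property(rs):
    once = deduplicate(rs)
    assert deduplicate(once).reports == once.reports
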