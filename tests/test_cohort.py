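"""cohort: selection filters, therapy class, descriptive summary arithmetic."""

import itertools

import pytest

from pvsignal import cohort
from pvsignal.cohort import (
    CohortRow,
    CohortSpec,
    age_group,
    descriptive_summary,
    indication_group,
    label_universe,
    round_half_up,
    select_cohort,
    therapy_class,
)

from conftest import make_drug, make_report


def beva(route="INTRAVENOUS", role="PS"):
    return make_drug("AVASTIN", "BEVACIZUMAB", role=role, route=route)


@pytest.fixture
def spec():
    return CohortSpec(drug_of_interest="BEVACIZUMAB")


class TestCohortSpec:
    def test_unknown_drug_without_synonyms_is_hard_error(self):
        with pytest.raises(ValueError, match="synonyms"):
            CohortSpec(drug_of_interest="NOVELUMAB")

    def test_declared_synonyms_accepted(self):
        s = CohortSpec(drug_of_interest="NOVELUMAB", synonyms=("NOVELUMAB", "NOVELIX"))
        assert s.matches_drug(make_drug("NOVELIX 100MG", "NOVELUMAB"))

    def test_brand_containment_matching(self, spec):
        assert spec.matches_drug(make_drug("AVASTIN (SOLUTION)", ""))
        assert spec.matches_drug(make_drug("UNKNOWN", "BEVACIZUMAB"))
        assert not spec.matches_drug(make_drug("CYRAMZA", "RAMUCIRUMAB"))

    def test_empty_filters_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(drug_of_interest="BEVACIZUMAB", route_filter=frozenset())
        with pytest.raises(ValueError):
            CohortSpec(drug_of_interest="BEVACIZUMAB", reporter_filter=frozenset())


class TestSelectCohort:
    def test_paper_style_filters(self, spec, dictionary):
        kept = make_report("1", drugs=[beva()], reporter="physician")
        wrong_route = make_report("2", drugs=[beva(route="INTRAVITREAL")])
        unspecified_route = make_report("3", drugs=[beva(route="")])
        consumer = make_report("4", drugs=[beva()], reporter="consumer")
        not_suspect = make_report("5", drugs=[beva(role="SS")])
        rows = select_cohort(
            [kept, wrong_route, unspecified_route, consumer, not_suspect],
            spec, dictionary)
        assert [r.primaryid for r in rows] == ["1"]

    def test_ten_report_fixture_three_pass(self, spec, dictionary):
        reports = [
            make_report("1", drugs=[beva()], reporter="physician"),
            make_report("2", drugs=[beva()], reporter="pharmacist"),
            make_report("3", drugs=[beva()], reporter="other_health_professional"),
            make_report("4", drugs=[beva()], reporter="consumer"),
            make_report("5", drugs=[beva()], reporter="lawyer"),
            make_report("6", drugs=[beva(route="INTRAVITREAL")]),
            make_report("7", drugs=[beva(route="ORAL")]),
            make_report("8", drugs=[beva(route="")]),
            make_report("9", drugs=[beva(role="C")]),
            make_report("10", drugs=[make_drug("CYRAMZA", "RAMUCIRUMAB")]),
        ]
        rows = select_cohort(reports, spec, dictionary)
        assert sorted(int(r.primaryid) for r in rows) == [1, 2, 3]

    def test_window_applies_only_to_dated_events(self, dictionary):
        spec = CohortSpec(drug_of_interest="BEVACIZUMAB", window=("2023Q1", "2023Q2"))
        inside = make_report("1", drugs=[beva()], event="20230215")
        outside = make_report("2", drugs=[beva()], event="20231115")
        undated = make_report("3", drugs=[beva()], event="")
        rows = select_cohort([inside, outside, undated], spec, dictionary)
        assert sorted(r.primaryid for r in rows) == ["1", "3"]

    def test_filters_commute(self, spec, dictionary):
        # applying route/reporter/role as successive standalone passes in any
        # order retains the same report set as the combined selection
        reports = [
            make_report(str(i), drugs=[beva(route=rt, role=rl)], reporter=rep)
            for i, (rt, rl, rep) in enumerate(itertools.product(
                ["INTRAVENOUS", "INTRAVITREAL", ""],
                ["PS", "SS"],
                ["physician", "consumer"],
            ))
        ]

        def route_pass(rs):
            return [r for r in rs if any(
                d.route_class in spec.route_filter and spec.matches_drug(d)
                for d in r.drugs)]

        def role_pass(rs):
            return [r for r in rs if any(
                d.role_code == spec.required_role and spec.matches_drug(d)
                for d in r.drugs)]

        def reporter_pass(rs):
            return [r for r in rs if r.reporter_qualification in spec.reporter_filter]

        combined = {r.primaryid for r in select_cohort(reports, spec, dictionary)}
        for order in itertools.permutations([route_pass, role_pass, reporter_pass]):
            subset = reports
            for f in order:
                subset = f(subset)
            assert {r.primaryid for r in subset} == combined

    def test_annotations(self, spec, dictionary):
        r = make_report(
            "1", drugs=[beva()], outcomes=("DE", "HO"), age=70,
            pts=("PULMONARY EMBOLISM",), indications=[("1", "COLORECTAL CANCER")],
            start="20230401", event="20230531",
        )
        row = select_cohort([r], spec, dictionary)[0]
        assert row.fatal and row.age_group == "ge65"
        assert row.labels == {"PE", "VTE", "overall_TEE"}
        assert row.indication_group == "colorectal"
        assert row.onset_days == 60


class TestTherapyClass:
    def test_chemo_codrug(self, spec):
        r = make_report("1", drugs=[beva(), make_drug("OXALIPLATIN", role="SS", route="")])
        assert therapy_class(r, spec) == "plus_chemotherapy"

    def test_other_antineoplastic_codrug(self, spec):
        r = make_report("1", drugs=[beva(), make_drug("KEYTRUDA", "PEMBROLIZUMAB", role="C")])
        assert therapy_class(r, spec) == "other_combined"

    def test_no_codrugs_is_monotherapy(self, spec):
        assert therapy_class(make_report("1", drugs=[beva()]), spec) == "monotherapy"

    def test_unlisted_codrug_is_monotherapy(self, spec):
        r = make_report("1", drugs=[beva(), make_drug("OMEPRAZOLE", role="C")])
        assert therapy_class(r, spec) == "monotherapy"


class TestAgeGroup:
    @pytest.mark.parametrize("age,grp", [
        (None, "unknown"), (17.9, "lt18"), (18, "18to64"), (64.9, "18to64"),
        (65, "ge65"), (90, "ge65"),
    ])
    def test_bounds(self, age, grp):
        assert age_group(age) == grp


class TestRounding:
    @pytest.mark.parametrize("x,expected", [
        (34.812, 34.8), (30.446, 30.4), (59.95, 60.0), (65.476, 65.5), (0.25, 0.3),
    ])
    def test_half_up_one_decimal(self, x, expected):
        assert round_half_up(x, 1) == expected


def _rows(drug, n, fatal_n=0, male_n=None, onset_bins=None):
    """Programmatic cohort rows; attributes assigned by index, independently."""
    onset_days = []
    if onset_bins:
        reps = {"0-30d": 5, "31-60d": 40, "61-90d": 75, "91-180d": 120,
                "181-365d": 250, ">365d": 500}
        for label, count in onset_bins.items():
            onset_days += [reps[label]] * count
    rows = []
    for i in range(n):
        rows.append(CohortRow(
            primaryid=f"{drug}-{i}", drug=drug,
            labels=frozenset({"overall_TEE"}),
            sex="M" if male_n is not None and i < male_n else "F",
            age_group="18to64", fatal=i < fatal_n, country="US",
            indication_group="other", therapy_class="monotherapy",
            onset_days=onset_days[i] if i < len(onset_days) else None,
            onset_reason=None if i < len(onset_days) else "missing",
        ))
    return rows


class TestDescriptiveSummary:
    def test_all_male_cohort(self):
        table = descriptive_summary(_rows("X", 10, male_n=10))
        sex = table[(table.block == "sex")].set_index("level")["value"]
        assert sex["M"] == 100.0 and sex["F"] == 0.0

    def test_onset_percentages_over_available_subset(self):
        bins = {"0-30d": 31, "31-60d": 8, "61-90d": 7, "91-180d": 4,
                "181-365d": 2, ">365d": 2}
        table = descriptive_summary(_rows("X", 95, onset_bins=bins))
        onset = table[table.block == "onset_bin"].set_index("level")
        assert set(onset["denominator"]) == {54}
        assert onset.loc["0-30d", "value"] == 57.4  # 31/54

    def test_empty_cohort_no_division_by_zero(self):
        table = descriptive_summary([])
        assert len(table) == 0
        table2 = descriptive_summary(_rows("X", 0))
        assert len(table2) == 0

    def test_percentages_sum_to_100_within_blocks(self):
        rows = _rows("X", 37, fatal_n=11, male_n=20,
                     onset_bins={"0-30d": 9, "91-180d": 4})
        table = descriptive_summary(rows)
        for block in ("sex", "outcome", "therapy_class", "onset_bin", "age_group"):
            sub = table[table.block == block]
            if sub["denominator"].iloc[0] == 0:
                continue
            assert abs(sub["value"].sum() - 100.0) <= 0.1 * len(sub)

    def test_counts_sum_to_cohort_size(self):
        rows = _rows("X", 37, fatal_n=11, male_n=20)
        table = descriptive_summary(rows)
        for block in ("sex", "outcome", "age_group", "therapy_class"):
            assert table[table.block == block]["count"].sum() == 37


class TestIndicationGroup:
    @pytest.mark.parametrize("pt,grp", [
        ("COLORECTAL CANCER", "colorectal"),
        ("COLON CANCER METASTATIC", "colorectal"),
        ("NON-SMALL CELL LUNG CANCER", "nsclc"),
        ("GASTRIC CANCER", "gastroesophageal"),
        ("OVARIAN CANCER", "ovarian"),
        ("GLIOBLASTOMA MULTIFORME", "glioblastoma"),
        ("BREAST CANCER", "other"),
    ])
    def test_mapping(self, pt, grp):
        r = make_report("1", indications=[("1", pt)])
        assert indication_group(r) == grp

    def test_no_indication_is_unknown(self):
        assert indication_group(make_report("1")) == "unknown"


def test_label_universe_respects_route(dictionary):
    spec = CohortSpec(drug_of_interest="BEVACIZUMAB")
    iv = make_report("1", drugs=[beva()], pts=("PULMONARY EMBOLISM",))
    ocular = make_report("2", drugs=[beva(route="INTRAVITREAL")], pts=("NAUSEA",))
    universe = label_universe([iv, ocular], [spec], dictionary)
    assert universe[0].drug_labels == {"BEVACIZUMAB"}
    assert universe[1].drug_labels == frozenset()
    assert "PE" in universe[0].event_labels
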