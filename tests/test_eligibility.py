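"""Visit classification, attrition arithmetic, reach, deduplication."""

import datetime as dt

import pandas as pd
import pytest

import pars_reach as pr
from pars_reach.eligibility import (
    ScopeConfig,
    UnclassifiableVisitError,
    Visit,
    attrition_from_classification,
    build_attrition,
    classify_visit,
    classify_visits,
    compute_reach,
    count_referred,
    round_half_away,
    unique_patient_counts,
)

from conftest import make_dx, make_refs, make_visits

SCOPE = ScopeConfig()  # 18-80, 2021-03-15..2022-09-30, REF201


def _visit(codes, age=45, date=dt.date(2021, 6, 1), vid="V1", pid="P1", clinic="C01"):
    dx = tuple((pr.normalize_code(c), src) for c, src in codes)
    return Visit(visit_id=vid, patient_id=pid, clinic_id=clinic, provider_id="DR1",
                 service_date=date, age_at_visit=age, dx=dx)


class TestClassifyVisit:
    def test_hypertension_only_is_eligible(self, criteria_set):
        res = classify_visit(_visit([("I10", "problem_list")]), SCOPE, criteria_set)
        assert res.inclusion_hits == ("hypertension",)
        assert res.exclusion_hits == ()
        assert res.eligible

    def test_severe_asthma_disqualifies(self, criteria_set):
        res = classify_visit(
            _visit([("I10", "problem_list"), ("J45.51", "encounter")]), SCOPE, criteria_set)
        assert res.inclusion_hits == ("hypertension",)
        assert res.exclusion_hits  # severe-asthma criterion
        hit = {c.id: c for c in criteria_set.criteria}[res.exclusion_hits[0]]
        assert hit.category == "moderate/severe asthma" and str(hit.pattern) == "J455*"
        assert not res.eligible

    def test_mild_asthma_matches_nothing(self, criteria_set):
        res = classify_visit(_visit([("J45.20", "encounter")]), SCOPE, criteria_set)
        assert res.inclusion_hits == () and res.exclusion_hits == ()
        assert not res.eligible

    @pytest.mark.parametrize("age, in_scope", [(17, False), (18, True), (80, True), (81, False)])
    def test_age_bounds_inclusive(self, criteria_set, age, in_scope):
        res = classify_visit(_visit([("I10", "problem_list")], age=age), SCOPE, criteria_set)
        assert res.in_scope is in_scope and res.eligible is in_scope

    @pytest.mark.parametrize("date, in_scope", [
        (dt.date(2021, 3, 14), False), (dt.date(2021, 3, 15), True),
        (dt.date(2022, 9, 30), True), (dt.date(2022, 10, 1), False),
    ])
    def test_window_bounds_inclusive(self, criteria_set, date, in_scope):
        res = classify_visit(_visit([("I10", "problem_list")], date=date), SCOPE, criteria_set)
        assert res.in_scope is in_scope

    def test_hits_recorded_even_out_of_scope(self, criteria_set):
        res = classify_visit(_visit([("I10", "problem_list")], age=99), SCOPE, criteria_set)
        assert not res.in_scope and res.inclusion_hits == ("hypertension",)

    def test_source_restriction(self, criteria_set):
        visit = _visit([("I10", "encounter")])
        assert classify_visit(visit, SCOPE, criteria_set, dx_sources=("problem_list",)).inclusion_hits == ()
        assert classify_visit(visit, SCOPE, criteria_set, dx_sources=("encounter",)).inclusion_hits == ("hypertension",)

    def test_negative_age_is_unclassifiable(self, criteria_set):
        with pytest.raises(UnclassifiableVisitError):
            classify_visit(_visit([("I10", "problem_list")], age=-1), SCOPE, criteria_set)


class TestAttritionArithmetic:
    def test_visit_flow_counts(self):
        """The worked example: half a million visits, two criteria stages."""
        rep = build_attrition(479_536, [("inclusion criteria", 202_021),
                                        ("exclusion criteria", 63_203)])
        assert [s.remaining for s in rep.stages] == [277_515, 214_312]
        assert rep.pct_removed_of_entering(0) == 42
        assert rep.pct_remaining_of_initial(0) == 58
        assert rep.pct_removed_of_entering(1) == 23
        assert rep.pct_reduction_from_initial == 55

    def test_unique_patient_flow_counts(self):
        rep = build_attrition(110_362, [("inclusion criteria", 110_362 - 66_993),
                                        ("exclusion criteria", 66_993 - 60_102)])
        assert [s.remaining for s in rep.stages] == [66_993, 60_102]
        assert rep.pct_reduction_from_initial == 46

    def test_zero_removal(self):
        rep = build_attrition(1000, [("nothing", 0)])
        assert rep.final == 1000 and rep.pct_reduction_from_initial == 0

    def test_conservation_at_every_stage(self):
        rep = build_attrition(100, [("a", 10), ("b", 20), ("c", 70)])
        entering = 100
        for s in rep.stages:
            assert s.entering == entering and s.remaining == s.entering - s.removed
            entering = s.remaining
        assert rep.final == 0

    def test_removal_exceeding_entering_rejected(self):
        with pytest.raises(ValueError):
            build_attrition(10, [("too much", 11)])
        with pytest.raises(ValueError):
            build_attrition(10, [("negative", -1)])

    def test_flow_text_matches_json(self):
        rep = build_attrition(479_536, [("inclusion criteria", 202_021),
                                        ("exclusion criteria", 63_203)])
        text = rep.flow_text()
        doc = rep.to_dict()
        assert "55% reduction" in text
        for stage in doc["stages"]:
            assert f"{stage['removed']:,}" in text
            assert f"{stage['pct_removed_of_entering']}% of entering" in text

    @pytest.mark.parametrize("x, expected", [(0.5, 1), (1.5, 2), (2.4, 2), (2.5, 3),
                                             (-0.5, -1), (-2.5, -3), (45.54, 46)])
    def test_round_half_away(self, x, expected):
        assert round_half_away(x) == expected


def _mini_extract():
    """Five visits, three patients, two clinics, hand-computable."""
    visits = make_visits([
        ("V1", "P1", "C01", "D1", "2021-06-01", "45"),  # hypertension -> eligible, referred
        ("V2", "P1", "C02", "D1", "2021-07-01", "45"),  # hypertension + severe asthma -> excluded
        ("V3", "P2", "C01", "D1", "2021-08-01", "30"),  # nothing -> not included, noisy referral
        ("V4", "P2", "C01", "D1", "2021-09-01", "30"),  # obesity -> eligible
        ("V5", "P3", "C01", "D1", "2021-10-01", "85"),  # out of scope by age
    ])
    dx = make_dx([
        ("V1", "problem_list", "I10"),
        ("V2", "problem_list", "I10"),
        ("V2", "encounter", "J45.51"),
        ("V4", "encounter", "E66.9"),
        ("V5", "problem_list", "I10"),
    ])
    refs = make_refs([("V1", "REF201"), ("V3", "REF201"), ("V2", "REF201")])
    return visits, dx, refs


class TestPipeline:
    def test_mini_extract_classification(self, criteria_set):
        visits, dx, refs = _mini_extract()
        cl = classify_visits(visits, dx, SCOPE, criteria_set)
        by_id = cl.set_index("visit_id")
        assert by_id.loc["V1", "eligible"]
        assert not by_id.loc["V2", "eligible"] and by_id.loc["V2", "exclusion_hits"]
        assert not by_id.loc["V3", "eligible"]
        assert by_id.loc["V4", "eligible"]
        assert not by_id.loc["V5", "in_scope"] and by_id.loc["V5", "inclusion_hits"] == ("hypertension",)

    def test_numerator_modes(self, criteria_set):
        visits, dx, refs = _mini_extract()
        cl = classify_visits(visits, dx, SCOPE, criteria_set)
        # default: V1 (eligible+referred) and V2 (inclusion-hit but excluded) count;
        # V3's noisy referral has no inclusion hit and does not
        assert count_referred(cl, refs, SCOPE) == 2
        # strict mode intersects with the denominator set
        assert count_referred(cl, refs, SCOPE, strict=True) == 1

    def test_orphan_referrals_ignored_with_warning(self, criteria_set, caplog):
        visits, dx, _ = _mini_extract()
        refs = make_refs([("V1", "REF201"), ("V999", "REF201")])
        cl = classify_visits(visits, dx, SCOPE, criteria_set)
        with caplog.at_level("WARNING", logger="pars_reach.eligibility"):
            assert count_referred(cl, refs, SCOPE) == 1
        assert any("unknown visit_id" in r.message for r in caplog.records)

    def test_reach_visits_unit(self, criteria_set):
        visits, dx, refs = _mini_extract()
        cl = classify_visits(visits, dx, SCOPE, criteria_set)
        est = compute_reach(cl, refs, SCOPE, unit="visits")
        assert (est.numerator, est.denominator) == (2, 2)
        strict = compute_reach(cl, refs, SCOPE, unit="visits", strict_numerator=True)
        assert (strict.numerator, strict.denominator) == (1, 2)

    def test_reach_unique_patients_unit(self, criteria_set):
        visits, dx, refs = _mini_extract()
        cl = classify_visits(visits, dx, SCOPE, criteria_set)
        est = compute_reach(cl, refs, SCOPE, unit="unique_patients")
        # P1 referred (V1), P1 and P2 have eligible visits
        assert (est.numerator, est.denominator) == (1, 2)

    def test_reach_proportion_from_published_counts(self):
        est = pr.ReachEstimate(unit="visits", numerator=334, denominator=214_312)
        assert est.proportion == pytest.approx(0.00155847, rel=1e-4)

    def test_zero_denominator_is_undefined_not_zero(self):
        est = pr.ReachEstimate(unit="visits", numerator=0, denominator=0)
        assert est.proportion is None
        assert est.to_dict()["proportion"] is None

    def test_attrition_from_classification(self, criteria_set):
        visits, dx, refs = _mini_extract()
        cl = classify_visits(visits, dx, SCOPE, criteria_set)
        rep = attrition_from_classification(cl, unit="visits")
        # 4 in scope; V3 removed by inclusion; V2 removed by exclusion
        assert rep.initial == 4
        assert [s.removed for s in rep.stages] == [1, 1]
        assert rep.final == 2
        prep = attrition_from_classification(cl, unit="unique_patients")
        assert prep.initial == 2 and prep.final == 2  # P1, P2 both keep an eligible visit

    def test_unclassifiable_records_excluded_not_dropped_silently(self, criteria_set, caplog):
        visits = make_visits([
            ("V1", "P1", "C01", "D1", "2021-06-01", "45"),
            ("V2", "P2", "C01", "D1", "not-a-date", "45"),
            ("V3", "P3", "C01", "D1", "2021-06-01", "-2"),
        ])
        dx = make_dx([("V1", "problem_list", "I10"), ("V2", "problem_list", "I10")])
        with caplog.at_level("WARNING", logger="pars_reach.eligibility"):
            cl = classify_visits(visits, dx, SCOPE, criteria_set)
        assert cl["unclassifiable"].tolist() == [False, True, True]
        assert not cl.loc[cl["unclassifiable"], "in_scope"].any()
        assert not cl.loc[cl["unclassifiable"], "eligible"].any()
        assert any("unclassifiable" in r.message for r in caplog.records)

    def test_filter_order_invariance(self, criteria_set, small_extract):
        """Exclusion-then-inclusion yields the same final eligible set as
        inclusion-then-exclusion (both are per-visit predicates)."""
        cfg = small_extract.config
        cl = classify_visits(small_extract.visits, small_extract.diagnoses,
                             cfg.scope(), criteria_set)
        inc_first = cl[cl["in_scope"] & cl["inclusion_hits"].map(bool)]
        final_a = set(inc_first.loc[~inc_first["exclusion_hits"].map(bool), "visit_id"])
        exc_first = cl[cl["in_scope"] & ~cl["exclusion_hits"].map(bool)]
        final_b = set(exc_first.loc[exc_first["inclusion_hits"].map(bool), "visit_id"])
        assert final_a == final_b == set(cl.loc[cl["eligible"], "visit_id"])

    def test_criteria_monotonicity(self, criteria_set, small_extract):
        """Dropping an exclusion criterion never shrinks the eligible set;
        dropping an inclusion criterion never grows it."""
        cfg = small_extract.config
        full = classify_visits(small_extract.visits, small_extract.diagnoses,
                               cfg.scope(), criteria_set)
        n_full = int(full["eligible"].sum())
        fewer_exc = pr.CriteriaSet(name="t", version="1", criteria=[
            c for c in criteria_set.criteria
            if not (c.direction == "exclusion" and c.id == "EXC001")])
        n_fewer_exc = int(classify_visits(small_extract.visits, small_extract.diagnoses,
                                          cfg.scope(), fewer_exc)["eligible"].sum())
        assert n_fewer_exc >= n_full
        fewer_inc = pr.CriteriaSet(name="t", version="1", criteria=[
            c for c in criteria_set.criteria
            if not (c.direction == "inclusion" and c.category == "hypertension")])
        n_fewer_inc = int(classify_visits(small_extract.visits, small_extract.diagnoses,
                                          cfg.scope(), fewer_inc)["eligible"].sum())
        assert n_fewer_inc <= n_full


class TestUniquePatients:
    def test_clinic_switcher_double_counted_per_clinic(self):
        visits = make_visits([
            ("V1", "P1", "C01", "D1", "2021-06-01", "45"),
            ("V2", "P1", "C02", "D1", "2021-07-01", "45"),
        ])
        assert unique_patient_counts(visits, "system") == 1
        assert unique_patient_counts(visits, "per_clinic_sum") == 2

    def test_levels_equal_without_switching(self, criteria_set):
        from pars_reach.synthetic import SyntheticConfig, generate_extract
        ext = generate_extract(SyntheticConfig(seed=3, n_patients=200, p_clinic_switch=0.0),
                               criteria_set)
        assert unique_patient_counts(ext.visits, "system") == \
               unique_patient_counts(ext.visits, "per_clinic_sum")

    def test_per_clinic_sum_dominates_system(self, small_extract):
        assert unique_patient_counts(small_extract.visits, "per_clinic_sum") >= \
               unique_patient_counts(small_extract.visits, "system")

    def test_switch_count_recovered(self, small_extract):
        diff = unique_patient_counts(small_extract.visits, "per_clinic_sum") - \
               unique_patient_counts(small_extract.visits, "system")
        assert diff == small_extract.n_switchers
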