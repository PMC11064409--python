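import pandas as pd
import pytest

import oracle
from conftest import day, dx, enc, lab, make_bundle, px
from pheindex.criteria import (
    CRITERIA,
    evaluate_all,
    evaluate_cohort,
    evaluate_death,
    evaluate_developmental_delay,
    evaluate_er_visits,
    evaluate_feeding_support,
    evaluate_heart_surgery,
    evaluate_hospitalizations,
    evaluate_metabolic_icd,
    evaluate_multiple_specialists,
    evaluate_nicu_stay,
    evaluate_order_criterion,
    evaluate_respiratory_support,
    max_score,
)
from pheindex.emr import TermStatus
from pheindex.synthetic import GeneratorConfig, generate_cohort

FULL, PRE = 280, 210  # gestational ages used throughout


class TestNicuStay:
    def test_full_term_early_long_stay_met(self, specs):
        b = make_bundle(ga=FULL, encounters=[enc("icu", 1, dur_days=5)])
        r = evaluate_nicu_stay(b, specs["nicu_stay"])
        assert r.met and r.first_met_age == pytest.approx(5)

    def test_pre_term_never_met(self, specs):
        b = make_bundle(ga=PRE, encounters=[enc("icu", 0, dur_days=30)])
        assert not evaluate_nicu_stay(b, specs["nicu_stay"]).met

    def test_late_admission_outside_birth_window_not_met(self, specs):
        b = make_bundle(ga=FULL, encounters=[enc("icu", 10, dur_days=6)])
        assert not evaluate_nicu_stay(b, specs["nicu_stay"]).met


class TestHospitalizations:
    def test_single_prolonged_stay_met(self, specs):
        b = make_bundle(ga=FULL, encounters=[enc("inpatient", 60, dur_days=15)])
        assert evaluate_hospitalizations(b, specs["hospitalizations"]).met

    def test_pre_term_two_stays_below_count_threshold(self, specs):
        b = make_bundle(
            ga=PRE,
            encounters=[enc("inpatient", 100, dur_days=3), enc("inpatient", 200, dur_days=3)],
        )
        assert not evaluate_hospitalizations(b, specs["hospitalizations"]).met

    def test_very_preterm_birth_hospitalization_excluded(self, specs):
        # born at 26 weeks (182 d); a 60-day birth stay starts below 35 w PMA
        b = make_bundle(ga=182, encounters=[enc("inpatient", 0, dur_days=60)])
        assert not evaluate_hospitalizations(b, specs["hospitalizations"]).met

    def test_stay_before_35_weeks_pma_not_counted(self, specs):
        # GA 210 d: day-20 admission is 230 d PMA -> ineligible even at 20 d long
        b = make_bundle(
            ga=210,
            encounters=[enc("inpatient", 20, dur_days=20)],
        )
        assert not evaluate_hospitalizations(b, specs["hospitalizations"]).met


class TestMultipleSpecialists:
    def test_three_types_full_term_met(self, specs, vocab):
        b = make_bundle(
            ga=FULL,
            encounters=[
                enc("specialist_visit", 10, dur_hours=1, specialty="Pediatric Cardiology"),
                enc("specialist_visit", 20, dur_hours=1, specialty="Pediatric Neurology"),
                enc("specialist_visit", 30, dur_hours=1, specialty="Medical Genetics"),
            ],
        )
        r = evaluate_multiple_specialists(b, specs["multiple_specialists"], vocab)
        assert r.met and r.first_met_age == pytest.approx(30)

    def test_repeat_visits_to_one_type_count_once(self, specs, vocab):
        b = make_bundle(
            ga=FULL,
            encounters=[
                enc("specialist_visit", d, dur_hours=1, specialty="Pediatric Cardiology", eid=f"E{d}")
                for d in range(10, 110, 10)
            ],
        )
        r = evaluate_multiple_specialists(b, specs["multiple_specialists"], vocab)
        assert not r.met and r.evidence_count == 1

    def test_excluded_specialty_never_counts(self, specs, vocab):
        b = make_bundle(
            ga=PRE,
            encounters=[
                enc("specialist_visit", 10, dur_hours=1, specialty="Pediatric Cardiology"),
                enc("specialist_visit", 20, dur_hours=1, specialty="Pediatric Neurology"),
                enc("specialist_visit", 30, dur_hours=1, specialty="Pediatric Infectious Disease"),
            ],
        )
        r = evaluate_multiple_specialists(b, specs["multiple_specialists"], vocab)
        assert not r.met and r.evidence_count == 2


class TestErVisits:
    def test_fifth_visit_triggers_full_term(self, specs):
        b = make_bundle(
            ga=FULL,
            encounters=[enc("emergency", d, dur_hours=4, eid=f"E{d}") for d in (5, 50, 100, 200, 400)],
        )
        r = evaluate_er_visits(b, specs["er_visits"])
        assert r.met and r.first_met_age == pytest.approx(400)

    def test_four_visits_not_met(self, specs):
        b = make_bundle(
            ga=FULL,
            encounters=[enc("emergency", d, dur_hours=4, eid=f"E{d}") for d in (5, 50, 100, 200)],
        )
        assert not evaluate_er_visits(b, specs["er_visits"]).met

    def test_pre_term_needs_seven(self, specs):
        b = make_bundle(
            ga=PRE,
            encounters=[enc("emergency", d, dur_hours=4, eid=f"E{d}") for d in range(10, 70, 10)],
        )
        assert not evaluate_er_visits(b, specs["er_visits"]).met


class TestFeedingSupport:
    def test_matching_procedure_met(self, specs, vocab):
        b = make_bundle(procedures=[px("Gastrostomy tube placement", 30)])
        assert evaluate_feeding_support(b, specs["feeding_support"], vocab).met

    def test_cancelled_procedure_not_met(self, specs, vocab):
        b = make_bundle(procedures=[px("Gastrostomy tube placement", 30, status="cancelled")])
        assert not evaluate_feeding_support(b, specs["feeding_support"], vocab).met

    def test_no_events_not_met(self, specs, vocab):
        assert not evaluate_feeding_support(make_bundle(), specs["feeding_support"], vocab).met


class TestRespiratorySupport:
    def test_ventilation_without_surgery_met(self, specs, vocab):
        b = make_bundle(procedures=[px("Mechanical ventilation", 30)])
        assert evaluate_respiratory_support(b, specs["respiratory_support"], vocab).met

    @pytest.mark.parametrize("vent_day,met", [(30, False), (36, True), (29, True), (34, False)])
    def test_perioperative_window(self, specs, vocab, vent_day, met):
        # surgery on day 30: qualifying vents are <= day 29 or >= day 35
        b = make_bundle(
            procedures=[
                px("Appendectomy", 30, surgical=True),
                px("Mechanical ventilation", vent_day),
            ]
        )
        assert evaluate_respiratory_support(b, specs["respiratory_support"], vocab).met is met

    def test_vent_must_clear_every_surgery(self, specs, vocab):
        b = make_bundle(
            procedures=[
                px("Appendectomy", 30, surgical=True),
                px("Hernia repair", 38, surgical=True),
                px("Mechanical ventilation", 38),  # clears surgery 1, not surgery 2
            ]
        )
        assert not evaluate_respiratory_support(b, specs["respiratory_support"], vocab).met


class TestOrderCriteria:
    @pytest.mark.parametrize(
        "category,lab_cat,status,met",
        [
            ("imaging", "imaging_mri", "final", True),
            ("imaging", "imaging_ct", "cancelled", False),
            ("metabolic_tests", "metabolic_test", "completed", True),
            ("genetic_tests", "genetic_test", "preliminary", True),
            ("genetic_tests", "metabolic_test", "completed", False),
        ],
    )
    def test_status_and_category(self, specs, category, lab_cat, status, met):
        b = make_bundle(labs=[lab(lab_cat, 100, status=status)])
        assert evaluate_order_criterion(b, specs[category], category).met is met

    def test_unknown_category_rejected(self, specs):
        with pytest.raises(ValueError):
            evaluate_order_criterion(make_bundle(), specs["imaging"], "bloodwork")


class TestDeath:
    def test_expired_disposition_met(self, specs, vocab):
        b = make_bundle(encounters=[enc("inpatient", 100, dur_hours=20, dispo="expired")])
        assert evaluate_death(b, specs["death"], vocab).met

    def test_home_disposition_not_met(self, specs, vocab):
        b = make_bundle(encounters=[enc("inpatient", 100, dur_hours=20, dispo="home")])
        assert not evaluate_death(b, specs["death"], vocab).met

    def test_death_date_alone_met(self, specs, vocab):
        b = make_bundle(death_day=400)
        r = evaluate_death(b, specs["death"], vocab)
        assert r.met and r.first_met_age == pytest.approx(400)


class TestDevelopmentalDelay:
    def test_single_developmental_pediatrician_visit_met(self, specs, vocab):
        b = make_bundle(
            encounters=[enc("specialist_visit", 200, dur_hours=1, specialty="Developmental Pediatrics")]
        )
        assert evaluate_developmental_delay(b, specs["developmental_delay"], vocab).met

    def test_single_icd_date_not_met(self, specs, vocab):
        b = make_bundle(diagnoses=[dx("F80.1", 100), dx("F82", 100)])  # same date
        assert not evaluate_developmental_delay(b, specs["developmental_delay"], vocab).met

    def test_two_icd_dates_met(self, specs, vocab):
        b = make_bundle(diagnoses=[dx("F80.1", 100), dx("F80.1", 150)])
        r = evaluate_developmental_delay(b, specs["developmental_delay"], vocab)
        assert r.met and r.first_met_age == pytest.approx(150)


class TestMetabolicIcd:
    def test_two_distinct_encounters_met(self, specs, vocab):
        b = make_bundle(diagnoses=[dx("E71.0", 100, "EA"), dx("E71.0", 150, "EB")])
        assert evaluate_metabolic_icd(b, specs["metabolic_icd"], vocab).met

    def test_same_encounter_twice_not_met(self, specs, vocab):
        b = make_bundle(diagnoses=[dx("E71.0", 100, "EA"), dx("E71.0", 100, "EA")])
        assert not evaluate_metabolic_icd(b, specs["metabolic_icd"], vocab).met

    def test_no_matches_not_met(self, specs, vocab):
        b = make_bundle(diagnoses=[dx("J45.0", 100, "EA")])
        assert not evaluate_metabolic_icd(b, specs["metabolic_icd"], vocab).met


class TestHeartSurgery:
    def test_cticu_encounter_met(self, specs):
        b = make_bundle(encounters=[enc("cticu", 3, dur_days=4)])
        r = evaluate_heart_surgery(b, specs["heart_surgery"])
        assert r.met and r.first_met_age == pytest.approx(3)

    def test_cardiothoracic_procedure_met(self, specs):
        b = make_bundle(procedures=[px("VSD repair", 50, surgical=True, cardio=True)])
        assert evaluate_heart_surgery(b, specs["heart_surgery"]).met

    def test_general_surgery_not_met(self, specs):
        b = make_bundle(procedures=[px("Hernia repair", 50, surgical=True)])
        assert not evaluate_heart_surgery(b, specs["heart_surgery"]).met


class TestEvaluateAll:
    def test_no_events_nothing_met(self, specs, vocab):
        profile = evaluate_all(make_bundle(), specs, vocab)
        assert profile.met_ids() == set()

    def test_composition_er_plus_imaging(self, specs, vocab):
        b = make_bundle(
            ga=FULL,
            encounters=[enc("emergency", d, dur_hours=4, eid=f"E{d}") for d in (5, 50, 100, 200, 400)],
            labs=[lab("imaging_mri", 300, "final")],
        )
        assert evaluate_all(b, specs, vocab).met_ids() == {"er_visits", "imaging"}

    def test_preterm_long_nicu_stay_meets_nothing(self, specs, vocab):
        # 30-day ICU stay from birth at PMA < 35 w: NICU rule excluded
        # pre-term, and the stay is ICU-class, not an inpatient episode
        b = make_bundle(ga=210, encounters=[enc("icu", 0, dur_days=30)])
        assert evaluate_all(b, specs, vocab).met_ids() == set()

    def test_events_after_three_years_ignored(self, specs, vocab):
        cohort, _ = generate_cohort(GeneratorConfig(n_children=1, seed=0, base_rates={}))
        late = cohort.lab_orders.copy()
        cid = cohort.children.loc[0, "child_id"]
        late.loc[len(late)] = [
            cid,
            "imaging_mri",
            cohort.children.loc[0, "birth_date"] + pd.Timedelta(days=1200),
            "final",
        ]
        from pheindex.emr import Cohort

        c = Cohort(
            children=cohort.children,
            encounters=cohort.encounters,
            diagnoses=cohort.diagnoses,
            procedures=cohort.procedures,
            lab_orders=late,
        ).censored()
        prof = evaluate_cohort(c)
        assert not prof.loc[0, "imaging"]


def test_agrees_with_bruteforce_oracle_on_random_children(specs, vocab):
    """The composed engine matches naive per-rule re-implementations on a
    generated cohort (decoys exercise every rule boundary)."""
    rates = {c: 0.25 for c in CRITERIA}
    cohort, _ = generate_cohort(
        GeneratorConfig(
            n_children=400,
            seed=99,
            base_rates=rates,
            disorder_rate_multipliers={c: 1.0 for c in CRITERIA},
            co_occurrence_pairs=(),
        )
    )
    for bundle in cohort.bundles():
        got = {cid: r.met for cid, r in evaluate_all(bundle, specs, vocab).results.items()}
        expected = oracle.all_rules(bundle, vocab)
        assert got == expected, bundle.child.child_id


def test_max_score_by_term_status(specs):
    assert max_score(TermStatus.FULL_TERM, specs) == 25
    assert max_score(TermStatus.PRE_TERM, specs) == 22


def test_first_met_ages_within_window(specs, vocab):
    cohort, _ = generate_cohort(GeneratorConfig(n_children=300, seed=5))
    prof = evaluate_cohort(cohort, specs, vocab)
    for c in CRITERIA:
        ages = prof.loc[prof[c], f"first_met_{c}"]
        assert ages.notna().all()
        assert ((ages >= 0) & (ages <= 1095)).all()
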