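"""Eligibility, index-visit selection, timepoint inference, and the
longitudinal invariants (backward consistency, denominator monotonicity,
parameter recovery)."""

import math
from datetime import date

import pytest

import babyfeed as bf
from babyfeed.cohort import DEFAULT_WINDOWS
from babyfeed.errors import DataIntegrityError


def record(infant_id="i1", ga=40, plurality=1):
    return bf.MaternalBirthRecord(
        infant_id=infant_id,
        maternal_age=30,
        parity=0,
        urban=True,
        immigrant=False,
        income_quintile=3,
        world_region="Canada",
        birth_date=date(2010, 6, 1),
        birthweight_g=3400,
        gestational_age_wk=ga,
        infant_sex="F",
        plurality=plurality,
    )


def obs(age, status="EBF", infant_id="i1", tense="current", duration=None):
    return bf.FeedingObservation(
        infant_id=infant_id,
        age_days=age,
        status=status,
        tense=tense,
        historical_duration=duration,
    )


# ------------------------------------------------------------- eligibility


def test_first_visit_at_200_days_excluded():
    cohort = bf.build_cohort([record()], [obs(200)])
    assert cohort.records == []
    assert cohort.exclusions == [("i1", "no_visit_before_190d")]


def test_preterm_excluded():
    cohort = bf.build_cohort([record(ga=36)], [obs(60)])
    assert cohort.exclusions == [("i1", "preterm")]


def test_multiple_birth_excluded():
    cohort = bf.build_cohort([record(plurality=2)], [obs(60)])
    assert cohort.exclusions == [("i1", "multiple_birth")]


def test_visit_beyond_750_days_dropped_infant_retained():
    cohort = bf.build_cohort([record()], [obs(60), obs(800)])
    assert len(cohort.records) == 1
    assert [o.age_days for o in cohort.observations["i1"]] == [60]


def test_observation_without_registry_record_is_integrity_error():
    with pytest.raises(DataIntegrityError):
        bf.build_cohort([record()], [obs(60, infant_id="ghost")])


# ---------------------------------------------------------- index selection


@pytest.mark.parametrize(
    "ages,target,expected",
    [
        ([58, 63, 130], 60, 63),
        ([58], 60, None),
        ([60, 185], 60, 60),
        ([], 122, None),
        ([182], 182, 182),
    ],
)
def test_select_index_visit(ages, target, expected):
    chosen = bf.select_index_visit([obs(a) for a in ages], target)
    assert (chosen.age_days if chosen else None) == expected


# ------------------------------------------------------ timepoint inference


def test_future_current_ebf_infers_earlier_targets():
    observations = [obs(60, "EBF"), obs(185, "EBF")]
    for target in (122, 182):
        st = bf.infer_status_at_timepoint(observations, target)
        assert st.status == "EBF"
        assert st.in_denominator


def test_distant_mixed_visit_determines_only_its_own_target():
    observations = [obs(185, "MIXED")]
    assert bf.infer_status_at_timepoint(observations, 182).status == "NOT_EBF"
    st60 = bf.infer_status_at_timepoint(observations, 60)
    assert st60.status == "UNDETERMINED"
    assert st60.in_denominator  # has a qualifying visit, status unresolvable
    assert st60.evidence == "none"


def test_historical_duration_splits_targets():
    # single visit at 200 d stating exclusive breastfeeding lasted 152 d
    observations = [
        obs(200, "NONE_DOCUMENTED"),
        obs(200, "EBF", tense="historical", duration=152),
    ]
    assert bf.infer_status_at_timepoint(observations, 60).status == "EBF"
    assert bf.infer_status_at_timepoint(observations, 122).status == "EBF"
    assert bf.infer_status_at_timepoint(observations, 182).status == "NOT_EBF"


def test_no_qualifying_visit_is_out_of_denominator():
    st = bf.infer_status_at_timepoint([obs(58)], 60)
    assert not st.in_denominator
    assert st.status == "UNDETERMINED"
    assert st.evidence == "none"


def test_evidence_labels():
    within = bf.infer_status_at_timepoint([obs(62, "EBF")], 60)
    assert within.evidence == "index_visit"
    beyond = bf.infer_status_at_timepoint([obs(180, "EBF")], 60)
    assert beyond.evidence == "future_current_ebf"
    hist = bf.infer_status_at_timepoint(
        [obs(200, "FORMULA"), obs(200, "EBF", tense="historical", duration=130)], 60
    )
    assert hist.status == "EBF"
    assert hist.evidence == "future_historical_ebf"


def test_default_windows_cover_gap_to_next_target():
    assert DEFAULT_WINDOWS == {60: 62, 122: 60, 182: 568}


# ----------------------------------------------------------- table & rates


def test_timepoint_table_three_rows_per_infant(study_run):
    assert len(study_run.statuses) == 3 * len(study_run.cohort.records)


def test_backward_consistency_ebf_propagates_to_earlier_targets(study_run):
    by_infant = {}
    for s in study_run.statuses:
        by_infant.setdefault(s.infant_id, {})[s.target_age] = s.status
    for statuses in by_infant.values():
        if statuses[182] == "EBF":
            assert statuses[60] == "EBF" and statuses[122] == "EBF"
        if statuses[122] == "EBF":
            assert statuses[60] == "EBF"


def test_denominator_monotone_in_target_age(study_run):
    counts = {
        t: sum(
            1
            for s in study_run.statuses
            if s.target_age == t and s.in_denominator
        )
        for t in (60, 122, 182)
    }
    assert counts[60] >= counts[122] >= counts[182]


def test_closure_corpus_has_zero_undetermined_and_exact_truth(closure_run):
    for s in closure_run.statuses:
        assert s.status != "UNDETERMINED"
        truth = closure_run.trajectories[s.infant_id].status_at(s.target_age)
        assert s.status == ("EBF" if truth == "EBF" else "NOT_EBF")


def test_pipeline_recovers_generator_survival_targets(study_run):
    """Estimated EBF rates at 60/122/182 d lie within 3 binomial SEs of the
    generator's survival targets on the default synthetic cohort."""
    rates = bf.ebf_rates(study_run.statuses)
    for t, tgt in zip((60, 122, 182), study_run.cfg.ebf_survival_targets):
        _, den, pct = rates[t]
        tol = 3 * math.sqrt(tgt * (1 - tgt) / den)
        assert abs(pct / 100 - tgt) < tol


# -------------------------------------------------------- duration & subset


@pytest.mark.parametrize(
    "observations,expected",
    [
        ([obs(60, "EBF"), obs(122, "EBF"), obs(182, "MIXED")], 122),
        ([obs(60, "FORMULA")], None),
        ([obs(5, "EBF")], 5),
    ],
)
def test_ebf_duration(observations, expected):
    assert bf.ebf_duration(observations) == expected


def test_complete_case_membership():
    registry = [record("a"), record("b")]
    cohort = bf.build_cohort(
        registry,
        # infant a: documented at all three targets; infant b: no 4-month visit
        [bf.FeedingObservation("a", a, s) for a, s in
         [(62, "EBF"), (125, "EBF"), (183, "MIXED")]]
        + [bf.FeedingObservation("b", a, s) for a, s in
           [(62, "EBF"), (183, "MIXED")]],
    )
    statuses = bf.timepoint_table(cohort)
    cc = bf.complete_case_subset(cohort, statuses)
    assert cc.infant_ids == ["a"]
    assert len(cc.records) <= len(cohort.records)


def test_complete_case_rates_close_to_full_cohort(study_run):
    full = bf.ebf_rates(study_run.statuses)
    cc = bf.complete_case_subset(study_run.cohort, study_run.statuses)
    cc_rates = bf.ebf_rates(bf.timepoint_table(cc))
    for t in (60, 122, 182):
        p = full[t][2] / 100
        _, den, pct = cc_rates[t]
        tol = 3 * math.sqrt(p * (1 - p) / den)
        assert abs(pct / 100 - p) < tol
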