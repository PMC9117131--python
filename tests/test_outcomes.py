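"""Outcome definitions: lapse allowance, validation hierarchy, reduction."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pregquit.outcomes import (classify_cohort, classify_prolonged,
                               classify_record, classify_reduction,
                               nonallocated_use_flag, validate_abstinence)
from pregquit.records import (Arm, AssayPanel, Education, EopReport,
                              ParticipantBaseline, ParticipantRecord,
                              ProductUsePattern, WeeklyStatus)
from pregquit.simulate import SimulationConfig, generate_cohort


def make_record(eop=EopReport.ABSTINENT_7DAY, lapse_count=0,
                weekly=(WeeklyStatus.ABSTINENT,) * 4, cotinine=None,
                anabasine=None, co=None, saliva=None, product_user=False,
                baseline_cigs=10, eop_cigs=None):
    if saliva is None:
        saliva = cotinine is not None or anabasine is not None
    return ParticipantRecord(
        id="x", arm=Arm.ECIG,
        baseline=ParticipantBaseline(
            age_years=27.0, gestation_weeks_at_entry=16.0,
            cigarettes_per_day=baseline_cigs, ftcd_score=4,
            cotinine_ng_ml=115.0, lives_with_smoker=True,
            education=Education.FURTHER, employed=True),
        tqd_set=True, contacted_ever=True, started_allocated_product=True,
        weekly_self_report=weekly, lapse_count=lapse_count,
        eop_self_report=eop, eop_cigarettes_per_day=eop_cigs,
        product_use=ProductUsePattern(),
        assays=AssayPanel(saliva_returned=saliva, cotinine_ng_ml=cotinine,
                          anabasine_ng_ml=anabasine, co_ppm=co,
                          nicotine_product_user_at_validation=product_user),
    )


class TestProlongedAbstinence:
    def test_five_lapses_allowed_six_disqualify(self):
        assert classify_prolonged(make_record(lapse_count=5))
        assert not classify_prolonged(make_record(lapse_count=6))

    def test_missing_eop_report_counts_as_non_abstinent(self):
        assert not classify_prolonged(make_record(eop=EopReport.MISSING))

    def test_smoking_after_grace_period_disqualifies(self):
        weekly = (WeeklyStatus.SMOKING, WeeklyStatus.ABSTINENT,
                  WeeklyStatus.ABSTINENT, WeeklyStatus.ABSTINENT)
        assert classify_prolonged(make_record(weekly=weekly))
        weekly = (WeeklyStatus.ABSTINENT, WeeklyStatus.ABSTINENT,
                  WeeklyStatus.SMOKING, WeeklyStatus.ABSTINENT)
        assert not classify_prolonged(make_record(weekly=weekly))


class TestValidationHierarchy:
    def test_cotinine_boundary_is_strict(self):
        assert validate_abstinence(make_record(cotinine=9.9))
        assert not validate_abstinence(make_record(cotinine=10.0))

    def test_anabasine_boundary_for_product_users(self):
        assert validate_abstinence(make_record(anabasine=0.9, product_user=True))
        assert not validate_abstinence(make_record(anabasine=1.0, product_user=True))

    def test_co_overrides_anabasine_on_discrepancy(self):
        # anabasine says smoking, CO says abstinent: CO verdict wins
        assert validate_abstinence(
            make_record(anabasine=2.0, co=5.0, product_user=True))
        # and the other way round
        assert not validate_abstinence(
            make_record(anabasine=0.5, co=9.0, product_user=True))

    def test_non_user_judged_on_cotinine_even_with_co(self):
        assert not validate_abstinence(make_record(cotinine=50.0, co=3.0))

    def test_no_sample_no_co_means_non_abstinent(self):
        assert not validate_abstinence(make_record(saliva=False))

    def test_relapsed_after_delivery_is_self_but_not_validated_abstinent(self):
        rec = make_record(eop=EopReport.ABSTINENT_AT_DELIVERY_RELAPSED_SINCE,
                          cotinine=1.0)
        calls = classify_record(rec)
        assert calls.self_prolonged_eop and calls.self_pp_eop
        assert not calls.validated_prolonged_eop
        assert not calls.validated_pp_eop

    def test_negative_assay_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            validate_abstinence(make_record(cotinine=-1.0))

    def test_validation_never_creates_abstinence(self):
        rec = make_record(eop=EopReport.SMOKING, cotinine=1.0, eop_cigs=10)
        assert not validate_abstinence(rec)


class TestReduction:
    def test_half_of_baseline_is_inclusive(self):
        rec = make_record(eop=EopReport.SMOKING, eop_cigs=5, baseline_cigs=10)
        assert classify_reduction(rec) == (True, False)
        rec = make_record(eop=EopReport.SMOKING, eop_cigs=6, baseline_cigs=10)
        assert classify_reduction(rec) == (False, False)

    def test_abstinent_participants_excluded_from_denominator(self):
        assert classify_reduction(make_record()) == (None, None)

    def test_validated_reduction_uses_assay_hierarchy(self):
        rec = make_record(eop=EopReport.SMOKING, eop_cigs=4, baseline_cigs=10,
                          co=5.0, product_user=True)
        assert classify_reduction(rec) == (True, True)


@pytest.mark.parametrize("flag", [
    "nonallocated_5plus_consecutive_days_first4wks",
    "nonallocated_current_eop",
    "nonallocated_regular_1wk",
    "nonallocated_occasional_3wks",
])
def test_any_single_disjunct_sets_the_nonallocated_flag(flag):
    assert nonallocated_use_flag(ProductUsePattern(**{flag: True}))


def test_all_flags_false_means_no_nonallocated_use():
    assert not nonallocated_use_flag(ProductUsePattern())


assay_values = st.one_of(st.none(),
                         st.floats(min_value=0.0, max_value=50.0,
                                   allow_nan=False, allow_infinity=False))


@settings(max_examples=150, deadline=None)
@given(cot=assay_values, anab=assay_values, co=assay_values,
       user=st.booleans(), bump=st.floats(min_value=0.0, max_value=100.0,
                                          allow_nan=False))
def test_raising_an_assay_value_never_rescues_a_failed_validation(
        cot, anab, co, user, bump):
    """Monotonicity: pushing any assay upward never flips validation to pass."""
    base = make_record(cotinine=cot, anabasine=anab, co=co, product_user=user,
                       saliva=cot is not None or anab is not None)
    before = validate_abstinence(base)
    for field in ("cotinine_ng_ml", "anabasine_ng_ml", "co_ppm"):
        v = getattr(base.assays, field)
        if v is None:
            continue
        setattr(base.assays, field, v + bump)
        after = validate_abstinence(base)
        setattr(base.assays, field, v)
        if not before:
            assert not after


def test_validated_implies_self_reported_over_large_cohort():
    """Checked over >=10^4 generated records with stressed misreporting."""
    cfg = SimulationConfig(n_per_arm=(5000, 5000), misreport_prob=0.2, seed=6)
    calls = classify_cohort(generate_cohort(cfg))
    assert len(calls) == 10000
    assert (calls["validated_prolonged_eop"] <= calls["self_prolonged_eop"]).all()
    assert (calls["validated_pp_eop"] <= calls["self_pp_eop"]).all()
    switchers = calls["abstinent_switcher"]
    any_self = (calls["self_prolonged_eop"] | calls["self_pp_eop"]
                | calls["self_pp_4wk"])
    assert (any_self[switchers]).all()


def test_classification_is_order_independent(trial_cohort):
    forward = classify_cohort(trial_cohort)
    backward = classify_cohort(list(reversed(trial_cohort)))
    merged = backward.set_index("id").loc[forward["id"]].reset_index()
    assert merged.equals(forward[merged.columns])
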