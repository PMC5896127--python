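"""Trial-adequacy gates, adjudication verdicts and pseudo-resistance screening."""

from datetime import date

import pytest

from msm_staging import (
    AdequacyConfig,
    ECTCourse,
    Instrument,
    Outcome,
    PseudoResistanceFlag,
    SeverityAssessment,
    UnknownDrugError,
    Verdict,
    adjudicate_episode,
    adjudicate_trial,
    count_failed_antidepressants,
    ect_counts,
    is_adequate_trial,
    pseudo_resistance_flags,
)

from conftest import make_episode, make_trial


class TestIsAdequateTrial:
    def test_all_gates_pass_exactly_at_thresholds(self):
        trial = make_trial(drug="fluoxetine", dose=20, weeks=6)
        assert is_adequate_trial(trial) == (True, [])

    def test_five_weeks_fails_default_six_week_minimum(self):
        trial = make_trial(weeks=5)
        ok, reasons = is_adequate_trial(trial)
        assert not ok and reasons == [PseudoResistanceFlag.INADEQUATE_DURATION]

    def test_research_mode_lowers_minimum_to_four_weeks(self):
        trial = make_trial(weeks=5)
        cfg = AdequacyConfig(research_mode_four_weeks=True)
        assert cfg.min_duration_weeks == 4
        assert is_adequate_trial(trial, cfg) == (True, [])

    def test_reasons_enumerate_every_failed_gate(self):
        trial = make_trial(dose=5, weeks=2, adherent=False, tolerated=False)
        ok, reasons = is_adequate_trial(trial)
        assert not ok
        assert set(reasons) == {
            PseudoResistanceFlag.INADEQUATE_DOSE,
            PseudoResistanceFlag.INADEQUATE_DURATION,
            PseudoResistanceFlag.NON_ADHERENCE,
            PseudoResistanceFlag.INTOLERANCE,
        }

    def test_unknown_drug_fails_loudly(self):
        with pytest.raises(UnknownDrugError, match="dose-table entry"):
            is_adequate_trial(make_trial(drug="novadrug"))

    def test_research_mode_never_shrinks_the_adequate_set(self):
        # any trial adequate at 6 weeks is adequate at 4 weeks
        six = AdequacyConfig()
        four = AdequacyConfig(research_mode_four_weeks=True)
        for weeks in (3, 4, 5, 6, 7, 10):
            trial = make_trial(weeks=weeks)
            if is_adequate_trial(trial, six)[0]:
                assert is_adequate_trial(trial, four)[0]


class TestAdjudicateTrial:
    def test_response_short_of_remission_counts_as_failure(self):
        trial = make_trial(outcome=Outcome.RESPONDED_NOT_REMITTED)
        verdict, _ = adjudicate_trial(trial)
        assert verdict is Verdict.COUNTED_FAILURE

    def test_end_of_trial_hrsd_of_seven_is_remission(self):
        trial = make_trial(
            outcome=Outcome.UNKNOWN,
            instrument_outcome=SeverityAssessment(instrument=Instrument.HRSD17, score=7),
        )
        assert adjudicate_trial(trial)[0] is Verdict.REMITTED

    def test_instrument_score_overrides_categorical_outcome(self):
        trial = make_trial(
            outcome=Outcome.NO_RESPONSE,
            instrument_outcome=SeverityAssessment(instrument=Instrument.QIDS_C16, score=4),
        )
        assert adjudicate_trial(trial)[0] is Verdict.REMITTED

    def test_non_tolerated_trial_is_inadequate(self):
        trial = make_trial(tolerated=False, outcome=Outcome.NO_RESPONSE)
        verdict, reason = adjudicate_trial(trial)
        assert verdict is Verdict.INADEQUATE
        assert "intolerance" in reason

    def test_unknown_outcome_without_score_is_unratable(self):
        trial = make_trial(outcome=Outcome.UNKNOWN)
        verdict, reason = adjudicate_trial(trial)
        assert verdict is Verdict.INADEQUATE
        assert "unratable" in reason

    def test_sustained_rule_needs_confirmation_sixty_days_later(self):
        cfg = AdequacyConfig(remission_duration_rule="sustained_two_months")
        first = SeverityAssessment(
            instrument=Instrument.HRSD17, score=6, assessment_date=date(2020, 1, 1)
        )
        confirmed = SeverityAssessment(
            instrument=Instrument.HRSD17, score=5, assessment_date=date(2020, 3, 15)
        )
        relapsed = SeverityAssessment(
            instrument=Instrument.HRSD17, score=20, assessment_date=date(2020, 3, 15)
        )
        t_ok = make_trial(instrument_outcome=first, confirmatory_outcome=confirmed)
        t_relapse = make_trial(instrument_outcome=first, confirmatory_outcome=relapsed)
        assert adjudicate_trial(t_ok, cfg)[0] is Verdict.REMITTED
        assert adjudicate_trial(t_relapse, cfg)[0] is Verdict.COUNTED_FAILURE

    def test_sustained_rule_degrades_with_single_measure(self, caplog):
        cfg = AdequacyConfig(remission_duration_rule="sustained_two_months")
        trial = make_trial(
            instrument_outcome=SeverityAssessment(
                instrument=Instrument.HRSD17, score=6, assessment_date=date(2020, 1, 1)
            )
        )
        with caplog.at_level("WARNING"):
            assert adjudicate_trial(trial, cfg)[0] is Verdict.REMITTED
        assert any("single_measure" in r.message for r in caplog.records)


class TestCountingAndFlags:
    def test_zero_trials_count_zero(self):
        assert count_failed_antidepressants(make_episode()) == 0

    def test_mixed_verdicts_count_only_failures(self):
        trials = (
            [make_trial() for _ in range(4)]
            + [make_trial(weeks=2)]  # inadequate
            + [make_trial(outcome=Outcome.REMITTED)]
        )
        rec = make_episode(trials=trials)
        assert count_failed_antidepressants(rec) == 4

    def test_two_courses_of_same_drug_count_separately(self):
        rec = make_episode(trials=[make_trial("sertraline", dose=50),
                                   make_trial("sertraline", dose=100)])
        assert count_failed_antidepressants(rec) == 2

    def test_verdicts_partition_the_trial_list(self):
        trials = [make_trial(), make_trial(weeks=2),
                  make_trial(outcome=Outcome.REMITTED), make_trial(adherent=False)]
        rec = make_episode(trials=trials)
        adjudications = adjudicate_episode(rec)
        assert [a.trial_index for a in adjudications] == [0, 1, 2, 3]
        assert all(a.verdict in Verdict for a in adjudications)

    def test_appending_a_failure_is_monotone(self):
        trials = [make_trial(weeks=2)]
        rec = make_episode(trials=trials)
        before = count_failed_antidepressants(rec)
        rec2 = make_episode(trials=trials + [make_trial()])
        assert count_failed_antidepressants(rec2) == before + 1

    def test_flags_empty_when_all_trials_adequate(self):
        rec = make_episode(trials=[make_trial(), make_trial("venlafaxine", dose=150)])
        assert pseudo_resistance_flags(rec) == []

    def test_single_non_adherent_trial_flags_non_adherence(self):
        rec = make_episode(trials=[make_trial(adherent=False)])
        assert pseudo_resistance_flags(rec) == [PseudoResistanceFlag.NON_ADHERENCE]

    def test_flags_union_across_trials(self):
        rec = make_episode(trials=[make_trial(dose=5), make_trial(weeks=2)])
        assert pseudo_resistance_flags(rec) == [
            PseudoResistanceFlag.INADEQUATE_DOSE,
            PseudoResistanceFlag.INADEQUATE_DURATION,
        ]


class TestECT:
    def test_absent_course_does_not_count(self):
        assert ect_counts(None) is False

    @pytest.mark.parametrize("n,expected", [(8, True), (3, False), (12, True), (7, False)])
    def test_eight_session_threshold(self, n, expected):
        course = ECTCourse(n_sessions=n, outcome=Outcome.NO_RESPONSE)
        assert ect_counts(course) is expected

    def test_qualifying_course_counts_regardless_of_outcome(self):
        for outcome in Outcome:
            assert ect_counts(ECTCourse(n_sessions=8, outcome=outcome)) is True
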