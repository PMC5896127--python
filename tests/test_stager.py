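"""Dimension combination: levels, totals, bands, and the full staging pipeline."""

import itertools
import re

import pytest

from msm_staging import (
    Band,
    DimensionScores,
    MSMResult,
    NotTreatmentResistant,
    NotTreatmentResistantError,
    Outcome,
    StagingConfig,
    antidepressant_level,
    band,
    lattice_fixtures,
    stage,
    total_score,
    treatment_dimension_score,
)
from msm_staging.model import StagingRefusedError

from conftest import make_episode, make_trial


def level_oracle(n):
    """Independent lookup of the failure-count level from the published bands."""
    for lo, hi, score in [(1, 2, 1), (3, 4, 2), (5, 6, 3), (7, 10, 4)]:
        if lo <= n <= hi:
            return score
    return 5


class TestAntidepressantLevel:
    @pytest.mark.parametrize("n", [1, 2, 3, 4, 5, 6, 7, 10, 11, 15, 20])
    def test_matches_published_level_bands(self, n):
        assert antidepressant_level(n) == level_oracle(n)

    def test_zero_failures_is_not_treatment_resistant(self):
        with pytest.raises(NotTreatmentResistantError):
            antidepressant_level(0)


class TestTreatmentDimension:
    def test_maximum_is_seven(self):
        assert treatment_dimension_score(11, True, True) == 7

    def test_floor_is_one(self):
        assert treatment_dimension_score(1, False, False) == 1

    def test_indicators_add_one_each(self):
        assert treatment_dimension_score(3, True, False) == 3
        assert treatment_dimension_score(3, False, True) == 3
        assert treatment_dimension_score(3, True, True) == 4


def dims(t, s, d, n=1, aug=False, ect=False):
    return DimensionScores(
        treatment_failure_score=t, severity_score=s, duration_score=d,
        n_failed_antidepressants=n, augmentation_used=aug, ect_used=ect,
    )


class TestTotalAndBand:
    @pytest.mark.parametrize("t,s,d,expected", [(7, 5, 3, 15), (1, 1, 1, 3), (4, 3, 2, 9)])
    def test_total_is_the_sum(self, t, s, d, expected):
        assert total_score(dims(t, s, d)) == expected

    def test_out_of_range_components_rejected(self):
        with pytest.raises(ValueError):
            total_score(dims(8, 1, 1))
        with pytest.raises(ValueError):
            total_score(dims(1, 0, 1))

    @pytest.mark.parametrize(
        "total,expected",
        [(3, Band.MILD), (6, Band.MILD), (7, Band.MODERATE), (10, Band.MODERATE),
         (11, Band.SEVERE), (15, Band.SEVERE)],
    )
    def test_band_boundaries(self, total, expected):
        assert band(total) == expected

    def test_band_out_of_range(self):
        for bad in (2, 16, 0):
            with pytest.raises(ValueError):
                band(bad)

    def test_exhaustive_combination_oracle(self):
        """Over the whole input lattice the attainable totals are exactly 3..15,
        totals match independent arithmetic, and bands match at every point."""
        totals = set()
        for n, aug, ect, sev, dur in itertools.product(
            range(1, 21), (False, True), (False, True), range(1, 6), range(1, 4)
        ):
            t = treatment_dimension_score(n, aug, ect)
            total = total_score(dims(t, sev, dur, n=n, aug=aug, ect=ect))
            assert total == level_oracle(n) + aug + ect + sev + dur
            expected_band = (
                Band.MILD if total <= 6 else Band.MODERATE if total <= 10 else Band.SEVERE
            )
            assert band(total) == expected_band
            totals.add(total)
        assert totals == set(range(3, 16))

    def test_monotonicity_in_every_dimension(self):
        base = (3, False, False, 2, 2)
        n, aug, ect, sev, dur = base

        def total_of(n, aug, ect, sev, dur):
            return total_score(
                dims(treatment_dimension_score(n, aug, ect), sev, dur, n=n, aug=aug, ect=ect)
            )

        t0 = total_of(*base)
        assert total_of(n + 4, aug, ect, sev, dur) >= t0
        assert total_of(n, True, ect, sev, dur) >= t0
        assert total_of(n, aug, True, sev, dur) >= t0
        assert total_of(n, aug, ect, sev + 1, dur) >= t0
        assert total_of(n, aug, ect, sev, dur + 1) >= t0


class TestStagePipeline:
    def test_worked_composite_example(self):
        """Four failures + augmentation (no ECT), HRSD17 22 non-psychotic,
        18-month episode → (2+1) + 3 + 2 = 8, moderate."""
        from datetime import date

        from msm_staging import AugmentationRecord

        rec = make_episode(
            trials=[make_trial() for _ in range(4)],
            augmentations=(AugmentationRecord(agent_name="lithium", used=True),),
            onset=date(2018, 12, 1),
            assessment=date(2020, 6, 1),  # ~17.9 months
            baseline_score=22,
        )
        res = stage(rec)
        assert isinstance(res, MSMResult)
        assert res.dimensions.treatment_failure_score == 3
        assert res.dimensions.severity_score == 3
        assert res.dimensions.duration_score == 2
        assert res.total == 8
        assert res.band is Band.MODERATE

    def test_lattice_equivalence_with_per_dimension_arithmetic(self):
        """Stage all 300 lattice cells; totals equal the independent sum
        decoded from each cell's label."""
        fixtures = lattice_fixtures()
        assert len(fixtures) == 300
        pat = re.compile(r"lattice-L(\d)-A(\d)-E(\d)-S(\d)-D(\d)")
        seen_totals = set()
        for rec in fixtures:
            level, aug, ect, sev, dur = map(int, pat.match(rec.patient_id).groups())
            res = stage(rec)
            assert isinstance(res, MSMResult)
            assert res.total == level + aug + ect + sev + dur
            assert res.total == (
                res.dimensions.treatment_failure_score
                + res.dimensions.severity_score
                + res.dimensions.duration_score
            )
            assert res.pseudo_resistance_flags == ()
            seen_totals.add(res.total)
        assert seen_totals == set(range(3, 16))

    def test_minimal_qualifying_record_scores_three(self):
        rec = make_episode(trials=[make_trial()], baseline_score=10)
        res = stage(rec)
        assert res.total == 3 and res.band is Band.MILD

    def test_zero_counted_failures_yields_status_not_score(self):
        rec = make_episode(trials=[make_trial(weeks=2)])  # only an inadequate trial
        res = stage(rec)
        assert isinstance(res, NotTreatmentResistant)
        assert res.status == "not_treatment_resistant"
        assert res.pseudo_resistance_flags  # the inadequate trial is flagged

    def test_remitted_baseline_refused(self):
        rec = make_episode(trials=[make_trial()], baseline_score=5)
        with pytest.raises(StagingRefusedError):
            stage(rec)

    def test_invalid_record_rejected(self):
        from datetime import date

        rec = make_episode(trials=[make_trial()], onset=date(2021, 1, 1),
                           assessment=date(2020, 1, 1))
        with pytest.raises(ValueError, match="validation"):
            stage(rec)

    def test_adjudication_trail_covers_every_trial(self):
        rec = make_episode(
            trials=[make_trial(), make_trial(weeks=2),
                    make_trial(outcome=Outcome.REMITTED)]
        )
        res = stage(rec)
        assert [a.trial_index for a in res.trial_adjudications] == [0, 1, 2]

    def test_research_mode_can_only_raise_failure_count(self):
        rec = make_episode(trials=[make_trial(weeks=5) for _ in range(3)]
                           + [make_trial()])
        strict = stage(rec)
        relaxed = stage(rec, StagingConfig(
            adequacy=__import__("msm_staging").AdequacyConfig(research_mode_four_weeks=True)
        ))
        assert relaxed.dimensions.n_failed_antidepressants >= strict.dimensions.n_failed_antidepressants
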