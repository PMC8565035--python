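"""Date-completion strategies and the death-date algorithm."""

import datetime as dt
import itertools

import pytest
from hypothesis import given, settings, strategies as st

from omopmap.config import MappingConfig
from omopmap.dates import PartialDate
from omopmap.imputation import (
    DeathCandidate,
    ReferenceTimeline,
    UnresolvableDateError,
    impute_by_timepoint,
    impute_death_date,
    impute_drug_start,
    impute_generic,
    impute_lab_date,
)


class TestGenericCompletion:
    def test_missing_day_takes_first_of_month(self):
        assert impute_generic(PartialDate(2015, 6)) == dt.date(2015, 6, 1)

    def test_missing_day_and_month_takes_january_first(self):
        assert impute_generic(PartialDate(2015)) == dt.date(2015, 1, 1)

    def test_complete_date_is_identity(self):
        assert impute_generic(PartialDate(2015, 6, 11)) == dt.date(2015, 6, 11)


class TestDrugStart:
    def test_overlap_with_previous_interval_shifts_one_day_after(self):
        result = impute_drug_start(PartialDate(2015, 6), dt.date(2015, 6, 10))
        assert result.imputed == dt.date(2015, 6, 11)
        assert result.strategy == "prev_interval"

    def test_no_previous_interval_uses_first_day(self):
        result = impute_drug_start(PartialDate(2015, 6), None)
        assert result.imputed == dt.date(2015, 6, 1)

    def test_candidate_already_after_previous_interval_is_kept(self):
        result = impute_drug_start(PartialDate(2015, 6), dt.date(2015, 5, 20))
        assert result.imputed == dt.date(2015, 6, 1)
        assert result.strategy != "prev_interval"

    def test_contradicting_shift_is_flagged_and_candidate_kept(self):
        # previous interval ends in July; a June-recorded start cannot be
        # shifted into July without contradicting the recorded month
        result = impute_drug_start(PartialDate(2015, 6), dt.date(2015, 7, 15))
        assert result.imputed == dt.date(2015, 6, 1)
        assert "conflict" in result.notes

    def test_complete_date_untouched(self):
        result = impute_drug_start(PartialDate(2015, 6, 11), dt.date(2015, 6, 20))
        assert result.imputed == dt.date(2015, 6, 11)
        assert result.strategy is None


class TestLabDate:
    def test_drug_initiation_timepoint_with_agreeing_parts(self):
        timeline = ReferenceTimeline(
            "P1", drug_initiation=PartialDate(2015, 6, 15)
        )
        result = impute_lab_date(PartialDate(2015, 6), "DRUG INITIATION", timeline)
        assert result.imputed == dt.date(2015, 6, 15)

    def test_last_available_takes_earlier_of_drug_end_and_study_end(self):
        timeline = ReferenceTimeline(
            "P1",
            drug_end=PartialDate(2016, 2, 10),
            study_end=dt.date(2016, 3, 1),
        )
        result = impute_lab_date(None, "LAST AVAILABLE", timeline)
        assert result.imputed == dt.date(2016, 2, 10)

    def test_complete_date_is_identity(self):
        timeline = ReferenceTimeline("P1")
        result = impute_lab_date(PartialDate(2016, 3, 4), "ANY", timeline)
        assert result.imputed == dt.date(2016, 3, 4)
        assert result.strategy is None

    def test_year_bearing_date_falls_through_to_generic(self):
        timeline = ReferenceTimeline("P1")
        result = impute_lab_date(PartialDate(2016, 3), "", timeline)
        assert result.imputed == dt.date(2016, 3, 1)

    def test_no_year_and_no_anchor_is_unresolvable(self):
        with pytest.raises(UnresolvableDateError):
            impute_lab_date(None, "", ReferenceTimeline("P1"))


class TestDeathDate:
    def test_fewest_missing_parts_wins_over_hierarchy(self):
        result = impute_death_date(
            [
                DeathCandidate("crf_death_details", PartialDate(2016, 3)),
                DeathCandidate("crf_fatal_ae", PartialDate(2016, 3, 15)),
            ],
            dt.date(2016, 1, 1),
        )
        assert result.imputed == dt.date(2016, 3, 15)

    def test_hierarchy_breaks_ties_then_floor_applies(self):
        result = impute_death_date(
            [
                DeathCandidate("crf_death_details", PartialDate(2016, 3)),
                DeathCandidate("safety_db", PartialDate(2016, 4)),
            ],
            dt.date(2016, 3, 20),
        )
        # CRF death details selected, completed to 2016-03-01, floored
        assert result.imputed == dt.date(2016, 3, 20)

    def test_no_candidates_fall_back_to_last_available_info(self):
        result = impute_death_date([], dt.date(2016, 5, 2))
        assert result.imputed == dt.date(2016, 5, 2)

    def test_complete_candidate_is_not_floored(self):
        result = impute_death_date(
            [DeathCandidate("safety_db", PartialDate(2016, 3, 5))],
            dt.date(2016, 3, 20),
        )
        assert result.imputed == dt.date(2016, 3, 5)

    def test_nothing_to_go_on_is_fatal(self):
        with pytest.raises(UnresolvableDateError):
            impute_death_date([], None)

    def test_result_invariant_under_candidate_permutation(self):
        candidates = [
            DeathCandidate("crf_death_details", PartialDate(2016, 3)),
            DeathCandidate("crf_fatal_ae", PartialDate(2016)),
            DeathCandidate("safety_db", PartialDate(2016, 3, 10)),
        ]
        results = {
            impute_death_date(list(p), dt.date(2016, 1, 1)).imputed
            for p in itertools.permutations(candidates)
        }
        assert len(results) == 1

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["crf_death_details", "crf_fatal_ae", "safety_db"]),
                st.integers(2010, 2020),
                st.one_of(st.none(), st.integers(1, 12)),
            ),
            min_size=1, max_size=5,
        )
    )
    @settings(max_examples=100, derandomize=True)
    def test_partial_candidate_never_precedes_last_available_info(self, raw):
        candidates = [
            DeathCandidate(src, PartialDate(y, m)) for src, y, m in raw
        ]
        floor = dt.date(2015, 6, 15)
        result = impute_death_date(candidates, floor)
        # every candidate here is partial, so the floor always applies
        assert result.imputed >= floor


class TestTimepointTable:
    def test_configured_labels_resolve_to_anchors(self):
        config = MappingConfig()
        timeline = ReferenceTimeline(
            "P1",
            last_available_info=dt.date(2016, 5, 2),
            enrollment=dt.date(2015, 1, 10),
        )
        assert impute_by_timepoint(
            "BEFORE DISCONTINUATION", timeline, config
        ) == dt.date(2016, 5, 2)
        assert impute_by_timepoint(
            "WITHIN 3 MONTHS OF BASELINE", timeline, config
        ) == dt.date(2015, 1, 10)

    def test_unknown_label_returns_none(self):
        config = MappingConfig()
        assert impute_by_timepoint(
            "UNKNOWN LABEL", ReferenceTimeline("P1"), config
        ) is None

    def test_offset_days_shift_the_anchor(self):
        from omopmap.config import TimepointRule

        config = MappingConfig(
            timepoint_rules=[TimepointRule("WEEK 2", "enrollment", 14)]
        )
        timeline = ReferenceTimeline("P1", enrollment=dt.date(2015, 1, 10))
        assert impute_by_timepoint("WEEK 2", timeline, config) == dt.date(2015, 1, 24)
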