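"""Quality-assessment arithmetic and source-vs-CDM consistency."""

import copy

import pytest
from hypothesis import given, settings, strategies as st

from omopmap.etl import run_mapping
from omopmap.qa import (
    QACounts,
    aggregate_counts,
    compute_qa_report,
    consistency_check,
    exclusion_accounting,
    redundancy_pct,
)


class TestRedundancy:
    @pytest.mark.parametrize(
        "values, concepts, expected",
        [(10659, 3698, 65), (4013, 2704, 33), (449, 337, 25), (100, 100, 0)],
    )
    def test_consolidation_percentages(self, values, concepts, expected):
        assert redundancy_pct(values, concepts) == expected

    def test_zero_source_values_not_applicable(self):
        assert redundancy_pct(0, 0) is None

    @given(st.integers(1, 10_000), st.integers(0, 10_000), st.integers(2, 9))
    @settings(max_examples=100, derandomize=True)
    def test_scale_invariance(self, a, delta, k):
        b = max(0, a - delta)
        assert redundancy_pct(a, b) == redundancy_pct(k * a, k * b)


class TestExclusionAccounting:
    @pytest.mark.parametrize(
        "n_db, n_violators, n_excluded, expected",
        [
            (2722, 46, 2, (2674, 98.2)),
            (3142, 85, 25, (3032, 96.5)),
            (758, 1, 6, (751, 99.1)),
            (10, 0, 0, (10, 100.0)),
        ],
    )
    def test_patient_accounting(self, n_db, n_violators, n_excluded, expected):
        assert exclusion_accounting(n_db, n_violators, n_excluded) == expected

    def test_negative_remainder_is_fatal(self):
        with pytest.raises(ValueError):
            exclusion_accounting(10, 8, 5)


class TestAggregation:
    def test_condition_and_drug_totals(self):
        condition = [
            QACounts("condition", n_unique_source_records=n_src,
                     n_unique_cdm_records=n_cdm)
            for n_src, n_cdm in
            [(128858, 62048), (41960, 41993), (28347, 4616)]
        ]
        total = aggregate_counts(condition)
        assert total.n_unique_source_records == 199165
        assert total.n_unique_cdm_records == 108657
        drug = [
            QACounts("drug", n_unique_source_records=n_src,
                     n_unique_cdm_records=n_cdm)
            for n_src, n_cdm in [(26276, 23368), (16498, 15169), (8838, 7823)]
        ]
        total = aggregate_counts(drug)
        assert total.n_unique_source_records == 51612
        assert total.n_unique_cdm_records == 46360

    def test_mixed_categories_fatal(self):
        with pytest.raises(ValueError, match="mixed"):
            aggregate_counts([QACounts("condition"), QACounts("drug")])

    def test_empty_list_gives_zero_totals(self):
        total = aggregate_counts([])
        assert total.n_unique_source_records == 0


class TestConsistency:
    def test_lossless_demographics_raise_no_flags(self, small_study, store):
        config, study, _ = small_study
        output = run_mapping(study, copy.deepcopy(store), config.mapping_config())
        comparison = consistency_check(study, output)
        assert comparison.flags == []
        assert comparison.age_mean_sdtm == pytest.approx(
            comparison.age_mean_cdm, abs=0.01
        )

    def test_deleted_person_row_is_flagged(self, small_study, store):
        config, study, _ = small_study
        output = run_mapping(study, copy.deepcopy(store), config.mapping_config())
        output.persons.pop()
        comparison = consistency_check(study, output)
        assert any("count mismatch" in f for f in comparison.flags)

    def test_report_percentages_within_bounds(self, small_study, store):
        config, study, _ = small_study
        output = run_mapping(study, copy.deepcopy(store), config.mapping_config())
        report = compute_qa_report(study, output)
        for mapping in (report.mapping_rate_pct,
                        report.mapping_rate_excl_non_events_pct):
            for value in mapping.values():
                if value is not None:
                    assert 0.0 <= value <= 100.0
        for value in report.exclusion.values():
            assert value >= 0
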