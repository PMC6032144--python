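"""Rubric scoring, decision rules, cohort summaries and cohort selection."""

import itertools

import pytest

from discqc import (
    SampleRecord,
    ValidationError,
    classify_dd,
    classify_ivd,
    score_rubric,
    select_microarray_cohort,
    summarize_cohort,
)


def make_record(compartment="AF", donor="d1", sample_id=1, age=50, gender="m",
                **kwargs):
    defaults = dict(
        donor_id=donor, gender=gender, age=age, sample_id=sample_id,
        disc_level="C4/5", mri_grade=3, compartment=compartment,
    )
    defaults.update(kwargs)
    return SampleRecord(**defaults)


class TestScoreRubric:
    @pytest.mark.parametrize(
        "items,rubric,expected",
        [
            ([2, 2, 2, 2, 2, 2], "IVD", (12, False)),
            ([1, 1, 1, 1, 1, 1], "IVD", (6, False)),
            ([2, 1, 1, 1, 1, 0], "IVD", (6, True)),
            ([2, 1, 0], "DD", (3, True)),
            ([1, 1, 1], "DD", (3, False)),
            ([0, 0, 0], "DD", (0, False)),
        ],
    )
    def test_totals_and_flags(self, items, rubric, expected):
        assert score_rubric(items, rubric) == expected

    @pytest.mark.parametrize(
        "items,rubric",
        [
            ([1, 1, 1], "IVD"),  # wrong count
            ([1, 1, 1, 1, 1, 1, 1], "IVD"),
            ([1, 1], "DD"),
            ([1, 3, 1, 1, 1, 1], "IVD"),  # grade out of range
            ([1, -1, 1], "DD"),
        ],
    )
    def test_invalid_items_rejected(self, items, rubric):
        with pytest.raises(ValidationError):
            score_rubric(items, rubric)

    def test_error_names_offending_item(self):
        with pytest.raises(ValidationError, match="item 2"):
            score_rubric([1, 3, 1, 1, 1, 1], "IVD")


class TestDecisionRules:
    @pytest.mark.parametrize(
        "total,any_zero,expected",
        [(10, False, "clear"), (6, False, "unknown"), (9, True, "unknown"),
         (7, False, "clear"), (12, False, "clear"), (0, True, "unknown")],
    )
    def test_ivd_rule(self, total, any_zero, expected):
        assert classify_ivd(total, any_zero) == expected

    @pytest.mark.parametrize(
        "total,any_two,mode,expected",
        [
            (4, True, "strict_gt3", "severe"),
            (4, False, "strict_gt3", "severe"),
            (3, False, "strict_gt3", "mild"),
            (3, False, "ge3", "severe"),
            (2, False, "ge3", "mild"),
            (0, False, "strict_gt3", "mild"),
            (2, True, "strict_gt3", "severe"),
        ],
    )
    def test_dd_rule(self, total, any_two, mode, expected):
        assert classify_dd(total, any_two, mode) == expected

    @pytest.mark.parametrize("fn,bad", [(classify_ivd, 13), (classify_ivd, -1)])
    def test_out_of_range_total(self, fn, bad):
        with pytest.raises(ValidationError):
            fn(bad, False)

    def test_dd_out_of_range(self):
        with pytest.raises(ValidationError):
            classify_dd(7, False)


class TestItemAggregateEquivalence:
    """Classifying from item grades equals classifying from (total, flag)."""

    def test_ivd_exhaustive(self):
        for items in itertools.product((0, 1, 2), repeat=6):
            total, flag = score_rubric(list(items), "IVD")
            assert total == sum(items)
            assert flag == (0 in items)
            via_items = make_record(ivd_items=items, dd_items=(0, 0, 0))
            assert classify_ivd(via_items.ivd_total, via_items.ivd_any_zero) == \
                classify_ivd(total, flag)

    def test_dd_exhaustive(self):
        for items in itertools.product((0, 1, 2), repeat=3):
            total, flag = score_rubric(list(items), "DD")
            assert total == sum(items)
            assert flag == (2 in items)
            for mode in ("strict_gt3", "ge3"):
                assert classify_dd(total, flag, mode) in ("mild", "severe")

    def test_monotonicity_of_ivd_clear(self):
        """Raising any single item grade never turns clear into unknown."""
        for items in itertools.product((0, 1, 2), repeat=6):
            before = classify_ivd(*score_rubric(list(items), "IVD"))
            for i in range(6):
                if items[i] == 2:
                    continue
                raised = list(items)
                raised[i] += 1
                after = classify_ivd(*score_rubric(raised, "IVD"))
                if before == "clear":
                    assert after == "clear"

    def test_monotonicity_of_dd_severe(self):
        """Severe is monotone non-decreasing in each DD item grade."""
        for items in itertools.product((0, 1, 2), repeat=3):
            before = classify_dd(*score_rubric(list(items), "DD"))
            for i in range(3):
                if items[i] == 2:
                    continue
                raised = list(items)
                raised[i] += 1
                after = classify_dd(*score_rubric(raised, "DD"))
                if before == "severe":
                    assert after == "severe"


class TestRecordValidation:
    def test_items_and_aggregate_conflict(self):
        with pytest.raises(ValidationError, match="not both"):
            make_record(ivd_items=(1,) * 6, ivd_total=6, ivd_any_zero=False,
                        dd_items=(0, 0, 0))

    def test_neither_dialect(self):
        with pytest.raises(ValidationError):
            make_record(ivd_items=(1,) * 6)

    def test_aggregate_out_of_range(self):
        with pytest.raises(ValidationError):
            make_record(ivd_total=13, ivd_any_zero=False, dd_total=0,
                        dd_any_two=False)


class TestCohortSummary:
    def test_reference_cohort_counts(self, table3_records):
        s = summarize_cohort(table3_records)
        assert (s.n_af, s.n_np) == (28, 28)
        assert (s.n_af_clear, s.n_np_clear) == (17, 16)
        assert (s.n_af_eligible, s.n_np_eligible) == (15, 11)

    def test_severe_fraction_under_inclusive_rule(self, table3_records):
        """The inclusive DD rule (total >= 3 or any item 2) flags 38% severe."""
        s = summarize_cohort(table3_records, dd_rule="ge3")
        assert s.n_severe == 21
        assert round(100 * s.fraction_severe) == 38

    def test_single_record(self):
        rec = make_record(ivd_total=12, ivd_any_zero=False, dd_total=0,
                          dd_any_two=False)
        s = summarize_cohort([rec])
        assert s.n_af_clear == 1 and s.n_af_eligible == 1

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            summarize_cohort([])


class TestCohortSelection:
    def test_reference_cohort_selection(self, table3_records):
        c = select_microarray_cohort(table3_records)
        assert len(c.af_sample_ids) == 11
        assert len(c.np_sample_ids) == 9
        assert c.n_donors == 13
        assert c.mean_age_rounded == 53
        assert c.age_range == (36, 76)
        assert (c.female_count, c.male_count) == (6, 7)

    def test_tie_break_prefers_higher_ivd(self):
        a = make_record(sample_id=1, ivd_total=10, ivd_any_zero=False,
                        dd_total=1, dd_any_two=False)
        b = make_record(sample_id=2, ivd_total=9, ivd_any_zero=False,
                        dd_total=0, dd_any_two=False)
        c = select_microarray_cohort([a, b])
        assert c.af_sample_ids == (1,)

    def test_tie_break_then_lower_dd_then_lower_id(self):
        recs = [
            make_record(sample_id=1, ivd_total=9, ivd_any_zero=False,
                        dd_total=2, dd_any_two=False),
            make_record(sample_id=2, ivd_total=9, ivd_any_zero=False,
                        dd_total=1, dd_any_two=False),
            make_record(sample_id=3, ivd_total=9, ivd_any_zero=False,
                        dd_total=1, dd_any_two=False),
        ]
        assert select_microarray_cohort(recs).af_sample_ids == (2,)

    def test_donor_level_outputs_invariant_to_tie_break(self, table3_records):
        """Donor union / age stats do not depend on which duplicate is kept."""
        c = select_microarray_cohort(table3_records)
        # recompute donor-level stats directly from the eligible set
        eligible = [r for r in table3_records
                    if r.verdict().eligible_microarray]
        donors = {r.donor_id: r for r in eligible}
        ages = [r.age for r in donors.values()]
        assert set(c.donor_ids) == set(donors)
        assert c.mean_age == pytest.approx(sum(ages) / len(ages))
        assert c.age_range == (min(ages), max(ages))

    def test_empty_selection_allowed(self):
        rec = make_record(ivd_total=3, ivd_any_zero=True, dd_total=6,
                          dd_any_two=True)
        c = select_microarray_cohort([rec])
        assert c.af_sample_ids == () and c.n_donors == 0
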