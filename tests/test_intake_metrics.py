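"""Occasion aggregation and within-subject variation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietval import intake_metrics as im
from dietval.cohort_io import EatingOccasion, FoodItem, Recall24Record
from dietval.errors import DomainError


def _rec(pid, day, ts, label, kcal=None):
    items = [] if kcal is None else [FoodItem(name="x", energy_kcal=kcal)]
    return EatingOccasion(participant_id=pid, day_index=day, timestamp=ts,
                          label=label, items=items)


class TestAggregateDaily:
    def test_ate_everything_consumes_before_total(self):
        daily = im.aggregate_daily([
            _rec("P01", 1, "t1", "before", 500.0),
            _rec("P01", 1, "t2", "ate_everything"),
        ], fill_days=[1])
        assert daily[0].tdei_kcal == 500.0
        assert daily[0].occasions_n == 1

    def test_after_subtracts_leftovers(self):
        daily = im.aggregate_daily([
            _rec("P01", 1, "t1", "before", 500.0),
            _rec("P01", 1, "t2", "after", 100.0),
        ], fill_days=[1])
        assert daily[0].tdei_kcal == 400.0

    def test_day_sums_over_occasions(self):
        records = []
        for j, kcal in enumerate((400.0, 300.0, 300.0)):
            records.append(_rec("P01", 1, f"t{2*j}", "before", kcal))
            records.append(_rec("P01", 1, f"t{2*j+1}", "ate_everything"))
        daily = im.aggregate_daily(records, fill_days=[1])
        assert daily[0].tdei_kcal == 1000.0
        assert daily[0].occasions_n == 3

    def test_negative_consumed_floored_and_logged(self, caplog):
        with caplog.at_level("WARNING"):
            daily = im.aggregate_daily([
                _rec("P01", 1, "t1", "before", 100.0),
                _rec("P01", 1, "t2", "after", 150.0),
            ], fill_days=[1])
        assert daily[0].tdei_kcal == 0.0
        assert "floored" in caplog.text

    def test_empty_days_filled_with_zero(self):
        daily = im.aggregate_daily([
            _rec("P01", 2, "t1", "before", 500.0),
            _rec("P01", 2, "t2", "ate_everything"),
        ])
        by_day = {d.day_index: d for d in daily}
        assert len(daily) == 7
        assert by_day[2].tdei_kcal == 500.0
        assert by_day[1].tdei_kcal == 0.0 and by_day[1].occasions_n == 0

    def test_summation_conservation(self, study):
        """Sum of daily intakes equals the sum of paired occasion energies."""
        daily = im.aggregate_daily(study.occasions)
        total_daily = sum(d.tdei_kcal for d in daily)
        consumed = 0.0
        stack = {}
        for r in sorted(study.occasions,
                        key=lambda r: (r.participant_id, r.day_index, r.timestamp)):
            key = (r.participant_id, r.day_index)
            if r.label == "before":
                stack.setdefault(key, []).append(r.energy_kcal)
            else:
                b = stack[key].pop()
                a = r.energy_kcal if r.label == "after" else 0.0
                consumed += max(0.0, b - a)
        assert total_daily == pytest.approx(consumed, rel=1e-12)


class TestWithinSubjectCV:
    def test_constant_series_is_zero(self):
        assert im.within_subject_cv([1500.0] * 5) == 0.0

    def test_hand_value(self):
        # SD 707.107 over mean 1500
        assert im.within_subject_cv([1000.0, 2000.0]) == pytest.approx(47.14, abs=0.01)

    @given(st.floats(0.5, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, c):
        base = im.within_subject_cv([900.0, 1500.0, 2100.0])
        assert im.within_subject_cv([c * 900.0, c * 1500.0, c * 2100.0]) == \
            pytest.approx(base, rel=1e-9)

    def test_single_day_rejected(self):
        with pytest.raises(DomainError):
            im.within_subject_cv([1500.0])

    def test_zero_mean_rejected(self):
        with pytest.raises(DomainError):
            im.within_subject_cv([0.0, 0.0])


class TestPooledCV:
    def test_root_mean_square(self):
        assert im.pooled_cv([30.0, 50.0]) == pytest.approx(np.sqrt(1700.0))
        assert im.pooled_cv([30.0, 50.0]) == pytest.approx(41.231, abs=1e-3)

    def test_constant_and_singleton(self):
        assert im.pooled_cv([25.0, 25.0, 25.0]) == pytest.approx(25.0)
        assert im.pooled_cv([33.3]) == pytest.approx(33.3)

    @given(st.lists(st.floats(0.0, 200.0), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_bounded_by_min_and_max(self, cvs):
        pooled = im.pooled_cv(cvs)
        assert min(cvs) - 1e-9 <= pooled <= max(cvs) + 1e-9

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            im.pooled_cv([])


class TestToolSummary:
    def test_paired_cardinality(self, study):
        daily = im.aggregate_daily(study.occasions)
        series = im.build_series(daily)
        table = im.tool_summary(series, study.recalls)
        assert len(table) == 30
        assert (table["tdei_diff_kcal"] ==
                table["app_tdei_kcal"] - table["recall_tdei_kcal"]).all()

    def test_missing_participant_excluded_with_log(self, study, caplog):
        daily = im.aggregate_daily(study.occasions)
        series = im.build_series(daily)
        with caplog.at_level("WARNING"):
            table = im.tool_summary(series, study.recalls[:-1])
        assert len(table) == 29
        assert "excluded" in caplog.text

    def test_empty_intersection_rejected(self, study):
        daily = im.aggregate_daily(study.occasions)
        series = im.build_series(daily)
        other = [Recall24Record(participant_id="Z99", tdei_kcal=1500, carb_g=0,
                                sugar_g=0, fat_g=0, satfat_g=0, protein_g=0,
                                fiber_g=0, eating_occasions=4)]
        with pytest.raises(DomainError):
            im.tool_summary(series, other)

    def test_mean_difference_column(self):
        """Group means of the two tools differ by the difference of means."""
        series = im.build_series([
            im.DailyIntake("P01", d, 1900.0) for d in range(1, 8)
        ] + [im.DailyIntake("P02", d, 2000.0) for d in range(1, 8)])
        recalls = [
            Recall24Record(participant_id="P01", tdei_kcal=1650.0, carb_g=0,
                           sugar_g=0, fat_g=0, satfat_g=0, protein_g=0,
                           fiber_g=0, eating_occasions=4),
            Recall24Record(participant_id="P02", tdei_kcal=1823.2, carb_g=0,
                           sugar_g=0, fat_g=0, satfat_g=0, protein_g=0,
                           fiber_g=0, eating_occasions=5),
        ]
        table = im.tool_summary(series, recalls)
        assert table["tdei_diff_kcal"].mean() == pytest.approx(
            table["app_tdei_kcal"].mean() - table["recall_tdei_kcal"].mean())
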