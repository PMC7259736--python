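"""Survey-data model: stages, filtering, standardization, naive metrics."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nutcracker_occupancy.data_model import (
    DetectionHistory,
    RadiusClass,
    Stage,
    StageAssignmentError,
    STUDY_SURVEY_SCHEDULE,
    SurveyRecord,
    ValidationError,
    assign_stage,
    check_radius_consistency,
    decompose_zero_inflated,
    first_visit_filter,
    naive_metrics,
    read_covariates,
    read_surveys,
    tally_surveys,
    zscore,
)


def rec(site="A", year=2011, date="2011-07-20", counts=(0, 1, 0), radius=RadiusClass.INFINITE):
    d = dt.date.fromisoformat(date)
    return SurveyRecord(
        site_id=site,
        year=year,
        date=d,
        stage=assign_stage(d),
        counts=counts,
        radius_class=radius,
    )


class TestStageAssignment:
    @pytest.mark.parametrize(
        "date, expected",
        [
            ("2011-03-10", Stage.BREEDING),
            ("2011-03-05", Stage.BREEDING),   # opening day
            ("2011-06-15", Stage.BREEDING),   # last nestling day
            ("2011-06-16", Stage.EARLY_SUMMER),
            ("2011-07-20", Stage.LATE_SUMMER),
            ("2011-08-20", Stage.FALL_HARVEST),
            ("2011-10-01", Stage.POST_HARVEST),
        ],
    )
    def test_default_windows(self, date, expected):
        assert assign_stage(dt.date.fromisoformat(date)) is expected

    def test_winter_date_rejected(self):
        with pytest.raises(StageAssignmentError):
            assign_stage(dt.date(2011, 2, 1))


class TestFirstVisitFilter:
    def test_keeps_earliest_visit(self):
        r1 = rec(date="2011-07-20")
        r2 = rec(date="2011-07-25")
        assert first_visit_filter([r2, r1]) == [r1]

    def test_single_visit_unchanged(self):
        r1 = rec()
        assert first_visit_filter([r1]) == [r1]

    def test_same_stage_different_years_both_kept(self):
        r1 = rec(year=2011, date="2011-07-20")
        r2 = rec(year=2012, date="2012-07-20")
        assert first_visit_filter([r1, r2]) == [r1, r2]

    def test_radius_classes_kept_separately(self):
        r1 = rec(radius=RadiusClass.INFINITE)
        r2 = rec(radius=RadiusClass.WITHIN_100M, counts=(0, 0, 0))
        assert len(first_visit_filter([r1, r2])) == 2

    def test_idempotent(self):
        records = [
            rec(date="2011-07-20"),
            rec(date="2011-07-25"),
            rec(site="B", date="2011-07-22"),
            rec(year=2012, date="2012-07-21"),
        ]
        once = first_visit_filter(records)
        assert first_visit_filter(once) == once


class TestZscore:
    def test_simple_triple(self):
        np.testing.assert_allclose(zscore([1, 2, 3]), [-1.0, 0.0, 1.0])

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError):
            zscore([2.0, 2.0, 2.0])

    def test_idempotent_on_standardized_input(self):
        x = zscore([3.0, 1.0, 4.0, 1.0, 5.0])
        np.testing.assert_allclose(zscore(x), x, atol=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.floats(-1e6, 1e6, allow_nan=False), min_size=2, max_size=40
        ).filter(lambda v: np.std(v) > 1e-9)
    )
    def test_mean_zero_sd_one(self, values):
        z = zscore(values)
        assert abs(z.mean()) < 1e-10
        assert abs(z.std(ddof=1) - 1.0) < 1e-10


class TestZeroInflatedDecomposition:
    def test_mixed_vector(self):
        absence, magnitude = decompose_zero_inflated([0.0, 10.0, 20.0])
        np.testing.assert_allclose(absence, [1, 0, 0])
        np.testing.assert_allclose(magnitude, [0.0, -np.sqrt(0.5), np.sqrt(0.5)])

    def test_all_positive_no_absences(self):
        absence, _ = decompose_zero_inflated([1.0, 2.0, 3.0])
        assert absence.sum() == 0

    def test_all_zero_flags_magnitude_undefined(self):
        absence, magnitude = decompose_zero_inflated([0.0, 0.0])
        np.testing.assert_allclose(absence, [1, 1])
        assert np.isnan(magnitude).all()

    def test_magnitude_vanishes_at_absent_sites(self):
        _, magnitude = decompose_zero_inflated([0.0, 5.0, 0.0, 9.0, 13.0])
        assert magnitude[0] == 0.0 and magnitude[2] == 0.0


class TestNaiveMetrics:
    @pytest.mark.parametrize(
        "h, expected",
        [
            ((0, 0, 0), (0, 0.0)),
            ((1, 0, 1), (1, 2 / 3)),
            ((0, 1, 0), (1, 1 / 3)),
            ((1, 1, 1), (1, 1.0)),
        ],
    )
    def test_examples(self, h, expected):
        assert naive_metrics(h) == expected

    def test_occurrence_iff_positive_proportion(self):
        for code in range(8):
            h = ((code >> 2) & 1, (code >> 1) & 1, code & 1)
            occ, prop = naive_metrics(h)
            assert (occ == 1) == (prop > 0)


class TestTally:
    def test_study_schedule_total(self):
        tally = tally_surveys(STUDY_SURVEY_SCHEDULE)
        assert tally["total"] == 2526
        assert tally["breeding"] == 384

    def test_empty_table(self):
        empty = pd.DataFrame({"stage": [], "n_surveys": []})
        tally = tally_surveys(empty)
        assert (tally == 0).all()

    def test_record_list(self):
        records = [rec(), rec(site="B"), rec(date="2011-08-20")]
        tally = tally_surveys(records)
        assert tally["late_summer"] == 2 and tally["fall_harvest"] == 1
        assert tally["total"] == 3


class TestRadiusConsistency:
    def test_subset_violation_detected(self):
        near = rec(radius=RadiusClass.WITHIN_100M, counts=(1, 0, 0))
        far = rec(radius=RadiusClass.INFINITE, counts=(0, 0, 0))
        problems = check_radius_consistency([near, far])
        assert len(problems) == 1

    def test_consistent_pair_passes(self):
        near = rec(radius=RadiusClass.WITHIN_100M, counts=(1, 0, 0))
        far = rec(radius=RadiusClass.INFINITE, counts=(1, 0, 1))
        assert check_radius_consistency([near, far]) == []


class TestCsvIngest:
    def test_roundtrip_with_derived_stage(self, tmp_path):
        path = tmp_path / "surveys.csv"
        pd.DataFrame(
            {
                "site_id": ["A", "B"],
                "year": [2011, 2011],
                "date": ["2011-07-20", "2011-08-20"],
                "count1": [0, 1],
                "count2": [1, 0],
                "count3": [0, 1],
                "radius_class": ["infinite", "infinite"],
            }
        ).to_csv(path, index=False)
        records = read_surveys(path)
        assert [r.stage for r in records] == [Stage.LATE_SUMMER, Stage.FALL_HARVEST]

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "surveys.csv"
        pd.DataFrame({"site_id": ["A"], "year": [2011]}).to_csv(path, index=False)
        with pytest.raises(ValidationError):
            read_surveys(path)

    def test_covariates_negative_rejected(self, tmp_path):
        path = tmp_path / "cov.csv"
        pd.DataFrame(
            {
                "site_id": ["A"],
                "cone_density": [-5.0],
                "wbp_importance": [10.0],
                "df_importance": [0.0],
                "wbp_landscape_area": [40000.0],
                "df_landscape_area": [200.0],
                "tree_density": [300.0],
            }
        ).to_csv(path, index=False)
        with pytest.raises(ValidationError):
            read_covariates(path)


def test_history_validation():
    with pytest.raises(ValidationError):
        DetectionHistory("A", 2011, Stage.BREEDING, RadiusClass.INFINITE, (0, 2, 0))
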