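"""Containers, the acquisition schedule, NIfTI round trips and the cohort fixture."""

import json

import numpy as np
import pandas as pd
import pytest

from fetomics.core import DynamicPETSeries, FrameSchedule, make_frame_schedule
from fetomics.io import (
    fixture_frame,
    load_table1_fixture,
    read_feature_table,
    read_series,
    write_feature_table,
    write_metrics_report,
    write_series,
)
from fetomics.stats import ClassificationMetrics


class TestFrameSchedule:
    def test_canonical_14_frame_schedule(self):
        sched = make_frame_schedule()
        assert len(sched) == 14
        assert sched.durations.tolist() == [1] * 5 + [3] * 5 + [5] * 4
        assert sched.ends[-1] == 40.0

    def test_mid_times_match_the_acquisition_grid(self):
        sched = make_frame_schedule()
        expected = [0.5, 1.5, 2.5, 3.5, 4.5, 6.5, 9.5, 12.5, 15.5, 18.5,
                    22.5, 27.5, 32.5, 37.5]
        assert sched.mid_times.tolist() == expected
        assert sched.mid_times[10] == 22.5  # start 20 + 5/2

    def test_non_contiguous_frames_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            FrameSchedule(starts=np.array([0.0, 2.0]), durations=np.array([1.0, 1.0]))


class TestSeriesValidation:
    def test_frame_count_must_match_schedule(self):
        with pytest.raises(ValueError, match="frame count"):
            DynamicPETSeries(
                values=np.zeros((4, 4, 4, 3)),
                voxel_size=(2, 2, 2.4),
                schedule=make_frame_schedule(),
            )

    def test_negative_suv_rejected(self):
        vals = np.zeros((2, 2, 2, 14))
        vals[0, 0, 0, 0] = -1.0
        with pytest.raises(ValueError, match="non-negative"):
            DynamicPETSeries(vals, (2, 2, 2.4), make_frame_schedule())


class TestNiftiRoundTrip:
    def test_series_round_trip(self, tmp_path, noisefree_patient):
        series = noisefree_patient["series"]
        path = tmp_path / "series.nii.gz"
        write_series(series, path)
        back = read_series(path)
        np.testing.assert_allclose(back.values, series.values, rtol=1e-6)
        assert back.voxel_size == pytest.approx((2.0, 2.0, 2.4))

    def test_wrong_dimensionality_named_in_error(self, tmp_path):
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.zeros((4, 4, 4)), np.eye(4)), tmp_path / "x.nii")
        with pytest.raises(ValueError, match="expected 4D"):
            read_series(tmp_path / "x.nii")


class TestCohortFixture:
    def test_cohort_composition(self):
        records = load_table1_fixture()
        assert len(records) == 34
        assert sum(r.diagnosis == "PSP" for r in records) == 16
        assert sum(r.diagnosis == "EP" for r in records) == 18

    def test_known_rows(self):
        by_id = {r.patient_id: r for r in load_table1_fixture()}
        assert by_id[8].tbr_max == 3.9 and by_id[8].slope == -1.9
        assert by_id[34].pfs_months == 24 and by_id[34].pfs_censored
        assert by_id[25].pfs_months is None
        assert by_id[13].mgmt == "missing"
        assert by_id[34].idh == "mut"

    def test_column_checksums_lock_transcription(self):
        df = fixture_frame()
        sums = {
            "tbr_mean": 67.7, "tbr_max": 78.7, "ttp": 962.0, "slope": 6.6,
            "pfs_months": 318.0, "os_months": 579.0,
            "pfs_censored": 1, "os_censored": 17,
        }
        for col, want in sums.items():
            assert df[col].sum() == pytest.approx(want), col


class TestTabularIO:
    def test_empty_feature_table_header(self, tmp_path):
        path = tmp_path / "features.csv"
        write_feature_table(pd.DataFrame(), path)
        cols = pd.read_csv(path).columns
        assert len(cols) == 946  # 2 key columns + 944 features

    def test_feature_table_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(
            {"patient_id": ["P1"], "segmentation_threshold": [1.6],
             "a": rng.random(1), "b": rng.random(1)}
        )
        path = tmp_path / "t.csv"
        write_feature_table(table, path)
        back = read_feature_table(path)
        np.testing.assert_allclose(back[["a", "b"]], table[["a", "b"]], atol=1e-12)

    def test_metrics_report_names(self, tmp_path):
        m = ClassificationMetrics(tp=13, fp=6, fn=3, tn=12, auc=0.79)
        path = tmp_path / "metrics.json"
        write_metrics_report(m, path)
        data = json.loads(path.read_text())
        for name in ("sensitivity", "specificity", "ppv", "npv", "fnr", "fpr",
                     "accuracy", "f1", "mcc", "auc"):
            assert name in data
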