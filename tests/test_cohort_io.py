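import io

import numpy as np
import pandas as pd
import pytest

from jdmjm import (
    CohortValidationError,
    build_cohort,
    filter_history_complete,
    read_cohort,
)


def make_df():
    return pd.DataFrame({
        "patient_id": ["b", "b", "a"],
        "time_years": [0.5, 0.0, 0.0],
        "ck": [120.0, 300.0, 90.0],
        "cmas": [52.0, 30.0, 45.0],
        "mmt8": [80.0, 60.0, 80.0],
        "pga": [0.0, 5.0, 1.5],
        "sym_a": [1.0, 0.0, np.nan],
        "hist_b": [0.0, 0.0, np.nan],
        "trt_c": [1.0, 1.0, 0.0],
    })


def test_build_densifies_and_sorts(roster3):
    cohort = build_cohort(make_df(), roster3)
    assert cohort.n_patients == 2
    assert cohort.patient_ids == ["b", "a"]
    # visits of each patient sorted by time
    tb = cohort.df[cohort.df["patient_id"] == "b"]["time_years"].tolist()
    assert tb == sorted(tb)
    assert cohort.df["patient_index"].tolist() == [0, 0, 1]


def test_read_cohort_missing_token(roster3):
    csv = make_df().to_csv(index=False, na_rep="NA")
    cohort = read_cohort(io.StringIO(csv), roster3)
    assert np.isnan(cohort.df["sym_a"]).sum() == 1


def test_row_level_problems(roster3):
    df = make_df()
    df.loc[0, "ck"] = -5.0          # log domain violation
    df.loc[1, "cmas"] = 53.0        # above upper bound
    df.loc[2, "sym_a"] = 2.0        # non-binary covariate
    with pytest.raises(CohortValidationError) as exc:
        build_cohort(df, roster3)
    cols = {p["column"] for p in exc.value.problems}
    assert cols == {"ck", "cmas", "sym_a"}


def test_unknown_column_rejected(roster3):
    df = make_df()
    df["mystery"] = 1.0
    with pytest.raises(CohortValidationError, match="mystery"):
        build_cohort(df, roster3)


def test_missing_roster_column_rejected(roster3):
    df = make_df().drop(columns=["trt_c"])
    with pytest.raises(CohortValidationError, match="trt_c"):
        build_cohort(df, roster3)


def test_filter_history_complete(roster3):
    cohort = build_cohort(make_df(), roster3)
    filtered, report = filter_history_complete(cohort)
    # patient "a" had a missing history covariate on its only visit
    assert report.dropped_patients == ["a"]
    assert len(report.dropped_visits) == 1
    assert filtered.n_patients == 1
    # indices re-densified
    assert sorted(filtered.df["patient_index"].unique()) == [0]


def test_fully_observed_patients(roster3):
    cohort = build_cohort(make_df(), roster3)
    assert cohort.fully_observed_patients() == [0]


def test_write_read_round_trip(tmp_path, roster3):
    cohort = build_cohort(make_df(), roster3)
    path = tmp_path / "cohort.csv"
    cohort.write_csv(path)
    back = read_cohort(path, roster3)
    pd.testing.assert_frame_equal(back.df, cohort.df)
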