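"""Clinical-record validation and the derived placental morphometrics."""

import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ivs_hemoflow.cohort import (
    EXEMPLARY_COHORT,
    CohortParseError,
    CohortSchemaError,
    InvalidRecordError,
    PlacentaRecord,
    morphometrics,
    read_cohort_csv,
)


@pytest.mark.parametrize(
    "group, pw_bw, roundness",
    [("normal", 0.16, 1.17), ("iugr", 0.17, 1.15), ("iugr_pe", 0.23, 1.86)],
)
def test_exemplary_morphometrics_match_printed_ratios(group, pw_bw, roundness):
    """PW/BW and LD/SD reproduce the printed clinical-table values at 2 dp."""
    rec = next(r for r in EXEMPLARY_COHORT if r.group == group)
    m = morphometrics(rec)
    assert m["pw_bw_ratio_2dp"] == pw_bw
    assert m["roundness_2dp"] == roundness
    # full precision is retained alongside the rounded values
    assert abs(m["pw_bw_ratio"] - rec.pw_g / rec.bw_g) < 1e-12


def test_identity_cases():
    rec = PlacentaRecord("normal", 39.0, 500.0, 500.0, 12.0, 12.0, 400.0, 2.0)
    m = morphometrics(rec)
    assert m["pw_bw_ratio"] == 1.0
    assert m["roundness"] == 1.0


@given(
    ld=st.floats(1.0, 40.0),
    ratio=st.floats(1.0, 4.0),
    bw=st.floats(300.0, 5000.0),
    pw=st.floats(50.0, 1500.0),
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_roundness_at_least_one_for_valid_records(ld, ratio, bw, pw):
    rec = PlacentaRecord("iugr", 33.0, bw, pw, ld * ratio, ld, 500.0, 2.0)
    assert morphometrics(rec)["roundness"] >= 1.0


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(bw_g=0.0),
        dict(pw_g=-1.0),
        dict(ld_cm=10.0, sd_cm=12.0),
        dict(group="unknown"),
    ],
)
def test_invalid_records_rejected(kwargs):
    base = dict(group="normal", ga_weeks=38.0, bw_g=3000.0, pw_g=450.0,
                ld_cm=18.0, sd_cm=15.0, surface_cm2=800.0, thickness_cm=2.0)
    base.update(kwargs)
    with pytest.raises(InvalidRecordError):
        PlacentaRecord(**base)


HEADER = "group,ga_weeks,bw_g,pw_g,ld_cm,sd_cm,surface_cm2,thickness_cm"


def test_csv_roundtrip_with_annotations(tmp_path):
    p = tmp_path / "cohort.csv"
    p.write_text(
        HEADER + ",note\n"
        "normal,38.5,3130,488,17.5,15.0,825,2.10,first\n"
        "iugr,33.6,1620,277,15.0,13.0,613,2.00,second\n"
        "iugr_pe,33.3,1470,339,19.5,10.5,643,1.30,third\n"
    )
    records = read_cohort_csv(p)
    assert len(records) == 3
    assert records[0].annotations["note"] == "first"
    assert [r.group for r in records] == ["normal", "iugr", "iugr_pe"]


def test_empty_csv_yields_empty_list_with_warning():
    with pytest.warns(UserWarning):
        assert read_cohort_csv(io.StringIO("")) == []


def test_zero_birthweight_names_the_row():
    csv = HEADER + "\nnormal,38.5,0,488,17.5,15.0,825,2.10\n"
    with pytest.raises(InvalidRecordError, match="row 0"):
        read_cohort_csv(io.StringIO(csv))


def test_missing_column_and_bad_cell():
    with pytest.raises(CohortSchemaError):
        read_cohort_csv(io.StringIO("group,bw_g\nnormal,3000\n"))
    bad = HEADER + "\nnormal,38.5,abc,488,17.5,15.0,825,2.10\n"
    with pytest.raises(CohortParseError, match="row 0"):
        read_cohort_csv(io.StringIO(bad))
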