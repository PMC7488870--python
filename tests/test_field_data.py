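"""Growth-record I/O, cessation/start detection, and shoot categorisation."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shootzones.errors import DataError
from shootzones.field_data import (
    GD_LONG, GD_MEDIUM, GD_SHORT, GP_EARLY, GP_LATE, ONE_GU, TWO_GUS,
    BranchingSequence, CategoryConfig, GrowthObservation, GUSpan,
    ShootCategory, ShootGrowthSeries, classify_shoot, compute_start_date,
    detect_cessations, read_growth_records, read_sequences, write_sequences,
)

CFG = CategoryConfig()


def weekly_series(lengths, start=dt.date(2016, 4, 20), shoot_id="s1"):
    obs = [GrowthObservation(shoot_id, start + dt.timedelta(days=7 * k), l)
           for k, l in enumerate(lengths)]
    return ShootGrowthSeries(shoot_id, obs)


# ---------------------------------------------------------------------- #
# CSV I/O
# ---------------------------------------------------------------------- #

def test_growth_csv_roundtrip(tmp_path):
    p = tmp_path / "g.csv"
    p.write_text("shoot_id,date,length_cm\n"
                 "a,2016-04-20,2.0\na,2016-04-27,4.5\na,2016-05-04,8.0\n")
    series, report = read_growth_records(p)
    assert report.rows_read == 3 and report.rows_rejected == 0
    assert len(series) == 1 and len(series[0].observations) == 3
    assert series[0].dates[0] == dt.date(2016, 4, 20)


def test_growth_csv_duplicate_date_rejected(tmp_path):
    p = tmp_path / "g.csv"
    p.write_text("shoot_id,date,length_cm\n"
                 "a,2016-04-20,2.0\na,2016-04-20,3.0\na,2016-04-27,4.0\n"
                 "a,2016-05-04,5.0\n")
    series, report = read_growth_records(p)
    assert report.rows_rejected == 1
    assert any("duplicate" in e and "2016-04-20" in e for e in report.errors)
    assert len(series) == 1  # remaining rows still form a valid series


def test_growth_csv_empty_and_bad_rows(tmp_path):
    p = tmp_path / "empty.csv"
    p.write_text("shoot_id,date,length_cm\n")
    series, report = read_growth_records(p)
    assert series == [] and report.rows_read == 0
    p2 = tmp_path / "bad.csv"
    p2.write_text("shoot_id,date,length_cm\na,not-a-date,2.0\n"
                  "a,2016-04-20,1.0\na,2016-04-27,2.0\n")
    series, report = read_growth_records(p2)
    assert report.rows_rejected == 1 and "line 2" in report.errors[0]


def test_growth_csv_missing_columns(tmp_path):
    p = tmp_path / "g.csv"
    p.write_text("shoot,when,cm\na,2016-04-20,2.0\n")
    with pytest.raises(DataError):
        read_growth_records(p)


def test_series_rejects_true_shrinkage():
    with pytest.raises(DataError):
        weekly_series([5.0, 10.0, 8.5])


# ---------------------------------------------------------------------- #
# cessation and start rules
# ---------------------------------------------------------------------- #

def test_cessation_single_episode():
    # trailing 14-day gains: 10, 5.3, 0.4 -> first qualifying at the last obs
    s = weekly_series([5, 10, 15, 15.3, 15.4])
    dates = detect_cessations(s, CFG)
    assert dates == [s.dates[4]]


def test_cessation_none_for_linear_growth():
    s = weekly_series([5, 8, 11, 14, 17, 20])
    assert detect_cessations(s, CFG) == []


def test_cessation_two_episodes_after_renewed_growth():
    s = weekly_series([5, 10, 15, 15.2, 15.3, 20, 26, 30, 30.1, 30.2])
    dates = detect_cessations(s, CFG)
    assert dates == [s.dates[4], s.dates[9]]


def test_cessation_no_assessment_for_short_series():
    s = weekly_series([5, 8])  # span 7 d < 14 d window
    assert detect_cessations(s, CFG) is None


def test_start_date_first_crossing():
    s = weekly_series([2, 4, 6])
    assert compute_start_date(s, CFG) == s.dates[2]
    assert compute_start_date(weekly_series([1, 2, 3]), CFG) is None


def test_second_gu_start_uses_cessation_baseline():
    s = weekly_series([2, 6, 10, 10.2, 10.3, 13, 16, 20])
    first = compute_start_date(s, CFG)
    assert first == s.dates[1]
    second = compute_start_date(s, CFG, after=s.dates[4], baseline=10.3)
    assert second == s.dates[6]  # 16 >= 10.3 + 5


# ---------------------------------------------------------------------- #
# classification
# ---------------------------------------------------------------------- #

def gu(index, start, gd_days):
    return GUSpan(index, start, start + dt.timedelta(days=gd_days))


@pytest.mark.parametrize("gd,start,expected", [
    (30, dt.date(2016, 5, 10), (GD_MEDIUM, GP_EARLY)),   # closed boundary
    (90, dt.date(2016, 5, 10), (GD_MEDIUM, GP_EARLY)),
    (91, dt.date(2016, 5, 10), (GD_LONG, GP_EARLY)),
    (29, dt.date(2016, 6, 3), (GD_SHORT, GP_EARLY)),     # on-threshold -> early
    (100, dt.date(2016, 6, 10), (GD_LONG, GP_LATE)),
])
def test_classify_one_gu(gd, start, expected):
    cat = classify_shoot([gu(1, start, gd)], CFG)
    assert cat.cyclicity == ONE_GU and cat.gu_classes == (expected,)


def test_classify_two_gus():
    spans = [gu(1, dt.date(2016, 5, 1), 20), gu(2, dt.date(2016, 7, 25), 50)]
    cat = classify_shoot(spans, CFG)
    assert cat.cyclicity == TWO_GUS
    assert cat.gu_classes == ((GD_SHORT, GP_EARLY), (GD_LONG, GP_LATE))


def test_classify_rejects_three_spans():
    spans = [gu(1, dt.date(2016, 5, 1), 10), gu(2, dt.date(2016, 6, 15), 10),
             gu(2, dt.date(2016, 8, 1), 10)]
    with pytest.raises(DataError):
        classify_shoot(spans, CFG)


_GD_ORDER = {GD_SHORT: 0, GD_MEDIUM: 1, GD_LONG: 2}


@settings(max_examples=200, deadline=None)
@given(gd=st.integers(min_value=0, max_value=200),
       delta=st.integers(min_value=1, max_value=60))
def test_gd_class_monotone_in_duration(gd, delta):
    start = dt.date(2016, 5, 1)
    a = classify_shoot([gu(1, start, gd)], CFG).gu_classes[0][0]
    b = classify_shoot([gu(1, start, gd + delta)], CFG).gu_classes[0][0]
    assert _GD_ORDER[b] >= _GD_ORDER[a]


# ---------------------------------------------------------------------- #
# sequence TSV
# ---------------------------------------------------------------------- #

def test_sequence_tsv_roundtrip(tmp_path):
    cat1 = ShootCategory(ONE_GU, ((GD_SHORT, GP_EARLY),))
    cat2 = ShootCategory(TWO_GUS, ((GD_SHORT, GP_EARLY), (GD_LONG, GP_LATE)))
    seqs = [
        BranchingSequence("a", [0, 0, 3, 1], cat1),
        BranchingSequence("b", [0, 0, 3, 5, 5, 0, 0, 2], cat2),
    ]
    p = tmp_path / "seqs.tsv"
    write_sequences(seqs, p)
    back = read_sequences(p)
    assert [s.shoot_id for s in back] == ["a", "b"]
    for orig, rb in zip(seqs, back):
        assert np.array_equal(orig.symbols, rb.symbols)
        assert rb.category.label() == orig.category.label()


def test_sequence_invalid_symbol_position():
    with pytest.raises(DataError, match="node 2"):
        BranchingSequence("x", [0, 1, 7, 0])


def test_scar_run_constraints():
    two = ShootCategory(TWO_GUS, ((GD_SHORT, GP_EARLY), (GD_SHORT, GP_LATE)))
    one = ShootCategory(ONE_GU, ((GD_SHORT, GP_EARLY),))
    BranchingSequence("ok", [0, 5, 5, 0, 1], two)
    with pytest.raises(DataError, match="contiguous"):
        BranchingSequence("bad", [0, 5, 0, 5, 1], two)
    with pytest.raises(DataError, match="two-GUs"):
        BranchingSequence("bad2", [0, 5, 5, 1], one)
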