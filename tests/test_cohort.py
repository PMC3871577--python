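import datetime

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cwprisk.cohort import (
    Area,
    ConcentrationTable,
    ExposureSegment,
    InvalidRecordError,
    MissingConcentrationError,
    classify_occupation,
    compute_cde,
    observation_window,
    read_cohort,
    write_cohort,
)

from conftest import chain, seg, worker

Y = 365  # whole days per nominal "year" for segment construction


class TestClassifyOccupation:
    @pytest.mark.parametrize(
        "parts, expected",
        [
            # single consistent area
            ([("helping", 30 * Y)], "helping"),
            # tunneling more than half of 20 y
            ([("tunneling", 12 * Y), ("helping", 8 * Y)], "tunneling"),
            # tunneling > 2 y but not more than half
            ([("tunneling", 3 * Y), ("mining", 15 * Y), ("helping", 2 * Y)], "combining"),
            # tunneling < 2 y, mining more than half
            ([("tunneling", 1 * Y), ("mining", 12 * Y), ("helping", 7 * Y)], "mining"),
            # fall-through: no rule fires
            ([("mining", 6 * Y), ("helping", 14 * Y)], "helping"),
            # tunneling exactly half of the total is not "more than half";
            # 3652 d ≈ 10 y of tunneling is >= 2 y, so combining
            ([("tunneling", 3652), ("mining", 3652)], "combining"),
        ],
    )
    def test_rule_cascade(self, parts, expected):
        segs = chain("1975-01-01", *parts)
        assert classify_occupation(segs) is Area(expected)

    def test_order_invariance(self):
        segs = list(chain("1975-01-01", ("tunneling", 900), ("mining", 5000), ("helping", 700)))
        expected = classify_occupation(segs)
        for perm in ([2, 0, 1], [1, 2, 0], [2, 1, 0]):
            assert classify_occupation([segs[i] for i in perm]) is expected

    def test_empty_list_rejected(self):
        with pytest.raises(InvalidRecordError):
            classify_occupation([])


class TestComputeCde:
    def test_constant_concentration_is_duration_times_level(self, flat_conc):
        # 10 "years" of 365.25 days at 5 mg/m³
        segs = chain("1980-01-01", ("mining", 3653))
        assert compute_cde(segs, flat_conc) == pytest.approx(3653 / 365.25 * 5.0)

    def test_empty_segments_zero(self, flat_conc):
        assert compute_cde([], flat_conc) == 0.0

    def test_against_per_day_oracle(self):
        # year-varying concentrations, spells crossing year boundaries
        table = ConcentrationTable(
            [("mining", y, y, float(y - 1969), None) for y in range(1970, 1990)]
            + [("helping", y, y, 0.5 * (y - 1969), None) for y in range(1970, 1990)]
        )
        segs = [
            seg("mining", "1972-03-15", "1975-08-02"),
            seg("helping", "1975-08-02", "1979-01-20"),
            seg("mining", "1980-12-31", "1984-02-29"),
        ]

        def per_day(segments):
            total = 0.0
            for s in segments:
                d = s.start
                while d < s.end:
                    total += table.value(s.area, d.year) / 365.25
                    d += datetime.timedelta(days=1)
            return total

        assert compute_cde(segs, table) == pytest.approx(per_day(segs), rel=1e-9)

    @given(
        start_off=st.integers(0, 2000),
        length=st.integers(2, 4000),
        cut=st.floats(0.01, 0.99),
    )
    @settings(max_examples=50, deadline=None)
    def test_additive_under_split(self, start_off, length, cut):
        """Splitting a spell at any date leaves CDE unchanged."""
        table = ConcentrationTable(
            [("tunneling", y, y, 1.0 + (y % 7), None) for y in range(1969, 1995)]
        )
        start = datetime.date(1970, 1, 1) + datetime.timedelta(days=start_off)
        end = start + datetime.timedelta(days=length)
        mid = start + datetime.timedelta(days=max(1, int(length * cut)))
        if mid >= end:
            mid = end - datetime.timedelta(days=1)
        whole = [seg("tunneling", start, end)]
        split = [seg("tunneling", start, mid), seg("tunneling", mid, end)]
        assert compute_cde(whole, table) == pytest.approx(
            compute_cde(split, table), rel=1e-9
        )

    def test_missing_cell_reported(self, conc):
        segs = [seg("mining", "1960-01-01", "1965-01-01")]
        with pytest.raises(MissingConcentrationError, match="1960"):
            compute_cde(segs, conc)


class TestObservationWindow:
    def test_case_latency(self):
        w = worker(case=True, diagnosis="2004-01-01", censor=None)
        assert observation_window(w) == pytest.approx(29.0, abs=0.01)

    def test_short_censored_window(self):
        w = worker(
            entry="2010-01-01",
            segments=chain("2010-01-01", ("helping", 500)),
            censor="2011-12-31",
        )
        assert observation_window(w) == pytest.approx(2.0, abs=0.05)

    def test_diagnosis_before_entry_invalid(self):
        w = worker(case=True, diagnosis="1970-01-01", censor=None)
        with pytest.raises(InvalidRecordError):
            w.validate()
        with pytest.raises(InvalidRecordError):
            observation_window(worker(case=True, diagnosis=None, censor=None))


class TestRecordInvariants:
    def test_overlapping_segments_rejected(self):
        w = worker(
            segments=[
                seg("mining", "1975-01-01", "1980-01-01"),
                seg("helping", "1979-06-01", "1985-01-01"),
            ]
        )
        with pytest.raises(InvalidRecordError, match="overlap"):
            w.validate()

    def test_short_total_exposure_rejected(self):
        w = worker(segments=chain("1975-01-01", ("mining", 200)))
        with pytest.raises(InvalidRecordError, match="inclusion"):
            w.validate()


class TestCohortIO:
    def test_round_trip(self, tmp_path):
        from cwprisk.simulate import CohortSpec, generate_cohort

        records, _ = generate_cohort(CohortSpec(n_workers=100, seed=3))
        write_cohort(records, tmp_path / "c.csv", tmp_path / "s.csv")
        back = read_cohort(tmp_path / "c.csv", tmp_path / "s.csv")
        assert back == records

    def test_duplicate_worker_id(self, tmp_path):
        (tmp_path / "c.csv").write_text(
            "worker_id,birth_year,first_exposure_date,cwp_status,diagnosis_date,censor_date\n"
            "a1,1950,1975-01-01,0,,2011-12-31\n"
            "a1,1951,1976-01-01,0,,2011-12-31\n"
        )
        (tmp_path / "s.csv").write_text("worker_id,area,start_date,end_date\n")
        with pytest.raises(InvalidRecordError, match="a1"):
            read_cohort(tmp_path / "c.csv", tmp_path / "s.csv")

    def test_header_only_warns_empty(self, tmp_path):
        (tmp_path / "c.csv").write_text(
            "worker_id,birth_year,first_exposure_date,cwp_status,diagnosis_date,censor_date\n"
        )
        (tmp_path / "s.csv").write_text("worker_id,area,start_date,end_date\n")
        with pytest.warns(UserWarning, match="empty cohort"):
            assert read_cohort(tmp_path / "c.csv", tmp_path / "s.csv") == []

    def test_missing_column_rejected(self, tmp_path):
        (tmp_path / "c.csv").write_text("worker_id,birth_year\n")
        (tmp_path / "s.csv").write_text("worker_id,area,start_date,end_date\n")
        with pytest.raises(InvalidRecordError, match="missing columns"):
            read_cohort(tmp_path / "c.csv", tmp_path / "s.csv")


class TestConcentrationTable:
    def test_decade_block_lookup(self, conc):
        assert conc.value("tunneling", 1975) == 72.6
        assert conc.value("helping", 2005) == 0.2
        assert conc.value("mining", 1989) == 64.0

    def test_exact_year_overrides_block(self, conc):
        df = conc.to_frame()
        table = ConcentrationTable(
            [tuple(r) for r in df.to_records(index=False)]
            + [("tunneling", 1975, 1975, 99.0, None)]
        )
        assert table.value("tunneling", 1975) == 99.0
        assert table.value("tunneling", 1976) == 72.6

    def test_csv_round_trip(self, conc, tmp_path):
        conc.to_csv(tmp_path / "conc.csv")
        back = ConcentrationTable.from_csv(tmp_path / "conc.csv")
        for area in Area:
            for year in (1970, 1985, 1999, 2011):
                assert back.value(area, year) == conc.value(area, year)

    def test_gsd_backsolved_from_sd_columns(self, conc):
        gm, gsd = conc.lookup("tunneling", 1972)
        assert gm == 72.6
        # +1 SD / -1 SD columns are 218.4 and 24.2
        assert gsd == pytest.approx((218.4 / 24.2) ** 0.5)
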