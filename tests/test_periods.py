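import numpy as np
import pandas as pd
import pytest

from conftest import diagnoses_frame, purchases_frame
from hcepi.periods import STUDY_END, build_periods, censor_by_pregnancy, first_usage_periods
from hcepi.simulate import EPOCH, make_fixture
from oracles import day_grid_periods, oracle_covered_days


def one(df):
    assert len(df) == 1
    return df.iloc[0]


class TestBuildPeriods:
    def test_single_purchase_inclusive_interval(self):
        p = build_periods(purchases_frame([("P1", "2010-01-01", "G03AA12", 3)]))
        row = one(p)
        assert row["start_date"] == pd.Timestamp("2010-01-01")
        assert row["end_date"] == pd.Timestamp("2010-03-25")
        assert row["length_days"] == 84

    def test_gap_89_merges_gap_90_splits(self):
        merged = build_periods(make_fixture("gap_merge_89_days").purchases)
        assert len(merged) == 1 and one(merged)["n_purchases"] == 2
        split = build_periods(make_fixture("gap_split_90_days").purchases)
        assert len(split) == 2

    def test_clock_reset_on_refill(self):
        # second purchase 10 days in: coverage runs from the refill date
        p = build_periods(
            purchases_frame(
                [("P1", "2010-01-01", "G03AA12", 1), ("P1", "2010-01-11", "G03AA12", 1)]
            )
        )
        assert one(p)["end_date"] == pd.Timestamp("2010-01-11") + pd.Timedelta(days=27)

    def test_additive_carry_over_mode(self):
        p = build_periods(
            purchases_frame(
                [("P1", "2010-01-01", "G03AA12", 1), ("P1", "2010-01-11", "G03AA12", 1)]
            ),
            coverage_mode="carry",
        )
        # 18 unused days carry over: end = Jan 28 + 28
        assert one(p)["end_date"] == pd.Timestamp("2010-01-28") + pd.Timedelta(days=28)

    def test_same_day_purchases_sum_coverage(self):
        p = build_periods(
            purchases_frame(
                [("P1", "2010-01-01", "G03AA12", 1), ("P1", "2010-01-01", "G03AA12", 2)]
            )
        )
        assert one(p)["length_days"] == 84

    def test_formulation_switch_truncates_to_day_before(self):
        p = build_periods(make_fixture("switch_truncation").purchases)
        assert len(p) == 2
        assert p.iloc[0]["censor_reason"] == "formulation_switch"
        assert p.iloc[0]["end_date"] == pd.Timestamp("2010-01-10")
        assert p.iloc[1]["start_date"] == pd.Timestamp("2010-01-11")

    def test_iud_period_length(self):
        p = build_periods(purchases_frame([("P1", "2010-06-01", "G02BA03", 1, "52 mg")]))
        assert one(p)["length_days"] == 2190

    def test_study_end_truncation(self):
        p = build_periods(purchases_frame([("P1", "2022-10-01", "G03AA12", 6)]))
        row = one(p)
        assert row["end_date"] == STUDY_END
        assert row["censor_reason"] == "study_end"

    def test_age_limit_truncation_at_year_end(self):
        parts = pd.DataFrame({"participant_id": ["P1"], "birth_year": [1967]})
        p = build_periods(
            purchases_frame([("P1", "2022-06-01", "G02BA03", 1, "52 mg")]),
            participants=parts,
            study_end=pd.Timestamp("2030-12-31"),
        )
        row = one(p)
        assert row["end_date"] == pd.Timestamp("2022-12-31")  # turns 56 in 2023
        assert row["censor_reason"] == "age_limit"

    def test_non_overlap_invariant(self, clean_cohort):
        from hcepi.prepare import prepare_purchases

        prep = prepare_purchases(
            clean_cohort.purchases, clean_cohort.participants, clean_cohort.bmi
        )
        periods = build_periods(prep.purchases, participants=prep.participants)
        for _, grp in periods.groupby("participant_id"):
            g = grp.sort_values("start_date")
            starts = g["start_date"].to_numpy()[1:]
            ends = g["end_date"].to_numpy()[:-1]
            assert (starts > ends).all()

    def test_purchase_dates_inside_period(self, clean_cohort):
        from hcepi.prepare import prepare_purchases

        prep = prepare_purchases(
            clean_cohort.purchases, clean_cohort.participants, clean_cohort.bmi
        )
        periods = build_periods(prep.purchases, participants=prep.participants)
        for row in periods.itertuples(index=False):
            dates = list(row.purchase_dates)
            assert dates == sorted(dates)
            assert row.start_date <= dates[0] and dates[-1] <= row.end_date


class TestPregnancyCensoring:
    def test_ends_at_diagnosis_date(self):
        fx = make_fixture("pregnancy_censor")
        p = censor_by_pregnancy(build_periods(fx.purchases), fx.diagnoses)
        row = one(p)
        assert row["end_date"] == pd.Timestamp("2010-02-01")
        assert row["censor_reason"] == "pregnancy"

    def test_puerperium_codes_never_censor(self):
        purchases = purchases_frame([("P1", "2010-01-01", "G03AA12", 3)])
        dx = diagnoses_frame([("P1", "2010-02-01", "O86")])
        p = censor_by_pregnancy(build_periods(purchases), dx)
        assert one(p)["censor_reason"] == "none"

    def test_code_on_start_date_collapses_to_one_day(self):
        purchases = purchases_frame([("P1", "2010-01-01", "G03AA12", 3)])
        dx = diagnoses_frame([("P1", "2010-01-01", "O04")])
        row = one(censor_by_pregnancy(build_periods(purchases), dx))
        assert row["length_days"] == 1

    def test_earliest_qualifying_code_wins(self):
        purchases = purchases_frame([("P1", "2010-01-01", "G03AA12", 6)])
        dx = diagnoses_frame(
            [("P1", "2010-04-01", "O20"), ("P1", "2010-02-15", "O03"), ("P1", "2009-12-01", "O04")]
        )
        assert one(censor_by_pregnancy(build_periods(purchases), dx))["end_date"] == pd.Timestamp(
            "2010-02-15"
        )

    def test_censoring_is_monotone(self, clean_cohort):
        from hcepi.prepare import prepare_purchases

        prep = prepare_purchases(
            clean_cohort.purchases, clean_cohort.participants, clean_cohort.bmi
        )
        raw = build_periods(prep.purchases, participants=prep.participants)
        cen = censor_by_pregnancy(raw, clean_cohort.diagnoses)
        assert (cen["start_date"] == raw["start_date"]).all()
        assert (cen["end_date"] <= raw["end_date"]).all()


class TestFirstUsagePeriod:
    def test_earliest_start_selected(self):
        p = build_periods(make_fixture("gap_split_90_days").purchases)
        first = first_usage_periods(p)
        assert one(first)["start_date"] == p["start_date"].min()

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            first_usage_periods(pd.DataFrame(columns=["participant_id", "start_date"]))


class TestDayGridOracle:
    """build_periods must agree with a brute-force day-grid simulation."""

    KEYS = ["G03AA12", "G03AC09", "G03AC03"]

    def _random_case(self, rng):
        n = int(rng.integers(1, 6))
        days = sorted(rng.choice(1096, size=n, replace=False).tolist())
        purchases, oracle_input = [], []
        for d in days:
            key = self.KEYS[int(rng.integers(0, len(self.KEYS)))]
            dosage = float(rng.choice([0.5, 1.0, 2.0, 3.0, 6.0]))
            purchases.append(("P1", (EPOCH + pd.Timedelta(days=int(d))).date().isoformat(), key, dosage))
            oracle_input.append((int(d), key, oracle_covered_days(key, dosage)))
        preg_days = rng.choice(1300, size=int(rng.integers(0, 3)), replace=False).tolist()
        return purchases, oracle_input, sorted(int(d) for d in preg_days)

    def test_matches_on_randomized_fixtures(self):
        rng = np.random.default_rng(2024)
        horizon = (STUDY_END - EPOCH).days
        for _ in range(300):
            purchases, oracle_input, preg_days = self._random_case(rng)
            dx = diagnoses_frame(
                [("P1", (EPOCH + pd.Timedelta(days=d)).date().isoformat(), "O04") for d in preg_days]
            )
            got = censor_by_pregnancy(build_periods(purchases_frame(purchases)), dx)
            expected = day_grid_periods(
                oracle_input, horizon=horizon, pregnancy_days=preg_days
            )
            assert len(got) == len(expected)
            for row, (key, start, end, censor) in zip(got.itertuples(index=False), expected):
                assert row.formulation_key == key
                assert (row.start_date - EPOCH).days == start
                assert (row.end_date - EPOCH).days == end
                assert row.censor_reason == censor
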