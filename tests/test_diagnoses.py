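import pandas as pd
import pytest

from conftest import diagnoses_frame, purchases_frame
from hcepi.classify import RapidSwitchEvent
from hcepi.diagnoses import (
    abortion_overlap,
    first_ever_diagnoses_during_use,
    pre_initiation_diagnoses,
    switch_gap_diagnoses,
    thrombosis_during_use,
)
from hcepi.periods import build_periods
from hcepi.registry import CodeSet, default_registry


def shift_all(df, days, cols):
    out = df.copy()
    for col in cols:
        out[col] = out[col] + pd.Timedelta(days=days)
    return out


class TestPreInitiation:
    def setup_method(self):
        self.first = {"start_date": pd.Timestamp("2010-04-01")}

    def test_code_in_window_included(self):
        dx = diagnoses_frame([("P1", "2010-03-22", "Z30")])
        codes, no_record = pre_initiation_diagnoses(self.first, dx)
        assert codes == {"Z30"} and not no_record

    @pytest.mark.parametrize(
        "date,included",
        [
            ("2010-01-01", True),    # start - 90, boundary
            ("2009-12-31", False),   # start - 91
            ("2010-03-31", True),    # start - 1
            ("2010-04-01", False),   # on the start date
        ],
    )
    def test_window_boundaries(self, date, included):
        codes, _ = pre_initiation_diagnoses(self.first, diagnoses_frame([("P1", date, "N92")]))
        assert ("N92" in codes) == included

    def test_empty_history_flagged(self):
        codes, no_record = pre_initiation_diagnoses(self.first, diagnoses_frame([]))
        assert codes == set() and no_record


class TestFirstEverDuringUse:
    def periods(self):
        return build_periods(purchases_frame([("P1", "2010-01-01", "G03AA12", 3)]))

    def test_new_code_in_period_included(self):
        dx = diagnoses_frame([("P1", "2010-02-01", "N94")])
        assert first_ever_diagnoses_during_use(self.periods(), dx) == [{"N94"}]

    def test_pre_existing_code_excluded_even_if_repeated(self):
        dx = diagnoses_frame([("P1", "2008-01-01", "N94"), ("P1", "2010-02-01", "N94")])
        assert first_ever_diagnoses_during_use(self.periods(), dx) == [set()]

    def test_post_window_boundary(self):
        # period ends 2010-03-25; end+90 = 2010-06-23
        assert first_ever_diagnoses_during_use(
            self.periods(), diagnoses_frame([("P1", "2010-06-23", "G43")])
        ) == [{"G43"}]
        assert first_ever_diagnoses_during_use(
            self.periods(), diagnoses_frame([("P1", "2010-06-24", "G43")])
        ) == [set()]

    def test_history_monotone(self):
        dx = diagnoses_frame([("P1", "2010-02-01", "N94"), ("P1", "2010-02-05", "G43")])
        more_history = diagnoses_frame(
            [("P1", "2005-01-01", "N94"), ("P1", "2010-02-01", "N94"), ("P1", "2010-02-05", "G43")]
        )
        base = first_ever_diagnoses_during_use(self.periods(), dx)[0]
        with_history = first_ever_diagnoses_during_use(self.periods(), more_history)[0]
        assert with_history <= base


class TestSwitchGap:
    def event(self):
        return RapidSwitchEvent(
            pre_key="G03AA12",
            post_key="G03AC09",
            gap_days=20,
            pre_length_days=28,
            pre_first_purchase=pd.Timestamp("2010-01-01"),
            post_first_purchase=pd.Timestamp("2010-02-17"),
        )

    def test_first_ever_panel_code_flags(self):
        dx = diagnoses_frame([("P1", "2010-02-01", "N92")])
        (res,) = switch_gap_diagnoses([self.event()], dx)
        assert res["codes"] == {"N92"} and res["side_effect_flag"]

    def test_endpoints_inclusive(self):
        for date in ("2010-01-01", "2010-02-17"):
            (res,) = switch_gap_diagnoses([self.event()], diagnoses_frame([("P1", date, "L70")]))
            assert res["side_effect_flag"]

    def test_no_codes_unflagged(self):
        (res,) = switch_gap_diagnoses([self.event()], diagnoses_frame([("P1", "2012-01-01", "N92")]))
        assert res["codes"] == set() and not res["side_effect_flag"]

    def test_pre_existing_panel_code_unflagged(self):
        dx = diagnoses_frame([("P1", "2009-01-01", "N92"), ("P1", "2010-02-01", "N92")])
        (res,) = switch_gap_diagnoses([self.event()], dx)
        assert not res["side_effect_flag"]

    def test_subcode_matches_category_panel_entry(self):
        (res,) = switch_gap_diagnoses(
            [self.event()], diagnoses_frame([("P1", "2010-02-01", "N92.0")])
        )
        assert res["side_effect_flag"]

    def test_registry_override_changes_membership_only(self):
        registry = default_registry().with_set(
            "side_effect_panel", CodeSet.from_entries("side_effect_panel", codes=["R51"])
        )
        dx = diagnoses_frame([("P1", "2010-02-01", "N92")])
        (res,) = switch_gap_diagnoses([self.event()], dx, registry=registry)
        assert res["codes"] == {"N92"} and not res["side_effect_flag"]


class TestAbortionOverlap:
    def test_inside_coverage_with_next_period_gap(self):
        purchases = purchases_frame(
            [("P1", "2010-01-01", "G03AA12", 3), ("P1", "2010-07-01", "G03AC09", 3)]
        )
        periods = build_periods(purchases)
        dx = diagnoses_frame([("P1", "2010-02-01", "O04")])
        events = abortion_overlap(periods, dx)
        assert len(events) == 1
        assert events.iloc[0]["days_to_next_formulation"] == (
            pd.Timestamp("2010-07-01") - pd.Timestamp("2010-02-01")
        ).days

    def test_outside_coverage_no_event(self):
        periods = build_periods(purchases_frame([("P1", "2010-01-01", "G03AA12", 3)]))
        events = abortion_overlap(periods, diagnoses_frame([("P1", "2011-01-01", "O04")]))
        assert len(events) == 0

    def test_non_abortion_pregnancy_codes_ignored(self):
        periods = build_periods(purchases_frame([("P1", "2010-01-01", "G03AA12", 3)]))
        events = abortion_overlap(periods, diagnoses_frame([("P1", "2010-02-01", "O03")]))
        assert len(events) == 0


class TestThrombosisDuringUse:
    def test_event_and_antithrombotic_in_period(self):
        periods = build_periods(purchases_frame([("P1", "2010-01-01", "G03AA12", 6)]))
        dx = diagnoses_frame([("P1", "2010-03-01", "I80.2")])
        b01a = purchases_frame([("P1", "2010-03-11", "B01AF01", 1)])
        row = thrombosis_during_use(periods, dx, b01a).iloc[0]
        assert row["event_in_period"] and row["antithrombotic_while_active"]

    def test_antithrombotic_after_period_end_does_not_count(self):
        periods = build_periods(purchases_frame([("P1", "2010-01-01", "G03AA12", 3)]))
        dx = diagnoses_frame([("P1", "2010-03-01", "I80.2")])
        b01a = purchases_frame([("P1", "2010-05-01", "B01AF01", 1)])
        row = thrombosis_during_use(periods, dx, b01a).iloc[0]
        assert row["event_in_period"] and not row["antithrombotic_while_active"]

    def test_no_codes_both_false(self):
        periods = build_periods(purchases_frame([("P1", "2010-01-01", "G03AA12", 3)]))
        row = thrombosis_during_use(periods, diagnoses_frame([]), None).iloc[0]
        assert not row["event_in_period"] and not row["antithrombotic_while_active"]


class TestTranslationInvariance:
    def test_all_window_logic_shifts_with_dates(self):
        purchases = purchases_frame(
            [("P1", "2010-01-01", "G03AA12", 3), ("P1", "2010-07-01", "G03AC09", 3)]
        )
        dx = diagnoses_frame(
            [("P1", "2009-11-01", "Z30"), ("P1", "2010-02-01", "N92"), ("P1", "2010-02-10", "O04")]
        )
        shift = 37
        periods0 = build_periods(purchases)
        shifted_purchases = purchases.copy()
        shifted_purchases["purchase_date"] += pd.Timedelta(days=shift)
        periods1 = build_periods(shifted_purchases)
        dx1 = shift_all(dx, shift, ["date"])

        pre0, _ = pre_initiation_diagnoses({"start_date": periods0.iloc[0]["start_date"]}, dx)
        pre1, _ = pre_initiation_diagnoses({"start_date": periods1.iloc[0]["start_date"]}, dx1)
        assert pre0 == pre1

        fe0 = first_ever_diagnoses_during_use(periods0, dx)
        fe1 = first_ever_diagnoses_during_use(periods1, dx1)
        assert fe0 == fe1

        ab0 = abortion_overlap(periods0, dx)
        ab1 = abortion_overlap(periods1, dx1)
        assert ab0["days_to_next_formulation"].tolist() == ab1["days_to_next_formulation"].tolist()
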