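"""Construction of contiguous exposure episodes ("usage periods") from
filtered purchase records.

A usage period is a maximal run of purchases of the same formulation in
which consecutive purchase dates are less than 90 days apart; drug-free
days inside the run belong to the period.  Periods are closed intervals of
calendar days:

* the period starts on the first purchase date of the run;
* each purchase resets the coverage clock — the period ends on
  ``last purchase date + covered_days - 1`` — except that same-day
  purchases of the same formulation sum their covered days (multi-package
  buys split across invoices).  The alternative additive carry-over rule
  is available via ``coverage_mode="carry"``;
* a purchase of a *different* formulation while the previous period is
  still covered truncates it to the day before (minimum one-day period,
  censor reason ``formulation_switch``) and always opens a new period;
* periods are truncated at the study end (censor ``study_end``) and at the
  end of the calendar year in which the participant turns 56, i.e. the
  last year with age <= 55 under the year-subtraction age convention
  (censor ``age_limit``);
* pregnancy censoring (ICD-10 O00-O99 excluding O85-O92) ends a period on
  the earliest qualifying diagnosis date inside it, without backdating; a
  code on the start date collapses the period to a single day.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .catalog import FormulationCatalog, default_catalog
from .registry import CodeRegistry, default_registry

__all__ = [
    "build_periods",
    "censor_by_pregnancy",
    "first_usage_periods",
    "STUDY_END",
    "PERIOD_COLUMNS",
]

STUDY_END = pd.Timestamp("2022-12-31")

PERIOD_COLUMNS = [
    "participant_id",
    "formulation_key",
    "atc5",
    "route",
    "start_date",
    "end_date",
    "length_days",
    "n_purchases",
    "first_purchase_date",
    "last_purchase_date",
    "purchase_dates",
    "censor_reason",
]


@dataclass
class _Open:
    key: str
    atc5: str
    route: str
    start: pd.Timestamp
    coverage_end: pd.Timestamp
    purchase_dates: list


def _close(cur: _Open, end: pd.Timestamp, reason: str, pid) -> dict:
    end = max(end, cur.start)  # minimum one-day period
    return {
        "participant_id": pid,
        "formulation_key": cur.key,
        "atc5": cur.atc5,
        "route": cur.route,
        "start_date": cur.start,
        "end_date": end,
        "length_days": (end - cur.start).days + 1,
        "n_purchases": len(cur.purchase_dates),
        "first_purchase_date": cur.purchase_dates[0],
        "last_purchase_date": cur.purchase_dates[-1],
        "purchase_dates": tuple(cur.purchase_dates),
        "censor_reason": "none" if reason == "none" else reason,
    }


def _truncate(row: dict, study_end: pd.Timestamp, age_end: Optional[pd.Timestamp]) -> dict:
    limit, reason = study_end, "study_end"
    if age_end is not None and age_end < limit:
        limit, reason = age_end, "age_limit"
    if row["end_date"] > limit and row["censor_reason"] == "none":
        end = max(limit, row["start_date"])
        row = dict(row)
        row["end_date"] = end
        row["length_days"] = (end - row["start_date"]).days + 1
        row["censor_reason"] = reason
    return row


def build_periods(
    purchases: pd.DataFrame,
    catalog: Optional[FormulationCatalog] = None,
    gap_days: int = 90,
    study_end: pd.Timestamp = STUDY_END,
    participants: Optional[pd.DataFrame] = None,
    age_limit: int = 55,
    coverage_mode: str = "reset",
) -> pd.DataFrame:
    """Build usage periods for every participant in ``purchases``.

    ``purchases`` must already have passed the filtering cascade.  When
    ``participants`` (with ``birth_year``) is given, periods are truncated
    at the end of the last calendar year with age <= ``age_limit``.
    """
    if coverage_mode not in ("reset", "carry"):
        raise ValueError("coverage_mode must be 'reset' or 'carry'")
    catalog = catalog or default_catalog()
    study_end = pd.Timestamp(study_end)

    birth: dict = {}
    if participants is not None:
        birth = dict(
            zip(participants["participant_id"], participants["birth_year"].astype(int))
        )

    spec_cache: dict[str, tuple] = {}

    def resolve(code: str):
        hit = spec_cache.get(code)
        if hit is None:
            spec = catalog.lookup(code)
            hit = (spec.formulation_key, spec.atc5, spec.route, spec)
            spec_cache[code] = hit
        return hit

    df = purchases.copy()
    df["purchase_date"] = pd.to_datetime(df["purchase_date"])
    df = df.sort_values(["participant_id", "purchase_date"], kind="stable")

    rows: list[dict] = []
    for pid, grp in df.groupby("participant_id", sort=True):
        age_end = None
        if pid in birth:
            age_end = pd.Timestamp(year=birth[pid] + age_limit, month=12, day=31)
        cur: Optional[_Open] = None
        for rec in grp.itertuples(index=False):
            key, atc5, route, spec = resolve(rec.purchased_atc)
            label = getattr(rec, "iud_dose_label", None)
            if isinstance(label, float):
                label = None
            cd = catalog.covered_days(rec.purchased_atc, float(rec.dosage), label)
            date = rec.purchase_date
            cov_end = date + pd.Timedelta(days=cd - 1)
            if cur is None:
                cur = _Open(key, atc5, route, date, cov_end, [date])
            elif key == cur.key and (date - cur.purchase_dates[-1]).days < gap_days:
                if date == cur.purchase_dates[-1]:
                    # same-day multi-invoice buy: covered days accumulate
                    cur.coverage_end = cur.coverage_end + pd.Timedelta(days=cd)
                elif coverage_mode == "carry":
                    base = max(cur.coverage_end, date - pd.Timedelta(days=1))
                    cur.coverage_end = base + pd.Timedelta(days=cd)
                    cur.purchase_dates.append(date)
                else:
                    cur.coverage_end = cov_end
                    cur.purchase_dates.append(date)
            elif key == cur.key:
                # >= gap_days pause: a new period of the same formulation
                rows.append(
                    _truncate(_close(cur, cur.coverage_end, "none", pid), study_end, age_end)
                )
                cur = _Open(key, atc5, route, date, cov_end, [date])
            else:
                # different formulation always starts a new period and
                # truncates a still-covered one to the day before
                if date <= cur.coverage_end:
                    rows.append(
                        _truncate(
                            _close(cur, date - pd.Timedelta(days=1), "formulation_switch", pid),
                            study_end,
                            age_end,
                        )
                    )
                else:
                    rows.append(
                        _truncate(_close(cur, cur.coverage_end, "none", pid), study_end, age_end)
                    )
                cur = _Open(key, atc5, route, date, cov_end, [date])
        if cur is not None:
            rows.append(
                _truncate(_close(cur, cur.coverage_end, "none", pid), study_end, age_end)
            )
    out = pd.DataFrame(rows, columns=PERIOD_COLUMNS)
    return out


def censor_by_pregnancy(
    periods: pd.DataFrame,
    diagnoses: pd.DataFrame,
    registry: Optional[CodeRegistry] = None,
) -> pd.DataFrame:
    """Censor periods at the earliest pregnancy diagnosis they contain.

    Only codes in the registry's ``pregnancy`` set qualify (O00-O99
    excluding O85-O92).  Censoring never lengthens a period nor moves its
    start; a qualifying code on the start date yields a one-day period.
    """
    registry = registry or default_registry()
    preg_set = registry.codeset("pregnancy")
    if len(periods) == 0 or len(diagnoses) == 0:
        return periods.copy()
    dx = diagnoses.copy()
    dx["date"] = pd.to_datetime(dx["date"])
    dx = dx[[c in preg_set for c in dx["icd10"]]]
    by_pid = {pid: grp["date"].sort_values().to_numpy() for pid, grp in dx.groupby("participant_id")}

    out = periods.copy()
    new_end, new_reason = [], []
    for row in out.itertuples(index=False):
        dates = by_pid.get(row.participant_id)
        end, reason = row.end_date, row.censor_reason
        if dates is not None:
            inside = dates[(dates >= row.start_date.to_datetime64()) & (dates <= row.end_date.to_datetime64())]
            if len(inside):
                end = pd.Timestamp(inside[0])
                reason = "pregnancy"
        new_end.append(end)
        new_reason.append(reason)
    out["end_date"] = new_end
    out["censor_reason"] = new_reason
    out["length_days"] = (out["end_date"] - out["start_date"]).dt.days + 1
    return out


def first_usage_periods(periods: pd.DataFrame) -> pd.DataFrame:
    """The initiation period: each participant's earliest-starting period."""
    if len(periods) == 0:
        raise ValueError("no usage periods")
    idx = periods.groupby("participant_id")["start_date"].idxmin()
    return periods.loc[idx].reset_index(drop=True)
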