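"""Linking ICD-10 diagnosis records to usage periods.

Four questions, all answered over closed day windows:

* which diagnoses precede HC initiation (the 90 days before the first
  period's start) — candidate non-contraceptive reasons for starting;
* which *first-time-ever* diagnoses fall inside a usage period or within
  90 days after its end — candidate side effects / reasons to stop.  The
  first-ever restriction uses the participant's entire diagnosis history,
  so pre-existing conditions repeated during use never qualify;
* which first-ever diagnoses fall between the first purchase of the
  pre-switch formulation and the first purchase of the new formulation in
  rapid switchers, and whether any belongs to the side-effect panel;
* which medical-abortion codes (O04) fall inside the *original* (i.e.
  pre-pregnancy-censoring) coverage of a period, and how long until the
  next formulation;
* whether a thromboembolism code occurs during a usage period and, if so,
  whether an antithrombotic (ATC B01A) was purchased after the event
  while the period was still running.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import RapidSwitchEvent
from .registry import CodeRegistry, atc_matches, default_registry

__all__ = [
    "pre_initiation_diagnoses",
    "first_ever_dates",
    "first_ever_diagnoses_during_use",
    "switch_gap_diagnoses",
    "abortion_overlap",
    "thrombosis_during_use",
    "NO_RECORD_FLAG",
]

NO_RECORD_FLAG = "no_medical_condition_record"


def _dx_norm(diagnoses: pd.DataFrame) -> pd.DataFrame:
    dx = diagnoses.copy()
    dx["date"] = pd.to_datetime(dx["date"])
    return dx


def pre_initiation_diagnoses(
    first_period: pd.Series | dict,
    diagnoses: pd.DataFrame,
    window_days: int = 90,
) -> tuple[set, bool]:
    """Codes recorded in the ``window_days`` before the first period start.

    Returns ``(codes, no_record)`` where the window is the closed interval
    [start - window_days, start - 1] and ``no_record`` flags an empty set.
    """
    start = pd.Timestamp(first_period["start_date"])
    lo = start - pd.Timedelta(days=window_days)
    hi = start - pd.Timedelta(days=1)
    if len(diagnoses) == 0:
        return set(), True
    dx = _dx_norm(diagnoses)
    hit = dx[(dx["date"] >= lo) & (dx["date"] <= hi)]
    codes = set(hit["icd10"])
    return codes, len(codes) == 0


def first_ever_dates(diagnoses: pd.DataFrame) -> pd.Series:
    """Earliest occurrence date of each code in one participant's history."""
    dx = _dx_norm(diagnoses)
    return dx.groupby("icd10")["date"].min()


def first_ever_diagnoses_during_use(
    periods: pd.DataFrame,
    diagnoses: pd.DataFrame,
    post_window_days: int = 90,
) -> list[set]:
    """Per period: codes whose first-ever date is in [start, end + 90].

    ``diagnoses`` must be the participant's full history — adding earlier
    history can only remove codes from the result.
    """
    if len(diagnoses) == 0:
        return [set() for _ in range(len(periods))]
    firsts = first_ever_dates(diagnoses)
    out = []
    for r in periods.itertuples(index=False):
        hi = r.end_date + pd.Timedelta(days=post_window_days)
        mask = (firsts >= r.start_date) & (firsts <= hi)
        out.append(set(firsts.index[mask]))
    return out


def switch_gap_diagnoses(
    events: Sequence[RapidSwitchEvent],
    diagnoses: pd.DataFrame,
    registry: Optional[CodeRegistry] = None,
) -> list[dict]:
    """First-ever codes between the two first-purchase dates of each
    rapid-switch event, with a side-effect-panel flag.

    Both window endpoints (the purchase dates themselves) are inclusive.
    """
    registry = registry or default_registry()
    panel = registry.codeset("side_effect_panel")
    firsts = first_ever_dates(diagnoses) if len(diagnoses) else pd.Series(dtype="datetime64[ns]")
    out = []
    for e in events:
        lo, hi = pd.Timestamp(e.pre_first_purchase), pd.Timestamp(e.post_first_purchase)
        mask = (firsts >= lo) & (firsts <= hi)
        codes = set(firsts.index[mask])
        out.append(
            {
                "event": e,
                "codes": codes,
                "side_effect_flag": any(c in panel for c in codes),
            }
        )
    return out


def abortion_overlap(
    periods_uncensored: pd.DataFrame,
    diagnoses: pd.DataFrame,
    registry: Optional[CodeRegistry] = None,
) -> pd.DataFrame:
    """Medical-abortion codes inside original coverage intervals.

    ``periods_uncensored`` must be the period table *before* pregnancy
    censoring so the original coverage is intact.  For each overlap event
    the days to the next period start (any formulation) are reported; NaN
    when no later period exists.
    """
    registry = registry or default_registry()
    ab = registry.codeset("abortion")
    rows = []
    if len(diagnoses) == 0:
        return pd.DataFrame(
            columns=["participant_id", "abortion_date", "period_start", "formulation_key", "days_to_next_formulation"]
        )
    dx = _dx_norm(diagnoses)
    dx = dx[[c in ab for c in dx["icd10"]]]
    for pid, grp in periods_uncensored.groupby("participant_id", sort=True):
        events = dx[dx["participant_id"] == pid]
        if len(events) == 0:
            continue
        starts = grp["start_date"].sort_values().to_numpy()
        for r in grp.itertuples(index=False):
            inside = events[(events["date"] >= r.start_date) & (events["date"] <= r.end_date)]
            for d in inside["date"]:
                later = starts[starts > np.datetime64(d)]
                gap = (pd.Timestamp(later[0]) - d).days if len(later) else np.nan
                rows.append(
                    {
                        "participant_id": pid,
                        "abortion_date": d,
                        "period_start": r.start_date,
                        "formulation_key": r.formulation_key,
                        "days_to_next_formulation": gap,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["participant_id", "abortion_date", "period_start", "formulation_key", "days_to_next_formulation"],
    )


def thrombosis_during_use(
    periods: pd.DataFrame,
    diagnoses: pd.DataFrame,
    purchases: Optional[pd.DataFrame] = None,
    registry: Optional[CodeRegistry] = None,
) -> pd.DataFrame:
    """Per-user flags: thromboembolism during a usage period, and an
    antithrombotic purchase after the event while the period still ran.

    ``purchases`` is the raw purchase table (it may contain non-HC rows;
    only ATC B01A rows are consulted).
    """
    registry = registry or default_registry()
    vte = registry.codeset("vte_ate")
    b01a = registry.prefixes("antithrombotics")
    dx = _dx_norm(diagnoses) if len(diagnoses) else pd.DataFrame(columns=["participant_id", "date", "icd10"])
    dx = dx[[c in vte for c in dx["icd10"]]] if len(dx) else dx
    anti = pd.DataFrame(columns=["participant_id", "purchase_date"])
    if purchases is not None and len(purchases):
        mask = [atc_matches(c, b01a) for c in purchases["purchased_atc"]]
        anti = purchases.loc[mask, ["participant_id", "purchase_date"]].copy()
        anti["purchase_date"] = pd.to_datetime(anti["purchase_date"])
    rows = []
    for pid, grp in periods.groupby("participant_id", sort=True):
        events = dx[dx["participant_id"] == pid].sort_values("date") if len(dx) else dx
        event_date, in_period_end = None, None
        for r in grp.sort_values("start_date", kind="stable").itertuples(index=False):
            inside = events[(events["date"] >= r.start_date) & (events["date"] <= r.end_date)] if len(events) else events
            if len(inside):
                event_date = inside["date"].iloc[0]
                in_period_end = r.end_date
                break
        anti_flag = False
        if event_date is not None and len(anti):
            mine = anti[anti["participant_id"] == pid]
            anti_flag = bool(
                ((mine["purchase_date"] > event_date) & (mine["purchase_date"] <= in_period_end)).any()
            )
        rows.append(
            {
                "participant_id": pid,
                "event_in_period": event_date is not None,
                "event_date": event_date,
                "antithrombotic_while_active": anti_flag,
            }
        )
    return pd.DataFrame(rows)
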