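"""Classification of users by formulation-switching behaviour.

From each participant's ordered usage periods the classifier derives:

* **broad switcher** — used two or more different formulations;
* **rapid switcher** — a subset of broad switchers: some consecutive pair
  of different-formulation periods has an inter-period gap of at most 90
  days *and* a pre-switch period shorter than 90 days;
* **non-switcher** — one formulation only, with at least one period longer
  than 180 days;
* **rapid discontinuer** — exactly one period of one formulation, shorter
  than 90 days, verified by (i) any diagnosis record after the first
  purchase date (evidence the person remained in the health system) and
  (ii) a first purchase more than 90 days before the study end (so the
  short period is not an observation-window artefact);
* **unclassified** — everything else, e.g. a single period of 90-180 days.

The gap between periods is measured from the end of the earlier period to
the start of the later one; the pre-switch length criterion applies to any
consecutive different-formulation pair, and a user may contribute several
rapid-switch events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .periods import STUDY_END

__all__ = [
    "RapidSwitchEvent",
    "UserClassification",
    "classify_user",
    "classify_cohort",
    "classification_table",
    "cohort_classification_summary",
    "extract_rapid_switch_flows",
]

LABELS = ("non_switcher", "broad_switcher", "rapid_switcher", "rapid_discontinuer", "unclassified")


@dataclass(frozen=True)
class RapidSwitchEvent:
    pre_key: str
    post_key: str
    gap_days: int
    pre_length_days: int
    pre_first_purchase: pd.Timestamp
    post_first_purchase: pd.Timestamp


@dataclass
class UserClassification:
    participant_id: object
    n_formulations: int
    labels: frozenset
    rapid_switch_events: list = field(default_factory=list)
    time_to_switch_days: list = field(default_factory=list)

    def __post_init__(self):
        if not self.labels:
            raise ValueError("labels must never be empty")


def classify_user(
    periods: pd.DataFrame,
    diagnoses: Optional[pd.DataFrame] = None,
    study_end: pd.Timestamp = STUDY_END,
    rapid_gap_days: int = 90,
    rapid_pre_days: int = 90,
    nonswitcher_days: int = 180,
) -> UserClassification:
    """Classify one participant from her usage periods.

    ``diagnoses`` (any ICD-10 records of the participant) is used only for
    the rapid-discontinuer residency verification.
    """
    if len(periods) == 0:
        raise ValueError("cannot classify a participant without usage periods")
    p = periods.sort_values("start_date", kind="stable").reset_index(drop=True)
    pid = p["participant_id"].iloc[0]
    keys = p["formulation_key"].tolist()
    n_form = len(set(keys))

    events: list[RapidSwitchEvent] = []
    gaps: list[int] = []
    for i in range(len(p) - 1):
        if keys[i] == keys[i + 1]:
            continue
        gap = (p["start_date"].iloc[i + 1] - p["end_date"].iloc[i]).days
        pre_len = int(p["length_days"].iloc[i])
        gaps.append(gap)
        if gap <= rapid_gap_days and pre_len < rapid_pre_days:
            events.append(
                RapidSwitchEvent(
                    pre_key=keys[i],
                    post_key=keys[i + 1],
                    gap_days=gap,
                    pre_length_days=pre_len,
                    pre_first_purchase=p["first_purchase_date"].iloc[i],
                    post_first_purchase=p["first_purchase_date"].iloc[i + 1],
                )
            )

    labels: set[str] = set()
    if n_form >= 2:
        labels.add("broad_switcher")
        if events:
            labels.add("rapid_switcher")
    else:
        long_period = bool((p["length_days"] > nonswitcher_days).any())
        if long_period:
            labels.add("non_switcher")
        elif len(p) == 1 and int(p["length_days"].iloc[0]) < 90:
            first_purchase = p["first_purchase_date"].iloc[0]
            has_later_dx = False
            if diagnoses is not None and len(diagnoses):
                dates = pd.to_datetime(diagnoses["date"])
                has_later_dx = bool((dates > first_purchase).any())
            window_ok = (pd.Timestamp(study_end) - first_purchase).days > 90
            if has_later_dx and window_ok:
                labels.add("rapid_discontinuer")
            else:
                labels.add("unclassified")
        else:
            labels.add("unclassified")

    return UserClassification(
        participant_id=pid,
        n_formulations=n_form,
        labels=frozenset(labels),
        rapid_switch_events=events,
        time_to_switch_days=gaps,
    )


def classify_cohort(
    periods: pd.DataFrame,
    diagnoses: Optional[pd.DataFrame] = None,
    study_end: pd.Timestamp = STUDY_END,
    **thresholds,
) -> list[UserClassification]:
    dx_by_pid = {}
    if diagnoses is not None and len(diagnoses):
        dx_by_pid = dict(tuple(diagnoses.groupby("participant_id")))
    return [
        classify_user(grp, dx_by_pid.get(pid), study_end=study_end, **thresholds)
        for pid, grp in periods.groupby("participant_id", sort=True)
    ]


def classification_table(classifications: Sequence[UserClassification]) -> pd.DataFrame:
    rows = []
    for c in classifications:
        row = {"participant_id": c.participant_id, "n_formulations": c.n_formulations}
        for label in LABELS:
            row[label] = label in c.labels
        row["n_rapid_switch_events"] = len(c.rapid_switch_events)
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_classification_summary(
    classifications: Sequence[UserClassification],
) -> pd.DataFrame:
    """Counts and shares per label over all users.

    Rapid switchers are a subset of broad switchers, so the table reports
    broad switchers both including and excluding rapid switchers; the
    disjoint rows (non-switcher, broad excl. rapid, rapid, rapid
    discontinuer, unclassified) sum to the number of users.
    """
    n = len(classifications)
    if n == 0:
        raise ValueError("no classifications")
    counts = {label: 0 for label in LABELS}
    broad_excl = 0
    for c in classifications:
        for label in LABELS:
            if label in c.labels:
                counts[label] += 1
        if "broad_switcher" in c.labels and "rapid_switcher" not in c.labels:
            broad_excl += 1
    rows = [
        {"label": label, "count": counts[label], "share": counts[label] / n}
        for label in LABELS
    ]
    rows.append(
        {"label": "broad_switcher_excl_rapid", "count": broad_excl, "share": broad_excl / n}
    )
    return pd.DataFrame(rows)


def extract_rapid_switch_flows(
    classifications: Sequence[UserClassification],
) -> pd.DataFrame:
    """Aggregate directed pre->post formulation flows of rapid switchers."""
    events = [e for c in classifications for e in c.rapid_switch_events]
    if not events:
        return pd.DataFrame(
            columns=["pre_formulation", "post_formulation", "count", "mean_gap_days", "mean_pre_length_days"]
        )
    df = pd.DataFrame(
        {
            "pre_formulation": [e.pre_key for e in events],
            "post_formulation": [e.post_key for e in events],
            "gap_days": [e.gap_days for e in events],
            "pre_length_days": [e.pre_length_days for e in events],
        }
    )
    out = (
        df.groupby(["pre_formulation", "post_formulation"], sort=True)
        .agg(
            count=("gap_days", "size"),
            mean_gap_days=("gap_days", "mean"),
            mean_pre_length_days=("pre_length_days", "mean"),
        )
        .reset_index()
    )
    return out
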