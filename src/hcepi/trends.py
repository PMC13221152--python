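"""Cohort-level use trends.

Annual age-stratified user prevalence, covered-day shares by
contraceptive-method type, initiator summaries, and monthly purchase
deviation ratios.

Conventions shared with the rest of the pipeline: age in year Y is
``Y - birth_year`` (year subtraction, no birthdays); the five age groups
are 15-19, 20-29, 30-39, 40-49 and 50-55; a user is *active* in a
calendar year for a contraceptive class if any usage period of that class
overlaps the year by at least one day, so long-acting methods keep a user
active in years without purchases.  Users active with both classes in a
year count in both.  Covered days of a period are apportioned to calendar
years by exact day overlap, and follow the year's age group as a user
ages across a period.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .catalog import FormulationCatalog, default_catalog
from .prepare import closest_bmi

__all__ = [
    "AGE_GROUPS",
    "age_group",
    "annual_prevalence",
    "covered_days_shares",
    "initiator_summary",
    "monthly_deviation_ratios",
]

AGE_GROUPS = ("15-19", "20-29", "30-39", "40-49", "50-55")
_BOUNDS = ((15, 19), (20, 29), (30, 39), (40, 49), (50, 55))


def age_group(age: int) -> Optional[str]:
    for (lo, hi), name in zip(_BOUNDS, AGE_GROUPS):
        if lo <= age <= hi:
            return name
    return None


def _period_years(periods: pd.DataFrame) -> pd.DataFrame:
    """Explode periods into one row per overlapped calendar year with the
    exact number of overlap days."""
    rows = []
    for r in periods.itertuples(index=False):
        start, end = r.start_date, r.end_date
        for year in range(start.year, end.year + 1):
            y0 = pd.Timestamp(year=year, month=1, day=1)
            y1 = pd.Timestamp(year=year, month=12, day=31)
            days = (min(end, y1) - max(start, y0)).days + 1
            rows.append(
                {
                    "participant_id": r.participant_id,
                    "formulation_key": r.formulation_key,
                    "atc5": r.atc5,
                    "route": r.route,
                    "year": year,
                    "overlap_days": days,
                }
            )
    return pd.DataFrame(rows)


def _attach_types(df: pd.DataFrame, catalog: FormulationCatalog) -> pd.DataFrame:
    info = {s.formulation_key: (s.hc_type, s.hc_class) for s in catalog}
    df = df.copy()
    df["hc_type"] = [info[k][0] for k in df["formulation_key"]]
    df["hc_class"] = [info[k][1] for k in df["formulation_key"]]
    return df


def annual_prevalence(
    periods: pd.DataFrame,
    participants: pd.DataFrame,
    denominators: Optional[pd.DataFrame] = None,
    catalog: Optional[FormulationCatalog] = None,
) -> pd.DataFrame:
    """Annual prevalence of active users per (year, age group, HC class).

    The denominator defaults to all participants (users and non-users) of
    the age group in the year; an external table with columns
    ``year, age_group, n`` overrides it.
    """
    catalog = catalog or default_catalog()
    birth = dict(zip(participants["participant_id"], participants["birth_year"].astype(int)))

    py = _attach_types(_period_years(periods), catalog)
    py["age"] = py["year"] - py["participant_id"].map(birth)
    py["age_group"] = py["age"].map(age_group)
    py = py.dropna(subset=["age_group"])
    active = (
        py.groupby(["year", "age_group", "hc_class"])["participant_id"]
        .nunique()
        .rename("n_active_users")
        .reset_index()
    )

    if denominators is None:
        years = range(int(py["year"].min()), int(py["year"].max()) + 1)
        byear = participants["birth_year"].astype(int).to_numpy()
        denom_rows = []
        for year in years:
            ages = year - byear
            groups = pd.Series([age_group(a) for a in ages])
            counts = groups.value_counts()
            for g in AGE_GROUPS:
                denom_rows.append({"year": year, "age_group": g, "n": int(counts.get(g, 0))})
        denominators = pd.DataFrame(denom_rows)

    out = active.merge(denominators.rename(columns={"n": "n_denominator"}),
                       on=["year", "age_group"], how="left")
    if out["n_denominator"].isna().any():
        missing = out.loc[out["n_denominator"].isna(), ["year", "age_group"]].iloc[0]
        raise KeyError(f"missing denominator cell for {tuple(missing)}")
    out["prevalence"] = out["n_active_users"] / out["n_denominator"]
    return out.sort_values(["year", "age_group", "hc_class"]).reset_index(drop=True)


def covered_days_shares(
    periods: pd.DataFrame, catalog: Optional[FormulationCatalog] = None,
    participants: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Share of total covered days by HC type per (year, age group).

    Without ``participants`` the age stratification is skipped (one
    "all" stratum per year).
    """
    catalog = catalog or default_catalog()
    py = _attach_types(_period_years(periods), catalog)
    if participants is not None:
        birth = dict(zip(participants["participant_id"], participants["birth_year"].astype(int)))
        py["age_group"] = (py["year"] - py["participant_id"].map(birth)).map(age_group)
        py = py.dropna(subset=["age_group"])
    else:
        py["age_group"] = "all"
    agg = (
        py.groupby(["year", "age_group", "hc_type"])["overlap_days"]
        .sum()
        .rename("covered_days")
        .reset_index()
    )
    totals = agg.groupby(["year", "age_group"])["covered_days"].transform("sum")
    agg["share_of_total"] = agg["covered_days"] / totals
    return agg


def initiator_summary(
    first_periods: pd.DataFrame,
    participants: pd.DataFrame,
    bmi_records: Optional[pd.DataFrame] = None,
    catalog: Optional[FormulationCatalog] = None,
) -> dict:
    """Descriptives of HC initiators (first observed usage period).

    Returns a dict with age statistics (mean/SD/median/IQR/mode at first
    purchase), per-year HC-type shares among initiators, and the
    BMI-category breakdown using the BMI record closest to the first
    period start.
    """
    catalog = catalog or default_catalog()
    birth = dict(zip(participants["participant_id"], participants["birth_year"].astype(int)))
    fp = first_periods.copy()
    fp["age_at_first"] = fp["first_purchase_date"].dt.year - fp["participant_id"].map(birth)

    ages = fp["age_at_first"].astype(int)
    age_stats = {
        "mean": float(ages.mean()),
        "sd": float(ages.std(ddof=1)) if len(ages) > 1 else 0.0,
        "median": float(ages.median()),
        "q1": float(ages.quantile(0.25)),
        "q3": float(ages.quantile(0.75)),
        "mode": int(ages.mode().iloc[0]),
    }

    fp = _attach_types(fp, catalog)
    fp["year"] = fp["start_date"].dt.year
    yearly = (
        fp.groupby(["year", "hc_type"])["participant_id"].size().rename("count").reset_index()
    )
    yearly["share"] = yearly["count"] / yearly.groupby("year")["count"].transform("sum")
    class_share = fp["hc_class"].value_counts(normalize=True).to_dict()

    bmi_shares: dict = {}
    if bmi_records is not None and len(bmi_records):
        by_pid = dict(tuple(bmi_records.groupby("participant_id")))
        cats = []
        for r in fp.itertuples(index=False):
            _, cat = closest_bmi(by_pid.get(r.participant_id), r.start_date)
            cats.append(cat)
        bmi_shares = pd.Series(cats).value_counts(normalize=True).to_dict()

    return {
        "n_initiators": len(fp),
        "age": age_stats,
        "hc_class_shares": class_share,
        "hc_type_shares_by_year": yearly,
        "bmi_category_shares": bmi_shares,
    }


def monthly_deviation_ratios(
    purchases: pd.DataFrame, year: int, baseline: str = "year"
) -> np.ndarray:
    """Ratio of each month's purchase count to the mean monthly count.

    ``baseline="year"`` divides by that year's mean monthly count
    (total/12); ``baseline="pooled"`` divides by the mean monthly count
    over all years present in ``purchases``.
    """
    dates = pd.to_datetime(purchases["purchase_date"])
    in_year = dates[dates.dt.year == year]
    if len(in_year) == 0:
        raise ValueError(f"no purchases in year {year}")
    counts = in_year.dt.month.value_counts().reindex(range(1, 13), fill_value=0)
    if baseline == "year":
        mean = counts.sum() / 12.0
    elif baseline == "pooled":
        n_years = dates.dt.year.nunique()
        mean = len(dates) / (12.0 * n_years)
    else:
        raise ValueError("baseline must be 'year' or 'pooled'")
    return (counts / mean).to_numpy()
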