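"""Purchase-record filtering cascade.

Raw pharmacy invoices become analysis-eligible records through five steps,
applied in this fixed order:

1. keep hormonal-contraceptive purchases (ATC level 3 ``G02B``/``G03A`` or
   level 5 ``G03HB01``), dropping emergency contraceptives (``G03AD``);
2. drop records whose prescribed and purchased ATC codes differ (a missing
   code counts as a mismatch — the match cannot be affirmed);
3. drop short-acting records with dosage < 0.3 or > 6 packages (bounds
   inclusive: 0.3 and 6 are retained); long-acting records are never
   dropped here; missing dosages are dropped and counted separately;
4. drop records where age at purchase (purchase year minus birth year) is
   outside 15-55, bounds inclusive;
5. drop *individuals* whose BMI record closest to their first retained
   purchase date is outside 14.0-43.0 (bounds inclusive); individuals with
   no BMI record are retained.

Each step emits a :class:`FilterStep` and the cascade a
:class:`FilterReport` whose removals sum exactly to input minus output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .catalog import FormulationCatalog, default_catalog
from .registry import CodeRegistry, default_registry

__all__ = [
    "FilterStep",
    "FilterReport",
    "PreparedData",
    "select_hc_purchases",
    "filter_atc_mismatch",
    "filter_dosage",
    "filter_age_at_purchase",
    "filter_bmi_eligibility",
    "closest_bmi",
    "bmi_category",
    "prepare_purchases",
]

BMI_MISSING = "missing"


@dataclass(frozen=True)
class FilterStep:
    name: str
    n_in: int
    n_removed: int
    n_out: int
    detail: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_in - self.n_removed != self.n_out:
            raise ValueError(f"filter step {self.name}: counts do not reconcile")


@dataclass
class FilterReport:
    steps: list[FilterStep] = field(default_factory=list)

    def add(self, step: FilterStep) -> None:
        self.steps.append(step)

    @property
    def n_input(self) -> int:
        return self.steps[0].n_in if self.steps else 0

    @property
    def n_output(self) -> int:
        return self.steps[-1].n_out if self.steps else 0

    @property
    def total_removed(self) -> int:
        return sum(s.n_removed for s in self.steps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"step": s.name, "n_in": s.n_in, "n_removed": s.n_removed, "n_out": s.n_out}
                for s in self.steps
            ]
        )

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "step": s.name,
                    "n_in": s.n_in,
                    "n_removed": s.n_removed,
                    "n_out": s.n_out,
                    "detail": s.detail,
                }
                for s in self.steps
            ],
            indent=2,
        )


@dataclass
class PreparedData:
    purchases: pd.DataFrame
    participants: pd.DataFrame
    report: FilterReport
    excluded_participants: list = field(default_factory=list)


def _norm_atc(series: pd.Series) -> pd.Series:
    return series.astype("string").str.strip().str.upper()


def select_hc_purchases(
    purchases: pd.DataFrame, registry: Optional[CodeRegistry] = None
) -> pd.DataFrame:
    """Keep hormonal-contraceptive purchases; drop emergency contraceptives."""
    registry = registry or default_registry()
    code = _norm_atc(purchases["purchased_atc"]).fillna("")
    level3 = registry.prefixes("hc_level3")
    exact = registry.prefixes("hc_exact")
    emergency = registry.prefixes("emergency_contraceptive")
    keep = (
        code.str.startswith(level3) | code.str.startswith(exact)
    ) & ~code.str.startswith(emergency)
    return purchases.loc[keep.to_numpy()].copy()


def filter_atc_mismatch(purchases: pd.DataFrame) -> tuple[pd.DataFrame, FilterStep]:
    presc = _norm_atc(purchases["prescribed_atc"])
    purch = _norm_atc(purchases["purchased_atc"])
    keep = (presc == purch) & presc.notna() & purch.notna()
    keep = keep.fillna(False).to_numpy()
    out = purchases.loc[keep].copy()
    step = FilterStep("atc_mismatch", len(purchases), int((~keep).sum()), len(out))
    return out, step


def filter_dosage(
    purchases: pd.DataFrame,
    catalog: Optional[FormulationCatalog] = None,
    bounds: tuple[float, float] = (0.3, 6.0),
) -> tuple[pd.DataFrame, FilterStep]:
    catalog = catalog or default_catalog()
    lo, hi = bounds
    short_by_code = {
        code: catalog.lookup(code).is_short_acting
        for code in purchases["purchased_atc"].unique()
    }
    short = purchases["purchased_atc"].map(short_by_code).to_numpy(dtype=bool)
    dosage = pd.to_numeric(purchases["dosage"], errors="coerce")
    missing = dosage.isna().to_numpy()
    out_of_range = ((dosage < lo) | (dosage > hi)).fillna(False).to_numpy()
    drop = short & (out_of_range | missing)
    out = purchases.loc[~drop].copy()
    step = FilterStep(
        "dosage_out_of_range",
        len(purchases),
        int(drop.sum()),
        len(out),
        detail={"n_missing_dosage": int((short & missing).sum())},
    )
    return out, step


def filter_age_at_purchase(
    purchases: pd.DataFrame,
    participants: pd.DataFrame,
    bounds: tuple[int, int] = (15, 55),
) -> tuple[pd.DataFrame, FilterStep]:
    lo, hi = bounds
    birth = participants.set_index("participant_id")["birth_year"]
    by = purchases["participant_id"].map(birth)
    if by.isna().any():
        unknown = purchases.loc[by.isna(), "participant_id"].unique()[:5]
        raise KeyError(f"purchases reference unknown participants, e.g. {list(unknown)}")
    age = pd.to_datetime(purchases["purchase_date"]).dt.year - by.astype(int)
    keep = ((age >= lo) & (age <= hi)).to_numpy()
    out = purchases.loc[keep].copy()
    step = FilterStep("age_at_purchase", len(purchases), int((~keep).sum()), len(out))
    return out, step


def bmi_category(value: float) -> str:
    """CDC adult BMI category with left-closed upper classes."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return BMI_MISSING
    if value < 18.5:
        return "underweight"
    if value < 25.0:
        return "healthy_weight"
    if value < 30.0:
        return "overweight"
    return "obese"


def closest_bmi(
    bmi_records: pd.DataFrame, reference_date: pd.Timestamp
) -> tuple[float, str]:
    """BMI record closest in time to ``reference_date``.

    Ties in absolute distance resolve to the earlier-dated record
    (deterministic, and it favours the pre-exposure measurement).  With no
    records, returns ``(nan, "missing")``.
    """
    if bmi_records is None or len(bmi_records) == 0:
        return (math.nan, BMI_MISSING)
    dates = pd.to_datetime(bmi_records["date"])
    dist = (dates - pd.Timestamp(reference_date)).abs()
    order = pd.DataFrame({"dist": dist.values, "date": dates.values, "bmi": bmi_records["bmi"].values})
    order = order.sort_values(["dist", "date"], kind="stable")
    value = float(order.iloc[0]["bmi"])
    return value, bmi_category(value)


def filter_bmi_eligibility(
    participants: pd.DataFrame,
    purchases: pd.DataFrame,
    bmi_records: pd.DataFrame,
    bounds: tuple[float, float] = (14.0, 43.0),
) -> tuple[pd.DataFrame, pd.DataFrame, FilterStep]:
    """Individual-level BMI eligibility against the first usage-period start.

    The first usage period of a participant starts at her earliest retained
    purchase date, so the reference date needs no period construction.
    Individuals whose closest BMI lies outside ``bounds`` lose all their
    records; individuals without any BMI record are retained.
    """
    lo, hi = bounds
    first_purchase = (
        pd.to_datetime(purchases["purchase_date"])
        .groupby(purchases["participant_id"])
        .min()
        .rename("reference_date")
    )
    excluded: list = []
    if len(bmi_records):
        merged = bmi_records.merge(
            first_purchase, left_on="participant_id", right_index=True, how="inner"
        )
        merged["date"] = pd.to_datetime(merged["date"])
        merged["dist"] = (merged["date"] - merged["reference_date"]).abs()
        # closest record per participant; equidistant ties -> earlier date
        closest = (
            merged.sort_values(["participant_id", "dist", "date"], kind="stable")
            .drop_duplicates("participant_id", keep="first")
        )
        bad = closest[(closest["bmi"] < lo) | (closest["bmi"] > hi)]
        excluded = sorted(bad["participant_id"])
    excluded_set = set(excluded)
    keep = ~purchases["participant_id"].isin(excluded_set).to_numpy()
    out_purchases = purchases.loc[keep].copy()
    out_participants = participants.loc[
        ~participants["participant_id"].isin(excluded_set)
    ].copy()
    step = FilterStep(
        "bmi_out_of_range",
        len(purchases),
        int((~keep).sum()),
        len(out_purchases),
        detail={"n_individuals_removed": len(excluded)},
    )
    return out_participants, out_purchases, step


def prepare_purchases(
    purchases: pd.DataFrame,
    participants: pd.DataFrame,
    bmi_records: pd.DataFrame,
    catalog: Optional[FormulationCatalog] = None,
    registry: Optional[CodeRegistry] = None,
    dosage_bounds: tuple[float, float] = (0.3, 6.0),
    age_bounds: tuple[int, int] = (15, 55),
    bmi_bounds: tuple[float, float] = (14.0, 43.0),
) -> PreparedData:
    """Run the full filtering cascade in its fixed order."""
    catalog = catalog or default_catalog()
    report = FilterReport()

    selected = select_hc_purchases(purchases, registry=registry)
    report.add(
        FilterStep("non_hc_atc", len(purchases), len(purchases) - len(selected), len(selected))
    )
    matched, step = filter_atc_mismatch(selected)
    report.add(step)
    dosed, step = filter_dosage(matched, catalog, bounds=dosage_bounds)
    report.add(step)
    aged, step = filter_age_at_purchase(dosed, participants, bounds=age_bounds)
    report.add(step)
    kept_participants, kept, step = filter_bmi_eligibility(
        participants, aged, bmi_records, bounds=bmi_bounds
    )
    report.add(step)
    excluded = sorted(
        set(aged["participant_id"]) - set(kept["participant_id"])
    )
    return PreparedData(
        purchases=kept.reset_index(drop=True),
        participants=kept_participants.reset_index(drop=True),
        report=report,
        excluded_participants=excluded,
    )
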