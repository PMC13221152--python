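"""Thromboembolism risk-factor assessment for index-year contraceptive
users.

Users with at least one HC purchase in the index year (2022 in the
reference analysis) are split into CHC and POC groups by the class of
their *first* purchase that year; that purchase's date is the index date.
Fifteen risk factors are then assessed per user:

* seven fixed factors — age > 35 in the index year (year arithmetic),
  obesity (closest BMI >= 30), migraine, purchase of risk-increasing
  medication (ATC H02 corticosteroids / N05A antipsychotics / N06A
  antidepressants) in the two-year window, carrier status for Factor V
  Leiden (rs6025) or prothrombin G20210A (rs1799963), personal
  thromboembolism history (whole history before the index date), family
  thromboembolism history (any first-degree relative diagnosed before the
  index date);
* eight configurable condition factors, by default hypertension,
  hyperlipidaemia, diabetes, pneumonia, cardiovascular disease, cancer,
  smoking-related disorders, and other thrombosis-risk conditions,
  resolved against registry code sets of the same names.

Condition and medication factors look back over the closed two-year
window [index - 730 days, index].  Group prevalences are compared with
prevalence ratios (POC as reference), Fisher p-values and a Bonferroni
correction across the 15 factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import math

import pandas as pd

from .catalog import FormulationCatalog, default_catalog
from .prepare import closest_bmi
from .registry import CodeRegistry, atc_matches, default_registry
from .stats import FourfoldTable, bonferroni, fisher_exact, odds_ratio, prevalence_ratio, proportion_ci

__all__ = [
    "CarrierStatus",
    "RiskProfile",
    "read_genotypes_vcf",
    "DEFAULT_CONDITION_FACTORS",
    "FIXED_FACTORS",
    "carrier_status",
    "index_year_groups",
    "assess_risk_factors",
    "factor_prevalence_comparison",
    "family_history_vs_carrier",
    "carrier_thrombosis_association",
]

LOOKBACK_DAYS = 730

FIXED_FACTORS = (
    "age_over_35",
    "obesity",
    "migraine",
    "risk_medication",
    "carrier",
    "personal_vte_ate_history",
    "family_vte_ate_history",
)

#: Registry code-set names of the eight default condition factors.
DEFAULT_CONDITION_FACTORS = (
    "hypertension",
    "hyperlipidaemia",
    "diabetes",
    "pneumonia",
    "cardiovascular_disease",
    "cancer",
    "smoking_related",
    "other_thrombosis_risk",
)

_MIGRAINE_CATEGORY = "G43"


@dataclass(frozen=True)
class CarrierStatus:
    fvl_carrier: Optional[bool]
    ptm_carrier: Optional[bool]

    @property
    def any_carrier(self) -> Optional[bool]:
        if self.fvl_carrier is None and self.ptm_carrier is None:
            return None
        return bool(self.fvl_carrier) or bool(self.ptm_carrier)


def carrier_status(fvl_copies, ptm_copies) -> CarrierStatus:
    """Carrier = at least one alternate allele; imputed decimal dosages
    threshold at 0.5 copies; missing genotypes stay missing."""

    def one(copies):
        if copies is None or (isinstance(copies, float) and math.isnan(copies)):
            return None
        return float(copies) >= 0.5

    return CarrierStatus(one(fvl_copies), one(ptm_copies))


def read_genotypes_vcf(
    path, fvl_rsid: str = "rs6025", ptm_rsid: str = "rs1799963"
) -> pd.DataFrame:
    """Read per-participant allele copies for the two risk variants from a
    VCF.

    Matches records by rsID; prefers imputed dosages (FORMAT ``DS``) and
    falls back to hard genotype calls.  Sample names are taken as
    participant ids.  Variants absent from the file yield missing copies.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    copies = {fvl_rsid: [math.nan] * len(samples), ptm_rsid: [math.nan] * len(samples)}
    wanted = set(copies)
    for variant in vcf:
        if variant.ID not in wanted:
            continue
        ds = None
        try:
            ds = variant.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            values = [float(v) for v in ds.reshape(-1)]
        else:
            # gt_types codes: 0=hom-ref 1=het 2=unknown 3=hom-alt
            values = []
            for g in variant.gt_types:
                if g == 0:
                    values.append(0.0)
                elif g == 1:
                    values.append(1.0)
                elif g == 3:
                    values.append(2.0)
                else:
                    values.append(math.nan)
        copies[variant.ID] = values
    return pd.DataFrame(
        {
            "participant_id": samples,
            "fvl_copies": copies[fvl_rsid],
            "ptm_copies": copies[ptm_rsid],
        }
    )


@dataclass
class RiskProfile:
    participant_id: object
    group: str               # "CHC" | "POC"
    index_date: pd.Timestamp
    factors: dict = field(default_factory=dict)


def index_year_groups(
    purchases: pd.DataFrame,
    year: int,
    catalog: Optional[FormulationCatalog] = None,
) -> list[RiskProfile]:
    """Profile skeletons for users with >= 1 HC purchase in ``year``.

    The group is the HC class of the chronologically first purchase of the
    year (ties on the same day resolve by input order).
    """
    catalog = catalog or default_catalog()
    df = purchases.copy()
    df["purchase_date"] = pd.to_datetime(df["purchase_date"])
    df = df[df["purchase_date"].dt.year == year]
    if len(df) == 0:
        return []
    df = df.sort_values("purchase_date", kind="stable")
    out = []
    for pid, grp in df.groupby("participant_id", sort=True):
        first = grp.iloc[0]
        spec = catalog.lookup(first["purchased_atc"])
        out.append(
            RiskProfile(
                participant_id=pid,
                group=spec.hc_class,
                index_date=first["purchase_date"],
            )
        )
    return out


def assess_risk_factors(
    profile: RiskProfile,
    diagnoses: pd.DataFrame,
    purchases: pd.DataFrame,
    participant: pd.Series | dict,
    relative_diagnoses: Optional[pd.DataFrame] = None,
    bmi_records: Optional[pd.DataFrame] = None,
    registry: Optional[CodeRegistry] = None,
    condition_factors=DEFAULT_CONDITION_FACTORS,
    lookback_days: int = LOOKBACK_DAYS,
) -> RiskProfile:
    """Populate the 15-factor map of one profile skeleton.

    ``diagnoses``/``purchases`` are the participant's own records;
    ``relative_diagnoses`` pools all records of her first-degree
    relatives.  A missing genotype leaves the carrier factor ``None`` so
    it can be excluded from that factor's denominators.
    """
    registry = registry or default_registry()
    index = pd.Timestamp(profile.index_date)
    lo = index - pd.Timedelta(days=lookback_days)

    dx = diagnoses.copy() if len(diagnoses) else pd.DataFrame(columns=["date", "icd10"])
    if len(dx):
        dx["date"] = pd.to_datetime(dx["date"])
    in_window = dx[(dx["date"] >= lo) & (dx["date"] <= index)] if len(dx) else dx

    factors: dict = {}
    birth_year = int(participant["birth_year"])
    factors["age_over_35"] = (index.year - birth_year) > 35

    bmi_value, _ = closest_bmi(bmi_records, index) if bmi_records is not None else (math.nan, "missing")
    factors["obesity"] = bool(bmi_value >= 30.0) if not math.isnan(bmi_value) else False

    migraine_set = registry.code_sets.get("migraine")
    if migraine_set is not None:
        factors["migraine"] = any(c in migraine_set for c in in_window["icd10"]) if len(in_window) else False
    else:
        factors["migraine"] = (
            any(str(c).upper().startswith(_MIGRAINE_CATEGORY) for c in in_window["icd10"])
            if len(in_window)
            else False
        )

    meds = registry.prefixes("risk_medications")
    med_flag = False
    if purchases is not None and len(purchases):
        pp = purchases.copy()
        pp["purchase_date"] = pd.to_datetime(pp["purchase_date"])
        pp = pp[(pp["purchase_date"] >= lo) & (pp["purchase_date"] <= index)]
        med_flag = any(atc_matches(c, meds) for c in pp["purchased_atc"])
    factors["risk_medication"] = med_flag

    status = carrier_status(participant.get("fvl_copies"), participant.get("ptm_copies"))
    factors["carrier"] = status.any_carrier

    vte = registry.codeset("vte_ate")
    personal = False
    if len(dx):
        before = dx[dx["date"] < index]
        personal = any(c in vte for c in before["icd10"])
    factors["personal_vte_ate_history"] = personal

    family = False
    if relative_diagnoses is not None and len(relative_diagnoses):
        rdx = relative_diagnoses.copy()
        rdx["date"] = pd.to_datetime(rdx["date"])
        before = rdx[rdx["date"] < index]
        family = any(c in vte for c in before["icd10"])
    factors["family_vte_ate_history"] = family

    for name in condition_factors:
        cset = registry.codeset(name)
        factors[name] = any(c in cset for c in in_window["icd10"]) if len(in_window) else False

    profile.factors = factors
    return profile


def _profiles_frame(profiles) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"participant_id": p.participant_id, "group": p.group, "index_date": p.index_date}
        row.update(p.factors)
        rows.append(row)
    return pd.DataFrame(rows)


def factor_prevalence_comparison(profiles, m: Optional[int] = None) -> pd.DataFrame:
    """Per-factor CHC vs. POC comparison (POC is the reference group).

    Returns counts, within-group percentages, the prevalence ratio with
    Katz 95% CI, the Fisher p-value and Bonferroni-adjusted p across the
    factor roster (m defaults to the number of factors).
    """
    df = _profiles_frame(profiles)
    if (df["group"] == "CHC").sum() == 0 or (df["group"] == "POC").sum() == 0:
        raise ValueError("both CHC and POC groups must be non-empty")
    factor_names = [c for c in df.columns if c not in ("participant_id", "group", "index_date")]
    m = m or len(factor_names)
    rows = []
    for name in factor_names:
        sub = df[df[name].notna()]
        chc = sub[sub["group"] == "CHC"][name].astype(bool)
        poc = sub[sub["group"] == "POC"][name].astype(bool)
        t = FourfoldTable(int(chc.sum()), int((~chc).sum()), int(poc.sum()), int((~poc).sum()))
        pr = prevalence_ratio(t, continuity=True)
        p = fisher_exact(t)
        rows.append(
            {
                "factor": name,
                "n_chc": int(len(chc)),
                "n_chc_with_factor": t.a,
                "pct_chc": 100.0 * t.a / len(chc),
                "n_poc": int(len(poc)),
                "n_poc_with_factor": t.c,
                "pct_poc": 100.0 * t.c / len(poc),
                "pr": pr.estimate,
                "pr_ci_low": pr.ci_low,
                "pr_ci_high": pr.ci_high,
                "p_raw": p,
            }
        )
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = bonferroni(out["p_raw"].tolist(), m=m)
    return out


def family_history_vs_carrier(profiles) -> dict:
    """Family history of thromboembolism as a proxy for carrier status.

    Restricted to users whose family-history factor could be evaluated
    against at least one first-degree relative (callers pass only those
    profiles) and whose carrier status is known.  Returns the 2x2 table,
    the odds ratio with Woolf CI and Fisher p, and the
    sensitivity/specificity of family history for identifying carriers
    with Wald CIs (sensitivity is missing when there are no carriers).
    """
    df = _profiles_frame(profiles)
    df = df[df["carrier"].notna()]
    fh = df["family_vte_ate_history"].astype(bool)
    ca = df["carrier"].astype(bool)
    t = FourfoldTable(
        int((fh & ca).sum()),
        int((fh & ~ca).sum()),
        int((~fh & ca).sum()),
        int((~fh & ~ca).sum()),
    )
    orr = odds_ratio(t)
    n_carrier = t.a + t.c
    n_noncarrier = t.b + t.d
    sens = proportion_ci(t.a, n_carrier) if n_carrier else None
    spec = proportion_ci(t.d, n_noncarrier) if n_noncarrier else None
    return {
        "table": t,
        "odds_ratio": orr,
        "p": fisher_exact(t),
        "sensitivity": sens,
        "specificity": spec,
    }


def carrier_thrombosis_association(
    participants: pd.DataFrame,
    diagnoses: pd.DataFrame,
    registry: Optional[CodeRegistry] = None,
) -> dict:
    """Thromboembolism at any time in carriers vs. non-carriers.

    Also reports the carrier breakdown (FVL only / PTM only / both / any)
    among participants with known genotypes.
    """
    registry = registry or default_registry()
    vte = registry.codeset("vte_ate")
    dx = diagnoses.copy()
    if len(dx):
        event_pids = set(dx.loc[[c in vte for c in dx["icd10"]], "participant_id"])
    else:
        event_pids = set()

    fvl = pd.to_numeric(participants["fvl_copies"], errors="coerce")
    ptm = pd.to_numeric(participants["ptm_copies"], errors="coerce")
    known = fvl.notna() & ptm.notna()
    fvl_c = (fvl >= 0.5) & known
    ptm_c = (ptm >= 0.5) & known
    any_c = fvl_c | ptm_c

    breakdown = {
        "n_genotyped": int(known.sum()),
        "fvl_only": int((fvl_c & ~ptm_c).sum()),
        "ptm_only": int((ptm_c & ~fvl_c).sum()),
        "both": int((fvl_c & ptm_c).sum()),
        "any": int(any_c.sum()),
    }
    breakdown["any_pct"] = (
        100.0 * breakdown["any"] / breakdown["n_genotyped"] if breakdown["n_genotyped"] else math.nan
    )

    has_event = participants["participant_id"].isin(event_pids)
    a = int((any_c & has_event & known).sum())
    b = int((any_c & ~has_event & known).sum())
    c = int((~any_c & has_event & known).sum())
    d = int((~any_c & ~has_event & known).sum())
    t = FourfoldTable(a, b, c, d)
    orr = odds_ratio(t) if breakdown["any"] else None
    return {
        "table": t,
        "odds_ratio": orr,
        "p": fisher_exact(t) if breakdown["any"] else None,
        "carrier_breakdown": breakdown,
        "pct_events_carriers": 100.0 * a / (a + b) if (a + b) else math.nan,
        "pct_events_noncarriers": 100.0 * c / (c + d) if (c + d) else math.nan,
    }
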